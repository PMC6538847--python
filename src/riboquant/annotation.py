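"""Genome and annotation input: ORF models, protein masses, motif counting.

Reads a genome FASTA and a GFF3 annotation into a simple ORF model suited
to bacterial single-span CDS features, computes average-isotopic protein
molecular weights, and counts degenerate (IUPAC) DNA motifs such as the
CcrM methylation site GANTC.

Coordinates are 0-based half-open internally; GFF3 I/O converts from and
to the file format's 1-based inclusive convention.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import gffutils
from Bio import SeqIO
from Bio.Data.IUPACData import protein_weights
from Bio.Seq import Seq
from Bio.SeqUtils import molecular_weight as _bio_molecular_weight

logger = logging.getLogger(__name__)

VALID_BASES = set("ACGTN")

#: IUPAC nucleotide codes mapped to the concrete bases they stand for.
IUPAC_CODES: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}


@dataclass
class Genome:
    """A set of chromosomes, id -> uppercase A/C/G/T/N sequence."""

    chromosomes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, seq in self.chromosomes.items():
            if not seq:
                raise ValueError(f"chromosome {name!r} has an empty sequence")
            bad = set(seq) - VALID_BASES
            if bad:
                raise ValueError(
                    f"chromosome {name!r} contains non-ACGTN characters: {sorted(bad)}"
                )

    def __getitem__(self, name: str) -> str:
        return self.chromosomes[name]

    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.chromosomes.items()}


@dataclass(frozen=True)
class Orf:
    """An annotated coding region.

    ``start``/``end`` are 0-based half-open nucleotide coordinates on the
    chromosome; the span includes the stop codon, which never contributes
    a protein residue. ``mol_weight`` is the average-isotopic protein mass
    in daltons with the N-terminal residue retained.
    """

    locus_tag: str
    chromosome: str
    start: int
    end: int
    strand: str
    protein_sequence: str
    mol_weight: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"{self.locus_tag}: end must exceed start")
        if (self.end - self.start) % 3 != 0:
            raise ValueError(f"{self.locus_tag}: length not divisible by 3")
        if self.strand not in "+-":
            raise ValueError(f"{self.locus_tag}: strand must be + or -")

    @property
    def length_nt(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class MotifCount:
    chromosome: str
    motif: str
    count: int
    positions: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.count != len(self.positions):
            raise ValueError("count must equal the number of positions")
        if any(b >= a for a, b in zip(self.positions[1:], self.positions)):
            raise ValueError("positions must be strictly increasing")


def read_genome(fasta_path) -> Genome:
    """Read a FASTA file into a :class:`Genome`, uppercasing sequences."""
    chromosomes: dict[str, str] = {}
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        if record.id in chromosomes:
            raise ValueError(f"duplicate FASTA record id {record.id!r}")
        chromosomes[record.id] = str(record.seq).upper()
    if not chromosomes:
        raise ValueError(f"no FASTA records found in {fasta_path}")
    return Genome(chromosomes)


def protein_molecular_weight(protein_sequence: str) -> float:
    """Average-isotopic molecular weight of a protein, in daltons.

    The mass is the sum of average residue masses plus one water
    (18.0153 Da); the N-terminal methionine is not excised. Stop
    characters must be stripped by the caller.
    """
    if not protein_sequence:
        raise ValueError("empty protein sequence")
    for i, aa in enumerate(protein_sequence):
        if aa not in protein_weights:
            raise ValueError(
                f"unknown amino-acid character {aa!r} at position {i}"
            )
    return _bio_molecular_weight(protein_sequence, seq_type="protein")


def read_annotation(gff_path, genome: Genome) -> list[Orf]:
    """Parse CDS features from a GFF3 file into :class:`Orf` records.

    GFF coordinates (1-based inclusive) are converted to 0-based
    half-open. Proteins are translated from the genome with the
    bacterial code (reverse-complemented for the minus strand) and the
    trailing stop removed. Features whose length is not a multiple of 3,
    that lack a locus_tag, or that contain an internal stop codon are
    skipped with a warning.
    """
    db = gffutils.create_db(
        str(gff_path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    orfs: list[Orf] = []
    for feature in db.features_of_type("CDS", order_by=("seqid", "start")):
        tags = feature.attributes.get("locus_tag")
        if not tags:
            logger.warning("CDS at %s:%s-%s has no locus_tag; skipped",
                           feature.seqid, feature.start, feature.end)
            continue
        locus_tag = tags[0]
        start, end = feature.start - 1, feature.end  # to 0-based half-open
        if (end - start) % 3 != 0:
            logger.warning("%s: CDS length %d not divisible by 3; skipped",
                           locus_tag, end - start)
            continue
        nt = genome[feature.seqid][start:end]
        if feature.strand == "-":
            nt = str(Seq(nt).reverse_complement())
        protein = str(Seq(nt).translate(table=11))
        if protein.endswith("*"):
            protein = protein[:-1]
        if "*" in protein:
            logger.warning("%s: internal stop codon; skipped", locus_tag)
            continue
        orfs.append(Orf(
            locus_tag=locus_tag,
            chromosome=feature.seqid,
            start=start,
            end=end,
            strand=feature.strand,
            protein_sequence=protein,
            mol_weight=protein_molecular_weight(protein),
        ))
    return orfs


def write_annotation(gff_path, orfs: list[Orf]) -> None:
    """Write ORFs back out as GFF3 CDS features (1-based inclusive)."""
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for orf in orfs:
            fh.write(
                f"{orf.chromosome}\triboquant\tCDS\t{orf.start + 1}\t{orf.end}\t"
                f".\t{orf.strand}\t0\tID={orf.locus_tag};locus_tag={orf.locus_tag}\n"
            )


def _iupac_regex(pattern: str) -> re.Pattern:
    classes = []
    for letter in pattern.upper():
        if letter not in IUPAC_CODES:
            raise ValueError(f"invalid IUPAC code {letter!r} in pattern")
        bases = IUPAC_CODES[letter]
        # genome N only ever matches a pattern N, never a concrete code
        if letter == "N":
            bases += "N"
        classes.append(f"[{bases}]")
    # lookahead so overlapping matches are all reported
    return re.compile("(?=" + "".join(classes) + ")")


def count_motif(genome: Genome, iupac_pattern: str) -> list[MotifCount]:
    """Count forward-strand matches of an IUPAC motif on each chromosome.

    Overlapping matches are all counted. For strand-palindromic motifs
    such as GANTC (whose reverse complement is itself) a forward-strand
    scan enumerates each physical double-stranded site exactly once.
    """
    regex = _iupac_regex(iupac_pattern)
    out = []
    for name, seq in genome.chromosomes.items():
        positions = tuple(m.start() for m in regex.finditer(seq))
        out.append(MotifCount(
            chromosome=name,
            motif=iupac_pattern.upper(),
            count=len(positions),
            positions=positions,
        ))
    return out
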