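"""Center-weighted footprint density tracks and per-ORF occupancy profiles.

Each accepted footprint alignment contributes unit weight to the genome,
spread uniformly over the central portion of the read after trimming a
fixed number of nucleotides from each end. The ends of a nuclease
footprint are positionally noisy, so only the center is informative about
where the ribosome sat; trimming 11 nt per end leaves >= 6 central
positions for the dominant ~28-nt footprints. Density is kept per
chromosome and per strand so overlapping genes on opposite strands do not
mix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pysam

from .annotation import Orf

logger = logging.getLogger(__name__)

DEFAULT_TRIM = 11
DEFAULT_MIN_LEN = 24
DEFAULT_MAX_LEN = 40
DEFAULT_EXCLUDE_NT = 15


@dataclass(frozen=True, slots=True)
class FootprintAlignment:
    """A mapped footprint: chromosome, 0-based start, span and strand."""

    chromosome: str
    start: int
    length: int
    strand: str


@dataclass
class DensityTrack:
    """Per-chromosome, per-strand arrays of weighted reads per nucleotide."""

    arrays: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)

    @classmethod
    def zeros(cls, chrom_lengths: dict[str, int]) -> "DensityTrack":
        return cls({
            (name, strand): np.zeros(length)
            for name, length in chrom_lengths.items()
            for strand in "+-"
        })

    def __getitem__(self, key: tuple[str, str]) -> np.ndarray:
        return self.arrays[key]

    def total(self) -> float:
        return float(sum(a.sum() for a in self.arrays.values()))

    def to_bedgraph(self, path, strand: str) -> None:
        """Export one strand as bedGraph (0-based half-open intervals)."""
        with open(path, "w") as fh:
            for (chrom, s), arr in self.arrays.items():
                if s != strand:
                    continue
                # run-length encode identical consecutive values
                change = np.flatnonzero(np.diff(arr) != 0) + 1
                starts = np.concatenate(([0], change))
                ends = np.concatenate((change, [arr.size]))
                for a, b in zip(starts, ends):
                    if arr[a] != 0:
                        fh.write(f"{chrom}\t{a}\t{b}\t{arr[a]:.6g}\n")


@dataclass
class OrfProfile:
    """Per-nucleotide weights along an ORF, 5'->3' on the coding strand.

    ``analysis_window`` is the (first, last-exclusive) index pair after
    start/stop exclusion; ``short_orf`` flags ORFs too short for the
    requested exclusion, for which the window falls back to the full ORF
    minus the start and stop codons.
    """

    locus_tag: str
    values: np.ndarray
    analysis_window: tuple[int, int]
    short_orf: bool = False

    @property
    def window_values(self) -> np.ndarray:
        a, b = self.analysis_window
        return self.values[a:b]


def load_alignments(path, min_len: int = DEFAULT_MIN_LEN,
                    max_len: int = DEFAULT_MAX_LEN) -> list[FootprintAlignment]:
    """Load mapped footprints from SAM/BAM, filtering by reference span.

    Unmapped, secondary and supplementary records are discarded, as are
    reads whose aligned span falls outside ``[min_len, max_len]``.
    """
    kept, dropped_flag, dropped_len = 0, 0, 0
    out: list[FootprintAlignment] = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                dropped_flag += 1
                continue
            span = rec.reference_length
            if span is None or not (min_len <= span <= max_len):
                dropped_len += 1
                continue
            out.append(FootprintAlignment(
                chromosome=rec.reference_name,
                start=rec.reference_start,
                length=span,
                strand="-" if rec.is_reverse else "+",
            ))
            kept += 1
    logger.info("loaded %d alignments (%d flag-filtered, %d length-filtered)",
                kept, dropped_flag, dropped_len)
    return out


def center_weights(read_length: int, trim: int = DEFAULT_TRIM):
    """Offsets and uniform weight for the central region of a read.

    Returns ``(offsets, weight)`` with offsets ``trim .. read_length -
    trim - 1`` and weight ``1 / (read_length - 2*trim)`` so the weights
    sum to one, or ``None`` if trimming leaves no central position.
    """
    n_center = read_length - 2 * trim
    if n_center < 1:
        return None
    return np.arange(trim, read_length - trim), 1.0 / n_center


def accumulate_density(alignments, chrom_lengths: dict[str, int],
                       trim: int = DEFAULT_TRIM) -> DensityTrack:
    """Accumulate center weights of all alignments into a density track.

    Each read adds total weight one; reads whose central region is empty
    after trimming, or that overhang the chromosome end, are skipped and
    counted. The grand total of the track equals the number of
    contributing reads (to float tolerance).
    """
    track = DensityTrack.zeros(chrom_lengths)
    skipped_short = skipped_bounds = 0

    by_group: dict[tuple[str, str, int], list[int]] = {}
    for aln in alignments:
        by_group.setdefault(
            (aln.chromosome, aln.strand, aln.length), []
        ).append(aln.start)

    for (chrom, strand, length), starts in by_group.items():
        cw = center_weights(length, trim)
        if cw is None:
            skipped_short += len(starts)
            logger.warning("%d reads of length %d have no central region "
                           "at trim %d; skipped", len(starts), length, trim)
            continue
        offsets, weight = cw
        starts_arr = np.asarray(starts)
        in_bounds = (starts_arr >= 0) & (starts_arr + length <= chrom_lengths[chrom])
        skipped_bounds += int((~in_bounds).sum())
        starts_arr = starts_arr[in_bounds]
        arr = track[chrom, strand]
        np.add.at(arr, (starts_arr[:, None] + offsets[None, :]).ravel(),
                  weight)
    if skipped_bounds:
        logger.warning("%d reads overhang a chromosome end; skipped",
                       skipped_bounds)
    return track


def orf_profile(track: DensityTrack, orf: Orf,
                exclude_nt: int = DEFAULT_EXCLUDE_NT) -> OrfProfile:
    """Extract an ORF's density profile, oriented 5'->3' on its strand.

    Index 0 is the first nucleotide of the start codon. The analysis
    window drops ``exclude_nt`` from each end to avoid initiation and
    termination peaks; ORFs too short for that fall back to excluding
    just the start and stop codons and are flagged.
    """
    values = track[orf.chromosome, orf.strand][orf.start:orf.end]
    if orf.strand == "-":
        values = values[::-1]
    length = orf.length_nt
    short = length <= 2 * exclude_nt + 30
    if short:
        window = (3, length - 3)
        logger.warning("%s: length %d too short for %d-nt exclusion; "
                       "using full ORF minus start/stop codons",
                       orf.locus_tag, length, exclude_nt)
    else:
        window = (exclude_nt, length - exclude_nt)
    return OrfProfile(locus_tag=orf.locus_tag, values=np.asarray(values),
                      analysis_window=window, short_orf=short)


def orf_profiles(track: DensityTrack, orfs,
                 exclude_nt: int = DEFAULT_EXCLUDE_NT) -> dict[str, OrfProfile]:
    """Profiles for a collection of ORFs, keyed by locus tag."""
    return {orf.locus_tag: orf_profile(track, orf, exclude_nt) for orf in orfs}
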