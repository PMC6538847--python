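"""Synthetic data with known ground truth for every pipeline stage.

The generator emulates the statistical structure of bacterial (MNase)
ribosome profiling on a high-GC alphaproteobacterial chromosome: a few
hundred non-overlapping ORFs on both strands, heavy-tailed (lognormal)
per-gene synthesis weights, ~28-nt footprints whose centers sample the
expected occupancy, positional pause spikes at a fraction of codons,
elevated start/stop-codon occupancy, and a residual rRNA-contamination
read fraction mapped to a designated non-CDS locus. Every generator is
deterministic under a fixed seed.

True per-gene footprint fractions (phi) derive from the baseline
synthesis weights only — pauses and start/stop peaks are the noise the
quantitation pipeline must remove.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .annotation import Genome, Orf, protein_molecular_weight, write_annotation
from .footprints import FootprintAlignment
from .quant import N_AVOGADRO

#: Cyanocobalamin grid (nM) used by the riboswitch reporter assay.
B12_CONCENTRATIONS_NM = (27.0, 2.7, 0.9, 0.3, 0.1, 0.033, 0.0)

#: Half-repression presets for the two B12 riboswitch reporters (nM).
K_HALF_METE_NM = 0.062
K_HALF_BTUB_NM = 0.19

#: Average protein mass per cell in M2G minimal medium, g/cell.
MASS_PER_CELL_M2G = 492e-15

_STOP_CODONS = {"TAA", "TAG", "TGA"}
_CHROM = "chr_sim"


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic ribosome-profiling dataset."""

    seed: int = 0
    n_orfs: int = 200
    orf_len_min: int = 300       # nt incl. stop codon, multiple of 3
    orf_len_mean: int = 900
    orf_len_max: int = 3000
    gc_fraction: float = 0.67
    sigma_log_weight: float = 1.5     # lognormal sigma on synthesis weights
    n_reads: int = 1_000_000
    read_len_mean: float = 28.0
    read_len_sd: float = 2.0
    read_len_min: int = 24
    read_len_max: int = 40
    pause_fraction: float = 0.05      # fraction of internal codons paused
    pause_multiplier: float = 10.0
    peak_multiplier: float = 3.0      # start/stop occupancy elevation
    peak_width_nt: int = 9
    rrna_contamination_fraction: float = 0.2
    spacer_mean_nt: int = 150
    rrna_locus_nt: int = 5000
    mass_per_cell_g: float = MASS_PER_CELL_M2G

    def __post_init__(self) -> None:
        if not (0 <= self.pause_fraction <= 1):
            raise ValueError("pause_fraction must be in [0, 1]")
        if not (0 <= self.rrna_contamination_fraction < 1):
            raise ValueError("rrna_contamination_fraction must be in [0, 1)")
        if not (0 < self.gc_fraction < 1):
            raise ValueError("gc_fraction must be in (0, 1)")
        if self.n_reads <= 0:
            raise ValueError("n_reads must be positive")
        if self.orf_len_min % 3 or self.orf_len_max % 3:
            raise ValueError("ORF length bounds must be multiples of 3")


@dataclass
class SimulatedGenome:
    genome: Genome
    orfs: list[Orf]
    rrna_interval: tuple[int, int]   # non-CDS contamination locus


@dataclass
class SimulatedReads:
    alignments: list[FootprintAlignment]
    truth: pd.DataFrame               # per gene: weight, true_phi, true_k
    n_contamination: int


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(np.array(list("ACGT")), size=n, p=p)


def _random_codons(rng: np.random.Generator, n: int, gc: float) -> list[str]:
    """n random sense codons at the target GC, stop codons rejected."""
    out: list[str] = []
    while len(out) < n:
        draw = _random_bases(rng, 3 * (n - len(out) + 8), gc)
        for i in range(0, len(draw) - 2, 3):
            codon = "".join(draw[i:i + 3])
            if codon not in _STOP_CODONS:
                out.append(codon)
                if len(out) == n:
                    break
    return out


def _draw_orf_lengths(rng: np.random.Generator, cfg: SimConfig) -> np.ndarray:
    """ORF lengths (nt, multiples of 3) from a moderately skewed gamma."""
    shape = 3.0
    scale = max(cfg.orf_len_mean - cfg.orf_len_min, 3) / shape
    raw = cfg.orf_len_min + rng.gamma(shape, scale, size=cfg.n_orfs)
    lengths = (np.rint(raw / 3).astype(int) * 3)
    return np.clip(lengths, cfg.orf_len_min, cfg.orf_len_max)


def simulate_genome(config: SimConfig) -> SimulatedGenome:
    """A single chromosome of non-overlapping ORFs plus an rRNA locus.

    ORFs are laid out left to right with random intergenic spacers,
    strand chosen at random; each is ATG + sense codons + TGA at the
    configured GC fraction, so annotation round-trips translate without
    internal stops.
    """
    rng = np.random.default_rng(config.seed)
    lengths = _draw_orf_lengths(rng, config)
    strands = rng.choice(np.array(["+", "-"]), size=config.n_orfs)

    parts: list[str] = []
    orfs: list[Orf] = []
    pos = 0
    for i in range(config.n_orfs):
        spacer = int(rng.integers(config.spacer_mean_nt // 2,
                                  config.spacer_mean_nt * 3 // 2 + 1))
        parts.append("".join(_random_bases(rng, spacer, config.gc_fraction)))
        pos += spacer
        n_codons = lengths[i] // 3 - 2
        coding = "ATG" + "".join(_random_codons(rng, n_codons,
                                                config.gc_fraction)) + "TGA"
        genomic = coding if strands[i] == "+" else str(Seq(coding).reverse_complement())
        parts.append(genomic)
        protein = str(Seq(coding).translate(table=11)).rstrip("*")
        orfs.append(Orf(
            locus_tag=f"SIM_{i:04d}", chromosome=_CHROM,
            start=pos, end=pos + lengths[i], strand=str(strands[i]),
            protein_sequence=protein,
            mol_weight=protein_molecular_weight(protein),
        ))
        pos += lengths[i]
    # trailing spacer, then the non-CDS rRNA contamination locus
    tail = int(rng.integers(config.spacer_mean_nt // 2,
                            config.spacer_mean_nt * 3 // 2 + 1))
    parts.append("".join(_random_bases(rng, tail, config.gc_fraction)))
    pos += tail
    rrna_interval = (pos, pos + config.rrna_locus_nt)
    parts.append("".join(_random_bases(rng, config.rrna_locus_nt, 0.55)))
    pos += config.rrna_locus_nt
    parts.append("".join(_random_bases(rng, 100, config.gc_fraction)))

    genome = Genome({_CHROM: "".join(parts)})
    return SimulatedGenome(genome, orfs, rrna_interval)


def draw_truth_weights(config: SimConfig,
                       rng: np.random.Generator) -> np.ndarray:
    """Heavy-tailed per-gene synthesis weights (per-nucleotide density)."""
    return rng.lognormal(mean=0.0, sigma=config.sigma_log_weight,
                         size=config.n_orfs)


def simulate_footprints(sim: SimulatedGenome, config: SimConfig,
                        weights: np.ndarray | None = None,
                        seed: int | None = None) -> SimulatedReads:
    """Sample footprint alignments from the expected occupancy landscape.

    Expected per-nucleotide occupancy of gene i is proportional to its
    synthesis weight, modulated by pause multipliers at randomly chosen
    internal codons and by start/stop peaks; read centers are drawn
    multinomially over positions, read lengths per read, and each read
    is placed so its center covers the sampled nucleotide.
    rRNA-contamination reads land uniformly in the designated non-CDS
    locus (on the plus strand, as a mapped contaminant).
    """
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    orfs = sim.orfs
    if weights is None:
        weights = draw_truth_weights(config, rng)
    weights = np.asarray(weights, dtype=float)

    chrom_len = len(sim.genome[_CHROM])
    occ = {"+": np.zeros(chrom_len), "-": np.zeros(chrom_len)}
    for orf, w in zip(orfs, weights):
        profile = np.full(orf.length_nt, w)
        n_internal = orf.length_nt // 3 - 2
        paused = np.flatnonzero(rng.random(n_internal) < config.pause_fraction)
        for c in paused:
            profile[3 * (c + 1):3 * (c + 2)] *= config.pause_multiplier
        pw = min(config.peak_width_nt, orf.length_nt // 2)
        profile[:pw] *= config.peak_multiplier
        profile[-pw:] *= config.peak_multiplier
        if orf.strand == "-":
            profile = profile[::-1]
        occ[orf.strand][orf.start:orf.end] += profile

    cds_total = occ["+"].sum() + occ["-"].sum()
    f = config.rrna_contamination_fraction
    a, b = sim.rrna_interval
    if f > 0:
        occ["+"][a:b] += cds_total * f / (1 - f) / (b - a)

    p = np.concatenate([occ["+"], occ["-"]])
    p /= p.sum()
    counts = rng.multinomial(config.n_reads, p)
    nz = np.flatnonzero(counts)
    centers = np.repeat(nz, counts[nz])
    strands = np.where(centers < chrom_len, "+", "-")
    centers = np.where(centers < chrom_len, centers, centers - chrom_len)

    lengths = np.rint(rng.normal(config.read_len_mean, config.read_len_sd,
                                 size=centers.size)).astype(int)
    lengths = np.clip(lengths, config.read_len_min, config.read_len_max)
    starts = np.clip(centers - (lengths - 1) // 2, 0, chrom_len - lengths)

    n_contam = int(((strands == "+") & (centers >= a) & (centers < b)).sum())
    alignments = [
        FootprintAlignment(_CHROM, int(s), int(l), str(st))
        for s, l, st in zip(starts, lengths, strands)
    ]

    length_nt = np.array([o.length_nt for o in orfs])
    mol_weight = np.array([o.mol_weight for o in orfs])
    true_phi = weights * length_nt / (weights * length_nt).sum()
    truth = pd.DataFrame({
        "locus_tag": [o.locus_tag for o in orfs],
        "weight": weights,
        "length_nt": length_nt,
        "mol_weight_da": mol_weight,
        "true_phi": true_phi,
        "true_k": true_phi * config.mass_per_cell_g * N_AVOGADRO / mol_weight,
        "expected_reads": (1 - f) * config.n_reads * weights * length_nt
        / (weights * length_nt).sum(),
    }).set_index("locus_tag")
    return SimulatedReads(alignments, truth, n_contam)


def write_fasta(genome: Genome, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.chromosomes.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_sam(alignments, chrom_lengths: dict[str, int], path) -> None:
    """Emit alignments as a minimal valid SAM file (ungapped, no SEQ)."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for name, length in chrom_lengths.items():
            fh.write(f"@SQ\tSN:{name}\tLN:{length}\n")
        for i, aln in enumerate(alignments):
            flag = 16 if aln.strand == "-" else 0
            fh.write(f"r{i}\t{flag}\t{aln.chromosome}\t{aln.start + 1}\t255\t"
                     f"{aln.length}M\t*\t0\t0\t*\t*\n")


def simulate_dose_response(k_half: float, i0: float, i_inf: float,
                           cv: float = 0.0,
                           concentrations=B12_CONCENTRATIONS_NM,
                           n_reps: int = 3, seed: int = 0) -> pd.DataFrame:
    """Replicate reporter intensities from the repression hyperbola with
    multiplicative lognormal noise of unit mean and the given CV."""
    from .dose_response import repression_model

    if cv < 0:
        raise ValueError("cv must be non-negative")
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(n_reps):
        for c in concentrations:
            mu = repression_model(c, i0, i_inf, k_half)
            if cv > 0:
                s = np.sqrt(np.log1p(cv ** 2))
                mu *= rng.lognormal(mean=-s ** 2 / 2, sigma=s)
            rows.append({"conc_nM": c, "intensity": float(mu),
                         "replicate": rep})
    return pd.DataFrame(rows)


def simulate_growth_curve(doubling_time_h: float, t_grid_h,
                          od0: float = 0.05, noise_cv: float = 0.0,
                          seed: int = 0) -> pd.DataFrame:
    """OD600 time series od0 * 2^(t/T_d) with multiplicative noise."""
    if doubling_time_h <= 0:
        raise ValueError("doubling time must be positive")
    rng = np.random.default_rng(seed)
    t = np.asarray(t_grid_h, dtype=float)
    od = od0 * 2.0 ** (t / doubling_time_h)
    if noise_cv > 0:
        s = np.sqrt(np.log1p(noise_cv ** 2))
        od = od * rng.lognormal(mean=-s ** 2 / 2, sigma=s, size=t.size)
    return pd.DataFrame({"time_h": t, "od600": od})


def simulate_dataset(config: SimConfig, outdir) -> SimulatedReads:
    """Write FASTA + GFF3 + SAM + truth TSV for a full synthetic study."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = simulate_genome(config)
    reads = simulate_footprints(sim, config)
    write_fasta(sim.genome, outdir / "genome.fasta")
    write_annotation(outdir / "annotation.gff3", sim.orfs)
    write_sam(reads.alignments, sim.genome.lengths(), outdir / "footprints.sam")
    reads.truth.to_csv(outdir / "truth.tsv", sep="\t")
    return reads
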