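"""Absolute quantitation: winsorized densities, footprint fractions and
molecules of protein translated per cell.

The model: with a constant elongation rate per mRNA and all initiated
ribosomes running to completion, an ORF's mean footprint density is
proportional to its protein synthesis rate. Pause sites (slow codons)
and fast codons distort the per-nucleotide profile, so each profile is
winsorized at its 5th/95th percentiles before averaging. A gene's share
of total footprints phi_i then converts to molecules translated per cell

    k_i = phi_i * P * N_A / mW_i

where P is the average protein mass per cell (g/cell), mW_i the protein
molecular weight (Da) and N_A Avogadro's number. Summed over genes this
bookkeeping conserves the measured protein mass exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: 2019 SI exact value, mol^-1.
N_AVOGADRO = 6.02214076e23


@dataclass(frozen=True)
class CellMassParams:
    """Average protein mass per cell, grams/cell, with uncertainty."""

    mass_per_cell: float
    sd: float = 0.0
    medium: str = ""

    def __post_init__(self) -> None:
        if self.mass_per_cell <= 0:
            raise ValueError("mass_per_cell must be positive")


def winsorize(values, lower_pct: float = 5.0, upper_pct: float = 95.0,
              upper_only: bool = False) -> np.ndarray:
    """Clamp a vector at its lower/upper percentiles.

    Percentiles use linear interpolation on the sorted values (the
    common "type 7" estimator). With ``upper_only`` the lower tail is
    left untouched.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot winsorize an empty vector")
    hi = np.percentile(values, upper_pct)
    lo = -np.inf if upper_only else np.percentile(values, lower_pct)
    return np.clip(values, lo, hi)


def phi_fractions(profiles: dict, orfs, lower_pct: float = 5.0,
                  upper_pct: float = 95.0, winsorized: bool = True,
                  upper_only: bool = False) -> pd.DataFrame:
    """Per-gene winsorized mean densities and footprint fractions phi_i.

    A gene's weight is its (winsorized) mean density over the
    start/stop-excluded analysis window times its full ORF nucleotide
    length, extrapolating the excluded ends; phi_i normalizes the
    weights to sum to one over the included genes. The denominator
    contains exactly the ORFs passed in (annotated CDS features), so
    rRNA/tRNA or intergenic signal never dilutes phi.
    """
    rows = []
    for orf in orfs:
        profile = profiles[orf.locus_tag]
        vals = profile.window_values
        if winsorized:
            vals = winsorize(vals, lower_pct, upper_pct, upper_only=upper_only)
        rows.append({
            "locus_tag": orf.locus_tag,
            "mean_density": float(np.mean(vals)),
            "length_nt": orf.length_nt,
            "mol_weight_da": orf.mol_weight,
            "short_orf": profile.short_orf,
        })
    table = pd.DataFrame(rows).set_index("locus_tag")
    weights = table["mean_density"] * table["length_nt"]
    total = weights.sum()
    if total <= 0:
        raise ValueError("all profiles are zero; cannot form footprint fractions")
    table["phi"] = weights / total
    return table


def molecules_per_cell(phi, mass_params: CellMassParams, mol_weight):
    """Molecules of protein translated per cell: k = phi * P * N_A / mW."""
    mol_weight = np.asarray(mol_weight, dtype=float)
    if np.any(mol_weight <= 0):
        raise ValueError("molecular weight must be positive")
    return np.asarray(phi) * mass_params.mass_per_cell * N_AVOGADRO / mol_weight


def synthesis_table(profiles: dict, orfs, mass_params: CellMassParams,
                    lower_pct: float = 5.0, upper_pct: float = 95.0,
                    winsorized: bool = True,
                    upper_only: bool = False) -> pd.DataFrame:
    """Full per-gene table: winsorized density, phi_i, mW_i and k_i."""
    table = phi_fractions(profiles, orfs, lower_pct, upper_pct,
                          winsorized=winsorized, upper_only=upper_only)
    table["k_molecules_per_cell"] = molecules_per_cell(
        table["phi"].to_numpy(), mass_params, table["mol_weight_da"].to_numpy())
    return table


def fold_ratio(translated_k: float, measured_copies: float) -> float:
    """Translated-over-measured copy-number ratio (dimensionless).

    Proteolyzed proteins (FtsZ, DnaA, CcrM) sit well above 1; stable
    proteins cluster near it.
    """
    if translated_k <= 0 or measured_copies <= 0:
        raise ValueError("both copy numbers must be positive")
    return translated_k / measured_copies


def sites_per_protein(k: float, n_sites_per_chromosome: float,
                      ploidy: float = 1.0) -> float:
    """Genomic target sites available per enzyme molecule.

    ``ploidy`` scales the per-chromosome site count for replicating
    cells (2 for a fully replicated chromosome pair).
    """
    if k <= 0:
        raise ValueError("protein copy number must be positive")
    if n_sites_per_chromosome <= 0 or ploidy <= 0:
        raise ValueError("site count and ploidy must be positive")
    return n_sites_per_chromosome * ploidy / k


def binding_site_excess(k: float, n_binding_sites: float) -> float:
    """Fold excess of protein copies over known DNA binding sites."""
    if n_binding_sites <= 0:
        raise ValueError("binding-site count must be positive: ratio undefined")
    if k <= 0:
        raise ValueError("protein copy number must be positive")
    return k / n_binding_sites


def write_synthesis_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t")
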