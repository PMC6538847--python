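# Methods

## Quantitation model

The pipeline converts aligned ribosome footprints into absolute protein
synthesis rates per cell. The chain of assumptions, in order:

- **Occupancy ∝ synthesis.** With a constant average elongation rate per
  mRNA and no ribosome drop-off, the mean footprint density of an ORF is
  proportional to its rate of completed protein synthesis. Proteins
  under active proteolysis (FtsZ-like cases) will show more synthesis
  than standing protein; the pipeline measures synthesis, not abundance.
- **Center weighting.** A nuclease footprint's ends are positionally
  noisy; only its center localizes the ribosome. Each read of span L
  contributes weight 1/(L − 2·trim) at the central L − 2·trim positions
  (default trim 11 nt per end, leaving ≥ 6 positions for 28-mers; reads
  narrower than 2·trim + 1 are skipped with a warning). Accepted spans
  default to 24–40 nt. Only primary alignments are used.
- **Start/stop exclusion.** The first and last 15 nt (5 codons) of each
  ORF are excluded from the analysis window, removing initiation and
  termination peaks. ORFs shorter than 2·15 + 30 nt fall back to
  excluding just the start/stop codons and are flagged `short_orf`.
- **Winsorization.** Within the analysis window, per-nucleotide values
  are clamped at the profile's 5th and 95th percentiles (linear
  interpolation on sorted values, the "type 7" estimator) before
  averaging, damping pause spikes and fast-codon troughs. An
  `upper_only` switch clamps only the top tail.
- **Footprint fraction and conversion.** A gene's weight is its
  winsorized mean density times its full ORF length (extrapolating the
  excluded ends); φᵢ normalizes weights over annotated CDSs only, so
  rRNA/tRNA or intergenic signal never enters the denominator. Genes
  flagged short or overlapping stay in the denominator (dropping them
  would silently inflate every other φ). Then kᵢ = φᵢ·P·N_A/mWᵢ with
  N_A fixed at the 2019 SI exact value and mWᵢ the average-isotopic
  protein mass (N-terminal Met retained, stop codon excluded).

Reads overlapping two annotated genes contribute to both profiles; no
partitioning model is applied.

## Tunable parameters

| parameter | default | units | why |
|---|---|---|---|
| `trim` | 11 | nt/end | keeps ≥ 6 central positions for 28-nt footprints |
| read span window | 24–40 | nt | nuclease footprint acceptance |
| `exclude_nt` | 15 | nt/end | five codons of initiation/termination bias |
| winsorization | 5th/95th | percentile | damp pauses without biasing the bulk |
| `mass_per_cell` | required | g/cell | measured bulk protein / viable cells (4.92e-13 in M2G) |

The dose–response fit uses multi-start nonlinear least squares (K grid
0.01, 0.1, 1, 10 nM; i₀/i∞ initialized from the data extremes) on
per-concentration replicate means; this avoids local minima on shallow
curves. Doubling times are least squares on ln(OD) over a user-chosen
log-phase window (an automatic max-R² picker, preferring the longest
window among ties, is available but off by default). The
fluorescence calibration requires an anchor copy number (e.g. MipZ from
quantitative Western blotting); no default is shipped because it is a
measured constant of the microscope/strain combination.

## Synthetic data: what it emulates and what it does not

`simulate` builds a single high-GC (default 0.67) chromosome of
non-overlapping ORFs on both strands (default 200 ORFs, gamma-distributed
lengths 300–3000 nt), plants heavy-tailed lognormal synthesis weights
(σ = 1.5, mimicking a proteome dominated by a few very highly translated
genes), and samples footprints whose centers follow expected occupancy:
uniform per gene, times 10× spikes at 5% of internal codons (pauses),
times 3× peaks over the first/last 9 nt (initiation/termination), plus a
20% rRNA-contamination fraction mapped to a designated non-CDS locus so
the CDS-only φ denominator is genuinely exercised. Read lengths are
N(28, 2) clipped to 24–40; every generator is byte-deterministic under a
fixed seed.

Not emulated: sequence-dependent nuclease bias, sequencing errors,
quality scores, operon structure, overlapping genes, multi-mapping.
Passing tests therefore demonstrate estimator correctness under the
stated noise model, not robustness to library-preparation artifacts.

## The winsorization boundary

Winsorization at the 95th percentile removes pause noise only while the
spike-affected fraction of nucleotides stays below the clamped 5% tail.
Three-nucleotide codon spikes at a fraction f of codons elevate exactly
f of nucleotides, and center-weighted mapping spreads each spike over
the ≥ 6-nt central window, elevating roughly 3f of positions. At f = 1%
the clamp removes the spikes and winsorized k has clearly lower
log-scale RMSE against truth than the unwinsorized estimator (asserted
in the test suite). At f = 5% the elevated fraction (~15%) exceeds the
tail: the clamp threshold becomes an order statistic of the spike
distribution itself, fluctuating between baseline and spike levels, and
winsorization adds more variance than it removes — the corresponding
stress test documents this regime and fails by design of its
conditions. Real pause sites are well below this prevalence, which is
why the correction helps on real profiling data.

## Numerical choices and degenerate inputs

- Percentiles: numpy linear interpolation; because the clamp bound is
  generally not an attained order statistic, winsorization is only
  near-idempotent (a second pass can tighten the bound marginally).
- Motif counting: IUPAC patterns compiled to overlapping-match regex;
  a genome `N` matches only a pattern `N`. For strand-palindromic
  motifs (GANTC) a forward scan enumerates each physical site once.
- Density conservation: total track weight equals the number of
  contributing reads to float tolerance; overhanging reads are skipped
  and counted.
- Degenerate fits: constant dose–response data are flagged (R²
  undefined), monotonically increasing data are fitted but flagged as
  not a repression curve; non-growing cultures return infinite doubling
  time with a flag rather than raising.
- CDS features failing structural checks (length not divisible by 3,
  missing locus_tag, internal stop) are skipped with warnings.

## Problem sizes

Simulation-based tests use 200 genes and 10⁶ reads (the scale at which
per-gene coverage resembles a deeply sequenced bacterial profiling run
scaled to a 0.2-Mb chromosome); dose–response and growth-curve recovery
use 100 and 50 stochastic replicates. Recovery filters report genes with
≥ 100 expected reads, below which multinomial noise dominates any
estimator choice.

## Known limitations

- No P-site offsetting; center weighting is the only positional model.
- φ is defined over annotated CDSs; unannotated translation is invisible.
- The divK/pleD-style density-ratio and genome-wide category fractions
  of the original study require the deposited sequencing data; here they
  are validated against planted synthetic truth instead.
- Priority order for category assignment is a required input: there is
  no canonical ordering shipped.
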