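# riboquant

Absolute quantitation of protein synthesis from bacterial ribosome
profiling — from aligned ~28-nt ribosome footprints to **molecules of
protein translated per cell** — together with the downstream analyses a
systems study of *Caulobacter crescentus* builds on it: proteome
resource allocation, enzyme-to-target-site bookkeeping, riboswitch
dose–response fitting, fluorescence-to-copies calibration, and doubling
times from OD₆₀₀ growth curves. A synthetic-data generator with planted
ground truth makes every stage testable without any sequencing download.

## The model

Ribosome-protected mRNA footprints report where ribosomes sit. Under two
assumptions — the average elongation rate is constant along each mRNA,
and every initiated ribosome finishes its protein — an ORF's mean
footprint density is proportional to its protein synthesis rate. The
pipeline:

1. **Center-weighted density.** Each accepted footprint (span 24–40 nt)
   spreads unit weight uniformly over its central region after trimming
   11 nt per end, accumulated per chromosome and strand.
2. **Winsorized per-gene density.** Within each ORF (first/last 15 nt
   excluded to avoid initiation/termination peaks) the per-nucleotide
   profile is clamped at its 5th/95th percentiles to damp pause-site
   spikes and fast-codon troughs.
3. **Footprint fractions.** φᵢ = (winsorized mean density × ORF length)
   normalized over all annotated CDSs, so Σφᵢ = 1.
4. **Absolute rates.** With the measured average protein mass per cell
   *P* (4.92 × 10⁻¹³ g in M2G minimal medium) and protein molecular
   weight *mWᵢ*:

   **kᵢ = φᵢ · P · N_A / mWᵢ**  (molecules translated per cell)

   This bookkeeping conserves mass exactly: Σ kᵢ·mWᵢ/N_A = *P*.

Auxiliary quantitations: riboswitch repression curves are fitted as
I(c) = i∞ + (i₀ − i∞)·K/(K + c) to extract the half-repression
concentration K₁/₂; doubling times come from least squares on ln(OD₆₀₀)
vs time (T_d = ln 2 / slope); fluorescent-fusion intensities convert to
copies/cell through a single anchor protein of known abundance.

## Worked example

```sh
python analysis/01_simulate_dataset.py
python analysis/02_quantify_synthesis.py
```

simulates a 200-ORF, 67%-GC chromosome with one million footprints
(20% rRNA contamination, 5% of codons carrying 10× pause spikes) and
quantifies it:

```
phi vs truth: Spearman rho = 0.9965
k median relative error (genes with >=100 expected reads, n=192): 7.34%
mass bookkeeping: sum k_i*mW_i/N_A = 4.920e-13 g/cell (input P = 4.920e-13)
```

The rank correlation says the per-gene synthesis fractions recover the
planted truth almost perfectly; the median error reflects the planted
pause noise; the mass line checks the conversion identity. The remaining
drivers fit riboswitch curves (`04`: metE-like K₁/₂ = 0.063 nM fitted vs
0.062 planted, btuB-like 0.192 vs 0.19) and growth curves (`05`: up to
~21–23% faster doubling at saturating B₁₂, matching the planted
enhancement).

The same machinery is exposed as a CLI for real data:

```sh
riboquant quantify --bam footprints.bam --fasta genome.fasta \
    --gff annotation.gff3 --mass-per-cell 4.92e-13 --out synthesis.tsv
riboquant count-motif --fasta genome.fasta --motif GANTC
riboquant fit-dose --tsv reporter.tsv
```

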