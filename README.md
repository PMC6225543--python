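# denitflux

Tools for the computational chain of a chamber-based field study of
nitrous oxide (N₂O) emissions and denitrifier communities: static-chamber
flux estimation, cumulative emissions and emission factors, soil
aeration metrics, and alignment of T-RFLP community fingerprints. The
package is aimed at soil biogeochemists and microbial ecologists who
monitor trace-gas fluxes alongside community fingerprinting, and at
anyone who needs a tested, scriptable implementation of these steps.

## What it computes

**Chamber fluxes.** A closed chamber on soil accumulates N₂O; the
surface flux is the initial slope of the headspace concentration
C(t), converted to mass units by the ideal-gas law. Besides ordinary
linear regression, the Hutchinson–Mosier (HM) model

> C(t) = φ + (C₀ − φ)·e^(−κt),  f₀ = h·κ·(φ − C₀)

captures the flattening of C(t) as the gradient saturates (φ is the
asymptote, κ the curvature rate, h the chamber height). κ is profiled
over a log-spaced grid with (φ, C₀) solved linearly, and the
linear-vs-HM choice is automated (ΔAIC > 2 with interior κ) with a
per-chamber override.

**Cumulative emissions and emission factors.** Per-plot flux series are
integrated with trapezoid quadrature weights
w₁ = (t₂−t₁)/2, wᵢ = (tᵢ₊₁−tᵢ₋₁)/2, w_n = (t_n−t_{n−1})/2 — the same
vectors usable as contrast coefficients in a gamma GLMM. Emission
factors are background-corrected ratios, EF = (cum − background)/N
input, area-based or scaled by plant N uptake. Benjamini–Yekutieli
step-up FDR adjustment is included for multiple comparisons.

**Soil aeration.** Water-filled pore space (WFPS = θ_g·ρ_b/Φ with
Φ = 1 − ρ_b/ρ_s) and the Moldrup-type relative gas diffusivity
Dp/D0 = Φ²·(ε/Φ)^X with X = 2 + log(ε₁₀₀^0.25)/log(ε₁₀₀/Φ), plus
growing-degree-day sums.

**T-RFLP alignment.** Fragment-size jitter means the "same" terminal
restriction fragment drifts between samples. The pipeline merges
shoulder peaks, relativizes areas/heights, separates signal from noise
by an iterative 3σ-about-zero rule pooled across samples, aligns
profiles pairwise by dynamic programming under a size/area/height
dissimilarity with gap costs, builds a multiple alignment by
random-order insertion against a consensus of bin-averaged peaks,
refines it by leave-one-out realignment while the overall score
improves, and combines the two enzyme digests of each gene. Wisconsin
double standardization and Bray–Curtis dissimilarities prepare the
resulting bin tables for NMDS ordination in external tools.

A synthetic-data module generates chamber series, gamma-distributed
campaign fluxes and labelled T-RFLP peak tables with known ground
truth, so every stage is testable end to end.

## Worked example

```bash
python examples/trflp_alignment.py
```

```
generated 979 peaks across 20 samples (300 true, 614 noise)
alignment: 22 bins, score history [70.1]
co-binning purity: 1.000 (300 true peaks)
```

Twenty simulated samples of a 15-fragment community (0.2 bp
size-calling jitter, ~30 spurious peaks per profile, shoulder peaks on)
are pushed through the full pipeline; purity of 1.0 means every true
peak ended up in the modal bin of its ground-truth fragment, i.e. the
community table was reconstructed perfectly despite noise. Other
examples cover chamber fitting (`chamber_flux_demo.py`, recovering a
100 µg N₂O-N m⁻² h⁻¹ flux from a noisy 5-point series), emission
factors, soil aeration and community dissimilarities.

A thin CLI mirrors the library for shell workflows, e.g.:

```bash
denitflux simulate trflp --seed 2 --out peaks.csv
denitflux align --in peaks.csv --gene nirK --seed 3 --out aligned.csv
denitflux dissim --in aligned.csv --wisconsin --out bc.csv
```

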