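# Methods

This note documents the models, numerical choices and assumptions
behind `denitflux`, and what the synthetic-data tests do and do not
demonstrate about real field data.

## Chamber flux estimation

A static-chamber deployment yields N₂O mixing ratios (ppb) at a handful
of times over ~2 h. The surface flux is the initial concentration slope
converted to mass units by the ideal-gas law at the deployment's air
temperature and pressure (default 101.325 kPa): 1 ppb h⁻¹ corresponds
to 10⁻⁹ · P/(RT) mol N₂O m⁻³ h⁻¹, times 28.014 g N mol⁻¹ and the
chamber height (default 0.20 m over a 0.75 × 0.75 m collar, five
samples over 2 h).

Two models are fitted:

* **linear** — OLS slope; unbiased only when the headspace gradient has
  not yet fed back on the flux;
* **Hutchinson–Mosier** — C(t) = φ + (C₀ − φ)e^(−κt), f₀ = h·κ·(φ − C₀).
  κ ≥ 0 by construction; κ = 0 degenerates to the linear model.

The HM fit profiles κ over 64 log-spaced points in [10⁻³, 10²] h⁻¹; at
each κ the model is linear in (φ, C₀ − φ) and solved by least squares,
giving a smooth one-dimensional SSE profile that is then minimised by
bounded scalar search (xatol 10⁻¹⁰ in log κ) between the grid
neighbours of the best point. If the SSE minimum sits on a bound there
is no interior HM optimum (typically: genuinely linear data) and the
fit is flagged `no-HM-fit`. The reported SE of f₀ is the
linear-conditional standard error of C₀ − φ at the fitted κ scaled by
h·κ and the gas factor; it ignores κ's own uncertainty and should be
read as a lower bound.

Model selection, done by visual inspection in many field studies, is
replaced by an explicit reproducible rule: HM is used only when it
converged with interior κ and improves AIC over linear by more than 2;
a per-chamber override mapping can force either model, preserving the
manual workflow where an analyst has reason to intervene. The decision
and ΔAIC are recorded in `selection_note`.

## Cumulative emissions and emission factors

Per-plot flux series are integrated by the trapezoid rule expressed as
quadrature weights over the sampling dates; the weights sum to the
window length and the weighted sum is exact for constant and linear
flux. The same weight vectors serve as contrast coefficients when
cumulative emissions are instead estimated as contrasts inside a gamma
GLMM fitted with standard mixed-model software; this package applies
them directly to plot-level fluxes and exports the vectors, leaving the
GLMM itself to off-the-shelf tools. Unit handling: fluxes tagged
µg N₂O-N m⁻² h⁻¹ convert to kg N ha⁻¹ via ×24 h d⁻¹ ×10⁻⁹ kg µg⁻¹
×10⁴ m² ha⁻¹.

Emission factors are background-corrected ratios against a zero-N
reference treatment: area-based EF = (cum − background)/N input, with N
input the catch-crop residue N plus fertilizer N where both apply;
yield-scaled EF divides by plant N uptake at harvest instead. Negative
EFs are reported, not truncated — a treatment can emit less than the
reference. The Benjamini–Yekutieli step-up (statsmodels `fdr_by`)
provides FDR control under arbitrary dependence for post-hoc
comparisons.

## Soil aeration metrics

WFPS = θ_g·ρ_b/Φ with Φ = 1 − ρ_b/ρ_s; particle density defaults to
2.65 g cm⁻³, the standard mineral-soil value (the field site is a sandy
loam). Values marginally above 1 from measurement error are clipped
with a warning. Relative gas diffusivity uses the Moldrup-type
water-retention form Dp/D0 = Φ²(ε/Φ)^X,
X = 2 + log(ε₁₀₀^0.25)/log(ε₁₀₀/Φ); the log base cancels, the result
lies in [0, Φ²], is monotone in ε, and ε₁₀₀ = Φ is rejected as a
division by zero. ε₁₀₀ (air content at −100 cm H₂O) is a user input —
no water-retention-curve fitting is attempted. Growing-degree-day sums
use Σ max(0, T̄ − T_base) with T_base = 0 °C by default; the base
temperature is a convention that differs between crops, so it is an
explicit parameter rather than a fixed constant.

## T-RFLP processing and alignment

Inputs are peak tables (size bp, area, height) as exported by
fragment-analysis software; raw trace parsing is out of scope.

* **Merging** (δ = 0.5 bp default): the closest pair of peaks closer
  than δ is merged repeatedly — area-weighted mean size, summed area,
  max height, label of the larger-area member. Closest-pair-first makes
  chains deterministic. This operates on peak tables; a kernel-density
  smoothing of raw traces would be the analogue upstream.
* **Relativization**: areas and heights each divided by their
  within-profile sums.
* **Noise classification** (k = 3): pooled over all samples of one
  (gene, enzyme), σ = √(Σx²/n) about a theoretical zero baseline is
  computed for relative areas and heights over all peaks not yet
  flagged signal; peaks ≥ kσ are flagged, removed from the pool, and σ
  recomputed until a fixed point. The published description of the
  threshold ("areas or heights" below 3σ) is ambiguous between AND/OR
  semantics; the default here requires a signal peak to exceed the
  threshold in **both** metrics (the stricter reading), switchable via
  `noise_require_both=False`.
* **Pairwise alignment**: global DP over two size-sorted peak lists
  minimising Σ match dissimilarities + g per unmatched peak, matches
  non-crossing and restricted to |Δsize| ≤ D_max. Dissimilarity
  d = w_s|Δsize| + w_a|Δarea| + w_h|Δheight| with unit weights: sizes
  in bp and relativized signals in [0, 1] are then on comparable
  scales, and with g = 0.75 a match beats two gaps whenever d < 1.5.
  D_max = 1.0 bp tolerates ±0.5 bp calling error on both peaks. Ties
  break deterministically (match preferred over gap, then gap in the
  first sequence); tied costs are measure-zero on real data.
* **Multiple alignment**: a seeded RNG orders the profiles; the first
  two are aligned and converted to bins (unweighted mean size, area,
  height of members), then each remaining profile is aligned against
  the running consensus — matched peaks join bins, unmatched peaks open
  new ones. Each sample contributes at most one peak per bin.
* **Overall score**: Σ over member peaks of the peak-to-bin-consensus
  dissimilarity, with singleton bins contributing the gap cost g
  instead. Charging g for singletons stops the score from rewarding
  fragmentation into one-peak bins; whether the original score counted
  unmatched peaks is not documented, so this choice is recorded here.
* **Refinement**: per pass, every sample in seeded random order is
  removed (bin means recomputed, empty bins dropped) and realigned; a
  pass is kept only if the score strictly decreased, the first
  non-improving pass is reverted and refinement stops (hard cap 20
  passes). Accepted scores are strictly decreasing by construction.
* **Enzyme combination**: bin tables of the two digests of one gene are
  concatenated column-wise with enzyme-prefixed bin ids.

Fragment sizes are kept fractional throughout; no integer rounding.
Wisconsin double standardization (divide by column maxima, then by row
sums) and Bray–Curtis dissimilarities prepare the combined tables for
NMDS; ordination, environmental-vector fitting and their permutation
tests are delegated to standard ordination software (e.g. vegan), whose
exact inputs this package writes.

## Synthetic data: what it emulates and what it does not

* **Chamber series** follow the HM model (or its exact linear κ = 0
  limit) with additive iid Gaussian noise (default 5 ppb); real GC
  measurement error can be heteroscedastic and chambers can leak, which
  is not modelled.
* **Campaign fluxes** are gamma draws in the (mean, shape)
  parameterisation around a mean schedule with a post-fertilization
  exponential pulse (base 5, peak +120 µg N₂O-N m⁻² h⁻¹, 12-day decay
  over DOY 95–166) — the positive skew and pulse timing of spring
  emissions — but plots are independent draws: the spatial and temporal
  autocorrelation that motivates a mixed model in real data is absent.
* **T-RFLP tables** contain, per sample, true fragments with Gaussian
  size jitter (0.2 bp), log-normal areas (σ = 0.5) around per-fragment
  mean log abundances spread over ~1.5 decades (the skewed
  rank-abundance structure typical of community fingerprints — and a
  precondition for the iterative 3σ rule to cascade, since a perfectly
  even community has no peaks above 3σ of its own pool), heights a
  fixed fraction (0.8) of area with log-normal noise (σ = 0.2);
  Poisson(30) spurious peaks with areas below 10% of the profile's
  smallest true peak; shoulder peaks at +0.3 bp carrying 5–25% of the
  parent's area with probability 0.2. Every peak carries a truth label.
  Real electropherograms have size-dependent calling error, pull-up
  peaks and detector saturation; none of that is modelled, so passing
  recovery tests demonstrates the algorithm's correctness under its
  stated error model, not performance guarantees on arbitrary real
  runs.

Recovery is scored as co-binning purity: the fraction of true peaks
that fall in the modal bin of their ground-truth fragment. At the
default study-like scale (20 samples × 15 fragments) the pipeline
reaches purity 1.0 and discards ≥ 95% of noise peaks; these thresholds
are properties of this artifact's pipeline on its own generator, not
claims about any published dataset.

## Degenerate inputs and tie-breaks

Profiles must be strictly size-sorted (enforced); an all-zero profile
cannot be relativized; two all-zero samples have undefined Bray–Curtis
dissimilarity (NaN, warned); all-zero bins make Wisconsin
standardization undefined (error naming the bin); fewer than 2 dates
cannot be integrated; κ bounds must be positive. Exact ties in merge
distances and DP costs resolve deterministically as documented above,
so identical inputs and seeds give byte-identical outputs.

## Problem sizes

Default test and example scales — 500 simulated deployments for flux
error, 200 random toy instances for the DP oracle, 20 samples × 15
fragments for pipeline recovery — were chosen as the scale of a
two-year, five-treatment field campaign; the whole suite runs in a few
seconds on one CPU.

## Known limitations

The gamma GLMM, post-hoc contrast machinery, NMDS/envfit, and qPCR
quantification are deliberately out of scope (standard tools exist);
growing-degree-day base temperature and the noise-rule AND/OR semantics
are documented assumptions; the HM SE understates uncertainty in κ-rich
regimes; manual bin curation is supported only by editing the exported
bin tables, not interactively.
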