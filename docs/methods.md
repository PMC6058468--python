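# Methods

## The measurement being modelled

Blood plasma scatters laser light as a mixture of particle populations:
free plasma proteins of a few nanometres, circulating immune complexes
(CICs) of ~100–300 nm, and, after adding anti-isotype antibodies,
crosslinked super-aggregates up to ~700 nm.  A single-angle dynamic light
scattering (DLS) instrument records the normalized intensity
autocorrelation g₂(τ); the Siegert relation

    g₂(τ) = 1 + β |g₁(τ)|²

links it to the field correlation, and for a dilute polydisperse sample

    |g₁(τ)| = Σⱼ wⱼ exp(−Γⱼ τ),  Γⱼ = D(R_j) q²,  D = k_B T / (6π η R)

with q = (4π n / λ₀) sin(θ/2).  The intensity weights wⱼ, normalized so
that total scattering is 100%, are the "contribution to scattering" of
each size subfraction — the package's central observable.

All radii everywhere are hydrodynamic radii in nanometres; no diameter
fields exist.  All windows are half-open [lo, hi) so that contributions
are exactly additive over disjoint windows.

## Forward simulator

`simulate.simulate_trace` evaluates the model above on a quasi-logarithmic
lag grid (default 256 channels spanning 10⁻⁶–10 s, which brackets the
decay times of 1 nm to ~1 µm particles at the default geometry; a grid
that fails to bracket a component's 1/Γ by a decade on each side records a
warning in the trace metadata).  Defaults describe a standard He–Ne setup:
λ₀ = 632.8 nm, θ = 90°, n = 1.333, T = 298.15 K, η = 0.89 mPa·s, coherence
factor β = 0.8 recorded in each trace.  The correlator band (2048 or
8096 Hz) is carried as metadata rather than used to truncate the lag grid:
a shortest lag of 1/2048 s would make the few-nanometre plasma background
(decay time ~4·10⁻⁵ s) invisible, contradicting the requirement that the
grid bracket every component.

Noise is additive Gaussian on g₂ with per-channel scale
σ₀·((i+1)/n)^s (s = 0 by default, i.e. homoscedastic); σ₀ = 0 yields
bit-identical traces regardless of seed, and all stochastic outputs are
reproducible from a single integer seed.  The model deliberately omits
photon-count (Poisson) statistics, multi-tau variance structure, dust
spikes and multiple scattering; passing tests therefore demonstrate
correctness of the inversion and profiling logic under well-behaved noise,
not robustness to every artefact of a real correlator.

Study-condition presets are the simulator's defaults:

* human plasma: 3.5 nm background plus a food-CIC component whose
  contribution rises piecewise-linearly from 5.9% (radius 116.6 nm) before
  the meal to 78.7% (radius 121.1 nm) at 3.5 h, returning to baseline by
  14 h, sampled at 0, 1.5, 3.5, 5, 7, 12 and 14 h; per-donor jitter is
  Gaussian with σ = 0.5 percentage points (the cohort's printed
  peak-contribution spread).  The piecewise-linear shape is a stand-in:
  only the sampling times, the peak location and the return time are
  constrained by the data, not a functional form.
* antibody panels: a panel moves a preset fraction of the IC-window weight
  to an aggregate radius (IgG1 → 271.6 nm, IgG3 → 260.5 nm, IgA →
  267.2 nm, fractions chosen so the shifted contributions equal the cohort
  means 33.1 / 4.1 / 42.0%).  Combined panels cover the two behaviours the
  cohort data show: IgG1+IgG3 is additive (37.2% to one intermediate
  aggregate at 316.2 nm), whereas IgG1+IgA is modelled with an explicit
  dual-positive sub-population — 3.2% of total scattering forms 653 nm
  super-aggregates while the single-positive remainder shifts to the
  intermediate radius.
* rats: fed animals carry a 200–300 nm food-IC component at ~73% in portal
  blood and only ~5% inert large particles in the vena cava; starved
  animals show ~6% inert large particles at both sites.

Protein-A depletion multiplies the weight of **immunoglobulin-bearing**
components inside the IC window by (1 − efficiency) and renormalizes to
100%.  Components carry an `ig_bearing` flag (default True); the inert
large-particle background of starved-animal serum is planted with
`ig_bearing=False` and survives depletion — that survival is precisely
what makes the native-vs-depleted differential a specific IC detector
rather than a large-particle detector.

## Inversion

`inversion.invert` solves the classic ill-posed Laplace inversion as a
Tikhonov-regularized non-negative least-squares problem on a fixed grid of
64 log-spaced radius bins over 1–10,000 nm:

    min_{w ≥ 0} ‖W (K w − g₁)‖² + λ ‖L w‖²

with K the exponential kernel (exponents clipped at −700 for overflow
safety) and L a finite-difference penalty (order 2, curvature smoothing,
by default; orders 0–1 selectable).  Three numerical choices matter:

* **Signed Siegert transform.**  g₁ is computed as
  sign(g₂−baseline)·√(|g₂−baseline|/β).  Clipping negative excursions at
  zero before the square root — the naive transform — rectifies long-lag
  noise into a positive plateau which the fit attributes to a spurious
  huge-radius component; at σ₀ = 0.005 this artefact completely absorbs
  minority fractions.  Keeping the sign leaves the tail noise zero-mean.
* **Amplitude weighting** (default `weighting="amplitude"`, W =
  diag(|g₁|) floored at 1% of its maximum).  First-order error
  propagation through the square root gives σ_g₁ = σ_g₂/(2β g₁), so
  weighting by |g₁| approximates maximum-likelihood fitting of g₂ itself
  and concentrates fidelity in the channels that carry information.
  `weighting="none"` restores the plain objective.
* **Discrete refinement** (default `refine=True`).  The regularized
  histogram localizes mass only to within the resolution the noise
  allows.  A second stage re-fits the trace in g₂ space with a small
  number of discrete exponentials: candidate models come from the
  histogram's contiguous clusters (as found, split at their weighted
  medians, merged pairwise, and augmented by a six-point logarithmic scan
  of a minority radius), each is optimized by bounded least squares on
  (log R, amplitude), and the most parsimonious model whose χ² is within
  ~4σ per removed component pair of the best is selected.  Component
  weights are deposited back onto the grid log-linearly between the two
  nearest bin centers, so the output remains a histogram.  On noise-free
  input the refinement is exact (monodisperse mass stays within one bin of
  truth).

λ is either fixed or chosen by the L-curve criterion: a 26-point
logarithmic ladder over 10⁻⁸–10², the corner found as the maximum signed
Menger curvature of (log residual, log seminorm), ties broken toward the
smallest λ (fidelity over smoothness), with a ladder-midpoint fallback
when fewer than three ladder points are feasible.  On very clean traces
the flat residual curve can push the corner toward large λ; the
refinement stage makes the final histogram insensitive to this known
L-curve pathology.

Degenerate inputs: an all-zero solution raises "degenerate trace";
g₂ below baseline at more than half the channels raises "baseline exceeds
data"; the baseline may optionally be fit as the mean of the last 5% of
lags, and β as the maximal excess when not recorded.

`cumulant_check` provides the standard inversion-independent cross-check:
a second-order polynomial fit of ln|g₁| over the first decade of lags
returning the intensity-weighted harmonic-mean radius and polydispersity
index; on monodisperse data it agrees with the inversion to within one
grid bin.

### Resolution limits

A numerical Cramér–Rao analysis at the default instrument (256 channels,
homoscedastic σ₀ = 0.005 on g₂) shows the log-radius of a minority
component is fundamentally poorly determined when its intensity weight is
small: the CRB standard deviation of ln R is ≈1.3 at 5.9% weight and
radius ratio 35 (i.e. a factor-3.6 1σ band), ≈0.08 at 25% weight, and
±15% (2σ) localization requires roughly ≥25% weight at ratio 35 or ≥40%
at ratio 10.  A two-exponential maximum-likelihood fit initialized at the
truth shows the same scatter, confirming this is an information limit of
the data, not of the algorithm.  Round-trip tests therefore assert
window-contribution and peak-radius recovery on mixtures inside this
identifiable region (minor weight ≥ ~20%, ratio ≥ 10, including the
peak-state plasma composition 21.3/78.7 at ratio 35); outside it, only
contribution recovery is meaningful, and at ~5% weight even detection of
the component is probabilistic.  Similarly, the antibody-shift assay
separates radii by factors ≈2 (121 → 267 nm), near the resolution limit:
end-to-end isotype additivity is tested at high acquisition quality
(σ₀ = 3·10⁻⁵), and the dual-positive 3.2% fraction at 653 nm adjacent to
a dominant ~300 nm aggregate is exercised on planted histograms only.

## Profiling

Subfractions are maximal contiguous runs of occupied bins, reported with
window, contribution-weighted modal radius, and summed contribution.  The
IC detector compares a native and a protein-A-depleted profile over a
radius window (default 100–400 nm, covering human ~120 nm and rat
200–300 nm food CICs): the fraction is declared present when the native
contribution is at least `abs_min_pct` (1%) and at least `ratio_min` (2×)
the depleted contribution — thresholds that separate a fed-animal portal
sample (~73% vs ~0%) from the inert starved background (~6% vs ~6%) with
wide margin.  Human analyses use a 50–400 nm window: food CICs at ~117 nm
sit close to a 100 nm edge, and the log-radius scatter of a ~6% fraction
would otherwise spill below it.  Isotyping uses a 50–200 nm IC window and
per-panel aggregate windows (200–500 nm for single panels and IgG1+IgG3,
500–800 nm for IgG1+IgA); the proportion attributed to an isotype is the
contribution appearing in the aggregate window minus whatever the native
sample already had there, so baseline large particles are not counted as
signal.

`pipeline.profile_mixture` mirrors the bench protocol of measuring each
sample at least three times: it simulates three replicate traces,
averages them channel-wise in g₂ (as a correlator accumulating repeated
runs would), and inverts once.  The default simulated noise for pipeline
fixtures is σ₀ = 10⁻³, a typical baseline ripple for a 15-minute
acquisition.

## Kinetics and statistics

Time courses collect the IC-window contribution of one subject's native
profiles sorted by time.  `peak_time` returns the earliest time of the
maximal contribution; `return_to_baseline` returns the earliest post-peak
time within `tolerance_pct` (default 2 percentage points ≈ 3 standard
deviations of the repeat-sampling scatter at default settings) of the
pre-meal value.  Both are invariant under uniform scaling of the course.

Cohort summaries use the arithmetic mean and the **population** standard
deviation (divisor n).  The printed per-column summaries of the reference
tables are internally inconsistent between conventions; the population
convention reproduces strictly more of the reconcilable cells (e.g. the
peak-contribution SD 0.5 and the IgG1 SD 1.6), so it is fixed
package-wide and rounding (half-up, one decimal) is applied only at
report time.  A handful of printed cells cannot be recovered from the
printed per-donor values under any convention (pre-meal size SD 6.0 vs
5.9/6.3; peak size mean 121.1 vs 121.2), indicating the original summaries
were computed on unrounded data; those cells are not used as checks.

Group differences use the Welch construction: difference of means with
sample variances, Satterthwaite degrees of freedom, and a t quantile at
the requested level (default 99%).  Zero-variance groups yield a
degenerate zero-width interval.  Coverage of the 99% interval over 1,000
simulated normal replicates at n = 50 per group lies in the 97.5–100%
band (measured ≈ 98.7–99.6%).

## Problem sizes

Default test and acceptance workloads: 20 noise seeds per round-trip
mixture; a 10-donor simulated cohort at 7 time points; 3 rats per feeding
group with 4 site-comparisons each; 1,000 replicates for interval
coverage.  These match the study's cohort sizes where the study states
them (10 donors, 3 rats per group, 7 sampling times).

## Known limitations

* Intensity-weighted distributions only; no Mie corrections or conversion
  to number/mass distributions — a 5.9% intensity contribution is not a
  5.9% mass fraction.
* The regularizer and λ-selection are CONTIN-like stand-ins; no claim of
  bit-identity with any instrument vendor's software.
* The dual-positive combined-panel model is one parameterization
  consistent with the reference tables, not an inference about binding
  chemistry; depletion efficiency is a per-class simulator parameter, and
  the package does not attempt to explain why protein A (a weak IgA
  binder) removes IgA-dominated complexes.
* The noise model is additive Gaussian on g₂; detector afterpulsing,
  normalization drift and dust events are out of scope.
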