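# cicdls

Dynamic-light-scattering (DLS) profiling of circulating immune complexes
(CICs) in blood plasma: a tested pipeline for the "food immune complex"
experiment, in which large antigen–antibody aggregates appear in the blood
after a meal, peak about 3.5 hours later, and are cleared again by ~14 h.

The package is for biophysicists and immunologists who want to

* simulate single-angle DLS correlograms of plasma-like particle mixtures,
* invert correlograms into **subfraction histograms** — percent
  contribution to total scattering per hydrodynamic-radius bin,
* identify the CIC fraction as the part of the histogram that disappears
  after protein-A depletion (native vs depleted differential),
* quantify the immunoglobulin-isotype composition of the complexes from
  antibody-induced aggregation shifts, and
* summarize postprandial kinetics and cohort statistics
  (mean, population SD, 99% Welch confidence intervals).

## The model

A DLS correlator measures the normalized intensity autocorrelation
g₂(τ).  Via the Siegert relation g₂ = 1 + β|g₁|², the field correlation of
a dilute polydisperse sample is a non-negative mixture of exponentials,

    |g₁(τ)| = Σⱼ wⱼ e^(−Γⱼτ),   Γⱼ = q² k_B T / (6π η R_j),
    q = (4π n / λ₀) sin(θ/2),

one decay rate per hydrodynamic radius R_j (Stokes–Einstein).  Recovering
the intensity weights wⱼ is an ill-posed Laplace inversion; `cicdls`
solves it as CONTIN-style Tikhonov-regularized non-negative least squares
on a log-spaced radius grid (64 bins, 1–10,000 nm), with
error-propagation channel weighting, L-curve selection of the
regularization weight, and a parsimonious discrete-exponential refinement
that sharpens the histogram to the resolution the noise supports.  See
`docs/methods.md` for the numerics and the resolution limits.

## Worked example

Simulate peak-state plasma (78.7% of scattering from ~121 nm food CICs,
the rest from the few-nm protein background), invert, and profile:

```python
import cicdls as c
from cicdls.pipeline import profile_mixture

mix = c.human_plasma_mixture(ic_pct=78.7, ic_radius_nm=121.1)
trace = c.simulate_trace(mix, noise=c.NoiseModel(sigma0=0.001, seed=42))
dist = c.invert(trace)
for s in c.find_subfractions(dist, min_pct=1.0):
    print(f"{s.window_nm[0]:8.1f}-{s.window_nm[1]:<8.1f} nm"
          f"  peak {s.peak_nm:7.1f} nm  {s.contribution_pct:5.1f} %")
```

prints

```
     3.2-4.2      nm  peak     3.5 nm   21.3 %
   100.0-133.4    nm  peak   121.1 nm   78.7 %
```

two subfractions: the free-protein background (3.5 nm, 21.3% of total
scattering) and the immune-complex fraction (121 nm, 78.7%) — the planted
composition recovered from the correlogram alone.  The depletion
differential then confirms the large fraction is immunoglobulin-bound:

```python
native   = profile_mixture(mix, "D01", "native",   seed=1)
depleted = profile_mixture(c.apply_depletion(mix), "D01", "depleted", seed=2)
print(c.detect_ic_fraction(native, depleted))
```

```
ICFractionResult(window_nm=(100.0, 400.0), native_pct=78.66, depleted_pct=0.0,
                 detected=True, ic_size_nm=121.48)
```

78.7% of scattering in the 100–400 nm window before depletion, none
after: an IC fraction of ~121 nm particles is detected.

A command-line interface wraps the same steps
(`cicdls simulate | invert | profile | deplete-compare | isotype |
kinetics | report`); `cicdls report --style table1` prints the bundled
ten-donor reference table with its Mean and SD rows recomputed.

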