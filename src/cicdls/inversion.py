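"""Regularized inversion of intensity-autocorrelation traces.

A DLS correlator measures the normalized intensity autocorrelation
g2(tau).  The Siegert relation links it to the field correlation that
carries the size information:

    g2(tau) = 1 + beta * |g1(tau)|**2

For a polydisperse sample, |g1| is a nonnegative mixture of exponentials,
one decay rate per particle size:

    |g1(tau)| = sum_j w_j * exp(-Gamma_j * tau),   w_j >= 0

Recovering the intensity weights w from a sampled trace is a classic
ill-posed Laplace inversion.  Following CONTIN-style practice, we solve a
Tikhonov-regularized non-negative least-squares problem on a fixed
log-spaced radius grid,

    min_{w >= 0}  || W (K w - g1) ||^2  +  lambda * || L w ||^2

with K the exponential kernel, L a finite-difference smoothing operator,
and W an optional diagonal channel weighting.  Two numerical choices
matter at realistic noise levels:

* the Siegert transform keeps the sign of g2 - baseline
  (``sign(x) * sqrt(|x| / beta)``) instead of clipping negatives at zero;
  clipping rectifies the long-lag noise into a positive plateau that the
  fit would otherwise attribute to a spurious huge-radius component;
* with ``weighting="amplitude"`` (the default) channel i is weighted by
  |g1_i| (floored), which is first-order error propagation through the
  square root: for additive noise on g2, sigma_g1 = sigma_g2 / (2 beta g1),
  so the weighted problem approximates maximum-likelihood fitting of g2
  itself and concentrates fidelity where the correlogram actually carries
  information.  ``weighting="none"`` gives the plain unweighted objective.

The solution is reported as per-bin percent contributions to total
scattering (summing to 100%), i.e. the subfraction histogram.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares, nnls

from .physics import InstrumentConfig, decay_rate

__all__ = [
    "CorrelationTrace",
    "SizeGrid",
    "SizeDistribution",
    "InversionSettings",
    "build_kernel",
    "difference_operator",
    "invert",
    "refine_distribution",
    "select_lambda",
    "cumulant_check",
]

_EXP_CLIP = -700.0  # exp underflows below this; keeps the kernel finite
_WEIGHT_FLOOR = 0.01  # channel weight floor, relative to the largest weight


@dataclass
class CorrelationTrace:
    """A sampled, normalized intensity autocorrelation g2(tau).

    ``beta`` is the coherence (intercept) factor of the Siegert relation; it
    is recorded by the simulator and may alternatively be fitted during
    inversion.  ``baseline`` is the long-lag asymptote of g2, 1 for a
    properly normalized trace.  ``meta`` carries the instrument
    configuration and free-form provenance (seed, ground truth, warnings).
    """

    tau_s: np.ndarray
    g2: np.ndarray
    beta: float | None = None
    baseline: float = 1.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.tau_s = np.asarray(self.tau_s, dtype=float)
        self.g2 = np.asarray(self.g2, dtype=float)
        if self.tau_s.ndim != 1 or self.g2.shape != self.tau_s.shape:
            raise ValueError("tau_s and g2 must be 1-D arrays of equal length")
        if self.tau_s.size < 8:
            raise ValueError("trace must have at least 8 channels")
        if np.any(self.tau_s <= 0) or np.any(np.diff(self.tau_s) <= 0):
            raise ValueError("tau_s must be positive and strictly increasing")

    @property
    def config(self) -> InstrumentConfig | None:
        cfg = self.meta.get("instrument")
        if cfg is None:
            return None
        return cfg if isinstance(cfg, InstrumentConfig) else InstrumentConfig.from_dict(cfg)


@dataclass(frozen=True)
class SizeGrid:
    """Log-spaced hydrodynamic-radius bins (nm) with geometric centers."""

    edges_nm: np.ndarray

    def __post_init__(self) -> None:
        edges = np.asarray(self.edges_nm, dtype=float)
        if edges.ndim != 1 or edges.size < 2:
            raise ValueError("need at least two bin edges")
        if np.any(edges <= 0) or np.any(np.diff(edges) <= 0):
            raise ValueError("edges must be positive and strictly increasing")
        object.__setattr__(self, "edges_nm", edges)

    @classmethod
    def logspaced(cls, min_nm: float, max_nm: float, n_bins: int) -> "SizeGrid":
        if not 0 < min_nm < max_nm:
            raise ValueError("require 0 < min_nm < max_nm")
        if n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        return cls(np.geomspace(min_nm, max_nm, n_bins + 1))

    @property
    def centers_nm(self) -> np.ndarray:
        return np.sqrt(self.edges_nm[:-1] * self.edges_nm[1:])

    @property
    def n_bins(self) -> int:
        return self.edges_nm.size - 1

    def bin_of(self, radius_nm: float) -> int:
        """Index of the bin containing ``radius_nm`` (half-open bins)."""
        idx = int(np.searchsorted(self.edges_nm, radius_nm, side="right")) - 1
        if not 0 <= idx < self.n_bins:
            raise ValueError(f"radius {radius_nm} nm outside grid")
        return idx


@dataclass
class SizeDistribution:
    """Subfraction histogram: percent contribution to scattering per bin."""

    grid: SizeGrid
    contribution_pct: np.ndarray
    residual_norm: float = 0.0
    lambda_reg: float = 0.0

    def __post_init__(self) -> None:
        c = np.asarray(self.contribution_pct, dtype=float)
        if c.shape != (self.grid.n_bins,):
            raise ValueError("contribution_pct length must match grid bins")
        if np.any(c < -1e-12):
            raise ValueError("contributions must be nonnegative")
        total = c.sum()
        if abs(total - 100.0) > 1e-6:
            raise ValueError(f"contributions sum to {total}, expected 100")
        self.contribution_pct = np.clip(c, 0.0, None)

    def peak_radius_nm(self, window_nm=None) -> float:
        """Contribution-weighted modal radius, optionally inside a window.

        The mode is the center of the highest-contribution bin; it is
        refined to the contribution-weighted mean over that bin and its
        immediate neighbours, which interpolates between bin centers
        without letting mass elsewhere in the window drag the estimate.
        """
        centers = self.grid.centers_nm
        c = self.contribution_pct
        if window_nm is not None:
            lo, hi = window_nm
            mask = (centers >= lo) & (centers < hi)
            centers, c = centers[mask], c[mask]
        if c.size == 0 or c.sum() <= 0:
            return float("nan")
        k = int(np.argmax(c))
        sl = slice(max(k - 1, 0), k + 2)
        return float(np.average(centers[sl], weights=c[sl]))


@dataclass(frozen=True)
class InversionSettings:
    """Grid construction and regularization choices for :func:`invert`.

    The default 64 log-spaced bins over 1-10,000 nm cover both the
    small-particle plasma background (a few nm) and antibody-induced
    super-aggregates (up to ~700 nm) with margin on either side.
    ``lambda_reg`` may be a number or ``"auto"`` for L-curve selection.
    ``penalty_order`` selects the difference operator L: 0 = ridge,
    1 = slope, 2 = curvature smoothing (CONTIN-like default).
    ``weighting`` is ``"amplitude"`` (error-propagation channel weights,
    default) or ``"none"`` (plain objective).  With ``refine`` (default)
    the regularized histogram is sharpened by a parsimonious
    discrete-exponential refit (see :func:`refine_distribution`); switch it
    off to obtain the raw penalized-NNLS solution.
    """

    grid_min_nm: float = 1.0
    grid_max_nm: float = 10_000.0
    n_bins: int = 64
    lambda_reg: float | str = "auto"
    penalty_order: int = 2
    weighting: str = "amplitude"
    refine: bool = True
    fit_beta: bool = False
    fit_baseline: bool = False

    def __post_init__(self) -> None:
        if not self.grid_min_nm < self.grid_max_nm:
            raise ValueError("grid_min_nm must be < grid_max_nm")
        if self.n_bins < 10:
            raise ValueError("n_bins must be >= 10")
        if self.penalty_order not in (0, 1, 2):
            raise ValueError("penalty_order must be 0, 1 or 2")
        if self.weighting not in ("amplitude", "none"):
            raise ValueError("weighting must be 'amplitude' or 'none'")
        if not (self.lambda_reg == "auto" or float(self.lambda_reg) >= 0):
            raise ValueError("lambda_reg must be 'auto' or a nonnegative number")

    def make_grid(self) -> SizeGrid:
        return SizeGrid.logspaced(self.grid_min_nm, self.grid_max_nm, self.n_bins)

    def to_dict(self) -> dict:
        return {
            "grid_min_nm": self.grid_min_nm,
            "grid_max_nm": self.grid_max_nm,
            "n_bins": self.n_bins,
            "lambda_reg": self.lambda_reg,
            "penalty_order": self.penalty_order,
            "weighting": self.weighting,
            "refine": self.refine,
            "fit_beta": self.fit_beta,
            "fit_baseline": self.fit_baseline,
        }


def build_kernel(grid: SizeGrid, trace: CorrelationTrace,
                 config: InstrumentConfig | None = None) -> np.ndarray:
    """Exponential kernel K[i, j] = exp(-Gamma(center_j) * tau_i)."""
    cfg = config or trace.config
    if cfg is None:
        raise ValueError("trace carries no instrument config and none was given")
    gammas = decay_rate(grid.centers_nm, cfg)
    expo = -np.outer(trace.tau_s, gammas)
    return np.exp(np.clip(expo, _EXP_CLIP, 0.0))


def difference_operator(n: int, order: int) -> np.ndarray:
    """Finite-difference penalty matrix L of the given order (0, 1 or 2)."""
    if order == 0:
        return np.eye(n)
    mat = np.eye(n)
    for _ in range(order):
        mat = np.diff(mat, axis=0)
    return mat


def _field_correlation(trace: CorrelationTrace, settings: InversionSettings):
    """Signed |g1| from g2 via the Siegert relation.

    Returns (g1, channel weights, beta, baseline).  The sign of
    g2 - baseline is kept through the square root so long-lag noise stays
    zero-mean instead of rectifying into a spurious positive plateau.
    """
    baseline = trace.baseline
    if settings.fit_baseline:
        tail = max(2, trace.g2.size // 20)  # mean of last 5% of lags
        baseline = float(trace.g2[-tail:].mean())
    excess = trace.g2 - baseline
    if np.sum(excess < 0) > trace.g2.size / 2:
        raise ValueError("baseline exceeds data")
    beta = trace.beta
    if settings.fit_beta or beta is None:
        beta = float(np.clip(np.max(excess), 1e-6, 1.0))
    if beta <= 0:
        raise ValueError("beta must be positive")
    g1 = np.sign(excess) * np.sqrt(np.abs(excess) / beta)
    if settings.weighting == "amplitude":
        wts = np.abs(g1)
        wts = np.maximum(wts, _WEIGHT_FLOOR * max(wts.max(), 1e-30))
    else:
        wts = np.ones_like(g1)
    return g1, wts, beta, baseline


def _solve_penalized(kernel, g1, wts, lam, lmat):
    """NNLS on the stacked system [W K; sqrt(lam) L] w = [W g1; 0]."""
    if lam > 0:
        a = np.vstack([wts[:, None] * kernel, np.sqrt(lam) * lmat])
        b = np.concatenate([wts * g1, np.zeros(lmat.shape[0])])
    else:
        a, b = wts[:, None] * kernel, wts * g1
    w, _ = nnls(a, b)
    resid = float(np.linalg.norm(wts * (kernel @ w - g1)))
    return w, resid


_LAMBDA_LADDER = np.geomspace(1e-8, 1e2, 26)


def select_lambda(trace: CorrelationTrace, settings: InversionSettings,
                  ladder: np.ndarray = _LAMBDA_LADDER,
                  grid: SizeGrid | None = None) -> float:
    """L-curve choice of the regularization weight.

    Solves the penalized problem along a log-spaced lambda ladder, traces
    the (log residual norm, log solution seminorm) curve, and returns the
    ladder member at the point of maximum Menger curvature of its convex
    corner.  Ties are broken toward the smallest lambda (prefer fidelity
    over smoothness).  Deterministic for a fixed trace.
    """
    grid = grid or settings.make_grid()
    kernel = build_kernel(grid, trace)
    g1, wts, _, _ = _field_correlation(trace, settings)
    lmat = difference_operator(grid.n_bins, settings.penalty_order)

    rho, eta, lams = [], [], []
    for lam in ladder:
        w, resid = _solve_penalized(kernel, g1, wts, float(lam), lmat)
        seminorm = float(np.linalg.norm(lmat @ w))
        if resid <= 0:
            continue
        rho.append(np.log(resid))
        eta.append(np.log(max(seminorm, 1e-300)))
        lams.append(float(lam))
    if len(lams) < 3:
        warnings.warn("fewer than 3 feasible ladder points; using the midpoint",
                      stacklevel=2)
        return float(ladder[len(ladder) // 2])

    x, y = np.asarray(rho), np.asarray(eta)
    curvature = np.zeros(len(lams))
    for k in range(1, len(lams) - 1):
        p0 = np.array([x[k - 1], y[k - 1]])
        p1 = np.array([x[k], y[k]])
        p2 = np.array([x[k + 1], y[k + 1]])
        a = np.linalg.norm(p1 - p0)
        b = np.linalg.norm(p2 - p1)
        c = np.linalg.norm(p2 - p0)
        if min(a, b, c) < 1e-12:
            continue
        cross = (p1 - p0)[0] * (p2 - p0)[1] - (p1 - p0)[1] * (p2 - p0)[0]
        # signed so that only the convex (L-shaped) corner scores positive
        curvature[k] = -2.0 * cross / (a * b * c)
    best = int(np.argmax(curvature))
    top = curvature[best]
    ties = [k for k in range(len(lams)) if abs(curvature[k] - top) < 1e-12]
    return float(lams[min(ties)])


def invert(trace: CorrelationTrace, settings: InversionSettings | None = None,
           grid: SizeGrid | None = None) -> SizeDistribution:
    """Invert a correlation trace to a subfraction histogram.

    Computes |g1| by the Siegert relation, solves the (weighted)
    Tikhonov-regularized NNLS problem on the settings' log-spaced radius
    grid, and normalizes the solution to percent contributions summing
    to 100.  An explicit ``grid`` overrides the grid the settings would
    construct.
    """
    settings = settings or InversionSettings()
    grid = grid or settings.make_grid()
    kernel = build_kernel(grid, trace)
    g1, wts, _, _ = _field_correlation(trace, settings)

    if settings.lambda_reg == "auto":
        lam = select_lambda(trace, settings)
    else:
        lam = float(settings.lambda_reg)
    lmat = difference_operator(grid.n_bins, settings.penalty_order)
    w, resid = _solve_penalized(kernel, g1, wts, lam, lmat)
    total = w.sum()
    if total <= 0:
        raise ValueError("degenerate trace: inversion found no signal")
    dist = SizeDistribution(
        grid=grid,
        contribution_pct=w / total * 100.0,
        residual_norm=resid,
        lambda_reg=lam,
    )
    if settings.refine:
        dist = refine_distribution(trace, dist, settings)
    return dist


def _histogram_clusters(dist: SizeDistribution, floor_pct: float = 0.1):
    """Contiguous occupied runs as (geometric-mean radius, weight fraction)."""
    pct = dist.contribution_pct
    log_cen = np.log(dist.grid.centers_nm)
    occupied = pct > floor_pct
    out = []
    i, n = 0, pct.size
    while i < n:
        if not occupied[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and occupied[j + 1]:
            j += 1
        w = pct[i : j + 1].sum()
        r = float(np.exp(np.average(log_cen[i : j + 1], weights=pct[i : j + 1])))
        out.append((r, float(w) / 100.0))
        i = j + 1
    return out


def _fit_discrete(trace, config, radii0, amps0, r_lo, r_hi, beta):
    """Bounded least squares of a k-exponential model directly on g2."""
    tau, g2 = trace.tau_s, trace.g2
    k = len(radii0)

    def residuals(p):
        gammas = decay_rate(np.exp(p[:k]), config)
        g1 = np.exp(-np.clip(np.outer(tau, gammas), 0.0, -_EXP_CLIP)) @ p[k:]
        return 1.0 + beta * g1**2 - g2

    p0 = np.concatenate(
        [np.log(np.clip(radii0, r_lo * 1.01, r_hi * 0.99)),
         np.clip(amps0, 1e-6, None)]
    )
    bounds = (
        np.concatenate([np.full(k, np.log(r_lo)), np.zeros(k)]),
        np.concatenate([np.full(k, np.log(r_hi)), np.full(k, 2.0)]),
    )
    sol = least_squares(residuals, p0, bounds=bounds, max_nfev=250)
    return np.exp(sol.x[:k]), sol.x[k:], float(2.0 * sol.cost)


def refine_distribution(trace: CorrelationTrace, dist: SizeDistribution,
                        settings: InversionSettings | None = None,
                        max_components: int = 4) -> SizeDistribution:
    """Sharpen a regularized histogram by a parsimonious discrete refit.

    The penalized-NNLS histogram localizes mass only to within the
    resolution the noise allows, which smears minority fractions over a
    decade or more.  This stage re-fits the trace in g2 space with a small
    number of discrete exponential components: candidate models are built
    from the histogram's clusters (as found, split, merged, and with a
    systematic scan of minority-radius starting points), each is optimized
    by bounded least squares, and the model chosen is the most parsimonious
    one whose chi-square is statistically indistinguishable from the best.
    Each refined component's weight is then deposited back onto the grid,
    split log-linearly between the two nearest bin centers, so the result
    is still a :class:`SizeDistribution` — just a sharp one.
    """
    settings = settings or InversionSettings()
    cfg = trace.config
    if cfg is None:
        return dist
    clusters = _histogram_clusters(dist)
    if not clusters:
        return dist
    _, _, beta, _ = _field_correlation(trace, settings)
    r_lo, r_hi = dist.grid.edges_nm[0], dist.grid.edges_nm[-1]
    log_cen = np.log(dist.grid.centers_nm)
    pct = dist.contribution_pct

    total = sum(w for _, w in clusters)
    r_all = float(np.exp(sum(np.log(r) * w for r, w in clusters) / total))
    dominant = max(range(len(clusters)), key=lambda k: clusters[k][1])
    r_dom, w_dom = clusters[dominant]
    minority = max(total - w_dom, 0.05)

    candidates: dict[int, list] = {1: [[(r_all, total)]]}
    candidates.setdefault(len(clusters), []).append(list(clusters))
    # systematic starts scanning a minority radius over the grid, both
    # against the dominant cluster alone and on top of all found clusters
    for r_minor in np.geomspace(r_lo * 5, r_hi / 5, 6):
        candidates.setdefault(2, []).append(
            [(r_dom, w_dom), (float(r_minor), minority)]
        )
        if 1 < len(clusters) < max_components:
            candidates.setdefault(len(clusters) + 1, []).append(
                list(clusters) + [(float(r_minor), 0.05)]
            )
    # split each wide cluster at its weighted median
    occ_runs = []
    i, n = 0, pct.size
    floor = 0.1
    while i < n:
        if pct[i] <= floor:
            i += 1
            continue
        j = i
        while j + 1 < n and pct[j + 1] > floor:
            j += 1
        occ_runs.append((i, j))
        i = j + 1
    for ci, (i, j) in enumerate(occ_runs):
        if j - i < 1:
            continue
        csum = np.cumsum(pct[i : j + 1])
        m = i + min(int(np.searchsorted(csum, csum[-1] / 2.0)), j - i - 1)
        halves = []
        for a, b in ((i, m), (m + 1, j)):
            w = pct[a : b + 1].sum()
            if w > 0.01:
                halves.append(
                    (float(np.exp(np.average(log_cen[a : b + 1],
                                             weights=pct[a : b + 1]))),
                     float(w) / 100.0)
                )
        if len(halves) == 2:
            comps = [c for k2, c in enumerate(clusters) if k2 != ci] + halves
            candidates.setdefault(len(comps), []).append(comps)
    # merge adjacent cluster pairs
    for ci in range(len(clusters) - 1):
        (ra, wa), (rb, wb) = clusters[ci], clusters[ci + 1]
        merged = (float(np.exp((np.log(ra) * wa + np.log(rb) * wb) / (wa + wb))),
                  wa + wb)
        comps = clusters[:ci] + [merged] + clusters[ci + 2 :]
        candidates.setdefault(len(comps), []).append(comps)

    fits: dict[int, tuple] = {}
    for k, starts in candidates.items():
        if k > max_components:
            continue
        for comps in starts:
            radii0 = np.array([c[0] for c in comps])
            amps0 = np.array([c[1] for c in comps])
            r, a, chi2 = _fit_discrete(trace, cfg, radii0, amps0, r_lo, r_hi, beta)
            if k not in fits or chi2 < fits[k][2]:
                fits[k] = (r, a, chi2)

    k_best = min(fits, key=lambda k: fits[k][2])
    chi_best = fits[k_best][2]
    dof = max(trace.g2.size - 2 * k_best, 1)
    noise_var = chi_best / dof
    # accept a simpler model if removing components costs < ~4 sigma per pair
    threshold = chi_best + 16.0 * noise_var + 1e-12
    k_sel = k_best
    for k in sorted(fits):
        if fits[k][2] <= threshold:
            k_sel = k
            break
    radii, amps, _ = fits[k_sel]

    out = np.zeros(dist.grid.n_bins)
    centers = dist.grid.centers_nm
    for r, a in zip(radii, amps):
        if a <= 1e-9:
            continue
        pos = int(np.searchsorted(centers, r))
        if pos == 0:
            out[0] += a
        elif pos >= centers.size:
            out[-1] += a
        else:
            frac = (np.log(r) - log_cen[pos - 1]) / (log_cen[pos] - log_cen[pos - 1])
            out[pos - 1] += a * (1.0 - frac)
            out[pos] += a * frac
    if out.sum() <= 0:
        return dist
    return SizeDistribution(
        grid=dist.grid,
        contribution_pct=out / out.sum() * 100.0,
        residual_norm=dist.residual_norm,
        lambda_reg=dist.lambda_reg,
    )


def cumulant_check(trace: CorrelationTrace, n_decades: float = 1.0,
                   ) -> tuple[float, float]:
    """Second-order cumulant fit: (mean hydrodynamic radius nm, PDI).

    Fits ln|g1| = c0 - Gamma_mean * tau + (mu2 / 2) * tau^2 over the lags
    in the first ``n_decades`` decades of the trace.  Returns the
    intensity-weighted harmonic-mean radius via Stokes-Einstein and the
    polydispersity index mu2 / Gamma_mean^2.  Serves as an
    inversion-independent cross-check on unimodal samples.
    """
    cfg = trace.config
    if cfg is None:
        raise ValueError("trace carries no instrument config")
    excess = trace.g2 - trace.baseline
    beta = trace.beta if trace.beta is not None else float(np.max(excess))
    window = trace.tau_s <= trace.tau_s[0] * 10.0 ** n_decades
    if np.any(excess[window] <= 0):
        raise ValueError("non-positive g2 - baseline inside the fitted window")
    ln_g1 = 0.5 * np.log(excess[window] / beta)
    tau = trace.tau_s[window]
    if tau.size < 3:
        raise ValueError("too few channels in the cumulant window")
    coeffs = np.polynomial.polynomial.polyfit(tau, ln_g1, 2)
    gamma_mean = -coeffs[1]
    mu2 = 2.0 * coeffs[2]
    if gamma_mean <= 0:
        raise ValueError("cumulant fit produced a non-positive decay rate")
    # invert Gamma = D q^2 and Stokes-Einstein for the radius
    ref = decay_rate(1.0, cfg)  # Gamma of a 1 nm particle; Gamma ~ 1/R
    radius_nm = ref / gamma_mean
    pdi = max(mu2, 0.0) / gamma_mean**2
    return float(radius_nm), float(pdi)
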