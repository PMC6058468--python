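"""Ground-truth particle mixtures and the bench treatments applied to them.

A plasma or serum sample is modelled as a small set of discrete scattering
components, each with a hydrodynamic radius (nm) and an intensity-weighted
"contribution to scattering" in percent; contributions always sum to 100.
Two in-silico treatments mirror the wet-bench ones:

* protein-A depletion — immunoglobulins and their complexes are pulled out
  on sepharose beads, so the weight of every immunoglobulin-bearing
  component inside the immune-complex (IC) radius window is reduced by the
  depletion efficiency and the histogram is renormalized to 100%.  Large
  particles that contain no immunoglobulin (``ig_bearing=False``, e.g. the
  few-percent large-aggregate background of starved-animal serum) are not
  touched: the native-vs-depleted differential is exactly what identifies
  the IC fraction.
* anti-isotype antibody addition — complexes carrying the probed isotype
  are crosslinked into larger aggregates, so a chosen fraction of the
  IC-window weight moves to a new, larger radius (total weight conserved).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DEFAULT_IC_WINDOW",
    "MixtureComponent",
    "GroundTruthMixture",
    "NoiseModel",
    "apply_depletion",
    "apply_antibody_shift",
]

#: Default IC radius window, nm (half-open).  Food CICs sit at ~110-130 nm
#: in humans and 200-300 nm in rats; 100-400 nm covers both with margin.
DEFAULT_IC_WINDOW = (100.0, 400.0)

_WEIGHT_TOL = 1e-9


@dataclass(frozen=True)
class MixtureComponent:
    """One scattering species.

    ``ig_bearing`` marks components that contain immunoglobulin and are
    therefore removable by protein A and crosslinkable by anti-isotype
    antibodies; it defaults to True (immune complexes) and is set False for
    inert large-particle background.
    """

    radius_nm: float
    weight_pct: float
    ig_bearing: bool = True

    def __post_init__(self) -> None:
        if self.radius_nm <= 0:
            raise ValueError("radius_nm must be positive")
        if not 0.0 <= self.weight_pct <= 100.0:
            raise ValueError("weight_pct must lie in [0, 100]")


@dataclass(frozen=True)
class GroundTruthMixture:
    """An ordered set of components whose weights sum to 100%.

    Components are stored sorted by radius; components with identical radius
    and class are merged, so sorted radii within a class are strictly
    increasing.
    """

    components: tuple
    label: str = ""

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError("empty mixture")
        comps = [
            c if isinstance(c, MixtureComponent) else MixtureComponent(*c)
            for c in self.components
        ]
        merged: dict = {}
        for c in sorted(comps, key=lambda c: (c.radius_nm, not c.ig_bearing)):
            key = (c.radius_nm, c.ig_bearing)
            merged[key] = merged.get(key, 0.0) + c.weight_pct
        comps = tuple(
            MixtureComponent(r, w, ig) for (r, ig), w in merged.items()
        )
        total = sum(c.weight_pct for c in comps)
        if abs(total - 100.0) > _WEIGHT_TOL:
            raise ValueError(f"component weights sum to {total}, expected 100")
        object.__setattr__(self, "components", comps)

    @property
    def radii_nm(self) -> np.ndarray:
        return np.array([c.radius_nm for c in self.components])

    @property
    def weights_pct(self) -> np.ndarray:
        return np.array([c.weight_pct for c in self.components])

    def window_weight(self, window_nm) -> float:
        """Summed weight of components with radius in the half-open window."""
        lo, hi = window_nm
        return float(
            sum(c.weight_pct for c in self.components if lo <= c.radius_nm < hi)
        )

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "components": [
                {
                    "radius_nm": c.radius_nm,
                    "weight_pct": c.weight_pct,
                    "ig_bearing": c.ig_bearing,
                }
                for c in self.components
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruthMixture":
        return cls(
            components=tuple(
                MixtureComponent(
                    c["radius_nm"], c["weight_pct"], c.get("ig_bearing", True)
                )
                for c in d["components"]
            ),
            label=d.get("label", ""),
        )


@dataclass(frozen=True)
class NoiseModel:
    """Additive Gaussian perturbation of the measured correlation values.

    The per-channel standard deviation is ``sigma0 * ((i + 1) / n) **
    tau_scaling`` for channel index i of n, so ``tau_scaling = 0`` gives
    homoscedastic noise and positive values grow the noise toward long lags,
    where photon-correlation estimates are genuinely poorer.  ``sigma0 = 0``
    produces bit-identical noise-free traces regardless of seed.
    """

    sigma0: float = 0.0
    tau_scaling: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma0 < 0:
            raise ValueError("sigma0 must be >= 0")

    def sample(self, n: int) -> np.ndarray:
        if self.sigma0 == 0:
            return np.zeros(n)
        rng = np.random.default_rng(self.seed)
        scale = self.sigma0 * ((np.arange(n) + 1.0) / n) ** self.tau_scaling
        return rng.normal(0.0, 1.0, n) * scale


def _rebuild(comps, label) -> GroundTruthMixture:
    comps = [c for c in comps if c.weight_pct > 0]
    total = sum(c.weight_pct for c in comps)
    if total <= 0:
        raise ValueError("treatment removed all scattering weight")
    comps = [
        MixtureComponent(
            c.radius_nm, min(c.weight_pct * 100.0 / total, 100.0), c.ig_bearing
        )
        for c in comps
    ]
    return GroundTruthMixture(tuple(comps), label=label)


def apply_depletion(
    mixture: GroundTruthMixture,
    ic_window=DEFAULT_IC_WINDOW,
    efficiency: float = 1.0,
) -> GroundTruthMixture:
    """Protein-A depletion: attenuate Ig-bearing IC-window weight, renormalize.

    Ig-bearing components with radius inside the half-open ``ic_window``
    keep a fraction ``1 - efficiency`` of their weight; all weights are then
    rescaled so the histogram again sums to 100%.  ``efficiency = 0`` is the
    identity, as is an empty window.
    """
    if not 0.0 <= efficiency <= 1.0:
        raise ValueError("efficiency must lie in [0, 1]")
    lo, hi = ic_window
    if not lo < hi:
        warnings.warn("empty ic_window: depletion is the identity", stacklevel=2)
        return mixture
    if efficiency == 0.0:
        return mixture
    comps = [
        MixtureComponent(
            c.radius_nm,
            c.weight_pct * (1.0 - efficiency)
            if (c.ig_bearing and lo <= c.radius_nm < hi)
            else c.weight_pct,
            c.ig_bearing,
        )
        for c in mixture.components
    ]
    return _rebuild(comps, f"{mixture.label}+depleted".lstrip("+"))


def apply_antibody_shift(
    mixture: GroundTruthMixture,
    target_fraction: float,
    shifted_radius_nm: float,
    ic_window=DEFAULT_IC_WINDOW,
) -> GroundTruthMixture:
    """Anti-isotype crosslinking: move part of the IC weight to a larger radius.

    ``target_fraction`` of the Ig-bearing weight inside ``ic_window`` (the
    share of ICs carrying the probed isotype) is relocated to a single new
    component at ``shifted_radius_nm``.  Total weight is conserved, so no
    renormalization is needed.
    """
    if not 0.0 <= target_fraction <= 1.0:
        raise ValueError("target_fraction must lie in [0, 1]")
    lo, hi = ic_window
    inside = [
        c for c in mixture.components if c.ig_bearing and lo <= c.radius_nm < hi
    ]
    if target_fraction == 0.0 or not inside:
        return mixture
    max_ic_radius = max(c.radius_nm for c in inside)
    if shifted_radius_nm <= max_ic_radius:
        raise ValueError(
            f"shift must enlarge: shifted_radius_nm={shifted_radius_nm} is not "
            f"above the largest IC radius {max_ic_radius}"
        )
    moved = sum(c.weight_pct for c in inside) * target_fraction
    comps = [
        MixtureComponent(
            c.radius_nm,
            c.weight_pct * (1.0 - target_fraction)
            if (c.ig_bearing and lo <= c.radius_nm < hi)
            else c.weight_pct,
            c.ig_bearing,
        )
        for c in mixture.components
        if not (c.ig_bearing and lo <= c.radius_nm < hi and target_fraction == 1.0)
    ]
    comps.append(MixtureComponent(shifted_radius_nm, moved, True))
    return GroundTruthMixture(
        tuple(c for c in comps if c.weight_pct > 0),
        label=f"{mixture.label}+shifted".lstrip("+"),
    )
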