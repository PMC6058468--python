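"""File formats: trace CSV, distribution TSV, profile/config sidecars.

All files are UTF-8 text with "." decimals: correlation traces are
comma-separated (columns ``tau_s, g2``) with an optional JSON sidecar
carrying the instrument config, coherence factor and provenance; size
distributions are tab-separated (columns ``rh_lo_nm, rh_hi_nm,
rh_center_nm, contribution_pct``) with a JSON metadata sidecar; pipeline
configuration is YAML.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .inversion import CorrelationTrace, InversionSettings, SizeDistribution, SizeGrid
from .mixtures import DEFAULT_IC_WINDOW
from .physics import InstrumentConfig
from .profiling import DEFAULT_SHIFTED_WINDOWS, SampleProfile
from .simulate import DEFAULT_BETA, HUMAN_ISOTYPE_IC_WINDOW

__all__ = [
    "PipelineConfig",
    "read_trace",
    "write_trace",
    "read_distribution",
    "write_distribution",
    "read_profile",
    "write_profile",
]

log = logging.getLogger("cicdls")


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_trace(trace: CorrelationTrace, path) -> Path:
    """Write a trace as CSV plus a JSON sidecar; returns the CSV path."""
    path = Path(path)
    pd.DataFrame({"tau_s": trace.tau_s, "g2": trace.g2}).to_csv(
        path, index=False, float_format="%.17g"
    )
    meta = dict(trace.meta)
    meta["beta"] = trace.beta
    meta["baseline"] = trace.baseline
    _sidecar(path).write_text(json.dumps(meta, indent=1))
    return path


def read_trace(path) -> CorrelationTrace:
    """Read a trace CSV (columns tau_s, g2) and its JSON sidecar if present.

    Without a sidecar the default coherence factor is assumed and a warning
    is logged.  Non-monotone lag times are rejected with the offending line
    number (line 1 is the header).
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = {"tau_s", "g2"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    tau = df["tau_s"].to_numpy(float)
    bad = np.nonzero(np.diff(tau) <= 0)[0]
    if tau.size and tau[0] <= 0:
        raise ValueError(f"{path}: non-positive tau_s at line 2")
    if bad.size:
        raise ValueError(
            f"{path}: tau_s not strictly increasing at line {int(bad[0]) + 3}"
        )
    side = _sidecar(path)
    if side.exists():
        meta = json.loads(side.read_text())
        beta = meta.pop("beta", DEFAULT_BETA)
        baseline = meta.pop("baseline", 1.0)
    else:
        log.warning("%s: no sidecar found, assuming beta=%s", path, DEFAULT_BETA)
        meta, beta, baseline = {}, DEFAULT_BETA, 1.0
    return CorrelationTrace(
        tau_s=tau, g2=df["g2"].to_numpy(float), beta=beta,
        baseline=baseline, meta=meta,
    )


def write_distribution(dist: SizeDistribution, path) -> Path:
    """Write a subfraction histogram as TSV plus JSON metadata."""
    path = Path(path)
    edges = dist.grid.edges_nm
    pd.DataFrame(
        {
            "rh_lo_nm": edges[:-1],
            "rh_hi_nm": edges[1:],
            "rh_center_nm": dist.grid.centers_nm,
            "contribution_pct": dist.contribution_pct,
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.17g")
    _sidecar(path).write_text(
        json.dumps(
            {"lambda_reg": dist.lambda_reg, "residual_norm": dist.residual_norm},
            indent=1,
        )
    )
    return path


def read_distribution(path) -> SizeDistribution:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    required = {"rh_lo_nm", "rh_hi_nm", "contribution_pct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    edges = np.concatenate([df["rh_lo_nm"].to_numpy(float),
                            df["rh_hi_nm"].to_numpy(float)[-1:]])
    meta = {}
    side = _sidecar(path)
    if side.exists():
        meta = json.loads(side.read_text())
    return SizeDistribution(
        grid=SizeGrid(edges),
        contribution_pct=df["contribution_pct"].to_numpy(float),
        residual_norm=float(meta.get("residual_norm", 0.0)),
        lambda_reg=float(meta.get("lambda_reg", 0.0)),
    )


def write_profile(profile: SampleProfile, tsv_path) -> Path:
    """Write a profile: distribution TSV plus a metadata JSON sidecar."""
    tsv_path = Path(tsv_path)
    write_distribution(profile.distribution, tsv_path)
    meta = json.loads(_sidecar(tsv_path).read_text())
    meta.update(
        {
            "subject_id": profile.subject_id,
            "time_h": profile.time_h,
            "treatment": profile.treatment,
            "panel": profile.panel,
            "site": profile.site,
        }
    )
    _sidecar(tsv_path).write_text(json.dumps(meta, indent=1))
    return tsv_path


def read_profile(tsv_path) -> SampleProfile:
    tsv_path = Path(tsv_path)
    dist = read_distribution(tsv_path)
    side = _sidecar(tsv_path)
    if not side.exists():
        raise ValueError(f"{tsv_path}: profile metadata sidecar missing")
    meta = json.loads(side.read_text())
    return SampleProfile(
        distribution=dist,
        subject_id=meta["subject_id"],
        time_h=meta.get("time_h"),
        treatment=meta.get("treatment", "native"),
        panel=meta.get("panel"),
        site=meta.get("site"),
    )


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs, loadable from one YAML file."""

    instrument: InstrumentConfig = field(default_factory=InstrumentConfig)
    inversion: InversionSettings = field(default_factory=InversionSettings)
    ic_window_nm: tuple[float, float] = DEFAULT_IC_WINDOW
    isotype_ic_window_nm: tuple[float, float] = HUMAN_ISOTYPE_IC_WINDOW
    shifted_windows: dict = field(
        default_factory=lambda: dict(DEFAULT_SHIFTED_WINDOWS)
    )
    ratio_min: float = 2.0
    abs_min_pct: float = 1.0
    seed: int = 0
    output_dir: str = "."

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        if "instrument" in raw:
            kwargs["instrument"] = InstrumentConfig.from_dict(raw["instrument"])
        if "inversion" in raw:
            kwargs["inversion"] = InversionSettings(**raw["inversion"])
        for key in ("ic_window_nm", "isotype_ic_window_nm"):
            if key in raw:
                kwargs[key] = tuple(raw[key])
        if "shifted_windows" in raw:
            kwargs["shifted_windows"] = {
                k: tuple(v) for k, v in raw["shifted_windows"].items()
            }
        for key in ("ratio_min", "abs_min_pct", "seed", "output_dir"):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(
                {
                    "instrument": self.instrument.to_dict(),
                    "inversion": self.inversion.to_dict(),
                    "ic_window_nm": list(self.ic_window_nm),
                    "isotype_ic_window_nm": list(self.isotype_ic_window_nm),
                    "shifted_windows": {
                        k: list(v) for k, v in self.shifted_windows.items()
                    },
                    "ratio_min": self.ratio_min,
                    "abs_min_pct": self.abs_min_pct,
                    "seed": self.seed,
                    "output_dir": self.output_dir,
                },
                sort_keys=False,
            )
        )
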