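"""Readers, writers and run configuration.

Datasets travel as CSV with columns ``time_min, lactate_mmol_L, phase`` and
an optional metadata block of ``# key: value`` comment lines (body weight,
dose, duration, infusion kind).  Reports are JSON; configuration round-trips
through YAML or JSON.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .estimation import FitResult, KineticDataset
from .exceptions import ParameterDomainError
from .infusion import InfusionProfile

REQUIRED_COLUMNS = ("time_min", "lactate_mmol_L", "phase")


@dataclass
class RunConfig:
    """Configuration for a full pipeline run."""

    model: str = "U"
    n_cells: int = 8
    shutoff_fraction: float = 0.99
    fsd: float = 0.05
    noise_cv: float = 0.05
    use_prior: bool = True
    transform: str = "log"
    seed: int | None = None
    out_dir: str = "."

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


def read_dataset(path: str | Path) -> KineticDataset:
    """Read a challenge dataset from CSV (with ``# key: value`` metadata)."""
    path = Path(path)
    meta: dict[str, str] = {}
    for line in path.read_text().splitlines():
        if not line.startswith("#"):
            break
        if ":" in line:
            key, _, val = line.lstrip("# ").partition(":")
            meta[key.strip()] = val.strip()
    df = pd.read_csv(path, comment="#")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ParameterDomainError(f"missing columns: {missing}")

    weight = float(meta.get("body_weight_kg", "nan"))
    if not np.isfinite(weight):
        raise ParameterDomainError("metadata body_weight_kg is required")
    dose = float(meta.get("dose_mmol_per_kg", 1.0))
    duration = float(meta.get("duration_min", 15.0))
    kind = meta.get("infusion_kind", "rectangular")
    mode = meta.get("units_mode", "U")
    profile = InfusionProfile(
        mode=mode,
        dose=dose if mode != "S" else dose * weight,
        nominal_duration=duration,
        body_weight=weight,
        kind=kind,
        n_cells=int(meta.get("n_cells", 8)),
    )
    return KineticDataset(
        times=df["time_min"].to_numpy(float),
        concentrations=df["lactate_mmol_L"].to_numpy(float),
        phase=df["phase"].to_numpy(object),
        body_weight=weight,
        protocol=profile,
        meta=meta,
    )


def write_dataset(dataset: KineticDataset, path: str | Path) -> None:
    """Write a dataset as CSV with its protocol metadata block."""
    path = Path(path)
    proto = dataset.protocol
    dose_per_kg = proto.dose if proto.mode != "S" else proto.dose / dataset.body_weight
    lines = [
        f"# body_weight_kg: {dataset.body_weight}",
        f"# dose_mmol_per_kg: {dose_per_kg}",
        f"# duration_min: {proto.nominal_duration}",
        f"# infusion_kind: {proto.kind}",
        f"# units_mode: {proto.mode}",
        f"# n_cells: {proto.n_cells}",
    ]
    body = dataset.to_frame().to_csv(index=False)
    path.write_text("\n".join(lines) + "\n" + body)


def write_truth(dataset: KineticDataset, path: str | Path) -> None:
    """Ground-truth sidecar (JSON) for recovery experiments."""
    if dataset.truth is None:
        raise ParameterDomainError("dataset has no ground truth attached")
    t = dataset.truth
    payload = {
        "units_mode": t.units_mode,
        "L01": t.l01,
        "L21": t.l21,
        "L12": t.l12,
        "P1": t.baseline,
        "P2": t.pool_size,
        "K1": t.inverse_pool,
        "DT": t.dt,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def fit_report(fit: FitResult, dataset: KineticDataset, config: RunConfig | None = None) -> dict:
    """JSON-serializable parameter report (estimate, error, CV%).

    CVs are also given rounded to integer percent, the conventional
    presentation; full precision is retained alongside.
    """
    return {
        "package": "lactokin",
        "version": __version__,
        "model": fit.model,
        "converged": bool(fit.converged),
        "objective": fit.objective,
        "n_obs": int(np.sum(dataset.fit_mask)),
        "body_weight_kg": dataset.body_weight,
        "dose": dataset.protocol.dose,
        "duration_min": dataset.protocol.nominal_duration,
        "estimates": fit.estimates,
        "errors": fit.se,
        "cv_percent": fit.cv,
        "cv_percent_rounded": {k: int(round(v)) for k, v in fit.cv.items() if np.isfinite(v)},
        "baseline_prior": (
            {"mean": fit.prior.mean, "sd": fit.prior.sd, "n_obs": fit.prior.n_obs}
            if fit.prior is not None
            else None
        ),
        "config": asdict(config) if config is not None else None,
    }


def write_json(payload: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, default=float))


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
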