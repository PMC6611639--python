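"""Single-signal dose-response curves, (f, theta) fitting, and QS thresholds.

A tester strain exposed to increasing volumes of its cognate supernatant
shows a sigmoidal rise in LacZ fold change.  Simulating that curve with
the forward model and minimising the RMSE against measured fold changes
yields each strain's activation fold change ``f`` and half-maximum
concentration ``theta``.  The simulated fold change at a cognate
concentration of exactly ``theta`` defines the strain's activation
threshold: QS counts as ON when the fold change meets or exceeds it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .errors import NonIdentifiableError
from .params import EnvironmentParams, SignalMixture, StrainParams
from .simulate import fold_change_at

__all__ = [
    "DoseResponseDataset",
    "FitResult",
    "volume_to_concentration",
    "simulate_dose_response",
    "fit_dose_response",
    "activation_threshold",
]

DEFAULT_VOLUMES_UL = np.arange(0.0, 26.0, 1.0)  # 0-25 ul in 1 ul steps

# Fit bounds: f in (0, 100], theta in (0, 30] nM (30 nM = undiluted stock).
_F_BOUNDS = (1e-3, 100.0)
_THETA_BOUNDS = (1e-3, 30.0)


@dataclass(frozen=True)
class DoseResponseDataset:
    """Fold-change measurements (or synthetic stand-ins) for one strain."""

    strain_id: str
    volumes: np.ndarray  # ul
    fold_changes: np.ndarray  # dimensionless
    noise_sd: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.volumes, dtype=float)
        fc = np.asarray(self.fold_changes, dtype=float)
        object.__setattr__(self, "volumes", v)
        object.__setattr__(self, "fold_changes", fc)
        if v.shape != fc.shape:
            raise ValueError("volumes and fold_changes must have equal length")
        if np.any(v < 0):
            raise ValueError("volumes must be >= 0")
        if np.any(fc <= 0):
            raise ValueError("fold changes must be > 0")

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"volume_ul": self.volumes, "fold_change": self.fold_changes}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path: str | Path, strain_id: str = "") -> "DoseResponseDataset":
        df = pd.read_csv(path)
        return cls(strain_id=strain_id, volumes=df["volume_ul"].to_numpy(),
                   fold_changes=df["fold_change"].to_numpy())


@dataclass(frozen=True)
class FitResult:
    """Best-fit (f, theta), fit RMSE and the implied activation threshold."""

    strain_id: str
    f_hat: float
    theta_hat: float
    rmse: float
    threshold_fold: float

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "strain": self.strain_id,
                "f": self.f_hat,
                "theta_nM": self.theta_hat,
                "rmse": self.rmse,
                "threshold_fold": self.threshold_fold,
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload


def volume_to_concentration(x: float, mixture_defaults: SignalMixture | None = None):
    """Convert a supernatant volume (ul) to a signal concentration (nM).

    ``x`` ul of supernatant at the stock concentration (default 30 nM)
    diluted into the assay volume (default 200 ul) gives
    ``stock_conc * x / total_volume`` nM.  Accepts scalars or arrays.
    """
    mix = mixture_defaults or SignalMixture()
    xv = np.asarray(x, dtype=float)
    if np.any(xv < 0) or np.any(xv > mix.total_volume):
        raise ValueError(f"volume must lie in [0, {mix.total_volume}] ul")
    out = mix.stock_conc * xv / mix.total_volume
    return float(out) if np.isscalar(x) else out


def simulate_dose_response(
    params: StrainParams,
    env: EnvironmentParams | None = None,
    volumes: Sequence[float] = DEFAULT_VOLUMES_UL,
    mixture_defaults: SignalMixture | None = None,
) -> DoseResponseDataset:
    """Noise-free simulated fold changes of a tester vs cognate supernatant volume."""
    env = env or EnvironmentParams.tester_default()
    vols = np.asarray(volumes, dtype=float)
    conc = volume_to_concentration(vols, mixture_defaults)
    folds = fold_change_at(params, env, conc)
    return DoseResponseDataset(strain_id=params.strain_id, volumes=vols, fold_changes=folds)


def _rmse(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean((a - b) ** 2)))


def fit_dose_response(
    data: DoseResponseDataset,
    fixed: StrainParams | None = None,
    env: EnvironmentParams | None = None,
    mixture_defaults: SignalMixture | None = None,
    n_grid: int = 5,
    n_polish: int = 3,
) -> FitResult:
    """Fit (f, theta) to a dose-response curve by RMSE minimisation.

    All other kinetic constants are taken from ``fixed`` (defaults if
    omitted).  The optimiser evaluates the forward model on an
    ``n_grid`` x ``n_grid`` log-spaced grid of (f, theta) and polishes the
    ``n_polish`` best grid points with Nelder-Mead in log-parameter space,
    which makes the result deterministic and insensitive to the starting
    point.  Flat data (no dose dependence) raise
    :class:`~qscrosstalk.errors.NonIdentifiableError` rather than
    returning an arbitrary fit.
    """
    if data.volumes.size < 4:
        raise ValueError("need at least 4 dose-response points to fit")
    if np.ptp(data.fold_changes) < 0.05:
        raise NonIdentifiableError(
            "fold changes show no dose dependence; f and theta are not identifiable"
        )
    env = env or EnvironmentParams.tester_default()
    base = fixed or StrainParams(strain_id=data.strain_id or "?", f=1.0, theta=1.0)
    conc = volume_to_concentration(data.volumes, mixture_defaults)
    target = data.fold_changes

    def objective(log_ft: np.ndarray) -> float:
        f, theta = np.exp(log_ft)
        if not (_F_BOUNDS[0] <= f <= _F_BOUNDS[1] and _THETA_BOUNDS[0] <= theta <= _THETA_BOUNDS[1]):
            return np.inf
        candidate = base.with_fit(f, theta)
        return _rmse(fold_change_at(candidate, env, conc), target)

    f_grid = np.geomspace(0.5, _F_BOUNDS[1], n_grid)
    theta_grid = np.geomspace(0.05, _THETA_BOUNDS[1], n_grid)
    starts = [(np.log([f0, t0]), objective(np.log([f0, t0])))
              for f0 in f_grid for t0 in theta_grid]
    starts.sort(key=lambda s: s[1])

    best_x, best_val = starts[0]
    for x0, _ in starts[:n_polish]:
        res = minimize(
            objective, x0, method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-12, "maxiter": 2000},
        )
        if res.fun < best_val:
            best_x, best_val = res.x, res.fun

    f_hat, theta_hat = np.exp(best_x)
    fitted = base.with_fit(float(f_hat), float(theta_hat))
    return FitResult(
        strain_id=data.strain_id,
        f_hat=float(f_hat),
        theta_hat=float(theta_hat),
        rmse=float(best_val),
        threshold_fold=activation_threshold(fitted, env),
    )


def activation_threshold(params: StrainParams, env: EnvironmentParams | None = None) -> float:
    """Fold change at a cognate concentration of exactly ``theta``.

    This simulated value is the strain's ON/OFF boundary: a mixture
    activates QS when its fold change meets or exceeds it.  With a
    constant signal the fold change equals ``f * H + 1``, so the
    threshold approaches ``f/2 + 1``.
    """
    env = env or EnvironmentParams.tester_default()
    return float(fold_change_at(params, env, params.theta))
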