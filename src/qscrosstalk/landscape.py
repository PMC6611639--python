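"""Binary activation landscapes and crosstalk-weight extraction.

A pairwise crosstalk experiment loads a grid of (cognate volume,
interacting volume) supernatant combinations onto a tester strain and
records, for each cell, whether QS activated (fold change at or above the
strain's threshold).  Simulating the same grid for a candidate weight
``w`` of the interacting signal produces a predicted boolean landscape;
scanning ``w`` and keeping every value whose predicted landscape matches
the observation exactly yields a compatible interval, reported as
(midpoint, range).  The boundary of the ON region moves monotonically
with ``w``, which is what makes the landscape informative about both the
sign and the magnitude of the crosstalk.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .dose_response import activation_threshold, volume_to_concentration
from .errors import DimensionError, NoCompatibleWeightError
from .params import EnvironmentParams, SignalMixture, StrainParams
from .simulate import fold_change_at

__all__ = [
    "ActivationLandscape",
    "WeightEstimate",
    "DEFAULT_GRID_UL",
    "FINE_GRID_UL",
    "simulate_landscape",
    "extract_weight",
    "landscape_mismatch",
]

DEFAULT_GRID_UL = np.arange(0.0, 26.0, 5.0)  # 6x6: 0-25 ul in 5 ul steps
FINE_GRID_UL = np.arange(0.0, 26.0, 1.0)  # 26x26: 1 ul steps


@dataclass(frozen=True)
class ActivationLandscape:
    """Boolean QS activation grid over two supernatant volume axes.

    Rows index the cognate-signal volume, columns the interacting-signal
    volume; ``on[i, j]`` is True where QS activated.
    """

    tester_id: str
    interactor_id: str
    cognate_volumes: np.ndarray  # ul
    interactor_volumes: np.ndarray  # ul
    on: np.ndarray  # bool, (len(cognate), len(interactor))

    def __post_init__(self) -> None:
        cv = np.asarray(self.cognate_volumes, dtype=float)
        iv = np.asarray(self.interactor_volumes, dtype=float)
        on = np.asarray(self.on, dtype=bool)
        object.__setattr__(self, "cognate_volumes", cv)
        object.__setattr__(self, "interactor_volumes", iv)
        object.__setattr__(self, "on", on)
        for name, ax in (("cognate", cv), ("interactor", iv)):
            if ax.ndim != 1 or np.any(np.diff(ax) <= 0):
                raise ValueError(f"{name} volumes must be strictly increasing")
        if on.shape != (cv.size, iv.size):
            raise DimensionError(
                f"grid shape {on.shape} does not match axes ({cv.size}, {iv.size})"
            )

    def to_csv(self, path: str | Path) -> None:
        """Write as CSV: header = interactor volumes, first column = cognate."""
        df = pd.DataFrame(self.on.astype(int), index=self.cognate_volumes,
                          columns=self.interactor_volumes)
        df.to_csv(path, index_label="cognate_ul")

    @classmethod
    def from_csv(cls, path: str | Path, tester_id: str = "",
                 interactor_id: str = "") -> "ActivationLandscape":
        df = pd.read_csv(path, index_col=0)
        return cls(
            tester_id=tester_id,
            interactor_id=interactor_id,
            cognate_volumes=df.index.to_numpy(dtype=float),
            interactor_volumes=np.array([float(c) for c in df.columns]),
            on=df.to_numpy(dtype=float) != 0,
        )


@dataclass(frozen=True)
class WeightEstimate:
    """Interval of crosstalk weights compatible with an observed landscape."""

    w_mean: float
    w_lo: float
    w_hi: float
    compatible_count: int

    def __post_init__(self) -> None:
        if not (self.w_lo <= self.w_mean <= self.w_hi):
            raise ValueError("w_mean must lie within [w_lo, w_hi]")
        if self.compatible_count < 1:
            raise ValueError("a weight estimate requires at least one compatible weight")

    def __contains__(self, w: float) -> bool:
        return self.w_lo <= w <= self.w_hi


def simulate_landscape(
    tester: StrainParams,
    w_int: float,
    env: EnvironmentParams | None = None,
    cognate_volumes: Sequence[float] = DEFAULT_GRID_UL,
    interactor_volumes: Sequence[float] = DEFAULT_GRID_UL,
    interactor_id: str = "",
    mixture_defaults: SignalMixture | None = None,
) -> ActivationLandscape:
    """Predicted boolean activation landscape for one interaction weight.

    Each grid cell's effective concentration is
    ``max(0, c_cognate + w_int * c_interactor)``; the cell is ON when the
    simulated fold change at that effective concentration reaches the
    tester's activation threshold.
    """
    env = env or EnvironmentParams.tester_default()
    cv = np.asarray(cognate_volumes, dtype=float)
    iv = np.asarray(interactor_volumes, dtype=float)
    c_cog = volume_to_concentration(cv, mixture_defaults)
    c_int = volume_to_concentration(iv, mixture_defaults)
    c_eff = np.maximum(0.0, c_cog[:, None] + w_int * c_int[None, :])
    folds = fold_change_at(tester, env, c_eff.ravel()).reshape(c_eff.shape)
    threshold = activation_threshold(tester, env)
    return ActivationLandscape(
        tester_id=tester.strain_id,
        interactor_id=interactor_id,
        cognate_volumes=cv,
        interactor_volumes=iv,
        on=folds >= threshold,
    )


def landscape_mismatch(a: ActivationLandscape, b: ActivationLandscape) -> int:
    """Number of grid cells on which two landscapes disagree (0 iff equal)."""
    if not (
        np.array_equal(a.cognate_volumes, b.cognate_volumes)
        and np.array_equal(a.interactor_volumes, b.interactor_volumes)
    ):
        raise DimensionError("landscapes are defined on different grids")
    return int(np.sum(a.on != b.on))


def _critical_ceff(tester: StrainParams, env: EnvironmentParams) -> float:
    """Effective concentration at which the simulated fold change crosses threshold.

    With a constant effective signal the discrete reporter recurrence is
    linear in the activation boost, so the simulated fold change is a
    strictly increasing function of c_eff and the crossing point is
    unique; it is located by bisection on the same forward readout used
    by :func:`simulate_landscape`.
    """
    threshold = activation_threshold(tester, env)
    lo, hi = 0.0, 30.0 * max(1.0, tester.theta)
    if fold_change_at(tester, env, hi) < threshold:
        return np.inf
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if fold_change_at(tester, env, mid) >= threshold:
            hi = mid
        else:
            lo = mid
    return hi


def extract_weight(
    observed: ActivationLandscape,
    tester: StrainParams,
    env: EnvironmentParams | None = None,
    scan_lo: float = -3.0,
    scan_hi: float = 3.0,
    scan_step: float = 0.001,
    max_mismatch: int = 0,
    mixture_defaults: SignalMixture | None = None,
    method: str = "boundary",
) -> WeightEstimate:
    """Scan candidate weights and keep those reproducing the observed landscape.

    Parameters
    ----------
    observed :
        Measured (or synthetic) boolean landscape for one tester /
        interactor pair.
    scan_lo, scan_hi, scan_step :
        Inclusive weight scan range and step.
    max_mismatch :
        Number of disagreeing cells tolerated (0 = exact match, the
        default; useful > 0 for noisy observations).
    method :
        ``"boundary"`` (default) inverts the unique fold-change/threshold
        crossing once; for exact matching this yields the continuum
        compatible interval (endpoints not limited to the scan step),
        with the upper endpoint an open bound.  ``"direct"`` simulates
        the full landscape at every scanned weight and reports the
        min/max compatible scan point.  The two agree to within one scan
        step because the simulated fold change is strictly monotone in
        the effective concentration; the direct route is retained as the
        reference implementation.

    Returns
    -------
    WeightEstimate with the min, max, midpoint and count of compatible
    scanned weights.

    Raises
    ------
    NoCompatibleWeightError
        If no scanned weight reproduces the observation within
        ``max_mismatch`` cells.
    """
    if not scan_lo < scan_hi:
        raise ValueError("scan_lo must be < scan_hi")
    if scan_step <= 0:
        raise ValueError("scan_step must be > 0")
    env = env or EnvironmentParams.tester_default()
    n_w = int(round((scan_hi - scan_lo) / scan_step)) + 1
    ws = scan_lo + scan_step * np.arange(n_w)

    c_cog = volume_to_concentration(observed.cognate_volumes, mixture_defaults)
    c_int = volume_to_concentration(observed.interactor_volumes, mixture_defaults)

    if method == "boundary" and max_mismatch == 0:
        # Each cell with a non-zero interactor dose flips ON at a single
        # critical weight w_crit = (c* - c_cog) / c_int, so the exact
        # compatible set is the intersection of per-cell half-lines and
        # the scan endpoints are not resolution-limited.
        c_star = _critical_ceff(tester, env)
        lo, hi = scan_lo, scan_hi  # hi is an open (supremum) bound
        feasible = True
        for i, cc in enumerate(c_cog):
            for j, ci in enumerate(c_int):
                on_obs = observed.on[i, j]
                if ci == 0.0:
                    if on_obs != (cc >= c_star):
                        feasible = False
                else:
                    w_crit = (c_star - cc) / ci
                    if on_obs:
                        lo = max(lo, w_crit)
                    else:
                        hi = min(hi, w_crit)
        if not feasible or not lo < hi:
            raise NoCompatibleWeightError(
                f"no weight in [{scan_lo}, {scan_hi}] reproduces the observed landscape"
            )
        in_interval = int(np.sum((ws >= lo) & (ws < hi)))
        return WeightEstimate(
            w_mean=float(0.5 * (lo + hi)),
            w_lo=float(lo),
            w_hi=float(hi),
            compatible_count=max(1, in_interval),
        )

    if method == "boundary":
        c_star = _critical_ceff(tester, env)
        # (n_w, n_cog, n_int) boolean stack of predicted landscapes
        c_eff = np.maximum(
            0.0,
            c_cog[None, :, None] + ws[:, None, None] * c_int[None, None, :],
        )
        on = c_eff >= c_star
    elif method == "direct":
        c_eff = np.maximum(
            0.0,
            c_cog[None, :, None] + ws[:, None, None] * c_int[None, None, :],
        )
        folds = fold_change_at(tester, env, c_eff.ravel()).reshape(c_eff.shape)
        on = folds >= activation_threshold(tester, env)
    else:
        raise ValueError(f"unknown method {method!r}")

    mismatches = np.sum(on != observed.on[None, :, :], axis=(1, 2))
    compatible = ws[mismatches <= max_mismatch]
    if compatible.size == 0:
        raise NoCompatibleWeightError(
            f"no weight in [{scan_lo}, {scan_hi}] reproduces the observed landscape "
            f"(best match differs in {int(mismatches.min())} cells)"
        )
    w_lo, w_hi = float(compatible.min()), float(compatible.max())
    return WeightEstimate(
        w_mean=0.5 * (w_lo + w_hi),
        w_lo=w_lo,
        w_hi=w_hi,
        compatible_count=int(compatible.size),
    )
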