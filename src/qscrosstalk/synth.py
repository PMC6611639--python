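"""Synthetic data generators with known ground truth.

Every input the analysis stages consume can be generated here from the
forward model itself: plate-reader-style fluorescence-per-cell traces of
the LacZ reporter assay, dose-response curves with additive measurement
noise, boolean activation landscapes with bit-flip noise, and random
multi-strain communities.  Because the generating parameters are known,
each downstream stage (fitting, threshold extraction, weight inversion,
state prediction) can be validated end-to-end without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .dose_response import DoseResponseDataset, simulate_dose_response
from .landscape import ActivationLandscape, DEFAULT_GRID_UL, simulate_landscape
from .params import (
    EnvironmentParams,
    StrainParams,
    WeightMatrix,
    table1_params,
)
from .simulate import SimulationResult

__all__ = [
    "FluorescenceTrace",
    "emulate_plate_reader",
    "lacz_rate",
    "gen_dose_response",
    "gen_landscape",
    "gen_community_fixture",
]

DEFAULT_GAIN = 1.0  # fluorescence units per (LacZ unit / cell-density unit)


@dataclass(frozen=True)
class FluorescenceTrace:
    """Plate-reader-style readout: fluorescence per cell and an OD proxy."""

    times: np.ndarray  # min
    fluor_per_cell: np.ndarray  # arbitrary fluorescence units
    od: np.ndarray  # optical-density proxy (density / capacity)

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        fl = np.asarray(self.fluor_per_cell, dtype=float)
        od = np.asarray(self.od, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "fluor_per_cell", fl)
        object.__setattr__(self, "od", od)
        if not (t.shape == fl.shape == od.shape):
            raise ValueError("times, fluorescence and OD must have equal length")


def emulate_plate_reader(
    sim: SimulationResult,
    gain: float = DEFAULT_GAIN,
    noise_sd: float = 0.0,
    seed: int | None = None,
    capacity: float = 1e9,
) -> FluorescenceTrace:
    """Turn a simulated tester run into a noisy fluorescence-per-cell trace.

    The fluorogenic LacZ substrate reports accumulated enzyme activity,
    so the trace is ``gain * L(t) / n(t)`` plus seeded additive Gaussian
    noise.  The OD channel is the tester density relative to capacity.
    """
    if sim.L is None or sim.tester is None:
        raise ValueError("simulation must include a tester LacZ trajectory")
    n = sim.n[sim.tester]
    rng = np.random.default_rng(seed)
    clean = gain * sim.L / np.maximum(n, 1.0)
    noise = rng.normal(0.0, noise_sd, size=clean.shape) if noise_sd > 0 else 0.0
    return FluorescenceTrace(
        times=sim.times.copy(),
        fluor_per_cell=clean + noise,
        od=n / capacity,
    )


def lacz_rate(trace: FluorescenceTrace, window: tuple[float, float] = (0.0, 5.0)) -> float:
    """LacZ expression level: fluorescence-per-cell slope over a time window.

    Ordinary least-squares gradient (fluorescence units per min) over the
    window given in hours, default the 0-5 h linear region.
    """
    lo, hi = (w * 60.0 for w in window)
    mask = (trace.times >= lo) & (trace.times <= hi)
    if mask.sum() < 3:
        raise ValueError("rate window must contain at least 3 trace points")
    slope = np.polyfit(trace.times[mask], trace.fluor_per_cell[mask], 1)[0]
    return float(slope)


def gen_dose_response(
    truth: StrainParams,
    volumes: Sequence[float] | None = None,
    noise_sd: float = 0.0,
    seed: int | None = None,
    env: EnvironmentParams | None = None,
    floor: float = 0.05,
) -> DoseResponseDataset:
    """Dose-response curve from known truth plus additive Gaussian noise.

    Noise is applied to the fold changes and floored at a small positive
    value so the dataset stays admissible.  ``noise_sd=0`` returns the
    noiseless forward simulation unchanged.
    """
    from .dose_response import DEFAULT_VOLUMES_UL

    vols = DEFAULT_VOLUMES_UL if volumes is None else np.asarray(volumes, dtype=float)
    clean = simulate_dose_response(truth, env=env, volumes=vols)
    if noise_sd <= 0:
        return clean
    rng = np.random.default_rng(seed)
    noisy = np.maximum(floor, clean.fold_changes + rng.normal(0.0, noise_sd, vols.shape))
    return DoseResponseDataset(
        strain_id=truth.strain_id, volumes=vols, fold_changes=noisy,
        noise_sd=noise_sd, seed=seed,
    )


def gen_landscape(
    truth: StrainParams,
    true_w: float,
    grid: Sequence[float] = DEFAULT_GRID_UL,
    flip_prob: float = 0.0,
    seed: int | None = None,
    env: EnvironmentParams | None = None,
    interactor_id: str = "",
) -> ActivationLandscape:
    """Activation landscape from a known weight, with optional bit-flip noise."""
    if not 0.0 <= flip_prob < 0.5:
        raise ValueError("flip_prob must lie in [0, 0.5)")
    clean = simulate_landscape(
        truth, true_w, env=env,
        cognate_volumes=grid, interactor_volumes=grid,
        interactor_id=interactor_id,
    )
    if flip_prob == 0.0:
        return clean
    rng = np.random.default_rng(seed)
    flips = rng.random(clean.on.shape) < flip_prob
    return ActivationLandscape(
        tester_id=clean.tester_id,
        interactor_id=clean.interactor_id,
        cognate_volumes=clean.cognate_volumes,
        interactor_volumes=clean.interactor_volumes,
        on=clean.on ^ flips,
    )


def gen_community_fixture(
    n_strains: int,
    weight_law: str | tuple[float, float] = (-1.5, 1.5),
    seed: int | None = None,
) -> tuple[list[StrainParams], WeightMatrix]:
    """Random community with known parameters and crosstalk weights.

    Strain (f, theta) values are reused cyclically from the packaged
    five-strain community; off-diagonal weights are drawn uniformly from
    the given ``(lo, hi)`` range (or all set to 0 for
    ``weight_law="zero"``), with unit self-weights.
    """
    if n_strains < 2:
        raise ValueError("a community needs at least 2 strains")
    base = table1_params()
    strains = []
    for i in range(n_strains):
        src = base[i % len(base)]
        sid = src.strain_id if n_strains <= len(base) else f"{src.strain_id}{i // len(base)}"
        strains.append(StrainParams(strain_id=sid, f=src.f, theta=src.theta))
    order = tuple(p.strain_id for p in strains)

    if weight_law == "zero":
        w = np.eye(n_strains)
    else:
        lo, hi = weight_law
        rng = np.random.default_rng(seed)
        w = rng.uniform(lo, hi, size=(n_strains, n_strains))
        np.fill_diagonal(w, 1.0)
    return strains, WeightMatrix(order, w)
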