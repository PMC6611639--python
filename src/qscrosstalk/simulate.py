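"""Forward simulation of quorum-sensing gene expression and signal dynamics.

The model couples three processes with explicit forward-Euler stepping
(default step 1 min):

* logistic growth of each strain's cell density ``n_i`` toward a shared
  carrying capacity ``s``:  dn_i/dt = mu_i n_i (1 - n_tot / s);

* Hill-regulated production of the LacZ reporter in a tester strain:
  dL/dt = rho_L n_i (f_i H(C_eff,i) + 1) - gamma_L L, where
  H(c) = c^m / (c^m + theta^m);

* Hill-regulated production of each producer strain's signal:
  dc_i/dt = rho_c,i n_i (f_i H(C_eff,i) + 1) - gamma_c,i c_i.

Crosstalk enters through the effective concentration
C_eff,i = max(0, sum_j w_ij c_j): every signal variant contributes to each
strain's activation with a signed weight, and a net-inhibitory mixture is
clamped to zero (no "negative concentration" is sensed).

Tester strains carry the reporter but do not produce signal; in a
supernatant assay the exogenous signal bolus is held constant by default
(``decay_tester_signal=True`` enables first-order decay instead).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateBaselineError, DimensionError, IntegrationError
from .params import EnvironmentParams, StrainParams, WeightMatrix

__all__ = [
    "SimulationResult",
    "effective_concentration",
    "hill_activation",
    "simulate",
    "fold_change",
    "fold_change_at",
]


def effective_concentration(weights_row: np.ndarray, conc: np.ndarray) -> float:
    """Clamped weighted sum of signal concentrations sensed by one strain.

    Returns ``max(0, sum_j w_j * c_j)`` in nM.  A net-inhibitory mixture
    yields exactly 0: inhibitory signals can cancel excitatory ones but a
    receptor cannot see less than no signal.
    """
    w = np.asarray(weights_row, dtype=float)
    c = np.asarray(conc, dtype=float)
    if w.shape != c.shape:
        raise DimensionError(f"weights {w.shape} and concentrations {c.shape} differ")
    if np.any(c < 0):
        raise ValueError("signal concentrations must be >= 0")
    return float(max(0.0, np.dot(w, c)))


def hill_activation(c_eff, theta: float, m: float):
    """Hill fraction ``c^m / (c^m + theta^m)`` in [0, 1].

    Accepts scalar or array ``c_eff`` (nM); monotone non-decreasing, with
    value 0 at zero signal and 1/2 at ``c_eff == theta``.
    """
    if theta <= 0 or m <= 0:
        raise ValueError("theta and m must be > 0")
    c = np.asarray(c_eff, dtype=float)
    if np.any(c < 0):
        raise ValueError("effective concentration must be >= 0")
    cm = np.power(c, m)
    out = cm / (cm + theta**m)
    return float(out) if np.isscalar(c_eff) else out


@dataclass(frozen=True)
class SimulationResult:
    """Trajectories from one forward run.

    Attributes
    ----------
    times : (T,) array, minutes.
    strain_order : labels of the simulated strains.
    n : (k, T) cell densities, cells/mL.
    c : (k, T) signal concentrations, nM.
    L : (T,) LacZ trajectory of the tester, or None if no tester was set.
    tester : index of the tester strain, or None.
    """

    times: np.ndarray
    strain_order: tuple[str, ...]
    n: np.ndarray
    c: np.ndarray
    L: np.ndarray | None = None
    tester: int | None = None

    @property
    def final_L(self) -> float:
        if self.L is None:
            raise ValueError("this run had no tester reporter")
        return float(self.L[-1])

    def final_c(self) -> np.ndarray:
        return self.c[:, -1].copy()

    def to_tidy(self) -> pd.DataFrame:
        """Long-format table: time_min, variable, strain, value."""
        rows = []
        for i, sid in enumerate(self.strain_order):
            rows.append(pd.DataFrame({"time_min": self.times, "variable": "n",
                                      "strain": sid, "value": self.n[i]}))
            rows.append(pd.DataFrame({"time_min": self.times, "variable": "c",
                                      "strain": sid, "value": self.c[i]}))
        if self.L is not None:
            sid = self.strain_order[self.tester] if self.tester is not None else ""
            rows.append(pd.DataFrame({"time_min": self.times, "variable": "L",
                                      "strain": sid, "value": self.L}))
        return pd.concat(rows, ignore_index=True)

    def to_csv(self, path: str | Path) -> None:
        self.to_tidy().to_csv(path, index=False)


def _check_finite(name: str, value: np.ndarray, t_min: float) -> None:
    if not np.all(np.isfinite(value)):
        raise IntegrationError(f"state {name!r} became non-finite at t = {t_min:g} min")


def simulate(
    strains: Sequence[StrainParams],
    W: WeightMatrix,
    env: EnvironmentParams,
    init_c: Sequence[float] | None = None,
    produce_signal: Sequence[bool] | None = None,
    tester: int | None = None,
    decay_tester_signal: bool = False,
    boluses: Sequence[tuple[float, int, float]] = (),
) -> SimulationResult:
    """Integrate the coupled growth/signal/reporter equations.

    Parameters
    ----------
    strains, W, env :
        Strain parameters, crosstalk weights and environment.  Dimensions
        must agree; ``env.n0`` supplies one initial density per strain.
    init_c :
        Initial signal concentration per strain (nM), default all zero.
    produce_signal :
        Flags marking producer strains.  Non-producers (testers) hold
        their signal constant unless ``decay_tester_signal`` is set, in
        which case the signal decays at ``gamma_c``.
    tester :
        Index of the strain whose LacZ reporter is tracked (optional).
    boluses :
        Instantaneous signal additions ``(time_min, strain_index,
        delta_conc_nM)`` applied at the first step at or after the given
        time (used for supernatant perturbations).

    Returns
    -------
    SimulationResult with uniformly spaced times (env.dt minutes apart).
    """
    k = len(strains)
    if len(W.strain_order) != k:
        raise DimensionError(f"{k} strains but weight matrix is {len(W.strain_order)}x")
    if len(env.n0) != k:
        raise DimensionError(f"{k} strains but env.n0 has {len(env.n0)} entries")
    c = np.zeros(k) if init_c is None else np.asarray(init_c, dtype=float).copy()
    if c.shape != (k,):
        raise DimensionError(f"init_c must have length {k}")
    if np.any(c < 0):
        raise ValueError("init_c must be >= 0")
    produce = (
        np.ones(k, dtype=bool)
        if produce_signal is None
        else np.asarray(produce_signal, dtype=bool)
    )
    if produce.shape != (k,):
        raise DimensionError(f"produce_signal must have length {k}")

    f = np.array([p.f for p in strains])
    theta = np.array([p.theta for p in strains])
    m = np.array([p.m for p in strains])
    rho_c = np.array([p.rho_c for p in strains])
    gamma_c = np.array([p.gamma_c for p in strains])
    mu = np.array([p.mu for p in strains]) / 60.0  # 1/h -> 1/min
    dt = env.dt
    n_steps = env.n_steps

    n = np.asarray(env.n0, dtype=float).copy()
    L = 0.0
    if tester is not None:
        p_t = strains[tester]

    pending = sorted(boluses, key=lambda b: b[0])
    for t_min, idx, dc in pending:
        if not 0 <= idx < k:
            raise DimensionError(f"bolus strain index {idx} out of range")
        if t_min > env.duration * 60.0:
            raise ValueError(f"bolus at {t_min} min is after the simulated duration")

    times = np.arange(n_steps + 1, dtype=float) * dt
    n_traj = np.empty((k, n_steps + 1))
    c_traj = np.empty((k, n_steps + 1))
    L_traj = np.empty(n_steps + 1) if tester is not None else None

    bolus_i = 0
    # overflow/invalid intermediates are caught explicitly and reported as
    # IntegrationError, so numpy's runtime warnings are suppressed here
    with np.errstate(over="ignore", invalid="ignore"):
        for step in range(n_steps + 1):
            t = times[step]
            while bolus_i < len(pending) and pending[bolus_i][0] <= t:
                _, idx, dc = pending[bolus_i]
                c[idx] += dc
                bolus_i += 1

            n_traj[:, step] = n
            c_traj[:, step] = c
            c_eff = np.maximum(0.0, W.w @ c)
            cm = np.power(c_eff, m)
            H = cm / (cm + np.power(theta, m))
            if L_traj is not None:
                L_traj[step] = L
            if step == n_steps:
                break

            boost = f * H + 1.0
            dn = mu * n * (1.0 - n.sum() / env.s)
            dc_dt = np.where(
                produce,
                rho_c * n * boost - gamma_c * c,
                -gamma_c * c if decay_tester_signal else 0.0,
            )
            n = np.maximum(0.0, n + dt * dn)
            c = np.maximum(0.0, c + dt * dc_dt)
            _check_finite("n", n, t)
            _check_finite("c", c, t)
            if tester is not None:
                dL = p_t.rho_L * n_traj[tester, step] * boost[tester] - p_t.gamma_L * L
                L = max(0.0, L + dt * dL)
                if not np.isfinite(L):
                    raise IntegrationError(
                        f"state 'L' became non-finite at t = {t:g} min"
                    )

    return SimulationResult(
        times=times, strain_order=W.strain_order, n=n_traj, c=c_traj,
        L=L_traj, tester=tester,
    )


def fold_change(L_signal: SimulationResult, L_nosignal: SimulationResult) -> float:
    """Ratio of final LacZ with signal to final LacZ without signal.

    Both runs must share environment and strain parameters so that the
    baseline differs only in the absence of signal.
    """
    base = L_nosignal.final_L
    if base <= 0:
        raise DegenerateBaselineError("no-signal reference run has zero final LacZ")
    return L_signal.final_L / base


def fold_change_at(
    tester: StrainParams,
    env: EnvironmentParams,
    c_eff,
) -> np.ndarray | float:
    """Simulated LacZ fold change of a tester held at constant effective signal.

    Integrates reporter expression and logistic growth for each effective
    concentration in ``c_eff`` (scalar or array, nM) alongside a shared
    no-signal baseline, and returns final-time LacZ ratios with the same
    shape as the input.  This is the elementary readout behind
    dose-response curves, activation thresholds, landscape cells and
    community-state bits.
    """
    scalar = np.isscalar(c_eff)
    ce = np.atleast_1d(np.asarray(c_eff, dtype=float))
    if np.any(ce < 0):
        raise ValueError("effective concentrations must be >= 0")
    H = hill_activation(ce, tester.theta, tester.m)
    boost = tester.f * H + 1.0

    dt = env.dt
    mu = tester.mu / 60.0
    n = float(env.n0[0])
    L = np.zeros_like(boost)
    L_base = 0.0
    for _ in range(env.n_steps):
        prod = tester.rho_L * n
        L = np.maximum(0.0, L + dt * (prod * boost - tester.gamma_L * L))
        L_base = max(0.0, L_base + dt * (prod - tester.gamma_L * L_base))
        n = max(0.0, n + dt * mu * n * (1.0 - n / env.s))
    if L_base <= 0:
        raise DegenerateBaselineError("no-signal reference trajectory has zero LacZ")
    folds = L / L_base
    return float(folds[0]) if scalar else folds
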