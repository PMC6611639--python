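"""Growing producer cocultures, inoculation-ratio sweeps and signal perturbations.

When producer strains grow together from low density, each strain's
signal production is itself QS-regulated, so the signals, the growth and
the crosstalk feed back on one another.  The outcome — which strains'
signals accumulate past their activation thresholds by harvest time — can
then depend on the inoculation ratio and on the timing of an external
signal perturbation, not just on which strains are present.

As in the wet protocol, a coculture's QS outcome is read out indirectly:
the supernatant harvested at the end of the run is applied to tester
strains, whose fold change (normalised by each strain's activation
threshold) determines the reported ON/OFF state.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .dose_response import activation_threshold
from .params import EnvironmentParams, StrainParams, WeightMatrix
from .simulate import SimulationResult, fold_change_at, simulate

__all__ = [
    "PerturbationSpec",
    "CocultureOutcome",
    "RatioSweepResult",
    "simulate_coculture",
    "supernatant_assay",
    "ratio_sweep",
    "perturbation_timing_scan",
]

# Fraction of the 200 ul assay well occupied by coculture supernatant
# when testing mixed-producer cultures (150 ul of supernatant per well).
ASSAY_DILUTION = 150.0 / 200.0


@dataclass(frozen=True)
class PerturbationSpec:
    """A bolus of one strain's supernatant added to a growing coculture."""

    source_strain: str
    volume: float  # ul
    time: float  # h after inoculation
    supernatant_conc: float = 30.0  # nM

    def __post_init__(self) -> None:
        if self.volume < 0:
            raise ValueError("perturbation volume must be >= 0")
        if self.time < 0:
            raise ValueError("perturbation time must be >= 0")

    def delta_conc(self, culture_volume_ml: float) -> float:
        """Instantaneous signal increment (nM) after dilution into the culture."""
        vol_ml = self.volume / 1000.0
        return self.supernatant_conc * vol_ml / (culture_volume_ml + vol_ml)


@dataclass(frozen=True)
class CocultureOutcome:
    """Threshold-normalised tester response to a coculture's supernatant."""

    strain_order: tuple[str, ...]
    final_c: np.ndarray  # nM, undiluted coculture concentrations
    tester_fold: np.ndarray  # fold change / activation threshold, per strain
    active: tuple[bool, ...]
    ratio: float | None = None  # n0 ratio of first to second strain, if relevant

    def __post_init__(self) -> None:
        object.__setattr__(self, "final_c", np.asarray(self.final_c, dtype=float))
        object.__setattr__(self, "tester_fold", np.asarray(self.tester_fold, dtype=float))
        object.__setattr__(self, "active", tuple(bool(a) for a in self.active))
        if not all(
            a == (tf >= 1.0) for a, tf in zip(self.active, self.tester_fold)
        ):
            raise ValueError("active flags must equal (normalised fold >= 1)")


def simulate_coculture(
    strains: Sequence[StrainParams],
    W: WeightMatrix,
    n0: Sequence[float] | None = None,
    env: EnvironmentParams | None = None,
    perturbations: Sequence[PerturbationSpec] = (),
) -> SimulationResult:
    """Coupled growth and QS-regulated signal production of producer strains.

    All strains are producers sharing one logistic carrying capacity.
    Each perturbation adds an instantaneous signal increment
    ``conc * vol / (culture_volume + vol)`` to its source strain's signal
    at its given time; the added signal then decays like any other.
    """
    env = env or EnvironmentParams.coculture_default(len(strains))
    if n0 is not None:
        env = replace(env, n0=tuple(float(x) for x in n0))
    boluses = []
    for p in perturbations:
        if p.time > env.duration:
            raise ValueError(
                f"perturbation at {p.time} h is after the {env.duration} h run"
            )
        boluses.append((p.time * 60.0, W.index(p.source_strain), p.delta_conc(env.v)))
    return simulate(
        strains, W, env,
        produce_signal=[True] * len(strains),
        boluses=boluses,
    )


def supernatant_assay(
    coculture: SimulationResult,
    testers: Sequence[StrainParams],
    W: WeightMatrix,
    env: EnvironmentParams | None = None,
    dilution: float = ASSAY_DILUTION,
    ratio: float | None = None,
) -> CocultureOutcome:
    """Apply a coculture's final supernatant to tester strains.

    The harvested signal concentrations are diluted by the supernatant
    fraction of the assay well (default 150/200), each tester's fold
    change is simulated at its clamped weighted signal sum, and the
    result is normalised by that strain's activation threshold; a strain
    counts as QS ON when the normalised fold is >= 1.
    """
    tester_env = env or EnvironmentParams.tester_default()
    c_final = coculture.final_c() * dilution
    folds = []
    for i, p in enumerate(testers):
        c_eff = max(0.0, float(np.dot(W.w[i], c_final)))
        folds.append(
            fold_change_at(p, tester_env, c_eff) / activation_threshold(p, tester_env)
        )
    folds = np.array(folds)
    return CocultureOutcome(
        strain_order=W.strain_order,
        final_c=coculture.final_c(),
        tester_fold=folds,
        active=tuple(folds >= 1.0),
        ratio=ratio,
    )


@dataclass(frozen=True)
class RatioSweepResult:
    """Outcomes over a sweep of inoculation ratios plus the refined critical ratio."""

    outcomes: tuple[CocultureOutcome, ...]
    critical_ratio: float | None  # first A:B ratio at which B fails to activate


def _outcome_at_ratio(
    params_a: StrainParams,
    params_b: StrainParams,
    W: WeightMatrix,
    ratio: float,
    env: EnvironmentParams,
    total_n0: float,
) -> CocultureOutcome:
    n0_a = total_n0 * ratio / (1.0 + ratio)
    n0_b = total_n0 / (1.0 + ratio)
    run = simulate_coculture([params_a, params_b], W, n0=[n0_a, n0_b], env=env)
    return supernatant_assay(run, [params_a, params_b], W, ratio=ratio)


def ratio_sweep(
    params_a: StrainParams,
    params_b: StrainParams,
    W: WeightMatrix,
    ratios: Sequence[float],
    env: EnvironmentParams | None = None,
    total_n0: float = 2e6,
    refine_rtol: float = 0.02,
) -> RatioSweepResult:
    """QS outcomes of a two-producer coculture over inoculation ratios A:B.

    The total inoculum density is held fixed while the A:B split varies.
    If strain B is active at some swept ratio and inactive at a larger
    one, the boundary is refined by bisection (in log ratio) to
    ``refine_rtol`` relative precision and reported as the critical
    ratio.
    """
    env = env or EnvironmentParams.coculture_default(2)
    ratios = np.asarray(ratios, dtype=float)
    if np.any(ratios <= 0):
        raise ValueError("ratios must be > 0")
    outcomes = tuple(
        _outcome_at_ratio(params_a, params_b, W, r, env, total_n0) for r in ratios
    )

    b_active = np.array([o.active[1] for o in outcomes])
    critical = None
    # bracket: largest swept ratio with B on that is followed by B off
    on_idx = [i for i in range(len(ratios) - 1) if b_active[i] and not b_active[i + 1]]
    if on_idx:
        i = on_idx[0]
        lo, hi = ratios[i], ratios[i + 1]
        while hi / lo > 1.0 + refine_rtol:
            mid = float(np.sqrt(lo * hi))
            if _outcome_at_ratio(params_a, params_b, W, mid, env, total_n0).active[1]:
                lo = mid
            else:
                hi = mid
        critical = float(np.sqrt(lo * hi))
    return RatioSweepResult(outcomes=outcomes, critical_ratio=critical)


def perturbation_timing_scan(
    strains: Sequence[StrainParams],
    W: WeightMatrix,
    n0: Sequence[float],
    perturbation_template: PerturbationSpec,
    times: Sequence[float],
    env: EnvironmentParams | None = None,
) -> list[tuple[float, CocultureOutcome]]:
    """Coculture outcome as a function of the perturbation time.

    Runs one perturbed coculture per entry of ``times`` (hours after
    inoculation) and assays the final supernatant, returning
    ``(t_p, outcome)`` pairs.
    """
    env = env or EnvironmentParams.coculture_default(len(strains))
    results = []
    for t_p in times:
        pert = replace(perturbation_template, time=float(t_p))
        run = simulate_coculture(strains, W, n0=n0, env=env, perturbations=[pert])
        results.append((float(t_p), supernatant_assay(run, strains, W)))
    return results
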