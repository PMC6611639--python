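"""Parameter containers for the quorum-sensing crosstalk model.

The model describes a community of *Bacillus subtilis* strains, each
producing and sensing a chemical variant of the ComX quorum-sensing (QS)
peptide.  Each strain is characterised by the kinetics of its QS-regulated
reporter (LacZ), its signal production/degradation rates, and the two
regulatory constants that differ most between strains: the fold change
``f`` by which QS activation boosts expression and the half-maximum
effective signal concentration ``theta`` (nM) of the Hill response.

Crosstalk between signal variants is encoded in a signed weight matrix
``w`` where entry ``w[i, j]`` scales the contribution of strain *j*'s
signal to the effective concentration sensed by strain *i*.  Self-weights
are 1 by definition.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StrainParams",
    "WeightMatrix",
    "EnvironmentParams",
    "SignalMixture",
    "table1_params",
    "table1_strain",
    "load_strain_table",
    "save_strain_table",
    "load_weight_matrix",
    "save_weight_matrix",
    "DEFAULT_HILL_COEFF",
    "DEFAULT_RHO_L",
    "DEFAULT_GAMMA_L",
    "DEFAULT_RHO_C",
    "DEFAULT_GAMMA_C",
    "DEFAULT_MU",
    "DEFAULT_CAPACITY",
]

# Defaults for the rate constants that are shared between strains.  The
# reporter and signal rates are calibrated, not measured: rho_c is chosen so
# that a lone producer growing from low density approaches a supernatant
# signal concentration of ~30 nM after 10 h (the concentration reported for
# stationary-phase ComX supernatant), and rho_L so that basal reporter
# levels are comfortably non-zero in simulation units.  See docs/methods.md.
DEFAULT_HILL_COEFF = 2.0
DEFAULT_RHO_L = 1e-9  # LacZ units * mL / (cell * min)
DEFAULT_GAMMA_L = 0.01  # 1/min
DEFAULT_RHO_C = 3.0e-11  # nM * mL / (cell * min)
DEFAULT_GAMMA_C = 0.005  # 1/min
DEFAULT_MU = 1.5  # 1/h
DEFAULT_CAPACITY = 1e9  # cells/mL


@dataclass(frozen=True)
class StrainParams:
    """Kinetic and regulatory constants for one strain.

    Parameters
    ----------
    strain_id : str
        Strain label (``"A"``–``"E"`` for the packaged community).
    f : float
        Fold increase of expression/production upon full QS activation
        (dimensionless, > 0).
    theta : float
        Effective signal concentration of half-maximal activation (nM).
    m : float
        Hill coefficient of the activation function.
    rho_L : float
        Basal LacZ production rate per cell density unit
        (LacZ units * mL / cell / min).
    gamma_L : float
        LacZ degradation rate (1/min).
    rho_c : float
        Basal signal production rate per cell density unit
        (nM * mL / cell / min).
    gamma_c : float
        Signal degradation rate (1/min).
    mu : float
        Exponential growth rate (1/h).
    """

    strain_id: str
    f: float
    theta: float
    m: float = DEFAULT_HILL_COEFF
    rho_L: float = DEFAULT_RHO_L
    gamma_L: float = DEFAULT_GAMMA_L
    rho_c: float = DEFAULT_RHO_C
    gamma_c: float = DEFAULT_GAMMA_C
    mu: float = DEFAULT_MU

    def __post_init__(self) -> None:
        if not self.f > 0:
            raise ValueError(f"f must be > 0, got {self.f}")
        if not self.theta > 0:
            raise ValueError(f"theta must be > 0, got {self.theta}")
        if not self.m > 0:
            raise ValueError(f"m must be > 0, got {self.m}")
        for name in ("rho_L", "gamma_L", "rho_c", "gamma_c", "mu"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def with_fit(self, f: float, theta: float) -> "StrainParams":
        """Copy of these parameters with ``f`` and ``theta`` replaced."""
        return replace(self, f=f, theta=theta)


# Best-fit (f, theta) per strain from single-signal dose-response curves.
_COMMUNITY_FIT = {
    "A": (5.955, 1.393),
    "B": (4.083, 1.633),
    "C": (24.839, 1.364),
    "D": (8.345, 1.394),
    "E": (6.951, 1.815),
}

STRAIN_IDS = tuple(_COMMUNITY_FIT)


def table1_strain(strain_id: str, **overrides) -> StrainParams:
    """Parameters for one strain of the packaged five-strain community."""
    try:
        f, theta = _COMMUNITY_FIT[strain_id]
    except KeyError:
        raise KeyError(
            f"unknown strain {strain_id!r}; expected one of {sorted(_COMMUNITY_FIT)}"
        ) from None
    return StrainParams(strain_id=strain_id, f=f, theta=theta, **overrides)


def table1_params(**overrides) -> list[StrainParams]:
    """Parameters for all five strains A–E, in order."""
    return [table1_strain(s, **overrides) for s in STRAIN_IDS]


@dataclass(frozen=True)
class WeightMatrix:
    """Signed crosstalk weights between signal variants.

    ``w[i, j]`` is the effect of the signal produced by strain
    ``strain_order[j]`` on QS activation in strain ``strain_order[i]``.
    Positive weights are excitatory, negative inhibitory.  The diagonal
    (each strain's response to its own signal) is exactly 1.
    """

    strain_order: tuple[str, ...]
    w: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.w, dtype=float)
        object.__setattr__(self, "w", w)
        object.__setattr__(self, "strain_order", tuple(self.strain_order))
        k = len(self.strain_order)
        if w.shape != (k, k):
            raise ValueError(f"weight matrix shape {w.shape} does not match {k} strains")
        if not np.allclose(np.diag(w), 1.0, rtol=0, atol=0):
            raise ValueError("self-weights (diagonal) must all be exactly 1")

    def row(self, strain_id: str) -> np.ndarray:
        """Weight row of the given receiver strain."""
        return self.w[self.index(strain_id)]

    def index(self, strain_id: str) -> int:
        try:
            return self.strain_order.index(strain_id)
        except ValueError:
            raise KeyError(f"strain {strain_id!r} not in weight matrix") from None

    @classmethod
    def identity(cls, strain_order: Sequence[str]) -> "WeightMatrix":
        """No-crosstalk matrix: each strain senses only its own signal."""
        return cls(tuple(strain_order), np.eye(len(strain_order)))


@dataclass(frozen=True)
class EnvironmentParams:
    """Culture environment and integration settings.

    Cell state is tracked as a density (cells/mL); the culture volume ``v``
    (mL) enters only when an added supernatant bolus is diluted into the
    culture.  ``s`` is the carrying capacity shared by all strains.
    """

    v: float = 0.2  # mL (one 200 ul plate well)
    s: float = DEFAULT_CAPACITY  # cells/mL
    dt: float = 1.0  # min
    duration: float = 10.0  # h
    n0: tuple[float, ...] = (1e8,)  # cells/mL per strain

    def __post_init__(self) -> None:
        object.__setattr__(self, "n0", tuple(float(x) for x in np.atleast_1d(self.n0)))
        if self.v <= 0 or self.s <= 0 or self.dt <= 0 or self.duration <= 0:
            raise ValueError("v, s, dt and duration must all be > 0")
        if any(x < 0 for x in self.n0):
            raise ValueError("initial densities must be >= 0")
        if sum(self.n0) > self.s:
            raise ValueError("total initial density exceeds carrying capacity")

    @property
    def n_steps(self) -> int:
        return int(round(self.duration * 60.0 / self.dt))

    @classmethod
    def tester_default(cls, n_strains: int = 1, **overrides) -> "EnvironmentParams":
        """Plate-well tester assay: grows from 1e8 to ~1e9 cells/mL in 10 h."""
        kw = dict(v=0.2, n0=(1e8,) * n_strains)
        kw.update(overrides)
        return cls(**kw)

    @classmethod
    def coculture_default(cls, n_strains: int = 2, **overrides) -> "EnvironmentParams":
        """Producer coculture in a 3 mL tube inoculated at 1e6 cells/mL."""
        kw = dict(v=3.0, n0=(1e6,) * n_strains)
        kw.update(overrides)
        return cls(**kw)


@dataclass(frozen=True)
class SignalMixture:
    """Per-strain supernatant volumes loaded into one assay well.

    A volume ``x`` ul of supernatant (assumed to carry ``stock_conc`` nM of
    signal) diluted into a ``total_volume`` ul well contributes a signal
    concentration of ``stock_conc * x / total_volume``.
    """

    volumes: dict[str, float] = field(default_factory=dict)
    total_volume: float = 200.0  # ul
    stock_conc: float = 30.0  # nM

    def __post_init__(self) -> None:
        if self.stock_conc <= 0 or self.total_volume <= 0:
            raise ValueError("stock_conc and total_volume must be > 0")
        for strain, x in self.volumes.items():
            if x < 0:
                raise ValueError(f"volume for {strain} is negative")
        if sum(self.volumes.values()) > self.total_volume:
            raise ValueError("supernatant volumes exceed the assay volume")

    def concentration(self, strain_id: str) -> float:
        """Signal concentration (nM) contributed by one strain's supernatant."""
        return self.stock_conc * self.volumes.get(strain_id, 0.0) / self.total_volume

    def concentrations(self, strain_order: Sequence[str]) -> np.ndarray:
        """Concentration vector (nM) in a given strain order."""
        return np.array([self.concentration(s) for s in strain_order])

    @classmethod
    def parse(cls, spec: str, **kwargs) -> "SignalMixture":
        """Parse a mixture spec such as ``"A=10,B=4,C=15"`` (volumes in ul)."""
        volumes: dict[str, float] = {}
        for item in spec.split(","):
            item = item.strip()
            if not item:
                continue
            strain, _, val = item.partition("=")
            volumes[strain.strip()] = float(val)
        return cls(volumes=volumes, **kwargs)


# ---------------------------------------------------------------------------
# Delimited-text I/O

_STRAIN_COLUMNS = ["strain", "f", "theta", "m", "rho_L", "gamma_L", "rho_c", "gamma_c", "mu"]


def load_strain_table(path: str | Path) -> list[StrainParams]:
    """Read strain parameters from a CSV with the standard header."""
    df = pd.read_csv(path)
    missing = set(_STRAIN_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"strain table is missing columns: {sorted(missing)}")
    return [
        StrainParams(
            strain_id=str(row["strain"]),
            f=row["f"],
            theta=row["theta"],
            m=row["m"],
            rho_L=row["rho_L"],
            gamma_L=row["gamma_L"],
            rho_c=row["rho_c"],
            gamma_c=row["gamma_c"],
            mu=row["mu"],
        )
        for _, row in df.iterrows()
    ]


def save_strain_table(strains: Sequence[StrainParams], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            [p.strain_id, p.f, p.theta, p.m, p.rho_L, p.gamma_L, p.rho_c, p.gamma_c, p.mu]
            for p in strains
        ],
        columns=_STRAIN_COLUMNS,
    )
    df.to_csv(path, index=False)


def load_weight_matrix(path: str | Path) -> WeightMatrix:
    """Read a crosstalk matrix from CSV (labels in first row and column)."""
    df = pd.read_csv(path, index_col=0)
    order = tuple(str(s) for s in df.index)
    if tuple(str(s) for s in df.columns) != order:
        raise ValueError("weight matrix row and column labels must match")
    return WeightMatrix(order, df.to_numpy(dtype=float))


def save_weight_matrix(wm: WeightMatrix, path: str | Path) -> None:
    pd.DataFrame(wm.w, index=list(wm.strain_order), columns=list(wm.strain_order)).to_csv(path)
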