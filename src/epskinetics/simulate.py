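"""Synthetic replicated fermentation time courses.

Emulates a two-temperature EPS fermentation experiment: shake-flask cultures
of *Rhodotorula glutinis* grown under heat stress (30 deg C) and under the
strain's optimal temperature (15 deg C), sampled at 6, 12, 24, 36, 48, 72,
96 and 120 h in triplicate.  Noise-free means come from the closed-form
logistic and Luedeking-Piret curves; each observation is perturbed by an
independent multiplicative Gaussian factor (mean 1, sd = CV), mimicking the
proportional error of optical-density and colorimetric assays.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .kinetics import (
    GrowthParams,
    ProductParams,
    logistic_solution,
    lp_solution,
)

__all__ = [
    "PAPER_SCHEDULE",
    "Scenario",
    "TimeCourse",
    "default_scenarios",
    "generate_timecourse",
    "generate_study",
]

#: Sampling schedule of the emulated experiment (hours).
PAPER_SCHEDULE: tuple[float, ...] = (6.0, 12.0, 24.0, 36.0, 48.0, 72.0, 96.0, 120.0)

#: Published maximum specific growth rates (1/h).
MU_MAX_HEAT = 0.33528
MU_MAX_NORMAL = 0.13286
#: Published maximum specific EPS production rate under heat stress (1/h).
QP_MAX_HEAT = 0.87670

TIMECOURSE_COLUMNS = ("replicate", "time_h", "biomass", "product")


@dataclass(frozen=True)
class Scenario:
    """Generative specification for one culture condition.

    ``decay_rate``/``decay_after`` switch on an optional contamination mode:
    after ``decay_after`` hours the biomass mean decays exponentially at
    ``decay_rate`` (1/h), emulating late-culture lysis that a pure logistic
    cannot represent.  Off by default.
    """

    growth: GrowthParams
    product: ProductParams
    schedule: tuple[float, ...] = PAPER_SCHEDULE
    n_replicates: int = 3
    noise_cv: float = 0.03
    seed: int = 0
    decay_rate: float = 0.0
    decay_after: float | None = None

    def __post_init__(self) -> None:
        sched = np.asarray(self.schedule, dtype=float)
        if sched.size == 0 or np.any(sched < 0) or np.any(np.diff(sched) <= 0):
            raise ValueError("schedule must be strictly increasing and >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.decay_rate < 0:
            raise ValueError("decay_rate must be >= 0")


@dataclass
class TimeCourse:
    """Replicated (time, biomass, product) observations for one condition.

    ``data`` is a tidy long table with columns ``replicate`` (int),
    ``time_h``, ``biomass`` and ``product`` (``product`` may be NaN where
    not assayed).  Rows are kept sorted by (replicate, time_h).
    """

    condition: str
    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = set(TIMECOURSE_COLUMNS) - set(self.data.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        df = self.data.loc[:, list(TIMECOURSE_COLUMNS)].copy()
        df["replicate"] = df["replicate"].astype(int)
        for col in ("time_h", "biomass", "product"):
            df[col] = pd.to_numeric(df[col], errors="raise").astype(float)
        if len(df) == 0:
            raise ValueError("time course has no observations")
        df = df.sort_values(["replicate", "time_h"], kind="mergesort").reset_index(
            drop=True
        )
        if df.duplicated(["replicate", "time_h"]).any():
            raise ValueError("duplicate (replicate, time) observation")
        for col in ("biomass", "product"):
            vals = df[col].to_numpy(float)
            if np.any(vals[np.isfinite(vals)] < 0):
                raise ValueError(f"negative {col} value")
        if df["biomass"].isna().any():
            raise ValueError("biomass must be observed in every row")
        self.data = df

    @property
    def n_obs(self) -> int:
        return len(self.data)

    def times(self) -> np.ndarray:
        return self.data["time_h"].to_numpy(float)

    def biomass(self) -> np.ndarray:
        return self.data["biomass"].to_numpy(float)

    def product(self) -> np.ndarray:
        return self.data["product"].to_numpy(float)


def _heat_alpha(growth: GrowthParams, beta: float, qp_max: float = QP_MAX_HEAT) -> float:
    # q_P is maximal at t=0: qp_max = alpha + beta*mu*(1 - X0/Xmax).
    return qp_max - beta * growth.mu_max * (1.0 - growth.X0 / growth.Xmax)


def default_scenarios(noise_cv: float = 0.03, seed: int = 0) -> dict[str, Scenario]:
    """The two study conditions: ``heat_stress`` (30 deg C) and ``normal`` (15 deg C).

    Growth rates carry the published values (0.33528 and 0.13286 1/h).  The
    remaining parameters are package defaults chosen for well-conditioned
    fits on the 8-point schedule: X0 = 0.1, Xmax = 6 (heat) / 10 (normal,
    the colder culture grows further), P0 = 0.05 g/L, beta = 0.5.  The
    heat-stress alpha is set so that the construction reproduces the
    published maximum specific production rate q_P,max = 0.87670 1/h exactly;
    the normal-condition alpha defaults to 0.05 1/h (lower non-growth-
    associated production at the optimal temperature).
    """
    growth_heat = GrowthParams(X0=0.1, Xmax=6.0, mu_max=MU_MAX_HEAT)
    growth_normal = GrowthParams(X0=0.1, Xmax=10.0, mu_max=MU_MAX_NORMAL)
    beta = 0.5
    return {
        "heat_stress": Scenario(
            growth=growth_heat,
            product=ProductParams(P0=0.05, alpha=_heat_alpha(growth_heat, beta), beta=beta),
            noise_cv=noise_cv,
            seed=seed,
        ),
        "normal": Scenario(
            growth=growth_normal,
            product=ProductParams(P0=0.05, alpha=0.05, beta=beta),
            noise_cv=noise_cv,
            seed=seed,
        ),
    }


def _mean_curves(sc: Scenario) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(sc.schedule, dtype=float)
    X = np.asarray(logistic_solution(sc.growth, t))
    P = np.asarray(lp_solution(sc.growth, sc.product, t))
    if sc.decay_after is not None:
        late = t > sc.decay_after
        X = np.where(late, X * np.exp(-sc.decay_rate * (t - sc.decay_after)), X)
    return X, P


def generate_timecourse(sc: Scenario, condition: str = "synthetic") -> TimeCourse:
    """Draw one replicated noisy time course from a scenario.

    Each observation is the noise-free mean times an independent Gaussian
    factor N(1, noise_cv), truncated below at zero; fully determined by
    ``sc.seed``.
    """
    X_mean, P_mean = _mean_curves(sc)
    t = np.asarray(sc.schedule, dtype=float)
    rng = np.random.default_rng(sc.seed)
    rows = []
    for rep in range(1, sc.n_replicates + 1):
        fx = rng.normal(1.0, sc.noise_cv, size=t.size)
        fp = rng.normal(1.0, sc.noise_cv, size=t.size)
        rows.append(
            pd.DataFrame(
                {
                    "replicate": rep,
                    "time_h": t,
                    "biomass": np.maximum(X_mean * fx, 0.0),
                    "product": np.maximum(P_mean * fp, 0.0),
                }
            )
        )
    return TimeCourse(condition=condition, data=pd.concat(rows, ignore_index=True))


def subseed(seed: int, label: str) -> int:
    """Stable per-condition sub-seed: CRC-32 of the label mixed with ``seed``.

    Adding or renaming one scenario never perturbs the draws of another.
    The result is reduced below 2**31 for portability.
    """
    ss = np.random.SeedSequence([int(seed), zlib.crc32(label.encode("utf-8"))])
    return int(ss.generate_state(1, dtype=np.uint64)[0] % (2**31))


def generate_study(
    sc_map: dict[str, Scenario], seed: int
) -> dict[str, TimeCourse]:
    """One TimeCourse per scenario, with independent label-derived sub-seeds."""
    if not sc_map:
        raise ValueError("scenario set is empty")
    out = {}
    for label, sc in sc_map.items():
        sc_seeded = replace(sc, seed=subseed(seed, label))
        out[label] = generate_timecourse(sc_seeded, condition=label)
    return out
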