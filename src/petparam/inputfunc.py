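"""Arterial input curves for simulation.

Measured studies provide a metabolite-corrected arterial plasma input curve
and a whole-blood curve.  For simulation we use a Feng-type bolus for total
plasma activity,

    C_plasma(t) = [A1 (t - t0) - A2 - A3] exp(-mu1 (t - t0))
                  + A2 exp(-mu2 (t - t0)) + A3 exp(-mu3 (t - t0)),   t > t0,

zero before the delay ``t0``: a linear rise times a fast exponential plus two
slower exponential tails.  The metabolite parent fraction decays
mono-exponentially towards a plateau, and the plasma-to-whole-blood ratio
drifts slowly and linearly, so that

    plasma_parent(t)  = C_plasma(t) * parent_fraction(t)
    whole_blood(t)    = C_plasma(t) / plasma_to_wholeblood(t).

All curves live on a shared fine time grid (sub-second spacing early) so that
convolutions and frame averages can be computed accurately.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .schedule import FrameSchedule


@dataclass(frozen=True)
class FengParams:
    """Coefficients of the bolus input model.

    Units: amplitudes ``a1`` in kBq mL^-1 min^-1, ``a2``/``a3`` in kBq/mL,
    rates ``mu1 > mu2 > mu3`` in min^-1, delay ``t0`` in minutes.  Parent
    fraction: plateau ``pf_inf`` (unitless) reached at rate ``pf_rate``
    (min^-1).  Plasma-to-whole-blood ratio ``r0 + r1*t``.
    """

    a1: float = 60.0
    a2: float = 1.8
    a3: float = 1.2
    mu1: float = 4.0
    mu2: float = 0.35
    mu3: float = 0.010
    t0: float = 0.5
    pf_inf: float = 0.22
    pf_rate: float = 0.05
    r0: float = 1.10
    r1: float = 0.0015

    def plasma_total(self, t: np.ndarray) -> np.ndarray:
        """Total plasma activity (kBq/mL) at times ``t`` (minutes)."""
        t = np.asarray(t, dtype=float)
        u = t - self.t0
        c = np.where(
            u > 0,
            (self.a1 * u - self.a2 - self.a3) * np.exp(-self.mu1 * u)
            + self.a2 * np.exp(-self.mu2 * u)
            + self.a3 * np.exp(-self.mu3 * u),
            0.0,
        )
        return c

    def parent_fraction(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.pf_inf + (1.0 - self.pf_inf) * np.exp(-self.pf_rate * t)

    def plasma_to_wholeblood(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.r0 + self.r1 * t

    def jittered(self, fraction: float, rng: np.random.Generator) -> "FengParams":
        """Multiplicatively perturb amplitudes and rates by ~N(0, fraction)."""
        if fraction == 0:
            return self
        d = asdict(self)
        for key in ("a1", "a2", "a3", "mu1", "mu2", "mu3"):
            d[key] = d[key] * float(1.0 + fraction * rng.standard_normal())
        return FengParams(**d)


@dataclass(frozen=True)
class InputFunction:
    """Input curves sampled on a fine time grid (minutes, kBq/mL)."""

    time: np.ndarray
    plasma_parent: np.ndarray
    whole_blood: np.ndarray
    parent_fraction: np.ndarray
    plasma_to_wholeblood: np.ndarray

    def __post_init__(self) -> None:
        for name in (
            "time",
            "plasma_parent",
            "whole_blood",
            "parent_fraction",
            "plasma_to_wholeblood",
        ):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        n = self.time.size
        if any(
            getattr(self, f).size != n
            for f in ("plasma_parent", "whole_blood", "parent_fraction")
        ):
            raise ValueError("input-function curves must share the time grid")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if np.any(self.plasma_parent < 0) or np.any(self.whole_blood < 0):
            raise ValueError("activity curves must be non-negative")

    @property
    def plasma_total(self) -> np.ndarray:
        """Total (parent + metabolite) plasma activity."""
        with np.errstate(invalid="ignore"):
            return self.plasma_parent / self.parent_fraction

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_min": self.time,
                "plasma_parent_kBq_ml": self.plasma_parent,
                "whole_blood_kBq_ml": self.whole_blood,
                "parent_fraction": self.parent_fraction,
                "plasma_to_wholeblood": self.plasma_to_wholeblood,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "InputFunction":
        df = pd.read_csv(path, sep="\t")
        return cls(
            time=df["time_min"].to_numpy(),
            plasma_parent=df["plasma_parent_kBq_ml"].to_numpy(),
            whole_blood=df["whole_blood_kBq_ml"].to_numpy(),
            parent_fraction=df["parent_fraction"].to_numpy(),
            plasma_to_wholeblood=df["plasma_to_wholeblood"].to_numpy(),
        )


def fine_time_grid(t_end: float, dt_early: float = 1.0 / 120.0, dt_late: float = 0.05,
                   t_switch: float = 5.0) -> np.ndarray:
    """Fine grid on [0, t_end] minutes: 0.5 s spacing before ``t_switch``,
    3 s after.  Guaranteed to include 0 and t_end."""
    if t_end <= t_switch:
        return np.arange(0.0, t_end + 0.5 * dt_early, dt_early)
    early = np.arange(0.0, t_switch, dt_early)
    late = np.arange(t_switch, t_end + 0.5 * dt_late, dt_late)
    grid = np.concatenate([early, late])
    if grid[-1] < t_end:
        grid = np.append(grid, t_end)
    return grid


def make_input_function(
    params: FengParams | None = None,
    schedule: FrameSchedule | None = None,
    *,
    t_end: float | None = None,
) -> InputFunction:
    """Generate input curves covering the schedule on a fine grid.

    Raises
    ------
    ValueError
        If the coefficients yield a negative total-plasma concentration
        anywhere on the grid.
    """
    params = params or FengParams()
    if t_end is None:
        if schedule is None:
            schedule = FrameSchedule.default()
        t_end = schedule.total_minutes
    time = fine_time_grid(t_end)
    total = params.plasma_total(time)
    if np.any(total < -1e-9 * max(1.0, float(np.max(np.abs(total))))):
        tmin = time[int(np.argmin(total))]
        raise ValueError(
            f"bolus coefficients produce negative plasma concentration "
            f"(minimum {total.min():.4g} kBq/mL at t = {tmin:.3g} min)"
        )
    total = np.clip(total, 0.0, None)
    pf = params.parent_fraction(time)
    ratio = params.plasma_to_wholeblood(time)
    return InputFunction(
        time=time,
        plasma_parent=total * pf,
        whole_blood=total / ratio,
        parent_fraction=pf,
        plasma_to_wholeblood=ratio,
    )
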