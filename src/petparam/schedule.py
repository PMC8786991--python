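"""Frame timing of a dynamic PET acquisition.

A :class:`FrameSchedule` carries, per reconstructed frame, the start time and
duration (minutes), the decay-correction factor (dcf, unitless, >= 1) and the
whole-scanner true counts accumulated during the frame.  It is the time axis
of every curve in the package and the source of the count-based frame
variances used for weighted fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: physical decay constant of carbon-11, min^-1 (half-life 20.364 min)
C11_LAMBDA = np.log(2.0) / 20.364

#: the 19-frame rebinning used throughout: 1x15, 3x5, 3x10, 4x60, 2x150,
#: 2x300 and 4x600 seconds (60 min total)
DEFAULT_FRAME_DURATIONS_S = (
    [15.0]
    + [5.0] * 3
    + [10.0] * 3
    + [60.0] * 4
    + [150.0] * 2
    + [300.0] * 2
    + [600.0] * 4
)


@dataclass(frozen=True)
class FrameSchedule:
    """Per-frame timing, decay correction and true counts.

    Parameters
    ----------
    start, duration
        Frame start times and lengths in minutes.  Frames must be ordered,
        non-overlapping and strictly positive in length.
    dcf
        Unitless decay-correction factor per frame (>= 1).
    trues
        Whole-scanner true counts per frame (arbitrary count units, >= 0).
    """

    start: np.ndarray
    duration: np.ndarray
    dcf: np.ndarray
    trues: np.ndarray

    def __post_init__(self) -> None:
        for name in ("start", "duration", "dcf", "trues"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        n = self.start.size
        if not (self.duration.size == self.dcf.size == self.trues.size == n):
            raise ValueError("schedule fields must have equal length")
        if n == 0:
            raise ValueError("schedule must contain at least one frame")
        if np.any(self.duration <= 0):
            raise ValueError("frame durations must be > 0")
        if np.any(np.diff(self.start) <= 0):
            raise ValueError("frame starts must be strictly increasing")
        if np.any(self.start[1:] < self.end[:-1] - 1e-9):
            raise ValueError("frames must not overlap")
        if np.any(self.dcf < 1.0 - 1e-12):
            raise ValueError("decay-correction factors must be >= 1")
        if np.any(self.trues < 0):
            raise ValueError("true counts must be >= 0")

    # -- derived time points -------------------------------------------------
    @property
    def end(self) -> np.ndarray:
        """Frame end times, minutes."""
        return self.start + self.duration

    @property
    def mid(self) -> np.ndarray:
        """Frame mid-times, minutes."""
        return self.start + 0.5 * self.duration

    @property
    def duration_s(self) -> np.ndarray:
        """Frame lengths in seconds (the unit the variance model expects)."""
        return self.duration * 60.0

    @property
    def total_minutes(self) -> float:
        return float(self.end[-1])

    def __len__(self) -> int:
        return self.start.size

    # -- construction --------------------------------------------------------
    @classmethod
    def from_durations(
        cls,
        durations_s,
        *,
        isotope_lambda: float = C11_LAMBDA,
        trues_rate_cps: float = 2.0e4,
        start_min: float = 0.0,
    ) -> "FrameSchedule":
        """Build a contiguous schedule from frame lengths in seconds.

        The decay-correction factor per frame is the exact analytic factor
        that converts decaying-activity counts back to activity at time
        zero::

            dcf = exp(lambda * t0) * lambda * L / (1 - exp(-lambda * L))

        with ``t0`` the frame start and ``L`` the frame length (both in
        minutes here).  True counts follow a simple decaying-source model:
        ``trues = rate * L_s * exp(-lambda * t_mid)``, which captures the
        dominant count-rate trend of a bolus study.
        """
        durations_min = np.asarray(durations_s, dtype=float) / 60.0
        start = start_min + np.concatenate([[0.0], np.cumsum(durations_min)[:-1]])
        lam = isotope_lambda
        x = lam * durations_min
        dcf = np.exp(lam * start) * x / (-np.expm1(-x))
        mid = start + 0.5 * durations_min
        trues = trues_rate_cps * np.asarray(durations_s, dtype=float) * np.exp(-lam * mid)
        return cls(start=start, duration=durations_min, dcf=dcf, trues=trues)

    @classmethod
    def default(cls) -> "FrameSchedule":
        """The 19-frame, 60-minute default schedule."""
        return cls.from_durations(DEFAULT_FRAME_DURATIONS_S)

    # -- I/O -----------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame_start_min": self.start,
                "frame_duration_min": self.duration,
                "dcf": self.dcf,
                "trues": self.trues,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "FrameSchedule":
        df = pd.read_csv(path, sep="\t")
        return cls(
            start=df["frame_start_min"].to_numpy(),
            duration=df["frame_duration_min"].to_numpy(),
            dcf=df["dcf"].to_numpy(),
            trues=df["trues"].to_numpy(),
        )
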