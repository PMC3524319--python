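"""Stimulation protocols and time-course containers.

A priming experiment compares four arms: untreated, low dose alone (LD),
high dose alone (HD), and the sequential low-then-high dose (LD+HD,
optionally separated by a wash).  Protocols are piecewise-constant dose
schedules; time courses are dense trajectories on a shared grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np

PROTOCOL_LABELS = ("untreated", "LD", "HD", "LD_HD")


@dataclass(frozen=True)
class StimulusProtocol:
    """Piecewise-constant dose schedule.

    Parameters
    ----------
    segments
        Ordered ``(duration, dose)`` pairs.  Durations are in the model's
        time unit (hours for the Jak/STAT model, arbitrary units for the
        three-node motif model); doses in the model's concentration unit.
    label
        One of ``untreated``, ``LD``, ``HD``, ``LD_HD``.
    """

    segments: tuple[tuple[float, float], ...]
    label: str

    def __post_init__(self) -> None:
        if self.label not in PROTOCOL_LABELS:
            raise ValueError(f"unknown protocol label {self.label!r}")
        if not self.segments:
            raise ValueError("protocol needs at least one segment")
        for dur, dose in self.segments:
            if dur <= 0:
                raise ValueError("segment durations must be > 0")
            if dose < 0:
                raise ValueError("doses must be >= 0")
        if self.label == "LD_HD":
            doses = [d for _, d in self.segments if d > 0]
            if len(doses) < 2 or not doses[0] < doses[-1]:
                raise ValueError(
                    "LD_HD protocol must contain an LD segment strictly "
                    "before the HD segment (an optional zero-dose wash may "
                    "separate them)"
                )

    @property
    def total_time(self) -> float:
        return float(sum(d for d, _ in self.segments))

    def dose_at(self, t: float) -> float:
        """Dose at time ``t`` (right-continuous at segment boundaries)."""
        acc = 0.0
        for dur, dose in self.segments:
            acc += dur
            if t < acc:
                return dose
        return self.segments[-1][1]

    def boundaries(self) -> np.ndarray:
        """Cumulative segment end times, including the final time."""
        return np.cumsum([d for d, _ in self.segments])


def standard_protocols(
    ld_dose: float,
    hd_dose: float,
    ld_duration: float,
    hd_duration: float,
    wash_duration: float = 0.0,
) -> dict[str, StimulusProtocol]:
    """Build the four standard arms of a priming experiment.

    The LD arm is extended with a zero-dose tail so every arm spans the
    same total time; the HD arm is delayed by the LD period so its HD
    window aligns in absolute time with the LD+HD arm's HD window.
    """
    if not 0 <= ld_dose < hd_dose:
        raise ValueError("need 0 <= ld_dose < hd_dose")
    lead = ld_duration + wash_duration
    total = lead + hd_duration
    segs_ldhd = [(ld_duration, ld_dose)]
    if wash_duration > 0:
        segs_ldhd.append((wash_duration, 0.0))
    segs_ldhd.append((hd_duration, hd_dose))
    return {
        "untreated": StimulusProtocol(((total, 0.0),), "untreated"),
        "LD": StimulusProtocol(
            ((ld_duration, ld_dose), (total - ld_duration, 0.0)), "LD"
        ),
        "HD": StimulusProtocol(((lead, 0.0), (hd_duration, hd_dose)), "HD"),
        "LD_HD": StimulusProtocol(tuple(segs_ldhd), "LD_HD"),
    }


@dataclass
class TimeCourse:
    """Trajectories of named variables on a strictly increasing grid."""

    times: np.ndarray
    values: np.ndarray  # shape (n_vars, n_times)
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.names = tuple(self.names)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.values.shape != (len(self.names), self.times.size):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.names)} variables x {self.times.size} times"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trajectories contain non-finite values")

    def __getitem__(self, name: str) -> np.ndarray:
        try:
            return self.values[self.names.index(name)]
        except ValueError:
            raise KeyError(name) from None

    def window(self, t0: float, t1: float) -> np.ndarray:
        """Boolean mask of grid points in ``[t0, t1]``."""
        if t0 < self.times[0] - 1e-9 or t1 > self.times[-1] + 1e-9:
            raise ValueError(
                f"window [{t0}, {t1}] outside grid "
                f"[{self.times[0]}, {self.times[-1]}]"
            )
        return (self.times >= t0 - 1e-9) & (self.times <= t1 + 1e-9)

    def max_in(self, name: str, t0: float, t1: float) -> float:
        return float(self[name][self.window(t0, t1)].max())

    def value_at(self, name: str, t: float) -> float:
        """Linear interpolation of a variable at time ``t``."""
        return float(np.interp(t, self.times, self[name]))


@dataclass
class TimeCourseSet:
    """The four experimental arms, keyed by protocol label."""

    courses: dict[str, TimeCourse]
    protocols: dict[str, StimulusProtocol] = field(default_factory=dict)

    def __getitem__(self, label: str) -> TimeCourse:
        if label not in self.courses:
            raise KeyError(
                f"no trajectory for protocol {label!r}; have "
                f"{sorted(self.courses)}"
            )
        return self.courses[label]

    def __contains__(self, label: str) -> bool:
        return label in self.courses
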