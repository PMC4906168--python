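"""Baseline cumulative-hazard estimation and evaluation.

The proportional-hazards models in this package are fitted in two stages:
the baseline cumulative hazard Lambda0 is estimated once from the survival
data of all patients (Nelson-Aalen step estimator) and then held fixed while
the survival coefficient beta is maximized per exon.  A constant-rate
baseline is also provided for fully synthetic cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import SurvivalRecord

__all__ = ["BaselineHazard", "ConstantBaseline", "nelson_aalen"]


@dataclass(frozen=True)
class BaselineHazard:
    """Step-function cumulative baseline hazard at distinct event times.

    ``cum_hazard[i]`` is Lambda0 evaluated at ``event_times[i]``;
    ``increments[i]`` is the Nelson-Aalen jump d_i / n_i, used as the
    hazard mass of an event occurring at that time.
    """

    event_times: np.ndarray
    cum_hazard: np.ndarray
    increments: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.event_times, dtype=float)
        if t.size == 0:
            raise ValueError("baseline hazard requires at least one event time")
        if not (np.diff(t) > 0).all():
            raise ValueError("event_times must be strictly increasing")

    def cumulative(self, t) -> np.ndarray:
        """Lambda0(t): value at the largest event time <= t, 0 before the first."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.event_times, t, side="right")
        padded = np.concatenate(([0.0], self.cum_hazard))
        return padded[idx]

    def hazard_mass(self, t) -> np.ndarray:
        """Nelson-Aalen increment at the largest event time <= t.

        Events recorded before the first baseline event time fall back on the
        first increment (floor convention).
        """
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return self.increments[np.clip(idx, 0, None)]

    def inverse(self, target) -> tuple[np.ndarray, np.ndarray]:
        """Smallest event time with Lambda0 >= target.

        Returns ``(times, exceeded)`` where ``exceeded`` marks targets above
        the top of the step function; those times are set to the largest
        event time (administrative censoring at the support edge).
        """
        target = np.asarray(target, dtype=float)
        idx = np.searchsorted(self.cum_hazard, target, side="left")
        exceeded = idx >= len(self.event_times)
        times = self.event_times[np.clip(idx, 0, len(self.event_times) - 1)]
        return times, exceeded


@dataclass(frozen=True)
class ConstantBaseline:
    """Constant baseline hazard lambda0(t) = rate, Lambda0(t) = rate * t."""

    rate: float = 1.0

    def cumulative(self, t) -> np.ndarray:
        return self.rate * np.asarray(t, dtype=float)

    def hazard_mass(self, t) -> np.ndarray:
        return np.full_like(np.asarray(t, dtype=float), self.rate)

    def inverse(self, target) -> tuple[np.ndarray, np.ndarray]:
        target = np.asarray(target, dtype=float)
        return target / self.rate, np.zeros(target.shape, dtype=bool)


def nelson_aalen(records: Sequence[SurvivalRecord]) -> BaselineHazard:
    """Nelson-Aalen estimator of the cumulative baseline hazard.

    At each distinct event time t_i with d_i deaths among n_i patients at
    risk, Lambda0 jumps by d_i / n_i; censored patients leave the risk set
    at their censoring time (Breslow convention for ties: all tied deaths
    share the same risk set).
    """
    if not records:
        raise ValueError("no survival records")
    times = np.array([r.time for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=int)
    if events.sum() == 0:
        raise ValueError("baseline hazard undefined: no events in cohort")
    ev_times = np.unique(times[events == 1])
    # at risk: t_k >= t_i ; deaths: events at exactly t_i
    n_at_risk = (times[None, :] >= ev_times[:, None]).sum(axis=1)
    deaths = ((times[None, :] == ev_times[:, None]) & (events[None, :] == 1)).sum(axis=1)
    increments = deaths / n_at_risk
    return BaselineHazard(ev_times, np.cumsum(increments), increments)
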