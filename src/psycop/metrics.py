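"""Derived behavioral variables from home-cage event streams.

The home-cage system records corner visits, nosepokes at doors and licks at
bottle nipples continuously. From these raw events we derive the cohort's
learning and activity variables:

* **trials** — visits containing at least one nosepoke; a trial is *correct*
  when made in the animal's assigned corner;
* **preference scores** — the weighted contrast ``(A - wB) / (A + wB)``
  where the weight ``w`` makes chance-level behavior map to 0
  (``w = 1/3`` for one target corner out of four; ``w = 1`` for binary
  contrasts such as sucrose vs. water or night vs. day);
* **learning criterion** — number of trials needed to cross the upper
  boundary of a Bernoulli sequential probability ratio test (SPRT) with
  null success probability ``p0`` (random expectation, 25% for four
  corners) and alternative ``p1 = p0 + 10%``; an animal that never crosses
  within a phase is censored at its total trial count;
* **serial-reversal AUC** — trapezoidal area under the trials-to-criterion
  curve across all reversal phases (unit phase spacing);
* **activity and nocturnality** — visit frequency per day, a night-vs-day
  preference score, and a 24-bin zeitgeber-time activity profile.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import (
    EventStream,
    LightSchedule,
    Phase,
    PhaseSchedule,
    ValidationError,
)

log = logging.getLogger("psycop")


# ---------------------------------------------------------------------------
# trials
# ---------------------------------------------------------------------------

@dataclass
class TrialSequence:
    """Ordered binary trial outcomes of one animal in one phase."""

    animal_id: str
    phase: str
    #: columns: corner, assigned, correct
    trials: pd.DataFrame

    @property
    def outcomes(self) -> np.ndarray:
        return self.trials["correct"].to_numpy(dtype=bool)

    def __len__(self) -> int:
        return len(self.trials)


def extract_trials(
    stream: EventStream,
    schedule: PhaseSchedule,
    phase: str | Phase,
) -> dict[str, TrialSequence]:
    """Per-animal trial sequences for a place or reversal phase.

    Only visits containing at least one nosepoke (same animal and corner,
    nosepoke time within the visit interval) become trials; nosepoke-less
    visits are dropped and their count logged.
    """
    ph = schedule.phase(phase) if isinstance(phase, str) else phase
    if ph.paradigm not in ("place", "reversal"):
        raise ValidationError(f"phase {ph.name!r} has no corner assignments to score")
    window = stream.between(ph.start, ph.end)
    visits = window.visits()
    pokes = window.of_kind("nosepoke")

    out: dict[str, TrialSequence] = {}
    n_dropped = 0
    for animal in stream.animals:
        if animal not in ph.assignments:
            raise ValidationError(f"animal {animal!r} has no corner assignment in phase {ph.name!r}")
        assigned = int(ph.assignments[animal])
        av = visits[visits["animal_id"] == animal]
        ap = pokes[pokes["animal_id"] == animal]
        rows = []
        for _, v in av.iterrows():
            end = v["timestamp"] + pd.to_timedelta(
                0.0 if pd.isna(v["duration"]) else v["duration"], unit="s"
            )
            has_poke = (
                (ap["corner"] == v["corner"])
                & (ap["timestamp"] >= v["timestamp"])
                & (ap["timestamp"] <= end)
            ).any()
            if has_poke:
                rows.append(
                    {
                        "corner": int(v["corner"]),
                        "assigned": assigned,
                        "correct": int(v["corner"]) == assigned,
                    }
                )
            else:
                n_dropped += 1
        out[animal] = TrialSequence(
            animal_id=animal,
            phase=ph.name,
            trials=pd.DataFrame(rows, columns=["corner", "assigned", "correct"]),
        )
    if n_dropped:
        log.info("phase %s: dropped %d visits without nosepokes", ph.name, n_dropped)
    return out


# ---------------------------------------------------------------------------
# preference scores
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PreferenceScore:
    """Weighted contrast of two counts, anchored so chance maps to 0."""

    value: float  # NaN when undefined
    n_target: float
    n_other: float
    weight: float

    @property
    def is_missing(self) -> bool:
        return math.isnan(self.value)


def preference_score(n_target: float, n_other: float, weight: float = 1.0) -> PreferenceScore:
    """``(A - wB) / (A + wB)`` for counts ``A`` (target) and ``B`` (other).

    ``weight`` is the ratio of target to non-target chance expectation
    (``k_target / k_other``): 1/3 for one assigned corner of four, 1 for
    binary contrasts. A zero denominator yields a missing value.
    """
    if n_target < 0 or n_other < 0:
        raise ValidationError("counts must be non-negative")
    if weight <= 0:
        raise ValidationError("weight must be positive")
    denom = n_target + weight * n_other
    if denom == 0:
        log.info("preference score undefined: A + wB = 0")
        value = math.nan
    else:
        value = (n_target - weight * n_other) / denom
    return PreferenceScore(value=value, n_target=n_target, n_other=n_other, weight=weight)


def corner_weight(k_target: int, k_total: int) -> float:
    """Chance weight for ``k_target`` assigned corners out of ``k_total``."""
    if not 0 < k_target < k_total:
        raise ValidationError("need 0 < k_target < k_total")
    return k_target / (k_total - k_target)


# ---------------------------------------------------------------------------
# SPRT learning criterion
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SPRTConfig:
    """Bernoulli SPRT bounds for the learning criterion.

    Defaults suit a four-corner cage: the lower bound ``p0`` is random
    expectation (25%), the upper bound ``p1`` adds 10 percentage points
    (35%), and both significance levels are 5%.
    """

    p0: float = 0.25
    p1: float = 0.35
    alpha: float = 0.05
    beta: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.p0 < self.p1 < 1:
            raise ValidationError("need 0 < p0 < p1 < 1")
        if not (0 < self.alpha <= 0.5 and 0 < self.beta <= 0.5):
            raise ValidationError("alpha and beta must lie in (0, 0.5]")

    @property
    def upper_threshold(self) -> float:
        """Wald's upper decision boundary ln((1 - beta) / alpha)."""
        return math.log((1 - self.beta) / self.alpha)

    def llr_increments(self, outcomes: np.ndarray) -> np.ndarray:
        """Per-trial log-likelihood-ratio increments."""
        win = math.log(self.p1 / self.p0)
        lose = math.log((1 - self.p1) / (1 - self.p0))
        return np.where(np.asarray(outcomes, dtype=bool), win, lose)


@dataclass(frozen=True)
class CriterionResult:
    trials_to_criterion: int
    censored: bool


def sprt_trials_to_criterion(
    seq: TrialSequence | np.ndarray | list,
    cfg: SPRTConfig = SPRTConfig(),
) -> CriterionResult:
    """Trials needed to cross the SPRT upper boundary.

    The cumulative Bernoulli log-likelihood ratio is accumulated trial by
    trial; the criterion is reached at the first trial where it meets
    ``ln((1 - beta) / alpha)``. Crossing the Wald lower boundary does not
    terminate the test — the statistic keeps accumulating until the upper
    boundary is crossed or the phase ends. An animal that never crosses is
    censored at its total trial count (0 for an empty sequence).
    """
    outcomes = seq.outcomes if isinstance(seq, TrialSequence) else np.asarray(seq, dtype=bool)
    n = len(outcomes)
    if n == 0:
        return CriterionResult(trials_to_criterion=0, censored=True)
    llr = np.cumsum(cfg.llr_increments(outcomes))
    crossed = np.flatnonzero(llr >= cfg.upper_threshold)
    if len(crossed) == 0:
        return CriterionResult(trials_to_criterion=n, censored=True)
    return CriterionResult(trials_to_criterion=int(crossed[0]) + 1, censored=False)


# ---------------------------------------------------------------------------
# serial reversal AUC
# ---------------------------------------------------------------------------

def serial_reversal_auc(per_phase: list[float] | np.ndarray) -> float:
    """Trapezoidal area under trials-to-criterion across reversal phases.

    Phases are unit-spaced; censored values enter as-is (they already carry
    the phase's total trial count). Any missing phase value yields a missing
    AUC.
    """
    y = np.asarray(per_phase, dtype=float)
    if len(y) < 2:
        raise ValidationError("serial-reversal AUC needs at least 2 phases")
    if np.isnan(y).any():
        log.info("serial-reversal AUC missing: %d phase value(s) missing", int(np.isnan(y).sum()))
        return math.nan
    return float(np.trapezoid(y))


# ---------------------------------------------------------------------------
# activity & circadian measures
# ---------------------------------------------------------------------------

def nocturnality_score(stream: EventStream, lights: LightSchedule) -> PreferenceScore:
    """Night-vs-day visit preference (weight 1; night is ZT12-24).

    Visits are attributed by their start timestamp. The stream should span
    at least 24 h for the score to be interpretable.
    """
    visits = stream.visits()
    if len(visits) == 0:
        return PreferenceScore(value=math.nan, n_target=0, n_other=0, weight=1.0)
    start, end = stream.span()
    if end - start < pd.Timedelta(hours=24):
        log.warning("nocturnality: stream spans less than 24 h")
    dark = lights.is_dark(visits["timestamp"])
    a = int(np.sum(dark))
    b = int(len(visits) - a)
    return preference_score(a, b, weight=1.0)


def activity_measures(stream: EventStream, window_days: float) -> float:
    """Visit frequency (visits/day) averaged over the first ``window_days``."""
    visits = stream.visits()
    if len(visits) == 0:
        return math.nan
    start, end = stream.span()
    span_days = (end - start) / pd.Timedelta(days=1)
    if window_days > span_days + 1e-9:
        raise ValidationError(
            f"window of {window_days} days exceeds recording span of {span_days:.2f} days"
        )
    cutoff = start + pd.Timedelta(days=window_days)
    n = int((visits["timestamp"] < cutoff).sum())
    return n / window_days


def hourly_profile(stream: EventStream, lights: LightSchedule) -> np.ndarray:
    """Visit counts per zeitgeber-hour bin [0,1), ..., [23,24), averaged across days."""
    visits = stream.visits()
    if len(visits) == 0:
        return np.zeros(24)
    start, end = stream.span()
    n_days = max((end - start) / pd.Timedelta(days=1), 1.0)
    zt = lights.zt(visits["timestamp"])
    counts, _ = np.histogram(zt, bins=np.arange(25))
    return counts / n_days


# ---------------------------------------------------------------------------
# derived-measure table
# ---------------------------------------------------------------------------

def compute_intellicage_measures(
    stream: EventStream,
    schedule: PhaseSchedule,
    lights: LightSchedule,
    sprt: SPRTConfig = SPRTConfig(),
    activity_window_days: float = 5.0,
) -> pd.DataFrame:
    """One row per animal with the home-cage derived variables.

    Columns: ``place_learning`` (corner preference score, weight 1/3),
    ``first_reversal`` (trials to criterion after the first reversal),
    ``serial_reversal_auc``, ``sucrose_preference`` (licks, weight 1),
    ``activity`` (visits/day) and ``nocturnality``.
    """
    animals = stream.animals
    out = pd.DataFrame(index=pd.Index(animals, name="animal_id"), dtype=float)

    place_phases = schedule.of_paradigm("place")
    if place_phases:
        w = corner_weight(1, 4)
        trials = extract_trials(stream, schedule, place_phases[-1])
        for animal, seq in trials.items():
            correct = int(seq.outcomes.sum())
            incorrect = len(seq) - correct
            out.loc[animal, "place_learning"] = preference_score(correct, incorrect, w).value

    reversals = schedule.reversal_phases()
    if reversals:
        per_phase: dict[str, list[float]] = {a: [] for a in animals}
        for ph in reversals:
            trials = extract_trials(stream, schedule, ph)
            for animal, seq in trials.items():
                per_phase[animal].append(float(sprt_trials_to_criterion(seq, sprt).trials_to_criterion))
        for animal in animals:
            vals = per_phase[animal]
            out.loc[animal, "first_reversal"] = vals[0] if vals else math.nan
            out.loc[animal, "serial_reversal_auc"] = (
                serial_reversal_auc(vals) if len(vals) >= 2 else math.nan
            )

    sucrose_phases = schedule.of_paradigm("sucrose")
    if sucrose_phases:
        ph = sucrose_phases[-1]
        licks = stream.between(ph.start, ph.end).of_kind("lick")
        for animal in animals:
            al = licks[licks["animal_id"] == animal]
            # sucrose bottles sit on the same side in every corner
            a = int((al["side"] == "right").sum())
            b = int((al["side"] == "left").sum())
            out.loc[animal, "sucrose_preference"] = preference_score(a, b, 1.0).value

    for animal in animals:
        sub = EventStream(stream.for_animal(animal).copy())
        out.loc[animal, "activity"] = activity_measures(sub, activity_window_days)
        out.loc[animal, "nocturnality"] = nocturnality_score(sub, lights).value
    return out
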