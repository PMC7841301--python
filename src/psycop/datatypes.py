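"""Shared data model for 2x2 genotype-by-environment behavioral cohorts.

A cohort is a set of animals crossed over two binary factors:

* ``genotype`` — ``wt`` (wildtype) vs ``tg`` (transgenic),
* ``environment`` — ``ns`` (no-stress control) vs ``sd`` (social defeat).

Per-animal behavioral measures live in a :class:`BehaviorTable`; raw
home-cage event recordings (corner visits, nosepokes, licks) live in an
:class:`EventStream`; the experimental timeline is a :class:`PhaseSchedule`;
variables are assigned *a priori* to Research Domain Criteria (RDoC) domains
through an :class:`RDoCMap`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

GENOTYPE_LEVELS = ("wt", "tg")
ENVIRONMENT_LEVELS = ("ns", "sd")

#: Canonical group order used in every table and figure.
GROUP_ORDER = ("wt-ns", "wt-sd", "tg-ns", "tg-sd")

#: RDoC domain codes: cognitive, sensorimotor, positive valence,
#: negative valence, arousal/regulatory.
RDOC_DOMAINS = ("C", "S", "+", "-", "A")

EVENT_KINDS = ("visit", "nosepoke", "lick")
SIDES = ("left", "right")

PARADIGMS = ("free", "nosepoke", "probabilistic", "place", "reversal", "sucrose")


class ValidationError(ValueError):
    """Raised when an input violates the cohort data model."""


def group_label(genotype: str, environment: str) -> str:
    return f"{genotype}-{environment}"


@dataclass
class BehaviorTable:
    """Animals x variables matrix with two crossed binary factors.

    Parameters
    ----------
    data : DataFrame
        Indexed by animal id; one float column per behavioral variable.
        Missing measurements are ``NaN`` — never zero.
    factors : DataFrame
        Indexed identically; columns ``genotype`` and ``environment``.
    """

    data: pd.DataFrame
    factors: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.data.index.equals(self.factors.index):
            raise ValidationError("data and factors must share the same animal index")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate animal_id: {dups}")
        for col, levels in (("genotype", GENOTYPE_LEVELS), ("environment", ENVIRONMENT_LEVELS)):
            if col not in self.factors.columns:
                raise ValidationError(f"missing factor column {col!r}")
            bad = self.factors.loc[~self.factors[col].isin(levels), col]
            if len(bad):
                raise ValidationError(
                    f"unknown {col} level {bad.iloc[0]!r} for animal "
                    f"{bad.index[0]!r}; allowed levels: {list(levels)}"
                )
            if self.factors[col].isna().any():
                raise ValidationError(f"animal with unassigned {col}")
        self.data = self.data.astype(float)

    # -- basic views ------------------------------------------------------
    @property
    def animals(self) -> pd.Index:
        return self.data.index

    @property
    def variables(self) -> list[str]:
        return list(self.data.columns)

    @property
    def groups(self) -> pd.Series:
        """Per-animal group label, e.g. ``wt-ns``."""
        g = self.factors["genotype"].astype(str) + "-" + self.factors["environment"].astype(str)
        g.name = "group"
        return g

    def group_sizes(self) -> pd.Series:
        """Animal counts per factor-level combination, in canonical order."""
        return self.groups.value_counts().reindex(GROUP_ORDER, fill_value=0)

    def design_codes(self) -> pd.DataFrame:
        """Sum-to-zero (-1/+1) codes for genotype, environment and their product.

        ``wt``/``ns`` are coded -1 and ``tg``/``sd`` +1, so main-effect
        contrasts are level-2 minus level-1.
        """
        g = self.factors["genotype"].map({"wt": -1.0, "tg": 1.0})
        e = self.factors["environment"].map({"ns": -1.0, "sd": 1.0})
        return pd.DataFrame({"g": g, "e": e, "ge": g * e}, index=self.animals)

    def complete_cases(self) -> "BehaviorTable":
        """Listwise-complete subset (animals with no missing variable)."""
        mask = self.data.notna().all(axis=1)
        return BehaviorTable(self.data.loc[mask].copy(), self.factors.loc[mask].copy())

    def require_filled_cells(self, min_per_cell: int = 1) -> None:
        sizes = self.group_sizes()
        low = sizes[sizes < min_per_cell]
        if len(low):
            raise ValidationError(
                f"factor cells with fewer than {min_per_cell} animals: "
                f"{dict(low)}"
            )

    def to_frame(self) -> pd.DataFrame:
        """Single DataFrame with factor columns first, for writing to disk."""
        return pd.concat([self.factors, self.data], axis=1)


@dataclass(frozen=True)
class RDoCMap:
    """A priori assignment of behavioral variables to RDoC domains."""

    assignments: Mapping[str, str]

    def __post_init__(self) -> None:
        for var, dom in self.assignments.items():
            if dom not in RDOC_DOMAINS:
                raise ValidationError(
                    f"variable {var!r} assigned to unknown domain {dom!r}; "
                    f"allowed: {list(RDOC_DOMAINS)}"
                )

    def domain_of(self, variable: str) -> str:
        try:
            return self.assignments[variable]
        except KeyError:
            raise ValidationError(f"variable {variable!r} has no RDoC domain") from None

    def blocked_order(self, variables: Iterable[str]) -> list[str]:
        """Variables ordered by domain block (fixed domain order), stable within."""
        variables = list(variables)
        for v in variables:
            self.domain_of(v)
        return [v for d in RDOC_DOMAINS for v in variables if self.assignments[v] == d]

    def block_sizes(self, variables: Iterable[str]) -> dict[str, int]:
        variables = list(variables)
        return {
            d: sum(1 for v in variables if self.domain_of(v) == d)
            for d in RDOC_DOMAINS
            if any(self.domain_of(v) == d for v in variables)
        }


@dataclass
class EventStream:
    """Ordered home-cage event records (visits, nosepokes, licks).

    ``records`` columns: ``animal_id``, ``timestamp`` (datetime64),
    ``corner`` (1-4), ``side`` (left/right, visits use the entry side's
    placeholder ``left``), ``kind`` (visit/nosepoke/lick), ``duration``
    (seconds; NaN for instantaneous events).
    """

    records: pd.DataFrame
    n_orphans: int = 0

    def __post_init__(self) -> None:
        required = {"animal_id", "timestamp", "corner", "side", "kind"}
        missing = required - set(self.records.columns)
        if missing:
            raise ValidationError(f"event stream missing columns: {sorted(missing)}")
        if "duration" not in self.records.columns:
            self.records["duration"] = np.nan
        bad_kind = set(self.records["kind"]) - set(EVENT_KINDS)
        if bad_kind:
            raise ValidationError(f"unknown event kinds: {sorted(bad_kind)}")
        self.records = (
            self.records.sort_values(["animal_id", "timestamp"], kind="stable")
            .reset_index(drop=True)
        )

    @property
    def animals(self) -> list[str]:
        return sorted(self.records["animal_id"].unique())

    def visits(self) -> pd.DataFrame:
        return self.records[self.records["kind"] == "visit"]

    def of_kind(self, kind: str) -> pd.DataFrame:
        return self.records[self.records["kind"] == kind]

    def for_animal(self, animal_id: str) -> pd.DataFrame:
        return self.records[self.records["animal_id"] == animal_id]

    def between(self, start, end) -> "EventStream":
        """Events with timestamp in ``[start, end)``."""
        m = (self.records["timestamp"] >= start) & (self.records["timestamp"] < end)
        return EventStream(self.records[m].copy(), n_orphans=0)

    def span(self) -> tuple[pd.Timestamp, pd.Timestamp]:
        ts = self.records["timestamp"]
        return ts.min(), ts.max()


@dataclass(frozen=True)
class Phase:
    name: str
    start: pd.Timestamp
    end: pd.Timestamp
    paradigm: str
    #: animal_id -> assigned corner, for place/reversal paradigms
    assignments: Mapping[str, int] | None = None
    door_open_prob: float | None = None

    def __post_init__(self) -> None:
        if self.paradigm not in PARADIGMS:
            raise ValidationError(f"unknown paradigm {self.paradigm!r}")
        if self.end <= self.start:
            raise ValidationError(f"phase {self.name!r}: end must follow start")
        if self.paradigm in ("place", "reversal") and not self.assignments:
            raise ValidationError(
                f"phase {self.name!r}: {self.paradigm} paradigm requires corner assignments"
            )


@dataclass
class PhaseSchedule:
    """Ordered, non-overlapping experiment phases."""

    phases: list[Phase] = field(default_factory=list)

    def __post_init__(self) -> None:
        for a, b in zip(self.phases, self.phases[1:]):
            if b.start < a.end:
                raise ValidationError(f"phases {a.name!r} and {b.name!r} overlap")
        # consecutive place/reversal phases must reassign each animal's corner
        prev: Phase | None = None
        for ph in self.phases:
            if ph.paradigm == "reversal" and prev is not None and prev.assignments:
                for animal, corner in (ph.assignments or {}).items():
                    if prev.assignments.get(animal) == corner:
                        raise ValidationError(
                            f"phase {ph.name!r}: animal {animal!r} keeps corner "
                            f"{corner} from {prev.name!r}; reversal must reassign"
                        )
            if ph.paradigm in ("place", "reversal"):
                prev = ph

    def __iter__(self):
        return iter(self.phases)

    def __len__(self) -> int:
        return len(self.phases)

    def phase(self, name: str) -> Phase:
        for ph in self.phases:
            if ph.name == name:
                return ph
        raise KeyError(f"no phase named {name!r}")

    def of_paradigm(self, paradigm: str) -> list[Phase]:
        return [ph for ph in self.phases if ph.paradigm == paradigm]

    def reversal_phases(self) -> list[Phase]:
        return self.of_paradigm("reversal")


@dataclass(frozen=True)
class LightSchedule:
    """Light/dark cycle; zeitgeber time ZT0 is lights-on."""

    lights_on: float = 7.0  # clock hour
    light_hours: float = 12.0
    dark_hours: float = 12.0

    def __post_init__(self) -> None:
        if abs(self.light_hours + self.dark_hours - 24.0) > 1e-9:
            raise ValidationError("light + dark hours must equal 24")
        if not 0 <= self.lights_on < 24:
            raise ValidationError("lights_on must be a clock hour in [0, 24)")

    def zt(self, timestamps: pd.Series | pd.Timestamp) -> np.ndarray | float:
        """Zeitgeber time in hours (0 = lights-on) for timestamps."""
        if isinstance(timestamps, pd.Timestamp):
            clock = timestamps.hour + timestamps.minute / 60 + timestamps.second / 3600
            return float((clock - self.lights_on) % 24.0)
        t = pd.to_datetime(timestamps)
        clock = t.dt.hour + t.dt.minute / 60 + t.dt.second / 3600
        return ((clock - self.lights_on) % 24.0).to_numpy()

    def is_dark(self, timestamps) -> np.ndarray | bool:
        """True for timestamps in the dark phase (ZT >= light_hours)."""
        z = self.zt(timestamps)
        return z >= self.light_hours
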