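"""Synthetic cohorts and home-cage event streams with known ground truth.

The generator emulates the data structure the pipeline assumes, not mouse
behavior per se: a four-group 2x2 cohort (default n = 15/17/15/17) of 19
correlated continuous variables with configurable genotype, environment and
interaction mean shifts plus missing cells, and event streams whose corner
choice follows a learnable process (correct-choice probability relaxing
exponentially toward an asymptote, resetting at each reversal).

Effect sizes are expressed in residual-sd units as the *difference between
factor levels* (Cohen's d): an effect of d means the two levels of that
factor differ by d sd, i.e. a per-level offset of ±d/2 under sum-to-zero
coding. This makes closed-form noncentral-F power oracles directly
applicable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import (
    GROUP_ORDER,
    BehaviorTable,
    EventStream,
    LightSchedule,
    Phase,
    PhaseSchedule,
    RDoCMap,
    ValidationError,
)

# ---------------------------------------------------------------------------
# default variable battery (19 variables, RDoC domains a priori)
# ---------------------------------------------------------------------------

#: variable -> (RDoC domain, G shift, E shift, GxE shift) in sd units.
#: Defaults plant a strong environment signature on valence/arousal and
#: fear-memory variables, a genotype signature on sensorimotor gating and
#: serial-reversal learning, and an interaction only on open-field speed.
DEFAULT_BATTERY: dict[str, tuple[str, float, float, float]] = {
    "y_maze_alternation": ("C", 0.0, 0.0, 0.0),
    "first_reversal": ("C", 0.0, -0.9, 0.0),
    "serial_reversal_auc": ("C", -0.7, -1.4, 0.0),
    "contextual_fear": ("C", -0.8, -1.6, 0.0),
    "cued_fear": ("C", -0.9, -1.2, 0.0),
    "place_learning": ("C", 0.0, 0.0, 0.0),
    "ppi_69db": ("S", -0.9, 0.0, 0.0),
    "ppi_73db": ("S", -1.1, 0.0, 0.0),
    "ppi_77db": ("S", -1.2, 0.0, 0.0),
    "ppi_81db": ("S", -1.0, 0.0, 0.0),
    "startle_amplitude": ("S", 0.5, 0.0, 0.0),
    "sucrose_preference": ("+", 0.0, -0.8, 0.0),
    "of_center_time": ("-", 0.0, 0.9, 0.0),
    "tail_suspension_struggle": ("-", 0.0, 0.0, 0.0),
    "novel_freezing": ("-", 0.0, 0.0, 0.0),
    "of_mean_speed": ("A", 0.0, 0.6, 0.8),
    "y_maze_choices": ("A", 0.0, 1.2, 0.0),
    "activity": ("A", 0.0, -0.9, 0.0),
    "nocturnality": ("A", 0.0, 0.0, 0.0),
}


def default_rdoc_map() -> RDoCMap:
    return RDoCMap({v: spec[0] for v, spec in DEFAULT_BATTERY.items()})


def default_effects() -> pd.DataFrame:
    """Variables x (G, E, GxE) mean-shift matrix in sd units."""
    return pd.DataFrame(
        {v: spec[1:] for v, spec in DEFAULT_BATTERY.items()},
        index=["G", "E", "GxE"],
    ).T


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

@dataclass
class CohortSpec:
    """Study-condition parameters of the synthetic cohort.

    ``group_sizes`` follows the canonical group order (wt-ns, wt-sd, tg-ns,
    tg-sd); ``effects`` holds per-variable mean shifts in sd units for G, E
    and GxE; ``correlation`` is the common pairwise correlation of an
    exchangeable correlation matrix (or a full matrix); ``missing_prob`` is
    the independent per-cell deletion probability.
    """

    group_sizes: tuple[int, int, int, int] = (15, 17, 15, 17)
    effects: pd.DataFrame = field(default_factory=default_effects)
    baseline: float = 0.0
    correlation: float | np.ndarray = 0.2
    missing_prob: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 2 for n in self.group_sizes):
            raise ValidationError("every group needs at least 2 animals")
        if not 0 <= self.missing_prob <= 0.3:
            raise ValidationError("missing probability must lie in [0, 0.3]")
        missing_terms = {"G", "E", "GxE"} - set(self.effects.columns)
        if missing_terms:
            raise ValidationError(f"effects matrix lacks columns {sorted(missing_terms)}")

    @property
    def variables(self) -> list[str]:
        return list(self.effects.index)

    def correlation_matrix(self) -> np.ndarray:
        p = len(self.variables)
        if np.isscalar(self.correlation):
            C = np.full((p, p), float(self.correlation))
            np.fill_diagonal(C, 1.0)
        else:
            C = np.asarray(self.correlation, dtype=float)
        if np.linalg.eigvalsh(C).min() <= 0:
            raise ValidationError("correlation matrix must be positive definite")
        return C


@dataclass
class CohortTruth:
    """Ground truth saved alongside a simulated cohort."""

    effects: pd.DataFrame            # planted shifts, sd units
    cell_means: pd.DataFrame         # groups x variables true means
    deleted: pd.DataFrame            # animal_id, variable, true_value
    complete: pd.DataFrame           # the table before deletion


def simulate_cohort(
    spec: CohortSpec, seed: int | np.random.Generator | None = None
) -> tuple[BehaviorTable, CohortTruth]:
    """Draw a multivariate-normal 2x2 cohort with planted effects.

    Group means are ``baseline + (g*dG + e*dE + g*e*dGxE)/2`` with
    sum-to-zero codes g, e in {-1, +1}; residuals have unit sd and the
    spec's correlation structure. Cells are then deleted independently at
    ``missing_prob``; the ground-truth record keeps the deleted values.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(spec.seed if seed is None else seed)
    )
    variables = spec.variables
    eff = spec.effects
    codes = {"wt-ns": (-1, -1), "wt-sd": (-1, 1), "tg-ns": (1, -1), "tg-sd": (1, 1)}
    cell_means = pd.DataFrame(
        {
            grp: spec.baseline
            + 0.5 * (g * eff["G"] + e * eff["E"] + g * e * eff["GxE"])
            for grp, (g, e) in codes.items()
        }
    ).T.loc[list(GROUP_ORDER)]

    L = np.linalg.cholesky(spec.correlation_matrix())
    rows, gts, envs, ids = [], [], [], []
    counter = 1
    for grp, n in zip(GROUP_ORDER, spec.group_sizes):
        gt, env = grp.split("-")
        noise = rng.standard_normal((n, len(variables))) @ L.T
        rows.append(cell_means.loc[grp].to_numpy() + noise)
        gts += [gt] * n
        envs += [env] * n
        ids += [f"m{counter + i:03d}" for i in range(n)]
        counter += n
    data = pd.DataFrame(
        np.vstack(rows), index=pd.Index(ids, name="animal_id"), columns=variables
    )
    factors = pd.DataFrame(
        {"genotype": gts, "environment": envs}, index=data.index
    )
    complete = data.copy()
    deleted_rows = []
    if spec.missing_prob > 0:
        mask = rng.random(data.shape) < spec.missing_prob
        for i, j in zip(*np.nonzero(mask)):
            deleted_rows.append(
                {
                    "animal_id": data.index[i],
                    "variable": variables[j],
                    "true_value": data.iat[i, j],
                }
            )
            data.iat[i, j] = np.nan
    truth = CohortTruth(
        effects=eff.copy(),
        cell_means=cell_means,
        deleted=pd.DataFrame(deleted_rows, columns=["animal_id", "variable", "true_value"]),
        complete=complete,
    )
    return BehaviorTable(data=data, factors=factors), truth


# ---------------------------------------------------------------------------
# default phase schedule
# ---------------------------------------------------------------------------

def default_schedule(
    animal_ids: list[str],
    start: pd.Timestamp | str = "2024-01-08 07:00:00",
    n_reversals: int = 7,
    seed: int = 0,
) -> PhaseSchedule:
    """Home-cage timeline: adaptation, place learning, serial reversal, sucrose.

    Corner assignments are balanced round-robin over the four corners;
    each reversal phase reassigns every animal to a new corner following a
    per-animal rotation, so consecutive assignments always differ.
    """
    start = pd.Timestamp(start)
    rng = np.random.default_rng(seed)
    day = pd.Timedelta(days=1)

    def ph(name, offset, days, paradigm, assignments=None, prob=None):
        return Phase(
            name=name,
            start=start + offset * day,
            end=start + (offset + days) * day,
            paradigm=paradigm,
            assignments=assignments,
            door_open_prob=prob,
        )

    base = {a: (i % 4) + 1 for i, a in enumerate(sorted(animal_ids))}
    steps = rng.integers(1, 4, size=n_reversals)  # shared shift pattern, never 0 mod 4

    phases = [
        ph("free_adaptation", 0, 2, "free"),
        ph("free_adaptation_doors", 2, 1, "free"),
        ph("nosepoke_adaptation", 3, 2, "nosepoke"),
        ph("nosepoke_50", 5, 1, "probabilistic", prob=0.5),
        ph("nosepoke_30", 6, 1, "probabilistic", prob=0.3),
        ph("place_learning", 7, 2, "place", assignments=dict(base)),
    ]
    current = dict(base)
    offset = 9
    for r in range(n_reversals):
        current = {a: ((c - 1 + int(steps[r])) % 4) + 1 for a, c in current.items()}
        phases.append(ph(f"reversal_{r + 1}", offset, 1, "reversal", assignments=dict(current)))
        offset += 1
    phases.append(ph("sucrose_preference", offset, 1, "sucrose"))
    return PhaseSchedule(phases)


# ---------------------------------------------------------------------------
# event-stream simulation
# ---------------------------------------------------------------------------

@dataclass
class LearnerSpec:
    """Corner-choice learning process and activity parameters."""

    initial_p: float = 0.25          # correct-choice probability at phase start
    learning_rate: float = 0.08      # relaxation per trial toward the asymptote
    asymptote: float = 0.85
    visits_per_day: float = 120.0
    nosepoke_prob: float = 0.8       # probability a visit contains nosepokes
    lick_mean: float = 20.0          # licks per rewarded visit
    sucrose_lick_mean: float = 30.0  # licks/visit at the sucrose bottle
    water_lick_mean: float = 10.0    # licks/visit at the water bottle
    night_day_ratio: float = 3.0     # visit-rate ratio dark : light
    mean_visit_s: float = 20.0

    def __post_init__(self) -> None:
        for name in ("initial_p", "nosepoke_prob"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValidationError(f"{name} must lie in [0, 1]")
        if not 0 <= self.asymptote <= 1:
            raise ValidationError("asymptote must lie in [0, 1]")
        if self.asymptote < self.initial_p:
            raise ValidationError("asymptote below initial probability: not a learner")
        if self.visits_per_day <= 0:
            raise ValidationError("visit rate must be positive")


def _visit_times(
    rng: np.random.Generator,
    start: pd.Timestamp,
    end: pd.Timestamp,
    lights: LightSchedule,
    spec: LearnerSpec,
) -> np.ndarray:
    """Two-rate (light/dark) Poisson visit-start times, as absolute timestamps."""
    r = spec.night_day_ratio
    day_rate = spec.visits_per_day / (lights.light_hours + r * lights.dark_hours)
    night_rate = r * day_rate  # per hour
    times = []
    t = start
    while t < end:
        nxt = min(t + pd.Timedelta(hours=1), end)
        hours = (nxt - t) / pd.Timedelta(hours=1)
        rate = night_rate if lights.is_dark(t) else day_rate
        n = rng.poisson(rate * hours)
        if n:
            offs = np.sort(rng.random(n)) * hours
            times.extend(t + pd.to_timedelta(offs, unit="h"))
        t = nxt
    return np.array(times, dtype="datetime64[ns]")


def simulate_intellicage(
    spec: LearnerSpec,
    schedule: PhaseSchedule,
    lights: LightSchedule,
    animal_ids: list[str],
    seed: int | np.random.Generator = 0,
) -> tuple[EventStream, pd.DataFrame]:
    """Simulate visit/nosepoke/lick streams for every animal.

    Corner choice in place/reversal phases follows
    ``p <- p + learning_rate * (asymptote - p)`` after each trial (a visit
    with nosepokes), resetting to ``initial_p`` at each phase start. Correct
    nosepoked visits are rewarded with licks; in the sucrose phase every
    corner serves sucrose on the right side and water on the left. Returns
    the stream and a per-visit ground-truth table.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    records: list[dict] = []
    truth_rows: list[dict] = []
    for animal in sorted(animal_ids):
        for ph in schedule:
            times = _visit_times(rng, ph.start, ph.end, lights, spec)
            scored = ph.paradigm in ("place", "reversal")
            assigned = int(ph.assignments[animal]) if scored else None
            p_correct = spec.initial_p
            for t in times:
                ts = pd.Timestamp(t)
                duration = float(rng.lognormal(np.log(spec.mean_visit_s), 0.4))
                if scored:
                    if rng.random() < p_correct:
                        corner = assigned
                    else:
                        others = [c for c in (1, 2, 3, 4) if c != assigned]
                        corner = int(others[rng.integers(3)])
                else:
                    corner = int(rng.integers(1, 5))
                records.append(
                    {
                        "animal_id": animal, "timestamp": ts, "corner": corner,
                        "side": "left", "kind": "visit", "duration": duration,
                    }
                )
                has_poke = bool(rng.random() < spec.nosepoke_prob)
                if has_poke:
                    n_pokes = 1 + int(rng.poisson(1.0))
                    for off in np.sort(rng.random(n_pokes)) * duration:
                        records.append(
                            {
                                "animal_id": animal,
                                "timestamp": ts + pd.Timedelta(seconds=float(off)),
                                "corner": corner, "side": "left",
                                "kind": "nosepoke", "duration": np.nan,
                            }
                        )
                correct = (corner == assigned) if scored else None
                if ph.paradigm == "sucrose":
                    for side, mean in (("right", spec.sucrose_lick_mean),
                                       ("left", spec.water_lick_mean)):
                        n_licks = int(rng.poisson(mean))
                        for off in np.sort(rng.random(n_licks)) * duration:
                            records.append(
                                {
                                    "animal_id": animal,
                                    "timestamp": ts + pd.Timedelta(seconds=float(off)),
                                    "corner": corner, "side": side,
                                    "kind": "lick", "duration": np.nan,
                                }
                            )
                elif scored and has_poke and correct:
                    n_licks = int(rng.poisson(spec.lick_mean))
                    for off in np.sort(rng.random(n_licks)) * duration:
                        records.append(
                            {
                                "animal_id": animal,
                                "timestamp": ts + pd.Timedelta(seconds=float(off)),
                                "corner": corner, "side": "left",
                                "kind": "lick", "duration": np.nan,
                            }
                        )
                truth_rows.append(
                    {
                        "animal_id": animal, "phase": ph.name, "timestamp": ts,
                        "corner": corner, "assigned": assigned,
                        "has_nosepoke": has_poke,
                        "correct": correct if scored else np.nan,
                    }
                )
                if scored and has_poke:
                    p_correct += spec.learning_rate * (spec.asymptote - p_correct)
    stream = EventStream(pd.DataFrame.from_records(records))
    truth = pd.DataFrame.from_records(truth_rows)
    return stream, truth


# ---------------------------------------------------------------------------
# parameter recovery
# ---------------------------------------------------------------------------

def simulate_bernoulli_phases(
    p: float, n_phases: int, phase_length: int, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Bernoulli(p) trial matrices for SPRT operating-characteristic checks."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.random((n_phases, phase_length)) < p


#: variables carrying each planted effect in the recovery grid
RECOVERY_SETS = {"G": (0, 1, 2), "E": (3, 4, 5), "GxE": (6, 7, 8)}


def parameter_recovery_suite(
    seed: int = 0,
    n_sims: int = 100,
    effect: float = 1.5,
    n_per_group: int = 16,
    missing_prob: float = 0.05,
    n_variables: int = 9,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Planted-effect recovery rates for the full analysis chain.

    For each term, plants an ``effect``-sd shift on three variables
    (disjoint sets per term), simulates ``n_sims`` cohorts, and reports the
    MANOVA detection rate, the mean FDR-adjusted univariate detection rate
    over the planted variables, the cosine alignment of the term's CDA
    direction with the population discriminant direction (the
    correlation-matrix-whitened planted shift, ``Sigma^-1 delta``), and the
    NIPALS imputation RMSE against deleted ground truth. A null row
    (no effects) reports family-wise false-positive rates.
    """
    from .dimred import nipals_impute, per_term_cda, standardize
    from .stats import fit_factorial, univariate_followups

    rng = np.random.default_rng(seed)
    variables = [f"v{i + 1}" for i in range(n_variables)]
    rows = []
    for term in ("null", "G", "E", "GxE"):
        eff = pd.DataFrame(0.0, index=variables, columns=["G", "E", "GxE"])
        planted_vars: tuple[int, ...] = ()
        if term != "null":
            planted_vars = RECOVERY_SETS[term]
            for i in planted_vars:
                eff.iloc[i, list(eff.columns).index(term)] = effect
        spec = CohortSpec(
            group_sizes=(n_per_group,) * 4,
            effects=eff,
            correlation=0.2,
            missing_prob=missing_prob,
        )
        delta = eff[term].to_numpy() if term != "null" else None
        if delta is not None:
            # population discriminant in z-score units: the CDA consumes
            # z-standardized columns, whose total sd is sqrt(1 + delta_j^2/4)
            # (residual sd 1 plus the between-level shift of +-delta/2)
            col_sd = np.sqrt(1.0 + delta**2 / 4.0)
            ref = col_sd * np.linalg.solve(spec.correlation_matrix(), delta)
            ref /= np.linalg.norm(ref)
        uni_hits = manova_hits = 0
        cosines, rmses = [], []
        for _ in range(n_sims):
            table, truth = simulate_cohort(spec, seed=rng)
            model = fit_factorial(table)
            uni = univariate_followups(model)
            nip = nipals_impute(table)
            if len(truth.deleted):
                pred = np.array(
                    [
                        nip.reconstituted.loc[r.animal_id, r.variable]
                        for r in truth.deleted.itertuples()
                    ]
                )
                rmses.append(
                    float(np.sqrt(np.mean((pred - truth.deleted["true_value"]) ** 2)))
                )
            if term == "null":
                uni_hits += int(uni["significant"].any())
                manova_hits += int((manova_table_p(model) < alpha).any())
            else:
                uni_hits += float(
                    np.mean(
                        [
                            uni.loc[(variables[i], term), "significant"]
                            for i in planted_vars
                        ]
                    )
                )
                manova_hits += int(manova_table_p(model)[term] < alpha)
                z = standardize(nip.reconstituted)
                zmodel = fit_factorial(BehaviorTable(z, table.factors))
                c = per_term_cda(zmodel)[term].coefficients.to_numpy()
                cosines.append(float(np.abs(c @ ref) / np.linalg.norm(c)))
        rows.append(
            {
                "term": term,
                "detection_rate": uni_hits / n_sims,
                "manova_rate": manova_hits / n_sims,
                "cda_cosine": float(np.mean(cosines)) if cosines else np.nan,
                "imputation_rmse": float(np.mean(rmses)) if rmses else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("term")


def manova_table_p(model) -> pd.Series:
    from .stats import manova_table, manova_wilks

    return manova_table(manova_wilks(model))["p"]
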