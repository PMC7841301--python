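"""End-to-end profiling pipeline.

A single YAML configuration names the inputs (a measure table and/or an
event stream, or a synthetic-cohort block), the RDoC map, the phase
schedule, the output directory and the random seed. The run produces

1. the derived-measure table (CSV),
2. the factorial statistics report (MANOVA summary, per-variable Type-II
   tests with FDR-adjusted p-values, interaction follow-ups, E-test; TSV),
3. the profile figures (heatmap, CDA dimension plots, boxplots, residual
   diagnostics; SVG + PNG),
4. a run log recording package versions and the seed.

Outputs are staged in a temporary directory and moved into place only when
every stage succeeds; a failing stage aborts with its name and leaves no
partial outputs. The same configuration and seed give byte-identical
tables.
"""

from __future__ import annotations

import logging
import shutil
import tempfile
from pathlib import Path

import matplotlib
import numpy as np
import pandas as pd
import scipy
import statsmodels

from . import __version__, io, metrics, simulate, viz
from .datatypes import BehaviorTable, RDoCMap, ValidationError
from .dimred import cda, nipals_impute, per_term_cda, standardize, term_coefficient_matrix
from .stats import run_factorial_stats

log = logging.getLogger("psycop")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(
    config: str | Path | dict,
    seed: int | None = None,
    out: str | Path | None = None,
) -> Path:
    """Run the full profiling pipeline; returns the report directory."""
    cfg = io.read_config(config) if not isinstance(config, dict) else dict(config)
    seed = int(cfg.get("seed", 0)) if seed is None else int(seed)
    out_dir = Path(out or cfg.get("output_dir", "psycop_report"))
    stats_cfg = dict(cfg.get("stats", {}))
    make_figures = bool(cfg.get("figures", True))

    # -- validate configuration before any computation
    if "rdoc_map" not in cfg:
        raise ValidationError("config missing 'rdoc_map'")
    if not any(k in cfg for k in ("measure_table", "event_stream", "simulate")):
        raise ValidationError(
            "config must name a 'measure_table', an 'event_stream' or a 'simulate' block"
        )

    stage_dir = Path(tempfile.mkdtemp(prefix="psycop_stage_"))
    try:
        table, rdoc = _stage_inputs(cfg, seed, stage_dir)
        report = _stage_stats(table, stats_cfg, seed, stage_dir)
        z, cda_res, terms = _stage_dimred(table, stage_dir)
        if make_figures:
            _stage_figures(table, z, cda_res, terms, report, rdoc, seed, stage_dir)
        _write_run_log(stage_dir, seed, cfg)
    except StageError:
        shutil.rmtree(stage_dir, ignore_errors=True)
        raise
    except Exception as exc:  # config/IO errors before the first stage
        shutil.rmtree(stage_dir, ignore_errors=True)
        raise

    out_dir.mkdir(parents=True, exist_ok=True)
    for item in sorted(stage_dir.iterdir()):
        target = out_dir / item.name
        if target.exists():
            target.unlink()
        shutil.move(str(item), target)
    shutil.rmtree(stage_dir, ignore_errors=True)
    log.info("pipeline report written to %s", out_dir)
    return out_dir


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_inputs(cfg: dict, seed: int, stage: Path) -> tuple[BehaviorTable, RDoCMap]:
    try:
        rdoc_cfg = cfg["rdoc_map"]
        rdoc = (
            RDoCMap(dict(rdoc_cfg)) if isinstance(rdoc_cfg, dict) else io.read_rdoc_map(rdoc_cfg)
        )
        if "measure_table" in cfg:
            table = io.read_behavior_table(cfg["measure_table"])
        elif "simulate" in cfg:
            sim = dict(cfg.get("simulate") or {})
            spec_kwargs = {}
            if "group_sizes" in sim:
                spec_kwargs["group_sizes"] = tuple(sim["group_sizes"])
            if "missing_prob" in sim:
                spec_kwargs["missing_prob"] = float(sim["missing_prob"])
            if "correlation" in sim:
                spec_kwargs["correlation"] = float(sim["correlation"])
            if "effects" in sim:
                spec_kwargs["effects"] = pd.DataFrame(sim["effects"]).T.reindex(
                    columns=["G", "E", "GxE"], fill_value=0.0
                )
            spec = simulate.CohortSpec(seed=seed, **spec_kwargs)
            table, _ = simulate.simulate_cohort(spec, seed=seed)
        else:
            raise ValidationError("event-stream-only runs need a 'schedule' block")

        if "event_stream" in cfg:
            stream = io.read_event_stream(cfg["event_stream"])
            schedule = io.read_schedule(cfg["schedule"])
            lights = io.lights_from_dict(cfg.get("lights"))
            derived = metrics.compute_intellicage_measures(stream, schedule, lights)
            table = _merge_derived(table, derived)

        exclusions = cfg.get("exclude_animals") or []
        if exclusions:
            log.info("excluding animals per config: %s", list(exclusions))
            keep = ~table.animals.isin(exclusions)
            table = BehaviorTable(table.data.loc[keep], table.factors.loc[keep])
        for var in table.variables:
            rdoc.domain_of(var)
        io.write_behavior_table(table, stage / "derived_measures.csv")
        return table, rdoc
    except StageError:
        raise
    except Exception as exc:
        raise StageError("inputs", exc) from exc


def _merge_derived(table: BehaviorTable, derived: pd.DataFrame) -> BehaviorTable:
    data = table.data.join(derived, how="left", rsuffix="_ic")
    return BehaviorTable(data=data, factors=table.factors)


def _stage_stats(table, stats_cfg: dict, seed: int, stage: Path):
    try:
        report = run_factorial_stats(
            table,
            fdr_scope=stats_cfg.get("fdr_scope", "all"),
            alpha=float(stats_cfg.get("alpha", 0.05)),
            n_boot=int(stats_cfg.get("n_boot", 1000)),
            seed=np.random.default_rng(seed),
            run_etest=bool(stats_cfg.get("etest", True)),
        )
        io.write_tsv(report.manova, stage / "manova.tsv")
        io.write_tsv(report.univariate, stage / "univariate_tests.tsv")
        for var, tbl in report.interactions.items():
            io.write_tsv(tbl, stage / f"interaction_{var}.tsv")
        if report.etest is not None:
            io.write_tsv(
                pd.DataFrame(
                    {"statistic": [report.etest.statistic], "p": [report.etest.p],
                     "n_boot": [report.etest.n_boot]}
                ),
                stage / "etest_mvn.tsv",
                index=False,
            )
        return report
    except Exception as exc:
        raise StageError("stats", exc) from exc


def _stage_dimred(table: BehaviorTable, stage: Path):
    try:
        nip = nipals_impute(table)
        z = standardize(nip.reconstituted)
        groups = table.groups
        cda_res = cda(z, groups)
        zmodel_table = BehaviorTable(z, table.factors)
        from .stats import fit_factorial

        terms = per_term_cda(fit_factorial(zmodel_table))
        io.write_tsv(nip.reconstituted, stage / "reconstituted.csv")
        io.write_tsv(cda_res.scores, stage / "cda_scores.tsv")
        io.write_tsv(cda_res.coefficients, stage / "cda_coefficients.tsv")
        io.write_tsv(
            pd.DataFrame(
                {"singular_value": cda_res.singular_values, "percent": cda_res.percent},
                index=cda_res.scores.columns,
            ),
            stage / "cda_percent.tsv",
        )
        io.write_tsv(term_coefficient_matrix(terms), stage / "term_coefficients.tsv")
        return z, cda_res, terms
    except Exception as exc:
        raise StageError("dimred", exc) from exc


def _stage_figures(table, z, cda_res, terms, report, rdoc, seed: int, stage: Path):
    try:
        groups = table.groups
        stars = (
            report.univariate["stars"].unstack(level="term")
            if len(report.univariate)
            else None
        )
        spec, fig = viz.make_heatmap(z, groups, rdoc, stars=stars)
        viz.save_figure(fig, stage / "heatmap")
        io.write_tsv(spec.cells, stage / "heatmap_matrix.tsv")
        fig = viz.make_dimension_plot(cda_res, groups, mode="points")
        viz.save_figure(fig, stage / "cda_points")
        fig = viz.make_dimension_plot(cda_res, groups, mode="vectors")
        viz.save_figure(fig, stage / "cda_vectors")
        fig = viz.residual_diagnostics(report.model)
        viz.save_figure(fig, stage / "residual_diagnostics")
        box_dir = stage / "boxplots"
        box_dir.mkdir()
        for var in table.variables:
            rows = report.univariate.xs(var, level="variable")
            fig = viz.make_boxplots(table, var, stats_rows=rows, seed=seed)
            viz.save_figure(fig, box_dir / var, formats=("png",))
    except Exception as exc:
        raise StageError("figures", exc) from exc


def _write_run_log(stage: Path, seed: int, cfg: dict) -> None:
    lines = [
        f"psycop {__version__}",
        f"numpy {np.__version__}",
        f"scipy {scipy.__version__}",
        f"pandas {pd.__version__}",
        f"statsmodels {statsmodels.__version__}",
        f"matplotlib {matplotlib.__version__}",
        f"seed {seed}",
        f"config_keys {sorted(cfg.keys())}",
    ]
    (stage / "run_log.txt").write_text("\n".join(lines) + "\n")
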