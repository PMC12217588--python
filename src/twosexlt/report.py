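"""Full-analysis orchestration: tables, significance letters, projections.

``run_full_analysis`` drives the whole pipeline for one or more treatment
cohorts: schedules -> demographic parameters -> bootstrap SEs -> pairwise
paired bootstrap tests -> compact-letter significance display ->
population projection, writing paper-style CSV tables (stage durations /
mortality, reproductive summaries, demographic parameters), schedule and
projection series, a JSON parameter dump at full precision, and a run
log.  Plots are optional so the pipeline runs headless.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from ._version import __version__ as _version
from .bootstrap import PARAMETERS, PairedTestResult, bootstrap_cohort, paired_bootstrap_test
from .cohort import CohortTable, read_cohort, stage_summaries
from .demography import demographic_params
from .lifetable import compute_schedules, reproductive_summary
from .projection import project

__all__ = ["AnalysisConfig", "run_full_analysis", "significance_letters"]

log = logging.getLogger(__name__)

# parameters compared across treatments in the demographic table
_TABLE4_PARAMS = ("R0", "r", "lambda", "T")


@dataclass(frozen=True)
class AnalysisConfig:
    """Configuration for one full analysis run."""

    cohorts: dict[str, str | Path]  # treatment label -> cohort CSV path
    b: int = 100_000
    seed: int = 1
    level: float = 0.95
    initial_eggs: float = 10.0
    horizon: int = 60
    outdir: str | Path = "results"
    rounding: int = 2
    plots: bool = False

    def __post_init__(self) -> None:
        if self.b < 1:
            raise ValueError("b must be >= 1")
        if not 0 < self.level < 1:
            raise ValueError("level must be in (0, 1)")
        if self.horizon < 1:
            raise ValueError("horizon must be >= 1")
        if not self.cohorts:
            raise ValueError("at least one cohort is required")


def significance_letters(
    test_results: list[PairedTestResult],
) -> dict[str, str]:
    """Compact letter display from all pairwise paired-test results.

    Treatments share a letter iff they are not significantly different;
    letters are the maximal cliques of the not-different graph (greedy
    clique cover).  A non-transitive significance pattern still gets a
    consistent assignment (its cliques overlap), which is noted in the
    log.
    """
    if not test_results:
        return {}
    params = {t.parameter for t in test_results}
    if len(params) != 1:
        raise ValueError("significance_letters expects results for one parameter")
    treatments: list[str] = []
    for t in test_results:
        for name in t.treatments:
            if name not in treatments:
                treatments.append(name)
    g = nx.Graph()
    g.add_nodes_from(treatments)
    for t in test_results:
        if not t.significant:
            g.add_edge(*t.treatments)
    cliques = sorted(
        (sorted(c, key=treatments.index) for c in nx.find_cliques(g)),
        key=lambda c: treatments.index(c[0]),
    )
    letters = {name: "" for name in treatments}
    for letter_i, clique in enumerate(cliques):
        letter = chr(ord("a") + letter_i)
        for name in clique:
            letters[name] += letter
    if any(len(v) > 1 for v in letters.values()):
        log.info("non-disjoint letter display (overlapping cliques): %s", letters)
    return letters


def _fmt(mean: float, se: float, nd: int) -> str:
    if np.isnan(mean):
        return "–"
    return f"{mean:.{nd}f} ± {se:.{nd}f}" if np.isfinite(se) else f"{mean:.{nd}f}"


def run_full_analysis(config: AnalysisConfig) -> dict[str, Path]:
    """Run the complete pipeline and write the report bundle.

    Returns a mapping of artifact names to the files written.  Any stage
    failure removes partial outputs and re-raises with the stage named.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    stage = "setup"
    try:
        stage = "read"
        cohorts: dict[str, CohortTable] = {
            label: read_cohort(path) for label, path in config.cohorts.items()
        }
        labels = list(cohorts)

        stage = "compute"
        scheds = {lab: compute_schedules(c) for lab, c in cohorts.items()}
        params = {lab: demographic_params(s) for lab, s in scheds.items()}
        summaries = {lab: stage_summaries(c) for lab, c in cohorts.items()}
        reprods = {lab: reproductive_summary(c) for lab, c in cohorts.items()}

        stage = "bootstrap"
        boots = {
            lab: {r.parameter: r for r in bootstrap_cohort(c, config.b, config.seed)}
            for lab, c in cohorts.items()
        }

        stage = "compare"
        letters: dict[str, dict[str, str]] = {}
        tests: list[PairedTestResult] = []
        if len(labels) >= 2:
            for p in _TABLE4_PARAMS:
                results = [
                    paired_bootstrap_test(
                        cohorts[a], cohorts[b_], config.b, config.seed, p, config.level
                    )
                    for i, a in enumerate(labels)
                    for b_ in labels[i + 1 :]
                ]
                tests.extend(results)
                letters[p] = significance_letters(results)

        stage = "tables"
        nd = config.rounding
        rows = []
        for lab in labels:
            ss = summaries[lab]
            row = {"treatment": lab, "n01": ss.n01,
                   "immature_mortality": round(ss.immature_mortality, nd)}
            for s_name, ms in ss.durations.items():
                row[f"{s_name}_duration"] = _fmt(ms.mean, ms.se, nd)
                row[f"{s_name}_deaths"] = ss.deaths[s_name]
            row["female_preadult"] = _fmt(ss.female_preadult.mean, ss.female_preadult.se, nd)
            row["male_preadult"] = _fmt(ss.male_preadult.mean, ss.male_preadult.se, nd)
            rows.append(row)
        stages_table = pd.DataFrame(rows)

        rows = []
        for lab in labels:
            rs = reprods[lab]
            rows.append(
                {
                    "treatment": lab,
                    "APOP": _fmt(rs.apop.mean, rs.apop.se, nd),
                    "TPOP": _fmt(rs.tpop.mean, rs.tpop.se, nd),
                    "oviposition_days": _fmt(rs.oviposition_days.mean, rs.oviposition_days.se, nd),
                    "female_adult_longevity": _fmt(rs.female_longevity.mean, rs.female_longevity.se, nd),
                    "male_adult_longevity": _fmt(rs.male_longevity.mean, rs.male_longevity.se, nd),
                    "sex_ratio": round(rs.sex_ratio, nd),
                    "sex_ratio_of_adults": round(rs.sex_ratio_of_adults, nd),
                    "fecundity": _fmt(rs.fecundity.mean, rs.fecundity.se, nd),
                }
            )
        repro_table = pd.DataFrame(rows)

        rows = []
        for lab in labels:
            dp = params[lab]
            row = {"treatment": lab, "n01": cohorts[lab].n01}
            for p, value in zip(_TABLE4_PARAMS, (dp.r0, dp.r, dp.lam, dp.t)):
                se = boots[lab][p].se
                cell = _fmt(value, se, nd)
                if p in letters:
                    cell += letters[p].get(lab, "")
                row[p] = cell
            rows.append(row)
        demo_table = pd.DataFrame(rows)

        stage = "project"
        projections = {
            lab: project(scheds[lab], config.initial_eggs, config.horizon)
            for lab in labels
        }

        stage = "write"
        written["stages_table"] = outdir / "stage_durations_mortality.csv"
        stages_table.to_csv(written["stages_table"], index=False)
        written["reproductive_table"] = outdir / "reproductive_summaries.csv"
        repro_table.to_csv(written["reproductive_table"], index=False)
        written["demographic_table"] = outdir / "demographic_parameters.csv"
        demo_table.to_csv(written["demographic_table"], index=False)
        for lab in labels:
            p = outdir / f"schedules_{lab}.csv"
            scheds[lab].to_wide_frame().to_csv(p, index=False)
            written[f"schedules_{lab}"] = p
            p = outdir / f"schedules_{lab}_long.csv"
            scheds[lab].to_long_frame().to_csv(p, index=False)
            written[f"schedules_long_{lab}"] = p
            p = outdir / f"projection_{lab}.csv"
            projections[lab].to_frame().to_csv(p, index=False)
            written[f"projection_{lab}"] = p

        dump = {
            "version": _version,
            "config": {
                "B": config.b, "seed": config.seed, "level": config.level,
                "initial_eggs": config.initial_eggs, "horizon": config.horizon,
            },
            "treatments": {
                lab: {
                    "n01": cohorts[lab].n01,
                    "R0": params[lab].r0,
                    "r": params[lab].r,
                    "lambda": params[lab].lam,
                    "T": params[lab].t,
                    "euler_lotka_residual": params[lab].residual,
                    "bootstrap": {
                        p: {
                            "boot_mean": boots[lab][p].boot_mean,
                            "se": boots[lab][p].se,
                            "ci": list(boots[lab][p].ci),
                            "b_valid": boots[lab][p].b_valid,
                        }
                        for p in PARAMETERS
                    },
                    "final_population": float(projections[lab].totals[-1]),
                }
                for lab in labels
            },
            "pairwise_tests": [
                {
                    "parameter": t.parameter,
                    "treatments": list(t.treatments),
                    "difference": t.difference,
                    "ci": list(t.ci),
                    "significant": t.significant,
                }
                for t in tests
            ],
            "significance_letters": letters,
        }
        written["parameters_json"] = outdir / "parameters.json"
        written["parameters_json"].write_text(json.dumps(dump, indent=2))

        if config.plots:
            stage = "plots"
            written.update(_write_plots(outdir, scheds, projections))

        stage = "log"
        written["run_log"] = outdir / "run.log"
        written["run_log"].write_text(
            "twosexlt full analysis\n"
            f"version: {_version}\n"
            f"seed: {config.seed}\nB: {config.b}\nlevel: {config.level}\n"
            f"initial_eggs: {config.initial_eggs}\nhorizon: {config.horizon}\n"
            f"treatments: {', '.join(labels)}\n"
        )
        return written
    except Exception as exc:
        for p in written.values():
            if p.exists():
                p.unlink()
        raise RuntimeError(f"analysis failed in stage {stage!r}: {exc}") from exc


def _write_plots(outdir, scheds, projections) -> dict[str, Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = {}
    for lab, sch in scheds.items():
        fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(7, 7), sharex=True)
        for j, name in enumerate(sch.stage_names):
            ax1.plot(sch.s[:, j], label=name)
        ax1.set_ylabel("s_xj")
        ax1.legend(fontsize=7)
        ax2.plot(sch.l, label="l_x")
        ax2.plot(sch.m, label="m_x")
        ax2.plot(sch.f.max(axis=1), label="f_x,female")
        ax2.set_xlabel("age (days)")
        ax2.legend(fontsize=7)
        fig.suptitle(f"Schedules: {lab}")
        p = outdir / f"schedules_{lab}.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written[f"schedules_plot_{lab}"] = p

    fig, ax = plt.subplots(figsize=(7, 4.5))
    for lab, series in projections.items():
        ax.plot(series.totals, label=lab)
    ax.set_yscale("log")
    ax.set_xlabel("day")
    ax.set_ylabel("total population")
    ax.legend()
    p = outdir / "projection.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written["projection_plot"] = p
    return written
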