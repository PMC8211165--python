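"""End-to-end orchestration: simulate -> fit -> WBIC -> analyze -> report.

Stages are plain functions over in-memory objects so they can be run
separately (the CLI exposes them as subcommands) or composed by
:func:`run_pipeline`; both routes derive per-unit random streams from the
single run seed the same way, so the staged and one-shot paths produce
identical artifacts.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import analysis as ga
from .errors import ConfigurationError, DesignError
from .inference import (
    McmcSettings,
    ModelComparison,
    PriorSpec,
    compare_models,
    compute_wbic,
    fit_map,
)
from .qlearning import MODEL_ASYMMETRIC, MODEL_SIMPLE, SimpleParams
from .sessions import Session
from .synthetic import Dataset, GroupDesign, generate_dataset
from .task import TaskConfig
from . import io as gio

logger = logging.getLogger("groupbandit")

SIZE_LABELS = {1: "individual", 2: "dyad", 3: "triad"}

# Fixed stream tags so staged and one-shot runs consume identical substreams.
_STREAM_SIMULATE = 0
_STREAM_FIT = 1
_STREAM_WBIC = 2

_MODEL_PREFIX = {MODEL_SIMPLE: "simple", MODEL_ASYMMETRIC: "asym"}


@dataclasses.dataclass
class RunConfig:
    """Everything a reproducible run needs."""

    design: GroupDesign = dataclasses.field(default_factory=GroupDesign)
    priors: PriorSpec = dataclasses.field(default_factory=PriorSpec)
    mcmc: McmcSettings = dataclasses.field(default_factory=McmcSettings)
    models: tuple[str, ...] = (MODEL_SIMPLE, MODEL_ASYMMETRIC)
    n_restarts: int = 10
    run_wbic: bool = True
    regression_specs: tuple[str, ...] = ga.REGRESSION_SPECS
    paired_contrasts: bool = False
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self) -> None:
        self.models = tuple(self.models)
        self.regression_specs = tuple(self.regression_specs)
        self.design.seed = int(self.seed)

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        d = dict(d)
        design_d = dict(d.pop("design", {}))
        if "task" in d:
            design_d["task"] = d.pop("task")
        if isinstance(design_d.get("task"), Mapping):
            design_d["task"] = TaskConfig.from_dict(design_d["task"])
        if isinstance(design_d.get("population"), Mapping):
            from .synthetic import PopulationSpec

            design_d["population"] = PopulationSpec(**design_d["population"])
        kwargs: dict = {"design": GroupDesign(**design_d)}
        if "priors" in d:
            kwargs["priors"] = PriorSpec(**d.pop("priors"))
        if "mcmc" in d:
            kwargs["mcmc"] = McmcSettings(**d.pop("mcmc"))
        fitting = d.pop("fitting", {})
        if "n_restarts" in fitting:
            kwargs["n_restarts"] = int(fitting["n_restarts"])
        analysis_opts = d.pop("analysis", {})
        for key in ("run_wbic", "regression_specs", "paired_contrasts", "models"):
            if key in analysis_opts:
                kwargs[key] = analysis_opts[key]
        for key in ("seed", "outdir", "models", "n_restarts"):
            if key in d:
                kwargs[key] = d.pop(key)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, Mapping):
            raise ConfigurationError(f"config file {path} must hold a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "outdir": self.outdir,
            "models": list(self.models),
            "design": {
                **{
                    k: getattr(self.design, k)
                    for k in (
                        "n_individual_sessions",
                        "n_dyads",
                        "n_triads",
                        "membership_overlap",
                        "model_id",
                        "shared_updates",
                    )
                },
                "coherence": dict(self.design.coherence),
                "population": dataclasses.asdict(self.design.population),
                "task": self.design.task.to_dict(),
            },
            "priors": dataclasses.asdict(self.priors),
            "mcmc": dataclasses.asdict(self.mcmc),
            "fitting": {"n_restarts": self.n_restarts},
            "analysis": {
                "run_wbic": self.run_wbic,
                "regression_specs": list(self.regression_specs),
                "paired_contrasts": self.paired_contrasts,
            },
        }

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def _unit_rng(seed: int, stream: int, unit_index: int, model_index: int = 0):
    return np.random.default_rng([int(seed), stream, unit_index, model_index])


def simulate_stage(config: RunConfig) -> Dataset:
    """Generate the synthetic dataset the config's design describes."""
    t0 = time.perf_counter()
    dataset = generate_dataset(
        config.design, rng=np.random.default_rng([int(config.seed), _STREAM_SIMULATE])
    )
    logger.info(
        "simulate: %d sessions (%d members) in %.2fs",
        len(dataset),
        len(dataset.members),
        time.perf_counter() - t0,
    )
    return dataset


def _fit_row(session: Session, model: str, result) -> dict:
    p = result.map_params
    row = {
        "unit_id": session.unit_id,
        "size": session.size,
        "model": model,
        "alpha": np.nan,
        "alpha_plus": np.nan,
        "alpha_minus": np.nan,
        "pos_bias": np.nan,
        "beta": p.beta,
        "phi": np.nan,
        "log_posterior": result.log_posterior,
        "log_likelihood": result.log_likelihood,
        "converged": result.converged,
        "best_restart_index": result.best_restart_index,
    }
    if isinstance(p, SimpleParams):
        row["alpha"] = p.alpha
    else:
        row.update(
            alpha_plus=p.alpha_plus,
            alpha_minus=p.alpha_minus,
            pos_bias=p.positivity_bias,
            phi=p.phi,
        )
    return row


def fit_stage(sessions: Sequence[Session], config: RunConfig) -> pd.DataFrame:
    """MAP-fit every session under every configured model."""
    t0 = time.perf_counter()
    rows = []
    for i, session in enumerate(sessions):
        for mi, model in enumerate(config.models):
            result = fit_map(
                session,
                model_id=model,
                priors=config.priors,
                n_restarts=config.n_restarts,
                rng=_unit_rng(config.seed, _STREAM_FIT, i, mi),
            )
            rows.append(_fit_row(session, model, result))
    frame = pd.DataFrame(rows)
    frame["seed"] = config.seed
    logger.info(
        "fit: %d fits (%d sessions x %d models) in %.2fs",
        len(frame),
        len(sessions),
        len(config.models),
        time.perf_counter() - t0,
    )
    return frame


def wbic_stage(
    sessions: Sequence[Session], config: RunConfig
) -> tuple[pd.DataFrame, ModelComparison | None]:
    """Compute per-session WBIC for every configured model."""
    t0 = time.perf_counter()
    rows = []
    for i, session in enumerate(sessions):
        for mi, model in enumerate(config.models):
            res = compute_wbic(
                session,
                model_id=model,
                priors=config.priors,
                mcmc=config.mcmc,
                rng=_unit_rng(config.seed, _STREAM_WBIC, i, mi),
            )
            rows.append(
                {
                    "unit_id": session.unit_id,
                    "size": session.size,
                    "model": model,
                    "wbic": res.wbic,
                    "temperature": res.temperature,
                    "acceptance_rate": res.acceptance_rate,
                }
            )
    frame = pd.DataFrame(rows)
    frame["seed"] = config.seed
    comparison = None
    if {MODEL_SIMPLE, MODEL_ASYMMETRIC}.issubset(config.models) and len(frame):
        comparison = compare_models(
            frame.loc[frame["model"] == MODEL_SIMPLE, "wbic"].to_numpy(),
            frame.loc[frame["model"] == MODEL_ASYMMETRIC, "wbic"].to_numpy(),
        )
    logger.info("wbic: %d chains in %.2fs", len(frame), time.perf_counter() - t0)
    return frame, comparison


#: Unit-table quantities eligible for member max/min/mean aggregation.
_AGGREGATE_QUANTITIES = (
    "performance",
    "simple_alpha",
    "simple_beta",
    "asym_pos_bias",
    "asym_beta",
)


def build_unit_table(sessions: Sequence[Session], fits: pd.DataFrame) -> pd.DataFrame:
    """One row per unit: performance, fitted parameters, member aggregates.

    Member aggregates (max / min / mean over group members' *individual*
    sessions) are defined only for units of size >= 2 whose members have
    individual records; elsewhere they are NaN.
    """
    base = pd.DataFrame(
        {
            "unit_id": [s.unit_id for s in sessions],
            "size": [s.size for s in sessions],
            "test_id": [s.test_id for s in sessions],
            "performance": [s.performance for s in sessions],
        }
    )
    table = base
    for model, prefix in _MODEL_PREFIX.items():
        sub = fits[fits["model"] == model]
        if sub.empty:
            continue
        cols = ["alpha", "beta"] if model == MODEL_SIMPLE else [
            "alpha_plus",
            "alpha_minus",
            "pos_bias",
            "beta",
            "phi",
        ]
        renamed = sub[["unit_id", *cols, "log_posterior"]].rename(
            columns={c: f"{prefix}_{c}" for c in (*cols, "log_posterior")}
        )
        table = table.merge(renamed, on="unit_id", how="left")

    # Map each member to their individual-session unit row.
    member_unit: dict[str, str] = {}
    for s in sessions:
        if s.size == 1 and s.member_ids:
            member_unit.setdefault(s.member_ids[0], s.unit_id)
    indexed = table.set_index("unit_id")
    member_rows = {s.unit_id: s.member_ids for s in sessions}
    for qty in _AGGREGATE_QUANTITIES:
        if qty not in table.columns:
            continue
        maxs, mins, means = [], [], []
        for s in sessions:
            vals = [
                indexed.at[member_unit[m], qty]
                for m in member_rows[s.unit_id]
                if m in member_unit
            ]
            vals = [v for v in vals if pd.notna(v)]
            if s.size >= 2 and vals:
                maxs.append(max(vals))
                mins.append(min(vals))
                means.append(sum(vals) / len(vals))
            else:
                maxs.append(np.nan)
                mins.append(np.nan)
                means.append(np.nan)
        table[f"member_{qty}_max"] = maxs
        table[f"member_{qty}_min"] = mins
        table[f"member_{qty}_mean"] = means
    return table


def _render(frame: pd.DataFrame) -> str:
    """Fixed-width text rendering inside a Markdown code fence."""
    return "```\n" + frame.to_string(index=False) + "\n```"


@dataclasses.dataclass
class AnalysisReport:
    """Tidy result tables plus a Markdown rendering."""

    descriptives: pd.DataFrame
    tests: pd.DataFrame
    contrasts: pd.DataFrame
    regressions: pd.DataFrame
    model_comparison: pd.DataFrame
    seed: int

    def to_markdown(self) -> str:
        lines = [
            "# Group learning analysis report",
            "",
            f"Run seed: {self.seed}",
            "",
            "## Descriptive statistics by group size",
            "",
            _render(self.descriptives),
            "",
            "## Omnibus, pairwise, and positivity-bias tests",
            "",
            _render(self.tests),
            "",
            "## Within-group contrasts (group value vs member aggregate)",
            "",
            _render(self.contrasts)
            if len(self.contrasts)
            else "(no group units with member individual sessions)",
            "",
            "## Poisson regressions of performance (identity link)",
            "",
            _render(self.regressions)
            if len(self.regressions)
            else "(no regressions run)",
            "",
            "## Model comparison (WBIC)",
            "",
            _render(self.model_comparison)
            if len(self.model_comparison)
            else "(WBIC stage not run)",
            "",
        ]
        return "\n".join(lines)


_ANALYSIS_VARIABLES = (
    ("performance", "performance"),
    ("simple_alpha", "alpha (simple)"),
    ("simple_beta", "beta (simple)"),
    ("asym_pos_bias", "alpha+ - alpha- (asymmetric)"),
    ("asym_beta", "beta (asymmetric)"),
    ("asym_phi", "phi (asymmetric)"),
)


def analyze_stage(
    unit_table: pd.DataFrame,
    config: RunConfig,
    comparison: ModelComparison | None = None,
) -> AnalysisReport:
    """Run the full statistical battery on a unit table."""
    sizes_present = sorted(unit_table["size"].unique())

    desc_rows = []
    for col, label in _ANALYSIS_VARIABLES:
        if col not in unit_table.columns:
            continue
        row = {"variable": label}
        for size in sizes_present:
            vals = unit_table.loc[unit_table["size"] == size, col].dropna()
            row[f"{SIZE_LABELS[size]}_mean"] = vals.mean() if len(vals) else np.nan
            row[f"{SIZE_LABELS[size]}_sd"] = vals.std(ddof=1) if len(vals) > 1 else np.nan
            row[f"{SIZE_LABELS[size]}_n"] = len(vals)
        desc_rows.append(row)
    descriptives = pd.DataFrame(desc_rows)

    test_rows = []
    if len(sizes_present) >= 2:
        for col, label in _ANALYSIS_VARIABLES:
            if col not in unit_table.columns:
                continue
            samples = {
                SIZE_LABELS[size]: unit_table.loc[unit_table["size"] == size, col].dropna()
                for size in sizes_present
            }
            samples = {k: v for k, v in samples.items() if len(v)}
            if len(samples) < 2:
                continue
            kw = ga.kruskal_wallis(samples)
            test_rows.append(_test_row(label, kw))
            for t in ga.pairwise_wilcoxon_bonferroni(samples):
                test_rows.append(_test_row(label, t))
    if "asym_pos_bias" in unit_table.columns:
        for size in sizes_present:
            vals = unit_table.loc[unit_table["size"] == size, "asym_pos_bias"].dropna()
            if len(vals):
                t = ga.positivity_bias_test(vals)
                test_rows.append(
                    _test_row(f"alpha+ - alpha- ({SIZE_LABELS[size]}s)", t)
                )
    tests = pd.DataFrame(test_rows)

    contrast_rows = []
    for size in (2, 3):
        sub = unit_table[unit_table["size"] == size]
        if sub.empty:
            continue
        for qty in _AGGREGATE_QUANTITIES:
            if qty not in unit_table.columns:
                continue
            for agg in ("max", "min", "mean"):
                col = f"member_{qty}_{agg}"
                if col not in sub.columns:
                    continue
                paired = sub[[qty, col]].dropna()
                if len(paired) < 2:
                    continue
                t = ga.within_group_contrast(
                    paired[qty],
                    paired[col],
                    paired=config.paired_contrasts,
                    name=f"{qty}_vs_member_{agg}",
                )
                contrast_rows.append(
                    {
                        "size": SIZE_LABELS[size],
                        "variable": qty,
                        "aggregate": agg,
                        "statistic": t.statistic,
                        "df": t.df,
                        "p": t.p_raw,
                        "direction": t.direction,
                        "n": len(paired),
                    }
                )
    contrasts = pd.DataFrame(contrast_rows)

    reg_rows = []
    for model in config.models:
        prefix = _MODEL_PREFIX[model]
        covs = (
            {"alpha": f"{prefix}_alpha", "beta": f"{prefix}_beta"}
            if model == MODEL_SIMPLE
            else {
                "pos_bias": f"{prefix}_pos_bias",
                "beta": f"{prefix}_beta",
                "phi": f"{prefix}_phi",
            }
        )
        if not set(covs.values()).issubset(unit_table.columns):
            continue
        records = unit_table[["performance", "size", *covs.values()]].rename(
            columns={v: k for k, v in covs.items()}
        ).dropna()
        if records.empty:
            continue
        for spec in config.regression_specs:
            try:
                table = ga.poisson_regression(records, spec=spec, model_id=model)
            except DesignError as exc:
                logger.warning("regression %s/%s skipped: %s", model, spec, exc)
                continue
            for term, r in table.params.iterrows():
                reg_rows.append(
                    {
                        "model": model,
                        "spec": spec,
                        "term": term,
                        "estimate": r["estimate"],
                        "se": r["se"],
                        "z": r["z"],
                        "p": r["p"],
                        "aic": table.aic,
                        "n": table.n,
                    }
                )
    regressions = pd.DataFrame(reg_rows)

    if comparison is not None:
        model_comparison = pd.DataFrame(
            [
                {
                    "mean_wbic_simple": comparison.mean_simple,
                    "mean_wbic_asymmetric": comparison.mean_asymmetric,
                    "t": comparison.statistic,
                    "df": comparison.df,
                    "p": comparison.p_value,
                }
            ]
        )
    else:
        model_comparison = pd.DataFrame()

    return AnalysisReport(
        descriptives=descriptives,
        tests=tests,
        contrasts=contrasts,
        regressions=regressions,
        model_comparison=model_comparison,
        seed=config.seed,
    )


def _test_row(variable: str, t: ga.TestSummary) -> dict:
    return {
        "variable": variable,
        "test": t.name,
        "comparison": " vs ".join(t.comparison) if t.comparison else "omnibus",
        "statistic": t.statistic,
        "df": t.df,
        "p_raw": t.p_raw,
        "p_adjusted": t.p_adjusted,
        "direction": t.direction,
    }


@dataclasses.dataclass
class PipelineResult:
    dataset: Dataset | None
    sessions: list[Session]
    fits: pd.DataFrame
    wbic: pd.DataFrame | None
    unit_table: pd.DataFrame
    report: AnalysisReport


def _write_table(frame: pd.DataFrame, path: Path, seed: int) -> None:
    out = frame.copy()
    if "seed" not in out.columns:
        out["seed"] = seed
    out.to_csv(path, index=False)


def run_pipeline(
    config: RunConfig,
    outdir: str | Path | None = None,
    sessions: Sequence[Session] | None = None,
) -> PipelineResult:
    """Run every stage and (optionally) write all artifacts to ``outdir``.

    Identical config + seed produce byte-identical tables and report.
    ``sessions`` may be supplied to analyze externally loaded data instead
    of generating synthetic sessions.
    """
    outdir = Path(outdir or config.outdir) if (outdir or config.outdir) else None
    handler = None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
        handler = logging.FileHandler(outdir / "pipeline.log", mode="w")
        handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)
    try:
        import groupbandit

        logger.info(
            "run: seed=%d groupbandit=%s numpy=%s",
            config.seed,
            groupbandit.__version__,
            np.__version__,
        )
        dataset = None
        if sessions is None:
            dataset = simulate_stage(config)
            sessions = dataset.sessions
        sessions = list(sessions)
        fits = fit_stage(sessions, config)
        wbic_frame, comparison = (None, None)
        if config.run_wbic:
            wbic_frame, comparison = wbic_stage(sessions, config)
        unit_table = build_unit_table(sessions, fits)
        report = analyze_stage(unit_table, config, comparison)

        if outdir is not None:
            gio.write_sessions(sessions, outdir / "sessions.csv")
            gio.write_units(sessions, outdir / "units.csv")
            if dataset is not None:
                gio.write_ground_truth(dataset, outdir / "ground_truth.csv")
            _write_table(fits, outdir / "fits.csv", config.seed)
            if wbic_frame is not None:
                _write_table(wbic_frame, outdir / "wbic.csv", config.seed)
            _write_table(unit_table, outdir / "unit_table.csv", config.seed)
            _write_table(report.descriptives, outdir / "descriptives.csv", config.seed)
            _write_table(report.tests, outdir / "tests.csv", config.seed)
            _write_table(report.contrasts, outdir / "contrasts.csv", config.seed)
            _write_table(report.regressions, outdir / "regressions.csv", config.seed)
            _write_table(
                report.model_comparison, outdir / "model_comparison.csv", config.seed
            )
            (outdir / "report.md").write_text(report.to_markdown())
            config.to_yaml(outdir / "config.yaml")
            logger.info("artifacts written to %s", outdir)
        return PipelineResult(
            dataset=dataset,
            sessions=sessions,
            fits=fits,
            wbic=wbic_frame,
            unit_table=unit_table,
            report=report,
        )
    finally:
        if handler is not None:
            logger.removeHandler(handler)
            handler.close()
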