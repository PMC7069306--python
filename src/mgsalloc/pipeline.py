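"""End-to-end orchestration: simulate/load -> graph -> allocate -> fit -> report.

`run_analysis` is the single entry point for both real CSV data and
synthetic populations; `run_recovery` wraps replicated simulate+analyze
runs into a parameter-recovery summary (bias and Wald-interval coverage
per coefficient), the standard desk check that the fitting machinery
returns what the generator put in.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from mgsalloc.io import (
    IndividualRecord,
    StudyConfig,
    read_individuals,
    write_individuals,
    validate_records,
)
from mgsalloc.graph import (
    build_mating_graph,
    compute_mgs,
    apply_inclusion_filter,
    write_mgs_csv,
)
from mgsalloc.allocation import (
    build_analysis_table,
    penis_fraction_of_male_output,
    FilterCounts,
)
from mgsalloc.inference import (
    PREDICTORS,
    RESPONSES,
    LMMFit,
    fit_lmm,
    vif,
    lrt_drop_predictor,
    marginal_line,
)
from mgsalloc.simulate import GeneratorConfig, generate_population


class PipelineError(RuntimeError):
    """A stage-labelled failure inside run_analysis."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"[{stage}] {original}")
        self.stage = stage
        self.original = original


@dataclass
class RunReport:
    """Everything one analysis run produced, ready for serialization."""

    fits: dict[str, LMMFit]
    vifs: dict[str, float]
    lrts: dict[str, tuple[float, int, float]]  # response -> (chi2, df, p)
    marginal_lines: dict[str, tuple[float, float]]  # vary -> (slope, intercept)
    descriptives: dict[str, tuple[float, float]]  # quantity -> (min, max)
    mean_penis_fraction_pct: float
    counts: FilterCounts
    n_shells: int
    seed: int
    config: StudyConfig
    log: list[str] = field(default_factory=list)


def _log(report_log: list[str], msg: str) -> None:
    report_log.append(f"[{time.strftime('%H:%M:%S')}] {msg}")


def run_analysis(
    source: "str | Path | Sequence[IndividualRecord] | GeneratorConfig",
    config: StudyConfig | None = None,
    out_dir: "str | Path | None" = None,
) -> RunReport:
    """Run the full pipeline on a CSV path, records, or a generator config.

    Deterministic given data + config + seed. When ``out_dir`` is set,
    writes the individuals CSV (for generated data), analysis table, MGS
    table, edge list, model report, marginal-line data and a run log.
    """
    config = config or StudyConfig()
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    log: list[str] = []

    # --- stage: input -------------------------------------------------
    truth = None
    try:
        if isinstance(source, GeneratorConfig):
            records, truth = generate_population(source)
            _log(log, f"generated {len(records)} individuals "
                      f"on {source.n_shells} shells (seed {source.seed})")
        elif isinstance(source, (str, Path)):
            records = read_individuals(source, config)
            _log(log, f"read {len(records)} individuals from {source}")
        else:
            records = list(source)
            _log(log, f"received {len(records)} in-memory records")
        report = validate_records(records)
        if not report.ok:
            raise ValueError(str(report))
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError("input", e) from e

    # --- stage: graph -------------------------------------------------
    try:
        graph = build_mating_graph(records, config)
        mgs_records = compute_mgs(graph)
        flags = apply_inclusion_filter(records, mgs_records, config)
        _log(log, f"built reach graph: {graph.n_edges} directed edges "
                  f"over {len(graph.nodes)} shells")
    except Exception as e:
        raise PipelineError("graph", e) from e

    # --- stage: allocation ---------------------------------------------
    try:
        table, counts = build_analysis_table(
            records, mgs_records, config, return_counts=True
        )
        _log(log, f"analysis table: {counts.n_analyzed} of {counts.n_input} "
                  f"individuals ({counts.n_excluded_isolated} isolated, "
                  f"{counts.n_excluded_missing_organ} missing organs)")
    except Exception as e:
        raise PipelineError("allocation", e) from e

    # --- stage: inference ----------------------------------------------
    try:
        fits = {resp: fit_lmm(table, resp) for resp in RESPONSES}
        vifs = vif(table, PREDICTORS)
        lrts = {resp: lrt_drop_predictor(table, resp, "mgs_f") for resp in RESPONSES}
        body_mean = float(table["body_weight"].mean())
        mgs_mode = int(
            pd.concat([table["mgs_m"], table["mgs_f"]]).mode().iloc[0]
        )
        alloc_fit = fits["sex_allocation"]
        lines = {
            "mgs_m": marginal_line(
                alloc_fit, "mgs_m", {"mgs_f": mgs_mode, "body_weight": body_mean}
            ),
            "mgs_f": marginal_line(
                alloc_fit, "mgs_f", {"mgs_m": mgs_mode, "body_weight": body_mean}
            ),
        }
        _log(log, "fitted 4 response models (REML), VIFs "
                  + ", ".join(f"{k}={v:.3g}" for k, v in vifs.items()))
        for resp, (chi2, df, p) in lrts.items():
            _log(log, f"LRT drop MGSf from {resp}: chi2={chi2:.3f} df={df} p={p:.3g}")
    except Exception as e:
        raise PipelineError("inference", e) from e

    # --- stage: report ---------------------------------------------------
    incl = table
    descriptives = {
        "penis_length_cm": (min(r.penis_length for r in records),
                            max(r.penis_length for r in records)),
        "operculum_weight_mg": (float(incl["body_weight"].min()),
                                float(incl["body_weight"].max())),
        "testis_sv_weight_mg": (float(incl["male_variable"].min()),
                                float(incl["male_variable"].max())),
        "penis_weight_mg": (float(incl["male_fixed"].min()),
                            float(incl["male_fixed"].max())),
        "ovary_weight_mg": (float(incl["female_variable"].min()),
                            float(incl["female_variable"].max())),
        "mgs_m": (int(incl["mgs_m"].min()), int(incl["mgs_m"].max())),
        "mgs_f": (int(incl["mgs_f"].min()), int(incl["mgs_f"].max())),
    }
    fractions = [
        penis_fraction_of_male_output(row.male_fixed, row.male_variable)
        for row in incl.itertuples()
    ]
    mean_fraction = float(np.mean(fractions))
    _log(log, f"mean penis fraction of total male output: {mean_fraction:.3f}%")

    report = RunReport(
        fits=fits,
        vifs=vifs,
        lrts=lrts,
        marginal_lines={k: (v.slope, v.intercept) for k, v in lines.items()},
        descriptives=descriptives,
        mean_penis_fraction_pct=mean_fraction,
        counts=counts,
        n_shells=len(graph.nodes),
        seed=config.seed,
        config=config,
        log=log,
    )

    if out is not None:
        if isinstance(source, GeneratorConfig):
            write_individuals(records, out / "individuals.csv")
            truth.to_json(out / "truth.json")
        table.to_csv(out / "analysis_table.csv", index=False)
        write_mgs_csv(mgs_records, flags, out / "mgs.csv")
        graph.write_edge_list(out / "edges.csv")
        _write_model_report(report, out / "model_report.csv")
        _write_marginal_lines(lines, out / "marginal_lines.csv")
        (out / "run_log.txt").write_text("\n".join(log) + "\n", encoding="utf-8")
    return report


def _write_model_report(report: RunReport, path: Path) -> None:
    rows = []
    for resp, fit in report.fits.items():
        for term in ["intercept", *fit.predictors]:
            rows.append(
                {
                    "response": resp,
                    "term": term,
                    "estimate": fit.params[term],
                    "se": fit.bse[term],
                    "p": fit.pvalues[term],
                    "criterion": fit.method,
                    "n_obs": fit.n_obs,
                    "n_shells": fit.n_groups,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def _write_marginal_lines(lines: dict, path: Path) -> None:
    rows = [
        {
            "vary": k,
            "slope": v.slope,
            "intercept": v.intercept,
            **{f"held_{p}": val for p, val in v.held.items()},
        }
        for k, v in lines.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


@dataclass
class RecoverySummary:
    """Replicated simulate+fit summary for one response model."""

    response: str
    replicates: int
    n_failed: int
    truth: dict[str, float]
    mean: dict[str, float]
    sd: dict[str, float]
    bias: dict[str, float]
    coverage: dict[str, float]  # share of replicates whose 95% Wald CI covers truth

    def as_frame(self) -> pd.DataFrame:
        terms = list(self.truth)
        return pd.DataFrame(
            {
                "term": terms,
                "truth": [self.truth[t] for t in terms],
                "mean": [self.mean[t] for t in terms],
                "sd": [self.sd[t] for t in terms],
                "bias": [self.bias[t] for t in terms],
                "coverage95": [self.coverage[t] for t in terms],
            }
        )


def run_recovery(
    gen_config: GeneratorConfig,
    replicates: int,
    response: str = "sex_allocation",
    study_config: StudyConfig | None = None,
) -> RecoverySummary:
    """Replicated parameter-recovery experiment.

    Each replicate re-generates a population (seed = master seed +
    replicate index), reruns graph/MGS/filter, and refits the response
    model; a replicate whose fit fails is recorded and skipped. Coverage
    counts 95% Wald intervals containing the generating value.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    study_config = study_config or StudyConfig(
        elongation_factor=gen_config.elongation_factor
    )
    coefs = gen_config.coefficient_sets[response]
    truth = {
        "intercept": coefs.intercept,
        "mgs_m": coefs.mgs_m,
        "mgs_f": coefs.mgs_f,
        "body_weight": coefs.body,
    }
    terms = list(truth)
    estimates: dict[str, list[float]] = {t: [] for t in terms}
    covered: dict[str, list[bool]] = {t: [] for t in terms}
    n_failed = 0
    from dataclasses import replace

    for i in range(replicates):
        cfg = replace(gen_config, seed=gen_config.seed + i)
        try:
            records, _ = generate_population(cfg)
            graph = build_mating_graph(records, study_config)
            mgs_records = compute_mgs(graph)
            table = build_analysis_table(records, mgs_records, study_config)
            fit = fit_lmm(table, response)
        except Exception as e:  # noqa: BLE001 - replicate-level resilience
            import warnings

            warnings.warn(f"replicate {i} failed and was skipped: {e}")
            n_failed += 1
            continue
        for t in terms:
            est, se = fit.params[t], fit.bse[t]
            estimates[t].append(est)
            covered[t].append(abs(est - truth[t]) <= 1.959963984540054 * se)

    n_ok = replicates - n_failed
    if n_ok == 0:
        raise RuntimeError("all recovery replicates failed")
    return RecoverySummary(
        response=response,
        replicates=replicates,
        n_failed=n_failed,
        truth=truth,
        mean={t: float(np.mean(estimates[t])) for t in terms},
        sd={t: float(np.std(estimates[t], ddof=1)) if n_ok > 1 else 0.0 for t in terms},
        bias={t: float(np.mean(estimates[t]) - truth[t]) for t in terms},
        coverage={t: float(np.mean(covered[t])) for t in terms},
    )
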