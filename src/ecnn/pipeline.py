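"""End-to-end pipeline: cross-validated training, feature ranking,
selection, and subset re-evaluation, with all results written to disk.

Ranking is computed from an ensemble trained on the training+validation
roles of the plan's first evaluation only, so the test role never informs
which features are selected; the selected subset is then re-evaluated with
the same cross-validation plan.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import EventMatrix, FoldPlan, make_cv_folds, normalize
from .config import TrainConfig
from .evaluation import CVResults, random_subset, run_cv
from .ranking import ImportanceReport, SelectionResult, apply_policy, importance_report
from .training import SnapshotEnsemble, train_snapshots

__all__ = ["PipelineResult", "rank_features", "run_pipeline"]


@dataclass
class PipelineResult:
    """Everything one pipeline run produces."""

    plan: FoldPlan
    report: ImportanceReport
    selection: SelectionResult
    subset_used: list[str]
    cv_full: CVResults
    cv_subset: CVResults
    cv_random: CVResults


def rank_features(
    dataset: EventMatrix,
    config: TrainConfig,
    plan: FoldPlan | None = None,
) -> tuple[ImportanceReport, SnapshotEnsemble]:
    """Train one snapshot ensemble on the first evaluation's training and
    validation roles and score every feature."""
    if dataset.labels is None:
        raise ValueError("dataset has no labels")
    if plan is None:
        plan = make_cv_folds(dataset.n_patients, config.cv_k, config.cv_repeats,
                             seed=config.seed)
    a = plan.assignments[0]
    fit_idx = np.sort(np.concatenate([a.train, a.validation]))
    X = dataset.dense()
    Xfit, _ = normalize(X[fit_idx])
    ensemble = train_snapshots(Xfit, np.asarray(dataset.labels)[fit_idx], config)
    return importance_report(ensemble, dataset.feature_names), ensemble


def _cv_to_dict(cv: CVResults) -> dict:
    return {
        "aggregate": {k: {"mean": v[0], "sd": v[1]} for k, v in cv.aggregate.items()},
        "n_degenerate": cv.n_degenerate,
        "per_evaluation": [
            {"repeat": rep, "fold": fold, **m.as_dict(),
             "counts": {"tp": m.tp, "fp": m.fp, "tn": m.tn, "fn": m.fn}}
            for rep, fold, m in cv.per_evaluation
        ],
    }


def run_pipeline(
    dataset: EventMatrix,
    config: TrainConfig,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Full-feature CV, ranking, selection, and subset/random re-evaluation.

    When the configured selection policy returns an empty set (possible for
    the outlier policy on signal-free data) the top-k policy is used for
    the subset re-evaluation so the comparison stays defined; the original
    empty selection is still reported.
    """
    plan = make_cv_folds(dataset.n_patients, config.cv_k, config.cv_repeats,
                         seed=config.seed)
    cv_full = run_cv(dataset, config, plan=plan)
    report, _ = rank_features(dataset, config, plan)
    selection = apply_policy(
        report, config.selection_policy,
        k=config.top_k, n_sigma=config.n_sigma, quantile=config.cumulative_quantile,
    )
    subset = selection.names
    if not subset:
        subset = apply_policy(report, "top_k", k=config.top_k).names
    cv_subset = run_cv(dataset, config, feature_subset=subset, plan=plan)
    rand_names = [dataset.feature_names[i]
                  for i in random_subset(dataset.n_features, len(subset), config.seed)]
    cv_random = run_cv(dataset, config, feature_subset=rand_names, plan=plan)

    result = PipelineResult(
        plan=plan, report=report, selection=selection, subset_used=subset,
        cv_full=cv_full, cv_subset=cv_subset, cv_random=cv_random,
    )
    if out_dir is not None:
        _write_outputs(result, dataset, config, Path(out_dir))
    return result


def _write_outputs(
    result: PipelineResult, dataset: EventMatrix, config: TrainConfig, out: Path
) -> None:
    out.mkdir(parents=True, exist_ok=True)

    (out / "cv_results.json").write_text(json.dumps({
        "full": _cv_to_dict(result.cv_full),
        "subset": _cv_to_dict(result.cv_subset),
        "random": _cv_to_dict(result.cv_random),
    }, indent=1))

    rep = result.report
    table = pd.DataFrame(
        rep.per_snapshot.T,
        columns=[f"snapshot_{i}" for i in range(rep.per_snapshot.shape[0])],
    )
    table.insert(0, "feature_name", rep.feature_names)
    table["aggregated"] = rep.aggregated
    table["category"] = rep.categories
    table.to_csv(out / "importance_report.tsv", sep="\t", index=False)

    (out / "selections.json").write_text(json.dumps({
        "policy": result.selection.policy,
        "parameters": result.selection.parameters,
        "selected": result.selection.selected,
        "subset_used": result.subset_used,
        "distribution_fit": {"mu": rep.distribution_fit[0],
                             "sigma": rep.distribution_fit[1]},
    }, indent=1))

    rows = []
    for label, cv in (("full", result.cv_full), ("selected", result.cv_subset),
                      ("random", result.cv_random)):
        row = {"subset": label,
               "n_features": {"full": dataset.n_features,
                              "selected": len(result.subset_used),
                              "random": len(result.subset_used)}[label]}
        for metric, (mean, sd) in cv.aggregate.items():
            row[metric] = f"{mean:.4f} ({sd:.4f})"
        rows.append(row)
    pd.DataFrame(rows).to_csv(out / "comparison_table.tsv", sep="\t", index=False)

    (out / "manifest.json").write_text(json.dumps({
        "version": __version__,
        "config": config.to_dict(flag_provenance=True),
        "seed": config.seed,
        "n_patients": dataset.n_patients,
        "n_features": dataset.n_features,
    }, indent=1))
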