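"""End-to-end orchestration: recording -> features -> selection -> screening.

``analyze_recording`` runs the image pipeline for a single recording and
``run_all`` reproduces the cohort analysis: per-infant features with
quality control, risk grouping from the questionnaire, Brunner-Munzel
feature selection with correlation lumping, and leave-one-out evaluation
of the four classifiers.  Every run writes a manifest (config digest,
seed, library versions) sufficient to reproduce the outputs bit-exactly.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import ClassifierSpec, CVResult, loo_evaluate, nested_tune
from .config import RunConfig, DEFAULTS
from .features import FEATURE_NAMES, FeatureVector, extract_all, qc_filter
from .kinematics import compute_motion_series
from .mchat import N_ITEMS, score_table
from .preprocessing import FrameStack, split_subsegments
from .regions import compute_regions
from .stats import SelectionOutcome, run_selection

log = logging.getLogger(__name__)


def analyze_recording(stack: FrameStack, config: RunConfig = DEFAULTS
                      ) -> tuple[FeatureVector, float]:
    """Image pipeline for one recording: masks, regions, motion, features.

    Returns the feature vector and the analysable duration in seconds
    (retained frames only).
    """
    masks = split_subsegments(stack, config)
    regions = compute_regions(masks, config)
    motion = compute_motion_series(masks, regions, config)
    fv = extract_all(motion, config, source_id=stack.source_id)
    return fv, masks.duration_s


@dataclass
class CohortReport:
    features: pd.DataFrame          # kept infants x 26 features
    qc_log: pd.DataFrame            # all infants: kept flag + reason
    labels: np.ndarray              # 1 = high risk
    selection: SelectionOutcome
    results: dict[str, CVResult]    # per classifier kind
    manifest: dict


def _classify_all(predictors: pd.DataFrame, labels: np.ndarray,
                  config: RunConfig, models=("lda", "lr", "mlp", "llgmn"),
                  epochs: int = 400) -> dict[str, CVResult]:
    X = predictors.to_numpy(float)
    ids = np.arange(len(labels))
    results: dict[str, CVResult] = {}
    for kind in models:
        log.info("evaluating %s under leave-one-out", kind)
        if kind in ("mlp", "llgmn"):
            grid = (config.mlp_hidden_grid if kind == "mlp"
                    else config.llgmn_components_grid)
            results[kind] = nested_tune(
                kind, grid, X, labels, sample_ids=ids, seed=config.seed,
                repetitions=config.tuning_repetitions, epochs=epochs,
                threshold=config.decision_threshold)
        else:
            results[kind] = loo_evaluate(
                ClassifierSpec(kind, seed=config.seed), X, labels,
                sample_ids=ids, threshold=config.decision_threshold)
    return results


def _manifest(config: RunConfig) -> dict:
    import scipy
    import sklearn
    return {
        "package_version": __version__,
        "config": config.to_dict(),
        "config_digest": config.digest(),
        "seed": config.seed,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "sklearn": sklearn.__version__,
    }


def run_cohort_analysis(features: pd.DataFrame, labels: np.ndarray,
                        config: RunConfig = DEFAULTS,
                        models=("lda", "lr", "mlp", "llgmn"),
                        epochs: int = 400) -> tuple[SelectionOutcome,
                                                    dict[str, CVResult]]:
    """Selection plus classification on an assembled feature matrix."""
    selection = run_selection(features[list(FEATURE_NAMES)], labels,
                              alpha=config.retention_alpha,
                              lump_r=config.lump_r)
    if selection.predictors.shape[1] == 0:
        raise ValueError("feature selection retained nothing; cannot classify")
    results = _classify_all(selection.predictors, labels, config, models,
                            epochs=epochs)
    return selection, results


def run_all(config: RunConfig = DEFAULTS, *,
            cohort_csv: str | Path | None = None,
            recordings_dir: str | Path | None = None,
            mchat_csv: str | Path | None = None,
            out_dir: str | Path | None = None,
            models=("lda", "lr", "mlp", "llgmn"),
            epochs: int = 400) -> CohortReport:
    """Full cohort run from either recordings or a prepared cohort table.

    Recording mode expects ``recordings_dir`` with one sub-directory per
    infant (PNG frames + background + exclusion) and an ``mchat_csv`` with
    ``infant_id, item1..item23``.  Cohort mode expects a single CSV with
    the 26 feature columns, the 23 item columns and an ``infant_id``
    column (the format written by the cohort simulator).
    """
    if (cohort_csv is None) == (recordings_dir is None):
        raise ValueError("provide exactly one of cohort_csv or recordings_dir")

    if cohort_csv is not None:
        df = pd.read_csv(cohort_csv, index_col="infant_id")
        features = df[list(FEATURE_NAMES)].copy()
        items = df[[f"item{i}" for i in range(1, N_ITEMS + 1)]].copy()
        items.insert(0, "infant_id", items.index)
        qc_log = pd.DataFrame({"infant_id": features.index,
                               "kept": True, "reason": ""})
    else:
        from .io import read_recording
        rec_dirs = sorted(p for p in Path(recordings_dir).iterdir() if p.is_dir())
        if not rec_dirs:
            raise ValueError(f"no recordings under {recordings_dir}")
        rows, qc_rows = [], []
        for rec in rec_dirs:
            try:
                stack = read_recording(rec, fps=config.fps)
            except Exception as err:
                raise RuntimeError(
                    f"stage 'read' failed for infant {rec.name}: {err}"
                ) from err
            retained = sum(e - s for s, e in stack.retained_intervals())
            duration = retained / stack.fps
            # short recordings are discarded before feature extraction:
            # the reference windows need a minimum analyzable length
            if duration <= config.qc_min_duration_s:
                qc_rows.append({"infant_id": rec.name, "kept": False,
                                "reason": "short length",
                                "duration_s": duration, "I1_A7": np.nan})
                continue
            try:
                fv, duration = analyze_recording(stack, config)
            except Exception as err:
                raise RuntimeError(
                    f"stage 'features' failed for infant {rec.name}: {err}"
                ) from err
            keep, reason = qc_filter(duration, fv.i1_a7, config)
            qc_rows.append({"infant_id": rec.name, "kept": keep,
                            "reason": reason or "",
                            "duration_s": duration, "I1_A7": fv.i1_a7})
            if keep:
                s = fv.to_series()
                s.name = rec.name
                rows.append(s)
        qc_log = pd.DataFrame(qc_rows)
        if not rows:
            raise ValueError("all recordings discarded by quality control")
        features = pd.DataFrame(rows)[list(FEATURE_NAMES)]
        mdf = pd.read_csv(mchat_csv)
        items = mdf[mdf["infant_id"].astype(str).isin(features.index)]

    scored = score_table(items)
    scored = scored.set_index(items["infant_id"].astype(str)) \
        if "infant_id" in items.columns else scored
    scored = scored.loc[[str(i) for i in features.index]]
    labels = (scored["risk"] == "high").to_numpy().astype(int)

    selection, results = run_cohort_analysis(features, labels, config,
                                             models, epochs=epochs)
    report = CohortReport(features=features, qc_log=qc_log, labels=labels,
                          selection=selection, results=results,
                          manifest=_manifest(config))
    if out_dir is not None:
        write_report(report, out_dir)
    return report


def write_report(report: CohortReport, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.features.to_csv(out / "features.csv", index_label="infant_id")
    report.qc_log.to_csv(out / "qc_log.csv", index=False)
    sel = {
        "alpha": report.selection.alpha,
        "lump_r": report.selection.lump_r,
        "tests": {name: {"W": r.W, "df": r.df, "p": r.p, "p_hat": r.p_hat}
                  for name, r in report.selection.bm.items()},
        "retained": report.selection.retained,
        "groups": report.selection.groups,
        "predictors": report.selection.predictor_names,
    }
    with open(out / "selection.json", "w") as fh:
        json.dump(sel, fh, indent=2)
    mets = {}
    for kind, res in report.results.items():
        mets[kind] = {**res.metrics, "confusion": res.confusion}
        if res.tuned_mean is not None:
            mets[kind]["tuned_mean"] = res.tuned_mean
            mets[kind]["tuned_sd"] = res.tuned_sd
        pd.DataFrame({"y_true": res.y_true, "score": res.scores,
                      "label": res.labels.astype(int)}).to_csv(
            out / f"folds_{kind}.csv", index_label="fold")
    with open(out / "metrics.json", "w") as fh:
        json.dump(mets, fh, indent=2, sort_keys=True)
    with open(out / "manifest.json", "w") as fh:
        json.dump(report.manifest, fh, indent=2, sort_keys=True)
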