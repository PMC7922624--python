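"""Repeated k-fold cross-validation of genomic prediction accuracy.

Compares GBLUP models (SNP-only vs SNP+SV) on identical random partitions:
per fold, variance components are estimated on the training records (or
reused from a full-data fit when ``refit_vc=False``, the flagged speed
option), BLUP solutions are computed, validation individuals are predicted
through the GRM off-diagonals, and accuracy is the Pearson correlation
between predicted GEBV and the held-out phenotype (DTD). Results aggregate
as the mean over folds within a repeat, then mean and SE over repeats.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .imputeval import make_folds
from .mixedmodel import make_spec, reml_fit, solve_blup

log = logging.getLogger(__name__)


@dataclass
class CVScheme:
    k: int = 10
    repeats: int = 10
    seed: int = 0
    cohort: np.ndarray | None = None  # boolean mask or index array over individuals


@dataclass
class AccuracyReport:
    table: pd.DataFrame                      # model, mean_accuracy, se, n_repeats, k
    repeat_means: dict[str, np.ndarray]
    fold_accuracies: dict[str, np.ndarray]   # (repeats, k), NaN where skipped


def _partitions(scheme: CVScheme, n: int) -> list:
    return [make_folds(n, k=scheme.k, seed=scheme.seed + 1000 * r) for r in range(scheme.repeats)]


def run_cv(
    y,
    grms_by_model: dict[str, list[tuple[np.ndarray, str]]],
    scheme: CVScheme,
    covariates: np.ndarray | None = None,
    refit_vc: bool = True,
    vc_by_model: dict | None = None,
    min_validation: int = 10,
) -> AccuracyReport:
    """Evaluate each model on identical repeated k-fold partitions.

    ``grms_by_model`` maps a model label (e.g. ``"SNP"``, ``"SNP+SV"``) to
    its list of (GRM, component label) pairs over the full cohort. With
    ``refit_vc=False`` components come from ``vc_by_model`` or, failing
    that, a single full-data fit per model (flagged in the log). Folds with
    constant held-out phenotype are skipped; folds with fewer than
    ``min_validation`` records raise a warning.
    """
    y = np.asarray(y, dtype=float).ravel()
    if scheme.cohort is not None:
        cohort = np.asarray(scheme.cohort)
        idx_all = np.flatnonzero(cohort) if cohort.dtype == bool else cohort
    else:
        idx_all = np.arange(y.size)
    yc = y[idx_all]
    cov = None if covariates is None else np.atleast_2d(np.asarray(covariates, dtype=float))
    if cov is not None and cov.shape[0] != y.size:
        cov = cov.T
    covc = None if cov is None else cov[idx_all]
    grms_c = {
        model: [(np.asarray(g.matrix if hasattr(g, "matrix") else g)[np.ix_(idx_all, idx_all)], lab) for g, lab in pairs]
        for model, pairs in grms_by_model.items()
    }
    n = idx_all.size
    plans = _partitions(scheme, n)

    full_vc = {}
    if not refit_vc:
        if vc_by_model is not None:
            full_vc = dict(vc_by_model)
        else:
            log.info("reusing full-data variance components across folds (speed option)")
            for model, pairs in grms_c.items():
                spec = make_spec(yc, pairs, covariates=covc)
                full_vc[model] = reml_fit(spec)

    fold_acc = {m: np.full((scheme.repeats, scheme.k), np.nan) for m in grms_c}
    for r, plan in enumerate(plans):
        for fold in range(scheme.k):
            val = plan.test_indices(fold)
            train = plan.reference_indices(fold)
            if val.size < min_validation:
                warnings.warn(f"fold {fold} of repeat {r} has only {val.size} validation records")
            if np.std(yc[val]) == 0:
                log.info("repeat %d fold %d skipped: constant held-out phenotype", r, fold)
                continue
            for model, pairs in grms_c.items():
                spec = make_spec(
                    yc[train],
                    pairs,
                    covariates=None if covc is None else covc[train],
                    individual_idx=train,
                )
                vc = reml_fit(spec) if refit_vc else full_vc[model]
                sol = solve_blup(spec, vc)
                pred = sol.gebv[val]
                if np.std(pred) == 0:
                    continue
                fold_acc[model][r, fold] = float(np.corrcoef(pred, yc[val])[0, 1])

    rows = []
    repeat_means = {}
    for model in grms_c:
        rm = np.nanmean(fold_acc[model], axis=1)
        repeat_means[model] = rm
        se = float(np.std(rm, ddof=1) / np.sqrt(scheme.repeats)) if scheme.repeats > 1 else np.nan
        rows.append(
            {
                "model": model,
                "mean_accuracy": float(np.nanmean(rm)),
                "se": se,
                "n_repeats": scheme.repeats,
                "k": scheme.k,
            }
        )
    return AccuracyReport(table=pd.DataFrame(rows), repeat_means=repeat_means, fold_accuracies=fold_acc)
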