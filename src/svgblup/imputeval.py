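"""Masking-based cross-validation of SV imputation accuracy.

Individuals are split into k folds; in turn each fold's SV genotypes are
masked (coded 5) while its SNPs are kept, and a stand-in imputer predicts
the masked dosages from the reference (the other folds). The stand-in is a
least-squares regression of each SV's dosage on its ``w`` nearest flanking
SNP dosages, clipped to [0, 2] — a pluggable interface, so an external
phasing/imputation engine can be dropped in. Accuracy per SV is the squared
Pearson correlation between imputed dosage and true code over all masked
individuals pooled across folds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Protocol

import numpy as np
import pandas as pd

from .containers import MISSING, GenotypeMatrix
from .relmat import allele_frequencies
from .sv_catalog import SVRecord, _merge_pool

log = logging.getLogger(__name__)

ANCHOR_MODES = ("start", "middle", "end")


@dataclass
class FoldPlan:
    """Seeded k-fold partition; folds are disjoint, cover everyone and
    differ in size by at most one."""

    assignment: np.ndarray
    k: int
    seed: int

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == fold)

    def reference_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignment != fold)


def make_folds(n_or_ids, k: int = 5, seed: int = 0) -> FoldPlan:
    n = n_or_ids if isinstance(n_or_ids, (int, np.integer)) else len(n_or_ids)
    if k > n:
        raise ValueError(f"cannot split {n} individuals into {k} folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    assignment = np.empty(n, dtype=int)
    assignment[perm] = np.arange(n) % k
    return FoldPlan(assignment=assignment, k=k, seed=seed)


class Imputer(Protocol):
    """Anything that can fill masked SV dosages from a reference panel.

    An external phasing/imputation engine can be wrapped by implementing
    these two methods and passing the object to :func:`mask_and_impute`.
    """

    def select_snps(self, snp_map: pd.DataFrame, chrom: str, anchor_pos: int,
                    exclude: np.ndarray | None = None) -> np.ndarray: ...

    def impute_one(self, x_ref: np.ndarray, y_ref: np.ndarray,
                   x_test: np.ndarray) -> np.ndarray: ...


def _anchor_pos(row, anchor: str) -> int:
    if anchor == "start":
        return int(row.start)
    if anchor == "middle":
        return int((row.start + row.end) // 2)
    if anchor == "end":
        return int(row.end)
    raise ValueError(f"anchor must be one of {ANCHOR_MODES}")


def snps_in_interval(snp_map: pd.DataFrame, chrom: str, start: int, end: int) -> np.ndarray:
    """Indices of SNPs whose position lies inside [start, end)."""
    sel = (snp_map["chrom"] == chrom) & (snp_map["start"] >= start) & (snp_map["start"] < end)
    return np.flatnonzero(sel.to_numpy())


class FlankingSNPImputer:
    """Least-squares regression on the ``w`` nearest flanking SNPs.

    Nearest is by |SNP position - SV anchor| on the same chromosome, ties
    broken by lower genomic position. Reference rows where the SV call is
    missing are excluded from the fit; predictions are clipped to [0, 2].
    SVs with fewer than two usable flanking SNPs get NaN predictions.
    """

    def __init__(self, w: int = 20):
        self.w = w

    def select_snps(self, snp_map: pd.DataFrame, chrom: str, anchor_pos: int,
                    exclude: np.ndarray | None = None) -> np.ndarray:
        on_chrom = np.flatnonzero((snp_map["chrom"] == chrom).to_numpy())
        if exclude is not None and exclude.size:
            on_chrom = np.setdiff1d(on_chrom, exclude)
        pos = snp_map["start"].to_numpy()[on_chrom]
        d = np.abs(pos - anchor_pos)
        order = np.lexsort((pos, d))
        return on_chrom[order[: self.w]]

    def impute_one(self, x_ref: np.ndarray, y_ref: np.ndarray, x_test: np.ndarray) -> np.ndarray:
        ok = y_ref != MISSING
        if x_ref.shape[1] < 2 or ok.sum() < x_ref.shape[1] + 2:
            return np.full(x_test.shape[0], np.nan)
        A = np.column_stack([np.ones(int(ok.sum())), x_ref[ok]])
        coef, *_ = np.linalg.lstsq(A, y_ref[ok].astype(float), rcond=None)
        pred = np.column_stack([np.ones(x_test.shape[0]), x_test]) @ coef
        return np.clip(pred, 0.0, 2.0)


def mask_and_impute(
    snp_genotypes,
    sv_genotypes,
    snp_map: pd.DataFrame,
    sv_map: pd.DataFrame,
    test_individuals: np.ndarray,
    anchor: str = "start",
    exclude_snps_in_sv: bool = False,
    w: int = 20,
    imputer: FlankingSNPImputer | None = None,
) -> np.ndarray:
    """Impute every SV dosage of the test individuals from the reference.

    Test individuals keep their SNP genotypes; their SV genotypes are
    treated as masked (the reference never contains a test individual's SV
    genotypes, so there is no train/test leakage). With
    ``exclude_snps_in_sv`` the SNPs lying inside each SV's half-open
    interval are removed from that SV's scaffold. Returns a
    (n_test, n_sv) float array of imputed dosages.
    """
    if anchor not in ANCHOR_MODES:
        raise ValueError(f"anchor must be one of {ANCHOR_MODES}")
    snp_codes = snp_genotypes.codes if isinstance(snp_genotypes, GenotypeMatrix) else np.asarray(snp_genotypes)
    sv_codes = sv_genotypes.codes if isinstance(sv_genotypes, GenotypeMatrix) else np.asarray(sv_genotypes)
    test_individuals = np.asarray(test_individuals)
    ref = np.setdiff1d(np.arange(snp_codes.shape[0]), test_individuals)
    imp = imputer or FlankingSNPImputer(w=w)
    # mean-impute missing SNP calls on the dosage scale
    snp_d = snp_codes.astype(float)
    miss = snp_codes == MISSING
    if miss.any():
        snp_d[miss] = np.nan
        mu = np.nanmean(snp_d, axis=0)
        idx = np.where(miss)
        snp_d[idx] = np.where(np.isnan(mu[idx[1]]), 0.0, mu[idx[1]])
    out = np.empty((test_individuals.size, sv_codes.shape[1]))
    for j, row in enumerate(sv_map.itertuples()):
        excl = (
            snps_in_interval(snp_map, row.chrom, int(row.start), int(row.end))
            if exclude_snps_in_sv
            else None
        )
        cols = imp.select_snps(snp_map, row.chrom, _anchor_pos(row, anchor), exclude=excl)
        if cols.size < 2:
            out[:, j] = np.nan
            continue
        out[:, j] = imp.impute_one(
            snp_d[np.ix_(ref, cols)], sv_codes[ref, j], snp_d[np.ix_(test_individuals, cols)]
        )
    return out


def run_masking_cv(
    snp_genotypes,
    sv_genotypes,
    snp_map: pd.DataFrame,
    sv_map: pd.DataFrame,
    plan: FoldPlan,
    **kwargs,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Fivefold (or k-fold) masking CV over all individuals.

    Each fold is masked and imputed in turn; returns the full imputed
    dosage matrix (every individual imputed exactly once) and the per-SV
    accuracy table from :func:`accuracy_table`.
    """
    sv_codes = sv_genotypes.codes if isinstance(sv_genotypes, GenotypeMatrix) else np.asarray(sv_genotypes)
    imputed = np.full(sv_codes.shape, np.nan)
    for fold in range(plan.k):
        test = plan.test_indices(fold)
        imputed[test] = mask_and_impute(
            snp_genotypes, sv_genotypes, snp_map, sv_map, test, **kwargs
        )
    acc = accuracy_table(sv_codes, imputed, sv_ids=list(sv_map["id"]))
    return imputed, acc


def accuracy_table(
    true_codes: np.ndarray,
    imputed_dosages: np.ndarray,
    sv_ids: list[str] | None = None,
    plan: FoldPlan | None = None,
) -> pd.DataFrame:
    """Per-SV squared Pearson correlation of imputed dosage vs true code.

    Pooled over all masked individuals across folds. Rows with missing
    truth (code 5) or NaN prediction are excluded per SV; the accuracy is
    NA when either vector is constant. Note r^2 is sign-blind: a predictor
    equal to ``2 - true`` also scores 1. MAF is computed from the true codes.
    """
    true_codes = np.asarray(true_codes)
    imputed = np.asarray(imputed_dosages, dtype=float)
    if true_codes.shape != imputed.shape:
        raise ValueError("true and imputed matrices differ in shape")
    if plan is not None and plan.assignment.size != true_codes.shape[0]:
        raise ValueError("fold plan does not cover the individuals")
    freqs = allele_frequencies(true_codes)
    rows = []
    for j in range(true_codes.shape[1]):
        t = true_codes[:, j]
        x = imputed[:, j]
        ok = (t != MISSING) & np.isfinite(x)
        r2 = np.nan
        if ok.sum() >= 3:
            tv = t[ok].astype(float)
            xv = x[ok]
            if tv.std() > 0 and xv.std() > 0:
                r = np.corrcoef(tv, xv)[0, 1]
                r2 = r * r
        rows.append(
            {
                "sv_id": sv_ids[j] if sv_ids else f"sv{j}",
                "r2": r2,
                "maf": freqs.maf[j],
                "n_used": int(ok.sum()),
            }
        )
    return pd.DataFrame(rows)


def threshold_summary(acc_table: pd.DataFrame, thresholds=(0.5, 0.8)) -> pd.DataFrame:
    """Fraction (and percent) of SVs with accuracy strictly above each threshold.

    NA accuracies are excluded from the denominator; their count is reported.
    """
    if acc_table.empty:
        raise ValueError("empty accuracy table")
    r2 = acc_table["r2"].to_numpy(dtype=float)
    ok = np.isfinite(r2)
    rows = []
    for thr in thresholds:
        frac = float((r2[ok] > thr).mean()) if ok.any() else np.nan
        rows.append(
            {
                "threshold": thr,
                "fraction_above": frac,
                "percent_above": 100.0 * frac,
                "n_eval": int(ok.sum()),
                "n_na": int((~ok).sum()),
            }
        )
    return pd.DataFrame(rows)


def accuracy_by_maf(acc_table: pd.DataFrame, bins: np.ndarray | None = None) -> pd.DataFrame:
    """Mean accuracy per MAF bin (default width 0.05 on [0, 0.5])."""
    if bins is None:
        bins = np.round(np.arange(0.0, 0.55, 0.05), 10)
    bins = np.asarray(bins, dtype=float)
    maf = acc_table["maf"].to_numpy(dtype=float)
    r2 = acc_table["r2"].to_numpy(dtype=float)
    rows = []
    for lo, hi in zip(bins[:-1], bins[1:]):
        sel = (maf >= lo) & (maf < hi) & np.isfinite(r2)
        rows.append(
            {
                "maf_lo": lo,
                "maf_hi": hi,
                "mean_r2": float(r2[sel].mean()) if sel.any() else np.nan,
                "n": int(sel.sum()),
            }
        )
    return pd.DataFrame(rows)


def select_svs(acc_table: pd.DataFrame, min_r2: float = 0.5) -> list[str]:
    """IDs of SVs imputed with accuracy strictly above ``min_r2``."""
    r2 = acc_table["r2"].to_numpy(dtype=float)
    keep = np.isfinite(r2) & (r2 > min_r2)
    return list(acc_table["sv_id"].to_numpy()[keep])


def merge_selected_sets(record_sets: list[list[SVRecord]], min_overlap_bp: int = 1) -> list[SVRecord]:
    """Union of selected SV sets, merged across sets by >= 1 bp overlap."""
    pool: list[SVRecord] = [r for s in record_sets for r in s]
    if not pool:
        return []
    return _merge_pool(pool, min_overlap_bp=min_overlap_bp)
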