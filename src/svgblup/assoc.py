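"""Mixed-linear-model GWAS, multi-trait meta-analysis, FDR and LD windows.

Markers are tested one at a time by generalised least squares with the
record covariance V fixed at null-model REML components (the
population-parameters-previously-determined scheme used by EMMAX/GCTA-MLMA).
Single- and multi-trait meta-analyses combine signed t-values across
cohort-traits through chi2 = t' V^-1 t with V the t-correlation matrix
estimated over all markers, and the SV false discovery rate uses the
threshold-count estimator FDR = P (1 - S/T) / ((S/T)(1 - P)).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .containers import MISSING
from .mixedmodel import MixedModelSpec, VarianceComponents, _safe_cholesky

log = logging.getLogger(__name__)

#: fixed descending ladder of exploratory p-value thresholds
THRESHOLD_LADDER = (1e-7, 1e-5, 1e-4)


def _record_v(spec: MixedModelSpec, vc: VarianceComponents) -> np.ndarray:
    n = spec.n_records
    V = vc.sigma2_e * np.eye(n)
    for Vk, (_, lab) in zip(spec.record_covariances(), spec.grms):
        V = V + vc.components[lab] * Vk
    return V


def _prep_dosages(dosages: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean-impute missing codes; return (float dosages, monomorphic mask)."""
    x = np.asarray(dosages, dtype=float)
    miss = x == MISSING
    if miss.any():
        x = x.copy()
        x[miss] = np.nan
        mu = np.nanmean(x, axis=0)
        mu = np.where(np.isnan(mu), 0.0, mu)
        idx = np.where(miss)
        x[idx] = mu[idx[1]]
    mono = x.std(axis=0) == 0.0
    return x, mono


def mlma_scan(
    spec: MixedModelSpec,
    dosages: np.ndarray,
    vc: VarianceComponents,
    marker_info: pd.DataFrame | None = None,
    trait: str = "trait",
    cohort: str = "all",
) -> pd.DataFrame:
    """Per-marker GLS scan at fixed null variance components.

    For each marker the model is y ~ [spec.X, marker] with cov(y) = V from
    the null fit; the marker effect b, its SE, signed t = b/SE and the
    two-sided standard-normal p-value are returned. Monomorphic markers and
    markers aliased with the fixed design give NA rows with a reason.
    """
    y, X = spec.y, spec.X
    V = _record_v(spec, vc)
    c = _safe_cholesky(V, "V")
    L = np.tril(c[0])
    ys = linalg.solve_triangular(L, y, lower=True)
    Xs = linalg.solve_triangular(L, X, lower=True)
    M, mono = _prep_dosages(dosages)
    Ms = linalg.solve_triangular(L, M, lower=True)
    # residualise out the fixed design in the whitened space
    coef_y, *_ = np.linalg.lstsq(Xs, ys, rcond=None)
    ry = ys - Xs @ coef_y
    coef_m, *_ = np.linalg.lstsq(Xs, Ms, rcond=None)
    RM = Ms - Xs @ coef_m
    denom = np.einsum("ij,ij->j", RM, RM)
    colnorm = np.einsum("ij,ij->j", Ms, Ms)
    aliased = denom <= 1e-8 * np.maximum(colnorm, 1e-12)
    with np.errstate(divide="ignore", invalid="ignore"):
        b = (RM.T @ ry) / denom
        se = 1.0 / np.sqrt(denom)
        t = b / se
    p = 2.0 * stats.norm.sf(np.abs(t))
    bad = mono | aliased
    b[bad] = np.nan
    se[bad] = np.nan
    t[bad] = np.nan
    p[bad] = np.nan
    note = np.where(mono, "monomorphic", np.where(aliased, "aliased", ""))
    m = M.shape[1]
    out = {
        "id": marker_info["id"].to_numpy() if marker_info is not None else [f"m{j}" for j in range(m)],
        "chrom": marker_info["chrom"].to_numpy() if marker_info is not None else "",
        "pos": marker_info["start"].to_numpy() if marker_info is not None else np.arange(m),
        "class": marker_info["class"].to_numpy() if marker_info is not None and "class" in marker_info else "SNP",
        "cohort": cohort,
        "trait": trait,
        "b": b,
        "se": se,
        "t": t,
        "p": p,
        "note": note,
    }
    return pd.DataFrame(out)


def conditional_scan(
    spec: MixedModelSpec,
    dosages: np.ndarray,
    vc: VarianceComponents,
    conditioning_dosage: np.ndarray,
    **kwargs,
) -> pd.DataFrame:
    """GWAS scan with a conditioning marker added as a fixed covariate.

    Identical to :func:`mlma_scan` except the conditioning marker's dosage
    is appended to the fixed design; a tested marker in perfect LD with it
    comes back NA/aliased.
    """
    cond = np.asarray(conditioning_dosage, dtype=float).reshape(-1, 1)
    if cond.shape[0] != spec.n_records:
        raise ValueError("conditioning marker must be genotyped in all tested individuals")
    cond_imp, _ = _prep_dosages(cond)
    spec2 = MixedModelSpec(
        y=spec.y,
        X=np.column_stack([spec.X, cond_imp]),
        grms=spec.grms,
        individual_idx=spec.individual_idx,
        fixed_names=list(spec.fixed_names) + ["conditioning_marker"],
    )
    return mlma_scan(spec2, dosages, vc, **kwargs)


def t_correlation(tables: list[pd.DataFrame], min_shared: int = 10) -> pd.DataFrame:
    """Correlation matrix of signed t-values across cohort-trait scans.

    Pearson correlation over the shared marker universe, pairwise-complete;
    raises if any pair shares fewer than ``min_shared`` markers with finite
    t in both.
    """
    if len(tables) < 2:
        raise ValueError("need at least two cohort-trait tables")
    cols = {}
    for tab in tables:
        key = f"{tab['cohort'].iloc[0]}:{tab['trait'].iloc[0]}"
        cols[key] = tab.set_index("id")["t"]
    tmat = pd.DataFrame(cols)
    keys = list(tmat.columns)
    for i in range(len(keys)):
        for j in range(i + 1, len(keys)):
            shared = int((tmat[keys[i]].notna() & tmat[keys[j]].notna()).sum())
            if shared < min_shared:
                raise ValueError(f"only {shared} shared markers between {keys[i]} and {keys[j]}")
    V = tmat.corr(method="pearson")
    np.fill_diagonal(V.values, 1.0)
    return V


@dataclass
class MetaResult:
    table: pd.DataFrame     # id, chi2, df, p
    V: pd.DataFrame | np.ndarray
    df: int


def multi_trait_chi2(T, V, marker_ids=None) -> MetaResult:
    """Per-marker chi2 = t' V^-1 t with df = number of cohort-traits.

    ``T`` is markers x k of signed t-values; rows with any missing t give
    NA. An ill-conditioned V (condition number > 1e10) is handled by the
    Moore-Penrose pseudo-inverse with a warning.
    """
    Tm = np.asarray(T, dtype=float)
    if Tm.ndim == 1:
        Tm = Tm[:, None]
    Vm = np.asarray(V.values if isinstance(V, pd.DataFrame) else V, dtype=float)
    k = Tm.shape[1]
    if Vm.shape != (k, k):
        raise ValueError("V dimension does not match the number of cohort-traits")
    if np.linalg.cond(Vm) > 1e10:
        warnings.warn("t-correlation matrix ill-conditioned; using pseudo-inverse")
        Vinv = np.linalg.pinv(Vm)
    else:
        Vinv = np.linalg.inv(Vm)
    ok = np.isfinite(Tm).all(axis=1)
    chi2 = np.full(Tm.shape[0], np.nan)
    chi2[ok] = np.einsum("ij,jk,ik->i", Tm[ok], Vinv, Tm[ok])
    p = stats.chi2.sf(chi2, df=k)
    ids = marker_ids if marker_ids is not None else np.arange(Tm.shape[0])
    return MetaResult(table=pd.DataFrame({"id": ids, "chi2": chi2, "df": k, "p": p}), V=V, df=k)


def meta_single_trait(bull_table: pd.DataFrame, cow_table: pd.DataFrame) -> MetaResult:
    """Bull/cow combination of one trait: the k = 2 case of the chi2 meta."""
    a = bull_table.set_index("id")["t"]
    b = cow_table.set_index("id")["t"]
    shared = a.index.intersection(b.index)
    V = t_correlation([bull_table, cow_table])
    T = np.column_stack([a.loc[shared].to_numpy(), b.loc[shared].to_numpy()])
    return multi_trait_chi2(T, V, marker_ids=shared.to_numpy())


@dataclass
class FDRQuery:
    """A p-value threshold P with S significant SVs out of T total."""

    P: float
    S: int
    T: int

    def __post_init__(self) -> None:
        if not 0.0 < self.P < 1.0:
            raise ValueError("P must be in (0, 1)")
        if self.T <= 0:
            raise ValueError("T must be positive")
        if not 0 <= self.S <= self.T:
            raise ValueError("S must be in [0, T]")


def fdr(query: FDRQuery | None = None, P: float | None = None, S: int | None = None, T: int | None = None) -> float:
    """False discovery rate  FDR = P (1 - S/T) / ((S/T)(1 - P)).

    Returned as a fraction (multiply by 100 for the percent scale used in
    reports). With S = 0 the estimator is undefined and NaN is returned.
    """
    q = query if query is not None else FDRQuery(P=P, S=S, T=T)
    if q.S == 0:
        return float("nan")
    rate = q.S / q.T
    return float(q.P * (1.0 - rate) / (rate * (1.0 - q.P)))


@dataclass
class SignificanceThresholds:
    bonferroni: float
    ladder: tuple[float, ...]


def significance_thresholds(n_tests: int) -> SignificanceThresholds:
    """Bonferroni 0.05/n plus the fixed exploratory ladder, sorted ascending."""
    if n_tests <= 0:
        raise ValueError("n_tests must be positive")
    return SignificanceThresholds(
        bonferroni=0.05 / n_tests,
        ladder=tuple(sorted(THRESHOLD_LADDER)),
    )


def ld_window(
    sv_dosage: np.ndarray,
    sv_interval: tuple[str, int, int],
    snp_dosages: np.ndarray,
    snp_map: pd.DataFrame,
    window_bp: int,
    high_ld: float = 0.5,
) -> pd.DataFrame:
    """Dosage r^2 between one SV and the SNPs within ``window_bp`` of it.

    The window is anchored at the SV interval midpoint; r^2 is the squared
    Pearson correlation of (composite) dosages, NaN for monomorphic SNPs.
    SNPs with r^2 above ``high_ld`` are flagged.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    chrom, start, end = sv_interval
    mid = (start + end) // 2
    sel = (snp_map["chrom"] == chrom) & (np.abs(snp_map["start"] - mid) <= window_bp)
    idx = np.flatnonzero(sel.to_numpy())
    sv, _ = _prep_dosages(np.asarray(sv_dosage, dtype=float).reshape(-1, 1))
    sv = sv[:, 0]
    X, mono = _prep_dosages(np.asarray(snp_dosages, dtype=float)[:, idx])
    svc = sv - sv.mean()
    Xc = X - X.mean(axis=0)
    denom = np.sqrt((svc @ svc) * np.einsum("ij,ij->j", Xc, Xc))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Xc.T @ svc) / denom
    r2 = r * r
    r2[mono] = np.nan
    if svc @ svc == 0:
        r2[:] = np.nan
    return pd.DataFrame(
        {
            "snp_id": snp_map["id"].to_numpy()[idx],
            "pos": snp_map["start"].to_numpy()[idx],
            "r2": r2,
            "high_ld": r2 > high_ld,
        }
    )
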