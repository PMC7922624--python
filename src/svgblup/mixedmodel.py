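"""Variance components and BLUP for GRM-based mixed models.

Model:  y = X b + sum_k Z u_k + e,  u_k ~ N(0, G_k s2_k),  e ~ N(0, I s2_e)

with one or two genomic relationship matrices (typically a SNP GRM and an
SV GRM). Variance components are estimated by average-information (AI) REML
with EM-REML fallback steps whenever an AI update would leave the parameter
space; breeding values solve the mixed-model equations (equivalently GLS)
at the estimated components. Individuals without phenotype records receive
predictions through the off-diagonal entries of G.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .relmat import GRM

log = logging.getLogger(__name__)

#: ridge added to a numerically singular covariance before factorisation
RIDGE = 1e-6


@dataclass
class MixedModelSpec:
    """Phenotype records, fixed design and random GRM terms.

    ``individual_idx`` maps each record to a row of the GRMs; identity when
    omitted (every record is a distinct genotyped individual). The fixed
    design always contains an intercept; aliased columns are dropped at
    construction by :func:`make_spec`.
    """

    y: np.ndarray
    X: np.ndarray
    grms: list[tuple[np.ndarray, str]]
    individual_idx: np.ndarray | None = None
    fixed_names: list[str] = field(default_factory=list)

    @property
    def n_records(self) -> int:
        return self.y.size

    def grm_matrix(self, k: int) -> np.ndarray:
        g = self.grms[k][0]
        return g.matrix if isinstance(g, GRM) else np.asarray(g)

    def record_covariances(self) -> list[np.ndarray]:
        """Per-component record-level covariance Z G_k Z'."""
        out = []
        for k in range(len(self.grms)):
            g = self.grm_matrix(k)
            if self.individual_idx is None:
                if g.shape[0] != self.n_records:
                    raise ValueError("GRM size does not match records; provide individual_idx")
                out.append(g)
            else:
                idx = np.asarray(self.individual_idx)
                out.append(g[np.ix_(idx, idx)])
        return out


def make_spec(
    y,
    grms,
    covariates: np.ndarray | None = None,
    covariate_names: list[str] | None = None,
    individual_idx=None,
) -> MixedModelSpec:
    """Assemble a model spec: intercept + covariates, dropping aliased columns."""
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    cols = [np.ones(n)]
    names = ["intercept"]
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != n:
            cov = cov.T
        cnames = covariate_names or [f"cov{j}" for j in range(cov.shape[1])]
        for j in range(cov.shape[1]):
            cols.append(cov[:, j])
            names.append(cnames[j])
    X = np.column_stack(cols)
    # drop aliased (rank-deficient) columns, keeping the earliest ones
    keep, basis = [], []
    for j in range(X.shape[1]):
        v = X[:, j]
        r = v - sum((v @ b) * b for b in basis)
        nr = np.linalg.norm(r)
        if nr > 1e-8 * max(1.0, np.linalg.norm(v)):
            basis.append(r / nr)
            keep.append(j)
    if len(keep) < X.shape[1]:
        dropped = [names[j] for j in range(X.shape[1]) if j not in keep]
        warnings.warn(f"dropping aliased fixed-effect columns: {dropped}")
    X = X[:, keep]
    names = [names[j] for j in keep]
    grms = [(g, lab) for g, lab in grms]
    return MixedModelSpec(
        y=y,
        X=X,
        grms=grms,
        individual_idx=None if individual_idx is None else np.asarray(individual_idx),
        fixed_names=names,
    )


@dataclass
class VarianceComponents:
    """REML estimates with AI standard errors.

    ``components``/``se`` are keyed by GRM label plus ``"residual"``;
    ``history`` records (iteration, log-likelihood, step kind).
    """

    labels: list[str]
    components: dict[str, float]
    se: dict[str, float]
    loglik: float
    converged: bool
    n_iter: int
    history: list[tuple[int, float, str]] = field(default_factory=list)

    @property
    def sigma2_e(self) -> float:
        return self.components["residual"]

    @property
    def sigma2_p(self) -> float:
        return float(sum(self.components.values()))

    def genetic_variance(self) -> float:
        return float(sum(v for k, v in self.components.items() if k != "residual"))


def _safe_cholesky(a: np.ndarray, what: str):
    try:
        return linalg.cho_factor(a, lower=True)
    except linalg.LinAlgError:
        ridge = RIDGE * float(np.mean(np.diag(a)))
        log.warning("%s numerically singular; adding ridge %.3g to diagonal", what, ridge)
        return linalg.cho_factor(a + ridge * np.eye(a.shape[0]), lower=True)


def _reml_pieces(theta, vlist, X, y):
    n = y.size
    V = theta[-1] * np.eye(n)
    for t, Vk in zip(theta[:-1], vlist):
        V = V + t * Vk
    c = _safe_cholesky(V, "V")
    logdet_v = 2.0 * float(np.sum(np.log(np.diag(c[0]))))
    Vi = linalg.cho_solve(c, np.eye(n))
    ViX = Vi @ X
    XtViX = X.T @ ViX
    cx = _safe_cholesky(XtViX, "X'V^-1X")
    logdet_x = 2.0 * float(np.sum(np.log(np.diag(cx[0]))))
    B = linalg.cho_solve(cx, ViX.T)
    P = Vi - ViX @ B
    w = P @ y
    ll = -0.5 * (logdet_v + logdet_x + float(y @ w))
    return P, w, ll


def reml_fit(
    spec: MixedModelSpec,
    max_iter: int = 200,
    tol: float = 1e-8,
    init: np.ndarray | None = None,
    method: str = "ai",
) -> VarianceComponents:
    """AI-REML with EM fallback for the components (s2_1[, s2_2], s2_e).

    The first update is always an EM step for stability; afterwards AI
    updates are used unless they would push a component below the floor
    ``1e-8 * var(y)``, in which case an EM step (which preserves
    positivity) is substituted and the result clamped at the floor.
    Convergence: relative restricted log-likelihood change below ``tol``.
    ``method='em'`` forces EM-only iteration (monotone in the restricted
    likelihood; mainly for testing).
    """
    y, X = spec.y, spec.X
    n = y.size
    if n < 30:
        warnings.warn("fewer than 30 records; REML estimates will be unstable")
    vlist = spec.record_covariances()
    K = len(vlist)
    labels = [lab for _, lab in spec.grms] + ["residual"]
    vary = float(np.var(y))
    if vary <= 0:
        raise ValueError("phenotype has zero variance")
    floor = 1e-8 * vary
    if init is None:
        theta = np.array([0.5 * vary / K] * K + [0.5 * vary])
    else:
        theta = np.asarray(init, dtype=float).copy()
    history: list[tuple[int, float, str]] = []
    ll_prev = -np.inf
    converged = False
    ai = np.eye(K + 1)
    it = 0
    for it in range(1, max_iter + 1):
        P, w, ll = _reml_pieces(theta, vlist, X, y)
        # score and AI for each component (residual has V_k = I)
        tr_pv = np.empty(K + 1)
        ypvpy = np.empty(K + 1)
        q = []
        for k in range(K):
            tr_pv[k] = float(np.sum(P * vlist[k]))
            qk = vlist[k] @ w
            q.append(qk)
            ypvpy[k] = float(w @ qk)
        tr_pv[K] = float(np.trace(P))
        q.append(w)
        ypvpy[K] = float(w @ w)
        score = -0.5 * (tr_pv - ypvpy)
        Pq = [P @ qk for qk in q]
        ai = 0.5 * np.array([[q[i] @ Pq[j] for j in range(K + 1)] for i in range(K + 1)])

        step_kind = "ai"
        em_new = theta + theta**2 * (ypvpy - tr_pv) / n
        if it == 1 or method == "em":
            step_kind = "em"
            theta_new = em_new
        else:
            try:
                cand = theta + np.linalg.solve(ai, score)
            except np.linalg.LinAlgError:
                cand = None
            if cand is not None and np.all(cand >= floor):
                theta_new = cand
            elif cand is not None and np.any(cand >= floor):
                # active-set step: clamp the components the AI update pushed
                # out of the parameter space and re-solve for the free ones
                bound = cand < floor
                free = np.flatnonzero(~bound)
                try:
                    delta_f = np.linalg.solve(ai[np.ix_(free, free)], score[free])
                    cand2 = theta.copy()
                    cand2[bound] = floor
                    cand2[free] = theta[free] + delta_f
                except np.linalg.LinAlgError:
                    cand2 = None
                if cand2 is not None and np.all(cand2 >= floor):
                    theta_new = cand2
                    step_kind = "ai-bound"
                else:
                    theta_new = em_new
                    step_kind = "em-fallback"
            else:
                theta_new = em_new
                step_kind = "em-fallback"
        theta = np.maximum(theta_new, floor)
        history.append((it, ll, step_kind))
        if it > 1 and abs(ll - ll_prev) < tol * max(1.0, abs(ll)):
            converged = True
            ll_prev = ll
            break
        ll_prev = ll
    _, _, ll_final = _reml_pieces(theta, vlist, X, y)
    try:
        se = np.sqrt(np.maximum(np.diag(np.linalg.inv(ai)), 0.0))
    except np.linalg.LinAlgError:
        se = np.full(K + 1, np.nan)
    if not converged:
        warnings.warn(f"REML did not converge in {max_iter} iterations")
    return VarianceComponents(
        labels=labels,
        components={lab: float(t) for lab, t in zip(labels, theta)},
        se={lab: float(s) for lab, s in zip(labels, se)},
        loglik=float(ll_final),
        converged=converged,
        n_iter=it,
        history=history,
    )


def variance_ratios(vc: VarianceComponents, sv_label: str = "sv", snp_label: str = "snp") -> dict:
    """Variance-ratio table: shares of phenotypic and of genetic variance.

    Components below ``1e-6 * s2_p`` are reported as exactly 0 (this is a
    presentation rule; the stored estimates stay unrounded). When the total
    genetic variance is zero the SV share of genetic variance is reported
    as 0 with ``degenerate=True``.
    """
    s2p = vc.sigma2_p
    comp = dict(vc.components)
    for k, v in comp.items():
        if k != "residual" and v < 1e-6 * s2p:
            comp[k] = 0.0
    s2_snp = comp.get(snp_label, 0.0)
    s2_sv = comp.get(sv_label, 0.0)
    genetic = s2_snp + s2_sv
    degenerate = genetic <= 0
    return {
        "snp_vs_p": s2_snp / s2p,
        "sv_vs_p": s2_sv / s2p,
        "genetic_vs_p": genetic / s2p,
        "sv_vs_genetic": 0.0 if degenerate else s2_sv / genetic,
        "degenerate": degenerate,
    }


@dataclass
class RandomEffectSolution:
    """Fixed-effect estimates and per-component breeding values.

    ``u`` maps each GRM label to breeding values over *all* GRM individuals
    (records and unphenotyped alike); ``gebv`` is their sum.
    """

    b: np.ndarray
    fixed_names: list[str]
    u: dict[str, np.ndarray]
    gebv: np.ndarray


def solve_blup(spec: MixedModelSpec, vc: VarianceComponents) -> RandomEffectSolution:
    """GLS/Henderson solutions at fixed variance components.

    b = (X'V^-1 X)^-1 X'V^-1 y and u_k = s2_k G_k Z' V^-1 (y - Xb); these
    satisfy the mixed-model equations exactly, and individuals without
    records are predicted through the G off-diagonals.
    """
    y, X = spec.y, spec.X
    n = y.size
    vlist = spec.record_covariances()
    theta = [vc.components[lab] for _, lab in spec.grms]
    V = vc.sigma2_e * np.eye(n)
    for t, Vk in zip(theta, vlist):
        V = V + t * Vk
    c = _safe_cholesky(V, "V")
    ViX = linalg.cho_solve(c, X)
    XtViX = X.T @ ViX
    cx = _safe_cholesky(XtViX, "X'V^-1X")
    b = linalg.cho_solve(cx, ViX.T @ y)
    alpha = linalg.cho_solve(c, y - X @ b)
    idx = spec.individual_idx
    u: dict[str, np.ndarray] = {}
    gebv = None
    for k, (g, lab) in enumerate(spec.grms):
        gm = spec.grm_matrix(k)
        gz = gm if idx is None else gm[:, np.asarray(idx)]
        uk = theta[k] * (gz @ alpha)
        u[lab] = uk
        gebv = uk if gebv is None else gebv + uk
    return RandomEffectSolution(b=b, fixed_names=list(spec.fixed_names), u=u, gebv=gebv)
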