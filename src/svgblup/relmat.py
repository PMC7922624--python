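"""Allele frequencies and genomic relationship matrices (GRMs).

The GRM is the marker-based estimate of additive relatedness used by GBLUP:

    G_jk = (1/m) * sum_i (x_ij - 2 p_i)(x_ik - 2 p_i) / (2 p_i (1 - p_i))

with x the alt-allele dosage and p_i the alt-allele frequency of marker i
computed on the analysis cohort itself. Missing calls (code 5) are
mean-imputed to 2 p_i before standardisation, which leaves p_i unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .containers import MISSING, GenotypeMatrix

log = logging.getLogger(__name__)


@dataclass
class AlleleFrequencies:
    """Per-marker alternative-allele frequency and call counts.

    Attributes
    ----------
    p : ndarray
        Alt-allele frequency in [0, 1]; NaN where every call is missing.
    n_obs : ndarray
        Number of non-missing calls per marker.
    """

    p: np.ndarray
    n_obs: np.ndarray

    @property
    def maf(self) -> np.ndarray:
        return np.minimum(self.p, 1.0 - self.p)

    @property
    def all_missing(self) -> np.ndarray:
        return self.n_obs == 0

    @property
    def monomorphic(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return (self.p <= 0.0) | (self.p >= 1.0)


def _codes(genotypes) -> np.ndarray:
    if isinstance(genotypes, GenotypeMatrix):
        return genotypes.codes
    return np.asarray(genotypes)


def allele_frequencies(genotypes) -> AlleleFrequencies:
    """Alt-allele frequencies ``p_i = mean(code)/2`` over non-missing calls.

    Markers where every call is missing get ``p = NaN`` and are flagged for
    exclusion downstream.
    """
    codes = _codes(genotypes)
    miss = codes == MISSING
    n_obs = (~miss).sum(axis=0)
    x = np.where(miss, 0, codes).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_obs > 0, x.sum(axis=0) / (2.0 * np.maximum(n_obs, 1)), np.nan)
    return AlleleFrequencies(p=p, n_obs=np.asarray(n_obs))


@dataclass
class GRM:
    """Symmetric genomic relationship matrix plus the inputs that built it.

    Attributes
    ----------
    matrix : ndarray, shape (n, n)
    sample_ids : list of str
    n_markers : int
        Number of markers used after filtering.
    freqs : ndarray
        Alt-allele frequencies of the markers used.
    kept_markers : ndarray
        Column indices (into the input genotype matrix) of the markers used.
    """

    matrix: np.ndarray
    sample_ids: list[str]
    n_markers: int
    freqs: np.ndarray
    kept_markers: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.matrix)
        if not np.allclose(a, a.T, atol=1e-12):
            raise ValueError("GRM must be symmetric")
        if not np.isfinite(a).all():
            raise ValueError("GRM has non-finite entries")


def build_grm(
    genotypes,
    freqs: AlleleFrequencies | None = None,
    maf_min: float = 0.0,
    yang_diagonal: bool = False,
    sample_ids: list[str] | None = None,
) -> GRM:
    """Build a GRM from 0/1/2/5 genotype codes.

    Markers are used when polymorphic, not all-missing, and with
    MAF >= ``maf_min``. With ``yang_diagonal`` the self-relationship is
    computed with the dedicated diagonal estimator
    ``1 + (x^2 - (1+2p)x + 2p^2)/(2p(1-p))`` averaged over markers; by
    default the diagonal uses the same cross formula with j = k.
    """
    codes = _codes(genotypes)
    if sample_ids is None:
        sample_ids = (
            list(genotypes.sample_ids)
            if isinstance(genotypes, GenotypeMatrix)
            else [f"s{i}" for i in range(codes.shape[0])]
        )
    if freqs is None:
        freqs = allele_frequencies(codes)
    keep = ~(freqs.all_missing | freqs.monomorphic) & (freqs.maf >= maf_min)
    kept = np.flatnonzero(keep)
    if kept.size == 0:
        raise ValueError("no polymorphic markers survive the MAF filter")
    p = freqs.p[kept]
    x = codes[:, kept].astype(float)
    miss = codes[:, kept] == MISSING
    if miss.any():
        idx = np.where(miss)
        x[idx] = 2.0 * p[idx[1]]
    denom = np.sqrt(2.0 * p * (1.0 - p))
    w = (x - 2.0 * p) / denom
    m = kept.size
    g = (w @ w.T) / m
    if yang_diagonal:
        diag = 1.0 + ((x * x - (1.0 + 2.0 * p) * x + 2.0 * p * p) / (2.0 * p * (1.0 - p))).mean(axis=1)
        np.fill_diagonal(g, diag)
    g = (g + g.T) / 2.0  # enforce exact symmetry against fp round-off
    return GRM(matrix=g, sample_ids=sample_ids, n_markers=m, freqs=p, kept_markers=kept)
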