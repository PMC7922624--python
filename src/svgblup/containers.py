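"""Shared in-memory containers and exceptions."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Genotype code used for a missing call (literally part of the alphabet).
MISSING = 5

#: Full genotype alphabet: alt-allele dosage 0/1/2 plus the missing code.
CODES = (0, 1, 2, MISSING)


class InvalidConfigError(ValueError):
    """A configuration value is outside its allowed range."""


@dataclass
class GenotypeMatrix:
    """Individuals x markers dosage codes in {0, 1, 2, 5}.

    ``depth`` (same shape) carries the per-call sequencing read depth where
    that is meaningful (SV calls); ``None`` otherwise.
    """

    codes: np.ndarray
    sample_ids: list[str]
    marker_ids: list[str]
    depth: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes)
        if self.codes.ndim != 2:
            raise ValueError("codes must be 2-D (individuals x markers)")
        if self.codes.shape != (len(self.sample_ids), len(self.marker_ids)):
            raise ValueError(
                f"codes shape {self.codes.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.marker_ids)} markers"
            )
        bad = ~np.isin(self.codes, CODES)
        if bad.any():
            raise ValueError(f"genotype codes outside alphabet {CODES}")
        if self.depth is not None:
            self.depth = np.asarray(self.depth)
            if self.depth.shape != self.codes.shape:
                raise ValueError("depth shape must match codes shape")

    @property
    def n_individuals(self) -> int:
        return self.codes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.codes.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return self.codes == MISSING

    @property
    def missing_rate(self) -> float:
        return float(self.missing_mask.mean())

    def dosages(self, impute: str = "mean") -> np.ndarray:
        """Return float dosages with missing calls handled.

        ``impute='mean'`` replaces code-5 calls by twice the observed
        alternative-allele frequency of the marker (the GCTA convention);
        ``impute='nan'`` leaves them as NaN.
        """
        x = self.codes.astype(float)
        miss = self.codes == MISSING
        if not miss.any():
            return x
        x[miss] = np.nan
        if impute == "nan":
            return x
        if impute != "mean":
            raise ValueError(f"unknown impute mode {impute!r}")
        col_mean = np.nanmean(x, axis=0)
        col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
        idx = np.where(miss)
        x[idx] = col_mean[idx[1]]
        return x

    def subset(self, individuals=None, markers=None) -> "GenotypeMatrix":
        ind = np.arange(self.n_individuals) if individuals is None else np.asarray(individuals)
        mk = np.arange(self.n_markers) if markers is None else np.asarray(markers)
        return GenotypeMatrix(
            codes=self.codes[np.ix_(ind, mk)],
            sample_ids=[self.sample_ids[i] for i in ind],
            marker_ids=[self.marker_ids[j] for j in mk],
            depth=None if self.depth is None else self.depth[np.ix_(ind, mk)],
        )
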