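"""Structural-variant interval sets: merging, validation and genotype encoding.

SVs are intervals (0-based half-open) of type DEL/INS/INV/DUP. Calls from two
callers are merged when same-type intervals on the same chromosome share at
least ``min_overlap_bp`` of sequence; multi-way overlaps collapse transitively
into a single record spanning the union of its members. Validation sets keep
only SVs seen in both sequencing replicates of an individual (TWICE_SEQ) or in
both members of a sire-son pair (FAM), which enriches for true transmissible
variants.
"""

from __future__ import annotations

import logging
import warnings
from bisect import bisect_left
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .containers import MISSING, GenotypeMatrix

log = logging.getLogger(__name__)

SV_TYPES = ("DEL", "INS", "INV", "DUP")


@dataclass(frozen=True, order=True)
class SVRecord:
    """An interval variant with caller provenance.

    Coordinates are 0-based half-open; an insertion is represented as a
    1-bp interval (``end == start + 1``).
    """

    chrom: str
    start: int
    end: int
    sv_type: str
    source: tuple[str, ...] = field(default=(), compare=False)

    def __post_init__(self) -> None:
        if self.sv_type not in SV_TYPES:
            raise ValueError(f"unknown SV type {self.sv_type!r}")
        if self.start >= self.end:
            raise ValueError(f"empty interval {self.chrom}:{self.start}-{self.end}")
        if self.sv_type == "INS" and self.end != self.start + 1:
            raise ValueError("insertions must be 1-bp point intervals")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlap_bp(self, other: "SVRecord") -> int:
        """Intersection length in bp (0 if different chrom or type)."""
        if self.chrom != other.chrom or self.sv_type != other.sv_type:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


def _check_sorted(records: Sequence[SVRecord], label: str) -> list[SVRecord]:
    recs = list(records)
    keys = [(r.chrom, r.start) for r in recs]
    if keys != sorted(keys):
        warnings.warn(f"{label} not sorted by (chrom, start); sorting internally")
        recs.sort(key=lambda r: (r.chrom, r.start, r.end))
    return recs


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def _merge_pool(records: Sequence[SVRecord], min_overlap_bp: int = 1) -> list[SVRecord]:
    """Collapse transitively-overlapping same-chrom same-type records.

    Union-find over the pairwise-overlap graph; each component becomes one
    record spanning the union of member intervals with unioned sources.
    """
    if min_overlap_bp < 1:
        raise ValueError("min_overlap_bp must be >= 1")
    n = len(records)
    uf = _UnionFind(n)
    by_group: dict[tuple[str, str], list[int]] = {}
    for i, r in enumerate(records):
        by_group.setdefault((r.chrom, r.sv_type), []).append(i)
    for idxs in by_group.values():
        idxs = sorted(idxs, key=lambda i: records[i].start)
        active: list[int] = []
        for i in idxs:
            cur = records[i]
            active = [j for j in active if records[j].end >= cur.start + min_overlap_bp]
            for j in active:
                if cur.overlap_bp(records[j]) >= min_overlap_bp:
                    uf.union(i, j)
            active.append(i)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(uf.find(i), []).append(i)
    merged = []
    for members in groups.values():
        recs = [records[i] for i in members]
        src: list[str] = []
        for r in recs:
            for s in r.source:
                if s not in src:
                    src.append(s)
        merged.append(
            SVRecord(
                chrom=recs[0].chrom,
                start=min(r.start for r in recs),
                end=max(r.end for r in recs),
                sv_type=recs[0].sv_type,
                source=tuple(src),
            )
        )
    merged.sort(key=lambda r: (r.chrom, r.start, r.end, r.sv_type))
    return merged


def merge_sv_calls(
    set_a: Sequence[SVRecord],
    set_b: Sequence[SVRecord],
    min_overlap_bp: int = 1,
) -> list[SVRecord]:
    """Merge two caller outputs by >= ``min_overlap_bp`` same-type overlap.

    Overlapping records become one record spanning the union of their
    intervals; records unique to one caller are kept as singletons carrying
    their own source tags.
    """
    a = _check_sorted(set_a, "set_a")
    b = _check_sorted(set_b, "set_b")
    return _merge_pool(list(a) + list(b), min_overlap_bp=min_overlap_bp)


def intersect_with_target(
    calls: Sequence[SVRecord],
    target_set: Sequence[SVRecord],
    min_overlap_bp: int = 1,
) -> list[SVRecord]:
    """Keep calls overlapping (>= min_overlap_bp, same type) a target record.

    Calls with no overlapping target are dropped (the drop count is logged):
    a call is treated as real only when it also appears in the target set.
    """
    calls = _check_sorted(calls, "calls")
    if not target_set:
        warnings.warn("empty target set: all calls dropped")
        return []
    targets = _check_sorted(target_set, "target_set")
    by_group: dict[tuple[str, str], tuple[list[int], list[SVRecord]]] = {}
    for t in targets:
        starts, recs = by_group.setdefault((t.chrom, t.sv_type), ([], []))
        starts.append(t.start)
        recs.append(t)
    kept = []
    for c in calls:
        grp = by_group.get((c.chrom, c.sv_type))
        if grp is None:
            continue
        starts, recs = grp
        hi = bisect_left(starts, c.end - min_overlap_bp + 1)
        if any(recs[j].overlap_bp(c) >= min_overlap_bp for j in range(hi)):
            kept.append(c)
    log.info("intersect_with_target: kept %d of %d calls", len(kept), len(calls))
    return kept


def build_validation_sets(
    per_individual_calls: Mapping[str, Sequence[SVRecord]],
    samples: Sequence,
    min_overlap_bp: int = 1,
) -> dict[str, list[SVRecord]]:
    """Validation SV sets from twice-sequenced duplicates and sire-son pairs.

    TWICE_SEQ holds SVs called (>= 1 bp overlap, same type) in both sequencing
    replicates of at least one duplicated individual; FAM holds SVs called in
    both members of at least one sire-son pair (an SV seen in the son only is
    excluded). Returns ``{"TWICE_SEQ": [...], "FAM": [...]}``.
    """
    dup_pairs = [
        (s.id, s.duplicate_of) for s in samples if getattr(s, "duplicate_of", None)
    ]
    fam_pairs = [(s.id, s.sire_id) for s in samples if getattr(s, "sire_id", None)]
    if not dup_pairs and not fam_pairs:
        warnings.warn("no duplicate or sire links among samples; empty validation sets")

    def _validated(pairs: list[tuple[str, str]]) -> list[SVRecord]:
        hits: list[SVRecord] = []
        for a_id, b_id in pairs:
            calls_a = list(per_individual_calls.get(a_id, ()))
            calls_b = list(per_individual_calls.get(b_id, ()))
            for ra in calls_a:
                for rb in calls_b:
                    if ra.overlap_bp(rb) >= min_overlap_bp:
                        hits.append(
                            SVRecord(
                                chrom=ra.chrom,
                                start=min(ra.start, rb.start),
                                end=max(ra.end, rb.end),
                                sv_type=ra.sv_type,
                                source=tuple(dict.fromkeys(ra.source + rb.source)),
                            )
                        )
        return _merge_pool(hits, min_overlap_bp=min_overlap_bp) if hits else []

    return {"TWICE_SEQ": _validated(dup_pairs), "FAM": _validated(fam_pairs)}


_GT_SYMBOLS = {
    "0/0": 0, "0|0": 0,
    "0/1": 1, "1/0": 1, "0|1": 1, "1|0": 1,
    "1/1": 2, "1|1": 2,
    "./.": MISSING, ".|.": MISSING, ".": MISSING,
    0: 0, 1: 1, 2: 2, MISSING: MISSING,
}


def encode_genotypes(
    calls,
    depths,
    threshold: int = 5,
    sample_ids: Sequence[str] | None = None,
    marker_ids: Sequence[str] | None = None,
) -> GenotypeMatrix:
    """Encode caller genotypes to the 0/1/2/5 alphabet with a depth filter.

    ``calls`` is individuals x SVs of genotype symbols (``"0/1"`` style or
    integer dosages); ``depths`` the matching read depths. Calls with depth
    below ``threshold`` are recoded to the missing code 5.
    """
    if threshold < 0:
        raise ValueError("depth threshold must be non-negative")
    calls = np.asarray(calls, dtype=object)
    depths = np.asarray(depths)
    if calls.shape != depths.shape:
        raise ValueError("calls and depths shapes differ")
    n, m = calls.shape
    codes = np.empty((n, m), dtype=np.int8)
    for i in range(n):
        for j in range(m):
            sym = calls[i, j]
            if sym not in _GT_SYMBOLS:
                name = marker_ids[j] if marker_ids else f"column {j}"
                raise ValueError(f"unknown genotype symbol {sym!r} at {name}, sample row {i}")
            codes[i, j] = _GT_SYMBOLS[sym]
    codes[depths < threshold] = MISSING
    return GenotypeMatrix(
        codes=codes,
        sample_ids=list(sample_ids) if sample_ids else [f"s{i}" for i in range(n)],
        marker_ids=list(marker_ids) if marker_ids else [f"sv{j}" for j in range(m)],
        depth=depths,
    )
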