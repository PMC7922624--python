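"""Synthetic two-breed populations with LD, SVs, depth and pedigree links.

The generator emulates the statistical structure the downstream analyses
assume, so every stage is testable without restricted animal data:

* two breed-specific founder haplotype pools; sampled haplotypes are
  founder mosaics built by a copy-with-switch process whose per-bp switch
  rate (``ld_rho``) tunes LD decay with distance;
* SNPs and SVs live on the same haplotype lattice — an SV allele is carried
  on haplotypes exactly like a SNP allele, with an interval attached;
* admixed individuals with breed (Holstein) fractions in
  {0, 0.25, 0.5, 0.75, 1} (0 = pure Jersey, 1 = pure Holstein);
* additive phenotypes whose variance splits into a large SNP component and
  a small SV component, with the true per-individual components stored;
* Poisson per-call sequencing depth with calls below a threshold recoded to
  the missing code 5;
* sire-son pairs (the son carries one recombinant gamete from the sire) and
  twice-sequenced duplicate samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import MISSING, GenotypeMatrix, InvalidConfigError
from .sv_catalog import SVRecord

ALLOWED_FRACTIONS = (0.0, 0.25, 0.5, 0.75, 1.0)

#: per-bp crossover rate used for the sire gamete (about 1 cM/Mb)
MEIOTIC_RATE = 1e-8


@dataclass
class SimConfig:
    """Parameters of the synthetic population.

    ``ld_rho`` is the per-bp founder copy-switch rate in [0, 1] (0 = every
    haplotype is a pure founder copy per chromosome, larger = faster LD
    decay). ``breed_fractions`` maps each allowed Holstein fraction to its
    mixture weight. ``prop_var_snp``/``prop_var_sv`` are the fractions of
    phenotypic variance assigned to the SNP and SV additive components.
    """

    n_individuals: int = 500
    n_snp: int = 5000
    n_sv: int = 200
    n_chrom: int = 5
    chrom_length_bp: int = 10_000_000
    ld_rho: float = 1e-5
    breed_fractions: dict = field(
        default_factory=lambda: {1.0: 0.55, 0.0: 0.25, 0.5: 0.10, 0.25: 0.05, 0.75: 0.05}
    )
    prop_var_snp: float = 0.5
    prop_var_sv: float = 0.05
    depth_mean: float = 8.0
    n_sire_son_pairs: int = 25
    n_duplicates: int = 10
    seed: int = 0
    # shaping knobs the downstream analyses do not depend on
    n_founders: int = 10
    maf_shape: float = 1.0
    n_traits: int = 3
    causal_fraction: float = 0.1
    breed_effect: float = 0.5
    depth_threshold: int = 5
    sv_type_weights: dict = field(
        default_factory=lambda: {"DEL": 0.90, "INV": 0.05, "DUP": 0.05}
    )

    def __post_init__(self) -> None:
        for name in ("n_individuals", "n_snp", "n_sv", "n_chrom", "chrom_length_bp", "n_founders"):
            if getattr(self, name) <= 0:
                raise InvalidConfigError(f"{name} must be positive")
        if not 0.0 <= self.ld_rho <= 1.0:
            raise InvalidConfigError("ld_rho must be in [0, 1]")
        for frac in self.breed_fractions:
            if frac not in ALLOWED_FRACTIONS:
                raise InvalidConfigError(f"breed fraction {frac} not in {ALLOWED_FRACTIONS}")
        if sum(self.breed_fractions.values()) <= 0:
            raise InvalidConfigError("breed fraction weights must sum to a positive value")
        for name in ("prop_var_snp", "prop_var_sv"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise InvalidConfigError(f"{name} must be in [0, 1]")
        if self.prop_var_snp + self.prop_var_sv > 1.0:
            raise InvalidConfigError("prop_var_snp + prop_var_sv must be <= 1")
        if self.n_snp < 2 * self.n_sv:
            raise InvalidConfigError("need n_snp >= 2 * n_sv")
        if self.depth_threshold < 0:
            raise InvalidConfigError("depth_threshold must be non-negative")
        if self.n_sire_son_pairs < 0 or self.n_duplicates < 0:
            raise InvalidConfigError("pair/duplicate counts must be non-negative")
        if 2 * self.n_sire_son_pairs > self.n_individuals:
            raise InvalidConfigError("too many sire-son pairs for the population size")


@dataclass
class SampleInfo:
    id: str
    sex: str
    breed_fraction: float
    sire_id: str | None = None
    duplicate_of: str | None = None


@dataclass
class HaplotypePool:
    """Breed founder haplotypes over the joint SNP+SV marker lattice."""

    founders: dict[int, np.ndarray]  # breed (0=Jersey, 1=Holstein) -> (F, m) alleles
    chrom: np.ndarray                # (m,) chromosome label per lattice marker
    pos: np.ndarray                  # (m,) bp position per lattice marker
    p_switch: np.ndarray             # (m,) founder switch probability before marker
    snp_cols: np.ndarray             # lattice columns that are SNPs
    sv_cols: np.ndarray              # lattice columns that are SVs
    snp_map: pd.DataFrame            # chrom, start, end, id, type
    sv_map: pd.DataFrame             # chrom, start, end, id, type (intervals)

    @property
    def n_markers(self) -> int:
        return self.pos.size

    def sv_records(self) -> list[SVRecord]:
        return [
            SVRecord(r.chrom, int(r.start), int(r.end), r.type, source=("sim",))
            for r in self.sv_map.itertuples()
        ]


@dataclass
class PhenotypeTable:
    """Phenotypes plus the true per-individual components that built them."""

    values: pd.DataFrame      # columns: id, trait1..traitT
    components: pd.DataFrame  # columns: id, trait, fixed, g_snp, g_sv, resid

    @property
    def trait_names(self) -> list[str]:
        return [c for c in self.values.columns if c != "id"]


@dataclass
class SyntheticDataset:
    config: SimConfig
    snp_genotypes: GenotypeMatrix
    sv_genotypes: GenotypeMatrix       # depth-filtered, with per-call depth
    sv_truth: GenotypeMatrix           # SV codes before depth missingness
    snp_map: pd.DataFrame
    sv_map: pd.DataFrame
    samples: list[SampleInfo]
    phenotypes: PhenotypeTable
    haplotypes: np.ndarray             # (n_samples, 2, m) lattice alleles
    pool: HaplotypePool
    sv_missing_rate: float

    @property
    def primary_index(self) -> np.ndarray:
        """Row indices of non-duplicate samples (the analysis cohort)."""
        return np.array([i for i, s in enumerate(self.samples) if s.duplicate_of is None])

    def breed_fraction(self) -> np.ndarray:
        return np.array([s.breed_fraction for s in self.samples])

    def sv_calls_by_sample(self, use_truth: bool = False) -> dict[str, list[SVRecord]]:
        """Per-sample SV call lists (code 1 or 2 = called), for validation sets."""
        gm = self.sv_truth if use_truth else self.sv_genotypes
        records = self.pool.sv_records()
        out: dict[str, list[SVRecord]] = {}
        for i, sid in enumerate(gm.sample_ids):
            row = gm.codes[i]
            out[sid] = [records[j] for j in np.flatnonzero((row == 1) | (row == 2))]
        return out


def simulate_haplotypes(config: SimConfig, rng: np.random.Generator | None = None) -> HaplotypePool:
    """Build breed founder pools and the SNP/SV marker maps.

    SNP positions are uniform per chromosome; each SV start falls in a
    random inter-SNP gap with a log-uniform length (100 bp - 10 kb), so some
    SV intervals span SNPs. Founder alleles are Bernoulli draws from
    per-breed frequencies shaped by ``maf_shape`` (Beta(a, a) scaled into
    [0.05, 0.95]) with a small between-breed divergence jitter.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    chroms, positions, is_sv, sv_rows = [], [], [], []
    snp_per_chrom = np.full(config.n_chrom, config.n_snp // config.n_chrom)
    snp_per_chrom[: config.n_snp % config.n_chrom] += 1
    sv_per_chrom = np.full(config.n_chrom, config.n_sv // config.n_chrom)
    sv_per_chrom[: config.n_sv % config.n_chrom] += 1
    sv_types = list(config.sv_type_weights)
    sv_type_p = np.array(list(config.sv_type_weights.values()), dtype=float)
    sv_type_p /= sv_type_p.sum()
    for c in range(config.n_chrom):
        name = f"chr{c + 1}"
        n_s = int(snp_per_chrom[c])
        snp_pos = np.sort(rng.choice(config.chrom_length_bp - 2, size=n_s, replace=False)) + 1
        n_v = int(sv_per_chrom[c])
        gap_idx = rng.integers(0, n_s - 1, size=n_v)
        entries = []
        for g in gap_idx:
            lo, hi = int(snp_pos[g]), int(snp_pos[g + 1])
            start = int(rng.integers(lo, hi)) if hi > lo + 1 else lo
            svt = sv_types[rng.choice(len(sv_types), p=sv_type_p)]
            if svt == "INS":
                end = start + 1
            else:
                length = int(10 ** rng.uniform(2.0, 4.0))
                end = min(start + max(length, 2), config.chrom_length_bp)
            entries.append((start, end, svt))
        for p in snp_pos:
            chroms.append(name)
            positions.append(int(p))
            is_sv.append(False)
            sv_rows.append(None)
        for start, end, svt in entries:
            chroms.append(name)
            positions.append(start)
            is_sv.append(True)
            sv_rows.append((name, start, end, svt))
    chrom_arr = np.array(chroms)
    pos_arr = np.array(positions, dtype=np.int64)
    sv_flag = np.array(is_sv)
    order = np.lexsort((sv_flag, pos_arr, chrom_arr))
    chrom_arr, pos_arr, sv_flag = chrom_arr[order], pos_arr[order], sv_flag[order]
    sv_rows = [sv_rows[i] for i in order]
    m = pos_arr.size

    # switch probability before each marker; chromosome starts always switch
    p_switch = np.empty(m)
    prev_chrom = None
    for j in range(m):
        if chrom_arr[j] != prev_chrom:
            p_switch[j] = 1.0
            prev_chrom = chrom_arr[j]
        else:
            d = pos_arr[j] - pos_arr[j - 1]
            p_switch[j] = 1.0 - np.exp(-config.ld_rho * d)

    a = config.maf_shape
    base_p = 0.05 + 0.90 * rng.beta(a, a, size=m)
    founders: dict[int, np.ndarray] = {}
    for breed in (0, 1):
        p_b = np.clip(base_p + rng.normal(0.0, 0.05, size=m), 0.02, 0.98)
        founders[breed] = (rng.random((config.n_founders, m)) < p_b).astype(np.int8)

    snp_cols = np.flatnonzero(~sv_flag)
    sv_cols = np.flatnonzero(sv_flag)
    snp_map = pd.DataFrame(
        {
            "chrom": chrom_arr[snp_cols],
            "start": pos_arr[snp_cols],
            "end": pos_arr[snp_cols] + 1,
            "id": [f"snp_{k}" for k in range(snp_cols.size)],
            "type": "SNP",
        }
    )
    sv_map = pd.DataFrame(
        [
            {"chrom": sv_rows[j][0], "start": sv_rows[j][1], "end": sv_rows[j][2],
             "id": f"sv_{k}", "type": sv_rows[j][3]}
            for k, j in enumerate(sv_cols)
        ]
    )
    return HaplotypePool(
        founders=founders,
        chrom=chrom_arr,
        pos=pos_arr,
        p_switch=p_switch,
        snp_cols=snp_cols,
        sv_cols=sv_cols,
        snp_map=snp_map,
        sv_map=sv_map,
    )


def _draw_mosaics(
    founders: np.ndarray, p_switch: np.ndarray, n_hap: int, rng: np.random.Generator
) -> np.ndarray:
    """Sample mosaic haplotypes from a founder pool (vectorised)."""
    n_f, m = founders.shape
    switch = rng.random((n_hap, m)) < p_switch
    switch[:, 0] = True
    draws = rng.integers(0, n_f, size=(n_hap, m))
    idx = np.where(switch, np.arange(m), 0)
    last = np.maximum.accumulate(idx, axis=1)
    f = np.take_along_axis(draws, last, axis=1)
    return founders[f, np.arange(m)]


def _recombine(h0: np.ndarray, h1: np.ndarray, pool: HaplotypePool, rng: np.random.Generator) -> np.ndarray:
    """One meiotic gamete from a parent's two haplotypes."""
    m = h0.size
    p_x = np.empty(m)
    prev = None
    for j in range(m):
        if pool.chrom[j] != prev:
            p_x[j] = 0.5
            prev = pool.chrom[j]
        else:
            p_x[j] = 0.5 * (1.0 - np.exp(-2.0 * MEIOTIC_RATE * (pool.pos[j] - pool.pos[j - 1])))
    cross = rng.random(m) < p_x
    strand = np.cumsum(cross) % 2
    return np.where(strand == 0, h0, h1).astype(np.int8)


def apply_depth_missingness(
    sv_genotypes,
    depth_mean: float,
    threshold: int = 5,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    depths: np.ndarray | None = None,
) -> tuple[GenotypeMatrix, float]:
    """Recode calls with read depth below ``threshold`` to the missing code 5.

    Depths are drawn per call from Poisson(``depth_mean``) unless supplied.
    Returns the filtered matrix (depth attached) and the missingness rate,
    i.e. roughly the Poisson CDF at ``threshold - 1``.
    """
    if threshold < 0:
        raise InvalidConfigError("depth threshold must be non-negative")
    if isinstance(sv_genotypes, GenotypeMatrix):
        codes = sv_genotypes.codes
        sample_ids, marker_ids = sv_genotypes.sample_ids, sv_genotypes.marker_ids
    else:
        codes = np.asarray(sv_genotypes)
        sample_ids = [f"s{i}" for i in range(codes.shape[0])]
        marker_ids = [f"sv{j}" for j in range(codes.shape[1])]
    if depths is None:
        if rng is None:
            rng = np.random.default_rng(seed)
        depths = rng.poisson(depth_mean, size=codes.shape)
    low = depths < threshold
    out = codes.copy()
    out[low] = MISSING
    gm = GenotypeMatrix(codes=out, sample_ids=list(sample_ids), marker_ids=list(marker_ids), depth=depths)
    return gm, float(low.mean())


def _exact_scale(v: np.ndarray, target_var: float) -> np.ndarray:
    v = v - v.mean()
    s = v.var()
    if target_var <= 0:
        return np.zeros_like(v)
    if s <= 0:
        raise ValueError("component has zero variance but a positive target was requested")
    return v * np.sqrt(target_var / s)


def _residualise(v: np.ndarray, basis: list[np.ndarray]) -> np.ndarray:
    v = v - v.mean()
    for b in basis:
        nb = b @ b
        if nb > 0:
            v = v - (v @ b) / nb * b
    return v


def simulate_phenotypes(
    dataset_or_genotypes,
    prop_var_snp: float,
    prop_var_sv: float,
    n_traits: int = 1,
    seed: int = 0,
    causal_fraction: float = 0.1,
    breed_effect: float = 0.0,
    breed_fraction: np.ndarray | None = None,
    sample_ids: list[str] | None = None,
    sv_genotypes=None,
) -> PhenotypeTable:
    """Additive phenotypes with exact SNP/SV variance fractions.

    Per trait, Gaussian effects are drawn for a random ``causal_fraction``
    of SNPs and of SVs; the two genetic components and the Gaussian residual
    are mutually orthogonalised in-sample and scaled so their sample
    variances are exactly ``prop_var_snp``, ``prop_var_sv`` and the
    remainder of a unit phenotypic variance. The true components are stored
    so variance bookkeeping is checkable without re-estimation.
    """
    if prop_var_snp < 0 or prop_var_sv < 0 or prop_var_snp + prop_var_sv > 1.0:
        raise InvalidConfigError("variance proportions must be >= 0 and sum to <= 1")
    if isinstance(dataset_or_genotypes, SyntheticDataset):
        ds = dataset_or_genotypes
        idx = ds.primary_index
        snp = ds.snp_genotypes.codes[idx].astype(float)
        sv = ds.sv_truth.codes[idx].astype(float)
        ids = [ds.samples[i].id for i in idx]
        bf = np.array([ds.samples[i].breed_fraction for i in idx])
    else:
        snp = np.asarray(_as_codes(dataset_or_genotypes), dtype=float)
        sv = np.asarray(_as_codes(sv_genotypes), dtype=float) if sv_genotypes is not None else None
        ids = sample_ids or [f"ind{i}" for i in range(snp.shape[0])]
        bf = breed_fraction if breed_fraction is not None else np.zeros(snp.shape[0])
    rng = np.random.default_rng(seed)
    n = snp.shape[0]
    values = {"id": ids}
    comp_rows = []
    for t in range(n_traits):
        trait = f"trait{t + 1}"
        g1 = _component(snp, causal_fraction, rng) if prop_var_snp > 0 else np.zeros(n)
        g1 = _exact_scale(g1, prop_var_snp) if prop_var_snp > 0 else g1
        if prop_var_sv > 0:
            if sv is None:
                raise InvalidConfigError("SV genotypes required when prop_var_sv > 0")
            g2 = _residualise(_component(sv, causal_fraction, rng), [g1])
            g2 = _exact_scale(g2, prop_var_sv)
        else:
            g2 = np.zeros(n)
        e = _residualise(rng.normal(size=n), [g1, g2])
        e = _exact_scale(e, 1.0 - prop_var_snp - prop_var_sv)
        fixed = breed_effect * (bf - bf.mean())
        y = fixed + g1 + g2 + e
        values[trait] = y
        comp_rows.append(
            pd.DataFrame({"id": ids, "trait": trait, "fixed": fixed, "g_snp": g1, "g_sv": g2, "resid": e})
        )
    return PhenotypeTable(values=pd.DataFrame(values), components=pd.concat(comp_rows, ignore_index=True))


def _as_codes(g):
    return g.codes if isinstance(g, GenotypeMatrix) else g


def _component(x: np.ndarray, causal_fraction: float, rng: np.random.Generator) -> np.ndarray:
    m = x.shape[1]
    n_causal = max(1, int(round(causal_fraction * m)))
    cols = rng.choice(m, size=n_causal, replace=False)
    beta = rng.normal(size=n_causal)
    xc = x[:, cols] - x[:, cols].mean(axis=0)
    return xc @ beta


def simulate_dataset(config: SimConfig) -> SyntheticDataset:
    """Full synthetic dataset: genotypes, depth-filtered SVs, phenotypes, links."""
    rng = np.random.default_rng(config.seed)
    pool = simulate_haplotypes(config, rng)
    m = pool.n_markers
    n = config.n_individuals

    fracs = np.array(list(config.breed_fractions), dtype=float)
    weights = np.array([config.breed_fractions[f] for f in fracs], dtype=float)
    weights /= weights.sum()
    breed_frac = fracs[rng.choice(fracs.size, size=n, p=weights)]
    sex = np.where(rng.random(n) < 0.5, "M", "F")

    # haplotype breed origin: each of the two haplotypes is Holstein (breed 1)
    # with probability equal to the individual's Holstein fraction
    origin = rng.random((n, 2)) < breed_frac[:, None]
    haps = np.empty((n, 2, m), dtype=np.int8)
    for breed in (0, 1):
        mask = origin == breed
        count = int(mask.sum())
        if count:
            drawn = _draw_mosaics(pool.founders[breed], pool.p_switch, count, rng)
            haps[mask] = drawn

    samples = [
        SampleInfo(id=f"ind{i}", sex=str(sex[i]), breed_fraction=float(breed_frac[i]))
        for i in range(n)
    ]

    # sire-son pairs: sires are the first block, sons the second; the son's
    # paternal haplotype is a recombinant gamete from the sire
    for k in range(config.n_sire_son_pairs):
        sire, son = k, config.n_sire_son_pairs + k
        samples[sire].sex = "M"
        samples[son].sire_id = samples[sire].id
        haps[son, 0] = _recombine(haps[sire, 0], haps[sire, 1], pool, rng)
        samples[son].breed_fraction = samples[sire].breed_fraction
        breed_frac[son] = breed_frac[sire]

    geno = haps.sum(axis=1, dtype=np.int8)
    sample_ids = [s.id for s in samples]

    # twice-sequenced duplicates: same DNA, appended as extra rows
    dup_idx = rng.choice(n, size=min(config.n_duplicates, n), replace=False)
    for i in dup_idx:
        orig = samples[i]
        samples.append(
            SampleInfo(
                id=f"{orig.id}_rep",
                sex=orig.sex,
                breed_fraction=orig.breed_fraction,
                duplicate_of=orig.id,
            )
        )
    all_ids = [s.id for s in samples]
    geno_all = np.vstack([geno, geno[dup_idx]])
    haps_all = np.concatenate([haps, haps[dup_idx]], axis=0)

    snp_gm = GenotypeMatrix(
        codes=geno_all[:, pool.snp_cols],
        sample_ids=all_ids,
        marker_ids=list(pool.snp_map["id"]),
    )
    sv_truth = GenotypeMatrix(
        codes=geno_all[:, pool.sv_cols],
        sample_ids=all_ids,
        marker_ids=list(pool.sv_map["id"]),
    )
    sv_gm, miss_rate = apply_depth_missingness(
        sv_truth, config.depth_mean, threshold=config.depth_threshold, rng=rng
    )

    ds = SyntheticDataset(
        config=config,
        snp_genotypes=snp_gm,
        sv_genotypes=sv_gm,
        sv_truth=sv_truth,
        snp_map=pool.snp_map,
        sv_map=pool.sv_map,
        samples=samples,
        phenotypes=PhenotypeTable(values=pd.DataFrame({"id": sample_ids}), components=pd.DataFrame()),
        haplotypes=haps_all,
        pool=pool,
        sv_missing_rate=miss_rate,
    )
    ds.phenotypes = simulate_phenotypes(
        ds,
        prop_var_snp=config.prop_var_snp,
        prop_var_sv=config.prop_var_sv,
        n_traits=config.n_traits,
        seed=int(rng.integers(2**31 - 1)),
        causal_fraction=config.causal_fraction,
        breed_effect=config.breed_effect,
    )
    return ds


def expected_missing_rate(depth_mean: float, threshold: int = 5) -> float:
    """Closed-form Poisson missingness rate: P(depth < threshold)."""
    return float(stats.poisson.cdf(threshold - 1, depth_mean))
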