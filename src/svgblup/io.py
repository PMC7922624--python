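"""Readers and writers for the pipeline's on-disk formats.

Dosage matrices, marker maps (BED-like, 0-based half-open), phenotypes,
sample metadata and GRMs travel as TSV for inspectability; SV genotype
calls cross the boundary as VCF (POS/INFO:END 1-based inclusive on disk,
converted to half-open internally). All writers round-trip bit-exactly
with their readers.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import MISSING, GenotypeMatrix
from .relmat import GRM
from .sv_catalog import SVRecord

MAP_COLUMNS = ["chrom", "start", "end", "id", "type"]


# ---------------------------------------------------------------- TSV tables

def write_dosage_tsv(gm: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(gm.codes, index=gm.sample_ids, columns=gm.marker_ids)
    df.to_csv(path, sep="\t", index_label="id")


def read_dosage_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col="id")
    return GenotypeMatrix(
        codes=df.to_numpy(dtype=np.int8),
        sample_ids=[str(s) for s in df.index],
        marker_ids=[str(c) for c in df.columns],
    )


def write_marker_map(df: pd.DataFrame, path) -> None:
    df[MAP_COLUMNS].to_csv(path, sep="\t", index=False)


def read_marker_map(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "id": str, "type": str})
    missing = set(MAP_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"marker map missing columns {sorted(missing)}")
    return df


def write_phenotypes(values: pd.DataFrame, path) -> None:
    values.to_csv(path, sep="\t", index=False)


def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"id": str})


def write_samples(samples, path) -> None:
    rows = [
        {
            "id": s.id,
            "sex": s.sex,
            "breed_fraction": s.breed_fraction,
            "sire_id": s.sire_id or "",
            "duplicate_of": s.duplicate_of or "",
        }
        for s in samples
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_samples(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"id": str}, keep_default_na=False)
    return df


# --------------------------------------------------------------------- GRMs

def write_grm_tsv(grm: GRM, path) -> None:
    df = pd.DataFrame(grm.matrix, index=grm.sample_ids, columns=grm.sample_ids)
    df.to_csv(path, sep="\t", index_label="id")


def read_grm_tsv(path) -> GRM:
    df = pd.read_csv(path, sep="\t", index_col="id")
    a = df.to_numpy(dtype=float)
    a = (a + a.T) / 2.0
    return GRM(
        matrix=a,
        sample_ids=[str(s) for s in df.index],
        n_markers=0,
        freqs=np.array([]),
        kept_markers=np.array([], dtype=int),
    )


def write_grm_bin(grm: GRM, prefix) -> None:
    """Compact lower-triangle float64 binary plus an id sidecar."""
    prefix = Path(prefix)
    n = len(grm.sample_ids)
    tri = grm.matrix[np.tril_indices(n)]
    tri.astype("<f8").tofile(prefix.with_suffix(".grm.bin"))
    prefix.with_suffix(".grm.id").write_text("\n".join(grm.sample_ids) + "\n")


def read_grm_bin(prefix) -> GRM:
    prefix = Path(prefix)
    ids = prefix.with_suffix(".grm.id").read_text().splitlines()
    n = len(ids)
    tri = np.fromfile(prefix.with_suffix(".grm.bin"), dtype="<f8")
    if tri.size != n * (n + 1) // 2:
        raise ValueError("GRM binary size does not match id sidecar")
    a = np.zeros((n, n))
    a[np.tril_indices(n)] = tri
    a = a + np.tril(a, -1).T
    return GRM(matrix=a, sample_ids=ids, n_markers=0, freqs=np.array([]), kept_markers=np.array([], dtype=int))


# ---------------------------------------------------------------------- VCF

def read_genotype_vcf(path):
    """Read a VCF into codes {0,1,2,5}, depths and a marker map.

    Missing GT becomes code 5. SV records (INFO/SVTYPE present) get their
    1-based inclusive POS/END converted to 0-based half-open intervals;
    plain variants become 1-bp intervals. Returns
    ``(GenotypeMatrix, map DataFrame)``.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    codes_rows, depth_rows, map_rows = [], [], []
    for rec_no, rec in enumerate(vcf, start=1):
        try:
            gts = rec.gt_types  # 0=hom-ref 1=het 2=unknown 3=hom-alt
            row = np.select([gts == 0, gts == 1, gts == 3], [0, 1, 2], default=MISSING)
            dp = rec.format("DP")
            depth_rows.append(dp[:, 0].astype(int) if dp is not None else np.full(len(samples), -1))
            svtype = rec.INFO.get("SVTYPE")
            end = rec.INFO.get("END")
            start0 = rec.POS - 1
            if svtype is not None:
                end0 = int(end) if end is not None else start0 + max(len(rec.REF), 1)
                mtype = str(svtype)
                if mtype == "INS":
                    end0 = start0 + 1
            else:
                end0 = start0 + 1
                mtype = "SNP"
            map_rows.append(
                {
                    "chrom": rec.CHROM,
                    "start": start0,
                    "end": end0,
                    "id": rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}",
                    "type": mtype,
                }
            )
            codes_rows.append(row)
        except Exception as exc:  # pragma: no cover - malformed input path
            raise ValueError(f"malformed VCF record #{rec_no} in {path}: {exc}") from exc
    codes = np.array(codes_rows, dtype=np.int8).T
    depth = np.array(depth_rows, dtype=int).T
    marker_map = pd.DataFrame(map_rows)
    gm = GenotypeMatrix(
        codes=codes,
        sample_ids=samples,
        marker_ids=list(marker_map["id"]),
        depth=depth if (depth >= 0).any() else None,
    )
    return gm, marker_map


_CODE_TO_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_sv_vcf(gm: GenotypeMatrix, marker_map: pd.DataFrame, path) -> None:
    """Write SV genotypes as a minimal VCF 4.2 with GT:DP and END/SVTYPE."""
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=END,Number=1,Type=Integer,Description="End position">',
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
    ]
    for chrom in dict.fromkeys(marker_map["chrom"]):
        lines.append(f"##contig=<ID={chrom}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(gm.sample_ids))
    for j, row in enumerate(marker_map.itertuples()):
        pos = int(row.start) + 1  # back to 1-based
        info = f"END={int(row.end)};SVTYPE={row.type}"
        alt = f"<{row.type}>"
        fields = []
        for i in range(gm.n_individuals):
            dp = int(gm.depth[i, j]) if gm.depth is not None else 0
            fields.append(f"{_CODE_TO_GT[int(gm.codes[i, j])]}:{dp}")
        lines.append(
            f"{row.chrom}\t{pos}\t{row.id}\tN\t{alt}\t.\t.\t{info}\tGT:DP\t" + "\t".join(fields)
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ------------------------------------------------------------------- config

def load_config(path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text)
    if path.suffix == ".json":
        return json.loads(text)
    raise ValueError(f"unknown config format {path.suffix!r}")


def save_config(config: dict, path) -> None:
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(config, sort_keys=False))
    elif path.suffix == ".json":
        path.write_text(json.dumps(config, indent=2, sort_keys=True))
    else:
        raise ValueError(f"unknown config format {path.suffix!r}")
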