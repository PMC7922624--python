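"""Merge SV calls from two callers and build validation sets.

Two caller outputs are merged by >= 1 bp same-type overlap, intersected
with a trusted target set, and validated against twice-sequenced
duplicates and sire-son pairs from a simulated cohort.
"""

import svgblup as sg
from svgblup.sv_catalog import SVRecord

caller_a = [
    SVRecord("chr1", 100, 2_000, "DEL", ("breakdancer",)),
    SVRecord("chr1", 10_000, 12_500, "INV", ("breakdancer",)),
    SVRecord("chr2", 500, 900, "DEL", ("breakdancer",)),
]
caller_b = [
    SVRecord("chr1", 1_999, 3_200, "DEL", ("pindel",)),   # 1 bp overlap -> merges
    SVRecord("chr1", 12_500, 13_000, "INV", ("pindel",)),  # touching, 0 bp -> separate
    SVRecord("chr2", 5_000, 5_400, "DUP", ("pindel",)),
]
merged = sg.merge_sv_calls(caller_a, caller_b)
print(f"{len(caller_a)} + {len(caller_b)} calls merge into {len(merged)} records:")
for r in merged:
    print(f"  {r.chrom}:{r.start}-{r.end} {r.sv_type} from {'+'.join(r.source)}")

target = [SVRecord("chr1", 0, 5_000, "DEL", ("target",))]
kept = sg.intersect_with_target(merged, target)
print(f"kept after target intersection: {len(kept)} (calls without target support are dropped)")

# validation sets from a simulated cohort with duplicates and sire-son pairs
ds = sg.simulate_dataset(sg.SimConfig(n_individuals=200, n_snp=800, n_sv=40, n_chrom=2,
                                      n_sire_son_pairs=12, n_duplicates=8, seed=2))
sets = sg.build_validation_sets(ds.sv_calls_by_sample(use_truth=True), ds.samples)
print(f"TWICE_SEQ: {len(sets['TWICE_SEQ'])} SVs seen in both replicates of a duplicate")
print(f"FAM:       {len(sets['FAM'])} SVs seen in both members of a sire-son pair")
# Requiring the SV in both members of a pair removes unreplicated calls,
# enriching the catalog for true transmissible variants.
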