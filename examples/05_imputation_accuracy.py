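"""Fivefold masking cross-validation of SV imputation accuracy.

Each fold's SV genotypes are masked and re-imputed from the flanking-SNP
reference; accuracy is the squared correlation between imputed dosage and
true code, summarised against the 0.5 and 0.8 thresholds and by MAF bin.
"""

import svgblup as sg

cfg = sg.SimConfig(n_individuals=400, n_snp=2000, n_sv=150, n_chrom=3,
                   ld_rho=2e-6, seed=5)
ds = sg.simulate_dataset(cfg)
plan = sg.make_folds(len(ds.samples), k=5, seed=0)

_, acc = sg.run_masking_cv(ds.snp_genotypes, ds.sv_truth, ds.snp_map, ds.sv_map,
                           plan, anchor="start", w=20)
print(sg.threshold_summary(acc).to_string(index=False))
selected = sg.select_svs(acc, min_r2=0.5)
print(f"{len(selected)} of {len(acc)} SVs selected at accuracy > 0.5")

binned = sg.accuracy_by_maf(acc)
print(binned[binned.n > 0].to_string(index=False))
# Accuracy rises with MAF: rare SVs sit on few reference haplotypes and are
# hard to impute, which is why a MAF-dependent share of SVs survives the
# accuracy filter.
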