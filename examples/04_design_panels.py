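"""The full panel-design cascade: split, select, thin, filter, multiplex.

Sets aside a 25% holdout, finds fixed SNPs on the training scan, thins
them to >= 5 kb spacing with functional priority, applies the
flank-quality filters, and packs the survivors into four disjoint
multiplex panels of at most 40 SNPs plus size-matched random assays.
"""

import warnings

from introgress_panel import (
    SimConfig,
    annotate_loci,
    apply_flank_filters,
    assemble_multiplexes,
    build_random_assays,
    find_fixed,
    fst_scan,
    generate_dataset,
    split_train_holdout,
    thin_by_distance,
)

cfg = SimConfig(n_M=117, n_C=59, n_loci=20_000, seed=5)
ds = annotate_loci(generate_dataset(cfg), cfg)

split = split_train_holdout(ds, holdout_fraction=0.25, seed=0)
print(f"training {len(split['training'])}, holdout {len(split['holdout'])}")

train_m = ds.sample_indices(lineage="M", role="training")
train_c = ds.sample_indices(lineage="C", role="training")
fixed = find_fixed(fst_scan(ds, train_m, train_c))
print(f"fixed SNPs in the training scan: {len(fixed)}")

index = ds.locus_index()
fixed_sorted = sorted((ds.loci[index[l]] for l in fixed),
                      key=lambda l: (l.chrom, l.pos))
thinned = thin_by_distance(fixed_sorted, min_bp=5_000)
candidates, removed = apply_flank_filters(
    [ds.loci[index[l]] for l in sorted(thinned)])
print(f"after 5 kb thinning: {len(thinned)}; after flank filters: "
      f"{len(candidates)} (removed per rule: {removed})")

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    panels = assemble_multiplexes(ds, candidates, n_panels=4, max_size=40,
                                  min_functional=4, seed=0)
randoms = build_random_assays(ds, [p.size for p in panels], seed=0)

for p in panels:
    a = p.audit
    print(f"{p.name}: {a['size']} SNPs, {len(a['chroms_covered'])} chromosomes, "
          f"{a['n_functional']} functional, disjoint from {a['disjoint_from']}")
# each panel covers every chromosome it can, carries >= 4 putative
# functional SNPs, and shares no SNP with any other panel — the three
# multiplex constraints of the design.
print("random assay sizes:", [p.size for p in randoms])
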