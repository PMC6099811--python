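"""End-to-end orchestration of the panel-design workflow.

Stages, in order: simulate a two-lineage dataset -> screen sample purity
(unsupervised K=2 on a locus subsample) -> stratified training/holdout
split -> fixed-SNP selection on the training scan -> distance thinning and
flank filters -> multiplex assembly plus size-matched random assays ->
hybrid simulation from holdout parents -> whole-genome reference Q
(supervised, training frequencies) -> per-panel validation report.

Every stage draws from a named substream of the master seed, writes its
artifacts into the run directory, and logs in/out counts, so any number in
the final report is recomputable from the emitted intermediates.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import core_io
from .ancestry import estimate_q_supervised, orient_and_classify, fit_admixture
from .core_io import HaploidDataset, RecombinationMap, write_dataset, write_metadata
from .fst import find_fixed, fst_scan
from .hybrid_sim import simulate_hybrids, write_tracts_bed, write_truth_table
from .panel_design import (
    apply_flank_filters,
    assemble_multiplexes,
    build_random_assays,
    split_train_holdout,
    thin_by_distance,
)
from .sampling_bias import size_scan
from .synthetic import SimConfig, annotate_loci, generate_dataset
from .validation import panel_benchmark, reports_frame

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Configuration of a full run; defaults are the canonical design values.

    The simulated population sizes default to the study scale (117 focal M,
    59 reference C) so the 25% holdout split yields the 29 + 15 individuals
    the hybrid design consumes (15 F1 parents + 14 BC1 parents; 15 C
    parents).
    """

    sim: SimConfig = field(default_factory=lambda: SimConfig(n_M=117, n_C=59))
    holdout_fraction: float = 0.25
    min_bp: int = 5_000
    max_flank_variable: int = 5
    max_flank_n_run: int = 5
    n_panels: int = 4
    max_panel_size: int = 40
    min_functional: int = 4
    n_f1: int = 15
    n_bc1: int = 14
    recomb_rate_cM_per_Mb: float = 20.0
    recomb_window_bp: int = 100_000
    em_K: int = 2
    em_tol: float = 1e-4
    n_boot: int = 200
    q_hi: float = 0.95
    q_lo: float = 0.05
    screen_n_loci: int = 3_000
    bias_sizes: tuple[int, ...] = (5, 10, 25, 50, 75, 100)
    bias_reps: int = 5
    run_bias_scan: bool = True
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["bias_sizes"] = list(self.bias_sizes)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @staticmethod
    def from_yaml(path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        sim = SimConfig(**d.pop("sim", {}))
        if "bias_sizes" in d:
            d["bias_sizes"] = tuple(d["bias_sizes"])
        return PipelineConfig(sim=sim, **d)


class _RunLog:
    def __init__(self) -> None:
        self.stages: list[dict] = []
        self._t0 = time.time()

    def stage(self, name: str, **counts) -> None:
        self.stages.append(
            dict(stage=name, elapsed_s=round(time.time() - self._t0, 3), **counts)
        )

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(self.stages, indent=2))


def run_pipeline(cfg: PipelineConfig, outdir: str | Path) -> dict:
    """Run the full workflow; returns a summary dict of headline numbers."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    log = _RunLog()
    cfg.to_yaml(out / "config.yaml")
    seed = cfg.seed

    # -- stage 1: simulate -------------------------------------------------
    ds = annotate_loci(generate_dataset(cfg.sim), cfg.sim)
    write_dataset(ds, out / "dataset.vcf")
    write_metadata(ds.samples, out / "samples.tsv")
    log.stage("simulate", n_samples=ds.n_samples, n_loci=ds.n_loci,
              genotyping_rate=round(ds.genotyping_rate(), 4))

    # -- stage 2: purity screen -------------------------------------------
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    screen_cols = sorted(
        rng.choice(ds.n_loci, size=min(cfg.screen_n_loci, ds.n_loci),
                   replace=False).tolist()
    )
    screen_ds = ds.subset_loci([ds.loci[j].locus_id for j in screen_cols])
    fit = fit_admixture(screen_ds, K=cfg.em_K, tol=cfg.em_tol, seed=seed)
    c_refs = ds.sample_indices(lineage="C")
    c_anc, purity = orient_and_classify(fit, c_refs, cfg.q_hi, cfg.q_lo)
    impure = [
        ds.samples[i].sample_id
        for i in range(ds.n_samples)
        if (ds.samples[i].lineage == "M" and purity[i] != "pure_M")
        or (ds.samples[i].lineage == "C" and purity[i] != "pure_C")
    ]
    core_io.write_q_matrix(fit.Q, out / "purity_screen.Q")
    log.stage("purity_screen", n_screen_loci=screen_ds.n_loci,
              n_impure=len(impure))

    # -- stage 3: split ----------------------------------------------------
    split = split_train_holdout(ds, cfg.holdout_fraction, seed=seed)
    write_metadata(ds.samples, out / "samples.tsv")  # roles now filled in
    log.stage("split", n_training=len(split["training"]),
              n_holdout=len(split["holdout"]))

    train_M = ds.sample_indices(lineage="M", role="training")
    train_C = ds.sample_indices(lineage="C", role="training")
    hold_M = ds.sample_indices(lineage="M", role="holdout")
    hold_C = ds.sample_indices(lineage="C", role="holdout")

    # -- stage 4: fixed-SNP selection on training data ---------------------
    train_table = fst_scan(ds, train_M, train_C)
    train_table.write(out / "fst_training.tsv")
    fixed = find_fixed(train_table)
    log.stage("fixed_snps", n_fixed=len(fixed),
              genomewide_fst=round(train_table.genomewide_ratio_of_sums, 4))
    if not fixed:
        raise RuntimeError(
            "panel design aborted at the selection stage: no fixed SNPs found "
            f"(artifacts so far in {out})"
        )

    # -- stage 5: thinning + flank filters ---------------------------------
    index = ds.locus_index()
    fixed_loci = sorted((ds.loci[index[lid]] for lid in fixed),
                        key=lambda l: (l.chrom, l.pos))
    thinned = thin_by_distance(fixed_loci, min_bp=cfg.min_bp)
    flank_ok, removal = apply_flank_filters(
        [ds.loci[index[lid]] for lid in sorted(thinned)],
        max_variable=cfg.max_flank_variable, max_n_run=cfg.max_flank_n_run,
    )
    log.stage("filters", n_fixed=len(fixed), n_after_thinning=len(thinned),
              n_after_flank=len(flank_ok), **{f"removed_{k}": v
                                              for k, v in removal.items()})

    # -- stage 6: panels ---------------------------------------------------
    panels = assemble_multiplexes(
        ds, flank_ok, n_panels=cfg.n_panels, max_size=cfg.max_panel_size,
        min_functional=cfg.min_functional, seed=seed,
    )
    randoms = build_random_assays(ds, [p.size for p in panels], seed=seed)
    for p in panels + randoms:
        core_io.write_panel(p, ds, out / f"panel_{p.name}.tsv",
                            out / f"panel_{p.name}.bed")
    log.stage("panels", sizes=[p.size for p in panels])

    # -- stage 7: hybrids --------------------------------------------------
    rmap = RecombinationMap.uniform(
        cfg.sim.n_chroms, cfg.sim.chrom_length_bp, cfg.recomb_rate_cM_per_Mb,
        cfg.recomb_window_bp,
    )
    core_io.write_recomb_map(rmap, out / "recomb_map.tsv")
    hybrid_records, hybrid_ds = simulate_hybrids(
        ds, hold_M, hold_C, rmap, seed=seed, n_f1=cfg.n_f1, n_bc1=cfg.n_bc1,
    )
    write_truth_table(hybrid_records, out / "hybrid_truth.tsv")
    write_tracts_bed(hybrid_records, out / "hybrid_tracts.bed")
    log.stage("hybrids", n_f1=sum(r.generation == "F1" for r in hybrid_records),
              n_bc1=sum(r.generation == "BC1" for r in hybrid_records))

    # -- stage 8: evaluation dataset + reference Q -------------------------
    eval_rows = np.concatenate([hold_M, hold_C])
    eval_ds = ds.subset_samples(eval_rows.tolist())
    eval_ds = HaploidDataset(
        samples=eval_ds.samples + hybrid_ds.samples,
        loci=eval_ds.loci,
        calls=np.vstack([eval_ds.calls, hybrid_ds.calls]),
    )
    write_dataset(eval_ds, out / "evaluation.vcf")
    write_metadata(eval_ds.samples, out / "evaluation_samples.tsv")
    # supervised whole-genome reference Q from training allele frequencies
    _, alt_M = _freqs(ds, train_M)
    _, alt_C = _freqs(ds, train_C)
    F_ref = np.vstack([alt_C, alt_M])  # cluster 1 = C, so q = C ancestry
    truth_q = np.array([
        estimate_q_supervised(eval_ds.calls[i], F_ref)[0]
        for i in range(eval_ds.n_samples)
    ])
    np.savetxt(out / "truth_q.txt", truth_q, fmt="%.6f")
    log.stage("reference_q", n_eval_samples=eval_ds.n_samples)

    # -- stage 9: validation ----------------------------------------------
    c_ref_rows = [i for i, s in enumerate(eval_ds.samples) if s.lineage == "C"]
    combos = [["M3", "M4"], ["M1", "M3", "M4"], ["M1", "M2", "M3", "M4"],
              ["R3", "R4"], ["R1", "R3", "R4"], ["R1", "R2", "R3", "R4"]]
    reports = panel_benchmark(
        eval_ds, panels + randoms, truth_q, c_ref_rows,
        combinations=combos, n_boot=cfg.n_boot, seed=seed, k=cfg.em_K,
    )
    frame = reports_frame(reports)
    frame.to_csv(out / "performance.tsv", sep="\t", index=False)
    log.stage("validation", n_reports=len(reports))

    # -- stage 10: bias scans (optional) -----------------------------------
    if cfg.run_bias_scan:
        sizes = [s for s in cfg.bias_sizes if s <= len(train_M) + len(hold_M)]
        rows_df, summary = size_scan(ds, "M", "C", sizes=sizes,
                                     reps=cfg.bias_reps, seed=seed)
        rows_df.to_csv(out / "bias_size_scan.tsv", sep="\t", index=False)
        summary.to_csv(out / "bias_size_summary.tsv", sep="\t", index=False)
        log.stage("bias_scan", n_rows=len(rows_df))

    log.write(out / "run_log.json")
    best = frame.loc[frame["mean_accuracy_pct"].idxmax()]
    return dict(
        n_fixed_training=len(fixed),
        n_candidates=len(flank_ok),
        panel_sizes=[p.size for p in panels],
        n_hybrids=len(hybrid_records),
        best_assay=str(best["assay"]),
        best_accuracy_pct=float(best["mean_accuracy_pct"]),
        outdir=str(out),
    )


def _freqs(ds: HaploidDataset, rows: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    from .fst import group_counts

    n, alt = group_counts(ds, rows)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n > 0, alt / np.maximum(n, 1), 0.5)
    return n, p
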