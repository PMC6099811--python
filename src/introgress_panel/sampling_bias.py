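"""Sampling-bias experiments for fixed-SNP discovery.

A locus can look fixed (F_ST = 1) in a small or geographically narrow
subsample while segregating in the full population — a false-positive
ancestry-informative marker. This module quantifies that bias two ways,
mirroring the study design the package implements:

* ``size_scan``: subsample the focal population at a ladder of sample sizes
  (default N = 5, 10, 25, 50, 75, 100; five replicates each), count fixed
  SNPs against the full reference set, and compare against the fixed set of
  the complete focal sample.
* ``region_scan``: subsample a fixed number of individuals from single
  geographic regions versus the whole range, with the same accounting.

For each subset, false positives are the loci fixed in the subset scan but
not in the full-sample scan; each is annotated with its full-data theta, so
the output reports how badly a panel built from the biased subset would
overestimate marker informativeness (percentage of false positives whose
full-data theta <= 0.95, and the minimum full-data theta).

Counts are computed set-wise rather than by subtracting totals: with missing
data a locus can be defined in the subset but undefined in the full scan, and
plain subtraction would miscount. On complete-case data the two agree.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import substream
from .core_io import HaploidDataset
from .fst import FstTable, find_fixed, fst_scan

__all__ = ["size_scan", "region_scan", "false_positive_stats"]

#: Region label meaning "the whole focal range" in region_scan.
WHOLE_RANGE = "IP"


def false_positive_stats(
    subset_fixed: set[str], full_fixed: set[str], full_table: FstTable
) -> dict:
    """False-positive set and its full-data theta summary for one subset."""
    fp = subset_fixed - full_fixed
    theta = full_table.theta_by_locus()
    fp_theta = np.array([theta[lid] for lid in fp], dtype=float)
    fp_theta = fp_theta[~np.isnan(fp_theta)]
    if fp_theta.size:
        pct_le = 100.0 * float((fp_theta <= 0.95).mean())
        min_theta = float(fp_theta.min())
    else:
        pct_le = 0.0
        min_theta = float("nan")
    return dict(
        n_fixed_subset=len(subset_fixed),
        n_false_positive=len(fp),
        pct_fp_theta_le_095=pct_le,
        min_full_theta=min_theta,
        false_positives=fp,
    )


def _scan_fixed(ds: HaploidDataset, rows: np.ndarray, ref: np.ndarray) -> set[str]:
    return find_fixed(fst_scan(ds, rows, ref))


def size_scan(
    ds: HaploidDataset,
    focal: str,
    reference: str,
    sizes: Sequence[int] = (5, 10, 25, 50, 75, 100),
    reps: int = 5,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fixed-SNP counts from random focal subsamples of increasing size.

    ``focal`` and ``reference`` are lineage labels ("M", "C"). Returns
    ``(rows, summary)``: one row per size x replicate with false-positive
    accounting, and a per-size summary with the mean fixed count and a
    t-based 95% confidence interval across replicates.

    Each (size, replicate) cell draws from its own named substream, so
    adding replicates or sizes never changes earlier draws.
    """
    focal_idx = ds.sample_indices(lineage=focal)
    ref_idx = ds.sample_indices(lineage=reference)
    if max(sizes) > focal_idx.size:
        raise ValueError(
            f"requested subset size {max(sizes)} exceeds focal population "
            f"size {focal_idx.size}"
        )
    if reps < 1:
        raise ValueError("reps must be >= 1")

    full_table = fst_scan(ds, focal_idx, ref_idx)
    full_fixed = find_fixed(full_table)

    records = []
    for size in sizes:
        for rep in range(reps):
            rng = substream(seed, "size_scan", size, rep)
            rows = rng.choice(focal_idx, size=size, replace=False)
            fp = false_positive_stats(
                _scan_fixed(ds, rows, ref_idx), full_fixed, full_table
            )
            records.append(
                dict(subset_label=f"N={size}", size=size, replicate=rep,
                     n_fixed_subset=fp["n_fixed_subset"],
                     n_false_positive=fp["n_false_positive"],
                     pct_fp_theta_le_095=fp["pct_fp_theta_le_095"],
                     min_full_theta=fp["min_full_theta"])
            )
    rows_df = pd.DataFrame(records)

    summaries = []
    for size, grp in rows_df.groupby("size"):
        vals = grp["n_fixed_subset"].to_numpy(dtype=float)
        mean = float(vals.mean())
        if len(vals) > 1 and vals.std(ddof=1) > 0:
            half = float(
                stats.t.ppf(0.975, len(vals) - 1)
                * vals.std(ddof=1) / np.sqrt(len(vals))
            )
        else:
            half = 0.0
        summaries.append(
            dict(size=size, mean_n_fixed=mean, ci95_half_width=half,
                 mean_n_false_positive=float(grp["n_false_positive"].mean()),
                 mean_pct_fp_theta_le_095=float(grp["pct_fp_theta_le_095"].mean()),
                 mean_min_full_theta=float(grp["min_full_theta"].mean()))
        )
    return rows_df, pd.DataFrame(summaries).sort_values("size").reset_index(drop=True)


def region_scan(
    ds: HaploidDataset,
    regions: Sequence[str],
    subset_size: int = 25,
    focal: str = "M",
    reference: str = "C",
    seed: int = 0,
) -> pd.DataFrame:
    """Fixed-SNP counts from geographically restricted focal subsets.

    ``regions`` are region tags; the special label ``"IP"`` selects from the
    whole focal range. One subset of ``subset_size`` individuals is drawn per
    region, and false positives are counted against the full-sample scan.
    """
    focal_idx = ds.sample_indices(lineage=focal)
    ref_idx = ds.sample_indices(lineage=reference)
    full_table = fst_scan(ds, focal_idx, ref_idx)
    full_fixed = find_fixed(full_table)

    records = []
    for region in regions:
        if region == WHOLE_RANGE:
            pool = focal_idx
        else:
            pool = ds.sample_indices(lineage=focal, region_tag=region)
        if pool.size < subset_size:
            raise ValueError(
                f"region {region!r} has {pool.size} focal samples, "
                f"fewer than subset_size={subset_size}"
            )
        rng = substream(seed, "region_scan", region)
        rows = rng.choice(pool, size=subset_size, replace=False)
        fp = false_positive_stats(
            _scan_fixed(ds, rows, ref_idx), full_fixed, full_table
        )
        records.append(
            dict(subset_label=region, replicate=0,
                 n_fixed_subset=fp["n_fixed_subset"],
                 n_false_positive=fp["n_false_positive"],
                 pct_fp_theta_le_095=fp["pct_fp_theta_le_095"],
                 min_full_theta=fp["min_full_theta"])
        )
    return pd.DataFrame(records)
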