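"""Panel performance metrics against reference ("true") ancestry values.

``compare_q`` measures how well panel-based C-ancestry estimates reproduce
a reference Q vector (whole-genome estimates or simulated truth) with the
eight-statistic suite used to benchmark reduced assays:

(i)    Pearson's r with a Fisher-z 95% CI,
(ii)   mean bootstrap standard error (if supplied),
(iii)  mean absolute error,
(iv)   number of individuals with error > 0.05,
(v)    maximum error,
(vi)   mean accuracy as a percentage, defined as mean of 100*(1 - |error|)
       — so mean_accuracy_pct = 100 - 100*mean_error identically,
(vii)  precision = standard deviation of the absolute error,
(viii) misclassifications at the 0.05/0.95 purity thresholds, counted both
       ways (true-pure estimated hybrid, true-hybrid estimated pure).

``panel_benchmark`` runs the full estimate-and-compare loop for a list of
panels and panel combinations (locus-set unions).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ancestry import bootstrap_se, fit_admixture, orient_and_classify
from .core_io import HaploidDataset
from .panel_design import PanelDefinition

__all__ = ["PerformanceReport", "compare_q", "panel_benchmark"]


@dataclass
class PerformanceReport:
    """Eight-statistic performance summary for one panel (or combination)."""

    name: str
    n_snps: int
    n_samples: int
    pearson_r: float
    pearson_ci: tuple[float, float]
    mean_boot_se: float
    mean_error: float
    n_error_gt_005: int
    max_error: float
    mean_accuracy_pct: float
    precision_sd: float
    n_pure_as_hybrid: int
    n_hybrid_as_pure: int

    def to_row(self) -> dict:
        return dict(
            assay=self.name, n_snps=self.n_snps,
            pearson_r=self.pearson_r,
            pearson_ci_low=self.pearson_ci[0], pearson_ci_high=self.pearson_ci[1],
            mean_boot_se=self.mean_boot_se, mean_error=self.mean_error,
            n_error_gt_005=self.n_error_gt_005, max_error=self.max_error,
            mean_accuracy_pct=self.mean_accuracy_pct,
            precision_sd=self.precision_sd,
            n_pure_as_hybrid=self.n_pure_as_hybrid,
            n_hybrid_as_pure=self.n_hybrid_as_pure,
        )


def _fisher_ci(r: float, n: int, level: float = 0.95) -> tuple[float, float]:
    if n < 4 or not np.isfinite(r) or abs(r) >= 1.0:
        return (float("nan"), float("nan"))
    z = np.arctanh(r)
    half = stats.norm.ppf(0.5 + level / 2) / np.sqrt(n - 3)
    return (float(np.tanh(z - half)), float(np.tanh(z + half)))


def compare_q(
    q_est: np.ndarray,
    q_true: np.ndarray,
    boot_se: np.ndarray | None = None,
    q_threshold: float = 0.05,
    error_threshold: float = 0.05,
    name: str = "panel",
) -> PerformanceReport:
    """Compare estimated against reference C-ancestry values.

    A sample is "true pure" when its reference value lies below
    ``q_threshold`` or above ``1 - q_threshold``, and "estimated pure" by
    the same rule on the estimate; the two misclassification counts use
    these classes crosswise. Pearson r is NA (with a warning) when either
    vector is constant.
    """
    q_est = np.asarray(q_est, dtype=float)
    q_true = np.asarray(q_true, dtype=float)
    if q_est.shape != q_true.shape or q_est.ndim != 1:
        raise ValueError("q_est and q_true must be 1-D and the same length")
    if q_est.size < 3:
        raise ValueError("need at least 3 samples")
    if ((q_est < 0) | (q_est > 1) | (q_true < 0) | (q_true > 1)).any():
        raise ValueError("Q values must lie in [0, 1]")

    error = np.abs(q_est - q_true)
    mean_error = float(error.mean())
    # mean over i of 100*(1 - error_i), written in the algebraically equal
    # form that keeps the identity mean_accuracy_pct = 100*(1 - mean_error)
    # exact in floating point
    mean_accuracy = 100.0 * (1.0 - mean_error)
    precision = float(error.std(ddof=1))

    if np.std(q_true) == 0 or np.std(q_est) == 0:
        warnings.warn(f"{name}: constant Q vector, Pearson r undefined",
                      stacklevel=2)
        r, ci = float("nan"), (float("nan"), float("nan"))
    else:
        r = float(stats.pearsonr(q_est, q_true).statistic)
        ci = _fisher_ci(r, q_est.size)

    hi = 1.0 - q_threshold
    true_pure = (q_true < q_threshold) | (q_true > hi)
    est_pure = (q_est < q_threshold) | (q_est > hi)
    n_pure_as_hybrid = int((true_pure & ~est_pure).sum())
    n_hybrid_as_pure = int((~true_pure & est_pure).sum())

    return PerformanceReport(
        name=name,
        n_snps=0,
        n_samples=int(q_est.size),
        pearson_r=r,
        pearson_ci=ci,
        mean_boot_se=float(np.mean(boot_se)) if boot_se is not None else float("nan"),
        mean_error=mean_error,
        n_error_gt_005=int((error > error_threshold).sum()),
        max_error=float(error.max()),
        mean_accuracy_pct=mean_accuracy,
        precision_sd=precision,
        n_pure_as_hybrid=n_pure_as_hybrid,
        n_hybrid_as_pure=n_hybrid_as_pure,
    )


def panel_benchmark(
    ds: HaploidDataset,
    panels: Sequence[PanelDefinition],
    truth_q: np.ndarray,
    reference_c_indices: Sequence[int],
    combinations: Sequence[Sequence[str]] = (),
    n_boot: int = 200,
    seed: int = 0,
    k: int = 2,
    n_restarts: int = 3,
) -> list[PerformanceReport]:
    """Benchmark panels (and unions of panels) on one evaluation dataset.

    For each panel, or union of panels named in ``combinations``, the
    dataset is restricted to the panel loci, an unsupervised K=2 admixture
    fit with bootstrap SEs is run, the fit is oriented with the labelled
    C-lineage reference samples, and the resulting C-ancestry vector is
    compared against ``truth_q``. Set ``n_boot=0`` to skip bootstrapping.
    """
    by_name = {p.name: p for p in panels}
    jobs: list[tuple[str, list[str]]] = [(p.name, list(p.locus_ids)) for p in panels]
    for combo in combinations:
        ids: set[str] = set()
        for name in combo:
            if name not in by_name:
                raise KeyError(f"unknown panel {name!r} in combination")
            ids |= set(by_name[name].locus_ids)
        jobs.append(("+".join(combo), sorted(ids)))

    reports = []
    for name, locus_ids in jobs:
        if not locus_ids:
            raise ValueError(f"panel {name!r} selects no loci")
        sub = ds.subset_loci(locus_ids)
        fit = fit_admixture(sub, K=k, n_restarts=n_restarts, seed=seed)
        se = bootstrap_se(fit, sub, n_boot=n_boot, seed=seed) if n_boot else None
        c_anc, _ = orient_and_classify(fit, reference_c_indices)
        # bootstrap SE is label-symmetric for K=2, no reorientation needed
        rep = compare_q(c_anc, truth_q, boot_se=se, name=name)
        rep.n_snps = sub.n_loci
        reports.append(rep)
    return reports


def reports_frame(reports: Sequence[PerformanceReport]) -> pd.DataFrame:
    return pd.DataFrame([r.to_row() for r in reports])
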