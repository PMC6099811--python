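"""Weir–Cockerham F_ST for haploid samples and fixed-SNP detection.

Haploid individuals contribute one allele each, so the two-population
(r = 2) variance-components estimator works directly on allele indicators:

    p_bar = (n1 p1 + n2 p2) / (n1 + n2)
    MSP   = [n1 (p1 - p_bar)^2 + n2 (p2 - p_bar)^2] / (r - 1)
    MSG   = [n1 p1 (1 - p1) + n2 p2 (1 - p2)] / [(n1 - 1) + (n2 - 1)]
    n_c   = (n - (n1^2 + n2^2) / n) / (r - 1),   n = n1 + n2
    theta = (MSP - MSG) / (MSP + (n_c - 1) MSG)

With this haploid form, opposite fixation (p1, p2 in {0, 1}, p1 != p2)
gives theta = 1 exactly, which is the fixed-SNP (ancestry-informative
marker) criterion. Loci where both populations are fixed for the same
allele have a zero denominator and are reported as undefined (NaN), and
excluded from genomewide summaries.

The genomewide summary is the ratio of sums, sum(MSP - MSG) over
sum(MSP + (n_c - 1) MSG) across defined loci — the "weighted" average that
standard tooling reports as the headline genomewide F_ST. The unweighted
mean of per-locus theta is also provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import MISSING, HaploidDataset

__all__ = ["FstRecord", "FstTable", "wc_theta", "fst_scan", "find_fixed"]


@dataclass
class FstRecord:
    """Per-locus variance components and theta for one two-group comparison."""

    locus_id: str
    n1: int
    n2: int
    p1: float
    p2: float
    msp: float
    msg: float
    theta: float  # NaN when undefined

    @property
    def defined(self) -> bool:
        return not np.isnan(self.theta)


@dataclass
class FstTable:
    """Vector of per-locus F_ST components plus genomewide summaries."""

    locus_ids: list[str]
    n1: np.ndarray
    n2: np.ndarray
    p1: np.ndarray
    p2: np.ndarray
    msp: np.ndarray
    msg: np.ndarray
    num: np.ndarray  # MSP - MSG
    den: np.ndarray  # MSP + (n_c - 1) MSG
    theta: np.ndarray  # NaN = undefined
    chrom: np.ndarray | None = None
    pos: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.locus_ids)

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.theta)

    @property
    def genomewide_ratio_of_sums(self) -> float:
        """Headline genomewide F_ST: sum of numerators over sum of denominators."""
        d = self.defined
        if not d.any():
            return float("nan")
        return float(self.num[d].sum() / self.den[d].sum())

    @property
    def genomewide_mean_of_ratios(self) -> float:
        d = self.defined
        if not d.any():
            return float("nan")
        return float(self.theta[d].mean())

    def record(self, j: int) -> FstRecord:
        return FstRecord(
            locus_id=self.locus_ids[j], n1=int(self.n1[j]), n2=int(self.n2[j]),
            p1=float(self.p1[j]), p2=float(self.p2[j]), msp=float(self.msp[j]),
            msg=float(self.msg[j]), theta=float(self.theta[j]),
        )

    def theta_by_locus(self) -> dict[str, float]:
        return dict(zip(self.locus_ids, self.theta.tolist()))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            dict(locus_id=self.locus_ids, n1=self.n1, n2=self.n2,
                 p1=self.p1, p2=self.p2, theta=self.theta)
        )
        if self.chrom is not None:
            df.insert(1, "chrom", self.chrom)
            df.insert(2, "pos", self.pos)
        return df

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _components(
    n1: np.ndarray, p1: np.ndarray, n2: np.ndarray, p2: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized MSP, MSG, num, den, theta. Undefined entries are NaN."""
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    n = n1 + n2
    with np.errstate(divide="ignore", invalid="ignore"):
        pbar = (n1 * p1 + n2 * p2) / n
        msp = n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2  # / (r-1) with r=2
        msg = (n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)) / (n - 2)
        nc = n - (n1**2 + n2**2) / n  # / (r-1)
        num = msp - msg
        den = msp + (nc - 1) * msg
        theta = num / den
        # Opposite fixation: MSG is exactly 0 and theta exactly 1, even when
        # n1 + n2 = 2 leaves the MSG denominator degenerate (0/0).
        opposite = np.abs(p1 - p2) == 1.0
    msg = np.where(opposite, 0.0, msg)
    num = np.where(opposite, msp, num)
    den = np.where(opposite, msp, den)
    theta = np.where(opposite, 1.0, theta)
    # MSG denominator requires n1 + n2 >= 3; empty group handled by caller
    bad = (~opposite & (n < 3)) | (den == 0) | ~np.isfinite(theta)
    theta = np.where(bad, np.nan, theta)
    num = np.where(bad, np.nan, num)
    den = np.where(bad, np.nan, den)
    return msp, msg, num, den, theta


def wc_theta(n1: int, p1: float, n2: int, p2: float,
             locus_id: str = "locus") -> FstRecord:
    """Weir–Cockerham theta for one locus from haploid allele counts.

    Parameters are the non-missing allele counts and alt-allele frequencies
    of the two populations. Raises on an empty population; returns
    ``theta = NaN`` when the estimator is undefined (both populations fixed
    for the same allele, or n1 + n2 < 3).
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("empty population: n1 and n2 must be >= 1")
    if not (0.0 <= p1 <= 1.0 and 0.0 <= p2 <= 1.0):
        raise ValueError("allele frequencies must lie in [0, 1]")
    msp, msg, num, den, theta = _components(
        np.array([n1]), np.array([p1]), np.array([n2]), np.array([p2])
    )
    return FstRecord(locus_id=locus_id, n1=n1, n2=n2, p1=p1, p2=p2,
                     msp=float(msp[0]), msg=float(msg[0]), theta=float(theta[0]))


def group_counts(ds: HaploidDataset, rows: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Non-missing allele counts and alt counts per locus for a sample subset."""
    sub = ds.calls[np.asarray(rows, dtype=int), :]
    n = (sub != MISSING).sum(axis=0)
    alt = (sub == 1).sum(axis=0)
    return n.astype(np.int64), alt.astype(np.int64)


def fst_scan(
    ds: HaploidDataset,
    group_a: Sequence[int] | np.ndarray,
    group_b: Sequence[int] | np.ndarray,
) -> FstTable:
    """Per-locus Weir–Cockerham scan between two disjoint sample groups.

    Groups are sample indices into the dataset. Only non-missing calls
    contribute; loci with zero non-missing calls in either group are
    flagged undefined and excluded from the genomewide summaries.
    """
    a = np.asarray(group_a, dtype=int)
    b = np.asarray(group_b, dtype=int)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if np.intersect1d(a, b).size:
        raise ValueError("groups overlap")
    n1, alt1 = group_counts(ds, a)
    n2, alt2 = group_counts(ds, b)
    with np.errstate(divide="ignore", invalid="ignore"):
        p1 = np.where(n1 > 0, alt1 / np.maximum(n1, 1), np.nan)
        p2 = np.where(n2 > 0, alt2 / np.maximum(n2, 1), np.nan)
    msp, msg, num, den, theta = _components(n1, p1, n2, p2)
    empty = (n1 == 0) | (n2 == 0)
    theta = np.where(empty, np.nan, theta)
    num = np.where(empty, np.nan, num)
    den = np.where(empty, np.nan, den)
    lf = ds.loci
    return FstTable(
        locus_ids=[l.locus_id for l in lf],
        n1=n1, n2=n2, p1=p1, p2=p2, msp=msp, msg=msg,
        num=num, den=den, theta=theta,
        chrom=np.array([l.chrom for l in lf]),
        pos=np.array([l.pos for l in lf]),
    )


def find_fixed(fst: FstTable) -> set[str]:
    """Loci fixed for opposite alleles in the two groups (theta = 1 exactly).

    The criterion is exact on allele counts — p1, p2 in {0, 1} with
    p1 != p2 and at least one observed allele per group — so no
    floating-point tolerance is involved.
    """
    n1p1 = np.round(fst.p1 * fst.n1)
    n2p2 = np.round(fst.p2 * fst.n2)
    fixed1 = (n1p1 == 0) | (n1p1 == fst.n1)
    fixed2 = (n2p2 == 0) | (n2p2 == fst.n2)
    ok = (fst.n1 >= 1) & (fst.n2 >= 1) & fixed1 & fixed2
    with np.errstate(invalid="ignore"):
        opposite = np.abs(fst.p1 - fst.p2) == 1.0
    sel = ok & opposite
    return {fst.locus_ids[j] for j in np.nonzero(sel)[0]}
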