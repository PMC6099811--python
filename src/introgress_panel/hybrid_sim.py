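"""Hybrid haploid genomes by explicit meiosis on a recombination map.

F1 haplotypes are produced by recombining one pure M genome with one pure C
genome; first-generation backcross (BC1) haplotypes recombine an F1 mosaic
with a fresh pure M genome. Crossovers per chromosome are Poisson with mean
equal to the chromosome's genetic length in Morgans, placed by inverse-CDF
sampling on the cumulative genetic map (so breakpoints concentrate where the
local cM/Mb rate is high). No crossover interference and no obligate
chiasma are modelled.

True ancestry is tracked two ways for each simulated haplotype: as tiled
half-open ancestry tracts per chromosome (source M or C) and as realized
C-fractions, both per locus and per bp. Expected C-fraction is 0.5 for F1
and 0.25 for BC1. Each parental genome is used exactly once across the
whole design, so simulated haplotypes are unrelated.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._rng import substream
from .core_io import HaploidDataset, MISSING, RecombinationMap, SampleRecord

__all__ = [
    "AncestryTract",
    "HybridRecord",
    "sample_breakpoints",
    "recombine",
    "simulate_hybrids",
]


@dataclass
class AncestryTract:
    """Half-open [start_bp, end_bp) ancestry segment on one chromosome."""

    chrom: int
    start_bp: int
    end_bp: int
    source: str  # "M" or "C"

    @property
    def length(self) -> int:
        return self.end_bp - self.start_bp


@dataclass
class HybridRecord:
    """One simulated hybrid haplotype with its true ancestry."""

    sample_id: str
    generation: str  # "F1" or "BC1"
    parent_ids: tuple[str, str]
    tracts: list[AncestryTract]
    realized_c_fraction_loci: float
    realized_c_fraction_bp: float


def sample_breakpoints(
    chrom: int, rmap: RecombinationMap, rng: np.random.Generator
) -> list[int]:
    """Crossover breakpoints (bp) for one meiosis on one chromosome.

    The crossover count is Poisson with mean equal to the chromosome's
    genetic length in Morgans; positions are i.i.d. with density
    proportional to the window rate, found by inverting the cumulative
    genetic map. Returns sorted, deduplicated integer positions.
    """
    if chrom not in rmap.windows:
        raise KeyError(f"map does not cover chromosome {chrom}")
    if rmap.chrom_length(chrom) <= 0:
        raise ValueError(f"chromosome {chrom} has zero length")
    win = rmap.windows[chrom]
    glen_per_win = win[:, 2] * (win[:, 1] - win[:, 0]) / 100.0 / 1e6  # Morgans
    total = glen_per_win.sum()
    if total <= 0:
        return []
    n_x = rng.poisson(total)
    if n_x == 0:
        return []
    cum = np.concatenate([[0.0], np.cumsum(glen_per_win)])
    u = rng.uniform(0.0, total, size=n_x)
    idx = np.searchsorted(cum, u, side="right") - 1
    idx = np.clip(idx, 0, len(glen_per_win) - 1)
    frac = (u - cum[idx]) / glen_per_win[idx]
    pos = win[idx, 0] + frac * (win[idx, 1] - win[idx, 0])
    bp = sorted({int(p) for p in pos})
    return [b for b in bp if 0 < b < rmap.chrom_length(chrom)]


def _segments(breakpoints: Sequence[int], chrom_len: int) -> list[tuple[int, int]]:
    edges = [0] + [int(b) for b in breakpoints] + [chrom_len]
    return [(edges[i], edges[i + 1]) for i in range(len(edges) - 1)]


def _merge_tracts(tracts: list[AncestryTract]) -> list[AncestryTract]:
    merged: list[AncestryTract] = []
    for t in tracts:
        if merged and merged[-1].source == t.source and merged[-1].end_bp == t.start_bp:
            merged[-1] = AncestryTract(t.chrom, merged[-1].start_bp, t.end_bp, t.source)
        else:
            merged.append(t)
    return merged


def _clip_tracts(tracts: list[AncestryTract], start: int, end: int) -> list[AncestryTract]:
    out = []
    for t in tracts:
        lo, hi = max(t.start_bp, start), min(t.end_bp, end)
        if lo < hi:
            out.append(AncestryTract(t.chrom, lo, hi, t.source))
    return out


def recombine(
    hap_a: np.ndarray,
    hap_b: np.ndarray,
    positions: np.ndarray,
    breakpoints: Sequence[int],
    chrom: int,
    chrom_length: int,
    start_with_a: bool,
    tracts_a: list[AncestryTract] | None = None,
    tracts_b: list[AncestryTract] | None = None,
    source_a: str = "M",
    source_b: str = "C",
) -> tuple[np.ndarray, list[AncestryTract]]:
    """One-chromosome meiosis: alternate copying between two haplotypes.

    ``hap_a``/``hap_b`` are allele rows over the chromosome's loci at
    1-based ``positions``; copying starts from ``hap_a`` iff
    ``start_with_a`` and switches parent at every breakpoint. Parent
    ancestry tracts (for mosaic parents such as F1s) are clipped into the
    copied segments; pure parents default to a single whole-chromosome
    tract of ``source_a``/``source_b``. Returns the mosaic allele row and
    the child's merged tract list.
    """
    hap_a = np.asarray(hap_a)
    hap_b = np.asarray(hap_b)
    positions = np.asarray(positions)
    if hap_a.shape != hap_b.shape or hap_a.shape != positions.shape:
        raise ValueError("hap_a, hap_b and positions must have matching shapes")
    if tracts_a is None:
        tracts_a = [AncestryTract(chrom, 0, chrom_length, source_a)]
    if tracts_b is None:
        tracts_b = [AncestryTract(chrom, 0, chrom_length, source_b)]

    child = np.empty_like(hap_a)
    child_tracts: list[AncestryTract] = []
    use_a = start_with_a
    for start, end in _segments(breakpoints, chrom_length):
        # locus j belongs to this segment when start < pos <= end (1-based pos
        # against 0-based half-open segment)
        in_seg = (positions > start) & (positions <= end)
        child[in_seg] = hap_a[in_seg] if use_a else hap_b[in_seg]
        child_tracts.extend(
            _clip_tracts(tracts_a if use_a else tracts_b, start, end)
        )
        use_a = not use_a
    return child, _merge_tracts(child_tracts)


def _meiosis(
    ds_cols: dict[int, np.ndarray],
    hap_a: np.ndarray,
    hap_b: np.ndarray,
    tracts_a: dict[int, list[AncestryTract]] | None,
    tracts_b: dict[int, list[AncestryTract]] | None,
    rmap: RecombinationMap,
    rng: np.random.Generator,
    source_a: str,
    source_b: str,
) -> tuple[np.ndarray, dict[int, list[AncestryTract]]]:
    """Whole-genome meiosis across all chromosomes of the map."""
    child = np.empty_like(hap_a)
    child_tracts: dict[int, list[AncestryTract]] = {}
    for chrom in rmap.chroms:
        cols, positions = ds_cols[chrom]
        bps = sample_breakpoints(chrom, rmap, rng)
        start_with_a = bool(rng.random() < 0.5)
        mosaic, tracts = recombine(
            hap_a[cols], hap_b[cols], positions, bps, chrom,
            rmap.chrom_length(chrom), start_with_a,
            tracts_a[chrom] if tracts_a else None,
            tracts_b[chrom] if tracts_b else None,
            source_a, source_b,
        )
        child[cols] = mosaic
        child_tracts[chrom] = tracts
    return child, child_tracts


def _c_fraction_by_locus(tracts: dict[int, list[AncestryTract]],
                         ds_cols: dict[int, tuple[np.ndarray, np.ndarray]]) -> float:
    n_c = 0
    n_tot = 0
    for chrom, tr in tracts.items():
        _, positions = ds_cols[chrom]
        n_tot += len(positions)
        for t in tr:
            if t.source == "C":
                n_c += int(((positions > t.start_bp) & (positions <= t.end_bp)).sum())
    return n_c / n_tot if n_tot else float("nan")


def _c_fraction_by_bp(tracts: dict[int, list[AncestryTract]]) -> float:
    c = sum(t.length for tr in tracts.values() for t in tr if t.source == "C")
    tot = sum(t.length for tr in tracts.values() for t in tr)
    return c / tot if tot else float("nan")


def simulate_hybrids(
    ds: HaploidDataset,
    holdout_M: Sequence[int],
    holdout_C: Sequence[int],
    rmap: RecombinationMap,
    seed: int = 0,
    n_f1: int = 15,
    n_bc1: int = 14,
) -> tuple[list[HybridRecord], HaploidDataset]:
    """Simulate F1 and BC1 haplotypes from holdout parents, each used once.

    The default design takes 15 M + 15 C parents for the F1s and the next
    14 unused M parents for the backcrosses (F1_j x M'_j), consuming F1s in
    creation order; it therefore needs at least ``n_f1 + n_bc1`` holdout M
    samples and ``n_f1`` holdout C samples. Returns the hybrid records
    (with true ancestry) and a dataset of the hybrid haplotypes over the
    same loci, with population label HYBRID and role "simulated".
    """
    m_idx = list(holdout_M)
    c_idx = list(holdout_C)
    if len(m_idx) < n_f1 + n_bc1:
        raise ValueError(
            f"need >= {n_f1 + n_bc1} holdout M parents, got {len(m_idx)}"
        )
    if len(c_idx) < n_f1:
        raise ValueError(f"need >= {n_f1} holdout C parents, got {len(c_idx)}")
    missing_chroms = {l.chrom for l in ds.loci} - set(rmap.chroms)
    if missing_chroms:
        raise KeyError(f"map does not cover chromosomes {sorted(missing_chroms)}")

    # per-chromosome column indices and positions, in locus order
    ds_cols: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in rmap.chroms:
        cols = np.array([j for j, l in enumerate(ds.loci) if l.chrom == chrom],
                        dtype=int)
        positions = np.array([ds.loci[j].pos for j in cols])
        ds_cols[chrom] = (cols, positions)

    rng = substream(seed, "hybrids")
    m_order = rng.permutation(len(m_idx))
    c_order = rng.permutation(len(c_idx))
    f1_M = [m_idx[i] for i in m_order[:n_f1]]
    bc_M = [m_idx[i] for i in m_order[n_f1:n_f1 + n_bc1]]
    f1_C = [c_idx[i] for i in c_order[:n_f1]]

    records: list[HybridRecord] = []
    rows: list[np.ndarray] = []
    samples: list[SampleRecord] = []
    f1_genomes: list[tuple[np.ndarray, dict[int, list[AncestryTract]]]] = []

    for k in range(n_f1):
        mi, ci = f1_M[k], f1_C[k]
        child, tracts = _meiosis(
            ds_cols, ds.calls[mi], ds.calls[ci], None, None, rmap, rng, "M", "C"
        )
        sid = f"F1_{k:03d}"
        records.append(HybridRecord(
            sample_id=sid, generation="F1",
            parent_ids=(ds.samples[mi].sample_id, ds.samples[ci].sample_id),
            tracts=[t for c in rmap.chroms for t in tracts[c]],
            realized_c_fraction_loci=_c_fraction_by_locus(tracts, ds_cols),
            realized_c_fraction_bp=_c_fraction_by_bp(tracts),
        ))
        rows.append(child)
        samples.append(SampleRecord(sample_id=sid, population="HYBRID",
                                    role="simulated"))
        f1_genomes.append((child, tracts))

    for k in range(n_bc1):
        f1_child, f1_tracts = f1_genomes[k]  # F1s consumed in creation order
        mi = bc_M[k]
        child, tracts = _meiosis(
            ds_cols, f1_child, ds.calls[mi], f1_tracts, None, rmap, rng, "M", "M"
        )
        sid = f"BC1_{k:03d}"
        records.append(HybridRecord(
            sample_id=sid, generation="BC1",
            parent_ids=(records[k].sample_id, ds.samples[mi].sample_id),
            tracts=[t for c in rmap.chroms for t in tracts[c]],
            realized_c_fraction_loci=_c_fraction_by_locus(tracts, ds_cols),
            realized_c_fraction_bp=_c_fraction_by_bp(tracts),
        ))
        rows.append(child)
        samples.append(SampleRecord(sample_id=sid, population="HYBRID",
                                    role="simulated"))

    hybrids = HaploidDataset(
        samples=samples,
        loci=[replace(l) for l in ds.loci],
        calls=np.vstack(rows) if rows else np.empty((0, ds.n_loci), dtype=np.int8),
    )
    return records, hybrids


def write_truth_table(records: Sequence[HybridRecord], path: str | Path) -> None:
    """Truth TSV: sample_id, generation, realized C fraction by locus and bp."""
    pd.DataFrame(
        [dict(sample_id=r.sample_id, generation=r.generation,
              parent_a=r.parent_ids[0], parent_b=r.parent_ids[1],
              realized_c_fraction_by_locus=r.realized_c_fraction_loci,
              realized_c_fraction_by_bp=r.realized_c_fraction_bp)
         for r in records]
    ).to_csv(path, sep="\t", index=False)


def write_tracts_bed(records: Sequence[HybridRecord], path: str | Path) -> None:
    """All ancestry tracts as BED (chrom, start, end, sample|source)."""
    with open(path, "w") as fh:
        for r in records:
            for t in r.tracts:
                fh.write(f"{t.chrom}\t{t.start_bp}\t{t.end_bp}\t"
                         f"{r.sample_id}|{t.source}\n")
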