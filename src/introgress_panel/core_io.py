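"""Data model and readers/writers for haploid SNP genotype data.

The package works on haploid biallelic genotypes (honeybee drones carry a
single genome copy, so a genotype is one allele). The central container is
:class:`HaploidDataset`: a samples-by-loci call matrix with ``0`` (reference
allele), ``1`` (alternate allele) or :data:`MISSING`, plus per-sample metadata
(population, geographic tag, training/holdout role) and a per-locus table
(position, alleles, functional-effect class, flanking-sequence quality
attributes used by the panel-design filter cascade).

Conventions
-----------
* VCF coordinates are 1-based inclusive; all internal interval arithmetic
  (recombination-map windows, ancestry tracts, BED output) is 0-based
  half-open. Conversions happen in this module only.
* Haploid GT fields ("0", "1", ".") and homozygous-diploid encodings
  ("0/0", "1|1") are both accepted on input — variant callers frequently
  emit drones as diploid — and collapsed to one allele. Heterozygous calls
  are impossible for a true haploid and raise an error.
* ``MISSING`` is a distinct sentinel (-1), never conflated with the
  reference allele.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

__all__ = [
    "MISSING",
    "FUNCTIONAL_CLASSES",
    "EFFECT_CLASSES",
    "POPULATIONS",
    "REGION_TAGS",
    "ROLES",
    "SampleRecord",
    "LocusRecord",
    "HaploidDataset",
    "RecombinationMap",
    "read_dataset",
    "write_dataset",
    "read_metadata",
    "write_metadata",
    "read_recomb_map",
    "write_recomb_map",
    "write_panel",
    "write_q_matrix",
    "read_q_matrix",
]

#: Sentinel for a missing call in the genotype matrix.
MISSING: int = -1

EFFECT_CLASSES = (
    "intergenic",
    "intron",
    "synonymous",
    "utr3",
    "utr5",
    "missense",
    "splice_donor",
    "splice_region",
    "other",
)

#: Classes treated as "putative functional" by the panel-design cascade.
FUNCTIONAL_CLASSES = frozenset(
    {"utr3", "utr5", "missense", "splice_donor", "splice_region"}
)

POPULATIONS = ("IHB", "CAR", "LIG", "HYBRID", "UNKNOWN")
REGION_TAGS = ("AT", "CT", "MT", "PT", "IP", "OTHER")
ROLES = ("training", "holdout", "simulated", "unassigned")

_POP_TO_LINEAGE = {
    "IHB": "M",
    "CAR": "C",
    "LIG": "C",
    "HYBRID": "MIXED",
    "UNKNOWN": "UNKNOWN",
}


@dataclass
class SampleRecord:
    """One haploid individual: identity, population label and role."""

    sample_id: str
    population: str = "UNKNOWN"
    region_tag: str | None = None
    coordinate: tuple[float, float] | None = None
    role: str = "unassigned"

    def __post_init__(self) -> None:
        if self.population not in POPULATIONS:
            raise ValueError(f"unknown population {self.population!r}")
        if self.region_tag is not None and self.region_tag not in REGION_TAGS:
            raise ValueError(f"unknown region tag {self.region_tag!r}")
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")

    @property
    def lineage(self) -> str:
        """Evolutionary lineage implied by the population label (M or C)."""
        return _POP_TO_LINEAGE[self.population]


@dataclass
class LocusRecord:
    """One biallelic SNP with the attributes the filter cascade consumes.

    ``flank_variable_left/right`` count variable nucleotides within the
    250 bp flanking sequences on either side of the SNP; ``flank_max_n_run``
    is the longest run of unknown bases (N) in the flanks; the two flags mark
    flanks that map to multiple contigs or consist of short repeats.
    """

    locus_id: str
    chrom: int
    pos: int  # 1-based
    ref_allele: str = "A"
    alt_allele: str = "G"
    effect_class: str = "other"
    flank_variable_left: int = 0
    flank_variable_right: int = 0
    flank_max_n_run: int = 0
    flank_multimap: bool = False
    flank_repeat: bool = False

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"{self.locus_id}: position must be >= 1")
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"{self.locus_id}: ref and alt alleles are equal")
        if self.effect_class not in EFFECT_CLASSES:
            raise ValueError(f"{self.locus_id}: unknown effect class {self.effect_class!r}")
        if min(self.flank_variable_left, self.flank_variable_right, self.flank_max_n_run) < 0:
            raise ValueError(f"{self.locus_id}: flank counts must be >= 0")

    @property
    def is_functional(self) -> bool:
        return self.effect_class in FUNCTIONAL_CLASSES


@dataclass
class HaploidDataset:
    """Samples x loci haploid call matrix with metadata.

    ``calls[i, j]`` is 0 (ref), 1 (alt) or :data:`MISSING` for sample ``i``
    at locus ``j``. Loci are kept sorted by (chrom, pos).
    """

    samples: list[SampleRecord]
    loci: list[LocusRecord]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.loci)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.loci)} loci"
            )
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample_id in dataset")
        ok = np.isin(self.calls, (0, 1, MISSING))
        if not ok.all():
            raise ValueError("calls must be 0, 1 or MISSING")

    # -- basic accessors ---------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def locus_ids(self) -> list[str]:
        return [l.locus_id for l in self.loci]

    def genotyping_rate(self) -> float:
        """Fraction of non-missing entries in the call matrix."""
        if self.calls.size == 0:
            return 1.0
        return 1.0 - float((self.calls == MISSING).sum()) / self.calls.size

    def sample_indices(
        self,
        population: str | None = None,
        role: str | None = None,
        region_tag: str | None = None,
        lineage: str | None = None,
    ) -> np.ndarray:
        """Indices of samples matching all given metadata filters."""
        idx = []
        for i, s in enumerate(self.samples):
            if population is not None and s.population != population:
                continue
            if role is not None and s.role != role:
                continue
            if region_tag is not None and s.region_tag != region_tag:
                continue
            if lineage is not None and s.lineage != lineage:
                continue
            idx.append(i)
        return np.asarray(idx, dtype=int)

    def locus_index(self) -> dict[str, int]:
        return {l.locus_id: j for j, l in enumerate(self.loci)}

    def subset_loci(self, locus_ids: Sequence[str]) -> "HaploidDataset":
        """Dataset restricted to the given loci, in (chrom, pos) order."""
        index = self.locus_index()
        missing = [lid for lid in locus_ids if lid not in index]
        if missing:
            raise KeyError(f"loci not in dataset: {missing[:5]}")
        cols = sorted(index[lid] for lid in set(locus_ids))
        return HaploidDataset(
            samples=[replace(s) for s in self.samples],
            loci=[replace(self.loci[j]) for j in cols],
            calls=self.calls[:, cols].copy(),
        )

    def subset_samples(self, indices: Iterable[int]) -> "HaploidDataset":
        rows = list(indices)
        return HaploidDataset(
            samples=[replace(self.samples[i]) for i in rows],
            loci=[replace(l) for l in self.loci],
            calls=self.calls[rows, :].copy(),
        )

    def samples_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.samples:
            x, y = s.coordinate if s.coordinate is not None else (np.nan, np.nan)
            rows.append(
                dict(sample_id=s.sample_id, population=s.population, lineage=s.lineage,
                     region_tag=s.region_tag, x=x, y=y, role=s.role)
            )
        return pd.DataFrame(rows)

    def loci_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [dict(locus_id=l.locus_id, chrom=l.chrom, pos=l.pos,
                  ref_allele=l.ref_allele, alt_allele=l.alt_allele,
                  effect_class=l.effect_class,
                  flank_variable_left=l.flank_variable_left,
                  flank_variable_right=l.flank_variable_right,
                  flank_max_n_run=l.flank_max_n_run,
                  flank_multimap=l.flank_multimap, flank_repeat=l.flank_repeat)
             for l in self.loci]
        )


def _sorted_locus_order(loci: Sequence[LocusRecord]) -> list[int]:
    return sorted(range(len(loci)), key=lambda j: (loci[j].chrom, loci[j].pos))


def sort_dataset(ds: HaploidDataset) -> HaploidDataset:
    """Return the dataset with loci sorted by (chrom, pos)."""
    order = _sorted_locus_order(ds.loci)
    return HaploidDataset(
        samples=ds.samples,
        loci=[ds.loci[j] for j in order],
        calls=ds.calls[:, order],
    )


# ---------------------------------------------------------------------------
# recombination map
# ---------------------------------------------------------------------------

@dataclass
class RecombinationMap:
    """Windowed recombination map: per chromosome, tiled (start, end, rate).

    Intervals are 0-based half-open in bp; rates are cM/Mb. Windows must tile
    each chromosome without gaps or overlaps.
    """

    windows: dict[int, np.ndarray]  # chrom -> array (n, 3): start, end, rate

    def __post_init__(self) -> None:
        clean: dict[int, np.ndarray] = {}
        for chrom, win in self.windows.items():
            win = np.asarray(win, dtype=float)
            if win.ndim != 2 or win.shape[1] != 3 or win.shape[0] == 0:
                raise ValueError(f"chrom {chrom}: windows must be (n, 3), n >= 1")
            order = np.argsort(win[:, 0])
            win = win[order]
            if (win[:, 2] < 0).any():
                bad = win[win[:, 2] < 0][0]
                raise ValueError(f"chrom {chrom}: negative rate in window {bad[:2]}")
            if (win[:, 1] <= win[:, 0]).any():
                raise ValueError(f"chrom {chrom}: empty or inverted window")
            gaps = win[1:, 0] != win[:-1, 1]
            if gaps.any():
                k = int(np.nonzero(gaps)[0][0])
                raise ValueError(
                    f"chrom {chrom}: windows {win[k, :2]} and {win[k + 1, :2]} "
                    "do not tile (gap or overlap)"
                )
            clean[int(chrom)] = win
        self.windows = clean

    @property
    def chroms(self) -> list[int]:
        return sorted(self.windows)

    def chrom_length(self, chrom: int) -> int:
        return int(self.windows[chrom][-1, 1])

    def genetic_length(self, chrom: int) -> float:
        """Genetic length of a chromosome in Morgans: sum(rate * len)/100/1e6."""
        win = self.windows[chrom]
        return float(np.sum(win[:, 2] * (win[:, 1] - win[:, 0])) / 100.0 / 1e6)

    def total_genetic_length(self) -> float:
        return sum(self.genetic_length(c) for c in self.chroms)

    @staticmethod
    def uniform(
        n_chroms: int,
        chrom_length_bp: int,
        rate_cM_per_Mb: float,
        window_bp: int = 100_000,
    ) -> "RecombinationMap":
        """Constant-rate map with the given window resolution."""
        edges = np.arange(0, chrom_length_bp, window_bp)
        starts = edges
        ends = np.minimum(edges + window_bp, chrom_length_bp)
        win = np.column_stack([starts, ends, np.full(len(starts), rate_cM_per_Mb)])
        return RecombinationMap({c: win.copy() for c in range(1, n_chroms + 1)})


def read_recomb_map(path: str | Path) -> RecombinationMap:
    """Read a recombination map from a TSV with columns chrom, start, end, rate."""
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "start", "end", "rate"}
    if not required.issubset(df.columns):
        raise ValueError(f"recombination map needs columns {sorted(required)}")
    windows = {
        int(chrom): grp[["start", "end", "rate"]].to_numpy(dtype=float)
        for chrom, grp in df.groupby("chrom")
    }
    return RecombinationMap(windows)


def write_recomb_map(rmap: RecombinationMap, path: str | Path) -> None:
    rows = []
    for chrom in rmap.chroms:
        for start, end, rate in rmap.windows[chrom]:
            rows.append(dict(chrom=chrom, start=int(start), end=int(end), rate=rate))
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# sample metadata
# ---------------------------------------------------------------------------

_META_COLS = ["sample_id", "population", "region_tag", "x", "y", "role"]


def write_metadata(samples: Sequence[SampleRecord], path: str | Path) -> None:
    """Write sample metadata as TSV (sample_id, population, region_tag, x, y, role)."""
    rows = []
    for s in samples:
        x, y = s.coordinate if s.coordinate is not None else ("", "")
        rows.append(dict(sample_id=s.sample_id, population=s.population,
                         region_tag=s.region_tag or "", x=x, y=y, role=s.role))
    pd.DataFrame(rows, columns=_META_COLS).to_csv(path, sep="\t", index=False)


def read_metadata(path: str | Path) -> dict[str, SampleRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str}, keep_default_na=False)
    if "sample_id" not in df.columns or "population" not in df.columns:
        raise ValueError("metadata needs at least sample_id and population columns")
    out: dict[str, SampleRecord] = {}
    for row in df.itertuples(index=False):
        coord = None
        x = getattr(row, "x", "")
        y = getattr(row, "y", "")
        if x != "" and y != "":
            coord = (float(x), float(y))
        region = getattr(row, "region_tag", "") or None
        role = getattr(row, "role", "") or "unassigned"
        out[row.sample_id] = SampleRecord(
            sample_id=row.sample_id,
            population=row.population,
            region_tag=region,
            coordinate=coord,
            role=role,
        )
    return out


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_dataset(vcf_path: str | Path, metadata_path: str | Path) -> HaploidDataset:
    """Read haploid genotypes from a VCF plus a sample-metadata TSV.

    Haploid GT ("0", "1", ".") and homozygous-diploid GT ("0/0", "1|1") are
    accepted; heterozygous diploid GT raises ``ValueError`` listing the
    offending (locus, sample) pairs. Multi-allelic records are rejected.
    Loci are returned sorted by (chrom, pos).
    """
    meta = read_metadata(metadata_path)
    vcf = VCF(str(vcf_path))
    sample_names = list(vcf.samples)
    absent = [s for s in sample_names if s not in meta]
    if absent:
        raise ValueError(f"metadata is missing rows for samples: {absent}")

    samples = [meta[s] for s in sample_names]
    loci: list[LocusRecord] = []
    columns: list[np.ndarray] = []
    het_records: list[str] = []
    for var in vcf:
        if len(var.ALT) != 1:
            raise ValueError(
                f"multi-allelic record at {var.CHROM}:{var.POS} "
                f"(ALT={var.ALT}); only biallelic SNPs are supported"
            )
        col = np.empty(len(sample_names), dtype=np.int8)
        for i, gt in enumerate(var.genotypes):
            alleles = [a for a in gt[:-1]]  # last element is the phased flag
            if len(alleles) == 2 and alleles[0] != alleles[1] and min(alleles) >= 0:
                het_records.append(f"{var.CHROM}:{var.POS} sample {sample_names[i]}")
                col[i] = MISSING
                continue
            a = alleles[0]
            col[i] = MISSING if a < 0 else a
        info = dict(var.INFO) if var.INFO else {}
        locus_id = var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}"
        loci.append(
            LocusRecord(
                locus_id=locus_id,
                chrom=int(var.CHROM),
                pos=int(var.POS),
                ref_allele=var.REF,
                alt_allele=var.ALT[0],
                effect_class=info.get("EFFECT", "other"),
                flank_variable_left=int(info.get("FVL", 0)),
                flank_variable_right=int(info.get("FVR", 0)),
                flank_max_n_run=int(info.get("FNRUN", 0)),
                flank_multimap=bool(int(info.get("FMULTI", 0))),
                flank_repeat=bool(int(info.get("FREP", 0))),
            )
        )
        columns.append(col)
    if het_records:
        shown = ", ".join(het_records[:10])
        raise ValueError(
            f"heterozygous call in haploid data ({len(het_records)} records): {shown}"
        )
    calls = (
        np.column_stack(columns) if columns
        else np.empty((len(samples), 0), dtype=np.int8)
    )
    return sort_dataset(HaploidDataset(samples=samples, loci=loci, calls=calls))


_VCF_HEADER = """\
##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Haploid genotype">
##INFO=<ID=EFFECT,Number=1,Type=String,Description="Functional effect class">
##INFO=<ID=FVL,Number=1,Type=Integer,Description="Variable nucleotides in left 250bp flank">
##INFO=<ID=FVR,Number=1,Type=Integer,Description="Variable nucleotides in right 250bp flank">
##INFO=<ID=FNRUN,Number=1,Type=Integer,Description="Longest N run in flanks">
##INFO=<ID=FMULTI,Number=1,Type=Integer,Description="Flank maps to multiple contigs (0/1)">
##INFO=<ID=FREP,Number=1,Type=Integer,Description="Flank consists of short repeats (0/1)">
"""


def write_dataset(ds: HaploidDataset, vcf_path: str | Path) -> None:
    """Write the dataset as a VCF 4.2 with haploid GT; MISSING becomes ".". """
    buf = io.StringIO()
    buf.write(_VCF_HEADER)
    for chrom in sorted({l.chrom for l in ds.loci}):
        buf.write(f"##contig=<ID={chrom}>\n")
    buf.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
    buf.write("\t".join(ds.sample_ids))
    buf.write("\n")
    gt_map = {0: "0", 1: "1", MISSING: "."}
    for j, loc in enumerate(ds.loci):
        info = (
            f"EFFECT={loc.effect_class};FVL={loc.flank_variable_left};"
            f"FVR={loc.flank_variable_right};FNRUN={loc.flank_max_n_run};"
            f"FMULTI={int(loc.flank_multimap)};FREP={int(loc.flank_repeat)}"
        )
        gts = "\t".join(gt_map[int(c)] for c in ds.calls[:, j])
        buf.write(
            f"{loc.chrom}\t{loc.pos}\t{loc.locus_id}\t{loc.ref_allele}\t"
            f"{loc.alt_allele}\t.\t.\t{info}\tGT\t{gts}\n"
        )
    Path(vcf_path).write_text(buf.getvalue())


# ---------------------------------------------------------------------------
# panels and Q matrices
# ---------------------------------------------------------------------------

def write_panel(panel, ds: HaploidDataset, tsv_path: str | Path,
                bed_path: str | Path | None = None) -> None:
    """Write a panel as TSV (panel, locus_id, chrom, pos, effect_class) + BED.

    BED intervals are 0-based half-open single-base intervals.
    """
    index = ds.locus_index()
    rows = []
    for lid in panel.locus_ids:
        loc = ds.loci[index[lid]]
        rows.append(dict(panel=panel.name, locus_id=lid, chrom=loc.chrom,
                         pos=loc.pos, effect_class=loc.effect_class))
    pd.DataFrame(rows, columns=["panel", "locus_id", "chrom", "pos", "effect_class"]
                 ).to_csv(tsv_path, sep="\t", index=False)
    if bed_path is not None:
        with open(bed_path, "w") as fh:
            for r in rows:
                fh.write(f"{r['chrom']}\t{r['pos'] - 1}\t{r['pos']}\t{r['locus_id']}\n")


def write_q_matrix(q: np.ndarray, path: str | Path) -> None:
    """Write a Q matrix in .Q layout: one row per sample, one column per cluster."""
    np.savetxt(path, np.atleast_2d(q), fmt="%.6f", delimiter=" ")


def read_q_matrix(path: str | Path) -> np.ndarray:
    return np.atleast_2d(np.loadtxt(path))
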