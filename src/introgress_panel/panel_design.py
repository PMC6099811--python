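"""The panel-design cascade: split, select, thin, filter, multiplex.

Reduced SNP assays are built in stages:

1. ``split_train_holdout`` — set aside a random, population-stratified
   holdout fraction (default 25%) so marker selection and validation use
   disjoint individuals (the simple training/holdout guard against
   ascertainment bias).
2. Fixed-SNP selection on the training scan (``fst.find_fixed``).
3. ``thin_by_distance`` — drop SNPs closer than 5,000 bp (redundant under
   the honeybee's fast LD decay), preferentially retaining putative
   functional classes (3'UTR, 5'UTR, missense, splice donor/region).
4. ``apply_flank_filters`` — genotyping-chemistry feasibility: reject SNPs
   with >5 variable nucleotides in either 250 bp flank, >5 consecutive
   unknown bases, multimapping flanks, or repeat flanks.
5. ``assemble_multiplexes`` — pack the survivors into a small number of
   disjoint assays (max 40 SNPs each) such that each assay covers every
   chromosome it can and carries at least four functional SNPs. Chemistry
   compatibility (hairpin/dimer interactions on the real instrument) enters
   through a pluggable predicate, defaulting to accept-all.
6. ``build_random_assays`` — size-matched random panels drawn from the full
   SNP set, the baseline the designed panels are benchmarked against.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from ._rng import substream
from .core_io import FUNCTIONAL_CLASSES, HaploidDataset, LocusRecord, SampleRecord

__all__ = [
    "PanelDefinition",
    "split_train_holdout",
    "thin_by_distance",
    "apply_flank_filters",
    "assemble_multiplexes",
    "build_random_assays",
]

CompatPredicate = Callable[[LocusRecord, list[LocusRecord]], bool]


def accept_all(locus: LocusRecord, selected: list[LocusRecord]) -> bool:
    """Default multiplex-compatibility predicate: every SNP is compatible."""
    return True


@dataclass
class PanelDefinition:
    """An ordered set of panel loci with a recomputable constraint audit."""

    name: str
    locus_ids: list[str]
    audit: dict = field(default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.locus_ids)

    def recompute_audit(self, ds: HaploidDataset,
                        disjoint_from: dict[str, "PanelDefinition"] | None = None,
                        max_size: int = 40) -> dict:
        index = ds.locus_index()
        records = [ds.loci[index[lid]] for lid in self.locus_ids]
        audit = dict(
            size=len(records),
            size_ok=len(records) <= max_size,
            chroms_covered=sorted({r.chrom for r in records}),
            n_functional=sum(r.is_functional for r in records),
            disjoint_from=[],
        )
        for other_name, other in (disjoint_from or {}).items():
            if other_name == self.name:
                continue
            if not set(self.locus_ids) & set(other.locus_ids):
                audit["disjoint_from"].append(other_name)
        self.audit = audit
        return audit


def split_train_holdout(
    ds: HaploidDataset, holdout_fraction: float = 0.25, seed: int = 0
) -> dict[str, list[str]]:
    """Assign training/holdout roles, stratified by population label.

    Within each population the holdout count is ``fraction * n`` rounded to
    the nearest integer (half up), which reproduces the study-scale split:
    117 focal + (28 + 31) reference at 25% yields holdout 29 + (7 + 8) =
    29 + 15. Roles are written into the sample records; the mapping
    role -> sample ids is returned.
    """
    if not 0.0 < holdout_fraction < 1.0:
        raise ValueError("holdout_fraction must lie in (0, 1)")
    by_pop: dict[str, list[int]] = {}
    for i, s in enumerate(ds.samples):
        by_pop.setdefault(s.population, []).append(i)

    counts = {pop: int(np.floor(holdout_fraction * len(idx) + 0.5))
              for pop, idx in by_pop.items()}
    for pop, k in counts.items():
        if k < 1:
            raise ValueError(
                f"stratum {pop!r} too small for >= 1 holdout sample "
                f"at fraction {holdout_fraction}"
            )
        if k >= len(by_pop[pop]):
            raise ValueError(f"stratum {pop!r} would have no training samples")

    rng = substream(seed, "train_holdout_split")
    assignment: dict[str, list[str]] = {"training": [], "holdout": []}
    for pop in sorted(by_pop):
        idx = np.array(by_pop[pop])
        hold = set(rng.choice(idx, size=counts[pop], replace=False).tolist())
        for i in idx:
            role = "holdout" if i in hold else "training"
            ds.samples[i].role = role
            assignment[role].append(ds.samples[i].sample_id)
    return assignment


def _priority(locus: LocusRecord) -> int:
    return 1 if locus.effect_class in FUNCTIONAL_CLASSES else 0


def thin_by_distance(
    loci: Sequence[LocusRecord], min_bp: int = 5_000
) -> set[str]:
    """Greedy distance thinning with functional priority.

    Sweeps each chromosome left to right keeping a stack of retained loci.
    When the next locus lies closer than ``min_bp`` to the last retained
    one, the higher-priority locus survives (functional classes beat
    others; ties keep the lower position). A survivor that displaces the
    stack top is re-checked against the remaining stack, so the output has
    no pair closer than ``min_bp``.
    """
    for a, b in zip(loci, list(loci)[1:]):
        if (a.chrom, a.pos) >= (b.chrom, b.pos):
            raise ValueError(
                f"loci must be sorted by (chrom, pos): {a.locus_id} before {b.locus_id}"
            )
    retained: set[str] = set()
    by_chrom: dict[int, list[LocusRecord]] = {}
    for loc in loci:
        by_chrom.setdefault(loc.chrom, []).append(loc)
    for chrom_loci in by_chrom.values():
        stack: list[LocusRecord] = []
        for loc in chrom_loci:
            current = loc
            while stack and current.pos - stack[-1].pos < min_bp:
                top = stack.pop()
                if _priority(current) > _priority(top):
                    # current displaces top; re-check against the new stack top
                    continue
                # equal or higher priority on top: keep the lower position,
                # which is already compatible with the rest of the stack
                current = top
                break
            stack.append(current)
        retained.update(l.locus_id for l in stack)
    return retained


def apply_flank_filters(
    loci: Sequence[LocusRecord],
    max_variable: int = 5,
    max_n_run: int = 5,
) -> tuple[set[str], dict[str, int]]:
    """Flank-quality filters for genotyping-assay feasibility.

    A locus is removed iff any rule fires:
    ``variable_left > 5``, ``variable_right > 5`` (too many variable
    nucleotides in the 250 bp flanks), ``n_run > 5`` (ambiguous reference),
    ``multimap`` or ``repeat``. Removal counts are attributed to the first
    failing rule in that order. Returns (retained ids, counts per rule).
    """
    counts = {"variable_left": 0, "variable_right": 0, "n_run": 0,
              "multimap": 0, "repeat": 0}
    retained: set[str] = set()
    for loc in loci:
        if loc.flank_variable_left > max_variable:
            counts["variable_left"] += 1
        elif loc.flank_variable_right > max_variable:
            counts["variable_right"] += 1
        elif loc.flank_max_n_run > max_n_run:
            counts["n_run"] += 1
        elif loc.flank_multimap:
            counts["multimap"] += 1
        elif loc.flank_repeat:
            counts["repeat"] += 1
        else:
            retained.add(loc.locus_id)
    return retained, counts


def assemble_multiplexes(
    ds: HaploidDataset,
    candidates: set[str],
    n_panels: int = 4,
    max_size: int = 40,
    min_functional: int = 4,
    compat: CompatPredicate = accept_all,
    seed: int = 0,
    name_prefix: str = "M",
) -> list[PanelDefinition]:
    """Greedy seeded assembly of disjoint multiplex panels.

    For each panel: first pass takes one compatible SNP per chromosome
    (skipping chromosomes with no remaining candidates — later panels can
    run short just as real assays sometimes lack a chromosome); second pass
    tops up putative-functional SNPs to ``min_functional``; third pass
    fills to ``max_size`` at random. Chosen SNPs leave the pool before the
    next panel is built, so panels are pairwise disjoint by construction.
    Unmet chromosome coverage or functional quota produces a warning, not
    an error.
    """
    if not candidates:
        raise ValueError("empty candidate pool")
    index = ds.locus_index()
    unknown = candidates - set(index)
    if unknown:
        raise KeyError(f"candidate loci not in dataset: {sorted(unknown)[:5]}")
    all_chroms = sorted({l.chrom for l in ds.loci})
    pool = set(candidates)
    panels: list[PanelDefinition] = []
    max_attempts = 20 * max_size

    for p in range(n_panels):
        rng = substream(seed, "multiplex", p)
        selected: list[LocusRecord] = []
        rejected_compat = 0

        def try_add(lid: str) -> bool:
            nonlocal rejected_compat
            loc = ds.loci[index[lid]]
            if compat(loc, selected):
                selected.append(loc)
                pool.discard(lid)
                return True
            rejected_compat += 1
            return False

        # pass 1: one SNP per chromosome
        for chrom in all_chroms:
            chrom_pool = [lid for lid in pool if ds.loci[index[lid]].chrom == chrom]
            rng.shuffle(chrom_pool)
            for lid in chrom_pool:
                if try_add(lid):
                    break
        # pass 2: functional quota
        func_pool = [lid for lid in pool
                     if ds.loci[index[lid]].is_functional]
        rng.shuffle(func_pool)
        for lid in func_pool:
            if sum(l.is_functional for l in selected) >= min_functional:
                break
            if len(selected) >= max_size:
                break
            try_add(lid)
        # pass 3: random fill
        fill_pool = sorted(pool)
        rng.shuffle(fill_pool)
        attempts = 0
        for lid in fill_pool:
            if len(selected) >= max_size:
                break
            attempts += 1
            if attempts > max_attempts:
                break
            try_add(lid)

        if not selected:
            if rejected_compat:
                raise RuntimeError(
                    f"could not assemble panel {name_prefix}{p + 1}: compatibility "
                    f"predicate rejected all {rejected_compat} attempted candidates"
                )
            raise ValueError(
                f"candidate pool exhausted after {len(panels)} panel(s); "
                f"reduce n_panels or max_size, or supply more candidates"
            )
        selected.sort(key=lambda l: (l.chrom, l.pos))
        panel = PanelDefinition(
            name=f"{name_prefix}{p + 1}", locus_ids=[l.locus_id for l in selected]
        )
        covered = {l.chrom for l in selected}
        if covered != set(all_chroms):
            missing = sorted(set(all_chroms) - covered)
            warnings.warn(
                f"panel {panel.name} lacks SNPs on chromosome(s) {missing}",
                stacklevel=2,
            )
        if sum(l.is_functional for l in selected) < min_functional:
            warnings.warn(
                f"panel {panel.name} has fewer than {min_functional} functional SNPs",
                stacklevel=2,
            )
        panels.append(panel)

    lookup = {pnl.name: pnl for pnl in panels}
    for pnl in panels:
        pnl.recompute_audit(ds, disjoint_from=lookup, max_size=max_size)
    return panels


def build_random_assays(
    ds: HaploidDataset,
    sizes: Sequence[int],
    seed: int = 0,
    name_prefix: str = "R",
) -> list[PanelDefinition]:
    """Mutually disjoint random panels drawn uniformly from the full SNP set."""
    total = sum(sizes)
    if any(s < 0 for s in sizes):
        raise ValueError("panel sizes must be >= 0")
    if total > ds.n_loci:
        raise ValueError(
            f"requested {total} random SNPs but the dataset has {ds.n_loci}"
        )
    rng = substream(seed, "random_assays")
    drawn = rng.choice(ds.n_loci, size=total, replace=False)
    panels = []
    offset = 0
    for k, size in enumerate(sizes):
        cols = sorted(drawn[offset:offset + size].tolist())
        offset += size
        panels.append(
            PanelDefinition(
                name=f"{name_prefix}{k + 1}",
                locus_ids=[ds.loci[j].locus_id for j in cols],
            )
        )
    lookup = {pnl.name: pnl for pnl in panels}
    for pnl in panels:
        pnl.recompute_audit(ds, disjoint_from=lookup, max_size=max(sizes) if sizes else 0)
    return panels
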