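"""Synthetic haploid two-lineage datasets for desk-scale pipeline runs.

The generator emulates the population structure the panel-design workflow is
built for: a focal native population (M lineage, population label IHB) deeply
diverged from a reference pool (C lineage, labels CAR/LIG split evenly), with
an internal cline inside the focal population — two intra-M subclusters mixed
along a one-dimensional coordinate x in [0, 1] with a logistic profile, which
is what makes geographically restricted subsets genuinely less diverse than
range-wide ones.

Allele frequencies follow the Balding–Nichols drift model: given an ancestral
frequency p, a population with drift parameter F draws its frequency from
Beta(p (1-F)/F, (1-p)(1-F)/F), so E[freq] = p and Var = F p (1-p). Larger F
means stronger drift, more loci near fixation, and higher realized F_ST
between the lineages; ``calibrate_divergence`` bisects F against the realized
genomewide Weir–Cockerham F_ST of probe simulations to hit a target level
(the real M-C divergence is around 0.53).

Region tags mimic the study geography on the synthetic coordinate: PT is the
low-x end of the cline (a country-restricted sample), CT and MT are interior
bands, AT the high-x end, and IP denotes the whole range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Callable

import numpy as np

from ._rng import substream
from .core_io import (
    EFFECT_CLASSES,
    HaploidDataset,
    LocusRecord,
    MISSING,
    SampleRecord,
    sort_dataset,
)
from .fst import fst_scan

__all__ = ["SimConfig", "generate_dataset", "calibrate_divergence", "annotate_loci"]

#: Default effect-class proportions, approximating the observed composition of
#: fixed SNPs in honeybee M-vs-C scans (introns ~42%, intergenic ~23%, the
#: rest spread over the remaining classes).
DEFAULT_EFFECT_WEIGHTS: dict[str, float] = {
    "intron": 0.42,
    "intergenic": 0.23,
    "synonymous": 0.13,
    "utr3": 0.05,
    "utr5": 0.04,
    "missense": 0.04,
    "splice_donor": 0.01,
    "splice_region": 0.03,
    "other": 0.05,
}


def logistic_cline(steepness: float = 10.0, midpoint: float = 0.5) -> Callable:
    """Logistic subcluster-weight profile w(x) on [0, 1]."""

    def profile(x: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-steepness * (np.asarray(x) - midpoint)))

    return profile


@dataclass
class SimConfig:
    """Parameters of the two-lineage haploid simulator.

    ``divergence_F_MC`` is the Balding–Nichols drift parameter applied
    independently to the M and C lineages around a shared ancestral
    frequency; ``cline_F`` is the (smaller) drift parameter separating the
    two intra-M subclusters around the M lineage frequency. The default
    divergence value was calibrated once (bisection against the realized
    genomewide F_ST, see ``calibrate_divergence``) to put the realized M-C
    F_ST near 0.53, the level observed between the Iberian honeybee and the
    C lineage.
    """

    n_M: int = 50
    n_C: int = 30
    n_loci: int = 20_000
    n_chroms: int = 16
    chrom_length_bp: int = 15_000_000
    divergence_F_MC: float = 0.531
    cline_F: float = 0.08
    cline_steepness: float = 10.0
    ancestral_freq_low: float = 0.05
    ancestral_freq_high: float = 0.95
    effect_class_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EFFECT_WEIGHTS)
    )
    flank_variable_mean: float = 1.5
    flank_n_run_mean: float = 0.8
    flank_multimap_rate: float = 0.05
    flank_repeat_rate: float = 0.05
    missing_rate: float = 0.014
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_M, self.n_C, self.n_loci, self.n_chroms) < 1:
            raise ValueError("counts must be >= 1")
        if not 0.0 < self.divergence_F_MC < 1.0:
            raise ValueError("divergence_F_MC must lie in (0, 1)")
        if not 0.0 <= self.cline_F < 1.0:
            raise ValueError("cline_F must lie in [0, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if not 0.0 < self.ancestral_freq_low < self.ancestral_freq_high < 1.0:
            raise ValueError("ancestral frequency bounds must satisfy 0 < lo < hi < 1")
        for rate in (self.flank_multimap_rate, self.flank_repeat_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("flag rates must lie in [0, 1]")


def _bn_draw(rng: np.random.Generator, p: np.ndarray, F: float) -> np.ndarray:
    """Balding–Nichols frequency draw around ancestral p with drift F."""
    if F <= 0.0:
        return p.copy()
    # frequencies at or near fixation stay there: drift cannot resurrect an
    # absent allele, and zero Beta shape parameters are undefined
    eps = 1e-9
    p = np.clip(p, eps, 1.0 - eps)
    a = p * (1.0 - F) / F
    b = (1.0 - p) * (1.0 - F) / F
    return rng.beta(a, b)


def _region_tag(x: float) -> str:
    # Rectangular zones of the 1-D cline coordinate, mirroring the study's
    # sampling areas: PT at one end, AT at the other, CT/MT interior bands.
    if x < 0.25:
        return "PT"
    if x < 0.50:
        return "CT"
    if x < 0.75:
        return "MT"
    return "AT"


def generate_dataset(cfg: SimConfig) -> HaploidDataset:
    """Simulate a haploid M + C dataset under the configured structure.

    Deterministic given ``cfg.seed``: the same config yields byte-identical
    call matrices and metadata.
    """
    rng_freq = substream(cfg.seed, "frequencies")
    rng_calls = substream(cfg.seed, "calls")
    rng_pos = substream(cfg.seed, "positions")
    rng_miss = substream(cfg.seed, "missing")

    L = cfg.n_loci
    p_anc = rng_freq.uniform(cfg.ancestral_freq_low, cfg.ancestral_freq_high, size=L)
    p_M = _bn_draw(rng_freq, p_anc, cfg.divergence_F_MC)
    p_C = _bn_draw(rng_freq, p_anc, cfg.divergence_F_MC)
    # intra-M subclusters drift around the M lineage frequency
    p_M1 = _bn_draw(rng_freq, p_M, cfg.cline_F)
    p_M2 = _bn_draw(rng_freq, p_M, cfg.cline_F)

    x_M = rng_calls.uniform(0.0, 1.0, size=cfg.n_M)
    w = logistic_cline(cfg.cline_steepness)(x_M)  # weight of subcluster 2

    samples: list[SampleRecord] = []
    rows: list[np.ndarray] = []
    for i in range(cfg.n_M):
        freq = (1.0 - w[i]) * p_M1 + w[i] * p_M2
        rows.append((rng_calls.random(L) < freq).astype(np.int8))
        samples.append(
            SampleRecord(
                sample_id=f"M{i:04d}", population="IHB",
                region_tag=_region_tag(x_M[i]),
                coordinate=(float(x_M[i]), 0.0),
            )
        )
    half = cfg.n_C // 2
    for i in range(cfg.n_C):
        rows.append((rng_calls.random(L) < p_C).astype(np.int8))
        samples.append(
            SampleRecord(
                sample_id=f"C{i:04d}",
                population="CAR" if i < half else "LIG",
                region_tag="OTHER",
            )
        )
    calls = np.vstack(rows)

    if cfg.missing_rate > 0:
        mask = rng_miss.random(calls.shape) < cfg.missing_rate
        calls[mask] = MISSING

    # uniform chromosome assignment with sorted random positions
    chroms = rng_pos.integers(1, cfg.n_chroms + 1, size=L)
    positions = rng_pos.integers(1, cfg.chrom_length_bp + 1, size=L)
    loci = []
    for j in range(L):
        loci.append(
            LocusRecord(locus_id=f"snp{j:06d}", chrom=int(chroms[j]),
                        pos=int(positions[j]))
        )
    ds = sort_dataset(HaploidDataset(samples=samples, loci=loci, calls=calls))
    # deduplicate positions that collide after sorting (keep determinism)
    _bump_duplicate_positions(ds)
    return ds


def _bump_duplicate_positions(ds: HaploidDataset) -> None:
    """Shift exact position collisions by +1 bp so (chrom, pos) is unique."""
    last: dict[int, int] = {}
    for loc in ds.loci:
        prev = last.get(loc.chrom, 0)
        if loc.pos <= prev:
            loc.pos = prev + 1
        last[loc.chrom] = loc.pos


def annotate_loci(ds: HaploidDataset, cfg: SimConfig) -> HaploidDataset:
    """Draw effect classes and flank-quality attributes onto the loci.

    Effect classes are categorical with ``cfg.effect_class_weights``;
    flank variable-nucleotide counts and N-run lengths are Poisson with the
    configured means; multimap/repeat flags are Bernoulli. Mutates and
    returns the dataset.
    """
    weights = cfg.effect_class_weights
    unknown = set(weights) - set(EFFECT_CLASSES)
    if unknown:
        raise ValueError(f"unknown effect classes in weights: {sorted(unknown)}")
    total = sum(weights.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"effect_class_weights sum to {total}, expected 1")
    classes = list(weights)
    probs = np.array([weights[c] for c in classes])

    rng = substream(cfg.seed, "annotation")
    L = ds.n_loci
    drawn = rng.choice(len(classes), size=L, p=probs)
    fvl = rng.poisson(cfg.flank_variable_mean, size=L)
    fvr = rng.poisson(cfg.flank_variable_mean, size=L)
    nrun = rng.poisson(cfg.flank_n_run_mean, size=L)
    multi = rng.random(L) < cfg.flank_multimap_rate
    rep = rng.random(L) < cfg.flank_repeat_rate
    for j, loc in enumerate(ds.loci):
        loc.effect_class = classes[drawn[j]]
        loc.flank_variable_left = int(fvl[j])
        loc.flank_variable_right = int(fvr[j])
        loc.flank_max_n_run = int(nrun[j])
        loc.flank_multimap = bool(multi[j])
        loc.flank_repeat = bool(rep[j])
    return ds


def calibrate_divergence(
    target_fst: float,
    cfg: SimConfig | None = None,
    n_probe: int = 2_000,
    tol: float = 0.02,
    max_iter: int = 30,
) -> float:
    """Find a drift parameter F whose realized genomewide F_ST hits a target.

    Runs probe simulations (``n_probe`` loci, no missingness) at candidate F
    values and bisects on the realized ratio-of-sums Weir–Cockerham F_ST
    between the M and C samples, which is monotone in F. Returns F such that
    the probe F_ST is within ``tol`` of ``target_fst`` (well inside the
    +/-0.05 band the downstream experiments assume).
    """
    if not 0.0 < target_fst < 1.0:
        raise ValueError("target_fst must lie in the open interval (0, 1)")
    base = cfg or SimConfig()

    def realized(F: float) -> float:
        probe = SimConfig(
            n_M=base.n_M, n_C=base.n_C, n_loci=n_probe, n_chroms=base.n_chroms,
            chrom_length_bp=base.chrom_length_bp, divergence_F_MC=F,
            cline_F=base.cline_F, cline_steepness=base.cline_steepness,
            ancestral_freq_low=base.ancestral_freq_low,
            ancestral_freq_high=base.ancestral_freq_high,
            missing_rate=0.0, seed=base.seed,
        )
        ds = generate_dataset(probe)
        m = ds.sample_indices(lineage="M")
        c = ds.sample_indices(lineage="C")
        return fst_scan(ds, m, c).genomewide_ratio_of_sums

    lo, hi = 1e-4, 1.0 - 1e-4
    f_lo, f_hi = realized(lo), realized(hi)
    if not (f_lo - tol <= target_fst <= f_hi + tol):
        raise RuntimeError(
            f"target {target_fst} outside achievable bracket "
            f"[{f_lo:.3f}, {f_hi:.3f}] for F in [{lo}, {hi}]"
        )
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f_mid = realized(mid)
        if abs(f_mid - target_fst) <= tol:
            return mid
        if f_mid < target_fst:
            lo = mid
        else:
            hi = mid
    raise RuntimeError(
        f"bisection did not converge after {max_iter} iterations; "
        f"final bracket F in [{lo:.4f}, {hi:.4f}]"
    )
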