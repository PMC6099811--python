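import numpy as np
import pytest

from introgress_panel import (
    RecombinationMap,
    SimConfig,
    generate_dataset,
    recombine,
    sample_breakpoints,
    simulate_hybrids,
)


@pytest.fixture(scope="module")
def parent_ds():
    cfg = SimConfig(n_M=30, n_C=16, n_loci=1_500, n_chroms=4,
                    chrom_length_bp=10_000_000, missing_rate=0.0, seed=51)
    return generate_dataset(cfg)


@pytest.fixture(scope="module")
def rmap4():
    # 4 chromosomes x 10 Mb at 20 cM/Mb = 2 Morgans each
    return RecombinationMap.uniform(4, 10_000_000, 20.0)


class TestSampleBreakpoints:
    def test_zero_rate_map_never_recombines(self):
        rmap = RecombinationMap.uniform(1, 1_000_000, 0.0)
        rng = np.random.default_rng(0)
        assert all(sample_breakpoints(1, rmap, rng) == [] for _ in range(20))

    def test_poisson_mean_matches_genetic_length(self):
        """10 Mb at 20 cM/Mb is 2 Morgans: mean crossover count ~ 2."""
        rmap = RecombinationMap.uniform(1, 10_000_000, 20.0)
        rng = np.random.default_rng(1)
        counts = [len(sample_breakpoints(1, rmap, rng)) for _ in range(10_000)]
        mean = np.mean(counts)
        se = np.sqrt(2.0 / 10_000)  # Poisson variance = mean
        assert abs(mean - 2.0) < 3 * se

    def test_density_proportional_to_rate(self):
        """Windows at rates 10 and 30 receive breakpoints 1:3."""
        rmap = RecombinationMap(
            {1: np.array([[0, 1_000_000, 10.0], [1_000_000, 2_000_000, 30.0]])}
        )
        rng = np.random.default_rng(2)
        hits_high = total = 0
        for _ in range(4_000):
            for b in sample_breakpoints(1, rmap, rng):
                total += 1
                hits_high += b >= 1_000_000
        frac = hits_high / total
        se = np.sqrt(0.75 * 0.25 / total)
        assert abs(frac - 0.75) < 3 * se

    def test_uncovered_chrom_rejected(self, rmap4):
        with pytest.raises(KeyError):
            sample_breakpoints(99, rmap4, np.random.default_rng(0))


class TestRecombine:
    def test_no_breakpoints_copies_one_parent(self):
        pos = np.array([100, 200, 300])
        a = np.array([0, 0, 0], dtype=np.int8)
        b = np.array([1, 1, 1], dtype=np.int8)
        child, tracts = recombine(a, b, pos, [], chrom=1, chrom_length=1_000,
                                  start_with_a=True)
        np.testing.assert_array_equal(child, a)
        assert len(tracts) == 1
        assert (tracts[0].start_bp, tracts[0].end_bp, tracts[0].source) == (0, 1_000, "M")

    def test_single_breakpoint_switches_at_boundary(self):
        pos = np.array([100, 200, 300, 400])
        a = np.zeros(4, dtype=np.int8)
        b = np.ones(4, dtype=np.int8)
        child, tracts = recombine(a, b, pos, [250], chrom=1, chrom_length=1_000,
                                  start_with_a=True)
        np.testing.assert_array_equal(child, [0, 0, 1, 1])
        assert [(t.source, t.start_bp, t.end_bp) for t in tracts] == [
            ("M", 0, 250), ("C", 250, 1_000)]

    def test_allele_matches_covering_tract(self):
        """Random trials: every allele equals its tract's source parent."""
        rng = np.random.default_rng(3)
        for _ in range(200):
            L = int(rng.integers(2, 40))
            chrom_len = 10_000
            pos = np.sort(rng.choice(np.arange(1, chrom_len), size=L, replace=False))
            a = rng.integers(0, 2, L).astype(np.int8)
            b = rng.integers(0, 2, L).astype(np.int8)
            n_b = int(rng.integers(0, 6))
            bps = sorted(rng.choice(np.arange(1, chrom_len), size=n_b,
                                    replace=False).tolist())
            start_a = bool(rng.random() < 0.5)
            child, tracts = recombine(a, b, pos, bps, chrom=1,
                                      chrom_length=chrom_len, start_with_a=start_a)
            # tracts tile the chromosome and alternate in source
            assert tracts[0].start_bp == 0 and tracts[-1].end_bp == chrom_len
            for t1, t2 in zip(tracts, tracts[1:]):
                assert t1.end_bp == t2.start_bp and t1.source != t2.source
            for j, p in enumerate(pos):
                t = next(t for t in tracts if t.start_bp < p <= t.end_bp)
                expected = a[j] if t.source == "M" else b[j]
                assert child[j] == expected

    def test_mismatched_loci_rejected(self):
        with pytest.raises(ValueError):
            recombine(np.zeros(3), np.zeros(4), np.arange(1, 4), [], 1, 100, True)


class TestSimulateHybrids:
    def test_default_design_makes_29_hybrids(self):
        cfg = SimConfig(n_M=35, n_C=16, n_loci=400, n_chroms=4,
                        chrom_length_bp=10_000_000, seed=52)
        ds = generate_dataset(cfg)
        rmap = RecombinationMap.uniform(4, 10_000_000, 20.0)
        records, hybrids = simulate_hybrids(
            ds, ds.sample_indices(lineage="M"), ds.sample_indices(lineage="C"),
            rmap, seed=0)
        assert len(records) == 29
        assert sum(r.generation == "F1" for r in records) == 15
        assert sum(r.generation == "BC1" for r in records) == 14
        assert hybrids.n_samples == 29
        assert hybrids.n_loci == ds.n_loci
        # each pure parent is used exactly once
        parents = [p for r in records for p in r.parent_ids
                   if not p.startswith(("F1_", "BC1_"))]
        assert len(parents) == len(set(parents)) == 15 + 15 + 14

    def test_insufficient_parents_rejected(self, parent_ds, rmap4):
        m = parent_ds.sample_indices(lineage="M")
        c = parent_ds.sample_indices(lineage="C")
        with pytest.raises(ValueError, match="holdout M"):
            simulate_hybrids(parent_ds, m[:10], c, rmap4)
        with pytest.raises(ValueError, match="holdout C"):
            simulate_hybrids(parent_ds, m, c[:5], rmap4)

    def test_tracts_tile_and_fractions_bounded(self, parent_ds, rmap4):
        records, _ = simulate_hybrids(
            parent_ds, parent_ds.sample_indices(lineage="M"),
            parent_ds.sample_indices(lineage="C"), rmap4, seed=1,
            n_f1=4, n_bc1=3)
        for r in records:
            assert 0.0 <= r.realized_c_fraction_loci <= 1.0
            assert 0.0 <= r.realized_c_fraction_bp <= 1.0
            by_chrom: dict[int, list] = {}
            for t in r.tracts:
                by_chrom.setdefault(t.chrom, []).append(t)
            for chrom, tr in by_chrom.items():
                assert tr[0].start_bp == 0
                assert tr[-1].end_bp == rmap4.chrom_length(chrom)
                total = sum(t.length for t in tr)
                assert total == rmap4.chrom_length(chrom)

    def test_mean_c_fractions(self, parent_ds, rmap4):
        """F1 mean C-fraction ~ 0.5, BC1 ~ 0.25 over seeded repetitions."""
        f1, bc1 = [], []
        for seed in range(60):
            records, _ = simulate_hybrids(
                parent_ds, parent_ds.sample_indices(lineage="M"),
                parent_ds.sample_indices(lineage="C"), rmap4, seed=seed,
                n_f1=5, n_bc1=4)
            f1.append(np.mean([r.realized_c_fraction_bp for r in records
                               if r.generation == "F1"]))
            bc1.append(np.mean([r.realized_c_fraction_bp for r in records
                                if r.generation == "BC1"]))
        for vals, expect in ((f1, 0.5), (bc1, 0.25)):
            se = np.std(vals, ddof=1) / np.sqrt(len(vals))
            assert abs(np.mean(vals) - expect) < 3 * se + 1e-3

    def test_f1_fraction_tightens_with_longer_map(self, parent_ds):
        """More crossovers pull F1 realized fractions toward 0.5."""
        spreads = []
        for rate in (5.0, 40.0):
            rmap = RecombinationMap.uniform(4, 10_000_000, rate)
            vals = []
            for seed in range(40):
                records, _ = simulate_hybrids(
                    parent_ds, parent_ds.sample_indices(lineage="M"),
                    parent_ds.sample_indices(lineage="C"), rmap, seed=seed,
                    n_f1=5, n_bc1=0)
                vals.extend(r.realized_c_fraction_bp for r in records)
            spreads.append(np.var(vals))
        assert spreads[1] < spreads[0]

    def test_seeded_determinism(self, parent_ds, rmap4):
        kw = dict(seed=4, n_f1=3, n_bc1=2)
        m = parent_ds.sample_indices(lineage="M")
        c = parent_ds.sample_indices(lineage="C")
        r1, h1 = simulate_hybrids(parent_ds, m, c, rmap4, **kw)
        r2, h2 = simulate_hybrids(parent_ds, m, c, rmap4, **kw)
        np.testing.assert_array_equal(h1.calls, h2.calls)
        assert [r.realized_c_fraction_bp for r in r1] == \
               [r.realized_c_fraction_bp for r in r2]
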