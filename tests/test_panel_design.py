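import warnings

import numpy as np
import pytest

from introgress_panel import (
    HaploidDataset,
    LocusRecord,
    SampleRecord,
    apply_flank_filters,
    assemble_multiplexes,
    build_random_assays,
    split_train_holdout,
    thin_by_distance,
)


def _locus(pos, effect="intron", chrom=1, **kw):
    return LocusRecord(locus_id=f"c{chrom}_{pos}", chrom=chrom, pos=pos,
                       effect_class=effect, **kw)


def _dataset(n_loci=800, n_chroms=16, seed=0, functional_every=10):
    """Deterministic candidate dataset: loci spread over chromosomes, 40 kb
    apart, every tenth locus functional."""
    rng = np.random.default_rng(seed)
    loci = []
    per_chrom = n_loci // n_chroms
    k = 0
    for chrom in range(1, n_chroms + 1):
        for i in range(per_chrom):
            effect = "missense" if k % functional_every == 0 else "intron"
            loci.append(_locus(40_000 * (i + 1), effect, chrom))
            k += 1
    samples = [SampleRecord(f"s{i}", population="IHB") for i in range(4)]
    calls = np.zeros((4, len(loci)), dtype=np.int8)
    return HaploidDataset(samples=samples, loci=loci, calls=calls)


class TestSplit:
    def test_study_scale_counts(self):
        """117 + 59 at 25% leaves holdout 29 + 15, training 88 + 44."""
        samples = [SampleRecord(f"i{i}", population="IHB") for i in range(117)]
        samples += [SampleRecord(f"c{i}", population="CAR") for i in range(28)]
        samples += [SampleRecord(f"l{i}", population="LIG") for i in range(31)]
        ds = HaploidDataset(samples=samples, loci=[_locus(100)],
                            calls=np.zeros((176, 1), dtype=np.int8))
        split_train_holdout(ds, 0.25, seed=0)
        m_hold = ds.sample_indices(lineage="M", role="holdout")
        c_hold = ds.sample_indices(lineage="C", role="holdout")
        assert len(m_hold) == 29
        assert len(c_hold) == 15
        assert len(ds.sample_indices(lineage="M", role="training")) == 88
        assert len(ds.sample_indices(lineage="C", role="training")) == 44

    def test_even_split(self):
        samples = [SampleRecord(f"a{i}", population="IHB") for i in range(4)]
        samples += [SampleRecord(f"b{i}", population="CAR") for i in range(4)]
        ds = HaploidDataset(samples=samples, loci=[_locus(100)],
                            calls=np.zeros((8, 1), dtype=np.int8))
        split_train_holdout(ds, 0.5, seed=1)
        assert len(ds.sample_indices(population="IHB", role="holdout")) == 2
        assert len(ds.sample_indices(population="CAR", role="holdout")) == 2

    def test_seed_contract(self):
        def split_ids(seed):
            samples = [SampleRecord(f"a{i}", population="IHB") for i in range(20)]
            ds = HaploidDataset(samples=samples, loci=[_locus(100)],
                                calls=np.zeros((20, 1), dtype=np.int8))
            return tuple(split_train_holdout(ds, 0.25, seed=seed)["holdout"])

        assert split_ids(5) == split_ids(5)
        assert split_ids(5) != split_ids(6)
        assert len(split_ids(5)) == len(split_ids(6)) == 5

    def test_tiny_stratum_rejected(self):
        samples = [SampleRecord("a", population="IHB"),
                   SampleRecord("b", population="CAR")] + [
            SampleRecord(f"x{i}", population="LIG") for i in range(8)]
        ds = HaploidDataset(samples=samples, loci=[_locus(100)],
                            calls=np.zeros((10, 1), dtype=np.int8))
        with pytest.raises(ValueError):
            split_train_holdout(ds, 0.25, seed=0)


class TestThinByDistance:
    def test_functional_priority_example(self):
        """intron@1000 vs missense@4000 conflict: missense wins; 9500 clears."""
        loci = [_locus(1_000, "intron"), _locus(4_000, "missense"),
                _locus(9_500, "intron")]
        assert thin_by_distance(loci) == {"c1_4000", "c1_9500"}

    def test_tie_keeps_lower_position(self):
        loci = [_locus(1_000, "intron"), _locus(2_000, "intron")]
        assert thin_by_distance(loci) == {"c1_1000"}

    def test_unsorted_rejected(self):
        loci = [_locus(5_000), _locus(1_000)]
        with pytest.raises(ValueError, match="sorted"):
            thin_by_distance(loci)

    def test_chromosomes_independent(self):
        loci = [_locus(1_000, chrom=1), _locus(2_000, chrom=2)]
        assert thin_by_distance(loci) == {"c1_1000", "c2_2000"}

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_no_close_pair_and_maximality(self, seed):
        """Oracle properties on random inputs: the retained set has no pair
        closer than 5 kb (checked pairwise by brute force), every dropped
        locus conflicts with a retained one (maximality), and the priority
        rule never retains fewer functional loci than a priority-blind run."""
        rng = np.random.default_rng(seed)
        positions = np.sort(rng.choice(np.arange(1, 2_000_000), size=1_000,
                                       replace=False))
        effects = rng.choice(["intron", "missense"], size=1_000, p=[0.8, 0.2])
        loci = [_locus(int(p), e) for p, e in zip(positions, effects)]
        kept = thin_by_distance(loci)
        kept_pos = np.sort([l.pos for l in loci if l.locus_id in kept])
        # brute-force pairwise check
        diff = kept_pos[:, None] - kept_pos[None, :]
        off = ~np.eye(len(kept_pos), dtype=bool)
        assert np.abs(diff[off]).min() >= 5_000
        # maximality: every dropped locus is within 5 kb of a retained one
        for l in loci:
            if l.locus_id not in kept:
                assert np.abs(kept_pos - l.pos).min() < 5_000
        # functional priority pays off against a priority-blind sweep
        blind = thin_by_distance([_locus(l.pos, "intron") for l in loci])
        n_func_kept = sum(1 for l in loci
                          if l.locus_id in kept and l.effect_class == "missense")
        n_func_blind = sum(1 for l in loci
                           if f"c1_{l.pos}" in blind and l.effect_class == "missense")
        assert n_func_kept >= n_func_blind


class TestFlankFilters:
    def test_boundary_values(self):
        """>5 removes, =5 retains, on both flanks and the N-run rule."""
        loci = [
            _locus(1_000, flank_variable_left=6),
            _locus(10_000, flank_variable_left=5),
            _locus(20_000, flank_variable_right=6),
            _locus(30_000, flank_max_n_run=6),
            _locus(40_000, flank_max_n_run=5),
            _locus(50_000, flank_multimap=True),
            _locus(60_000, flank_repeat=True),
            _locus(70_000),
        ]
        kept, counts = apply_flank_filters(loci)
        assert kept == {"c1_10000", "c1_40000", "c1_70000"}
        assert counts == {"variable_left": 1, "variable_right": 1, "n_run": 1,
                          "multimap": 1, "repeat": 1}

    def test_first_failing_rule_attribution(self):
        loci = [_locus(1_000, flank_variable_left=9, flank_multimap=True)]
        _, counts = apply_flank_filters(loci)
        assert counts["variable_left"] == 1
        assert counts["multimap"] == 0


class TestAssembleMultiplexes:
    def test_constraint_audit(self):
        ds = _dataset(n_loci=800)
        candidates = set(ds.locus_ids)
        panels = assemble_multiplexes(ds, candidates, seed=0)
        assert len(panels) == 4
        ids = [set(p.locus_ids) for p in panels]
        for i in range(4):
            assert len(ids[i]) <= 40
            assert panels[i].audit["n_functional"] >= 4
            assert panels[i].audit["chroms_covered"] == list(range(1, 17))
            for j in range(i + 1, 4):
                assert not ids[i] & ids[j]

    def test_missing_chromosome_warns(self):
        ds = _dataset(n_loci=800)
        candidates = {lid for lid in ds.locus_ids
                      if not lid.startswith("c16_")}
        with pytest.warns(UserWarning, match="chromosome"):
            panels = assemble_multiplexes(ds, candidates, n_panels=1, seed=0)
        assert panels[0].audit["chroms_covered"] == list(range(1, 16))

    def test_reject_all_predicate_errors(self):
        ds = _dataset(n_loci=160)
        with pytest.raises(RuntimeError, match="compatibility"):
            assemble_multiplexes(ds, set(ds.locus_ids), n_panels=1,
                                 compat=lambda loc, sel: False, seed=0)

    def test_empty_pool_rejected(self):
        ds = _dataset(n_loci=160)
        with pytest.raises(ValueError, match="empty"):
            assemble_multiplexes(ds, set(), seed=0)

    def test_seeded_determinism(self):
        ds = _dataset(n_loci=800)
        a = assemble_multiplexes(ds, set(ds.locus_ids), seed=3)
        b = assemble_multiplexes(ds, set(ds.locus_ids), seed=3)
        assert [p.locus_ids for p in a] == [p.locus_ids for p in b]


class TestRandomAssays:
    def test_exact_sizes_and_disjoint(self):
        ds = _dataset(n_loci=800)
        panels = build_random_assays(ds, [37, 38, 40, 38], seed=0)
        assert [p.size for p in panels] == [37, 38, 40, 38]
        all_ids = [lid for p in panels for lid in p.locus_ids]
        assert len(all_ids) == len(set(all_ids))

    def test_empty_panel(self):
        ds = _dataset(n_loci=160)
        panels = build_random_assays(ds, [0], seed=0)
        assert panels[0].size == 0

    def test_infeasible_sizes_rejected(self):
        ds = _dataset(n_loci=160)
        with pytest.raises(ValueError):
            build_random_assays(ds, [100, 100], seed=0)

    def test_seeded_determinism(self):
        ds = _dataset(n_loci=800)
        a = build_random_assays(ds, [40, 40], seed=5)
        b = build_random_assays(ds, [40, 40], seed=5)
        assert [p.locus_ids for p in a] == [p.locus_ids for p in b]
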