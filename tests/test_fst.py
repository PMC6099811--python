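import numpy as np
import pytest

from introgress_panel import (
    MISSING,
    SimConfig,
    find_fixed,
    fst_scan,
    generate_dataset,
    wc_theta,
)

from conftest import make_toy_dataset


def indicator_anova_theta(x1: np.ndarray, x2: np.ndarray) -> float:
    """Independent oracle: variance components from raw allele indicators.

    Builds the one-way ANOVA sums of squares directly on the 0/1 allele
    observations instead of the (n, p) summaries the estimator consumes.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    n1, n2 = len(x1), len(x2)
    allx = np.concatenate([x1, x2])
    grand = allx.mean()
    ssb = n1 * (x1.mean() - grand) ** 2 + n2 * (x2.mean() - grand) ** 2
    ssw = ((x1 - x1.mean()) ** 2).sum() + ((x2 - x2.mean()) ** 2).sum()
    msp = ssb / 1.0  # r - 1 = 1
    msg = ssw / (n1 - 1 + n2 - 1)
    n = n1 + n2
    nc = n - (n1 * n1 + n2 * n2) / n
    den = msp + (nc - 1) * msg
    if den == 0:
        return float("nan")
    return (msp - msg) / den


class TestWcTheta:
    def test_opposite_fixation_is_one(self):
        assert wc_theta(10, 1.0, 10, 0.0).theta == 1.0
        assert wc_theta(3, 0.0, 7, 1.0).theta == 1.0
        # exactly 1 even with a single haplotype per group
        assert wc_theta(1, 1.0, 1, 0.0).theta == 1.0

    def test_equal_intermediate_frequencies(self):
        """n1 = n2 = 10, p = 0.5 in both: MSP = 0, MSG = 5/18, theta = -1/9."""
        rec = wc_theta(10, 0.5, 10, 0.5)
        assert rec.msp == pytest.approx(0.0)
        assert rec.msg == pytest.approx(5 / 18)
        assert rec.theta == pytest.approx(-1 / 9, abs=1e-15)

    def test_against_indicator_oracle_single_case(self):
        x1 = np.array([1, 1, 1, 0])            # n1=4, p1=0.75
        x2 = np.array([0, 0, 0, 0, 0, 1])      # n2=6, p2=1/6
        rec = wc_theta(4, 0.75, 6, 1 / 6)
        assert rec.theta == pytest.approx(indicator_anova_theta(x1, x2), abs=1e-12)

    def test_against_indicator_oracle_random(self):
        rng = np.random.default_rng(2024)
        for _ in range(300):
            n1 = int(rng.integers(2, 40))
            n2 = int(rng.integers(2, 40))
            x1 = (rng.random(n1) < rng.random()).astype(int)
            x2 = (rng.random(n2) < rng.random()).astype(int)
            expected = indicator_anova_theta(x1, x2)
            got = wc_theta(n1, x1.mean(), n2, x2.mean()).theta
            if np.isnan(expected):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(expected, abs=1e-12)

    def test_allele_relabeling_invariance(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            n1, n2 = int(rng.integers(2, 30)), int(rng.integers(2, 30))
            p1 = rng.integers(0, n1 + 1) / n1
            p2 = rng.integers(0, n2 + 1) / n2
            a = wc_theta(n1, p1, n2, p2).theta
            b = wc_theta(n1, 1 - p1, n2, 1 - p2).theta
            assert (np.isnan(a) and np.isnan(b)) or a == pytest.approx(b, abs=1e-12)

    def test_empty_population_rejected(self):
        with pytest.raises(ValueError, match="empty population"):
            wc_theta(0, 0.0, 5, 0.5)

    def test_same_allele_fixation_undefined(self):
        assert np.isnan(wc_theta(10, 0.0, 10, 0.0).theta)
        assert np.isnan(wc_theta(10, 1.0, 10, 1.0).theta)

    def test_hudson_cross_check_on_diverged_loci(self):
        """Sign/ordering agreement with Hudson's 1 - Hw/Hb at high divergence."""
        rng = np.random.default_rng(42)
        pairs = []
        while len(pairs) < 50:
            n1 = n2 = 25
            a1 = int(rng.integers(0, n1 + 1))
            a2 = int(rng.integers(0, n2 + 1))
            p1, p2 = a1 / n1, a2 / n2
            if abs(p1 - p2) <= 0.8:
                continue
            hw = 0.5 * (2 * a1 * (n1 - a1) / (n1 * (n1 - 1))
                        + 2 * a2 * (n2 - a2) / (n2 * (n2 - 1)))
            hb = p1 * (1 - p2) + p2 * (1 - p1)
            hudson = 1 - hw / hb
            pairs.append((wc_theta(n1, p1, n2, p2).theta, hudson))
        theta, hudson = map(np.array, zip(*pairs))
        assert (np.sign(theta) == np.sign(hudson)).all()
        order_t = np.argsort(theta)
        # rank correlation of the two estimators is essentially perfect here
        rho = np.corrcoef(theta, hudson)[0, 1]
        assert rho > 0.99


class TestFstScan:
    def test_all_opposite_fixed(self):
        calls = np.array([[1, 1, 1], [1, 1, 1], [0, 0, 0], [0, 0, 0]])
        ds = make_toy_dataset(calls)
        t = fst_scan(ds, [0, 1], [2, 3])
        assert np.allclose(t.theta, 1.0)
        assert t.genomewide_ratio_of_sums == pytest.approx(1.0)

    def test_ratio_of_sums_hand_computed(self):
        """Mixed 3-locus toy: ratio of sums = sum(num)/sum(den) by hand."""
        calls = np.array([
            [1, 1, 0],
            [1, 0, 1],
            [0, 1, 1],
            [0, 0, 0],
        ])
        ds = make_toy_dataset(calls)
        t = fst_scan(ds, [0, 1], [2, 3])
        nums, dens = [], []
        for j in range(3):
            x1, x2 = calls[:2, j], calls[2:, j]
            n1, n2 = 2, 2
            p1, p2 = x1.mean(), x2.mean()
            pbar = (p1 + p2) / 2
            msp = n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2
            msg = (n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)) / 2
            nc = 4 - (4 + 4) / 4
            nums.append(msp - msg)
            dens.append(msp + (nc - 1) * msg)
        assert t.genomewide_ratio_of_sums == pytest.approx(sum(nums) / sum(dens))

    def test_panmictic_null_near_zero(self):
        """Random splits of one panmictic population give F_ST ~ 0."""
        rng = np.random.default_rng(77)
        freqs = rng.uniform(0.1, 0.9, size=400)
        calls = (rng.random((40, 400)) < freqs).astype(np.int8)
        ds = make_toy_dataset(calls)
        values = []
        for rep in range(20):
            perm = np.random.default_rng(rep).permutation(40)
            t = fst_scan(ds, perm[:20], perm[20:])
            values.append(t.genomewide_ratio_of_sums)
        values = np.array(values)
        assert abs(values.mean()) < 3 * values.std(ddof=1) / np.sqrt(len(values)) + 0.01

    def test_missing_only_group_is_undefined(self):
        calls = np.array([[MISSING, 1], [MISSING, 0], [1, 1], [0, 0]])
        ds = make_toy_dataset(calls)
        t = fst_scan(ds, [0, 1], [2, 3])
        assert np.isnan(t.theta[0])
        assert not np.isnan(t.genomewide_ratio_of_sums)

    def test_overlapping_groups_rejected(self, small_ds):
        with pytest.raises(ValueError, match="overlap"):
            fst_scan(small_ds, [0, 1], [1, 2])


class TestFindFixed:
    def test_toy_selection(self):
        calls = np.array([
            [1, 0, 1, 1],
            [1, 0, 1, 1],
            [0, 1, 1, 0],
            [0, 1, 1, 0],
        ])
        # p1, p2 per locus: (1,0), (0,1), (1,1), (1,0)
        ds = make_toy_dataset(calls)
        t = fst_scan(ds, [0, 1], [2, 3])
        assert find_fixed(t) == {"l0", "l1", "l3"}

    def test_nearly_fixed_excluded(self):
        calls = np.array([
            [1, 1], [1, 1], [1, 1], [1, 1], [1, 1],
            [1, 1], [1, 1], [1, 1], [1, 0], [1, 0],
            [0, 0], [0, 0],
        ])
        ds = make_toy_dataset(calls)
        t = fst_scan(ds, list(range(10)), [10, 11])
        # locus 1 has p1 = 0.8: not fixed
        assert find_fixed(t) == {"l0"}

    def test_empty_table(self):
        ds = make_toy_dataset(np.empty((4, 0), dtype=np.int8))
        t = fst_scan(ds, [0, 1], [2, 3])
        assert find_fixed(t) == set()

    def test_subset_monotonicity_complete_case(self, complete_ds):
        """On complete data, full-sample fixed set <= any subsample's fixed set."""
        m = complete_ds.sample_indices(lineage="M")
        c = complete_ds.sample_indices(lineage="C")
        full = find_fixed(fst_scan(complete_ds, m, c))
        rng = np.random.default_rng(1)
        for _ in range(30):
            size = int(rng.integers(3, len(m)))
            sub = rng.choice(m, size=size, replace=False)
            sub_fixed = find_fixed(fst_scan(complete_ds, sub, c))
            assert full <= sub_fixed
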