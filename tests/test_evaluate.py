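"""NF/NRQ normalization and Mann-Whitney group comparison."""

import itertools

import numpy as np
import pytest

from refstab import (
    DropoutSpec,
    SimulationConfig,
    compare_groups,
    generate,
    mann_whitney,
    normalize,
    run_qc,
    to_log2_rq,
)
from conftest import make_matrix


def exact_mw_p(x, y):
    """Exhaustive-enumeration oracle for the two-sided exact p-value:
    the null probability (over all group assignments of the pooled
    values) that min(U_x, U_y) is at least as extreme as observed."""
    pooled = list(x) + list(y)
    n1, n2 = len(x), len(y)

    def u_min(xs, ys):
        u1 = sum(1 for a in xs for b in ys if a > b)
        return min(u1, n1 * n2 - u1)

    observed = u_min(x, y)
    count = total = 0
    for pos in itertools.combinations(range(len(pooled)), n1):
        chosen = set(pos)
        xs = [pooled[i] for i in chosen]
        ys = [pooled[i] for i in range(len(pooled)) if i not in chosen]
        total += 1
        if u_min(xs, ys) <= observed:
            count += 1
    return count / total


class TestMannWhitney:
    def test_complete_separation_small_groups(self):
        u, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0
        assert p == pytest.approx(0.1)
        assert p == pytest.approx(exact_mw_p([1, 2, 3], [4, 5, 6]))

    @pytest.mark.parametrize("seed", range(4))
    def test_exact_p_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        x = list(rng.normal(size=rng.integers(2, 6)))
        y = list(rng.normal(size=rng.integers(2, 6)))
        _, p = mann_whitney(x, y)
        assert p == pytest.approx(exact_mw_p(x, y), abs=1e-12)

    def test_identical_groups_p_one(self):
        x = [1.0, 2.0, 3.0, 4.0]
        _, p = mann_whitney(x, x)
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_symmetric_in_group_order(self, rng):
        x, y = rng.normal(size=8), rng.normal(1, 1, size=9)
        u1, p1 = mann_whitney(x, y)
        u2, p2 = mann_whitney(y, x)
        assert u1 == u2 and p1 == pytest.approx(p2)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


def two_group_rq(values, n_a, n_b):
    samples = [f"a{j:02d}" for j in range(n_a)] + [f"b{j:02d}" for j in range(n_b)]
    groups = {s: s[0] for s in samples}
    return make_matrix(values, samples=samples, groups=groups, scale="log2rq")


class TestNormalize:
    def test_self_normalization_is_unity(self, rng):
        m = two_group_rq(rng.normal(0, 1, (3, 8)), 4, 4)
        rep = normalize(m, rg_set=["g0"], targets=["g0"])
        np.testing.assert_allclose(rep.nrq.loc["g0"], 1.0, atol=1e-12)

    def test_nf_is_geometric_mean(self):
        # RQ of the two references in sample 0: 1 and 4 -> NF = 2
        log2 = [[0.0, 1.0], [2.0, 1.0], [3.0, 0.0]]
        m = two_group_rq(log2, 1, 1)
        rep = normalize(m, rg_set=["g0", "g1"], targets=["g2"])
        assert rep.nf.iloc[0] == pytest.approx(2.0)
        assert rep.nrq.loc["g2"].iloc[0] == pytest.approx(8.0 / 2.0)

    def test_mean_anchored_nf_centres_to_one(self, rng):
        cq = make_matrix(rng.uniform(18, 30, (5, 10)), scale="cq")
        log2rq = to_log2_rq(cq)
        rep = normalize(log2rq, rg_set=["g0", "g1"], targets=["g2"])
        gm = np.exp(np.log(rep.nf).mean())
        assert gm == pytest.approx(1.0, abs=1e-9)

    def test_qc_excluded_reference_is_named(self):
        cfg = SimulationConfig(
            n_stable=3, n_unstable=2, n_regulated=0, n_per_group=(4, 4),
            dropout=DropoutSpec(n_genes=1, total_missing=3), seed=3,
        )
        panel, truth = generate(cfg)
        dropped = next(iter(truth.dropout_cells))
        matrix, _ = run_qc(panel)
        log2rq = to_log2_rq(matrix)
        with pytest.raises(ValueError, match=dropped):
            normalize(log2rq, rg_set=[dropped])


class TestCompareGroups:
    def planted(self, rng, delta_log2, n=20, sigma=0.3):
        # one flat reference pair, one target shifted in group b
        k, total = 3, 2 * n
        values = rng.normal(0, sigma, (k, total))
        values[2, n:] += delta_log2
        return two_group_rq(values, n, n)

    def test_planted_shift_is_detected(self, rng):
        m = self.planted(rng, delta_log2=2.0)
        rep = compare_groups(normalize(m, ["g0", "g1"], ["g2"]))
        row = rep.comparisons.loc["g2"]
        assert row["p_value"] < 0.01
        assert row["fold_change"] > 1
        assert row["significance"] == "**"

    def test_identical_groups_fold_change_one(self):
        values = np.tile(np.array([[0.0, 1.0, -1.0, 0.5]]), (3, 1))
        m = two_group_rq(np.hstack([values, values]), 4, 4)
        rep = compare_groups(normalize(m, ["g0"], ["g2"]))
        assert rep.comparisons.loc["g2", "fold_change"] == pytest.approx(1.0)

    def test_type_one_error_rate_controlled(self):
        rejections = 0
        reps = 200
        for seed in range(reps):
            rng = np.random.default_rng(seed)
            m = self.planted(rng, delta_log2=0.0)
            rep = compare_groups(normalize(m, ["g0", "g1"], ["g2"]))
            if rep.comparisons.loc["g2", "p_value"] < 0.05:
                rejections += 1
        assert 0.02 < rejections / reps < 0.09

    def test_invariant_to_common_nf_rescaling(self, rng):
        m = self.planted(rng, delta_log2=1.0)
        rep1 = compare_groups(normalize(m, ["g0", "g1"], ["g2"]))
        shifted = make_matrix(
            (m.data + 1.7).to_numpy(), samples=m.samples, groups=m.groups
        )  # scales every sample's RQ, hence NF, by the same constant
        rep2 = compare_groups(normalize(shifted, ["g0", "g1"], ["g2"]))
        assert rep1.comparisons.loc["g2", "p_value"] == pytest.approx(
            rep2.comparisons.loc["g2", "p_value"]
        )

    def test_biased_references_bias_targets_oppositely(self, rng):
        # references carry a planted +1 log2 group effect; a truly null
        # target then appears DOWN-regulated after normalization
        k, n = 3, 30
        values = rng.normal(0, 0.2, (k, 2 * n))
        values[0, n:] += 1.0
        values[1, n:] += 1.0
        m = two_group_rq(values, n, n)
        rep = compare_groups(normalize(m, ["g0", "g1"], ["g2"]))
        assert rep.comparisons.loc["g2", "fold_change"] < 1.0
        assert rep.comparisons.loc["g2", "p_value"] < 0.01

    def test_requires_two_groups(self, rng):
        m = make_matrix(rng.normal(0, 1, (3, 6)), scale="log2rq")
        with pytest.raises(ValueError, match="2 groups"):
            compare_groups(normalize(m, ["g0"], ["g2"]))
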