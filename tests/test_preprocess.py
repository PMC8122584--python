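"""Normalisation, variance/Cox feature selection and fusion."""

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from omicsfuse.preprocess import (
    ClinicalTable,
    OmicsBlock,
    cox_univariate,
    fuse,
    minmax_normalize,
    restrict,
    select_by_cox,
    select_by_variance,
)


def block_of(values, name="mrna"):
    values = np.asarray(values, dtype=float)
    return OmicsBlock(
        values=values,
        sample_ids=[f"s{i}" for i in range(values.shape[0])],
        feature_ids=[f"f{j}" for j in range(values.shape[1])],
        omic_name=name,
    )


# ---------------------------------------------------------------------------
# min-max normalisation
# ---------------------------------------------------------------------------

class TestMinMax:
    def test_basic_column_scaling(self):
        out = minmax_normalize(block_of([[2], [4], [6]]))
        np.testing.assert_allclose(out.values[:, 0], [0.0, 0.5, 1.0])

    def test_constant_feature_maps_to_zero(self):
        out = minmax_normalize(block_of([[5], [5], [5]]))
        np.testing.assert_array_equal(out.values[:, 0], [0.0, 0.0, 0.0])

    def test_full_range_column_is_unchanged(self):
        out = minmax_normalize(block_of([[0.0], [0.25], [1.0]]))
        np.testing.assert_allclose(out.values[:, 0], [0.0, 0.25, 1.0])

    def test_idempotent_on_full_range_blocks(self):
        rng = np.random.default_rng(0)
        x = rng.random((20, 5))
        x[0] = 0.0
        x[1] = 1.0  # every feature spans [0, 1]
        once = minmax_normalize(block_of(x))
        twice = minmax_normalize(once)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-15)

    def test_bounds_always_hold(self):
        rng = np.random.default_rng(1)
        out = minmax_normalize(block_of(rng.normal(3, 10, (30, 8))))
        assert out.values.min() >= 0.0 and out.values.max() <= 1.0

    def test_missing_values_rejected_at_load(self):
        with pytest.raises(ValueError, match="missing"):
            block_of([[1.0], [np.nan], [2.0]])


# ---------------------------------------------------------------------------
# variance selection
# ---------------------------------------------------------------------------

class TestVarianceSelection:
    def test_matches_brute_force_ranking(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, rng.uniform(0.1, 3.0, 12), size=(40, 12))
        block = block_of(x)
        sel = select_by_variance(block, 5)
        var = x.var(axis=0, ddof=1)
        expected = sorted(np.argsort(-var)[:5])
        assert sel.kept_ids == [block.feature_ids[i] for i in expected]

    def test_known_variances(self):
        x = np.array([[0.0, -1.0, -2.0], [0.0, 0.0, 0.0], [0.0, 1.0, 2.0]])
        sel = select_by_variance(block_of(x), 2)  # variances 0, 1, 4
        assert sel.kept_ids == ["f1", "f2"]

    def test_invariant_to_sample_reordering(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(25, 10))
        sel1 = select_by_variance(block_of(x), 4)
        perm = rng.permutation(25)
        shuffled = OmicsBlock(
            x[perm], [f"s{i}" for i in perm], [f"f{j}" for j in range(10)], "mrna"
        )
        sel2 = select_by_variance(shuffled, 4)
        assert sel1.kept_ids == sel2.kept_ids

    def test_k_equal_to_width_keeps_original_order(self):
        block = block_of(np.random.default_rng(4).normal(size=(10, 6)))
        sel = select_by_variance(block, 6)
        assert sel.kept_ids == block.feature_ids

    @pytest.mark.parametrize("k", [0, 7, -1])
    def test_k_out_of_range(self, k):
        block = block_of(np.zeros((5, 6)) + np.arange(5)[:, None])
        with pytest.raises(ValueError, match="out of range"):
            select_by_variance(block, k)


# ---------------------------------------------------------------------------
# univariate Cox screening
# ---------------------------------------------------------------------------

def brute_force_cox(x, time, event):
    """Independent maximization of the loop-written Breslow partial
    likelihood, with numerical information for the Wald statistic."""
    x = np.asarray(x, float)
    time = np.asarray(time, float)
    event = np.asarray(event, int)

    def negpl(beta):
        ll = 0.0
        for t in np.unique(time[event == 1]):
            tied = (time == t) & (event == 1)
            risk = time >= t
            ll += beta * x[tied].sum() - tied.sum() * np.log(
                np.exp(beta * x[risk]).sum()
            )
        return -ll

    res = minimize_scalar(negpl, bounds=(-20, 20), method="bounded",
                          options={"xatol": 1e-12})
    beta = res.x
    h = 1e-4
    info = (negpl(beta + h) - 2 * negpl(beta) + negpl(beta - h)) / h**2
    return beta, 1.0 / np.sqrt(info)


@pytest.fixture(scope="module")
def ten_sample_fixture():
    rng = np.random.default_rng(5)
    x = rng.normal(size=10)
    time = rng.exponential(100, size=10) * np.exp(-0.5 * x)
    event = np.ones(10, dtype=int)
    event[[2, 7]] = 0
    return x, time, event


class TestCoxScreening:
    def test_newton_matches_brute_force_maximization(self, ten_sample_fixture):
        x, time, event = ten_sample_fixture
        beta, se, _ = cox_univariate(x, time, event)
        beta_b, se_b = brute_force_cox(x, time, event)
        assert abs(beta - beta_b) < 1e-6
        assert abs(beta / se - beta_b / se_b) < 1e-6  # Wald statistic

    def test_matches_breslow_reference_implementation(self, ten_sample_fixture):
        sksurv = pytest.importorskip("sksurv.linear_model")
        x, time, event = ten_sample_fixture
        beta, _, _ = cox_univariate(x, time, event)
        y = np.array(
            [(bool(e), t) for e, t in zip(event, time)],
            dtype=[("event", bool), ("time", float)],
        )
        ref = sksurv.CoxPHSurvivalAnalysis(ties="breslow", tol=1e-12)
        ref.fit(x.reshape(-1, 1), y)
        assert abs(beta - ref.coef_[0]) < 1e-6

    def test_signal_feature_kept_noise_feature_mostly_dropped(self):
        rng = np.random.default_rng(7)
        n = 300
        signal = rng.normal(size=n)
        noise = rng.normal(size=n)
        time = rng.exponential(1000, size=n) * np.exp(-1.5 * signal)
        event = np.ones(n, dtype=int)
        block = OmicsBlock(
            np.column_stack([signal, noise]),
            [f"s{i}" for i in range(n)],
            ["signal", "noise"],
            "mrna",
        )
        clin = ClinicalTable([f"s{i}" for i in range(n)], time, event)
        sel = select_by_cox(block, clin, alpha=0.05)
        assert "signal" in sel.kept_ids
        assert sel.scores["signal"] < 1e-10

    def test_constant_feature_is_skipped_not_fatal(self):
        rng = np.random.default_rng(8)
        n = 50
        x = np.column_stack([np.full(n, 3.0), rng.normal(size=n)])
        block = block_of(x)
        clin = ClinicalTable(
            block.sample_ids, rng.exponential(100, n), np.ones(n, dtype=int)
        )
        sel = select_by_cox(block, clin, alpha=1.0)
        assert sel.skipped_ids == ["f0"]
        assert sel.kept_ids == ["f1"]  # alpha=1 keeps every testable feature

    def test_requires_at_least_one_event(self):
        block = block_of(np.random.default_rng(9).normal(size=(10, 2)))
        clin = ClinicalTable(
            block.sample_ids, np.arange(10.0) + 1, np.zeros(10, dtype=int)
        )
        with pytest.raises(ValueError, match="event"):
            select_by_cox(block, clin)


# ---------------------------------------------------------------------------
# fusion
# ---------------------------------------------------------------------------

class TestFuse:
    def _normalized_blocks(self, widths=(50, 40, 10)):
        rng = np.random.default_rng(10)
        names = ("mrna", "methylation", "mirna")
        return [
            minmax_normalize(block_of(rng.normal(size=(12, w)), name))
            for name, w in zip(names, widths)
        ]

    def test_width_is_sum_of_kept_features(self):
        fused = fuse(self._normalized_blocks())
        assert fused.shape == (12, 100)
        assert fused.columns[0].startswith("mrna:")
        assert fused.columns[-1].startswith("mirna:")

    def test_single_block_identity(self):
        block = self._normalized_blocks()[0]
        fused = fuse([block])
        np.testing.assert_array_equal(fused.to_numpy(), block.values)

    def test_sample_mismatch_raises_with_ids(self):
        blocks = self._normalized_blocks()
        blocks[1].sample_ids = blocks[1].sample_ids[::-1]
        with pytest.raises(ValueError, match="methylation"):
            fuse(blocks)

    def test_restriction_respects_selection_order(self):
        block = self._normalized_blocks()[0]
        sel = select_by_variance(block, 7)
        sub = restrict(block, sel)
        assert sub.feature_ids == sel.kept_ids
        cols = [block.feature_ids.index(f) for f in sel.kept_ids]
        np.testing.assert_array_equal(sub.values, block.values[:, cols])
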