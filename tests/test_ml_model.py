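import itertools

import numpy as np
import pytest
from scipy.stats import rankdata

from bulgeselect.library_model import sample_genotypes
from bulgeselect.ml_model import (
    DEFAULT_FRACTIONS,
    EncodedDataset,
    NetworkConfig,
    PositionalBaseline,
    SplitPlan,
    baseline_positional,
    compute_metrics,
    decode_one_hot,
    fit_network,
    grid_search_cv,
    learning_curve,
    make_split,
    one_hot_encode,
    run_regression,
)


class TestOneHotEncoding:
    def test_single_position_a(self):
        d = one_hot_encode(["A"], [0.0])
        assert d.X.tolist() == [[1.0, 0.0, 0.0, 0.0]]

    def test_block_sums(self, spec):
        genotypes = sample_genotypes(spec, 30, seed=1)
        d = one_hot_encode(genotypes, np.zeros(30))
        assert d.X.shape == (30, 56)
        blocks = d.X.reshape(30, 14, 4)
        assert np.all(blocks.sum(axis=2) == 1.0)
        assert np.all(d.X.sum(axis=1) == 14)

    def test_decode_round_trip(self, spec):
        genotypes = sample_genotypes(spec, 10, seed=2)
        d = one_hot_encode(genotypes, np.zeros(10))
        for i, g in enumerate(genotypes):
            assert decode_one_hot(d.X[i]) == g

    def test_non_acgt_rejected(self):
        with pytest.raises(ValueError, match="non-ACGT"):
            one_hot_encode(["AXGT"], [0.0])

    def test_nonuniform_length_rejected(self):
        with pytest.raises(ValueError):
            one_hot_encode(["AC", "ACG"], [0.0, 1.0])


class TestMakeSplit:
    def test_eighty_twenty(self):
        s = make_split(10, SplitPlan(seed=0))
        assert len(s.test) == 2
        assert len(s.train_full) == 8

    def test_disjoint_exhaustive(self):
        s = make_split(103, SplitPlan(seed=1))
        assert not (set(s.test) & set(s.train_full))
        assert len(s.test) + len(s.train_full) == 103

    def test_nesting(self):
        s = make_split(1000, SplitPlan(seed=2, fractions=(1.0, 0.5, 0.25)))
        assert set(s.subsets[0.25]) <= set(s.subsets[0.5]) <= set(s.subsets[1.0])

    def test_determinism(self):
        a = make_split(500, SplitPlan(seed=3))
        b = make_split(500, SplitPlan(seed=3))
        assert np.array_equal(a.test, b.test)
        for f in DEFAULT_FRACTIONS:
            assert np.array_equal(a.subsets[f], b.subsets[f])

    def test_no_test_leakage_into_subsets(self):
        s = make_split(200, SplitPlan(seed=4))
        for idx in s.subsets.values():
            assert not (set(idx) & set(s.test))

    def test_too_few_rows(self):
        with pytest.raises(ValueError):
            make_split(5, SplitPlan())


class TestMetrics:
    def test_perfect_predictions(self):
        y = np.arange(10.0)
        m = compute_metrics(y, y)
        assert m.spearman_rho == pytest.approx(1.0)
        assert m.r_squared == pytest.approx(1.0)
        assert m.mae == 0.0

    def test_constant_offset(self):
        y = np.arange(10.0)
        m = compute_metrics(y, y + 2.5)
        assert m.mae == pytest.approx(2.5)
        assert m.spearman_rho == pytest.approx(1.0)

    def test_oracle_equivalence_on_random_pairs(self):
        # rank-based rho by explicit ranking; R^2 by its definition formula
        rng = np.random.default_rng(5)
        for _ in range(100):
            y = rng.normal(size=30)
            p = rng.normal(size=30)
            m = compute_metrics(y, p)
            ry, rp = rankdata(y), rankdata(p)
            rho_oracle = np.corrcoef(ry, rp)[0, 1]
            r2_oracle = 1 - np.sum((y - p) ** 2) / np.sum((y - np.mean(y)) ** 2)
            assert m.spearman_rho == pytest.approx(rho_oracle)
            assert m.r_squared == pytest.approx(r2_oracle)
            assert m.mae == pytest.approx(np.mean(np.abs(y - p)))

    def test_too_small(self):
        with pytest.raises(ValueError):
            compute_metrics([1.0], [1.0])


class TestNetwork:
    def test_default_config_is_final_model(self):
        c = NetworkConfig()
        assert c.hidden_layer_sizes == (200, 200, 200)
        assert c.alpha == 0.001
        assert c.learning_rate_init == 0.01
        assert c.learning_rate == "constant"
        assert c.batch_size == 100
        assert c.early_stopping is True
        assert c.max_iter == 200

    def test_constant_target(self, spec):
        genotypes = sample_genotypes(spec, 300, seed=6)
        d = one_hot_encode(genotypes, np.full(300, 3.0))
        # early stopping scores R^2, which is undefined on a constant
        # validation target, so it is off for this degenerate fit; strong
        # L2 drives the weights to zero and the bias to the constant
        model = fit_network(
            d,
            NetworkConfig(
                hidden_layer_sizes=(16,),
                alpha=1.0,
                max_iter=300,
                batch_size=50,
                early_stopping=False,
            ),
            seed=0,
        )
        assert np.allclose(model.predict(d.X), 3.0, atol=1e-2)

    def test_determinism(self, spec):
        genotypes = sample_genotypes(spec, 200, seed=7)
        y = np.random.default_rng(0).normal(size=200)
        d = one_hot_encode(genotypes, y)
        cfg = NetworkConfig(hidden_layer_sizes=(8,), max_iter=20, batch_size=50)
        p1 = fit_network(d, cfg, seed=1).predict(d.X)
        p2 = fit_network(d, cfg, seed=1).predict(d.X)
        assert np.array_equal(p1, p2)


class TestGridSearch:
    def test_one_point_grid(self, spec):
        genotypes = sample_genotypes(spec, 120, seed=8)
        y = np.random.default_rng(1).normal(size=120)
        d = one_hot_encode(genotypes, y)
        cfg = NetworkConfig(hidden_layer_sizes=(4,), max_iter=10, batch_size=40)
        best, table = grid_search_cv(d, [cfg], folds=3, seed=0)
        assert best == cfg
        assert len(table) == 1

    def test_selects_adequate_capacity(self, spec):
        # additive target: a 1-unit net underfits relative to a 32-unit net
        rng = np.random.default_rng(2)
        genotypes = sample_genotypes(spec, 2000, seed=9)
        effects = {
            (j, b): rng.normal() for j in range(14) for b in "ACGT"
        }
        y = np.array([sum(effects[(j, b)] for j, b in enumerate(g)) for g in genotypes])
        d = one_hot_encode(genotypes, y)
        weak = NetworkConfig(hidden_layer_sizes=(1,), max_iter=30, batch_size=100)
        strong = NetworkConfig(hidden_layer_sizes=(32,), max_iter=30, batch_size=100)
        best, _ = grid_search_cv(d, [weak, strong], folds=3, seed=0)
        assert best == strong

    def test_empty_grid(self, spec):
        d = one_hot_encode(["A" * 14] * 12, np.zeros(12))
        with pytest.raises(ValueError):
            grid_search_cv(d, [], folds=3, seed=0)


class TestLearningCurve:
    def test_single_fraction_matches_direct_run(self, spec):
        genotypes = sample_genotypes(spec, 400, seed=10)
        y = np.random.default_rng(3).normal(size=400)
        d = one_hot_encode(genotypes, y)
        plan = SplitPlan(seed=5, fractions=(1.0,))
        cfg = NetworkConfig(hidden_layer_sizes=(8,), max_iter=15, batch_size=100)
        curve = learning_curve(d, plan, cfg)
        assert len(curve) == 1
        direct = run_regression(genotypes, y, plan, cfg)
        assert curve.iloc[0]["r_squared"] == pytest.approx(direct.metrics.r_squared)

    def test_rows_per_fraction(self, spec):
        genotypes = sample_genotypes(spec, 300, seed=11)
        y = np.random.default_rng(4).normal(size=300)
        d = one_hot_encode(genotypes, y)
        plan = SplitPlan(seed=6, fractions=(1.0, 0.5))
        cfg = NetworkConfig(hidden_layer_sizes=(4,), max_iter=10, batch_size=100)
        curve = learning_curve(d, plan, cfg)
        assert curve["fraction"].tolist() == [1.0, 0.5]
        assert curve.iloc[0]["n_train"] == 2 * curve.iloc[1]["n_train"]


class TestBaselines:
    def test_exactly_additive_target(self, spec):
        # effects only at unconstrained positions: the marginal-mean
        # estimator is consistent only when positions are independent
        rng = np.random.default_rng(7)
        genotypes = sample_genotypes(spec, 20_000, seed=12)
        free = {
            spec.position_index(p) for p in spec.unconstrained_base_sets()
        }
        effects = {(j, b): rng.normal() for j in free for b in "ACGT"}
        y = np.array(
            [
                sum(effects[(j, b)] for j, b in enumerate(g) if j in free)
                for g in genotypes
            ]
        )
        d = one_hot_encode(genotypes, y)
        base = baseline_positional(d)
        pred = base.predict(genotypes)
        m = compute_metrics(y, pred)
        assert m.r_squared > 0.995

    @pytest.mark.filterwarnings("ignore::scipy.stats.ConstantInputWarning")
    def test_xor_interaction_defeats_single_position(self):
        # balanced two-position XOR-like target: main effects are all zero
        genotypes = ["".join(p) for p in itertools.product("AC", "AC")] * 50
        y = np.array([1.0 if g[0] == g[1] else -1.0 for g in genotypes])
        d = one_hot_encode(genotypes, y)
        base = PositionalBaseline().fit(genotypes, y)
        m = compute_metrics(y, base.predict(genotypes))
        assert abs(m.r_squared) < 0.01

    def test_base_pair_mode_captures_pair_identity(self, spec):
        # target depends only on the 16-42 duplet
        genotypes = sample_genotypes(spec, 2000, seed=13)
        i5 = spec.position_index(16)
        i3 = spec.position_index(42)
        values = {d: float(i) for i, d in enumerate(sorted({g[i5] + g[i3] for g in genotypes}))}
        y = np.array([values[g[i5] + g[i3]] for g in genotypes])
        d = one_hot_encode(genotypes, y)
        pair = baseline_positional(d, mode="base-pair", spec=spec)
        m = compute_metrics(y, pair.predict(genotypes))
        assert m.r_squared > 0.95

    def test_unfitted_predict_raises(self):
        with pytest.raises(RuntimeError):
            PositionalBaseline().predict(["ACGT"])


class TestLeakageAudit:
    def test_cv_never_touches_test_rows(self, spec):
        from sklearn.model_selection import KFold

        n = 200
        plan = SplitPlan(seed=8)
        split = make_split(n, plan)
        kf = KFold(n_splits=plan.cv_folds, shuffle=True, random_state=plan.seed)
        train_rows = split.subsets[1.0]
        for tr, va in kf.split(train_rows):
            assert not (set(train_rows[tr]) & set(split.test))
            assert not (set(train_rows[va]) & set(split.test))


def test_weight_replication(spec):
    genotypes = sample_genotypes(spec, 50, seed=14)
    y = np.zeros(50)
    d = one_hot_encode(genotypes, y, weights=np.ones(50))
    cfg = NetworkConfig(hidden_layer_sizes=(4,), max_iter=5, batch_size=20)
    model = fit_network(d, cfg, seed=0, weight_mode="replicate")
    assert model is not None
    with pytest.raises(ValueError):
        fit_network(d, cfg, seed=0, weight_mode="bogus")
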