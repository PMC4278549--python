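import numpy as np
import pandas as pd
import pytest

from mcdmri.fitting import FitResult, warm_start_chain
from mcdmri.model_space import get_model
from mcdmri.selection import (
    bic,
    bootstrap_rankings,
    cross_validate,
    make_cv_folds,
    rank_models,
    resample_within_shells,
)


def _fake_fit(name, lse, K, N=1536):
    return FitResult(model_name=name, params={}, lse=lse, K=K, N=N,
                     n_restarts_used=1, converged_fraction=1.0, seed=0)


class TestBIC:
    def test_hand_evaluated_example(self):
        # LSE/sigma^2 + K ln N at LSE=0.5, sigma=0.05, K=5, N=1356
        assert bic(0.5, 0.05, 5, 1356) == pytest.approx(236.06, abs=0.01)

    def test_penalty_monotone_in_k(self):
        assert bic(1.0, 0.05, 3, 1536) < bic(1.0, 0.05, 4, 1536)

    def test_delta_bic_invariant_to_additive_constant(self):
        d0 = bic(1.0, 0.05, 3, 1536) - bic(0.8, 0.05, 7, 1536)
        shift = 0.25  # add the same chi-squared offset to both
        d1 = (bic(1.0 + shift, 0.05, 3, 1536) - bic(0.8 + shift, 0.05, 7, 1536))
        assert d0 == pytest.approx(d1, abs=1e-9)

    def test_requires_more_data_than_parameters(self):
        with pytest.raises(ValueError):
            bic(1.0, 0.05, 10, 10)


class TestRanking:
    def test_single_model(self):
        r = rank_models([_fake_fit("Ball", 1.0, 2)], 0.05)
        assert r.order == ["Ball"]

    def test_sorting_and_tie_breaks(self):
        fits = [
            _fake_fit("B_complex", 1.0, 8),
            _fake_fit("A_simple", 1.0, 5),
            _fake_fit("Best", 0.1, 5),
        ]
        r = rank_models(fits, 0.05)
        assert r.order[0] == "Best"
        # equal LSE: smaller K wins through the smaller penalty
        assert r.order[1] == "A_simple"

    def test_order_invariance(self):
        fits = [_fake_fit(n, l, k) for n, l, k in
                [("a", 0.5, 3), ("b", 0.4, 6), ("c", 0.45, 4)]]
        r1 = rank_models(fits, 0.05)
        r2 = rank_models(fits[::-1], 0.05)
        assert r1.order == r2.order

    def test_inconsistent_n_rejected(self):
        with pytest.raises(ValueError):
            rank_models([_fake_fit("a", 1, 2, N=100), _fake_fit("b", 1, 2, N=200)], 0.05)


class TestBootstrap:
    def test_resampling_preserves_b0_and_shell_counts(self, scheme):
        rng = np.random.default_rng(0)
        idx = resample_within_shells(scheme, rng)
        assert len(idx) == len(scheme)
        b0_rows = np.flatnonzero(scheme.is_b0)
        np.testing.assert_array_equal(idx[b0_rows], b0_rows)
        for s in (0, 31):
            rows = np.flatnonzero((scheme.shell_id == s) & scheme.weighted)
            assert set(idx[rows]) <= set(rows)

    def test_b1_is_permutation_matrix(self, scheme, cc_voxel):
        models = [get_model(n) for n in ("Ball", "BallStick", "ZeppelinStick")]
        pv = bootstrap_rankings(cc_voxel, scheme, models, B=1, n_restarts=1, seed=0)
        m = pv.counts.to_numpy()
        assert pv.B == 1
        assert np.all(m.sum(axis=0) == 1) and np.all(m.sum(axis=1) == 1)

    def test_row_and_column_sums_equal_b(self, scheme, cc_voxel):
        models = [get_model(n) for n in ("Ball", "BallStick", "ZeppelinStick")]
        pv = bootstrap_rankings(cc_voxel, scheme, models, B=4, n_restarts=1, seed=2)
        m = pv.counts.to_numpy()
        assert np.all(m.sum(axis=0) == pv.B) and np.all(m.sum(axis=1) == pv.B)


class TestCVFolds:
    def test_partition_and_per_delta_constraint(self, scheme):
        table = scheme.shell_table()
        Deltas = sorted({v[2] for v in table.values()})
        low = set(Deltas[:2])
        for seed in range(100):
            folds = make_cv_folds(scheme, seed=seed)
            shells = [s for f in folds for s in f.shells]
            assert sorted(shells) == list(range(32))
            for f in folds:
                assert len(f.shells) == 8
                for d in sorted({v[1] for v in table.values()}):
                    sub = [s for s in f.shells if table[s][1] == d]
                    assert len(sub) == 2
                    assert sum(table[s][2] in low for s in sub) == 1

    def test_determinism(self, scheme):
        assert make_cv_folds(scheme, seed=5) == make_cv_folds(scheme, seed=5)
        assert make_cv_folds(scheme, seed=5) != make_cv_folds(scheme, seed=6)


class TestCrossValidate:
    def test_selfconsistency_on_rician_mean_data(self, scheme):
        # data generated by the fitted model itself (at its offset-Gaussian
        # fixed point): held-out LSE is at numerical zero for every fold
        m = get_model("BallStick")
        truth = {"S0": 1.0, "f_ic": 0.4, "theta": np.pi / 2, "phi": 0.2,
                 "d_par": 1.8e-9, "d_iso": 0.9e-9}
        y = np.sqrt(m.predict(truth, scheme) ** 2 + 0.05**2)
        folds = make_cv_folds(scheme, seed=0)
        cv = cross_validate([m], y, scheme, folds, n_restarts=3, seed=0)
        assert len(cv) == 4
        assert (cv["lse"] < 1e-8).all()

    def test_no_test_row_used_in_training(self, scheme, cc_voxel, monkeypatch):
        # row-index bookkeeping: the train and held-out shells are disjoint
        import mcdmri.selection as sel

        seen = {}
        orig = sel.warm_start_chain

        def spy(models, measured, train_scheme, **kw):
            seen["train_shells"] = set(np.unique(train_scheme.shell_id))
            return orig(models, measured, train_scheme, **kw)

        monkeypatch.setattr(sel, "warm_start_chain", spy)
        folds = make_cv_folds(scheme, seed=1)
        sel.cross_validate([get_model("Ball")], cc_voxel, scheme, folds[:1]
                           + folds[1:], n_restarts=1, seed=0)
        assert seen["train_shells"].isdisjoint(set(folds[-1].shells))

    def test_fold_label_shuffle_leaves_score_multiset(self, scheme):
        m = get_model("Ball")
        y = np.sqrt(m.predict({"S0": 1.0, "d_iso": 1e-9}, scheme) ** 2 + 0.05**2)
        folds = make_cv_folds(scheme, seed=2)
        a = cross_validate([m], y, scheme, folds, n_restarts=1, seed=0)
        b = cross_validate([m], y, scheme, folds[::-1], n_restarts=1, seed=0)
        assert sorted(np.round(a["lse"], 12)) == sorted(np.round(b["lse"], 12))
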