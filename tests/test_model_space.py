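import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mcdmri import compartments as cp
from mcdmri.model_space import (
    CompositeModel,
    enumerate_taxonomy,
    get_model,
    parent_model,
    taxonomy_group,
    transform_params,
    untransform_params,
    bound_flags,
)

MODELS = enumerate_taxonomy()


class TestEnumeration:
    def test_counts(self):
        assert len(MODELS) == 49
        assert sum(m.n_compartments == 3 for m in MODELS) == 36
        assert sum(m.n_compartments == 2 for m in MODELS) == 9

    def test_expected_names_present(self):
        names = {m.name for m in MODELS}
        assert {"ZeppelinCylinderDot", "TensorGDRcylindersSphere", "Bizeppelin",
                "Tensor", "Zeppelin", "Ball", "BallStick"} <= names

    def test_k_bounds(self):
        kmax = get_model("TensorGDRcylindersSphere").K
        for m in MODELS:
            assert 1 <= m.K <= kmax

    def test_removing_a_compartment_strictly_decreases_k(self):
        for m in MODELS:
            if m.iso is not None:
                reduced = get_model((m.extra or "") + (m.intra or ""))
                assert reduced.K < m.K
            if m.intra is not None and m.n_compartments == 2:
                assert get_model(m.extra).K < m.K

    def test_groups(self):
        assert taxonomy_group("ZeppelinCylinderDot") == "i"
        assert taxonomy_group("TensorStickSphere") == "i"
        assert taxonomy_group("ZeppelinStickAstrosticks") == "ii"
        assert taxonomy_group("BallStickDot") == "iii"
        assert taxonomy_group("BallStick") == "iii"
        assert taxonomy_group("Tensor") == "dt"

    def test_parent_chain_terminates_at_ball(self):
        for m in MODELS:
            seen, cur = set(), m
            while cur is not None:
                assert cur.name not in seen  # no cycles
                seen.add(cur.name)
                nxt = parent_model(cur)
                if nxt is not None:
                    assert nxt.K < cur.K
                cur = nxt
            assert "Ball" in seen


class TestPredict:
    def test_pure_stick_mixture(self, scheme):
        m = get_model("BallStick")
        p = {"S0": 1.1, "f_ic": 1.0, "theta": 0.3, "phi": 0.2,
             "d_par": 2e-9, "d_iso": 1e-9}
        n = cp.orientation_vector(0.3, 0.2)
        np.testing.assert_allclose(
            m.predict(p, scheme), 1.1 * cp.stick_signal(scheme, n, 2e-9), atol=1e-14
        )

    def test_ballstick_perpendicular_identity(self, scheme):
        # with g perpendicular to n the stick does not attenuate:
        # S = S0 [f_ic + f_ec exp(-b d)]
        m = get_model("BallStick")
        d = 1.3e-9
        p = {"S0": 1.0, "f_ic": 0.4, "theta": 0.0, "phi": 0.0, "d_par": d, "d_iso": d}
        pred = m.predict(p, scheme)
        perp = np.abs(scheme.directions @ np.array([0, 0, 1.0])) < 1e-12
        expected = 0.4 + 0.6 * np.exp(-scheme.b[perp] * d)
        np.testing.assert_allclose(pred[perp], expected, atol=1e-12)

    def test_b0_rows_return_s0(self, scheme):
        for name in ("Ball", "Bizeppelin", "ZeppelinCylinderDot",
                     "TensorGDRcylindersSphere"):
            m = get_model(name)
            p = m.default_params()
            p["S0"] = 1.23
            np.testing.assert_allclose(m.predict(p, scheme)[scheme.is_b0], 1.23,
                                       atol=1e-12)

    def test_fraction_simplex_violation_raises(self, scheme):
        m = get_model("ZeppelinStickDot")
        p = m.default_params()
        p["f_ic"], p["f_iso"] = 0.8, 0.5
        with pytest.raises(ValueError):
            m.predict(p, scheme)

    def test_nesting_identities_at_protocol_rows(self, scheme):
        zs = get_model("ZeppelinStick")
        zc = get_model("ZeppelinCylinder")
        p = zc.default_params()
        p["R"] = 1.001e-7  # near-zero radius: Cylinder -> Stick
        ps = {k: v for k, v in p.items() if k in zs.symbols}
        assert np.abs(zc.predict(p, scheme) - zs.predict(ps, scheme)).max() < 1e-6

        zsd = get_model("ZeppelinStickDot")
        zss = get_model("ZeppelinStickSphere")
        p3 = zss.default_params()
        p3["R_iso"] = 1.001e-7  # Sphere -> Dot
        pd = {k: v for k, v in p3.items() if k in zsd.symbols}
        assert np.abs(zss.predict(p3, scheme) - zsd.predict(pd, scheme)).max() < 1e-6


class TestTransforms:
    @settings(max_examples=30, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_roundtrip_random_parameters(self, seed):
        rng = np.random.default_rng(seed)
        m = MODELS[int(rng.integers(len(MODELS)))]
        u = rng.normal(0, 2, size=m.K)
        p = untransform_params(m, u)
        u2 = transform_params(m, p)
        p2 = untransform_params(m, u2)
        for s in p:
            assert p2[s] == pytest.approx(p[s], rel=1e-8, abs=1e-20)

    def test_fraction_roundtrip(self):
        m = get_model("ZeppelinStickDot")
        p = m.default_params()
        p["f_ic"], p["f_iso"] = 0.5, 0.25
        out = untransform_params(m, transform_params(m, p))
        assert out["f_ic"] == pytest.approx(0.5, abs=1e-10)
        assert out["f_iso"] == pytest.approx(0.25, abs=1e-10)

    def test_kappa_on_bound_is_nudged_and_flagged(self):
        m = get_model("ZeppelinGDRcylinders")
        p = m.default_params()
        p["kappa"] = 10.0
        out = untransform_params(m, transform_params(m, p))
        assert out["kappa"] < 10.0
        assert out["kappa"] == pytest.approx(10.0, rel=1e-4)
        assert bound_flags(m, out).get("kappa") == "upper"

    def test_predict_continuous_in_parameters(self, scheme):
        # small parameter perturbations produce small signal changes
        m = get_model("ZeppelinCylinderDot")
        u = transform_params(m, m.default_params())
        base = m.predict(untransform_params(m, u), scheme)
        for i in range(m.K):
            du = np.zeros(m.K)
            du[i] = 1e-6
            pert = m.predict(untransform_params(m, u + du), scheme)
            assert np.abs(pert - base).max() < 1e-4
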