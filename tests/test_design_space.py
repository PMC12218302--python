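import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mediabo.design_space import (
    DesignFactor,
    DesignPoint,
    DesignSpace,
    LinearEqualityConstraint,
    load_space,
    save_space,
    space_from_dict,
    space_to_dict,
)


class TestFactorInvariants:
    def test_continuous_needs_ordered_bounds(self):
        with pytest.raises(ValueError):
            DesignFactor(name="x", kind="continuous", lower=1.0, upper=1.0)

    def test_categorical_needs_two_distinct_labels(self):
        with pytest.raises(ValueError):
            DesignFactor(name="x", kind="categorical", categories=("a",))
        with pytest.raises(ValueError):
            DesignFactor(name="x", kind="categorical", categories=("a", "a"))

    def test_discrete_needs_increasing_levels(self):
        with pytest.raises(ValueError):
            DesignFactor(name="pH", kind="discrete", levels=(6.5, 6.0))
        f = DesignFactor(name="pH", kind="discrete", levels=(5.75, 6.0, 6.5))
        assert f.lower == 5.75 and f.upper == 6.5

    def test_linked_to_must_name_categorical(self, yeast_space):
        assert yeast_space.factor("CoFeedConc").linked_to == "CoFeedType"
        with pytest.raises(ValueError):
            DesignSpace([
                DesignFactor(name="a", kind="continuous", lower=0, upper=1),
                DesignFactor(name="b", kind="continuous", lower=0, upper=1, linked_to="a"),
            ])


class TestValidation:
    def test_symmetric_blend_is_feasible(self, blend_space):
        p = DesignPoint({m: 0.25 for m in ("DMEM", "AR5", "XVIVO", "RPMI")})
        assert blend_space.validate_point(p).valid

    def test_constraint_violation_reported(self, blend_space):
        p = DesignPoint({m: 0.5 for m in ("DMEM", "AR5", "XVIVO", "RPMI")})
        res = blend_space.validate_point(p)
        assert not res.valid
        assert any("constraint" in v for v in res.violations)

    def test_benchmark2_condition_valid(self, yeast_space):
        p = DesignPoint({"Glycerol": 4.0, "Methanol": 1.5,
                         "CoFeedType": "Sorbitol", "CoFeedConc": 40.0})
        assert yeast_space.validate_point(p).valid

    def test_unknown_factor_raises(self, yeast_space):
        with pytest.raises(KeyError, match="Sucrose%"):
            yeast_space.validate_point(DesignPoint({"Sucrose%": 1.0}))

    def test_out_of_bounds_named(self, yeast_space):
        p = DesignPoint({"Glycerol": 11.0, "Methanol": 1.5,
                         "CoFeedType": "Sorbitol", "CoFeedConc": 40.0})
        res = yeast_space.validate_point(p)
        assert not res.valid and "Glycerol" in res.violations[0]


class TestEncoding:
    def test_midpoint_and_endpoints_scale(self, yeast_space):
        for glyc, expect in [(5.0, 0.5), (0.0, 0.0), (10.0, 1.0)]:
            p = DesignPoint({"Glycerol": glyc, "Methanol": 0.0,
                             "CoFeedType": "Ethanol", "CoFeedConc": 0.0})
            x, h = yeast_space.encode_point(p)
            assert x[0] == pytest.approx(expect)

    def test_first_category_is_index_zero(self, yeast_space):
        p = DesignPoint({"Glycerol": 0.0, "Methanol": 0.0,
                         "CoFeedType": "Ethanol", "CoFeedConc": 0.0})
        _, h = yeast_space.encode_point(p)
        assert h[0] == 0

    def test_encode_rejects_invalid(self, yeast_space):
        with pytest.raises(ValueError):
            yeast_space.encode_point(DesignPoint(
                {"Glycerol": -1.0, "Methanol": 0.0, "CoFeedType": "Ethanol", "CoFeedConc": 0.0}
            ))

    @given(st.floats(0.0, 10.0), st.floats(0.0, 10.0),
           st.sampled_from(["Ethanol", "Sorbitol", "Rhamnose"]), st.floats(0.0, 50.0))
    @settings(max_examples=50, deadline=None)
    def test_encode_decode_identity(self, glyc, meth, cofeed, conc):
        space = DesignSpace([
            DesignFactor(name="Glycerol", kind="continuous", lower=0.0, upper=10.0),
            DesignFactor(name="Methanol", kind="continuous", lower=0.0, upper=10.0),
            DesignFactor(name="CoFeedType", kind="categorical",
                         categories=("Ethanol", "Sorbitol", "Rhamnose")),
            DesignFactor(name="CoFeedConc", kind="continuous", lower=0.0, upper=50.0),
        ])
        p = DesignPoint({"Glycerol": glyc, "Methanol": meth,
                         "CoFeedType": cofeed, "CoFeedConc": conc})
        q = space.decode_point(*space.encode_point(p))
        assert q["CoFeedType"] == cofeed
        for name in ("Glycerol", "Methanol", "CoFeedConc"):
            assert abs(float(q[name]) - float(p[name])) <= 1e-12 * max(1.0, abs(float(p[name])))

    def test_discrete_decodes_to_nearest_level(self):
        space = DesignSpace([DesignFactor(name="pH", kind="discrete", levels=(5.75, 6.0, 6.5))])
        p = space.decode_point(np.array([0.4]), np.zeros(0, dtype=int))
        assert p["pH"] in (5.75, 6.0, 6.5)


class TestFeasibleSampling:
    def test_simplex_points_satisfy_constraint(self, blend_space):
        pts = blend_space.sample_uniform_feasible(10, seed=0)
        assert len(pts) == 10
        for p in pts:
            assert blend_space.validate_point(p).valid
            assert abs(sum(float(p[m]) for m in ("DMEM", "AR5", "XVIVO", "RPMI")) - 1.0) < 1e-9

    def test_same_seed_reproduces(self, blend_space):
        a = blend_space.sample_uniform_feasible(5, seed=7)
        b = blend_space.sample_uniform_feasible(5, seed=7)
        assert [p.values for p in a] == [p.values for p in b]

    def test_simplex_marginals_match_dirichlet(self, blend_space):
        # symmetric Dirichlet(1,1,1,1) has per-coordinate mean 1/4
        pts = blend_space.sample_uniform_feasible(10_000, seed=3)
        arr = np.array([[float(p[m]) for m in ("DMEM", "AR5", "XVIVO", "RPMI")] for p in pts])
        assert np.allclose(arr.mean(axis=0), 0.25, atol=0.01)

    def test_infeasible_system_raises(self):
        space = DesignSpace(
            [DesignFactor(name="a", kind="continuous", lower=0.0, upper=0.1),
             DesignFactor(name="b", kind="continuous", lower=0.0, upper=0.1)],
            [LinearEqualityConstraint({"a": 1.0, "b": 1.0}, rhs=5.0)],
        )
        with pytest.raises(RuntimeError):
            space.sample_uniform_feasible(1, seed=0, )


class TestConfigRoundTrip:
    @pytest.mark.parametrize("suffix", [".json", ".yaml"])
    def test_save_load_identity(self, yeast_space, tmp_path, suffix):
        path = tmp_path / f"space{suffix}"
        save_space(yeast_space, path)
        assert load_space(path) == yeast_space

    def test_dict_round_trip_preserves_constraints(self, blend_space):
        assert space_from_dict(space_to_dict(blend_space)) == blend_space
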