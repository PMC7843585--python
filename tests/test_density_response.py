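"""Density-response model: evaluation, application, fitting, serialization."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import maizecanopy as mc
from maizecanopy import (
    DensityLevel,
    EarParams,
    GroupParams,
    OrganDim,
    OrganResponse,
    RankDomainError,
    RegressorDomainError,
    ResponseParams,
    SingularDesignError,
)

X_GRID = (1.5, 3.0, 4.5, 10.5)  # density increments of the elevated trial levels


def make_params(A=1.0, B=0.0, C=0.0, D=0.0, E=0.0):
    """Uniform parameterization: every organ/group shares the same coefficients."""
    organs = {
        o: OrganResponse(
            lower=GroupParams(A, B, C), ear=EarParams(D, E), upper=GroupParams(A, B, C)
        )
        for o in OrganDim
    }
    return ResponseParams(organs=organs)


class TestRelativeChange:
    @pytest.mark.parametrize(
        "organ, rank, density, expected",
        [
            # ear phytomer, linear in the increment: 0.11*10.5 + 1.70
            (OrganDim.LL, 12, 15.0, 2.855),
            # lower group, log+linear: 2.99*ln(1.5) + 0.12*8 + 0.32
            (OrganDim.LL, 8, 6.0, 2.99 * math.log(1.5) + 0.12 * 8 + 0.32),
            # upper group: -9.66*ln(3) + 0.07*14 - 8.52
            (OrganDim.ID, 14, 7.5, -9.66 * math.log(3.0) + 0.07 * 14 - 8.52),
        ],
    )
    def test_published_coefficients_evaluate(self, params, organ, rank, density, expected):
        y = mc.relative_change(organ, rank, DensityLevel(density), params)
        assert y == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("organ", list(OrganDim))
    @pytest.mark.parametrize("rank", [6, 12, 18])
    def test_reference_density_is_zero_change(self, params, organ, rank):
        assert mc.relative_change(organ, rank, DensityLevel(4.5), params) == 0.0

    @pytest.mark.parametrize("rank", [1, 5, 19, 25])
    def test_rank_outside_model_domain(self, params, rank):
        with pytest.raises(RankDomainError):
            mc.relative_change(OrganDim.LL, rank, DensityLevel(6.0), params)

    def test_density_below_reference_rejected(self):
        with pytest.raises(ValueError):
            DensityLevel(3.0)

    def test_absolute_mode_uses_plant_density(self):
        p = make_params(A=2.0, B=0.0, C=0.0)
        p_abs = ResponseParams(organs=p.organs, regressor_mode="absolute")
        y = mc.relative_change(OrganDim.LL, 8, DensityLevel(6.0), p_abs)
        assert y == pytest.approx(2.0 * math.log(6.0))

    def test_extrapolation_above_calibration_warns(self, params, caplog):
        with caplog.at_level("WARNING", logger="maizecanopy"):
            mc.relative_change(OrganDim.LL, 8, DensityLevel(20.0), params)
        assert any("extrapolating" in r.message for r in caplog.records)

    @given(
        x=st.floats(min_value=0.01, max_value=10.4),
        dx=st.floats(min_value=1e-6, max_value=0.1),
        rank=st.sampled_from([6, 9, 11, 13, 18]),
    )
    @settings(max_examples=60, deadline=None)
    def test_monotone_in_density_with_signed_log_coefficient(self, x, dx, rank):
        """A > 0 makes Y nondecreasing in density; A < 0 nonincreasing."""
        for a, cmp in ((3.0, float.__le__), (-3.0, float.__ge__)):
            p = make_params(A=a, B=0.5, C=1.0)
            y1 = mc.relative_change(OrganDim.SL, rank, DensityLevel(4.5 + x), p)
            y2 = mc.relative_change(OrganDim.SL, rank, DensityLevel(4.5 + x + dx), p)
            assert cmp(y1, y2)


class TestDefaultParams:
    def test_published_table_spot_values(self, params):
        assert params.lower(OrganDim.SW) == GroupParams(-8.99, -0.24, 4.92)
        assert params.ear(OrganDim.ID) == EarParams(-1.63, -9.53)
        assert params.upper(OrganDim.IL) == GroupParams(2.91, -2.06, 32.08)
        assert params.ear(OrganDim.LL) == EarParams(0.11, 1.70)
        assert params.ear_rank == 12

    def test_complete_and_validated(self, params):
        assert set(params.organs) == set(OrganDim)
        with pytest.raises(ValueError):
            ResponseParams(organs={OrganDim.LL: params.organs[OrganDim.LL]})


class TestApplyResponse:
    def test_multiplicative_application(self, base_profile, params):
        level = DensityLevel(6.0)
        pred = mc.apply_response(base_profile, level, params)
        y = mc.relative_change(OrganDim.LL, 8, level, params)
        expected = base_profile.entries[(8, OrganDim.LL)] * (1 + y / 100.0)
        assert pred.entries[(8, OrganDim.LL)] == pytest.approx(expected)
        assert pred.density == 6.0

    def test_reference_density_is_identity(self, base_profile, params):
        pred = mc.apply_response(base_profile, DensityLevel(4.5), params)
        assert pred.entries == dict(base_profile.entries)

    def test_sizes_floor_at_zero(self, base_profile):
        # a -150 % "change" must clamp to zero, never go negative
        p = make_params(A=0.0, B=0.0, C=-150.0, D=0.0, E=-150.0)
        pred = mc.apply_response(base_profile, DensityLevel(9.0), p)
        assert all(v == 0.0 for v in pred.entries.values())

    def test_incomplete_profile_lists_missing_entries(self, base_profile, params):
        entries = dict(base_profile.entries)
        del entries[(7, OrganDim.SL)]
        partial = base_profile.with_entries(entries)
        with pytest.raises(mc.MissingEntryError) as err:
            mc.apply_response(partial, DensityLevel(6.0), params)
        assert (7, OrganDim.SL) in err.value.missing


class TestFitGroup:
    @pytest.mark.parametrize("organ", list(OrganDim))
    @pytest.mark.parametrize("group", ["lower", "upper"])
    def test_grouped_roundtrip_recovers_published_coefficients(self, params, organ, group):
        g = getattr(params, group)(organ)
        ranks = ResponseParams.LOWER_RANKS if group == "lower" else ResponseParams.UPPER_RANKS
        obs = [
            (x, r, g.A * math.log(x) + g.B * r + g.C) for x in X_GRID for r in ranks
        ]
        fit = mc.fit_group(obs, "grouped")
        assert fit.params.A == pytest.approx(g.A, rel=1e-8, abs=1e-8)
        assert fit.params.B == pytest.approx(g.B, rel=1e-8, abs=1e-8)
        assert fit.params.C == pytest.approx(g.C, rel=1e-8, abs=1e-8)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.n_points == len(obs)

    @pytest.mark.parametrize("organ", list(OrganDim))
    def test_ear_roundtrip_recovers_published_coefficients(self, params, organ):
        e = params.ear(organ)
        obs = [(x, 12, e.D * x + e.E) for x in X_GRID]
        fit = mc.fit_group(obs, "ear")
        assert fit.params.D == pytest.approx(e.D, rel=1e-8, abs=1e-8)
        assert fit.params.E == pytest.approx(e.E, rel=1e-8, abs=1e-8)

    def test_constant_response_gives_zero_slope(self):
        fit = mc.fit_group([(x, 12, 5.5) for x in X_GRID], "ear")
        assert fit.params.D == pytest.approx(0.0, abs=1e-12)
        assert fit.params.E == pytest.approx(5.5)
        assert fit.r_squared == 1.0  # SST = 0 with vanishing residuals

    @pytest.mark.parametrize(
        "obs, model",
        [
            ([(1.5, 6, 1.0), (1.5, 7, 2.0), (1.5, 8, 3.0)], "grouped"),  # one x
            ([(1.5, 6, 1.0), (3.0, 6, 2.0), (4.5, 6, 3.0)], "grouped"),  # one rank
            ([(1.5, 6, 1.0), (3.0, 7, 2.0)], "grouped"),  # too few points
            ([(1.5, 12, 1.0)], "ear"),  # single x
        ],
    )
    def test_degenerate_designs_rejected(self, obs, model):
        with pytest.raises(SingularDesignError):
            mc.fit_group(obs, model)

    def test_nonpositive_regressor_rejected_for_log_model(self):
        with pytest.raises(RegressorDomainError):
            mc.fit_group([(-1.0, 6, 1.0), (2.0, 7, 2.0), (3.0, 8, 3.0)], "grouped")

    @given(
        a=st.floats(-20, 20),
        b=st.floats(-5, 5),
        c=st.floats(-50, 50),
    )
    @settings(max_examples=50, deadline=None)
    def test_roundtrip_recovery_for_arbitrary_coefficients(self, a, b, c):
        obs = [
            (x, r, a * math.log(x) + b * r + c)
            for x in X_GRID
            for r in range(6, 12)
        ]
        fit = mc.fit_group(obs, "grouped")
        assert fit.params.A == pytest.approx(a, rel=1e-6, abs=1e-6)
        assert fit.params.B == pytest.approx(b, rel=1e-6, abs=1e-6)
        assert fit.params.C == pytest.approx(c, rel=1e-6, abs=1e-6)

    def test_r_squared_degrades_with_noise(self):
        """R² < 1 on noisy data and decreases as noise grows (fixed seeds)."""
        rng = np.random.default_rng(42)
        truth = [(x, r, 3.0 * math.log(x) - 1.0 * r + 5.0) for x in X_GRID for r in range(6, 12)]
        r2 = []
        for sd in (0.5, 2.0, 8.0):
            noisy = [(x, r, y + rng.normal(0, sd)) for x, r, y in truth]
            r2.append(mc.fit_group(noisy, "grouped").r_squared)
        assert all(v < 1.0 for v in r2)
        assert r2[0] > r2[1] > r2[2]


class TestPercentChanges:
    def test_noisefree_table_reproduces_model_changes(
        self, noisefree_observations, params
    ):
        changes = mc.percent_changes(noisefree_observations)
        sub = changes[(changes["organ"] == "LL") & (changes["rank"] == 8)]
        for _, rec in sub.iterrows():
            expected = mc.relative_change(
                OrganDim.LL, 8, DensityLevel(rec["density"]), params
            )
            assert rec["y"] == pytest.approx(expected, abs=1e-9)
            assert rec["x"] == pytest.approx(rec["density"] - 4.5)

    def test_missing_reference_density_rejected(self, noisefree_observations):
        elevated = noisefree_observations[noisefree_observations["density"] > 5]
        with pytest.raises(ValueError):
            mc.percent_changes(elevated)


class TestSerialization:
    def test_default_roundtrip_is_bit_exact(self, params):
        text = mc.params_to_text(params)
        back = mc.params_from_text(text)
        assert back == params

    def test_awkward_floats_roundtrip_bit_exact(self):
        p = make_params(A=1 / 3, B=-2.0000000001, C=1e-17, D=math.pi, E=-0.1)
        assert mc.params_from_text(mc.params_to_text(p)) == p

    def test_unknown_key_is_fatal(self, params):
        text = mc.params_to_text(params) + "LL.lower.Z = 1.0\n"
        with pytest.raises(ValueError, match="unknown"):
            mc.params_from_text(text)

    def test_missing_key_is_fatal(self, params):
        text = "\n".join(mc.params_to_text(params).splitlines()[:-1])
        with pytest.raises(ValueError, match="missing"):
            mc.params_from_text(text)
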