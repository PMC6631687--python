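"""Microsomal depletion fitting, binding correction and CL_int scaling."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ivivekit import (
    AssayContext,
    DepletionTimecourse,
    FitFailureError,
    InvalidInputError,
    NoiseConfig,
    PROFILES,
    ScalingFactors,
    fit_monoexponential,
    generate_depletion,
    microsomal_unbound_fraction,
    scale_intrinsic_clearance,
    summarize_replicates,
)

from conftest import REFERENCE

LN2 = np.log(2.0)
TIMES = np.array([0.0, 2.0, 5.0, 10.0, 15.0, 20.0])


def _course(t_half, c0=100.0, times=TIMES):
    remaining = c0 * np.exp(-LN2 * times / t_half)
    remaining = remaining * (100.0 / remaining[0])
    return DepletionTimecourse("X", times, remaining)


class TestFitMonoexponential:
    def test_exact_recovery(self):
        fit = fit_monoexponential(_course(35.1))
        assert fit.t_half == pytest.approx(35.1, rel=1e-6)
        assert fit.c0 == pytest.approx(100.0, rel=1e-6)
        assert fit.residual_sse < 1e-12
        assert fit.n_points == 6

    def test_no_decay_is_a_fit_failure(self):
        tc = DepletionTimecourse("X", TIMES, np.full(6, 100.0))
        with pytest.raises(FitFailureError):
            fit_monoexponential(tc)

    def test_too_few_points_rejected(self):
        tc = DepletionTimecourse("X", np.array([0.0, 5.0]),
                                 np.array([100.0, 50.0]))
        with pytest.raises(InvalidInputError):
            fit_monoexponential(tc)

    def test_matches_grid_search_oracle_on_noisy_data(self):
        """On noisy data the nonlinear fit must reach (at least) the optimum
        found by exhaustive 1-D search over t1/2 with C0 profiled out."""
        profile = dataclasses.replace(PROFILES["CBX"], t_half_vitro_true=20.0)
        tc = generate_depletion(profile, NoiseConfig(seed=7), 1)[0]

        grid = np.arange(1.0, 200.0 + 1e-9, 0.01)
        # for fixed t_half the optimal C0 is linear least squares:
        # C0* = sum(y*e) / sum(e^2) with e = exp(-ln2 t / t_half)
        e = np.exp(-LN2 * np.outer(1.0 / grid, tc.times))
        c0_star = (e @ tc.remaining) / np.sum(e**2, axis=1)
        sse = np.sum((c0_star[:, None] * e - tc.remaining) ** 2, axis=1)
        k = int(np.argmin(sse))

        fit = fit_monoexponential(tc)
        assert fit.residual_sse <= sse[k] * (1 + 1e-6)
        assert fit.t_half == pytest.approx(grid[k], abs=0.01)

    def test_timecourse_invariants_enforced(self):
        with pytest.raises(InvalidInputError):
            DepletionTimecourse("X", np.array([1.0, 2.0, 3.0]),
                                np.array([100.0, 80.0, 60.0]))  # t0 != 0
        with pytest.raises(InvalidInputError):
            DepletionTimecourse("X", np.array([0.0, 5.0, 2.0]),
                                np.array([100.0, 80.0, 60.0]))  # not ascending
        with pytest.raises(InvalidInputError):
            DepletionTimecourse("X", TIMES[:3],
                                np.array([90.0, 80.0, 60.0]))  # t0 not 100


class TestMicrosomalUnboundFraction:
    @pytest.mark.parametrize(
        "log_p,expected",
        [(2.19, 0.90), (2.82, 0.82), (2.93, 0.80)],
    )
    def test_reference_compounds(self, log_p, expected):
        assert round(microsomal_unbound_fraction(log_p, 0.5), 2) == expected

    def test_no_protein_means_fully_unbound(self):
        assert microsomal_unbound_fraction(4.2, 0.0) == 1.0

    def test_negative_protein_rejected(self):
        with pytest.raises(InvalidInputError):
            microsomal_unbound_fraction(2.0, -0.1)

    @given(st.floats(0.01, 10.0), st.floats(0.01, 10.0),
           st.floats(-2.0, 6.0))
    @settings(max_examples=100, deadline=None)
    def test_decreasing_in_protein_concentration(self, p1, dp, log_p):
        f1 = microsomal_unbound_fraction(log_p, p1)
        f2 = microsomal_unbound_fraction(log_p, p1 + dp)
        assert f2 < f1 <= 1.0

    @given(st.floats(0.0, 6.0), st.floats(0.01, 3.0))
    @settings(max_examples=100, deadline=None)
    def test_decreasing_in_lipophilicity(self, log_p, dlp):
        # the quadratic exponent has its vertex near log P = -0.465, so the
        # binding term is strictly increasing for positive log P
        p = 0.5
        assert (microsomal_unbound_fraction(log_p + dlp, p)
                < microsomal_unbound_fraction(log_p, p))


class TestScaleIntrinsicClearance:
    @pytest.mark.parametrize("cid", ["CBX", "MCBX", "CPFPX"])
    def test_reference_values_within_one_percent(self, cid):
        ref = REFERENCE[cid]
        f_mic = microsomal_unbound_fraction(ref["log_p"], 0.5)
        cl_int = scale_intrinsic_clearance(
            ref["t_half"], f_mic, AssayContext(log_p=ref["log_p"])
        )
        assert cl_int == pytest.approx(ref["cl_int"], rel=0.01)

    def test_proportionality_in_half_life(self):
        ctx = AssayContext(log_p=2.0)
        one = scale_intrinsic_clearance(10.0, 0.8, ctx)
        two = scale_intrinsic_clearance(20.0, 0.8, ctx)
        assert one == pytest.approx(2.0 * two, rel=1e-12)

    @given(st.floats(1.0, 200.0), st.floats(0.05, 1.0),
           st.floats(0.1, 2.0))
    @settings(max_examples=100, deadline=None)
    def test_agrees_with_unit_tracked_recomputation(self, t_half, f_mic, p):
        """Independent term-by-term recomputation with explicit units."""
        ctx = AssayContext(protein_conc=p, log_p=1.0)
        sf = ScalingFactors()
        per_min_unbound = np.log(2.0) / t_half / f_mic          # 1/min
        ml_per_mg_protein = 1.0 / p                              # mL/mg
        ml_per_min_per_g_liver = (
            per_min_unbound * ml_per_mg_protein * sf.mg_protein_per_g_liver
        )
        expected = ml_per_min_per_g_liver * sf.g_liver_per_kg_bw  # mL/min/kg
        got = scale_intrinsic_clearance(t_half, f_mic, ctx, sf)
        assert got == pytest.approx(expected, rel=1e-9)

    def test_invalid_inputs_rejected(self):
        ctx = AssayContext(log_p=2.0)
        with pytest.raises(InvalidInputError):
            scale_intrinsic_clearance(-1.0, 0.8, ctx)
        with pytest.raises(InvalidInputError):
            scale_intrinsic_clearance(10.0, 0.0, ctx)
        with pytest.raises(InvalidInputError):
            scale_intrinsic_clearance(10.0, 1.5, ctx)


class TestSummarizeReplicates:
    def test_mean_and_sd_across_replicates(self):
        ctx = AssayContext(log_p=2.19)
        fits = [fit_monoexponential(_course(th)) for th in (34.0, 35.0, 36.0)]
        res = summarize_replicates(fits, "CBX", ctx)
        assert res.t_half_vitro == pytest.approx(35.0, rel=1e-6)
        assert res.t_half_sd == pytest.approx(1.0, rel=1e-5)
        assert res.n_replicates == 3
        assert 0 < res.f_mic <= 1

    def test_single_replicate_has_no_sd(self):
        ctx = AssayContext(log_p=2.19)
        res = summarize_replicates(
            [fit_monoexponential(_course(35.1))], "CBX", ctx
        )
        assert res.t_half_sd is None and res.cl_int_sd is None
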