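"""Pattern classification and Cleland-rule mechanism inference."""

import numpy as np
import pytest

from pkmech.dataset import VelocityDataset
from pkmech.designs import TPPK_MG_PARAMS
from pkmech.fitting import fit_inhibition_series
from pkmech.mechanism import (
    InhibitionCall,
    PatternCall,
    classify_inhibition,
    double_reciprocal_pattern,
    infer_mechanism,
    replot_effects,
)
from pkmech.rate_laws import InhibitionParams, OrderedParams, PingPongParams
from pkmech.synthetic import NoiseModel, make_velocity_dataset
from tests.conftest import inhibition_design


class TestDoubleReciprocalPattern:
    def test_random_re_intersects_on_s_axis_at_minus_one_over_ka(
        self, noiseless_random_re
    ):
        pat = double_reciprocal_pattern(noiseless_random_re)
        assert pat.family == "intersecting_on_S_axis"
        x0, y0 = pat.intersection
        assert x0 == pytest.approx(-1.0 / 0.38, rel=1e-6)
        assert abs(y0) < 1e-10

    def test_ping_pong_lines_are_parallel(self, velocity_grid):
        ds = make_velocity_dataset(
            "ping_pong", PingPongParams(183.0, 0.38, 0.16), velocity_grid
        )
        assert double_reciprocal_pattern(ds).family == "parallel"

    @pytest.mark.parametrize(
        "kia,family",
        [(2.0, "intersecting_left_above"), (0.15, "intersecting_left_below")],
    )
    def test_ordered_intersects_off_axis(self, velocity_grid, kia, family):
        # intersection ordinate (1/V)(1 - Ka/Kia) changes sign with Kia
        ds = make_velocity_dataset(
            "ordered", OrderedParams(183.0, 0.38, 0.16, kia), velocity_grid
        )
        pat = double_reciprocal_pattern(ds)
        assert pat.family == family
        assert pat.intersection[0] == pytest.approx(-1.0 / kia, rel=1e-6)

    def test_too_few_series_rejected(self):
        ds = make_velocity_dataset(
            "random_re", TPPK_MG_PARAMS,
            {"a_levels": (0.05, 0.1, 0.3, 1.0), "b_levels": (0.1, 0.5)},
        )
        with pytest.raises(ValueError, match="co-substrate series"):
            double_reciprocal_pattern(ds)

    def test_short_series_rejected(self):
        ds = make_velocity_dataset(
            "random_re", TPPK_MG_PARAMS,
            {"a_levels": (0.05, 0.3, 1.0), "b_levels": (0.1, 0.2, 0.5)},
        )
        with pytest.raises(ValueError, match="varied levels"):
            double_reciprocal_pattern(ds)

    def test_family_invariant_to_velocity_scaling_and_row_order(self, velocity_grid):
        ds = make_velocity_dataset(
            "random_re", TPPK_MG_PARAMS, velocity_grid,
            NoiseModel(scale=0.05, seed=31), replicates=5,
        )
        base = double_reciprocal_pattern(ds).family
        pts = ds.points.sample(frac=1.0, random_state=1).reset_index(drop=True)
        pts["v"] *= 7.5
        scaled = VelocityDataset(pts, varied=ds.varied)
        assert double_reciprocal_pattern(scaled).family == base

    def test_noiseless_recovery_over_parameter_grid(self):
        # exhaustive sweep: each generator family recovered exactly
        a_levels = (0.031, 0.14, 0.34, 0.69, 1.30)
        b_levels = (0.084, 0.12, 0.16, 0.37, 0.67)
        grid = {"a_levels": a_levels, "b_levels": b_levels}
        for ka in (0.1, 0.38, 1.0):
            for kb in (0.05, 0.16, 0.5):
                from pkmech.rate_laws import RandomREParams

                ds = make_velocity_dataset(
                    "random_re", RandomREParams(100.0, ka, kb), grid
                )
                assert (
                    double_reciprocal_pattern(ds).family
                    == "intersecting_on_S_axis"
                )
                ds = make_velocity_dataset(
                    "ping_pong", PingPongParams(100.0, ka, kb), grid
                )
                assert double_reciprocal_pattern(ds).family == "parallel"


class TestClassifyInhibition:
    @staticmethod
    def _call(kind, params, design_key, seed=None, replicates=1):
        noise = None if seed is None else NoiseModel(scale=0.05, seed=seed)
        ds = make_velocity_dataset(
            kind, params, inhibition_design(design_key), noise, replicates
        )
        fit = fit_inhibition_series(ds)
        return classify_inhibition(fit, replot_effects(ds))

    def test_competitive_oxalate_vs_pep(self):
        call = self._call(
            "competitive",
            InhibitionParams(v=183.0, km=0.38, ki=0.05, kind="competitive"),
            "oxalate_vs_pep",
        )
        assert call.kind == "C"
        assert call.slope_effect and not call.intercept_effect

    def test_noncompetitive_oxalate_vs_adpmg(self):
        call = self._call(
            "noncompetitive",
            InhibitionParams(v=183.0, km=0.16, ki=0.05, kind="noncompetitive"),
            "oxalate_vs_adpmg",
        )
        assert call.kind == "NC"
        assert call.slope_effect and call.intercept_effect

    def test_mixed_amp_vs_pep_alpha_below_one(self):
        call = self._call(
            "mixed",
            InhibitionParams(v=183.0, km=0.38, ki=35.0, alpha=0.5, kind="mixed"),
            "amp_vs_pep",
            seed=41,
            replicates=5,
        )
        assert call.kind == "MT"
        assert call.alpha_flag == "α<1"

    def test_flat_inhibitor_yields_no_inhibition_call(self):
        # zero-effect inhibitor: Ki effectively infinite
        params = InhibitionParams(v=183.0, km=0.38, ki=1e6, kind="competitive")
        ds = make_velocity_dataset(
            "competitive", params, inhibition_design("oxalate_vs_pep"),
            NoiseModel(scale=0.02, seed=3), replicates=3,
        )
        fit = fit_inhibition_series(ds)
        call = classify_inhibition(fit, replot_effects(ds))
        assert call.kind == "none"


class TestInferMechanism:
    PATTERN = PatternCall(
        "intersecting_on_S_axis", (-2.63, 0.0), (0.01, 0.001), {}, {}, {}
    )

    @staticmethod
    def _call(kind, alpha_flag="α=1"):
        return InhibitionCall(kind, True, kind != "C", alpha_flag)

    def test_published_pattern_set_gives_random_rapid_equilibrium(self):
        # oxalate: C vs PEP, NC vs ADP-Mg; AMP: MT vs PEP, C vs ADP-Mg
        calls = [
            (self._call("C"), "PEP3-", "PEP3-"),
            (self._call("NC"), "ADP-Mg", "PEP3-"),
            (self._call("MT", "α<1"), "PEP3-", "ADP-Mg"),
            (self._call("C"), "ADP-Mg", "ADP-Mg"),
        ]
        out = infer_mechanism(self.PATTERN, calls)
        assert out.mechanism == "rapid_equilibrium_random"

    def test_uncompetitive_cross_pattern_gives_ordered(self):
        calls = [
            (self._call("C"), "ADP-Mg", "ADP-Mg"),
            (InhibitionCall("UC", False, True, "α=1"), "PEP3-", "ADP-Mg"),
        ]
        out = infer_mechanism(self.PATTERN, calls)
        assert out.mechanism == "ordered"
        assert "PEP3-" in out.notes

    def test_parallel_pattern_gives_ping_pong(self):
        pat = PatternCall("parallel", None, None, {}, {}, {})
        assert infer_mechanism(pat, []).mechanism == "ping_pong"

    def test_no_inhibition_evidence_is_ambiguous(self):
        out = infer_mechanism(self.PATTERN, [])
        assert out.mechanism == "ambiguous"
        assert "dead-end inhibition" in out.notes

    def test_conflicting_calls_are_ambiguous(self):
        calls = [
            (self._call("NC"), "PEP3-", "PEP3-"),  # analog not competitive vs itself
            (self._call("C"), "ADP-Mg", "ADP-Mg"),
        ]
        assert infer_mechanism(self.PATTERN, calls).mechanism == "ambiguous"
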