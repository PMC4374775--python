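"""Global least-squares estimation and inhibition model selection."""

import numpy as np
import pytest

from pkmech.dataset import VelocityDataset
from pkmech.designs import TPPK_MG_PARAMS
from pkmech.fitting import (
    IdentifiabilityError,
    fit_global,
    fit_inhibition_series,
)
from pkmech.rate_laws import InhibitionParams
from pkmech.synthetic import NoiseModel, make_velocity_dataset
from tests.conftest import inhibition_design


class TestFitGlobal:
    def test_noiseless_random_re_recovers_generator(self, noiseless_random_re):
        fr = fit_global(noiseless_random_re, "random_re")
        assert fr.converged
        assert fr.estimates["vmax"] == pytest.approx(183.0, rel=1e-6)
        assert fr.estimates["ka"] == pytest.approx(0.38, rel=1e-6)
        assert fr.estimates["kb"] == pytest.approx(0.16, rel=1e-6)

    def test_noiseless_competitive_recovers_ki(self, noiseless_oxalate_competitive):
        fr = fit_global(noiseless_oxalate_competitive, "competitive")
        assert fr.estimates["ki"] == pytest.approx(0.05, rel=1e-6)

    def test_single_substrate_level_is_unidentifiable(self):
        ds = VelocityDataset.from_arrays(
            a=[0.1] * 6,
            b=[0.1, 0.2, 0.4, 0.8, 1.6, 3.2],
            i=[0.0] * 6,
            v=[10, 20, 30, 40, 50, 55],
            varied="b",
        )
        with pytest.raises(IdentifiabilityError):
            fit_global(ds, "random_re")

    def test_rss_matches_direct_recomputation(self, velocity_grid):
        ds = make_velocity_dataset(
            "random_re", TPPK_MG_PARAMS, velocity_grid,
            NoiseModel(scale=0.05, seed=11), replicates=3,
        )
        fr = fit_global(ds, "random_re")
        resid = fr.predict(ds) - ds.v
        assert fr.rss == pytest.approx(float(np.sum(resid**2)), rel=1e-12)

    def test_invariant_to_point_order(self, velocity_grid):
        ds = make_velocity_dataset(
            "random_re", TPPK_MG_PARAMS, velocity_grid,
            NoiseModel(scale=0.05, seed=5), replicates=2,
        )
        shuffled = VelocityDataset(
            ds.points.sample(frac=1.0, random_state=3).reset_index(drop=True),
            varied=ds.varied,
        )
        f1 = fit_global(ds, "random_re")
        f2 = fit_global(shuffled, "random_re")
        for p in f1.estimates:
            assert f1.estimates[p] == pytest.approx(f2.estimates[p], rel=1e-8)

    def test_equivariant_under_velocity_rescaling(self, velocity_grid):
        ds = make_velocity_dataset(
            "random_re", TPPK_MG_PARAMS, velocity_grid,
            NoiseModel(scale=0.05, seed=9), replicates=2,
        )
        scaled_pts = ds.points.copy()
        scaled_pts["v"] *= 3.0
        scaled = VelocityDataset(scaled_pts, varied=ds.varied)
        f1 = fit_global(ds, "random_re")
        f2 = fit_global(scaled, "random_re")
        assert f2.estimates["vmax"] == pytest.approx(3 * f1.estimates["vmax"], rel=1e-6)
        assert f2.estimates["ka"] == pytest.approx(f1.estimates["ka"], rel=1e-6)
        assert f2.estimates["kb"] == pytest.approx(f1.estimates["kb"], rel=1e-6)

    def test_unknown_model_rejected(self, noiseless_random_re):
        with pytest.raises(ValueError, match="unknown model"):
            fit_global(noiseless_random_re, "king_altman")

    def test_stderr_reported_on_noisy_fit(self, velocity_grid):
        ds = make_velocity_dataset(
            "random_re", TPPK_MG_PARAMS, velocity_grid,
            NoiseModel(scale=0.05, seed=2), replicates=5,
        )
        fr = fit_global(ds, "random_re")
        assert all(se > 0 for se in fr.stderr.values())
        assert np.isfinite(fr.aicc)


class TestInhibitionSeries:
    def test_competitive_data_selects_competitive(self):
        params = InhibitionParams(v=183.0, km=0.38, ki=0.05, kind="competitive")
        ds = make_velocity_dataset(
            "competitive", params, inhibition_design("oxalate_vs_pep"),
            NoiseModel(scale=0.05, seed=17), replicates=5,
        )
        out = fit_inhibition_series(ds)
        assert out.kind == "competitive"
        assert out.best.estimates["ki"] == pytest.approx(0.05, rel=0.2)

    def test_mixed_alpha_below_one_flagged(self):
        params = InhibitionParams(v=183.0, km=0.38, ki=35.0, alpha=0.5, kind="mixed")
        ds = make_velocity_dataset(
            "mixed", params, inhibition_design("amp_vs_pep"),
            NoiseModel(scale=0.05, seed=23), replicates=5,
        )
        out = fit_inhibition_series(ds)
        assert out.kind == "mixed"
        assert out.alpha_flag == "α<1"

    def test_close_candidates_reported_ambiguous_not_dropped(self):
        # noiseless noncompetitive data: mixed nests it exactly, so it ties
        # to within the one-parameter AICc penalty and must be surfaced
        # inside a band of that width, not silently discarded
        params = InhibitionParams(v=100.0, km=0.4, ki=1.0, kind="noncompetitive")
        ds = make_velocity_dataset(
            "noncompetitive", params, inhibition_design("oxalate_vs_adpmg")
        )
        out = fit_inhibition_series(ds, ambiguity_band=4.0)
        assert out.kind == "noncompetitive"
        assert out.delta_aicc["mixed"] < 4.0
        assert "mixed" in out.ambiguous

    def test_requires_zero_inhibitor_level(self):
        params = InhibitionParams(v=100.0, km=0.4, ki=1.0, kind="competitive")
        design = dict(inhibition_design("oxalate_vs_pep"))
        design["i_levels"] = (0.01, 0.02, 0.03)
        ds = make_velocity_dataset("competitive", params, design)
        with pytest.raises(IdentifiabilityError, match=r"\[I\] = 0"):
            fit_inhibition_series(ds)

    def test_requires_three_inhibitor_levels(self):
        params = InhibitionParams(v=100.0, km=0.4, ki=1.0, kind="competitive")
        design = dict(inhibition_design("oxalate_vs_pep"))
        design["i_levels"] = (0.0, 0.02)
        ds = make_velocity_dataset("competitive", params, design)
        with pytest.raises(IdentifiabilityError, match="3 inhibitor levels"):
            fit_inhibition_series(ds)


class TestDatasetIO:
    def test_table_round_trip(self, tmp_path, noiseless_random_re):
        path = tmp_path / "grid.tsv"
        noiseless_random_re.write_table(path)
        back = VelocityDataset.read_table(path)
        np.testing.assert_allclose(back.v, noiseless_random_re.v)
        np.testing.assert_allclose(back.a, noiseless_random_re.a)

    def test_negative_velocity_rejected(self):
        with pytest.raises(ValueError, match="v"):
            VelocityDataset.from_arrays(
                a=[1, 2], b=[1, 1], i=[0, 0], v=[1.0, -0.5]
            )
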