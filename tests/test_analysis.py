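"""Fluence-map analysis: normalization, contours, superposition, sweeps."""
import math

import numpy as np
import pytest

from skinmc import (ConstantCoefficientTable, GridSpec, LayerSpec,
                    SkinModel, SourceSpec, contour_depth, critical_width,
                    fluence_ratio, infinite_beam_profile, make_fixture,
                    normalize, run_simulation, sweep_beamwidth,
                    sweep_wavelength)
from skinmc.analysis import SweepResult
import pandas as pd


def _uniform_slab(lateral_um=100_000.0, depth_um=5_000.0, cell_um=10.0):
    layer = LayerSpec(name="slab", thickness_um=depth_um, refractive_index=1.4,
                      anisotropy_g=0.789)
    grid = GridSpec(cell_um=cell_um, lateral_extent_um=lateral_um,
                    depth_extent_um=depth_um)
    model = SkinModel(layers=(layer,), grid=grid)
    table = ConstantCoefficientTable(mua_default=0.03, mus_default=14.2)
    return model, table


@pytest.fixture(scope="module")
def slab_runs():
    """Pencil, 1 mm, 10 mm and 40 mm runs on one uniform slab."""
    model, table = _uniform_slab()
    runs = {}
    for name, width, n, seed in [("pencil", 0.01, 150_000, 11),
                                 ("w1", 1.0, 100_000, 12),
                                 ("w10", 10.0, 100_000, 13),
                                 ("w40", 40.0, 150_000, 14)]:
        src = SourceSpec.monochromatic(600.0, beam_width_mm=width,
                                       photon_count=n, seed=seed)
        runs[name] = (run_simulation(model, table, src), src)
    return runs


class TestNormalize:
    def test_per_max_puts_peak_at_one(self):
        fx = make_fixture("beer_lambert", {"photons": 20_000}, seed=1)
        res = run_simulation(fx["model"], fx["table"], fx["source"])
        fmap = normalize(res, fx["source"], "per_max_deposition")
        assert fmap.values.max() == 1.0
        assert np.all(fmap.values >= 0)

    def test_single_hot_cell(self):
        fx = make_fixture("exp_decay_map")
        fmap = fx["map"]
        values = np.zeros_like(fmap.values)
        values[7, 3] = 4.2
        res_like = type("R", (), dict(absorbed=values, cell_um=fmap.cell_um,
                                      y_min_um=fmap.y_min_um, photons_launched=10,
                                      beam_width_mm=1.0))()
        out = normalize(res_like, make_fixture("beer_lambert")["source"],
                        "per_max_deposition")
        assert out.values[7, 3] == 1.0
        assert out.values.sum() == 1.0

    def test_all_zero_grid_rejected(self):
        fx = make_fixture("beer_lambert", {"photons": 10}, seed=1)
        res = run_simulation(fx["model"], fx["table"], fx["source"])
        res.absorbed[:] = 0.0
        with pytest.raises(ValueError, match="all-zero"):
            normalize(res, fx["source"], "per_max_deposition")

    def test_per_incident_bounded_by_unity_total(self):
        fx = make_fixture("beamwidth_study_setup", {"photons": 30_000}, seed=2)
        res = run_simulation(fx["model"], fx["table"], fx["source"])
        # total deposited energy cannot exceed incident energy
        assert res.absorbed_total <= res.photons_launched

    def test_per_max_invariant_to_photon_count(self):
        # doubling the photon budget must not change the normalized map
        # beyond Monte Carlo error; compare band profiles on their own
        # maxima (the low-variance estimator used for contouring)
        fx1 = make_fixture("beer_lambert", {"photons": 50_000}, seed=3)
        fx2 = make_fixture("beer_lambert", {"photons": 100_000}, seed=4)
        profiles = []
        for fx in (fx1, fx2):
            res = run_simulation(fx["model"], fx["table"], fx["source"])
            fmap = normalize(res, fx["source"], "per_max_deposition")
            p = fmap.band_profile(300.0)
            # rebin by 10 cells in depth so each point has enough counts
            p = p[: p.size // 10 * 10].reshape(-1, 10).mean(axis=1)
            profiles.append(p / p.max())
        p1, p2 = profiles
        assert np.allclose(p1, p2, rtol=0.10, atol=0.02)


class TestContourDepth:
    def test_exponential_map_closed_form(self):
        fx = make_fixture("exp_decay_map", {"delta_mm": 0.5})
        pen = contour_depth(fx["map"], 0.01)
        # delta * ln(100) = 2302.6 um, within one 5-um cell
        assert pen.depth_um == pytest.approx(fx["expected_depth_um"], abs=10.0)

    def test_single_nonzero_cell(self):
        fx = make_fixture("exp_decay_map")
        fmap = fx["map"]
        fmap.values[:] = 0.0
        fmap.values[41, 5] = 1.0
        for frac in (0.01, 0.5, 0.99):
            assert contour_depth(fmap, frac).depth_um == pytest.approx(42 * 5.0)

    def test_threshold_monotonicity(self):
        fx = make_fixture("exp_decay_map", {"delta_mm": 0.3})
        d_1pct = contour_depth(fx["map"], 0.01).depth_um
        d_135 = contour_depth(fx["map"], 0.135).depth_um
        d_e = contour_depth(fx["map"], 1 / math.e).depth_um
        assert d_e <= d_135 <= d_1pct

    def test_fraction_domain(self):
        fx = make_fixture("exp_decay_map")
        for bad in (0.0, 1.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                contour_depth(fx["map"], bad)

    def test_surface_only_map_warns(self):
        fx = make_fixture("exp_decay_map")
        fmap = fx["map"]
        fmap.values[:] = 0.0
        fmap.values[0, :] = 1.0
        with pytest.warns(UserWarning, match="below the surface"):
            contour_depth(fmap, 0.5)


class TestSuperposition:
    def test_pencil_requires_one_cell_beam(self, slab_runs):
        res, _ = slab_runs["w10"]
        with pytest.raises(ValueError, match="one cell wide"):
            infinite_beam_profile(res)

    def test_beer_lambert_limit(self):
        # mu_s = 0: the superposed infinite beam is exactly Beer-Lambert
        fx = make_fixture("beer_lambert", {"photons": 80_000, "mua_mm": 1.0,
                                           "cell_um": 10.0}, seed=8)
        src = SourceSpec.monochromatic(600.0, beam_width_mm=0.01,
                                       photon_count=80_000, seed=8)
        res = run_simulation(fx["model"], fx["table"], src)
        prof = infinite_beam_profile(res)
        z_mm = (np.arange(prof.size) + 0.5) * 0.01
        keep = prof * 80_000 > 50
        slope = np.polyfit(z_mm[keep], np.log(prof[keep]), 1)[0]
        assert slope == pytest.approx(-1.0, rel=0.05)

    def test_superposition_matches_direct_wide_beam(self, slab_runs):
        pencil, _ = slab_runs["pencil"]
        direct, dsrc = slab_runs["w40"]
        prof_inf = infinite_beam_profile(pencil)
        fmap = normalize(direct, dsrc, "per_incident")
        prof_dir = fmap.band_profile(1000.0)
        for z_mm in (0.5, 1.0, 2.0, 3.0):
            iz = int(z_mm * 100)
            assert prof_dir[iz] == pytest.approx(prof_inf[iz], rel=0.10)

    def test_all_zero_pencil_rejected(self, slab_runs):
        pencil, _ = slab_runs["pencil"]
        empty = type(pencil)(**{**pencil.__dict__, "absorbed": np.zeros_like(pencil.absorbed)})
        with pytest.raises(ValueError, match="all-zero"):
            infinite_beam_profile(empty)


class TestFluenceRatio:
    def test_identity_inputs_give_unity(self, slab_runs):
        res, src = slab_runs["w10"]
        fmap = normalize(res, src, "per_incident")
        prof = fmap.band_profile(1000.0)
        for d in (0.5, 1.5, 2.5):
            assert fluence_ratio(fmap, prof, d) == pytest.approx(1.0)

    def test_ratio_non_increasing_with_depth(self, slab_runs):
        pencil, _ = slab_runs["pencil"]
        prof = infinite_beam_profile(pencil)
        res, src = slab_runs["w10"]
        fmap = normalize(res, src, "per_incident")
        ratios = [fluence_ratio(fmap, prof, d) for d in (1.0, 2.0, 3.0)]
        assert ratios[0] >= ratios[1] - 0.05
        assert ratios[1] >= ratios[2] - 0.05

    def test_narrow_beam_ratio_smaller(self, slab_runs):
        pencil, _ = slab_runs["pencil"]
        prof = infinite_beam_profile(pencil)
        r1, s1 = slab_runs["w1"]
        r10, s10 = slab_runs["w10"]
        ratio1 = fluence_ratio(normalize(r1, s1, "per_incident"), prof, 2.0,
                               band_halfwidth_um=300.0)
        ratio10 = fluence_ratio(normalize(r10, s10, "per_incident"), prof, 2.0)
        assert ratio1 < ratio10

    def test_depth_beyond_grid_rejected(self, slab_runs):
        res, src = slab_runs["w10"]
        fmap = normalize(res, src, "per_incident")
        prof = fmap.band_profile(1000.0)
        with pytest.raises(ValueError, match="beyond grid"):
            fluence_ratio(fmap, prof, 99.0)


class TestSweeps:
    def test_wavelength_sweep_point_count_and_order(self):
        fx = make_fixture("wavelength_study_setup")
        lams = list(range(300, 751, 50))
        sweep = sweep_wavelength(fx["model"], fx["table"], lams,
                                 photons=5_000, seed=3)
        assert len(sweep.table) == 10
        assert list(sweep.table["wavelength_nm"]) == lams

    def test_single_point_sweep_equals_direct_run(self):
        fx = make_fixture("wavelength_study_setup")
        sweep = sweep_wavelength(fx["model"], fx["table"], [600.0],
                                 photons=20_000, seed=17)
        src = SourceSpec.monochromatic(600.0, beam_width_mm=30.0,
                                       photon_count=20_000, seed=17)
        res = run_simulation(fx["model"], fx["table"], src)
        fmap = normalize(res, src, "per_max_deposition")
        direct = contour_depth(fmap, 0.01, band_halfwidth_um=0.25 * 30_000 / 2)
        assert sweep.table["depth_um_0.01"].iloc[0] == direct.depth_um

    def test_empty_sweep_rejected(self):
        fx = make_fixture("wavelength_study_setup")
        with pytest.raises(ValueError):
            sweep_wavelength(fx["model"], fx["table"], [], photons=10)

    def test_beamwidth_sweep_runs(self):
        fx = make_fixture("beamwidth_study_setup")
        sweep = sweep_beamwidth(fx["model"], fx["table"],
                                fx["source"].spectrum, [1.0, 5.0, 10.0],
                                photons=5_000, seed=9)
        assert len(sweep.table) == 3
        assert (sweep.table["escaped_fraction"] < 1.0).all()


class TestCriticalWidth:
    def _sweep(self, widths, depths_mm):
        table = pd.DataFrame({"beam_width_mm": widths,
                              "depth_um_0.01": [d * 1000 for d in depths_mm]})
        return SweepResult(axis="beam_width", table=table, criteria=(0.01,))

    def test_constructed_plateau(self):
        fx = make_fixture("toy_sweep")
        assert critical_width(fx["sweep"], 0.05) == 10.0

    def test_strictly_rising_has_no_plateau(self):
        sweep = self._sweep([1, 5, 10, 20, 40], [1.0, 2.0, 3.0, 4.0, 5.0])
        assert critical_width(sweep, 0.05) is None

    def test_degenerate_tolerance_returns_smallest(self):
        fx = make_fixture("toy_sweep")
        assert critical_width(fx["sweep"], 1.0) == 1.0

    def test_needs_three_points(self):
        sweep = self._sweep([1, 5], [1.0, 1.0])
        with pytest.raises(ValueError):
            critical_width(sweep)
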