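"""Simulator: primary model, both scatter engines, rendered acquisitions."""

import math
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from ctscatter.geometry import (BlockerArray, ConfigurationError, Phantom,
                                ScannerGeometry, project_shadow)
from ctscatter.physics import Spectrum, blocker_transmission, get_material
from ctscatter.raw_io import read_frame
from ctscatter.simulator import (AcquisitionSetup, GroundTruth, make_study_fixtures,
                                 render_acquisition_pair, simulate_primary,
                                 simulate_scatter_deterministic, simulate_scatter_mc)


class TestPrimary:
    def test_open_beam_is_flat(self, small_geom, coarse_spectrum):
        setup = AcquisitionSetup(geometry=small_geom, spectrum=coarse_spectrum)
        p = simulate_primary(setup)
        assert p.shape == (8, 228)
        assert np.allclose(p, p[0, 0])

    def test_blocker_scales_core_channels_by_lead_transmission(
            self, small_geom, small_blocker, coarse_spectrum):
        setup = AcquisitionSetup(geometry=small_geom, blocker=small_blocker,
                                 spectrum=coarse_spectrum)
        p = simulate_primary(setup)
        open_setup = AcquisitionSetup(geometry=small_geom, spectrum=coarse_spectrum)
        p0 = simulate_primary(open_setup)
        mask = project_shadow(small_geom, small_blocker, penumbra_margin=0)
        core = mask.labels == 2
        t = blocker_transmission(small_blocker.bar_thickness / 10)
        assert np.allclose(p[:, core], p0[:, core] * t, rtol=1e-12)
        untouched = mask.coverage == 0
        assert np.allclose(p[:, untouched], p0[:, untouched], rtol=1e-12)

    def test_monoenergetic_beer_lambert_by_hand(self, small_geom, water_phantom):
        """Central-channel signal equals a hand-evaluated Beer-Lambert product."""
        sp = Spectrum.monoenergetic(60.0)
        setup = AcquisitionSetup(geometry=small_geom, phantom=water_phantom,
                                 spectrum=sp, tube_current=100.0, exposure_time=3.0)
        p = simulate_primary(setup)
        n = small_geom.n_channels_total
        theta = math.radians((0 - (n - 1) / 2 + (n // 2)) * 56.0 / n)
        d = 540.0 * abs(math.sin(theta))
        l_w = 2 * math.sqrt(107.5 ** 2 - d ** 2) / 10
        l_p = (2 * math.sqrt(113.5 ** 2 - d ** 2)) / 10 - l_w
        mu_w = get_material("water").linear_attenuation(60.0)
        mu_p = get_material("plexiglas").linear_attenuation(60.0)
        expected = 100.0 * 3.0 * 60.0 ** 2 * 60.0 * math.exp(-mu_w * l_w - mu_p * l_p)
        assert p[0, n // 2] == pytest.approx(expected, rel=1e-6)


class TestDeterministicEngine:
    def test_requires_phantom_and_positive_resolution(self, small_geom, coarse_spectrum):
        s = AcquisitionSetup(geometry=small_geom, spectrum=coarse_spectrum)
        with pytest.raises(ConfigurationError):
            simulate_scatter_deterministic(s)
        s2 = AcquisitionSetup(geometry=small_geom, spectrum=coarse_spectrum,
                              phantom=Phantom(fill_diameter=100, fill_material="water"))
        with pytest.raises(ConfigurationError):
            simulate_scatter_deterministic(s2, grid_resolution=0.0)

    def test_vanishing_phantom_gives_vanishing_scatter(self, small_geom, coarse_spectrum):
        big = AcquisitionSetup(geometry=small_geom, spectrum=coarse_spectrum,
                               phantom=Phantom(fill_diameter=215, fill_material="water"))
        tiny = AcquisitionSetup(geometry=small_geom, spectrum=coarse_spectrum,
                                phantom=Phantom(fill_diameter=2, fill_material="water"))
        sb = simulate_scatter_deterministic(big, grid_resolution=5.0).sum()
        st = simulate_scatter_deterministic(tiny, grid_resolution=0.5).sum()
        assert st < 1e-2 * sb

    def test_self_convergence_under_grid_refinement(self, small_setup):
        coarse = simulate_scatter_deterministic(small_setup, grid_resolution=8.0)
        fine = simulate_scatter_deterministic(small_setup, grid_resolution=4.0)
        rel = np.abs(fine - coarse) / fine.max()
        assert rel.max() < 0.01

    def test_centred_phantom_profile_mirror_symmetric(self, small_setup):
        s = simulate_scatter_deterministic(small_setup, grid_resolution=5.0,
                                           exploit_symmetry=False)
        asym = np.abs(s - s[:, ::-1]) / s.max()
        assert asym.max() < 1e-3

    def test_symmetry_shortcut_matches_full_loop(self, small_setup):
        full = simulate_scatter_deterministic(small_setup, grid_resolution=8.0,
                                              exploit_symmetry=False)
        half = simulate_scatter_deterministic(small_setup, grid_resolution=8.0,
                                              exploit_symmetry=True)
        np.testing.assert_allclose(half, full, rtol=1e-9, atol=full.max() * 1e-12)

    def test_scatter_fraction_grows_with_phantom_diameter(self, small_geom,
                                                          coarse_spectrum):
        fractions = []
        for dia, mat in ((215.0, "water"), (300.0, "polypropylene")):
            ph = Phantom(fill_diameter=dia, fill_material=mat)
            s = AcquisitionSetup(geometry=small_geom, phantom=ph,
                                 spectrum=coarse_spectrum)
            centre = small_geom.n_channels_total // 2
            sc = simulate_scatter_deterministic(s, grid_resolution=5.0)[4, centre]
            pr = simulate_primary(s)[4, centre]
            fractions.append(sc / (sc + pr))
        assert fractions[1] > fractions[0]

    def test_air_gap_scatter_monotone_in_offset(self, small_geom, coarse_spectrum):
        totals = []
        for off in (-100.0, 0.0, 100.0):
            ph = Phantom(fill_diameter=215.0, fill_material="water", axial_offset=off)
            s = AcquisitionSetup(geometry=small_geom, phantom=ph,
                                 spectrum=coarse_spectrum)
            totals.append(simulate_scatter_deterministic(s, grid_resolution=5.0).sum())
        assert totals[0] < totals[1] < totals[2]


class TestMonteCarloEngine:
    def test_zero_photons_zero_matrix(self, small_setup):
        s = replace(small_setup, n_photons=0)
        m, se = simulate_scatter_mc(s)
        assert not m.any() and not se.any()

    def test_same_seed_bit_identical(self, small_setup):
        s = replace(small_setup, n_photons=50_000)
        m1, se1 = simulate_scatter_mc(s)
        m2, se2 = simulate_scatter_mc(s)
        np.testing.assert_array_equal(m1, m2)
        np.testing.assert_array_equal(se1, se2)

    def test_different_seed_differs(self, small_setup):
        m1, _ = simulate_scatter_mc(replace(small_setup, n_photons=50_000, seed=1))
        m2, _ = simulate_scatter_mc(replace(small_setup, n_photons=50_000, seed=2))
        assert not np.array_equal(m1, m2)

    def test_phantom_required(self, small_geom, coarse_spectrum):
        with pytest.raises(ConfigurationError):
            simulate_scatter_mc(AcquisitionSetup(geometry=small_geom,
                                                 spectrum=coarse_spectrum))

    def test_agrees_with_quadrature_oracle(self, small_setup):
        """Row-summed per-channel MC estimates sit within 3 standard errors of
        the deterministic quadrature for nearly all channels."""
        s = replace(small_setup, n_photons=1_000_000)
        det = simulate_scatter_deterministic(s, grid_resolution=5.0).sum(axis=0)
        mc, se = simulate_scatter_mc(s)
        m = mc.sum(axis=0)
        sig = np.sqrt((se ** 2).sum(axis=0))
        z = (m - det) / np.where(sig > 0, sig, np.inf)
        assert (np.abs(z) <= 3).mean() >= 0.95
        # grand totals agree within 3 standard errors of the total
        assert abs(m.sum() - det.sum()) <= 3 * np.sqrt((sig ** 2).sum())


class TestRenderedAcquisitions:
    def test_conservation_and_frame_contents(self, rendered_pair, small_identity_cal):
        truth = rendered_pair["truth_obj"]
        np.testing.assert_array_equal(truth.total, truth.primary + truth.scatter)
        with_frame = read_frame(rendered_pair["phantom_frame"])
        assert with_frame.meta.phantom_present and with_frame.meta.blocker_present
        # float32 container: conservation holds to float32 precision
        np.testing.assert_allclose(with_frame.readings, truth.total, rtol=2e-7)
        blocker_frame = read_frame(rendered_pair["blocker_frame"])
        assert not blocker_frame.meta.phantom_present

    def test_blocker_frame_shadow_carries_leakage_only(self, rendered_pair,
                                                       small_geom, small_blocker):
        frame = read_frame(rendered_pair["blocker_frame"])
        mask = project_shadow(small_geom, small_blocker, penumbra_margin=0)
        core = mask.labels == 2
        open_ = mask.coverage == 0
        t = blocker_transmission(small_blocker.bar_thickness / 10)
        assert frame.readings[:, core].max() <= frame.readings[:, open_].max() * t * 1.01

    def test_poisson_noise_reproducible(self, small_setup, small_identity_cal, tmp_path):
        s = replace(small_setup, noise="poisson")
        e1 = render_acquisition_pair(s, small_identity_cal, tmp_path / "a", tag="n")
        e2 = render_acquisition_pair(s, small_identity_cal, tmp_path / "b", tag="n")
        b1 = open(e1["phantom_frame"], "rb").read()
        b2 = open(e2["phantom_frame"], "rb").read()
        assert b1 == b2

    def test_requires_blocker_and_phantom(self, small_geom, coarse_spectrum,
                                          small_identity_cal, tmp_path):
        s = AcquisitionSetup(geometry=small_geom, spectrum=coarse_spectrum,
                             phantom=Phantom(fill_diameter=100, fill_material="water"))
        with pytest.raises(ConfigurationError):
            render_acquisition_pair(s, small_identity_cal, tmp_path)


class TestStudyFixtures:
    def test_manifest_enumerates_all_pairs(self, small_geom, small_blocker, tmp_path):
        manifest = make_study_fixtures(tmp_path, geometry=small_geom,
                                       blocker=small_blocker, seed=3,
                                       kvps=(80.0, 140.0), offsets=(-50.0, 0.0, 50.0),
                                       grid_resolution=10.0, spectrum_bin=20.0)
        df = pd.read_csv(manifest, sep="\t")
        assert len(df) == 2 * 2 + 3
        for _, row in df.iterrows():
            for key in ("blocker_frame", "phantom_frame", "truth"):
                assert (tmp_path / row[key]).exists() or __import__("pathlib").Path(row[key]).exists()
        assert df.seed.nunique() == len(df)

    def test_ground_truth_sidecar_roundtrip(self, rendered_pair):
        truth = rendered_pair["truth_obj"]
        reloaded = GroundTruth.load(rendered_pair["truth"])
        np.testing.assert_allclose(reloaded.primary, truth.primary, rtol=1e-8)
        np.testing.assert_allclose(reloaded.scatter, truth.scatter, rtol=1e-8)
        np.testing.assert_allclose(reloaded.primary_unblocked, truth.primary_unblocked,
                                   rtol=1e-8)
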