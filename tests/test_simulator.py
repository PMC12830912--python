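"""Detector geometry, photon transport, blurring and binning."""

import numpy as np
import pytest
from scipy import stats

from entpet import kinematics as kin
from entpet.geometry import DetectorGeometry
from entpet.simulator import (
    EnergyModel,
    InteractionModel,
    SourceConfig,
    blur_energy,
    generate_decays,
    sample_photon_history,
)


class TestGeometry:
    def test_crystal_count_and_extent(self, geometry):
        assert geometry.crystals_per_panel == 150
        assert geometry.half_x * 2 == 150.0   # 30 crystals x 5 mm
        assert geometry.half_y * 2 == 200.0   # 5 crystals x 40 mm

    def test_invalid_separation_rejected(self):
        with pytest.raises(ValueError):
            DetectorGeometry(panel_separation=-1.0)

    @pytest.mark.parametrize("local_z, expected", [
        (0.3, 0.5),    # snaps to the first voxel center
        (1.0, 0.5),    # boundary tie rounds toward the lower voxel
        (1.2, 1.5),
        (39.9, 39.5),
    ])
    def test_voxelize_center_convention(self, geometry, local_z, expected):
        lo, _ = geometry.panel_bounds(1)
        point = lo + np.array([2.2, 3.7, local_z])
        out = geometry.voxelize(point)
        assert out[2] == pytest.approx(lo[2] + expected)

    def test_voxelize_idempotent(self, geometry):
        rng = np.random.default_rng(0)
        lo, hi = geometry.panel_bounds(0)
        pts = rng.uniform(lo, hi, size=(500, 3))
        once = geometry.voxelize(pts)
        assert np.array_equal(geometry.voxelize(once), once)

    def test_voxelize_outside_raises(self, geometry):
        with pytest.raises(ValueError):
            geometry.voxelize(np.array([0.0, 0.0, 0.0]))  # in the gap


class TestBlurEnergy:
    def test_zero_resolution_is_identity(self):
        model = EnergyModel(reference_resolution=0.0)
        e = np.linspace(100.0, 600.0, 11)
        assert np.array_equal(blur_energy(e, model, rng=1), e)

    def test_fwhm_recovered_at_511(self):
        model = EnergyModel()
        blurred = blur_energy(np.full(100_000, 511.0), model, rng=2)
        mu, sigma = stats.norm.fit(blurred)
        fwhm_frac = 2.3548 * sigma / 511.0
        assert fwhm_frac == pytest.approx(0.0585, abs=0.001)

    def test_mean_preserved(self):
        blurred = blur_energy(np.full(100_000, 511.0), EnergyModel(), rng=3)
        assert blurred.mean() == pytest.approx(511.0, abs=0.2)

    def test_inverse_sqrt_scaling(self):
        model = EnergyModel()
        # fractional FWHM at 4x the reference energy is half the reference
        assert (model.fwhm(4 * 511.0) / (4 * 511.0)
                == pytest.approx(0.0585 / 2.0))


class TestPhotonHistories:
    def test_photoelectric_only_when_compton_disabled(self, geometry):
        model = InteractionModel(compton_prob_override=0.0)
        rng = np.random.default_rng(4)
        for _ in range(200):
            h = sample_photon_history((0, 0, 0), (0.1, -0.05, 1.0), 511.0,
                                      geometry, model, rng)
            if len(h.processes):
                assert h.processes == ["photoelectric"]
                assert h.deposits[0] == pytest.approx(511.0)
                assert h.escape_kev == pytest.approx(0.0)

    def test_forced_absorption_conserves_energy(self, geometry):
        model = InteractionModel(compton_prob_override=1.0, force_absorption=True)
        rng = np.random.default_rng(5)
        seen = 0
        for _ in range(200):
            h = sample_photon_history((0, 0, 0), (0.0, 0.1, 1.0), 511.0,
                                      geometry, model, rng)
            if len(h.processes) == 0:
                continue
            seen += 1
            assert h.processes == ["compton", "photoelectric"]
            assert h.deposits.sum() == pytest.approx(511.0, abs=1e-9)
        assert seen > 100

    def test_energy_conservation_all_topologies(self, geometry):
        rng = np.random.default_rng(6)
        for _ in range(500):
            h = sample_photon_history((0, 0, 0), (0.05, 0.02, -1.0), 511.0,
                                      geometry, rng_seed=rng)
            total = (h.deposits.sum() if len(h.deposits) else 0.0) + h.escape_kev
            assert total == pytest.approx(511.0, abs=1e-9)

    def test_vanishing_attenuation_length_hits_entry_face(self, geometry):
        model = InteractionModel(att_scale=1e-9)
        h = sample_photon_history((0, 0, 0), (0.0, 0.0, 1.0), 511.0,
                                  geometry, model, rng_seed=7)
        assert len(h.deposits) >= 1
        assert h.positions[0][2] == pytest.approx(geometry.panel_separation / 2.0,
                                                  abs=1e-6)

    def test_ray_missing_panels_raises(self, geometry):
        with pytest.raises(ValueError):
            sample_photon_history((0, 0, 0), (1.0, 0.0, 0.001), 511.0, geometry)


class TestGenerateDecays:
    def test_determinism(self, geometry, source):
        h1, _ = generate_decays(geometry, source, 2_000, rng_seed=11)
        h2, _ = generate_decays(geometry, source, 2_000, rng_seed=11)
        assert h1.equals(h2)

    def test_positions_inside_crystals(self, geometry, source, truth_run):
        hits, _ = truth_run
        pts = hits[["x_mm", "y_mm", "z_mm"]].to_numpy()
        assert np.all(geometry.contains(pts))
        assert np.array_equal(hits["panel"].to_numpy(),
                              geometry.panel_of(pts))

    def test_pair_rays_antiparallel_through_source(self, geometry, source):
        hits, _ = generate_decays(geometry, source, 20_000, rng_seed=12)
        first = hits[hits["interaction_index"] == 0]
        a = first[first["photon_id"] == "annih_A"].set_index("event_id")
        b = first[first["photon_id"] == "annih_B"].set_index("event_id")
        shared = a.index.intersection(b.index)
        va = a.loc[shared, ["x_mm", "y_mm", "z_mm"]].to_numpy()
        vb = b.loc[shared, ["x_mm", "y_mm", "z_mm"]].to_numpy()
        cos = np.sum(va * vb, axis=1) / (
            np.linalg.norm(va, axis=1) * np.linalg.norm(vb, axis=1))
        ang = np.degrees(np.arccos(np.clip(cos, -1, 1)))
        # 0.1 mm source jitter over ~100 mm flight paths: < ~0.25 deg
        assert np.all(ang > 179.5)

    def test_lor_acceptance_matches_solid_angle(self, geometry, truth_run):
        """Logged acceptance vs the analytic rectangle solid angle."""
        _, info = truth_run
        z = geometry.panel_separation / 2.0
        a, b = geometry.half_x, geometry.half_y
        omega = 4.0 * np.arctan(a * b / (z * np.sqrt(z * z + a * a + b * b)))
        expected = omega / (2.0 * np.pi)  # LOR folded onto one hemisphere
        n = info["n_decays"]
        sigma = np.sqrt(expected * (1 - expected) / info["lor_trials"]) / expected
        assert info["lor_acceptance"] == pytest.approx(
            expected, rel=max(3.0 * sigma, 1e-3))
        # prompt hits either panel: same fraction of the full sphere
        assert info["prompt_acceptance"] == pytest.approx(expected, rel=0.02)

    def test_entangled_truth_dphi_matches_density(self, truth_run):
        """Ground-truth azimuthal differences of pairs in which both photons
        Compton-scatter follow the entangled conditional c0 + c1 sin^2."""
        _, info = truth_run
        tr = info["_truth"]
        th1, th2 = tr["theta"]
        ph1, ph2 = tr["phi"]
        ra = tr["results"]["annih_A"]
        rb = tr["results"]["annih_B"]
        # selection independent of phi: first interaction detected + Compton
        sel = ra["isC1"] & rb["isC1"]
        assert sel.sum() > 100_000
        d = np.abs(ph1[sel] - ph2[sel]) % 360.0
        d = np.where(d > 180.0, 360.0 - d, d)
        counts, edges = np.histogram(d, bins=18, range=(0.0, 180.0))
        # oracle: expected bin mass from the exact conditional per pair
        t1 = np.radians(th1[sel])
        t2 = np.radians(th2[sel])
        k1 = 1.0 / (2.0 - np.cos(t1)); g1 = k1 + 1.0 / k1
        k2 = 1.0 / (2.0 - np.cos(t2)); g2 = k2 + 1.0 / k2
        s1, s2 = np.sin(t1) ** 2, np.sin(t2) ** 2
        c0 = g1 * g2 - g1 * s2 - g2 * s1
        c1 = 2.0 * s1 * s2
        grid = np.radians((edges[:-1] + edges[1:]) / 2.0)
        width = np.radians(np.diff(edges))
        dens = c0[:, None] + c1[:, None] * np.sin(grid[None, :]) ** 2
        dens /= dens.sum(axis=1, keepdims=True)
        expected = dens.sum(axis=0) * counts.sum() / sel.sum()
        chi2 = np.sum((counts - expected) ** 2 / expected)
        assert stats.chi2.sf(chi2, df=len(counts) - 1) > 0.01

    def test_independent_mode_dphi_flat(self, geometry, source):
        _, info = generate_decays(geometry, source, 150_000, mode="independent",
                                  rng_seed=77, _return_truth=True)
        tr = info["_truth"]
        ph1, ph2 = tr["phi"]
        ra = tr["results"]["annih_A"]
        rb = tr["results"]["annih_B"]
        sel = ra["isC1"] & rb["isC1"]
        assert sel.sum() > 50_000
        d = np.abs(ph1[sel] - ph2[sel]) % 360.0
        d = np.where(d > 180.0, 360.0 - d, d)
        counts, _ = np.histogram(d, bins=18, range=(0.0, 180.0))
        assert stats.chisquare(counts).pvalue > 0.01

    def test_staged_fast_path_emits_only_complete_groups(
            self, geometry, source):
        """only_complete_groups emits decays whose three photons each have
        exactly two interactions, at a survival rate statistically
        compatible with the unstaged stream."""
        fast, fi = generate_decays(geometry, source, 60_000, rng_seed=13,
                                   only_complete_groups=True)
        counts = fast.groupby(["event_id", "photon_id"]).size().unstack(fill_value=0)
        assert counts.shape[1] == 3
        assert np.all(counts.to_numpy() == 2)
        full, gi = generate_decays(geometry, source, 60_000, rng_seed=14)
        p_full = gi["complete_groups"] / gi["n_decays"]
        p_fast = fi["complete_groups"] / fi["n_decays"]
        sigma = np.sqrt(2 * p_full * (1 - p_full) / 60_000)
        assert abs(p_fast - p_full) < 4.0 * sigma

    def test_topology_counts_logged(self, truth_run):
        _, info = truth_run
        for pid in ("prompt", "annih_A", "annih_B"):
            assert set(info["topology_counts"][pid]) <= {0, 1, 2}
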