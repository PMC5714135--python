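"""Synthetic renderer: worm-like chains, height maps, movie frames."""

import math

import numpy as np
import pytest

import recascan as rs
from recascan.afm_synth import generate_movie, generate_wlc, render_field
from recascan.kinetic_model import SYN, BoundFilament
from recascan.kinetics import radius_of_gyration

from conftest import SUITE_SEED


class TestGenerateWlc:
    def test_arc_length_exact(self, image_config):
        poly = generate_wlc(890, image_config, seed=1)
        arc = np.hypot(*np.diff(poly, axis=0).T).sum()
        assert arc == pytest.approx(890 * 0.34, rel=1e-6)

    def test_rigid_limit_is_straight(self):
        cfg = rs.ImageConfig(persistence_length_nm=float("inf"))
        poly = generate_wlc(890, cfg, seed=2)
        end_to_end = np.linalg.norm(poly[-1] - poly[0])
        assert end_to_end == pytest.approx(890 * 0.34, rel=1e-6)

    def test_mean_squared_end_to_end_matches_2d_closed_form(self, image_config):
        """<R^2> = 4PL[1 - (2P/L)(1 - exp(-L/2P))] for the 2D worm-like
        chain, Monte Carlo over 2000 chains within 5%."""
        rng = np.random.default_rng(SUITE_SEED)
        P = image_config.persistence_length_nm
        L = 890 * image_config.rise_nm_per_bp
        r2 = [
            np.sum(
                (lambda p: p[-1] - p[0])(
                    generate_wlc(890, image_config, rng=rng)
                )
                ** 2
            )
            for _ in range(2000)
        ]
        expected = 4 * P * L * (1 - (2 * P / L) * (1 - math.exp(-L / (2 * P))))
        assert np.mean(r2) == pytest.approx(expected, rel=0.05)

    def test_too_short_rejected(self, image_config):
        with pytest.raises(ValueError):
            generate_wlc(1, image_config, seed=0)


def _one_molecule_snapshot(joints=()):
    return rs.PopulationSnapshot(0.0, [list(joints)], 1.0, 0)


class TestRenderField:
    def test_empty_snapshot_is_pure_noise(self, image_config):
        cfg = image_config.replace(frame_px=256)
        empty = rs.PopulationSnapshot(0.0, [], 1.0, 0)
        image, truth = render_field(empty, cfg, seed=3)
        assert truth.molecules == []
        assert abs(float(np.mean(image))) < 0.02
        assert float(np.std(image)) == pytest.approx(cfg.noise_sd_nm, rel=0.1)

    def test_bare_molecule_peak_close_to_dna_height(self, quiet_config):
        image, _ = render_field(_one_molecule_snapshot(), quiet_config, seed=4)
        peak = float(image.max())
        assert peak <= quiet_config.dna_height_nm * 1.01
        assert peak >= quiet_config.dna_height_nm * 0.8  # blur loss <= 20%

    def test_filament_is_local_maximum_at_its_arc_position(self, quiet_config):
        snap = _one_molecule_snapshot([BoundFilament(360, SYN, 0.0)])
        image, truth = render_field(snap, quiet_config, seed=5)
        assert float(image.max()) >= 3 * quiet_config.dna_height_nm
        # ground truth: filament centre sits at arc (360+30)*0.34 from one end
        mol = truth.molecules[0]
        arc_mid = (360 + 30) * quiet_config.rise_nm_per_bp
        d = np.hypot(*np.diff(mol.vertices_nm, axis=0).T)
        arc = np.concatenate([[0.0], np.cumsum(d)])
        centre = mol.vertices_nm[int(np.argmin(np.abs(arc - arc_mid)))]
        peak_rc = np.unravel_index(int(np.argmax(image)), image.shape)
        peak_nm = np.array([peak_rc[1], peak_rc[0]]) * quiet_config.pixel_nm
        assert np.linalg.norm(peak_nm - centre) < 20.0

    def test_ground_truth_records_geometry(self, image_config, params37):
        snaps = rs.simulate_population(params37, 6, [600.0], seed=6)
        image, truth = render_field(snaps[0], image_config, seed=7)
        assert len(truth.molecules) == 6
        for m in truth.molecules:
            assert m.contour_length_nm == pytest.approx(890 * 0.34, rel=0.01)
            assert len(m.filaments) == len(snaps[0].molecules[m.molecule_id])

    def test_determinism(self, image_config, params37):
        snap = rs.simulate_population(params37, 4, [600.0], seed=8)[0]
        a, _ = render_field(snap, image_config, seed=9)
        b, _ = render_field(snap, image_config, seed=9)
        assert np.array_equal(a, b)

    def test_height_ordering_before_noise(self, quiet_config):
        snap = _one_molecule_snapshot([BoundFilament(500, SYN, 0.0)])
        image, _ = render_field(snap, quiet_config, seed=10)
        # filament features strictly higher than bare-DNA features
        assert float(image.max()) > 3 * quiet_config.dna_height_nm
        assert float(image.max()) <= quiet_config.filament_height_nm * 1.05


class TestGenerateMovie:
    def test_initial_radius_matches_gaussian_cloud(self, image_config):
        """Rg of a 2D Gaussian cloud is sigma*sqrt(2) (large n)."""
        frames, truth = generate_movie(
            400, 94.0, [0.0], image_config, seed=11, jitter_nm=0.0
        )
        rg = radius_of_gyration(truth.frame_centroids_nm[0])
        expected = image_config.cluster_sigma0_nm * math.sqrt(2.0)
        assert rg == pytest.approx(expected, rel=3.0 / math.sqrt(400))

    def test_infinite_tau_is_time_invariant(self, image_config):
        frames, truth = generate_movie(
            12, float("inf"), [0.0, 50.0, 100.0], image_config,
            seed=12, jitter_nm=0.0,
        )
        r = [radius_of_gyration(c) for c in truth.frame_centroids_nm]
        assert r[0] == pytest.approx(r[1]) == pytest.approx(r[2])

    def test_radius_grows_exponentially(self, image_config):
        frames, truth = generate_movie(
            12, 94.0, [0.0, 94.0, 188.0], image_config, seed=13,
            jitter_nm=0.0,
        )
        r = [radius_of_gyration(c) for c in truth.frame_centroids_nm]
        assert r[1] / r[0] == pytest.approx(math.e, rel=0.02)
        assert r[2] / r[1] == pytest.approx(math.e, rel=0.02)

    def test_frames_shape_and_determinism(self, image_config):
        times = [0.0, 20.0, 40.0]
        a, ta = generate_movie(5, 94.0, times, image_config, seed=14)
        b, tb = generate_movie(5, 94.0, times, image_config, seed=14)
        assert a.shape == (3, image_config.frame_px, image_config.frame_px)
        assert np.array_equal(a, b)
        for ca, cb in zip(ta.frame_centroids_nm, tb.frame_centroids_nm):
            assert np.array_equal(ca, cb)

    def test_too_few_filaments_rejected(self, image_config):
        with pytest.raises(ValueError):
            generate_movie(2, 94.0, [0.0, 1.0, 2.0], image_config, seed=0)
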