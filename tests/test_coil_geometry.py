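"""Coiled-coil profile estimators against closed-form and generator oracles."""

import math

import numpy as np
import pytest

from conftest import random_rotation
from ifdimer.coil_geometry import (
    MajorAxis, compute_central_axis, compute_helix_axis, compute_hinge_angle,
    compute_local_pitch, compute_local_radius, compute_major_axis,
    compute_profile, compute_rotation_angle,
)
from ifdimer.structure_io import ChainStructure, DimerStructure, Residue
from ifdimer.synthetic_data import (
    CrickParams, NoiseSpec, generate_alpha_helix, generate_crick_coil,
    perturb_ensemble,
)


def straight_chain(label, x, n=20, dz=1.5):
    """Cα stacked along z at fixed (x, 0) — a degenerate straight 'helix'
    stand-in built as a very thin helix for axis estimation."""
    h = generate_alpha_helix(n, axis=(0, 0, 1), origin=(x, 0, 0))
    return ChainStructure(label, h.residues)


class TestHelixAxis:
    def test_ideal_helix_axis_on_true_axis(self):
        h = generate_alpha_helix(50, axis=(0, 0, 1))
        path = compute_helix_axis(h)
        pts = np.array([path[i] for i in path.indices()])
        assert np.max(np.linalg.norm(pts[:, :2], axis=1)) <= 0.05
        assert len(path.indices()) == 50 - 3

    def test_rigid_transform_equivariance(self, rng):
        h = generate_alpha_helix(30)
        R = random_rotation(rng)
        t = np.array([5.0, -3.0, 12.0])
        moved = DimerStructure([h]).transformed(R, t).chains[0]
        p1 = compute_helix_axis(h)
        p2 = compute_helix_axis(moved)
        for i in p1.indices():
            np.testing.assert_allclose(R @ p1[i] + t, p2[i], atol=1e-6)

    def test_noisy_helix_axis_tolerance(self):
        h = generate_alpha_helix(60)
        ens = perturb_ensemble(DimerStructure([h]), 1, NoiseSpec(0.1, seed=4))
        noisy = ens.frames[0].chains[0]
        path = compute_helix_axis(noisy)
        pts = np.array([path[i] for i in path.indices()])
        assert np.max(np.linalg.norm(pts[:, :2], axis=1)) <= 0.3

    def test_short_range_rejected(self):
        h = generate_alpha_helix(10)
        with pytest.raises(ValueError, match="4 residues"):
            compute_helix_axis(h, 1, 3)


class TestCentralAxis:
    def test_identity(self):
        h = generate_alpha_helix(20)
        p = compute_helix_axis(h)
        c = compute_central_axis(p, p)
        for i in c:
            np.testing.assert_allclose(c[i], p[i])

    def test_symmetry_of_offset_helices(self):
        a = compute_helix_axis(straight_chain("K1", -5.0))
        b = compute_helix_axis(straight_chain("K10", +5.0))
        c = compute_central_axis(a, b)
        for i in c:
            assert abs(c[i][0]) <= 1e-9

    def test_crick_central_axis_near_superhelical_axis(self, reference_coil):
        a = compute_helix_axis(reference_coil.chain("K1"))
        b = compute_helix_axis(reference_coil.chain("K10"))
        c = compute_central_axis(a, b)
        # generator's superhelical axis is the z-axis
        for i in c:
            assert np.linalg.norm(c[i][:2]) <= 0.2

    def test_empty_overlap_rejected(self):
        h = generate_alpha_helix(20)
        from ifdimer.coil_geometry import AxisPath
        a = AxisPath("A", {1: np.zeros(3)})
        b = AxisPath("B", {5: np.ones(3)})
        with pytest.raises(ValueError, match="overlap"):
            compute_central_axis(a, b)


class TestLocalRadius:
    def test_parallel_helices_half_separation(self):
        a = compute_helix_axis(straight_chain("K1", -5.0))
        b = compute_helix_axis(straight_chain("K10", +5.0))
        c = compute_central_axis(a, b)
        R = compute_local_radius(a, b, c)
        for v in R.values():
            assert v == pytest.approx(5.0, abs=0.05)

    def test_coincident_paths_zero(self):
        h = generate_alpha_helix(20)
        p = compute_helix_axis(h)
        c = compute_central_axis(p, p)
        R = compute_local_radius(p, p, c)
        assert all(v == pytest.approx(0.0, abs=1e-9) for v in R.values())

    def test_crick_mean_radius(self, reference_coil):
        prof = compute_profile(reference_coil.chain("K1"),
                               reference_coil.chain("K10"))
        assert prof.mean_radius() == pytest.approx(5.0, rel=0.02)


class TestRotationAngle:
    def test_parallel_chains_zero(self):
        a = compute_helix_axis(straight_chain("K1", -5.0, n=30))
        b = compute_helix_axis(straight_chain("K10", +5.0, n=30))
        c = compute_central_axis(a, b)
        mid = sorted(c)[len(c) // 2]
        psi = compute_rotation_angle(a, b, c, mid)
        assert abs(psi) <= 0.01

    def test_crick_psi_matches_rise_over_pitch(self, reference_coil):
        """|Ψ| per residue = 360° · (arc rise / turn length): for r0 = 5,
        pitch = 170, rise 1.51 the closed form gives 3.144°."""
        prof = compute_profile(reference_coil.chain("K1"),
                               reference_coil.chain("K10"))
        turn_len = math.hypot(170.0, 2 * math.pi * 5.0)
        expected = 360.0 * 1.51 / turn_len
        psis = [abs(v) for v in prof.psi.values() if v is not None]
        assert np.mean(psis) == pytest.approx(expected, rel=0.05)
        # left-handed: negative sign
        assert all(v < 0 for v in prof.psi.values() if v is not None)

    def test_mirror_image_flips_sign(self, reference_coil):
        mirror = DimerStructure([
            ChainStructure(c.label, [
                Residue(r.name, r.number,
                        {a: p * np.array([-1.0, 1.0, 1.0]) for a, p in r.atoms.items()})
                for r in c.residues
            ])
            for c in reference_coil.chains
        ])
        p1 = compute_profile(reference_coil.chain("K1"), reference_coil.chain("K10"))
        p2 = compute_profile(mirror.chain("K1"), mirror.chain("K10"))
        for i in p1.psi:
            if p1.psi[i] is not None and p2.psi.get(i) is not None:
                assert p2.psi[i] == pytest.approx(-p1.psi[i], abs=1e-6)
                # magnitudes of R and λ unchanged under reflection
                assert p2.radius[i] == pytest.approx(p1.radius[i], abs=1e-9)


class TestLocalPitch:
    def test_crick_pitch_recovered(self, reference_coil):
        prof = compute_profile(reference_coil.chain("K1"),
                               reference_coil.chain("K10"))
        assert prof.mean_pitch() == pytest.approx(170.0, rel=0.05)

    def test_near_parallel_indeterminate(self):
        central = {0: np.zeros(3), 1: np.array([0, 0, 1.5]), 2: np.array([0, 0, 3.0])}
        assert compute_local_pitch(central, 0.2, 1) is None
        assert compute_local_pitch(central, None, 1) is None

    def test_doubling_pitch_doubles_recovery(self):
        means = []
        for pitch in (120.0, 240.0):
            coil = generate_crick_coil(CrickParams(
                r0=5.0, superhelical_pitch=pitch, n_residues=80))
            prof = compute_profile(coil.chain("K1"), coil.chain("K10"))
            means.append(prof.mean_pitch())
        assert means[1] / means[0] == pytest.approx(2.0, rel=0.05)


class TestParameterRecoverySweep:
    @pytest.mark.parametrize("r0", [3.0, 8.0])
    @pytest.mark.parametrize("pitch", [100.0, 300.0])
    @pytest.mark.parametrize("handedness", ["left", "right"])
    def test_full_recovery(self, r0, pitch, handedness):
        """Radius within 2%, pitch within 5%, handedness exact on every
        interior residue, across the physiological parameter range."""
        coil = generate_crick_coil(CrickParams(
            r0=r0, superhelical_pitch=pitch, handedness=handedness,
            n_residues=100))
        prof = compute_profile(coil.chain("K1"), coil.chain("K10"))
        assert prof.mean_radius() == pytest.approx(r0, rel=0.02)
        assert prof.mean_pitch() == pytest.approx(pitch, rel=0.05)
        interior = prof.indices()[2:-2]
        for i in interior:
            if i in prof.handedness:
                assert prof.handedness[i] == handedness


class TestMajorAxisAndHinge:
    def test_straight_coil_along_y(self):
        coil = generate_crick_coil(CrickParams(
            r0=4.0, superhelical_pitch=1e6, n_residues=40))
        rot = np.array([[1.0, 0, 0], [0, 0, 1.0], [0, -1.0, 0]])  # z -> +y
        coil = coil.transformed(rot, np.zeros(3))
        a = compute_helix_axis(coil.chain("K1"))
        b = compute_helix_axis(coil.chain("K10"))
        c = compute_central_axis(a, b)
        axis = compute_major_axis(c)
        np.testing.assert_allclose(axis.vector, [0, 1, 0], atol=1e-6)

    def test_reversed_order_flips_sign(self):
        central = {i: np.array([0.0, 0.0, float(i)]) for i in range(10)}
        fwd = compute_major_axis(central)
        rev = compute_major_axis({i: central[9 - i] for i in range(10)})
        np.testing.assert_allclose(fwd.vector, -rev.vector, atol=1e-12)

    def test_bent_coil_axis_is_chord(self):
        """Two straight halves meeting at 150°: the major axis follows the
        chord between the anchor points, not either half."""
        half1 = [np.array([0.0, 0.0, float(i)]) for i in range(10)]
        ang = math.radians(30)  # 150° interior angle
        d = np.array([0.0, math.sin(ang), math.cos(ang)])
        half2 = [half1[-1] + d * (i + 1) for i in range(10)]
        central = {i: p for i, p in enumerate(half1 + half2)}
        axis = compute_major_axis(central)
        chord = central[19] - central[0]
        chord /= np.linalg.norm(chord)
        np.testing.assert_allclose(axis.vector, chord, atol=1e-12)

    @pytest.mark.parametrize("v,interior", [
        ((0, 0, 1), 0.0),
        ((0, 1, 0), 90.0),
        ((0, 0, -1), 180.0),
    ])
    def test_hinge_conventions(self, v, interior):
        u = MajorAxis(np.array([0.0, 0.0, 1.0]), np.zeros(3), np.array([0.0, 0.0, 1.0]))
        w = MajorAxis(np.array(v, dtype=float), np.zeros(3), np.array(v, dtype=float))
        assert compute_hinge_angle(u, w) == pytest.approx(interior, abs=1e-9)
        assert compute_hinge_angle(u, w, convention="paper") == \
            pytest.approx(360.0 - interior, abs=1e-9)
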