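"""Torsion, displacement, segment-motion, aperture and coupling metrics."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from ctsdyn import metrics, structure as st, synthetic as syn


def helix_trace(n=12, rise=1.5, twist_deg=100.0, radius=2.3):
    t = np.arange(n)
    w = np.radians(twist_deg)
    return np.c_[radius * np.cos(w * t), radius * np.sin(w * t), rise * t]


class TestTorsions:
    def test_extended_builder_output(self):
        coords = np.array([[0.0, 0, 0], [1.458, 0, 0], [2.0, 1.4, 0.2]])
        base = st.make_structure(coords, ["A"] * 3, [1] * 3,
                                 res_names=["GLY"] * 3,
                                 atom_names=["N", "CA", "C"])
        out = st.append_tail(base, "A", "GGMG")
        tors = metrics.backbone_torsions(out, "A")
        for rid in (2, 3, 4):
            assert tors[rid][0] == pytest.approx(-120.0, abs=0.5)
            assert tors[rid][1] == pytest.approx(120.0, abs=0.5)
        # chain termini: no phi for first residue, no psi for last
        assert tors[1][0] is None
        assert tors[5][1] is None

    def test_sign_flips_under_mirror(self):
        coords = np.array([[0.0, 0, 0], [1.458, 0, 0], [2.0, 1.4, 0.2]])
        base = st.make_structure(coords, ["A"] * 3, [1] * 3,
                                 res_names=["GLY"] * 3,
                                 atom_names=["N", "CA", "C"])
        out = st.append_tail(base, "A", "GGG")
        mirrored = st.Structure(out.atoms.copy())
        mirrored.atoms.coord = out.atoms.coord * [1, 1, -1]
        t1 = metrics.backbone_torsions(out, "A")
        t2 = metrics.backbone_torsions(mirrored, "A")
        phi1, _ = t1[2]
        phi2, _ = t2[2]
        assert phi2 == pytest.approx(-phi1, abs=1e-6)


class TestVirtualAlpha:
    def test_planar_zigzag_is_180(self):
        zig = np.array([[0, 0, 0], [1, 1, 0], [2, 0, 0], [3, 1, 0.0]])
        assert abs(metrics.virtual_alpha_torsion(zig)[1]) == pytest.approx(
            180.0, abs=1e-9)

    def test_ideal_helix_constant_positive(self):
        alpha = metrics.virtual_alpha_torsion(helix_trace())
        interior = alpha[1:-2]
        assert np.all(interior > 0)
        assert interior.std() < 1e-6
        assert interior[0] == pytest.approx(50.0, abs=2.0)

    def test_three_residues_all_undefined(self):
        out = metrics.virtual_alpha_torsion(np.zeros((3, 3)))
        assert np.isnan(out).all()

    def test_chain_break_splits_series(self):
        trace = helix_trace(10)
        trace[5:] += 50.0  # break between residues 4 and 5
        alpha = metrics.virtual_alpha_torsion(trace)
        assert np.isnan(alpha[4]) and np.isnan(alpha[5])


class TestFluctuationProfile:
    def test_constant_path_all_zero(self, ring_and_info):
        ring, info = ring_and_info
        cmap = metrics.ChainMap.from_structure(ring)
        frames = np.repeat(ring.ca_coords()[None], 4, axis=0)
        prof = metrics.fluctuation_profile(frames, cmap)
        assert np.abs(prof.d_ca).max() < 1e-9
        ok = ~np.isnan(prof.d_alpha)
        assert np.abs(prof.d_alpha[ok]).max() < 1e-6

    def test_motion_confined_to_moving_segment(self, ring_and_info):
        # measured in the frame of the static equatorial base, motion
        # stays confined to the planted moving set
        ring, info = ring_and_info
        cmap = metrics.ChainMap.from_structure(ring)
        base = ring.ca_coords()
        frames = [base]
        moving = info.all_indices(info.tail)
        for k in (1, 2, 3):
            f = base.copy()
            f[moving] += [0, 0, 1.5 * k]
            frames.append(f)
        prof = metrics.fluctuation_profile(
            np.array(frames), cmap,
            selection=info.all_indices(info.equatorial))
        tail_mean = prof.d_ca[info.tail].mean()
        body = np.setdiff1d(np.arange(info.n_per_chain), info.tail)
        assert prof.d_ca[body].max() < 1e-9
        assert tail_mean > 1.0
        assert len(prof.d_ca) == info.n_per_chain

    def test_equatorial_immobile_when_only_apical_and_tail_move(
            self, ring_and_info):
        ring, info = ring_and_info
        cmap = metrics.ChainMap.from_structure(ring)
        base = ring.ca_coords()
        moving = np.concatenate([info.all_indices(info.apical),
                                 info.all_indices(info.tail)])
        frames = [base]
        for k in (1, 2):
            f = base.copy()
            f[moving] += [0, 0, 2.0 * k]
            frames.append(f)
        prof = metrics.fluctuation_profile(
            np.array(frames), cmap,
            selection=info.all_indices(info.equatorial))
        eq = prof.d_ca[info.equatorial].mean()
        moved = prof.d_ca[info.apical].mean()
        assert eq < 0.05 * moved


class TestSegmentMotion:
    def test_identical_endpoints_zero(self, ring_and_info):
        ring, info = ring_and_info
        cmap = metrics.ChainMap.from_structure(ring)
        seg = info.segment(info.tail)
        m = metrics.segment_motion(ring.ca_coords(), ring.ca_coords(),
                                   cmap, seg)
        assert m.rotation_deg == pytest.approx(0.0, abs=1e-6)
        assert m.translation_ang == pytest.approx(0.0, abs=1e-9)

    def test_planted_70deg_45ang_recovery(self, two_state):
        st_t, st_r, planted, info = two_state
        cmap = metrics.ChainMap.from_structure(st_t)
        seg = info.segment(info.tail)
        body = np.setdiff1d(np.arange(st_t.n_atoms),
                            info.all_indices(info.tail))
        m = metrics.segment_motion(st_t.ca_coords(), st_r.ca_coords(),
                                   cmap, seg, pre_superpose=body)
        assert m.rotation_deg == pytest.approx(planted["rotation_deg"],
                                               abs=1e-4)
        assert m.translation_ang == pytest.approx(
            planted["translation_ang"], abs=1e-4)

    def test_noisy_recovery_within_tolerance(self, ring_and_info):
        ring, info = ring_and_info
        _, st_r, planted = syn.make_two_state(ring, info, noise=0.1, seed=5)
        cmap = metrics.ChainMap.from_structure(ring)
        seg = info.segment(info.tail)
        body = np.setdiff1d(np.arange(ring.n_atoms),
                            info.all_indices(info.tail))
        m = metrics.segment_motion(ring.ca_coords(), st_r.ca_coords(),
                                   cmap, seg, pre_superpose=body)
        assert abs(m.rotation_deg - planted["rotation_deg"]) < 1.0
        assert abs(m.translation_ang - planted["translation_ang"]) < 0.2

    def test_rigid_transform_of_both_states_invariant(self, two_state):
        st_t, st_r, planted, info = two_state
        cmap = metrics.ChainMap.from_structure(st_t)
        seg = info.segment(info.tail)
        R = Rotation.from_rotvec([1.0, 0.3, -0.4]).as_matrix()
        a = st_t.ca_coords() @ R.T + 7.0
        b = st_r.ca_coords() @ R.T + 7.0
        body = np.setdiff1d(np.arange(st_t.n_atoms),
                            info.all_indices(info.tail))
        m = metrics.segment_motion(a, b, cmap, seg, pre_superpose=body)
        assert m.rotation_deg == pytest.approx(planted["rotation_deg"],
                                               abs=1e-4)

    def test_short_segment_rejected(self, ring_and_info):
        ring, info = ring_and_info
        cmap = metrics.ChainMap.from_structure(ring)
        with pytest.raises(ValueError):
            metrics.segment_motion(ring.ca_coords(), ring.ca_coords(), cmap,
                                   {"A": info.global_indices("A",
                                                             info.tail[:2])})


class TestAperture:
    def test_regular_ring_radius(self):
        n = 7
        theta = 2 * np.pi * np.arange(n) / n
        nodes = np.c_[10 * np.cos(theta), 10 * np.sin(theta), np.zeros(n)]
        jitter = np.c_[10.5 * np.cos(theta), 10.5 * np.sin(theta),
                       np.ones(n)]
        coords = np.vstack([nodes, jitter])
        cmap = metrics.ChainMap(
            {chr(65 + i): np.array([i, n + i]) for i in range(n)})
        ap = metrics.aperture_radius(coords[None], cmap, np.arange(n))
        assert ap[0] == pytest.approx(10.0, abs=1e-9)

    def test_node_on_axis_gives_zero(self, ring_and_info):
        ring, info = ring_and_info
        cmap = metrics.ChainMap.from_structure(ring)
        coords = ring.ca_coords().copy()
        sel = info.all_indices(info.tail)
        origin, direction = metrics.ring_axis(coords, cmap)
        coords[sel[0]] = origin
        ap = metrics.aperture_radius(coords[None], cmap, sel)
        # the axis is refit after the move, so "on axis" holds to the
        # small tilt that one displaced node induces
        assert ap[0] == pytest.approx(0.0, abs=0.1)

    def test_monotone_opening_when_tails_retract(self, ring_and_info):
        ring, info = ring_and_info
        cmap = metrics.ChainMap.from_structure(ring)
        base = ring.ca_coords()
        sel = info.all_indices(info.tail)
        frames = []
        origin, direction = metrics.ring_axis(base, cmap)
        for k in range(5):
            f = base.copy()
            rel = f[sel] - origin
            radial = rel - (rel @ direction)[:, None] * direction
            f[sel] += 0.6 * k * radial / np.linalg.norm(
                radial, axis=1, keepdims=True)
            frames.append(f)
        ap = metrics.aperture_radius(np.array(frames), cmap, sel)
        assert np.all(np.diff(ap) > 0)


class TestChainCorrelation:
    def test_symmetric_path_fully_synchronous(self, ring_and_info):
        ring, info = ring_and_info
        cmap = metrics.ChainMap.from_structure(ring)
        base = ring.ca_coords()
        cts = info.segment(info.tail)
        frames = [base]
        for k in (1, 2, 3):
            f = base.copy()
            f[info.all_indices(info.tail)] += [0, 0, 1.0 * k ** 1.3]
            frames.append(f)
        corr = metrics.cts_chain_correlation(np.array(frames), cmap, cts)
        assert np.allclose(np.diag(corr.values), 1.0)
        assert np.nanmin(corr.values) > 0.999

    def test_antiphase_chains_anticorrelated(self, ring_and_info):
        # A's tail excursion from T grows over the path while B's
        # shrinks back: their displacement series anti-correlate
        ring, info = ring_and_info
        cmap = metrics.ChainMap.from_structure(ring)
        base = ring.ca_coords()
        ia = info.global_indices("A", info.tail)
        ib = info.global_indices("B", info.tail)
        frames = [base]
        for amp_a, amp_b in ((1.0, 3.0), (2.0, 2.0), (3.0, 1.0)):
            f = base.copy()
            f[ia] += [0, 0, amp_a]
            f[ib] += [0, 0, amp_b]
            frames.append(f)
        corr = metrics.cts_chain_correlation(
            np.array(frames), cmap, {"A": ia, "B": ib})
        assert corr.values[0, 1] == pytest.approx(-1.0, abs=1e-3)

    def test_static_path_entries_reported_missing(self, ring_and_info):
        ring, info = ring_and_info
        cmap = metrics.ChainMap.from_structure(ring)
        frames = np.repeat(ring.ca_coords()[None], 3, axis=0)
        corr = metrics.cts_chain_correlation(
            frames, cmap, info.segment(info.tail))
        off = corr.values[~np.eye(len(corr.labels), dtype=bool)]
        assert np.isnan(off).all()
        assert np.allclose(np.diag(corr.values), 1.0)


class TestSegmentCoupling:
    def test_identical_segments_plus_one(self, ring_and_info):
        ring, info = ring_and_info
        cmap = metrics.ChainMap.from_structure(ring)
        base = ring.ca_coords()
        seg = info.segment(info.tail)
        frames = []
        origin, direction = metrics.ring_axis(base, cmap)
        sel = info.all_indices(info.tail)
        for k in range(4):
            f = base.copy()
            rel = f[sel] - origin
            radial = rel - (rel @ direction)[:, None] * direction
            f[sel] += 0.4 * k * radial / np.linalg.norm(
                radial, axis=1, keepdims=True)
            frames.append(f)
        assert metrics.segment_coupling(np.array(frames), cmap, seg,
                                        seg) == pytest.approx(1.0)

    def test_antagonistic_radial_motion_minus_one(self, ring_and_info):
        ring, info = ring_and_info
        cmap = metrics.ChainMap.from_structure(ring)
        base = ring.ca_coords()
        seg_a = info.segment(info.apical)
        seg_b = info.segment(info.tail)
        sel_a = info.all_indices(info.apical)
        sel_b = info.all_indices(info.tail)
        origin, direction = metrics.ring_axis(base, cmap)
        frames = []
        for k in range(4):
            f = base.copy()
            for sel, sign in ((sel_a, 1.0), (sel_b, -1.0)):
                rel = f[sel] - origin
                radial = rel - (rel @ direction)[:, None] * direction
                f[sel] += sign * 0.3 * k * radial / np.linalg.norm(
                    radial, axis=1, keepdims=True)
            frames.append(f)
        c = metrics.segment_coupling(np.array(frames), cmap, seg_a, seg_b)
        assert c == pytest.approx(-1.0, abs=1e-3)

    def test_static_segments_undefined(self, ring_and_info):
        ring, info = ring_and_info
        cmap = metrics.ChainMap.from_structure(ring)
        frames = np.repeat(ring.ca_coords()[None], 3, axis=0)
        c = metrics.segment_coupling(frames, cmap,
                                     info.segment(info.apical),
                                     info.segment(info.tail))
        assert np.isnan(c)
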