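"""Per-residue and per-segment motion metrics for chaperonin ring paths.

All metrics operate on coordinate frames (F, N, 3) plus a chain map
(chain id -> ordered node indices), so they apply equally to C-alpha
structures, ENM node sets, and transition-path trajectories.  Every
metric pre-superposes frames onto the reference (T) frame so that
rigid-body motion of the whole ring never counts as internal motion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ctsdyn.structure import Structure, kabsch_superpose

log = logging.getLogger(__name__)

CHAIN_BREAK = 4.5  # A, max consecutive C-alpha distance


def wrap_angle(deg: np.ndarray) -> np.ndarray:
    """Wrap angle differences into (-180, 180]."""
    return -((-np.asarray(deg) + 180.0) % 360.0 - 180.0)


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle in degrees, IUPAC sign convention."""
    b0 = np.asarray(p0) - np.asarray(p1)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - (b0 @ b1n) * b1n
    w = b2 - (b2 @ b1n) * b1n
    x = v @ w
    y = np.cross(b1n, v) @ w
    return float(np.degrees(np.arctan2(y, x)))


@dataclass(frozen=True)
class ChainMap:
    """Ordered node indices per chain (all chains same residue count
    for per-position averaging)."""

    chains: dict[str, np.ndarray]

    @property
    def chain_ids(self) -> list[str]:
        return list(self.chains)

    @property
    def residues_per_chain(self) -> int:
        sizes = {len(v) for v in self.chains.values()}
        if len(sizes) != 1:
            raise ValueError("chains differ in residue count")
        return sizes.pop()

    @classmethod
    def from_structure(cls, structure: Structure) -> "ChainMap":
        """C-alpha node indices per chain, in residue order."""
        atoms = structure.atoms
        ca = np.flatnonzero(atoms.atom_name == "CA")
        chains: dict[str, list[int]] = {}
        for pos, idx in enumerate(ca):
            chains.setdefault(str(atoms.chain_id[idx]), []).append(pos)
        return cls({c: np.asarray(v) for c, v in chains.items()})


def backbone_torsions(structure: Structure, chain_id: str
                      ) -> dict[int, tuple[float | None, float | None]]:
    """Standard (phi, psi) per residue; undefined at termini or where a
    backbone atom is missing (residue simply absent from the output)."""
    chain = structure.chain(chain_id)
    res_ids = sorted(set(int(r) for r in chain.res_id))
    bb = {}
    for rid in res_ids:
        res = chain[chain.res_id == rid]
        atoms = {}
        for name in ("N", "CA", "C"):
            sel = res[res.atom_name == name]
            if sel.array_length():
                atoms[name] = sel.coord[0].astype(float)
        if len(atoms) == 3:
            bb[rid] = atoms
    out: dict[int, tuple[float | None, float | None]] = {}
    for rid in res_ids:
        if rid not in bb:
            continue
        prev_ok = (rid - 1) in bb
        next_ok = (rid + 1) in bb
        phi = dihedral(bb[rid - 1]["C"], bb[rid]["N"], bb[rid]["CA"],
                       bb[rid]["C"]) if prev_ok else None
        psi = dihedral(bb[rid]["N"], bb[rid]["CA"], bb[rid]["C"],
                       bb[rid + 1]["N"]) if next_ok else None
        if phi is None and psi is None:
            continue
        out[rid] = (phi, psi)
    return out


def virtual_alpha_torsion(calphas: np.ndarray) -> np.ndarray:
    """Virtual C-alpha dihedral CA(i-1)-CA(i)-CA(i+1)-CA(i+2) assigned to
    residue i (0-based array, NaN where undefined).  Runs are split at
    chain breaks (consecutive CA > 4.5 A)."""
    ca = np.asarray(calphas, dtype=float)
    n = len(ca)
    out = np.full(n, np.nan)
    if n < 4:
        return out
    gaps = np.linalg.norm(np.diff(ca, axis=0), axis=1) > CHAIN_BREAK
    for i in range(1, n - 2):
        if gaps[i - 1] or gaps[i] or gaps[i + 1]:
            continue
        out[i] = dihedral(ca[i - 1], ca[i], ca[i + 1], ca[i + 2])
    return out


def superpose_frames(frames: np.ndarray, ref_index: int = 0,
                     selection: np.ndarray | None = None) -> np.ndarray:
    """Superpose every frame onto the reference frame (Kabsch on
    ``selection`` nodes, default all)."""
    frames = np.asarray(frames, dtype=float)
    ref = frames[ref_index]
    sel = selection if selection is not None else np.arange(frames.shape[1])
    out = np.empty_like(frames)
    for f in range(len(frames)):
        tf, _ = kabsch_superpose(frames[f][sel], ref[sel])
        out[f] = tf.apply(frames[f])
    return out


@dataclass
class FluctuationProfile:
    """RMS fluctuation vs the T frame per residue position, chain-averaged.

    ``d_alpha`` is the circular virtual-dihedral fluctuation (degrees),
    ``d_ca`` the C-alpha displacement (A); phi/psi entries are NaN for
    C-alpha-only inputs.
    """

    d_ca: np.ndarray
    d_alpha: np.ndarray
    d_phi: np.ndarray
    d_psi: np.ndarray
    n_averaged: int   # chains x frames


def fluctuation_profile(frames: np.ndarray, chain_map: ChainMap,
                        ref_index: int = 0,
                        selection: np.ndarray | None = None
                        ) -> FluctuationProfile:
    """Chain-averaged, frame-RMS fluctuations relative to the T frame.

    Frames are superposed onto the reference first -- on all nodes by
    default, or on ``selection`` (e.g. the equatorial core, so that
    displacement is measured in the frame of the static base rather
    than being smeared by the least-squares fit of the moving parts).
    Angle differences are wrapped to (-180, 180] before averaging.
    """
    frames = superpose_frames(np.asarray(frames, float), ref_index,
                              selection)
    n_res = chain_map.residues_per_chain
    chain_ids = chain_map.chain_ids
    ref = frames[ref_index]
    others = [f for f in range(len(frames)) if f != ref_index]
    if not others:
        z = np.zeros(n_res)
        nanv = np.full(n_res, np.nan)
        return FluctuationProfile(z, z.copy(), nanv, nanv.copy(), 0)

    ref_alpha = {c: virtual_alpha_torsion(ref[idx])
                 for c, idx in chain_map.chains.items()}
    dca_sq = np.zeros(n_res)
    dal_sq = np.zeros(n_res)
    al_count = np.zeros(n_res)
    for f in others:
        x = frames[f]
        dca_frame = np.zeros(n_res)
        dal_frame = np.zeros(n_res)
        al_n = np.zeros(n_res)
        for c in chain_ids:
            idx = chain_map.chains[c]
            dca_frame += np.linalg.norm(x[idx] - ref[idx], axis=1)
            alpha = virtual_alpha_torsion(x[idx])
            diff = wrap_angle(alpha - ref_alpha[c])
            ok = ~np.isnan(diff)
            dal_frame[ok] += diff[ok]
            al_n += ok
        dca_sq += (dca_frame / len(chain_ids)) ** 2
        with np.errstate(invalid="ignore"):
            mean_al = np.where(al_n > 0, dal_frame / np.maximum(al_n, 1),
                               np.nan)
        ok = ~np.isnan(mean_al)
        dal_sq[ok] += mean_al[ok] ** 2
        al_count += ok
    d_ca = np.sqrt(dca_sq / len(others))
    with np.errstate(invalid="ignore", divide="ignore"):
        d_alpha = np.where(al_count > 0,
                           np.sqrt(dal_sq / np.maximum(al_count, 1)), np.nan)
    nanv = np.full(n_res, np.nan)
    return FluctuationProfile(d_ca, d_alpha, nanv, nanv.copy(),
                              len(chain_ids) * len(others))


@dataclass
class SegmentMotion:
    """Rigid-body motion of one segment between two endpoint states."""

    rotation_deg: float
    translation_ang: float
    axis: np.ndarray
    per_chain: dict[str, tuple[float, float]]


def segment_motion(
    state_t: np.ndarray,
    state_r: np.ndarray,
    chain_map: ChainMap,
    segment: dict[str, np.ndarray],
    pre_superpose: np.ndarray | None = None,
) -> SegmentMotion:
    """Least-squares rigid motion of a segment between two states.

    After optional whole-ring pre-superposition of R onto T (on the
    ``pre_superpose`` node indices, e.g. the equatorial core), the
    segment of each chain is fitted by Kabsch; the angle comes from the
    rotation-matrix trace, the translation is the centroid shift.
    """
    state_t = np.asarray(state_t, float)
    state_r = np.asarray(state_r, float)
    if pre_superpose is not None:
        tf, _ = kabsch_superpose(state_r[pre_superpose],
                                 state_t[pre_superpose])
        state_r = tf.apply(state_r)
    per_chain = {}
    axes = []
    for c, idx in segment.items():
        if len(idx) < 3:
            raise ValueError(f"segment of chain {c} shorter than 3 residues")
        a = state_t[idx]
        b = state_r[idx]
        tf, _ = kabsch_superpose(a, b)
        per_chain[c] = (tf.angle_deg,
                        float(np.linalg.norm(b.mean(0) - a.mean(0))))
        axes.append(tf.axis)
    rot = float(np.mean([v[0] for v in per_chain.values()]))
    tra = float(np.mean([v[1] for v in per_chain.values()]))
    return SegmentMotion(rot, tra, np.mean(axes, axis=0), per_chain)


def ring_axis(coords: np.ndarray, chain_map: ChainMap
              ) -> tuple[np.ndarray, np.ndarray]:
    """Symmetry axis of a ring: the normal of the best-fit plane of the
    chain centroids (smallest principal component), through their mean."""
    cents = np.array([coords[idx].mean(axis=0)
                      for idx in chain_map.chains.values()])
    if len(cents) < 3:
        raise ValueError("need at least 3 chains to define a ring axis")
    centered = cents - cents.mean(axis=0)
    cov = centered.T @ centered
    vals, vecs = np.linalg.eigh(cov)
    if vals[1] < 1e-9 * max(vals[-1], 1.0):
        raise ValueError("degenerate ring: chain centroids nearly collinear")
    return cents.mean(axis=0), vecs[:, 0]


def _axis_distance(points: np.ndarray, origin: np.ndarray,
                   direction: np.ndarray) -> np.ndarray:
    rel = points - origin
    proj = rel @ direction
    return np.linalg.norm(rel - proj[:, None] * direction, axis=1)


def aperture_radius(frames: np.ndarray, chain_map: ChainMap,
                    base_selection: np.ndarray) -> np.ndarray:
    """Minimal radial clearance about the ring symmetry axis, per frame:
    the distance from the axis to the nearest selected atom."""
    frames = np.asarray(frames, float)
    if frames.ndim == 2:
        frames = frames[None]
    out = np.empty(len(frames))
    for f, x in enumerate(frames):
        origin, direction = ring_axis(x, chain_map)
        out[f] = _axis_distance(x[base_selection], origin, direction).min()
    return out


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa < 1e-12 or sb < 1e-12:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


@dataclass
class ChainCorrMatrix:
    labels: list[str]
    values: np.ndarray  # NaN marks undefined (zero-variance) entries


def cts_chain_correlation(frames: np.ndarray, chain_map: ChainMap,
                          cts: dict[str, np.ndarray],
                          ref_index: int = 0) -> ChainCorrMatrix:
    """Chain-pairwise synchrony of CTS motion along a path.

    Per chain, the mean C-alpha displacement of its CTS nodes versus the
    T frame (after whole-ring superposition) forms a series over the
    non-reference frames (the reference itself is identically zero and
    carries no information); entries are Pearson correlations of those
    series.  Zero-variance series give NaN entries (reported missing,
    never silently 0); the diagonal is exactly 1.
    """
    frames = np.asarray(frames, float)
    if len(frames) < 3:
        raise ValueError("need at least 3 frames for correlations")
    sup = superpose_frames(frames, ref_index)
    ref = sup[ref_index]
    labels = list(cts)
    others = [f for f in range(len(sup)) if f != ref_index]
    series = {
        c: np.array([np.linalg.norm(sup[f][idx] - ref[idx], axis=1).mean()
                     for f in others])
        for c, idx in cts.items()
    }
    n = len(labels)
    m = np.full((n, n), np.nan)
    for i in range(n):
        m[i, i] = 1.0
        for j in range(i + 1, n):
            r = _pearson(series[labels[i]], series[labels[j]])
            m[i, j] = m[j, i] = r
    return ChainCorrMatrix(labels, m)


def segment_coupling(frames: np.ndarray, chain_map: ChainMap,
                     segment_a: dict[str, np.ndarray],
                     segment_b: dict[str, np.ndarray]) -> float:
    """Pearson correlation of two segments' chain-averaged radial
    centroid coordinates along the path (NaN when either is static).

    A value of -1 is the anti-correlated apical-vs-CTS signature: one
    segment moves toward the axis while the other moves away.
    """
    frames = np.asarray(frames, float)
    if len(frames) < 3:
        raise ValueError("need at least 3 frames for coupling")

    def radial_series(segment):
        vals = np.empty(len(frames))
        for f, x in enumerate(frames):
            origin, direction = ring_axis(x, chain_map)
            per_chain = [
                _axis_distance(x[idx].mean(axis=0)[None], origin,
                               direction)[0]
                for idx in segment.values()
            ]
            vals[f] = np.mean(per_chain)
        return vals

    return _pearson(radial_series(segment_a), radial_series(segment_b))
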