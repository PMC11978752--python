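"""Two-basin mixed elastic-network potential and T -> R'' transition paths.

Two ENMs, one per endpoint conformation, are combined by exponential
(log-sum-exp) mixing::

    V_mix(x) = -(1/beta) * ln[ exp(-beta V_T(x)) + exp(-beta (V_R(x) + eps)) ]

``beta`` controls how sharply the surface follows the lower basin
(large beta -> hard minimum of the two potentials); ``eps`` offsets the
second basin and is calibrated so both basin minima sit at equal depth.
For well-separated endpoints the surface has two minima near the input
structures and a saddle point between them -- the transition state.
Because the basin energies are elastic (not globally quadratic in the
coordinates), a large conformational change can additionally create
metastable intermediates on the mixed surface, exactly as the chaperonin
ring passes through its R and R' intermediates; the path builder then
chains saddle-descent legs through those intermediates until the
endpoints are connected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.optimize

from ctsdyn.enm import EnmModel
from ctsdyn.structure import kabsch_superpose, rmsd

log = logging.getLogger(__name__)

RIGID_TOL = 1e-8
ENDPOINT_TOL = 0.5  # A RMSD, path endpoint fidelity


class SaddleConvergenceError(RuntimeError):
    def __init__(self, msg, trace=None):
        super().__init__(msg)
        self.trace = trace or []


@dataclass
class MixedPotential:
    enm_t: EnmModel
    enm_r: EnmModel
    beta: float
    eps: float = 0.0

    def __post_init__(self) -> None:
        if self.enm_t.n_nodes != self.enm_r.n_nodes:
            raise ValueError(
                f"node-count mismatch: {self.enm_t.n_nodes} vs "
                f"{self.enm_r.n_nodes}"
            )
        if self.beta <= 0:
            raise ValueError("beta must be positive")

    @property
    def n_nodes(self) -> int:
        return self.enm_t.n_nodes

    def _weights(self, x):
        a = -self.beta * self.enm_t.energy(x)
        b = -self.beta * (self.enm_r.energy(x) + self.eps)
        m = max(a, b)
        wa = np.exp(a - m)
        wb = np.exp(b - m)
        z = wa + wb
        return wa / z, wb / z, m, z

    def energy(self, x: np.ndarray) -> float:
        _, _, m, z = self._weights(x)
        return float(-(m + np.log(z)) / self.beta)

    def gradient(self, x: np.ndarray) -> np.ndarray:
        wt, wr, _, _ = self._weights(x)
        return wt * self.enm_t.gradient(x) + wr * self.enm_r.gradient(x)

    def hessian(self, x: np.ndarray) -> np.ndarray:
        wt, wr, _, _ = self._weights(x)
        gt = self.enm_t.gradient(x)
        gr = self.enm_r.gradient(x)
        dg = gt - gr
        return (wt * self.enm_t.hessian_at(x)
                + wr * self.enm_r.hessian_at(x)
                - self.beta * wt * wr * np.outer(dg, dg))

    def minimize(self, x0: np.ndarray, gtol: float = 1e-9) -> np.ndarray:
        res = scipy.optimize.minimize(
            self.energy, np.ravel(x0), jac=self.gradient,
            method="L-BFGS-B",
            options={"gtol": gtol, "ftol": 1e-15, "maxiter": 10000})
        return res.x


# ---------------------------------------------------------------------------
# string relaxation


def _relax_string(mp: MixedPotential, x_from: np.ndarray, x_to: np.ndarray,
                  n_images: int = 21, iters: int = 200) -> np.ndarray:
    """Simplified string method: steepest descent of the perpendicular
    gradient component with equal-arc-length reparametrization."""
    ts = np.linspace(0.0, 1.0, n_images)
    images = np.array([(1 - t) * x_from + t * x_to for t in ts])
    scale = max(np.linalg.norm(x_to - x_from) / n_images, 1e-9)
    for _ in range(iters):
        for i in range(1, n_images - 1):
            tau = images[i + 1] - images[i - 1]
            tau /= np.linalg.norm(tau) + 1e-300
            g = mp.gradient(images[i])
            g_perp = g - (g @ tau) * tau
            gn = np.linalg.norm(g_perp)
            if gn > 0:
                images[i] -= min(0.05, 0.2 * scale / gn) * g_perp
        seg = np.linalg.norm(np.diff(images, axis=0), axis=1)
        arc = np.concatenate([[0.0], np.cumsum(seg)])
        if arc[-1] < 1e-12:
            break
        targets = np.linspace(0.0, arc[-1], n_images)
        new_images = np.empty_like(images)
        for i, s in enumerate(targets):
            j = min(np.searchsorted(arc, s, side="right") - 1, n_images - 2)
            f = (s - arc[j]) / max(arc[j + 1] - arc[j], 1e-300)
            new_images[i] = (1 - f) * images[j] + f * images[j + 1]
        images = new_images
    return images


def _auto_beta(enm_t: EnmModel, enm_r: EnmModel, eps: float = 0.0,
               smoothing: float = 0.05) -> float:
    """Choose beta so log-sum-exp smoothing lowers the barrier by at most
    ``smoothing`` of its height (ln 2 / beta <= smoothing * barrier).

    Two stages: a provisional beta from the linear-interpolation barrier,
    then a refinement from the barrier of a coarsely relaxed string under
    the provisional mixing (the linear path badly overestimates barriers
    for large motions).
    """
    xt = enm_t.coords.ravel()
    xr = enm_r.coords.ravel()
    ts = np.linspace(0.0, 1.0, 101)
    barrier = min(
        max(enm_t.energy((1 - t) * xt + t * xr),
            enm_r.energy((1 - t) * xt + t * xr) + eps)
        for t in ts
    )
    if barrier < 1e-9:
        return 1e3  # effectively identical endpoints
    beta1 = float(np.log(2.0) / (smoothing * barrier))
    mp1 = MixedPotential(enm_t, enm_r, beta1, eps)
    images = _relax_string(mp1, xt, xr, n_images=15, iters=80)
    relaxed = max(mp1.energy(im) for im in images[1:-1])
    if relaxed < 1e-9:
        return beta1
    return float(np.log(2.0) / (smoothing * relaxed))


def build_mixed_potential(
    enm_t: EnmModel,
    enm_r: EnmModel,
    beta: float | None = None,
    eps: float | None = None,
    presuperpose: bool = True,
) -> MixedPotential:
    """Combine two endpoint ENMs into the mixed two-basin surface.

    The R'' reference is first superposed onto T (all nodes) so rigid
    body motion does not masquerade as transition.  When ``eps`` is not
    given it is calibrated so the two relaxed basin minima have equal
    mixed energy (|difference| < 1e-6).
    """
    if enm_t.n_nodes != enm_r.n_nodes:
        raise ValueError("node-count mismatch between basin models")
    if presuperpose:
        try:
            tf, _ = kabsch_superpose(enm_r.coords, enm_t.coords)
        except ValueError:   # < 3 nodes or collinear: nothing to align
            pass
        else:
            enm_r = EnmModel(tf.apply(enm_r.coords), enm_r.cutoff,
                             enm_r.spring, enm_r.gamma)
    if beta is None:
        beta = _auto_beta(enm_t, enm_r, eps or 0.0)
    mp = MixedPotential(enm_t, enm_r, beta, eps if eps is not None else 0.0)
    if eps is None:
        for _ in range(20):
            xt = mp.minimize(enm_t.coords)
            xr = mp.minimize(enm_r.coords)
            diff = mp.energy(xt) - mp.energy(xr)
            if abs(diff) < 1e-8:
                break
            mp.eps += diff
    return mp


# ---------------------------------------------------------------------------
# saddle search


def _aligned_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """RMSD after optimal rigid superposition (translation-only for
    degenerate node sets) -- basin identity must ignore rigid drift."""
    a = a.reshape(-1, 3)
    b = b.reshape(-1, 3)
    if len(a) == 2:
        # a two-node shape is its separation
        return abs(np.linalg.norm(a[1] - a[0])
                   - np.linalg.norm(b[1] - b[0])) / 2.0
    try:
        tf, fit = kabsch_superpose(a, b)
        return fit
    except ValueError:
        return rmsd(a - a.mean(0), b - b.mean(0))


def _align_onto(frames: list[np.ndarray], target: np.ndarray
                ) -> list[np.ndarray]:
    """Rigidly transform a whole leg so its first frame matches target
    (mixed energies are rigid-invariant, so this is free)."""
    first = frames[0].reshape(-1, 3)
    tgt = target.reshape(-1, 3)
    try:
        tf, _ = kabsch_superpose(first, tgt)
        return [tf.apply(f.reshape(-1, 3)).ravel() for f in frames]
    except ValueError:
        shift = (tgt.mean(0) - first.mean(0))
        return [(f.reshape(-1, 3) + shift).ravel() for f in frames]


@dataclass
class SaddleResult:
    coords: np.ndarray          # (N, 3)
    energy: float
    gradient_norm: float
    n_negative: int
    no_barrier: bool = False


def _spectral(mp: MixedPotential, x: np.ndarray):
    vals, vecs = np.linalg.eigh(mp.hessian(x))
    scale = max(abs(vals[0]), abs(vals[-1]), 1.0)
    nonrigid = np.abs(vals) > RIGID_TOL * scale
    n_neg = int(np.sum(vals < -RIGID_TOL * scale))
    return vals, vecs, nonrigid, n_neg


def _ef_step(vals, vecs, nonrigid, g):
    """Eigenvector-following step: Newton toward the nearest stationary
    point, climbing along the softest non-rigid mode when it is not yet
    unstable; rigid-body null directions are projected out."""
    gi = vecs.T @ g
    lam = vals.copy()
    nz = np.flatnonzero(nonrigid)
    if len(nz) and lam[nz[0]] > 0:
        lam[nz[0]] = -abs(lam[nz[0]])     # climb along softest mode
    step = np.zeros_like(g)
    step[nonrigid] = -gi[nonrigid] / lam[nonrigid]
    return vecs @ step


def _climb(mp: MixedPotential, x0: np.ndarray, lo: np.ndarray,
           hi: np.ndarray, max_iter: int = 4000, step: float = 0.02,
           ftol: float = 1e-2) -> np.ndarray:
    """Climbing-image relaxation: ascend the tangent (from the flanking
    string images), descend perpendicular to it.  Robustly walks the
    high-dimensional ridge down to the saddle before Newton polishing.
    The step adapts on the climbing-force norm to avoid oscillation in
    steep seam regions."""
    x = x0.copy()
    tau = hi - lo
    tau /= np.linalg.norm(tau) + 1e-300
    g = mp.gradient(x)
    f = -(g - 2.0 * (g @ tau) * tau)
    fn = np.linalg.norm(f)
    best_x, best_fn = x.copy(), fn
    for _ in range(max_iter):
        if fn < ftol:
            break
        x_new = x + min(step, 0.5 / fn) * f
        g = mp.gradient(x_new)
        f_new = -(g - 2.0 * (g @ tau) * tau)
        fn_new = np.linalg.norm(f_new)
        if fn_new > 1.5 * fn:      # overshoot: shrink and retry
            step = max(step * 0.5, 1e-6)
            continue
        x, f, fn = x_new, f_new, fn_new
        step = min(step * 1.05, 0.1)
        if fn < best_fn:
            best_x, best_fn = x.copy(), fn
    return best_x


def _refine_saddle(mp: MixedPotential, x0: np.ndarray, gtol: float,
                   max_iter: int = 300, trust0: float = 1.0
                   ) -> tuple[np.ndarray, list[float]]:
    """Trust-region eigenvector following to a stationary point."""
    x = x0.copy()
    trust = trust0
    trace = []
    for _ in range(max_iter):
        g = mp.gradient(x)
        gn = float(np.linalg.norm(g))
        trace.append(gn)
        if gn < gtol:
            return x, trace
        vals, vecs, nonrigid, _ = _spectral(mp, x)
        step = _ef_step(vals, vecs, nonrigid, g)
        sn = np.linalg.norm(step)
        if sn > trust:
            step *= trust / sn
        gn_new = np.linalg.norm(mp.gradient(x + step))
        if gn_new < gn * 1.2:
            x = x + step
            trust = min(trust * 1.3, 5.0)
        else:
            trust = max(trust * 0.5, 1e-6)
    raise SaddleConvergenceError(
        f"saddle refinement stalled at |g| = {trace[-1]:.3g} "
        f"(target {gtol})", trace)


def find_saddle(
    mp: MixedPotential,
    x_from: np.ndarray | None = None,
    x_to: np.ndarray | None = None,
    n_images: int = 21,
    string_iters: int = 200,
    gtol: float = 1e-6,
    index_reduction_rounds: int = 4,
    strict: bool = True,
) -> SaddleResult:
    """Locate a transition state between two basins of the mixed surface.

    A linear interpolation of ``n_images`` images is relaxed by the
    simplified string method; the maximum-energy interior image seeds a
    trust-region eigenvector-following refinement.  If the stationary
    point has more than one negative curvature direction (degenerate
    symmetric crossings of ring assemblies do this), the search kicks
    along the extra unstable directions and re-refines for up to
    ``index_reduction_rounds`` rounds, keeping the lowest-index result.
    """
    xt = (mp.enm_t.coords.ravel() if x_from is None
          else np.ravel(x_from).copy())
    xr = (mp.enm_r.coords.ravel() if x_to is None else np.ravel(x_to).copy())
    if rmsd(xt.reshape(-1, 3), xr.reshape(-1, 3)) < 1e-6:
        log.info("endpoint structures identical: no barrier")
        return SaddleResult(xt.reshape(-1, 3), mp.energy(xt), 0.0, 0,
                            no_barrier=True)

    images = _relax_string(mp, xt, xr, n_images, string_iters)
    energies = np.array([mp.energy(im) for im in images])
    i_max = int(np.argmax(energies[1:-1])) + 1
    x_ci = _climb(mp, images[i_max], images[i_max - 1], images[i_max + 1])
    try:
        x, trace = _refine_saddle(mp, x_ci, gtol)
    except SaddleConvergenceError:
        if strict:
            raise
        # keep the climbing-image ridge point as an approximate saddle
        gn_ci = float(np.linalg.norm(mp.gradient(x_ci)))
        log.warning("Newton polish stalled; using climbing-image saddle "
                    "approximation (|g| = %.3g)", gn_ci)
        _, _, _, n_neg = _spectral(mp, x_ci)
        return SaddleResult(x_ci.reshape(-1, 3), mp.energy(x_ci), gn_ci,
                            max(n_neg, 1))

    _, vecs, _, n_neg = _spectral(mp, x)
    rounds = 0
    while n_neg > 1 and rounds < index_reduction_rounds:
        rounds += 1
        # symmetry-breaking kick along the second unstable direction
        kick = vecs[:, 1]
        try:
            x_new, _ = _refine_saddle(mp, x + 0.5 * kick, gtol)
        except SaddleConvergenceError:
            break
        _, vecs_new, _, n_neg_new = _spectral(mp, x_new)
        if 0 < n_neg_new < n_neg:
            x, vecs, n_neg = x_new, vecs_new, n_neg_new
        else:
            break
    if n_neg == 0:
        if strict:
            raise SaddleConvergenceError(
                "refinement converged to a minimum, not a saddle")
        gn_ci = float(np.linalg.norm(mp.gradient(x_ci)))
        log.warning("refinement slid into a minimum; keeping climbing-image "
                    "saddle approximation (|g| = %.3g)", gn_ci)
        _, _, _, n_ci = _spectral(mp, x_ci)
        return SaddleResult(x_ci.reshape(-1, 3), mp.energy(x_ci), gn_ci,
                            max(n_ci, 1))
    if n_neg > 1:
        log.info("transition state is a degenerate (index-%d) stationary "
                 "point, typical of symmetric ring crossings", n_neg)
    return SaddleResult(x.reshape(-1, 3), mp.energy(x),
                        float(np.linalg.norm(mp.gradient(x))), n_neg)


# ---------------------------------------------------------------------------
# transition path


@dataclass
class TransitionPath:
    """Ordered conformations from T to R'' on the mixed surface.

    ``saddle_index`` marks the highest-energy frame (the rate-limiting
    transition state).  ``n_intermediates`` counts metastable minima the
    path passes through; it is 0 for a clean two-basin transition, in
    which case the energy profile is unimodal.
    """

    frames: np.ndarray          # (n_frames, N, 3)
    energies: np.ndarray
    progress: np.ndarray        # arc-length fraction in [0, 1], increasing
    saddle_index: int
    n_intermediates: int = 0
    no_barrier: bool = False

    def __post_init__(self) -> None:
        assert len(self.frames) == len(self.energies) == len(self.progress)


def _descend(mp: MixedPotential, x0: np.ndarray, gtol: float = 1e-4,
             max_steps: int = 50000) -> list[np.ndarray]:
    """Steepest descent with backtracking; records every accepted state
    and finishes with an L-BFGS-polished minimum."""
    x = x0.copy()
    e = mp.energy(x)
    frames = [x.copy()]
    step = 0.05
    for _ in range(max_steps):
        g = mp.gradient(x)
        gn = np.linalg.norm(g)
        if gn < gtol:
            break
        direction = -g / gn
        trial = step
        for _ in range(50):
            x_new = x + trial * direction
            e_new = mp.energy(x_new)
            if e_new < e:
                break
            trial *= 0.5
        else:
            break
        x, e = x_new, e_new
        step = min(trial * 1.5, 0.5)
        frames.append(x.copy())
    x_min = mp.minimize(x)
    if mp.energy(x_min) < e - 1e-12 or np.linalg.norm(x_min - x) > 1e-9:
        frames.append(x_min)
    return frames


def _connect(mp: MixedPotential, x_a: np.ndarray, x_b: np.ndarray,
             depth: int, max_depth: int = 3,
             join_tol: float = 0.35) -> list[list[np.ndarray]]:
    """Recursively connect two minima by saddle-descent legs.

    Returns a list of legs; each leg is an ordered list of states from
    (a neighbourhood of) one minimum over one saddle to the next.
    """
    if depth > max_depth:
        raise SaddleConvergenceError(
            f"could not connect basins within {max_depth} legs")
    n = mp.n_nodes
    saddle = find_saddle(mp, x_a, x_b, strict=False)
    xs = saddle.coords.ravel()
    vals, vecs, nonrigid, _ = _spectral(mp, xs)
    v = vecs[:, 0]
    if v @ (x_b - xs) < 0:
        v = -v
    delta = 0.25
    down_b = _descend(mp, xs + delta * v)
    down_a = _descend(mp, xs - delta * v)
    m_a, m_b = down_a[-1], down_b[-1]
    leg = list(reversed(down_a)) + [xs] + down_b
    legs: list[list[np.ndarray]] = []
    if _aligned_rmsd(m_a, x_a) > join_tol:
        legs.extend(_connect(mp, x_a, m_a, depth + 1, max_depth, join_tol))
    legs.append(leg)
    if _aligned_rmsd(m_b, x_b) > join_tol:
        legs.extend(_connect(mp, m_b, x_b, depth + 1, max_depth, join_tol))
    return legs


def _string_path(mp: MixedPotential, x_t: np.ndarray, x_r: np.ndarray,
                 n_frames: int) -> TransitionPath:
    """Fallback path: a densely relaxed string between the basin minima
    with the maximum-energy image polished by the climbing image.  Used
    when the saddle-descent cascade cannot connect the basins (rough
    multi-basin surfaces from very large conformational changes)."""
    n = mp.n_nodes
    n_images = max(2 * n_frames + 1, 61)
    images = _relax_string(mp, x_t, x_r, n_images=n_images, iters=300)
    energies = np.array([mp.energy(im) for im in images])
    i_max = int(np.argmax(energies[1:-1])) + 1
    images[i_max] = _climb(mp, images[i_max], images[i_max - 1],
                           images[i_max + 1])
    energies[i_max] = mp.energy(images[i_max])
    seg = np.linalg.norm(np.diff(images, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = max(arc[-1], 1e-300)
    targets = np.linspace(0.0, total, n_frames)
    picked = sorted({int(np.argmin(np.abs(arc - s))) for s in targets}
                    | {i_max})
    frames = images[picked].reshape(len(picked), n, 3)
    e_out = energies[picked]
    prog = arc[picked] / total
    interior = e_out[1:-1]
    n_minima = int(np.sum((interior[1:-1] < interior[:-2] - 1e-9)
                          & (interior[1:-1] < interior[2:] - 1e-9)))
    return TransitionPath(frames, e_out, prog, int(np.argmax(e_out)),
                          n_intermediates=n_minima)


def transition_path(mp: MixedPotential, n_frames: int = 50,
                    saddle: SaddleResult | None = None) -> TransitionPath:
    """Steepest-descent transition path from T to R''.

    Builds descent legs over the saddle (recursively through metastable
    intermediates when the surface has them), concatenates them, and
    resamples to ``n_frames`` visited states evenly spaced in arc length
    while always keeping every saddle as an exact frame.  If the cascade
    cannot connect the basins, a densely relaxed string with a
    climbing-image transition state is returned instead.
    """
    if saddle is not None and saddle.no_barrier:
        frames = np.repeat(saddle.coords[None], 2, axis=0)
        return TransitionPath(frames, np.array([saddle.energy] * 2),
                              np.array([0.0, 1.0]), 0, no_barrier=True)
    x_t = mp.minimize(mp.enm_t.coords)
    x_r = mp.minimize(mp.enm_r.coords)
    n = mp.n_nodes
    if rmsd(x_t.reshape(n, 3), x_r.reshape(n, 3)) < 1e-6:
        frames = np.repeat(x_t.reshape(1, n, 3), 2, axis=0)
        e = mp.energy(x_t)
        return TransitionPath(frames, np.array([e, e]),
                              np.array([0.0, 1.0]), 0, no_barrier=True)
    try:
        legs = _connect(mp, x_t, x_r, depth=0)
    except SaddleConvergenceError as exc:
        log.warning("saddle-descent cascade failed (%s); "
                    "falling back to the relaxed-string path", exc)
        return _string_path(mp, x_t, x_r, n_frames)
    n_intermediates = len(legs) - 1

    # concatenate legs, rigidly gluing each onto the end of the previous
    # one (descents drift rigidly; the mixed energy is invariant)
    seq: list[np.ndarray] = []
    for leg in legs:
        anchor = seq[-1] if seq else x_t
        leg = _align_onto(leg, anchor)
        seq.extend(leg[1:] if seq else leg)
    seq_arr = np.array(seq)
    energies = np.array([mp.energy(f) for f in seq_arr])

    seg = np.linalg.norm(np.diff(seq_arr, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = max(arc[-1], 1e-300)

    # frame selection: even arc-length targets snapped to visited states,
    # plus the global maximum (the rate-limiting saddle) kept exactly
    targets = np.linspace(0.0, total, n_frames)
    picked = sorted({int(np.argmin(np.abs(arc - s))) for s in targets}
                    | {int(np.argmax(energies))})
    frames = seq_arr[picked].reshape(len(picked), n, 3)
    e_out = energies[picked]
    prog = arc[picked] / total
    # enforce strictly increasing progress by dropping exact duplicates
    keep = np.concatenate([[True], np.diff(prog) > 1e-12])
    frames, e_out, prog = frames[keep], e_out[keep], prog[keep]
    saddle_index = int(np.argmax(e_out))
    return TransitionPath(frames, e_out, prog, saddle_index,
                          n_intermediates=n_intermediates)
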