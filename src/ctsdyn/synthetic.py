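"""Synthetic inputs with known ground truth for every pipeline stage.

Generators cover (i) MSAs evolved by a Poisson substitution process with
gamma-distributed site rates on a known tree, optionally with an
elevated-rate C-terminal region; (ii) CTS sequence sets of the three
composition classes seen across bacterial chaperonins; (iii) toy
C-alpha ring assemblies -- seven subunits of three stacked pseudo-domains
with a flexible tail pointing at the ring axis -- and two-state (T, R'')
conformational pairs with a planted rigid tail motion.  Every stochastic
output is a pure function of its seed, and every dataset returns the
ground truth needed for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ctsdyn.phylo import Msa, PhyloTree, TreeNode
from ctsdyn.structure import RigidTransform, Structure, make_structure

AA20 = "ACDEFGHIKLMNPQRSTVWY"

# planted T -> R'' tail motion defaults: the chaperonin CTS moves by an
# overall 70 degree rotation and 45 A translation between the two states
DEFAULT_ROTATION_DEG = 70.0
DEFAULT_TRANSLATION_ANG = 45.0


# ---------------------------------------------------------------------------
# trees and MSA evolution


def random_tree(n_taxa: int, seed: int = 0,
                bl_range: tuple[float, float] = (0.03, 0.15)) -> PhyloTree:
    """Random binary unrooted tree over taxa t01..tNN with uniform
    branch lengths (substitutions/site) in ``bl_range``."""
    if n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    rng = np.random.default_rng(seed)
    width = len(str(n_taxa))
    nodes = [TreeNode(name=f"t{i + 1:0{width}d}") for i in range(n_taxa)]
    for node in nodes:
        node.length = float(rng.uniform(*bl_range))
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = TreeNode(length=float(rng.uniform(*bl_range)))
        parent.children = [nodes[i], nodes[j]]
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)]
        nodes.append(parent)
    root = TreeNode()
    root.children = nodes
    return PhyloTree(root)


def evolve_msa(
    tree: PhyloTree,
    root_seq: str | int,
    shape: float = 1.0,
    tail_region: tuple[int, int] | None = None,
    tail_factor: float = 1.0,
    seed: int = 0,
) -> tuple[Msa, np.ndarray]:
    """Evolve sequences on a tree under Poisson substitution.

    Site rates are gamma(shape, mean 1); sites inside ``tail_region``
    (half-open, 0-based) are multiplied by ``tail_factor`` to emulate the
    faster-diverging CTS.  Along a branch of length b the number of
    events at site s is Poisson(rate_s * b), each event replacing the
    residue with one of the other 19 uniformly.  Returns the leaf
    alignment (gap-free) and the true site rates.
    """
    rng = np.random.default_rng(seed)
    if isinstance(root_seq, int):
        root = "".join(rng.choice(list(AA20), size=root_seq))
    else:
        root = root_seq.upper()
    n_sites = len(root)
    rates = rng.gamma(shape, 1.0 / shape, size=n_sites)
    if tail_region is not None:
        lo, hi = tail_region
        rates[lo:hi] *= tail_factor

    aa_index = {a: i for i, a in enumerate(AA20)}
    leaves: list[tuple[str, str]] = []

    def walk(node: TreeNode, seq: np.ndarray) -> None:
        seq = seq.copy()
        if node.length > 0:
            k = rng.poisson(rates * node.length)
            for site in np.flatnonzero(k):
                for _ in range(k[site]):
                    cur = seq[site]
                    repl = rng.integers(0, 19)
                    seq[site] = repl if repl < cur else repl + 1
        if node.is_leaf:
            leaves.append(
                (node.name, "".join(AA20[i] for i in seq)))
        for child in node.children:
            walk(child, seq)

    root_arr = np.array([aa_index[a] for a in root])
    for child in tree.root.children:
        walk(child, root_arr)
    leaves.sort()
    return Msa(tuple(leaves)), rates


# ---------------------------------------------------------------------------
# CTS sequence sets


def _gly_met_tail(rng) -> str:
    k = int(rng.integers(2, 6))
    tail = list("GGM" * k + "M")
    for _ in range(int(rng.integers(0, 3))):
        pos = int(rng.integers(0, len(tail)))
        tail[pos] = AA20[rng.integers(0, 20)]
    return "".join(tail)


def _his_rich_tail(rng) -> str:
    n = int(rng.integers(10, 16))
    n_his = max(int(np.ceil(0.3 * n)) + int(rng.integers(0, 3)), 4)
    n_de = int(rng.integers(1, 4))
    rest = n - n_his - n_de
    letters = (["H"] * n_his + [rng.choice(list("DE")) for _ in range(n_de)]
               + [AA20[rng.integers(0, 20)] for _ in range(max(rest, 0))])
    rng.shuffle(letters)
    return "".join(letters)


def _pattern_free_tail(rng) -> str:
    # rejection keeps the planted class honest: a pattern-free tail has
    # neither a gly-met-dominated nor a charge/His-dominated composition
    while True:
        n = int(rng.integers(10, 16))
        tail = "".join(AA20[i] for i in rng.integers(0, 20, size=n))
        gm = (tail.count("G") + tail.count("M")) / n
        his = tail.count("H") / n
        charged = sum(tail.count(a) for a in "DEKRH") / n
        if gm < 0.5 and his < 0.2 and charged < 0.35:
            return tail


def make_cts_set(n_per_class: int = 100, seed: int = 0
                 ) -> list[tuple[str, str]]:
    """Labeled synthetic tails: (class_label, tail) for the three
    composition classes (gly_met_rich / charged_his_rich / pattern_free)."""
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_per_class):
        out.append(("gly_met_rich", _gly_met_tail(rng)))
        out.append(("charged_his_rich", _his_rich_tail(rng)))
        out.append(("pattern_free", _pattern_free_tail(rng)))
    return out


# ---------------------------------------------------------------------------
# toy ring assemblies


@dataclass
class RingInfo:
    """Ground-truth layout of a synthetic ring.

    Local residue positions (0-based, identical for every chain) for the
    three stacked pseudo-domains and the tail, plus chain ids.
    """

    chain_ids: list[str]
    n_per_chain: int
    equatorial: np.ndarray
    intermediate: np.ndarray
    apical: np.ndarray
    tail: np.ndarray

    def global_indices(self, chain: str, local: np.ndarray) -> np.ndarray:
        offset = self.chain_ids.index(chain) * self.n_per_chain
        return offset + np.asarray(local)

    def segment(self, local: np.ndarray) -> dict[str, np.ndarray]:
        return {c: self.global_indices(c, local) for c in self.chain_ids}

    def all_indices(self, local: np.ndarray) -> np.ndarray:
        return np.concatenate(
            [self.global_indices(c, local) for c in self.chain_ids])


def _subunit_template(nodes_per_domain: int, tail_len: int, radius: float,
                      rng) -> tuple[np.ndarray, RingInfo]:
    """One subunit: three stacked pseudo-domain slabs forming a tall
    cavity wall (radial extent ``radius - 5`` .. ``radius + 1``) plus a
    tail descending inward toward the axis base.

    The wall is tall enough that a tail translated up the axis by the
    default planted motion stays within the default ENM cutoff of the
    apical wall nodes, keeping both endpoint networks connected.
    """
    coords = []
    xs = [radius - 5.0, radius + 1.0]
    ys = [-3.0, 3.0]
    for d in range(3):           # equatorial, intermediate, apical
        z0 = 2.0 + d * 13.0
        count = 0
        for dz in (0.0, 6.0):
            for y in ys:
                for x in xs:
                    if count >= nodes_per_domain:
                        break
                    coords.append([x, y, z0 + dz + 0.5 * ((count % 2))])
                    count += 1
    n_body = len(coords)
    # tail: from the equatorial base inward to near the axis, zigzag so
    # the segment is never collinear
    start = np.array([radius - 7.0, 0.0, -1.0])
    end = np.array([4.5, 0.0, -5.0])
    for t in range(tail_len):
        f = t / max(tail_len - 1, 1)
        p = (1 - f) * start + f * end
        p[1] += 1.2 * ((-1) ** t)
        coords.append(p)
    coords = np.array(coords)
    coords += rng.normal(0.0, 0.25, size=coords.shape)
    npd = nodes_per_domain
    info = RingInfo(
        chain_ids=[],
        n_per_chain=n_body + tail_len,
        equatorial=np.arange(0, npd),
        intermediate=np.arange(npd, 2 * npd),
        apical=np.arange(2 * npd, 3 * npd),
        tail=np.arange(n_body, n_body + tail_len),
    )
    return coords, info


def make_ring(
    n_subunits: int = 7,
    nodes_per_subunit: int = 24,
    tail_len: int = 5,
    radius: float = 16.0,
    seed: int = 0,
) -> tuple[Structure, RingInfo]:
    """Cn-symmetric C-alpha-only ring with inward-pointing tails.

    ``nodes_per_subunit`` counts the body nodes (three equal stacked
    pseudo-domains); the tail adds ``tail_len`` more per chain.  All
    chains share one jittered template, so the assembly is exactly
    Cn-symmetric.  Default geometry is connected at the default ENM
    cutoff (12 A) and the tails are the nodes nearest the axis.
    """
    if n_subunits < 3:
        raise ValueError("need at least 3 subunits")
    if nodes_per_subunit % 3:
        raise ValueError("nodes_per_subunit must be divisible by 3")
    rng = np.random.default_rng(seed)
    template, info = _subunit_template(nodes_per_subunit // 3, tail_len,
                                       radius, rng)
    chain_ids = [chr(ord("A") + i) for i in range(n_subunits)]
    coords = []
    chains = []
    res_ids = []
    for i, cid in enumerate(chain_ids):
        theta = 2 * np.pi * i / n_subunits
        c, s = np.cos(theta), np.sin(theta)
        rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        coords.append(template @ rot.T)
        chains.extend([cid] * len(template))
        res_ids.extend(range(1, len(template) + 1))
    structure = make_structure(np.vstack(coords), chains, res_ids)
    info.chain_ids = chain_ids
    return structure, info


def protomer_of(ring: Structure, ring_info: RingInfo,
                chain: str = "A") -> Structure:
    """One subunit (with its tail) cut out of a ring."""
    arr = ring.atoms[ring.atoms.chain_id == chain]
    return Structure(arr.copy())


def make_two_state(
    ring: Structure,
    ring_info: RingInfo,
    rotation_deg: float = DEFAULT_ROTATION_DEG,
    translation_ang: float = DEFAULT_TRANSLATION_ANG,
    segment: np.ndarray | None = None,
    noise: float = 0.0,
    seed: int = 0,
) -> tuple[Structure, Structure, dict]:
    """Two-state (T, R'') pair with a planted rigid tail motion.

    In the R'' state each chain's segment (default: the tail) is rotated
    by ``rotation_deg`` about an axis through its own centroid (the
    chain's radial direction) and translated ``translation_ang`` A along
    the ring axis; the transform is identical per chain up to ring
    symmetry, so the planted motion is Cn-synchronous.  Optional
    isotropic noise (sd ``noise`` A) is added to every R'' coordinate.
    """
    if segment is None:
        segment = ring_info.tail
    if len(segment) == 0:
        raise ValueError("empty moving segment")
    rng = np.random.default_rng(seed)
    state_t = ring.copy()
    coords = ring.coords.astype(float).copy()
    angle = np.radians(rotation_deg)
    for chain in ring_info.chain_ids:
        idx = ring_info.global_indices(chain, segment)
        seg = coords[idx]
        centroid = seg.mean(axis=0)
        radial = centroid - np.array([0.0, 0.0, centroid[2]])
        norm = np.linalg.norm(radial)
        axis = radial / norm if norm > 1e-9 else np.array([1.0, 0.0, 0.0])
        K = np.array([[0, -axis[2], axis[1]],
                      [axis[2], 0, -axis[0]],
                      [-axis[1], axis[0], 0]])
        R = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)
        moved = (seg - centroid) @ R.T + centroid
        moved += np.array([0.0, 0.0, translation_ang])
        coords[idx] = moved
    if noise > 0:
        coords += rng.normal(0.0, noise, size=coords.shape)
    arr = ring.atoms.copy()
    arr.coord = coords
    planted = {
        "rotation_deg": float(rotation_deg),
        "translation_ang": float(translation_ang),
        "segment": np.asarray(segment).tolist(),
        "noise": float(noise),
        "seed": int(seed),
    }
    return state_t, Structure(arr), planted
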