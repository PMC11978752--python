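"""Distance phylogenetics and conservation profiling for chaperonin MSAs.

Distances are Poisson-corrected with gamma-distributed site rates
(``d = a * ((1 - p)^(-1/a) - 1)``, shape ``a``; the chaperonin study uses
``a = 1``), computed with pairwise deletion of gapped/ambiguous sites.
Trees are built by neighbour joining with a deterministic tie-break and
bootstrapped by column resampling.  Site conservation is profiled by an
empirical-Bayes Poisson-gamma rate estimator over Fitch parsimony change
counts on the NJ tree, z-normalized so that lower scores mean stronger
conservation (mean 0, sd 1).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from Bio import AlignIO

log = logging.getLogger(__name__)

GAP = "-"
MISSING_CODES = set("-.BZX*?")


class SaturationError(ValueError):
    """Observed proportion of differences implies infinite distance."""


class NoComparableSitesError(ValueError):
    """Pairwise deletion removed every alignment column."""


class FlatProfileError(ValueError):
    """All columns have the same rate; z-normalization is undefined."""


@dataclass(frozen=True)
class Msa:
    """A protein multiple sequence alignment (gap character ``-``)."""

    records: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if len(self.records) < 2:
            raise ValueError("an MSA needs at least 2 sequences")
        lengths = {len(s) for _, s in self.records}
        if len(lengths) != 1:
            raise ValueError("aligned sequences differ in length")
        ids = [i for i, _ in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sequence ids in MSA")

    @property
    def ids(self) -> list[str]:
        return [i for i, _ in self.records]

    @property
    def n_sites(self) -> int:
        return len(self.records[0][1])

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, seq_id: str) -> str:
        for i, s in self.records:
            if i == seq_id:
                return s
        raise KeyError(seq_id)

    def to_array(self) -> np.ndarray:
        """(n_seq, n_sites) array of single characters."""
        return np.array([list(s) for _, s in self.records])

    def subset_columns(self, columns) -> "Msa":
        arr = self.to_array()[:, list(columns)]
        return Msa(
            tuple(
                (i, "".join(row)) for i, row in zip(self.ids, arr)
            )
        )

    @classmethod
    def read(cls, path) -> "Msa":
        aln = AlignIO.read(str(path), "fasta")
        return cls(
            tuple((rec.id, str(rec.seq).upper()) for rec in aln)
        )

    def write(self, path) -> None:
        with open(path, "w") as fh:
            for i, s in self.records:
                fh.write(f">{i}\n{s}\n")


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValueError("distance matrix not symmetric")
        self.values = v

    def __getitem__(self, pair):
        a, b = pair
        return self.values[self.labels.index(a), self.labels.index(b)]


# ---------------------------------------------------------------------------
# pairwise distances


def p_distance(a: str, b: str) -> tuple[float, int]:
    """Proportion of differing sites after pairwise deletion.

    Sites where either sequence carries a gap or ambiguity code are
    removed for this pair only.  Returns ``(p, n_compared)``.
    """
    if len(a) != len(b):
        raise ValueError("sequences differ in length")
    n = 0
    mismatches = 0
    for x, y in zip(a.upper(), b.upper()):
        if x in MISSING_CODES or y in MISSING_CODES:
            continue
        n += 1
        if x != y:
            mismatches += 1
    if n == 0:
        raise NoComparableSitesError("no comparable sites after pairwise deletion")
    return mismatches / n, n


def poisson_gamma_distance(p: float, shape: float = 1.0) -> float:
    """Poisson-corrected distance with gamma rate variation of shape ``a``.

    ``d = a * ((1 - p)^(-1/a) - 1)``; at ``a = 1`` this is ``p / (1 - p)``
    and the ``a -> inf`` limit recovers the plain Poisson correction
    ``-ln(1 - p)``.
    """
    if shape <= 0:
        raise ValueError("gamma shape must be positive")
    if not 0.0 <= p < 1.0:
        raise SaturationError(f"p = {p} is saturated (p >= 1) or negative")
    return shape * ((1.0 - p) ** (-1.0 / shape) - 1.0)


def msa_distance_matrix(
    msa: Msa,
    shape: float = 1.0,
    region: tuple[int, int] | None = None,
    cap: float | None = None,
) -> DistanceMatrix:
    """Corrected pairwise distances for an MSA.

    ``region`` is an optional half-open 0-based column range.  Saturated
    pairs become ``inf`` (or ``cap`` when given) with a warning rather
    than being silently clipped.
    """
    seqs = {i: s for i, s in msa.records}
    if region is not None:
        lo, hi = region
        if not (0 <= lo < hi <= msa.n_sites):
            raise ValueError(f"region {region} outside alignment width")
        seqs = {i: s[lo:hi] for i, s in seqs.items()}
    labels = msa.ids
    n = len(labels)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        p, _ = p_distance(seqs[labels[i]], seqs[labels[j]])
        try:
            dij = poisson_gamma_distance(p, shape)
        except SaturationError:
            dij = np.inf
        if not np.isfinite(dij):
            if cap is not None:
                dij = cap
            else:
                log.warning("saturated pair (%s, %s): distance set to inf",
                            labels[i], labels[j])
        d[i, j] = d[j, i] = dij
    return DistanceMatrix(labels, d)


# ---------------------------------------------------------------------------
# trees


class TreeNode:
    """Node of an (unrooted) phylogenetic tree, stored rooted at the
    final NJ trichotomy for traversal."""

    __slots__ = ("name", "length", "children", "support")

    def __init__(self, name: str = "", length: float = 0.0):
        self.name = name
        self.length = length
        self.children: list["TreeNode"] = []
        self.support: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self):
        for child in self.children:
            yield from child.postorder()
        yield self

    def leaf_names(self) -> frozenset[str]:
        return frozenset(n.name for n in self.postorder() if n.is_leaf)


@dataclass
class PhyloTree:
    root: TreeNode
    negative_branch_deficit: float = 0.0

    @property
    def leaves(self) -> frozenset[str]:
        return self.root.leaf_names()

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial bipartitions, each canonicalized as the side not
        containing the lexicographically smallest leaf."""
        all_leaves = self.leaves
        anchor = min(all_leaves)
        parts: set[frozenset[str]] = set()
        for node in self.root.postorder():
            if node is self.root or node.is_leaf:
                continue
            below = node.leaf_names()
            if 1 < len(below) < len(all_leaves) - 1:
                side = below if anchor not in below else all_leaves - below
                parts.add(side)
        return parts

    def newick(self, with_support: bool = False) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                return f"{node.name}:{node.length:.6f}"
            inner = ",".join(fmt(c) for c in node.children)
            label = ""
            if with_support and node.support is not None:
                label = f"{node.support:.0f}"
            return f"({inner}){label}:{node.length:.6f}"

        inner = ",".join(fmt(c) for c in self.root.children)
        return f"({inner});"

    def path_lengths(self) -> dict[tuple[str, str], float]:
        """Leaf-to-leaf path lengths (sums of branch lengths)."""
        dists: dict[tuple[str, str], float] = {}

        def below(node):
            # list of (leaf, distance-to-node)
            if node.is_leaf:
                return [(node.name, 0.0)]
            out = []
            groups = [
                [(leaf, d + c.length) for leaf, d in below(c)]
                for c in node.children
            ]
            for g1, g2 in itertools.combinations(groups, 2):
                for (l1, d1) in g1:
                    for (l2, d2) in g2:
                        key = tuple(sorted((l1, l2)))
                        dists[key] = d1 + d2
            for g in groups:
                out.extend(g)
            return out

        below(self.root)
        return dists


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Classic neighbour joining (Saitou-Nei).

    Labels are sorted lexicographically first and Q-matrix ties broken on
    the lowest (i, j) pair, so the result is deterministic and
    independent of input label order.  Negative branch lengths are
    clamped to zero and the total clamped deficit recorded.
    """
    order = np.argsort(np.array(dm.labels, dtype=object))
    labels = [dm.labels[i] for i in order]
    d = dm.values[np.ix_(order, order)].astype(float).copy()
    n = len(labels)
    if n < 3:
        raise ValueError("neighbour joining needs at least 3 taxa")
    if not np.all(np.isfinite(d)):
        raise ValueError("non-finite distance in matrix")

    nodes: list[TreeNode] = [TreeNode(name=l) for l in labels]
    deficit = 0.0

    def clamp(x: float) -> float:
        nonlocal deficit
        if x < 0:
            deficit += -x
            return 0.0
        return x

    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest (i, j) among ties
        qmin = q.min()
        ties = np.argwhere(np.isclose(q, qmin, rtol=0, atol=1e-12))
        i_loc, j_loc = min((min(a, b), max(a, b)) for a, b in ties)
        i, j = active[i_loc], active[j_loc]
        dij = d[i, j]
        li = 0.5 * dij + (r[i_loc] - r[j_loc]) / (2 * (m - 2))
        lj = dij - li
        parent = TreeNode()
        nodes[i].length = clamp(li)
        nodes[j].length = clamp(lj)
        parent.children = [nodes[i], nodes[j]]
        # reuse slot i for the new node
        new_d = 0.5 * (d[i, :] + d[j, :] - dij)
        d[i, :] = new_d
        d[:, i] = new_d
        d[i, i] = 0.0
        nodes[i] = parent
        active.remove(j)

    a, b, c = active
    root = TreeNode()
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    for idx, length in ((a, la), (b, lb), (c, lc)):
        nodes[idx].length = clamp(length)
        root.children.append(nodes[idx])
    if deficit > 0:
        log.info("clamped negative NJ branch lengths; total deficit %.4g",
                 deficit)
    return PhyloTree(root, negative_branch_deficit=deficit)


def nj_from_msa(msa: Msa, shape: float = 1.0,
                region: tuple[int, int] | None = None,
                cap: float | None = None) -> PhyloTree:
    return neighbor_joining(msa_distance_matrix(msa, shape, region, cap))


def bootstrap_support(
    msa: Msa,
    replicates: int = 500,
    seed: int = 0,
    shape: float = 1.0,
    cap: float | None = None,
) -> PhyloTree:
    """NJ tree with bootstrap supports from column resampling.

    Replicate ``r`` uses the ``r``-th child of ``SeedSequence(seed)``, so
    supports depend only on the seed and the alignment content, never on
    taxon order.  Replicates whose resampled alignment yields no
    comparable sites or a saturated pair are dropped and logged.
    """
    if replicates < 1:
        raise ValueError("need at least one bootstrap replicate")
    point = nj_from_msa(msa, shape=shape, cap=cap)
    target = point.bipartitions()
    counts = {bp: 0 for bp in target}
    streams = np.random.SeedSequence(seed).spawn(replicates)
    used = 0
    for ss in streams:
        rng = np.random.default_rng(ss)
        cols = rng.integers(0, msa.n_sites, size=msa.n_sites)
        rep = msa.subset_columns(cols)
        try:
            tree = nj_from_msa(rep, shape=shape, cap=cap)
        except (NoComparableSitesError, SaturationError, ValueError) as exc:
            log.warning("bootstrap replicate dropped: %s", exc)
            continue
        used += 1
        rep_parts = tree.bipartitions()
        for bp in target:
            if bp in rep_parts:
                counts[bp] += 1
    if used == 0:
        raise RuntimeError("all bootstrap replicates failed")
    anchor = min(point.leaves)
    all_leaves = point.leaves
    for node in point.root.postorder():
        if node is point.root or node.is_leaf:
            continue
        below = node.leaf_names()
        if 1 < len(below) < len(all_leaves) - 1:
            side = below if anchor not in below else all_leaves - below
            node.support = 100.0 * counts[side] / used
    return point


# ---------------------------------------------------------------------------
# parsimony, conservation, consensus


def _fitch_column(tree: PhyloTree, states: dict[str, str]) -> int:
    """Minimum number of state changes for one column (Fitch parsimony).

    Leaves with gap/ambiguity states are wildcards (any residue).
    """
    WILD = None  # sentinel: compatible with everything

    changes = 0

    def visit(node: TreeNode):
        nonlocal changes
        if node.is_leaf:
            s = states[node.name]
            return WILD if s in MISSING_CODES else frozenset(s)
        sets = [visit(c) for c in node.children]
        sets = [s for s in sets if s is not WILD]
        if not sets:
            return WILD
        inter = frozenset.intersection(*sets)
        if inter:
            return inter
        # pairwise-sequential Fitch for multifurcation at the root
        acc = sets[0]
        for s in sets[1:]:
            both = acc & s
            if both:
                acc = both
            else:
                acc = acc | s
                changes += 1
        return acc

    visit(tree.root)
    return changes


def count_substitutions(
    msa: Msa,
    region: tuple[int, int] | None = None,
    method: str = "parsimony",
    tree: PhyloTree | None = None,
) -> int:
    """Observed substitutions in an alignment (optionally a column range).

    ``parsimony`` (default): Fitch minimum change counts per column on
    the NJ tree of the alignment, summed.  ``consensus``: per column, the
    number of non-gap residues differing from the plurality residue.
    """
    if region is not None:
        lo, hi = region
        if not (0 <= lo < hi <= msa.n_sites):
            raise ValueError(f"empty or out-of-range region {region}")
        sub = msa.subset_columns(range(lo, hi))
    else:
        sub = msa
    if method == "parsimony":
        if tree is None:
            tree = nj_from_msa(msa, cap=10.0)
        arr = sub.to_array()
        ids = sub.ids
        total = 0
        for col in arr.T:
            total += _fitch_column(tree, dict(zip(ids, col)))
        return total
    if method == "consensus":
        total = 0
        for col in sub.to_array().T:
            residues = [c for c in col if c not in MISSING_CODES]
            if not residues:
                continue
            vals, counts = np.unique(residues, return_counts=True)
            total += len(residues) - counts.max()
        return total
    raise ValueError(f"unknown counting method {method!r}")


@dataclass
class ConservationProfile:
    """Per reference position: z-scaled rate (lower = conserved) and
    column coverage (non-gap sequence count)."""

    ref_id: str
    positions: np.ndarray      # 1-based positions in the ungapped reference
    scores: np.ndarray         # mean 0, sd 1
    coverage: np.ndarray
    raw_rates: np.ndarray      # posterior-mean substitution rates


def conservation_profile(msa: Msa, ref_id: str,
                         tree: PhyloTree | None = None) -> ConservationProfile:
    """Site-specific conservation mapped onto one reference sequence.

    Per-column Fitch change counts on the NJ tree are treated as Poisson
    observations of a site rate with a gamma(shape 1) prior; the
    posterior-mean rates are z-normalized so the most conserved sites get
    the lowest scores.
    """
    if ref_id not in msa.ids:
        raise KeyError(f"reference {ref_id!r} not in alignment")
    if tree is None:
        tree = nj_from_msa(msa, cap=10.0)
    arr = msa.to_array()
    ids = msa.ids
    ref_row = arr[ids.index(ref_id)]
    tree_length = sum(
        n.length for n in tree.root.postorder() if n is not tree.root
    )
    counts = np.array([
        _fitch_column(tree, dict(zip(ids, col))) for col in arr.T
    ], dtype=float)
    mean_count = counts.mean()
    # empirical-Bayes gamma(1, b) prior with prior mean = overall mean rate
    exposure = max(tree_length, 1e-9)
    b = exposure / mean_count if mean_count > 0 else exposure
    rates = (1.0 + counts) / (b + exposure)

    keep = ref_row != GAP
    positions = np.arange(1, keep.sum() + 1)
    site_rates = rates[keep]
    coverage = (arr[:, keep] != GAP).sum(axis=0)
    sd = site_rates.std()
    if sd < 1e-12:
        raise FlatProfileError(
            "all reference columns have identical rates; profile is flat"
        )
    scores = (site_rates - site_rates.mean()) / sd
    return ConservationProfile(ref_id, positions, scores, coverage, site_rates)


def consensus(msa: Msa, plurality: float = 0.5) -> str:
    """Plurality consensus: per column the most common residue when its
    fraction of all rows (gaps included in the denominator) meets the
    threshold, else ``x``.  Ties at the max count resolve alphabetically."""
    arr = msa.to_array()
    n = len(msa)
    out = []
    for col in arr.T:
        residues = sorted(c for c in col if c != GAP)
        if not residues:
            out.append("x")
            continue
        vals, counts = np.unique(residues, return_counts=True)
        best = vals[np.argmax(counts)]
        if counts.max() / n >= plurality:
            out.append(best)
        else:
            out.append("x")
    return "".join(out)
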