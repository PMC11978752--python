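"""Structure I/O, least-squares superposition, tail building, assembly.

PDB reading/writing goes through biotite; coordinates are Angstrom,
author residue numbering is preserved.  The tail builder appends
missing C-terminal residues with ideal backbone geometry in the extended
conformation and relieves steric clashes with a soft-sphere penalty --
the downstream elastic-network model is C-alpha based, so side-chain
detail is deliberately omitted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile
from scipy.spatial.transform import Rotation

log = logging.getLogger(__name__)

# ideal backbone internal coordinates (extended beta conformation)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
ANGLE_N_CA_C = 111.0
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
PHI_EXTENDED = -120.0
PSI_EXTENDED = 120.0
OMEGA_TRANS = 180.0

CLASH_CUTOFF = 2.6  # Angstrom, heavy-atom soft-sphere radius sum

AA3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


class StructureError(ValueError):
    pass


@dataclass
class Structure:
    """Thin wrapper around a biotite AtomArray."""

    atoms: struc.AtomArray

    @property
    def n_atoms(self) -> int:
        return self.atoms.array_length()

    @property
    def coords(self) -> np.ndarray:
        return self.atoms.coord

    def chains(self) -> list[str]:
        seen: list[str] = []
        for c in self.atoms.chain_id:
            if c not in seen:
                seen.append(c)
        return seen

    def chain(self, chain_id: str) -> struc.AtomArray:
        sel = self.atoms[self.atoms.chain_id == chain_id]
        if sel.array_length() == 0:
            raise StructureError(f"no chain {chain_id!r}")
        return sel

    def ca_mask(self, chain_id: str | None = None,
                res_range: tuple[int, int] | None = None) -> np.ndarray:
        m = self.atoms.atom_name == "CA"
        if chain_id is not None:
            m &= self.atoms.chain_id == chain_id
        if res_range is not None:
            lo, hi = res_range
            m &= (self.atoms.res_id >= lo) & (self.atoms.res_id <= hi)
        return m

    def ca_coords(self, chain_id: str | None = None,
                  res_range: tuple[int, int] | None = None) -> np.ndarray:
        return self.atoms.coord[self.ca_mask(chain_id, res_range)]

    def copy(self) -> "Structure":
        return Structure(self.atoms.copy())

    def transformed(self, transform: "RigidTransform") -> "Structure":
        out = self.atoms.copy()
        out.coord = transform.apply(out.coord)
        return Structure(out)


def make_structure(
    coords: np.ndarray,
    chain_ids,
    res_ids,
    res_names=None,
    atom_names=None,
    elements=None,
) -> Structure:
    """Build a Structure from arrays (defaults: CA atoms of GLY)."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    arr = struc.AtomArray(n)
    arr.coord = coords
    arr.chain_id = np.asarray(chain_ids, dtype="U4")
    arr.res_id = np.asarray(res_ids, dtype=int)
    arr.res_name = (np.asarray(res_names, dtype="U3") if res_names is not None
                    else np.full(n, "GLY", dtype="U3"))
    arr.atom_name = (np.asarray(atom_names, dtype="U6") if atom_names is not None
                     else np.full(n, "CA", dtype="U6"))
    arr.element = (np.asarray(elements, dtype="U2") if elements is not None
                   else np.full(n, "C", dtype="U2"))
    arr.hetero = np.zeros(n, dtype=bool)
    arr.ins_code = np.full(n, "", dtype="U1")
    return Structure(arr)


def read_pdb(path, model: int | None = None) -> Structure:
    """Read one model of a PDB file (1-based model index, default first)."""
    pdb = PDBFile.read(str(path))
    n_models = pdb.get_model_count()
    if model is not None and not 1 <= model <= n_models:
        raise StructureError(
            f"model {model} requested but file has {n_models} model(s)"
        )
    arr = pdb.get_structure(model=model if model is not None else 1)
    standard = ~arr.hetero
    if standard.any():
        # warn on standard residues missing CA (ENM build will fail there)
        sub = arr[standard]
        for chain in np.unique(sub.chain_id):
            csub = sub[sub.chain_id == chain]
            for rid in np.unique(csub.res_id):
                names = csub.atom_name[csub.res_id == rid]
                if "CA" not in names:
                    log.warning("chain %s residue %d has no CA", chain, rid)
    return Structure(arr)


def read_models(path) -> list[Structure]:
    """All MODELs of a (trajectory) PDB file as separate Structures."""
    pdb = PDBFile.read(str(path))
    return [Structure(pdb.get_structure(model=m))
            for m in range(1, pdb.get_model_count() + 1)]


def write_pdb(target, path) -> None:
    """Write a Structure, or a list of same-topology Structures as a
    multi-MODEL trajectory."""
    pdb = PDBFile()
    if isinstance(target, Structure):
        pdb.set_structure(target.atoms)
    else:
        frames = list(target)
        stack = struc.stack([f.atoms for f in frames])
        pdb.set_structure(stack)
    pdb.write(str(path))


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x -> R x + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-6):
            raise ValueError("rotation not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("improper rotation (det < 0)")

    @property
    def angle_deg(self) -> float:
        cos = np.clip((np.trace(self.rotation) - 1.0) / 2.0, -1.0, 1.0)
        return float(np.degrees(np.arccos(cos)))

    @property
    def axis(self) -> np.ndarray:
        rv = Rotation.from_matrix(self.rotation).as_rotvec()
        n = np.linalg.norm(rv)
        return rv / n if n > 1e-12 else np.array([0.0, 0.0, 1.0])

    @property
    def translation_norm(self) -> float:
        return float(np.linalg.norm(self.translation))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ np.asarray(self.rotation).T + self.translation

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))


def kabsch_superpose(
    mobile: np.ndarray, target: np.ndarray
) -> tuple[RigidTransform, float]:
    """Least-squares optimal proper rotation + translation of ``mobile``
    onto ``target``; returns the transform and the post-fit RMSD."""
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("coordinate sets must both be (n, 3)")
    n = len(mobile)
    if n < 3:
        raise ValueError("need at least 3 atoms to superpose")
    cm = mobile.mean(axis=0)
    ct = target.mean(axis=0)
    X = mobile - cm
    Y = target - ct
    s = np.linalg.svd(X, compute_uv=False)
    if s[1] < 1e-9 * max(s[0], 1.0):
        raise ValueError("degenerate (collinear) selection")
    H = X.T @ Y
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ct - R @ cm
    rmsd = float(np.sqrt(((mobile @ R.T + t - target) ** 2).sum() / n))
    return RigidTransform(R, t), rmsd


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    return float(np.sqrt(((a - b) ** 2).sum() / len(a)))


# ---------------------------------------------------------------------------
# tail building


def _place_atom(a, b, c, bond, angle_deg, dihedral_deg):
    """NeRF placement of atom d given three predecessors a-b-c."""
    angle = np.radians(angle_deg)
    dihedral = np.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(angle),
        bond * np.sin(angle) * np.cos(dihedral),
        bond * np.sin(angle) * np.sin(dihedral),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


class ClashError(StructureError):
    def __init__(self, pairs):
        self.pairs = pairs
        super().__init__(
            f"unrelievable clashes after relaxation cap: {pairs[:10]}"
        )


def count_clashes(coords: np.ndarray, mobile_idx: np.ndarray,
                  exclude: set[tuple[int, int]],
                  cutoff: float = CLASH_CUTOFF) -> list[tuple[int, int]]:
    """Heavy-atom pairs under the clash cutoff that involve a mobile atom."""
    pairs = []
    mobile = set(int(i) for i in mobile_idx)
    from scipy.spatial import cKDTree

    tree = cKDTree(coords)
    for i, j in tree.query_pairs(cutoff):
        if (i in mobile or j in mobile):
            key = (min(i, j), max(i, j))
            if key not in exclude:
                pairs.append(key)
    return pairs


def append_tail(
    protomer: Structure,
    chain_id: str,
    tail_seq: str,
    context: Structure | None = None,
    max_iter: int = 500,
    step: float = 0.05,
) -> Structure:
    """Append ``tail_seq`` to a chain with ideal extended backbone geometry.

    New residues get N/CA/C atoms placed by internal coordinates
    (phi = -120, psi = +120, omega = 180) and are then relaxed on a
    soft-sphere clash penalty (plus stiff bond restraints) against the
    rest of the structure (and ``context`` if given).  Pre-existing atoms
    never move.  Raises :class:`ClashError` if clashes survive the
    iteration cap.
    """
    if not tail_seq:
        raise ValueError("empty tail sequence")
    tail_seq = tail_seq.upper()
    chain = protomer.chain(chain_id)
    last_res = chain.res_id.max()
    last = chain[chain.res_id == last_res]

    def atom_of(res, name):
        sel = res[res.atom_name == name]
        if sel.array_length() == 0:
            raise StructureError(
                f"chain {chain_id} residue {last_res} lacks backbone {name}"
            )
        return sel.coord[0].astype(float)

    prev_n = atom_of(last, "N")
    prev_ca = atom_of(last, "CA")
    prev_c = atom_of(last, "C")

    new_coords = []
    new_res_ids = []
    new_res_names = []
    new_atom_names = []
    rid = int(last_res)
    for aa in tail_seq:
        rid += 1
        n_new = _place_atom(prev_n, prev_ca, prev_c,
                            BOND_C_N, ANGLE_CA_C_N, PSI_EXTENDED)
        ca_new = _place_atom(prev_ca, prev_c, n_new,
                             BOND_N_CA, ANGLE_C_N_CA, OMEGA_TRANS)
        c_new = _place_atom(prev_c, n_new, ca_new,
                            BOND_CA_C, ANGLE_N_CA_C, PHI_EXTENDED)
        for name, xyz in (("N", n_new), ("CA", ca_new), ("C", c_new)):
            new_coords.append(xyz)
            new_res_ids.append(rid)
            new_res_names.append(AA3.get(aa, "UNK"))
            new_atom_names.append(name)
        prev_n, prev_ca, prev_c = n_new, ca_new, c_new

    n_new_atoms = len(new_coords)
    new = struc.AtomArray(n_new_atoms)
    new.coord = np.asarray(new_coords)
    new.chain_id = np.full(n_new_atoms, chain_id, dtype="U4")
    new.res_id = np.asarray(new_res_ids)
    new.res_name = np.asarray(new_res_names, dtype="U3")
    new.atom_name = np.asarray(new_atom_names, dtype="U6")
    new.element = np.asarray(
        ["N" if n == "N" else "C" for n in new_atom_names], dtype="U2")
    new.hetero = np.zeros(n_new_atoms, dtype=bool)
    new.ins_code = np.full(n_new_atoms, "", dtype="U1")

    merged = Structure(protomer.atoms + new)
    if context is not None:
        env = Structure(merged.atoms + context.atoms)
    else:
        env = merged
    # indices of the mobile tail atoms inside env
    mobile = np.arange(protomer.n_atoms, protomer.n_atoms + n_new_atoms)

    coords = env.coords.astype(float).copy()
    # bonded pairs among new atoms (sequential backbone), excluded from clashes
    bonded = set()
    for k in range(n_new_atoms - 1):
        bonded.add((int(mobile[k]), int(mobile[k + 1])))
    # junction: the anchor residue's backbone is 1-3 bonds from the first
    # new residue's atoms -- never clash-counted
    anchor_mask = (env.atoms.chain_id == chain_id) & \
                  (env.atoms.res_id == last_res)
    for a in np.flatnonzero(anchor_mask):
        for b in mobile[:3]:
            bonded.add((min(int(a), int(b)), max(int(a), int(b))))
    exclude = bonded | {(min(a, b), max(a, b))
                        for a in mobile for b in mobile
                        if abs(int(a) - int(b)) <= 3 and a < b}

    # stiff bond restraints: sequence is N,CA,C,N,CA,C...
    bond_pairs = [(int(mobile[k]), int(mobile[k + 1]))
                  for k in range(n_new_atoms - 1)]
    bond_targets = [
        {("N", "CA"): BOND_N_CA, ("CA", "C"): BOND_CA_C,
         ("C", "N"): BOND_C_N}[(new_atom_names[k], new_atom_names[k + 1])]
        for k in range(n_new_atoms - 1)
    ]

    def clashes():
        return count_clashes(coords, mobile, exclude)

    for _ in range(max_iter):
        bad = clashes()
        if not bad:
            break
        grad = np.zeros_like(coords)
        for i, j in bad:
            d = coords[i] - coords[j]
            r = np.linalg.norm(d)
            if r < 1e-9:
                continue
            f = 2.0 * (CLASH_CUTOFF - r) * (d / r)
            if i in set(map(int, mobile)):
                grad[i] -= f
            if j in set(map(int, mobile)):
                grad[j] += f
        # stiff bond restraints keep geometry near ideal while relaxing
        for (i, j), r0 in zip(bond_pairs, bond_targets):
            d = coords[i] - coords[j]
            r = np.linalg.norm(d)
            g = 20.0 * (r - r0) * (d / max(r, 1e-9))
            grad[i] += g
            grad[j] -= g
        coords[mobile] -= step * grad[mobile]
    else:
        remaining = clashes()
        if remaining:
            raise ClashError(remaining)

    out = merged.atoms.copy()
    out.coord = coords[: merged.n_atoms]
    return Structure(out)


def assemble_by_superposition(
    protomer: Structure,
    reference_assembly: Structure,
    selection=None,
) -> tuple[Structure, dict[str, float]]:
    """Place one protomer copy per reference chain by superposition.

    ``selection`` maps an AtomArray to a boolean mask of shared atoms
    (default: all CA atoms).  Each copy keeps the protomer's internal
    geometry exactly and adopts the reference chain's id.  Returns the
    assembly and per-chain placement RMSDs.
    """
    if selection is None:
        selection = lambda arr: arr.atom_name == "CA"
    prot_sel = protomer.atoms[selection(protomer.atoms)]
    if prot_sel.array_length() == 0:
        raise StructureError("selection matches no protomer atoms")
    placed = []
    rmsds: dict[str, float] = {}
    for chain_id in reference_assembly.chains():
        ref_chain = reference_assembly.chain(chain_id)
        ref_sel = ref_chain[selection(ref_chain)]
        if ref_sel.array_length() != prot_sel.array_length():
            raise StructureError(
                f"selection mismatch in reference chain {chain_id}: "
                f"{ref_sel.array_length()} vs {prot_sel.array_length()} atoms"
            )
        tf, fit = kabsch_superpose(prot_sel.coord, ref_sel.coord)
        copy = protomer.atoms.copy()
        copy.coord = tf.apply(copy.coord)
        copy.chain_id = np.full(copy.array_length(), chain_id, dtype="U4")
        placed.append(copy)
        rmsds[chain_id] = fit
    assembly = placed[0]
    for arr in placed[1:]:
        assembly = assembly + arr
    return Structure(assembly), rmsds
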