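"""Atomic-model data layer.

Coordinates are in Å in a right-handed frame; residue numbering is 1-based as
in PDB records.  Models are flat arrays of atoms with chain/residue labels,
plus light annotations (secondary-structure segments, linker range) used by
the scoring and refinement layers.  Chains are classified as protein or RNA
from their residue names.

PDB reading/writing is backed by biotite; insertion codes and altlocs are not
supported and are rejected with a clear error.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as pdb_io
from scipy.spatial.transform import Rotation

__all__ = [
    "AtomicModel",
    "RigidGroupPartition",
    "PDBParseError",
    "read_pdb",
    "write_pdb",
    "ring_center",
    "backbone_rmsd",
    "superpose",
    "apply_move",
    "apply_torsion",
    "parse_selection",
]

PROTEIN_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}
RNA_RESIDUES = {"A", "C", "G", "U"}

PROTEIN_BACKBONE = ("N", "CA", "C", "O")
RNA_BACKBONE = ("P", "O5'", "C5'", "C4'", "C3'", "O3'")

# Six-membered ring atom names used for ring-centroid distances.  Purines use
# their pyrimidine-like six-ring so that all rings are comparable hexagons.
RING_ATOMS = {
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "A": ("N1", "C2", "N3", "C4", "C5", "C6"),
    "G": ("N1", "C2", "N3", "C4", "C5", "C6"),
    "C": ("N1", "C2", "N3", "C4", "C5", "C6"),
    "U": ("N1", "C2", "N3", "C4", "C5", "C6"),
}


class PDBParseError(ValueError):
    pass


@dataclass
class AtomicModel:
    """Flat atom table with per-atom labels and Nx3 coordinates (Å)."""

    serial: np.ndarray
    name: np.ndarray
    element: np.ndarray
    res_id: np.ndarray
    res_name: np.ndarray
    chain_id: np.ndarray
    coord: np.ndarray
    ss_segments: list = field(default_factory=list)  # (chain, first, last)
    linker: tuple | None = None                       # (chain, first, last)

    def __post_init__(self):
        self.coord = np.asarray(self.coord, dtype=float)
        if not np.all(np.isfinite(self.coord)):
            raise ValueError("non-finite coordinates in model")
        keys = list(zip(self.chain_id, self.res_id, self.name))
        if len(set(keys)) != len(keys):
            raise ValueError("(chain, residue, atom name) not unique")

    def __len__(self):
        return len(self.coord)

    def copy(self) -> "AtomicModel":
        return dataclasses.replace(
            self,
            coord=self.coord.copy(),
            ss_segments=list(self.ss_segments),
        )

    # -- lookups ---------------------------------------------------------

    def chain_role(self, chain: str) -> str:
        names = set(self.res_name[self.chain_id == chain])
        if names and names <= PROTEIN_RESIDUES:
            return "protein"
        if names and names <= RNA_RESIDUES:
            return "RNA"
        raise ValueError(f"chain {chain!r} has mixed or unknown residues: {sorted(names)}")

    @property
    def chain_roles(self) -> dict:
        return {c: self.chain_role(c) for c in dict.fromkeys(self.chain_id)}

    def atom_index(self, chain: str, res_id: int, name: str) -> int:
        mask = (self.chain_id == chain) & (self.res_id == res_id) & (self.name == name)
        idx = np.flatnonzero(mask)
        if len(idx) == 0:
            raise KeyError(f"atom {chain}:{res_id}:{name} not in model")
        return int(idx[0])

    def residue_mask(self, chain: str, res_id: int) -> np.ndarray:
        return (self.chain_id == chain) & (self.res_id == res_id)

    def residue_keys(self) -> list:
        seen = dict.fromkeys(zip(self.chain_id, self.res_id.tolist()))
        return list(seen)

    def get_coord(self, chain: str, res_id: int, name: str) -> np.ndarray:
        return self.coord[self.atom_index(chain, res_id, name)]


@dataclass
class RigidGroupPartition:
    """Named rigid residue groups plus individually flexible linker residues.

    ``order`` lists every residue key (chain, res_id) in topological order
    along the complex; a torsion at a flexible residue rotates everything that
    comes after it in this order.  Bound ligand residues are interleaved with
    the domain they attach to, so they ride along with that domain.
    """

    groups: dict           # name -> frozenset of (chain, res_id)
    flexible: list         # [(chain, res_id), ...] linker residues
    order: list            # all residue keys, topological order
    _mask_cache: dict = field(default_factory=dict, repr=False)

    def atom_mask(self, model: "AtomicModel", group: str) -> np.ndarray:
        """Boolean atom mask of a group (cached per atom layout)."""
        key = ("group", group, len(model))
        if key not in self._mask_cache:
            residues = self.groups[group]
            mask = np.array(
                [(c, int(r)) in residues for c, r in zip(model.chain_id, model.res_id)]
            )
            self._mask_cache[key] = mask
        return self._mask_cache[key]

    def downstream_mask(self, model: "AtomicModel", residue) -> np.ndarray:
        key = ("downstream", residue, len(model))
        if key not in self._mask_cache:
            pos = self.order.index(residue)
            downstream = set(self.order[pos + 1:])
            mask = np.array(
                [(c, int(r)) in downstream for c, r in zip(model.chain_id, model.res_id)]
            )
            self._mask_cache[key] = mask
        return self._mask_cache[key]

    def validate(self, model: AtomicModel) -> None:
        all_group = set()
        for name, residues in self.groups.items():
            overlap = all_group & set(residues)
            if overlap:
                raise ValueError(f"group {name} overlaps another group: {sorted(overlap)}")
            all_group |= set(residues)
        covered = all_group | set(self.flexible)
        model_res = set(model.residue_keys())
        if covered != model_res:
            raise ValueError("groups + flexible residues do not cover the model exactly")
        if model.linker is not None:
            chain, lo, hi = model.linker
            for c, r in self.flexible:
                if c != chain or not (lo <= r <= hi):
                    raise ValueError(f"flexible torsion {c}:{r} outside linker range")


# ---------------------------------------------------------------------------
# PDB I/O


def _prescan_pdb(path) -> None:
    with open(path) as fh:
        lines = fh.readlines()
    n_atoms = 0
    for i, line in enumerate(lines, start=1):
        if line.startswith(("ATOM", "HETATM")):
            n_atoms += 1
            if len(line.rstrip("\n")) < 54:
                raise PDBParseError(f"line {i}: truncated ATOM/HETATM record")
            if line[26].strip():
                raise PDBParseError(f"line {i}: insertion codes are not supported")
            try:
                float(line[30:38]); float(line[38:46]); float(line[46:54])
            except ValueError:
                raise PDBParseError(f"line {i}: malformed coordinate fields") from None
    if n_atoms == 0:
        raise PDBParseError(f"{path}: no ATOM/HETATM records")


def read_pdb(path) -> AtomicModel:
    """Read an ATOM/HETATM-record PDB file into an :class:`AtomicModel`."""
    _prescan_pdb(path)
    try:
        pdb_file = pdb_io.PDBFile.read(str(path))
        atoms = pdb_file.get_structure(model=1, extra_fields=["atom_id"])
    except Exception as exc:  # biotite raises various subclasses
        raise PDBParseError(f"{path}: {exc}") from exc
    element = atoms.element.astype("U2")
    # fall back to first letter of the atom name when the element column is blank
    blank = element == ""
    if blank.any():
        element = element.copy()
        element[blank] = [n.lstrip("0123456789")[:1] for n in atoms.atom_name[blank]]
    return AtomicModel(
        serial=atoms.atom_id.copy(),
        name=atoms.atom_name.astype("U6"),
        element=element,
        res_id=atoms.res_id.copy(),
        res_name=atoms.res_name.astype("U5"),
        chain_id=atoms.chain_id.astype("U4"),
        coord=atoms.coord.astype(float),
    )


def write_pdb(model: AtomicModel, path) -> None:
    """Write the model as ATOM records; coordinates kept to 3 decimals."""
    n = len(model)
    atoms = struc.AtomArray(n)
    atoms.coord = model.coord.astype(np.float32)
    atoms.chain_id = model.chain_id
    atoms.res_id = model.res_id
    atoms.res_name = model.res_name
    atoms.atom_name = model.name
    atoms.element = model.element
    atoms.set_annotation("atom_id", np.asarray(model.serial, dtype=int))
    atoms.hetero = np.zeros(n, dtype=bool)
    pdb_file = pdb_io.PDBFile()
    pdb_file.set_structure(atoms)
    pdb_file.write(str(path))


# ---------------------------------------------------------------------------
# Geometry


def ring_center(model: AtomicModel, residue_spec) -> np.ndarray:
    """Arithmetic centroid of the six-membered ring of a residue.

    ``residue_spec`` is ``(chain, res_id)``.  Supported residue types: Phe and
    the four ribonucleotides (purines contribute their six-membered ring).
    """
    chain, res_id = residue_spec
    mask = model.residue_mask(chain, res_id)
    if not mask.any():
        raise KeyError(f"residue {chain}:{res_id} not in model")
    res_name = model.res_name[mask][0]
    try:
        ring_names = RING_ATOMS[res_name]
    except KeyError:
        raise ValueError(f"no ring definition for residue type {res_name!r}") from None
    names_here = set(model.name[mask])
    missing = [a for a in ring_names if a not in names_here]
    if missing:
        raise ValueError(f"residue {chain}:{res_id} ({res_name}) missing ring atoms {missing}")
    coords = np.array([model.get_coord(chain, res_id, a) for a in ring_names])
    return coords.mean(axis=0)


def parse_selection(spec: str):
    """Parse ``"chain:first-last[:atoms]"`` into (chain, first, last, atoms).

    ``atoms`` is a tuple of atom names or None (= all atoms).  A bare chain id
    selects the whole chain.
    """
    parts = spec.split(":")
    chain = parts[0]
    first, last = None, None
    atoms = None
    if len(parts) >= 2 and parts[1]:
        lo, _, hi = parts[1].partition("-")
        first = int(lo)
        last = int(hi) if hi else first
    if len(parts) >= 3 and parts[2]:
        atoms = tuple(a.strip() for a in parts[2].split(","))
    return chain, first, last, atoms


def _selection_mask(model: AtomicModel, selection) -> np.ndarray:
    if selection is None:
        return np.ones(len(model), dtype=bool)
    if isinstance(selection, str):
        selection = [selection]
    mask = np.zeros(len(model), dtype=bool)
    for spec in selection:
        if isinstance(spec, str):
            chain, first, last, atoms = parse_selection(spec)
        else:
            chain, first, last, atoms = spec
        m = model.chain_id == chain
        if first is not None:
            m &= (model.res_id >= first) & (model.res_id <= last)
        if atoms is not None:
            m &= np.isin(model.name, atoms)
        mask |= m
    return mask


def _backbone_mask(model: AtomicModel) -> np.ndarray:
    mask = np.zeros(len(model), dtype=bool)
    for chain, role in model.chain_roles.items():
        names = PROTEIN_BACKBONE if role == "protein" else RNA_BACKBONE
        mask |= (model.chain_id == chain) & np.isin(model.name, names)
    return mask


def _matched_coords(model_a, model_b, selection, backbone_only):
    mask_a = _selection_mask(model_a, selection)
    mask_b = _selection_mask(model_b, selection)
    if backbone_only:
        mask_a &= _backbone_mask(model_a)
        mask_b &= _backbone_mask(model_b)
    keys_a = {
        (c, int(r), n): i
        for i, (c, r, n) in enumerate(zip(model_a.chain_id, model_a.res_id, model_a.name))
        if mask_a[i]
    }
    keys_b = {
        (c, int(r), n): i
        for i, (c, r, n) in enumerate(zip(model_b.chain_id, model_b.res_id, model_b.name))
        if mask_b[i]
    }
    if not keys_a or not keys_b:
        raise ValueError("empty selection")
    unmatched = set(keys_a) ^ set(keys_b)
    if unmatched:
        raise ValueError(f"unmatched atoms in selection: {sorted(unmatched)[:10]}")
    common = sorted(keys_a)
    xa = model_a.coord[[keys_a[k] for k in common]]
    xb = model_b.coord[[keys_b[k] for k in common]]
    return xa, xb


def superpose(mobile: np.ndarray, target: np.ndarray):
    """Least-squares (Kabsch) superposition of point set ``mobile`` onto ``target``.

    Returns (rotation 3x3, translation 3,) such that mobile @ R.T + t best
    fits target.  All points weighted equally.
    """
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    rot, _ = Rotation.align_vectors(target - tc, mobile - mc)
    R = rot.as_matrix()
    t = tc - mc @ R.T
    return R, t


def backbone_rmsd(model_a, model_b, selection=None, superpose_first=True) -> float:
    """Backbone RMSD (Å) between two models over a residue selection.

    Backbone atoms are N, CA, C, O for protein chains and P, O5', C5', C4',
    C3', O3' for RNA chains; atoms are matched one-to-one by
    (chain, residue, atom name).  With ``superpose_first`` the optimal
    least-squares superposition is applied before the RMSD.
    """
    xa, xb = _matched_coords(model_a, model_b, selection, backbone_only=True)
    if superpose_first:
        R, t = superpose(xb, xa)
        xb = xb @ R.T + t
    return float(np.sqrt(np.mean(np.sum((xa - xb) ** 2, axis=1))))


# ---------------------------------------------------------------------------
# Moves


def apply_move(model, partition, group, rotation=None, translation=None) -> AtomicModel:
    """Rigid move of one named group: rotate about its centroid, then translate.

    Only atoms of the moved group change; rigid moves preserve intra-group
    pairwise distances.
    """
    if group not in partition.groups:
        raise KeyError(f"no group named {group!r}")
    if rotation is None:
        rotation = np.eye(3)
    rotation = np.asarray(rotation, dtype=float)
    if not np.isclose(np.linalg.det(rotation), 1.0, atol=1e-8):
        raise ValueError("rotation must be proper (determinant +1)")
    if translation is None:
        translation = np.zeros(3)
    out = model.copy()
    if np.array_equal(rotation, np.eye(3)) and not np.any(translation):
        return out
    mask = partition.atom_mask(model, group)
    pivot = model.coord[mask].mean(axis=0)
    out.coord[mask] = (model.coord[mask] - pivot) @ rotation.T + pivot + translation
    return out


def apply_torsion(model, partition, residue, delta_deg: float) -> AtomicModel:
    """Rotate everything downstream of a flexible linker residue.

    The rotation axis runs from CA of the flexible residue to CA of the next
    residue in the chain; all residues after the flexible residue in
    ``partition.order`` rotate about it by ``delta_deg``.
    """
    if residue not in partition.flexible:
        raise KeyError(f"{residue} is not a flexible torsion residue")
    chain, res_id = residue
    p0 = model.get_coord(chain, res_id, "CA")
    p1 = model.get_coord(chain, res_id + 1, "CA")
    axis = p1 - p0
    norm = np.linalg.norm(axis)
    if norm < 1e-9:
        raise ValueError("degenerate torsion axis")
    rot = Rotation.from_rotvec(np.deg2rad(delta_deg) * axis / norm).as_matrix()
    out = model.copy()
    mask = partition.downstream_mask(model, residue)
    out.coord[mask] = (model.coord[mask] - p0) @ rot.T + p0
    return out
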