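"""Collective-variable geometry on protein structures.

A collective variable (CV) is a scalar observable of the centers of mass
(COM) of named atom groups: a distance between two COMs (nm), a planar
angle over three (degrees, [0, 180]), or a dihedral over four (degrees,
(-180, 180], signed atan2 convention).  These are the descriptors used to
steer and bin the open->closed conformational transition of albumin.

Atom groups are configuration-driven: a YAML file maps CV labels to
chain/residue-range/atom-name selections over a PDB structure.  The
shipped example selections in ``default_cv_config`` cover the albumin
domain ranges (domain I ~ residues 1-195, II ~ 196-383, III ~ 384-585)
and are illustrative placeholders, not an authoritative reproduction of
any published restraint set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

try:  # Biopython: PDB parsing + Kabsch superposition
    from Bio.PDB import PDBParser
    from Bio.SVDSuperimposer import SVDSuperimposer
except ImportError:  # pragma: no cover
    PDBParser = None
    SVDSuperimposer = None

__all__ = [
    "AtomGroup",
    "CollectiveVariable",
    "UndefinedGeometryError",
    "center_of_mass",
    "eval_cv",
    "backbone_rmsd",
    "load_structure_atoms",
    "select_group",
    "cv_from_config",
    "default_cv_config",
]

RMSD_CLOSED_STATE_THRESHOLD_NM = 0.25  # transition-completeness criterion

CV_GROUP_COUNT = {"distance": 2, "planar_angle": 3, "dihedral": 4}


class UndefinedGeometryError(ValueError):
    """Raised when the CV geometry is degenerate (e.g. colinear triple)."""


@dataclass(frozen=True)
class AtomGroup:
    """A set of atoms: coordinates (nm, shape (n, 3)) and masses (amu)."""

    coords: np.ndarray
    masses: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        masses = np.atleast_1d(np.asarray(self.masses, dtype=float))
        if coords.shape[0] == 0:
            raise ValueError("AtomGroup must be non-empty")
        if coords.shape[0] != masses.shape[0]:
            raise ValueError("coords and masses length mismatch")
        if np.any(masses <= 0):
            raise ValueError("masses must be > 0")
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "masses", masses)


@dataclass(frozen=True)
class CollectiveVariable:
    """A geometric observable over atom-group centers of mass."""

    kind: str
    groups: tuple[AtomGroup, ...]
    label: str = ""

    def __post_init__(self) -> None:
        if self.kind not in CV_GROUP_COUNT:
            raise ValueError(f"unknown CV kind {self.kind!r}")
        if len(self.groups) != CV_GROUP_COUNT[self.kind]:
            raise ValueError(
                f"{self.kind} CV needs {CV_GROUP_COUNT[self.kind]} groups, "
                f"got {len(self.groups)}"
            )
        object.__setattr__(self, "groups", tuple(self.groups))


def center_of_mass(group: AtomGroup) -> np.ndarray:
    """Mass-weighted mean position of the group (nm)."""
    total = group.masses.sum()
    if total <= 0:
        raise ValueError("zero total mass")
    return group.masses @ group.coords / total


def _dihedral(p0, p1, p2, p3) -> float:
    b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-12 or np.linalg.norm(n2) < 1e-12:
        raise UndefinedGeometryError("colinear triple: dihedral undefined")
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = n1 @ n2
    y = m1 @ n2
    ang = np.degrees(np.arctan2(y, x))
    # atan2 returns (-180, 180]; map -180 to +180 for a half-open interval
    return float(ang if ang != -180.0 else 180.0)


def eval_cv(cv: CollectiveVariable) -> float:
    """Evaluate the CV: nm for distances, degrees for angles/dihedrals."""
    coms = [center_of_mass(g) for g in cv.groups]
    if not all(np.all(np.isfinite(c)) for c in coms):
        raise ValueError("non-finite coordinates")
    if cv.kind == "distance":
        return float(np.linalg.norm(coms[1] - coms[0]))
    if cv.kind == "planar_angle":
        v1 = coms[0] - coms[1]
        v2 = coms[2] - coms[1]
        d1, d2 = np.linalg.norm(v1), np.linalg.norm(v2)
        if d1 < 1e-12 or d2 < 1e-12:
            raise UndefinedGeometryError("coincident COMs: angle undefined")
        cosang = np.clip(v1 @ v2 / (d1 * d2), -1.0, 1.0)
        return float(np.degrees(np.arccos(cosang)))
    return _dihedral(*coms)


def backbone_rmsd(coords_a, coords_b, superpose: bool = True) -> float:
    """RMSD (nm) between two conformations of the same atoms.

    With ``superpose=True`` an optimal rigid-body (Kabsch) alignment is
    applied first, so the value is invariant under rotation+translation
    of either set.  A value below ``RMSD_CLOSED_STATE_THRESHOLD_NM`` is
    the criterion for a completed open->closed transition.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError(f"coordinate shape mismatch: {a.shape} vs {b.shape}")
    if superpose:
        sup = SVDSuperimposer()
        sup.set(a, b)
        sup.run()
        return float(sup.get_rms())
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


# ---------------------------------------------------------------------------
# PDB selection plumbing

BACKBONE_ATOMS = ("N", "CA", "C", "O")


def load_structure_atoms(pdb_path, model_index: int = 0):
    """Flat atom table from a PDB file.

    Returns a list of dicts with chain, residue number, atom name,
    coordinates in nm and mass in amu.  Altloc ambiguity is resolved by
    Biopython's default first-listed conformer.
    """
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("s", str(pdb_path))
    model = list(structure)[model_index]
    atoms = []
    for chain in model:
        for residue in chain:
            het, resseq, _ = residue.id
            if het.strip():
                continue  # ATOM records only
            for atom in residue:
                atoms.append(
                    {
                        "chain": chain.id,
                        "resseq": int(resseq),
                        "name": atom.get_name(),
                        # PDB coordinates are Angstrom; store nm
                        "coord": np.asarray(atom.coord, dtype=float) / 10.0,
                        "mass": float(atom.mass),
                    }
                )
    return atoms


def select_group(atoms, selection: dict, label: str = "") -> AtomGroup:
    """Build an AtomGroup from a selection dict.

    Keys: ``chain`` (str, optional), ``residues`` ([first, last],
    1-based inclusive, optional), ``atoms`` (list of atom names,
    optional; e.g. ["CA"] or the backbone set).
    """
    chain = selection.get("chain")
    residues = selection.get("residues")
    names = selection.get("atoms")
    picked = [
        a
        for a in atoms
        if (chain is None or a["chain"] == chain)
        and (residues is None or residues[0] <= a["resseq"] <= residues[1])
        and (names is None or a["name"] in names)
    ]
    if not picked:
        raise ValueError(f"selection matched no atoms: {selection}")
    return AtomGroup(
        np.array([a["coord"] for a in picked]),
        np.array([a["mass"] for a in picked]),
        label=label,
    )


def cv_from_config(atoms, cv_spec: dict) -> CollectiveVariable:
    """Build one CV from a config entry.

    ``cv_spec``: ``{"label": "D1", "kind": "dihedral", "groups":
    [<selection>, ...]}`` with group count matching the kind.
    """
    groups = [
        select_group(atoms, sel, label=f"{cv_spec.get('label', '')}/g{i}")
        for i, sel in enumerate(cv_spec["groups"])
    ]
    return CollectiveVariable(cv_spec["kind"], tuple(groups), cv_spec.get("label", ""))


def default_cv_config() -> list[dict]:
    """Illustrative CV selections over albumin domain ranges.

    Placeholders over domain I (1-195), II (196-383) and III (384-585)
    C-alpha groups; useful for exercising the machinery on real albumin
    coordinates, not a published restraint definition.
    """
    dom1a = {"chain": "A", "residues": [1, 100], "atoms": ["CA"]}
    dom1b = {"chain": "A", "residues": [101, 195], "atoms": ["CA"]}
    dom2a = {"chain": "A", "residues": [196, 290], "atoms": ["CA"]}
    dom2b = {"chain": "A", "residues": [291, 383], "atoms": ["CA"]}
    dom3 = {"chain": "A", "residues": [384, 585], "atoms": ["CA"]}
    return [
        {"label": "D1", "kind": "dihedral", "groups": [dom1a, dom1b, dom2a, dom2b]},
        {"label": "P1", "kind": "planar_angle", "groups": [dom1a, dom2a, dom2b]},
        {"label": "R1", "kind": "distance", "groups": [dom1a, dom2a]},
        {"label": "R2", "kind": "distance", "groups": [dom1b, dom2b]},
        {"label": "R3", "kind": "distance", "groups": [dom1a, dom3]},
    ]
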