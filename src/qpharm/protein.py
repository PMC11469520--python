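"""Protein structures, functional-group annotation, and PDB reading.

The annotation step marks the protein-side chemical groups that complement
each pharmacophore feature class: hydrogen-bond donors and acceptors,
charged groups, aromatic rings and hydrophobic patches.  Group kinds are
assigned purely from a residue/atom-name lookup table of standard amino
acid chemistry; the table is overridable for non-standard residues.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import EmptyStructureError, FormatError
from .features import FeatureClass

GROUP_KINDS = (
    "donor_group", "acceptor_group", "aromatic_ring",
    "anionic_group", "cationic_group", "hydrophobic_patch",
)

#: Protein group kind that complements each feature class: a ligand-side
#: hydrogen acceptor pairs with a protein donor, an anion with a cation, ...
COMPLEMENTARY_GROUP = {
    FeatureClass.HydrogenAcceptor: "donor_group",
    FeatureClass.HydrogenDonor: "acceptor_group",
    FeatureClass.Hydrophobic: "hydrophobic_patch",
    FeatureClass.Aromatic: "aromatic_ring",
    FeatureClass.NegativeIon: "cationic_group",
    FeatureClass.PositiveIon: "anionic_group",
}

#: Maximum feature-to-group distance (Å) for a feature of each class to be
#: considered supported by a complementary protein group.  The
#: acceptor-to-donor cutoff is 4 Å; the others follow typical interaction
#: ranges and are configuration-overridable.
DEFAULT_COMP_DIST = {
    FeatureClass.HydrogenAcceptor: 4.0,
    FeatureClass.HydrogenDonor: 4.0,
    FeatureClass.Hydrophobic: 5.0,
    FeatureClass.Aromatic: 6.0,
    FeatureClass.NegativeIon: 5.0,
    FeatureClass.PositiveIon: 5.0,
}


@dataclass
class ProteinAtom:
    position: np.ndarray
    element: str
    residue_name: str
    atom_name: str
    is_hydrogen: bool = False
    res_id: int = 0
    chain: str = "A"

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError("atom position must be a finite 3-vector")
        self.element = str(self.element).strip().upper()
        self.residue_name = str(self.residue_name).strip().upper()
        self.atom_name = str(self.atom_name).strip().upper()


@dataclass
class FunctionalGroupSite:
    position: np.ndarray
    group_kind: str
    source_atoms: list[int] = field(default_factory=list)

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if self.group_kind not in GROUP_KINDS:
            raise ValueError(f"unknown group kind {self.group_kind!r}")


@dataclass
class ProteinStructure:
    atoms: list[ProteinAtom]
    groups: list[FunctionalGroupSite] = field(default_factory=list)

    def __post_init__(self):
        n = len(self.atoms)
        for g in self.groups:
            if any(i < 0 or i >= n for i in g.source_atoms):
                raise ValueError("group references an invalid atom index")

    @property
    def heavy_coords(self) -> np.ndarray:
        pts = [a.position for a in self.atoms if not a.is_hydrogen]
        return np.array(pts, dtype=float).reshape(-1, 3)

    def group_positions(self, kind: str) -> np.ndarray:
        pts = [g.position for g in self.groups if g.group_kind == kind]
        return np.array(pts, dtype=float).reshape(-1, 3)

    def translated(self, dv) -> "ProteinStructure":
        dv = np.asarray(dv, dtype=float)
        atoms = [ProteinAtom(a.position + dv, a.element, a.residue_name,
                             a.atom_name, a.is_hydrogen, a.res_id, a.chain)
                 for a in self.atoms]
        groups = [FunctionalGroupSite(g.position + dv, g.group_kind,
                                      list(g.source_atoms))
                  for g in self.groups]
        return ProteinStructure(atoms, groups)


# Side-chain lookup table.  Entries are (group_kind, atom_names, merged):
# merged sites are emitted once at the centroid of the named atoms (rings,
# carboxylates, guanidinium, hydrophobic patches); unmerged entries emit one
# site per listed atom.  Backbone N (donor) and O/OXT (acceptor) are handled
# separately and apply to every residue, known or not.
_RING_PHE = ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")
_RING_TRP = ("CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2")
_RING_HIS = ("CG", "ND1", "CD2", "CE1", "NE2")

RESIDUE_SITE_TABLE: dict[str, list[tuple[str, tuple[str, ...], bool]]] = {
    "SER": [("donor_group", ("OG",), False), ("acceptor_group", ("OG",), False)],
    "THR": [("donor_group", ("OG1",), False), ("acceptor_group", ("OG1",), False),
            ("hydrophobic_patch", ("CG2",), True)],
    "TYR": [("donor_group", ("OH",), False), ("acceptor_group", ("OH",), False),
            ("aromatic_ring", _RING_PHE, True)],
    "ASN": [("acceptor_group", ("OD1",), False), ("donor_group", ("ND2",), False)],
    "GLN": [("acceptor_group", ("OE1",), False), ("donor_group", ("NE2",), False)],
    "ASP": [("acceptor_group", ("OD1",), False), ("acceptor_group", ("OD2",), False),
            ("anionic_group", ("OD1", "OD2"), True)],
    "GLU": [("acceptor_group", ("OE1",), False), ("acceptor_group", ("OE2",), False),
            ("anionic_group", ("OE1", "OE2"), True)],
    "LYS": [("cationic_group", ("NZ",), False), ("donor_group", ("NZ",), False),
            ("hydrophobic_patch", ("CB", "CG", "CD"), True)],
    "ARG": [("cationic_group", ("NE", "CZ", "NH1", "NH2"), True),
            ("donor_group", ("NE",), False), ("donor_group", ("NH1",), False),
            ("donor_group", ("NH2",), False),
            ("hydrophobic_patch", ("CB", "CG"), True)],
    "HIS": [("aromatic_ring", _RING_HIS, True),
            ("donor_group", ("ND1",), False), ("acceptor_group", ("ND1",), False),
            ("donor_group", ("NE2",), False), ("acceptor_group", ("NE2",), False)],
    "PHE": [("aromatic_ring", _RING_PHE, True),
            ("hydrophobic_patch", ("CB",), True)],
    "TRP": [("aromatic_ring", _RING_TRP, True), ("donor_group", ("NE1",), False),
            ("hydrophobic_patch", ("CB",), True)],
    "ALA": [("hydrophobic_patch", ("CB",), True)],
    "VAL": [("hydrophobic_patch", ("CB", "CG1", "CG2"), True)],
    "LEU": [("hydrophobic_patch", ("CB", "CG", "CD1", "CD2"), True)],
    "ILE": [("hydrophobic_patch", ("CB", "CG1", "CG2", "CD1"), True)],
    "MET": [("hydrophobic_patch", ("CB", "CG", "CE"), True)],
    "PRO": [("hydrophobic_patch", ("CB", "CG", "CD"), True)],
    "CYS": [("hydrophobic_patch", ("CB",), True)],
    "GLY": [],
}

_BACKBONE_DONOR_ATOMS = ("N",)
_BACKBONE_ACCEPTOR_ATOMS = ("O", "OXT")


def annotate_groups(atoms: list[ProteinAtom],
                    table: dict | None = None) -> list[FunctionalGroupSite]:
    """Annotate complementary functional-group sites from atom names.

    Deterministic: atoms are grouped into residues by (chain, res_id,
    residue_name) and residues are visited in order of their first atom's
    index, so the result is independent of the input atom ordering up to
    the ordering of the returned list; sites themselves depend only on the
    residue content.
    """
    if not atoms:
        return []
    table = RESIDUE_SITE_TABLE if table is None else table

    residues: dict[tuple, list[int]] = {}
    first_seen: dict[tuple, int] = {}
    for i, a in enumerate(atoms):
        key = (a.chain, a.res_id, a.residue_name)
        residues.setdefault(key, []).append(i)
        first_seen.setdefault(key, i)

    sites: list[FunctionalGroupSite] = []
    for key in sorted(residues, key=lambda k: (k[0], k[1], k[2])):
        idxs = residues[key]
        by_name = {}
        for i in sorted(idxs):
            by_name.setdefault(atoms[i].atom_name, i)
        resname = key[2]
        # backbone donors/acceptors for every residue
        for name in _BACKBONE_DONOR_ATOMS:
            if name in by_name:
                i = by_name[name]
                sites.append(FunctionalGroupSite(atoms[i].position.copy(),
                                                 "donor_group", [i]))
        for name in _BACKBONE_ACCEPTOR_ATOMS:
            if name in by_name:
                i = by_name[name]
                sites.append(FunctionalGroupSite(atoms[i].position.copy(),
                                                 "acceptor_group", [i]))
        for kind, names, merged in table.get(resname, []):
            present = [by_name[n] for n in names if n in by_name]
            if merged:
                need = len(names) if kind in ("aromatic_ring", "anionic_group",
                                              "cationic_group") else 1
                if len(present) >= need and present:
                    centroid = np.mean([atoms[i].position for i in present], axis=0)
                    sites.append(FunctionalGroupSite(centroid, kind, present))
            else:
                for i in present:
                    sites.append(FunctionalGroupSite(atoms[i].position.copy(),
                                                     kind, [i]))
    return sites


# Atom-type channels used for voxelization (hydrogens excluded from density).
CHANNEL_NAMES = ("C_aliphatic", "C_aromatic", "N_donor", "N_other",
                 "O_acceptor", "O_other", "S", "other")
N_CHANNELS = len(CHANNEL_NAMES)

_AROMATIC_ATOMS = {
    "PHE": set(_RING_PHE), "TYR": set(_RING_PHE),
    "TRP": set(_RING_TRP), "HIS": set(_RING_HIS),
}
_SIDECHAIN_N_DONOR = {
    "LYS": {"NZ"}, "ARG": {"NE", "NH1", "NH2"}, "ASN": {"ND2"},
    "GLN": {"NE2"}, "TRP": {"NE1"}, "HIS": {"ND1", "NE2"},
}
_SIDECHAIN_O_ACCEPTOR = {
    "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"}, "ASN": {"OD1"},
    "GLN": {"OE1"}, "ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"},
}

VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80}
DEFAULT_VDW = 1.70


def atom_channel(atom: ProteinAtom) -> int | None:
    """Channel index for a heavy atom; None for hydrogens."""
    if atom.is_hydrogen or atom.element == "H":
        return None
    el, res, name = atom.element, atom.residue_name, atom.atom_name
    if el == "C":
        if name in _AROMATIC_ATOMS.get(res, ()):
            return CHANNEL_NAMES.index("C_aromatic")
        return CHANNEL_NAMES.index("C_aliphatic")
    if el == "N":
        if name in _BACKBONE_DONOR_ATOMS or name in _SIDECHAIN_N_DONOR.get(res, ()):
            return CHANNEL_NAMES.index("N_donor")
        return CHANNEL_NAMES.index("N_other")
    if el == "O":
        if name in _BACKBONE_ACCEPTOR_ATOMS or name in _SIDECHAIN_O_ACCEPTOR.get(res, ()):
            return CHANNEL_NAMES.index("O_acceptor")
        return CHANNEL_NAMES.index("O_other")
    if el == "S":
        return CHANNEL_NAMES.index("S")
    return CHANNEL_NAMES.index("other")


def vdw_radius(atom: ProteinAtom) -> float:
    return VDW_RADII.get(atom.element, DEFAULT_VDW)


def load_protein(path, table: dict | None = None) -> ProteinStructure:
    """Read a PDB file (ATOM/HETATM records, first model) and annotate groups.

    Hydrogens are flagged but kept.  Alternate locations beyond the first
    are dropped.
    """
    import biotite.structure.io.pdb as pdb

    try:
        pdb_file = pdb.PDBFile.read(str(path))
    except Exception as exc:
        raise FormatError(f"could not read PDB file {path}: {exc}") from exc
    has_atoms = any(line.startswith(("ATOM", "HETATM"))
                    for line in pdb_file.lines)
    if not has_atoms:
        raise EmptyStructureError(f"no atoms found in {path}")
    try:
        arr = pdb_file.get_structure(model=1, altloc="first")
    except Exception as exc:
        raise FormatError(f"could not parse PDB file {path}: {exc}") from exc
    if arr.array_length() == 0:
        raise EmptyStructureError(f"no atoms found in {path}")

    atoms = []
    for i in range(arr.array_length()):
        el = str(arr.element[i]).upper()
        atoms.append(ProteinAtom(
            position=np.asarray(arr.coord[i], dtype=float),
            element=el,
            residue_name=str(arr.res_name[i]),
            atom_name=str(arr.atom_name[i]),
            is_hydrogen=el == "H",
            res_id=int(arr.res_id[i]),
            chain=str(arr.chain_id[i]),
        ))
    return ProteinStructure(atoms, annotate_groups(atoms, table))


def write_protein_pdb(protein: ProteinStructure, path) -> None:
    """Write atoms as minimal PDB ATOM records (for synthetic structures)."""
    lines = []
    for i, a in enumerate(protein.atoms, start=1):
        name = a.atom_name if len(a.atom_name) >= 4 else f" {a.atom_name:<3s}"
        lines.append(
            f"ATOM  {i:5d} {name:<4s}{a.residue_name:>4s} {a.chain:1s}"
            f"{a.res_id:4d}    {a.position[0]:8.3f}{a.position[1]:8.3f}"
            f"{a.position[2]:8.3f}{1.0:6.2f}{0.0:6.2f}          "
            f"{a.element:>2s}"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
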