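"""Residue chemistry: warhead topologies, covalent patches, rotamers, masses.

The reactive group modelled here is a thioether-linked methacrylate ester
installed on a cysteine side chain. Conjugate (aza-Michael) addition of a
lysine amine across its activated alkene creates a new stereocenter, so the
*reacted* residue exists as two stereoisomers; they are represented as two
residue topologies, ``MCR`` and ``MCS``, that share an atom inventory and
differ only in the sign of the branch torsion at the stereocenter. The
nucleophile side is a covalent lysine variant ``LYX`` (lysine minus one NZ
proton, plus a connection at NZ) produced by a residue patch, and the
analogous cysteine variant ``CYX`` for thiol-targeted designs.

Each covalent residue carries a *virtual atom*: a non-physical topology atom
marking the ideal position of its covalent partner atom (the lysine NZ as
seen from the warhead, and the warhead methylene carbon as seen from the
lysine). Virtual atoms never score; they exist as anchors for harmonic
distance restraints during design.

Geometry uses fixed idealized internal coordinates (sp3 C-C 1.53 A, C-S
1.81 A, C-N 1.47 A, sp2 C=C 1.33 A, C=O 1.21 A, ester C-O 1.34 A; sp3
angles 109.5 deg, sp2 angles 120 deg). Mass tables carry monoisotopic and
average atomic masses plus residue and modification formulas for the
adduct arithmetic.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np

from .geometry import InternalCoordinate, dihedral_angle, place_atom
from .structure import AtomRecord

__all__ = [
    "ChemistryError",
    "UnknownResidueError",
    "PatchError",
    "ResidueTopology",
    "ResiduePatch",
    "RotamerGrid",
    "ChiDefinition",
    "load_topology",
    "apply_patch",
    "covalent_lysine_patch",
    "covalent_cysteine_patch",
    "build_sidechain",
    "measure_chis",
    "warhead_topology",
    "parse_formula",
    "formula_add",
    "formula_subtract",
    "fragment_mass",
    "ELEMENT_MASSES",
    "RESIDUE_FORMULAS",
    "MODIFICATION_DELTAS",
    "METHACRYLATE_FRAGMENT",
    "WARHEAD_CODES",
    "NUCLEOPHILE_VARIANTS",
    "topology_to_text",
    "topology_from_text",
]


class ChemistryError(Exception):
    pass


class UnknownResidueError(ChemistryError, KeyError):
    pass


class PatchError(ChemistryError):
    pass


BACKBONE_ATOMS = ("N", "CA", "C", "O")
#: protected against patching; an invalid backbone breaks every downstream build
_PROTECTED = {"N", "CA", "C", "O"}

METHACRYLATE_FRAGMENT = "C6H8O2"
WARHEAD_CODES = ("MCR", "MCS")


@dataclass(frozen=True)
class ChiDefinition:
    atoms: tuple[str, str, str, str]
    proton: bool = False


@dataclass
class ResidueTopology:
    name: str
    atoms: list[tuple[str, str, bool]]  # (name, element, is_virtual)
    bonds: list[tuple[str, str]]
    icoor: list[InternalCoordinate]
    chi_definitions: list[ChiDefinition] = field(default_factory=list)
    connect_atom: Optional[str] = None
    virtual_partner: Optional[str] = None
    stereo_tag: str = "none"

    def __post_init__(self):
        names = {a[0] for a in self.atoms}
        placed = set(BACKBONE_ATOMS[:3])  # N, CA, C come from the backbone anchor
        for ic in self.icoor:
            for ref in (ic.ref1, ic.ref2, ic.ref3):
                if ref not in placed and ref not in names:
                    raise ValueError(f"{self.name}: icoor for {ic.atom} references unknown {ref}")
                if ref == ic.atom:
                    raise ValueError(f"{self.name}: icoor for {ic.atom} references itself")
            if ic.ref3 not in placed:
                raise ValueError(
                    f"{self.name}: icoor graph not rooted — {ic.atom} placed before {ic.ref3}"
                )
            placed.add(ic.atom)
        for atom in (self.connect_atom, self.virtual_partner):
            if atom is not None and atom not in names:
                raise ValueError(f"{self.name}: declared atom {atom!r} not in atom list")
        if self.virtual_partner is not None and not self.is_virtual(self.virtual_partner):
            raise ValueError(f"{self.name}: virtual partner {self.virtual_partner} not virtual")
        for chi in self.chi_definitions:
            for ref in chi.atoms:
                if ref not in names and ref not in BACKBONE_ATOMS:
                    raise ValueError(f"{self.name}: chi references unknown atom {ref}")

    def atom_names(self) -> list[str]:
        return [a[0] for a in self.atoms]

    def element_of(self, name: str) -> str:
        for n, el, _ in self.atoms:
            if n == name:
                return el
        raise KeyError(name)

    def is_virtual(self, name: str) -> bool:
        for n, _, virt in self.atoms:
            if n == name:
                return virt
        raise KeyError(name)

    @property
    def n_chi(self) -> int:
        return len(self.chi_definitions)


@dataclass(frozen=True)
class ResiduePatch:
    base: str
    delete_atoms: tuple[str, ...] = ()
    add_connect: Optional[str] = None
    add_virtual: Optional[tuple[str, InternalCoordinate]] = None
    add_proton_chi: Optional[tuple[str, str, str, str]] = None


@dataclass(frozen=True)
class RotamerGrid:
    """Chi sampling grid: 30 deg steps on heavy chis, 10 deg on proton chis."""

    heavy_samples: tuple[float, ...] = tuple(float(x) for x in range(-180, 180, 30))
    proton_step: float = 10.0

    def samples_for(self, chi: ChiDefinition) -> tuple[float, ...]:
        if chi.proton:
            n = int(round(360.0 / self.proton_step))
            return tuple(-180.0 + i * self.proton_step for i in range(n))
        return self.heavy_samples

    def sample_vector(self, topology: ResidueTopology, rng: np.random.Generator) -> np.ndarray:
        return np.array(
            [rng.choice(self.samples_for(chi)) for chi in topology.chi_definitions]
        )


# ---------------------------------------------------------------------------
# built-in topologies
# ---------------------------------------------------------------------------

_SP3 = 109.5
_SP2 = 120.0
_CC = 1.53
_CS = 1.81
_CN = 1.47
_CO_DOUBLE = 1.21
_CO_ESTER = 1.34
_CO_HYDROXYL = 1.41
_C_AROM = 1.39


def _ic(atom, r1, r2, r3, length, angle, torsion):
    return InternalCoordinate(atom, r1, r2, r3, length, angle, torsion)


# Each sidechain entry: (atom, element, ref1, ref2, ref3, length, angle, torsion)
# where torsion may be the string "chi<k>" to mark a sampled rotatable bond
# (suffix "p" flags a proton/terminal chi, e.g. "chi2p").
_SIDECHAINS: dict[str, list[tuple]] = {
    "GLY": [],
    "ALA": [],
    "SER": [("OG", "O", "N", "CA", "CB", _CO_HYDROXYL, _SP3, "chi1")],
    "CYS": [
        ("SG", "S", "N", "CA", "CB", _CS, _SP3, "chi1"),
        ("HG", "H", "CA", "CB", "SG", 1.34, 96.0, "chi2p"),
    ],
    "THR": [
        ("OG1", "O", "N", "CA", "CB", _CO_HYDROXYL, _SP3, "chi1"),
        ("CG2", "C", "OG1", "CA", "CB", _CC, _SP3, -120.0),
    ],
    "VAL": [
        ("CG1", "C", "N", "CA", "CB", _CC, _SP3, "chi1"),
        ("CG2", "C", "CG1", "CA", "CB", _CC, _SP3, 120.0),
    ],
    "LEU": [
        ("CG", "C", "N", "CA", "CB", _CC, _SP3, "chi1"),
        ("CD1", "C", "CA", "CB", "CG", _CC, _SP3, "chi2"),
        ("CD2", "C", "CD1", "CB", "CG", _CC, _SP3, 120.0),
    ],
    "ILE": [
        ("CG1", "C", "N", "CA", "CB", _CC, _SP3, "chi1"),
        ("CG2", "C", "CG1", "CA", "CB", _CC, _SP3, -120.0),
        ("CD1", "C", "CA", "CB", "CG1", _CC, _SP3, "chi2"),
    ],
    "MET": [
        ("CG", "C", "N", "CA", "CB", _CC, _SP3, "chi1"),
        ("SD", "S", "CA", "CB", "CG", _CS, _SP3, "chi2"),
        ("CE", "C", "CB", "CG", "SD", _CS, _SP3, "chi3"),
    ],
    "PRO": [
        ("CG", "C", "N", "CA", "CB", _CC, 104.0, "chi1"),
        ("CD", "C", "CA", "CB", "CG", _CC, 104.0, "chi2"),
    ],
    "ASP": [
        ("CG", "C", "N", "CA", "CB", 1.52, _SP3, "chi1"),
        ("OD1", "O", "CA", "CB", "CG", 1.25, _SP2, "chi2"),
        ("OD2", "O", "OD1", "CB", "CG", 1.25, _SP2, 180.0),
    ],
    "ASN": [
        ("CG", "C", "N", "CA", "CB", 1.52, _SP3, "chi1"),
        ("OD1", "O", "CA", "CB", "CG", _CO_DOUBLE, _SP2, "chi2"),
        ("ND2", "N", "OD1", "CB", "CG", 1.33, _SP2, 180.0),
    ],
    "GLU": [
        ("CG", "C", "N", "CA", "CB", _CC, _SP3, "chi1"),
        ("CD", "C", "CA", "CB", "CG", 1.52, _SP3, "chi2"),
        ("OE1", "O", "CB", "CG", "CD", 1.25, _SP2, "chi3"),
        ("OE2", "O", "OE1", "CG", "CD", 1.25, _SP2, 180.0),
    ],
    "GLN": [
        ("CG", "C", "N", "CA", "CB", _CC, _SP3, "chi1"),
        ("CD", "C", "CA", "CB", "CG", 1.52, _SP3, "chi2"),
        ("OE1", "O", "CB", "CG", "CD", _CO_DOUBLE, _SP2, "chi3"),
        ("NE2", "N", "OE1", "CG", "CD", 1.33, _SP2, 180.0),
    ],
    "LYS": [
        ("CG", "C", "N", "CA", "CB", _CC, _SP3, "chi1"),
        ("CD", "C", "CA", "CB", "CG", _CC, _SP3, "chi2"),
        ("CE", "C", "CB", "CG", "CD", _CC, _SP3, "chi3"),
        ("NZ", "N", "CG", "CD", "CE", _CN, _SP3, "chi4"),
        ("HZ1", "H", "CD", "CE", "NZ", 1.01, _SP3, 180.0),
        ("HZ2", "H", "HZ1", "CE", "NZ", 1.01, _SP3, 120.0),
        ("HZ3", "H", "HZ1", "CE", "NZ", 1.01, _SP3, -120.0),
    ],
    "ARG": [
        ("CG", "C", "N", "CA", "CB", _CC, _SP3, "chi1"),
        ("CD", "C", "CA", "CB", "CG", _CC, _SP3, "chi2"),
        ("NE", "N", "CB", "CG", "CD", _CN, _SP3, "chi3"),
        ("CZ", "C", "CG", "CD", "NE", 1.33, _SP2, "chi4"),
        ("NH1", "N", "CD", "NE", "CZ", 1.33, _SP2, 0.0),
        ("NH2", "N", "NH1", "NE", "CZ", 1.33, _SP2, 180.0),
    ],
    "HIS": [
        ("CG", "C", "N", "CA", "CB", 1.50, _SP3, "chi1"),
        ("ND1", "N", "CA", "CB", "CG", 1.38, 122.0, "chi2"),
        ("CD2", "C", "ND1", "CB", "CG", 1.36, 122.0, 180.0),
        ("CE1", "C", "CB", "CG", "ND1", 1.32, 108.0, 180.0),
        ("NE2", "N", "CG", "ND1", "CE1", 1.33, 108.0, 0.0),
    ],
    "PHE": [
        ("CG", "C", "N", "CA", "CB", 1.50, _SP3, "chi1"),
        ("CD1", "C", "CA", "CB", "CG", _C_AROM, _SP2, "chi2"),
        ("CD2", "C", "CD1", "CB", "CG", _C_AROM, _SP2, 180.0),
        ("CE1", "C", "CB", "CG", "CD1", _C_AROM, _SP2, 180.0),
        ("CE2", "C", "CB", "CG", "CD2", _C_AROM, _SP2, 180.0),
        ("CZ", "C", "CG", "CD1", "CE1", _C_AROM, _SP2, 0.0),
    ],
    "TYR": [
        ("CG", "C", "N", "CA", "CB", 1.50, _SP3, "chi1"),
        ("CD1", "C", "CA", "CB", "CG", _C_AROM, _SP2, "chi2"),
        ("CD2", "C", "CD1", "CB", "CG", _C_AROM, _SP2, 180.0),
        ("CE1", "C", "CB", "CG", "CD1", _C_AROM, _SP2, 180.0),
        ("CE2", "C", "CB", "CG", "CD2", _C_AROM, _SP2, 180.0),
        ("CZ", "C", "CG", "CD1", "CE1", _C_AROM, _SP2, 0.0),
        ("OH", "O", "CD1", "CE1", "CZ", 1.37, _SP2, 180.0),
    ],
    "TRP": [
        ("CG", "C", "N", "CA", "CB", 1.50, _SP3, "chi1"),
        ("CD1", "C", "CA", "CB", "CG", 1.37, 127.0, "chi2"),
        ("CD2", "C", "CD1", "CB", "CG", 1.43, 127.0, 180.0),
        ("NE1", "N", "CB", "CG", "CD1", 1.38, 110.0, 180.0),
        ("CE2", "C", "CG", "CD1", "NE1", 1.37, 109.0, 0.0),
        ("CE3", "C", "CD1", "CG", "CD2", 1.40, 134.0, 180.0),
        ("CZ2", "C", "CD1", "NE1", "CE2", 1.40, 130.0, 180.0),
        ("CZ3", "C", "CG", "CD2", "CE3", _C_AROM, _SP2, 180.0),
        ("CH2", "C", "CD2", "CE3", "CZ3", 1.40, _SP2, 0.0),
    ],
}

_RING_CLOSURES = {
    "HIS": [("CD2", "NE2")],
    "PHE": [("CE2", "CZ")],
    "TYR": [("CE2", "CZ")],
    "TRP": [("CD2", "CE2"), ("CZ2", "CH2")],
    "PRO": [("CD", "N")],
}

# Reacted methacrylate-cysteine side chain. Walking out from the backbone:
# CB-SG (thioether sulfur), CD (S-methylene), CE (the new stereocenter,
# bearing the ester branch), CZ (methylene bonded to the nucleophile NZ).
# VNZ is the virtual marker for the ideal NZ position beyond CZ. The ester
# branch (CX carbonyl, OX1/OX2, ethyl CY1-CY2) hangs off CE; the branch
# torsion CZ-CD-CE-CX (+120 / -120 deg) is the only difference between the
# two stereoisomers.
def _warhead_sidechain(branch_sign: float) -> list[tuple]:
    return [
        ("SG", "S", "N", "CA", "CB", _CS, _SP3, "chi1"),
        ("CD", "C", "CA", "CB", "SG", _CS, _SP3, "chi2"),
        ("CE", "C", "CB", "SG", "CD", _CC, _SP3, "chi3"),
        ("CZ", "C", "SG", "CD", "CE", _CC, _SP3, "chi4"),
        ("VNZ", "X", "CD", "CE", "CZ", _CN, _SP3, "chi5p"),
        ("CX", "C", "CZ", "CD", "CE", _CC, _SP3, branch_sign * 120.0),
        ("OX1", "O", "CD", "CE", "CX", _CO_DOUBLE, _SP2, 0.0),
        ("OX2", "O", "OX1", "CE", "CX", _CO_ESTER, _SP2, 180.0),
        ("CY1", "C", "CE", "CX", "OX2", 1.44, 117.0, 180.0),
        ("CY2", "C", "CX", "OX2", "CY1", _CC, _SP3, 180.0),
    ]


_CHI_RE = re.compile(r"^chi(\d+)(p?)$")


def _build_topology(name: str, sidechain: list[tuple], **kwargs) -> ResidueTopology:
    atoms: list[tuple[str, str, bool]] = [
        ("N", "N", False),
        ("CA", "C", False),
        ("C", "C", False),
        ("O", "O", False),
    ]
    bonds: list[tuple[str, str]] = [("N", "CA"), ("CA", "C"), ("C", "O")]
    icoor: list[InternalCoordinate] = [_ic("O", "N", "CA", "C", 1.23, 120.5, 180.0)]
    chis: dict[int, ChiDefinition] = {}
    if sidechain is not None and name != "GLY":
        atoms.append(("CB", "C", False))
        bonds.append(("CA", "CB"))
        icoor.append(_ic("CB", "C", "N", "CA", _CC, 110.5, -122.0))
    for entry in sidechain:
        atom, element, r1, r2, r3, length, angle, torsion = entry
        is_virtual = element == "X"
        atoms.append((atom, "C" if is_virtual else element, is_virtual))
        bonds.append((r3, atom))
        if isinstance(torsion, str):
            m = _CHI_RE.match(torsion)
            if not m:
                raise ValueError(f"bad torsion spec {torsion!r}")
            k = int(m.group(1))
            chis[k] = ChiDefinition(atoms=(r1, r2, r3, atom), proton=bool(m.group(2)))
            torsion_value = 180.0
        else:
            torsion_value = float(torsion)
        icoor.append(_ic(atom, r1, r2, r3, length, angle, torsion_value))
    chi_list = [chis[k] for k in sorted(chis)]
    if sorted(chis) != list(range(1, len(chis) + 1)):
        raise ValueError(f"{name}: chi indices not consecutive")
    bonds.extend(_RING_CLOSURES.get(name, []))
    return ResidueTopology(
        name=name, atoms=atoms, bonds=bonds, icoor=icoor, chi_definitions=chi_list, **kwargs
    )


def covalent_lysine_patch() -> ResiduePatch:
    """The covalent-lysine patch: the reacted amine loses one proton and
    gains a connection to the warhead methylene carbon, whose ideal position
    is marked by the virtual atom VCM; a proton chi samples rotation about
    the CE-NZ bond."""
    return ResiduePatch(
        base="LYS",
        delete_atoms=("HZ3",),
        add_connect="NZ",
        add_virtual=("VCM", _ic("VCM", "CD", "CE", "NZ", _CN, _SP3, -60.0)),
        add_proton_chi=("CD", "CE", "NZ", "VCM"),
    )


def covalent_cysteine_patch() -> ResiduePatch:
    """Covalent-cysteine analog: thiol proton deleted, SG connected, VCM
    marking the ideal warhead carbon position beyond SG."""
    return ResiduePatch(
        base="CYS",
        delete_atoms=("HG",),
        add_connect="SG",
        add_virtual=("VCM", _ic("VCM", "CA", "CB", "SG", _CS, 98.0, 180.0)),
        add_proton_chi=("CA", "CB", "SG", "VCM"),
    )


def apply_patch(base: ResidueTopology, patch: ResiduePatch) -> ResidueTopology:
    """Apply a residue patch: deletions first, then additions."""
    if patch.base != base.name:
        raise PatchError(f"patch targets {patch.base}, got {base.name}")
    names = set(base.atom_names())
    for atom in patch.delete_atoms:
        if atom in _PROTECTED:
            raise PatchError(f"backbone atom {atom} is not patchable")
        if atom not in names:
            raise PatchError(f"cannot delete {atom}: not in {base.name}")
    deleted = set(patch.delete_atoms)
    for ic in base.icoor:
        if ic.atom not in deleted and deleted & {ic.ref1, ic.ref2, ic.ref3}:
            raise PatchError(f"cannot delete {sorted(deleted)}: {ic.atom} references them")
    atoms = [a for a in base.atoms if a[0] not in deleted]
    bonds = [b for b in base.bonds if not (deleted & set(b))]
    icoor = [ic for ic in base.icoor if ic.atom not in deleted]
    chis = [c for c in base.chi_definitions if not (deleted & set(c.atoms))]
    connect = base.connect_atom
    virtual = base.virtual_partner

    if patch.add_connect is not None:
        if patch.add_connect not in names - deleted:
            raise PatchError(f"connect atom {patch.add_connect} not present")
        connect = patch.add_connect
    if patch.add_virtual is not None:
        vname, vic = patch.add_virtual
        if vname in names:
            raise PatchError(f"added atom {vname} collides with an existing atom")
        atoms.append((vname, "C", True))
        bonds.append((vic.ref3, vname))
        icoor.append(replace(vic, atom=vname))
        virtual = vname
    if patch.add_proton_chi is not None:
        chis = chis + [ChiDefinition(atoms=tuple(patch.add_proton_chi), proton=True)]
        # the chi-controlled atom's stored torsion becomes the sampling default
    new_name = base.name if patch == ResiduePatch(base=base.name) else _PATCHED_NAMES.get(
        (base.name, patch.add_connect), base.name
    )
    return ResidueTopology(
        name=new_name,
        atoms=atoms,
        bonds=bonds,
        icoor=icoor,
        chi_definitions=chis,
        connect_atom=connect,
        virtual_partner=virtual,
        stereo_tag=base.stereo_tag,
    )


_PATCHED_NAMES = {("LYS", "NZ"): "LYX", ("CYS", "SG"): "CYX"}

STANDARD_RESIDUES = tuple(_SIDECHAINS)
NUCLEOPHILE_VARIANTS = {"LYS": "LYX", "CYS": "CYX"}


def load_topology(name: str) -> ResidueTopology:
    """Return a built-in residue topology.

    Accepts the 20 standard residues, the two reacted-warhead stereoisomers
    ``MCR``/``MCS``, and the covalent nucleophile variants ``LYX``/``CYX``.
    """
    name = name.upper()
    if name in _SIDECHAINS:
        return _build_topology(name, _SIDECHAINS[name])
    if name == "MCR":
        return _build_topology(
            "MCR", _warhead_sidechain(+1.0), connect_atom="CZ",
            virtual_partner="VNZ", stereo_tag="R",
        )
    if name == "MCS":
        return _build_topology(
            "MCS", _warhead_sidechain(-1.0), connect_atom="CZ",
            virtual_partner="VNZ", stereo_tag="S",
        )
    if name == "LYX":
        return apply_patch(load_topology("LYS"), covalent_lysine_patch())
    if name == "CYX":
        return apply_patch(load_topology("CYS"), covalent_cysteine_patch())
    raise UnknownResidueError(f"unknown residue code {name!r}")


def warhead_topology(stereo: str, nucleophile: str = "LYS") -> ResidueTopology:
    """Warhead topology with the virtual partner idealized for the target.

    The virtual atom VNZ marks the ideal position of the incoming
    nucleophile atom: N at 1.47 A for a lysine amine, S at 1.81 A for a
    cysteine thiolate.
    """
    if stereo not in WARHEAD_CODES:
        raise UnknownResidueError(f"stereo must be one of {WARHEAD_CODES}, got {stereo!r}")
    top = load_topology(stereo)
    if nucleophile.upper().startswith("CYS") or nucleophile.upper() == "CYX":
        top.icoor = [
            replace(ic, bond_length=_CS) if ic.atom == "VNZ" else ic for ic in top.icoor
        ]
    return top


def build_sidechain(
    topology: ResidueTopology,
    backbone_anchor: Mapping[str, np.ndarray] | Sequence[np.ndarray],
    chi: Sequence[float],
) -> list[AtomRecord]:
    """Place every topology atom from the N/CA/C anchor and a chi vector.

    Atoms are placed in internal-coordinate order; entries whose reference
    quadruple matches a chi definition take their torsion from ``chi``.
    Returns records for all placed atoms, virtual ones included.
    """
    chi = np.asarray(chi, dtype=float)
    if chi.shape != (topology.n_chi,):
        raise ValueError(
            f"{topology.name} has {topology.n_chi} chi angles, got vector of {chi.shape}"
        )
    if isinstance(backbone_anchor, Mapping):
        positions = {k: np.asarray(v, dtype=float) for k, v in backbone_anchor.items()}
    else:
        n, ca, c = backbone_anchor
        positions = {
            "N": np.asarray(n, dtype=float),
            "CA": np.asarray(ca, dtype=float),
            "C": np.asarray(c, dtype=float),
        }
    chi_lookup = {chidef.atoms: value for chidef, value in zip(topology.chi_definitions, chi)}
    records: list[AtomRecord] = []
    for ic in topology.icoor:
        key = (ic.ref1, ic.ref2, ic.ref3, ic.atom)
        torsion = chi_lookup.get(key, ic.torsion)
        if torsion != ic.torsion:
            ic = replace(ic, torsion=_wrap_angle(torsion))
        pos = place_atom(positions[ic.ref1], positions[ic.ref2], positions[ic.ref3], ic)
        positions[ic.atom] = pos
        records.append(
            AtomRecord(
                name=ic.atom,
                element=topology.element_of(ic.atom),
                position=pos,
                is_virtual=topology.is_virtual(ic.atom),
            )
        )
    return records


def _wrap_angle(a: float) -> float:
    a = (float(a) + 180.0) % 360.0 - 180.0
    return 180.0 if a == -180.0 else a


def measure_chis(
    topology: ResidueTopology, positions: Mapping[str, np.ndarray]
) -> np.ndarray:
    """Re-measure every chi angle from placed coordinates."""
    return np.array(
        [
            dihedral_angle(*(positions[a] for a in chi.atoms))
            for chi in topology.chi_definitions
        ]
    )


# ---------------------------------------------------------------------------
# masses
# ---------------------------------------------------------------------------

#: element -> (monoisotopic Da, average Da); IUPAC standard atomic weights
ELEMENT_MASSES: dict[str, tuple[float, float]] = {
    "H": (1.00782503207, 1.008),
    "C": (12.0, 12.011),
    "N": (14.0030740048, 14.007),
    "O": (15.9949146196, 15.999),
    "S": (31.97207100, 32.06),
    "P": (30.97376163, 30.973762),
    "Cl": (34.96885268, 35.45),
    "Br": (78.9183371, 79.904),
    "Na": (22.9897692809, 22.98976928),
    "K": (38.96370668, 39.0983),
    "Se": (79.9165213, 78.971),
}

#: one-letter code -> residue (chain-internal) elemental formula
RESIDUE_FORMULAS: dict[str, str] = {
    "G": "C2H3NO",
    "A": "C3H5NO",
    "S": "C3H5NO2",
    "P": "C5H7NO",
    "V": "C5H9NO",
    "T": "C4H7NO2",
    "C": "C3H5NOS",
    "L": "C6H11NO",
    "I": "C6H11NO",
    "N": "C4H6N2O2",
    "D": "C4H5NO3",
    "Q": "C5H8N2O2",
    "K": "C6H12N2O",
    "E": "C5H7NO3",
    "M": "C5H9NOS",
    "H": "C6H7N3O",
    "F": "C9H9NO",
    "R": "C6H12N4O",
    "Y": "C9H9NO2",
    "W": "C11H10N2O",
}

#: named modification -> signed atom-count delta
MODIFICATION_DELTAS: dict[str, dict[str, int]] = {
    "Ac-": {"C": 2, "H": 2, "O": 1},          # N-terminal acetylation
    "-NH2": {"N": 1, "H": 1, "O": -1},        # C-terminal amidation
    "phospho": {"H": 1, "P": 1, "O": 3},      # pS / pT
    "mC": {"C": 6, "H": 8, "O": 2},           # thioether methacrylate ester on Cys
}

#: gamma-chloroacetamido-diaminobutyric acid, as a whole residue formula
DAB_CHLOROACETAMIDE_FORMULA = "C6H9ClN2O2"

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str | Mapping[str, int]) -> dict[str, int]:
    """Parse ``"C6H8O2"`` into ``{"C": 6, "H": 8, "O": 2}``."""
    if isinstance(formula, Mapping):
        return {el: int(n) for el, n in formula.items() if n != 0}
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_RE.finditer(formula):
        if m.start() != pos:
            raise ValueError(f"unparseable formula {formula!r} at position {pos}")
        pos = m.end()
        counts[m.group(1)] = counts.get(m.group(1), 0) + (int(m.group(2)) if m.group(2) else 1)
    if pos != len(formula):
        raise ValueError(f"unparseable formula {formula!r}")
    return counts


def formula_add(a, b) -> dict[str, int]:
    out = dict(parse_formula(a))
    for el, n in parse_formula(b).items():
        out[el] = out.get(el, 0) + n
    return {el: n for el, n in out.items() if n != 0}


def formula_subtract(a, b) -> dict[str, int]:
    return formula_add(a, {el: -n for el, n in parse_formula(b).items()})


def fragment_mass(formula: str | Mapping[str, int], mode: str = "monoisotopic") -> float:
    """Mass of an elemental formula in Da (``monoisotopic`` or ``average``)."""
    if mode not in ("monoisotopic", "average"):
        raise ValueError(f"mode must be 'monoisotopic' or 'average', got {mode!r}")
    idx = 0 if mode == "monoisotopic" else 1
    total = 0.0
    for el, n in parse_formula(formula).items():
        if el not in ELEMENT_MASSES:
            raise ChemistryError(f"unknown element {el!r}")
        total += ELEMENT_MASSES[el][idx] * n
    return total


# ---------------------------------------------------------------------------
# plain-text topology format
# ---------------------------------------------------------------------------

def topology_to_text(top: ResidueTopology) -> str:
    """Serialize a topology to the package's line-oriented text format.

    One record per line: NAME, STEREO, ATOM name element [VIRTUAL],
    BOND a b, ICOOR atom ref1 ref2 ref3 length angle torsion,
    CHI i a b c d [PROTON], CONNECT atom, VIRTUAL_PARTNER atom. New
    electrophile chemotypes can be added as text files without code changes.
    """
    lines = [f"NAME {top.name}", f"STEREO {top.stereo_tag}"]
    for name, el, virt in top.atoms:
        lines.append(f"ATOM {name} {el}" + (" VIRTUAL" if virt else ""))
    for a, b in top.bonds:
        lines.append(f"BOND {a} {b}")
    for ic in top.icoor:
        lines.append(
            f"ICOOR {ic.atom} {ic.ref1} {ic.ref2} {ic.ref3} "
            f"{ic.bond_length:.4f} {ic.bond_angle:.3f} {ic.torsion:.3f}"
        )
    for i, chi in enumerate(top.chi_definitions, 1):
        lines.append(
            f"CHI {i} {' '.join(chi.atoms)}" + (" PROTON" if chi.proton else "")
        )
    if top.connect_atom:
        lines.append(f"CONNECT {top.connect_atom}")
    if top.virtual_partner:
        lines.append(f"VIRTUAL_PARTNER {top.virtual_partner}")
    return "\n".join(lines) + "\n"


def topology_from_text(text: str) -> ResidueTopology:
    name = ""
    stereo = "none"
    atoms: list[tuple[str, str, bool]] = []
    bonds: list[tuple[str, str]] = []
    icoor: list[InternalCoordinate] = []
    chis: dict[int, ChiDefinition] = {}
    connect = None
    virtual = None
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        fields = line.split()
        tag = fields[0]
        try:
            if tag == "NAME":
                name = fields[1]
            elif tag == "STEREO":
                stereo = fields[1]
            elif tag == "ATOM":
                atoms.append((fields[1], fields[2], len(fields) > 3 and fields[3] == "VIRTUAL"))
            elif tag == "BOND":
                bonds.append((fields[1], fields[2]))
            elif tag == "ICOOR":
                icoor.append(
                    _ic(fields[1], fields[2], fields[3], fields[4],
                        float(fields[5]), float(fields[6]), float(fields[7]))
                )
            elif tag == "CHI":
                chis[int(fields[1])] = ChiDefinition(
                    atoms=tuple(fields[2:6]), proton="PROTON" in fields[6:]
                )
            elif tag == "CONNECT":
                connect = fields[1]
            elif tag == "VIRTUAL_PARTNER":
                virtual = fields[1]
            else:
                raise ValueError(f"unknown record {tag!r}")
        except (IndexError, ValueError) as exc:
            raise ChemistryError(f"topology text line {lineno}: {exc}") from exc
    if not name:
        raise ChemistryError("topology text lacks a NAME record")
    return ResidueTopology(
        name=name,
        atoms=atoms,
        bonds=bonds,
        icoor=icoor,
        chi_definitions=[chis[k] for k in sorted(chis)],
        connect_atom=connect,
        virtual_partner=virtual,
        stereo_tag=stereo,
    )
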