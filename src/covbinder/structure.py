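"""Macromolecular complex structures: read, represent, select, write.

A :class:`StructureComplex` holds the receptor chains and the single ligand
chain of a receptor-ligand complex with author residue numbering preserved
exactly as deposited, so that residue labels like "Lys122" or "positions
126-131" mean the same thing here as in the deposited entry.

Parsing is delegated to :mod:`gemmi`; writing is a compact fixed-width
serializer because designed models need LINK records for the engineered
covalent bond, REMARK score blocks, and an explicit policy for virtual
(non-physical) atoms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import gemmi
import numpy as np

__all__ = [
    "StructureError",
    "ChainAbsentError",
    "FormatError",
    "LookupStructureError",
    "MissingAtomError",
    "AtomRecord",
    "ResidueRecord",
    "StructureComplex",
    "CovalentLink",
    "read_structure",
    "write_structure",
    "select_residue",
]

WATER_NAMES = {"HOH", "WAT", "DOD"}


class StructureError(Exception):
    """Base class for structure-handling failures."""


class ChainAbsentError(StructureError):
    """A declared receptor or ligand chain is absent from the input."""


class FormatError(StructureError):
    """Unparseable or unserializable PDB content."""


class LookupStructureError(StructureError, KeyError):
    """Residue lookup failed or was ambiguous."""


class MissingAtomError(StructureError, KeyError):
    """A required atom is absent from a residue."""


@dataclass(frozen=True)
class AtomRecord:
    name: str
    element: str
    position: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""
    is_virtual: bool = False

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"atom {self.name}: position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name}: occupancy {self.occupancy} outside [0, 1]")

    def moved_to(self, position) -> "AtomRecord":
        return replace(self, position=np.asarray(position, dtype=float))


@dataclass
class ResidueRecord:
    chain_id: str
    seq_number: int
    name: str
    atoms: list[AtomRecord] = field(default_factory=list)
    insertion_code: str = ""

    def __post_init__(self):
        names = [a.name for a in self.atoms]
        if len(names) != len(set(names)):
            raise ValueError(
                f"duplicate atom names in {self.name} {self.chain_id}{self.seq_number}"
            )

    @property
    def label(self) -> str:
        return f"{self.chain_id}{self.seq_number}{self.insertion_code}"

    def get_atom(self, name: str) -> Optional[AtomRecord]:
        for atom in self.atoms:
            if atom.name == name:
                return atom
        return None

    def atom_position(self, name: str) -> np.ndarray:
        atom = self.get_atom(name)
        if atom is None:
            raise MissingAtomError(
                f"residue {self.name} {self.chain_id}{self.seq_number} has no atom {name!r}"
            )
        return atom.position

    def heavy_atoms(self) -> list[AtomRecord]:
        return [a for a in self.atoms if a.element != "H" and not a.is_virtual]


@dataclass(frozen=True)
class CovalentLink:
    """One engineered covalent bond, serialized as a PDB LINK record."""

    chain_a: str
    resnum_a: int
    resname_a: str
    atom_a: str
    chain_b: str
    resnum_b: int
    resname_b: str
    atom_b: str


@dataclass
class StructureComplex:
    receptor_chains: list[str]
    ligand_chain: str
    residues: list[ResidueRecord]
    source_id: str = ""

    def __post_init__(self):
        if self.ligand_chain in self.receptor_chains:
            raise ValueError(f"ligand chain {self.ligand_chain!r} also declared as receptor")
        present = {r.chain_id for r in self.residues}
        for cid in [*self.receptor_chains, self.ligand_chain]:
            if cid not in present:
                raise ChainAbsentError(f"declared chain {cid!r} has no residues")

    def chain_residues(self, chain_id: str) -> list[ResidueRecord]:
        return [r for r in self.residues if r.chain_id == chain_id]

    @property
    def ligand_residues(self) -> list[ResidueRecord]:
        return self.chain_residues(self.ligand_chain)

    @property
    def receptor_residues(self) -> list[ResidueRecord]:
        return [r for r in self.residues if r.chain_id in self.receptor_chains]

    def copy(self) -> "StructureComplex":
        return StructureComplex(
            receptor_chains=list(self.receptor_chains),
            ligand_chain=self.ligand_chain,
            residues=[
                ResidueRecord(
                    chain_id=r.chain_id,
                    seq_number=r.seq_number,
                    name=r.name,
                    atoms=list(r.atoms),
                    insertion_code=r.insertion_code,
                )
                for r in self.residues
            ],
            source_id=self.source_id,
        )


def _resolve_altlocs(residue: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep one copy per atom name: highest occupancy, ties by altloc order."""
    by_name: dict[str, gemmi.Atom] = {}
    for atom in residue:
        prev = by_name.get(atom.name)
        if prev is None:
            by_name[atom.name] = atom
        elif (atom.occ, _altloc_rank(atom)) > (prev.occ, _altloc_rank(prev)):
            by_name[atom.name] = atom
    return list(by_name.values())


def _altloc_rank(atom: gemmi.Atom) -> int:
    # 'A' must beat 'B' on an occupancy tie: rank by negated codepoint
    return -ord(atom.altloc) if atom.altloc else 0


def read_structure(
    source: str | Path,
    receptor_chains: Sequence[str],
    ligand_chain: str,
    source_id: str = "",
) -> StructureComplex:
    """Parse PDB text (or a path to it) into a :class:`StructureComplex`.

    Only the first MODEL is kept; altlocs are resolved to a single copy per
    atom (highest occupancy, 'A' winning ties); waters and non-polymer
    HETATM groups are dropped. Author numbering and insertion codes are
    preserved verbatim.
    """
    text = None
    if isinstance(source, Path) or (
        isinstance(source, str)
        and source.strip()
        and "\n" not in source
        and Path(source).is_file()
    ):
        text = Path(source).read_text()
        if not source_id:
            source_id = Path(source).stem
    else:
        text = str(source)
    if not text.strip():
        raise FormatError("empty PDB input")
    try:
        st = gemmi.read_pdb_string(text)
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"unparseable PDB input: {exc}") from exc
    if len(st) == 0:
        raise FormatError("PDB input contains no model")
    st.setup_entities()
    model = st[0]

    residues: list[ResidueRecord] = []
    for chain in model:
        for res in chain:
            if res.name in WATER_NAMES:
                continue
            # drop non-polymer HETATM groups; keep modified amino acids
            if res.het_flag == "H":
                tab = gemmi.find_tabulated_residue(res.name)
                if tab is None or not tab.is_amino_acid():
                    continue
            atoms = [
                AtomRecord(
                    name=a.name,
                    element=a.element.name,
                    position=np.array([a.pos.x, a.pos.y, a.pos.z]),
                    occupancy=min(max(a.occ, 0.0), 1.0),
                    altloc=a.altloc.strip("\x00") if a.altloc else "",
                )
                for a in _resolve_altlocs(res)
            ]
            residues.append(
                ResidueRecord(
                    chain_id=chain.name,
                    seq_number=res.seqid.num,
                    name=res.name,
                    atoms=atoms,
                    insertion_code=(res.seqid.icode or "").strip(),
                )
            )

    present = {r.chain_id for r in residues}
    for cid in [*receptor_chains, ligand_chain]:
        if cid not in present:
            raise ChainAbsentError(
                f"declared chain {cid!r} not found in input (chains present: {sorted(present)})"
            )
    return StructureComplex(
        receptor_chains=list(receptor_chains),
        ligand_chain=ligand_chain,
        residues=residues,
        source_id=source_id,
    )


def select_residue(
    complex_: StructureComplex,
    chain: str,
    number: int,
    insertion_code: Optional[str] = None,
) -> ResidueRecord:
    """Return the unique residue at (chain, number[, insertion code])."""
    hits = [
        r
        for r in complex_.residues
        if r.chain_id == chain
        and r.seq_number == number
        and (insertion_code is None or r.insertion_code == insertion_code)
    ]
    if not hits:
        raise LookupStructureError(f"no residue {number} in chain {chain!r}")
    if len(hits) > 1:
        codes = sorted(repr(r.insertion_code) for r in hits)
        raise LookupStructureError(
            f"residue {chain}{number} is ambiguous (insertion codes {codes}); "
            "pass insertion_code to disambiguate"
        )
    return hits[0]


def _format_atom_line(
    serial: int, atom: AtomRecord, res: ResidueRecord, hetatm: bool = False
) -> str:
    x, y, z = atom.position
    for v in (x, y, z):
        if abs(v) >= 10000.0:
            raise FormatError(
                f"coordinate {v:.3f} of atom {atom.name} exceeds the fixed-width PDB field"
            )
    name = atom.name
    # PDB alignment rule: 1-letter elements start in column 14
    padded = f" {name:<3s}" if len(name) < 4 and len(atom.element) == 1 else f"{name:<4s}"
    record = "HETATM" if hetatm else "ATOM  "
    return (
        f"{record}{serial:>5d} {padded}{atom.altloc or ' '}{res.name:>3s} "
        f"{res.chain_id:1s}{res.seq_number:>4d}{res.insertion_code or ' '}   "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{0.0:6.2f}"
        f"          {atom.element:>2s}"
    )


def _format_link(link: CovalentLink) -> str:
    return (
        f"LINK        {link.atom_a:<4s}{'':1s}{link.resname_a:>3s} "
        f"{link.chain_a:1s}{link.resnum_a:>4d}{'':16s}"
        f"{link.atom_b:<4s}{'':1s}{link.resname_b:>3s} "
        f"{link.chain_b:1s}{link.resnum_b:>4d}{'':19s}"
    )


def write_structure(
    complex_: StructureComplex,
    covalent_links: Iterable[CovalentLink] = (),
    remarks: Iterable[str] = (),
    include_virtual: bool = False,
) -> str:
    """Serialize to PDB text; round-trip safe to 3-decimal coordinates.

    Virtual atoms are refused unless ``include_virtual`` is set, in which
    case they are emitted as zero-occupancy HETATM records so that standard
    tools ignore them.
    """
    lines: list[str] = []
    for remark in remarks:
        lines.append(f"REMARK 999 {remark}"[:80])
    for link in covalent_links:
        lines.append(_format_link(link))
    serial = 0
    last_chain = None
    for res in complex_.residues:
        if last_chain is not None and res.chain_id != last_chain:
            lines.append("TER")
        last_chain = res.chain_id
        for atom in res.atoms:
            if atom.is_virtual and not include_virtual:
                raise FormatError(
                    f"virtual atom {atom.name} in {res.label} cannot be serialized "
                    "without include_virtual=True"
                )
            serial += 1
            if atom.is_virtual:
                virt = replace(atom, occupancy=0.0)
                lines.append(_format_atom_line(serial, virt, res, hetatm=True))
            else:
                lines.append(_format_atom_line(serial, atom, res))
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"
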