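"""The covalent design engine.

Given a receptor-ligand complex, a target nucleophile (lysine NZ or
cysteine SG) and a ligand position to carry the methacrylate warhead, the
engine

1. enumerates installable ligand positions by the Calpha-Calpha < 14 A rule,
2. rebuilds the warhead and reacted-nucleophile side chains from idealized
   internal coordinates,
3. samples their chi angles by seeded random rotamer-grid restarts followed
   by coordinate-descent minimisation of a weighted sum of the covalent
   harmonic restraint score and a 12-6 interface proxy score, and
4. selects designs with the published geometric filters: harmonic
   constraint score < 2 and interface backbone RMSD < 1 A among the top
   interface-scoring models.

The harmonic restraints tether each real covalent-bond atom to the virtual
placeholder marking its ideal position in the partnering residue, centred
at 0 with standard deviation 0.3 A, so a perfectly formed covalent adduct
scores exactly zero.

The interface score is an explicit 12-6 proxy (per-element radii, well
depth 0.1 per pair, repulsion capped at +10 per pair, 6 A cutoff), not a
physics-grade force field: absolute values are meaningful only for ranking
models of the same complex.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from . import chemistry
from .chemistry import RotamerGrid, load_topology
from .geometry import _place as _geom_place
from .geometry import ca_distance, kabsch_superpose
from .structure import (
    AtomRecord,
    MissingAtomError,
    ResidueRecord,
    StructureComplex,
    select_residue,
)

__all__ = [
    "DesignError",
    "UnsupportedNucleophileError",
    "EmptyInterfaceError",
    "CovalentConstraint",
    "DesignTask",
    "ModelRecord",
    "DesignReport",
    "ReportEntry",
    "enumerate_positions",
    "filter_complexes",
    "make_covalent_constraints",
    "constraint_score",
    "interface_score",
    "interface_bb_rmsd",
    "sample_models",
    "select_designs",
    "mutate_ligand_cysteines_to_serine",
    "ELEMENT_RADII",
    "NUCLEOPHILE_ATOMS",
]

#: per-element van der Waals radii (A) of the interface proxy
ELEMENT_RADII = {"C": 1.7, "N": 1.55, "O": 1.52, "S": 1.8, "P": 1.8}
_DEFAULT_RADIUS = 1.7
_WELL_DEPTH = 0.1
_REPULSION_CAP = 10.0
_INTERFACE_CUTOFF = 6.0
#: a model whose minimised constraint score stays above this is geometrically
#: unreachable (both covalent pairs > ~2 A from their anchors)
UNSATISFIABLE_CONSTRAINT = 100.0

NUCLEOPHILE_ATOMS = {"LYS": "NZ", "LYX": "NZ", "CYS": "SG", "CYX": "SG"}


class DesignError(Exception):
    pass


class UnsupportedNucleophileError(DesignError):
    pass


class EmptyInterfaceError(DesignError):
    pass


ResidueRef = tuple[str, int]  # (chain id, author residue number)


@dataclass(frozen=True)
class CovalentConstraint:
    """Harmonic tether between a real atom and a virtual placeholder."""

    real_atom: tuple[ResidueRef, str]
    virtual_anchor: tuple[ResidueRef, str]
    x0: float = 0.0
    sd: float = 0.3

    def __post_init__(self):
        if not self.sd > 0:
            raise ValueError("constraint sd must be > 0")


@dataclass
class DesignTask:
    complex: StructureComplex
    target: ResidueRef
    position: int
    stereo: str = "both"  # MCR | MCS | both
    n_models: int = 100
    seed: int = 0
    weights: dict = field(default_factory=lambda: {"constraint": 1.0, "interface": 1.0})

    def __post_init__(self):
        if self.n_models < 1:
            raise ValueError("n_models must be >= 1")
        if self.stereo not in ("MCR", "MCS", "both"):
            raise ValueError(f"stereo must be MCR, MCS or both, got {self.stereo!r}")
        chain, num = self.target
        if chain not in self.complex.receptor_chains:
            raise ValueError(f"target chain {chain!r} is not a receptor chain")
        if not any(
            r.seq_number == self.position for r in self.complex.ligand_residues
        ):
            raise ValueError(f"position {self.position} not in ligand chain")

    @property
    def stereo_tags(self) -> tuple[str, ...]:
        return chemistry.WARHEAD_CODES if self.stereo == "both" else (self.stereo,)


@dataclass
class ModelRecord:
    coordinates: dict  # (chain, resnum, atom name) -> 3-vector
    constraint_score: float
    interface_score: float
    clash_score: float
    interface_bb_rmsd: float
    stereo: str
    model_index: int
    position: int
    chi_warhead: np.ndarray = None
    chi_nucleophile: np.ndarray = None
    unsatisfiable: bool = False

    def __post_init__(self):
        if self.constraint_score < 0 or self.interface_bb_rmsd < 0:
            raise ValueError("scores out of range")


@dataclass
class ReportEntry:
    position: int
    stereo: str
    model_index: int
    constraint_score: float
    interface_score: float
    clash_score: float
    interface_bb_rmsd: float
    rank: int
    passes_constraint: bool
    passes_rmsd: bool

    @property
    def passes(self) -> bool:
        return self.passes_constraint and self.passes_rmsd


@dataclass
class DesignReport:
    entries: list[ReportEntry]
    n_models: int
    top_k: int
    max_constraint: float
    max_rmsd: float

    @property
    def n_passing(self) -> int:
        return sum(e.passes for e in self.entries)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "rank": e.rank,
                    "position": e.position,
                    "stereo": e.stereo,
                    "model": e.model_index,
                    "interface_score": e.interface_score,
                    "constraint_score": e.constraint_score,
                    "clash_score": e.clash_score,
                    "interface_bb_rmsd": e.interface_bb_rmsd,
                    "pass_constraint": e.passes_constraint,
                    "pass_rmsd": e.passes_rmsd,
                    "pass": e.passes,
                }
                for e in self.entries
            ]
        )


# ---------------------------------------------------------------------------
# enumeration & structure filtering
# ---------------------------------------------------------------------------

def enumerate_positions(
    complex_: StructureComplex, target: ResidueRef, cutoff: float = 14.0
) -> list[int]:
    """Ligand residue numbers whose CA lies strictly within ``cutoff`` of
    the target residue's CA, in ascending author numbering."""
    target_res = select_residue(complex_, *target)
    if target_res.get_atom("CA") is None:
        raise MissingAtomError(f"target residue {target} has no CA atom")
    hits = [
        res.seq_number
        for res in complex_.ligand_residues
        if res.get_atom("CA") is not None and ca_distance(target_res, res) < cutoff
    ]
    return sorted(hits)


def filter_complexes(
    candidates: Iterable[StructureComplex],
    near: tuple[ResidueRef, float] = None,
    far: tuple[ResidueRef, float] = None,
    near_cutoff: float = 14.0,
    far_cutoff: float = 12.0,
) -> list[StructureComplex]:
    """Keep complexes whose ligand approaches the ``near`` residue (< 14 A
    for at least one ligand CA) while staying clear of the ``far`` residue
    (no ligand CA at <= 12 A).

    This is the template-selection rule used to pick structures binding
    near the reactive lysine but away from the competing cysteine.
    """
    near_ref, near_cut = (near[0], near[1]) if near else (None, near_cutoff)
    far_ref, far_cut = (far[0], far[1]) if far else (None, far_cutoff)
    kept = []
    for cx in candidates:
        ok = True
        if near_ref is not None:
            near_res = select_residue(cx, *near_ref)
            ok = any(
                ca_distance(near_res, r) < near_cut
                for r in cx.ligand_residues
                if r.get_atom("CA") is not None
            )
        if ok and far_ref is not None:
            far_res = select_residue(cx, *far_ref)
            ok = all(
                ca_distance(far_res, r) > far_cut
                for r in cx.ligand_residues
                if r.get_atom("CA") is not None
            )
        if ok:
            kept.append(cx)
    return kept


def mutate_ligand_cysteines_to_serine(
    complex_: StructureComplex, keep_position: int
) -> StructureComplex:
    """Mutate every native ligand cysteine except ``keep_position`` to
    serine (SG renamed to OG), avoiding side reactions with the second
    thiol once the warhead is installed."""
    out = complex_.copy()
    for res in out.ligand_residues:
        if res.name == "CYS" and res.seq_number != keep_position:
            res.name = "SER"
            res.atoms = [
                AtomRecord(
                    name="OG", element="O", position=a.position, occupancy=a.occupancy
                )
                if a.name == "SG"
                else a
                for a in res.atoms
                if a.name != "HG"
            ]
    return out


# ---------------------------------------------------------------------------
# constraints & scores
# ---------------------------------------------------------------------------

def make_covalent_constraints(task: DesignTask) -> list[CovalentConstraint]:
    """The two harmonic tethers enforcing the covalent bond geometry:
    warhead connect carbon <-> virtual anchor on the nucleophile, and
    nucleophile bonding atom (NZ/SG) <-> virtual anchor on the warhead."""
    target_res = select_residue(task.complex, *task.target)
    if target_res.name not in NUCLEOPHILE_ATOMS:
        raise UnsupportedNucleophileError(
            f"target residue {target_res.name} at {task.target} is not Lys or Cys"
        )
    nuc_atom = NUCLEOPHILE_ATOMS[target_res.name]
    warhead = load_topology("MCR")  # MCR/MCS share connect and virtual names
    nuc_variant = load_topology(chemistry.NUCLEOPHILE_VARIANTS[target_res.name[:3]])
    position_ref: ResidueRef = (task.complex.ligand_chain, task.position)
    return [
        CovalentConstraint(
            real_atom=(position_ref, warhead.connect_atom),
            virtual_anchor=(task.target, nuc_variant.virtual_partner),
        ),
        CovalentConstraint(
            real_atom=(task.target, nuc_atom),
            virtual_anchor=(position_ref, warhead.virtual_partner),
        ),
    ]


def _coord(coordinates, ref: tuple[ResidueRef, str]) -> np.ndarray:
    (chain, num), atom = ref
    key = (chain, num, atom)
    if key not in coordinates:
        raise MissingAtomError(f"atom {atom} of {chain}{num} not placed")
    return np.asarray(coordinates[key], dtype=float)


def constraint_score(coordinates, constraints: Sequence[CovalentConstraint]) -> float:
    """Sum of ((d - x0) / sd)^2 over the covalent-pair restraints."""
    total = 0.0
    for cst in constraints:
        d = float(
            np.linalg.norm(_coord(coordinates, cst.real_atom) - _coord(coordinates, cst.virtual_anchor))
        )
        total += ((d - cst.x0) / cst.sd) ** 2
    return total


def _pair_energies(pos_a, radii_a, pos_b, radii_b, exclude=None):
    """Vectorized 12-6 energies for all a-b pairs within the cutoff.

    ``exclude`` is an optional boolean (len(a), len(b)) matrix of pairs to
    skip — used for atoms bonded through the engineered covalent link.
    """
    if len(pos_a) == 0 or len(pos_b) == 0:
        return 0.0, 0.0
    diff = pos_a[:, None, :] - pos_b[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    rmin = radii_a[:, None] + radii_b[None, :]
    mask = d2 < _INTERFACE_CUTOFF**2
    if exclude is not None:
        mask &= ~exclude
    if not mask.any():
        return 0.0, 0.0
    d2 = np.maximum(d2[mask], 1e-6)
    s6 = (rmin[mask] ** 2 / d2) ** 3
    e = _WELL_DEPTH * (s6 * s6 - 2.0 * s6)
    e = np.minimum(e, _REPULSION_CAP)
    return float(e.sum()), float(e[e > 0].sum())


def _atom_arrays(atoms: Iterable[tuple[np.ndarray, str]]):
    pts, radii = [], []
    for pos, element in atoms:
        pts.append(pos)
        radii.append(ELEMENT_RADII.get(element, _DEFAULT_RADIUS))
    if not pts:
        return np.zeros((0, 3)), np.zeros(0)
    return np.asarray(pts, dtype=float), np.asarray(radii, dtype=float)


def interface_score(
    coordinates,
    complex_: StructureComplex,
    elements: Optional[dict] = None,
) -> float:
    """12-6 proxy interface score over receptor-ligand heavy-atom pairs.

    ``coordinates`` maps (chain, resnum, atom) to positions; ``elements``
    optionally maps the same keys to element symbols for atoms not present
    in the complex (rebuilt side chains). Lower is better; an empty
    interface scores 0.
    """
    elem_lookup = dict(elements or {})
    for res in complex_.residues:
        for atom in res.atoms:
            elem_lookup.setdefault((res.chain_id, res.seq_number, atom.name), atom.element)
    rec, lig = [], []
    for key, pos in coordinates.items():
        chain = key[0]
        el = elem_lookup.get(key, "C")
        if el == "H" or el == "X":
            continue
        if chain in complex_.receptor_chains:
            rec.append((np.asarray(pos), el))
        elif chain == complex_.ligand_chain:
            lig.append((np.asarray(pos), el))
    (pa, ra), (pb, rb) = _atom_arrays(rec), _atom_arrays(lig)
    total, _ = _pair_energies(pa, ra, pb, rb)
    return total


def _backbone_coords(residues: Iterable[ResidueRecord], atom_names=("N", "CA", "C", "O")):
    pts = []
    for res in residues:
        for name in atom_names:
            atom = res.get_atom(name)
            if atom is not None:
                pts.append(atom.position)
    return np.asarray(pts, dtype=float)


def interface_bb_rmsd(
    model_coordinates,
    template: StructureComplex,
    interface_cutoff: float = 8.0,
) -> float:
    """Backbone RMSD (N, CA, C, O) of interface ligand residues after
    superposing the model onto the template by receptor backbone.

    Interface residues are the template ligand residues with any heavy atom
    within ``interface_cutoff`` of any receptor heavy atom.
    """
    rec_heavy = np.asarray(
        [a.position for r in template.receptor_residues for a in r.heavy_atoms()]
    )
    interface = []
    for res in template.ligand_residues:
        pts = np.asarray([a.position for a in res.heavy_atoms()])
        if len(pts) and len(rec_heavy):
            d2 = ((pts[:, None, :] - rec_heavy[None, :, :]) ** 2).sum(-1)
            if (d2 < interface_cutoff**2).any():
                interface.append(res)
    if not interface:
        raise EmptyInterfaceError("no ligand residue within the interface cutoff")

    def model_pos(res: ResidueRecord, atom: str):
        return model_coordinates.get((res.chain_id, res.seq_number, atom))

    # superpose model onto template over receptor backbone
    mov, fix = [], []
    for res in template.receptor_residues:
        for name in ("N", "CA", "C", "O"):
            t_atom = res.get_atom(name)
            m_pos = model_pos(res, name)
            if t_atom is not None and m_pos is not None:
                fix.append(t_atom.position)
                mov.append(m_pos)
    sup = kabsch_superpose(np.asarray(mov), np.asarray(fix))

    mov_bb, fix_bb = [], []
    for res in interface:
        for name in ("N", "CA", "C", "O"):
            t_atom = res.get_atom(name)
            m_pos = model_pos(res, name)
            if t_atom is not None and m_pos is not None:
                fix_bb.append(t_atom.position)
                mov_bb.append(m_pos)
    mov_bb = sup.apply(np.asarray(mov_bb))
    fix_bb = np.asarray(fix_bb)
    return float(np.sqrt(((mov_bb - fix_bb) ** 2).sum(-1).mean()))


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def _bond_distances(top, origin: str, max_depth: int = 2) -> dict[str, int]:
    """Bond-graph distance from ``origin`` for every atom within max_depth."""
    adj: dict[str, set] = {}
    for a, b in top.bonds:
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    dist = {origin: 0}
    frontier = [origin]
    for depth in range(1, max_depth + 1):
        nxt = []
        for u in frontier:
            for v in adj.get(u, ()):
                if v not in dist:
                    dist[v] = depth
                    nxt.append(v)
        frontier = nxt
    return dist


def _build_plan(top):
    """Flatten a topology into a fast placement plan, skipping backbone O."""
    chi_lookup = {c.atoms: k for k, c in enumerate(top.chi_definitions)}
    plan = []
    for ic in top.icoor:
        if ic.atom == "O":
            continue
        chi_idx = chi_lookup.get((ic.ref1, ic.ref2, ic.ref3, ic.atom))
        plan.append(
            (ic.atom, ic.ref1, ic.ref2, ic.ref3,
             ic.bond_length, ic.bond_angle, ic.torsion, chi_idx)
        )
    return plan


class _DesignSystem:
    """Pre-indexed scoring context for one (task, stereoisomer)."""

    def __init__(self, task: DesignTask, stereo: str, constraints):
        cx = task.complex
        self.task = task
        self.constraints = constraints
        self.stereo = stereo
        target_res = select_residue(cx, *task.target)
        self.warhead_top = chemistry.warhead_topology(stereo, target_res.name)
        self.nuc_top = load_topology(chemistry.NUCLEOPHILE_VARIANTS[target_res.name[:3]])
        self.position_res = select_residue(cx, cx.ligand_chain, task.position)
        self.target_res = target_res
        self.warhead_key = (cx.ligand_chain, task.position)
        self.nuc_key = task.target

        self.warhead_anchor = tuple(
            self.position_res.atom_position(a) for a in ("N", "CA", "C")
        )
        self.nuc_anchor = tuple(target_res.atom_position(a) for a in ("N", "CA", "C"))

        # static partition: everything except the two rebuilt side chains
        rec_static, lig_static = [], []
        self.static_coords: dict = {}
        for res in cx.residues:
            rebuilt = (res.chain_id, res.seq_number) in (self.warhead_key, self.nuc_key)
            for atom in res.atoms:
                if rebuilt and atom.name not in ("N", "CA", "C", "O"):
                    continue
                self.static_coords[(res.chain_id, res.seq_number, atom.name)] = atom.position
                if atom.element == "H" or atom.is_virtual:
                    continue
                entry = (atom.position, atom.element)
                if res.chain_id in cx.receptor_chains:
                    rec_static.append(entry)
                else:
                    lig_static.append(entry)
        self.rec_pts, self.rec_radii = _atom_arrays(rec_static)
        self.lig_pts, self.lig_radii = _atom_arrays(lig_static)
        self.static_interface, _ = _pair_energies(
            self.rec_pts, self.rec_radii, self.lig_pts, self.lig_radii
        )
        self.grid = RotamerGrid()
        self._w_plan = _build_plan(self.warhead_top)
        self._n_plan = _build_plan(self.nuc_top)
        # pairs bonded through the covalent link (1-2 / 1-3 / 1-4) are not
        # nonbonded contacts; exclude them from the interface proxy
        w_names = self._heavy_names(self.warhead_top)
        n_names = self._heavy_names(self.nuc_top)
        d_w = _bond_distances(self.warhead_top, self.warhead_top.connect_atom)
        d_n = _bond_distances(self.nuc_top, self.nuc_top.connect_atom)
        self._link_exclude = np.zeros((len(n_names), len(w_names)), dtype=bool)
        for i, nn in enumerate(n_names):
            for j, wn in enumerate(w_names):
                if d_n.get(nn, 99) + 1 + d_w.get(wn, 99) <= 3:
                    self._link_exclude[i, j] = True
        # constraint atoms expressed as (residue tag, atom name)
        self._cst_refs = []
        for c in self.constraints:
            refs = []
            for (ch, nu), at in (c.real_atom, c.virtual_anchor):
                if (ch, nu) == self.warhead_key:
                    refs.append(("w", at))
                elif (ch, nu) == self.nuc_key:
                    refs.append(("n", at))
                else:
                    refs.append(("static", (ch, nu, at)))
            self._cst_refs.append((refs[0], refs[1], c.x0, c.sd))

    def place(self, which: str, chi) -> dict:
        plan, anchor = (
            (self._w_plan, self.warhead_anchor)
            if which == "w"
            else (self._n_plan, self.nuc_anchor)
        )
        pos = {"N": anchor[0], "CA": anchor[1], "C": anchor[2]}
        for atom, r1, r2, r3, length, angle, torsion, chi_idx in plan:
            if chi_idx is not None:
                torsion = chi[chi_idx]
            pos[atom] = _geom_place(pos[r1], pos[r2], pos[r3], length, angle, torsion)
        return pos

    def constraint_of(self, pos_w: dict, pos_n: dict) -> float:
        cst = 0.0
        for ref_a, ref_b, x0, sd in self._cst_refs:
            pq = []
            for tag, at in (ref_a, ref_b):
                if tag == "w":
                    pq.append(pos_w[at])
                elif tag == "n":
                    pq.append(pos_n[at])
                else:
                    pq.append(self.static_coords[at])
            d = pq[0] - pq[1]
            d = np.sqrt(d @ d)
            cst += ((d - x0) / sd) ** 2
        return cst

    def score(self, pos_w: dict, pos_n: dict):
        cst = 0.0
        for ref_a, ref_b, x0, sd in self._cst_refs:
            pq = []
            for tag, at in (ref_a, ref_b):
                if tag == "w":
                    pq.append(pos_w[at])
                elif tag == "n":
                    pq.append(pos_n[at])
                else:
                    pq.append(self.static_coords[at])
            d = pq[0] - pq[1]
            d = np.sqrt(d @ d)
            cst += ((d - x0) / sd) ** 2
        wp = np.asarray([pos_w[a] for a in self._w_plan_heavy])
        np_ = np.asarray([pos_n[a] for a in self._n_plan_heavy])
        e1, c1 = _pair_energies(self.rec_pts, self.rec_radii, wp, self._w_radii)
        e2, c2 = _pair_energies(np_, self._n_radii, self.lig_pts, self.lig_radii)
        e3, c3 = _pair_energies(np_, self._n_radii, wp, self._w_radii, self._link_exclude)
        iface = self.static_interface + e1 + e2 + e3
        clash = c1 + c2 + c3
        return cst, iface, clash

    @property
    def _w_plan_heavy(self):
        return self._heavy_names(self.warhead_top)

    @property
    def _n_plan_heavy(self):
        return self._heavy_names(self.nuc_top)

    def _heavy_names(self, top):
        cache = getattr(self, "_heavy_cache", None)
        if cache is None:
            cache = self._heavy_cache = {}
        if top.name not in cache:
            names = [
                ic.atom
                for ic in top.icoor
                if ic.atom != "O"
                and top.element_of(ic.atom) != "H"
                and not top.is_virtual(ic.atom)
            ]
            radii = np.asarray(
                [ELEMENT_RADII.get(top.element_of(n), _DEFAULT_RADIUS) for n in names]
            )
            cache[top.name] = (names, radii)
        return cache[top.name][0]

    @property
    def _w_radii(self):
        self._heavy_names(self.warhead_top)
        return self._heavy_cache[self.warhead_top.name][1]

    @property
    def _n_radii(self):
        self._heavy_names(self.nuc_top)
        return self._heavy_cache[self.nuc_top.name][1]

    def records(self, which: str, pos: dict) -> list[AtomRecord]:
        top = self.warhead_top if which == "w" else self.nuc_top
        return [
            AtomRecord(
                name=ic.atom,
                element=top.element_of(ic.atom),
                position=pos[ic.atom],
                is_virtual=top.is_virtual(ic.atom),
            )
            for ic in top.icoor
            if ic.atom != "O"
        ]

    def full_coordinates(self, pos_w: dict, pos_n: dict):
        coords = dict(self.static_coords)
        chain_w, num_w = self.warhead_key
        chain_n, num_n = self.nuc_key
        for a in self.records("w", pos_w):
            coords[(chain_w, num_w, a.name)] = a.position
        for a in self.records("n", pos_n):
            coords[(chain_n, num_n, a.name)] = a.position
        return coords


# constraint-snap phase: large moves minimising the covalent restraints only
_SNAP_DELTAS = (
    (-120.0, -60.0, -30.0, 30.0, 60.0, 120.0),
    (-15.0, -5.0, 5.0, 15.0),
)
# joint polish: smaller moves on the weighted total score
_POLISH_DELTAS = (
    (-20.0, -7.0, 7.0, 20.0),
    (-2.0, 2.0),
)


def _optimize_model(system: _DesignSystem, rng, weights):
    wc = weights.get("constraint", 1.0)
    wi = weights.get("interface", 1.0)
    chi_w = system.grid.sample_vector(system.warhead_top, rng)
    chi_n = system.grid.sample_vector(system.nuc_top, rng)
    pos_w = system.place("w", chi_w)
    pos_n = system.place("n", chi_n)

    def sweep(delta_sets, objective):
        nonlocal pos_w, pos_n
        best = objective(pos_w, pos_n)
        for deltas in delta_sets:
            for which in ("w", "n"):
                vec = chi_w if which == "w" else chi_n
                for k in range(len(vec)):
                    current = vec[k]
                    for delta in deltas:
                        vec[k] = chemistry._wrap_angle(current + delta)
                        pos_trial = system.place(which, vec)
                        value = (
                            objective(pos_trial, pos_n)
                            if which == "w"
                            else objective(pos_w, pos_trial)
                        )
                        if value < best - 1e-12:
                            best = value
                            current = vec[k]
                            if which == "w":
                                pos_w = pos_trial
                            else:
                                pos_n = pos_trial
                    vec[k] = current
        return best

    # phase 1: snap the covalent tether shut
    sweep(_SNAP_DELTAS, system.constraint_of)
    # phase 2: refine the weighted total without abandoning the tether
    def total(pw, pn):
        cst, iface, _ = system.score(pw, pn)
        return wc * cst + wi * iface

    best_obj = sweep(_POLISH_DELTAS, total)
    best_state = system.score(pos_w, pos_n)
    return best_obj, (pos_w, pos_n, *best_state), chi_w.copy(), chi_n.copy()


def sample_models(
    task: DesignTask,
    constraints: Optional[Sequence[CovalentConstraint]] = None,
    template: Optional[StructureComplex] = None,
    weights: Optional[dict] = None,
) -> list[ModelRecord]:
    """Generate ``task.n_models`` scored models per requested stereoisomer.

    Each model starts from a seeded random rotamer-grid chi vector and is
    refined by coordinate descent; the per-model random stream is derived
    as ``task.seed + model_index`` so any subset is reproducible. Models
    whose minimised constraint score remains above
    :data:`UNSATISFIABLE_CONSTRAINT` are flagged unsatisfiable, not raised.
    """
    if constraints is None:
        constraints = make_covalent_constraints(task)
    if weights is None:
        weights = task.weights
    template = template or task.complex
    records: list[ModelRecord] = []
    for stereo in task.stereo_tags:
        system = _DesignSystem(task, stereo, constraints)
        for idx in range(task.n_models):
            rng = np.random.default_rng((task.seed + idx) % 2**31)
            _, (pos_w, pos_n, cst, iface, clash), chi_w, chi_n = _optimize_model(
                system, rng, weights
            )
            coords = system.full_coordinates(pos_w, pos_n)
            try:
                rmsd = interface_bb_rmsd(coords, template)
            except EmptyInterfaceError:
                rmsd = 0.0  # no interface to deviate from; constraints still flag
            records.append(
                ModelRecord(
                    coordinates=coords,
                    constraint_score=cst,
                    interface_score=iface,
                    clash_score=clash,
                    interface_bb_rmsd=rmsd,
                    stereo=stereo,
                    model_index=idx,
                    position=task.position,
                    chi_warhead=chi_w,
                    chi_nucleophile=chi_n,
                    unsatisfiable=cst > UNSATISFIABLE_CONSTRAINT,
                )
            )
    return records


def select_designs(
    models: Sequence[ModelRecord],
    top_k: int = 10,
    max_constraint: float = 2.0,
    max_rmsd: float = 1.0,
) -> DesignReport:
    """Rank by interface score (ascending) and flag the published filters.

    Both filters are strict: a constraint score of exactly 2.0 or an
    interface backbone RMSD of exactly 1.0 A fails. Ties in interface
    score break by lower constraint score, then lower model index.
    """
    if not models:
        raise DesignError("empty model list")
    ranked = sorted(
        models,
        key=lambda m: (m.interface_score, m.constraint_score, m.stereo, m.model_index),
    )
    entries = [
        ReportEntry(
            position=m.position,
            stereo=m.stereo,
            model_index=m.model_index,
            constraint_score=m.constraint_score,
            interface_score=m.interface_score,
            clash_score=m.clash_score,
            interface_bb_rmsd=m.interface_bb_rmsd,
            rank=rank,
            passes_constraint=m.constraint_score < max_constraint,
            passes_rmsd=m.interface_bb_rmsd < max_rmsd,
        )
        for rank, m in enumerate(ranked[:top_k], 1)
    ]
    return DesignReport(
        entries=entries,
        n_models=len(models),
        top_k=top_k,
        max_constraint=max_constraint,
        max_rmsd=max_rmsd,
    )
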