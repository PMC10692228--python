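"""Synthetic toy receptor-ligand complexes with a planted covalent adduct.

These generated complexes stand in for deposited crystal structures so the
whole design engine is testable without any downloads: an ideal-geometry
poly-alanine receptor helix carries the nucleophile (Lys or Cys) at a
chosen position, and the ligand strand is grown *outward from the reacted
warhead geometry itself*, so that one ligand position (the planted one)
admits a chi vector with constraint score exactly zero by construction.

The generator also returns the ground truth: the planted chi vectors for
both side chains and the set of ligand positions within the enumeration
cutoff of the target (computed by a direct all-pairs CA scan over its own
output).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chemistry import build_sidechain, load_topology, measure_chis, warhead_topology
from .geometry import InternalCoordinate, dihedral_angle, place_atom
from .structure import AtomRecord, ResidueRecord, StructureComplex

__all__ = ["ToyComplexSpec", "ToyGroundTruth", "GenerationError", "make_toy_complex"]

# backbone geometry constants (Engh-Huber-like ideal values)
_N_CA = 1.458
_CA_C = 1.524
_C_N = 1.329
_C_O = 1.231
_ANG_N_CA_C = 111.2
_ANG_CA_C_N = 116.2
_ANG_C_N_CA = 121.7
_ANG_CA_C_O = 120.5
_HELIX_PHI, _HELIX_PSI = -57.0, -47.0
_STRAND_PHI, _STRAND_PSI = -120.0, 120.0
_OMEGA = 180.0


class GenerationError(ValueError):
    pass


@dataclass(frozen=True)
class ToyComplexSpec:
    receptor_size: int = 30
    ligand_size: int = 8
    nucleophile: str = "LYS"          # LYS | CYS
    nucleophile_position: int = 15    # receptor residue number carrying it
    planted_position: int = 4         # ligand residue engineered for an ideal adduct
    seed: int = 0
    receptor_chain: str = "A"
    ligand_chain: str = "B"
    cutoff: float = 14.0


@dataclass
class ToyGroundTruth:
    planted_position: int
    within_cutoff_positions: list[int]
    chi_warhead: np.ndarray
    chi_nucleophile: np.ndarray
    warhead_stereo: str
    target: tuple[str, int] = ("A", 0)


def _ic(atom, r1, r2, r3, length, angle, torsion):
    return InternalCoordinate(atom, r1, r2, r3, length, angle, torsion)


def _grow_backbone(n_res: int, phi: float, psi: float, start=None):
    """Return per-residue dicts of N/CA/C positions for an ideal chain."""
    res = []
    if start is None:
        n = np.array([0.0, 0.0, 0.0])
        ca = np.array([_N_CA, 0.0, 0.0])
        ang = np.radians(_ANG_N_CA_C)
        c = ca + _CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
        res.append({"N": n, "CA": ca, "C": c})
    else:
        res.append(dict(start))
    while len(res) < n_res:
        prev = res[-1]
        n_next = place_atom(
            prev["N"], prev["CA"], prev["C"],
            _ic("N", "N", "CA", "C", _C_N, _ANG_CA_C_N, psi),
        )
        ca_next = place_atom(
            prev["CA"], prev["C"], n_next,
            _ic("CA", "CA", "C", "N", _N_CA, _ANG_C_N_CA, _OMEGA),
        )
        c_next = place_atom(
            prev["C"], n_next, ca_next,
            _ic("C", "C", "N", "CA", _CA_C, _ANG_N_CA_C, phi),
        )
        res.append({"N": n_next, "CA": ca_next, "C": c_next})
    return res


def _grow_backbone_backward(n_res: int, phi: float, psi: float, start):
    """Grow toward the N terminus from a seed residue (excluded from output)."""
    res = [dict(start)]
    while len(res) < n_res + 1:
        nxt = res[0]
        c_prev = place_atom(
            nxt["C"], nxt["CA"], nxt["N"],
            _ic("C", "C", "CA", "N", _C_N, _ANG_C_N_CA, phi),
        )
        ca_prev = place_atom(
            nxt["CA"], nxt["N"], c_prev,
            _ic("CA", "CA", "N", "C", _CA_C, _ANG_CA_C_N, _OMEGA),
        )
        n_prev = place_atom(
            nxt["N"], c_prev, ca_prev,
            _ic("N", "N", "C", "CA", _N_CA, _ANG_N_CA_C, psi),
        )
        res.insert(0, {"N": n_prev, "CA": ca_prev, "C": c_prev})
    return res[:-1]


def _residue_from_backbone(chain, num, name, bb, extra_atoms=()):
    o = place_atom(bb["N"], bb["CA"], bb["C"], _ic("O", "N", "CA", "C", _C_O, _ANG_CA_C_O, 180.0))
    atoms = [
        AtomRecord("N", "N", bb["N"]),
        AtomRecord("CA", "C", bb["CA"]),
        AtomRecord("C", "C", bb["C"]),
        AtomRecord("O", "O", o),
    ]
    atoms.extend(extra_atoms)
    return ResidueRecord(chain_id=chain, seq_number=num, name=name, atoms=atoms)


def _build_ala_cb(bb):
    pos = place_atom(bb["C"], bb["N"], bb["CA"], _ic("CB", "C", "N", "CA", 1.53, 110.5, -122.0))
    return [AtomRecord("CB", "C", pos)]


#: CB(warhead position) -> CB(nucleophile) span beyond which satisfying the
#: covalent tether forces both side chains into a near-fully-extended,
#: essentially unique conformation (the joint maximum span is ~12.1 A for a
#: lysine target and ~9.2 A for a cysteine target, measured on the
#: idealized topologies)
_STRETCH_DISTANCE = {"LYS": 11.9, "CYS": 9.0}


def make_toy_complex(spec: ToyComplexSpec) -> tuple[StructureComplex, ToyGroundTruth]:
    """Build the toy complex and its ground truth; deterministic per seed."""
    if spec.receptor_size < 3 or spec.ligand_size < 3:
        raise GenerationError("receptor and ligand need at least 3 residues")
    if not 1 <= spec.nucleophile_position <= spec.receptor_size:
        raise GenerationError("nucleophile position outside the receptor")
    if not 1 <= spec.planted_position <= spec.ligand_size:
        raise GenerationError("planted position outside the ligand")
    if spec.nucleophile not in ("LYS", "CYS"):
        raise GenerationError(f"nucleophile must be LYS or CYS, got {spec.nucleophile!r}")
    rng = np.random.default_rng(spec.seed % 2**31)

    # --- receptor helix ---
    bbs = _grow_backbone(spec.receptor_size, _HELIX_PHI, _HELIX_PSI)
    nuc_idx = spec.nucleophile_position - 1
    nuc_bb = bbs[nuc_idx]
    nuc_top = load_topology(spec.nucleophile)
    # receptor surface atoms (everything except the nucleophile side chain,
    # which is resampled during design)
    surface = []
    for i, bb in enumerate(bbs):
        surface.extend([bb["N"], bb["CA"], bb["C"]])
        surface.append(
            place_atom(bb["N"], bb["CA"], bb["C"], _ic("O", "N", "CA", "C", _C_O, _ANG_CA_C_O, 180.0))
        )
        if i != nuc_idx:
            surface.append(
                place_atom(bb["C"], bb["N"], bb["CA"], _ic("CB", "C", "N", "CA", 1.53, 110.5, -122.0))
            )
    surface = np.asarray(surface)
    rec_ca = np.asarray([bb["CA"] for bb in bbs])

    # --- planted adduct + ligand strand, drawn until the fixture has the
    # documented discriminating geometry (see docstring) ---
    for _attempt in range(60000):
        # base chis rotamer-like so the side chain may run along the
        # surface; distal chis near-extended
        nuc_chi = np.array(
            [
                rng.choice([-60.0, 60.0, 180.0]) + rng.uniform(-10, 10)
                if k < 2
                else 180.0 + rng.uniform(-10, 10)
                for k in range(nuc_top.n_chi)
            ]
        )
        nuc_atoms = {
            a.name: a.position
            for a in build_sidechain(nuc_top, (nuc_bb["N"], nuc_bb["CA"], nuc_bb["C"]), nuc_chi)
        }
        if spec.nucleophile == "LYS":
            frame = (nuc_atoms["CD"], nuc_atoms["CE"], nuc_atoms["NZ"])
            link_len, link_ang = 1.47, 109.5
        else:
            frame = (nuc_bb["CA"], nuc_atoms["CB"], nuc_atoms["SG"])
            link_len, link_ang = 1.81, 98.0
        nuc_tip = frame[2]
        tors = np.concatenate(
            [
                rng.uniform(-180.0, 180.0, size=1),
                180.0 + rng.uniform(-10.0, 10.0, size=4),
                rng.uniform(-180.0, 180.0, size=1),
            ]
        )
        tors = (tors + 180.0) % 360.0 - 180.0
        cz = place_atom(*frame, _ic("CZ", "A", "B", "C", link_len, link_ang, tors[0]))
        ce = place_atom(frame[1], nuc_tip, cz, _ic("CE", "A", "B", "C", 1.53, 109.5, tors[1]))
        cd = place_atom(nuc_tip, cz, ce, _ic("CD", "A", "B", "C", 1.53, 109.5, tors[2]))
        sg = place_atom(cz, ce, cd, _ic("SG", "A", "B", "C", 1.81, 109.5, tors[3]))
        cb = place_atom(ce, cd, sg, _ic("CB", "A", "B", "C", 1.81, 109.5, tors[4]))
        # the planted mid-chain must run along the receptor surface: it then
        # collects van-der-Waals interface contacts that the near-unique
        # stretched conformations reachable from other positions cannot
        d_cd = float(np.sqrt(((surface - cd) ** 2).sum(-1).min()))
        d_ce = float(np.sqrt(((surface - ce) ** 2).sum(-1).min()))
        d_sg = float(np.sqrt(((surface - sg) ** 2).sum(-1).min()))
        d_cb = float(np.sqrt(((surface - cb) ** 2).sum(-1).min()))
        if not (3.4 <= d_cd <= 4.8 and 3.4 <= d_ce <= 4.8 and d_sg >= 3.4 and d_cb >= 3.4):
            continue
        ca = place_atom(cd, sg, cb, _ic("CA", "A", "B", "C", 1.53, 109.5, tors[5]))
        n = place_atom(sg, cb, ca, _ic("N", "A", "B", "C", _N_CA, 110.5, tors[0] * 0.5 + 60.0))
        c = place_atom(cb, n, ca, _ic("C", "A", "B", "C", _CA_C, _ANG_N_CA_C, 122.0))

        planted_bb = {"N": n, "CA": ca, "C": c}
        before = _grow_backbone_backward(
            spec.planted_position - 1, _STRAND_PHI, _STRAND_PSI, planted_bb
        )
        after = _grow_backbone(
            spec.ligand_size - spec.planted_position + 1, _STRAND_PHI, _STRAND_PSI, planted_bb
        )
        ligand_bbs = before + after
        # every other position must be at or beyond the stretch distance:
        # models there can only satisfy the tether in an extended, pinned
        # conformation away from the surface contacts
        nuc_cb = nuc_atoms["CB"]
        other_cb = [
            place_atom(bb["C"], bb["N"], bb["CA"], _ic("CB", "C", "N", "CA", 1.53, 110.5, -122.0))
            for i, bb in enumerate(ligand_bbs)
            if i + 1 != spec.planted_position
        ]
        reach = min(float(np.linalg.norm(p - nuc_cb)) for p in other_cb)
        # receptor and ligand backbones must not interpenetrate
        lig_ca = np.asarray([bb["CA"] for bb in ligand_bbs])
        min_ca = float(
            np.sqrt(((lig_ca[:, None, :] - rec_ca[None, :, :]) ** 2).sum(-1).min())
        )
        target_ca_pos = nuc_bb["CA"]
        n_within = sum(
            1
            for bb in ligand_bbs
            if float(np.linalg.norm(bb["CA"] - target_ca_pos)) < spec.cutoff
        )
        # keep at least one competing enumerable position so that design
        # recovery is a real comparison, not a walkover
        if reach > _STRETCH_DISTANCE[spec.nucleophile] and min_ca > 4.5 and n_within >= 2:
            break
    else:
        raise GenerationError(
            "could not draw a fixture with a discriminating planted geometry"
        )

    receptor_residues = []
    for i, bb in enumerate(bbs):
        num = i + 1
        if i == nuc_idx:
            extra = [
                AtomRecord(nm, nuc_top.element_of(nm), p)
                for nm, p in nuc_atoms.items()
                if nm != "O" and not nuc_top.is_virtual(nm)
            ]
            receptor_residues.append(
                _residue_from_backbone(spec.receptor_chain, num, spec.nucleophile, bb, extra)
            )
        else:
            receptor_residues.append(
                _residue_from_backbone(spec.receptor_chain, num, "ALA", bb, _build_ala_cb(bb))
            )

    ligand_residues = []
    for i, bb in enumerate(ligand_bbs):
        num = i + 1
        if num == spec.planted_position:
            # the input complex carries the *unreacted* cysteine; the
            # warhead beyond SG exists only in the ground-truth chi vector
            sc = [AtomRecord("CB", "C", cb), AtomRecord("SG", "S", sg)]
            ligand_residues.append(
                _residue_from_backbone(spec.ligand_chain, num, "CYS", bb, sc)
            )
        else:
            ligand_residues.append(
                _residue_from_backbone(spec.ligand_chain, num, "ALA", bb, _build_ala_cb(bb))
            )

    complex_ = StructureComplex(
        receptor_chains=[spec.receptor_chain],
        ligand_chain=spec.ligand_chain,
        residues=receptor_residues + ligand_residues,
        source_id=f"toy-{spec.nucleophile.lower()}-{spec.seed}",
    )

    # --- ground-truth chi vectors at the planted geometry ---
    stereo = "MCR"
    warhead_top = warhead_topology(stereo, spec.nucleophile)
    w_positions = {"N": n, "CA": ca, "C": c, "CB": cb, "SG": sg, "CD": cd, "CE": ce,
                   "CZ": cz, "VNZ": frame[2]}
    chi_w = np.array(
        [
            dihedral_angle(*(w_positions[a] for a in chidef.atoms))
            for chidef in warhead_top.chi_definitions
        ]
    )
    nuc_variant = load_topology("LYX" if spec.nucleophile == "LYS" else "CYX")
    n_positions = dict(nuc_atoms)
    n_positions.update({"N": nuc_bb["N"], "CA": nuc_bb["CA"], "C": nuc_bb["C"], "VCM": cz})
    chi_n = measure_chis(nuc_variant, n_positions)

    # --- ground-truth enumeration by direct all-pairs scan ---
    target_ca = nuc_bb["CA"]
    within = sorted(
        res.seq_number
        for res in ligand_residues
        if float(np.linalg.norm(res.atom_position("CA") - target_ca)) < spec.cutoff
    )
    if spec.planted_position not in within:
        raise GenerationError(
            "planted position fell outside the enumeration cutoff; "
            "choose a nucleophile/planted placement that can touch"
        )
    truth = ToyGroundTruth(
        planted_position=spec.planted_position,
        within_cutoff_positions=within,
        chi_warhead=chi_w,
        chi_nucleophile=chi_n,
        warhead_stereo=stereo,
        target=(spec.receptor_chain, spec.nucleophile_position),
    )
    return complex_, truth
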