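"""End-to-end design runs: configuration, orchestration, reports, logging.

``run_design`` composes the whole pipeline for one complex: enumerate the
installable ligand positions around the target nucleophile, sample models
for every position and both warhead stereoisomers under the covalent
harmonic restraints, apply the selection filters, and write a deterministic
report (TSV + JSON), PDB models for passing designs, and a run log.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import __version__
from .design import (
    DesignReport,
    DesignTask,
    enumerate_positions,
    make_covalent_constraints,
    mutate_ligand_cysteines_to_serine,
    sample_models,
    select_designs,
)
from .structure import CovalentLink, StructureComplex, read_structure, select_residue, write_structure

__all__ = ["RunConfig", "RunResult", "run_design", "EXIT_OK", "EXIT_EMPTY", "EXIT_ERROR"]

EXIT_OK = 0
EXIT_EMPTY = 2
EXIT_ERROR = 1


@dataclass
class RunConfig:
    """Run parameters; the defaults are the published pipeline settings:
    Calpha cutoff 14 A, 100 models per stereoisomer, constraint score < 2,
    interface backbone RMSD < 1 A, top 10 models inspected."""

    input: str = ""
    receptor_chains: tuple[str, ...] = ("A",)
    ligand_chain: str = "B"
    target_chain: str = "A"
    target_residue: int = 0
    warhead: str = "both"            # MCR | MCS | both
    cutoff: float = 14.0
    n_models: int = 100              # per stereoisomer
    seed: int = 0
    max_constraint: float = 2.0
    max_rmsd: float = 1.0
    top_k: int = 10
    mutate_other_cys_to_ser: bool = True
    output_dir: str = "covbinder_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "receptor_chains" in data:
            data["receptor_chains"] = tuple(data["receptor_chains"])
        return cls(**data)

    def to_yaml(self) -> str:
        data = dataclasses.asdict(self)
        data["receptor_chains"] = list(self.receptor_chains)
        return yaml.safe_dump(data, sort_keys=True)


@dataclass
class RunResult:
    exit_code: int
    positions: list[int]
    reports: dict = field(default_factory=dict)   # (position, ) -> DesignReport
    best_positions: list[int] = field(default_factory=list)
    output_dir: Optional[Path] = None


def _report_rows(reports: dict[int, DesignReport]):
    rows = []
    for position in sorted(reports):
        for e in reports[position].entries:
            rows.append(
                {
                    "position": e.position,
                    "stereo": e.stereo,
                    "model": e.model_index,
                    "rank": e.rank,
                    "interface_score": f"{e.interface_score:.6f}",
                    "constraint_score": f"{e.constraint_score:.6f}",
                    "clash_score": f"{e.clash_score:.6f}",
                    "interface_bb_rmsd": f"{e.interface_bb_rmsd:.6f}",
                    "pass_constraint": int(e.passes_constraint),
                    "pass_rmsd": int(e.passes_rmsd),
                    "pass": int(e.passes),
                }
            )
    return rows


def run_design(
    config: RunConfig,
    complex_: Optional[StructureComplex] = None,
) -> RunResult:
    """Run the full design pipeline for one complex.

    ``complex_`` may be passed directly (e.g. a generated toy complex);
    otherwise ``config.input`` is read. Returns a :class:`RunResult` whose
    ``exit_code`` is 0 on success and 2 when no ligand position lies within
    the enumeration cutoff.
    """
    t_start = time.monotonic()
    log_lines = [
        f"covbinder {__version__}",
        f"seed {config.seed}",
        "config:",
        *("  " + line for line in config.to_yaml().splitlines()),
    ]
    if complex_ is None:
        complex_ = read_structure(
            config.input, list(config.receptor_chains), config.ligand_chain
        )
    target = (config.target_chain, config.target_residue)
    positions = enumerate_positions(complex_, target, cutoff=config.cutoff)
    log_lines.append(f"enumerated positions: {positions}")

    out_dir = Path(config.output_dir) if config.output_dir else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "config.yaml").write_text(config.to_yaml())

    if not positions:
        result = RunResult(exit_code=EXIT_EMPTY, positions=[], output_dir=out_dir)
        if out_dir is not None:
            (out_dir / "report.tsv").write_text(
                "position\tstereo\tmodel\trank\tinterface_score\tconstraint_score"
                "\tclash_score\tinterface_bb_rmsd\tpass_constraint\tpass_rmsd\tpass\n"
            )
            (out_dir / "report.json").write_text(json.dumps({"positions": [], "entries": []}))
            (out_dir / "run.log").write_text("\n".join(log_lines + ["no candidate positions"]) + "\n")
        return result

    reports: dict[int, DesignReport] = {}
    all_models: dict = {}
    position_stats: dict = {}
    for position in positions:
        t_pos = time.monotonic()
        working = (
            mutate_ligand_cysteines_to_serine(complex_, keep_position=position)
            if config.mutate_other_cys_to_ser
            else complex_
        )
        task = DesignTask(
            complex=working,
            target=target,
            position=position,
            stereo=config.warhead,
            n_models=config.n_models,
            seed=config.seed,
        )
        constraints = make_covalent_constraints(task)
        models = sample_models(task, constraints, template=complex_)
        models_by_key = {(m.position, m.stereo, m.model_index): m for m in models}
        all_models.update(models_by_key)
        passing = [
            m for m in models
            if m.constraint_score < config.max_constraint
            and m.interface_bb_rmsd < config.max_rmsd
        ]
        position_stats[position] = (
            min((m.interface_score for m in passing), default=None),
            min(m.interface_score for m in models),
        )
        reports[position] = select_designs(
            models,
            top_k=config.top_k,
            max_constraint=config.max_constraint,
            max_rmsd=config.max_rmsd,
        )
        log_lines.append(
            f"position {position}: {len(models)} models, "
            f"{reports[position].n_passing} passing, "
            f"{time.monotonic() - t_pos:.1f}s"
        )

    # rank positions: passing designs first, then best passing interface score
    def position_key(pos: int):
        best_passing, best_any = position_stats[pos]
        if best_passing is not None:
            return (0, best_passing, pos)
        return (1, best_any, pos)

    best_positions = sorted(positions, key=position_key)
    log_lines.append(f"position ranking: {best_positions}")

    if out_dir is not None:
        rows = _report_rows(reports)
        header = list(rows[0].keys()) if rows else []
        tsv = "\t".join(header) + "\n" + "\n".join(
            "\t".join(str(r[h]) for h in header) for r in rows
        ) + "\n"
        (out_dir / "report.tsv").write_text(tsv)
        (out_dir / "report.json").write_text(
            json.dumps(
                {
                    "positions": positions,
                    "position_ranking": best_positions,
                    "entries": rows,
                },
                indent=2,
            )
        )
        _write_passing_models(out_dir, complex_, reports, all_models, target)
        log_lines.append(f"total {time.monotonic() - t_start:.1f}s")
        (out_dir / "run.log").write_text("\n".join(log_lines) + "\n")

    return RunResult(
        exit_code=EXIT_OK,
        positions=positions,
        reports=reports,
        best_positions=best_positions,
        output_dir=out_dir,
    )


def _model_complex(base: StructureComplex, model, position, stereo, target):
    """A copy of the complex carrying one sampled model's coordinates."""
    from . import chemistry
    from .structure import AtomRecord

    cx = base.copy()
    target_res_name = select_residue(base, *target).name[:3]
    for res in cx.residues:
        key = (res.chain_id, res.seq_number)
        if key == (cx.ligand_chain, position):
            top = chemistry.warhead_topology(stereo, target_res_name)
            res.name = stereo
        elif key == target:
            top = chemistry.load_topology(chemistry.NUCLEOPHILE_VARIANTS[target_res_name])
            res.name = top.name
        else:
            continue
        names = ["N", "CA", "C", "O"] + [
            n for n in top.atom_names() if n not in ("N", "CA", "C", "O")
        ]
        atoms = []
        for name in names:
            pos = model.coordinates.get((res.chain_id, res.seq_number, name))
            if pos is None or (name in top.atom_names() and top.is_virtual(name)):
                continue
            el = top.element_of(name) if name in top.atom_names() else name[0]
            atoms.append(AtomRecord(name=name, element=el, position=pos))
        res.atoms = atoms
    return cx


def _write_passing_models(out_dir, complex_, reports, all_models, target):
    """Write a PDB (with the covalent LINK record) for each passing entry."""
    from .design import NUCLEOPHILE_ATOMS

    target_res = select_residue(complex_, *target)
    nuc_atom = NUCLEOPHILE_ATOMS.get(target_res.name, "NZ")
    for position, report in reports.items():
        for e in report.entries:
            if not e.passes:
                continue
            model = all_models[(e.position, e.stereo, e.model_index)]
            link = CovalentLink(
                chain_a=complex_.ligand_chain,
                resnum_a=position,
                resname_a=e.stereo,
                atom_a="CZ",
                chain_b=target_res.chain_id,
                resnum_b=target_res.seq_number,
                resname_b=target_res.name,
                atom_b=nuc_atom,
            )
            remarks = [
                f"covbinder model position={position} stereo={e.stereo} model={e.model_index}",
                f"interface_score={e.interface_score:.4f} "
                f"constraint_score={e.constraint_score:.4f} "
                f"interface_bb_rmsd={e.interface_bb_rmsd:.4f}",
            ]
            model_cx = _model_complex(complex_, model, position, e.stereo, target)
            out = write_structure(model_cx, covalent_links=[link], remarks=remarks)
            (out_dir / f"model_p{position}_{e.stereo}_{e.model_index}.pdb").write_text(out)
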