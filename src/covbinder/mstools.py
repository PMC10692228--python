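"""Covalent-labeling mass spectrometry arithmetic.

Everything downstream of the wet experiment's deconvoluted numbers lives
here: peptide masses under the modification grammar, expected covalent
adduct tables for intact-protein MS, labeling quantification from species
intensities, in-silico tryptic digestion, depletion-based localization of
the labeled site, and first-order labeling kinetics fits.

Modification grammar
--------------------
``Ac-`` N-terminal acetyl (+C2H2O); ``-NH2`` C-terminal amide (-O +NH);
``-OH`` free acid C-terminus (no change); ``(pS)``/``(pT)`` phosphoserine /
phosphothreonine (+HPO3); ``(mC)`` cysteine carrying the thioether
methacrylate ester (+C6H8O2); ``X`` gamma-chloroacetamido-diaminobutyric
acid as a whole residue.

Adduct chemistry
----------------
Aza-Michael addition of a target lysine across the methacrylate alkene
adds the *entire* peptide mass to the protein. Thiol substitution at a
target cysteine instead displaces the peptide (released as a free thiol)
and leaves only the +112 Da methacrylate fragment (C6H8O2) on the protein.
The three species are algebraically closed:
full_peptide_addition = warhead_only + released_thiol_peptide.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .chemistry import (
    DAB_CHLOROACETAMIDE_FORMULA,
    METHACRYLATE_FRAGMENT,
    MODIFICATION_DELTAS,
    RESIDUE_FORMULAS,
    formula_add,
    formula_subtract,
    fragment_mass,
    parse_formula,
)

__all__ = [
    "MSToolsError",
    "GrammarError",
    "WarheadCountError",
    "PeptideSpec",
    "AdductTable",
    "DigestPeptide",
    "DepletionResult",
    "KineticsFit",
    "TABLE1_PEPTIDES",
    "parse_peptide",
    "peptide_formula",
    "peptide_mass",
    "expected_adducts",
    "labeling_fraction",
    "digest",
    "site_tracking_peptides",
    "depletion_site_call",
    "fit_first_order",
]

WATER = "H2O"
HCL = "HCl"


class MSToolsError(Exception):
    pass


class GrammarError(MSToolsError, ValueError):
    pass


class WarheadCountError(MSToolsError, ValueError):
    pass


@dataclass(frozen=True)
class PeptideSpec:
    """A peptide sequence plus its modification tokens.

    ``residues`` uses one-letter codes ('X' allowed for the
    chloroacetamido-Dab residue); ``site_mods`` maps 1-based positions to
    tokens ('p' for phospho, 'mC' for the methacrylate cysteine).
    """

    residues: str
    n_term: str = ""      # "" or "Ac-"
    c_term: str = ""      # "" (free acid) or "-NH2"
    site_mods: tuple[tuple[int, str], ...] = ()

    def __post_init__(self):
        if not self.residues:
            raise GrammarError("empty peptide sequence")
        for i, aa in enumerate(self.residues, 1):
            if aa not in RESIDUE_FORMULAS and aa != "X":
                raise GrammarError(f"unknown residue {aa!r} at position {i}")
        for pos, token in self.site_mods:
            if not 1 <= pos <= len(self.residues):
                raise GrammarError(f"modification position {pos} out of range")
            aa = self.residues[pos - 1]
            if token == "p" and aa not in "ST":
                raise GrammarError(f"phospho token at non-S/T residue {aa}{pos}")
            if token == "mC" and aa != "C":
                raise GrammarError(f"mC token at non-Cys residue {aa}{pos}")
            if token not in ("p", "mC"):
                raise GrammarError(f"unknown modification token {token!r}")
        if self.n_term not in ("", "Ac-"):
            raise GrammarError(f"unknown N-terminal token {self.n_term!r}")
        if self.c_term not in ("", "-NH2"):
            raise GrammarError(f"unknown C-terminal token {self.c_term!r}")

    @property
    def n_warheads(self) -> int:
        return sum(t == "mC" for _, t in self.site_mods) + self.residues.count("X")


_TOKEN_RE = re.compile(r"\((p[ST]|mC)\)|([A-Z])")


def parse_peptide(text: str) -> PeptideSpec:
    """Parse printed peptide notation, e.g. ``Ac-RSA-(pT)-(mC)-PSL-NH2``."""
    s = text.strip().replace("_", "")
    n_term = ""
    c_term = ""
    if s.startswith("Ac-"):
        n_term = "Ac-"
        s = s[3:]
    if s.endswith("-NH2"):
        c_term = "-NH2"
        s = s[: -len("-NH2")]
    elif s.endswith("-OH"):
        s = s[: -len("-OH")]
    s = s.replace("-", "")
    residues = []
    mods = []
    pos = 0
    for m in _TOKEN_RE.finditer(s):
        if m.start() != pos:
            raise GrammarError(f"unparseable peptide notation {text!r}")
        pos = m.end()
        if m.group(1):
            token = m.group(1)
            residues.append(token[-1])  # pS -> S, pT -> T, mC -> C
            mods.append((len(residues), "p" if token.startswith("p") else "mC"))
        else:
            residues.append(m.group(2))
    if pos != len(s):
        raise GrammarError(f"unparseable peptide notation {text!r}")
    return PeptideSpec(
        residues="".join(residues), n_term=n_term, c_term=c_term, site_mods=tuple(mods)
    )


#: the published peptide panel (printed notation), peptide number -> spec text
TABLE1_PEPTIDES: dict[int, str] = {
    1: "Ac-SH-(pT)-(mC)-PS-NH2",
    2: "Ac-SH-(pT)-L-(mC)-S-NH2",
    3: "Ac-RSA-(pT)-(mC)-PSL-NH2",
    4: "Ac-RSA-(pT)-EP-(mC)-L-NH2",
    5: "Ac-RSA-(pT)-EPS-(mC)-NH2",
    6: "Ac-QRST-(pT)-(mC)-OH",
    7: "Ac-KRRK-(pT)-(mC)-NH2",
    8: "Ac-RAH-(pT)-(mC)-PASLQ-NH2",
    9: "Ac-RAH-(pT)-SP-(mC)-SLQ-NH2",
    10: "Ac-RAH-(pT)-SPA-(mC)-LQ-NH2",
    11: "Ac-RAH-(pT)-SPAS-(mC)-Q-NH2",
    12: "Ac-RAH-(pT)-SPASL-X-NH2",
}


def peptide_formula(spec: PeptideSpec | str) -> dict[str, int]:
    """Elemental composition of the full (modified) peptide."""
    if isinstance(spec, str):
        spec = parse_peptide(spec)
    formula: dict[str, int] = parse_formula(WATER)
    for aa in spec.residues:
        res_formula = DAB_CHLOROACETAMIDE_FORMULA if aa == "X" else RESIDUE_FORMULAS[aa]
        formula = formula_add(formula, res_formula)
    if spec.n_term == "Ac-":
        formula = formula_add(formula, MODIFICATION_DELTAS["Ac-"])
    if spec.c_term == "-NH2":
        formula = formula_add(formula, MODIFICATION_DELTAS["-NH2"])
    for _, token in spec.site_mods:
        delta = MODIFICATION_DELTAS["phospho" if token == "p" else "mC"]
        formula = formula_add(formula, delta)
    return formula


def peptide_mass(spec: PeptideSpec | str, mode: str = "monoisotopic") -> float:
    """Mass in Da of the modified peptide (residues + water + deltas)."""
    return fragment_mass(peptide_formula(spec), mode)


@dataclass(frozen=True)
class AdductTable:
    """Expected covalent adduct species for one warhead peptide + protein."""

    deltas: Mapping[str, float]          # species label -> mass shift (Da)
    absolute: Mapping[str, float]        # species label -> protein + shift (Da)
    mode: str


def expected_adducts(
    spec: PeptideSpec | str, protein_base_mass: float, mode: str = "average"
) -> AdductTable:
    """Expected intact-MS species for a single-warhead peptide.

    For the methacrylate warhead (mC): full peptide addition (aza-Michael),
    methacrylate-only (thiol substitution; +C6H8O2, the printed +112 Da),
    and the complementary released thiol peptide. For the chloroacetamide
    residue X the reaction is substitution of chloride, so the single
    expected species is peptide minus HCl.
    """
    if isinstance(spec, str):
        spec = parse_peptide(spec)
    if spec.n_warheads != 1:
        raise WarheadCountError(
            f"expected exactly one warhead residue, found {spec.n_warheads}"
        )
    pep = peptide_mass(spec, mode)
    if "X" in spec.residues:
        deltas = {"full_peptide_addition": pep - fragment_mass(HCL, mode)}
    else:
        warhead = fragment_mass(METHACRYLATE_FRAGMENT, mode)
        deltas = {
            "full_peptide_addition": pep,
            "warhead_only": warhead,
            "released_thiol_peptide": pep - warhead,
        }
    absolute = {k: protein_base_mass + v for k, v in deltas.items()}
    return AdductTable(deltas=deltas, absolute=absolute, mode=mode)


def labeling_fraction(intensities: Mapping[str, float]) -> dict[str, float]:
    """Percent share of each species in a deconvoluted intensity list."""
    for label, v in intensities.items():
        if v < 0:
            raise MSToolsError(f"negative intensity for {label!r}")
    total = float(sum(intensities.values()))
    if total <= 0:
        raise MSToolsError("all species intensities are zero: fraction undefined")
    return {label: 100.0 * v / total for label, v in intensities.items()}


# ---------------------------------------------------------------------------
# digestion & site localization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DigestPeptide:
    start: int  # 1-based inclusive
    end: int
    sequence: str
    missed_cleavages: int


def digest(
    sequence: str,
    enzyme: str = "trypsin/P",
    max_missed: int = 2,
    length_bounds: Optional[tuple[int, int]] = None,
) -> list[DigestPeptide]:
    """In-silico digest with positional bookkeeping.

    ``trypsin/P`` cleaves after every K or R, including when the next
    residue is proline. Products with 0..``max_missed`` missed cleavages
    are emitted in (start, missed) order; ``length_bounds`` (min, max)
    optionally filters by peptide length.
    """
    if not sequence:
        raise MSToolsError("empty sequence")
    if enzyme not in ("trypsin/P", "trypsin"):
        raise MSToolsError(f"unsupported enzyme {enzyme!r}")
    sequence = sequence.upper()
    cut_after = []
    for i, aa in enumerate(sequence):
        if aa in "KR":
            if enzyme == "trypsin" and i + 1 < len(sequence) and sequence[i + 1] == "P":
                continue
            cut_after.append(i + 1)  # 1-based position after which we cut
    boundaries = [0] + cut_after + ([] if cut_after and cut_after[-1] == len(sequence) else [len(sequence)])
    peptides = []
    n_frag = len(boundaries) - 1
    for i in range(n_frag):
        for missed in range(min(max_missed, n_frag - 1 - i) + 1):
            start = boundaries[i] + 1
            end = boundaries[i + 1 + missed]
            seq = sequence[start - 1 : end]
            if length_bounds and not length_bounds[0] <= len(seq) <= length_bounds[1]:
                continue
            peptides.append(
                DigestPeptide(start=start, end=end, sequence=seq, missed_cleavages=missed)
            )
    return peptides


def site_tracking_peptides(
    peptides: Sequence[DigestPeptide], site_index: int
) -> list[DigestPeptide]:
    """Digest peptides that report on a candidate labeling site.

    Returns the peptides whose span contains the site, plus — when the
    site residue is K/R, so that labeling blocks its cleavage — the
    peptides immediately following it (those starting at site + 1).
    """
    max_end = max((p.end for p in peptides), default=0)
    if not 1 <= site_index <= max_end:
        raise MSToolsError(f"site {site_index} outside digested sequence (1..{max_end})")
    containing = [p for p in peptides if p.start <= site_index <= p.end]
    site_residue = ""
    for p in containing:
        site_residue = p.sequence[site_index - p.start]
        break
    following = []
    if site_residue in "KR" and any(p.end == site_index for p in peptides):
        following = [p for p in peptides if p.start == site_index + 1]
    return containing + following


@dataclass(frozen=True)
class DepletionResult:
    peptide_ratios: Mapping[str, float]   # peptide id -> treated/control
    site_depletion: Mapping[str, float]   # site -> median ratio
    site_call: str                        # a site label or "ambiguous"


def depletion_site_call(
    peptide_signals: Mapping[str, tuple[float, float]],
    site_map: Mapping[str, Sequence[str]],
    sites: Sequence[str],
    depleted_below: float = 0.5,
    intact_above: float = 0.75,
) -> DepletionResult:
    """Localize the covalent site from depletion of unmodified peptides.

    Each tracked peptide's treated/control ratio is computed; each site is
    summarised by the median ratio over its peptides. The call is the site
    with the minimum median if that median is < ``depleted_below`` while
    every other site's median is > ``intact_above``; otherwise
    ``"ambiguous"``.
    """
    ratios = {}
    for pid, (treated, control) in peptide_signals.items():
        if control <= 0:
            raise MSToolsError(f"peptide {pid!r}: control signal must be > 0")
        if treated < 0:
            raise MSToolsError(f"peptide {pid!r}: negative treated signal")
        ratios[pid] = treated / control
    site_depletion = {}
    for site in sites:
        vals = [ratios[pid] for pid, mapped in site_map.items() if site in mapped]
        if not vals:
            raise MSToolsError(f"site {site!r} has no tracked peptides")
        site_depletion[site] = float(np.median(vals))
    best = min(site_depletion, key=site_depletion.get)
    others_intact = all(
        v > intact_above for s, v in site_depletion.items() if s != best
    )
    call = best if site_depletion[best] < depleted_below and others_intact else "ambiguous"
    return DepletionResult(
        peptide_ratios=ratios, site_depletion=site_depletion, site_call=call
    )


# ---------------------------------------------------------------------------
# labeling kinetics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KineticsFit:
    k_obs: float        # per minute
    plateau: float      # labeled fraction at t -> infinity
    residual_norm: float
    degenerate: bool = False

    @property
    def half_time(self) -> float:
        """Minutes to half of the plateau: ln(2) / k_obs."""
        return float(np.log(2.0) / self.k_obs)


def fit_first_order(timecourse: Sequence[tuple[float, float]]) -> KineticsFit:
    """Least-squares fit of f(t) = plateau * (1 - exp(-k_obs * t)).

    ``timecourse`` is a list of (time in minutes, labeled fraction) pairs
    with t >= 0. A flat series is flagged degenerate instead of raising.
    """
    data = np.asarray(timecourse, dtype=float)
    if data.ndim != 2 or data.shape[1] != 2 or len(data) < 3:
        raise MSToolsError("need at least 3 (t, fraction) points")
    t, f = data[:, 0], data[:, 1]
    if (t < 0).any():
        raise MSToolsError("negative time point")
    if np.allclose(f, f[0]):
        return KineticsFit(k_obs=0.0, plateau=float(f[0]), residual_norm=0.0, degenerate=True)

    def model(tt, k, plateau):
        return plateau * (1.0 - np.exp(-k * tt))

    f_max = float(f.max())
    # crude initial rate from the earliest nonzero rise
    rising = np.nonzero(f > 0.05 * f_max)[0]
    t0 = t[rising[0]] if len(rising) and t[rising[0]] > 0 else max(t[t > 0].min(), 1e-3)
    p0 = [np.log(2.0) / t0, f_max]
    popt, _ = curve_fit(
        model, t, f, p0=p0, bounds=([1e-9, 1e-9], [np.inf, np.inf]), maxfev=10000
    )
    resid = model(t, *popt) - f
    return KineticsFit(
        k_obs=float(popt[0]),
        plateau=float(popt[1]),
        residual_norm=float(np.linalg.norm(resid)),
    )
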