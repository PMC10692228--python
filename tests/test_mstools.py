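"""Peptide masses, adduct tables, digestion, site calls, kinetics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from pyteomics import mass as pyteomics_mass
from pyteomics import parser as pyteomics_parser

from covbinder.mstools import (
    TABLE1_PEPTIDES,
    GrammarError,
    MSToolsError,
    WarheadCountError,
    depletion_site_call,
    digest,
    expected_adducts,
    fit_first_order,
    labeling_fraction,
    parse_peptide,
    peptide_mass,
    site_tracking_peptides,
)


def pyteomics_oracle_mass(spec, mode="monoisotopic"):
    """Independent elemental-composition mass from pyteomics."""
    comp = pyteomics_mass.Composition(parsed_sequence=list(spec.residues.replace("X", "")))
    comp += pyteomics_mass.Composition(formula="H2O")
    if spec.n_term == "Ac-":
        comp += pyteomics_mass.Composition(formula="C2H2O")
    if spec.c_term == "-NH2":
        comp += pyteomics_mass.Composition(formula="NH")
        comp["O"] -= 1
    for _, token in spec.site_mods:
        if token == "p":
            comp += pyteomics_mass.Composition(formula="HPO3")
        else:
            comp += pyteomics_mass.Composition(formula="C6H8O2")
    if "X" in spec.residues:
        comp += pyteomics_mass.Composition(formula="C6H9ClN2O2")
    return pyteomics_mass.calculate_mass(composition=comp, average=(mode == "average"))


class TestPeptideMass:
    def test_diglycine_monoisotopic(self):
        assert peptide_mass("GG") == pytest.approx(132.054, abs=1e-3)

    def test_capped_glycine_against_formula_oracle(self):
        spec = parse_peptide("Ac-G-NH2")
        expected = 57.02146 + 18.010565 + 42.010565 - 0.984016
        assert peptide_mass(spec) == pytest.approx(expected, abs=1e-3)
        assert peptide_mass(spec) == pytest.approx(pyteomics_oracle_mass(spec), abs=1e-4)

    @pytest.mark.parametrize("number", sorted(TABLE1_PEPTIDES))
    def test_published_panel_vs_composition_oracle(self, number):
        """Every peptide of the published panel agrees with an independent
        pyteomics composition summation to 1e-4 Da."""
        spec = parse_peptide(TABLE1_PEPTIDES[number])
        # average-mass tables differ slightly between IUPAC revisions, so
        # the average-mode comparison allows 0.05 Da (still far below the
        # resolution of deconvoluted intact masses)
        for mode in ("monoisotopic", "average"):
            tolerance = 1e-4 if mode == "monoisotopic" else 5e-2
            assert peptide_mass(spec, mode) == pytest.approx(
                pyteomics_oracle_mass(spec, mode), abs=tolerance
            )

    def test_empty_sequence_is_grammar_error(self):
        with pytest.raises(GrammarError):
            parse_peptide("Ac--NH2")

    def test_bad_token(self):
        with pytest.raises(GrammarError):
            parse_peptide("Ac-R-(pQ)-NH2")

    def test_phospho_on_non_st_rejected(self):
        with pytest.raises(GrammarError):
            parse_peptide("A-(pT)").__class__(residues="AG", site_mods=((2, "p"),))


class TestAdducts:
    def test_warhead_only_prints_as_112(self):
        table = expected_adducts(TABLE1_PEPTIDES[3], 27000.0, "average")
        assert round(table.deltas["warhead_only"]) == 112

    @pytest.mark.parametrize("number", [n for n in TABLE1_PEPTIDES if n != 12])
    def test_mass_closure_addition_equals_substitution_plus_thiol(self, number):
        table = expected_adducts(TABLE1_PEPTIDES[number], 0.0, "monoisotopic")
        closure = (
            table.deltas["full_peptide_addition"]
            - table.deltas["warhead_only"]
            - table.deltas["released_thiol_peptide"]
        )
        assert closure == 0.0

    def test_full_adduct_is_base_plus_peptide(self):
        spec = parse_peptide(TABLE1_PEPTIDES[8])
        m = peptide_mass(spec, "average")
        table = expected_adducts(spec, 26978.0, "average")
        assert table.absolute["full_peptide_addition"] == pytest.approx(26978.0 + m)

    def test_no_warhead_rejected(self):
        with pytest.raises(WarheadCountError):
            expected_adducts("GG", 1000.0)

    def test_chloroacetamide_peptide_is_substitution_only(self):
        table = expected_adducts(TABLE1_PEPTIDES[12], 0.0, "average")
        assert set(table.deltas) == {"full_peptide_addition"}
        spec = parse_peptide(TABLE1_PEPTIDES[12])
        assert table.deltas["full_peptide_addition"] == pytest.approx(
            peptide_mass(spec, "average") - 36.458, abs=0.01
        )


class TestLabelingFraction:
    def test_even_split(self):
        assert labeling_fraction({"unlabeled": 500, "full": 500})["full"] == 50.0

    def test_single_species(self):
        assert labeling_fraction({"unlabeled": 0, "full": 7})["full"] == 100.0

    def test_three_species(self):
        out = labeling_fraction({"unlabeled": 2, "warhead_only": 1, "full": 1})
        assert out["warhead_only"] == 25.0 and out["full"] == 25.0

    def test_sums_to_100(self):
        out = labeling_fraction({"a": 3.1, "b": 2.7, "c": 9.9})
        assert sum(out.values()) == pytest.approx(100.0)

    def test_all_zero_undefined(self):
        with pytest.raises(MSToolsError):
            labeling_fraction({"a": 0.0, "b": 0.0})


class TestDigest:
    def test_akrgr_zero_missed(self):
        peps = digest("AKRGR", max_missed=0)
        assert [(p.start, p.end, p.sequence) for p in peps] == [
            (1, 2, "AK"), (3, 3, "R"), (4, 5, "GR"),
        ]

    def test_akrgr_one_missed_adds_two(self):
        seqs = {p.sequence for p in digest("AKRGR", max_missed=1)}
        assert seqs == {"AK", "R", "GR", "AKR", "RGR"}

    def test_no_cut_sites(self):
        peps = digest("AAGGS", max_missed=2)
        assert len(peps) == 1 and peps[0].sequence == "AAGGS"

    def test_trypsin_p_cuts_before_proline(self):
        seqs = {p.sequence for p in digest("AKPG", max_missed=0)}
        assert seqs == {"AK", "PG"}

    def test_matches_pyteomics_cleave(self):
        seq = "MKWVTFISLLLLFSSAYSRGVFRRDTHKSEIAHRFKDLGE"
        ours = {p.sequence for p in digest(seq, max_missed=2)}
        theirs = pyteomics_parser.cleave(seq, rule=r"(?<=[KR])", missed_cleavages=2)
        assert ours == set(theirs)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=40))
    def test_zero_missed_peptides_reconstruct_sequence(self, seq):
        peps = [p for p in digest(seq, max_missed=2) if p.missed_cleavages == 0]
        assert "".join(p.sequence for p in sorted(peps, key=lambda p: p.start)) == seq

    def test_length_bounds(self):
        peps = digest("AKRGR", max_missed=2, length_bounds=(2, 3))
        assert all(2 <= len(p.sequence) <= 3 for p in peps)

    def test_empty_sequence(self):
        with pytest.raises(MSToolsError):
            digest("")


class TestSiteTracking:
    def test_lysine_site_includes_following_peptides(self):
        peps = digest("AKRGR", max_missed=2)
        tracked = site_tracking_peptides(peps, 2)  # the K
        seqs = {p.sequence for p in tracked}
        assert {"AK", "AKR"}.issubset(seqs)
        # labeling the K blocks its cleavage: the peptides starting right
        # after it also report on the site
        assert {"R", "RGR"}.issubset(seqs)

    def test_whole_sequence_when_uncleavable(self):
        peps = digest("AAGG", max_missed=2)
        tracked = site_tracking_peptides(peps, 1)
        assert len(tracked) == 1 and tracked[0].sequence == "AAGG"

    def test_site_out_of_range(self):
        peps = digest("AKRGR", max_missed=0)
        with pytest.raises(MSToolsError):
            site_tracking_peptides(peps, 9)


class TestDepletion:
    SITES = ["Cys38", "Lys122"]

    def test_clear_single_site_depletion(self):
        signals = {"p1": (10.0, 100.0), "p2": (20.0, 100.0), "p3": (100.0, 100.0), "p4": (110.0, 100.0)}
        site_map = {"p1": ["Cys38"], "p2": ["Cys38"], "p3": ["Lys122"], "p4": ["Lys122"]}
        result = depletion_site_call(signals, site_map, self.SITES)
        assert result.site_call == "Cys38"
        assert result.site_depletion["Cys38"] == pytest.approx(0.15)

    def test_no_depletion_is_ambiguous(self):
        signals = {"p1": (100.0, 100.0), "p2": (98.0, 100.0)}
        site_map = {"p1": ["Cys38"], "p2": ["Lys122"]}
        assert depletion_site_call(signals, site_map, self.SITES).site_call == "ambiguous"

    def test_two_depleted_sites_ambiguous(self):
        signals = {"p1": (20.0, 100.0), "p2": (20.0, 100.0)}
        site_map = {"p1": ["Cys38"], "p2": ["Lys122"]}
        assert depletion_site_call(signals, site_map, self.SITES).site_call == "ambiguous"

    def test_zero_control_guard(self):
        with pytest.raises(MSToolsError):
            depletion_site_call({"p1": (1.0, 0.0)}, {"p1": ["Cys38"]}, ["Cys38"])


class TestKinetics:
    def test_noiseless_recovery(self):
        k, plateau = 0.01, 1.0
        t = np.linspace(0, 600, 13)
        f = plateau * (1 - np.exp(-k * t))
        fit = fit_first_order(list(zip(t, f)))
        assert fit.k_obs == pytest.approx(k, abs=1e-6)
        assert fit.plateau == pytest.approx(plateau, abs=1e-6)
        assert fit.residual_norm < 1e-8

    def test_model_starts_at_zero(self):
        fit = fit_first_order([(0.0, 0.0), (30.0, 0.3), (60.0, 0.5), (120.0, 0.75)])
        assert fit.plateau * (1 - np.exp(-fit.k_obs * 0.0)) == 0.0

    def test_half_time_is_ln2_over_k(self):
        t = np.linspace(0, 500, 10)
        f = 1.0 * (1 - np.exp(-0.02 * t))
        fit = fit_first_order(list(zip(t, f)))
        assert fit.half_time == pytest.approx(np.log(2) / fit.k_obs)

    def test_noisy_recovery_within_ten_percent(self):
        rng = np.random.default_rng(2024)
        k, plateau = 0.015, 0.9
        t = np.linspace(5, 600, 12)
        f = plateau * (1 - np.exp(-k * t)) * (1 + rng.normal(0, 0.01, len(t)))
        fit = fit_first_order(list(zip(t, f)))
        assert abs(fit.k_obs - k) / k < 0.10

    def test_flat_series_flagged_degenerate(self):
        fit = fit_first_order([(0.0, 0.4), (10.0, 0.4), (20.0, 0.4)])
        assert fit.degenerate

    def test_too_few_points(self):
        with pytest.raises(MSToolsError):
            fit_first_order([(0.0, 0.0), (1.0, 0.5)])
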