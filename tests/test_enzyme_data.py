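"""Enzyme molecular weights, entry assembly, and the proteome mass fraction."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecgem import (
    EnzymeEntry,
    ProteomeRecord,
    SubunitComposition,
    assign_enzyme_entries,
    complex_molecular_weight,
    compute_enzyme_mass_fraction,
    effective_efficiency,
    preprocess,
)
from ecgem.enzyme_data import (
    read_kcat_table,
    read_proteome_table,
    read_subunit_table,
    write_kcat_table,
    write_proteome_table,
    write_subunit_table,
)
from ecgem.fixtures import pdh_composition, toy_proteome


class TestComplexMolecularWeight:
    def test_pyruvate_dehydrogenase_one_copy_each(self):
        assert complex_molecular_weight(pdh_composition(stoichiometric=False)) == pytest.approx(
            216.43, abs=0.01
        )

    def test_pyruvate_dehydrogenase_true_stoichiometry(self):
        assert complex_molecular_weight(pdh_composition(stoichiometric=True)) == pytest.approx(
            4586.16, abs=0.01
        )

    def test_single_subunit_identity(self):
        comp = SubunitComposition((("g", 1, 42.5),))
        assert complex_molecular_weight(comp) == 42.5

    @given(
        st.lists(
            st.tuples(
                st.integers(1, 24),
                st.floats(1.0, 500.0, allow_nan=False, allow_infinity=False),
            ),
            min_size=1,
            max_size=6,
        )
    )
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_linear_in_copy_numbers(self, parts):
        comp = SubunitComposition(
            tuple((f"g{i}", c, mw) for i, (c, mw) in enumerate(parts))
        )
        doubled = SubunitComposition(
            tuple((f"g{i}", 2 * c, mw) for i, (c, mw) in enumerate(parts))
        )
        assert complex_molecular_weight(doubled) == pytest.approx(
            2 * complex_molecular_weight(comp), rel=1e-12
        )

    def test_empty_composition_is_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            complex_molecular_weight(SubunitComposition(()))

    def test_invalid_copy_number_is_rejected(self):
        with pytest.raises(ValueError, match="copy number"):
            SubunitComposition((("g", 0, 10.0),))


class TestEffectiveEfficiency:
    @pytest.mark.parametrize(
        "candidates, expected",
        [
            ([(3600.0, 100.0), (7200.0, 100.0)], (3600.0, 100.0)),  # ratios 36 vs 72
            ([(3600.0, 50.0), (3600.0, 100.0)], (3600.0, 100.0)),   # ratios 72 vs 36
            ([(500.0, 25.0)], (500.0, 25.0)),
        ],
    )
    def test_bottleneck_pair(self, candidates, expected):
        assert effective_efficiency(candidates) == expected

    def test_tie_broken_by_first_occurrence(self):
        assert effective_efficiency([(100.0, 10.0), (200.0, 20.0)]) == (100.0, 10.0)

    def test_output_is_an_input_element(self):
        candidates = [(3600.0, 77.0), (1800.0, 99.0), (7200.0, 11.0)]
        assert effective_efficiency(candidates) in candidates

    def test_empty_input_is_rejected(self):
        with pytest.raises(ValueError):
            effective_efficiency([])


class TestAssignEnzymeEntries:
    def test_toy_coverage_and_exclusions(self, toy_split):
        split, entries, _ = toy_split
        by_id = {e.reaction_id: e for e in entries}
        # enzymatic reactions with a kcat: RESP, both FERM isozymes, NADHOX
        assert set(by_id) == {"RESP", "FERM_num1", "FERM_num2", "NADHOX"}
        # exchanges, transporters (spontaneous) and biomass get no entry
        for rid in ("EX_glc__D_e", "GLCt", "ACt", "BIOMASS"):
            assert rid not in by_id

    def test_complex_mw_uses_copy_numbers(self, toy_split):
        _, entries, _ = toy_split
        resp = next(e for e in entries if e.reaction_id == "RESP")
        assert resp.mw == pytest.approx(2 * 300.0 + 2 * 200.0)

    def test_partial_kcat_coverage(self, toy_bundle):
        model, kcat_table, subunit_table = toy_bundle
        split, _ = preprocess(model)
        table = dict(kcat_table)
        del table["NADHOX"]
        entries = assign_enzyme_entries(split, table, subunit_table)
        assert {e.reaction_id for e in entries} == {"RESP", "FERM_num1", "FERM_num2"}

    def test_derived_id_kcat_overrides_source_id(self, toy_bundle):
        model, kcat_table, subunit_table = toy_bundle
        split, _ = preprocess(model)
        table = dict(kcat_table)
        table["FERM_num2"] = 99.0
        entries = assign_enzyme_entries(split, table, subunit_table)
        by_id = {e.reaction_id: e for e in entries}
        assert by_id["FERM_num2"].kcat == 99.0
        assert by_id["FERM_num1"].kcat == kcat_table["FERM"]

    def test_nonpositive_kcat_is_rejected_naming_the_reaction(self, toy_bundle):
        model, kcat_table, subunit_table = toy_bundle
        split, _ = preprocess(model)
        table = dict(kcat_table)
        table["RESP"] = -5.0
        with pytest.raises(ValueError, match="RESP"):
            assign_enzyme_entries(split, table, subunit_table)

    def test_every_entry_references_a_model_reaction(self, toy_split):
        split, entries, _ = toy_split
        rxn_ids = {r.id for r in split.reactions}
        assert all(e.reaction_id in rxn_ids for e in entries)


class TestEnzymeMassFraction:
    def test_worked_example(self):
        proteome = [
            ProteomeRecord("p1", 2.0, 10.0),
            ProteomeRecord("p2", 1.0, 20.0),
            ProteomeRecord("p3", 1.0, 10.0),
        ]
        assert compute_enzyme_mass_fraction(proteome, {"p1", "p2"}) == pytest.approx(40 / 50)

    def test_full_coverage_gives_one(self):
        proteome = [ProteomeRecord(f"p{i}", 1.0 + i, 10.0 * (i + 1)) for i in range(5)]
        ids = {r.protein_id for r in proteome}
        assert compute_enzyme_mass_fraction(proteome, ids) == pytest.approx(1.0)

    def test_empty_intersection_warns_and_returns_zero(self):
        proteome = [ProteomeRecord("p1", 1.0, 10.0)]
        with pytest.warns(UserWarning, match="no proteome protein matched"):
            assert compute_enzyme_mass_fraction(proteome, {"x"}) == 0.0

    def test_prefix_stripping(self):
        proteome = [ProteomeRecord("511145.b0001", 1.0, 10.0),
                    ProteomeRecord("511145.b0002", 3.0, 10.0)]
        f = compute_enzyme_mass_fraction(proteome, {"b0001"}, id_prefix_strip="511145.")
        assert f == pytest.approx(0.25)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_independent_arithmetic_on_seeded_proteomes(self, seed):
        records, model_ids, expected_f = toy_proteome(seed, n_total=30, n_in_model=11)
        # independent pass: plain python accumulation
        num = sum(r.abundance * r.mw for r in records if r.protein_id in model_ids)
        den = sum(r.abundance * r.mw for r in records)
        f = compute_enzyme_mass_fraction(records, model_ids)
        assert f == pytest.approx(num / den, rel=1e-12)
        assert f == pytest.approx(expected_f, rel=1e-12)

    def test_monotone_in_model_protein_set(self):
        records, _, _ = toy_proteome(1, n_total=20, n_in_model=20)
        ids = sorted(r.protein_id for r in records)
        previous = 0.0
        import warnings

        for k in range(0, 21, 4):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                f = compute_enzyme_mass_fraction(records, set(ids[:k]))
            assert f >= previous - 1e-12
            previous = f


class TestEntryValidation:
    def test_kcat_must_be_positive(self):
        with pytest.raises(ValueError, match="kcat"):
            EnzymeEntry("R", kcat=0.0, mw=10.0)

    def test_sigma_range(self):
        with pytest.raises(ValueError, match="sigma"):
            EnzymeEntry("R", kcat=100.0, mw=10.0, sigma=1.5)

    def test_cost_coefficient_arithmetic(self):
        entry = EnzymeEntry("R", kcat=3.6e6, mw=100.0, sigma=1.0)
        assert entry.cost_coefficient == pytest.approx(100.0 / 3.6e6)


class TestTabularIO:
    def test_kcat_round_trip_and_per_second_conversion(self, tmp_path):
        path = tmp_path / "kcat.tsv"
        write_kcat_table({"R1": 7200.0, "R2": 10.0}, path)
        assert read_kcat_table(path) == {"R1": 7200.0, "R2": 10.0}
        path.write_text("reaction_id\tkcat\tunit\nR1\t2.0\tper_s\n")
        assert read_kcat_table(path) == {"R1": 7200.0}

    def test_unknown_unit_is_rejected(self, tmp_path):
        path = tmp_path / "kcat.tsv"
        path.write_text("reaction_id\tkcat\tunit\nR1\t2.0\tper_min\n")
        with pytest.raises(ValueError, match="per_min"):
            read_kcat_table(path)

    def test_subunit_round_trip(self, tmp_path):
        table = {"g1": (2, 300.0), "g2": (1, 50.5)}
        path = tmp_path / "sub.tsv"
        write_subunit_table(table, path)
        assert read_subunit_table(path) == table

    def test_proteome_round_trip(self, tmp_path):
        records, _, _ = toy_proteome(5, 8, 3)
        path = tmp_path / "prot.tsv"
        write_proteome_table(records, path)
        loaded = read_proteome_table(path)
        assert [r.protein_id for r in loaded] == [r.protein_id for r in records]
        for got, want in zip(loaded, records):
            # text round trip is faithful to double precision
            assert got.abundance == pytest.approx(want.abundance, rel=1e-12)
            assert got.mw == pytest.approx(want.mw, rel=1e-12)
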