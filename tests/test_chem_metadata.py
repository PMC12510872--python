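"""Structure curation, descriptors, sample IDs, sequences, dedup."""

import re
from datetime import date

import pandas as pd
import pytest
from rdkit import Chem
from rdkit.Chem.rdMolDescriptors import CalcMolFormula

from msnforge.chem_metadata import (
    INCHIKEY_RE,
    Plate,
    StructureError,
    assign_sample_ids,
    compute_descriptors,
    curate_table,
    dedupe_structures,
    generate_sequence,
    make_demo_library,
    standardize_structure,
)

# independent oracle: most-abundant-isotope masses (CODATA/AME tabulated)
ISOTOPE_MASS = {
    "C": 12.0,
    "H": 1.0078250319,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "S": 31.97207069,
    "P": 30.97376151,
    "F": 18.99840320,
    "Cl": 34.96885271,
    "Br": 78.9183376,
    "Na": 22.98976928,
    "K": 38.96370649,
}


def formula_mass(formula: str) -> float:
    """Sum tabulated isotope masses over a molecular-formula string."""
    total = 0.0
    for element, count in re.findall(r"([A-Z][a-z]?)(\d*)", formula):
        if element:
            total += ISOTOPE_MASS[element] * (int(count) if count else 1)
    return total


class TestStandardize:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            ("CC(=O)[O-].[Na+]", "CC(=O)O"),  # sodium acetate -> acetic acid
            ("CC(=O)O", "CC(=O)O"),
            ("c1ccccc1", "c1ccccc1"),
            ("[Na+].[Cl-].NCCc1ccccc1", "NCCc1ccccc1"),  # salt + parent
        ],
    )
    def test_salt_removal_and_neutralization(self, raw, expected):
        assert standardize_structure(raw) == Chem.CanonSmiles(expected)

    @pytest.mark.parametrize(
        "raw",
        ["CC(=O)[O-].[Na+]", "CCN.Cl", "OC(=O)CC(O)(CC(O)=O)C(O)=O.OCCN(CCO)CCO", "c1ccncc1"],
    )
    def test_idempotent(self, raw):
        once = standardize_structure(raw)
        assert standardize_structure(once) == once

    def test_inchi_input_accepted(self):
        out = standardize_structure("InChI=1S/C2H4O2/c1-2(3)4/h1H3,(H,3,4)")
        assert out == Chem.CanonSmiles("CC(=O)O")

    @pytest.mark.parametrize("raw", ["", "   ", "not_a_smiles(", "InChI=junk"])
    def test_bad_input_raises(self, raw):
        with pytest.raises(StructureError):
            standardize_structure(raw)

    def test_output_single_component(self):
        assert "." not in standardize_structure("CCN.Cl.Cl")


class TestDescriptors:
    def test_glucose_monoisotopic_mass(self):
        d = compute_descriptors("OCC1OC(O)C(O)C(O)C1O")
        oracle = 6 * 12.0 + 12 * 1.0078250319 + 6 * 15.9949146221
        assert d["formula"] == "C6H12O6"
        assert d["monoisotopic_mass"] == pytest.approx(oracle, abs=1e-3)
        assert d["monoisotopic_mass"] == pytest.approx(180.0634, abs=1e-3)

    def test_water_monoisotopic_mass(self):
        assert compute_descriptors("O")["monoisotopic_mass"] == pytest.approx(18.0106, abs=1e-3)

    def test_inchikey_shape(self):
        assert INCHIKEY_RE.match(compute_descriptors("CCO")["inchikey"])

    def test_stereoisomers_share_first_block(self):
        l_ala = compute_descriptors("C[C@@H](N)C(=O)O")
        d_ala = compute_descriptors("C[C@H](N)C(=O)O")
        assert l_ala["inchikey"][:14] == d_ala["inchikey"][:14]
        assert l_ala["inchikey"] != d_ala["inchikey"]

    def test_mass_matches_isotope_sum_oracle_on_many_structures(self):
        """monoisotopic mass == independent isotope-mass summation, 1e-4 Da."""
        extra = ["CCS", "CC(=O)NC", "FC(F)(F)c1ccccc1", "ClCCBr", "OP(=O)(O)OC"]
        for smi in make_demo_library(50) + extra:
            d = compute_descriptors(smi)
            assert d["monoisotopic_mass"] == pytest.approx(
                formula_mass(d["formula"]), abs=1e-4
            ), smi


class TestSampleIds:
    def _rec(self, **kw):
        from msnforge.chem_metadata import CompoundRecord

        base = dict(
            source_name="x", raw_structure="CCO", library_code="MCEBIO", plate="1", well="A3"
        )
        base.update(kw)
        return CompoundRecord(**base)

    def test_construction_rule(self):
        (rec,) = assign_sample_ids([self._rec()])
        assert rec.unique_sample_id == "MCEBIO_1_A3"

    def test_ten_compounds_share_one_well_id(self):
        recs = assign_sample_ids([self._rec(source_name=f"c{i}") for i in range(10)])
        assert len({r.unique_sample_id for r in recs}) == 1

    def test_plates_distinguish_ids(self):
        a, b = assign_sample_ids([self._rec(plate="1"), self._rec(plate="2")])
        assert a.unique_sample_id != b.unique_sample_id

    def test_missing_well_is_error(self):
        with pytest.raises(ValueError, match="plate/well"):
            assign_sample_ids([self._rec(well="")])


class TestSequence:
    def test_polarity_ordering_and_count(self):
        rows = generate_sequence([Plate("L", "1", ["A1", "A2"])], date(2026, 1, 1), "FIMSN")
        assert [r.polarity for r in rows] == ["positive", "positive", "negative", "negative"]
        assert len(rows) == 2 * 2

    def test_filenames_contain_sample_id(self, demo_sequence):
        for row in demo_sequence:
            assert row.unique_sample_id in row.filename

    def test_row_count_is_twice_well_count(self):
        plates = [Plate("L", str(p), [f"B{i}" for i in range(6)]) for p in range(7)]
        rows = generate_sequence(plates, date(2026, 1, 1), "M")
        assert len(rows) == 2 * 7 * 6

    def test_filename_roundtrips_to_exactly_one_well(self, demo_sequence, demo_records):
        """Extracting the sample-ID substring recovers exactly one metadata well."""
        well_ids = {r.unique_sample_id for r in demo_records}
        for row in demo_sequence:
            hits = {usid for usid in well_ids if usid in row.filename}
            assert hits == {row.unique_sample_id}

    def test_duplicate_well_is_error(self):
        with pytest.raises(ValueError, match="duplicate"):
            generate_sequence([Plate("L", "1", ["A1", "A1"])], date(2026, 1, 1), "M")


class TestCurateTable:
    def test_rejects_collected_not_fatal(self):
        df = pd.DataFrame(
            {
                "name": ["good", "broken", "empty"],
                "structure": ["CCO", "xx(", ""],
                "library": "L",
                "plate": "1",
                "well": ["A1", "A1", "A2"],
            }
        )
        records, rejects = curate_table(df)
        assert len(records) == 1 and records[0].source_name == "good"
        assert sorted(rejects["reason"]) == ["empty_structure", "unparseable_structure"]

    def test_all_descriptors_populated(self):
        df = pd.DataFrame(
            {"name": ["a"], "structure": ["CC(=O)[O-].[Na+]"], "library": "L", "plate": "1", "well": "A1"}
        )
        (rec,), _ = curate_table(df)
        assert rec.cleaned_smiles == "CC(=O)O"
        assert rec.formula == "C2H4O2"
        assert rec.monoisotopic_mass > 0 and rec.inchikey and rec.inchi


class TestDedupe:
    def _records(self, smiles_list):
        df = pd.DataFrame(
            {
                "name": [f"c{i}" for i in range(len(smiles_list))],
                "structure": smiles_list,
                "library": "L",
                "plate": "1",
                "well": "A1",
            }
        )
        records, _ = curate_table(df)
        return records

    def test_stereoisomers(self):
        recs = self._records(["C[C@@H](N)C(=O)O", "C[C@H](N)C(=O)O"])
        assert dedupe_structures(recs, stereo=False)[1] == 1
        assert dedupe_structures(recs, stereo=True)[1] == 2

    def test_count_ordering_invariant(self):
        recs = self._records(
            ["C[C@@H](N)C(=O)O", "C[C@H](N)C(=O)O", "CC(N)C(=O)O", "CCO", "CCO"]
        )
        total, flat, _ = dedupe_structures(recs, stereo=False)
        _, stereo, _ = dedupe_structures(recs, stereo=True)
        assert flat <= stereo <= total


def test_enrichment_hooks_are_optional_and_composable():
    from msnforge.chem_metadata import CompoundRecord, enrich_records

    rec = CompoundRecord(source_name="x", raw_structure="CCO", inchikey="A" * 14)
    assert enrich_records([rec]) == [(rec, {})]
    hooks = [lambda r: {"is_drug": False}, lambda r: {"source": "local"}]
    (_, extra), = enrich_records([rec], hooks)
    assert extra == {"is_drug": False, "source": "local"}
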