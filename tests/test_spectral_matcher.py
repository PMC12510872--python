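"""Weighted cosine, library search, overlap sets, Tanimoto similarity."""

import random

import numpy as np
import pytest

from msnforge.spectral_matcher import (
    library_search,
    optimal_cosine,
    overlap_sets,
    remove_precursor_peaks,
    tanimoto_similarity,
    weighted_cosine,
)
from conftest import random_entry


class TestRemovePrecursor:
    PEAKS = [(100.0, 1.0), (195.0, 2.0), (200.0, 3.0), (205.0, 4.0)]

    def test_precursor_and_above_removed(self):
        out = remove_precursor_peaks(self.PEAKS, 200.0, 0.01)
        assert [mz for mz, _ in out] == [100.0, 195.0]

    def test_distant_lower_peak_kept(self):
        assert (195.0, 2.0) in remove_precursor_peaks(self.PEAKS, 200.0, 0.01)

    def test_all_above_gives_empty(self):
        assert remove_precursor_peaks(self.PEAKS, 50.0, 0.01) == []

    def test_window_mode_removes_only_the_window(self):
        out = remove_precursor_peaks(self.PEAKS, 200.0, 0.01, mode="window")
        assert [mz for mz, _ in out] == [100.0, 195.0, 205.0]


class TestWeightedCosine:
    def test_identical_spectra_score_one(self):
        peaks = [(100.0, 5.0), (150.0, 2.0), (200.0, 9.0)]
        score, matched = weighted_cosine(peaks, peaks, 0.01)
        assert score == pytest.approx(1.0)
        assert matched == 3

    def test_disjoint_spectra_score_zero(self):
        score, matched = weighted_cosine([(100.0, 5.0)], [(300.0, 5.0)], 0.01)
        assert score == 0.0 and matched == 0

    def test_hand_computed_example(self):
        """sqrt-intensity weights: products 12, norms 13x13 -> 144/169."""
        a = [(100.0, 4.0), (200.0, 9.0)]
        b = [(100.0, 9.0), (200.0, 4.0)]
        score, matched = weighted_cosine(a, b, 0.01)
        assert score == pytest.approx(144 / 169)
        assert matched == 2
        # the brute-force optimal assignment agrees here
        assert optimal_cosine(a, b, 0.01)[0] == pytest.approx(score)

    def test_symmetry(self):
        rng = random.Random(2)
        for _ in range(20):
            a = sorted((rng.uniform(50, 500), rng.uniform(1, 100)) for _ in range(8))
            b = sorted((rng.uniform(50, 500), rng.uniform(1, 100)) for _ in range(8))
            sa, _ = weighted_cosine(a, b, 0.5)
            sb, _ = weighted_cosine(b, a, 0.5)
            assert sa == pytest.approx(sb, abs=1e-12)

    def test_intensity_scale_invariance(self):
        rng = random.Random(3)
        a = sorted((rng.uniform(50, 500), rng.uniform(1, 100)) for _ in range(10))
        b = sorted((rng.uniform(50, 500), rng.uniform(1, 100)) for _ in range(10))
        base, _ = weighted_cosine(a, b, 1.0)
        for c in (1e-3, 7.0, 1e5):
            scaled = [(mz, i * c) for mz, i in a]
            assert weighted_cosine(scaled, b, 1.0)[0] == pytest.approx(base)

    def test_greedy_never_exceeds_optimal(self):
        rng = random.Random(17)
        for _ in range(200):
            n, m = rng.randint(1, 6), rng.randint(1, 6)
            a = sorted((rng.uniform(100, 102), rng.uniform(1, 100)) for _ in range(n))
            b = sorted((rng.uniform(100, 102), rng.uniform(1, 100)) for _ in range(m))
            greedy, _ = weighted_cosine(a, b, 0.5)
            optimal, _ = optimal_cosine(a, b, 0.5)
            assert greedy <= optimal + 1e-12

    def test_matches_matchms_reference_on_unambiguous_spectra(self):
        """On well-separated peaks the greedy pairing is unique, and the
        score equals the square of matchms's CosineGreedy (which reports
        the un-squared cosine with the same sqrt-intensity weighting)."""
        matchms = pytest.importorskip("matchms")
        from matchms.similarity import CosineGreedy

        rng = random.Random(8)
        sim = CosineGreedy(tolerance=0.01, mz_power=0.0, intensity_power=0.5)
        for _ in range(10):
            mzs = np.sort(rng.sample(range(100, 900), 12)).astype(float)
            a = [(mz, rng.uniform(10, 100)) for mz in mzs]
            keep = [p for p in a if rng.random() < 0.7] or a[:1]
            b = [(mz + rng.uniform(-0.003, 0.003), i * rng.uniform(0.5, 2)) for mz, i in keep]
            spec_a = matchms.Spectrum(
                mz=np.array([p[0] for p in a]), intensities=np.array([p[1] for p in a]),
                metadata={"precursor_mz": 1000.0}, metadata_harmonization=False,
            )
            spec_b = matchms.Spectrum(
                mz=np.array([p[0] for p in b]), intensities=np.array([p[1] for p in b]),
                metadata={"precursor_mz": 1000.0}, metadata_harmonization=False,
            )
            ref = sim.pair(spec_a, spec_b)
            ours, matched = weighted_cosine(a, b, 0.01)
            assert ours == pytest.approx(float(ref["score"]) ** 2, abs=1e-9)
            assert matched == int(ref["matches"])


class TestLibrarySearch:
    def _query_library(self):
        rng = random.Random(21)
        lib = [random_entry(rng, i) for i in range(10)]
        return lib

    def test_identical_query_is_rank_one_with_score_one(self):
        lib = self._query_library()
        results = library_search([lib[3]], lib, min_matched=2)
        assert results and results[0].score == pytest.approx(1.0)
        assert results[0].library_id.startswith(lib[3].compound.inchikey)

    def test_precursor_off_by_one_Th_yields_nothing(self):
        import copy

        lib = self._query_library()
        q = copy.deepcopy(lib[0])
        q.precursor_mz += 1.0
        assert library_search([q], lib, min_matched=2) == []

    def test_min_matched_signals_enforced(self):
        """A high-scoring 3-peak overlap is excluded at min_matched=4."""
        from msnforge.msdata_io import LibraryEntry

        base = random_entry(random.Random(5))
        peaks = [(100.0, 10.0), (150.0, 20.0), (200.0, 30.0)]
        q = LibraryEntry(
            compound=base.compound, adduct_name="[M+H]+", precursor_mz=400.0,
            ms_level=2, spec_type="SINGLE_BEST_SCAN", collision_energies=[20.0], peaks=peaks,
        )
        lib_entry = LibraryEntry(
            compound=base.compound, adduct_name="[M+H]+", precursor_mz=400.0,
            ms_level=2, spec_type="SINGLE_BEST_SCAN", collision_energies=[20.0], peaks=list(peaks),
        )
        assert library_search([q], [lib_entry], min_matched=4) == []
        hits = library_search([q], [lib_entry], min_matched=3)
        assert hits and hits[0].matched_signals == 3


class TestOverlapSets:
    def test_shared_block_counted_once(self):
        key = "AAAAAAAAAAAAAA-BBBBBBBBBB-N"
        out = overlap_sets({"A": [key], "B": [key]})
        assert out["patterns"] == {("A", "B"): 1}
        assert out["uniques"] == {"A": 0, "B": 0}

    def test_partial_overlap(self):
        x = "AAAAAAAAAAAAAA-BBBBBBBBBB-N"
        y = "CCCCCCCCCCCCCC-DDDDDDDDDD-N"
        out = overlap_sets({"A": [x, y], "B": [y]})
        assert out["patterns"][("A",)] == 1 and out["patterns"][("A", "B")] == 1

    def test_stereoisomers_count_as_shared(self):
        out = overlap_sets(
            {"A": ["AAAAAAAAAAAAAA-BBBBBBBBBB-N"], "B": ["AAAAAAAAAAAAAA-ZZZZZZZZZZ-N"]}
        )
        assert out["patterns"] == {("A", "B"): 1}

    def test_pattern_counts_sum_to_union(self):
        rng = random.Random(12)
        from conftest import random_inchikey

        pool = [random_inchikey(rng) for _ in range(50)]
        sources = {s: rng.sample(pool, rng.randint(5, 40)) for s in "ABCD"}
        out = overlap_sets(sources)
        assert sum(out["patterns"].values()) == out["union"]
        assert out["union"] == len({k.split("-")[0] for keys in sources.values() for k in keys})

    def test_malformed_key_is_error(self):
        with pytest.raises(ValueError, match="bad-key"):
            overlap_sets({"A": ["bad-key"]})

    def test_first_blocks_accepted_directly(self):
        assert overlap_sets({"A": ["AAAAAAAAAAAAAA"]})["union"] == 1


class TestTanimoto:
    def test_identical_structures(self):
        assert tanimoto_similarity("c1ccccc1O", "Oc1ccccc1") == 1.0

    def test_disjoint_fingerprints(self):
        assert tanimoto_similarity("C", "N") == 0.0

    def test_benzene_toluene_matches_bitset_oracle(self):
        from rdkit import Chem
        from rdkit.Chem import rdFingerprintGenerator

        gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)
        bits = [
            set(gen.GetFingerprint(Chem.MolFromSmiles(s)).GetOnBits())
            for s in ("c1ccccc1", "Cc1ccccc1")
        ]
        oracle = len(bits[0] & bits[1]) / len(bits[0] | bits[1])
        value = tanimoto_similarity("c1ccccc1", "Cc1ccccc1")
        assert 0.0 < value < 1.0
        assert value == pytest.approx(oracle)

    def test_unparseable_raises(self):
        with pytest.raises(ValueError):
            tanimoto_similarity("xx(", "CC")
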