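"""Consensus/merged spectrum construction and the pseudo-MS^2 composite."""

import random

import numpy as np
import pytest

from msnforge.spectral_merger import (
    bin_peaks,
    build_pseudo_ms2,
    merge_all_energies,
    merge_same_energy,
)
from msnforge.tree_builder import build_trees
from conftest import make_scan


class TestBinPeaks:
    def test_identical_spectra_collapse_to_normalized_input(self):
        spec = [(100.0, 50.0), (200.0, 100.0)]
        out = bin_peaks([spec, spec], mz_tol=0.01)
        assert [mz for mz, _ in out] == pytest.approx([100.0, 200.0])
        assert [i for _, i in out] == pytest.approx([50.0, 100.0])

    def test_close_peaks_merge_to_weighted_mean(self):
        out = bin_peaks([[(100.000, 100.0)], [(100.004, 50.0)]], mz_tol=0.01)
        assert len(out) == 1
        # both sources normalize to 100, so the weighted mean is the midpoint
        assert out[0][0] == pytest.approx(100.002)
        assert out[0][1] == pytest.approx(100.0)

    def test_disjoint_sets_union_additively(self):
        a = [(100.0, 10.0), (150.0, 20.0)]
        b = [(300.0, 5.0)]
        assert len(bin_peaks([a, b], mz_tol=0.01)) == 3

    def test_merged_mz_within_member_range_and_intensity_capped(self):
        rng = random.Random(4)
        spectra = [
            sorted((rng.uniform(100, 110), rng.uniform(1, 100)) for _ in range(20))
            for _ in range(4)
        ]
        out = bin_peaks(spectra, mz_tol=0.05)
        lo = min(mz for s in spectra for mz, _ in s)
        hi = max(mz for s in spectra for mz, _ in s)
        for mz, inten in out:
            assert lo <= mz <= hi
            assert inten <= 100.0 + 1e-9

    def test_source_order_invariance(self):
        rng = random.Random(9)
        spectra = [
            sorted((rng.uniform(50, 500), rng.uniform(1, 1e5)) for _ in range(15))
            for _ in range(5)
        ]
        base = bin_peaks(spectra, mz_tol=0.005)
        for _ in range(5):
            rng.shuffle(spectra)
            assert bin_peaks(spectra, mz_tol=0.005) == base

    def test_aggregate_modes(self):
        spectra = [[(100.0, 100.0)], [(100.002, 100.0)]]
        assert bin_peaks(spectra, aggregate="max")[0][1] == pytest.approx(100.0)
        assert bin_peaks(spectra, aggregate="sum")[0][1] == pytest.approx(200.0)
        assert bin_peaks(spectra, aggregate="mean")[0][1] == pytest.approx(100.0)


def tree_with_triggers():
    """Root triggered 3x at 20 eV, 1x at 60 eV, with one MS3 child."""
    scans = [
        make_scan(1, 2, [(100.0, 50), (150.0, 100)], chain=[(301.14, 1.2, 20.0)]),
        make_scan(2, 2, [(100.001, 60), (150.0, 90)], chain=[(301.14, 1.2, 20.0)]),
        make_scan(3, 2, [(100.0, 55), (150.001, 95)], chain=[(301.14, 1.2, 20.0)]),
        make_scan(4, 2, [(90.0, 10), (120.0, 80)], chain=[(301.14, 1.2, 60.0)]),
        make_scan(5, 3, [(91.05, 40)], chain=[(301.14, 1.2, 45.0), (150.0, 2.0, 40.0)]),
    ]
    (root,) = build_trees(scans)
    return root


class TestMergeSameEnergy:
    def test_consensus_over_repeat_triggers(self):
        root = tree_with_triggers()
        merged = merge_same_energy(root, 20.0)
        assert merged is not None
        assert merged.spec_type == "SAME_ENERGY"
        assert merged.collision_energies == [20.0]
        assert merged.source_scans == [1, 2, 3]
        assert len(merged.peaks) == 2  # 100 and 150 bins

    def test_single_trigger_returns_none(self):
        root = tree_with_triggers()
        assert merge_same_energy(root, 60.0) is None

    def test_consensus_count_bounded_by_member_sum(self):
        root = tree_with_triggers()
        merged = merge_same_energy(root, 20.0)
        member_total = sum(
            len(s.peaks) for s in root.member_scans if s.collision_energy == 20.0
        )
        assert len(merged.peaks) <= member_total


class TestMergeAllEnergies:
    def test_lists_every_energy_used(self):
        merged = merge_all_energies(tree_with_triggers())
        assert merged.spec_type == "ALL_ENERGIES"
        assert merged.collision_energies == [20.0, 60.0]

    def test_single_energy_equals_that_spectrum_normalized(self):
        scans = [make_scan(1, 2, [(100.0, 50.0), (150.0, 100.0)], chain=[(301.14, 1.2, 20.0)])]
        (root,) = build_trees(scans)
        merged = merge_all_energies(root)
        assert [i for _, i in merged.peaks] == pytest.approx([50.0, 100.0])

    def test_shared_peak_takes_max_normalized_intensity(self):
        scans = [
            make_scan(1, 2, [(100.0, 30.0), (150.0, 100.0)], chain=[(301.14, 1.2, 20.0)]),
            make_scan(2, 2, [(100.0, 100.0), (150.0, 20.0)], chain=[(301.14, 1.2, 60.0)]),
        ]
        (root,) = build_trees(scans)
        merged = merge_all_energies(root)
        by_mz = dict(merged.peaks)
        assert by_mz[100.0] == pytest.approx(100.0)
        assert by_mz[150.0] == pytest.approx(100.0)


class TestPseudoMs2:
    def test_ms2_only_tree_equals_all_energies(self):
        scans = [
            make_scan(1, 2, [(100.0, 50.0), (150.0, 100.0)], chain=[(301.14, 1.2, 20.0)]),
            make_scan(2, 2, [(90.0, 80.0), (120.0, 40.0)], chain=[(301.14, 1.2, 60.0)]),
        ]
        (root,) = build_trees(scans)
        pseudo = build_pseudo_ms2(root)
        merged = merge_all_energies(root)
        assert pseudo.spec_type == "ALL_MSN_TO_PSEUDO_MS2"
        assert pseudo.ms_level == 2
        assert [mz for mz, _ in pseudo.peaks] == pytest.approx([mz for mz, _ in merged.peaks])

    def test_ms3_only_fragment_appears(self):
        root = tree_with_triggers()
        pseudo = build_pseudo_ms2(root)
        assert any(abs(mz - 91.05) < 0.01 for mz, _ in pseudo.peaks)

    def test_precursor_on_root_precursor(self):
        root = tree_with_triggers()
        assert build_pseudo_ms2(root).precursor_mz == pytest.approx(301.14, abs=0.01)

    def test_pseudo_peak_count_at_least_root_all_energies(self):
        root = tree_with_triggers()
        assert len(build_pseudo_ms2(root).peaks) >= len(merge_all_energies(root).peaks)

    def test_residual_precursor_peaks_excluded(self):
        scans = [
            make_scan(1, 2, [(100.0, 50.0), (301.14, 99.0)], chain=[(301.14, 1.2, 20.0)]),
            make_scan(2, 2, [(100.0, 60.0), (301.141, 80.0)], chain=[(301.14, 1.2, 60.0)]),
        ]
        (root,) = build_trees(scans)
        pseudo = build_pseudo_ms2(root)
        assert all(mz < 301.0 for mz, _ in pseudo.peaks)

    def test_union_rebin_oracle(self):
        """Pseudo-MS^2 peak set equals brute-force union + re-binning of the
        per-node ALL_ENERGIES spectra (precursor-stripped)."""
        from msnforge.spectral_matcher import remove_precursor_peaks

        root = tree_with_triggers()
        pseudo = build_pseudo_ms2(root, mz_tol=0.005)
        union = []
        for node in root.walk():
            merged = merge_all_energies(node, 0.005)
            if merged:
                union.append(remove_precursor_peaks(merged.peaks, node.node_precursor_mz, 0.01))
        oracle = bin_peaks(union, 0.005)
        assert [mz for mz, _ in pseudo.peaks] == pytest.approx([mz for mz, _ in oracle])
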