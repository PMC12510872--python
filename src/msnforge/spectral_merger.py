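"""Multi-level spectral merging.

Three merge products per annotated precursor node, tagged via SPECTYPE:

* SAME_ENERGY — consensus over repeat triggers of one collision energy;
* ALL_ENERGIES — merge across all energies of a precursor, preferring
  each energy's SAME_ENERGY consensus, else its best (highest-TIC) scan;
* ALL_MSN_TO_PSEUDO_MS2 — the whole MS^n subtree collapsed into one
  MS^2-like composite fragment spectrum.

Merging normalizes every source spectrum to base peak 100 and bins peaks
greedily in ascending m/z (single linkage); a merged peak's m/z is the
intensity-weighted mean of its members and its intensity the maximum of
the normalized member intensities, which preserves fragments that are
prominent at any single energy. Sum/mean aggregation is selectable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

from .msdata_io import ScanRecord
from .tree_builder import MsnTreeNode, select_best_scan
from .spectral_matcher import remove_precursor_peaks

Peaks = list[tuple[float, float]]

DEFAULT_BIN_TOL = 0.005  # Th, matches the library-search fragment tolerance
BASE_PEAK_NORM = 100.0


@dataclass
class MergedSpectrum:
    """A merged peak list plus the metadata needed to build a LibraryEntry."""

    peaks: Peaks
    spec_type: str
    collision_energies: list[float]
    ms_level: int
    precursor_mz: float
    source_scans: list[int] = field(default_factory=list)


def _normalize(peaks: Sequence[tuple[float, float]]) -> Peaks:
    if not peaks:
        return []
    top = max(i for _, i in peaks)
    if top <= 0:
        return []
    return [(mz, i / top * BASE_PEAK_NORM) for mz, i in peaks]


def bin_peaks(
    spectra: Sequence[Sequence[tuple[float, float]]],
    mz_tol: float = DEFAULT_BIN_TOL,
    aggregate: Literal["max", "sum", "mean"] = "max",
) -> Peaks:
    """Merge peak lists: base-peak-normalize each source, pool, group
    peaks within ``mz_tol`` (greedy ascending single linkage), return
    intensity-weighted mean m/z per group with max/sum/mean intensity."""
    pool: Peaks = []
    for spec in spectra:
        pool.extend(_normalize(spec))
    if not pool:
        return []
    pool.sort()
    merged: Peaks = []
    group: Peaks = [pool[0]]
    for mz, inten in pool[1:]:
        if mz - group[-1][0] <= mz_tol:
            group.append((mz, inten))
        else:
            merged.append(_collapse(group, aggregate))
            group = [(mz, inten)]
    merged.append(_collapse(group, aggregate))
    return merged


def _collapse(group: Peaks, aggregate: str) -> tuple[float, float]:
    wsum = sum(i for _, i in group)
    if wsum > 0:
        mz = sum(mz * i for mz, i in group) / wsum
    else:
        mz = sum(mz for mz, _ in group) / len(group)
    intensities = [i for _, i in group]
    if aggregate == "max":
        return mz, max(intensities)
    if aggregate == "sum":
        return mz, sum(intensities)
    if aggregate == "mean":
        return mz, sum(intensities) / len(intensities)
    raise ValueError(f"unknown aggregate {aggregate!r}")


def merge_same_energy(
    node: MsnTreeNode, energy: float, mz_tol: float = DEFAULT_BIN_TOL, aggregate: str = "max"
) -> MergedSpectrum | None:
    """Consensus over repeat triggers at one energy; None if < 2 scans
    (the caller then falls back to the single best scan)."""
    scans = [s for s in node.member_scans if s.collision_energy == energy]
    if len(scans) < 2:
        return None
    peaks = bin_peaks([s.peaks for s in scans], mz_tol, aggregate)
    return MergedSpectrum(
        peaks=peaks,
        spec_type="SAME_ENERGY",
        collision_energies=[energy],
        ms_level=node.ms_level,
        precursor_mz=node.node_precursor_mz,
        source_scans=sorted(s.scan_number for s in scans),
    )


def merge_all_energies(
    node: MsnTreeNode, mz_tol: float = DEFAULT_BIN_TOL, aggregate: str = "max"
) -> MergedSpectrum | None:
    """Merge across every energy of the node, using each energy's
    SAME_ENERGY consensus when available, otherwise its best scan."""
    per_energy: list[Peaks] = []
    energies: list[float] = []
    sources: list[int] = []
    for energy in node.energies():
        consensus = merge_same_energy(node, energy, mz_tol, aggregate)
        if consensus is not None:
            per_energy.append(consensus.peaks)
            sources.extend(consensus.source_scans)
        else:
            best = select_best_scan(node, energy)
            if best is None or not best.peaks:
                continue
            per_energy.append(list(best.peaks))
            sources.append(best.scan_number)
        energies.append(energy)
    if not per_energy:
        return None
    return MergedSpectrum(
        peaks=bin_peaks(per_energy, mz_tol, aggregate),
        spec_type="ALL_ENERGIES",
        collision_energies=energies,
        ms_level=node.ms_level,
        precursor_mz=node.node_precursor_mz,
        source_scans=sorted(sources),
    )


def build_pseudo_ms2(
    root: MsnTreeNode,
    mz_tol: float = DEFAULT_BIN_TOL,
    aggregate: str = "max",
    precursor_removal_tol: float = 0.01,
) -> MergedSpectrum | None:
    """Collapse the full MS^n tree into one pseudo-MS^2 spectrum.

    Each node contributes its ALL_ENERGIES merge with that stage's
    residual precursor peak (and anything above it) removed, so the
    composite is a pure fragment spectrum on the root precursor. No
    per-level intensity re-weighting is applied.
    """
    contributions: list[Peaks] = []
    energies: set[float] = set()
    sources: list[int] = []
    for node in root.walk():
        merged = merge_all_energies(node, mz_tol, aggregate)
        if merged is None:
            continue
        peaks = remove_precursor_peaks(merged.peaks, node.node_precursor_mz, precursor_removal_tol)
        if not peaks:
            continue
        contributions.append(peaks)
        energies.update(merged.collision_energies)
        sources.extend(merged.source_scans)
    if not contributions:
        return None
    return MergedSpectrum(
        peaks=bin_peaks(contributions, mz_tol, aggregate),
        spec_type="ALL_MSN_TO_PSEUDO_MS2",
        collision_energies=sorted(energies),
        ms_level=2,
        precursor_mz=root.node_precursor_mz,
        source_scans=sorted(set(sources)),
    )
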