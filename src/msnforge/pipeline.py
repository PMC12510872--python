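"""End-to-end library generation.

Per scan file: read → denoise + background removal → MS^n tree building
→ sample-constrained adduct annotation → precursor-purity scoring →
best/merged spectra (SINGLE_BEST_SCAN, SAME_ENERGY, ALL_ENERGIES,
ALL_MSN_TO_PSEUDO_MS2) → minimum-two-signal filter → export per
polarity to MGF/MSP/JSON, plus a machine-readable run report with
per-stage counters and detection-by-polarity membership counts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

from . import annotator as _annotator
from .annotator import Annotation, annotate_forest, compounds_for_file
from .chem_metadata import CompoundRecord
from .msdata_io import LibraryEntry, ScanRecord, read_scans, write_library
from .quality_filters import (
    DEFAULT_CHIMERIC_THRESHOLD_PCT,
    DEFAULT_EXCLUSION_WINDOWS,
    DEFAULT_MIN_SIGNALS,
    DEFAULT_NOISE_FACTOR,
    ExclusionWindow,
    min_signal_filter,
    noise_filter,
    precursor_purity,
    remove_background,
)
from .spectral_merger import (
    DEFAULT_BIN_TOL,
    MergedSpectrum,
    build_pseudo_ms2,
    merge_all_energies,
    merge_same_energy,
)
from .spectral_matcher import overlap_sets
from .tree_builder import DEFAULT_MZ_TOL, MsnTreeNode, build_trees, select_best_scan

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Every pipeline threshold as a named key; method defaults."""

    noise_factor: float = DEFAULT_NOISE_FACTOR
    exclusion_windows: tuple[ExclusionWindow, ...] = DEFAULT_EXCLUSION_WINDOWS
    tree_mz_tol: float = DEFAULT_MZ_TOL
    annot_tol_ppm: float = 10.0
    annot_tol_abs: float = 0.005
    purity_match_tol: float = 0.01
    purity_n_isotopes: int = 3
    chimeric_threshold_pct: float = DEFAULT_CHIMERIC_THRESHOLD_PCT
    min_signals: int = DEFAULT_MIN_SIGNALS
    bin_mz_tol: float = DEFAULT_BIN_TOL
    aggregate: str = "max"


def coverage_percent(detected: int, sourced: int) -> float:
    """Detected unique structures as a percentage of those sourced."""
    if sourced <= 0:
        raise ValueError("sourced count must be positive")
    return 100.0 * detected / sourced


def _flanking_ms1(scans: Sequence[ScanRecord], scan_number: int):
    """Nearest MS^1 scans before and after the given scan number."""
    before = after = None
    for s in scans:
        if s.ms_level != 1:
            continue
        if s.scan_number < scan_number:
            before = s
        elif s.scan_number > scan_number and after is None:
            after = s
    return before, after


def _entry_from_merged(
    merged: MergedSpectrum,
    annotation: Annotation,
    filename: str,
    purity_pct: float | None,
    chimeric: bool,
) -> LibraryEntry:
    return LibraryEntry(
        compound=annotation.compound,
        adduct_name=annotation.adduct.name,
        precursor_mz=merged.precursor_mz,
        ms_level=merged.ms_level,
        spec_type=merged.spec_type,
        collision_energies=list(merged.collision_energies),
        peaks=merged.peaks,
        precursor_purity_pct=purity_pct,
        chimeric_flag=chimeric,
        provenance={filename: merged.source_scans},
    )


def process_file(
    path: str | Path,
    metadata: Sequence[CompoundRecord],
    config: PipelineConfig = PipelineConfig(),
) -> tuple[list[LibraryEntry], dict]:
    """Run the full per-file pipeline; returns (entries, file report)."""
    path = Path(path)
    filename = path.stem.removesuffix(".scanjson")
    scans = read_scans(path)
    stats = {
        "file": path.name,
        "scans_in": len(scans),
        "msn_scans": sum(1 for s in scans if s.ms_level >= 2),
        "peaks_in": sum(len(s.peaks) for s in scans),
    }
    polarity = scans[0].polarity if scans else "positive"

    filtered = [
        remove_background(noise_filter(s, config.noise_factor), config.exclusion_windows)
        for s in scans
    ]
    stats["peaks_after_filters"] = sum(len(s.peaks) for s in filtered)

    forest = build_trees([s for s in filtered if s.ms_level >= 2], config.tree_mz_tol)
    stats["trees"] = sum(1 for r in forest if not r.orphan)
    stats["orphan_trees"] = sum(1 for r in forest if r.orphan)

    candidates = compounds_for_file(filename, metadata)
    stats["candidate_compounds"] = len(candidates)
    if not candidates:
        logger.warning("%s: no metadata compounds match the file name", path.name)

    annotations = annotate_forest(
        forest,
        candidates,
        tol_ppm=config.annot_tol_ppm,
        tol_abs=config.annot_tol_abs,
        polarity=polarity,
    )
    stats["annotations"] = len(annotations)

    entries: list[LibraryEntry] = []
    rejected_min_signal = 0
    for ann in annotations:
        root = ann.node
        # isolation purity of the root precursor, averaged over member MS2 scans
        purities = []
        chimeric_any = False
        for scan in root.member_scans:
            before, after = _flanking_ms1(filtered, scan.scan_number)
            if before is None:
                continue
            res = precursor_purity(
                before,
                after,
                scan.precursor_chain[0].precursor_mz,
                scan.precursor_chain[0].isolation_width,
                match_tol=config.purity_match_tol,
                n_isotopes=config.purity_n_isotopes,
                chimeric_threshold_pct=config.chimeric_threshold_pct,
            )
            purities.append(res.purity_pct)
            chimeric_any = chimeric_any or res.chimeric_flag
        purity = sum(purities) / len(purities) if purities else None
        chimeric = chimeric_any if purities else False

        for node in root.walk():
            node_purity = purity if node.ms_level == 2 else None
            node_chim = chimeric if node.ms_level == 2 else False
            for energy in node.energies():
                consensus = merge_same_energy(node, energy, config.bin_mz_tol, config.aggregate)
                if consensus is None:
                    best = select_best_scan(node, energy)
                    if best is None or not best.peaks:
                        continue
                    consensus = MergedSpectrum(
                        peaks=list(best.peaks),
                        spec_type="SINGLE_BEST_SCAN",
                        collision_energies=[energy],
                        ms_level=node.ms_level,
                        precursor_mz=node.node_precursor_mz,
                        source_scans=[best.scan_number],
                    )
                if not min_signal_filter(consensus.peaks, config.min_signals):
                    rejected_min_signal += 1
                    continue
                entries.append(
                    _entry_from_merged(consensus, ann, filename, node_purity, node_chim)
                )
            if len(node.energies()) >= 2:
                merged = merge_all_energies(node, config.bin_mz_tol, config.aggregate)
                if merged is not None:
                    if min_signal_filter(merged.peaks, config.min_signals):
                        entries.append(
                            _entry_from_merged(merged, ann, filename, node_purity, node_chim)
                        )
                    else:
                        rejected_min_signal += 1
        pseudo = build_pseudo_ms2(root, config.bin_mz_tol, config.aggregate)
        if pseudo is not None:
            if min_signal_filter(pseudo.peaks, config.min_signals):
                entries.append(_entry_from_merged(pseudo, ann, filename, purity, chimeric))
            else:
                rejected_min_signal += 1

    stats["entries"] = len(entries)
    stats["rejected_min_signal"] = rejected_min_signal
    stats["polarity"] = polarity
    return entries, stats


def build_library(
    metadata: Sequence[CompoundRecord],
    scan_files: Sequence[str | Path],
    outdir: str | Path,
    config: PipelineConfig = PipelineConfig(),
    formats: Sequence[str] = ("mgf", "msp", "json"),
    stereo: bool = True,
) -> dict:
    """Process every scan file and export per-polarity libraries.

    Returns the run report: per-file stats, attempted/detected compound
    counts per polarity and their membership (UpSet) counts, entry counts
    by SPECTYPE. File-level failures are logged and skipped; raises only
    if every file fails."""
    if not scan_files:
        raise ValueError("no scan files given")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    per_polarity: dict[str, list[LibraryEntry]] = {"positive": [], "negative": []}
    report: dict = {"files": [], "failed_files": []}
    detected: dict[str, set[str]] = {"positive": set(), "negative": set()}
    attempted: dict[str, set[str]] = {"positive": set(), "negative": set()}

    for path in scan_files:
        try:
            entries, stats = process_file(path, metadata, config)
        except Exception as exc:  # file-level failure: log, skip
            logger.error("failed to process %s: %s", path, exc)
            report["failed_files"].append({"file": str(path), "error": str(exc)})
            continue
        report["files"].append(stats)
        pol = stats["polarity"]
        per_polarity[pol].extend(entries)
        fname = Path(path).stem.removesuffix(".scanjson")
        for rec in compounds_for_file(fname, metadata):
            key = rec.inchikey if stereo else rec.inchikey.split("-")[0]
            attempted[pol].add(key)
        for e in entries:
            key = e.compound.inchikey if stereo else e.compound.inchikey.split("-")[0]
            detected[pol].add(key)

    if not report["files"]:
        raise RuntimeError("all scan files failed to process")

    outputs = []
    for pol, entries in per_polarity.items():
        if not entries:
            continue
        for fmt in formats:
            out = outdir / f"library_{pol}.{fmt}"
            write_library(entries, out, fmt)
            outputs.append(str(out))
    report["outputs"] = outputs

    spectype_counts: dict[str, int] = {}
    for entries in per_polarity.values():
        for e in entries:
            spectype_counts[e.spec_type] = spectype_counts.get(e.spec_type, 0) + 1
    report["entries_by_spectype"] = spectype_counts
    report["entry_counts"] = {pol: len(v) for pol, v in per_polarity.items()}

    detection_upset = overlap_sets(
        {pol: [k if len(k) == 27 else f"{k}-UHFFFAOYSA-N" for k in keys] for pol, keys in detected.items() if keys}
    ) if any(detected.values()) else {"patterns": {}, "uniques": {}, "union": 0}
    report["compounds"] = {
        "attempted": {pol: len(v) for pol, v in attempted.items()},
        "detected": {pol: len(v) for pol, v in detected.items()},
        "detected_total": len(detected["positive"] | detected["negative"]),
        "attempted_total": len(attempted["positive"] | attempted["negative"]),
        "detection_by_polarity": {
            "+".join(pat): n for pat, n in detection_upset["patterns"].items()
        },
    }
    total_attempted = report["compounds"]["attempted_total"]
    if total_attempted:
        report["compounds"]["coverage_pct"] = coverage_percent(
            report["compounds"]["detected_total"], total_attempted
        )
    (outdir / "report.json").write_text(json.dumps(report, indent=1))
    return report
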