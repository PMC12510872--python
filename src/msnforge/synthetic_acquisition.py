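"""Synthetic pooled-well flow-injection MS^n acquisition.

Emulates the data-dependent MS^2–MS^5 schema used for library
acquisition so every pipeline stage is testable without instrument data:
survey MS^1 scans of pooled wells (up to 10 compounds, several adducts
each, isotope envelopes, background ions, a noise floor), top-3 MS^2
selection with per-polarity minimum-intensity gates and three collision
energies, top-5 MS^3 from the assisted-energy MS^2 scan, top-2 MS^4 from
the 40 eV MS^3, top-2 MS^5 from the 40 eV MS^4, repeat triggers (each
precursor selected three times, as under dynamic exclusion), and
optional chimeric co-isolation.

Fragment m/z values are random neutral losses from the precursor
(always below it, never under 50 Th) — chemically plain, but sufficient
to exercise tree building, merging, annotation and matching. Every
emitted (compound, adduct, tree) is recorded as ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .annotator import DEFAULT_ADDUCTS, AdductDefinition, expected_ion_mz
from .chem_metadata import CompoundRecord, SequenceRow
from .msdata_io import PrecursorStep, ScanRecord, write_mzml, write_scanjson
from .quality_filters import ISOTOPE_SPACING, DEFAULT_EXCLUSION_WINDOWS

DEFAULT_ADDUCT_PROBABILITIES = {
    "[M+H]+": 0.95,
    "[M+Na]+": 0.40,
    "[M+NH4]+": 0.20,
    "[M+K]+": 0.10,
    "[2M+H]+": 0.05,
    "[M+H-H2O]+": 0.15,
    "[M-H]-": 0.95,
    "[M+HCOO]-": 0.30,
    "[M+Cl]-": 0.15,
    "[2M-H]-": 0.05,
}


@dataclass
class SimulationConfig:
    """Acquisition-schema parameters; defaults mirror the instrument method."""

    seed: int = 0
    compounds_per_well: int = 10
    adduct_probabilities: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ADDUCT_PROBABILITIES)
    )
    fragments_per_level: tuple[int, int] = (3, 8)
    noise_peaks_per_scan: tuple[int, int] = (5, 15)
    noise_intensity_logmean: float = 8.0  # ln a.u.; median ~3e3
    noise_intensity_logsigma: float = 0.8
    background_ions: tuple[tuple[float, float, float], ...] = tuple(
        (w.center_mz, w.width, 5e4) for w in DEFAULT_EXCLUSION_WINDOWS
    )
    chimera_rate: float = 0.1
    topn_ms2: int = 3
    topn_ms3: int = 5
    topn_ms4: int = 2
    topn_ms5: int = 2
    energies_ms2: tuple[float, ...] = (20.0, 60.0, 45.0)  # 45 eV stands for the assisted energy
    energies_msn: tuple[float, ...] = (20.0, 40.0, 60.0)
    energies_ms5: tuple[float, ...] = (40.0, 60.0)
    assisted_energy: float = 45.0
    repeat_triggers: int = 3  # precursor selected three times under dynamic exclusion
    isolation_widths: tuple[float, float, float, float] = (1.2, 2.0, 2.2, 3.0)
    min_intensity_ms2: dict[str, float] = field(
        default_factory=lambda: {"positive": 6e5, "negative": 2e5}
    )
    min_intensity_msn: dict[str, float] = field(
        default_factory=lambda: {"positive": 2e4, "negative": 1e4}
    )
    ms1_range: tuple[float, float] = (115.0, 2000.0)
    ms3_min_mz: float = 90.0
    ms5_min_mz: float = 150.0
    fragment_min_mz: float = 50.0
    mz_jitter: float = 0.0005  # Th, per-scan mass-accuracy wobble
    max_cycles: int = 60


@dataclass
class _Ion:
    compound: CompoundRecord
    adduct: AdductDefinition
    mz: float
    intensity: float
    selections: int = 0
    chimera_mz: float | None = None
    chimera_intensity: float = 0.0


def _pick_ions(
    config: SimulationConfig,
    compounds: Sequence[CompoundRecord],
    polarity: str,
    rng: np.random.Generator,
) -> list[_Ion]:
    adducts = {a.name: a for a in DEFAULT_ADDUCTS if a.polarity == polarity}
    primary = "[M+H]+" if polarity == "positive" else "[M-H]-"
    ions: list[_Ion] = []
    for comp in compounds:
        chosen: list[AdductDefinition] = []
        for name, adduct in adducts.items():
            prob = config.adduct_probabilities.get(name, 0.0)
            if rng.random() < prob:
                chosen.append(adduct)
        if not chosen:
            chosen.append(adducts[primary])
        for adduct in chosen:
            mz = expected_ion_mz(comp.monoisotopic_mass, adduct)
            if not (config.ms1_range[0] <= mz <= config.ms1_range[1]):
                continue
            intensity = float(np.exp(rng.normal(15.0, 0.8)))  # median ~3e6 a.u.
            ion = _Ion(compound=comp, adduct=adduct, mz=mz, intensity=intensity)
            if rng.random() < config.chimera_rate:
                half = config.isolation_widths[0] / 2.0
                offset = rng.uniform(0.08, half * 0.9) * rng.choice([-1.0, 1.0])
                ion.chimera_mz = mz + offset
                ion.chimera_intensity = intensity * rng.uniform(0.2, 0.8)
            ions.append(ion)
    return ions


def _make_fragments(
    config: SimulationConfig,
    precursor_mz: float,
    min_mz: float,
    gate: float,
    rng: np.random.Generator,
) -> list[tuple[float, float]]:
    """Fixed fragment template for one node: random losses below the
    precursor, never under the instrument's lower mass cutoff."""
    lo = max(config.fragment_min_mz, min_mz)
    hi = precursor_mz - 2.0
    if hi <= lo:
        return []
    n = rng.integers(config.fragments_per_level[0], config.fragments_per_level[1] + 1)
    frags = []
    for _ in range(int(n)):
        mz = float(rng.uniform(lo, hi))
        inten = float(gate * np.exp(rng.uniform(1.0, 4.5)))  # comfortably above gate
        frags.append((mz, inten))
    return sorted(frags)


def _noise_peaks(config: SimulationConfig, lo: float, hi: float, rng: np.random.Generator):
    n = int(rng.integers(config.noise_peaks_per_scan[0], config.noise_peaks_per_scan[1] + 1))
    return [
        (
            float(rng.uniform(lo, hi)),
            float(np.exp(rng.normal(config.noise_intensity_logmean, config.noise_intensity_logsigma))),
        )
        for _ in range(n)
    ]


def _jitter(mz: float, config: SimulationConfig, rng: np.random.Generator) -> float:
    return mz + float(rng.normal(0.0, config.mz_jitter))


def simulate_well(
    config: SimulationConfig,
    compounds: Sequence[CompoundRecord],
    polarity: str,
    rng: np.random.Generator | None = None,
) -> tuple[list[ScanRecord], list[dict]]:
    """Simulate one injection of a pooled well; returns (scans, ground truth).

    Ground truth lists one record per (compound, adduct) precursor that
    was actually selected for MS^2 fragmentation.
    """
    if not compounds:
        raise ValueError("no compounds in well")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    ions = _pick_ions(config, compounds, polarity, rng)
    gate_ms2 = config.min_intensity_ms2[polarity]
    gate_msn = config.min_intensity_msn[polarity]
    iso_ms2, iso_ms3, iso_ms4, iso_ms5 = config.isolation_widths

    # per-ion fragment templates, generated lazily per tree node
    ms2_templates: dict[int, list[tuple[float, float]]] = {}

    scans: list[ScanRecord] = []
    truth: list[dict] = []
    scan_number = 0
    rt = 0.0

    def emit(ms_level: int, peaks, chain: list[PrecursorStep]) -> ScanRecord:
        nonlocal scan_number, rt
        scan_number += 1
        rt += 0.004
        peaks = sorted((mz, i) for mz, i in peaks if i > 0)
        scan = ScanRecord(
            scan_number=scan_number,
            ms_level=ms_level,
            polarity=polarity,
            retention_time=round(rt, 4),
            peaks=peaks,
            precursor_chain=chain,
        )
        scans.append(scan)
        return scan

    def ms1_peaks() -> list[tuple[float, float]]:
        peaks = []
        for ion in ions:
            jmz = _jitter(ion.mz, config, rng)
            inten = ion.intensity * rng.uniform(0.85, 1.15)
            peaks.append((jmz, inten))
            peaks.append((jmz + ISOTOPE_SPACING, inten * rng.uniform(0.05, 0.30)))
            peaks.append((jmz + 2 * ISOTOPE_SPACING, inten * rng.uniform(0.0, 0.10)))
            if ion.chimera_mz is not None:
                peaks.append((_jitter(ion.chimera_mz, config, rng), ion.chimera_intensity))
        for center, width, inten in config.background_ions:
            peaks.append((center + rng.uniform(-width / 4, width / 4), inten * rng.uniform(0.7, 1.3)))
        peaks.extend(_noise_peaks(config, *config.ms1_range, rng))
        return peaks

    def fragment_scan_peaks(template, precursor_mz, residual_frac, lo, chimera=None):
        peaks = [(_jitter(mz, config, rng), i * rng.uniform(0.8, 1.2)) for mz, i in template]
        peaks.append((_jitter(precursor_mz, config, rng), max(i for _, i in template or [(0, gate_msn)]) * residual_frac))
        if chimera is not None:
            cmz, cint = chimera
            for _ in range(3):
                peaks.append((float(rng.uniform(lo, cmz - 1.0)), cint * rng.uniform(0.1, 0.4)))
        peaks.extend(_noise_peaks(config, lo, precursor_mz, rng))
        return peaks

    def acquire_deep_tree(ion: _Ion, ms2_template) -> None:
        """MS^3–MS^5 stages grown from the assisted-energy MS^2 scan."""
        ms3_parents = [p for p in ms2_template if p[0] >= config.ms3_min_mz and p[1] >= gate_msn]
        ms3_parents = sorted(ms3_parents, key=lambda p: -p[1])[: config.topn_ms3]
        for p3_mz, _ in ms3_parents:
            t3 = _make_fragments(config, p3_mz, config.fragment_min_mz, gate_msn, rng)
            if not t3:
                continue
            chain3_base = [
                PrecursorStep(ion.mz, iso_ms2, config.assisted_energy),
            ]
            for e3 in config.energies_msn:
                chain = chain3_base + [PrecursorStep(p3_mz, iso_ms3, e3)]
                emit(3, fragment_scan_peaks(t3, p3_mz, 0.3, config.fragment_min_mz), chain)
            ms4_parents = sorted(
                (p for p in t3 if p[1] >= gate_msn), key=lambda p: -p[1]
            )[: config.topn_ms4]
            for p4_mz, _ in ms4_parents:
                t4 = _make_fragments(config, p4_mz, config.fragment_min_mz, gate_msn, rng)
                if not t4:
                    continue
                for e4 in config.energies_msn:
                    chain = chain3_base + [
                        PrecursorStep(p3_mz, iso_ms3, 40.0),
                        PrecursorStep(p4_mz, iso_ms4, e4),
                    ]
                    emit(4, fragment_scan_peaks(t4, p4_mz, 0.3, config.fragment_min_mz), chain)
                ms5_parents = sorted(
                    (p for p in t4 if p[1] >= gate_msn and p[0] >= config.ms5_min_mz),
                    key=lambda p: -p[1],
                )[: config.topn_ms5]
                for p5_mz, _ in ms5_parents:
                    t5 = _make_fragments(config, p5_mz, config.fragment_min_mz, gate_msn, rng)
                    if not t5:
                        continue
                    for e5 in config.energies_ms5:
                        chain = chain3_base + [
                            PrecursorStep(p3_mz, iso_ms3, 40.0),
                            PrecursorStep(p4_mz, iso_ms4, 40.0),
                            PrecursorStep(p5_mz, iso_ms5, e5),
                        ]
                        emit(5, fragment_scan_peaks(t5, p5_mz, 0.3, config.fragment_min_mz), chain)

    for _ in range(config.max_cycles):
        eligible = [
            ion
            for ion in ions
            if ion.intensity >= gate_ms2 and ion.selections < config.repeat_triggers
        ]
        if not eligible:
            break
        emit(1, ms1_peaks(), [])
        selected = sorted(eligible, key=lambda x: -x.intensity)[: config.topn_ms2]
        for ion in selected:
            idx = ions.index(ion)
            first_selection = ion.selections == 0
            ion.selections += 1
            if idx not in ms2_templates:
                ms2_templates[idx] = _make_fragments(
                    config, ion.mz, config.fragment_min_mz, gate_msn, rng
                )
            template = ms2_templates[idx]
            if not template:
                continue
            chimera = (
                (ion.chimera_mz, ion.chimera_intensity) if ion.chimera_mz is not None else None
            )
            for energy in config.energies_ms2:
                emit(
                    2,
                    fragment_scan_peaks(template, ion.mz, 0.5, config.fragment_min_mz, chimera),
                    [PrecursorStep(ion.mz, iso_ms2, energy)],
                )
            if first_selection:
                truth.append(
                    {
                        "inchikey": ion.compound.inchikey,
                        "compound": ion.compound.source_name,
                        "adduct": ion.adduct.name,
                        "expected_mz": ion.mz,
                        "polarity": polarity,
                        "unique_sample_id": ion.compound.unique_sample_id,
                    }
                )
                acquire_deep_tree(ion, template)
        # closing MS1 so the last fragmentation block has a following survey scan
    emit(1, ms1_peaks(), [])
    return scans, truth


def simulate_plate(
    config: SimulationConfig,
    metadata: Sequence[CompoundRecord],
    sequence: Sequence[SequenceRow],
    outdir: str | Path,
    write_mzml_files: bool = False,
) -> dict:
    """Simulate one scan file per sequence row.

    File names come from the sequence rows (and therefore contain the
    unique sample ID). Writes scanjson always, mzML optionally, plus a
    ground-truth JSON; returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    by_well: dict[str, list[CompoundRecord]] = {}
    for rec in metadata:
        by_well.setdefault(rec.unique_sample_id, []).append(rec)
    manifest = {"files": [], "ground_truth": []}
    for row in sequence:
        compounds = by_well.get(row.unique_sample_id)
        if not compounds:
            raise ValueError(f"sequence row references unknown well {row.unique_sample_id}")
        rng = np.random.default_rng(
            np.random.SeedSequence([config.seed & 0x7FFFFFFF, row.injection_index])
        )
        scans, truth = simulate_well(config, compounds, row.polarity, rng)
        path = outdir / f"{row.filename}.scanjson"
        write_scanjson(scans, path)
        if write_mzml_files:
            write_mzml(scans, outdir / f"{row.filename}.mzML")
        manifest["files"].append(str(path))
        for t in truth:
            t["filename"] = row.filename
        manifest["ground_truth"].extend(truth)
    (outdir / "ground_truth.json").write_text(json.dumps(manifest, indent=1))
    return manifest
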