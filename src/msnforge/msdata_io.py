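"""Scan and spectral-library I/O.

Reads centroided MS^n scan data from mzML (via pyteomics) and from
"scanjson", a small versioned JSON dialect used as the package's
first-class fixture format, and reads/writes spectral libraries as MGF
(GNPS-style keys), MSP (NIST-style keys) and JSON.

mzML writers differ in how they encode precursor chains for MS^n (n>2):
some store the full selection chain as multiple <precursor> elements,
others only the immediate precursor. The reader accepts both — when only
the immediate precursor is present, the chain is reconstructed from the
most recent ancestor scan at each lower MS level, and the choice is
logged once per file.
"""

from __future__ import annotations

import base64
import json
import logging
import struct
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .chem_metadata import CompoundRecord

logger = logging.getLogger(__name__)

SCANJSON_FORMAT = "msnforge-scanjson"
SCANJSON_VERSION = 1

SPEC_TYPES = ("SINGLE_BEST_SCAN", "SAME_ENERGY", "ALL_ENERGIES", "ALL_MSN_TO_PSEUDO_MS2")


class ScanFileError(ValueError):
    """Raised on malformed scan or library files."""


@dataclass
class PrecursorStep:
    """One stage of an MS^n selection chain."""

    precursor_mz: float  # Th
    isolation_width: float  # Th, full width
    collision_energy: float  # eV

    def __post_init__(self):
        if self.precursor_mz <= 0:
            raise ValueError(f"precursor_mz must be > 0, got {self.precursor_mz}")
        if self.isolation_width <= 0:
            raise ValueError(f"isolation_width must be > 0, got {self.isolation_width}")


@dataclass
class ScanRecord:
    """One centroided scan with its full precursor chain.

    ``precursor_chain`` is ordered from the MS^2 selection down to the
    deepest stage and has length ``ms_level - 1``.
    """

    scan_number: int
    ms_level: int
    polarity: str  # "positive" | "negative"
    retention_time: float  # minutes
    peaks: list[tuple[float, float]]
    precursor_chain: list[PrecursorStep] = field(default_factory=list)
    #: noise floor estimated from the raw scan on first filtering; filters
    #: anchor their thresholds here so they stay idempotent
    noise_floor: float | None = None

    def __post_init__(self):
        if len(self.precursor_chain) != self.ms_level - 1:
            raise ValueError(
                f"scan {self.scan_number}: chain length {len(self.precursor_chain)} "
                f"!= ms_level-1 ({self.ms_level - 1})"
            )
        mzs = [p[0] for p in self.peaks]
        if any(b <= a for a, b in zip(mzs, mzs[1:])):
            self.peaks = sorted(self.peaks, key=lambda p: p[0])

    @property
    def tic(self) -> float:
        return float(sum(i for _, i in self.peaks))

    @property
    def collision_energy(self) -> float | None:
        """Collision energy of this scan's own fragmentation stage."""
        return self.precursor_chain[-1].collision_energy if self.precursor_chain else None

    @property
    def precursor_mz(self) -> float | None:
        return self.precursor_chain[-1].precursor_mz if self.precursor_chain else None


@dataclass
class LibraryEntry:
    """An exportable annotated spectrum with quality scores and provenance."""

    compound: CompoundRecord
    adduct_name: str
    precursor_mz: float
    ms_level: int
    spec_type: str
    collision_energies: list[float]
    peaks: list[tuple[float, float]]
    precursor_purity_pct: float | None = None
    chimeric_flag: bool = False
    provenance: dict[str, list[int]] = field(default_factory=dict)

    def __post_init__(self):
        if self.spec_type not in SPEC_TYPES:
            raise ValueError(f"unknown spec_type {self.spec_type!r}")
        if self.spec_type == "SAME_ENERGY" and len(set(self.collision_energies)) != 1:
            raise ValueError("SAME_ENERGY entry must list exactly one distinct energy")
        if not self.peaks:
            raise ValueError("entry has no peaks")
        self.peaks = sorted(self.peaks, key=lambda p: p[0])


# ---------------------------------------------------------------------------
# scanjson
# ---------------------------------------------------------------------------

def _scan_to_dict(s: ScanRecord) -> dict:
    return {
        "scan_number": s.scan_number,
        "ms_level": s.ms_level,
        "polarity": s.polarity,
        "retention_time": s.retention_time,
        "peaks": [[mz, inten] for mz, inten in s.peaks],
        "precursor_chain": [
            {
                "precursor_mz": p.precursor_mz,
                "isolation_width": p.isolation_width,
                "collision_energy": p.collision_energy,
            }
            for p in s.precursor_chain
        ],
    }


def _scan_from_dict(d: dict) -> ScanRecord:
    return ScanRecord(
        scan_number=int(d["scan_number"]),
        ms_level=int(d["ms_level"]),
        polarity=d["polarity"],
        retention_time=float(d["retention_time"]),
        peaks=[(float(mz), float(i)) for mz, i in d["peaks"]],
        precursor_chain=[
            PrecursorStep(
                precursor_mz=float(p["precursor_mz"]),
                isolation_width=float(p["isolation_width"]),
                collision_energy=float(p["collision_energy"]),
            )
            for p in d["precursor_chain"]
        ],
    )


def write_scanjson(scans: Sequence[ScanRecord], path: str | Path) -> Path:
    path = Path(path)
    doc = {
        "format": SCANJSON_FORMAT,
        "version": SCANJSON_VERSION,
        "scans": [_scan_to_dict(s) for s in scans],
    }
    path.write_text(json.dumps(doc, separators=(",", ":")))
    return path


def read_scanjson(path: str | Path) -> list[ScanRecord]:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ScanFileError(f"{path}: malformed scanjson: {exc}") from exc
    if not isinstance(doc, dict) or doc.get("format") != SCANJSON_FORMAT:
        raise ScanFileError(f"{path}: not a {SCANJSON_FORMAT} file")
    try:
        return [_scan_from_dict(d) for d in doc["scans"]]
    except (KeyError, TypeError, ValueError) as exc:
        raise ScanFileError(f"{path}: malformed scan record: {exc}") from exc


# ---------------------------------------------------------------------------
# mzML
# ---------------------------------------------------------------------------

def _encode_array(values: Sequence[float]) -> str:
    raw = struct.pack(f"<{len(values)}d", *values)
    return base64.b64encode(raw).decode()


def write_mzml(scans: Sequence[ScanRecord], path: str | Path) -> Path:
    """Write a minimal centroided mzML file.

    Emits the full precursor chain of each MS^n scan as consecutive
    <precursor> elements (deepest stage last). 64-bit uncompressed arrays.
    """
    path = Path(path)
    parts: list[str] = []
    parts.append('<?xml version="1.0" encoding="utf-8"?>')
    parts.append(
        '<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">'
        "<cvList count=\"1\">"
        '<cv id="MS" fullName="PSI-MS" URI="https://raw.githubusercontent.com/'
        'HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/></cvList>'
        "<run id=\"run\">"
        f'<spectrumList count="{len(scans)}">'
    )
    for i, s in enumerate(scans):
        mzs = [p[0] for p in s.peaks]
        ints = [p[1] for p in s.peaks]
        pol_acc, pol_name = (
            ("MS:1000130", "positive scan") if s.polarity == "positive" else ("MS:1000129", "negative scan")
        )
        parts.append(
            f'<spectrum index="{i}" id="scan={s.scan_number}" defaultArrayLength="{len(mzs)}">'
            f'<cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="{s.ms_level}"/>'
            f'<cvParam cvRef="MS" accession="{pol_acc}" name="{pol_name}" value=""/>'
            '<cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>'
            "<scanList count=\"1\"><scan>"
            f'<cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{s.retention_time!r}" '
            'unitAccession="UO:0000031" unitName="minute"/>'
            "</scan></scanList>"
        )
        if s.precursor_chain:
            parts.append(f'<precursorList count="{len(s.precursor_chain)}">')
            for step in s.precursor_chain:
                half = step.isolation_width / 2.0
                parts.append(
                    "<precursor><isolationWindow>"
                    f'<cvParam cvRef="MS" accession="MS:1000827" name="isolation window target m/z" value="{step.precursor_mz!r}"/>'
                    f'<cvParam cvRef="MS" accession="MS:1000828" name="isolation window lower offset" value="{half!r}"/>'
                    f'<cvParam cvRef="MS" accession="MS:1000829" name="isolation window upper offset" value="{half!r}"/>'
                    "</isolationWindow><selectedIonList count=\"1\"><selectedIon>"
                    f'<cvParam cvRef="MS" accession="MS:1000744" name="selected ion m/z" value="{step.precursor_mz!r}"/>'
                    "</selectedIon></selectedIonList><activation>"
                    '<cvParam cvRef="MS" accession="MS:1000422" name="beam-type collision-induced dissociation" value=""/>'
                    f'<cvParam cvRef="MS" accession="MS:1000045" name="collision energy" value="{step.collision_energy!r}" '
                    'unitAccession="UO:0000266" unitName="electronvolt"/>'
                    "</activation></precursor>"
                )
            parts.append("</precursorList>")
        parts.append('<binaryDataArrayList count="2">')
        for arr, acc, name in (
            (mzs, "MS:1000514", "m/z array"),
            (ints, "MS:1000515", "intensity array"),
        ):
            b64 = _encode_array(arr)
            parts.append(
                f'<binaryDataArray encodedLength="{len(b64)}">'
                '<cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>'
                '<cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>'
                f'<cvParam cvRef="MS" accession="{acc}" name="{name}" value=""/>'
                f"<binary>{b64}</binary></binaryDataArray>"
            )
        parts.append("</binaryDataArrayList></spectrum>")
    parts.append("</spectrumList></run></mzML>")
    path.write_text("".join(parts))
    return path


def _decode_binary_array(node) -> np.ndarray:
    """Decode one <binaryDataArray>: 32/64-bit floats, zlib or none."""
    fmt = "d"
    decompress = False
    for cv in node.iter("{*}cvParam"):
        acc = cv.get("accession", "")
        if acc == "MS:1000521":
            fmt = "f"
        elif acc == "MS:1000523":
            fmt = "d"
        elif acc == "MS:1000574":
            decompress = True
    binary = node.find("{*}binary")
    raw = base64.b64decode((binary.text or "").strip()) if binary is not None else b""
    if decompress:
        raw = zlib.decompress(raw)
    return np.frombuffer(raw, dtype=np.dtype("<" + fmt)).astype(float)


def _cv_accessions(node) -> dict[str, str]:
    return {cv.get("accession", ""): cv.get("value", "") for cv in node.iter("{*}cvParam")}


def _parse_mzml_spectrum(elem) -> tuple[int, int, str, float, list, list[PrecursorStep]]:
    params = {cv.get("accession", ""): cv.get("value", "") for cv in elem.findall("{*}cvParam")}
    ms_level = int(params.get("MS:1000511", 1))
    polarity = "negative" if "MS:1000129" in params else "positive"
    rt = 0.0
    for scan in elem.iter("{*}scan"):
        for cv in scan.findall("{*}cvParam"):
            if cv.get("accession") == "MS:1000016":
                rt = float(cv.get("value"))
                if cv.get("unitName", "minute").lower().startswith("second"):
                    rt /= 60.0
        break
    mz = inten = None
    for arr in elem.iter("{*}binaryDataArray"):
        acc = _cv_accessions(arr)
        if "MS:1000514" in acc:
            mz = _decode_binary_array(arr)
        elif "MS:1000515" in acc:
            inten = _decode_binary_array(arr)
    if mz is None or inten is None or len(mz) != len(inten):
        raise ValueError("missing or inconsistent m/z / intensity arrays")
    order = np.argsort(mz, kind="stable")
    peaks = [(float(a), float(b)) for a, b in zip(mz[order], inten[order])]

    steps: list[PrecursorStep] = []
    for prec in elem.iter("{*}precursor"):
        iso = prec.find("{*}isolationWindow")
        iso_acc = _cv_accessions(iso) if iso is not None else {}
        sel_mz = None
        sel = prec.find("{*}selectedIonList/{*}selectedIon")
        if sel is not None:
            sel_mz = _cv_accessions(sel).get("MS:1000744")
        if sel_mz is None:
            sel_mz = iso_acc.get("MS:1000827")
        if sel_mz is None:
            continue
        lo = float(iso_acc.get("MS:1000828", 0.6))
        hi = float(iso_acc.get("MS:1000829", 0.6))
        act = prec.find("{*}activation")
        ce = float(_cv_accessions(act).get("MS:1000045", 0.0)) if act is not None else 0.0
        steps.append(PrecursorStep(precursor_mz=float(sel_mz), isolation_width=lo + hi, collision_energy=ce))

    sid = elem.get("id", "")
    scan_number = 0
    for tok in sid.split():
        if tok.startswith("scan="):
            scan_number = int(tok.split("=", 1)[1])
    return scan_number, ms_level, polarity, rt, peaks, steps


def _read_mzml(path: Path) -> list[ScanRecord]:
    from lxml import etree

    scans: list[ScanRecord] = []
    last_at_level: dict[int, ScanRecord] = {}
    reconstructed = False
    dropped = 0
    try:
        context = etree.iterparse(str(path), events=("end",), tag="{*}spectrum")
        for idx, (_, elem) in enumerate(context):
            try:
                scan_number, ms_level, polarity, rt, peaks, steps = _parse_mzml_spectrum(elem)
                if scan_number == 0:
                    scan_number = idx + 1
            except (KeyError, ValueError, TypeError, AttributeError) as exc:
                raise ScanFileError(f"{path}: malformed spectrum at index {idx}: {exc}") from exc
            finally:
                elem.clear()
            if ms_level >= 2 and not steps:
                dropped += 1
                logger.warning("%s: MS%d scan %s lacks precursor info; excluded", path, ms_level, scan_number)
                continue
            if ms_level > 2 and len(steps) == 1:
                parent = last_at_level.get(ms_level - 1)
                if parent is None or len(parent.precursor_chain) != ms_level - 2:
                    dropped += 1
                    logger.warning(
                        "%s: MS%d scan %s has only its immediate precursor and no "
                        "ancestor scan to reconstruct the chain; excluded", path, ms_level, scan_number
                    )
                    continue
                steps = list(parent.precursor_chain) + steps
                if not reconstructed:
                    logger.info("%s: reconstructing precursor chains from ancestor scans", path)
                    reconstructed = True
            rec = ScanRecord(
                scan_number=scan_number,
                ms_level=ms_level,
                polarity=polarity,
                retention_time=rt,
                peaks=peaks,
                precursor_chain=steps,
            )
            last_at_level[ms_level] = rec
            scans.append(rec)
    except etree.XMLSyntaxError as exc:
        raise ScanFileError(f"{path}: malformed mzML near spectrum index {len(scans)}: {exc}") from exc
    if dropped:
        logger.warning("%s: excluded %d MS^n scans lacking usable precursor info", path, dropped)
    return scans


def read_scans(path: str | Path, format: str | None = None) -> list[ScanRecord]:
    """Read all scans from an mzML or scanjson file, in acquisition order."""
    path = Path(path)
    if format is None:
        format = "mzml" if path.suffix.lower() == ".mzml" else "scanjson"
    if format == "mzml":
        scans = _read_mzml(path)
    elif format == "scanjson":
        scans = read_scanjson(path)
    else:
        raise ValueError(f"unknown scan format {format!r}")
    if not scans:
        logger.warning("%s: file contains no scans", path)
    polarities = {s.polarity for s in scans}
    if len(polarities) > 1:
        raise ScanFileError(f"{path}: file mixes polarities {sorted(polarities)}")
    return scans


# ---------------------------------------------------------------------------
# spectral library serialization
# ---------------------------------------------------------------------------

def _provenance_to_str(prov: dict[str, list[int]]) -> str:
    return ";".join(f"{fn}:{','.join(str(n) for n in nums)}" for fn, nums in sorted(prov.items()))


def _provenance_from_str(s: str) -> dict[str, list[int]]:
    out: dict[str, list[int]] = {}
    for part in s.split(";"):
        if not part:
            continue
        fn, _, nums = part.rpartition(":")
        out[fn] = [int(x) for x in nums.split(",") if x]
    return out


def _entry_meta(e: LibraryEntry) -> dict[str, str]:
    c = e.compound
    meta = {
        "NAME": c.source_name,
        "FORMULA": c.formula,
        "SMILES": c.cleaned_smiles,
        "INCHI": c.inchi,
        "INCHIKEY": c.inchikey,
        "EXACTMASS": repr(c.monoisotopic_mass),
        "SAMPLE_ID": c.unique_sample_id,
        "ADDUCT": e.adduct_name,
        "SPECTYPE": e.spec_type,
        "MSLEVEL": str(e.ms_level),
        "COLLISION_ENERGY": ",".join(repr(x) for x in e.collision_energies),
        "CHIMERIC": "1" if e.chimeric_flag else "0",
        "PROVENANCE": _provenance_to_str(e.provenance),
    }
    if e.precursor_purity_pct is not None:
        meta["PRECURSOR_PURITY"] = repr(e.precursor_purity_pct)
    return meta


#: accepted key variants (lowercased) for foreign MGF/MSP files
KEY_ALIASES = {
    "name": "NAME",
    "compound_name": "NAME",
    "title": "NAME",
    "formula": "FORMULA",
    "molecular_formula": "FORMULA",
    "smiles": "SMILES",
    "inchi": "INCHI",
    "inchikey": "INCHIKEY",
    "inchiaux": "INCHIKEY",
    "exactmass": "EXACTMASS",
    "exact_mass": "EXACTMASS",
    "monoisotopic_mass": "EXACTMASS",
    "sample_id": "SAMPLE_ID",
    "adduct": "ADDUCT",
    "precursor_type": "ADDUCT",
    "precursortype": "ADDUCT",
    "spectype": "SPECTYPE",
    "spec_type": "SPECTYPE",
    "mslevel": "MSLEVEL",
    "ms_level": "MSLEVEL",
    "collision_energy": "COLLISION_ENERGY",
    "collisionenergy": "COLLISION_ENERGY",
    "fragmentation_energy": "COLLISION_ENERGY",
    "chimeric": "CHIMERIC",
    "precursor_purity": "PRECURSOR_PURITY",
    "provenance": "PROVENANCE",
    "pepmass": "PEPMASS",
    "precursormz": "PEPMASS",
    "precursor_mz": "PEPMASS",
    "precursormz:": "PEPMASS",
}


def _entry_from_meta(meta: dict[str, str], precursor_mz: float, peaks: list[tuple[float, float]]) -> LibraryEntry:
    energies = [float(x) for x in meta.get("COLLISION_ENERGY", "").split(",") if x]
    compound = CompoundRecord(
        source_name=meta.get("NAME", ""),
        raw_structure=meta.get("SMILES", ""),
        cleaned_smiles=meta.get("SMILES", ""),
        inchi=meta.get("INCHI", ""),
        inchikey=meta.get("INCHIKEY", ""),
        formula=meta.get("FORMULA", ""),
        monoisotopic_mass=float(meta.get("EXACTMASS", 0) or 0),
        unique_sample_id=meta.get("SAMPLE_ID", ""),
    )
    purity = meta.get("PRECURSOR_PURITY")
    return LibraryEntry(
        compound=compound,
        adduct_name=meta.get("ADDUCT", ""),
        precursor_mz=precursor_mz,
        ms_level=int(meta.get("MSLEVEL", 2)),
        spec_type=meta.get("SPECTYPE", "SINGLE_BEST_SCAN"),
        collision_energies=energies,
        peaks=peaks,
        precursor_purity_pct=float(purity) if purity is not None else None,
        chimeric_flag=meta.get("CHIMERIC", "0") in ("1", "true", "True"),
        provenance=_provenance_from_str(meta.get("PROVENANCE", "")),
    )


# --- MGF ---

def _write_mgf(entries: Sequence[LibraryEntry], path: Path) -> None:
    with path.open("w") as fh:
        for e in entries:
            fh.write("BEGIN IONS\n")
            fh.write(f"PEPMASS={e.precursor_mz!r}\n")
            for k, v in _entry_meta(e).items():
                fh.write(f"{k}={v}\n")
            for mz, inten in e.peaks:
                fh.write(f"{mz!r} {inten!r}\n")
            fh.write("END IONS\n\n")


def _read_mgf(path: Path) -> tuple[list[LibraryEntry], int]:
    from pyteomics import mgf as _mgf

    entries: list[LibraryEntry] = []
    skipped = 0
    with _mgf.MGF(str(path), convert_arrays=1) as reader:
        for idx, rec in enumerate(reader):
            params = rec.get("params", {})
            meta: dict[str, str] = {}
            pepmass = None
            for key, val in params.items():
                canon = KEY_ALIASES.get(str(key).lower())
                if canon == "PEPMASS":
                    pepmass = val[0] if isinstance(val, (tuple, list)) else val
                elif canon:
                    meta[canon] = str(val)
            if pepmass is None:
                raise ScanFileError(f"{path}: MGF record {idx} lacks a precursor m/z")
            mzs = rec.get("m/z array")
            ints = rec.get("intensity array")
            peaks = [(float(a), float(b)) for a, b in zip(mzs, ints)] if mzs is not None else []
            if not peaks:
                skipped += 1
                continue
            entries.append(_entry_from_meta(meta, float(pepmass), peaks))
    return entries, skipped


# --- MSP ---

def _write_msp(entries: Sequence[LibraryEntry], path: Path) -> None:
    with path.open("w") as fh:
        for e in entries:
            meta = _entry_meta(e)
            fh.write(f"Name: {meta.pop('NAME')}\n")
            fh.write(f"PrecursorMZ: {e.precursor_mz!r}\n")
            for k, v in meta.items():
                fh.write(f"{k.capitalize() if k.isupper() else k}: {v}\n")
            fh.write(f"Num Peaks: {len(e.peaks)}\n")
            for mz, inten in e.peaks:
                fh.write(f"{mz!r} {inten!r}\n")
            fh.write("\n")


def _read_msp(path: Path) -> tuple[list[LibraryEntry], int]:
    entries: list[LibraryEntry] = []
    skipped = 0
    meta: dict[str, str] = {}
    peaks: list[tuple[float, float]] = []
    npeaks: int | None = None
    pepmass: float | None = None

    def flush(line_no: int):
        nonlocal meta, peaks, npeaks, pepmass, skipped
        if not meta and not peaks:
            return
        if npeaks is not None and len(peaks) != npeaks:
            raise ScanFileError(
                f"{path}: truncated record {meta.get('NAME', '?')!r} near line {line_no}: "
                f"expected {npeaks} peaks, found {len(peaks)}"
            )
        if not peaks:
            skipped += 1
        else:
            if pepmass is None:
                raise ScanFileError(f"{path}: record {meta.get('NAME','?')!r} lacks PrecursorMZ")
            entries.append(_entry_from_meta(meta, pepmass, peaks))
        meta, peaks, npeaks, pepmass = {}, [], None, None

    with path.open() as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                flush(line_no)
                continue
            if ":" in line and not line[0].isdigit():
                key, _, val = line.partition(":")
                key_l = key.strip().lower().replace(" ", "_")
                val = val.strip()
                if key_l == "num_peaks":
                    npeaks = int(val)
                elif key_l in ("precursormz", "precursor_mz", "pepmass"):
                    pepmass = float(val)
                else:
                    canon = KEY_ALIASES.get(key_l)
                    if canon:
                        meta[canon] = val
                continue
            fields = line.replace("\t", " ").split()
            if len(fields) >= 2:
                peaks.append((float(fields[0]), float(fields[1])))
    flush(-1)
    return entries, skipped


# --- JSON ---

def _write_json(entries: Sequence[LibraryEntry], path: Path) -> None:
    out = []
    for e in entries:
        d = {
            "compound": {
                "name": e.compound.source_name,
                "formula": e.compound.formula,
                "smiles": e.compound.cleaned_smiles,
                "inchi": e.compound.inchi,
                "inchikey": e.compound.inchikey,
                "monoisotopic_mass": e.compound.monoisotopic_mass,
                "sample_id": e.compound.unique_sample_id,
            },
            "adduct": e.adduct_name,
            "precursor_mz": e.precursor_mz,
            "ms_level": e.ms_level,
            "spec_type": e.spec_type,
            "collision_energies": e.collision_energies,
            "peaks": [[mz, i] for mz, i in e.peaks],
            "precursor_purity_pct": e.precursor_purity_pct,
            "chimeric": e.chimeric_flag,
            "provenance": e.provenance,
        }
        out.append(d)
    path.write_text(json.dumps(out))


_JSON_SYNONYMS = {
    "adduct": ("adduct", "adduct_name", "precursor_type"),
    "precursor_mz": ("precursor_mz", "precursormz", "pepmass"),
    "spec_type": ("spec_type", "spectype"),
    "ms_level": ("ms_level", "mslevel"),
    "collision_energies": ("collision_energies", "collision_energy", "energies"),
    "peaks": ("peaks", "spectrum"),
}


def _json_get(d: dict, logical: str, default=None):
    for k in _JSON_SYNONYMS.get(logical, (logical,)):
        if k in d:
            return d[k]
    return default


def _read_json(path: Path) -> tuple[list[LibraryEntry], int]:
    data = json.loads(path.read_text())
    entries: list[LibraryEntry] = []
    skipped = 0
    for d in data:
        peaks = [(float(a), float(b)) for a, b in _json_get(d, "peaks", [])]
        if not peaks:
            skipped += 1
            continue
        c = d.get("compound", {})
        energies = _json_get(d, "collision_energies", [])
        if isinstance(energies, (int, float)):
            energies = [energies]
        compound = CompoundRecord(
            source_name=c.get("name", ""),
            raw_structure=c.get("smiles", ""),
            cleaned_smiles=c.get("smiles", ""),
            inchi=c.get("inchi", ""),
            inchikey=c.get("inchikey", ""),
            formula=c.get("formula", ""),
            monoisotopic_mass=float(c.get("monoisotopic_mass", 0) or 0),
            unique_sample_id=c.get("sample_id", ""),
        )
        entries.append(
            LibraryEntry(
                compound=compound,
                adduct_name=_json_get(d, "adduct", ""),
                precursor_mz=float(_json_get(d, "precursor_mz")),
                ms_level=int(_json_get(d, "ms_level", 2)),
                spec_type=_json_get(d, "spec_type", "SINGLE_BEST_SCAN"),
                collision_energies=[float(x) for x in energies],
                peaks=peaks,
                precursor_purity_pct=d.get("precursor_purity_pct"),
                chimeric_flag=bool(d.get("chimeric", False)),
                provenance={k: [int(n) for n in v] for k, v in d.get("provenance", {}).items()},
            )
        )
    return entries, skipped


LIBRARY_FORMATS = ("mgf", "msp", "json")


def write_library(entries: Sequence[LibraryEntry], path: str | Path, format: str | None = None) -> Path:
    """Write a spectral library; format inferred from the suffix if omitted."""
    path = Path(path)
    format = format or path.suffix.lstrip(".").lower()
    if format not in LIBRARY_FORMATS:
        raise ValueError(f"unknown library format {format!r}")
    {"mgf": _write_mgf, "msp": _write_msp, "json": _write_json}[format](entries, path)
    return path


def read_library(path: str | Path, format: str | None = None) -> list[LibraryEntry]:
    """Read a spectral library; records without peaks are skipped (counted)."""
    path = Path(path)
    format = format or path.suffix.lstrip(".").lower()
    if format not in LIBRARY_FORMATS:
        raise ValueError(f"unknown library format {format!r}")
    entries, skipped = {"mgf": _read_mgf, "msp": _read_msp, "json": _read_json}[format](path)
    if skipped:
        logger.warning("%s: skipped %d records without peaks", path, skipped)
    return entries
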