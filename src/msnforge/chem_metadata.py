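"""Compound metadata curation.

Curates vendor compound tables (SMILES or InChI structures plus
library/plate/well placement) into the clean records the rest of the
pipeline consumes: salt-stripped standardized structures, descriptors
(InChI, InChIKey, formula, monoisotopic mass, logP), unique sample
identifiers and flow-injection acquisition sequences.

Standardization runs two salt-strip + normalize passes because some vendor
entries encode salts without a fragment dot, which only resolves after a
first normalization round.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from datetime import date as _date
from typing import Iterable, Mapping, Sequence

import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import Crippen, Descriptors, inchi as _inchi
from rdkit.Chem.MolStandardize import rdMolStandardize
from rdkit.Chem.rdMolDescriptors import CalcMolFormula

RDLogger.DisableLog("rdApp.*")

INCHIKEY_RE = re.compile(r"^[A-Z]{14}-[A-Z]{10}-[A-Z]$")

#: reason codes used in rejects reports
REJECT_UNPARSEABLE = "unparseable_structure"
REJECT_EMPTY = "empty_structure"
REJECT_DESCRIPTOR = "descriptor_failure"
REJECT_MISSING_WELL = "missing_plate_or_well"


class StructureError(ValueError):
    """Raised when a structure cannot be parsed or standardized."""


@dataclass
class CompoundRecord:
    """One curated compound with structure descriptors and plate placement."""

    source_name: str
    raw_structure: str
    cleaned_smiles: str = ""
    isomeric_smiles: str | None = None
    inchi: str = ""
    inchikey: str = ""
    formula: str = ""
    monoisotopic_mass: float = 0.0
    logp: float | None = None
    library_code: str = ""
    plate: str = ""
    well: str = ""
    unique_sample_id: str = ""


@dataclass
class SequenceRow:
    """One row of the acquisition sequence (one injection)."""

    acquisition_date: _date
    unique_sample_id: str
    method_name: str
    polarity: str  # "positive" | "negative"
    filename: str
    injection_index: int


# ---------------------------------------------------------------------------
# structure standardization
# ---------------------------------------------------------------------------

def _parse_structure(raw: str) -> Chem.Mol:
    raw = (raw or "").strip()
    if not raw:
        raise StructureError("empty structure string")
    if raw.startswith("InChI="):
        mol = Chem.MolFromInchi(raw, sanitize=True)
    else:
        mol = Chem.MolFromSmiles(raw)
    if mol is None:
        raise StructureError(f"unparseable structure: {raw!r}")
    return mol


def _largest_fragment(mol: Chem.Mol) -> Chem.Mol:
    """Keep the largest fragment; ties broken by monoisotopic mass, then
    lexicographically smallest canonical SMILES, so output is deterministic."""
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) == 1:
        return mol

    def key(f: Chem.Mol):
        return (
            -f.GetNumHeavyAtoms(),
            -Descriptors.ExactMolWt(f),
            Chem.MolToSmiles(f),
        )

    return sorted(frags, key=key)[0]


def _strip_and_normalize(mol: Chem.Mol) -> Chem.Mol:
    mol = _largest_fragment(mol)
    mol = rdMolStandardize.Cleanup(mol)  # normalize drawings, disconnect metals
    mol = _largest_fragment(mol)  # Cleanup may re-split metal salts
    mol = rdMolStandardize.Uncharger().uncharge(mol)
    return mol


def standardize_structure(raw: str) -> str:
    """Return the canonical SMILES of the neutral parent structure.

    Two full salt-strip + normalize passes are applied; the result is a
    single connected component and the function is idempotent.
    """
    mol = _parse_structure(raw)
    mol = _strip_and_normalize(mol)
    mol = _strip_and_normalize(mol)  # second pass catches dot-less salts
    smiles = Chem.MolToSmiles(mol)
    if not smiles or "." in smiles:
        raise StructureError(f"standardization left disconnected fragments: {smiles!r}")
    return smiles


def compute_descriptors(cleaned: str) -> dict:
    """Compute InChI, InChIKey, formula, monoisotopic mass and logP.

    ``monoisotopic_mass`` is the sum of the most-abundant-isotope atomic
    masses of the molecular formula (Da). ``logp`` is the Crippen
    atom-contribution estimate and is metadata only.
    """
    mol = Chem.MolFromSmiles(cleaned)
    if mol is None:
        raise StructureError(f"invalid cleaned structure: {cleaned!r}")
    inchi = _inchi.MolToInchi(mol)
    if not inchi:
        raise StructureError(f"InChI generation failed for {cleaned!r}")
    inchikey = _inchi.InchiToInchiKey(inchi)
    if not inchikey or not INCHIKEY_RE.match(inchikey):
        raise StructureError(f"InChIKey generation failed for {cleaned!r}")
    isomeric = Chem.MolToSmiles(mol, isomericSmiles=True)
    return {
        "inchi": inchi,
        "inchikey": inchikey,
        "formula": CalcMolFormula(mol),
        "monoisotopic_mass": Descriptors.ExactMolWt(mol),
        "logp": Crippen.MolLogP(mol),
        "isomeric_smiles": isomeric if isomeric != Chem.MolToSmiles(mol, isomericSmiles=False) else None,
    }


# ---------------------------------------------------------------------------
# table curation
# ---------------------------------------------------------------------------

DEFAULT_COLUMNS = {
    "name": "name",
    "structure": "structure",
    "library": "library",
    "plate": "plate",
    "well": "well",
}


def curate_table(
    df: pd.DataFrame, columns: Mapping[str, str] | None = None
) -> tuple[list[CompoundRecord], pd.DataFrame]:
    """Curate a metadata table into CompoundRecords plus a rejects table.

    ``columns`` maps the logical names name/structure/library/plate/well to
    the table's column names. Structure strings may be SMILES or InChI
    (auto-detected by the ``InChI=`` prefix). Failing rows are collected
    into the rejects DataFrame with a reason code; the run continues.
    """
    cols = dict(DEFAULT_COLUMNS)
    if columns:
        cols.update(columns)
    records: list[CompoundRecord] = []
    rejects: list[dict] = []
    for idx, row in df.iterrows():
        raw = str(row.get(cols["structure"], "") or "")
        name = str(row.get(cols["name"], f"row{idx}"))
        plate = str(row.get(cols["plate"], "") or "")
        well = str(row.get(cols["well"], "") or "")
        lib = str(row.get(cols["library"], "") or "")
        if not raw.strip():
            rejects.append({"row": idx, "name": name, "reason": REJECT_EMPTY})
            continue
        try:
            cleaned = standardize_structure(raw)
            desc = compute_descriptors(cleaned)
        except StructureError as exc:
            reason = REJECT_EMPTY if "empty" in str(exc) else REJECT_UNPARSEABLE
            rejects.append({"row": idx, "name": name, "reason": reason, "detail": str(exc)})
            continue
        records.append(
            CompoundRecord(
                source_name=name,
                raw_structure=raw,
                cleaned_smiles=cleaned,
                isomeric_smiles=desc["isomeric_smiles"],
                inchi=desc["inchi"],
                inchikey=desc["inchikey"],
                formula=desc["formula"],
                monoisotopic_mass=desc["monoisotopic_mass"],
                logp=desc["logp"],
                library_code=lib,
                plate=plate,
                well=well,
            )
        )
    return records, pd.DataFrame(rejects, columns=["row", "name", "reason", "detail"])


def assign_sample_ids(records: Sequence[CompoundRecord]) -> list[CompoundRecord]:
    """Assign ``LIBRARY_PLATE_WELL`` (uppercase, "_"-delimited) sample IDs.

    All compounds sharing (library_code, plate, well) receive the same ID;
    distinct wells cannot collide by construction.
    """
    missing = [r.source_name for r in records if not (r.plate and r.well)]
    if missing:
        raise ValueError(f"records missing plate/well: {missing}")
    return [
        replace(r, unique_sample_id=f"{r.library_code}_{r.plate}_{r.well}".upper())
        for r in records
    ]


def records_to_frame(records: Sequence[CompoundRecord]) -> pd.DataFrame:
    """Curated metadata as a flat table, one row per compound."""
    return pd.DataFrame([vars(r) for r in records])


def records_from_frame(df: pd.DataFrame) -> list[CompoundRecord]:
    fields_ = set(CompoundRecord.__dataclass_fields__)
    out = []
    for _, row in df.iterrows():
        d = {k: row[k] for k in df.columns if k in fields_}
        if "logp" in d and pd.isna(d["logp"]):
            d["logp"] = None
        if "isomeric_smiles" in d and (d["isomeric_smiles"] is None or pd.isna(d["isomeric_smiles"])):
            d["isomeric_smiles"] = None
        out.append(CompoundRecord(**d))
    return out


# ---------------------------------------------------------------------------
# sequence generation
# ---------------------------------------------------------------------------

@dataclass
class Plate:
    library_code: str
    plate: str
    wells: list[str] = field(default_factory=list)


def generate_sequence(
    plates: Sequence[Plate],
    start_date: _date,
    method_name: str,
) -> list[SequenceRow]:
    """Emit the acquisition sequence: per plate, every well first in positive
    then in negative polarity. Filenames embed the unique sample ID so the
    annotator can recover the well from the file name alone."""
    if not plates:
        raise ValueError("no plates given")
    rows: list[SequenceRow] = []
    index = 1
    datestr = start_date.strftime("%Y%m%d")
    for plate in plates:
        if len(set(plate.wells)) != len(plate.wells):
            dupes = sorted({w for w in plate.wells if plate.wells.count(w) > 1})
            raise ValueError(f"duplicate wells in plate {plate.plate}: {dupes}")
        for polarity in ("positive", "negative"):
            for well in plate.wells:
                usid = f"{plate.library_code}_{plate.plate}_{well}".upper()
                filename = f"{datestr}_{usid}_{method_name}_{polarity[:3]}"
                rows.append(
                    SequenceRow(
                        acquisition_date=start_date,
                        unique_sample_id=usid,
                        method_name=method_name,
                        polarity=polarity,
                        filename=filename,
                        injection_index=index,
                    )
                )
                index += 1
    return rows


def sequence_to_frame(rows: Sequence[SequenceRow]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in rows])


# ---------------------------------------------------------------------------
# deduplication
# ---------------------------------------------------------------------------

def dedupe_structures(
    records: Sequence[CompoundRecord], stereo: bool = False
) -> tuple[int, int, dict[str, list[CompoundRecord]]]:
    """Group compounds by InChIKey.

    ``stereo=True`` groups by the full 27-character key; ``stereo=False``
    by the first 14-character connectivity block (stereochemistry ignored).
    Returns (total, unique, groups keyed by the grouping key).
    """
    groups: dict[str, list[CompoundRecord]] = {}
    for r in records:
        if not r.inchikey:
            raise ValueError(f"record without inchikey: {r.source_name}")
        key = r.inchikey if stereo else r.inchikey.split("-")[0]
        groups.setdefault(key, []).append(r)
    return len(records), len(groups), groups


# ---------------------------------------------------------------------------
# enrichment hooks
# ---------------------------------------------------------------------------

def enrich_records(
    records: Sequence[CompoundRecord], hooks: Sequence = ()
) -> list[tuple[CompoundRecord, dict]]:
    """Apply metadata-enrichment hooks to curated records.

    Each hook is a callable ``CompoundRecord -> mapping`` contributing
    extra metadata (e.g. drug or natural-product flags from external
    databases). No hooks ship by default and none perform network access;
    this is the extension point for plugging such queries in.
    """
    out = []
    for rec in records:
        extra: dict = {}
        for hook in hooks:
            extra.update(hook(rec) or {})
        out.append((rec, extra))
    return out


# ---------------------------------------------------------------------------
# demo structure generator (valid, distinct small molecules for simulations)
# ---------------------------------------------------------------------------

_SCAFFOLDS = [
    "C{n}C(=O)O",          # fatty acids
    "C{n}N",               # amines
    "C{n}O",               # alcohols
    "C{n}C(=O)N",          # amides
    "c1ccccc1C{n}C(=O)O",  # arylalkanoic acids
    "c1ccncc1C{n}O",       # pyridyl alcohols
    "C{n}C(=O)OC",         # methyl esters
    "c1ccc(cc1)OC{n}N",    # aryloxy amines
]


def make_demo_library(n: int) -> list[str]:
    """Generate ``n`` distinct valid SMILES spanning ~100-500 Da.

    Simple homologous series over a handful of functional scaffolds —
    chemically plain but structurally distinct, which is all the
    mass-based pipeline needs for end-to-end exercises."""
    out: list[str] = []
    seen: set[str] = set()
    length = 3
    while len(out) < n:
        for scaf in _SCAFFOLDS:
            smi = scaf.replace("C{n}", "C" * length)
            mol = Chem.MolFromSmiles(smi)
            if mol is None:
                continue
            canon = Chem.MolToSmiles(mol)
            if canon in seen:
                continue
            seen.add(canon)
            out.append(canon)
            if len(out) >= n:
                break
        length += 1
        if length > 40:  # pragma: no cover - generator exhausted
            raise ValueError(f"cannot generate {n} distinct demo structures")
    return out
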