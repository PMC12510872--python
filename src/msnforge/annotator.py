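"""Sample-constrained adduct annotation.

The expected ion m/z for an adduct is ``(multimer * M + mass_delta) /
|charge|`` where ``mass_delta`` includes the electron mass correction
(proton delta = 1.007276 Da) — a 10-ppm annotation below m/z 200 is
sensitive to the ~0.5 mDa electron term.

Annotation is constrained to the compounds known to be in the injected
sample: the curated metadata's unique sample ID must occur in the file
name, bounded by non-alphanumeric characters or string edges so that a
well ID like ``P1_A1`` cannot match a file belonging to ``P1_A11``.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

from .chem_metadata import CompoundRecord
from .tree_builder import MsnTreeNode

ELECTRON_MASS = 0.000548579909  # Da
PROTON_MASS = 1.00727646688  # Da, includes electron correction


@dataclass(frozen=True)
class AdductDefinition:
    name: str  # e.g. "[M+H]+"
    multimer: int  # 1 for M, 2 for 2M dimers
    mass_delta: float  # Da, signed, electron-corrected
    charge: int  # signed, never 0
    polarity: str  # "positive" | "negative"

    def __post_init__(self):
        if self.charge == 0:
            raise ValueError("charge must be nonzero")
        if (self.charge > 0) != (self.polarity == "positive"):
            raise ValueError(f"{self.name}: charge sign inconsistent with polarity")


@dataclass
class Annotation:
    compound: CompoundRecord
    adduct: AdductDefinition
    node: MsnTreeNode
    expected_mz: float
    observed_mz: float
    mz_error_ppm: float
    ambiguous: bool = False


def load_adducts(path: str | Path | None = None) -> list[AdductDefinition]:
    """Load an adduct table CSV (name, multimer, mass_delta, charge,
    polarity); defaults to the table shipped with the package."""
    if path is None:
        text = resources.files("msnforge").joinpath("data/adducts.csv").read_text()
    else:
        text = Path(path).read_text()
    out = []
    for row in csv.DictReader(text.splitlines()):
        out.append(
            AdductDefinition(
                name=row["name"],
                multimer=int(row["multimer"]),
                mass_delta=float(row["mass_delta"]),
                charge=int(row["charge"]),
                polarity=row["polarity"],
            )
        )
    return out


DEFAULT_ADDUCTS = tuple(load_adducts())


def expected_ion_mz(monoisotopic_mass: float, adduct: AdductDefinition) -> float:
    """m/z of ``adduct`` for a neutral of the given monoisotopic mass."""
    if monoisotopic_mass <= 0:
        raise ValueError("monoisotopic_mass must be > 0")
    return (adduct.multimer * monoisotopic_mass + adduct.mass_delta) / abs(adduct.charge)


def compounds_for_file(
    filename: str, metadata: Sequence[CompoundRecord]
) -> list[CompoundRecord]:
    """Compounds whose unique sample ID occurs in ``filename``.

    The ID must be bounded by non-alphanumeric characters or the string
    edges (token-boundary guard). Matching more than one distinct sample
    ID is a hard error: file names must be unambiguous.
    """
    hits: list[CompoundRecord] = []
    matched_ids: set[str] = set()
    for rec in metadata:
        usid = rec.unique_sample_id
        if not usid:
            continue
        pattern = r"(?<![A-Za-z0-9])" + re.escape(usid) + r"(?![A-Za-z0-9])"
        if re.search(pattern, filename):
            hits.append(rec)
            matched_ids.add(usid)
    if len(matched_ids) > 1:
        raise ValueError(
            f"filename {filename!r} matches multiple sample IDs: {sorted(matched_ids)}"
        )
    return hits


def annotate_forest(
    forest: Sequence[MsnTreeNode],
    candidates: Sequence[CompoundRecord],
    adducts: Sequence[AdductDefinition] = DEFAULT_ADDUCTS,
    tol_ppm: float = 10.0,
    tol_abs: float = 0.005,
    polarity: str | None = None,
) -> list[Annotation]:
    """Match tree roots against every (candidate, adduct) pair.

    A root matches when |observed - expected| <= max(tol_abs,
    tol_ppm * expected * 1e-6). All matches are retained, ranked by
    absolute ppm error per root; roots matching several candidates (e.g.
    isomers pooled in one well) are flagged ambiguous. Result is
    independent of candidate order.
    """
    annotations: list[Annotation] = []
    use_adducts = [a for a in adducts if polarity is None or a.polarity == polarity]
    for root in forest:
        if root.ms_level != 2 or root.orphan:
            continue
        observed = root.node_precursor_mz
        matches: list[Annotation] = []
        for comp in candidates:
            for adduct in use_adducts:
                expected = expected_ion_mz(comp.monoisotopic_mass, adduct)
                tol = max(tol_abs, tol_ppm * expected * 1e-6)
                if abs(observed - expected) <= tol:
                    ppm = (observed - expected) / expected * 1e6
                    matches.append(
                        Annotation(
                            compound=comp,
                            adduct=adduct,
                            node=root,
                            expected_mz=expected,
                            observed_mz=observed,
                            mz_error_ppm=ppm,
                        )
                    )
        matches.sort(key=lambda a: (abs(a.mz_error_ppm), a.compound.inchikey, a.adduct.name))
        distinct = {a.compound.inchikey for a in matches}
        for a in matches:
            a.ambiguous = len(distinct) > 1
        annotations.extend(matches)
    return annotations
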