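"""Shared fixtures: small curated compound sets, random scans and
random library entries — all generated programmatically and seeded."""

from __future__ import annotations

import random
import string
from datetime import date

import numpy as np
import pandas as pd
import pytest

from msnforge.chem_metadata import (
    CompoundRecord,
    Plate,
    assign_sample_ids,
    curate_table,
    generate_sequence,
    make_demo_library,
)
from msnforge.msdata_io import LibraryEntry, PrecursorStep, ScanRecord


@pytest.fixture(scope="session")
def demo_records() -> list[CompoundRecord]:
    """20 curated demo compounds over 4 wells (2 plates x 2 wells)."""
    smiles = make_demo_library(20)
    rows = []
    for i, smi in enumerate(smiles):
        rows.append(
            {
                "name": f"cpd{i}",
                "structure": smi,
                "library": "DEMO",
                "plate": str(i // 10 + 1),
                "well": f"A{(i % 10) // 5 + 1}",
            }
        )
    records, rejects = curate_table(pd.DataFrame(rows))
    assert rejects.empty
    return assign_sample_ids(records)


@pytest.fixture(scope="session")
def demo_sequence(demo_records):
    plates = [Plate("DEMO", "1", ["A1", "A2"]), Plate("DEMO", "2", ["A1", "A2"])]
    return generate_sequence(plates, date(2026, 1, 1), "FIMSN")


def make_scan(
    scan_number: int,
    ms_level: int,
    peaks,
    chain=(),
    polarity: str = "positive",
    rt: float = 0.1,
) -> ScanRecord:
    return ScanRecord(
        scan_number=scan_number,
        ms_level=ms_level,
        polarity=polarity,
        retention_time=rt,
        peaks=[(float(mz), float(i)) for mz, i in peaks],
        precursor_chain=[PrecursorStep(*step) for step in chain],
    )


def random_scan(rng: np.random.Generator, scan_number: int = 1) -> ScanRecord:
    n = int(rng.integers(1, 30))
    mzs = np.sort(rng.uniform(50, 500, n))
    intensities = rng.uniform(1, 1e6, n)
    return make_scan(scan_number, 1, list(zip(mzs, intensities)))


def random_inchikey(rng: random.Random) -> str:
    blocks = (
        "".join(rng.choices(string.ascii_uppercase, k=14)),
        "".join(rng.choices(string.ascii_uppercase, k=10)),
        rng.choice(string.ascii_uppercase),
    )
    return "-".join(blocks)


def random_entry(rng: random.Random, index: int = 0) -> LibraryEntry:
    n = rng.randint(2, 25)
    mzs = sorted(rng.uniform(50, 900) for _ in range(n))
    peaks = [(mz, rng.uniform(1, 1e6)) for mz in mzs]
    spec_type = rng.choice(
        ["SINGLE_BEST_SCAN", "SAME_ENERGY", "ALL_ENERGIES", "ALL_MSN_TO_PSEUDO_MS2"]
    )
    energies = [rng.choice([20.0, 40.0, 45.0, 60.0])]
    if spec_type in ("ALL_ENERGIES", "ALL_MSN_TO_PSEUDO_MS2"):
        energies = sorted(rng.sample([20.0, 40.0, 45.0, 60.0], k=rng.randint(1, 3)))
    compound = CompoundRecord(
        source_name=f"compound {index}",
        raw_structure="CCO",
        cleaned_smiles="CCO",
        inchi="InChI=1S/C2H6O/c1-2-3/h3H,2H2,1H3",
        inchikey=random_inchikey(rng),
        formula="C2H6O",
        monoisotopic_mass=rng.uniform(100, 800),
        unique_sample_id=f"LIB_{rng.randint(1, 5)}_A{rng.randint(1, 12)}",
    )
    return LibraryEntry(
        compound=compound,
        adduct_name=rng.choice(["[M+H]+", "[M+Na]+", "[M-H]-"]),
        precursor_mz=max(m for m, _ in peaks) + rng.uniform(1, 50),
        ms_level=rng.randint(2, 5),
        spec_type=spec_type,
        collision_energies=energies,
        peaks=peaks,
        precursor_purity_pct=rng.choice([None, rng.uniform(0, 100)]),
        chimeric_flag=rng.random() < 0.2,
        provenance={f"file_{rng.randint(1, 3)}": sorted(rng.sample(range(1, 500), k=3))},
    )


def entries_equal(a: LibraryEntry, b: LibraryEntry, rel: float = 1e-6) -> bool:
    """Field-for-field equality up to float text precision."""
    def close(x, y):
        if x is None or y is None:
            return x is y
        return abs(x - y) <= rel * max(1.0, abs(x), abs(y))

    return (
        a.compound.source_name == b.compound.source_name
        and a.compound.inchikey == b.compound.inchikey
        and a.compound.formula == b.compound.formula
        and a.compound.cleaned_smiles == b.compound.cleaned_smiles
        and a.compound.inchi == b.compound.inchi
        and close(a.compound.monoisotopic_mass, b.compound.monoisotopic_mass)
        and a.compound.unique_sample_id == b.compound.unique_sample_id
        and a.adduct_name == b.adduct_name
        and close(a.precursor_mz, b.precursor_mz)
        and a.ms_level == b.ms_level
        and a.spec_type == b.spec_type
        and len(a.collision_energies) == len(b.collision_energies)
        and all(close(x, y) for x, y in zip(a.collision_energies, b.collision_energies))
        and len(a.peaks) == len(b.peaks)
        and all(close(p[0], q[0]) and close(p[1], q[1]) for p, q in zip(a.peaks, b.peaks))
        and close(a.precursor_purity_pct, b.precursor_purity_pct)
        and a.chimeric_flag == b.chimeric_flag
        and a.provenance == b.provenance
    )
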