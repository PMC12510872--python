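# msnforge

Automated generation of multi-stage fragmentation (MSⁿ) spectral
libraries from pooled-compound flow-injection runs.

Compound identification in untargeted mass spectrometry hinges on
matching fragmentation spectra against reference libraries, and open
MSⁿ (n > 2) reference data are scarce. One practical way to build such
libraries at scale is to pool up to ten reference compounds per well,
inject each well by flow injection (no chromatography), and acquire
deep data-dependent MS²–MS⁵ fragmentation trees at several collision
energies in both ionization modes. `msnforge` implements the data side
of that workflow for analytical chemists and mass-spectrometry
informaticians:

- **Metadata curation** — two-pass salt stripping and structure
  standardization (RDKit), descriptors (InChI/InChIKey, formula,
  monoisotopic mass, logP), unique sample IDs
  (`LIBRARY_PLATE_WELL`), acquisition-sequence generation, and
  InChIKey-based deduplication with or without stereochemistry.
- **Scan ingestion** — mzML and a JSON scan dialect (`scanjson`), with
  full MSⁿ precursor-chain reconstruction.
- **Tree building** — scans grouped into precursor-lineage trees rooted
  at MS² precursors; the full selection chain is matched so isobaric
  fragments cannot cross-link trees.
- **Sample-constrained annotation** — expected ion m/z
  `(k·M + Δ)/|z|` for a configurable adduct/in-source-fragment table;
  candidates restricted to the compounds whose unique sample ID occurs
  (token-bounded) in the file name.
- **Quality control** — noise filtering at 2.5× the scan noise floor,
  background-ion exclusion windows (defaults at m/z 149.72 and 173.52,
  width 0.03), precursor isolation purity from the flanking MS¹ scans
  with chimera flagging, and a minimum-two-signal library filter.
- **Spectral merging** — `SAME_ENERGY` consensus over repeat triggers,
  `ALL_ENERGIES` merges per precursor, and `ALL_MSN_TO_PSEUDO_MS2`
  composites collapsing a whole tree into one MS²-like spectrum.
- **Export and evaluation** — MGF/MSP/JSON libraries; weighted-cosine
  library search (w = m/z⁰·I⁰·⁵, greedy pairing, score
  (Σw_q·w_l)²⁄(Σw_q²·Σw_l²), min score 0.6, min 4 matched signals);
  InChIKey-first-block overlap (UpSet) counts; Morgan/Tanimoto
  structure similarity.
- **A DDA simulator** — first-class, tested code that emulates the
  pooled-well MS²–MS⁵ acquisition schema (top-3/5/2/2 selection,
  per-polarity intensity gates, repeat triggers, isotope envelopes,
  background ions, chimeric co-isolation) with full ground truth, so
  the entire pipeline runs without instrument data.

## Worked example

Curate three compounds pooled in one well, generate the acquisition
sequence, simulate the injections, and build the library:

```bash
msnforge clean-metadata compounds.csv --out curated.csv
# curated 3 compounds (0 rejected); 3 unique with stereochemistry, 3 unique by connectivity

msnforge make-sequence curated.csv --out sequence.csv --date 2026-01-01
# wrote 2 sequence rows to sequence.csv

msnforge simulate curated.csv sequence.csv --outdir sim --seed 1
# simulated 2 injections, 10 ground-truth precursors

msnforge build-library curated.csv sim/*.scanjson --outdir lib
# {"attempted": {"positive": 3, "negative": 3},
#  "detected":  {"positive": 3, "negative": 3},
#  "detected_total": 3, "attempted_total": 3,
#  "detection_by_polarity": {"negative+positive": 3},
#  "coverage_pct": 100.0}
```

The report says all three compounds were annotated in both polarities
(the `detection_by_polarity` entry is the UpSet membership count), so
simulated coverage is 100%. `lib/` now holds `library_positive.mgf`
(and `.msp`/`.json`, plus the negative-mode files) and `report.json`
with per-file stage counters. Inspect a fragmentation tree:

```bash
msnforge inspect-tree sim/20260101_DEMO_1_A1_FIMSN_pos.scanjson
# MS2 m/z 177.0771 (9 scans, energies [20.0, 45.0, 60.0])
#   MS3 m/z 122.0688 (3 scans, energies [20.0, 40.0, 60.0])
#     MS4 m/z 99.2223 (3 scans, energies [20.0, 40.0, 60.0])
#     ...
```

The first root (m/z 177.0771) is caffeine's [M+H–H₂O]⁺ in-source
fragment and the second (m/z 195.0877) its [M+H]⁺; every root is
matched against the configured adducts of the well's own compounds
only. Each MS² root carries 9 scans (3 repeat triggers × 3 collision
energies), exactly the simulated acquisition schema. Library search of
the produced library against itself:

```bash
msnforge match lib/library_positive.mgf lib/library_positive.mgf \
    --out matches.tsv --min-matched 2
# 1562 matches written to matches.tsv
```

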