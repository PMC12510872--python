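# Methods

This note documents the models and procedures implemented in
`msnforge`, the defaults that matter, the numerical choices made where
the design was genuinely open, and what the synthetic acquisition does
and does not emulate.

## Structure curation

Input structures (SMILES, or InChI auto-detected by prefix) are
standardized in two full passes of: largest-fragment selection →
normalization (`rdMolStandardize.Cleanup`, which also disconnects
metals) → largest-fragment again → charge neutralization (`Uncharger`).
The second pass exists because some vendor entries encode salts without
a fragment separator; these only become strippable after one
normalization round. Largest-fragment ties (equal heavy-atom count) are
broken by larger monoisotopic mass, then lexicographically smaller
canonical SMILES, so output is deterministic. The function is
idempotent, and unparseable rows go to a rejects table with reason
codes rather than aborting the run.

Descriptors: InChI/InChIKey via RDKit's InChI layer, molecular formula,
monoisotopic mass (most-abundant-isotope atomic masses), and Crippen
atom-contribution logP. logP is metadata only — approximate by
construction and never used in matching. Deduplication groups by full
InChIKey (`stereo=True`) or by its first 14-character connectivity
block (`stereo=False`); both counts are reported because sourcing
statistics are usually quoted with stereochemistry and cross-library
overlaps without it.

Unique sample IDs are `LIBRARY_PLATE_WELL`, uppercase,
underscore-delimited. Only substring matchability is required
downstream, but a fixed delimiter makes the token-boundary guard (below)
reliable. Acquisition sequences emit, per plate, every well first in
positive then in negative polarity; the generated file name embeds the
sample ID.

## Scan ingestion

Two scan formats are read: mzML and `scanjson`, a small versioned JSON
dialect that serves as the package's plain-text fixture format. The
mzML reader is a minimal accession-keyed cvParam parser (lxml,
32/64-bit and zlib-compressed arrays). mzML writers differ in how they
encode MSⁿ precursor chains: when a spectrum stores only its immediate
precursor, the full chain is reconstructed from the most recent
ancestor scan at each lower MS level, and the choice is logged per
file. Files mixing polarities are rejected — the acquisition runs
polarities separately. A matching minimal mzML writer exists so the
simulator can round-trip through the standard format.

## Tree building

All MSⁿ (n ≥ 2) scans of one injection form a forest: MS² scans whose
selection m/z agree within `mz_tol` (default 0.01 Th — isolation
windows are ≥ 1.2 Th, so this is safely tight) share a root, and deeper
scans attach where *every* stage of their precursor chain matches the
path from the root. Full-chain matching means isobaric product ions
under different roots cannot cross-link trees, which matters for pooled
wells. A node's representative m/z is the TIC-weighted mean of its
member selections (stable under repeat triggers). Scans with no
matching parent become flagged single-node orphan trees rather than
errors; scan conservation (every input MSⁿ scan sits in exactly one
node) and input-order invariance are tested properties. Flow injection
means no chromatographic deconvolution: one "feature" per precursor per
file, retention time kept as provenance only.

## Annotation

Expected ion m/z is `(k·M + Δ)/|z|` with the electron mass
(0.000548579909 Da) folded into Δ, so the proton delta is 1.007276 Da —
at 10 ppm below m/z 200 the electron term is not negligible. The
shipped adduct table (editable CSV) defaults to
[M+H]⁺, [M+Na]⁺, [M+NH₄]⁺, [M+K]⁺, [2M+H]⁺, [M+H−H₂O]⁺ in positive
mode and [M−H]⁻, [M+HCOO]⁻, [M+Cl]⁻, [2M−H]⁻ in negative mode — a
declared default, configurable. Candidates for a file are exactly the
compounds whose sample ID occurs in the file name bounded by
non-alphanumeric characters or string edges (so `P1_A1` never matches a
`P1_A11` file); a file name matching two distinct IDs is a hard error.
A root matches when |observed − expected| ≤ max(0.005 Th, 10 ppm) —
the max composition is the permissive reading of an "x or y ppm"
tolerance and mirrors the matching defaults. All matches are retained,
ranked by |ppm error|; isomer co-matches are flagged ambiguous.

## Quality filters

*Noise.* Threshold = 2.5 × the scan's noise floor, where the floor is
the lowest intensity of the **raw** scan, estimated once and carried on
the record. Anchoring the floor to the raw scan (mass-detector
semantics: noise estimation precedes any filtering) makes the noise and
background filters exactly idempotent and mutually commuting. Boundary:
with a factor > 1 the minimal peak always falls below its own scaled
threshold, so uniform-intensity scans empty completely; such spectra
would fail the two-signal filter anyway.

*Background.* Exclusion windows (center ± width/2) applied at every MS
level; defaults are the two static flow-injection background signals at
m/z 149.72 and 173.52, width 0.03.

*Isolation purity.* For each flanking MS¹ scan, purity = intensity
attributable to the precursor within the isolation window ÷ total
window intensity × 100, where "attributable" is the peak nearest the
selected m/z within ±0.01 Th plus charge-1 isotope peaks at
+k·1.00335 Th (k = 1..3, same tolerance). The final value averages the
preceding and (when present) following MS¹ scan; below 90% the spectrum
is flagged chimeric. The formula, isotope treatment and 90% cutoff are
explicit package choices (configurable) — purity definitions vary
between tools — and the value is scale invariant by construction.
Chimeric entries are exported with their flag, not dropped.

*Library filter.* An exported spectrum must keep at least two signals
after noise filtering.

## Spectral merging

The merging primitive normalizes every source spectrum to base peak
100, pools all peaks, and groups them by greedy ascending-m/z single
linkage within 0.005 Th (the same tolerance as spectral matching).
Merged m/z is the intensity-weighted mean of the group; merged
intensity is the **maximum** of the normalized member intensities —
max preserves fragments that are prominent at any single energy, which
is the point of a multi-energy merge (sum/mean are selectable).

- `SAME_ENERGY`: consensus over ≥ 2 repeat triggers of one energy;
  with a single trigger the caller falls back to `SINGLE_BEST_SCAN`
  (highest TIC, ties to the earlier scan number).
- `ALL_ENERGIES`: per energy take the consensus if available, else the
  best scan, then merge; the entry lists every energy used.
- `ALL_MSN_TO_PSEUDO_MS2`: merge the `ALL_ENERGIES` spectra of every
  node in the subtree after stripping each stage's residual precursor
  (and everything above it), so the composite is a pure fragment
  spectrum on the root precursor, recorded at MS level 2. No per-level
  intensity re-weighting is applied — a flagged assumption.

## Matching and overlap

The similarity is a weighted cosine with w = m/z⁰ · I⁰·⁵ (square-root
intensity weighting). Peaks are paired greedily — ascending |Δm/z|,
ties to the larger weight product, each peak used at most once — and
the score is (Σ w_q·w_l)² ⁄ (Σ w_q²)(Σ w_l²): 1.0 for identical
spectra, symmetric, scale invariant. Greedy pairing can fall below the
optimal one-to-one assignment on near-coincident peak clusters; a
Hungarian-algorithm oracle (`optimal_cosine`) bounds it in the test
suite, where equality holds in ≈ 97% of randomized small instances
(instances mirror centroided high-resolution spectra: peaks spread over
m/z 50–500, shared peaks perturbed within the 0.01 Th tolerance, 15% of
trials containing one sub-tolerance cluster). Library search restricts
candidates to |Δprecursor| ≤ max(0.005 Th, 10 ppm), strips residual
precursors from both sides, and keeps hits with score ≥ 0.6 and ≥ 4
matched signals, top-k per query (optionally deduplicated by library
compound first).

Library overlap reduces InChIKeys to their first block and reports
counts per exact source-membership pattern (UpSet semantics) plus
per-source unique counts; pattern counts sum to the union size.
Structure similarity is Tanimoto on Morgan fingerprints (radius 2,
2048 bits).

## Synthetic acquisition

The simulator emulates the pooled-well flow-injection DDA schema:

- MS¹ survey scans (m/z 115–2000) containing each compound's adduct
  ions (per-adduct probabilities, ≥ 1 ion guaranteed per compound),
  M+1 isotopes at 5–30% and M+2 at 0–10%, static background ions in the
  two exclusion windows, and a lognormal noise floor (median ≈ 3 × 10³
  a.u.).
- Top-3 MS² selection with minimum-intensity gates of 6 × 10⁵ /
  2 × 10⁵ a.u. (positive/negative), isolation 1.2 Th, energies 20 and
  60 eV plus a fixed 45 eV standing in for the assisted energy; each
  precursor is selected three times (the effect of dynamic exclusion
  with a maximum occurrence of three).
- Top-5 MS³ from the assisted-energy MS² template (m/z ≥ 90, gates
  2 × 10⁴ / 1 × 10⁴ a.u., isolation 2 Th, energies 20/40/60 eV); top-2
  MS⁴ from the 40 eV MS³ (isolation 2.2 Th); top-2 MS⁵ from the 40 eV
  MS⁴ (m/z ≥ 150, isolation 3 Th, energies 40/60 eV).
- Chimeric co-isolation: with probability `chimera_rate` (default 0.1)
  a contaminant ion is planted inside a precursor's isolation window,
  depressing its measured purity.
- Mass accuracy: per-scan jitter of 0.0005 Th (≈ 3 ppm at m/z 180).

Every precursor actually selected for MS² is recorded as ground truth
(compound, adduct, expected m/z, well, file), which is the reference
for end-to-end recovery.

What it does **not** emulate: fragment m/z values are random neutral
losses (≥ 50 Th, always below the precursor), not chemistry — so
passing tests demonstrate that tree assembly, annotation, merging,
export and matching are correct, not that the pipeline handles real
fragmentation patterns, isotope fine structure, profile-mode data, or
real detector noise statistics. There is no assisted-energy
optimization logic, no acquisition-time dynamic-exclusion bookkeeping
beyond the three-trigger effect, and no LC elution profile.

## Pipeline and reporting

`build_library` processes each file independently (failures are logged
and skipped; only all files failing is fatal), accumulates entries per
polarity, exports MGF/MSP/JSON, and writes a report with per-stage
counters (scans in, peaks before/after filtering, trees, orphans,
annotations, entries, two-signal rejections), attempted/detected
compound counts per polarity, detection-by-polarity membership counts,
and entry counts per SPECTYPE. Detected compounds are distinct
InChIKeys of exported entries.

## Problem sizes

The acceptance script runs a two-plate simulation (2 plates × 4 wells
× 10 compounds, both polarities = 16 injections, ≈ 200 ground-truth
precursors) — small enough to complete in seconds yet exercising every
stage at the defaults above; the test suite's end-to-end fixture uses
2 plates × 2 wells. The demo compound generator produces homologous
series over a handful of functional scaffolds: structurally distinct,
chemically plain, sufficient for a mass-based pipeline.

## Known limitations

- The JSON library schema is the package's own (documented by the
  writer); the reader additionally accepts obvious key synonyms.
- Purity formula/threshold and the adduct set are declared defaults,
  not community standards; both are configurable and surfaced in
  output metadata.
- No modified cosine (neutral-loss shifting), no maximum-common-edge
  subgraph distance, no external database enrichment (a no-op hook
  would slot into metadata curation), no vendor raw-file reading, and
  no LC feature alignment across samples.
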