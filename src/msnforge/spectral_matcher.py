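"""Weighted cosine matching, library search and library-overlap analysis.

The similarity is a weighted cosine on peak vectors with weights
``w = mz^mz_power * intensity^intensity_power`` (defaults mz^0 * I^0.5,
i.e. square-root intensity weighting). Peaks are paired greedily by best
m/z agreement within tolerance, each peak used at most once, and the
score is ``(sum of paired w_q*w_l)^2 / ((sum w_q^2)(sum w_l^2))`` over
all peaks of both spectra — 1.0 for identical spectra, scale invariant,
symmetric. Greedy pairing can fall below the optimal assignment on
pathological peak clusters; it never exceeds it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

from rdkit import Chem, DataStructs
from rdkit.Chem import rdFingerprintGenerator

Peaks = Sequence[tuple[float, float]]

DEFAULT_MZ_TOL = 0.005  # Th
DEFAULT_PRECURSOR_TOL_ABS = 0.005  # Th
DEFAULT_PRECURSOR_TOL_PPM = 10.0
DEFAULT_MIN_SCORE = 0.6
DEFAULT_MIN_MATCHED = 4


@dataclass
class MatchResult:
    query_id: str
    library_id: str
    score: float
    matched_signals: int
    precursor_delta_mz: float


def remove_precursor_peaks(
    peaks: Peaks, precursor_mz: float, tol: float, mode: Literal["all_above", "window"] = "all_above"
) -> list[tuple[float, float]]:
    """Strip the residual precursor: by default everything at or above
    ``precursor_mz - tol``; ``window`` mode removes only ±tol around it."""
    if mode == "all_above":
        return [(mz, i) for mz, i in peaks if mz < precursor_mz - tol]
    return [(mz, i) for mz, i in peaks if abs(mz - precursor_mz) > tol]


def _weights(peaks: Peaks, mz_power: float, intensity_power: float) -> list[float]:
    return [(mz ** mz_power) * (i ** intensity_power) for mz, i in peaks]


def weighted_cosine(
    a: Peaks,
    b: Peaks,
    mz_tol: float = DEFAULT_MZ_TOL,
    mz_power: float = 0.0,
    intensity_power: float = 0.5,
) -> tuple[float, int]:
    """Greedy weighted cosine between two spectra.

    Candidate pairs within ``mz_tol`` are assigned in order of ascending
    |Δm/z| (ties to the larger weight product), each peak at most once.
    Returns (score in [0,1], number of matched signals).
    """
    if not a or not b:
        return 0.0, 0
    wa = _weights(a, mz_power, intensity_power)
    wb = _weights(b, mz_power, intensity_power)
    candidates = []
    for i, (mza, _) in enumerate(a):
        for j, (mzb, _) in enumerate(b):
            d = abs(mza - mzb)
            if d <= mz_tol:
                candidates.append((d, -wa[i] * wb[j], i, j))
    candidates.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    dot = 0.0
    matched = 0
    for _, neg_prod, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        dot += -neg_prod
        matched += 1
    norm = sum(w * w for w in wa) * sum(w * w for w in wb)
    score = (dot * dot) / norm if norm > 0 else 0.0
    return min(score, 1.0), matched


def optimal_cosine(
    a: Peaks,
    b: Peaks,
    mz_tol: float = DEFAULT_MZ_TOL,
    mz_power: float = 0.0,
    intensity_power: float = 0.5,
) -> tuple[float, int]:
    """Brute-force optimal-assignment counterpart of :func:`weighted_cosine`.

    Maximizes the paired weight-product sum over all one-to-one pairings
    within tolerance (Hungarian algorithm). Intended as an oracle for
    small spectra, not for production matching.
    """
    import numpy as np
    from scipy.optimize import linear_sum_assignment

    if not a or not b:
        return 0.0, 0
    wa = _weights(a, mz_power, intensity_power)
    wb = _weights(b, mz_power, intensity_power)
    gain = np.zeros((len(a), len(b)))
    for i, (mza, _) in enumerate(a):
        for j, (mzb, _) in enumerate(b):
            if abs(mza - mzb) <= mz_tol:
                gain[i, j] = wa[i] * wb[j]
    rows, cols = linear_sum_assignment(-gain)
    dot = 0.0
    matched = 0
    for i, j in zip(rows, cols):
        if gain[i, j] > 0:
            dot += gain[i, j]
            matched += 1
    norm = sum(w * w for w in wa) * sum(w * w for w in wb)
    score = (dot * dot) / norm if norm > 0 else 0.0
    return min(score, 1.0), matched


def library_search(
    queries: Sequence,
    library: Sequence,
    precursor_tol_abs: float = DEFAULT_PRECURSOR_TOL_ABS,
    precursor_tol_ppm: float = DEFAULT_PRECURSOR_TOL_PPM,
    mz_tol: float = DEFAULT_MZ_TOL,
    min_score: float = DEFAULT_MIN_SCORE,
    min_matched: int = DEFAULT_MIN_MATCHED,
    top_k: int = 5,
    precursor_removal_tol: float = 0.01,
    dedupe_by_compound: bool = False,
) -> list[MatchResult]:
    """Search query entries against a library.

    Candidate pairs are restricted to precursor m/z within
    ``max(precursor_tol_abs, ppm-based)``; residual precursors are
    removed from both spectra before scoring. Hits must reach
    ``min_score`` and ``min_matched`` signals; per query the top_k hits
    by score are returned (optionally deduplicated by library InChIKey
    first, keeping each compound's best hit).
    """
    results: list[MatchResult] = []
    for qi, q in enumerate(queries):
        q_id = _entry_id(q, qi)
        q_peaks = remove_precursor_peaks(q.peaks, q.precursor_mz, precursor_removal_tol)
        if not q_peaks:
            continue
        hits: list[MatchResult] = []
        for li, lib in enumerate(library):
            tol = max(precursor_tol_abs, precursor_tol_ppm * lib.precursor_mz * 1e-6)
            delta = q.precursor_mz - lib.precursor_mz
            if abs(delta) > tol:
                continue
            l_peaks = remove_precursor_peaks(lib.peaks, lib.precursor_mz, precursor_removal_tol)
            if not l_peaks:
                continue
            score, matched = weighted_cosine(q_peaks, l_peaks, mz_tol)
            if score >= min_score and matched >= min_matched:
                hits.append(
                    MatchResult(
                        query_id=q_id,
                        library_id=_entry_id(lib, li),
                        score=score,
                        matched_signals=matched,
                        precursor_delta_mz=delta,
                    )
                )
        hits.sort(key=lambda h: -h.score)
        if dedupe_by_compound:
            seen: set[str] = set()
            unique = []
            for h in hits:
                key = h.library_id.split("|")[0]
                if key in seen:
                    continue
                seen.add(key)
                unique.append(h)
            hits = unique
        results.extend(hits[:top_k])
    return results


def _entry_id(entry, index: int) -> str:
    key = getattr(entry.compound, "inchikey", "") if hasattr(entry, "compound") else ""
    name = getattr(entry.compound, "source_name", "") if hasattr(entry, "compound") else ""
    return f"{key or name or 'entry'}|{getattr(entry, 'spec_type', '')}|{index}"


# ---------------------------------------------------------------------------
# library overlap (UpSet semantics on InChIKey first blocks)
# ---------------------------------------------------------------------------

def _first_block(key: str) -> str:
    key = key.strip()
    block = key.split("-")[0]
    if len(block) != 14 or not block.isalpha() or not block.isupper():
        raise ValueError(f"malformed InChIKey or first block: {key!r}")
    return block


def overlap_sets(sources: Mapping[str, Sequence[str]]) -> dict:
    """Membership counts per source combination, on InChIKey first blocks.

    Returns ``{"patterns": {frozenset-as-sorted-tuple: count}, "uniques":
    {source: count}, "union": total}`` — UpSet semantics: every block is
    counted once, under the exact combination of sources containing it.
    """
    membership: dict[str, set[str]] = {}
    for source, keys in sources.items():
        for key in keys:
            membership.setdefault(_first_block(key), set()).add(source)
    patterns: dict[tuple[str, ...], int] = {}
    for block, srcs in membership.items():
        pat = tuple(sorted(srcs))
        patterns[pat] = patterns.get(pat, 0) + 1
    uniques = {
        source: patterns.get((source,), 0) for source in sources
    }
    return {"patterns": patterns, "uniques": uniques, "union": len(membership)}


# ---------------------------------------------------------------------------
# structure similarity
# ---------------------------------------------------------------------------

_MORGAN = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)


def tanimoto_similarity(a: str, b: str) -> float:
    """Tanimoto similarity of Morgan fingerprints (radius 2, 2048 bits)."""
    mols = []
    for smi in (a, b):
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise ValueError(f"unparseable structure: {smi!r}")
        mols.append(mol)
    fps = [_MORGAN.GetFingerprint(m) for m in mols]
    return DataStructs.TanimotoSimilarity(fps[0], fps[1])
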