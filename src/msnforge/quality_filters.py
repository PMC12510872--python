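"""Scan denoising, background-ion removal, precursor isolation purity.

The noise filter mirrors the "factor of the lowest signal" mass detector:
every peak below ``noise_factor x min(intensity in scan)`` is removed.
With a factor > 1 the minimal peak itself always falls below its own
scaled threshold, so a scan of uniform intensities empties completely —
a documented boundary that the downstream minimum-two-signal library
filter would reject anyway.

Flow-injection acquisition on the instrument used here shows static
background signals near m/z 149.72 and m/z 173.52; both ship as default
exclusion windows of full width 0.03 Th applied at every MS level.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

from .msdata_io import ScanRecord

#: isotope spacing for singly charged ions (Th)
ISOTOPE_SPACING = 1.00335
DEFAULT_NOISE_FACTOR = 2.5
DEFAULT_CHIMERIC_THRESHOLD_PCT = 90.0
DEFAULT_MIN_SIGNALS = 2


@dataclass(frozen=True)
class ExclusionWindow:
    center_mz: float  # Th
    width: float  # Th, full window width

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError("window width must be > 0")

    def contains(self, mz: float) -> bool:
        return abs(mz - self.center_mz) <= self.width / 2.0


def load_exclusion_windows(path=None) -> tuple[ExclusionWindow, ...]:
    """Load an exclusion-list CSV of (center_mz, width); defaults to the
    table shipped with the package (the two static background windows)."""
    import csv
    from importlib import resources
    from pathlib import Path

    if path is None:
        text = resources.files("msnforge").joinpath("data/exclusion_windows.csv").read_text()
    else:
        text = Path(path).read_text()
    return tuple(
        ExclusionWindow(float(row["center_mz"]), float(row["width"]))
        for row in csv.DictReader(text.splitlines())
    )


DEFAULT_EXCLUSION_WINDOWS = load_exclusion_windows()


@dataclass
class PurityResult:
    purity_pct: float
    chimeric_flag: bool
    ms1_scans_used: int


def _with_noise_floor(scan: ScanRecord) -> ScanRecord:
    """Record the raw scan's lowest intensity as its noise floor (once)."""
    if scan.noise_floor is not None or not scan.peaks:
        return scan
    return replace(scan, noise_floor=min(i for _, i in scan.peaks))


def noise_filter(scan: ScanRecord, noise_factor: float = DEFAULT_NOISE_FACTOR) -> ScanRecord:
    """Remove peaks below ``noise_factor`` times the scan's noise floor.

    The floor is the lowest intensity of the raw scan, estimated once and
    carried on the record — reapplying the filter (or interleaving it
    with background removal) therefore changes nothing."""
    scan = _with_noise_floor(scan)
    if not scan.peaks or scan.noise_floor is None:
        return scan
    threshold = noise_factor * scan.noise_floor
    kept = [(mz, i) for mz, i in scan.peaks if i >= threshold]
    return replace(scan, peaks=kept)


def remove_background(
    scan: ScanRecord, windows: Sequence[ExclusionWindow] = DEFAULT_EXCLUSION_WINDOWS
) -> ScanRecord:
    """Drop peaks inside any exclusion window, at every MS level."""
    scan = _with_noise_floor(scan)
    if not windows:
        return scan
    kept = [(mz, i) for mz, i in scan.peaks if not any(w.contains(mz) for w in windows)]
    return replace(scan, peaks=kept)


def _window_purity(
    ms1: ScanRecord, precursor_mz: float, isolation_width: float, match_tol: float, n_isotopes: int
) -> float:
    half = isolation_width / 2.0
    in_window = [(mz, i) for mz, i in ms1.peaks if abs(mz - precursor_mz) <= half]
    if not in_window:
        return 0.0
    total = sum(i for _, i in in_window)
    # the peak nearest the precursor within the match window anchors attribution
    candidates = [(abs(mz - precursor_mz), mz, i) for mz, i in in_window if abs(mz - precursor_mz) <= match_tol]
    if not candidates:
        return 0.0
    _, anchor_mz, anchor_i = min(candidates)
    attributable = anchor_i
    for k in range(1, n_isotopes + 1):
        iso_mz = anchor_mz + k * ISOTOPE_SPACING
        hits = [i for mz, i in in_window if abs(mz - iso_mz) <= match_tol]
        attributable += sum(hits)
    return 100.0 * attributable / total


def precursor_purity(
    before: ScanRecord,
    after: ScanRecord | None,
    precursor_mz: float,
    isolation_width: float,
    match_tol: float = 0.01,
    n_isotopes: int = 3,
    chimeric_threshold_pct: float = DEFAULT_CHIMERIC_THRESHOLD_PCT,
) -> PurityResult:
    """Precursor isolation purity from the flanking MS^1 scan(s).

    Purity per MS^1 scan is the fraction of ion current inside the
    isolation window attributable to the precursor: the peak nearest the
    selected m/z (within ``match_tol``) plus its charge-1 isotope peaks at
    +k*1.00335 Th (k=1..n_isotopes, same tolerance). The final value is
    the mean over the one or two available MS^1 scans; values below
    ``chimeric_threshold_pct`` flag the spectrum as chimeric. Scale
    invariant by construction.
    """
    if before.ms_level != 1:
        raise ValueError("'before' scan must be an MS1 scan")
    values = [
        _window_purity(scan, precursor_mz, isolation_width, match_tol, n_isotopes)
        for scan in (before, after)
        if scan is not None
    ]
    purity = sum(values) / len(values)
    return PurityResult(
        purity_pct=purity,
        chimeric_flag=purity < chimeric_threshold_pct,
        ms1_scans_used=len(values),
    )


def min_signal_filter(peaks: Sequence[tuple[float, float]], min_signals: int = DEFAULT_MIN_SIGNALS) -> bool:
    """True iff the (already noise-filtered) spectrum keeps >= min_signals peaks."""
    return len(peaks) >= min_signals
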