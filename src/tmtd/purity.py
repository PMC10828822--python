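"""Isolation-window purity and signal metrics.

The precursor purity fraction (PPF) measures, for one PSM, the fraction of
MS1 signal in the isolation window attributable to the targeted precursor
ion and its +/-1 isotopes, retention-time-weighted across the two bordering
MS1 scans.  TIW is the weighted total isolation-window intensity (the PPF
denominator), PIC the MS2 total ion current minus reporter signal, and OIL
the ground-truth observed interference level available in designs with
spike-free channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .errors import MetricError
from .io import Ms1Snapshot, PsmRecord
from .layout import ChannelLayout

#: m/z spacing of one isotope at charge 1 (mass of a neutron, Da).
ISOTOPE_SPACING = 1.00335484

PRECURSOR_TOL = 0.0025
ISOTOPE_TOL = 0.00125


@dataclass
class WindowPeak:
    mz: float
    weighted_intensity: float
    is_precursor: bool
    noise: float | None = None


@dataclass
class ScanExtract:
    """One bordering scan's contribution to the isolation-window extract."""

    side: int  # -1 preceding, +1 following
    scan_number: int
    d: float  # |t_i - t_MS2|, minutes
    weight: float
    peaks: list[WindowPeak]
    precursor_imputed: bool = False

    @property
    def k(self) -> int:
        return len(self.peaks)


@dataclass
class IsolationWindowExtract:
    psm_id: tuple[str, int]
    scans: list[ScanExtract] = field(default_factory=list)
    preceding_window_noise: list[float] = field(default_factory=list)
    #: the MS1 scan used as the preceding scan (noise fallback source)
    preceding_scan: Ms1Snapshot | None = None

    @property
    def used_scans(self) -> list[ScanExtract]:
        return self.scans


def _find_precursor(peaks, mz: float, tol: float = PRECURSOR_TOL):
    """Most intense peak within +/- tol of mz, or None."""
    best = None
    for p in peaks:
        if abs(p.mz - mz) <= tol and (best is None or p.intensity > best.intensity):
            best = p
    return best


def extract_isolation_window(
    psm: PsmRecord,
    scans: Sequence[Ms1Snapshot],
    precursor_tol: float = PRECURSOR_TOL,
    isotope_tol: float = ISOTOPE_TOL,
) -> IsolationWindowExtract:
    """Extract weighted isolation-window peaks from the bordering MS1 scans.

    Branch logic:

    * the precursor is searched in the preceding MS1 scan at the declared
      m/z (+/- ``precursor_tol``); failing that, the second-last MS1 scan
      substitutes as the preceding scan provided the precursor is found
      there (its retention time is used for the weight); failing that too,
      the precursor is imputed at the declared m/z with the minimum observed
      peak intensity of the preceding scan;
    * the following scan is skipped when its window is empty, and also when
      the precursor was found in neither bordering scan; when its window is
      non-empty but lacks the precursor (while the preceding side found
      one), the precursor is imputed there from that scan's minimum peak
      intensity;
    * +/-1 isotope peaks are precursor-flagged at spacing 1.00335484/z
      within ``isotope_tol``;
    * weights are 1 - d_i / sum(d_i) over the used scans, and 1 when a
      single scan is used.
    """
    if psm.isolation_width <= 0:
        raise MetricError(f"PSM {psm.ms2_scan}: isolation width must be positive")
    half = psm.isolation_width / 2.0
    lo, hi = psm.precursor_mz - half, psm.precursor_mz + half

    preceding_idx = None
    following_idx = None
    for i, s in enumerate(scans):
        if s.scan_number < psm.ms2_scan:
            preceding_idx = i
        elif s.scan_number > psm.ms2_scan and following_idx is None:
            following_idx = i
            break
    if preceding_idx is None:
        raise MetricError(
            f"PSM {psm.ms2_scan} in {psm.raw_file}: no preceding MS1 scan; unquantifiable"
        )

    preceding = scans[preceding_idx]
    pre_window = preceding.window(lo, hi)
    pre_hit = _find_precursor(pre_window, psm.precursor_mz, precursor_tol)
    precursor_found = pre_hit is not None
    pre_imputed = False
    if not precursor_found and preceding_idx >= 1:
        second_last = scans[preceding_idx - 1]
        sl_window = second_last.window(lo, hi)
        if _find_precursor(sl_window, psm.precursor_mz, precursor_tol) is not None:
            preceding = second_last
            pre_window = sl_window
            precursor_found = True
    if not precursor_found and _imputable(preceding):
        pre_imputed = True

    following = scans[following_idx] if following_idx is not None else None
    fol_window = following.window(lo, hi) if following is not None else []
    fol_hit = (
        _find_precursor(fol_window, psm.precursor_mz, precursor_tol)
        if fol_window
        else None
    )
    precursor_anywhere = precursor_found or fol_hit is not None

    use_following = bool(fol_window) and precursor_anywhere

    entries: list[tuple[int, Ms1Snapshot, list, bool]] = [
        (-1, preceding, pre_window, pre_imputed and not precursor_found)
    ]
    if use_following and following is not None:
        entries.append((+1, following, fol_window, fol_hit is None))

    ds = [abs(s.retention_time - psm.retention_time) for _, s, _, _ in entries]
    total_d = sum(ds)
    if len(entries) == 1 or total_d == 0:
        weights = [1.0] * len(entries)
    else:
        weights = [1.0 - d / total_d for d in ds]

    extract = IsolationWindowExtract(psm_id=(psm.raw_file, psm.ms2_scan))
    for (side, scan, window, impute), d, w in zip(entries, ds, weights):
        peaks = [
            WindowPeak(
                mz=p.mz,
                weighted_intensity=w * p.intensity,
                is_precursor=_flag_precursor_tols(
                    p.mz, psm.precursor_mz, psm.charge, precursor_tol, isotope_tol
                ),
                noise=p.noise,
            )
            for p in window
        ]
        if impute:
            imputed_intensity = min(p.intensity for p in scan.peaks)
            peaks.append(
                WindowPeak(
                    mz=psm.precursor_mz,
                    weighted_intensity=w * imputed_intensity,
                    is_precursor=True,
                    noise=None,
                )
            )
        extract.scans.append(
            ScanExtract(
                side=side,
                scan_number=scan.scan_number,
                d=d,
                weight=w,
                peaks=peaks,
                precursor_imputed=impute,
            )
        )
    extract.preceding_window_noise = [
        p.noise for p in pre_window if p.noise is not None
    ]
    extract.preceding_scan = preceding
    return extract


def _imputable(scan: Ms1Snapshot) -> bool:
    if not scan.peaks:
        raise MetricError(
            f"MS1 scan {scan.scan_number} has no peaks to impute the precursor from"
        )
    return True


def _flag_precursor_tols(mz, precursor_mz, charge, precursor_tol, isotope_tol) -> bool:
    if abs(mz - precursor_mz) <= precursor_tol:
        return True
    spacing = ISOTOPE_SPACING / max(charge, 1)
    return any(
        abs(mz - (precursor_mz + k * spacing)) <= isotope_tol for k in (-1, 1)
    )


def compute_ppf(extract: IsolationWindowExtract) -> float | None:
    """Precursor purity fraction: precursor-flagged share of weighted signal."""
    total = sum(p.weighted_intensity for s in extract.scans for p in s.peaks)
    if total <= 0:
        return None
    precursor = sum(
        p.weighted_intensity for s in extract.scans for p in s.peaks if p.is_precursor
    )
    return precursor / total


def compute_tiw(extract: IsolationWindowExtract) -> float:
    """Total weighted intensity in the isolation window (PPF denominator)."""
    return float(sum(p.weighted_intensity for s in extract.scans for p in s.peaks))


def compute_pic(psm: PsmRecord) -> float:
    """Total peptide ion current: MS2 TIC minus total reporter intensity.

    Missing reporter channels contribute 0; a pathological reporter sum
    above the TIC clamps to 0.
    """
    pic = psm.tic - psm.reporter_sum()
    if pic < 0:
        import warnings

        warnings.warn(
            f"PSM {psm.ms2_scan}: reporter sum exceeds TIC; PIC clamped to 0"
        )
        return 0.0
    return float(pic)


def compute_oil(
    norm_intensities: Mapping[str, float], layout: ChannelLayout
) -> float | None:
    """Observed interference level from between-sample-normalized intensities.

    Ratio of the mean over interference-only channels to the mean over the
    remaining peptide channels, capped at 1; missing values are excluded
    from each average.
    """
    num = [
        norm_intensities[c]
        for c in layout.interference_only_channels
        if norm_intensities.get(c) is not None
    ]
    den = [
        norm_intensities[c]
        for c in layout.quant_channels
        if norm_intensities.get(c) is not None
    ]
    if not den or not num:
        return None
    den_avg = sum(den) / len(den)
    if den_avg == 0:
        return None
    return min(sum(num) / len(num) / den_avg, 1.0)
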