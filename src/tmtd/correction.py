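"""Between-sample normalization and PSM-wise interference correction.

Interference adds a near-uniform reporter background across channels, which
compresses fold changes toward 1.  Correction subtracts, per PSM, the
channel-average intensity scaled by the (capped) estimated interference
level; values driven below the spectrum-wise minimum observed peak
intensity are floored there, and missing values are substituted by that
same minimum.  Applying the correction twice over-corrects — it is not
idempotent and must run exactly once.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .layout import ChannelLayout

EIL_CAP = 0.8
MIN_SHARED_PSMS = 10


@dataclass
class NormalizationResult:
    normalized: pd.DataFrame  # linear scale, NaN = missing
    factors: dict[str, float]  # linear per-channel size factors (divisors)
    flagged_channels: tuple[str, ...]


def normalize_between_samples(psm_matrix: pd.DataFrame) -> NormalizationResult:
    """Median-ratio size-factor normalization on log2 intensities.

    The reference is the per-PSM mean log2 intensity over channels
    quantified in every channel; each channel's factor is the median
    log2 deviation from that reference.  Factors are applied in log space
    and the matrix is transformed back to the linear scale.  Channels
    without overlap with the reference rows get a missing factor and are
    flagged (left unnormalized).
    """
    if psm_matrix.shape[1] < 2:
        raise ConfigurationError("need at least 2 channels to normalize")
    log2 = np.log2(psm_matrix.where(psm_matrix > 0))
    complete = log2.dropna(axis=0, how="any")
    if len(complete) < MIN_SHARED_PSMS:
        raise ConfigurationError(
            f"only {len(complete)} PSMs quantified in all channels "
            f"(need >= {MIN_SHARED_PSMS})"
        )
    reference = complete.mean(axis=1)
    log_factors = (complete.sub(reference, axis=0)).median(axis=0)
    flagged = tuple(c for c in psm_matrix.columns if not np.isfinite(log_factors[c]))
    if flagged:
        warnings.warn(f"channels without normalization overlap: {flagged}")
        log_factors = log_factors.fillna(0.0)
    normalized = np.power(2.0, log2.sub(log_factors, axis=1))
    return NormalizationResult(
        normalized=normalized,
        factors={c: float(2.0 ** log_factors[c]) for c in psm_matrix.columns},
        flagged_channels=flagged,
    )


def correct_interference(
    intensities: dict[str, float],
    eil: float,
    spectrum_min_peak: float,
    layout: ChannelLayout,
    eil_cap: float = EIL_CAP,
) -> dict[str, float] | None:
    """Interference-correct one PSM's normalized channel intensities.

    ``intensities`` holds the normalized, back-transformed (linear scale)
    values; channels missing from the map are treated as missing.  The
    channel average excludes empty channels and missing values.  Corrected
    (and missing) values below the spectrum-wise minimum observed MS2 peak
    intensity are replaced by that minimum.  Returns None when no channel
    average can be formed.
    """
    if not 0 <= eil <= 1:
        raise ConfigurationError(f"EIL must be in [0, 1], got {eil}")
    channels = layout.peptide_channels
    present = [intensities[c] for c in channels if intensities.get(c) is not None]
    if not present:
        return None
    mean_intensity = float(np.mean(present))
    subtract = mean_intensity * min(eil, eil_cap)
    out: dict[str, float] = {}
    for c in channels:
        v = intensities.get(c)
        if v is None:
            out[c] = spectrum_min_peak
        else:
            out[c] = max(v - subtract, spectrum_min_peak)
    return out


def correct_interference_table(
    normalized: pd.DataFrame,
    eil: pd.Series,
    spectrum_min_peak: pd.Series,
    layout: ChannelLayout,
    eil_cap: float = EIL_CAP,
) -> pd.DataFrame:
    """Vectorized :func:`correct_interference` over a PSM x channel table.

    Rows with a missing EIL or no quantified channel are dropped (counted
    in a warning).  Columns are the layout's peptide channels.
    """
    cols = [c for c in layout.peptide_channels if c in normalized.columns]
    sub = normalized[cols]
    ok = eil.notna() & sub.notna().any(axis=1) & spectrum_min_peak.notna()
    n_skipped = int((~ok).sum())
    if n_skipped:
        warnings.warn(f"skipped {n_skipped} PSMs without EIL or quantified channels")
    sub = sub.loc[ok]
    mean_intensity = sub.mean(axis=1, skipna=True)
    subtract = mean_intensity * np.minimum(eil.loc[ok], eil_cap)
    corrected = sub.sub(subtract, axis=0)
    floor = spectrum_min_peak.loc[ok]
    corrected = corrected.where(corrected.notna(), other=np.nan)
    corrected = corrected.clip(lower=floor, axis=0)
    # missing values substitute the spectrum minimum
    corrected = corrected.apply(lambda col: col.fillna(floor))
    return corrected
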