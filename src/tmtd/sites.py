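"""Feature aggregation and interference-balanced site-to-protein normalization.

PTM-site and protein reporter intensities carry different interference
levels; dividing one by the other therefore leaves a systematic,
interference-driven trend in the site-to-protein ratios.  Instead of
subtracting interference from both features (which inflates variance),
uniform interference background is *added* to the lower-interference
partner until both features share the same estimated interference level,
and only then are the per-channel ratios formed and median-scaled to 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np

from .errors import ConfigurationError
from .layout import ChannelLayout


@dataclass
class AggregatedFeature:
    feature_id: str
    level: Literal["protein", "site"]
    intensities: dict[str, float]  # channel -> summed normalized intensity
    eil: float | None
    n_psms: int


def aggregate(
    psm_intensities: Sequence[Mapping[str, float]],
    psm_eils: Sequence[float | None],
    grouping: Sequence[str],
    level: Literal["protein", "site"],
    ms3_flags: Sequence[bool] | None = None,
) -> list[AggregatedFeature]:
    """Sum channel intensities and intensity-weight-average EILs per feature.

    The EIL weight of a PSM is its total reporter intensity, so PSMs that
    dominate the aggregated signal dominate the aggregated interference
    estimate.  Features quantified via FAIMS-MS3 (``ms3_flags``) get EIL 0,
    MS3 quantification being essentially interference-free.
    """
    if not (len(psm_intensities) == len(psm_eils) == len(grouping)):
        raise ConfigurationError("aggregation inputs must align")
    buckets: dict[str, list[int]] = {}
    for i, fid in enumerate(grouping):
        buckets.setdefault(fid, []).append(i)
    out: list[AggregatedFeature] = []
    for fid, idx in buckets.items():
        channels: dict[str, float] = {}
        weight_sum = 0.0
        eil_sum = 0.0
        any_eil = False
        ms3 = False
        for i in idx:
            if ms3_flags is not None and ms3_flags[i]:
                ms3 = True
            w = 0.0
            for c, v in psm_intensities[i].items():
                if v is None or not np.isfinite(v):
                    continue
                channels[c] = channels.get(c, 0.0) + v
                w += v
            if psm_eils[i] is not None:
                weight_sum += w
                eil_sum += w * psm_eils[i]
                any_eil = True
        if ms3:
            eil: float | None = 0.0
        elif any_eil and weight_sum > 0:
            eil = eil_sum / weight_sum
        else:
            eil = None
            warnings.warn(f"feature {fid!r} has zero total intensity; EIL missing")
        out.append(
            AggregatedFeature(
                feature_id=fid, level=level, intensities=channels, eil=eil, n_psms=len(idx)
            )
        )
    return out


@dataclass
class SiteProteinRatio:
    site_id: str
    protein_id: str
    ratios: dict[str, float]  # channel -> r_{s,p,c}
    normalized_ratios: dict[str, float]  # channel -> r^norm (median over channels = 1)
    delta_eil: float
    delta_interference: float
    adjusted: Literal["protein", "site", "none"]


def balance_and_ratio(
    site: AggregatedFeature,
    protein: AggregatedFeature,
    layout: ChannelLayout,
) -> SiteProteinRatio | None:
    """Equalize interference levels, then form median-scaled channel ratios.

    With dEIL = EIL_site - EIL_protein > 0 the protein gets a uniform
    interference addition of mean(I_p) * (1 - EIL_p)/(1 - EIL_s) - mean(I_p)
    on every channel; with dEIL < 0 the site is adjusted symmetrically;
    the channel average runs over the layout's non-empty channels.  Pairs
    where the lower-interference feature already has EIL 1 are skipped.
    """
    if site.eil is None or protein.eil is None:
        return None
    channels = [
        c
        for c in layout.peptide_channels
        if site.intensities.get(c) is not None and protein.intensities.get(c) is not None
    ]
    if not channels:
        return None
    delta_eil = site.eil - protein.eil
    site_int = dict(site.intensities)
    prot_int = dict(protein.intensities)
    delta_interference = 0.0
    adjusted: Literal["protein", "site", "none"] = "none"
    if delta_eil > 0:
        lo, hi = protein.eil, site.eil
        if hi >= 1.0:
            warnings.warn(f"site {site.feature_id!r} has EIL 1; pair skipped")
            return None
        base = _channel_mean(prot_int, layout)
        delta_interference = base * (1.0 - lo) / (1.0 - hi) - base
        prot_int = {c: v + delta_interference for c, v in prot_int.items()}
        adjusted = "protein"
    elif delta_eil < 0:
        lo, hi = site.eil, protein.eil
        if hi >= 1.0:
            warnings.warn(f"protein {protein.feature_id!r} has EIL 1; pair skipped")
            return None
        base = _channel_mean(site_int, layout)
        delta_interference = base * (1.0 - lo) / (1.0 - hi) - base
        site_int = {c: v + delta_interference for c, v in site_int.items()}
        adjusted = "site"
    ratios = {c: site_int[c] / prot_int[c] for c in channels if prot_int[c] != 0}
    if not ratios:
        return None
    median = float(np.median(list(ratios.values())))
    if median == 0:
        return None
    return SiteProteinRatio(
        site_id=site.feature_id,
        protein_id=protein.feature_id,
        ratios=ratios,
        normalized_ratios={c: r / median for c, r in ratios.items()},
        delta_eil=delta_eil,
        delta_interference=delta_interference,
        adjusted=adjusted,
    )


def _channel_mean(intensities: Mapping[str, float], layout: ChannelLayout) -> float:
    vals = [
        intensities[c] for c in layout.peptide_channels if intensities.get(c) is not None
    ]
    if not vals:
        raise ConfigurationError("no non-empty channel intensities to average")
    return float(np.mean(vals))


def pick_protein_group(
    site_id: str,
    candidate_proteins: Sequence[AggregatedFeature],
) -> AggregatedFeature:
    """Sites matching several protein groups normalize against the group
    with the most quantified PSMs; ties break alphabetically."""
    if not candidate_proteins:
        raise ConfigurationError(f"site {site_id!r} has no candidate protein group")
    best = sorted(candidate_proteins, key=lambda p: (-p.n_psms, p.feature_id))[0]
    if len(candidate_proteins) > 1:
        warnings.warn(
            f"site {site_id!r} matches {len(candidate_proteins)} protein groups; "
            f"using {best.feature_id!r}"
        )
    return best
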