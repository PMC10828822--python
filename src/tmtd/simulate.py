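"""Synthetic two-proteome multiplex datasets with known ground-truth interference.

The generator emulates the benchmark design behind the method: a
constant-abundance background proteome in every peptide channel, a spiked
proteome varied 0 : 18 : 27 : 36 across four three-channel groups
(theoretical fold changes 1.5, 4/3 and 2), one label-only channel, and three
channels free of the spiked proteome that read out interference directly.
Reporter signal per PSM is generated from the causal model itself —
class-specific precursor yield, charge-specific yield of the visible
co-isolated ions, and a hidden-noise component proportional to the local
noise floor times the run-specific peptide density.  The hidden component
is, by construction, absent from the emitted MS1 peak lists yet present in
the reporter signal: that is the mechanism that makes isolation-window
purity under-predict the observed interference.

MS1 snapshots are emitted such that recomputing PPF, TIW and the noise
regressor from them reproduces the drawn values to floating-point accuracy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .correction import correct_interference_table, normalize_between_samples
from .density import build_density, interpolate_density_many
from .errors import ConfigurationError
from .io import Ms1Peak, Ms1Snapshot, PsmRecord
from .layout import ChannelLayout, two_proteome_layout
from .purity import compute_oil

CORE_ALPHABET = "ACDEFGHILMNPSTVWY"  # no K/R; those are placed deliberately


@dataclass(frozen=True)
class PlantedClass:
    """One planted fragmentation-efficiency class.

    ``has_r`` decides the tryptic C-terminus (R vs K); ``extra_k`` adds an
    internal (missed-cleavage) lysine, raising the TMT label count.
    """

    name: str
    beta: float
    has_r: bool
    extra_k: bool


def default_class_spec() -> tuple[PlantedClass, ...]:
    return (
        PlantedClass("Rplus", 0.14, has_r=True, extra_k=False),
        PlantedClass("Rminus", 0.06, has_r=False, extra_k=False),
    )


def four_class_spec() -> tuple[PlantedClass, ...]:
    return (
        PlantedClass("Rplus_K0", 0.28, has_r=True, extra_k=False),
        PlantedClass("Rplus_K1", 0.14, has_r=True, extra_k=True),
        PlantedClass("Rminus_K0", 0.07, has_r=False, extra_k=False),
        PlantedClass("Rminus_K1", 0.035, has_r=False, extra_k=True),
    )


@dataclass
class SimConfig:
    """Study conditions of the simulated experiment.

    The defaults reproduce the benchmark design: 16plex layout with spike
    amounts 0:18:27:36, background-to-spike mass ratio 10, multiplicative
    measurement noise with sd 0.3 on the log scale, and a two-class planted
    fragmentation-efficiency structure.  ``interference_share``, when set,
    pins the mean per-PSM interference fraction of reporter signal (split
    between visible and hidden ions); when None the interference emerges
    from the purity and noise draws.
    """

    seed: int = 0
    n_runs: int = 1
    psms_per_run: int = 5000
    layout: ChannelLayout = field(default_factory=two_proteome_layout)
    fraction_spike: float = 0.1
    background_to_spike_mass_ratio: float = 10.0
    class_spec: tuple[PlantedClass, ...] = field(default_factory=default_class_spec)
    beta_nonprecursor: dict[int, float] = field(
        default_factory=lambda: {1: 0.07, 2: 0.085, 3: 0.11}
    )
    beta_noise: float = 80.0
    noise_sd: float = 0.3  # sd of log measurement noise on total reporter signal
    channel_noise_sd: float = 0.15  # per-channel multiplicative jitter (log sd)
    interference_share: float | None = None
    hidden_fraction: float = 0.5  # hidden share of interference when share is pinned
    interference_uniformity: float = 1.0  # channel-uniform fraction of interference
    outlier_fraction: float = 0.0
    outlier_scale: float = 100.0
    charge_probs: dict[int, float] = field(
        default_factory=lambda: {2: 0.5, 3: 0.35, 4: 0.15}
    )
    tiw_log_mean: float = math.log(4e5)  # isolation-window total intensity
    tiw_log_sd: float = 0.45  # PSM-level intensity spread within a protein
    protein_log_sd: float = 0.7  # protein-level abundance spread
    ppf_beta: tuple[float, float] = (3.0, 1.5)
    #: impurity odds scale with (reference/intensity)**exponent — weak
    #: precursors sit in relatively more contaminated windows
    impurity_intensity_exponent: float = 0.5
    noise_floor: float = 5e3
    noise_floor_log_sd: float = 1.1
    ms2_transmission: float = 0.5  # PIC per unit of isolation-window intensity
    isolation_width: float = 0.7
    gradient_min: float = 120.0
    mz_range: tuple[float, float] = (400.0, 1200.0)
    n_proteins_spike: int = 80
    n_proteins_background: int = 600


@dataclass
class SimResult:
    psms: list[PsmRecord]
    snapshots: dict[str, list[Ms1Snapshot]]
    truth: pd.DataFrame
    true_beta: dict[str, float]
    config: SimConfig


def validate_config(config: SimConfig) -> dict[tuple[str, str], float]:
    """Check feasibility and return the design's theoretical fold changes."""
    if not config.class_spec:
        raise ConfigurationError("class_spec must contain at least one planted class")
    for cls in config.class_spec:
        if cls.beta <= 0:
            raise ConfigurationError(f"class {cls.name!r} has non-positive yield")
    if any(b < 0 for b in config.beta_nonprecursor.values()) or config.beta_noise < 0:
        raise ConfigurationError("interference coefficients must be non-negative")
    if not 0 < config.fraction_spike < 1:
        raise ConfigurationError("fraction_spike must be in (0, 1)")
    if config.interference_share is not None and not 0 < config.interference_share < 0.95:
        raise ConfigurationError("interference_share must be in (0, 0.95)")
    if not 0 <= config.hidden_fraction <= 1:
        raise ConfigurationError("hidden_fraction must be in [0, 1]")
    if not config.layout.groups:
        raise ConfigurationError("layout must define design groups")
    return config.layout.design_fold_changes()


def _spike_share(layout: ChannelLayout) -> np.ndarray:
    """Per peptide channel, the spiked proteome's precursor share."""
    amounts = np.array(
        [
            (layout.groups[g].spike_amount if (g := layout.group_of(c)) else 0.0)
            for c in layout.peptide_channels
        ]
    )
    total = amounts.sum()
    if total <= 0:
        raise ConfigurationError("spiked proteome absent from every channel")
    return amounts / total


def _interference_share_vector(config: SimConfig) -> np.ndarray:
    layout = config.layout
    k = len(layout.peptide_channels)
    uniform = np.full(k, 1.0 / k)
    u = config.interference_uniformity
    if u >= 1.0:
        return uniform
    r = config.background_to_spike_mass_ratio
    loading = r * uniform + 1.0 * _spike_share(layout)
    loading = loading / loading.sum()
    return u * uniform + (1.0 - u) * loading


def _make_sequence(rng: np.random.Generator, cls: PlantedClass) -> str:
    length = int(rng.integers(6, 15))
    core = "".join(rng.choice(list(CORE_ALPHABET), size=length))
    if cls.extra_k:
        pos = int(rng.integers(0, length + 1))
        core = core[:pos] + "K" + core[pos:]
    return core + ("R" if cls.has_r else "K")


def simulate_dataset(config: SimConfig) -> SimResult:
    """Generate PSM table, MS1 snapshots and ground-truth table.

    The same seed always yields bit-identical output.
    """
    validate_config(config)
    rng = np.random.default_rng(config.seed)
    layout = config.layout
    pep_channels = list(layout.peptide_channels)
    spike_share = _spike_share(layout)
    bg_share = np.full(len(pep_channels), 1.0 / len(pep_channels))
    int_share = _interference_share_vector(config)
    charges = np.array(sorted(config.charge_probs))
    charge_p = np.array([config.charge_probs[c] for c in charges], dtype=float)
    charge_p = charge_p / charge_p.sum()
    spike_intensity_scale = (
        (1.0 / config.background_to_spike_mass_ratio)
        * (1.0 - config.fraction_spike)
        / config.fraction_spike
    )

    records: list[PsmRecord] = []
    snapshots: dict[str, list[Ms1Snapshot]] = {}
    truth_rows: list[dict] = []

    for run in range(config.n_runs):
        raw_file = f"run{run + 1}"
        n = config.psms_per_run
        is_spike = rng.random(n) < config.fraction_spike
        class_idx = rng.integers(0, len(config.class_spec), size=n)
        charge = rng.choice(charges, size=n, p=charge_p)
        mz = config.mz_range[0] + (config.mz_range[1] - config.mz_range[0]) * rng.beta(
            1.6, 2.4, size=n
        )
        rt = config.gradient_min * rng.beta(2.5, 2.5, size=n)
        d_pre = rng.uniform(0.01, 0.05, size=n)  # minutes to preceding MS1 scan
        d_fol = rng.uniform(0.01, 0.05, size=n)
        protein = np.where(
            is_spike,
            rng.integers(0, config.n_proteins_spike, size=n),
            rng.integers(0, config.n_proteins_background, size=n),
        )
        # protein-persistent abundance effect plus PSM-level spread
        spike_effect = rng.normal(0.0, config.protein_log_sd, size=config.n_proteins_spike)
        bg_effect = rng.normal(0.0, config.protein_log_sd, size=config.n_proteins_background)
        protein_effect = np.empty(n)
        protein_effect[is_spike] = spike_effect[protein[is_spike]]
        protein_effect[~is_spike] = bg_effect[protein[~is_spike]]
        tiw = np.exp(
            config.tiw_log_mean
            + protein_effect
            + rng.normal(0.0, config.tiw_log_sd, size=n)
        )
        tiw = np.where(is_spike, tiw * spike_intensity_scale, tiw)
        sequences = [_make_sequence(rng, config.class_spec[k]) for k in class_idx]

        # measurement order follows elution
        order = np.argsort(rt, kind="stable")
        is_spike, class_idx, charge = is_spike[order], class_idx[order], charge[order]
        mz, rt, tiw = mz[order], rt[order], tiw[order]
        d_pre, d_fol, protein = d_pre[order], d_fol[order], protein[order]
        sequences = [sequences[i] for i in order]

        grid = build_density(list(zip(mz, rt)))
        dens = interpolate_density_many(grid, mz, rt)

        beta_p = np.array([config.class_spec[k].beta for k in class_idx])
        beta_c = np.array([config.beta_nonprecursor[min(int(c), 3)] for c in charge])
        tau = config.ms2_transmission
        pic = tau * tiw

        if config.interference_share is not None:
            f = np.clip(
                config.interference_share * np.exp(rng.uniform(-0.6, 0.6, size=n)),
                0.01,
                0.9,
            )
            t = f / (1.0 - f)  # target interference-to-precursor ratio
            # hidden-noise part drawn independently of the precursor scale
            # (a proportional draw would alias the noise and precursor
            # columns of the design matrix), then capped for feasibility
            ref = tau * math.exp(config.tiw_log_mean)
            nz = (
                config.hidden_fraction
                * t
                * beta_p
                * ref
                * np.exp(rng.normal(0.0, 0.9, size=n))
            )
            nz = np.minimum(nz, 0.95 * t * beta_p * pic)
            # purity solving precursor + visible + hidden = (1 + t) * precursor
            ratio_bc = beta_c / beta_p
            ppf = np.clip(
                (ratio_bc + nz / (beta_p * pic)) / (t + ratio_bc), 0.05, 0.9999
            )
            precursor_part = beta_p * pic * ppf
            noise_est = nz / max(config.beta_noise, 1e-12)
            with np.errstate(divide="ignore"):
                noise_floor = np.where(dens > 0, noise_est / np.maximum(dens, 1e-300), 0.0)
        else:
            x = np.clip(rng.beta(*config.ppf_beta, size=n), 0.05, 0.9999)
            odds = (1.0 - x) / x * (np.exp(config.tiw_log_mean) / tiw) ** (
                config.impurity_intensity_exponent
            )
            ppf = np.clip(1.0 / (1.0 + odds), 0.05, 0.9999)
            noise_floor = np.exp(
                rng.normal(math.log(config.noise_floor), config.noise_floor_log_sd, size=n)
            )
            noise_est = noise_floor * dens
            precursor_part = beta_p * pic * ppf

        s_p = tiw * ppf  # visible precursor peak intensity in the window
        visible_part = beta_c * pic * (1.0 - ppf)
        noise_part = config.beta_noise * noise_est
        y0 = precursor_part + visible_part + noise_part
        true_frac = (visible_part + noise_part) / y0

        meas = np.exp(rng.normal(0.0, config.noise_sd, size=n))
        outlier = rng.random(n) < config.outlier_fraction
        meas = meas * np.where(outlier, config.outlier_scale, 1.0)

        prec_share = np.where(is_spike[:, None], spike_share[None, :], bg_share[None, :])
        channel_mean = (
            precursor_part[:, None] * prec_share
            + (visible_part + noise_part)[:, None] * int_share[None, :]
        )
        # channel jitter is mean-1: it is summed over channels into y, so a
        # median-1 law would systematically inflate the reporter total
        jitter = np.exp(
            rng.normal(
                -config.channel_noise_sd**2 / 2.0,
                config.channel_noise_sd,
                size=channel_mean.shape,
            )
        )
        intensities = channel_mean * meas[:, None] * jitter

        scans: list[Ms1Snapshot] = []
        contaminant_offset = 0.21  # Th; inside a 0.7 Th window, off any isotope
        for i in range(n):
            ms2_scan = 3 * i + 2
            reporters = {
                c: float(v) for c, v in zip(pep_channels, intensities[i]) if v > 0
            }
            rep_sum = sum(reporters.values())
            seq = sequences[i]
            mods = [(0, "TMTpro")] + [
                (j + 1, "TMTpro") for j, aa in enumerate(seq) if aa == "K"
            ]
            spectrum_min = 0.05 * min(reporters.values()) if reporters else 1.0
            records.append(
                PsmRecord(
                    raw_file=raw_file,
                    ms2_scan=ms2_scan,
                    sequence=seq,
                    modifications=mods,
                    charge=int(charge[i]),
                    precursor_mz=float(mz[i]),
                    retention_time=float(rt[i]),
                    isolation_width=config.isolation_width,
                    tic=float(pic[i] + rep_sum),
                    reporter_intensities=reporters,
                    species_tag="spike" if is_spike[i] else "background",
                    spectrum_min_peak=float(spectrum_min),
                )
            )
            s_v = tiw[i] - s_p[i]
            peak_noise = float(noise_floor[i]) if noise_floor[i] > 0 else 1.0
            peaks = [Ms1Peak(float(mz[i]), float(s_p[i]), peak_noise)]
            if s_v > 1e-12 * s_p[i]:
                peaks.append(
                    Ms1Peak(float(mz[i] + contaminant_offset), float(s_v), peak_noise)
                )
            peaks.sort(key=lambda p: p.mz)
            scans.append(Ms1Snapshot(ms2_scan - 1, float(rt[i] - d_pre[i]), peaks))
            scans.append(Ms1Snapshot(ms2_scan + 1, float(rt[i] + d_fol[i]), list(peaks)))
            truth_rows.append(
                {
                    "raw_file": raw_file,
                    "ms2_scan": ms2_scan,
                    "species": "spike" if is_spike[i] else "background",
                    "protein_id": ("SP" if is_spike[i] else "BG") + str(int(protein[i])),
                    "true_class": config.class_spec[class_idx[i]].name,
                    "true_interference_fraction": float(true_frac[i]),
                    "true_ppf": float(ppf[i]),
                    "true_noise_estimate": float(noise_est[i]),
                    "is_outlier": bool(outlier[i]),
                }
            )
        snapshots[raw_file] = scans

    true_beta = {f"precursor:pepClass={c.name}": c.beta for c in config.class_spec}
    true_beta.update(
        {f"nonprecursor:charge={c}": b for c, b in config.beta_nonprecursor.items()}
    )
    true_beta["noiseEstimate"] = config.beta_noise
    return SimResult(
        psms=records,
        snapshots=snapshots,
        truth=pd.DataFrame(truth_rows),
        true_beta=true_beta,
        config=config,
    )


def write_sim_dir(result: SimResult, out_dir) -> None:
    """Write psm.tsv, ms1.tsv, truth.tsv and layout.json to a directory."""
    from pathlib import Path

    from .io import write_ms1_snapshots, write_psm_table

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_psm_table(result.psms, out / "psm.tsv", result.config.layout)
    write_ms1_snapshots(result.snapshots, out / "ms1.tsv")
    result.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    result.config.layout.to_json(out / "layout.json")


def no_interference_config(base: SimConfig) -> SimConfig:
    """A copy of ``base`` with both interference routes switched off."""
    return replace(
        base,
        beta_nonprecursor={c: 0.0 for c in base.beta_nonprecursor},
        beta_noise=0.0,
        interference_share=None,
    )


# ---------------------------------------------------------------------------
def simulate_class_structure(
    class_spec: Sequence[PlantedClass],
    n_per_class: int,
    within_sd: float,
    seed: int,
):
    """Planted fragmentation-efficiency responses for tree-recovery tests.

    Returns (responses, PsmRecord-like feature inputs, true labels); the
    response is the log reporter yield around each planted class's log beta.
    """
    rng = np.random.default_rng(seed)
    responses: list[float] = []
    psms: list[PsmRecord] = []
    labels: list[str] = []
    order = rng.permutation(len(class_spec) * n_per_class)
    pool = [cls for cls in class_spec for _ in range(n_per_class)]
    for i in order:
        cls = pool[i]
        seq = _make_sequence(rng, cls)
        mods = [(0, "TMTpro")] + [
            (j + 1, "TMTpro") for j, aa in enumerate(seq) if aa == "K"
        ]
        psms.append(
            PsmRecord(
                raw_file="sim",
                ms2_scan=len(psms) + 1,
                sequence=seq,
                modifications=mods,
                charge=int(rng.choice([2, 3])),
                precursor_mz=500.0,
                retention_time=10.0,
                isolation_width=0.7,
                tic=1.0,
                reporter_intensities={},
            )
        )
        responses.append(float(math.log(cls.beta) + rng.normal(0.0, within_sd)))
        labels.append(cls.name)
    return np.array(responses), psms, labels


# ---------------------------------------------------------------------------
def simulate_site_protein_pairs(
    n_pairs: int,
    layout: ChannelLayout,
    fold_change_pattern: dict[str, float],
    site_interference: float,
    protein_interference: float,
    noise_sd: float,
    seed: int,
) -> list[dict]:
    """Site/protein feature pairs sharing a true abundance pattern but
    differing in interference level.

    ``fold_change_pattern`` maps each peptide channel to its relative true
    abundance.  Each feature's channel intensity is the interference-free
    pattern mixed with a channel-uniform background at the feature's
    interference fraction, times lognormal noise.  Returns one dict per
    pair with site/protein intensity maps and the true interference levels.
    """
    rng = np.random.default_rng(seed)
    channels = [c for c in layout.peptide_channels if c in fold_change_pattern]
    pattern = np.array([fold_change_pattern[c] for c in channels], dtype=float)
    pattern = pattern / pattern.mean()
    out = []
    for i in range(n_pairs):
        base_site = float(np.exp(rng.normal(math.log(1e4), 0.5)))
        base_prot = float(np.exp(rng.normal(math.log(1e5), 0.5)))
        rows = {}
        for name, base, eil in (
            ("site", base_site, site_interference),
            ("protein", base_prot, protein_interference),
        ):
            clean = base * pattern
            mixed = (1.0 - eil) * clean + eil * np.full(len(channels), base)
            noisy = mixed * np.exp(rng.normal(-noise_sd**2 / 2, noise_sd, len(channels)))
            rows[name] = dict(zip(channels, noisy.tolist()))
        out.append(
            {
                "pair_id": i,
                "site_intensities": rows["site"],
                "protein_intensities": rows["protein"],
                "site_eil": site_interference,
                "protein_eil": protein_interference,
            }
        )
    return out


# ---------------------------------------------------------------------------
def evaluate_ground_truth(
    metrics: pd.DataFrame, truth: pd.DataFrame, layout: ChannelLayout
) -> dict:
    """Ground-truth report: OIL correlations and design fold-change recovery.

    ``metrics`` is the pipeline's PSM table with ppf, eil and reporter
    columns.  Computes, on spiked-proteome PSMs, the Pearson correlations
    of observed interference (OIL) with the model's EIL and with the
    isolation-window impurity 1-PPF — at PSM level and aggregated to
    protein level — plus, per design group pair, the median log2 fold
    change before and after EIL-based interference correction next to the
    design value.
    """
    df = metrics.merge(truth, on=["raw_file", "ms2_scan"], how="inner", validate="1:1")
    rep_cols = {c: f"reporter_{c}" for c in layout.peptide_channels}
    matrix = df[[col for col in rep_cols.values() if col in df.columns]].copy()
    matrix.columns = [c for c in rep_cols if rep_cols[c] in df.columns]
    norm = normalize_between_samples(matrix).normalized

    spike = df["species"] == "spike"
    num = norm[[c for c in layout.interference_only_channels if c in norm.columns]]
    den = norm[[c for c in layout.quant_channels if c in norm.columns]]
    oil = (num.mean(axis=1, skipna=True) / den.mean(axis=1, skipna=True)).clip(upper=1.0)
    df = df.assign(oil=oil.to_numpy())

    def corr(a, b, mask):
        ok = mask & np.isfinite(a) & np.isfinite(b)
        if ok.sum() < 3:
            return float("nan")
        return float(np.corrcoef(a[ok], b[ok])[0, 1])

    impurity = 1.0 - df["ppf"].to_numpy(dtype=float)
    eil = df["eil"].to_numpy(dtype=float)
    report: dict = {
        "psm": {
            "r_oil_eil": corr(df["oil"].to_numpy(), eil, spike.to_numpy()),
            "r_oil_impurity": corr(df["oil"].to_numpy(), impurity, spike.to_numpy()),
            "n": int(spike.sum()),
        }
    }

    # protein-level aggregation: intensities by summation, EIL/PPF by
    # intensity-weighted average, OIL recomputed from the summed intensities
    sdf = df[spike].copy()
    sdf["weight"] = norm[spike.to_numpy()].sum(axis=1).to_numpy()
    rows = []
    for pid, grp in sdf.groupby("protein_id"):
        idx = grp.index
        sums = norm.loc[idx].sum(axis=0, skipna=True)
        agg_oil = compute_oil(
            {c: (float(v) if np.isfinite(v) else None) for c, v in sums.items()}, layout
        )
        w = grp["weight"].to_numpy()
        if w.sum() <= 0 or agg_oil is None:
            continue
        rows.append(
            {
                "protein": pid,
                "oil": agg_oil,
                "eil": float(np.average(grp["eil"], weights=w)),
                "impurity": float(np.average(1 - grp["ppf"], weights=w)),
            }
        )
    pdf = pd.DataFrame(rows)
    report["protein"] = {
        "r_oil_eil": corr(pdf["oil"].to_numpy(), pdf["eil"].to_numpy(), np.ones(len(pdf), bool)),
        "r_oil_impurity": corr(
            pdf["oil"].to_numpy(), pdf["impurity"].to_numpy(), np.ones(len(pdf), bool)
        ),
        "n": len(pdf),
    }

    corrected = correct_interference_table(
        norm, df["eil"], df["spectrum_min_peak"].astype(float), layout
    )
    spike_idx = df.index[spike]

    def median_log2(mat: pd.DataFrame, hi_ch, lo_ch) -> float:
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.log2(mat[hi_ch].mean(axis=1, skipna=True) / mat[lo_ch].mean(axis=1, skipna=True))
        return float(np.nanmedian(r.replace([np.inf, -np.inf], np.nan)))

    def protein_sums(mat: pd.DataFrame) -> pd.DataFrame:
        sub = mat.loc[mat.index.intersection(spike_idx)]
        return sub.groupby(df.loc[sub.index, "protein_id"]).sum(min_count=1)

    fold_changes = {}
    for (hi, lo), design in layout.design_fold_changes().items():
        hi_ch = list(layout.groups[hi].channels)
        lo_ch = list(layout.groups[lo].channels)
        fold_changes[f"{hi}_vs_{lo}"] = {
            "design_log2": float(np.log2(design)),
            "uncorrected_log2": median_log2(protein_sums(norm), hi_ch, lo_ch),
            "corrected_log2": median_log2(protein_sums(corrected), hi_ch, lo_ch),
            "uncorrected_psm_log2": median_log2(
                norm.loc[norm.index.intersection(spike_idx)], hi_ch, lo_ch
            ),
            "corrected_psm_log2": median_log2(
                corrected.loc[corrected.index.intersection(spike_idx)], hi_ch, lo_ch
            ),
        }
    report["fold_changes"] = fold_changes
    return report
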