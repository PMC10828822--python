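"""End-to-end pipeline: metrics -> density -> classes -> fit -> EIL -> correction.

Every stage is a plain function over records/frames and is independently
invocable from the CLI with identical results; :func:`run_pipeline` chains
them and writes a machine-readable manifest.  All analysis stages are
deterministic — randomness exists only in the simulator.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .classes import (
    MIN_GAIN,
    MIN_LEAF,
    ClassTree,
    assign_class,
    featurize,
    fit_class_tree,
    fragmentation_response,
)
from .correction import EIL_CAP, correct_interference_table, normalize_between_samples
from .density import (
    DensityGrid,
    build_density,
    compute_noise_estimate,
    unique_feature_coordinates,
)
from .errors import ConfigurationError, MetricError
from .io import (
    Ms1Snapshot,
    PsmRecord,
    format_modifications,
    read_ms1_snapshots,
    read_psm_table,
)
from .layout import ChannelLayout
from .model import FitResult, build_design, compute_eil, fit_robust
from .purity import (
    compute_oil,
    compute_pic,
    compute_ppf,
    compute_tiw,
    extract_isolation_window,
)

log = logging.getLogger("tmtd")


# ---------------------------------------------------------------------------
def _bordering_slice(
    scans: Sequence[Ms1Snapshot], scan_numbers: np.ndarray, ms2_scan: int
) -> list[Ms1Snapshot]:
    """The (second-last, preceding, following) MS1 scans around an MS2 scan."""
    pos = int(np.searchsorted(scan_numbers, ms2_scan))
    lo = max(pos - 2, 0)
    hi = min(pos + 1, len(scans))
    return list(scans[lo:hi])


def compute_purity_metrics(
    records: Sequence[PsmRecord], snapshots: dict[str, list[Ms1Snapshot]]
) -> tuple[int, dict[tuple[str, int], object]]:
    """Annotate records with PPF, TIW, PIC in place.

    Returns (failure count, isolation-window extracts keyed by PSM id) —
    the extracts are reused by the noise stage.
    """
    failures = 0
    numbers = {rf: np.array([s.scan_number for s in scans]) for rf, scans in snapshots.items()}
    extracts: dict[tuple[str, int], object] = {}
    for r in records:
        scans = snapshots.get(r.raw_file)
        if scans is None:
            raise ConfigurationError(f"no MS1 snapshots for raw file {r.raw_file!r}")
        try:
            extract = extract_isolation_window(
                r, _bordering_slice(scans, numbers[r.raw_file], r.ms2_scan)
            )
        except MetricError:
            failures += 1
            continue
        r.metrics.ppf = compute_ppf(extract)
        r.metrics.tiw = compute_tiw(extract)
        r.metrics.pic = compute_pic(r)
        extracts[(r.raw_file, r.ms2_scan)] = extract
    return failures, extracts


def compute_noise_estimates(
    records: Sequence[PsmRecord],
    snapshots: dict[str, list[Ms1Snapshot]],
    extracts: dict[tuple[str, int], object] | None = None,
    grids: dict[str, DensityGrid] | None = None,
) -> dict[str, DensityGrid]:
    """Build per-run density grids and annotate the noise regressor in place."""
    if grids is None:
        grids = {}
        for raw_file in sorted({r.raw_file for r in records}):
            run_psms = [r for r in records if r.raw_file == raw_file]
            grids[raw_file] = build_density(unique_feature_coordinates(run_psms))
    extracts = extracts or {}
    numbers = {rf: np.array([s.scan_number for s in scans]) for rf, scans in snapshots.items()}
    for r in records:
        key = (r.raw_file, r.ms2_scan)
        extract = extracts.get(key)
        if extract is None:
            try:
                extract = extract_isolation_window(
                    r, _bordering_slice(snapshots[r.raw_file], numbers[r.raw_file], r.ms2_scan)
                )
            except MetricError:
                continue
        try:
            r.metrics.noise_estimate = compute_noise_estimate(extract, grids[r.raw_file], r)
        except MetricError:
            continue
    return grids


def assign_peptide_classes(
    records: Sequence[PsmRecord],
    min_leaf: int = MIN_LEAF,
    min_gain: float = MIN_GAIN,
) -> ClassTree:
    """Fit the empirical class tree on the fragmentation response and label
    every record in place.

    Variable modifications (non-TMT) present in more than ``min_leaf`` PSMs
    enter as additional boolean features.
    """
    mod_counts: dict[str, int] = {}
    for r in records:
        for name in {m for _, m in r.modifications if "tmt" not in m.lower()}:
            mod_counts[name] = mod_counts.get(name, 0) + 1
    mod_features = tuple(sorted(m for m, n in mod_counts.items() if n > min_leaf))
    feats = [featurize(r, mod_features) for r in records]
    pairs = []
    for r, f in zip(records, feats):
        m = r.metrics
        if m.pic is None or m.ppf is None:
            continue
        resp = fragmentation_response(r.reporter_sum(), m.pic, m.ppf)
        if resp is not None and np.isfinite(resp):
            pairs.append((resp, f))
    tree = fit_class_tree(
        [p[0] for p in pairs], [p[1] for p in pairs], min_leaf=min_leaf, min_gain=min_gain
    )
    for r, f in zip(records, feats):
        r.metrics.pep_class = assign_class(tree, f)
    return tree


def records_to_frame(records: Sequence[PsmRecord], layout: ChannelLayout) -> pd.DataFrame:
    rows = []
    for r in records:
        row: dict = {
            "raw_file": r.raw_file,
            "ms2_scan": r.ms2_scan,
            "sequence": r.sequence,
            "modifications": format_modifications(r.modifications),
            "charge": r.charge,
            "precursor_mz": r.precursor_mz,
            "retention_time_min": r.retention_time,
            "isolation_width": r.isolation_width,
            "tic": r.tic,
            "species_tag": r.species_tag,
            "compensation_voltage": (
                np.nan if r.compensation_voltage is None else float(r.compensation_voltage)
            ),
            "spectrum_min_peak": r.spectrum_min_peak,
            "ppf": r.metrics.ppf,
            "tiw": r.metrics.tiw,
            "pic": r.metrics.pic,
            "noise_estimate": r.metrics.noise_estimate,
            "pep_class": r.metrics.pep_class,
            "eil": r.metrics.eil,
            "oil": r.metrics.oil,
        }
        for c in layout.channel_names:
            row[f"reporter_{c}"] = r.reporter_intensities.get(c, np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def fit_models(
    records: Sequence[PsmRecord],
    layout: ChannelLayout,
    model: str = "general",
) -> dict[tuple, FitResult]:
    """Fit the chosen model per raw file and per compensation voltage."""
    frame = records_to_frame(records, layout)
    fits: dict[tuple, FitResult] = {}
    for (raw_file, voltage), sub in frame.groupby(
        ["raw_file", frame["compensation_voltage"].astype(float).fillna(np.inf)],
        sort=True,
    ):
        rows = build_design(sub, model=model, layout=layout)
        cv = None if voltage == np.inf else float(voltage)
        fits[(raw_file, cv)] = fit_robust(
            rows, model=model, raw_file=str(raw_file), compensation_voltage=cv
        )
    return fits


def add_eil(
    records: Sequence[PsmRecord], fits: dict[tuple, FitResult], layout: ChannelLayout
) -> int:
    """Annotate records with EIL from the general-model fits; returns count set."""
    frame = records_to_frame(records, layout)
    n_set = 0
    for (raw_file, cv), fit in fits.items():
        mask = frame["raw_file"] == raw_file
        if cv is not None:
            mask &= frame["compensation_voltage"] == cv
        sub = frame[mask]
        rows = build_design(sub, model="general", layout=layout)
        positions = np.flatnonzero(mask.to_numpy())
        for row in rows:
            rec = records[positions[row.psm_index]]
            rec.metrics.eil = compute_eil(fit, row)
            if rec.metrics.eil is not None:
                n_set += 1
    return n_set


def normalize_and_correct(
    frame: pd.DataFrame, layout: ChannelLayout, eil_cap: float = EIL_CAP
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, float]]:
    """Between-sample normalization, OIL annotation, interference correction.

    Returns (normalized matrix with oil column, corrected matrix, factors).
    """
    cols = {c: f"reporter_{c}" for c in layout.peptide_channels}
    matrix = frame[[v for v in cols.values() if v in frame.columns]].copy()
    matrix.columns = [c for c in cols if cols[c] in frame.columns]
    result = normalize_between_samples(matrix)
    norm = result.normalized
    if layout.interference_only_channels:
        oil = [
            compute_oil(
                {c: (float(v) if np.isfinite(v) else None) for c, v in row.items()}, layout
            )
            for _, row in norm.iterrows()
        ]
        norm = norm.assign(oil=[np.nan if v is None else v for v in oil])
    corrected = correct_interference_table(
        norm[[c for c in matrix.columns]],
        frame["eil"],
        frame["spectrum_min_peak"].astype(float),
        layout,
        eil_cap=eil_cap,
    )
    return norm, corrected, result.factors


# ---------------------------------------------------------------------------
@dataclass
class PipelineConfig:
    psm_path: str
    ms1_path: str
    layout_path: str
    out_dir: str
    model: str = "general"
    eil_cap: float = EIL_CAP
    min_leaf: int = MIN_LEAF
    min_gain: float = MIN_GAIN
    seed: int = 0
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        import tomllib

        with open(path, "rb") as fh:
            d = tomllib.load(fh)
        known = {k: d.pop(k) for k in list(d) if k in cls.__dataclass_fields__}
        return cls(**known, extra=d) if "extra" not in known else cls(**known)

    def digest(self) -> str:
        payload = json.dumps(
            {k: v for k, v in self.__dict__.items() if k != "extra"}, sort_keys=True
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and write artifacts plus a run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config_hash": config.digest(),
        "stages": [],
    }

    def stage(name, fn):
        t0 = time.perf_counter()
        try:
            value = fn()
        except Exception as exc:
            manifest["stages"].append({"name": name, "status": "failed", "error": str(exc)})
            manifest["failed_stage"] = name
            with open(out / "manifest.json", "w") as fh:
                json.dump(manifest, fh, indent=1)
            raise
        dt = time.perf_counter() - t0
        log.info("stage %s finished in %.2fs", name, dt)
        manifest["stages"].append({"name": name, "status": "ok", "seconds": round(dt, 3)})
        return value

    layout = ChannelLayout.from_file(config.layout_path)
    records = stage("read", lambda: read_psm_table(config.psm_path, layout))
    snapshots = read_ms1_snapshots(config.ms1_path)

    _, extracts = stage("metrics", lambda: compute_purity_metrics(records, snapshots))
    stage("density", lambda: compute_noise_estimates(records, snapshots, extracts))
    tree = stage(
        "classes",
        lambda: assign_peptide_classes(records, config.min_leaf, config.min_gain),
    )
    fits = stage("fit", lambda: fit_models(records, layout, model=config.model))
    stage("eil", lambda: add_eil(records, fits, layout))
    frame = records_to_frame(records, layout)
    norm, corrected, factors = stage(
        "correct", lambda: normalize_and_correct(frame, layout, config.eil_cap)
    )

    frame.to_csv(out / "metrics.tsv", sep="\t", index=False)
    norm.to_csv(out / "normalized.tsv", sep="\t", index=False)
    corrected.to_csv(out / "corrected.tsv", sep="\t", index=False)
    with open(out / "classes.json", "w") as fh:
        json.dump(tree.to_dict(), fh, indent=1)
    with open(out / "fit.json", "w") as fh:
        json.dump([f.to_dict() for f in fits.values()], fh, indent=1)
    manifest["rows"] = {
        "psms": len(records),
        "with_eil": int(frame["eil"].notna().sum()),
        "corrected": len(corrected),
    }
    manifest["normalization_factors"] = factors
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
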