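"""PSM tables, MS1 spectral snapshots, reporter inference, impurity correction.

The PSM table is a MaxQuant-evidence-like TSV keyed by header names; the MS1
snapshot table carries centroided peaks (m/z, intensity, noise) per MS1 scan,
the role an external raw-file extractor plays for vendor data.  An optional
mzML route populates the same snapshot structure, provided the file exports
per-peak noise values.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, NumericsError
from .layout import ChannelLayout

PSM_COLUMNS = [
    "raw_file",
    "ms2_scan",
    "sequence",
    "modifications",
    "charge",
    "precursor_mz",
    "retention_time_min",
    "isolation_width",
    "tic",
]

MS1_COLUMNS = ["raw_file", "scan_number", "retention_time_min", "mz", "intensity", "noise"]


@dataclass(frozen=True)
class Ms1Peak:
    mz: float
    intensity: float
    noise: float

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError("peak m/z must be positive")
        if self.intensity < 0:
            raise ValueError("peak intensity must be non-negative")


@dataclass
class Ms1Snapshot:
    """One MS1 scan's centroided peaks, sorted by m/z."""

    scan_number: int
    retention_time: float  # minutes
    peaks: list[Ms1Peak]

    def window(self, lo: float, hi: float) -> list[Ms1Peak]:
        """Peaks inside the closed m/z interval [lo, hi]."""
        return [p for p in self.peaks if lo <= p.mz <= hi]


@dataclass
class DerivedMetrics:
    """PSM-wise metrics filled in by the pipeline stages."""

    ppf: float | None = None
    tiw: float | None = None
    pic: float | None = None
    noise_estimate: float | None = None
    pep_class: str | None = None
    eil: float | None = None
    oil: float | None = None


@dataclass
class PsmRecord:
    raw_file: str
    ms2_scan: int
    sequence: str
    modifications: list[tuple[int, str]]
    charge: int
    precursor_mz: float
    retention_time: float  # minutes, t_MS2
    isolation_width: float
    tic: float
    reporter_intensities: dict[str, float]  # missing channels absent from the map
    species_tag: str | None = None
    compensation_voltage: float | None = None
    ms3_quantified: bool = False
    spectrum_min_peak: float | None = None
    metrics: DerivedMetrics = field(default_factory=DerivedMetrics)

    def reporter_sum(self) -> float:
        return float(sum(self.reporter_intensities.values()))


# --------------------------------------------------------------------------
# modifications encoding: "pos:name" joined by ';', empty string for none
def format_modifications(mods: Sequence[tuple[int, str]]) -> str:
    return ";".join(f"{pos}:{name}" for pos, name in mods)


def parse_modifications(text: str) -> list[tuple[int, str]]:
    if not isinstance(text, str) or not text.strip():
        return []
    out = []
    for token in text.split(";"):
        pos, _, name = token.partition(":")
        if not name:
            raise ConfigurationError(f"unparseable modification token {token!r}")
        out.append((int(pos), name))
    return out


# --------------------------------------------------------------------------
def read_psm_table(path, layout: ChannelLayout) -> list[PsmRecord]:
    """Read a PSM TSV into records; unparseable reporter cells become missing."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in PSM_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(f"PSM table is missing required columns: {missing}")
    reporter_cols = {
        c: f"reporter_{c}" for c in layout.channel_names if f"reporter_{c}" in df.columns
    }
    records: list[PsmRecord] = []
    for row in df.itertuples(index=False):
        row = row._asdict()
        reporters: dict[str, float] = {}
        for channel, col in reporter_cols.items():
            cell = row[col]
            if cell is None or (isinstance(cell, float) and math.isnan(cell)):
                continue
            try:
                value = float(cell)
            except (TypeError, ValueError):
                continue  # unparseable -> missing, not zero
            if not math.isnan(value):
                reporters[channel] = value
        records.append(
            PsmRecord(
                raw_file=row["raw_file"],
                ms2_scan=int(row["ms2_scan"]),
                sequence=row["sequence"],
                modifications=parse_modifications(row["modifications"]),
                charge=int(row["charge"]),
                precursor_mz=float(row["precursor_mz"]),
                retention_time=float(row["retention_time_min"]),
                isolation_width=float(row["isolation_width"]),
                tic=float(row["tic"]),
                reporter_intensities=reporters,
                species_tag=_opt_str(row.get("species_tag")),
                compensation_voltage=_opt_float(row.get("compensation_voltage")),
                ms3_quantified=_opt_bool(row.get("ms3_quantified")),
                spectrum_min_peak=_opt_float(row.get("spectrum_min_peak")),
            )
        )
    return records


def _opt_str(x):
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return None
    return str(x) if str(x).strip() else None


def _opt_float(x):
    if x is None or (isinstance(x, str) and not x.strip()):
        return None
    v = float(x)
    return None if math.isnan(v) else v


def _opt_bool(x) -> bool:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return False
    return str(x).strip().lower() in {"1", "true", "yes"}


def write_psm_table(records: Iterable[PsmRecord], path, layout: ChannelLayout) -> None:
    """Write records back to the TSV dialect read by :func:`read_psm_table`.

    Numeric fields are emitted with `repr` round-trip precision so a
    read/write cycle is bit-identical.
    """
    rows = []
    for r in records:
        row: dict[str, object] = {
            "raw_file": r.raw_file,
            "ms2_scan": r.ms2_scan,
            "sequence": r.sequence,
            "modifications": format_modifications(r.modifications),
            "charge": r.charge,
            "precursor_mz": repr(r.precursor_mz),
            "retention_time_min": repr(r.retention_time),
            "isolation_width": repr(r.isolation_width),
            "tic": repr(r.tic),
            "species_tag": r.species_tag or "",
            "compensation_voltage": "" if r.compensation_voltage is None else repr(r.compensation_voltage),
            "ms3_quantified": "true" if r.ms3_quantified else "",
            "spectrum_min_peak": "" if r.spectrum_min_peak is None else repr(r.spectrum_min_peak),
        }
        for c in layout.channel_names:
            v = r.reporter_intensities.get(c)
            row[f"reporter_{c}"] = "" if v is None else repr(v)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------
def read_ms1_snapshots(path) -> dict[str, list[Ms1Snapshot]]:
    """Read the MS1 snapshot TSV into per-run, scan-ordered snapshot lists.

    Rows with non-positive noise are rejected with a single summary warning;
    scans present in the table but without any (valid) peak are retained
    with an empty peak list, which the purity stage's empty-window branch
    relies on.
    """
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = [c for c in MS1_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(f"MS1 table is missing required columns: {missing}")
    has_peak = df["mz"].notna()
    bad = has_peak & ~(df["noise"] > 0)
    if bad.any():
        warnings.warn(f"rejected {int(bad.sum())} MS1 peak rows with noise <= 0")
    out: dict[str, list[Ms1Snapshot]] = {}
    for raw_file, sub in df.groupby("raw_file", sort=False):
        scans = []
        for (scan, rt), peaks in sub.groupby(["scan_number", "retention_time_min"], sort=False):
            ok = peaks[peaks["mz"].notna() & (peaks["noise"] > 0)]
            plist = [
                Ms1Peak(float(m), float(i), float(n))
                for m, i, n in zip(ok["mz"], ok["intensity"], ok["noise"])
            ]
            plist.sort(key=lambda p: p.mz)
            scans.append(Ms1Snapshot(int(scan), float(rt), plist))
        scans.sort(key=lambda s: s.scan_number)
        out[str(raw_file)] = scans
    return out


def write_ms1_snapshots(snapshots: Mapping[str, list[Ms1Snapshot]], path) -> None:
    rows = []
    for raw_file, scans in snapshots.items():
        for s in scans:
            if not s.peaks:
                rows.append((raw_file, s.scan_number, repr(s.retention_time), "", "", ""))
            for p in s.peaks:
                rows.append(
                    (raw_file, s.scan_number, repr(s.retention_time), repr(p.mz), repr(p.intensity), repr(p.noise))
                )
    pd.DataFrame(rows, columns=MS1_COLUMNS).to_csv(path, sep="\t", index=False)


def _decode_binary_array(node, ns: str) -> tuple[str | None, np.ndarray]:
    """Decode one mzML binaryDataArray: (cv name, values)."""
    import base64
    import zlib

    dtype = "<f8"
    compressed = False
    name = None
    for cv in node.findall(f"{ns}cvParam"):
        acc = cv.get("accession", "")
        if acc == "MS:1000521":
            dtype = "<f4"
        elif acc == "MS:1000523":
            dtype = "<f8"
        elif acc == "MS:1000574":
            compressed = True
        elif acc not in ("MS:1000576",):  # not "no compression"
            name = cv.get("name", name) if acc.startswith("MS:100") else name
    binary = node.find(f"{ns}binary")
    raw = base64.b64decode(binary.text or "")
    if compressed:
        raw = zlib.decompress(raw)
    return name, np.frombuffer(raw, dtype=dtype).astype(float)


def read_ms1_from_mzml(path, raw_file: str | None = None) -> dict[str, list[Ms1Snapshot]]:
    """Populate MS1 snapshots from an mzML file.

    A narrow MS1-only extraction (64/32-bit float arrays, zlib or no
    compression).  Per-peak noise must be present as a binary data array
    whose CV name contains "noise" (e.g. ``sampled noise intensity array``)
    of the same length as the m/z array; mzML files lacking it are
    rejected, since the noise regressor cannot be formed without it.
    """
    from lxml import etree

    name = raw_file or str(path)
    scans: list[Ms1Snapshot] = []
    ns = "{http://psi.hupo.org/ms/mzml}"
    for _, elem in etree.iterparse(str(path), tag=(f"{ns}spectrum", "spectrum")):
        tag_ns = ns if elem.tag.startswith("{") else ""
        params = {
            cv.get("accession"): cv.get("value")
            for cv in elem.findall(f"{tag_ns}cvParam")
        }
        if params.get("MS:1000511") != "1":  # ms level
            elem.clear()
            continue
        arrays: dict[str, np.ndarray] = {}
        for node in elem.iter(f"{tag_ns}binaryDataArray" if tag_ns else "binaryDataArray"):
            arr_name, values = _decode_binary_array(node, tag_ns)
            if arr_name:
                arrays[arr_name] = values
        mzs = arrays.get("m/z array")
        ints = arrays.get("intensity array")
        noise_key = next(
            (k for k in arrays if "noise" in k and "m/z" not in k and "baseline" not in k),
            None,
        )
        if mzs is None or ints is None:
            raise ConfigurationError(f"{path}: spectrum lacks m/z or intensity array")
        if noise_key is None:
            raise ConfigurationError(
                f"{path}: MS1 spectra carry no noise array; cannot build snapshots"
            )
        noise = arrays[noise_key]
        if len(noise) != len(mzs):
            raise ConfigurationError(f"{path}: noise array length mismatch")
        rt_min = np.nan
        for scan in elem.iter(f"{tag_ns}scan" if tag_ns else "scan"):
            for cv in scan.findall(f"{tag_ns}cvParam"):
                if cv.get("accession") == "MS:1000016":
                    rt_min = float(cv.get("value"))
                    if cv.get("unitName") == "second":
                        rt_min /= 60.0
        scan_number = int(str(elem.get("id")).rsplit("=", 1)[-1])
        ok = noise > 0
        if not ok.all():
            warnings.warn(f"rejected {int((~ok).sum())} peaks with noise <= 0")
        order = np.argsort(mzs[ok], kind="stable")
        peaks = [
            Ms1Peak(float(m), float(i), float(n))
            for m, i, n in zip(mzs[ok][order], ints[ok][order], noise[ok][order])
        ]
        scans.append(Ms1Snapshot(scan_number, float(rt_min), peaks))
        elem.clear()
    scans.sort(key=lambda s: s.scan_number)
    return {name: scans}


# --------------------------------------------------------------------------
def infer_reporter_intensities(
    ms2_peaks: Sequence[tuple[float, float]],
    layout: ChannelLayout,
    tol: float = 0.002,
) -> dict[str, float]:
    """Maximum peak intensity within +/- `tol` Th of each reporter m/z.

    Windows are closed intervals; channels without any peak in the window
    are absent from the result (missing, not zero).
    """
    if tol <= 0:
        raise ConfigurationError("reporter tolerance must be positive")
    centers = sorted(layout.reporter_mz[c] for c in layout.channel_names)
    for a, b in zip(centers, centers[1:]):
        if b - a <= 2 * tol:
            raise ConfigurationError(
                f"reporter windows overlap at m/z {a:.5f}/{b:.5f} with tol={tol}"
            )
    out: dict[str, float] = {}
    for channel in layout.channel_names:
        center = layout.reporter_mz[channel]
        best = None
        for mz, intensity in ms2_peaks:
            if abs(mz - center) <= tol and (best is None or intensity > best):
                best = intensity
        if best is not None:
            out[channel] = float(best)
    return out


def correct_isotopic_impurities(
    intensities: Mapping[str, float], layout: ChannelLayout
) -> dict[str, float]:
    """Invert the label-lot impurity matrix: solve observed = M @ true.

    Missing channels are imputed as 0 for the solve and restored to missing
    afterwards; negative solutions are clamped to 0.  With no impurity
    matrix configured the input is returned unchanged.
    """
    m = layout.impurity_matrix
    if m is None:
        return dict(intensities)
    cond = np.linalg.cond(m)
    if not np.isfinite(cond) or cond > 1e12:
        raise NumericsError(f"impurity matrix is singular (condition number {cond:.3g})")
    observed = np.array(
        [intensities.get(c, 0.0) for c in layout.channel_names], dtype=float
    )
    true = np.linalg.solve(m, observed)
    true = np.maximum(true, 0.0)
    return {
        c: float(v)
        for c, v in zip(layout.channel_names, true)
        if c in intensities
    }
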