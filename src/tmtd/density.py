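"""Run-specific peptide density over (m/z, retention time) and the noise regressor.

Orbitrap raw data discards sub-threshold signal, so co-isolated low-abundance
labeled peptides can contribute reporter signal without appearing in the MS1
peak list.  Their potential magnitude is bounded by the local noise values
recorded with each centroided peak, and their local frequency is approximated
by a run-specific 2D kernel density of identified peptide features.  The
product of the two is the PSM-wise ``noiseEstimate`` regressor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .errors import MetricError, NumericsError
from .io import PsmRecord
from .purity import IsolationWindowExtract

GRID_SIZE = 200


@dataclass
class DensityGrid:
    """200 x 200 peptide density surface, normalized then square-rooted."""

    mz_axis: np.ndarray
    rt_axis: np.ndarray
    values: np.ndarray  # shape (len(mz_axis), len(rt_axis)), all > 0

    def save(self, path) -> None:
        np.savez(path, mz_axis=self.mz_axis, rt_axis=self.rt_axis, values=self.values)

    @classmethod
    def load(cls, path) -> "DensityGrid":
        with np.load(path) as d:
            return cls(d["mz_axis"].copy(), d["rt_axis"].copy(), d["values"].copy())


def _nrd_bandwidth(x: np.ndarray) -> float:
    """Normal-reference (Silverman-type) bandwidth: 1.06 min(sd, IQR/1.349) n^-1/5."""
    n = len(x)
    sd = float(np.std(x, ddof=1))
    q1, q3 = np.quantile(x, [0.25, 0.75])
    iqr = float(q3 - q1)
    spread = min(sd, iqr / 1.349) if iqr > 0 else sd
    h = 1.06 * spread * n ** (-1 / 5)
    if not h > 0:
        raise NumericsError("degenerate bandwidth: features have no spread on an axis")
    return h


def build_density(
    features: Sequence[tuple[float, float]],
    grid_size: int = GRID_SIZE,
    bandwidth: tuple[float, float] | None = None,
) -> DensityGrid:
    """Gaussian-product KDE of (m/z, rt) features on a regular grid.

    The grid spans the feature range padded by one bandwidth per axis.  The
    evaluated field is rescaled to sum to 1, zeros are replaced by the
    minimum positive value, and the square root is taken, in that order —
    the square root damps extreme density contrasts across the plane.
    """
    pts = np.asarray(features, dtype=float)
    if pts.ndim != 2 or len(pts) < 2:
        raise MetricError("need at least 2 (mz, rt) features to build a density")
    x, y = pts[:, 0], pts[:, 1]
    hx, hy = bandwidth if bandwidth is not None else (_nrd_bandwidth(x), _nrd_bandwidth(y))
    gx = np.linspace(x.min() - hx, x.max() + hx, grid_size)
    gy = np.linspace(y.min() - hy, y.max() + hy, grid_size)
    # separable kernel: D[a, b] = (1/n) sum_k phi_hx(gx[a]-x_k) phi_hy(gy[b]-y_k)
    ax = np.exp(-0.5 * ((gx[:, None] - x[None, :]) / hx) ** 2) / (hx * np.sqrt(2 * np.pi))
    ay = np.exp(-0.5 * ((gy[:, None] - y[None, :]) / hy) ** 2) / (hy * np.sqrt(2 * np.pi))
    values = ax @ ay.T / len(x)
    total = values.sum()
    if total <= 0:
        raise NumericsError("density evaluated to zero everywhere")
    values = values / total
    positive_min = values[values > 0].min()
    values[values == 0] = positive_min
    values = np.sqrt(values)
    return DensityGrid(mz_axis=gx, rt_axis=gy, values=values)


def interpolate_density(grid: DensityGrid, mz: float, rt: float) -> float:
    """Bilinear interpolation; out-of-range coordinates clamp to the border."""
    mz = float(np.clip(mz, grid.mz_axis[0], grid.mz_axis[-1]))
    rt = float(np.clip(rt, grid.rt_axis[0], grid.rt_axis[-1]))
    interp = RegularGridInterpolator(
        (grid.mz_axis, grid.rt_axis), grid.values, method="linear"
    )
    return float(interp((mz, rt)))


def interpolate_density_many(grid: DensityGrid, mz, rt) -> np.ndarray:
    """Vectorized :func:`interpolate_density` for aligned coordinate arrays."""
    mzc = np.clip(np.asarray(mz, dtype=float), grid.mz_axis[0], grid.mz_axis[-1])
    rtc = np.clip(np.asarray(rt, dtype=float), grid.rt_axis[0], grid.rt_axis[-1])
    interp = RegularGridInterpolator(
        (grid.mz_axis, grid.rt_axis), grid.values, method="linear"
    )
    return interp(np.column_stack([mzc, rtc]))


def unique_feature_coordinates(psms: Sequence[PsmRecord]) -> list[tuple[float, float]]:
    """One (mz, rt) per distinct (sequence, modifications, charge) triple.

    When a triple was measured more than once the PSM with the maximal
    reporter sum provides the coordinate.
    """
    best: dict[tuple, PsmRecord] = {}
    for p in psms:
        key = (p.sequence, tuple(sorted(p.modifications)), p.charge)
        cur = best.get(key)
        if cur is None or p.reporter_sum() > cur.reporter_sum():
            best[key] = p
    return [(p.precursor_mz, p.retention_time) for p in best.values()]


def compute_noise_estimate(
    extract: IsolationWindowExtract, grid: DensityGrid, psm: PsmRecord
) -> float:
    """Mean noise of preceding-scan window peaks times local peptide density.

    An empty isolation window falls back to the noise of the nearest peak
    in m/z within the preceding scan (noise floors are locally smooth).
    """
    noises = extract.preceding_window_noise
    if not noises:
        scan = extract.preceding_scan
        if scan is None or not scan.peaks:
            raise MetricError(
                f"PSM {psm.ms2_scan}: no peaks available for a noise estimate"
            )
        nearest = min(scan.peaks, key=lambda p: abs(p.mz - psm.precursor_mz))
        noises = [nearest.noise]
    mean_noise = float(np.mean(noises))
    return mean_noise * interpolate_density(grid, psm.precursor_mz, psm.retention_time)
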