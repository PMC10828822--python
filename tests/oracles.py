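"""Independent brute-force oracles; share no code with the package."""

from __future__ import annotations

import math


def oracle_ppf(scan_entries):
    """Naive retention-time-weighted purity.

    ``scan_entries``: list of (d, peaks) per used scan, where peaks are
    (intensity, is_precursor) tuples.  Returns (ppf, tiw).
    """
    total_d = 0.0
    for d, _ in scan_entries:
        total_d += d
    weights = []
    for d, _ in scan_entries:
        if len(scan_entries) == 1 or total_d == 0:
            weights.append(1.0)
        else:
            weights.append(1.0 - d / total_d)
    num = 0.0
    den = 0.0
    for (d, peaks), w in zip(scan_entries, weights):
        for intensity, is_precursor in peaks:
            den += w * intensity
            if is_precursor:
                num += w * intensity
    if den == 0:
        return None, 0.0
    return num / den, den


def oracle_bilinear(x_axis, y_axis, values, x, y):
    """Naive bilinear interpolation with explicit cell search and clamping."""
    x = min(max(x, x_axis[0]), x_axis[-1])
    y = min(max(y, y_axis[0]), y_axis[-1])
    i = 0
    while i < len(x_axis) - 2 and x_axis[i + 1] < x:
        i += 1
    j = 0
    while j < len(y_axis) - 2 and y_axis[j + 1] < y:
        j += 1
    x0, x1 = x_axis[i], x_axis[i + 1]
    y0, y1 = y_axis[j], y_axis[j + 1]
    tx = 0.0 if x1 == x0 else (x - x0) / (x1 - x0)
    ty = 0.0 if y1 == y0 else (y - y0) / (y1 - y0)
    v00, v01 = values[i][j], values[i][j + 1]
    v10, v11 = values[i + 1][j], values[i + 1][j + 1]
    return (
        v00 * (1 - tx) * (1 - ty)
        + v10 * tx * (1 - ty)
        + v01 * (1 - tx) * ty
        + v11 * tx * ty
    )


def oracle_reporter_max(peaks, center, tol):
    """Naive closed-window maximum; peaks are (mz, intensity) tuples."""
    best = None
    for mz, intensity in peaks:
        if center - tol <= mz <= center + tol:
            if best is None or intensity > best:
                best = intensity
    return best


def oracle_irls_bisquare(x_rows, y, c=4.685, max_iter=50, tol=1e-8):
    """Textbook IRLS M-estimation with Tukey bisquare weights and MAD scale.

    Pure-python implementation over lists; weighted least squares solved by
    normal equations with Gaussian elimination.
    """
    n = len(y)
    k = len(x_rows[0])

    def wls(weights):
        ata = [[0.0] * k for _ in range(k)]
        atb = [0.0] * k
        for row, yi, wi in zip(x_rows, y, weights):
            for a in range(k):
                atb[a] += wi * row[a] * yi
                for b in range(k):
                    ata[a][b] += wi * row[a] * row[b]
        # gaussian elimination with partial pivoting
        m = [ata[i][:] + [atb[i]] for i in range(k)]
        for col in range(k):
            piv = max(range(col, k), key=lambda r: abs(m[r][col]))
            m[col], m[piv] = m[piv], m[col]
            for r in range(k):
                if r != col and m[col][col] != 0:
                    f = m[r][col] / m[col][col]
                    for cc in range(col, k + 1):
                        m[r][cc] -= f * m[col][cc]
        return [m[i][k] / m[i][i] for i in range(k)]

    beta = wls([1.0] * n)
    for _ in range(max_iter):
        resid = [
            yi - sum(b * xv for b, xv in zip(beta, row)) for row, yi in zip(x_rows, y)
        ]
        abs_r = sorted(abs(r) for r in resid)
        mid = len(abs_r) // 2
        mad = abs_r[mid] if len(abs_r) % 2 else 0.5 * (abs_r[mid - 1] + abs_r[mid])
        scale = mad / 0.6744897501960817
        if scale == 0:
            break
        weights = []
        for r in resid:
            u = r / (scale * c)
            weights.append((1 - u * u) ** 2 if abs(u) < 1 else 0.0)
        new_beta = wls(weights)
        delta = max(abs(a - b) for a, b in zip(beta, new_beta))
        beta = new_beta
        if delta / max(scale, 1e-300) < tol:
            break
    return beta
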