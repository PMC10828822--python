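"""Per-run robust regression of reporter signal and the estimated interference level.

Two intercept-free linear models explain reporter signal per MS2 scan:

* ground-truth model (two-proteome designs only): the summed reporter
  intensity of the interference-only channels is regressed on the visible
  non-precursor isolation-window signal ``TIW * (1 - PPF)`` interacted with
  the charge category, plus the hidden-ion ``noiseEstimate`` term;
* general model (any MS2 multiplex dataset): the total reporter intensity
  is regressed on ``precursor = PIC * PPF`` interacted with the empirical
  peptide class, ``nonprecursor = PIC * (1 - PPF)`` interacted with charge,
  plus ``noiseEstimate``.

Coefficients are estimated per raw file (and per FAIMS compensation voltage
when present) by IRLS M-estimation with Tukey bisquare weights.  The
estimated interference level of a PSM is one minus the fitted precursor
share of its fitted total reporter signal, clamped to [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import scipy.linalg
import statsmodels.api as sm

from .errors import ConfigurationError, NumericsError
from .layout import ChannelLayout

NOISE_COLUMN = "noiseEstimate"
#: charge categories rarer than this merge into the nearest category
MIN_CHARGE_OBS = 25

BISQUARE_C = 4.685
MAX_ITER = 50
CONV_TOL = 1e-8


@dataclass
class DesignRow:
    psm_index: int
    y: float
    precursor_term: float
    nonprecursor_term: float
    noise_term: float
    charge_cat: int
    pep_class: str | None = None


@dataclass
class FitResult:
    raw_file: str
    model: Literal["ground_truth", "general"]
    coef: dict[str, float]
    precursor_coef_names: tuple[str, ...]
    scale: float
    converged: bool
    n_obs: int
    robust_weights: np.ndarray
    compensation_voltage: float | None = None
    dropped_columns: tuple[str, ...] = ()
    charge_merges: dict[int, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "raw_file": self.raw_file,
            "model": self.model,
            "compensation_voltage": self.compensation_voltage,
            "coef": self.coef,
            "precursor_coef_names": list(self.precursor_coef_names),
            "scale": self.scale,
            "converged": self.converged,
            "n_obs": self.n_obs,
            "dropped_columns": list(self.dropped_columns),
            "charge_merges": {str(k): v for k, v in self.charge_merges.items()},
            "robust_weights_summary": {
                "min": float(self.robust_weights.min()),
                "median": float(np.median(self.robust_weights)),
                "frac_below_half": float((self.robust_weights < 0.5).mean()),
            },
        }


def build_design(
    psms: pd.DataFrame,
    model: Literal["ground_truth", "general"],
    layout: ChannelLayout | None = None,
) -> list[DesignRow]:
    """Assemble design rows from a metrics table.

    Expects columns ``ppf``, ``pic``, ``tiw``, ``noise_estimate``,
    ``charge`` and reporter columns; the general model additionally needs
    ``pep_class``.  PSMs missing any required metric are excluded (counted
    in a warning).
    """
    if model == "ground_truth":
        if layout is None or not layout.interference_only_channels:
            raise ConfigurationError(
                "ground-truth model requires a layout with interference-only channels"
            )
        rep_cols = [f"reporter_{c}" for c in sorted(layout.interference_only_channels)]
        y = psms[rep_cols].sum(axis=1, min_count=1)
        visible = psms["tiw"] * (1.0 - psms["ppf"])
        precursor = pd.Series(0.0, index=psms.index)
    else:
        all_rep = [c for c in psms.columns if c.startswith("reporter_")]
        if layout is not None:
            all_rep = [f"reporter_{c}" for c in layout.channel_names if f"reporter_{c}" in psms.columns]
        y = psms[all_rep].sum(axis=1, min_count=1)
        visible = psms["pic"] * (1.0 - psms["ppf"])
        precursor = psms["pic"] * psms["ppf"]

    required = [y, psms["ppf"], psms["noise_estimate"], visible]
    ok = np.logical_and.reduce([np.isfinite(np.asarray(r, dtype=float)) for r in required])
    if model == "general":
        ok &= psms["pep_class"].notna().to_numpy()
    n_dropped = int((~ok).sum())
    if n_dropped:
        warnings.warn(f"excluded {n_dropped} PSMs with missing metrics from the design")

    rows: list[DesignRow] = []
    for i in np.flatnonzero(ok):
        idx = psms.index[i]
        rows.append(
            DesignRow(
                psm_index=int(i),
                y=float(y.loc[idx]),
                precursor_term=float(precursor.loc[idx]),
                nonprecursor_term=float(visible.loc[idx]),
                noise_term=float(psms["noise_estimate"].loc[idx]),
                charge_cat=min(int(psms["charge"].loc[idx]), 3),
                pep_class=(
                    str(psms["pep_class"].loc[idx]) if model == "general" else None
                ),
            )
        )
    return rows


def _merge_rare_charges(rows: Sequence[DesignRow]) -> dict[int, int]:
    counts: dict[int, int] = {}
    for r in rows:
        counts[r.charge_cat] = counts.get(r.charge_cat, 0) + 1
    merges: dict[int, int] = {}
    kept = {c for c, n in counts.items() if n >= MIN_CHARGE_OBS}
    if not kept:
        kept = {max(counts, key=counts.get)}
    for c, n in counts.items():
        if c not in kept:
            merges[c] = min(kept, key=lambda k: (abs(k - c), k))
    return merges


def _design_matrix(rows: Sequence[DesignRow], model: str):
    merges = _merge_rare_charges(rows)
    charges = sorted({merges.get(r.charge_cat, r.charge_cat) for r in rows})
    classes = sorted({r.pep_class for r in rows}) if model == "general" else []
    columns: list[str] = []
    if model == "general":
        columns += [f"precursor:pepClass={k}" for k in classes]
    columns += [f"nonprecursor:charge={c}" for c in charges]
    columns += [NOISE_COLUMN]
    X = np.zeros((len(rows), len(columns)))
    y = np.empty(len(rows))
    for i, r in enumerate(rows):
        c = merges.get(r.charge_cat, r.charge_cat)
        if model == "general":
            X[i, classes.index(r.pep_class)] = r.precursor_term
        X[i, len(classes) + charges.index(c)] = r.nonprecursor_term
        X[i, -1] = r.noise_term
        y[i] = r.y
    precursor_names = tuple(c for c in columns if c.startswith("precursor:"))
    return X, y, columns, precursor_names, merges


def fit_robust(
    rows: Sequence[DesignRow],
    model: Literal["ground_truth", "general"] = "general",
    raw_file: str = "",
    compensation_voltage: float | None = None,
    bisquare_c: float = BISQUARE_C,
    max_iter: int = MAX_ITER,
    tol: float = CONV_TOL,
) -> FitResult:
    """IRLS M-estimation with Tukey bisquare weights and MAD residual scale.

    Aliased (rank-deficient) columns are dropped with a warning; a fit that
    fails to converge within ``max_iter`` iterations is returned flagged
    with its last iterate.  Negative coefficients are retained.
    """
    X, y, columns, precursor_names, merges = _design_matrix(rows, model)
    if len(rows) <= X.shape[1]:
        raise ConfigurationError(
            f"{len(rows)} observations cannot identify {X.shape[1]} coefficients"
        )
    keep = list(range(X.shape[1]))
    rank = np.linalg.matrix_rank(X)
    dropped: list[str] = []
    if rank < X.shape[1]:
        # greedy drop of aliased columns via pivoted QR
        _, _, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
        keep = sorted(piv[:rank])
        dropped = [columns[j] for j in range(X.shape[1]) if j not in keep]
        warnings.warn(f"dropping aliased design columns: {dropped}")
        X = X[:, keep]
    used_columns = [columns[j] for j in keep]

    rlm = sm.RLM(y, X, M=sm.robust.norms.TukeyBiweight(c=bisquare_c))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = rlm.fit(
            maxiter=max_iter, tol=tol, scale_est="mad", conv="coefs", update_scale=True
        )
    converged = bool(getattr(res, "converged", True))
    if not converged:
        warnings.warn(f"{raw_file}: robust fit did not converge in {max_iter} iterations")
    coef = {name: float(b) for name, b in zip(used_columns, res.params)}
    for name in dropped:
        coef[name] = 0.0
    try:
        robust_weights = np.asarray(res.weights, dtype=float)
    except AttributeError:  # perfect fit: scale 0, no IRLS pass ran
        robust_weights = np.ones(len(rows))
    return FitResult(
        raw_file=raw_file,
        model=model,
        coef=coef,
        precursor_coef_names=tuple(n for n in precursor_names if n in coef),
        scale=float(res.scale),
        converged=converged,
        n_obs=len(rows),
        robust_weights=robust_weights,
        compensation_voltage=compensation_voltage,
        dropped_columns=tuple(dropped),
        charge_merges=merges,
    )


def _row_vectors(fit: FitResult, row: DesignRow) -> tuple[float, float]:
    """Return (fitted precursor part, fitted total) for one design row."""
    merged = fit.charge_merges.get(row.charge_cat, row.charge_cat)
    total = fit.coef.get(NOISE_COLUMN, 0.0) * row.noise_term
    charge_name = f"nonprecursor:charge={merged}"
    if charge_name not in fit.coef:
        raise ConfigurationError(f"fit has no coefficient for charge {merged}")
    total += fit.coef[charge_name] * row.nonprecursor_term
    precursor_part = 0.0
    if fit.model == "general":
        class_name = f"precursor:pepClass={row.pep_class}"
        if class_name not in fit.coef:
            raise ConfigurationError(f"fit has no coefficient for class {row.pep_class!r}")
        precursor_part = fit.coef[class_name] * row.precursor_term
        total += precursor_part
    return precursor_part, total


def compute_eil(fit: FitResult, row: DesignRow) -> float | None:
    """Estimated interference level: 1 - fitted precursor share, in [0, 1].

    Only defined for the general model; a non-positive fitted total yields
    a missing EIL.
    """
    if fit.model != "general":
        raise ConfigurationError("EIL is defined for the general model only")
    precursor_part, total = _row_vectors(fit, row)
    if total <= 0:
        return None
    return float(np.clip(1.0 - precursor_part / total, 0.0, 1.0))


def decompose_signal(fit: FitResult, rows: Sequence[DesignRow]) -> dict[str, float]:
    """Share of summed fitted signal per term family (precursor, nonprecursor, noise)."""
    if not fit.converged:
        warnings.warn("decomposing a non-converged fit")
    prec = nonprec = noise = 0.0
    for row in rows:
        merged = fit.charge_merges.get(row.charge_cat, row.charge_cat)
        nonprec += fit.coef[f"nonprecursor:charge={merged}"] * row.nonprecursor_term
        noise += fit.coef.get(NOISE_COLUMN, 0.0) * row.noise_term
        if fit.model == "general":
            prec += fit.coef[f"precursor:pepClass={row.pep_class}"] * row.precursor_term
    total = prec + nonprec + noise
    if total == 0:
        raise NumericsError("fitted total is zero; cannot decompose")
    return {
        "precursor": prec / total,
        "nonprecursor": nonprec / total,
        "noise": noise / total,
    }
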