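"""BRET saturation-curve fitting and fold-over-control AUC (FOC_AUC) scoring.

A donor (luciferase-tagged) and acceptor (fluorophore-tagged) protein
pair is titrated over acceptor:donor expression ratios. The BRET ratio
is the 535 nm / 460 nm intensity ratio; net BRET subtracts the
donor-only bleed-through. Plotting net BRET against the acceptor/donor
ratio x = FI / L460 gives a hyperbolic saturation curve for a true
interaction, modeled with the one-site binding equation

    y(x) = bret_max * x / (k_half + x)

The interaction score is the area under the fitted curve over a shared
x range relative to a negative-control pair (FOC_AUC), with an unpaired
two-tailed t-test across replicate AUCs. A pair is a PPI hit when
FOC_AUC > 1.0 and p < 0.01.
"""

from __future__ import annotations

import warnings
from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "bret_ratio",
    "net_bret",
    "titration_to_curve",
    "BindingFit",
    "fit_one_site",
    "curve_auc",
    "PPIScore",
    "score_ppi",
    "shared_x_max",
]


def bret_ratio(i535: float | np.ndarray, i460: float | np.ndarray) -> float | np.ndarray:
    """BRET ratio: intensity at 535 nm over intensity at 460 nm."""
    i460 = np.asarray(i460, dtype=float)
    if np.any(i460 <= 0):
        raise ValueError("donor channel intensity (460 nm) must be positive")
    out = np.asarray(i535, dtype=float) / i460
    return float(out) if out.ndim == 0 else out


def net_bret(
    pair_ratio: float | np.ndarray, donor_only_ratio: float | np.ndarray
) -> float | np.ndarray:
    """Bleed-through corrected BRET: pair ratio minus matched donor-only ratio.

    Negative values are retained (truncation would bias the plateau
    estimate downward) but reported with a warning.
    """
    if donor_only_ratio is None:
        raise ValueError("missing donor-only control ratio")
    out = np.asarray(pair_ratio, dtype=float) - np.asarray(donor_only_ratio, dtype=float)
    if np.any(np.asarray(out) < 0):
        warnings.warn("negative net BRET values retained for fitting", stacklevel=2)
    return float(out) if out.ndim == 0 else out


def titration_to_curve(
    plate: pd.DataFrame,
    condition: str,
    replicate: int | str | None = None,
    donor_condition: str = "donor_only",
) -> pd.DataFrame:
    """Convert plate-reader rows into (x, y) saturation-curve points.

    ``plate`` is long format with columns condition, replicate, L460,
    I535, venus_FI. x = venus_FI / L460; y = net BRET using the mean
    donor-only ratio of the matching replicate (falling back to the
    plate-wide donor-only mean when the replicate has no donor wells).
    """
    required = {"condition", "replicate", "L460", "I535", "venus_FI"}
    missing = required - set(plate.columns)
    if missing:
        raise ValueError(f"titration table lacks columns {sorted(missing)}")
    donors = plate[plate["condition"] == donor_condition]
    if donors.empty:
        raise ValueError(f"no donor-only control rows (condition={donor_condition!r})")
    sel = plate["condition"] == condition
    if replicate is not None:
        sel &= plate["replicate"] == replicate
    sub = plate[sel]
    rows = []
    for _, r in sub.iterrows():
        rep_donors = donors[donors["replicate"] == r["replicate"]]
        ref = rep_donors if not rep_donors.empty else donors
        donor_ratio = float(np.mean(bret_ratio(ref["I535"].values, ref["L460"].values)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            y = net_bret(bret_ratio(r["I535"], r["L460"]), donor_ratio)
        rows.append(
            {
                "replicate": r["replicate"],
                "x": float(r["venus_FI"]) / float(r["L460"]),
                "y": y,
            }
        )
    return pd.DataFrame(rows, columns=["replicate", "x", "y"])


@dataclass
class BindingFit:
    """One-site binding fit y = bret_max * x / (k_half + x)."""

    bret_max: float
    k_half: float
    residual_norm: float
    converged: bool
    identifiable: bool
    n_points: int

    def predict(self, x: np.ndarray | float) -> np.ndarray | float:
        return self.bret_max * np.asarray(x, dtype=float) / (self.k_half + np.asarray(x, float))


def _one_site(x: np.ndarray, bmax: float, k: float) -> np.ndarray:
    return bmax * x / (k + x)


def fit_one_site(
    x: Sequence[float] | np.ndarray,
    y: Sequence[float] | np.ndarray,
) -> BindingFit:
    """Deterministic least-squares fit of the one-site binding equation.

    Initialization: ``bret_max0 = max(y)``; ``k_half0`` = x at half of
    max(y) by linear interpolation along the x-sorted curve. Both
    parameters are bounded positive; no random restarts. The fit is
    flagged non-identifiable when the recovered half-saturation point
    lies far outside the sampled x range (the data never bend), e.g.
    for flat titrations.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or x.shape != y.shape:
        raise ValueError("x and y must be equal-length 1-D arrays")
    if np.any(x < 0):
        raise ValueError("acceptor/donor ratios must be non-negative")
    distinct = np.unique(x)
    if distinct.size < 4:
        warnings.warn("fewer than 4 distinct x values: fit may be unreliable", stacklevel=2)

    ymax = float(y.max(initial=0.0))
    if np.all(y == 0.0):
        return BindingFit(0.0, 1.0, 0.0, True, True, x.size)
    if ymax <= 0.0:
        # all-negative net BRET: no binding signal
        return BindingFit(0.0, 1.0, float(np.sqrt((y**2).sum())), True, False, x.size)

    order = np.argsort(x)
    xs, ys = x[order], y[order]
    half = ymax / 2.0
    above = np.nonzero(ys >= half)[0]
    i = int(above[0]) if above.size else len(xs) - 1
    if i == 0 or ys[i] == ys[i - 1]:
        k0 = max(xs[i], 1e-6)
    else:
        k0 = xs[i - 1] + (half - ys[i - 1]) * (xs[i] - xs[i - 1]) / (ys[i] - ys[i - 1])
        k0 = max(k0, 1e-6)

    xmax = float(x.max())
    lo, hi = 1e-12, 1e12
    res = optimize.least_squares(
        lambda p: _one_site(x, p[0], p[1]) - y,
        x0=[max(ymax, 1e-6), k0],
        bounds=([lo, lo], [hi, hi]),
        xtol=1e-15,
        ftol=1e-15,
        gtol=1e-15,
    )
    bmax, k = float(res.x[0]), float(res.x[1])
    identifiable = bool(1e-4 * max(xmax, 1e-12) < k < 1e4 * max(xmax, 1e-12))
    return BindingFit(
        bret_max=bmax,
        k_half=k,
        residual_norm=float(np.linalg.norm(res.fun)),
        converged=bool(res.success),
        identifiable=identifiable,
        n_points=int(x.size),
    )


def curve_auc(fit: BindingFit, x_max: float) -> float:
    """Closed-form area under the fitted saturation curve on [0, x_max].

    integral 0..x_max of bret_max*x/(k+x) dx
        = bret_max * (x_max - k * ln(1 + x_max / k))
    """
    if x_max <= 0:
        raise ValueError("x_max must be positive")
    if not fit.identifiable:
        raise ValueError("cannot integrate a non-identifiable fit")
    k = fit.k_half
    return fit.bret_max * (x_max - k * np.log1p(x_max / k))


@dataclass
class PPIScore:
    """FOC_AUC interaction score for one donor/acceptor pair."""

    auc_pair: float
    auc_control: float
    foc_auc: float
    p_value: float
    is_hit: bool
    x_max: float
    n_pair: int
    n_control: int


def score_ppi(
    pair_fits: Sequence[BindingFit],
    control_fits: Sequence[BindingFit],
    x_max: float,
    foc_threshold: float = 1.0,
    p_threshold: float = 0.01,
) -> PPIScore:
    """Fold-over-control AUC with an unpaired two-tailed t-test.

    ``x_max`` should be the shared integration range, conventionally the
    smaller of the two conditions' maximum observed acceptor/donor
    ratios (avoids extrapolating the control curve). Non-identifiable
    or non-converged replicate fits are excluded from scoring. With
    fewer than 2 usable replicates per condition the FOC is still
    reported but no p-value or hit call is made.
    """
    pair_aucs = [curve_auc(f, x_max) for f in pair_fits if f.identifiable and f.converged]
    ctrl_aucs = [curve_auc(f, x_max) for f in control_fits if f.identifiable and f.converged]
    if not pair_aucs or not ctrl_aucs:
        raise ValueError("need at least one identifiable fit per condition")
    mean_ctrl = float(np.mean(ctrl_aucs))
    if mean_ctrl == 0.0:
        raise ValueError("control AUC is zero: FOC undefined")
    foc = float(np.mean(pair_aucs)) / mean_ctrl
    if len(pair_aucs) >= 2 and len(ctrl_aucs) >= 2:
        _, p = stats.ttest_ind(pair_aucs, ctrl_aucs, equal_var=True)
        p = float(p)
        is_hit = foc > foc_threshold and p < p_threshold
    else:
        warnings.warn("fewer than 2 replicates per condition: no p-value or hit call",
                      stacklevel=2)
        p = np.nan
        is_hit = False
    return PPIScore(
        auc_pair=float(np.mean(pair_aucs)),
        auc_control=mean_ctrl,
        foc_auc=foc,
        p_value=p,
        is_hit=is_hit,
        x_max=x_max,
        n_pair=len(pair_aucs),
        n_control=len(ctrl_aucs),
    )


def shared_x_max(pair_points: pd.DataFrame, control_points: pd.DataFrame) -> float:
    """Shared AUC range: min of the two conditions' maximum observed x."""
    return float(min(pair_points["x"].max(), control_points["x"].max()))
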