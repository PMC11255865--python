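"""Diffusion interaction parameter (kD) from concentration-dependent DLS.

The mutual diffusion coefficient of a dilute protein solution varies
linearly with concentration, D = D0 (1 + kD * C). With C in g/mL the slope
over the intercept gives kD in mL/g. Negative kD reports weak attractive
protein-protein interactions, positive kD weak repulsion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .fileio import DLSSeries


@dataclass
class DIPFit:
    D0: float  # same unit as the input D
    kd: float  # mL/g
    ci95: dict = field(default_factory=dict)  # 'D0' and 'kd' -> (lo, hi)
    r2: float = float("nan")
    n_points: int = 0

    def __post_init__(self):
        if not math.isfinite(self.kd):
            raise ValueError("kd must be finite")

    def to_dict(self) -> dict:
        return {
            "D0": self.D0,
            "kd_ml_per_g": self.kd,
            "ci95": {k: list(v) for k, v in self.ci95.items()},
            "r2": self.r2,
            "n_points": self.n_points,
        }


def fit_dip(series: DLSSeries, average_replicates: bool = False) -> DIPFit:
    """Ordinary least squares of D on C: intercept D0, slope D0*kd.

    kd = slope/intercept in mL/g (C in g/mL). 95% CIs from the t
    distribution on the regression; the kd interval by first-order
    propagation of the (intercept, slope) covariance. All replicate points
    enter individually unless ``average_replicates``.
    """
    df = series.data
    if average_replicates:
        df = df.groupby("conc_g_ml", as_index=False)["D"].mean()
    x = df["conc_g_ml"].to_numpy(dtype=float)
    y = df["D"].to_numpy(dtype=float)
    if len(np.unique(x)) < 2:
        raise ValueError("all concentrations identical: slope undefined")
    n = len(x)
    xbar = x.mean()
    sxx = float(np.sum((x - xbar) ** 2))
    b = float(np.sum((x - xbar) * (y - y.mean())) / sxx)  # slope
    a = float(y.mean() - b * xbar)  # intercept = D0
    yhat = a + b * x
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    kd = b / a

    dof = n - 2
    if dof > 0:
        s2 = ss_res / dof
        var_b = s2 / sxx
        var_a = s2 * (1.0 / n + xbar**2 / sxx)
        cov_ab = -s2 * xbar / sxx
        tcrit = float(stats.t.ppf(0.975, dof))
        # delta method for kd = b/a
        var_kd = var_b / a**2 + (b**2 / a**4) * var_a - 2.0 * (b / a**3) * cov_ab
        ci = {
            "D0": (a - tcrit * math.sqrt(var_a), a + tcrit * math.sqrt(var_a)),
            "kd": (kd - tcrit * math.sqrt(max(var_kd, 0.0)),
                   kd + tcrit * math.sqrt(max(var_kd, 0.0))),
        }
    else:
        nan = float("nan")
        ci = {"D0": (nan, nan), "kd": (nan, nan)}
    return DIPFit(D0=a, kd=kd, ci95=ci, r2=r2, n_points=n)


def classify_interaction(fit: DIPFit) -> str:
    """'attractive' if the kd CI is entirely negative, 'repulsive' if
    entirely positive, else 'indeterminate' (including NaN intervals)."""
    lo, hi = fit.ci95.get("kd", (float("nan"), float("nan")))
    if math.isnan(lo) or math.isnan(hi):
        return "indeterminate"
    if hi < 0:
        return "attractive"
    if lo > 0:
        return "repulsive"
    return "indeterminate"
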