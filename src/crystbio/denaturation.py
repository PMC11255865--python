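"""Two-state chemical denaturation analysis (linear extrapolation model).

The unfolding free energy is assumed linear in denaturant concentration,
dG(C) = m (Cm - C), so the unfolded fraction follows

    fU(C) = 1 / (1 + exp(m (Cm - C) / RT))

and the observable (tryptophan fluorescence, raw or ratioed -- the model is
agnostic) is a population-weighted mix of two sloping baselines:

    y(C) = (aN + bN C)(1 - fU) + (aU + bU C) fU

The fit is parameterized in (Cm, m) rather than (dG, m) for conditioning;
dG = m * Cm by construction. 95% intervals come from residual-bootstrap
percentiles (seeded) or, with n_boot=0, from the t distribution on the
least-squares covariance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats

from .fileio import Isotherm, R_KCAL, T_DEFAULT

_PARAM_NAMES = ("Cm", "m", "aN", "bN", "aU", "bU")


def fraction_unfolded(C, Cm: float, m: float, T: float = T_DEFAULT):
    """Unfolded fraction at denaturant concentration C (M).

    m in kcal/mol/M, Cm in M, T in K. Strictly increasing in C with
    fU(Cm) = 1/2 exactly.
    """
    if m <= 0:
        raise ValueError(f"m must be positive, got {m}")
    if T <= 0:
        raise ValueError(f"T must be positive, got {T}")
    C = np.asarray(C, dtype=float)
    return special.expit(-(m * (Cm - C)) / (R_KCAL * T))


@dataclass
class TwoStateFit:
    """Linear-extrapolation fit result. dG (kcal/mol) is m*Cm identically."""

    Cm: float  # M
    m: float  # kcal/mol/M
    aN: float
    bN: float
    aU: float
    bU: float
    T: float = T_DEFAULT
    ci95: dict = field(default_factory=dict)  # name -> (lo, hi)
    warning: str | None = None
    n_points: int = 0

    def __post_init__(self):
        if self.m <= 0 or self.Cm <= 0:
            raise ValueError("fitted m and Cm must be positive")

    @property
    def dG(self) -> float:
        """Unfolding free energy at zero denaturant, kcal/mol."""
        return self.m * self.Cm

    @property
    def m_cal(self) -> float:
        """m-value expressed in cal/mol/M."""
        return self.m * 1e3

    def params(self) -> np.ndarray:
        return np.array([self.Cm, self.m, self.aN, self.bN, self.aU, self.bU])

    def to_dict(self) -> dict:
        return {
            "Cm_M": self.Cm,
            "m_kcal_per_mol_M": self.m,
            "m_cal_per_mol_M": self.m_cal,
            "dG_kcal_per_mol": self.dG,
            "aN": self.aN,
            "bN": self.bN,
            "aU": self.aU,
            "bU": self.bU,
            "T_K": self.T,
            "ci95": {k: list(v) for k, v in self.ci95.items()},
            "warning": self.warning,
            "n_points": self.n_points,
        }


def predict_signal(C, fit) -> np.ndarray:
    """Observable of the two-state sloping-baseline model."""
    if isinstance(fit, TwoStateFit):
        p, T = fit.params(), fit.T
    else:
        p, T = fit  # (param vector, temperature)
    Cm, m, aN, bN, aU, bU = p
    C = np.asarray(C, dtype=float)
    fU = fraction_unfolded(C, Cm, m, T)
    return (aN + bN * C) * (1.0 - fU) + (aU + bU * C) * fU


def _model_residuals(p, C, y, T):
    Cm, m, aN, bN, aU, bU = p
    fU = special.expit(-(m * (Cm - C)) / (R_KCAL * T))
    return (aN + bN * C) * (1.0 - fU) + (aU + bU * C) * fU - y


def _endpoint_baseline(C, y, low: bool):
    """Linear fit through the 3 lowest (or highest) distinct concentrations."""
    order = np.unique(C)
    chosen = order[:3] if low else order[-3:]
    mask = np.isin(C, chosen)
    if mask.sum() < 2 or len(np.unique(C[mask])) < 2:
        return float(np.mean(y[mask])), 0.0
    b, a = np.polyfit(C[mask], y[mask], 1)
    return float(a), float(b)


def _starting_points(C, y):
    aN, bN = _endpoint_baseline(C, y, low=True)
    aU, bU = _endpoint_baseline(C, y, low=False)
    # Cm guess: concentration whose mean signal is nearest mid-range
    grid = np.unique(C)
    means = np.array([y[C == c].mean() for c in grid])
    mid = 0.5 * (means[0] + means[-1])
    cm0 = float(grid[np.argmin(np.abs(means - mid))])
    cm0 = max(cm0, 0.1)
    return [np.array([cm0, m0, aN, bN, aU, bU]) for m0 in (1.0, 2.0, 4.0)]


def fit_isotherm(
    iso: Isotherm,
    T: float = T_DEFAULT,
    n_boot: int = 1000,
    seed=None,
    average_replicates: bool = False,
) -> TwoStateFit:
    """Fit the six-parameter two-state model to an isotherm.

    Multi-start bounded least squares (m-value starts at 1, 2 and 4
    kcal/mol/M; baselines from endpoint linear fits). Replicates enter
    jointly by default; ``average_replicates`` averages per concentration
    first. Residual-bootstrap percentile CIs for (Cm, m, dG) and baselines
    when ``n_boot > 0``, otherwise t-based intervals from the Jacobian.
    """
    df = iso.data
    if average_replicates:
        df = df.groupby("conc_M", as_index=False)["signal"].mean().assign(replicate=1)
    if df["conc_M"].nunique() < 8:
        raise ValueError("need at least 8 distinct denaturant concentrations to fit")
    C = df["conc_M"].to_numpy(dtype=float)
    y = df["signal"].to_numpy(dtype=float)

    lb = np.array([1e-6, 1e-6, -np.inf, -np.inf, -np.inf, -np.inf])
    ub = np.full(6, np.inf)
    starts = _starting_points(C, y)
    best, failures = None, []
    for p0 in starts:
        try:
            res = optimize.least_squares(
                _model_residuals, np.clip(p0, lb, ub), args=(C, y, T), bounds=(lb, ub)
            )
        except Exception as exc:  # pragma: no cover - defensive
            failures.append(f"start {p0.tolist()}: {exc}")
            continue
        if not res.success:
            failures.append(f"start {p0.tolist()}: {res.message}")
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError("two-state fit failed to converge from all starts:\n" + "\n".join(failures))

    p = best.x
    warning = None
    if not (C.min() <= p[0] <= C.max()):
        warning = f"fitted midpoint {p[0]:.3g} M lies outside the sampled range"

    ci95 = _confidence_intervals(best, C, y, T, n_boot, seed)
    return TwoStateFit(
        Cm=float(p[0]), m=float(p[1]), aN=float(p[2]), bN=float(p[3]),
        aU=float(p[4]), bU=float(p[5]), T=T, ci95=ci95, warning=warning,
        n_points=len(C),
    )


def _confidence_intervals(res, C, y, T, n_boot, seed):
    p = res.x
    if n_boot and n_boot > 0:
        rng = np.random.default_rng(seed)
        resid = _model_residuals(p, C, y, T)
        yhat = y - resid
        lb = np.array([1e-6, 1e-6, -np.inf, -np.inf, -np.inf, -np.inf])
        ub = np.full(6, np.inf)
        samples = []
        for _ in range(int(n_boot)):
            y_star = yhat + rng.choice(resid, size=len(resid), replace=True)
            try:
                b = optimize.least_squares(
                    _model_residuals, p, args=(C, y_star, T), bounds=(lb, ub)
                )
            except Exception:
                continue
            if b.success:
                samples.append(b.x)
        if len(samples) < max(20, n_boot // 10):
            raise RuntimeError("bootstrap refits failed too often to form intervals")
        S = np.array(samples)
        out = {}
        for i, name in enumerate(_PARAM_NAMES):
            lo, hi = np.percentile(S[:, i], [2.5, 97.5])
            out[name] = (float(lo), float(hi))
        dg = S[:, 0] * S[:, 1]
        lo, hi = np.percentile(dg, [2.5, 97.5])
        out["dG"] = (float(lo), float(hi))
        return out
    # analytic: covariance from the Jacobian at the solution
    dof = max(len(C) - len(p), 1)
    s2 = 2.0 * res.cost / dof
    J = res.jac
    cov = s2 * np.linalg.pinv(J.T @ J)
    tcrit = stats.t.ppf(0.975, dof)
    out = {}
    for i, name in enumerate(_PARAM_NAMES):
        half = tcrit * math.sqrt(max(cov[i, i], 0.0))
        out[name] = (float(p[i] - half), float(p[i] + half))
    # dG = Cm * m, delta method
    g = np.zeros(len(p))
    g[0], g[1] = p[1], p[0]
    var_dg = float(g @ cov @ g)
    half = tcrit * math.sqrt(max(var_dg, 0.0))
    dg = p[0] * p[1]
    out["dG"] = (float(dg - half), float(dg + half))
    return out


def delta_delta_g(fit_a: TwoStateFit, fit_b: TwoStateFit):
    """dG_a - dG_b (kcal/mol) with uncertainty from the quadrature of the
    two 95% CI half-widths. Returns (ddG, uncertainty); uncertainty is NaN
    when either fit lacks a dG interval."""
    if not math.isclose(fit_a.T, fit_b.T, rel_tol=1e-9):
        raise ValueError("fits were performed at different temperatures")
    ddg = fit_a.dG - fit_b.dG
    halves = []
    for fit in (fit_a, fit_b):
        ci = fit.ci95.get("dG")
        halves.append(0.5 * (ci[1] - ci[0]) if ci else float("nan"))
    return ddg, float(math.hypot(*halves))
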