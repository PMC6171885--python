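"""Fire size vs. pre-fire FMC statistics.

One fire = one sample: the zonal mean pre-fire FMC of each retained fire is
related to the area it reached. Small and large fires are compared with the
tie-corrected Kruskal-Wallis rank test, and the conditional size quantiles
are modelled with linear quantile regression over the deciles
τ = 0.1 ... 0.9, fitted exactly as a linear program minimizing the pinball
(check) loss. Goodness of fit per quantile is the Koenker-Machado pseudo-R¹:
1 − V(τ)/Ṽ(τ), the minimized loss relative to the intercept-only fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import linprog


class SingularFitError(ValueError):
    """Degenerate predictor: quantile regression slope is unidentified."""


def kruskal_wallis(groups: list[np.ndarray]) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and chi-square p-value.

    Degenerate input where every pooled value is identical returns
    (H=0, p=1): no evidence of any group difference.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("groups must be non-empty")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*arrays)
    return float(h), float(p)


def pinball_loss(y: np.ndarray, pred: np.ndarray, tau: float) -> float:
    """Sum of check-function losses ρ_τ(y - pred)."""
    resid = np.asarray(y, dtype=float) - np.asarray(pred, dtype=float)
    return float(np.sum(np.where(resid >= 0, tau * resid, (tau - 1.0) * resid)))


def fit_quantile(x: np.ndarray, y: np.ndarray, tau: float) -> tuple[float, float]:
    """(intercept, slope) minimizing the pinball loss, via an exact LP.

    Decision variables are the split-signed intercept and slope plus the
    positive/negative residual parts; HiGHS solves the program exactly.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("need at least two observations")
    if np.ptp(x) == 0:
        raise SingularFitError("predictor has zero variance")
    if not 0 < tau < 1:
        raise ValueError("tau must lie in (0, 1)")
    # variables: a+, a-, b+, b-, u_1..u_n, v_1..v_n
    c = np.concatenate(([0.0, 0.0, 0.0, 0.0], np.full(n, tau), np.full(n, 1.0 - tau)))
    a_eq = np.zeros((n, 4 + 2 * n))
    a_eq[:, 0] = 1.0
    a_eq[:, 1] = -1.0
    a_eq[:, 2] = x
    a_eq[:, 3] = -x
    a_eq[:, 4:4 + n] = np.eye(n)
    a_eq[:, 4 + n:] = -np.eye(n)
    res = linprog(c, A_eq=a_eq, b_eq=y, bounds=[(0, None)] * (4 + 2 * n),
                  method="highs")
    if not res.success:
        raise SingularFitError(f"quantile fit failed: {res.message}")
    sol = res.x
    return float(sol[0] - sol[1]), float(sol[2] - sol[3])


def _intercept_only_loss(y: np.ndarray, tau: float) -> float:
    """Pinball loss of the best constant fit (the empirical τ-quantile)."""
    q = np.quantile(np.asarray(y, dtype=float), tau, method="linear")
    return pinball_loss(y, np.full(len(y), q), tau)


@dataclass
class QuantRegResult:
    """Decile quantile-regression fits of fire size on pre-fire FMC."""

    table: pd.DataFrame  # tau, intercept, slope, slope_lo, slope_hi, p_value, pseudo_r1, loss

    def crossing_report(self, x_ref: float) -> pd.DataFrame:
        """Fitted values at a reference x per τ, flagging quantile crossings."""
        fitted = self.table["intercept"] + self.table["slope"] * x_ref
        return pd.DataFrame({
            "tau": self.table["tau"],
            "fitted_at_ref": fitted,
            "crosses_previous": fitted.diff() < 0,
        })


def quantile_regression(
    dataset: pd.DataFrame,
    taus: tuple[float, ...] = tuple(np.round(np.arange(0.1, 1.0, 0.1), 1)),
    n_bootstrap: int = 2000,
    seed: int = 0,
    x_col: str = "mean_fmc",
    y_col: str = "area_ha",
) -> QuantRegResult:
    """Fit fire size on pre-fire FMC at each requested quantile.

    Slope confidence intervals (95 %) and a two-sided p-value come from a
    seeded nonparametric bootstrap over fires; pseudo-R¹ is the
    Koenker-Machado goodness of fit.
    """
    if list(taus) != sorted(taus) or len(set(taus)) != len(taus):
        raise ValueError("quantile list must be strictly increasing")
    x = dataset[x_col].to_numpy(dtype=float)
    y = dataset[y_col].to_numpy(dtype=float)
    if x.size <= 2:
        raise ValueError("need more than two fires for a quantile fit")
    if np.ptp(x) == 0:
        raise SingularFitError("pre-fire FMC has zero variance")
    rng = np.random.default_rng(seed)
    n = x.size
    boot_idx = rng.integers(0, n, size=(n_bootstrap, n)) if n_bootstrap else None

    rows = []
    for tau in taus:
        a, b = fit_quantile(x, y, tau)
        loss = pinball_loss(y, a + b * x, tau)
        null_loss = _intercept_only_loss(y, tau)
        pseudo = 0.0 if null_loss == 0 else 1.0 - loss / null_loss
        pseudo = min(max(pseudo, 0.0), 1.0)
        lo = hi = pval = np.nan
        if n_bootstrap:
            slopes = np.empty(n_bootstrap)
            for i in range(n_bootstrap):
                idx = boot_idx[i]
                xb = x[idx]
                if np.ptp(xb) == 0:
                    slopes[i] = np.nan
                    continue
                try:
                    _, slopes[i] = fit_quantile(xb, y[idx], tau)
                except SingularFitError:
                    slopes[i] = np.nan
            slopes = slopes[~np.isnan(slopes)]
            lo, hi = np.percentile(slopes, [2.5, 97.5])
            # two-sided bootstrap p for H0: slope = 0
            frac = np.mean(slopes > 0.0)
            pval = 2.0 * min(frac, 1.0 - frac)
        rows.append((tau, a, b, lo, hi, pval, pseudo, loss))
    return QuantRegResult(table=pd.DataFrame(
        rows, columns=["tau", "intercept", "slope", "slope_lo", "slope_hi",
                       "p_value", "pseudo_r1", "loss"]))


def summarize_by_size(
    dataset: pd.DataFrame,
    value_col: str = "mean_fmc",
    class_col: str = "size_class",
) -> pd.DataFrame:
    """Per size class: n, mean, min, max, median, Q1, Q3 and IQR of mean FMC.

    Quartiles use the same linear-interpolation convention as the hazard
    thresholds.
    """
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    rows = []
    order = {"small": 0, "medium": 1, "large": 2}
    for cls, group in sorted(dataset.groupby(class_col),
                             key=lambda kv: order.get(kv[0], 99)):
        v = group[value_col].to_numpy(dtype=float)
        q1, med, q3 = np.percentile(v, [25, 50, 75], method="linear")
        rows.append((cls, len(v), v.mean(), v.min(), v.max(), med, q1, q3, q3 - q1))
    return pd.DataFrame(rows, columns=[
        "size_class", "n", "mean", "min", "max", "median", "q1", "q3", "iqr"])


def compare_small_large(dataset: pd.DataFrame,
                        value_col: str = "mean_fmc") -> tuple[float, float]:
    """Kruskal-Wallis on small vs. large fires (medium excluded by default,
    mirroring analyses where intermediate sizes are too few to test)."""
    small = dataset.loc[dataset["size_class"] == "small", value_col].to_numpy()
    large = dataset.loc[dataset["size_class"] == "large", value_col].to_numpy()
    return kruskal_wallis([small, large])


def load_fire_samples_csv(path) -> pd.DataFrame:
    """Read a fire-sample table (fire_id, area_ha, mean_fmc [, size_class])."""
    df = pd.read_csv(path)
    required = {"fire_id", "area_ha", "mean_fmc"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"fire-sample CSV missing columns: {sorted(missing)}")
    if "size_class" not in df.columns:
        from .prefire import size_class
        df["size_class"] = df["area_ha"].map(size_class)
    return df
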