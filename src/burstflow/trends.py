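"""Cross-clone trend analyses.

Log-log power-law regressions of distribution variance and of fitted burst
parameters against the distribution mean, the 'typical' distribution shape
obtained by translating and variance-rescaling all clones to a common mean,
the burst-size/burst-frequency correlation, and the two candidate modes of
integration-site control of burst size:

* Mode 1 -- the stability of the active promoter state varies across
  integration sites (kappa_r varies, transcription rate fixed), so the
  active duration tau_i = b_i / kappa_t_plus and the predicted active
  fraction scales with the clone mean.
* Mode 2 -- the active-state transcription rate varies (tau fixed), so the
  predicted active fraction mirrors the scatter of the burst frequencies.

All regressions are ordinary least squares on log10-transformed values with
standard 95% confidence intervals (statsmodels OLS).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cytometry import RfuHistogram
from .params import active_fraction

__all__ = [
    "CloneSummary",
    "PowerLawFit",
    "TrendReport",
    "summaries_frame",
    "variance_mean_regression",
    "parameter_trend",
    "burst_correlation",
    "typical_shape",
    "mode_prediction",
    "trend_report",
]

MIN_CLONES = 5


@dataclass(frozen=True)
class CloneSummary:
    """Per-clone quantities entering the cross-clone analyses."""

    clone_id: str
    mu: float                 # processed-histogram mean (RFU)
    sigma2: float             # processed-histogram variance (RFU^2)
    b: float | None = None
    kappa_a: float | None = None
    tau_max: float | None = None
    f_max: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ValueError("clone mean must be positive (inclusion rule)")


def summaries_frame(summaries) -> pd.DataFrame:
    if isinstance(summaries, pd.DataFrame):
        return summaries
    return pd.DataFrame([s.__dict__ for s in summaries])


@dataclass(frozen=True)
class PowerLawFit:
    """y = 10^beta * x^alpha fitted by OLS on log10 values."""

    alpha: float
    beta: float
    r2: float
    alpha_ci: tuple
    beta_ci: tuple
    n: int

    def predict(self, x):
        return 10.0**self.beta * np.asarray(x) ** self.alpha


def _loglog_ols(x: np.ndarray, y: np.ndarray) -> PowerLawFit:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < MIN_CLONES:
        raise ValueError(f"need >= {MIN_CLONES} clones, got {x.size}")
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("power-law regression requires positive values")
    X = sm.add_constant(np.log10(x))
    res = sm.OLS(np.log10(y), X).fit()
    ci = res.conf_int(alpha=0.05)
    return PowerLawFit(
        alpha=float(res.params[1]),
        beta=float(res.params[0]),
        r2=float(res.rsquared),
        alpha_ci=(float(ci[1, 0]), float(ci[1, 1])),
        beta_ci=(float(ci[0, 0]), float(ci[0, 1])),
        n=int(x.size),
    )


def variance_mean_regression(summaries) -> PowerLawFit:
    """Power law sigma^2 ~ mu^alpha across clones.

    alpha = 1 is Poisson-like shape variation (only a constant production
    rate varies); alpha = 2 is pure distribution scaling (all fluorescence
    values multiplied by a clone constant).
    """
    df = summaries_frame(summaries)
    return _loglog_ols(df["mu"].to_numpy(), df["sigma2"].to_numpy())


def parameter_trend(summaries, which: str) -> PowerLawFit:
    """Power-law scaling of a fitted burst parameter with the clone mean."""
    if which not in ("b", "kappa_a"):
        raise ValueError("which must be 'b' or 'kappa_a'")
    df = summaries_frame(summaries).dropna(subset=[which])
    return _loglog_ols(df["mu"].to_numpy(), df[which].to_numpy())


def scatter_statistics(summaries) -> dict:
    """sigma/mu of the log10 parameter samples (dimensionless scatter).

    Sensitive to the log base and to the sign of the mean log value; reported
    on natural-sign log10 values for comparability.
    """
    df = summaries_frame(summaries)
    out = {}
    for which in ("b", "kappa_a"):
        vals = np.log10(df[which].dropna().to_numpy())
        mean = vals.mean()
        out[which] = {
            "log10_mean": float(mean),
            "log10_sd": float(vals.std(ddof=1)),
            "sigma_over_mu": float(vals.std(ddof=1) / mean) if mean != 0 else np.inf,
        }
    return out


def burst_correlation(summaries) -> dict:
    """Correlation between log10 b and log10 kappa_a across clones.

    Returns the Pearson r, the OLS slope of log10 b on log10 kappa_a with its
    95% CI, and R^2.  Diagonals of constant mean expression follow
    mu ~ kappa_a * b in the bursting regime.
    """
    df = summaries_frame(summaries).dropna(subset=["b", "kappa_a"])
    if len(df) < MIN_CLONES:
        raise ValueError(f"need >= {MIN_CLONES} clones")
    lb = np.log10(df["b"].to_numpy())
    lk = np.log10(df["kappa_a"].to_numpy())
    X = sm.add_constant(lk)
    res = sm.OLS(lb, X).fit()
    ci = res.conf_int(alpha=0.05)
    r = float(np.corrcoef(lk, lb)[0, 1])
    return {
        "pearson_r": r,
        "slope": float(res.params[1]),
        "slope_ci": (float(ci[1, 0]), float(ci[1, 1])),
        "r2": float(res.rsquared),
        "n": int(len(df)),
    }


def typical_shape(
    histograms: list[RfuHistogram],
    alpha: float,
    target_mean: float | None = None,
) -> RfuHistogram:
    """Common distribution shape after translation and variance rescaling.

    Each (deconvolved) clone histogram is shifted to the common mean mu_0
    (median of the clone means unless given) and its fluorescence values are
    scaled about that mean by (mu_0/mu)^(alpha/2), the spread predicted by
    the variance-mean regression; the equal-weight average of the transformed
    distributions is the 'typical' expression profile.
    """
    means = np.array([h.mean for h in histograms])
    if np.any(means <= 0):
        raise ValueError("all histogram means must be positive")
    mu0 = float(np.median(means)) if target_mean is None else float(target_mean)
    edges = histograms[0].edges
    acc = np.zeros(edges.size - 1)
    for h in histograms:
        if not h.same_binning(histograms[0]):
            raise ValueError("histograms must share binning")
        scale = (mu0 / h.mean) ** (alpha / 2.0)
        x = mu0 + (h.centers - h.mean) * scale
        idx = np.clip(np.searchsorted(edges, x) - 1, 0, edges.size - 2)
        mass = np.zeros_like(acc)
        np.add.at(mass, idx[x > edges[0]], h.mass[x > edges[0]])
        if mass.sum() > 0:
            acc += mass / mass.sum()
    acc /= acc.sum()
    out = RfuHistogram(edges=edges, mass=acc, meta={"mu0": mu0, "alpha": alpha})
    return out


def mode_prediction(summaries, mode: int, fixed_value: float) -> pd.DataFrame:
    """Predicted active fraction per clone under one mode of burst-size control.

    Mode 1: fixed transcription rate ``fixed_value`` = kappa_t_plus; the
    active duration follows from the fitted burst size (tau_i = b_i /
    kappa_t_plus) and f rises roughly in proportion to the clone mean.
    Mode 2: fixed active duration ``fixed_value`` = tau; f mirrors the
    burst-frequency scatter.  Predictions exceeding the per-clone bound
    f_max are clipped and flagged.
    """
    if fixed_value <= 0:
        raise ValueError("fixed_value must be positive")
    if mode not in (1, 2):
        raise ValueError("mode must be 1 or 2")
    df = summaries_frame(summaries).dropna(subset=["b", "kappa_a"]).copy()
    if mode == 1:
        df["tau_pred"] = df["b"] / fixed_value
    else:
        df["tau_pred"] = fixed_value
    df["f_pred"] = active_fraction(df["kappa_a"].to_numpy(), df["tau_pred"].to_numpy())
    if "f_max" in df and df["f_max"].notna().any():
        bound = df["f_max"].fillna(np.inf).to_numpy()
        df["f_exceeds_bound"] = df["f_pred"] > bound
        df["f_pred_clipped"] = np.minimum(df["f_pred"], bound)
    else:
        df["f_exceeds_bound"] = False
        df["f_pred_clipped"] = df["f_pred"]
    return df


@dataclass(frozen=True)
class TrendReport:
    """All cross-clone statistics in one serializable bundle."""

    variance_mean: PowerLawFit
    b_trend: PowerLawFit | None
    kappa_a_trend: PowerLawFit | None
    correlation: dict | None
    scatter: dict | None
    n_clones: int

    def to_dict(self) -> dict:
        def pl(f):
            return None if f is None else f.__dict__
        return {
            "variance_mean": pl(self.variance_mean),
            "b_trend": pl(self.b_trend),
            "kappa_a_trend": pl(self.kappa_a_trend),
            "correlation": self.correlation,
            "scatter": self.scatter,
            "n_clones": self.n_clones,
        }


def trend_report(summaries) -> TrendReport:
    df = summaries_frame(summaries)
    have_fits = "b" in df and df["b"].notna().sum() >= MIN_CLONES
    return TrendReport(
        variance_mean=variance_mean_regression(df),
        b_trend=parameter_trend(df, "b") if have_fits else None,
        kappa_a_trend=parameter_trend(df, "kappa_a") if have_fits else None,
        correlation=burst_correlation(df) if have_fits else None,
        scatter=scatter_statistics(df) if have_fits else None,
        n_clones=int(len(df)),
    )
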