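"""Publication-style diagnostic plots (matplotlib imported lazily)."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_histograms", "plot_fit", "plot_profile", "plot_trends", "plot_active_fraction"]


def _axes(ax=None):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    return ax


def plot_histograms(hists, labels=None, ax=None):
    """Clone distributions on the log-RFU axis."""
    ax = _axes(ax)
    for k, h in enumerate(hists):
        label = labels[k] if labels else None
        ax.plot(h.centers, h.mass, lw=1.2, label=label)
    ax.set_xscale("log")
    ax.set_xlabel("fluorescence (RFU)")
    ax.set_ylabel("probability / bin")
    if labels:
        ax.legend(fontsize=8)
    return ax


def plot_fit(result, ax=None):
    """Data vs fitted model distribution for one clone."""
    ax = _axes(ax)
    data = result.model.data
    pred = result.predict()
    ax.plot(data.centers, data.mass, "k-", lw=1.5, label="data (smoothed)")
    ax.plot(pred.centers, pred.mass, "r--", lw=1.5,
            label=f"fit: b={result.b:.1f}, $\\kappa_a$={result.kappa_a:.2f}")
    ax.plot(result.model.autofluor.centers, result.model.autofluor.mass,
            color="0.6", lw=1.0, label="autofluorescence")
    ax.set_xscale("log")
    ax.set_xlabel("fluorescence (RFU)")
    ax.set_ylabel("probability / bin")
    ax.legend(fontsize=8)
    return ax


def plot_profile(profile, ax=None):
    """Dev_r versus active duration with the distinguishability cut-off."""
    ax = _axes(ax)
    y = profile.dev_r_profile if profile.dev_r_profile is not None else profile.dev_fit_profile
    ax.plot(profile.tau_grid, y, "o-", lw=1.2)
    if profile.dev_r_opt is not None:
        ax.axhline(profile.dev_r_opt + 1.0, ls="--", color="0.4", label=r"$Dev_r^{Opt}+1$")
        ax.axvline(profile.tau_max, ls=":", color="r", label=r"$\tau_{Max}$")
    ax.set_xscale("log")
    ax.set_xlabel(r"active duration $\tau$ (transcript lifetimes)")
    ax.set_ylabel(r"$Dev_r$")
    ax.legend(fontsize=8)
    return ax


def plot_trends(summaries, report, axs=None):
    """Variance-mean and burst-parameter power laws across clones."""
    import matplotlib.pyplot as plt

    from .trends import summaries_frame

    df = summaries_frame(summaries)
    if axs is None:
        _, axs = plt.subplots(1, 3, figsize=(12, 3.5))
    panels = [
        ("sigma2", report.variance_mean, r"variance $\sigma^2$ (RFU$^2$)"),
        ("b", report.b_trend, "burst size $b$"),
        ("kappa_a", report.kappa_a_trend, r"burst frequency $\kappa_a$"),
    ]
    x = df["mu"].to_numpy()
    grid = np.geomspace(x.min(), x.max(), 50)
    for ax, (col, fit, ylabel) in zip(axs, panels):
        if col not in df or df[col].isna().all():
            continue
        ax.loglog(x, df[col], "k.", ms=5)
        if fit is not None:
            ax.loglog(grid, fit.predict(grid), "r-", lw=1.2,
                      label=f"$\\alpha$={fit.alpha:.2f}, $R^2$={fit.r2:.2f}")
            ax.legend(fontsize=8)
        ax.set_xlabel(r"mean $\mu$ (RFU)")
        ax.set_ylabel(ylabel)
    return axs


def plot_active_fraction(mode1, mode2, f_max=None, ax=None):
    """Predicted active fractions under the two modes of burst-size control."""
    ax = _axes(ax)
    order = np.argsort(mode1["mu"].to_numpy())
    x = np.arange(len(order))
    if f_max is not None:
        ax.bar(x, np.asarray(f_max)[order], color="0.85", label=r"$f_{Max}$ bound")
    ax.plot(x, mode1["f_pred"].to_numpy()[order], "o", label="Mode 1 (fixed $\\kappa_t^+$)")
    ax.plot(x, mode2["f_pred"].to_numpy()[order], "s", label="Mode 2 (fixed $\\tau$)")
    ax.set_yscale("log")
    ax.set_xlabel("clone (ordered by mean)")
    ax.set_ylabel("active fraction $f$")
    ax.legend(fontsize=8)
    return ax
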