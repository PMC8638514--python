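"""Optional matplotlib figures: curve plots and agreement panels.

Imported lazily by the CLI so the core package works without matplotlib.
"""

from __future__ import annotations

import numpy as np

from .core import ClinicalMetrics, DisplacementCurve, VelocityCurve
from .evaluation import AgreementStats


def _agg_figure():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def plot_curves(
    displacement: DisplacementCurve,
    velocity: VelocityCurve | None = None,
    metrics: ClinicalMetrics | None = None,
    path=None,
):
    """Displacement (and optionally velocity) over the cycle, peaks marked."""
    plt = _agg_figure()
    n_rows = 2 if velocity is not None else 1
    fig, axes = plt.subplots(n_rows, 1, figsize=(6, 3 * n_rows), sharex=True)
    axes = np.atleast_1d(axes)
    axes[0].plot(displacement.times, displacement.values, "-o", ms=3)
    axes[0].set_ylabel("displacement (mm)")
    if metrics is not None:
        axes[0].plot(metrics.mapse_time_s, metrics.mapse_mm, "r^",
                     label=f"MAPSE {metrics.mapse_mm:.1f} mm")
        axes[0].legend(loc="upper right", fontsize=8)
    if velocity is not None:
        axes[1].plot(velocity.times, velocity.values, "-o", ms=3)
        axes[1].axhline(0.0, color="0.7", lw=0.8)
        axes[1].set_ylabel("velocity (cm/s)")
        if metrics is not None:
            for name, t, v in (
                ("s'", metrics.s_prime_time_s, metrics.s_prime_cm_s),
                ("e'", metrics.e_prime_time_s, -metrics.e_prime_cm_s),
                ("a'", metrics.a_prime_time_s, -metrics.a_prime_cm_s),
            ):
                if np.isfinite(t):
                    axes[1].annotate(name, (t, v), textcoords="offset points",
                                     xytext=(0, 6), ha="center")
    axes[-1].set_xlabel("time (s)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def agreement_panels(x, y, stats: AgreementStats, label: str = "", path=None):
    """Regression (identity line) and Bland-Altman panels for paired values."""
    plt = _agg_figure()
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    fig, (ax_reg, ax_ba) = plt.subplots(1, 2, figsize=(9, 4))

    lims = [min(x.min(), y.min()), max(x.max(), y.max())]
    ax_reg.plot(lims, lims, "k-", lw=1)
    ax_reg.plot(x, y, "o", ms=4, alpha=0.7)
    ax_reg.plot(lims, stats.intercept + stats.slope * np.asarray(lims), "b--",
                lw=1)
    ax_reg.set_xlabel(f"reference {label}")
    ax_reg.set_ylabel(f"measured {label}")
    ax_reg.set_title(f"ICC {stats.icc:.2f} "
                     f"({stats.icc_ci95[0]:.2f}-{stats.icc_ci95[1]:.2f}), "
                     f"r {stats.r:.2f}", fontsize=9)

    mean, diff = (x + y) / 2.0, y - x
    ax_ba.plot(mean, diff, "o", ms=4, alpha=0.7)
    ax_ba.axhline(stats.bias, color="r", lw=1)
    for lim in stats.loa:
        ax_ba.axhline(lim, color="0.5", ls=":", lw=1)
    ax_ba.set_xlabel(f"mean {label}")
    ax_ba.set_ylabel(f"difference {label}")
    ax_ba.set_title(f"bias {stats.bias:.2f}, "
                    f"LoA [{stats.loa[0]:.2f}, {stats.loa[1]:.2f}]", fontsize=9)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
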