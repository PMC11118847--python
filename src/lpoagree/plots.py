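"""Convenience plots: scatter with OLS line, Bland-Altman with CI bands.

Cosmetic output only; nothing downstream depends on these files.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import numpy as np

from .agreement import AgreementRow


def _ols_band(x: np.ndarray, y: np.ndarray, ax, alpha: float = 0.05) -> None:
    from scipy import stats
    res = stats.linregress(x, y)
    xs = np.linspace(x.min(), x.max(), 100)
    pred = res.intercept + res.slope * xs
    n = x.size
    s_err = np.sqrt(np.sum((y - (res.intercept + res.slope * x)) ** 2) / (n - 2))
    half = stats.t.ppf(1 - alpha / 2, n - 2) * s_err * np.sqrt(
        1.0 / n + (xs - x.mean()) ** 2 / np.sum((x - x.mean()) ** 2))
    ax.plot(xs, pred, color="black")
    ax.fill_between(xs, pred - half, pred + half, color="grey", alpha=0.3)


def scatter_plot(row: AgreementRow, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ds = row.dataset
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(ds.plasma, ds.saliva, color="tab:blue", s=25)
    _ols_band(ds.plasma, ds.saliva, ax)
    ax.set_xlabel("plasma level")
    ax.set_ylabel("saliva level")
    ax.set_title(ds.label)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def bland_altman_plot(row: AgreementRow, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ds, ba = row.dataset, row.ba
    d = ds.saliva - ds.plasma
    m = (ds.saliva + ds.plasma) / 2.0
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(m, d, color="tab:blue", s=25)
    ax.axhline(ba.mean_diff, ls="--", color="tab:blue")
    ax.axhspan(*ba.mean_diff_ci, color="tab:blue", alpha=0.2)
    for loa, ci, color in ((ba.loa_low, ba.loa_low_ci, "tab:red"),
                           (ba.loa_high, ba.loa_high_ci, "tab:green")):
        ax.axhline(loa, ls="--", color=color)
        if ci is not None:
            ax.axhspan(*ci, color=color, alpha=0.2)
    if np.ptp(m) > 0:
        _ols_band(m, d, ax)
    ax.set_xlabel("mean of saliva and plasma")
    ax.set_ylabel("difference (saliva - plasma)")
    ax.set_title(ds.label)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def emit_run_plots(rows: Iterable[AgreementRow], outdir: Path) -> list:
    """Write one scatter and one Bland-Altman plot per successful stratum."""
    plot_dir = Path(outdir) / "plots"
    plot_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for row in rows:
        if row.error is not None:
            continue
        stem = row.dataset.label.replace("/", "_")
        for kind, fn in (("scatter", scatter_plot), ("bland_altman", bland_altman_plot)):
            path = plot_dir / f"{stem}_{kind}.png"
            fn(row, path)
            written.append(str(path))
    return written
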