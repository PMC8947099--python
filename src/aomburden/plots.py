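"""Figure rendering: observed annual incidence with fitted ITS segments."""

from __future__ import annotations

import pandas as pd
from matplotlib.backends.backend_agg import FigureCanvasAgg
from matplotlib.figure import Figure

from .trends import ITSResult, fitted_annual_rates


def plot_its_panels(panels: dict[str, tuple[pd.DataFrame, ITSResult | None]], path=None):
    """Multi-panel plot of annual IR series with fitted segment curves.

    ``panels`` maps a title (e.g. "overall", "<2") to (annual IR table with
    year/ir columns, ITS fit or None). Returns the Figure; writes ``path``
    if given.
    """
    n = max(len(panels), 1)
    ncols = 2 if n > 1 else 1
    nrows = (n + ncols - 1) // ncols
    fig = Figure(figsize=(5.0 * ncols, 3.4 * nrows))
    axes = fig.subplots(nrows, ncols, squeeze=False)
    for ax in axes.flat:
        ax.set_visible(False)
    for ax, (title, (annual, its)) in zip(axes.flat, panels.items()):
        ax.set_visible(True)
        ax.plot(annual["year"], annual["ir"], "o", color="black", ms=4, label="observed")
        if its is not None:
            fit = fitted_annual_rates(its)
            pre = fit[fit["year"] < its.breakpoint_year]
            post = fit[fit["year"] >= its.breakpoint_year]
            ax.plot(pre["year"], pre["ir"], "-", color="tab:blue", label="fitted (early)")
            ax.plot(post["year"], post["ir"], "-", color="tab:red", label="fitted (late)")
            ax.axvline(its.breakpoint_year - 0.5, color="grey", ls=":", lw=1)
        ax.set_title(title)
        ax.set_xlabel("year")
        ax.set_ylabel("IR per 1000 PY")
    handles, labels = axes.flat[0].get_legend_handles_labels()
    if handles:
        fig.legend(handles, labels, loc="lower right", frameon=False)
    fig.tight_layout()
    if path is not None:
        FigureCanvasAgg(fig).print_figure(str(path), dpi=150)
    return fig
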