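"""Tabular and plot-ready report emission.

Every figure-type the pipeline supports (bias curve on log/linear scale,
fold-change ratio curve, per-locus bars, window-GC histogram) has a
machine-readable TSV; plots are derived views only and never required by
the analysis itself.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd

from .coverage import BiasCurve, fold_change
from .qpcr import PlateauResult

__all__ = ["summary_report", "write_table", "plot_curves"]


def write_table(df: pd.DataFrame, path: str | Path,
                metadata: Mapping | None = None) -> None:
    """TSV with '#'-prefixed provenance comments before the header line."""
    from . import __version__

    with open(path, "w") as fh:
        fh.write(f"# gcbias {__version__}\n")
        for k, v in (metadata or {}).items():
            fh.write(f"# {k}\t{v}\n")
        df.to_csv(fh, sep="\t", index=False)


def summary_report(
    curves: Mapping[str, BiasCurve],
    plateaus: Mapping[str, PlateauResult] | None = None,
    under_coverage: Mapping[str, float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long-format per-(sample, bin) table plus a per-sample summary block.

    With exactly two samples the per-bin table gains a fold_change column
    (first sample over second).  Raises on an empty curve set.
    """
    if len(curves) == 0:
        raise ValueError("no curves to report")
    rows = []
    for name, curve in curves.items():
        t = curve.table.copy()
        t.insert(0, "sample", name)
        rows.append(t)
    per_bin = pd.concat(rows, ignore_index=True)
    if len(curves) == 2:
        (name_a, a), (name_b, b) = curves.items()
        fc = fold_change(a, b)[["bin_percent", "fold_change"]]
        per_bin = per_bin.merge(fc, on="bin_percent", how="left")
    summary_rows = []
    for name in curves:
        p = (plateaus or {}).get(name)
        summary_rows.append(
            {
                "sample": name,
                "plateau_gc_low": p.gc_low if p else float("nan"),
                "plateau_gc_high": p.gc_high if p else float("nan"),
                "plateau_n_points": p.n_points if p else 0,
                "under_coverage_fraction": (under_coverage or {}).get(
                    name, float("nan")
                ),
            }
        )
    return per_bin, pd.DataFrame(summary_rows)


def plot_curves(
    curves: Mapping[str, BiasCurve],
    path: str | Path,
    scale: str = "log",
) -> None:
    """Bias curves on a shared axis; masked bins drawn as open symbols."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if len(curves) == 0:
        raise ValueError("no curves to plot")
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for name, curve in curves.items():
        t = curve.table
        solid = ~t["masked"]
        (line,) = ax.plot(
            t.loc[solid, "bin_percent"], t.loc[solid, "relative_value"],
            marker="o", ms=3.5, lw=1, label=name,
        )
        if (~solid).any():
            ax.plot(
                t.loc[~solid, "bin_percent"], t.loc[~solid, "relative_value"],
                marker="o", ms=4.5, lw=0, mfc="none", color=line.get_color(),
            )
    if scale == "log":
        ax.set_yscale("log")
    ax.set_xlabel("%GC of 50-bp window")
    ax.set_ylabel("relative coverage")
    ax.axhline(1.0, color="grey", lw=0.5, zorder=0)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
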