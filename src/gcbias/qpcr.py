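"""qPCR-based GC-bias assay: absolute quantification and the plateau statistic.

Workflow (order matters and is fixed): Cq values are converted to absolute
quantities against a log-linear standard curve, each replicate is filtered
against the no-template-control background (omit if quantity <= 3x NTC),
surviving replicates are averaged, and every locus is normalized to the
mean quantity of the two panel amplicons closest to 50% GC (or a designated
control-locus set).  The resulting relative-abundance-vs-%GC table is the
qPCR analogue of a sequencing bias curve; its flat segment is summarized by
the plateau statistic (maximal contiguous %GC run with at most one point
below relative abundance 0.7).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StandardCurve",
    "QpcrPanel",
    "QpcrRun",
    "PlateauResult",
    "fit_standard_curve",
    "quantify",
    "background_filter",
    "average_duplicates",
    "anchor_loci",
    "normalize_panel",
    "process_run",
    "plateau",
    "compare_samples",
]


# ---------------------------------------------------------------------------
# standard curve
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StandardCurve:
    """Log-linear calibration Cq = intercept + slope * log10(quantity).

    ``efficiency`` is the per-cycle amplification gain as a fraction:
    10**(-1/slope) - 1, i.e. 1.0 for a perfect doubling assay
    (slope -log2(10) ~ -3.32193).
    """

    slope: float
    intercept: float
    efficiency: float
    r_squared: float


def fit_standard_curve(standards: Sequence[tuple[float, float]]) -> StandardCurve:
    """Ordinary least squares of Cq on log10(quantity).

    ``standards`` are (known_quantity, Cq) pairs, e.g. a five-fold dilution
    series.  Requires at least two distinct positive quantities; a
    non-negative slope (no dilution signal) triggers a warning.
    """
    if len(standards) < 2:
        raise ValueError("need at least two standard points")
    q = np.asarray([s[0] for s in standards], dtype=float)
    cq = np.asarray([s[1] for s in standards], dtype=float)
    if (q <= 0).any():
        raise ValueError("standard quantities must be positive")
    if np.unique(q).size < 2:
        raise ValueError("standard quantities are all identical")
    res = stats.linregress(np.log10(q), cq)
    slope = float(res.slope)
    if slope >= 0:
        warnings.warn(
            f"standard-curve slope {slope:.3f} is not negative; "
            "Cq should fall as quantity rises",
            stacklevel=2,
        )
    efficiency = 10.0 ** (-1.0 / slope) - 1.0 if slope != 0 else float("nan")
    return StandardCurve(
        slope=slope,
        intercept=float(res.intercept),
        efficiency=float(efficiency),
        r_squared=float(res.rvalue) ** 2,
    )


def quantify(curve: StandardCurve, cq: float) -> float:
    """Absolute quantity from a Cq value: 10**((Cq - intercept)/slope)."""
    return float(10.0 ** ((cq - curve.intercept) / curve.slope))


def background_filter(
    sample_quantity: float, ntc_quantity: float, factor: float = 3.0
) -> bool:
    """True if the data point is kept, False if omitted.

    A measurement is omitted when it is equal to or less than ``factor``
    times the no-template-control background.  An NTC that never amplified
    is encoded as quantity 0, which keeps every positive measurement.
    """
    if sample_quantity < 0 or ntc_quantity < 0:
        raise ValueError("quantities must be non-negative")
    return sample_quantity > factor * ntc_quantity


def average_duplicates(
    quantities: Sequence[float],
) -> tuple[float, float, float]:
    """Arithmetic mean and (min, max) range of surviving replicates."""
    if len(quantities) == 0:
        raise ValueError("no surviving replicates")
    q = np.asarray(quantities, dtype=float)
    return float(q.mean()), float(q.min()), float(q.max())


# ---------------------------------------------------------------------------
# panels and runs
# ---------------------------------------------------------------------------

@dataclass
class QpcrPanel:
    """Amplicon loci with %GC and an optional role designation.

    ``loci`` columns: locus_id, gc_percent, and optionally contig, start,
    end, amplicon_length, gc_class (low/mid/high) and role
    (test/anchor/control).  Normalization uses role=='control' loci when
    present, otherwise the two loci nearest 50% GC.
    """

    loci: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("locus_id", "gc_percent"):
            if col not in self.loci.columns:
                raise ValueError(f"panel missing column {col!r}")
        if self.loci["locus_id"].duplicated().any():
            raise ValueError("duplicate locus_id in panel")
        gc = self.loci["gc_percent"]
        if ((gc < 0) | (gc > 100)).any():
            raise ValueError("gc_percent outside [0, 100]")
        if "role" not in self.loci.columns:
            self.loci = self.loci.assign(role="test")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "QpcrPanel":
        return cls(pd.read_csv(path, sep="\t", comment="#"))

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("# gcbias QpcrPanel\n")
            self.loci.to_csv(fh, sep="\t", index=False)


@dataclass
class QpcrRun:
    """Replicate Cq measurements plus the run's standard-curve points.

    ``measurements`` columns: locus_id, sample_id, replicate, cq, is_ntc.
    NTC rows carry the no-template background for their locus; a NaN cq in
    an NTC row means the control never amplified.  ``standards`` columns:
    quantity, cq.
    """

    measurements: pd.DataFrame
    standards: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"locus_id", "sample_id", "replicate", "cq", "is_ntc"}
        missing = need - set(self.measurements.columns)
        if missing:
            raise ValueError(f"measurements missing columns: {sorted(missing)}")
        if not {"quantity", "cq"} <= set(self.standards.columns):
            raise ValueError("standards need 'quantity' and 'cq' columns")
        cq = self.measurements.loc[~self.measurements["is_ntc"], "cq"]
        if (cq.dropna() <= 0).any():
            raise ValueError("Cq values must be positive")

    @classmethod
    def from_tsv(
        cls, measurements_path: str | Path, standards_path: str | Path
    ) -> "QpcrRun":
        meas = pd.read_csv(measurements_path, sep="\t", comment="#")
        if "is_ntc" in meas.columns:
            meas["is_ntc"] = meas["is_ntc"].astype(bool)
        std = pd.read_csv(standards_path, sep="\t", comment="#")
        return cls(meas, std)

    def to_tsv(
        self, measurements_path: str | Path, standards_path: str | Path
    ) -> None:
        self.measurements.to_csv(measurements_path, sep="\t", index=False)
        self.standards.to_csv(standards_path, sep="\t", index=False)


def anchor_loci(panel: QpcrPanel) -> list:
    """Locus ids used as the normalization denominator.

    Designated control loci win; otherwise the two loci with minimal
    |gc - 50| (all tied loci enter if the cutoff is shared).
    """
    loci = panel.loci
    controls = loci.loc[loci["role"] == "control", "locus_id"].tolist()
    if controls:
        return controls
    d = (loci["gc_percent"] - 50.0).abs()
    order = np.sort(d.unique())
    chosen: list = []
    for dist in order:
        chosen.extend(loci.loc[d == dist, "locus_id"].tolist())
        if len(chosen) >= 2:
            break
    return chosen


def normalize_panel(
    quantities: pd.DataFrame | Mapping[object, float],
    panel: QpcrPanel,
) -> pd.DataFrame:
    """Divide every locus quantity by the mean of the anchor loci.

    ``quantities`` is either a mapping locus_id -> mean quantity or a
    DataFrame with columns locus_id, mean_quantity and optionally
    range_low, range_high, omitted, reason.  Returns the relative-abundance
    table (locus_id, gc_percent, mean_quantity, range_low, range_high,
    relative_value, omitted, reason); the anchor loci average to
    relative_value 1 by construction.
    """
    if not isinstance(quantities, pd.DataFrame):
        quantities = pd.DataFrame(
            {"locus_id": list(quantities), "mean_quantity": list(quantities.values())}
        )
    q = quantities.copy()
    for col, default in (
        ("range_low", np.nan),
        ("range_high", np.nan),
        ("omitted", False),
        ("reason", ""),
    ):
        if col not in q.columns:
            q[col] = default
    table = panel.loci[["locus_id", "gc_percent"]].merge(q, on="locus_id", how="left")
    table["omitted"] = table["omitted"].fillna(True).astype(bool)
    table.loc[table["mean_quantity"].isna() & (table["reason"] == ""), "reason"] = (
        "not measured"
    )
    anchors = anchor_loci(panel)
    amask = table["locus_id"].isin(anchors)
    if (table.loc[amask, "omitted"]).any() or not amask.any():
        raise ValueError("normalization undefined: anchor loci omitted or missing")
    denom = float(table.loc[amask, "mean_quantity"].mean())
    if denom <= 0:
        raise ValueError("normalization undefined: anchor mean is zero")
    for col in ("mean_quantity", "range_low", "range_high"):
        table[f"relative_{col}" if col != "mean_quantity" else "relative_value"] = (
            table[col] / denom
        )
    table = table.rename(
        columns={
            "relative_range_low": "relative_low",
            "relative_range_high": "relative_high",
        }
    )
    cols = [
        "locus_id",
        "gc_percent",
        "mean_quantity",
        "range_low",
        "range_high",
        "relative_value",
        "relative_low",
        "relative_high",
        "omitted",
        "reason",
    ]
    return table[cols].sort_values("gc_percent").reset_index(drop=True)


def process_run(
    run: QpcrRun,
    panel: QpcrPanel,
    background_factor: float = 3.0,
) -> dict[str, pd.DataFrame]:
    """Full assay pipeline for every sample in a run.

    Fixed order: quantify each replicate -> background-filter each
    replicate on the quantity scale -> average surviving duplicates ->
    normalize to the anchor loci.  Returns one relative-abundance table per
    sample_id.
    """
    curve = fit_standard_curve(
        list(zip(run.standards["quantity"], run.standards["cq"]))
    )
    meas = run.measurements
    ntc = meas[meas["is_ntc"]]
    ntc_q: dict[object, float] = {}
    for locus, grp in ntc.groupby("locus_id"):
        vals = [quantify(curve, c) for c in grp["cq"].dropna()]
        ntc_q[locus] = max(vals) if vals else 0.0

    out: dict[str, pd.DataFrame] = {}
    samples = meas.loc[~meas["is_ntc"], "sample_id"].unique()
    for sample in samples:
        rows = []
        sub = meas[(meas["sample_id"] == sample) & ~meas["is_ntc"]]
        for locus, grp in sub.groupby("locus_id", sort=False):
            reps = [quantify(curve, c) for c in grp["cq"].dropna()]
            kept = [
                q for q in reps
                if background_filter(q, ntc_q.get(locus, 0.0), background_factor)
            ]
            if not kept:
                rows.append((locus, np.nan, np.nan, np.nan, True,
                             "all replicates at or below background"))
                continue
            mean, lo, hi = average_duplicates(kept)
            reason = "single replicate" if len(kept) < len(reps) else ""
            rows.append((locus, mean, lo, hi, False, reason))
        q = pd.DataFrame(
            rows,
            columns=["locus_id", "mean_quantity", "range_low", "range_high",
                     "omitted", "reason"],
        )
        out[str(sample)] = normalize_panel(q, panel)
    if not out:
        raise ValueError("run contains no non-NTC measurements")
    return out


# ---------------------------------------------------------------------------
# plateau
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlateauResult:
    gc_low: float
    gc_high: float
    n_points: int
    n_below: int


def _extract_points(table) -> tuple[np.ndarray, np.ndarray]:
    """(gc, value) arrays from a relative-abundance table or a BiasCurve."""
    if hasattr(table, "table"):  # BiasCurve
        df = table.table
        gc = df["bin_percent"].to_numpy(dtype=float)
        val = df["relative_value"].to_numpy(dtype=float)
        keep = ~df["masked"].to_numpy(dtype=bool)
        return gc[keep], val[keep]
    df = table
    gc = df["gc_percent" if "gc_percent" in df.columns else "bin_percent"].to_numpy(
        dtype=float
    )
    val = df["relative_value"].to_numpy(dtype=float)
    if "omitted" in df.columns:
        keep = ~df["omitted"].to_numpy(dtype=bool)
        gc, val = gc[keep], val[keep]
    return gc, val


def plateau(
    table,
    floor: float = 0.7,
    max_below: int = 1,
) -> PlateauResult:
    """The flat segment of a bias profile.

    Maximal-length contiguous run of points (in %GC order) containing at
    most ``max_below`` points with value strictly below ``floor``.  Among
    equally long runs the one whose closest point to 50% GC is nearest
    wins (then the leftmost).  Endpoints are the %GC of the run's first
    and last points.  Accepts a relative-abundance table (DataFrame) or a
    BiasCurve; omitted/masked points are excluded first.
    """
    gc, val = _extract_points(table)
    if len(gc) == 0:
        raise ValueError("no points for plateau")
    order = np.argsort(gc, kind="stable")
    gc, val = gc[order], val[order]
    below = val < floor
    n = len(gc)
    # two-pointer: for each right end, smallest left keeping <=max_below
    best: tuple | None = None
    left = 0
    n_below_run = 0
    for right in range(n):
        n_below_run += int(below[right])
        while n_below_run > max_below:
            n_below_run -= int(below[left])
            left += 1
        length = right - left + 1
        dist50 = float(np.min(np.abs(gc[left : right + 1] - 50.0)))
        key = (-length, dist50, gc[left])
        if best is None or key < best[0]:
            best = (key, left, right, n_below_run)
    _, left, right, nb = best
    return PlateauResult(
        gc_low=float(gc[left]),
        gc_high=float(gc[right]),
        n_points=right - left + 1,
        n_below=int(nb),
    )


def compare_samples(
    tables: Mapping[str, pd.DataFrame],
    floor: float = 0.7,
) -> tuple[pd.DataFrame, dict[str, PlateauResult]]:
    """Align per-locus relative abundances across samples.

    Returns a wide table (locus metadata plus one relative-value column
    per sample, shared loci only) and each sample's plateau.  Samples with
    no loci in common are an error.
    """
    if len(tables) == 0:
        raise ValueError("no samples to compare")
    wide: pd.DataFrame | None = None
    plateaus: dict[str, PlateauResult] = {}
    for name, tbl in tables.items():
        plateaus[name] = plateau(tbl, floor=floor)
        cur = tbl[["locus_id", "gc_percent", "relative_value"]].rename(
            columns={"relative_value": name}
        )
        wide = cur if wide is None else wide.merge(
            cur, on=["locus_id", "gc_percent"], how="inner"
        )
    if len(wide) == 0:
        raise ValueError("samples share no panel loci")
    return wide.sort_values("gc_percent").reset_index(drop=True), plateaus
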