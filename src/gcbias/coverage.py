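"""Alignment ingest and GC-bias statistics from read coverage.

The central object is the :class:`BiasCurve`: for each %GC bin, the number
of reads assigned to windows of that bin divided by the number of windows
in the bin, normalized so the mid-GC anchor bins (48-52% by default)
average exactly 1.  Alongside it live the per-base coverage profile, the
under-coverage fraction (share of non-ambiguous bases below one-tenth of
the genome-wide mean), per-locus representation, Q20 quality masking,
fold-change between curves, and read pooling.

Read-to-window assignment: a read spans two or more 50-bp windows, so each
usable read is counted once, in the valid window containing its
alignment-span midpoint (ties to the left window for even spans; on
overlapping sliding grids, the candidate window whose center is nearest
the midpoint).  Usable means mapped, primary, non-duplicate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam

from .genome import ReferenceSet

__all__ = [
    "AlignmentSet",
    "BiasCurve",
    "CoverageProfile",
    "load_alignments",
    "assign_reads_to_windows",
    "reads_per_bin",
    "bias_curve",
    "per_base_coverage",
    "under_coverage_fraction",
    "locus_representation",
    "quality_mask",
    "fold_change",
    "pool_curves",
]

logger = logging.getLogger(__name__)

_REC_COLUMNS = [
    "contig",
    "start",
    "aligned_length",
    "mapq",
    "mean_quality",
    "is_mapped",
    "is_secondary",
    "is_duplicate",
]


@dataclass
class AlignmentSet:
    """Minimal alignment records sufficient for bias statistics.

    ``records`` columns: contig, start (0-based), aligned_length (bases on
    the reference), mapq, mean_quality (mean Phred over the read's bases),
    and the is_mapped / is_secondary / is_duplicate flags.  Only mapped,
    primary, non-duplicate records enter any statistic.
    """

    records: pd.DataFrame
    n_skipped: int = 0

    def __post_init__(self) -> None:
        missing = [c for c in _REC_COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"alignment table missing columns: {missing}")

    @property
    def usable(self) -> pd.DataFrame:
        r = self.records
        return r[r["is_mapped"] & ~r["is_secondary"] & ~r["is_duplicate"]]

    def __len__(self) -> int:
        return len(self.records)

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_sam(cls, path: str | Path) -> "AlignmentSet":
        rows = []
        n_skipped = 0
        with pysam.AlignmentFile(str(path), check_sq=False) as fh:
            for rec in fh:
                if rec.is_unmapped:
                    rows.append(("", -1, 0, 0, _mean_qual(rec), False, False, False))
                    continue
                alen = rec.reference_length
                if alen is None or alen == 0:
                    n_skipped += 1
                    continue
                rows.append(
                    (
                        rec.reference_name,
                        rec.reference_start,
                        alen,
                        rec.mapping_quality,
                        _mean_qual(rec),
                        True,
                        rec.is_secondary or rec.is_supplementary,
                        rec.is_duplicate,
                    )
                )
        if not rows and n_skipped:
            raise ValueError(f"all records malformed in {path}")
        if n_skipped:
            logger.warning("skipped %d records without usable CIGAR in %s",
                           n_skipped, path)
        df = pd.DataFrame(rows, columns=_REC_COLUMNS)
        return cls(df, n_skipped=n_skipped)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AlignmentSet":
        """Read the simulator's TSV alignment dialect.

        Columns: contig, start0, aligned_length, mapq, mean_qual[, flags]
        with SAM flag semantics for bits 0x4/0x100/0x400.  Malformed rows
        are skipped with a logged count.
        """
        raw = pd.read_csv(path, sep="\t", comment="#", dtype=str)
        expected = ["contig", "start0", "aligned_length", "mapq", "mean_qual"]
        if list(raw.columns[:5]) != expected:
            # headerless file: retry positionally
            raw = pd.read_csv(path, sep="\t", comment="#", header=None, dtype=str)
            if raw.shape[1] < 5:
                raise ValueError(f"TSV dialect needs >=5 columns: {path}")
            raw.columns = expected + [f"extra{i}" for i in range(raw.shape[1] - 5)]
            if raw.shape[1] >= 6:
                raw = raw.rename(columns={"extra0": "flags"})
        if "flags" not in raw.columns:
            raw["flags"] = "0"
        num = raw[["start0", "aligned_length", "mapq", "mean_qual", "flags"]].apply(
            pd.to_numeric, errors="coerce"
        )
        ok = num.notna().all(axis=1) & raw["contig"].notna()
        n_skipped = int((~ok).sum())
        if n_skipped:
            logger.warning("skipped %d malformed rows in %s", n_skipped, path)
        if ok.sum() == 0:
            raise ValueError(f"all records malformed in {path}")
        flags = num.loc[ok, "flags"].astype(int)
        df = pd.DataFrame(
            {
                "contig": raw.loc[ok, "contig"].to_numpy(),
                "start": num.loc[ok, "start0"].astype(int).to_numpy(),
                "aligned_length": num.loc[ok, "aligned_length"].astype(int).to_numpy(),
                "mapq": num.loc[ok, "mapq"].astype(int).to_numpy(),
                "mean_quality": num.loc[ok, "mean_qual"].astype(float).to_numpy(),
                "is_mapped": (~(flags & 0x4).astype(bool)).to_numpy(),
                "is_secondary": (flags & 0x100).astype(bool).to_numpy(),
                "is_duplicate": (flags & 0x400).astype(bool).to_numpy(),
            }
        )
        return cls(df, n_skipped=n_skipped)


def _mean_qual(rec: pysam.AlignedSegment) -> float:
    q = rec.query_qualities
    if q is None or len(q) == 0:
        return float("nan")
    return float(np.mean(q))


def load_alignments(path: str | Path, dialect: str | None = None) -> AlignmentSet:
    """Load SAM/BAM or the simulator TSV dialect.

    ``dialect`` is one of ``sam``, ``bam``, ``tsv``; by default it is
    inferred from the file suffix.
    """
    if dialect is None:
        suffix = Path(path).suffix.lower()
        dialect = {".sam": "sam", ".bam": "bam", ".tsv": "tsv"}.get(suffix)
        if dialect is None:
            raise ValueError(f"cannot infer alignment dialect from {path}")
    if dialect in ("sam", "bam"):
        return AlignmentSet.from_sam(path)
    if dialect == "tsv":
        return AlignmentSet.from_tsv(path)
    raise ValueError(f"unknown alignment dialect {dialect!r}")


# ---------------------------------------------------------------------------
# read -> window assignment
# ---------------------------------------------------------------------------

def _assign_contig(
    mids: np.ndarray, starts: np.ndarray, window: int, valid: np.ndarray
) -> np.ndarray:
    """Window row index for each midpoint, -1 where no valid window contains it.

    ``starts`` must be sorted.  Fast path requires a uniform grid (true for
    window tables built by :func:`gcbias.genome.window_gc`).
    """
    n = len(starts)
    out = np.full(len(mids), -1, dtype=np.int64)
    if n == 0:
        return out
    s0 = int(starts[0])
    step = int(starts[1] - starts[0]) if n > 1 else window
    if n > 2 and np.any(np.diff(starts) != step):
        # irregular grid: per-read scan (small inputs only)
        for k, mid in enumerate(mids):
            lo = np.searchsorted(starts, mid - window + 1, side="left")
            hi = np.searchsorted(starts, mid, side="right")
            best = -1
            best_d = None
            for i in range(lo, hi):
                if not valid[i]:
                    continue
                d = abs(starts[i] + (window - 1) / 2 - mid)
                if best_d is None or d < best_d:
                    best, best_d = i, d
            out[k] = best
        return out
    # nearest-center candidate on the uniform grid, ties to the left
    f = (mids - (window - 1) / 2 - s0) / step
    idx = np.ceil(f - 0.5).astype(np.int64)
    np.clip(idx, 0, n - 1, out=idx)
    # containment check (fails only near contig edges)
    ws = s0 + idx * step
    contained = (ws <= mids) & (mids < ws + window)
    # shift into range where possible
    too_left = ~contained & (mids >= ws + window)
    idx[too_left] = np.minimum(idx[too_left] + 1, n - 1)
    too_right = ~contained & (mids < ws)
    idx[too_right] = np.maximum(idx[too_right] - 1, 0)
    ws = s0 + idx * step
    contained = (ws <= mids) & (mids < ws + window)
    ok = contained & valid[idx]
    out[ok] = idx[ok]
    # fallback: chosen window invalid but a neighbor containing mid may not be
    retry = np.flatnonzero(contained & ~valid[idx])
    for k in retry:
        mid = mids[k]
        lo = max(0, int(np.ceil((mid - window + 1 - s0) / step)))
        hi = min(n - 1, (mid - s0) // step)
        best, best_d = -1, None
        for i in range(lo, hi + 1):
            if not valid[i]:
                continue
            d = abs(s0 + i * step + (window - 1) / 2 - mid)
            if best_d is None or d < best_d:
                best, best_d = i, d
        out[k] = best
    return out


def assign_reads_to_windows(
    aln: AlignmentSet, windows: pd.DataFrame, mapq_min: int = 0
) -> tuple[np.ndarray, np.ndarray, int]:
    """Assign each usable read to exactly one window.

    Returns ``(window_index, counts, n_dropped)``: ``window_index`` has one
    entry per usable read (row index into ``windows``, -1 if dropped),
    ``counts`` is the per-window read count, and ``n_dropped`` counts reads
    whose midpoint falls in no valid window.  Reads on contigs absent from
    the window table raise an error listing the unmatched names.
    """
    if len(windows) == 0:
        raise ValueError("empty window table")
    w = int(windows["length"].iloc[0])
    usable = aln.usable
    if mapq_min > 0:
        usable = usable[usable["mapq"] >= mapq_min]
    win_contigs = set(windows["contig"].unique())
    read_contigs = set(usable["contig"].unique())
    unmatched = sorted(read_contigs - win_contigs)
    if unmatched:
        raise ValueError(f"alignment contigs not in window table: {unmatched}")

    index = np.full(len(usable), -1, dtype=np.int64)
    starts_all = usable["start"].to_numpy()
    alen_all = usable["aligned_length"].to_numpy()
    mids_all = starts_all + (alen_all - 1) // 2
    contig_arr = usable["contig"].to_numpy()
    for contig, wgrp in windows.groupby("contig", sort=False):
        sel = np.flatnonzero(contig_arr == contig)
        if len(sel) == 0:
            continue
        rows = _assign_contig(
            mids_all[sel],
            wgrp["start"].to_numpy(),
            w,
            wgrp["valid"].to_numpy(),
        )
        base = wgrp.index.to_numpy()
        assigned = rows >= 0
        index[sel[assigned]] = base[rows[assigned]]
    counts = np.zeros(len(windows), dtype=np.int64)
    hit = index[index >= 0]
    np.add.at(counts, hit, 1)
    n_dropped = int((index < 0).sum())
    return index, counts, n_dropped


def reads_per_bin(windows: pd.DataFrame, counts: np.ndarray) -> pd.Series:
    """Sum per-window read counts into %GC bins (valid windows only)."""
    w = int(windows["length"].iloc[0])
    valid = windows["valid"].to_numpy()
    bins = 100.0 * windows["gc_count"].to_numpy() / w
    ser = pd.Series(counts[valid]).groupby(bins[valid]).sum()
    ser.index.name = "bin_percent"
    ser.name = "observed_reads"
    return ser


# ---------------------------------------------------------------------------
# BiasCurve
# ---------------------------------------------------------------------------

@dataclass
class BiasCurve:
    """Per-%GC-bin relative coverage, anchored to the mid-GC bins.

    ``table`` columns: bin_percent, observed_reads, expected_windows,
    relative_value, masked, mask_reason, mean_quality.  Values are stored
    linear; log scaling is a presentation choice only.  The mean of
    relative_value over the anchor bins is exactly 1.
    """

    table: pd.DataFrame
    anchor_bins: tuple[float, ...] = (48.0, 50.0, 52.0)

    @property
    def bins(self) -> np.ndarray:
        return self.table["bin_percent"].to_numpy()

    def value(self, bin_percent: float) -> float:
        row = self.table[self.table["bin_percent"] == bin_percent]
        if len(row) == 0:
            raise KeyError(f"bin {bin_percent} not in curve")
        return float(row["relative_value"].iloc[0])

    def to_tsv(self, path: str | Path, metadata: dict | None = None) -> None:
        with open(path, "w") as fh:
            fh.write("# gcbias BiasCurve\n")
            fh.write(f"# anchor_bins\t{','.join(str(b) for b in self.anchor_bins)}\n")
            for k, v in (metadata or {}).items():
                fh.write(f"# {k}\t{v}\n")
            self.table.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "BiasCurve":
        anchor: tuple[float, ...] = (48.0, 50.0, 52.0)
        with open(path) as fh:
            pos = 0
            for line in fh:
                if not line.startswith("#"):
                    break
                if line.startswith("# anchor_bins\t"):
                    anchor = tuple(
                        float(x) for x in line.split("\t", 1)[1].strip().split(",")
                    )
                pos += len(line)
        table = pd.read_csv(path, sep="\t", comment="#")
        if "mask_reason" in table.columns:
            table["mask_reason"] = table["mask_reason"].fillna("")
        return cls(table=table, anchor_bins=anchor)


def bias_curve(
    observed: pd.Series,
    histogram: pd.Series,
    anchor: Sequence[float] = (48.0, 50.0, 52.0),
) -> BiasCurve:
    """Observed/expected coverage per %GC bin, anchored at mid-GC.

    ``observed`` maps bin_percent -> read count (e.g. from
    :func:`reads_per_bin`); ``histogram`` maps bin_percent -> window count
    (the *expected* weight).  relative_value(b) = (reads_b / windows_b)
    divided by the mean of that ratio over the anchor bins.  Bins with zero
    windows are absent; bins with zero reads are present with value 0.
    """
    hist = histogram[histogram > 0]
    extra = set(observed.index) - set(hist.index)
    if extra:
        raise ValueError(
            f"observed counts in bins without windows: {sorted(extra)[:5]}"
        )
    obs = observed.reindex(hist.index, fill_value=0).astype(float)
    ratio = obs / hist.astype(float)
    anchor = tuple(float(a) for a in anchor)
    missing = [a for a in anchor if a not in set(hist.index)]
    if missing:
        raise ValueError(f"anchor bins without windows: {missing}")
    anchor_ratios = ratio.loc[list(anchor)]
    if (obs.loc[list(anchor)] == 0).all():
        raise ValueError("anchor undefined: zero reads in all anchor bins")
    anchor_mean = float(anchor_ratios.mean())
    rel = ratio / anchor_mean
    table = pd.DataFrame(
        {
            "bin_percent": hist.index.to_numpy(dtype=float),
            "observed_reads": obs.to_numpy(dtype=np.int64),
            "expected_windows": hist.to_numpy(dtype=np.int64),
            "relative_value": rel.to_numpy(),
            "masked": False,
            "mask_reason": "",
            "mean_quality": np.nan,
        }
    ).reset_index(drop=True)
    return BiasCurve(table=table, anchor_bins=anchor)


# ---------------------------------------------------------------------------
# per-base coverage
# ---------------------------------------------------------------------------

@dataclass
class CoverageProfile:
    """Per-base read-overlap counts for every base, with the genome-wide
    mean computed over non-ambiguous bases only."""

    counts: dict[str, np.ndarray]
    ambiguity: dict[str, np.ndarray]
    genome_mean: float = field(init=False)

    def __post_init__(self) -> None:
        total = 0
        n = 0
        for name, c in self.counts.items():
            keep = ~self.ambiguity[name]
            total += int(c[keep].sum())
            n += int(keep.sum())
        self.genome_mean = total / n if n else 0.0


def per_base_coverage(aln: AlignmentSet, ref: ReferenceSet) -> CoverageProfile:
    """Count, for every base, the number of usable reads overlapping it."""
    counts = {name: np.zeros(len(ref.sequence(name)) + 1, dtype=np.int64)
              for name in ref.names}
    usable = aln.usable
    for contig, grp in usable.groupby("contig", sort=False):
        if contig not in counts:
            raise ValueError(f"alignment contig {contig!r} not in reference")
        diff = counts[contig]
        starts = grp["start"].to_numpy()
        ends = starts + grp["aligned_length"].to_numpy()
        n = len(diff) - 1
        if (starts < 0).any() or (ends > n).any():
            raise ValueError(f"alignment outside contig bounds on {contig!r}")
        np.add.at(diff, starts, 1)
        np.add.at(diff, ends, -1)
    out = {name: np.cumsum(diff[:-1]) for name, diff in counts.items()}
    return CoverageProfile(
        counts=out, ambiguity={n: ref.ambiguity_mask(n) for n in ref.names}
    )


def under_coverage_fraction(
    profile: CoverageProfile, threshold_fraction: float = 0.1
) -> float:
    """Fraction of non-ambiguous bases covered at strictly less than
    ``threshold_fraction`` times the genome-wide mean."""
    if profile.genome_mean <= 0:
        raise ValueError("no coverage: genome mean is zero")
    thr = threshold_fraction * profile.genome_mean
    under = 0
    total = 0
    for name, c in profile.counts.items():
        keep = ~profile.ambiguity[name]
        under += int((c[keep] < thr).sum())
        total += int(keep.sum())
    return under / total


def locus_representation(
    profile: CoverageProfile,
    loci: Iterable[tuple[str, int, int]] | pd.DataFrame,
    mode: str = "per-locus",
) -> pd.Series | float:
    """Mean per-base coverage of loci relative to the genome-wide mean.

    ``mode='per-locus'`` returns one value per locus; ``mode='pooled'``
    treats all loci as one region (total read-bases over total length) --
    the right statistic when single-locus coverage is too shallow to be
    meaningful on its own.
    """
    if profile.genome_mean <= 0:
        raise ValueError("no coverage: genome mean is zero")
    if isinstance(loci, pd.DataFrame):
        names_col = (
            loci["name"].tolist() if "name" in loci.columns else list(range(len(loci)))
        )
        items = [
            (row["contig"], int(row["start"]), int(row["end"]), names_col[i])
            for i, (_, row) in enumerate(loci.iterrows())
        ]
    else:
        items = [(c, s, e, i) for i, (c, s, e) in enumerate(loci)]
    sums, lengths, names = [], [], []
    for contig, start, end, name in items:
        if contig not in profile.counts:
            raise ValueError(f"locus contig {contig!r} not in coverage profile")
        if end <= start:
            raise ValueError(f"empty locus {name!r}: [{start}, {end})")
        sums.append(int(profile.counts[contig][start:end].sum()))
        lengths.append(end - start)
        names.append(name)
    if mode == "pooled":
        return (sum(sums) / sum(lengths)) / profile.genome_mean
    if mode == "per-locus":
        vals = [s / l / profile.genome_mean for s, l in zip(sums, lengths)]
        return pd.Series(vals, index=names, name="relative_representation")
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# masking, ratios, pooling
# ---------------------------------------------------------------------------

def quality_mask(
    aln: AlignmentSet,
    windows: pd.DataFrame,
    curve: BiasCurve,
    q_threshold: float = 20.0,
) -> BiasCurve:
    """Flag curve bins whose reads average below a Phred threshold.

    The bin statistic is the mean over assigned reads of each read's mean
    base quality.  Bins with no reads are masked with reason ``no reads``.
    Values are retained; only the flags change.
    """
    index, _, _ = assign_reads_to_windows(aln, windows)
    usable = aln.usable
    w = int(windows["length"].iloc[0])
    win_bins = 100.0 * windows["gc_count"].to_numpy() / w
    assigned = index >= 0
    read_bins = win_bins[index[assigned]]
    read_quals = usable["mean_quality"].to_numpy()[assigned]
    per_bin = pd.Series(read_quals).groupby(read_bins).mean()

    table = curve.table.copy()
    qual = table["bin_percent"].map(per_bin)
    table["mean_quality"] = qual
    no_reads = qual.isna()
    low = qual < q_threshold
    table["masked"] = (no_reads | low).to_numpy()
    reason = np.where(
        no_reads, "no reads", np.where(low, f"mean quality < Q{q_threshold:g}", "")
    )
    table["mask_reason"] = reason
    return BiasCurve(table=table, anchor_bins=curve.anchor_bins)


def fold_change(curve_a: BiasCurve, curve_b: BiasCurve) -> pd.DataFrame:
    """Per-bin ratio a/b of two anchored curves.

    Bins present in only one curve are dropped; fully disjoint bins are an
    error.  Where b is 0 the ratio is flagged undefined.  Masks propagate
    as the union of the inputs' masks.
    """
    if tuple(curve_a.anchor_bins) != tuple(curve_b.anchor_bins):
        raise ValueError("curves use different anchor definitions")
    a = curve_a.table.set_index("bin_percent")
    b = curve_b.table.set_index("bin_percent")
    shared = a.index.intersection(b.index)
    if len(shared) == 0:
        raise ValueError("curves have disjoint bins")
    va = a.loc[shared, "relative_value"].to_numpy()
    vb = b.loc[shared, "relative_value"].to_numpy()
    undefined = vb == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(undefined, np.nan, va / np.where(undefined, 1.0, vb))
    return pd.DataFrame(
        {
            "bin_percent": shared.to_numpy(),
            "fold_change": ratio,
            "undefined": undefined,
            "masked": (
                a.loc[shared, "masked"].to_numpy()
                | b.loc[shared, "masked"].to_numpy()
            ),
        }
    )


def pool_curves(
    read_sets: Sequence[AlignmentSet],
    windows: pd.DataFrame,
    histogram: pd.Series,
    anchor: Sequence[float] = (48.0, 50.0, 52.0),
) -> BiasCurve:
    """Bias curve of the concatenation of several read sets.

    Reads are pooled *before* binning (the curve of the merged library, not
    an average of curves) and the result is re-anchored.
    """
    if len(read_sets) < 2:
        raise ValueError("need at least two read sets to pool")
    merged = AlignmentSet(
        pd.concat([rs.records for rs in read_sets], ignore_index=True),
        n_skipped=sum(rs.n_skipped for rs in read_sets),
    )
    _, counts, _ = assign_reads_to_windows(merged, windows)
    return bias_curve(reads_per_bin(windows, counts), histogram, anchor)
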