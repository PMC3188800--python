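"""Reference sequences, windowed GC content and GC histograms.

The central question this module serves is "how many 50-bp windows of the
reference fall in each %GC category?" -- the *expected* side of an
observed/expected coverage curve.  Sequences are held uppercase with a
per-base ambiguity mask (any base outside A/C/G/T); windows that overlap an
ambiguous base are excluded from both sides of the normalization.

Coordinates are 0-based, half-open throughout.  BED input is taken as-is;
SAM positions are converted on ingest (see :mod:`gcbias.coverage`).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "ReferenceSet",
    "read_fasta",
    "window_gc",
    "gc_bin",
    "gc_histogram",
    "context_gc",
    "build_composite",
    "read_bed",
]

_IUPAC_DNA = frozenset(b"ACGTRYSWKMBDHVN")
_GC_BYTES = (ord("G"), ord("C"))
_ACGT_BYTES = frozenset(b"ACGT")


def _as_bytes(sequence: str) -> np.ndarray:
    return np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)


class ReferenceSet:
    """An ordered collection of named uppercase DNA sequences.

    Parameters
    ----------
    contigs:
        Iterable of ``(name, sequence)`` pairs.  Sequences are folded to
        uppercase; characters outside the IUPAC DNA alphabet raise a
        ``ValueError`` naming the offending record.
    """

    def __init__(self, contigs: Iterable[tuple[str, str]]):
        self._seqs: dict[str, str] = {}
        self._gc: dict[str, np.ndarray] = {}
        self._ambig: dict[str, np.ndarray] = {}
        for name, seq in contigs:
            if name in self._seqs:
                raise ValueError(f"duplicate contig name: {name!r}")
            seq = seq.upper()
            arr = _as_bytes(seq)
            bad = set(arr.tolist()) - set(_IUPAC_DNA)
            if bad:
                chars = ", ".join(sorted(chr(b) for b in bad))
                raise ValueError(
                    f"record {name!r} contains non-IUPAC characters: {chars}"
                )
            self._seqs[name] = seq
            self._gc[name] = (arr == _GC_BYTES[0]) | (arr == _GC_BYTES[1])
            self._ambig[name] = ~np.isin(arr, np.frombuffer(b"ACGT", dtype=np.uint8))
        if not self._seqs:
            raise ValueError("reference contains no records")

    # -- basic accessors ---------------------------------------------------
    @property
    def names(self) -> list[str]:
        return list(self._seqs)

    @property
    def lengths(self) -> dict[str, int]:
        return {n: len(s) for n, s in self._seqs.items()}

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self._seqs.values())

    def sequence(self, name: str) -> str:
        return self._seqs[name]

    def gc_mask(self, name: str) -> np.ndarray:
        """Boolean per-base array, True where the base is G or C."""
        return self._gc[name]

    def ambiguity_mask(self, name: str) -> np.ndarray:
        """Boolean per-base array, True where the base is not A/C/G/T."""
        return self._ambig[name]

    def gc_fraction(self, name: str | None = None) -> float:
        """GC fraction over non-ambiguous bases (one contig or genome-wide)."""
        names = [name] if name is not None else self.names
        gc = sum(int(self._gc[n].sum()) for n in names)
        valid = sum(int((~self._ambig[n]).sum()) for n in names)
        if valid == 0:
            raise ValueError("no non-ambiguous bases")
        return gc / valid

    def contigs(self) -> Iterable[tuple[str, str]]:
        return self._seqs.items()

    # -- I/O ---------------------------------------------------------------
    @classmethod
    def from_fasta(cls, path: str | Path) -> "ReferenceSet":
        records = []
        for rec in SeqIO.parse(str(path), "fasta"):
            records.append((rec.id, str(rec.seq)))
        if not records:
            raise ValueError(f"no FASTA records in {path}")
        return cls(records)

    def write_fasta(self, path: str | Path, width: int = 70) -> None:
        recs = [
            SeqRecord(Seq(seq), id=name, description="")
            for name, seq in self._seqs.items()
        ]
        with open(path, "w") as fh:
            writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
            writer.write_file(recs)

    def __repr__(self) -> str:  # pragma: no cover
        return f"ReferenceSet({len(self._seqs)} contigs, {self.total_length} bp)"


def read_fasta(path: str | Path) -> ReferenceSet:
    """Read a (wrapped or unwrapped, multi-record) FASTA into a ReferenceSet."""
    return ReferenceSet.from_fasta(path)


def window_gc(ref: ReferenceSet, window_length: int, step: int = 1) -> pd.DataFrame:
    """Tabulate GC content of windows tiled/slid across every contig.

    Returns a DataFrame with columns ``contig, start, length, gc_count,
    gc_percent, valid``.  ``valid`` is False for windows overlapping any
    ambiguous base.  Windows never span contigs; contigs shorter than the
    window contribute no rows.  The default ``step=1`` gives sliding
    windows; ``step=window_length`` gives a non-overlapping tiling.
    """
    if window_length < 1:
        raise ValueError("window_length must be >= 1")
    if step < 1:
        raise ValueError("step must be >= 1")
    frames = []
    for name, seq in ref.contigs():
        n = len(seq)
        if n < window_length:
            continue
        gc_cum = np.concatenate(([0], np.cumsum(ref.gc_mask(name), dtype=np.int64)))
        am_cum = np.concatenate(
            ([0], np.cumsum(ref.ambiguity_mask(name), dtype=np.int64))
        )
        starts = np.arange(0, n - window_length + 1, step, dtype=np.int64)
        gc_counts = gc_cum[starts + window_length] - gc_cum[starts]
        ambig = (am_cum[starts + window_length] - am_cum[starts]) > 0
        frames.append(
            pd.DataFrame(
                {
                    "contig": name,
                    "start": starts,
                    "length": window_length,
                    "gc_count": gc_counts,
                    "gc_percent": 100.0 * gc_counts / window_length,
                    "valid": ~ambig,
                }
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=["contig", "start", "length", "gc_count", "gc_percent", "valid"]
        )
    return pd.concat(frames, ignore_index=True)


def gc_bin(gc_count: int, window_length: int) -> float:
    """Map a window's GC base count to its %GC bin.

    The natural bin granularity is ``100/window_length`` percent (2% for
    50-bp windows), and since ``gc_count`` is an integer the value
    ``100*gc_count/window_length`` already lies exactly on that grid.
    """
    if window_length < 1:
        raise ValueError("window_length must be >= 1")
    if not 0 <= gc_count <= window_length:
        raise ValueError(
            f"gc_count {gc_count} out of range for window length {window_length}"
        )
    return 100.0 * gc_count / window_length


def gc_histogram(windows: pd.DataFrame) -> pd.Series:
    """Count valid windows per %GC bin.

    Bins with zero windows are present (count 0) across the observed range
    at the window's natural granularity.  Raises if the table is empty or
    no window is valid.
    """
    if len(windows) == 0:
        raise ValueError("empty window table")
    lengths = windows["length"].unique()
    if len(lengths) != 1:
        raise ValueError("window table mixes window lengths")
    w = int(lengths[0])
    valid = windows[windows["valid"]]
    if len(valid) == 0:
        raise ValueError("no valid windows")
    counts = valid.groupby("gc_count").size()
    lo, hi = int(counts.index.min()), int(counts.index.max())
    full = counts.reindex(range(lo, hi + 1), fill_value=0)
    hist = pd.Series(
        full.to_numpy(), index=[gc_bin(c, w) for c in full.index], name="count"
    )
    hist.index.name = "bin_percent"
    return hist


def context_gc(
    ref: ReferenceSet,
    locus: tuple[str, int, int],
    context_length: int = 250,
) -> tuple[float, int]:
    """%GC of a fixed-size window centered on a locus midpoint.

    The window is clipped at contig edges rather than discarded; the actual
    span length is returned alongside the %GC.  Used to ask whether the
    sequence *context* of an amplicon (default 250 bp) predicts its
    coverage better than the amplicon's own %GC.
    """
    contig, start, end = locus
    if contig not in ref.names:
        raise ValueError(f"unknown contig {contig!r}")
    n = len(ref.sequence(contig))
    if not (0 <= start < end <= n):
        raise ValueError(f"locus {locus} outside contig bounds (length {n})")
    mid = (start + end) // 2
    lo = max(0, mid - context_length // 2)
    hi = min(n, mid - context_length // 2 + context_length)
    span = hi - lo
    gc = int(ref.gc_mask(contig)[lo:hi].sum())
    return 100.0 * gc / span, span


def build_composite(
    components: Sequence[ReferenceSet],
    prefixes: Sequence[str] | None = None,
) -> ReferenceSet:
    """Concatenate reference sets into one composite reference.

    All contigs are retained.  ``prefixes`` (one per component) disambiguates
    contig names as ``prefix.contig``; without prefixes a name collision is
    an error.  Total length is additive.
    """
    if len(components) == 0:
        raise ValueError("need at least one component")
    if prefixes is not None and len(prefixes) != len(components):
        raise ValueError("one prefix per component required")
    contigs: list[tuple[str, str]] = []
    seen: set[str] = set()
    for i, comp in enumerate(components):
        for name, seq in comp.contigs():
            out = f"{prefixes[i]}.{name}" if prefixes is not None else name
            if out in seen:
                raise ValueError(
                    f"contig name collision: {out!r} (pass prefixes to disambiguate)"
                )
            seen.add(out)
            contigs.append((out, seq))
    return ReferenceSet(contigs)


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read BED3/BED6 loci (0-based half-open, as BED is defined)."""
    raw = pd.read_csv(path, sep="\t", comment="#", header=None, dtype=str)
    if raw.shape[1] < 3:
        raise ValueError(f"malformed BED file (need >=3 columns): {path}")
    df = raw.iloc[:, :3].copy()
    df.columns = ["contig", "start", "end"]
    try:
        df["start"] = df["start"].astype(int)
        df["end"] = df["end"].astype(int)
    except ValueError as exc:
        raise ValueError(f"malformed BED coordinates in {path}: {exc}") from exc
    if raw.shape[1] >= 4:
        df["name"] = raw.iloc[:, 3].astype(str)
    else:
        df["name"] = [f"locus_{i}" for i in range(len(df))]
    return df
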