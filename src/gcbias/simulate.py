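"""Synthetic inputs with known ground truth.

Generates everything the pipeline consumes: a scaled three-component
composite genome spanning ~19-69% GC (emulating an equimolar
P. falciparum / E. coli / R. sphaeroides pool), sheared fragment pools
with gel size selection, PCR-amplified libraries (via
:mod:`gcbias.amplification`), 101-base paired reads with their true
alignments, and qPCR runs drawn from a log-linear standard curve.

Genome model: each component is a chain of fixed-length blocks.  Block GC
follows a stationary AR(1) series around the component target (recentred
so the realized mean hits the target, clipped to [0,1], and by default
quantized to the 2% grid of 50-bp window bins); within a block, G/C
positions are evenly interleaved so that every 50-bp window, and every
fragment, carries the block's GC to within a base or two.  This makes the
window-GC distribution -- and hence the bias curve -- directly
controllable, at the cost of realism in local composition (see
docs/methods.md for what this does and does not exercise).

Every stochastic operation takes an explicit seed or Generator and is
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .amplification import EfficiencyProfile, simulate_pcr
from .coverage import AlignmentSet
from .genome import ReferenceSet, build_composite
from .qpcr import QpcrRun

__all__ = [
    "ComponentSpec",
    "SimConfig",
    "generate_component",
    "scaled_per_reference",
    "fragment_genome",
    "gel_window",
    "size_select",
    "amplify_pool",
    "emit_reads",
    "expected_library_curve",
    "uniform_alignments",
    "emulate_qpcr",
    "genome_equivalents",
    "write_truth_tsv",
    "write_sam",
    "write_fastq",
]

AVOGADRO = 6.0221e23
#: mean molar mass of a DNA base pair, g/mol (650 is the usual convention;
#: 660 is also seen and supported by passing mass_per_bp explicitly)
MASS_PER_BP_GRAMS = 650.0 / AVOGADRO


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# genome generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ComponentSpec:
    """One synthetic genome component: length, target GC, block structure.

    ``gc_block_sd`` is the stationary block-to-block GC standard deviation;
    ``block_corr`` the AR(1) lag-1 correlation between neighbouring blocks
    (smooth local GC, like real isochore-ish structure); ``gc_quantum``
    snaps block GC to the window-bin grid (0 disables).
    """

    name: str
    length: int
    gc_target: float
    block_length: int = 1000
    gc_block_sd: float = 0.08
    block_corr: float = 0.8
    gc_quantum: float = 0.02

    def __post_init__(self) -> None:
        if not 0.0 <= self.gc_target <= 1.0:
            raise ValueError("gc_target must be in [0, 1]")
        if self.length < self.block_length:
            raise ValueError("length must be >= block_length")
        if not 0.0 <= self.block_corr < 1.0:
            raise ValueError("block_corr must be in [0, 1)")


def _block_gc_series(spec: ComponentSpec, n_blocks: int,
                     rng: np.random.Generator) -> np.ndarray:
    if spec.gc_target in (0.0, 1.0) or spec.gc_block_sd == 0.0:
        # boundary targets leave no room for symmetric block noise
        return np.full(n_blocks, spec.gc_target)
    rho = spec.block_corr
    z = np.empty(n_blocks)
    z[0] = rng.normal()
    innov = rng.normal(size=n_blocks - 1) * np.sqrt(1.0 - rho * rho)
    for t in range(1, n_blocks):
        z[t] = rho * z[t - 1] + innov[t - 1]
    q = spec.gc_target + spec.gc_block_sd * z
    q = q - (q.mean() - spec.gc_target)  # pin the realized mean to target
    q = np.clip(q, 0.0, 1.0)
    if spec.gc_quantum > 0:
        q = np.round(q / spec.gc_quantum) * spec.gc_quantum
    return q


def generate_component(spec: ComponentSpec, rng_seed) -> ReferenceSet:
    """Generate one single-contig component genome.

    Block GC values come from the recentred AR(1) series; within each
    block, GC positions are spread evenly (Bresenham placement with a
    random phase) and each chosen position becomes G or C -- each
    unchosen one A or T -- with equal probability.  The realized
    genome-wide GC is within ~2% of the target for any length >= 50 kb
    (pinned by the recentring).
    """
    rng = _rng(rng_seed)
    n_blocks = int(np.ceil(spec.length / spec.block_length))
    q_blocks = _block_gc_series(spec, n_blocks, rng)
    phases = rng.uniform(size=n_blocks)

    block_idx = np.minimum(
        np.arange(spec.length) // spec.block_length, n_blocks - 1
    )
    q = q_blocks[block_idx]
    phi = phases[block_idx]
    local_i = np.arange(spec.length) - block_idx * spec.block_length
    is_gc = np.floor((local_i + 1) * q + phi) - np.floor(local_i * q + phi) >= 1.0

    strong = rng.integers(0, 2, size=spec.length)  # G vs C / A vs T identity
    bases = np.where(is_gc, np.where(strong == 1, ord("G"), ord("C")),
                     np.where(strong == 1, ord("A"), ord("T")))
    seq = bases.astype(np.uint8).tobytes().decode("ascii")
    return ReferenceSet([(spec.name, seq)])


#: the three components of the composite test genome, full scale
PER_COMPONENTS: tuple[tuple[str, int, float], ...] = (
    ("pfalciparum", 23_000_000, 0.19),
    ("ecoli", 4_600_000, 0.51),
    ("rsphaeroides", 4_600_000, 0.69),
)


def scaled_per_reference(
    scale: float,
    rng_seed,
    block_length: int = 1000,
    gc_block_sd: float = 0.08,
) -> ReferenceSet:
    """A scaled-down composite genome: 19%, 51% and 69% GC components with
    lengths scale x {23 Mb, 4.6 Mb, 4.6 Mb}, concatenated.

    scale=0.01 gives the 322-kb desk-scale genome used throughout the
    tests (230 kb + 46 kb + 46 kb).
    """
    if not 0.0 < scale <= 1.0:
        raise ValueError("scale must be in (0, 1]")
    rng = _rng(rng_seed)
    comps = []
    for name, length, gc in PER_COMPONENTS:
        n = int(round(length * scale))
        if n < 2 * block_length:
            raise ValueError(
                f"scale {scale} leaves component {name!r} shorter than two "
                f"blocks ({n} < {2 * block_length} bases)"
            )
        comps.append(
            generate_component(
                ComponentSpec(name, n, gc, block_length=block_length,
                              gc_block_sd=gc_block_sd),
                rng,
            )
        )
    return build_composite(comps)


# ---------------------------------------------------------------------------
# fragmentation and size selection
# ---------------------------------------------------------------------------

def fragment_genome(
    ref: ReferenceSet,
    n_fragments: int,
    mode_length: int = 225,
    spread: float = 40.0,
    rng_seed=None,
) -> pd.DataFrame:
    """Shear the reference into random fragments.

    Lengths follow a discretized gamma with the requested mode and
    spread (~standard deviation); start positions are uniform over valid
    placements (contigs chosen proportional to length).  Returns a
    FragmentPool DataFrame: contig, start, length, gc_percent,
    copy_number (initialized to 1).
    """
    rng = _rng(rng_seed)
    names = ref.names
    lengths = np.array([len(ref.sequence(n)) for n in names])
    if mode_length >= lengths.min():
        raise ValueError("mode_length must be smaller than the shortest contig")
    shape = (mode_length / spread) ** 2 + 1.0
    scale = spread**2 / mode_length
    frag_len = np.maximum(
        1, np.round(rng.gamma(shape, scale, size=n_fragments))
    ).astype(np.int64)
    contig_idx = rng.choice(len(names), size=n_fragments, p=lengths / lengths.sum())
    clen = lengths[contig_idx]
    frag_len = np.minimum(frag_len, clen)
    starts = rng.integers(0, clen - frag_len + 1)

    gc_cums = {
        n: np.concatenate(([0], np.cumsum(ref.gc_mask(n), dtype=np.int64)))
        for n in names
    }
    gc_counts = np.empty(n_fragments, dtype=np.int64)
    for i, n in enumerate(names):
        sel = contig_idx == i
        cs = gc_cums[n]
        gc_counts[sel] = cs[starts[sel] + frag_len[sel]] - cs[starts[sel]]
    return pd.DataFrame(
        {
            "contig": np.array(names, dtype=object)[contig_idx],
            "start": starts,
            "length": frag_len,
            "gc_percent": 100.0 * gc_counts / frag_len,
            "copy_number": np.ones(n_fragments, dtype=np.int64),
        }
    )


def gel_window(
    insert_target: int, tolerance: int, adapter_offset: int = 90
) -> tuple[int, int]:
    """Apparent gel excision window for a desired insert size.

    Adapter-ligated molecules run ``adapter_offset`` (90 bp) larger than
    their inserts, so a (180 +/- 20)-bp insert is cut at 250-290 bp.
    """
    if tolerance >= insert_target:
        raise ValueError("tolerance must be smaller than insert_target")
    return (
        insert_target - tolerance + adapter_offset,
        insert_target + tolerance + adapter_offset,
    )


def size_select(
    pool: pd.DataFrame, insert_target: int, tolerance: int
) -> pd.DataFrame:
    """Keep fragments with length in [target - tol, target + tol]."""
    if len(pool) == 0:
        raise ValueError("empty fragment pool")
    lo, hi = insert_target - tolerance, insert_target + tolerance
    kept = pool[(pool["length"] >= lo) & (pool["length"] <= hi)]
    if len(kept) == 0:
        raise ValueError(
            "size selection kept no fragments "
            f"(observed lengths {int(pool['length'].min())}-"
            f"{int(pool['length'].max())}, window [{lo}, {hi}])"
        )
    return kept.reset_index(drop=True)


def amplify_pool(
    pool: pd.DataFrame,
    profile: EfficiencyProfile,
    n_cycles: int,
    rng_seed,
) -> pd.DataFrame:
    """PCR-amplify a fragment pool: branching process on copy_number."""
    out = pool.copy()
    out["copy_number"] = simulate_pcr(
        pool["copy_number"].to_numpy(),
        pool["gc_percent"].to_numpy(),
        profile,
        n_cycles,
        _rng(rng_seed),
    )
    return out


# ---------------------------------------------------------------------------
# read emission
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimConfig:
    """Read-emission settings (defaults follow the emulated study design:
    101-base paired reads from (180 +/- 20)-bp inserts, 90-bp adapter
    offset on the gel)."""

    rng_seed: int
    n_reads: int
    read_length: int = 101
    paired: bool = True
    insert_target: int = 180
    insert_tolerance: int = 20
    adapter_offset: int = 90
    quality_mean: float = 35.0
    quality_sd: float = 3.0
    quality_gc_droop: float = 0.0  # Phred lost per %GC above droop_onset
    quality_droop_onset: float = 70.0
    qpcr_noise_sd: float = 0.2

    def __post_init__(self) -> None:
        if self.n_reads <= 0 or self.read_length <= 0:
            raise ValueError("counts must be positive")


def emit_reads(
    pool: pd.DataFrame,
    ref: ReferenceSet,
    config: SimConfig,
    rng_seed=None,
) -> tuple[AlignmentSet, pd.DataFrame]:
    """Sample reads from an (amplified) fragment pool.

    Fragments are drawn with replacement proportional to copy_number; in
    paired mode each drawn fragment emits both ends, inward-facing.  The
    emitted coordinates are ground truth: read sequences equal the
    reference at those coordinates.  Per-read mean quality comes from a
    clipped normal, optionally drooping linearly with fragment %GC above
    an onset (to exercise Q20 masking).  Returns the AlignmentSet and the
    truth table (contig, start0, aligned_length, mapq, mean_qual, flags,
    reverse).
    """
    rng = _rng(config.rng_seed if rng_seed is None else rng_seed)
    copies = pool["copy_number"].to_numpy(dtype=float)
    total = copies.sum()
    if total <= 0:
        raise ValueError("fragment pool has no copies to sequence")
    prob = copies / total
    if config.paired:
        n_templates = (config.n_reads + 1) // 2
    else:
        n_templates = config.n_reads
    idx = rng.choice(len(pool), size=n_templates, p=prob)
    f_start = pool["start"].to_numpy()[idx]
    f_len = pool["length"].to_numpy()[idx]
    f_contig = pool["contig"].to_numpy()[idx]
    f_gc = pool["gc_percent"].to_numpy()[idx]
    rl = np.minimum(config.read_length, f_len)

    if config.paired:
        starts = np.concatenate([f_start, f_start + f_len - rl])
        alens = np.concatenate([rl, rl])
        contigs = np.concatenate([f_contig, f_contig])
        gcs = np.concatenate([f_gc, f_gc])
        reverse = np.concatenate(
            [np.zeros(n_templates, bool), np.ones(n_templates, bool)]
        )
        # n_reads is rounded up to a whole number of templates
        flags = np.where(reverse, 0x1 | 0x2 | 0x10 | 0x80, 0x1 | 0x2 | 0x20 | 0x40)
    else:
        starts, alens, contigs, gcs = f_start, rl, f_contig, f_gc
        reverse = np.zeros(n_templates, bool)
        flags = np.zeros(n_templates, dtype=np.int64)

    mean_q = config.quality_mean - config.quality_gc_droop * np.maximum(
        0.0, gcs - config.quality_droop_onset
    )
    quals = np.clip(
        np.round(rng.normal(mean_q, config.quality_sd)), 2, 41
    ).astype(np.int64)

    truth = pd.DataFrame(
        {
            "contig": contigs,
            "start0": starts.astype(np.int64),
            "aligned_length": alens.astype(np.int64),
            "mapq": 60,
            "mean_qual": quals.astype(float),
            "flags": flags,
            "reverse": reverse,
        }
    )
    records = pd.DataFrame(
        {
            "contig": truth["contig"],
            "start": truth["start0"],
            "aligned_length": truth["aligned_length"],
            "mapq": truth["mapq"],
            "mean_quality": truth["mean_qual"],
            "is_mapped": True,
            "is_secondary": False,
            "is_duplicate": False,
        }
    )
    return AlignmentSet(records), truth


def uniform_alignments(
    ref: ReferenceSet,
    n_reads: int,
    read_length: int = 101,
    mean_quality: float = 35.0,
    rng_seed=None,
) -> AlignmentSet:
    """Idealized unbiased sequencing: read starts uniform over all valid
    placements of every contig.  The null control for bias statistics."""
    rng = _rng(rng_seed)
    names = [n for n in ref.names if len(ref.sequence(n)) >= read_length]
    if not names:
        raise ValueError("no contig long enough for the read length")
    placements = np.array(
        [len(ref.sequence(n)) - read_length + 1 for n in names], dtype=float
    )
    cidx = rng.choice(len(names), size=n_reads, p=placements / placements.sum())
    starts = rng.integers(0, placements[cidx].astype(np.int64))
    records = pd.DataFrame(
        {
            "contig": np.array(names, dtype=object)[cidx],
            "start": starts.astype(np.int64),
            "aligned_length": read_length,
            "mapq": 60,
            "mean_quality": float(mean_quality),
            "is_mapped": True,
            "is_secondary": False,
            "is_duplicate": False,
        }
    )
    return AlignmentSet(records)


def expected_library_curve(
    pool: pd.DataFrame,
    profile: EfficiencyProfile,
    n_cycles: int,
    windows: pd.DataFrame,
    histogram: pd.Series,
    read_length: int = 101,
    paired: bool = True,
    anchor: Sequence[float] = (48.0, 50.0, 52.0),
) -> pd.DataFrame:
    """Closed-form expectation of the bias curve for a specific library.

    :func:`gcbias.amplification.predicted_bias_curve` is the idealized
    GC-only prediction; this function evaluates the same branching-process
    mean (1+p(gc))^n fragment by fragment on an actual (pre-amplification)
    pool, places each fragment's read midpoints deterministically, and
    aggregates into window bins.  It therefore accounts for the fact that
    a read's 50-bp window GC and its fragment's GC differ near block and
    GC-domain boundaries, which is what the stochastic pipeline actually
    samples.  Columns: bin_percent, expected_relative (anchored like a
    BiasCurve), weight (expected read share, arbitrary scale) and
    branch_relvar (relative variance contributed by branching noise,
    for error bars: Var/mean^2 of the Galton-Watson copy number,
    aggregated per bin).
    """
    from .coverage import assign_reads_to_windows

    p = profile.efficiency(pool["gc_percent"].to_numpy())
    mean = np.ones_like(p)
    var = np.zeros_like(p)
    s2 = p * (1.0 - p)  # offspring variance: copy duplicates or not
    for _ in range(n_cycles):
        var = (1.0 + p) ** 2 * var + s2 * mean
        mean = mean * (1.0 + p)
    relvar = np.where(mean > 0, var / mean**2, 0.0)
    weights0 = mean * pool["copy_number"].to_numpy()

    starts = pool["start"].to_numpy()
    lens = pool["length"].to_numpy()
    rl = np.minimum(read_length, lens)
    if paired:
        pr_starts = np.concatenate([starts, starts + lens - rl])
        pr_len = np.concatenate([rl, rl])
        pr_contig = np.concatenate([pool["contig"], pool["contig"]])
        wt = np.concatenate([weights0, weights0]) / 2.0
        rv = np.concatenate([relvar, relvar])
    else:
        pr_starts, pr_len, pr_contig = starts, rl, pool["contig"].to_numpy()
        wt, rv = weights0, relvar
    pseudo = AlignmentSet(
        pd.DataFrame(
            {
                "contig": pr_contig,
                "start": pr_starts.astype(np.int64),
                "aligned_length": pr_len.astype(np.int64),
                "mapq": 60,
                "mean_quality": np.nan,
                "is_mapped": True,
                "is_secondary": False,
                "is_duplicate": False,
            }
        )
    )
    idx, _, _ = assign_reads_to_windows(pseudo, windows)
    w = int(windows["length"].iloc[0])
    win_bins = 100.0 * windows["gc_count"].to_numpy() / w
    ok = idx >= 0
    bins_hit = win_bins[idx[ok]]
    S = pd.Series(wt[ok]).groupby(bins_hit).sum()
    V = pd.Series((wt[ok] ** 2) * rv[ok]).groupby(bins_hit).sum()

    hist = histogram[histogram > 0].astype(float)
    S = S.reindex(hist.index, fill_value=0.0)
    V = V.reindex(hist.index, fill_value=0.0)
    ratio = S / hist
    anchor = [float(a) for a in anchor]
    amean = float(ratio.loc[anchor].mean())
    if amean <= 0:
        raise ValueError("anchor undefined in expected curve")
    with np.errstate(invalid="ignore", divide="ignore"):
        branch_relvar = np.where(S > 0, V / S**2, 0.0)
    return pd.DataFrame(
        {
            "bin_percent": hist.index.to_numpy(dtype=float),
            "expected_relative": (ratio / amean).to_numpy(),
            "weight": S.to_numpy(),
            "branch_relvar": branch_relvar,
        }
    )


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_truth_tsv(truth: pd.DataFrame, path: str | Path,
                    metadata: Mapping | None = None) -> None:
    """Write the simulator's TSV alignment dialect."""
    cols = ["contig", "start0", "aligned_length", "mapq", "mean_qual", "flags"]
    with open(path, "w") as fh:
        fh.write("# gcbias simulated alignments\n")
        for k, v in (metadata or {}).items():
            fh.write(f"# {k}\t{v}\n")
        truth[cols].to_csv(fh, sep="\t", index=False)


def _read_seq(ref: ReferenceSet, contig: str, start: int, length: int,
              reverse: bool) -> str:
    seq = ref.sequence(contig)[start : start + length]
    if reverse:
        comp = str.maketrans("ACGTN", "TGCAN")
        seq = seq.translate(comp)[::-1]
    return seq


def write_sam(truth: pd.DataFrame, ref: ReferenceSet, path: str | Path) -> None:
    """Write simulated reads as SAM with sequences taken from the reference."""
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": n, "LN": len(ref.sequence(n))} for n in ref.names],
    }
    tid = {n: i for i, n in enumerate(ref.names)}
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for i, row in enumerate(truth.itertuples(index=False)):
            a = pysam.AlignedSegment(out.header)
            a.query_name = f"sim_{i // 2}" if row.flags & 0x1 else f"sim_{i}"
            a.flag = int(row.flags)
            a.reference_id = tid[row.contig]
            a.reference_start = int(row.start0)
            a.mapping_quality = int(row.mapq)
            alen = int(row.aligned_length)
            a.cigarstring = f"{alen}M"
            a.query_sequence = _read_seq(
                ref, row.contig, int(row.start0), alen, bool(row.reverse)
            )
            a.query_qualities = pysam.qualitystring_to_array(
                chr(int(row.mean_qual) + 33) * alen
            )
            out.write(a)


def write_fastq(truth: pd.DataFrame, ref: ReferenceSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, row in enumerate(truth.itertuples(index=False)):
            alen = int(row.aligned_length)
            seq = _read_seq(ref, row.contig, int(row.start0), alen,
                            bool(row.reverse))
            qual = chr(int(row.mean_qual) + 33) * alen
            fh.write(f"@sim_{i}\n{seq}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# qPCR emulation & unit conversion
# ---------------------------------------------------------------------------

def emulate_qpcr(
    true_quantities: Mapping[object, float],
    curve_params: tuple[float, float] = (-3.32193, 38.0),
    noise_sd: float = 0.0,
    replicates: int = 2,
    rng_seed=None,
    standard_quantities: Sequence[float] | None = None,
    sample_id: str = "sample",
) -> QpcrRun:
    """Simulated qPCR measurements from known per-locus quantities.

    Cq = intercept + slope*log10(quantity) + N(0, noise_sd) per replicate.
    Standards (default: a five-fold dilution series from 75125 down to ~5
    genome equivalents) are emitted noiselessly from the same curve.  A
    true quantity of 0 produces NTC-like no-amplification rows (NaN Cq).
    """
    slope, intercept = curve_params
    rng = _rng(rng_seed)
    if standard_quantities is None:
        standard_quantities = [75125.0 / 5.0**i for i in range(7)]
    std = pd.DataFrame(
        {
            "quantity": list(standard_quantities),
            "cq": [intercept + slope * np.log10(q) for q in standard_quantities],
        }
    )
    rows = []
    for locus, q in true_quantities.items():
        if q < 0:
            raise ValueError(f"negative quantity for locus {locus!r}")
        for rep in range(1, replicates + 1):
            if q == 0:
                rows.append((locus, sample_id, rep, np.nan, True))
            else:
                cq = intercept + slope * np.log10(q) + rng.normal(0.0, noise_sd)
                rows.append((locus, sample_id, rep, cq, False))
    meas = pd.DataFrame(
        rows, columns=["locus_id", "sample_id", "replicate", "cq", "is_ntc"]
    )
    return QpcrRun(meas, std)


def genome_equivalents(
    mass: float,
    genome_length: int,
    mass_per_bp: float = MASS_PER_BP_GRAMS,
) -> float:
    """Haploid genome copies in a DNA mass: mass / (length * mass_per_bp).

    170 fg of a 32-Mb genome is ~4.9 copies (nominally 5); 2.6 ng is
    ~7.5e4 copies.
    """
    if mass <= 0 or genome_length <= 0 or mass_per_bp <= 0:
        raise ValueError("inputs must be positive")
    return mass / (genome_length * mass_per_bp)
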