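"""Per-cycle PCR efficiency as a function of fragment %GC.

Model: during each PCR cycle every template copy duplicates independently
with probability p(g), where g is the fragment's %GC.  p(g) is a product
of two logistic shoulders,

    p(g) = p_max * sigma((g - low_mid)/low_scale) * sigma((high_mid - g)/high_scale)

so the AT-side and GC-side drop-offs can be shaped independently; either
shoulder can be disabled (scale None).  Expected amplification after n
cycles is (1+p)^n, so the predicted abundance of a fragment relative to a
mid-GC anchor is ((1+p(g))/(1+p(anchor)))^n -- a closed form that a
stochastic Galton-Watson simulation (binomial duplications per cycle)
matches in the mean.

The named presets are calibrated *emulations* of published protocol
behaviours (ramp rate, denaturation time, betaine, enzyme, extension
temperature): those wet-lab variables are not modelled mechanistically,
they only select a parameter bundle.  See docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "EfficiencyProfile",
    "PRESETS",
    "get_preset",
    "efficiency",
    "expected_amplification",
    "predicted_bias_curve",
    "fit_relative_efficiency",
    "simulate_pcr",
    "load_profile",
    "save_profile",
]


@dataclass(frozen=True)
class EfficiencyProfile:
    """Parameters of the two-shoulder logistic efficiency curve.

    p_max is the plateau duplication probability per cycle; (low_mid,
    low_scale) place the AT-side shoulder in %GC, (high_mid, high_scale)
    the GC-side shoulder.  A shoulder with scale None is disabled (its
    logistic factor is 1 everywhere).
    """

    p_max: float
    low_mid: float | None = None
    low_scale: float | None = None
    high_mid: float | None = None
    high_scale: float | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_max <= 1.0:
            raise ValueError("p_max must be in [0, 1]")
        for mid, scale, side in (
            (self.low_mid, self.low_scale, "low"),
            (self.high_mid, self.high_scale, "high"),
        ):
            if (scale is None) != (mid is None):
                raise ValueError(f"{side} shoulder needs both mid and scale (or neither)")
            if scale is not None and scale <= 0:
                raise ValueError(f"{side}_scale must be positive")

    def efficiency(self, g):
        """Duplication probability at %GC ``g`` (scalar or array)."""
        garr = np.asarray(g, dtype=float)
        if np.any((garr < 0) | (garr > 100)):
            raise ValueError("%GC must lie in [0, 100]")
        p = np.full_like(garr, self.p_max, dtype=float)
        if self.low_scale is not None:
            p = p * expit((garr - self.low_mid) / self.low_scale)
        if self.high_scale is not None:
            p = p * expit((self.high_mid - garr) / self.high_scale)
        return p if p.ndim else float(p)


def efficiency(g, profile: EfficiencyProfile):
    """Functional alias for :meth:`EfficiencyProfile.efficiency`."""
    return profile.efficiency(g)


# Calibrated emulations of the protocol families studied with the qPCR bias
# assay.  The shoulder placements reproduce the printed plateau endpoints
# and depletion scales of each protocol (standard fast-ramp Phusion:
# plateau ~11-56% GC, >65% GC depleted to ~1/100, <12% GC to ~1/10;
# slow-ramp: flat to ~84%; long denaturation + 2M betaine: plateau shifted
# right to ~23-90%; AccuPrime at 65C: plateau ~11-84%; at 60C: everything
# from ~2% to ~96% above one-tenth).  They are phenomenological fixtures,
# not mechanistic fits.
PRESETS: dict[str, EfficiencyProfile] = {
    "phusion-fast-ramp": EfficiencyProfile(
        0.95, low_mid=5.3, low_scale=2.23, high_mid=68.0, high_scale=4.5,
        name="phusion-fast-ramp",
    ),
    "phusion-slow-ramp": EfficiencyProfile(
        0.95, low_mid=6.0, low_scale=2.3, high_mid=96.0, high_scale=3.5,
        name="phusion-slow-ramp",
    ),
    "phusion-long-denat-betaine": EfficiencyProfile(
        0.95, low_mid=14.0, low_scale=3.5, high_mid=105.0, high_scale=5.0,
        name="phusion-long-denat-betaine",
    ),
    "accuprime-65": EfficiencyProfile(
        0.95, low_mid=4.0, low_scale=2.0, high_mid=99.0, high_scale=3.2,
        name="accuprime-65",
    ),
    "accuprime-60": EfficiencyProfile(
        0.95, low_mid=1.0, low_scale=2.0, high_mid=98.5, high_scale=4.2,
        name="accuprime-60",
    ),
    "pcr-free": EfficiencyProfile(0.0, name="pcr-free"),
}


def get_preset(name: str) -> EfficiencyProfile:
    try:
        return PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; choose from {sorted(PRESETS)}"
        ) from None


def expected_amplification(p: float, n_cycles: int) -> float:
    """Expected fold amplification after n cycles: (1+p)**n."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    if n_cycles < 0:
        raise ValueError("n_cycles must be >= 0")
    return float((1.0 + p) ** n_cycles)


def predicted_bias_curve(
    profile: EfficiencyProfile,
    n_cycles: int,
    anchor_gc: float = 50.0,
    bins: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Closed-form bias curve implied by the efficiency profile.

    value(g) = ((1 + p(g)) / (1 + p(anchor_gc)))**n, which is 1 at the
    anchor for any profile.  ``bins`` defaults to a 2%-spaced grid.
    """
    if bins is None:
        bins = np.arange(0.0, 101.0, 2.0)
    bins = np.asarray(bins, dtype=float)
    p = profile.efficiency(bins)
    p_anchor = profile.efficiency(anchor_gc)
    values = ((1.0 + p) / (1.0 + p_anchor)) ** n_cycles
    return pd.DataFrame({"bin_percent": bins, "relative_value": values})


def fit_relative_efficiency(observed, n_cycles: int) -> pd.DataFrame:
    """Invert an observed bias curve to per-cycle relative efficiency.

    r(g) = observed(g)**(1/n) is the per-cycle amplification factor of bin
    g relative to the anchor (r(anchor)=1).  Bins with non-positive
    observed values cannot be inverted and are flagged.  Accepts a
    BiasCurve or any DataFrame with bin_percent and relative_value.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    df = observed.table if hasattr(observed, "table") else observed
    bins = df["bin_percent"].to_numpy(dtype=float)
    vals = df["relative_value"].to_numpy(dtype=float)
    invertible = vals > 0
    r = np.full_like(vals, np.nan)
    r[invertible] = vals[invertible] ** (1.0 / n_cycles)
    return pd.DataFrame(
        {"bin_percent": bins, "rel_efficiency": r, "invertible": invertible}
    )


def simulate_pcr(
    copy_counts: np.ndarray,
    fragment_gc: np.ndarray,
    profile: EfficiencyProfile,
    n_cycles: int,
    rng: np.random.Generator | int,
) -> np.ndarray:
    """Stochastic branching-process amplification of a fragment pool.

    Each cycle, every existing copy of fragment i duplicates with
    probability p(gc_i): new copies ~ Binomial(current, p).  Deterministic
    given the generator/seed; the empirical mean matches (1+p)^n.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    counts = np.asarray(copy_counts, dtype=np.int64).copy()
    if (counts < 0).any():
        raise ValueError("copy counts must be >= 0")
    if n_cycles < 0:
        raise ValueError("n_cycles must be >= 0")
    p = np.broadcast_to(
        np.asarray(profile.efficiency(fragment_gc), dtype=float), counts.shape
    )
    for _ in range(n_cycles):
        counts = counts + rng.binomial(counts, p)
    return counts


# ---------------------------------------------------------------------------
# plain-text profile config
# ---------------------------------------------------------------------------

_FIELDS = ("p_max", "low_mid", "low_scale", "high_mid", "high_scale")


def save_profile(profile: EfficiencyProfile, path: str | Path) -> None:
    """Write a profile as flat key=value text (units: %GC, probabilities)."""
    with open(path, "w") as fh:
        fh.write("# gcbias efficiency profile\n")
        fh.write(f"name = {profile.name}\n")
        for f in _FIELDS:
            v = getattr(profile, f)
            fh.write(f"{f} = {'none' if v is None else repr(v)}\n")


def load_profile(path: str | Path) -> EfficiencyProfile:
    values: dict[str, object] = {}
    name = ""
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"malformed profile line: {line!r}")
            key, _, val = (s.strip() for s in line.partition("="))
            if key == "name":
                name = val
            elif key in _FIELDS:
                values[key] = None if val.lower() == "none" else float(val)
            else:
                raise ValueError(f"unknown profile key {key!r}")
    if "p_max" not in values:
        raise ValueError(f"profile {path} missing p_max")
    return EfficiencyProfile(name=name, **values)  # type: ignore[arg-type]
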