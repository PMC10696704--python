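"""CsCl buoyant-density gradient profile analysis.

After isopycnic centrifugation a SIP gradient is fractionated and each
fraction is assayed by qPCR for 16S rRNA gene copies, giving a
(density, copies) curve per sample. This module normalizes those
curves, locates the peak, labels fractions by the configured
light/heavy/ultra-heavy (L/H/UH) density windows, selects the 1-3
contiguous fractions carrying the most copies for sequencing, and runs
the cross-feeding control: the dual-labeled (13C+15N) peak must band
heavier than the 13C-only peak, otherwise label transfer to
heterotrophs is suspected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .config import RunConfig

__all__ = [
    "Fraction",
    "GradientProfile",
    "FractionSelection",
    "CrossfeedVerdict",
    "normalize_profile",
    "peak_density",
    "classify_fractions",
    "select_fractions",
    "crossfeed_check",
    "is_single_peaked",
]

TREATMENTS = ("13C+15N", "13C+14N", "12C+14N", "13C")


@dataclass(frozen=True)
class Fraction:
    fraction_id: str
    density: float  # g/mL
    copies: float  # 16S rRNA gene copies per mL (or normalized units)


@dataclass(frozen=True)
class GradientProfile:
    """One sample/treatment's gradient curve, ordered light to heavy."""

    sample_id: str
    treatment: str
    fractions: tuple[Fraction, ...]

    def __post_init__(self) -> None:
        if len(self.fractions) < 3:
            raise ValueError("a gradient profile needs at least 3 fractions")
        dens = self.densities
        if not np.all(np.diff(dens) > 0):
            raise ValueError("fraction densities must be strictly increasing")
        if np.any(self.copies < 0):
            raise ValueError("copies must be non-negative")

    @property
    def densities(self) -> np.ndarray:
        return np.array([f.density for f in self.fractions])

    @property
    def copies(self) -> np.ndarray:
        return np.array([f.copies for f in self.fractions])


@dataclass(frozen=True)
class FractionSelection:
    """The contiguous fractions of one window chosen for sequencing."""

    window: str
    fraction_ids: tuple[str, ...]
    summed_copies: float


@dataclass(frozen=True)
class CrossfeedVerdict:
    verdict: str  # "negligible" or "suspected"
    peak_density_13c15n: float
    peak_density_13c: float

    @property
    def density_shift(self) -> float:
        return self.peak_density_13c15n - self.peak_density_13c


def normalize_profile(profile: GradientProfile) -> GradientProfile:
    """Min-max rescale copies to [0, 1]; densities are untouched.

    The minimum maps to 0 and the maximum to 1, so normalization is
    idempotent. Raises for a flat profile (all copies equal), where the
    scaling is degenerate.
    """
    copies = profile.copies
    lo, hi = copies.min(), copies.max()
    if hi == lo:
        raise ValueError("cannot min-max normalize a profile with all copies equal")
    scaled = (copies - lo) / (hi - lo)
    fractions = tuple(
        replace(f, copies=float(s)) for f, s in zip(profile.fractions, scaled)
    )
    return replace(profile, fractions=fractions)


def peak_density(profile: GradientProfile) -> float:
    """Density of the maximum-copies fraction; ties go to the heavier one."""
    copies = profile.copies
    # argmax returns the first maximum; reversing makes ties resolve heavy.
    idx = len(copies) - 1 - int(np.argmax(copies[::-1]))
    return float(profile.fractions[idx].density)


def classify_fractions(
    profile: GradientProfile, config: RunConfig | None = None
) -> list[str]:
    """Label each fraction L/H/UH/outside by its density window.

    Windows are half-open [lower, upper), so a density exactly on a
    shared boundary belongs to the upper (heavier) window.
    """
    config = config or RunConfig()
    labels = []
    for f in profile.fractions:
        for name in ("L", "H", "UH"):
            if f.density in config.density_windows[name]:
                labels.append(name)
                break
        else:
            labels.append("outside")
    return labels


def select_fractions(
    profile: GradientProfile,
    window: str,
    config: RunConfig | None = None,
    k: int | None = None,
) -> FractionSelection:
    """Pick the contiguous run of fractions with the most copies in a window.

    ``k`` is the run length, defaulting to min(3, fractions available in
    the window); explicit overrides must be 1, 2 or 3. Ties are broken
    toward heavier densities. Raises if the window holds no fraction.
    """
    config = config or RunConfig()
    labels = classify_fractions(profile, config)
    idx = [i for i, lab in enumerate(labels) if lab == window]
    if not idx:
        raise ValueError(f"no fractions fall in window {window!r}")
    if k is None:
        k = min(3, len(idx))
    elif k not in (1, 2, 3):
        raise ValueError(f"k must be 1, 2 or 3, got {k}")
    k = min(k, len(idx))

    copies = profile.copies
    best_start, best_sum = None, -np.inf
    # in-window fractions are contiguous in density order because the
    # window is an interval; scan all contiguous runs of length k
    for s in range(len(idx) - k + 1):
        run = idx[s : s + k]
        total = float(copies[run].sum())
        if total >= best_sum:  # >= resolves ties toward heavier runs
            best_start, best_sum = s, total
    chosen = idx[best_start : best_start + k]
    return FractionSelection(
        window=window,
        fraction_ids=tuple(profile.fractions[i].fraction_id for i in chosen),
        summed_copies=best_sum,
    )


def is_single_peaked(profile: GradientProfile) -> bool:
    """True if copies rise then fall after a 3-point median smoothing."""
    c = profile.copies
    smoothed = c.copy()
    for i in range(1, len(c) - 1):
        smoothed[i] = np.median(c[i - 1 : i + 2])
    d = np.diff(smoothed)
    signs = np.sign(d[d != 0])
    # a single peak means no sign change from -1 back to +1
    for a, b in zip(signs, signs[1:]):
        if a < 0 < b:
            return False
    return True


def crossfeed_check(
    profile_13c15n: GradientProfile, profile_13c: GradientProfile
) -> CrossfeedVerdict:
    """Compare dual-label vs 13C-only peak densities.

    Cross-feeding is negligible iff the 13C+15N peak bands strictly
    heavier than the 13C-only peak (the 15N shift shows the same
    autotrophic populations took up both tracers directly). Warns if
    either profile is not single-peaked.
    """
    for p in (profile_13c15n, profile_13c):
        if not is_single_peaked(p):
            warnings.warn(
                f"profile {p.sample_id}/{p.treatment} is not single-peaked; "
                "peak comparison may be unreliable",
                stacklevel=2,
            )
    d_dual = peak_density(profile_13c15n)
    d_13c = peak_density(profile_13c)
    verdict = "negligible" if d_dual > d_13c else "suspected"
    return CrossfeedVerdict(
        verdict=verdict, peak_density_13c15n=d_dual, peak_density_13c=d_13c
    )
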