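"""Per-taxon 13C-incorporation calls from L/H/UH relative abundances.

A taxon that fixed 13C-labeled DIC shifts its DNA into the heavy
fraction, so its relative abundance in H is similar to or higher than
in L; an unlabeled taxon's relative abundance declines sharply from L
to H. This module quantifies that qualitative rule with two explicit
H/L ratio thresholds: unlabeled when H/L <= theta_unlabeled (default
0.5, a two-fold decline), labeled when H/L >= theta_labeled (default
0.8), ambiguous in between, and insufficient when the taxon is below
an abundance floor in every fraction. The UH/L ratio is reported as
corroborating evidence but does not enter the verdict.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .config import RunConfig

__all__ = [
    "TaxonFractionAbundance",
    "LabelingCall",
    "call_labeling",
    "call_labeling_table",
]


@dataclass(frozen=True)
class TaxonFractionAbundance:
    """One taxon's relative abundance in the L, H and (optionally) UH fractions."""

    taxon: str
    rel_abundance_L: float
    rel_abundance_H: float
    rel_abundance_UH: float | None = None

    def __post_init__(self) -> None:
        for name in ("rel_abundance_L", "rel_abundance_H", "rel_abundance_UH"):
            v = getattr(self, name)
            if v is not None and not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass(frozen=True)
class LabelingCall:
    taxon: str
    verdict: str  # labeled | unlabeled | ambiguous | insufficient
    hl_ratio: float  # math.inf when L == 0 < H
    uh_l_ratio: float | None = None


def call_labeling(
    rec: TaxonFractionAbundance, config: RunConfig | None = None
) -> LabelingCall:
    """Call one taxon from its H/L (and optional UH/L) ratio.

    L = 0 with H > 0 is reported as labeled with an infinite ratio.
    Both L and H below ``config.abundance_floor`` yields "insufficient".
    """
    config = config or RunConfig()
    L, H = rec.rel_abundance_L, rec.rel_abundance_H

    uh_ratio = None
    if rec.rel_abundance_UH is not None:
        if L > 0:
            uh_ratio = rec.rel_abundance_UH / L
        elif rec.rel_abundance_UH > 0:
            uh_ratio = math.inf
        else:
            uh_ratio = 0.0

    if L < config.abundance_floor and H < config.abundance_floor:
        ratio = H / L if L > 0 else (math.inf if H > 0 else 0.0)
        return LabelingCall(rec.taxon, "insufficient", ratio, uh_ratio)

    if L == 0:
        # H must be > 0 here (floor check above); all mass is heavy
        return LabelingCall(rec.taxon, "labeled", math.inf, uh_ratio)

    ratio = H / L
    if ratio >= config.theta_labeled:
        verdict = "labeled"
    elif ratio <= config.theta_unlabeled:
        verdict = "unlabeled"
    else:
        verdict = "ambiguous"
    return LabelingCall(rec.taxon, verdict, ratio, uh_ratio)


def call_labeling_table(
    table: Sequence[TaxonFractionAbundance],
    config: RunConfig | None = None,
    min_abundance: float = 0.005,
) -> list[LabelingCall]:
    """Call every sufficiently abundant taxon in a table.

    Taxa below ``min_abundance`` in *all* fractions are excluded before
    calling (default 0.005, i.e. the 0.5%-in-at-least-one-fraction
    screen applied to SIP amplicon data). Output is sorted by verdict
    (labeled, ambiguous, unlabeled, insufficient) and then by descending
    peak abundance.
    """
    if not table:
        raise ValueError("labeling table is empty")
    config = config or RunConfig()

    def peak(rec: TaxonFractionAbundance) -> float:
        vals = [rec.rel_abundance_L, rec.rel_abundance_H]
        if rec.rel_abundance_UH is not None:
            vals.append(rec.rel_abundance_UH)
        return max(vals)

    kept = [rec for rec in table if peak(rec) > min_abundance or min_abundance == 0]
    calls = [(call_labeling(rec, config), peak(rec)) for rec in kept]
    order = {"labeled": 0, "ambiguous": 1, "unlabeled": 2, "insufficient": 3}
    calls.sort(key=lambda cp: (order[cp[0].verdict], -cp[1]))
    return [c for c, _ in calls]
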