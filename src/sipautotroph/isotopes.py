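"""Stable-isotope arithmetic and DIC assimilation rates.

Implements the delta-notation chain used to turn end-point delta-13C
measurements of particulate organic carbon (POC) into a dissolved
inorganic carbon (DIC) assimilation rate for a 13C-bicarbonate tracer
incubation:

    R_sample = (delta13C / 1000 + 1) * R_VPDB
    n        = R_sample / (R_sample + 1)
    rate     = (POC_t * n_t - POC_0 * n_0) / t * (Ca + Cs) / Cs

where ``n`` is the 13C atom fraction, ``R_VPDB`` = 0.0112372 is the
13C/12C ratio of the Vienna Peedee Belemnite standard, ``POC_0`` and
``POC_t`` are POC concentrations (umol C/L) at the start and end of
the incubation of duration ``t`` (days), and ``Ca``/``Cs`` are the
ambient and added (tracer) DIC concentrations (umol/L). The factor
(Ca + Cs) / Cs corrects for dilution of the 13C tracer in the ambient
DIC pool, so the result is the assimilation rate of *total* DIC in
umol C L^-1 day^-1.

A rate is below detection (BDL) when the delta-13C shift over the
incubation is smaller than the IRMS analytical precision (0.1 permil
by default); the detection limit reported alongside is the rate that
a shift of exactly one precision unit would imply.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = [
    "R_VPDB",
    "TracerIncubation",
    "RateResult",
    "ReplicateSummary",
    "delta_to_ratio",
    "ratio_to_delta",
    "ratio_to_atom_fraction",
    "atom_fraction_to_ratio",
    "delta_to_atom_fraction",
    "atom_fraction_to_delta",
    "dic_assimilation_rate",
    "detection_limit_rate",
    "average_replicates",
]

#: 13C/12C ratio of the Vienna Peedee Belemnite reference standard.
R_VPDB = 0.0112372


def delta_to_ratio(delta: float) -> float:
    """Convert delta-13C (permil vs VPDB) to the 13C/12C ratio R_sample.

    Raises ValueError for delta <= -1000 permil, which would imply a
    non-positive isotope ratio.
    """
    if delta <= -1000.0:
        raise ValueError(
            f"delta13C = {delta} permil implies a non-positive 13C/12C ratio"
        )
    return (delta / 1000.0 + 1.0) * R_VPDB


def ratio_to_delta(r: float) -> float:
    """Inverse of :func:`delta_to_ratio`: 13C/12C ratio to permil vs VPDB."""
    if r <= 0:
        raise ValueError(f"isotope ratio must be positive, got {r}")
    return (r / R_VPDB - 1.0) * 1000.0


def ratio_to_atom_fraction(r: float) -> float:
    """13C/12C ratio to 13C atom fraction n = R / (R + 1), in [0, 1)."""
    if r < 0:
        raise ValueError(f"isotope ratio must be non-negative, got {r}")
    return r / (r + 1.0)


def atom_fraction_to_ratio(n: float) -> float:
    """Inverse of :func:`ratio_to_atom_fraction`: n in [0, 1) to R = n/(1-n)."""
    if not 0 <= n < 1:
        raise ValueError(f"atom fraction must lie in [0, 1), got {n}")
    return n / (1.0 - n)


def delta_to_atom_fraction(delta: float) -> float:
    """delta-13C (permil) straight to 13C atom fraction."""
    return ratio_to_atom_fraction(delta_to_ratio(delta))


def atom_fraction_to_delta(n: float) -> float:
    """13C atom fraction straight back to delta-13C (permil)."""
    return ratio_to_delta(atom_fraction_to_ratio(n))


@dataclass(frozen=True)
class TracerIncubation:
    """One bottle's record for rate computation.

    Attributes
    ----------
    delta_0, delta_t:
        delta-13C of POC (permil vs VPDB) at the start and end.
    poc_0, poc_t:
        POC concentration (umol C/L) at the start and end.
    t:
        Incubation time in days.
    ca_dic, cs_dic:
        Ambient and added DIC concentrations (umol/L).
    """

    delta_0: float
    delta_t: float
    poc_0: float
    poc_t: float
    t: float
    ca_dic: float
    cs_dic: float

    def __post_init__(self) -> None:
        if self.poc_0 <= 0 or self.poc_t <= 0:
            raise ValueError("POC concentrations must be positive")
        if self.t <= 0:
            raise ValueError("incubation time must be positive")
        if self.cs_dic <= 0:
            raise ValueError("added DIC concentration must be positive")
        if self.ca_dic < 0:
            raise ValueError("ambient DIC concentration must be non-negative")


@dataclass(frozen=True)
class RateResult:
    """A DIC assimilation rate with below-detection handling.

    ``rate`` is in umol C L^-1 day^-1 and is None when flagged BDL;
    ``detection_limit`` is the smallest resolvable rate given the
    delta-13C analytical precision.
    """

    rate: float | None
    bdl: bool
    detection_limit: float

    @property
    def is_bdl(self) -> bool:
        return self.bdl


def detection_limit_rate(inc: TracerIncubation, delta_precision: float = 0.1) -> float:
    """Smallest rate resolvable at the given delta-13C precision (permil).

    Defined as the rate implied by an end-point delta-13C shift of exactly
    one precision unit at unchanged POC.
    """
    n0 = delta_to_atom_fraction(inc.delta_0)
    n_min = delta_to_atom_fraction(inc.delta_0 + delta_precision)
    dilution = (inc.ca_dic + inc.cs_dic) / inc.cs_dic
    return inc.poc_0 * (n_min - n0) / inc.t * dilution


def dic_assimilation_rate(
    inc: TracerIncubation, delta_precision: float = 0.1
) -> RateResult:
    """Compute the DIC assimilation rate for one incubation bottle.

    The raw rate is (POC_t * n_t - POC_0 * n_0) / t scaled by the tracer
    dilution factor (Ca + Cs) / Cs. When the observed delta-13C shift is
    smaller than ``delta_precision`` the result is flagged BDL and
    ``rate`` is None. A computed rate more negative than minus the
    detection limit indicates inconsistent inputs and raises ValueError;
    small negative rates within the detection limit are clamped to BDL.
    """
    n0 = delta_to_atom_fraction(inc.delta_0)
    nt = delta_to_atom_fraction(inc.delta_t)
    dilution = (inc.ca_dic + inc.cs_dic) / inc.cs_dic
    raw = (inc.poc_t * nt - inc.poc_0 * n0) / inc.t * dilution
    limit = detection_limit_rate(inc, delta_precision)

    if raw < -limit:
        raise ValueError(
            f"computed rate {raw:.3e} is below -detection_limit ({-limit:.3e}); "
            "inputs are inconsistent (delta-13C decreased beyond analytical precision)"
        )
    if abs(inc.delta_t - inc.delta_0) < delta_precision:
        return RateResult(rate=None, bdl=True, detection_limit=limit)
    return RateResult(rate=max(raw, 0.0), bdl=False, detection_limit=limit)


@dataclass(frozen=True)
class ReplicateSummary:
    """Mean and sample sd over non-BDL replicate rates; ND when all BDL."""

    mean: float | None
    sd: float | None
    n: int
    all_bdl: bool

    @property
    def is_nd(self) -> bool:
        return self.all_bdl


def average_replicates(
    rates: Sequence[RateResult | float | None],
) -> ReplicateSummary:
    """Average replicate rates, skipping BDL entries.

    Accepts RateResult objects, bare floats, or None (BDL). Returns the
    mean and sample standard deviation (n-1 denominator) of the non-BDL
    replicates; when every replicate is BDL the summary is ND (no data),
    mirroring how an all-below-detection condition is reported.
    """
    if len(rates) == 0:
        raise ValueError("cannot average an empty replicate list")
    values: list[float] = []
    for r in rates:
        if r is None:
            continue
        if isinstance(r, RateResult):
            if r.bdl:
                continue
            values.append(float(r.rate))
        else:
            values.append(float(r))
    if not values:
        return ReplicateSummary(mean=None, sd=None, n=0, all_bdl=True)
    n = len(values)
    mean = sum(values) / n
    sd = math.sqrt(sum((v - mean) ** 2 for v in values) / (n - 1)) if n > 1 else None
    return ReplicateSummary(mean=mean, sd=sd, n=n, all_bdl=False)
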