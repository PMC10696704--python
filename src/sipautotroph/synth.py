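"""Synthetic inputs with the statistical structure the analysis assumes.

Every downstream stage of the pipeline is testable without sequencing
or IRMS data because these generators plant known truth:

* :func:`simulate_gradient` — single-peaked CsCl gradient curves.
  Unlabeled DNA bands at a GC-dependent buoyant density
  (1.660 + 0.098*GC g/mL); full 13C labeling shifts the band by
  +0.036 g/mL and full 15N labeling by a further +0.016 g/mL.
  Per-fraction copies get lognormal multiplicative noise (qPCR-like).
* :func:`simulate_tracer` — POC / delta-13C end points generated by
  running the DIC assimilation-rate mass balance *forward* from a known
  true rate, with Gaussian noise on the delta values (IRMS-like,
  default sd 0.1 permil). Defaults follow the incubation design this
  package targets: 3 mM added NaH13CO3 (cs_dic = 3000 umol/L) and a
  1-day incubation.
* :func:`simulate_ko_table` — KO-by-3-library abundance tables with
  planted core / enriched / diluted structure on a per-million scale.
* :func:`simulate_fraction_taxa` — taxon relative abundances across the
  L/H/UH fractions with planted labeled/unlabeled states.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .config import RunConfig
from .gradient import Fraction, GradientProfile
from .isotopes import (
    TracerIncubation,
    atom_fraction_to_delta,
    delta_to_atom_fraction,
)
from .labeling import TaxonFractionAbundance, call_labeling
from .ternary import PER_MILLION, KOAbundanceTriple, classify_ko

__all__ = [
    "PopulationSpec",
    "TracerSimSpec",
    "SimulatedTracer",
    "simulate_gradient",
    "simulate_tracer",
    "simulate_ko_table",
    "simulate_fraction_taxa",
    "RHO_BASE",
    "RHO_PER_GC",
    "SHIFT_C13",
    "SHIFT_N15",
]

# Buoyant density model for double-stranded DNA in CsCl (g/mL):
# rho = RHO_BASE + RHO_PER_GC * GC, plus labeling shifts for full
# heavy-isotope substitution. Standard SIP physical values, exposed as
# parameters because real shifts depend on the degree of labeling.
RHO_BASE = 1.660
RHO_PER_GC = 0.098
SHIFT_C13 = 0.036
SHIFT_N15 = 0.016

LABELING_STATES = ("unlabeled", "C13", "C13N15")


@dataclass(frozen=True)
class PopulationSpec:
    """One banded population in a gradient.

    ``gc_content`` is the genomic GC fraction, ``abundance`` the total
    16S copies/mL the population contributes across the gradient, and
    ``band_sigma`` the Gaussian band width in g/mL.
    """

    name: str
    gc_content: float
    labeling_state: str = "unlabeled"
    abundance: float = 1e8
    band_sigma: float = 0.003

    def __post_init__(self) -> None:
        if not 0 <= self.gc_content <= 1:
            raise ValueError(f"gc_content must be in [0, 1], got {self.gc_content}")
        if self.labeling_state not in LABELING_STATES:
            raise ValueError(
                f"labeling_state must be one of {LABELING_STATES}, got {self.labeling_state!r}"
            )
        if self.abundance < 0:
            raise ValueError("abundance must be >= 0")
        if self.band_sigma <= 0:
            raise ValueError("band_sigma must be positive")

    def band_center(
        self, shift_c13: float = SHIFT_C13, shift_n15: float = SHIFT_N15
    ) -> float:
        rho = RHO_BASE + RHO_PER_GC * self.gc_content
        if self.labeling_state in ("C13", "C13N15"):
            rho += shift_c13
        if self.labeling_state == "C13N15":
            rho += shift_n15
        return rho


def simulate_gradient(
    populations: Sequence[PopulationSpec],
    fraction_densities: Sequence[float],
    noise_cv: float = 0.0,
    seed: int = 0,
    sample_id: str = "synthetic",
    treatment: str = "13C+15N",
    shift_c13: float = SHIFT_C13,
    shift_n15: float = SHIFT_N15,
) -> GradientProfile:
    """Simulate a fractionated CsCl gradient for a mixed community.

    Each population contributes a Gaussian band centered at its
    (GC- and labeling-dependent) buoyant density; per-fraction copies
    are the summed band masses times lognormal multiplicative noise
    with coefficient of variation ``noise_cv``.
    """
    if not populations:
        raise ValueError("population list is empty")
    dens = np.asarray(fraction_densities, dtype=float)
    if dens.ndim != 1 or len(dens) < 3:
        raise ValueError("need at least 3 fraction densities")
    if not np.all(np.diff(dens) > 0):
        raise ValueError("fraction densities must be strictly increasing")
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")

    copies = np.zeros_like(dens)
    for pop in populations:
        center = pop.band_center(shift_c13, shift_n15)
        w = np.exp(-0.5 * ((dens - center) / pop.band_sigma) ** 2)
        total = w.sum()
        if total > 0:
            copies += pop.abundance * w / total

    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        sigma = np.sqrt(np.log1p(noise_cv**2))
        noise = rng.lognormal(mean=-sigma**2 / 2, sigma=sigma, size=len(dens))
        copies = copies * noise

    fractions = tuple(
        Fraction(fraction_id=f"F{i + 1}", density=float(d), copies=float(c))
        for i, (d, c) in enumerate(zip(dens, copies))
    )
    return GradientProfile(sample_id=sample_id, treatment=treatment, fractions=fractions)


@dataclass(frozen=True)
class TracerSimSpec:
    """Forward-model parameters for one simulated tracer incubation.

    ``true_rate`` is the DIC assimilation rate (umol C L^-1 day^-1) the
    simulation encodes; ``poc_0``/``delta_0`` the initial POC pool;
    ``ca_dic``/``cs_dic`` the ambient and added DIC (umol/L, default
    3000 added = 3 mM bicarbonate spike); ``delta_noise_sd`` the IRMS
    noise on each delta-13C reading (permil, default 0.1).
    """

    true_rate: float
    poc_0: float = 10.0
    delta_0: float = -25.0
    t: float = 1.0
    ca_dic: float = 2000.0
    cs_dic: float = 3000.0
    delta_noise_sd: float = 0.1
    tracer_atom_fraction: float = 0.99

    def __post_init__(self) -> None:
        if self.true_rate < 0:
            raise ValueError("true_rate must be >= 0")
        if self.poc_0 <= 0 or self.ca_dic < 0 or self.cs_dic <= 0:
            raise ValueError("concentrations must be positive (ca_dic >= 0)")
        if self.t <= 0:
            raise ValueError("incubation time must be positive")
        if self.delta_noise_sd < 0:
            raise ValueError("delta_noise_sd must be >= 0")


@dataclass(frozen=True)
class SimulatedTracer:
    """A simulated incubation plus its hidden true rate."""

    incubation: TracerIncubation
    true_rate: float


def simulate_tracer(spec: TracerSimSpec, seed: int = 0) -> SimulatedTracer:
    """Run the assimilation-rate mass balance forward from a known rate.

    The 13C inventory of POC grows by true_rate * t * Cs/(Ca+Cs) (the
    inverse of the tracer dilution correction), POC itself grows by
    true_rate * t (all fixed carbon retained as POC), and the end-point
    atom fraction is converted back to delta-13C. Gaussian noise with
    sd ``delta_noise_sd`` is then added to both delta readings.
    """
    n0 = delta_to_atom_fraction(spec.delta_0)
    poc_t = spec.poc_0 + spec.true_rate * spec.t
    c13_t = (
        spec.poc_0 * n0
        + spec.true_rate * spec.t * spec.cs_dic / (spec.ca_dic + spec.cs_dic)
    )
    nt = c13_t / poc_t
    if nt >= 1:
        raise ValueError(
            f"simulated end-point atom fraction {nt:.3f} >= 1; "
            "rate/time/DIC parameters are unphysical"
        )
    delta_t = atom_fraction_to_delta(nt)

    delta_0, delta_t_obs = spec.delta_0, delta_t
    if spec.delta_noise_sd > 0:
        rng = np.random.default_rng(seed)
        delta_0 = spec.delta_0 + rng.normal(0.0, spec.delta_noise_sd)
        delta_t_obs = delta_t + rng.normal(0.0, spec.delta_noise_sd)

    inc = TracerIncubation(
        delta_0=float(delta_0),
        delta_t=float(delta_t_obs),
        poc_0=spec.poc_0,
        poc_t=float(poc_t),
        t=spec.t,
        ca_dic=spec.ca_dic,
        cs_dic=spec.cs_dic,
    )
    return SimulatedTracer(incubation=inc, true_rate=spec.true_rate)


def _counts_per_library(value: int | Sequence[int], name: str) -> np.ndarray:
    arr = np.atleast_1d(np.asarray(value, dtype=int))
    if arr.size == 1:
        arr = np.repeat(arr, 3)
    if arr.size != 3 or np.any(arr < 0):
        raise ValueError(f"{name} must be a count or three counts >= 0")
    return arr


def simulate_ko_table(
    n_core: int,
    n_enriched: int | Sequence[int] = 0,
    n_diluted: int | Sequence[int] = 0,
    fold: float = 4.0,
    noise_cv: float = 0.0,
    seed: int = 0,
    config: RunConfig | None = None,
) -> tuple[list[KOAbundanceTriple], dict[str, str]]:
    """Plant core / enriched / diluted KOs across three libraries.

    Returns the table and a ``{ko_id: true_category}`` mapping. Core KOs
    get three abundances within a <1.24-fold spread; enriched (diluted)
    KOs are exactly ``fold`` times above (below) the more extreme of the
    two other libraries, which must exceed the configured fold
    threshold. Abundances are on a per-million scale: a common factor
    scales all cells so the mean library total is one million (the
    shortfall of any one library is the unannotated remainder of its
    gene catalog, so columns are not re-closed — re-closing would
    distort the planted cross-library ratios).

    At zero noise the planted classes are guaranteed recoverable by
    :func:`sipautotroph.ternary.classify_ko` and the generator verifies
    this before returning.
    """
    config = config or RunConfig()
    if fold <= config.fold_threshold:
        raise ValueError(
            f"fold ({fold}) must exceed the configured fold_threshold "
            f"({config.fold_threshold}) or planted classes are not recoverable"
        )
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    n_enr = _counts_per_library(n_enriched, "n_enriched")
    n_dil = _counts_per_library(n_diluted, "n_diluted")
    if n_core < 0:
        raise ValueError("n_core must be >= 0")
    n_total = n_core + int(n_enr.sum() + n_dil.sum())
    if n_total == 0:
        raise ValueError("no KOs requested")

    rng = np.random.default_rng(seed)
    rows: list[np.ndarray] = []
    truth: dict[str, str] = {}
    ids: list[str] = []

    def add(values: np.ndarray, category: str) -> None:
        ko_id = f"K{len(ids) + 1:05d}"
        ids.append(ko_id)
        truth[ko_id] = category
        rows.append(values)

    for _ in range(n_core):
        base = rng.lognormal(mean=0.0, sigma=1.0)
        add(base * rng.uniform(0.9, 1.11, size=3), "core")
    for lib in range(3):
        for _ in range(n_enr[lib]):
            base = rng.lognormal(mean=0.0, sigma=1.0)
            others = base * rng.uniform(0.8, 1.25, size=2)
            vals = np.empty(3)
            vals[[j for j in range(3) if j != lib]] = others
            vals[lib] = fold * others.max()
            add(vals, f"enriched({lib + 1})")
    for lib in range(3):
        for _ in range(n_dil[lib]):
            base = rng.lognormal(mean=0.0, sigma=1.0)
            others = base * rng.uniform(0.8, 1.25, size=2)
            vals = np.empty(3)
            vals[[j for j in range(3) if j != lib]] = others
            vals[lib] = others.min() / fold
            add(vals, f"diluted({lib + 1})")

    arr = np.vstack(rows)
    if noise_cv > 0:
        sigma = np.sqrt(np.log1p(noise_cv**2))
        arr = arr * rng.lognormal(mean=-sigma**2 / 2, sigma=sigma, size=arr.shape)
    # common per-million scaling preserves every cross-library ratio
    arr = arr * (PER_MILLION / arr.sum(axis=0).mean())

    triples = [
        KOAbundanceTriple(ko_id, *map(float, row)) for ko_id, row in zip(ids, arr)
    ]
    if noise_cv == 0:
        for t in triples:
            got = classify_ko(t, config).category
            if got != truth[t.ko_id]:
                raise RuntimeError(
                    f"internal error: planted {truth[t.ko_id]} KO {t.ko_id} "
                    f"classified as {got} at zero noise"
                )
    return triples, truth


def simulate_fraction_taxa(
    labeled_taxa: Sequence[str],
    unlabeled_taxa: Sequence[str] = (),
    seed: int = 0,
    config: RunConfig | None = None,
) -> tuple[list[TaxonFractionAbundance], dict[str, str]]:
    """Plant labeled/unlabeled taxa in an L/H/UH relative-abundance table.

    Labeled taxa keep or increase their relative abundance from L to H
    (and UH); unlabeled taxa decline at least two-fold from L to H. Each
    fraction's relative abundances sum to 1 (compositional closure).

    Closure couples the taxa: the L-mass-weighted mean of all H/L ratios
    is identically 1, so a community containing unlabeled taxa but no
    labeled taxa cannot show a two-fold decline for every taxon, and
    such a request raises ValueError. The generator widens the raw
    labeled/unlabeled contrast until the planted verdicts survive
    closure exactly (guaranteed recovery at zero noise).
    """
    labeled = list(labeled_taxa)
    unlabeled = list(unlabeled_taxa)
    names = labeled + unlabeled
    if not names:
        raise ValueError("at least one taxon is required")
    if len(set(names)) != len(names):
        raise ValueError("taxon names must be unique")
    if unlabeled and not labeled:
        raise ValueError(
            "a community with unlabeled taxa but no labeled taxa is not "
            "representable under per-fraction closure: relative H/L ratios "
            "are pinned near 1 when nothing shifts into the heavy fractions"
        )
    config = config or RunConfig()
    truth = {t: "labeled" for t in labeled} | {t: "unlabeled" for t in unlabeled}

    margin = 8.0
    while margin <= 2**24:
        rng = np.random.default_rng(seed)
        raw = np.empty((len(names), 3))  # columns: L, H, UH
        for i, name in enumerate(names):
            base = rng.uniform(0.5, 1.5)
            if truth[name] == "labeled":
                # heavy-dominant: L carries only 1/margin of the band
                # H/UH multipliers stay within 1.15x of each other so the
                # closed H/L ratio (~u_i / weighted-mean u) stays >= 0.87
                # even when every taxon in the community is labeled
                raw[i] = [
                    base / margin,
                    base * rng.uniform(1.0, 1.15),
                    base * rng.uniform(1.0, 1.15),
                ]
            else:
                h = base * rng.uniform(0.8, 1.0) / margin
                raw[i] = [base, h, h * rng.uniform(0.5, 1.0)]
        closed = raw / raw.sum(axis=0)

        records = [
            TaxonFractionAbundance(
                taxon=name,
                rel_abundance_L=float(closed[i, 0]),
                rel_abundance_H=float(closed[i, 1]),
                rel_abundance_UH=float(closed[i, 2]),
            )
            for i, name in enumerate(names)
        ]
        verdicts = {r.taxon: call_labeling(r, config).verdict for r in records}
        if all(verdicts[t] == truth[t] for t in names):
            return records, truth
        margin *= 2.0

    raise RuntimeError(
        "could not realize the planted labeling structure under closure; "
        "the community composition is too unbalanced"
    )
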