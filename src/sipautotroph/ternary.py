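"""Three-library KO classification: core, enriched, diluted.

Comparing one KEGG ortholog's normalized relative abundance (per
million) across three metagenomic libraries:

* **core** — the spread across libraries is less than two-fold
  (max/min < fold_threshold, all abundances positive);
* **enriched in library i** — abundance in i is at least two-fold
  higher than in both other libraries;
* **diluted in library i** — abundance in i is at least two-fold lower
  than in both other libraries;
* **unclassified** — none of the three rules fires (possible, e.g.
  (1, 1.5, 2.5)).

The two-fold constant is ``RunConfig.fold_threshold``. All comparisons
are written multiplicatively (a >= fold * b), never as divisions, so
zero abundances are safe: a KO present in exactly one library is
enriched there. When a triple satisfies both an enriched and a diluted
rule (e.g. (1, 3, 9)), enriched takes precedence.

Barycentric (ternary) coordinates a_i / sum(a) place each KO in the
simplex for plotting; core KOs sit near the centroid, enriched KOs near
their library's vertex.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .config import RunConfig

__all__ = [
    "KOAbundanceTriple",
    "TernaryClass",
    "normalize_per_million",
    "classify_ko",
    "classify_ko_table",
    "ternary_coordinates",
    "summarize_categories",
    "filter_high_abundance",
    "plot_ternary",
]

PER_MILLION = 1_000_000.0


@dataclass(frozen=True)
class KOAbundanceTriple:
    """One KO's relative abundance (per million) in three libraries."""

    ko_id: str
    a1: float
    a2: float
    a3: float

    def __post_init__(self) -> None:
        if min(self.a1, self.a2, self.a3) < 0:
            raise ValueError(f"abundances must be >= 0 for {self.ko_id}")

    @property
    def values(self) -> tuple[float, float, float]:
        return (self.a1, self.a2, self.a3)


@dataclass(frozen=True)
class TernaryClass:
    ko_id: str
    category: str  # "core", "enriched(1|2|3)", "diluted(1|2|3)", "unclassified"
    ternary_coords: tuple[float, float, float]


def normalize_per_million(
    triples: Sequence[KOAbundanceTriple],
) -> list[KOAbundanceTriple]:
    """Rescale each library column so its abundances total one million."""
    if not triples:
        return []
    arr = np.array([t.values for t in triples], dtype=float)
    sums = arr.sum(axis=0)
    if np.any(sums == 0):
        raise ValueError("a library has zero total abundance; cannot normalize")
    arr = arr / sums * PER_MILLION
    return [
        KOAbundanceTriple(t.ko_id, *map(float, row)) for t, row in zip(triples, arr)
    ]


def ternary_coordinates(triple: KOAbundanceTriple) -> tuple[float, float, float]:
    """Barycentric coordinates a_i / (a1+a2+a3); requires a positive sum."""
    total = sum(triple.values)
    if total <= 0:
        raise ValueError(f"KO {triple.ko_id} has zero total abundance")
    return tuple(v / total for v in triple.values)


def classify_ko(
    triple: KOAbundanceTriple, config: RunConfig | None = None
) -> TernaryClass:
    """Apply the two-fold core/enriched/diluted rule to one KO."""
    config = config or RunConfig()
    f = config.fold_threshold
    a = triple.values
    if max(a) == 0:
        raise ValueError(f"KO {triple.ko_id} is absent from all three libraries")

    coords = ternary_coordinates(triple)

    if min(a) > 0 and max(a) < f * min(a):
        return TernaryClass(triple.ko_id, "core", coords)
    for i in range(3):
        others = [a[j] for j in range(3) if j != i]
        if a[i] >= f * max(others):
            return TernaryClass(triple.ko_id, f"enriched({i + 1})", coords)
    for i in range(3):
        others = [a[j] for j in range(3) if j != i]
        if f * a[i] <= min(others):
            return TernaryClass(triple.ko_id, f"diluted({i + 1})", coords)
    return TernaryClass(triple.ko_id, "unclassified", coords)


def classify_ko_table(
    triples: Sequence[KOAbundanceTriple],
    config: RunConfig | None = None,
    normalize: bool = True,
) -> list[TernaryClass]:
    """Classify a whole KO table, normalizing to per-million first by default."""
    if normalize:
        triples = normalize_per_million(triples)
    return [classify_ko(t, config) for t in triples]


def summarize_categories(
    classes: Sequence[TernaryClass], triples: Sequence[KOAbundanceTriple]
) -> pd.DataFrame:
    """Per-category KO counts and per-library total abundance.

    ``classes`` and ``triples`` must carry the same KO ids. The returned
    frame has one row per category with columns ``n_kos`` and
    ``abundance_lib1..3``; the abundance columns sum (over categories)
    to each library's total.
    """
    by_id = {t.ko_id: t for t in triples}
    if set(c.ko_id for c in classes) != set(by_id):
        raise ValueError("classes and triples carry different KO ids")
    rows: dict[str, dict[str, float]] = {}
    for c in classes:
        t = by_id[c.ko_id]
        row = rows.setdefault(
            c.category,
            {"n_kos": 0, "abundance_lib1": 0.0, "abundance_lib2": 0.0, "abundance_lib3": 0.0},
        )
        row["n_kos"] += 1
        row["abundance_lib1"] += t.a1
        row["abundance_lib2"] += t.a2
        row["abundance_lib3"] += t.a3
    df = pd.DataFrame.from_dict(rows, orient="index").sort_values(
        "n_kos", ascending=False
    )
    df.index.name = "category"
    df["n_kos"] = df["n_kos"].astype(int)
    return df


def filter_high_abundance(
    classes: Sequence[TernaryClass],
    triples: Sequence[KOAbundanceTriple],
    floor: float,
) -> tuple[list[TernaryClass], list[KOAbundanceTriple]]:
    """Keep KOs whose maximum abundance across libraries exceeds ``floor``.

    The floor is in per-million units and the comparison is strict
    (a KO at exactly the floor is dropped).
    """
    if floor < 0:
        raise ValueError("floor must be >= 0")
    by_id = {t.ko_id: t for t in triples}
    kept_c = [c for c in classes if max(by_id[c.ko_id].values) > floor]
    kept_ids = {c.ko_id for c in kept_c}
    kept_t = [t for t in triples if t.ko_id in kept_ids]
    return kept_c, kept_t


# vertex layout for the ternary scatter: lib1 top, lib2 lower-left, lib3 lower-right
_VERTICES = np.array([[0.5, np.sqrt(3) / 2], [0.0, 0.0], [1.0, 0.0]])

_CATEGORY_COLORS = {
    "core": "0.5",
    "enriched(1)": "tab:red",
    "enriched(2)": "tab:blue",
    "enriched(3)": "tab:green",
    "diluted(1)": "tab:red",
    "diluted(2)": "tab:blue",
    "diluted(3)": "tab:green",
    "unclassified": "0.8",
}


def plot_ternary(
    classes: Sequence[TernaryClass],
    triples: Sequence[KOAbundanceTriple],
    labels: tuple[str, str, str] = ("lib1", "lib2", "lib3"),
    ax=None,
):
    """Ternary scatter of KO categories.

    Circle area scales with the KO's highest abundance among the three
    libraries; core KOs are gray filled, enriched KOs colored filled,
    diluted KOs colored open circles. Returns the matplotlib Axes.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5.5))
    by_id = {t.ko_id: t for t in triples}
    coords = np.array([c.ternary_coords for c in classes])
    xy = coords @ _VERTICES
    max_ab = np.array([max(by_id[c.ko_id].values) for c in classes])
    sizes = 4 + 120 * max_ab / max(max_ab.max(), 1e-12)
    for c, (x, y), s in zip(classes, xy, sizes):
        color = _CATEGORY_COLORS.get(c.category, "0.8")
        open_circle = c.category.startswith("diluted")
        ax.scatter(
            x, y, s=s,
            facecolors="none" if open_circle else color,
            edgecolors=color, linewidths=0.6, alpha=0.7,
        )
    tri = np.vstack([_VERTICES, _VERTICES[0]])
    ax.plot(tri[:, 0], tri[:, 1], color="k", lw=1)
    for (x, y), lab, va in zip(_VERTICES, labels, ("bottom", "top", "top")):
        ax.annotate(lab, (x, y), ha="center", va=va, fontsize=10)
    ax.set_aspect("equal")
    ax.axis("off")
    return ax
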