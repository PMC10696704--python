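"""Run configuration for the SIP analysis pipeline.

A :class:`RunConfig` collects every tunable threshold used downstream:
the buoyant-density windows that define the light (L), heavy (H) and
ultra-heavy (UH) gradient fractions, the H/L ratio thresholds of the
labeling caller, the fold threshold of the KO core/enriched/diluted
classifier, and the IRMS delta-13C analytical precision that defines
the rate detection limit.

Config files are flat YAML (a JSON document is valid YAML, so both
work); absent keys take the documented defaults.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

__all__ = ["DensityWindow", "RunConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    """A configuration value violates an invariant; names the field."""


@dataclass(frozen=True)
class DensityWindow:
    """Half-open buoyant-density interval [lower, upper) in g/mL."""

    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ConfigError(
                f"density window lower bound {self.lower} must be < upper bound {self.upper}"
            )

    def __contains__(self, density: float) -> bool:
        return self.lower <= density < self.upper


# Default L/H/UH windows (g/mL). The three labels refer to unlabeled DNA,
# 13C-labeled DNA, and dual 13C+15N-labeled DNA respectively. Boundaries
# are explicit configuration: gradient studies place them by inspecting
# the per-sample profiles, so these defaults suit the synthetic profiles
# generated by this package and should be overridden for real gradients.
DEFAULT_WINDOWS: dict[str, tuple[float, float]] = {
    "L": (1.690, 1.712),
    "H": (1.715, 1.735),
    "UH": (1.735, 1.760),
}


@dataclass(frozen=True)
class RunConfig:
    """All pipeline thresholds, with invariants enforced at construction.

    Parameters
    ----------
    density_windows:
        Mapping of window name ("L", "H", "UH") to a half-open density
        interval in g/mL. Windows must be disjoint and ordered
        L < H < UH by lower bound.
    theta_unlabeled, theta_labeled:
        H/L relative-abundance ratio thresholds for the labeling caller.
        A taxon is called unlabeled when H/L <= theta_unlabeled (default
        0.5, a two-fold decline from light to heavy) and labeled when
        H/L >= theta_labeled (default 0.8, i.e. similar or higher in the
        heavy fraction).
    fold_threshold:
        Fold change defining the KO core/enriched/diluted categories
        (default 2.0: "less than two-fold" spread means core).
    delta_precision:
        IRMS analytical precision of delta-13C in permil (default 0.1).
        Rate changes smaller than this delta shift are below detection.
    abundance_floor:
        Minimum relative abundance below which a taxon's labeling call
        is "insufficient" (default 0.001).
    seed:
        Default random seed recorded in provenance.
    output_precision:
        Decimal places used by report writers.
    """

    density_windows: Mapping[str, DensityWindow] = field(
        default_factory=lambda: {
            name: DensityWindow(*bounds) for name, bounds in DEFAULT_WINDOWS.items()
        }
    )
    theta_unlabeled: float = 0.5
    theta_labeled: float = 0.8
    fold_threshold: float = 2.0
    delta_precision: float = 0.1
    abundance_floor: float = 0.001
    seed: int = 0
    output_precision: int = 4

    def __post_init__(self) -> None:
        required = ("L", "H", "UH")
        for name in required:
            if name not in self.density_windows:
                raise ConfigError(f"density_windows missing window {name!r}")
        windows = [self.density_windows[name] for name in required]
        for (a_name, a), (b_name, b) in zip(
            zip(required, windows), zip(required[1:], windows[1:])
        ):
            if a.lower >= b.lower:
                raise ConfigError(
                    f"density windows must be ordered {a_name} < {b_name} by lower bound"
                )
            if a.upper > b.lower:
                raise ConfigError(
                    f"density windows {a_name} and {b_name} overlap"
                )
        if not 0 < self.theta_unlabeled <= self.theta_labeled:
            raise ConfigError(
                "labeling thresholds must satisfy 0 < theta_unlabeled <= theta_labeled, "
                f"got ({self.theta_unlabeled}, {self.theta_labeled})"
            )
        if not self.fold_threshold > 1:
            raise ConfigError(
                f"fold_threshold must exceed 1, got {self.fold_threshold}"
            )
        if not self.delta_precision > 0:
            raise ConfigError(
                f"delta_precision must be positive, got {self.delta_precision}"
            )
        if self.abundance_floor < 0:
            raise ConfigError(
                f"abundance_floor must be >= 0, got {self.abundance_floor}"
            )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["density_windows"] = {
            name: [w.lower, w.upper] for name, w in self.density_windows.items()
        }
        return d

    def config_hash(self) -> str:
        """Stable short hash of the configuration, for provenance blocks."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load a :class:`RunConfig` from a flat YAML/JSON file.

    Absent keys take their documented defaults; an empty or missing file
    yields the all-default configuration. Invariant violations raise
    :class:`ConfigError` naming the offending field.
    """
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        data = loaded

    kwargs: dict = {}
    if "density_windows" in data:
        raw = data["density_windows"]
        if not isinstance(raw, dict):
            raise ConfigError("density_windows must map window names to [lower, upper]")
        kwargs["density_windows"] = {
            name: DensityWindow(float(lo), float(hi)) for name, (lo, hi) in raw.items()
        }
    for key in (
        "theta_unlabeled",
        "theta_labeled",
        "fold_threshold",
        "delta_precision",
        "abundance_floor",
        "output_precision",
        "seed",
    ):
        if key in data:
            kwargs[key] = data[key]
    unknown = set(data) - set(kwargs) - {"density_windows"}
    if unknown:
        raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
    return RunConfig(**kwargs)
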