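"""Small reference datasets shipped with the package.

``VENT_RATE_REPLICATES`` holds the measured carbon fixation rates
(umol C L^-1 day^-1) from the Kueishantao shallow-sea hydrothermal-vent
temperature-gradient incubations at the white vent (WV, pH 5.6) and
yellow vent (YV, pH 2.2). Each condition has three replicate bottles —
the 13C+15N, 13C+14N and 13C-only treatments, which behave as
biological replicates because ammonium addition did not alter the
rate. None encodes a below-detection replicate.
"""

from __future__ import annotations

__all__ = ["VENT_RATE_REPLICATES", "VENT_CONDITION_ORDER"]

# (site, temperature degC) -> replicate rates in treatment order
# (13C+15N, 13C+14N, 13C); None = below detection limit
VENT_RATE_REPLICATES: dict[tuple[str, int], tuple[float | None, float | None, float | None]] = {
    ("WV", 65): (1.43, 1.68, 1.38),
    ("WV", 45): (1.82, 2.49, 1.87),
    ("WV", 30): (1.67, 2.04, 1.63),
    ("YV", 65): (None, None, None),
    ("YV", 45): (0.017, 0.012, 0.013),
    ("YV", 30): (0.054, 0.09, 0.046),
}

VENT_CONDITION_ORDER: tuple[tuple[str, int], ...] = tuple(VENT_RATE_REPLICATES)
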