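"""Tab-separated table IO with schema validation and provenance.

All pipeline tables are UTF-8 TSV with one header row; "." or an empty
cell encodes a missing value, and below-detection rates are written as
the literal token "BDL". Every writer also emits a JSON sidecar
(``<table>.provenance.json``) recording the package version, seed,
configuration hash and timestamp, so any output file can be traced back
to its run.
"""

from __future__ import annotations

import datetime as _dt
import json
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .config import RunConfig

__all__ = [
    "SchemaError",
    "MISSING_TOKENS",
    "BDL_TOKEN",
    "read_table",
    "write_table",
    "write_provenance",
    "GRADIENT_SCHEMA",
    "TAXON_SCHEMA",
    "INCUBATION_SCHEMA",
    "GENE_SCHEMA",
    "KO_SCHEMA",
]

MISSING_TOKENS = (".", "")
BDL_TOKEN = "BDL"

# column name -> required dtype kind ("num" or "str")
GRADIENT_SCHEMA: Mapping[str, str] = {
    "fraction_id": "str",
    "density": "num",
    "copies": "num",
}
TAXON_SCHEMA: Mapping[str, str] = {
    "taxon": "str",
    "rel_abundance_L": "num",
    "rel_abundance_H": "num",
}
INCUBATION_SCHEMA: Mapping[str, str] = {
    "bottle_id": "str",
    "delta_0": "num",
    "delta_t": "num",
    "poc_0": "num",
    "poc_t": "num",
    "t": "num",
    "ca_dic": "num",
    "cs_dic": "num",
}
GENE_SCHEMA: Mapping[str, str] = {
    "gene_id": "str",
    "mapped_reads": "num",
    "length": "num",
}
KO_SCHEMA: Mapping[str, str] = {
    "ko_id": "str",
    "a1": "num",
    "a2": "num",
    "a3": "num",
}


class SchemaError(ValueError):
    """A table does not match its expected schema."""


def read_table(path: str | Path, schema: Mapping[str, str]) -> pd.DataFrame:
    """Read a TSV table and validate it against a column schema.

    Required columns must be present (extra columns pass through);
    numeric columns must parse as numbers apart from missing tokens
    ("." or empty) and, for rate-like columns, the "BDL" token, which
    both become NaN. Errors name the offending column or row.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(
        path, sep="\t", dtype=str, keep_default_na=False, na_values=[], comment="#"
    )
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required column(s) {missing}")
    for col, kind in schema.items():
        if kind != "num":
            continue
        raw = df[col].str.strip()
        cleaned = raw.replace(list(MISSING_TOKENS) + [BDL_TOKEN], pd.NA)
        parsed = pd.to_numeric(cleaned, errors="coerce")
        bad = parsed.isna() & cleaned.notna()
        if bad.any():
            row = int(bad.idxmax())
            raise SchemaError(
                f"{path.name}: non-numeric value {raw[row]!r} in numeric column "
                f"{col!r} at row {row}"
            )
        df[col] = parsed.astype(float)
    return df


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    config: RunConfig | None = None,
    seed: int | None = None,
    float_format: str | None = None,
) -> Path:
    """Write a TSV table plus its JSON provenance sidecar.

    NaN cells are written as "."; columns are kept in order. Returns
    the table path.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, na_rep=".", float_format=float_format)
    write_provenance(path, config=config, seed=seed)
    return path


def write_provenance(
    table_path: str | Path,
    config: RunConfig | None = None,
    seed: int | None = None,
    extra: Mapping[str, object] | None = None,
) -> Path:
    """Emit ``<table>.provenance.json`` next to a written table."""
    from . import __version__

    table_path = Path(table_path)
    config = config or RunConfig()
    block = {
        "package": "sipautotroph",
        "version": __version__,
        "table": table_path.name,
        "seed": seed if seed is not None else config.seed,
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
        "timestamp": _dt.datetime.now(_dt.timezone.utc).isoformat(),
    }
    if extra:
        block.update(extra)
    out = table_path.with_suffix(table_path.suffix + ".provenance.json")
    out.write_text(json.dumps(block, indent=2, sort_keys=True) + "\n")
    return out
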