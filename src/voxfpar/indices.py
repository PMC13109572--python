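"""The 14-entry vegetation index registry.

Each entry has a ``canonical`` formula (the literature-standard form, the
default) and, where the source table's printed formula differs but is still
parseable, an ``as_printed`` variant that reproduces it verbatim. Zero
denominators yield missing values (NaN), never exceptions.

Band naming: blue = 450 nm, green = 560 nm, red = 650 nm, rededge = 730 nm,
nir = 840 nm; reflectances in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, NamedTuple

import numpy as np
import pandas as pd

from .fusion import REFLECTANCE_COLUMNS


class BandVector(NamedTuple):
    blue: float
    green: float
    red: float
    rededge: float
    nir: float


def _div(num, den):
    """Elementwise division returning NaN where the denominator is zero."""
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    out = np.full(np.broadcast(num, den).shape, np.nan)
    ok = den != 0
    np.divide(num, den, out=out, where=ok)
    return out if out.shape else float(out)


@dataclass(frozen=True)
class IndexDefinition:
    name: str
    canonical: Callable
    canonical_formula: str
    as_printed: Callable
    printed_formula: str


def _definition(name, canonical, canonical_formula,
                as_printed=None, printed_formula=None):
    return IndexDefinition(name, canonical, canonical_formula,
                           as_printed or canonical,
                           printed_formula or canonical_formula)


REGISTRY = {d.name: d for d in [
    _definition("NDVI",
                lambda b: _div(b.nir - b.red, b.nir + b.red),
                "(NIR - RED) / (NIR + RED)"),
    _definition("OSAVI",
                lambda b: 1.16 * _div(b.nir - b.red, b.nir + b.red + 0.16),
                "(1 + 0.16) (NIR - RED) / (NIR + RED + 0.16)"),
    _definition("GNDVI",
                lambda b: _div(b.nir - b.green, b.nir + b.green),
                "(NIR - GREEN) / (NIR + GREEN)"),
    _definition("SAVI",
                lambda b: 1.5 * _div(b.nir - b.red, b.nir + b.red + 0.5),
                "(1 + 0.5) (NIR - RED) / (NIR + RED + 0.5)"),
    _definition("MSAVI",
                lambda b: 1.1 * _div(b.nir - b.red, b.nir + b.red + 0.1),
                "(1 + L) (NIR - RED) / (NIR + RED + L), L = 0.1"),
    _definition("GCI",
                lambda b: _div(b.nir, b.green) - 1.0,
                "NIR / GREEN - 1",
                lambda b: _div(b.green - b.red, b.red),
                "(GREEN - RED) / RED"),
    _definition("RECI",
                lambda b: _div(b.nir, b.rededge) - 1.0,
                "NIR / REDEDGE - 1",
                lambda b: _div(b.nir, b.red - b.rededge) - 1.0,
                "NIR / (RED - REDEDGE) - 1"),
    _definition("LCI",
                lambda b: _div(b.nir - b.rededge, b.nir + b.red),
                "(NIR - REDEDGE) / (NIR + RED)",
                lambda b: _div(b.nir - b.green, b.green),
                "(NIR - GREEN) / GREEN"),
    _definition("GRVI",
                lambda b: _div(b.green - b.red, b.green + b.red),
                "(GREEN - RED) / (GREEN + RED)",
                lambda b: _div(b.green, b.nir),
                "GREEN / NIR"),
    _definition("MGRVI",
                lambda b: _div(b.green ** 2 - b.red ** 2,
                               b.green ** 2 + b.red ** 2),
                "(GREEN^2 - RED^2) / (GREEN^2 + RED^2)",
                lambda b: _div(b.green, b.nir + b.red),
                "GREEN / (NIR + RED)"),
    _definition("NDRE",
                lambda b: _div(b.nir - b.rededge, b.nir + b.rededge),
                "(NIR - REDEDGE) / (NIR + REDEDGE)",
                lambda b: np.asarray(b.nir - b.red - b.rededge, dtype=float),
                "NIR - RED - REDEDGE"),
    _definition("MACI",
                lambda b: _div(b.nir, b.green),
                "NIR / GREEN",
                lambda b: _div(b.nir, b.red),
                "NIR / RED"),
    _definition("ARI",
                lambda b: _div(1.0, b.green) - _div(1.0, b.rededge),
                "1/GREEN - 1/REDEDGE",
                lambda b: _div(b.nir - b.green, b.nir + b.green),
                "(NIR - GREEN) / (NIR + GREEN)"),
    _definition("MARI",
                lambda b: (_div(1.0, b.green) - _div(1.0, b.rededge)) * b.nir,
                "(1/GREEN - 1/REDEDGE) NIR",
                lambda b: _div(b.nir, b.red - b.rededge),
                "NIR / (RED - REDEDGE)"),
]}

INDEX_NAMES = list(REGISTRY)


def compute_index(name: str, bands, variant: str = "canonical"):
    """Evaluate one registered index on a band vector (scalars or arrays)."""
    if name not in REGISTRY:
        raise KeyError(f"unknown index {name!r}; valid names: "
                       + ", ".join(INDEX_NAMES))
    if variant not in ("canonical", "as_printed"):
        raise ValueError("variant must be 'canonical' or 'as_printed'")
    if not isinstance(bands, BandVector):
        bands = BandVector(*bands)
    d = REGISTRY[name]
    fn = d.canonical if variant == "canonical" else d.as_printed
    return fn(bands)


def compute_all(table: pd.DataFrame, variant: str = "canonical") -> pd.DataFrame:
    """Add the 14 VI columns to a fused voxel table.

    Missing reflectance propagates to missing indices; since reflectance is
    constant within a column, so is every index.
    """
    missing = [c for c in REFLECTANCE_COLUMNS if c not in table.columns]
    if missing:
        raise KeyError(f"table lacks reflectance columns: {missing}")
    bands = BandVector(*(table[c].to_numpy(dtype=float)
                         for c in REFLECTANCE_COLUMNS))
    out = table.copy()
    any_nan = np.zeros(len(table), dtype=bool)
    for c in REFLECTANCE_COLUMNS:
        any_nan |= ~np.isfinite(out[c].to_numpy(dtype=float))
    for name in INDEX_NAMES:
        vals = np.asarray(compute_index(name, bands, variant), dtype=float)
        if vals.ndim == 0:
            vals = np.full(len(out), float(vals))
        vals[any_nan] = np.nan
        out[name] = vals
    return out


def registry_table() -> pd.DataFrame:
    """Dump the registry (name, variant, formula) for documentation."""
    rows = []
    for d in REGISTRY.values():
        rows.append((d.name, "canonical", d.canonical_formula))
        rows.append((d.name, "as_printed", d.printed_formula))
    return pd.DataFrame(rows, columns=["name", "variant", "formula"])
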