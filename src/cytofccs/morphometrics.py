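"""Cell- and tissue-scale quantifications on tabular morphometry records.

Covers the measurements used to score cytoneme-mediated signalling
phenotypes: filopodium classification and length binning, cell circularity
in the notochord, expression-domain width/length ratios, kinase
translocation reporter (KTR) activity calls from nuclear/cytoplasmic
intensity ratios, and per-cell-row paracrine activation profiles around a
signal-producing clone.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .synthetic import CellGrid

__all__ = [
    "ProtrusionRecord",
    "CellShape",
    "classify_filopodium",
    "bin_lengths",
    "circularity",
    "domain_ratio",
    "ktr_activity",
    "paracrine_profile",
    "KTR_THRESHOLD",
    "FILOPODIUM_MIN_LENGTH",
    "FILOPODIUM_MIN_WIDTH",
]

#: Minimum length and width (µm) for a membrane protrusion to count as a
#: filopodium; boundary inclusive.
FILOPODIUM_MIN_LENGTH = 1.0
FILOPODIUM_MIN_WIDTH = 1.0

#: Nuclear/cytoplasmic reporter ratio below which a cell is called active
#: (nuclear exclusion of the reporter indicates kinase activity).
KTR_THRESHOLD = 1.0


@dataclass(frozen=True)
class ProtrusionRecord:
    """One membrane protrusion, measured base to tip."""

    length: float  # µm
    width: float  # µm
    carries_cargo: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.length < 0 or self.width < 0:
            raise ValueError("length and width must be non-negative")


@dataclass(frozen=True)
class CellShape:
    """Planar outline measurements of a single cell."""

    area: float  # µm²
    perimeter: float  # µm
    max_width: float = 0.0  # µm
    max_length: float = 0.0  # µm

    def __post_init__(self) -> None:
        if self.area < 0 or self.perimeter < 0:
            raise ValueError("area and perimeter must be non-negative")
        if self.perimeter > 0 and self.perimeter**2 < 4 * np.pi * self.area * (1 - 1e-9):
            raise ValueError("isoperimetric inequality violated: not a planar shape")


def classify_filopodium(p: ProtrusionRecord, *, rule: str = "both_min") -> bool:
    """Whether a protrusion qualifies as a filopodium.

    ``rule="both_min"`` (default): length >= 1 µm AND width >= 1 µm, the
    literal conjunctive reading of the defining criterion.
    ``rule="long_thin"``: length >= 1 µm AND width <= 1 µm, the alternative
    thin-protrusion reading.
    """
    if rule == "both_min":
        return p.length >= FILOPODIUM_MIN_LENGTH and p.width >= FILOPODIUM_MIN_WIDTH
    if rule == "long_thin":
        return p.length >= FILOPODIUM_MIN_LENGTH and p.width <= FILOPODIUM_MIN_WIDTH
    raise ValueError("rule must be 'both_min' or 'long_thin'")


def bin_lengths(
    lengths: Sequence[float], edges: Sequence[float]
) -> pd.DataFrame:
    """Bin protrusion lengths; returns per-bin counts and fractions.

    Fractions sum to 1 over non-empty input. Edges must increase strictly.
    """
    e = np.asarray(edges, dtype=float)
    if len(e) < 2 or (np.diff(e) <= 0).any():
        raise ValueError("bin edges must be strictly increasing")
    counts, _ = np.histogram(np.asarray(list(lengths), dtype=float), bins=e)
    total = counts.sum()
    frac = counts / total if total > 0 else np.zeros(len(counts))
    return pd.DataFrame(
        {
            "bin_low": e[:-1],
            "bin_high": e[1:],
            "count": counts,
            "fraction": frac,
        }
    )


def circularity(shape: CellShape) -> float:
    """Circularity 4π·area/perimeter², 1 for a circle, → 0 for elongated cells."""
    if shape.perimeter <= 0:
        raise ValueError("perimeter must be positive")
    return 4.0 * np.pi * shape.area / shape.perimeter**2


def domain_ratio(width: float, length: float) -> float:
    """Width/length ratio of an expression domain (dimensionless)."""
    if length <= 0:
        raise ValueError("length must be positive")
    if width < 0:
        raise ValueError("width must be non-negative")
    return width / length


def ktr_activity(
    nuclear: float, cytoplasmic: float, threshold: float = KTR_THRESHOLD
) -> tuple[float, bool]:
    """KTR signalling call from reporter intensities.

    Returns (nuclear/cytoplasmic ratio, active flag); a cell is active when
    the reporter is excluded from the nucleus, i.e. ratio < threshold.
    """
    if cytoplasmic <= 0:
        raise ValueError("cytoplasmic intensity must be positive")
    if nuclear < 0:
        raise ValueError("nuclear intensity must be non-negative")
    ratio = nuclear / cytoplasmic
    return ratio, ratio < threshold


def paracrine_profile(
    grid: CellGrid, max_rows: int = 5, threshold: float = KTR_THRESHOLD
) -> pd.DataFrame:
    """Fraction of active cells per cell-row distance from the clone.

    Analyses non-clone cells up to ``max_rows`` rows away (rows are graph
    distance on cell adjacency, i.e. counted in cells, not µm). Returns a
    DataFrame with one row per distance 1..max_rows: number of cells,
    number active and the active fraction (nan where a row has no cells).
    """
    if max_rows < 1:
        raise ValueError("max_rows must be >= 1")
    rows = []
    for d in range(1, max_rows + 1):
        cells = [c for c in grid.cells if not c.is_clone and c.row_distance == d]
        n = len(cells)
        n_active = sum(
            ktr_activity(c.nuclear_intensity, c.cytoplasmic_intensity, threshold)[1]
            for c in cells
        )
        rows.append(
            {
                "row": d,
                "n_cells": n,
                "n_active": n_active,
                "fraction_active": n_active / n if n else np.nan,
            }
        )
    return pd.DataFrame(rows)
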