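"""Translate clinical IHC scores into a common 4-level ordinal scale.

Breast-cancer biomarkers are reported on heterogeneous native scales —
Allred 0-8 for ER/PR, the FDA 0/1+/2+/3+ membrane score for HER2, and a
percent-positive index for Ki-67. For cross-method concordance analysis
all three are mapped onto the same ordered categories:

    NEG (-)  <  WEAK (+)  <  INTERMEDIATE (++)  <  STRONG (+++)

with integer codes 0..3. The mappings are monotone by construction.
Positive-cell percentages can be derived from a label mask by counting
connected components of stained (SP) and unstained (NSP) cell regions.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np
from skimage.measure import label as cc_label

from .errors import ConfigurationError, UndefinedFieldError
from .gmm import NSP, SP


class OrdinalScore(IntEnum):
    NEG = 0
    WEAK = 1
    INTERMEDIATE = 2
    STRONG = 3

    @property
    def glyph(self) -> str:
        return {0: "-", 1: "+", 2: "++", 3: "+++"}[int(self)]

    @classmethod
    def from_glyph(cls, glyph: str) -> "OrdinalScore":
        table = {"-": 0, "−": 0, "+": 1, "++": 2, "+++": 3}
        if glyph not in table:
            raise ConfigurationError(f"unknown ordinal glyph {glyph!r}")
        return cls(table[glyph])


def allred_to_category(score: int) -> OrdinalScore:
    """Allred composite score (0-8) to ordinal category.

    0 is negative; 2-3 weak; 4-6 intermediate; 7-8 strong. An Allred
    score of 1 cannot occur (proportion >= 1 forces intensity >= 1, so the
    composite is 0 or >= 2) and is rejected rather than guessed at.
    """
    if score == 0:
        return OrdinalScore.NEG
    if score in (2, 3):
        return OrdinalScore.WEAK
    if score in (4, 5, 6):
        return OrdinalScore.INTERMEDIATE
    if score in (7, 8):
        return OrdinalScore.STRONG
    raise ConfigurationError(f"invalid Allred score {score!r}: must be 0 or 2..8")


def her2_to_category(score: int) -> OrdinalScore:
    """HER2 FDA score 0/1+/2+/3+ maps one-to-one onto the ordinal scale."""
    if score in (0, 1, 2, 3):
        return OrdinalScore(score)
    raise ConfigurationError(f"invalid HER2 score {score!r}: must be 0..3")


def ki67_to_category(percent: float) -> OrdinalScore:
    """Ki-67 percent-positive index to ordinal category.

    Right-closed bins: <=5% negative; (5, 20] weak; (20, 40] intermediate;
    >40% strong.
    """
    if not 0.0 <= percent <= 100.0:
        raise ConfigurationError(f"Ki-67 percentage {percent!r} outside [0, 100]")
    if percent <= 5.0:
        return OrdinalScore.NEG
    if percent <= 20.0:
        return OrdinalScore.WEAK
    if percent <= 40.0:
        return OrdinalScore.INTERMEDIATE
    return OrdinalScore.STRONG


@dataclass
class CellCount:
    positive_cells: int
    total_cells: int
    percent_positive: float


def count_positive_cells(
    labels: np.ndarray, connectivity: int = 8, min_size_px: int = 30
) -> CellCount:
    """Count stained and unstained cells as connected components of the mask.

    Components smaller than ``min_size_px`` are treated as debris and
    dropped; components touching the field border are counted. 8- or
    4-connectivity selectable (default 8).
    """
    if connectivity not in (4, 8):
        raise ConfigurationError("connectivity must be 4 or 8")
    conn = 2 if connectivity == 8 else 1
    labels = np.asarray(labels)

    def _count(code: int) -> int:
        cc = cc_label(labels == code, connectivity=conn)
        sizes = np.bincount(cc.ravel())[1:]  # skip background id 0
        return int((sizes >= min_size_px).sum())

    positive = _count(SP)
    negative = _count(NSP)
    total = positive + negative
    if total == 0:
        raise UndefinedFieldError("no cells above the minimum size; percent undefined")
    return CellCount(
        positive_cells=positive,
        total_cells=total,
        percent_positive=100.0 * positive / total,
    )
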