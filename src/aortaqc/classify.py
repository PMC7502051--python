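"""Expert rule tables: HU categories per ROI and the final contrast class.

The contrast quality of a CTA study is judged from the mean HU inside two
aortic ROIs and one femoral ROI. Each mean is first binned into one of five
expert categories:

=========  ============  =======================
Category   Range [HU]    Meaning
=========  ============  =======================
A          <= 180        HU value too low
B          181 - 240     lower tolerance area
C          241 - 300     target area
D          301 - 360     upper tolerance area
E          > 360         excessive HU value
=========  ============  =======================

and the category combination is then mapped to a class:

* class 1 (insufficient): at least one ROI in A;
* class 2 (optimal): all ROIs in B, C or D;
* class 3 (excessive): at least one ROI in E, the remaining ROIs in D.

The class rules are applied literally over however many ROIs are available
(two or three). They do not cover every combination: an E next to a B or C
(or an all-E study) matches no rule and is reported as *indeterminate*
rather than silently coerced — the method's headline guarantee (no false
class-3 call) rests on the class-3 condition being exactly as narrow as
printed. An optional ``total_coverage`` mode maps every indeterminate
combination (all of which contain an E and no A) to class 3 for users who
prefer a total function.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

#: Upper bounds of categories A..D (category E is unbounded above).
DEFAULT_BOUNDARIES: tuple[float, float, float, float] = (180.0, 240.0, 300.0, 360.0)


class Category(str, Enum):
    A = "A"
    B = "B"
    C = "C"
    D = "D"
    E = "E"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


def categorize(
    mean_hu: float,
    boundaries: Sequence[float] = DEFAULT_BOUNDARIES,
) -> Category:
    """Bin a mean HU value into its expert category.

    The printed table uses integer ranges (A <= 180, B 181-240, C 241-300,
    D 301-360, E > 360). Real-valued means are binned by the same
    inequalities: a value is in A iff <= 180, in B iff it is above 180 and
    below 241, and so on — e.g. 180.5 falls in B, 360.5 in D.
    """
    if not math.isfinite(mean_hu):
        raise ValueError(f"mean HU must be finite, got {mean_hu}")
    b0, b1, b2, b3 = boundaries
    if mean_hu <= b0:
        return Category.A
    if mean_hu < b1 + 1:
        return Category.B
    if mean_hu < b2 + 1:
        return Category.C
    if mean_hu < b3 + 1:
        return Category.D
    return Category.E


INDETERMINATE = "indeterminate"


@dataclass
class ClassResult:
    """Outcome of the rule-based classification.

    ``label`` is ``"1"``, ``"2"``, ``"3"`` or ``"indeterminate"``;
    ``matched_rule`` is a human-readable trace of the condition that fired
    (or of the uncovered combination).
    """

    label: str
    matched_rule: str
    n_rois_used: int
    categories: tuple[Category, ...]

    @property
    def klass(self) -> int | None:
        return int(self.label) if self.label != INDETERMINATE else None

    @property
    def is_indeterminate(self) -> bool:
        return self.label == INDETERMINATE


def classify(
    categories: Sequence[Category | str],
    total_coverage: bool = False,
) -> ClassResult:
    """Map 2 or 3 ROI categories to the final contrast class.

    The three rules are evaluated literally over the ROIs present. The
    class-3 condition requires at least one non-E ROI (all in D): an all-E
    combination matches no rule. With ``total_coverage=True`` the
    indeterminate combinations — all of which contain an E and no A — are
    mapped to class 3.
    """
    cats = tuple(Category(c) for c in categories)
    if len(cats) not in (2, 3):
        raise ValueError(f"expected 2 or 3 ROI categories, got {len(cats)}")
    combo = "/".join(c.value for c in cats)

    if any(c is Category.A for c in cats):
        return ClassResult("1", f"at least one ROI in A ({combo})", len(cats), cats)
    if all(c in (Category.B, Category.C, Category.D) for c in cats):
        return ClassResult("2", f"all ROIs in B, C or D ({combo})", len(cats), cats)
    remaining = [c for c in cats if c is not Category.E]
    if remaining and all(c is Category.D for c in remaining):
        return ClassResult(
            "3", f"at least one ROI in E, remaining in D ({combo})", len(cats), cats
        )
    if total_coverage:
        return ClassResult(
            "3",
            f"no rule matched ({combo}); total-coverage mode maps E-containing "
            "combinations to class 3",
            len(cats),
            cats,
        )
    return ClassResult(INDETERMINATE, f"no rule matched ({combo})", len(cats), cats)


@dataclass
class RoiMeasurement:
    """A placed ROI, its mean HU and its category.

    ``descriptor`` records the mask geometry: for the aortic ROIs a disc
    (``center``, ``radius_px``, ``reduced_radius_px``), for the femoral ROI
    an explicit pixel list.
    """

    roi_id: int
    slice_index: int
    mean_hu: float
    n_pixels: int
    category: Category
    descriptor: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_pixels < 1:
            raise ValueError("an ROI must contain at least one pixel")

    def to_dict(self) -> dict:
        return {
            "roi_id": self.roi_id,
            "slice_index": self.slice_index,
            "mean_hu": round(float(self.mean_hu), 3),
            "n_pixels": self.n_pixels,
            "category": self.category.value,
            "descriptor": self.descriptor,
        }
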