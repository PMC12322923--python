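"""Vessel patterns, dominance ratios, threshold ratings and sweeps.

A hemisphere's *vessel pattern* is the set of arteries with nonzero supply
volume fraction (between 1 and 5 of the canonical vessels; 3-5 in typical
cohorts). *Vessel dominance* (VDom) relates two competing supply volumes:

.. math:: \\text{ratio} = \\frac{V_{\\text{interest}}}
                               {V_{\\text{interest}} + V_{\\text{counterpart}}}

which is 1.0 when the vessel of interest is the sole supplier, 0.5 at equal
contribution and 0.0 when it does not contribute. Continuous ratios are
converted to categorical ratings with a lower/upper threshold pair: ratios
within ``[lower, upper]`` count as equal contribution, above ``upper`` as
dominance of the numerator vessel, below ``lower`` as dominance of the
counterpart. The default pair (0.33, 0.66) splits [0, 1] equidistantly; the
sweep machinery varies the pair jointly (``upper = 1 - lower``) to check how
robust rating frequencies are and which pair best matches an external
reference frequency table.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import SupplyFractionRecord
from .volumes import ACA_IDS, CANONICAL_VESSELS, MCA_IDS

__all__ = [
    "VesselPattern",
    "DominanceRatios",
    "ThresholdPair",
    "DominanceCategory",
    "DominanceRating",
    "SweepResult",
    "classify_pattern",
    "dominance_ratios",
    "rate_dominance",
    "build_sweep_grid",
    "sweep_agreement",
    "frequency_table",
    "interrater_correlation",
]

PERICALLOSA, CALLOSOMARGINALIS = ACA_IDS
PRECENTRAL, CENTRAL, POSTCENTRAL = MCA_IDS


@dataclass(frozen=True)
class VesselPattern:
    """Number and identity of the arteries supplying one hemisphere."""

    count: int
    composition: frozenset[str]

    def __post_init__(self) -> None:
        if self.count != len(self.composition):
            raise ValueError("pattern count must equal composition size")

    @property
    def key(self) -> str:
        """Stable name, e.g. ``'pericallosa+precentral+central'``."""
        order = {name: vid for vid, name in CANONICAL_VESSELS.items()}
        return "+".join(sorted(self.composition, key=order.__getitem__))


@dataclass(frozen=True)
class DominanceRatios:
    """The four supply-volume ratios; ``None`` encodes a zero denominator."""

    aca_mca: float | None
    peri_callosomarginalis: float | None
    central_precentral: float | None
    postcentral_mca: float | None


@dataclass(frozen=True)
class ThresholdPair:
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not (0.0 < self.lower < self.upper < 1.0):
            raise ValueError(f"need 0 < lower < upper < 1, got {self}")


class DominanceCategory(str, enum.Enum):
    NUMERATOR_DOMINANT = "numerator_dominant"
    EQUAL = "equal"
    DENOMINATOR_DOMINANT = "denominator_dominant"
    UNDEFINED = "undefined"


@dataclass(frozen=True)
class DominanceRating:
    category: DominanceCategory
    ratio: float | None
    thresholds: ThresholdPair


@dataclass
class SweepResult:
    pairs: list[ThresholdPair]
    frequencies: pd.DataFrame  # one row per pair, one column per category
    agreement: np.ndarray
    best_pair: ThresholdPair


def classify_pattern(record: SupplyFractionRecord) -> VesselPattern:
    """Count the arteries with strictly positive supply volume fraction.

    The zero test is exact: fractions derive from integer voxel counts, so
    an absent vessel is exactly 0, never a small float.
    """
    present = record.present_ids()
    if not present:
        raise ValueError("all supply fractions are zero; no pattern defined")
    names = frozenset(record.labels.get(vid, CANONICAL_VESSELS[vid]) for vid in present)
    return VesselPattern(count=len(present), composition=names)


def _ratio(numerator: float, denominator: float) -> float | None:
    return None if denominator == 0 else numerator / denominator


def dominance_ratios(record: SupplyFractionRecord) -> DominanceRatios:
    """Compute the four dominance ratios from one hemisphere's fractions.

    * ACA/MCA: combined ACA-branch fraction over the whole ROI supply;
    * pericallosa vs. callosomarginalis within the ACA supply;
    * central vs. precentral group within their combined MCA supply
      (postcentral excluded from this pairing);
    * postcentral group within the whole MCA supply.
    """
    f = record.fraction
    total = sum(record.fractions.values())
    aca = f(PERICALLOSA) + f(CALLOSOMARGINALIS)
    central_pre = f(CENTRAL) + f(PRECENTRAL)
    mca = central_pre + f(POSTCENTRAL)
    return DominanceRatios(
        aca_mca=_ratio(aca, total),
        peri_callosomarginalis=_ratio(f(PERICALLOSA), aca),
        central_precentral=_ratio(f(CENTRAL), central_pre),
        postcentral_mca=_ratio(f(POSTCENTRAL), mca),
    )


def rate_dominance(
    ratio: float | None, thresholds: ThresholdPair
) -> DominanceRating:
    """Convert a continuous ratio into a categorical dominance rating.

    Closed-interval rule: a ratio exactly at either threshold counts as
    equal contribution, keeping the equidistant pair symmetric.
    """
    if ratio is None or (isinstance(ratio, float) and math.isnan(ratio)):
        return DominanceRating(DominanceCategory.UNDEFINED, None, thresholds)
    ratio = float(ratio)
    if not (0.0 <= ratio <= 1.0):
        raise ValueError(f"dominance ratio must lie in [0, 1], got {ratio}")
    if ratio > thresholds.upper:
        category = DominanceCategory.NUMERATOR_DOMINANT
    elif ratio < thresholds.lower:
        category = DominanceCategory.DENOMINATOR_DOMINANT
    else:
        category = DominanceCategory.EQUAL
    return DominanceRating(category, ratio, thresholds)


def build_sweep_grid(
    n: int = 100, low: float = 0.05, high: float = 0.45
) -> list[ThresholdPair]:
    """Joint threshold grid: ``n`` lower values equally spaced on
    ``[low, high]`` (endpoints included), each paired with ``1 - lower``."""
    if n < 2:
        raise ValueError("need at least 2 sweep points")
    if not (0.0 < low < high < 0.5):
        raise ValueError(f"need 0 < low < high < 0.5, got ({low}, {high})")
    lowers = np.linspace(low, high, n)
    return [ThresholdPair(float(lo), float(1.0 - lo)) for lo in lowers]


_RATED = (
    DominanceCategory.NUMERATOR_DOMINANT,
    DominanceCategory.EQUAL,
    DominanceCategory.DENOMINATOR_DOMINANT,
)


def _category_frequencies(
    ratios: Sequence[float | None], pair: ThresholdPair
) -> dict[DominanceCategory, float]:
    cats = [rate_dominance(r, pair).category for r in ratios]
    rated = [c for c in cats if c is not DominanceCategory.UNDEFINED]
    n = len(rated)
    freqs = {c: (rated.count(c) / n if n else 0.0) for c in _RATED}
    return freqs


def agreement_score(
    freqs: Mapping[DominanceCategory, float],
    reference: Mapping[DominanceCategory, float],
) -> float:
    """1 minus half the L1 distance between two frequency tables (in [0, 1])."""
    keys = set(freqs) | set(reference)
    l1 = sum(abs(freqs.get(k, 0.0) - reference.get(k, 0.0)) for k in keys)
    return 1.0 - 0.5 * l1


def sweep_agreement(
    ratios: Sequence[float | None],
    grid: Sequence[ThresholdPair],
    reference: Mapping[DominanceCategory | str, float],
) -> SweepResult:
    """Rate all hemispheres under every threshold pair and score each pair's
    category frequencies against a reference table.

    The best pair maximizes the agreement score; ties resolve to the
    smallest lower threshold. Undefined ratios are excluded from the rated
    denominator (they cannot respond to thresholds).
    """
    if len(ratios) == 0:
        raise ValueError("no ratios to sweep")
    reference = {DominanceCategory(k): float(v) for k, v in reference.items()}
    ref_sum = sum(reference.values())
    if abs(ref_sum - 1.0) > 1e-9:
        raise ValueError(f"reference frequencies must sum to 1, got {ref_sum}")

    rows = []
    scores = []
    for pair in grid:
        freqs = _category_frequencies(ratios, pair)
        rows.append({c.value: freqs[c] for c in _RATED})
        scores.append(agreement_score(freqs, reference))
    scores = np.asarray(scores)
    best_index = int(np.argmax(scores))  # argmax keeps first (smallest lower) tie
    return SweepResult(
        pairs=list(grid),
        frequencies=pd.DataFrame(rows),
        agreement=scores,
        best_pair=grid[best_index],
    )


def frequency_table(items: Iterable[VesselPattern | DominanceRating]) -> pd.DataFrame:
    """Counts and percentages (one decimal) per pattern or rating category."""
    items = list(items)
    if not items:
        raise ValueError("no items to tabulate")
    keys = []
    for item in items:
        if isinstance(item, VesselPattern):
            keys.append(f"{item.count}-vessel")
        elif isinstance(item, DominanceRating):
            keys.append(item.category.value)
        else:
            raise TypeError(f"cannot tabulate {type(item).__name__}")
    counts = pd.Series(keys).value_counts().sort_index()
    table = pd.DataFrame(
        {
            "count": counts,
            "percentage": (100.0 * counts / counts.sum()).round(1),
        }
    )
    table.index.name = "category"
    return table


def interrater_correlation(
    fractions_a: Sequence[float], fractions_b: Sequence[float]
) -> tuple[float, float]:
    """Pearson correlation between two raters' supply volume fractions."""
    a = np.asarray(fractions_a, dtype=float)
    b = np.asarray(fractions_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 3:
        raise ValueError("need two equal-length vectors of >= 3 fractions")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    result = sps.pearsonr(a, b)
    return float(result.statistic), float(result.pvalue)
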