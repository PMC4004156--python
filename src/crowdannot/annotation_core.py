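"""Core data model and aggregation statistics for crowdsourced photo annotation.

The unit of annotation is a photograph of a retail point-of-sale environment.
Independent crowd raters answer small questions about each photo (is a tobacco
ad present? which brand? what is the lowest advertised price? draw a box around
the ad), and this module turns those independent answers into crowd-level
results: plurality/supermajority consensus, vote-fraction classifier scores,
price summaries, crop-box agreement clustering, and the descriptive and
inferential statistics used in tool-usability comparisons.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as _sps
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "PRESENT",
    "ABSENT",
    "NO_CONSENSUS",
    "UNDEFINED",
    "AnswerKind",
    "FeatureKind",
    "PhotoRecord",
    "TargetFeature",
    "Rating",
    "CropBox",
    "TaggedCrop",
    "ConsensusResult",
    "PriceSummary",
    "ContingencyTable",
    "CropCluster",
    "ChiSquareResult",
    "majority_vote",
    "vote_fraction_score",
    "aggregate_prices",
    "crop_iou",
    "cluster_crops",
    "chi_square_homogeneity",
    "proportion_with_ci",
    "parse_price",
]

PRESENT = "present"
ABSENT = "absent"


class _Sentinel:
    """Unique, picklable sentinel with a readable repr."""

    __slots__ = ("_name",)
    _registry: dict[str, "_Sentinel"] = {}

    def __new__(cls, name: str):
        if name not in cls._registry:
            obj = super().__new__(cls)
            obj._name = name
            cls._registry[name] = obj
        return cls._registry[name]

    def __repr__(self) -> str:
        return self._name

    def __reduce__(self):
        return (_Sentinel, (self._name,))


#: Consensus decision when the tie/threshold condition fails; routes a photo
#: to expert escalation in the tiered workflow.
NO_CONSENSUS = _Sentinel("NO_CONSENSUS")

#: Sample SD of a single observation.
UNDEFINED = _Sentinel("UNDEFINED")


class AnswerKind:
    """Closed set of answer payload kinds a rating may carry."""

    BINARY = "binary"
    CATEGORICAL = "categorical"
    NUMERIC = "numeric"
    CROP = "crop"
    ALL = frozenset({BINARY, CATEGORICAL, NUMERIC, CROP})


class FeatureKind:
    """Closed set of annotation-target kinds."""

    AD_PRESENCE = "ad_presence"
    BRAND = "brand"
    PRICE = "price"
    MENTHOL_STATUS = "menthol_status"
    CUSTOM = "custom"
    ALL = frozenset({AD_PRESENCE, BRAND, PRICE, MENTHOL_STATUS, CUSTOM})


@dataclass(frozen=True)
class PhotoRecord:
    """A photograph under annotation; geometry only, never pixel content.

    ``feature_set`` lists the target features truly present and is populated
    only for gold-standard or simulated photos.
    """

    photo_id: str
    width_px: int
    height_px: int
    feature_set: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError(
                f"photo {self.photo_id!r}: dimensions must be positive, "
                f"got {self.width_px}x{self.height_px}"
            )
        object.__setattr__(self, "feature_set", frozenset(self.feature_set))


@dataclass(frozen=True)
class TargetFeature:
    """A thing raters are asked about: an ad, a brand, a price, menthol status."""

    feature_id: str
    kind: str = FeatureKind.AD_PRESENCE
    label: str = ""

    def __post_init__(self):
        if self.kind not in FeatureKind.ALL:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.kind == FeatureKind.BRAND and not self.label:
            raise ValueError("brand features require a nonempty label")


@dataclass(frozen=True)
class CropBox:
    """Axis-aligned pixel rectangle, origin top-left, half-open [x0,x1)x[y0,y1).

    The half-open convention makes areas exact integer pixel counts and avoids
    off-by-one disputes when boxes share an edge.
    """

    x0: float
    y0: float
    x1: float
    y1: float
    tag: str = ""

    def __post_init__(self):
        if not (self.x0 < self.x1 and self.y0 < self.y1):
            raise ValueError(
                f"degenerate crop box ({self.x0},{self.y0})-({self.x1},{self.y1})"
            )
        if self.x0 < 0 or self.y0 < 0:
            raise ValueError("crop box extends outside the photo frame")

    @property
    def area(self) -> float:
        return (self.x1 - self.x0) * (self.y1 - self.y0)

    def clipped(self, width_px: float, height_px: float) -> "CropBox":
        """Clamp to the photo frame, preserving validity."""
        x0 = min(max(self.x0, 0.0), width_px - 1)
        y0 = min(max(self.y0, 0.0), height_px - 1)
        x1 = max(min(self.x1, width_px), x0 + 1)
        y1 = max(min(self.y1, height_px), y0 + 1)
        return CropBox(x0, y0, x1, y1, self.tag)


@dataclass(frozen=True)
class TaggedCrop:
    """One or more box selections sharing a category tag.

    A single photo can yield a variable number of tags, each associated with
    multiple selections (e.g. every "ad with a price" in a storefront).
    """

    tag: str
    boxes: tuple

    def __post_init__(self):
        boxes = tuple(self.boxes)
        if not boxes:
            raise ValueError("tagged crop requires at least one box")
        object.__setattr__(
            self, "boxes", tuple(b if b.tag == self.tag else CropBox(b.x0, b.y0, b.x1, b.y1, self.tag) for b in boxes)
        )


@dataclass(frozen=True)
class Rating:
    """One rater's answer to one question about one photo."""

    photo_id: str
    rater_id: str
    question_id: str
    kind: str
    value: object
    task_id: str = "t0"
    timestamp: str | None = None

    def __post_init__(self):
        if self.kind not in AnswerKind.ALL:
            raise ValueError(f"unknown answer kind {self.kind!r}")
        if self.kind == AnswerKind.NUMERIC:
            v = float(self.value)
            if v < 0:
                raise ValueError(f"invalid price {v!r}: prices are nonnegative")
            object.__setattr__(self, "value", v)
        elif self.kind == AnswerKind.BINARY and self.value not in (PRESENT, ABSENT):
            raise ValueError(f"binary answer must be present/absent, got {self.value!r}")
        elif self.kind == AnswerKind.CROP and not isinstance(self.value, TaggedCrop):
            raise ValueError("crop answers carry a TaggedCrop payload")


@dataclass(frozen=True)
class ConsensusResult:
    """Aggregated crowd answer for one photo-question."""

    photo_id: str
    question_id: str
    decision: object
    vote_fraction: float
    n_raters: int

    def __post_init__(self):
        if not (0.0 <= self.vote_fraction <= 1.0):
            raise ValueError("vote_fraction outside [0,1]")
        if self.n_raters < 1:
            raise ValueError("n_raters must be positive")

    @property
    def reached(self) -> bool:
        return self.decision is not NO_CONSENSUS


@dataclass(frozen=True)
class PriceSummary:
    mean: float
    sd: object  # float, or UNDEFINED when n == 1
    n: int
    min: float


@dataclass(frozen=True)
class ContingencyTable:
    """r x c count grid for a homogeneity comparison across task arms."""

    counts: tuple
    row_labels: tuple = ()
    col_labels: tuple = ()

    def __post_init__(self):
        arr = np.asarray(self.counts, dtype=np.int64)
        if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
            raise ValueError("contingency table must be at least 2x2")
        if (arr < 0).any():
            raise ValueError("counts must be nonnegative")
        if arr.sum() == 0:
            raise ValueError("empty table")
        object.__setattr__(self, "counts", tuple(map(tuple, arr.tolist())))
        r, c = arr.shape
        object.__setattr__(
            self, "row_labels", tuple(self.row_labels) or tuple(f"row{i}" for i in range(r))
        )
        object.__setattr__(
            self, "col_labels", tuple(self.col_labels) or tuple(f"col{j}" for j in range(c))
        )

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=np.int64)


ChiSquareResult = tuple  # (statistic, df, p)


def _check_homogeneous(ratings: Sequence[Rating]) -> tuple[str, str]:
    keys = {(r.photo_id, r.question_id) for r in ratings}
    if len(keys) > 1:
        raise ValueError("heterogeneous input: ratings span multiple photo-questions")
    return next(iter(keys))


def majority_vote(
    ratings: Sequence[Rating],
    rule: str = "plurality",
    threshold: float | None = None,
) -> ConsensusResult:
    """Aggregate binary/categorical ratings into a crowd consensus.

    ``rule="plurality"`` takes the modal answer; an exact tie for the lead
    yields NO_CONSENSUS (the photo is then escalated, never decided by a coin
    flip).  ``rule="supermajority"`` additionally requires the leading vote
    fraction to reach ``threshold``; a sub-threshold plurality also yields
    NO_CONSENSUS.  In either failure case ``vote_fraction`` reports the
    fraction of the lexicographically smallest leading answer, so the result
    is deterministic.
    """
    ratings = list(ratings)
    if not ratings:
        raise ValueError("no ratings")
    photo_id, question_id = _check_homogeneous(ratings)
    if rule not in ("plurality", "supermajority"):
        raise ValueError(f"unknown consensus rule {rule!r}")
    if rule == "supermajority":
        if threshold is None or not (0.5 < threshold <= 1.0):
            raise ValueError("supermajority requires a threshold in (0.5, 1]")

    counts = Counter(str(r.value) for r in ratings)
    n = len(ratings)
    top = max(counts.values())
    leaders = sorted(a for a, c in counts.items() if c == top)
    frac = top / n

    tie = len(leaders) > 1
    below = rule == "supermajority" and frac < threshold
    decision = NO_CONSENSUS if (tie or below) else leaders[0]
    return ConsensusResult(photo_id, question_id, decision, frac, n)


def vote_fraction_score(ratings: Sequence[Rating]) -> float:
    """Share of raters reporting the target present.

    This is the continuous per-photo classifier score fed to ROC analysis;
    thresholding it at 0.5 recovers the majority vote.
    """
    ratings = list(ratings)
    if not ratings:
        raise ValueError("no ratings")
    _check_homogeneous(ratings)
    return sum(1 for r in ratings if r.value == PRESENT) / len(ratings)


def parse_price(text: object) -> float:
    """Parse a currency reading: strips '$' and thousands commas, 2-digit cents."""
    if isinstance(text, (int, float)):
        v = float(text)
    else:
        v = float(str(text).strip().lstrip("$").replace(",", ""))
    return round(v, 2)


def aggregate_prices(readings: Sequence[Rating | float]) -> PriceSummary:
    """Summarise numeric price readings from a crowd.

    Sample SD uses the n-1 denominator and is UNDEFINED for a single reading.
    """
    values = []
    for r in readings:
        v = r.value if isinstance(r, Rating) else float(r)
        if isinstance(r, Rating) and r.kind != AnswerKind.NUMERIC:
            raise ValueError("aggregate_prices requires numeric ratings")
        if v < 0:
            raise ValueError(f"invalid price {v!r}")
        values.append(float(v))
    if not values:
        raise ValueError("no readings")
    arr = np.asarray(values)
    if arr.size == 1:
        sd = UNDEFINED
        mean = float(arr[0])
    elif arr.max() == arr.min():  # unanimous crowd: mean is the value, SD exactly 0
        sd = 0.0
        mean = float(arr[0])
    else:
        sd = float(arr.std(ddof=1))
        mean = float(arr.mean())
    return PriceSummary(mean=mean, sd=sd, n=arr.size, min=float(arr.min()))


def crop_iou(a: CropBox, b: CropBox) -> float:
    """Intersection-over-union of two crop boxes under the half-open convention."""
    ix = max(0.0, min(a.x1, b.x1) - max(a.x0, b.x0))
    iy = max(0.0, min(a.y1, b.y1) - max(a.y0, b.y0))
    inter = ix * iy
    union = a.area + b.area - inter
    return inter / union


@dataclass(frozen=True)
class CropCluster:
    """A group of near-duplicate boxes judged to denote the same item."""

    tag: str
    boxes: tuple
    raters: frozenset
    representative: CropBox

    @property
    def support(self) -> int:
        """Number of distinct raters contributing a box to the cluster."""
        return len(self.raters)


def _median_box(boxes: Sequence[CropBox], tag: str) -> CropBox:
    coords = np.array([[b.x0, b.y0, b.x1, b.y1] for b in boxes])
    x0, y0, x1, y1 = np.median(coords, axis=0)
    if x1 <= x0:  # guard: medians of valid boxes can only coincide, not cross
        x1 = x0 + 1
    if y1 <= y0:
        y1 = y0 + 1
    return CropBox(float(x0), float(y0), float(x1), float(y1), tag)


def cluster_crops(
    crops: Iterable[tuple[str, TaggedCrop]] | Mapping[str, Sequence[TaggedCrop]],
    iou_threshold: float = 0.5,
) -> list[CropCluster]:
    """Single-linkage clustering of crop boxes from multiple raters.

    Two boxes are linked when they share a tag and overlap with IoU at or
    above ``iou_threshold``; clusters are the connected components of that
    graph.  Each cluster reports the coordinate-wise median box as its
    representative and the number of distinct supporting raters.  The default
    threshold 0.5 is the standard detection-overlap convention.
    """
    if not (0.0 < iou_threshold <= 1.0):
        raise ValueError("iou_threshold must lie in (0, 1]")
    if isinstance(crops, Mapping):
        pairs = [(rid, tc) for rid, tcs in crops.items() for tc in tcs]
    else:
        pairs = list(crops)

    items: list[tuple[str, str, CropBox]] = []  # (rater, tag, box)
    for rater_id, tagged in pairs:
        for box in tagged.boxes:
            items.append((rater_id, tagged.tag, box))

    n = len(items)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if items[i][1] != items[j][1]:
                continue
            if crop_iou(items[i][2], items[j][2]) >= iou_threshold:
                parent[find(i)] = find(j)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)

    clusters = []
    for members in groups.values():
        tag = items[members[0]][1]
        boxes = tuple(items[i][2] for i in members)
        raters = frozenset(items[i][0] for i in members)
        clusters.append(CropCluster(tag, boxes, raters, _median_box(boxes, tag)))
    # deterministic order: by tag, then by representative position
    clusters.sort(key=lambda c: (c.tag, c.representative.x0, c.representative.y0))
    return clusters


def chi_square_homogeneity(table: ContingencyTable) -> tuple[float, int, float]:
    """Pearson chi-square test of homogeneity across task arms.

    No continuity correction; df = (r-1)(c-1); expected counts from the
    row/column margins.  Raises on a zero margin (degenerate table).
    """
    arr = table.array
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("degenerate table: zero row or column margin")
    stat, p, df, _ = _sps.chi2_contingency(arr, correction=False)
    return float(stat), int(df), float(p)


def proportion_with_ci(
    successes: int, n: int, confidence: float = 0.95
) -> tuple[float, tuple[float, float]]:
    """Point estimate with a Wilson score interval, bounded in [0,1]."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not (0 <= successes <= n):
        raise ValueError("successes must lie in [0, n]")
    lo, hi = proportion_confint(successes, n, alpha=1 - confidence, method="wilson")
    return successes / n, (float(lo), float(hi))
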