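"""Synthetic rater-pool and gold-standard generator.

Emulates the crowd-size study design — a fixed pool of raters who all rate the
same photo set — so that every downstream stage (consensus, workflow routing,
crowd-size calibration) runs end-to-end with no crowdsourcing platform and no
real images.  Photos are abstract records carrying a truth assignment: which
target features are present, the true lowest advertised price plus a salient
distractor price, and a true crop box per present feature.

Raters are parameterised by sensitivity (P(report present | present)) and
specificity (P(report absent | absent)), with optional pool heterogeneity.
Price readings add Gaussian noise and, with some probability, substitute the
distractor price — the failure mode where a cheap non-tobacco ad is reported
as the lowest tobacco price.  Crop boxes get independent Gaussian jitter on
each edge, clamped to the photo frame.  Errors are independent across raters
and photos.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as _sps

from .annotation_core import (
    ABSENT,
    PRESENT,
    AnswerKind,
    CropBox,
    PhotoRecord,
    Rating,
    TaggedCrop,
)

__all__ = [
    "RaterProfile",
    "SimConfig",
    "GoldStandard",
    "Study",
    "generate_study",
    "simulate_binary_ratings",
    "binary_vote_matrix",
    "simulate_price_readings",
    "simulate_crop_boxes",
    "consensus_accuracy_closed_form",
]


@dataclass(frozen=True)
class RaterProfile:
    """Error model for one simulated crowd rater."""

    rater_id: str
    sensitivity: float = 0.75
    specificity: float = 0.75
    price_noise_sd: float = 0.25
    crop_jitter_sd: float = 4.0
    distractor_rate: float = 0.0

    def __post_init__(self):
        for name in ("sensitivity", "specificity", "distractor_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0,1]")
        if self.price_noise_sd < 0 or self.crop_jitter_sd < 0:
            raise ValueError("noise parameters must be nonnegative")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for a synthetic crowd-annotation experiment.

    Defaults mirror the reference crowd-size design: a pool of 500 raters all
    rating the same 8 storefront photographs, with moderately accurate raters
    (sensitivity = specificity = 0.75).  ``features`` maps feature id to
    prevalence.  ``sensitivity_sd``/``specificity_sd`` > 0 draw heterogeneous
    per-rater accuracies (truncated to [0.01, 0.99]).
    """

    n_photos: int = 8
    n_raters: int = 500
    features: Mapping[str, float] = field(
        default_factory=lambda: {"tobacco_ad": 0.5}
    )
    sensitivity: float = 0.75
    specificity: float = 0.75
    sensitivity_sd: float = 0.0
    specificity_sd: float = 0.0
    price_noise_sd: float = 0.25
    distractor_rate: float = 0.0
    crop_jitter_sd: float = 4.0
    photo_width: int = 1600
    photo_height: int = 1200
    price_range: tuple = (4.50, 9.00)
    distractor_price: float = 2.59
    seed: int = 0

    def __post_init__(self):
        if self.n_photos <= 0:
            raise ValueError("n_photos must be positive")
        if self.n_raters < 2:
            raise ValueError("n_raters must be at least 2")
        for fid, prev in dict(self.features).items():
            if not (0.0 <= prev <= 1.0):
                raise ValueError(f"prevalence for {fid!r} outside [0,1]")
        for name in ("sensitivity", "specificity", "distractor_rate"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} outside [0,1]")
        object.__setattr__(self, "features", dict(self.features))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["features"] = dict(self.features)
        d["price_range"] = list(self.price_range)
        return d


@dataclass(frozen=True)
class GoldStandard:
    """Complete truth assignment for a simulated (or field-surveyed) study.

    ``truth[photo_id][feature_id]`` is ``present``/``absent``; priced photos
    also carry a (true_price, distractor_price) pair and one true crop box per
    present feature.
    """

    truth: Mapping[str, Mapping[str, str]]
    prices: Mapping[str, tuple] = field(default_factory=dict)
    boxes: Mapping[str, Sequence[CropBox]] = field(default_factory=dict)

    def labels(self, feature_id: str, photo_ids: Sequence[str]) -> np.ndarray:
        """Binary truth vector (1 = present) for one feature over given photos."""
        out = []
        for pid in photo_ids:
            row = self.truth.get(pid)
            if row is None or feature_id not in row:
                raise KeyError(f"unknown feature {feature_id!r} for photo {pid!r}")
            out.append(1 if row[feature_id] == PRESENT else 0)
        return np.asarray(out, dtype=int)


@dataclass(frozen=True)
class Study:
    photos: tuple
    gold: GoldStandard
    raters: tuple
    config: SimConfig

    @property
    def photo_ids(self) -> list[str]:
        return [p.photo_id for p in self.photos]

    @property
    def rater_ids(self) -> list[str]:
        return [r.rater_id for r in self.raters]


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def generate_study(config: SimConfig) -> Study:
    """Draw photos, their truth assignment, and a rater pool.

    Deterministic given ``config.seed``: the same configuration always yields
    the identical study, byte for byte once serialised.
    """
    rng = _rng(config.seed)
    photos = []
    truth: dict[str, dict[str, str]] = {}
    prices: dict[str, tuple] = {}
    boxes: dict[str, list[CropBox]] = {}

    w, h = config.photo_width, config.photo_height
    for i in range(config.n_photos):
        pid = f"photo{i:05d}"
        feats = {}
        present_ids = []
        for fid, prev in config.features.items():
            hit = rng.random() < prev
            feats[fid] = PRESENT if hit else ABSENT
            if hit:
                present_ids.append(fid)
        truth[pid] = feats
        lo, hi = config.price_range
        true_price = round(float(rng.uniform(lo, hi)), 2)
        prices[pid] = (true_price, config.distractor_price)
        pboxes = []
        for fid in present_ids:
            # a plausible ad footprint: 10-30% of each frame dimension
            bw = rng.uniform(0.10, 0.30) * w
            bh = rng.uniform(0.10, 0.30) * h
            x0 = rng.uniform(0, w - bw)
            y0 = rng.uniform(0, h - bh)
            pboxes.append(
                CropBox(round(x0), round(y0), round(x0 + bw), round(y0 + bh), tag=fid)
            )
        boxes[pid] = pboxes
        photos.append(PhotoRecord(pid, w, h, frozenset(present_ids)))

    def _trunc(mean: float, sd: float, size: int) -> np.ndarray:
        if sd == 0:
            return np.full(size, mean)
        return np.clip(rng.normal(mean, sd, size), 0.01, 0.99)

    sens = _trunc(config.sensitivity, config.sensitivity_sd, config.n_raters)
    spec = _trunc(config.specificity, config.specificity_sd, config.n_raters)
    raters = tuple(
        RaterProfile(
            rater_id=f"rater{j:05d}",
            sensitivity=float(sens[j]),
            specificity=float(spec[j]),
            price_noise_sd=config.price_noise_sd,
            crop_jitter_sd=config.crop_jitter_sd,
            distractor_rate=config.distractor_rate,
        )
        for j in range(config.n_raters)
    )
    gold = GoldStandard(truth=truth, prices=prices, boxes=boxes)
    return Study(photos=tuple(photos), gold=gold, raters=raters, config=config)


def binary_vote_matrix(
    study: Study, feature_id: str, seed
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate the complete rater x photo 0/1 vote matrix for one feature.

    Returns ``(votes, labels)`` with ``votes[i, j]`` the vote of rater i on
    photo j (1 = present) and ``labels`` the binary truth per photo.  Every
    rater rates every photo (complete design); errors are independent across
    cells: a rater reports ``present`` on a positive photo with probability
    equal to their sensitivity, and ``absent`` on a negative photo with
    probability equal to their specificity.
    """
    if feature_id not in study.config.features:
        raise KeyError(f"unknown feature {feature_id!r}")
    rng = _rng(seed)
    labels = study.gold.labels(feature_id, study.photo_ids)
    sens = np.array([r.sensitivity for r in study.raters])[:, None]
    spec = np.array([r.specificity for r in study.raters])[:, None]
    p_present = np.where(labels[None, :] == 1, sens, 1.0 - spec)
    votes = (rng.random(p_present.shape) < p_present).astype(np.int8)
    return votes, labels


def simulate_binary_ratings(
    study: Study, feature_id: str, seed, question_id: str | None = None
) -> list[Rating]:
    """Materialise the vote matrix as individual Rating records."""
    votes, _ = binary_vote_matrix(study, feature_id, seed)
    qid = question_id or feature_id
    pids, rids = study.photo_ids, study.rater_ids
    out = []
    for i, rid in enumerate(rids):
        for j, pid in enumerate(pids):
            out.append(
                Rating(
                    photo_id=pid,
                    rater_id=rid,
                    question_id=qid,
                    kind=AnswerKind.BINARY,
                    value=PRESENT if votes[i, j] else ABSENT,
                )
            )
    return out


def simulate_price_readings(
    study: Study, seed, question_id: str = "lowest_price"
) -> list[Rating]:
    """Simulate "lowest advertised price" readings for every rater x photo.

    With probability ``distractor_rate`` the rater reports the photo's salient
    distractor price (a cheap non-target ad); otherwise the true price plus
    Gaussian noise, truncated at zero and rounded to cents.
    """
    rng = _rng(seed)
    out = []
    for rater in study.raters:
        for pid in study.photo_ids:
            true_price, distractor = study.gold.prices[pid]
            if rng.random() < rater.distractor_rate:
                value = distractor
            else:
                value = max(0.0, true_price + rng.normal(0, rater.price_noise_sd)) if rater.price_noise_sd > 0 else true_price
            out.append(
                Rating(
                    photo_id=pid,
                    rater_id=rater.rater_id,
                    question_id=question_id,
                    kind=AnswerKind.NUMERIC,
                    value=round(float(value), 2),
                )
            )
    return out


def simulate_crop_boxes(study: Study, seed) -> list[tuple[str, str, TaggedCrop]]:
    """Simulate jittered crop boxes: (photo_id, rater_id, TaggedCrop) triples.

    Each reported box is the true box with independent Gaussian jitter on each
    of its four edges, clamped to the photo frame so the result is always a
    valid box.
    """
    rng = _rng(seed)
    out = []
    frame = {p.photo_id: (p.width_px, p.height_px) for p in study.photos}
    for rater in study.raters:
        sd = rater.crop_jitter_sd
        for pid in study.photo_ids:
            w, h = frame[pid]
            for true_box in study.gold.boxes[pid]:
                if sd > 0:
                    dx0, dy0, dx1, dy1 = rng.normal(0, sd, 4)
                else:
                    dx0 = dy0 = dx1 = dy1 = 0.0
                x0, y0 = true_box.x0 + dx0, true_box.y0 + dy0
                x1, y1 = true_box.x1 + dx1, true_box.y1 + dy1
                if x1 <= x0:  # crossed edges: fall back to the true extent
                    x0, x1 = true_box.x0, true_box.x1
                if y1 <= y0:
                    y0, y1 = true_box.y0, true_box.y1
                x0 = min(max(x0, 0.0), w - 1.0)
                x1 = min(max(x1, x0 + 1.0), w)
                y0 = min(max(y0, 0.0), h - 1.0)
                y1 = min(max(y1, y0 + 1.0), h)
                jittered = CropBox(x0, y0, x1, y1, true_box.tag)
                out.append((pid, rater.rater_id, TaggedCrop(true_box.tag, (jittered,))))
    return out


def consensus_accuracy_closed_form(n_raters: int, p: float) -> float:
    """P(majority of n independent raters is correct), each correct w.p. p.

    Exact binomial upper-tail sum P(Binomial(n, p) > n/2); requires odd n so
    ties are impossible (use the simulation path for even crowds).
    """
    if n_raters % 2 == 0:
        raise ValueError("n_raters must be odd: even crowds can tie")
    if not (0.0 <= p <= 1.0):
        raise ValueError("p outside [0,1]")
    return float(_sps.binom.sf(n_raters // 2, n_raters, p))
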