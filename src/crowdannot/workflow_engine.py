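"""Tiered adaptive annotation workflow.

Annotation is decomposed into a DAG of small tasks (tiers): a cheap filter
question first (is any tobacco ad present?), then progressively more detailed
questions (which brand? what price?) only for photos that warrant them.
Routing is adaptive: an "absent" consensus at a filter tier drops the photo
from the pipeline (no point asking the brand of an ad that is not there), a
failed consensus escalates the photo to an expert queue, and everything else
flows to a child tier.  The engine also covers the reverse-crop ("black-out")
round structure: regions already cropped are masked before the photo is
reshown, discoveries are deduplicated across rounds by crop-box clustering,
and payment is graded so that items first found in later rounds — the
difficult-to-spot ones — pay more.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence

from shapely.geometry import box as _shapely_box
from shapely.ops import unary_union

from .annotation_core import (
    ABSENT,
    NO_CONSENSUS,
    ConsensusResult,
    CropBox,
    PhotoRecord,
    Rating,
    TaggedCrop,
    cluster_crops,
    majority_vote,
)

__all__ = [
    "TERMINAL",
    "ESCALATE",
    "FILTER",
    "ANY",
    "RoutingRule",
    "TaskTier",
    "Workflow",
    "WorkItem",
    "PaymentSchedule",
    "MaskedPhoto",
    "DiscoveryRecord",
    "route_next",
    "run_workflow",
    "replay_audit_log",
    "apply_reverse_crop",
    "deduplicate_discoveries",
    "compute_payment",
]

# routing destinations / wildcards
TERMINAL = "TERMINAL"
ESCALATE = "ESCALATE"
FILTER = "FILTER"
ANY = "ANY"

_STATUS_PENDING = "pending"
_STATUS_AWAITING = "awaiting_ratings"
_STATUS_RESOLVED = "resolved"
_STATUS_ESCALATED = "escalated"
_STATUS_FILTERED = "filtered_out"


@dataclass(frozen=True)
class RoutingRule:
    """One edge of the tier graph: a condition on the consensus, a destination.

    ``when`` is a concrete answer value, the string "NO_CONSENSUS", or the
    wildcard ANY.  ``goto`` is a child tier id or one of the terminal
    destinations TERMINAL / ESCALATE / FILTER.  Rules are evaluated in
    declaration order; the first match wins.
    """

    when: object
    goto: str

    def matches(self, consensus: ConsensusResult) -> bool:
        if self.when == ANY:
            return True
        if self.when == "NO_CONSENSUS" or self.when is NO_CONSENSUS:
            return consensus.decision is NO_CONSENSUS
        return consensus.decision == self.when


@dataclass(frozen=True)
class TaskTier:
    tier_id: str
    question_id: str
    required_raters: int = 5
    rule: str = "plurality"
    threshold: float | None = None
    routes: tuple = ()

    def __post_init__(self):
        if self.required_raters < 1:
            raise ValueError("required_raters must be at least 1")
        object.__setattr__(self, "routes", tuple(self.routes))


@dataclass(frozen=True)
class Workflow:
    """Validated tier graph with a single entry tier."""

    tiers: Mapping[str, TaskTier]
    entry: str

    def __post_init__(self):
        tiers = dict(self.tiers)
        object.__setattr__(self, "tiers", tiers)
        if self.entry not in tiers:
            raise ValueError(f"entry tier {self.entry!r} not defined")
        for tier in tiers.values():
            if not tier.routes:
                raise ValueError(f"tier {tier.tier_id!r} has no routing rules")
            for r in tier.routes:
                if r.goto not in (TERMINAL, ESCALATE, FILTER) and r.goto not in tiers:
                    raise ValueError(
                        f"tier {tier.tier_id!r} routes to unknown tier {r.goto!r}"
                    )
            covered = any(
                r.when == ANY or r.when == "NO_CONSENSUS" or r.when is NO_CONSENSUS
                for r in tier.routes
            )
            if not covered:
                raise ValueError(
                    f"tier {tier.tier_id!r} routing does not cover NO_CONSENSUS"
                )
        self._check_acyclic()

    def _check_acyclic(self):
        WHITE, GREY, BLACK = 0, 1, 2
        colour = {t: WHITE for t in self.tiers}

        def visit(t: str, stack: list[str]):
            colour[t] = GREY
            for r in self.tiers[t].routes:
                nxt = r.goto
                if nxt in (TERMINAL, ESCALATE, FILTER):
                    continue
                if colour[nxt] == GREY:
                    raise ValueError(f"cycle in tier graph through {nxt!r}")
                if colour[nxt] == WHITE:
                    visit(nxt, stack + [nxt])
            colour[t] = BLACK

        for t in self.tiers:
            if colour[t] == WHITE:
                visit(t, [t])


@dataclass(frozen=True)
class WorkItem:
    """A photo's position in the workflow."""

    photo_id: str
    tier_id: str
    status: str = _STATUS_PENDING
    history: tuple = ()  # accumulated ConsensusResults
    mask: tuple = ()  # CropBoxes blacked out so far

    @property
    def terminal(self) -> bool:
        return self.status in (_STATUS_RESOLVED, _STATUS_ESCALATED, _STATUS_FILTERED)


@dataclass(frozen=True)
class PaymentSchedule:
    """Graded payment: items first discovered in later rounds pay more.

    A discovery first made in round r is credited base_rate * multiplier**(r-1)
    (multiplier >= 1, so payment is monotone nondecreasing in difficulty);
    redundant re-finds of an already-discovered item pay the base rate only.
    """

    base_rate: float = 0.05
    multiplier: float = 2.0

    def __post_init__(self):
        if self.base_rate < 0:
            raise ValueError("negative rates are not allowed")
        if self.multiplier < 1:
            raise ValueError("multiplier must be at least 1")

    def rate_for_round(self, discovery_round: int) -> float:
        return self.base_rate * self.multiplier ** (discovery_round - 1)


def route_next(item: WorkItem, consensus: ConsensusResult, workflow: Workflow) -> WorkItem:
    """Advance a work item given the consensus reached at its current tier."""
    if item.terminal:
        raise ValueError(f"photo {item.photo_id!r} already terminal")
    tier = workflow.tiers[item.tier_id]
    for rule in tier.routes:
        if not rule.matches(consensus):
            continue
        history = item.history + (consensus,)
        if rule.goto == TERMINAL:
            return replace(item, status=_STATUS_RESOLVED, history=history)
        if rule.goto == ESCALATE:
            return replace(item, status=_STATUS_ESCALATED, history=history)
        if rule.goto == FILTER:
            return replace(item, status=_STATUS_FILTERED, history=history)
        return replace(item, tier_id=rule.goto, status=_STATUS_PENDING, history=history)
    raise ValueError(
        f"routing table incomplete: tier {item.tier_id!r} has no rule for "
        f"decision {consensus.decision!r}"
    )


RatingsProvider = Callable[[str, str, int], Sequence[Rating]]


def run_workflow(
    photos: Sequence[PhotoRecord],
    provider: RatingsProvider,
    workflow: Workflow,
) -> tuple[list[WorkItem], list[dict]]:
    """Flow every photo through the tier graph until it reaches a terminal status.

    ``provider(photo_id, question_id, n)`` supplies the n ratings for a task
    instance — a recorded table or a simulator.  Returns the final work items
    and an audit log with one entry per transition (photo, tier, consensus
    decision and vote fraction, outcome), from which the run can be replayed
    and verified.  Deterministic given a deterministic provider.
    """
    items: list[WorkItem] = []
    audit: list[dict] = []
    for photo in photos:
        item = WorkItem(photo_id=photo.photo_id, tier_id=workflow.entry)
        while not item.terminal:
            tier = workflow.tiers[item.tier_id]
            ratings = provider(photo.photo_id, tier.question_id, tier.required_raters)
            item = replace(item, status=_STATUS_AWAITING)
            consensus = majority_vote(ratings, rule=tier.rule, threshold=tier.threshold)
            prev_tier = item.tier_id
            item = route_next(item, consensus, workflow)
            audit.append(
                {
                    "photo_id": photo.photo_id,
                    "tier": prev_tier,
                    "question_id": tier.question_id,
                    "decision": "NO_CONSENSUS" if consensus.decision is NO_CONSENSUS else consensus.decision,
                    "vote_fraction": consensus.vote_fraction,
                    "n_raters": consensus.n_raters,
                    "outcome": item.status if item.terminal else item.tier_id,
                }
            )
        items.append(item)
    return items, audit


def replay_audit_log(audit: Iterable[dict], workflow: Workflow) -> dict[str, str]:
    """Re-derive each photo's final status from the audit log alone.

    Used to verify determinism: replaying the log through the routing tables
    must land every photo in the same terminal status as the original run.
    """
    state: dict[str, WorkItem] = {}
    for entry in audit:
        pid = entry["photo_id"]
        item = state.get(pid) or WorkItem(photo_id=pid, tier_id=workflow.entry)
        if item.tier_id != entry["tier"]:
            raise ValueError(f"audit log out of order for photo {pid!r}")
        decision = NO_CONSENSUS if entry["decision"] == "NO_CONSENSUS" else entry["decision"]
        consensus = ConsensusResult(
            pid, entry["question_id"], decision, entry["vote_fraction"], entry["n_raters"]
        )
        state[pid] = route_next(item, consensus, workflow)
    return {pid: it.status for pid, it in state.items()}


@dataclass(frozen=True)
class MaskedPhoto:
    """A photo descriptor with blacked-out regions (stored as boxes, not pixels)."""

    photo_id: str
    width_px: int
    height_px: int
    regions: tuple = ()
    revealable: bool = False

    @property
    def masked_area(self) -> float:
        """Area of the union of masked regions (overlaps counted once)."""
        if not self.regions:
            return 0.0
        geom = unary_union([_shapely_box(b.x0, b.y0, b.x1, b.y1) for b in self.regions])
        return float(geom.area)

    @property
    def visible_area(self) -> float:
        return self.width_px * self.height_px - self.masked_area


def apply_reverse_crop(
    photo: PhotoRecord | MaskedPhoto,
    found: Sequence[CropBox],
    reveal_toggle: bool = False,
) -> MaskedPhoto:
    """Black out the already-cropped regions before reshowing a photo.

    The next rater works from a less complex image: easy, already-found items
    are hidden, which cuts redundancy and surfaces what was missed.  The mask
    is the union of found boxes (idempotent: masking the same box twice
    changes nothing); ``reveal_toggle`` marks the regions as visually
    recoverable for cases where a wide crop encroached on a neighbouring item.
    """
    if isinstance(photo, MaskedPhoto):
        base = photo
    else:
        base = MaskedPhoto(photo.photo_id, photo.width_px, photo.height_px)
    for b in found:
        if b.x1 > base.width_px or b.y1 > base.height_px:
            raise ValueError(f"mask box exceeds the frame of {base.photo_id!r}")
    merged = {(b.x0, b.y0, b.x1, b.y1): b for b in (*base.regions, *found)}
    regions = tuple(merged[k] for k in sorted(merged))
    return MaskedPhoto(
        base.photo_id, base.width_px, base.height_px, regions, reveal_toggle
    )


@dataclass(frozen=True)
class DiscoveryRecord:
    """One deduplicated item from a multi-round reverse-crop pass."""

    tag: str
    representative: CropBox
    discovery_round: int
    finders_by_round: Mapping[int, frozenset]  # round -> rater ids

    @property
    def redundancy(self) -> int:
        """Finds in rounds after the discovery round (re-finds of a known item)."""
        return sum(
            len(rids)
            for rnd, rids in self.finders_by_round.items()
            if rnd > self.discovery_round
        )


def deduplicate_discoveries(
    rounds: Sequence[Sequence[tuple[str, TaggedCrop]]],
    iou_threshold: float = 0.5,
) -> list[DiscoveryRecord]:
    """Cluster crop finds across reverse-crop rounds into distinct items.

    ``rounds[r]`` holds the (rater_id, TaggedCrop) finds of round r+1.  Boxes
    are clustered across all rounds (same tag, IoU at or above threshold,
    single linkage); each cluster's discovery round is the earliest round with
    a member, and later-round members count as redundancy.  Items surfacing
    only in late rounds are the difficult-to-spot ones that the graded payment
    schedule rewards.
    """
    if not rounds:
        raise ValueError("at least one round is required")
    flat: list[tuple[str, TaggedCrop]] = []
    origin: dict[tuple[float, float, float, float, str], list[tuple[int, str]]] = {}
    for rnd, finds in enumerate(rounds, start=1):
        for rater_id, tagged in finds:
            flat.append((rater_id, tagged))
            for b in tagged.boxes:
                origin.setdefault((b.x0, b.y0, b.x1, b.y1, b.tag), []).append(
                    (rnd, rater_id)
                )

    records = []
    for cluster in cluster_crops(flat, iou_threshold=iou_threshold):
        finders: dict[int, set] = {}
        for b in cluster.boxes:
            for rnd, rater_id in origin[(b.x0, b.y0, b.x1, b.y1, b.tag)]:
                finders.setdefault(rnd, set()).add(rater_id)
        disc = min(finders)
        records.append(
            DiscoveryRecord(
                tag=cluster.tag,
                representative=cluster.representative,
                discovery_round=disc,
                finders_by_round={r: frozenset(v) for r, v in sorted(finders.items())},
            )
        )
    records.sort(key=lambda r: (r.discovery_round, r.tag, r.representative.x0))
    return records


def compute_payment(
    ledger: Sequence[DiscoveryRecord], schedule: PaymentSchedule
) -> dict[str, float]:
    """Per-rater payment under the graded schedule.

    Raters who first surface an item in its discovery round earn the
    difficulty-multiplied rate for that round; raters who re-find an already
    discovered item earn the base rate.
    """
    payments: dict[str, float] = {}
    for record in ledger:
        for rnd, raters in record.finders_by_round.items():
            rate = (
                schedule.rate_for_round(rnd)
                if rnd == record.discovery_round
                else schedule.base_rate
            )
            for rater_id in raters:
                payments[rater_id] = payments.get(rater_id, 0.0) + rate
    return payments
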