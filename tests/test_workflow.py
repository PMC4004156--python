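"""Tests for tiered routing, reverse-crop masking, dedup, and payments."""

import math

import numpy as np
import pytest

from crowdannot.annotation_core import (
    ABSENT,
    NO_CONSENSUS,
    PRESENT,
    AnswerKind,
    ConsensusResult,
    CropBox,
    PhotoRecord,
    Rating,
    TaggedCrop,
)
from crowdannot.rater_sim import SimConfig, binary_vote_matrix, generate_study
from crowdannot.workflow_engine import (
    ANY,
    ESCALATE,
    FILTER,
    TERMINAL,
    DiscoveryRecord,
    MaskedPhoto,
    PaymentSchedule,
    RoutingRule,
    TaskTier,
    WorkItem,
    Workflow,
    apply_reverse_crop,
    compute_payment,
    deduplicate_discoveries,
    replay_audit_log,
    route_next,
    run_workflow,
)


def presence_brand_workflow(required=5):
    """Two-tier workflow: ad presence filter, then brand identification."""
    return Workflow(
        tiers={
            "presence": TaskTier(
                tier_id="presence",
                question_id="tobacco_ad",
                required_raters=required,
                routes=(
                    RoutingRule(when=ABSENT, goto=FILTER),
                    RoutingRule(when="NO_CONSENSUS", goto=ESCALATE),
                    RoutingRule(when=ANY, goto="brand"),
                ),
            ),
            "brand": TaskTier(
                tier_id="brand",
                question_id="brand",
                required_raters=required,
                routes=(
                    RoutingRule(when="NO_CONSENSUS", goto=ESCALATE),
                    RoutingRule(when=ANY, goto=TERMINAL),
                ),
            ),
        },
        entry="presence",
    )


def simulated_provider(study, seed, brand="Newport"):
    """Ratings provider backed by the synthetic rater pool."""
    votes = {}
    for fid in study.config.features:
        m, _ = binary_vote_matrix(study, fid, seed)
        votes[fid] = m
    pidx = {p: j for j, p in enumerate(study.photo_ids)}
    ridx = list(range(len(study.raters)))

    def provider(photo_id, question_id, n):
        j = pidx[photo_id]
        if question_id in votes:
            return [
                Rating(photo_id, f"r{i}", question_id, AnswerKind.BINARY,
                       PRESENT if votes[question_id][i, j] else ABSENT)
                for i in ridx[:n]
            ]
        # brand question: perfect raters name the gold brand
        return [
            Rating(photo_id, f"r{i}", question_id, AnswerKind.CATEGORICAL, brand)
            for i in ridx[:n]
        ]

    return provider


class TestWorkflowValidation:
    def test_cycle_rejected(self):
        with pytest.raises(ValueError, match="cycle"):
            Workflow(
                tiers={
                    "a": TaskTier("a", "q1", routes=(
                        RoutingRule(when="NO_CONSENSUS", goto=ESCALATE),
                        RoutingRule(when=ANY, goto="b"))),
                    "b": TaskTier("b", "q2", routes=(
                        RoutingRule(when="NO_CONSENSUS", goto=ESCALATE),
                        RoutingRule(when=ANY, goto="a"))),
                },
                entry="a",
            )

    def test_missing_no_consensus_coverage_rejected(self):
        with pytest.raises(ValueError, match="NO_CONSENSUS"):
            Workflow(
                tiers={"a": TaskTier("a", "q", routes=(RoutingRule(when=PRESENT, goto=TERMINAL),))},
                entry="a",
            )

    def test_unknown_target_tier_rejected(self):
        with pytest.raises(ValueError, match="unknown tier"):
            Workflow(
                tiers={"a": TaskTier("a", "q", routes=(RoutingRule(when=ANY, goto="ghost"),))},
                entry="a",
            )


class TestRouting:
    def test_absent_consensus_filters_out(self):
        wf = presence_brand_workflow()
        item = WorkItem("p1", "presence")
        c = ConsensusResult("p1", "tobacco_ad", ABSENT, 0.9, 10)
        assert route_next(item, c, wf).status == "filtered_out"

    def test_no_consensus_escalates(self):
        wf = presence_brand_workflow()
        c = ConsensusResult("p1", "tobacco_ad", NO_CONSENSUS, 0.5, 10)
        assert route_next(WorkItem("p1", "presence"), c, wf).status == "escalated"

    def test_present_advances_to_brand_tier(self):
        wf = presence_brand_workflow()
        c = ConsensusResult("p1", "tobacco_ad", PRESENT, 0.8, 10)
        nxt = route_next(WorkItem("p1", "presence"), c, wf)
        assert nxt.tier_id == "brand" and not nxt.terminal
        assert nxt.history == (c,)

    def test_terminal_transition(self):
        wf = presence_brand_workflow()
        c = ConsensusResult("p1", "brand", "Newport", 1.0, 5)
        assert route_next(WorkItem("p1", "brand"), c, wf).status == "resolved"

    def test_incomplete_routing_table_errors_at_runtime(self):
        wf = Workflow(
            tiers={"a": TaskTier("a", "q", routes=(
                RoutingRule(when="NO_CONSENSUS", goto=ESCALATE),
                RoutingRule(when=PRESENT, goto=TERMINAL)))},
            entry="a",
        )
        c = ConsensusResult("p1", "q", ABSENT, 1.0, 5)
        with pytest.raises(ValueError, match="routing table incomplete"):
            route_next(WorkItem("p1", "a"), c, wf)


class TestRunWorkflow:
    def test_zero_prevalence_filters_everything(self):
        study = generate_study(SimConfig(
            n_photos=30, n_raters=5, features={"tobacco_ad": 0.0},
            sensitivity=1.0, specificity=1.0, seed=80))
        wf = presence_brand_workflow()
        items, audit = run_workflow(study.photos, simulated_provider(study, 81), wf)
        assert all(it.status == "filtered_out" for it in items)
        assert not any(e["tier"] == "brand" for e in audit)

    def test_full_prevalence_perfect_raters_all_resolved(self):
        study = generate_study(SimConfig(
            n_photos=30, n_raters=5, features={"tobacco_ad": 1.0},
            sensitivity=1.0, specificity=1.0, seed=82))
        wf = presence_brand_workflow()
        items, _ = run_workflow(study.photos, simulated_provider(study, 83), wf)
        assert all(it.status == "resolved" for it in items)
        assert all(it.history[-1].decision == "Newport" for it in items)

    def test_conservation_and_adaptive_filtering(self):
        """resolved + escalated + filtered_out = n_photos; with perfect
        raters brand tasks equal the brute-force count of positive photos."""
        study = generate_study(SimConfig(
            n_photos=400, n_raters=5, features={"tobacco_ad": 0.4},
            sensitivity=1.0, specificity=1.0, seed=84))
        wf = presence_brand_workflow()
        items, audit = run_workflow(study.photos, simulated_provider(study, 85), wf)
        statuses = [it.status for it in items]
        assert len(items) == 400
        assert sum(s in ("resolved", "escalated", "filtered_out") for s in statuses) == 400
        n_brand_tasks = sum(e["tier"] == "brand" for e in audit)
        truly_positive = int(study.gold.labels("tobacco_ad", study.photo_ids).sum())
        assert n_brand_tasks == truly_positive
        n_pos_expected = 0.4 * 400
        assert abs(truly_positive - n_pos_expected) <= 3 * math.sqrt(400 * 0.4 * 0.6)

    def test_audit_log_replays_to_identical_state(self):
        study = generate_study(SimConfig(
            n_photos=60, n_raters=6, features={"tobacco_ad": 0.5}, seed=86))
        wf = presence_brand_workflow(required=6)
        items, audit = run_workflow(study.photos, simulated_provider(study, 87), wf)
        replayed = replay_audit_log(audit, wf)
        assert replayed == {it.photo_id: it.status for it in items}


class TestReverseCrop:
    def test_no_boxes_identity(self):
        photo = PhotoRecord("p1", 800, 600)
        m = apply_reverse_crop(photo, [])
        assert m.regions == () and m.masked_area == 0.0
        assert m.visible_area == 800 * 600

    def test_overlapping_boxes_mask_union_not_sum(self):
        """Two 100x100 boxes overlapping by 50x100: union is 15000, not 20000."""
        photo = PhotoRecord("p1", 800, 600)
        m = apply_reverse_crop(photo, [CropBox(0, 0, 100, 100), CropBox(50, 0, 150, 100)])
        assert m.masked_area == pytest.approx(15000.0)

    def test_idempotence(self):
        photo = PhotoRecord("p1", 800, 600)
        b = CropBox(10, 10, 60, 60)
        once = apply_reverse_crop(photo, [b])
        twice = apply_reverse_crop(once, [b])
        assert once.regions == twice.regions
        assert once.masked_area == twice.masked_area

    def test_masked_area_monotone_across_rounds(self, rng):
        photo = PhotoRecord("p1", 1000, 1000)
        m = apply_reverse_crop(photo, [])
        prev = 0.0
        for _ in range(5):
            x0, y0 = rng.uniform(0, 800, 2)
            m = apply_reverse_crop(m, [CropBox(x0, y0, x0 + 150, y0 + 150)])
            assert m.masked_area >= prev - 1e-9
            assert m.visible_area <= 1000 * 1000
            prev = m.masked_area

    def test_out_of_frame_mask_rejected(self):
        with pytest.raises(ValueError, match="frame"):
            apply_reverse_crop(PhotoRecord("p1", 100, 100), [CropBox(50, 50, 200, 80)])

    def test_reveal_toggle_recorded(self):
        m = apply_reverse_crop(PhotoRecord("p1", 100, 100), [CropBox(0, 0, 10, 10)],
                               reveal_toggle=True)
        assert m.revealable


def tc(x0, y0, x1, y1, tag="ad"):
    return TaggedCrop(tag, (CropBox(x0, y0, x1, y1, tag),))


class TestDiscoveryDedup:
    def test_refind_counts_as_redundancy(self):
        rounds = [[("r1", tc(0, 0, 100, 100))], [("r2", tc(2, 0, 100, 100))]]
        ledger = deduplicate_discoveries(rounds)
        assert len(ledger) == 1
        rec = ledger[0]
        assert rec.discovery_round == 1
        assert rec.redundancy == 1

    def test_late_round_discovery(self):
        rounds = [[], [], [("r9", tc(0, 0, 50, 50))]]
        ledger = deduplicate_discoveries(rounds)
        assert ledger[0].discovery_round == 3

    def test_randomized_three_round_scenario(self, rng):
        """5 separated true boxes found across 3 rounds: ledger matches a
        brute-force first-round/matching oracle."""
        truths = [CropBox(200 * i + 50, 200 * i + 50, 200 * i + 170, 200 * i + 170, "ad")
                  for i in range(5)]
        appearances = {i: sorted(rng.choice([1, 2, 3], size=int(rng.integers(1, 4)),
                                            replace=False)) for i in range(5)}
        rounds = [[], [], []]
        for i, rnds in appearances.items():
            for r in rnds:
                t = truths[i]
                d = rng.normal(0, 2, 4)
                rounds[r - 1].append(
                    (f"r{i}_{r}", TaggedCrop("ad", (CropBox(
                        t.x0 + d[0], t.y0 + d[1], t.x1 + d[2], t.y1 + d[3], "ad"),)))
                )
        ledger = deduplicate_discoveries(rounds)
        assert len(ledger) == 5
        got = sorted((rec.discovery_round, rec.redundancy) for rec in ledger)
        expected = sorted((min(r), len(r) - sum(1 for x in r if x == min(r)))
                          for r in appearances.values())
        assert got == expected

    def test_empty_rounds_rejected(self):
        with pytest.raises(ValueError):
            deduplicate_discoveries([])


class TestPayments:
    def test_round_one_discoveries_pay_base(self):
        rounds = [[("r1", tc(0, 0, 10, 10)), ("r2", tc(100, 100, 110, 110))]]
        ledger = deduplicate_discoveries(rounds)
        pay = compute_payment(ledger, PaymentSchedule(base_rate=0.05, multiplier=2))
        assert pay == {"r1": 0.05, "r2": 0.05}

    def test_round_three_discovery_pays_quadruple(self):
        """m=2: an item first found in round 3 pays 2^(3-1) = 4x base."""
        rounds = [[], [], [("r9", tc(0, 0, 10, 10))]]
        ledger = deduplicate_discoveries(rounds)
        pay = compute_payment(ledger, PaymentSchedule(base_rate=0.05, multiplier=2))
        assert pay["r9"] == pytest.approx(0.20)

    def test_redundant_find_pays_base_only(self):
        rounds = [[("r1", tc(0, 0, 10, 10))], [("r2", tc(0, 0, 10, 10))]]
        pay = compute_payment(deduplicate_discoveries(rounds),
                              PaymentSchedule(base_rate=0.10, multiplier=3))
        assert pay == {"r1": pytest.approx(0.10), "r2": pytest.approx(0.10)}

    def test_empty_ledger(self):
        assert compute_payment([], PaymentSchedule()) == {}

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            PaymentSchedule(base_rate=-1.0)

    def test_payment_monotone_in_round(self):
        s = PaymentSchedule(base_rate=0.05, multiplier=1.5)
        rates = [s.rate_for_round(r) for r in range(1, 6)]
        assert rates == sorted(rates)
        assert all(r >= s.base_rate for r in rates)
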