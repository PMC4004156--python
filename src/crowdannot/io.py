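"""Readers, writers, and reporting for the study file formats.

All tabular artifacts are plain UTF-8 CSV with header rows (RFC 4180
quoting); currency is serialised as decimal strings so round-trips are exact.

ratings.csv   photo_id, rater_id, task_id, question_id, answer_type, answer, timestamp
crops.csv     photo_id, rater_id, task_id, tag, x0, y0, x1, y1   (half-open pixels)
gold.csv      photo_id, feature_id, truth
manifest.json study configuration echo, including the seed
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .annotation_core import (
    NO_CONSENSUS,
    PRESENT,
    AnswerKind,
    ConsensusResult,
    ContingencyTable,
    CropBox,
    Rating,
    TaggedCrop,
    chi_square_homogeneity,
    parse_price,
    proportion_with_ci,
)
from .rater_sim import GoldStandard, Study
from .workflow_engine import PaymentSchedule, RoutingRule, TaskTier, Workflow

logger = logging.getLogger("crowdannot")

RATINGS_COLUMNS = [
    "photo_id",
    "rater_id",
    "task_id",
    "question_id",
    "answer_type",
    "answer",
    "timestamp",
]
CROPS_COLUMNS = ["photo_id", "rater_id", "task_id", "tag", "x0", "y0", "x1", "y1"]
GOLD_COLUMNS = ["photo_id", "feature_id", "truth"]

#: gold.csv feature ids reserved for price truth rows
PRICE_FEATURE = "lowest_price"
DISTRACTOR_FEATURE = "distractor_price"


@dataclass(frozen=True)
class StudyBundle:
    """Resolved file paths of one study directory."""

    ratings: Path
    gold: Path
    crops: Path | None = None
    workflow: Path | None = None
    manifest: Path | None = None

    @classmethod
    def from_dir(cls, directory) -> "StudyBundle":
        d = Path(directory)
        ratings, gold = d / "ratings.csv", d / "gold.csv"
        for p in (ratings, gold):
            if not p.exists():
                raise FileNotFoundError(f"study bundle missing {p.name} in {d}")
        crops = d / "crops.csv"
        wf = d / "workflow.yaml"
        mf = d / "manifest.json"
        return cls(
            ratings=ratings,
            gold=gold,
            crops=crops if crops.exists() else None,
            workflow=wf if wf.exists() else None,
            manifest=mf if mf.exists() else None,
        )


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {', '.join(missing)}")


def read_ratings(path, strict: bool = True) -> list[Rating]:
    """Read ratings.csv into typed Ratings.

    Malformed rows (bad answer type, negative price, missing fields) are
    rejected with line-numbered diagnostics; ``strict=True`` aborts on the
    first batch of problems, ``strict=False`` skips them and logs a count.
    Crop geometry travels in crops.csv, so crop-type rows here are malformed.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False, comment="#")
    _require_columns(df, [c for c in RATINGS_COLUMNS if c != "timestamp"], path)
    ratings: list[Rating] = []
    problems: list[str] = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):  # 1-based + header
        try:
            kind = row.answer_type
            if kind == AnswerKind.CROP:
                raise ValueError("crop answers belong in crops.csv")
            if kind not in AnswerKind.ALL:
                raise ValueError(f"unknown answer_type {kind!r}")
            value = parse_price(row.answer) if kind == AnswerKind.NUMERIC else row.answer
            ratings.append(
                Rating(
                    photo_id=row.photo_id,
                    rater_id=row.rater_id,
                    question_id=row.question_id,
                    kind=kind,
                    value=value,
                    task_id=row.task_id or "t0",
                    timestamp=(getattr(row, "timestamp", "") or None),
                )
            )
        except (ValueError, TypeError) as exc:
            problems.append(f"{path}:{idx}: {exc}")
    if problems:
        if strict:
            raise ValueError(
                f"{len(problems)} malformed row(s):\n" + "\n".join(problems[:20])
            )
        logger.warning("skipped %d malformed rating row(s) in %s", len(problems), path)
    return ratings


def write_ratings(ratings: Iterable[Rating], path) -> None:
    rows = []
    for r in ratings:
        if r.kind == AnswerKind.CROP:
            continue  # geometry is written by write_crops
        answer = f"{r.value:.2f}" if r.kind == AnswerKind.NUMERIC else str(r.value)
        rows.append(
            {
                "photo_id": r.photo_id,
                "rater_id": r.rater_id,
                "task_id": r.task_id,
                "question_id": r.question_id,
                "answer_type": r.kind,
                "answer": answer,
                "timestamp": r.timestamp or "",
            }
        )
    pd.DataFrame(rows, columns=RATINGS_COLUMNS).to_csv(path, index=False)


def read_crops(path, strict: bool = True) -> list[tuple[str, str, TaggedCrop]]:
    """Read crops.csv into (photo_id, rater_id, TaggedCrop) triples.

    One output triple per row; callers regroup per rater or tag as needed.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False, comment="#")
    _require_columns(df, CROPS_COLUMNS, path)
    out, problems = [], []
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        try:
            box = CropBox(
                float(row.x0), float(row.y0), float(row.x1), float(row.y1), row.tag
            )
            out.append((row.photo_id, row.rater_id, TaggedCrop(row.tag, (box,))))
        except (ValueError, TypeError) as exc:
            problems.append(f"{path}:{idx}: {exc}")
    if problems:
        if strict:
            raise ValueError(
                f"{len(problems)} malformed row(s):\n" + "\n".join(problems[:20])
            )
        logger.warning("skipped %d malformed crop row(s) in %s", len(problems), path)
    return out


def write_crops(crops: Iterable[tuple[str, str, TaggedCrop]], path, task_id: str = "t0") -> None:
    rows = []
    for photo_id, rater_id, tagged in crops:
        for b in tagged.boxes:
            rows.append(
                {
                    "photo_id": photo_id,
                    "rater_id": rater_id,
                    "task_id": task_id,
                    "tag": tagged.tag,
                    "x0": int(round(b.x0)),
                    "y0": int(round(b.y0)),
                    "x1": int(round(b.x1)),
                    "y1": int(round(b.y1)),
                }
            )
    pd.DataFrame(rows, columns=CROPS_COLUMNS).to_csv(path, index=False)


def read_gold(path) -> GoldStandard:
    """Read gold.csv; price truth rows use the reserved feature ids."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False, comment="#")
    _require_columns(df, GOLD_COLUMNS, path)
    truth: dict[str, dict[str, str]] = {}
    true_price: dict[str, float] = {}
    distractor: dict[str, float] = {}
    for row in df.itertuples(index=False):
        if row.feature_id == PRICE_FEATURE:
            true_price[row.photo_id] = parse_price(row.truth)
        elif row.feature_id == DISTRACTOR_FEATURE:
            distractor[row.photo_id] = parse_price(row.truth)
        else:
            truth.setdefault(row.photo_id, {})[row.feature_id] = row.truth
    prices = {
        pid: (tp, distractor.get(pid, float("nan"))) for pid, tp in true_price.items()
    }
    return GoldStandard(truth=truth, prices=prices)


def write_gold(gold: GoldStandard, path) -> None:
    rows = []
    for pid in sorted(gold.truth):
        for fid, val in sorted(gold.truth[pid].items()):
            rows.append({"photo_id": pid, "feature_id": fid, "truth": val})
        if pid in gold.prices:
            tp, dp = gold.prices[pid]
            rows.append({"photo_id": pid, "feature_id": PRICE_FEATURE, "truth": f"{tp:.2f}"})
            if dp == dp:  # skip NaN distractors
                rows.append(
                    {"photo_id": pid, "feature_id": DISTRACTOR_FEATURE, "truth": f"{dp:.2f}"}
                )
    pd.DataFrame(rows, columns=GOLD_COLUMNS).to_csv(path, index=False)


def write_manifest(study: Study, path) -> None:
    payload = {"format": "crowdannot-study/1", "config": study.config.to_dict()}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def votes_from_ratings(
    ratings: Sequence[Rating], question_id: str
) -> tuple[np.ndarray, list[str], list[str]]:
    """Pivot binary ratings into a complete rater x photo 0/1 matrix.

    Returns (votes, rater_ids, photo_ids); raises if the design is incomplete
    (some rater skipped some photo) since the resampling procedure assumes a
    complete design.
    """
    rows = [
        (r.rater_id, r.photo_id, 1 if r.value == PRESENT else 0)
        for r in ratings
        if r.question_id == question_id and r.kind == AnswerKind.BINARY
    ]
    if not rows:
        raise ValueError(f"no binary ratings for question {question_id!r}")
    df = pd.DataFrame(rows, columns=["rater_id", "photo_id", "vote"])
    pivot = df.pivot_table(index="rater_id", columns="photo_id", values="vote")
    if pivot.isna().any().any():
        raise ValueError("incomplete design: every rater must rate every photo")
    pivot = pivot.sort_index(axis=0).sort_index(axis=1)
    return pivot.to_numpy(dtype=np.int8), list(pivot.index), list(pivot.columns)


# ---------------------------------------------------------------------------
# workflow configuration


def load_workflow(path) -> tuple[Workflow, PaymentSchedule]:
    """Parse workflow.yaml into a validated tier graph and payment schedule."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "tiers" not in doc:
        raise ValueError(f"{path}: workflow file must define 'tiers'")
    tiers: dict[str, TaskTier] = {}
    for spec in doc["tiers"]:
        consensus = spec.get("consensus", {}) or {}
        routes = tuple(
            RoutingRule(when=r["when"], goto=str(r["goto"]))
            for r in spec.get("routes", [])
        )
        tier = TaskTier(
            tier_id=str(spec["tier_id"]),
            question_id=str(spec["question_id"]),
            required_raters=int(spec.get("required_raters", 5)),
            rule=consensus.get("rule", "plurality"),
            threshold=consensus.get("threshold"),
            routes=routes,
        )
        tiers[tier.tier_id] = tier
    entry = doc.get("entry") or next(iter(tiers))
    pay = doc.get("payment", {}) or {}
    schedule = PaymentSchedule(
        base_rate=float(pay.get("base_rate", 0.05)),
        multiplier=float(pay.get("multiplier", 2.0)),
    )
    return Workflow(tiers=tiers, entry=entry), schedule


# ---------------------------------------------------------------------------
# reporting


def report(
    consensus: Sequence[ConsensusResult] = (),
    proportions: Sequence[tuple[str, int, int]] = (),
    contingency: ContingencyTable | None = None,
    curve=None,
    payments: dict[str, float] | None = None,
    prices=None,
) -> tuple[str, dict]:
    """Assemble results from any pipeline stage into a report.

    Returns ``(text, data)``: a human-readable summary and a JSON-stable dict
    (sorted keys, plain types) that serialises byte-identically for identical
    inputs.  All sections are optional; an empty call yields a valid empty
    report.
    """
    data: dict = {"format": "crowdannot-report/1"}
    lines: list[str] = ["crowdannot report", "=" * 17]

    if consensus:
        rows = []
        for c in sorted(consensus, key=lambda c: (c.photo_id, c.question_id)):
            rows.append(
                {
                    "photo_id": c.photo_id,
                    "question_id": c.question_id,
                    "decision": "NO_CONSENSUS" if c.decision is NO_CONSENSUS else c.decision,
                    "vote_fraction": round(c.vote_fraction, 6),
                    "n_raters": c.n_raters,
                }
            )
        data["consensus"] = rows
        reached = sum(1 for r in rows if r["decision"] != "NO_CONSENSUS")
        lines.append(f"consensus: {reached}/{len(rows)} photo-questions decided")

    if proportions:
        sect = []
        for name, k, n in proportions:
            p, (lo, hi) = proportion_with_ci(k, n)
            sect.append(
                {
                    "name": name,
                    "successes": k,
                    "n": n,
                    "proportion": round(p, 6),
                    "wilson_95": [round(lo, 6), round(hi, 6)],
                }
            )
            lines.append(
                f"{name}: {k}/{n} = {100 * p:.1f}% (95% CI {100 * lo:.1f}-{100 * hi:.1f}%)"
            )
        data["proportions"] = sect

    if contingency is not None:
        stat, df_, p = chi_square_homogeneity(contingency)
        data["chi_square"] = {
            "counts": [list(r) for r in contingency.counts],
            "statistic": round(stat, 6),
            "df": df_,
            "p": float(f"{p:.6g}"),
        }
        lines.append(f"chi-square({df_}) = {stat:.2f}, p = {p:.3g}")

    if curve is not None:
        tbl = curve.table if hasattr(curve, "table") else curve
        def _plain(v):
            if isinstance(v, float):
                return round(v, 6)
            if isinstance(v, (int, np.integer)):
                return int(v)
            return str(v)

        data["crowd_size_curve"] = [
            {k: _plain(v) for k, v in row.items()} for row in tbl.to_dict(orient="records")
        ]
        lines.append(f"crowd-size curve over k = {int(tbl['k'].min())}..{int(tbl['k'].max())}")

    if payments:
        data["payments"] = {k: round(v, 2) for k, v in sorted(payments.items())}
        lines.append(
            f"payments: {len(payments)} raters, total ${sum(payments.values()):.2f}"
        )

    if prices is not None:
        sd = prices.sd if isinstance(prices.sd, float) else "UNDEFINED"
        data["prices"] = {
            "mean": round(prices.mean, 2),
            "sd": round(sd, 2) if isinstance(sd, float) else sd,
            "n": prices.n,
            "min": round(prices.min, 2),
        }
        lines.append(
            f"prices: mean ${prices.mean:.2f} "
            + (f"(SD {sd:.2f}) " if isinstance(sd, float) else "(SD undefined) ")
            + f"over {prices.n} readings"
        )

    if len(data) == 1:
        lines.append("(no results)")
    return "\n".join(lines) + "\n", data


def dump_report(data: dict, path) -> None:
    Path(path).write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")
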