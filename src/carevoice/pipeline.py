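"""End-to-end run orchestration.

One call wires the whole analysis together: synthetic (or user-supplied) data
-> eligibility filtering and deduplication -> text classification and
sentiment scoring of microblog items -> windowed collective judgement scores
paired with inspection ratings -> separate hospital- and trust-level ordinal
model fits -> bottom-n prioritisation evaluation and figures.  Every stage's
exclusion counts land in a structured run log, and a fixed seed makes the run
directory contents reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import io as cvio
from .cjs import CJSConfig, pair_with_inspections
from .model import ConvergenceError, fit_cumulative_logit
from .prioritise import box_plot_by_rating, evaluate_prioritisation, rank_and_select
from .simulate import (
    GeneratorConfig,
    generate_feedback,
    generate_inspections,
    generate_labelled_corpus,
    generate_organisations,
)
from .text import classify, score_sentiment, train_text_model
from .types import FeedbackItem, Source

logger = logging.getLogger("carevoice")


@dataclass
class PipelineConfig:
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    cjs: CJSConfig = field(default_factory=CJSConfig)
    corpus_n: int = 3000
    corpus_separation: float = 0.9
    n_select_hospitals: int = 80
    n_select_trusts: int = 50
    proportional: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        # one seed drives everything, including the generator
        self.generator = dataclasses.replace(self.generator, seed=self.seed)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        gen = data.pop("generator", None)
        cjs = data.pop("cjs", None)
        cfg = cls(**data)
        if gen is not None:
            cfg.generator = dataclasses.replace(
                GeneratorConfig.from_dict(gen), seed=cfg.seed
            )
        if cjs is not None:
            cfg.cjs = CJSConfig(**cjs)
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def score_microblog_items(items, relevance_model, sentiment_model) -> tuple[list[FeedbackItem], dict]:
    """Classify microblog texts, drop non-care-quality posts, score the rest.

    Non-microblog items pass through untouched.  Returns the scored stream
    and the stage counts.
    """
    micro = [it for it in items if it.source is Source.microblog]
    other = [it for it in items if it.source is not Source.microblog]
    counts = {"microblog_in": len(micro), "other_in": len(other)}
    if micro:
        labels = classify(relevance_model, [it.text or "" for it in micro])
        relevant = [it for it, lab in zip(micro, labels) if lab != "not_care_quality"]
        counts["microblog_not_care_quality"] = len(micro) - len(relevant)
        if relevant:
            stars = score_sentiment(sentiment_model, [it.text or "" for it in relevant])
            relevant = [
                dataclasses.replace(it, stars=int(s)) for it, s in zip(relevant, stars)
            ]
        counts["microblog_scored"] = len(relevant)
    else:
        relevant = []
        counts["microblog_not_care_quality"] = 0
        counts["microblog_scored"] = 0
    scored = other + relevant
    scored.sort(key=lambda it: it.item_id)
    return scored, counts


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run the full analysis into a directory; returns the run log dict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {"seed": config.seed, "stages": {}}

    # 1. synthetic data
    registry, quality = generate_organisations(config.generator)
    items = generate_feedback(registry, quality, config.generator,
                              text_separation=config.corpus_separation)
    inspections = generate_inspections(registry, quality, config.generator)
    cvio.write_organisations(out / "organisations.csv", registry)
    cvio.write_inspections(out / "inspections.csv", inspections)
    log["stages"]["simulate"] = {
        "n_trusts": len(registry.trusts()),
        "n_hospitals": len(registry.hospitals()),
        "n_feedback_items": len(items),
        "n_inspections": len(inspections),
    }

    # 2. eligibility and deduplication
    eligible = cvio.filter_eligible(items)
    deduped = cvio.deduplicate(eligible)
    log["stages"]["filter"] = {
        "in": len(items),
        "removed_repost_or_org": len(items) - len(eligible),
        "removed_duplicates": len(eligible) - len(deduped),
        "out": len(deduped),
    }

    # 3. text models on a labelled corpus, then score the microblog stream
    corpus = generate_labelled_corpus(
        config.corpus_n, separation=config.corpus_separation, seed=config.seed + 17
    )
    relevance_model, rel_report = train_text_model(corpus, "relevance", seed=config.seed + 19)
    sentiment_model, sent_report = train_text_model(corpus, "sentiment", seed=config.seed + 23)
    with open(out / "cv_report.json", "w") as fh:
        json.dump({"relevance": _slim(rel_report), "sentiment": _slim(sent_report)}, fh, indent=2)
    scored, text_counts = score_microblog_items(deduped, relevance_model, sentiment_model)
    log["stages"]["text"] = {
        **text_counts,
        "relevance_holdout_macro_f1": rel_report["holdout_macro_f1"],
        "sentiment_holdout_exact": sent_report["holdout_exact_accuracy"],
        "sentiment_holdout_within_one": sent_report["holdout_within_one_accuracy"],
    }
    cvio.write_feedback(out / "feedback_scored.jsonl", scored)

    # 4. pair CJS at inspection start with ratings, per organisation kind
    paired = pair_with_inspections(scored, inspections, registry, config.cjs)
    paired.rows.to_csv(out / "paired.csv", index=False)
    log["stages"]["pair"] = {
        "rows": len(paired.rows),
        "dropped_unrated": paired.n_unrated_dropped,
        "dropped_low_volume": paired.n_low_volume_dropped,
    }

    results = {"log": log, "paired": paired.rows, "fits": {}, "prioritisation": {}}
    for kind, n_select in (("hospital", config.n_select_hospitals), ("trust", config.n_select_trusts)):
        rows = paired.rows[paired.rows["kind"] == kind].reset_index(drop=True)
        rows.to_csv(out / f"paired_{kind}.csv", index=False)
        fit_log: dict = {"n": len(rows)}
        # 5. ordinal model (hospitals and trusts are never pooled in one fit)
        try:
            res = fit_cumulative_logit(rows, proportional=config.proportional)
            results["fits"][kind] = res
            with open(out / f"fit_{kind}.json", "w") as fh:
                json.dump(res.to_dict(), fh, indent=2)
            (out / f"fit_{kind}.txt").write_text(res.summary() + "\n")
            fit_log["converged"] = res.converged
            fit_log["betas"] = res.betas.tolist()
        except ConvergenceError as exc:
            fit_log["error"] = str(exc)
            logger.warning("%s-level fit failed: %s", kind, exc)
        # 6. prioritisation
        n_sel = min(n_select, len(rows))
        if n_sel > 0:
            selection = rank_and_select(rows, n_sel)
            prio = evaluate_prioritisation(selection, rows)
            results["prioritisation"][kind] = prio
            with open(out / f"prioritisation_{kind}.json", "w") as fh:
                json.dump(prio.to_dict(), fh, indent=2)
            fit_log["precision"] = prio.precision
            fit_log["chance_baseline"] = prio.chance_baseline
        log["stages"][f"analysis_{kind}"] = fit_log
        # 7. figure
        if not rows.empty:
            fig, summary = box_plot_by_rating(rows, path=out / f"box_plot_{kind}.png")
            import matplotlib.pyplot as plt

            plt.close(fig)
            summary.to_csv(out / f"cjs_by_rating_{kind}.csv")

    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2)
    return results


def _slim(report: dict) -> dict:
    """cv_report without the index partitions (kept in memory for audits)."""
    return {k: v for k, v in report.items() if not k.endswith("_indices")}
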