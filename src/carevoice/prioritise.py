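"""Risk-based inspection prioritisation and its evaluation.

Given the paired dataset (one row per rated inspection with the organisation's
collective judgement score on the inspection start date), rank organisations
by score, select the n lowest for inspection, and evaluate the selection
against the ratings actually awarded: a 2x4 contingency table, the precision
(share of selected organisations rated Inadequate or Requires improvement) and
the chance baseline (the marginal Inadequate/Requires-improvement rate, i.e.
the expected precision of selecting at random).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import RATING_LEVELS, ValidationError

logger = logging.getLogger("carevoice")

AT_RISK = ("Inadequate", "Requires improvement")


def rank_and_select(rows: pd.DataFrame, n: int) -> list[str]:
    """org_ids of the n rows with the lowest score.

    Ties at the boundary are broken by more feedback items first (a better
    supported low score is more actionable), then lexicographic org_id; ties
    at the cutoff are logged.
    """
    if n > len(rows):
        raise ValidationError(f"cannot select {n} of {len(rows)} rows")
    if rows["kind"].nunique() > 1:
        raise ValidationError("rows mix organisation kinds; rank hospitals and trusts separately")
    ordered = rows.sort_values(
        ["cjs", "n_items", "org_id"], ascending=[True, False, True], kind="mergesort"
    )
    if 0 < n < len(ordered):
        cutoff = ordered["cjs"].iloc[n - 1]
        n_tied = int((rows["cjs"] == cutoff).sum())
        if n_tied > 1:
            logger.info(
                "rank_and_select: %d organisations tied at the cutoff score %.4f; "
                "tie broken by item volume then org_id", n_tied, cutoff,
            )
    return ordered["org_id"].head(n).tolist()


@dataclass
class PrioritisationResult:
    kind: str
    n_selected: int
    n_total: int
    table: pd.DataFrame  # index {selected, not_selected}, columns RATING_LEVELS
    precision: float
    chance_baseline: float
    burden: dict  # Good/Outstanding counts among the selected

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "n_selected": self.n_selected,
            "n_total": self.n_total,
            "table": {str(k): [int(v) for v in row] for k, row in self.table.iterrows()},
            "precision": self.precision,
            "chance_baseline": self.chance_baseline,
            "burden": self.burden,
        }


def evaluate_prioritisation(selected, rows: pd.DataFrame) -> PrioritisationResult:
    """Contingency table, precision and chance baseline for a selection."""
    selected = set(selected)
    if not selected:
        raise ValidationError("empty selection")
    known = set(rows["org_id"])
    if not selected <= known:
        raise ValidationError(f"selection contains unknown org_ids: {sorted(selected - known)[:5]}")
    is_sel = rows["org_id"].isin(selected)
    table = pd.DataFrame(
        0, index=["selected", "not_selected"], columns=list(RATING_LEVELS), dtype=int
    )
    for sel_label, mask in (("selected", is_sel), ("not_selected", ~is_sel)):
        counts = rows.loc[mask, "rating"].value_counts()
        for rating in RATING_LEVELS:
            table.loc[sel_label, rating] = int(counts.get(rating, 0))
    n_selected = int(table.loc["selected"].sum())
    n_total = int(table.to_numpy().sum())
    precision = float(table.loc["selected", list(AT_RISK)].sum() / n_selected)
    chance = float(table[list(AT_RISK)].to_numpy().sum() / n_total)
    burden = {
        "Good": int(table.loc["selected", "Good"]),
        "Outstanding": int(table.loc["selected", "Outstanding"]),
    }
    kinds = rows["kind"].unique()
    return PrioritisationResult(
        kind=str(kinds[0]) if len(kinds) == 1 else "mixed",
        n_selected=n_selected,
        n_total=n_total,
        table=table,
        precision=precision,
        chance_baseline=chance,
        burden=burden,
    )


def above_average_share(rows: pd.DataFrame, categories) -> tuple[int, int, float]:
    """Among rows rated in ``categories``, how many have an above-average score?

    The average is the overall mean score across *all* rows.  Returns
    (count above, count in categories, share).
    """
    if rows.empty:
        raise ValidationError("empty paired dataset")
    overall_mean = float(rows["cjs"].mean())
    sub = rows[rows["rating"].isin(list(categories))]
    n_cat = int(len(sub))
    if n_cat == 0:
        raise ValidationError(f"no rows rated in {categories}")
    n_above = int((sub["cjs"] > overall_mean).sum())
    return n_above, n_cat, n_above / n_cat


def box_plot_by_rating(rows: pd.DataFrame, path=None):
    """Box plot of scores grouped by inspection rating, plus a summary table.

    Returns (figure, summary DataFrame with n, min, q1, median, q3, max, mean
    per rating present in the data).
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    present = [r for r in RATING_LEVELS if (rows["rating"] == r).any()]
    if not present:
        raise ValidationError("no rated rows to plot")
    groups = [rows.loc[rows["rating"] == r, "cjs"].to_numpy() for r in present]
    summary = pd.DataFrame(
        {
            "rating": present,
            "n": [len(g) for g in groups],
            "min": [float(np.min(g)) for g in groups],
            "q1": [float(np.percentile(g, 25)) for g in groups],
            "median": [float(np.median(g)) for g in groups],
            "q3": [float(np.percentile(g, 75)) for g in groups],
            "max": [float(np.max(g)) for g in groups],
            "mean": [float(np.mean(g)) for g in groups],
        }
    ).set_index("rating")
    fig, ax = plt.subplots(figsize=(7, 4.5))
    ax.boxplot(groups, tick_labels=present, showmeans=True)
    ax.set_ylabel("Collective judgement score at inspection start")
    ax.set_xlabel("Inspection rating")
    ax.set_ylim(1, 5)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig, summary
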