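"""Histology and IHC quantitative scores, and drift-score concordance.

Pathologist-scored readouts per tumor: Ki67 percent-positive cells,
percent necrosis, CD31 vessel counts per 10x field, and a membranous
TfR1 score (stain intensity 0-3 times percent positive cells, range
0-300, used as a ferroptosis readout).  Histologic drift of PDX passages
from the clinical tumor is rated 0-4 by independent raters; concordance
counts a model-passage as concordant when all rater scores pairwise
agree within a tolerance (default +/- 1 score).
"""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np
import pandas as pd

from .growth import two_sample_t

__all__ = [
    "tfr1_score",
    "vessel_density",
    "compare_ihc",
    "drift_concordance",
]


def tfr1_score(intensity: int, percent_positive: float) -> float:
    """Membranous TfR1 score: average stain intensity x percent positive.

    Intensity is an integer 0-3 (0 none, 1 weak/blush, 2 moderate,
    3 very strong); the product ranges 0-300.
    """
    if intensity not in (0, 1, 2, 3):
        raise ValueError("intensity must be an integer in 0-3")
    if not 0.0 <= percent_positive <= 100.0:
        raise ValueError("percent_positive must lie in [0, 100]")
    return float(intensity * percent_positive)


def vessel_density(counts_per_field):
    """Mean and SD of CD31-positive vessel counts over 10x fields.

    Returns ``(mean, sd, single_field)``; with a single field the SD is
    reported as 0.0 and flagged via ``single_field=True``.
    """
    counts = np.asarray(counts_per_field, dtype=float)
    if counts.size == 0:
        raise ValueError("need >= 1 field")
    if (counts < 0).any():
        raise ValueError("vessel counts must be >= 0")
    single = counts.size == 1
    sd = 0.0 if single else float(np.std(counts, ddof=1))
    return float(counts.mean()), sd, single


def compare_ihc(vehicle_values, treated_values):
    """Two-sided pooled-variance t-test on one stain's per-tumor scalar.

    Returns ``(t, p)``; raises ``ValueError`` when either group has
    fewer than 2 tumors (not evaluable).
    """
    return two_sample_t(vehicle_values, treated_values, equal_var=True)


def drift_concordance(
    table: pd.DataFrame, tolerance: int = 1
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Inter-rater concordance of 0-4 histologic drift scores.

    ``table`` has columns ``model, passage_class, rater, score``.  A
    model-passage is concordant when all rater scores pairwise differ by
    <= ``tolerance``; rows with a single rater are excluded with a
    warning.  Returns ``(per_class, trajectory)``:

    * ``per_class``: ``passage_class, n_evaluated, n_concordant, pct``;
    * ``trajectory``: per model with both low and high passage, the
      rater-consensus score (rounded mean) at each passage and its
      direction (``increased`` vs ``maintained_or_decreased``), plus the
      cohort fraction in each direction.
    """
    if not table["score"].isin([0, 1, 2, 3, 4]).all():
        raise ValueError("scores must be integers 0-4")
    rows = []
    consensus = {}
    for (model, pclass), g in table.groupby(["model", "passage_class"]):
        scores = g["score"].to_numpy()
        if len(scores) < 2:
            warnings.warn(
                f"model {model!r} {pclass} passage has a single rater; excluded"
            )
            continue
        concordant = all(
            abs(int(a) - int(b)) <= tolerance for a, b in combinations(scores, 2)
        )
        rows.append((model, pclass, concordant))
        consensus[(model, pclass)] = int(round(float(np.mean(scores))))
    if not rows:
        raise ValueError("no model-passage with >= 2 raters")
    evaluated = pd.DataFrame(rows, columns=["model", "passage_class", "concordant"])
    per_class = (
        evaluated.groupby("passage_class")["concordant"]
        .agg(n_evaluated="size", n_concordant="sum")
        .reset_index()
    )
    per_class["pct"] = 100.0 * per_class["n_concordant"] / per_class["n_evaluated"]

    traj_rows = []
    for model in evaluated["model"].unique():
        lo = consensus.get((model, "low"))
        hi = consensus.get((model, "high"))
        if lo is None or hi is None:
            continue
        direction = "increased" if hi > lo else "maintained_or_decreased"
        traj_rows.append((model, lo, hi, direction))
    trajectory = pd.DataFrame(
        traj_rows, columns=["model", "consensus_low", "consensus_high", "direction"]
    )
    if not trajectory.empty:
        n = len(trajectory)
        frac = (trajectory["direction"] == "maintained_or_decreased").sum() / n
        trajectory.attrs["pct_maintained_or_decreased"] = 100.0 * frac
        trajectory.attrs["pct_increased"] = 100.0 * (1.0 - frac)
    return per_class, trajectory
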