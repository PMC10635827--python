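"""Drug- and CRISPR-screen score aggregation for steatosis models.

Drug screens are summarized as a drug x dose matrix of lipid scores
(WT reference = 0, vehicle-treated steatotic reference = 1; toxic wells
carry no score), ranked by the best (minimum) non-toxic score per drug.
Agreement between steatosis models is the squared Pearson correlation of
paired per-drug scores.  CRISPR loss-of-function phenotypes use a
three-way steatosis call relative to the untreated steatotic baseline:
-1 (lighter / reduced steatosis), 0 (similar) or +1 (darker / aggravated).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .imaging import lipid_score

__all__ = [
    "ScoreMatrix",
    "CrisprCall",
    "build_score_matrix",
    "rank_drugs",
    "model_correlation",
    "crispr_steatosis_call",
]


@dataclass(frozen=True)
class ScoreMatrix:
    """Lipid scores per drug (rows) and dose index (columns).

    ``scores`` holds NaN where ``toxic`` is True; scores are unclipped.
    """

    scores: pd.DataFrame
    toxic: pd.DataFrame
    model: str = ""
    n_replicates: int | None = None


@dataclass(frozen=True)
class CrisprCall:
    gene: str
    call: int  # -1 lighter, 0 similar, +1 darker
    score: float
    mean_target_coverage: float
    mean_control_coverage: float


def build_score_matrix(
    coverage: pd.DataFrame,
    wt_mean: float,
    steatotic_mean: float,
    model: str = "",
    stat: str = "mean",
) -> ScoreMatrix:
    """Aggregate replicate coverages into a drug x dose lipid-score matrix.

    ``coverage`` needs columns ``drug, dose_index, replicate, coverage,
    toxic``.  Replicates of each cell are averaged (or median with
    ``stat="median"``) before scoring; cells flagged toxic get NaN.
    """
    required = {"drug", "dose_index", "replicate", "coverage", "toxic"}
    missing = required - set(coverage.columns)
    if missing:
        raise ValueError(f"coverage table missing columns: {sorted(missing)}")
    if stat not in ("mean", "median"):
        raise ValueError("stat must be 'mean' or 'median'")
    agg = coverage.groupby(["drug", "dose_index"]).agg(
        coverage=("coverage", stat),
        toxic=("toxic", "any"),
        n=("replicate", "nunique"),
    )
    mean_cov = agg["coverage"].unstack("dose_index")
    toxic = agg["toxic"].astype(bool).unstack("dose_index", fill_value=False)
    scores = mean_cov.map(
        lambda c: np.nan if pd.isna(c) else lipid_score(c, wt_mean, steatotic_mean).score
    )
    scores = scores.mask(toxic)
    return ScoreMatrix(
        scores=scores,
        toxic=toxic,
        model=model,
        n_replicates=int(agg["n"].max()),
    )


def rank_drugs(matrix: ScoreMatrix, effective_threshold: float = 0.5) -> pd.DataFrame:
    """Order drugs by their best (minimum) non-toxic score.

    Ties break stably by drug name.  A drug whose every dose is toxic is
    excluded with a warning.  ``effective`` flags drugs whose best score
    is at or below ``effective_threshold``.
    """
    best = matrix.scores.min(axis=1, skipna=True)
    dead = best.index[best.isna()]
    if len(dead):
        warnings.warn(f"drugs excluded (all doses toxic): {list(dead)}", stacklevel=2)
        best = best.drop(dead)
    out = (
        best.rename("best_score")
        .reset_index()
        .sort_values(["best_score", "drug"], kind="stable")
        .reset_index(drop=True)
    )
    out["effective"] = out["best_score"] <= effective_threshold
    return out


def model_correlation(scores_a: Sequence[float], scores_b: Sequence[float]) -> float:
    """Squared Pearson correlation (R^2) between paired per-drug scores.

    Pairs with a missing value in either vector are dropped listwise;
    at least three complete pairs and non-zero variance are required.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("score vectors must have equal length")
    keep = ~(np.isnan(a) | np.isnan(b))
    a, b = a[keep], b[keep]
    if a.size < 3:
        raise ValueError("need at least three complete score pairs")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("zero variance in one of the score vectors")
    r = stats.pearsonr(a, b).statistic
    return float(r * r)


def crispr_steatosis_call(
    target_coverages: Sequence[float],
    control_coverages: Sequence[float],
    wt_mean: float,
    gene: str = "",
    delta: float = 0.25,
) -> CrisprCall:
    """Three-way steatosis call for one CRISPR-targeted gene.

    The effect score is the mean coverage change of targeted organoids
    relative to the control excess over the WT baseline,

        s = (mean_target - mean_control) / (mean_control - wt_mean),

    so s = -1 means full reversion to WT lipid levels and s = +1 a
    doubling of the steatosis excess.  Calls: -1 if s <= -delta, +1 if
    s >= +delta, else 0.
    """
    t = np.asarray(target_coverages, dtype=float)
    c = np.asarray(control_coverages, dtype=float)
    if t.size < 3 or c.size < 3:
        raise ValueError("need at least three measurements per group")
    mean_t, mean_c = float(t.mean()), float(c.mean())
    if mean_c == wt_mean:
        raise ValueError("degenerate references: control mean equals WT mean")
    s = (mean_t - mean_c) / (mean_c - wt_mean)
    call = -1 if s <= -delta else (1 if s >= delta else 0)
    return CrisprCall(
        gene=gene,
        call=call,
        score=float(s),
        mean_target_coverage=mean_t,
        mean_control_coverage=mean_c,
    )
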