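"""Variable screening and descriptive/group-comparison statistics.

The screening funnel mirrors standard DEA practice for trimming a candidate
variable list: (i) hierarchical clustering of candidates on correlation
distance to expose redundancy, (ii) dropping one member of every
highly-correlated pair, (iii) keeping only inputs whose regression on the
selected outputs explains enough variance (R-squared above a benchmark,
default 0.5).  Alongside it live the descriptive table, the pooled-variance
Student's t comparison of two groups, and the score-band distribution used
for reporting efficiency histograms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "ScreeningReport",
    "screen_variables",
    "compare_groups",
    "band_distribution",
    "descriptive_table",
]

DEFAULT_R_THRESHOLD = 0.9
DEFAULT_R2_THRESHOLD = 0.5
DEFAULT_BAND_EDGES = (0.0, 0.7, 0.8, 0.9, 1.0)


@dataclass
class ScreeningReport:
    candidates: list[str]
    cluster_assignments: dict[str, int]
    dropped: list[dict]                 # {"variable", "rule", "detail"}
    input_r2: dict[str, float]
    final_inputs: list[str]
    final_outputs: list[str]
    r_threshold: float
    r2_threshold: float
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "candidates": self.candidates,
            "cluster_assignments": self.cluster_assignments,
            "dropped": self.dropped,
            "input_r2": self.input_r2,
            "final_inputs": self.final_inputs,
            "final_outputs": self.final_outputs,
            "r_threshold": self.r_threshold,
            "r2_threshold": self.r2_threshold,
            "warnings": self.warnings,
        }


def _r2(y: np.ndarray, X: np.ndarray) -> float:
    """Coefficient of determination of an OLS fit with intercept."""
    Xd = np.column_stack([np.ones(len(y)), X])
    coef, *_ = np.linalg.lstsq(Xd, y, rcond=None)
    resid = y - Xd @ coef
    tss = float(((y - y.mean()) ** 2).sum())
    if tss == 0:
        return 0.0
    return 1.0 - float((resid**2).sum()) / tss


def screen_variables(
    candidate_table: pd.DataFrame,
    input_candidates: list[str],
    output_candidates: list[str],
    r_threshold: float = DEFAULT_R_THRESHOLD,
    r2_threshold: float = DEFAULT_R2_THRESHOLD,
) -> ScreeningReport:
    """Run the cluster / correlation / regression screening funnel.

    Within each role (inputs, outputs), candidate pairs with ``|r| >
    r_threshold`` lose the member whose own variation is less explained by
    the output set; surviving inputs must then achieve ``R^2 >
    r2_threshold`` when regressed on the surviving outputs.
    """
    candidates = list(input_candidates) + list(output_candidates)
    if len(candidates) < 2:
        raise ValueError("need at least two candidate variables")
    if len(candidate_table) < 3:
        raise ValueError("need at least three observations")
    missing = [c for c in candidates if c not in candidate_table.columns]
    if missing:
        raise ValueError(f"candidates absent from table: {missing}")
    warns: list[str] = []
    dropped: list[dict] = []

    # constant columns cannot be screened meaningfully
    live = []
    for c in candidates:
        if candidate_table[c].std(ddof=0) == 0:
            msg = f"constant column {c!r} dropped"
            warnings.warn(msg)
            warns.append(msg)
            dropped.append({"variable": c, "rule": "constant", "detail": "zero variance"})
        else:
            live.append(c)
    if len(candidate_table) < len(live):
        msg = "fewer observations than candidates: regression screens are rank deficient"
        warnings.warn(msg)
        warns.append(msg)

    data = candidate_table[live].to_numpy(float)
    corr = np.corrcoef(data, rowvar=False)
    corr = np.atleast_2d(corr)

    # (i) hierarchical clustering on 1 - |r| distance, average linkage
    dist = 1.0 - np.abs(corr)
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    if len(live) > 1:
        link = hierarchy.linkage(squareform(dist, checks=False), method="average")
        labels = hierarchy.fcluster(link, t=1.0 - r_threshold, criterion="distance")
    else:
        labels = np.ones(len(live), dtype=int)
    assignments = {c: int(l) for c, l in zip(live, labels)}

    out_live = [c for c in live if c in output_candidates]

    def explained(var: str, exclude: set[str]) -> float:
        """R^2 of a candidate against the (surviving) output set."""
        others = [o for o in out_live if o != var and o not in exclude]
        if not others:
            return 0.0
        return _r2(
            candidate_table[var].to_numpy(float),
            candidate_table[others].to_numpy(float),
        )

    # (ii) correlation rule within each role, strongest pairs first
    def prune(role_vars: list[str]) -> list[str]:
        removed: set[str] = set()
        pairs = []
        for i, a in enumerate(role_vars):
            for b in role_vars[i + 1 :]:
                r = corr[live.index(a), live.index(b)]
                if np.abs(r) > r_threshold:
                    lo, hi = sorted((a, b))  # name order, not column order
                    pairs.append((abs(r), r, lo, hi))
        for _, r, a, b in sorted(pairs, key=lambda t: (-t[0], t[2], t[3])):
            if a in removed or b in removed:
                continue
            loser = a if explained(a, removed) <= explained(b, removed) else b
            removed.add(loser)
            dropped.append(
                {
                    "variable": loser,
                    "rule": "correlation",
                    "detail": f"|r|={abs(r):.4f} with {a if loser == b else b}",
                }
            )
        return [v for v in role_vars if v not in removed]

    inputs_after = prune([c for c in live if c in input_candidates])
    outputs_after = prune(out_live)

    # (iii) regression screen of the inputs against the selected outputs
    input_r2: dict[str, float] = {}
    final_inputs = []
    Ysel = candidate_table[outputs_after].to_numpy(float) if outputs_after else None
    for c in inputs_after:
        r2 = _r2(candidate_table[c].to_numpy(float), Ysel) if Ysel is not None else 0.0
        input_r2[c] = r2
        if r2 > r2_threshold:
            final_inputs.append(c)
        else:
            dropped.append(
                {"variable": c, "rule": "regression", "detail": f"R2={r2:.4f}"}
            )

    return ScreeningReport(
        candidates=candidates,
        cluster_assignments=assignments,
        dropped=dropped,
        input_r2=input_r2,
        final_inputs=final_inputs,
        final_outputs=outputs_after,
        r_threshold=r_threshold,
        r2_threshold=r2_threshold,
        warnings=warns,
    )


def compare_groups(scores_a: np.ndarray, scores_b: np.ndarray) -> dict:
    """Two-sided pooled-variance Student's t-test between two score groups.

    Returns a record shaped like a comparison-table row: per-group n, mean
    and SD, the t statistic and the two-sided p-value.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two observations")
    pooled_var = (
        ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1))
        / (a.size + b.size - 2)
    )
    if pooled_var == 0:
        if a.mean() == b.mean():
            t, p = 0.0, 1.0
        else:
            raise ValueError("zero pooled variance with unequal group means")
    else:
        t, p = stats.ttest_ind(a, b, equal_var=True)
        t, p = float(t), float(p)
    return {
        "n_a": int(a.size),
        "n_b": int(b.size),
        "mean_a": float(a.mean()),
        "mean_b": float(b.mean()),
        "sd_a": float(a.std(ddof=1)),
        "sd_b": float(b.std(ddof=1)),
        "t": t,
        "p": p,
    }


def band_distribution(
    scores: np.ndarray, band_edges=DEFAULT_BAND_EDGES
) -> pd.DataFrame:
    """Counts and percentages of scores per half-open band, plus an exact-1 band.

    Bands are ``[lo, hi)`` over ``(0, 1)``; scores exactly equal to 1 (on the
    frontier) are reported in their own band.  Percentages sum to 100.
    """
    scores = np.asarray(scores, dtype=float)
    edges = np.asarray(band_edges, dtype=float)
    if np.any(scores <= 0) or np.any(scores > 1):
        raise ValueError("scores must lie in (0, 1]")
    if np.any(np.diff(edges) <= 0):
        raise ValueError("band edges must be strictly increasing")
    if edges[0] > 0 or edges[-1] < 1:
        raise ValueError("band edges must cover (0, 1]")
    interior = scores[scores < 1.0]
    counts = np.histogram(interior, bins=edges)[0]
    labels = [f"[{lo:g}, {hi:g})" for lo, hi in zip(edges[:-1], edges[1:])]
    labels.append("= 1")
    counts = np.append(counts, int(np.sum(scores == 1.0)))
    pct = 100.0 * counts / scores.size
    return pd.DataFrame({"band": labels, "count": counts, "percent": pct})


def descriptive_table(df: pd.DataFrame, group_col: str, variables: list[str]) -> pd.DataFrame:
    """Per-group mean and SD of each variable (descriptives-table shape)."""
    rows = []
    for g, sub in df.groupby(group_col, sort=False):
        for v in variables:
            rows.append(
                {
                    "variable": v,
                    "group": g,
                    "mean": float(sub[v].mean()),
                    "sd": float(sub[v].std(ddof=1)),
                }
            )
    return pd.DataFrame(rows)
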