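"""Cell-type marker enrichment by random gene-set resampling, and marker-set
age-trend statistics.

The enrichment null draws module-sized uniform gene sets from the study's
gene universe and counts marker hits; fold enrichment is observed over the
null MEDIAN, and the empirical p-value carries the add-one correction
(#{null >= observed} + 1) / (B + 1), so it is bounded below by 1/(B+1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import pearson_with_p
from .study import ExpressionStudy

__all__ = [
    "EnrichmentResult",
    "fold_enrichment",
    "marker_enrichment",
    "TrendReport",
    "marker_age_trend",
    "regression_slope",
]


@dataclass
class EnrichmentResult:
    observed: int
    null_counts: np.ndarray
    null_median: float
    null_mean: float
    fold: float
    p_empirical: float
    B: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "observed": self.observed,
            "null_median": self.null_median,
            "null_mean": self.null_mean,
            "fold": self.fold,
            "p_empirical": self.p_empirical,
            "B": self.B,
            "seed": self.seed,
        }


def fold_enrichment(observed: float, null_median: float) -> float:
    """Fold enrichment against the null median; inf when the median is 0
    and something was observed, 1 when both are 0."""
    if null_median == 0:
        return float("inf") if observed > 0 else 1.0
    return observed / null_median


def marker_enrichment(
    module: set[str],
    panel: set[str],
    universe: set[str],
    B: int = 1000,
    seed: int = 0,
) -> EnrichmentResult:
    """Marker-panel enrichment of a module against random same-size gene sets.

    observed = |module ∩ panel| (panel clipped to the universe); null = B
    uniform draws of |module| genes from the universe.
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    if not module <= universe:
        raise ValueError("module must be a subset of the universe")
    if len(module) > len(universe):
        raise ValueError("module larger than universe")
    panel_in = panel & universe
    observed = len(module & panel_in)
    rng = np.random.default_rng(seed)
    uni = np.array(sorted(universe))
    is_marker = np.isin(uni, np.array(sorted(panel_in))) if panel_in else np.zeros(
        len(uni), dtype=bool
    )
    k = len(module)
    null = np.empty(B, dtype=int)
    for b in range(B):
        pick = rng.choice(len(uni), size=k, replace=False)
        null[b] = int(is_marker[pick].sum())
    med = float(np.median(null))
    p = float(((null >= observed).sum() + 1) / (B + 1))
    return EnrichmentResult(
        observed=observed,
        null_counts=null,
        null_median=med,
        null_mean=float(null.mean()),
        fold=fold_enrichment(observed, med),
        p_empirical=p,
        B=B,
        seed=seed,
    )


@dataclass
class TrendReport:
    """Per-gene age correlations for a marker panel and the panel summary."""

    per_gene: pd.DataFrame  # gene_id, r, p
    mean_r: float
    p_mean_r: float  # one-sample two-sided t-test of per-gene r against 0
    n_genes: int
    n_samples: int
    min_age: float | None

    def to_dict(self) -> dict:
        return {
            "mean_r": self.mean_r,
            "p_mean_r": self.p_mean_r,
            "n_genes": self.n_genes,
            "n_samples": self.n_samples,
            "min_age": self.min_age,
        }


def marker_age_trend(
    study: ExpressionStudy, panel: set[str], min_age: float | None = None
) -> TrendReport:
    """Mean age correlation of a marker panel's expressed genes.

    Each expressed panel gene gets a Pearson r (and two-sided p) versus age;
    the panel summary is the mean r with a one-sample t-test of the per-gene
    correlations against zero.  `min_age` optionally restricts to older
    subjects (re-testing whether a trend persists late in life).
    """
    expressed = [g for g in panel if g in set(study.genes)]
    if not expressed:
        raise ValueError("no panel genes expressed in the study")
    age = study.age
    keep = np.ones(len(age), dtype=bool)
    if min_age is not None:
        keep = age >= min_age
        if keep.sum() < 10:
            raise ValueError("fewer than 10 samples above min_age")
    idx = study.gene_index(expressed)
    rows = []
    for g, i in zip(expressed, idx):
        x = study.values[i][keep]
        if np.std(x) == 0:
            continue
        r, p = pearson_with_p(x, age[keep])
        rows.append({"gene_id": g, "r": r, "p": p})
    per_gene = pd.DataFrame(rows).sort_values("gene_id").reset_index(drop=True)
    rs = per_gene["r"].to_numpy()
    if len(rs) > 1:
        t = stats.ttest_1samp(rs, 0.0)
        p_mean = float(t.pvalue)
    else:
        p_mean = float("nan")
    return TrendReport(
        per_gene=per_gene,
        mean_r=float(rs.mean()),
        p_mean_r=p_mean,
        n_genes=len(rs),
        n_samples=int(keep.sum()),
        min_age=min_age,
    )


def regression_slope(y, x) -> tuple[float, float, float, float]:
    """Ordinary least squares of y on x: (slope, intercept, r, two-sided p)."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors with >= 3 points")
    if np.std(x) == 0:
        raise ValueError("constant predictor")
    res = stats.linregress(x, y)
    return (
        float(res.slope),
        float(res.intercept),
        float(res.rvalue),
        float(res.pvalue),
    )
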