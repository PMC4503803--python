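"""Weighted gene co-expression network analysis.

Pipeline: Pearson correlation matrix -> soft-threshold adjacency |r|^beta
(power chosen by the scale-free topology fit index) -> topological overlap
matrix (TOM) -> average-linkage tree on 1-TOM -> static branch cut ->
minimum-size filter -> iterative eigengene merging at a dissimilarity height
cut (default 0.25, i.e. eigengene correlation 0.75) -> module selection by
the age rule: a module is age-dependent when its eigengene correlates with
age at a more significant p-value than with every measured confounder.

The branch cut is a static height cut on the average-linkage tree (default
height: the 0.99 quantile of merge heights), an approximation of the Dynamic
Tree Cut procedure; the minimum-size filter and eigengene merging follow it.
Networks are unsigned (adjacency |r|^beta) by default.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from ._utils import pearson_with_p, standardize
from .study import ExpressionStudy

log = logging.getLogger(__name__)

__all__ = [
    "correlation_matrix",
    "pick_soft_power",
    "adjacency_to_tom",
    "module_eigengene",
    "detect_modules",
    "select_age_modules",
    "matched_correlation",
    "ModuleAssignment",
    "AgeModuleReport",
]


def correlation_matrix(study: ExpressionStudy) -> np.ndarray:
    """All-pairs Pearson correlation of genes across samples.

    Symmetric with unit diagonal.  Raises on zero-variance genes (callers
    should have filtered with `ExpressionStudy.drop_zero_variance`).
    """
    if study.n_samples < 3:
        raise ValueError("need at least 3 samples for a correlation network")
    sd = study.values.std(axis=1)
    if np.any(sd == 0):
        bad = [g for g, s in zip(study.genes, sd) if s == 0]
        raise ValueError(f"zero-variance genes: {bad[:5]}")
    r = np.corrcoef(study.values)
    np.fill_diagonal(r, 1.0)
    return np.clip(r, -1.0, 1.0)


def scale_free_fit(connectivity: np.ndarray, n_bins: int = 10) -> float:
    """Scale-free topology fit index: R^2 of log10 frequency vs log10 mean
    connectivity over equal-width connectivity bins; 0 when the log-log
    slope is positive (a positive slope is not scale-free).

    Equal-width binning follows common WGCNA practice; equal-count bins are
    fooled by a bimodal connectivity profile (a tight background bulk plus
    a structured tail reads as a steep power law), selecting powers far too
    soft to suppress background correlation noise.
    """
    k = np.asarray(connectivity, dtype=float)
    k = k[k > 0]
    if len(k) < n_bins or np.ptp(k) == 0:
        raise ValueError("degenerate connectivity: cannot assess scale-free fit")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        m = idx == b
        if not m.any():
            continue
        xs.append(np.log10(k[m].mean()))
        ys.append(np.log10(m.mean()))
    if len(xs) < 3:
        raise ValueError("degenerate connectivity: too few usable bins")
    slope, _, r, _, _ = stats.linregress(xs, ys)
    if slope >= 0:
        return 0.0
    return float(r * r)


def pick_soft_power(
    sim: np.ndarray,
    powers=tuple(range(1, 21)),
    fit_target: float = 0.85,
    n_bins: int = 10,
) -> tuple[int, pd.DataFrame]:
    """Smallest power whose adjacency reaches the scale-free fit target.

    Returns (power, fit table).  Falls back to the argmax-fit power with a
    logged warning when no power reaches the target.
    """
    powers = list(powers)
    if not powers or sorted(powers) != powers:
        raise ValueError("powers must be a nonempty ascending list")
    absr = np.abs(np.asarray(sim, dtype=float))
    np.fill_diagonal(absr, 0.0)
    rows = []
    for beta in powers:
        a = absr**beta
        k = a.sum(axis=1)
        fit = scale_free_fit(k, n_bins=n_bins)
        rows.append({"power": beta, "fit": fit, "mean_k": float(k.mean())})
    table = pd.DataFrame(rows)
    ok = table[table["fit"] >= fit_target]
    if len(ok):
        return int(ok.iloc[0]["power"]), table
    best = int(table.loc[table["fit"].idxmax(), "power"])
    log.warning(
        "no power reached scale-free fit %.2f; using argmax fit power %d",
        fit_target,
        best,
    )
    return best, table


def adjacency_to_tom(adjacency: np.ndarray) -> np.ndarray:
    """Unsigned topological overlap matrix.

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij), where
    l_ij = sum_u a_iu a_uj and k_i = sum_u a_iu; diagonal set to 1.
    """
    a = np.asarray(adjacency, dtype=float).copy()
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(a, a.T, atol=1e-12):
        raise ValueError("adjacency must be symmetric")
    np.fill_diagonal(a, 0.0)
    if np.any((a < 0) | (a > 1)):
        raise ValueError("adjacency entries must lie in [0, 1]")
    k = a.sum(axis=1)
    l = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (l + a) / denom
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


def module_eigengene(
    study: ExpressionStudy, member_genes, values: np.ndarray | None = None
) -> np.ndarray:
    """Module eigengene: first principal component (over samples) of the
    gene-standardized member submatrix, unit norm, sign-oriented so the mean
    correlation with member genes is non-negative."""
    member_genes = list(member_genes)
    if not member_genes:
        raise ValueError("empty module membership")
    if values is None:
        idx = study.gene_index(member_genes)
        values = study.values[idx]
    x = standardize(values, axis=1)
    # right singular vector of the genes x samples matrix = PC over samples
    _, _, vt = np.linalg.svd(x, full_matrices=False)
    e = vt[0]
    e = e / np.linalg.norm(e)
    mean_corr = np.mean([np.corrcoef(row, e)[0, 1] for row in x])
    if mean_corr < 0:
        e = -e
    return e


@dataclass
class ModuleAssignment:
    """Gene -> module labels (0 = unassigned) with per-module eigengenes."""

    genes: list[str]
    labels: dict[str, int]
    eigengenes: dict[int, np.ndarray]
    params: dict = field(default_factory=dict)

    def module_ids(self) -> list[int]:
        return sorted(m for m in set(self.labels.values()) if m != 0)

    def members(self, module_id: int) -> list[str]:
        return [g for g in self.genes if self.labels[g] == module_id]

    def sizes(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for m in self.labels.values():
            out[m] = out.get(m, 0) + 1
        return out

    def membership_table(self, study: ExpressionStudy) -> pd.DataFrame:
        """gene_id, module_id and module membership (gene-eigengene r)."""
        rows = []
        for g in self.genes:
            mid = self.labels[g]
            mm = np.nan
            if mid != 0:
                i = study.gene_index([g])[0]
                mm = float(np.corrcoef(study.values[i], self.eigengenes[mid])[0, 1])
            rows.append({"gene_id": g, "module_id": mid, "module_membership": mm})
        return pd.DataFrame(rows)


def _relabel_by_size(genes, raw_labels) -> dict[str, int]:
    """Stable module ids: 1 = largest; ties broken by smallest member id
    (invariant to gene-order permutation)."""
    clusters: dict[int, list[str]] = {}
    for g, lab in zip(genes, raw_labels):
        clusters.setdefault(lab, []).append(g)
    keyed = sorted(
        clusters.items(), key=lambda kv: (-len(kv[1]), min(kv[1]))
    )
    out: dict[str, int] = {}
    for new_id, (_, members) in enumerate(keyed, start=1):
        for g in members:
            out[g] = new_id
    return out


def detect_modules(
    tom: np.ndarray,
    study: ExpressionStudy,
    min_size: int = 10,
    merge_height: float = 0.25,
    cut_height: float | None = None,
    cut_fraction: float = 0.995,
) -> ModuleAssignment:
    """Cut the average-linkage tree on 1-TOM into modules and merge modules
    with correlated eigengenes.

    Branches are formed by a static height cut.  The default cut is
    `cut_fraction` of the tree's maximum merge height: in a TOM tree the
    unclustered background joins in a narrow band just below the top, so a
    cut anchored to the tree height separates branches from background
    robustly (a cut at a quantile of the merge heights does not, because
    most merges ARE background merges).  Clusters below `min_size` go to
    module 0;
    modules whose eigengene dissimilarity (1 - eigengene correlation) falls
    below `merge_height` are merged iteratively, recomputing eigengenes
    after every merge, until no pair qualifies.
    """
    genes = list(study.genes)
    n = len(genes)
    if tom.shape != (n, n):
        raise ValueError("TOM shape does not match study gene count")
    if min_size < 2:
        raise ValueError("min_size must be >= 2")
    if n < min_size:
        warnings.warn("fewer genes than min_size: single unassigned module")
        return ModuleAssignment(
            genes=genes,
            labels={g: 0 for g in genes},
            eigengenes={},
            params={"min_size": min_size, "merge_height": merge_height},
        )
    diss = 1.0 - np.asarray(tom, dtype=float)
    np.fill_diagonal(diss, 0.0)
    z = linkage(squareform(diss, checks=False), method="average")
    if cut_height is None:
        cut_height = float(cut_fraction * z[:, 2].max())
    raw = fcluster(z, t=cut_height, criterion="distance")

    labels = _relabel_by_size(genes, raw)
    sizes: dict[int, int] = {}
    for lab in labels.values():
        sizes[lab] = sizes.get(lab, 0) + 1
    labels = {g: (lab if sizes[lab] >= min_size else 0) for g, lab in labels.items()}
    # re-densify ids after dropping small clusters
    kept = sorted({lab for lab in labels.values() if lab != 0})
    remap = {old: new for new, old in enumerate(kept, start=1)}
    labels = {g: (remap[lab] if lab else 0) for g, lab in labels.items()}

    def compute_eigengenes(lbls) -> dict[int, np.ndarray]:
        out = {}
        for mid in sorted({v for v in lbls.values() if v != 0}):
            members = [g for g in genes if lbls[g] == mid]
            out[mid] = module_eigengene(study, members)
        return out

    eigengenes = compute_eigengenes(labels)

    # iterative eigengene merging
    while len(eigengenes) > 1:
        ids = sorted(eigengenes)
        em = np.array([eigengenes[m] for m in ids])
        corr = np.corrcoef(em)
        np.fill_diagonal(corr, -np.inf)
        i, j = np.unravel_index(np.argmax(corr), corr.shape)
        if 1.0 - corr[i, j] >= merge_height:
            break
        a, b = ids[i], ids[j]
        keep, drop = min(a, b), max(a, b)
        labels = {g: (keep if lab == drop else lab) for g, lab in labels.items()}
        kept = sorted({lab for lab in labels.values() if lab != 0})
        remap = {old: new for new, old in enumerate(kept, start=1)}
        labels = {g: (remap[lab] if lab else 0) for g, lab in labels.items()}
        eigengenes = compute_eigengenes(labels)

    # final stable ordering by size
    assigned = [g for g in genes if labels[g] != 0]
    if assigned:
        by_size = _relabel_by_size(
            assigned, [labels[g] for g in assigned]
        )
        labels = {g: by_size.get(g, 0) for g in genes}
        eigengenes = compute_eigengenes(labels)
    return ModuleAssignment(
        genes=genes,
        labels=labels,
        eigengenes=eigengenes,
        params={
            "min_size": min_size,
            "merge_height": merge_height,
            "cut_height": cut_height,
        },
    )


def matched_correlation(
    eigengene: np.ndarray,
    age: np.ndarray,
    confounder: np.ndarray,
    min_group: int = 5,
) -> list[tuple[float, int, float]]:
    """Eigengene-age Pearson correlation within strata of samples sharing
    the same recorded confounder value (>= min_group samples per stratum).

    Returns a list of (level, n_samples, r).  Empty (with a warning) when no
    stratum is large enough.
    """
    eigengene = np.asarray(eigengene, float)
    age = np.asarray(age, float)
    confounder = np.asarray(confounder, float)
    if not len(eigengene) == len(age) == len(confounder):
        raise ValueError("vectors must be aligned")
    out = []
    for level in np.unique(confounder):
        m = confounder == level
        if m.sum() < min_group:
            continue
        if np.std(age[m]) == 0 or np.std(eigengene[m]) == 0:
            continue
        r = float(np.corrcoef(eigengene[m], age[m])[0, 1])
        out.append((float(level), int(m.sum()), r))
    if not out:
        warnings.warn("no confounder stratum reaches min_group samples")
    return out


@dataclass
class AgeModuleReport:
    """Per-module age/confounder correlations, the selection flag, and the
    matched-sample validation of selected modules."""

    table: pd.DataFrame
    matched_validation: dict[int, dict[str, list[tuple[float, int, float]]]]
    alpha: float

    def selected_modules(self) -> list[int]:
        return [int(m) for m in self.table[self.table["selected"]]["module_id"]]

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "modules": self.table.to_dict(orient="records"),
            "matched_validation": {
                str(mid): {
                    conf: [
                        {"level": lv, "n": n, "r": r} for lv, n, r in strata
                    ]
                    for conf, strata in by_conf.items()
                }
                for mid, by_conf in self.matched_validation.items()
            },
        }


def select_age_modules(
    modules: ModuleAssignment,
    study: ExpressionStudy,
    alpha: float = 0.05,
    min_group: int = 5,
    method: str = "pearson",
) -> AgeModuleReport:
    """Apply the age-dependence selection rule to every module.

    A module is selected when its eigengene-age p-value is below `alpha`
    AND below the eigengene p-value for every available confounder.
    Selected modules get a matched-sample validation: eigengene-age
    correlation within strata of constant confounder value.
    """
    age = study.age
    confs = study.confounder_names()
    usable_confs = []
    for c in confs:
        if np.std(study.traits[c].to_numpy(float)) == 0:
            warnings.warn(f"constant confounder {c!r} skipped")
            continue
        usable_confs.append(c)

    def corr(x, y):
        if method == "pearson":
            return pearson_with_p(x, y)
        if method == "spearman":
            r, p = stats.spearmanr(x, y)
            return float(r), float(p)
        raise ValueError("method must be 'pearson' or 'spearman'")

    rows = []
    matched: dict[int, dict[str, list]] = {}
    for mid in modules.module_ids():
        e = modules.eigengenes[mid]
        r_age, p_age = corr(e, age)
        row = {
            "module_id": mid,
            "n_genes": modules.sizes()[mid],
            "r_age": r_age,
            "p_age": p_age,
        }
        beats_all = True
        for c in usable_confs:
            r_c, p_c = corr(e, study.traits[c].to_numpy(float))
            row[f"r_{c}"] = r_c
            row[f"p_{c}"] = p_c
            if not p_age < p_c:
                beats_all = False
        row["selected"] = bool(p_age < alpha and beats_all)
        rows.append(row)
        if row["selected"]:
            matched[mid] = {
                c: matched_correlation(
                    e, age, study.traits[c].to_numpy(float), min_group=min_group
                )
                for c in usable_confs
            }
    table = pd.DataFrame(rows)
    if len(table):
        table = table.sort_values("p_age").reset_index(drop=True)
    return AgeModuleReport(table=table, matched_validation=matched, alpha=alpha)
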