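"""Mutual-information network reverse engineering with DPI pruning.

The network is built in three steps: (1) pairwise mutual information between
all genes, (2) an MI threshold obtained by inverting a right-tail
exponential fit to a permutation null at a user p-value (stringent p-values
such as 1e-7 cannot be reached by permutation counting and are reached by
tail extrapolation instead), and (3) data-processing-inequality pruning: in
every triangle the weakest edge is removed when it falls below the smaller
of the other two by a multiplicative tolerance, except that an edge incident
to a transcription factor is never eliminated in favor of an edge joining
two non-TFs.  A bootstrap-consensus variant aggregates edge support over
sample resamples.

Two MI estimators are provided.  The reference estimator ('kde') applies a
normal-scores (copula) transform and a product Gaussian kernel with the
Silverman two-dimensional bandwidth h = sigma * n^(-1/6), evaluated
leave-one-out at the sample points (plug-in average of the log density
ratio).  The 'binned' estimator (equal-frequency bins) is a fast surrogate
used for all-pairs network construction; both are exposed everywhere.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.stats import rankdata

from .study import ExpressionStudy

log = logging.getLogger(__name__)

__all__ = [
    "mutual_information",
    "mi_threshold",
    "MINetwork",
    "apply_dpi",
    "build_mi_network",
    "bootstrap_consensus",
    "extract_regulons",
]


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------


def _normal_scores(x: np.ndarray) -> np.ndarray:
    n = len(x)
    return stats.norm.ppf((rankdata(x) - 0.5) / n)


def _kde_mi(x: np.ndarray, y: np.ndarray, chunk: int = 1024) -> float:
    """Leave-one-out Gaussian-kernel plug-in MI on normal scores (nats)."""
    n = len(x)
    zx, zy = _normal_scores(x), _normal_scores(y)
    h = zx.std(ddof=1) * n ** (-1.0 / 6.0)
    fj = np.empty(n)
    fx = np.empty(n)
    fy = np.empty(n)
    for i0 in range(0, n, chunk):
        sl = slice(i0, min(i0 + chunk, n))
        dx = (zx[sl, None] - zx[None, :]) / h
        dy = (zy[sl, None] - zy[None, :]) / h
        kx = np.exp(-0.5 * dx * dx)
        ky = np.exp(-0.5 * dy * dy)
        m = kx.shape[0]
        rows = np.arange(m)
        cols = np.arange(i0, i0 + m)
        kj = kx * ky
        kj[rows, cols] = 0.0
        fj[sl] = kj.sum(1) / ((n - 1) * 2 * np.pi * h * h)
        fx[sl] = (kx.sum(1) - 1.0) / ((n - 1) * np.sqrt(2 * np.pi) * h)
        fy[sl] = (ky.sum(1) - 1.0) / ((n - 1) * np.sqrt(2 * np.pi) * h)
    mi = float(np.mean(np.log(fj) - np.log(fx) - np.log(fy)))
    return max(mi, 0.0)


def default_bins(n_samples: int) -> int:
    """Equal-frequency bin count for the binned estimator: ~sqrt(n/5),
    at least 2 (keeps expected cell counts ~5)."""
    return max(2, int(np.floor(np.sqrt(n_samples / 5.0))))


def _discretize(x: np.ndarray, bins: int) -> np.ndarray:
    """Equal-frequency bin labels in [0, bins)."""
    n = len(x)
    order = rankdata(x, method="ordinal") - 1  # 0..n-1, ties broken by order
    return (order * bins // n).astype(np.int64)


def _binned_mi_from_labels(lx: np.ndarray, ly: np.ndarray, bins: int) -> float:
    n = len(lx)
    counts = np.bincount(lx * bins + ly, minlength=bins * bins).reshape(bins, bins)
    p = counts / n
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = p * (np.log(p) - np.log(px) - np.log(py))
    return float(np.where(counts > 0, term, 0.0).sum())


def mutual_information(
    x: np.ndarray, y: np.ndarray, method: str = "kde", bins: int | None = None
) -> float:
    """MI between two sample vectors, in nats (>= 0, symmetric).

    method='kde' is the Gaussian-kernel reference estimator; 'binned' is
    the fast equal-frequency surrogate.  Constant input yields MI = 0 with
    a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("vectors must have equal length")
    if len(x) < 20:
        raise ValueError("need at least 20 samples for MI estimation")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in input")
    if np.std(x) == 0 or np.std(y) == 0:
        warnings.warn("constant vector: MI set to 0")
        return 0.0
    if method == "kde":
        return _kde_mi(x, y)
    if method == "binned":
        b = bins or default_bins(len(x))
        return _binned_mi_from_labels(_discretize(x, b), _discretize(y, b), b)
    raise ValueError("method must be 'kde' or 'binned'")


def _all_pairs_binned_mi(values: np.ndarray, bins: int, chunk: int = 128) -> np.ndarray:
    """All-pairs binned MI matrix (G x G, zero diagonal), vectorized via
    one-hot joint-count matmuls."""
    g, n = values.shape
    labels = np.empty((g, n), dtype=np.int64)
    for i in range(g):
        labels[i] = _discretize(values[i], bins)
    onehot = np.zeros((g, bins, n), dtype=np.float32)
    rows = np.arange(n)
    for i in range(g):
        onehot[i, labels[i], rows] = 1.0
    flat = onehot.reshape(g * bins, n)
    mi = np.zeros((g, g), dtype=float)
    logn = np.log(n)
    for i0 in range(0, g, chunk):
        i1 = min(i0 + chunk, g)
        c = flat[i0 * bins : i1 * bins] @ flat.T  # (ci*bins, g*bins)
        c = c.reshape(i1 - i0, bins, g, bins).transpose(0, 2, 1, 3)
        ri = c.sum(axis=3, keepdims=True)  # (ci, g, bins, 1)
        rj = c.sum(axis=2, keepdims=True)  # (ci, g, 1, bins)
        with np.errstate(divide="ignore", invalid="ignore"):
            term = c * (np.log(c) + logn - np.log(ri) - np.log(rj))
        term = np.where(c > 0, term, 0.0)
        mi[i0:i1] = term.sum(axis=(2, 3)) / n
    np.fill_diagonal(mi, 0.0)
    return np.maximum(mi, 0.0)


# ---------------------------------------------------------------------------
# threshold
# ---------------------------------------------------------------------------


def mi_threshold(
    study: ExpressionStudy,
    p_value: float = 1e-7,
    n_null: int = 10_000,
    seed: int = 0,
    method: str = "binned",
    bins: int | None = None,
) -> float:
    """MI threshold corresponding to a null p-value.

    Builds a null MI distribution from `n_null` random gene pairs with one
    member permuted, fits an exponential to the right tail (exceedances over
    the 90th percentile) and inverts the fitted survival function at
    `p_value`.  For p >= 0.1 the empirical quantile is returned directly.
    """
    if not 0 < p_value < 1:
        raise ValueError("p_value must be in (0, 1)")
    if n_null < 1000:
        raise ValueError("n_null < 1000: tail fit would be unstable")
    rng = np.random.default_rng(seed)
    g, n = study.values.shape
    null = np.empty(n_null)
    if method == "binned":
        b = bins or default_bins(n)
        labels = {}
        for k in range(n_null):
            i, j = rng.integers(0, g, size=2)
            if i not in labels:
                labels[i] = _discretize(study.values[i], b)
            if j not in labels:
                labels[j] = _discretize(study.values[j], b)
            null[k] = _binned_mi_from_labels(
                labels[i], rng.permutation(labels[j]), b
            )
    elif method == "kde":
        for k in range(n_null):
            i, j = rng.integers(0, g, size=2)
            null[k] = _kde_mi(study.values[i], rng.permutation(study.values[j]))
    else:
        raise ValueError("method must be 'kde' or 'binned'")
    if p_value >= 0.1:
        return float(max(np.quantile(null, 1.0 - p_value), 1e-12))
    u = float(np.quantile(null, 0.9))
    exceed = null[null > u] - u
    lam = float(exceed.mean()) if len(exceed) else 1e-12
    thr = u + lam * np.log(0.1 / p_value)
    return float(max(thr, 1e-12))


# ---------------------------------------------------------------------------
# network container + DPI
# ---------------------------------------------------------------------------


@dataclass
class MINetwork:
    """Undirected weighted MI network with TF flags.

    Edges are keyed by sorted gene-id pairs; `support` optionally carries
    bootstrap support fractions.
    """

    nodes: list[str]
    is_tf: dict[str, bool]
    edges: dict[tuple[str, str], float]
    params: dict = field(default_factory=dict)
    support: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (a, b) in self.edges:
            if a == b:
                raise ValueError(f"self-edge on {a}")
            if a > b:
                raise ValueError("edge keys must be sorted pairs")

    def n_edges(self) -> int:
        return len(self.edges)

    def neighbors(self) -> dict[str, set[str]]:
        nb: dict[str, set[str]] = {v: set() for v in self.nodes}
        for a, b in self.edges:
            nb[a].add(b)
            nb[b].add(a)
        return nb

    def tf_nodes(self) -> list[str]:
        return [v for v in self.nodes if self.is_tf.get(v, False)]


def _edge_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a < b else (b, a)


def apply_dpi(network: MINetwork, epsilon: float = 0.1) -> MINetwork:
    """Data-processing-inequality pruning with TF protection.

    For every triangle (i, j, k) the edge (i, j) is marked for removal when
    MI_ij < min(MI_ik, MI_jk) * (1 - epsilon).  TF protection: a marked edge
    incident to a TF is exempt when either alternative edge of that triangle
    joins two non-TFs — removing it would eliminate a TF-target interaction
    in favor of an edge between two non-TFs.  (Equivalently, for a TF-target
    edge, only a triangle whose third node is itself a TF can remove it.)
    All removals are applied simultaneously after scanning every triangle,
    so the result is independent of edge order.
    """
    if not 0 <= epsilon <= 1:
        raise ValueError("epsilon must be in [0, 1]")
    nb = network.neighbors()
    mi = network.edges
    is_tf = network.is_tf
    to_remove: set[tuple[str, str]] = set()
    for (u, v), w_uv in mi.items():
        common = nb[u] & nb[v]
        for k in common:
            w_uk = mi[_edge_key(u, k)]
            w_vk = mi[_edge_key(v, k)]
            if not w_uv < min(w_uk, w_vk) * (1.0 - epsilon):
                continue
            if is_tf.get(u, False) or is_tf.get(v, False):
                tf_u, tf_v = is_tf.get(u, False), is_tf.get(v, False)
                tf_k = is_tf.get(k, False)
                alt_uk_nontf = not tf_u and not tf_k
                alt_vk_nontf = not tf_v and not tf_k
                if alt_uk_nontf or alt_vk_nontf:
                    continue
            to_remove.add((u, v))
            break
    kept = {e: w for e, w in mi.items() if e not in to_remove}
    return MINetwork(
        nodes=list(network.nodes),
        is_tf=dict(network.is_tf),
        edges=kept,
        params={**network.params, "dpi_tolerance": epsilon},
        support={e: s for e, s in network.support.items() if e in kept},
    )


# ---------------------------------------------------------------------------
# network construction
# ---------------------------------------------------------------------------


def build_mi_network(
    study: ExpressionStudy,
    tf_list,
    p_value: float = 1e-7,
    epsilon: float = 0.1,
    seed: int = 0,
    method: str = "binned",
    bins: int | None = None,
    n_null: int = 5000,
) -> MINetwork:
    """All-pairs MI -> p-value threshold -> DPI with TF protection."""
    if study.n_samples < 20:
        raise ValueError("need at least 20 samples for MI network inference")
    genes = list(study.genes)
    gene_set = set(genes)
    tfs = [t for t in tf_list if t in gene_set]
    missing = sorted(set(tf_list) - gene_set)
    if missing:
        log.info("%d TFs absent from the study were ignored", len(missing))
    is_tf = {g: (g in set(tfs)) for g in genes}

    b = bins or default_bins(study.n_samples)
    if method == "binned":
        mi_mat = _all_pairs_binned_mi(study.values, b)
    elif method == "kde":
        g = len(genes)
        mi_mat = np.zeros((g, g))
        for i in range(g):
            for j in range(i + 1, g):
                mi_mat[i, j] = mi_mat[j, i] = _kde_mi(
                    study.values[i], study.values[j]
                )
    else:
        raise ValueError("method must be 'kde' or 'binned'")

    thr = mi_threshold(
        study, p_value=p_value, n_null=n_null, seed=seed, method=method, bins=b
    )
    ii, jj = np.nonzero(np.triu(mi_mat >= thr, k=1))
    edges = {
        _edge_key(genes[i], genes[j]): float(mi_mat[i, j]) for i, j in zip(ii, jj)
    }
    net = MINetwork(
        nodes=genes,
        is_tf=is_tf,
        edges=edges,
        params={
            "mi_pvalue": p_value,
            "mi_threshold": thr,
            "estimator": method,
            "bins": b,
            "seed": seed,
        },
    )
    return apply_dpi(net, epsilon)


def bootstrap_consensus(
    study: ExpressionStudy,
    rounds: int = 100,
    p_value: float = 1e-7,
    epsilon: float = 0.1,
    tf_list=(),
    seed: int = 0,
    method: str = "binned",
    bins: int | None = None,
    n_null: int = 2000,
    alpha: float = 0.05,
) -> MINetwork:
    """Consensus network over sample-bootstrap rebuilds.

    Each round rebuilds the full network on a bootstrap resample of the
    samples.  An edge enters the consensus when its support count is
    significantly above the per-round mean edge rate under a binomial null
    (Benjamini-Hochberg corrected at `alpha`); its consensus MI is the mean
    over supporting rounds.
    """
    if rounds < 2:
        raise ValueError("rounds must be >= 2")
    if rounds > 10_000:
        raise ValueError("rounds > 10000 refused (cost guard)")
    rng = np.random.default_rng(seed)
    genes = list(study.genes)
    n = study.n_samples
    support: dict[tuple[str, str], int] = {}
    mi_sum: dict[tuple[str, str], float] = {}
    total_edges = 0
    for r in range(rounds):
        idx = rng.integers(0, n, size=n)
        boot = ExpressionStudy(
            genes=genes,
            samples=[f"b{t}" for t in range(n)],
            values=study.values[:, idx],
            traits=study.traits.iloc[idx].set_axis(
                [f"b{t}" for t in range(n)]
            ),
        )
        net = build_mi_network(
            boot,
            tf_list,
            p_value=p_value,
            epsilon=epsilon,
            seed=int(rng.integers(0, 2**31 - 1)),
            method=method,
            bins=bins,
            n_null=n_null,
        )
        total_edges += net.n_edges()
        for e, w in net.edges.items():
            support[e] = support.get(e, 0) + 1
            mi_sum[e] = mi_sum.get(e, 0.0) + w
    n_pairs = len(genes) * (len(genes) - 1) // 2
    p0 = total_edges / (rounds * n_pairs) if n_pairs else 0.0
    cand = sorted(support)
    pvals = np.array(
        [stats.binom.sf(support[e] - 1, rounds, p0) for e in cand]
    )
    from .regdom import adjust_pvalues

    q = adjust_pvalues(pvals) if len(pvals) else np.empty(0)
    edges = {}
    supp_frac = {}
    for e, qe in zip(cand, q):
        if qe < alpha:
            edges[e] = mi_sum[e] / support[e]
            supp_frac[e] = support[e] / rounds
    gene_set = set(genes)
    is_tf = {g: (g in set(t for t in tf_list if t in gene_set)) for g in genes}
    return MINetwork(
        nodes=genes,
        is_tf=is_tf,
        edges=edges,
        params={
            "mi_pvalue": p_value,
            "dpi_tolerance": epsilon,
            "bootstrap_rounds": rounds,
            "per_round_edge_rate": p0,
            "estimator": method,
            "seed": seed,
        },
        support=supp_frac,
    )


def extract_regulons(network: MINetwork) -> dict[str, set[str]]:
    """Per-TF regulon: the TF's adjacent nodes in the final network.

    TFs with empty regulons are reported via the logger and included with
    empty target sets.
    """
    nb = network.neighbors()
    regs = {tf: set(nb[tf]) for tf in network.tf_nodes()}
    empty = sorted(tf for tf, t in regs.items() if not t)
    if empty:
        log.info("%d TFs have empty regulons: %s", len(empty), empty[:10])
    return regs
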