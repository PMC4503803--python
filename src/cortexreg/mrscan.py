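"""Master-regulator identification and cross-dataset replication.

A transcription factor is a master regulator (MR) for a module when its
regulon over-intersects the module beyond chance: one-sided Fisher's exact
test (hypergeometric upper tail) on the module-membership x regulon-
membership contingency table, Bonferroni-corrected for the number of TFs
tested in that dataset's network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

__all__ = [
    "fisher_overlap",
    "MRResult",
    "identify_master_regulators",
    "combine_across_datasets",
    "ReplicationReport",
]


def fisher_overlap(
    overlap: int, regulon_size: int, module_size: int, universe_size: int
) -> float:
    """P(X >= overlap) for X ~ Hypergeometric(universe, module, regulon):
    the one-sided (greater) Fisher's exact test p-value for the observed
    module/regulon intersection."""
    overlap, regulon_size, module_size, universe_size = (
        int(overlap),
        int(regulon_size),
        int(module_size),
        int(universe_size),
    )
    if min(overlap, regulon_size, module_size, universe_size) < 0:
        raise ValueError("negative count")
    if overlap > min(regulon_size, module_size):
        raise ValueError("overlap exceeds a set size")
    if max(regulon_size, module_size) > universe_size:
        raise ValueError("set size exceeds universe")
    if regulon_size + module_size - overlap > universe_size:
        raise ValueError("inconsistent counts: union exceeds universe")
    return float(
        stats.hypergeom.sf(overlap - 1, universe_size, module_size, regulon_size)
    )


@dataclass
class MRResult:
    tf: str
    overlap: int
    regulon_size: int
    module_size: int
    universe_size: int
    p_raw: float
    p_adj: float
    is_mr: bool

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def identify_master_regulators(
    regulons: dict[str, set[str]],
    module: set[str],
    universe: set[str],
    alpha: float = 0.05,
) -> list[MRResult]:
    """Test every TF's regulon against the module.

    Regulons are intersected with the universe before testing; TFs with
    empty (intersected) regulons are excluded from the Bonferroni count
    (they cannot be tested) and logged.  Results sorted by raw p.
    """
    if not module:
        raise ValueError("empty module")
    if not module <= universe:
        raise ValueError("module is not a subset of the universe")
    mod = module
    clipped = {tf: (targets & universe) for tf, targets in regulons.items()}
    testable = {tf: t for tf, t in clipped.items() if t}
    skipped = sorted(set(clipped) - set(testable))
    if skipped:
        log.info("%d TFs with empty regulons excluded from testing", len(skipped))
    n_tested = len(testable)
    results = []
    for tf, targets in testable.items():
        ov = len(targets & mod)
        p = fisher_overlap(ov, len(targets), len(mod), len(universe))
        p_adj = min(1.0, p * n_tested)
        results.append(
            MRResult(
                tf=tf,
                overlap=ov,
                regulon_size=len(targets),
                module_size=len(mod),
                universe_size=len(universe),
                p_raw=p,
                p_adj=p_adj,
                is_mr=bool(p_adj < alpha),
            )
        )
    results.sort(key=lambda r: (r.p_raw, r.tf))
    return results


def results_table(results: list[MRResult]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in results])


@dataclass
class ReplicationReport:
    """Replication of MR calls across datasets."""

    per_dataset: dict[str, set[str]]
    replication_count: dict[str, int]
    union: set[str]
    intersection: set[str]

    def replicated_in_all(self) -> set[str]:
        return self.intersection

    def to_dict(self) -> dict:
        return {
            "per_dataset": {k: sorted(v) for k, v in self.per_dataset.items()},
            "replication_count": dict(sorted(self.replication_count.items())),
            "union": sorted(self.union),
            "intersection": sorted(self.intersection),
            "counts_per_dataset": {
                k: len(v) for k, v in sorted(self.per_dataset.items())
            },
        }


def combine_across_datasets(
    results: dict[str, list[MRResult]]
) -> ReplicationReport:
    """Summarize MR replication across >= 2 datasets."""
    if len(results) < 2:
        raise ValueError("need at least 2 datasets to assess replication")
    per_dataset = {
        ds: {r.tf for r in rs if r.is_mr} for ds, rs in results.items()
    }
    union: set[str] = set().union(*per_dataset.values())
    inter = (
        set.intersection(*per_dataset.values()) if per_dataset else set()
    )
    counts = {
        tf: sum(tf in mrs for mrs in per_dataset.values()) for tf in union
    }
    return ReplicationReport(
        per_dataset=per_dataset,
        replication_count=counts,
        union=union,
        intersection=inter,
    )
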