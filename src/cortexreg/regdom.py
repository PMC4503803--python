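"""Strand-aware basal regulatory domains and interval-overlap randomization.

Genomic intervals are 0-based half-open throughout (BED native).  The
association test compares the observed nucleotide overlap between a peak set
and a target set against a null in which every peak is re-placed uniformly
at random, length preserved, within the provided workspace (placements never
cross workspace gaps).  This is a workspace-restricted randomization in the
spirit of genomic association testers; composition (G+C/isochore)
conditioning is deliberately not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "IntervalSet",
    "GeneAnnotation",
    "OverlapTestResult",
    "basal_regulatory_domains",
    "interval_overlap_test",
    "adjust_pvalues",
]


@dataclass
class IntervalSet:
    """A set of genomic intervals, sorted within chromosome.

    Intervals may carry names (e.g. per-gene domains) and are allowed to
    overlap; `merged()` returns the normalized, non-overlapping union used
    by all coverage arithmetic.
    """

    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)
    names: dict[str, np.ndarray] = field(default_factory=dict)

    @classmethod
    def from_arrays(cls, chroms, starts, ends, names=None) -> "IntervalSet":
        chroms = np.asarray(chroms, dtype=object)
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        if np.any(starts >= ends):
            bad = int(np.argmax(starts >= ends))
            raise ValueError(
                f"interval start >= end at record {bad}: "
                f"{chroms[bad]}:{starts[bad]}-{ends[bad]}"
            )
        if np.any(starts < 0):
            raise ValueError("negative interval start")
        obj = cls()
        names = None if names is None else np.asarray(names, dtype=object)
        for chrom in sorted(set(chroms.tolist())):
            m = chroms == chrom
            order = np.argsort(starts[m], kind="stable")
            obj.by_chrom[chrom] = (starts[m][order], ends[m][order])
            if names is not None:
                obj.names[chrom] = names[m][order]
        return obj

    def chroms(self) -> list[str]:
        return sorted(self.by_chrom)

    def starts(self, chrom: str) -> np.ndarray:
        return self.by_chrom[chrom][0]

    def ends(self, chrom: str) -> np.ndarray:
        return self.by_chrom[chrom][1]

    def n_intervals(self) -> int:
        return sum(len(s) for s, _ in self.by_chrom.values())

    def total_bp(self) -> int:
        return int(sum((e - s).sum() for s, e in self.by_chrom.values()))

    def merged(self) -> "IntervalSet":
        """Union of intervals: sorted, non-overlapping, unnamed."""
        out = IntervalSet()
        for chrom, (s, e) in self.by_chrom.items():
            if len(s) == 0:
                continue
            ms, me = [int(s[0])], [int(e[0])]
            for a, b in zip(s[1:], e[1:]):
                if a <= me[-1]:
                    me[-1] = max(me[-1], int(b))
                else:
                    ms.append(int(a))
                    me.append(int(b))
            out.by_chrom[chrom] = (
                np.asarray(ms, dtype=np.int64),
                np.asarray(me, dtype=np.int64),
            )
        return out

    def intersect(self, other: "IntervalSet") -> "IntervalSet":
        """Clip this set's intervals to the union of `other` (names kept;
        an interval split by a gap yields multiple fragments)."""
        other_m = other.merged()
        chroms, starts, ends, names = [], [], [], []
        for chrom, (s, e) in self.by_chrom.items():
            if chrom not in other_m.by_chrom:
                continue
            os, oe = other_m.by_chrom[chrom]
            nm = self.names.get(chrom)
            for i in range(len(s)):
                lo = np.searchsorted(oe, s[i], side="right")
                hi = np.searchsorted(os, e[i], side="left")
                for j in range(lo, hi):
                    a, b = max(s[i], os[j]), min(e[i], oe[j])
                    if a < b:
                        chroms.append(chrom)
                        starts.append(a)
                        ends.append(b)
                        names.append(nm[i] if nm is not None else None)
        if not chroms:
            return IntervalSet()
        use_names = any(n is not None for n in names)
        return IntervalSet.from_arrays(
            chroms, starts, ends, names if use_names else None
        )

    def place_uniform(self, lengths, rng: np.random.Generator):
        """Place intervals of the given lengths uniformly within this set's
        merged segments (length preserved, never crossing a gap).

        Returns a list of (chrom, start).  Raises if some length exceeds
        every segment.
        """
        merged = self.merged()
        seg_chrom, seg_start, seg_len = [], [], []
        for chrom, (s, e) in merged.by_chrom.items():
            seg_chrom += [chrom] * len(s)
            seg_start += list(s)
            seg_len += list(e - s)
        seg_start = np.asarray(seg_start, dtype=np.int64)
        seg_len = np.asarray(seg_len, dtype=np.int64)
        out = []
        for L in np.asarray(lengths, dtype=np.int64):
            w = np.maximum(seg_len - L + 1, 0)
            total = int(w.sum())
            if total == 0:
                raise ValueError(f"peak of length {L} exceeds every workspace segment")
            u = int(rng.integers(0, total))
            cum = np.cumsum(w)
            k = int(np.searchsorted(cum, u, side="right"))
            offset = u - (cum[k - 1] if k else 0)
            out.append((seg_chrom[k], int(seg_start[k] + offset)))
        return out

    # ---- BED ----

    def to_bed(self, path) -> None:
        rows = []
        for chrom in self.chroms():
            s, e = self.by_chrom[chrom]
            nm = self.names.get(chrom)
            for i in range(len(s)):
                if nm is not None:
                    rows.append(f"{chrom}\t{s[i]}\t{e[i]}\t{nm[i]}\n")
                else:
                    rows.append(f"{chrom}\t{s[i]}\t{e[i]}\n")
        Path(path).write_text("".join(rows))

    @classmethod
    def from_bed(cls, path) -> "IntervalSet":
        chroms, starts, ends, names = [], [], [], []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                chroms.append(parts[0])
                starts.append(int(parts[1]))
                ends.append(int(parts[2]))
                names.append(parts[3] if len(parts) > 3 else None)
        use_names = any(n is not None for n in names)
        return cls.from_arrays(chroms, starts, ends, names if use_names else None)


@dataclass
class GeneAnnotation:
    """Gene annotation: table with gene_id, chrom, tss, strand columns plus
    known chromosome lengths."""

    table: pd.DataFrame
    chrom_lengths: dict[str, int]

    def subset(self, gene_ids) -> "GeneAnnotation":
        wanted = set(gene_ids)
        return GeneAnnotation(
            table=self.table[self.table["gene_id"].isin(wanted)].reset_index(drop=True),
            chrom_lengths=self.chrom_lengths,
        )

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for chrom, ln in sorted(self.chrom_lengths.items()):
                fh.write(f"#chrom_length\t{chrom}\t{ln}\n")
            self.table.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "GeneAnnotation":
        lengths = {}
        with open(path) as fh:
            pos = 0
            for line in fh:
                if line.startswith("#chrom_length"):
                    _, chrom, ln = line.rstrip("\n").split("\t")
                    lengths[chrom] = int(ln)
                    pos = fh.tell()
                else:
                    break
        table = pd.read_csv(path, sep="\t", comment="#")
        return cls(table=table, chrom_lengths=lengths)


def basal_regulatory_domains(
    annotation: GeneAnnotation, up: int = 5000, down: int = 1000
) -> IntervalSet:
    """Per-gene basal regulatory domain around the TSS.

    + strand: [TSS-up, TSS+down); - strand: [TSS-down, TSS+up);
    clipped to [0, chrom_length).
    """
    t = annotation.table
    chroms, starts, ends, names = [], [], [], []
    for gene_id, chrom, tss, strand in zip(
        t["gene_id"], t["chrom"], t["tss"], t["strand"]
    ):
        if chrom not in annotation.chrom_lengths:
            raise ValueError(f"unknown chromosome {chrom!r} for gene {gene_id}")
        if tss < 0:
            raise ValueError(f"negative TSS for gene {gene_id}")
        if strand not in ("+", "-"):
            raise ValueError(f"bad strand {strand!r} for gene {gene_id}")
        clen = annotation.chrom_lengths[chrom]
        if strand == "+":
            a, b = tss - up, tss + down
        else:
            a, b = tss - down, tss + up
        a, b = max(0, int(a)), min(int(clen), int(b))
        if a < b:
            chroms.append(chrom)
            starts.append(a)
            ends.append(b)
            names.append(gene_id)
    return IntervalSet.from_arrays(chroms, starts, ends, names)


# ---------------------------------------------------------------------------
# overlap randomization test
# ---------------------------------------------------------------------------


@dataclass
class OverlapTestResult:
    observed_bp: float
    expected_bp: float
    fold: float
    p_empirical: float
    n_sim: int
    statistic: str = "bp"
    null_values: np.ndarray | None = None
    saturated: bool = False

    def to_dict(self) -> dict:
        return {
            "observed_bp": self.observed_bp,
            "expected_bp": self.expected_bp,
            "fold": self.fold,
            "p_empirical": self.p_empirical,
            "n_sim": self.n_sim,
            "statistic": self.statistic,
            "saturated": self.saturated,
        }


class _Coverage:
    """Prefix-sum coverage of a merged interval set in flattened coordinates:
    F(x) = covered bp in (-inf, x); overlap of [a,b) = F(b) - F(a)."""

    def __init__(self, starts: np.ndarray, ends: np.ndarray):
        self.starts = starts
        self.ends = ends
        self.cum = np.concatenate([[0], np.cumsum(ends - starts)])

    def f(self, x: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(self.starts, x, side="right") - 1
        idx_c = np.clip(idx, 0, len(self.starts) - 1)
        inside = np.clip(x - self.starts[idx_c], 0, self.ends[idx_c] - self.starts[idx_c])
        return np.where(idx < 0, 0, self.cum[idx_c] + inside)

    def overlap(self, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        return self.f(b) - self.f(a)


def _flat_offsets(sets: list[IntervalSet]) -> dict[str, int]:
    """Assign each chromosome a disjoint window on a single coordinate line."""
    max_end: dict[str, int] = {}
    for s in sets:
        for chrom, (_, e) in s.by_chrom.items():
            if len(e):
                max_end[chrom] = max(max_end.get(chrom, 0), int(e.max()))
    offsets, cursor = {}, 0
    for chrom in sorted(max_end):
        offsets[chrom] = cursor
        cursor += max_end[chrom] + 1
    return offsets


def _flatten(s: IntervalSet, offsets: dict[str, int]):
    starts, ends = [], []
    for chrom, (a, b) in s.by_chrom.items():
        off = offsets[chrom]
        starts.append(a + off)
        ends.append(b + off)
    if not starts:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    starts = np.concatenate(starts)
    ends = np.concatenate(ends)
    order = np.argsort(starts)
    return starts[order], ends[order]


def interval_overlap_test(
    peaks: IntervalSet,
    targets: IntervalSet,
    workspace: IntervalSet,
    n_sim: int = 1000,
    seed: int = 0,
    statistic: str = "bp",
    keep_null: bool = False,
) -> OverlapTestResult:
    """Randomization test of peak/target association within a workspace.

    Peaks and targets are clipped to the workspace; the observed statistic
    (total nucleotide overlap by default, or the count of overlapping peaks
    with ``statistic='count'``) is compared to `n_sim` simulations that
    re-place every peak uniformly within the workspace, lengths preserved.
    Empirical p uses the add-one correction: (#{null >= obs} + 1)/(n_sim + 1).
    """
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100")
    if statistic not in ("bp", "count"):
        raise ValueError("statistic must be 'bp' or 'count'")
    rng = np.random.default_rng(seed)
    ws = workspace.merged()
    peaks_w = peaks.intersect(ws)
    targets_m = targets.intersect(ws).merged()

    offsets = _flat_offsets([ws, peaks_w, targets_m])
    t_s, t_e = _flatten(targets_m, offsets)
    cov = _Coverage(t_s, t_e)

    # flattened workspace segments for placement
    w_s, w_e = _flatten(ws, offsets)
    seg_len = w_e - w_s

    p_s, p_e = _flatten(peaks_w, offsets)
    lengths = p_e - p_s
    k = len(lengths)
    if k == 0:
        raise ValueError("no peaks inside workspace")
    per_peak = cov.overlap(p_s, p_e)
    if statistic == "bp":
        observed = float(per_peak.sum())
    else:
        observed = float((per_peak > 0).sum())

    # vectorized null: for each peak, n_sim placements
    null_stat = np.zeros(n_sim)
    for j in range(k):
        w = np.maximum(seg_len - lengths[j] + 1, 0)
        total = int(w.sum())
        if total == 0:
            raise ValueError(
                f"peak of length {int(lengths[j])} exceeds every workspace segment"
            )
        cum = np.cumsum(w)
        u = rng.integers(0, total, size=n_sim)
        seg = np.searchsorted(cum, u, side="right")
        offset = u - np.where(seg > 0, cum[seg - 1], 0)
        a = w_s[seg] + offset
        ov = cov.overlap(a, a + lengths[j])
        if statistic == "bp":
            null_stat += ov
        else:
            null_stat += ov > 0

    expected = float(null_stat.mean())
    p = float(((null_stat >= observed).sum() + 1) / (n_sim + 1))
    if expected > 0:
        fold = observed / expected
    else:
        fold = float("inf") if observed > 0 else 1.0
    saturated = targets_m.total_bp() >= ws.total_bp()
    return OverlapTestResult(
        observed_bp=observed,
        expected_bp=expected,
        fold=fold,
        p_empirical=p,
        n_sim=n_sim,
        statistic=statistic,
        null_values=null_stat if keep_null else None,
        saturated=saturated,
    )


def adjust_pvalues(p, method: str = "BH") -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values outside [0, 1]")
    if method != "BH":
        raise ValueError("only BH correction is supported")
    return multipletests(p, method="fdr_bh")[1]
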