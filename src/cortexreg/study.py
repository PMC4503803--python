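"""The universal input container: a gene x sample expression matrix with a
per-sample trait table (age in years plus zero or more confounders such as
RIN, pH and PMI).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


@dataclass
class ExpressionStudy:
    """Normalized expression (e.g. log-ratio) for `genes` x `samples`.

    `traits` is indexed by sample id and must contain an ``age`` column;
    every other column is treated as a potential confounder.
    """

    genes: list[str]
    samples: list[str]
    values: np.ndarray  # shape (n_genes, n_samples)
    traits: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene ids")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids")
        if not self.traits.empty:
            self.traits = self.traits.loc[self.samples]

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def age(self) -> np.ndarray:
        if "age" not in self.traits.columns:
            raise KeyError("traits table has no 'age' column")
        return self.traits["age"].to_numpy(dtype=float)

    def confounder_names(self) -> list[str]:
        return [c for c in self.traits.columns if c != "age"]

    def gene_index(self, gene_ids) -> np.ndarray:
        lut = {g: i for i, g in enumerate(self.genes)}
        return np.array([lut[g] for g in gene_ids], dtype=int)

    def drop_zero_variance(self) -> "ExpressionStudy":
        """Return a copy without zero-variance genes (warn if any dropped)."""
        sd = self.values.std(axis=1)
        keep = sd > 0
        n_drop = int((~keep).sum())
        if n_drop:
            dropped = [g for g, k in zip(self.genes, keep) if not k]
            warnings.warn(f"dropping {n_drop} zero-variance genes: {dropped[:5]}...")
            return ExpressionStudy(
                genes=[g for g, k in zip(self.genes, keep) if k],
                samples=list(self.samples),
                values=self.values[keep],
                traits=self.traits,
            )
        return self

    # -- TSV dialect: genes x samples matrix with a header row of sample ids --

    def to_tsv(self, expr_path, traits_path=None) -> None:
        df = pd.DataFrame(self.values, index=self.genes, columns=self.samples)
        df.index.name = "gene_id"
        df.to_csv(expr_path, sep="\t", float_format="%.10g")
        if traits_path is not None:
            t = self.traits.copy()
            t.index.name = "sample_id"
            t.to_csv(traits_path, sep="\t", float_format="%.10g")

    @classmethod
    def from_tsv(cls, expr_path, traits_path=None) -> "ExpressionStudy":
        df = pd.read_csv(expr_path, sep="\t", index_col=0)
        traits = pd.DataFrame(index=df.columns)
        if traits_path is not None:
            traits = pd.read_csv(traits_path, sep="\t", index_col=0)
            traits.index = traits.index.astype(str)
        return cls(
            genes=[str(g) for g in df.index],
            samples=[str(s) for s in df.columns],
            values=df.to_numpy(dtype=float),
            traits=traits,
        )


def collapse_probes(
    probe_matrix: pd.DataFrame, probe_to_gene: dict[str, str]
) -> pd.DataFrame:
    """Average multiple probes mapping to the same gene.

    `probe_matrix` is probe x sample; unmapped probes are dropped (count
    logged).  Returns a gene x sample DataFrame of per-gene probe means.
    """
    if not probe_to_gene:
        raise ValueError("empty probe-to-gene mapping")
    mapped = [p for p in probe_matrix.index if p in probe_to_gene]
    n_unmapped = len(probe_matrix.index) - len(mapped)
    if n_unmapped:
        log.info("collapse_probes: dropping %d unmapped probes", n_unmapped)
    sub = probe_matrix.loc[mapped]
    genes = pd.Series({p: probe_to_gene[p] for p in mapped}, name="gene_id")
    out = sub.groupby(genes).mean()
    out.index.name = "gene_id"
    return out
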