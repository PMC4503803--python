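"""Synthetic cortex-transcriptome studies with planted ground truth.

The generator emulates the statistical structure the downstream analysis
assumes, with known truth for parameter recovery:

* one latent-factor ("eigengene") gene block whose summary expression is a
  declining function of age, hitting a target Pearson correlation exactly by
  construction (the latent factor is a linear blend of standardized age and
  a noise vector orthogonalized against it);
* transcription-factor-driven regulons: *driver* TFs regulate subsets of the
  planted module, other TFs regulate disjoint background blocks;
* tissue-quality confounders (RIN / pH / PMI style) sampled independently of
  age, enforced by rejection resampling;
* cell-type marker panels with a stated overlap with the planted module;
* a synthetic chromosome with per-gene TSS/strand, ChIP-style peaks enriched
  in the basal regulatory domains of the module genes, and a workspace;
* a preferential-attachment protein-interaction graph with a densified
  seed clique.

All outputs are byte-identical under a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from ._utils import standardize
from .regdom import GeneAnnotation, IntervalSet, basal_regulatory_domains
from .study import ExpressionStudy

__all__ = [
    "ConfounderSpec",
    "SynthConfig",
    "GroundTruth",
    "generate_expression",
    "generate_marker_panels",
    "generate_genome_and_peaks",
    "generate_ppi",
    "generate_study",
    "SyntheticStudy",
]


@dataclass(frozen=True)
class ConfounderSpec:
    """Distribution of one age-independent confounder.

    dist: 'normal' (params mean, sd), 'lognormal' (params mu, sigma of log)
    or 'uniform' (params lo, hi).  `round_to` optionally discretizes the
    recorded value (postmortem metadata is recorded coarsely; discreteness
    also gives the matched-sample validation non-trivial strata).
    """

    name: str
    dist: str = "normal"
    params: tuple[float, float] = (0.0, 1.0)
    round_to: float | None = None

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.dist == "normal":
            x = rng.normal(self.params[0], self.params[1], n)
        elif self.dist == "lognormal":
            x = rng.lognormal(self.params[0], self.params[1], n)
        elif self.dist == "uniform":
            x = rng.uniform(self.params[0], self.params[1], n)
        else:
            raise ValueError(f"unknown confounder distribution {self.dist!r}")
        if self.round_to:
            x = np.round(x / self.round_to) * self.round_to
        return x


def default_confounders() -> tuple[ConfounderSpec, ...]:
    return (
        ConfounderSpec("RIN", "normal", (7.5, 0.8), round_to=0.5),
        ConfounderSpec("pH", "normal", (6.5, 0.25), round_to=0.1),
        ConfounderSpec("PMI", "lognormal", (3.4, 0.4), round_to=1.0),
    )


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of one synthetic study.

    Defaults plant a 100-gene module in a 2000-gene, 150-sample study with
    eigengene-age correlation -0.4, 5 driver TFs among 20, regulons of 30
    genes, and three age-independent confounders.
    """

    n_genes: int = 2000
    n_samples: int = 150
    age_range: tuple[float, float] = (13.0, 80.0)
    n_module_genes: int = 100
    module_age_corr: float = -0.4
    n_tfs: int = 20
    n_driver_tfs: int = 5
    regulon_size: int = 10
    within_module_corr: float = 0.41
    tf_target_loading: float = 1.15
    noise_sd: float = 1.0
    confounder_spec: tuple[ConfounderSpec, ...] = field(
        default_factory=default_confounders
    )
    # optional adversarial scenario: one confounder coupled to the planted
    # eigengene (more strongly than age), to exercise selection suppression
    dominant_confounder: str | None = None
    dominant_confounder_corr: float = 0.8
    # genome / peaks
    gene_spacing: int = 20_000
    n_peaks: int = 200
    peak_length_median: float = 300.0
    peak_length_sigma: float = 0.5
    peak_enrichment_fraction: float = 0.8
    basal_up: int = 5000
    basal_down: int = 1000
    # marker panels
    marker_panel_size: int = 162
    marker_overlap: int = 40
    off_panel_sizes: tuple[int, ...] = (29,)
    # PPI
    n_ppi_nodes: int = 1000
    ppi_clique_size: int = 10
    ppi_attach_m: int = 3
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.n_module_genes <= self.n_genes:
            raise ValueError("n_module_genes must be in (0, n_genes]")
        if self.n_driver_tfs > self.n_tfs:
            raise ValueError("n_driver_tfs exceeds n_tfs")
        if abs(self.module_age_corr) > 1:
            raise ValueError("|module_age_corr| must be <= 1")
        if not 0 < self.within_module_corr <= 1:
            raise ValueError("within_module_corr must be in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.module_noise_var() < 0:
            raise ValueError(
                "infeasible correlation target: within_module_corr "
                f"{self.within_module_corr} is unreachable with "
                f"tf_target_loading {self.tf_target_loading} "
                "(implied module noise variance is negative)"
            )
        if self.regulon_size > self.n_module_genes:
            raise ValueError("regulon_size exceeds module size")
        n_bg = self.n_genes - self.n_module_genes - self.n_tfs
        need = (self.n_tfs - self.n_driver_tfs) * self.regulon_size
        if need > n_bg:
            raise ValueError(
                f"non-driver regulons need {need} background genes, "
                f"only {n_bg} available"
            )

    def module_noise_var(self) -> float:
        """Module-gene noise variance implied by the within-module
        correlation target for a pair of genes sharing only the eigengene:
        r = 1 / (1 + loading^2 + var)."""
        return 1.0 / self.within_module_corr - 1.0 - self.tf_target_loading**2


@dataclass
class GroundTruth:
    """Planted truth of one synthetic study (filled in progressively by the
    individual generators)."""

    module_genes: set[str]
    driver_tfs: set[str]
    regulons: dict[str, set[str]]
    marker_overlap: set[str] = field(default_factory=set)
    peak_target_genes: set[str] = field(default_factory=set)
    ppi_seed_clique: set[str] = field(default_factory=set)
    planted_eigengene: np.ndarray | None = None

    def to_json(self, path) -> None:
        payload = {
            "module_genes": sorted(self.module_genes),
            "driver_tfs": sorted(self.driver_tfs),
            "regulons": {tf: sorted(t) for tf, t in sorted(self.regulons.items())},
            "marker_overlap": sorted(self.marker_overlap),
            "peak_target_genes": sorted(self.peak_target_genes),
            "ppi_seed_clique": sorted(self.ppi_seed_clique),
            "planted_eigengene": (
                None
                if self.planted_eigengene is None
                else [round(float(v), 10) for v in self.planted_eigengene]
            ),
        }
        Path(path).write_text(json.dumps(payload, indent=1) + "\n")

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            module_genes=set(d["module_genes"]),
            driver_tfs=set(d["driver_tfs"]),
            regulons={tf: set(t) for tf, t in d["regulons"].items()},
            marker_overlap=set(d["marker_overlap"]),
            peak_target_genes=set(d["peak_target_genes"]),
            ppi_seed_clique=set(d["ppi_seed_clique"]),
            planted_eigengene=(
                None
                if d.get("planted_eigengene") is None
                else np.asarray(d["planted_eigengene"], dtype=float)
            ),
        )


def _rng(config: SynthConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stream]))


def _orthogonal_unit_noise(rng, z: np.ndarray) -> np.ndarray:
    """Zero-mean noise vector orthogonal to `z` (and to the constant),
    scaled to unit sample variance."""
    n = len(z)
    for _ in range(100):
        w = rng.standard_normal(n)
        w = w - w.mean()
        w = w - (w @ z) / (z @ z) * z
        if w.std(ddof=1) > 1e-12:
            return w / w.std(ddof=1)
    raise RuntimeError("could not draw a noise vector orthogonal to age")


def generate_expression(config: SynthConfig) -> tuple[ExpressionStudy, GroundTruth]:
    """Generate the expression matrix, traits and planted truth.

    The planted eigengene is ``e = c*z_age + sqrt(1-c^2)*w`` with `w`
    orthogonalized against standardized age, so the realized sample
    correlation of the latent eigengene with age equals `module_age_corr`
    exactly.  Module gene g: ``x_g = e + loading * sum(driver factors of g's
    regulons) + noise_sd * sigma_m * eps``.  Driver TFs are the private
    regulon factors; non-driver TFs drive disjoint background regulons;
    remaining background genes are i.i.d. standard normal.
    """
    config.validate()
    rng = _rng(config, 0)
    n, m = config.n_genes, config.n_samples

    ages = np.sort(rng.uniform(*config.age_range, m))
    z_age = standardize(ages)

    c = float(config.module_age_corr)
    if abs(c) == 1.0:
        eigengene = c * z_age
    else:
        w = _orthogonal_unit_noise(rng, z_age)
        eigengene = c * z_age + np.sqrt(1.0 - c * c) * w

    # ---- ids ----
    n_nontf = n - config.n_tfs
    gene_ids = [f"G{i:05d}" for i in range(1, n_nontf + 1)]
    tf_ids = [f"TF{i:03d}" for i in range(1, config.n_tfs + 1)]
    module_genes = sorted(
        rng.choice(gene_ids, size=config.n_module_genes, replace=False)
    )
    driver_tfs = list(tf_ids[: config.n_driver_tfs])
    other_tfs = list(tf_ids[config.n_driver_tfs :])

    regulons: dict[str, set[str]] = {}
    # driver regulons partition the module when they fit (keeps every module
    # gene under at most one driver, so TF-target coupling is undiluted);
    # otherwise fall back to independent random subsets
    if config.n_driver_tfs * config.regulon_size <= config.n_module_genes:
        shuffled = list(module_genes)
        rng.shuffle(shuffled)
        for d, tf in enumerate(driver_tfs):
            lo = d * config.regulon_size
            regulons[tf] = set(shuffled[lo : lo + config.regulon_size])
    else:
        for tf in driver_tfs:
            regulons[tf] = set(
                rng.choice(module_genes, size=config.regulon_size, replace=False)
            )
    background_pool = [g for g in gene_ids if g not in set(module_genes)]
    rng.shuffle(background_pool)
    cursor = 0
    for tf in other_tfs:
        regulons[tf] = set(background_pool[cursor : cursor + config.regulon_size])
        cursor += config.regulon_size

    # ---- expression ----
    gamma = config.tf_target_loading
    sigma_m = config.noise_sd * np.sqrt(config.module_noise_var())
    tf_factors = {tf: rng.standard_normal(m) for tf in tf_ids}

    values = np.empty((n, m))
    all_ids = gene_ids + tf_ids
    row = {g: i for i, g in enumerate(all_ids)}
    membership: dict[str, list[str]] = {g: [] for g in gene_ids}
    for tf, targets in regulons.items():
        for g in targets:
            membership[g].append(tf)

    module_set = set(module_genes)
    bg_regulated_noise = config.noise_sd * np.sqrt(1.0 + config.module_noise_var())
    for g in gene_ids:
        drivers_here = membership[g]
        if g in module_set:
            x = eigengene.copy()
            for tf in drivers_here:
                x += gamma * tf_factors[tf]
            x += sigma_m * rng.standard_normal(m)
        elif drivers_here:
            x = np.zeros(m)
            for tf in drivers_here:
                x += gamma * tf_factors[tf]
            x += bg_regulated_noise * rng.standard_normal(m)
        else:
            x = rng.standard_normal(m)
        values[row[g]] = x
    for tf in tf_ids:
        values[row[tf]] = tf_factors[tf]

    # ---- traits: confounders independent of age by rejection resampling ----
    traits = pd.DataFrame({"age": ages})
    for spec in config.confounder_spec:
        if config.dominant_confounder == spec.name:
            rho = config.dominant_confounder_corr
            e_std = standardize(eigengene)
            noise = _orthogonal_unit_noise(rng, e_std)
            x = rho * e_std + np.sqrt(1 - rho * rho) * noise
            traits[spec.name] = x
            continue
        for attempt in range(1000):
            x = spec.sample(rng, m)
            if np.std(x) == 0:
                continue
            if abs(np.corrcoef(x, ages)[0, 1]) <= 0.15:
                break
        else:
            raise RuntimeError(f"could not sample {spec.name} independent of age")
        traits[spec.name] = x
    sample_ids = [f"S{i:04d}" for i in range(1, m + 1)]
    traits.index = pd.Index(sample_ids, name="sample_id")

    study = ExpressionStudy(
        genes=all_ids, samples=sample_ids, values=values, traits=traits
    )
    truth = GroundTruth(
        module_genes=set(module_genes),
        driver_tfs=set(driver_tfs),
        regulons=regulons,
        peak_target_genes=set(module_genes),
        planted_eigengene=eigengene,
    )
    return study, truth


def generate_marker_panels(
    config: SynthConfig, truth: GroundTruth, study: ExpressionStudy
) -> dict[str, set[str]]:
    """One "target-cell" panel with a stated overlap with the planted module
    plus off-cell panels disjoint from it.  Updates truth.marker_overlap."""
    if config.marker_overlap > min(config.marker_panel_size, len(truth.module_genes)):
        raise ValueError("requested marker overlap exceeds module/panel size")
    rng = _rng(config, 1)
    module = sorted(truth.module_genes)
    non_module = sorted(set(study.genes) - truth.module_genes)
    inside = list(rng.choice(module, size=config.marker_overlap, replace=False))
    n_out = config.marker_panel_size - config.marker_overlap
    if n_out > len(non_module):
        raise ValueError("panel larger than available non-module genes")
    chosen = rng.choice(non_module, size=n_out, replace=False)
    panels = {"target_cell": set(inside) | set(chosen)}
    used = set(chosen)
    for i, size in enumerate(config.off_panel_sizes, start=1):
        pool = sorted(set(non_module) - used)
        pick = set(rng.choice(pool, size=size, replace=False))
        used |= pick
        panels[f"off_cell_{i}"] = pick
    truth.marker_overlap = set(inside)
    return panels


def generate_genome_and_peaks(
    config: SynthConfig, truth: GroundTruth, study: ExpressionStudy
) -> tuple[GeneAnnotation, IntervalSet, IntervalSet]:
    """Synthetic single-chromosome annotation, ChIP-style peaks, workspace.

    Genes are placed on one chromosome at `gene_spacing`; peak lengths are
    log-normal; a fraction `peak_enrichment_fraction` of peaks is placed
    inside basal regulatory domains of the planted target genes, the rest
    uniformly (length-preserving) within the workspace.  The workspace is
    the union of the basal domains of *all* genes, mirroring an analysis
    restricted to regulatory territory of expressed genes.
    """
    rng = _rng(config, 2)
    genes = list(study.genes)
    margin = config.basal_up + config.basal_down
    spacing = config.gene_spacing
    if spacing < 2 * margin // 3:
        raise ValueError("genes do not fit on chromosome at stated spacing")
    chrom_len = margin + spacing * len(genes) + margin
    tss = margin + spacing * np.arange(len(genes)) + rng.integers(
        0, spacing // 4, len(genes)
    )
    strand = np.where(rng.random(len(genes)) < 0.5, "+", "-")
    ann = GeneAnnotation(
        table=pd.DataFrame(
            {"gene_id": genes, "chrom": "chr1", "tss": tss, "strand": strand}
        ),
        chrom_lengths={"chr1": int(chrom_len)},
    )
    domains = basal_regulatory_domains(ann, up=config.basal_up, down=config.basal_down)
    workspace = domains.merged()
    target_doms = basal_regulatory_domains(
        ann.subset(sorted(truth.peak_target_genes)),
        up=config.basal_up,
        down=config.basal_down,
    ).merged()

    lengths = np.round(
        np.exp(np.log(config.peak_length_median) + config.peak_length_sigma
               * rng.standard_normal(config.n_peaks))
    ).astype(int)
    lengths = np.clip(lengths, 20, config.basal_up + config.basal_down)

    n_enriched = int(round(config.peak_enrichment_fraction * config.n_peaks))
    starts = np.empty(config.n_peaks, dtype=int)
    t_starts, t_ends = target_doms.starts("chr1"), target_doms.ends("chr1")
    for i in range(n_enriched):
        k = rng.integers(0, len(t_starts))
        lo, hi = t_starts[k], t_ends[k]
        L = min(lengths[i], hi - lo)
        lengths[i] = L
        starts[i] = rng.integers(lo, hi - L + 1)
    if n_enriched < config.n_peaks:
        rest = workspace.place_uniform(
            lengths[n_enriched:], rng
        )  # (chrom, start) placements; single chromosome here
        starts[n_enriched:] = [s for _, s in rest]
    order = np.argsort(starts)
    peaks = IntervalSet.from_arrays(
        ["chr1"] * config.n_peaks, starts[order], starts[order] + lengths[order]
    )
    return ann, peaks, workspace


def generate_ppi(config: SynthConfig, truth: GroundTruth, study: ExpressionStudy):
    """Preferential-attachment background PPI graph with the seed clique
    (driver TFs plus module genes) additionally wired into a clique."""
    if config.ppi_clique_size > config.n_ppi_nodes:
        raise ValueError("clique size exceeds PPI node count")
    rng = _rng(config, 3)
    tfs = [g for g in study.genes if g in truth.regulons]
    others = [g for g in study.genes if g not in truth.regulons]
    n_other = min(config.n_ppi_nodes, len(study.genes)) - len(tfs)
    if n_other < 0:
        raise ValueError("n_ppi_nodes smaller than TF count")
    nodes = tfs + list(rng.choice(others, size=n_other, replace=False))
    # random attachment order: early nodes of a preferential-attachment graph
    # are its hubs, so a fixed order would hand every TF a unique hub degree
    rng.shuffle(nodes)

    g = nx.barabasi_albert_graph(
        len(nodes), config.ppi_attach_m, seed=int(rng.integers(0, 2**31 - 1))
    )
    g = nx.relabel_nodes(g, dict(enumerate(nodes)))

    clique = sorted(truth.driver_tfs)
    module_in_ppi = sorted(truth.module_genes & set(nodes))
    need = config.ppi_clique_size - len(clique)
    if need > 0:
        clique += list(rng.choice(module_in_ppi, size=need, replace=False))
    clique = clique[: config.ppi_clique_size]
    for i, a in enumerate(clique):
        for b in clique[i + 1 :]:
            g.add_edge(a, b)
    truth.ppi_seed_clique = set(clique)
    return g


@dataclass
class SyntheticStudy:
    """Bundle of everything one seed generates."""

    config: SynthConfig
    study: ExpressionStudy
    truth: GroundTruth
    panels: dict[str, set[str]]
    annotation: GeneAnnotation
    peaks: IntervalSet
    workspace: IntervalSet
    ppi: nx.Graph

    def write(self, outdir) -> dict[str, Path]:
        """Persist every artifact as plain text; returns name -> path."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "expression": out / "expression.tsv",
            "traits": out / "traits.tsv",
            "tfs": out / "tfs.txt",
            "panels": out / "marker_panels.tsv",
            "annotation": out / "gene_annotation.tsv",
            "peaks": out / "peaks.bed",
            "workspace": out / "workspace.bed",
            "ppi": out / "ppi_edges.tsv",
            "truth": out / "ground_truth.json",
        }
        self.study.to_tsv(paths["expression"], paths["traits"])
        paths["tfs"].write_text(
            "".join(f"{tf}\n" for tf in sorted(self.truth.regulons))
        )
        rows = [
            {"panel_name": name, "gene_id": g}
            for name in sorted(self.panels)
            for g in sorted(self.panels[name])
        ]
        pd.DataFrame(rows).to_csv(paths["panels"], sep="\t", index=False)
        self.annotation.to_tsv(paths["annotation"])
        self.peaks.to_bed(paths["peaks"])
        self.workspace.to_bed(paths["workspace"])
        edges = sorted(tuple(sorted(e)) for e in self.ppi.edges())
        pd.DataFrame(edges, columns=["protein_a", "protein_b"]).to_csv(
            paths["ppi"], sep="\t", index=False
        )
        self.truth.to_json(paths["truth"])
        return paths


def generate_study(config: SynthConfig) -> SyntheticStudy:
    """Run every generator for one config; the one-stop entry point."""
    study, truth = generate_expression(config)
    panels = generate_marker_panels(config, truth, study)
    ann, peaks, workspace = generate_genome_and_peaks(config, truth, study)
    ppi = generate_ppi(config, truth, study)
    return SyntheticStudy(
        config=config,
        study=study,
        truth=truth,
        panels=panels,
        annotation=ann,
        peaks=peaks,
        workspace=workspace,
        ppi=ppi,
    )
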