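"""End-to-end orchestration: synthetic study (optional) -> co-expression
module selection -> MI network & regulons -> master regulators -> marker
enrichment -> peak/regulatory-domain overlap -> PPI connectivity -> report.

Every stage consumes only files produced by earlier stages or config inputs,
persists its artifacts under the output directory, and derives its RNG seed
from the global seed via a stage-name hash, so stages can be rerun
independently and a fixed seed yields a byte-identical report (no
timestamps inside the report payload).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import coexpr, markers, minet, mrscan, ppinet, regdom, synthio
from ._utils import stage_seed
from .study import ExpressionStudy

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""

    def __init__(self, stage: str, cause: str):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Inputs and per-stage parameters.

    Either `simulate` holds a synthio config (inputs are generated into
    outdir/data) or the explicit input paths must all exist.
    """

    outdir: str = "cortexreg_out"
    seed: int = 0
    simulate: synthio.SynthConfig | None = None
    # explicit inputs (used when simulate is None)
    expression: str | None = None
    traits: str | None = None
    tfs: str | None = None
    marker_panels: str | None = None
    annotation: str | None = None
    peaks: str | None = None
    workspace: str | None = None
    ppi: str | None = None
    # stage parameters (cohort-study-scale defaults)
    min_size: int = 10
    merge_height: float = 0.25
    alpha: float = 0.05
    powers: tuple[int, ...] = tuple(range(1, 21))
    fit_target: float = 0.85
    mi_pvalue: float = 1e-7
    dpi_tolerance: float = 0.1
    bootstrap_rounds: int = 100
    mi_estimator: str = "binned"
    B_enrich: int = 1000
    nsim_overlap: int = 1000
    perms_ppi: int = 1000
    basal_up: int = 5000
    basal_down: int = 1000

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulate", None)
        if sim is not None:
            confs = sim.pop("confounder_spec", None)
            if confs is not None:
                sim["confounder_spec"] = tuple(
                    synthio.ConfounderSpec(**c) for c in confs
                )
            for key in ("age_range", "off_panel_sizes"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            sim = synthio.SynthConfig(**sim)
        raw.update(overrides)
        if "powers" in raw:
            raw["powers"] = tuple(raw["powers"])
        return cls(simulate=sim, **raw)

    def validate_inputs(self) -> None:
        if self.simulate is not None:
            return
        required = {
            "expression": self.expression,
            "traits": self.traits,
            "tfs": self.tfs,
        }
        for name, p in required.items():
            if p is None:
                raise PipelineError("config", f"missing required input {name!r}")
            if not Path(p).exists():
                raise PipelineError("config", f"input path does not exist: {p}")
        for name, p in {
            "marker_panels": self.marker_panels,
            "annotation": self.annotation,
            "peaks": self.peaks,
            "workspace": self.workspace,
            "ppi": self.ppi,
        }.items():
            if p is not None and not Path(p).exists():
                raise PipelineError("config", f"input path does not exist: {p}")


def _read_panels(path) -> dict[str, set[str]]:
    df = pd.read_csv(path, sep="\t")
    return {
        name: set(sub["gene_id"].astype(str))
        for name, sub in df.groupby("panel_name")
    }


def write_network_tsv(net: minet.MINetwork, path) -> None:
    rows = [
        {
            "gene_a": a,
            "gene_b": b,
            "mi": mi,
            "support": net.support.get((a, b), np.nan),
        }
        for (a, b), mi in sorted(net.edges.items())
    ]
    pd.DataFrame(rows, columns=["gene_a", "gene_b", "mi", "support"]).to_csv(
        path, sep="\t", index=False, float_format="%.8g"
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage in order; returns (and persists) the report."""
    config.validate_inputs()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "seed": config.seed,
        # outdir is a machine-local path and is excluded so that reports from
        # identical runs are byte-identical wherever they are written
        "parameters": {
            k: v
            for k, v in dataclasses.asdict(config).items()
            if k not in ("simulate", "outdir")
        },
        "stages": {},
    }
    if config.simulate is not None:
        report["parameters"]["simulate"] = dataclasses.asdict(config.simulate)

    # ---- stage: inputs ----
    if config.simulate is not None:
        sim_cfg = dataclasses.replace(
            config.simulate, seed=stage_seed(config.seed, "simulate")
        )
        bundle = synthio.generate_study(sim_cfg)
        paths = bundle.write(out / "data")
        study = bundle.study
        tf_list = sorted(bundle.truth.regulons)
        panels = bundle.panels
        annotation = bundle.annotation
        peaks = bundle.peaks
        workspace = bundle.workspace
        ppi_graph = bundle.ppi
        report["stages"]["simulate"] = {
            "seed": sim_cfg.seed,
            "files": {k: str(v.relative_to(out)) for k, v in paths.items()},
            "n_genes": study.n_genes,
            "n_samples": study.n_samples,
        }
    else:
        study = ExpressionStudy.from_tsv(config.expression, config.traits)
        tf_list = [
            line.strip()
            for line in Path(config.tfs).read_text().splitlines()
            if line.strip()
        ]
        panels = (
            _read_panels(config.marker_panels) if config.marker_panels else {}
        )
        annotation = (
            regdom.GeneAnnotation.from_tsv(config.annotation)
            if config.annotation
            else None
        )
        peaks = regdom.IntervalSet.from_bed(config.peaks) if config.peaks else None
        workspace = (
            regdom.IntervalSet.from_bed(config.workspace)
            if config.workspace
            else None
        )
        ppi_graph = ppinet.read_ppi_tsv(config.ppi) if config.ppi else None

    # ---- stage: coexpr ----
    try:
        study = study.drop_zero_variance()
        sim = coexpr.correlation_matrix(study)
        beta, fit_table = coexpr.pick_soft_power(
            sim, powers=config.powers, fit_target=config.fit_target
        )
        adj = np.abs(sim) ** beta
        np.fill_diagonal(adj, 0.0)
        tom = coexpr.adjacency_to_tom(adj)
        modules = coexpr.detect_modules(
            tom, study, min_size=config.min_size, merge_height=config.merge_height
        )
        age_report = coexpr.select_age_modules(modules, study, alpha=config.alpha)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("coexpr", str(e)) from e
    modules.membership_table(study).to_csv(
        out / "module_membership.tsv", sep="\t", index=False, float_format="%.6g"
    )
    eig = pd.DataFrame(
        {f"ME{m}": modules.eigengenes[m] for m in modules.module_ids()},
        index=study.samples,
    )
    eig.index.name = "sample_id"
    eig.to_csv(out / "module_eigengenes.tsv", sep="\t", float_format="%.8g")
    (out / "age_module_report.json").write_text(
        json.dumps(age_report.to_dict(), indent=1, default=float) + "\n"
    )
    selected = age_report.selected_modules()
    if not selected:
        raise PipelineError(
            "coexpr", "no module passed the age-dependence selection rule"
        )
    target_module_id = selected[0]  # most significant age p among selected
    module_genes = set(modules.members(target_module_id))
    (out / "age_module_genes.txt").write_text(
        "".join(g + "\n" for g in sorted(module_genes))
    )
    report["stages"]["coexpr"] = {
        "soft_power": beta,
        "fit_table": fit_table.to_dict(orient="records"),
        "n_modules": len(modules.module_ids()),
        "module_sizes": {str(k): v for k, v in sorted(modules.sizes().items())},
        "selected_modules": selected,
        "age_module_id": target_module_id,
        "age_module_size": len(module_genes),
        "age_report": age_report.to_dict(),
    }

    # ---- stage: minet ----
    try:
        seed_minet = stage_seed(config.seed, "minet")
        if config.bootstrap_rounds >= 2:
            net = minet.bootstrap_consensus(
                study,
                rounds=config.bootstrap_rounds,
                p_value=config.mi_pvalue,
                epsilon=config.dpi_tolerance,
                tf_list=tf_list,
                seed=seed_minet,
                method=config.mi_estimator,
            )
        else:
            net = minet.build_mi_network(
                study,
                tf_list,
                p_value=config.mi_pvalue,
                epsilon=config.dpi_tolerance,
                seed=seed_minet,
                method=config.mi_estimator,
            )
        regulons = minet.extract_regulons(net)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("minet", str(e)) from e
    write_network_tsv(net, out / "mi_network.tsv")
    report["stages"]["minet"] = {
        "seed": seed_minet,
        "n_edges": net.n_edges(),
        "n_tfs_in_network": len(net.tf_nodes()),
        "n_tfs_with_regulon": sum(1 for t in regulons.values() if t),
        "params": {k: v for k, v in net.params.items()},
    }

    # ---- stage: mrscan ----
    try:
        universe = set(net.nodes)
        mr_results = mrscan.identify_master_regulators(
            regulons, module_genes & universe, universe, alpha=config.alpha
        )
    except Exception as e:  # noqa: BLE001
        raise PipelineError("mrscan", str(e)) from e
    mrscan.results_table(mr_results).to_csv(
        out / "master_regulators.tsv", sep="\t", index=False, float_format="%.6g"
    )
    mrs = [r.tf for r in mr_results if r.is_mr]
    report["stages"]["mrscan"] = {
        "n_tested": len(mr_results),
        "master_regulators": mrs,
        "top": [r.to_dict() for r in mr_results[:10]],
    }

    # ---- stage: markers ----
    if panels:
        try:
            seed_markers = stage_seed(config.seed, "markers")
            enrich = {}
            trends = {}
            for name, panel in sorted(panels.items()):
                res = markers.marker_enrichment(
                    module_genes,
                    panel,
                    set(study.genes),
                    B=config.B_enrich,
                    seed=seed_markers,
                )
                enrich[name] = res.to_dict()
                trend = markers.marker_age_trend(study, panel)
                trends[name] = trend.to_dict()
        except Exception as e:  # noqa: BLE001
            raise PipelineError("markers", str(e)) from e
        (out / "marker_enrichment.json").write_text(
            json.dumps({"enrichment": enrich, "age_trends": trends}, indent=1)
            + "\n"
        )
        report["stages"]["markers"] = {
            "seed": seed_markers,
            "enrichment": enrich,
            "age_trends": trends,
        }

    # ---- stage: regdom ----
    if annotation is not None and peaks is not None and workspace is not None:
        try:
            seed_regdom = stage_seed(config.seed, "regdom")
            module_ann = annotation.subset(sorted(module_genes))
            targets = regdom.basal_regulatory_domains(
                module_ann, up=config.basal_up, down=config.basal_down
            )
            ov = regdom.interval_overlap_test(
                peaks,
                targets,
                workspace,
                n_sim=config.nsim_overlap,
                seed=seed_regdom,
            )
            qs = regdom.adjust_pvalues([ov.p_empirical])
        except Exception as e:  # noqa: BLE001
            raise PipelineError("regdom", str(e)) from e
        res = ov.to_dict()
        res["q_value"] = float(qs[0])
        pd.DataFrame([res]).to_csv(
            out / "peak_overlap.tsv", sep="\t", index=False, float_format="%.6g"
        )
        report["stages"]["regdom"] = {"seed": seed_regdom, **res}

    # ---- stage: ppinet ----
    if ppi_graph is not None:
        try:
            seed_ppi = stage_seed(config.seed, "ppinet")
            seeds = [m for m in mrs if m in ppi_graph]
            if not seeds:
                report["stages"]["ppinet"] = {
                    "note": "no master regulators present in the PPI network"
                }
            else:
                _, stats = ppinet.seed_subnetwork(ppi_graph, seeds)
                perm = ppinet.within_degree_permutation_test(
                    ppi_graph, seeds, B=config.perms_ppi, seed=seed_ppi
                )
                pd.DataFrame(
                    [
                        {"protein": s, "p_empirical": p}
                        for s, p in sorted(perm.per_node_p.items())
                    ]
                ).to_csv(
                    out / "ppi_node_p.tsv",
                    sep="\t",
                    index=False,
                    float_format="%.6g",
                )
                report["stages"]["ppinet"] = {
                    "seed": seed_ppi,
                    **perm.to_dict(),
                }
        except Exception as e:  # noqa: BLE001
            raise PipelineError("ppinet", str(e)) from e

    payload = json.dumps(report, indent=1, sort_keys=True, default=float) + "\n"
    (out / "report.json").write_text(payload)
    (out / "report.md").write_text(_markdown_summary(report))
    return report


def _markdown_summary(report: dict) -> str:
    lines = ["# cortexreg pipeline report", ""]
    lines.append(f"Global seed: {report['seed']}")
    co = report["stages"].get("coexpr", {})
    if co:
        lines += [
            "",
            "## Age-dependent module",
            f"- soft power: {co['soft_power']}",
            f"- modules detected: {co['n_modules']}",
            f"- selected (age rule): {co['selected_modules']}",
            f"- age module id {co['age_module_id']} with {co['age_module_size']} genes",
        ]
    mr = report["stages"].get("mrscan", {})
    if mr:
        lines += [
            "",
            "## Master regulators",
            f"- TFs tested: {mr['n_tested']}",
            f"- flagged: {', '.join(mr['master_regulators']) or 'none'}",
        ]
    mk = report["stages"].get("markers", {})
    if mk:
        lines += ["", "## Marker enrichment"]
        for name, e in mk["enrichment"].items():
            lines.append(
                f"- {name}: observed {e['observed']}, null median "
                f"{e['null_median']}, fold {e['fold']:.3g}, "
                f"p {e['p_empirical']:.3g}"
            )
    rg = report["stages"].get("regdom", {})
    if rg and "observed_bp" in rg:
        lines += [
            "",
            "## Peak / regulatory-domain overlap",
            f"- observed {rg['observed_bp']:.0f} bp vs expected "
            f"{rg['expected_bp']:.1f} bp (fold {rg['fold']:.3g}), "
            f"p {rg['p_empirical']:.3g}, q {rg['q_value']:.3g}",
        ]
    pp = report["stages"].get("ppinet", {})
    if pp and "n_direct_edges" in pp:
        lines += [
            "",
            "## PPI connectivity",
            f"- {pp['n_direct_edges']} direct edges among "
            f"{pp['n_connected_seeds']} connected seeds "
            f"(mean direct degree {pp['mean_direct_degree']:.2f})",
            f"- network p-values: {pp['network_p']}",
        ]
    return "\n".join(lines) + "\n"
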