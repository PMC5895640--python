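"""Pipeline orchestration: ordered stages, config, seeds, run manifest.

Stages (in order): select-genes -> network (per condition + combined) ->
stats -> preserve -> ppi -> qtl -> neo.  Each stage writes its outputs under
the run directory together with a small stage record (input hashes + config
hash); a stage re-runs only when its outputs are missing or its recorded
hashes changed, so deleting one intermediate regenerates just the downstream
stages.  A single global seed is fanned out to per-stage seeds via
``numpy.random.SeedSequence.spawn``.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .datamodel import CONDITIONS, ExpressionMatrix, ModuleAssignment, PhenotypeTable
from . import io as bio
from .coexpression import ModuleDetector
from .module_stats import enrichment_table, module_trait_correlation, summarize_patterns
from .ppi import export_subnetworks, extract_subnetworks, filter_ppi, intersect_with_modules
from .preservation import call_specific_modules, module_overlap
from .causality import eqtl_scan, peak_marker, qtl_scan, screen_causal_genes
from .variable_genes import select_for_conditions

log = logging.getLogger(__name__)

STAGES = ("select-genes", "network", "stats", "preserve", "ppi", "qtl", "neo")

_ALLOWED_KEYS = {
    "expression", "genotypes", "phenotypes", "ppi", "gene_sets",
    "gene_positions", "outdir", "seed", "mean_floor", "resp_cutoff",
    "rsq_target", "min_module_size", "cut_height_frac", "pattern_delta_min",
    "ppi_min_score", "preserve_alpha", "enrich_alpha", "leo_threshold",
    "lrs_min", "cis_window", "display_p", "min_subnetwork_nodes", "power",
}


@dataclass
class PipelineConfig:
    """Validated configuration for a full run."""

    expression: dict[str, str]  # condition -> TSV path
    genotypes: str
    phenotypes: str
    ppi: str | None = None
    gene_sets: str | None = None
    gene_positions: str | None = None
    outdir: str = "bxdnet_run"
    seed: int = 0
    mean_floor: float = 8.0
    resp_cutoff: float = 0.5
    rsq_target: float = 0.8
    min_module_size: int = 30
    cut_height_frac: float = 0.99
    power: int | None = None
    pattern_delta_min: float = 0.1
    ppi_min_score: int = 700
    preserve_alpha: float = 0.01
    enrich_alpha: float = 0.05
    leo_threshold: float = 0.5
    lrs_min: float = 15.0
    cis_window: float = 10.0
    display_p: float = 0.1
    min_subnetwork_nodes: int = 5

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        unknown = set(d) - _ALLOWED_KEYS
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**d)

    def validate_files(self) -> None:
        paths = list(self.expression.values()) + [self.genotypes, self.phenotypes]
        for opt in (self.ppi, self.gene_sets, self.gene_positions):
            if opt:
                paths.append(opt)
        missing = [p for p in paths if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"missing input file(s): {missing}")
        bounds = {
            "resp_cutoff": (0, 1), "rsq_target": (0, 1),
            "cut_height_frac": (0, 1), "preserve_alpha": (0, 1),
            "enrich_alpha": (0, 1), "display_p": (0, 1),
            "ppi_min_score": (0, 1000),
        }
        for key, (lo, hi) in bounds.items():
            v = getattr(self, key)
            if not lo <= v <= hi:
                raise ValueError(f"config {key}={v} outside [{lo}, {hi}]")


def stage_seeds(seed: int, n: int = len(STAGES)) -> dict[str, int]:
    """Per-stage 31-bit seeds derived from the global seed."""
    children = np.random.SeedSequence(seed).spawn(n)
    return {
        name: int(np.random.default_rng(s).integers(0, 2**31))
        for name, s in zip(STAGES, children)
    }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    config: dict
    version: str = __version__
    stages: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(
            {"config": self.config, "version": self.version,
             "stages": self.stages, "warnings": self.warnings},
            indent=2, sort_keys=True, default=str))


class PipelineRunner:
    """Executes the stages with per-stage caching and a run manifest."""

    def __init__(self, config: PipelineConfig):
        config.validate_files()
        self.cfg = config
        self.outdir = Path(config.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.seeds = stage_seeds(config.seed)
        self.manifest = RunManifest(config=config.__dict__.copy())

    # -- caching helpers ---------------------------------------------------
    def _record(self, stage: str, inputs: list[Path], outputs: list[Path],
                elapsed: float) -> None:
        self.manifest.stages[stage] = {
            "inputs": {str(p): _sha256(p) for p in inputs if p.exists()},
            "outputs": {str(p): _sha256(p) for p in outputs if p.exists()},
            "seed": self.seeds.get(stage),
            "elapsed_s": round(elapsed, 3),
        }
        (self.outdir / f".stage_{stage.replace('-', '_')}.json").write_text(
            json.dumps(self.manifest.stages[stage]["inputs"], sort_keys=True))

    def _fresh(self, stage: str, inputs: list[Path], outputs: list[Path]) -> bool:
        rec = self.outdir / f".stage_{stage.replace('-', '_')}.json"
        if not rec.exists() or not all(p.exists() for p in outputs):
            return False
        old = json.loads(rec.read_text())
        now = {str(p): _sha256(p) for p in inputs if p.exists()}
        return old == now

    # -- stages ------------------------------------------------------------
    def run(self, force: bool = False) -> RunManifest:
        t_all = time.time()
        try:
            self.stage_select_genes(force)
            self.stage_network(force)
            self.stage_stats(force)
            self.stage_preserve(force)
            self.stage_ppi(force)
            self.stage_qtl(force)
            self.stage_neo(force)
        except Exception as err:
            self.manifest.warnings.append(f"pipeline aborted: {err}")
            self.manifest.write(self.outdir / "manifest.json")
            raise RuntimeError(f"stage failed: {err}") from err
        self.manifest.stages["total_elapsed_s"] = round(time.time() - t_all, 3)
        self.manifest.write(self.outdir / "manifest.json")
        return self.manifest

    def _load_expression(self) -> dict[str, ExpressionMatrix]:
        return {
            cond: bio.read_expression(path, condition=cond)
            for cond, path in self.cfg.expression.items()
        }

    def stage_select_genes(self, force: bool = False) -> None:
        stage = "select-genes"
        inputs = [Path(p) for p in self.cfg.expression.values()]
        out = self.outdir / "variable_genes.tsv"
        if not force and self._fresh(stage, inputs, [out]):
            log.info("stage %s cached", stage)
            return
        t0 = time.time()
        exprs = self._load_expression()
        merged, fits, profiles = select_for_conditions(
            exprs, self.cfg.mean_floor, self.cfg.resp_cutoff,
            seed=self.seeds[stage],
        )
        rows = []
        for cond, prof in profiles.items():
            tab = prof.table.copy()
            tab["condition"] = cond
            tab["responsibility"] = fits[cond].responsibility
            tab["selected"] = tab.index.isin(merged.provenance.get(cond, set()))
            rows.append(tab.reset_index(names="gene"))
        pd.concat(rows).to_csv(out, sep="\t", index=False, na_rep="NA")
        (self.outdir / "mixture_fits.json").write_text(json.dumps({
            cond: {"weights": list(f.weights), "means": list(f.means),
                   "sds": list(f.sds), "converged": f.converged}
            for cond, f in fits.items()}, indent=2))
        (self.outdir / "merged_genes.txt").write_text(
            "\n".join(sorted(merged.genes)) + "\n")
        self._record(stage, inputs, [out], time.time() - t0)

    def _merged_genes(self) -> list[str]:
        return (self.outdir / "merged_genes.txt").read_text().split()

    def _combined_matrix(self, exprs, genes) -> ExpressionMatrix:
        """Condition matrices concatenated column-wise, condition-tagged."""
        parts = []
        for cond in exprs:
            sub = exprs[cond].data.reindex(genes)
            sub.columns = [f"{cond}:{s}" for s in sub.columns]
            parts.append(sub)
        return ExpressionMatrix(pd.concat(parts, axis=1), condition="combined")

    def stage_network(self, force: bool = False) -> None:
        stage = "network"
        inputs = [self.outdir / "merged_genes.txt"] + [
            Path(p) for p in self.cfg.expression.values()]
        names = ["combined"] + list(self.cfg.expression)
        outs = [self.outdir / f"modules_{n}.tsv" for n in names]
        if not force and self._fresh(stage, inputs, outs):
            log.info("stage %s cached", stage)
            return
        t0 = time.time()
        exprs = self._load_expression()
        genes = [g for g in self._merged_genes()
                 if all(g in e.data.index for e in exprs.values())]
        targets: dict[str, ExpressionMatrix] = {
            "combined": self._combined_matrix(exprs, genes)}
        for cond, e in exprs.items():
            targets[cond] = ExpressionMatrix(
                e.data.reindex(genes), condition=cond)
        for name, expr in targets.items():
            det = ModuleDetector(
                power=self.cfg.power, rsq_target=self.cfg.rsq_target,
                min_module_size=self.cfg.min_module_size,
                cut_height_frac=self.cfg.cut_height_frac,
            ).fit(expr)
            ms = det.modules_
            pd.DataFrame({
                "gene": ms.assignment.genes,
                "module": ms.assignment.labels.to_numpy(),
                "kME": ms.kme.to_numpy(),
                "k_in": ms.k_in.to_numpy(),
            }).to_csv(self.outdir / f"modules_{name}.tsv", sep="\t",
                      index=False, na_rep="NA")
            ms.eigengenes.to_csv(self.outdir / f"eigengenes_{name}.tsv",
                                 sep="\t", na_rep="NA")
            if det.scan_ is not None:
                det.scan_.table.assign(chosen=lambda t: t.index == det.power_) \
                    .to_csv(self.outdir / f"power_scan_{name}.tsv", sep="\t")
        self._record(stage, inputs, outs, time.time() - t0)

    def _assignment(self, name: str) -> ModuleAssignment:
        df = pd.read_csv(self.outdir / f"modules_{name}.tsv", sep="\t")
        return ModuleAssignment(pd.Series(
            df["module"].to_numpy(), index=df["gene"].astype(str)))

    def stage_stats(self, force: bool = False) -> None:
        stage = "stats"
        inputs = [self.outdir / "modules_combined.tsv", Path(self.cfg.phenotypes)]
        outs = [self.outdir / "patterns.tsv", self.outdir / "trait_correlation.tsv"]
        if not force and self._fresh(stage, inputs, outs):
            log.info("stage %s cached", stage)
            return
        t0 = time.time()
        exprs = self._load_expression()
        assignment = self._assignment("combined")
        summary = summarize_patterns(exprs, assignment, self.cfg.pattern_delta_min)
        summary.table.to_csv(outs[0], sep="\t", na_rep="NA")
        mes = pd.read_csv(self.outdir / "eigengenes_combined.tsv",
                          sep="\t", index_col=0)
        # combined eigengenes are condition-tagged; correlate per condition block
        pheno = bio.read_phenotypes(self.cfg.phenotypes)
        blocks = []
        for cond in self.cfg.expression:
            cols = [c for c in mes.columns if c.startswith(f"{cond}:")]
            sub = mes[cols]
            sub.columns = [c.split(":", 1)[1] for c in cols]
            tc = module_trait_correlation(sub, pheno, self.cfg.display_p)
            tc["condition"] = cond
            blocks.append(tc)
        pd.concat(blocks).to_csv(outs[1], sep="\t", index=False, na_rep="NA")
        if self.cfg.gene_sets:
            coll = bio.read_gmt(self.cfg.gene_sets)
            enrichment_table(assignment, coll, alpha=self.cfg.enrich_alpha) \
                .to_csv(self.outdir / "enrichment.tsv", sep="\t", index=False)
        self._record(stage, inputs, outs, time.time() - t0)

    def stage_preserve(self, force: bool = False) -> None:
        stage = "preserve"
        conds = list(self.cfg.expression)
        inputs = [self.outdir / f"modules_{c}.tsv" for c in conds]
        outs = [self.outdir / "overlaps.tsv", self.outdir / "specificity.tsv"]
        if not force and self._fresh(stage, inputs, outs):
            log.info("stage %s cached", stage)
            return
        t0 = time.time()
        parts = {c: self._assignment(c) for c in conds}
        rows, calls = [], []
        for ca in conds:
            per_cond = []
            for cb in conds:
                if ca == cb:
                    continue
                ov = module_overlap(parts[ca], parts[cb],
                                    alpha=self.cfg.preserve_alpha,
                                    condition_a=ca, condition_b=cb)
                tab = ov.table.copy()
                tab["condition_a"], tab["condition_b"] = ca, cb
                rows.append(tab)
                per_cond.append(ov)
            for call in call_specific_modules(per_cond):
                calls.append({
                    "module": call.module, "condition": call.condition,
                    "specific": call.specific, "best_p": call.best_p,
                })
        pd.concat(rows).to_csv(outs[0], sep="\t", index=False)
        pd.DataFrame(calls).to_csv(outs[1], sep="\t", index=False)
        self._record(stage, inputs, outs, time.time() - t0)

    def stage_ppi(self, force: bool = False) -> None:
        stage = "ppi"
        if not self.cfg.ppi:
            return
        inputs = [Path(self.cfg.ppi), self.outdir / "modules_combined.tsv"]
        outs = [self.outdir / "common_interactions.tsv",
                self.outdir / "subnetworks.tsv"]
        if not force and self._fresh(stage, inputs, outs):
            log.info("stage %s cached", stage)
            return
        t0 = time.time()
        ppi = bio.read_ppi(self.cfg.ppi)
        filtered = filter_ppi(ppi, self.cfg.ppi_min_score)
        assignment = self._assignment("combined")
        common = intersect_with_modules(filtered, assignment)
        common.to_csv(outs[0], sep="\t", index=False)
        subnets = extract_subnetworks(common, self.cfg.min_subnetwork_nodes)
        pd.DataFrame([{
            "rank": i + 1, "module": s.module, "n_nodes": s.size,
            "n_edges": len(s.edges), "nodes": ",".join(s.nodes),
        } for i, s in enumerate(subnets)]).to_csv(outs[1], sep="\t", index=False)
        mod_df = pd.read_csv(self.outdir / "modules_combined.tsv", sep="\t",
                             index_col="gene")
        export_subnetworks(subnets, self.outdir / "subnetworks", "SIF", mod_df)
        self._record(stage, inputs, outs, time.time() - t0)

    def stage_qtl(self, force: bool = False) -> None:
        stage = "qtl"
        inputs = [Path(self.cfg.phenotypes), Path(self.cfg.genotypes)]
        outs = [self.outdir / "qtl.tsv"]
        if not force and self._fresh(stage, inputs, outs):
            log.info("stage %s cached", stage)
            return
        t0 = time.time()
        pheno = bio.read_phenotypes(self.cfg.phenotypes)
        geno = bio.read_genotypes(self.cfg.genotypes)
        qtl_scan(pheno, geno).to_csv(outs[0], sep="\t", index=False)
        self._record(stage, inputs, outs, time.time() - t0)

    def stage_neo(self, force: bool = False) -> None:
        stage = "neo"
        inputs = [self.outdir / "qtl.tsv", self.outdir / "modules_combined.tsv"]
        outs = [self.outdir / "leo.tsv"]
        if not force and self._fresh(stage, inputs, outs):
            log.info("stage %s cached", stage)
            return
        t0 = time.time()
        qtl = pd.read_csv(self.outdir / "qtl.tsv", sep="\t")
        geno = bio.read_genotypes(self.cfg.genotypes)
        pheno = bio.read_phenotypes(self.cfg.phenotypes)
        assignment = self._assignment("combined")
        exprs = self._load_expression()
        # per trait: anchor at its peak marker, screen genes of each module
        results = []
        eqtl_rows = []
        for trait in pheno.traits:
            try:
                marker = peak_marker(qtl, trait)
            except ValueError:
                continue
            codes = geno.codes.loc[marker]
            for module in assignment.modules():
                genes = sorted(assignment.members(module))
                for cond, expr in exprs.items():
                    present = [g for g in genes if g in expr.data.index]
                    if not present:
                        continue
                    shared = [s for s in expr.strains
                              if s in codes.index and s in pheno.strains]
                    sub = ExpressionMatrix(
                        expr.data.loc[present, shared], condition=cond)
                    one = PhenotypeTable(pheno.data.loc[shared, [trait]])
                    df = screen_causal_genes(
                        codes[shared].to_numpy(), sub, one,
                        marker_name=marker, threshold=self.cfg.leo_threshold)
                    if len(df):
                        df["module"], df["condition"] = module, cond
                        results.append(df)
                    break  # screen in the trait's own condition ordering
        if results:
            pd.concat(results).to_csv(outs[0], sep="\t", index=False)
        else:
            pd.DataFrame(columns=["gene", "phenotype", "leo"]).to_csv(
                outs[0], sep="\t", index=False)
        # cis-eQTL table for passing genes, when positions are available
        if self.cfg.gene_positions:
            pos = pd.read_csv(self.cfg.gene_positions, sep="\t", index_col=0)
            expr0 = next(iter(exprs.values()))
            eqtl = eqtl_scan(expr0, geno, pos, self.cfg.cis_window,
                             lrs_min=self.cfg.lrs_min)
            eqtl.to_csv(self.outdir / "eqtl.tsv", sep="\t", index=False)
            eqtl_rows.append(len(eqtl))
        self._record(stage, inputs, outs, time.time() - t0)


def run_pipeline(config: PipelineConfig, force: bool = False) -> RunManifest:
    """Run all stages in order; returns the manifest."""
    return PipelineRunner(config).run(force=force)
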