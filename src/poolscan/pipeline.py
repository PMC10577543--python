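"""End-to-end orchestration: config, stage execution, manifest, CLI.

Stages run in dependency order (I/O and frequency estimation feed the
association scan, tag selection, the permutation depletion test, the
multivariate stage and the kernel tests).  Every stage writes its outputs
under its own subdirectory of the run directory, and a manifest records
package version, seeds, parameters and input checksums so a rerun with the
same config reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import click
import numpy as np
import yaml

from . import __version__
from . import assoc as assoc_mod
from . import kerneltest, ldtags, multivar, poolio, riskperm, simcohort

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "cli"]


@dataclass
class RunConfig:
    """All paths and stage parameters of one pipeline run."""

    vcf: str
    design: str
    regions_bed: str
    known_ids: str
    flag_snps: str
    mac_min: int = 4
    alpha: float = 0.05
    r2_max: float = 0.1
    n_blocks: int = 5
    n_perm_depletion: int = 10_000
    n_perm_classifier: int = 1000
    n_perm_burden: int = 10_000
    pca_components: int = 5
    screen_components: int = 3
    classifier_components: tuple[int, ...] = (2, 3)
    top_k_importance: int = 20
    weights_beta: tuple[float, float] = (1.0, 25.0)
    seed: int = 0
    stages: tuple[str, ...] = ("summarize", "assoc", "tags", "permtest",
                               "pca", "kernel")

    def to_yaml(self, path: str) -> None:
        d = dataclasses.asdict(self)
        d["classifier_components"] = list(self.classifier_components)
        d["weights_beta"] = list(self.weights_beta)
        d["stages"] = list(self.stages)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        for k in ("classifier_components", "weights_beta", "stages"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: RunConfig, outdir: str) -> dict:
    """Execute the configured stages and return the manifest dict.

    A stage failure raises :class:`StageError` naming the stage; outputs
    of completed stages are retained."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {k: v for k, v in dataclasses.asdict(config).items()
                       if not isinstance(v, str)},
        "inputs": {k: _sha256(getattr(config, k))
                   for k in ("vcf", "design", "regions_bed", "known_ids",
                             "flag_snps")},
        "stages": {},
    }

    def _stage(name):
        def deco(fn):
            if name in config.stages or name == "poolio":
                try:
                    log.info("stage %s", name)
                    fn()
                    manifest["stages"][name] = "ok"
                except Exception as e:  # noqa: BLE001 — rewrap with stage name
                    manifest["stages"][name] = f"failed: {e}"
                    (out / "manifest.json").write_text(
                        json.dumps(manifest, indent=2, sort_keys=True))
                    raise StageError(name, e) from e
            return fn
        return deco

    state: dict = {}

    @_stage("poolio")
    def _io():
        design = poolio.read_pool_design(config.design)
        counts = poolio.read_pooled_vcf(config.vcf, design)
        freq = poolio.estimate_frequencies(counts, design)
        state.update(design=design, counts=counts, freq=freq)
        d = out / "poolio"
        d.mkdir(exist_ok=True)
        freq.to_frame().to_csv(d / "frequencies.tsv", sep="\t")

    @_stage("summarize")
    def _summarize():
        freq = state["freq"]
        known = poolio.load_known_ids(config.known_ids)
        variants = _variants_from_vcf(config.vcf)
        variants = poolio.flag_novelty(variants, known)
        summary = poolio.summarize_variants(variants, freq,
                                            mac_min=config.mac_min)
        state["variants"] = variants
        d = out / "summarize"
        d.mkdir(exist_ok=True)
        (d / "summary.json").write_text(
            json.dumps(summary.to_json_dict(), indent=2))
        summary.bin_counts.to_csv(d / "maf_bins.tsv", sep="\t")

    @_stage("assoc")
    def _assoc():
        table = assoc_mod.assoc_scan(state["freq"], state["design"],
                                     mac_min=config.mac_min,
                                     alpha=config.alpha)
        flags = poolio.load_flag_snps(config.flag_snps)
        forest = assoc_mod.forest_table(state["freq"], state["design"], flags,
                                        mac_min=config.mac_min)
        state.update(assoc=table, flags=flags, forest=forest)
        d = out / "assoc"
        d.mkdir(exist_ok=True)
        table.table.to_csv(d / "association.tsv", sep="\t", index=False)
        forest.to_csv(d / "forest.tsv", sep="\t", index=False)

    @_stage("tags")
    def _tags():
        freq, table, flags = state["freq"], state["assoc"], state["flags"]
        eligible = [f.id for f in flags if f.id in freq.variant_ids]
        corr_all = ldtags.pool_correlation(
            freq, [v for v, m in zip(freq.variant_ids, freq.mac)
                   if m >= config.mac_min])
        blocks = ldtags.cluster_blocks(corr_all, n_blocks=config.n_blocks)
        prio = {r["id"]: -np.log10(max(r["p_nominal"], 1e-300))
                for _, r in table.table.iterrows()}
        cand = [(v, prio.get(v, 0.0)) for v in eligible
                if v in corr_all.variant_ids]
        tagset = ldtags.select_tags(corr_all, cand, r2_max=config.r2_max)
        tagset.risk_alleles = {f.id: f.risk_allele for f in flags
                               if f.id in tagset.tags}
        state.update(corr=corr_all, blocks=blocks, tags=tagset)
        d = out / "tags"
        d.mkdir(exist_ok=True)
        blocks.to_csv(d / "blocks.tsv", sep="\t")
        present = [v for v in eligible if v in corr_all.variant_ids]
        corr_all.r.loc[present, present].to_csv(
            d / "flag_correlation.tsv", sep="\t")
        (d / "tagset.json").write_text(json.dumps(
            {"tags": tagset.tags, "r2_max": tagset.r2_max,
             "representatives": tagset.representatives,
             "risk_alleles": tagset.risk_alleles}, indent=2))

    @_stage("permtest")
    def _permtest():
        res = riskperm.depletion_permutation_test(
            state["freq"], state["design"], state["tags"],
            n_perm=config.n_perm_depletion, seed=config.seed)
        state["permtest"] = res
        d = out / "permtest"
        d.mkdir(exist_ok=True)
        (d / "depletion.json").write_text(
            json.dumps(res.to_json_dict(), indent=2))

    @_stage("pca")
    def _pca():
        freq, design = state["freq"], state["design"]
        pca = multivar.pca_pools(freq, mac_min=config.mac_min,
                                 n_components=config.pca_components)
        screen = multivar.screen_components(
            pca, design, n_components=config.screen_components,
            alpha=config.alpha)
        clf = multivar.classify_pools(pca, design,
                                      components=config.classifier_components,
                                      n_perm=config.n_perm_classifier,
                                      seed=config.seed)
        pattern = multivar.find_separating_components(
            pca, freq, design, state["flags"],
            n_components=config.pca_components,
            n_perm=config.n_perm_classifier, seed=config.seed)
        sets = {}
        for c in config.classifier_components:
            imp = multivar.pc_feature_importance(pca, c,
                                                 top_k=config.top_k_importance)
            sets[f"PC{c}"] = imp.loc[imp["selected"], "id"].tolist()
        corr = multivar.importance_risk_correlation(freq, sets, state["flags"])
        state.update(pca=pca, screen=screen, classifier=clf, imp_corr=corr,
                     pattern=pattern)
        d = out / "pca"
        d.mkdir(exist_ok=True)
        np.savetxt(d / "scores.tsv", pca.scores, delimiter="\t")
        screen.to_csv(d / "screen.tsv", sep="\t", index=False)
        corr.to_csv(d / "importance_risk_correlation.tsv", sep="\t",
                    index=False)
        (d / "classifier.json").write_text(
            json.dumps(clf.to_json_dict(), indent=2))
        (d / "pattern.json").write_text(json.dumps({
            "found": bool(pattern.found),
            "positive_pc": pattern.positive_pc,
            "negative_pc": pattern.negative_pc,
            "p_positive": pattern.p_positive,
            "p_negative": pattern.p_negative,
            "corr_positive": pattern.corr_positive,
            "corr_negative": pattern.corr_negative,
            "classifier": (pattern.classifier.to_json_dict()
                           if pattern.classifier else None)}, indent=2))

    @_stage("kernel")
    def _kernel():
        freq, design = state["freq"], state["design"]
        bed = kerneltest.load_regions_bed(config.regions_bed)
        variants = state.get("variants") or _variants_from_vcf(config.vcf)
        members = kerneltest.region_variants(
            bed, [v for v in variants if v.id in set(freq.variant_ids)])
        table = kerneltest.region_scan(freq, design, members,
                                       mac_min=config.mac_min,
                                       weights_beta=config.weights_beta,
                                       n_perm=config.n_perm_burden,
                                       seed=config.seed)
        state["kernel"] = table
        d = out / "kernel"
        d.mkdir(exist_ok=True)
        table.to_csv(d / "region_tests.tsv", sep="\t", index=False)

    manifest["state_keys"] = sorted(state.keys())
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True))
    state["manifest"] = manifest
    return state


def _variants_from_vcf(path: str) -> list[simcohort.VariantRecord]:
    import pysam

    out = []
    for rec in pysam.VariantFile(path):
        for ai, alt in enumerate(rec.alts or ()):
            rid = rec.id or f"{rec.chrom}:{rec.pos}"
            if len(rec.alts) > 1:
                rid = f"{rid}_{ai + 1}"
            vclass = "SNP" if len(rec.ref) == 1 and len(alt) == 1 else "complex"
            out.append(simcohort.VariantRecord(
                id=rid, position=rec.pos - 1, ref=rec.ref, alt=alt,
                true_af=0.0, vclass=vclass))
    return out


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------


@click.group()
@click.option("--log-level", default="INFO")
def cli(log_level: str) -> None:
    """Pooled-sequencing regional case-control analysis."""
    logging.basicConfig(level=getattr(logging, log_level.upper(), "INFO"),
                        format="%(levelname)s %(name)s: %(message)s")


@cli.command()
@click.option("--seed", type=int, default=0)
@click.option("--out", "outdir", type=click.Path(), required=True)
@click.option("--n-variants", type=int, default=2000)
def simulate(seed: int, outdir: str, n_variants: int) -> None:
    """Generate a synthetic pooled study (VCF, design, BED, id lists)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    sc = simcohort.default_scenario(seed=seed, n_variants=n_variants)
    simcohort.write_vcf(sc.counts, sc.panel.variants, sc.region,
                        str(out / "pools.vcf"))
    simcohort.write_pool_design(sc.design, str(out / "design.tsv"))
    simcohort.write_ground_truth(sc.panel, str(out / "truth.tsv"))
    simcohort.write_flag_snps(sc.flags, str(out / "flags.tsv"))
    simcohort.write_known_ids(sc.known_ids, str(out / "known_ids.tsv"))
    simcohort.write_regions_bed(sc.region, str(out / "regions.bed"))
    cfg = RunConfig(vcf=str(out / "pools.vcf"), design=str(out / "design.tsv"),
                    regions_bed=str(out / "regions.bed"),
                    known_ids=str(out / "known_ids.tsv"),
                    flag_snps=str(out / "flags.tsv"), seed=seed)
    cfg.to_yaml(str(out / "config.yaml"))
    click.echo(f"synthetic study written to {out}")


@cli.command("run-all")
@click.option("--config", "config_path", type=click.Path(exists=True),
              required=True)
@click.option("--out", "outdir", type=click.Path(), required=True)
@click.option("--seed", type=int, default=None)
def run_all(config_path: str, outdir: str, seed: int | None) -> None:
    """Run every configured stage."""
    cfg = RunConfig.from_yaml(config_path)
    if seed is not None:
        cfg = dataclasses.replace(cfg, seed=seed)
    state = run_pipeline(cfg, outdir)
    perm = state.get("permtest")
    if perm is not None:
        click.echo(f"combined depletion T = {perm.observed:.3f}, "
                   f"p = {perm.p_empirical:.5g}")
    click.echo(f"outputs in {outdir}")


def _single_stage(stage: str):
    @cli.command(stage)
    @click.option("--config", "config_path", type=click.Path(exists=True),
                  required=True)
    @click.option("--out", "outdir", type=click.Path(), required=True)
    def _cmd(config_path: str, outdir: str, _stage=stage) -> None:
        cfg = RunConfig.from_yaml(config_path)
        need = {"summarize": ("summarize",),
                "assoc": ("assoc",),
                "tags": ("assoc", "tags"),
                "permtest": ("assoc", "tags", "permtest"),
                "pca": ("assoc", "pca"),
                "kernel": ("summarize", "kernel")}[_stage]
        cfg = dataclasses.replace(cfg, stages=need)
        run_pipeline(cfg, outdir)
        click.echo(f"stage {_stage} outputs in {outdir}")
    return _cmd


for _s in ("summarize", "assoc", "tags", "permtest", "pca", "kernel"):
    _single_stage(_s)
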