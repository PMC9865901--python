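"""End-to-end orchestration: simulate/ingest -> genotype -> score ->
PCA -> cluster -> contrasts -> haplotypes -> report.

A single :class:`RunConfig` (YAML-loadable) drives every stage; all
intermediate artifacts are written deterministically under the output
directory with the config hash in a header comment, and a
machine-readable JSON report plus a human-readable summary are emitted.
Identical config + seed give identical reports.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import contrasts, genotype, haplotypes, mutations, pca, scoring, synthetic
from .errors import PyramidkitError

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    out_dir: str = "pyramidkit_run"
    seed: int = synthetic.DEFAULT_SEED
    # input paths; when None the corresponding data are simulated
    bins_path: str | None = None
    phenotypes_path: str | None = None
    loci_path: str | None = None
    vcf_path: str | None = None
    metadata_path: str | None = None
    # analysis parameters
    k_genes: int = 8
    n_groups: int = 3
    alpha: float = 0.05
    min_count: int = 10
    trait: str = "gnpp"
    qtn_pair: tuple[str, str] = ("LAX1", "GNP1")
    sim: synthetic.SimConfig = field(default_factory=synthetic.SimConfig)
    panel: synthetic.PanelConfig = field(default_factory=synthetic.PanelConfig)

    def config_hash(self) -> str:
        payload = asdict(self)
        payload.pop("out_dir")  # where outputs land is not part of the analysis
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def load_run_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sim = synthetic.SimConfig(**raw.pop("sim", {}))
    panel = synthetic.PanelConfig(**raw.pop("panel", {}))
    if "qtn_pair" in raw:
        raw["qtn_pair"] = tuple(raw["qtn_pair"])
    return RunConfig(sim=sim, panel=panel, **raw)


def run_pipeline(config: RunConfig) -> dict:
    """Execute every analysis stage in order and write a run report.

    Stages: (1) obtain bin matrix, loci and phenotypes (simulated when
    no paths are given, reseeded from ``config.seed``); (2) resolve
    per-gene parental origins and consanguinity; (3) build score cards
    and the assigned score matrix; (4) PCA and key-gene selection;
    (5) hierarchical L/M/H grouping and superior-genotype frequencies;
    (6) single- and two-locus QTN contrasts; (7) variety-panel
    haplotype analysis with per-gene summaries, composition tables and
    superior-haplotype calls.
    """
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tag = f"config_hash: {config.config_hash()}"
    report: dict = {"config_hash": config.config_hash(), "seed": config.seed,
                    "stages": {}}

    def stage(name):
        logger.info("stage %s (t=%.1fs)", name, time.time() - t0)

    try:
        # -- stage 1: inputs -------------------------------------------------
        stage("inputs")
        sim = config.sim
        if config.bins_path:
            bins = genotype.read_bin_matrix(config.bins_path)
        else:
            sim = synthetic.SimConfig(**{**asdict(sim), "seed": config.seed})
            bins = synthetic.simulate_bin_matrix(sim)
            genotype.write_bin_matrix(bins, out / "bins.tsv", tag)
        if config.loci_path:
            loci = genotype.read_loci(config.loci_path)
        else:
            loci = synthetic.default_loci(sim)
            genotype.write_loci(loci, out / "loci.tsv", tag)
        if config.phenotypes_path:
            pheno = synthetic.read_phenotypes(config.phenotypes_path)
        else:
            pheno = synthetic.simulate_phenotypes(bins, loci, sim)
            synthetic.write_phenotypes(pheno, out / "phenotypes.csv", tag)
        report["stages"]["inputs"] = {
            "n_lines": bins.n_lines, "n_bins": len(bins.bins),
            "n_loci": len(loci), "n_environments": pheno.shape[1],
        }

        # -- stage 2: genotypes ---------------------------------------------
        stage("genotype")
        geno = genotype.genotype_table(bins, loci)
        with open(out / "genotypes.tsv", "w") as fh:
            fh.write(f"# {tag}\n")
            g = geno.copy()
            g.insert(0, "line_id", g.index)
            g.to_csv(fh, sep="\t", index=False)
        blood = pd.DataFrame({
            "consanguinity_F": genotype.consanguinity_rate(bins, "F"),
            "consanguinity_M": genotype.consanguinity_rate(bins, "M"),
        })
        report["stages"]["genotype"] = {
            "n_genes": geno.shape[1],
            "mean_consanguinity_F": round(float(blood["consanguinity_F"].mean()), 4),
        }

        # -- stage 3: scoring -----------------------------------------------
        stage("scoring")
        cards = {g: scoring.build_score_card(g, pheno, geno[g]) for g in geno.columns}
        matrix = scoring.assign_scores(cards, geno)
        scoring.write_score_cards(cards, out / "score_cards.tsv", tag)
        scoring.write_score_matrix(matrix, out / "score_matrix.tsv", tag)
        report["stages"]["scoring"] = {
            "n_cards": len(cards),
            "missing_cells": int(matrix.values.isna().sum().sum()),
        }

        # -- stage 4: PCA / key genes ----------------------------------------
        stage("pca")
        pca_res = pca.run_pca(matrix)
        selection = pca.select_key_genes(pca_res, k=config.k_genes)
        for name, frame in (("pca_loadings", pca_res.loadings),
                            ("pca_scores", pca_res.scores)):
            with open(out / f"{name}.tsv", "w") as fh:
                fh.write(f"# {tag}\n")
                frame.to_csv(fh, sep="\t")
        report["stages"]["pca"] = {
            "explained_variance_ratio": [round(float(v), 4)
                                         for v in pca_res.explained_variance_ratio[:4]],
            "selected_genes": selection.ranked,
            "pc1_max": selection.pc1_max,
            "pc2_min": selection.pc2_min,
        }

        # -- stage 5: phenotype groups ---------------------------------------
        stage("grouping")
        grouping = pca.cluster_phenotype_groups(pheno, k=config.n_groups)
        with open(out / "groups.tsv", "w") as fh:
            fh.write(f"# {tag}\n")
            g = grouping.assignments.to_frame()
            g.insert(0, "line_id", g.index)
            g.to_csv(fh, sep="\t", index=False)
        superior = {g: ("F" if cards[g].score_f >= cards[g].score_m else "M")
                    for g in geno.columns}
        freqs = pca.group_frequency_table(grouping, geno, superior)
        with open(out / "group_frequencies.tsv", "w") as fh:
            fh.write(f"# {tag}\n")
            freqs.to_csv(fh, sep="\t")
        report["stages"]["grouping"] = {
            "group_sizes": {k: int(v) for k, v in grouping.group_sizes.items()},
            "group_means": {k: round(float(v), 2)
                            for k, v in grouping.group_means.items()},
        }

        # -- stage 6: QTN contrasts ------------------------------------------
        stage("contrasts")
        gene_a, gene_b = config.qtn_pair
        trait_mean = pheno.mean(axis=1)
        contrast_report = {}
        if gene_a in geno.columns and gene_b in geno.columns:
            single = contrasts.contrast_single_locus(trait_mean, geno[gene_a],
                                                     alpha=config.alpha)
            double = contrasts.contrast_two_locus(trait_mean, geno[gene_a],
                                                  geno[gene_b], alpha=config.alpha)
            contrasts.write_contrast(single, out / f"contrast_{gene_a}.tsv",
                                     out / f"contrast_{gene_a}_pvalues.tsv", tag)
            contrasts.write_contrast(double, out / f"contrast_{gene_a}_{gene_b}.tsv",
                                     out / f"contrast_{gene_a}_{gene_b}_pvalues.tsv", tag)
            contrast_report = {
                "single_locus_letters": single.letters,
                "best_combination": double.best_group,
                "combination_letters": double.letters,
            }
        report["stages"]["contrasts"] = contrast_report

        # -- stage 7: haplotype panel ----------------------------------------
        stage("haplotypes")
        panel_cfg = config.panel
        if config.vcf_path and config.metadata_path:
            vcf_path = config.vcf_path
            meta = haplotypes.validate_metadata(synthetic.read_metadata(config.metadata_path))
            panel_loci = genotype.read_loci(config.loci_path) if config.loci_path else []
            panel_loci = [l for l in panel_loci if l.gene in dict.fromkeys([gene_a, gene_b])] \
                or panel_loci
        else:
            panel_cfg = synthetic.PanelConfig(**{**asdict(panel_cfg), "seed": config.seed + 7})
            sim_panel = synthetic.simulate_variety_panel(panel_cfg, out / "panel.vcf")
            vcf_path = sim_panel.vcf_path
            meta = sim_panel.metadata
            panel_loci = sim_panel.loci
            synthetic.write_metadata(meta, out / "panel_metadata.tsv", tag)
        panels = {}
        hap_report = {}
        for locus in panel_loci:
            haps = haplotypes.call_haplotypes(vcf_path, locus, min_count=config.min_count)
            panels[locus.gene] = haps
            summary = haplotypes.haplotype_trait_summary(haps, meta, trait=config.trait,
                                                         alpha=config.alpha)
            best = haplotypes.superior_haplotype(summary)
            sub, ori = haplotypes.composition_tables(haps, meta)
            with open(out / f"haplotype_summary_{locus.gene}.tsv", "w") as fh:
                fh.write(f"# {tag}\n")
                summary.table.to_csv(fh, sep="\t")
            with open(out / f"haplotype_subpop_{locus.gene}.tsv", "w") as fh:
                fh.write(f"# {tag}\n")
                sub.to_csv(fh, sep="\t")
            hap_report[locus.gene] = {
                "n_haplotypes": len(haps.retained),
                "counts": {k: int(v) for k, v in haps.counts.items()},
                "rare": haps.rare_count,
                "superior": best,
            }
        haplotypes.write_assignments(panels, out / "haplotype_assignments.tsv", tag)
        if len(panels) >= 2:
            g1, g2 = list(panels)[:2]
            s1 = hap_report[g1]["superior"]
            s2 = hap_report[g2]["superior"]
            if s1 and s2:
                _, n_co = haplotypes.co_occurrence(panels[g1], panels[g2], s1, s2)
                hap_report["co_occurrence"] = {
                    "genes": [g1, g2], "haplotypes": [s1, s2], "count": n_co,
                }
        report["stages"]["haplotypes"] = hap_report
    except PyramidkitError as exc:
        raise PyramidkitError(f"pipeline aborted: {exc}") from exc

    report["runtime_s"] = round(time.time() - t0, 2)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    _write_summary(report, out / "summary.txt")
    return report


def _write_summary(report: dict, path) -> None:
    s = report["stages"]
    lines = [
        f"pyramidkit run (config {report['config_hash']}, seed {report['seed']})",
        f"lines: {s['inputs']['n_lines']}, bins: {s['inputs']['n_bins']}, "
        f"environments: {s['inputs']['n_environments']}",
        f"selected key genes: {', '.join(s['pca']['selected_genes'])}",
        f"PC1 max loading: {s['pca']['pc1_max']}; PC2 min loading: {s['pca']['pc2_min']}",
        f"phenotype groups (n): {s['grouping']['group_sizes']}",
    ]
    if s.get("contrasts"):
        lines.append(f"best QTN combination: {s['contrasts'].get('best_combination')}")
    for gene, info in s.get("haplotypes", {}).items():
        if gene == "co_occurrence":
            lines.append(
                f"co-occurrence {info['haplotypes'][0]}+{info['haplotypes'][1]} "
                f"({info['genes'][0]}/{info['genes'][1]}): {info['count']} varieties"
            )
        else:
            lines.append(f"{gene}: {info['n_haplotypes']} haplotypes, "
                         f"superior {info['superior']}")
    Path(path).write_text("\n".join(lines) + "\n")
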