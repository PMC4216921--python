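"""End-to-end orchestration: configuration, stage execution, manifest.

A single YAML config drives the run. Inputs come either from a ``simulate``
block (the synthetic generator) or from an ``inputs`` block naming on-disk
files. Each requested stage writes TSV outputs (with a '#' metadata line)
into the output directory; a ``manifest.json`` records the config hash, the
seed, package version, and which stages ran. Identical configs produce
byte-identical numeric outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .background import background_distributions, compare_observed_to_background
from .context import chromatin_association, colocalization_test
from .core import (
    CountMatrix,
    read_bed,
    read_cds_fasta,
    read_counts,
    read_trna_annotation,
    write_cds_fasta,
    write_counts,
    write_trna_annotation,
    write_tsv,
)
from .expression import call_expressed_trnas, de_test, normalize_counts, spearman_pca
from .families import (
    cluster_randomization_test,
    compensation_screen,
    compensation_vs_clustering,
    define_clusters,
)
from .simulate import SimConfig, generate_chromatin_marks, generate_counts, generate_genome
from .usage import (
    anticodon_abundance,
    codon_count_matrix,
    interface_correlation,
    weighted_usage,
)
from .wobble import (
    assign_wobble_decoders,
    find_orphan_codons,
    wobble_corrected_correlation,
)

logger = logging.getLogger("codonbalance")

ALL_STAGES = ("simulate", "expression", "de", "pca", "usage", "background",
              "wobble", "compensation", "clusters", "coloc", "chromatin")


def setup_logging(level: str = "INFO", logfile: str | Path | None = None) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler()]
    if logfile is not None:
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(level=getattr(logging, level.upper()),
                        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
                        handlers=handlers, force=True)


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping")
    return cfg


def _config_hash(cfg: Mapping[str, Any]) -> str:
    canonical = yaml.safe_dump(cfg, sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()


def run_pipeline(config: Mapping[str, Any] | str | Path,
                 out_dir: str | Path | None = None) -> Path:
    """Execute the analysis described by ``config``; returns the output dir."""
    if not isinstance(config, Mapping):
        config = load_config(config)
    cfg = dict(config)
    out = Path(out_dir or cfg.get("out", "codonbalance_out"))
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    thresholds = dict(cfg.get("thresholds", {}))
    min_reads = int(thresholds.get("min_reads", 10))
    de_alpha = float(thresholds.get("de_alpha", 0.001))
    bg_reps = int(thresholds.get("background_reps", 100))
    gap_kb = float(thresholds.get("cluster_gap_kb", 7.5))
    coloc_alphas = list(thresholds.get("coloc_alphas", [0.1, 0.05, 0.01]))
    windows_kb = list(thresholds.get("coloc_windows_kb", [10.0, 50.0, 100.0]))
    mark_distances = list(thresholds.get("chromatin_distances_kb", [0.1, 0.5, 1.0]))

    requested = list(cfg.get("run", ALL_STAGES))
    bad = [s for s in requested if s not in ALL_STAGES]
    if bad:
        raise ValueError(f"unknown pipeline stage(s) {bad}; valid: {ALL_STAGES}")

    # ------------------------------------------------------------------ inputs
    marks: dict[str, pd.DataFrame] = {}
    truth = None
    if "simulate" in cfg:
        sim_kwargs = dict(cfg["simulate"] or {})
        for key in ("tissues", "stages", "compensated_families"):
            if key in sim_kwargs:
                sim_kwargs[key] = tuple(sim_kwargs[key])
        sim_kwargs.setdefault("seed", seed)
        sim = SimConfig(**sim_kwargs)
        genome = generate_genome(sim)
        mrna, trna, truth = generate_counts(sim, genome)
        transcripts, trna_genes = genome.transcripts, genome.trna_genes
        pc_coords = genome.pc_coords
        stage_order = list(sim.stages)
        tissues = list(sim.tissues)
        if "simulate" in requested:
            write_cds_fasta(out / "cds.fa", transcripts)
            write_trna_annotation(out / "trna.bed", trna_genes)
            write_counts(out / "mrna_counts.tsv", mrna, meta=f"seed={sim.seed}")
            write_counts(out / "trna_counts.tsv", trna, meta=f"seed={sim.seed}")
            truth.mrna_mean.round(6).to_csv(out / "truth_mrna_mean.tsv", sep="\t")
            truth.trna_mean.round(6).to_csv(out / "truth_trna_mean.tsv", sep="\t")
            with open(out / "config_echo.yaml", "w") as fh:
                yaml.safe_dump({"simulate": asdict(sim)}, fh, sort_keys=True)
    elif "inputs" in cfg:
        inputs = cfg["inputs"]
        stage_order = list(cfg.get("stage_order") or [])
        if not stage_order:
            raise ValueError("stage_order is required when reading inputs")
        transcripts = read_cds_fasta(inputs["cds_fasta"])
        trna_genes = read_trna_annotation(inputs["trna_annotation"])
        mrna = read_counts(inputs["mrna_counts"], stage_order)
        trna = read_counts(inputs["trna_counts"], stage_order)
        tissues = sorted({s.tissue for s in mrna.samples})
        pc_coords = None
        if "pc_coords" in inputs:
            pc_coords = pd.read_csv(inputs["pc_coords"], sep="\t", comment="#")
        for mark, path in (inputs.get("marks") or {}).items():
            marks[mark] = read_bed(path)
    else:
        raise ValueError("config needs a 'simulate' or an 'inputs' block")

    if "simulate" in cfg and cfg.get("simulate_marks", False):
        # marks enriched near active tRNA genes (mirrors the active-vs-inactive
        # chromatin comparison)
        active_truth = [g.gene_id for g in trna_genes
                        if g.gene_id not in truth.inactive_trnas]
        marks["synthetic_mark"] = generate_chromatin_marks(
            trna_genes, enriched_ids=active_truth, seed=seed + 17)

    manifest_stages: dict[str, str] = {}

    # --------------------------------------------------------- expression call
    expressed = call_expressed_trnas(trna, min_reads=min_reads)
    trna_expr_cm = trna.subset_genes(sorted(expressed)) if expressed else trna
    mrna_norm = normalize_counts(mrna)
    trna_norm = normalize_counts(trna_expr_cm)
    non_sec = {g.gene_id for g in trna_genes if not g.is_selenocysteine}
    if "expression" in requested:
        write_tsv(out / "expressed_trnas.tsv",
                  pd.DataFrame({"gene_id": sorted(expressed)}),
                  meta=f"min_reads={min_reads}; {len(expressed)}/{len(trna.genes)} expressed")
        write_tsv(out / "size_factors.tsv", pd.DataFrame({
            "sample": [s.label for s in mrna.samples],
            "mrna_size_factor": np.round(mrna_norm.size_factors, 6),
            "trna_size_factor": np.round(trna_norm.size_factors, 6)}))
        manifest_stages["expression"] = "ok"

    # ------------------------------------------------------------------- DE
    de_tables: dict[str, list] = {"mrna": [], "trna": []}
    if {"de", "coloc"} & set(requested):
        for label, cm in (("mrna", mrna), ("trna", trna_expr_cm)):
            for tissue in tissues:
                for i, sa in enumerate(stage_order):
                    for sb in stage_order[i + 1:]:
                        if (tissue, sa) not in cm.condition_columns():
                            continue
                        results = de_test(cm, (tissue, sa), (tissue, sb),
                                          alpha=de_alpha)
                        de_tables[label].extend(results)
        if "de" in requested:
            for label, results in de_tables.items():
                df = pd.DataFrame([{
                    "gene_id": r.gene_id, "tissue": r.stage_pair[2],
                    "stage_a": r.stage_pair[0], "stage_b": r.stage_pair[1],
                    "log2_fold_change": round(r.log2_fold_change, 6),
                    "p_value": r.p_value, "p_adjusted": r.p_adjusted,
                    "significant": r.significant} for r in results])
                write_tsv(out / f"de_{label}.tsv", df,
                          meta=f"NB Wald stand-in; BH alpha={de_alpha}")
            manifest_stages["de"] = "ok"

    # ------------------------------------------------------------------- PCA
    if "pca" in requested:
        for label, em in (("mrna", mrna_norm), ("trna", trna_norm)):
            pca = spearman_pca(em)
            df = pd.DataFrame(pca.components[:, :5].round(6),
                              columns=[f"PC{k + 1}" for k in range(min(5, pca.components.shape[1]))])
            df.insert(0, "sample", [s.label for s in pca.samples])
            write_tsv(out / f"pca_{label}_scores.tsv", df)
            write_tsv(out / f"pca_{label}_variance.tsv", pd.DataFrame({
                "component": np.arange(1, len(pca.variance_fraction) + 1),
                "variance_fraction": pca.variance_fraction.round(6),
                "variance_fraction_of_remaining":
                    pca.variance_fraction_of_remaining.round(6)}))
        manifest_stages["pca"] = "ok"

    # ------------------------------------------------- usage and correlations
    tables = codon_count_matrix(transcripts)
    need_usage = {"usage", "background", "wobble"} & set(requested)
    usage_rows, profiles = [], {}
    if need_usage:
        for tissue in tissues:
            for stage in stage_order:
                if (tissue, stage) not in mrna.condition_columns():
                    continue
                m_expr = mrna_norm.sample_values(tissue, stage)
                t_expr = trna_norm.sample_values(tissue, stage)
                t_expr = t_expr[t_expr.index.isin(non_sec)]
                codon_u = weighted_usage(tables, m_expr, level="codon").normalize()
                aa_u = weighted_usage(tables, m_expr, level="amino_acid").normalize()
                anti_u = anticodon_abundance(t_expr, trna_genes, level="anticodon")
                iso_u = anticodon_abundance(t_expr, trna_genes, level="isotype")
                profiles[(tissue, stage)] = (codon_u, aa_u, anti_u, iso_u, m_expr, t_expr)
                for level, (pu, pa) in (("codon", (codon_u, anti_u)),
                                        ("amino_acid", (aa_u, iso_u))):
                    pairing = None if level == "codon" else {
                        k: k for k in pu.keys if k in set(pa.keys)}
                    rho, p, n = interface_correlation(pu, pa, pairing=pairing)
                    usage_rows.append({"tissue": tissue, "stage": stage,
                                       "level": level, "rho": round(rho, 6),
                                       "p": p, "n_pairs": n})
        if "usage" in requested:
            prof_rows = []
            for (tissue, stage), (codon_u, aa_u, anti_u, iso_u, _, _) in profiles.items():
                for prof in (codon_u, aa_u, anti_u, iso_u):
                    for k, v in zip(prof.keys, prof.values):
                        prof_rows.append({"tissue": tissue, "stage": stage,
                                          "kind": prof.kind, "key": k,
                                          "relative_usage": round(float(v), 9)})
            write_tsv(out / "usage_profiles.tsv", pd.DataFrame(prof_rows))
            write_tsv(out / "interface_correlations.tsv", pd.DataFrame(usage_rows))
            manifest_stages["usage"] = "ok"

    # ------------------------------------------------------------ backgrounds
    if "background" in requested and profiles:
        bg_rows = []
        for i, ((tissue, stage), (codon_u, _, anti_u, _, m_expr, t_expr)) \
                in enumerate(sorted(profiles.items())):
            summary = background_distributions(
                tables, m_expr, t_expr, trna_genes, universe="expressed",
                n_reps=bg_reps, seed=seed + 100 + i)
            rho, _, _ = interface_correlation(codon_u, anti_u)
            cmp_ = compare_observed_to_background(rho, summary.correlations)
            bg_rows.append({"tissue": tissue, "stage": stage,
                            "observed_rho": round(cmp_.observed_rho, 6),
                            "background_mean": round(cmp_.background_mean, 6),
                            "background_max": round(cmp_.background_max, 6),
                            "background_sd": round(cmp_.background_sd, 6),
                            "exceedance": round(cmp_.exceedance, 6),
                            "n_reps": bg_reps})
        write_tsv(out / "background_correlations.tsv", pd.DataFrame(bg_rows),
                  meta=f"expressed-mode shuffles, n_reps={bg_reps}")
        manifest_stages["background"] = "ok"

    # ------------------------------------------------------------------ wobble
    if "wobble" in requested and profiles:
        encoded = sorted({g.family_id for g in trna_genes
                          if not g.is_selenocysteine})
        orphans = find_orphan_codons(None, encoded)
        dmap = assign_wobble_decoders(orphans, encoded)
        write_tsv(out / "decoding_map.tsv", pd.DataFrame(
            [{"codon": c, "family": f} for c, f in sorted(dmap.codon_to_family.items())]),
            meta=f"{len(orphans)} orphan codons; {len(dmap.unmatchable)} unmatchable")
        wob_rows = []
        for (tissue, stage), (codon_u, _, anti_u, _, _, _) in sorted(profiles.items()):
            rho_u, p_u, n_u = interface_correlation(codon_u, anti_u)
            rho_c, p_c, n_c = wobble_corrected_correlation(codon_u, anti_u)
            wob_rows.append({"tissue": tissue, "stage": stage,
                             "rho_uncorrected": round(rho_u, 6),
                             "rho_corrected": round(rho_c, 6),
                             "p_corrected": p_c, "n_codons": n_c})
        write_tsv(out / "wobble_correlations.tsv", pd.DataFrame(wob_rows))
        manifest_stages["wobble"] = "ok"

    # ------------------------------------------------------------ compensation
    screen = None
    if {"compensation", "clusters"} & set(requested):
        fam_of = {g.gene_id: g.family_id for g in trna_genes
                  if not g.is_selenocysteine}
        tissue0 = tissues[0]
        fam_expr: dict[str, pd.DataFrame] = {}
        stage_means = pd.DataFrame(
            {stage: trna_norm.sample_values(tissue0, stage)
             for stage in stage_order if (tissue0, stage) in trna.condition_columns()})
        for fam in sorted(set(fam_of.values())):
            members = [g for g in stage_means.index if fam_of.get(g) == fam]
            if len(members) > 2:
                fam_expr[fam] = stage_means.loc[members]
        screen = compensation_screen(fam_expr, seed=seed + 7)
        if "compensation" in requested:
            rows = [{"family_id": r.family_id, "n_genes": r.n_genes,
                     "chi2": round(r.chi2_stat, 4), "p_raw": r.p_raw,
                     "p_corrected": r.p_corrected, "significant": r.significant,
                     "bimodality": round(r.bimodality, 4)}
                    for r in screen.reported]
            write_tsv(out / "compensation.tsv", pd.DataFrame(rows),
                      meta=f"tissue={tissue0}; Bonferroni over "
                           f"{len(screen.reported)} families with >=6 genes")
            manifest_stages["compensation"] = "ok"

    # ---------------------------------------------------------------- clusters
    if "clusters" in requested:
        non_sec_genes = [g for g in trna_genes if not g.is_selenocysteine]
        clusters = define_clusters(non_sec_genes, gap_kb=gap_kb)
        rand = cluster_randomization_test(non_sec_genes, clusters,
                                          n_rand=int(thresholds.get("n_rand", 1000)),
                                          seed=seed + 11)
        write_tsv(out / "clusters.tsv", pd.DataFrame(
            [{"cluster": i, "n_genes": len(cl), "gene_ids": ",".join(cl)}
             for i, cl in enumerate(clusters.clusters)]),
            meta=f"gap_kb={gap_kb}; {clusters.n_clusters} clusters")
        rows = {"observed_mean_pct": round(rand.observed_mean_pct, 4),
                "null_mean_pct": round(rand.null_mean_pct, 4),
                "empirical_p": rand.empirical_p, "binomial_p": rand.binomial_p,
                "n_colocalized": rand.n_colocalized, "n_genes": rand.n_genes}
        if screen is not None and len(screen.reported) >= 4:
            try:
                chi2, p = compensation_vs_clustering(
                    screen.reported, rand.family_fractions.reindex(
                        [r.family_id for r in screen.reported]).fillna(0.0))
                rows["compensated_vs_not_chi2"] = round(chi2, 4)
                rows["compensated_vs_not_p"] = p
            except ValueError as exc:
                logger.warning("compensation-vs-clustering skipped: %s", exc)
        write_tsv(out / "cluster_randomization.tsv", pd.DataFrame([rows]))
        manifest_stages["clusters"] = "ok"

    # -------------------------------------------------------------- colocaliz.
    if "coloc" in requested:
        if pc_coords is None:
            logger.warning("coloc requested but no protein-coding coordinates")
            manifest_stages["coloc"] = "skipped (no pc coordinates)"
        else:
            tissue0 = tissues[0]
            sa, sb = stage_order[0], stage_order[-1]
            trna_de = [r for r in de_tables["trna"]
                       if r.stage_pair[:2] == (sa, sb) and r.stage_pair[2] == tissue0]
            mrna_de = [r for r in de_tables["mrna"]
                       if r.stage_pair[:2] == (sa, sb) and r.stage_pair[2] == tissue0]
            rows = []
            for alpha in coloc_alphas:
                t_up = {r.gene_id for r in trna_de
                        if r.p_adjusted < alpha and r.log2_fold_change > 0}
                t_non = {r.gene_id for r in trna_de
                         if not (r.p_adjusted < alpha)}
                p_up = {r.gene_id for r in mrna_de
                        if r.p_adjusted < alpha and r.log2_fold_change > 0}
                cells = colocalization_test(t_up, t_non, trna_genes, pc_coords,
                                            p_up, windows_kb=windows_kb)
                for c in cells:
                    rows.append({"tissue": tissue0, "stage_a": sa, "stage_b": sb,
                                 "alpha": alpha, "window_kb": c.window_kb,
                                 "ks_statistic": c.ks_statistic, "ks_p": c.ks_p,
                                 "n_up": c.n_up, "n_nonde": c.n_nonde,
                                 "n_excluded": c.n_excluded})
            write_tsv(out / "colocalization.tsv", pd.DataFrame(rows))
            manifest_stages["coloc"] = "ok"

    # ---------------------------------------------------------------- chromatin
    if "chromatin" in requested:
        if not marks:
            logger.warning("chromatin requested but no mark intervals available")
            manifest_stages["chromatin"] = "skipped (no marks)"
        else:
            inactive = sorted(non_sec - expressed)
            active = sorted(expressed & non_sec)
            if not inactive or not active:
                manifest_stages["chromatin"] = "skipped (need active and inactive sets)"
            else:
                cells = chromatin_association(marks, active, inactive, trna_genes,
                                              distances_kb=mark_distances)
                write_tsv(out / "chromatin_association.tsv", pd.DataFrame(
                    [{"mark": c.mark, "distance_kb": c.distance_kb,
                      "odds_ratio": c.odds_ratio, "p": c.p_value,
                      "a_present": c.table[0][0], "a_absent": c.table[0][1],
                      "b_present": c.table[1][0], "b_absent": c.table[1][1]}
                     for c in cells]),
                    meta="set A = expressed tRNA genes, set B = not expressed")
                manifest_stages["chromatin"] = "ok"

    for stage in ALL_STAGES:
        if stage in requested and stage not in manifest_stages:
            manifest_stages[stage] = "ok" if stage == "simulate" and "simulate" in cfg \
                else manifest_stages.get(stage, "skipped")
    manifest = {
        "config_hash": _config_hash(cfg),
        "seed": seed,
        "version": __version__,
        "stages": manifest_stages,
        "n_expressed_trnas": len(expressed),
        "n_trna_genes": len(trna.genes),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out
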