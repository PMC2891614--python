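"""Enumeration reports and end-to-end pipeline orchestration.

All tabular artifacts are TSV with ``#``-prefixed provenance headers
(package version, seed, configuration hash) so a rerun with the same
configuration and seed produces identical files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import __version__
from .classify import GROUPS, ClassificationConfig, calls_to_frame, classify_genome, sweep_territory_distance

log = logging.getLogger(__name__)

__all__ = ["enumeration_report", "run_pipeline", "write_tsv"]

#: Aggregate rows reported alongside the six groups.
AGGREGATES = {"overlapping": ("5PP", "EE", "5PI_EI"), "co-clustering": ("COS", "CSS")}


def enumeration_report(calls_or_counts) -> pd.DataFrame:
    """Counts and percentages of classified genes per constellation group.

    Accepts either classification calls or a mapping group -> count.
    Percentages are over the non-CONFLICT total, rounded to one decimal;
    aggregate rows for the overlapping (5PP+EE+5PI_EI) and co-clustering
    (COS+CSS) classes are appended.
    """
    if isinstance(calls_or_counts, Mapping):
        counts = {g: int(calls_or_counts.get(g, 0)) for g in GROUPS}
        n_conflict = int(calls_or_counts.get("CONFLICT", 0))
    else:
        counts = {g: 0 for g in GROUPS}
        n_conflict = 0
        for call in calls_or_counts:
            if call.group == "CONFLICT":
                n_conflict += 1
            else:
                counts[call.group] += 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no classified genes")
    rows = [
        {"group": g, "count": counts[g], "percent": round(100.0 * counts[g] / total, 1)}
        for g in GROUPS
    ]
    for name, members in AGGREGATES.items():
        agg = sum(counts[m] for m in members)
        rows.append({"group": name, "count": agg, "percent": round(100.0 * agg / total, 1)})
    rows.append({"group": "total", "count": total, "percent": 100.0})
    if n_conflict:
        rows.append({"group": "CONFLICT (excluded)", "count": n_conflict, "percent": float("nan")})
    return pd.DataFrame(rows)


def write_tsv(frame: pd.DataFrame, path: str | Path, seed=None, config: Mapping | None = None,
              index: bool = False) -> None:
    """TSV with a provenance header (version, seed, config hash)."""
    digest = hashlib.sha256(
        json.dumps(config or {}, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]
    with open(path, "w") as fh:
        fh.write(f"# constellation {__version__}\n")
        fh.write(f"# seed: {seed}\n")
        fh.write(f"# config: {digest}\n")
        frame.to_csv(fh, sep="\t", index=index)


def run_pipeline(config: Mapping | str | Path, out_dir: str | Path) -> dict[str, Path]:
    """Run the synthetic end-to-end pipeline described by a config mapping.

    The config selects stages; missing optional sections skip the dependent
    stages with a log message rather than failing.  Recognised sections:

    - ``genome``: quotas / promoter_len / territory_dist / distances
    - ``go``: toy-ontology sizes for similarity and enrichment
    - ``expression``: planted-correlation and population-structure settings
    - ``haplotypes``: coalescent settings for diversity statistics
    - ``regression``: planted standardized coefficients
    - ``seed``: top-level seed fanned out to every stage
    """
    if isinstance(config, (str, Path)):
        import yaml

        with open(config) as fh:
            config = yaml.safe_load(fh)
    config = dict(config)
    seed = int(config.get("seed", 0))
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    from . import cohort_stats, evo_stats, go_semantics, synthetic_data

    genome_cfg = config.get("genome")
    if genome_cfg is None:
        log.info("no genome section; classification stages skipped")
    else:
        territory = int(genome_cfg.get("territory_dist", 20000))
        if territory < 0:
            raise ValueError("territory_dist must be >= 0")
        sim = synthetic_data.simulate_genome(
            quotas=genome_cfg.get("quotas", {"SG": 20, "5PP": 20, "EE": 10, "5PI_EI": 10, "COS": 20, "CSS": 10}),
            promoter_len=int(genome_cfg.get("promoter_len", 1000)),
            territory_dist=territory,
            seed=seed,
        )
        sim.write(out_dir)
        calls = classify_genome(sim.genes, sim.config, sim.chrom_lengths)
        frame = calls_to_frame(calls)
        frame["true_group"] = frame["gene_id"].map(sim.truth)
        write_tsv(frame, out_dir / "calls.tsv", seed, genome_cfg)
        artifacts["calls"] = out_dir / "calls.tsv"
        log.info("classified %d genes", len(frame))

        sweep = sweep_territory_distance(
            sim.genes, sim.config, genome_cfg.get("distances", [2000, 20000, 100000, 200000]),
            sim.chrom_lengths,
        )
        write_tsv(sweep, out_dir / "sweep.tsv", seed, genome_cfg)
        artifacts["sweep"] = out_dir / "sweep.tsv"

        report = enumeration_report(calls)
        write_tsv(report, out_dir / "enumeration.tsv", seed, genome_cfg)
        artifacts["enumeration"] = out_dir / "enumeration.tsv"

    go_cfg = config.get("go")
    if go_cfg is None:
        log.info("no go section; similarity/enrichment skipped")
    else:
        dag, corpus, truth = synthetic_data.simulate_go(
            n_terms=int(go_cfg.get("n_terms", 40)),
            n_genes=int(go_cfg.get("n_genes", 200)),
            n_planted_pairs=int(go_cfg.get("n_planted_pairs", 10)),
            seed=seed,
        )
        corpus = go_semantics.propagate_annotations(corpus, dag)
        pairs = truth["planted_pairs"]
        rows = []
        for g1, g2 in pairs:
            s = go_semantics.combined_similarity(g1, g2, "rel", "BM", corpus, dag)
            rows.append({"gene_a": g1, "gene_b": g2, "sim_rel_all_bm": s})
        write_tsv(pd.DataFrame(rows), out_dir / "go_similarity.tsv", seed, go_cfg)
        artifacts["go_similarity"] = out_dir / "go_similarity.tsv"

        genes = corpus.genes
        gene_set = [g for pair in pairs for g in pair]
        enrich = go_semantics.functional_enrichment(gene_set, genes, corpus, dag)
        write_tsv(enrich, out_dir / "enrichment.tsv", seed, go_cfg)
        artifacts["enrichment"] = out_dir / "enrichment.tsv"

    hap_cfg = config.get("haplotypes")
    if hap_cfg is None:
        log.info("no haplotypes section; polymorphism statistics skipped")
    else:
        samples, truth = synthetic_data.simulate_haplotypes(
            n_per_pop=tuple(hap_cfg.get("n_per_pop", (10, 40))),
            L=int(hap_cfg.get("L", 1000)),
            theta=float(hap_cfg.get("theta", 0.005)),
            split_depth=float(hap_cfg.get("split_depth", 0.0)),
            seed=seed,
        )
        synthetic_data.write_haplotype_fasta(samples, out_dir / "haplotypes.fasta")
        pooled = evo_stats.HaplotypeSample(
            samples[0].gene_id, "pooled", samples[0].sequences + samples[1].sequences
        )
        stats_ = evo_stats.diversity_stats(pooled)
        fst = evo_stats.fst_hudson(samples[0], samples[1])
        frame = pd.DataFrame(
            [
                {
                    "gene_id": samples[0].gene_id,
                    "theta_w": stats_.theta_w,
                    "theta_pi": stats_.theta_pi,
                    "tajimas_d": stats_.tajimas_d,
                    "S": stats_.s,
                    "fst": fst,
                }
            ]
        )
        write_tsv(frame, out_dir / "polymorphism.tsv", seed, hap_cfg)
        artifacts["polymorphism"] = out_dir / "polymorphism.tsv"

    expr_cfg = config.get("expression")
    if expr_cfg is None:
        log.info("no expression section; expression statistics skipped")
    else:
        sim = synthetic_data.simulate_expression(
            n_genes=int(expr_cfg.get("n_genes", 100)),
            n_samples=int(expr_cfg.get("n_samples", 40)),
            n_planted_pairs=int(expr_cfg.get("n_planted_pairs", 5)),
            planted_r=float(expr_cfg.get("planted_r", 0.8)),
            pop_effect_sd=float(expr_cfg.get("pop_effect_sd", 1.0)),
            strain_sd=float(expr_cfg.get("strain_sd", 1.0)),
            seed=seed,
        )
        corr = evo_stats.expression_correlation(sim.planted_pairs, sim.matrix)
        write_tsv(corr, out_dir / "expression_correlation.tsv", seed, expr_cfg)
        artifacts["expression_correlation"] = out_dir / "expression_correlation.tsv"
        qst_rows = []
        for gene in sim.matrix.index[:50]:
            q = evo_stats.qst(sim.matrix.loc[gene].to_dict(), sim.sample_populations)
            qst_rows.append({"gene_id": gene, "qst": q})
        write_tsv(pd.DataFrame(qst_rows), out_dir / "qst.tsv", seed, expr_cfg)
        artifacts["qst"] = out_dir / "qst.tsv"

    reg_cfg = config.get("regression")
    if reg_cfg is None:
        log.info("no regression section; model fitting skipped")
    else:
        table, truth = synthetic_data.simulate_regression(
            n=int(reg_cfg.get("n", 2000)),
            coefficients=reg_cfg.get("coefficients", {"recomb": 0.25, "const_code": 0.05}),
            seed=seed,
        )
        model = cohort_stats.stepwise_fit(table["y"], table.drop(columns="y"))
        frame = pd.DataFrame(
            [
                {
                    "fitted_model": model.formula("y"),
                    "R": model.r,
                    "p_value": model.p_value,
                    "n": model.n,
                }
            ]
        )
        write_tsv(frame, out_dir / "regression.tsv", seed, reg_cfg)
        artifacts["regression"] = out_dir / "regression.tsv"

    return artifacts
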