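"""End-to-end orchestration: dedup -> detect -> lifestyle -> disseminate ->
MGE -> enrichment -> tree, from one structured config.

The configuration defaults reproduce the screen's quoted thresholds; unknown
keys are rejected so silent typos cannot relax a filter. All randomness
flows from the single ``seed``, and the summary JSON is written with sorted
keys, so a fixed config yields byte-identical output.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import detection, enrichment, lifestyle, mge
from .dissemination import call_dissemination, pseudolysogeny_flag
from .io import write_json, write_tsv
from .records import protein_id, split_protein_id
from .synth import Cohort, CohortConfig, generate_cohort, write_cohort

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All stage thresholds, toggles and keyword lists in one place."""

    seed: int = 42
    outdir: str = "phagescreen_out"
    # detection
    e_max: float = 1e-5
    qcov_min: float = 60.0
    score_min: float = 40.0
    structure_similarity_min: float = 0.2
    reported_id_min: float = 90.0
    reported_qcov_min: float = 85.0
    sensitivity_cutoffs: tuple[float, ...] = (30, 40, 50, 60, 70, 80, 90)
    blacklist_keywords: tuple[str, ...] = ("regulator", "repressor", "mutation")
    # dissemination
    dissemination_id_min: float = 90.0  # strict >
    dissemination_cov_min: float = 90.0  # strict >
    pseudolysogeny_id_min: float = 95.0
    pseudolysogeny_cov_min: float = 95.0
    plasmid_replication_keywords: tuple[str, ...] = (
        "replication initiator",
        "rep protein",
        "plasmid replication",
    )
    # MGE
    is_min_length: int = 150
    is_e_max: float = 1e-30
    is_id_min: float = 40.0  # strict >
    conj_e_max: float = 0.001  # strict <
    conj_cov_min: float = 50.0
    adjacency_max_intervening: int = 5  # strict <
    # stage toggles
    run_dedup: bool = True
    run_detection: bool = True
    run_lifestyle: bool = True
    run_dissemination: bool = True
    run_mge: bool = True
    run_enrichment: bool = True
    run_tree: bool = True
    # synthetic cohort (None -> use default CohortConfig with this seed)
    cohort: dict | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("sensitivity_cutoffs", "blacklist_keywords", "plasmid_replication_keywords"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def cohort_config(self) -> CohortConfig:
        overrides = dict(self.cohort or {})
        overrides.setdefault("seed", self.seed)
        if "genes_per_phage" in overrides:
            overrides["genes_per_phage"] = tuple(overrides["genes_per_phage"])
        if "divergence_levels" in overrides:
            overrides["divergence_levels"] = tuple(overrides["divergence_levels"])
        return CohortConfig(**overrides)


def demo_config(seed: int = 42) -> PipelineConfig:
    """The bundled demo cohort: a 60-phage screen, fully synthetic."""
    return PipelineConfig(seed=seed, cohort={"n_phages": 60, "seed": seed})


@dataclass
class PipelineResult:
    cohort: Cohort
    summary: dict
    tables: dict = field(default_factory=dict)
    candidates: list = field(default_factory=list)


def run_pipeline(
    config: PipelineConfig,
    cohort: Cohort | None = None,
    write: bool = True,
) -> PipelineResult:
    """Run every enabled stage and (optionally) write the report bundle."""
    outdir = Path(config.outdir)
    if write:
        outdir.mkdir(parents=True, exist_ok=True)
    if cohort is None:
        logger.info("generating synthetic cohort")
        cohort = generate_cohort(config.cohort_config())
        if write:
            write_cohort(cohort, outdir / "cohort")
    summary: dict = {"seed": config.seed, "n_phages_input": len(cohort.phages)}
    tables: dict = {}

    phages = cohort.phages
    if config.run_dedup:
        phages = detection.dedup_genomes(phages)
        summary["n_phages_after_dedup"] = len(phages)
    phage_ids = [p.id for p in phages]
    products = cohort.products()
    proteins = {
        pid: seq
        for pid, seq in cohort.proteins.items()
        if split_protein_id(pid)[0] in set(phage_ids)
    }

    candidates = []
    venn = {}
    if config.run_detection:
        logger.info("detection: %d proteins vs %d references", len(proteins), len(cohort.refdb))
        hits_h = detection.channel_homology(
            proteins, cohort.refdb, e_max=config.e_max, qcov_min=config.qcov_min
        )
        hits_d = detection.channel_domain(
            proteins, cohort.profiles, score_min=config.score_min, e_max=config.e_max
        )
        centroids = detection.build_family_centroids(cohort.refdb)
        hits_s = detection.channel_structure(
            proteins, centroids, similarity_min=config.structure_similarity_min
        )
        extra = {
            pid: proteins[pid]
            for pid in (set(hits_d) | set(hits_s)) - set(hits_h)
        }
        best_id = detection.best_identity_vs_refdb(extra, cohort.refdb)
        candidates, venn = detection.merge_channels(
            hits_h, hits_d, hits_s, cohort.refdb, products=products, best_identity=best_id
        )
        candidates = detection.blacklist_filter(candidates, list(config.blacklist_keywords))
        summary["venn"] = venn
        summary["n_candidates"] = len(candidates)
        reported = detection.reported_arg_class(
            candidates, id_min=config.reported_id_min, qcov_min=config.reported_qcov_min
        )
        summary["n_reported_args"] = len(reported)
        summary["reported_arg_ids"] = sorted(c.protein_id for c in reported)

    lifestyle_calls = {}
    if config.run_lifestyle:
        by_phage: dict[str, dict[str, str]] = {}
        for pid, seq in proteins.items():
            phage, _ = split_protein_id(pid)
            by_phage.setdefault(phage, {})[pid] = seq
        lifestyle_calls = lifestyle.classify_cohort(
            phage_ids,
            cohort.predictor_calls,
            by_phage,
            cohort.parab_profiles["parA"],
            cohort.parab_profiles["parB"],
        )
        labels = {p: c.label for p, c in lifestyle_calls.items()}
        summary["lifestyle_counts"] = {
            "lytic": sum(1 for v in labels.values() if v == "lytic"),
            "temperate": sum(1 for v in labels.values() if v == "temperate"),
        }
        if config.run_detection:
            scan = detection.sensitivity_scan(
                candidates, labels, cutoffs=config.sensitivity_cutoffs
            )
            tables["sensitivity_scan"] = scan
            summary["sensitivity_scan"] = scan.to_dict(orient="records")

    if config.run_dissemination and config.run_detection:
        gene_seqs = {
            c.protein_id: cohort.gene_nt[c.protein_id]
            for c in candidates
            if c.protein_id in cohort.gene_nt
        }
        source = dict(
            zip(cohort.pool_meta["replicon_id"], cohort.pool_meta["source"])
        )
        labels = {p: c.label for p, c in lifestyle_calls.items()}
        diss = call_dissemination(
            gene_seqs,
            cohort.pool,
            source,
            lifestyles=labels or None,
            id_min=config.dissemination_id_min,
            cov_min=config.dissemination_cov_min,
        )
        summary["dissemination"] = {
            "n_disseminated": sum(c.disseminated for c in diss.calls),
            "rate_per_lifestyle": diss.rate_per_lifestyle,
            "counts_per_lifestyle": {
                k: list(v) for k, v in diss.counts_per_lifestyle.items()
            },
            "disseminated_gene_ids": sorted(
                c.gene_id for c in diss.calls if c.disseminated
            ),
        }
        rep_type = dict(zip(cohort.pool_meta["replicon_id"], cohort.pool_meta["type"]))
        plasmids = [r for r in cohort.pool if rep_type.get(r.id) == "plasmid"]
        pseudo = sorted(
            r.id
            for r in plasmids
            if pseudolysogeny_flag(
                r,
                phages,
                keywords=tuple(config.plasmid_replication_keywords),
                id_min=config.pseudolysogeny_id_min,
                cov_min=config.pseudolysogeny_cov_min,
            )
        )
        summary["pseudolysogenic_plasmids"] = pseudo

    if config.run_mge and config.run_detection:
        is_hits = mge.detect_is(
            proteins,
            cohort.is_db,
            min_length=config.is_min_length,
            e_max=config.is_e_max,
            id_min=config.is_id_min,
        )
        conj_hits = mge.detect_conjugative(
            proteins,
            cohort.conj_db,
            e_max=config.conj_e_max,
            cov_min=config.conj_cov_min,
        )
        integron_hits = mge.integron_channel(None)
        all_mge = is_hits + conj_hits + integron_hits
        adj = mge.adjacency_table(candidates, all_mge)
        tables["adjacency"] = adj
        summary["mge"] = {
            "n_is_hits": len(is_hits),
            "n_conjugative_hits": len(conj_hits),
            "n_integron_hits": len(integron_hits),
            "n_args_with_adjacent_mge": int(adj["adjacent"].sum()) if len(adj) else 0,
        }

    if config.run_enrichment and config.run_detection and lifestyle_calls:
        labels = {p: c.label for p, c in lifestyle_calls.items()}
        fam_counts: dict[str, tuple[int, int]] = {}
        for c in candidates:
            lab = labels.get(c.phage_id)
            lc, tc = fam_counts.get(c.best_family, (0, 0))
            fam_counts[c.best_family] = (
                lc + (lab == "lytic"),
                tc + (lab == "temperate"),
            )
        lytic_total = sum(v[0] for v in fam_counts.values())
        temp_total = sum(v[1] for v in fam_counts.values())
        if lytic_total and temp_total:
            rows = enrichment.fold_enrichment(fam_counts, lytic_total, temp_total)
            summary["enrichment"] = [
                {
                    "family": r.family,
                    "lytic_count": r.lytic_count,
                    "temperate_count": r.temperate_count,
                    "fold": r.fold if r.fold != float("inf") else "inf",
                }
                for r in rows
            ]
        carrier_names = {
            c.phage_id: next(p.name for p in phages if p.id == c.phage_id)
            for c in candidates
        }
        summary["hosts"] = enrichment.host_aggregate(carrier_names)
        metrics = enrichment.evaluate_against_truth(
            {c.protein_id for c in candidates},
            {p: c.label for p, c in lifestyle_calls.items()},
            set(summary.get("dissemination", {}).get("disseminated_gene_ids", [])),
            set(tables["adjacency"].loc[tables["adjacency"]["adjacent"], "gene_id"])
            if "adjacency" in tables and len(tables["adjacency"])
            else set(),
            cohort.truth,
            set(cohort.proteins),
        )
        summary["truth_metrics"] = metrics

    if config.run_tree and config.run_detection:
        dfr = {
            c.protein_id: proteins[c.protein_id]
            for c in candidates
            if c.best_family == "dfrA"
        }
        if len(dfr) >= 3:
            from .phylo import midpoint_root, neighbor_joining, pdistance_matrix

            dm = pdistance_matrix(dfr)
            tree = midpoint_root(neighbor_joining(dm))
            summary["tree"] = {
                "n_taxa": len(dm.taxa),
                "clade_sizes": {
                    "A": sum(1 for v in tree.clades.values() if v == "A"),
                    "B": sum(1 for v in tree.clades.values() if v == "B"),
                },
            }
            if write:
                (outdir / "dfrA_tree.nwk").write_text(tree.newick() + "\n")
                (outdir / "dfrA_distances.phylip").write_text(dm.to_phylip())

    if write:
        write_json(summary, outdir / "summary.json")
        for name, df in tables.items():
            write_tsv(df, outdir / f"{name}.tsv")
        if candidates:
            import pandas as pd

            write_tsv(
                pd.DataFrame(
                    [
                        {
                            "protein_id": c.protein_id,
                            "phage_id": c.phage_id,
                            "gene_index": c.gene_index,
                            "channels": "+".join(sorted(c.channels)),
                            "family": c.best_family,
                            "mechanism": c.mechanism,
                            "identity_pct": round(c.best_identity_pct, 2),
                            "qcov_pct": round(c.best_qcov_pct, 2),
                        }
                        for c in candidates
                    ]
                ),
                outdir / "candidates.tsv",
            )
    return PipelineResult(cohort=cohort, summary=summary, tables=tables, candidates=candidates)
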