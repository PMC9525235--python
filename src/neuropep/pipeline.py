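"""End-to-end orchestration with one config and a provenance manifest.

The stage order mirrors the analysis it reproduces: PSM curation ->
precursor annotation -> precursor similarity clustering -> peptide-GPCR
prediction -> single-cell target mapping. Every stage writes plain text
files into the output directory so any stage can be rerun standalone, and
a run manifest records parameters, seeds and input digests (no timestamps:
two runs of the same config must be byte-identical).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from . import gpcr_pred, precursor_annot, precursor_cluster, psm_filter, sc_expression
from . import synthetic_data as synth
from .psm_filter import FilterConfig

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run", "load_config", "save_config"]


@dataclass
class PipelineConfig:
    """All stage parameters, with the analysis defaults baked in."""

    seed: int = 0
    # stage toggles
    stages: dict = field(
        default_factory=lambda: {
            "filter": True, "annotate": True, "cluster": True,
            "predict": True, "targets": True,
        }
    )
    # psm curation
    exclusion_evalue: float = 1e-10
    require_amidation: bool = True
    allowed_motifs: list = field(default_factory=lambda: [synth.ALLOWED_MOTIF])
    # annotation
    site_len: int = 2
    flank_len: int = 6
    # similarity clustering
    cluster_cutoff: float = 1e-5
    # gpcr prediction
    tm_scan_evalue: float = 0.01
    threshold: float = 0.5
    max_per_peptide: int = 5
    # single-cell
    scale_factor: float = 10000.0
    min_gene_total: int = 10
    # synthetic generation (desk-scale defaults for a quick full run)
    synthetic: bool = True
    n_precursors: int = 40
    n_psm_records: int | None = None
    cpi_n_peptides: int = 60
    cpi_n_receptors: int = 100
    cpi_n_positives: int = 80
    cpi_n_planted: int = 12
    umi_n_genes: int = 400
    umi_n_cells: int = 800
    umi_n_clusters: int = 6
    # non-synthetic inputs (paths; used when synthetic is False)
    inputs: dict = field(default_factory=dict)


def save_config(cfg: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(cfg), fh, sort_keys=True)


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return PipelineConfig(**data)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _gen_config(cfg: PipelineConfig) -> synth.GenConfig:
    return synth.GenConfig(
        seed=cfg.seed,
        n_precursors=cfg.n_precursors,
        n_psm_records=cfg.n_psm_records,
        cpi=synth.CPIConfig(
            n_peptides=cfg.cpi_n_peptides,
            n_receptors=cfg.cpi_n_receptors,
            n_positives=cfg.cpi_n_positives,
            n_planted_pairs=cfg.cpi_n_planted,
        ),
        umi=synth.UMIConfig(
            n_genes=cfg.umi_n_genes,
            n_cells=cfg.umi_n_cells,
            n_clusters=cfg.umi_n_clusters,
        ),
    )


def run(cfg: PipelineConfig, outdir) -> dict:
    """Execute the configured stages; returns the run manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": dataclasses.asdict(cfg),
        "stages_run": [],
        "inputs": {},
    }

    if not cfg.synthetic and not cfg.inputs:
        raise FileNotFoundError("non-synthetic run requires input paths in cfg.inputs")

    # ------------------------------------------------------------------ inputs
    if cfg.synthetic:
        gen = _gen_config(cfg)
        precursors, truth = synth.gen_precursors(gen)
        records, hits, truth = synth.gen_psm_table(gen, truth)
        precursor_annot.write_fasta(precursors, out / "precursors.fasta")
        psm_filter.write_psm_table(records, out / "psms.tsv")
        with open(out / "domains.tsv", "w") as fh:
            fh.write("protein_id\tmotif_accession\tevalue\n")
            for h in hits:
                fh.write(f"{h.protein_id}\t{h.motif_accession}\t{h.evalue:.6g}\n")
        truth.to_json(out / "truth.json")
    else:
        for key in ("precursors_fasta", "psms", "domains"):
            p = Path(cfg.inputs[key]) if key in cfg.inputs else None
            if p is None or not p.exists():
                raise FileNotFoundError(f"stage 'filter' missing input {key}: {p}")
        precursors = precursor_annot.read_fasta(cfg.inputs["precursors_fasta"])
        records = psm_filter.read_psm_table(cfg.inputs["psms"])
        hits = psm_filter.read_domain_table(cfg.inputs["domains"])

    for name in ("precursors.fasta", "psms.tsv", "domains.tsv"):
        p = out / name
        if p.exists():
            manifest["inputs"][name] = _digest(p)

    # ------------------------------------------------------------------ filter
    curated = records
    if cfg.stages.get("filter", True):
        fcfg = FilterConfig(
            allowed_motifs=set(cfg.allowed_motifs),
            exclusion_evalue=cfg.exclusion_evalue,
            require_amidation=cfg.require_amidation,
        )
        curated = psm_filter.run_filter(records, hits, fcfg)
        psm_filter.write_psm_table(curated, out / "curated_psms.tsv")
        manifest["stages_run"].append("filter")
        logger.info("filter: %d/%d records survive", len(curated), len(records))
    else:
        manifest.setdefault("skipped", []).append("filter")

    # ---------------------------------------------------------------- annotate
    if cfg.stages.get("annotate", True):
        annotations = []
        all_misses = []
        for r in curated:
            if r.precursor_id not in precursors:
                all_misses.append(r.peptide)
                continue
            ann, misses = precursor_annot.annotate_precursor(
                r.precursor_id, precursors[r.precursor_id], [r.peptide]
            )
            annotations.append(ann)
            all_misses.extend(misses)
        n_ctx, c_ctx = precursor_annot.cleavage_context(
            annotations, site_len=cfg.site_len, flank_len=cfg.flank_len
        )
        n_ctx.frequencies.rename_axis("position").to_csv(
            out / "context_nterm.tsv", sep="\t", float_format="%.6g"
        )
        c_ctx.frequencies.rename_axis("position").to_csv(
            out / "context_cterm.tsv", sep="\t", float_format="%.6g"
        )
        with open(out / "annotations.tsv", "w") as fh:
            fh.write("precursor_id\tpeptide\tstart\tend\tside\tsite\tclass\n")
            for ann in annotations:
                for site in ann.cleavage_sites:
                    pep, (s, e) = ann.peptide_spans[0]
                    fh.write(
                        f"{ann.precursor_id}\t{pep.sequence}\t{s}\t{e}\t"
                        f"{site.side}\t{site.site_residues}\t{site.cls}\n"
                    )
        manifest["stages_run"].append("annotate")
        manifest["unmapped_peptides"] = len(all_misses)
    else:
        manifest.setdefault("skipped", []).append("annotate")

    # ----------------------------------------------------------------- cluster
    if cfg.stages.get("cluster", True):
        graph = precursor_cluster.build_graph(precursors, cutoff=cfg.cluster_cutoff)
        comps = precursor_cluster.components(graph)
        precursor_cluster.write_edge_table(graph, out / "similarity_edges.tsv")
        precursor_cluster.write_partition_table(comps, out / "clusters.tsv")
        manifest["stages_run"].append("cluster")
        logger.info("cluster: %d components over %d precursors", len(comps), len(graph.nodes))
    else:
        manifest.setdefault("skipped", []).append("cluster")

    # ----------------------------------------------------------------- predict
    assignments = None
    cpi_truth = None
    if cfg.stages.get("predict", True):
        gen = _gen_config(cfg)
        cpis, receptors, cpi_truth = synth.gen_cpi(gen)
        negatives = []  # shuffle negatives already included by the generator
        full = gpcr_pred.filter_seven_tm(receptors)
        gpcr_pred.write_cpi_table(cpis + negatives, out / "cpi.tsv")
        gpcr_pred.write_tm_table(receptors, out / "tm_segments.tsv")
        X, y = gpcr_pred.cpi_features(cpis)
        model = gpcr_pred.train(X, y, seed=cfg.seed)
        peptides = sorted(
            {r.peptide.precursor_id: r.peptide for r in cpis}.values(),
            key=lambda p: p.precursor_id,
        )
        scores, predicted = gpcr_pred.predict_pairs(
            model, peptides, full, threshold=cfg.threshold
        )
        assignments = gpcr_pred.assign_receptors(scores, max_per_peptide=cfg.max_per_peptide)
        scores.to_csv(out / "pair_scores.tsv", sep="\t", index=False, float_format="%.6g")
        predicted.to_csv(out / "predicted_pairs.tsv", sep="\t", index=False, float_format="%.6g")
        assignments.to_csv(out / "assignments.tsv", sep="\t", index=False, float_format="%.6g")
        manifest["stages_run"].append("predict")
        logger.info("predict: %d predicted pairs, %d assigned", len(predicted), len(assignments))
    else:
        manifest.setdefault("skipped", []).append("predict")

    # ----------------------------------------------------------------- targets
    if cfg.stages.get("targets", True):
        if assignments is None:
            raise RuntimeError("stage 'targets' requires stage 'predict'")
        gen = _gen_config(cfg)
        marker_home = {}
        if cpi_truth is not None:
            # all planted receptors of one peptide share a home cluster, so
            # the peptide's planted target cluster is well defined
            clusters = [f"C{k:02d}" for k in range(cfg.umi_n_clusters)]
            home_of_pep = {}
            for pid, rid in cpi_truth.cpi["planted_pairs"]:
                if pid not in home_of_pep:
                    home_of_pep[pid] = clusters[len(home_of_pep) % len(clusters)]
                marker_home[rid] = home_of_pep[pid]
        counts, cluster_of, umi_truth = synth.gen_umi(gen, marker_genes=marker_home)
        m = sc_expression.UMIMatrix(counts=counts, cluster_of=cluster_of)
        normalized = sc_expression.normalize_cells(m, scale_factor=cfg.scale_factor)
        kept = sc_expression.filter_genes(m, min_total=cfg.min_gene_total)
        normalized = normalized.loc[normalized.index.intersection(kept.genes)]
        ce = sc_expression.cluster_means(normalized, m.cluster_of)
        ce = sc_expression.scale_by_gene(ce)
        targets, unmapped = sc_expression.peptide_cell_targets(assignments, ce)
        ce.normalized_mean.rename_axis("gene").to_csv(
            out / "cluster_means.tsv", sep="\t", float_format="%.6g"
        )
        ce.scaled.rename_axis("gene").to_csv(
            out / "cluster_means_scaled.tsv", sep="\t", float_format="%.6g"
        )
        targets.to_csv(out / "peptide_targets.tsv", sep="\t", float_format="%.6g")
        manifest["stages_run"].append("targets")
        manifest["unmapped_receptors"] = {k: v for k, v in sorted(unmapped.items())}
    else:
        manifest.setdefault("skipped", []).append("targets")

    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
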