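"""Pipeline orchestration, Venn counts, and the run report.

``run_pipeline`` chains the in-memory stages (map -> screen -> classify ->
enrich -> summarise); ``run_all`` wraps it with file I/O, writing every
stage output as TSV plus a JSON run report whose provenance block records
the thresholds and the SHA-256 digests of the inputs, so regenerating a
report from identical inputs is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import (
    CorrClass,
    classify_pairs,
    cluster_order,
    summarize_classes,
)
from .enrichment import (
    TermAnnotation,
    enrich_layer,
    joint_enrichment,
    read_gmt,
    read_namespace_map,
)
from .errors import IntegrityError
from .mapping import build_pairs, filter_hits, read_blast_tabular
from .screening import (
    DiffStatus,
    ScreeningThresholds,
    call_degs,
    call_deps,
    read_protein_table,
    read_transcript_table,
)

__all__ = ["venn_counts", "run_pipeline", "run_all", "PipelineResult"]

logger = logging.getLogger("omicslink")


def venn_counts(
    transcript_ids,
    protein_ids,
    pairs: pd.DataFrame,
    deg_ids,
    dep_ids,
    classified_pairs: pd.DataFrame,
) -> dict:
    """Identification- and differential-level Venn counts.

    Identification: transcripts without a paired protein, uncorrelated
    proteins, and correlated pairs. Differential: DEG-side and DEP-side
    set sizes and the number of doubly-differential correlations
    (same-trend plus opposite) in the intersection.
    """
    transcript_set = {str(t) for t in transcript_ids}
    protein_set = {str(p) for p in protein_ids}
    if not set(pairs["transcript_id"]) <= transcript_set:
        raise IntegrityError("pair table references unknown transcripts")
    if not set(pairs["protein_id"]) <= protein_set:
        raise IntegrityError("pair table references unknown proteins")
    if len(classified_pairs) != len(pairs):
        raise IntegrityError("classified pair table size differs from pair table")
    cls = classified_pairs["corr_class"]
    n_same = int((cls == CorrClass.SAME_TREND.value).sum())
    n_opp = int((cls == CorrClass.OPPOSITE.value).sum())
    return {
        "identification": {
            "transcripts_only": len(transcript_set) - pairs["transcript_id"].nunique(),
            "proteins_only": len(protein_set) - pairs["protein_id"].nunique(),
            "correlated": int(len(pairs)),
        },
        "differential": {
            "deg": len({str(d) for d in deg_ids}),
            "dep": len({str(d) for d in dep_ids}),
            "differential_correlations": n_same + n_opp,
            "same_trend": n_same,
            "opposite": n_opp,
        },
    }


@dataclass
class PipelineResult:
    """All stage outputs of one integration run."""

    pairs: pd.DataFrame
    uncorrelated_proteins: list[str]
    gene_status: pd.Series
    protein_status: pd.Series
    classified_pairs: pd.DataFrame
    class_summary: pd.DataFrame
    scatter: pd.DataFrame
    enrichment_protein: pd.DataFrame
    enrichment_gene: pd.DataFrame
    enrichment_joint: pd.DataFrame
    venn: dict
    cluster_leaf_order: list[str] = field(default_factory=list)


def run_pipeline(
    transcript_table: pd.DataFrame,
    protein_table: pd.DataFrame,
    blast_hits: pd.DataFrame,
    annotation: dict[str, TermAnnotation] | None = None,
    thresholds: ScreeningThresholds | None = None,
    min_identity: float = 100.0,
    max_evalue: float = 1e-8,
    alpha: float = 0.05,
    universe: str = "annotated",
    bh: bool = False,
) -> PipelineResult:
    """Run map -> screen -> classify -> enrich on in-memory tables."""
    thresholds = thresholds or ScreeningThresholds()

    retained = filter_hits(blast_hits, min_identity=min_identity, max_evalue=max_evalue)
    pairs, uncorrelated = build_pairs(
        protein_table["protein_id"], transcript_table["transcript_id"], retained
    )
    logger.info(
        "identified: %d transcripts, %d proteins, %d correlated pairs, %d uncorrelated proteins",
        len(transcript_table), len(protein_table), len(pairs), len(uncorrelated),
    )

    gene_status = call_degs(transcript_table, thresholds)
    protein_status = call_deps(protein_table, thresholds)
    deg_ids = gene_status.index[gene_status != DiffStatus.NOT_DE.value]
    dep_ids = protein_status.index[protein_status != DiffStatus.NOT_DE.value]
    logger.info("differential: %d DEGs, %d DEPs", len(deg_ids), len(dep_ids))

    classified = classify_pairs(pairs, gene_status, protein_status)
    summary = summarize_classes(classified, transcript_table, protein_table)
    logger.info(
        "classes: %s",
        ", ".join(f"{r.corr_class}={r.n}" for r in summary.itertuples()),
    )

    lfc = transcript_table.set_index("transcript_id")["log2fc"]
    ratio = protein_table.set_index("protein_id")["ratio"]
    scatter = pd.DataFrame(
        {
            "protein_id": classified["protein_id"],
            "transcript_id": classified["transcript_id"],
            "gene_log2fc": lfc.reindex(classified["transcript_id"]).to_numpy(),
            "protein_log2_ratio": np.log2(ratio.reindex(classified["protein_id"]).to_numpy()),
            "corr_class": classified["corr_class"],
        }
    )

    same = scatter[scatter["corr_class"] == CorrClass.SAME_TREND.value]
    leaf_order: list[str] = []
    if len(same) >= 2:
        order, _ = cluster_order(same[["gene_log2fc", "protein_log2_ratio"]])
        leaf_order = same["protein_id"].to_numpy()[order].tolist()

    if annotation:
        enr_prot = enrich_layer(
            dep_ids, protein_table["protein_id"], annotation,
            alpha=alpha, universe=universe, bh=bh,
        )
        enr_gene = enrich_layer(
            deg_ids, transcript_table["transcript_id"], annotation,
            alpha=alpha, universe=universe, bh=bh,
        )
        joint = joint_enrichment(enr_prot, enr_gene, classified, annotation)
        logger.info(
            "enrichment: %d terms, %d jointly significant",
            len(joint), int(joint["jointly_significant"].sum()),
        )
    else:
        enr_prot = enr_gene = joint = pd.DataFrame()

    venn = venn_counts(
        transcript_table["transcript_id"], protein_table["protein_id"],
        pairs, deg_ids, dep_ids, classified,
    )
    return PipelineResult(
        pairs=pairs,
        uncorrelated_proteins=uncorrelated,
        gene_status=gene_status,
        protein_status=protein_status,
        classified_pairs=classified,
        class_summary=summary,
        scatter=scatter,
        enrichment_protein=enr_prot,
        enrichment_gene=enr_gene,
        enrichment_joint=joint,
        venn=venn,
        cluster_leaf_order=leaf_order,
    )


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(
    transcripts: str | Path,
    proteins: str | Path,
    blast: str | Path,
    annotation: str | Path | None,
    outdir: str | Path,
    namespace_map: str | Path | None = None,
    thresholds: ScreeningThresholds | None = None,
    min_identity: float = 100.0,
    max_evalue: float = 1e-8,
    alpha: float = 0.05,
    universe: str = "annotated",
    bh: bool = False,
    seed: int | None = None,
) -> dict:
    """File-level pipeline: read inputs, run every stage, write all outputs.

    Returns the run report (also written to ``<outdir>/report.json``).
    Any stage failure propagates with the stage name prepended.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    stage = "read-inputs"
    try:
        t_table = read_transcript_table(transcripts)
        p_table = read_protein_table(proteins)
        hits = read_blast_tabular(blast)
        ann = None
        if annotation is not None:
            ns = read_namespace_map(namespace_map) if namespace_map else None
            ann = read_gmt(annotation, namespace_map=ns)
        stage = "pipeline"
        result = run_pipeline(
            t_table, p_table, hits, ann,
            thresholds=thresholds, min_identity=min_identity,
            max_evalue=max_evalue, alpha=alpha, universe=universe, bh=bh,
        )
        stage = "write-outputs"
        result.pairs.to_csv(outdir / "pairs.tsv", sep="\t", index=False)
        pd.Series(result.uncorrelated_proteins, name="protein_id").to_csv(
            outdir / "uncorrelated_proteins.tsv", sep="\t", index=False
        )
        result.classified_pairs.to_csv(outdir / "classified_pairs.tsv", sep="\t", index=False)
        result.class_summary.to_csv(outdir / "class_summary.tsv", sep="\t", index=False)
        result.scatter.to_csv(outdir / "scatter.tsv", sep="\t", index=False)
        if len(result.enrichment_joint):
            result.enrichment_protein.to_csv(outdir / "enrichment_protein.tsv", sep="\t", index=False)
            result.enrichment_gene.to_csv(outdir / "enrichment_gene.tsv", sep="\t", index=False)
            result.enrichment_joint.to_csv(outdir / "enrichment_joint.tsv", sep="\t", index=False)
    except Exception as exc:
        raise type(exc)(f"[stage {stage}] {exc}") from exc

    th = thresholds or ScreeningThresholds()
    report = {
        "venn": result.venn,
        "class_summary": result.class_summary.to_dict(orient="records"),
        "jointly_significant_terms": (
            result.enrichment_joint.loc[
                result.enrichment_joint["jointly_significant"], "term_id"
            ].tolist()
            if len(result.enrichment_joint)
            else []
        ),
        "cluster_leaf_order": result.cluster_leaf_order,
        "provenance": {
            "tool": "omicslink",
            "version": __version__,
            "seed": seed,
            "thresholds": {
                "gene_fold_change": th.gene_fold_change,
                "gene_p": th.gene_p,
                "protein_fold_change": th.protein_fold_change,
                "protein_p": th.protein_p,
                "min_unique_peptides": th.min_unique_peptides,
                "blast_min_identity": min_identity,
                "blast_max_evalue": max_evalue,
                "enrichment_alpha": alpha,
                "universe": universe,
                "bh": bh,
            },
            "input_digests": {
                "transcripts": _sha256(transcripts),
                "proteins": _sha256(proteins),
                "blast": _sha256(blast),
                **({"annotation": _sha256(annotation)} if annotation else {}),
            },
        },
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
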