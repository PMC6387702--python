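"""Bundled reference data: the 15 same-trend salinity-response pairs.

This is the published set of mud-crab (*Scylla paramamosain*) gill
protein-transcript pairs that were differential in the same direction at
both layers after a salinity drop from 23 permil to 3 permil (low-salinity
over control ratios): nine up-regulated and six down-regulated pairs, with
iTRAQ protein ratios, RNA-seq gene log2 fold changes, unique-peptide
counts and functional annotations. It serves as a small end-to-end fixture
whose summary statistics (same-trend Spearman ~0.908, gene-to-protein
ratio-of-ratios ranges) are known.

The quantification P-values are synthetic (fixed at 0.01): the published
table reports none, and any value at or below the 0.05 screen is
equivalent under the thresholding pipeline.
"""

from __future__ import annotations

import pandas as pd

from .mapping import BLAST_COLUMNS

__all__ = ["load_same_trend_reference", "reference_pipeline_inputs"]

# columns: id, unique peptides, protein ratio (linear), gene log2FC, direction, description
_SAME_TREND_ROWS = [
    ("Unigene38622_All", 14, 2.30, 3.57, "Up", "Sodium/hydrogen exchanger"),
    ("Unigene15693_All", 7, 2.28, 2.21, "Up", "Carbonic anhydrase"),
    ("Unigene27170_All", 3, 1.49, 3.80, "Up", "NA"),
    ("CL5876.Contig2_All", 3, 1.47, 3.31, "Up", "Sodium- and chloride-dependent glycine transporter"),
    ("Unigene15443_All", 8, 1.36, 1.49, "Up", "Chloride channel"),
    ("Unigene30725_All", 9, 1.36, 1.71, "Up", "NA"),
    ("Unigene33785_All", 1, 1.34, 2.62, "Up", "NA"),
    ("Unigene10671_All", 11, 1.30, 1.40, "Up", "Serine proteinase inhibitor"),
    ("Unigene12149_All", 6, 1.26, 1.61, "Up", "Cystatin A precursor"),
    ("CL41.Contig2_All", 2, 0.78, -1.46, "Down", "Urea transporter"),
    ("Unigene44550_All", 3, 0.75, -4.08, "Down", "NA"),
    ("Unigene38779_All", 6, 0.70, -2.37, "Down", "NA"),
    ("Unigene5126_All", 5, 0.59, -2.40, "Down", "Protein takeout"),
    ("CL4395.Contig1_All", 6, 0.49, -4.17, "Down", "Mannose-binding protein"),
    ("CL3399.Contig2_All", 2, 0.46, -4.01, "Down", "Glutamine synthetase"),
]

_FIXTURE_PVALUE = 0.01


def load_same_trend_reference() -> pd.DataFrame:
    """The 15-pair same-trend reference table.

    Columns: ``pair_id``, ``unique_peptides``, ``protein_ratio`` (linear
    LS/CK), ``gene_log2fc`` (log2 LS/CK), ``direction`` (Up/Down),
    ``description``.
    """
    return pd.DataFrame(
        _SAME_TREND_ROWS,
        columns=[
            "pair_id", "unique_peptides", "protein_ratio",
            "gene_log2fc", "direction", "description",
        ],
    )


def reference_pipeline_inputs() -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Expand the reference set into full pipeline inputs.

    Returns (transcript table, protein table, BLAST hit table). Protein
    IDs are the pair IDs suffixed ``.pro``; each protein has a single
    perfect-identity hit against its transcript.
    """
    ref = load_same_trend_reference()
    transcripts = pd.DataFrame(
        {
            "transcript_id": ref["pair_id"],
            "log2fc": ref["gene_log2fc"],
            "pvalue": _FIXTURE_PVALUE,
        }
    )
    proteins = pd.DataFrame(
        {
            "protein_id": ref["pair_id"] + ".pro",
            "ratio": ref["protein_ratio"],
            "pvalue": _FIXTURE_PVALUE,
            "unique_peptides": ref["unique_peptides"],
        }
    )
    hits = pd.DataFrame(
        {
            "qseqid": proteins["protein_id"],
            "sseqid": ref["pair_id"],
            "pident": 100.0,
            "length": 300,
            "mismatch": 0,
            "gapopen": 0,
            "qstart": 1,
            "qend": 300,
            "sstart": 1,
            "send": 300,
            "evalue": 1e-50,
            "bitscore": 500.0,
        }
    )[BLAST_COLUMNS]
    return transcripts, proteins, hits
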