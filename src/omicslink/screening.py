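"""Differential screening of transcript and protein quantification tables.

A feature is called differential when its fold change clears a threshold
*and* its P-value is at most the significance cutoff; both comparisons are
inclusive. Transcript tables carry log2 fold changes (low-salinity over
control); protein tables carry linear ratios, plus the unique-peptide count
used as an identification-quality gate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError

__all__ = [
    "DiffStatus",
    "ScreeningThresholds",
    "read_transcript_table",
    "read_protein_table",
    "call_degs",
    "call_deps",
]

TRANSCRIPT_COLUMNS = ["transcript_id", "log2fc", "pvalue"]
PROTEIN_COLUMNS = ["protein_id", "ratio", "pvalue", "unique_peptides"]


class DiffStatus(str, Enum):
    """Per-feature differential-expression call."""

    UP = "UP"
    DOWN = "DOWN"
    NOT_DE = "NOT_DE"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class ScreeningThresholds:
    """Fold-change / P-value cutoffs for the two omics layers.

    ``gene_fold_change`` and ``protein_fold_change`` are *linear* ratios
    (a transcript is UP when its log2 fold change is at least
    ``log2(gene_fold_change)``). ``min_unique_peptides`` gates protein
    eligibility: proteins identified by fewer unique peptides are never
    called differential.
    """

    gene_fold_change: float = 2.0
    gene_p: float = 0.05
    protein_fold_change: float = 1.2
    protein_p: float = 0.05
    min_unique_peptides: int = 1

    def __post_init__(self) -> None:
        if not (self.gene_fold_change > 1 and self.protein_fold_change > 1):
            raise ConfigError("fold-change thresholds must be > 1 (linear ratios)")
        for name, p in (("gene_p", self.gene_p), ("protein_p", self.protein_p)):
            if not (0 < p < 1):
                raise ConfigError(f"{name} must lie in (0, 1), got {p}")
        if self.min_unique_peptides < 0:
            raise ConfigError("min_unique_peptides must be non-negative")


def _require_columns(df: pd.DataFrame, required: list[str], path) -> pd.DataFrame:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ConfigError(f"{path}: missing required column(s) {missing}")
    return df[required].copy()


def read_transcript_table(path: str | Path) -> pd.DataFrame:
    """Read a transcript quantification TSV (id, log2fc, pvalue).

    A header row is required; extra columns are ignored.
    """
    df = pd.read_csv(path, sep="\t")
    df = _require_columns(df, TRANSCRIPT_COLUMNS, path)
    df["transcript_id"] = df["transcript_id"].astype(str)
    df["log2fc"] = df["log2fc"].astype(float)
    df["pvalue"] = df["pvalue"].astype(float)
    if not np.isfinite(df["log2fc"]).all():
        raise ConfigError(f"{path}: non-finite log2fc values")
    if ((df["pvalue"] < 0) | (df["pvalue"] > 1)).any():
        raise ConfigError(f"{path}: P-values outside [0, 1]")
    return df


def read_protein_table(path: str | Path) -> pd.DataFrame:
    """Read a protein quantification TSV (id, linear ratio, pvalue, unique_peptides)."""
    df = pd.read_csv(path, sep="\t")
    df = _require_columns(df, PROTEIN_COLUMNS, path)
    df["protein_id"] = df["protein_id"].astype(str)
    df["ratio"] = df["ratio"].astype(float)
    df["pvalue"] = df["pvalue"].astype(float)
    df["unique_peptides"] = df["unique_peptides"].astype(int)
    if (df["ratio"] <= 0).any():
        raise ConfigError(f"{path}: protein ratios must be positive")
    if ((df["pvalue"] < 0) | (df["pvalue"] > 1)).any():
        raise ConfigError(f"{path}: P-values outside [0, 1]")
    return df


def call_degs(
    transcripts: pd.DataFrame,
    thresholds: ScreeningThresholds | None = None,
) -> pd.Series:
    """Call differentially expressed genes (DEGs).

    UP iff ``log2fc >= log2(gene_fold_change)`` and ``pvalue <= gene_p``;
    DOWN iff ``log2fc <= -log2(gene_fold_change)`` and ``pvalue <= gene_p``;
    otherwise NOT_DE. Returns a Series of status strings indexed by
    transcript_id.
    """
    thresholds = thresholds or ScreeningThresholds()
    cut = math.log2(thresholds.gene_fold_change)
    sig = transcripts["pvalue"].to_numpy() <= thresholds.gene_p
    lfc = transcripts["log2fc"].to_numpy()
    status = np.select(
        [sig & (lfc >= cut), sig & (lfc <= -cut)],
        [DiffStatus.UP.value, DiffStatus.DOWN.value],
        default=DiffStatus.NOT_DE.value,
    )
    return pd.Series(status, index=pd.Index(transcripts["transcript_id"], name="transcript_id"), name="gene_status")


def call_deps(
    proteins: pd.DataFrame,
    thresholds: ScreeningThresholds | None = None,
) -> pd.Series:
    """Call differentially expressed proteins (DEPs).

    Only proteins with ``unique_peptides >= min_unique_peptides`` are
    eligible. UP iff ``ratio >= protein_fold_change`` and
    ``pvalue <= protein_p``; DOWN iff ``ratio <= 1/protein_fold_change``
    and ``pvalue <= protein_p``; otherwise NOT_DE.
    """
    thresholds = thresholds or ScreeningThresholds()
    eligible = proteins["unique_peptides"].to_numpy() >= thresholds.min_unique_peptides
    sig = eligible & (proteins["pvalue"].to_numpy() <= thresholds.protein_p)
    ratio = proteins["ratio"].to_numpy()
    status = np.select(
        [sig & (ratio >= thresholds.protein_fold_change), sig & (ratio <= 1.0 / thresholds.protein_fold_change)],
        [DiffStatus.UP.value, DiffStatus.DOWN.value],
        default=DiffStatus.NOT_DE.value,
    )
    return pd.Series(status, index=pd.Index(proteins["protein_id"], name="protein_id"), name="protein_status")
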