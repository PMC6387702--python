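"""Six-way concordance classification of protein-transcript pairs.

Each correlated pair carries a differential status at both layers; the
cross of the two statuses partitions the pairs into five classes (same
trend, opposite, protein-only, gene-only, neither), and "Quant" — all
pairs regardless of status — completes the six summary groups for which a
Spearman rank correlation between protein and transcript fold changes is
reported. Because the correlation is rank-based, using linear or log
protein ratios cannot change it.
"""

from __future__ import annotations

import warnings
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .errors import DomainError, IntegrityError
from .screening import DiffStatus

__all__ = [
    "CorrClass",
    "CLASS_DISPLAY_NAMES",
    "classify_pair",
    "classify_pairs",
    "spearman",
    "summarize_classes",
    "ratio_of_ratios",
    "cluster_order",
]


class CorrClass(str, Enum):
    """Concordance class of one protein-transcript pair."""

    SAME_TREND = "SAME_TREND"
    OPPOSITE = "OPPOSITE"
    DEP_ONLY = "DEP_ONLY"
    DEG_ONLY = "DEG_ONLY"
    NEITHER = "NEITHER"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Field-standard display labels for reports.
CLASS_DISPLAY_NAMES = {
    CorrClass.SAME_TREND: "DEPs_DEGs_Same Trend",
    CorrClass.OPPOSITE: "DEPs_DEGs_Opposite",
    CorrClass.DEP_ONLY: "DEPs_NDEGs",
    CorrClass.DEG_ONLY: "NDEPs_DEGs",
    CorrClass.NEITHER: "NDEPs_NDEGs",
}

#: Label for the all-pairs summary group.
QUANT = "QUANT"


def classify_pair(gene_status: str | DiffStatus, protein_status: str | DiffStatus) -> CorrClass:
    """Map a (gene, protein) status pair to its concordance class.

    (UP, UP) / (DOWN, DOWN) -> SAME_TREND; (UP, DOWN) / (DOWN, UP) ->
    OPPOSITE; differential protein with non-differential gene -> DEP_ONLY;
    the converse -> DEG_ONLY; neither differential -> NEITHER.
    """
    g = DiffStatus(gene_status)
    p = DiffStatus(protein_status)
    g_de = g is not DiffStatus.NOT_DE
    p_de = p is not DiffStatus.NOT_DE
    if g_de and p_de:
        return CorrClass.SAME_TREND if g is p else CorrClass.OPPOSITE
    if p_de:
        return CorrClass.DEP_ONLY
    if g_de:
        return CorrClass.DEG_ONLY
    return CorrClass.NEITHER


def classify_pairs(
    pairs: pd.DataFrame,
    gene_status: pd.Series,
    protein_status: pd.Series,
) -> pd.DataFrame:
    """Attach statuses and concordance class to a pair table.

    ``gene_status`` / ``protein_status`` are Series indexed by feature ID
    (as returned by :func:`omicslink.screening.call_degs` /
    :func:`~omicslink.screening.call_deps`). Pairs referencing features
    absent from either status table raise :class:`IntegrityError`.
    """
    out = pairs[["protein_id", "transcript_id"]].copy()
    missing_t = set(out["transcript_id"]) - set(gene_status.index)
    missing_p = set(out["protein_id"]) - set(protein_status.index)
    if missing_t or missing_p:
        raise IntegrityError(
            f"pairs reference unknown features: transcripts {sorted(missing_t)[:5]}, "
            f"proteins {sorted(missing_p)[:5]}"
        )
    out["gene_status"] = gene_status.reindex(out["transcript_id"]).to_numpy()
    out["protein_status"] = protein_status.reindex(out["protein_id"]).to_numpy()
    out["corr_class"] = [
        classify_pair(g, p).value
        for g, p in zip(out["gene_status"], out["protein_status"])
    ]
    return out


def spearman(x, y) -> float:
    """Spearman rank correlation with midranks for ties.

    Equivalent to the Pearson correlation of the midrank-transformed
    vectors, hence invariant under any strictly increasing transform of
    either argument. Degenerate inputs (length < 2, or zero rank variance
    in either vector) return NaN rather than raising; callers that report
    per-class coefficients replace NaN by the documented empty-class
    sentinel.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise DomainError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.ndim != 1:
        raise DomainError("expected 1-D vectors")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise DomainError("non-finite values")
    if len(x) < 2 or np.unique(x).size < 2 or np.unique(y).size < 2:
        return float("nan")
    return float(stats.spearmanr(x, y).statistic)


def summarize_classes(
    classified_pairs: pd.DataFrame,
    transcript_table: pd.DataFrame,
    protein_table: pd.DataFrame,
) -> pd.DataFrame:
    """Per-class pair counts and Spearman coefficients, plus the Quant row.

    Correlates the protein log2 ratio against the gene log2 fold change
    within each concordance class and over all pairs. Classes that are
    empty or rank-degenerate get ``spearman = 0.0`` with
    ``degenerate = True`` (the correlation is undefined, and the sentinel
    mirrors how such classes are conventionally reported).

    Returns a DataFrame with columns ``corr_class``, ``display_name``,
    ``n``, ``spearman``, ``degenerate``; class counts sum to the Quant
    count.
    """
    lfc = transcript_table.set_index("transcript_id")["log2fc"]
    ratio = protein_table.set_index("protein_id")["ratio"]
    missing_t = set(classified_pairs["transcript_id"]) - set(lfc.index)
    missing_p = set(classified_pairs["protein_id"]) - set(ratio.index)
    if missing_t or missing_p:
        raise IntegrityError(
            f"classified pairs reference unquantified features: "
            f"transcripts {sorted(missing_t)[:5]}, proteins {sorted(missing_p)[:5]}"
        )
    gene = lfc.reindex(classified_pairs["transcript_id"]).to_numpy()
    prot = np.log2(ratio.reindex(classified_pairs["protein_id"]).to_numpy())

    rows = []

    def _row(label: str, display: str, mask: np.ndarray) -> None:
        r = spearman(gene[mask], prot[mask]) if mask.any() else float("nan")
        degenerate = not np.isfinite(r)
        rows.append(
            {
                "corr_class": label,
                "display_name": display,
                "n": int(mask.sum()),
                "spearman": 0.0 if degenerate else r,
                "degenerate": degenerate,
            }
        )

    cls = classified_pairs["corr_class"].to_numpy()
    _row(QUANT, "Quant", np.ones(len(cls), dtype=bool))
    for c in CorrClass:
        _row(c.value, CLASS_DISPLAY_NAMES[c], cls == c.value)
    out = pd.DataFrame(rows)
    assert out.loc[out["corr_class"] != QUANT, "n"].sum() == len(classified_pairs)
    return out


def ratio_of_ratios(gene_log2fc, protein_ratio):
    """Linear gene fold change divided by protein fold change.

    ``2**gene_log2fc / protein_ratio`` — a diagnostic of how much stronger
    the transcriptional response is than the translational one (values > 1
    for up-regulated pairs indicate attenuation at the protein layer).
    Accepts scalars or arrays; non-positive protein ratios raise
    :class:`DomainError`.
    """
    gene_log2fc = np.asarray(gene_log2fc, dtype=float)
    protein_ratio = np.asarray(protein_ratio, dtype=float)
    if (protein_ratio <= 0).any():
        raise DomainError("protein ratio must be positive")
    out = np.power(2.0, gene_log2fc) / protein_ratio
    return float(out) if out.ndim == 0 else out


def _deterministic_leaf_order(linkage_matrix: np.ndarray, n: int) -> list[int]:
    """Leaf order with the lower original row index first at every rotation."""
    children: dict[int, tuple[int, int]] = {
        n + i: (int(a), int(b)) for i, (a, b, _, _) in enumerate(linkage_matrix)
    }
    min_leaf: dict[int, int] = {}

    def resolve(node: int) -> int:
        if node < n:
            return node
        if node not in min_leaf:
            a, b = children[node]
            min_leaf[node] = min(resolve(a), resolve(b))
        return min_leaf[node]

    order: list[int] = []
    stack = [2 * n - 2]
    while stack:
        node = stack.pop()
        if node < n:
            order.append(node)
        else:
            a, b = children[node]
            first, second = (a, b) if resolve(a) <= resolve(b) else (b, a)
            stack.append(second)
            stack.append(first)
    return order


def cluster_order(
    matrix: pd.DataFrame | np.ndarray,
    method: str = "average",
    metric: str = "euclidean",
) -> tuple[list[int], np.ndarray | None]:
    """Hierarchically cluster expression rows and return a deterministic row order.

    ``matrix`` holds one row per pair (typically the two columns gene
    log2FC and protein log2 ratio). Agglomeration uses the given linkage
    method and metric (defaults: average linkage, Euclidean distance). The
    leaf order is made platform-independent by placing, at every internal
    node, the subtree containing the lower original row index first.

    Returns ``(order, linkage_matrix)`` where ``order`` is a permutation
    of row positions. With fewer than two rows the input order is returned
    with a warning and ``linkage_matrix`` is None.
    """
    values = np.asarray(matrix, dtype=float)
    if values.ndim == 1:
        values = values[:, None]
    n = values.shape[0]
    if n < 2:
        warnings.warn("cluster_order needs at least 2 rows; returning input order")
        return list(range(n)), None
    linkage_matrix = hierarchy.linkage(pdist(values, metric=metric), method=method)
    return _deterministic_leaf_order(linkage_matrix, n), linkage_matrix
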