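"""Term tabulation and hypergeometric enrichment at both omics layers.

Terms (KEGG pathways, GO classes, COG categories) are member-ID sets read
from a GMT-style file; a member list may mix transcript and protein IDs,
and each layer's membership is derived by intersecting with that layer's
universe at evaluation time. Enrichment at one layer is an upper-tail
hypergeometric test of the overlap between a term and the differential
set; a term is *jointly significant* when it is significant (raw P below
alpha, strict) at both the proteome and the transcriptome layer.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .classify import CorrClass
from .errors import ConfigError, DomainError

__all__ = [
    "TermAnnotation",
    "read_gmt",
    "write_gmt",
    "read_namespace_map",
    "hypergeom_upper_tail",
    "enrich_layer",
    "joint_enrichment",
    "tabulate_classes",
]

NAMESPACES = ("KEGG", "GO_BP", "GO_CC", "GO_MF", "COG")


@dataclass(frozen=True)
class TermAnnotation:
    """One term: identifier, human-readable name, member-ID set, namespace.

    Members may reference either omics layer; per-layer member sets are
    obtained by intersecting with the layer universe when the term is
    evaluated.
    """

    term_id: str
    term_name: str
    members: frozenset[str]
    namespace: str = "KEGG"

    def members_in(self, universe: Iterable[str]) -> frozenset[str]:
        return self.members & frozenset(universe)


def read_gmt(
    path: str | Path,
    namespace_map: Mapping[str, str] | None = None,
    default_namespace: str = "KEGG",
) -> dict[str, TermAnnotation]:
    """Read a GMT-style annotation file (term_id, term_name, members...).

    Tab-separated; lines starting with ``#`` are skipped. ``namespace_map``
    (term_id -> namespace) assigns namespaces; unmapped terms get
    ``default_namespace``.
    """
    terms: dict[str, TermAnnotation] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ConfigError(f"{path} line {lineno}: need at least term_id and term_name")
            term_id, term_name = fields[0], fields[1]
            members = frozenset(m for m in fields[2:] if m)
            ns = (namespace_map or {}).get(term_id, default_namespace)
            terms[term_id] = TermAnnotation(term_id, term_name, members, ns)
    return terms


def write_gmt(terms: Mapping[str, TermAnnotation], path: str | Path) -> None:
    """Write terms to a GMT-style file (members sorted for reproducibility)."""
    with open(path, "w") as fh:
        for term in terms.values():
            fh.write("\t".join([term.term_id, term.term_name, *sorted(term.members)]) + "\n")


def read_namespace_map(path: str | Path) -> dict[str, str]:
    """Read a two-column (term_id, namespace) TSV."""
    df = pd.read_csv(path, sep="\t", header=None, names=["term_id", "namespace"], comment="#")
    return dict(zip(df["term_id"].astype(str), df["namespace"].astype(str)))


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    X counts the overlap when ``n`` features are drawn without replacement
    from a universe of ``N`` features of which ``K`` belong to the term.
    Computed via the survival function of ``scipy.stats.hypergeom``, which
    accumulates log point masses and is stable for large counts.
    """
    N, K, n, k = int(N), int(K), int(n), int(k)
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(K, n)):
        raise DomainError(f"inconsistent hypergeometric counts N={N}, K={K}, n={n}, k={k}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def _bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    return stats.false_discovery_control(pvalues, method="bh")


def enrich_layer(
    differential_ids: Iterable[str],
    universe_ids: Iterable[str],
    annotation: Mapping[str, TermAnnotation],
    alpha: float = 0.05,
    namespace: str | None = None,
    universe: str = "annotated",
    bh: bool = False,
) -> pd.DataFrame:
    """Per-term hypergeometric enrichment at one omics layer.

    ``universe`` chooses the background: ``"annotated"`` (default)
    restricts the quantified universe to features carrying at least one
    annotation in the tested namespace(s); ``"quantified"`` uses all
    quantified features. Term membership is intersected with the universe
    before counting. Significance is raw ``p < alpha`` (strict); with
    ``bh=True`` a Benjamini-Hochberg adjusted P-value is added and used
    for the significance flag instead.

    Returns a DataFrame with columns term_id, term_name, namespace,
    k (overlap), K (term size in universe), n (differential size in
    universe), N (universe size), pvalue, significant.
    """
    universe_set = {str(u) for u in universe_ids}
    if not universe_set:
        raise ConfigError("empty universe")
    diff_set = {str(d) for d in differential_ids}
    if not diff_set <= universe_set:
        raise ConfigError("differential IDs must be a subset of the universe")
    terms = [
        t for t in annotation.values() if namespace is None or t.namespace == namespace
    ]
    if universe == "annotated":
        annotated = frozenset().union(*(t.members for t in terms)) if terms else frozenset()
        universe_set = universe_set & annotated
        diff_set = diff_set & universe_set
        if not universe_set:
            raise ConfigError("no quantified feature carries an annotation in this namespace")
    elif universe != "quantified":
        raise ConfigError(f"unknown universe mode {universe!r}")

    N = len(universe_set)
    n = len(diff_set)
    rows = []
    for t in sorted(terms, key=lambda t: t.term_id):
        members = t.members & universe_set
        K = len(members)
        k = len(members & diff_set)
        p = hypergeom_upper_tail(N, K, n, k)
        rows.append(
            {
                "term_id": t.term_id,
                "term_name": t.term_name,
                "namespace": t.namespace,
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "pvalue": p,
            }
        )
    out = pd.DataFrame(
        rows, columns=["term_id", "term_name", "namespace", "k", "K", "n", "N", "pvalue"]
    )
    if bh and len(out):
        out["pvalue_bh"] = _bh_adjust(out["pvalue"].to_numpy())
        out["significant"] = out["pvalue_bh"] < alpha
    else:
        out["significant"] = out["pvalue"] < alpha
    return out


def joint_enrichment(
    protein_results: pd.DataFrame,
    gene_results: pd.DataFrame,
    classified_pairs: pd.DataFrame,
    annotation: Mapping[str, TermAnnotation],
) -> pd.DataFrame:
    """Combine per-layer enrichment into the joint-significance table.

    A term is jointly significant iff it is significant at both layers
    (per-layer flags are taken as computed — P-values are never
    recomputed here). ``n_correlations`` counts same-trend pairs whose
    protein *and* transcript are both members of the term.

    Output columns mirror the conventional dual-omics pathway table:
    term_id, term_name, k/K at each layer, n_correlations, p_prot,
    p_gene, jointly_significant.
    """
    prot = protein_results.set_index("term_id")
    gene = gene_results.set_index("term_id")
    shared = prot.index.intersection(gene.index)

    same = classified_pairs.loc[
        classified_pairs["corr_class"] == CorrClass.SAME_TREND.value,
        ["protein_id", "transcript_id"],
    ]
    rows = []
    for term_id in shared:
        members = annotation[term_id].members
        n_corr = int(
            (same["protein_id"].isin(members) & same["transcript_id"].isin(members)).sum()
        )
        rows.append(
            {
                "term_id": term_id,
                "term_name": annotation[term_id].term_name,
                "namespace": annotation[term_id].namespace,
                "k_prot": int(prot.at[term_id, "k"]),
                "K_prot": int(prot.at[term_id, "K"]),
                "k_gene": int(gene.at[term_id, "k"]),
                "K_gene": int(gene.at[term_id, "K"]),
                "n_correlations": n_corr,
                "p_prot": float(prot.at[term_id, "pvalue"]),
                "p_gene": float(gene.at[term_id, "pvalue"]),
                "jointly_significant": bool(prot.at[term_id, "significant"])
                and bool(gene.at[term_id, "significant"]),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "term_id", "term_name", "namespace", "k_prot", "K_prot",
            "k_gene", "K_gene", "n_correlations", "p_prot", "p_gene",
            "jointly_significant",
        ],
    )


def tabulate_classes(
    member_ids: Iterable[str],
    annotation: Mapping[str, TermAnnotation],
    namespace: str,
) -> pd.DataFrame:
    """Functional-class tabulation (GO / COG style) of a feature set.

    Counts, for every term in ``namespace``, how many of ``member_ids``
    it annotates. Percentages use as denominator the number of input
    features carrying at least one annotation in the namespace — features
    without any annotation are excluded, matching how functional-class
    bar charts are conventionally normalised.
    """
    ids = {str(m) for m in member_ids}
    terms = [t for t in annotation.values() if t.namespace == namespace]
    annotated = ids & (frozenset().union(*(t.members for t in terms)) if terms else frozenset())
    denom = len(annotated)
    rows = []
    for t in sorted(terms, key=lambda t: t.term_id):
        count = len(t.members & ids)
        if count == 0:
            continue
        rows.append(
            {
                "term_id": t.term_id,
                "term_name": t.term_name,
                "count": count,
                "percentage": 100.0 * count / denom if denom else 0.0,
            }
        )
    return pd.DataFrame(rows, columns=["term_id", "term_name", "count", "percentage"])
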