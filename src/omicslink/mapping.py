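"""Protein-to-transcript pairing from BLAST tabular hits.

A protein is "correlated" when at least one of its BLAST hits against the
transcript assembly survives the identity / E-value filter; it is then
paired to a single transcript by a deterministic best-hit rule. Proteins
with no surviving hit are reported as uncorrelated.
"""

from __future__ import annotations

from collections.abc import Iterable
from pathlib import Path

import pandas as pd

from .errors import BlastParseError, IntegrityError

__all__ = [
    "BLAST_COLUMNS",
    "read_blast_tabular",
    "write_blast_tabular",
    "filter_hits",
    "build_pairs",
]

#: Standard 12-column BLAST tabular (outfmt 6) layout.
BLAST_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]

_INT_COLS = ["length", "mismatch", "gapopen", "qstart", "qend", "sstart", "send"]
_FLOAT_COLS = ["pident", "evalue", "bitscore"]

DEFAULT_MIN_IDENTITY = 100.0
DEFAULT_MAX_EVALUE = 1e-8


def read_blast_tabular(path: str | Path) -> pd.DataFrame:
    """Parse a 12-column BLAST tabular file into a hit table.

    Comment lines starting with ``#`` and blank lines are skipped. A line
    with the wrong column count or an unparsable numeric field raises
    :class:`BlastParseError` carrying the 1-based line number.
    """
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise BlastParseError(
                    f"expected 12 tab-separated columns, found {len(fields)}", lineno
                )
            try:
                rows.append(
                    (
                        fields[0], fields[1], float(fields[2]),
                        int(fields[3]), int(fields[4]), int(fields[5]),
                        int(fields[6]), int(fields[7]), int(fields[8]), int(fields[9]),
                        float(fields[10]), float(fields[11]),
                    )
                )
            except ValueError as exc:
                raise BlastParseError(f"unparsable numeric field ({exc})", lineno) from exc
    df = pd.DataFrame(rows, columns=BLAST_COLUMNS)
    if len(df):
        if ((df["pident"] < 0) | (df["pident"] > 100)).any():
            raise BlastParseError("pident outside [0, 100]")
        if (df["evalue"] < 0).any():
            raise BlastParseError("negative E-value")
    return df


def write_blast_tabular(hits: pd.DataFrame, path: str | Path) -> None:
    """Write a hit table back to 12-column BLAST tabular format."""
    out = hits[BLAST_COLUMNS].copy()
    out["pident"] = out["pident"].map(lambda v: f"{v:.3f}")
    out.to_csv(path, sep="\t", header=False, index=False)


def filter_hits(
    hits: pd.DataFrame,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    max_evalue: float = DEFAULT_MAX_EVALUE,
) -> pd.DataFrame:
    """Retain hits with ``pident >= min_identity`` and ``evalue <= max_evalue``.

    Both comparisons are inclusive. Identity is compared after rounding to
    three decimals, the precision BLAST prints in tabular output.
    """
    if not len(hits):
        return hits.copy()
    pident = hits["pident"].astype(float).round(3)
    keep = (pident >= min_identity) & (hits["evalue"].astype(float) <= max_evalue)
    return hits.loc[keep].copy()


def build_pairs(
    protein_ids: Iterable[str],
    transcript_ids: Iterable[str],
    retained_hits: pd.DataFrame,
) -> tuple[pd.DataFrame, list[str]]:
    """Pair each protein with a single transcript via its best retained hit.

    Best-hit rule (deterministic): highest bitscore, then lowest E-value,
    then highest identity, then lexicographically smallest transcript ID.
    Several proteins may map to the same transcript. Returns the pair table
    (``protein_id``, ``transcript_id`` plus the evidence columns of the
    winning hit) and the sorted list of uncorrelated protein IDs. Every
    protein lands in exactly one of the two outputs.

    Hits referencing IDs absent from either universe raise
    :class:`IntegrityError`.
    """
    protein_ids = list(dict.fromkeys(str(p) for p in protein_ids))
    transcript_set = {str(t) for t in transcript_ids}
    protein_set = set(protein_ids)

    if len(retained_hits):
        bad_t = set(retained_hits["sseqid"]) - transcript_set
        if bad_t:
            raise IntegrityError(f"hits reference unknown transcript IDs: {sorted(bad_t)[:5]}")
        bad_p = set(retained_hits["qseqid"]) - protein_set
        if bad_p:
            raise IntegrityError(f"hits reference unknown protein IDs: {sorted(bad_p)[:5]}")
        best = (
            retained_hits.sort_values(
                ["qseqid", "bitscore", "evalue", "pident", "sseqid"],
                ascending=[True, False, True, False, True],
                kind="mergesort",
            )
            .drop_duplicates("qseqid", keep="first")
        )
    else:
        best = retained_hits

    pairs = pd.DataFrame({"protein_id": pd.Series(protein_ids, dtype=str)}).merge(
        best.rename(columns={"qseqid": "protein_id", "sseqid": "transcript_id"}),
        on="protein_id",
        how="inner",
    )
    pairs = pairs[["protein_id", "transcript_id", "pident", "evalue", "bitscore"]]
    uncorrelated = sorted(protein_set - set(pairs["protein_id"]))
    assert len(pairs) + len(uncorrelated) == len(protein_ids)
    return pairs.reset_index(drop=True), uncorrelated
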