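"""Paired transcriptome/proteome dataset generator with known ground truth.

The generator emulates the four inputs of the integration pipeline — a
transcript quantification table (log2 fold change + P-value), a protein
quantification table (linear ratio + P-value + unique-peptide count),
protein-vs-transcript BLAST tabular hits, and a GMT-style term annotation
— together with truth tables giving every mapped pair's concordance class
and every term's designed enrichment status.

Differential features are drawn with *decisive margins*: their P-values
fall strictly below the screening cutoff and their effect sizes clear the
fold-change thresholds with room to spare, while null features stay
strictly inside the dead zone with P-values above the cutoff. Screening
therefore recovers the designed labels deterministically, which is what
makes the truth tables exact rather than probabilistic.

The effect model uses a shared latent log2 effect per doubly-differential
pair: the protein-layer log2 fold change is ``protein_attenuation`` times
the gene-layer effect plus noise, reproducing the wedge-shaped
transcript-vs-protein scatter seen in real integration studies where
transcriptional responses overshoot translational ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .classify import CorrClass, classify_pair
from .enrichment import TermAnnotation, read_gmt, read_namespace_map, write_gmt
from .errors import ConfigError
from .mapping import BLAST_COLUMNS, read_blast_tabular, write_blast_tabular
from .screening import DiffStatus, read_protein_table, read_transcript_table

__all__ = ["SimulationConfig", "SyntheticDataset", "generate_dataset", "write_dataset", "read_dataset"]

# Margins guaranteeing deterministic screen recovery under default thresholds
# (gene |log2FC| cutoff 1, protein |log2 ratio| cutoff log2(1.2) ~= 0.263).
_GENE_EFFECT_FLOOR = 1.25
_GENE_NULL_CEIL = 0.9
_PROT_EFFECT_FLOOR = 0.35
_PROT_NULL_CEIL = 0.2
_P_DIFF_LOW, _P_DIFF_HIGH = 1e-4, 0.04
_P_NULL_LOW, _P_NULL_HIGH = 0.06, 1.0

# Loading factors making designed enriched terms decisively significant at
# both layers (overlap expectations sit far above the null expectation).
_DEG_LOAD_MIN, _DEG_LOAD_FRAC = 8, 0.5
_DEP_LOAD_MIN, _DEP_LOAD_FRAC = 5, 0.25


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic paired-omics dataset.

    Fractions are probabilities per feature (or per mapped pair);
    ``concordance`` is the probability that a doubly-differential pair has
    the same direction at both layers; ``layer_coupling`` is the
    probability that a mapped transcript inherits its partner protein's
    differential indicator instead of an independent draw — it controls
    how many pairs are differential at both layers. ``protein_attenuation``
    scales the gene log2 effect down at the protein layer.
    """

    n_transcripts: int = 2000
    n_proteins: int = 400
    frac_unmapped_proteins: float = 0.02
    frac_deg: float = 0.05
    frac_dep: float = 0.20
    concordance: float = 1.0
    effect_log2fc_mean: float = 2.5
    effect_log2fc_sd: float = 0.8
    null_log2fc_sd: float = 0.3
    protein_attenuation: float = 0.5
    n_terms: int = 20
    term_size_range: tuple[int, int] = (12, 30)
    n_enriched_terms: int = 3
    layer_coupling: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_transcripts <= 0 or self.n_proteins <= 0:
            raise ConfigError("n_transcripts and n_proteins must be positive")
        if self.n_proteins > self.n_transcripts:
            raise ConfigError("n_proteins must not exceed n_transcripts")
        for name in ("frac_unmapped_proteins", "frac_deg", "frac_dep", "concordance", "layer_coupling"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if self.effect_log2fc_sd < 0 or self.null_log2fc_sd < 0:
            raise ConfigError("standard deviations must be non-negative")
        if self.protein_attenuation <= 0:
            raise ConfigError("protein_attenuation must be positive")
        if self.n_terms < 0 or self.n_enriched_terms < 0:
            raise ConfigError("term counts must be non-negative")
        if self.n_enriched_terms > self.n_terms:
            raise ConfigError("n_enriched_terms must not exceed n_terms")
        lo, hi = self.term_size_range
        if not (0 < lo <= hi):
            raise ConfigError("term_size_range must satisfy 0 < lo <= hi")
        if self.n_terms > 0 and hi > self.n_transcripts:
            raise ConfigError("term sizes cannot exceed n_transcripts")
        if self.n_enriched_terms > 0 and (self.frac_deg == 0 or self.frac_dep == 0):
            raise ConfigError(
                "n_enriched_terms > 0 requires frac_deg > 0 and frac_dep > 0 "
                "(enriched terms are loaded with differential members at both layers)"
            )

    @classmethod
    def from_file(cls, path: str | Path) -> "SimulationConfig":
        """Load a flat key: value config file (YAML syntax)."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "term_size_range" in raw:
            raw["term_size_range"] = tuple(raw["term_size_range"])
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(f"unknown config key: {exc}") from exc

    def to_dict(self) -> dict:
        d = asdict(self)
        d["term_size_range"] = list(d["term_size_range"])
        return d


@dataclass
class SyntheticDataset:
    """Generated input files plus ground truth.

    ``truth_pairs`` holds one row per mapped pair (protein_id,
    transcript_id, gene_status, protein_status, corr_class);
    ``truth_terms`` one row per term (term_id, enriched).
    """

    config: SimulationConfig
    transcript_table: pd.DataFrame
    protein_table: pd.DataFrame
    blast_hits: pd.DataFrame
    annotation: dict[str, TermAnnotation]
    truth_pairs: pd.DataFrame
    truth_terms: pd.DataFrame
    unmapped_proteins: list[str] = field(default_factory=list)


def _status(differential: np.ndarray, sign: np.ndarray) -> np.ndarray:
    return np.select(
        [differential & (sign > 0), differential & (sign < 0)],
        [DiffStatus.UP.value, DiffStatus.DOWN.value],
        default=DiffStatus.NOT_DE.value,
    )


def generate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate one dataset; identical config (including seed) gives identical output."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    transcript_ids = np.array([f"T{i:06d}" for i in range(cfg.n_transcripts)])
    protein_ids = np.array([f"P{i:05d}" for i in range(cfg.n_proteins)])

    # --- mapping structure -------------------------------------------------
    n_unmapped = int(round(cfg.frac_unmapped_proteins * cfg.n_proteins))
    unmapped_idx = np.sort(rng.choice(cfg.n_proteins, size=n_unmapped, replace=False))
    mapped_mask = np.ones(cfg.n_proteins, dtype=bool)
    mapped_mask[unmapped_idx] = False
    mapped_idx = np.flatnonzero(mapped_mask)
    n_mapped = len(mapped_idx)
    partner_t = rng.choice(cfg.n_transcripts, size=n_mapped, replace=False)

    # --- designed differential structure -----------------------------------
    is_dep = rng.random(cfg.n_proteins) < cfg.frac_dep
    deg_t = rng.random(cfg.n_transcripts) < cfg.frac_deg
    couple = rng.random(n_mapped) < cfg.layer_coupling
    if cfg.frac_deg > 0:
        # a mapped transcript may inherit its partner protein's indicator
        deg_t[partner_t[couple]] = is_dep[mapped_idx[couple]]
    same_trend_draw = rng.random(cfg.n_proteins) < cfg.concordance
    sign_t = rng.choice(np.array([-1.0, 1.0]), size=cfg.n_transcripts)
    indep_sign_p = rng.choice(np.array([-1.0, 1.0]), size=cfg.n_proteins)

    sign_p = indep_sign_p.copy()
    pair_both = is_dep[mapped_idx] & deg_t[partner_t]
    pair_same = same_trend_draw[mapped_idx]
    sign_p[mapped_idx[pair_both & pair_same]] = sign_t[partner_t[pair_both & pair_same]]
    sign_p[mapped_idx[pair_both & ~pair_same]] = -sign_t[partner_t[pair_both & ~pair_same]]

    # --- transcript layer effects ------------------------------------------
    gene_mag = np.maximum(
        np.abs(rng.normal(cfg.effect_log2fc_mean, cfg.effect_log2fc_sd, cfg.n_transcripts)),
        _GENE_EFFECT_FLOOR,
    )
    gene_null = np.clip(
        rng.normal(0.0, cfg.null_log2fc_sd, cfg.n_transcripts), -_GENE_NULL_CEIL, _GENE_NULL_CEIL
    )
    log2fc = np.where(deg_t, sign_t * gene_mag, gene_null)
    gene_p = np.where(
        deg_t,
        rng.uniform(_P_DIFF_LOW, _P_DIFF_HIGH, cfg.n_transcripts),
        rng.uniform(_P_NULL_LOW, _P_NULL_HIGH, cfg.n_transcripts),
    )

    # --- protein layer effects (attenuated shared latent effect) -----------
    own_mag = np.abs(
        rng.normal(
            cfg.protein_attenuation * cfg.effect_log2fc_mean,
            cfg.protein_attenuation * cfg.effect_log2fc_sd,
            cfg.n_proteins,
        )
    )
    atten_noise = rng.normal(0.0, 0.1, cfg.n_proteins)
    prot_mag = own_mag.copy()
    shared = cfg.protein_attenuation * gene_mag[partner_t] + atten_noise[mapped_idx]
    prot_mag[mapped_idx[pair_both]] = shared[pair_both]
    prot_mag = np.maximum(prot_mag, _PROT_EFFECT_FLOOR)
    prot_null = np.clip(rng.normal(0.0, 0.1, cfg.n_proteins), -_PROT_NULL_CEIL, _PROT_NULL_CEIL)
    prot_log2 = np.where(is_dep, sign_p * prot_mag, prot_null)
    prot_p = np.where(
        is_dep,
        rng.uniform(_P_DIFF_LOW, _P_DIFF_HIGH, cfg.n_proteins),
        rng.uniform(_P_NULL_LOW, _P_NULL_HIGH, cfg.n_proteins),
    )
    unique_peptides = rng.integers(1, 16, cfg.n_proteins)

    transcript_table = pd.DataFrame(
        {
            "transcript_id": transcript_ids,
            "log2fc": np.round(log2fc, 6),
            "pvalue": np.round(gene_p, 8),
        }
    )
    protein_table = pd.DataFrame(
        {
            "protein_id": protein_ids,
            "ratio": np.round(np.power(2.0, prot_log2), 6),
            "pvalue": np.round(prot_p, 8),
            "unique_peptides": unique_peptides,
        }
    )

    # --- truth tables -------------------------------------------------------
    g_status = _status(deg_t, sign_t)
    p_status = _status(is_dep, sign_p)
    truth_pairs = pd.DataFrame(
        {
            "protein_id": protein_ids[mapped_idx],
            "transcript_id": transcript_ids[partner_t],
            "gene_status": g_status[partner_t],
            "protein_status": p_status[mapped_idx],
        }
    )
    truth_pairs["corr_class"] = [
        classify_pair(g, p).value
        for g, p in zip(truth_pairs["gene_status"], truth_pairs["protein_status"])
    ]

    # --- BLAST evidence ------------------------------------------------------
    blast_rows: list[tuple] = []

    def _hit(q: str, s: str, pident: float, evalue: float, bitscore: float) -> None:
        length = int(rng.integers(150, 601))
        blast_rows.append(
            (q, s, round(pident, 3), length, 0, 0, 1, length, 1, length,
             float(evalue), round(float(bitscore), 1))
        )

    main_bitscore = rng.uniform(300.0, 900.0, n_mapped)
    main_evalue = np.power(10.0, -rng.uniform(20.0, 120.0, n_mapped))
    decoy_better = rng.random(n_mapped) < 0.10   # second qualifying hit, lower bitscore
    decoy_fail = rng.random(n_mapped) < 0.10     # extra hit failing the filter
    for j in range(n_mapped):
        pid = protein_ids[mapped_idx[j]]
        _hit(pid, transcript_ids[partner_t[j]], 100.0, main_evalue[j], main_bitscore[j])
        if decoy_better[j]:
            other = int(rng.integers(cfg.n_transcripts))
            if other == partner_t[j]:
                other = (other + 1) % cfg.n_transcripts
            _hit(pid, transcript_ids[other], 100.0,
                 10.0 ** -float(rng.uniform(15, 60)),
                 max(main_bitscore[j] - float(rng.uniform(20, 150)), 60.0))
        if decoy_fail[j]:
            other = int(rng.integers(cfg.n_transcripts))
            if j % 2 == 0:  # fails the identity filter
                _hit(pid, transcript_ids[other], float(rng.uniform(80.0, 99.8)),
                     10.0 ** -float(rng.uniform(15, 60)), float(rng.uniform(100, 400)))
            else:  # fails the E-value filter
                _hit(pid, transcript_ids[other], 100.0,
                     10.0 ** -float(rng.uniform(2.0, 7.9)), float(rng.uniform(100, 400)))
    # unmapped proteins: half carry hits that fail the filter, half carry none
    for r, i in enumerate(unmapped_idx):
        if r % 2 == 0:
            other = int(rng.integers(cfg.n_transcripts))
            if r % 4 == 0:
                _hit(protein_ids[i], transcript_ids[other], float(rng.uniform(80.0, 99.8)),
                     10.0 ** -float(rng.uniform(15, 60)), float(rng.uniform(100, 400)))
            else:
                _hit(protein_ids[i], transcript_ids[other], 100.0,
                     10.0 ** -float(rng.uniform(2.0, 7.9)), float(rng.uniform(100, 400)))
    blast_hits = pd.DataFrame(blast_rows, columns=BLAST_COLUMNS)

    # --- term annotation ------------------------------------------------------
    annotation: dict[str, TermAnnotation] = {}
    truth_term_rows = []
    if cfg.n_terms:
        sizes = rng.integers(cfg.term_size_range[0], cfg.term_size_range[1] + 1, cfg.n_terms)
        enriched_set = set(
            rng.choice(cfg.n_terms, size=cfg.n_enriched_terms, replace=False).tolist()
        )
        same_pool = mapped_idx[
            (truth_pairs["corr_class"] == CorrClass.SAME_TREND.value).to_numpy()
        ]
        same_partner = partner_t[(truth_pairs["corr_class"] == CorrClass.SAME_TREND.value).to_numpy()]
        deg_pool = np.flatnonzero(deg_t)
        dep_pool = np.flatnonzero(is_dep)
        if enriched_set:
            if len(same_pool) == 0:
                raise ConfigError(
                    "designed enrichment requires at least one same-trend pair; "
                    "increase frac_deg/frac_dep/layer_coupling or set n_enriched_terms=0"
                )
            if len(deg_pool) < _DEG_LOAD_MIN or len(dep_pool) < _DEP_LOAD_MIN:
                raise ConfigError(
                    "too few differential features to load enriched terms decisively"
                )
        partner_of = dict(zip(partner_t.tolist(), mapped_idx.tolist()))
        for j in range(cfg.n_terms):
            term_id = f"KO{j:04d}"
            s = int(sizes[j])
            if j in enriched_set:
                n_corr = int(min(len(same_pool), rng.integers(1, 3)))
                corr_sel = rng.choice(len(same_pool), size=n_corr, replace=False)
                corr_t = same_partner[corr_sel]
                deg_load = min(max(_DEG_LOAD_MIN, round(_DEG_LOAD_FRAC * s)), len(deg_pool))
                extra_deg = rng.choice(
                    np.setdiff1d(deg_pool, corr_t), size=max(deg_load - n_corr, 0), replace=False
                )
                member_t = set(corr_t.tolist()) | set(extra_deg.tolist())
                non_deg = np.setdiff1d(np.flatnonzero(~deg_t), np.array(sorted(member_t), dtype=int))
                fill = rng.choice(non_deg, size=max(s - len(member_t), 0), replace=False)
                member_t |= set(fill.tolist())
                dep_load = min(max(_DEP_LOAD_MIN, round(_DEP_LOAD_FRAC * s)), len(dep_pool))
                extra_dep = rng.choice(dep_pool, size=dep_load, replace=False)
                member_p = {partner_of[t] for t in member_t if t in partner_of}
                member_p |= set(extra_dep.tolist())
                enriched = True
            else:
                member_t = set(rng.choice(cfg.n_transcripts, size=s, replace=False).tolist())
                # protein members: non-differential mapped partners only, so a
                # null term can never fire at the protein layer (see methods)
                member_p = {
                    partner_of[t]
                    for t in member_t
                    if t in partner_of and not is_dep[partner_of[t]]
                }
                enriched = False
            members = frozenset(transcript_ids[sorted(member_t)]) | frozenset(
                protein_ids[sorted(member_p)]
            )
            annotation[term_id] = TermAnnotation(term_id, f"pathway {j:04d}", members, "KEGG")
            truth_term_rows.append({"term_id": term_id, "enriched": enriched})

    truth_terms = pd.DataFrame(truth_term_rows, columns=["term_id", "enriched"])

    return SyntheticDataset(
        config=cfg,
        transcript_table=transcript_table,
        protein_table=protein_table,
        blast_hits=blast_hits,
        annotation=annotation,
        truth_pairs=truth_pairs,
        truth_terms=truth_terms,
        unmapped_proteins=sorted(protein_ids[unmapped_idx].tolist()),
    )


_FILES = {
    "transcripts": "transcripts.tsv",
    "proteins": "proteins.tsv",
    "blast_hits": "blast_hits.tsv",
    "annotation": "annotation.gmt",
    "namespaces": "namespaces.tsv",
    "truth_pairs": "truth_pairs.tsv",
    "truth_terms": "truth_terms.tsv",
    "config": "config.yaml",
}


def write_dataset(dataset: SyntheticDataset, directory: str | Path) -> dict[str, Path]:
    """Write the four pipeline inputs plus truth files; returns the manifest.

    Everything round-trips losslessly through the package readers.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {key: directory / name for key, name in _FILES.items()}
    try:
        dataset.transcript_table.to_csv(paths["transcripts"], sep="\t", index=False)
        dataset.protein_table.to_csv(paths["proteins"], sep="\t", index=False)
        write_blast_tabular(dataset.blast_hits, paths["blast_hits"])
        write_gmt(dataset.annotation, paths["annotation"])
        with open(paths["namespaces"], "w") as fh:
            for t in dataset.annotation.values():
                fh.write(f"{t.term_id}\t{t.namespace}\n")
        dataset.truth_pairs.to_csv(paths["truth_pairs"], sep="\t", index=False)
        dataset.truth_terms.to_csv(paths["truth_terms"], sep="\t", index=False)
        with open(paths["config"], "w") as fh:
            yaml.safe_dump(dataset.config.to_dict(), fh, sort_keys=True)
    except OSError as exc:
        raise OSError(f"failed writing dataset file under {directory}: {exc}") from exc
    return paths


def read_dataset(directory: str | Path) -> SyntheticDataset:
    """Read back a dataset written by :func:`write_dataset`."""
    directory = Path(directory)
    paths = {key: directory / name for key, name in _FILES.items()}
    cfg = SimulationConfig.from_file(paths["config"])
    ns_map = read_namespace_map(paths["namespaces"]) if paths["namespaces"].exists() else None
    truth_pairs = pd.read_csv(paths["truth_pairs"], sep="\t", dtype={"protein_id": str, "transcript_id": str})
    truth_terms = pd.read_csv(paths["truth_terms"], sep="\t", dtype={"term_id": str})
    ds = SyntheticDataset(
        config=cfg,
        transcript_table=read_transcript_table(paths["transcripts"]),
        protein_table=read_protein_table(paths["proteins"]),
        blast_hits=read_blast_tabular(paths["blast_hits"]),
        annotation=read_gmt(paths["annotation"], namespace_map=ns_map),
        truth_pairs=truth_pairs,
        truth_terms=truth_terms,
    )
    mapped = set(ds.truth_pairs["protein_id"])
    ds.unmapped_proteins = sorted(set(ds.protein_table["protein_id"]) - mapped)
    return ds
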