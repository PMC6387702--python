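# Methods

## Scope and model

`omicslink` integrates a quantified transcriptome and a quantified proteome
from the same contrast (treatment over control) in a species without a
reference genome. The integration unit is the *correlation pair*: one
protein matched to one transcript by sequence-similarity evidence. All
statistics downstream — concordance classes, rank correlations, dual-layer
enrichment — are computed over these pairs. Differential testing itself is
upstream: the package consumes per-feature fold changes and P-values as
given and never recomputes them.

## ID mapping

BLAST tabular hits (the standard 12-column layout) are filtered on
`pident >= min_identity` (default 100) and `evalue <= max_evalue`
(default 1e-8). Both comparisons are inclusive — the usual reading of a
threshold table — and identity is compared after rounding to three
decimals, the precision BLAST prints, so a stored 99.9996 equals a printed
100.000. When several hits survive for one protein, the pair is chosen
deterministically: highest bitscore, then lowest E-value, then highest
identity, then lexicographically smallest transcript ID. The published
analyses this mirrors do not state a tie policy; a fixed rule was chosen
over an arbitrary one so output is identical across platforms. Several
proteins may map to the same transcript (nothing in the data model forbids
it); each such pair is counted separately downstream. Conservation —
`|pairs| + |uncorrelated proteins| = |proteins|` — is asserted inside
`build_pairs` and property-tested.

## Screening

DEG rule: `log2FC >= log2(f_g)` (UP) or `<= -log2(f_g)` (DOWN) with
`P <= p_g`; defaults `f_g = 2.0`, `p_g = 0.05`. The equivalent linear
formulation "fold change <= 0.5" for down-calls is exactly
`log2FC <= -1`. DEP rule: linear `ratio >= f_p` or `<= 1/f_p` with
`P <= p_p`; defaults `f_p = 1.2`, `p_p = 0.05`, plus an eligibility gate
`unique_peptides >= 1` (proteins identified by a single peptide are kept by
default; the gate exists because one-hit identifications are often
excluded in stricter workflows). All comparisons are inclusive. The
protein fold-change default of 1.2 follows the operative text of the
source analyses; a published parameter table prints 1 in one place, but a
threshold of 1 would make every quantified protein differential, which is
inconsistent with the reported counts, so 1.2 is the default and the value
is configurable.

## Concordance classes and Spearman

The class of a pair is a pure function of its two statuses: same direction
at both layers → Same Trend; differential at both but discordant →
Opposite; differential at exactly one layer → DEPs_NDEGs / NDEPs_DEGs;
neither → NDEPs_NDEGs. "Same trend" is defined on post-screening statuses,
not on raw sign agreement of sub-threshold effects — a pair whose protein
moved 5 % in the same direction as a strong transcript response is *not*
concordant under this definition.

Spearman coefficients are midrank-based (Pearson correlation of
average-rank-transformed vectors, via `scipy.stats.spearmanr`), which is
exact under ties; the classical `1 - 6Σd²/(n³-n)` shortcut differs only in
tied data and agrees to 3 d.p. on the bundled reference set. Rank
invariance means linear vs log protein ratios give identical coefficients;
this is asserted in the tests. An empty or rank-degenerate class has no
defined coefficient; it is reported as `0.0` with an explicit
`degenerate` flag rather than NaN, mirroring how empty classes are
conventionally printed, and the flag prevents silent propagation.

The ratio-of-ratios diagnostic is `2^gene_log2FC / protein_ratio`: > 1 for
up-regulated pairs (and < 1 for down-regulated pairs) means the transcript
response is larger in magnitude than the protein response.

Hierarchical clustering of the same-trend pairs uses average linkage on
Euclidean distances over the 2-column matrix (gene log2FC, protein log2
ratio); linkage method and metric are exposed. Dendrogram leaf order is
made deterministic by placing, at every internal node, the subtree
containing the lower original row index first.

## Enrichment

Per layer, the test is the upper-tail hypergeometric probability
P(X ≥ k) for overlap k between a term's members and the differential set,
with K = term size, n = differential-set size and N = universe size, all
counted after intersecting memberships with the universe
(`scipy.stats.hypergeom.sf`, which accumulates log point masses; an exact
integer enumeration oracle backs it in the tests). Significance is raw
`p < alpha` (strict, default 0.05) with **no** multiple-testing
correction, matching the convention of the joint analyses this package
reproduces; Benjamini–Hochberg adjustment is available behind a flag,
default off. A term is *jointly significant* iff significant at both
layers — a conjunction of the per-layer flags, never a recomputation.

The background (universe) is configurable: `annotated` (default) uses all
quantified features carrying at least one annotation in the tested
namespace; `quantified` uses every quantified feature. The published
tables do not determine which background was used; `annotated` is the more
common convention for sparsely annotated non-model species.

Functional-class tabulation (GO/COG bar-chart style) counts term
assignments among a feature set; percentages divide by the number of
*annotated* input features, because features without any annotation in the
namespace carry no information about class composition.

Annotation terms store a single mixed member-ID set (matching the GMT
on-disk format, where one line may list transcript and protein IDs
together); per-layer member sets are derived by intersection with each
layer's universe at evaluation time.

## Synthetic data

The generator emulates the study conditions at desk scale. Defaults:
2 000 transcripts, 400 proteins (2 % unmapped), 5 % DEGs, 20 % DEPs
(matching the roughly 20 % DEP rate of the motivating study), concordance
1.0 (the study observed no opposite pair), gene effect |log2FC| ~
|N(2.5, 0.8)| floored at 1.25, protein effect = 0.5 × gene effect + noise
floored at 0.35 (the attenuation factor 0.5 reproduces the observed 2–9×
transcriptional overshoot and the wedge-shaped scatter), null effects
clipped inside the dead zones, 20 KEGG-style terms of 12–30 transcript
members, 3 of them designed enriched.

Layer coupling. The DEG and DEP indicator draws must be positively coupled
for a realistic number of doubly-differential pairs to exist at this
scale. Each mapped pair's transcript inherits its protein's differential
indicator with probability `layer_coupling` (default 0.15) and is an
independent Bernoulli(frac_deg) draw otherwise; coupling 1 with equal
fractions makes the two differential sets identical over mapped pairs, so
the same-trend count is Binomial(n_mapped, frac) — a property the tests
exploit. The marginal DEG rate among mapped transcripts is therefore
`coupling·frac_dep + (1-coupling)·frac_deg`, slightly above `frac_deg`;
unmapped transcripts use `frac_deg` exactly.

Decisive margins. Differential features receive P ~ U(1e-4, 0.04) and
effects beyond the screening thresholds with a fixed margin; null features
receive P ~ U(0.06, 1] and sub-threshold effects. Screening consequently
recovers the designed statuses *deterministically*, which is what licenses
the truth tables being exact. The generated P-values are drawn directly
(not produced by simulating a replicate-level test): the pipeline consumes
P-values as given, so the upstream test is out of scope.

Mapping evidence. Every mapped protein has one perfect-identity,
low-E-value hit; 10 % additionally carry a second qualifying hit with a
strictly lower bitscore (exercising the best-hit rule) and 10 % a hit
failing a filter. Unmapped proteins split between carrying only failing
hits (alternating identity failures and E-value failures, exercising both
rejection paths) and carrying no hits at all.

Term design. Designed enriched terms are loaded with one or two same-trend
pairs (both members annotated — these drive the `n_correlations` column),
DEG transcripts to half the term size, and DEP proteins to a quarter of
the term size, giving both layers overlaps far above the null expectation
(typical per-layer P between 1e-3 and 1e-8). Null terms draw their
transcript members uniformly from all transcripts — an honest null at the
transcript layer, used for the false-positive-rate calibration check — but
their protein members are restricted to the *non-differential* mapped
partners of those transcripts. A null term therefore has zero overlap with
the DEP set, cannot fire at the protein layer, and joint significance of a
null term is impossible by construction. This is a deliberate design
choice: it makes "exactly the designed terms are jointly flagged" a true
invariant of the generator rather than a knife-edge stochastic property,
at the cost that the protein layer's calibration is not exercised by the
null terms (its false-positive rate is structurally 0). Note also that
under the default `annotated` universe the transcript-layer null is
conservative: loading the enriched terms inflates the differential density
of the annotated background, so null-term P-values are stochastically
larger than uniform and the empirical false-positive rate sits well below
alpha. Under `universe="quantified"` the transcript-layer null is an exact
hypergeometric null.

What the generator does not emulate: read-level RNA-seq or spectrum-level
iTRAQ noise, replicate-level count distributions, correlated effect sizes
along pathways, many-to-one protein–transcript mappings, and incomplete /
biased annotation. Passing the recovery tests therefore demonstrates that
the pipeline's logic is correct under its stated rules, not that those
rules are robust to upstream measurement error in real data.

## Problem sizes and determinism

The bundled reference set has 15 pairs and runs in milliseconds. The
synthetic acceptance checks use the default 2 000 × 400 configuration over
20 seeds (truth recovery) and the calibration check over 100–200 seeds —
sizes chosen so the generator's asymptotics are visible while a full run
of the suite stays under half a minute. All randomness flows through
`numpy.random.default_rng` seeded from a single integer; identical config
and seed give byte-identical written datasets, and regenerating a run
report from unchanged inputs is byte-identical (the provenance block
records thresholds and input SHA-256 digests, never timestamps).

## Known limitations

- Best-hit pairing discards secondary qualifying hits; an all-hits mode
  would multi-count proteins and is not implemented.
- The enrichment test is one-sided (over-representation only).
- The empty-class Spearman sentinel (0 with a flag) is a reporting
  convention; consumers doing arithmetic on coefficients must honour the
  flag.
- With very small universes the hypergeometric test is conservative at
  any fixed alpha; no mid-P variant is offered.
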