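# Methods

## The model

A protein's *feature architecture* is the arrangement of annotated
features along its sequence: functional domains (Pfam, SMART,
transmembrane segments, signal peptides), secondary-structure elements
(helix, strand, coiled coil) and compositional properties
(low-complexity regions, biased composition).  Each feature occurrence
is an instance with 1-based inclusive start/end coordinates.  The
working hypothesis is that two proteins performing the same function
tend to share a similar feature architecture even when their sequences
have diverged beyond the reach of alignment-based search, so ranking a
pre-annotated proteome by architecture similarity proposes a
*functionally equivalent* protein for a query.

Four scoring functions compare a query architecture Q with a subject P,
all bounded in [0, 1].  Writing N^Q, N^P for the numbers of distinct
feature types, N^PQ for the shared types and N_i for instance counts:

* **MLS** (modified Lin score)
  `0.365 · N^PQ/(N^P + N^Q − N^PQ) + 0.635 · exp(−Σ_i |N_i^P − N_i^Q| / N_max)`
  with `N_max = Σ_i max(N_i^P, N_i^Q)`, both sums over the *union* of
  feature types with absent counts 0.  This is the only score in which
  features private to one protein lower the result.  The two constants
  are the historical Jaccard/duplication weights renormalised after
  dropping the order-dependent third term (order is undefined once
  features may overlap); they are configurable.
* **MS** (multiplicity similarity)
  `Σ_{i shared} ω_i · N_i^P N_i^Q / max(N_i^P, N_i^Q)²`.
  With uniform weights `ω_i = 1/N^Q` this is **MS_uni**; note the sum
  runs over shared features only, so MS_uni reaches 1 exactly when all
  of Q's features are shared.  With proteome-frequency weights
  `ω_i = Σ_k N_i^{P_k} / Σ_k Σ_{j∈Q} N_j^{P_k}` over a reference
  proteome {P_k} it is **MS_st**.
* **CS** (clan similarity): the same instance-count agreement computed
  on Pfam-clan totals, normalised by the query's clan count C^Q.
  Different domains from one clan are structurally related and often
  functionally interchangeable; CS credits such swaps.
* **PS** (positional similarity)
  `Σ_{i shared} (ω_i/N_i^Q) Σ_j (1 − min_l |q_j − p_l|)`, where q_j, p_l
  are instance centers divided by protein length.  Relative coordinates
  keep, say, C-terminal anchors comparable across different lengths.
  PS shares MS_st's weights.

The composite score is `α·MS_st + β·CS + γ·PS` with α : β : γ = 3 : 1 : 1
(0.6, 0.2, 0.2) by default.  The coefficients are deliberately not
optimised against any benchmark: multiplicity of shared features is
treated as the primary signal, clans and positions as moderate
supplementary evidence, and tuning them against an enzyme-only label
set would bias the tool toward enzymes.

### The weight-direction ambiguity

The proteome-frequency formula above gives *frequent* features larger
weights, yet the motivating intuition — shared rare features are
stronger evidence of shared function than shared promiscuous ones —
points the other way.  Both readings are defensible and the source
material for this method states both.  This package implements both:
`proteome_weights(..., scheme="frequency")` (the default, the formula
as printed) and `scheme="inverse"`, which sets ω_i ∝ 1/total_i over the
query's features with nonzero reference totals.  The switch is exposed
on the CLI (`--weight-scheme`).  Neither choice affects MS_uni, MLS or
CS.

### Conventions for degenerate inputs

* A featureless query or subject: every score is 0, the breakdown is
  flagged `degenerate` (the MLS is 0/0 there; a constant offset within
  one query's search cannot change rankings).
* Query without clan-assigned Pfam domains: CS = 0, again constant
  within a search, so rankings are unaffected and α, β, γ are *not*
  renormalised.
* None of the query's features occurs in the reference proteome:
  all-zero weight vector, flagged; MS_st and PS are then 0.
* Uniform weights over an empty query: empty vector, flagged.

When the query belongs to the search proteome it contributes to the
reference totals like any other member; it is never added when absent.

## Search statistics

All scores of one query against a proteome form a sample on [0, 1]; a
beta distribution is fitted by the method of moments (the beta is
flexible in shape and lives exactly on the score range).  With sample
mean m and unbiased (n−1) variance v, `c = m(1−m)/v − 1`, shapes are
`(mc, (1−m)c)`.  The fit is degenerate when v ≤ 1e-14 (constant samples
leave rounding residue below that) or c ≤ 0; the p-value of the top
score x is the fitted upper tail `1 − F(x)`, reported as NaN with a
warning when the fit is degenerate.  The top score is part of the fit
sample by default (`exclude_top_from_fit` removes it); flagged
degenerate pairs stay in the sample by default
(`drop_degenerate_from_fit` removes them).  P-values are per query and
not adjusted for multiplicity.

Rankings are deterministic: score descending, competition ranks
(1, 1, 3, …) on exact float equality, protein id ascending within ties.

## Evaluation against EC labels

Functional equivalence is operationalised as sharing an EC number
prefix, compared field-wise on the dotted string (never numerically),
at a configurable level 1–4.  The query's self-hit is removed from its
ranking first.  *Any-tie* fidelity counts a query as a success when any
protein in the rank-1 tie group matches; *strict* fidelity requires the
top rank to be a single matching protein.  Strict ≤ any-tie by
construction.  The p-value threshold curve reports coverage (queries
with top-hit p-value below the cutoff) and fidelity on that subset,
as observed — monotonicity is not assumed.  The comparison matrix bins
queries by best sequence-search E-value × top architecture-search
p-value (decade-structured default edges; E-value 0 in the smallest
bin) and counts, per cell, strict successes of each method.  Pearson
correlation between E-values and p-values is computed on the raw values
by default; a log10 switch floors non-positive entries at a tenth of
the smallest positive value.

## The synthetic proteome generator

The generator emulates the *structure* of an annotated proteome used
for benchmarking, not its biology:

* **Catalog** — 80 Pfam-like and 30 SMART-like domain types plus six
  canonical structural/compositional classes (`tmhmm:TM`, `signalp:SP`,
  `coils:CC`, `phd:H`, `phd:E`, `seg:LC`); 60% of Pfam types are
  assigned to one of 10 clans.
* **Background skew** — decoy proteins draw a Poisson(4) number of
  instances from a power-law (exponent 1.5) over feature types ranked
  with the structural classes first: transmembrane segments, helices
  and low-complexity regions are the ubiquitous annotations, and a few
  promiscuous domains dominate the remaining mass, as in real
  proteomes.
* **Planted families** — 50 families of 3 members within 500 proteins.
  A family core is a *specific* combination of 3–6 domains sampled
  uniformly from the domain catalog (what defines a real family is
  which domains it combines, not how common they are), anchored on at
  least one clan-assigned Pfam domain, extended by one structural
  feature with probability 0.5, with a 15% chance of a tandem duplicate
  per core feature.  Protein length (uniform 100–1000) is constant
  within a family, so zero-noise members are identical and score
  exactly 1 under every component.
* **Noise** — each member independently drops each core instance with
  probability 0.1 (never all of them), gains one spurious
  background-drawn instance with probability 0.05, and has its instance
  centers jittered by a normal with σ = 5% of protein length (spans
  preserved, clipped to protein bounds).
* **Labels** — each family shares one four-field dotted code; each
  decoy gets a unique code, so the EC-based evaluation path runs
  unchanged on synthetic data.

Everything is deterministic under the config seed, including the
on-disk TSV output.

What passing tests on this generator do **not** show: robustness to
correlated annotation errors (real predictors err systematically, not
independently), to domain-boundary disagreement between annotation
versions, to homologous-but-not-equivalent proteins sharing partial
cores, or to sequence-level effects — sequences are not simulated at
all.  Absolute fidelity numbers on synthetic data therefore do not
transfer to real proteomes; the tests establish correctness of the
arithmetic and qualitative behaviour (recovery of planted structure,
tie inflation under Pfam-only comparison, p-value separation).

## Problem sizes used in the checks

The bundled acceptance script searches a 500-protein proteome
(50 planted families of 3) with all 150 family members as queries, under
zero noise and under the default noise; the tie-structure comparison
runs all 500 proteins as queries against the full and the Pfam-only
restriction of the identical-copy proteome — exact score ties require
identical architectures, so the noise-free proteome (standing in for
real annotation duplicates) is where content ties are visible.  Beta
recovery uses n = 10,000 samples per shape pair.

## Feature dotplot

For one query–subject pair, every shared feature contributes one
diagonal segment per (query instance, subject instance) pair — the
information-preserving reading when instance counts differ — from
(q_start, p_start) to (q_end, p_end); the slope is the inclusive-length
ratio.  The query runs on the x-axis, the subject on the y-axis (a
convention; nothing downstream depends on it).  Features private to one
protein become margin marks on that protein's axis.  The embedded
amino-acid dotplot marks every exact w-mer match (default word size 3);
it requires both sequences.  SVG and PNG output, plus a bit-exact TSV
dump of segments and dots for testing.

## Known limitations

* Identical domains reported by two annotation sources (e.g. Pfam and
  SMART) remain distinct feature types; no cross-namespace
  deduplication is attempted.
* Importers exist for HMMER `--domtblout` only; outputs of
  SignalP/TMHMM/COILS/seg change format across versions and must be
  converted to the interchange TSV by the user.
* The beta null is fitted to the very scores it judges; with small
  proteomes (tens of proteins) the fit is unstable and p-values should
  be read qualitatively.
* Scores are content/position-based only; feature order is ignored by
  design (undefined under overlaps).
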