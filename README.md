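# fact — feature-architecture comparison for functional annotation

`fact` searches for **functionally equivalent proteins** by comparing
*feature architectures* — the arrangement of functional domains (Pfam,
SMART, transmembrane segments, signal peptides), secondary-structure
elements and compositional properties along a protein sequence —
instead of the sequences themselves.  It is aimed at annotating
proteins whose sequences have diverged beyond the reach of BLAST-style
search, or whose functional counterparts are not homologs at all: given
a query and a pre-annotated proteome, it ranks every protein by
architecture similarity, attaches a beta-distribution p-value to the
best hit, and draws a *feature dotplot* for visual curation of any
query–hit pair.

## Scores

For a query Q and subject P with N^Q, N^P distinct feature types, N^PQ
shared types and per-feature instance counts N_i:

* **MLS** — modified Lin score,
  `0.365·N^PQ/(N^P+N^Q−N^PQ) + 0.635·exp(−Σ|N_i^P−N_i^Q|/N_max)`,
  `N_max = Σ max(N_i^P, N_i^Q)`; features private to one protein lower it.
* **MS_uni / MS_st** — multiplicity similarity
  `Σ_{i shared} ω_i·N_i^P N_i^Q/max(N_i^P,N_i^Q)²`, with uniform weights
  `ω_i = 1/N^Q` (MS_uni) or weights from feature frequencies in the
  search proteome (MS_st).
* **CS** — the same agreement computed on Pfam-clan instance counts,
  normalised by the query's clan count.
* **PS** — positional similarity of shared features via relative
  instance centers, `Σ (ω_i/N_i^Q) Σ_j (1 − min_l |q_j − p_l|)`.
* **composite** — `0.6·MS_st + 0.2·CS + 0.2·PS` (the 3:1:1 ratio;
  coefficients configurable, deliberately not optimised).

The p-value of the top hit is one minus the CDF of a beta distribution
fitted to all of the query's scores by the method of moments.  See
`docs/methods.md` for conventions, degenerate cases and the
frequency-vs-inverse-frequency weighting switch.

## Worked example

Simulate a small annotated proteome with planted families, then search
it with one family member as the query:

```sh
$ fact simulate --seed 5 --n-proteins 60 --n-families 8 --family-size 2 --out-dir demo
$ fact search --proteins demo/proteins.tsv --features demo/features.tsv \
      --clans demo/clans.tsv --query F000_0 --exclude-self --out-dir demo/out
F000_0: best fact hit F000_1 score=0.785756 p-value=0.009191885652195135
```

`F000_1` is the planted co-member of the query's family; its composite
score 0.786 stands out from the proteome (p ≈ 0.009).  The report file
shows the per-score breakdown of the top hits:

```
$ head -4 demo/out/search_F000_0.tsv
# query: F000_0
rank	protein_id	ms_uni	ms_st	cs	ps	mls	fact	tie_group
1	F000_1	0.916667	0.682927	1.000000	0.879998	0.807396	0.785756	1
2	D0033	0.166667	0.634146	0.000000	0.606364	0.325808	0.501761	1
```

Reading rank 1: the hit shares almost all of the query's feature types
with matching instance counts (MS_uni 0.92), all of its Pfam clans
(CS 1.0), and the shared features sit at similar relative positions
(PS 0.88); the runner-up decoy `D0033` shares only ubiquitous features
and no clan.  `fact score-pair` prints the same six numbers for any
single pair, and

```sh
fact dotplot --proteins demo/proteins.tsv --features demo/features.tsv \
     --query F000_0 --subject F000_1 --out pair.svg
```

renders the feature dotplot (shared features as colored diagonals whose
slope is the instance length ratio; query-only/subject-only features as
axis-margin marks).  `fact import` converts HMMER `--domtblout` files
to the two-file TSV interchange format (`proteins.tsv`: id + length;
`features.tsv`: id, feature, start, end), and `fact evaluate`
benchmarks search fidelity against a label table of four-field EC-style
codes.

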