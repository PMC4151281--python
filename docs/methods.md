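# Methods

## Scope and model

The package infers orthologous groups (OGs) in a multi-copy gene family
across four species on the fixed topology ((Vv,At),(Os,Ma)) — a
slow-evolving dicot reference (Vv), a fast dicot (At) and two monocots
(Os, Ma). An OG is the set of present-day copies descending from one
gene in the monocot/dicot common ancestor. The method is similarity-
based, not tree-based: it assumes (a) a higher local-alignment score
means a smaller protein distance, and (b) for each query-species gene
the smallest distance is found in an orthologue of the subject species.
Assumption (b) fails for strongly rate-shifted sequences, which is why
the pipeline carries explicit score thresholds and an *unassignable*
status instead of forcing every sequence into a group.

## Scoring

Smith–Waterman local alignment with affine gaps, delegated to
Biopython's `PairwiseAligner`. Gap costs follow the BLAST convention —
a gap of length k costs `gap_open + k·gap_extend` (defaults 11 + k) —
implemented as aligner penalties open = −(gap_open+gap_extend),
extend = −gap_extend. Raw scores map to bits via the Karlin–Altschul
transformation (λ = 0.267, K = 0.041, the gapped BLOSUM62/11/1
constants). E-values are **not** computed in-house (they depend on
database size and composition); operations that need them ingest
precomputed 12-column tabular hits.

All grouping thresholds are interpreted as bit scores and are
configurable per species. The study defaults mirror the NAC analysis:
exclusion below 170 / retention above 250 bits for At (and Os, whose
bound was only reported qualitatively), 130/200 for Ma. Scores between
the two bounds are *borderline*: reported, excluded from groups. On
the published data this zone is empty, so the distinction does not
change results there.

## Grouping rules

* **Anchoring** takes the single best reference hit; co-best ties
  (within `tie_epsilon`, default 5 bits — the published account says
  only "very similar scores", so this is a knob) resolve provisionally
  to the lexicographically smallest reference id and are flagged for
  verification.
* **Cross-verification** tallies the groups of the best hits in the
  three other species; 2 of 3 must agree. A species whose co-best hits
  span ≥2 groups casts no vote; two silenced species, or fewer than two
  votes, or no majority ⇒ unassignable. Query–query votes only count
  when the hit clears both species' exclusion thresholds, so random
  best hits among unrelated sequences cannot vote.
* **Reference self-grouping** applies the same majority rule to
  reference sequences that anchor nobody; a reference sequence that
  anchors its own group never migrates.
* **Lineage-specific groups** are seeded by reciprocal best hits among
  threshold-excluded non-reference sequences (scores above both
  species' exclusion thresholds) and closed transitively. A remaining
  singleton then joins the component of its best qualifying hit — a
  deliberate extension of plain reciprocal-best seeding, mirroring the
  anchor logic, without which the extra copies of multi-copy
  lineage-restricted families stay stranded as singletons.
* **Nomenclature**: cluster number of the reference members (from a
  config TSV) plus letters assigned within each cluster by ascending
  smallest reference id; an override table can reproduce historical
  labels exactly. Groups without reference members get lineage labels
  (MS monocot-specific, DS dicot-specific, XS mixed), numbered when
  repeated. `merge_groups` records explicit merges (e.g. joining a
  dicot-specific and a monocot-specific remnant of one ancestral gene).

Determinism: every tie anywhere (anchor ties, closest-pair ties in
clustering, ordering of outputs) breaks on lexicographic ids, so a run
is reproducible across input orderings and platforms.

## Companion analyses

* **Tandem duplication**: family genes on one chromosome chain into a
  cluster when consecutive members are separated by ≤ `max_intervening`
  (default 10) other annotated genes; intervening counts use the rank
  of *all* annotated genes in the GFF3. The boundary is inclusive and
  clusters are maximal (transitive closure).
* **Segmental duplication**: counts syntenic pairs with family genes on
  both sides (a one-sided mode exists for sensitivity analysis);
  reports distinct family genes involved.
* **Gene structure**: intron phases are cumulative CDS length mod 3;
  subdomains (input coordinates, 1-based protein positions) map to the
  CDS exon holding the majority of their codons (codon located by its
  middle nucleotide; ties to the earlier exon). The decision table
  distinguishes canonical (3 exons, phases [1,0], A–B exon 1, C–D
  exon 2), first/second intron loss, mono-exonic, extra N-terminal
  exons, and counts extra TRR exons; anything else is labelled `other`,
  never an exception. UTR-only exons are ignored. Motif-based subdomain
  detection is out of scope — coordinates are an input.
* **Copy number**: per-OG species counts (pseudogene-flagged members
  excluded by default), row z-scores with sample SD (n−1, matching
  common heatmap software; population SD available), zero-variance rows
  mapping to zeros, Euclidean distances, and WPGMA/McQuitty
  agglomeration: d(ij,k) = (d(i,k)+d(j,k))/2 with merges drawn at
  d(i,j)/2, ties on smallest index pair. scipy's `weighted` linkage is
  the independent cross-check in the tests (its heights are the full
  pair distances, i.e. exactly twice ours).
* **Markov clustering**: plain MCL (expansion 2, configurable
  inflation, pruning at 1e−5, convergence 1e−8) on a symmetrised
  similarity graph — edge weights −log10(e-value) capped at 200 under
  an e-value cutoff (1e−10), or raw bit scores for in-house hits;
  self-loops at the maximum incident weight. This is a *behavioural*
  comparator: the species-aware normalisation of OrthoMCL-style tools
  is intentionally not reproduced, so cluster counts on real data are
  not expected to match any specific tool's output. At extreme
  inflation (≳12) even a clique fragments into singletons, which is the
  expected flow-clustering behaviour; the sound invariants (output is a
  partition; disconnected components never merge; column stochasticity
  after every inflation) are what the tests enforce.

## Simulator

`synthetic_data.simulate` evolves `n_ancestral_genes` unrelated random
proteins (default 20 × 350 residues) down the fixed topology. Default
branch lengths (substitution-probability units): stems 1.0, Vv 1.5,
At 3.0, Os 3.0, Ma 2.0 — a slow reference and faster query lineages.
Per branch, in order: WGD events (every gene doubled; the extra copy
kept with `retention_prob`, default one event at 0.3 on each of the At,
Os and Ma terminal branches), per-gene loss (0.1), tandem duplication
(Poisson, 0.05 per gene per branch; copies stay rank-adjacent through
descent until a neighbour is lost), optional terminal-branch rate
shifts (`divergent_fraction` of genes at `divergent_factor` = 5×), then
per-site substitution with probability `sub_prob_per_unit` × branch
length × rate multiplier. Replacements are drawn with probability
∝ exp(score/2) under the scoring matrix — enough realism to stress
bit-score ranking, but explicitly not a phylogenetic-grade model (no
rate heterogeneity across sites, no indels by default, no codon
structure). Chromosome layout: tandem copies separated by 0–3 filler
genes, everything else by 15–40, so the ≤10-intervening rule detects
exactly the tandem events; WGD copy pairs are emitted as a syntenic
pair list with block ids. Every branch has its own integer-keyed RNG
stream, so output is byte-identical per seed across platforms.

What the simulator does *not* emulate: real NAC divergence depths,
domain architecture (sequences are unrelated random proteins, so
between-family similarity is near zero, unlike real subfamilies that
share the NAC domain), annotation errors, and splice variants. Passing
recovery tests therefore shows the machinery is correct under the
stated model, not that real-data accuracy equals the simulated ARI.

Simulation score thresholds: a single line (exclusion = retention) at
1.35 bits per residue (472.5 bits at length 350), set from the score
distributions the generative model produces — orthologous best-vs-
reference scores concentrate around 1.6–1.9 bits/residue at the
default divergence, 5×-rate-shifted sequences below ~0.95, unrelated
pairs near 0.1 — leaving ≈4–5 standard deviations of margin on either
side. The toy and recovery experiments use these defaults unchanged.

## Recovery benchmark and problem sizes

The standard experiment runs 20 replicates of the default conditions
(~75–105 sequences each; replicate seeds `seed·1000 + r`), executing
simulate → all-vs-all scoring → full inference, and scores pair
precision/recall and the adjusted Rand index against the true
ancestral-gene partition, with non-grouped sequences counted as
singletons. Observed: pair precision 1.0 in every replicate; ARI
median ≈ 0.97. The recall shortfall is structural, not a bug: when the
*reference* lineage retains two copies of one ancestral gene, anchoring
genuinely splits that family into two groups — the same behaviour that
makes, on real data, two reference paralogues head separate letter
groups unless expert evidence merges them. The rate-shift experiment
(20 % of genes at 5×) uses 4 replicates; the shifted sequences' best
reference scores fall well under the threshold line and are flagged
species-specific essentially always.

These problem sizes (20 genes, 20 + 4 replicates, full-length
proteins) keep the whole benchmark around two minutes on one core
while leaving the acceptance margins wide.

## Known limitations

* The reference-paralogue split above bounds achievable pair recall;
  resolving it would need an explicit reference-merging step driven by
  within-reference similarity, which the algorithm deliberately leaves
  to expert review.
* Bit-score thresholds are global per species pair; composition-biased
  or partial sequences would need per-sequence calibration.
* The MCL comparator is not an OrthoMCL reimplementation (see above).
* Subdomain coordinates for structure classification are inputs;
  the classifier is only as good as the provided annotation.
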