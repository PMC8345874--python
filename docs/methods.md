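# Methods

## The harvesting rule chain

Candidate harvesting runs per gene, per new taxon, as a fixed sequence of
filters over engine-agnostic hit tables:

1. **Collection.** Targets of the profile-HMM search with e-value below the
   significance cutoff (default 10⁻¹⁰), ordered by significance, truncated
   to `max_candidates` (default 5). An empty list skips the gene for that
   taxon. The cutoff and cap are the workflow's standard operating point
   and are exposed on `HarvestConfig`.
2. **Informed reprioritization** (only when the metadata lists blast-seed
   taxa). The first listed seed taxon holding the gene supplies the BLAST
   query; the candidate list is rebuilt as the significant BLAST targets in
   BLAST order, intersected with the HMM set. A seed whose BLAST returns
   nothing significant is skipped in favour of the next; if every seed
   fails, the gene is skipped. Sequences found by BLAST but not by the HMM
   search are discarded, and HMM candidates without a significant BLAST hit
   drop off the list entirely. The second half of that sentence is a design
   choice: whether such candidates should instead keep tail positions is
   genuinely ambiguous, and the intersection semantics is the simpler,
   deterministic reading (documented here, not asserted as the only one).
3. **Orthogroup screen.** Any significant hit to a bacterial orthogroup
   discards the candidate; this rule dominates the requirement of a
   significant hit to one of the gene's expected orthogroups, which
   otherwise discards. Rule order is fixed and covered by an enumerated
   oracle test over all candidate-fate combinations.
4. **Database best-hit check.** The candidate's best database hit must
   belong to the retrieving gene. Under the default route a failure
   discards; under the informed route the candidate is retained with a
   note, and the (sequence, gene) pair is logged to
   `non-reciprocal_hits.txt`. A candidate with no database hit at all is
   treated as non-reciprocal. The e-value threshold for this check is not
   separately specified anywhere; the global cutoff is used uniformly.
5. **Tree check** (informed route, after alignment and gene-tree building).
   Candidates branching sister to or within a clade of leaves sharing their
   own higher taxonomy are moved, stably, ahead of candidates that do not.
6. **Finalization.** Rank 1 becomes the putative ortholog; the rest become
   putative paralogs with collision-free `<taxon>..p<k>` identifiers.

Ties in significance are broken by bitscore (descending) then target id
(lexicographic). The source workflow orders only by "significance"; the
extra keys exist purely to make identical inputs produce identical outputs.

**Redundancy removal.** Input proteomes are deduplicated by greedy
clustering, longest sequence first: a sequence joins the first cluster whose
representative it matches at ≥ 98% global identity, computed as matches in
a global pairwise alignment divided by the shorter sequence's length. This
reproduces the short-sequence-relative convention of the usual clustering
tools closely enough at the 0.98 operating point; the greedy order and the
identity definition are both fixed and tested against an all-pairs oracle.

## The nestedness test

"Sister to or within" is evaluated locally: at the candidate's attachment
node (with artifact degree-2 root nodes contracted so the test is invariant
under rerooting), the candidate qualifies if at least one adjacent subtree
is non-empty and all its leaves share the candidate's higher taxonomy. A
lone same-taxonomy sister leaf qualifies. Two caveats, verified by the test
suite: (i) with only *two* taxonomy groups in the tree, a sequence attaching
on the edge between the groups is vacuously "sister" to a pure clade, so
the test is only informative when the database's taxonomy is finer than a
single bipartition; (ii) a taxon that is the sole representative of its
group can never pass, so the check cannot promote its true ortholog either
— final authority stays with the curation decision file.

## Supermatrix conventions

Genes are concatenated in lexicographic name order (no order is inherent to
the data; lexicographic is platform-stable). Missing (taxon, gene) blocks
are filled with `-`: downstream inference treats gaps as missing data, which
is the desired semantics (an `X` would be scored as an observed unknown
residue). Partitions are 1-based inclusive and tile the matrix exactly; all
removal operations preserve survivor order and re-tile partitions, dropping
genes whose every column was removed. The occupancy filter runs genes first
(against the full taxon set), then taxa (against the kept genes), in a
single pass — iterating the two filters can oscillate, and the single pass
reproduces "genes present in ≥ X% of taxa" selections deterministically.
The length filter counts non-gap, non-X residues and removes sequences
strictly below half the alignment length (exactly half is retained).

## Site rates and heterotachy

The internal site-rate estimator is parsimony-based: Fitch minimum
substitution counts on a fixed tree (20-state, gaps contribute wildcard
state sets and never force substitutions; multifurcations folded child by
child), normalized by the number of scored leaves. The stepwise removal
tools only consume the *ranking* of sites, for which parsimony counts are a
faithful, dependency-free proxy; externally computed model-based rates can
be supplied as a two-column `site rate` table and used identically.

Heterotachy is scored per site as the ratio of smoothed rates on the
fast-taxon and slow-taxon leaf restrictions of the tree, with rate =
(steps + 0.5) / scored leaves; the half-substitution pseudocount keeps
ratios finite on invariant sites. The fast/slow taxon partition defaults to
the upper/lower halves of the mean tip-to-tip distance ranking — the
original analysis never defines its split, so the default is a documented
choice, overridable by the caller. p-values are empirical upper-tail
probabilities against a null ratio sample generated by simulating
rate-homogeneous alignments on the same tree (single-matrix LG+Γ reduction;
profile-mixture components are out of scope). Because the parsimony ratio
is a discrete statistic, the p-value at an observed atom is randomized:
p = (#{null > r} + U·(1 + #{null = r}))/(N + 1) with seeded uniform U,
which is exactly Uniform(0,1) under the null; `randomize=False` gives the
deterministic conservative variant. The calibration test (fraction of
p < 0.05 within three binomial standard errors at 2,000 sites, fixed seeds)
passes under the randomized definition and would not under heavy ties.

## Resampling, RTC, recoding

For subsampling percentage p the subset size is ⌊p·n/100⌋ and the replicate
count R(p) is the smallest R for which the union bound guarantees every
gene appears in at least one replicate with probability ≥ ci:
n(1 − s/n)^R ≤ 1 − ci, i.e. R = ⌈log((1−ci)/n) / log(1−s/n)⌉. The original
tool's "sampling confidence interval" semantics are not pinned down; the
union-bound coverage guarantee is this package's concrete reading.

RTC uses IC = 1 + p·log₂p + q·log₂q per internal branch of the ML tree,
where p and q normalize the bootstrap frequencies of the branch and of its
most frequent conflicting bipartition (conflict = all four split
intersections non-empty; only bipartitions observed in the bootstrap sample
are considered; no conflict ⇒ IC = 1). TC sums IC and RTC divides by
n_leaves − 3. Top-k% bins take round(k%·n) genes by descending RTC
(round matches 180 = 75% of 240 exactly; floor and ceiling do not for all
bins), ties broken by gene name.

SR4 recoding maps {A,G,N,P,S,T}→A, {C,H,W,Y}→C, {D,E,K,Q,R}→G,
{F,I,L,M,V}→T — the published four-class reduction, held in one editable
table (`explore.SR4_CLASSES`); gap and X pass through, any other character
is an error with its position.

## The simulators

`simulate_tree` is a pure-birth (Yule) process started from two lineages:
speciation waiting times are Exp(k·λ) over k active lineages, plus a final
Exp(n·λ) stretch of the terminal branches, giving expected mean branch
length 1/(2λ) (tested by Monte-Carlo against the closed form).
`simulate_alignment` draws root states from the stationary frequencies,
assigns each site one of the discrete-gamma categories (equal-probability
bins, mean-one rates), and propagates states with the matrix exponential of
the normalized LG rate matrix per branch and category; a heterotachy
specification rescales the branches of a taxon subset on a random site
subset and returns the site mask as truth. The LG exchangeabilities and
frequencies ship as a plain-text data file with a provenance note
(Le & Gascuel 2008).

`simulate_gene_families` defines the study conditions for the end-to-end
tests: 12 taxa (birth rate 4, keeping pairwise divergences inside the
informative range of the identity surrogate), 30 genes of 200 indel-free
sites, duplication probability 0.3 per gene (paralog copies re-descend the
duplication node's subtree with a 0.4-substitution stem and branches ×1.5),
contamination 0.1 per gene (one recipient among the held-out taxa receives
a sequence derived from the most distant donor lineage), loss 0.1 per
(gene, taxon), and three unrelated decoy sequences per proteome. The mock
search harness converts identities into e-value surrogates
(e = exp(−0.5·identity·length)) — a harness convention, not biology: it
preserves the ranking structure real search tools produce (orthologs above
paralogs above decoys) without modelling score statistics.

What passing these tests shows — and does not. The simulations are
indel-free, composition-homogeneous, single-matrix, and their contaminants
are whole-sequence transfers from within the same gene family; real
proteomes add fragmentary models, alignment error, compositional
heterogeneity and chimeric contigs. The end-to-end precision/recall of 1.0
(clean) and ≥ 0.9 (noisy regime) therefore validates the *logic* of the
rule chain, not the field error rate of any search engine.

## Numerical and interface choices

* Problem sizes in the acceptance script: the 72,632-column matrices use 16
  taxa and uniform random residues (the removal operations are pure column
  arithmetic, so sequence content is irrelevant); heterotachy calibration
  uses 16 taxa × 2,000 sites; recovery benchmarks 12 taxa × 30 genes.
* Ranking ties everywhere are resolved toward lower column index / smaller
  name so repeated runs and platforms agree byte-for-byte.
* Stop codons `*` are legal on input and removed only by the explicit
  stripping operation, never silently by a parser.
* Stage runners validate outputs with the declared kind's parser and carry
  captured stderr on failure; passthrough mode exercises pipeline plumbing
  without external binaries. Preset templates record the workflow's printed
  parameter sets (trimAl gap thresholds 0.2 / 0.01 / 0.80, BMGE gap rate
  0.3, MAFFT global-pair settings) as data, not hard-coded behaviour.
* Thread scheduling: more genes than threads ⇒ single-thread jobs with at
  most `n_threads` concurrent; otherwise threads split as evenly as
  possible (difference ≤ 1).

## Known limitations

Likelihood-based site rates, profile-mixture models, PMSF fitting, codon
models, indel processes, and interactive tree visualization are out of
scope. The decision file, not any automated rule, is the final authority on
ortholog assignments.
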