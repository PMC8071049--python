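# Methods

This note documents the models, rules and numerical choices behind
`nifloss`, in the spirit of a methods supplement: what each stage assumes,
which knobs matter, and what the synthetic benchmarks do and do not show.

## 1. Operon detection from gene order

Operons are inferred purely from gene adjacency in the annotation, not from
transcription evidence.

**Gap rule.** Two nif-tagged genes on the same contig belong to the same
cluster when strictly fewer than `max_gap` annotated genes (of any kind,
pseudogenes included) lie between them. `max_gap` defaults to 4, i.e. the
"< 4 intervening genes" reading, counted as ordinal difference minus one.
Strand is recorded but not used as a splitting criterion by default
(`respect_strand` exists for users who want it): conserved nif blocks are
co-oriented in practice, and requiring it would only remove sensitivity to
annotation strand errors.

**Bridging rule.** An isolated nif gene whose nearest nif clusters both
upstream and downstream (same contig) are multi-gene clusters is absorbed
into them, iterated to a fixed point. The rule does not require the flanking
clusters to belong to the same canonical operon — that case is ambiguous in
principle — so every bridged member is flagged in the output for review, and
the whole rule can be disabled (`bridging_enabled`).

**Template splitting.** Clusters are matched against the four canonical
templates (nifBSU, nifHDK, nifENXW, nifVZT). A super-operon such as
nifBSUHDKENXW yields one call per represented template, preserving member
order. A fused nifEN record satisfies both the nifE and nifN slots. A nifK
travelling with the nifENXW block while nifH/nifD are absent from the
cluster is attached to the nifENXW call as a cross-reference rather than
seeding a one-gene nifHDK call. Duplicate copies of a template member within
one cluster are reported as extras; a call is `complete` iff no template
member is missing, and co-located partial calls of the same template are
re-marked `split`.

**Dual operon sets.** Two calls of the same template separated by at least
`dual_set_min_separation` genes (default 50) or lying on different contigs
mark the genome as carrying two operon sets. The value 50 operationalizes
"distant positions": it only needs to sit far above any gap-rule merge range
(4) and below realistic genome sizes; detection is insensitive to its exact
value in that window. Calls are partitioned into co-located groups; the
group at the smallest genomic position is bookkeeping `set1`, and the
nif1/nif2 biology is assigned later (section 4). Three or more copies of a
template are flagged supernumerary.

## 2. Distances and trees

Protein distances ignore, per pair, every column where either row carries a
gap. Three models are exposed: the raw p-distance; the Poisson correction
−ln(1−p); and the 20-state correction d = −(19/20)·ln(1−(20/19)·p). The
third is the package default for tree building because it is additive in
expectation under a uniform-replacement substitution process (the same
process the simulator uses): with raw p-distances, short internal edges
under long terminal branches are systematically mis-resolved, which we
observed directly on simulated 10-taxon families. Distances past the
correction's domain (p ≥ 19/20) are set to a saturation ceiling (default 10)
and flagged.

Neighbor joining follows Saitou–Nei with the standard Q criterion. Two
determinism guarantees are added that the classical description leaves open:
ties in Q are broken by the lexicographic pair of cluster representatives
(each cluster represented by its smallest leaf label), and negative
branch-length estimates are clamped to zero. NJ is exact on additive
matrices — the anchor property the test suite enforces (RF = 0 to the
generating tree on random additive instances).

Bootstrap support resamples columns with replacement; each internal edge of
the full-data tree receives the percentage of replicate trees containing its
bipartition. Replicates are driven by a single seeded generator and rows are
sorted by taxon before resampling, so supports are invariant under taxon
reordering of the input alignment.

Robinson–Foulds distances are computed on normalized non-trivial bipartition
sets; restriction of those sets to a leaf subset equals the bipartition set
of the pruned tree, which makes leave-one-out congruence scans cheap
(no tree surgery).

Outgroup rooting places the root on the edge separating the outgroup clade,
splitting that edge's length evenly — a convention; the data cannot locate
the root along the edge.

## 3. Branch-length outliers

For each edge in scope, z = (length − median) / (1.4826·MAD) over the
in-scope edge lengths; edges with z > k (default 3) are flagged. When more
than half the lengths are identical the MAD collapses to zero while a real
outlier may exist; the scale then falls back to the mean absolute deviation
with the Gaussian consistency factor 1.2533. Each flag records whether the
edge attaches root-proximally (its parent node's root distance below the
median node depth).

## 4. Paralog selection and nif1/nif2 identity

When a genome carries several copies of the same gene in operon context, one
representative is chosen by congruence: each candidate joins a gene tree
with the single-copy sequences of the other genomes, and the candidate whose
tree has the smallest Robinson–Foulds distance to the species tree (pruned
to the shared taxa) wins; ties go to the shorter external branch, then the
lexicographically smaller locus tag. Candidates are scored one at a time
against a single-copy cohort rather than in one joint tree, to avoid
paralog attraction between the copies being compared.

Dual operon sets are labelled nif1/nif2 by affinity to a reference genome
whose labels are supplied externally (the literature-anchored convention).
For every gene tree containing the reference nif1 tip and both set tips of a
genome, the set with the smaller patristic distance to the reference nif1
votes nif1; the per-genome label is the majority across genes and the margin
is reported, so low-confidence assignments are visible. Genomes with a
single set default to nif1 (vertical presumption).

## 5. Transfer classification and Dollo losses

Per gene family and taxon, three signals are combined:

* **extra_phylum_hgt** — the taxon's external branch (or the internal branch
  subtending it with at most one sister, the paired-species pattern) is a
  flagged length outlier *and* is extreme: at least `extreme_depth_ratio`
  (default 1.0) times the gene tree's median root-to-tip depth. A branch
  carrying more change than a typical lineage accumulated since the root is
  implausible for a within-phylum origin; the criterion deliberately does
  not depend on where the near-saturated sequence happens to be placed,
  because that placement is unreliable. Root-proximal attachment is recorded
  as corroborating evidence rather than gating the verdict: in benchmark
  scenarios a depth-based root-proximality gate both missed erratically
  placed foreign sequences and admitted legitimately long basal branches.
* **intra_phylum_hgt** — no long-branch flag, but removing the taxon lowers
  the pruned RF distance to the species tree by at least
  `incongruence_margin` (default 2, the smallest possible RF change).
  On short, information-poor genes this margin also fires on ordinary
  estimation noise, so isolated intra-phylum signals should be read as
  placement anomalies, not confirmed transfers; the scenario headline
  accordingly counts only extra-phylum calls.
* **unresolved** — a long-branch flag short of the extreme bar.
* **vertical** — neither signal.

Gene-loss histories assume Dollo parsimony: a single gain at the MRCA of the
present taxa (or a user-pinned ancestor) and one loss per maximal absent
clade below it. This loss set is the unique minimum — splitting a loss adds
events, and raising one above a present leaf contradicts the data — and the
suite verifies it against exhaustive enumeration. The competing
no-losses-allowed explanation (one gain per maximal present clade) is
reported alongside for contrast.

## 6. The synthetic-data generator

The simulator produces the statistical structure the analysis assumes, with
every event logged as ground truth.

* **Species tree:** Yule (pure birth) with exponential waiting times,
  default 20 ingroup taxa at birth rate 1. One outgroup leaf (`OUT`) is
  attached below the ingroup root (stem 0.3×, outgroup branch 1.3× the mean
  ingroup depth) so that inferred trees can be outgroup-rooted the way the
  real workflow roots them; it carries markers but no nif genes.
* **Sequences:** gap-free; root sequence uniform over the 20 amino acids;
  along each edge every site is replaced with probability 1−exp(−rate·ℓ),
  the new state uniform over the other 19 letters. Default rate 0.1 per site
  per unit branch length keeps typical pairwise p-distances in the 0.1–0.4
  range where distance methods are well behaved. The expected p-distance
  between two tips has the closed form (19/20)·(1−∏ₑ(1−(20/19)·qₑ)) with
  qₑ = 1−exp(−rate·ℓₑ) over the connecting path; the calibration tests hold
  the simulator to it. Note the model applies at most one replacement per
  site per edge, so it is not a reversible CTMC; the expectation can exceed
  the uniform-stationary 19/20 on long edges.
* **Markers:** 31 alignments of 100 columns each (the species-tree signal),
  enough that the inferred species tree is essentially always exact at the
  default rate.
* **nif repertoire:** gained at the ingroup root; each edge loses the whole
  repertoire with `loss_prob_per_edge` (default 0.05), inherited by
  descendants — matching the diazotroph/non-diazotroph dichotomy. A lost
  lineage keeps a residual nifS or nifV with `residual_retention_prob`
  (default 0.1), recreating the observed pattern of isolated nif homologs in
  non-diazotrophs.
* **Gene order:** operon blocks embedded among unlabeled filler genes
  (fresh random sequences, unalignable by construction, so orthogrouping
  cannot absorb them); block order permuted per genome (translocation);
  single filler insertions inside operons with `insertion_prob` 0.2 ("a few
  genes between nifB and nifS"); fused nifEN with `fusion_prob` 0.1 (about
  the observed frequency); protein lengths default to 300 aa except the
  short accessory genes (nifX 137, nifW 106, nifZ 94, nifT 67 — the reported
  means, rounded).
* **Dual sets:** with `dual_set_prob` 0.3 one diazotroph clade of 2–4 leaves
  receives a second operon set copied from a donor lineage (sequences
  re-evolved from the donor's parent node down the recipient subtree), at a
  genomic position ≥ 60 genes away.
* **Extra-phylum transfers:** an event replaces a carrier's copy of a gene
  with a sequence evolved from the root along a branch `multiplier` (default
  5) times the mean root-to-tip depth — a long, basally attached foreign
  homolog. Targeting a lineage that lost the gene without residual is a
  configuration error.

Everything is driven by one seeded generator; the emitted files are
byte-identical across runs of the same scenario.

**What the simulator does not emulate:** insertions/deletions (no gaps),
empirical amino-acid exchangeabilities (WAG/LG), rate heterogeneity across
sites or lineages, genome rearrangements beyond operon-block permutation,
partial (single-gene) losses, pseudogenization, and annotation error.
Passing benchmarks therefore demonstrate the correctness and calibration of
the inference chain under its own assumptions, not robustness to every
artifact of real annotations; real-data users should inject externally
computed alignments, trees and orthogroups through the provided readers.

## 7. Benchmark problem sizes

The standing study conditions are 20-taxon scenarios, 31×100 marker columns,
13 nif families; scenario batteries run 100 replicates (60 in the
acceptance script) and oracle comparisons use hundreds of random instances
of ≤ 8–12 leaves, where exhaustive enumeration is exact. These sizes give
the oracles full coverage of the combinatorics while keeping any single
suite run in the tens of seconds.

## 8. Numerical and tie-breaking conventions

* NJ Q-ties: lexicographic cluster representatives; negative branch
  estimates clamped to 0.
* Outgroup rooting splits the root edge evenly.
* Copy-selection ties: shorter external branch, then locus tag.
* Fused nifEN in gene trees: the family's modal length decides how much of
  the fused sequence enters (nifE prefix / nifN suffix).
* MAD = 0 with spread: fall back to 1.2533 × mean absolute deviation.
* Gene trees need ≥ 4 tips; families with fewer carriers are skipped and
  their taxa receive no per-gene verdict (visible as absent rows in the
  evidence table).
* All randomness flows from `numpy.random.default_rng` seeded explicitly;
  derived seeds stay below 2³¹.
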