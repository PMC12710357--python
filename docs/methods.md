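# Methods

`cimsym` re-implements, as a tested library, the computational stages of a
family-wide survey of nutritional symbionts in bed bugs (Cimicidae). This
note documents the procedures, the modelling assumptions, the parameters
that matter, and the limits of what the synthetic-data tests demonstrate.

## Amplicon screening (`amplicon_filter`)

The screening stage assumes that true symbiont OTUs are abundant in 16S
amplicon data and that low-abundance signal is mostly bleed-through and
contamination. The chain is fixed:

1. **Taxonomic filter.** OTUs whose lineage string contains *Archaea*,
   *Eukaryota*, *Mitochondria*, or *Chloroplast* (case-insensitive, any
   rank) are removed.
2. **Abundance floor** (`threshold`, default 0.01). For each sample
   independently, any OTU holding strictly less than the threshold
   fraction of that sample's reads is set to zero there; a cell at
   exactly 1% is retained, and presence in other samples is never
   consulted. Sample totals for the rule are taken *after* the taxonomic
   filter (the earlier stage has already removed non-target reads). The
   operation is idempotent: totals only shrink, so surviving cells can
   only grow in relative abundance.
3. **Rarefaction** (`depth`, default 1000 reads; `seed`). Classic
   subsampling without replacement (multivariate hypergeometric draw per
   sample); samples below the depth are dropped and reported. Each
   rarefied count therefore has expectation `depth * count / total`.
4. **Dominant-OTU summary** (`top_k`, default 13, the figure convention
   of the source survey). OTUs rank by total count; ties break
   lexicographically by id.

## Contig binning (`symbiont_binning`)

Candidate contigs are recruited by having at least one hit to a target
genus, then validated by a majority vote over the best hit of every
annotated gene on the contig ("back-BLAST"): the bacterial genus with
the strict plurality of hits is the contig's origin. Three
operationalizations where the qualitative procedure needed a precise
rule:

* *predominant eukaryotic* means eukaryotic hits strictly outnumber the
  best bacterial genus tally;
* a tie for the best bacterial genus yields UNCLASSIFIED rather than an
  arbitrary pick;
* archaeal and viral hits vote for neither side.

One vote is counted per annotated gene (its best hit), not per HSP.
Bin statistics: genome size is the contig-length sum, GC% is computed
over non-N bases, and coding density uses the per-contig union of CDS
intervals (1-based inclusive, GFF-style), so overlapping CDS are not
double-counted.

## Strain deconvolution (`strain_deconvolution`)

A double infection — two strains of one genus in one host — shows up as
an excess of duplicated orthologs and as genes recovered twice on
contigs of distinct coverage. `detect_double_infection` reports the
fraction of present orthogroups with two or more copies and flags it at
a configurable threshold (default 0.2; "excess" has no canonical
value).

`split_by_coverage` works on log2 coverage, where sequencing depth is
approximately normal per strain (log-normal on the natural scale keeps
coverage positive and right-skewed). The threshold maximizes two-class
between-class variance (Otsu's criterion, exhaustive 1-D search) and is
placed at the midpoint between the adjacent class extremes, which makes
the split scale-equivariant and permutation-invariant. Two guards:

* **bimodality guard** — if the class means differ by less than
  log2(1.5), the bin is deemed unimodal and the split is *refused*
  (a distinct outcome, not an error);
* **intermediate band** (`band_fraction`, default 0.2) — contigs within
  `band_fraction * (mean_high - mean_low)` of the threshold are
  excluded, mirroring the source procedure's removal of
  intermediate-coverage contigs. At 4-fold mode separation and 0.3
  log2 sd, the default band leaves essentially zero probability of a
  misassigned non-excluded contig; at sd 0.5 the modes overlap beyond
  any fixed band and perfect assignment cannot be guaranteed.

Contigs are assigned atomically (no splitting), matching the fact that
such strain pairs cannot be fully separated. For metabolic analysis the
opposite strategy applies: `composite_genome` pools all genes of the
co-resident strains, duplicates retained, into one entry.

## Pathway scoring (`vitamin_pathways`)

Inputs are per-genome gene-copy status lists (INTACT / DISRUPTED /
ABSENT; a pseudogene broken by a premature stop is DISRUPTED and does
not satisfy a step, but is reported distinctly from ABSENT). Rules:

* **copy collapse** — a gene is intact if any copy is intact; this is
  what lets a duplicated operon complement itself when each copy is
  broken in a different gene;
* **step satisfaction** — any one of the step's alternative gene
  symbols intact;
* **cohort-absence rule** — a step unsatisfied in strictly more than
  `majority_fraction` (default 0.5) of the analyzed cohort is treated
  as potentially nonessential, but only within *otherwise intact*
  pathways: every other missing step must itself be cohort-absent or
  alternative-enzyme-flagged, and at least one step must actually be
  satisfied (a pathway lost wholesale is simply nonfunctional);
* **alternative-enzyme rule** — a step flagged as catalyzable by
  unrelated enzymes (by default only the riboflavin dephosphorylation
  step) may be missing without penalty.

A pathway is FUNCTIONAL with no missing step, PUTATIVELY_FUNCTIONAL
when every missing step is excused, NONFUNCTIONAL otherwise. Calls are
monotone under copy upgrades. Host-level complementation scores the
union of step satisfaction across co-resident symbionts and is never
worse than the best individual call. Double-infection strains are
pooled into composites before cohort-wide scoring, so the cohort is the
set of analyzed entries.

The shipped pathway definitions (`data/b_vitamin_pathways.yaml`) are
curated configuration following common KEGG-module conventions, marked
editable on purpose: exact module boundaries (e.g. cobalamin de novo
vs. salvage) and the full set of alternative-enzyme steps are
judgement calls, and the defaults are deliberately conservative
(alternative-enzyme flag on the riboflavin dephosphorylation step
only).

## Origin counting (`origin_mapping`)

All analyses are topology-level: branch lengths and supports are parsed
and ignored. The minimum number of independent acquisitions is obtained
by collapsing each *coevolving clade* into one origin. A genus-tree
clade qualifies when:

1. it has at least `min_clade_size` (default 2) strains;
2. its strains map to pairwise-distinct hosts (two strains in one host
   cannot descend from one acquisition-then-cospeciation history);
3. the mapped host set is **monophyletic in the host tree** —
   codiversification tracks host speciation, so a single acquisition
   that spread across host species boundaries must occupy a host
   clade; and
4. relabelling the strains by their hosts yields a topology identical
   to the induced host subtree (unrooted Robinson–Foulds distance 0).

Condition 3 is what separates, for example, a pruned three-strain genus
tree whose root spans phylogenetically scattered hosts (three
independent acquisitions) from a genuine mirror clade: on three or
fewer leaves the unrooted RF test alone is vacuous. Two-leaf clades are
congruent by construction and are flagged `trivial` in the report.

The search is greedy top-down from the genus-tree root, accepting the
largest qualifying clade first and never descending into it; this
guarantees maximality and disjointness. Strains outside every accepted
clade, and genera known from a single association row without a genome
tree, count one origin each.

Host samples are the units of congruence (two conspecific samples are
distinct leaves), and the two strains of a double infection are
distinct leaves that may fall into different clades. Supplied trees are
accepted as-is; where published analyses disagree on a topology, the
packaged fixture follows the maximum-likelihood arrangement.

## Synthetic data (`synthetic_data`)

The generator emulates the statistical structure each stage assumes;
all randomness flows from `SimConfig.seed` through independent
per-stage `numpy` streams, so outputs are byte-identical across reruns.

* **Host trees** grow by random sequential leaf attachment (Yule-like);
  only the topology matters downstream.
* **Acquisitions** (`n_origins`, default 5, cycling the five surveyed
  genera over `n_hosts`, default 14 — the survey's metagenomic sample
  count) either stay singletons or expand, with probability
  `clade_expansion_prob` (default 0.5), into a coevolving clade whose
  symbiont subtree is an exact copy of a 2–4-leaf host clade. Per-genus
  placements are resampled if the union of a genus's host sets happens
  to be monophyletic, which could disguise several origins as one;
  remaining strains attach at the genus-tree root as a polytomy,
  mimicking trees pruned to the focal strains.
* **Contigs** draw coverage log-normally around per-strain modes
  (`coverage_log2_means`, default (6, 2) — i.e. 64x and 4x, a 16-fold
  contrast; `coverage_log2_sd` default 0.3), 30 contigs per strain, 1–5
  genes per contig; hits report the true genus except with probability
  `hit_error_rate` (default 0.02), and eukaryote-only contigs are
  injected at `euk_contig_rate` (default 0.05).
* **Gene matrices** lose each gene with probability
  `pathway_loss_rate` (default 0.15), duplicate it with probability
  0.05, and disrupt each copy with probability `pseudogene_rate`
  (default 0.10). Ground-truth calls come from
  `reference_pathway_calls`, a deliberately plain nested-loop
  re-statement of the scoring rules kept separate from the production
  scorer (oracle pattern).
* **OTU tables** draw per-sample depths uniformly from
  `otu_depth_range` (default 5,000–20,000) and split read mass
  multinomially: resident symbiont OTUs share 70% in expectation,
  background OTUs (organellar, eukaryotic, archaeal, environmental
  labels) the rest.

What the synthetic tests do **not** show: real amplicon data have
chimeras, compositional noise, and ragged taxonomy strings; real
assemblies have shared k-mer artifacts, strain-overlapping contigs, and
coverage that varies along the genome; real annotation has K-number
assignment errors upstream of the gene matrix. The generators model
none of these, so passing recovery tests demonstrates correctness of
the algorithms under their stated assumptions, not robustness to every
real-data pathology.

## Problem sizes and numerical choices

The recovery suites use 100 random scenarios for origin counting
(8–15 hosts, 1–6 origins) and 100 seeds of 55-contig bimodal coverage
for the splitter; oracle-equivalence suites use 1,000 random hit
multisets, 500 random 8-leaf tree pairs, and 200 random degraded gene
matrices — sizes chosen to exercise every code path while keeping the
default suite interactive. Rarefaction's mean behaviour is checked
against the hypergeometric expectation over 10,000 seeded draws.
Degenerate inputs are contracts, not crashes: empty hit sets are
UNCLASSIFIED, zero-total samples pass the floor untouched, unimodal
bins refuse (not fail) to split, and single-genome cohorts produce an
empty absence profile.

## Known limitations

* Congruence is a binary RF-identity test; near-congruent clades
  (one misplaced strain) decompose rather than being scored partially,
  and no event-based reconciliation (duplication/loss/host-switch) is
  attempted.
* The origin count is a minimum: a collapsed two-leaf clade is equally
  consistent with two independent acquisitions, which is why such
  clades are flagged trivial.
* Pathway calls inherit whatever is wrong with the upstream gene
  annotations; the scorer assesses presence logic only.
* The Otsu-style splitter assumes exactly two coverage classes; three
  co-resident strains would need a multi-class extension.
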