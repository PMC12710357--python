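# cimsym

Toolkit for surveying nutritional symbionts across the bed bug family
(Cimicidae) — and, more generally, for any host clade whose
blood-feeding members depend on B-vitamin-provisioning bacteria. It
packages the computational stages such a survey needs once sequencing,
assembly, and annotation are done:

* **Amplicon screening** — filter a 16S OTU table (taxonomy filter,
  per-sample <1% abundance floor, rarefaction to fixed depth with
  exclusion of shallow samples) and summarize the dominant OTUs.
* **Contig binning** — recruit candidate symbiont contigs by
  marker-gene hits and assign each contig a genus by a majority vote
  over its genes' best database hits ("back-BLAST"), excluding
  contigs with predominant eukaryotic hits; summarize bins (size,
  GC%, CDS count, coding density).
* **Strain deconvolution** — detect double infections from the excess
  of duplicated orthologs, split a bin into high- and low-coverage
  strain genomes by maximizing between-class variance on log2 coverage
  (excluding an intermediate band), or pool the strains into a
  copy-preserving composite genome for metabolic analysis.
* **B-vitamin pathway scoring** — call each biosynthesis pathway
  FUNCTIONAL / PUTATIVELY_FUNCTIONAL / NONFUNCTIONAL per genome from
  gene-copy statuses (intact / disrupted / absent), with copy-level
  complementation, alternative-enzyme excusal, cohort-wide-absence
  excusal, and cross-symbiont complementation within one host.
* **Origin counting** — count the minimum number of independent
  symbiont acquisitions on the host phylogeny by collapsing coevolving
  clades: symbiont clades on distinct, monophyletic hosts whose
  topology mirrors the induced host subtree (unrooted
  Robinson–Foulds distance 0).
* **Synthetic data** — generate every input above with the statistical
  structure the pipeline assumes (host-congruent clades,
  coverage-bimodal double infections, controllable hit error and
  pathway degradation), with recorded ground truth, so the whole chain
  is testable offline.

A transcription of a published family-wide survey (host and symbiont
tree topologies plus the sample–symbiont association table) ships as a
packaged fixture.

## Worked example: counting independent acquisitions

The key quantity of a symbiont survey is how many times each bacterial
genus was independently acquired. Given a host tree, per-genus symbiont
trees, and a strain-to-host association table:

```sh
cimsym origins --out-dir out/            # uses the packaged fixture
```

prints (abridged):

```json
{
 "per_genus": {
  "Serratia": 1,
  "Sodalis": 2,
  "Symbiopectobacterium": 4,
  "Tisiphia": 1,
  "Wolbachia": 8
 },
 "total": 16,
 "clades": [
  {"genus": "Wolbachia", "size": 7, "trivial": false,
   "hosts": ["C44", "C49", "C51", "C56", "C57", "C61", "C66"]},
  {"genus": "Symbiopectobacterium", "size": 2, "trivial": true,
   "hosts": ["C19", "C28"]},
  {"genus": "Sodalis", "size": 2, "trivial": true,
   "hosts": ["C12", "C21"]}
 ]
}
```

Reading: of 24 symbiont strains, three clades collapse into single
acquisitions — a seven-strain *Wolbachia* lineage codiversifying with
its host subfamily, and one two-strain clade each of
*Symbiopectobacterium* and *Sodalis* (flagged `trivial`, since any
two-leaf topology mirrors any other) — leaving 16 independent origins
in total. The 14 *Wolbachia* strains sit in 11 host samples; the
`association_summary` block in the same report identifies the three
double-infected samples (C12, C21, C51).

The same library call is two lines:

```python
from cimsym.fixtures import survey_origin_report
report = survey_origin_report()   # report.total == 16
```

## Other entry points

```sh
cimsym simulate --out-dir fx/ --seed 7 --n-hosts 12 --n-origins 5
cimsym run --data-dir fx/ --out-dir out/ --seed 7    # full pipeline
cimsym amplicon-filter --data-dir fx/ --out-dir out/ --depth 1000
cimsym deconvolve --data-dir fx/ --out-dir out/ --band-fraction 0.2
cimsym vitamins --data-dir fx/ --out-dir out/ --majority-fraction 0.5
```

Every stage is also a plain function (`cimsym.amplicon_filter`,
`cimsym.symbiont_binning`, `cimsym.strain_deconvolution`,
`cimsym.vitamin_pathways`, `cimsym.origin_mapping`,
`cimsym.synthetic_data`); the CLI is a thin wrapper. Reports are pure
JSON without timestamps, so reruns with the same seed are
byte-identical. See `docs/methods.md` for the models, rules, defaults,
and limitations.

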