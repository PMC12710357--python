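# Default B-vitamin (plus lipoic acid) biosynthesis step definitions.
#
# Each pathway is an ordered list of steps; a step is satisfied when any
# one of its gene symbols is intact in the genome.  Steps flagged
# alternative_enzymes are known to be catalyzable by unrelated enzymes
# outside the canonical gene set (e.g. the riboflavin dephosphorylation
# step), so their absence does not by itself break the pathway.
#
# These defaults are curated configuration following common KEGG-module
# conventions, not ground truth; edit or replace per study.
biotin:
  - {step: bioF, genes: [bioF]}
  - {step: bioH, genes: [bioH]}
  - {step: bioC, genes: [bioC]}
  - {step: bioA, genes: [bioA]}
  - {step: bioD, genes: [bioD]}
  - {step: bioB, genes: [bioB]}
riboflavin:
  - {step: ribA, genes: [ribA]}
  - {step: ribD, genes: [ribD]}
  - {step: dephosphorylation, genes: [yigB], alternative_enzymes: true}
  - {step: ribH, genes: [ribH]}
  - {step: ribB, genes: [ribB]}
  - {step: ribE, genes: [ribE]}
folate:
  - {step: folE, genes: [folE]}
  - {step: folB, genes: [folB]}
  - {step: folK, genes: [folK]}
  - {step: folP, genes: [folP]}
  - {step: folC, genes: [folC]}
  - {step: folA, genes: [folA]}
thiamine:
  - {step: thiC, genes: [thiC]}
  - {step: thiD, genes: [thiD]}
  - {step: thiG, genes: [thiG, thiH]}
  - {step: thiE, genes: [thiE]}
pyridoxal:
  - {step: pdxA, genes: [pdxA]}
  - {step: pdxB, genes: [pdxB]}
  - {step: serC, genes: [serC]}
  - {step: pdxJ, genes: [pdxJ]}
  - {step: pdxH, genes: [pdxH]}
pantothenate:
  - {step: panB, genes: [panB]}
  - {step: panE, genes: [panD, panE]}
  - {step: panC, genes: [panC]}
nicotinate:
  - {step: nadB, genes: [nadB]}
  - {step: nadA, genes: [nadA]}
  - {step: nadC, genes: [nadC]}
  - {step: nadD, genes: [nadD]}
  - {step: nadE, genes: [nadE]}
cobalamin:
  - {step: cbiA, genes: [cbiA]}
  - {step: cbiB, genes: [cbiB]}
  - {step: cobU, genes: [cobU]}
  - {step: cobS, genes: [cobS]}
  - {step: cobC, genes: [cobC]}
lipoic_acid:
  - {step: lipB, genes: [lipB]}
  - {step: lipA, genes: [lipA]}
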