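"""Packaged survey fixture: transcribed trees and associations.

The fixture holds topology-level transcriptions of the published host
phylogeny, the cimicid-strain subtrees of the symbiont genus phylogenies
(pruning the non-cimicid reference strains leaves polytomies), and the
sample-symbiont association table.  Genera known from a single strain
without a usable genome tree (Serratia, Tisiphia) have association rows
but no tree file.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import dendropy

from cimsym.origin_mapping import (
    AssociationTable,
    OriginReport,
    count_origins,
    find_coevolving_clades,
    read_newick,
)

__all__ = ["survey_fixture_dir", "load_survey_fixture", "survey_origin_report"]

GENUS_TREE_FILES = {
    "Wolbachia": "wolbachia.nwk",
    "Symbiopectobacterium": "symbiopectobacterium.nwk",
    "Sodalis": "sodalis.nwk",
}


def survey_fixture_dir() -> Path:
    """Filesystem path of the packaged fixture directory."""
    return Path(resources.files("cimsym") / "survey_fixture")


def load_survey_fixture(
    directory: str | Path | None = None,
) -> tuple[dendropy.Tree, dict[str, dendropy.Tree], AssociationTable]:
    """Load (host tree, genus trees by genus, association table)."""
    d = Path(directory) if directory is not None else survey_fixture_dir()
    host = read_newick(d / "host_tree.nwk")
    genus_trees = {
        genus: read_newick(d / fname)
        for genus, fname in GENUS_TREE_FILES.items()
        if (d / fname).exists()
    }
    assoc = AssociationTable.from_tsv(d / "association.tsv")
    return host, genus_trees, assoc


def survey_origin_report(
    directory: str | Path | None = None, min_size: int = 2
) -> OriginReport:
    """Run clade detection and origin counting on the packaged fixture."""
    host, genus_trees, assoc = load_survey_fixture(directory)
    clades = []
    for tree in genus_trees.values():
        clades.extend(find_coevolving_clades(tree, host, assoc, min_size=min_size))
    return count_origins(assoc, clades)
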