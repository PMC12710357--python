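"""Counting independent symbiont acquisitions on the host phylogeny.

A symbiont genus may have colonized its host family once and then
codiversified, or repeatedly through independent acquisitions.  The
minimum number of acquisitions compatible with the data is obtained by
collapsing every *coevolving clade* — a clade of symbiont strains whose
hosts form a clade of their own and whose topology, after relabelling
strains by their hosts, is identical to the induced host subtree — into
a single origin; every strain outside such a clade is its own origin.

Trees are topology-only: branch lengths and support values are parsed
but ignored.  "Identical topology" is operationalized as unrooted
Robinson-Foulds distance zero.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import pandas as pd
from dendropy.calculate import treecompare

from cimsym.errors import InputConsistencyError, InvalidParameterError

__all__ = [
    "AssociationTable",
    "CoevolvingClade",
    "OriginReport",
    "read_newick",
    "write_newick",
    "leaf_labels",
    "induced_subtree",
    "rf_distance",
    "find_coevolving_clades",
    "count_origins",
    "association_summary",
]


# ---------------------------------------------------------------------------
# trees


def read_newick(source: str | Path) -> dendropy.Tree:
    """Read a rooted tree from a Newick file path or a Newick string.

    Branch lengths and internal-node labels are parsed but play no role
    downstream.  Underscores in labels are preserved verbatim.
    """
    text = str(source)
    if "(" not in text:  # a path, not a Newick string
        text = Path(source).read_text()
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise InvalidParameterError(f"malformed Newick input: {exc}") from exc
    tree.is_rooted = True
    labels = leaf_labels(tree)
    if len(labels) != len(set(labels)):
        raise InvalidParameterError("duplicate leaf labels in tree")
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    """Render a tree as a Newick string without branch lengths."""
    return tree.as_string(
        schema="newick",
        suppress_rooting=True,
        suppress_edge_lengths=True,
        unquoted_underscores=True,
    ).strip()


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def induced_subtree(tree: dendropy.Tree, leaves: Iterable[str]) -> dendropy.Tree:
    """Restrict ``tree`` to ``leaves``, suppressing degree-2 nodes."""
    wanted = set(leaves)
    known = set(leaf_labels(tree))
    unknown = wanted - known
    if unknown:
        raise InvalidParameterError(
            f"leaves not in tree: {', '.join(sorted(unknown))}"
        )
    if len(wanted) < 2:
        raise InvalidParameterError("induced subtree needs >= 2 leaves")
    taxa = [t for t in tree.taxon_namespace if t.label in wanted]
    sub = tree.extract_tree_with_taxa(taxa=taxa)
    sub.is_rooted = True
    return sub


def rf_distance(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Robinson-Foulds distance between two unrooted topologies.

    Zero iff the trees carry the same set of non-trivial bipartitions.
    Both trees must have the same leaf-label set.
    """
    l1, l2 = set(leaf_labels(t1)), set(leaf_labels(t2))
    if l1 != l2:
        raise InvalidParameterError(
            f"leaf sets differ: only-in-first={sorted(l1 - l2)}, "
            f"only-in-second={sorted(l2 - l1)}"
        )
    ns = dendropy.TaxonNamespace()
    a = dendropy.Tree.get(
        data=write_newick(t1), schema="newick",
        preserve_underscores=True, taxon_namespace=ns,
    )
    b = dendropy.Tree.get(
        data=write_newick(t2), schema="newick",
        preserve_underscores=True, taxon_namespace=ns,
    )
    a.is_rooted = False
    b.is_rooted = False
    a.encode_bipartitions()
    b.encode_bipartitions()
    return int(treecompare.symmetric_difference(a, b))


def relabel_leaves(tree: dendropy.Tree, mapping: Mapping[str, str]) -> dendropy.Tree:
    """Return a copy of ``tree`` with leaf labels replaced via ``mapping``."""
    clone = read_newick(write_newick(tree))
    for leaf in clone.leaf_node_iter():
        leaf.taxon.label = mapping[leaf.taxon.label]
    return clone


# ---------------------------------------------------------------------------
# associations


@dataclass(frozen=True)
class AssociationTable:
    """Strain-to-host mapping: one row per symbiont strain.

    Columns: ``strain_id`` (unique), ``host_id``, ``genus``.  A host may
    carry two strains of one genus (a double infection); each strain is
    its own row and its own tree leaf.
    """

    frame: pd.DataFrame

    REQUIRED = ("strain_id", "host_id", "genus")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise InvalidParameterError(f"association table lacks columns {missing}")
        if self.frame["strain_id"].duplicated().any():
            dups = self.frame.loc[self.frame["strain_id"].duplicated(), "strain_id"]
            raise InputConsistencyError(f"duplicate strain ids: {list(dups)}")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AssociationTable":
        return cls(pd.read_csv(path, sep="\t", dtype=str))

    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    def host_of(self) -> dict[str, str]:
        return dict(zip(self.frame["strain_id"], self.frame["host_id"]))

    def genus_of(self) -> dict[str, str]:
        return dict(zip(self.frame["strain_id"], self.frame["genus"]))

    def strains(self, genus: str | None = None) -> list[str]:
        f = self.frame
        if genus is not None:
            f = f[f["genus"] == genus]
        return list(f["strain_id"])

    @property
    def genera(self) -> list[str]:
        return list(dict.fromkeys(self.frame["genus"]))


def association_summary(assoc: AssociationTable) -> dict:
    """Per-genus strain/host accounting, including double infections.

    A double infection is a (host, genus) pair carried by two or more
    distinct strains.
    """
    out: dict[str, dict] = {}
    for genus, grp in assoc.frame.groupby("genus", sort=True):
        per_host = grp.groupby("host_id")["strain_id"].count()
        out[genus] = {
            "n_strains": int(len(grp)),
            "n_hosts": int(per_host.size),
            "double_infection_hosts": sorted(per_host[per_host >= 2].index),
        }
    return out


# ---------------------------------------------------------------------------
# coevolving clades and origin counting


@dataclass(frozen=True)
class CoevolvingClade:
    """A symbiont clade collapsed to a single acquisition event."""

    genus: str
    strain_ids: tuple[str, ...]
    host_ids: tuple[str, ...]
    congruent: bool = True
    #: two-leaf clades are congruent by construction (a single topology
    #: exists on two leaves), so their coevolutionary signal is weak
    trivial: bool = False

    @property
    def size(self) -> int:
        return len(self.strain_ids)


@dataclass
class OriginReport:
    """Minimum independent-acquisition breakdown."""

    per_genus: dict[str, int]
    total: int
    clades: list[CoevolvingClade] = field(default_factory=list)
    singletons: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "per_genus": dict(sorted(self.per_genus.items())),
            "total": self.total,
            "clades": [
                {
                    "genus": c.genus,
                    "strains": list(c.strain_ids),
                    "hosts": list(c.host_ids),
                    "size": c.size,
                    "trivial": c.trivial,
                }
                for c in self.clades
            ],
            "singletons": list(self.singletons),
        }


def _node_leaf_labels(node: dendropy.Node) -> list[str]:
    return [lf.taxon.label for lf in node.leaf_iter()]


def _hosts_monophyletic(host_tree: dendropy.Tree, hosts: set[str]) -> bool:
    """True iff ``hosts`` is exactly the leaf set of some host-tree clade."""
    taxa = [t for t in host_tree.taxon_namespace if t.label in hosts]
    if len(taxa) != len(hosts):
        missing = hosts - {t.label for t in host_tree.taxon_namespace}
        raise InvalidParameterError(f"hosts not in host tree: {sorted(missing)}")
    mrca = host_tree.mrca(taxa=taxa)
    return set(_node_leaf_labels(mrca)) == hosts


def find_coevolving_clades(
    genus_tree: dendropy.Tree,
    host_tree: dendropy.Tree,
    assoc: AssociationTable,
    min_size: int = 2,
) -> list[CoevolvingClade]:
    """Find maximal host-congruent clades in one genus tree.

    A clade of strains qualifies when (i) it has at least ``min_size``
    leaves, (ii) its strains map to pairwise-distinct hosts, (iii) those
    hosts are monophyletic in the host tree — codiversification after a
    single acquisition tracks host speciation, so the host set must be a
    clade — and (iv) relabelling the strains by their hosts yields a
    topology identical (unrooted RF = 0) to the induced host subtree.

    The search is greedy top-down from the genus-tree root: the largest
    qualifying clades are accepted first and never descended into, which
    guarantees maximality and disjointness.  Strains in no accepted
    clade are independent (singleton) acquisitions.
    """
    host_map = assoc.host_of()
    unmapped = [l for l in leaf_labels(genus_tree) if l not in host_map]
    if unmapped:
        raise InputConsistencyError(
            f"genus-tree strains missing from association table: {unmapped}"
        )

    accepted: list[CoevolvingClade] = []
    genus_by_strain = assoc.genus_of()
    stack = [genus_tree.seed_node]
    while stack:
        node = stack.pop()
        strains = sorted(_node_leaf_labels(node))
        if len(strains) >= min_size:
            hosts = [host_map[s] for s in strains]
            if len(set(hosts)) == len(hosts) and _hosts_monophyletic(
                host_tree, set(hosts)
            ):
                sub = induced_subtree(genus_tree, strains)
                relabelled = relabel_leaves(sub, host_map)
                host_sub = induced_subtree(host_tree, hosts)
                if rf_distance(relabelled, host_sub) == 0:
                    genus = genus_by_strain[strains[0]]
                    accepted.append(
                        CoevolvingClade(
                            genus=genus,
                            strain_ids=tuple(strains),
                            host_ids=tuple(sorted(set(hosts))),
                            congruent=True,
                            trivial=len(strains) == 2,
                        )
                    )
                    continue  # maximal: do not descend
        stack.extend(ch for ch in node.child_nodes() if not ch.is_leaf())
    return accepted


def count_origins(
    assoc: AssociationTable,
    clades: Sequence[CoevolvingClade],
) -> OriginReport:
    """Count minimum independent acquisitions per genus and in total.

    Per genus: one origin per coevolving clade plus one per strain
    outside every clade.  Genera known only from a single association
    row (e.g. detected by amplicons alone, with no genome tree)
    contribute one origin each.
    """
    in_clade: dict[str, str] = {}
    for clade in clades:
        for s in clade.strain_ids:
            if s in in_clade:
                raise InputConsistencyError(
                    f"strain {s!r} appears in overlapping clades"
                )
            in_clade[s] = clade.genus
    known = set(assoc.frame["strain_id"])
    dangling = set(in_clade) - known
    if dangling:
        raise InputConsistencyError(
            f"clade strains missing from association table: {sorted(dangling)}"
        )

    per_genus: dict[str, int] = {}
    singletons: list[str] = []
    for genus in assoc.genera:
        strains = assoc.strains(genus)
        genus_clades = [c for c in clades if c.genus == genus]
        outside = [s for s in strains if s not in in_clade]
        per_genus[genus] = len(genus_clades) + len(outside)
        singletons.extend(outside)
    return OriginReport(
        per_genus=per_genus,
        total=sum(per_genus.values()),
        clades=list(clades),
        singletons=singletons,
    )
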