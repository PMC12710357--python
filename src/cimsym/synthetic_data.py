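"""Synthetic inputs with the statistical structure the pipeline assumes.

Every stage of the survey pipeline can be exercised without sequence
archives: the generator emits a host phylogeny, symbiont acquisitions
(optionally expanding into host-congruent coevolving clades), contig
sets whose coverages are log-normal around per-strain modes (bimodal
for double infections), per-gene taxonomic hit tables with controllable
misassignment and eukaryotic contamination, gene-copy matrices with
controlled degradation, and OTU tables dominated by symbiont reads.
Ground truth is recorded alongside so parameter-recovery tests can
compare pipeline output with the simulated reality.

All randomness flows from ``SimConfig.seed`` through per-stage
``numpy`` generator streams, so identical configurations reproduce
byte-identical outputs.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, asdict
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from cimsym.amplicon_filter import OtuTable
from cimsym.errors import InvalidParameterError, SimulationError
from cimsym.origin_mapping import (
    AssociationTable,
    induced_subtree,
    leaf_labels,
    read_newick,
    relabel_leaves,
    write_newick,
)
from cimsym.symbiont_binning import ContigRecord, HitRecord, write_hits_tsv
from cimsym.vitamin_pathways import (
    ABSENT,
    DISRUPTED,
    INTACT,
    GeneCopyMatrix,
    PathwayDefinition,
    load_pathway_definitions,
)

__all__ = [
    "SimConfig",
    "GroundTruth",
    "GENUS_POOL",
    "simulate_host_tree",
    "simulate_symbiosis",
    "simulate_metagenome",
    "simulate_gene_matrix",
    "simulate_otu_table",
    "write_fixture",
]

#: symbiont genera cycled over origins, mirroring the surveyed taxa
GENUS_POOL = ("Wolbachia", "Symbiopectobacterium", "Sodalis", "Serratia", "Tisiphia")
#: wrong-genus labels used for misassigned hits
DECOY_GENERA = ("Rickettsia", "Arsenophonus", "Hamiltonella", "Buchnera")
EUK_GENERA = ("Homo", "Drosophila")

HIGH, LOW, HOST, EUK = "HIGH", "LOW", "HOST", "EUK"


@dataclass
class SimConfig:
    """Scenario parameters for every generator.

    Probabilities are in [0, 1]; coverage parameters are on the log2
    scale (log-normal coverage keeps depths positive and right-skewed).
    """

    seed: int = 0
    n_hosts: int = 14
    n_origins: int = 5
    clade_expansion_prob: float = 0.5
    coverage_log2_means: tuple[float, float] = (6.0, 2.0)  # (high, low) strain
    coverage_log2_sd: float = 0.3
    hit_error_rate: float = 0.02
    euk_contig_rate: float = 0.05
    pathway_loss_rate: float = 0.15
    pseudogene_rate: float = 0.10
    otu_depth_range: tuple[int, int] = (5000, 20000)
    # generator knobs beyond the headline scenario parameters
    n_contigs_per_strain: int = 30
    genes_per_contig: tuple[int, int] = (1, 5)
    background_fraction: float = 0.3
    double_infection_prob: float = 0.0
    duplication_rate: float = 0.05
    max_clade_size: int = 4

    def __post_init__(self) -> None:
        probs = {
            "clade_expansion_prob": self.clade_expansion_prob,
            "hit_error_rate": self.hit_error_rate,
            "euk_contig_rate": self.euk_contig_rate,
            "pathway_loss_rate": self.pathway_loss_rate,
            "pseudogene_rate": self.pseudogene_rate,
            "background_fraction": self.background_fraction,
            "double_infection_prob": self.double_infection_prob,
            "duplication_rate": self.duplication_rate,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise InvalidParameterError(f"{name} must lie in [0, 1], got {p}")
        if self.n_origins < 1:
            raise InvalidParameterError("n_origins must be >= 1")
        if self.n_hosts < 2:
            raise InvalidParameterError("n_hosts must be >= 2")
        lo, hi = self.otu_depth_range
        if not (1 <= lo <= hi):
            raise InvalidParameterError("otu_depth_range must be a valid pair")
        if self.coverage_log2_sd < 0:
            raise InvalidParameterError("coverage_log2_sd must be >= 0")
        if self.max_clade_size < 2:
            raise InvalidParameterError("max_clade_size must be >= 2")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent, reproducible generator for one stage."""
        return np.random.default_rng([self.seed, stream])


@dataclass
class GroundTruth:
    """Simulated reality recorded for parameter-recovery checks."""

    true_origin_count_per_genus: dict[str, int] = field(default_factory=dict)
    true_contig_strain: dict[str, str] = field(default_factory=dict)
    true_pathway_calls: dict[str, str] = field(default_factory=dict)  # "genome|pathway"

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))


# ---------------------------------------------------------------------------
# host tree


def simulate_host_tree(n_hosts: int, seed: int) -> dendropy.Tree:
    """Random binary rooted host tree by sequential leaf attachment.

    Starting from a two-leaf tree, a uniformly chosen extant leaf is
    repeatedly split into a cherry (Yule-like growth).  Branch lengths
    play no role in any downstream analysis and are omitted.
    """
    if n_hosts < 2:
        raise InvalidParameterError("n_hosts must be >= 2")
    rng = np.random.default_rng([seed, 101])
    newick = "(h1,h2)"
    leaves = ["h1", "h2"]
    for i in range(3, n_hosts + 1):
        victim = leaves[int(rng.integers(len(leaves)))]
        new = f"h{i}"
        newick = re.sub(rf"\b{victim}\b", f"({victim},{new})", newick, count=1)
        leaves.append(new)
    return read_newick(newick + ";")


# ---------------------------------------------------------------------------
# symbiosis scenarios


def _clade_nodes(tree: dendropy.Tree, max_size: int) -> list[tuple[str, ...]]:
    """Leaf sets of internal clades with 2..max_size leaves, sorted for
    deterministic choice."""
    out = []
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        ls = tuple(sorted(lf.taxon.label for lf in node.leaf_iter()))
        if 2 <= len(ls) <= max_size:
            out.append(ls)
    return sorted(out)


def _hosts_form_clade(tree: dendropy.Tree, hosts: set[str]) -> bool:
    taxa = [t for t in tree.taxon_namespace if t.label in hosts]
    mrca = tree.mrca(taxa=taxa)
    return {lf.taxon.label for lf in mrca.leaf_iter()} == hosts


def simulate_symbiosis(
    host_tree: dendropy.Tree, cfg: SimConfig
) -> tuple[AssociationTable, dict[str, dendropy.Tree | None], GroundTruth]:
    """Place ``cfg.n_origins`` independent acquisitions on the host tree.

    Each origin either stays a single-strain acquisition or, with
    probability ``clade_expansion_prob``, expands into a coevolving
    clade: a host-tree clade of 2..max_clade_size hosts whose induced
    topology the symbiont subtree copies exactly (congruent by
    construction).  Genera cycle through :data:`GENUS_POOL`.  Per-genus
    placements are resampled if the union of a genus's host sets
    accidentally forms a host clade, which could merge distinct origins
    into one apparent acquisition.

    Returns the association table, one tree per genus with >= 2 strains
    (``None`` for single-strain genera), and the ground truth.
    """
    hosts = sorted(leaf_labels(host_tree))
    if len(hosts) < cfg.n_origins:
        raise SimulationError(
            f"{cfg.n_origins} origins cannot be placed on {len(hosts)} hosts"
        )
    rng = cfg.rng(102)
    genera = [GENUS_POOL[i % len(GENUS_POOL)] for i in range(cfg.n_origins)]
    per_genus_n = {g: genera.count(g) for g in set(genera)}
    clade_pool = _clade_nodes(host_tree, cfg.max_clade_size)

    rows: list[tuple[str, str, str]] = []
    genus_trees: dict[str, dendropy.Tree | None] = {}
    truth = GroundTruth()

    for genus in sorted(per_genus_n):
        n_origins = per_genus_n[genus]
        for attempt in range(200):
            used: set[str] = set()
            origins: list[dict] = []
            ok = True
            for _ in range(n_origins):
                expand = (
                    float(rng.random()) < cfg.clade_expansion_prob
                    and any(set(c).isdisjoint(used) for c in clade_pool)
                )
                if expand:
                    options = [c for c in clade_pool if set(c).isdisjoint(used)]
                    clade = options[int(rng.integers(len(options)))]
                    origins.append({"hosts": list(clade), "clade": True})
                    used.update(clade)
                else:
                    free = [h for h in hosts if h not in used]
                    if not free:
                        ok = False
                        break
                    if used and float(rng.random()) < cfg.double_infection_prob:
                        h = sorted(used)[int(rng.integers(len(used)))]
                    else:
                        h = free[int(rng.integers(len(free)))]
                    origins.append({"hosts": [h], "clade": False})
                    used.add(h)
            if not ok:
                continue
            union = {h for o in origins for h in o["hosts"]}
            # a genus-wide host union that is itself a host clade could
            # disguise several origins as one; resample
            if n_origins >= 2 and len(union) >= 2 and _hosts_form_clade(host_tree, union):
                continue
            break
        else:
            raise SimulationError(
                f"could not place {n_origins} origins of {genus} on "
                f"{len(hosts)} hosts without ambiguity"
            )

        parts: list[str] = []
        strain_count = 0
        for o in origins:
            if o["clade"]:
                strain_map = {h: f"{genus}-{h}" for h in o["hosts"]}
                sub = relabel_leaves(
                    induced_subtree(host_tree, o["hosts"]), strain_map
                )
                parts.append(write_newick(sub).rstrip(";"))
                for h in o["hosts"]:
                    rows.append((strain_map[h], h, genus))
                    strain_count += 1
            else:
                h = o["hosts"][0]
                sid = f"{genus}-{h}"
                existing = {r[0] for r in rows}
                while sid in existing:
                    sid += "b"
                parts.append(sid)
                rows.append((sid, h, genus))
                strain_count += 1
        truth.true_origin_count_per_genus[genus] = n_origins
        if strain_count >= 2:
            genus_trees[genus] = read_newick(
                "(" + ",".join(parts) + ");" if len(parts) > 1 else parts[0] + ";"
            )
        else:
            genus_trees[genus] = None

    assoc = AssociationTable(
        pd.DataFrame(rows, columns=["strain_id", "host_id", "genus"]).sort_values(
            "strain_id", kind="stable", ignore_index=True
        )
    )
    return assoc, genus_trees, truth


# ---------------------------------------------------------------------------
# metagenome contigs and hit tables


def simulate_metagenome(
    assoc: AssociationTable, cfg: SimConfig
) -> tuple[list[ContigRecord], list[HitRecord], GroundTruth]:
    """Contigs and per-gene hit tables for every strain in ``assoc``.

    Coverage is log-normal around a per-strain mode: in hosts carrying
    two strains of one genus, the strains receive the high and low
    ``coverage_log2_means`` modes respectively; single strains use the
    high mode.  Each contig carries at least one gene; each gene's hit
    reports the emitting strain's genus with probability
    ``1 - hit_error_rate`` and a decoy genus otherwise.  Eukaryotic
    contamination contigs (eukaryote-only hits) are injected at
    ``euk_contig_rate`` relative to the symbiont contig count.
    """
    rng = cfg.rng(103)
    mean_high, mean_low = cfg.coverage_log2_means
    contigs: list[ContigRecord] = []
    hits: list[HitRecord] = []
    truth = GroundTruth()
    other_genera = list(DECOY_GENERA)

    frame = assoc.frame.sort_values("strain_id", kind="stable")
    for (host, genus), grp in frame.groupby(["host_id", "genus"], sort=True):
        strains = list(grp["strain_id"])
        if len(strains) > 1 and mean_high == mean_low:
            raise InvalidParameterError(
                "coverage_log2_means must differ to simulate a double infection"
            )
        for rank, strain in enumerate(sorted(strains)):
            mode = mean_high if rank == 0 else mean_low
            label = HIGH if rank == 0 else LOW
            for i in range(cfg.n_contigs_per_strain):
                cid = f"{strain}.c{i:03d}"
                coverage = float(2.0 ** rng.normal(mode, cfg.coverage_log2_sd))
                length = int(rng.integers(1000, 5001))
                contigs.append(ContigRecord(cid, length, coverage))
                truth.true_contig_strain[cid] = label
                n_genes = int(rng.integers(cfg.genes_per_contig[0],
                                           cfg.genes_per_contig[1] + 1))
                for j in range(n_genes):
                    if float(rng.random()) < cfg.hit_error_rate:
                        wrong = other_genera[int(rng.integers(len(other_genera)))]
                        hits.append(HitRecord(cid, f"{cid}.g{j}", wrong, "Bacteria"))
                    else:
                        hits.append(HitRecord(cid, f"{cid}.g{j}", genus, "Bacteria"))
    n_euk = int(rng.binomial(len(contigs), cfg.euk_contig_rate)) if contigs else 0
    mid = (mean_high + mean_low) / 2.0
    for i in range(n_euk):
        cid = f"euk.c{i:03d}"
        coverage = float(2.0 ** rng.normal(mid, 1.0))
        length = int(rng.integers(1000, 5001))
        contigs.append(ContigRecord(cid, length, coverage))
        truth.true_contig_strain[cid] = EUK
        for j in range(int(rng.integers(1, 4))):
            org = EUK_GENERA[int(rng.integers(len(EUK_GENERA)))]
            hits.append(HitRecord(cid, f"{cid}.g{j}", org, "Eukaryota"))
    return contigs, hits, truth


# ---------------------------------------------------------------------------
# gene-copy matrices with a straight-line reference scorer


def simulate_gene_matrix(
    genomes: list[str],
    defs: list[PathwayDefinition] | None,
    cfg: SimConfig,
) -> tuple[GeneCopyMatrix, GroundTruth]:
    """Degraded gene-copy matrices plus brute-force ground-truth calls.

    Per genome and gene: the gene is absent with probability
    ``pathway_loss_rate``; otherwise it has one copy (two with
    probability ``duplication_rate``), each disrupted by a premature
    stop with probability ``pseudogene_rate``.  Ground-truth calls come
    from :func:`reference_pathway_calls`, a deliberately plain
    re-statement of the scoring rules kept independent of the
    production scorer.
    """
    defs = defs if defs is not None else load_pathway_definitions()
    if not defs:
        raise InvalidParameterError("pathway definitions must be nonempty")
    rng = cfg.rng(104)
    genes = sorted({g for d in defs for g in d.gene_symbols})
    entries: dict[tuple[str, str], list[str]] = {}
    for genome in sorted(genomes):
        for gene in genes:
            if float(rng.random()) < cfg.pathway_loss_rate:
                entries[(genome, gene)] = [ABSENT]
                continue
            n_copies = 2 if float(rng.random()) < cfg.duplication_rate else 1
            entries[(genome, gene)] = [
                DISRUPTED if float(rng.random()) < cfg.pseudogene_rate else INTACT
                for _ in range(n_copies)
            ]
    matrix = GeneCopyMatrix(entries)
    truth = GroundTruth(
        true_pathway_calls=reference_pathway_calls(matrix, defs, list(genomes))
    )
    return matrix, truth


def reference_pathway_calls(
    matrix: GeneCopyMatrix,
    defs: list[PathwayDefinition],
    genomes: list[str],
    majority_fraction: float = 0.5,
) -> dict[str, str]:
    """Straight-line oracle for pathway calls, keyed ``genome|pathway``.

    Written as explicit nested loops, independent of the production
    scorer, so the two can disagree if either drifts.
    """
    genomes = sorted(genomes)

    def intact(genome: str, gene: str) -> bool:
        copies = matrix.copies(genome, gene)
        for c in copies:
            if c == "INTACT":
                return True
        return False

    def sat(genome: str, step) -> bool:
        for g in sorted(step.genes):
            if intact(genome, g):
                return True
        return False

    # cohort-absence profile
    profile: set[tuple[str, str]] = set()
    if len(genomes) >= 2:
        for pdef in defs:
            for step in pdef.steps:
                n_unsat = 0
                for genome in genomes:
                    if not sat(genome, step):
                        n_unsat += 1
                if n_unsat > majority_fraction * len(genomes):
                    profile.add((pdef.pathway_id, step.name))

    calls: dict[str, str] = {}
    for genome in genomes:
        for pdef in defs:
            missing = [s for s in pdef.steps if not sat(genome, s)]
            if not missing:
                calls[f"{genome}|{pdef.pathway_id}"] = "FUNCTIONAL"
                continue
            any_satisfied = len(missing) < len(pdef.steps)
            all_excusable_kind = True
            for s in missing:
                if s.has_known_alternative_enzymes:
                    continue
                if (pdef.pathway_id, s.name) in profile and any_satisfied:
                    continue
                all_excusable_kind = False
            if all_excusable_kind:
                calls[f"{genome}|{pdef.pathway_id}"] = "PUTATIVELY_FUNCTIONAL"
            else:
                calls[f"{genome}|{pdef.pathway_id}"] = "NONFUNCTIONAL"
    return calls


# ---------------------------------------------------------------------------
# OTU tables


BACKGROUND_OTUS = {
    "OTU_mito": "Eukaryota;Opisthokonta;Metazoa;Mitochondria",
    "OTU_chloro": "Bacteria;Cyanobacteria;Chloroplast",
    "OTU_euk": "Eukaryota;Fungi;Ascomycota",
    "OTU_arch": "Archaea;Euryarchaeota",
    "OTU_env1": "Bacteria;Proteobacteria;Pseudomonas",
    "OTU_env2": "Bacteria;Firmicutes;Bacillus",
}


def simulate_otu_table(assoc: AssociationTable, cfg: SimConfig) -> OtuTable:
    """Per-sample multinomial OTU counts dominated by symbiont OTUs.

    Each host sample draws a depth from ``otu_depth_range``; resident
    symbiont genera share ``1 - background_fraction`` of the read mass
    equally, and the background OTUs (organellar, eukaryotic, archaeal,
    environmental labels) share the remainder.  With zero background
    the table contains only symbiont OTUs.
    """
    rng = cfg.rng(105)
    samples = sorted(set(assoc.frame["host_id"]))
    genera = sorted(set(assoc.frame["genus"]))
    otu_ids = [f"OTU_{g}" for g in genera]
    taxonomy = {f"OTU_{g}": f"Bacteria;Proteobacteria;{g}" for g in genera}
    background = dict(BACKGROUND_OTUS) if cfg.background_fraction > 0 else {}
    otu_ids += list(background)
    taxonomy.update(background)

    lo, hi = cfg.otu_depth_range
    data = {}
    for sample in samples:
        depth = int(rng.integers(lo, hi + 1))
        resident = sorted(set(assoc.frame.loc[assoc.frame["host_id"] == sample, "genus"]))
        probs = np.zeros(len(otu_ids))
        sym_mass = 1.0 - cfg.background_fraction
        for g in resident:
            probs[otu_ids.index(f"OTU_{g}")] = sym_mass / len(resident)
        if background:
            bg_w = rng.dirichlet(np.ones(len(background)))
            for w, b in zip(bg_w, background):
                probs[otu_ids.index(b)] = cfg.background_fraction * w
        data[sample] = rng.multinomial(depth, probs / probs.sum())
    counts = pd.DataFrame(data, index=otu_ids, dtype=np.int64)
    return OtuTable(counts, pd.Series(taxonomy).loc[otu_ids])


# ---------------------------------------------------------------------------
# full fixture directory


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def write_fixture(outdir: str | Path, cfg: SimConfig) -> dict:
    """Generate and write a complete fixture directory.

    Emits Newick trees, the association TSV, contig FASTA + coverage
    TSV, the hits TSV, the gene-copy matrix TSV, the OTU table TSV, and
    ground-truth JSON.  Returns a manifest of paths.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    host = simulate_host_tree(cfg.n_hosts, cfg.seed)
    assoc, genus_trees, truth_sym = simulate_symbiosis(host, cfg)
    contigs, hits, truth_meta = simulate_metagenome(assoc, cfg)
    defs = load_pathway_definitions()
    matrix, truth_path = simulate_gene_matrix(assoc.strains(), defs, cfg)
    otus = simulate_otu_table(assoc, cfg)

    (out / "host_tree.nwk").write_text(write_newick(host) + "\n")
    tree_files = {}
    for genus, tree in genus_trees.items():
        if tree is None:
            continue
        fname = f"{genus.lower()}.nwk"
        (out / fname).write_text(write_newick(tree) + "\n")
        tree_files[genus] = fname
    assoc.to_tsv(out / "association.tsv")
    write_hits_tsv(hits, out / "hits.tsv")
    pd.DataFrame(
        [(c.contig_id, c.length, f"{c.coverage:.6f}") for c in contigs],
        columns=["contig_id", "length", "coverage"],
    ).to_csv(out / "coverage.tsv", sep="\t", index=False)
    rng = cfg.rng(106)
    with open(out / "contigs.fasta", "w") as fa:
        for c in contigs:
            seq = c.sequence or _random_sequence(rng, min(c.length, 2000))
            fa.write(f">{c.contig_id}\n{seq}\n")
    matrix.to_tsv(out / "gene_matrix.tsv")
    otus.to_tsv(out / "otu_table.tsv")

    truth = GroundTruth(
        true_origin_count_per_genus=truth_sym.true_origin_count_per_genus,
        true_contig_strain=truth_meta.true_contig_strain,
        true_pathway_calls=truth_path.true_pathway_calls,
    )
    truth.to_json(out / "ground_truth.json")
    manifest = {
        "host_tree": "host_tree.nwk",
        "genus_trees": tree_files,
        "association": "association.tsv",
        "hits": "hits.tsv",
        "coverage": "coverage.tsv",
        "contigs": "contigs.fasta",
        "gene_matrix": "gene_matrix.tsv",
        "otu_table": "otu_table.tsv",
        "ground_truth": "ground_truth.json",
        "seed": cfg.seed,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
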