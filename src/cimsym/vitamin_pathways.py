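"""B-vitamin pathway functionality scoring.

Symbiont genomes degrade: genes vanish or persist as pseudogenes broken
by premature stop codons.  A pathway is FUNCTIONAL when every step has
at least one intact gene, and NONFUNCTIONAL when a missing step cannot
be excused.  Two excusal rules keep the call biologically honest:

* a step whose canonical gene is known to be replaceable by unrelated
  alternative enzymes (e.g. the riboflavin dephosphorylation step) may
  be missing without breaking the pathway;
* a step missing across most of the symbiont cohort within otherwise
  intact pathways is treated as potentially nonessential.

A pathway whose every missing step is excused is PUTATIVELY_FUNCTIONAL.
Duplicated genes complement at the copy level: one intact copy is
enough even if another copy is disrupted.  Co-resident symbionts of a
host may complement each other at the step level (the pooled call is
never worse than the best individual one).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from cimsym.errors import InvalidParameterError

__all__ = [
    "INTACT",
    "DISRUPTED",
    "ABSENT",
    "FUNCTIONAL",
    "PUTATIVELY_FUNCTIONAL",
    "NONFUNCTIONAL",
    "CALL_ORDER",
    "GeneCopyMatrix",
    "PathwayStep",
    "PathwayDefinition",
    "PathwayCall",
    "load_pathway_definitions",
    "gene_status",
    "step_satisfied",
    "cohort_absence_profile",
    "score_pathway",
    "complementation_call",
    "vitamin_matrix",
]

INTACT = "INTACT"
DISRUPTED = "DISRUPTED"
ABSENT = "ABSENT"
STATUSES = (INTACT, DISRUPTED, ABSENT)

FUNCTIONAL = "FUNCTIONAL"
PUTATIVELY_FUNCTIONAL = "PUTATIVELY_FUNCTIONAL"
NONFUNCTIONAL = "NONFUNCTIONAL"
#: worst-to-best ordering used for complementation dominance
CALL_ORDER = {NONFUNCTIONAL: 0, PUTATIVELY_FUNCTIONAL: 1, FUNCTIONAL: 2}

ALT_ENZYME = "ALT_ENZYME"
COHORT_ABSENT = "COHORT_ABSENT"


class GeneCopyMatrix:
    """Mapping (genome_id, gene_symbol) -> list of copy statuses.

    A gene not listed for a genome is absent.  Listed entries carry one
    status per copy; an absent gene must be the single status ABSENT.
    """

    def __init__(self, entries: Mapping[tuple[str, str], Sequence[str]]):
        self._entries: dict[tuple[str, str], list[str]] = {}
        for (genome, gene), copies in entries.items():
            copies = list(copies)
            if not copies:
                raise InvalidParameterError(
                    f"empty copy list for ({genome}, {gene})"
                )
            bad = [s for s in copies if s not in STATUSES]
            if bad:
                raise InvalidParameterError(f"unknown statuses {bad}")
            if ABSENT in copies and len(copies) > 1:
                raise InvalidParameterError(
                    f"({genome}, {gene}): ABSENT must be a single status"
                )
            self._entries[(genome, gene)] = copies

    def copies(self, genome: str, gene: str) -> list[str]:
        return self._entries.get((genome, gene), [ABSENT])

    @property
    def genomes(self) -> list[str]:
        return sorted({g for g, _ in self._entries})

    def items(self):
        return self._entries.items()

    def merged(self, composites: Mapping[str, Sequence[str]]) -> "GeneCopyMatrix":
        """Pool members of each composite into one copy-preserving entry.

        ``composites`` maps composite id -> member genome ids; member
        rows are replaced by the composite (concatenated copy lists,
        ABSENT placeholders dropped when another member has the gene).
        """
        member_of: dict[str, str] = {}
        for comp, members in composites.items():
            for m in members:
                if m in member_of:
                    raise InvalidParameterError(
                        f"genome {m!r} in two composites"
                    )
                member_of[m] = comp
        pooled: dict[tuple[str, str], list[str]] = {}
        for (genome, gene), copies in self._entries.items():
            target = member_of.get(genome, genome)
            pooled.setdefault((target, gene), []).extend(copies)
        cleaned = {}
        for key, copies in pooled.items():
            real = [s for s in copies if s != ABSENT]
            cleaned[key] = real if real else [ABSENT]
        return GeneCopyMatrix(cleaned)

    # --- interchange: TSV (genome_id, gene_symbol, copy_index, status)
    @classmethod
    def from_tsv(cls, path: str | Path) -> "GeneCopyMatrix":
        frame = pd.read_csv(path, sep="\t", dtype=str)
        entries: dict[tuple[str, str], list[str]] = {}
        frame["copy_index"] = frame["copy_index"].astype(int)
        for (genome, gene), grp in frame.groupby(
            ["genome_id", "gene_symbol"], sort=True
        ):
            entries[(genome, gene)] = list(
                grp.sort_values("copy_index")["status"]
            )
        return cls(entries)

    def to_tsv(self, path: str | Path) -> None:
        rows = []
        for (genome, gene), copies in sorted(self._entries.items()):
            for i, status in enumerate(copies):
                rows.append((genome, gene, i, status))
        pd.DataFrame(
            rows, columns=["genome_id", "gene_symbol", "copy_index", "status"]
        ).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class PathwayStep:
    """One biosynthetic step: alternative gene symbols (any suffices)
    plus whether unrelated alternative enzymes are known for it."""

    name: str
    genes: frozenset[str]
    has_known_alternative_enzymes: bool = False

    def __post_init__(self) -> None:
        if not self.genes:
            raise InvalidParameterError(f"step {self.name!r} has no genes")


@dataclass(frozen=True)
class PathwayDefinition:
    pathway_id: str
    steps: tuple[PathwayStep, ...]

    def __post_init__(self) -> None:
        if not self.steps:
            raise InvalidParameterError(
                f"pathway {self.pathway_id!r} has no steps"
            )

    @property
    def gene_symbols(self) -> set[str]:
        return {g for s in self.steps for g in s.genes}


@dataclass(frozen=True)
class PathwayCall:
    genome_id: str
    pathway_id: str
    call: str
    missing_steps: tuple[str, ...] = ()
    excusals: dict = field(default_factory=dict)  # step -> ALT_ENZYME|COHORT_ABSENT|None


def load_pathway_definitions(path: str | Path | None = None) -> list[PathwayDefinition]:
    """Load pathway step definitions from YAML (packaged defaults when
    ``path`` is None)."""
    if path is None:
        text = (resources.files("cimsym") / "data" / "b_vitamin_pathways.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    defs = []
    for pid, steps in raw.items():
        defs.append(
            PathwayDefinition(
                pathway_id=pid,
                steps=tuple(
                    PathwayStep(
                        name=s["step"],
                        genes=frozenset(s["genes"]),
                        has_known_alternative_enzymes=bool(
                            s.get("alternative_enzymes", False)
                        ),
                    )
                    for s in steps
                ),
            )
        )
    return defs


# ---------------------------------------------------------------------------
# scoring


def gene_status(copies: Sequence[str]) -> str:
    """Collapse a copy list: any intact copy makes the gene intact
    (copy-level complementation, as in a duplicated operon where each
    copy is broken in a different gene)."""
    if not copies:
        raise InvalidParameterError("empty copy list")
    if INTACT in copies:
        return INTACT
    if DISRUPTED in copies:
        return DISRUPTED
    return ABSENT


def step_satisfied(genome: str, step: PathwayStep, matrix: GeneCopyMatrix) -> bool:
    """A step is satisfied iff some alternative gene is intact;
    disrupted copies do not count."""
    return any(
        gene_status(matrix.copies(genome, g)) == INTACT for g in step.genes
    )


def cohort_absence_profile(
    matrix: GeneCopyMatrix,
    defs: Sequence[PathwayDefinition],
    genomes: Sequence[str] | None = None,
    majority_fraction: float = 0.5,
) -> set[tuple[str, str]]:
    """(pathway, step) pairs unsatisfied in strictly more than
    ``majority_fraction`` of the cohort ("absent across all or most
    symbionts").  A single-genome cohort yields an empty profile."""
    if not 0 <= majority_fraction < 1:
        raise InvalidParameterError("majority_fraction must lie in [0, 1)")
    genomes = list(genomes) if genomes is not None else matrix.genomes
    if len(genomes) < 2:
        return set()
    profile = set()
    for pdef in defs:
        for step in pdef.steps:
            unsat = sum(
                1 for g in genomes if not step_satisfied(g, step, matrix)
            )
            if unsat > majority_fraction * len(genomes):
                profile.add((pdef.pathway_id, step.name))
    return profile


def _score(
    genome_id: str,
    pdef: PathwayDefinition,
    satisfied: Mapping[str, bool],
    profile: set[tuple[str, str]],
) -> PathwayCall:
    missing = tuple(s.name for s in pdef.steps if not satisfied[s.name])
    by_name = {s.name: s for s in pdef.steps}
    # "otherwise intact": every missing step is itself excusable-in-kind
    # (cohort-absent or alternative-enzyme) and the pathway retains at
    # least one working step; a pathway with an idiosyncratic hole, or
    # one lost wholesale, is not otherwise intact
    otherwise_intact = len(missing) < len(pdef.steps) and all(
        (pdef.pathway_id, m) in profile
        or by_name[m].has_known_alternative_enzymes
        for m in missing
    )
    excusals: dict[str, str | None] = {}
    for m in missing:
        if by_name[m].has_known_alternative_enzymes:
            excusals[m] = ALT_ENZYME
        elif (pdef.pathway_id, m) in profile and otherwise_intact:
            excusals[m] = COHORT_ABSENT
        else:
            excusals[m] = None
    if not missing:
        call = FUNCTIONAL
    elif all(v is not None for v in excusals.values()):
        call = PUTATIVELY_FUNCTIONAL
    else:
        call = NONFUNCTIONAL
    return PathwayCall(
        genome_id=genome_id,
        pathway_id=pdef.pathway_id,
        call=call,
        missing_steps=missing,
        excusals=excusals,
    )


def score_pathway(
    genome: str,
    pdef: PathwayDefinition,
    matrix: GeneCopyMatrix,
    profile: set[tuple[str, str]] | None = None,
) -> PathwayCall:
    """Score one pathway in one genome, assessing each missing step
    individually against the two excusal rules."""
    profile = profile or set()
    satisfied = {s.name: step_satisfied(genome, s, matrix) for s in pdef.steps}
    return _score(genome, pdef, satisfied, profile)


def complementation_call(
    residents: Sequence[str],
    pdef: PathwayDefinition,
    matrix: GeneCopyMatrix,
    profile: set[tuple[str, str]] | None = None,
    host_id: str | None = None,
) -> PathwayCall:
    """Host-level call when several symbionts co-reside.

    Step satisfaction is the union across residents, so partial
    biosynthetic capacities combine; the pooled call is never worse
    than the best individual call (guaranteed by monotonicity and
    enforced explicitly).
    """
    if not residents:
        raise InvalidParameterError("need >= 1 resident symbiont")
    profile = profile or set()
    satisfied = {
        s.name: any(step_satisfied(g, s, matrix) for g in residents)
        for s in pdef.steps
    }
    label = host_id or "+".join(residents)
    pooled = _score(label, pdef, satisfied, profile)
    best = max(
        (score_pathway(g, pdef, matrix, profile) for g in residents),
        key=lambda c: CALL_ORDER[c.call],
    )
    if CALL_ORDER[pooled.call] < CALL_ORDER[best.call]:
        pooled = PathwayCall(
            genome_id=label,
            pathway_id=pdef.pathway_id,
            call=best.call,
            missing_steps=pooled.missing_steps,
            excusals=pooled.excusals,
        )
    return pooled


def vitamin_matrix(
    matrix: GeneCopyMatrix,
    defs: Sequence[PathwayDefinition],
    composites: Mapping[str, Sequence[str]] | None = None,
    majority_fraction: float = 0.5,
) -> tuple[pd.DataFrame, dict]:
    """Score every pathway in every genome.

    ``composites`` pools double-infection strains into single entries
    before scoring, so the cohort used for the cohort-absence rule is
    the set of analyzed entries.  Returns the genome-by-pathway call
    table and a per-cell audit of missing steps and excusals.
    """
    if composites:
        matrix = matrix.merged(composites)
    genomes = matrix.genomes
    profile = cohort_absence_profile(
        matrix, defs, genomes, majority_fraction=majority_fraction
    )
    calls = pd.DataFrame(index=genomes, columns=[d.pathway_id for d in defs], dtype=object)
    audit: dict[str, dict] = {}
    for g in genomes:
        for pdef in defs:
            pc = score_pathway(g, pdef, matrix, profile)
            calls.loc[g, pdef.pathway_id] = pc.call
            audit.setdefault(g, {})[pdef.pathway_id] = {
                "call": pc.call,
                "missing_steps": list(pc.missing_steps),
                "excusals": dict(pc.excusals),
            }
    return calls, audit
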