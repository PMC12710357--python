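"""Contig recruitment and majority-vote ("back-BLAST") taxonomy.

Candidate symbiont contigs are recruited by marker-gene hits; each
contig's identity is then decided by tallying the best hit of every
annotated gene on it: the bacterial genus with the strict plurality of
hits wins, contigs whose eukaryotic hits outnumber the best bacterial
genus are excluded, and contigs with no evidence or a tie stay
unclassified.  Bins are summarized with assembly-style statistics
(size, GC%, CDS count, coding density).
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from cimsym.errors import InputConsistencyError, InvalidParameterError

__all__ = [
    "ContigRecord",
    "HitRecord",
    "ContigCall",
    "GenomeSummary",
    "recruit_contigs",
    "classify_contig",
    "classify_all",
    "build_bins",
    "genome_summary",
    "read_hits_tsv",
    "write_hits_tsv",
]

SUPERKINGDOMS = ("Bacteria", "Eukaryota", "Archaea", "Viruses")

UNCLASSIFIED = "UNCLASSIFIED"
EUKARYOTIC_EXCLUDED = "EUKARYOTIC_EXCLUDED"


@dataclass(frozen=True)
class ContigRecord:
    """An assembled contig: id, length (bp), mean read coverage, and
    optionally the nucleotide sequence."""

    contig_id: str
    length: int
    coverage: float
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.length < 1:
            raise InvalidParameterError(f"{self.contig_id}: length must be >= 1")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise InvalidParameterError(
                f"{self.contig_id}: sequence length {len(self.sequence)} "
                f"!= declared length {self.length}"
            )


@dataclass(frozen=True)
class HitRecord:
    """Best database hit of one annotated gene on a contig."""

    contig_id: str
    gene_id: str
    hit_genus: str
    hit_superkingdom: str

    def __post_init__(self) -> None:
        if self.hit_superkingdom not in SUPERKINGDOMS:
            raise InvalidParameterError(
                f"unknown superkingdom {self.hit_superkingdom!r}"
            )


@dataclass(frozen=True)
class ContigCall:
    """Majority-vote verdict for one contig."""

    contig_id: str
    verdict: str  # genus | UNCLASSIFIED | EUKARYOTIC_EXCLUDED
    tally: dict[str, int] = field(default_factory=dict)
    euk_hits: int = 0


@dataclass(frozen=True)
class GenomeSummary:
    """Bin-level assembly statistics."""

    genus: str
    n_contigs: int
    genome_size_bp: int
    gc_percent: float
    cds_count: int
    coding_density_percent: float


# ---------------------------------------------------------------------------


def recruit_contigs(
    hits: Iterable[HitRecord], target_genera: Iterable[str]
) -> set[str]:
    """Contigs with at least one hit to a target genus.

    Recruitment is a permissive pre-filter; final identity is decided by
    :func:`classify_contig`.
    """
    targets = set(target_genera)
    if not targets:
        raise InvalidParameterError("target_genera must be nonempty")
    return {h.contig_id for h in hits if h.hit_genus in targets}


def classify_contig(hits: Sequence[HitRecord]) -> ContigCall:
    """Tally per-gene hits for one contig and call its origin.

    Bacterial hits vote for their genus; eukaryotic hits count as
    exclusion evidence; archaeal and viral hits count for neither.  The
    verdict is the strict-plurality bacterial genus, unless eukaryotic
    hits strictly outnumber it (excluded) or there is no winner
    (unclassified).
    """
    contig_ids = {h.contig_id for h in hits}
    if len(contig_ids) > 1:
        raise InvalidParameterError(
            f"hits span multiple contigs: {sorted(contig_ids)}"
        )
    contig_id = next(iter(contig_ids)) if contig_ids else ""
    tally = Counter(
        h.hit_genus for h in hits if h.hit_superkingdom == "Bacteria"
    )
    euk = sum(1 for h in hits if h.hit_superkingdom == "Eukaryota")
    best = max(tally.values()) if tally else 0
    if euk > best:
        verdict = EUKARYOTIC_EXCLUDED
    elif best == 0:
        verdict = UNCLASSIFIED
    else:
        winners = [g for g, n in tally.items() if n == best]
        verdict = winners[0] if len(winners) == 1 else UNCLASSIFIED
    return ContigCall(
        contig_id=contig_id, verdict=verdict, tally=dict(tally), euk_hits=euk
    )


def classify_all(hits: Iterable[HitRecord]) -> list[ContigCall]:
    """Group hits by contig and classify each; deterministic order."""
    by_contig: dict[str, list[HitRecord]] = defaultdict(list)
    for h in hits:
        by_contig[h.contig_id].append(h)
    return [classify_contig(by_contig[c]) for c in sorted(by_contig)]


def build_bins(
    calls: Iterable[ContigCall], contigs: Mapping[str, ContigRecord]
) -> dict[str, set[str]]:
    """Partition classified contigs by verdict genus.

    Unclassified and excluded contigs are omitted; bins are disjoint by
    construction because each contig has one verdict.
    """
    bins: dict[str, set[str]] = defaultdict(set)
    for call in calls:
        if call.contig_id not in contigs:
            raise InputConsistencyError(
                f"call references unknown contig {call.contig_id!r}"
            )
        if call.verdict not in (UNCLASSIFIED, EUKARYOTIC_EXCLUDED):
            bins[call.verdict].add(call.contig_id)
    return dict(bins)


def _union_length(intervals: list[tuple[int, int]]) -> int:
    """Total bp covered by 1-based inclusive intervals."""
    covered = 0
    last_end = 0
    for start, end in sorted(intervals):
        if start > last_end:
            covered += end - start + 1
            last_end = end
        elif end > last_end:
            covered += end - last_end
            last_end = end
    return covered


def genome_summary(
    genus: str,
    contigs: Sequence[ContigRecord],
    cds_intervals: Iterable[tuple[str, int, int]],
) -> GenomeSummary:
    """Assembly statistics for one bin.

    ``cds_intervals`` are (contig_id, start, end), 1-based inclusive
    (GFF-style).  GC% is computed over non-N bases; coding density is
    the per-contig union of CDS intervals over total genome size, so
    overlapping CDS are not double-counted.
    """
    by_id = {c.contig_id: c for c in contigs}
    missing_seq = [c.contig_id for c in contigs if c.sequence is None]
    if missing_seq:
        raise InvalidParameterError(f"contigs without sequence: {missing_seq}")
    size = sum(c.length for c in contigs)
    gc = at = 0
    for c in contigs:
        seq = c.sequence.upper()
        gc += seq.count("G") + seq.count("C")
        at += seq.count("A") + seq.count("T")
    per_contig: dict[str, list[tuple[int, int]]] = defaultdict(list)
    n_cds = 0
    for contig_id, start, end in cds_intervals:
        if contig_id not in by_id:
            raise InputConsistencyError(f"CDS on unknown contig {contig_id!r}")
        if not (1 <= start <= end <= by_id[contig_id].length):
            raise InputConsistencyError(
                f"CDS [{start},{end}] outside contig {contig_id!r} "
                f"(length {by_id[contig_id].length})"
            )
        per_contig[contig_id].append((start, end))
        n_cds += 1
    coding_bp = sum(_union_length(iv) for iv in per_contig.values())
    return GenomeSummary(
        genus=genus,
        n_contigs=len(contigs),
        genome_size_bp=size,
        gc_percent=100.0 * gc / (gc + at) if gc + at else 0.0,
        cds_count=n_cds,
        coding_density_percent=100.0 * coding_bp / size if size else 0.0,
    )


# ---------------------------------------------------------------------------
# interchange


HITS_COLUMNS = ["contig_id", "gene_id", "hit_genus", "hit_superkingdom"]


def read_hits_tsv(path: str | Path) -> list[HitRecord]:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in HITS_COLUMNS if c not in frame.columns]
    if missing:
        raise InvalidParameterError(f"hits TSV lacks columns {missing}")
    return [HitRecord(*row) for row in frame[HITS_COLUMNS].itertuples(index=False)]


def write_hits_tsv(hits: Iterable[HitRecord], path: str | Path) -> None:
    frame = pd.DataFrame(
        [(h.contig_id, h.gene_id, h.hit_genus, h.hit_superkingdom) for h in hits],
        columns=HITS_COLUMNS,
    )
    frame.to_csv(path, sep="\t", index=False)
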