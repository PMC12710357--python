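"""Double-infection detection and coverage-based strain splitting.

When one host carries two strains of the same symbiont genus, the bin
shows an excess of duplicated orthologs, and most genes occur twice on
contigs with distinct read coverage.  The two strain genomes are pulled
apart by thresholding log2 coverage with a two-class between-class
variance maximizer (Otsu's criterion in one dimension), discarding
contigs in an intermediate band around the threshold where the two
coverage distributions overlap.  For metabolic analysis the strains are
instead pooled into a copy-preserving "composite genome".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from cimsym.errors import InvalidParameterError
from cimsym.symbiont_binning import ContigRecord

__all__ = [
    "OrthogroupProfile",
    "CoverageSplit",
    "detect_double_infection",
    "split_by_coverage",
    "composite_genome",
    "HIGH",
    "LOW",
    "EXCLUDED_INTERMEDIATE",
]

HIGH = "HIGH"
LOW = "LOW"
EXCLUDED_INTERMEDIATE = "EXCLUDED_INTERMEDIATE"

#: the two strain coverage modes must differ at least this much (log2)
#: for a split to be meaningful; below it the bin is called unimodal
MIN_MODE_SEPARATION_LOG2 = math.log2(1.5)


@dataclass(frozen=True)
class OrthogroupProfile:
    """Copy count of one orthogroup within a genus bin."""

    orthogroup_id: str
    copy_count: int

    def __post_init__(self) -> None:
        if self.copy_count < 0:
            raise InvalidParameterError("copy_count must be >= 0")


@dataclass
class CoverageSplit:
    """Result of a coverage split; ``refused`` marks a unimodal bin
    (distinct from an error) and carries no assignment."""

    threshold_log2: float | None
    band_halfwidth_log2: float | None
    assignment: dict[str, str] = field(default_factory=dict)
    mean_high_log2: float | None = None
    mean_low_log2: float | None = None
    refused: bool = False
    reason: str | None = None

    def ids(self, label: str) -> list[str]:
        return sorted(c for c, v in self.assignment.items() if v == label)

    def to_dict(self) -> dict:
        return {
            "refused": self.refused,
            "reason": self.reason,
            "threshold_log2": self.threshold_log2,
            "band_halfwidth_log2": self.band_halfwidth_log2,
            "mean_high_log2": self.mean_high_log2,
            "mean_low_log2": self.mean_low_log2,
            "high": self.ids(HIGH),
            "low": self.ids(LOW),
            "excluded": self.ids(EXCLUDED_INTERMEDIATE),
        }


def detect_double_infection(
    profiles: Sequence[OrthogroupProfile],
    dup_fraction_threshold: float = 0.2,
) -> tuple[bool, float]:
    """Flag a bin whose duplicated-ortholog fraction is excessive.

    The duplicated fraction is the share of present orthogroups
    (copy_count >= 1) that occur in two or more copies; the flag fires
    at or above ``dup_fraction_threshold``.
    """
    if not profiles:
        raise InvalidParameterError("empty orthogroup profile table")
    present = sum(1 for p in profiles if p.copy_count >= 1)
    if present == 0:
        raise InvalidParameterError("no orthogroup is present in the bin")
    duplicated = sum(1 for p in profiles if p.copy_count >= 2)
    fraction = duplicated / present
    return fraction >= dup_fraction_threshold, fraction


def _otsu_boundary(values: np.ndarray) -> int:
    """Index i maximizing between-class variance for the split
    values[:i] | values[i:] of a sorted array."""
    n = values.size
    best_i, best_score = 1, -1.0
    csum = np.cumsum(values)
    total = csum[-1]
    for i in range(1, n):
        w0 = i / n
        w1 = 1.0 - w0
        m0 = csum[i - 1] / i
        m1 = (total - csum[i - 1]) / (n - i)
        score = w0 * w1 * (m1 - m0) ** 2
        if score > best_score:
            best_score, best_i = score, i
    return best_i


def split_by_coverage(
    contigs: Sequence[ContigRecord],
    band_fraction: float = 0.2,
    min_separation_log2: float = MIN_MODE_SEPARATION_LOG2,
) -> CoverageSplit:
    """Split a bin into high- and low-coverage strain sets.

    The threshold on log2 coverage maximizes the two-class
    between-class variance (exhaustive 1-D search) and is placed at the
    midpoint between the adjacent class extremes, so multiplying all
    coverages by a constant shifts the threshold by exactly log2 of
    that constant.  If the class means differ by less than
    ``min_separation_log2`` the bin is deemed unimodal and the split is
    refused.  Contigs within ``band_fraction * (mean_high - mean_low)``
    of the threshold are excluded as intermediate.
    """
    if len(contigs) < 4:
        raise InvalidParameterError("need >= 4 contigs to attempt a split")
    if any(c.coverage <= 0 for c in contigs):
        raise InvalidParameterError("all coverages must be > 0")
    if not 0 <= band_fraction < 0.5:
        raise InvalidParameterError("band_fraction must lie in [0, 0.5)")

    order = sorted(contigs, key=lambda c: (c.coverage, c.contig_id))
    logcov = np.array([math.log2(c.coverage) for c in order])
    boundary = _otsu_boundary(logcov)
    mean_low = float(logcov[:boundary].mean())
    mean_high = float(logcov[boundary:].mean())
    if mean_high - mean_low < min_separation_log2:
        return CoverageSplit(
            threshold_log2=None,
            band_halfwidth_log2=None,
            refused=True,
            reason=(
                f"class means separated by {mean_high - mean_low:.3f} log2 "
                f"< required {min_separation_log2:.3f}: no coverage bimodality"
            ),
        )
    threshold = float((logcov[boundary - 1] + logcov[boundary]) / 2.0)
    halfwidth = band_fraction * (mean_high - mean_low)
    assignment: dict[str, str] = {}
    for c, x in zip(order, logcov):
        if abs(x - threshold) < halfwidth:
            assignment[c.contig_id] = EXCLUDED_INTERMEDIATE
        elif x > threshold:
            assignment[c.contig_id] = HIGH
        else:
            assignment[c.contig_id] = LOW
    return CoverageSplit(
        threshold_log2=threshold,
        band_halfwidth_log2=halfwidth,
        assignment=assignment,
        mean_high_log2=mean_high,
        mean_low_log2=mean_low,
    )


def composite_genome(gene_sets: Iterable[Iterable[str]] | Mapping[str, Iterable[str]]) -> list[str]:
    """Pool the gene sets of co-resident same-genus strains.

    Duplicates are retained as separate copies (multiset union), so a
    gene present in both strains appears twice in the composite.
    """
    if isinstance(gene_sets, Mapping):
        gene_sets = [gene_sets[k] for k in sorted(gene_sets)]
    merged: list[str] = []
    for genes in gene_sets:
        merged.extend(genes)
    return sorted(merged)
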