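"""16S OTU-table screening: taxonomy filter, abundance floor, rarefaction.

The screening stage assumes symbiont OTUs are abundant, so it removes
organellar/non-bacterial OTUs, zeroes any OTU below 1% of a sample's
reads (per sample, independently of other samples), rarefies every
retained sample to a fixed depth, and drops samples with fewer reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from cimsym.errors import InvalidParameterError

__all__ = [
    "OtuTable",
    "FilterReport",
    "FILTER_TERMS",
    "taxonomic_filter",
    "abundance_floor",
    "rarefy",
    "dominant_otus",
    "run_amplicon_filter",
]

#: lineage substrings (matched case-insensitively at any rank) that mark
#: an OTU as non-target: archaeal, eukaryotic, or organellar 16S
FILTER_TERMS = ("archaea", "eukaryota", "mitochondria", "chloroplast")


@dataclass(frozen=True)
class OtuTable:
    """Integer OTU-by-sample counts plus a per-OTU taxonomy lineage.

    ``counts`` is indexed by otu_id with one column per sample;
    ``taxonomy`` maps every otu_id to a semicolon-delimited lineage
    string (possibly ``Unassigned``).
    """

    counts: pd.DataFrame
    taxonomy: pd.Series

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise InvalidParameterError("negative counts in OTU table")
        missing = self.counts.index.difference(self.taxonomy.index)
        if len(missing):
            raise InvalidParameterError(
                f"OTUs without taxonomy entry: {list(missing)}"
            )

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def restrict(self, otus=None, samples=None) -> "OtuTable":
        counts = self.counts
        if otus is not None:
            counts = counts.loc[list(otus)]
        if samples is not None:
            counts = counts[list(samples)]
        return OtuTable(counts, self.taxonomy.loc[counts.index])

    # --- interchange: TSV with first column otu_id, last column taxonomy
    @classmethod
    def from_tsv(cls, path: str | Path) -> "OtuTable":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        if "taxonomy" not in frame.columns:
            raise InvalidParameterError("OTU TSV lacks a 'taxonomy' column")
        taxonomy = frame.pop("taxonomy").astype(str)
        return cls(frame.astype(np.int64), taxonomy)

    def to_tsv(self, path: str | Path) -> None:
        out = self.counts.copy()
        out["taxonomy"] = self.taxonomy.loc[out.index]
        out.to_csv(path, sep="\t", index_label="otu_id")


@dataclass
class FilterReport:
    """Bookkeeping emitted by each screening step."""

    otus_removed_taxonomy: int = 0
    cells_zeroed: int = 0
    samples_dropped: list[str] = field(default_factory=list)
    depth: int = 0
    seed: int = 0
    truncated_k: bool = False

    def to_dict(self) -> dict:
        return {
            "otus_removed_taxonomy": self.otus_removed_taxonomy,
            "cells_zeroed": self.cells_zeroed,
            "samples_dropped": list(self.samples_dropped),
            "depth": self.depth,
            "seed": self.seed,
        }


def taxonomic_filter(table: OtuTable) -> tuple[OtuTable, FilterReport]:
    """Drop archaeal, eukaryotic, mitochondrial, and chloroplast OTUs.

    Matching is case-insensitive against the whole lineage string, so a
    term at any rank removes the OTU.
    """
    lineage = table.taxonomy.loc[table.counts.index].str.lower()
    bad = lineage.str.contains("|".join(FILTER_TERMS), regex=True)
    kept = table.restrict(otus=table.counts.index[~bad.values])
    return kept, FilterReport(otus_removed_taxonomy=int(bad.sum()))


def abundance_floor(
    table: OtuTable, threshold: float = 0.01
) -> tuple[OtuTable, FilterReport]:
    """Zero every cell below ``threshold`` of its sample's reads.

    Each sample is floored independently: presence across other samples
    is not considered.  The comparison is strict (<), so a cell at
    exactly the threshold is retained.  Samples with zero total are
    left unchanged.
    """
    if not 0 < threshold < 1:
        raise InvalidParameterError("threshold must lie in (0, 1)")
    counts = table.counts.to_numpy(dtype=np.int64, copy=True)
    totals = counts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(totals > 0, counts / np.maximum(totals, 1), 0.0)
    mask = (frac < threshold) & (counts > 0) & (totals > 0)
    counts[mask] = 0
    floored = OtuTable(
        pd.DataFrame(counts, index=table.counts.index, columns=table.counts.columns),
        table.taxonomy,
    )
    return floored, FilterReport(cells_zeroed=int(mask.sum()))


def rarefy(
    table: OtuTable, depth: int = 1000, seed: int = 0
) -> tuple[OtuTable, FilterReport]:
    """Subsample every sample to exactly ``depth`` reads, without
    replacement; samples with fewer reads are dropped and reported.

    Without-replacement subsampling makes each rarefied count
    hypergeometric with mean ``depth * count / total``.
    """
    if depth < 1:
        raise InvalidParameterError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    kept_cols: list[str] = []
    dropped: list[str] = []
    data = {}
    for sample in table.sample_ids:
        col = table.counts[sample].to_numpy(dtype=np.int64)
        total = int(col.sum())
        if total < depth:
            dropped.append(sample)
            continue
        if total == depth:
            data[sample] = col
        else:
            data[sample] = rng.multivariate_hypergeometric(col, depth)
        kept_cols.append(sample)
    counts = pd.DataFrame(data, index=table.counts.index, columns=kept_cols, dtype=np.int64)
    report = FilterReport(samples_dropped=dropped, depth=depth, seed=seed)
    return OtuTable(counts, table.taxonomy), report


def dominant_otus(
    table: OtuTable, k: int = 13
) -> tuple[pd.DataFrame, FilterReport]:
    """Rank OTUs by total count and return the top ``k`` with their
    per-sample relative abundances.

    Ties on total count break lexicographically by otu_id.  If ``k``
    exceeds the number of OTUs, all are returned and the report flags
    the truncation.
    """
    if table.counts.empty:
        raise InvalidParameterError("empty OTU table")
    totals = table.counts.sum(axis=1)
    order = sorted(table.otu_ids, key=lambda o: (-totals[o], o))
    report = FilterReport(truncated_k=k > len(order))
    top = order[: min(k, len(order))]
    sample_totals = table.counts.sum(axis=0).replace(0, 1)
    rel = table.counts.loc[top].div(sample_totals, axis=1)
    return rel, report


def run_amplicon_filter(
    table: OtuTable,
    threshold: float = 0.01,
    depth: int = 1000,
    seed: int = 0,
    top_k: int = 13,
) -> dict:
    """Full screening chain: taxonomy filter -> abundance floor ->
    rarefaction -> dominant-OTU summary.  Returns all stage outputs."""
    filtered, rep_tax = taxonomic_filter(table)
    floored, rep_floor = abundance_floor(filtered, threshold=threshold)
    rarefied, rep_rare = rarefy(floored, depth=depth, seed=seed)
    if rarefied.counts.empty or not rarefied.sample_ids:
        top, rep_top = pd.DataFrame(), FilterReport()
    else:
        top, rep_top = dominant_otus(rarefied, k=top_k)
    return {
        "table": rarefied,
        "dominant": top,
        "report": FilterReport(
            otus_removed_taxonomy=rep_tax.otus_removed_taxonomy,
            cells_zeroed=rep_floor.cells_zeroed,
            samples_dropped=rep_rare.samples_dropped,
            depth=depth,
            seed=seed,
            truncated_k=rep_top.truncated_k,
        ),
    }
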