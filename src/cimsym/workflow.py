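"""End-to-end driver chaining the pipeline stages.

Stages run in a fixed order — simulate -> amplicon-filter -> bin ->
deconvolve -> vitamins -> origins — each reading the interchange files
of the previous ones from a single directory and embedding its report
in a consolidated JSON.  Reports contain no timestamps, so reruns with
the same configuration and seed are byte-identical; timing goes to the
log only.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from cimsym.amplicon_filter import OtuTable, run_amplicon_filter
from cimsym.errors import CimsymError
from cimsym.origin_mapping import (
    AssociationTable,
    association_summary,
    count_origins,
    find_coevolving_clades,
    read_newick,
)
from cimsym.strain_deconvolution import detect_double_infection, split_by_coverage
from cimsym.strain_deconvolution import OrthogroupProfile
from cimsym.symbiont_binning import (
    ContigRecord,
    build_bins,
    classify_all,
    read_hits_tsv,
    recruit_contigs,
)
from cimsym.synthetic_data import GENUS_POOL, SimConfig, write_fixture
from cimsym.vitamin_pathways import (
    GeneCopyMatrix,
    load_pathway_definitions,
    vitamin_matrix,
)

__all__ = ["RunConfig", "run_pipeline", "stage_amplicon", "stage_bin",
           "stage_deconvolve", "stage_vitamins", "stage_origins"]

log = logging.getLogger("cimsym")


@dataclass
class RunConfig:
    """Paths, toggles, and stage parameters for one pipeline run."""

    data_dir: Path
    out_dir: Path
    seed: int = 0
    simulate: bool = False
    sim: SimConfig | None = None
    threshold: float = 0.01
    depth: int = 1000
    top_k: int = 13
    targets: tuple[str, ...] = GENUS_POOL
    band_fraction: float = 0.2
    dup_threshold: float = 0.2
    majority_fraction: float = 0.5
    min_clade_size: int = 2
    stages: tuple[str, ...] = (
        "amplicon_filter", "bin", "deconvolve", "vitamins", "origins"
    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = SimConfig(**raw.pop("sim")) if "sim" in raw else None
        raw["data_dir"] = Path(raw["data_dir"])
        raw["out_dir"] = Path(raw["out_dir"])
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        if "targets" in raw:
            raw["targets"] = tuple(raw["targets"])
        return cls(sim=sim, **raw)


def _setup_logging(out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    handlers = [
        logging.StreamHandler(sys.stderr),
        logging.FileHandler(out_dir / "pipeline.log"),
    ]
    logging.basicConfig(
        level=logging.INFO,
        format="%(asctime)s %(levelname)s %(message)s",
        handlers=handlers,
        force=True,
    )


# --------------------------------------------------------------------------
# stages (each independently invocable)


def stage_amplicon(cfg: RunConfig) -> dict:
    table = OtuTable.from_tsv(cfg.data_dir / "otu_table.tsv")
    result = run_amplicon_filter(
        table, threshold=cfg.threshold, depth=cfg.depth,
        seed=cfg.seed, top_k=cfg.top_k,
    )
    result["table"].to_tsv(cfg.out_dir / "otu_table.filtered.tsv")
    dom = result["dominant"]
    dom.to_csv(cfg.out_dir / "dominant_otus.tsv", sep="\t", index_label="otu_id")
    return {
        "report": result["report"].to_dict(),
        "n_samples_retained": len(result["table"].sample_ids),
        "n_otus": len(result["table"].otu_ids),
        "dominant_otus": list(dom.index),
    }


def stage_bin(cfg: RunConfig) -> dict:
    hits = read_hits_tsv(cfg.data_dir / "hits.tsv")
    cov = pd.read_csv(cfg.data_dir / "coverage.tsv", sep="\t")
    contigs = {
        r.contig_id: ContigRecord(r.contig_id, int(r.length), float(r.coverage))
        for r in cov.itertuples(index=False)
    }
    recruited = recruit_contigs(hits, cfg.targets)
    calls = classify_all([h for h in hits if h.contig_id in recruited])
    bins = build_bins(calls, contigs)
    for genus, members in sorted(bins.items()):
        (cfg.out_dir / f"bin.{genus}.txt").write_text(
            "\n".join(sorted(members)) + "\n"
        )
    return {
        "n_recruited": len(recruited),
        "bins": {g: sorted(m) for g, m in sorted(bins.items())},
        "n_unclassified": sum(1 for c in calls if c.verdict == "UNCLASSIFIED"),
        "n_excluded_eukaryotic": sum(
            1 for c in calls if c.verdict == "EUKARYOTIC_EXCLUDED"
        ),
    }


def stage_deconvolve(cfg: RunConfig, bins: dict[str, list[str]]) -> dict:
    cov = pd.read_csv(cfg.data_dir / "coverage.tsv", sep="\t")
    contigs = {
        r.contig_id: ContigRecord(r.contig_id, int(r.length), float(r.coverage))
        for r in cov.itertuples(index=False)
    }
    og_path = cfg.data_dir / "orthogroups.tsv"
    out: dict[str, dict] = {}
    for genus, members in sorted(bins.items()):
        entry: dict = {}
        if og_path.exists():
            og = pd.read_csv(og_path, sep="\t")
            og = og[og["genus"] == genus] if "genus" in og.columns else og
            if len(og):
                profiles = [
                    OrthogroupProfile(r.orthogroup_id, int(r.copy_count))
                    for r in og.itertuples(index=False)
                ]
                flag, frac = detect_double_infection(profiles, cfg.dup_threshold)
                entry["double_infection"] = {"flag": flag, "duplicated_fraction": frac}
        if len(members) >= 4:
            split = split_by_coverage(
                [contigs[c] for c in members], band_fraction=cfg.band_fraction
            )
            entry["coverage_split"] = split.to_dict()
        out[genus] = entry
    (cfg.out_dir / "deconvolution.json").write_text(
        json.dumps(out, indent=1, sort_keys=True)
    )
    return out


def stage_vitamins(cfg: RunConfig) -> dict:
    matrix = GeneCopyMatrix.from_tsv(cfg.data_dir / "gene_matrix.tsv")
    defs = load_pathway_definitions()
    composites = None
    comp_path = cfg.data_dir / "composites.json"
    if comp_path.exists():
        composites = json.loads(comp_path.read_text())
    calls, audit = vitamin_matrix(
        matrix, defs, composites=composites,
        majority_fraction=cfg.majority_fraction,
    )
    calls.to_csv(cfg.out_dir / "vitamin_calls.tsv", sep="\t", index_label="genome_id")
    (cfg.out_dir / "vitamin_audit.json").write_text(
        json.dumps(audit, indent=1, sort_keys=True)
    )
    return {"calls": {g: dict(row) for g, row in calls.iterrows()}}


def stage_origins(cfg: RunConfig) -> dict:
    assoc = AssociationTable.from_tsv(cfg.data_dir / "association.tsv")
    host = read_newick(cfg.data_dir / "host_tree.nwk")
    clades = []
    for genus in assoc.genera:
        tree_path = cfg.data_dir / f"{genus.lower()}.nwk"
        if tree_path.exists():
            clades.extend(
                find_coevolving_clades(
                    read_newick(tree_path), host, assoc,
                    min_size=cfg.min_clade_size,
                )
            )
    report = count_origins(assoc, clades)
    payload = report.to_dict()
    payload["association_summary"] = association_summary(assoc)
    (cfg.out_dir / "origins.json").write_text(
        json.dumps(payload, indent=1, sort_keys=True)
    )
    pd.DataFrame(
        sorted(report.per_genus.items()), columns=["genus", "origins"]
    ).to_csv(cfg.out_dir / "origins_per_genus.tsv", sep="\t", index=False)
    return payload


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the configured stages in fixed order; returns (and writes)
    the consolidated report."""
    _setup_logging(cfg.out_dir)
    if cfg.simulate:
        sim = cfg.sim or SimConfig(seed=cfg.seed)
        log.info("simulating fixture into %s", cfg.data_dir)
        write_fixture(cfg.data_dir, sim)
    required = {
        "amplicon_filter": ["otu_table.tsv"],
        "bin": ["hits.tsv", "coverage.tsv"],
        "deconvolve": ["coverage.tsv"],
        "vitamins": ["gene_matrix.tsv"],
        "origins": ["association.tsv", "host_tree.nwk"],
    }
    for stage in cfg.stages:
        for fname in required.get(stage, []):
            if not (cfg.data_dir / fname).exists():
                raise CimsymError(
                    f"stage {stage!r} requires missing input file "
                    f"{cfg.data_dir / fname}"
                )
    report: dict = {"seed": cfg.seed, "stages": list(cfg.stages)}
    bins: dict[str, list[str]] = {}
    for stage in cfg.stages:
        log.info("running stage %s", stage)
        if stage == "amplicon_filter":
            report["amplicon_filter"] = stage_amplicon(cfg)
        elif stage == "bin":
            report["bin"] = stage_bin(cfg)
            bins = report["bin"]["bins"]
        elif stage == "deconvolve":
            report["deconvolve"] = stage_deconvolve(cfg, bins)
        elif stage == "vitamins":
            report["vitamins"] = stage_vitamins(cfg)
        elif stage == "origins":
            report["origins"] = stage_origins(cfg)
        else:
            raise CimsymError(f"unknown stage {stage!r}")
    (cfg.out_dir / "report.json").write_text(
        json.dumps(report, indent=1, sort_keys=True)
    )
    return report
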