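"""Stage orchestration with file handoffs.

Each stage reads its inputs from, and writes its outputs to, a fixed layout
under one working directory, so stages are independently runnable and
testable and a full run is a pure function of (config, seed):

    sim/         genome.fa transcripts.fa genes.gff3 tags_<LIB>.tsv truth.tsv config.yaml
    counts/      <LIB>.counts.tsv <LIB>.norm.tsv <LIB>.rejects.tsv counting_summary.tsv
    de/          <A>_vs_<B>.tsv summary.tsv
    annotation/  annotation.tsv sisters.tsv loci.tsv
    anchoring/   anchors.tsv clusters.tsv synteny.tsv summary.yaml circos/
    manifest.json run.log

Nothing in the outputs depends on wall-clock time, so two runs with the
same config and seed produce byte-identical trees.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

import supersage
from supersage import io as sio
from supersage import anchoring, annotate, de, tags
from supersage.simulate import LIBRARIES, SimulationConfig, simulate_dataset

logger = logging.getLogger("supersage")

DEFAULT_CONTRASTS = [["TS", "TC"], ["SS", "SC"], ["TS", "SS"], ["TC", "SC"]]


class PipelineError(RuntimeError):
    """A stage failed for a named cause (missing input, invalid config...)."""


@dataclass
class PipelineConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    alpha: float = 0.05
    contrasts: list[list[str]] = field(default_factory=lambda: [list(c) for c in DEFAULT_CONTRASTS])
    # cluster defaults scaled to the synthetic chromosomes (500 kb); the
    # max-gap rule itself defaults to 1 Mb at the library level
    max_gap: int = 50_000
    min_cluster_size: int = 2

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        libraries = set(LIBRARIES)
        for pair in self.contrasts:
            if len(pair) != 2 or not set(pair) <= libraries:
                raise ValueError(f"invalid contrast {pair}: libraries are {sorted(libraries)}")

    def to_dict(self) -> dict:
        data = dataclasses.asdict(self)
        data["simulation"] = self.simulation.to_dict()
        return data

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        sim = data.pop("simulation", {})
        if isinstance(sim, dict):
            sim.setdefault("families", None)
            sim = {k: v for k, v in sim.items() if v is not None}
            if "true_fc_values" in sim:
                sim["true_fc_values"] = tuple(sim["true_fc_values"])
            if "isoform_distribution" in sim:
                sim["isoform_distribution"] = {
                    int(k): float(v) for k, v in sim["isoform_distribution"].items()
                }
            sim = SimulationConfig(**sim)
        return cls(simulation=sim, **data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        return cls.from_dict(data)

    def config_hash(self) -> str:
        canonical = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def _prepare_dir(path: Path, force: bool) -> Path:
    if path.exists() and any(path.iterdir()):
        if not force:
            raise PipelineError(
                f"output directory {path} already contains files; pass --force to overwrite"
            )
        for child in sorted(path.rglob("*"), reverse=True):
            child.unlink() if child.is_file() else child.rmdir()
    path.mkdir(parents=True, exist_ok=True)
    return path


def _require(path: Path, produced_by: str) -> Path:
    if not path.exists():
        raise PipelineError(
            f"missing input {path}: run the '{produced_by}' stage first"
        )
    return path


def stage_simulate(config: PipelineConfig, outdir: Path, force: bool = False) -> Path:
    simdir = _prepare_dir(outdir / "sim", force)
    simulate_dataset(config.simulation, simdir)
    logger.info("simulate: wrote dataset (seed=%d) to %s", config.simulation.seed, simdir.name)
    return simdir


def _load_raw_counts(simdir: Path, library: str) -> tags.UnitagTable:
    path = _require(simdir / f"tags_{library}.tsv", "simulate")
    frame = pd.read_csv(path, sep="\t", dtype={"tag": str, "count": int})
    table = tags.UnitagTable(library=library)
    for tag, count in zip(frame["tag"], frame["count"]):
        tag = str(tag).upper()
        reason = tags._validate_tag(tag)
        if reason is None:
            table.counts[tag] = table.counts.get(tag, 0) + int(count)
        else:
            table.rejects.append((tag, reason))
    return table


def stage_count(config: PipelineConfig, outdir: Path, force: bool = False) -> Path:
    simdir = outdir / "sim"
    countdir = _prepare_dir(outdir / "counts", force)
    summary_rows = []
    for library in LIBRARIES:
        raw = _load_raw_counts(simdir, library)
        filtered = tags.exclude_singlets(raw)
        normalised = tags.normalize_tpm(filtered)
        tags.write_counts_tsv(raw, countdir / f"{library}.counts.tsv")
        tags.write_counts_tsv(normalised, countdir / f"{library}.norm.tsv")
        tags.write_rejects_tsv(raw, countdir / f"{library}.rejects.tsv")
        summary_rows.append(
            {
                "library": library,
                "raw_unitags": raw.n_unitags,
                "raw_total": raw.total,
                "singlets_excluded": filtered.singlets_excluded,
                "retained_unitags": filtered.n_unitags,
                "retained_total": filtered.total,
                "rejects": len(raw.rejects),
            }
        )
        logger.info(
            "count: %s retained %d unitags (%d tags) after excluding %d singlets",
            library, filtered.n_unitags, filtered.total, filtered.singlets_excluded,
        )
    pd.DataFrame(summary_rows).to_csv(
        countdir / "counting_summary.tsv", sep="\t", index=False
    )
    return countdir


def load_normalised(countdir: Path, library: str) -> tags.UnitagTable:
    path = _require(countdir / f"{library}.norm.tsv", "count")
    frame = pd.read_csv(path, sep="\t")
    table = tags.UnitagTable(
        library=library,
        counts=dict(zip(frame["tag"], frame["count"].astype(int))),
        tpm=dict(zip(frame["tag"], frame["tpm"].astype(float))),
        filtered=True,
    )
    return table


def stage_de(config: PipelineConfig, outdir: Path, force: bool = False) -> Path:
    countdir = outdir / "counts"
    dedir = _prepare_dir(outdir / "de", force)
    tables = {lib: load_normalised(countdir, lib) for lib in LIBRARIES}
    summaries = []
    for lib_a, lib_b in config.contrasts:
        result, summary = de.run_contrast(tables[lib_a], tables[lib_b], config.alpha)
        result.to_csv(
            dedir / f"{lib_a}_vs_{lib_b}.tsv", sep="\t", index=False, float_format="%.6g"
        )
        summaries.append(summary)
        logger.info(
            "de: %s UR=%d DR=%d ns=%d unitags=%d",
            summary["contrast"], summary["UR"], summary["DR"],
            summary["ns"], summary["unitags"],
        )
    de.summary_table(summaries).to_csv(dedir / "summary.tsv", sep="\t")
    return dedir


def stage_annotate(config: PipelineConfig, outdir: Path, force: bool = False) -> Path:
    simdir = outdir / "sim"
    countdir = outdir / "counts"
    anndir = _prepare_dir(outdir / "annotation", force)
    transcripts = sio.read_gene_models(
        _require(simdir / "transcripts.fa", "simulate"),
        _require(simdir / "genes.gff3", "simulate"),
    )
    index = annotate.TranscriptIndex(transcripts)
    tables = {lib: load_normalised(countdir, lib) for lib in LIBRARIES}
    unitags = sorted(set().union(*(t.counts for t in tables.values())))
    matches = annotate.match_all(unitags, index)
    sisters = annotate.detect_sister_tags(unitags, matches)
    loci = annotate.collapse_to_loci(matches)

    contrast_results = {}
    dedir = outdir / "de"
    for lib_a, lib_b in config.contrasts:
        path = dedir / f"{lib_a}_vs_{lib_b}.tsv"
        if path.exists():
            contrast_results[f"{lib_a}_vs_{lib_b}"] = pd.read_csv(path, sep="\t")
    report = annotate.annotation_report(
        matches,
        contrast_results or None,
        tpm={lib: tables[lib].tpm for lib in LIBRARIES},
    )
    annotate.write_report(report, anndir / "annotation.tsv")
    pd.DataFrame(
        [
            {
                "tag_1": p.tag_1, "tag_2": p.tag_2, "position": p.position,
                "shared_transcripts": ",".join(p.shared_transcripts),
            }
            for p in sisters
        ],
        columns=["tag_1", "tag_2", "position", "shared_transcripts"],
    ).to_csv(anndir / "sisters.tsv", sep="\t", index=False)
    loci.to_csv(anndir / "loci.tsv", sep="\t", index=False)
    n_matched = sum(1 for t in unitags if matches[t])
    logger.info(
        "annotate: %d/%d unitags matched; %d transcripts in %d loci; %d sister pairs",
        n_matched, len(unitags),
        len({m.transcript_id for ms in matches.values() for m in ms}),
        len(loci), len(sisters),
    )
    return anndir


def stage_anchor(config: PipelineConfig, outdir: Path, force: bool = False) -> Path:
    simdir = outdir / "sim"
    anndir = outdir / "annotation"
    anchordir = _prepare_dir(outdir / "anchoring", force)
    gff3 = _require(simdir / "genes.gff3", "simulate")
    loci_path = _require(anndir / "loci.tsv", "annotate")
    matched = set(pd.read_csv(loci_path, sep="\t")["locus_id"])
    locus_table = [row for row in sio.read_locus_table(gff3) if row["locus_id"] in matched]
    lengths = sio.read_chromosome_lengths(gff3)
    sim = config.simulation
    anchors, unplaced = anchoring.anchor_loci(
        locus_table,
        lengths,
        centromere_fraction=sim.centromere_fraction,
        subterminal_fraction=sim.subterminal_arm_fraction,
        pericentromere_fraction=sim.pericentromere_fraction,
    )
    clusters = anchoring.call_clusters(anchors, config.max_gap, config.min_cluster_size)
    links = anchoring.find_synteny_links(anchors)
    summary = anchoring.distribution_summary(anchors, lengths)
    summary["n_clusters"] = len(clusters)
    summary["n_synteny_links"] = len(links)
    summary["n_unplaced"] = len(unplaced)

    anchoring.anchors_to_frame(anchors).to_csv(
        anchordir / "anchors.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        [
            {
                "chromosome": c.chromosome, "start": c.start, "end": c.end,
                "n_members": len(c), "families": ",".join(c.families),
                "members": ",".join(m.locus_id for m in c.members),
            }
            for c in clusters
        ],
        columns=["chromosome", "start", "end", "n_members", "families", "members"],
    ).to_csv(anchordir / "clusters.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "family": l.family,
                "chromosome_a": l.chromosome_a, "start_a": l.start_a, "end_a": l.end_a,
                "chromosome_b": l.chromosome_b, "start_b": l.start_b, "end_b": l.end_b,
            }
            for l in links
        ],
        columns=["family", "chromosome_a", "start_a", "end_a",
                 "chromosome_b", "start_b", "end_b"],
    ).to_csv(anchordir / "synteny.tsv", sep="\t", index=False)
    (anchordir / "summary.yaml").write_text(yaml.safe_dump(summary, sort_keys=True))
    anchoring.write_circos(anchors, links, lengths, anchordir / "circos")
    logger.info(
        "anchor: %d loci on %d/%d chromosomes; %d clusters; %d synteny links",
        summary["n_loci"], summary["chromosomes_with_loci"],
        summary["n_chromosomes"], len(clusters), len(links),
    )
    return anchordir


STAGES = {
    "simulate": stage_simulate,
    "count": stage_count,
    "de": stage_de,
    "annotate": stage_annotate,
    "anchor": stage_anchor,
}
STAGE_ORDER = ["simulate", "count", "de", "annotate", "anchor"]


def write_manifest(config: PipelineConfig, outdir: Path, stages: list[str]) -> None:
    import numpy, scipy

    manifest = {
        "supersage_version": supersage.__version__,
        "python_version": sys.version.split()[0],
        "numpy_version": numpy.__version__,
        "scipy_version": scipy.__version__,
        "pandas_version": pd.__version__,
        "seed": config.simulation.seed,
        "config_hash": config.config_hash(),
        "stages": stages,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    (outdir / "config.echo.yaml").write_text(
        yaml.safe_dump(config.to_dict(), sort_keys=True)
    )
    logger.info(
        "run: supersage %s seed=%d config=%s stages=%s",
        manifest["supersage_version"], manifest["seed"],
        manifest["config_hash"], ",".join(stages),
    )


def run(
    stage: str,
    config: PipelineConfig,
    outdir: str | Path,
    force: bool = False,
) -> Path:
    """Run one stage, or ``all`` of them in order, under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = STAGE_ORDER if stage == "all" else [stage]
    if stage != "all" and stage not in STAGES:
        raise PipelineError(f"unknown stage {stage!r}; choose from {STAGE_ORDER + ['all']}")
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(handler)
    try:
        write_manifest(config, outdir, stages)
        for name in stages:
            STAGES[name](config, outdir, force)
    finally:
        handler.close()
        logger.removeHandler(handler)
    return outdir
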