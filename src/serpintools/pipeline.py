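"""End-to-end pipeline: collapse -> SSN -> MCL -> profile alignment ->
marker screen -> tree views, behind one structured YAML config.

Every stage is a pure call into the library; the pipeline adds input
loading, output writing, stage-level logging and a run manifest with
per-output checksums, so that a rerun with identical config and inputs is
checksum-identical for all deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import __version__
from .core_io import (
    Alignment,
    CdsRecord,
    SequenceRecord,
    hinge_motif_scan,
    length_filter,
    read_alignment,
    read_fasta,
    write_alignment,
    write_filter_report,
)
from .hgt_markers import CodonMarkerConfig, marker_report
from .profile_align import superfamily_align
from .ssn import (
    annotation_coverage,
    build_network,
    collapse_redundancy,
    mcl_cluster,
    write_cluster_table,
    write_edge_list,
    write_node_table,
)
from .tree_utils import collapse_low_support, midpoint_root, read_newick, write_newick

__all__ = ["PipelineConfig", "validate_config", "run_pipeline"]

logger = logging.getLogger(__name__)


class PipelineConfig(BaseModel):
    """Validated pipeline configuration.

    Threshold defaults are the published workflow's values: redundancy
    collapse at 75% identity, network edges above 40%, refinement at 52.5%,
    support collapse at 90, GC ratio bounds 0.8/1.2, a 25% length filter
    and a minimum reported cluster size of 4.
    """

    model_config = ConfigDict(extra="forbid")

    # inputs
    proteins: Path
    seed_alignment: Optional[Path] = None
    seed_alignment_format: str = "stockholm"
    cds: Optional[Path] = None
    genome_gc_table: Optional[Path] = None
    tree: Optional[Path] = None
    markers: bool = False
    marker_column: int = 0
    output_dir: Path = Path("pipeline_out")

    # thresholds (defaults are the published values)
    collapse_threshold: float = Field(75.0, ge=0.0, le=100.0)
    edge_threshold: float = Field(40.0, ge=0.0, le=100.0)
    recluster_threshold: float = Field(52.5, ge=0.0, le=100.0)
    support_collapse: float = Field(90.0, ge=0.0, le=100.0)
    gc_ratio_low: float = Field(0.8, gt=0.0)
    gc_ratio_high: float = Field(1.2, gt=0.0)
    length_tolerance: float = Field(0.25, ge=0.0, le=1.0)
    min_cluster_size: int = Field(4, ge=1)
    inflation: float = Field(2.0, gt=1.0, le=10.0)
    seed: int = 0

    @model_validator(mode="before")
    @classmethod
    def _normalize_gc_bounds(cls, data):
        if isinstance(data, dict):
            lo = data.get("gc_ratio_low")
            hi = data.get("gc_ratio_high")
            if lo is not None and hi is not None and lo > hi:
                data["gc_ratio_low"], data["gc_ratio_high"] = hi, lo
        return data

    @model_validator(mode="after")
    def _check_marker_inputs(self):
        if self.markers:
            missing = [name for name in ("cds", "genome_gc_table", "tree")
                       if getattr(self, name) is None]
            if missing:
                raise ValueError(
                    f"markers enabled but required inputs missing: {missing}"
                )
        return self


def validate_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML config; unknown keys are rejected and all
    violations are reported at once (pydantic aggregates them)."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    return PipelineConfig(**data)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """Run all configured stages in dependency order.

    Outputs land under ``config.output_dir``; a ``manifest.json`` with the
    config snapshot, package version, per-stage wall time and per-output
    sha256 checksums is written even when a stage fails (the failing stage
    is named in the raised error and in the manifest).
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": json.loads(config.model_dump_json()),
        "version": __version__,
        "stages": {},
        "outputs": {},
        "status": "running",
    }
    stage_name = "setup"

    def run_stage(name, fn):
        nonlocal stage_name
        stage_name = name
        t0 = time.perf_counter()
        logger.info("stage %s: start", name)
        result = fn()
        dt = time.perf_counter() - t0
        manifest["stages"][name] = {"wall_time_s": round(dt, 3)}
        logger.info("stage %s: done in %.2fs", name, dt)
        return result

    try:
        records = run_stage("load_inputs", lambda: read_fasta(config.proteins))

        def _filter():
            kept, removed = length_filter(records, config.length_tolerance)
            write_filter_report(kept, removed, out / "filter_report.tsv",
                                config.length_tolerance)
            return kept

        survivors = run_stage("length_filter", _filter)

        nodes = run_stage("collapse", lambda: collapse_redundancy(
            survivors, config.collapse_threshold))
        run_stage("write_nodes", lambda: write_node_table(
            nodes, survivors, out / "nodes.tsv"))

        network = run_stage("network", lambda: build_network(
            nodes, survivors, config.edge_threshold))
        run_stage("write_edges", lambda: write_edge_list(
            network, out / "edges.tsv"))

        clusters = run_stage("mcl", lambda: mcl_cluster(
            network, inflation=config.inflation))
        run_stage("write_clusters", lambda: write_cluster_table(
            clusters, out / "clusters.tsv"))

        def _coverage():
            table, summary = annotation_coverage(
                clusters, nodes, survivors, config.min_cluster_size)
            table.to_csv(out / "coverage.tsv", sep="\t", index=False)
            manifest["coverage_summary"] = summary
            return summary

        run_stage("annotation_coverage", _coverage)

        def _hinge():
            with (out / "hinge_motifs.tsv").open("w") as fh:
                fh.write("id\tstart\tmotif\n")
                for rec in survivors:
                    for start, motif in hinge_motif_scan(rec):
                        fh.write(f"{rec.id}\t{start}\t{motif}\n")

        run_stage("hinge_scan", _hinge)

        if config.seed_alignment is not None:
            def _align():
                seed_aln = read_alignment(config.seed_alignment,
                                          config.seed_alignment_format)
                mask = seed_aln.resolved_mask()
                by_node = {n.representative_id: n.member_ids for n in nodes}
                member_clusters = [
                    [mid for nid in cl for mid in by_node[nid]]
                    for cl in clusters.clusters
                ]
                aln = superfamily_align(
                    seed_aln, mask, member_clusters, survivors,
                    length_tolerance=config.length_tolerance)
                write_alignment(aln, out / "alignment.fasta")
                return aln

            final_alignment = run_stage("superfamily_align", _align)

        if config.markers:
            def _markers():
                cds_records = _read_cds(config.cds, config.genome_gc_table)
                tree = read_newick(config.tree)
                aln = final_alignment if config.seed_alignment is not None \
                    else _trivial_alignment(survivors)
                table, summary = marker_report(
                    cds_records, aln, tree,
                    CodonMarkerConfig(marker_column=config.marker_column))
                table.to_csv(out / "marker_report.tsv", sep="\t", index=False)
                (out / "parsimony.json").write_text(
                    json.dumps(summary, indent=1))

            run_stage("markers", _markers)

        if config.tree is not None:
            def _trees():
                tree = read_newick(config.tree)
                rooted = midpoint_root(tree)
                (out / "midpoint_rooted.nwk").write_text(
                    write_newick(rooted) + "\n")
                collapsed, log = collapse_low_support(
                    tree, config.support_collapse)
                (out / "support_collapsed.nwk").write_text(
                    write_newick(collapsed) + "\n")
                manifest["collapsed_edges"] = len(log)

            run_stage("tree_views", _trees)

        manifest["status"] = "ok"
    except Exception as exc:
        manifest["status"] = f"failed at stage {stage_name}: {exc}"
        raise RuntimeError(f"pipeline failed at stage {stage_name!r}: {exc}") from exc
    finally:
        for p in sorted(out.iterdir()):
            if p.is_file() and p.name != "manifest.json":
                manifest["outputs"][p.name] = _sha256(p)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out


def _read_cds(cds_path: Path, gc_table: Path) -> list[CdsRecord]:
    gc: dict[str, float] = {}
    lines = Path(gc_table).read_text().splitlines()
    for line in lines[1:]:  # header: id <TAB> genome_gc
        if not line.strip():
            continue
        gid, value = line.split("\t")[:2]
        gc[gid] = float(value)
    records = []
    for rec in read_fasta_dna(cds_path):
        if rec[0] not in gc:
            raise ValueError(f"no genome GC entry for gene {rec[0]!r}")
        records.append(CdsRecord(id=rec[0], cds=rec[1], genome_gc=gc[rec[0]]))
    return records


def read_fasta_dna(path: Path) -> list[tuple[str, str]]:
    """(id, sequence) pairs from a DNA FASTA (no protein-alphabet check)."""
    from Bio import SeqIO

    out = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate id {rec.id!r} in {path}")
        seen.add(rec.id)
        out.append((rec.id, str(rec.seq).upper()))
    return out


def _trivial_alignment(records: list[SequenceRecord]) -> Alignment:
    """Pad-to-width alignment used only when no seed alignment is given."""
    width = max(len(r.sequence) for r in records)
    return Alignment(rows=[(r.id, r.sequence.ljust(width, "-"))
                           for r in records])
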