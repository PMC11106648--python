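"""End-to-end run: read structures, segment, score, cluster, superpose, report.

One invocation processes a set of coordinate files plus a mapping table and
writes, per segment: the GLOCON matrix (CSV and PHYLIP), the UPGMA
dendrogram (Newick), the cluster assignment (CSV), superposed coordinates
(mmCIF, all chains in the frame of the top cluster's representative) and —
when a predicted model is supplied for the accession — a model-vs-state
RMSD table.  A JSON summary records counts, parameters and a content hash
of the text outputs so that reruns can be checked for byte identity.

The analysis path contains no randomness; rerunning on the same inputs
produces byte-identical outputs regardless of input file order.

Failures are isolated per segment: a corrupt file or an unscorable chain
pair marks its segment failed and the run continues; the run as a whole is
reported failed if any segment hard-failed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import __version__
from .clustering import ClusterAssignment, Dendrogram, cut_dendrogram, upgma
from .errors import GloconError
from .score import GloconMatrix, GloconParams, pairwise_glocon
from .segmentation import Segment, assign_segments, segments_report
from .structure_io import (
    ChainRecord,
    MappingRow,
    MappingTable,
    extract_chain,
    read_structure,
    select_model,
    write_superposed,
)
from .superpose import kabsch_superpose, model_vs_representatives, superpose_segment

logger = logging.getLogger("glocon")


@dataclass
class PipelineConfig:
    """Validated configuration for one pipeline run."""

    inputs: list[Path]                 # coordinate files, or a single directory
    mapping_path: Path
    out_dir: Path
    params: GloconParams = field(default_factory=GloconParams)
    min_overlap_fraction: float = 0.8
    model_paths: dict[str, Path] = field(default_factory=dict)  # accession -> file
    log_level: str = "INFO"

    def resolve_input_files(self) -> list[Path]:
        files: list[Path] = []
        for p in self.inputs:
            if p.is_dir():
                files.extend(
                    q for q in p.iterdir()
                    if q.suffix.lower() in (".cif", ".pdb", ".ent", ".mmcif")
                )
            else:
                files.append(p)
        # canonical order: results must not depend on filesystem enumeration
        return sorted(set(files), key=lambda q: q.name)

    def validate(self) -> None:
        if not 0 < self.min_overlap_fraction <= 1:
            raise ValueError("min_overlap_fraction must be in (0, 1]")
        for p in self.inputs:
            if not p.exists():
                raise FileNotFoundError(f"input path does not exist: {p}")
        if not self.mapping_path.exists():
            raise FileNotFoundError(f"mapping table does not exist: {self.mapping_path}")
        for acc, p in self.model_paths.items():
            if not p.exists():
                raise FileNotFoundError(f"model file for {acc} does not exist: {p}")
        if not self.resolve_input_files():
            raise FileNotFoundError("no coordinate files found among the inputs")


@dataclass
class SegmentResult:
    segment: Segment
    status: str                       # "ok" | "failed" | "skipped"
    message: str = ""
    glocon: Optional[GloconMatrix] = None
    dendrogram: Optional[Dendrogram] = None
    assignment: Optional[ClusterAssignment] = None
    model_rmsd: Optional[dict[int, Optional[float]]] = None
    closest_cluster: Optional[int] = None


@dataclass
class RunReport:
    segments: list[SegmentResult]
    failed_files: list[tuple[str, str]]
    summary: dict

    @property
    def ok(self) -> bool:
        return not self.failed_files and all(
            s.status != "failed" for s in self.segments
        )


def _load_chains(
    files: Sequence[Path], mapping: MappingTable
) -> tuple[list[ChainRecord], list[tuple[str, str]], set[str]]:
    """Read every mapped chain; collect per-file errors and affected accessions."""
    records: list[ChainRecord] = []
    failures: list[tuple[str, str]] = []
    failed_accessions: set[str] = set()
    for path in files:
        sid = path.stem
        rows = [r for r in mapping if r.structure_id == sid]
        if not rows:
            logger.warning("no mapping rows for %s; file skipped", path.name)
            continue
        try:
            handle = select_model(read_structure(path))
        except GloconError as exc:
            failures.append((path.name, str(exc)))
            failed_accessions.update(r.accession for r in rows)
            continue
        for row in rows:
            try:
                records.append(extract_chain(handle, row.chain_id, row))
            except GloconError as exc:
                failures.append((f"{path.name}:{row.chain_id}", str(exc)))
                failed_accessions.add(row.accession)
    return records, failures, failed_accessions


def _load_model_chain(path: Path, segment: Segment) -> ChainRecord:
    """Read a predicted model: first chain of the first model, reference numbering.

    Predicted models are assumed to be numbered directly in reference
    coordinates (full-length models are), so the mapping offset is zero and
    the interval is the segment's.
    """
    handle = select_model(read_structure(path))
    chain_id = handle[0][0].name
    row = MappingRow(path.stem, chain_id, segment.accession,
                     segment.ref_start, segment.ref_end, 0)
    return extract_chain(handle, chain_id, row)


def _process_segment(
    seg: Segment,
    cfg: PipelineConfig,
    out_dir: Path,
) -> SegmentResult:
    if len(seg.members) < 2:
        return SegmentResult(seg, "skipped", "fewer than 2 chains; nothing to cluster")
    try:
        g = pairwise_glocon(seg, cfg.params)
        dend = upgma(g)
        assignment = cut_dendrogram(dend, g, cfg.params.cut_fraction)
    except GloconError as exc:
        return SegmentResult(seg, "failed", str(exc))

    g.to_csv(out_dir / f"{seg.segment_id}_glocon.csv")
    g.to_phylip(out_dir / f"{seg.segment_id}_glocon.phy")
    (out_dir / f"{seg.segment_id}_dendrogram.nwk").write_text(dend.to_newick() + "\n")

    rows = [
        {
            "segment_id": seg.segment_id,
            "structure_id": seg.member(cid).structure_id,
            "chain_id": seg.member(cid).chain_id,
            "cluster": assignment.labels[cid],
            "is_representative": assignment.representatives[assignment.labels[cid]] == cid,
        }
        for cid in sorted(assignment.labels)
    ]
    pd.DataFrame(rows).to_csv(out_dir / f"{seg.segment_id}_clusters.csv", index=False)

    # common display frame: the representative of the largest cluster
    reference = assignment.representatives[1]
    try:
        sup = superpose_segment(seg, reference)
    except RuntimeError as exc:
        return SegmentResult(seg, "failed", str(exc), g, dend, assignment)
    ordered = sorted(seg.members, key=lambda m: m.key)
    transforms = [None if m.key == reference else sup[m.key].transform for m in ordered]
    write_superposed(ordered, transforms, out_dir / f"{seg.segment_id}_superposed.cif")

    model_rmsd = None
    closest = None
    if seg.accession in cfg.model_paths:
        try:
            model = _load_model_chain(cfg.model_paths[seg.accession], seg)
        except GloconError as exc:
            return SegmentResult(seg, "failed", f"model load failed: {exc}",
                                 g, dend, assignment)
        chains = {m.key: m for m in seg.members}
        per_cluster, closest = model_vs_representatives(model, assignment, chains)
        model_rmsd = {
            lbl: (None if r is None else r.rmsd) for lbl, r in per_cluster.items()
        }
        pd.DataFrame(
            [
                {
                    "segment_id": seg.segment_id,
                    "cluster": lbl,
                    "representative": assignment.representatives[lbl],
                    "model_rmsd": "" if r is None else f"{r.rmsd:.6f}",
                    "n_aligned": 0 if r is None else r.n_aligned,
                    "is_closest": lbl == closest,
                }
                for lbl, r in sorted(per_cluster.items())
            ]
        ).to_csv(out_dir / f"{seg.segment_id}_model_rmsd.csv", index=False)

    return SegmentResult(seg, "ok", "", g, dend, assignment, model_rmsd, closest)


def _output_hash(out_dir: Path) -> str:
    """SHA-256 over the sorted text outputs (CSV/Newick/PHYLIP) of a run."""
    h = hashlib.sha256()
    for p in sorted(out_dir.glob("*")):
        if p.suffix in (".csv", ".nwk", ".phy"):
            h.update(p.name.encode())
            h.update(p.read_bytes())
    return h.hexdigest()


def run(config: PipelineConfig) -> RunReport:
    """Execute the full pipeline; see module docstring for outputs."""
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out_dir = config.out_dir
    out_dir.mkdir(parents=True, exist_ok=True)

    mapping = MappingTable.read_tsv(config.mapping_path)
    files = config.resolve_input_files()
    records, failed_files, failed_accessions = _load_chains(files, mapping)

    segments = assign_segments(records, mapping, config.min_overlap_fraction)
    segments_report(segments, out_dir / "segments.csv")

    results: list[SegmentResult] = []
    for seg in segments:
        if seg.accession in failed_accessions:
            results.append(SegmentResult(
                seg, "failed", "a file mapping to this accession failed to load"))
            continue
        results.append(_process_segment(seg, config, out_dir))

    summary = {
        "version": __version__,
        "parameters": {
            "noise_threshold": config.params.noise_threshold,
            "normalization_mode": config.params.normalization_mode,
            "cut_fraction": config.params.cut_fraction,
            "min_overlap_fraction": config.min_overlap_fraction,
        },
        "n_input_files": len(files),
        "n_chains": len(records),
        "n_segments": len(segments),
        "segments": {
            r.segment.segment_id: {
                "status": r.status,
                "message": r.message,
                "n_chains": len(r.segment.members),
                "n_clusters": r.assignment.n_clusters if r.assignment else None,
                "cut_height": r.assignment.cut_height if r.assignment else None,
                "closest_cluster_to_model": r.closest_cluster,
            }
            for r in results
        },
        "failed_files": failed_files,
        "output_hash": _output_hash(out_dir),
    }
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)

    return RunReport(results, failed_files, summary)
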