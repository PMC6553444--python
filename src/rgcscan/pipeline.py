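"""End-to-end scan: detect → classify → polarize → export.

Order matters and is fixed: indel events are characterized on the UNSTRIPPED
alignment (gap columns carry the events); only afterwards are gap columns
stripped to form the nucleotide matrix that is exported alongside the binary
characters.  Optionally the second inverted-repeat copy (IRa) is excised
first to remove its redundancy, and binary characters are mapped onto a tree
as taxonomic markers.  A JSON manifest records the stage order, versions,
configuration and counts; on any stage failure the partial outputs are
removed and the failing stage is named.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import __version__
from .coding import build_matrix, polarize, write_combined, write_restriction_nexus
from .detect import (
    RgcConfig,
    cluster_events,
    extract_gap_runs,
    filter_rgc,
    flag_ambiguous,
)
from .errors import ConfigError, DataError, StageError
from .io import Alignment, excise_interval, read_alignment, read_newick, strip_gap_columns
from .markers import marker_report
from .mechanism import MechanismConfig, classify_mechanism

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    alignment_path: str
    outgroups: tuple[str, ...]
    output_dir: str
    tree_path: Optional[str] = None
    rgc: RgcConfig = field(default_factory=RgcConfig)
    mechanism: MechanismConfig = field(default_factory=MechanismConfig)
    strip_mode: str = "any_gap"
    ira_interval: Optional[tuple[int, int]] = None
    seed: int = 0

    def __post_init__(self):
        if not self.outgroups:
            raise ConfigError("at least one outgroup taxon is required")


@dataclass(frozen=True)
class ScanResult:
    events: tuple
    rgc: tuple
    microstructural: tuple
    ambiguous: tuple
    matrix: object
    report: object  # MarkerReport or None
    manifest: dict
    output_dir: Path


def _event_table(events) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "id": e.id,
                "start_col": e.cols[0],
                "end_col": e.cols[1],
                "length": e.length,
                "n_gap_taxa": len(e.gap_taxa),
                "gap_taxa": ",".join(sorted(e.gap_taxa)),
                "status": e.status,
                "polarity": e.polarity,
                "mechanism": e.mechanism,
            }
            for e in events
        ],
        columns=["id", "start_col", "end_col", "length", "n_gap_taxa",
                 "gap_taxa", "status", "polarity", "mechanism"],
    )


def _mechanism_table(events) -> pd.DataFrame:
    rows = []
    for e in events:
        rep = e.flanking_repeat
        tan = e.tandem
        rows.append(
            {
                "event_id": e.id,
                "mechanism": e.mechanism,
                "repeat_seq": rep.sequence if rep else (tan.unit if tan else ""),
                "repeat_len": rep.length if rep else (tan.unit_length if tan else 0),
                "reference_taxon": (
                    rep.reference_taxon if rep else (tan.reference_taxon if tan else "")
                ),
                "copy1": f"{rep.copy1_cols[0]}-{rep.copy1_cols[1]}" if rep else "",
                "copy2": f"{rep.copy2_cols[0]}-{rep.copy2_cols[1]}" if rep else "",
            }
        )
    return pd.DataFrame(
        rows,
        columns=["event_id", "mechanism", "repeat_seq", "repeat_len",
                 "reference_taxon", "copy1", "copy2"],
    )


def run_scan(cfg: RunConfig) -> ScanResult:
    """Execute the full analysis; writes the artifact bundle to the output
    directory and returns the in-memory results."""
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stages: list[str] = []

    def _emit(name: str, writer) -> Path:
        path = outdir / name
        writer(path)
        written.append(path)
        return path

    try:
        stage = "read_alignment"
        stages.append(stage)
        aln = read_alignment(cfg.alignment_path)
        for og in cfg.outgroups:
            if og not in aln.taxa:
                raise DataError(f"outgroup taxon {og!r} not in alignment")

        if cfg.ira_interval is not None:
            stage = "excise_ira"
            stages.append(stage)
            aln = excise_interval(aln, cfg.ira_interval)

        stage = "detect_events"  # on the UNSTRIPPED alignment
        stages.append(stage)
        runs = extract_gap_runs(aln)
        events = cluster_events(runs, cfg.rgc)
        events = flag_ambiguous(events, aln, cfg.outgroups, cfg.rgc)
        split = filter_rgc(events, cfg.rgc)

        stage = "classify_mechanism"
        stages.append(stage)
        rgc = tuple(classify_mechanism(aln, e, cfg.mechanism) for e in split.rgc)

        stage = "polarize"
        stages.append(stage)
        chars = [polarize(e, aln, cfg.outgroups,
                          cfg.rgc.present_max_gap_fraction,
                          cfg.rgc.absent_min_gap_fraction) for e in rgc]
        polarity = {c.event_id: c.polarity for c in chars if c is not None}
        rgc = tuple(
            dataclasses.replace(e, polarity=polarity.get(e.id, "unknown"))
            for e in rgc
        )
        matrix = build_matrix(chars, taxa=aln.taxa)

        stage = "strip_gap_columns"  # after event characterization
        stages.append(stage)
        stripped = strip_gap_columns(aln, cfg.strip_mode)

        stage = "write_outputs"
        stages.append(stage)
        _emit("events.tsv", lambda p: _event_table(
            list(rgc) + list(split.microstructural) + list(split.ambiguous)
        ).to_csv(p, sep="\t", index=False))
        _emit("mechanisms.tsv",
              lambda p: _mechanism_table(rgc).to_csv(p, sep="\t", index=False))
        _emit("rgc_matrix.nex", lambda p: write_restriction_nexus(matrix, p))
        phy, part = write_combined(stripped, matrix, outdir / "combined")
        written += [phy, part]

        report = None
        if cfg.tree_path is not None:
            stage = "map_markers"
            stages.append(stage)
            tree = read_newick(cfg.tree_path)
            report = marker_report(tree, matrix, cfg.outgroups)
            _emit("markers.tsv",
                  lambda p: report.to_dataframe().to_csv(p, sep="\t", index=False))

        stage = "manifest"
        stages.append(stage)
        manifest = {
            "rgcscan_version": __version__,
            "stage_order": stages,
            "config": {
                "alignment": str(cfg.alignment_path),
                "outgroups": list(cfg.outgroups),
                "tree": str(cfg.tree_path) if cfg.tree_path else None,
                "strip_mode": cfg.strip_mode,
                "ira_interval": list(cfg.ira_interval) if cfg.ira_interval else None,
                "min_rgc_len": cfg.rgc.min_rgc_len,
                "min_repeat_len": cfg.mechanism.min_repeat_len,
                "max_boundary_offset": cfg.mechanism.max_boundary_offset,
                "seed": cfg.seed,
            },
            "counts": {
                "taxa": len(aln.taxa),
                "columns": aln.column_count,
                "stripped_columns": stripped.column_count,
                "events": len(events),
                "rgc": len(rgc),
                "microstructural": len(split.microstructural),
                "ambiguous": len(split.ambiguous),
                "binary_characters": matrix.n_characters,
            },
        }
        if report is not None:
            manifest["counts"]["markers"] = report.counts
        _emit("manifest.json",
              lambda p: p.write_text(json.dumps(manifest, indent=2) + "\n"))
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        if isinstance(exc, (DataError, ConfigError)):
            raise StageError(stage, exc) from exc
        raise
    return ScanResult(
        events=tuple(events),
        rgc=rgc,
        microstructural=split.microstructural,
        ambiguous=split.ambiguous,
        matrix=matrix,
        report=report,
        manifest=manifest,
        output_dir=outdir,
    )
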