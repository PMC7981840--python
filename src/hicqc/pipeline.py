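"""End-to-end composition: extract -> read context -> QC report.

Also provides the pairs/FASTQ annotation step shared by the estimator (the
short-insert subset and adapter flags) and the multi-library comparison
table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from ._seq import revcomp
from .adapters import AdapterSpec, get_adapter
from .pairs import extract_pairs, write_pairs_tsv
from .qc import (
    INSERT_MAX_DEFAULT,
    BackLigationModel,
    EstimatorError,
    LibraryQCReport,
    summarize_library,
)
from .readctx import merge_inserts_batch

log = logging.getLogger("hicqc")


class PipelineConfigError(ValueError):
    """Invalid pipeline configuration (bad paths or parameters)."""


def read_fastq_pairs(path_r1: str, path_r2: str) -> dict[str, tuple[str, str]]:
    """Load a FASTQ pair into a read-id -> (mate1, mate2) mapping."""
    reads: dict[str, tuple[str, str]] = {}
    with pysam.FastxFile(path_r1) as f1, pysam.FastxFile(path_r2) as f2:
        for e1, e2 in zip(f1, f2):
            if e1.name != e2.name:
                raise PipelineConfigError(
                    f"mate files out of sync: {e1.name!r} vs {e2.name!r}"
                )
            reads[e1.name] = (e1.sequence.upper(), e2.sequence.upper())
    return reads


def annotate_pairs(
    pairs: pd.DataFrame,
    reads: dict[str, tuple[str, str]],
    adapter: AdapterSpec | None,
    min_overlap: int = 10,
    max_mismatch_rate: float = 0.1,
) -> pd.DataFrame:
    """Add ``insert`` and ``has_adapter`` columns to a pairs table.

    The insert is called by mate-overlap merging (-1 when the mates do not
    overlap, i.e. the fragment exceeds the summed read lengths); the
    adapter flag records an exact full-length occurrence of the adapter
    (either strand) in the merged fragment sequence.  Only cis valid pairs
    are annotated — the estimator uses nothing else.
    """
    out = pairs.copy()
    out["insert"] = -1
    out["has_adapter"] = False
    mask = (out["status"] == "valid") & out["orientation"].isin(("FR", "RF", "FF", "RR"))
    ids = out["read_id"].to_numpy()
    hit = [i for i in np.nonzero(mask.to_numpy())[0] if ids[i] in reads]
    if not hit:
        return out
    r1 = [reads[ids[i]][0] for i in hit]
    r2 = [reads[ids[i]][1] for i in hit]
    inserts, merged = merge_inserts_batch(
        r1, r2, min_overlap=min_overlap, max_mismatch_rate=max_mismatch_rate
    )
    labels = out.index.to_numpy()[hit]
    out.loc[labels, "insert"] = inserts
    if adapter is not None:
        fwd = adapter.sequence
        rev = revcomp(fwd)
        flags = [m is not None and (fwd in m or rev in m) for m in merged]
        out.loc[labels, "has_adapter"] = flags
    return out


@dataclass
class PipelineConfig:
    """Configuration of one `run` invocation."""

    sam: str
    out: str
    r1: str | None = None
    r2: str | None = None
    adapter: str | None = None       # preset name or raw sequence
    c: float | None = None           # incidental rate; default from preset
    min_mapq: int = 1
    insert_max: int = INSERT_MAX_DEFAULT
    merge_min_overlap: int = 10
    merge_max_mismatch_rate: float = 0.1
    n_boot: int = 200
    seed: int = 0

    def validate(self) -> None:
        if not Path(self.sam).exists():
            raise PipelineConfigError(f"SAM file not found: {self.sam}")
        for p in (self.r1, self.r2):
            if p is not None and not Path(p).exists():
                raise PipelineConfigError(f"FASTQ file not found: {p}")
        if (self.r1 is None) != (self.r2 is None):
            raise PipelineConfigError("r1 and r2 must be given together")
        if self.c is not None and not 0.0 <= self.c < 1.0:
            raise PipelineConfigError(f"c must be in [0, 1), got {self.c}")
        if self.min_mapq < 0:
            raise PipelineConfigError("min_mapq must be >= 0")


def run_pipeline(config: PipelineConfig) -> LibraryQCReport:
    """extract -> (context) -> qc; writes pairs.tsv, report.json, report.tsv."""
    config.validate()
    outdir = Path(config.out)
    outdir.mkdir(parents=True, exist_ok=True)

    log.info("extracting pairs from %s", config.sam)
    pairs = extract_pairs(config.sam, min_mapq=config.min_mapq)
    counts = pairs.attrs["stage_counts"]
    log.info(
        "stage counts: total=%(total)d mapped=%(mapped)d two_sided=%(two_sided)d "
        "valid=%(valid)d deduplicated=%(deduplicated)d", counts,
    )

    results = None
    adapter = get_adapter(config.adapter) if config.adapter else None
    if config.r1 and adapter is not None:
        log.info("annotating short-insert subset from %s / %s", config.r1, config.r2)
        reads = read_fastq_pairs(config.r1, config.r2)
        pairs = annotate_pairs(
            pairs, reads, adapter,
            min_overlap=config.merge_min_overlap,
            max_mismatch_rate=config.merge_max_mismatch_rate,
        )
        n_subset = int(((pairs["insert"] >= 0) & (pairs["insert"] < config.insert_max)
                        & (pairs["status"] == "valid")).sum())
        log.info("short-insert subset (< %d bp): %d pairs", config.insert_max, n_subset)
        c = config.c
        if c is None:
            c = adapter.incidental_rate if adapter.incidental_rate is not None else 0.0
        model = BackLigationModel.from_annotated_pairs(pairs, c=c, insert_max=config.insert_max)
        try:
            results = model.fit(n_boot=config.n_boot, seed=config.seed)
        except EstimatorError as exc:
            log.warning("back-ligation estimator unavailable: %s", exc)

    write_pairs_tsv(pairs, str(outdir / "pairs.tsv"))
    report = summarize_library(
        pairs, raw_read_count=counts["total"], results=results,
        insert_max=config.insert_max,
    )
    report.to_json(str(outdir / "report.json"))
    pd.DataFrame([report.flat_row()]).to_csv(outdir / "report.tsv", sep="\t", index=False)
    return report


def compare_libraries(report_paths: list[str], names: list[str] | None = None) -> pd.DataFrame:
    """Combine per-library JSON reports into one comparison table."""
    import json

    if not report_paths:
        raise PipelineConfigError("at least one report required")
    rows = []
    names = names or [Path(p).parent.name or Path(p).stem for p in report_paths]
    for name, path in zip(names, report_paths):
        with open(path) as fh:
            data = json.load(fh)
        try:
            rep = LibraryQCReport.from_dict(data)
        except ValueError as exc:
            raise PipelineConfigError(f"{path}: {exc}") from exc
        rows.append({"library": name, **rep.flat_row()})
    return pd.DataFrame(rows)
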