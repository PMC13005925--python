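"""Per-target read depth extraction and three-stage normalization.

Raw fragment counts (``RD_r``) are corrected for target length
(``RD_l = RD_r / L``), for GC composition against a LOWESS trend
(``RD_GC = RD_l / (Fit / median(Fit))``), and finally scaled so the
panel-wide median is 1 (``RD_nor``).  Stages are tracked on the vector
and transitions are enforced in order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from .targets import Panel, canonical_chrom

__all__ = [
    "Stage",
    "DepthVector",
    "GcCurve",
    "count_reads",
    "length_normalize",
    "fit_gc_curve",
    "gc_correct",
    "global_normalize",
    "normalize_depth",
    "write_depth_tsv",
    "read_depth_tsv",
]


class Stage:
    RAW = "RD_r"
    LENGTH = "RD_l"
    GC = "RD_GC"
    NORM = "RD_nor"


_ORDER = [Stage.RAW, Stage.LENGTH, Stage.GC, Stage.NORM]


@dataclass
class DepthVector:
    """Per-target depth values of one sample at a named normalization stage."""

    values: np.ndarray
    stage: str
    sample_id: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.stage not in _ORDER:
            raise ValueError(f"unknown stage {self.stage!r}")
        if np.any(self.values < 0):
            raise ValueError("depth values must be non-negative")

    def __len__(self) -> int:
        return len(self.values)


def _require_stage(rd: DepthVector, stage: str) -> None:
    if rd.stage != stage:
        raise ValueError(f"expected stage {stage}, got {rd.stage}")


@dataclass
class GcCurve:
    """LOWESS estimate of depth vs GC, floored at a small positive epsilon."""

    fit: np.ndarray
    span: float
    fit_median: float = field(init=False)

    def __post_init__(self):
        self.fit = np.asarray(self.fit, dtype=float)
        if np.any(self.fit <= 0):
            raise ValueError("GC curve fit values must be positive")
        self.fit_median = float(np.median(self.fit))


def count_reads(bam_path: str | Path, panel: Panel, min_mapq: int = 1) -> DepthVector:
    """Count properly-paired fragments overlapping each target.

    A fragment (read pair) is counted once per region it overlaps, even
    when both mates fall inside the region.  Duplicates, secondary and
    supplementary alignments, QC failures, unmapped reads and reads
    below ``min_mapq`` are excluded.
    """
    import pysam

    with pysam.AlignmentFile(str(bam_path)) as bam:
        if not bam.has_index():
            raise ValueError(f"{bam_path}: BAM index required (run samtools index)")
        refs = {canonical_chrom(r): r for r in bam.references}
        values = np.zeros(len(panel))
        warned: set[str] = set()
        for i, region in enumerate(panel):
            ref = refs.get(region.chrom)
            if ref is None:
                if region.chrom not in warned:
                    warnings.warn(
                        f"chromosome {region.chrom} absent from BAM header; counting 0"
                    )
                    warned.add(region.chrom)
                continue
            fragments: set[str] = set()
            for read in bam.fetch(ref, region.start, region.end):
                if (
                    read.is_unmapped
                    or read.is_duplicate
                    or read.is_secondary
                    or read.is_supplementary
                    or read.is_qcfail
                    or not read.is_proper_pair
                    or read.mapping_quality < min_mapq
                ):
                    continue
                fragments.add(read.query_name)
            values[i] = len(fragments)
    return DepthVector(values, Stage.RAW, sample_id=Path(bam_path).stem)


def length_normalize(rd: DepthVector, panel: Panel) -> DepthVector:
    """RD_l = RD_r / L."""
    _require_stage(rd, Stage.RAW)
    if len(rd) != len(panel):
        raise ValueError("depth vector length does not match panel")
    return DepthVector(rd.values / panel.lengths, Stage.LENGTH, rd.sample_id)


def fit_gc_curve(
    rd: DepthVector,
    panel: Panel,
    span: float = 0.3,
    min_targets: int = 50,
    floor_frac: float = 1e-3,
) -> GcCurve:
    """LOWESS fit of length-normalized depth against GC fraction.

    Targets without a valid GC value receive the median fit (neutral
    correction).  Degenerate GC spread falls back to a flat curve at the
    global median depth.
    """
    _require_stage(rd, Stage.LENGTH)
    gc = panel.gc
    valid = np.isfinite(gc)
    if valid.sum() < min_targets:
        raise ValueError(
            f"only {int(valid.sum())} targets with valid GC; need >= {min_targets}"
        )
    fit = np.empty(len(rd))
    x, y = gc[valid], rd.values[valid]
    if np.ptp(x) == 0:
        fit[:] = np.median(y)
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pred = _sm_lowess(y, x, frac=span, it=1, xvals=x)
        fit[valid] = pred
        fit[~valid] = np.median(pred)
    med = np.median(fit)
    if not np.isfinite(med) or med <= 0:
        fit[:] = max(np.median(y), 1e-12)
        med = np.median(fit)
    floor = max(floor_frac * med, 1e-12)
    fit = np.maximum(fit, floor)
    return GcCurve(fit, span=span)


def gc_correct(rd: DepthVector, curve: GcCurve) -> DepthVector:
    """RD_GC = RD_l / (Fit / median(Fit))."""
    _require_stage(rd, Stage.LENGTH)
    if len(curve.fit) != len(rd):
        raise ValueError("GC curve length does not match depth vector")
    return DepthVector(
        rd.values / (curve.fit / curve.fit_median), Stage.GC, rd.sample_id
    )


def global_normalize(rd: DepthVector, include: Optional[np.ndarray] = None) -> DepthVector:
    """RD_nor = RD_GC / median(RD_GC); median taken over included targets."""
    _require_stage(rd, Stage.GC)
    vals = rd.values if include is None else rd.values[np.asarray(include, bool)]
    med = np.median(vals)
    if med <= 0:
        raise ValueError("sample has no usable coverage (median depth is 0)")
    return DepthVector(rd.values / med, Stage.NORM, rd.sample_id)


def normalize_depth(
    rd: DepthVector,
    panel: Panel,
    span: float = 0.3,
    min_gc_targets: int = 50,
) -> DepthVector:
    """Full RD_r -> RD_nor chain for one sample."""
    rd_l = length_normalize(rd, panel)
    curve = fit_gc_curve(rd_l, panel, span=span, min_targets=min_gc_targets)
    rd_gc = gc_correct(rd_l, curve)
    return global_normalize(rd_gc)


def write_depth_tsv(rd: DepthVector, panel: Panel, path: str | Path) -> None:
    df = panel.to_dataframe()[["chrom", "start", "end", "gene"]].copy()
    df["value"] = rd.values
    with open(path, "w") as fh:
        fh.write(f"# stage={rd.stage} sample={rd.sample_id}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_depth_tsv(path: str | Path, panel: Optional[Panel] = None) -> DepthVector:
    stage, sample_id = Stage.RAW, ""
    with open(path) as fh:
        first = fh.readline()
    skip = 0
    if first.startswith("#"):
        skip = 1
        for token in first[1:].split():
            if token.startswith("stage="):
                stage = token.split("=", 1)[1]
            elif token.startswith("sample="):
                sample_id = token.split("=", 1)[1]
    df = pd.read_csv(path, sep="\t", skiprows=skip)
    if "value" not in df.columns:
        raise ValueError(f"{path}: depth TSV requires a 'value' column")
    if panel is not None:
        if len(df) != len(panel):
            raise ValueError(f"{path}: {len(df)} rows, panel has {len(panel)} targets")
        same = np.all(
            [canonical_chrom(c) for c in df["chrom"]] == panel.chroms
        ) and np.array_equal(df["start"].to_numpy(), panel.starts)
        if not same:
            raise ValueError(f"{path}: depth TSV coordinates do not match panel")
    return DepthVector(df["value"].to_numpy(float), stage, sample_id)
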