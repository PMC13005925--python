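"""End-to-end orchestration: normalize -> stable chromosome -> ridge ->
segment -> call, plus the benchmark driver used for in-silico evaluation."""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .baseline import BaselineCohort, build_pon
from .calling import CallThresholds, CNVCall, call_segments
from .depth import DepthVector, Stage, count_reads, normalize_depth
from .ridge import LogRatioProfile, RidgeModel, self_normalize
from .segment import (
    CbsParams,
    PresegConfig,
    SegmentSet,
    SmootherConfig,
    segment_profile,
)
from .simulate import BenchmarkData, EvalResult, SimConfig, evaluate_calls, simulate_benchmark
from .stable import select_stable_chromosome
from .targets import Panel

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "build_pon_from_depths",
           "run_benchmark", "BenchmarkOutcome"]


@dataclass
class PipelineConfig:
    """Every tunable of the single-sample workflow, with the package defaults."""

    min_mapq: int = 1
    lowess_span: float = 0.3
    min_gc_targets: int = 50
    depth_floor: float = 0.05
    pseudocount: float = 1e-3
    ridge_alpha: float = 1.0
    stable_min_targets: int = 10
    mean_of_abs: bool = False
    z_thresh: float = 3.0
    min_sd: float = 0.05
    min_window: int = 5
    smooth_alpha: float = 0.3
    cbs_alpha: float = 0.01
    cbs_nperm: int = 10_000
    t_del0: float = -1.1
    t_del1: float = -0.25
    t_amp: float = 0.2
    t_amp2: float = 0.7
    seed: int = 0

    def preseg(self) -> PresegConfig:
        return PresegConfig(self.z_thresh, self.min_sd, self.min_window)

    def smoother(self) -> SmootherConfig:
        return SmootherConfig(self.smooth_alpha)

    def cbs(self) -> CbsParams:
        return CbsParams(alpha=self.cbs_alpha, nperm=self.cbs_nperm)

    def thresholds(self) -> CallThresholds:
        return CallThresholds(self.t_del0, self.t_del1, self.t_amp, self.t_amp2)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class PipelineResult:
    profile: LogRatioProfile
    smoothed: LogRatioProfile
    stable_chrom: str
    stability: pd.DataFrame
    model: RidgeModel
    segments: SegmentSet
    calls: list[CNVCall]
    manifest: dict


def build_pon_from_depths(
    raw_depths: list[DepthVector], panel: Panel, config: Optional[PipelineConfig] = None
) -> BaselineCohort:
    """Normalize raw baseline counts and assemble the PoN."""
    config = config or PipelineConfig()
    normed = [
        normalize_depth(rd, panel, span=config.lowess_span, min_gc_targets=config.min_gc_targets)
        if rd.stage == Stage.RAW
        else rd
        for rd in raw_depths
    ]
    return build_pon(normed, panel, depth_floor=config.depth_floor)


def run_pipeline(
    sample: DepthVector | str | Path,
    pon: BaselineCohort,
    panel: Panel,
    config: Optional[PipelineConfig] = None,
    purity: Optional[float] = None,
    seed: Optional[int] = None,
) -> PipelineResult:
    """Run the full single-sample workflow.

    ``sample`` is either a raw/normalized depth vector or a BAM path.
    All randomness (CBS permutations) flows from ``seed`` (falls back to
    ``config.seed``).
    """
    config = config or PipelineConfig()
    seed = config.seed if seed is None else seed
    if pon.panel_digest != panel.digest():
        raise ValueError("PoN digest does not match the panel")

    if isinstance(sample, (str, Path)):
        sample = count_reads(sample, panel, min_mapq=config.min_mapq)
    if sample.stage == Stage.RAW:
        sample = normalize_depth(
            sample, panel, span=config.lowess_span, min_gc_targets=config.min_gc_targets
        )
    if sample.stage != Stage.NORM:
        raise ValueError(f"sample must be raw or fully normalized, got {sample.stage}")

    stable_chrom, stability = select_stable_chromosome(
        sample,
        pon,
        panel,
        min_targets=config.stable_min_targets,
        pseudocount=config.pseudocount,
        mean_of_abs=config.mean_of_abs,
    )
    profile, model = self_normalize(
        sample, pon, panel, stable_chrom,
        alpha=config.ridge_alpha, pseudocount=config.pseudocount,
    )
    segments, smoothed, _ = segment_profile(
        profile,
        panel,
        preseg_cfg=config.preseg(),
        smoother_cfg=config.smoother(),
        cbs_params=config.cbs(),
        seed=seed,
    )
    calls = call_segments(segments, panel, purity=purity, thresholds=config.thresholds())
    manifest = {
        "version": __version__,
        "seed": seed,
        "sample_id": sample.sample_id,
        "stable_chrom": stable_chrom,
        "purity": purity,
        "config": asdict(config),
        "panel_digest": panel.digest(),
        "n_targets": len(panel),
        "n_masked": int((~pon.mask).sum()),
    }
    return PipelineResult(
        profile=profile,
        smoothed=smoothed,
        stable_chrom=stable_chrom,
        stability=stability,
        model=model,
        segments=segments,
        calls=calls,
        manifest=manifest,
    )


@dataclass
class BenchmarkOutcome:
    result: EvalResult
    per_sample: pd.DataFrame
    truth: pd.DataFrame
    n_events: int


def run_benchmark(
    sim_cfg: Optional[SimConfig] = None,
    pipe_cfg: Optional[PipelineConfig] = None,
    data: Optional[BenchmarkData] = None,
    progress: bool = False,
) -> BenchmarkOutcome:
    """Simulate (or take) a benchmark, run the pipeline on every tumor
    sample in non-matched mode, and pool event-level metrics."""
    sim_cfg = sim_cfg or SimConfig()
    pipe_cfg = pipe_cfg or PipelineConfig()
    if data is None:
        data = simulate_benchmark(sim_cfg)
    pon = build_pon_from_depths(data.pon, data.panel, pipe_cfg)
    pooled = EvalResult(0, 0, 0)
    rows = []
    by_sample = dict(tuple(data.truth.groupby("sample_id")))
    for k, (sid, purity, raw) in enumerate(data.tumors):
        res = run_pipeline(
            raw, pon, data.panel, pipe_cfg, seed=pipe_cfg.seed + 1 + k
        )
        ev = evaluate_calls(res.calls, by_sample[sid])
        pooled = pooled + ev
        rows.append(
            {
                "sample_id": sid,
                "purity": purity,
                "stable_chrom": res.stable_chrom,
                "tp": ev.tp,
                "fp": ev.fp,
                "fn": ev.fn,
            }
        )
        if progress and (k + 1) % 25 == 0:
            print(f"  {k + 1}/{len(data.tumors)} samples", flush=True)
    return BenchmarkOutcome(
        result=pooled,
        per_sample=pd.DataFrame(rows),
        truth=data.truth,
        n_events=len(data.truth),
    )
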