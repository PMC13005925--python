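"""Depth-level benchmark simulator and evaluation harness.

The generator emulates a targeted-panel in-silico benchmark at the
level the caller consumes — per-target fragment counts — rather than
at read level: a synthetic panel over the 22 autosomes, a cohort of
diploid normals for the PoN, and groups of tumor samples carrying
non-overlapping CNV events instantiated at several tumor purities.
The default design is 50 groups x 10 CNVs x 6 purities
(0.2, 0.3, 0.4, 0.6, 0.8, 1.0) with copy states drawn from
{0, 1, 3, 4, 5, 6, 8, 10}, i.e. 3000 truth events in total.

Counts are negative binomial around a per-target expectation

    mean_depth * (L_i / mean L) * efficiency_i * gcbias_s(gc_i)
              * wave_s(i) * (p * CN_i + (1-p) * 2) / 2

where ``efficiency_i`` (lognormal) is the capture structure shared by
every sample of a run, while the GC-bias curve, the AR(1) "wave" along
the genome and sporadic single-target outliers are sample specific —
the residual structure that a plain cohort baseline cannot remove and
the self-normalization stage exists to absorb.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .calling import CNVCall, DELETION, DUPLICATION
from .depth import DepthVector, Stage
from .targets import Panel, TargetRegion

__all__ = [
    "SimConfig",
    "SimTruthEvent",
    "EvalResult",
    "BenchmarkData",
    "simulate_panel",
    "simulate_depth",
    "simulate_benchmark",
    "evaluate_calls",
    "expected_log2",
]

_N_AUTOSOMES = 22


@dataclass
class SimConfig:
    """Benchmark design and noise model; defaults are the study conditions."""

    n_groups: int = 50
    cnvs_per_group: int = 10
    purities: tuple[float, ...] = (0.2, 0.3, 0.4, 0.6, 0.8, 1.0)
    copy_states: tuple[int, ...] = (0, 1, 3, 4, 5, 6, 8, 10)
    cnv_length_range: tuple[int, int] = (5, 100)   # targets, log-uniform
    panel_size: int = 2000
    pon_size: int = 50
    mean_depth: float = 400.0
    dispersion: float = 50.0            # negative binomial size parameter
    gc_bias_strength: float = 0.5       # sd of per-sample GC curve coefficients
    capture_efficiency_sd: float = 0.5  # lognormal sd, shared across samples
    wave_sd: float = 0.02               # AR(1) amplitude, natural-log scale
    wave_rho: float = 0.7
    outlier_rate: float = 0.002         # per target per sample
    outlier_log_sd: float = 1.0         # natural-log scale
    seed: int = 0

    def __post_init__(self):
        if not all(0.0 < p <= 1.0 for p in self.purities):
            raise ValueError("purities must lie in (0, 1]")
        if any(s == 2 or s < 0 for s in self.copy_states):
            raise ValueError("copy states must be non-negative integers != 2")
        if self.cnv_length_range[0] < 1:
            raise ValueError("CNV length must be >= 1 target")


@dataclass
class SimTruthEvent:
    """One simulated CNV with its expected log2 shift under the purity mix."""

    group_id: int
    purity: float
    chrom: str
    start_target: int  # global panel ordinal, inclusive
    end_target: int    # global panel ordinal, exclusive
    copy_number: int
    expected_log2: float


def expected_log2(cn: int, purity: float, clip: float = -8.0) -> float:
    """log2((p*CN + (1-p)*2) / 2), clipped for the homozygous-loss limit."""
    mix = (purity * cn + (1.0 - purity) * 2.0) / 2.0
    if mix <= 0:
        return clip
    return max(float(np.log2(mix)), clip)


@dataclass
class EvalResult:
    tp: int
    fp: int
    fn: int
    rule: str = "reciprocal_overlap>=0.5, concordant direction"

    @property
    def sensitivity(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else 0.0

    @property
    def precision(self) -> float:
        d = self.tp + self.fp
        return self.tp / d if d else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.sensitivity
        return 2 * p * r / (p + r) if (p + r) > 0 else 0.0

    def __add__(self, other: "EvalResult") -> "EvalResult":
        return EvalResult(self.tp + other.tp, self.fp + other.fp, self.fn + other.fn)


def simulate_panel(cfg: SimConfig, rng: Optional[np.random.Generator] = None) -> Panel:
    """Synthetic capture panel over the 22 autosomes.

    Target lengths are uniform in 80-300 bp, GC a clipped normal inside
    [0.25, 0.75], and inter-target gaps lognormal (exon-scale spacing).
    Consecutive targets share gene labels in blocks of four.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    per_chrom = np.full(_N_AUTOSOMES, cfg.panel_size // _N_AUTOSOMES)
    per_chrom[: cfg.panel_size % _N_AUTOSOMES] += 1
    regions = []
    gidx = 0
    for c in range(_N_AUTOSOMES):
        chrom = f"chr{c + 1}"
        pos = 1_000_000
        for k in range(per_chrom[c]):
            gap = int(rng.lognormal(mean=np.log(20_000), sigma=0.8))
            length = int(rng.integers(80, 301))
            gc = float(np.clip(rng.normal(0.45, 0.12), 0.25, 0.75))
            start = pos + gap
            gene = f"G{c + 1:02d}_{gidx // 4:04d}"
            regions.append(TargetRegion(chrom, start, start + length, gc=gc, gene=gene))
            pos = start + length
            gidx += 1
    return Panel(regions)


def _sample_biases(n: int, panel: Panel, cfg: SimConfig, rng: np.random.Generator):
    """Per-sample multiplicative bias field: GC curve x AR(1) wave x outliers."""
    a = rng.normal(0.0, cfg.gc_bias_strength)
    b = rng.normal(0.0, cfg.gc_bias_strength)
    g = panel.gc - 0.45
    bias = np.exp(a * g + b * g * g)
    if cfg.wave_sd > 0:
        e = np.empty(n)
        e[0] = rng.normal(0.0, cfg.wave_sd)
        innov = rng.normal(0.0, cfg.wave_sd * np.sqrt(1 - cfg.wave_rho**2), n - 1)
        for i in range(1, n):
            e[i] = cfg.wave_rho * e[i - 1] + innov[i - 1]
        bias *= np.exp(e)
    if cfg.outlier_rate > 0:
        hit = rng.random(n) < cfg.outlier_rate
        if hit.any():
            bias[hit] *= np.exp(rng.normal(0.0, cfg.outlier_log_sd, int(hit.sum())))
    return bias


def simulate_depth(
    panel: Panel,
    cn_profile: np.ndarray,
    purity: float,
    cfg: SimConfig,
    rng: np.random.Generator,
    efficiency: Optional[np.ndarray] = None,
    sample_id: str = "sim",
) -> DepthVector:
    """Draw one sample's raw per-target counts for a given copy-number profile."""
    n = len(panel)
    cn = np.asarray(cn_profile, dtype=float)
    if cn.shape != (n,):
        raise ValueError("cn_profile length must match panel")
    if efficiency is None:
        efficiency = np.ones(n)
    mix = (purity * cn + (1.0 - purity) * 2.0) / 2.0
    mu = (
        cfg.mean_depth
        * (panel.lengths / panel.lengths.mean())
        * efficiency
        * _sample_biases(n, panel, cfg, rng)
        * mix
    )
    r = cfg.dispersion
    counts = np.zeros(n)
    pos = mu > 0
    p = r / (r + mu[pos])
    counts[pos] = rng.negative_binomial(r, p)
    return DepthVector(counts, Stage.RAW, sample_id=sample_id)


def draw_capture_efficiency(
    panel: Panel, cfg: SimConfig, rng: np.random.Generator
) -> np.ndarray:
    """Per-target lognormal capture efficiency, fixed for a whole run."""
    return rng.lognormal(mean=0.0, sigma=cfg.capture_efficiency_sd, size=len(panel))


def _place_events(
    panel: Panel, cfg: SimConfig, rng: np.random.Generator
) -> list[tuple[str, int, int, int]]:
    """Non-overlapping (chrom, start_ord, end_ord, cn) events for one group."""
    chroms = panel.autosomes()
    lo, hi = cfg.cnv_length_range
    taken: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    events = []
    tries = 0
    while len(events) < cfg.cnvs_per_group:
        tries += 1
        if tries > 1000 * cfg.cnvs_per_group:
            raise RuntimeError("could not place non-overlapping CNV events")
        chrom = chroms[rng.integers(len(chroms))]
        crange = panel.chrom_index[chrom]
        nc = crange.stop - crange.start
        length = int(round(np.exp(rng.uniform(np.log(lo), np.log(hi)))))
        length = min(max(length, 1), nc)
        start_local = int(rng.integers(0, nc - length + 1))
        a = crange.start + start_local
        b = a + length
        if any(a < e and s < b for s, e in taken[chrom]):
            continue
        cn = int(cfg.copy_states[rng.integers(len(cfg.copy_states))])
        taken[chrom].append((a, b))
        events.append((chrom, a, b, cn))
    return events


@dataclass
class BenchmarkData:
    panel: Panel
    pon: list[DepthVector]                  # raw counts, diploid normals
    tumors: list[tuple[str, float, DepthVector]]  # (sample_id, purity, raw counts)
    truth: pd.DataFrame                     # one row per SimTruthEvent


def simulate_benchmark(cfg: SimConfig) -> BenchmarkData:
    """Full benchmark: PoN normals, tumor samples per group x purity, truth table."""
    ss = np.random.SeedSequence(cfg.seed)
    panel_rng, eff_rng, event_rng, pon_rng, tumor_rng = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )
    panel = simulate_panel(cfg, panel_rng)
    efficiency = draw_capture_efficiency(panel, cfg, eff_rng)

    diploid = np.full(len(panel), 2.0)
    pon = [
        simulate_depth(panel, diploid, 1.0, cfg, pon_rng, efficiency, f"normal_{j:04d}")
        for j in range(cfg.pon_size)
    ]

    truth_rows = []
    tumors = []
    for g in range(cfg.n_groups):
        events = _place_events(panel, cfg, event_rng)
        cn = np.full(len(panel), 2.0)
        for chrom, a, b, state in events:
            cn[a:b] = state
        for purity in cfg.purities:
            sid = f"tumor_g{g:03d}_p{purity:.1f}"
            tumors.append(
                (sid, purity, simulate_depth(panel, cn, purity, cfg, tumor_rng, efficiency, sid))
            )
            for chrom, a, b, state in events:
                truth_rows.append(
                    {
                        "sample_id": sid,
                        "group_id": g,
                        "purity": purity,
                        "chrom": chrom,
                        "start_target": a,
                        "end_target": b,
                        "copy_number": state,
                        "expected_log2": expected_log2(state, purity),
                    }
                )
    return BenchmarkData(panel, pon, tumors, pd.DataFrame(truth_rows))


def _reciprocal_overlap(a0: int, a1: int, b0: int, b1: int) -> float:
    inter = min(a1, b1) - max(a0, b0)
    if inter <= 0:
        return 0.0
    return min(inter / (a1 - a0), inter / (b1 - b0))


def evaluate_calls(
    calls: Sequence[CNVCall],
    truth: pd.DataFrame,
    min_reciprocal: float = 0.5,
) -> EvalResult:
    """Score non-neutral calls against truth events for one sample.

    A truth event is a true positive when a direction-concordant
    non-neutral call overlaps it reciprocally by at least
    ``min_reciprocal`` (in target-ordinal space); greedy one-to-one
    matching in descending overlap order.  Unmatched truth events are
    false negatives; unmatched non-neutral calls false positives.
    """
    events = truth.sort_values("start_target").reset_index(drop=True)
    ends = events["end_target"].to_numpy()
    starts = events["start_target"].to_numpy()
    same_chrom = events["chrom"].to_numpy()
    for c in np.unique(same_chrom):
        s = starts[same_chrom == c]
        e = ends[same_chrom == c]
        if np.any(s[1:] < e[:-1]):
            raise ValueError("overlapping truth events")

    nonneutral = [c for c in calls if c.state in (DELETION, DUPLICATION)]
    pairs = []
    for ti, trow in events.iterrows():
        t_dir = DELETION if trow.copy_number < 2 else DUPLICATION
        for ci, call in enumerate(nonneutral):
            if call.segment.chrom != trow.chrom or call.state != t_dir:
                continue
            ov = _reciprocal_overlap(
                int(trow.start_target),
                int(trow.end_target),
                call.segment.first_index,
                call.segment.last_index + 1,
            )
            if ov >= min_reciprocal:
                pairs.append((ov, ti, ci))
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    matched_t: set[int] = set()
    matched_c: set[int] = set()
    for ov, ti, ci in pairs:
        if ti in matched_t or ci in matched_c:
            continue
        matched_t.add(ti)
        matched_c.add(ci)
    tp = len(matched_t)
    return EvalResult(tp=tp, fp=len(nonneutral) - tp, fn=len(events) - tp)
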