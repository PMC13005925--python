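"""Discrete CNV state calling and gene-level annotation.

Final segments are converted to integer copy numbers either by fixed
log2-ratio thresholds (the convention popularized by CNVkit-style
callers, all four cutoffs configurable) or, when tumor purity is known,
by inverting the purity mixing model
``2^r = (p*CN + (1-p)*2) / 2`` to recover the tumor-intrinsic copy
number before rounding.  States follow CN < 2 = deletion, CN = 2 =
neutral, CN > 2 = duplication (autosomal ploidy 2; sex chromosomes are
called against ploidy 2 with a warning).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .segment import Segment, SegmentSet
from .targets import Panel, is_autosome

__all__ = ["CallThresholds", "CNVCall", "call_segments", "annotate_genes", "state_of"]

DELETION = "deletion"
NEUTRAL = "neutral"
DUPLICATION = "duplication"

_LOG2_CLIP = -8.0  # CN 0 corresponds to log2 -inf; clip before inversion


@dataclass
class CallThresholds:
    """log2-ratio cutoffs for threshold-mode calling (purity unknown)."""

    t_del0: float = -1.1   # below: CN 0
    t_del1: float = -0.25  # below: CN 1
    t_amp: float = 0.2     # at or below: CN 2 (neutral)
    t_amp2: float = 0.7    # at or below: CN 3; above: CN = round(2 * 2^r)


@dataclass
class CNVCall:
    segment: Segment
    state: str
    copy_number: int
    genes: list[str] = field(default_factory=list)
    purity_used: Optional[float] = None


def state_of(cn: int) -> str:
    if cn < 2:
        return DELETION
    if cn == 2:
        return NEUTRAL
    return DUPLICATION


def _cn_threshold(r: float, t: CallThresholds) -> int:
    if r < t.t_del0:
        return 0
    if r < t.t_del1:
        return 1
    if r <= t.t_amp:
        return 2
    if r <= t.t_amp2:
        return 3
    return int(round(2.0 * 2.0 ** r))


def _cn_purity(r: float, purity: float) -> int:
    # invert 2^r = (p*CN + (1-p)*2) / 2 for the tumor-intrinsic copy number
    r = max(r, _LOG2_CLIP)
    ratio = (2.0 ** (r + 1.0) - 2.0 * (1.0 - purity)) / (2.0 * purity)
    return max(int(round(2.0 * ratio)), 0)


def call_segments(
    segments: SegmentSet,
    panel: Panel,
    purity: Optional[float] = None,
    thresholds: Optional[CallThresholds] = None,
) -> list[CNVCall]:
    """Assign copy numbers and states to final segments.

    ``purity`` in (0, 1] switches on the mixing-model inversion;
    without it the log2 thresholds apply directly.
    """
    if purity is not None and not (0.0 < purity <= 1.0):
        raise ValueError("purity must lie in (0, 1]")
    thresholds = thresholds or CallThresholds()
    warned_sex = False
    calls = []
    for seg in segments:
        if not is_autosome(seg.chrom) and not warned_sex:
            warnings.warn(
                "sex-chromosome segments are called against ploidy 2; "
                "interpret with care"
            )
            warned_sex = True
        r = max(seg.mean_log2, _LOG2_CLIP)
        if purity is None:
            cn = _cn_threshold(r, thresholds)
        else:
            cn = _cn_purity(r, purity)
        gene_set = []
        for g in panel.genes[seg.first_index : seg.last_index + 1]:
            if g and g not in gene_set:
                gene_set.append(g)
        calls.append(
            CNVCall(
                segment=seg,
                state=state_of(cn),
                copy_number=cn,
                genes=gene_set,
                purity_used=purity,
            )
        )
    return calls


def annotate_genes(calls: Sequence[CNVCall], panel: Panel) -> pd.DataFrame:
    """Per-gene summary: length-weighted modal state across the gene's targets.

    Genes split by a breakpoint (targets under calls with different
    states) are flagged with both states listed; genes whose targets are
    covered by no call (masked out) are reported as not evaluable.
    """
    # map each panel target to the call covering it
    call_of = {}
    for call in calls:
        for t in range(call.segment.first_index, call.segment.last_index + 1):
            call_of[t] = call
    rows = []
    genes = {}
    for i, g in enumerate(panel.genes):
        if g:
            genes.setdefault(g, []).append(i)
    for gene, targets in genes.items():
        weights: dict[str, float] = {}
        cns: dict[str, int] = {}
        uncovered = 0
        for t in targets:
            call = call_of.get(t)
            if call is None:
                uncovered += 1
                continue
            w = float(panel.lengths[t])
            weights[call.state] = weights.get(call.state, 0.0) + w
            cns.setdefault(call.state, call.copy_number)
        if not weights:
            rows.append(
                {
                    "gene": gene,
                    "state": "not_evaluable",
                    "copy_number": pd.NA,
                    "split": False,
                    "states": "",
                    "n_targets": len(targets),
                }
            )
            continue
        modal = max(weights, key=lambda s: weights[s])
        split = len(weights) > 1
        rows.append(
            {
                "gene": gene,
                "state": modal,
                "copy_number": cns[modal],
                "split": split,
                "states": ",".join(sorted(weights)),
                "n_targets": len(targets),
            }
        )
    return pd.DataFrame(rows)


def calls_to_dataframe(calls: Sequence[CNVCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": c.segment.chrom,
                "start": c.segment.start,
                "end": c.segment.end,
                "n_targets": c.segment.n_targets,
                "mean_log2": c.segment.mean_log2,
                "cn": c.copy_number,
                "state": c.state,
                "genes": ",".join(c.genes),
            }
            for c in calls
        ]
    )
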