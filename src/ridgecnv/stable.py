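"""Sample-specific stable-chromosome selection.

For each autosome the test sample's normalized depths are compared with
the PoN median profile through two indices: the absolute mean log2
difference AL_c (systematic bias; note the absolute value sits OUTSIDE
the mean, so signed deviations may cancel) and the Pearson correlation
PR_c (coverage-pattern concordance).  Both are min-max scaled across
eligible autosomes and each chromosome becomes a point (NA_c, NP_c);
the chromosome closest to the ideal point (0, 1) in Euclidean distance
is the stable chromosome, used as the training set for ridge
self-normalization.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .baseline import BaselineCohort
from .depth import DepthVector, Stage
from .targets import Panel, is_autosome

__all__ = [
    "chromosome_bias",
    "chromosome_concordance",
    "select_stable_chromosome",
]


def _chrom_values(
    test: DepthVector, cohort: BaselineCohort, panel: Panel, chrom: str
) -> tuple[np.ndarray, np.ndarray]:
    rng = panel.chrom_index[chrom]
    idx = np.arange(rng.start, rng.stop)
    idx = idx[cohort.mask[idx]]
    return test.values[idx], cohort.median_profile[idx]


def chromosome_bias(
    test: DepthVector,
    cohort: BaselineCohort,
    panel: Panel,
    chrom: str,
    pseudocount: float = 1e-3,
    mean_of_abs: bool = False,
) -> float:
    """AL_c = |mean(log2 testRD - log2 baseRD)| over unmasked targets of ``chrom``.

    ``mean_of_abs`` switches to the mean of absolute differences, a
    stricter variant in which +/- deviations cannot cancel (off by
    default; the canonical definition places |.| outside the mean).
    """
    t, b = _chrom_values(test, cohort, panel, chrom)
    diff = np.log2(t + pseudocount) - np.log2(b + pseudocount)
    if mean_of_abs:
        return float(np.mean(np.abs(diff)))
    return float(abs(np.mean(diff)))


def chromosome_concordance(
    test: DepthVector, cohort: BaselineCohort, panel: Panel, chrom: str
) -> float:
    """PR_c: Pearson correlation of test vs baseline depths on ``chrom``.

    Returns NaN when either vector has zero variance (chromosome is then
    ineligible for selection).
    """
    t, b = _chrom_values(test, cohort, panel, chrom)
    if len(t) < 2 or np.std(t) == 0 or np.std(b) == 0:
        return float("nan")
    return float(np.corrcoef(t, b)[0, 1])


def _minmax(x: np.ndarray) -> np.ndarray:
    lo, hi = np.min(x), np.max(x)
    # zero spread (to numerical precision) carries no ranking information
    if hi - lo <= 1e-9 * max(abs(hi), abs(lo), 1.0):
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def select_stable_chromosome(
    test: DepthVector,
    cohort: BaselineCohort,
    panel: Panel,
    min_targets: int = 10,
    pseudocount: float = 1e-3,
    mean_of_abs: bool = False,
) -> tuple[str, pd.DataFrame]:
    """Pick the autosome minimizing d = sqrt(NA^2 + (NP - 1)^2).

    Only autosomes (chr1..chr22) with at least ``min_targets`` unmasked
    targets and a defined Pearson correlation are eligible.  Ties break
    to the lowest-numbered chromosome.  Returns the selected chromosome
    and the full stability table (one row per eligible autosome).
    """
    if test.stage != Stage.NORM:
        raise ValueError(f"expected stage RD_nor, got {test.stage}")
    rows = []
    for chrom in panel.chromosomes:
        if not is_autosome(chrom):
            continue
        t, b = _chrom_values(test, cohort, panel, chrom)
        if len(t) < min_targets:
            continue
        al = chromosome_bias(test, cohort, panel, chrom, pseudocount, mean_of_abs)
        pr = chromosome_concordance(test, cohort, panel, chrom)
        if not np.isfinite(pr):
            continue
        rows.append({"chrom": chrom, "AL": al, "PR": pr, "n_targets": len(t)})
    if len(rows) < 2:
        raise ValueError(
            "panel too narrow for stable-chromosome selection "
            f"({len(rows)} eligible autosomes; need >= 2)"
        )
    table = pd.DataFrame(rows)
    table["NA"] = _minmax(table["AL"].to_numpy())
    table["NP"] = _minmax(table["PR"].to_numpy())
    table["d"] = np.sqrt(table["NA"] ** 2 + (table["NP"] - 1.0) ** 2)
    # argmin with lowest-chromosome-number tie-break: table rows are in panel
    # order (chr1..chr22), so the first minimum wins.
    best = int(np.argmin(table["d"].to_numpy()))
    table["selected"] = False
    table.loc[best, "selected"] = True
    return str(table.loc[best, "chrom"]), table
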