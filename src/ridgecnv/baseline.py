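"""Panel of normals (PoN): region x sample baseline matrix and median profile.

The PoN is assembled from fully normalized (``RD_nor``) depth vectors of
CNV-negative normal samples so that columns are cross-comparable.  Each
region's baseline reference is the median across samples; regions whose
baseline median falls below a depth floor (uncapturable targets) or that
lack a GC value are masked out of all downstream vectors while keeping
their panel ordinals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .depth import DepthVector, Stage
from .targets import Panel

__all__ = ["BaselineCohort", "build_pon", "pon_qc", "save_pon", "load_pon"]

_FORMAT_VERSION = 1


@dataclass
class BaselineCohort:
    """Region x sample matrix of normalized baseline depths plus its median profile."""

    matrix: np.ndarray            # N regions x M samples, RD_nor entries
    sample_ids: list[str]
    median_profile: np.ndarray    # per-region median over samples
    mask: np.ndarray              # True = region usable
    panel_digest: str
    depth_floor: float = 0.05

    @property
    def n_regions(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[1]


def build_pon(
    baseline_depths: Sequence[DepthVector],
    panel: Panel,
    depth_floor: float = 0.05,
) -> BaselineCohort:
    """Assemble the PoN from per-sample RD_nor vectors sharing one panel."""
    if len(baseline_depths) < 2:
        raise ValueError("panel of normals requires at least 2 samples")
    n = len(panel)
    cols = []
    ids = []
    for k, rd in enumerate(baseline_depths):
        if rd.stage != Stage.NORM:
            raise ValueError(f"baseline sample {k}: expected stage RD_nor, got {rd.stage}")
        if len(rd) != n:
            raise ValueError(f"baseline sample {k}: length {len(rd)} != panel size {n}")
        cols.append(rd.values)
        ids.append(rd.sample_id or f"normal_{k}")
    matrix = np.column_stack(cols)
    median_profile = np.median(matrix, axis=1)
    mask = (median_profile >= depth_floor) & np.isfinite(panel.gc)
    return BaselineCohort(
        matrix=matrix,
        sample_ids=ids,
        median_profile=median_profile,
        mask=mask,
        panel_digest=panel.digest(),
        depth_floor=depth_floor,
    )


def pon_qc(cohort: BaselineCohort, cutoff: float = 0.3, pseudocount: float = 1e-3) -> pd.DataFrame:
    """Advisory per-sample QC: median |log2 sample - log2 median profile|.

    Samples whose deviation exceeds ``cutoff`` are flagged for manual
    exclusion; nothing is dropped automatically.
    """
    m = cohort.mask
    base = np.log2(cohort.median_profile[m] + pseudocount)
    rows = []
    for j, sid in enumerate(cohort.sample_ids):
        dev = float(np.median(np.abs(np.log2(cohort.matrix[m, j] + pseudocount) - base)))
        rows.append({"sample_id": sid, "log2_mad": dev, "flagged": dev > cutoff})
    df = pd.DataFrame(rows)
    df.attrs["n_masked_regions"] = int((~cohort.mask).sum())
    return df


def save_pon(cohort: BaselineCohort, path: str | Path) -> None:
    """Persist the PoN as a compressed archive with embedded JSON metadata."""
    meta = {
        "format_version": _FORMAT_VERSION,
        "sample_ids": cohort.sample_ids,
        "panel_digest": cohort.panel_digest,
        "depth_floor": cohort.depth_floor,
    }
    np.savez_compressed(
        str(path),
        matrix=cohort.matrix,
        median_profile=cohort.median_profile,
        mask=cohort.mask,
        meta=np.array(json.dumps(meta)),
    )


def load_pon(path: str | Path, panel: Optional[Panel] = None) -> BaselineCohort:
    """Load a persisted PoN; verifies the panel digest when a panel is given."""
    try:
        with np.load(str(path), allow_pickle=False) as npz:
            meta = json.loads(str(npz["meta"]))
            cohort = BaselineCohort(
                matrix=npz["matrix"],
                sample_ids=list(meta["sample_ids"]),
                median_profile=npz["median_profile"],
                mask=npz["mask"].astype(bool),
                panel_digest=meta["panel_digest"],
                depth_floor=float(meta["depth_floor"]),
            )
    except Exception as exc:  # zip/npz corruption surfaces many exception types
        raise ValueError(f"{path}: not a valid PoN archive ({exc})") from exc
    if panel is not None and cohort.panel_digest != panel.digest():
        raise ValueError(
            f"{path}: PoN was built for a different panel (digest mismatch)"
        )
    return cohort
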