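"""Capture target intervals: loading, validation, GC annotation.

The atomic genomic unit of the caller is a capture target (an exonic
interval of the panel BED).  Coordinates are BED-standard 0-based
half-open everywhere internally; 1-based conversion happens only at
report boundaries.  Chromosome names are canonicalized so that ``1``
and ``chr1`` compare equal.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TargetRegion",
    "Panel",
    "load_targets",
    "write_targets",
    "annotate_gc",
    "read_targets_tsv",
    "write_targets_tsv",
]

_AUTOSOMES = {str(i) for i in range(1, 23)}


def canonical_chrom(name: str) -> str:
    """Map '1', 'chr1', 'Chr1' -> 'chr1'; 'chrX'/'X' -> 'chrX'."""
    base = name[3:] if name.lower().startswith("chr") else name
    if base.upper() in ("X", "Y", "M", "MT"):
        base = base.upper()
    return "chr" + base


def _chrom_rank(canon: str) -> tuple[int, str]:
    base = canon[3:]
    if base in _AUTOSOMES:
        return (int(base), "")
    order = {"X": 23, "Y": 24, "M": 25, "MT": 25}
    return (order.get(base, 99), base)


def is_autosome(canon: str) -> bool:
    return canon[3:] in _AUTOSOMES


@dataclass(frozen=True)
class TargetRegion:
    """One capture interval. ``gc`` is NaN until annotated; all-N regions stay NaN."""

    chrom: str
    start: int
    end: int
    gc: float = float("nan")
    gene: Optional[str] = None
    index: int = -1

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: end <= start"
            )
        if np.isfinite(self.gc) and not (0.0 <= self.gc <= 1.0):
            raise ValueError(f"gc {self.gc} outside [0,1]")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)


class Panel:
    """Ordered, indexed collection of target regions.

    Regions are sorted by (chromosome rank, start) and assigned stable
    ordinal indices; per-chromosome targets occupy a contiguous ordinal
    range, exposed through :attr:`chrom_index`.
    """

    def __init__(self, regions: Iterable[TargetRegion], merge_overlaps: bool = False):
        regs = [
            replace(r, chrom=canonical_chrom(r.chrom)) for r in regions
        ]
        regs.sort(key=lambda r: (_chrom_rank(r.chrom), r.start, r.end))
        regs = self._check_overlaps(regs, merge_overlaps)
        self.regions: list[TargetRegion] = [
            replace(r, index=i) for i, r in enumerate(regs)
        ]
        if not self.regions:
            raise ValueError("panel has no targets")
        # cached arrays for numeric code paths
        self.chroms = np.array([r.chrom for r in self.regions])
        self.starts = np.array([r.start for r in self.regions], dtype=np.int64)
        self.ends = np.array([r.end for r in self.regions], dtype=np.int64)
        self.lengths = self.ends - self.starts
        self.midpoints = 0.5 * (self.starts + self.ends)
        self.gc = np.array([r.gc for r in self.regions], dtype=float)
        self.genes = np.array(
            [r.gene if r.gene is not None else "" for r in self.regions]
        )
        self.chrom_index: dict[str, range] = {}
        i = 0
        while i < len(self.regions):
            c = self.regions[i].chrom
            j = i
            while j < len(self.regions) and self.regions[j].chrom == c:
                j += 1
            self.chrom_index[c] = range(i, j)
            i = j

    @staticmethod
    def _check_overlaps(regs: list[TargetRegion], merge: bool) -> list[TargetRegion]:
        out: list[TargetRegion] = []
        for r in regs:
            if out and out[-1].chrom == r.chrom and r.start < out[-1].end:
                if not merge:
                    raise ValueError(
                        f"overlapping targets {out[-1].chrom}:{out[-1].start}-"
                        f"{out[-1].end} and {r.chrom}:{r.start}-{r.end} "
                        "(pass merge_overlaps=True to merge)"
                    )
                prev = out.pop()
                gene = prev.gene or r.gene
                if prev.gene and r.gene and prev.gene != r.gene:
                    gene = f"{prev.gene},{r.gene}"
                out.append(
                    TargetRegion(prev.chrom, prev.start, max(prev.end, r.end), gene=gene)
                )
            else:
                out.append(r)
        return out

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)

    def __getitem__(self, i: int) -> TargetRegion:
        return self.regions[i]

    @property
    def chromosomes(self) -> list[str]:
        return list(self.chrom_index)

    def autosomes(self) -> list[str]:
        return [c for c in self.chrom_index if is_autosome(c)]

    def digest(self) -> str:
        """Checksum over coordinates, binding derived artifacts (PoN) to this panel."""
        h = hashlib.sha256()
        for r in self.regions:
            h.update(f"{r.chrom}:{r.start}-{r.end}\n".encode())
        return h.hexdigest()

    def with_gc(self, gc: Sequence[float]) -> "Panel":
        gc = np.asarray(gc, dtype=float)
        if gc.shape != (len(self),):
            raise ValueError("gc vector length does not match panel")
        return Panel(
            replace(r, gc=float(g), index=-1) for r, g in zip(self.regions, gc)
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chroms,
                "start": self.starts,
                "end": self.ends,
                "gene": self.genes,
                "gc": self.gc,
            }
        )


def load_targets(bed_path: str | Path, merge_overlaps: bool = False) -> Panel:
    """Load a 3+ column BED file of capture targets.

    The optional 4th column is stored as the gene label.  Input need not
    be sorted; overlapping intervals are rejected unless
    ``merge_overlaps`` is set.
    """
    bed_path = Path(bed_path)
    regions = []
    with open(bed_path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise ValueError(f"{bed_path}:{ln}: expected >=3 columns, got {len(fields)}")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{bed_path}:{ln}: non-integer coordinates") from exc
            gene = fields[3] if len(fields) > 3 and fields[3] not in (".", "") else None
            try:
                regions.append(TargetRegion(fields[0], start, end, gene=gene))
            except ValueError as exc:
                raise ValueError(f"{bed_path}:{ln}: {exc}") from exc
    return Panel(regions, merge_overlaps=merge_overlaps)


def write_targets(panel: Panel, path: str | Path) -> None:
    """Write the panel back to BED (4 columns when genes are present)."""
    with open(path, "w") as fh:
        for r in panel:
            if r.gene is not None:
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.gene}\n")
            else:
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\n")


class _SequenceAccessor:
    """Duck-typed reference access: pysam FastaFile, pyfaidx Fasta, or dict of str."""

    def __init__(self, source):
        self.source = source

    def fetch(self, chrom: str, start: int, end: int) -> str:
        src = self.source
        names = getattr(src, "references", None)
        if names is None:
            try:
                names = list(src.keys())
            except AttributeError:
                names = None
        key = chrom
        if names is not None:
            canon = {canonical_chrom(n): n for n in names}
            if chrom in canon:
                key = canon[chrom]
            elif chrom not in names:
                raise KeyError(f"chromosome {chrom} absent from reference")
        if hasattr(src, "fetch"):
            return str(src.fetch(key, start, end))
        try:
            return str(src[key][start:end])
        except KeyError as exc:
            raise KeyError(f"chromosome {chrom} absent from reference") from exc


def gc_fraction(seq: str) -> float:
    """GC over non-N bases; soft-masked (lowercase) bases count. NaN if all-N."""
    seq = seq.upper()
    non_n = sum(1 for b in seq if b != "N")
    if non_n == 0:
        return float("nan")
    gc = sum(1 for b in seq if b in "GC")
    return gc / non_n


def annotate_gc(panel: Panel, sequence_source) -> Panel:
    """Compute per-target GC fractions from a reference sequence source.

    Regions made entirely of N keep gc = NaN and are excluded from
    normalization downstream (via the baseline mask).
    """
    acc = _SequenceAccessor(sequence_source)
    gc = np.empty(len(panel))
    for i, r in enumerate(panel):
        gc[i] = gc_fraction(acc.fetch(r.chrom, r.start, r.end))
    return panel.with_gc(gc)


_TSV_COLS = ["chrom", "start", "end", "gene", "gc"]


def write_targets_tsv(panel: Panel, path: str | Path) -> None:
    panel.to_dataframe().to_csv(path, sep="\t", index=False)


def read_targets_tsv(path: str | Path) -> Panel:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "gene": str})
    missing = [c for c in _TSV_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"targets TSV missing columns: {missing}")
    regions = [
        TargetRegion(
            str(row.chrom),
            int(row.start),
            int(row.end),
            gc=float(row.gc) if np.isfinite(row.gc) else float("nan"),
            gene=None if pd.isna(row.gene) or row.gene == "" else str(row.gene),
        )
        for row in df.itertuples()
    ]
    return Panel(regions)
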