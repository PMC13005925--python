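import numpy as np
import pytest

from ridgecnv.baseline import build_pon
from ridgecnv.depth import DepthVector, Stage
from ridgecnv.ridge import LogRatioProfile
from ridgecnv.targets import Panel, TargetRegion


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def panel_factory():
    """Build a synthetic panel: n targets per chromosome, fixed spacing."""

    def make(n_per_chrom=30, chroms=("chr1", "chr2"), spacing=10_000, length=100,
             gc=0.5, genes=None):
        regions = []
        k = 0
        for c in chroms:
            pos = 1000
            for i in range(n_per_chrom):
                g = genes[k] if genes is not None else f"GENE{k // 4:03d}"
                gval = gc[k] if hasattr(gc, "__len__") else gc
                regions.append(
                    TargetRegion(c, pos, pos + length, gc=gval, gene=g)
                )
                pos += spacing
                k += 1
        return Panel(regions)

    return make


@pytest.fixture
def profile_factory(panel_factory):
    """LogRatioProfile over a fresh panel with given per-target values."""

    def make(values, n_per_chrom=None, chroms=("chr1",), **panel_kw):
        values = np.asarray(values, dtype=float)
        n_per_chrom = n_per_chrom or len(values) // len(chroms)
        panel = panel_factory(n_per_chrom=n_per_chrom, chroms=chroms, **panel_kw)
        assert len(panel) == len(values)
        prof = LogRatioProfile(values, np.arange(len(panel)), sample_id="t")
        return prof, panel

    return make


@pytest.fixture
def cohort_factory():
    """BaselineCohort from an explicit region x sample matrix."""

    def make(matrix, panel, depth_floor=0.05):
        matrix = np.asarray(matrix, dtype=float)
        depths = [
            DepthVector(matrix[:, j], Stage.NORM, f"n{j}")
            for j in range(matrix.shape[1])
        ]
        return build_pon(depths, panel, depth_floor=depth_floor)

    return make


@pytest.fixture
def bam_factory(tmp_path):
    """Write a coordinate-sorted, indexed BAM of proper read pairs.

    ``pairs`` is a list of dicts: name, chrom, pos1, pos2 (0-based left
    ends of the two mates), and optional read_len / mapq / duplicate /
    proper (default True) / secondary / qcfail flags.
    """

    def make(pairs, references=(("chr1", 1_000_000), ("chr2", 1_000_000)),
             name="sample.bam"):
        import pysam

        header = {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": c, "LN": ln} for c, ln in references],
        }
        tid = {c: i for i, (c, _) in enumerate(references)}
        reads = []
        for p in pairs:
            rl = p.get("read_len", 50)
            for which, (pos, mpos) in enumerate(
                [(p["pos1"], p["pos2"]), (p["pos2"], p["pos1"])]
            ):
                a = pysam.AlignedSegment()
                a.query_name = p["name"]
                a.query_sequence = "A" * rl
                a.query_qualities = pysam.qualitystring_to_array("I" * rl)
                a.reference_id = tid[p["chrom"]]
                a.reference_start = pos
                a.cigarstring = f"{rl}M"
                a.mapping_quality = p.get("mapq", 60)
                a.next_reference_id = tid[p["chrom"]]
                a.next_reference_start = mpos
                a.is_paired = True
                a.is_proper_pair = p.get("proper", True)
                a.is_read1 = which == 0
                a.is_read2 = which == 1
                a.is_reverse = which == 1
                a.mate_is_reverse = which == 0
                a.is_duplicate = p.get("duplicate", False)
                a.is_secondary = p.get("secondary", False)
                a.is_qcfail = p.get("qcfail", False)
                a.template_length = (mpos + rl - pos) if which == 0 else -(
                    mpos + rl - pos
                )
                reads.append(a)
        reads.sort(key=lambda a: (a.reference_id, a.reference_start))
        path = tmp_path / name
        with pysam.AlignmentFile(path, "wb", header=header) as fh:
            for a in reads:
                fh.write(a)
        pysam.index(str(path))
        return path

    return make
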