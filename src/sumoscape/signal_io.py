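"""Stranded binned coverage, depth normalization, window signals and
metaprofile matrices, plus BED / bedGraph plumbing.

Coverage is held per chromosome as two float arrays (plus / minus strand) of
``bin_size``-bp bins.  Two counting modes exist:

* ``5prime`` — each read adds one tag to the bin holding its 5' end on its own
  strand (nascent-transcription / GRO-seq semantics).
* ``fragment`` — each read distributes one tag across the bins it overlaps,
  proportionally to the overlap (ChIP fragment semantics; both strands are
  pooled onto the plus array).

Both modes conserve the total tag count, so depth normalization to a target
(default 10^7 tags) makes window signals comparable across samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .genome_model import GenomicInterval

__all__ = [
    "ReadSet",
    "StrandedCoverage",
    "read_bed",
    "write_bed",
    "read_readset_bed",
    "build_coverage",
    "normalize_depth",
    "window_signal",
    "rpkm",
    "signal_matrix",
    "write_bedgraph",
    "count_reads",
    "ReadCounter",
]

NORM_TARGET = 1e7


class ReadSet:
    """Aligned reads of one sample (interval-level; no sequences).

    Reads are stored as per-chromosome ``(starts, ends, strands)`` arrays
    (strand +1 / -1 / 0 for '.') so that million-read samples bin and count
    quickly; the ``reads`` property materializes :class:`GenomicInterval`
    objects on demand.
    """

    def __init__(self, sample_id: str, condition: str, replicate: int,
                 arrays: dict, total_reads: int | None = None):
        self.sample_id = sample_id
        self.condition = condition
        self.replicate = replicate
        self.arrays = arrays  # chrom -> (starts, ends, strands) int arrays
        n = sum(len(a[0]) for a in arrays.values())
        self.total_reads = n if total_reads is None else total_reads

    @classmethod
    def from_intervals(cls, sample_id: str, condition: str, replicate: int,
                       intervals, total_reads: int | None = None) -> "ReadSet":
        tmp: dict[str, list] = {}
        code = {"+": 1, "-": -1, ".": 0}
        for iv in intervals:
            tmp.setdefault(iv.chrom, []).append((iv.start, iv.end, code[iv.strand]))
        arrays = {}
        for c, rows in tmp.items():
            a = np.asarray(rows, dtype=np.int64)
            arrays[c] = (a[:, 0], a[:, 1], a[:, 2].astype(np.int8))
        return cls(sample_id, condition, replicate, arrays, total_reads)

    @property
    def reads(self) -> list[GenomicInterval]:
        sym = {1: "+", -1: "-", 0: "."}
        out = []
        for c in sorted(self.arrays):
            starts, ends, strands = self.arrays[c]
            out.extend(
                GenomicInterval(c, int(s), int(e), sym[int(st)])
                for s, e, st in zip(starts, ends, strands)
            )
        return out

    def __len__(self) -> int:
        return sum(len(a[0]) for a in self.arrays.values())


@dataclass
class StrandedCoverage:
    """Binned per-strand tag counts with depth bookkeeping.

    ``scale`` is 1.0 for raw coverage and ``target / total_reads`` after
    :func:`normalize_depth`; stored counts are already multiplied by it.
    """

    counts: dict  # chrom -> {"+": np.ndarray, "-": np.ndarray}
    bin_size: int
    chrom_sizes: dict
    total_reads: float
    scale: float = 1.0
    _cum: dict = field(default_factory=dict, repr=False, compare=False)

    def chroms(self):
        return list(self.counts)

    def strand_array(self, chrom: str, strand: str) -> np.ndarray:
        return self.counts[chrom][strand]

    def cumulative(self, chrom: str, strand: str) -> np.ndarray:
        key = (chrom, strand)
        if key not in self._cum:
            arr = self.counts[chrom][strand]
            c = np.zeros(len(arr) + 1)
            np.cumsum(arr, out=c[1:])
            self._cum[key] = c
        return self._cum[key]

    def invalidate(self):
        self._cum.clear()


# ---------------------------------------------------------------------------
# BED plumbing

def read_bed(path) -> list[GenomicInterval]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            p = line.rstrip("\n").split("\t")
            if len(p) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs >= 3 columns")
            try:
                start, end = int(p[1]), int(p[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            strand = p[5] if len(p) >= 6 else "."
            try:
                out.append(GenomicInterval(p[0], start, end, strand))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_bed(intervals, path, names=None, scores=None) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names is not None else f"iv{i}"
            score = scores[i] if scores is not None else 0
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n")


def write_readset_bed(rs: ReadSet, path) -> None:
    sym = {1: "+", -1: "-", 0: "."}
    with open(path, "w") as fh:
        i = 0
        for c in sorted(rs.arrays):
            starts, ends, strands = rs.arrays[c]
            for s, e, st in zip(starts, ends, strands):
                fh.write(f"{c}\t{s}\t{e}\tr{i}\t0\t{sym[int(st)]}\n")
                i += 1


def read_readset_bed(path, sample_id: str, condition: str, replicate: int = 1) -> ReadSet:
    return ReadSet.from_intervals(sample_id, condition, replicate, read_bed(path))


# ---------------------------------------------------------------------------
# Coverage construction

def build_coverage(
    reads: ReadSet,
    chrom_sizes: dict,
    bin_size: int = 50,
    mode: str = "fragment",
) -> StrandedCoverage:
    """Bin a read set into stranded coverage (see module docstring for modes)."""
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    if mode not in ("fragment", "5prime"):
        raise ValueError(f"unknown mode {mode!r}")
    counts = {
        c: {
            "+": np.zeros(int(np.ceil(L / bin_size))),
            "-": np.zeros(int(np.ceil(L / bin_size))),
        }
        for c, L in chrom_sizes.items()
    }
    clipped = 0
    for chrom, (starts, ends, strands) in reads.arrays.items():
        if chrom not in counts:
            clipped += len(starts)
            continue
        L = chrom_sizes[chrom]
        keep = starts < L
        clipped += int(np.sum(~keep) + np.sum(ends[keep] > L))
        starts = np.clip(starts[keep], 0, None)
        ends = np.minimum(ends[keep], L)
        strands = strands[keep]
        if mode == "5prime":
            minus = strands == -1
            pos = np.where(minus, ends - 1, starts)
            for arr, sel in ((counts[chrom]["+"], ~minus), (counts[chrom]["-"], minus)):
                np.add.at(arr, pos[sel] // bin_size, 1.0)
        else:
            arr = counts[chrom]["+"]  # fragment mode pools strands
            b0 = starts // bin_size
            b1 = (ends - 1) // bin_size
            lengths = (ends - starts).astype(float)
            max_span = int((b1 - b0).max()) + 1 if len(b0) else 0
            for k in range(max_span):
                b = b0 + k
                sel = b <= b1
                if not np.any(sel):
                    break
                bs_, ss, es, ls = b[sel], starts[sel], ends[sel], lengths[sel]
                overlap = np.minimum(es, (bs_ + 1) * bin_size) - np.maximum(ss, bs_ * bin_size)
                np.add.at(arr, bs_, overlap / ls)
    if clipped:
        warnings.warn(f"{clipped} reads beyond chromosome bounds were clipped/dropped")
    return StrandedCoverage(counts, bin_size, dict(chrom_sizes), float(reads.total_reads))


def normalize_depth(cov: StrandedCoverage, target: float = NORM_TARGET) -> StrandedCoverage:
    """Scale counts so the genome-wide tag total equals ``target``."""
    if cov.total_reads <= 0:
        raise ValueError("cannot normalize coverage with total_reads = 0")
    factor = target / cov.total_reads
    new_counts = {
        c: {s: arr * factor for s, arr in d.items()} for c, d in cov.counts.items()
    }
    return StrandedCoverage(
        new_counts, cov.bin_size, dict(cov.chrom_sizes), cov.total_reads,
        scale=cov.scale * factor,
    )


# ---------------------------------------------------------------------------
# Window signals

def _cum_at(cov: StrandedCoverage, chrom: str, strand: str, pos: float) -> float:
    """Pro-rated cumulative signal on [0, pos): full bins plus a fractional
    share of the bin containing ``pos`` (uniform-within-bin assumption)."""
    arr = cov.counts[chrom][strand]
    cum = cov.cumulative(chrom, strand)
    pos = min(max(pos, 0.0), len(arr) * cov.bin_size)
    b, frac = divmod(pos, cov.bin_size)
    b = int(b)
    val = cum[b]
    if frac and b < len(arr):
        val += arr[b] * (frac / cov.bin_size)
    return float(val)


def window_signal(
    cov: StrandedCoverage, iv: GenomicInterval, strand_mode: str = "both"
) -> float:
    """Tag sum over ``iv``; partial bins are pro-rated.

    ``strand_mode``: ``both`` pools strands; ``sense`` uses the interval's own
    strand; ``antisense`` the opposite.  Regions outside coverage contribute 0.
    """
    if iv.chrom not in cov.counts:
        return 0.0
    if strand_mode == "both":
        strands = ("+", "-")
    elif strand_mode == "sense":
        strands = ("-",) if iv.strand == "-" else ("+",)
    elif strand_mode == "antisense":
        strands = ("+",) if iv.strand == "-" else ("-",)
    else:
        raise ValueError(f"unknown strand_mode {strand_mode!r}")
    return sum(
        _cum_at(cov, iv.chrom, s, iv.end) - _cum_at(cov, iv.chrom, s, iv.start)
        for s in strands
    )


def rpkm(tag_count: float, length_bp: int, total_reads: float) -> float:
    """Reads per kilobase of feature per million mapped reads."""
    if length_bp <= 0:
        raise ValueError("length_bp must be > 0")
    if total_reads <= 0:
        raise ValueError("total_reads must be > 0")
    return tag_count / (length_bp / 1e3) / (total_reads / 1e6)


def count_reads(reads: ReadSet, iv: GenomicInterval) -> int:
    """Integer count of reads overlapping ``iv`` by >= 1 bp (used for the
    raw-read peak filters, which are defined on read counts, not binned tags)."""
    return ReadCounter(reads).count(iv)


class ReadCounter:
    """Vectorized interval read counting over a fixed read set.

    Counts reads overlapping a query as ``#(start < q_end) - #(end <= q_start)``
    using sorted start/end arrays per chromosome.
    """

    def __init__(self, reads: ReadSet):
        self.total_reads = reads.total_reads
        self._starts = {c: np.sort(a[0]) for c, a in reads.arrays.items()}
        self._ends = {c: np.sort(a[1]) for c, a in reads.arrays.items()}

    def count(self, iv: GenomicInterval) -> int:
        if iv.chrom not in self._starts:
            return 0
        n_started = np.searchsorted(self._starts[iv.chrom], iv.end, side="left")
        n_ended = np.searchsorted(self._ends[iv.chrom], iv.start, side="right")
        return int(n_started - n_ended)


# ---------------------------------------------------------------------------
# Metaprofile matrices

def signal_matrix(
    centers: list[GenomicInterval],
    cov: StrandedCoverage,
    flank: int = 2000,
    bin: int = 25,
    strand_mode: str = "both",
):
    """Signal matrix around interval centers (rows) in ``bin``-bp columns over
    ±``flank``; minus-strand rows are orientation-flipped.  Returns
    ``(matrix, mean_profile, edge_flags)``; rows that run over a chromosome
    edge are zero-padded there and flagged.
    """
    if flank % bin != 0:
        raise ValueError("flank must be a multiple of bin")
    ncol = 2 * flank // bin
    mat = np.zeros((len(centers), ncol))
    edge = np.zeros(len(centers), dtype=bool)
    for i, iv in enumerate(centers):
        c = iv.center
        lo = c - flank
        chrom_len = cov.chrom_sizes.get(iv.chrom, 0)
        for j in range(ncol):
            s, e = lo + j * bin, lo + (j + 1) * bin
            if s < 0 or e > chrom_len:
                edge[i] = True
                continue
            mat[i, j] = window_signal(
                cov, GenomicInterval(iv.chrom, s, e, iv.strand), strand_mode
            )
        if iv.strand == "-":
            mat[i] = mat[i, ::-1]
    return mat, mat.mean(axis=0) if len(centers) else np.zeros(ncol), edge


def write_bedgraph(cov: StrandedCoverage, prefix) -> None:
    """Per-strand bedGraph export (``<prefix>.plus.bedgraph`` / ``.minus.…``)."""
    for strand, tag in (("+", "plus"), ("-", "minus")):
        with open(f"{prefix}.{tag}.bedgraph", "w") as fh:
            for chrom in sorted(cov.counts):
                arr = cov.counts[chrom][strand]
                L = cov.chrom_sizes[chrom]
                nz = np.nonzero(arr)[0]
                for b in nz:
                    s = b * cov.bin_size
                    fh.write(f"{chrom}\t{s}\t{min(s + cov.bin_size, L)}\t{arr[b]:g}\n")
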