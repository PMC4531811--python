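"""Enrichment peak calling against an input/control sample, replicate and
read-count filtering, condition classification, fold-enrichment classes, and
peak-set co-occurrence.

The caller scans fixed-width sliding windows, tests the raw sample tag count
against a depth-scaled control expectation with a Poisson upper tail, and
merges significant windows into peaks.  Replicate handling follows the
"defined in both biological replicates" rule: only base-pair intersections of
peaks found in both replicates survive.  Sparse peaks are removed with strict
raw-read cutoffs (e.g. control < 9 reads, heat shock < 10 reads).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .genome_model import GenomicInterval
from .signal_io import NORM_TARGET, ReadCounter, ReadSet, StrandedCoverage

__all__ = [
    "Peak",
    "PeakSet",
    "PeakCallerParams",
    "ConditionClassification",
    "call_peaks",
    "intersect_replicates",
    "filter_min_reads",
    "classify_condition",
    "fold_enrichment_class",
    "cooccurrence",
    "venn_counts",
    "add_tag_counts",
    "write_peaks",
    "read_peaks",
]


@dataclass
class Peak:
    interval: GenomicInterval
    raw_tags: dict = field(default_factory=dict)
    norm_tags: dict = field(default_factory=dict)
    fold_vs_control: float = 0.0
    pvalue: float = 1.0
    summit: int | None = None
    feature: object | None = None
    enrichment_class: str | None = None

    def __post_init__(self):
        if any(v < 0 for v in self.raw_tags.values()):
            raise ValueError("raw tag counts must be >= 0")
        if self.fold_vs_control < 0:
            raise ValueError("fold_vs_control must be >= 0")


@dataclass
class PeakSet:
    sample_id: str
    condition: str
    peaks: list[Peak]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.peaks = _merge_same_set(self.peaks)

    def __len__(self):
        return len(self.peaks)

    def intervals(self) -> list[GenomicInterval]:
        return [p.interval for p in self.peaks]


def _merge_same_set(peaks: list[Peak]) -> list[Peak]:
    """Sort and merge overlapping peaks within one set (union of bases)."""
    peaks = sorted(peaks, key=lambda p: (p.interval.chrom, p.interval.start))
    out: list[Peak] = []
    for p in peaks:
        if out and out[-1].interval.chrom == p.interval.chrom and p.interval.start < out[-1].interval.end:
            prev = out[-1]
            merged = GenomicInterval(
                prev.interval.chrom,
                prev.interval.start,
                max(prev.interval.end, p.interval.end),
                prev.interval.strand,
            )
            keep = prev if prev.pvalue <= p.pvalue else p
            out[-1] = Peak(
                merged, dict(keep.raw_tags), dict(keep.norm_tags),
                max(prev.fold_vs_control, p.fold_vs_control),
                min(prev.pvalue, p.pvalue), keep.summit,
            )
        else:
            out.append(p)
    return out


@dataclass
class PeakCallerParams:
    """Sliding-window caller parameters (HOMER-like desk defaults)."""

    window_bp: int = 200
    step_bp: int = 50
    min_fold: float = 4.0
    max_p: float = 1e-4
    merge_gap: int = 100
    min_width: int = 100
    pseudo_expect: float = 1.0  # floor on the control expectation, in raw tags
    # control lambda is estimated over this wider window and scaled down, so
    # the expectation is not dominated by control shot noise
    control_window_bp: int = 2000


def call_peaks(
    sample: StrandedCoverage,
    control: StrandedCoverage | None,
    params: PeakCallerParams | None = None,
    sample_id: str = "sample",
    condition: str = "C",
) -> PeakSet:
    """Sliding-window Poisson peak calling against a control sample.

    Raw sample window counts are tested against ``max(scaled control window,
    pseudo_expect)`` with a Poisson upper tail; windows passing both the
    p-value and the fold cutoff are merged (gap <= ``merge_gap``) into peaks.
    With no/empty control, a genome-wide uniform expectation is used.
    """
    params = params or PeakCallerParams()
    bs = sample.bin_size
    if params.window_bp % bs or params.step_bp % bs:
        raise ValueError("window_bp and step_bp must be multiples of the coverage bin size")
    use_uniform = control is None or control.total_reads == 0 or all(
        not np.any(d["+"]) and not np.any(d["-"]) for d in (control.counts.values() if control else [])
    )
    if control is not None and use_uniform and control.total_reads == 0:
        warnings.warn("empty control: falling back to genome-wide uniform expectation")
    genome_bp = sum(sample.chrom_sizes.values())
    sample_total_raw = sample.total_reads
    depth_ratio = None if use_uniform else sample.total_reads / control.total_reads

    w_bins = params.window_bp // bs
    step_bins = params.step_bp // bs
    peaks: list[Peak] = []
    for chrom in sample.counts:
        raw = (sample.counts[chrom]["+"] + sample.counts[chrom]["-"]) / sample.scale
        n = len(raw)
        if n < w_bins:
            continue
        cum = np.concatenate([[0.0], np.cumsum(raw)])
        starts = np.arange(0, n - w_bins + 1, step_bins)
        win = cum[starts + w_bins] - cum[starts]
        if use_uniform:
            expected = np.full_like(win, sample_total_raw * params.window_bp / genome_bp)
        else:
            craw = (control.counts[chrom]["+"] + control.counts[chrom]["-"]) / control.scale
            ccum = np.concatenate([[0.0], np.cumsum(craw)])
            cw_bins = max(params.control_window_bp // bs, w_bins)
            half = (cw_bins - w_bins) // 2
            lo = np.clip(starts - half, 0, n)
            hi = np.clip(starts + w_bins + half, 0, n)
            expected = (ccum[hi] - ccum[lo]) / (hi - lo) * w_bins * depth_ratio
        expected = np.maximum(expected, params.pseudo_expect)
        with np.errstate(divide="ignore", invalid="ignore"):
            fold = win / expected
        pvals = sps.poisson.sf(np.round(win) - 1, expected)
        sig = (pvals <= params.max_p) & (fold >= params.min_fold)
        if not np.any(sig):
            continue
        # merge significant windows into peak regions
        idx = np.nonzero(sig)[0]
        regions: list[list[int]] = []
        for i in idx:
            s, e = starts[i] * bs, (starts[i] + w_bins) * bs
            if regions and s - regions[-1][1] <= params.merge_gap:
                regions[-1][1] = max(regions[-1][1], e)
                regions[-1][2] = min(regions[-1][2], pvals[i])
                regions[-1][3] = max(regions[-1][3], fold[i])
            else:
                regions.append([s, e, pvals[i], fold[i]])
        for s, e, p, f in regions:
            if e - s < params.min_width:
                continue
            b0, b1 = s // bs, e // bs
            summit_bin = b0 + int(np.argmax(raw[b0:b1]))
            peaks.append(
                Peak(
                    GenomicInterval(chrom, s, min(e, sample.chrom_sizes[chrom])),
                    fold_vs_control=float(f),
                    pvalue=float(p),
                    summit=summit_bin * bs + bs // 2,
                )
            )
    return PeakSet(
        sample_id, condition, peaks,
        provenance={"replicate_intersected": False, "filters": [], "params": vars(params)},
    )


def add_tag_counts(ps: PeakSet, readsets: dict[str, ReadSet]) -> PeakSet:
    """Fill per-sample raw read counts (integer overlap counts) and
    depth-normalized tags (per 10^7 reads) for every peak."""
    counters = {sid: ReadCounter(rs) for sid, rs in readsets.items()}
    for p in ps.peaks:
        for sid, counter in counters.items():
            raw = counter.count(p.interval)
            p.raw_tags[sid] = raw
            p.norm_tags[sid] = raw * NORM_TARGET / counter.total_reads
    return ps


def intersect_replicates(a: PeakSet, b: PeakSet) -> PeakSet:
    """Base-pair intersections of overlapping peaks from two replicates.

    Only regions covered by a peak in both replicates survive; tag counts must
    be recomputed on the output regions (:func:`add_tag_counts`).
    """
    if a.condition != b.condition:
        raise ValueError("replicates must share the condition")
    chroms_a = {p.interval.chrom for p in a.peaks}
    chroms_b = {p.interval.chrom for p in b.peaks}
    if chroms_a and chroms_b and not (chroms_a & chroms_b):
        raise ValueError("replicate peak sets use disjoint chromosome namespaces")
    by_chrom: dict[str, list[Peak]] = {}
    for p in b.peaks:
        by_chrom.setdefault(p.interval.chrom, []).append(p)
    out = []
    for p in a.peaks:
        for q in by_chrom.get(p.interval.chrom, []):
            s = max(p.interval.start, q.interval.start)
            e = min(p.interval.end, q.interval.end)
            if s < e:
                out.append(
                    Peak(
                        GenomicInterval(p.interval.chrom, s, e),
                        fold_vs_control=min(p.fold_vs_control, q.fold_vs_control),
                        pvalue=max(p.pvalue, q.pvalue),
                        summit=p.summit,
                    )
                )
    prov = dict(a.provenance)
    prov["replicate_intersected"] = True
    return PeakSet(a.sample_id, a.condition, out, prov)


def filter_min_reads(ps: PeakSet, sample_id: str, min_reads: int) -> PeakSet:
    """Remove peaks whose raw read count for ``sample_id`` is strictly below
    ``min_reads`` (e.g. min_reads=9 removes peaks with <= 8 reads)."""
    kept = []
    for p in ps.peaks:
        if sample_id not in p.raw_tags:
            raise KeyError(f"peak lacks raw counts for sample {sample_id!r}")
        if p.raw_tags[sample_id] >= min_reads:
            kept.append(p)
    prov = dict(ps.provenance)
    prov.setdefault("filters", []).append(f"min_reads[{sample_id}]>={min_reads}")
    return PeakSet(ps.sample_id, ps.condition, kept, prov)


class _OverlapIndex:
    """Sorted-interval index answering 'does anything overlap this?'."""

    def __init__(self, intervals):
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        tmp: dict[str, list] = {}
        for iv in intervals:
            tmp.setdefault(iv.chrom, []).append((iv.start, iv.end))
        for c, ivs in tmp.items():
            a = np.asarray(sorted(ivs))
            # merged intervals -> max-end is monotone; plain sort suffices here
            self._by_chrom[c] = (a[:, 0], np.maximum.accumulate(a[:, 1]))

    def overlaps(self, iv: GenomicInterval) -> bool:
        if iv.chrom not in self._by_chrom:
            return False
        starts, maxends = self._by_chrom[iv.chrom]
        i = np.searchsorted(starts, iv.end, side="left")
        return i > 0 and maxends[i - 1] > iv.start


@dataclass
class ConditionClassification:
    """Partition of control and heat-shock peak sets by >= 1 bp overlap.

    Shared regions are reported once, from the control set's coordinates.
    """

    c_unique: list[Peak]
    shared: list[Peak]
    hs_unique: list[Peak]
    n_shared_hs: int = 0


def classify_condition(psC: PeakSet, psHS: PeakSet) -> ConditionClassification:
    idx_hs = _OverlapIndex(psHS.intervals())
    idx_c = _OverlapIndex(psC.intervals())
    c_unique, shared = [], []
    for p in psC.peaks:
        (shared if idx_hs.overlaps(p.interval) else c_unique).append(p)
    hs_unique = [p for p in psHS.peaks if not idx_c.overlaps(p.interval)]
    return ConditionClassification(
        c_unique, shared, hs_unique, n_shared_hs=len(psHS) - len(hs_unique)
    )


def fold_enrichment_class(
    ps: PeakSet,
    hs_sample: str,
    c_sample: str,
    fold: float = 4.0,
    pseudo: float = 1.0,
) -> dict[str, list[Peak]]:
    """Classify peaks by normalized-tag ratio: HS-enriched if
    ``(HS+eps)/(C+eps) > fold``, HS-depleted if ``< 1/fold``, else unchanged."""
    out = {"HS_enriched": [], "HS_depleted": [], "unchanged": []}
    for p in ps.peaks:
        hs, c = p.norm_tags[hs_sample], p.norm_tags[c_sample]
        if hs < 0 or c < 0:
            raise ValueError("negative tag counts")
        ratio = (hs + pseudo) / (c + pseudo)
        if ratio > fold:
            cls = "HS_enriched"
        elif ratio < 1.0 / fold:
            cls = "HS_depleted"
        else:
            cls = "unchanged"
        p.enrichment_class = cls
        out[cls].append(p)
    return out


def cooccurrence(tf: PeakSet, reference: PeakSet) -> float:
    """Percentage of ``tf`` peaks overlapping >= 1 reference peak by >= 1 bp."""
    if len(tf) == 0:
        raise ValueError("empty query peak set")
    idx = _OverlapIndex(reference.intervals())
    n = sum(1 for p in tf.peaks if idx.overlaps(p.interval))
    return 100.0 * n / len(tf)


def venn_counts(sets: list[PeakSet]) -> dict[frozenset, int]:
    """Peak counts per overlap-membership pattern for 2-3 peak sets.

    Each peak is counted once, under the membership pattern of the sets it
    overlaps (always including its own); a pattern's count is taken from the
    first member set in input order, so identical sets are not double-counted.
    """
    if not 2 <= len(sets) <= 3:
        raise ValueError("venn_counts supports 2 or 3 peak sets")
    names = [ps.sample_id for ps in sets]
    if len(set(names)) != len(names):
        names = [f"{n}#{i}" for i, n in enumerate(names)]
    indexes = {name: _OverlapIndex(ps.intervals()) for name, ps in zip(names, sets)}
    counts: dict[frozenset, int] = {}
    for i, (name, ps) in enumerate(zip(names, sets)):
        for p in ps.peaks:
            pattern = frozenset(
                m for m in names if m == name or indexes[m].overlaps(p.interval)
            )
            if min(names.index(m) for m in pattern) == i:  # first member reports
                counts[pattern] = counts.get(pattern, 0) + 1
    return counts


# ---------------------------------------------------------------------------
# BED6+ peak I/O

def write_peaks(ps: PeakSet, path) -> None:
    sample_ids = sorted({sid for p in ps.peaks for sid in p.raw_tags})
    with open(path, "w") as fh:
        cols = ["#chrom", "start", "end", "name", "score", "strand", "fold", "class"]
        cols += [f"raw[{s}]" for s in sample_ids] + [f"norm[{s}]" for s in sample_ids]
        fh.write("\t".join(cols) + "\n")
        for i, p in enumerate(ps.peaks):
            score = 0.0 if p.pvalue <= 0 else min(-np.log10(max(p.pvalue, 1e-300)), 1000)
            row = [
                p.interval.chrom, str(p.interval.start), str(p.interval.end),
                f"peak{i}", f"{score:.3f}", p.interval.strand,
                f"{p.fold_vs_control:.4g}", p.enrichment_class or ".",
            ]
            row += [str(p.raw_tags.get(s, 0)) for s in sample_ids]
            row += [f"{p.norm_tags.get(s, 0.0):.4g}" for s in sample_ids]
            fh.write("\t".join(row) + "\n")


def read_peaks(path, sample_id: str = "sample", condition: str = "C") -> PeakSet:
    peaks = []
    with open(path) as fh:
        header = None
        for line in fh:
            if line.startswith("#"):
                header = line.lstrip("#").rstrip("\n").split("\t")
                continue
            if not line.strip():
                continue
            p = line.rstrip("\n").split("\t")
            peak = Peak(GenomicInterval(p[0], int(p[1]), int(p[2]), p[5] if len(p) > 5 else "."))
            if header:
                for col, val in zip(header, p):
                    if col.startswith("raw["):
                        peak.raw_tags[col[4:-1]] = int(val)
                    elif col.startswith("norm["):
                        peak.norm_tags[col[5:-1]] = float(val)
                    elif col == "fold":
                        peak.fold_vs_control = float(val)
            peaks.append(peak)
    return PeakSet(sample_id, condition, peaks)
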