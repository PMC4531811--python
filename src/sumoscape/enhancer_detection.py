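"""Divergent eRNA enhancer calling from stranded nascent-transcription
coverage.

Pipeline: (1) segment each strand into de novo transcripts (maximal runs of
bins above a density threshold, bridging short gaps); (2) drop genic
segments and segments within 10 kb downstream of any TTS (read-through
guard); (3) pair opposing-strand transcripts in divergent (outward)
orientation whose proximal ends lie <= 1 kb apart; (4) require balanced
transcription: <= 2-fold difference between the strand read counts in
±500 bp of the pair center; (5) quantify eRNA and ChIP signal in the 1-kb
window centered on the locus.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome_model import GeneModel, GenomicInterval
from .signal_io import StrandedCoverage, window_signal

__all__ = [
    "TranscriptSegment",
    "EnhancerLocus",
    "SegmentationParams",
    "segment_transcripts",
    "mask_genic",
    "pair_divergent",
    "balance_filter",
    "quantify_enhancer",
    "call_enhancers",
    "write_enhancers",
]

HALF_WINDOW_BP = 500  # balance / quantification half-window around the center
PAIR_MAX_GAP_BP = 1000
BALANCE_MAX_FOLD = 2.0
TTS_EXCLUSION_BP = 10000


@dataclass
class TranscriptSegment:
    interval: GenomicInterval
    tag_count: float
    mean_density: float  # tags per bp


@dataclass
class EnhancerLocus:
    chrom: str
    center: int
    plus_count: float
    minus_count: float
    window_1kb: GenomicInterval
    balance_ratio: float = field(init=False)
    erna_total: float = field(init=False)
    chip_signal: dict = field(default_factory=dict)

    def __post_init__(self):
        lo = min(self.plus_count, self.minus_count)
        hi = max(self.plus_count, self.minus_count)
        self.balance_ratio = hi / lo if lo > 0 else float("inf")
        self.erna_total = self.plus_count + self.minus_count


@dataclass
class SegmentationParams:
    density_min: float = 0.5   # tags per bin
    max_gap: int = 250         # bp bridged between above-threshold runs
    min_length: int = 150      # bp


def segment_transcripts(
    cov: StrandedCoverage, strand: str, params: SegmentationParams | None = None
) -> list[TranscriptSegment]:
    """Maximal above-threshold runs per strand, gap-bridged and length-filtered."""
    params = params or SegmentationParams()
    bs = cov.bin_size
    gap_bins = params.max_gap // bs
    segments = []
    for chrom in cov.counts:
        arr = cov.counts[chrom][strand]
        above = arr >= params.density_min
        idx = np.nonzero(above)[0]
        if len(idx) == 0:
            continue
        runs: list[list[int]] = [[idx[0], idx[0]]]
        for b in idx[1:]:
            if b - runs[-1][1] - 1 <= gap_bins:
                runs[-1][1] = b
            else:
                runs.append([b, b])
        for b0, b1 in runs:
            start, end = b0 * bs, min((b1 + 1) * bs, cov.chrom_sizes[chrom])
            if end - start < params.min_length:
                continue
            tags = float(arr[b0 : b1 + 1].sum())
            segments.append(
                TranscriptSegment(
                    GenomicInterval(chrom, start, end, strand),
                    tags,
                    tags / (end - start),
                )
            )
    return segments


def mask_genic(
    segments: list[TranscriptSegment],
    genes: list[GeneModel],
    tts_exclusion: int = TTS_EXCLUSION_BP,
) -> list[TranscriptSegment]:
    """Keep intergenic segments only: drop any segment overlapping a gene
    body or lying within ``tts_exclusion`` bp downstream of a TTS (on the
    gene's strand), guarding against read-through."""
    zones: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        zones.setdefault(g.chrom, []).append((g.start, g.end))
        if g.strand == "+":
            zones[g.chrom].append((g.end, g.end + tts_exclusion))
        else:
            zones[g.chrom].append((max(g.start - tts_exclusion, 0), g.start))
    for c in zones:
        zones[c].sort()
    out = []
    for seg in segments:
        iv = seg.interval
        hit = any(
            iv.start < e and s < iv.end for s, e in zones.get(iv.chrom, [])
        )
        if not hit:
            out.append(seg)
    return out


def pair_divergent(
    plus_segs: list[TranscriptSegment],
    minus_segs: list[TranscriptSegment],
    max_gap: int = PAIR_MAX_GAP_BP,
) -> list[tuple[TranscriptSegment, TranscriptSegment, int]]:
    """Match opposing-strand segments into divergent pairs.

    Divergent geometry: the minus-strand segment lies 5'-ward (left) of the
    plus-strand segment; the proximal ends are the minus segment's right end
    and the plus segment's left end.  Pairs with proximal-end distance <=
    ``max_gap`` (overlap counts as distance 0) are matched greedily by
    closest distance, leftmost first; each segment joins at most one pair.
    Returns ``(plus_seg, minus_seg, center)`` triples sorted by position.
    """
    candidates = []
    for mi, m in enumerate(minus_segs):
        for pi, p in enumerate(plus_segs):
            if p.interval.chrom != m.interval.chrom:
                continue
            # reject convergent/nested geometry
            if p.interval.start < m.interval.start or p.interval.end < m.interval.end:
                continue
            dist = max(p.interval.start - m.interval.end, 0)
            if dist > max_gap:
                continue
            center = (m.interval.end + p.interval.start) // 2
            candidates.append((dist, m.interval.start, p.interval.start, mi, pi, center))
    candidates.sort()
    used_m, used_p = set(), set()
    pairs = []
    for _, _, _, mi, pi, center in candidates:
        if mi in used_m or pi in used_p:
            continue
        used_m.add(mi)
        used_p.add(pi)
        pairs.append((plus_segs[pi], minus_segs[mi], center))
    pairs.sort(key=lambda t: (t[0].interval.chrom, t[2]))
    return pairs


def strand_counts(cov: StrandedCoverage, chrom: str, center: int,
                  half: int = HALF_WINDOW_BP) -> tuple[float, float]:
    lo, hi = max(center - half, 0), center + half
    plus = window_signal(cov, GenomicInterval(chrom, lo, hi, "+"), "sense")
    minus = window_signal(cov, GenomicInterval(chrom, lo, hi, "-"), "sense")
    return plus, minus


def balance_filter(
    plus_count: float, minus_count: float, max_fold: float = BALANCE_MAX_FOLD
) -> tuple[bool, str]:
    """Accept iff both strand counts are > 0 and their ratio is <= max_fold
    ("no more than two-fold difference"; exactly two-fold is accepted)."""
    lo, hi = min(plus_count, minus_count), max(plus_count, minus_count)
    if lo <= 0:
        return False, "one-sided transcription (zero count on one strand)"
    if hi / lo > max_fold:
        return False, f"unbalanced strands ({hi / lo:.2f}-fold > {max_fold:g})"
    return True, "balanced"


def quantify_enhancer(
    chrom: str,
    center: int,
    groseq_cov: StrandedCoverage,
    chip_covs: dict[str, StrandedCoverage] | None = None,
) -> EnhancerLocus:
    """eRNA totals and per-condition ChIP signal in the 1-kb locus window."""
    plus, minus = strand_counts(groseq_cov, chrom, center)
    win = GenomicInterval(chrom, max(center - HALF_WINDOW_BP, 0), center + HALF_WINDOW_BP)
    locus = EnhancerLocus(chrom, center, plus, minus, win)
    if chip_covs:
        for cond, cov in chip_covs.items():
            locus.chip_signal[cond] = window_signal(cov, win, "both")
    return locus


def call_enhancers(
    groseq_cov: StrandedCoverage,
    genes: list[GeneModel],
    chip_covs: dict[str, StrandedCoverage] | None = None,
    seg_params: SegmentationParams | None = None,
    max_gap: int = PAIR_MAX_GAP_BP,
    tts_exclusion: int = TTS_EXCLUSION_BP,
    max_fold: float = BALANCE_MAX_FOLD,
) -> list[EnhancerLocus]:
    """Full eRNA-enhancer pipeline on pooled stranded GRO-seq coverage."""
    plus = mask_genic(segment_transcripts(groseq_cov, "+", seg_params), genes, tts_exclusion)
    minus = mask_genic(segment_transcripts(groseq_cov, "-", seg_params), genes, tts_exclusion)
    loci = []
    for _p, _m, center in pair_divergent(plus, minus, max_gap):
        pc, mc = strand_counts(groseq_cov, _p.interval.chrom, center)
        ok, _reason = balance_filter(pc, mc, max_fold)
        if not ok:
            continue
        loci.append(quantify_enhancer(_p.interval.chrom, center, groseq_cov, chip_covs))
    return loci


def write_enhancers(loci: list[EnhancerLocus], path) -> None:
    conds = sorted({c for l in loci for c in l.chip_signal})
    with open(path, "w") as fh:
        cols = ["#chrom", "start", "end", "name", "score", "strand",
                "center", "plus_count", "minus_count", "balance_ratio", "erna_total"]
        cols += [f"chip[{c}]" for c in conds]
        fh.write("\t".join(cols) + "\n")
        for i, l in enumerate(loci):
            row = [l.chrom, str(l.window_1kb.start), str(l.window_1kb.end),
                   f"eRNA{i}", "0", ".", str(l.center),
                   f"{l.plus_count:.4g}", f"{l.minus_count:.4g}",
                   f"{l.balance_ratio:.4g}", f"{l.erna_total:.4g}"]
            row += [f"{l.chip_signal.get(c, 0.0):.4g}" for c in conds]
            fh.write("\t".join(row) + "\n")
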