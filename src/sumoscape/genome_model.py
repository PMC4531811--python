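"""Gene and interval data model, coordinate conventions, and feature annotation.

All coordinates are 0-based half-open (BED convention) internally; GTF input
(1-based closed) is converted on read.  A gene's TSS is ``start`` on the plus
strand and ``end`` on the minus strand; windows specified as upstream/downstream
are oriented in the direction of transcription.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "FeatureClass",
    "AnnotationConfig",
    "promoter_window",
    "annotate_interval",
    "annotate_intervals",
    "tss_tts_signal",
    "read_gtf",
    "write_gtf",
    "read_bed12_genes",
]

FEATURE_PRECEDENCE = ("promoter", "TTS", "exon", "intron", "intergenic")


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(require 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class GeneModel:
    """A transcript unit; the coordinate frame for promoter/body/TTS windows."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if not (0 <= self.start < self.end):
            raise ValueError(f"gene {self.gene_id}: require 0 <= start < end")
        for s, e in self.exons:
            if not (self.start <= s < e <= self.end):
                raise ValueError(f"gene {self.gene_id}: exon [{s},{e}) outside gene")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def tts(self) -> int:
        return self.end if self.strand == "+" else self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)


@dataclass
class FeatureClass:
    """Genomic feature assignment of an interval: exactly one class, plus the
    nearest gene and the signed distance from interval center to its TSS
    (positive downstream of the TSS in the direction of transcription)."""

    feature: str
    nearest_gene_id: str | None
    distance_to_tss: int | None

    def __post_init__(self):
        if self.feature not in FEATURE_PRECEDENCE:
            raise ValueError(f"unknown feature class {self.feature!r}")


@dataclass
class AnnotationConfig:
    """Windows used for feature-class annotation.

    The promoter annotation window (default 1000 bp upstream to 100 bp
    downstream of the TSS) is distinct from the promoter-proximal pausing
    window (TSS..+250), which is fixed in the transcription-metrics layer.
    """

    promoter_upstream: int = 1000
    promoter_downstream: int = 100
    tts_flank: int = 100


def promoter_window(
    gene: GeneModel,
    upstream: int,
    downstream: int,
    chrom_length: int | None = None,
) -> GenomicInterval:
    """Strand-oriented window around the TSS.

    ``upstream`` extends 5' of the TSS against the direction of transcription;
    ``downstream`` extends into the gene.  Clipped to ``[0, chrom_length)``.
    """
    if upstream < 0 or downstream < 0:
        raise ValueError("upstream and downstream must be >= 0")
    if gene.strand == "+":
        start, end = gene.tss - upstream, gene.tss + downstream
    else:
        start, end = gene.tss - downstream, gene.tss + upstream
    start = max(start, 0)
    if chrom_length is not None:
        end = min(end, chrom_length)
    if end <= start:
        raise ValueError(
            f"promoter window of {gene.gene_id} falls entirely outside the chromosome"
        )
    return GenomicInterval(gene.chrom, start, end, gene.strand)


def tts_window(gene: GeneModel, flank: int, chrom_length: int | None = None) -> GenomicInterval:
    start = max(gene.tts - flank, 0)
    end = gene.tts + flank
    if chrom_length is not None:
        end = min(end, chrom_length)
    return GenomicInterval(gene.chrom, start, end, gene.strand)


def _signed_tss_distance(center: int, gene: GeneModel) -> int:
    d = center - gene.tss
    return d if gene.strand == "+" else -d


def annotate_interval(
    iv: GenomicInterval,
    genes: list[GeneModel],
    config: AnnotationConfig | None = None,
) -> FeatureClass:
    """Assign one feature class by precedence promoter > TTS > exon > intron >
    intergenic, and the nearest gene by |interval center - TSS| (ties broken by
    smallest gene_id)."""
    config = config or AnnotationConfig()
    chrom_genes = [g for g in genes if g.chrom == iv.chrom]
    if not genes:
        warnings.warn("empty gene set: all intervals annotated intergenic")
    if not chrom_genes:
        return FeatureClass("intergenic", None, None)

    center = iv.center
    nearest = min(chrom_genes, key=lambda g: (abs(center - g.tss), g.gene_id))
    dist = _signed_tss_distance(center, nearest)

    best = "intergenic"
    rank = {f: i for i, f in enumerate(FEATURE_PRECEDENCE)}
    for g in chrom_genes:
        pw = promoter_window(g, config.promoter_upstream, config.promoter_downstream)
        if iv.overlaps(pw):
            cls = "promoter"
        elif iv.overlaps(tts_window(g, config.tts_flank)):
            cls = "TTS"
        elif iv.start < g.end and g.start < iv.end:
            cls = "intron"
            for s, e in g.exons:
                if iv.start < e and s < iv.end:
                    cls = "exon"
                    break
            if not g.exons:
                cls = "exon"  # single-exon model: the whole body is exonic
        else:
            continue
        if rank[cls] < rank[best]:
            best = cls
    if best == "promoter":
        # promoter hits report distance 0 per convention
        promoter_genes = [
            g
            for g in chrom_genes
            if iv.overlaps(
                promoter_window(g, config.promoter_upstream, config.promoter_downstream)
            )
        ]
        nearest = min(promoter_genes, key=lambda g: (abs(center - g.tss), g.gene_id))
        return FeatureClass("promoter", nearest.gene_id, 0)
    return FeatureClass(best, nearest.gene_id, dist)


def annotate_intervals(
    intervals: list[GenomicInterval],
    genes: list[GeneModel],
    config: AnnotationConfig | None = None,
) -> list[FeatureClass]:
    return [annotate_interval(iv, genes, config) for iv in intervals]


def tss_tts_signal(genes, cov, flank: int) -> pd.DataFrame:
    """Normalized tag sums in [TSS-flank, TSS+flank) and [TTS-flank, TTS+flank)
    per gene.  Genes shorter than ``flank`` have overlapping windows; they are
    flagged, not dropped."""
    from .signal_io import window_signal  # local import to avoid a cycle

    if flank <= 0:
        raise ValueError("flank must be > 0")
    rows = []
    for g in genes:
        tss_iv = GenomicInterval(g.chrom, max(g.tss - flank, 0), g.tss + flank)
        tts_iv = GenomicInterval(g.chrom, max(g.tts - flank, 0), g.tts + flank)
        rows.append(
            {
                "gene_id": g.gene_id,
                "tss_signal": window_signal(cov, tss_iv),
                "tts_signal": window_signal(cov, tts_iv),
                "windows_overlap": g.length < flank,
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")


# ---------------------------------------------------------------------------
# GTF / BED12 gene ingestion

_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')


def read_gtf(path) -> list[GeneModel]:
    """Read gene models from a GTF file (transcript and exon lines).

    GTF 1-based closed coordinates are converted to 0-based half-open.  One
    model is kept per gene_id: the longest transcript.
    """
    transcripts: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GTF columns")
            chrom, _, feat, start, end, _, strand, _, attrs = parts[:9]
            if feat not in ("transcript", "exon", "gene"):
                continue
            a = dict(_ATTR_RE.findall(attrs))
            gid = a.get("gene_id")
            if gid is None:
                raise ValueError(f"{path}:{lineno}: missing gene_id attribute")
            tid = a.get("transcript_id", gid)
            key = (gid, tid)
            start0, end1 = int(start) - 1, int(end)
            rec = transcripts.setdefault(
                key, {"chrom": chrom, "strand": strand, "start": None, "end": None, "exons": []}
            )
            if feat in ("transcript", "gene"):
                rec["start"], rec["end"] = start0, end1
            elif feat == "exon":
                rec["exons"].append((start0, end1))

    by_gene: dict[str, GeneModel] = {}
    for (gid, _tid), rec in transcripts.items():
        if rec["start"] is None:
            if not rec["exons"]:
                continue
            rec["start"] = min(s for s, _ in rec["exons"])
            rec["end"] = max(e for _, e in rec["exons"])
        model = GeneModel(
            gid, rec["chrom"], rec["strand"], rec["start"], rec["end"],
            sorted(rec["exons"]),
        )
        prev = by_gene.get(gid)
        if prev is None or model.length > prev.length:
            by_gene[gid] = model
    return sorted(by_gene.values(), key=lambda g: (g.chrom, g.start, g.gene_id))


def write_gtf(genes: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.1";'
            fh.write(
                f"{g.chrom}\tsumoscape\ttranscript\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )
            for s, e in g.exons:
                fh.write(
                    f"{g.chrom}\tsumoscape\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attrs}\n"
                )


def read_bed12_genes(path) -> list[GeneModel]:
    """Read gene models from BED12 (block fields become exons)."""
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            p = line.rstrip("\n").split("\t")
            if len(p) < 6:
                raise ValueError(f"{path}:{lineno}: need >= 6 BED columns for genes")
            chrom, start, end, name, _, strand = p[:6]
            start, end = int(start), int(end)
            exons = []
            if len(p) >= 12:
                sizes = [int(x) for x in p[10].rstrip(",").split(",")]
                offs = [int(x) for x in p[11].rstrip(",").split(",")]
                exons = [(start + o, start + o + s) for o, s in zip(offs, sizes)]
            genes.append(GeneModel(name, chrom, strand, start, end, exons))
    return genes
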