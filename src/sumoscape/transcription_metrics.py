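"""Per-gene transcription quantification from stranded nascent-transcription
coverage, promoter-proximal pausing, activity classes, response ratios, and
quartile stratification.

Conventions (all strand-oriented):

* promoter window: TSS to +250 bp, sense strand;
* gene body: +250 bp to the TTS, sense strand;
* transcribed: gene-body RPKM > 0.5 in control or heat shock;
* pausing index (PPI): promoter RPKM / body RPKM (undefined when body = 0);
* Pol II activity: promoter Pol II RPKM > 0.2 (signal pooled over strands);
* Pol II gene counting window: TSS to TTS + 3 kb.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome_model import GeneModel, GenomicInterval
from .signal_io import StrandedCoverage, rpkm, window_signal

__all__ = [
    "TranscriptionRecord",
    "PROMOTER_BP",
    "quantify_transcription",
    "classify_transcribed",
    "pausing_index",
    "classify_pol2_active",
    "pol2_gene_counts",
    "response_log2",
    "quartile_groups",
    "transcription_table",
]

PROMOTER_BP = 250  # pausing-index promoter window, TSS..+250
BODY_RPKM_CUTOFF = 0.5
POL2_RPKM_CUTOFF = 0.2
TTS_EXTENSION_BP = 3000


@dataclass
class TranscriptionRecord:
    gene_id: str
    condition: str
    promoter_rpkm: float
    body_rpkm: float | None
    ppi: float | None
    transcribed: bool = False
    pol2_promoter_rpkm: float | None = None
    pol2_active: bool | None = None
    log2_response: float | None = None


def _gene_windows(gene: GeneModel) -> tuple[GenomicInterval, GenomicInterval | None]:
    if gene.strand == "+":
        prom = GenomicInterval(gene.chrom, gene.tss, gene.tss + PROMOTER_BP, "+")
        body = (
            GenomicInterval(gene.chrom, gene.tss + PROMOTER_BP, gene.end, "+")
            if gene.length > PROMOTER_BP
            else None
        )
    else:
        prom = GenomicInterval(gene.chrom, gene.tss - PROMOTER_BP, gene.tss, "-")
        body = (
            GenomicInterval(gene.chrom, gene.start, gene.tss - PROMOTER_BP, "-")
            if gene.length > PROMOTER_BP
            else None
        )
    return prom, body


def quantify_transcription(
    gene: GeneModel, cov: StrandedCoverage
) -> tuple[float, float | None]:
    """Sense-strand promoter (TSS..+250) and gene-body (+250..TTS) RPKM.

    Genes of <= 250 bp have no body window; body RPKM is None and callers
    must treat the record as flagged.
    """
    prom, body = _gene_windows(gene)
    total = cov.total_reads
    prom_tags = window_signal(cov, prom, strand_mode="sense") / cov.scale
    promoter_rpkm = rpkm(prom_tags, len(prom), total)
    if body is None:
        return promoter_rpkm, None
    body_tags = window_signal(cov, body, strand_mode="sense") / cov.scale
    return promoter_rpkm, rpkm(body_tags, len(body), total)


def classify_transcribed(body_rpkm_c: float | None, body_rpkm_hs: float | None) -> bool:
    """Transcribed iff gene-body RPKM > 0.5 in control *or* heat shock."""
    vals = [v for v in (body_rpkm_c, body_rpkm_hs) if v is not None]
    if any(v < 0 for v in vals):
        raise ValueError("RPKM must be >= 0")
    return any(v > BODY_RPKM_CUTOFF for v in vals)


def pausing_index(promoter_rpkm: float, body_rpkm: float | None) -> float | None:
    """Promoter-proximal pausing index: promoter RPKM / body RPKM."""
    if body_rpkm is None or body_rpkm == 0:
        return None
    return promoter_rpkm / body_rpkm


def classify_pol2_active(pol2_promoter_rpkm: float) -> bool:
    """Active iff promoter Pol II RPKM > 0.2 (strict)."""
    if pol2_promoter_rpkm < 0:
        raise ValueError("RPKM must be >= 0")
    return pol2_promoter_rpkm > POL2_RPKM_CUTOFF


def pol2_gene_counts(
    gene: GeneModel, pol2_cov: StrandedCoverage, extension: int = TTS_EXTENSION_BP
) -> tuple[float, float]:
    """Strand-pooled Pol II tag count and RPKM over TSS..TTS+3 kb.

    The extension runs downstream of the TTS in the direction of
    transcription; the window is clipped at chromosome bounds.
    """
    L = pol2_cov.chrom_sizes.get(gene.chrom, math.inf)
    if gene.strand == "+":
        start, end = gene.start, min(gene.end + extension, L)
    else:
        start, end = max(gene.start - extension, 0), gene.end
    iv = GenomicInterval(gene.chrom, int(start), int(end), gene.strand)
    tags = window_signal(pol2_cov, iv, strand_mode="both") / pol2_cov.scale
    return tags, rpkm(tags, len(iv), pol2_cov.total_reads)


def response_log2(
    body_rpkm_hs: float, body_rpkm_c: float, pseudo: float = 0.1
) -> float:
    """log2((HS + pseudo) / (C + pseudo)) transcriptional response."""
    if body_rpkm_hs < 0 or body_rpkm_c < 0:
        raise ValueError("RPKM must be >= 0")
    return math.log2((body_rpkm_hs + pseudo) / (body_rpkm_c + pseudo))


def quartile_groups(values, k: int = 4) -> np.ndarray:
    """Split values into ``k`` ascending groups of near-equal size.

    Returns a label array (0 = lowest group).  Group sizes differ by at most
    one; ties keep stable input order.
    """
    values = np.asarray(values, dtype=float)
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(values) < k:
        raise ValueError("need at least k values")
    order = np.argsort(values, kind="stable")
    labels = np.empty(len(values), dtype=int)
    for gi, chunk in enumerate(np.array_split(order, k)):
        labels[chunk] = gi
    return labels


def transcription_table(
    genes: list[GeneModel],
    cov_c: StrandedCoverage,
    cov_hs: StrandedCoverage,
    pol2_cov: dict[str, StrandedCoverage] | None = None,
    response_pseudo: float = 0.1,
) -> pd.DataFrame:
    """Per-gene transcription metrics for control and heat shock.

    One row per gene with both conditions' promoter/body RPKM, PPI,
    transcribed flag, optional Pol II promoter RPKM/activity, and the
    log2(HS/C) body response (transcribed genes with defined bodies only).
    """
    rows = []
    for g in genes:
        pr_c, body_c = quantify_transcription(g, cov_c)
        pr_hs, body_hs = quantify_transcription(g, cov_hs)
        transcribed = classify_transcribed(body_c, body_hs)
        row = {
            "gene_id": g.gene_id,
            "promoter_rpkm_C": pr_c,
            "promoter_rpkm_HS": pr_hs,
            "body_rpkm_C": body_c,
            "body_rpkm_HS": body_hs,
            "ppi_C": pausing_index(pr_c, body_c),
            "ppi_HS": pausing_index(pr_hs, body_hs),
            "transcribed": transcribed,
            "log2_response": (
                response_log2(body_hs, body_c, response_pseudo)
                if transcribed and body_c is not None and body_hs is not None
                else None
            ),
        }
        if pol2_cov:
            for cond, cov in pol2_cov.items():
                prom, _ = _gene_windows(g)
                tags = window_signal(cov, prom, strand_mode="both") / cov.scale
                r = rpkm(tags, len(prom), cov.total_reads)
                row[f"pol2_promoter_rpkm_{cond}"] = r
                row[f"pol2_active_{cond}"] = classify_pol2_active(r)
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene_id")
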