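"""End-to-end workflows tying the modules together on one scenario.

These are the compositions the individual modules exist for: replicate-
filtered condition peak sets, their feature annotation and condition
classes, per-gene transcription metrics, and the stratified association
analysis (pausing / response / transcription by SUMO-peak association).
"""

from __future__ import annotations

import numpy as np

from .association import (
    associate_intergenic,
    associate_promoter,
    stratified_comparison,
)
from .genome_model import AnnotationConfig, annotate_interval
from .peak_analysis import (
    PeakCallerParams,
    PeakSet,
    add_tag_counts,
    call_peaks,
    classify_condition,
    filter_min_reads,
    intersect_replicates,
)
from .signal_io import build_coverage
from .synthetic_data import (
    SimConfig,
    TruthLedger,
    generate_genome,
    pool_readsets,
    simulate_chip,
    simulate_groseq,
)
from .transcription_metrics import transcription_table

# raw-read peak filters per condition (strict <)
MIN_READS = {"C": 9, "HS": 10}


def sumo_peak_sets(
    cfg: SimConfig,
    genes,
    truth: TruthLedger,
    conditions=("C", "HS"),
    params: PeakCallerParams | None = None,
) -> dict[str, PeakSet]:
    """Replicate-intersected, read-count-filtered SUMO peak sets per condition.

    Each replicate is called against the shared input sample; only base-pair
    regions supported by both replicates survive, and peaks with fewer pooled
    raw reads than the condition's cutoff are removed.
    """
    sizes = truth.chrom_sizes
    ctl_cov = build_coverage(
        simulate_chip(cfg, genes, truth, "INPUT", "C", 1), sizes, 50, "fragment"
    )
    out = {}
    for cond in conditions:
        reps, readsets = [], []
        for rep in (1, 2):
            rs = simulate_chip(cfg, genes, truth, "SUMO", cond, rep)
            readsets.append(rs)
            cov = build_coverage(rs, sizes, 50, "fragment")
            reps.append(call_peaks(cov, ctl_cov, params,
                                   sample_id=f"SUMO_{cond}", condition=cond))
        inter = intersect_replicates(reps[0], reps[1])
        pooled = pool_readsets(readsets, f"SUMO_{cond}_pooled")
        add_tag_counts(inter, {f"SUMO_{cond}": pooled})
        out[cond] = filter_min_reads(inter, f"SUMO_{cond}", MIN_READS[cond])
    return out


def feature_fractions(peaks: list, genes, config: AnnotationConfig | None = None) -> dict:
    """Fraction of peaks per feature class (promoter/TTS/exon/intron/intergenic)."""
    if not peaks:
        return {}
    feats = [annotate_interval(p.interval, genes, config).feature for p in peaks]
    return {f: feats.count(f) / len(feats) for f in set(feats)}


def hs_scenario_analysis(cfg: SimConfig) -> dict:
    """Full heat-shock scenario: peaks, condition classes, transcription,
    association, and the stratified directional comparisons.

    Returns the quantities behind the headline contrasts: where HS-gained and
    HS-lost SUMO peaks sit in the genome, and how promoter- or intergenic-
    SUMO-associated genes differ in pausing, response and HS transcription.
    """
    genes, truth = generate_genome(cfg)
    sizes = truth.chrom_sizes
    peaksets = sumo_peak_sets(cfg, genes, truth)
    cc = classify_condition(peaksets["C"], peaksets["HS"])

    anno = AnnotationConfig()
    gain_frac = feature_fractions(cc.hs_unique, genes, anno)
    loss_frac = feature_fractions(cc.c_unique, genes, anno)

    # transcription from pooled GRO-seq replicates per condition
    covs = {}
    for cond in ("C", "HS"):
        pooled = pool_readsets(
            [simulate_groseq(cfg, genes, truth, cond, r) for r in (1, 2)]
        )
        covs[cond] = build_coverage(pooled, sizes, 50, "5prime")
    records = transcription_table(genes, covs["C"], covs["HS"])

    # association flags from the called peak sets
    prom_flags = associate_promoter(genes, peaksets["HS"], anno)
    intergenic_peaks = PeakSet(
        "SUMO_C_intergenic", "C",
        [p for p in peaksets["C"].peaks
         if annotate_interval(p.interval, genes, anno).feature == "intergenic"],
    )
    inter_flags = associate_intergenic(genes, intergenic_peaks)

    transcribed = records[records.transcribed]
    comparisons = {
        "ppi_by_promoter": stratified_comparison(
            transcribed.assign(ppi_HS=transcribed.ppi_HS.astype(float)),
            prom_flags, "ppi_HS"),
        "response_by_promoter": stratified_comparison(
            transcribed.assign(log2_response=transcribed.log2_response.astype(float)),
            prom_flags, "log2_response"),
        "hs_transcription_by_intergenic": stratified_comparison(
            transcribed.assign(body_rpkm_HS=transcribed.body_rpkm_HS.astype(float)),
            inter_flags, "body_rpkm_HS"),
    }

    return {
        "genes": genes,
        "truth": truth,
        "peaksets": peaksets,
        "condition_classes": cc,
        "gain_feature_fractions": gain_frac,
        "loss_feature_fractions": loss_frac,
        "records": records,
        "promoter_flags": prom_flags,
        "intergenic_flags": inter_flags,
        "comparisons": comparisons,
        "n_transcribed": int(records.transcribed.sum()),
    }


def directional_summary(analysis: dict) -> dict:
    """Boil the scenario analysis down to the directional contrasts:
    medians per group and rank-test p-values for each comparison, plus the
    feature-class shifts of HS-gain vs HS-loss peaks."""
    out = {}
    for name, comp in analysis["comparisons"].items():
        s = comp["summary"]
        out[name] = {
            "median_associated": float(s.loc["associated", "median"]),
            "median_unassociated": float(s.loc["unassociated", "median"]),
            "mannwhitney_p": float(comp["tests"]["mannwhitney_p"]),
        }
    out["gain_promoter_fraction"] = analysis["gain_feature_fractions"].get("promoter", 0.0)
    out["loss_promoter_fraction"] = analysis["loss_feature_fractions"].get("promoter", 0.0)
    out["gain_intergenic_fraction"] = analysis["gain_feature_fractions"].get("intergenic", 0.0)
    out["loss_intergenic_fraction"] = analysis["loss_feature_fractions"].get("intergenic", 0.0)
    return out
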