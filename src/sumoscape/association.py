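"""Peak-to-gene association and stratified group comparisons.

Genes are flagged by (i) a SUMO peak overlapping their promoter window and
(ii) a nearby intergenic SUMO peak (peak center within 100 kb of the TSS).
Transcription metrics (body RPKM, pausing index, log2 response) are then
compared between flagged and unflagged genes with rank-based tests, the
framework behind associated-vs-unassociated whisker plots.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .genome_model import AnnotationConfig, GeneModel, GenomicInterval, promoter_window
from .peak_analysis import PeakSet, _OverlapIndex
from .signal_io import StrandedCoverage, signal_matrix, window_signal
from .stats import group_tests

__all__ = [
    "associate_promoter",
    "associate_intergenic",
    "association_table",
    "stratified_comparison",
    "signal_at_peak_subsets",
    "background_level",
]

INTERGENIC_MAX_DIST_BP = 100000


def associate_promoter(
    genes: list[GeneModel],
    peaks: PeakSet,
    config: AnnotationConfig | None = None,
) -> pd.Series:
    """True per gene iff >= 1 peak overlaps its promoter window by >= 1 bp."""
    config = config or AnnotationConfig()
    idx = _OverlapIndex(peaks.intervals())
    flags = {
        g.gene_id: idx.overlaps(
            promoter_window(g, config.promoter_upstream, config.promoter_downstream)
        )
        for g in genes
    }
    return pd.Series(flags, name="promoter_assoc")


def associate_intergenic(
    genes: list[GeneModel],
    intergenic_peaks: PeakSet,
    max_dist: int = INTERGENIC_MAX_DIST_BP,
) -> pd.Series:
    """True per gene iff an intergenic peak center lies within ``max_dist``
    of the TSS on the same chromosome."""
    centers: dict[str, np.ndarray] = {}
    for p in intergenic_peaks.peaks:
        centers.setdefault(p.interval.chrom, []).append(p.interval.center)
    centers = {c: np.sort(np.asarray(v)) for c, v in centers.items()}
    flags = {}
    for g in genes:
        arr = centers.get(g.chrom)
        if arr is None or len(arr) == 0:
            flags[g.gene_id] = False
            continue
        i = np.searchsorted(arr, g.tss)
        best = min(
            abs(int(arr[j]) - g.tss) for j in (i - 1, i) if 0 <= j < len(arr)
        )
        flags[g.gene_id] = best <= max_dist
    return pd.Series(flags, name="intergenic_assoc")


def association_table(
    genes: list[GeneModel],
    promoter_peaks: dict[str, PeakSet],
    intergenic_peaks: dict[str, PeakSet],
    config: AnnotationConfig | None = None,
    max_dist: int = INTERGENIC_MAX_DIST_BP,
) -> pd.DataFrame:
    """Per-gene association flags for each condition's peak sets
    (columns ``promoter_sumo_<cond>`` / ``intergenic_sumo_<cond>``)."""
    out = {}
    for cond, ps in promoter_peaks.items():
        out[f"promoter_sumo_{cond}"] = associate_promoter(genes, ps, config)
    for cond, ps in intergenic_peaks.items():
        out[f"intergenic_sumo_{cond}"] = associate_intergenic(genes, ps, max_dist)
    return pd.DataFrame(out)


def stratified_comparison(
    records: pd.DataFrame,
    flags: pd.Series,
    metric: str,
    min_group: int = 3,
) -> dict:
    """Compare a transcription metric between flag-positive and -negative
    genes: whisker-plot summaries (median, quartiles, 10/90 percentiles) per
    group plus rank-based test p-values."""
    if metric not in records.columns:
        raise KeyError(f"metric {metric!r} not in records")
    joined = records.join(flags.rename("flag"), how="inner")
    joined = joined[np.isfinite(joined[metric].astype(float))]
    groups, labels = [], []
    for flag_val in (True, False):
        vals = joined.loc[joined["flag"] == flag_val, metric].to_numpy(dtype=float)
        if len(vals) < min_group:
            warnings.warn(f"group flag={flag_val} has < {min_group} genes; excluded")
            continue
        groups.append(vals)
        labels.append("associated" if flag_val else "unassociated")
    summary = pd.DataFrame(
        {
            lab: {
                "n": len(v),
                "p10": np.percentile(v, 10),
                "q25": np.percentile(v, 25),
                "median": np.median(v),
                "q75": np.percentile(v, 75),
                "p90": np.percentile(v, 90),
            }
            for lab, v in zip(labels, groups)
        }
    ).T
    result = {"metric": metric, "summary": summary}
    if len(groups) == 2:
        result["tests"] = group_tests(groups)
    return result


def signal_at_peak_subsets(
    peaks: PeakSet,
    partner: PeakSet,
    cov: StrandedCoverage,
    flank: int = 2000,
    bin: int = 25,
) -> dict[str, np.ndarray]:
    """Mean signal profiles at peaks split by >= 1 bp overlap with a partner
    set (co-occurring vs not; e.g. SUMO peaks with/without a second factor)."""
    idx = _OverlapIndex(partner.intervals())
    with_p = [p.interval for p in peaks.peaks if idx.overlaps(p.interval)]
    without = [p.interval for p in peaks.peaks if not idx.overlaps(p.interval)]
    out = {}
    for name, subset in (("with_partner", with_p), ("without_partner", without)):
        if not subset:
            warnings.warn(f"subset {name!r} is empty; profile omitted")
            continue
        _, profile, _ = signal_matrix(subset, cov, flank=flank, bin=bin)
        out[name] = profile
    return out


def background_level(
    control_cov: StrandedCoverage, windows: list[GenomicInterval]
) -> float:
    """Median control (e.g. IgG) window signal over the given windows — the
    gray background line of the whisker plots."""
    if not windows:
        raise ValueError("need at least one window")
    return float(np.median([window_signal(control_cov, w, "both") for w in windows]))
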