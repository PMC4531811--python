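"""Synthetic heat-shock genome generator with planted ground truth.

Emulates the data structure of an acute heat-shock (HS) experiment on a small
genome: gene models in five classes (HS-induced, HS-repressed, stable, silent,
and a ZNF-like class carrying 3'-end SUMO peaks), stranded nascent-
transcription reads with planted promoter-pausing structure, two-replicate
ChIP fragment sets for SUMO / PIAS1-like / Pol II-like / TF-like factors with
planted condition-dependent peaks, divergent eRNA loci with balanced and
decoy (unbalanced / too-far / near-TTS) geometry, and a truth ledger
sufficient to score every caller.

Planted biology in the default scenario mirrors the contrasts the pipeline is
meant to detect: promoter SUMO sites gain occupancy in HS at transcribed
genes whose pausing rises and whose transcription is preferentially
repressed; intergenic SUMO sites lose occupancy in HS and sit near genes
whose HS transcription is boosted; balanced divergent eRNA loci carry
SUMO signal that doubles in HS.

Randomness is drawn from counter-style substreams keyed by ``(seed, stream,
sub-keys)`` so each component's stream is independent of call order, and read
budgets are allocated by a single multinomial draw, so generated totals match
the configured budgets exactly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .genome_model import GeneModel, GenomicInterval
from .signal_io import ReadSet

__all__ = [
    "SimConfig",
    "PlantedSite",
    "PlantedEnhancer",
    "TruthLedger",
    "generate_genome",
    "simulate_groseq",
    "simulate_chip",
    "pool_readsets",
    "write_truth",
    "score_against_truth",
    "score_enhancers",
    "sites_to_intervals",
]

CONDITIONS = ("C", "HS", "Re")
FACTORS = ("SUMO", "PIAS1", "POL2", "TF", "INPUT")
_STREAM = {"genome": 0, "groseq": 1, "chip": 2}


def _rng(seed: int, *key: int) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=tuple(int(k) for k in key))
    return np.random.default_rng(ss)


@dataclass
class SimConfig:
    seed: int = 0
    # genome
    n_chrom: int = 2
    chrom_length: int = 5_000_000
    n_genes: int = 200
    gene_length_range: tuple = (2_000, 10_000)
    min_spacer: int = 20_000
    margin: int = 50_000
    class_proportions: dict = field(
        default_factory=lambda: {
            "induced": 0.15, "repressed": 0.20, "stable": 0.30,
            "silent": 0.25, "znf_like": 0.10,
        }
    )
    # nascent transcription
    groseq_reads: int = 1_000_000
    groseq_background_fraction: float = 0.005
    read_length: int = 30
    rate_log_sigma: float = 1.0        # spread of per-gene body rates
    induced_hs_fold: float = 4.0
    repressed_hs_fold: float = 0.25
    znf_hs_fold: float = 0.7
    ppi_log_mean: float = float(np.log(2.5))
    ppi_log_sigma: float = 0.4
    ppi_global_hs_mult: float = 1.5    # genome-wide pausing gain in HS
    # promoter-SUMO-linked effects
    promoter_assoc_fraction: float = 0.5
    promoter_assoc_ppi_mult: float = 1.6
    promoter_assoc_ppi_hs_mult: float = 1.5
    promoter_assoc_hs_body_mult: float = 0.4
    intergenic_assoc_hs_body_mult: float = 3.0
    # eRNA enhancers
    n_enhancers: int = 40
    n_decoy_unbalanced: int = 13
    n_decoy_too_far: int = 13
    n_decoy_near_tts: int = 13
    enhancer_halfwidth: int = 400
    enhancer_strand_weight: float = 120.0  # relative read weight per strand
    enhancer_weight_log_sigma: float = 0.3
    unbalanced_plus_share: float = 0.85
    too_far_offset: int = 1_250        # proximal-end gap = 2 * offset (> 1 kb)
    near_tts_offset: int = 5_000       # inside the 10 kb read-through exclusion
    # ChIP
    chip_reads: int = 500_000
    replicates: int = 2
    fragment_length: int = 200
    site_width: int = 300
    n_intergenic_sites: int = 15       # SUMO HS-loss
    n_stable_sites: int = 10           # tRNA-like, condition-stable
    n_rep_specific_sites: int = 4      # per condition, replicate 1 only
    fold_promoter_hs_gain: tuple = (1.0, 10.0)
    fold_promoter_shared: tuple = (8.0, 20.0)
    fold_intergenic_hs_loss: tuple = (10.0, 1.0)
    fold_stable: tuple = (10.0, 10.0)
    fold_znf_tts: tuple = (8.0, 1.0)
    fold_enhancer: tuple = (5.0, 10.0)
    fold_rep_specific: float = 10.0
    n_tf_peaks: int = 60
    tf_sumo_overlap_fraction: float = 0.7
    pol2_background_fraction: float = 0.002
    pol2_promoter_share: float = 0.7

    def chrom_sizes(self) -> dict:
        return {f"chr{i + 1}": self.chrom_length for i in range(self.n_chrom)}

    @classmethod
    def small(cls, seed: int = 0, **overrides) -> "SimConfig":
        """Reduced-scale scenario (same structure, ~3x smaller genome).

        The background fraction is scaled with genome size so that
        background RPKM at silent genes stays at the default scenario's
        level (background RPKM scales as fraction / genome length).
        """
        kwargs = dict(
            seed=seed,
            chrom_length=1_500_000,
            n_genes=50,
            groseq_reads=300_000,
            groseq_background_fraction=0.0015,
            chip_reads=150_000,
            n_enhancers=10,
            n_decoy_unbalanced=4,
            n_decoy_too_far=4,
            n_decoy_near_tts=4,
            n_intergenic_sites=6,
            n_stable_sites=4,
            n_rep_specific_sites=2,
            n_tf_peaks=20,
        )
        kwargs.update(overrides)
        return cls(**kwargs)

    def validate(self) -> None:
        if abs(sum(self.class_proportions.values()) - 1.0) > 1e-9:
            raise ValueError("class proportions must sum to 1")
        if any(v < 0 for v in self.class_proportions.values()):
            raise ValueError("class proportions must be >= 0")


@dataclass
class PlantedSite:
    chrom: str
    center: int
    width: int
    fold: dict            # condition -> enrichment fold over background
    replicates: tuple     # replicates carrying the site
    group: str

    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.center - self.width // 2,
                               self.center + self.width // 2)


@dataclass
class PlantedEnhancer:
    chrom: str
    center: int
    kind: str             # balanced | unbalanced | too_far | near_tts
    plus_weight: float
    minus_weight: float


@dataclass
class TruthLedger:
    config: SimConfig
    chrom_sizes: dict
    genes: pd.DataFrame
    sites: dict           # factor -> list[PlantedSite]
    enhancers: list


# ---------------------------------------------------------------------------
# genome construction

def _class_counts(n: int, proportions: dict) -> dict:
    """Largest-remainder apportionment of n genes over classes."""
    items = sorted(proportions.items())
    raw = {k: n * p for k, p in items}
    counts = {k: int(v) for k, v in raw.items()}
    rem = n - sum(counts.values())
    for k, _ in sorted(items, key=lambda kv: -(raw[kv[0]] - counts[kv[0]])):
        if rem == 0:
            break
        counts[k] += 1
        rem -= 1
    return counts


class _Placer:
    """Draw well-separated positions from a set of free intervals."""

    def __init__(self, free, rng, clearance=2000, separation=6000):
        self.free = [(s + clearance, e - clearance) for s, e in free if e - s > 2 * clearance]
        self.rng = rng
        self.sep = separation

    def place(self) -> int:
        lens = np.array([e - s for s, e in self.free], dtype=float)
        if not len(lens) or lens.sum() <= 0:
            raise RuntimeError("no intergenic room left for placement")
        i = self.rng.choice(len(lens), p=lens / lens.sum())
        s, e = self.free[i]
        pos = int(self.rng.integers(s, e))
        del self.free[i]
        for ns, ne in ((s, pos - self.sep), (pos + self.sep, e)):
            if ne - ns > 0:
                self.free.append((ns, ne))
        return pos


def _exclusion_blocks(genes, chrom, tts_excl=10_000, prom_margin=2_500):
    blocks = []
    for g in genes:
        if g.chrom != chrom:
            continue
        if g.strand == "+":
            blocks.append((g.start - prom_margin, g.end + tts_excl + 500))
        else:
            blocks.append((g.start - tts_excl - 500, g.end + prom_margin))
    return sorted(blocks)


def _complement(blocks, lo, hi):
    out = []
    cur = lo
    for s, e in blocks:
        if s > cur:
            out.append((cur, min(s, hi)))
        cur = max(cur, e)
        if cur >= hi:
            break
    if cur < hi:
        out.append((cur, hi))
    return [(s, e) for s, e in out if e > s]


def generate_genome(config: SimConfig) -> tuple[list[GeneModel], TruthLedger]:
    """Lay out genes, plant ChIP sites and eRNA loci, and assign per-gene
    transcription rates and pausing indices for both conditions."""
    config.validate()
    rng = _rng(config.seed, _STREAM["genome"])
    sizes = config.chrom_sizes()
    chrom_names = list(sizes)

    # --- gene placement, round-robin across chromosomes
    per_chrom = {c: config.n_genes // config.n_chrom for c in chrom_names}
    for i in range(config.n_genes % config.n_chrom):
        per_chrom[chrom_names[i]] += 1
    genes: list[GeneModel] = []
    gid = 0
    for chrom in chrom_names:
        n = per_chrom[chrom]
        lengths = rng.integers(*config.gene_length_range, size=n)
        usable = sizes[chrom] - 2 * config.margin
        free = usable - int(lengths.sum())
        if free < (n + 1) * config.min_spacer:
            raise ValueError("genome too small for the requested genes and spacers")
        extra = free - (n + 1) * config.min_spacer
        extra_units = rng.multinomial(extra // 100, np.full(n + 1, 1.0 / (n + 1))) * 100
        gaps = config.min_spacer + extra_units
        strands = rng.choice(["+", "-"], size=n)
        pos = config.margin
        for i in range(n):
            pos += int(gaps[i])
            start = pos
            end = start + int(lengths[i])
            genes.append(GeneModel(f"g{gid:04d}", chrom, str(strands[i]), start, end))
            gid += 1
            pos = end

    # --- gene classes, apportioned per chromosome so that geography-linked
    # analyses (e.g. the 100-kb intergenic association) are not confounded
    # by chance class imbalance between chromosomes
    labels = np.empty(config.n_genes, dtype=object)
    for chrom in chrom_names:
        idx = np.array([i for i, g in enumerate(genes) if g.chrom == chrom])
        counts = _class_counts(len(idx), config.class_proportions)
        chrom_labels = np.concatenate([[k] * v for k, v in sorted(counts.items())])
        labels[idx] = chrom_labels[rng.permutation(len(idx))]

    rate_c = np.exp(rng.normal(0.0, config.rate_log_sigma, config.n_genes))
    rate_c[labels == "silent"] = 0.0
    ppi_c = np.exp(rng.normal(config.ppi_log_mean, config.ppi_log_sigma, config.n_genes))

    class_mult = {
        "induced": config.induced_hs_fold,
        "repressed": config.repressed_hs_fold,
        "stable": 1.0,
        "znf_like": config.znf_hs_fold,
        "silent": 1.0,
    }
    hs_mult = np.array([class_mult[c] for c in labels])

    transcribed = labels != "silent"
    eligible = transcribed & (labels != "znf_like")
    # promoter-SUMO genes sampled stratified within (chromosome, class) so
    # flagged and unflagged groups share the class mix: the planted pausing /
    # repression effects are then not confounded by class composition
    promoter_sumo = np.zeros(config.n_genes, dtype=bool)
    for chrom in chrom_names:
        for cls in np.unique(labels[eligible]):
            idx = np.array([
                i for i in np.nonzero(eligible)[0]
                if genes[i].chrom == chrom and labels[i] == cls
            ])
            if len(idx) == 0:
                continue
            k = int(round(config.promoter_assoc_fraction * len(idx)))
            promoter_sumo[rng.choice(idx, size=k, replace=False)] = True

    # --- SUMO promoter and ZNF 3'-end sites
    sites: dict[str, list[PlantedSite]] = {f: [] for f in FACTORS if f != "INPUT"}
    w = config.site_width
    hs_gain_flag = rng.random(config.n_genes) < 0.5
    for i in np.nonzero(promoter_sumo)[0]:
        g = genes[i]
        center = g.tss + 50 if g.strand == "+" else g.tss - 50
        fold_c, fold_hs = (
            config.fold_promoter_hs_gain if hs_gain_flag[i] else config.fold_promoter_shared
        )
        group = "hs_gain_promoter" if hs_gain_flag[i] else "shared_promoter"
        sites["SUMO"].append(
            PlantedSite(g.chrom, center, w, {"C": fold_c, "HS": fold_hs}, (1, 2), group)
        )
    for i in np.nonzero(labels == "znf_like")[0]:
        g = genes[i]
        center = g.tts - 50 if g.strand == "+" else g.tts + 50
        fc, fh = config.fold_znf_tts
        sites["SUMO"].append(
            PlantedSite(g.chrom, center, w, {"C": fc, "HS": fh}, (1, 2), "znf_tts")
        )

    # --- intergenic placements (chrom1 hosts the SUMO intergenic territory
    # and the eRNA loci, so the 100-kb association flag stays informative)
    placers = {}
    for chrom in chrom_names:
        blocks = _exclusion_blocks(genes, chrom)
        free = _complement(blocks, config.margin // 2, sizes[chrom] - config.margin // 2)
        placers[chrom] = _Placer(free, rng)
    c1 = chrom_names[0]

    for _ in range(config.n_intergenic_sites):
        fc, fh = config.fold_intergenic_hs_loss
        sites["SUMO"].append(PlantedSite(
            c1, placers[c1].place(), w, {"C": fc, "HS": fh}, (1, 2), "hs_loss_intergenic"))
    for _ in range(config.n_stable_sites):
        fc, fh = config.fold_stable
        sites["SUMO"].append(PlantedSite(
            c1, placers[c1].place(), w, {"C": fc, "HS": fh}, (1, 2), "stable_intergenic"))
    for cond in ("C", "HS"):
        for _ in range(config.n_rep_specific_sites):
            chrom = chrom_names[-1]
            f = config.fold_rep_specific
            sites["SUMO"].append(PlantedSite(
                chrom, placers[chrom].place(), w,
                {"C": f if cond == "C" else 1.0, "HS": f if cond == "HS" else 1.0},
                (1,), f"rep1_only_{cond}"))

    # --- eRNA loci (balanced on chrom1, decoys likewise)
    enhancers: list[PlantedEnhancer] = []
    base = config.enhancer_strand_weight
    for _ in range(config.n_enhancers):
        jitter = float(np.exp(rng.normal(0.0, config.enhancer_weight_log_sigma)))
        enhancers.append(PlantedEnhancer(
            c1, placers[c1].place(), "balanced", base * jitter, base * jitter))
    for _ in range(config.n_decoy_unbalanced):
        share = config.unbalanced_plus_share
        enhancers.append(PlantedEnhancer(
            c1, placers[c1].place(), "unbalanced",
            2 * base * share, 2 * base * (1 - share)))
    for _ in range(config.n_decoy_too_far):
        enhancers.append(PlantedEnhancer(
            c1, placers[c1].place(), "too_far", base, base))
    tts_hosts = rng.choice(
        [i for i, g in enumerate(genes) if g.chrom == c1],
        size=config.n_decoy_near_tts, replace=False)
    for i in tts_hosts:
        g = genes[i]
        center = g.tts + config.near_tts_offset if g.strand == "+" else g.tts - config.near_tts_offset
        enhancers.append(PlantedEnhancer(c1, int(center), "near_tts", base, base))

    # SUMO signal at balanced eRNA loci (HS gain)
    fc, fh = config.fold_enhancer
    for e in enhancers:
        if e.kind == "balanced":
            sites["SUMO"].append(PlantedSite(
                e.chrom, e.center, w, {"C": fc, "HS": fh}, (1, 2), "enhancer"))

    # --- PIAS1-like: at the strong shared promoter sites, HS only
    for s in sites["SUMO"]:
        if s.group == "shared_promoter":
            sites["PIAS1"].append(PlantedSite(
                s.chrom, s.center, w, {"C": 1.0, "HS": 10.0}, (1, 2), "pias_promoter"))

    # --- TF-like: a configured fraction overlaps SUMO C sites
    sumo_c_sites = [s for s in sites["SUMO"]
                    if s.fold.get("C", 1.0) > 1.0 and s.replicates == (1, 2)]
    n_over = int(round(config.tf_sumo_overlap_fraction * config.n_tf_peaks))
    n_over = min(n_over, len(sumo_c_sites))
    chosen = rng.choice(len(sumo_c_sites), size=n_over, replace=False)
    for i in chosen:
        s = sumo_c_sites[i]
        sites["TF"].append(PlantedSite(
            s.chrom, s.center, w, {"C": 10.0, "HS": 10.0}, (1, 2), "tf_on_sumo"))
    for _ in range(config.n_tf_peaks - n_over):
        chrom = chrom_names[-1]
        sites["TF"].append(PlantedSite(
            chrom, placers[chrom].place(), w, {"C": 10.0, "HS": 10.0}, (1, 2), "tf_free"))

    # --- association flags from planted geometry (100 kb TSS rule), then
    # HS effect multipliers keyed on the flags
    intergenic_c_centers = np.sort(np.array(
        [s.center for s in sites["SUMO"]
         if s.group in ("hs_loss_intergenic", "stable_intergenic", "enhancer")]))
    intergenic_sumo = np.zeros(config.n_genes, dtype=bool)
    for i, g in enumerate(genes):
        if g.chrom != c1 or len(intergenic_c_centers) == 0:
            continue
        j = np.searchsorted(intergenic_c_centers, g.tss)
        best = min(abs(int(intergenic_c_centers[k]) - g.tss)
                   for k in (j - 1, j) if 0 <= k < len(intergenic_c_centers))
        intergenic_sumo[i] = best <= 100_000

    hs_mult = hs_mult * np.where(promoter_sumo, config.promoter_assoc_hs_body_mult, 1.0)
    hs_mult = hs_mult * np.where(
        intergenic_sumo & transcribed, config.intergenic_assoc_hs_body_mult, 1.0)
    rate_hs = rate_c * hs_mult
    ppi_c_eff = ppi_c * np.where(promoter_sumo, config.promoter_assoc_ppi_mult, 1.0)
    ppi_hs = ppi_c_eff * config.ppi_global_hs_mult * np.where(
        promoter_sumo, config.promoter_assoc_ppi_hs_mult, 1.0)

    with np.errstate(divide="ignore", invalid="ignore"):
        expected_log2 = np.where(rate_c > 0, np.log2(np.maximum(rate_hs, 1e-12) / np.maximum(rate_c, 1e-12)), np.nan)
    gene_df = pd.DataFrame({
        "gene_id": [g.gene_id for g in genes],
        "chrom": [g.chrom for g in genes],
        "strand": [g.strand for g in genes],
        "start": [g.start for g in genes],
        "end": [g.end for g in genes],
        "gene_class": labels,
        "rate_C": rate_c,
        "rate_HS": rate_hs,
        "ppi_C": ppi_c_eff,
        "ppi_HS": ppi_hs,
        "transcribed": transcribed,
        "paused_up": transcribed,  # genome-wide pausing gain in HS
        "promoter_sumo": promoter_sumo,
        "intergenic_sumo": intergenic_sumo,
        "expected_log2_response": expected_log2,
    }).set_index("gene_id")

    truth = TruthLedger(config, sizes, gene_df, sites, enhancers)
    return genes, truth


# ---------------------------------------------------------------------------
# read simulation

def _emit(rng, chrom_of, src_lo, src_hi, src_strand, weights, n_reads, read_len, sizes):
    """Multinomial budget allocation over sources, then uniform positions.

    Returns per-chromosome (starts, ends, strands) arrays.  ``src_strand`` is
    +1 (read 5' at sampled position, extends right), -1 (extends left) or 0.
    """
    weights = np.asarray(weights, dtype=float)
    counts = rng.multinomial(n_reads, weights / weights.sum())
    per_chrom: dict[str, list] = {}
    for i, n in enumerate(counts):
        if n == 0:
            continue
        chrom = chrom_of[i]
        L = sizes[chrom]
        lo = max(src_lo[i], read_len)
        hi = min(src_hi[i], L - read_len)
        if hi <= lo:
            lo, hi = read_len, L - read_len
        pos = rng.integers(lo, hi, size=n)
        st = src_strand[i]
        if st == -1:
            starts, ends = pos + 1 - read_len, pos + 1
        else:
            starts, ends = pos, pos + read_len
        per_chrom.setdefault(chrom, []).append(
            (starts, ends, np.full(n, st, dtype=np.int8)))
    arrays = {}
    for chrom, chunks in per_chrom.items():
        arrays[chrom] = (
            np.concatenate([c[0] for c in chunks]),
            np.concatenate([c[1] for c in chunks]),
            np.concatenate([c[2] for c in chunks]),
        )
    return arrays


def simulate_groseq(config: SimConfig, genes: list[GeneModel], truth: TruthLedger,
                    condition: str, replicate: int) -> ReadSet:
    """Stranded nascent-transcription reads for one condition and replicate.

    Per transcribed gene, promoter-window (TSS..+250) 5'-start density is the
    planted pausing index times the body density; eRNA loci emit divergent
    reads with the planted strand balance; the remainder is uniform
    background.
    """
    rng = _rng(config.seed, _STREAM["groseq"], CONDITIONS.index(condition), replicate)
    sizes = truth.chrom_sizes
    chrom_of, lo, hi, strand, wt = [], [], [], [], []

    df = truth.genes
    rate_col, ppi_col = f"rate_{condition}", f"ppi_{condition}"
    sgn = {"+": 1, "-": -1}
    for g in genes:
        row = df.loc[g.gene_id]
        rate = float(row[rate_col])
        if rate <= 0 or g.length <= 250:
            continue
        s = sgn[g.strand]
        if g.strand == "+":
            prom = (g.tss, g.tss + 250)
            body = (g.tss + 250, g.end)
        else:
            prom = (g.tss - 250, g.tss)
            body = (g.start, g.tss - 250)
        ppi = float(row[ppi_col])
        chrom_of += [g.chrom, g.chrom]
        lo += [prom[0], body[0]]
        hi += [prom[1], body[1]]
        strand += [s, s]
        wt += [rate * ppi * 250, rate * (body[1] - body[0])]

    hw = config.enhancer_halfwidth
    for e in truth.enhancers:
        off = config.too_far_offset if e.kind == "too_far" else 0
        chrom_of += [e.chrom, e.chrom]
        lo += [e.center + off, e.center - off - hw]
        hi += [e.center + off + hw, e.center - off]
        strand += [1, -1]
        wt += [e.plus_weight, e.minus_weight]

    total_w = sum(wt)
    bg_total = total_w * config.groseq_background_fraction / (1 - config.groseq_background_fraction)
    for chrom, L in sizes.items():
        for s in (1, -1):
            chrom_of.append(chrom)
            lo.append(0)
            hi.append(L)
            strand.append(s)
            wt.append(bg_total * L / sum(sizes.values()) / 2)

    arrays = _emit(rng, chrom_of, lo, hi, strand, wt, config.groseq_reads,
                   config.read_length, sizes)
    return ReadSet(f"gro_{condition}_r{replicate}", condition, replicate, arrays)


def simulate_chip(config: SimConfig, genes: list[GeneModel], truth: TruthLedger,
                  factor: str, condition: str, replicate: int = 1) -> ReadSet:
    """ChIP fragment reads for one factor/condition/replicate.

    Planted sites draw fragment centers from a triangular kernel of half-width
    ``fragment_length`` around the site center, with excess mass
    ``(fold - 1) x background density x site width``; INPUT is background
    only; the Pol II-like factor tracks each transcribed gene's rate with a
    promoter-concentrated profile.
    """
    if factor not in FACTORS:
        raise ValueError(f"unknown factor {factor!r}")
    rng = _rng(config.seed, _STREAM["chip"], FACTORS.index(factor),
               CONDITIONS.index(condition), replicate)
    sizes = truth.chrom_sizes
    genome_bp = sum(sizes.values())
    flen = config.fragment_length
    sample_id = f"{factor}_{condition}_r{replicate}" if factor != "INPUT" else "INPUT"

    if factor == "POL2":
        chrom_of, lo, hi, wt = [], [], [], []
        df = truth.genes
        for g in genes:
            rate = float(df.loc[g.gene_id, f"rate_{condition}"])
            if rate <= 0:
                continue
            if g.strand == "+":
                prom = (g.tss, g.tss + 400)
                body = (g.start, min(g.end + 1000, sizes[g.chrom]))
            else:
                prom = (g.tss - 400, g.tss)
                body = (max(g.start - 1000, 0), g.end)
            chrom_of += [g.chrom, g.chrom]
            lo += [prom[0], body[0]]
            hi += [prom[1], body[1]]
            wt += [rate * config.pol2_promoter_share,
                   rate * (1 - config.pol2_promoter_share)]
        bgf = config.pol2_background_fraction
        bg_total = sum(wt) * bgf / (1 - bgf)
        for chrom, L in sizes.items():
            chrom_of.append(chrom)
            lo.append(0)
            hi.append(L)
            wt.append(bg_total * L / genome_bp)
        arrays = _emit(rng, chrom_of, lo, hi, [0] * len(wt), wt,
                       config.chip_reads, flen, sizes)
        return ReadSet(sample_id, condition, replicate, arrays)

    active_sites = [] if factor == "INPUT" else [
        s for s in truth.sites[factor]
        if s.fold.get(condition, 1.0) > 1.0 and replicate in s.replicates
    ]
    # weights in per-bp background units: background = genome_bp,
    # each site = (fold - 1) * width
    weights = [float(genome_bp)] + [
        (s.fold[condition] - 1.0) * s.width for s in active_sites
    ]
    counts = rng.multinomial(config.chip_reads, np.asarray(weights) / sum(weights))
    per_chrom: dict[str, list] = {}
    # background fragments
    n_bg = counts[0]
    bg_chroms = rng.choice(len(sizes), size=n_bg,
                           p=np.array(list(sizes.values())) / genome_bp)
    names = list(sizes)
    for ci, chrom in enumerate(names):
        n = int(np.sum(bg_chroms == ci))
        if n == 0:
            continue
        c = rng.integers(flen // 2, sizes[chrom] - flen // 2, size=n)
        per_chrom.setdefault(chrom, []).append(
            (c - flen // 2, c + flen // 2, np.zeros(n, dtype=np.int8)))
    # site fragments: triangular kernel around the center
    for s, n in zip(active_sites, counts[1:]):
        if n == 0:
            continue
        offs = rng.triangular(-flen, 0, flen, size=n).astype(np.int64)
        c = np.clip(s.center + offs, flen // 2, sizes[s.chrom] - flen // 2)
        per_chrom.setdefault(s.chrom, []).append(
            (c - flen // 2, c + flen // 2, np.zeros(n, dtype=np.int8)))
    arrays = {
        chrom: (
            np.concatenate([x[0] for x in chunks]),
            np.concatenate([x[1] for x in chunks]),
            np.concatenate([x[2] for x in chunks]),
        )
        for chrom, chunks in per_chrom.items()
    }
    return ReadSet(sample_id, condition, replicate, arrays)


def pool_readsets(readsets: list[ReadSet], sample_id: str = "pooled") -> ReadSet:
    arrays: dict[str, list] = {}
    for rs in readsets:
        for chrom, (s, e, st) in rs.arrays.items():
            arrays.setdefault(chrom, []).append((s, e, st))
    pooled = {
        c: (
            np.concatenate([x[0] for x in chunks]),
            np.concatenate([x[1] for x in chunks]),
            np.concatenate([x[2] for x in chunks]),
        )
        for c, chunks in arrays.items()
    }
    return ReadSet(sample_id, readsets[0].condition, 0, pooled)


# ---------------------------------------------------------------------------
# truth ledger I/O and scoring

def write_truth(truth: TruthLedger, path) -> None:
    payload = {
        "config": asdict(truth.config),
        "chrom_sizes": truth.chrom_sizes,
        "genes": truth.genes.reset_index().to_dict(orient="list"),
        "sites": {
            f: [asdict(s) for s in slist] for f, slist in truth.sites.items()
        },
        "enhancers": [asdict(e) for e in truth.enhancers],
    }

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, (np.bool_,)):
            return bool(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, default=_default, sort_keys=True)


def sites_to_intervals(sites: list[PlantedSite]) -> list[GenomicInterval]:
    return [s.interval() for s in sites]


def score_against_truth(called: list[GenomicInterval],
                        planted: list[GenomicInterval]) -> dict:
    """Recall / precision of called intervals against planted ones, matching
    by >= 1 bp overlap."""
    def _hit(iv, pool):
        return any(iv.overlaps(o) for o in pool)

    n_p = len(planted)
    n_c = len(called)
    matched_planted = sum(1 for p in planted if _hit(p, called))
    matched_called = sum(1 for c in called if _hit(c, planted))
    return {
        "n_planted": n_p,
        "n_called": n_c,
        "recall": matched_planted / n_p if n_p else float("nan"),
        "precision": matched_called / n_c if n_c else float("nan"),
    }


def score_enhancers(loci, truth: TruthLedger, max_center_dist: int = 500) -> dict:
    """Recall of planted balanced loci and per-kind decoy call counts,
    matching emitted locus centers to planted centers within
    ``max_center_dist`` bp."""
    called = {}
    for l in loci:
        called.setdefault(l.chrom, []).append(l.center)
    out = {"n_called": len(loci)}
    for kind in ("balanced", "unbalanced", "too_far", "near_tts"):
        planted = [e for e in truth.enhancers if e.kind == kind]
        hit = 0
        for e in planted:
            centers = called.get(e.chrom, [])
            if any(abs(c - e.center) <= max_center_dist for c in centers):
                hit += 1
        if kind == "balanced":
            out["recall_balanced"] = hit / len(planted) if planted else float("nan")
        else:
            out[f"called_{kind}"] = hit
    return out
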