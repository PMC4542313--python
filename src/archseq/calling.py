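"""Mutation calling at hotspot codons from quality-filtered site counts.

A clone is *called* at a hotspot when every codon position has adequate
filtered coverage (>= 1,000 reads by default) and the largest site VAF
across the codon reaches the calling threshold (VAF >= 0.008, i.e. a
heterozygous clone comprising >= 1.6% of leukocytes).  The chance that
sequencing error alone produces a call is quantified by an upper-tail
binomial model: with per-base error rate e and filtered depth D, the
false-positive probability is P[X >= ceil(0.008 * D)] for
X ~ Binomial(D, e) — negligible (< 1e-5) for the error rates and depths
this assay operates at.

The canonical NPM1 mutation (a 4-bp TCTG duplication, "mutation A") is
not a substitution and gets a dedicated detector that counts insertion
operations in read alignments near the configured insertion point.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam
from scipy import stats

from .counting import (
    DEFAULT_BQ_MIN,
    DEFAULT_MQ_MIN,
    SiteCounts,
    pileup_counts,
    site_vaf,
)
from .panel import NPM1_MUTATION_A_SEQ, Hotspot, PanelConfig
from .simulate import ReadBlock, SimulatedSample


@dataclass(frozen=True)
class CallingConfig:
    """Thresholds of the calling rule.

    ``vaf_threshold`` is inclusive (a VAF exactly at threshold is called);
    ``min_depth`` applies to the *filtered* depth at every codon position;
    ``assumed_error_rate`` feeds the false-positive model attached to each
    call; ``fp_alpha`` is the bound that model is expected to stay below
    at adequate depths.  ``npm1_window`` is the +/- tolerance (bp) around
    the canonical insertion point within which a 4-bp insertion counts as
    NPM1 mutation A; ``npm1_require_seq`` additionally demands the
    inserted bases be exactly TCTG.
    """

    vaf_threshold: float = 0.008
    min_depth: int = 1000
    bq_min: int = DEFAULT_BQ_MIN
    mq_min: int = DEFAULT_MQ_MIN
    fp_alpha: float = 1e-5
    assumed_error_rate: float = 1e-3
    npm1_window: int = 5
    npm1_require_seq: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.vaf_threshold < 1.0:
            raise ValueError(f"vaf_threshold must be in (0, 1), got {self.vaf_threshold}")
        if self.min_depth < 1:
            raise ValueError(f"min_depth must be >= 1, got {self.min_depth}")


@dataclass(frozen=True)
class MutationCall:
    """Outcome of interrogating one hotspot in one sample."""

    sample_id: str
    hotspot_label: str
    position: int
    alt: str | None  # nucleotide, insertion sequence, or None if no variant reads
    vaf: float
    filtered_depth: int  # at the reported (maximizing) position
    called: bool
    adequate_coverage: bool
    fp_prob: float
    tie: bool = False

    def __post_init__(self) -> None:
        if self.called and not (self.adequate_coverage and self.vaf >= 0):
            raise ValueError("called implies adequate coverage")


def fp_probability(e: float, depth: int, vaf_threshold: float = 0.008) -> float:
    """P[error alone reaches the calling threshold] under Binomial(depth, e).

    The threshold count is ``ceil(vaf_threshold * depth)``, mirroring the
    inclusive VAF >= threshold call rule.  Monotone non-decreasing in
    ``e`` and non-increasing in ``vaf_threshold``.
    """
    if not 0.0 <= e < 1.0:
        raise ValueError(f"error rate must be in [0, 1), got {e}")
    if depth < 1:
        raise ValueError(f"depth must be >= 1, got {depth}")
    k = max(1, math.ceil(vaf_threshold * depth))
    return float(stats.binom.sf(k - 1, depth, e))


def call_hotspot(
    counts: Sequence[SiteCounts],
    cfg: CallingConfig | None = None,
    sample_id: str = "sample",
    hotspot_label: str | None = None,
) -> MutationCall:
    """Call one hotspot from its per-codon-position counts.

    Coverage is adequate only if *every* position's filtered depth meets
    ``cfg.min_depth``; the reported VAF/alt come from the position whose
    site VAF is largest (only the most-frequent variant nucleotide is
    considered; secondary alternates at a site are not called).
    """
    if not counts:
        raise ValueError("cannot call a hotspot from empty counts")
    cfg = cfg if cfg is not None else CallingConfig()
    label = hotspot_label or f"{counts[0].contig}"
    adequate = all(sc.filtered_depth >= cfg.min_depth for sc in counts)
    best = None  # (vaf, pos, alt, depth, tie)
    for sc in counts:
        if sc.filtered_depth == 0:
            continue
        res = site_vaf(sc)
        if best is None or res.vaf > best[0]:
            best = (res.vaf, sc.pos, res.top_alt, sc.filtered_depth, res.tie)
    if best is None:  # all positions empty
        sc = counts[0]
        return MutationCall(
            sample_id, label, sc.pos, None, 0.0, 0, False, False,
            fp_prob=0.0,
        )
    vaf, pos, alt, depth, tie = best
    called = bool(adequate and alt is not None and vaf >= cfg.vaf_threshold)
    fp = fp_probability(cfg.assumed_error_rate, depth, cfg.vaf_threshold) if depth else 0.0
    return MutationCall(sample_id, label, pos, alt, vaf, depth, called, adequate, fp, tie)


@dataclass(frozen=True)
class ErrorRateEstimate:
    e: float
    ci_low: float
    ci_high: float
    n_nonref: int
    pooled_depth: int


def estimate_error_rate(
    counts: Iterable[SiteCounts],
    exclude_alts: Mapping[tuple[str, int], frozenset[str] | set[str]] | None = None,
    confidence: float = 0.95,
) -> ErrorRateEstimate:
    """Pooled substitution-error estimate from mutation-negative sites.

    ``e`` is the total non-reference count divided by the pooled filtered
    depth; designated hotspot alternates (``exclude_alts``, keyed by
    (contig, pos)) are excluded from the numerator so that genuine
    low-level clones do not inflate the error estimate.  The confidence
    interval is the exact (Clopper-Pearson) binomial interval.
    """
    exclude_alts = exclude_alts or {}
    n_err = 0
    n_tot = 0
    for sc in counts:
        excluded = exclude_alts.get((sc.contig, sc.pos), frozenset())
        n_tot += sc.filtered_depth
        n_err += sum(
            c for n, c in sc.counts.items() if n != sc.ref_base and n not in excluded
        )
    if n_tot == 0:
        raise ValueError("cannot estimate error rate from zero pooled depth")
    ci = stats.binomtest(n_err, n_tot).proportion_ci(
        confidence_level=confidence, method="exact"
    )
    return ErrorRateEstimate(n_err / n_tot, float(ci.low), float(ci.high), n_err, n_tot)


def _block_npm1_tally(
    block: ReadBlock, point: int, window: int, cfg: CallingConfig
) -> tuple[int, int, dict[str, int]]:
    """(spanning, insertion, per-sequence counts) for a read block.

    Vectorised over the (dominant) non-insertion reads; only the few
    insertion-bearing rows are handled individually.
    """
    ins_rows = block.insertion_rows()
    mq_ok = block.mapq > cfg.mq_min
    hits: dict[str, int] = {}
    n_hit = 0
    if not (block.start <= point and point + 1 <= block.end):
        return 0, 0, hits
    spanning = int(mq_ok.sum())
    for row, (after, seq) in ins_rows.items():
        if not mq_ok[row]:
            continue
        if point + 1 > block.end - len(seq):  # shortened span misses the junction
            spanning -= 1
            continue
        if abs(after - point) <= window and len(seq) == len(NPM1_MUTATION_A_SEQ):
            if not cfg.npm1_require_seq or seq == NPM1_MUTATION_A_SEQ:
                n_hit += 1
                hits[seq] = hits.get(seq, 0) + 1
    return spanning, n_hit, hits


def _segment_npm1_tally(
    reads: Iterable[pysam.AlignedSegment], point: int, window: int, cfg: CallingConfig
) -> tuple[int, int, dict[str, int]]:
    spanning = 0
    n_hit = 0
    hits: dict[str, int] = {}
    for read in reads:
        if read.is_unmapped or read.mapping_quality <= cfg.mq_min:
            continue
        if not (read.reference_start + 1 <= point and point + 1 <= read.reference_end):
            continue
        spanning += 1
        ref = read.reference_start
        query = 0
        for op, length in read.cigartuples:
            if op in (0, 7, 8):
                ref += length
                query += length
            elif op == 1:
                if length == len(NPM1_MUTATION_A_SEQ) and abs(ref - point) <= window:
                    seq = read.query_sequence[query : query + length].upper()
                    if not cfg.npm1_require_seq or seq == NPM1_MUTATION_A_SEQ:
                        n_hit += 1
                        hits[seq] = hits.get(seq, 0) + 1
                query += length
            elif op in (2, 3):
                ref += length
            elif op == 4:
                query += length
    return spanning, n_hit, hits


def npm1_mutation_a_vaf(
    reads,
    hotspot: Hotspot,
    cfg: CallingConfig | None = None,
    sample_id: str = "sample",
) -> MutationCall:
    """Detect the canonical NPM1 TCTG duplication and report its VAF.

    The numerator counts mapping-quality-passing reads whose alignment
    contains a 4-bp insertion within ``cfg.npm1_window`` bp of the
    configured insertion point (inserted sequence exactly TCTG unless
    ``npm1_require_seq`` is off); the denominator is every
    quality-passing read whose alignment spans the insertion junction.
    Raises when no read spans the locus.
    """
    cfg = cfg if cfg is not None else CallingConfig()
    if not hotspot.is_indel_locus or hotspot.insertion_point is None:
        raise ValueError(f"{hotspot.label} is not configured as an indel locus")
    point = hotspot.insertion_point
    if isinstance(reads, ReadBlock):
        spanning, n_hit, hits = _block_npm1_tally(reads, point, cfg.npm1_window, cfg)
    else:
        spanning, n_hit, hits = _segment_npm1_tally(reads, point, cfg.npm1_window, cfg)
    if spanning == 0:
        raise ValueError(f"VAF undefined: no quality-passing reads span {hotspot.label}")
    vaf = n_hit / spanning
    alt = max(hits, key=hits.get) if hits else (NPM1_MUTATION_A_SEQ if cfg.npm1_require_seq else None)
    adequate = spanning >= cfg.min_depth
    called = bool(adequate and n_hit > 0 and vaf >= cfg.vaf_threshold)
    fp = fp_probability(cfg.assumed_error_rate, spanning, cfg.vaf_threshold)
    return MutationCall(
        sample_id, hotspot.label, point, alt, vaf, spanning, called, adequate, fp
    )


def vaf_to_cell_fraction(vaf: float, zygosity: str = "heterozygous") -> float:
    """Clone cell fraction implied by a VAF: 2x for heterozygous, 1x homozygous.

    A heterozygous autosomal mutation is present on one of two alleles,
    so a clone at VAF v comprises 2v of nucleated cells; at the 0.008
    calling threshold that is 1.6% of blood leukocytes.
    """
    if not 0.0 <= vaf <= 1.0:
        raise ValueError(f"VAF must be in [0, 1], got {vaf}")
    if zygosity == "heterozygous":
        if vaf > 0.5:
            raise ValueError(f"heterozygous VAF cannot exceed 0.5, got {vaf}")
        return 2.0 * vaf
    if zygosity == "homozygous":
        return vaf
    raise ValueError(f"zygosity must be 'heterozygous' or 'homozygous', got {zygosity!r}")


def call_sample(
    sample: SimulatedSample,
    cfg: CallingConfig | None = None,
) -> list[MutationCall]:
    """Run the full calling pipeline over every hotspot of one sample.

    Substitution hotspots go through pileup counting and the threshold
    rule; the indel locus goes through the NPM1 duplication detector.
    """
    cfg = cfg if cfg is not None else CallingConfig()
    calls = []
    for hs in sample.panel:
        block = sample.blocks.get(hs.label)
        if block is None:
            continue
        if hs.is_indel_locus:
            calls.append(npm1_mutation_a_vaf(block, hs, cfg, sample.sample_id))
        else:
            counts = pileup_counts(block, hs.sites(), cfg.bq_min, cfg.mq_min)
            calls.append(call_hotspot(counts, cfg, sample.sample_id, hs.label))
    return calls


def calls_frame(calls: Sequence[MutationCall]) -> pd.DataFrame:
    """Calls as a table (one row per sample x hotspot), TSV-friendly."""
    return pd.DataFrame(
        [
            {
                "sample_id": c.sample_id,
                "hotspot": c.hotspot_label,
                "position": c.position,
                "alt": c.alt,
                "vaf": c.vaf,
                "filtered_depth": c.filtered_depth,
                "called": c.called,
                "adequate_coverage": c.adequate_coverage,
                "fp_prob": c.fp_prob,
            }
            for c in calls
        ]
    )
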