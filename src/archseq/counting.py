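"""Quality-filtered per-position allele counting (pileup) and VAF derivation.

Only reads with mapping quality strictly greater than 15 and a base
quality strictly greater than 25 at the interrogated position contribute
to the counts — the strict inequalities are deliberate, so boundary
values fail.  "Sequence quality" is the per-base quality at the position,
not a read-mean, matching standard pileup semantics.  Deletions and
reference skips spanning a position are excluded and tallied, as are N
bases; insertions immediately after a position contribute no substitution
count (the indel locus has its own detector in the calling module).

The VAF at a site is the count of the most-frequent non-reference
nucleotide divided by the filtered depth.
"""
from __future__ import annotations

from collections.abc import Sequence as AbcSequence
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .panel import NUCLEOTIDES, Site
from .simulate import ReadBlock

DEFAULT_BQ_MIN = 25
DEFAULT_MQ_MIN = 15

# Filter-failure reasons, in precedence order (read-level before base-level).
FAIL_MAPPING_QUALITY = "mapping_quality"
FAIL_BASE_QUALITY = "base_quality"
FAIL_NOT_ALIGNED = "not_aligned"  # deletion or reference skip at the position
FAIL_N_BASE = "n_base"


@dataclass
class SiteCounts:
    """Nucleotide tallies at one reference position among passing reads.

    ``filtered_depth`` (the sum of ``counts``) plus the three dropped
    tallies always equals ``raw_depth``, the number of reads whose
    alignment spans the position at all.
    """

    contig: str
    pos: int  # 1-based
    ref_base: str
    counts: dict[str, int] = field(default_factory=lambda: dict.fromkeys(NUCLEOTIDES, 0))
    raw_depth: int = 0
    dropped_bq: int = 0
    dropped_mq: int = 0
    dropped_other: int = 0
    off_contig: bool = False

    @property
    def filtered_depth(self) -> int:
        return sum(self.counts.values())

    def check(self) -> None:
        total = self.filtered_depth + self.dropped_bq + self.dropped_mq + self.dropped_other
        if total != self.raw_depth:
            raise AssertionError(
                f"{self.contig}:{self.pos}: accounting broken "
                f"({total} classified vs raw_depth {self.raw_depth})"
            )


@dataclass(frozen=True)
class VafResult:
    vaf: float
    top_alt: str | None  # None when no variant reads at all
    tie: bool = False


def _query_index_at(read: pysam.AlignedSegment, pos0: int) -> tuple[int | None, str]:
    """Query offset aligned to 0-based reference position, walking the CIGAR.

    Returns ``(index, "match")`` for an aligned base, ``(None, kind)``
    when the position falls in a deletion/skip. Raises if the read does
    not overlap the position at all (caller contract).
    """
    if not (read.reference_start <= pos0 < read.reference_end):
        raise ValueError(
            f"read {read.query_name} [{read.reference_start}, {read.reference_end}) "
            f"does not overlap position {pos0}"
        )
    ref = read.reference_start
    query = 0
    for op, length in read.cigartuples:
        if op in (0, 7, 8):  # M/=/X consume both
            if ref <= pos0 < ref + length:
                return query + (pos0 - ref), "match"
            ref += length
            query += length
        elif op == 1:  # I consumes query only
            query += length
        elif op == 2:  # D consumes reference only
            if ref <= pos0 < ref + length:
                return None, "deletion"
            ref += length
        elif op == 3:  # N
            if ref <= pos0 < ref + length:
                return None, "refskip"
            ref += length
        elif op in (4, 5, 6):  # S consumes query; H/P consume neither
            if op == 4:
                query += length
        else:
            raise ValueError(f"unsupported CIGAR op {op}")
    raise ValueError(f"CIGAR of {read.query_name} ended before position {pos0}")


def read_passes_filters(
    read: pysam.AlignedSegment,
    pos: int,
    bq_min: int = DEFAULT_BQ_MIN,
    mq_min: int = DEFAULT_MQ_MIN,
) -> tuple[bool, str | None]:
    """Does this read contribute a countable base at 1-based ``pos``?

    Pass requires mapping quality > ``mq_min`` AND base quality at the
    position > ``bq_min`` (both strict) and an aligned non-N base.  On
    failure the second element names the first failing criterion
    (mapping quality is checked before the base-level criteria).
    """
    qidx, kind = _query_index_at(read, pos - 1)
    if read.mapping_quality <= mq_min:
        return False, FAIL_MAPPING_QUALITY
    if qidx is None:
        return False, FAIL_NOT_ALIGNED
    base = read.query_sequence[qidx].upper()
    if base not in NUCLEOTIDES:
        return False, FAIL_N_BASE
    if read.query_qualities[qidx] <= bq_min:
        return False, FAIL_BASE_QUALITY
    return True, None


def _empty_counts(site: Site) -> SiteCounts:
    return SiteCounts(site.contig, site.pos, site.ref_base)


def _count_block(
    block: ReadBlock, site: Site, bq_min: int, mq_min: int, out: SiteCounts
) -> None:
    if block.contig != site.contig or not block.covers(site.pos):
        return
    col = site.pos - block.start
    covered = np.ones(block.n_reads, dtype=bool)
    # Insertion-bearing reads keep the read length fixed, so their aligned
    # span is shorter: the trailing columns are not covered by them.
    for row, _after, ins_seq in block.insertions:
        if col >= block.read_length - len(ins_seq):
            covered[row] = False
    bases = block.seqs[covered, col]
    bquals = block.base_quals[covered, col]
    mapq = block.mapq[covered]
    out.raw_depth += int(covered.sum())
    mq_ok = mapq > mq_min
    out.dropped_mq += int((~mq_ok).sum())
    bq_ok = bquals > bq_min
    dropped_bq = mq_ok & ~bq_ok
    out.dropped_bq += int(dropped_bq.sum())
    keep = mq_ok & bq_ok
    kept = bases[keep]
    for nuc in NUCLEOTIDES:
        out.counts[nuc] += int((kept == ord(nuc)).sum())
    # anything kept but non-ACGT (e.g. N) is "other"
    out.dropped_other += int(keep.sum()) - sum(
        int((kept == ord(n)).sum()) for n in NUCLEOTIDES
    )


def _count_segments(
    reads: Iterable[pysam.AlignedSegment],
    by_contig: Mapping[str, list[tuple[int, SiteCounts]]],
    bq_min: int,
    mq_min: int,
) -> None:
    for read in reads:
        if read.is_unmapped:
            continue
        sites_here = by_contig.get(read.reference_name)
        if not sites_here:
            continue
        for pos, out in sites_here:
            if not (read.reference_start < pos <= read.reference_end):
                continue
            out.raw_depth += 1
            ok, reason = read_passes_filters(read, pos, bq_min, mq_min)
            if ok:
                qidx, _ = _query_index_at(read, pos - 1)
                out.counts[read.query_sequence[qidx].upper()] += 1
            elif reason == FAIL_MAPPING_QUALITY:
                out.dropped_mq += 1
            elif reason == FAIL_BASE_QUALITY:
                out.dropped_bq += 1
            else:
                out.dropped_other += 1


def pileup_counts(
    reads,
    sites: Sequence[Site],
    bq_min: int = DEFAULT_BQ_MIN,
    mq_min: int = DEFAULT_MQ_MIN,
    contig_lengths: Mapping[str, int] | None = None,
) -> list[SiteCounts]:
    """Per-site quality-filtered nucleotide counts.

    ``reads`` may be a :class:`~archseq.simulate.ReadBlock`, a sequence of
    blocks, an iterable of pysam aligned segments, or a path to a SAM/BAM
    file.  Both routes enforce the same filters and satisfy the same
    depth-accounting invariant (checked before returning).  A site beyond
    the end of its contig (when ``contig_lengths`` is supplied) comes back
    empty with ``off_contig`` set.
    """
    results = [_empty_counts(s) for s in sites]
    live: list[tuple[Site, SiteCounts]] = []
    for site, out in zip(sites, results):
        if contig_lengths is not None:
            length = contig_lengths.get(site.contig)
            if length is None or not 1 <= site.pos <= length:
                out.off_contig = True
                continue
        live.append((site, out))

    if isinstance(reads, ReadBlock):
        blocks: Sequence[ReadBlock] = [reads]
        for site, out in live:
            for block in blocks:
                _count_block(block, site, bq_min, mq_min, out)
    elif isinstance(reads, AbcSequence) and len(reads) and isinstance(reads[0], ReadBlock):
        for site, out in live:
            for block in reads:
                _count_block(block, site, bq_min, mq_min, out)
    else:
        by_contig: dict[str, list[tuple[int, SiteCounts]]] = {}
        for site, out in live:
            by_contig.setdefault(site.contig, []).append((site.pos, out))
        if isinstance(reads, (str, Path)):
            with pysam.AlignmentFile(str(reads), check_sq=False) as fh:
                _count_segments(fh, by_contig, bq_min, mq_min)
        else:
            _count_segments(reads, by_contig, bq_min, mq_min)

    for out in results:
        out.check()
    return results


def site_vaf(sc: SiteCounts) -> VafResult:
    """VAF of the most-frequent non-reference nucleotide at a site.

    Ties between variant nucleotides are broken alphabetically and
    flagged.  Undefined (raises) when the filtered depth is zero.
    """
    depth = sc.filtered_depth
    if depth == 0:
        raise ValueError(f"VAF undefined at {sc.contig}:{sc.pos}: filtered depth is 0")
    variants = {n: c for n, c in sc.counts.items() if n != sc.ref_base}
    top_count = max(variants.values(), default=0)
    if top_count == 0:
        return VafResult(0.0, None, False)
    leaders = sorted(n for n, c in variants.items() if c == top_count)
    return VafResult(top_count / depth, leaders[0], len(leaders) > 1)


def counts_frame(site_counts: Sequence[SiteCounts]) -> pd.DataFrame:
    """Tabular per-position report (one row per site), TSV-friendly."""
    rows = []
    for sc in site_counts:
        if sc.filtered_depth > 0:
            res = site_vaf(sc)
            vaf, top_alt, tie = res.vaf, res.top_alt, res.tie
        else:
            vaf, top_alt, tie = float("nan"), None, False
        flags = []
        if sc.off_contig:
            flags.append("off_contig")
        if tie:
            flags.append("tie")
        rows.append(
            {
                "contig": sc.contig,
                "pos": sc.pos,
                "ref": sc.ref_base,
                **{n: sc.counts[n] for n in NUCLEOTIDES},
                "filtered_depth": sc.filtered_depth,
                "raw_depth": sc.raw_depth,
                "dropped_bq": sc.dropped_bq,
                "dropped_mq": sc.dropped_mq,
                "dropped_other": sc.dropped_other,
                "vaf": vaf,
                "top_alt": top_alt,
                "flags": ",".join(flags),
            }
        )
    return pd.DataFrame(rows)
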