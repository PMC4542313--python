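"""Synthetic aligned reads and cohorts for ultra-deep amplicon hotspot panels.

The generator emulates the data the pipeline was built for: single-end
150-bp amplicon reads at ~1,000-10,000x depth over each hotspot codon,
with heterozygous clones injected at variant allele fractions (VAFs) of
0.008-0.45, i.i.d. per-base substitution error (default 1e-3), and base /
mapping qualities drawn from two-point distributions straddling the
pipeline's filter bounds (so filter behaviour is exactly testable).

Reads are emitted pre-aligned.  The native container is :class:`ReadBlock`
— one amplicon's reads as numpy matrices, convertible losslessly to
coordinate-sorted SAM via pysam — because at cohort scale (thousands of
samples x 15 amplicons x thousands of reads) per-read Python objects are
the bottleneck, not the statistics.

Cohort simulation layers a clone-kinetics model on top: an *early-drift*
mutation class (e.g. DNMT3A R882) is acquired stochastically through life
and its clone expands steadily, while an *age-gated* class (spliceosome
genes SRSF2/SF3B1) confers no advantage before a threshold age (default
70), after which clones appear and expand — so simulated cohorts show
rising prevalence with age and a hard age gate for spliceosome clones.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .panel import (
    DEFAULT_CONTIG_LENGTH,
    NPM1_MUTATION_A_SEQ,
    Hotspot,
    PanelConfig,
    default_panel,
    reference_sequences,
)

DEFAULT_READ_LENGTH = 150

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_INDEX[_b] = _i


class SimulationConfigError(ValueError):
    """Invalid simulation specification."""


@dataclass(frozen=True)
class ErrorModel:
    """Sequencing-noise model: substitution errors plus quality strata.

    ``sub_error_rate`` is the i.i.d. per-base probability that a read base
    differs from the template (uniform over the three other nucleotides).
    Base and mapping qualities are two-point: a fraction of bases/reads is
    drawn at the passing level, the remainder at the failing level, chosen
    to straddle the pipeline's default filter bounds (base quality > 25,
    mapping quality > 15).
    """

    sub_error_rate: float = 1e-3
    bq_pass_fraction: float = 0.9
    mq_pass_fraction: float = 0.95
    bq_levels: tuple[int, int] = (30, 20)  # (pass, fail)
    mq_levels: tuple[int, int] = (60, 10)

    def __post_init__(self) -> None:
        if not 0.0 <= self.sub_error_rate <= 0.05:
            raise SimulationConfigError(
                f"sub_error_rate must be in [0, 0.05], got {self.sub_error_rate}"
            )
        for name in ("bq_pass_fraction", "mq_pass_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimulationConfigError(f"{name} must be in [0, 1], got {v}")


@dataclass(frozen=True)
class CloneSpec:
    """One hemopoietic clone: a hotspot, an alternate allele, a true VAF.

    ``alt`` is a single nucleotide for substitutions, or the inserted
    sequence (e.g. ``TCTG``) at the indel locus.  ``position`` is the
    1-based genomic coordinate of the substituted base (ignored for
    insertions, which use the hotspot's configured insertion point).
    ``true_vaf`` is capped at 0.5 — the heterozygous-autosomal assumption
    — unless ``homozygous`` is set.
    """

    hotspot: Hotspot
    alt: str
    true_vaf: float
    position: int | None = None
    homozygous: bool = False

    def __post_init__(self) -> None:
        cap = 1.0 if self.homozygous else 0.5
        if not 0.0 <= self.true_vaf <= cap:
            raise SimulationConfigError(
                f"true_vaf {self.true_vaf} outside [0, {cap}] for {self.hotspot.label}"
            )
        if self.is_insertion:
            if not self.hotspot.is_indel_locus:
                raise SimulationConfigError(
                    f"insertion clone at non-indel locus {self.hotspot.label}"
                )
        else:
            if self.position is None:
                raise SimulationConfigError("substitution clone needs a position")
            if self.position not in self.hotspot.positions:
                raise SimulationConfigError(
                    f"position {self.position} is not a codon position of {self.hotspot.label}"
                )
            ref = self.hotspot.ref_bases[self.hotspot.positions.index(self.position)]
            if self.alt == ref:
                raise SimulationConfigError(
                    f"alt {self.alt} equals reference at {self.hotspot.label}:{self.position}"
                )

    @property
    def is_insertion(self) -> bool:
        return len(self.alt) > 1


@dataclass(frozen=True)
class SimSampleSpec:
    """One simulated individual: identity, age, clones, target depth, seed."""

    sample_id: str
    age_years: int
    clones: tuple[CloneSpec, ...] = ()
    depth: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise SimulationConfigError(f"depth must be >= 1, got {self.depth}")


@dataclass
class ReadBlock:
    """All reads of one amplicon, reference-aligned, as numpy matrices.

    Rows are reads; columns are reference offsets from ``start`` (1-based
    leftmost aligned position).  Insertion-bearing reads are stored
    ref-aligned with the inserted bases recorded separately in
    ``insertions`` as ``(row, after_pos, sequence)``; on conversion to SAM
    the inserted bases are spliced into the query and the read's reference
    span shrinks accordingly (fixed read length).
    """

    contig: str
    start: int
    seqs: np.ndarray        # (n, L) uint8 ASCII
    base_quals: np.ndarray  # (n, L) uint8
    mapq: np.ndarray        # (n,) uint8
    insertions: list[tuple[int, int, str]] = field(default_factory=list)

    @property
    def n_reads(self) -> int:
        return int(self.seqs.shape[0])

    @property
    def read_length(self) -> int:
        return int(self.seqs.shape[1])

    @property
    def end(self) -> int:
        """1-based rightmost reference position covered by non-insertion reads."""
        return self.start + self.read_length - 1

    def covers(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def insertion_rows(self) -> dict[int, tuple[int, str]]:
        return {row: (after, seq) for row, after, seq in self.insertions}

    def to_alignments(
        self, header: pysam.AlignmentHeader, name_prefix: str = "read"
    ) -> list[pysam.AlignedSegment]:
        """Materialise pysam records (coordinate order is preserved)."""
        tid = header.get_tid(self.contig)
        if tid < 0:
            raise SimulationConfigError(f"contig {self.contig} not in SAM header")
        L = self.read_length
        ins_rows = self.insertion_rows()
        out = []
        for i in range(self.n_reads):
            a = pysam.AlignedSegment(header)
            a.query_name = f"{name_prefix}:{self.contig}:{i}"
            a.reference_id = tid
            a.reference_start = self.start - 1
            a.mapping_quality = int(self.mapq[i])
            a.flag = 0
            if i in ins_rows:
                after, ins_seq = ins_rows[i]
                k = len(ins_seq)
                nleft = after - self.start + 1  # aligned bases before the insertion
                seq = self.seqs[i].tobytes().decode()
                quals = self.base_quals[i]
                a.query_sequence = seq[:nleft] + ins_seq + seq[nleft : L - k]
                a.cigartuples = [(0, nleft), (1, k), (0, L - k - nleft)]
                ins_q = np.full(k, int(quals[nleft - 1]) if nleft else 30, dtype=np.uint8)
                a.query_qualities = np.concatenate(
                    [quals[:nleft], ins_q, quals[nleft : L - k]]
                ).tolist()
            else:
                a.query_sequence = self.seqs[i].tobytes().decode()
                a.cigartuples = [(0, L)]
                a.query_qualities = self.base_quals[i].tolist()
            out.append(a)
        return out


@dataclass
class SimulatedSample:
    """Per-hotspot read blocks for one simulated individual."""

    sample_id: str
    blocks: dict[str, ReadBlock]  # hotspot label -> reads
    panel: PanelConfig

    def header(self, contig_length: int = DEFAULT_CONTIG_LENGTH) -> pysam.AlignmentHeader:
        return sam_header(self.panel, contig_length)

    def write_sam(self, path: str | Path, contig_length: int = DEFAULT_CONTIG_LENGTH) -> Path:
        """Write all reads as a coordinate-sorted SAM file."""
        path = Path(path)
        header = self.header(contig_length)
        order = {c: i for i, c in enumerate(header.references)}
        blocks = sorted(self.blocks.values(), key=lambda b: (order[b.contig], b.start))
        with pysam.AlignmentFile(str(path), "w", header=header) as fh:
            for block in blocks:
                for rec in block.to_alignments(header, name_prefix=self.sample_id):
                    fh.write(rec)
        return path


def sam_header(
    panel: PanelConfig, contig_length: int = DEFAULT_CONTIG_LENGTH
) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": c, "LN": contig_length} for c in panel.contigs],
        }
    )


def amplicon_start(hotspot: Hotspot, read_length: int = DEFAULT_READ_LENGTH) -> int:
    """Fixed amplicon start placing the codon mid-read (fully spanned)."""
    start = hotspot.positions[0] - (read_length // 2 - 1)
    return max(1, start)


def _inject_errors(rng: np.random.Generator, seqs: np.ndarray, rate: float) -> None:
    if rate <= 0:
        return
    mask = rng.random(seqs.shape) < rate
    n_err = int(mask.sum())
    if n_err == 0:
        return
    idx = _BASE_INDEX[seqs[mask]]
    shift = rng.integers(1, 4, size=n_err)
    seqs[mask] = _BASES[(idx + shift) % 4]


def _draw_qualities(
    rng: np.random.Generator, shape, pass_fraction: float, levels: tuple[int, int]
) -> np.ndarray:
    hi, lo = levels
    return np.where(rng.random(shape) < pass_fraction, hi, lo).astype(np.uint8)


def _simulate_block(
    rng: np.random.Generator,
    hotspot: Hotspot,
    refseq: str,
    depth: int,
    err: ErrorModel,
    clones: Sequence[CloneSpec],
    read_length: int,
) -> ReadBlock:
    start = amplicon_start(hotspot, read_length)
    template = np.frombuffer(
        refseq[start - 1 : start - 1 + read_length].encode(), dtype=np.uint8
    ).copy()
    seqs = np.tile(template, (depth, 1))
    insertions: list[tuple[int, int, str]] = []
    for clone in clones:
        n_var = int(rng.binomial(depth, clone.true_vaf))
        rows = rng.choice(depth, size=n_var, replace=False)
        if clone.is_insertion:
            point = hotspot.insertion_point
            assert point is not None
            insertions.extend((int(r), point, clone.alt) for r in rows)
        else:
            col = clone.position - start
            seqs[rows, col] = ord(clone.alt)
    _inject_errors(rng, seqs, err.sub_error_rate)
    base_quals = _draw_qualities(rng, seqs.shape, err.bq_pass_fraction, err.bq_levels)
    mapq = _draw_qualities(rng, depth, err.mq_pass_fraction, err.mq_levels)
    return ReadBlock(hotspot.contig, start, seqs, base_quals, mapq, insertions)


def simulate_reads(
    spec: SimSampleSpec,
    panel: PanelConfig | None = None,
    err: ErrorModel | None = None,
    read_length: int = DEFAULT_READ_LENGTH,
    contig_length: int = DEFAULT_CONTIG_LENGTH,
) -> SimulatedSample:
    """Simulate one sample's amplicon reads over every panel hotspot.

    For each clone, the number of variant-carrying reads is drawn
    Binomial(depth, true VAF) *before* sequencing error; errors are then
    injected i.i.d. per base.  Output is fully determined by ``spec.seed``.
    """
    panel = panel if panel is not None else default_panel()
    err = err if err is not None else ErrorModel()
    labels = {hs.label for hs in panel}
    for clone in spec.clones:
        if clone.hotspot.label not in labels:
            raise SimulationConfigError(
                f"clone hotspot {clone.hotspot.label!r} is not in panel {panel.name!r}"
            )
    refs = reference_sequences(panel, contig_length)
    seeds = np.random.SeedSequence(spec.seed).spawn(len(panel))
    blocks: dict[str, ReadBlock] = {}
    for hs, child in zip(panel, seeds):
        rng = np.random.default_rng(child)
        here = [c for c in spec.clones if c.hotspot.label == hs.label]
        blocks[hs.label] = _simulate_block(
            rng, hs, refs[hs.contig], spec.depth, err, here, read_length
        )
    return SimulatedSample(spec.sample_id, blocks, panel)


def simulate_npm1_reads(
    n_total: int,
    n_mut: int,
    err: ErrorModel | None = None,
    seed: int = 0,
    panel: PanelConfig | None = None,
    read_length: int = DEFAULT_READ_LENGTH,
    contig_length: int = DEFAULT_CONTIG_LENGTH,
) -> ReadBlock:
    """Reads at the NPM1 locus with an exact number of TCTG-duplication reads.

    Exactly ``n_mut`` of the ``n_total`` reads carry the canonical 4-bp
    TCTG insertion (encoded as an insertion CIGAR operation on SAM
    export); the rest match the reference up to sequencing error.
    """
    if n_mut > n_total:
        raise SimulationConfigError(f"n_mut {n_mut} exceeds n_total {n_total}")
    err = err if err is not None else ErrorModel()
    panel = panel if panel is not None else default_panel()
    loci = panel.indel_loci
    if not loci:
        raise SimulationConfigError(f"panel {panel.name!r} has no indel locus")
    hs = loci[0]
    refs = reference_sequences(panel, contig_length)
    rng = np.random.default_rng(seed)
    block = _simulate_block(rng, hs, refs[hs.contig], n_total, err, [], read_length)
    rows = rng.choice(n_total, size=n_mut, replace=False)
    block.insertions = [
        (int(r), int(hs.insertion_point), NPM1_MUTATION_A_SEQ) for r in sorted(rows)
    ]
    return block


# ---------------------------------------------------------------------------
# Clone kinetics and whole-cohort simulation
# ---------------------------------------------------------------------------

EARLY_DRIFT = "early-drift"
AGE_GATED = "age-gated"

#: Genes whose clones are gated to old age in the default kinetics.
SPLICEOSOME_GENES = frozenset({"SRSF2", "SF3B1"})


def _logistic(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


@dataclass(frozen=True)
class KineticsModel:
    """Age law of one mutation class: when clones appear and how they grow.

    ``acquisition_rate`` is the per-year increment of the probability that
    an individual carries a detectable clone of this class, accruing from
    ``acquisition_age`` (early-drift) or from ``onset_gate_age``
    (age-gated; zero prevalence below the gate, default 70).
    ``growth_rate`` is the per-year increment of the clone cell fraction
    on the logit scale, setting how large clones can have grown by a given
    age; a carrier's VAF is drawn log-uniformly between the detection-scale
    floor (0.008) and the age-dependent ceiling (capped at 0.45).
    """

    class_label: str
    hotspot_label: str
    alt: str
    codon_offset: int  # 0..2: which codon base carries the substitution
    acquisition_rate: float
    acquisition_age: float = 20.0
    growth_rate: float = 0.25
    onset_gate_age: float | None = None
    init_cell_fraction: float = 0.02
    vaf_floor: float = 0.008

    def __post_init__(self) -> None:
        if self.class_label not in (EARLY_DRIFT, AGE_GATED):
            raise SimulationConfigError(f"unknown kinetics class {self.class_label!r}")
        if self.class_label == AGE_GATED and self.onset_gate_age is None:
            object.__setattr__(self, "onset_gate_age", 70.0)

    @property
    def onset_age(self) -> float:
        if self.class_label == AGE_GATED:
            return float(self.onset_gate_age)
        return self.acquisition_age

    def prevalence(self, age: float) -> float:
        """Probability that an individual of this age carries a clone."""
        years = age - self.onset_age
        if years < 0 or (self.class_label == AGE_GATED and age < self.onset_gate_age):
            return 0.0
        return min(0.9, self.acquisition_rate * years)

    def vaf_ceiling(self, age: float) -> float:
        """Largest clone VAF attainable by this age (non-decreasing in age)."""
        years = max(0.0, age - self.onset_age)
        f = _logistic(
            math.log(self.init_cell_fraction / (1 - self.init_cell_fraction))
            + self.growth_rate * years
        )
        return min(0.45, max(1.5 * self.vaf_floor, f / 2.0))

    def sample_vaf(self, rng: np.random.Generator, age: float) -> float:
        lo, hi = self.vaf_floor, self.vaf_ceiling(age)
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def default_kinetics() -> dict[str, KineticsModel]:
    """Study-like kinetics for the default panel.

    Early-drift laws are anchored to the observed rise of DNMT3A R882
    carriage from ~0.2% in the youngest bin to ~3.1% in the ninth decade;
    the age-gated spliceosome laws jointly rise from ~2% shortly after the
    70-year gate to ~9% in the tenth decade.  Rare IDH/RAS classes are
    included at low flat rates.
    """
    return {
        "DNMT3A_R882H": KineticsModel(
            EARLY_DRIFT, "DNMT3A R882", "A", 1, acquisition_rate=5e-4
        ),
        "JAK2_V617F": KineticsModel(
            EARLY_DRIFT, "JAK2 V617", "T", 0, acquisition_rate=3e-4
        ),
        "SRSF2_P95L": KineticsModel(
            AGE_GATED, "SRSF2 P95", "T", 1, acquisition_rate=2e-3, growth_rate=0.5
        ),
        "SF3B1_K666N": KineticsModel(
            AGE_GATED, "SF3B1 K666", "T", 2, acquisition_rate=1e-3, growth_rate=0.5
        ),
        "SF3B1_K700E": KineticsModel(
            AGE_GATED, "SF3B1 K700", "G", 0, acquisition_rate=1e-3, growth_rate=0.5
        ),
        "IDH2_R140Q": KineticsModel(
            EARLY_DRIFT, "IDH2 R140", "A", 1, acquisition_rate=3e-5, acquisition_age=40
        ),
        "NRAS_G12D": KineticsModel(
            EARLY_DRIFT, "NRAS G12", "A", 1, acquisition_rate=5e-5, acquisition_age=40
        ),
        "KRAS_G12S": KineticsModel(
            EARLY_DRIFT, "KRAS G12", "A", 0, acquisition_rate=5e-5, acquisition_age=40
        ),
    }


def default_age_law() -> dict:
    """Two-arm age mixture echoing the study cohorts: a broad donor arm
    aged 17-70 plus an elderly arm aged 60-98."""
    return {
        "kind": "mixture",
        "weights": [0.73, 0.27],
        "components": [
            {"kind": "uniform", "low": 17, "high": 70},
            {"kind": "uniform", "low": 60, "high": 98},
        ],
    }


def _age_sampler(spec: Mapping) -> Callable[[np.random.Generator, int], np.ndarray]:
    if not isinstance(spec, Mapping) or "kind" not in spec:
        raise SimulationConfigError(f"age law must be a mapping with a 'kind': {spec!r}")
    kind = spec["kind"]
    if kind == "uniform":
        low, high = int(spec["low"]), int(spec["high"])
        if high < low:
            raise SimulationConfigError(f"uniform age law with high < low: {spec!r}")
        return lambda rng, n: rng.integers(low, high + 1, size=n)
    if kind == "mixture":
        comps = [_age_sampler(c) for c in spec["components"]]
        weights = np.asarray(spec["weights"], dtype=float)
        if len(weights) != len(comps) or weights.sum() <= 0 or (weights < 0).any():
            raise SimulationConfigError(f"bad mixture weights: {spec!r}")
        weights = weights / weights.sum()

        def draw(rng: np.random.Generator, n: int) -> np.ndarray:
            which = rng.choice(len(comps), size=n, p=weights)
            ages = np.empty(n, dtype=int)
            for i, comp in enumerate(comps):
                idx = np.nonzero(which == i)[0]
                ages[idx] = comp(rng, len(idx))
            return ages

        return draw
    raise SimulationConfigError(f"unknown age law kind {kind!r}")


def _clone_from_kinetics(
    model: KineticsModel, panel: PanelConfig, vaf: float
) -> CloneSpec:
    hs = panel.get(model.hotspot_label)
    if hs.is_indel_locus and len(model.alt) > 1:
        return CloneSpec(hs, model.alt, vaf)
    return CloneSpec(hs, model.alt, vaf, position=hs.positions[model.codon_offset])


@dataclass
class SimulatedCohort:
    """Truth table plus deterministic per-sample read regeneration.

    ``table`` has one row per individual: sample id, age, per-sample seed,
    and the truth columns (clone class, hotspot, alt, true VAF, joined by
    ``;`` for multi-clone individuals).  Reads are regenerated lazily from
    the stored seeds so multi-thousand cohorts stay cheap to hold.
    """

    table: pd.DataFrame
    clone_truth: pd.DataFrame  # one row per true clone
    panel: PanelConfig
    err: ErrorModel
    depth: int
    kinetics: dict[str, KineticsModel]

    def sample_spec(self, sample_id: str) -> SimSampleSpec:
        row = self.table.loc[self.table.sample_id == sample_id]
        if row.empty:
            raise KeyError(sample_id)
        row = row.iloc[0]
        clones = []
        for t in self.clone_truth.itertuples(index=False):
            if t.sample_id == sample_id:
                clones.append(
                    _clone_from_kinetics(self.kinetics[t.clone_class], self.panel, t.true_vaf)
                )
        return SimSampleSpec(
            sample_id=sample_id,
            age_years=int(row.age_years),
            clones=tuple(clones),
            depth=self.depth,
            seed=int(row.seed),
        )

    def reads_for(self, sample_id: str) -> SimulatedSample:
        return simulate_reads(self.sample_spec(sample_id), self.panel, self.err)

    def iter_samples(self) -> Iterator[SimulatedSample]:
        for sid in self.table.sample_id:
            yield self.reads_for(sid)

    def write_table(self, path: str | Path) -> Path:
        path = Path(path)
        self.table.to_csv(path, sep="\t", index=False)
        return path


def simulate_cohort(
    n: int,
    age_law: Mapping | None = None,
    kinetics: Mapping[str, KineticsModel] | None = None,
    err: ErrorModel | None = None,
    seed: int = 0,
    depth: int = 5000,
    panel: PanelConfig | None = None,
) -> SimulatedCohort:
    """Simulate a cohort: ages, age-dependent clone carriage, read seeds.

    Each individual draws an age from ``age_law``, then independently for
    each kinetics class carries a clone with the class's age-dependent
    probability; carriers draw a VAF between the detection floor and the
    class's age-dependent ceiling.  Age-gated classes (the spliceosome
    genes in the default kinetics) contribute nothing below their gate
    age.  Reads are regenerated on demand via :meth:`SimulatedCohort.reads_for`.
    """
    if n < 1:
        raise SimulationConfigError(f"cohort size must be >= 1, got {n}")
    panel = panel if panel is not None else default_panel()
    err = err if err is not None else ErrorModel()
    kinetics = dict(kinetics) if kinetics is not None else default_kinetics()
    for name, model in kinetics.items():
        try:
            panel.get(model.hotspot_label)
        except KeyError as exc:
            raise SimulationConfigError(
                f"kinetics class {name!r} targets {model.hotspot_label!r}, "
                f"absent from panel {panel.name!r}"
            ) from exc
    age_law = age_law if age_law is not None else default_age_law()
    draw_ages = _age_sampler(age_law)

    rng = np.random.default_rng(seed)
    ages = draw_ages(rng, n)
    sample_seeds = rng.integers(0, 2**31 - 1, size=n)
    rows = []
    truth_rows = []
    for i in range(n):
        sid = f"S{i:05d}"
        age = int(ages[i])
        clone_descr = []
        for name, model in kinetics.items():
            if rng.random() < model.prevalence(age):
                vaf = model.sample_vaf(rng, age)
                truth_rows.append(
                    {
                        "sample_id": sid,
                        "clone_class": name,
                        "hotspot": model.hotspot_label,
                        "alt": model.alt,
                        "true_vaf": vaf,
                        "age_years": age,
                        "kinetics": model.class_label,
                    }
                )
                clone_descr.append(f"{model.hotspot_label}:{model.alt}:{vaf:.4f}")
        rows.append(
            {
                "sample_id": sid,
                "age_years": age,
                "seed": int(sample_seeds[i]),
                "n_clones": len(clone_descr),
                "clones": ";".join(clone_descr),
            }
        )
    table = pd.DataFrame(rows)
    truth = pd.DataFrame(
        truth_rows,
        columns=["sample_id", "clone_class", "hotspot", "alt", "true_vaf", "age_years", "kinetics"],
    )
    return SimulatedCohort(table, truth, panel, err, depth, dict(kinetics))
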