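"""Hotspot panel definition, validation and synthetic reference sequences.

A *hotspot* is one recurrently mutated codon (e.g. ``DNMT3A R882``)
interrogated at its three constituent nucleotide positions.  The default
panel covers the 15 myeloid-leukemia hotspots used throughout this package;
each lives on its own synthetic 300-bp contig so that the full pipeline —
simulation, pileup counting, calling — runs without any external reference.
Users working from real alignments can supply their own panel config with
genome coordinates.
"""
from __future__ import annotations

import importlib.resources
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import yaml

NUCLEOTIDES = ("A", "C", "G", "T")

#: Inserted sequence of the canonical NPM1 mutation A (a 4-bp duplication).
NPM1_MUTATION_A_SEQ = "TCTG"

DEFAULT_CONTIG_LENGTH = 300


class PanelError(ValueError):
    """Malformed or invalid panel configuration."""


@dataclass(frozen=True)
class Site:
    """One interrogated reference position."""

    contig: str
    pos: int  # 1-based
    ref_base: str


@dataclass(frozen=True)
class Hotspot:
    """One interrogated codon.

    ``positions`` are the 1-based genomic coordinates of the three codon
    bases, strictly increasing and contiguous; ``ref_bases`` are the
    corresponding reference nucleotides (coding-strand as configured).
    ``interrogated_alts`` optionally restricts which alternates are counted
    per position; by default every non-reference nucleotide at every codon
    position is interrogated.  ``is_indel_locus`` marks the single locus
    (NPM1 L287) whose canonical mutation is a 4-bp duplication rather than
    a substitution; ``insertion_point`` is the 1-based position immediately
    after which the duplicated unit is inserted.
    """

    gene: str
    codon_label: str
    contig: str
    strand: str
    positions: tuple[int, int, int]
    ref_bases: str
    interrogated_alts: Mapping[int, frozenset[str]] | None = None
    is_indel_locus: bool = False
    insertion_point: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise PanelError(f"{self.label}: strand must be '+' or '-', got {self.strand!r}")
        if len(self.positions) != 3:
            raise PanelError(f"{self.label}: a codon has exactly 3 positions")
        p = self.positions
        if not (p[0] + 1 == p[1] and p[1] + 1 == p[2]):
            raise PanelError(
                f"{self.label}: codon positions must be strictly increasing and "
                f"contiguous, got {p}"
            )
        if len(self.ref_bases) != 3 or any(b not in NUCLEOTIDES for b in self.ref_bases):
            raise PanelError(f"{self.label}: ref_bases must be 3 of A/C/G/T, got {self.ref_bases!r}")
        if self.is_indel_locus and self.insertion_point is None:
            raise PanelError(f"{self.label}: indel locus needs an insertion_point")

    @property
    def label(self) -> str:
        return f"{self.gene} {self.codon_label}"

    def sites(self) -> list[Site]:
        return [
            Site(self.contig, pos, ref)
            for pos, ref in zip(self.positions, self.ref_bases)
        ]


@dataclass
class PanelConfig:
    """A named, validated collection of hotspots."""

    name: str
    hotspots: list[Hotspot] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for hs in self.hotspots:
            key = (hs.gene, hs.codon_label)
            if key in seen:
                raise PanelError(f"duplicate hotspot entry: {hs.label}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.hotspots)

    def __iter__(self) -> Iterator[Hotspot]:
        return iter(self.hotspots)

    def get(self, label: str) -> Hotspot:
        for hs in self.hotspots:
            if hs.label == label:
                return hs
        raise KeyError(f"hotspot {label!r} not in panel {self.name!r}")

    @property
    def contigs(self) -> list[str]:
        return [hs.contig for hs in self.hotspots]

    def sites(self) -> list[Site]:
        return [s for hs in self.hotspots for s in hs.sites()]

    @property
    def indel_loci(self) -> list[Hotspot]:
        return [hs for hs in self.hotspots if hs.is_indel_locus]


def _parse_hotspot(entry: Mapping, index: int) -> Hotspot:
    required = ("gene", "codon_label", "contig", "strand", "positions", "ref_bases")
    missing = [k for k in required if k not in entry]
    if missing:
        raise PanelError(f"hotspot entry #{index + 1} is missing fields: {', '.join(missing)}")
    alts = entry.get("interrogated_alts")
    if alts is not None:
        alts = {int(pos): frozenset(str(a).upper() for a in bases) for pos, bases in alts.items()}
    try:
        return Hotspot(
            gene=str(entry["gene"]),
            codon_label=str(entry["codon_label"]),
            contig=str(entry["contig"]),
            strand=str(entry["strand"]),
            positions=tuple(int(p) for p in entry["positions"]),
            ref_bases=str(entry["ref_bases"]).upper(),
            interrogated_alts=alts,
            is_indel_locus=bool(entry.get("is_indel_locus", False)),
            insertion_point=entry.get("insertion_point"),
        )
    except PanelError:
        raise
    except (TypeError, ValueError) as exc:
        raise PanelError(f"hotspot entry #{index + 1} is malformed: {exc}") from exc


def load_panel(path: str | Path) -> PanelConfig:
    """Load and validate a panel configuration from YAML or JSON.

    Raises :class:`PanelError` naming the offending entry on malformed
    input, duplicate (gene, codon) pairs, or codon-position violations.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    try:
        raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    except (json.JSONDecodeError, yaml.YAMLError) as exc:
        raise PanelError(f"cannot parse panel config {path}: {exc}") from exc
    if not isinstance(raw, Mapping) or "hotspots" not in raw:
        raise PanelError(f"panel config {path} must be a mapping with a 'hotspots' list")
    hotspots = [_parse_hotspot(e, i) for i, e in enumerate(raw["hotspots"])]
    return PanelConfig(name=str(raw.get("name", path.stem)), hotspots=hotspots)


def default_panel() -> PanelConfig:
    """The shipped 15-hotspot myeloid panel on synthetic contigs."""
    ref = importlib.resources.files("archseq.data") / "default_panel.yaml"
    with importlib.resources.as_file(ref) as path:
        return load_panel(path)


def reference_sequences(
    panel: PanelConfig, contig_length: int = DEFAULT_CONTIG_LENGTH
) -> dict[str, str]:
    """Deterministic synthetic reference sequence for every panel contig.

    Background bases are drawn from a generator seeded by a CRC of the
    contig name (stable across runs and platforms); the configured codon
    bases are then written at the hotspot positions, and for the indel
    locus the 4 bp ending at ``insertion_point`` are set to the duplicated
    unit so a true tandem duplication can be simulated.
    """
    refs: dict[str, str] = {}
    for hs in panel:
        if hs.positions[-1] > contig_length:
            raise PanelError(f"{hs.label}: positions exceed contig length {contig_length}")
        rng = np.random.default_rng(zlib.crc32(hs.contig.encode()))
        seq = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=contig_length)
        for pos, base in zip(hs.positions, hs.ref_bases):
            seq[pos - 1] = ord(base)
        if hs.is_indel_locus and hs.insertion_point is not None:
            start = hs.insertion_point - len(NPM1_MUTATION_A_SEQ)
            seq[start : hs.insertion_point] = np.frombuffer(
                NPM1_MUTATION_A_SEQ.encode(), dtype=np.uint8
            )
        refs[hs.contig] = seq.tobytes().decode()
    return refs


def write_reference_fasta(
    panel: PanelConfig, path: str | Path, contig_length: int = DEFAULT_CONTIG_LENGTH
) -> Path:
    """Write the synthetic panel reference as an uncompressed FASTA."""
    path = Path(path)
    with open(path, "w") as fh:
        for contig, seq in reference_sequences(panel, contig_length).items():
            fh.write(f">{contig}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
    return path
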