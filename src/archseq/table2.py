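"""Packaged fixture of the study's 112 clonal mutations.

Each record is one printed row of the published mutation table: hotspot,
protein change, VAF (as a percentage, as printed), carrier age, and an
optional symbol marking mutations found in the same individual.  Symbols
are transliterated to ASCII (``*``, ``**``, ``+``, ``++``, ``#``, ``##``).
"""
from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import pandas as pd

FIXTURE_NAME = "table2_clonal_mutations.tsv"

#: Age range covered by the packaged fixture.
FIXTURE_AGE_RANGE = (17, 98)


@dataclass(frozen=True)
class ClonalMutationRecord:
    """One clonal mutation identified in one individual."""

    gene: str
    hotspot_label: str
    protein_change: str
    vaf_percent: float
    age_years: int
    sample_symbol: str | None = None

    def __post_init__(self) -> None:
        if not self.vaf_percent > 0:
            raise ValueError(f"vaf_percent must be > 0, got {self.vaf_percent}")
        if self.age_years < 0:
            raise ValueError(f"age_years must be non-negative, got {self.age_years}")

    @property
    def vaf_fraction(self) -> float:
        """VAF as a fraction in (0, 1]; the table stores percent as printed."""
        return self.vaf_percent / 100.0


def load_table2_fixture() -> list[ClonalMutationRecord]:
    """Load the packaged 112-record clonal mutation table.

    Raises :class:`FileNotFoundError` if the fixture resource is missing
    from the installation.
    """
    ref = importlib.resources.files("archseq.data") / FIXTURE_NAME
    if not ref.is_file():
        raise FileNotFoundError(f"packaged fixture {FIXTURE_NAME} not found")
    with ref.open("r") as fh:
        df = pd.read_csv(fh, sep="\t", dtype={"symbol": "string"})
    records = []
    for row in df.itertuples(index=False):
        symbol = None if pd.isna(row.symbol) else str(row.symbol)
        records.append(
            ClonalMutationRecord(
                gene=row.gene,
                hotspot_label=row.hotspot,
                protein_change=row.protein_change,
                vaf_percent=float(row.vaf_percent),
                age_years=int(row.age),
                sample_symbol=symbol,
            )
        )
    lo, hi = FIXTURE_AGE_RANGE
    bad = [r for r in records if not lo <= r.age_years <= hi]
    if bad:
        raise ValueError(f"fixture ages outside [{lo}, {hi}]: {bad}")
    return records


def fixture_frame() -> pd.DataFrame:
    """The fixture as a DataFrame (one row per clonal mutation)."""
    return pd.DataFrame([r.__dict__ for r in load_table2_fixture()])
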