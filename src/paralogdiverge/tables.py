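"""Typed tabular inputs: fluctuation-assay cultures and tetrad counts.

One tabular dialect is used throughout: tab-separated, UTF-8, with a
header row.  Readers validate domain invariants (non-negative counts,
revertants never exceeding viable cells) and writers round-trip exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import ValidationError

CULTURE_COLUMNS = ["strain", "batch", "revertants", "viable"]
TETRAD_COLUMNS = ["genotype", "TT", "PD"]


@dataclass
class CultureTable:
    """Per-culture revertant and viable-cell counts, grouped by strain."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing = set(CULTURE_COLUMNS) - set(df.columns)
        if missing:
            raise ValidationError(f"culture table missing columns {sorted(missing)}")
        if (df["revertants"] < 0).any():
            raise ValidationError("negative revertant count")
        if (df["viable"] <= 0).any():
            raise ValidationError("viable counts must be positive")
        if (df["revertants"] > df["viable"]).any():
            raise ValidationError("revertants exceed viable cells")
        self.data = df.reset_index(drop=True)

    def strains(self) -> list[str]:
        return list(dict.fromkeys(self.data["strain"]))

    def for_strain(self, strain: str) -> pd.DataFrame:
        sub = self.data[self.data["strain"] == strain]
        if sub.empty:
            raise KeyError(f"no cultures for strain {strain!r}")
        return sub


@dataclass
class TetradTable:
    """Tetratype / parental-ditype counts per genotype."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing = set(TETRAD_COLUMNS) - set(df.columns)
        if missing:
            raise ValidationError(f"tetrad table missing columns {sorted(missing)}")
        if (df["TT"] < 0).any() or (df["PD"] < 0).any():
            raise ValidationError("negative tetrad count")
        if ((df["TT"] + df["PD"]) <= 0).any():
            raise ValidationError("each genotype needs at least one tetrad")
        self.data = df.reset_index(drop=True)

    def counts(self, genotype: str) -> tuple[int, int]:
        sub = self.data[self.data["genotype"] == genotype]
        if sub.empty:
            raise KeyError(f"no counts for genotype {genotype!r}")
        return int(sub["TT"].sum()), int(sub["PD"].sum())

    @property
    def n(self) -> pd.Series:
        return self.data["TT"] + self.data["PD"]


def read_table(path) -> pd.DataFrame:
    """Read a generic TSV with header."""
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_culture_table(path) -> CultureTable:
    return CultureTable(read_table(path))


def read_tetrad_table(path) -> TetradTable:
    return TetradTable(read_table(path))
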