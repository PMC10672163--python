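"""Core domain containers shared by every pipeline stage.

All heavier tabular results (differential-expression tables, candidate
tables, ranked target tables, enrichment tables) are plain pandas DataFrames
with documented column contracts; the small typed records below carry the
objects that move between stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "SampleSheet",
    "TargetPrediction",
    "GeneSet",
    "NetworkEdge",
    "SeedSite",
    "ValidationError",
]


class ValidationError(ValueError):
    """An input violates a domain-type invariant."""


@dataclass
class CountMatrix:
    """Integer feature-by-sample count table (miRNA or gene space).

    Parameters
    ----------
    feature_ids : list of str
        Unique row identifiers (miRNAs or genes).
    sample_ids : list of str
        Unique column identifiers.
    counts : ndarray of shape (n_features, n_samples)
        Non-negative integer counts.
    """

    feature_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValidationError(
                f"counts shape {counts.shape} inconsistent with "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if len(set(self.feature_ids)) != len(self.feature_ids):
            dup = _first_duplicate(self.feature_ids)
            raise ValidationError(f"duplicate feature identifier: {dup!r}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dup = _first_duplicate(self.sample_ids)
            raise ValidationError(f"duplicate sample identifier: {dup!r}")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.allclose(counts, np.round(counts)):
                i, j = np.argwhere(counts != np.round(counts))[0]
                raise ValidationError(
                    f"non-integer count at feature {self.feature_ids[i]!r}, "
                    f"sample {self.sample_ids[j]!r}: {counts[i, j]}"
                )
            counts = counts.astype(np.int64)
        if (counts < 0).any():
            i, j = np.argwhere(counts < 0)[0]
            raise ValidationError(
                f"negative count at feature {self.feature_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}: {counts[i, j]}"
            )
        self.counts = counts

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.feature_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CountMatrix":
        return cls(list(df.index.astype(str)), list(df.columns.astype(str)), df.to_numpy())

    def subset_samples(self, sample_ids: list[str]) -> "CountMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return CountMatrix(list(self.feature_ids), list(sample_ids), self.counts[:, idx])

    def subset_features(self, feature_ids: list[str]) -> "CountMatrix":
        idx = [self.feature_ids.index(f) for f in feature_ids]
        return CountMatrix(list(feature_ids), list(self.sample_ids), self.counts[idx, :])


def _first_duplicate(items: list[str]) -> str:
    seen: set[str] = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return ""


@dataclass
class SampleSheet:
    """Per-sample metadata: cohort label, two-level condition, QC read count.

    Stored as a DataFrame with columns sample_id, cohort_id, condition,
    assigned_reads; ``condition`` must have exactly two levels within any
    analyzed design (control vs case).
    """

    table: pd.DataFrame

    REQUIRED = ("sample_id", "cohort_id", "condition", "assigned_reads")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValidationError(f"sample sheet missing columns: {missing}")
        tab = self.table.reset_index(drop=True).copy()
        tab["sample_id"] = tab["sample_id"].astype(str)
        if tab["sample_id"].duplicated().any():
            dup = tab.loc[tab["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ValidationError(f"duplicate sample_id: {dup!r}")
        if (tab["assigned_reads"] < 0).any():
            raise ValidationError("assigned_reads must be non-negative")
        self.table = tab

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def condition_of(self, sample_id: str) -> str:
        row = self.table.loc[self.table["sample_id"] == sample_id]
        if row.empty:
            raise KeyError(sample_id)
        return str(row["condition"].iloc[0])

    def subset(self, sample_ids: list[str]) -> "SampleSheet":
        keep = self.table[self.table["sample_id"].isin(sample_ids)]
        keep = keep.set_index("sample_id").loc[sample_ids].reset_index()
        return SampleSheet(keep)


@dataclass(frozen=True)
class TargetPrediction:
    """One predicted miRNA-family -> gene interaction.

    ``cwcs`` is TargetScan's cumulative weighted context++ score: more
    negative means stronger predicted repression (typically <= 0).
    """

    mirna_family: str
    gene_id: str
    cwcs: float
    conserved_sites: int = 0
    transcript_id: str | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.cwcs):
            raise ValidationError(f"CWCS must be finite, got {self.cwcs} for {self.gene_id}")
        if self.conserved_sites < 0:
            raise ValidationError(f"conserved_sites < 0 for {self.gene_id}")


@dataclass
class GeneSet:
    """A named gene set (e.g. one GO term) with unique members."""

    term_id: str
    term_name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        self.members = frozenset(self.members)
        if not self.members:
            raise ValidationError(f"gene set {self.term_id} has no members")


@dataclass(frozen=True)
class NetworkEdge:
    """A retained miRNA -> mRNA interaction with its confidence tier."""

    mirna_id: str
    gene_id: str
    cwcs: float
    tier: str

    def __post_init__(self) -> None:
        if self.tier not in ("high", "moderate"):
            raise ValidationError(f"tier must be high|moderate, got {self.tier!r}")
        if not self.cwcs < -0.2:
            raise ValidationError(
                f"edge {self.mirna_id}->{self.gene_id} has CWCS {self.cwcs} >= -0.2"
            )


@dataclass(frozen=True)
class SeedSite:
    """A classified seed-match occurrence in a 3'UTR (1-based start)."""

    utr_id: str
    start: int
    site_type: str

    SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1", "6mer")

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValidationError(f"site start must be >= 1, got {self.start}")
        if self.site_type not in self.SITE_TYPES:
            raise ValidationError(f"unknown site type {self.site_type!r}")
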