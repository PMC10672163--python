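"""Seed handling, CWCS-stratified target filtering, and network integration.

This is the pipeline's core: miRNA seeds (nucleotides 2-8) define seed
families; TargetScan-style predictions are collapsed to gene level, tiered
by the cumulative weighted context++ score (CWCS; more negative = stronger
predicted repression), intersected with significantly down-regulated mRNAs,
and emitted as the edges of the bipartite miRNA-mRNA network. A canonical
seed-site scanner (8mer / 7mer-m8 / 7mer-A1 / 6mer) supports validation on
sequence-level synthetic data.

Tier boundaries follow strict inequalities: predictions are retained iff
CWCS < -0.2; high confidence iff CWCS < -0.4; a CWCS of exactly -0.4 is
moderate and exactly -0.2 is dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .types import NetworkEdge, SeedSite, TargetPrediction

logger = logging.getLogger(__name__)

__all__ = [
    "seed_of",
    "seed_families",
    "SeedFamily",
    "scan_sites",
    "gene_level_predictions",
    "tier_predictions",
    "integrate",
    "ranked_target_table",
    "RETAIN_BELOW",
    "HIGH_BELOW",
]

RETAIN_BELOW = -0.2
HIGH_BELOW = -0.4

_RNA = set("ACGU")
_COMPLEMENT = str.maketrans("ACGU", "UGCA")


def _normalize_rna(seq: str, what: str) -> str:
    s = seq.upper().replace("T", "U")
    bad = set(s) - _RNA
    if bad:
        raise ValueError(f"{what} contains invalid characters {sorted(bad)}")
    return s


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# seeds and families


def seed_of(mirna_sequence: str) -> str:
    """Seed region of a mature miRNA: nucleotides 2-8, 5' to 3'.

    >>> seed_of("UAUUGCACUUGUCCCGGCCUGU")  # miR-92a-3p
    'AUUGCAC'
    """
    seq = _normalize_rna(mirna_sequence, "miRNA sequence")
    if len(seq) < 8:
        raise ValueError(f"miRNA sequence too short for a seed (length {len(seq)} < 8)")
    return seq[1:8]


@dataclass(frozen=True)
class SeedFamily:
    """A group of miRNAs sharing an identical seed."""

    label: str
    seed: str
    members: tuple[str, ...]


def seed_families(
    mirna_sequences: Mapping[str, str],
    labels: Mapping[str, str] | None = None,
) -> list[SeedFamily]:
    """Group miRNAs by identical seed (nucleotides 2-8).

    The family label is the lexicographically first member plus "-family"
    unless an explicit seed -> label map is supplied.
    """
    by_seed: dict[str, list[str]] = {}
    for mirna, seq in mirna_sequences.items():
        by_seed.setdefault(seed_of(seq), []).append(mirna)
    families = []
    for seed, members in by_seed.items():
        members = sorted(members)
        label = (labels or {}).get(seed, members[0] + "-family")
        families.append(SeedFamily(label=label, seed=seed, members=tuple(members)))
    families.sort(key=lambda f: f.label)
    return families


def family_map(families: Iterable[SeedFamily]) -> dict[str, str]:
    """miRNA id -> family label map for joining candidates to predictions."""
    return {m: fam.label for fam in families for m in fam.members}


# ---------------------------------------------------------------------------
# seed-site scanning


def scan_sites(utr: str, seed: str, utr_id: str = "utr") -> list[SeedSite]:
    """Classify every canonical seed-match site of ``seed`` in a 3'UTR.

    Site motifs derive from the 7-nt seed s (miRNA positions 2-8):
    the seed-match core is the reverse complement of s[1..6] (positions
    2-7); prepending the complement of position 8 gives the 7mer-m8 motif,
    and an adenosine 3' of the core gives the A1 anchor. Each core
    occurrence is counted once at its highest-priority classification
    (8mer > 7mer-m8 > 7mer-A1 > 6mer). Start positions are 1-based on the
    UTR 5'->3' and point at the site's 5'-most matched base (the m8
    position for 8mer/7mer-m8 sites, the core start otherwise).
    """
    seed = _normalize_rna(seed, "seed")
    if len(seed) != 7:
        raise ValueError(f"seed must be 7 nt, got {len(seed)}")
    utr = _normalize_rna(utr, "UTR")
    core = _revcomp(seed[:6])  # match to miRNA positions 2-7
    m8_base = _COMPLEMENT_CHAR[seed[6]]  # pairs miRNA position 8

    sites = []
    pos = utr.find(core)
    while pos != -1:
        has_m8 = pos >= 1 and utr[pos - 1] == m8_base
        a1_index = pos + 6
        has_a1 = a1_index < len(utr) and utr[a1_index] == "A"
        if has_m8 and has_a1:
            sites.append(SeedSite(utr_id, pos, "8mer"))  # start = m8 position (1-based)
        elif has_m8:
            sites.append(SeedSite(utr_id, pos, "7mer-m8"))
        elif has_a1:
            sites.append(SeedSite(utr_id, pos + 1, "7mer-A1"))
        else:
            sites.append(SeedSite(utr_id, pos + 1, "6mer"))
        pos = utr.find(core, pos + 1)
    return sites


_COMPLEMENT_CHAR = {"A": "U", "C": "G", "G": "C", "U": "A"}


# ---------------------------------------------------------------------------
# prediction collapsing and tiering


def gene_level_predictions(predictions: Iterable[TargetPrediction]) -> pd.DataFrame:
    """Collapse per-transcript predictions to one record per (family, gene).

    The gene-level CWCS is the minimum (most negative, i.e. strongest
    predicted repression) over transcripts; conserved_sites is the maximum.
    """
    rows = [
        (p.mirna_family, p.gene_id, p.cwcs, p.conserved_sites) for p in predictions
    ]
    df = pd.DataFrame(rows, columns=["mirna_family", "gene_id", "cwcs", "conserved_sites"])
    if df.empty:
        return df
    out = (
        df.groupby(["mirna_family", "gene_id"], as_index=False, sort=True)
        .agg(cwcs=("cwcs", "min"), conserved_sites=("conserved_sites", "max"))
    )
    return out


def tier_predictions(
    records: pd.DataFrame,
    retain_below: float = RETAIN_BELOW,
    high_below: float = HIGH_BELOW,
) -> pd.DataFrame:
    """Keep predictions with CWCS < retain_below; assign confidence tiers.

    tier = "high" iff CWCS < high_below, else "moderate"; both boundaries
    strict, so a CWCS of exactly -0.4 is moderate and exactly -0.2 drops.
    """
    kept = records.loc[records["cwcs"] < retain_below].copy()
    kept["tier"] = np.where(kept["cwcs"] < high_below, "high", "moderate")
    return kept.reset_index(drop=True)


# ---------------------------------------------------------------------------
# integration


def integrate(
    up_mirnas: Iterable[str],
    tiered: pd.DataFrame,
    down_genes: set[str],
    mirna_to_family: Mapping[str, str] | None = None,
) -> list[NetworkEdge]:
    """Intersect tiered predictions with the down-regulated gene set.

    An edge (miRNA, gene) is kept iff the miRNA is an up-regulated
    candidate, its family has a retained (CWCS < -0.2) prediction for the
    gene, and the gene is significantly down-regulated. When no explicit
    miRNA -> family map is given, prediction families are assumed to be
    keyed by the miRNA identifier itself. Candidates whose family has no
    predictions contribute no edges and are logged.
    """
    by_family: dict[str, pd.DataFrame] = {
        fam: grp for fam, grp in tiered.groupby("mirna_family")
    }
    edges = []
    for mirna in sorted(set(up_mirnas)):
        fam = (mirna_to_family or {}).get(mirna, mirna)
        grp = by_family.get(fam)
        if grp is None:
            logger.warning("integrate: candidate %s has no prediction family (%s)", mirna, fam)
            continue
        for _, row in grp.iterrows():
            if row["gene_id"] in down_genes:
                edges.append(
                    NetworkEdge(
                        mirna_id=mirna,
                        gene_id=row["gene_id"],
                        cwcs=float(row["cwcs"]),
                        tier=row["tier"],
                    )
                )
    return edges


def ranked_target_table(
    family: str,
    tiered: pd.DataFrame,
    mrna_de: pd.DataFrame,
    validated: set[str] | None = None,
    alpha: float = 0.05,
    min_change: float = 0.5,
) -> pd.DataFrame:
    """Ranked table of one seed family's down-regulated predicted targets.

    Rows are genes with a retained prediction (CWCS < -0.2) for ``family``
    that are also significantly down-regulated in the mRNA DE table
    (fdr < alpha and lfc < -log2(1 + min_change)), sorted by ascending CWCS
    (most negative, i.e. highest-confidence, first) and annotated with
    conserved-site counts, an experimental-validation flag, and the DE
    statistics.
    """
    fam_records = tiered.loc[tiered["mirna_family"] == family]
    if fam_records.empty:
        raise KeyError(f"family {family!r} absent from tiered predictions")
    de = mrna_de.set_index("feature_id")
    bound = -np.log2(1.0 + min_change)
    rows = []
    for _, rec in fam_records.iterrows():
        gene = rec["gene_id"]
        if gene not in de.index:
            continue
        lfc, fdr = float(de.loc[gene, "lfc"]), float(de.loc[gene, "fdr"])
        if fdr < alpha and lfc < bound:
            rows.append(
                {
                    "gene_id": gene,
                    "cwcs": float(rec["cwcs"]),
                    "conserved_sites": int(rec["conserved_sites"]),
                    "validated": gene in (validated or set()),
                    "lfc": lfc,
                    "fdr": fdr,
                }
            )
    table = pd.DataFrame(
        rows, columns=["gene_id", "cwcs", "conserved_sites", "validated", "lfc", "fdr"]
    )
    table = table.sort_values(["cwcs", "gene_id"], kind="mergesort").reset_index(drop=True)
    table.insert(0, "rank", np.arange(1, len(table) + 1))
    return table
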