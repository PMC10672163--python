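"""Cross-cohort consensus selection and ranking of candidate miRNAs.

Candidates are miRNAs independently called differentially expressed in
every cohort (by default also with the same direction of change), ranked by
the maximal -log10 FDR-adjusted p-value across cohorts so that the miRNA
with the lowest adjusted p-value in its best cohort ranks first.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .diffexp import call_de
from .types import SampleSheet

logger = logging.getLogger(__name__)

__all__ = ["consensus_candidates", "candidate_heatmap_matrix"]

_FDR_FLOOR = 1e-300  # keeps -log10(fdr) finite


def consensus_candidates(
    cohort_results: list[pd.DataFrame],
    alpha: float = 0.05,
    min_change: float = 0.5,
    require_concordance: bool = True,
) -> pd.DataFrame:
    """Intersect per-cohort DE calls and rank the consensus set.

    Parameters
    ----------
    cohort_results : list of DataFrame
        One differential-expression table per cohort (columns of
        ``diffexp.wald_test``), sharing a feature namespace.
    require_concordance : bool
        When True (default), a miRNA significant in all cohorts but with
        opposite directions of change is excluded and logged as discordant.

    Returns
    -------
    DataFrame with columns mirna, rank, rank_score, direction, and
    per-cohort lfc_cohort<i> / fdr_cohort<i>; sorted by rank. rank_score is
    the maximum over cohorts of -log10(fdr) (fdr floored at 1e-300); ties
    are broken by lexicographic miRNA identifier.
    """
    if len(cohort_results) < 2:
        raise ValueError("consensus requires >= 2 cohorts")
    namespaces = [set(t["feature_id"]) for t in cohort_results]
    shared = set.intersection(*namespaces)
    if not shared:
        raise ValueError(
            f"cohort feature namespaces are disjoint (overlap size {len(shared)})"
        )

    calls = [call_de(t, alpha=alpha, min_change=min_change) for t in cohort_results]
    candidate_set = set.intersection(*(c.all for c in calls))

    concordant_up = set.intersection(*(c.up for c in calls))
    concordant_down = set.intersection(*(c.down for c in calls))
    discordant = candidate_set - concordant_up - concordant_down
    if require_concordance:
        if discordant:
            logger.info(
                "consensus_candidates: excluded %d discordant miRNAs: %s",
                len(discordant),
                sorted(discordant),
            )
        candidate_set = concordant_up | concordant_down

    indexed = [t.set_index("feature_id") for t in cohort_results]
    rows = []
    for mirna in sorted(candidate_set):
        row: dict[str, object] = {"mirna": mirna}
        score = -np.inf
        for i, tab in enumerate(indexed, start=1):
            fdr = float(tab.loc[mirna, "fdr"])
            row[f"lfc_cohort{i}"] = float(tab.loc[mirna, "lfc"])
            row[f"fdr_cohort{i}"] = fdr
            score = max(score, -np.log10(max(fdr, _FDR_FLOOR)))
        row["rank_score"] = score
        row["direction"] = "up" if mirna in concordant_up else (
            "down" if mirna in concordant_down else "discordant"
        )
        rows.append(row)

    if not rows:
        cols = ["mirna", "rank", "rank_score", "direction"]
        return pd.DataFrame(columns=cols)
    table = pd.DataFrame(rows)
    table = table.sort_values(
        ["rank_score", "mirna"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    table.insert(1, "rank", np.arange(1, len(table) + 1))
    return table


def candidate_heatmap_matrix(
    candidates: pd.DataFrame,
    vst_matrices: list[tuple[pd.DataFrame, SampleSheet]],
    zscore: bool = False,
) -> list[pd.DataFrame]:
    """Per-cohort VST submatrices of the candidates, in rank order.

    Rows are the candidate miRNAs ordered by rank; columns are grouped
    control-then-case within each cohort. With ``zscore=True`` each row is
    centered and scaled to unit standard deviation for display.
    """
    if candidates.empty:
        raise ValueError("candidate table is empty")
    order = list(candidates.sort_values("rank")["mirna"])
    out = []
    for vst_mat, sheet in vst_matrices:
        missing = [m for m in order if m not in vst_mat.index]
        if missing:
            raise KeyError(f"candidates absent from VST matrix: {missing}")
        tab = sheet.table
        levels = sorted(tab["condition"].unique())
        ctrl = next((l for l in levels if l in ("control", "ctrl", "healthy")), levels[0])
        ordered_samples = list(tab.loc[tab["condition"] == ctrl, "sample_id"]) + list(
            tab.loc[tab["condition"] != ctrl, "sample_id"]
        )
        sub = vst_mat.loc[order, ordered_samples]
        if zscore:
            sub = sub.sub(sub.mean(axis=1), axis=0).div(sub.std(axis=1, ddof=0), axis=0)
        out.append(sub)
    return out
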