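"""Assay-level computations with study-specific rules.

Implements relative qPCR quantification (2^-ddCt on the means of technical
triplicates), real-time viability normalization (each well to its own
baseline, then linearly between the death-control 0% and vehicle-control
100% group means), dual-luciferase RLU normalization (firefly/renilla, then
to the control-group mean), and the clinical-score statistics for the EAE
(experimental autoimmune encephalomyelitis) mouse model: exclusion of
symptom-free animals, conservative imputation of missing daily scores by
the group mean of that day, per-animal area under the score curve, and the
Mann-Whitney U test on those AUCs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "CtRecord",
    "ViabilityTrace",
    "MWUResult",
    "ddct",
    "viability_normalize",
    "rlu_normalize",
    "eae_prepare",
    "eae_auc",
    "mann_whitney",
    "EAE_SCORE_SCALE",
]

EAE_SCORE_SCALE = (0.0, 1.0, 2.0, 3.0, 3.5, 4.0, 5.0)


# ---------------------------------------------------------------------------
# qRT-PCR


@dataclass(frozen=True)
class CtRecord:
    """Technical-replicate Ct values for one sample/assay pair."""

    sample_id: str
    group: str
    assay: str
    ct_replicates: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.ct_replicates:
            raise ValueError(f"{self.sample_id}/{self.assay}: no Ct replicates")
        if not all(np.isfinite(self.ct_replicates)):
            raise ValueError(f"{self.sample_id}/{self.assay}: non-finite Ct")

    @property
    def mean_ct(self) -> float:
        return float(np.mean(self.ct_replicates))


def ddct(
    records: list[CtRecord], reference_assay: str, control_group: str
) -> pd.DataFrame:
    """Relative quantification by 2^-ddCt on triplicate-mean Ct values.

    dCt_s = mean Ct(target) - mean Ct(reference); ddCt_s = dCt_s minus the
    mean dCt over control-group samples; RQ_s = 2^-ddCt_s. Amplification
    efficiency is fixed at exact doubling.

    Returns a DataFrame with columns sample_id, group, dct, ddct, rq.
    """
    by_sample: dict[str, dict[str, CtRecord]] = {}
    groups: dict[str, str] = {}
    for rec in records:
        slot = "reference" if rec.assay == reference_assay else "target"
        by_sample.setdefault(rec.sample_id, {})[slot] = rec
        groups[rec.sample_id] = rec.group

    rows = []
    for sample_id, slots in by_sample.items():
        if "reference" not in slots:
            raise ValueError(f"sample {sample_id!r} lacks reference assay {reference_assay!r}")
        if "target" not in slots:
            raise ValueError(f"sample {sample_id!r} lacks a target assay")
        rows.append(
            {
                "sample_id": sample_id,
                "group": groups[sample_id],
                "dct": slots["target"].mean_ct - slots["reference"].mean_ct,
            }
        )
    table = pd.DataFrame(rows)
    control_dct = table.loc[table["group"] == control_group, "dct"]
    if control_dct.empty:
        raise ValueError(f"control group {control_group!r} has no samples")
    table["ddct"] = table["dct"] - control_dct.mean()
    table["rq"] = 2.0 ** (-table["ddct"])
    return table


# ---------------------------------------------------------------------------
# real-time viability


@dataclass
class ViabilityTrace:
    """Luminescence time series for one well."""

    well_id: str
    group: str
    times: np.ndarray
    luminescence: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.luminescence = np.asarray(self.luminescence, dtype=float)
        if self.times.shape != self.luminescence.shape:
            raise ValueError(f"well {self.well_id}: times/luminescence length mismatch")
        if not (np.diff(self.times) > 0).all():
            raise ValueError(f"well {self.well_id}: times must be strictly increasing")
        if not (self.luminescence > 0).all():
            raise ValueError(f"well {self.well_id}: luminescence must be positive")


def viability_normalize(
    traces: list[ViabilityTrace],
    vehicle_group: str,
    death_group: str,
    baseline_time: float = 5.0,
) -> pd.DataFrame:
    """Percent viability per well and time point.

    Each well is first normalized to its own luminescence at the baseline
    time, R_w(t) = L_w(t)/L_w(baseline); the percent scale then interpolates
    linearly between the death-control group mean (0%) and the vehicle
    (unstimulated) group mean (100%) of R at each time. Values outside
    [0, 100] are not clipped. Rows are wells, columns time points.

    Only time points strictly after the baseline are reported: at (and
    before) the baseline every well has R = 1 by construction, so the
    vehicle/death group means coincide and the percent scale is undefined
    there. If the means coincide at any later time point, an error is
    raised.
    """
    if not any(t.group == vehicle_group for t in traces):
        raise ValueError(f"no wells in vehicle group {vehicle_group!r}")
    if not any(t.group == death_group for t in traces):
        raise ValueError(f"no wells in death group {death_group!r}")
    times = traces[0].times
    ratios = {}
    for tr in traces:
        if not np.array_equal(tr.times, times):
            raise ValueError("all traces must share the same time grid")
        at_baseline = np.isclose(tr.times, baseline_time)
        if not at_baseline.any():
            raise ValueError(f"well {tr.well_id}: baseline time {baseline_time} h absent")
        ratios[tr.well_id] = tr.luminescence / tr.luminescence[at_baseline][0]

    rmat = pd.DataFrame(ratios, index=times).T
    rmat = rmat.loc[:, times > baseline_time]
    if rmat.shape[1] == 0:
        raise ValueError("no time points after the baseline")
    vehicle_mean = rmat.loc[[t.well_id for t in traces if t.group == vehicle_group]].mean()
    death_mean = rmat.loc[[t.well_id for t in traces if t.group == death_group]].mean()
    denom = vehicle_mean - death_mean
    degenerate = np.isclose(denom, 0.0)
    if degenerate.any():
        bad = list(rmat.columns[degenerate])
        raise ValueError(f"vehicle and death means coincide at t={bad}; normalization degenerate")
    return 100.0 * rmat.sub(death_mean, axis=1).div(denom, axis=1)


# ---------------------------------------------------------------------------
# dual luciferase


def rlu_normalize(
    firefly: dict[str, float],
    renilla: dict[str, float],
    groups: dict[str, str],
    control_group: str,
) -> pd.Series:
    """Firefly/renilla ratio, normalized to the control-group mean RLU."""
    missing = set(firefly) ^ set(renilla)
    if missing:
        raise ValueError(f"unpaired firefly/renilla samples: {sorted(missing)}")
    zero = [s for s, v in renilla.items() if v == 0]
    if zero:
        raise ValueError(f"renilla signal is zero for samples {zero}")
    rlu = pd.Series({s: firefly[s] / renilla[s] for s in firefly})
    controls = [s for s in rlu.index if groups.get(s) == control_group]
    if not controls:
        raise ValueError(f"control group {control_group!r} has no samples")
    return rlu / rlu[controls].mean()


# ---------------------------------------------------------------------------
# EAE clinical scores


def eae_prepare(table: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Exclusions and conservative imputation for daily EAE scores.

    Input is long-form with columns animal_id, group, day, score (score may
    be NaN for missed observations); scores must come from the 0-5 clinical
    scale {0, 1, 2, 3, 3.5, 4, 5}. Animals whose observed scores are all
    zero (no disease symptoms) or entirely missing are excluded. Remaining
    missing (animal, day) cells are imputed with the mean observed score of
    the animal's group on that day. Returns a wide animals x days frame and
    a report dict with ``excluded`` and ``imputed`` entries.
    """
    required = {"animal_id", "group", "day", "score"}
    if not required <= set(table.columns):
        raise ValueError(f"EAE table must have columns {sorted(required)}")
    observed = table.dropna(subset=["score"])
    bad = set(observed["score"]) - set(EAE_SCORE_SCALE)
    if bad:
        raise ValueError(f"scores outside the clinical scale: {sorted(bad)}")
    if table.duplicated(["animal_id", "day"]).any():
        raise ValueError("multiple scores for one animal-day")

    group_of = table.groupby("animal_id")["group"].first()
    observed_max = observed.groupby("animal_id")["score"].max()
    excluded = [
        a for a in group_of.index
        if a not in observed_max.index or observed_max[a] == 0
    ]
    if excluded:
        logger.info("eae_prepare: excluded %d symptom-free animals: %s", len(excluded), excluded)
    kept = table[~table["animal_id"].isin(excluded)]

    wide = kept.pivot(index="animal_id", columns="day", values="score").sort_index()
    wide = wide[sorted(wide.columns)]
    group_means = (
        kept.dropna(subset=["score"]).groupby(["group", "day"])["score"].mean()
    )
    imputed = []
    for animal in wide.index:
        grp = group_of[animal]
        for day in wide.columns:
            if pd.isna(wide.loc[animal, day]):
                key = (grp, day)
                if key not in group_means.index:
                    raise ValueError(
                        f"cannot impute animal {animal!r} day {day}: no observed "
                        f"scores in group {grp!r} that day"
                    )
                value = float(group_means.loc[key])
                wide.loc[animal, day] = value
                imputed.append((animal, day, value))
    report = {"excluded": excluded, "imputed": imputed}
    return wide, report


def eae_auc(series: pd.DataFrame, window: str = "common") -> pd.Series:
    """Per-animal trapezoidal area under the daily clinical-score curve.

    ``window="common"`` (default) restricts to days scored for every
    animal; ``window="full"`` uses each animal's own observed day range.
    With unit day spacing the trapezoid equals the sum of interior scores
    plus half of the endpoints.
    """
    if window not in ("common", "full"):
        raise ValueError("window must be 'common' or 'full'")
    aucs = {}
    common_days = [d for d in series.columns if series[d].notna().all()]
    for animal in series.index:
        row = series.loc[animal]
        days = common_days if window == "common" else [d for d in series.columns if pd.notna(row[d])]
        if len(days) < 2:
            raise ValueError(f"animal {animal!r}: fewer than 2 scored days")
        aucs[animal] = float(np.trapezoid(row[days].to_numpy(dtype=float), np.asarray(days, dtype=float)))
    return pd.Series(aucs)


# ---------------------------------------------------------------------------
# Mann-Whitney U


@dataclass(frozen=True)
class MWUResult:
    """Mann-Whitney U test outcome (U is the statistic of group A)."""

    U: float
    n1: int
    n2: int
    pvalue: float
    alternative: str
    method: str


_EXACT_LIMIT = 400  # n1*n2 above which the normal approximation is used


def mann_whitney(
    groupA, groupB, alternative: str = "two-sided", method: str = "auto"
) -> MWUResult:
    """Mann-Whitney U test with an exact small-sample path.

    U is computed from rank sums with midranks for ties. The exact null
    distribution is used when n1*n2 <= 400 and there are no ties (or when
    ``method="exact"`` forces it); otherwise the normal approximation with
    tie and continuity corrections applies. The two-sided p-value is
    min(1, 2 * one-sided).
    """
    a = np.asarray(groupA, dtype=float)
    b = np.asarray(groupB, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    if alternative not in ("two-sided", "less", "greater"):
        raise ValueError(f"unknown alternative {alternative!r}")
    ranks = stats.rankdata(np.concatenate([a, b]))
    u_a = float(ranks[: a.size].sum() - a.size * (a.size + 1) / 2.0)
    has_ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    if method == "auto":
        use_exact = (a.size * b.size <= _EXACT_LIMIT) and not has_ties
    elif method == "exact":
        use_exact = True
    elif method in ("normal-approx", "asymptotic"):
        use_exact = False
    else:
        raise ValueError(f"unknown method {method!r}")
    res = stats.mannwhitneyu(
        a, b, alternative=alternative,
        method="exact" if use_exact else "asymptotic",
        use_continuity=True,
    )
    return MWUResult(
        U=u_a,
        n1=int(a.size),
        n2=int(b.size),
        pvalue=float(min(1.0, res.pvalue)),
        alternative=alternative,
        method="exact" if use_exact else "normal-approx",
    )
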