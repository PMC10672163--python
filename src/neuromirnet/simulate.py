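"""Synthetic inputs with the statistical structure the pipeline assumes.

Every downstream stage gets a recovery test: two independent miRNA cohorts
(control vs case) with planted, cohort-consistent log2 fold changes under
negative-binomial noise; an mRNA cohort in which the true targets of the
planted up-regulated miRNAs are silenced; a prediction table whose CWCS
values separate true edges from decoys; 3'UTRs with planted seed-match
sites; and assay fixtures (Ct triplicates, luminescence traces, daily EAE
scores) with planted group effects. Ground truth for each output is
returned alongside it.

The negative binomial is parameterized by mean mu and dispersion alpha
with variance mu + alpha*mu^2, matching the differential-expression model.
Each output draws from its own RNG substream keyed by (seed, stream id),
so adding one output never shifts the others; a fixed seed yields
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .assays import CtRecord, ViabilityTrace, EAE_SCORE_SCALE
from .target_integration import _revcomp, scan_sites
from .types import CountMatrix, SampleSheet, SeedSite, TargetPrediction

__all__ = [
    "SimulationConfig",
    "TruthTable",
    "simulate_mirna_cohorts",
    "simulate_mrna_with_targets",
    "simulate_utrs",
    "simulate_assays",
]

# RNG substream ids (stable; append-only)
_STREAM_MIRNA_BASE = 0
_STREAM_MIRNA_COUNTS = 1
_STREAM_MRNA = 2
_STREAM_PREDICTIONS = 3
_STREAM_UTRS = 4
_STREAM_ASSAYS = 5


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults mirror the study design: two independent miRNA cohorts with 5
    and 4 animals per group, 24 planted miRNAs with cohort-consistent
    effects, NB dispersion 0.1, strong (4-fold) silencing of true targets,
    and CWCS ranges that put every true edge below the -0.2 retention
    boundary and every decoy above it.
    """

    seed: int = 0
    n_mirna: int = 300
    n_gene: int = 2000
    n_per_group: tuple[int, ...] = (5, 4)  # per cohort
    n_cohorts: int = 2
    mean_range: tuple[float, float] = (20.0, 2000.0)
    dispersion: float = 0.1
    planted_mirnas: list[tuple[str, float]] | None = None  # None -> 24 default
    n_planted: int = 24
    planted_lfc_range: tuple[float, float] = (2.0, 3.0)  # magnitude
    frac_planted_up: float = 0.5
    target_density: float = 0.02
    silencing_lfc: float = -2.0
    cwcs_true_range: tuple[float, float] = (-0.9, -0.25)
    cwcs_decoy_range: tuple[float, float] = (-0.15, -0.01)
    mrna_n_per_group: int = 5
    # UTR simulation
    n_utr: int = 100
    utr_length_range: tuple[int, int] = (200, 2000)
    planted_sites_per_utr: int = 2
    # assay simulation
    ddct_effect: float = -1.0
    ct_sd: float = 0.2
    viability_plateau: float = 0.5
    eae_shift: float = 1.0
    eae_n_per_group: int = 8
    eae_n_zero_per_group: int = 1
    eae_days: int = 25
    eae_missing_prob: float = 0.05

    def __post_init__(self) -> None:
        if isinstance(self.n_per_group, int):
            self.n_per_group = (self.n_per_group,) * self.n_cohorts
        if len(self.n_per_group) != self.n_cohorts:
            raise ValueError("n_per_group must give one size per cohort")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if not (0 < self.target_density <= 1):
            raise ValueError("target_density must be in (0, 1]")
        if self.planted_mirnas is not None:
            for _, lfc in self.planted_mirnas:
                if not np.isfinite(lfc):
                    raise ValueError("planted LFCs must be finite")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([int(self.seed), stream]))


@dataclass
class TruthTable:
    """Ground truth accompanying each synthetic output."""

    mirna_effects: dict[str, float] = field(default_factory=dict)
    true_edges: set[tuple[str, str]] = field(default_factory=set)
    silenced_genes: set[str] = field(default_factory=set)
    utr_sites: dict[str, dict[str, list[SeedSite]]] = field(default_factory=dict)
    planted_utr_sites: dict[str, dict[str, list[SeedSite]]] = field(default_factory=dict)
    assay_effects: dict[str, float] = field(default_factory=dict)
    eae_zero_animals: list[str] = field(default_factory=list)


def _loguniform(rng: np.random.Generator, low: float, high: float, size: int) -> np.ndarray:
    return np.exp(rng.uniform(np.log(low), np.log(high), size=size))


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    """NB(mu, alpha) with Var = mu + alpha*mu^2 via numpy's (n, p) form."""
    n = 1.0 / alpha
    p = n / (n + mu)
    return rng.negative_binomial(n, p)


# ---------------------------------------------------------------------------
# miRNA cohorts


def simulate_mirna_cohorts(
    config: SimulationConfig,
) -> tuple[list[tuple[CountMatrix, SampleSheet]], TruthTable]:
    """Two (or more) independent case-vs-control miRNA count cohorts.

    Counts are NB(mean * 2^(LFC * case), dispersion) drawn independently per
    cohort with modest per-sample size-factor variation; all cohorts share
    the planted effect list — cross-cohort consistency is the planted
    signal. Non-planted miRNAs have LFC 0.
    """
    for n in config.n_per_group:
        if n < 2:
            raise ValueError("n_per_group must be >= 2 in every cohort (DE undefined)")

    rng_base = config.rng(_STREAM_MIRNA_BASE)
    mirna_ids = [f"miR-sim-{i + 1:03d}" for i in range(config.n_mirna)]
    base_means = _loguniform(rng_base, *config.mean_range, config.n_mirna)

    if config.planted_mirnas is None:
        # plant among robustly expressed miRNAs so the consensus stage sees
        # the signal in both cohorts
        eligible = np.flatnonzero(base_means >= 100.0)
        if len(eligible) < config.n_planted:
            eligible = np.argsort(base_means)[-config.n_planted :]
        chosen = rng_base.choice(eligible, size=config.n_planted, replace=False)
        n_up = int(round(config.n_planted * config.frac_planted_up))
        magnitudes = rng_base.uniform(*config.planted_lfc_range, size=config.n_planted)
        signs = np.array([1.0] * n_up + [-1.0] * (config.n_planted - n_up))
        planted = [
            (mirna_ids[idx], float(sign * mag))
            for idx, sign, mag in zip(chosen, signs, magnitudes)
        ]
    else:
        planted = [(str(m), float(l)) for m, l in config.planted_mirnas]
        unknown = [m for m, _ in planted if m not in set(mirna_ids)]
        if unknown:
            raise ValueError(f"planted miRNAs not in feature namespace: {unknown}")

    effects = dict.fromkeys(mirna_ids, 0.0)
    effects.update(dict(planted))
    lfc_vec = np.array([effects[m] for m in mirna_ids])

    rng_counts = config.rng(_STREAM_MIRNA_COUNTS)
    cohorts = []
    for c, n_rep in enumerate(config.n_per_group, start=1):
        sample_ids, conditions = [], []
        columns = []
        for cond, mult in (("control", 1.0), ("case", 2.0**lfc_vec)):
            for k in range(n_rep):
                sid = f"cohort{c}_{cond}{k + 1}"
                sample_ids.append(sid)
                conditions.append(cond)
                s_j = float(np.exp(rng_counts.normal(0.0, 0.15)))
                mu = base_means * mult * s_j
                columns.append(_nb_draw(rng_counts, mu, config.dispersion))
        counts = np.column_stack(columns)
        matrix = CountMatrix(mirna_ids, sample_ids, counts)
        sheet = SampleSheet(
            pd.DataFrame(
                {
                    "sample_id": sample_ids,
                    "cohort_id": f"cohort{c}",
                    "condition": conditions,
                    "assigned_reads": rng_counts.integers(2_000_000, 20_000_000, len(sample_ids)),
                }
            )
        )
        cohorts.append((matrix, sheet))

    truth = TruthTable(mirna_effects={m: l for m, l in planted})
    return cohorts, truth


# ---------------------------------------------------------------------------
# mRNA cohort with planted targets


def simulate_mrna_with_targets(
    config: SimulationConfig, truth: TruthTable
) -> tuple[tuple[CountMatrix, SampleSheet], list[TargetPrediction], TruthTable]:
    """mRNA counts where true targets of planted up-miRNAs are silenced.

    Each planted up-regulated miRNA is assigned ``target_density * n_gene``
    true target genes, down-shifted by ``silencing_lfc`` in case samples.
    The returned prediction table contains every true edge with CWCS drawn
    from ``cwcs_true_range`` plus an equal number of decoy edges per miRNA
    (non-regulated genes, CWCS from ``cwcs_decoy_range``); conserved-site
    counts are 1-4 for true edges and 0-2 for decoys. Prediction families
    are keyed by the miRNA identifier.
    """
    n_targets = int(round(config.target_density * config.n_gene))
    if n_targets < 1:
        raise ValueError("target_density * n_gene < 1: no targets to plant")

    rng = config.rng(_STREAM_MRNA)
    gene_ids = [f"gene-{i + 1:04d}" for i in range(config.n_gene)]
    base_means = _loguniform(rng, *config.mean_range, config.n_gene)

    up_mirnas = sorted(m for m, l in truth.mirna_effects.items() if l > 0)
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    true_edges: set[tuple[str, str]] = set()
    for mirna in up_mirnas:
        targets = rng.choice(config.n_gene, size=n_targets, replace=False)
        true_edges |= {(mirna, gene_ids[t]) for t in targets}
    silenced = {g for _, g in true_edges}

    lfc_vec = np.zeros(config.n_gene)
    for g in silenced:
        lfc_vec[gene_index[g]] = config.silencing_lfc

    sample_ids, conditions, columns = [], [], []
    for cond, mult in (("control", 1.0), ("case", 2.0**lfc_vec)):
        for k in range(config.mrna_n_per_group):
            sample_ids.append(f"mrna_{cond}{k + 1}")
            conditions.append(cond)
            s_j = float(np.exp(rng.normal(0.0, 0.15)))
            columns.append(_nb_draw(rng, base_means * mult * s_j, config.dispersion))
    matrix = CountMatrix(gene_ids, sample_ids, np.column_stack(columns))
    sheet = SampleSheet(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "cohort_id": "mrna_cohort",
                "condition": conditions,
                "assigned_reads": rng.integers(2_000_000, 20_000_000, len(sample_ids)),
            }
        )
    )

    rng_pred = config.rng(_STREAM_PREDICTIONS)
    predictions = []
    for mirna in up_mirnas:
        mirna_targets = sorted(g for m, g in true_edges if m == mirna)
        for gene in mirna_targets:
            predictions.append(
                TargetPrediction(
                    mirna_family=mirna,
                    gene_id=gene,
                    transcript_id=f"{gene}-tx1",
                    cwcs=float(rng_pred.uniform(*config.cwcs_true_range)),
                    conserved_sites=int(rng_pred.integers(1, 5)),
                )
            )
        decoy_pool = sorted(set(gene_ids) - silenced)
        decoys = rng_pred.choice(len(decoy_pool), size=min(n_targets, len(decoy_pool)), replace=False)
        for d in decoys:
            predictions.append(
                TargetPrediction(
                    mirna_family=mirna,
                    gene_id=decoy_pool[d],
                    transcript_id=f"{decoy_pool[d]}-tx1",
                    cwcs=float(rng_pred.uniform(*config.cwcs_decoy_range)),
                    conserved_sites=int(rng_pred.integers(0, 3)),
                )
            )

    new_truth = replace(truth, true_edges=true_edges, silenced_genes=silenced)
    return (matrix, sheet), predictions, new_truth


# ---------------------------------------------------------------------------
# 3'UTRs with planted seed sites


_SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1")


def _site_motif(seed: str, site_type: str) -> str:
    core = _revcomp(seed[:6])
    m8 = _revcomp(seed)[0]
    if site_type == "8mer":
        return m8 + core + "A"
    if site_type == "7mer-m8":
        return m8 + core
    if site_type == "7mer-A1":
        return core + "A"
    raise ValueError(site_type)


def simulate_utrs(
    config: SimulationConfig, seed_sequences: list[str]
) -> tuple[dict[str, str], TruthTable]:
    """Random-background UTRs with planted canonical seed-match sites.

    Backgrounds are uniform over {A,C,G,U}; ``planted_sites_per_utr`` sites
    (types cycling through 8mer/7mer-m8/7mer-A1, seeds cycling through
    ``seed_sequences``) are written at non-overlapping positions. The truth
    table records both the planted sites and, authoritatively, a post-scan
    of every finished UTR — so chance-occurring sites are included and
    scanner tests can assert exact set equality.
    """
    for s in seed_sequences:
        if len(s) != 7 or set(s.upper().replace("T", "U")) - set("ACGU"):
            raise ValueError(f"seed {s!r} must be a 7-mer over A/C/G/U")
    seeds = [s.upper().replace("T", "U") for s in seed_sequences]

    rng = config.rng(_STREAM_UTRS)
    utrs: dict[str, str] = {}
    planted: dict[str, dict[str, list[SeedSite]]] = {s: {} for s in seeds}
    for i in range(config.n_utr):
        utr_id = f"utr-{i + 1:03d}"
        length = int(rng.integers(config.utr_length_range[0], config.utr_length_range[1] + 1))
        seq = rng.choice(list("ACGU"), size=length)
        occupied: list[tuple[int, int]] = []
        for k in range(config.planted_sites_per_utr):
            seed = seeds[(i + k) % len(seeds)]
            site_type = _SITE_TYPES[(i + k) % len(_SITE_TYPES)]
            motif = _site_motif(seed, site_type)
            for _ in range(50):  # rejection on overlap only
                start = int(rng.integers(1, length - len(motif)))
                span = (start, start + len(motif))
                if all(span[1] <= a or span[0] >= b for a, b in occupied):
                    occupied.append(span)
                    seq[span[0] : span[1]] = list(motif)
                    planted[seed].setdefault(utr_id, []).append(
                        SeedSite(utr_id, start + 1, site_type)
                    )
                    break
        utrs[utr_id] = "".join(seq)

    scanned = {
        s: {uid: scan_sites(seq, s, utr_id=uid) for uid, seq in utrs.items()}
        for s in seeds
    }
    truth = TruthTable(utr_sites=scanned, planted_utr_sites=planted)
    return utrs, truth


# ---------------------------------------------------------------------------
# assay fixtures


def simulate_assays(config: SimulationConfig) -> tuple[dict, TruthTable]:
    """Ct triplicates, viability traces, and EAE score tables with truth.

    Returns a dict with keys ``ct_records`` (list of CtRecord),
    ``viability`` (list of ViabilityTrace), and ``eae`` (long-form
    DataFrame), plus a TruthTable carrying the planted effects.
    """
    rng = config.rng(_STREAM_ASSAYS)

    # --- qPCR: planted ddCt between control and treated
    ct_records = []
    for group, shift in (("control", 0.0), ("treated", config.ddct_effect)):
        for k in range(4):
            sid = f"{group}{k + 1}"
            target_base = 25.0 + shift + rng.normal(0.0, 0.1)
            ref_base = 20.0 + rng.normal(0.0, 0.1)
            ct_records.append(
                CtRecord(sid, group, "target", tuple(target_base + rng.normal(0, config.ct_sd, 3)))
            )
            ct_records.append(
                CtRecord(sid, group, "reference", tuple(ref_base + rng.normal(0, config.ct_sd, 3)))
            )

    # --- viability: exponential decay toward planted plateaus after baseline
    times = np.arange(0.5, 24.5, 0.5)
    plateaus = {"vehicle": 1.0, "death": 0.0, "treatment": config.viability_plateau}
    traces = []
    for group, plateau in plateaus.items():
        for k in range(5):
            shape = np.where(
                times <= 5.0, 1.0, plateau + (1.0 - plateau) * np.exp(-(times - 5.0) / 3.0)
            )
            gain = float(np.exp(rng.normal(np.log(1e5), 0.2)))
            lum = gain * np.maximum(shape, 1e-3) * np.exp(rng.normal(0.0, 0.02, len(times)))
            traces.append(ViabilityTrace(f"{group}{k + 1}", group, times, lum))

    # --- EAE: onset, rise to peak, slow recovery; 0.5-step clinical scale
    scale = np.array(EAE_SCORE_SCALE)
    rows = []
    zero_animals = []
    for group, shift in (("control", 0.0), ("treated", config.eae_shift)):
        for k in range(config.eae_n_per_group):
            animal = f"{group}_a{k + 1}"
            is_zero = k < config.eae_n_zero_per_group
            if is_zero:
                zero_animals.append(animal)
                latent = np.zeros(config.eae_days)
            else:
                onset = rng.normal(11.0, 1.5)
                peak = np.clip(rng.normal(3.2 - shift, 0.5), 0.5, 5.0)
                days = np.arange(1, config.eae_days + 1, dtype=float)
                rise = np.clip((days - onset) / 3.0, 0.0, 1.0)
                recovery = np.clip((days - onset - 6.0) / 20.0, 0.0, 0.3)
                latent = np.clip(peak * rise - peak * recovery + rng.normal(0, 0.25, len(days)), 0, 5)
            scores = scale[np.abs(latent[:, None] - scale[None, :]).argmin(axis=1)]
            for day, score in zip(range(1, config.eae_days + 1), scores):
                missing = (not is_zero) and rng.uniform() < config.eae_missing_prob
                rows.append(
                    {
                        "animal_id": animal,
                        "group": group,
                        "day": day,
                        "score": np.nan if missing else float(score),
                    }
                )
    eae = pd.DataFrame(rows)

    truth = TruthTable(
        assay_effects={
            "ddct": config.ddct_effect,
            "viability_plateau": config.viability_plateau,
            "eae_shift": config.eae_shift,
        },
        eae_zero_animals=zero_animals,
    )
    return {"ct_records": ct_records, "viability": traces, "eae": eae}, truth
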