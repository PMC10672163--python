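import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from neuromirnet import diffexp
from neuromirnet.simulate import SimulationConfig, simulate_mirna_cohorts, simulate_mrna_with_targets
from neuromirnet.target_integration import (
    gene_level_predictions,
    integrate,
    ranked_target_table,
    scan_sites,
    seed_families,
    seed_of,
    tier_predictions,
)
from neuromirnet.types import TargetPrediction

from conftest import de_table

MIR_92A = "UAUUGCACUUGUCCCGGCCUGU"  # mature miR-92a-3p
SEED = "AUUGCAC"  # shared by the miR-25 family


class TestSeeds:
    def test_mir92a_seed(self):
        assert seed_of(MIR_92A) == SEED

    def test_homopolymer(self):
        assert seed_of("AAAAAAAA") == "AAAAAAA"

    def test_short_sequence_rejected(self):
        with pytest.raises(ValueError, match="short"):
            seed_of("AUUGCAC")

    def test_invalid_alphabet_rejected(self):
        with pytest.raises(ValueError, match="invalid"):
            seed_of("AUUGCACXX")

    def test_family_grouping_by_shared_seed(self):
        seqs = {
            "miR-92a-3p": MIR_92A,
            "miR-25-3p": "CAUUGCACUUGUCUCGGUCUGA",  # same seed AUUGCAC
            "miR-999": "UGGGGGGGGGGG",
        }
        fams = seed_families(seqs)
        by_seed = {f.seed: f for f in fams}
        assert by_seed[SEED].members == ("miR-25-3p", "miR-92a-3p")
        assert by_seed[SEED].label == "miR-25-3p-family"

    def test_singletons_and_empty(self):
        fams = seed_families({"a": "ACGUACGUA", "b": "CCCCCCCCC"})
        assert all(len(f.members) == 1 for f in fams)
        assert seed_families({}) == []


def naive_scan(utr: str, seed: str):
    """Independent brute-force scanner: substring tests at every offset."""
    comp = {"A": "U", "C": "G", "G": "C", "U": "A"}
    rc = lambda s: "".join(comp[c] for c in reversed(s))
    utr = utr.upper().replace("T", "U")
    core = rc(seed[:6])
    m8 = comp[seed[6]]
    sites = []
    for i in range(len(utr) - 5):
        if utr[i : i + 6] != core:
            continue
        has_m8 = i >= 1 and utr[i - 1] == m8
        has_a1 = i + 6 < len(utr) and utr[i + 6] == "A"
        if has_m8 and has_a1:
            sites.append((i, "8mer"))
        elif has_m8:
            sites.append((i, "7mer-m8"))
        elif has_a1:
            sites.append((i + 1, "7mer-A1"))
        else:
            sites.append((i + 1, "6mer"))
    return sites


class TestScanSites:
    def test_mir92a_seed_example_8mer_at_3(self):
        """Reverse complement of AUUGCAC plus A: GUGCAAUA at position 3."""
        sites = scan_sites("AAGUGCAAUAAA", SEED)
        assert len(sites) == 1
        assert sites[0].site_type == "8mer"
        assert sites[0].start == 3

    def test_no_sites_in_poly_c(self):
        assert scan_sites("C" * 100, SEED) == []

    @pytest.mark.parametrize(
        "utr, expected",
        [
            ("GGUGCAAUC", [(2, "7mer-m8")]),   # m8 base, no A1
            ("CUGCAAUAC", [(2, "7mer-A1")]),   # A1 anchor, no m8 base
            ("CUGCAAUCC", [(2, "6mer")]),      # bare core
            ("GUGCAAUAC", [(1, "8mer")]),      # both flanks present
        ],
    )
    def test_site_type_taxonomy(self, utr, expected):
        sites = scan_sites(utr, SEED)
        assert [(s.start, s.site_type) for s in sites] == expected

    def test_matches_naive_oracle_on_random_utrs(self):
        rng = np.random.default_rng(40)
        for _ in range(300):
            utr = "".join(rng.choice(list("ACGU"), size=rng.integers(20, 120)))
            got = {(s.start, s.site_type) for s in scan_sites(utr, SEED)}
            assert got == set(naive_scan(utr, SEED))

    @given(st.text(alphabet="ACGU", min_size=0, max_size=80),
           st.text(alphabet="ACGU", min_size=7, max_size=7))
    def test_oracle_equivalence_property(self, utr, seed):
        got = {(s.start, s.site_type) for s in scan_sites(utr, seed)}
        assert got == set(naive_scan(utr, seed))


class TestGeneLevel:
    def test_min_cwcs_max_sites(self):
        preds = [
            TargetPrediction("miR-25", "Cpeb3", -0.3, 2, "tx1"),
            TargetPrediction("miR-25", "Cpeb3", -0.82, 4, "tx2"),
        ]
        out = gene_level_predictions(preds)
        assert len(out) == 1
        assert out.loc[0, "cwcs"] == pytest.approx(-0.82)
        assert out.loc[0, "conserved_sites"] == 4

    def test_single_row_identity(self):
        out = gene_level_predictions([TargetPrediction("m", "g", -0.5, 1)])
        assert out.loc[0, "cwcs"] == pytest.approx(-0.5)

    def test_matches_groupby_oracle_on_random_duplicates(self):
        rng = np.random.default_rng(41)
        preds = [
            TargetPrediction(
                f"m{rng.integers(3)}", f"g{rng.integers(5)}",
                float(rng.uniform(-1, 0)), int(rng.integers(5)),
            )
            for _ in range(200)
        ]
        out = gene_level_predictions(preds).set_index(["mirna_family", "gene_id"])
        expected: dict[tuple[str, str], list[float]] = {}
        for p in preds:
            expected.setdefault((p.mirna_family, p.gene_id), []).append(
                (p.cwcs, p.conserved_sites)
            )
        for key, vals in expected.items():
            assert out.loc[key, "cwcs"] == pytest.approx(min(v[0] for v in vals))
            assert out.loc[key, "conserved_sites"] == max(v[1] for v in vals)


class TestTiering:
    @pytest.mark.parametrize(
        "cwcs, retained, tier",
        [
            (-0.82, True, "high"),
            (-0.41, True, "high"),
            (-0.4, True, "moderate"),   # boundary: strictly below -0.4 is high
            (-0.25, True, "moderate"),
            (-0.2, False, None),        # boundary: strict retention cutoff
            (-0.1, False, None),
        ],
    )
    def test_boundaries(self, cwcs, retained, tier):
        records = gene_level_predictions([TargetPrediction("m", "g", cwcs, 1)])
        out = tier_predictions(records)
        assert (len(out) == 1) is retained
        if retained:
            assert out.loc[0, "tier"] == tier

    def test_partition_no_record_in_both_tiers(self):
        rng = np.random.default_rng(42)
        preds = [TargetPrediction("m", f"g{i}", float(rng.uniform(-1, 0)), 1)
                 for i in range(100)]
        out = tier_predictions(gene_level_predictions(preds))
        assert set(out["tier"]) <= {"high", "moderate"}
        assert (out["cwcs"] < -0.2).all()
        assert ((out["cwcs"] < -0.4) == (out["tier"] == "high")).all()


class TestIntegrate:
    def _tiered(self):
        preds = [
            TargetPrediction("miR-1", "gA", -0.5, 2),
            TargetPrediction("miR-1", "gB", -0.3, 1),
            TargetPrediction("miR-2", "gA", -0.1, 1),  # dropped by tiering
        ]
        return tier_predictions(gene_level_predictions(preds))

    def test_empty_down_genes_gives_empty_network(self):
        assert integrate(["miR-1"], self._tiered(), set()) == []

    def test_candidate_with_only_weak_predictions_contributes_nothing(self):
        edges = integrate(["miR-2"], self._tiered(), {"gA", "gB"})
        assert edges == []

    def test_edge_carries_cwcs_and_tier(self):
        edges = integrate(["miR-1"], self._tiered(), {"gA"})
        assert len(edges) == 1
        assert edges[0].gene_id == "gA"
        assert edges[0].cwcs == pytest.approx(-0.5)
        assert edges[0].tier == "high"

    def test_containment_chain(self):
        rng = np.random.default_rng(43)
        preds = [
            TargetPrediction(f"m{rng.integers(4)}", f"g{rng.integers(30)}",
                             float(rng.uniform(-1, 0)), 1)
            for _ in range(200)
        ]
        gene_level = gene_level_predictions(preds)
        tiered = tier_predictions(gene_level)
        down = {f"g{i}" for i in range(0, 30, 2)}
        edges = integrate([f"m{i}" for i in range(4)], tiered, down)
        edge_pairs = {(e.mirna_id, e.gene_id) for e in edges}
        tier_pairs = set(zip(tiered["mirna_family"], tiered["gene_id"]))
        gl_pairs = set(zip(gene_level["mirna_family"], gene_level["gene_id"]))
        assert edge_pairs <= tier_pairs <= gl_pairs

    def test_planted_edge_recovery_end_to_end(self):
        cfg = SimulationConfig(seed=44, n_mirna=150, n_gene=600, n_planted=8)
        cohorts, truth = simulate_mirna_cohorts(cfg)
        (m, s), preds, truth = simulate_mrna_with_targets(cfg, truth)
        down = diffexp.call_de(diffexp.wald_test(m, s)).down
        tiered = tier_predictions(gene_level_predictions(preds))
        up = [mi for mi, l in truth.mirna_effects.items() if l > 0]
        edges = integrate(up, tiered, down)
        got = {(e.mirna_id, e.gene_id) for e in edges}
        tp = len(got & truth.true_edges)
        assert tp / len(got) >= 0.95
        assert tp / len(truth.true_edges) >= 0.95


class TestRankedTargetTable:
    def _fixture(self):
        preds = [
            TargetPrediction("miR-25-family", "Cpeb3", -0.82, 4),
            TargetPrediction("miR-25-family", "GeneB", -0.5, 2),
            TargetPrediction("miR-25-family", "GeneC", -0.3, 1),
            TargetPrediction("miR-25-family", "GeneUp", -0.9, 3),
        ]
        tiered = tier_predictions(gene_level_predictions(preds))
        de = de_table([
            ("Cpeb3", -1.2, 0.001),
            ("GeneB", -0.8, 0.01),
            ("GeneC", -1.0, 0.02),
            ("GeneUp", 1.5, 0.001),   # up-regulated: excluded
        ])
        return tiered, de

    def test_most_negative_cwcs_ranks_first(self):
        tiered, de = self._fixture()
        table = ranked_target_table("miR-25-family", tiered, de, validated={"Cpeb3"})
        assert list(table["gene_id"]) == ["Cpeb3", "GeneB", "GeneC"]
        assert table.loc[0, "rank"] == 1
        assert bool(table.loc[0, "validated"])
        assert table.loc[0, "conserved_sites"] == 4

    def test_empty_validated_set(self):
        tiered, de = self._fixture()
        table = ranked_target_table("miR-25-family", tiered, de)
        assert not table["validated"].any()

    def test_unknown_family_errors(self):
        tiered, de = self._fixture()
        with pytest.raises(KeyError):
            ranked_target_table("nope-family", tiered, de)

    def test_ordering_matches_sort_oracle(self):
        rng = np.random.default_rng(45)
        genes = [f"g{i}" for i in range(40)]
        preds = [TargetPrediction("fam", g, float(rng.uniform(-1, -0.21)), 1) for g in genes]
        de = de_table([(g, -1.0, 0.001) for g in genes])
        tiered = tier_predictions(gene_level_predictions(preds))
        table = ranked_target_table("fam", tiered, de)
        cwcs_of = {p.gene_id: p.cwcs for p in preds}
        expected = sorted(genes, key=lambda g: (cwcs_of[g], g))
        assert list(table["gene_id"]) == expected
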