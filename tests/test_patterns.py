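import numpy as np
import pandas as pd
import pytest

from pahmsc import (
    classify_patterns,
    export_heatmap_matrix,
    select_predominant,
    select_reversed,
)
from pahmsc.patterns import DEFAULT_GROUP_MAP, ReversionSelection

COMPARISONS = ["MCT/CON", "AD/MCT", "BM/MCT", "UCB/MCT"]


def _frame(genes, calls, lmrs=None, qs=None):
    """Build a minimal results frame from per-gene calls (up/down/none)."""
    lmrs = lmrs or {}
    qs = qs or {}
    rows = []
    for g in genes:
        call = calls.get(g, "none")
        lmr = lmrs.get(g, {"up": 1.0, "down": -1.0, "none": 0.1}[call])
        rows.append({
            "gene_id": g,
            "t": lmr * 3,
            "lmr": lmr,
            "p_t": 0.5, "p_lmr": 0.5, "z": 0.0,
            "p": 0.001 if call != "none" else 0.8,
            "q": qs.get(g, 0.01 if call != "none" else 0.9),
            "is_deg": call != "none",
            "direction": "up" if lmr >= 0 else "down",
        })
    return pd.DataFrame(rows)


@pytest.fixture
def toy_results():
    genes = [f"g{i}" for i in range(6)]
    # g0: disease-up, all arms down      -> G1
    # g1: disease-down, UCB up only      -> G4 (consensus: one up, none down)
    # g2: disease none, arms up          -> G2
    # g3: disease-up, arms none          -> G6
    # g4: no DEG anywhere                -> excluded
    # g5: disease-up, AD up / UCB down   -> conflict, unclassified
    return {
        "MCT/CON": _frame(genes, {"g0": "up", "g1": "down", "g3": "up",
                                  "g5": "up"}),
        "AD/MCT": _frame(genes, {"g0": "down", "g2": "up", "g5": "up"}),
        "BM/MCT": _frame(genes, {"g0": "down", "g2": "up"}),
        "UCB/MCT": _frame(genes, {"g0": "down", "g1": "up", "g2": "up",
                                  "g5": "down"}),
    }


class TestClassifyPatterns:
    def test_fixed_group_anchors(self, toy_results):
        out = classify_patterns(toy_results).set_index("gene_id")
        assert out.loc["g0", "group"] == "G1"
        assert out.loc["g1", "group"] == "G4"
        assert out.loc["g2", "group"] == "G2"
        assert out.loc["g3", "group"] == "G6"

    def test_non_deg_excluded_and_conflict_unclassified(self, toy_results):
        out = classify_patterns(toy_results)
        assert "g4" not in set(out["gene_id"])
        row = out[out["gene_id"] == "g5"]
        assert len(row) == 1 and row["group"].isna().all()

    def test_missing_comparison_rejected(self, toy_results):
        del toy_results["BM/MCT"]
        with pytest.raises(ValueError, match="missing"):
            classify_patterns(toy_results)

    def test_partition_of_degs(self, fitted):
        """Every DEG of any comparison lands in exactly one group (or is
        explicitly unclassified)."""
        out = classify_patterns(fitted)
        all_degs = set()
        for name in COMPARISONS:
            f = fitted[name].frame
            all_degs |= set(f.loc[f["is_deg"], "gene_id"])
        assert set(out["gene_id"]) == all_degs
        assert not out["gene_id"].duplicated().any()
        classified = out["group"].dropna()
        assert classified.isin(list(DEFAULT_GROUP_MAP.values())).all()

    def test_pure_g1_design_classifies_everything_g1(self):
        genes = [f"g{i}" for i in range(4)]
        results = {
            "MCT/CON": _frame(genes, {g: "up" for g in genes}),
            "AD/MCT": _frame(genes, {g: "down" for g in genes}),
            "BM/MCT": _frame(genes, {g: "down" for g in genes}),
            "UCB/MCT": _frame(genes, {g: "down" for g in genes}),
        }
        out = classify_patterns(results)
        assert (out["group"] == "G1").all()


class TestReversionSelection:
    def test_definition_on_toy_data(self, toy_results):
        out = classify_patterns(toy_results)
        sel = select_reversed(out, "UCB")
        assert sel["G1"].reversed_gene_ids == ["g0"]
        assert sel["G4"].reversed_gene_ids == ["g1"]
        # AD did not revert g1 (G4 needs an up call from the arm)
        assert select_reversed(out, "AD")["G4"].reversed_gene_ids == []

    def test_unknown_msc_rejected(self, toy_results):
        out = classify_patterns(toy_results)
        with pytest.raises(ValueError):
            select_reversed(out, "XX")

    def test_subset_invariants_enforced(self):
        with pytest.raises(ValueError):
            ReversionSelection("G1", "UCB", ["a"], ["a", "b"])

    def test_recovery_of_planted_reversions(self, fitted, study, study_config):
        """Genes the UCB arm fully reverts are recovered in G1/G4."""
        _, truth = study
        out = classify_patterns(fitted)
        sel = select_reversed(out, "UCB")
        recovered = set(sel["G1"].reversed_gene_ids) | set(
            sel["G4"].reversed_gene_ids)
        full = truth["rev_UCB"] >= study_config.effect_size
        planted = set(truth.loc[full & (truth["mct_direction"] != "null"),
                                "gene_id"])
        sensitivity = len(recovered & planted) / len(planted)
        assert sensitivity >= 0.7
        assert recovered <= set(out["gene_id"])


class TestPredominantSelection:
    def test_conjunction_over_both_head_to_heads(self):
        sel = ReversionSelection("G1", "UCB", ["g0", "g1", "g2"])
        strong = {"g0": -1.0, "g1": -1.0, "g2": -1.0}
        h2h = {
            "UCB/AD": _frame(["g0", "g1", "g2"],
                             {"g0": "down", "g1": "down"}, strong),
            "UCB/BM": _frame(["g0", "g1", "g2"], {"g0": "down"}, strong),
        }
        out = select_predominant(sel, h2h)
        assert out.predominant_gene_ids == ["g0"]  # g1 significant vs AD only

    def test_sign_must_match_reversion_direction(self):
        sel = ReversionSelection("G4", "UCB", ["g0"])
        h2h = {
            "UCB/AD": _frame(["g0"], {"g0": "down"}),  # wrong sign for G4
            "UCB/BM": _frame(["g0"], {"g0": "up"}),
        }
        assert select_predominant(sel, h2h).predominant_gene_ids == []

    def test_missing_table_rejected(self):
        sel = ReversionSelection("G1", "UCB", ["g0"])
        with pytest.raises(ValueError):
            select_predominant(sel, {})

    def test_predominance_recovered_on_pipeline_run(self, fitted, study,
                                                    study_config):
        """UCB-only reverted planted genes survive the head-to-head cut."""
        _, truth = study
        out = classify_patterns(fitted)
        h2h = {name: fitted[name] for name in ("UCB/AD", "UCB/BM")}
        n_predominant = 0
        for group, sel in select_reversed(out, "UCB").items():
            pred = select_predominant(sel, h2h)
            assert set(pred.predominant_gene_ids) <= set(
                pred.reversed_gene_ids)
            n_predominant += len(pred.predominant_gene_ids)
        # genes fully reverted by UCB but untouched by AD and BM
        only_ucb = truth[(truth["rev_UCB"] >= study_config.effect_size)
                         & (truth["rev_AD"] == 0) & (truth["rev_BM"] == 0)
                         & (truth["mct_direction"] != "null")]
        assert n_predominant >= 0.7 * len(only_ucb)


class TestHeatmapExport:
    def test_shape_and_column_order(self, toy_results):
        out = classify_patterns(toy_results)
        heat = export_heatmap_matrix(out, COMPARISONS)
        assert list(heat.columns) == ["gene_id", "group"] + COMPARISONS
        assert len(heat) == (out["group"].notna()).sum()
        # grouped ordering: G1 rows precede G4 rows
        groups = list(heat["group"])
        assert groups.index("G1") < groups.index("G4")

    def test_round_trip_six_decimals(self, toy_results, tmp_path):
        heat = export_heatmap_matrix(classify_patterns(toy_results),
                                     COMPARISONS)
        path = tmp_path / "heat.tsv"
        heat.to_csv(path, sep="\t", index=False, float_format="%.6f")
        back = pd.read_csv(path, sep="\t")
        np.testing.assert_allclose(back[COMPARISONS].to_numpy(),
                                   heat[COMPARISONS].to_numpy(), atol=1e-6)

    def test_empty_assignments_rejected(self):
        with pytest.raises(ValueError):
            export_heatmap_matrix(pd.DataFrame())
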