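import numpy as np
import pandas as pd
import pytest

from adrpath import docking
from adrpath.io import Direction, DockingScoreMatrix


class TestMergePockets:
    def test_lower_better_takes_min(self, docking_matrix):
        best = docking.merge_pockets(docking_matrix)
        d1p1 = best[(best.drug_id == "d1") & (best.protein_id == "p1")].raw_score.item()
        assert d1p1 == -8.2

    def test_higher_better_takes_max(self, docking_matrix):
        flipped = DockingScoreMatrix(docking_matrix.entries, Direction.HIGHER)
        best = docking.merge_pockets(flipped)
        d1p1 = best[(best.drug_id == "d1") & (best.protein_id == "p1")].raw_score.item()
        assert d1p1 == -6.1

    def test_single_pocket_passthrough(self, docking_matrix):
        best = docking.merge_pockets(docking_matrix)
        d2p2 = best[(best.drug_id == "d2") & (best.protein_id == "p2")].raw_score.item()
        assert d2p2 == -4.0

    def test_one_row_per_pair(self, docking_matrix):
        best = docking.merge_pockets(docking_matrix)
        assert not best.duplicated(["drug_id", "protein_id"]).any()


def pair_table(scores_by_protein):
    rows = [
        (f"d{i}", prot, s)
        for prot, scores in scores_by_protein.items()
        for i, s in enumerate(scores)
    ]
    return pd.DataFrame(rows, columns=["drug_id", "protein_id", "raw_score"])


class TestNormalizeScores:
    def test_hand_computed_z(self):
        tab = pair_table({"p": [2.0, 4.0, 6.0]})
        z = docking.normalize_scores(tab, Direction.HIGHER).z.to_numpy()
        np.testing.assert_allclose(z, [-1.224744871, 0.0, 1.224744871], atol=1e-9)

    def test_group_mean_zero_sd_one(self):
        rng = np.random.default_rng(5)
        tab = pair_table({f"p{k}": rng.normal(k, k + 1, size=7) for k in range(4)})
        out = docking.normalize_scores(tab, Direction.HIGHER)
        for _, g in out.groupby("protein_id"):
            assert abs(g.z.mean()) < 1e-10
            assert abs(g.z.std(ddof=0) - 1) < 1e-10

    def test_lower_better_orients_sign(self):
        tab = pair_table({"p": [-9.0, -1.0]})  # -9 is the strong binder
        z = docking.normalize_scores(tab, Direction.LOWER).set_index("drug_id").z
        assert z["d0"] > 0 > z["d1"]

    def test_constant_group_maps_to_zero(self, caplog):
        tab = pair_table({"p": [3.0, 3.0, 3.0], "q": [1.0, 2.0, 3.0]})
        out = docking.normalize_scores(tab, Direction.HIGHER)
        assert (out[out.protein_id == "p"].z == 0).all()

    def test_singleton_group_zero_with_warning(self, caplog):
        tab = pair_table({"p": [3.0]})
        with caplog.at_level("WARNING"):
            out = docking.normalize_scores(tab, Direction.HIGHER)
        assert out.z.item() == 0.0
        assert any("zero-variance" in r.message for r in caplog.records)

    def test_per_drug_axis(self):
        tab = pair_table({"p": [1.0, 5.0], "q": [3.0, 7.0]})
        out = docking.normalize_scores(tab, Direction.HIGHER, axis="drug")
        for _, g in out.groupby("drug_id"):
            assert abs(g.z.mean()) < 1e-10

    def test_row_order_invariance(self):
        rng = np.random.default_rng(9)
        tab = pair_table({f"p{k}": rng.normal(size=6) for k in range(3)})
        out1 = docking.normalize_scores(tab, Direction.HIGHER)
        shuffled = tab.sample(frac=1, random_state=1)
        out2 = docking.normalize_scores(shuffled, Direction.HIGHER)
        merged = out1.merge(out2, on=["drug_id", "protein_id"], suffixes=("_a", "_b"))
        np.testing.assert_allclose(merged.z_a, merged.z_b, atol=1e-12)


class TestCallInteractions:
    def test_hand_computed_threshold(self):
        tab = pd.DataFrame({
            "drug_id": ["d"] * 4,
            "protein_id": list("wxyz"),
            "z": [2.0, 0.0, -1.0, -1.0],   # mean 0, sd ~1.2247
        })
        out = docking.call_interactions(tab).set_index("protein_id")
        assert out.retained.tolist() == [True, False, False, False]

    def test_all_equal_retains_nothing(self):
        tab = pd.DataFrame({"drug_id": ["d"] * 3, "protein_id": list("abc"), "z": [1.0] * 3})
        assert not docking.call_interactions(tab).retained.any()

    def test_boundary_is_strict(self):
        # z = {1, -1}: mean 0, sd 1, so z = 1 sits exactly at mean + sd
        tab = pd.DataFrame({"drug_id": ["d"] * 2, "protein_id": ["a", "b"], "z": [1.0, -1.0]})
        assert not docking.call_interactions(tab).retained.any()

    def test_single_protein_drug_retains_nothing(self, caplog):
        tab = pd.DataFrame({"drug_id": ["d"], "protein_id": ["a"], "z": [5.0]})
        with caplog.at_level("WARNING"):
            out = docking.call_interactions(tab)
        assert not out.retained.any()


class TestPathwayFeatures:
    pmap = pd.DataFrame({
        "protein_id": ["p1", "p1", "p2", "p3"],
        "pathway_id": ["A", "B", "A", "C"],
    })

    def table(self, rows):
        df = pd.DataFrame(rows, columns=["drug_id", "protein_id", "z", "retained"])
        return df

    def test_multi_membership_credits_all_columns(self):
        tab = self.table([("d", "p1", 1.5, True)])
        X = docking.build_pathway_features(tab, self.pmap, drugs=["d"])
        assert X.loc["d", "A"] == 1.5 and X.loc["d", "B"] == 1.5

    def test_sum_within_pathway(self):
        tab = self.table([("d", "p1", 1.2, True), ("d", "p2", 2.0, True)])
        X = docking.build_pathway_features(tab, self.pmap, drugs=["d"])
        assert X.loc["d", "A"] == pytest.approx(3.2)

    def test_unretained_and_unmapped_contribute_nothing(self, caplog):
        tab = self.table([("d", "p2", 9.0, False), ("d", "ghost", 1.0, True)])
        with caplog.at_level("WARNING"):
            X = docking.build_pathway_features(tab, self.pmap, drugs=["d"])
        assert (X.loc["d"] == 0).all()

    def test_additivity_over_row_splits(self):
        rng = np.random.default_rng(2)
        rows = [
            (f"d{i}", f"p{j+1}", float(rng.normal()), True)
            for i in range(4) for j in range(3)
        ]
        tab = self.table(rows)
        drugs = [f"d{i}" for i in range(4)]
        full = docking.build_pathway_features(tab, self.pmap, drugs=drugs)
        half = docking.build_pathway_features(tab.iloc[:6], self.pmap, drugs=drugs)
        rest = docking.build_pathway_features(tab.iloc[6:], self.pmap, drugs=drugs)
        pd.testing.assert_frame_equal(full, half + rest)
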