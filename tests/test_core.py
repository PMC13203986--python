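import numpy as np
import pandas as pd
import pytest

import neutralcore as nc
from neutralcore.neutral import OccupancyAbundanceTable


def oa_from(records: dict[str, tuple[float, float]]) -> OccupancyAbundanceTable:
    frame = pd.DataFrame(
        {
            "occupancy": {k: v[0] for k, v in records.items()},
            "mean_abundance": {k: v[1] for k, v in records.items()},
        }
    )
    frame.index.name = "taxon_id"
    return OccupancyAbundanceTable(frame, 10, 1000, "all_samples")


def curve_from(deltas: list[float]) -> pd.DataFrame:
    e = [deltas[0]]
    for d in deltas[1:]:
        e.append(e[-1] * (1 + d))
    return pd.DataFrame(
        {"rank": range(1, len(deltas) + 1), "E_k": e, "delta_k": deltas},
        index=pd.Index([f"t{i}" for i in range(len(deltas))], name="taxon_id"),
    )


class TestRankTaxa:
    def test_occupancy_primary(self):
        ranking = nc.rank_taxa(oa_from({"X": (1.0, 0.001), "Y": (0.5, 0.9)}))
        assert ranking == ["X", "Y"]

    def test_abundance_breaks_ties(self):
        ranking = nc.rank_taxa(oa_from({"X": (0.5, 0.1), "Y": (0.5, 0.3)}))
        assert ranking == ["Y", "X"]

    def test_lexicographic_final_tie_break(self):
        ranking = nc.rank_taxa(oa_from({"B": (0.5, 0.1), "A": (0.5, 0.1)}))
        assert ranking == ["A", "B"]


class TestContributionCurve:
    def two_sample_table(self):
        return nc.FeatureTable(
            pd.DataFrame([[4, 0], [0, 4]], index=["x", "y"], columns=["t1", "t2"])
        )

    def test_hand_computed_halves(self):
        curve = nc.bray_curtis_contribution_curve(self.two_sample_table(), ["t1", "t2"])
        assert curve["E_k"].tolist() == pytest.approx([0.5, 1.0])

    def test_full_rank_reaches_one(self, neutral_sim):
        _, table = neutral_sim
        sub = table.filter_samples(table.sample_ids[:15]).drop_empty_taxa()
        oa = nc.occupancy_abundance(sub, "all_samples")
        curve = nc.bray_curtis_contribution_curve(sub, nc.rank_taxa(oa))
        assert curve["E_k"].iloc[-1] == pytest.approx(1.0, abs=1e-12)

    def test_monotone_non_decreasing(self, neutral_sim):
        _, table = neutral_sim
        sub = table.filter_samples(table.sample_ids[:12]).drop_empty_taxa()
        oa = nc.occupancy_abundance(sub, "all_samples")
        curve = nc.bray_curtis_contribution_curve(sub, nc.rank_taxa(oa))
        assert (np.diff(curve["E_k"]) >= -1e-15).all()

    def test_full_rank_matches_mean_bray_curtis(self, neutral_sim):
        # the partial numerator at full rank is the full numerator, so the
        # curve's normalizer equals the diversity module's mean dissimilarity
        _, table = neutral_sim
        sub = table.filter_samples(table.sample_ids[:10]).drop_empty_taxa()
        counts = sub.counts.astype(float)
        iu, ju = np.triu_indices(sub.n_samples, k=1)
        full_num = np.abs(counts[iu] - counts[ju]).sum(axis=1)
        denom = counts.sum(axis=1)[iu] + counts.sum(axis=1)[ju]
        mean_bc_direct = (full_num / denom).mean()
        mean_bc_module = nc.bray_curtis(sub).condensed_form().mean()
        assert mean_bc_direct == pytest.approx(mean_bc_module, abs=1e-12)

    def test_identical_samples_rejected(self):
        table = nc.FeatureTable(
            pd.DataFrame([[2, 2], [2, 2]], index=["x", "y"], columns=["t1", "t2"])
        )
        with pytest.raises(ValueError, match="no dissimilarity"):
            nc.bray_curtis_contribution_curve(table, ["t1", "t2"])


class TestSelectCore:
    def test_prefix_stops_at_first_failure(self):
        core = nc.select_core_members(curve_from([0.30, 0.10, 0.04, 0.06]), 0.05)
        assert core.tolist() == [True, True, False, False]

    def test_zero_threshold_admits_all(self):
        core = nc.select_core_members(curve_from([0.3, 0.2, 0.01]), 0.0)
        assert core.all()

    def test_first_rank_anchors_core(self):
        with pytest.warns(UserWarning, match="anchors"):
            core = nc.select_core_members(curve_from([0.01, 0.2, 0.01]), 0.05)
        assert core.tolist() == [True, True, False]

    def test_monotone_in_threshold(self, neutral_sim):
        _, table = neutral_sim
        sub = table.filter_samples(table.sample_ids[:12]).drop_empty_taxa()
        oa = nc.occupancy_abundance(sub, "all_samples")
        curve = nc.bray_curtis_contribution_curve(sub, nc.rank_taxa(oa))
        sizes = [
            nc.select_core_members(curve, th).sum() for th in (0.10, 0.05, 0.01)
        ]
        assert sizes[0] <= sizes[1] <= sizes[2]

    def test_constructed_dominants_match_brute_force(self):
        # three ubiquitous high-abundance taxa over a sparse rare tail
        rng = np.random.default_rng(0)
        n = 12
        dom = rng.integers(200, 400, size=(n, 3))
        tail = rng.binomial(1, 0.2, size=(n, 40)) * rng.integers(1, 4, size=(n, 40))
        counts = np.hstack([dom, tail])
        counts[:, 0] += 1
        table = nc.FeatureTable(
            pd.DataFrame(
                counts, index=[f"s{i}" for i in range(n)],
                columns=[f"t{j:02d}" for j in range(43)],
            )
        )
        rare = nc.rarefy(table, int(table.library_sizes().min()), seed=0)
        oa = nc.occupancy_abundance(rare, "all_samples")
        ranking = nc.rank_taxa(oa)
        curve = nc.bray_curtis_contribution_curve(rare, ranking)
        core = nc.select_core_members(curve, 0.05)
        # brute-force prefix scan oracle
        delta = curve["delta_k"].to_numpy()
        expected = 0
        for d in delta:
            if d >= 0.05:
                expected += 1
            else:
                break
        assert core.sum() == expected
        assert set(curve.index[:3]) == {"t00", "t01", "t02"}

    def test_core_is_prefix_of_ranking(self, neutral_sim):
        _, table = neutral_sim
        sub = table.filter_samples(table.sample_ids[:12]).drop_empty_taxa()
        oa = nc.occupancy_abundance(sub, "all_samples")
        sel = nc.build_core_selection(sub, oa, 0.05)
        flags = sel.frame["core"].to_numpy()
        first_false = np.argmin(flags) if not flags.all() else len(flags)
        assert not flags[first_false:].any()


class TestSetOperations:
    def test_over_occupant_core_intersection(self):
        part = pd.DataFrame(
            {"partition": ["above", "neutral", "above", "below"]},
            index=["B", "A", "D", "C"],
        )
        assert nc.over_occupant_core({"A", "B", "C"}, part) == {"B"}

    def test_compare_core_sets(self):
        res = nc.compare_core_sets({"A", "B"}, {"B", "C"})
        assert res == {"shared": {"B"}, "unique_a": {"A"}, "unique_b": {"C"}}

    def test_compare_identical_and_empty(self):
        assert nc.compare_core_sets({"A"}, {"A"})["shared"] == {"A"}
        res = nc.compare_core_sets(set(), {"X", "Y"})
        assert res["unique_b"] == {"X", "Y"} and not res["shared"]


class TestClassAggregation:
    def table_with_taxonomy(self):
        frame = pd.DataFrame(
            [[50, 30, 20], [10, 60, 30]], index=["s1", "s2"],
            columns=["t1", "t2", "t3"],
        )
        taxonomy = {
            "t1": "Bacteria;Proteobacteria;Alphaproteobacteria;o;f;g;s",
            "t2": "Bacteria;Proteobacteria;Alphaproteobacteria;o2;f2;g2;s2",
            "t3": "Bacteria;Acidobacteriota",  # truncated lineage, no class
        }
        return nc.FeatureTable(frame, taxonomy)

    def test_same_class_summed(self):
        table = self.table_with_taxonomy()
        agg = nc.aggregate_class_abundance(table, {"t1", "t2"})
        assert list(agg.index) == ["Alphaproteobacteria"]
        assert agg.iloc[0] == pytest.approx((0.5 + 0.3 + 0.1 + 0.6) / 2)

    def test_short_lineage_unclassified(self):
        agg = nc.aggregate_class_abundance(self.table_with_taxonomy(), {"t3"})
        assert list(agg.index) == ["Unclassified"]

    def test_totals_conserved(self):
        table = self.table_with_taxonomy()
        subset = {"t1", "t2", "t3"}
        agg = nc.aggregate_class_abundance(table, subset)
        total = table.relative_abundance()[list(subset)].mean(axis=0).sum()
        assert agg.sum() == pytest.approx(total, abs=1e-12)
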