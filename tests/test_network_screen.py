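"""Screening features, composite scoring, ranking and panel tables."""

import math

import numpy as np
import pandas as pd
import pytest

from foxnet.network_screen import (
    CellLineFeatures,
    NetworkNeighborhood,
    PanelTable,
    ScreenFeatures,
    build_screen_features,
    compare_candidates,
    composite_score,
    load_foxm1_target_panel,
    panel_consensus_table,
    rank_candidates,
    read_network,
)
from foxnet.signature_core import (
    ConsensusSpec,
    PerturbationType,
    Signature,
    SignatureCollection,
    signature_similarity,
)
from foxnet.simulate import ScreenSimConfig, simulate_screen

from conftest import make_signature


def _collection_from(arrays, cell_lines, ptype, target=None, prefix="p"):
    genes = [f"g{i}" for i in range(len(next(iter(arrays.values()))))]
    sigs = []
    for pid, values in arrays.items():
        for cl in cell_lines:
            sigs.append(
                Signature(
                    perturbation_id=pid,
                    cell_line=cl,
                    values=pd.Series(values, index=genes),
                    perturbation_type=ptype,
                    target_gene=target if ptype is PerturbationType.KNOCKDOWN else None,
                )
            )
    return SignatureCollection(sigs, genes)


class TestNetworkNeighborhood:
    def test_proxy_not_among_partners(self):
        with pytest.raises(ValueError):
            NetworkNeighborhood("NPM1", ("NPM1", "FOXM1"))

    def test_read_edge_list(self, tmp_path):
        path = tmp_path / "net.tsv"
        path.write_text("NPM1\tFOXM1\nAURKB\tNPM1\nFOXM1\tPLK1\nNPM1\tFOXM1\n")
        net = read_network(path, "NPM1")
        assert net.proxy_target == "NPM1"
        assert net.partners == ("FOXM1", "AURKB")


class TestBuildScreenFeatures:
    def test_exact_mimic_supported_everywhere(self, rng):
        cell_lines = [f"CL{i}" for i in range(7)]
        base = rng.standard_normal(50)
        kd = _collection_from({"shNPM1": base}, cell_lines,
                              PerturbationType.KNOCKDOWN, target="NPM1")
        compounds = _collection_from({"mimic": base}, cell_lines,
                                     PerturbationType.COMPOUND)
        feats = build_screen_features(
            compounds, kd, NetworkNeighborhood("NPM1"), support_threshold=0.3
        )
        assert len(feats) == 1
        assert feats[0].support_count == 7
        assert all(
            f.direct_corr == pytest.approx(1.0)
            for f in feats[0].per_cell_line.values()
        )

    def test_noise_compound_rarely_supported(self, rng):
        cell_lines = [f"CL{i}" for i in range(7)]
        genes = [f"g{i}" for i in range(100)]
        sigs = []
        for cl in cell_lines:
            sigs.append(Signature("shNPM1", cl,
                                  pd.Series(rng.standard_normal(100), index=genes),
                                  PerturbationType.KNOCKDOWN, "NPM1"))
            sigs.append(Signature("noise", cl,
                                  pd.Series(rng.standard_normal(100), index=genes),
                                  PerturbationType.COMPOUND))
        collection = SignatureCollection(sigs, genes)
        feats = build_screen_features(
            collection.subset(perturbation_type="compound"),
            collection.subset(perturbation_type="knockdown"),
            NetworkNeighborhood("NPM1"),
            support_threshold=0.3,
        )
        assert feats[0].support_count <= 1
        # brute-force recomputation of each correlation
        for cl, cell_feats in feats[0].per_cell_line.items():
            compound = collection.subset(
                cell_line=cl, perturbation_type="compound"
            ).signatures[0]
            kd = collection.subset(
                cell_line=cl, perturbation_type="knockdown"
            ).signatures[0]
            assert cell_feats.direct_corr == pytest.approx(
                signature_similarity(compound, kd)
            )

    def test_planted_inhibitor_reaches_min_support(self, small_screen):
        collection, truth = small_screen
        feats = build_screen_features(
            collection.subset(perturbation_type="compound"),
            collection.subset(perturbation_type="knockdown"),
            NetworkNeighborhood(truth["proxy_target"], tuple(truth["partners"])),
            support_threshold=0.3,
        )
        planted = next(
            f for f in feats if f.compound_id == truth["planted_compound"]
        )
        assert planted.support_count >= 4
        assert planted.n_cell_lines == 7
        assert not math.isnan(
            next(iter(planted.per_cell_line.values())).best_indirect_corr
        )

    def test_missing_proxy_knockdown_errors(self, rng):
        compounds = _collection_from(
            {"c": rng.standard_normal(10)}, ["A"], PerturbationType.COMPOUND
        )
        kd = _collection_from(
            {"shOTHER": rng.standard_normal(10)}, ["A"],
            PerturbationType.KNOCKDOWN, target="OTHER"
        )
        with pytest.raises(ValueError, match="NPM1"):
            build_screen_features(compounds, kd, NetworkNeighborhood("NPM1"))

    def test_disjoint_cell_lines_yield_empty_features(self, rng):
        compounds = _collection_from(
            {"c": rng.standard_normal(10)}, ["B"], PerturbationType.COMPOUND
        )
        kd = _collection_from(
            {"shNPM1": rng.standard_normal(10)}, ["A"],
            PerturbationType.KNOCKDOWN, target="NPM1"
        )
        feats = build_screen_features(compounds, kd, NetworkNeighborhood("NPM1"))
        assert feats[0].n_cell_lines == 0
        assert feats[0].support_count == 0


class TestCompositeScore:
    def _features(self, per_line, threshold=0.3):
        return ScreenFeatures("c", per_line, threshold)

    def test_perfect_mimic(self):
        per_line = {
            f"CL{i}": CellLineFeatures(1.0, 1.0, 1.0) for i in range(7)
        }
        score, qualified = composite_score(self._features(per_line),
                                           lambda_indirect=0.5)
        assert qualified
        assert score == pytest.approx(1.5)

    def test_below_min_support_unqualified(self):
        per_line = {f"CL{i}": CellLineFeatures(0.9, 0.5, 0.5) for i in range(3)}
        score, qualified = composite_score(self._features(per_line),
                                           min_support=4)
        assert not qualified
        assert score == -math.inf

    def test_hand_computed_mean_over_supported_lines(self):
        per_line = {
            "A": CellLineFeatures(0.5, 0.2, 0.1),
            "B": CellLineFeatures(0.4, 0.0, 0.0),
            "C": CellLineFeatures(0.6, -0.2, -0.1),
            "D": CellLineFeatures(0.8, 0.4, 0.3),
            "E": CellLineFeatures(0.1, 0.9, 0.9),  # below support threshold
        }
        expected = np.mean(
            [0.5 + 0.5 * 0.2, 0.4 + 0.0, 0.6 + 0.5 * -0.2, 0.8 + 0.5 * 0.4]
        )
        score, qualified = composite_score(self._features(per_line),
                                           lambda_indirect=0.5, min_support=4)
        assert qualified
        assert score == pytest.approx(expected)

    def test_monotone_in_correlations(self):
        base = {f"CL{i}": CellLineFeatures(0.5, 0.2, 0.2) for i in range(5)}
        better = dict(base)
        better["CL0"] = CellLineFeatures(0.7, 0.2, 0.2)
        low, _ = composite_score(self._features(base))
        high, _ = composite_score(self._features(better))
        assert high >= low

    def test_no_cell_lines_unqualified(self):
        score, qualified = composite_score(self._features({}))
        assert not qualified and score == -math.inf


class TestRankCandidates:
    def test_mimic_outranks_noise(self, rng):
        cell_lines = [f"CL{i}" for i in range(7)]
        base = rng.standard_normal(60)
        genes = [f"g{i}" for i in range(60)]
        sigs = []
        for cl in cell_lines:
            sigs.append(Signature("shNPM1", cl, pd.Series(base, index=genes),
                                  PerturbationType.KNOCKDOWN, "NPM1"))
            sigs.append(Signature("mimic", cl, pd.Series(base, index=genes),
                                  PerturbationType.COMPOUND))
            sigs.append(Signature("noise", cl,
                                  pd.Series(rng.standard_normal(60), index=genes),
                                  PerturbationType.COMPOUND))
        collection = SignatureCollection(sigs, genes)
        feats = build_screen_features(
            collection.subset(perturbation_type="compound"),
            collection.subset(perturbation_type="knockdown"),
            NetworkNeighborhood("NPM1"),
        )
        ranking = rank_candidates(feats)
        assert ranking.entries[0][0] == "mimic"

    def test_planted_inhibitor_ranked_first(self, small_screen):
        collection, truth = small_screen
        feats = build_screen_features(
            collection.subset(perturbation_type="compound"),
            collection.subset(perturbation_type="knockdown"),
            NetworkNeighborhood(truth["proxy_target"], tuple(truth["partners"])),
        )
        ranking = rank_candidates(feats, seed=17)
        assert ranking.rank_of(truth["planted_compound"]) == 1
        frame = ranking.to_frame()
        # qualified compounds sort strictly above unqualified ones
        qualified_flags = frame["qualified"].tolist()
        assert qualified_flags == sorted(qualified_flags, reverse=True)

    def test_degenerate_training_errors(self, small_screen):
        collection, truth = small_screen
        feats = build_screen_features(
            collection.subset(perturbation_type="compound"),
            collection.subset(perturbation_type="knockdown"),
            NetworkNeighborhood(truth["proxy_target"], tuple(truth["partners"])),
        )
        with pytest.raises(ValueError, match="composite_score"):
            rank_candidates(feats, training={feats[0].compound_id: 1,
                                             feats[1].compound_id: 1})

    def test_trained_classifier_recovers_held_out_inhibitor(self):
        """Labels from independent screens rank a held-out inhibitor highly."""
        train_feats = []
        labels = {}
        for i, seed in enumerate([101, 102, 103, 104, 105]):
            collection, truth = simulate_screen(
                ScreenSimConfig(n_genes=200, n_decoy_compounds=8,
                                mixing_weight=0.7, seed=seed)
            )
            feats = build_screen_features(
                collection.subset(perturbation_type="compound"),
                collection.subset(perturbation_type="knockdown"),
                NetworkNeighborhood(truth["proxy_target"],
                                    tuple(truth["partners"])),
            )
            for f in feats:
                new_id = f"s{seed}_{f.compound_id}"
                f.compound_id = new_id
                labels[new_id] = int(new_id.endswith("CPD_PLANTED"))
                train_feats.append(f)
        collection, truth = simulate_screen(
            ScreenSimConfig(n_genes=200, n_decoy_compounds=30,
                            mixing_weight=0.7, seed=999)
        )
        test_feats = build_screen_features(
            collection.subset(perturbation_type="compound"),
            collection.subset(perturbation_type="knockdown"),
            NetworkNeighborhood(truth["proxy_target"], tuple(truth["partners"])),
        )
        ranking = rank_candidates(
            test_feats, training=labels, seed=7, training_features=train_feats
        )
        rank = ranking.rank_of(truth["planted_compound"])
        assert rank <= max(1, int(0.1 * len(ranking)))

    def test_deterministic_under_seed(self, small_screen):
        collection, truth = small_screen
        feats = build_screen_features(
            collection.subset(perturbation_type="compound"),
            collection.subset(perturbation_type="knockdown"),
            NetworkNeighborhood(truth["proxy_target"], tuple(truth["partners"])),
        )
        first = rank_candidates(feats, seed=5).entries
        second = rank_candidates(feats, seed=5).entries
        assert first == second


class TestPanelTable:
    def test_fixture_reproduces_printed_cells(self):
        table = load_foxm1_target_panel()
        assert table.values.loc["BIRC5", "STL427944"] == pytest.approx(-6.05)
        assert table.values.loc["CDC20", "MYC_KD"] == pytest.approx(-24.50)
        assert table.values.loc["UBE2C", "NPM1_KD"] == pytest.approx(-3.01)
        assert table.panel_genes == [
            "BIRC5", "CCNB1", "CCNB2", "CDK1", "CDC20", "CDC25A", "PLK1",
            "UBE2C",
        ]

    def test_consensus_table_from_collection(self, rng):
        genes = ["BIRC5", "CCNB1", "PLK1"]
        values_kd = [-2.0, -3.0, -1.0]
        sigs = [
            Signature("shNPM1", "A549", pd.Series(values_kd, index=genes),
                      PerturbationType.KNOCKDOWN, "NPM1"),
            Signature("cpd", "A549", pd.Series(values_kd, index=genes),
                      PerturbationType.COMPOUND),
        ]
        collection = SignatureCollection(sigs, genes)
        table = panel_consensus_table(collection, genes, ["shNPM1", "cpd"])
        pd.testing.assert_series_equal(
            table.values["shNPM1"], table.values["cpd"], check_names=False
        )

    def test_mean_aggregation_matches_hand_mean(self):
        genes = ["g1", "g2"]
        sigs = [
            Signature("cpd", "A", pd.Series([1.0, 3.0], index=genes),
                      replicate=0),
            Signature("cpd", "B", pd.Series([3.0, 5.0], index=genes),
                      replicate=0),
        ]
        collection = SignatureCollection(sigs, genes)
        table = panel_consensus_table(
            collection, genes, ["cpd"], ConsensusSpec(method="mean")
        )
        np.testing.assert_allclose(table.values["cpd"], [2.0, 4.0])

    def test_missing_panel_gene_named(self, rng):
        sig = make_signature({"g1": 1.0, "g2": 2.0}, perturbation_id="cpd")
        collection = SignatureCollection([sig], ["g1", "g2"])
        with pytest.raises(ValueError, match="BIRC5"):
            panel_consensus_table(collection, ["BIRC5"], ["cpd"])


class TestCompareCandidates:
    def test_stl_ranks_above_benzamil(self):
        table = load_foxm1_target_panel()
        result = compare_candidates(table, ["benzamil", "STL427944"])
        assert [r[0] for r in result] == ["STL427944", "benzamil"]
        stl = result[0]
        assert stl[1] == 8  # all eight panel genes suppressed below -1
        assert stl[2] == pytest.approx(-4.65875)
        assert result[1][1] == 2
        assert result[1][2] == pytest.approx(-0.38125)

    def test_zero_column(self):
        values = pd.DataFrame({"null": [0.0, 0.0, 0.0]},
                              index=["a", "b", "c"])
        table = PanelTable(["a", "b", "c"], ["null"], values)
        (_, n_suppressed, mean_z), = compare_candidates(table, ["null"])
        assert n_suppressed == 0 and mean_z == 0.0

    def test_constant_shift_moves_mean_exactly(self):
        values = pd.DataFrame(
            {"x": [-1.0, 0.5, -2.0], "y": [-3.0, -1.5, -4.0]},
            index=["a", "b", "c"],
        )
        table = PanelTable(["a", "b", "c"], ["x", "y"], values)
        result = dict(
            (name, mean_z)
            for name, _, mean_z in compare_candidates(table, ["x", "y"])
        )
        assert result["y"] == pytest.approx(result["x"] - 2.0)

    def test_panel_gene_order_invariance(self):
        table = load_foxm1_target_panel()
        shuffled = PanelTable(
            table.panel_genes[::-1],
            table.perturbations,
            table.values.iloc[::-1],
        )
        assert compare_candidates(table, ["STL427944", "benzamil"]) == \
            compare_candidates(shuffled, ["STL427944", "benzamil"])

    def test_unknown_candidate(self):
        table = load_foxm1_target_panel()
        with pytest.raises(KeyError, match="nope"):
            compare_candidates(table, ["nope"])
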