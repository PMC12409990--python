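import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from caspfold import rin, synthetic
from caspfold.ensemble import ConformationalEnsemble

from conftest import make_atoms, ensemble_from_frames
from oracles import enumerate_betweenness, random_weighted_graph


def _net_from_edges(edges, residues):
    frame = pd.DataFrame(
        edges, columns=["res_i", "res_j", "type", "mean_weight", "occupancy"]
    )
    return rin.ResidueInteractionNetwork(frame, np.asarray(residues), n_frames=1)


class TestDetectContacts:
    def test_cutoff_boundary(self):
        atoms = make_atoms([(1, "GLY", "A", "CA", "C"), (3, "GLY", "A", "CA", "C")])
        near = np.array([[0, 0, 0], [3.99, 0, 0.0]])
        far = np.array([[0, 0, 0], [4.01, 0, 0.0]])
        assert len(rin.detect_contacts(near, atoms)) == 1
        assert len(rin.detect_contacts(far, atoms)) == 0

    def test_salt_bridge_typed_electrostatic(self, salt_bridge_pair):
        coords, atoms = salt_bridge_pair
        contacts = rin.detect_contacts(coords, atoms)
        assert len(contacts) == 1
        row = contacts.iloc[0]
        assert row["type"] == "electrostatic"
        assert (row["res_i"], row["res_j"]) == (1, 3)
        assert row["distance"] == pytest.approx(3.5)

    def test_hydrophobic_typing(self):
        atoms = make_atoms([(1, "LEU", "A", "CD1", "C"), (3, "VAL", "A", "CG1", "C")])
        coords = np.array([[0, 0, 0], [3.0, 0, 0.0]])
        assert rin.detect_contacts(coords, atoms)["type"].iloc[0] == "hydrophobic"

    def test_backbone_carbons_are_vdw_not_hydrophobic(self):
        atoms = make_atoms([(1, "LEU", "A", "CA", "C"), (3, "VAL", "A", "CA", "C")])
        coords = np.array([[0, 0, 0], [3.0, 0, 0.0]])
        assert rin.detect_contacts(coords, atoms)["type"].iloc[0] == "vdw"

    def test_chain_adjacent_residues_excluded(self):
        atoms = make_atoms([(1, "GLY", "A", "CA", "C"), (2, "GLY", "A", "CA", "C")])
        coords = np.array([[0, 0, 0], [1.0, 0, 0.0]])
        assert len(rin.detect_contacts(coords, atoms)) == 0

    def test_different_chains_not_subject_to_adjacency(self):
        atoms = make_atoms([(1, "GLY", "A", "CA", "C"), (2, "GLY", "B", "CA", "C")])
        coords = np.array([[0, 0, 0], [1.0, 0, 0.0]])
        assert len(rin.detect_contacts(coords, atoms)) == 1

    def test_hydrogens_ignored(self):
        atoms = make_atoms([(1, "GLY", "A", "HA", "H"), (3, "GLY", "A", "CA", "C")])
        coords = np.array([[0, 0, 0], [2.0, 0, 0.0]])
        assert len(rin.detect_contacts(coords, atoms)) == 0

    def test_missing_element_metadata_rejected(self):
        atoms = make_atoms([(1, "GLY", "A", "CA", ""), (3, "GLY", "A", "CA", "C")])
        coords = np.zeros((2, 3))
        with pytest.raises(ValueError, match="element"):
            rin.detect_contacts(coords, atoms)


class TestBuildRin:
    def _three_residue_ensemble(self, frame_offsets):
        """Residues 1 and 3 have 3 atom pairs in range at offset 0, fewer when moved."""
        atoms = make_atoms(
            [
                (1, "GLY", "A", "CA", "C"),
                (1, "GLY", "A", "CB", "C"),
                (2, "GLY", "A", "CA", "C"),
                (3, "GLY", "A", "CA", "C"),
                (3, "GLY", "A", "CB", "C"),
            ]
        )
        base = np.array(
            [[0, 0, 0], [1.5, 0, 0], [50, 0, 0], [3.0, 0, 0], [4.4, 0, 0]], dtype=float
        )
        frames = []
        for off in frame_offsets:
            f = base.copy()
            f[3:, 0] += off  # push residue 3 away
            frames.append(f)
        return ensemble_from_frames(frames, atoms)

    def test_mean_weight_and_occupancy_hand_count(self):
        # offset 0: pairs (CA1-CA3)=3.0, (CB1-CA3)=1.5, (CB1-CB3)=2.9 -> 3 contacts
        # offset 2: (CA1-CA3)=5.0 out, (CB1-CA3)=3.5 in, (CB1-CB3)=4.9 out -> 1
        ens = self._three_residue_ensemble([0.0, 2.0])
        net = rin.build_rin(ens)
        assert len(net.edges) == 1
        edge = net.edges.iloc[0]
        assert edge["mean_weight"] == pytest.approx(2.0)
        assert edge["occupancy"] == pytest.approx(1.0)

    def test_partial_occupancy(self):
        # offset 1.2: only CB1-CA3 (2.7 A) in range, and only in frame 1 of 4
        ens = self._three_residue_ensemble([1.2, 30.0, 30.0, 30.0])
        net = rin.build_rin(ens)
        edge = net.edges.iloc[0]
        assert edge["mean_weight"] == pytest.approx(1 / 4)
        assert edge["occupancy"] == pytest.approx(0.25)

    def test_single_frame_identity(self):
        ens = self._three_residue_ensemble([0.0])
        edge = rin.build_rin(ens).edges.iloc[0]
        assert edge["mean_weight"] == pytest.approx(3.0)


class TestCentrality:
    def test_triangle_symmetric_dc(self):
        net = _net_from_edges(
            [(1, 2, "vdw", 1.0, 1.0), (2, 3, "vdw", 1.0, 1.0), (1, 3, "vdw", 1.0, 1.0)],
            [1, 2, 3],
        )
        dc = rin.degree_centrality(net)
        assert all(dc == 2.0)

    def test_star_weighted_degrees(self):
        net = _net_from_edges(
            [(1, 2, "vdw", 2.0, 1.0), (1, 3, "vdw", 3.0, 1.0), (1, 4, "vdw", 5.0, 1.0)],
            [1, 2, 3, 4],
        )
        dc = rin.degree_centrality(net)
        assert dc[1] == 10.0 and dc[2] == 2.0 and dc[3] == 3.0 and dc[4] == 5.0
        unweighted = rin.degree_centrality(net, weighted=False)
        assert unweighted[1] == 3.0

    def test_isolated_residues_zero(self):
        net = _net_from_edges([], [1, 2, 3])
        assert all(rin.degree_centrality(net) == 0.0)
        assert all(rin.betweenness_centrality(net) == 0.0)

    def test_path_betweenness(self):
        net = _net_from_edges(
            [(1, 2, "vdw", 1.0, 1.0), (2, 3, "vdw", 1.0, 1.0)], [1, 2, 3]
        )
        bc = rin.betweenness_centrality(net)
        assert bc[2] == pytest.approx(1.0)
        assert bc[1] == bc[3] == 0.0

    def test_star_center_betweenness(self):
        edges = [(1, leaf, "vdw", 1.0, 1.0) for leaf in (2, 3, 4, 5)]
        bc = rin.betweenness_centrality(_net_from_edges(edges, [1, 2, 3, 4, 5]))
        assert bc[1] == pytest.approx(6.0)  # all C(4,2) leaf pairs

    def test_nonpositive_weight_rejected(self):
        net = _net_from_edges([(1, 2, "vdw", 0.0, 1.0)], [1, 2])
        with pytest.raises(ValueError):
            rin.betweenness_centrality(net)

    @pytest.mark.parametrize("seed", range(12))
    def test_betweenness_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        g = random_weighted_graph(int(rng.integers(4, 9)), 0.5, rng)
        edges = [
            (i, j, "vdw", g[i][j]["weight"], 1.0) for i, j in g.edges
        ]
        net = _net_from_edges(edges, sorted(g.nodes))
        bc = rin.betweenness_centrality(net)
        oracle = enumerate_betweenness(g)
        for v in g.nodes:
            assert bc[v] == pytest.approx(oracle[v], abs=1e-9)

    def test_dc_conservation_on_generated_network(self, small_ensemble):
        net = rin.build_rin(small_ensemble)
        dc = rin.degree_centrality(net)
        assert dc.sum() == pytest.approx(2 * net.edges["mean_weight"].sum(), abs=1e-12)

    def test_permutation_invariance(self, small_ensemble):
        net = rin.build_rin(small_ensemble)
        dc = rin.degree_centrality(net)
        bc = rin.betweenness_centrality(net)
        # relabel residues by reversing the index space
        n = small_ensemble.n_residues
        atoms2 = small_ensemble.atoms.copy()
        atoms2["residue_index"] = n + 1 - atoms2["residue_index"]
        ens2 = ConformationalEnsemble(small_ensemble.coords, atoms2)
        net2 = rin.build_rin(ens2)
        dc2 = rin.degree_centrality(net2)
        bc2 = rin.betweenness_centrality(net2)
        for r in range(1, n + 1):
            assert dc2[n + 1 - r] == pytest.approx(dc[r], abs=1e-12)
            assert bc2[n + 1 - r] == pytest.approx(bc[r], abs=1e-9)


class TestConservationBinning:
    @pytest.mark.parametrize(
        "grade, expected",
        [(9, "high"), (8, "high"), (7, "intermediate"), (6, "intermediate"),
         (5, "variable"), (1, "variable")],
    )
    def test_bins(self, grade, expected):
        assert rin.bin_conservation(grade) == expected

    @pytest.mark.parametrize("grade", [0, 10, -1])
    def test_out_of_range_rejected(self, grade):
        with pytest.raises(ValueError):
            rin.bin_conservation(grade)


class TestHubClassification:
    def test_quadrant_rule(self):
        records = pd.DataFrame(
            {
                "residue": [1, 2, 3, 4],
                "DC": [25.0, 25.0, 10.0, 5.0],
                "BC": [1500.0, 10.0, 1500.0, 10.0],
            }
        )
        result = rin.classify_hubs(records)
        assert result.hubs == {1}
        assert result.quadrant_counts == {
            "both_high": 1, "dc_only": 1, "bc_only": 1, "both_low": 1,
        }

    def test_empty_input(self):
        empty = pd.DataFrame(columns=["residue", "DC", "BC"])
        assert rin.classify_hubs(empty).hubs == set()

    def test_planted_hub_recovered(self):
        ens = synthetic.make_hub_ensemble(n_residues=30, hub_residue=15, seed=1)
        net = rin.build_rin(ens)
        records = rin.residue_metric_records(net)
        # thresholds scaled to the fixture: upper quartiles of each metric
        result = rin.classify_hubs(
            records,
            dc_threshold=records["DC"].quantile(0.9),
            bc_threshold=records["BC"].quantile(0.9),
        )
        assert 15 in result.hubs


class TestMetricDistributions:
    def test_single_region_single_group(self):
        records = pd.DataFrame(
            {"residue": [1, 2], "DC": [1.0, 2.0], "BC": [0, 0], "region": ["helix"] * 2}
        )
        groups, summary = rin.metric_distributions(records, "region")
        assert list(groups) == ["helix"] and len(groups["helix"]) == 2

    def test_hand_computed_medians(self):
        records = pd.DataFrame(
            {
                "residue": range(1, 7),
                "DC": [1.0, 2.0, 3.0, 10.0, 20.0, 30.0],
                "BC": [0.0] * 6,
                "region": ["helix"] * 3 + ["beta"] * 3,
            }
        )
        _, summary = rin.metric_distributions(records, "region")
        med = dict(zip(summary["group"], summary["median"]))
        assert med == {"helix": 2.0, "beta": 20.0}

    def test_missing_attribute_rejected(self):
        records = pd.DataFrame({"residue": [1], "DC": [1.0], "BC": [0.0]})
        with pytest.raises(ValueError):
            rin.metric_distributions(records, "region")

    def test_urea_like_variance_inflation_lowers_degree(self):
        """Broader fluctuations (denaturant-like) should loosen packing."""
        rng = np.random.default_rng(0)
        modes = synthetic.random_orthonormal_modes(40, 1, rng)

        def median_dc(noise):
            spec = synthetic.EnsembleSpec(
                n_residues=20, n_frames=20, planted_modes=[(modes[0], 1.0)],
                isotropic_noise_sd=noise, seed=8,
            )
            net = rin.build_rin(synthetic.make_toy_ensemble(spec))
            return rin.degree_centrality(net).median()

        assert median_dc(0.05) > median_dc(1.0)


class TestFamilyAveraging:
    def _table(self, values):
        return pd.DataFrame(
            {
                "residue": range(1, len(values) + 1),
                "DC": values,
                "BC": [v * 10 for v in values],
            }
        )

    def test_single_protein_identity(self):
        table = self._table([1.0, 2.0, 3.0])
        out = rin.average_over_family({"p1": table}, {"p1": "AAA"})
        assert list(out["mean_DC"]) == [1.0, 2.0, 3.0]
        assert all(out["n_proteins"] == 1)

    def test_gap_rule(self):
        out = rin.average_over_family(
            {"p1": self._table([1.0, 2.0, 3.0]), "p2": self._table([5.0, 7.0])},
            {"p1": "AAA", "p2": "A-A"},
        )
        col2 = out[out["column"] == 2].iloc[0]
        assert col2["mean_DC"] == 2.0 and col2["n_proteins"] == 1

    def test_hand_mean(self):
        tables = {f"p{i}": self._table([v]) for i, v in enumerate([3.0, 5.0, 10.0])}
        aln = {name: "A" for name in tables}
        out = rin.average_over_family(tables, aln)
        assert out["mean_DC"].iloc[0] == pytest.approx(6.0)

    def test_mismatch_names_offender(self):
        with pytest.raises(ValueError, match="p2"):
            rin.average_over_family(
                {"p1": self._table([1.0]), "p2": self._table([1.0, 2.0])},
                {"p1": "A", "p2": "A-"},
            )


@settings(deadline=None, derandomize=True, max_examples=25)
@given(st.lists(st.tuples(st.integers(0, 7), st.integers(0, 7),
                          st.floats(0.1, 5.0)), max_size=15))
def test_dc_is_twice_total_edge_weight(pairs):
    """Sum of weighted degrees equals twice the pooled edge weight, always."""
    edges = {}
    for i, j, w in pairs:
        if i == j:
            continue
        key = (min(i, j) + 1, max(i, j) + 1)
        edges[key] = edges.get(key, 0.0) + w
    rows = [(i, j, "vdw", w, 1.0) for (i, j), w in edges.items()]
    net = _net_from_edges(rows, list(range(1, 9)))
    dc = rin.degree_centrality(net)
    assert dc.sum() == pytest.approx(2 * sum(edges.values()), rel=1e-12, abs=1e-12)
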