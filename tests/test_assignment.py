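"""Node labeling (majority / purity with rejection) and the three
classification rules."""

import numpy as np
import pytest

import hyperbin as hb
from hyperbin.classify import REJECT, Lineage
from hyperbin.errors import (
    ConfigurationError,
    InvalidParameterError,
    LineageValidationError,
)
from hyperbin.som import beam_search_bmu


def lin(*taxa):
    return Lineage(tuple(taxa))


@pytest.fixture()
def toy_model(rng):
    """A hand-built labeled model on a 1-ring lattice: prototypes at the
    corners of a simplex, one label table per rank."""
    lat = hb.build_lattice(8, 1)
    protos = np.zeros((9, 16))
    for i in range(9):
        protos[i, i] = 1.0  # mutually distant prototypes
    labels = {rank: [REJECT] * 9 for rank in hb.RANKS}
    for i, taxon in [(1, "A"), (2, "A"), (3, "B"), (4, "B")]:
        labels["superkingdom"][i] = "Bacteria"
        labels["phylum"][i] = taxon

    class Model:
        prototypes = protos
        lattice = lat
        node_labels = hb.NodeLabels(labels=labels, occupancy=np.zeros(9, dtype=int))
        classifier = hb.ClassifierConfig()

    return Model()


class TestLineage:
    def test_gap_rejected(self):
        with pytest.raises(LineageValidationError):
            Lineage(("Bacteria", "", "SomeClass"))

    def test_partial_depth_allowed(self):
        assert lin("Bacteria", "Nitrospirae").get("phylum") == "Nitrospirae"
        assert lin("Bacteria", "Nitrospirae").get("order") is None


class TestVoronoi:
    def test_features_on_prototypes_are_their_own_cells(self, toy_model):
        feats = [toy_model.prototypes[i] for i in (1, 3, 5)]
        cells = hb.voronoi_partition(feats, toy_model.prototypes,
                                     toy_model.lattice)
        assert cells == {1: [0], 3: [1], 5: [2]}

    def test_partition_property(self, toy_model, rng):
        feats = [rng.random(16) for _ in range(20)]
        cells = hb.voronoi_partition(feats, toy_model.prototypes,
                                     toy_model.lattice)
        members = sorted(i for cell in cells.values() for i in cell)
        assert members == list(range(20))

    def test_empty_features_rejected(self, toy_model):
        with pytest.raises(InvalidParameterError):
            hb.voronoi_partition([], toy_model.prototypes, toy_model.lattice)


class TestLabeling:
    lineages = [lin("Bacteria", "A")] * 3 + [lin("Bacteria", "B")]

    def test_majority(self):
        labels = hb.label_majority({1: [0, 1, 2, 3]}, self.lineages,
                                   "phylum", n_nodes=3)
        assert labels[1] == "A"
        assert labels[0] == REJECT  # empty cell

    def test_majority_tie_breaks_lexicographically(self):
        labels = hb.label_majority({0: [0, 3]}, self.lineages, "phylum", 1)
        assert labels[0] == "A"

    def test_purity_rejects_at_high_alpha(self):
        cells = {1: [0, 1, 2, 3]}
        assert hb.label_purity(cells, self.lineages, "phylum", 3, 0.8)[1] == REJECT
        assert hb.label_purity(cells, self.lineages, "phylum", 3, 0.5)[1] == "A"

    def test_pure_cell_survives_any_alpha_below_one(self):
        cells = {0: [0, 1]}
        assert hb.label_purity(cells, self.lineages, "phylum", 1, 0.99)[0] == "A"

    def test_purity_at_vanishing_alpha_equals_majority(self, rng):
        lineages = [lin("Bacteria", rng.choice(["A", "B", "C"]))
                    for _ in range(40)]
        cells = {int(n): list(members) for n, members in enumerate(
            np.array_split(rng.permutation(40), 5))}
        maj = hb.label_majority(cells, lineages, "phylum", 5)
        pur = hb.label_purity(cells, lineages, "phylum", 5, alpha=1e-9)
        assert maj == pur

    def test_rejection_monotone_in_alpha(self, rng):
        lineages = [lin("Bacteria", rng.choice(["A", "B"])) for _ in range(60)]
        cells = {int(n): list(members) for n, members in enumerate(
            np.array_split(rng.permutation(60), 6))}
        rejected_before: set = set()
        for alpha in (0.1, 0.3, 0.5, 0.7, 0.9):
            labels = hb.label_purity(cells, lineages, "phylum", 6, alpha)
            rejected = {i for i, lab in enumerate(labels) if lab == REJECT}
            assert rejected_before <= rejected
            rejected_before = rejected

    def test_alpha_out_of_range(self):
        with pytest.raises(InvalidParameterError):
            hb.label_purity({0: [0]}, self.lineages, "phylum", 1, 0.0)

    def test_members_without_the_rank_do_not_vote(self):
        lineages = [lin("Bacteria"), lin("Bacteria", "A")]
        labels = hb.label_majority({0: [0, 1]}, lineages, "phylum", 1)
        assert labels[0] == "A"
        none_at_rank = hb.label_majority({0: [0]}, lineages, "phylum", 1)
        assert none_at_rank[0] == REJECT


class TestClassifyRules:
    def test_nn_on_exact_prototype(self, toy_model):
        labels = toy_model.node_labels.for_rank("phylum")
        label, node, dist = hb.classify_nn(
            toy_model.prototypes[1], toy_model.prototypes, labels,
            toy_model.lattice)
        assert (label, node, dist) == ("A", 1, 0.0)

    def test_nn_rejection_passes_through(self, toy_model):
        labels = toy_model.node_labels.for_rank("phylum")
        label, node, _ = hb.classify_nn(
            toy_model.prototypes[7], toy_model.prototypes, labels,
            toy_model.lattice)
        assert node == 7 and label == REJECT

    def test_nn_tie_breaks_to_lowest_index(self, toy_model):
        labels = toy_model.node_labels.for_rank("phylum")
        x = np.zeros(16)  # equidistant from all ring-1 prototypes
        _, node, _ = hb.classify_nn(x, toy_model.prototypes, labels,
                                    toy_model.lattice)
        assert node == 1

    def test_thresh_below_and_above(self, toy_model):
        labels = toy_model.node_labels.for_rank("phylum")
        x = toy_model.prototypes[1] * 0.9  # distance 0.1-ish from node 1
        d = float(np.linalg.norm(x - toy_model.prototypes[1]))
        above, _, _ = hb.classify_thresh(
            x, toy_model.prototypes, labels, toy_model.lattice, beta=d / 2)
        below, _, _ = hb.classify_thresh(
            x, toy_model.prototypes, labels, toy_model.lattice, beta=d * 2)
        assert above == REJECT and below == "A"

    def test_thresh_infinite_beta_equals_nn(self, toy_model, rng):
        labels = toy_model.node_labels.for_rank("phylum")
        for _ in range(50):
            x = rng.random(16)
            nn = hb.classify_nn(x, toy_model.prototypes, labels,
                                toy_model.lattice)
            th = hb.classify_thresh(x, toy_model.prototypes, labels,
                                    toy_model.lattice, beta=np.inf)
            assert nn == th

    def test_thresh_requires_beta(self, toy_model):
        with pytest.raises(ConfigurationError):
            hb.classify_thresh(np.zeros(16), toy_model.prototypes,
                               toy_model.node_labels.for_rank("phylum"),
                               toy_model.lattice, beta=None)

    def test_nbrs_sibling_override(self, toy_model):
        # BMU node 1 ('A'); its ring siblings both labeled 'B' at
        # distances summing below 3 * d_bmu
        lat, protos = toy_model.lattice, toy_model.prototypes.copy()
        labels = ["_"] * 9
        prev, nxt = lat.nodes[1].ring_siblings
        labels[1], labels[prev], labels[nxt] = "A", "B", "B"
        # craft distances: d(x, u1)=1.0, siblings at 1.4 each
        protos[1] = np.r_[1.0, np.zeros(15)]
        x = np.zeros(16)
        protos[prev] = np.r_[0.0, 1.4, np.zeros(14)]
        protos[nxt] = np.r_[0.0, 0.0, 1.4, np.zeros(13)]
        for i in range(9):
            if i not in (1, prev, nxt):
                protos[i] = 50.0
        label, node, dist = hb.classify_nbrs(x, protos, labels, lat)
        assert node == 1 and dist == pytest.approx(1.0)
        assert label == "B"  # 1.4 + 1.4 < 3.0 and siblings agree

    def test_nbrs_disagreeing_siblings_fall_back_to_nn(self, toy_model):
        lat, protos = toy_model.lattice, toy_model.prototypes.copy()
        labels = ["_"] * 9
        prev, nxt = lat.nodes[1].ring_siblings
        labels[1], labels[prev], labels[nxt] = "A", "B", "C"
        protos[1] = np.r_[1.0, np.zeros(15)]
        protos[prev] = np.r_[0.0, 1.4, np.zeros(14)]
        protos[nxt] = np.r_[0.0, 0.0, 1.4, np.zeros(13)]
        for i in range(9):
            if i not in (1, prev, nxt):
                protos[i] = 50.0
        label, _, _ = hb.classify_nbrs(np.zeros(16), protos, labels, lat)
        assert label == "A"

    def test_nbrs_zero_distance_bmu_wins(self, toy_model):
        lat, protos = toy_model.lattice, toy_model.prototypes.copy()
        labels = ["A"] * 9
        labels[1] = "X"
        label, node, dist = hb.classify_nbrs(
            protos[1], protos, labels, lat)
        assert dist == 0.0 and label == "X" and node == 1


class TestEstimateBeta:
    def test_constant_list(self):
        assert hb.estimate_beta([1.0, 1.0, 1.0, 1.0], 0.5) == 1.0

    def test_interpolated_median(self):
        assert hb.estimate_beta(list(range(100)), 0.5) == pytest.approx(49.5)

    def test_open_interval_enforced(self):
        for q in (0.0, 1.0):
            with pytest.raises(InvalidParameterError):
                hb.estimate_beta([1.0], q)
        with pytest.raises(InvalidParameterError):
            hb.estimate_beta([], 0.5)


class TestAssignReads:
    def test_rejection_propagates_downward(self, toy_model):
        # node 1 labeled at superkingdom+phylum, rejected below
        a = hb.assign_reads([toy_model.prototypes[1]], toy_model)[0]
        assert a.predictions["superkingdom"] == "Bacteria"
        assert a.predictions["phylum"] == "A"
        assert a.predictions["class"] == REJECT
        assert a.predictions["order"] == REJECT
        assert a.lineage_path() == ["Bacteria", "A"]

    def test_no_gap_after_propagation(self, toy_model, rng):
        feats = [rng.random(16) for _ in range(30)]
        for a in hb.assign_reads(feats, toy_model):
            seen_reject = False
            for rank in hb.RANKS:
                if a.predictions[rank] == REJECT:
                    seen_reject = True
                else:
                    assert not seen_reject

    def test_empty_features(self, toy_model):
        assert hb.assign_reads([], toy_model) == []

    def test_pure_taxon_recovered_end_to_end(self, small_community, small_model):
        _, _, records, lineages = small_community
        assignments, skipped = hb.classify_records(records, small_model)
        assert not skipped
        correct = sum(
            a.predictions["phylum"] == lineages[a.read_id].get("phylum")
            for a in assignments
            if a.predictions["phylum"] != REJECT
        )
        assigned = sum(
            a.predictions["phylum"] != REJECT for a in assignments
        )
        assert assigned > 0.5 * len(assignments)
        assert correct / assigned >= 0.95
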