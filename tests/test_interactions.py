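"""Pairwise profiles, mediated triplet motifs, and group contact decomposition."""

from collections import Counter
from itertools import combinations

import numpy as np
import pytest

from coassembly.detect import Cluster, ContactGraph, find_clusters, contact_pairs
from coassembly.interactions import (
    TRIPLET_PATTERNS,
    ensemble_triplet_profile,
    group_contact_profile,
    mediated_triplet_counts,
    mediated_triplets,
    mediation_by_ions,
    pairwise_profile,
    triplet_label,
)
from coassembly.synthetic import generate_planted_configuration
from coassembly.topology import Kind, build_composition

from conftest import single_atom_frame


def graph_cluster(kinds, edges, box=500.0):
    """Build a frame + cluster with an exact prescribed contact graph."""
    # place components on a huge grid, then override the edge set directly
    pos = [[50.0 * i, 0, 0] for i in range(len(kinds))]
    frame = single_atom_frame(pos, box=box, kinds=kinds)
    edge_dict = {tuple(sorted(e)): 1.0 for e in edges}
    nodes = set()
    for e in edge_dict:
        nodes.update(e)
    graph = ContactGraph(n_components=len(kinds), edges=edge_dict, cutoff=3.5)
    clusters = find_clusters(graph)
    return frame, clusters


def brute_force_triplets(kinds, edges):
    """Independent enumeration over all (middle, flank pair) combinations."""
    adj = {i: set() for i in range(len(kinds))}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    counts = Counter()
    for mid in range(len(kinds)):
        if kinds[mid] not in (Kind.PEPTIDE, Kind.DRUG, Kind.ZN, Kind.NO3):
            continue
        flanks = [n for n in adj[mid] if kinds[n] in (Kind.PEPTIDE, Kind.DRUG)]
        for a, b in combinations(sorted(flanks), 2):
            counts[triplet_label(kinds[mid], kinds[a], kinds[b])] += 1
    return counts


def test_canonical_labels():
    assert triplet_label(Kind.NO3, Kind.DRUG, Kind.DRUG) == "DND"
    assert triplet_label(Kind.NO3, Kind.DRUG, Kind.PEPTIDE) == "PND"
    assert triplet_label(Kind.NO3, Kind.PEPTIDE, Kind.DRUG) == "PND"
    assert triplet_label(Kind.ZN, Kind.PEPTIDE, Kind.PEPTIDE) == "PZP"
    assert triplet_label(Kind.DRUG, Kind.PEPTIDE, Kind.PEPTIDE) == "PDP"
    assert triplet_label(Kind.PEPTIDE, Kind.DRUG, Kind.PEPTIDE) == "PPD"
    assert set(TRIPLET_PATTERNS) == {
        "PPP", "PDP", "PPD", "PDD", "DPD", "DDD",
        "PZP", "PZD", "DZD", "PNP", "PND", "DND",
    }


def test_minimal_pdp_motif():
    kinds = [Kind.PEPTIDE, Kind.DRUG, Kind.PEPTIDE]
    frame, clusters = graph_cluster(kinds, [(0, 1), (1, 2)])
    probs = mediated_triplets(clusters[0], frame)
    assert probs == {"PDP": 1.0}


def test_nitrate_star_motif_probabilities():
    # N middle contacting two drugs and one peptide: DND x1, PND x2
    kinds = [Kind.NO3, Kind.DRUG, Kind.DRUG, Kind.PEPTIDE]
    frame, clusters = graph_cluster(kinds, [(0, 1), (0, 2), (0, 3)])
    probs = mediated_triplets(clusters[0], frame)
    assert probs["DND"] == pytest.approx(1 / 3)
    assert probs["PND"] == pytest.approx(2 / 3)


def test_peptide_clique_counts_each_middle():
    kinds = [Kind.PEPTIDE] * 3
    frame, clusters = graph_cluster(kinds, [(0, 1), (1, 2), (0, 2)])
    counts = mediated_triplet_counts(clusters[0], frame)
    assert counts == Counter({"PPP": 3})


def test_small_cluster_returns_empty_table():
    kinds = [Kind.PEPTIDE, Kind.DRUG]
    frame, clusters = graph_cluster(kinds, [(0, 1)])
    assert mediated_triplets(clusters[0], frame) == {}


@pytest.mark.parametrize("seed", range(10))
def test_triplet_counts_match_exhaustive_enumeration(seed):
    rng = np.random.default_rng(seed)
    n = 14
    kinds = [list(Kind)[rng.integers(5)] for _ in range(n)]
    edges = [
        (i, j) for i in range(n) for j in range(i + 1, n) if rng.random() < 0.25
    ]
    if not edges:
        return
    frame, clusters = graph_cluster(kinds, edges)
    got = Counter()
    for c in clusters:
        got.update(mediated_triplet_counts(c, frame))
    assert got == brute_force_triplets(kinds, edges)


def test_pairwise_profile_single_edge():
    kinds = [Kind.PEPTIDE, Kind.DRUG]
    frame, clusters = graph_cluster(kinds, [(0, 1)])
    df = pairwise_profile(clusters, frame)
    assert len(df) == 1
    assert df.iloc[0]["probability"] == 1.0
    assert {df.iloc[0]["kind_a"], df.iloc[0]["kind_b"]} == {"PEPTIDE", "DRUG"}


def test_pairwise_profile_excludes_repulsive_pairs():
    kinds = [Kind.PEPTIDE, Kind.PEPTIDE, Kind.ZN, Kind.ZN]
    frame, clusters = graph_cluster(kinds, [(0, 1), (0, 2), (2, 3)])
    df = pairwise_profile(clusters, frame)
    pairs = {tuple(sorted((r.kind_a, r.kind_b))) for r in df.itertuples()}
    assert ("ZN", "ZN") not in pairs
    probs = dict(zip([tuple(sorted((r.kind_a, r.kind_b))) for r in df.itertuples()],
                     df["probability"]))
    assert probs[("PEPTIDE", "PEPTIDE")] == pytest.approx(0.5)
    assert probs[("PEPTIDE", "ZN")] == pytest.approx(0.5)
    assert df["probability"].sum() == pytest.approx(1.0, abs=1e-9)


@pytest.mark.parametrize("seed", [11, 42])
def test_pairwise_profile_matches_recount(seed):
    rng = np.random.default_rng(seed)
    n = 20
    kinds = [list(Kind)[rng.integers(5)] for _ in range(n)]
    edges = [
        (i, j) for i in range(n) for j in range(i + 1, n) if rng.random() < 0.2
    ]
    frame, clusters = graph_cluster(kinds, edges)
    df = pairwise_profile(clusters, frame)
    manual = Counter()
    cluster_edges = set()
    for c in clusters:
        cluster_edges |= set(c.edge_subgraph)
    for i, j in cluster_edges:
        ki, kj = kinds[i], kinds[j]
        if ki == kj and ki in (Kind.ZN, Kind.NO3):
            continue
        manual[tuple(sorted((ki.value, kj.value)))] += 1
    total = sum(manual.values())
    for a, b, n in zip(df["kind_a"], df["kind_b"], df["count"]):
        assert n == manual[tuple(sorted((a, b)))]
    if total:
        assert df["probability"].sum() == pytest.approx(1.0, abs=1e-9)


def test_triplet_probabilities_sum_to_one():
    rng = np.random.default_rng(3)
    n = 16
    kinds = [list(Kind)[rng.integers(4)] for _ in range(n)]
    edges = [
        (i, j) for i in range(n) for j in range(i + 1, n) if rng.random() < 0.3
    ]
    frame, clusters = graph_cluster(kinds, edges)
    for c in clusters:
        probs = mediated_triplets(c, frame)
        if probs:
            assert sum(probs.values()) == pytest.approx(1.0, abs=1e-9)
    ens = ensemble_triplet_profile(clusters, frame)
    if any(v for v in ens.values()):
        assert sum(ens.values()) == pytest.approx(1.0, abs=1e-9)


def test_ion_mediation_probabilities():
    # lone Zn bridging two peptides mediates; a single-neighbor Zn does not
    kinds = [Kind.ZN, Kind.PEPTIDE, Kind.PEPTIDE, Kind.ZN]
    frame, clusters = graph_cluster(kinds, [(0, 1), (0, 2), (2, 3)])
    med = mediation_by_ions(clusters, frame)
    assert med[Kind.ZN] == pytest.approx(0.5)       # one of two Zn mediates
    assert med[Kind.PEPTIDE] == pytest.approx(0.0)  # peptides have < 2 P/D contacts


def test_ion_mediation_matches_degree_recount():
    rng = np.random.default_rng(19)
    n = 15
    kinds = [list(Kind)[rng.integers(4)] for _ in range(n)]
    edges = [
        (i, j) for i in range(n) for j in range(i + 1, n) if rng.random() < 0.3
    ]
    frame, clusters = graph_cluster(kinds, edges)
    med = mediation_by_ions(clusters, frame)
    for kind in (Kind.PEPTIDE, Kind.DRUG, Kind.ZN, Kind.NO3):
        fracs = []
        for c in clusters:
            adj = {m: set() for m in c.members}
            for a, b in c.edge_subgraph:
                adj[a].add(b)
                adj[b].add(a)
            of_kind = [m for m in c.members if kinds[m] is kind]
            if not of_kind:
                continue
            mediating = sum(
                1 for m in of_kind
                if sum(1 for x in adj[m] if kinds[x] in (Kind.PEPTIDE, Kind.DRUG)) >= 2
            )
            fracs.append(mediating / len(of_kind))
        expected = float(np.mean(fracs)) if fracs else 0.0
        assert med[kind] == pytest.approx(expected, abs=1e-12)


def test_group_contacts_attribute_to_touching_group():
    comp = build_composition(4, 1, 0, 3, 70.0)
    frame, _ = generate_planted_configuration(
        comp, n_clusters=1,
        cluster_compositions=[{Kind.PEPTIDE: 2, Kind.DRUG: 1, Kind.ZN: 2}],
        seed=8,
    )
    clusters = find_clusters(contact_pairs(frame, 3.5))
    df = group_contact_profile(frame, clusters)
    assert not df.empty
    # per source group, probabilities sum to 1
    sums = df.groupby(["source_kind", "source_group"])["probability"].sum()
    np.testing.assert_allclose(sums.to_numpy(), 1.0, atol=1e-9)
    # only peptide/drug groups can be sources
    assert set(df["source_kind"]) <= {"PEPTIDE", "DRUG"}


def test_group_contacts_empty_when_no_clusters():
    frame = single_atom_frame([[0, 0, 0], [50, 0, 0]], box=100.0,
                              kinds=[Kind.PEPTIDE, Kind.ZN])
    df = group_contact_profile(frame, [])
    assert df.empty
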