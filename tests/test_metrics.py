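"""Cluster statistics: composition, encapsulation, Rg, and Shrake-Rupley SASA."""

import math

import numpy as np
import pytest

from coassembly.detect import Cluster, contact_pairs, find_clusters
from coassembly.metrics import (
    cluster_stats,
    composition_percentages,
    drug_encapsulation_percentage,
    encapsulation_summary,
    fibonacci_sphere,
    radius_of_gyration,
    ratios,
    sasa_ratio,
    shrake_rupley_sasa,
    size_binned_profiles,
)
from coassembly.synthetic import generate_planted_configuration
from coassembly.topology import Kind, build_composition

from conftest import single_atom_frame


def make_cluster(kinds, box=200.0, spacing=3.0):
    """Chain of single-atom components with the given kinds, plus its frame."""
    pos = [[i * spacing, 0, 0] for i in range(len(kinds))]
    frame = single_atom_frame(pos, box=box, kinds=kinds)
    clusters = find_clusters(contact_pairs(frame, spacing + 0.5))
    assert len(clusters) == 1
    return frame, clusters[0]


def test_composition_percentages_direct_count():
    frame, cluster = make_cluster([Kind.PEPTIDE, Kind.PEPTIDE, Kind.ZN, Kind.NO3])
    pct = composition_percentages(cluster, frame)
    assert pct[Kind.PEPTIDE] == 50.0
    assert pct[Kind.ZN] == 25.0
    assert pct[Kind.NO3] == 25.0
    assert pct[Kind.DRUG] == 0.0
    assert sum(pct.values()) == pytest.approx(100.0, abs=1e-6)


def test_composition_all_peptide():
    frame, cluster = make_cluster([Kind.PEPTIDE] * 5)
    assert composition_percentages(cluster, frame)[Kind.PEPTIDE] == 100.0


@pytest.mark.parametrize("seed", [2, 9])
def test_composition_matches_brute_force_tally(seed):
    rng = np.random.default_rng(seed)
    kinds = [list(Kind)[rng.integers(4)] for _ in range(20)]
    frame, cluster = make_cluster(kinds)
    pct = composition_percentages(cluster, frame)
    for k in Kind:
        manual = 100.0 * sum(1 for kk in kinds if kk is k) / len(kinds)
        assert pct[k] == pytest.approx(manual)


def test_encapsulation_summary_direct_counts():
    frames_and_clusters = [
        make_cluster([Kind.PEPTIDE] + [Kind.DRUG] * nd + [Kind.ZN])
        for nd in (0, 1, 2, 3)
    ]
    clusters = [c for _, c in frames_and_clusters]
    # use per-cluster frames via frame_index mapping
    frames = [f for f, _ in frames_and_clusters]
    clusters = [
        Cluster(members=c.members, frame_index=i, edge_subgraph=c.edge_subgraph)
        for i, c in enumerate(clusters)
    ]
    p0, p1, p2 = encapsulation_summary(clusters, frames)
    assert (p0, p1, p2) == (0.25, 0.75, 0.50)
    assert p0 + p1 == pytest.approx(1.0)
    assert p2 <= p1


def test_encapsulation_summary_no_drugs_and_empty():
    frame, cluster = make_cluster([Kind.PEPTIDE, Kind.ZN])
    assert encapsulation_summary([cluster], frame) == (1.0, 0.0, 0.0)
    with pytest.raises(ValueError):
        encapsulation_summary([], frame)


def test_drug_encapsulation_percentage():
    frame, cluster = make_cluster([Kind.DRUG] * 6 + [Kind.PEPTIDE])
    assert drug_encapsulation_percentage(cluster, frame, 12) == 50.0
    assert drug_encapsulation_percentage(cluster, frame, 6) == 100.0
    frame2, cluster2 = make_cluster([Kind.PEPTIDE, Kind.ZN])
    assert drug_encapsulation_percentage(cluster2, frame2, 12) == 0.0
    with pytest.raises(ValueError):
        drug_encapsulation_percentage(cluster, frame, 0)


def test_member_ratios():
    frame, cluster = make_cluster([Kind.PEPTIDE] * 4 + [Kind.DRUG] + [Kind.ZN] * 4)
    assert ratios(cluster, frame) == (0.25, 1.0)
    frame2, cluster2 = make_cluster(
        [Kind.PEPTIDE] * 10 + [Kind.DRUG] * 3 + [Kind.ZN] * 8
    )
    dp, zp = ratios(cluster2, frame2)
    assert dp == pytest.approx(0.3)
    assert zp == pytest.approx(0.8)
    frame3, cluster3 = make_cluster([Kind.DRUG, Kind.ZN])
    with pytest.warns(UserWarning):
        dp, zp = ratios(cluster3, frame3)
    assert math.isnan(dp) and math.isnan(zp)


def test_radius_of_gyration_closed_forms():
    assert radius_of_gyration(np.array([[1.0, 2.0, 3.0]])) == 0.0
    # two atoms 2 A apart: Rg = half the separation
    assert radius_of_gyration(np.array([[0, 0, 0], [2.0, 0, 0]])) == pytest.approx(1.0)


def test_radius_of_gyration_matches_direct_formula():
    rng = np.random.default_rng(31)
    coords = rng.normal(scale=4.0, size=(50, 3))
    manual = math.sqrt(
        np.mean(np.sum((coords - coords.mean(axis=0)) ** 2, axis=1))
    )
    assert radius_of_gyration(coords) == pytest.approx(manual, abs=1e-12)


def test_radius_of_gyration_rigid_motion_invariant():
    rng = np.random.default_rng(7)
    coords = rng.normal(size=(30, 3))
    base = radius_of_gyration(coords)
    # random rotation + translation
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    R = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    moved = coords @ R.T + rng.uniform(-50, 50, 3)
    assert radius_of_gyration(moved) == pytest.approx(base, abs=1e-9)


def test_fibonacci_points_lie_on_unit_sphere():
    pts = fibonacci_sphere(960)
    np.testing.assert_allclose(np.linalg.norm(pts, axis=1), 1.0, atol=1e-12)
    # quasi-uniform: centroid near origin
    assert np.linalg.norm(pts.mean(axis=0)) < 1e-2


def test_single_sphere_sasa_closed_form():
    r, rp = 1.7, 2.6
    area = shrake_rupley_sasa(np.zeros((1, 3)), np.array([r]), rp, 960)[0]
    assert area == pytest.approx(4 * math.pi * (r + rp) ** 2, rel=0.01)


def test_fully_enclosed_sphere_is_buried():
    r, rp = 1.7, 2.6
    shell_dirs = fibonacci_sphere(40)
    coords = np.vstack([np.zeros(3), 2.5 * shell_dirs])
    radii = np.full(len(coords), r)
    area = shrake_rupley_sasa(coords, radii, rp, 960, atom_subset=[0])[0]
    assert area < 0.01 * 4 * math.pi * (r + rp) ** 2


def test_two_sphere_buried_cap_closed_form():
    """Equal spheres at distance d bury a cap of height R - d/2 on each."""
    r, rp = 1.7, 2.6
    R = r + rp
    d = 5.0
    assert d < 2 * R
    coords = np.array([[0, 0, 0], [d, 0, 0]])
    areas = shrake_rupley_sasa(coords, np.array([r, r]), rp, 960)
    cap = 2 * math.pi * R * (R - d / 2)
    expected = 4 * math.pi * R * R - cap
    for a in areas:
        assert a == pytest.approx(expected, rel=0.02)


def test_sasa_monotone_in_neighbors():
    """Adding an occluding atom never increases exposure."""
    rng = np.random.default_rng(4)
    base = np.zeros((1, 3))
    neighbors = rng.uniform(-4, 4, size=(8, 3))
    radii = np.full(9, 1.7)
    prev = math.inf
    for k in range(9):
        coords = np.vstack([base, neighbors[:k]])
        a = shrake_rupley_sasa(coords, radii[: k + 1], 2.6, 480, atom_subset=[0])[0]
        assert a <= prev + 1e-12
        prev = a


def test_sasa_ratio_of_planted_cluster_members():
    comp = build_composition(6, 0, 0, 2, 70.0)
    frame, truth = generate_planted_configuration(
        comp, n_clusters=1,
        cluster_compositions=[{Kind.PEPTIDE: 4, Kind.ZN: 2}], seed=3,
    )
    cluster = find_clusters(contact_pairs(frame, 3.5))[0]
    for m in sorted(cluster.members):
        ratio = sasa_ratio(frame, cluster, m, n_points=240)
        assert 0.0 <= ratio <= 100.0
        assert ratio < 100.0  # every member touches a neighbor
    with pytest.raises(ValueError):
        sasa_ratio(frame, cluster, max(cluster.members) + 1, n_points=240)


def test_cluster_stats_and_size_binned_profiles():
    comp = build_composition(12, 4, 0, 6, 80.0)
    frame, _ = generate_planted_configuration(
        comp, n_clusters=2,
        cluster_compositions=[
            {Kind.PEPTIDE: 5, Kind.DRUG: 2, Kind.ZN: 3},
            {Kind.PEPTIDE: 3, Kind.NO3: 2},
        ],
        seed=5,
    )
    clusters = find_clusters(contact_pairs(frame, 3.5))
    stats = [
        cluster_stats(frame, c, total_drugs=4, sasa_points=120) for c in clusters
    ]
    sizes = sorted(s.size for s in stats)
    assert sizes == [5, 10]
    wide = size_binned_profiles(stats, bin_width=40)
    assert wide["n_clusters"].sum() == 2 and len(wide) == 1
    assert bool(wide["sd_defined"].iloc[0])
    narrow = size_binned_profiles(stats, bin_width=2)
    # singleton bins flag undefined sd and report it as 0
    assert (~narrow["sd_defined"]).all()
    assert (narrow.filter(like="sd_").drop(columns=["sd_defined"]) == 0).all().all()


def test_size_binned_profiles_binning_semantics():
    class S:  # minimal stats stub matching the table builder's fields
        def __init__(self, size):
            self.frame_index = 0
            self.size = size
            self.composition_pct = {k: 0.0 for k in Kind}
            self.n_drugs = 0
            self.drug_encap_pct = 0.0
            self.drug_peptide_ratio = 0.0
            self.zn_peptide_ratio = 0.0
            self.rg = 1.0
            self.sasa_ratio = {k: 50.0 for k in Kind}

    table = size_binned_profiles([S(31), S(35), S(72)], bin_width=40)
    assert list(table["n_clusters"]) == [2, 1]
    assert list(table["bin_lo"]) == [31, 71]
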