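"""Pairwise, triplet-motif, and chemical-group interaction profiles.

Pairwise profiles count contact edges by component-kind pair, excluding the
electrostatically repulsive like-ion pairs Zn2+-Zn2+ and NO3--NO3-.
Mediated triplets capture one component (peptide, drug, Zn2+, or NO3-)
simultaneously in contact with two peptide/drug flanks; labels are written
flank-middle-flank with a P-flank first (e.g. DND = two drugs bridged by a
nitrate, DZD = two drugs bridged by a zinc, PND = a peptide and a drug
bridged by a nitrate).  Chemical-group profiles attribute peptide/drug
contacts to the named groups their atoms belong to.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .detect import Cluster, ContactGraph, minimum_image_displacement
from .topology import Kind, REPULSIVE_SELF_PAIRS
from .trajectory import Frame

#: allowed middle kinds for mediated triplets
MIDDLE_KINDS = (Kind.PEPTIDE, Kind.DRUG, Kind.ZN, Kind.NO3)
#: canonical motif label order: molecule middles then ion middles
TRIPLET_PATTERNS = (
    "PPP", "PDP", "PPD", "PDD", "DPD", "DDD",
    "PZP", "PZD", "DZD", "PNP", "PND", "DND",
)


def triplet_label(middle: Kind, flank_a: Kind, flank_b: Kind) -> str:
    """Canonical flank-middle-flank label; P-flank written first."""
    letters = sorted(
        (flank_a.letter, flank_b.letter), key=lambda s: 0 if s == "P" else 1
    )
    return letters[0] + middle.letter + letters[1]


def pairwise_profile(clusters, frames) -> pd.DataFrame:
    """Contact-edge distribution over unordered kind pairs.

    Tallies every contact edge of every cluster by its endpoint kinds,
    drops Zn-Zn and NO3-NO3 edges, and normalizes to sum 1.  Also reports,
    for each endpoint kind, the conditional distribution over partner kinds.
    """
    clusters = list(clusters)
    if not clusters:
        raise ValueError("pairwise profile of an empty cluster list")
    counts: Counter = Counter()
    for c in clusters:
        frame = frames if isinstance(frames, Frame) else frames[c.frame_index]
        for (i, j) in c.edge_subgraph:
            ki, kj = frame.component_kind[i], frame.component_kind[j]
            if ki == kj and ki in REPULSIVE_SELF_PAIRS:
                continue
            pair = tuple(sorted((ki.value, kj.value)))
            counts[pair] += 1
    total = sum(counts.values())
    rows = []
    for (a, b), n in sorted(counts.items()):
        rows.append(
            {
                "kind_a": a,
                "kind_b": b,
                "count": n,
                "probability": n / total if total else 0.0,
            }
        )
    df = pd.DataFrame(rows, columns=["kind_a", "kind_b", "count", "probability"])
    for kind in (Kind.PEPTIDE, Kind.DRUG):
        sub_total = sum(
            n for (a, b), n in counts.items() if kind.value in (a, b)
        )
        col = f"p_given_{kind.value.lower()}"
        df[col] = [
            (n / sub_total if sub_total and kind.value in (a, b) else 0.0)
            for a, b, n in zip(df["kind_a"], df["kind_b"], df["count"])
        ]
    return df


def mediated_triplet_counts(cluster: Cluster, frame: Frame) -> Counter:
    """Exhaustive triplet tally: every (middle, unordered flank pair).

    The middle may be a peptide, drug, Zn2+, or NO3-; flanks are
    peptide/drug neighbors of the middle in the contact graph.  Flanks need
    not be in contact with each other, and every neighbor pair counts (a
    3-clique of peptides yields PPP three times, once per middle).
    """
    adj: dict = defaultdict(list)
    for (i, j) in cluster.edge_subgraph:
        adj[i].append(j)
        adj[j].append(i)
    counts: Counter = Counter()
    for mid in cluster.members:
        mk = frame.component_kind[mid]
        if mk not in MIDDLE_KINDS:
            continue
        flanks = [
            n for n in adj[mid]
            if frame.component_kind[n] in (Kind.PEPTIDE, Kind.DRUG)
        ]
        for a, b in combinations(flanks, 2):
            counts[
                triplet_label(mk, frame.component_kind[a], frame.component_kind[b])
            ] += 1
    return counts


def mediated_triplets(cluster: Cluster, frame: Frame) -> dict:
    """Per-cluster triplet probabilities (normalized over observed patterns).

    Clusters with fewer than three members, or no triplets, return an empty
    table.
    """
    if cluster.size < 3:
        return {}
    counts = mediated_triplet_counts(cluster, frame)
    total = sum(counts.values())
    if total == 0:
        return {}
    return {p: counts[p] / total for p in TRIPLET_PATTERNS if counts[p]}


def ensemble_triplet_profile(clusters, frames) -> dict:
    """Equal-weight average of per-cluster triplet probabilities.

    Each cluster with at least one triplet contributes its own normalized
    distribution; clusters without triplets are skipped.  All 12 canonical
    patterns are reported (absent ones as 0).
    """
    acc = {p: 0.0 for p in TRIPLET_PATTERNS}
    n_used = 0
    for c in clusters:
        frame = frames if isinstance(frames, Frame) else frames[c.frame_index]
        probs = mediated_triplets(c, frame)
        if not probs:
            continue
        n_used += 1
        for p, v in probs.items():
            acc[p] += v
    if n_used == 0:
        return dict(acc)
    return {p: v / n_used for p, v in acc.items()}


def pooled_triplet_profile(clusters, frames) -> dict:
    """Alternative normalization: pool raw triplet counts over all clusters."""
    counts: Counter = Counter()
    for c in clusters:
        frame = frames if isinstance(frames, Frame) else frames[c.frame_index]
        counts.update(mediated_triplet_counts(c, frame))
    total = sum(counts.values())
    return {
        p: (counts[p] / total if total else 0.0) for p in TRIPLET_PATTERNS
    }


def mediation_by_ions(clusters, frames) -> dict:
    """Probability of each kind to act as a mediator, averaged over clusters.

    A component mediates when it has at least two peptide/drug neighbors in
    the contact graph.  For each kind the per-cluster fraction of mediating
    components of that kind is averaged over clusters containing the kind.
    """
    clusters = list(clusters)
    if not clusters:
        raise ValueError("mediation profile of an empty cluster list")
    sums = {k: 0.0 for k in MIDDLE_KINDS}
    denom = {k: 0 for k in MIDDLE_KINDS}
    for c in clusters:
        frame = frames if isinstance(frames, Frame) else frames[c.frame_index]
        adj: dict = defaultdict(list)
        for (i, j) in c.edge_subgraph:
            adj[i].append(j)
            adj[j].append(i)
        per_kind_total: Counter = Counter()
        per_kind_mediators: Counter = Counter()
        for m in c.members:
            k = frame.component_kind[m]
            if k not in MIDDLE_KINDS:
                continue
            per_kind_total[k] += 1
            n_pd = sum(
                1
                for n in adj[m]
                if frame.component_kind[n] in (Kind.PEPTIDE, Kind.DRUG)
            )
            if n_pd >= 2:
                per_kind_mediators[k] += 1
        for k in MIDDLE_KINDS:
            if per_kind_total[k]:
                sums[k] += per_kind_mediators[k] / per_kind_total[k]
                denom[k] += 1
    return {
        k: (sums[k] / denom[k] if denom[k] else 0.0) for k in MIDDLE_KINDS
    }


def group_contact_profile(frame: Frame, clusters, cutoff: float = 3.5) -> pd.DataFrame:
    """Normalized contact probabilities of chemical groups with partners.

    A source group (of a peptide or drug) contacts a partner when any of
    its atoms lies within the cutoff of any partner atom in the same
    cluster.  Partners are ions (reported by kind) or named groups of other
    peptide/drug molecules.  For each source group, probabilities are
    normalized over its partners to sum to 1.  Missing group labels raise.
    """
    if any(g is None or g == "" for g in frame.atom_group):
        missing = [i for i, g in enumerate(frame.atom_group) if not g]
        raise ValueError(f"atoms without group labels: {missing[:10]}")
    L = frame.box_length
    pos = frame.coords % L
    tree = cKDTree(pos, boxsize=L)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    member_sets = [set(c.members) for c in clusters]
    in_any = set().union(*member_sets) if member_sets else set()
    counts: Counter = Counter()
    if len(pairs):
        delta = minimum_image_displacement(pos[pairs[:, 0]] - pos[pairs[:, 1]], L)
        dist = np.linalg.norm(delta, axis=1)
        pairs = pairs[dist < cutoff]
    seen: set = set()
    for ai, aj in pairs:
        ci, cj = int(frame.atom_component[ai]), int(frame.atom_component[aj])
        if ci == cj or ci not in in_any or cj not in in_any:
            continue
        if not any(ci in s and cj in s for s in member_sets):
            continue
        for src_atom, dst_atom, src_comp, dst_comp in (
            (ai, aj, ci, cj), (aj, ai, cj, ci)
        ):
            src_kind = frame.component_kind[src_comp]
            if src_kind not in (Kind.PEPTIDE, Kind.DRUG):
                continue
            src_group = frame.atom_group[src_atom]
            dst_kind = frame.component_kind[dst_comp]
            if dst_kind in (Kind.ZN, Kind.NO3, Kind.CL):
                partner = dst_kind.value
            else:
                partner = frame.atom_group[dst_atom]
            # one contact per (source group instance, partner instance)
            key = (src_comp, src_group, dst_comp, partner)
            if key in seen:
                continue
            seen.add(key)
            counts[(src_kind.value, src_group, partner)] += 1
    rows = []
    group_totals: Counter = Counter()
    for (skind, sgroup, partner), n in counts.items():
        group_totals[(skind, sgroup)] += n
    for (skind, sgroup, partner), n in sorted(counts.items()):
        rows.append(
            {
                "source_kind": skind,
                "source_group": sgroup,
                "partner": partner,
                "count": n,
                "probability": n / group_totals[(skind, sgroup)],
            }
        )
    return pd.DataFrame(
        rows, columns=["source_kind", "source_group", "partner", "count", "probability"]
    )
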