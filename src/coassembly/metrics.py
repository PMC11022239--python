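"""Per-cluster structural statistics.

For every detected cluster the analysis reports: percentage composition
per component kind, drug-encapsulation summaries, drug:peptide and
Zn:peptide number ratios, the radius of gyration of the unwrapped cluster,
and per-component solvent-accessible surface-area (SASA) burial ratios.
SASA uses the Shrake-Rupley method with a deterministic Fibonacci-lattice
point set, so results are exactly reproducible; the burial ratio divides a
component's SASA within the cluster by its SASA in isolation (100% = fully
exposed).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .detect import Cluster, unwrap_cluster
from .topology import Kind
from .trajectory import Frame


@dataclass
class ClusterStats:
    """Derived metrics for one cluster."""

    frame_index: int
    size: int
    composition_pct: dict            # Kind -> % of members
    n_drugs: int
    drug_encap_pct: float            # % of all system drugs in this cluster
    drug_peptide_ratio: float        # nan when the cluster has no peptide
    zn_peptide_ratio: float
    rg: float                        # A
    sasa_ratio: dict                 # Kind -> mean % exposure of that kind


def composition_percentages(cluster: Cluster, frame: Frame) -> dict:
    """Percentage of cluster members per kind; sums to 100."""
    if not cluster.members:
        raise ValueError("cluster must be nonempty")
    counts = {k: 0 for k in Kind}
    for m in cluster.members:
        counts[frame.component_kind[m]] += 1
    return {k: 100.0 * counts[k] / cluster.size for k in Kind}


def member_kind_counts(cluster: Cluster, frame: Frame) -> dict:
    counts = {k: 0 for k in Kind}
    for m in cluster.members:
        counts[frame.component_kind[m]] += 1
    return counts


def encapsulation_summary(clusters, frames) -> tuple:
    """(P_no_drug, P_at_least_one, P_at_least_two) over a cluster list.

    Fractions of clusters containing zero, at least one, and at least two
    drug members.  ``frames`` may be a single Frame (applied to all
    clusters) or a sequence indexed by ``cluster.frame_index``.
    """
    clusters = list(clusters)
    if not clusters:
        raise ValueError("encapsulation summary of an empty cluster list")
    n0 = n1 = n2 = 0
    for c in clusters:
        frame = frames if isinstance(frames, Frame) else frames[c.frame_index]
        nd = member_kind_counts(c, frame)[Kind.DRUG]
        if nd == 0:
            n0 += 1
        if nd >= 1:
            n1 += 1
        if nd >= 2:
            n2 += 1
    n = len(clusters)
    return n0 / n, n1 / n, n2 / n


def drug_encapsulation_percentage(cluster: Cluster, frame: Frame, total_drugs: int) -> float:
    """Percent of all drugs in the system that sit inside this cluster."""
    if total_drugs <= 0:
        raise ValueError("total_drugs must be positive")
    nd = member_kind_counts(cluster, frame)[Kind.DRUG]
    return 100.0 * nd / total_drugs


def ratios(cluster: Cluster, frame: Frame) -> tuple:
    """(drug:peptide, Zn:peptide) number ratios; NaN when no peptide."""
    counts = member_kind_counts(cluster, frame)
    npep = counts[Kind.PEPTIDE]
    if npep == 0:
        warnings.warn("cluster has no peptides; ratios undefined", stacklevel=2)
        return math.nan, math.nan
    return counts[Kind.DRUG] / npep, counts[Kind.ZN] / npep


def radius_of_gyration(coords: np.ndarray) -> float:
    """Root-mean-square atom distance from the centroid (uniform weights).

    ``coords`` must be unwrapped (contiguous) cluster coordinates.
    """
    coords = np.asarray(coords, dtype=float)
    centroid = coords.mean(axis=0)
    return float(np.sqrt(((coords - centroid) ** 2).sum(axis=1).mean()))


def fibonacci_sphere(n_points: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere point set (Fibonacci lattice)."""
    i = np.arange(n_points, dtype=float)
    phi = math.pi * (3.0 - math.sqrt(5.0))  # golden angle
    z = 1.0 - (2.0 * i + 1.0) / n_points
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    theta = phi * i
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def shrake_rupley_sasa(
    coords: np.ndarray,
    radii: np.ndarray,
    probe_radius: float = 2.6,
    n_points: int = 960,
    atom_subset=None,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area (A^2), Shrake-Rupley.

    Each atom is inflated by the probe radius and sampled with ``n_points``
    Fibonacci-lattice sphere points; a point is accessible when it lies
    outside every other inflated atom.  ``atom_subset`` restricts which
    atoms' areas are returned (occluders are always all atoms given).
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float) + probe_radius
    if np.any(radii <= 0):
        raise ValueError("inflated radii must be positive")
    n = len(coords)
    sphere = fibonacci_sphere(n_points)
    targets = np.arange(n) if atom_subset is None else np.asarray(atom_subset)
    tree = cKDTree(coords)
    out = np.zeros(len(targets))
    rmax = radii.max()
    for t, ai in enumerate(targets):
        ri = radii[ai]
        pts = coords[ai] + ri * sphere
        neigh = [j for j in tree.query_ball_point(coords[ai], ri + rmax) if j != ai]
        if neigh:
            nc = coords[neigh]
            nr = radii[neigh]
            d2 = ((pts[:, None, :] - nc[None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < (nr**2)[None, :]).any(axis=1)
            exposed = np.count_nonzero(~buried)
        else:
            exposed = n_points
        out[t] = 4.0 * math.pi * ri * ri * exposed / n_points
    return out


def sasa_ratio(
    frame: Frame,
    cluster: Cluster,
    component: int,
    probe_radius: float = 2.6,
    n_points: int = 960,
    unwrapped: np.ndarray | None = None,
) -> float:
    """Percent SASA of one component in its cluster vs. isolated.

    Occluders are the atoms of the cluster only (solvent is implicit and
    non-cluster components are excluded); the denominator is the same
    component with every other atom removed, so 100% means fully exposed.
    """
    if component not in cluster.members:
        raise ValueError("component is not a member of the cluster")
    coords = unwrap_cluster(frame, cluster) if unwrapped is None else unwrapped
    members = sorted(cluster.members)
    atom_idx = np.concatenate([frame.component_atoms(m) for m in members])
    own = frame.component_atoms(component)
    cluster_coords = coords[atom_idx]
    cluster_radii = frame.atom_radius[atom_idx]
    local = np.nonzero(np.isin(atom_idx, own))[0]
    in_cluster = shrake_rupley_sasa(
        cluster_coords, cluster_radii, probe_radius, n_points, atom_subset=local
    ).sum()
    isolated = shrake_rupley_sasa(
        coords[own], frame.atom_radius[own], probe_radius, n_points
    ).sum()
    if isolated <= 0:
        raise ValueError("isolated SASA is zero; radii must be positive")
    return 100.0 * in_cluster / isolated


def cluster_stats(
    frame: Frame,
    cluster: Cluster,
    total_drugs: int | None = None,
    probe_radius: float = 2.6,
    sasa_points: int = 960,
    compute_sasa: bool = True,
) -> ClusterStats:
    """Assemble all per-cluster metrics in one pass."""
    counts = member_kind_counts(cluster, frame)
    total_drugs = total_drugs if total_drugs is not None else frame.kind_counts()[Kind.DRUG]
    unwrapped = unwrap_cluster(frame, cluster)
    atom_idx = np.concatenate(
        [frame.component_atoms(m) for m in sorted(cluster.members)]
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        dp, zp = ratios(cluster, frame)
    sasa = {k: math.nan for k in Kind}
    if compute_sasa:
        per_kind: dict = {k: [] for k in Kind}
        for m in sorted(cluster.members):
            r = sasa_ratio(
                frame, cluster, m, probe_radius, sasa_points, unwrapped=unwrapped
            )
            per_kind[frame.component_kind[m]].append(r)
        sasa = {
            k: (float(np.mean(v)) if v else math.nan) for k, v in per_kind.items()
        }
    return ClusterStats(
        frame_index=cluster.frame_index,
        size=cluster.size,
        composition_pct=composition_percentages(cluster, frame),
        n_drugs=counts[Kind.DRUG],
        drug_encap_pct=(
            drug_encapsulation_percentage(cluster, frame, total_drugs)
            if total_drugs > 0
            else math.nan
        ),
        drug_peptide_ratio=dp,
        zn_peptide_ratio=zp,
        rg=radius_of_gyration(unwrapped[atom_idx]),
        sasa_ratio=sasa,
    )


def stats_frame(stats_list) -> pd.DataFrame:
    """Flatten ClusterStats into a tidy table (one row per cluster)."""
    rows = []
    for s in stats_list:
        row = {
            "frame": s.frame_index,
            "size": s.size,
            "n_drugs": s.n_drugs,
            "drug_encap_pct": s.drug_encap_pct,
            "drug_peptide_ratio": s.drug_peptide_ratio,
            "zn_peptide_ratio": s.zn_peptide_ratio,
            "rg": s.rg,
        }
        for k in Kind:
            row[f"pct_{k.value.lower()}"] = s.composition_pct[k]
            row[f"sasa_{k.value.lower()}"] = s.sasa_ratio[k]
        rows.append(row)
    return pd.DataFrame(rows)


def size_binned_profiles(stats_list, bin_width: int = 10) -> pd.DataFrame:
    """Per size-bin cluster count and mean +/- sd of each metric.

    Bins are half-open ``[lo, lo + bin_width)`` starting at the smallest
    observed size.  A bin with a single cluster reports sd 0 and
    ``sd_defined = False``.
    """
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    df = stats_frame(stats_list)
    if df.empty:
        return pd.DataFrame()
    lo0 = int(df["size"].min())
    df = df.assign(bin_lo=lo0 + ((df["size"] - lo0) // bin_width) * bin_width)
    metric_cols = [
        c for c in df.columns if c not in ("frame", "bin_lo") and df[c].dtype != object
    ]
    out = []
    for lo, grp in df.groupby("bin_lo"):
        row = {
            "bin_lo": int(lo),
            "bin_hi": int(lo + bin_width - 1),
            "n_clusters": len(grp),
            "sd_defined": len(grp) > 1,
        }
        for c in metric_cols:
            row[f"mean_{c}"] = float(grp[c].mean())
            row[f"sd_{c}"] = float(grp[c].std(ddof=1)) if len(grp) > 1 else 0.0
        out.append(row)
    return pd.DataFrame(out).sort_values("bin_lo").reset_index(drop=True)
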