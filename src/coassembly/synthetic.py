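"""Synthetic configuration generators standing in for MD trajectories.

Two generators produce :class:`~coassembly.trajectory.Frame` objects with
the statistical structure the cluster analysis assumes:

``generate_planted_configuration``
    places components so that a known partition into contact clusters holds
    exactly (an oracle for the detector), with guaranteed separation
    between planted clusters and scattered components.

``generate_mc_trajectory``
    runs a coarse-grained Metropolis Monte Carlo co-assembly process with
    square-well kind-pair affinities.  Tuning which pairs attract emulates
    qualitatively different drugs: ones whose encapsulation is driven by
    nitrate coordination, ones driven by zinc coordination, and ones that
    barely assemble at all.

Components are rigid bodies built from coarse pseudo-atom templates: the
cyclic dipeptide is 10 pseudo-atoms (a diketopiperazine ring plus two
imidazole side groups), drugs are 8 pseudo-atoms with charged/polar/
hydrophobic groups, Zn2+ and Cl- are single atoms and NO3- is four.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .topology import Kind, SystemComposition
from .trajectory import Frame

KIND_ORDER = (Kind.PEPTIDE, Kind.DRUG, Kind.ZN, Kind.NO3, Kind.CL)
_KIND_INDEX = {k: i for i, k in enumerate(KIND_ORDER)}


@dataclass(frozen=True)
class MoleculeTemplate:
    """Rigid pseudo-atom geometry of one component kind."""

    kind: Kind
    local_coords: np.ndarray          # (n_atoms, 3), centered on the centroid
    atom_labels: tuple
    group_labels: tuple
    atom_radii: tuple
    resname: str

    def __post_init__(self):
        coords = np.asarray(self.local_coords, dtype=float)
        object.__setattr__(self, "local_coords", coords)
        centroid = coords.mean(axis=0)
        if np.abs(centroid).max() > 1e-9:
            raise ValueError("template coordinates must be centered on the centroid")
        if len(coords) > 1:
            d = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
            if d[np.triu_indices(len(coords), 1)].min() <= 0.5:
                raise ValueError("intra-molecule atom distances must exceed 0.5 A")

    @property
    def n_atoms(self) -> int:
        return len(self.local_coords)


def _center(coords) -> np.ndarray:
    coords = np.asarray(coords, dtype=float)
    return coords - coords.mean(axis=0)


def default_templates() -> dict:
    """Coarse templates for all five component kinds.

    Peptide: a 4-atom diketopiperazine ring flanked by two 3-atom imidazole
    groups.  Drug: 2 charged + 3 polar + 3 hydrophobic pseudo-atoms.
    Zn2+ / Cl-: single spheres.  NO3-: planar N + 3 O.
    """
    ring = [(1.4, 0, 0), (0, 1.4, 0), (-1.4, 0, 0), (0, -1.4, 0)]
    im1 = [(3.0, 0.8, 0.6), (4.2, 0.0, 0.2), (3.4, -0.9, -0.5)]
    im2 = [(-3.0, -0.8, 0.6), (-4.2, 0.0, 0.2), (-3.4, 0.9, -0.5)]
    peptide = MoleculeTemplate(
        kind=Kind.PEPTIDE,
        local_coords=_center(ring + im1 + im2),
        atom_labels=tuple(f"R{i}" for i in range(1, 5))
        + ("IA1", "IA2", "IA3", "IB1", "IB2", "IB3"),
        group_labels=("cyclic_ring",) * 4 + ("imidazole_1",) * 3 + ("imidazole_2",) * 3,
        atom_radii=(1.7,) * 10,
        resname="CHH",
    )
    drug_coords = [
        (2.6, 0.0, 0.0), (3.2, 1.3, 0.4),              # charged group
        (0.8, 0.6, 0.9), (0.0, -1.0, 0.5), (-0.6, 0.9, -0.4),   # polar group
        (-2.4, -0.4, 0.2), (-3.3, 0.9, -0.3), (-3.1, -1.6, -0.4),  # hydrophobic
    ]
    drug = MoleculeTemplate(
        kind=Kind.DRUG,
        local_coords=_center(drug_coords),
        atom_labels=("Q1", "Q2", "P1", "P2", "P3", "H1", "H2", "H3"),
        group_labels=("charged_group",) * 2
        + ("polar_group",) * 3
        + ("hydrophobic_group",) * 3,
        atom_radii=(1.7,) * 8,
        resname="DRG",
    )
    zn = MoleculeTemplate(
        kind=Kind.ZN,
        local_coords=np.zeros((1, 3)),
        atom_labels=("ZN",),
        group_labels=("zn_ion",),
        atom_radii=(1.39,),
        resname="ZN",
    )
    t = 2 * math.pi / 3
    no3 = MoleculeTemplate(
        kind=Kind.NO3,
        local_coords=_center(
            [(0, 0, 0)]
            + [(1.25 * math.cos(k * t), 1.25 * math.sin(k * t), 0) for k in range(3)]
        ),
        atom_labels=("N", "O1", "O2", "O3"),
        group_labels=("nitrate",) * 4,
        atom_radii=(1.55, 1.52, 1.52, 1.52),
        resname="NO3",
    )
    cl = MoleculeTemplate(
        kind=Kind.CL,
        local_coords=np.zeros((1, 3)),
        atom_labels=("CL",),
        group_labels=("cl_ion",),
        atom_radii=(1.75,),
        resname="CL",
    )
    return {Kind.PEPTIDE: peptide, Kind.DRUG: drug, Kind.ZN: zn, Kind.NO3: no3, Kind.CL: cl}


@dataclass
class GroundTruth:
    """Planted partition: cluster memberships plus scattered singletons."""

    memberships: list        # list of frozenset of component indices
    scattered: list          # component indices outside every cluster

    def __post_init__(self):
        seen: set = set()
        for m in self.memberships:
            if len(m) < 2:
                raise ValueError("each planted cluster needs >= 2 members")
            if seen & set(m):
                raise ValueError("planted clusters must be disjoint")
            seen |= set(m)
        if seen & set(self.scattered):
            raise ValueError("scattered components overlap a planted cluster")


@dataclass(frozen=True)
class AffinityModel:
    """Square-well pair potential between component kinds.

    ``epsilon[a, b]`` is the well depth (units of kT>0 means attraction) for
    kinds indexed in :data:`KIND_ORDER`; any inter-atom distance below
    ``sigma`` is a hard-core overlap; the well extends to ``well_range``
    (kept equal to the contact cutoff so "interacting" means the same thing
    to the generator and the analyzer).  Like-charged ion pairs (Zn-Zn,
    NO3-NO3) carry a non-negative ``repulsion_penalty`` inside the well and
    must not attract.
    """

    epsilon: np.ndarray
    sigma: float = 2.0
    well_range: float = 3.5
    repulsion_penalty: float = 2.0

    def __post_init__(self):
        eps = np.asarray(self.epsilon, dtype=float)
        if eps.shape != (5, 5):
            raise ValueError("epsilon must be a 5x5 matrix over kinds P,D,Z,N,C")
        if not np.allclose(eps, eps.T):
            raise ValueError("epsilon must be symmetric")
        zi, ni = _KIND_INDEX[Kind.ZN], _KIND_INDEX[Kind.NO3]
        if eps[zi, zi] > 0 or eps[ni, ni] > 0:
            raise ValueError("Zn-Zn and NO3-NO3 wells must be repulsive (<= 0)")
        if self.sigma >= self.well_range:
            raise ValueError("sigma must be smaller than well_range")
        if self.repulsion_penalty < 0:
            raise ValueError("repulsion_penalty must be >= 0")
        object.__setattr__(self, "epsilon", eps)

    def eps(self, a: Kind, b: Kind) -> float:
        return float(self.epsilon[_KIND_INDEX[a], _KIND_INDEX[b]])


def affinity_from_pairs(pairs: dict | None = None, **kwargs) -> AffinityModel:
    """Build an :class:`AffinityModel` from a sparse {(kind, kind): eps} map."""
    eps = np.zeros((5, 5))
    for (a, b), v in (pairs or {}).items():
        ia, ib = _KIND_INDEX[Kind(a)], _KIND_INDEX[Kind(b)]
        eps[ia, ib] = eps[ib, ia] = v
    return AffinityModel(epsilon=eps, **kwargs)


# -- affinity presets for the three qualitative drug behaviours -------------

_BASE_PAIRS = {
    (Kind.PEPTIDE, Kind.PEPTIDE): 2.5,
    (Kind.PEPTIDE, Kind.ZN): 3.0,
    (Kind.PEPTIDE, Kind.NO3): 3.0,
    (Kind.ZN, Kind.NO3): 3.0,
}


def nitrate_coordinating_affinity(strength: float = 4.0) -> AffinityModel:
    """Drug binds NO3- and peptides (EPI/DOX-like encapsulation driver)."""
    pairs = dict(_BASE_PAIRS)
    pairs[(Kind.DRUG, Kind.NO3)] = strength
    pairs[(Kind.DRUG, Kind.PEPTIDE)] = 2.5
    pairs[(Kind.DRUG, Kind.DRUG)] = 2.0
    return affinity_from_pairs(pairs)


def zinc_coordinating_affinity(strength: float = 4.0) -> AffinityModel:
    """Drug binds Zn2+ and peptides (MTX-like encapsulation driver)."""
    pairs = dict(_BASE_PAIRS)
    pairs[(Kind.DRUG, Kind.ZN)] = strength
    pairs[(Kind.DRUG, Kind.PEPTIDE)] = 2.5
    pairs[(Kind.DRUG, Kind.DRUG)] = 2.0
    return affinity_from_pairs(pairs)


def inert_drug_affinity() -> AffinityModel:
    """Peptide/ion assembly proceeds but the drug does not join (CIS-like)."""
    return affinity_from_pairs(dict(_BASE_PAIRS))


def ideal_gas_affinity() -> AffinityModel:
    """No attractions, no penalties: hard spheres only."""
    return affinity_from_pairs({}, repulsion_penalty=0.0)


# ---------------------------------------------------------------------------
# shared plumbing


def _component_kinds(composition: SystemComposition) -> list:
    kinds = []
    for kind in KIND_ORDER:
        kinds.extend([kind] * composition.counts()[kind])
    return kinds


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (quaternion method)."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def _mic(delta: np.ndarray, box: float) -> np.ndarray:
    return delta - box * np.round(delta / box)


def _min_dist(a: np.ndarray, b: np.ndarray, box: float) -> float:
    delta = _mic(a[:, None, :] - b[None, :, :], box)
    return float(np.sqrt(np.einsum("ijk,ijk->ij", delta, delta).min()))


def _build_frame(composition, templates, kinds, placed_coords, box) -> Frame:
    coords, atom_component, atom_group, atom_radius, atom_label = [], [], [], [], []
    resnames = []
    for ci, kind in enumerate(kinds):
        tpl = templates[kind]
        coords.append(placed_coords[ci])
        atom_component.extend([ci] * tpl.n_atoms)
        atom_group.extend(tpl.group_labels)
        atom_radius.extend(tpl.atom_radii)
        atom_label.extend(tpl.atom_labels)
        resnames.append(
            composition.drug_name if kind is Kind.DRUG else tpl.resname
        )
    return Frame(
        coords=np.vstack(coords),
        box_length=box,
        atom_component=np.array(atom_component),
        component_kind=list(kinds),
        atom_group=atom_group,
        atom_radius=np.array(atom_radius),
        atom_label=atom_label,
        component_resname=resnames,
    )


# ---------------------------------------------------------------------------
# planted configurations


def generate_planted_configuration(
    composition: SystemComposition,
    templates: dict | None = None,
    n_clusters: int = 0,
    cluster_compositions: list | None = None,
    seed: int = 0,
    contact_cutoff: float = 3.5,
    sigma: float = 2.0,
    separation_margin: float = 1.0,
    max_attempts: int = 4000,
):
    """Place components so a known cluster partition holds at the cutoff.

    Each planted cluster is grown by attaching one component at a time at a
    minimum inter-atom distance in ``[sigma, contact_cutoff)`` from a
    previously placed member, so the cluster's contact graph is connected
    by construction.  Growth is confined to a ball of radius ``L/4`` around
    the cluster anchor, which keeps every cluster's extent below half the
    box: clusters can never touch their own periodic image, and unwrapping
    is always consistent.  Distinct clusters, and every scattered
    component, are kept more than ``contact_cutoff + separation_margin``
    apart (any-atom, minimum image), so no spurious edges can arise.
    Cluster anchors are uniform over the box, so clusters routinely
    straddle the periodic boundary.

    Parameters
    ----------
    cluster_compositions : list of dict, optional
        Per-cluster component makeup, e.g. ``[{Kind.PEPTIDE: 5, Kind.ZN: 2}]``.
        Must be given when ``n_clusters > 0`` and have that length.

    Returns
    -------
    (Frame, GroundTruth)

    Raises
    ------
    RuntimeError
        If placement fails after ``max_attempts`` rejections (box too small
        or too crowded).
    """
    templates = templates or default_templates()
    rng = np.random.default_rng(seed)
    L = composition.box_length
    kinds = _component_kinds(composition)
    if n_clusters:
        if cluster_compositions is None or len(cluster_compositions) != n_clusters:
            raise ValueError("cluster_compositions must match n_clusters")
    cluster_compositions = cluster_compositions or []

    # assign component indices to clusters, greedily from the per-kind pools
    pools = {k: [i for i, kk in enumerate(kinds) if kk is k] for k in KIND_ORDER}
    memberships = []
    for comp in cluster_compositions:
        members = []
        for kind, count in comp.items():
            kind = Kind(kind)
            if count > len(pools[kind]):
                raise ValueError(f"not enough {kind.value} components for the plant")
            members.extend(pools[kind][:count])
            del pools[kind][:count]
        if len(members) < 2:
            raise ValueError("each planted cluster needs >= 2 members")
        memberships.append(members)
    scattered = sorted(i for pool in pools.values() for i in pool)

    placed: dict = {}          # component index -> (n_atoms, 3) coords
    occupied_other: list = []  # atoms of fully placed clusters + scattered
    ball_radius = L / 4.0      # confines each cluster to < half-box extent

    def place_component(ci, anchor_atoms, cluster_atoms, cluster_center=None):
        """Sample a pose; anchor_atoms=None means free placement."""
        tpl = templates[kinds[ci]]
        for _ in range(max_attempts):
            local = tpl.local_coords @ _random_rotation(rng).T
            if anchor_atoms is None:
                centroid = rng.uniform(0, L, size=3)
            else:
                b = anchor_atoms[rng.integers(len(anchor_atoms))]
                a = local[rng.integers(len(local))]
                direction = rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                reach = rng.uniform(sigma + 0.05, contact_cutoff - 0.05)
                centroid = b + direction * reach - a
                if cluster_center is not None and (
                    np.linalg.norm(centroid - cluster_center)
                    + np.abs(local).max()
                    > ball_radius
                ):
                    continue
            pose = local + centroid
            if anchor_atoms is not None:
                d_anchor = _min_dist(pose, anchor_atoms, L)
                if not (sigma <= d_anchor < contact_cutoff):
                    continue
            if cluster_atoms is not None and len(cluster_atoms):
                if _min_dist(pose, cluster_atoms, L) < sigma:
                    continue
            if occupied_other:
                if _min_dist(pose, np.vstack(occupied_other), L) <= contact_cutoff + separation_margin:
                    continue
            return pose
        raise RuntimeError(
            f"could not place component {ci} after {max_attempts} attempts; "
            "box too small for the requested configuration"
        )

    truth_clusters = []
    for members in memberships:
        cluster_atoms: list = []
        # place bulky components first: decorating a blob of ions with a
        # large molecule is much harder than the reverse
        order = sorted(members, key=lambda ci: -templates[kinds[ci]].n_atoms)
        first = order[0]
        pose = place_component(first, None, np.empty((0, 3)))
        placed[first] = pose
        cluster_atoms.append(pose)
        center = pose.mean(axis=0)
        for ci in order[1:]:
            anchor_idx = rng.integers(len(cluster_atoms))
            pose = place_component(
                ci, cluster_atoms[anchor_idx], np.vstack(cluster_atoms),
                cluster_center=center,
            )
            placed[ci] = pose
            cluster_atoms.append(pose)
        occupied_other.extend(cluster_atoms)
        truth_clusters.append(frozenset(members))
    for ci in scattered:
        pose = place_component(ci, None, None)
        placed[ci] = pose
        occupied_other.append(pose)

    coords = [placed[ci] for ci in range(len(kinds))]
    frame = _build_frame(composition, templates, kinds, coords, L)
    return frame, GroundTruth(memberships=truth_clusters, scattered=scattered)


# ---------------------------------------------------------------------------
# Metropolis Monte Carlo co-assembly


class MonteCarloEngine:
    """Single-component rigid-body Metropolis sampler with square wells.

    The pair energy between two components is ``-epsilon(kind_a, kind_b)``
    when their minimum inter-atom minimum-image distance is inside
    ``[sigma, well_range)`` (plus the like-ion repulsion penalty for Zn-Zn
    and NO3-NO3), infinite below ``sigma`` (such moves are rejected), and
    zero beyond the well.  Energies are tracked incrementally; a full
    recomputation is available for bookkeeping audits.
    """

    def __init__(
        self,
        composition: SystemComposition,
        templates: dict | None = None,
        affinity: AffinityModel | None = None,
        kT: float = 1.0,
        seed: int = 0,
        max_translation: float = 3.0,
        max_rotation: float = math.pi / 4,
        init_max_attempts: int = 20000,
    ):
        if kT <= 0:
            raise ValueError("kT must be positive")
        self.composition = composition
        self.templates = templates or default_templates()
        self.affinity = affinity if affinity is not None else ideal_gas_affinity()
        self.kT = kT
        self.rng = np.random.default_rng(seed)
        self.box = composition.box_length
        self.max_translation = max_translation
        self.max_rotation = max_rotation
        self.kinds = _component_kinds(composition)
        self.n_components = len(self.kinds)
        self.kind_idx = np.array([_KIND_INDEX[k] for k in self.kinds])
        self._tpls = [self.templates[k] for k in self.kinds]
        counts = [t.n_atoms for t in self._tpls]
        self.offsets = np.concatenate([[0], np.cumsum(counts)])
        self.n_atoms = int(self.offsets[-1])
        self.comp_of_atom = np.repeat(np.arange(self.n_components), counts)
        self.coords = np.empty((self.n_atoms, 3))
        self._init_random(init_max_attempts)
        self.moves_attempted = 0
        self.moves_accepted = 0
        self.total_energy = self.recompute_total_energy()

    # -- energy ------------------------------------------------------------

    def _component_min_dists(self, pose: np.ndarray, exclude: int) -> np.ndarray:
        """Min inter-atom distance from ``pose`` to every other component."""
        delta = _mic(self.coords[None, :, :] - pose[:, None, :], self.box)
        d2 = np.einsum("aij,aij->ai", delta, delta).min(axis=0)
        dmin = np.sqrt(
            np.minimum.reduceat(d2, self.offsets[:-1])
        )
        dmin[exclude] = np.inf
        return dmin

    def _energy_of(self, pose: np.ndarray, ci: int) -> float:
        """Interaction energy of one component with all others (inf = overlap)."""
        dmin = self._component_min_dists(pose, ci)
        a = self.affinity
        if dmin.min() < a.sigma:
            return math.inf
        in_well = dmin < a.well_range
        if not in_well.any():
            return 0.0
        partners = self.kind_idx[in_well]
        e = -a.epsilon[self.kind_idx[ci], partners].sum()
        if self.kinds[ci] in (Kind.ZN, Kind.NO3):
            same = partners == self.kind_idx[ci]
            e += a.repulsion_penalty * same.sum()
        return float(e)

    def recompute_total_energy(self) -> float:
        """Full O(N^2) energy recomputation (bookkeeping audit)."""
        total = 0.0
        for ci in range(self.n_components):
            e = self._energy_of(self._pose(ci), ci)
            if not math.isfinite(e):
                return math.inf
            total += e
        return total / 2.0

    # -- state -------------------------------------------------------------

    def _pose(self, ci: int) -> np.ndarray:
        return self.coords[self.offsets[ci] : self.offsets[ci + 1]]

    def _set_pose(self, ci: int, pose: np.ndarray) -> None:
        self.coords[self.offsets[ci] : self.offsets[ci + 1]] = pose

    def _init_random(self, max_attempts: int) -> None:
        sigma = self.affinity.sigma
        placed = 0
        for ci in range(self.n_components):
            tpl = self._tpls[ci]
            for attempt in range(max_attempts):
                local = tpl.local_coords @ _random_rotation(self.rng).T
                pose = (local + self.rng.uniform(0, self.box, size=3)) % self.box
                if placed == 0:
                    break
                prior = self.coords[: self.offsets[ci]]
                if _min_dist(pose, prior, self.box) >= sigma:
                    break
            else:
                raise RuntimeError(
                    "could not place initial configuration without hard-core "
                    f"overlaps (component {ci})"
                )
            self._set_pose(ci, pose)
            placed += 1

    # -- sampling ----------------------------------------------------------

    def step(self) -> bool:
        """One trial move on a random component; returns acceptance."""
        ci = int(self.rng.integers(self.n_components))
        old_pose = self._pose(ci).copy()
        translation = self.rng.uniform(-self.max_translation, self.max_translation, 3)
        pose = old_pose + translation
        if len(old_pose) > 1:
            centroid = pose.mean(axis=0)
            angle_scale = self.rng.uniform(0, self.max_rotation) / math.pi
            # small random rotation: slerp-free approximation via axis-angle
            axis = self.rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            angle = angle_scale * math.pi
            K = np.array(
                [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
            )
            R = np.eye(3) + math.sin(angle) * K + (1 - math.cos(angle)) * (K @ K)
            pose = (pose - centroid) @ R.T + centroid
        pose %= self.box
        e_old = self._energy_of(old_pose, ci)
        e_new = self._energy_of(pose, ci)
        self.moves_attempted += 1
        accept = False
        if math.isfinite(e_new):
            dE = e_new - e_old
            if dE <= 0 or self.rng.random() < math.exp(-dE / self.kT):
                accept = True
        if accept:
            self._set_pose(ci, pose)
            self.total_energy += e_new - e_old
            self.moves_accepted += 1
        return accept

    def sweep(self) -> None:
        """N trial moves, one sweep per component on average."""
        for _ in range(self.n_components):
            self.step()

    def snapshot(self) -> Frame:
        coords = [self._pose(ci).copy() for ci in range(self.n_components)]
        return _build_frame(
            self.composition, self.templates, self.kinds, coords, self.box
        )

    @property
    def acceptance_rate(self) -> float:
        if self.moves_attempted == 0:
            return math.nan
        return self.moves_accepted / self.moves_attempted


def generate_mc_trajectory(
    composition: SystemComposition,
    templates: dict | None = None,
    affinity: AffinityModel | None = None,
    n_sweeps: int = 200,
    sample_every: int = 20,
    kT: float = 1.0,
    seed: int = 0,
    **engine_kwargs,
) -> list:
    """Run the MC co-assembly process and return sampled frames.

    One frame is recorded every ``sample_every`` sweeps (``n_sweeps //
    sample_every`` frames in total).  Identical ``(composition, affinity,
    seed)`` give an identical trajectory.
    """
    if n_sweeps < 1:
        raise ValueError("n_sweeps must be >= 1")
    engine = MonteCarloEngine(
        composition, templates=templates, affinity=affinity, kT=kT, seed=seed,
        **engine_kwargs,
    )
    frames = []
    for sweep in range(1, n_sweeps + 1):
        engine.sweep()
        if sweep % sample_every == 0:
            frames.append(engine.snapshot())
    return frames
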