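"""Component taxonomy, system composition, and neutralization arithmetic.

The simulated systems contain cyclic dihistidine peptides (Cyclo-HH), drug
molecules, Zn2+ cations, and neutralizing anions (NO3-, and Cl- for
positively charged drugs) in a cubic periodic box.  This module owns the
charge bookkeeping: given peptide/drug/zinc counts and the drug net charge,
it derives the counterion counts that make the system electroneutral.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Sequence


class Kind(str, enum.Enum):
    """Component kinds taking part in co-assembly."""

    PEPTIDE = "PEPTIDE"
    DRUG = "DRUG"
    ZN = "ZN"
    NO3 = "NO3"
    CL = "CL"

    @property
    def letter(self) -> str:
        """Single-letter code used in motif labels (P, D, Z, N, C)."""
        return _KIND_LETTER[self]


_KIND_LETTER = {
    Kind.PEPTIDE: "P",
    Kind.DRUG: "D",
    Kind.ZN: "Z",
    Kind.NO3: "N",
    Kind.CL: "C",
}

#: Kinds whose like-pairs are electrostatically repulsive and excluded from
#: pairwise interaction probabilities (Zn2+-Zn2+ and NO3--NO3-).
REPULSIVE_SELF_PAIRS = frozenset({Kind.ZN, Kind.NO3})


@dataclass(frozen=True)
class ComponentSpec:
    """Chemical description of one component type.

    Parameters
    ----------
    kind : Kind
        Component category.
    net_charge : int
        Net charge in elementary charge units.
    atom_labels : sequence of str
        Atom names, one per atom.
    group_labels : sequence of str
        Chemical-group name per atom (parallel to ``atom_labels``).
    atom_radii : sequence of float
        Van der Waals radii in Angstrom, parallel to ``atom_labels``.
    """

    kind: Kind
    net_charge: int
    atom_labels: tuple = ()
    group_labels: tuple = ()
    atom_radii: tuple = ()

    def __post_init__(self):
        object.__setattr__(self, "atom_labels", tuple(self.atom_labels))
        object.__setattr__(self, "group_labels", tuple(self.group_labels))
        object.__setattr__(self, "atom_radii", tuple(float(r) for r in self.atom_radii))
        n = len(self.atom_labels)
        if n == 0:
            raise ValueError("ComponentSpec needs at least one atom")
        if len(self.group_labels) != n or len(self.atom_radii) != n:
            raise ValueError("atom_labels, group_labels, atom_radii must be parallel")
        if any(r <= 0 for r in self.atom_radii):
            raise ValueError("atom radii must be positive")
        if self.kind is Kind.ZN and (n != 1 or self.net_charge != 2):
            raise ValueError("ZN must be a single atom with net charge +2")
        if self.kind is Kind.NO3 and self.net_charge != -1:
            raise ValueError("NO3 must have net charge -1")
        if self.kind is Kind.CL and (n != 1 or self.net_charge != -1):
            raise ValueError("CL must be a single atom with net charge -1")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_labels)


@dataclass(frozen=True)
class SystemComposition:
    """Counts, charges, and box size of one simulated system.

    Invariant: ``2*n_zn + drug_charge*n_drug - n_no3 - n_cl == 0``
    (the solvent is implicit and carries no charge; the peptide is neutral).
    """

    n_peptide: int
    n_drug: int
    drug_charge: int
    n_zn: int
    n_no3: int
    n_cl: int
    box_length: float
    drug_name: str = "DRG"

    def __post_init__(self):
        for name in ("n_peptide", "n_drug", "n_zn", "n_no3", "n_cl"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.box_length <= 0:
            raise ValueError("box_length must be positive")
        if self.total_charge != 0:
            raise ValueError(
                f"composition is not electroneutral (net charge {self.total_charge})"
            )

    @property
    def total_charge(self) -> int:
        return 2 * self.n_zn + self.drug_charge * self.n_drug - self.n_no3 - self.n_cl

    @property
    def n_components(self) -> int:
        return self.n_peptide + self.n_drug + self.n_zn + self.n_no3 + self.n_cl

    def counts(self) -> dict:
        return {
            Kind.PEPTIDE: self.n_peptide,
            Kind.DRUG: self.n_drug,
            Kind.ZN: self.n_zn,
            Kind.NO3: self.n_no3,
            Kind.CL: self.n_cl,
        }


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable parameters of the cluster analysis.

    contact_cutoff
        Any-atom inter-component distance (A) below which two components
        interact.  Default 3.5 A.
    min_cluster_size
        Smallest cluster (number of member components) retained by the
        size filter; 31 corresponds to "more than 30" members.
    probe_radius
        Solvent probe radius (A) for accessible-surface-area calculations.
        The default 2.6 A is a stand-in for an isopropanol-sized probe.
    sasa_points
        Number of deterministic sphere points per atom in the
        Shrake-Rupley calculation.
    """

    contact_cutoff: float = 3.5
    min_cluster_size: int = 31
    probe_radius: float = 2.6
    sasa_points: int = 960
    frame_stride: int = 1
    rng_seed: int = 0

    def __post_init__(self):
        if self.contact_cutoff <= 0:
            raise ValueError("contact_cutoff must be positive")
        if self.min_cluster_size < 2:
            raise ValueError("min_cluster_size must be >= 2")
        if self.probe_radius < 0:
            raise ValueError("probe_radius must be non-negative")
        if self.sasa_points < 16:
            raise ValueError("sasa_points must be >= 16")
        if self.frame_stride < 1:
            raise ValueError("frame_stride must be >= 1")


def build_composition(
    n_peptide: int,
    n_drug: int,
    drug_charge: int,
    n_zn: int,
    box_length: float,
    drug_name: str = "DRG",
) -> SystemComposition:
    """Derive counterion counts that neutralize the system.

    Nitrate absorbs the Zn2+ charge and, when the drug is negative, the
    drug charge as well (fewer NO3- are then needed); chloride is added only
    to balance positively charged drugs.  For the reference setup of
    48 peptides, 12 drugs and 48 Zn2+ this yields 96 NO3- for a neutral
    drug, 72 NO3- for a -2 drug, and 96 NO3- plus 12 Cl- for a +1 drug.

    Raises
    ------
    ValueError
        On negative counts, or when a negative drug charge would require a
        negative nitrate count.
    """
    for name, v in (("n_peptide", n_peptide), ("n_drug", n_drug), ("n_zn", n_zn)):
        if v < 0:
            raise ValueError(f"{name} must be non-negative")
    if drug_charge < 0:
        n_no3 = 2 * n_zn + n_drug * drug_charge
        if n_no3 < 0:
            raise ValueError(
                "drug negative charge exceeds available Zn2+ charge; "
                f"would need {n_no3} NO3-"
            )
        n_cl = 0
    else:
        n_no3 = 2 * n_zn
        n_cl = n_drug * drug_charge
    return SystemComposition(
        n_peptide=n_peptide,
        n_drug=n_drug,
        drug_charge=drug_charge,
        n_zn=n_zn,
        n_no3=n_no3,
        n_cl=n_cl,
        box_length=box_length,
        drug_name=drug_name,
    )


def initial_drug_peptide_ratio(composition: SystemComposition) -> float:
    """Drug:peptide number ratio of the simulation setup (0.25 = 1:4)."""
    if composition.n_peptide == 0:
        raise ValueError("drug:peptide ratio undefined for zero peptides")
    return composition.n_drug / composition.n_peptide


def reference_composition(
    drug_charge: int = 0, box_length: float = 83.0, drug_name: str = "DRG"
) -> SystemComposition:
    """The standard setup: 48 peptides, 12 drugs, 48 Zn2+ in an 83 A box."""
    return build_composition(48, 12, drug_charge, 48, box_length, drug_name=drug_name)
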