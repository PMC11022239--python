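"""Trajectory frames and multi-model PDB input/output.

A :class:`Frame` is one snapshot: wrapped coordinates in a cubic periodic
box plus the per-atom labeling (component index, component kind, chemical
group, radius) the downstream analysis needs.  Frames come either from the
synthetic generators or from externally produced multi-model PDB files with
a small component-map config assigning each residue name to a component
kind and each atom name to a chemical group and radius.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

from .topology import Kind

#: fallback van der Waals radii (A) by leading element letter
DEFAULT_ELEMENT_RADII = {
    "H": 1.2, "C": 1.7, "N": 1.55, "O": 1.52, "S": 1.8,
    "P": 1.8, "Z": 1.39, "F": 1.47,
}
_FALLBACK_RADIUS = 1.7


@dataclass
class Frame:
    """One trajectory snapshot in a cubic periodic box.

    Attributes
    ----------
    coords : (n_atoms, 3) float array
        Coordinates in Angstrom, wrapped into ``[0, box_length)``.
    box_length : float
        Cubic box edge length (A).
    atom_component : (n_atoms,) int array
        Component index of each atom (0-based, contiguous).
    component_kind : list of Kind
        Kind of each component, indexed by component index.
    atom_group : list of str
        Chemical-group label per atom.
    atom_radius : (n_atoms,) float array
        Van der Waals radius per atom (A).
    atom_label, component_resname, component_chain
        PDB bookkeeping (atom names, residue names, chain IDs).
    """

    coords: np.ndarray
    box_length: float
    atom_component: np.ndarray
    component_kind: list
    atom_group: list
    atom_radius: np.ndarray
    atom_label: list = field(default_factory=list)
    component_resname: list = field(default_factory=list)
    component_chain: list = field(default_factory=list)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.atom_component = np.asarray(self.atom_component, dtype=int)
        self.atom_radius = np.asarray(self.atom_radius, dtype=float)
        n = self.coords.shape[0]
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (n_atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if self.box_length <= 0:
            raise ValueError("box_length must be positive")
        if len(self.atom_component) != n or len(self.atom_group) != n:
            raise ValueError("per-atom arrays must match coords length")
        if len(self.atom_radius) != n:
            raise ValueError("atom_radius must match coords length")
        ncomp = len(self.component_kind)
        if ncomp and (self.atom_component.min() < 0 or self.atom_component.max() >= ncomp):
            raise ValueError("atom_component indices out of range")
        counts = np.bincount(self.atom_component, minlength=ncomp)
        if ncomp and counts.min() == 0:
            raise ValueError("every component must own at least one atom")
        if not self.atom_label:
            self.atom_label = [f"X{i}" for i in range(n)]
        if not self.component_resname:
            self.component_resname = [_default_resname(k) for k in self.component_kind]
        if not self.component_chain:
            self.component_chain = ["A"] * ncomp
        self.coords = self.coords % self.box_length

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    @property
    def n_components(self) -> int:
        return len(self.component_kind)

    def component_atoms(self, i: int) -> np.ndarray:
        """Atom indices belonging to component ``i``."""
        return np.nonzero(self.atom_component == i)[0]

    def kind_counts(self) -> dict:
        out = {k: 0 for k in Kind}
        for k in self.component_kind:
            out[k] += 1
        return out


def _default_resname(kind: Kind) -> str:
    return {
        Kind.PEPTIDE: "CHH", Kind.DRUG: "DRG", Kind.ZN: "ZN",
        Kind.NO3: "NO3", Kind.CL: "CL",
    }[kind]


# ---------------------------------------------------------------------------
# component map config


class ComponentMap:
    """Residue -> (kind, charge) and atom -> (group, radius) tables."""

    def __init__(self, residues: dict, atoms: dict, box_length: float | None = None):
        self.residues = residues    # resname -> {"kind": Kind, "charge": int}
        self.atoms = atoms          # (resname, atomname) -> {"group": str, "radius": float}
        self.box_length = box_length

    def kind_of(self, resname: str) -> Kind:
        if resname not in self.residues:
            raise KeyError(
                f"residue name {resname!r} not present in the component map"
            )
        return self.residues[resname]["kind"]

    def group_radius(self, resname: str, atomname: str) -> tuple:
        entry = self.atoms.get((resname, atomname))
        if entry is not None:
            return entry["group"], entry["radius"]
        radius = DEFAULT_ELEMENT_RADII.get(atomname[:1].upper(), _FALLBACK_RADIUS)
        warnings.warn(
            f"atom {atomname!r} of residue {resname!r} missing from the "
            f"component map; using element-default radius {radius} A",
            stacklevel=3,
        )
        return atomname, radius


def load_component_map(path) -> ComponentMap:
    """Load a YAML/JSON component+group map.

    Expected layout::

        box_length: 83.0        # optional, used when PDB lacks CRYST1
        residues:
          CHH: {kind: PEPTIDE, charge: 0}
          ZN:  {kind: ZN, charge: 2}
        atoms:
          CHH:
            IM1: {group: imidazole_1, radius: 1.7}

    Raises on unknown kind strings and duplicate residue entries.
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict) or "residues" not in data:
        raise ValueError("component map must contain a 'residues' section")
    residues: dict = {}
    raw_res = data["residues"]
    for resname, entry in raw_res.items():
        if resname in residues:
            raise ValueError(f"duplicate residue entry {resname!r}")
        kind_str = entry["kind"] if isinstance(entry, dict) else str(entry)
        try:
            kind = Kind(kind_str)
        except ValueError:
            raise ValueError(
                f"unknown component kind {kind_str!r} for residue {resname!r}; "
                f"expected one of {[k.value for k in Kind]}"
            ) from None
        charge = int(entry.get("charge", 0)) if isinstance(entry, dict) else 0
        residues[resname] = {"kind": kind, "charge": charge}
    atoms: dict = {}
    for resname, table in (data.get("atoms") or {}).items():
        for atomname, entry in table.items():
            radius = entry.get("radius")
            if radius is None:
                radius = DEFAULT_ELEMENT_RADII.get(
                    atomname[:1].upper(), _FALLBACK_RADIUS
                )
            atoms[(resname, atomname)] = {
                "group": str(entry.get("group", atomname)),
                "radius": float(radius),
            }
    box = data.get("box_length")
    return ComponentMap(residues, atoms, None if box is None else float(box))


def write_component_map(frame: Frame, path) -> None:
    """Emit a component map matching a (synthetic) frame, for round-trips."""
    residues: dict = {}
    atoms: dict = {}
    for ci, resname in enumerate(frame.component_resname):
        kind = frame.component_kind[ci]
        residues.setdefault(resname, {"kind": kind.value, "charge": 0})
        for ai in frame.component_atoms(ci):
            atoms.setdefault(resname, {})[frame.atom_label[ai]] = {
                "group": frame.atom_group[ai],
                "radius": float(frame.atom_radius[ai]),
            }
    data = {"box_length": float(frame.box_length), "residues": residues, "atoms": atoms}
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


# ---------------------------------------------------------------------------
# multi-model PDB I/O


def read_multimodel_pdb(path, component_map: ComponentMap) -> list:
    """Parse a multi-model PDB into one :class:`Frame` per MODEL block.

    Atoms are grouped into components by (chain ID, residue number,
    residue name).  The box length is taken from the CRYST1 record when
    present, otherwise from the component map.  Coordinates are wrapped
    into ``[0, L)`` on read.
    """
    path = Path(path)
    frames: list = []
    box = component_map.box_length
    current: list | None = None
    saw_model = False
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec.startswith("CRYST1"):
                box = float(line[6:15])
            elif rec.startswith("MODEL"):
                saw_model = True
                current = []
            elif rec.startswith("ENDMDL"):
                frames.append(_assemble_frame(current or [], box, component_map, path))
                current = None
            elif rec.startswith(("ATOM  ", "HETATM")):
                if current is None:
                    current = []
                try:
                    x = float(line[30:38]); y = float(line[38:46]); z = float(line[46:54])
                except ValueError:
                    raise ValueError(
                        f"{path}:{lineno}: missing or malformed coordinates"
                    ) from None
                current.append(
                    (
                        line[12:16].strip(),       # atom name
                        line[17:20].strip(),       # residue name
                        line[21].strip() or "A",   # chain
                        int(line[22:26]),          # residue number
                        (x, y, z),
                    )
                )
    if current:  # trailing atoms without ENDMDL (single-model files)
        frames.append(_assemble_frame(current, box, component_map, path))
    if not frames and not saw_model:
        raise ValueError(f"{path}: no ATOM/HETATM records found")
    return frames


def _assemble_frame(records, box, cmap: ComponentMap, path) -> Frame:
    if box is None:
        raise ValueError(
            f"{path}: no CRYST1 record and no box_length in the component map"
        )
    comp_index: dict = {}
    component_kind: list = []
    component_resname: list = []
    component_chain: list = []
    coords, atom_component, atom_group, atom_radius, atom_label = [], [], [], [], []
    for name, resname, chain, resnum, xyz in records:
        key = (chain, resnum, resname)
        if key not in comp_index:
            comp_index[key] = len(component_kind)
            component_kind.append(cmap.kind_of(resname))
            component_resname.append(resname)
            component_chain.append(chain)
        group, radius = cmap.group_radius(resname, name)
        coords.append(xyz)
        atom_component.append(comp_index[key])
        atom_group.append(group)
        atom_radius.append(radius)
        atom_label.append(name)
    return Frame(
        coords=np.array(coords, dtype=float),
        box_length=box,
        atom_component=np.array(atom_component),
        component_kind=component_kind,
        atom_group=atom_group,
        atom_radius=np.array(atom_radius),
        atom_label=atom_label,
        component_resname=component_resname,
        component_chain=component_chain,
    )


def write_multimodel_pdb(frames: Sequence[Frame], path) -> None:
    """Write frames as standard MODEL/ENDMDL blocks with a cubic CRYST1.

    Output is deterministic: identical frames give byte-identical files.
    """
    frames = list(frames)
    if not frames:
        raise ValueError("frames must be nonempty")
    lines = []
    L = frames[0].box_length
    lines.append(
        f"CRYST1{L:9.3f}{L:9.3f}{L:9.3f}{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1"
    )
    for mi, frame in enumerate(frames, start=1):
        lines.append(f"MODEL     {mi:4d}")
        serial = 0
        order = np.argsort(frame.atom_component, kind="stable")
        for ai in order:
            serial += 1
            ci = int(frame.atom_component[ai])
            name = frame.atom_label[ai][:4]
            resname = frame.component_resname[ci][:3]
            chain = (frame.component_chain[ci] or "A")[0]
            resnum = (ci % 9999) + 1
            x, y, z = frame.coords[ai]
            pdb_name = f" {name:<3s}" if len(name) < 4 else name
            lines.append(
                f"HETATM{serial % 100000:5d} {pdb_name}{'':1s}{resname:>3s} {chain}"
                f"{resnum:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
            )
        lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
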