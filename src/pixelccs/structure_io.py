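"""Read PDB structures into a sphere-set representation.

A protein structure is reduced to a :class:`SphereCloud` — one sphere per
accepted atom, centered on the atomic coordinate with radius equal to the
element's van der Waals radius plus a solvent-probe radius.  The silhouette
of that inflated sphere set equals the silhouette of the solvent-accessible
surface traced by a probe of the same radius, which is the surface whose
projected area the projection module measures.
"""

from __future__ import annotations

import csv
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import gemmi
import numpy as np

logger = logging.getLogger("pixelccs")

# Bondi-style van der Waals radii (Å).  User-overridable; see
# ``load_radii_table``.  Fallback for elements not listed: DEFAULT_FALLBACK_RADIUS.
DEFAULT_VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
}
DEFAULT_FALLBACK_RADIUS = 1.50

#: Default probe radius (Å) of the solvent-accessible surface.
DEFAULT_PROBE_RADIUS = 1.4

WATER_RESIDUES = frozenset({"HOH", "WAT", "DOD", "H2O"})

# Atom-name prefixes that denote two-letter elements, used only when the
# element columns (77-78) are blank.
_TWO_LETTER_ELEMENTS = frozenset({
    "FE", "ZN", "MG", "MN", "CU", "NI", "CO", "NA", "CL", "BR", "SE", "CA",
})


class StructureError(ValueError):
    """Raised for unreadable files or selections that accept zero atoms."""


@dataclass(frozen=True)
class AtomRecord:
    """A single ATOM/HETATM record after altloc resolution."""

    serial: int
    name: str
    element: str
    residue: str
    chain: str
    coords: tuple[float, float, float]
    occupancy: float
    altloc: str
    is_hetatm: bool


@dataclass(frozen=True)
class SelectionRules:
    """Which atoms contribute spheres.

    Defaults keep everything except water: hydrogens are retained when the
    file has them, and non-water HETATM groups (modified residues such as a
    fluorophore chromophore, bound cofactors) contribute to the envelope.
    """

    include_waters: bool = False
    include_hetatm: bool = True
    include_hydrogens: bool = True
    chains: frozenset[str] | None = None

    def accepts(self, atom: AtomRecord) -> bool:
        if not self.include_waters and atom.residue.upper() in WATER_RESIDUES:
            return False
        if not self.include_hetatm and atom.is_hetatm and \
                atom.residue.upper() not in WATER_RESIDUES:
            return False
        if not self.include_hydrogens and atom.element in ("H", "D"):
            return False
        if self.chains is not None and atom.chain not in self.chains:
            return False
        return True

    def describe(self) -> str:
        parts = []
        if not self.include_waters:
            parts.append("no waters")
        if not self.include_hetatm:
            parts.append("no HETATM")
        if not self.include_hydrogens:
            parts.append("no hydrogens")
        if self.chains is not None:
            parts.append("chains=" + ",".join(sorted(self.chains)))
        return "; ".join(parts) if parts else "all atoms"


@dataclass
class SphereCloud:
    """A structure as centered spheres: the object whose silhouette is measured."""

    centers: np.ndarray  # (n, 3) Å, centered at the centroid
    radii: np.ndarray  # (n,) Å, vdW + probe
    source_id: str
    probe_radius: float

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float).reshape(-1, 3)
        self.radii = np.asarray(self.radii, dtype=float).reshape(-1)
        if self.centers.shape[0] != self.radii.shape[0]:
            raise ValueError("centers and radii length mismatch")
        if self.centers.shape[0] == 0:
            raise StructureError("empty sphere cloud")
        if not np.all(np.isfinite(self.centers)):
            raise ValueError("non-finite coordinates")
        if np.any(self.radii <= 0):
            raise ValueError("all sphere radii must be positive")

    def __len__(self) -> int:
        return len(self.radii)

    @property
    def n_spheres(self) -> int:
        return len(self.radii)

    def centered(self) -> "SphereCloud":
        """Return a copy translated so the centroid of sphere centers is the origin."""
        c = self.centers.mean(axis=0)
        return SphereCloud(self.centers - c, self.radii.copy(),
                           self.source_id, self.probe_radius)

    def translated(self, shift: Sequence[float]) -> "SphereCloud":
        return SphereCloud(self.centers + np.asarray(shift, float),
                           self.radii.copy(), self.source_id, self.probe_radius)


def _infer_element(atom_name: str, residue: str) -> str:
    """Infer the element symbol from a PDB atom name.

    Used only when columns 77-78 are blank.  Digits are stripped; a leading
    digit (``1HB``) marks a hydrogen; recognised two-letter symbols are kept,
    otherwise the first alphabetic character is the element.
    """
    name = atom_name.strip()
    if not name:
        return ""
    if name[0].isdigit():
        return "H" if "H" in name.upper() else name.lstrip("0123456789")[:1].upper()
    stripped = "".join(ch for ch in name if ch.isalpha()).upper()
    if len(stripped) >= 2 and stripped[:2] in _TWO_LETTER_ELEMENTS:
        return stripped[0] + stripped[1].lower()
    return stripped[:1]


def parse_pdb(path: str | Path, model_index: int = 0,
              selection: SelectionRules | None = None) -> list[AtomRecord]:
    """Parse one model of a PDB file into accepted :class:`AtomRecord` objects.

    Parameters
    ----------
    path:
        PDB file (fixed-column ATOM/HETATM dialect; MODEL/ENDMDL honoured).
    model_index:
        Zero-based model to read; multi-model (NMR) files default to model 0.
    selection:
        Atom-acceptance rules; default :class:`SelectionRules`.

    Altloc conflicts at one site are resolved to the highest-occupancy
    conformer (ties broken by altloc letter, so the result is independent of
    record order).  The element is taken from columns 77-78 when present,
    otherwise inferred from the atom name.
    """
    path = Path(path)
    if not path.exists():
        raise StructureError(f"PDB file not found: {path}")
    selection = selection or SelectionRules()
    try:
        structure = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"could not parse {path}: {exc}") from exc
    if len(structure) == 0:
        raise StructureError(f"{path} contains no models")
    if not 0 <= model_index < len(structure):
        raise StructureError(
            f"model_index {model_index} out of range for {path} "
            f"({len(structure)} model(s))")
    model = structure[model_index]

    records: list[AtomRecord] = []
    # key: (chain, residue seqid, residue name, atom name) -> best conformer
    best: dict[tuple, AtomRecord] = {}
    order: list[tuple] = []
    serial = 0
    for chain in model:
        for residue in chain:
            is_het = residue.het_flag == "H"
            for atom in residue:
                serial += 1
                element = atom.element.name
                if element in ("", "X"):
                    element = _infer_element(atom.name, residue.name)
                altloc = atom.altloc if atom.altloc not in ("\x00",) else ""
                rec = AtomRecord(
                    serial=atom.serial if atom.serial else serial,
                    name=atom.name,
                    element=element,
                    residue=residue.name,
                    chain=chain.name,
                    coords=(atom.pos.x, atom.pos.y, atom.pos.z),
                    occupancy=float(atom.occ),
                    altloc=altloc,
                    is_hetatm=is_het,
                )
                key = (chain.name, str(residue.seqid), residue.name, atom.name)
                if key not in best:
                    best[key] = rec
                    order.append(key)
                else:
                    prev = best[key]
                    # highest occupancy wins; tie -> lexicographically first altloc
                    if (rec.occupancy, -ord(rec.altloc or "~")) > \
                            (prev.occupancy, -ord(prev.altloc or "~")):
                        best[key] = rec
    for key in order:
        rec = best[key]
        if selection.accepts(rec):
            records.append(rec)
    if not records:
        raise StructureError(
            f"no atoms accepted from {path} model {model_index} "
            f"under selection ({selection.describe()})")
    return records


def build_sphere_cloud(atoms: Sequence[AtomRecord], probe_radius: float = DEFAULT_PROBE_RADIUS,
                       radii_table: Mapping[str, float] | None = None,
                       fallback_radius: float = DEFAULT_FALLBACK_RADIUS,
                       source_id: str = "",
                       center: bool = True) -> SphereCloud:
    """Inflate atoms to spheres: radius = vdW(element) + probe_radius.

    Unknown elements take ``fallback_radius`` and are logged.  With the
    default probe of 1.4 Å the sphere set's silhouette is that of the 1.4 Å
    solvent-accessible surface.  Clouds are centered at the centroid by
    default (projected area is translation-invariant; centering just keeps
    rotations well-conditioned numerically).
    """
    if probe_radius < 0:
        raise ValueError(f"probe_radius must be >= 0, got {probe_radius}")
    if not atoms:
        raise StructureError("cannot build a sphere cloud from zero atoms")
    table = dict(DEFAULT_VDW_RADII)
    if radii_table:
        table.update({k.capitalize(): float(v) for k, v in radii_table.items()})
    centers = np.array([a.coords for a in atoms], dtype=float)
    radii = np.empty(len(atoms))
    unknown: set[str] = set()
    for i, a in enumerate(atoms):
        el = a.element.capitalize()
        vdw = table.get(el)
        if vdw is None:
            unknown.add(a.element)
            vdw = fallback_radius
        radii[i] = vdw + probe_radius
    for el in sorted(unknown):
        msg = (f"element {el!r} not in radii table; "
               f"using fallback {fallback_radius} Å")
        logger.warning(msg)
        warnings.warn(msg, stacklevel=2)
    cloud = SphereCloud(centers, radii, source_id, probe_radius)
    return cloud.centered() if center else cloud


def load_sphere_cloud(path: str | Path, model_index: int = 0,
                      probe_radius: float = DEFAULT_PROBE_RADIUS,
                      selection: SelectionRules | None = None,
                      radii_table: Mapping[str, float] | None = None) -> SphereCloud:
    """Convenience: parse a PDB file and inflate it in one step."""
    atoms = parse_pdb(path, model_index=model_index, selection=selection)
    sel = (selection or SelectionRules()).describe()
    src = f"{Path(path).name}#model{model_index}[{sel}]"
    return build_sphere_cloud(atoms, probe_radius=probe_radius,
                              radii_table=radii_table, source_id=src)


def load_radii_table(path: str | Path) -> dict[str, float]:
    """Load a radii override from JSON ({"C": 1.7, ...}) or CSV (element,radius)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
        return {str(k): float(v) for k, v in data.items()}
    table: dict[str, float] = {}
    reader = csv.reader(text.splitlines())
    for row in reader:
        if not row or row[0].strip().lower() in ("element", "#"):
            continue
        table[row[0].strip()] = float(row[1])
    return table


def write_pdb(atoms: Sequence[AtomRecord], path: str | Path) -> None:
    """Write atom records back out as a standard single-model PDB file."""
    st = gemmi.Structure()
    st.name = "pixelccs"
    model = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    seq: dict[str, int] = {}
    for rec in atoms:
        if rec.chain not in chains:
            chains[rec.chain] = gemmi.Chain(rec.chain)
            seq[rec.chain] = 0
        seq[rec.chain] += 1
        res = gemmi.Residue()
        res.name = rec.residue
        res.seqid = gemmi.SeqId(seq[rec.chain], " ")
        res.het_flag = "H" if rec.is_hetatm else "A"
        atom = gemmi.Atom()
        atom.name = rec.name
        atom.element = gemmi.Element(rec.element)
        atom.pos = gemmi.Position(*rec.coords)
        atom.occ = rec.occupancy
        atom.b_iso = 0.0
        if rec.altloc:
            atom.altloc = rec.altloc
        res.add_atom(atom)
        chains[rec.chain].add_residue(res)
    for ch in chains.values():
        model.add_chain(ch)
    st.add_model(model)
    Path(path).write_text(st.make_pdb_string())
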