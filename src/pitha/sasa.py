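"""Solvent-accessible surface area (SASA) and CDR-H3 hydrophobicity.

The hydrophobicity of the CDR-H3 loop is defined as the summed
solvent-accessible surface area of its hydrophobic atoms, computed over the
whole Fv so that the rest of the structure occludes the loop.  Carbon,
sulfur, and nitrogen atoms count as hydrophobic, except the non-protonated
nitrogen of the histidine side chain; oxygen and hydrogen do not.

Areas are computed with the Shrake-Rupley method on a deterministic
quasi-uniform (Fibonacci lattice) point set: each atom is inflated by the
probe radius (1.4 Å) and the fraction of its lattice points lying outside
every other inflated atom gives its exposed area.

Atomic radii: C 1.8, N 1.65, O 1.4, S 1.85, polar H 1.0 Å.  Non-polar
hydrogens (bonded to carbon) are excluded from the computation entirely;
hydrogen bonding partners are inferred geometrically (nearest heavy atom
within 1.3 Å).  Structures without hydrogens are processed heavy-atom-only
and flagged, with histidine assumed NE2-protonated for the hydrophobicity
rule.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .antibody_model import Atom, FvStructure, KabatNumbering, RegionAnnotation

__all__ = [
    "DEFAULT_RADII",
    "POLAR_H_RADIUS",
    "DEFAULT_PROBE_RADIUS",
    "DEFAULT_N_SPHERE_POINTS",
    "SasaResult",
    "atom_radius",
    "is_hydrophobic",
    "fibonacci_sphere",
    "shrake_rupley_areas",
    "compute_sasa",
    "region_hydrophobic_area",
    "region_hydrophobic_fraction",
]

DEFAULT_RADII: dict[str, float] = {"C": 1.8, "N": 1.65, "O": 1.4, "S": 1.85}
POLAR_H_RADIUS = 1.0
DEFAULT_PROBE_RADIUS = 1.4
DEFAULT_N_SPHERE_POINTS = 960
H_BOND_CUTOFF = 1.3  # Å, geometric criterion assigning an H to its heavy atom

_HIS_SIDECHAIN_N = {"ND1", "NE2"}


def atom_radius(
    atom: Atom,
    bonded_element: str | None = None,
    radii: dict[str, float] | None = None,
) -> float | None:
    """Radius in Å for a single atom, or ``None`` if it is excluded.

    Hydrogens take the radius of their polarity class: bonded to carbon they
    are non-polar and excluded (returns ``None``); bonded to N/O/S they are
    polar with radius 1.0 Å.  Unsupported elements (metals etc.) raise.
    """
    table = DEFAULT_RADII if radii is None else radii
    elem = atom.element.upper()
    if elem == "H":
        if bonded_element is None:
            raise ValueError(
                f"hydrogen atom {atom.serial} has no bonding partner within "
                f"{H_BOND_CUTOFF} Å"
            )
        partner = bonded_element.upper()
        if partner == "C":
            return None
        if partner in ("N", "O", "S"):
            return POLAR_H_RADIUS
        raise ValueError(
            f"hydrogen atom {atom.serial} bonded to unsupported element {partner!r}"
        )
    try:
        return table[elem]
    except KeyError:
        raise ValueError(
            f"unsupported element {atom.element!r} (atom {atom.serial})"
        ) from None


def is_hydrophobic(
    atom: Atom,
    has_attached_hydrogen: bool | None = None,
    structure_has_hydrogens: bool = True,
) -> bool:
    """Hydrophobic-atom rule: C and S always; N except the non-protonated
    histidine side-chain nitrogen; O and H never.

    For structures without hydrogens the protonation of histidine cannot be
    read off the coordinates; the NE2-protonated tautomer is assumed, making
    NE2 hydrophobic and ND1 not.
    """
    elem = atom.element.upper()
    if elem in ("C", "S"):
        return True
    if elem != "N":
        return False
    if atom.residue_name == "HIS" and atom.name in _HIS_SIDECHAIN_N:
        if structure_has_hydrogens:
            return bool(has_attached_hydrogen)
        return atom.name == "NE2"
    return True


def fibonacci_sphere(n_points: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    i = np.arange(n_points, dtype=float)
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i  # golden angle increments
    z = 1.0 - (2.0 * i + 1.0) / n_points
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def shrake_rupley_areas(
    coords: np.ndarray,
    radii: np.ndarray,
    probe: float = DEFAULT_PROBE_RADIUS,
    n_sphere_points: int = DEFAULT_N_SPHERE_POINTS,
) -> np.ndarray:
    """Per-atom solvent-accessible surface areas in Å².

    For each atom the fraction of lattice points on its probe-inflated sphere
    lying outside all other inflated spheres is multiplied by 4π(r+probe)².
    Deterministic for a fixed lattice size.
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    n = len(coords)
    if n == 0:
        raise ValueError("no atoms to compute SASA for")
    if n_sphere_points < 60:
        raise ValueError("n_sphere_points must be >= 60")
    unit = fibonacci_sphere(n_sphere_points)
    R = radii + probe
    tree = cKDTree(coords)
    r_max = R.max()
    areas = np.empty(n)
    for i in range(n):
        sphere = coords[i] + R[i] * unit
        nbrs = [j for j in tree.query_ball_point(coords[i], R[i] + r_max) if j != i]
        if nbrs:
            d2 = np.sum(
                (sphere[:, None, :] - coords[nbrs][None, :, :]) ** 2, axis=2
            )
            exposed = np.all(d2 >= (R[nbrs] ** 2)[None, :], axis=1)
            frac = exposed.mean()
        else:
            frac = 1.0
        areas[i] = frac * 4.0 * math.pi * R[i] ** 2
    return areas


@dataclass
class SasaResult:
    """Per-atom and aggregate accessible areas of one structure.

    ``per_atom_area`` is keyed by atom serial; excluded atoms (non-polar
    hydrogens) are absent.  ``no_hydrogens`` flags the heavy-atom-only mode
    used when the input carries no hydrogens.
    """

    per_atom_area: dict[int, float]
    hydrophobic: dict[int, bool]
    total_area: float
    hydrophobic_area: float
    no_hydrogens: bool = False

    @property
    def hydrophobic_fraction(self) -> float:
        """Hydrophobic share of the total area, as a percentage."""
        if self.total_area == 0.0:
            return 0.0
        return 100.0 * self.hydrophobic_area / self.total_area

    def to_json(self) -> str:
        return json.dumps(
            {
                "total_area": self.total_area,
                "hydrophobic_area": self.hydrophobic_area,
                "hydrophobic_fraction": self.hydrophobic_fraction,
                "no_hydrogens": self.no_hydrogens,
                "per_atom_area": {str(k): v for k, v in self.per_atom_area.items()},
            },
            indent=1,
        )


def _prepare_atoms(
    atoms: list[Atom],
    radii_table: dict[str, float] | None = None,
) -> tuple[list[Atom], np.ndarray, np.ndarray, list[bool], bool]:
    """Assign radii and hydrophobicity flags; drop non-polar hydrogens."""
    heavy = [a for a in atoms if a.element.upper() != "H"]
    hydrogens = [a for a in atoms if a.element.upper() == "H"]
    has_h = bool(hydrogens)

    partner_of: dict[int, str] = {}
    if has_h:
        if not heavy:
            raise ValueError("structure contains only hydrogens")
        heavy_tree = cKDTree(np.array([a.coord for a in heavy]))
        for h in hydrogens:
            dist, idx = heavy_tree.query(h.coord)
            if dist > H_BOND_CUTOFF:
                raise ValueError(
                    f"hydrogen atom {h.serial} has no heavy atom within "
                    f"{H_BOND_CUTOFF} Å"
                )
            partner_of[h.serial] = heavy[idx].element

    # which heavy atoms carry an attached hydrogen (for the His rule)
    attached_h: set[int] = set()
    if has_h:
        h_tree = cKDTree(np.array([a.coord for a in hydrogens]))
        for a in heavy:
            if h_tree.query_ball_point(a.coord, H_BOND_CUTOFF):
                attached_h.add(a.serial)

    included: list[Atom] = []
    radii: list[float] = []
    phobic: list[bool] = []
    for a in atoms:
        r = atom_radius(a, partner_of.get(a.serial), radii_table)
        if r is None:
            continue
        included.append(a)
        radii.append(r)
        phobic.append(
            is_hydrophobic(
                a,
                has_attached_hydrogen=a.serial in attached_h,
                structure_has_hydrogens=has_h,
            )
        )
    if not included:
        raise ValueError("no atoms remain after exclusions")
    coords = np.array([a.coord for a in included])
    return included, coords, np.array(radii), phobic, not has_h


def compute_sasa(
    structure: FvStructure,
    probe: float = DEFAULT_PROBE_RADIUS,
    n_sphere_points: int = DEFAULT_N_SPHERE_POINTS,
    radii_table: dict[str, float] | None = None,
) -> SasaResult:
    """SASA of the whole Fv (both chains occluding each other)."""
    atoms = structure.atoms
    serials = [a.serial for a in atoms]
    if len(set(serials)) != len(serials):
        raise ValueError("atom serials are not unique within the structure")
    included, coords, radii, phobic, no_h = _prepare_atoms(atoms, radii_table)
    areas = shrake_rupley_areas(coords, radii, probe, n_sphere_points)
    per_atom = {a.serial: float(ar) for a, ar in zip(included, areas)}
    hyd = {a.serial: p for a, p in zip(included, phobic)}
    total = float(areas.sum())
    hyd_area = float(sum(ar for a, ar, p in zip(included, areas, phobic) if p))
    return SasaResult(
        per_atom_area=per_atom, hydrophobic=hyd, total_area=total,
        hydrophobic_area=hyd_area, no_hydrogens=no_h,
    )


def residue_region_index(
    structure: FvStructure,
    annotation: RegionAnnotation,
    numbering: KabatNumbering,
) -> dict[tuple[str, str], str]:
    """Map (chain_id, residue_seq) -> region label.

    Numbering rows refer to residues by their 1-based position within the
    chain (``seq_index``); this joins them back onto the structure's residue
    list.  Residues without a numbering entry are labeled framework.
    """
    out: dict[tuple[str, str], str] = {}
    for chain_id, role, residues in (
        (structure.heavy_chain_id, "H", structure.heavy_chain),
        (structure.light_chain_id, "L", structure.light_chain),
    ):
        by_index = {e.seq_index: e for e in numbering.chain_entries(chain_id)}
        for pos, res in enumerate(residues, start=1):
            e = by_index.get(pos)
            if e is None:
                out[(chain_id, res.residue_seq)] = "FR"
            else:
                out[(chain_id, res.residue_seq)] = annotation.label(
                    role, e.kabat_number, e.insertion
                )
    return out


def _region_atoms(
    structure: FvStructure,
    annotation: RegionAnnotation,
    numbering: KabatNumbering,
    region_label: str,
) -> set[int]:
    index = residue_region_index(structure, annotation, numbering)
    serials: set[int] = set()
    for chain_id, residues in (
        (structure.heavy_chain_id, structure.heavy_chain),
        (structure.light_chain_id, structure.light_chain),
    ):
        for res in residues:
            if index[(chain_id, res.residue_seq)] == region_label:
                serials.update(a.serial for a in res.atoms)
    if not serials:
        raise ValueError(f"region {region_label!r} has no residues")
    return serials


def region_hydrophobic_area(
    structure: FvStructure,
    annotation: RegionAnnotation,
    numbering: KabatNumbering,
    region_label: str = "CDR-H3",
    sasa: SasaResult | None = None,
    **sasa_kwargs,
) -> float:
    """Summed SASA (Å²) of the hydrophobic atoms of one region.

    The SASA itself is computed over the whole Fv, so the environment
    occludes the region; only the summation is restricted to the region's
    residues.  A precomputed ``sasa`` result may be passed to avoid repeating
    the surface calculation.
    """
    if sasa is None:
        sasa = compute_sasa(structure, **sasa_kwargs)
    serials = _region_atoms(structure, annotation, numbering, region_label)
    return float(
        sum(
            area
            for serial, area in sasa.per_atom_area.items()
            if serial in serials and sasa.hydrophobic[serial]
        )
    )


def region_hydrophobic_fraction(
    structure: FvStructure,
    annotation: RegionAnnotation,
    numbering: KabatNumbering,
    region_label: str = "CDR-H3",
    sasa: SasaResult | None = None,
    **sasa_kwargs,
) -> float:
    """Hydrophobic share of a region's total SASA, as a percentage."""
    if sasa is None:
        sasa = compute_sasa(structure, **sasa_kwargs)
    serials = _region_atoms(structure, annotation, numbering, region_label)
    total = sum(
        area for serial, area in sasa.per_atom_area.items() if serial in serials
    )
    if total == 0.0:
        return 0.0
    hyd = sum(
        area
        for serial, area in sasa.per_atom_area.items()
        if serial in serials and sasa.hydrophobic[serial]
    )
    return 100.0 * hyd / total
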