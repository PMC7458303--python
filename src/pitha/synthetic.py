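"""Synthetic structures, Monte-Carlo oracles, and synthetic feature datasets.

Every geometric and statistical operation in the package can be exercised
offline against inputs with known ground truth:

* :func:`make_structure` builds small atom clouds — isolated atoms, seeded
  random clusters, a hollow spherical shell with a narrow mouth, a loop of
  residues buried inside a shell — together with a consistent Kabat
  numbering and region annotation, so the full feature pipeline runs on them.
* :func:`monte_carlo_sasa_oracle` estimates per-atom accessible areas by
  uniform rejection sampling on each probe-inflated sphere: an estimator
  implementationally independent of the deterministic lattice used by the
  production SASA code.
* :func:`monte_carlo_interior_volume` estimates the open volume inside an
  analytically constructed cavity region, independent of the grid detector's
  flood fill.
* :func:`two_sphere_exposed_areas` is the closed-form spherical-cap result
  for a pair of overlapping spheres.
* :func:`make_feature_dataset` draws two-feature Gaussian clusters with
  controllable class separation for classifier tests.

All generators take explicit seeds; a fixed seed reproduces byte-identical
output.
"""

from __future__ import annotations

import math

import numpy as np

from .antibody_model import (
    Atom,
    FvStructure,
    KabatEntry,
    KabatNumbering,
    RegionAnnotation,
    Residue,
    annotate_regions,
)
from .classifier import (
    LABEL_IMMUNOGENIC,
    LABEL_NON_IMMUNOGENIC,
    FeatureVector,
    LabeledDataset,
)
from .sasa import DEFAULT_PROBE_RADIUS

__all__ = [
    "make_structure",
    "make_feature_dataset",
    "monte_carlo_sasa_oracle",
    "monte_carlo_interior_volume",
    "two_sphere_exposed_areas",
    "write_pdb",
    "write_numbering_csv",
]

_KINDS = ("isolated_atoms", "random_cluster", "hollow_shell", "buried_loop")


# ---------------------------------------------------------------------------
# Structure generators
# ---------------------------------------------------------------------------

def _atoms_to_structure(
    coords: np.ndarray,
    elements: list[str],
    kind: str,
    loop_start: int | None = None,
    loop_len: int = 0,
) -> tuple[FvStructure, KabatNumbering]:
    """Wrap bare atoms into one-atom GLY residues on the heavy chain.

    Residues from ``loop_start`` (0-based) for ``loop_len`` residues receive
    heavy-chain Kabat numbers 95, 96, ... (CDR-H3); all others get framework
    numbers (small numbers below 26 continuing at 77+ to stay outside every
    CDR range).
    """
    residues: list[Residue] = []
    entries: list[KabatEntry] = []
    fr_numbers = [n for n in range(1, 26)] + [n for n in range(77, 95)] + [
        n for n in range(103, 114)
    ]
    fr_iter = iter(fr_numbers)
    fr_insertions = iter(
        [(n, chr(ord("A") + k)) for n in range(1, 26) for k in range(26)]
    )
    for i, (c, elem) in enumerate(zip(coords, elements)):
        seq = str(i + 1)
        atom = Atom(
            serial=i + 1, name=elem.upper(), element=elem, chain_id="H",
            residue_name="GLY", residue_seq=seq, coord=np.asarray(c, dtype=float),
        )
        residues.append(Residue(name="GLY", residue_seq=seq, atoms=[atom]))
        in_loop = (
            loop_start is not None and loop_start <= i < loop_start + loop_len
        )
        if in_loop:
            kabat, ins = 95 + (i - loop_start) % 8, ""
            if i - loop_start >= 8:  # long loops continue as 100A, 100B, ...
                kabat, ins = 102, chr(ord("A") + (i - loop_start - 8))
        else:
            try:
                kabat, ins = next(fr_iter), ""
            except StopIteration:
                kabat, ins = next(fr_insertions)
        entries.append(KabatEntry("H", i + 1, kabat, ins, "G"))
    entries.sort(key=lambda e: (e.kabat_number, e.insertion))
    # re-derive seq order: entries must follow chain order for the invariant,
    # so renumber residues to match sorted kabat order
    order = [e.seq_index for e in entries]
    residues = [residues[i - 1] for i in order]
    entries = [
        KabatEntry("H", j + 1, e.kabat_number, e.insertion, e.residue)
        for j, e in enumerate(entries)
    ]
    structure = FvStructure(
        heavy_chain=residues, light_chain=[], source_id=f"synthetic-{kind}"
    )
    return structure, KabatNumbering(entries)


def _fibonacci_shell(n: int, radius: float) -> np.ndarray:
    i = np.arange(n, dtype=float)
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - (2.0 * i + 1.0) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return radius * np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def make_structure(
    kind: str,
    n_atoms: int = 30,
    element: str = "C",
    cluster_radius: float = 6.0,
    inner_radius: float = 6.0,
    mouth_radius: float = 5.2,
    seed: int = 0,
    probe: float = DEFAULT_PROBE_RADIUS,
    atom_radius: float = 1.8,
) -> tuple[FvStructure, KabatNumbering, RegionAnnotation]:
    """Build a synthetic structure with known geometry.

    Kinds:

    * ``isolated_atoms`` — ``n_atoms`` atoms spaced 100 Å apart (no mutual
      occlusion; each atom's SASA is the closed-form sphere area).
    * ``random_cluster`` — ``n_atoms`` atoms uniform in a ball of
      ``cluster_radius`` Å (seeded).
    * ``hollow_shell`` — a dense spherical shell whose probe-inflated inner
      surface sits at ``inner_radius`` Å, with a mouth opened around +z by
      removing atoms within ``mouth_radius`` Å (in atom centers) of the axis;
      interior cavity volume ≈ (4/3)π·inner_radius³.
    * ``buried_loop`` — 3 loop residues (Kabat 95-97, CDR-H3) at the center
      of a closed shell: the loop is fully occluded from solvent.
    """
    if kind not in _KINDS:
        raise ValueError(f"unknown structure kind {kind!r}; expected one of {_KINDS}")
    rng = np.random.default_rng(seed)
    loop_start = None
    loop_len = 0
    if kind == "isolated_atoms":
        coords = np.zeros((n_atoms, 3))
        coords[:, 0] = 100.0 * np.arange(n_atoms)
        elements = [element] * n_atoms
    elif kind == "random_cluster":
        # rejection-free uniform ball sampling
        u = rng.random(n_atoms) ** (1.0 / 3.0)
        v = rng.normal(size=(n_atoms, 3))
        v /= np.linalg.norm(v, axis=1)[:, None]
        coords = cluster_radius * u[:, None] * v
        elements = [element] * n_atoms
    elif kind in ("hollow_shell", "buried_loop"):
        shell_radius = inner_radius + atom_radius + probe
        # ~2.0 Å center spacing keeps the inflated spheres overlapping
        n_shell = max(60, int(4.0 * math.pi * shell_radius ** 2 / 4.0))
        shell = _fibonacci_shell(n_shell, shell_radius)
        if kind == "hollow_shell":
            axis_dist = np.linalg.norm(shell[:, :2], axis=1)
            keep = ~((shell[:, 2] > 0) & (axis_dist < mouth_radius))
            shell = shell[keep]
            coords = shell
            elements = [element] * len(coords)
        else:
            # tight closed shell: every direction from a loop atom is blocked
            # within probe-inflated contact, so the loop is truly occluded
            loop = np.array([[-1.5, 0.0, 0.0], [0.0, 0.0, 0.0], [1.5, 0.0, 0.0]])
            tight_radius = 5.0
            n_tight = max(200, int(4.0 * math.pi * tight_radius ** 2 / 1.4))
            shell = _fibonacci_shell(n_tight, tight_radius)
            coords = np.vstack([loop, shell])
            elements = [element] * len(coords)
            loop_start, loop_len = 0, 3
    structure, numbering = _atoms_to_structure(
        coords, elements, kind, loop_start=loop_start, loop_len=loop_len
    )
    annotation = annotate_regions(numbering)
    return structure, numbering, annotation


# ---------------------------------------------------------------------------
# Monte-Carlo oracles
# ---------------------------------------------------------------------------

def monte_carlo_sasa_oracle(
    coords: np.ndarray,
    radii: np.ndarray,
    probe: float = DEFAULT_PROBE_RADIUS,
    n_samples: int = 100_000,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-atom SASA estimates by uniform sphere sampling, with standard errors.

    For each atom, ``n_samples`` points are drawn uniformly on its
    probe-inflated sphere; the fraction outside all other inflated spheres is
    an unbiased estimator of the exposed fraction.  Returns (areas, standard
    errors), both in Å².
    """
    if n_samples < 10_000:
        raise ValueError("n_samples must be >= 10000 per atom")
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    rng = np.random.default_rng(seed)
    n = len(coords)
    R = radii + probe
    areas = np.empty(n)
    errors = np.empty(n)
    for i in range(n):
        pts = rng.normal(size=(n_samples, 3))
        pts /= np.linalg.norm(pts, axis=1)[:, None]
        pts = coords[i] + R[i] * pts
        exposed = np.ones(n_samples, dtype=bool)
        for j in range(n):
            if j == i:
                continue
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            exposed &= d2 >= R[j] ** 2
        p = exposed.mean()
        full = 4.0 * math.pi * R[i] ** 2
        areas[i] = p * full
        errors[i] = full * math.sqrt(max(p * (1 - p), 1e-12) / n_samples)
    return areas, errors


def monte_carlo_interior_volume(
    coords: np.ndarray,
    radii: np.ndarray,
    center: np.ndarray,
    region_radius: float,
    probe: float = DEFAULT_PROBE_RADIUS,
    n_samples: int = 200_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Open volume (Å³) inside a spherical region, by rejection sampling.

    Estimates the volume of points within ``region_radius`` of ``center``
    lying outside every probe-inflated atom sphere.  For an analytically
    constructed cavity (e.g. the hollow-shell fixture with the region sphere
    covering the interior) this is the cavity volume.  Returns (volume,
    standard error).
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    center = np.asarray(center, dtype=float)
    rng = np.random.default_rng(seed)
    u = rng.random(n_samples) ** (1.0 / 3.0)
    v = rng.normal(size=(n_samples, 3))
    v /= np.linalg.norm(v, axis=1)[:, None]
    pts = center + region_radius * u[:, None] * v
    open_mask = np.ones(n_samples, dtype=bool)
    R2 = (radii + probe) ** 2
    for c, r2 in zip(coords, R2):
        open_mask &= np.sum((pts - c) ** 2, axis=1) >= r2
    p = open_mask.mean()
    region_volume = 4.0 / 3.0 * math.pi * region_radius ** 3
    return (
        p * region_volume,
        region_volume * math.sqrt(max(p * (1 - p), 1e-12) / n_samples),
    )


def two_sphere_exposed_areas(
    r1: float, r2: float, d: float, probe: float = DEFAULT_PROBE_RADIUS
) -> tuple[float, float]:
    """Closed-form exposed areas of two overlapping probe-inflated spheres.

    For inflated radii R_i = r_i + probe at center distance d, the area of
    sphere 1 buried inside sphere 2 is the spherical cap 2πR₁h₁ with
    h₁ = R₁ - (d² + R₁² - R₂²)/(2d); symmetrically for sphere 2.
    """
    R1, R2 = r1 + probe, r2 + probe
    full1, full2 = 4.0 * math.pi * R1 ** 2, 4.0 * math.pi * R2 ** 2
    if d >= R1 + R2:
        return full1, full2
    if d + min(R1, R2) <= max(R1, R2):  # one sphere engulfed by the other
        if R1 < R2:
            return 0.0, full2
        return full1, 0.0
    x1 = (d * d + R1 * R1 - R2 * R2) / (2.0 * d)
    h1 = R1 - x1
    h2 = R2 - (d - x1)
    return full1 - 2.0 * math.pi * R1 * h1, full2 - 2.0 * math.pi * R2 * h2


# ---------------------------------------------------------------------------
# Feature datasets for classifier tests
# ---------------------------------------------------------------------------

def make_feature_dataset(
    n_per_class: int = 10, separation: float = 10.0, seed: int = 0
) -> LabeledDataset:
    """Two-feature Gaussian clusters (unit σ) with mean separation
    ``separation``·σ along the feature diagonal; labels follow the cluster.

    Features are shifted to be non-negative and fill the (cavity volume,
    H3 area) slots of the feature vector.
    """
    if n_per_class < 3:
        raise ValueError("n_per_class must be >= 3")
    rng = np.random.default_rng(seed)
    offset = separation / math.sqrt(2.0)
    a = rng.normal(loc=0.0, scale=1.0, size=(n_per_class, 2))
    b = rng.normal(loc=offset, scale=1.0, size=(n_per_class, 2))
    X = np.vstack([a, b])
    X -= X.min(axis=0) - 1.0  # keep features positive
    items = []
    for i, row in enumerate(X):
        label = LABEL_IMMUNOGENIC if i < n_per_class else LABEL_NON_IMMUNOGENIC
        fv = FeatureVector(
            antibody_name=f"synthetic-{i:03d}",
            cavity_volume=float(row[0]),
            h3_hydrophobic_area=float(row[1]),
            gly_h2_turn_count=1,
            structure_source="synthetic",
        )
        items.append((fv, label))
    return LabeledDataset(items)


# ---------------------------------------------------------------------------
# Writers, so the full command-line path is exercisable offline
# ---------------------------------------------------------------------------

def write_pdb(structure: FvStructure) -> str:
    """Serialize a structure to minimal PDB-format text."""
    lines = []
    for chain_id, residues in (
        (structure.heavy_chain_id, structure.heavy_chain),
        (structure.light_chain_id, structure.light_chain),
    ):
        for i, res in enumerate(residues, start=1):
            for a in res.atoms:
                num = "".join(ch for ch in a.residue_seq if ch.isdigit()) or str(i)
                icode = a.residue_seq[len(num):] if a.residue_seq.startswith(num) else ""
                lines.append(
                    f"ATOM  {a.serial:5d} {a.name:<4s}{a.residue_name:>4s} "
                    f"{chain_id}{int(num):4d}{icode or ' ':1s}   "
                    f"{a.coord[0]:8.3f}{a.coord[1]:8.3f}{a.coord[2]:8.3f}"
                    f"{a.occupancy:6.2f}{0.0:6.2f}          "
                    f"{a.element.upper():>2s}"
                )
        if residues:
            lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


def write_numbering_csv(numbering: KabatNumbering) -> str:
    lines = ["chain,seq_index,kabat_number,insertion,residue"]
    for e in numbering.entries:
        lines.append(
            f"{e.chain},{e.seq_index},{e.kabat_number},{e.insertion},{e.residue}"
        )
    return "\n".join(lines) + "\n"
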