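"""Antibody Fv structures, Kabat numbering, and CDR region definitions.

The variable fragment (Fv) of an antibody — the paired heavy-chain (VH) and
light-chain (VL) variable domains — carries the six complementarity-
determining regions (CDRs) that form the antigen-binding site.  Anti-drug
antibody responses against therapeutic antibodies are directed almost
exclusively at these loops, so all downstream features (CDR cavity volume,
CDR-H3 hydrophobic surface, glycine at the CDR-H2 β-turn) are defined in
terms of Kabat-numbered CDR regions.

Numbering is an input, not a computation: residue-to-Kabat assignment is
delegated to an external numbering tool (ANARCI-style), whose output is
consumed here as a small CSV table.

CDR boundaries use an expanded heavy-chain definition relative to classical
Kabat: CDR-H1 starts at VH 26 (adding positions 26-30) and CDR-H2 starts at
VH 49.  Light-chain loops use the classical Kabat ranges.  The CDR-H2 β-turn
is VH 52-56, insertion-coded positions included.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "FvStructure",
    "KabatEntry",
    "KabatNumbering",
    "RegionAnnotation",
    "CDR_LABELS",
    "parse_pdb",
    "read_numbering",
    "annotate_regions",
    "h2_turn_gly_count",
    "cdr_h3_length",
]

CDR_LABELS = ("CDR-H1", "CDR-H2", "CDR-H3", "CDR-L1", "CDR-L2", "CDR-L3")
FRAMEWORK_LABEL = "FR"

# Kabat CDR ranges, inclusive.  Heavy-chain H1/H2 use the expanded
# definition (H1 from 26, H2 from 49); light chain is classical Kabat.
_HEAVY_RANGES = (("CDR-H1", 26, 35), ("CDR-H2", 49, 65), ("CDR-H3", 95, 102))
_LIGHT_RANGES = (("CDR-L1", 24, 34), ("CDR-L2", 50, 56), ("CDR-L3", 89, 97))
H2_TURN_RANGE = (52, 56)  # the glycine-rich β-turn of CDR-H2

AA_3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


@dataclass(frozen=True)
class Atom:
    """One atom of a structure, wwPDB ATOM-record fields."""

    serial: int
    name: str
    element: str
    chain_id: str
    residue_name: str
    residue_seq: str  # author residue number + insertion code, e.g. "100A"
    coord: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self) -> None:
        if not self.element:
            raise ValueError(f"atom {self.serial}: empty element")
        if not np.all(np.isfinite(self.coord)):
            raise ValueError(f"atom {self.serial}: non-finite coordinates")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.serial}: occupancy outside [0,1]")


@dataclass
class Residue:
    name: str           # 3-letter code
    residue_seq: str    # author numbering + insertion code
    atoms: list[Atom] = field(default_factory=list)

    @property
    def one_letter(self) -> str:
        return AA_3TO1.get(self.name, "X")


@dataclass
class FvStructure:
    """Heavy + light chain of an antibody variable fragment.

    Residues are kept in file order (author numbering); waters and
    heteroatom residues are never retained.  Synthetic test structures may
    leave the light chain empty.
    """

    heavy_chain: list[Residue]
    light_chain: list[Residue]
    source_id: str = ""
    heavy_chain_id: str = "H"
    light_chain_id: str = "L"

    def chain(self, role: str) -> list[Residue]:
        if role == "H":
            return self.heavy_chain
        if role == "L":
            return self.light_chain
        raise ValueError(f"unknown chain role {role!r}")

    @property
    def atoms(self) -> list[Atom]:
        out: list[Atom] = []
        for res in self.heavy_chain:
            out.extend(res.atoms)
        for res in self.light_chain:
            out.extend(res.atoms)
        return out

    def n_residues(self) -> int:
        return len(self.heavy_chain) + len(self.light_chain)


class KabatEntry(NamedTuple):
    chain: str          # chain identifier as in the structure
    seq_index: int      # 1-based position of the residue within its chain
    kabat_number: int
    insertion: str      # "" or a letter, e.g. "A" for 52A
    residue: str        # 1-letter code


@dataclass
class KabatNumbering:
    """Per-residue Kabat numbers, as produced by an external numbering tool."""

    entries: list[KabatEntry]

    def __post_init__(self) -> None:
        seen: set[tuple[str, int]] = set()
        last: dict[str, tuple[int, str]] = {}
        for e in self.entries:
            key = (e.chain, e.seq_index)
            if key in seen:
                raise ValueError(f"duplicate numbering entry for {key}")
            seen.add(key)
            prev = last.get(e.chain)
            if prev is not None and (e.kabat_number, e.insertion) < prev:
                raise ValueError(
                    f"Kabat numbers not non-decreasing in chain {e.chain!r} "
                    f"at seq_index {e.seq_index}"
                )
            last[e.chain] = (e.kabat_number, e.insertion)

    def chain_entries(self, chain: str) -> list[KabatEntry]:
        return [e for e in self.entries if e.chain == chain]

    @property
    def chains(self) -> list[str]:
        out: list[str] = []
        for e in self.entries:
            if e.chain not in out:
                out.append(e.chain)
        return out


@dataclass
class RegionAnnotation:
    """Map from (chain role, Kabat number, insertion code) to region label.

    Every numbered residue gets exactly one label: one of the six CDR loops
    or ``FR`` (framework).  ``h2_turn`` holds the heavy-chain β-turn
    positions (Kabat 52-56, insertions included); it is always a subset of
    the CDR-H2 positions.
    """

    region_of: dict[tuple[str, int, str], str]
    h2_turn: set[tuple[int, str]]

    def label(self, chain_role: str, kabat_number: int, insertion: str = "") -> str:
        return self.region_of.get(
            (chain_role, kabat_number, insertion),
            _label_for(chain_role, kabat_number),
        )

    def is_cdr(self, chain_role: str, kabat_number: int, insertion: str = "") -> bool:
        return self.label(chain_role, kabat_number, insertion) != FRAMEWORK_LABEL


def _label_for(chain_role: str, kabat_number: int) -> str:
    ranges = _HEAVY_RANGES if chain_role == "H" else _LIGHT_RANGES
    for label, lo, hi in ranges:
        # insertion-coded positions share their base number's region
        if lo <= kabat_number <= hi:
            return label
    return FRAMEWORK_LABEL


# ---------------------------------------------------------------------------
# PDB parsing
# ---------------------------------------------------------------------------

_WATER_NAMES = {"HOH", "WAT", "DOD"}


def _infer_element(atom_name_field: str) -> str:
    """Infer the element from PDB atom-name columns 13-16."""
    name = atom_name_field.strip()
    if not name:
        return ""
    # two-character elements occupy column 13 (e.g. "FE  ", "ZN  ")
    if len(atom_name_field) >= 2 and atom_name_field[0] not in (" ", ""):
        two = atom_name_field[:2].strip().upper()
        if two in ("FE", "ZN", "MG", "MN", "CU", "NA", "CL", "CA", "SE", "BR"):
            return two.capitalize()
    stripped = name.lstrip("0123456789")
    return stripped[0].upper() if stripped else ""


def parse_pdb(
    pdb_text: str,
    heavy_chain_id: str = "H",
    light_chain_id: str | None = "L",
    source_id: str = "",
) -> FvStructure:
    """Parse ATOM records of two chains from PDB-format text.

    Waters and heteroatom (HETATM) residues are dropped; alternate locations
    other than blank or 'A' are dropped.  Elements are taken from columns
    77-78 when present, otherwise inferred from the atom-name columns.
    ``light_chain_id=None`` reads a single-chain (heavy-only) structure.

    Raises ``ValueError`` if a requested chain has no atoms or a line cannot
    be parsed.
    """
    if light_chain_id == heavy_chain_id:
        raise ValueError("heavy and light chain ids must differ")
    chains: dict[str, list[Residue]] = {heavy_chain_id: []}
    if light_chain_id is not None:
        chains[light_chain_id] = []
    wanted = set(chains)
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        rec = line[:6]
        if rec not in ("ATOM  ", "HETATM"):
            continue
        if rec == "HETATM":
            continue  # waters/ligands/ions are never part of the Fv
        try:
            serial = int(line[6:11])
            name = line[12:16]
            altloc = line[16].strip()
            resname = line[17:20].strip()
            chain_id = line[21]
            resseq = line[22:26].strip() + line[26].strip()
            coord = np.array(
                [float(line[30:38]), float(line[38:46]), float(line[46:54])]
            )
            occ_field = line[54:60].strip()
            occupancy = float(occ_field) if occ_field else 1.0
            element_field = line[76:78].strip() if len(line) >= 78 else ""
        except (ValueError, IndexError) as exc:
            raise ValueError(f"unparseable ATOM record at line {lineno}: {exc}")
        if chain_id not in wanted or resname in _WATER_NAMES:
            continue
        if altloc not in ("", "A"):
            continue
        element = element_field.capitalize() if element_field else _infer_element(name)
        if not element:
            raise ValueError(f"cannot determine element at line {lineno}")
        atom = Atom(
            serial=serial, name=name.strip(), element=element, chain_id=chain_id,
            residue_name=resname, residue_seq=resseq, coord=coord,
            occupancy=min(occupancy, 1.0), altloc=altloc,
        )
        residues = chains[chain_id]
        if not residues or residues[-1].residue_seq != resseq:
            residues.append(Residue(name=resname, residue_seq=resseq))
        residues[-1].atoms.append(atom)
    for cid in wanted:
        if not chains[cid]:
            raise ValueError(f"chain {cid} not found in PDB text")
    return FvStructure(
        heavy_chain=chains[heavy_chain_id],
        light_chain=chains.get(light_chain_id, []) if light_chain_id else [],
        source_id=source_id,
        heavy_chain_id=heavy_chain_id,
        light_chain_id=light_chain_id if light_chain_id else "L",
    )


# ---------------------------------------------------------------------------
# Numbering table
# ---------------------------------------------------------------------------

def read_numbering(table_text: str) -> KabatNumbering:
    """Read an ANARCI-style numbering CSV.

    Expected header: ``chain,seq_index,kabat_number,insertion,residue``;
    residues are 1-letter codes, insertion is a letter or empty.
    """
    reader = csv.DictReader(io.StringIO(table_text))
    required = {"chain", "seq_index", "kabat_number", "insertion", "residue"}
    if reader.fieldnames is None or not required <= set(reader.fieldnames):
        raise ValueError(f"numbering CSV must have columns {sorted(required)}")
    entries: list[KabatEntry] = []
    for row in reader:
        try:
            kabat = int(row["kabat_number"])
            seq_index = int(row["seq_index"])
        except ValueError:
            raise ValueError(
                f"non-integer kabat_number/seq_index in row {row!r}"
            ) from None
        entries.append(
            KabatEntry(
                chain=row["chain"].strip(),
                seq_index=seq_index,
                kabat_number=kabat,
                insertion=(row["insertion"] or "").strip(),
                residue=row["residue"].strip().upper(),
            )
        )
    if not entries:
        raise ValueError("numbering table has no entries")
    return KabatNumbering(entries)


# ---------------------------------------------------------------------------
# Region annotation and sequence-level features
# ---------------------------------------------------------------------------

def annotate_regions(
    numbering: KabatNumbering,
    heavy_chain: str = "H",
    light_chain: str = "L",
) -> RegionAnnotation:
    """Assign each numbered residue to a CDR loop or the framework.

    Heavy-chain ranges (expanded Kabat): H1 26-35, H2 49-65, H3 95-102;
    light-chain (classical Kabat): L1 24-34, L2 50-56, L3 89-97.  Positions
    outside all ranges are framework.  Insertion-coded positions belong to
    the range of their base number, so 52A-56x are also part of the CDR-H2
    β-turn set.
    """
    region_of: dict[tuple[str, int, str], str] = {}
    h2_turn: set[tuple[int, str]] = set()
    roles = {heavy_chain: "H", light_chain: "L"}
    for e in numbering.entries:
        role = roles.get(e.chain)
        if role is None:
            continue
        label = _label_for(role, e.kabat_number)
        region_of[(role, e.kabat_number, e.insertion)] = label
        if role == "H" and H2_TURN_RANGE[0] <= e.kabat_number <= H2_TURN_RANGE[1]:
            h2_turn.add((e.kabat_number, e.insertion))
    return RegionAnnotation(region_of=region_of, h2_turn=h2_turn)


def h2_turn_gly_count(
    annotation: RegionAnnotation,
    numbering: KabatNumbering,
    heavy_chain: str = "H",
) -> int:
    """Number of glycines at the CDR-H2 β-turn (heavy Kabat 52-56)."""
    heavy = numbering.chain_entries(heavy_chain)
    if not heavy:
        raise ValueError(f"heavy chain {heavy_chain!r} absent from numbering")
    return sum(
        1
        for e in heavy
        if (e.kabat_number, e.insertion) in annotation.h2_turn and e.residue == "G"
    )


def gly_present(count: int) -> int:
    """Binary presence/absence of Gly at the CDR-H2 turn, as fed to the SVM."""
    return 1 if count > 0 else 0


def cdr_h3_length(
    annotation: RegionAnnotation,
    numbering: KabatNumbering,
    heavy_chain: str = "H",
) -> int:
    """Number of numbered residues in CDR-H3 (Kabat 95-102 incl. insertions)."""
    return sum(
        1
        for e in numbering.chain_entries(heavy_chain)
        if annotation.label("H", e.kabat_number, e.insertion) == "CDR-H3"
    )
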