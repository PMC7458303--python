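"""Profile-based humanness scoring of antibody variable-region sequences.

The humanness of a residue is measured by how well it is tolerated by human
sequence profiles: given a PSSM built from iterative profile search against
human sequences, the per-position score is

    S_human(i) = min(M_ir - B_rr, 0)

where M_ir is the self-substitution (log-odds) score of the query residue r
at position i and B_rr is the BLOSUM62 diagonal for r.  A residue scoring 0
is as conserved among human sequences as it is in its own substitution
class; strongly negative scores mark residues rarely seen in human
antibodies.  A residue is called *rare* when S_human < -6 (strict).  Scores
are summed separately over the CDR and framework regions.

This module consumes a ready-made PSI-BLAST ASCII PSSM; it never launches
searches, so results depend on the profile database the caller used.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

__all__ = [
    "BLOSUM62_DIAGONAL",
    "RARE_THRESHOLD",
    "PSSM",
    "HumannessSummary",
    "read_pssm",
    "residue_humanness",
    "is_rare",
    "region_humanness",
]

# diagonal of the BLOSUM62 substitution matrix
BLOSUM62_DIAGONAL: dict[str, int] = {
    "A": 4, "R": 5, "N": 6, "D": 6, "C": 9, "Q": 5, "E": 5, "G": 6, "H": 8,
    "I": 4, "L": 4, "K": 5, "M": 5, "F": 6, "P": 7, "S": 4, "T": 5, "W": 11,
    "Y": 7, "V": 4,
}

RARE_THRESHOLD = -6  # rare iff S_human < -6 (so -7 and below, strictly)


@dataclass
class PSSM:
    """A position-specific scoring matrix in PSI-BLAST layout.

    ``residue_order`` gives the column order of the 20 log-odds scores in
    each row; ``self_score(i)`` returns M_ir for the query residue at
    1-based position i.
    """

    positions: list[int]
    query_residues: list[str]
    scores: list[list[int]]        # one row of 20 ints per position
    residue_order: list[str]

    def __post_init__(self) -> None:
        if len(self.residue_order) != 20:
            raise ValueError("PSSM must have 20 residue columns")
        if not (len(self.positions) == len(self.query_residues) == len(self.scores)):
            raise ValueError("PSSM rows inconsistent")
        for pos, row in zip(self.positions, self.scores):
            if len(row) != 20:
                raise ValueError(f"PSSM row at position {pos} has {len(row)} scores")

    def __len__(self) -> int:
        return len(self.positions)

    def self_score(self, position: int) -> int:
        """M_ir: the log-odds score of the query's own residue at a position."""
        idx = self.positions.index(position)
        r = self.query_residues[idx]
        return self.scores[idx][self.residue_order.index(r)]


def read_pssm(ascii_text: str) -> PSSM:
    """Parse a PSI-BLAST ``-out_ascii_pssm`` file.

    Only the first 20 score columns (the log-odds part) are used.  Raises on
    an empty file, a truncated row, or an unknown query-residue letter.
    """
    residue_order: list[str] | None = None
    positions: list[int] = []
    residues: list[str] = []
    scores: list[list[int]] = []
    for line in ascii_text.splitlines():
        fields = line.split()
        if not fields:
            continue
        if residue_order is None:
            # header row: 20 (or 40) single-letter residue labels
            if len(fields) >= 20 and all(len(f) == 1 and f.isalpha() for f in fields):
                residue_order = fields[:20]
            continue
        if not fields[0].isdigit():
            continue  # trailing statistics block
        pos = int(fields[0])
        res = fields[1].upper()
        if res not in BLOSUM62_DIAGONAL:
            raise ValueError(f"position {pos}: unknown residue letter {res!r}")
        raw = fields[2:22]
        if len(raw) < 20:
            raise ValueError(
                f"position {pos}: expected 20 scores, found {len(raw)}"
            )
        try:
            row = [int(v) for v in raw]
        except ValueError:
            raise ValueError(f"position {pos}: non-integer score field") from None
        positions.append(pos)
        residues.append(res)
        scores.append(row)
    if not positions:
        raise ValueError("no PSSM rows found")
    if residue_order is None:
        raise ValueError("PSSM header with residue columns not found")
    return PSSM(
        positions=positions, query_residues=residues, scores=scores,
        residue_order=residue_order,
    )


def residue_humanness(m_ir: int, residue: str) -> int:
    """S_human = M_ir - B_rr when M_ir < B_rr, else 0.  Always <= 0."""
    try:
        b_rr = BLOSUM62_DIAGONAL[residue.upper()]
    except KeyError:
        raise ValueError(f"nonstandard residue type {residue!r}") from None
    return min(m_ir - b_rr, 0)


def is_rare(s_human: int) -> bool:
    """A residue is rare when its humanness score is below -6 (strict)."""
    return s_human < RARE_THRESHOLD


@dataclass
class HumannessSummary:
    """Per-region humanness sums and rare-residue counts."""

    per_position_score: dict[int, int]
    cdr_sum: int
    framework_sum: int
    cdr_rare_count: int
    framework_rare_count: int

    @property
    def total_sum(self) -> int:
        return self.cdr_sum + self.framework_sum

    def to_json(self) -> str:
        return json.dumps(
            {
                "cdr_sum": self.cdr_sum,
                "framework_sum": self.framework_sum,
                "cdr_rare_count": self.cdr_rare_count,
                "framework_rare_count": self.framework_rare_count,
                "per_position_score": {
                    str(k): v for k, v in self.per_position_score.items()
                },
            },
            indent=1,
        )


def region_humanness(
    pssm: PSSM,
    annotation,
    alignment: dict[int, tuple[str, int, str] | None],
) -> HumannessSummary:
    """Sum humanness scores over the CDR region and the framework.

    ``alignment`` maps each PSSM position to (chain_role, kabat_number,
    insertion) or to ``None`` to skip it explicitly (e.g. constant-region
    overhang).  A position absent from the alignment raises.
    """
    per_position: dict[int, int] = {}
    cdr_sum = fr_sum = cdr_rare = fr_rare = 0
    any_cdr = False
    for idx, pos in enumerate(pssm.positions):
        if pos not in alignment:
            raise ValueError(
                f"PSSM position {pos} has no region assignment and no skip flag"
            )
        target = alignment[pos]
        if target is None:
            continue
        role, kabat, ins = target
        m_ir = pssm.scores[idx][pssm.residue_order.index(pssm.query_residues[idx])]
        s = residue_humanness(m_ir, pssm.query_residues[idx])
        per_position[pos] = s
        if annotation.is_cdr(role, kabat, ins):
            any_cdr = True
            cdr_sum += s
            cdr_rare += int(is_rare(s))
        else:
            fr_sum += s
            fr_rare += int(is_rare(s))
    if not any_cdr:
        warnings.warn("no PSSM position maps to a CDR residue; cdr_sum is 0")
    return HumannessSummary(
        per_position_score=per_position,
        cdr_sum=cdr_sum,
        framework_sum=fr_sum,
        cdr_rare_count=cdr_rare,
        framework_rare_count=fr_rare,
    )
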