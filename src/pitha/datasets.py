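"""Bundled reference feature tables for 52 FDA-approved therapeutic antibodies.

Two datasets ship with the package:

* ``crystal`` — 29 antibodies with crystal structures: CDR cavity volume
  (Å³), CDR-H3 hydrophobic surface area (Å²), and the glycine count at the
  CDR-H2 β-turn, with clinical immunogenicity labels (an antibody is
  non-immunogenic when treatment-emergent anti-antibody responses were
  reported in under 2% of patients; 15 immunogenic / 14 non-immunogenic).
* ``modeled`` — 23 antibodies without crystal structures: CDR-H3 hydrophobic
  area from homology models and the Gly count (13 immunogenic /
  10 non-immunogenic), plus the originally reported SVM prediction for each.

Loading enforces the known row/label counts, guarding against transcription
drift.  Labels are taken as bundled; the underlying clinical-report
extraction is not re-performed here.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .classifier import (
    LABEL_IMMUNOGENIC,
    LABEL_NON_IMMUNOGENIC,
    LabeledDataset,
    read_dataset_csv,
)

__all__ = [
    "load_table",
    "load_dataframe",
    "summary_statistics",
    "compare_groups",
    "zero_gly_census",
]

_TABLE_FILES = {"crystal": "crystal_features.csv", "modeled": "modeled_features.csv"}
_TABLE_ALIASES = {3: "crystal", "3": "crystal", 4: "modeled", "4": "modeled"}
_EXPECTED_COUNTS = {
    "crystal": {"total": 29, LABEL_IMMUNOGENIC: 15, LABEL_NON_IMMUNOGENIC: 14},
    "modeled": {"total": 23, LABEL_IMMUNOGENIC: 13, LABEL_NON_IMMUNOGENIC: 10},
}


def _table_name(table_id) -> str:
    name = _TABLE_ALIASES.get(table_id, table_id)
    if name not in _TABLE_FILES:
        raise ValueError(
            f"unknown table {table_id!r}; expected 'crystal'/'modeled' (or 3/4)"
        )
    return name


def _read_text(name: str) -> str:
    return (resources.files("pitha") / "data" / _TABLE_FILES[name]).read_text()


def load_dataframe(table_id="crystal") -> pd.DataFrame:
    """The raw bundled table as a DataFrame (all printed columns)."""
    name = _table_name(table_id)
    df = pd.read_csv(
        (resources.files("pitha") / "data" / _TABLE_FILES[name]).open()
    )
    _check_counts(name, df)
    return df


def load_table(table_id="crystal") -> LabeledDataset:
    """The bundled table as a :class:`LabeledDataset` with integrity checks."""
    name = _table_name(table_id)
    text = _read_text(name)
    dataset = read_dataset_csv(text)
    df = pd.read_csv((resources.files("pitha") / "data" / _TABLE_FILES[name]).open())
    _check_counts(name, df)
    return dataset


def _check_counts(name: str, df: pd.DataFrame) -> None:
    expected = _EXPECTED_COUNTS[name]
    if len(df) != expected["total"]:
        raise ValueError(
            f"{name} table has {len(df)} rows, expected {expected['total']}"
        )
    counts = df["label"].value_counts().to_dict()
    for label in (LABEL_IMMUNOGENIC, LABEL_NON_IMMUNOGENIC):
        if counts.get(label, 0) != expected[label]:
            raise ValueError(
                f"{name} table has {counts.get(label, 0)} {label} rows, "
                f"expected {expected[label]}"
            )


@dataclass(frozen=True)
class GroupSummary:
    n: int
    mean: float
    std: float  # sample standard deviation (ddof=1)

    @property
    def mean_rounded(self) -> int:
        return int(round(self.mean))


def summary_statistics(
    dataset: LabeledDataset, feature: str, group: str
) -> GroupSummary:
    """Mean and dispersion of one feature within one label group."""
    values = [
        fv.get(feature) for fv, label in dataset.items if label == group
    ]
    if not values:
        raise ValueError(f"no antibodies labeled {group!r}")
    arr = np.asarray(values, dtype=float)
    return GroupSummary(
        n=len(arr), mean=float(arr.mean()),
        std=float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
    )


def compare_groups(
    dataset: LabeledDataset, feature: str, equal_var: bool = True
) -> tuple[float, float]:
    """Two-sample Student's t-test between the label groups.

    Returns (t statistic, two-sided p value); ``equal_var=False`` switches to
    Welch's unequal-variance form.
    """
    a = [fv.get(feature) for fv, lab in dataset.items if lab == LABEL_IMMUNOGENIC]
    b = [fv.get(feature) for fv, lab in dataset.items if lab == LABEL_NON_IMMUNOGENIC]
    if not a or not b:
        raise ValueError("both label groups must be non-empty")
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def zero_gly_census(datasets=None) -> tuple[int, int]:
    """Across the given datasets (default: both bundled tables), the number of
    antibodies with no glycine at the CDR-H2 β-turn, and how many of those are
    immunogenic."""
    if datasets is None:
        datasets = [load_table("crystal"), load_table("modeled")]
    zero = [
        (fv, lab)
        for ds in datasets
        for fv, lab in ds.items
        if fv.gly_h2_turn_count == 0
    ]
    return len(zero), sum(1 for _, lab in zero if lab == LABEL_IMMUNOGENIC)
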