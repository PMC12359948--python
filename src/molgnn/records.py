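"""Compound records and CSV input/output.

The raw unit of data is a compound: an identifier, a human-readable name, a
SMILES string and a binary label (0/1), or a fixed-length small-integer label
vector for two-task datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd


@dataclass(frozen=True)
class CompoundRecord:
    """One input compound.

    ``label`` is an ``int`` in {0, 1} for single-task data or a tuple of such
    ints for multi-task data; ``None`` for unlabelled records.
    """

    compound_id: str
    name: str
    smiles: str
    label: int | tuple[int, ...] | None = None

    def label_as_int(self) -> int:
        if self.label is None:
            raise ValueError(f"record {self.compound_id!r} has no label")
        if isinstance(self.label, tuple):
            raise ValueError(f"record {self.compound_id!r} is multi-task")
        return int(self.label)


def _check_unique_ids(records: Sequence[CompoundRecord]) -> None:
    seen: set[str] = set()
    for r in records:
        if r.compound_id in seen:
            raise ValueError(f"duplicate compound_id {r.compound_id!r}")
        seen.add(r.compound_id)


def read_compound_csv(
    path: str | Path,
    *,
    name_col: str = "name",
    smiles_col: str = "smiles",
    label_col: str | Sequence[str] = "label",
    id_col: str | None = None,
) -> list[CompoundRecord]:
    """Read a compound table from CSV.

    Column names are configurable; when ``id_col`` is None the row index is
    used as the identifier. ``label_col`` may be a list of columns for
    multi-task data.
    """
    df = pd.read_csv(path, encoding="utf-8")
    multi = not isinstance(label_col, str)
    label_cols = list(label_col) if multi else [label_col]
    for col in [name_col, smiles_col, *label_cols]:
        if col not in df.columns:
            raise ValueError(f"column {col!r} not found in {path}")
    records = []
    for i, row in df.iterrows():
        labels = tuple(int(row[c]) for c in label_cols)
        label: int | tuple[int, ...] = labels if multi else labels[0]
        cid = str(row[id_col]) if id_col is not None else str(i)
        records.append(
            CompoundRecord(
                compound_id=cid,
                name=str(row[name_col]),
                smiles=str(row[smiles_col]),
                label=label,
            )
        )
    _check_unique_ids(records)
    return records


def write_compound_csv(
    records: Sequence[CompoundRecord],
    path: str | Path,
    *,
    extra_columns: dict[str, Sequence] | None = None,
) -> None:
    """Write records (plus optional aligned extra columns) as UTF-8 CSV."""
    data: dict[str, list] = {
        "name": [r.name for r in records],
        "smiles": [r.smiles for r in records],
        "label": [r.label for r in records],
    }
    if extra_columns:
        for key, vals in extra_columns.items():
            if len(vals) != len(records):
                raise ValueError(f"extra column {key!r} has wrong length")
            data[key] = list(vals)
    pd.DataFrame(data).to_csv(path, index=False, encoding="utf-8")
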