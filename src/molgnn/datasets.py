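"""Published dataset constants and CSV adapters.

The FDA DILIst binary liver-injury annotation set, as published, contains 768
DILI-positive and 511 DILI-negative drugs (1,279 total). No download happens
here; the constants let summary arithmetic (class ratio, totals) be computed
locally, and the adapters ingest user-supplied DILIst-style or
MoleculeNet-style CSVs.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

from molgnn.records import CompoundRecord, read_compound_csv

#: Published DILIst class counts (drugs with binary liver-injury labels).
DILIST_POSITIVE = 768
DILIST_NEGATIVE = 511


def dilist_total() -> int:
    """Total drug count of the published DILIst release."""
    return DILIST_POSITIVE + DILIST_NEGATIVE


def dilist_positive_negative_ratio() -> float:
    """Positive-to-negative class ratio of the published DILIst release."""
    return DILIST_POSITIVE / DILIST_NEGATIVE


def load_dilist_csv(path: str | Path, **kwargs) -> list[CompoundRecord]:
    """Read a DILIst-style CSV (columns name, smiles, label by default)."""
    return read_compound_csv(path, **kwargs)


def load_moleculenet_csv(
    path: str | Path,
    smiles_col: str = "smiles",
    label_col: str | Sequence[str] = "label",
    name_col: str | None = None,
) -> list[CompoundRecord]:
    """Read a MoleculeNet-style CSV; two label columns give two-task records
    (the ClinTox layout)."""
    return read_compound_csv(
        path,
        name_col=name_col or smiles_col,
        smiles_col=smiles_col,
        label_col=label_col,
    )
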