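"""End-to-end convenience: raw records -> standardised -> featurised graphs."""

from __future__ import annotations

from typing import Sequence

from molgnn.featurize import FeatureSchema, FeaturizationFailure, GraphDataset, featurize_records
from molgnn.records import CompoundRecord
from molgnn.standardize import StandardizationOutcome, standardize_dataset


def records_to_graph_dataset(
    records: Sequence[CompoundRecord],
    mode: str = "custom",
    *,
    seed: int = 0,
    screen_after_parent: bool = False,
    max_attempts: int = 5000,
) -> tuple[GraphDataset, list[StandardizationOutcome], list[FeaturizationFailure]]:
    """Standardise and featurise a record list.

    Returns the graph dataset plus the standardisation outcomes (for
    rejection accounting) and any featurisation failures.
    """
    outcomes = standardize_dataset(records, screen_after_parent=screen_after_parent)
    accepted = [o for o in outcomes if o.accepted]
    dataset, failures = featurize_records(
        [o.record for o in accepted],
        [o.standardized_smiles for o in accepted],
        FeatureSchema(mode=mode),
        seed=seed,
        max_attempts=max_attempts,
    )
    return dataset, outcomes, failures
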