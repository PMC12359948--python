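"""Standardise a small compound library and account for every record.

Runs the bundled toy library through the screening/normalisation pipeline and
prints, per record, whether it was accepted (with its canonical standardised
SMILES) or rejected (with the failing stage). The accepted/rejected counts
always sum to the input count — rejection is a result, never an exception.
"""

from molgnn.standardize import standardize_dataset
from molgnn.synth import toy_library

outcomes = standardize_dataset(toy_library())
for o in outcomes:
    if o.accepted:
        print(f"  ok  {o.record.name:28s} -> {o.standardized_smiles}")
    else:
        print(f"REJECT {o.record.name:27s} at {o.stage_failed}: {o.message}")

n_ok = sum(o.accepted for o in outcomes)
print(f"\naccepted {n_ok} / {len(outcomes)} records")
print("Accepted SMILES are single-fragment, neutralised, tautomer-canonical")
print("forms over the ten allowed elements (H C N O F P S Cl Br I).")
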