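"""Published reference confusion matrices for the three taxonomies.

These evaluation-phase count matrices (video frames; rows true, columns
predicted) come from a published direct-observation video study of
free-living physical behavior and ship with the package as verification
fixtures: re-deriving their per-class precision/recall/F1 and overall
accuracy exercises the whole metrics stack against independently printed
numbers.

The Taxonomy 2 running row was scored on the testing fold (the class
appeared in too few videos to populate every fold) and its AUC weight was
suppressed by 94 percent in the published average — the same substitution
and suppression mechanisms :func:`behavframe.evaluate.ovr_auc` implements.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .evaluate import ConfusionMatrix

__all__ = ["REFERENCE_TAXONOMIES", "load_reference_confusion", "RUNNING_SUPPRESSION"]

REFERENCE_TAXONOMIES = ("T1_sedentary", "T2_activity_type", "T3_intensity")

_FILES = {
    "T1_sedentary": "confusion_t1.csv",
    "T2_activity_type": "confusion_t2.csv",
    "T3_intensity": "confusion_t3.csv",
}

#: Published weight multiplier for the running class in the T2 averaged AUC
#: (a 94 percent suppression).
RUNNING_SUPPRESSION = 0.06


def load_reference_confusion(taxonomy: str) -> ConfusionMatrix:
    """Load one shipped reference matrix by taxonomy name (or T1/T2/T3)."""
    aliases = {"T1": "T1_sedentary", "T2": "T2_activity_type", "T3": "T3_intensity"}
    taxonomy = aliases.get(taxonomy, taxonomy)
    if taxonomy not in _FILES:
        raise KeyError(f"no reference matrix for {taxonomy!r}")
    ref = resources.files("behavframe") / "data" / _FILES[taxonomy]
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, index_col="class")
    return ConfusionMatrix(tuple(df.columns), df.to_numpy())
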