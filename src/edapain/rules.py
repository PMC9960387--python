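"""Single-feature Boolean pain classifiers.

Four rules, each a strict inequality on one scalar computed from the raw
trace, decide "high pain" vs "no pain" without any training:

* ``start_end``       — high pain iff x_1 < x_l
* ``late_argmax``     — high pain iff the (1-based, first-occurrence) argmax
                        falls after 7/10 of the window
* ``argspan``         — high pain iff argmax - argmin (signed) exceeds l/4
* ``positive_drift``  — high pain iff the discrete derivative sums to > 0

Because the derivative telescopes (sum(x') = x_l - x_1 with x'_1 = 0),
``start_end`` and ``positive_drift`` are the same classifier; both are kept
because both summaries are in the feature battery. All four rules depend only
on value *order*, so they are invariant under any strictly increasing
transform of the trace.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .preprocess import discrete_derivative
from .synth import WindowSet

__all__ = ["RULE_IDS", "apply_rule", "rule_accuracy", "rule_decision_table"]

RULE_IDS = ("start_end", "late_argmax", "argspan", "positive_drift")

LATE_FRACTION = 7 / 10
SPAN_FRACTION = 1 / 4

HIGH_PAIN = "high_pain"
NO_PAIN = "no_pain"


def apply_rule(rule: str, values: np.ndarray) -> str:
    """Classify one raw trace; returns ``"high_pain"`` or ``"no_pain"``."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two samples")
    l = x.size
    if rule == "start_end":
        pain = x[0] < x[-1]
    elif rule == "late_argmax":
        pain = (np.argmax(x) + 1) > LATE_FRACTION * l
    elif rule == "argspan":
        pain = (np.argmax(x) - np.argmin(x)) > SPAN_FRACTION * l
    elif rule == "positive_drift":
        pain = discrete_derivative(x).sum() > 0
    else:
        raise ValueError(f"unknown rule {rule!r}; choose from {RULE_IDS}")
    return HIGH_PAIN if pain else NO_PAIN


def rule_decision_table(rule: str, windowset: WindowSet,
                        positive_label: str, negative_label: str) -> pd.DataFrame:
    """Per-window decisions for windows carrying the two task labels."""
    rows = []
    for w in windowset.windows:
        if w.label not in (positive_label, negative_label):
            continue
        pred = apply_rule(rule, w.values)
        truth = HIGH_PAIN if w.label == positive_label else NO_PAIN
        rows.append({
            "subject_id": w.subject_id, "label": w.label, "rep": w.rep,
            "prediction": pred, "truth": truth, "correct": pred == truth,
        })
    if not rows:
        raise ValueError(
            f"no windows labelled {positive_label!r} or {negative_label!r}")
    return pd.DataFrame(rows)


def rule_accuracy(rule: str, windowset: WindowSet,
                  positive_label: str, negative_label: str) -> float:
    """Fraction of two-class windows whose rule output matches their label."""
    table = rule_decision_table(rule, windowset, positive_label, negative_label)
    return float(table["correct"].mean())
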