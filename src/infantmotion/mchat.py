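"""M-CHAT scoring and ASD-risk grouping.

The Modified Checklist for Autism in Toddlers comprises 23 yes/no items;
an item is "failed" when the response indicates atypical development.
The Japanese version designates ten items as critical, and the screening
cutoff flags a child as high risk when at least one critical item or any
three items are failed.  Items are numbered 1-based as on the form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: 1-based indices of the critical items (Japanese M-CHAT).
CRITICAL_ITEMS = frozenset({2, 6, 7, 9, 13, 14, 15, 20, 21, 23})

N_ITEMS = 23

HIGH, LOW = "high", "low"


@dataclass(frozen=True)
class MChatRecord:
    items: tuple[bool, ...]   # True = failed, index 0 is item 1
    total_failed: int
    critical_failed: int
    risk: str
    infant_id: str = ""


def score(items, allow_missing: bool = False) -> tuple[int, int]:
    """Count failed items overall and within the critical subset.

    ``items`` holds 23 truthy/falsy responses (True = failed).  Missing
    values (None/NaN) are rejected unless ``allow_missing``, in which case
    they count as passed.
    """
    items = list(items)
    if len(items) != N_ITEMS:
        raise ValueError(f"expected {N_ITEMS} item responses, got {len(items)}")
    cleaned = []
    for i, v in enumerate(items, start=1):
        if v is None or (isinstance(v, float) and np.isnan(v)):
            if not allow_missing:
                raise ValueError(f"missing response for item {i}")
            v = False
        cleaned.append(bool(v))
    total = sum(cleaned)
    critical = sum(v for i, v in enumerate(cleaned, start=1)
                   if i in CRITICAL_ITEMS)
    return total, critical


def risk_group(total_failed: int, critical_failed: int) -> str:
    """Cutoff rule: high risk iff >= 1 critical item or >= 3 items failed."""
    if not 0 <= critical_failed <= total_failed <= N_ITEMS:
        raise ValueError("invalid failed-item counts")
    return HIGH if (critical_failed >= 1 or total_failed >= 3) else LOW


def classify_items(items, allow_missing: bool = False,
                   infant_id: str = "") -> MChatRecord:
    total, critical = score(items, allow_missing=allow_missing)
    return MChatRecord(items=tuple(bool(v) for v in items),
                       total_failed=total, critical_failed=critical,
                       risk=risk_group(total, critical), infant_id=infant_id)


def score_table(df: pd.DataFrame, allow_missing: bool = False) -> pd.DataFrame:
    """Score a table with columns infant_id, item1..item23.

    Returns a copy with total_failed, critical_failed and risk appended.
    """
    cols = [f"item{i}" for i in range(1, N_ITEMS + 1)]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"missing item columns: {missing}")
    out = df.copy()
    totals, criticals, risks = [], [], []
    for _, row in df.iterrows():
        t, c = score(row[cols].tolist(), allow_missing=allow_missing)
        totals.append(t)
        criticals.append(c)
        risks.append(risk_group(t, c))
    out["total_failed"] = totals
    out["critical_failed"] = criticals
    out["risk"] = risks
    return out
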