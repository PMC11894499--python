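"""Reporting utilities: rounded percentages, exclusion arithmetic, summaries.

``STUDY_FLOW`` holds the published cohort-flow and predictive-edge counts
of the longitudinal trauma-survivor study this pipeline emulates; they are
treated as input data for report tables (every derived percentage is
recomputed from the raw counts, never stored).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: Printed counts from the emulated study's cohort flow and edge summaries.
STUDY_FLOW = {
    "scanned_1m": 171,
    "excluded": {"missing_mri": 6, "missing_clinical": 3},
    "analyzed_1m": 162,
    "completed_6m": 136,
    "completed_14m": 133,
    "motor_vehicle": 143,
    "predictive_edges_1m": {"positive": 14, "negative": 701},
    "predictive_edges_14m": {"positive": 3, "negative": 1374},
}


def percentage(numerator: float, denominator: float, ndigits: int = 1) -> float:
    """100 * numerator / denominator, rounded to ``ndigits`` decimals."""
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    return round(100.0 * numerator / denominator, ndigits)


def apply_exclusions(total: int, exclusions: dict[str, int]) -> int:
    """Remaining sample size after named exclusions (must stay non-negative)."""
    remaining = total - sum(exclusions.values())
    if remaining < 0:
        raise ValueError(f"exclusions exceed the total ({total})")
    return remaining


def edge_sign_shares(positive: int, negative: int,
                     ndigits: int = 1) -> dict[str, float]:
    """Percentage split of predictive edges by sign."""
    total = positive + negative
    return {"total": total,
            "positive_pct": percentage(positive, total, ndigits),
            "negative_pct": percentage(negative, total, ndigits)}


def study_flow_table(flow: dict | None = None) -> pd.DataFrame:
    """Recompute every percentage in the cohort-flow summary from counts."""
    f = flow or STUDY_FLOW
    n = apply_exclusions(f["scanned_1m"], f["excluded"])
    e1 = edge_sign_shares(**f["predictive_edges_1m"])
    e14 = edge_sign_shares(**f["predictive_edges_14m"])
    rows = [
        ("analyzed at 1 month", n, percentage(n, n)),
        ("completed 6 months", f["completed_6m"], percentage(f["completed_6m"], n)),
        ("completed 14 months", f["completed_14m"], percentage(f["completed_14m"], n)),
        ("motor-vehicle trauma", f["motor_vehicle"], percentage(f["motor_vehicle"], n)),
        ("positive edges, 1 month", f["predictive_edges_1m"]["positive"],
         e1["positive_pct"]),
        ("negative edges, 1 month", f["predictive_edges_1m"]["negative"],
         e1["negative_pct"]),
        ("positive edges, 14 months", f["predictive_edges_14m"]["positive"],
         e14["positive_pct"]),
        ("negative edges, 14 months", f["predictive_edges_14m"]["negative"],
         e14["negative_pct"]),
    ]
    return pd.DataFrame(rows, columns=["quantity", "count", "percent"])


def selection_frequency_summary(counts: np.ndarray, n_fits: int,
                                consensus: float = 1.0) -> dict:
    """Consensus predictive-edge counts from per-edge selection frequencies.

    An edge is a consensus edge if it was selected in at least
    ``consensus`` fraction of all (fold x repeat) model fits.
    """
    freq = counts / max(n_fits, 1)
    return {"n_fits": n_fits,
            "consensus_threshold": consensus,
            "n_consensus_edges": int((freq >= consensus).sum()),
            "max_frequency": float(freq.max(initial=0.0))}
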