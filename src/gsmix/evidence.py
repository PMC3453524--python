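"""Per-marker Bayes-factor evidence from mixture-model fits.

The prior-to-posterior odds ratio (PPOR) for a marker is the Bayes factor
for membership of the substantial-effect mixture component,

    PPOR = (p1_hat / (1 - p1_hat)) / (pi1 / (1 - pi1)),

with p1_hat the marker's posterior inclusion probability and pi1 the prior
mixture fraction.  On the usual evidence scale, PPOR > 3.2 counts as
substantial evidence, > 10 as strong and > 100 as decisive; boundary values
fall in the lower class (the inequalities are strict).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data_model import MarkerMap

#: strict lower bounds of the evidence classes
THRESHOLDS = {"substantial": 3.2, "strong": 10.0, "decisive": 100.0}
CLASSES = ("none", "substantial", "strong", "decisive")


def ppor(p1_hat, pi1: float):
    """Prior-to-posterior odds ratio; accepts a scalar or an array.

    Both arguments must lie strictly inside (0, 1): callers should obtain
    p1_hat from the clamped posterior inclusion probabilities.
    """
    p = np.asarray(p1_hat, dtype=np.float64)
    if np.any(p <= 0.0) or np.any(p >= 1.0):
        raise ValueError("p1_hat must lie strictly in (0, 1); clamp first")
    if not (0.0 < pi1 < 1.0):
        raise ValueError("pi1 must lie strictly in (0, 1)")
    out = (p / (1.0 - p)) / (pi1 / (1.0 - pi1))
    return float(out) if np.isscalar(p1_hat) else out


def classify_value(value: float) -> str:
    if value > THRESHOLDS["decisive"]:
        return "decisive"
    if value > THRESHOLDS["strong"]:
        return "strong"
    if value > THRESHOLDS["substantial"]:
        return "substantial"
    return "none"


def classify(
    ppor_values: np.ndarray,
    marker_map: MarkerMap,
    p1_hat: np.ndarray | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Evidence table sorted by genome position plus per-class counts."""
    v = np.asarray(ppor_values, dtype=np.float64)
    if not np.all(np.isfinite(v)):
        raise ValueError("PPOR values must be finite")
    if len(v) != len(marker_map):
        raise ValueError("PPOR vector does not match the marker map")
    df = pd.DataFrame(
        {
            "marker": marker_map.marker_ids,
            "chrom": marker_map.chrom,
            "pos": marker_map.pos,
            "ppor": v,
            "class": [classify_value(x) for x in v],
        }
    )
    if p1_hat is not None:
        df.insert(3, "p1_hat", np.asarray(p1_hat, dtype=np.float64))
    df = df.sort_values(
        ["chrom", "pos"], key=lambda c: c.map(_chrom_key) if c.name == "chrom" else c
    ).reset_index(drop=True)
    counts = {c: int((df["class"] == c).sum()) for c in CLASSES}
    return df, counts


def _chrom_key(label: str):
    try:
        return (0, int(label))
    except (TypeError, ValueError):
        return (1, str(label))


def manhattan_table(evidence: pd.DataFrame) -> pd.DataFrame:
    """Add a cumulative genome coordinate for plotting.

    Chromosomes are laid end to end in sorted order; each chromosome's
    offset is the running sum of the preceding chromosomes' spans (their
    largest marker position), so a single-chromosome map passes positions
    through unchanged.
    """
    df = evidence.copy()
    offset = 0
    cum = np.empty(len(df), dtype=np.int64)
    for c in sorted(df["chrom"].unique(), key=_chrom_key):
        sel = df["chrom"] == c
        cum[sel.to_numpy()] = df.loc[sel, "pos"].to_numpy() + offset
        offset += int(df.loc[sel, "pos"].max())
    df["genome_pos"] = cum
    return df
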