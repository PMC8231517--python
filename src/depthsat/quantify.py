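"""Counts to expression values: CPM, log2(CPM), the count>3 detection
rule, and expression-quartile classes.

log2(CPM) is taken of raw CPM with no pseudocount: values are only ever
produced for expressed genes (count > threshold >= 0), whose CPM is
strictly positive.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ConfigError
from .processing import DEFAULT_EXPRESSION_THRESHOLD

QUARTILE_LABELS = ("Q1", "Q2", "Q3", "Q4")


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million normalization, per sample (column).

    Each column sums to 10^6 afterwards.  A sample with no counts at all
    cannot be normalized and raises :class:`ConfigError`.
    """
    totals = counts.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ConfigError(f"all-zero sample(s): {list(zero.index)}")
    return counts / totals * 1e6


def detect_expressed(
    counts: pd.DataFrame, threshold: int = DEFAULT_EXPRESSION_THRESHOLD
) -> pd.DataFrame:
    """Boolean detection mask: count strictly greater than ``threshold``."""
    return counts > threshold


def log2cpm(
    counts: pd.DataFrame, threshold: int = DEFAULT_EXPRESSION_THRESHOLD
) -> pd.DataFrame:
    """log2(CPM) for expressed genes; non-expressed entries are NaN."""
    masked = cpm(counts).where(detect_expressed(counts, threshold))
    return np.log2(masked)


def quartile_classes(
    expr: pd.Series, catalog: pd.DataFrame, scheme: str = "per_class"
) -> pd.DataFrame:
    """Assign detected genes to expression quartiles Q1 (low) .. Q4 (high).

    ``expr`` is a reference log2(CPM) column (NaN = not expressed).  With
    ``scheme='per_class'`` coding and non-coding genes are ranked
    separately, each split into four near-equal groups; with
    ``scheme='pooled'`` all detected genes are ranked together (useful to
    ask where each class falls in the global expression range).

    Ties at the boundaries are resolved by stable rank order on
    (value, gene_id), so class sizes within a ranking differ by at most 1.
    """
    if scheme not in ("per_class", "pooled"):
        raise ConfigError(f"unknown quartile scheme: {scheme!r}")
    classes = catalog.set_index("gene_id")["coding_class"]
    detected = expr.dropna()
    if detected.empty:
        raise ConfigError("no detected genes to classify")
    frame = pd.DataFrame(
        {"value": detected, "coding_class": classes.reindex(detected.index)}
    )
    frame.index.name = "gene_id"
    if frame["coding_class"].isna().any():
        missing = frame.index[frame["coding_class"].isna()].tolist()
        raise ConfigError(f"genes absent from catalog: {missing[:10]}")

    def assign(block: pd.DataFrame) -> pd.Series:
        n = len(block)
        if n < 4:
            raise ConfigError(f"fewer than 4 genes in ranking (got {n})")
        order = block.sort_index().sort_values("value", kind="mergesort").index
        ranks = pd.Series(np.arange(n), index=order)
        labels = np.asarray(QUARTILE_LABELS, dtype=object)
        return pd.Series(labels[(4 * ranks.to_numpy()) // n], index=order)

    if scheme == "per_class":
        parts = [
            assign(block) for _, block in frame.groupby("coding_class", sort=True)
        ]
        quartile = pd.concat(parts)
    else:
        quartile = assign(frame)
    out = frame.copy()
    out["quartile"] = quartile.reindex(out.index)
    return out.reset_index()[["gene_id", "coding_class", "quartile"]]
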