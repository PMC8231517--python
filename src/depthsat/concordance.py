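"""Correlation-based reliability checks: replicate/subset Pearson
correlations, barcode-vs-subset comparison, and qPCR delta-Ct agreement."""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, PairingError

PAIRING_MODES = ("intersection", "union-zero")

QPCR_COLUMNS = ["gene_id", "ct_target", "ct_reference"]


def pearson(x, y) -> tuple[float, float]:
    """Product-moment correlation with a two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ConfigError("x and y must be 1-D vectors of equal length")
    if len(x) < 3:
        raise ConfigError(f"need at least 3 observations, got {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConfigError("zero-variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def pair_expression(
    a: pd.Series, b: pd.Series, mode: str = "intersection"
) -> pd.DataFrame:
    """Pair two expression columns (NaN = not expressed) gene-by-gene.

    ``intersection`` keeps genes expressed in both columns; ``union-zero``
    keeps genes expressed in either, imputing the missing side as 0 (the
    imputed entries are flagged in the ``imputed`` column).
    """
    if mode not in PAIRING_MODES:
        raise ConfigError(f"mode must be one of {PAIRING_MODES}, got {mode!r}")
    frame = pd.DataFrame({"a": a, "b": b})
    if mode == "intersection":
        paired = frame.dropna()
        paired = paired.assign(imputed=False)
    else:
        keep = frame.notna().any(axis=1)
        paired = frame.loc[keep]
        paired = paired.assign(imputed=paired.isna().any(axis=1)).fillna(0.0)
    if paired.empty:
        raise PairingError(f"no genes paired under mode {mode!r}")
    return paired


def dct(panel: pd.DataFrame) -> pd.Series:
    """Delta cycle threshold per gene: ``ct_target - ct_reference``."""
    missing = [c for c in QPCR_COLUMNS if c not in panel.columns]
    if missing:
        raise ConfigError(f"qPCR panel missing column(s): {missing}")
    if panel["ct_reference"].isna().any():
        raise ConfigError("missing reference Ct value(s)")
    values = panel["ct_target"].astype(float) - panel["ct_reference"].astype(float)
    values.index = panel["gene_id"]
    return values.rename("dct")


def qpcr_concordance(expr: pd.Series, panel: pd.DataFrame) -> dict[str, float | int]:
    """Correlate expression (log2 CPM) with qPCR delta-Ct over panel genes.

    Panel genes absent from ``expr`` (or not expressed) are dropped; at
    least 3 must remain.  Both the signed correlation and its absolute
    value are reported: higher expression implies a lower delta-Ct, so the
    natural sign of the relationship is negative.
    """
    deltas = dct(panel)
    paired = pd.DataFrame({"expr": expr.reindex(deltas.index), "dct": deltas}).dropna()
    n_dropped = len(deltas) - len(paired)
    if len(paired) < 3:
        raise PairingError(
            f"only {len(paired)} panel gene(s) overlap the expression column"
        )
    r, p = pearson(paired["expr"], paired["dct"])
    return {
        "r": r,
        "abs_r": abs(r),
        "p_value": p,
        "n_genes": int(len(paired)),
        "n_dropped": int(n_dropped),
    }


def multiplex_vs_subset(
    barcode_expr: Mapping[str, pd.Series],
    subset_expr: pd.Series,
    mode: str = "intersection",
) -> pd.DataFrame:
    """Correlate each barcode's expression column against a reference subset.

    ``subset_expr`` should come from a subsample whose size matches the
    typical barcode library (so the comparison is at equal depth).
    Returns one row per barcode: expressed-gene counts, the number of
    genes paired, and the Pearson correlation.
    """
    if not barcode_expr:
        raise ConfigError("no barcode expression columns supplied")
    rows = []
    for label in sorted(barcode_expr):
        expr = barcode_expr[label]
        paired = pair_expression(expr, subset_expr, mode=mode)
        r, p = pearson(paired["a"], paired["b"])
        rows.append(
            {
                "barcode": label,
                "n_expressed": int(expr.notna().sum()),
                "n_paired": int(len(paired)),
                "r": r,
                "p_value": p,
            }
        )
    return pd.DataFrame(rows)


def read_qpcr_panel(path) -> pd.DataFrame:
    """Load a qPCR panel TSV with columns gene_id, ct_target, ct_reference."""
    panel = pd.read_csv(path, sep="\t")
    missing = [c for c in QPCR_COLUMNS if c not in panel.columns]
    if missing:
        raise ConfigError(f"{path}: missing column(s): {missing}")
    if (panel["ct_target"] <= 0).any() or (panel["ct_reference"] <= 0).any():
        raise ConfigError(f"{path}: Ct values must be positive")
    return panel
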