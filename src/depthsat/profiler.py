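"""Replicated fractional subsampling and depth-saturation statistics.

This is the core of the package: draw replicated random subsets of a read
library at a ladder of fractions, then summarise how gene detection and
expression quantification degrade with depth.  The per-gene statistic is
the percent expression variation

    variation = (reference - subset) / reference * 100

computed on log2(CPM) values, restricted to genes detected in at least
80% of a fraction's replicates (and in the reference, with nonzero
reference log2(CPM), which the formula divides by).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError
from .processing import DEFAULT_EXPRESSION_THRESHOLD, count_reads
from .quantify import QUARTILE_LABELS

DEFAULT_FRACTIONS = (0.9, 0.8, 0.7, 0.6, 0.5, 0.4, 0.3, 0.2, 0.1, 0.05)

#: Default fraction of replicates in which a gene must be detected to enter
#: the variation table.
DEFAULT_MIN_REPLICATE_DETECTION = 0.8

#: Stride separating the seed blocks of successive fractions.
_SEED_STRIDE = 10007

#: Label of the pseudo-gene bucket holding unassigned reads in count-level
#: subsampling.
UNMAPPED_BUCKET = "__unmapped__"


def subset_size(total_reads: int, fraction: float) -> int:
    """Number of reads in a fractional subset: round-half-up(fraction * total)."""
    if not 0.0 < fraction <= 1.0:
        raise ConfigError(f"fraction must be in (0, 1], got {fraction}")
    return math.floor(fraction * total_reads + 0.5)


@dataclass(frozen=True)
class SubsetSpec:
    """Subsampling plan: which fractions, how many replicates, base seed."""

    fractions: Sequence[float] = DEFAULT_FRACTIONS
    n_replicates: int = 10
    base_seed: int = 0

    def validate(self) -> None:
        for f in self.fractions:
            if not 0.0 < f <= 1.0:
                raise ConfigError(f"fraction must be in (0, 1], got {f}")
        if self.n_replicates < 1:
            raise ConfigError("n_replicates must be positive")

    def replicate_seed(self, fraction_index: int, replicate_index: int) -> int:
        # deterministic, collision-free for any plan with < _SEED_STRIDE replicates
        return self.base_seed + _SEED_STRIDE * fraction_index + replicate_index


@dataclass
class SubsetReplicate:
    """One random subsample: its provenance and the resulting gene counts."""

    fraction: float
    replicate: int
    seed: int
    counts: pd.Series  # indexed by gene_id, over the full catalog
    n_total_reads: int
    n_mapped_reads: int


def subsample(
    reads: pd.DataFrame, catalog: pd.DataFrame, spec: SubsetSpec
) -> list[SubsetReplicate]:
    """Read-level subsampling: uniform draws without replacement.

    For each (fraction, replicate) pair an independent subset of exactly
    ``subset_size(len(reads), fraction)`` reads is drawn from its own
    deterministic seed, and gene counts are recomputed on the subset.
    """
    spec.validate()
    if len(reads) == 0:
        raise ConfigError("read table is empty")
    n_total = len(reads)
    gene_codes, gene_index = _gene_codes(reads, catalog)
    out: list[SubsetReplicate] = []
    for fi, fraction in enumerate(spec.fractions):
        n = subset_size(n_total, fraction)
        if n == 0:
            raise ConfigError(f"fraction {fraction} yields an empty subset")
        for r in range(spec.n_replicates):
            seed = spec.replicate_seed(fi, r)
            rng = np.random.default_rng(seed)
            idx = rng.choice(n_total, size=n, replace=False)
            sub_codes = gene_codes[idx]
            sub_codes = sub_codes[sub_codes >= 0]
            counts = pd.Series(
                np.bincount(sub_codes, minlength=len(gene_index)).astype(np.int64),
                index=gene_index,
            )
            out.append(
                SubsetReplicate(
                    fraction=fraction,
                    replicate=r,
                    seed=seed,
                    counts=counts,
                    n_total_reads=n,
                    n_mapped_reads=int(counts.sum()),
                )
            )
    return out


def _gene_codes(reads: pd.DataFrame, catalog: pd.DataFrame):
    """Encode read gene assignments as catalog positions; unmapped = -1."""
    gene_index = pd.Index(catalog["gene_id"], name="gene_id")
    # reuse count_reads' validation of unknown genes on the full table
    count_reads(reads, catalog)
    codes = gene_index.get_indexer(reads["gene_id"].fillna(UNMAPPED_BUCKET))
    return codes, gene_index


def subsample_counts(
    counts: pd.Series,
    spec: SubsetSpec,
    n_unmapped: int = 0,
) -> list[SubsetReplicate]:
    """Count-level subsampling via multivariate hypergeometric draws.

    Marginally identical in distribution to read-level :func:`subsample`
    on the same library, but operates directly on a count column (plus an
    optional bucket of ``n_unmapped`` unassigned reads, so fractions apply
    to the whole library rather than only its mapped part).
    """
    spec.validate()
    if n_unmapped < 0:
        raise ConfigError("n_unmapped must be >= 0")
    colors = counts.to_numpy(dtype=np.int64)
    if (colors < 0).any():
        raise ConfigError("counts must be non-negative")
    n_total = int(colors.sum()) + n_unmapped
    pool = np.concatenate([colors, [n_unmapped]])
    out: list[SubsetReplicate] = []
    for fi, fraction in enumerate(spec.fractions):
        n = subset_size(n_total, fraction)
        if n == 0:
            raise ConfigError(f"fraction {fraction} yields an empty subset")
        if n > n_total:
            raise ConfigError("subset larger than library")
        for r in range(spec.n_replicates):
            seed = spec.replicate_seed(fi, r)
            rng = np.random.default_rng(seed)
            draw = rng.multivariate_hypergeometric(pool, n, method="marginals")
            sub = pd.Series(draw[:-1].astype(np.int64), index=counts.index)
            out.append(
                SubsetReplicate(
                    fraction=fraction,
                    replicate=r,
                    seed=seed,
                    counts=sub,
                    n_total_reads=n,
                    n_mapped_reads=int(sub.sum()),
                )
            )
    return out


def detection_curve(
    replicates: Iterable[SubsetReplicate],
    catalog: pd.DataFrame,
    threshold: int = DEFAULT_EXPRESSION_THRESHOLD,
) -> pd.DataFrame:
    """Per-fraction detection summary, split by coding class.

    For each fraction: mean and CV (across replicates, percent, sample SD)
    of the number of detected genes, the same means for coding and
    non-coding genes separately, and the mean mapped read count.
    """
    coding = catalog.set_index("gene_id")["coding_class"] == "coding"
    rows: dict[float, list[SubsetReplicate]] = {}
    for rep in replicates:
        rows.setdefault(rep.fraction, []).append(rep)
    if not rows:
        raise ConfigError("no replicates supplied")
    records = []
    for fraction in sorted(rows):
        reps = rows[fraction]
        det_total, det_cod, det_non, mapped = [], [], [], []
        for rep in reps:
            mask = rep.counts > threshold
            is_coding = coding.reindex(rep.counts.index).to_numpy()
            det_total.append(int(mask.sum()))
            det_cod.append(int((mask.to_numpy() & is_coding).sum()))
            det_non.append(int((mask.to_numpy() & ~is_coding).sum()))
            mapped.append(rep.n_mapped_reads)
        det = np.asarray(det_total, dtype=float)
        cv = float(det.std(ddof=1) / det.mean() * 100.0) if len(det) > 1 else None
        records.append(
            {
                "fraction": fraction,
                "n_replicates": len(reps),
                "mean_total_reads": float(np.mean([r.n_total_reads for r in reps])),
                "mean_mapped_reads": float(np.mean(mapped)),
                "mean_detected": float(det.mean()),
                "cv_detected_percent": cv,
                "mean_detected_coding": float(np.mean(det_cod)),
                "mean_detected_noncoding": float(np.mean(det_non)),
            }
        )
    return pd.DataFrame(records)


def gev(ref_log2cpm: float, subset_log2cpm: float) -> float:
    """Percent expression variation of a subset value against the reference.

    ``(ref - subset) / ref * 100``; positive when the subset
    under-estimates the reference.  Undefined for a zero reference.
    """
    if ref_log2cpm == 0:
        raise ConfigError("reference log2(CPM) is 0; variation undefined")
    return (ref_log2cpm - subset_log2cpm) / ref_log2cpm * 100.0


def gev_table(
    ref_expr: pd.Series,
    replicates: Iterable[SubsetReplicate],
    catalog: pd.DataFrame,
    quartiles: pd.DataFrame | None = None,
    threshold: int = DEFAULT_EXPRESSION_THRESHOLD,
    min_replicate_detection: float = DEFAULT_MIN_REPLICATE_DETECTION,
) -> pd.DataFrame:
    """Per-gene, per-replicate expression-variation table.

    For each fraction, eligible genes are those detected (count >
    ``threshold``) in at least ``ceil(min_replicate_detection *
    n_replicates)`` of its replicates, detected in the reference, and with
    nonzero reference log2(CPM).  One row is emitted per eligible gene per
    replicate in which it is detected, annotated with coding class and
    (when ``quartiles`` is given) reference expression quartile.
    """
    if not 0.0 < min_replicate_detection <= 1.0:
        raise ConfigError("min_replicate_detection must be in (0, 1]")
    coding = catalog.set_index("gene_id")["coding_class"]
    qmap = (
        quartiles.set_index("gene_id")["quartile"] if quartiles is not None else None
    )
    by_fraction: dict[float, list[SubsetReplicate]] = {}
    for rep in replicates:
        by_fraction.setdefault(rep.fraction, []).append(rep)

    ref_ok = ref_expr.notna() & (ref_expr != 0.0)
    frames = []
    for fraction in sorted(by_fraction):
        reps = by_fraction[fraction]
        need = math.ceil(min_replicate_detection * len(reps))
        det = pd.DataFrame({rep.replicate: rep.counts > threshold for rep in reps})
        eligible = (det.sum(axis=1) >= need) & ref_ok.reindex(det.index, fill_value=False)
        for rep in reps:
            detected = rep.counts > threshold
            sel = (eligible & detected).to_numpy()
            if not sel.any():
                continue
            genes = rep.counts.index[sel]
            lib = rep.counts.sum()
            sub_log = np.log2(rep.counts.to_numpy()[sel] / lib * 1e6)
            ref = ref_expr.reindex(genes).to_numpy()
            frames.append(
                pd.DataFrame(
                    {
                        "gene_id": genes,
                        "fraction": fraction,
                        "replicate": rep.replicate,
                        "gev_percent": (ref - sub_log) / ref * 100.0,
                        "coding_class": coding.reindex(genes).to_numpy(),
                        "quartile": (
                            qmap.reindex(genes).to_numpy() if qmap is not None else None
                        ),
                    }
                )
            )
    if not frames:
        return pd.DataFrame(
            columns=[
                "gene_id",
                "fraction",
                "replicate",
                "gev_percent",
                "coding_class",
                "quartile",
            ]
        )
    return pd.concat(frames, ignore_index=True)


@dataclass
class GevSummary:
    """Distribution summaries of an expression-variation table."""

    overall: pd.DataFrame
    by_class: pd.DataFrame
    by_quartile: pd.DataFrame
    quartile_correlation: pd.DataFrame = field(default_factory=pd.DataFrame)


def _summarize(group: pd.DataFrame) -> pd.Series:
    g = group["gev_percent"].to_numpy()
    q1, med, q3 = np.percentile(g, [25, 50, 75])
    return pd.Series(
        {
            "n": len(g),
            "median_gev": med,
            "iqr_gev": q3 - q1,
            "mean_abs_gev": float(np.abs(g).mean()),
            "median_abs_gev": float(np.median(np.abs(g))),
        }
    )


def gev_summary(table: pd.DataFrame) -> GevSummary:
    """Summaries per fraction, per coding class, and per expression quartile.

    Also reports, per fraction, the Spearman rank correlation between the
    quartile label (Q1=1 .. Q4=4) and the per-gene mean absolute
    variation, when quartile annotations are present.
    """
    if table.empty:
        raise ConfigError("empty variation table")
    overall = (
        table.groupby("fraction").apply(_summarize, include_groups=False).reset_index()
    )
    by_class = (
        table.groupby(["fraction", "coding_class"])
        .apply(_summarize, include_groups=False)
        .reset_index()
    )
    has_quartiles = table["quartile"].notna().any()
    if has_quartiles:
        by_quartile = (
            table.groupby(["fraction", "coding_class", "quartile"])
            .apply(_summarize, include_groups=False)
            .reset_index()
        )
        qnum = {label: i + 1 for i, label in enumerate(QUARTILE_LABELS)}
        corr_rows = []
        for fraction, block in table.groupby("fraction"):
            per_gene = (
                block.assign(abs_gev=block["gev_percent"].abs())
                .groupby("gene_id")
                .agg(abs_gev=("abs_gev", "mean"), quartile=("quartile", "first"))
            )
            ranks = per_gene["quartile"].map(qnum)
            rho, p = stats.spearmanr(ranks, per_gene["abs_gev"])
            corr_rows.append(
                {"fraction": fraction, "spearman_rho": float(rho), "p_value": float(p)}
            )
        quartile_correlation = pd.DataFrame(corr_rows)
    else:
        by_quartile = pd.DataFrame()
        quartile_correlation = pd.DataFrame()
    return GevSummary(
        overall=overall,
        by_class=by_class,
        by_quartile=by_quartile,
        quartile_correlation=quartile_correlation,
    )
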