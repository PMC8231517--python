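"""Read-level filters and transforms: quality filtering, demultiplexing,
read-to-gene counting, and ingest of featureCounts-style count tables."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, TableParseError

#: Group label for reads without a barcode.
UNCLASSIFIED = "unclassified"

#: Default detection rule: a gene is expressed when its count is strictly
#: greater than this many reads.
DEFAULT_EXPRESSION_THRESHOLD = 3

_FEATURECOUNTS_ANNOT = ["Geneid", "Chr", "Start", "End", "Strand", "Length"]


@dataclass(frozen=True)
class FilterResult:
    """Outcome of a quality filter pass."""

    reads: pd.DataFrame
    n_input: int
    n_pass: int

    @property
    def pass_fraction(self) -> float:
        return self.n_pass / self.n_input if self.n_input else float("nan")


def quality_filter(reads: pd.DataFrame, min_q: float = 7.0) -> FilterResult:
    """Retain reads whose mean Phred quality is at or above ``min_q``.

    Reads with mean quality exactly ``min_q`` are kept (only reads strictly
    below the threshold are discarded).  Input order is preserved.
    """
    if min_q < 0:
        raise ConfigError(f"min_q must be >= 0, got {min_q}")
    keep = reads["mean_q"].to_numpy() >= min_q
    out = reads.loc[keep].reset_index(drop=True)
    return FilterResult(reads=out, n_input=len(reads), n_pass=len(out))


def demultiplex(reads: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Split a read table by barcode.

    Reads with a null barcode are collected under the ``unclassified`` key.
    Group sizes always sum to the input size.
    """
    barcodes = reads["barcode"]
    groups: dict[str, pd.DataFrame] = {}
    null_mask = barcodes.isna()
    if null_mask.any():
        groups[UNCLASSIFIED] = reads.loc[null_mask].reset_index(drop=True)
    for label, frame in reads.loc[~null_mask].groupby("barcode", sort=True):
        groups[str(label)] = frame.reset_index(drop=True)
    return groups


def count_reads(
    reads: pd.DataFrame, catalog: pd.DataFrame, sample_label: str = "sample"
) -> pd.DataFrame:
    """Count mapped reads per gene into a one-column count matrix.

    The result is indexed by the catalog's ``gene_id`` order; genes absent
    from ``reads`` get 0 and unmapped reads are excluded.  A read assigned
    to a gene missing from the catalog is an error.
    """
    gene_index = pd.Index(catalog["gene_id"], name="gene_id")
    if gene_index.has_duplicates:
        raise ConfigError("catalog contains duplicate gene_id values")
    mapped = reads["gene_id"].dropna()
    unknown = sorted(set(mapped) - set(gene_index))
    if unknown:
        raise ConfigError(
            f"reads reference {len(unknown)} gene(s) absent from catalog: "
            + ", ".join(unknown[:10])
        )
    counts = mapped.value_counts().reindex(gene_index, fill_value=0).astype(np.int64)
    return counts.to_frame(name=sample_label)


def read_featurecounts_table(path) -> pd.DataFrame:
    """Parse a featureCounts-style TSV into a count matrix.

    Expected layout: an optional leading ``#`` program line, a header
    ``Geneid  Chr  Start  End  Strand  Length  <sample>...``, then one row
    per gene.  Annotation columns are discarded; counts must be
    non-negative integers and gene ids unique.
    """
    with open(path, encoding="utf-8") as fh:
        lines = fh.readlines()
    if lines and lines[0].startswith("#"):
        lines = lines[1:]
        offset = 2
    else:
        offset = 1
    if not lines:
        raise TableParseError(f"{path}: missing header line")
    header = lines[0].rstrip("\n").split("\t")
    if header[: len(_FEATURECOUNTS_ANNOT)] != _FEATURECOUNTS_ANNOT:
        raise TableParseError(
            f"{path}: line {offset}: header must start with {_FEATURECOUNTS_ANNOT}"
        )
    samples = header[len(_FEATURECOUNTS_ANNOT) :]
    if not samples:
        raise TableParseError(f"{path}: line {offset}: no sample columns")
    if len(set(samples)) != len(samples):
        raise TableParseError(f"{path}: duplicate sample labels")

    gene_ids: list[str] = []
    values: list[list[int]] = []
    for i, line in enumerate(lines[1:], start=offset + 1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != len(header):
            raise TableParseError(
                f"{path}: line {i}: expected {len(header)} fields, got {len(parts)}"
            )
        gene_ids.append(parts[0])
        row: list[int] = []
        for sample, raw in zip(samples, parts[len(_FEATURECOUNTS_ANNOT) :]):
            try:
                value = int(raw)
            except ValueError as exc:
                raise TableParseError(
                    f"{path}: line {i}: non-integer count {raw!r} in column {sample}"
                ) from exc
            if value < 0:
                raise TableParseError(
                    f"{path}: line {i}: negative count in column {sample}"
                )
            row.append(value)
        values.append(row)
    if len(set(gene_ids)) != len(gene_ids):
        dupes = pd.Series(gene_ids).value_counts()
        dupes = dupes[dupes > 1].index.tolist()
        raise TableParseError(f"{path}: duplicate Geneid values: {dupes[:10]}")
    return pd.DataFrame(
        np.asarray(values, dtype=np.int64).reshape(len(gene_ids), len(samples)),
        index=pd.Index(gene_ids, name="gene_id"),
        columns=samples,
    )


def barcode_summary(
    groups: dict[str, pd.DataFrame],
    catalog: pd.DataFrame,
    threshold: int = DEFAULT_EXPRESSION_THRESHOLD,
) -> pd.DataFrame:
    """Per-barcode totals: total reads, mapped reads and expressed genes.

    ``groups`` is the output of :func:`demultiplex`; the ``unclassified``
    group is excluded from the summary.  A gene counts as expressed in a
    barcode when its read count is strictly greater than ``threshold``.
    """
    labels = [k for k in groups if k != UNCLASSIFIED]
    if not labels:
        raise ConfigError("no barcode groups to summarize")
    rows = []
    for label in labels:
        frame = groups[label]
        counts = count_reads(frame, catalog, sample_label=label)[label]
        rows.append(
            {
                "barcode": label,
                "total_reads": len(frame),
                "mapped_reads": int(counts.sum()),
                "n_genes": int((counts > threshold).sum()),
            }
        )
    return pd.DataFrame(rows)


def barcode_stats(summary: pd.DataFrame) -> dict[str, float | None]:
    """Across-barcode statistics of a barcode summary table.

    Returns the mean and sum of ``total_reads``, the minimum of
    ``n_genes``, and the coefficient of variation of ``n_genes`` computed
    as 100 x sample standard deviation (n-1 denominator) / mean.  With a
    single barcode the CV is undefined and reported as None.
    """
    totals = summary["total_reads"].to_numpy(dtype=float)
    genes = summary["n_genes"].to_numpy(dtype=float)
    if len(summary) >= 2:
        cv = float(genes.std(ddof=1) / genes.mean() * 100.0)
    else:
        cv = None
    return {
        "n_barcodes": int(len(summary)),
        "mean_total_reads": float(totals.mean()),
        "sum_total_reads": float(totals.sum()),
        "min_n_genes": float(genes.min()),
        "gene_count_cv_percent": cv,
    }
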