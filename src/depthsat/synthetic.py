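"""Synthetic gene catalogs and long-read-style read tables.

Reads are atomic records (gene assignment, length, mean Phred quality,
optional barcode) -- no per-base simulation.  Every downstream statistic
in the package consumes only these four per-read quantities, so this is
all the structure a test dataset needs.

The default configuration emulates a combined Nanopore cDNA run: ~60/40
coding/non-coding gene split with non-coding genes shifted to lower
abundance, mean read length near 483 bp, ~58% of reads assigned to a
gene, and a Phred-quality distribution straddling the Q=7 cutoff.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, TableParseError

BIOTYPES = ("protein_coding", "lncRNA", "ncRNA", "pseudogene")
NONCODING_BIOTYPES = ("lncRNA", "ncRNA", "pseudogene")
CODING = "coding"
NONCODING = "non_coding"

#: Sentinel for a null gene or barcode in TSV files (echoes SAM's unmapped "*").
NULL_TOKEN = "*"

CATALOG_COLUMNS = ["gene_id", "biotype", "weight"]
READ_COLUMNS = ["read_id", "gene_id", "length", "mean_q", "barcode"]

# Mixing proportions of the three non-coding biotypes in generated catalogs.
_NONCODING_MIX = (0.5, 0.3, 0.2)


def coding_class(biotype: str) -> str:
    """Collapse a biotype into the binary coding / non-coding class."""
    if biotype == "protein_coding":
        return CODING
    if biotype in NONCODING_BIOTYPES:
        return NONCODING
    raise ConfigError(f"unknown biotype: {biotype!r}")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic dataset generator.

    Distribution "laws" are mappings with a ``name`` key plus parameters;
    the supported names are ``lognormal`` (expression and read length)
    and ``truncated_normal`` (quality).
    """

    n_genes: int = 20_000
    coding_fraction: float = 0.62
    expression_law: Mapping[str, object] = field(
        default_factory=lambda: {
            "name": "lognormal",
            "sigma": 2.0,
            # Down-shift of the non-coding location parameter, natural-log units.
            "noncoding_shift": 1.5,
        }
    )
    n_reads: int = 2_000_000
    mapped_fraction: float = 0.58
    read_length_law: Mapping[str, object] = field(
        default_factory=lambda: {"name": "lognormal", "mean": 483.0, "sigma": 0.35}
    )
    quality_law: Mapping[str, object] = field(
        default_factory=lambda: {
            "name": "truncated_normal",
            "mean": 10.0,
            "sd": 3.0,
            "lower": 0.0,
        }
    )
    n_barcodes: int = 0
    barcode_weights: Sequence[float] | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 2:
            raise ConfigError(f"n_genes must be >= 2, got {self.n_genes}")
        if not 0.0 < self.coding_fraction < 1.0:
            raise ConfigError(
                f"coding_fraction must be in (0, 1), got {self.coding_fraction}"
            )
        # mapped_fraction == 1.0 is allowed: an all-mapped toy dataset is useful.
        if not 0.0 < self.mapped_fraction <= 1.0:
            raise ConfigError(
                f"mapped_fraction must be in (0, 1], got {self.mapped_fraction}"
            )
        if self.n_reads < 1:
            raise ConfigError(f"n_reads must be positive, got {self.n_reads}")
        if self.n_barcodes < 0:
            raise ConfigError(f"n_barcodes must be >= 0, got {self.n_barcodes}")
        if self.barcode_weights is not None:
            w = np.asarray(self.barcode_weights, dtype=float)
            if len(w) != self.n_barcodes:
                raise ConfigError(
                    f"barcode_weights has length {len(w)}, expected {self.n_barcodes}"
                )
            if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
                raise ConfigError("barcode_weights must be >= 0 and sum to 1")
        for law, names in (
            (self.expression_law, {"lognormal"}),
            (self.read_length_law, {"lognormal"}),
            (self.quality_law, {"truncated_normal"}),
        ):
            if law.get("name") not in names:
                raise ConfigError(f"unsupported law: {law.get('name')!r}")

    def resolved_barcode_weights(self) -> np.ndarray | None:
        if self.n_barcodes == 0:
            return None
        if self.barcode_weights is None:
            return np.full(self.n_barcodes, 1.0 / self.n_barcodes)
        return np.asarray(self.barcode_weights, dtype=float)


def _round_half_up(x: float) -> int:
    return math.floor(x + 0.5)


def generate_catalog(config: SimulationConfig) -> pd.DataFrame:
    """Generate a gene catalog with abundance weights.

    Returns a DataFrame with columns ``gene_id``, ``biotype``,
    ``coding_class`` and ``weight``.  Exactly
    ``round(n_genes * coding_fraction)`` genes are protein-coding; weights
    are log-normal, normalized to sum to 1, with the non-coding location
    parameter shifted down so non-coding genes sit at lower abundance.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 0])
    n_coding = _round_half_up(config.n_genes * config.coding_fraction)
    n_noncoding = config.n_genes - n_coding

    gene_ids = [f"G{i:06d}" for i in range(config.n_genes)]
    biotypes = ["protein_coding"] * n_coding + list(
        rng.choice(NONCODING_BIOTYPES, size=n_noncoding, p=_NONCODING_MIX)
    )

    sigma = float(config.expression_law.get("sigma", 2.0))
    shift = float(config.expression_law.get("noncoding_shift", 1.5))
    mu = np.zeros(config.n_genes)
    mu[n_coding:] = -shift
    weights = np.exp(rng.normal(mu, sigma))
    weights /= weights.sum()

    catalog = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "biotype": biotypes,
            "coding_class": [coding_class(b) for b in biotypes],
            "weight": weights,
        }
    )
    return catalog


def _draw_lengths(rng: np.random.Generator, law: Mapping, n: int) -> np.ndarray:
    sigma = float(law.get("sigma", 0.35))
    mean = float(law.get("mean", 483.0))
    # log-normal parameterized by its arithmetic mean
    mu = math.log(mean) - sigma**2 / 2.0
    lengths = np.rint(rng.lognormal(mu, sigma, size=n)).astype(np.int64)
    return np.maximum(lengths, 1)


def _draw_qualities(rng: np.random.Generator, law: Mapping, n: int) -> np.ndarray:
    mean = float(law.get("mean", 10.0))
    sd = float(law.get("sd", 3.0))
    lower = float(law.get("lower", 0.0))
    a = (lower - mean) / sd
    q = stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=n, random_state=rng)
    return np.round(q, 3)


def quality_pass_probability(config: SimulationConfig, min_q: float = 7.0) -> float:
    """Mass of the configured quality law at or above ``min_q`` (closed form)."""
    law = config.quality_law
    mean, sd = float(law["mean"]), float(law["sd"])
    lower = float(law.get("lower", 0.0))
    a = (lower - mean) / sd
    return float(stats.truncnorm.sf((min_q - mean) / sd, a, np.inf))


def simulate_reads(catalog: pd.DataFrame, config: SimulationConfig) -> pd.DataFrame:
    """Simulate a read table over ``catalog``.

    Each read is mapped with probability ``mapped_fraction``; mapped reads
    are assigned to genes multinomially by abundance weight.  Lengths,
    qualities and (optionally) barcodes are drawn independently.  Fully
    reproducible from ``config.seed``.
    """
    config.validate()
    if len(catalog) == 0:
        raise ConfigError("catalog is empty")
    rng = np.random.default_rng([config.seed, 1])
    n = config.n_reads

    mapped = rng.random(n) < config.mapped_fraction
    n_mapped = int(mapped.sum())
    weights = catalog["weight"].to_numpy(dtype=float)
    weights = weights / weights.sum()
    gene_idx = rng.choice(len(catalog), size=n_mapped, p=weights)

    gene_ids = np.full(n, None, dtype=object)
    gene_ids[mapped] = catalog["gene_id"].to_numpy()[gene_idx]

    lengths = _draw_lengths(rng, config.read_length_law, n)
    qualities = _draw_qualities(rng, config.quality_law, n)

    barcodes = np.full(n, None, dtype=object)
    bw = config.resolved_barcode_weights()
    if bw is not None:
        labels = np.array([f"BC{i + 1}" for i in range(config.n_barcodes)], dtype=object)
        barcodes = labels[rng.choice(config.n_barcodes, size=n, p=bw)]

    return pd.DataFrame(
        {
            "read_id": [f"R{i:08d}" for i in range(n)],
            "gene_id": gene_ids,
            "length": lengths,
            "mean_q": qualities,
            "barcode": barcodes,
        }
    )


# ---------------------------------------------------------------------------
# TSV round-trip I/O
# ---------------------------------------------------------------------------


def write_catalog(catalog: pd.DataFrame, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(CATALOG_COLUMNS) + "\n")
        for row in catalog.itertuples(index=False):
            fh.write(f"{row.gene_id}\t{row.biotype}\t{row.weight!r}\n")


def read_catalog(path) -> pd.DataFrame:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        if header.split("\t") != CATALOG_COLUMNS:
            raise TableParseError(f"{path}: line 1: expected header {CATALOG_COLUMNS}")
        gene_ids: list[str] = []
        biotypes: list[str] = []
        weights: list[float] = []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3:
                raise TableParseError(f"{path}: line {lineno}: expected 3 fields")
            gid, biotype, weight = parts
            if biotype not in BIOTYPES:
                raise TableParseError(
                    f"{path}: line {lineno}: unknown biotype {biotype!r}"
                )
            try:
                weights.append(float(weight))
            except ValueError as exc:
                raise TableParseError(
                    f"{path}: line {lineno}: non-numeric weight {weight!r}"
                ) from exc
            gene_ids.append(gid)
            biotypes.append(biotype)
    if len(set(gene_ids)) != len(gene_ids):
        raise TableParseError(f"{path}: duplicate gene_id values")
    return pd.DataFrame(
        {
            "gene_id": gene_ids,
            "biotype": biotypes,
            "coding_class": [coding_class(b) for b in biotypes],
            "weight": weights,
        }
    )


def write_reads(reads: pd.DataFrame, path) -> None:
    """Write a read table as TSV; null gene/barcode encoded as ``*``."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(READ_COLUMNS) + "\n")
        for row in reads.itertuples(index=False):
            gene = NULL_TOKEN if row.gene_id is None else row.gene_id
            barcode = NULL_TOKEN if row.barcode is None else row.barcode
            fh.write(f"{row.read_id}\t{gene}\t{row.length:d}\t{row.mean_q:.3f}\t{barcode}\n")


def read_reads(path) -> pd.DataFrame:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        if header.split("\t") != READ_COLUMNS:
            raise TableParseError(f"{path}: line 1: expected header {READ_COLUMNS}")
        rows: list[tuple] = []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 5:
                raise TableParseError(f"{path}: line {lineno}: expected 5 fields")
            rid, gene, length, mean_q, barcode = parts
            try:
                length_i = int(length)
            except ValueError as exc:
                raise TableParseError(
                    f"{path}: line {lineno}: non-integer length {length!r}"
                ) from exc
            if length_i < 1:
                raise TableParseError(f"{path}: line {lineno}: length must be >= 1")
            try:
                q = float(mean_q)
            except ValueError as exc:
                raise TableParseError(
                    f"{path}: line {lineno}: non-numeric mean_q {mean_q!r}"
                ) from exc
            if q < 0:
                raise TableParseError(f"{path}: line {lineno}: mean_q must be >= 0")
            rows.append(
                (
                    rid,
                    None if gene == NULL_TOKEN else gene,
                    length_i,
                    q,
                    None if barcode == NULL_TOKEN else barcode,
                )
            )
    frame = pd.DataFrame(rows, columns=READ_COLUMNS)
    if frame.empty:
        frame = pd.DataFrame(
            {
                "read_id": pd.Series(dtype=object),
                "gene_id": pd.Series(dtype=object),
                "length": pd.Series(dtype=np.int64),
                "mean_q": pd.Series(dtype=float),
                "barcode": pd.Series(dtype=object),
            }
        )
    else:
        frame["length"] = frame["length"].astype(np.int64)
        frame["mean_q"] = frame["mean_q"].astype(float)
    return frame
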