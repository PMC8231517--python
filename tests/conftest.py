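"""Shared fixtures: hand-built toy catalogs and a medium synthetic dataset."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import depthsat as ds


def make_catalog(weights, biotypes=None) -> pd.DataFrame:
    """Build a catalog DataFrame with explicit weights (normalized)."""
    weights = np.asarray(weights, dtype=float)
    n = len(weights)
    if biotypes is None:
        biotypes = ["protein_coding"] * n
    coding = [
        "coding" if b == "protein_coding" else "non_coding" for b in biotypes
    ]
    return pd.DataFrame(
        {
            "gene_id": [f"g{i + 1}" for i in range(n)],
            "biotype": biotypes,
            "coding_class": coding,
            "weight": weights / weights.sum(),
        }
    )


def make_reads(gene_ids, mean_q=12.0, barcode=None) -> pd.DataFrame:
    """Build a read table from a list of gene ids (None = unmapped)."""
    n = len(gene_ids)
    if np.isscalar(mean_q):
        mean_q = [float(mean_q)] * n
    if barcode is None or isinstance(barcode, str):
        barcode = [barcode] * n
    return pd.DataFrame(
        {
            "read_id": [f"r{i + 1}" for i in range(n)],
            "gene_id": list(gene_ids),
            "length": np.full(n, 100, dtype=np.int64),
            "mean_q": np.asarray(mean_q, dtype=float),
            "barcode": list(barcode),
        }
    )


@pytest.fixture(scope="session")
def toy_catalog() -> pd.DataFrame:
    return make_catalog(
        [0.4, 0.3, 0.2, 0.07, 0.03],
        biotypes=["protein_coding", "protein_coding", "lncRNA", "ncRNA", "pseudogene"],
    )


@pytest.fixture(scope="session")
def medium_config() -> ds.SimulationConfig:
    return ds.SimulationConfig(n_genes=3000, n_reads=300_000, seed=5)


@pytest.fixture(scope="session")
def medium_data(medium_config):
    """A mid-sized simulated dataset profiled at three fractions."""
    catalog = ds.generate_catalog(medium_config)
    reads = ds.simulate_reads(catalog, medium_config)
    filt = ds.quality_filter(reads, min_q=7.0)
    counts = ds.count_reads(filt.reads, catalog, sample_label="reference")
    ref_counts = counts["reference"]
    n_unmapped = filt.n_pass - int(ref_counts.sum())
    spec = ds.SubsetSpec(fractions=(0.9, 0.5, 0.05), n_replicates=10, base_seed=5)
    replicates = ds.subsample_counts(ref_counts, spec, n_unmapped=n_unmapped)
    ref_expr = ds.log2cpm(counts)["reference"]
    quartiles = ds.quartile_classes(ref_expr, catalog)
    table = ds.gev_table(ref_expr, replicates, catalog, quartiles=quartiles)
    return {
        "config": medium_config,
        "catalog": catalog,
        "reads": reads,
        "filtered": filt,
        "counts": counts,
        "ref_counts": ref_counts,
        "n_unmapped": n_unmapped,
        "spec": spec,
        "replicates": replicates,
        "ref_expr": ref_expr,
        "quartiles": quartiles,
        "gev_table": table,
    }
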