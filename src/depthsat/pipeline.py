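"""End-to-end orchestration: simulate -> filter -> count -> quantify ->
profile -> concord, with TSV/JSON outputs and structured per-stage logging."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import concordance, processing, profiler, quantify, synthetic
from .errors import ConfigError, DepthSatError

log = logging.getLogger("depthsat")

#: Library size of the study-scale reference dataset used by
#: :func:`validate_against_table1`-style desk checks.
FULL_FRACTION_LADDER = (1.0,) + profiler.DEFAULT_FRACTIONS


@dataclass
class RunConfig:
    """Full pipeline configuration (simulation, subsampling, thresholds)."""

    simulation: synthetic.SimulationConfig = field(
        default_factory=synthetic.SimulationConfig
    )
    subsets: profiler.SubsetSpec = field(default_factory=profiler.SubsetSpec)
    quality_threshold: float = 7.0
    expression_threshold: int = 3
    min_replicate_detection: float = 0.8
    write_reads: bool = False
    write_gev_table: bool = False
    plots: bool = False

    def validate(self) -> None:
        self.simulation.validate()
        self.subsets.validate()
        if self.quality_threshold < 0:
            raise ConfigError("quality_threshold must be >= 0")
        if self.expression_threshold < 0:
            raise ConfigError("expression_threshold must be >= 0")
        if not 0.0 < self.min_replicate_detection <= 1.0:
            raise ConfigError("min_replicate_detection must be in (0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        sim = synthetic.SimulationConfig(**raw.pop("simulation", {}))
        sub_raw = raw.pop("subsets", {})
        if "fractions" in sub_raw:
            sub_raw["fractions"] = tuple(sub_raw["fractions"])
        subsets = profiler.SubsetSpec(**sub_raw)
        return cls(simulation=sim, subsets=subsets, **raw)

    def to_yaml(self, path) -> None:
        raw = dataclasses.asdict(self)
        raw["simulation"] = dataclasses.asdict(self.simulation)
        raw["subsets"] = dataclasses.asdict(self.subsets)
        raw["subsets"]["fractions"] = list(self.subsets.fractions)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(raw, fh, sort_keys=True)


def validate_against_table1(
    total_reads: int, fractions: Sequence[float] = FULL_FRACTION_LADDER
) -> pd.DataFrame:
    """Expected subset sizes for a fraction ladder over a fixed library."""
    return pd.DataFrame(
        {
            "fraction": list(fractions),
            "expected_total_reads": [
                profiler.subset_size(total_reads, f) for f in fractions
            ],
        }
    )


def _json_default(value):
    if isinstance(value, (np.integer,)):
        return int(value)
    if isinstance(value, (np.floating,)):
        return float(value)
    raise TypeError(f"not JSON serializable: {type(value)}")


def _round_floats(obj, ndigits: int = 10):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Run every stage on a synthetic dataset and write the report bundle.

    Writes TSV tables for counts, expression, quartiles, detection curve
    and variation summaries (plus optional read table, full variation
    table and PNG plots), and a machine-readable ``summary.json`` of the
    headline numbers.  Deterministic given the config (incl. seeds).
    Stage failures are re-raised with the stage name prepended.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config": {"seed": config.simulation.seed}}

    stage = "simulate"
    try:
        catalog = synthetic.generate_catalog(config.simulation)
        reads = synthetic.simulate_reads(catalog, config.simulation)
        synthetic.write_catalog(catalog, outdir / "catalog.tsv")
        if config.write_reads:
            synthetic.write_reads(reads, outdir / "reads.tsv")
        log.info("simulate: %d genes, %d reads", len(catalog), len(reads))
        summary["simulate"] = {"n_genes": len(catalog), "n_reads": len(reads)}

        stage = "filter"
        filt = processing.quality_filter(reads, min_q=config.quality_threshold)
        log.info(
            "filter: %d/%d reads pass (%.4f)",
            filt.n_pass,
            filt.n_input,
            filt.pass_fraction,
        )
        summary["filter"] = {
            "n_input": filt.n_input,
            "n_pass": filt.n_pass,
            "pass_fraction": filt.pass_fraction,
        }

        stage = "count"
        if filt.n_pass == 0:
            raise ConfigError("no reads pass the quality filter")
        counts = processing.count_reads(filt.reads, catalog, sample_label="reference")
        ref_counts = counts["reference"]
        n_mapped = int(ref_counts.sum())
        n_unmapped = filt.n_pass - n_mapped
        log.info("count: %d mapped of %d passed reads", n_mapped, filt.n_pass)
        summary["count"] = {
            "n_mapped": n_mapped,
            "n_unmapped": n_unmapped,
            "mapped_fraction": n_mapped / filt.n_pass,
        }
        counts.to_csv(outdir / "counts.tsv", sep="\t")

        stage = "quantify"
        expr = quantify.log2cpm(counts, threshold=config.expression_threshold)
        ref_expr = expr["reference"]
        detected = ref_expr.notna()
        coding = catalog.set_index("gene_id")["coding_class"] == "coding"
        quartiles = quantify.quartile_classes(ref_expr, catalog, scheme="per_class")
        expr.to_csv(outdir / "expression.tsv", sep="\t", na_rep="NA")
        quartiles.to_csv(outdir / "quartiles.tsv", sep="\t", index=False)
        summary["quantify"] = {
            "n_detected": int(detected.sum()),
            "n_detected_coding": int((detected & coding).sum()),
            "n_detected_noncoding": int((detected & ~coding).sum()),
        }

        stage = "profile"
        replicates = profiler.subsample_counts(
            ref_counts, config.subsets, n_unmapped=n_unmapped
        )
        curve = profiler.detection_curve(
            replicates, catalog, threshold=config.expression_threshold
        )
        table = profiler.gev_table(
            ref_expr,
            replicates,
            catalog,
            quartiles=quartiles,
            threshold=config.expression_threshold,
            min_replicate_detection=config.min_replicate_detection,
        )
        gsum = profiler.gev_summary(table)
        curve.to_csv(outdir / "detection_curve.tsv", sep="\t", index=False)
        if config.write_gev_table:
            table.to_csv(outdir / "gev_table.tsv", sep="\t", index=False)
        gsum.overall.to_csv(outdir / "gev_summary.tsv", sep="\t", index=False)
        gsum.by_class.to_csv(outdir / "gev_summary_by_class.tsv", sep="\t", index=False)
        gsum.by_quartile.to_csv(
            outdir / "gev_summary_by_quartile.tsv", sep="\t", index=False
        )
        gsum.quartile_correlation.to_csv(
            outdir / "gev_quartile_correlation.tsv", sep="\t", index=False
        )
        summary["profile"] = {
            "detection_curve": curve.to_dict(orient="records"),
            "gev_overall": gsum.overall.to_dict(orient="records"),
            "quartile_correlation": gsum.quartile_correlation.to_dict(orient="records"),
        }

        stage = "concord"
        concord: dict = {}
        # subset-vs-reference correlation per fraction (first replicate each)
        rows = []
        for rep in replicates:
            if rep.replicate != 0:
                continue
            rep_expr = quantify.log2cpm(
                rep.counts.to_frame("subset"), threshold=config.expression_threshold
            )["subset"]
            paired = concordance.pair_expression(rep_expr, ref_expr)
            r, p = concordance.pearson(paired["a"], paired["b"])
            rows.append({"fraction": rep.fraction, "r": r, "p_value": p})
        subset_corr = pd.DataFrame(rows).sort_values("fraction", ignore_index=True)
        subset_corr.to_csv(outdir / "subset_correlation.tsv", sep="\t", index=False)
        concord["subset_vs_reference"] = subset_corr.to_dict(orient="records")

        if config.simulation.n_barcodes > 0:
            groups = processing.demultiplex(filt.reads)
            bsum = processing.barcode_summary(
                groups, catalog, threshold=config.expression_threshold
            )
            bstats = processing.barcode_stats(bsum)
            bsum.to_csv(outdir / "barcode_summary.tsv", sep="\t", index=False)
            # equal-depth subset: fraction chosen so subset size ~ mean barcode total
            frac = min(1.0, bstats["mean_total_reads"] / filt.n_pass)
            eq_spec = profiler.SubsetSpec(
                fractions=(frac,),
                n_replicates=1,
                base_seed=config.subsets.base_seed + 1,
            )
            eq_rep = profiler.subsample_counts(
                ref_counts, eq_spec, n_unmapped=n_unmapped
            )[0]
            eq_expr = quantify.log2cpm(
                eq_rep.counts.to_frame("subset"), threshold=config.expression_threshold
            )["subset"]
            barcode_expr = {
                label: quantify.log2cpm(
                    processing.count_reads(frame, catalog, sample_label=label),
                    threshold=config.expression_threshold,
                )[label]
                for label, frame in groups.items()
                if label != processing.UNCLASSIFIED
            }
            mvs = concordance.multiplex_vs_subset(barcode_expr, eq_expr)
            mvs.to_csv(outdir / "multiplex_vs_subset.tsv", sep="\t", index=False)
            concord["barcode_stats"] = bstats
            concord["multiplex_vs_subset"] = mvs.to_dict(orient="records")
        summary["concord"] = concord

        if config.plots:
            stage = "plots"
            _write_plots(outdir, curve, table)
    except DepthSatError as exc:
        raise DepthSatError(f"stage {stage!r}: {exc}") from exc

    summary = _round_floats(summary)
    with open(outdir / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")
    return summary


def _write_plots(outdir: Path, curve: pd.DataFrame, table: pd.DataFrame) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(curve["fraction"], curve["mean_detected"], "o-k", label="total")
    ax.plot(curve["fraction"], curve["mean_detected_coding"], "o-r", label="coding")
    ax.plot(
        curve["fraction"], curve["mean_detected_noncoding"], "o-g", label="non-coding"
    )
    ax.set_xlabel("subset fraction")
    ax.set_ylabel("mean detected genes")
    ax.legend()
    fig.tight_layout()
    fig.savefig(outdir / "detection_curve.png", dpi=120)
    plt.close(fig)

    if not table.empty:
        fractions = sorted(table["fraction"].unique())
        data = [
            table.loc[table["fraction"] == f, "gev_percent"].to_numpy()
            for f in fractions
        ]
        fig, ax = plt.subplots(figsize=(7, 4))
        ax.violinplot(data, showmedians=True)
        ax.set_xticks(range(1, len(fractions) + 1))
        ax.set_xticklabels([f"{f:g}" for f in fractions])
        ax.set_xlabel("subset fraction")
        ax.set_ylabel("expression variation (%)")
        fig.tight_layout()
        fig.savefig(outdir / "gev_distributions.png", dpi=120)
        plt.close(fig)
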