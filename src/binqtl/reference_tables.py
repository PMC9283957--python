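"""Published summary tables from the B. napus seed-oil-content mapping study
these pipelines emulate, shipped as inputs for arithmetic cross-checks.

Three tables are bundled: per-environment trait summaries of the RIL and
diversity panels, per-chromosome SNP counts of the 2.34M-SNP panel set, and
the per-linkage-group characteristics of the 2,799-bin genetic map.  The
helpers recompute the derivable aggregate cells (CVs, totals, densities,
subgenome sums) from the raw columns so they can be compared with the
printed values.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _load(name: str) -> pd.DataFrame:
    with resources.files("binqtl.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def trait_summaries() -> pd.DataFrame:
    """Per-environment seed-oil-content summary rows (13 rows: 9 RIL
    environments, 3 panel years, panel BLUP)."""
    return _load("trait_summaries.tsv")


def snp_counts() -> pd.DataFrame:
    """Per-chromosome SNP counts and densities of the MAF-filtered panel."""
    return _load("snp_counts.tsv")


def linkage_map_characteristics() -> pd.DataFrame:
    """Per-linkage-group bin counts, distances and gap statistics."""
    return _load("linkage_map_characteristics.tsv")


def snp_count_summary(df: pd.DataFrame | None = None) -> dict:
    """Total SNPs, mean per chromosome, and per-kb densities recomputed from
    the raw count and length columns."""
    df = snp_counts() if df is None else df
    dens = (df["snp_number"] / df["chromosome_length"] * 1000).round(2)
    return {
        "total_snps": int(df["snp_number"].sum()),
        "mean_per_chromosome": int(round(df["snp_number"].sum() / len(df))),
        "density_per_kb": dict(zip(df["chromosome"], dens)),
    }
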