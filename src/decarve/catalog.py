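"""decRNA catalog tables: TSV/BED output and summary arithmetic.

The catalog mirrors the published supplementary-table schema: host gene,
percent overlap with the coding region, genomic coordinates (written
1-based inclusive), sequence and predicted per-nucleotide fold
stability.  Chaperone-interaction columns are appended when enrichment
results are available.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .detection import DecRnaCall
from .rnase_chaperone import EnrichmentResult
from .structure_stats import FoldingEngine, fold_energy, get_engine

CATALOG_COLUMNS = [
    "decrna_id", "host_gene", "chrom", "start", "end", "strand", "length",
    "cds_overlap_percent", "category", "n_replicates_support",
    "boundary_corrected", "fold_energy_kcal_mol", "stability_per_nt", "sequence",
]


def calls_to_dataframe(
    calls: Sequence[DecRnaCall],
    engine: Optional[FoldingEngine] = None,
    fold: bool = True,
) -> pd.DataFrame:
    """Catalog DataFrame; coordinates are converted to 1-based inclusive."""
    if fold and calls:
        engine = engine or get_engine()
    rows = []
    for c in calls:
        energy = fold_energy(c.sequence, engine) if fold else np.nan
        rows.append(
            {
                "decrna_id": c.id,
                "host_gene": c.host_gene_id,
                "chrom": c.replicon_id,
                "start": c.interval[0] + 1,
                "end": c.interval[1],
                "strand": c.strand,
                "length": c.length,
                "cds_overlap_percent": round(100.0 * c.cds_overlap_fraction, 2),
                "category": c.category,
                "n_replicates_support": c.n_replicates_support,
                "boundary_corrected": c.boundary_corrected,
                "fold_energy_kcal_mol": energy,
                "stability_per_nt": energy / c.length if fold else np.nan,
                "sequence": c.sequence,
            }
        )
    return pd.DataFrame(rows, columns=CATALOG_COLUMNS)


def merge_enrichment(
    catalog: pd.DataFrame, results: Sequence[EnrichmentResult]
) -> pd.DataFrame:
    enr = pd.DataFrame(
        [
            {
                "decrna_id": r.decrna_id,
                "hfq_mean_coverage": r.hfq_mean_coverage,
                "hfq_call": r.hfq_call,
                "proq_mean_coverage": r.proq_mean_coverage,
                "proq_enrichment": r.proq_enrichment,
                "proq_call": r.proq_call,
            }
            for r in results
        ]
    )
    return catalog.merge(enr, on="decrna_id", how="left")


def write_catalog_tsv(catalog: pd.DataFrame, path) -> None:
    catalog.to_csv(path, sep="\t", index=False)


def read_catalog_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_catalog_bed(calls: Sequence[DecRnaCall], path) -> None:
    """BED6 (0-based half-open) of the calls; score = replicate support."""
    with open(path, "w") as fh:
        for c in calls:
            fh.write(
                f"{c.replicon_id}\t{c.interval[0]}\t{c.interval[1]}\t{c.id}\t"
                f"{c.n_replicates_support}\t{c.strand}\n"
            )


def summarize_catalog(catalog: pd.DataFrame) -> dict:
    """Headline arithmetic over a catalog table.

    Returns segment count, length statistics, the fraction of segments
    with majority/complete CDS overlap, and — when enrichment columns
    are present — the number and fraction of chaperone-interacting
    segments plus the mean ProQ enrichment of the ProQ-called set.
    """
    n = len(catalog)
    out: dict = {"n_decrnas": n}
    if n == 0:
        return out
    out["mean_length_nt"] = float(catalog["length"].mean())
    out["min_length_nt"] = int(catalog["length"].min())
    out["max_length_nt"] = int(catalog["length"].max())
    cds_major = (catalog["cds_overlap_percent"] > 50.0).sum()
    within = (catalog["cds_overlap_percent"] == 100.0).sum()
    out["n_cds_majority"] = int(cds_major)
    out["pct_cds_majority"] = round(100.0 * cds_major / n, 1)
    out["n_within_cds"] = int(within)
    out["pct_within_cds"] = round(100.0 * within / n, 1)
    if "hfq_call" in catalog.columns or "proq_call" in catalog.columns:
        hfq = catalog.get("hfq_call", pd.Series(False, index=catalog.index)).fillna(False)
        proq = catalog.get("proq_call", pd.Series(False, index=catalog.index)).fillna(False)
        either = (hfq.astype(bool) | proq.astype(bool))
        out["n_hfq"] = int(hfq.astype(bool).sum())
        out["n_proq"] = int(proq.astype(bool).sum())
        out["n_chaperone"] = int(either.sum())
        out["pct_chaperone"] = round(100.0 * either.sum() / n, 1)
        if "proq_enrichment" in catalog.columns and proq.astype(bool).any():
            out["mean_proq_enrichment_called"] = round(
                float(catalog.loc[proq.astype(bool), "proq_enrichment"].mean()), 1
            )
    return out
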