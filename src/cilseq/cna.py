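"""Copy-number amplification calling and clustering from gene-level log2 ratios.

Works downstream of any segmentation tool: the input is a gene-by-sample
table of log2(CN/2) copy ratios (a simplified normalized-coverage ratio is
provided for the case where only per-bin coverage is available).  Deletions
are ignored throughout; only amplifications (log2 ratio >= 1, i.e. CN >= 4)
are called, then restricted to genes that are recurrently amplified in a
reference cohort and amplified more often in tumor than in paratumor
samples, and finally used to cluster samples.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from ._hierarchy import Dendrogram, hierarchical_cluster

logger = logging.getLogger(__name__)


def compute_gene_log2(sample_cov: pd.DataFrame, control_cov: pd.DataFrame,
                      gene_map: pd.DataFrame) -> pd.DataFrame:
    """Gene-level log2 copy ratio from per-bin coverage.

    ``sample_cov`` / ``control_cov`` columns: chrom, start, end, depth, on a
    shared set of bins; ``gene_map`` columns: gene, chrom, start, end
    (0-based half-open).  Each library is normalized by its genome-wide
    median bin coverage (so library-size differences cancel while focal
    gains do not), then per gene the log2 of (sample median bin coverage /
    control median bin coverage) is taken over the bins overlapping the
    gene.  Genes with no covered bin, or with zero control coverage across
    all bins, are flagged missing (NaN) and logged.
    """
    merged = sample_cov.merge(
        control_cov, on=["chrom", "start", "end"], suffixes=("_s", "_c"))
    s_norm = merged["depth_s"] / max(merged["depth_s"].median(), 1e-12)
    c_norm = merged["depth_c"] / max(merged["depth_c"].median(), 1e-12)
    merged = merged.assign(_s=s_norm, _c=c_norm)

    rows = []
    for g in gene_map.itertuples():
        hit = merged[(merged["chrom"] == g.chrom)
                     & (merged["start"] < g.end) & (merged["end"] > g.start)]
        if hit.empty:
            logger.warning("gene %s has no covered bins; flagged missing", g.gene)
            ratio = np.nan
        else:
            med_s = float(hit["_s"].median())
            med_c = float(hit["_c"].median())
            if med_c == 0:
                logger.warning("gene %s has zero control coverage; missing", g.gene)
                ratio = np.nan
            else:
                ratio = float(np.log2(med_s / med_c)) if med_s > 0 else -np.inf
        rows.append({"gene": g.gene, "chrom": g.chrom, "start": g.start,
                     "end": g.end, "log2_ratio": ratio})
    return pd.DataFrame(rows)


def qc_samples(table: pd.DataFrame, min_fraction: float = 0.5
               ) -> tuple[pd.DataFrame, list[str]]:
    """Drop samples covering less than ``min_fraction`` of target regions.

    ``table`` is a long gene-log2 table with a ``target_covered_fraction``
    per sample (fraction of target bases with >= 1 read).  Exactly at the
    threshold is retained (the rule is strictly "< 50%").  Returns the
    retained table and the dropped sample ids.
    """
    frac = table.groupby("sample_id")["target_covered_fraction"].first()
    dropped = sorted(frac.index[frac < min_fraction])
    if dropped:
        logger.info("samples failing coverage QC: %s", ", ".join(dropped))
    keep = table[~table["sample_id"].isin(dropped)].reset_index(drop=True)
    return keep, dropped


def call_amplifications(table: pd.DataFrame, compartments: dict[str, str],
                        threshold: float = 1.0) -> pd.DataFrame:
    """Boolean genes-by-samples amplification matrix.

    A gene is amplified in a sample iff its log2(CN/2) >= ``threshold``
    (inclusive at 1.0, i.e. CN >= 4).  Negative ratios (deletions) never
    produce calls; missing ratios are treated as not amplified.  Compartment
    labels (tumor/paratumor) must cover every sample and are attached as
    ``result.attrs["compartments"]``.
    """
    wide = table.pivot_table(index="gene", columns="sample_id",
                             values="log2_ratio", aggfunc="first")
    missing = [s for s in wide.columns if s not in compartments]
    if missing:
        raise ValueError(f"samples without compartment label: {missing}")
    amp = (wide >= threshold).fillna(False)
    amp = amp.sort_index(axis=0).sort_index(axis=1)
    amp.attrs["compartments"] = {s: compartments[s] for s in amp.columns}
    return amp


def filter_recurrent_genes(matrix: pd.DataFrame, cohort_freq: pd.DataFrame,
                           min_cohort_freq: float = 0.05,
                           min_tumor_excess: int = 3) -> list[str]:
    """Keep genes common in the reference cohort and tumor-enriched here.

    A gene is kept iff its cohort amplification frequency is >=
    ``min_cohort_freq`` AND (number of amplified tumor samples - number of
    amplified paratumor samples) >= ``min_tumor_excess``.  Genes absent from
    the cohort table count as frequency 0 (logged).
    """
    compartments = matrix.attrs.get("compartments")
    if compartments is None:
        raise ValueError("amplification matrix lacks compartment labels")
    freq = dict(zip(cohort_freq["gene"], cohort_freq["cohort_amp_frequency"]))
    tumor = [s for s in matrix.columns if compartments[s] == "tumor"]
    para = [s for s in matrix.columns if compartments[s] == "paratumor"]
    kept = []
    for gene, row in matrix.iterrows():
        f = freq.get(gene)
        if f is None:
            logger.info("gene %s absent from cohort table; frequency 0", gene)
            f = 0.0
        excess = int(row[tumor].sum()) - int(row[para].sum())
        if f >= min_cohort_freq and excess >= min_tumor_excess:
            kept.append(gene)
    return kept


def cluster_by_amplification(matrix: pd.DataFrame,
                             kept_genes: list[str] | None = None) -> Dendrogram:
    """Average-linkage tree over samples from Euclidean distances on the
    boolean amplification profiles, optionally restricted to kept genes."""
    sub = matrix.loc[kept_genes] if kept_genes is not None else matrix
    if sub.shape[0] == 0:
        raise ValueError(
            "no genes left to cluster on; review amplification thresholds")
    return hierarchical_cluster(sub.T.astype(float), metric="euclidean")
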