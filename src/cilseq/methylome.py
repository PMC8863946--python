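"""Tiled whole-genome bisulfite methylome analysis.

Input is a CX-report-like table per sample (chrom, pos, strand, context,
meth_count, unmeth_count).  The stages are:

* bisulfite conversion QC from non-CpG cytosines;
* per-base coverage filtering (3x to 500x inclusive);
* CpG dyad merging (+/− strand records summed per site) and tiling into
  fixed non-overlapping windows — 300 bp for fresh-frozen samples, 1 Mb for
  FFPE — discarding, per sample, tiles covered by fewer than three CpGs;
* global methylation levels and Pearson-correlation sample clustering;
* differential methylation between two sample groups by a 2x2 chi-square
  test on group-pooled counts with Benjamini-Hochberg correction — a DMR is
  a tile with q < 0.05 and absolute level difference > 0.25;
* chromatin-state annotation (15-state alphabet) by majority base overlap,
  Fisher-exact enrichment of DMRs per state (significant at q < 0.01), and
  the DMR-frequency statistic (DMR tiles / all common tiles x 100%).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import chi2, fisher_exact
from statsmodels.stats.multitest import multipletests

from ._hierarchy import Dendrogram, hierarchical_cluster, pairwise_pearson
from .synthetic import CHROMATIN_STATES

logger = logging.getLogger(__name__)

TILE_WIDTH = {"frozen": 300, "ffpe": 1_000_000}


def conversion_rate(non_cpg_calls: pd.DataFrame) -> tuple[float, float]:
    """Bisulfite conversion failure and conversion rate from non-CpG sites.

    The failure ratio r is methylated non-CpG observations over total
    non-CpG observations; conversion = 1 - r.  Returns ``(r, conversion)``.
    """
    nc = non_cpg_calls[non_cpg_calls["context"] != "CpG"]
    total = float(nc["meth_count"].sum() + nc["unmeth_count"].sum())
    if total == 0:
        raise ValueError("no non-CpG sites; cannot estimate conversion rate")
    r = float(nc["meth_count"].sum()) / total
    return r, 1.0 - r


def filter_bases(calls: pd.DataFrame, min_cov: int = 3, max_cov: int = 500
                 ) -> pd.DataFrame:
    """Discard bases covered below ``min_cov`` or above ``max_cov``.

    Both bounds are inclusive: exactly 3x and exactly 500x are kept, per the
    strict "larger than 500x or lower than 3x" discard wording.
    """
    cov = calls["meth_count"] + calls["unmeth_count"]
    return calls.loc[(cov >= min_cov) & (cov <= max_cov)].reset_index(drop=True)


def merge_cpg_dyads(calls: pd.DataFrame) -> pd.DataFrame:
    """Sum +/− strand records of each CpG dyad into one per-site record.

    A − strand record at pos is assigned to the dyad starting at pos - 1.
    Non-CpG contexts pass through unchanged.
    """
    cpg = calls[calls["context"] == "CpG"].copy()
    rest = calls[calls["context"] != "CpG"]
    if cpg.empty:
        return calls.copy()
    site = cpg["pos"].where(cpg["strand"] == "+", cpg["pos"] - 1)
    merged = (cpg.assign(pos=site)
              .groupby(["chrom", "pos"], as_index=False)[
                  ["meth_count", "unmeth_count"]].sum())
    merged["strand"] = "+"
    merged["context"] = "CpG"
    merged = merged[["chrom", "pos", "strand", "context",
                     "meth_count", "unmeth_count"]]
    return pd.concat([merged, rest], ignore_index=True)


def tile_windows(calls_by_sample: dict[str, pd.DataFrame], mode: str,
                 min_cpgs: int = 3, *, merge_dyads: bool = True,
                 prefilter: bool = True) -> pd.DataFrame:
    """Pool CpG counts into fixed non-overlapping windows per sample.

    ``mode`` selects the tile width: "frozen" = 300 bp, "ffpe" = 1 Mb (step
    equals width).  Dyad strands are merged per site before tiling, and the
    base filter is applied unless the caller already did so.  Per sample,
    tiles covered by fewer than ``min_cpgs`` CpG sites are discarded for
    that sample.

    Returns a long table: chrom, start, end, sample_id, n_cpgs, meth_count,
    coverage, level.
    """
    if mode not in TILE_WIDTH:
        raise ValueError(f"unknown tiling mode {mode!r}; use 'frozen' or 'ffpe'")
    width = TILE_WIDTH[mode]
    rows = []
    for sample_id, calls in calls_by_sample.items():
        cpg = calls[calls["context"] == "CpG"]
        if prefilter:
            cpg = filter_bases(cpg)
        if merge_dyads:
            cpg = merge_cpg_dyads(cpg)
        if cpg.empty:
            continue
        tile_start = (cpg["pos"] - 1) // width * width  # pos is 1-based
        grp = (cpg.assign(start=tile_start)
               .groupby(["chrom", "start"], as_index=False)
               .agg(n_cpgs=("pos", "size"), meth_count=("meth_count", "sum"),
                    unmeth=("unmeth_count", "sum")))
        grp = grp[grp["n_cpgs"] >= min_cpgs]
        grp["end"] = grp["start"] + width
        grp["sample_id"] = sample_id
        grp["coverage"] = grp["meth_count"] + grp["unmeth"]
        grp["level"] = grp["meth_count"] / grp["coverage"]
        rows.append(grp[["chrom", "start", "end", "sample_id", "n_cpgs",
                         "meth_count", "coverage", "level"]])
    if not rows:
        return pd.DataFrame(columns=["chrom", "start", "end", "sample_id",
                                     "n_cpgs", "meth_count", "coverage", "level"])
    return pd.concat(rows, ignore_index=True)


def global_level(calls: pd.DataFrame, prefilter: bool = True) -> float:
    """Coverage-weighted global CpG methylation: sum(meth) / sum(coverage)."""
    cpg = calls[calls["context"] == "CpG"]
    if prefilter:
        cpg = filter_bases(cpg)
    total = float(cpg["meth_count"].sum() + cpg["unmeth_count"].sum())
    if total == 0:
        raise ValueError("no covered CpG sites")
    return float(cpg["meth_count"].sum()) / total


def correlate_and_cluster(tiles: pd.DataFrame, samples: list[str] | None = None
                          ) -> tuple[pd.DataFrame, Dendrogram]:
    """Pearson correlation of per-tile levels and average-linkage clustering.

    Restricted to tiles present in every compared sample; the clustering
    distance is 1 - r.
    """
    wide = tiles.pivot_table(index=["chrom", "start"], columns="sample_id",
                             values="level", aggfunc="first")
    if samples is not None:
        wide = wide[samples]
    wide = wide.dropna(axis=0)
    if wide.shape[0] < 2:
        raise ValueError("fewer than 2 tiles shared by all samples")
    corr = pairwise_pearson(wide.T)
    tree = hierarchical_cluster(wide.T, metric="pearson")
    return corr, tree


def chi2_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Pearson chi-square (1 df, no continuity correction) on [[a,b],[c,d]].

    Returns (statistic, p).  Degenerate margins give statistic 0, p 1.
    """
    n = a + b + c + d
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    denom = r1 * r2 * c1 * c2
    if denom == 0:
        return 0.0, 1.0
    stat = n * (a * d - b * c) ** 2 / denom
    return float(stat), float(chi2.sf(stat, df=1))


def call_dmrs(tiles: pd.DataFrame, group_a: list[str], group_b: list[str],
              q_threshold: float = 0.05, diff_threshold: float = 0.25,
              min_samples_per_group: int = 2) -> pd.DataFrame:
    """Differential methylation between two sample groups over common tiles.

    Only tiles covered by >= ``min_samples_per_group`` samples in each group
    are tested.  Counts are pooled within each group and compared by the
    closed-form 2x2 chi-square (1 df, no continuity correction); p-values
    are Benjamini-Hochberg corrected across tested tiles.  ``diff`` is
    level_A - level_B; a DMR satisfies q < ``q_threshold`` and |diff| >
    ``diff_threshold`` (both strict); direction "hyper" means group B is
    hypermethylated relative to A (diff < -threshold), "hypo" the reverse.
    """
    in_a = tiles[tiles["sample_id"].isin(group_a)]
    in_b = tiles[tiles["sample_id"].isin(group_b)]
    key = ["chrom", "start", "end"]

    def pool(df: pd.DataFrame) -> pd.DataFrame:
        return df.groupby(key, as_index=False).agg(
            n_samples=("sample_id", "nunique"), meth=("meth_count", "sum"),
            cov=("coverage", "sum"))

    pa, pb = pool(in_a), pool(in_b)
    merged = pa.merge(pb, on=key, suffixes=("_a", "_b"))
    merged = merged[(merged["n_samples_a"] >= min_samples_per_group)
                    & (merged["n_samples_b"] >= min_samples_per_group)]
    zero = (merged["cov_a"] == 0) | (merged["cov_b"] == 0)
    if zero.any():
        logger.info("%d tiles with zero pooled coverage skipped", int(zero.sum()))
        merged = merged[~zero]
    merged = merged.reset_index(drop=True)
    if merged.empty:
        return pd.DataFrame(columns=key + [
            "level_a", "level_b", "diff", "chi2", "p", "q", "is_dmr",
            "direction"])

    level_a = merged["meth_a"] / merged["cov_a"]
    level_b = merged["meth_b"] / merged["cov_b"]
    # vectorized closed-form 2x2 chi-square (same arithmetic as chi2_2x2)
    a = merged["meth_a"].to_numpy(float)
    b = (merged["cov_a"] - merged["meth_a"]).to_numpy(float)
    c = merged["meth_b"].to_numpy(float)
    d = (merged["cov_b"] - merged["meth_b"]).to_numpy(float)
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(denom > 0, n * (a * d - b * c) ** 2 / denom, 0.0)
    p = chi2.sf(stat, df=1)
    p = np.where(denom > 0, p, 1.0)
    q = multipletests(p, method="fdr_bh")[1]
    diff = (level_a - level_b).to_numpy()
    is_dmr = (q < q_threshold) & (np.abs(diff) > diff_threshold)
    direction = np.where(diff < -diff_threshold, "hyper",
                         np.where(diff > diff_threshold, "hypo", "none"))
    out = merged[key].copy()
    out["level_a"] = level_a
    out["level_b"] = level_b
    out["diff"] = diff
    out["chi2"] = stat
    out["p"] = p
    out["q"] = q
    out["is_dmr"] = is_dmr
    out["direction"] = np.where(is_dmr, direction, "none")
    return out


def annotate_states(tiles: pd.DataFrame, annotation: pd.DataFrame) -> pd.Series:
    """Label each tile with the chromatin state of maximal base overlap.

    ``annotation`` is a BED-like table (chrom, start, end, state; 0-based
    half-open) over the 15-state alphabet.  Ties go to the lowest state
    number; tiles overlapping no interval are labeled "none".
    """
    bad = set(annotation["state"]) - set(CHROMATIN_STATES)
    if bad:
        raise ValueError(f"state labels outside the 15-state alphabet: {sorted(bad)}")
    order = {s: k for k, s in enumerate(CHROMATIN_STATES)}
    ann_by_chrom = {
        chrom: grp.sort_values("start")[["start", "end", "state"]].to_numpy()
        for chrom, grp in annotation.groupby("chrom")
    }
    labels = []
    for t in tiles.itertuples():
        best_state, best_ov = "none", 0
        for start, end, state in ann_by_chrom.get(t.chrom, ()):
            ov = min(t.end, end) - max(t.start, start)
            if ov <= 0:
                continue
            if ov > best_ov or (ov == best_ov and best_state != "none"
                                and order[state] < order[best_state]):
                best_state, best_ov = state, ov
        labels.append(best_state)
    return pd.Series(labels, index=tiles.index, name="state")


def enrichment(dmrs: pd.DataFrame, annotation: pd.DataFrame,
               q_threshold: float = 0.01) -> pd.DataFrame:
    """Fisher-exact chromatin-state enrichment of DMRs among common tiles.

    ``dmrs`` is the :func:`call_dmrs` output (all tested tiles, with
    ``is_dmr`` and ``direction``).  Per state and direction (hyper/hypo) the
    2x2 table [DMR-in-state, DMR-out; nonDMR-in-state, nonDMR-out] over all
    common tiles is tested two-sided; q-values are Benjamini-Hochberg within
    each direction across states; significant iff q < ``q_threshold`` and
    odds ratio > 1.  Also reports the per-state DMR frequency (percent of
    all common tiles).
    """
    tiles = dmrs.copy()
    tiles["state"] = annotate_states(tiles, annotation)
    n_total = len(tiles)
    rows = []
    for direction in ("hypo", "hyper"):
        flagged = tiles["is_dmr"] & (tiles["direction"] == direction)
        recs = []
        for state in CHROMATIN_STATES:
            in_state = tiles["state"] == state
            if not in_state.any():
                continue
            a = int((flagged & in_state).sum())
            b = int((flagged & ~in_state).sum())
            c = int((~flagged & in_state).sum())
            d = int((~flagged & ~in_state).sum())
            odds = (a * d) / (b * c) if b * c > 0 else np.inf
            _, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
            recs.append({"state": state, "direction": direction,
                         "dmr_in_state": a, "dmr_out": b,
                         "nondmr_in_state": c, "nondmr_out": d,
                         "odds_ratio": float(odds), "p": float(p),
                         "dmr_frequency": 100.0 * a / n_total})
        if recs:
            q = multipletests([r["p"] for r in recs], method="fdr_bh")[1]
            for r, qv in zip(recs, q):
                r["q"] = float(qv)
                r["significant"] = bool(qv < q_threshold and r["odds_ratio"] > 1)
            rows.extend(recs)
    return pd.DataFrame(rows, columns=[
        "state", "direction", "dmr_in_state", "dmr_out", "nondmr_in_state",
        "nondmr_out", "odds_ratio", "p", "q", "significant", "dmr_frequency"])


def dmr_frequency(dmrs: pd.DataFrame, state: str | None = None,
                  annotation: pd.DataFrame | None = None) -> float:
    """Percent of common tiles that are DMRs, optionally within one state.

    DMR frequency = DMR tiles (optionally restricted to a chromatin state) /
    all common identified tiles between the two cell types x 100%.
    """
    n_total = len(dmrs)
    if n_total == 0:
        raise ValueError("no common tiles: DMR frequency undefined")
    flagged = dmrs["is_dmr"]
    if state is not None:
        if annotation is None:
            raise ValueError("state restriction requires an annotation")
        labels = annotate_states(dmrs, annotation)
        flagged = flagged & (labels == state)
    return 100.0 * float(flagged.sum()) / n_total
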