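"""Somatic SNV filter cascade, dropout-adjusted mutation matrix and clustering.

Candidate somatic variants from low-input, whole-genome-amplified samples are
noisy: they contain residual germline polymorphisms, library-preparation
artifacts that cluster within a few base pairs, single-caller calls, and
spurious low-support calls.  The cascade applies six rules in a fixed order:

1. remove known population polymorphisms (panel-listed, or population allele
   frequency > 1%);
2. remove variants with another candidate within 10 bp on the same contig
   (both members of a close pair are dropped);
3. keep only variants reported by at least two callers;
4. require depth > 10 in both the sample and the matched control;
5. require >= 2 alternative reads, allele fraction > 5%, and zero alternative
   reads in the control;
6. optionally require recurrence in >= 2 samples of the same patient.

Surviving calls are converted to a sites-by-samples 0/1 matrix M.  Because
multiple-displacement amplification drops alleles at poorly covered sites,
entries with coverage <= 5x are softened using the other samples of the same
pathology group: M[i, j] = 0.9 when carriers outnumber wild-type among them,
0.1 when wild-type outnumber carriers (ties keep the observed value).
Samples are then clustered by Euclidean distance with average linkage.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from ._hierarchy import Dendrogram, hierarchical_cluster
from .synthetic import SPECTRUM_CLASSES

logger = logging.getLogger(__name__)

SITE_COLS = ["chrom", "pos"]

_PYRIMIDINE = {"C", "T"}
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _validate_calls(calls: pd.DataFrame) -> None:
    required = {"chrom", "pos", "ref", "alt", "sample_id", "callers",
                "depth", "alt_reads"}
    missing = required - set(calls.columns)
    if missing:
        raise ValueError(f"variant table missing columns: {sorted(missing)}")


# ---------------------------------------------------------------------------
# the six filters
# ---------------------------------------------------------------------------

def filter_population(calls: pd.DataFrame, panel: pd.DataFrame,
                      max_af: float = 0.01) -> pd.DataFrame:
    """Rule 1: drop panel-known sites and sites with population AF > ``max_af``.

    ``panel`` columns: chrom, pos, population_af, known.  Sites absent from
    the panel are kept; a site at exactly the threshold is kept (the rule is
    strictly "larger than").
    """
    _validate_calls(calls)
    if panel is None or panel.empty:
        return calls.copy()
    bad = panel[(panel.get("known", False)) | (panel["population_af"] > max_af)]
    bad_sites = set(zip(bad["chrom"], bad["pos"]))
    keep = [
        (c, p) not in bad_sites for c, p in zip(calls["chrom"], calls["pos"])
    ]
    return calls.loc[keep].reset_index(drop=True)


def filter_proximal(calls: pd.DataFrame, window_bp: int = 10) -> pd.DataFrame:
    """Rule 2: drop every site with another candidate within ``window_bp``.

    Operates on the union of candidate sites across samples, since
    library-preparation artifacts recur across amplified samples.  Both
    members of a close pair are removed; distance is |pos1 - pos2| on the
    same contig, and exactly ``window_bp`` apart still counts as close.
    """
    _validate_calls(calls)
    sites = calls[SITE_COLS].drop_duplicates().sort_values(SITE_COLS)
    bad: set[tuple[str, int]] = set()
    for chrom, grp in sites.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        close = np.diff(pos) <= window_bp
        for k in np.nonzero(close)[0]:
            bad.add((chrom, int(pos[k])))
            bad.add((chrom, int(pos[k + 1])))
    keep = [
        (c, p) not in bad for c, p in zip(calls["chrom"], calls["pos"])
    ]
    return calls.loc[keep].reset_index(drop=True)


def filter_concordance(calls: pd.DataFrame) -> pd.DataFrame:
    """Rule 3: keep calls identified by >= 2 algorithms.

    ``callers`` is a ';'-separated label set; an empty set is an input error.
    """
    _validate_calls(calls)
    n_callers = calls["callers"].astype(str).str.split(";").map(
        lambda xs: len([x for x in xs if x]))
    if (n_callers == 0).any():
        raise ValueError("call with empty caller set")
    return calls.loc[n_callers >= 2].reset_index(drop=True)


def filter_support(calls: pd.DataFrame, control_calls: pd.DataFrame,
                   control_coverage: pd.DataFrame,
                   min_depth: int = 10, min_alt: int = 2,
                   min_af: float = 0.05) -> pd.DataFrame:
    """Rules 4-5: depth and allele-support requirements against the control.

    Keep a call iff sample depth > ``min_depth``, control depth >
    ``min_depth``, alternative reads >= ``min_alt``, allele fraction >
    ``min_af``, and the control shows zero alternative reads at the site.
    Sites with no control coverage record are removed and logged.
    """
    _validate_calls(calls)
    ctrl_depth = {
        (c, p): d for c, p, d in zip(control_coverage["chrom"],
                                     control_coverage["pos"],
                                     control_coverage["depth"])
    }
    ctrl_alt: dict[tuple[str, int], int] = {}
    if control_calls is not None and not control_calls.empty:
        for r in control_calls.itertuples():
            key = (r.chrom, r.pos)
            ctrl_alt[key] = max(ctrl_alt.get(key, 0), int(r.alt_reads))

    keep = []
    for r in calls.itertuples():
        key = (r.chrom, r.pos)
        if key not in ctrl_depth:
            logger.warning("no control coverage at %s:%d; site removed", *key)
            keep.append(False)
            continue
        af = r.alt_reads / r.depth if r.depth else 0.0
        keep.append(
            r.depth > min_depth
            and ctrl_depth[key] > min_depth
            and r.alt_reads >= min_alt
            and af > min_af
            and ctrl_alt.get(key, 0) == 0
        )
    return calls.loc[keep].reset_index(drop=True)


def filter_recurrence(calls: pd.DataFrame, sample_patients: dict[str, str],
                      enabled_patients: set[str] | None,
                      min_samples: int = 2) -> pd.DataFrame:
    """Rule 6: per enabled patient, keep sites present in >= ``min_samples``
    of that patient's samples.  Patients not in ``enabled_patients`` pass
    through unchanged (the rule is unsuitable for patients with few samples).
    """
    _validate_calls(calls)
    if not enabled_patients:
        return calls.copy()
    patient = calls["sample_id"].map(sample_patients)
    if patient.isna().any():
        missing = sorted(calls.loc[patient.isna(), "sample_id"].unique())
        raise ValueError(f"samples without a patient label: {missing}")
    n_samples = calls.assign(_pat=patient).groupby(
        ["_pat", "chrom", "pos"])["sample_id"].transform("nunique")
    keep = (~patient.isin(enabled_patients)) | (n_samples >= min_samples)
    return calls.loc[keep.to_numpy()].reset_index(drop=True)


def run_filter_cascade(
    calls: pd.DataFrame, panel: pd.DataFrame, control_calls: pd.DataFrame,
    control_coverage: pd.DataFrame, sample_patients: dict[str, str],
    recurrence_patients: set[str] | None = None, *,
    max_pop_af: float = 0.01, window_bp: int = 10, min_depth: int = 10,
    min_alt: int = 2, min_af: float = 0.05, min_recurrence: int = 2,
) -> pd.DataFrame:
    """Apply rules 1-6 in order.  Idempotent on its own output."""
    out = filter_population(calls, panel, max_pop_af)
    out = filter_proximal(out, window_bp)
    out = filter_concordance(out)
    out = filter_support(out, control_calls, control_coverage,
                         min_depth, min_alt, min_af)
    out = filter_recurrence(out, sample_patients, recurrence_patients,
                            min_recurrence)
    return out


# ---------------------------------------------------------------------------
# mutation matrix
# ---------------------------------------------------------------------------

def build_mutation_matrix(
    calls: pd.DataFrame, samples: list[str], coverage: pd.DataFrame,
    groups: dict[str, str], low_cov: int = 5,
) -> pd.DataFrame:
    """Sites-by-samples matrix M with the allele-dropout adjustment.

    M[i, j] = 1 if the filtered call set contains (site i, sample j), else 0.
    Where sample j covers site i at <= ``low_cov`` reads (missing coverage
    counts as 0x), the entry is replaced by 0.9 if, among the *other* samples
    of j's pathology group, carriers outnumber wild-type, or by 0.1 if
    wild-type outnumber carriers; ties keep the observed value.  Entries are
    therefore always in {0, 0.1, 0.9, 1}.

    Returns a DataFrame indexed by "chrom:pos" site ids with sample columns;
    the group labels are attached as ``result.attrs["groups"]``.
    """
    for s in samples:
        if s not in groups:
            raise ValueError(f"sample {s!r} has no group label")
    sites = sorted(
        {(c, p) for c, p in zip(calls["chrom"], calls["pos"])})
    carrier = {
        (c, p, s) for c, p, s in zip(calls["chrom"], calls["pos"],
                                     calls["sample_id"]) if s in set(samples)
    }
    depth_of = {
        (c, p, s): d for c, p, s, d in zip(
            coverage["chrom"], coverage["pos"], coverage["sample_id"],
            coverage["depth"])
    }

    m = np.zeros((len(sites), len(samples)))
    for i, (c, p) in enumerate(sites):
        observed = {s: float((c, p, s) in carrier) for s in samples}
        for j, s in enumerate(samples):
            val = observed[s]
            if depth_of.get((c, p, s), 0) <= low_cov:
                others = [t for t in samples
                          if t != s and groups[t] == groups[s]]
                n_carrier = sum(observed[t] == 1.0 for t in others)
                n_wild = len(others) - n_carrier
                if n_carrier > n_wild:
                    val = 0.9
                elif n_wild > n_carrier:
                    val = 0.1
            m[i, j] = val

    out = pd.DataFrame(
        m, index=[f"{c}:{p}" for c, p in sites], columns=samples)
    out.attrs["groups"] = dict(groups)
    return out


def cluster_samples(matrix: pd.DataFrame) -> Dendrogram:
    """Average-linkage tree over samples from Euclidean distances on M."""
    return hierarchical_cluster(matrix.T, metric="euclidean")


# ---------------------------------------------------------------------------
# spectrum and overlap statistics
# ---------------------------------------------------------------------------

def mutation_spectrum(calls: pd.DataFrame) -> pd.Series:
    """Pyrimidine-collapsed six-class substitution proportions.

    Purine-reference substitutions are complemented onto the pyrimidine
    strand (e.g. G>A counts as C>T).  Proportions sum to 1 for non-empty
    input; an empty table returns all zeros with ``attrs["empty"] = True``.
    """
    counts = pd.Series(0.0, index=SPECTRUM_CLASSES)
    unique_sites = calls.drop_duplicates(subset=SITE_COLS) if len(calls) else calls
    for r in unique_sites.itertuples():
        ref, alt = str(r.ref).upper(), str(r.alt).upper()
        if ref not in _COMPLEMENT or alt not in _COMPLEMENT:
            raise ValueError(f"non-ACGT base in substitution {ref}>{alt}")
        if ref not in _PYRIMIDINE:
            ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
        counts[f"{ref}>{alt}"] += 1
    total = counts.sum()
    if total == 0:
        counts.attrs["empty"] = True
        return counts
    out = counts / total
    out.attrs["empty"] = False
    return out


def overlap_test(set_a: set, set_b: set, universe_size: int
                 ) -> tuple[int, float]:
    """Upper-tail hypergeometric test for the overlap of two SNV sets.

    With a universe of ``universe_size`` sites, |A| marked and |B| drawn,
    returns (|A ∩ B|, P(X >= |A ∩ B|)) under the hypergeometric null.
    """
    k = len(set_a & set_b)
    n_a, n_b = len(set_a), len(set_b)
    if n_a > universe_size or n_b > universe_size:
        raise ValueError("set larger than the universe")
    if k > min(n_a, n_b):
        raise ValueError("overlap exceeds the smaller set")
    p = float(hypergeom.sf(k - 1, universe_size, n_a, n_b))
    return k, min(p, 1.0)


def overlap_test_counts(n_a: int, n_b: int, overlap: int, universe_size: int
                        ) -> float:
    """As :func:`overlap_test` but from printed set sizes."""
    if n_a > universe_size or n_b > universe_size:
        raise ValueError("set larger than the universe")
    if overlap > min(n_a, n_b):
        raise ValueError("overlap exceeds the smaller set")
    return float(min(hypergeom.sf(overlap - 1, universe_size, n_a, n_b), 1.0))
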