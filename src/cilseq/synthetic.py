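"""Synthetic clonal multiomics generator.

Emulates the data structure of a mixed hepatocellular--cholangiocarcinoma
specimen profiled by microdissection of five cell populations (LCSL, HCC,
CCA, PDR, PL) plus a bulk immune control: a clone tree in which HCC and CCA
share a large truncal SNV set, LCSL carries a subset of that truncal set plus
private heterogeneous SNVs, and PL carries independent background SNVs;
C>T-dominated substitution spectra; coverage-dependent allele dropout of the
kind multiple-displacement amplification produces; chromatin-state-dependent
methylation shifts (demethylation of heterochromatin/quiescent states,
hypermethylation of bivalent/Polycomb states); amplified segments concentrated
in the HCC/CCA lineage; and cell-type-pure spatial expression spots.

Every observation traces to a ground-truth record so the downstream filtering,
clustering and testing stages can be verified without patient data.  A fixed
seed makes all outputs bit-for-bit reproducible; changing the seed changes
observations but never truth-level set sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

CHROMATIN_STATES = [
    "1_TssA", "2_TssAFlnk", "3_TxFlnk", "4_Tx", "5_TxWk",
    "6_EnhG", "7_Enh", "8_ZNF/Rpts", "9_Het", "10_TssBiv",
    "11_BivFlnk", "12_EnhBiv", "13_ReprPC", "14_ReprPCWk", "15_Quies",
]

CELL_TYPES = ["LCSL", "HCC", "CCA", "PDR", "PL"]
TUMOR_TYPES = {"LCSL", "HCC", "CCA"}

#: pyrimidine-reference substitution classes
SPECTRUM_CLASSES = ["C>A", "C>G", "C>T", "T>A", "T>C", "T>G"]

_DEFAULT_BRANCH_SNVS = {
    "tumor_truncal": 17,   # carried by LCSL, HCC and CCA
    "hcc_cca_extra": 35,   # carried by HCC and CCA only
    "hcc_private": 21,
    "cca_private": 18,
    "lcsl_private": 11,
    "pl_background": 43,
}

# resting methylation of each chromatin state in normal liver-like cells
_DEFAULT_BASELINE = {
    "1_TssA": 0.10, "2_TssAFlnk": 0.20, "3_TxFlnk": 0.60, "4_Tx": 0.80,
    "5_TxWk": 0.80, "6_EnhG": 0.60, "7_Enh": 0.55, "8_ZNF/Rpts": 0.80,
    "9_Het": 0.85, "10_TssBiv": 0.15, "11_BivFlnk": 0.15, "12_EnhBiv": 0.20,
    "13_ReprPC": 0.25, "14_ReprPCWk": 0.50, "15_Quies": 0.85,
}

# tumor lineage: demethylation of constitutive heterochromatin / quiescent
# chromatin, hypermethylation of promoter-proximal and bivalent states
_DEFAULT_TUMOR_SHIFT = {
    "9_Het": -0.40, "15_Quies": -0.40,
    "1_TssA": +0.30, "10_TssBiv": +0.40, "11_BivFlnk": +0.40,
    "12_EnhBiv": +0.40,
}

# stem-like cells: hypermethylation confined to bivalent/Polycomb states
_DEFAULT_LCSL_SHIFT = {"10_TssBiv": +0.30, "13_ReprPC": +0.30}

# default amplicons are high-level (CN 6, log2 ratio ~1.58) so that calls at
# the log2 >= 1 threshold are robust to ratio noise; CN 4 sits exactly on the
# calling boundary and is exercised explicitly in tests instead
_DEFAULT_AMP_SEGMENTS = {
    # a chr8q-like amplicon acquired on the HCC/CCA shared branch
    "hcc_cca_extra": [("chr8q", 0, 40_000, 6)],
    # a smaller private gain in HCC
    "hcc_private": [("chr5a", 0, 8_000, 6)],
}


@dataclass
class SimConfig:
    """All knobs of the generator.  Defaults are the study conditions."""

    seed: int = 0
    noise: str = "on"                      # "on" | "off" (deterministic limit)

    # --- clone tree / SNVs -------------------------------------------------
    branch_snv_counts: dict[str, int] = field(
        default_factory=lambda: dict(_DEFAULT_BRANCH_SNVS))
    samples_per_type: dict[str, int] = field(
        default_factory=lambda: {"LCSL": 4, "HCC": 4, "CCA": 4, "PDR": 2, "PL": 2})
    heterogeneous_branches: tuple[str, ...] = ("lcsl_private",)
    private_carriers: int = 2              # samples carrying each heterogeneous SNV
    patient: str = "P2"

    depth_mean: float = 30.0
    depth_dispersion: float = 8.0          # NB size parameter
    dropout_rate_low_input: float = 0.2    # per-allele, at mean depth
    seq_error: float = 1e-3
    ct_bias: float = 0.7                   # fraction of SNVs that are C>T class
    single_caller_rate: float = 0.05       # calls reported by one algorithm only
    n_germline_artifacts: int = 5          # population-polymorphic contaminants
    n_proximal_artifact_pairs: int = 2     # library-prep close-pair artifacts

    # --- methylome ---------------------------------------------------------
    n_cpg: int = 20_000
    cpg_spacing: int = 30                  # bp between simulated CpGs
    state_interval_bp: int = 3_000         # chromatin-state run length
    meth_samples_per_type: int = 2
    meth_baseline: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_BASELINE))
    tumor_meth_shift: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_TUMOR_SHIFT))
    lcsl_meth_shift: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_LCSL_SHIFT))
    coverage_meth_mean: float = 30.0
    meth_precision: float = 60.0           # beta-binomial concentration
    conversion_rate: float = 0.98
    n_noncpg: int = 50_000

    # --- CNA ---------------------------------------------------------------
    branch_amp_segments: dict[str, list[tuple[str, int, int, int]]] = field(
        default_factory=lambda: {k: list(v) for k, v in _DEFAULT_AMP_SEGMENTS.items()})
    n_genes: int = 200
    gene_length: int = 2_000
    cna_noise_sd: float = 0.1
    low_coverage_samples: tuple[str, ...] = ()
    n_lowfreq_decoys: int = 1              # amplified genes rare in the cohort

    # --- spatial -----------------------------------------------------------
    n_spots_per_type: int = 100
    n_spot_genes: int = 100
    n_panel_genes: int = 11
    spot_libsize_sd: float = 0.2

    def __post_init__(self) -> None:
        for name, p in [
            ("dropout_rate_low_input", self.dropout_rate_low_input),
            ("seq_error", self.seq_error), ("ct_bias", self.ct_bias),
            ("single_caller_rate", self.single_caller_rate),
            ("conversion_rate", self.conversion_rate),
        ]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.noise not in ("on", "off"):
            raise ValueError("noise must be 'on' or 'off'")
        for branch, n in self.branch_snv_counts.items():
            if branch not in _DEFAULT_BRANCH_SNVS:
                raise ValueError(f"unknown branch {branch!r}")
            if n < 0:
                raise ValueError(
                    f"branch_snv_counts[{branch!r}] must be >= 0, got {n}")
        for state in list(self.meth_baseline) + list(self.tumor_meth_shift) \
                + list(self.lcsl_meth_shift):
            if state not in CHROMATIN_STATES:
                raise ValueError(f"unknown chromatin state {state!r}")

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)


@dataclass
class CloneTree:
    """Clonal phylogeny with per-branch SNV and amplification payloads.

    SNV sets are nested along every root-to-leaf path: a site assigned to a
    branch is carried by every clone below that branch.
    """

    edges: dict[str, str]                       # child -> parent
    branch_sites: dict[str, list[str]]          # branch (child) -> site ids
    branch_amp_segments: dict[str, list[tuple[str, int, int, int]]]
    genotypes: dict[str, set[str]]              # leaf clone -> carried sites
    site_table: pd.DataFrame                    # site, chrom, pos, ref, alt, branch

    @property
    def clones(self) -> list[str]:
        return sorted(self.genotypes)


@dataclass
class TruthTables:
    """Ground truth written alongside every simulated dataset."""

    snv_truth: pd.DataFrame          # site, chrom, pos, ref, alt, branch, clones
    snv_sample_truth: pd.DataFrame   # site, sample_id (carrier samples)
    amp_truth: pd.DataFrame          # gene, chrom, start, end, copy_number, clones
    dmr_truth: pd.DataFrame          # chrom, start, end, state, pair, direction
    spot_truth: pd.DataFrame         # spot_id, cell_type


# ---------------------------------------------------------------------------
# clone tree
# ---------------------------------------------------------------------------

_TREE_EDGES = {
    "PL": "root", "PDR": "root", "tumor_truncal": "root",
    "LCSL": "tumor_truncal", "hcc_cca_shared": "tumor_truncal",
    "HCC": "hcc_cca_shared", "CCA": "hcc_cca_shared",
}

# which tree edge carries which configured branch count
_BRANCH_OF_EDGE = {
    "PL": "pl_background", "PDR": None, "tumor_truncal": "tumor_truncal",
    "LCSL": "lcsl_private", "hcc_cca_shared": "hcc_cca_extra",
    "HCC": "hcc_private", "CCA": "cca_private",
}

_SNV_CONTIGS = ["chr1", "chr2", "chr3", "chr4", "chr5"]

_PURINE_COMPLEMENT = {"G": "C", "A": "T", "C": "C", "T": "T"}
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _draw_substitutions(n: int, ct_bias: float, rng: np.random.Generator):
    """ref/alt pairs whose pyrimidine-collapsed class is C>T with mass ct_bias."""
    other = [c for c in SPECTRUM_CLASSES if c != "C>T"]
    probs = [ct_bias if c == "C>T" else (1 - ct_bias) / 5 for c in SPECTRUM_CLASSES]
    classes = rng.choice(SPECTRUM_CLASSES, size=n, p=probs)
    refs, alts = [], []
    flip = rng.random(n) < 0.5   # report on the purine strand half the time
    for cls, fl in zip(classes, flip):
        ref, alt = cls.split(">")
        if fl:
            ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
        refs.append(ref)
        alts.append(alt)
    return refs, alts


def sample_sheet(config: SimConfig) -> pd.DataFrame:
    """Sample metadata: one row per microdissected sample plus the control."""
    rows = []
    for ct in CELL_TYPES:
        for k in range(config.samples_per_type.get(ct, 0)):
            rows.append({
                "sample_id": f"{ct}_{k + 1}",
                "patient": config.patient,
                "cell_type": ct,
                "compartment": "tumor" if ct in TUMOR_TYPES else "paratumor",
                "preservation": "frozen",
            })
    rows.append({
        "sample_id": "CTRL_1", "patient": config.patient, "cell_type": "CONTROL",
        "compartment": "paratumor", "preservation": "frozen",
    })
    return pd.DataFrame(rows)


def simulate_clone_tree(config: SimConfig) -> tuple[CloneTree, TruthTables]:
    """Build the clonal phylogeny and its ground-truth SNV assignment.

    Truth-level set sizes equal the configured branch counts exactly.  With
    the default configuration the leaf genotype sizes are |HCC| = 73,
    |CCA| = 70, |HCC ∩ CCA| = 52, |LCSL| = 28, |LCSL ∩ (HCC ∪ CCA)| = 17 and
    |PL| = 43.
    """
    counts = dict(_DEFAULT_BRANCH_SNVS)
    counts.update(config.branch_snv_counts)
    bad = [b for b, n in counts.items() if n < 0]
    if bad:
        raise ValueError(f"negative SNV counts on branches: {', '.join(sorted(bad))}")

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))

    branch_sites: dict[str, list[str]] = {}
    records = []
    idx = 0
    for edge in ["tumor_truncal", "hcc_cca_shared", "HCC", "CCA", "LCSL", "PL", "PDR"]:
        branch = _BRANCH_OF_EDGE[edge]
        n = counts.get(branch, 0) if branch else 0
        sites = []
        for _ in range(n):
            contig = _SNV_CONTIGS[idx % len(_SNV_CONTIGS)]
            pos = 10_000 + (idx // len(_SNV_CONTIGS)) * 1_000  # >> 10 bp apart
            sites.append(f"S{idx:04d}")
            records.append({"site": f"S{idx:04d}", "chrom": contig, "pos": pos,
                            "branch": branch})
            idx += 1
        branch_sites[edge] = sites

    site_table = pd.DataFrame(
        records, columns=["site", "chrom", "pos", "branch"])
    refs, alts = _draw_substitutions(len(site_table), config.ct_bias, rng)
    site_table["ref"] = refs
    site_table["alt"] = alts
    site_table = site_table[["site", "chrom", "pos", "ref", "alt", "branch"]]

    # genotype of a leaf = union of branch payloads on its root path
    genotypes: dict[str, set[str]] = {}
    for leaf in CELL_TYPES:
        carried: set[str] = set()
        node = leaf
        while node != "root":
            carried |= set(branch_sites.get(node, []))
            node = _TREE_EDGES[node]
        genotypes[leaf] = carried

    tree = CloneTree(
        edges=dict(_TREE_EDGES),
        branch_sites=branch_sites,
        branch_amp_segments={k: list(v) for k, v in config.branch_amp_segments.items()},
        genotypes=genotypes,
        site_table=site_table,
    )

    clones_of_site = {
        s: sorted(c for c in CELL_TYPES if s in genotypes[c])
        for s in site_table["site"]
    }
    snv_truth = site_table.copy()
    snv_truth["clones"] = [";".join(clones_of_site[s]) for s in snv_truth["site"]]

    snv_sample_truth = _allocate_sample_truth(tree, config)
    truth = TruthTables(
        snv_truth=snv_truth,
        snv_sample_truth=snv_sample_truth,
        amp_truth=_amp_truth(tree, config),
        dmr_truth=_dmr_truth(config),
        spot_truth=_spot_truth(config),
    )
    return tree, truth


def _allocate_sample_truth(tree: CloneTree, config: SimConfig) -> pd.DataFrame:
    """Site -> carrier samples.  Clone-wide branches go to every sample of the
    carrier clones; heterogeneous branches (LCSL privates by default) rotate
    over ``private_carriers`` consecutive samples of the clone so that samples
    differ in their private sites while each site is still seen in >= 2
    samples."""
    sheet = sample_sheet(config)
    by_type = {
        ct: sorted(sheet.loc[sheet["cell_type"] == ct, "sample_id"])
        for ct in CELL_TYPES
    }
    rows = []
    for edge, sites in tree.branch_sites.items():
        branch = _BRANCH_OF_EDGE[edge]
        if not sites:
            continue
        carriers = sorted(c for c in CELL_TYPES if set(sites) <= tree.genotypes[c])
        hetero = branch in config.heterogeneous_branches
        for k, site in enumerate(sites):
            for clone in carriers:
                samples = by_type[clone]
                if hetero and len(samples) > config.private_carriers:
                    take = [samples[(k + j) % len(samples)]
                            for j in range(config.private_carriers)]
                else:
                    take = samples
                rows.extend({"site": site, "sample_id": s} for s in take)
    return pd.DataFrame(rows, columns=["site", "sample_id"]).sort_values(
        ["site", "sample_id"], ignore_index=True)


# ---------------------------------------------------------------------------
# variant observations
# ---------------------------------------------------------------------------

def _dropout_prob(depth: np.ndarray, mean: float, rate: float) -> np.ndarray:
    """Per-allele dropout probability, rising as depth falls.

    Complement form p = 1 - (1 - rate)^w with weight w = 2*mean/(mean+depth):
    equals ``rate`` at the mean depth, grows toward ``~2*rate`` as depth
    approaches zero (mirroring multiple-displacement amplification, where
    low-input sites lose alleles more often), decays at high depth, and is
    exactly 1 whenever ``rate`` is 1."""
    w = 2.0 * mean / (mean + np.maximum(depth, 1.0))
    return 1.0 - np.power(1.0 - np.clip(rate, 0.0, 1.0), w)


def _nb_depth(n: int, mean: float, disp: float, rng: np.random.Generator):
    p = disp / (disp + mean)
    return rng.negative_binomial(disp, p, size=n)


def simulate_variant_observations(
    tree: CloneTree, config: SimConfig, truth: TruthTables | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Observe the truth genotypes through a noisy low-input sequencing model.

    Returns ``(calls, coverage, panel)``:

    * ``calls`` — candidate somatic variant table (chrom, pos, ref, alt,
      sample_id, callers, depth, alt_reads, af), one row per sample-site with
      at least one alternative read, including artifact sites that the filter
      cascade is meant to remove and control-sample rows from sequencing
      error.
    * ``coverage`` — per-site per-sample depth (control included).
    * ``panel`` — population allele-frequency panel listing the germline
      artifact sites as known polymorphisms.

    Carrier samples are heterozygous (alt fraction 1/2) unless one allele
    dropped out; dropout probability rises as depth falls.  The immune
    control carries no somatic alternative reads beyond sequencing error.
    """
    if truth is None:
        _, truth = simulate_clone_tree(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 23]))
    sheet = sample_sheet(config)
    noise = config.noise == "on"

    carrier = {
        (r.site, r.sample_id) for r in truth.snv_sample_truth.itertuples()
    }

    sites = truth.snv_truth.copy()
    artifacts = _artifact_sites(config, rng)
    all_sites = pd.concat([sites, artifacts], ignore_index=True)

    call_rows, cov_rows = [], []
    for sample in sheet.itertuples():
        sid = sample.sample_id
        n = len(all_sites)
        if noise:
            depth = _nb_depth(n, config.depth_mean, config.depth_dispersion, rng)
        else:
            depth = np.full(n, int(config.depth_mean))
        for row, dp in zip(all_sites.itertuples(), depth):
            is_carrier = (
                (row.site, sid) in carrier
                or (row.branch == "germline_artifact" and sample.cell_type != "CONTROL")
                or (row.branch == "proximal_artifact"
                    and sample.cell_type != "CONTROL")
            )
            dp = int(dp)
            cov_rows.append((row.chrom, row.pos, sid, dp))
            if dp == 0:
                continue
            if not noise:
                alt = dp // 2 if is_carrier else 0
                callers = "muTect;varScan"
            else:
                if is_carrier:
                    p_alt = 0.5
                    if rng.random() < _dropout_prob(
                            np.array([dp]), config.depth_mean,
                            config.dropout_rate_low_input)[0]:
                        # one allele lost: alt or ref with equal chance
                        p_alt = (config.seq_error if rng.random() < 0.5
                                 else 1.0 - config.seq_error)
                    alt = int(rng.binomial(dp, p_alt))
                else:
                    alt = int(rng.binomial(dp, config.seq_error))
                if rng.random() < config.single_caller_rate:
                    callers = "muTect" if rng.random() < 0.5 else "varScan"
                else:
                    callers = "muTect;varScan"
            if alt >= 1:
                call_rows.append((row.chrom, row.pos, row.ref, row.alt, sid,
                                  callers, dp, alt, alt / dp))

    calls = pd.DataFrame(call_rows, columns=[
        "chrom", "pos", "ref", "alt", "sample_id", "callers",
        "depth", "alt_reads", "af"])
    coverage = pd.DataFrame(cov_rows, columns=["chrom", "pos", "sample_id", "depth"])

    panel = artifacts.loc[artifacts["branch"] == "germline_artifact",
                          ["chrom", "pos", "ref", "alt"]].copy()
    panel["population_af"] = 0.05
    panel["known"] = True
    return calls, coverage, panel.reset_index(drop=True)


def _artifact_sites(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Non-somatic contaminant sites the filter cascade must remove."""
    rows = []
    idx = 0
    for _ in range(config.n_germline_artifacts):
        rows.append({"site": f"GERM{idx:03d}", "chrom": "chr6",
                     "pos": 5_000 + idx * 1_000, "branch": "germline_artifact"})
        idx += 1
    for k in range(config.n_proximal_artifact_pairs):
        base = 100_000 + k * 1_000
        for off in (0, 7):   # 7 bp apart: inside the 10 bp exclusion window
            rows.append({"site": f"PROX{idx:03d}", "chrom": "chr6",
                         "pos": base + off, "branch": "proximal_artifact"})
            idx += 1
    if not rows:
        return pd.DataFrame(
            columns=["site", "chrom", "pos", "ref", "alt", "branch"])
    df = pd.DataFrame(rows)
    refs, alts = _draw_substitutions(len(df), config.ct_bias, rng)
    df["ref"] = refs
    df["alt"] = alts
    return df[["site", "chrom", "pos", "ref", "alt", "branch"]]


# ---------------------------------------------------------------------------
# methylomes
# ---------------------------------------------------------------------------

# genomic footprint of each state, in runs of state_interval_bp per cycle:
# quiescent chromatin dominates the genome, heterochromatin and weak
# transcription are broad, regulatory states are narrow — so planting
# demethylation in Het/Quies and hypermethylation in the narrow bivalent
# states lowers the tumor global methylation level, as broad tumor
# demethylation requires
_STATE_WEIGHTS = {
    "4_Tx": 2, "5_TxWk": 3, "9_Het": 3, "14_ReprPCWk": 2, "15_Quies": 8,
}


def state_track(config: SimConfig) -> pd.DataFrame:
    """Chromatin-state annotation BED (0-based half-open) for the toy contig.

    States cycle 1..15 with footprint-weighted run lengths (multiples of
    ``state_interval_bp``) so every 300-bp tile falls entirely inside one
    state and the broad repressed states cover most of the genome."""
    genome_len = config.n_cpg * config.cpg_spacing
    rows = []
    start = 0
    k = 0
    while start < genome_len:
        state = CHROMATIN_STATES[k % 15]
        run = config.state_interval_bp * _STATE_WEIGHTS.get(state, 1)
        end = min(start + run, genome_len)
        rows.append({"chrom": "chrM1", "start": start, "end": end,
                     "state": state})
        start = end
        k += 1
    return pd.DataFrame(rows)


def _clone_state_level(config: SimConfig, clone: str) -> dict[str, float]:
    shift: dict[str, float]
    if clone in ("HCC", "CCA"):
        shift = config.tumor_meth_shift
    elif clone == "LCSL":
        shift = config.lcsl_meth_shift
    else:
        shift = {}
    return {
        s: float(np.clip(config.meth_baseline[s] + shift.get(s, 0.0), 0.01, 0.99))
        for s in CHROMATIN_STATES
    }


def meth_sample_sheet(config: SimConfig) -> pd.DataFrame:
    rows = []
    for ct in CELL_TYPES:
        for k in range(config.meth_samples_per_type):
            rows.append({"sample_id": f"{ct}_M{k + 1}", "patient": config.patient,
                         "cell_type": ct,
                         "compartment": "tumor" if ct in TUMOR_TYPES else "paratumor",
                         "preservation": "frozen"})
    return pd.DataFrame(rows)


def simulate_methylomes(config: SimConfig) -> dict[str, pd.DataFrame]:
    """Per-sample CX-report-like methylation call tables.

    CpG dyads are emitted as two strand records (+ at pos, − at pos+1) whose
    counts sum to the site's coverage.  Methylated counts follow a
    beta-binomial around the clone/chromatin-state mean; non-CpG cytosines
    fail bisulfite conversion at rate ``1 - conversion_rate``.
    """
    for s in config.tumor_meth_shift:
        if s not in CHROMATIN_STATES:
            raise ValueError(f"state label outside the 15-state alphabet: {s!r}")
    track = state_track(config)
    positions = np.arange(config.n_cpg) * config.cpg_spacing + 2
    state_of = np.repeat(
        track["state"].to_numpy(),
        ((track["end"] - track["start"]) // config.cpg_spacing).to_numpy(),
    )[: config.n_cpg]

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 37]))
    noise = config.noise == "on"
    out: dict[str, pd.DataFrame] = {}
    for sample in meth_sample_sheet(config).itertuples():
        level_of_state = _clone_state_level(config, sample.cell_type)
        mean = np.array([level_of_state[s] for s in state_of])
        n = config.n_cpg
        if noise:
            cov = _nb_depth(n, config.coverage_meth_mean,
                            config.depth_dispersion, rng)
            prec = config.meth_precision
            p = rng.beta(mean * prec, (1.0 - mean) * prec)
            meth = rng.binomial(cov, p)
            cov_plus = rng.binomial(cov, 0.5)
            meth_plus = rng.hypergeometric(meth, cov - meth, cov_plus)
        else:
            cov = np.full(n, int(config.coverage_meth_mean))
            meth = np.rint(mean * cov).astype(int)
            cov_plus = cov // 2
            # deterministic proportional split of methylated reads by strand
            meth_plus = np.clip((meth * cov_plus) // np.maximum(cov, 1), 0, meth)
        cov_minus = cov - cov_plus
        meth_minus = meth - meth_plus

        cpg = pd.DataFrame({
            "chrom": "chrM1",
            "pos": np.concatenate([positions, positions + 1]),
            "strand": ["+"] * n + ["-"] * n,
            "context": "CpG",
            "meth_count": np.concatenate([meth_plus, meth_minus]),
            "unmeth_count": np.concatenate(
                [cov_plus - meth_plus, cov_minus - meth_minus]),
        })

        m = config.n_noncpg
        nc_pos = np.arange(m) * 7 + 3   # interleaved with CpGs; exact pos irrelevant
        if noise:
            nc_cov = np.maximum(
                _nb_depth(m, config.coverage_meth_mean, config.depth_dispersion, rng),
                1)
            nc_meth = rng.binomial(nc_cov, 1.0 - config.conversion_rate)
        else:
            nc_cov = np.full(m, max(int(config.coverage_meth_mean), 1))
            nc_meth = np.rint((1.0 - config.conversion_rate) * nc_cov).astype(int)
        noncpg = pd.DataFrame({
            "chrom": "chrM2", "pos": nc_pos, "strand": "+", "context": "CHH",
            "meth_count": nc_meth, "unmeth_count": nc_cov - nc_meth,
        })
        out[sample.sample_id] = pd.concat([cpg, noncpg], ignore_index=True)
    return out


def _dmr_truth(config: SimConfig) -> pd.DataFrame:
    """Tiles planted as differential, per compared pair of compartments."""
    track = state_track(config)
    tile_w = 300
    rows = []
    pairs = {
        "tumor_vs_paratumor": config.tumor_meth_shift,
        "lcsl_vs_paratumor": config.lcsl_meth_shift,
    }
    for pair, shifts in pairs.items():
        hot = {s: d for s, d in shifts.items() if abs(d) > 0.25}
        for iv in track.itertuples():
            if iv.state not in hot:
                continue
            d = hot[iv.state]
            for start in range(iv.start, iv.end, tile_w):
                rows.append({
                    "chrom": iv.chrom, "start": start,
                    "end": min(start + tile_w, iv.end), "state": iv.state,
                    "pair": pair,
                    "direction": "hyper" if d > 0 else "hypo",
                })
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "state", "pair", "direction"])


# ---------------------------------------------------------------------------
# CNA and spatial spots
# ---------------------------------------------------------------------------

_CNA_CONTIGS = ["chr8q", "chr5a", "chr11a", "chr17a"]


def gene_map(config: SimConfig) -> pd.DataFrame:
    """Toy gene intervals (0-based half-open) spread over four contigs."""
    rows = []
    per_contig = int(np.ceil(config.n_genes / len(_CNA_CONTIGS)))
    g = 0
    for contig in _CNA_CONTIGS:
        for k in range(per_contig):
            if g >= config.n_genes:
                break
            start = k * 2 * config.gene_length
            rows.append({"gene": f"G{g:04d}", "chrom": contig,
                         "start": start, "end": start + config.gene_length})
            g += 1
    return pd.DataFrame(rows)


def _merge_segments(segs: list[tuple[str, int, int, int]]):
    """Merge overlapping same-contig segments; warn via returned flag."""
    out: list[tuple[str, int, int, int]] = []
    merged_any = False
    for seg in sorted(segs):
        if out and out[-1][0] == seg[0] and seg[1] < out[-1][2]:
            prev = out.pop()
            out.append((prev[0], prev[1], max(prev[2], seg[2]),
                        max(prev[3], seg[3])))
            merged_any = True
        else:
            out.append(seg)
    return out, merged_any


def _amp_truth(tree_or_config, config: SimConfig | None = None) -> pd.DataFrame:
    if config is None:
        config = tree_or_config
        segments = config.branch_amp_segments
    else:
        segments = tree_or_config.branch_amp_segments
    genes = gene_map(config)
    edge_of_branch = {v: k for k, v in _BRANCH_OF_EDGE.items() if v}
    rows = []
    for edge, segs in segments.items():
        edge = edge_of_branch.get(edge, edge)   # accept branch or node names
        if edge not in _TREE_EDGES:
            raise ValueError(f"unknown branch {edge!r} in amp segments")
        segs, _ = _merge_segments(segs)
        carriers = sorted(
            leaf for leaf in CELL_TYPES
            if _edge_on_path(edge, leaf))
        for chrom, start, end, cn in segs:
            hit = genes[(genes["chrom"] == chrom)
                        & (genes["start"] < end) & (genes["end"] > start)]
            if hit.empty:
                raise ValueError(
                    f"amplified segment {chrom}:{start}-{end} maps to no gene")
            for g in hit.itertuples():
                rows.append({"gene": g.gene, "chrom": g.chrom, "start": g.start,
                             "end": g.end, "copy_number": cn,
                             "clones": ";".join(carriers)})
    return pd.DataFrame(
        rows, columns=["gene", "chrom", "start", "end", "copy_number", "clones"])


def _edge_on_path(edge: str, leaf: str) -> bool:
    node = leaf
    while node != "root":
        if node == edge:
            return True
        node = _TREE_EDGES[node]
    return False


def simulate_cna_and_spots(
    tree: CloneTree, config: SimConfig
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Gene-level log2 copy-ratio table, cohort frequencies, spot matrix, coords.

    Returns ``(gene_log2, cohort_freq, spot_counts, spot_coords)``.  Carrier
    clones receive log2(CN/2) plus Gaussian noise at amplified genes; all
    other gene/sample pairs are log2(2/2) = 0 plus noise.  Spots are
    cell-type-pure with type-specific expression programs over the marker
    panel."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 53]))
    noise = config.noise == "on"
    genes = gene_map(config)
    sheet = sample_sheet(config)
    wes = sheet[sheet["cell_type"] != "CONTROL"]

    amp = _amp_truth(tree, config)
    amp_of: dict[tuple[str, str], int] = {}
    for r in amp.itertuples():
        for clone in r.clones.split(";"):
            amp_of[(r.gene, clone)] = r.copy_number

    rows = []
    for s in wes.itertuples():
        covered = 0.4 if s.sample_id in config.low_coverage_samples else 1.0
        for g in genes.itertuples():
            cn = amp_of.get((g.gene, s.cell_type), 2)
            base = float(np.log2(cn / 2.0))
            val = base + (rng.normal(0.0, config.cna_noise_sd) if noise else 0.0)
            rows.append({"gene": g.gene, "chrom": g.chrom, "start": g.start,
                         "end": g.end, "sample_id": s.sample_id,
                         "log2_ratio": val,
                         "target_covered_fraction": covered})
    gene_log2 = pd.DataFrame(rows)

    # cohort amplification frequencies: truth-amplified genes are common in
    # the cohort except for a few low-frequency decoys
    amp_genes = sorted(amp["gene"].unique())
    decoys = set(amp_genes[: config.n_lowfreq_decoys])
    freq = {g.gene: 0.01 for g in genes.itertuples()}
    for g in amp_genes:
        freq[g] = 0.02 if g in decoys else 0.10
    cohort_freq = pd.DataFrame(
        {"gene": list(freq), "cohort_amp_frequency": list(freq.values())})

    spot_counts, spot_coords = _simulate_spots(config, rng, noise)
    return gene_log2, cohort_freq, spot_counts, spot_coords


def _panel_gene_names(config: SimConfig) -> list[str]:
    return [f"PANEL{k:02d}" for k in range(1, config.n_panel_genes + 1)]


def _spot_truth(config: SimConfig) -> pd.DataFrame:
    rows = []
    for t, ct in enumerate(CELL_TYPES):
        for k in range(config.n_spots_per_type):
            rows.append({"spot_id": f"SPOT_{ct}_{k:03d}", "cell_type": ct})
    return pd.DataFrame(rows)


def _simulate_spots(config: SimConfig, rng: np.random.Generator, noise: bool):
    """Cell-type-pure spots: Poisson counts around type programs.

    Panel genes follow liver-lineage logic — high in the stem/ductular
    populations (LCSL, PDR), intermediate in normal liver (PL), low in the
    dedifferentiated tumor populations (HCC, CCA) — so marker-panel
    clustering groups LCSL with PDR."""
    panel = _panel_gene_names(config)
    other = [f"G{k:04d}" for k in range(config.n_spot_genes - len(panel))]
    genes = panel + other
    panel_level = {"LCSL": 20.0, "PDR": 18.0, "PL": 10.0, "HCC": 2.0, "CCA": 2.5}

    programs = {}
    for t, ct in enumerate(CELL_TYPES):
        mean = np.full(len(genes), 5.0)
        mean[: len(panel)] = panel_level[ct]
        # a type-specific program over a block of non-panel genes
        lo = len(panel) + t * 10
        mean[lo: lo + 10] *= 8.0
        programs[ct] = mean

    truth = _spot_truth(config)
    counts = np.zeros((len(truth), len(genes)), dtype=int)
    coords = []
    for i, spot in enumerate(truth.itertuples()):
        mean = programs[spot.cell_type]
        if noise:
            lib = float(np.exp(rng.normal(0.0, config.spot_libsize_sd)))
            counts[i] = rng.poisson(mean * lib)
        else:
            counts[i] = np.rint(mean).astype(int)
        t = CELL_TYPES.index(spot.cell_type)
        k = i - t * config.n_spots_per_type
        coords.append({"spot_id": spot.spot_id, "row": t * 12 + k // 10,
                       "col": k % 10})
    spot_counts = pd.DataFrame(counts, index=truth["spot_id"], columns=genes)
    spot_counts.index.name = "spot_id"
    return spot_counts, pd.DataFrame(coords)


# ---------------------------------------------------------------------------
# one-call dataset bundle
# ---------------------------------------------------------------------------

@dataclass
class Dataset:
    """Everything one simulated specimen produces, in memory."""

    config: SimConfig
    tree: CloneTree
    truth: TruthTables
    sheet: pd.DataFrame
    meth_sheet: pd.DataFrame
    calls: pd.DataFrame
    coverage: pd.DataFrame
    panel: pd.DataFrame
    methylomes: dict[str, pd.DataFrame]
    states: pd.DataFrame
    gene_log2: pd.DataFrame
    cohort_freq: pd.DataFrame
    spot_counts: pd.DataFrame
    spot_coords: pd.DataFrame


def simulate_dataset(config: SimConfig) -> Dataset:
    """Run every generator stage under one seed."""
    tree, truth = simulate_clone_tree(config)
    calls, coverage, panel = simulate_variant_observations(tree, config, truth)
    methylomes = simulate_methylomes(config)
    gene_log2, cohort_freq, spots, coords = simulate_cna_and_spots(tree, config)
    return Dataset(
        config=config, tree=tree, truth=truth,
        sheet=sample_sheet(config), meth_sheet=meth_sample_sheet(config),
        calls=calls, coverage=coverage, panel=panel,
        methylomes=methylomes, states=state_track(config),
        gene_log2=gene_log2, cohort_freq=cohort_freq,
        spot_counts=spots, spot_coords=coords,
    )
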