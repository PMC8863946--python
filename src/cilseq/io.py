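"""Shared readers/writers, run configuration and the end-to-end pipeline.

Coordinate conventions are enforced at the boundaries: variant and
methylation positions are 1-based; BED state tracks, tiles and gene
intervals are 0-based half-open.  Every table writer sorts rows (contig,
position, sample) so outputs diff stably, and the pipeline records a
manifest with seeds, thresholds and SHA-256 input checksums so a rerun can
be verified bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import cna, methylome, snv, spatial
from .synthetic import (CELL_TYPES, Dataset, SimConfig, TUMOR_TYPES,
                        simulate_dataset)

logger = logging.getLogger(__name__)

VALID_CELL_TYPES = set(CELL_TYPES) | {"CONTROL"}


@dataclass
class RunConfig:
    """All pipeline thresholds; the defaults are the published values."""

    stages: tuple[str, ...] = ("simulate", "snv", "cna", "meth", "spatial")
    seed: int = 0
    out_dir: str = "cilseq_out"

    max_pop_af: float = 0.01
    proximity_bp: int = 10
    min_depth: int = 10
    min_alt_reads: int = 2
    min_af: float = 0.05
    min_recurrence: int = 2
    recurrence_patients: tuple[str, ...] = ("P2",)
    low_cov: int = 5

    log2_amp_threshold: float = 1.0
    min_cohort_freq: float = 0.05
    min_tumor_excess: int = 3
    min_target_fraction: float = 0.5

    min_base_cov: int = 3
    max_base_cov: int = 500
    tile_mode: str = "frozen"
    min_tile_cpgs: int = 3
    dmr_q: float = 0.05
    dmr_diff: float = 0.25
    enrichment_q: float = 0.01

    kmeans_k: int = 10

    sim: dict = field(default_factory=dict)   # SimConfig overrides

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        if "recurrence_patients" in raw:
            raw["recurrence_patients"] = tuple(raw["recurrence_patients"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def validate_sample_sheet(sheet: pd.DataFrame, require_control: bool = True
                          ) -> None:
    """Enforce the sample-typology invariants of the study design."""
    bad = set(sheet["cell_type"]) - VALID_CELL_TYPES
    if bad:
        raise ValueError(f"unknown cell types: {sorted(bad)}")
    for r in sheet.itertuples():
        if r.cell_type in TUMOR_TYPES and r.compartment != "tumor":
            raise ValueError(f"{r.sample_id}: {r.cell_type} must be tumor")
        if r.cell_type in ("PDR", "PL") and r.compartment != "paratumor":
            raise ValueError(f"{r.sample_id}: {r.cell_type} must be paratumor")
    if require_control:
        ctrl = sheet[sheet["cell_type"] == "CONTROL"]
        per_patient = ctrl.groupby("patient").size()
        for patient in sheet["patient"].unique():
            if per_patient.get(patient, 0) != 1:
                raise ValueError(
                    f"patient {patient}: exactly one CONTROL sample required")


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

_VARIANT_COLS = ["chrom", "pos", "ref", "alt", "sample_id", "callers",
                 "depth", "alt_reads"]


def read_variants(path: str | Path, format: str | None = None) -> pd.DataFrame:
    """Read candidate variants from TSV or minimal VCF 4.2 (1-based positions).

    Malformed rows (alt_reads > depth, negative counts) are rejected with
    their line numbers.
    """
    path = Path(path)
    if format is None:
        format = "vcf" if path.suffix.lower() == ".vcf" else "tsv"
    if format == "vcf":
        df = _read_vcf(path)
    else:
        df = pd.read_csv(path, sep="\t")
        df.columns = [c.lower() for c in df.columns]
        missing = [c for c in _VARIANT_COLS if c not in df.columns]
        if missing:
            raise ValueError(f"variant table missing column(s): {missing}")
    bad = df.index[(df["alt_reads"] > df["depth"]) | (df["alt_reads"] < 0)
                   | (df["depth"] < 0)]
    if len(bad):
        raise ValueError(
            f"invalid depth/alt_reads at data line(s) {[int(i) + 2 for i in bad]}")
    df["af"] = (df["alt_reads"] / df["depth"].replace(0, pd.NA)).fillna(0.0)
    return df[_VARIANT_COLS + ["af"]]


def _read_vcf(path: Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        samples: list[str] = []
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if line.startswith("##") or not line:
                continue
            fields = line.split("\t")
            if line.startswith("#CHROM"):
                samples = fields[9:]
                continue
            if not samples:
                raise ValueError(f"{path}: no #CHROM header before line {lineno}")
            chrom, pos, _, ref, alt = fields[0], int(fields[1]), fields[2], \
                fields[3], fields[4]
            info = dict(kv.split("=", 1) for kv in fields[7].split(";")
                        if "=" in kv)
            fmt = fields[8].split(":")
            for sample, value in zip(samples, fields[9:]):
                parts = dict(zip(fmt, value.split(":")))
                if parts.get("GT", "./.") in ("./.", "."):
                    continue
                dp = int(parts["DP"])
                ad = parts.get("AD", "")
                alt_reads = int(ad.split(",")[1]) if "," in ad else 0
                rows.append({"chrom": chrom, "pos": pos, "ref": ref,
                             "alt": alt, "sample_id": sample,
                             "callers": info.get("CALLERS", ""),
                             "depth": dp, "alt_reads": alt_reads})
    return pd.DataFrame(rows, columns=_VARIANT_COLS)


_METH_CONTEXTS = {"CpG", "CHG", "CHH"}


def read_methylation(path: str | Path) -> pd.DataFrame:
    """Read a CX-report-like methylation table (1-based positions)."""
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.lower() for c in df.columns]
    required = ["chrom", "pos", "strand", "context", "meth_count",
                "unmeth_count"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"methylation table missing column(s): {missing}")
    bad_ctx = set(df["context"]) - _METH_CONTEXTS
    if bad_ctx:
        raise ValueError(f"unknown context token(s): {sorted(bad_ctx)}")
    if (df["meth_count"] < 0).any() or (df["unmeth_count"] < 0).any():
        raise ValueError("negative methylation counts")
    if not df["strand"].isin(["+", "-"]).all():
        raise ValueError("strand must be '+' or '-'")
    return df[required]


def read_bed_states(path: str | Path) -> pd.DataFrame:
    """Read a chromatin-state BED (0-based half-open)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}: malformed BED at line {lineno}")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as err:
                raise ValueError(
                    f"{path}: malformed BED at line {lineno}") from err
            if end <= start:
                raise ValueError(
                    f"{path}: empty interval at line {lineno}")
            rows.append({"chrom": fields[0], "start": start, "end": end,
                         "state": fields[3]})
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "state"])


def read_matrix_mtx(mtx_path: str | Path, genes_path: str | Path,
                    spots_path: str | Path) -> pd.DataFrame:
    """Read a spots-by-genes matrix from MTX triplet + name files."""
    from scipy.io import mmread
    m = mmread(str(mtx_path)).toarray()
    genes = pd.read_csv(genes_path, sep="\t", header=None)[0].tolist()
    spots = pd.read_csv(spots_path, sep="\t", header=None)[0].tolist()
    out = pd.DataFrame(m, index=spots, columns=genes)
    out.index.name = "spot_id"
    return out


def write_matrix_mtx(matrix: pd.DataFrame, mtx_path: str | Path,
                     genes_path: str | Path, spots_path: str | Path) -> None:
    from scipy.io import mmwrite
    from scipy.sparse import csr_matrix
    mmwrite(str(mtx_path), csr_matrix(matrix.to_numpy()))
    pd.Series(matrix.columns).to_csv(genes_path, sep="\t", header=False,
                                     index=False)
    pd.Series(matrix.index).to_csv(spots_path, sep="\t", header=False,
                                   index=False)


def write_table(df: pd.DataFrame, path: str | Path,
                sort_by: list[str] | None = None) -> None:
    out = df.sort_values(sort_by, ignore_index=True) if sort_by else df
    out.to_csv(path, sep="\t", index=False)


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in ["chrom", "start", "end", "state"] if c in df.columns]
    df.sort_values(["chrom", "start"])[cols].to_csv(
        path, sep="\t", index=False, header=False)


# ---------------------------------------------------------------------------
# pipeline orchestration
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_simulated_dataset(ds: Dataset, out_dir: str | Path) -> dict[str, str]:
    """Write every simulated table (and ground truth) as sorted TSV/BED."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "methylomes").mkdir(exist_ok=True)
    write_table(ds.sheet, out / "samples.tsv", ["sample_id"])
    write_table(ds.meth_sheet, out / "meth_samples.tsv", ["sample_id"])
    write_table(ds.calls, out / "variants.tsv", ["chrom", "pos", "sample_id"])
    write_table(ds.coverage, out / "coverage.tsv", ["chrom", "pos", "sample_id"])
    write_table(ds.panel, out / "population_panel.tsv", ["chrom", "pos"])
    write_table(ds.gene_log2, out / "gene_log2.tsv", ["gene", "sample_id"])
    write_table(ds.cohort_freq, out / "cohort_frequency.tsv", ["gene"])
    write_bed(ds.states, out / "chromatin_states.bed")
    for sample, table in sorted(ds.methylomes.items()):
        write_table(table, out / "methylomes" / f"{sample}.cx.tsv",
                    ["chrom", "pos", "strand"])
    write_matrix_mtx(ds.spot_counts, out / "spots.mtx",
                     out / "spot_genes.tsv", out / "spot_barcodes.tsv")
    write_table(ds.spot_coords, out / "spot_coords.tsv", ["spot_id"])
    truth_dir = out / "truth"
    truth_dir.mkdir(exist_ok=True)
    write_table(ds.truth.snv_truth, truth_dir / "snv_truth.tsv", ["site"])
    write_table(ds.truth.snv_sample_truth, truth_dir / "snv_sample_truth.tsv",
                ["site", "sample_id"])
    write_table(ds.truth.amp_truth, truth_dir / "amp_truth.tsv", ["gene"])
    write_table(ds.truth.dmr_truth, truth_dir / "dmr_truth.tsv",
                ["pair", "chrom", "start"])
    write_table(ds.truth.spot_truth, truth_dir / "spot_truth.tsv", ["spot_id"])
    return {str(p.relative_to(out)): _sha256(p)
            for p in sorted(out.rglob("*")) if p.is_file()}


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None
                 ) -> dict:
    """Simulate a specimen and run every requested stage; write a manifest.

    Returns the manifest dict.  Stage order is fixed (simulate, snv, cna,
    meth, spatial); a failing stage halts with a stage-named error.
    """
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "thresholds": {k: v for k, v in asdict(config).items()
                       if k not in ("stages", "sim", "out_dir")},
        "stages": list(config.stages),
        "checksums": {},
    }

    sim_cfg = SimConfig(seed=config.seed, **config.sim)
    ds = simulate_dataset(sim_cfg)
    stage = "simulate"
    try:
        if "simulate" in config.stages:
            manifest["checksums"].update(
                {f"sim/{k}": v for k, v in
                 write_simulated_dataset(ds, out / "sim").items()})

        if "snv" in config.stages:
            stage = "snv"
            _run_snv_stage(ds, config, out)
        if "cna" in config.stages:
            stage = "cna"
            _run_cna_stage(ds, config, out)
        if "meth" in config.stages:
            stage = "meth"
            _run_meth_stage(ds, config, out)
        if "spatial" in config.stages:
            stage = "spatial"
            _run_spatial_stage(ds, config, out)
    except Exception as err:
        raise RuntimeError(f"stage '{stage}' failed: {err}") from err

    for p in sorted(out.rglob("*.tsv")) + sorted(out.rglob("*.nwk")):
        rel = str(p.relative_to(out))
        if rel not in manifest["checksums"]:
            manifest["checksums"][rel] = _sha256(p)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _run_snv_stage(ds: Dataset, config: RunConfig, out: Path) -> None:
    sheet = ds.sheet
    validate_sample_sheet(sheet)
    control = sheet.loc[sheet["cell_type"] == "CONTROL", "sample_id"].iloc[0]
    calls = ds.calls[ds.calls["sample_id"] != control]
    control_calls = ds.calls[ds.calls["sample_id"] == control]
    control_cov = ds.coverage[ds.coverage["sample_id"] == control]
    patients = dict(zip(sheet["sample_id"], sheet["patient"]))
    filtered = snv.run_filter_cascade(
        calls, ds.panel, control_calls, control_cov, patients,
        set(config.recurrence_patients), max_pop_af=config.max_pop_af,
        window_bp=config.proximity_bp, min_depth=config.min_depth,
        min_alt=config.min_alt_reads, min_af=config.min_af,
        min_recurrence=config.min_recurrence)
    samples = sorted(sheet.loc[sheet["cell_type"] != "CONTROL", "sample_id"])
    groups = dict(zip(sheet["sample_id"], sheet["cell_type"]))
    matrix = snv.build_mutation_matrix(
        filtered, samples, ds.coverage, groups, low_cov=config.low_cov)
    spectrum = snv.mutation_spectrum(filtered)
    tree = snv.cluster_samples(matrix)
    stage = out / "snv"
    stage.mkdir(exist_ok=True)
    write_table(filtered, stage / "filtered_calls.tsv",
                ["chrom", "pos", "sample_id"])
    matrix.rename_axis("site").reset_index().to_csv(
        stage / "mutation_matrix.tsv", sep="\t", index=False)
    spectrum.rename_axis("class").rename("proportion").reset_index().to_csv(
        stage / "spectrum.tsv", sep="\t", index=False)
    (stage / "dendrogram.nwk").write_text(tree.to_newick() + "\n")


def _run_cna_stage(ds: Dataset, config: RunConfig, out: Path) -> None:
    table, dropped = cna.qc_samples(ds.gene_log2, config.min_target_fraction)
    compartments = dict(zip(ds.sheet["sample_id"], ds.sheet["compartment"]))
    amp = cna.call_amplifications(table, compartments,
                                  config.log2_amp_threshold)
    kept = cna.filter_recurrent_genes(
        amp, ds.cohort_freq, config.min_cohort_freq, config.min_tumor_excess)
    tree = cna.cluster_by_amplification(amp, kept) if kept else None
    stage = out / "cna"
    stage.mkdir(exist_ok=True)
    amp.rename_axis("gene").reset_index().to_csv(
        stage / "amplification_matrix.tsv", sep="\t", index=False)
    pd.Series(kept, name="gene").to_csv(stage / "kept_genes.tsv", sep="\t",
                                        index=False)
    pd.Series(dropped, name="sample_id").to_csv(
        stage / "dropped_samples.tsv", sep="\t", index=False)
    if tree is not None:
        (stage / "dendrogram.nwk").write_text(tree.to_newick() + "\n")


def _run_meth_stage(ds: Dataset, config: RunConfig, out: Path) -> None:
    stage = out / "meth"
    stage.mkdir(exist_ok=True)
    conv = {s: methylome.conversion_rate(t)[1]
            for s, t in ds.methylomes.items()}
    tiles = methylome.tile_windows(ds.methylomes, config.tile_mode,
                                   config.min_tile_cpgs)
    sheet = ds.meth_sheet
    by_type = {ct: sorted(sheet.loc[sheet["cell_type"] == ct, "sample_id"])
               for ct in CELL_TYPES}
    corr, tree = methylome.correlate_and_cluster(tiles)
    pairs = {
        "tumor_vs_paratumor": (by_type["PDR"] + by_type["PL"],
                               by_type["HCC"] + by_type["CCA"]),
        "lcsl_vs_paratumor": (by_type["PDR"] + by_type["PL"], by_type["LCSL"]),
    }
    freq_rows = []
    for name, (ga, gb) in pairs.items():
        dmrs = methylome.call_dmrs(tiles, ga, gb, config.dmr_q,
                                   config.dmr_diff)
        enr = methylome.enrichment(dmrs, ds.states, config.enrichment_q)
        write_table(dmrs, stage / f"dmr_{name}.tsv", ["chrom", "start"])
        write_table(enr, stage / f"enrichment_{name}.tsv",
                    ["direction", "state"])
        freq_rows.append({"pair": name,
                          "dmr_frequency": methylome.dmr_frequency(dmrs)})
    write_table(pd.DataFrame(freq_rows), stage / "dmr_frequency.tsv", ["pair"])
    pd.Series(conv, name="conversion_rate").rename_axis("sample_id") \
        .reset_index().to_csv(stage / "conversion.tsv", sep="\t", index=False)
    corr.rename_axis("sample_id").reset_index().to_csv(
        stage / "correlation.tsv", sep="\t", index=False)
    write_table(tiles, stage / "tiles.tsv", ["chrom", "start", "sample_id"])
    (stage / "dendrogram.nwk").write_text(tree.to_newick() + "\n")


def _run_spatial_stage(ds: Dataset, config: RunConfig, out: Path) -> None:
    stage = out / "spatial"
    stage.mkdir(exist_ok=True)
    norm = spatial.median_normalize(ds.spot_counts)
    labels, inertia = spatial.kmeans_spots(norm, config.kmeans_k, config.seed)
    panel = [g for g in ds.spot_counts.columns if g.startswith("PANEL")]
    selected = ds.truth.spot_truth.loc[
        ds.truth.spot_truth["cell_type"].isin(["LCSL", "PDR", "HCC"]),
        "spot_id"].tolist()
    tree = spatial.panel_cluster(ds.spot_counts, selected, panel)
    labels.rename_axis("spot_id").reset_index().to_csv(
        stage / "kmeans_labels.tsv", sep="\t", index=False)
    (stage / "panel_dendrogram.nwk").write_text(tree.to_newick() + "\n")
    (stage / "kmeans_inertia.txt").write_text(f"{inertia:.6f}\n")


def verify_manifest(out_dir: str | Path) -> None:
    """Re-hash the outputs listed in a manifest; raise on any mismatch."""
    out = Path(out_dir)
    with open(out / "manifest.json") as fh:
        manifest = json.load(fh)
    bad = []
    for rel, digest in manifest["checksums"].items():
        p = out / rel
        if not p.exists() or _sha256(p) != digest:
            bad.append(rel)
    if bad:
        raise RuntimeError(
            "checksum mismatch; refusing to reuse outputs: " + ", ".join(bad))
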