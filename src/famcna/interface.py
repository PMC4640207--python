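"""File formats, configuration and pipeline orchestration.

All tables are UTF-8 tab-delimited text.  Matrices carry a header row of
sample ids and a first column of row ids; missing values are written as
``NA``.  Segment-style tables are BED-like and exported with 1-based
inclusive coordinates (internal indices are 0-based half-open); every such
file starts with a header comment declaring the convention.  Configuration
files are flat ``key = value`` text with dotted keys.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import class_comparison, cn_core, expression, loh_core
from . import synthetic_data as sd
from .exceptions import ConfigurationError, MatrixFormatError

logger = logging.getLogger("famcna")

FLOAT_FORMAT = "%.12g"
COORD_HEADER = "# coordinates: 1-based inclusive\n"


# ---------------------------------------------------------------------------
# matrices
# ---------------------------------------------------------------------------

def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a tab-delimited matrix with row ids and a sample-id header.

    Raises :class:`MatrixFormatError` (with a line number) on ragged rows and
    on duplicate row or column ids.  ``NA`` cells become NaN.
    """
    path = Path(path)
    with path.open(encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        n_cols = len(header)
        sample_ids = header[1:]
        dup = pd.Index(sample_ids)[pd.Index(sample_ids).duplicated()]
        if len(dup):
            raise MatrixFormatError(f"duplicate sample id {dup[0]!r}", line=1)
        row_ids: list[str] = []
        seen: set[str] = set()
        values: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != n_cols:
                raise MatrixFormatError(
                    f"expected {n_cols} fields, found {len(fields)}",
                    line=lineno)
            rid = fields[0]
            if rid in seen:
                raise MatrixFormatError(f"duplicate row id {rid!r}",
                                        line=lineno)
            seen.add(rid)
            row_ids.append(rid)
            try:
                values.append([float("nan") if f == "NA" else float(f)
                               for f in fields[1:]])
            except ValueError as err:
                raise MatrixFormatError(str(err), line=lineno) from err
    return pd.DataFrame(values, index=pd.Index(row_ids), columns=sample_ids)


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a matrix in the format :func:`read_matrix` reads back.

    Round-trip agreement is within 1e-9 (values are printed with 12
    significant digits).
    """
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("\t".join(["id"] + [str(c) for c in matrix.columns]) + "\n")
        for rid, row in zip(matrix.index, matrix.to_numpy()):
            cells = ["NA" if isinstance(v, float) and np.isnan(v)
                     else (FLOAT_FORMAT % v if isinstance(v, (float, np.floating))
                           else str(v))
                     for v in row]
            fh.write("\t".join([str(rid)] + cells) + "\n")


def write_table(table: pd.DataFrame, path: str | Path,
                coordinate_columns: tuple[str, str] | None = None) -> None:
    """Write a BED-like table; optional index columns exported 1-based
    inclusive (start+1, end unchanged since internal end is exclusive)."""
    out = table.copy()
    header = ""
    if coordinate_columns is not None:
        start, end = coordinate_columns
        out[start] = out[start].astype(int) + 1
        out[end] = out[end].astype(int)
        header = COORD_HEADER
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(header)
        out.to_csv(fh, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def linkage_to_newick(linkage: np.ndarray, leaf_names: list[str]) -> str:
    """Serialize a scipy linkage matrix as a Newick string."""
    n = len(leaf_names)
    heights = {i: 0.0 for i in range(n)}
    nodes = {i: leaf_names[i] for i in range(n)}
    for i, (a, b, h, _) in enumerate(linkage):
        a, b = int(a), int(b)
        la = h - heights[a]
        lb = h - heights[b]
        nodes[n + i] = f"({nodes[a]}:{la:.6g},{nodes[b]}:{lb:.6g})"
        heights[n + i] = h
    return nodes[n + len(linkage) - 1] + ";"


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PipelineConfig:
    """Every stage's parameters in one place, echoed to the run log."""

    simulation: sd.SimulationConfig = dataclasses.field(
        default_factory=sd.SimulationConfig)
    cn_params: cn_core.SegmentationParams = dataclasses.field(
        default_factory=cn_core.SegmentationParams)
    loh_params: loh_core.LohParams = dataclasses.field(
        default_factory=loh_core.LohParams)
    de_alpha: float = 0.05
    signature_alpha: float = 0.05
    top_variance_fraction: float = 0.5
    class_a: str = "CHEK2"
    class_b: str = "BRCAX"
    seed: int = 0

    def validate(self) -> None:
        self.simulation.validate()
        self.cn_params.validate()
        self.loh_params.validate()
        for name in ("de_alpha", "signature_alpha"):
            if not 0.0 < getattr(self, name) < 1.0:
                raise ConfigurationError(f"{name} must be in (0, 1)")
        if not 0.0 < self.top_variance_fraction <= 1.0:
            raise ConfigurationError(
                "top_variance_fraction must be in (0, 1]")


def _bool(raw: str) -> bool:
    lowered = raw.strip().lower()
    if lowered in ("true", "1", "yes"):
        return True
    if lowered in ("false", "0", "no"):
        return False
    raise ConfigurationError(f"expected a boolean, got {raw!r}")


_CONFIG_KEYS = {
    "simulation.n_markers_per_chromosome": ("simulation",
                                            "n_markers_per_chromosome", int),
    "simulation.n_reference_samples": ("simulation", "n_reference_samples",
                                       int),
    "simulation.lrr_noise_sd": ("simulation", "lrr_noise_sd", float),
    "simulation.baf_noise_sd": ("simulation", "baf_noise_sd", float),
    "simulation.het_fraction": ("simulation", "het_fraction", float),
    "simulation.gc_wave_sd": ("simulation", "gc_wave_sd", float),
    "simulation.fragment_wave_sd": ("simulation", "fragment_wave_sd", float),
    "simulation.til_high_cutoff": ("simulation", "til_high_cutoff", float),
    "simulation.seed": ("simulation", "seed", int),
    "simulation.plant_events": ("simulation", "plant_events", _bool),
    "groups.chek2_low": ("groups", "chek2_low", int),
    "groups.chek2_high": ("groups", "chek2_high", int),
    "groups.brcax_low": ("groups", "brcax_low", int),
    "groups.brcax_high": ("groups", "brcax_high", int),
    "groups.brca1": ("groups", "brca1", int),
    "groups.brca2": ("groups", "brca2", int),
    "expression.n_genes": ("expression", "n_genes", int),
    "expression.n_signature_genes": ("expression", "n_signature_genes", int),
    "expression.signature_effect_sd_units": (
        "expression", "signature_effect_sd_units", float),
    "expression.n_subtype_genes": ("expression", "n_subtype_genes", int),
    "expression.subtype_log2_separation": (
        "expression", "subtype_log2_separation", float),
    "expression.n_de_genes": ("expression", "n_de_genes", int),
    "expression.de_log2_fc": ("expression", "de_log2_fc", float),
    "expression.expr_noise_sd": ("expression", "expr_noise_sd", float),
    "cn.p_threshold": ("cn_params", "p_threshold", float),
    "cn.min_markers": ("cn_params", "min_markers", int),
    "cn.signal_noise_min": ("cn_params", "signal_noise_min", float),
    "loh.mbaf_threshold": ("loh_params", "mbaf_threshold", float),
    "loh.p_threshold": ("loh_params", "p_threshold", float),
    "loh.min_markers": ("loh_params", "min_markers", int),
    "loh.homozygous_cutoff": ("loh_params", "homozygous_cutoff", float),
    "de_alpha": (None, "de_alpha", float),
    "signature_alpha": (None, "signature_alpha", float),
    "top_variance_fraction": (None, "top_variance_fraction", float),
    "class_a": (None, "class_a", str),
    "class_b": (None, "class_b", str),
    "seed": (None, "seed", int),
}


def load_config(path: str | Path | None = None,
                overrides: dict[str, str] | None = None) -> PipelineConfig:
    """Build a PipelineConfig from a flat key-value file plus overrides.

    Unknown keys are rejected before any computation.  Lines starting with
    ``#`` and blank lines are ignored; ``key = value`` and ``key: value``
    are both accepted.
    """
    entries: dict[str, str] = {}
    if path is not None:
        for lineno, line in enumerate(
                Path(path).read_text(encoding="utf-8").splitlines(), 1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            sep = "=" if "=" in stripped else ":"
            if sep not in stripped:
                raise ConfigurationError(
                    f"config line {lineno}: expected 'key = value'")
            key, _, value = stripped.partition(sep)
            entries[key.strip()] = value.strip()
    entries.update(overrides or {})

    config = PipelineConfig()
    for key, raw in entries.items():
        if key not in _CONFIG_KEYS:
            raise ConfigurationError(f"unknown config key {key!r}")
        section, attr, cast = _CONFIG_KEYS[key]
        value = cast(raw)
        if section is None:
            setattr(config, attr, value)
        elif section == "groups":
            setattr(config.simulation.groups, attr, value)
        elif section == "expression":
            setattr(config.simulation.expression, attr, value)
        else:
            setattr(getattr(config, section), attr, value)
    config.simulation.seed = config.seed
    config.validate()
    return config


def log_parameters(config: PipelineConfig) -> None:
    """Echo every threshold into the run log so deviations are visible."""
    logger.info("seed=%d", config.seed)
    logger.info("cn segmentation: p<%g, min_markers=%d, signal/noise>=%g",
                config.cn_params.p_threshold, config.cn_params.min_markers,
                config.cn_params.signal_noise_min)
    logger.info("state thresholds: neutral [%g, %g] copies, amplification >%g",
                cn_core.NEUTRAL_LOW, cn_core.NEUTRAL_HIGH,
                cn_core.AMPLIFICATION_MIN)
    logger.info("LOH: mBAF>=%g, p<%g, min informative markers=%d, "
                "homozygous cutoff=%g",
                config.loh_params.mbaf_threshold,
                config.loh_params.p_threshold, config.loh_params.min_markers,
                config.loh_params.homozygous_cutoff)
    logger.info("expression: signature FDR<%g, DE FDR<%g, "
                "top variance fraction=%g", config.signature_alpha,
                config.de_alpha, config.top_variance_fraction)


# ---------------------------------------------------------------------------
# pipeline stages
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class PipelineRun:
    """Stage runner writing outputs and a machine-readable manifest."""

    def __init__(self, config: PipelineConfig, out_dir: str | Path):
        config.validate()
        self.config = config
        self.out = Path(out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.manifest: dict = {"stages": [], "parameters": {
            "seed": config.seed,
            "cn": dataclasses.asdict(config.cn_params),
            "loh": {k: v for k, v in
                    dataclasses.asdict(config.loh_params).items()
                    if k != "segmentation"},
            "de_alpha": config.de_alpha,
            "signature_alpha": config.signature_alpha,
        }, "outputs": {}}
        log_parameters(config)

    def _record(self, stage: str, files: list[Path]) -> None:
        self.manifest["stages"].append(stage)
        for f in files:
            self.manifest["outputs"][f.name] = _sha256(f)

    def _path(self, name: str) -> Path:
        return self.out / name

    def _require(self, name: str) -> Path:
        p = self._path(name)
        if not p.exists():
            raise FileNotFoundError(
                f"missing input {p}; run the producing stage first")
        return p

    def write_manifest(self) -> Path:
        p = self._path("manifest.json")
        p.write_text(json.dumps(self.manifest, indent=2, sort_keys=True),
                     encoding="utf-8")
        return p

    # -- simulate ----------------------------------------------------------
    def stage_simulate(self) -> None:
        cfg = self.config.simulation
        cohort = sd.simulate_cohort(cfg)
        expr, gene_info = sd.simulate_expression(cfg, cohort.truth)
        files = []

        mm = cohort.marker_map
        p = self._path("marker_map.tsv")
        mm.to_csv(p, sep="\t", index=False, float_format=FLOAT_FORMAT)
        files.append(p)
        for name, df in (("tumor_copy", cohort.tumor_copy),
                         ("tumor_baf", cohort.tumor_baf),
                         ("reference_copy", cohort.reference_copy),
                         ("expression", expr)):
            p = self._path(f"{name}.tsv")
            write_matrix(df, p)
            files.append(p)
        p = self._path("metadata.tsv")
        cohort.metadata.reset_index().to_csv(p, sep="\t", index=False,
                                             float_format=FLOAT_FORMAT)
        files.append(p)
        p = self._path("gene_info.tsv")
        gene_info.reset_index().to_csv(p, sep="\t", index=False,
                                       float_format=FLOAT_FORMAT)
        files.append(p)
        truth_rows = [(t.sample_id, e.name, e.chromosome, e.start, e.end,
                       e.total_copies, e.b_copies)
                      for t in cohort.truth.values() for e in t.events]
        p = self._path("truth_events.tsv")
        write_table(pd.DataFrame(truth_rows, columns=[
            "sample_id", "event", "chromosome", "start_index", "end_index",
            "total_copies", "b_copies"]), p,
            coordinate_columns=("start_index", "end_index"))
        files.append(p)
        self._record("simulate", files)

    # -- gate --------------------------------------------------------------
    def stage_gate(self) -> None:
        expr = read_matrix(self._require("expression.tsv"))
        meta = pd.read_csv(self._require("metadata.tsv"), sep="\t",
                           index_col="sample_id")
        gene_info = pd.read_csv(self._require("gene_info.tsv"), sep="\t",
                                index_col="gene_id")

        intrinsic = list(gene_info.index[gene_info["role"] == "subtype"])
        archetypes = gene_info.loc[intrinsic, ["luminal_mean", "basal_mean"]]
        archetypes.columns = ["luminal", "basal"]
        subtype = expression.assign_subtype(
            expr, intrinsic, archetypes,
            top_variance_fraction=self.config.top_variance_fraction)

        signature = expression.build_immune_signature(
            expr, meta["observed_til_percent"], subtype,
            alpha=self.config.signature_alpha)
        score = expression.signature_score(expr, signature)
        high = expression.gate_til(expr, signature)
        rho, pval = expression.spearman_til(score,
                                            meta["observed_til_percent"])
        logger.info("signature size=%d; Spearman score~TIL rho=%.3f p=%.2g",
                    len(signature), rho, pval)

        files = []
        p = self._path("signature_genes.tsv")
        pd.DataFrame({"gene_id": signature.genes,
                      "direction": signature.direction.to_numpy()}
                     ).to_csv(p, sep="\t", index=False)
        files.append(p)
        labels = pd.DataFrame({
            "sample_id": expr.columns,
            "assigned_subtype": subtype.to_numpy(),
            "high_til": high.to_numpy(),
            "signature_score": score.to_numpy(),
        })
        p = self._path("sample_labels.tsv")
        labels.to_csv(p, sep="\t", index=False, float_format=FLOAT_FORMAT)
        files.append(p)
        p = self._path("gate_summary.json")
        p.write_text(json.dumps({
            "signature_size": len(signature),
            "spearman_rho": rho, "spearman_p": pval,
            "n_high_til": int(high.sum())}, indent=2), encoding="utf-8")
        files.append(p)
        self._record("gate", files)

    # -- cnloh -------------------------------------------------------------
    def stage_cnloh(self) -> None:
        mm = pd.read_csv(self._require("marker_map.tsv"), sep="\t",
                         dtype={"chromosome": str})
        tumor = read_matrix(self._require("tumor_copy.tsv"))
        ref = read_matrix(self._require("reference_copy.tsv"))
        baf = read_matrix(self._require("tumor_baf.tsv"))

        lrr = np.column_stack([
            cn_core.compute_log2_ratio(tumor[c].to_numpy(), ref.to_numpy())
            for c in tumor.columns])
        lrr = cn_core.correct_covariates(lrr, mm)

        seg_tables = []
        loh_tables = []
        for j, sid in enumerate(tumor.columns):
            seg_tables.append(cn_core.segment_sample(
                lrr[:, j], mm, self.config.cn_params, sample_id=sid))
            loh_tables.append(loh_core.loh_profile(
                baf[sid].to_numpy(), mm, self.config.loh_params,
                sample_id=sid))
        segments = pd.concat(seg_tables, ignore_index=True)
        loh = pd.concat(loh_tables, ignore_index=True)

        files = []
        p = self._path("segments.tsv")
        write_table(segments, p,
                    coordinate_columns=("start_index", "end_index"))
        files.append(p)
        p = self._path("loh_segments.tsv")
        write_table(loh, p, coordinate_columns=("start_index", "end_index"))
        files.append(p)
        p = self._path("log2_ratios.tsv")
        write_matrix(pd.DataFrame(lrr, index=tumor.index,
                                  columns=tumor.columns), p)
        files.append(p)
        self._record("cnloh", files)

    # -- compare -----------------------------------------------------------
    def stage_compare(self) -> None:
        mm = pd.read_csv(self._require("marker_map.tsv"), sep="\t",
                         dtype={"chromosome": str})
        segments = read_table(self._require("segments.tsv"))
        segments = segments.assign(
            start_index=segments["start_index"] - 1,
            chromosome=segments["chromosome"].astype(str))
        labels_df = pd.read_csv(self._require("sample_labels.tsv"), sep="\t",
                                index_col="sample_id")
        meta = pd.read_csv(self._require("metadata.tsv"), sep="\t",
                           index_col="sample_id")

        # supervised comparison on low-TIL luminal samples of the two classes
        cls = meta["mutation_class"]
        keep = (~labels_df["high_til"]
                & (labels_df["assigned_subtype"] == "luminal")
                & cls.isin([self.config.class_a, self.config.class_b]))
        selected = labels_df.index[keep]
        logger.info("class comparison on %d samples (%s vs %s)",
                    len(selected), self.config.class_a, self.config.class_b)
        sub_segments = segments[segments["sample_id"].isin(selected)]
        regions, states = class_comparison.build_region_grid(sub_segments)
        tests = class_comparison.region_tests(
            regions, states, cls[selected], self.config.class_a,
            self.config.class_b)
        freqs = class_comparison.frequency_profiles(states, cls[selected])
        freq_table = pd.concat([regions, freqs], axis=1)

        # unsupervised clustering of all luminal samples of both classes
        lum = labels_df.index[(labels_df["assigned_subtype"] == "luminal")
                              & cls.isin([self.config.class_a,
                                          self.config.class_b])]
        marker_states = class_comparison.states_to_marker_matrix(
            segments[segments["sample_id"].isin(lum)], mm)
        linkage, clusters = class_comparison.cluster_state_profiles(
            marker_states, n_clusters=3)

        files = []
        p = self._path("region_tests.tsv")
        write_table(tests, p, coordinate_columns=("start_index", "end_index"))
        files.append(p)
        p = self._path("region_frequencies.tsv")
        write_table(freq_table, p,
                    coordinate_columns=("start_index", "end_index"))
        files.append(p)
        p = self._path("cn_dendrogram.nwk")
        p.write_text(linkage_to_newick(linkage, list(marker_states.columns)),
                     encoding="utf-8")
        files.append(p)
        p = self._path("cn_clusters.tsv")
        clusters.rename_axis("sample_id").reset_index().to_csv(
            p, sep="\t", index=False)
        files.append(p)
        self._record("compare", files)

    # -- de ------------------------------------------------------------------
    def stage_de(self) -> None:
        expr = read_matrix(self._require("expression.tsv"))
        labels_df = pd.read_csv(self._require("sample_labels.tsv"), sep="\t",
                                index_col="sample_id")
        meta = pd.read_csv(self._require("metadata.tsv"), sep="\t",
                           index_col="sample_id")
        cls = meta["mutation_class"]
        keep = (~labels_df["high_til"]
                & (labels_df["assigned_subtype"] == "luminal")
                & cls.isin([self.config.class_a, self.config.class_b]))
        selected = labels_df.index[keep]
        de = expression.differential_expression(
            expr[selected], cls[selected], self.config.class_a,
            self.config.class_b)
        de = de.sort_values("fdr_p", kind="stable")
        significant = de[de["fdr_p"] < self.config.de_alpha]
        logger.info("%d genes at FDR < %g", len(significant),
                    self.config.de_alpha)
        files = []
        p = self._path("de_results.tsv")
        de.rename_axis("gene_id").reset_index().to_csv(
            p, sep="\t", index=False, float_format=FLOAT_FORMAT)
        files.append(p)
        p = self._path("de_significant.tsv")
        significant.rename_axis("gene_id").reset_index().to_csv(
            p, sep="\t", index=False, float_format=FLOAT_FORMAT)
        files.append(p)
        self._record("de", files)

    STAGES = ("simulate", "gate", "cnloh", "compare", "de")

    def run(self, stages: tuple[str, ...] = STAGES) -> Path:
        for stage in stages:
            logger.info("stage %s", stage)
            getattr(self, f"stage_{stage}")()
        return self.write_manifest()
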