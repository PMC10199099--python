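"""End-to-end orchestration: simulate -> quantify -> classify -> gcr ->
compare -> som -> annotate -> integrate, with provenance-stamped TSV
outputs and a JSON summary report.

Every output file starts with a provenance header (package version,
config hash, seed), and a rerun with an identical config produces
byte-identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .annotate import AnnotationConfig, assign_gene_context, genes_for_region_class, integrate_with_expression
from .compare import CompareConfig, classify_density
from .dynamics import CadConfig, GcrConfig, class_shift_table, classify_all, detect_gcr, gcr_threshold
from .intervals import read_genes, read_peaks
from .signal import SignalMatrix, log_transform, rpkm_normalize
from .simulate import (
    SimConfig,
    simulate_cuttag,
    simulate_expression,
    simulate_peaks,
    simulate_timecourse,
)
from .som import SomConfig, som_assign, som_train, zscore_rows

logger = logging.getLogger(__name__)


class PipelineConfigError(ValueError):
    """Invalid pipeline configuration (missing inputs, bad values)."""


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """All stage configs plus I/O paths and the global seed.

    With ``simulate=True`` (the default) inputs are generated by the
    synthetic module; otherwise ``peaks_bed``, ``counts_tsv``,
    ``meta_tsv``, ``genes_bed`` must point at existing files.  The
    single seed is propagated with fixed per-stage offsets.
    """

    out_dir: str = "cadkit_out"
    seed: int = 0
    simulate: bool = True
    peaks_bed: str | None = None
    counts_tsv: str | None = None
    meta_tsv: str | None = None
    genes_bed: str | None = None
    sim: SimConfig = field(default_factory=SimConfig)
    cad: CadConfig = field(default_factory=CadConfig)
    gcr: GcrConfig = field(default_factory=GcrConfig)
    compare: CompareConfig = field(default_factory=CompareConfig)
    som: SomConfig = field(default_factory=SomConfig)
    annotation: AnnotationConfig = field(default_factory=AnnotationConfig)

    def __post_init__(self) -> None:
        if isinstance(self.sim, dict):
            self.sim = SimConfig(**self.sim)
        if isinstance(self.cad, dict):
            self.cad = CadConfig(**{**self.cad, "stages": tuple(self.cad.get("stages", CadConfig().stages))})
        if isinstance(self.gcr, dict):
            self.gcr = GcrConfig(**self.gcr)
        if isinstance(self.compare, dict):
            self.compare = CompareConfig(**self.compare)
        if isinstance(self.som, dict):
            som = dict(self.som)
            if "grid" in som:
                som["grid"] = tuple(som["grid"])
            self.som = SomConfig(**som)
        if isinstance(self.annotation, dict):
            self.annotation = AnnotationConfig(**self.annotation)

    def validate(self) -> None:
        if not self.simulate:
            for name in ("peaks_bed", "counts_tsv", "meta_tsv", "genes_bed"):
                path = getattr(self, name)
                if path is None:
                    raise PipelineConfigError(f"simulate disabled but {name} not set")
                if not Path(path).exists():
                    raise PipelineConfigError(f"input {name}={path!r} does not exist")

    def to_dict(self) -> dict[str, Any]:
        def conv(x: Any) -> Any:
            if dataclasses.is_dataclass(x) and not isinstance(x, type):
                return {k: conv(v) for k, v in dataclasses.asdict(x).items()}
            if isinstance(x, tuple):
                return list(x)
            if isinstance(x, dict):
                return {k: conv(v) for k, v in x.items()}
            return x

        return {f.name: conv(getattr(self, f.name)) for f in dataclasses.fields(self)}

    def config_hash(self) -> str:
        """Hash of the scientific configuration (excludes the output path)."""
        d = self.to_dict()
        d.pop("out_dir", None)
        payload = yaml.safe_dump(d, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineConfigError(f"unknown config keys: {sorted(unknown)}")
        if "sim" in raw and isinstance(raw["sim"], dict) and "stages" in raw["sim"]:
            raw["sim"]["stages"] = tuple(raw["sim"]["stages"])
        return cls(**raw)


def _provenance(cfg: PipelineConfig) -> str:
    return f"# cadkit {__version__} config_hash={cfg.config_hash()} seed={cfg.seed}\n"


def _write_tsv(df: pd.DataFrame, path: Path, cfg: PipelineConfig, index: bool = True) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance(cfg))
        df.to_csv(fh, sep="\t", index=index, float_format="%.6g")


def run_pipeline(cfg: PipelineConfig) -> dict[str, Any]:
    """Execute every stage and write the report bundle to ``out_dir``.

    Returns the report dict (also written as ``report.json``).  A stage
    failure raises :class:`StageError` naming the stage; outputs of
    completed stages are retained.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {
        "version": __version__,
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
    }

    stage = "simulate"
    try:
        if cfg.simulate:
            sim = dataclasses.replace(cfg.sim, seed=cfg.seed)
            peaks = simulate_peaks(sim)
            counts, truth = simulate_timecourse(sim, peaks)
            x, y = simulate_cuttag(sim, peaks, truth)
            expr, genes = simulate_expression(sim, peaks, truth)
            peaks.write_bed(out / "peaks.bed")
            counts.write_tsv(out / "counts_atac.tsv", out / "meta.tsv")
            _write_tsv(truth.peaks, out / "truth_peaks.tsv", cfg)
            _write_tsv(pd.DataFrame({"x": x, "y": y}), out / "density.tsv", cfg)
            _write_tsv(expr, out / "expr.tsv", cfg)
        else:
            peaks = read_peaks(cfg.peaks_bed)
            counts = SignalMatrix.read_tsv(cfg.counts_tsv, cfg.meta_tsv)
            genes = read_genes(cfg.genes_bed)
            truth = None
            x = y = expr = None

        stage = "quantify"
        rpkm = rpkm_normalize(counts, peaks.lengths())
        logm = log_transform(rpkm)

        stage = "classify"
        labels_by_cond: dict[str, pd.DataFrame] = {}
        summaries: dict[str, pd.Series] = {}
        for cond in rpkm.conditions:
            labels, summary = classify_all(rpkm, cfg.cad, cond)
            labels_by_cond[cond] = labels
            summaries[cond] = summary
            _write_tsv(labels, out / f"cad_labels_{cond}.tsv", cfg)
        summary_df = pd.DataFrame(summaries).fillna(0).astype(int)
        summary_df.index.name = "label"
        _write_tsv(summary_df, out / "cad_summary.tsv", cfg)
        report["cad_class_counts"] = {
            c: summaries[c].to_dict() for c in summaries
        }
        if len(labels_by_cond) == 2:
            a, b = list(labels_by_cond)
            shift = class_shift_table(labels_by_cond[a], labels_by_cond[b])
            _write_tsv(shift, out / "cad_class_shift.tsv", cfg)

        stage = "gcr"
        theta = gcr_threshold(logm, cfg.gcr)
        gcr = detect_gcr(logm, cfg.gcr, theta=theta)
        members = peaks.subset(gcr.members) if gcr.members else None
        if members is not None:
            members.write_bed(out / "gcr_regions.bed")
        _write_tsv(gcr.mean_trajectories, out / "gcr_trajectories.tsv", cfg)
        report["gcr"] = {
            "theta": theta,
            "n_members": len(gcr.members),
            "mean_trajectories": {
                c: [round(v, 6) for v in row]
                for c, row in gcr.mean_trajectories.iterrows()
            },
        }

        stage = "compare"
        if cfg.simulate:
            density = classify_density(list(x.index), x.values, y.values, cfg.compare)
            _write_tsv(density, out / "density_classes.tsv", cfg)
            report["density_class_counts"] = (
                density["class"].value_counts().to_dict()
            )
        else:
            density = None

        stage = "som"
        if cfg.simulate:
            z = zscore_rows(expr)
            som_cfg = dataclasses.replace(cfg.som, seed=cfg.seed)
            grid = som_train(z, som_cfg)
            som_labels, som_summary = som_assign(grid, z)
            _write_tsv(som_labels, out / "som_clusters.tsv", cfg)
            _write_tsv(som_summary, out / "som_summary.tsv", cfg)
            report["som_cluster_sizes"] = som_summary["size"].to_dict()
        else:
            som_labels = None

        stage = "annotate"
        annotation = assign_gene_context(peaks, genes, cfg.annotation)
        _write_tsv(annotation, out / "annotation.tsv", cfg, index=False)
        report["annotation_context_counts"] = (
            annotation["context"].value_counts().to_dict()
        )

        stage = "integrate"
        if cfg.simulate and som_labels is not None:
            ref_cond = rpkm.conditions[0]
            region_classes = labels_by_cond[ref_cond]["label"]
            gene_sets = genes_for_region_class(region_classes, annotation)
            expr_groups = som_labels["cluster"]
            universe = {
                g for g in annotation["gene_id"].dropna().unique()
            }
            table = integrate_with_expression(gene_sets, expr_groups, universe)
            _write_tsv(table, out / "integration.tsv", cfg, index=False)
            top = (
                table.dropna(subset=["q"]).sort_values("q").head(5)
                [["region_class", "expr_group", "count", "q"]]
            )
            report["integration_top_cells"] = top.to_dict("records")
    except (PipelineConfigError,):
        raise
    except Exception as exc:
        raise StageError(f"stage {stage!r} failed: {exc}") from exc

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return report
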