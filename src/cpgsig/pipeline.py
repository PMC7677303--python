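"""End-to-end orchestration: simulate/load -> rank -> IFS -> report.

A run is driven by a RunConfig (YAML-loadable) naming either the three input
files or a synthetic-data spec, and writes every intermediate plus a JSON
manifest echoing all parameters actually used, so a run is reproducible from
its manifest alone.  With synthetic input and a fixed seed the outputs are
bit-identical across runs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import __version__, io, mrmr, report
from .ifs import ClassifierConfig, ifs_curve, select_signature_size
from .simulate import SyntheticSpec, generate_dataset, write_truth

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything one pipeline run depends on.

    Exactly one of (matrix_path, labels_path) or synthetic must be given;
    annotation is optional either way.
    """

    out_dir: str = "cpgsig_run"
    matrix_path: str | None = None
    labels_path: str | None = None
    annotation_path: str | None = None
    matrix_dialect: str = "tsv"
    synthetic: SyntheticSpec | None = None
    n_rank: int = 300
    t: float = mrmr.DEFAULT_T
    mi_base: float = mrmr.DEFAULT_BASE
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    max_r: int | None = None  # default min(300, ranking length)
    heatmap: bool = False

    def validate(self) -> None:
        have_files = self.matrix_path is not None or self.labels_path is not None
        if have_files == (self.synthetic is not None):
            raise ValueError("provide either input paths or a synthetic spec, not both")
        if have_files:
            if self.matrix_path is None or self.labels_path is None:
                raise ValueError("both matrix_path and labels_path are required")
            for p in (self.matrix_path, self.labels_path, self.annotation_path):
                if p is not None and not Path(p).exists():
                    raise FileNotFoundError(p)
        if self.n_rank < 1:
            raise ValueError("n_rank must be >= 1")


def config_from_yaml(path: str | Path) -> RunConfig:
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "synthetic" in raw and raw["synthetic"] is not None:
        syn = raw["synthetic"]
        if "n_per_class" in syn:
            syn["n_per_class"] = tuple(syn["n_per_class"])
        if "class_names" in syn:
            syn["class_names"] = tuple(syn["class_names"])
        raw["synthetic"] = SyntheticSpec(**syn)
    if "classifier" in raw and raw["classifier"] is not None:
        raw["classifier"] = ClassifierConfig(**raw["classifier"])
    return RunConfig(**raw)


def _echo_config(config: RunConfig) -> dict:
    out = asdict(config)
    if config.synthetic is not None:
        out["synthetic"] = asdict(config.synthetic)
    out["classifier"] = asdict(config.classifier)
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage in order; return (and write) the run manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "parameters": _echo_config(config),
        "outputs": {},
        "stages_completed": [],
    }
    manifest_path = out / "manifest.json"

    def _fail(stage: str, err: Exception):
        manifest["failed_stage"] = stage
        manifest["error"] = str(err)
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    # --- input -----------------------------------------------------------
    try:
        annotation = None
        if config.synthetic is not None:
            dataset = generate_dataset(config.synthetic)
            matrix, labels = dataset.matrix, dataset.labels
            io.write_beta_matrix(matrix, out / "matrix.tsv")
            io.write_labels(labels, out / "labels.tsv")
            write_truth(dataset, out / "truth.tsv")
            manifest["outputs"]["matrix"] = str(out / "matrix.tsv")
            manifest["outputs"]["labels"] = str(out / "labels.tsv")
            manifest["outputs"]["truth"] = str(out / "truth.tsv")
        else:
            matrix = io.read_beta_matrix(config.matrix_path, dialect=config.matrix_dialect)
            labels = io.read_labels(config.labels_path)
        if config.annotation_path is not None:
            annotation = io.read_annotation(config.annotation_path)
        logger.info("input: %d sites x %d samples, %d classes",
                    matrix.n_sites, matrix.n_samples, labels.n_classes)
        manifest["stages_completed"].append("input")
    except Exception as err:  # noqa: BLE001 - stage boundary
        _fail("input", err)

    # --- rank ------------------------------------------------------------
    try:
        n_rank = min(config.n_rank, matrix.n_sites)
        dmatrix = mrmr.discretize(matrix, t=config.t)
        ranking = mrmr.mrmr_rank(dmatrix, labels, n_rank, base=config.mi_base)
        io.write_ranking(ranking, out / "ranking.tsv")
        manifest["outputs"]["ranking"] = str(out / "ranking.tsv")
        manifest["parameters"]["n_rank_effective"] = n_rank
        manifest["stages_completed"].append("rank")
    except Exception as err:  # noqa: BLE001
        _fail("rank", err)

    # --- ifs -------------------------------------------------------------
    try:
        max_r = config.max_r if config.max_r is not None else min(300, len(ranking))
        max_r = min(max_r, len(ranking))
        curve = ifs_curve(matrix, labels, ranking, max_r, config.classifier)
        io.write_curve(curve, out / "ifs_curve.tsv")
        size = select_signature_size(curve)
        manifest["outputs"]["ifs_curve"] = str(out / "ifs_curve.tsv")
        manifest["signature_size"] = size
        manifest["peak_accuracy"] = curve.points[size - 1][1]
        manifest["parameters"]["max_r_effective"] = max_r
        manifest["stages_completed"].append("ifs")
    except Exception as err:  # noqa: BLE001
        _fail("ifs", err)

    # --- report ----------------------------------------------------------
    try:
        prefix = ranking.top(size)
        annotation = annotation or io.ProbeAnnotation({})
        table = report.annotate_signature(prefix, annotation)
        io.write_signature(table, out / "signature.tsv")
        manifest["outputs"]["signature"] = str(out / "signature.tsv")

        summary = report.class_means(matrix, labels, table.probe_ids)
        summary.means.round(12).to_csv(out / "class_means.tsv", sep="\t",
                                       index_label="probe_id")
        manifest["outputs"]["class_means"] = str(out / "class_means.tsv")

        hyper = {}
        names = labels.class_names
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                a, b = names[i], names[j]
                ca, cb, ties = report.hypermethylation_count(summary, a, b)
                hyper[f"{a}_vs_{b}"] = {"higher_in_" + a: ca, "higher_in_" + b: cb,
                                        "ties": ties}
        (out / "hypermethylation.json").write_text(json.dumps(hyper, indent=2))
        manifest["outputs"]["hypermethylation"] = str(out / "hypermethylation.json")

        sub = matrix.restrict(list(table.probe_ids))
        scaled = report.scale_rows(sub)
        order, _tree = report.cluster_samples(scaled)
        with open(out / "scaled_matrix.tsv", "w") as fh:
            fh.write("probe_id\t" + "\t".join(sub.sample_ids) + "\n")
            for probe, row in zip(sub.probe_ids, scaled):
                fh.write(probe + "\t" + "\t".join("%.12g" % v for v in row) + "\n")
        (out / "sample_order.txt").write_text(
            "\n".join(sub.sample_ids[i] for i in order) + "\n"
        )
        manifest["outputs"]["scaled_matrix"] = str(out / "scaled_matrix.tsv")
        manifest["outputs"]["sample_order"] = str(out / "sample_order.txt")
        if config.heatmap:
            report.plot_heatmap(scaled, sub.probe_ids, sub.sample_ids, order,
                                out / "heatmap.png")
            manifest["outputs"]["heatmap"] = str(out / "heatmap.png")
        manifest["stages_completed"].append("report")
    except Exception as err:  # noqa: BLE001
        _fail("report", err)

    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
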