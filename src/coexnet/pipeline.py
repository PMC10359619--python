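"""End-to-end pipeline with a persistable run configuration.

``RunConfig`` holds every tunable parameter of every stage, the input
paths, the tool version, and the master seed; it round-trips through a
sectioned plain-text (INI) file so a run can be reproduced exactly.
``run_pipeline`` executes preprocess -> network -> modules -> stats and
writes every artifact plus the config snapshot into an output
directory; rerunning the same config on the same inputs reproduces
identical module assignments.
"""

from __future__ import annotations

import configparser
import json
import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

from coexnet.core_data import ExpressionDataset, attach_metadata, read_expression
from coexnet.module_detection import (
    ModuleAssignment,
    cluster_features,
    dynamic_tree_cut,
    merge_close_modules,
)
from coexnet.module_stats import module_trait_correlation
from coexnet.network import DEFAULT_POWERS, build_network
from coexnet.preprocessing import detect_outlier_samples, filter_features

logger = logging.getLogger(__name__)

_SECTIONS = {
    "input": ["expression_path", "sample_meta_path", "orientation", "delimiter"],
    "preprocess": ["min_total_expression", "max_missing_fraction", "sample_cut_height"],
    "network": [
        "power", "network_type", "tom_type", "corr_method",
        "candidate_powers", "fit_cutoff",
    ],
    "modules": ["min_module_size", "deep_split", "pam_stage", "merge_cut_height"],
    "run": ["seed", "version"],
}


@dataclass
class RunConfig:
    # input
    expression_path: str = ""
    sample_meta_path: str = ""
    orientation: str = "samples"
    delimiter: str = ""
    # preprocess
    min_total_expression: float = 1.0
    max_missing_fraction: float = 0.5
    sample_cut_height: float = 0.0  # 0 disables outlier removal
    # network
    power: float = 0.0  # 0 means automatic soft-threshold selection
    network_type: str = "signed"
    tom_type: str = "signed"
    corr_method: str = "pearson"
    candidate_powers: tuple[float, ...] = DEFAULT_POWERS
    fit_cutoff: float = 0.9
    # modules
    min_module_size: int = 30
    deep_split: int = 2
    pam_stage: bool = True
    merge_cut_height: float = 0.25
    # run
    seed: int = 0
    version: str = field(default="")

    def __post_init__(self) -> None:
        if not self.version:
            from coexnet import __version__

            self.version = __version__
        self.candidate_powers = tuple(float(p) for p in self.candidate_powers)

    # -- plain-text persistence -------------------------------------------
    def to_file(self, path: str | Path) -> None:
        cp = configparser.ConfigParser()
        values = asdict(self)
        for section, keys in _SECTIONS.items():
            cp[section] = {}
            for key in keys:
                v = values[key]
                if key == "candidate_powers":
                    v = ",".join(str(x) for x in v)
                cp[section][key] = str(v)
        with open(path, "w") as fh:
            cp.write(fh)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"config file not found: {path}")
        cp = configparser.ConfigParser()
        cp.read(path)
        kwargs: dict = {}
        types = {f.name: f.type for f in fields(cls)}
        for section, keys in _SECTIONS.items():
            for key in keys:
                if not cp.has_option(section, key):
                    continue
                raw = cp.get(section, key)
                t = types[key]
                if key == "candidate_powers":
                    kwargs[key] = tuple(float(x) for x in raw.split(",") if x.strip())
                elif t == "bool":
                    kwargs[key] = raw.strip().lower() in ("1", "true", "yes", "on")
                elif t == "int":
                    kwargs[key] = int(raw)
                elif t == "float":
                    kwargs[key] = float(raw)
                else:
                    kwargs[key] = raw
        return cls(**kwargs)


@dataclass
class PipelineResult:
    dataset: ExpressionDataset
    assignment: ModuleAssignment
    n_modules: int
    out_dir: Path | None


def run_pipeline(
    config: RunConfig,
    out_dir: str | Path | None = None,
    dataset: ExpressionDataset | None = None,
) -> PipelineResult:
    """Execute preprocess -> network -> modules -> stats.

    A dataset may be passed directly (e.g. from the simulator) instead
    of being read from ``config.expression_path``. Every stage failure
    is re-raised with the stage name and a remediation hint.
    """
    out = None
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        config.to_file(out / "run_config.ini")

    def stage(name: str, hint: str):
        def decorate(fn):
            try:
                return fn()
            except Exception as exc:  # noqa: BLE001 - annotate and re-raise
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc} ({hint})") from exc

        return decorate

    if dataset is None:
        if not config.expression_path:
            raise FileNotFoundError("no expression input: set expression_path or pass a dataset")
        dataset = stage("ingest", "check input paths and orientation")(
            lambda: read_expression(
                config.expression_path,
                orientation=config.orientation,  # type: ignore[arg-type]
                delimiter=config.delimiter or None,
            )
        )
        if config.sample_meta_path:
            import pandas as pd

            meta = pd.read_csv(
                config.sample_meta_path,
                sep="\t" if config.sample_meta_path.endswith(".tsv") else ",",
                index_col=0,
            )
            dataset = attach_metadata(dataset, meta, axis="sample")

    def do_preprocess():
        ds, report = filter_features(
            dataset, config.min_total_expression, config.max_missing_fraction
        )
        if config.sample_cut_height > 0:
            ds, sample_report = detect_outlier_samples(ds, config.sample_cut_height)
            report.removed_sample_ids = sample_report.removed_sample_ids
            report.thresholds_used.update(sample_report.thresholds_used)
        return ds, report

    ds, qc_report = stage("preprocess", "relax QC thresholds")(do_preprocess)

    net = stage("network", "check for missing values or zero-variance features")(
        lambda: build_network(
            ds,
            power=config.power if config.power > 0 else None,
            network_type=config.network_type,  # type: ignore[arg-type]
            tom_type=config.tom_type,  # type: ignore[arg-type]
            corr_method=config.corr_method,  # type: ignore[arg-type]
            candidate_powers=config.candidate_powers,
            fit_cutoff=config.fit_cutoff,
        )
    )

    def do_modules():
        diss = net.tom_dissimilarity
        Z = cluster_features(diss)
        assignment = dynamic_tree_cut(
            Z,
            diss,
            min_module_size=config.min_module_size,
            deep_split=config.deep_split,
            pam_stage=config.pam_stage,
            feature_ids=ds.feature_ids,
        )
        if assignment.n_modules > 1 and config.merge_cut_height > 0:
            assignment, eig = merge_close_modules(ds, assignment, config.merge_cut_height)
        elif assignment.n_modules >= 1:
            from coexnet.module_detection import compute_eigengenes

            eig = compute_eigengenes(ds, assignment)
        else:
            eig = None
        return assignment, eig

    assignment, eig = stage("modules", "lower min_module_size or raise deep_split")(do_modules)

    trait_table = None
    if eig is not None and ds.sample_meta.shape[1] > 0 and ds.n_samples >= 3:
        trait_table = stage("stats", "check trait columns")(
            lambda: module_trait_correlation(eig, ds.sample_meta)
        )

    if out is not None:
        (out / "qc_report.txt").write_text(qc_report.summary() + "\n")
        if net.soft_threshold is not None:
            net.soft_threshold.table.to_csv(out / "soft_threshold.tsv", sep="\t", index=False)
        (out / "network_params.json").write_text(
            json.dumps(
                {
                    "power": net.power,
                    "network_type": net.network_type,
                    "tom_type": net.tom_type,
                },
                indent=2,
            )
            + "\n"
        )
        assignment.to_tsv(out / "module_assignment.tsv")
        if eig is not None:
            eig.to_tsv(out / "eigengenes.tsv")
        if trait_table is not None:
            trait_table.table.to_csv(out / "module_trait_correlation.tsv", sep="\t", index=False)
        logger.info("pipeline artifacts written to %s", out)

    return PipelineResult(
        dataset=ds,
        assignment=assignment,
        n_modules=assignment.n_modules,
        out_dir=out,
    )
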