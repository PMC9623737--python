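"""Config-driven orchestration with a machine-readable report.

``run_pipeline`` reads a YAML config (paths plus per-stage parameters with an
explicit seed per stochastic stage), runs the full analysis through
``PANoptosisModel``, writes every stage's table under the output directory and
emits a schema-checked JSON report with file checksums, so each stage is
re-runnable from its written intermediates.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import yaml

from . import evaluation, io
from .datatypes import ExpressionMatrix
from .model import PANoptosisModel, PipelineParams

logger = logging.getLogger("panoptikit")

REPORT_REQUIRED_KEYS = (
    "version", "config_hash", "seed", "cohort", "chosen_k", "comparison",
    "screened_in", "top_genes", "files",
)


@dataclasses.dataclass
class PipelineConfig:
    expression_path: str
    clinical_path: str
    output_dir: str
    signature_path: str | None = None
    roles_path: str | None = None
    normals_path: str | None = None
    external_cohorts: list = dataclasses.field(default_factory=list)
    cohort: str = "cohort"
    seed: int = 0
    params: PipelineParams = dataclasses.field(default_factory=PipelineParams)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        pkeys = {f.name for f in dataclasses.fields(PipelineParams)}
        params = PipelineParams(**{k: v for k, v in raw.get("params", {}).items() if k in pkeys})
        if "rfs_grid" in raw.get("params", {}):
            params.rfs_grid = tuple(dict(g) for g in raw["params"]["rfs_grid"])
        cfg = cls(
            expression_path=raw["expression_path"],
            clinical_path=raw["clinical_path"],
            output_dir=raw["output_dir"],
            signature_path=raw.get("signature_path"),
            roles_path=raw.get("roles_path"),
            normals_path=raw.get("normals_path"),
            external_cohorts=raw.get("external_cohorts", []),
            cohort=raw.get("cohort", "cohort"),
            seed=int(raw.get("seed", 0)),
            params=params,
        )
        for p in (cfg.expression_path, cfg.clinical_path, cfg.signature_path,
                  cfg.normals_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"configured path does not exist: {p}")
        for ext in cfg.external_cohorts:
            for key in ("expression_path", "clinical_path"):
                if not Path(ext[key]).exists():
                    raise FileNotFoundError(f"external cohort path missing: {ext[key]}")
        return cfg

    def hash(self) -> str:
        payload = dataclasses.asdict(self)
        payload["params"] = self.params.asdict()
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage in order and write the report bundle."""
    from . import __version__

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "pipeline.log")
    logger.addHandler(handler)
    try:
        logger.info("loading inputs for cohort %s", config.cohort)
        model = PANoptosisModel.from_files(
            config.expression_path,
            config.clinical_path,
            signature_path=config.signature_path,
            roles_path=config.roles_path,
            normals_path=config.normals_path,
            params=config.params,
            cohort=config.cohort,
        )
        logger.info("fitting (seed=%d)", config.seed)
        res = model.fit(seed=config.seed)

        files: dict[str, str] = {}

        def _write(name: str, writer) -> None:
            path = out / name
            writer(path)
            files[name] = _sha256(path)

        _write("consensus.tsv", lambda p: res.consensus.consensus.to_csv(p, sep="\t"))
        labels = res.consensus.labels.to_frame()
        labels["stratum"] = res.strata
        _write("labels.tsv", lambda p: labels.rename_axis("sample_id").to_csv(p, sep="\t"))
        _write(
            "scores.tsv",
            lambda p: res.score.scores.rename_axis("sample_id").to_frame("es").to_csv(p, sep="\t"),
        )
        comp = res.comparison
        comp_row = {
            "cohort": comp.cohort, "N1": comp.n_high, "N2": comp.n_low,
            "events_high": comp.events_high, "events_low": comp.events_low,
            "HR": comp.hr, "ci_lower": comp.ci_lower, "ci_upper": comp.ci_upper,
            "p_logrank": comp.p_logrank, "p_wald": comp.p_wald,
        }
        import pandas as pd

        _write("comparison.tsv", lambda p: pd.DataFrame([comp_row]).to_csv(p, sep="\t", index=False))
        if res.marker_class is not None:
            _write(
                "marker_class.tsv",
                lambda p: res.marker_class.rename_axis("gene").to_frame().to_csv(p, sep="\t"),
            )
            for key, de in res.de_results.items():
                _write(f"de_{key}.tsv", lambda p, de=de: de.table.to_csv(p, sep="\t", index=False))
        _write("univariate.tsv", lambda p: res.univariate.to_csv(p, sep="\t", index=False))
        _write("stability.tsv", lambda p: res.stability.table.to_csv(p, sep="\t", index=False))
        _write("vimp.tsv", lambda p: res.vimp.table.to_csv(p, sep="\t", index=False))
        top_payload = {
            "genes": res.top.genes,
            "direction": res.top.direction,
        }
        _write("top_genes.json", lambda p: p.write_text(json.dumps(top_payload, indent=2)))

        validations = []
        if res.internal_validation is not None:
            validations.append(dataclasses.asdict(res.internal_validation))
        for ext in config.external_cohorts:
            if res.final_model is None:
                break
            expr = io.read_expression(ext["expression_path"])
            surv = io.read_clinical(ext["clinical_path"])
            expr = ExpressionMatrix(
                expr.data[[s for s in expr.sample_ids if s in set(surv.sample_ids)]]
            )
            surv = surv.aligned_to(expr.sample_ids)
            rep = evaluation.validate_external(
                res.final_model, expr, surv,
                times_years=config.params.validation_times_years,
                cohort_id=ext.get("name", "external"),
            )
            validations.append(dataclasses.asdict(rep))
        _write(
            "validation.json",
            lambda p: p.write_text(json.dumps(validations, indent=2, default=float)),
        )

        report = {
            "version": __version__,
            "config_hash": config.hash(),
            "seed": config.seed,
            "cohort": config.cohort,
            "chosen_k": int(res.chosen_k),
            "comparison": {k: (float(v) if isinstance(v, (int, float, np.floating)) else v)
                           for k, v in comp_row.items()},
            "screened_in": bool(res.screened_in),
            "top_genes": res.top.genes,
            "validations": validations,
            "files": files,
        }
        write_report(report, out / "report.json")
        logger.info("pipeline complete; report at %s", out / "report.json")
        return report
    finally:
        logger.removeHandler(handler)
        handler.close()


def write_report(report: dict, path) -> None:
    """Schema-check and serialize the pipeline report."""
    missing = [k for k in REPORT_REQUIRED_KEYS if k not in report]
    if missing:
        raise ValueError(f"report missing required keys: {missing}")
    Path(path).write_text(json.dumps(report, indent=2, default=float) + "\n")


def read_report(path) -> dict:
    return json.loads(Path(path).read_text())
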