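"""Pipeline orchestration with a reproducibility manifest.

``run_pipeline`` executes the analysis stages in dependency order from a
JSON-able config: screening summary (packaged fixture, a CSV, or the
synthetic generator), EEO-reversal reports, thermodynamic parameter
recovery on synthetic series, hysteresis-loop inference, multivariate
comparison with representative-set selection, and (optionally) the
cross-validated ML stage.  Every stage is a pure function of declared
inputs and seeds; the manifest records the config hash, package version,
seeds, input digests and per-stage status so that identical configs
reproduce identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .dataio import load_table1, read_screening_csv, write_tidy_results
from .hysteresis import detect_hysteresis, infer_loop, read_loop_csv
from .metrics import detect_eeo_reversals, screening_summary
from .mlmodel import crossvalidate, preprocess_features
from .multivariate import (
    build_feature_matrix,
    hierarchical_cluster,
    pairwise_correlation,
    pca,
    select_representative_set,
)
from .synthgen import SynthConfig, gen_hysteresis_loop, gen_vant_hoff_series
from .thermo import enantio_thermo

logger = logging.getLogger("enantiosep")

__all__ = ["RunManifest", "run_pipeline"]


def _digest(obj) -> str:
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def _file_digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    package_version: str
    seed: int
    input_digests: dict[str, str] = field(default_factory=dict)
    stages: dict[str, dict] = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "config_hash": self.config_hash,
            "package_version": self.package_version,
            "seed": self.seed,
            "input_digests": self.input_digests,
            "stages": self.stages,
        }


def run_pipeline(config: dict | str | Path, out_dir: str | Path | None = None) -> RunManifest:
    """Run the configured stages; optional stages fail soft (logged, not fatal).

    Config keys (all optional except ``screening``):
      screening: "fixture" | {"csv": path} | {"synthetic": SynthConfig kwargs}
      eeo_axes: list of reversal axes to report
      thermo: {"synthetic": SynthConfig kwargs} — parameter-recovery stage
      hysteresis: {"csv": path} | {"synthetic": SynthConfig kwargs}
      multivariate: {"k": int, "linkage": str}
      ml: {"model": name, "folds": int, "repeats": int}
      seed: master seed
    """
    if not isinstance(config, dict):
        config_path = Path(config)
        config = json.loads(config_path.read_text())
    if "screening" not in config:
        raise ValueError("config must declare the 'screening' stage input")
    seed = int(config.get("seed", 0))
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config_hash=_digest(config), package_version=__version__, seed=seed
    )

    def record(stage: str, status: str, outputs: dict | None = None, error: str | None = None):
        manifest.stages[stage] = {
            "status": status,
            "outputs": outputs or {},
            **({"error": error} if error else {}),
        }

    def save(stage: str, name: str, obj) -> dict:
        if out_dir is None:
            return {}
        path = out_dir / name
        write_tidy_results(obj, path)
        return {name: str(path)}

    t_start = time.perf_counter()

    # --- screening ---------------------------------------------------
    spec = config["screening"]
    if spec == "fixture":
        table = load_table1()
        manifest.input_digests["screening"] = "packaged-fixture"
    elif isinstance(spec, dict) and "csv" in spec:
        path = Path(spec["csv"])
        if not path.exists():
            raise FileNotFoundError(f"screening stage: input {path} not found")
        manifest.input_digests["screening"] = _file_digest(path)
        table = read_screening_csv(path)
    elif isinstance(spec, dict) and "synthetic" in spec:
        from .synthgen import gen_screening_table

        cfg = SynthConfig(seed=seed, **spec["synthetic"])
        table, _ = gen_screening_table(cfg)
        manifest.input_digests["screening"] = _digest(spec["synthetic"])
    else:
        raise ValueError(f"unrecognized screening input {spec!r}")
    summary = screening_summary(table, config.get("baseline_threshold", 1.5))
    outputs = save("screening", "screening_summary.json", summary)
    record("screening", "ok", outputs)
    logger.info(
        "screening: %d/%d separated (%.1f%%)",
        summary.n_separated, summary.n_total, summary.success_rate,
    )

    # --- EEO reversals -----------------------------------------------
    for axis in config.get("eeo_axes", []):
        report = detect_eeo_reversals(table, axis)
        outputs = save("eeo_" + axis, f"eeo_reversals_{axis}.json", report)
        record(f"eeo_{axis}", "ok", outputs)

    # --- thermodynamics (synthetic recovery) -------------------------
    if "thermo" in config:
        try:
            cfg = SynthConfig(seed=seed + 1, **config["thermo"].get("synthetic", {}))
            series, truth = gen_vant_hoff_series(cfg)
            th = enantio_thermo(series)
            payload = {"fit": th.to_json_dict(), "truth": truth.params}
            outputs = save("thermo", "thermo_recovery.json", payload)
            record("thermo", "ok", outputs)
        except Exception as exc:  # optional stage: log, do not abort
            logger.warning("thermo stage failed: %s", exc)
            record("thermo", "failed", error=str(exc))

    # --- hysteresis ---------------------------------------------------
    if "hysteresis" in config:
        try:
            spec = config["hysteresis"]
            if "csv" in spec:
                loop = read_loop_csv(spec["csv"])
                manifest.input_digests["hysteresis"] = _file_digest(Path(spec["csv"]))
            else:
                cfg = SynthConfig(seed=seed + 2, **spec.get("synthetic", {}))
                loop, _ = gen_hysteresis_loop(cfg)
            present, _flags = detect_hysteresis(loop, spec.get("threshold", 0.05))
            inference = infer_loop(loop)
            payload = {
                "hysteresis_present": present,
                "all_consistent": inference.all_consistent,
            }
            outputs = save("hysteresis", "hysteresis_inference.json", payload)
            record("hysteresis", "ok", outputs)
        except Exception as exc:
            logger.warning("hysteresis stage failed: %s", exc)
            record("hysteresis", "failed", error=str(exc))

    # --- multivariate -------------------------------------------------
    if "multivariate" in config:
        mv = config["multivariate"]
        fm = build_feature_matrix(table)
        corr = pairwise_correlation(fm)
        k = int(mv.get("k", 5))
        clus = hierarchical_cluster(fm, linkage=mv.get("linkage", "complete"), k=k)
        pc = pca(fm)
        sel = select_representative_set(clus, pc, k=k)
        payload = {
            "selected_systems": sel.selected,
            "explained_variance_ratio": pc.explained_variance_ratio.tolist(),
        }
        outputs = save("multivariate", "multivariate_selection.json", payload)
        if out_dir is not None:
            corr.r.to_csv(out_dir / "correlation_matrix.csv")
            outputs["correlation_matrix.csv"] = str(out_dir / "correlation_matrix.csv")
        record("multivariate", "ok", outputs)

    # --- ML -----------------------------------------------------------
    if "ml" in config:
        try:
            ml = config["ml"]
            fm = build_feature_matrix(table)
            long = (
                fm.data.reset_index(names="system")
                .melt(id_vars="system", var_name="feature", value_name="dirRs")
            )
            long[["csp", "eluent"]] = long["system"].str.split("-", n=1, expand=True)
            long["analyte"] = long["feature"].str.replace("dirRs_", "", regex=False)
            raw = long[["csp", "eluent", "analyte"]]
            y = long["dirRs"].fillna(0.0)
            data = preprocess_features(raw, y)
            cv = crossvalidate(
                data,
                model=ml.get("model", "random_forest"),
                folds=int(ml.get("folds", 3)),
                repeats=int(ml.get("repeats", 5)),
                seed=seed,
            )
            outputs = save("ml", "cv_result.json", cv)
            record("ml", "ok", outputs)
        except Exception as exc:
            logger.warning("ml stage failed: %s", exc)
            record("ml", "failed", error=str(exc))

    logger.info("pipeline finished in %.2f s", time.perf_counter() - t_start)
    if out_dir is not None:
        write_tidy_results(manifest, out_dir / "manifest.json")
    return manifest
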