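"""Dataset reading/validation, run configuration and the end-to-end pipeline.

A run is described by a small YAML/JSON config:

.. code-block:: yaml

    dataset: data.csv
    response: smoker
    modifier: wave
    n_waves: 55
    covariates:
      age: {levels: ["60-69", "18-29", ...], reference: "60-69"}
      ...
    model: {k: 55, degree: 3, penalty_order: 2, lambda_method: gcv, alpha: 0.05}
    seed: 7
    outdir: results/

The pipeline screens every covariate for time-varying coefficients,
forward-selects the varying terms, writes a screening table, a selection
trace, a final-model summary and one odds-ratio curve file per varying
non-reference category.  All outputs are stamped with the config hash and
seed so a rerun with the same config reproduces them exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from .basis import BasisSpec
from .exceptions import SchemaError
from .fit import TermSpec, VCMSpec
from .inference import summary_table
from .orcurves import ReferenceLevelError, or_curve
from .selection import forward_select, screen_varying

logger = logging.getLogger("tvcm")

__all__ = ["read_dataset", "load_config", "base_spec_from_config", "run_pipeline"]


def read_dataset(path, schema: dict) -> pd.DataFrame:
    """Read and validate a long-format respondent table.

    ``schema`` declares ``response``, ``modifier``, ``n_waves`` and
    ``covariates`` (name -> {levels, reference}).  Categorical levels are
    validated against the declaration, wave indices against
    ``[1, n_waves]``; rows with missing values are dropped with a logged
    count (listwise deletion).
    """
    frame = pd.read_csv(path)
    needed = [schema["response"], schema["modifier"], *schema["covariates"]]
    missing = [c for c in needed if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing columns in {path}: {missing}")

    n0 = len(frame)
    frame = frame.dropna(subset=needed).reset_index(drop=True)
    if len(frame) < n0:
        logger.info("dropped %d rows with missing values (of %d)",
                    n0 - len(frame), n0)

    for name, decl in schema["covariates"].items():
        levels = list(decl["levels"])
        observed = set(frame[name].astype(str))
        unknown = sorted(observed - set(levels))
        if unknown:
            raise SchemaError(
                f"column {name!r} has undeclared levels: {unknown}"
            )
        ref = decl.get("reference", levels[0])
        order = [ref] + [l for l in levels if l != ref]
        frame[name] = pd.Categorical(frame[name].astype(str), categories=order)

    waves = pd.to_numeric(frame[schema["modifier"]], errors="coerce")
    n_waves = int(schema.get("n_waves", int(waves.max())))
    bad = waves.isna() | (waves < 1) | (waves > n_waves)
    if bad.any():
        raise SchemaError(
            f"{int(bad.sum())} rows have wave indices outside [1, {n_waves}]"
        )
    frame[schema["modifier"]] = waves.astype(float)

    y = pd.to_numeric(frame[schema["response"]], errors="coerce")
    if y.isna().any() or not y.isin([0, 1]).all():
        raise SchemaError(f"response {schema['response']!r} must be coded 0/1")
    frame[schema["response"]] = y.astype(int)
    logger.info("read %d rows, %d waves", len(frame), frame[schema["modifier"]].nunique())
    return frame


def load_config(path) -> dict:
    text = Path(path).read_text()
    if str(path).endswith((".yml", ".yaml")):
        return yaml.safe_load(text)
    return json.loads(text)


def base_spec_from_config(config: dict) -> VCMSpec:
    """All-constant logistic model spec from a run config."""
    model = config.get("model", {})
    k = int(model.get("k", 55))
    degree = int(model.get("degree", 3))
    order = int(model.get("penalty_order", 2))
    n_waves = int(config.get("n_waves", 55))
    terms = tuple(
        TermSpec(name, "constant", decl.get("reference"))
        for name, decl in config["covariates"].items()
    )
    return VCMSpec(
        response=config["response"], family="binomial", terms=terms,
        modifier=config["modifier"],
        basis=BasisSpec(n_basis=k, degree=degree, domain=(1.0, float(n_waves))),
        penalty_order=order,
    )


def _config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def run_pipeline(config, outdir=None) -> dict:
    """Screen, forward-select and export odds-ratio curves.

    ``config`` is a dict or a path to YAML/JSON.  Returns a dict of output
    paths plus the final fit and trace objects.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    outdir = Path(outdir if outdir is not None else config.get("outdir", "."))
    outdir.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": _config_hash(config),
             "seed": config.get("seed")}

    model = config.get("model", {})
    alpha = float(model.get("alpha", 0.05))
    lambda_method = str(model.get("lambda_method", "gcv"))

    data = read_dataset(config["dataset"], config)
    spec = base_spec_from_config(config)

    logger.info("screening %d candidates", len(spec.terms) + 1)
    screened = screen_varying(data, spec, alpha=alpha,
                              lambda_method=lambda_method)
    screen_path = outdir / "screening.csv"
    screened.to_csv(screen_path, index=False)

    final_fit, trace = forward_select(data, spec, screened, alpha=alpha,
                                      lambda_method=lambda_method)
    trace_frame = trace.to_frame()
    trace_path = outdir / "selection_trace.csv"
    trace_frame.to_csv(trace_path, index=False)
    trace_json = outdir / "selection_trace.json"
    trace_json.write_text(json.dumps(
        {**stamp, "steps": trace.steps}, indent=2, default=float
    ))

    summary = summary_table(final_fit)
    summary_path = outdir / "final_model_summary.csv"
    summary.to_csv(summary_path, index=False)

    curve_paths = []
    for block in final_fit.design.blocks:
        if block.variable is None:
            continue
        try:
            curve = or_curve(final_fit, block.variable, block.level)
        except ReferenceLevelError:
            continue
        safe = f"{block.variable}_{block.level}".replace(" ", "_").replace("/", "-")
        cpath = outdir / f"or_curve_{safe}.csv"
        curve.to_frame().to_csv(cpath, index=False)
        curve_paths.append(cpath)

    manifest = {
        **stamp,
        "screening": str(screen_path),
        "trace": str(trace_path),
        "summary": str(summary_path),
        "or_curves": [str(p) for p in curve_paths],
        "final_model": final_fit.model_id(),
        "final_aic": final_fit.aic,
        "final_edf": final_fit.edf_total,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    logger.info("final model: %s (AIC %.1f, edf %.2f)",
                final_fit.model_id(), final_fit.aic, final_fit.edf_total)
    return {**manifest, "fit": final_fit, "trace_obj": trace,
            "screening_table": screened}
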