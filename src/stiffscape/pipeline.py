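"""End-to-end pipeline runs from a single YAML/JSON config.

A run is an ordered list of stages sharing a context: simulated or
loaded probe matrices flow into gene calling, dependence assessment and
cross-stimulus comparison; simulated or loaded force curves flow into
Hertz fitting and region aggregation; images into the measurement
stage. Every stage logs to stderr, outputs carry the run seed and
parameters, and the final JSON report is deterministic for a fixed seed
(modulo its timestamp field).
"""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import afm, imaging, io, synthetic, transcriptome as tx

logger = logging.getLogger("stiffscape")

PAPER_DEFAULTS = {"floor": 5.0, "threshold": 0.5, "min_probes": 3,
                  "poisson_ratio": 0.5, "edge_angle_deg": 25.0}


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Declarative description of a pipeline run."""

    stages: list
    seed: int = 0
    out_dir: str = "stiffscape_out"
    params: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigError("run config must be a mapping")
        stages = raw.get("stages", [])
        if not isinstance(stages, list):
            raise ConfigError("'stages' must be a list")
        return cls(stages=stages, seed=int(raw.get("seed", 0)),
                   out_dir=str(raw.get("out_dir", "stiffscape_out")),
                   params=dict(raw.get("params", {})))


def _stage_simulate_array(params, ctx, seed, out):
    cfg_kwargs = dict(params.get("config", {}))
    cfg_kwargs.setdefault("seed", seed)
    cfg = synthetic.ArraySimConfig(**cfg_kwargs)
    design = params.get("design", "stiffness_4arm")
    matrix, truth = synthetic.gen_probe_matrix(cfg, design=design)
    key = params.get("as", "array")
    ctx[f"matrix:{key}"] = matrix
    ctx[f"truth:{key}"] = truth
    io.write_probe_matrix(matrix, out / f"{key}_matrix.tsv", out / f"{key}_design.tsv")
    io.write_json(truth.to_dict(), out / f"{key}_truth.json")
    return {"n_probes": int(matrix.values.shape[0]),
            "n_samples": int(matrix.values.shape[1]),
            "n_planted_up": len(truth.up_genes),
            "n_planted_down": len(truth.down_genes)}


def _get_matrix(params, ctx):
    key = params.get("matrix", "array")
    mkey = f"matrix:{key}"
    if mkey in ctx:
        return ctx[mkey], key
    if "matrix_path" in params:
        m = io.read_probe_matrix(params["matrix_path"], params["design_path"])
        ctx[mkey] = m
        return m, key
    raise ConfigError(f"no matrix {key!r} in context and no matrix_path given")


def _stage_call_genes(params, ctx, seed, out):
    matrix, key = _get_matrix(params, ctx)
    model = tx.StiffnessResponseModel(
        matrix,
        floor=params.get("floor", PAPER_DEFAULTS["floor"]),
        threshold=params.get("threshold", PAPER_DEFAULTS["threshold"]),
        min_probes=params.get("min_probes", PAPER_DEFAULTS["min_probes"]))
    cond_a = params.get("cond_a", "ctrl-stiff")
    cond_b = params.get("cond_b", "ctrl-soft")
    res = model.fit(cond_a, cond_b)
    ctx[f"model:{key}"] = model
    ctx[f"calls:{key}"] = res
    res.to_frame().to_csv(out / f"{key}_gene_calls.tsv", sep="\t", index=False)
    return {"contrast": f"{cond_a} vs {cond_b}",
            "n_regulated": res.n_regulated,
            "n_up": len(res.up_genes), "n_down": len(res.down_genes),
            "n_bidirectional": len(res.bidirectional_genes),
            "bidirectional_fraction": res.bidirectional_fraction}


def _stage_dependence(params, ctx, seed, out):
    key = params.get("matrix", "array")
    model = ctx.get(f"model:{key}")
    calls = ctx.get(f"calls:{key}")
    if model is None or calls is None:
        raise ConfigError("dependence stage requires a prior call_genes stage")
    dep = model.assess_dependence(calls, params.get("cond_a", "ctrl-soft"),
                                  params.get("cond_b", "kd-soft"))
    ctx[f"dependence:{key}"] = dep
    dep.to_csv(out / f"{key}_dependence.tsv", sep="\t", index=False)
    n_dep = dep.loc[dep.dependent]
    return {"n_assessed": int(dep.assessable.sum()),
            "n_dependent": int(dep.dependent.sum()),
            "n_dependent_up": int((n_dep.status == "up").sum()),
            "n_dependent_down": int((n_dep.status == "down").sum())}


def _stage_flat_filter(params, ctx, seed, out):
    matrix, key = _get_matrix(params, ctx)
    up, down = tx.apply_flat_filter(
        matrix, params.get("cond_a", "static"), params.get("cond_b", "OSS"),
        floor=params.get("floor", PAPER_DEFAULTS["floor"]),
        threshold=params.get("threshold", PAPER_DEFAULTS["threshold"]))
    ctx[f"flat:{key}"] = (up, down)
    io.write_json({"up": sorted(up), "down": sorted(down)},
                  out / f"{key}_flat_calls.json")
    return {"n_up": len(up), "n_down": len(down)}


def _stage_compare(params, ctx, seed, out):
    key_a, key_b = params.get("a", "array"), params.get("b", "oss")
    ca = ctx.get(f"calls:{key_a}")
    if ca is not None:
        a_up, a_down = ca.up_genes, ca.down_genes
    elif f"flat:{key_a}" in ctx:
        a_up, a_down = ctx[f"flat:{key_a}"]
    else:
        raise ConfigError(f"no calls for {key_a!r}")
    cb = ctx.get(f"calls:{key_b}")
    if cb is not None:
        b_up, b_down = cb.up_genes, cb.down_genes
    elif f"flat:{key_b}" in ctx:
        b_up, b_down = ctx[f"flat:{key_b}"]
    else:
        raise ConfigError(f"no calls for {key_b!r}")
    id_map = None
    if "id_map_path" in params:
        import pandas as pd

        mp = pd.read_csv(params["id_map_path"], sep="\t")
        id_map = dict(zip(mp.iloc[:, 0].astype(str), mp.iloc[:, 1].astype(str)))
    ov = tx.cross_stimulus_overlap(a_up, a_down, b_up, b_down, id_map=id_map)
    io.write_json(ov.to_dict(), out / f"overlap_{key_a}_{key_b}.json")
    return ov.to_dict()


def _stage_simulate_curves(params, ctx, seed, out):
    regions = params.get("regions", {"CV": 3.6, "outside": 0.27})
    n_per_region = int(params.get("n_per_region", 10))
    base = dict(params.get("config", {}))
    curves, labels = [], []
    i = 0
    for region, modulus in regions.items():
        for _ in range(n_per_region):
            cfg = synthetic.CurveSimConfig(
                **{**base, "true_modulus_kPa": float(modulus),
                   "seed": seed + 1000 + i})
            curves.append(synthetic.gen_force_curve(cfg))
            labels.append(region)
            i += 1
    ctx["curves"] = curves
    ctx["curve_regions"] = labels
    return {"n_curves": len(curves), "regions": {k: float(v)
                                                 for k, v in regions.items()}}


def _stage_afm_fit(params, ctx, seed, out):
    curves = ctx.get("curves")
    if curves is None:
        raise ConfigError("afm_fit requires curves (simulate_curves or curve files)")
    fit_params = afm.FitParams(**params.get("fit_params", {}))
    fits = [afm.fit_hertz_pyramid(afm.preprocess_curve(c, fit_params), fit_params)
            for c in curves]
    ctx["fits"] = fits
    import pandas as pd

    pd.DataFrame([vars(f) for f in fits]).to_csv(out / "hertz_fits.tsv",
                                                 sep="\t", index=False)
    return {"n_fits": len(fits),
            "n_converged": sum(f.converged for f in fits)}


def _stage_afm_aggregate(params, ctx, seed, out):
    fits, regions = ctx.get("fits"), ctx.get("curve_regions")
    if fits is None or regions is None:
        raise ConfigError("afm_aggregate requires a prior afm_fit stage")
    stats, fold = afm.aggregate_region(fits, regions)
    payload = {r: s.to_dict() for r, s in stats.items()}
    payload["fold"] = fold
    io.write_json(payload, out / "region_stats.json")
    return payload


def _stage_simulate_images(params, ctx, seed, out):
    cfg_kwargs = dict(params.get("config", {}))
    cfg_kwargs.setdefault("seed", seed)
    img = synthetic.gen_image(synthetic.ImageSimConfig(**cfg_kwargs))
    ctx["image"] = img
    if params.get("write", False):
        io.write_image(img, out, stem=params.get("as", "sim"))
    return {"n_cells": int(len(img.truth.get("objects", [])))}


def _stage_quantify(params, ctx, seed, out):
    img = ctx.get("image")
    if img is None:
        raise ConfigError("quantify requires an image (simulate_images or files)")
    channel = img.channels[params.get("channel", "intensity")]
    measures = params.get("measures", ["ctcf", "circularity", "nuccyt"])
    report = {}
    if "ctcf" in measures:
        vals = imaging.ctcf(channel, img.masks["cell"], img.masks["background"])
        report["ctcf"] = {str(k): float(v) for k, v in vals.items()}
    if "circularity" in measures:
        circ = {}
        for lab in np.unique(img.masks["nucleus"]):
            if lab > 0:
                v, _ = imaging.circularity(img.masks["nucleus"], int(lab))
                circ[str(int(lab))] = v
        report["nuclear_circularity"] = circ
    if "nuccyt" in measures:
        nuc, cyto = imaging.nuclear_cytoplasmic_split(
            channel, img.masks["cell"], img.masks["nucleus"])
        report["nuclear_mean"] = nuc
        report["cytoplasmic_mean"] = cyto
    io.write_json(report, out / "image_measures.json")
    return report


_STAGES = {
    "simulate_array": _stage_simulate_array,
    "call_genes": _stage_call_genes,
    "dependence": _stage_dependence,
    "flat_filter": _stage_flat_filter,
    "compare": _stage_compare,
    "simulate_curves": _stage_simulate_curves,
    "afm_fit": _stage_afm_fit,
    "afm_aggregate": _stage_afm_aggregate,
    "simulate_images": _stage_simulate_images,
    "quantify": _stage_quantify,
}


def run(config: RunConfig) -> dict:
    """Execute the configured stages in order and write the run report.

    Returns the report dict. A stage failure raises :class:`StageError`
    after retaining partial outputs next to a FAILED marker file.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not logger.handlers:
        h = logging.StreamHandler(sys.stderr)
        h.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
        logger.addHandler(h)
        logger.setLevel(logging.INFO)
    ctx: dict = {}
    report: dict = {"seed": config.seed, "stages": [],
                    "params": config.params, "timestamp": time.time()}
    for block in config.stages:
        if isinstance(block, str):
            block = {"stage": block}
        name = block.get("stage")
        if name not in _STAGES:
            raise ConfigError(f"unknown stage {name!r}")
        params = {k: v for k, v in block.items() if k != "stage"}
        t0 = time.perf_counter()
        logger.info("stage %s starting", name)
        try:
            result = _STAGES[name](params, ctx, config.seed, out)
        except Exception as exc:
            (out / "FAILED").write_text(f"stage {name} failed: {exc}\n")
            write_report(report, out)
            raise StageError(name, exc) from exc
        dt = time.perf_counter() - t0
        logger.info("stage %s done in %.2fs", name, dt)
        report["stages"].append({"stage": name, "params": params,
                                 "elapsed_s": round(dt, 3), "result": result})
    write_report(report, out)
    return report


def write_report(report: dict, out_dir) -> Path:
    """Serialize the run report deterministically (timestamp aside)."""
    if not report.get("stages") and "timestamp" not in report:
        raise ValueError("nothing to report")
    path = Path(out_dir) / "run_report.json"
    io.write_json(report, path)
    text = [f"stiffscape run (seed {report.get('seed')})"]
    for st in report.get("stages", []):
        text.append(f"- {st['stage']}: "
                    + json.dumps(st["result"], sort_keys=True, default=str))
    (Path(out_dir) / "run_report.txt").write_text("\n".join(text) + "\n")
    return path
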