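"""Stage-based pipeline: generate -> oracle -> encode -> train -> evaluate.

Every stage writes its outputs plus a small JSON stage manifest containing
the configuration hash; downstream stages refuse to run against artifacts
produced under a different configuration.  A single global seed determines
every file the pipeline writes.
"""

from __future__ import annotations

import hashlib
import json
import os
import pickle
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from .benchmark import DESK_MODEL_KWARGS, desk_train_config
from .cohort import PRESETS, generate_case, GridPreset
from .dataset import WSSDataset
from .encoding import crop_wss_field, build_feature_tensor, build_graph
from .errors import PipelineStageError, ValidationError
from .evaluation import bland_altman, compute_metrics, render_report
from .geometry import write_centerline_csv
from .models import TrainConfig, train_surrogate
from .oracle import FlowParams, OracleConfig, oracle_wss_field, write_wss_csv
from .stenosis import SEVERITY_AR


@dataclass
class PipelineConfig:
    cohort_size: int = 20
    preset: str = "desk"
    severity: str | None = None        # None -> random AR in [0.1, 0.9]
    morphology: str | None = None      # None -> uniform mix
    dual_fraction: float = 0.3
    noise_sigma: float = 0.05
    model_kinds: tuple = ("pignn",)
    seed: int = 0
    out_root: str = "pipeline_out"
    train: dict = field(default_factory=dict)   # TrainConfig overrides

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if cfg.preset not in PRESETS:
            raise ValidationError(f"preset must be one of {sorted(PRESETS)}")
        if cfg.severity is not None and cfg.severity not in SEVERITY_AR:
            raise ValidationError(
                f"severity must be one of {sorted(SEVERITY_AR)}"
            )
        return cfg

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _stage_dir(cfg: PipelineConfig, stage: str) -> str:
    return os.path.join(cfg.out_root, stage)


def _write_manifest(cfg: PipelineConfig, stage: str, extra: dict | None = None):
    d = _stage_dir(cfg, stage)
    os.makedirs(d, exist_ok=True)
    manifest = {"stage": stage, "config_hash": cfg.config_hash(),
                "seed": cfg.seed}
    if extra:
        manifest.update(extra)
    with open(os.path.join(d, "stage.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)


def _check_upstream(cfg: PipelineConfig, stage: str):
    path = os.path.join(_stage_dir(cfg, stage), "stage.json")
    if not os.path.exists(path):
        raise PipelineStageError(
            f"missing {stage} outputs under {cfg.out_root!r}: "
            f"run stage '{stage}' first"
        )
    with open(path) as fh:
        manifest = json.load(fh)
    if manifest["config_hash"] != cfg.config_hash():
        raise PipelineStageError(
            f"stage '{stage}' was produced under a different configuration; "
            "refusing mixed-config resumption"
        )


def _case_seeds(cfg: PipelineConfig) -> np.ndarray:
    return np.random.SeedSequence(cfg.seed).generate_state(cfg.cohort_size) % 2**31


def _build_cases(cfg: PipelineConfig, with_oracle: bool) -> list:
    preset = PRESETS[cfg.preset]
    oc = OracleConfig(noise_sigma=cfg.noise_sigma)
    seeds = _case_seeds(cfg)
    return [
        generate_case(
            int(seeds[i]), preset=preset, oracle_config=oc,
            morphology=cfg.morphology, severity=cfg.severity,
            dual_fraction=cfg.dual_fraction, case_id=i,
        )
        for i in range(cfg.cohort_size)
    ]


def cmd_generate(cfg: PipelineConfig) -> str:
    """Write per-case geometry (STL, VTP, CSV) and the lesion manifest."""
    from .cohort import generate_cohort

    d = _stage_dir(cfg, "generate")
    os.makedirs(d, exist_ok=True)
    preset = PRESETS[cfg.preset]
    oc = OracleConfig(noise_sigma=cfg.noise_sigma)
    seeds = _case_seeds(cfg)
    rows = []
    from .stenosis import export_geometry, lattice_faces

    for i in range(cfg.cohort_size):
        sample = generate_case(
            int(seeds[i]), preset=preset, oracle_config=oc,
            morphology=cfg.morphology, severity=cfg.severity,
            dual_fraction=cfg.dual_fraction, case_id=i,
            keep_geometry=True,
        )
        stem = os.path.join(d, f"case{i:04d}")
        export_geometry(
            sample.lattice, sample.centerline,
            stl_path=stem + "_wall.stl",
            vtp_path=stem + "_centerline.vtp",
            csv_path=stem + "_nodes.csv",
        )
        for j, sp in enumerate(sample.specs):
            rows.append({"case_id": i, "lesion": j, **asdict_spec(sp)})
    pd.DataFrame(rows).to_csv(os.path.join(d, "manifest.csv"), index=False)
    _write_manifest(cfg, "generate", {"n_cases": cfg.cohort_size})
    return d


def asdict_spec(sp) -> dict:
    return {
        "morphology": sp.morphology, "area_ratio": sp.area_ratio,
        "position_mm": sp.position_mm,
        "eccentric_distance_mm": sp.eccentric_distance_mm,
        "semi_major_mm": sp.semi_major_mm, "semi_minor_mm": sp.semi_minor_mm,
        "orientation_rad": sp.orientation_rad,
        "axial_extent_mm": sp.axial_extent_mm,
    }


def cmd_oracle(cfg: PipelineConfig) -> str:
    """Generate the oracle WSS fields (requires generate)."""
    _check_upstream(cfg, "generate")
    d = _stage_dir(cfg, "oracle")
    os.makedirs(d, exist_ok=True)
    cases = _build_cases(cfg, with_oracle=True)
    for c in cases:
        write_wss_csv(c.wss, os.path.join(d, f"case{c.case_id:04d}_wss.csv"))
    _write_manifest(cfg, "oracle", {"n_cases": len(cases)})
    return d


def cmd_encode(cfg: PipelineConfig) -> str:
    """Write the encoded dataset (HDF5 of inputs/targets)."""
    _check_upstream(cfg, "oracle")
    import h5py

    d = _stage_dir(cfg, "encode")
    os.makedirs(d, exist_ok=True)
    cases = _build_cases(cfg, with_oracle=True)
    inputs = np.stack([c.tensor.grid for c in cases])
    targets = np.stack([c.wss.values for c in cases])
    with h5py.File(os.path.join(d, "dataset.h5"), "w") as fh:
        fh.create_dataset("inputs", data=inputs)
        fh.create_dataset("targets", data=targets)
    _write_manifest(cfg, "encode", {"input_shape": list(inputs.shape)})
    return d


def _train_config(cfg: PipelineConfig, kind: str) -> TrainConfig:
    if cfg.preset == "desk":
        tc = desk_train_config(kind, cfg.seed)
    else:
        tc = TrainConfig(seed=cfg.seed,
                         model_kwargs=dict(DESK_MODEL_KWARGS[kind]))
    for k, v in cfg.train.items():
        if k == "model_kwargs":
            tc.model_kwargs.update(v)
        else:
            setattr(tc, k, v)
    return tc


def cmd_train(cfg: PipelineConfig) -> str:
    """Train the configured surrogate kinds on the encoded cohort."""
    _check_upstream(cfg, "encode")
    d = _stage_dir(cfg, "train")
    os.makedirs(d, exist_ok=True)
    cases = _build_cases(cfg, with_oracle=True)
    dataset = WSSDataset(samples=cases)
    flow = FlowParams()
    for kind in cfg.model_kinds:
        trained = train_surrogate(dataset, kind, _train_config(cfg, kind),
                                  flow=flow)
        hist = pd.DataFrame(trained.history)
        hist.to_csv(os.path.join(d, f"history_{kind}.csv"), index=False)
        with open(os.path.join(d, f"model_{kind}.pkl"), "wb") as fh:
            pickle.dump({
                "kind": kind,
                "state": trained.model.state_dict(),
                "model_kwargs": _train_config(cfg, kind).model_kwargs,
                "scaler_mean": trained.scaler.mean,
                "scaler_sd": trained.scaler.sd,
                "norm_mean": dataset.normalizer.mean,
                "norm_sd": dataset.normalizer.sd,
                "config_hash": cfg.config_hash(),
            }, fh)
    _write_manifest(cfg, "train", {"kinds": list(cfg.model_kinds)})
    return d


def load_trained(cfg: PipelineConfig, kind: str,
                 dataset: WSSDataset):
    """Rebuild a trained surrogate from its checkpoint file."""
    from .encoding import WSSNormalizer
    from .models.mlp import MLPSurrogate
    from .models.pignn import PIGNN
    from .models.unet import UNet
    from .models.training import FeatureScaler, TrainedSurrogate

    path = os.path.join(_stage_dir(cfg, "train"), f"model_{kind}.pkl")
    if not os.path.exists(path):
        raise PipelineStageError(f"no checkpoint for {kind}: run stage 'train' first")
    with open(path, "rb") as fh:
        blob = pickle.load(fh)
    if blob["config_hash"] != cfg.config_hash():
        raise PipelineStageError("checkpoint from a different configuration")
    tc = _train_config(cfg, kind)
    dataset.split(fractions=tc.split, seed=tc.seed)
    dataset.normalizer = WSSNormalizer(blob["norm_mean"], blob["norm_sd"])
    kw = blob["model_kwargs"]
    grid_hw = dataset.samples[0].grid_shape
    if kind == "pignn":
        model = PIGNN(seed=tc.seed, **kw)
    elif kind == "unet":
        model = UNet(in_ch=8, seed=tc.seed, **kw)
    else:
        model = MLPSurrogate(grid_hw, seed=tc.seed, **kw)
        model.fitted = True
    model.load_state_dict(blob["state"])
    model.eval()
    scaler = FeatureScaler(blob["scaler_mean"], blob["scaler_sd"])
    return TrainedSurrogate(kind=kind, model=model, dataset=dataset,
                            scaler=scaler, history=[])


def cmd_evaluate(cfg: PipelineConfig) -> str:
    """Evaluate trained surrogates on the held-out split; writes the metrics
    CSV per scenario subset (concentric / eccentric / all) and a per-case
    report for the first test case."""
    _check_upstream(cfg, "train")
    d = _stage_dir(cfg, "evaluate")
    os.makedirs(d, exist_ok=True)
    cases = _build_cases(cfg, with_oracle=True)
    dataset = WSSDataset(samples=cases)
    rows = []
    for kind in cfg.model_kinds:
        trained = load_trained(cfg, kind, dataset)
        test = dataset.subset("test")
        preds = {s.case_id: trained.predict(s) for s in test}

        def scenario_of(s):
            return ("concentric" if all(not sp.is_eccentric for sp in s.specs)
                    else "eccentric")

        groups = {"all": test,
                  "concentric": [s for s in test if scenario_of(s) == "concentric"],
                  "eccentric": [s for s in test if scenario_of(s) == "eccentric"]}
        for scen, subset in groups.items():
            if len(subset) == 0:
                continue
            p = np.concatenate([preds[s.case_id].ravel() for s in subset])
            r = np.concatenate([s.wss.values.ravel() for s in subset])
            m = compute_metrics(p, r)
            a = bland_altman(p, r)
            rows.append({"model": kind, "scenario": scen, **m.as_dict(),
                         "bias": a.bias, "loa_low": a.loa_low,
                         "loa_high": a.loa_high})
        first = test[0]
        render_report(f"{kind}_case{first.case_id:04d}",
                      preds[first.case_id], first.wss.values,
                      os.path.join(d, f"report_{kind}"))
    pd.DataFrame(rows).to_csv(os.path.join(d, "metrics.csv"), index=False)
    _write_manifest(cfg, "evaluate", {"kinds": list(cfg.model_kinds)})
    return d


STAGES = {
    "generate": cmd_generate,
    "oracle": cmd_oracle,
    "encode": cmd_encode,
    "train": cmd_train,
    "evaluate": cmd_evaluate,
}
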