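"""End-to-end orchestration: phantom -> RF -> QUS maps -> classification.

A :class:`RunConfig` (usually loaded from YAML) names the stages to run
and their settings; :func:`run_pipeline` executes them in order, writes
every artifact under the output directory and returns a manifest recording
inputs, outputs, derived seeds and summary metrics, so any output can be
re-derived from the manifest alone.
"""

from __future__ import annotations

import json
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import acoustic, estimators, malignancy, phantom as phantom_mod
from .cohort import sample_cohort

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

STAGES = ("phantom", "simulate", "estimate", "cohort", "classify", "evaluate")


class PipelineError(RuntimeError):
    """Raised when a stage cannot run (missing upstream artifact etc.)."""


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "pwqus_out"
    stages: tuple[str, ...] = ("phantom", "simulate", "estimate", "classify")
    options: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: raw.pop(k) for k in ("seed", "outdir", "stages") if k in raw}
        if "stages" in known:
            known["stages"] = tuple(known["stages"])
        cfg = cls(**known, options=raw)
        for st in cfg.stages:
            if st not in STAGES:
                raise ValueError(f"unknown stage {st!r}; expected one of {STAGES}")
        return cfg

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the global seed."""
        return (self.seed * 1000003 + zlib.crc32(stage.encode())) % (2**31)

    def opt(self, stage: str) -> dict:
        return self.options.get(stage, {}) or {}


def _build_probe(cfg: RunConfig) -> acoustic.ProbeConfig:
    o = cfg.opt("probe")
    kwargs = {}
    if "angles" in o:
        kwargs["steering_angles_deg"] = tuple(float(a) for a in o["angles"])
    for k in ("snr_db", "pitch_mm", "center_freq_hz", "n_samples"):
        if k in o:
            kwargs[k] = o[k]
    return acoustic.ProbeConfig(**kwargs)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns (and writes) the manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "stages": list(config.stages),
        "stage_seeds": {s: config.stage_seed(s) for s in config.stages},
        "outputs": {},
        "metrics": {},
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }

    ph = None
    rf = None
    images: dict = {}

    for stage in config.stages:
        seed = config.stage_seed(stage)
        if stage == "phantom":
            o = config.opt("phantom")
            grid = tuple(o.get("grid", (128, 128)))
            pitch = float(o.get("pitch_mm", 0.2))
            lesion = None
            if "lesion" in o:
                lo = o["lesion"]
                lesion = phantom_mod.LesionSpec(
                    shape=lo.get("shape", "ellipse"),
                    center_mm=tuple(lo.get("center_mm", (grid[1] * pitch / 2, grid[0] * pitch / 2))),
                    axes_mm=tuple(lo.get("axes_mm", (4.0, 3.0))),
                    boundary_roughness=float(lo.get("boundary_roughness", 0.0)),
                    class_label=lo.get("class", "benign"),
                )
            ph = phantom_mod.generate_phantom(
                lesion=lesion, rng_seed=seed, pixel_pitch_mm=pitch, grid_shape=grid
            )
            path = outdir / "phantom.h5"
            phantom_mod.save_phantom(ph, path)
            manifest["outputs"]["phantom"] = str(path)

        elif stage == "simulate":
            if ph is None:
                src = config.opt("simulate").get("phantom")
                if src is None:
                    raise PipelineError(
                        "stage 'simulate' requires a phantom; run the 'phantom' "
                        "stage first or set simulate.phantom to a file"
                    )
                ph = phantom_mod.load_phantom(src)
            probe = _build_probe(config)
            rf = acoustic.simulate_rf(ph, probe, rng_seed=seed)
            path = outdir / "rf.h5"
            acoustic.save_rf(rf, path)
            manifest["outputs"]["rf"] = str(path)

        elif stage == "estimate":
            if rf is None:
                src = config.opt("estimate").get("rf")
                if src is None:
                    raise PipelineError(
                        "stage 'estimate' requires RF data; run the 'simulate' "
                        "stage first or set estimate.rf to a file"
                    )
                rf = acoustic.load_rf(src)
            o = config.opt("estimate")
            ref = estimators.make_reference_rf(rf.probe, rf.roi_mm)
            lo_c, hi_c, step = o.get("sos_candidates", (1450, 1630, 5))
            sos_img = estimators.estimate_sos(rf, np.arange(lo_c, hi_c + 1, step))
            ac_img = estimators.estimate_ac(rf, ref, beamform_c=sos_img.scalar)
            esd_img, esc_img = estimators.estimate_esd_esc(
                rf, ref, beamform_c=sos_img.scalar
            )
            images = {"AC": ac_img, "SoS": sos_img, "ESD": esd_img, "ESC": esc_img}
            import h5py

            path = outdir / "qus_maps.h5"
            with h5py.File(path, "w") as f:
                for name, img in images.items():
                    d = f.create_dataset(name, data=img.values)
                    d.attrs["units"] = img.units
                    d.attrs["summary"] = img.scalar
            manifest["outputs"]["qus_maps"] = str(path)
            manifest["metrics"]["qus_summaries"] = {
                k: img.scalar for k, img in images.items()
            }

        elif stage == "cohort":
            o = config.opt("cohort")
            table = sample_cohort(
                n_benign=int(o.get("n_benign", 32)),
                n_malignant=int(o.get("n_malignant", 23)),
                seed=seed,
            )
            path = outdir / "cohort.csv"
            table.to_csv(path, index=False)
            manifest["outputs"]["cohort"] = str(path)

        elif stage == "classify":
            rows = []
            if images and ph is not None and ph.lesion_mask.any():
                meas = estimators.lesion_measurements(images, ph)
                rows.append(
                    {
                        "id": "lesion-1",
                        "ac": meas["AC"],
                        "sos": meas["SoS"],
                        "esd": meas["ESD"],
                        "esc": meas["ESC"],
                    }
                )
            src = config.opt("classify").get("cohort")
            if src is not None:
                import pandas as pd

                rows.extend(pd.read_csv(src).to_dict("records"))
            if not rows:
                raise PipelineError(
                    "stage 'classify' has nothing to score; provide an estimated "
                    "lesion (phantom+simulate+estimate) or classify.cohort file"
                )
            import pandas as pd

            df = pd.DataFrame(rows)
            model = malignancy.default_model()
            scores = model.intercept + df[["ac", "sos", "esd", "esc"]].to_numpy() @ model.coefficients
            df["log_odds"] = scores
            df["probability"] = malignancy.probability(scores)
            df["call"] = np.where(df["probability"] >= 0.5, "malignant", "benign")
            path = outdir / "classification.csv"
            df.to_csv(path, index=False)
            manifest["outputs"]["classification"] = str(path)
            manifest["metrics"]["classification"] = df[
                [c for c in ("id", "probability", "call") if c in df]
            ].to_dict("records")

        elif stage == "evaluate":
            src = config.opt("evaluate").get("cohort", manifest["outputs"].get("cohort"))
            if src is None:
                raise PipelineError(
                    "stage 'evaluate' requires a labeled cohort; run the "
                    "'cohort' stage or set evaluate.cohort"
                )
            import pandas as pd

            df = pd.read_csv(src)
            model = malignancy.default_model()
            scores = model.intercept + df[["ac", "sos", "esd", "esc"]].to_numpy() @ model.coefficients
            res = malignancy.roc_auc(
                scores,
                df["label"].to_numpy(),
                n_boot=int(config.opt("evaluate").get("n_boot", 2000)),
                seed=seed,
            )
            manifest["metrics"]["auc"] = res.auc
            manifest["metrics"]["auc_ci"] = list(res.ci)

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
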