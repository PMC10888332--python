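"""Simulated training data for the reconstruction network.

Each sample is a (channel-data stack, condition, target map) triple: the
multi-angle RF frame of a simulated phantom becomes a stack of per-angle
planes on a 128 x 128 grid (128 receive elements laterally, the covered
depth range block-averaged to 128 rows), and the target is the phantom's
ground-truth map of the conditioned parameter, resampled to 128 x 128 and
scaled to [0, 1] by fixed physical ranges.
"""

from __future__ import annotations

import numpy as np

from .acoustic import PlaneWaveRF, ProbeConfig, simulate_rf
from .phantom import LesionSpec, TissuePhantom, sample_tissue_properties, generate_phantom, uniform_phantom
from .qusnet import PARAMETERS, scale_target

__all__ = ["rf_to_input", "phantom_targets", "make_toy_dataset"]


#: assumed speeds for the coherence-cue envelope channels (m/s)
_INPUT_BF_SPEEDS = (1480.0, 1540.0, 1600.0)


def rf_to_input(rf: PlaneWaveRF, size: int = 128) -> np.ndarray:
    """Network input stack (angles + 3 channels, size, size).

    Two groups of planes:

    * one magnitude plane per steering angle (elements laterally, the
      covered depth block-averaged to ``size`` rows) — carries the
      amplitude-decay and backscatter-level cues (attenuation, scatterer
      concentration/size);
    * compounded envelope images beamformed at three assumed sound speeds
      — coherent summation peaks when the assumed speed matches the
      medium, so the relative brightness across these channels encodes the
      speed of sound.

    Scales are fixed constants: per-sample normalization would erase the
    absolute backscatter level, which is itself a cue.
    """
    from scipy.signal import hilbert

    from .estimators import _patch_das

    probe = rf.probe
    depth_samples = int(round(2.0 * rf.roi_mm[1] * 1e-3 / probe.c_ref * probe.sampling_rate_hz))
    depth_samples = min(depth_samples, probe.n_samples)
    data = np.abs(rf.data[:, :, :depth_samples])
    edges = np.linspace(0, depth_samples, size + 1).astype(int)
    planes = np.add.reduceat(data, edges[:-1], axis=-1)
    widths = np.maximum(np.diff(edges), 1)
    planes = planes / widths
    planes = np.swapaxes(planes, 1, 2)  # (angles, depth, elements)
    if planes.shape[2] != size:
        x_old = np.linspace(0, 1, planes.shape[2])
        x_new = np.linspace(0, 1, size)
        planes = np.stack(
            [np.stack([np.interp(x_new, x_old, row) for row in p]) for p in planes]
        )
    planes = planes / 20.0

    bf_grid = size // 2
    roi_w, roi_d = rf.roi_mm
    gx = (np.arange(bf_grid) + 0.5) * roi_w / bf_grid
    gz = (np.arange(bf_grid) + 0.5) * min(
        roi_d, depth_samples / probe.sampling_rate_hz * probe.c_ref / 2 * 1e3
    ) / bf_grid
    GZ, GX = np.meshgrid(gz, gx, indexing="ij")
    analytic = hilbert(rf.data, axis=-1)
    coherence_planes = []
    for c in _INPUT_BF_SPEEDS:
        per_angle = _patch_das(analytic, probe, rf.roi_mm, c, GX.ravel(), GZ.ravel())
        env = np.abs(per_angle.sum(axis=0)).reshape(bf_grid, bf_grid)
        env = env.repeat(size // bf_grid, axis=0).repeat(size // bf_grid, axis=1)
        coherence_planes.append(env / 2e3)
    return np.concatenate([planes, np.stack(coherence_planes)]).astype(np.float32)


def _resample_map(values: np.ndarray, size: int) -> np.ndarray:
    zi = (np.arange(size) + 0.5) / size * values.shape[0]
    xi = (np.arange(size) + 0.5) / size * values.shape[1]
    zi = np.clip(zi.astype(int), 0, values.shape[0] - 1)
    xi = np.clip(xi.astype(int), 0, values.shape[1] - 1)
    return values[np.ix_(zi, xi)]


def phantom_targets(phantom: TissuePhantom, size: int = 128) -> dict[str, np.ndarray]:
    """Ground-truth maps per parameter, resampled and scaled to [0, 1]."""
    maps = {
        "AC": phantom.ac_map,
        "SoS": phantom.sos_map,
        "ESD": phantom.esd_map,
        "ESC": phantom.esc_map,
    }
    return {
        k: scale_target(_resample_map(v, size), k).astype(np.float32)
        for k, v in maps.items()
    }


def make_toy_dataset(
    n_samples: int = 64,
    seed: int = 0,
    probe: ProbeConfig | None = None,
    roi_mm: float = 12.8,
    pixel_pitch_mm: float = 0.2,
    with_lesions: bool = False,
    return_truths: bool = False,
    conditions: tuple[str, ...] = PARAMETERS,
):
    """Small simulated training set serving each frame under all conditions.

    Phantoms are homogeneous (optionally with an embedded lesion) with
    properties drawn from the soft-tissue ranges, so each target map is a
    near-constant image whose level encodes the parameter.  Every
    simulated frame appears once per requested condition with the
    matching target — identical inputs demanding different outputs is
    precisely what makes the conditional pathway necessary.

    Returns ``(X, cond, Y)`` with X (n, channels, 128, 128), cond (n,)
    names, Y (n, 128, 128) scaled targets; ``n_samples`` counts rows, so
    ``n_samples // len(conditions)`` distinct frames are simulated.
    """
    probe = probe or ProbeConfig()
    rng = np.random.default_rng(seed)
    grid = int(round(roi_mm / pixel_pitch_mm))
    X, conds, Y, truths = [], [], [], []
    n_frames = max(1, n_samples // len(conditions))
    for i in range(n_frames):
        props = sample_tissue_properties("gland", rng)
        props["ac"] = rng.uniform(0.1, 1.2)
        props["sos"] = rng.uniform(1450, 1650)
        props["esd"] = rng.uniform(40, 130)
        props["esc"] = rng.uniform(0.8, 5.0)
        if with_lesions and i % 2 == 0:
            lesion = LesionSpec(
                center_mm=(roi_mm / 2, roi_mm / 2),
                axes_mm=(roi_mm / 5, roi_mm / 6),
                class_label="malignant",
            )
            phantom = generate_phantom(
                lesion=lesion,
                rng_seed=int(rng.integers(2**31)),
                pixel_pitch_mm=pixel_pitch_mm,
                grid_shape=(grid, grid),
            )
        else:
            phantom = uniform_phantom(
                ac=props["ac"],
                sos=props["sos"],
                esd=props["esd"],
                esc=props["esc"],
                pixel_pitch_mm=pixel_pitch_mm,
                grid_shape=(grid, grid),
            )
        rf = simulate_rf(phantom, probe, rng_seed=int(rng.integers(2**31)))
        targets = phantom_targets(phantom)
        planes = rf_to_input(rf)
        for cond in conditions:
            X.append(planes)
            conds.append(cond)
            Y.append(targets[cond])
            truths.append(dict(props))
    if return_truths:
        return np.stack(X), np.array(conds), np.stack(Y), truths
    return np.stack(X), np.array(conds), np.stack(Y)
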