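"""Classical reference estimators for the four QUS parameters.

These implement the standard literature definitions that the four
parameters cite:

* **AC** — spectral log difference: power spectra of beamformed RF windows
  are normalized by a reference acquisition over a phantom of known
  attenuation; the slope of the log ratio in frequency grows linearly with
  depth at a rate set by the local attenuation coefficient.
* **SoS** — multi-angle phase coherence: each steering angle is beamformed
  with a candidate sound speed and the speed maximizing the coherence of
  the per-angle complex images is selected (grid search + parabolic
  refinement).
* **ESD / ESC** — Gaussian form-factor backscatter fit: the log of the
  reference-normalized power spectrum is fitted with a quadratic in
  frequency; the quadratic term maps to the effective scatterer diameter
  through ``F(f) = exp(-0.827 k^2 (ESD/2)^2)`` and the intercept to the
  effective scatterer concentration.

Spectra are estimated from per-angle complex beamformed images rather than
raw element traces: across the receive aperture the element signals within
one range gate are strongly correlated (they see the same scatterers),
whereas beamformed lines half a beamwidth apart carry independent speckle,
so averaging periodograms over lateral lines and steering angles gives far
more independent looks per analysis window.  Receive apertures are F-number
limited so the oblique-path geometry stays proportional to depth, the sound
speed used for beamforming is estimated first (phase coherence) so that
defocus does not distort the spectra, and additive electronic noise is
estimated from out-of-band bins and subtracted before any log-ratio is
formed, with per-bin signal-to-noise masks guarding the fits.

Per-window parameter maps at a 5 MHz, 4 x 4 mm window scale are inherently
high variance; each returned image therefore also carries a pooled
whole-region ``summary`` estimate obtained by fitting the spectra of all
usable windows jointly, which is the quantity the recovery guarantees refer
to.  All estimators operate on reference-normalized spectra, so they are
invariant to global RF amplitude scaling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

from .acoustic import DB_TO_NEPER, PlaneWaveRF, ProbeConfig, simulate_rf
from .phantom import TissuePhantom, uniform_phantom

__all__ = [
    "QUSImage",
    "AnalysisWindow",
    "ReferenceSpec",
    "make_reference_rf",
    "estimate_ac",
    "estimate_sos",
    "estimate_esd_esc",
    "lesion_measurements",
]

#: receive F-number for spectral-analysis beamforming
_SPECTRAL_FNUM = 1.0
#: axial beamforming step (mm); sets the axial Nyquist c/(4*dz) ~ 11 MHz
_AXIAL_STEP_MM = 0.035
#: lateral line spacing (mm); a few beamwidths, near-independent speckle
_LATERAL_STEP_MM = 0.4
_DEPTH_MARGIN_MM = 3.0
#: analysis band half-width in units of the pulse spectral std
_JOINT_BAND_SIGMAS = 2.6
#: default candidate speeds when the beamforming speed is auto-estimated
_DEFAULT_SOS_CANDIDATES = np.arange(1440.0, 1642.0, 8.0)


@dataclass
class QUSImage:
    """One reconstructed parameter map with units and grid.

    ``values`` is the per-window map; ``summary``, when present, is the
    pooled whole-region estimate (lower variance than any single window).
    """

    values: np.ndarray
    parameter: str  # AC | SoS | ESD | ESC
    pitch_mm: tuple[float, float]  # (depth, lateral) spacing of the value grid
    origin_mm: tuple[float, float] = (0.0, 0.0)
    summary: float | None = None
    warning: str | None = None

    UNITS = {"AC": "dB/cm/MHz", "SoS": "m/s", "ESD": "um", "ESC": "/wavelength^2"}

    def __post_init__(self) -> None:
        if self.parameter not in self.UNITS:
            raise ValueError(f"unknown parameter {self.parameter!r}")
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if not np.all(np.isfinite(self.values)):
            raise ValueError("QUS image contains non-finite values")

    @property
    def units(self) -> str:
        return self.UNITS[self.parameter]

    @property
    def scalar(self) -> float:
        """Pooled estimate if available, else the median over the map."""
        if self.summary is not None:
            return float(self.summary)
        return float(np.median(self.values))


@dataclass
class AnalysisWindow:
    """Sliding spectral-analysis window geometry."""

    lateral_mm: float = 4.0
    depth_mm: float = 4.0
    overlap: float = 0.5

    def __post_init__(self) -> None:
        if not 0 <= self.overlap < 1:
            raise ValueError("overlap must be in [0, 1)")


@dataclass
class ReferenceSpec:
    """Known uniform phantom used for spectral normalization."""

    ac: float = 0.5
    sos: float = 1540.0
    esd: float = 85.0
    esc: float = 2.0


_REFERENCE_CACHE: dict = {}


def make_reference_rf(
    probe: ProbeConfig,
    roi_mm: tuple[float, float],
    pixel_pitch_mm: float = 0.2,
    spec: ReferenceSpec | None = None,
    seed: int = 987654321,
) -> PlaneWaveRF:
    """Simulate (and cache) the reference acquisition for normalization."""
    spec = spec or ReferenceSpec()
    key = repr((vars(probe), roi_mm, pixel_pitch_mm, vars(spec), seed))
    if key not in _REFERENCE_CACHE:
        grid = (
            int(round(roi_mm[1] / pixel_pitch_mm)),
            int(round(roi_mm[0] / pixel_pitch_mm)),
        )
        ph = uniform_phantom(
            ac=spec.ac,
            sos=spec.sos,
            esd=spec.esd,
            esc=spec.esc,
            pixel_pitch_mm=pixel_pitch_mm,
            grid_shape=grid,
        )
        _REFERENCE_CACHE[key] = simulate_rf(ph, probe, rng_seed=seed)
    return _REFERENCE_CACHE[key]


def _check_reference(rf: PlaneWaveRF, reference: PlaneWaveRF) -> None:
    for k in ("n_elements", "center_freq_hz", "pitch_mm", "sampling_rate_hz", "n_samples"):
        if getattr(rf.probe, k) != getattr(reference.probe, k):
            raise ValueError(f"reference probe mismatch on {k}")


def _patch_das(
    analytic: np.ndarray,
    probe: ProbeConfig,
    roi_mm: tuple[float, float],
    assumed_c: float,
    gx: np.ndarray,
    gz: np.ndarray,
    fnum: float | None = None,
    chunk: int = 16384,
) -> np.ndarray:
    """Complex DAS of every steering angle onto an arbitrary pixel set.

    ``gx``/``gz`` are flat mm coordinate arrays; returns (angles, P).  With
    ``fnum`` set, the receive aperture per pixel is limited to elements
    within ``z / (2 fnum)`` laterally (at least 8 elements).
    """
    el_x = probe.element_positions_mm(roi_mm[0])
    fs = probe.sampling_rate_hz
    n_ang = analytic.shape[0]
    out = np.empty((n_ang, gx.size), dtype=complex)
    rows = np.arange(probe.n_elements)[:, None]
    min_half = 4 * probe.pitch_mm
    for lo in range(0, gx.size, chunk):
        px = gx[lo : lo + chunk][None, :]
        pz = gz[lo : lo + chunk][None, :]
        dx = px - el_x[:, None]
        r = np.sqrt(dx**2 + pz**2) * 1e-3 / assumed_c
        if fnum is not None:
            half = np.maximum(pz / (2.0 * fnum), min_half)
            apod = (np.abs(dx) <= half).astype(float)
        else:
            apod = None
        for ai, ang in enumerate(probe.steering_angles_deg):
            s_ang, c_ang = math.sin(math.radians(ang)), math.cos(math.radians(ang))
            x_ref = el_x[0] if s_ang >= 0 else el_x[-1]
            t_tx = ((px - x_ref) * s_ang + pz * c_ang) * 1e-3 / assumed_c
            idx = (t_tx + r) * fs
            i0 = np.clip(np.floor(idx).astype(int), 0, probe.n_samples - 2)
            frac = np.clip(idx - i0, 0.0, 1.0)
            ch = analytic[ai]
            vals = ch[rows, i0] * (1 - frac) + ch[rows, i0 + 1] * frac
            if apod is not None:
                vals = vals * apod
            out[ai, lo : lo + chunk] = vals.sum(axis=0)
    return out


def _path_factor(probe: ProbeConfig, fnum: float) -> float:
    """Mean two-way path length per unit depth for the analysis geometry.

    Transmit leg ~ z * mean cos(steering angle); receive leg
    z * mean sqrt(1 + u^2) over the F-number-limited aperture.
    """
    cos_mean = float(
        np.mean([math.cos(math.radians(a)) for a in probe.steering_angles_deg])
    )
    u = np.linspace(-1.0 / (2 * fnum), 1.0 / (2 * fnum), 201)
    kappa = float(np.mean(np.sqrt(1.0 + u**2)))
    return cos_mean + kappa


def _window_spectra(
    rf: PlaneWaveRF, window: AnalysisWindow, assumed_c: float | None = None
):
    """Averaged periodograms of beamformed lines on the analysis grid.

    Beamforms each angle at ``assumed_c`` (default: nominal tissue speed)
    with F-number-limited receive apertures, slides Hann windows along
    depth, and averages periodograms over the lateral lines of each window
    and over steering angles.  Returns ``(spectra[z, lat, freq], freqs_hz,
    depth_centers_mm, lateral_centers_mm, noise[z, lat])`` where ``noise``
    is the per-bin white-noise floor estimated from bins well above the
    pulse band.  Results are cached on the RF object.
    """
    probe = rf.probe
    c_bf = probe.c_ref if assumed_c is None else float(assumed_c)
    cache = getattr(rf, "_spectra_cache", None)
    if cache is None:
        cache = {}
        object.__setattr__(rf, "_spectra_cache", cache)
    key = (window.lateral_mm, window.depth_mm, window.overlap, round(c_bf, 3))
    if key in cache:
        return cache[key]

    roi_w, roi_d = rf.roi_mm
    record_mm = probe.n_samples / probe.sampling_rate_hz * c_bf / 2.0 * 1e3
    z_lo = _DEPTH_MARGIN_MM
    z_hi = min(roi_d, record_mm) - _DEPTH_MARGIN_MM / 2
    gz = np.arange(z_lo, z_hi, _AXIAL_STEP_MM)
    gx = np.arange(2.0, roi_w - 2.0, _LATERAL_STEP_MM)
    GZ, GX = np.meshgrid(gz, gx, indexing="ij")

    analytic = hilbert(rf.data, axis=-1)
    img = _patch_das(
        analytic, probe, rf.roi_mm, c_bf, GX.ravel(), GZ.ravel(), fnum=_SPECTRAL_FNUM
    )
    img = img.reshape(-1, len(gz), len(gx))  # (angles, nz, nx)

    n_win = max(8, int(round(window.depth_mm / _AXIAL_STEP_MM)))
    step = max(1, int(round(n_win * (1 - window.overlap))))
    n_lat = max(2, int(round(window.lateral_mm / _LATERAL_STEP_MM)))
    lat_step = max(1, int(round(n_lat * (1 - window.overlap))))
    taper = np.hanning(n_win)
    dt_ax = 2.0 * _AXIAL_STEP_MM * 1e-3 / c_bf  # axial sample spacing, echo time
    freqs = np.fft.fftfreq(n_win, dt_ax)
    keep = freqs >= 0
    freqs = freqs[keep]

    z_starts = np.arange(0, len(gz) - n_win + 1, step)
    lat_starts = np.arange(0, len(gx) - n_lat + 1, lat_step)
    spectra = np.empty((len(z_starts), len(lat_starts), int(keep.sum())))
    for zi, s0 in enumerate(z_starts):
        seg = img[:, s0 : s0 + n_win, :] * taper[None, :, None]
        pw = np.abs(np.fft.fft(seg, axis=1)) ** 2
        pw = pw[:, keep, :].mean(axis=0)  # average over angles
        for li, l0 in enumerate(lat_starts):
            spectra[zi, li] = pw[:, l0 : l0 + n_lat].mean(axis=-1)

    nb = freqs > probe.center_freq_hz + 3.0 * probe.sigma_f_hz
    if nb.sum() < 3:
        nb = freqs > 0.9 * freqs.max()
    noise = spectra[:, :, nb].mean(axis=-1)

    depth_centers = gz[z_starts] + (n_win - 1) / 2.0 * _AXIAL_STEP_MM
    lat_centers = gx[lat_starts] + (n_lat - 1) / 2.0 * _LATERAL_STEP_MM
    result = (spectra, freqs, depth_centers, lat_centers, noise)
    cache[key] = result
    return result


def _beamform_speed(rf: PlaneWaveRF, beamform_c: float | None) -> float:
    if beamform_c is not None:
        return float(beamform_c)
    return estimate_sos(rf, _DEFAULT_SOS_CANDIDATES).scalar


def _resample_log(spec: np.ndarray, from_f: np.ndarray, to_f: np.ndarray) -> np.ndarray:
    """Interpolate positive spectra onto a new frequency grid (log domain).

    The beamformed axial frequency axis scales with the beamforming speed,
    so target and reference spectra live on slightly different grids; they
    must be aligned before any log-ratio, otherwise the grid mismatch masquerades
    as a spectral shift/curvature.
    """
    ln = np.log(np.maximum(spec, 1e-300))
    flat = ln.reshape(-1, ln.shape[-1])
    out = np.empty((flat.shape[0], len(to_f)))
    for i in range(flat.shape[0]):
        out[i] = np.interp(to_f, from_f, flat[i])
    return np.exp(out.reshape(ln.shape[:-1] + (len(to_f),)))


def _pooled_lnr(
    rf: PlaneWaveRF,
    reference: PlaneWaveRF,
    windows: AnalysisWindow,
    c_bf: float,
    band_sigmas: float = _JOINT_BAND_SIGMAS,
    snr_gate: float = 2.0,
):
    """Laterally pooled, noise-subtracted log spectral ratio vs depth.

    Pools the analysis-window spectra across the lateral dimension (the
    residual noise scale drops with the number of pooled windows, so the
    SNR gate is applied against the reduced floor), aligns the reference
    onto the target frequency axis and returns ``(lnr[z, f], mask[z, f],
    weights[z, f], f_hz, z_cm)``.
    """
    probe = rf.probe
    spec, freqs, depths, _, noise = _window_spectra(rf, windows, assumed_c=c_bf)
    ref_spec, ref_freqs, rdepths, _, ref_noise = _window_spectra(
        reference, windows, assumed_c=reference.probe.c_ref
    )
    nz = min(len(depths), len(rdepths))
    band = np.abs(freqs - probe.center_freq_hz) <= band_sigmas * probe.sigma_f_hz
    f = freqs[band]
    red = math.sqrt(spec.shape[1])
    ns = noise[:nz].mean(1)[:, None]
    nr = ref_noise[:nz].mean(1)[:, None]
    sp = spec[:nz, :, band].mean(1) - ns
    rp = _resample_log(ref_spec[:nz], ref_freqs, f).mean(1) - nr
    mask = (sp > snr_gate * ns / red) & (rp > snr_gate * nr / red)
    lnr = np.log(np.maximum(sp, 1e-300)) - np.log(np.maximum(rp, 1e-300))
    wgt = np.maximum(rp, 1e-300)
    wgt = wgt / wgt.sum(-1, keepdims=True)
    return lnr, mask, wgt, f, depths[:nz] / 10.0


def _joint_fit(lnr, mask, wgt, fm, z_cm):
    """Joint linear model over all depths: A_z + B f + C f^2 + D z f.

    Per-depth intercepts absorb speckle power fluctuations; the shared
    ``C`` (per Hz^2) carries the form-factor curvature and the shared
    ``D`` (per Hz per cm) the attenuation slope.  Fitted in MHz for
    conditioning; returns None when fewer than 3 usable depths remain.
    """
    keep = mask.sum(-1) >= 10
    idx = np.where(keep)[0]
    nw = len(idx)
    if nw < 3:
        return None
    nrow = int(mask[idx].sum())
    X = np.zeros((nrow, nw + 3))
    y = np.zeros(nrow)
    ww = np.zeros(nrow)
    k = 0
    for j, i in enumerate(idx):
        b = np.where(mask[i])[0]
        n = len(b)
        X[k : k + n, j] = 1.0
        X[k : k + n, nw] = fm[b]
        X[k : k + n, nw + 1] = fm[b] ** 2
        X[k : k + n, nw + 2] = z_cm[i] * fm[b]
        y[k : k + n] = lnr[i, b]
        ww[k : k + n] = wgt[i, b]
        k += n
    sw = np.sqrt(ww)
    coef, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
    return {
        "A": coef[:nw],
        "B": coef[nw] * 1e-6,
        "C": coef[nw + 1] * 1e-12,
        "D": coef[nw + 2] * 1e-6,
        "depth_idx": idx,
    }


_KAPPA_CACHE: dict = {}


def _artifact_kappa(
    probe: ProbeConfig,
    roi_mm: tuple[float, float],
    windows: AnalysisWindow,
    pixel_pitch_mm: float = 0.2,
) -> float:
    """Beamforming curvature constant, calibrated on two known phantoms.

    Delay-and-sum receive apertures mix echo paths of different obliquity;
    attenuation reweights those components with depth, which leaves a
    residual quadratic spectral term proportional to ``delta_alpha * z``.
    The constant is a property of the acquisition geometry, so it is
    measured once per configuration from two reference phantoms whose
    attenuation differs by a known amount (same scatterer seed, so the
    speckle cancels in the ratio), exactly as a QUS lab would calibrate on
    physical phantoms.  Units: per Hz^2 per cm per (dB/cm/MHz).
    """
    key = repr((vars(probe), roi_mm, vars(windows), pixel_pitch_mm))
    if key in _KAPPA_CACHE:
        return _KAPPA_CACHE[key]
    lo_spec = ReferenceSpec()
    hi_spec = ReferenceSpec(ac=lo_spec.ac + 0.3)
    ref_lo = make_reference_rf(probe, roi_mm, pixel_pitch_mm, spec=lo_spec)
    ref_hi = make_reference_rf(probe, roi_mm, pixel_pitch_mm, spec=hi_spec)
    lnr, mask, wgt, f, z_cm = _pooled_lnr(
        ref_hi, ref_lo, windows, probe.c_ref
    )
    _, c2, ok = _quadratic_fit(lnr, f, wgt, mask)
    if ok.sum() < 3:
        kappa = 0.0
    else:
        slope = np.polyfit(z_cm[ok], c2[ok], 1)[0]
        kappa = float(slope / (hi_spec.ac - lo_spec.ac))
    _KAPPA_CACHE[key] = kappa
    return kappa


def _joint_summary(
    rf: PlaneWaveRF,
    reference: PlaneWaveRF,
    windows: AnalysisWindow,
    c_bf: float,
    reference_ac: float = 0.5,
):
    """Pooled whole-region spectral model shared by the AC and ESD/ESC
    summaries; cached on the RF object.

    Runs the joint fit, converts its attenuation term to a first-pass
    ``delta_alpha``, removes the calibrated beamforming curvature artifact
    ``kappa * delta_alpha * z * f^2`` from the data, and refits.
    """
    cache = getattr(rf, "_joint_cache", None)
    if cache is None:
        cache = {}
        object.__setattr__(rf, "_joint_cache", cache)
    key = (windows.lateral_mm, windows.depth_mm, windows.overlap, round(c_bf, 3))
    if key in cache:
        return cache[key]

    path = _path_factor(rf.probe, _SPECTRAL_FNUM)
    to_alpha = -1.0 / (2.0 * path * DB_TO_NEPER * 1e-6)
    lnr, mask, wgt, f, z_cm = _pooled_lnr(rf, reference, windows, c_bf)
    fm = f / 1e6
    fit = _joint_fit(lnr, mask, wgt, fm, z_cm)
    result = None
    if fit is not None:
        # the attenuation slope comes from the uncorrected fit (the
        # curvature artifact is orthogonal enough to z*f to leave D
        # unbiased); the corrected refit supplies curvature and intercepts
        d_alpha = fit["D"] * to_alpha
        kappa = _artifact_kappa(reference.probe, reference.roi_mm, windows)
        lnr2 = lnr - kappa * d_alpha * z_cm[:, None] * f[None, :] ** 2
        fit2 = _joint_fit(lnr2, mask, wgt, fm, z_cm)
        if fit2 is not None:
            result = {
                "C": fit2["C"],
                "D": fit["D"],
                "d_alpha": d_alpha,
                "A_med": float(np.median(fit2["A"])),
            }
    cache[key] = result
    return result


def _masked_slope(lnr, fc, w, mask, min_bins=6):
    """Weighted slope of lnr vs centered frequency under a per-bin mask."""
    wm = w * mask
    tot = wm.sum(-1)
    ok = mask.sum(-1) >= min_bins
    tot = np.where(tot > 0, tot, 1.0)
    fbar = (wm * fc).sum(-1) / tot
    fcc = fc[None, ...] - fbar[..., None] if fc.ndim == 1 else fc - fbar[..., None]
    num = (wm * fcc * lnr).sum(-1)
    den = (wm * fcc**2).sum(-1)
    den = np.where(den > 0, den, 1.0)
    return num / den, ok


def estimate_ac(
    rf: PlaneWaveRF,
    reference: PlaneWaveRF,
    windows: AnalysisWindow | None = None,
    reference_ac: float = 0.5,
    band_sigmas: float = 1.8,
    snr_gate: float = 5.0,
    beamform_c: float | None = None,
) -> QUSImage:
    """Attenuation map by the spectral-log-difference method (dB/cm/MHz).

    Per analysis window the log of the reference-normalized, noise-
    subtracted power spectrum is regressed on frequency; the depth
    derivative of that slope, divided by the mean acoustic path per unit
    depth, is the local attenuation offset from the reference.  The map is
    a sliding local regression; the pooled ``summary`` regresses the
    laterally averaged slopes over the full usable depth range.  The
    beamforming speed is estimated from the data unless given.
    """
    _check_reference(rf, reference)
    windows = windows or AnalysisWindow()
    probe = rf.probe
    c_bf = _beamform_speed(rf, beamform_c)
    spec, freqs, depths, lats, noise = _window_spectra(rf, windows, assumed_c=c_bf)
    ref_spec, ref_freqs, rdepths, _, ref_noise = _window_spectra(
        reference, windows, assumed_c=reference.probe.c_ref
    )
    nz = min(len(depths), len(rdepths))
    spec, noise, depths = spec[:nz], noise[:nz], depths[:nz]
    ref_spec, ref_noise = ref_spec[:nz], ref_noise[:nz]

    band = np.abs(freqs - probe.center_freq_hz) <= band_sigmas * probe.sigma_f_hz
    f = freqs[band]
    s = spec[:, :, band] - noise[:, :, None]
    r = _resample_log(ref_spec, ref_freqs, f) - ref_noise[:, :, None]
    mask = (s > snr_gate * noise[:, :, None]) & (r > snr_gate * ref_noise[:, :, None])
    s, r = np.maximum(s, 1e-300), np.maximum(r, 1e-300)
    lnr = np.log(s) - np.log(r)
    w = r / r.sum(-1, keepdims=True)
    fc = f - f.mean()
    slopes, good = _masked_slope(lnr, fc, w, mask)  # (z, lat)

    path = _path_factor(probe, _SPECTRAL_FNUM)  # ~2.03 for F# 1
    to_ac = 1.0 / (2.0 * path * DB_TO_NEPER * 1e-6)
    z_cm = depths / 10.0

    half = 2
    nl = slopes.shape[1]
    ac = np.full((nz, nl), reference_ac)
    for zi in range(nz):
        lo, hi = max(0, zi - half), min(nz, zi + half + 1)
        for li in range(nl):
            sel = good[lo:hi, li]
            if sel.sum() < 2:
                continue
            m = np.polyfit(z_cm[lo:hi][sel], slopes[lo:hi, li][sel], 1)[0]
            ac[zi, li] = reference_ac - m * to_ac
    ac = np.clip(ac, 0.0, None)

    # pooled summary: joint whole-region spectral model
    summary = None
    joint = _joint_summary(rf, reference, windows, c_bf, reference_ac)
    if joint is not None:
        summary = float(np.clip(reference_ac + joint["d_alpha"], 0.0, None))

    return QUSImage(
        values=ac,
        parameter="AC",
        pitch_mm=(
            float(depths[1] - depths[0]) if nz > 1 else windows.depth_mm,
            float(lats[1] - lats[0]) if nl > 1 else windows.lateral_mm,
        ),
        origin_mm=(float(depths[0]), float(lats[0])),
        summary=summary,
    )


def _coherence(per_angle: np.ndarray) -> float:
    """Energy-weighted coherence factor of per-angle complex images."""
    n = per_angle.shape[0]
    num = np.abs(per_angle.sum(axis=0)) ** 2
    den = (np.abs(per_angle) ** 2).sum(axis=0)
    return float(num.sum() / (n * den.sum() + 1e-300))


def estimate_sos(
    rf: PlaneWaveRF,
    candidate_speeds: np.ndarray | list,
    patch_grid: tuple[int, int] = (40, 40),
) -> QUSImage:
    """Global sound speed by cross-angle coherence maximization (m/s).

    Each candidate speed beamforms every steering angle onto a central
    patch (full aperture, for maximal defocus sensitivity); the phase
    coherence of the per-angle complex images peaks when the assumed speed
    matches the medium.  A parabola through the peak and its neighbors
    refines the grid search; ties break to the lowest candidate.  If the
    best candidate sits on the boundary of the search range the boundary
    value is returned with a warning flag.
    """
    if len(rf.probe.steering_angles_deg) < 2:
        raise ValueError("SoS requires multiple steering angles")
    candidates = np.asarray(candidate_speeds, dtype=float)
    if candidates.ndim != 1 or len(candidates) < 3:
        raise ValueError("need at least 3 candidate speeds")

    probe = rf.probe
    roi_w, roi_d = rf.roi_mm
    record_mm = probe.n_samples / probe.sampling_rate_hz * probe.c_ref / 2.0 * 1e3
    z_hi = min(roi_d, record_mm) * 0.85
    gx = np.linspace(0.3 * roi_w, 0.7 * roi_w, patch_grid[1])
    gz = np.linspace(0.3 * z_hi, z_hi, patch_grid[0])
    GX, GZ = np.meshgrid(gx, gz)

    analytic = hilbert(rf.data, axis=-1)
    scores = np.array(
        [
            _coherence(
                _patch_das(analytic, probe, rf.roi_mm, c, GX.ravel(), GZ.ravel())
            )
            for c in candidates
        ]
    )
    best = int(np.argmax(scores))  # argmax returns first (lowest) on ties
    warning = None
    if best in (0, len(candidates) - 1):
        c_hat = candidates[best]
        warning = "sound-speed search clamped at candidate range boundary"
    else:
        y0, y1, y2 = scores[best - 1 : best + 2]
        denom = y0 - 2 * y1 + y2
        shift = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
        step = (candidates[best + 1] - candidates[best - 1]) / 2.0
        c_hat = candidates[best] + float(np.clip(shift, -1, 1)) * step
    return QUSImage(
        values=np.array([[c_hat]]),
        parameter="SoS",
        pitch_mm=(roi_d, roi_w),
        summary=float(c_hat),
        warning=warning,
    )


def _quadratic_fit(lnr: np.ndarray, f: np.ndarray, w: np.ndarray, mask: np.ndarray):
    """Weighted masked quadratic fit of lnr(f); f in Hz, fitted in MHz."""
    fm = f / 1e6
    A = np.stack([np.ones_like(fm), fm, fm**2], axis=1)
    wm = w * mask
    out0 = np.zeros(lnr.shape[:-1])
    out2 = np.zeros(lnr.shape[:-1])
    ok = mask.sum(-1) >= 8
    flat_lnr = lnr.reshape(-1, len(f))
    flat_w = np.broadcast_to(wm, lnr.shape).reshape(-1, len(f))
    flat0 = out0.ravel()
    flat2 = out2.ravel()
    for i in range(flat_lnr.shape[0]):
        sw = np.sqrt(flat_w[i])
        coef, *_ = np.linalg.lstsq(A * sw[:, None], flat_lnr[i] * sw, rcond=None)
        flat0[i] = coef[0]
        flat2[i] = coef[2] * 1e-12  # back to per Hz^2
    return out0, out2, ok


def estimate_esd_esc(
    rf: PlaneWaveRF,
    reference: PlaneWaveRF,
    windows: AnalysisWindow | None = None,
    reference_spec: ReferenceSpec | None = None,
    band_sigmas: float = 2.2,
    snr_gate: float = 5.0,
    beamform_c: float | None = None,
) -> tuple[QUSImage, QUSImage]:
    """Scatterer diameter (um) and concentration (/wavelength^2) maps.

    Per analysis window the log reference-normalized power spectrum is
    fitted with a quadratic in frequency.  The linear term absorbs
    attenuation differences; the quadratic term is
    ``-0.827 (2 pi / c)^2 ((ESD/2)^2 - (ESD_ref/2)^2)`` from the Gaussian
    form factor; the intercept yields the concentration after correcting
    for the size-dependent scattering strength convention of the forward
    model.  The pooled ``summary`` fits the average spectrum of all usable
    windows; per-window maps are noisier by an order of magnitude.
    """
    _check_reference(rf, reference)
    windows = windows or AnalysisWindow()
    reference_spec = reference_spec or ReferenceSpec()
    probe = rf.probe
    c_bf = _beamform_speed(rf, beamform_c)
    spec, freqs, depths, lats, noise = _window_spectra(rf, windows, assumed_c=c_bf)
    ref_spec_pw, ref_freqs, rdepths, _, ref_noise = _window_spectra(
        reference, windows, assumed_c=reference.probe.c_ref
    )
    nz = min(len(depths), len(rdepths))
    spec, noise, depths = spec[:nz], noise[:nz], depths[:nz]
    ref_spec_pw, ref_noise = ref_spec_pw[:nz], ref_noise[:nz]

    band = np.abs(freqs - probe.center_freq_hz) <= band_sigmas * probe.sigma_f_hz
    f = freqs[band]
    if np.any(spec[:, :, band] <= 0) or np.any(ref_spec_pw[:, :, band] <= 0):
        raise ValueError("non-positive spectra in the analysis band")

    s = spec[:, :, band] - noise[:, :, None]
    r = _resample_log(ref_spec_pw, ref_freqs, f) - ref_noise[:, :, None]
    mask = (s > snr_gate * noise[:, :, None]) & (r > snr_gate * ref_noise[:, :, None])
    s, r = np.maximum(s, 1e-300), np.maximum(r, 1e-300)
    lnr = np.log(s) - np.log(r)
    w = (r / r.sum(-1, keepdims=True)).mean(axis=(0, 1))

    c0, c2, ok = _quadratic_fit(lnr, f, w[None, None, :], mask)

    kfac = 0.827 * (2.0 * math.pi / probe.c_ref) ** 2
    a_ref_m = reference_spec.esd * 1e-6 / 2.0

    def to_esd_esc(c0v, c2v):
        a_sq = np.maximum(a_ref_m**2 - c2v / kfac, (1e-6) ** 2)
        esd_v = 2.0 * np.sqrt(a_sq) * 1e6
        esc_v = (
            reference_spec.esc
            * np.exp(c0v)
            * (reference_spec.esd / np.maximum(esd_v, 1.0)) ** 2
        )
        return esd_v, esc_v

    esd, esc = to_esd_esc(c0, c2)
    if ok.any() and not ok.all():
        esd[~ok] = np.median(esd[ok])
        esc[~ok] = np.median(esc[ok])

    # pooled summary: average the cleanest windows, single quadratic fit.
    # Only windows with (nearly) the whole band above the noise gate enter
    # the pool, and a bin is kept only if every pooled window passes there,
    # so noise-contaminated bins of deep windows cannot skew the curvature.
    summary_esd = summary_esc = None
    joint = _joint_summary(rf, reference, windows, c_bf)
    if joint is not None:
        e1, e2 = to_esd_esc(joint["A_med"], joint["C"])
        summary_esd, summary_esc = float(e1), float(e2)

    pitch = (
        float(depths[1] - depths[0]) if nz > 1 else windows.depth_mm,
        float(lats[1] - lats[0]) if len(lats) > 1 else windows.lateral_mm,
    )
    origin = (float(depths[0]), float(lats[0]))
    return (
        QUSImage(
            values=esd, parameter="ESD", pitch_mm=pitch, origin_mm=origin,
            summary=summary_esd,
        ),
        QUSImage(
            values=esc, parameter="ESC", pitch_mm=pitch, origin_mm=origin,
            summary=summary_esc,
        ),
    )


def lesion_measurements(
    images: dict[str, QUSImage], phantom: TissuePhantom
) -> dict[str, float]:
    """Mean of each QUS map over the lesion mask, as one cohort-table row.

    Window-grid maps are sampled at the window centers falling inside the
    lesion; if none fall inside, the value nearest the lesion centroid is
    used.
    """
    if not phantom.lesion_mask.any():
        raise ValueError("phantom has no lesion")
    zc, xc = np.nonzero(phantom.lesion_mask)
    cz = zc.mean() * phantom.pixel_pitch_mm
    cx = xc.mean() * phantom.pixel_pitch_mm
    out = {}
    for key, img in images.items():
        vals = img.values
        if vals.size == 1:
            out[key] = float(vals.ravel()[0])
            continue
        gz = img.origin_mm[0] + np.arange(vals.shape[0]) * img.pitch_mm[0]
        gx = img.origin_mm[1] + np.arange(vals.shape[1]) * img.pitch_mm[1]
        GZ, GX = np.meshgrid(gz, gx, indexing="ij")
        iz = np.clip((GZ / phantom.pixel_pitch_mm).astype(int), 0, phantom.shape[0] - 1)
        ix = np.clip((GX / phantom.pixel_pitch_mm).astype(int), 0, phantom.shape[1] - 1)
        inside = phantom.lesion_mask[iz, ix]
        if inside.any():
            out[key] = float(vals[inside].mean())
        else:
            d2 = (GZ - cz) ** 2 + (GX - cx) ** 2
            out[key] = float(vals.ravel()[np.argmin(d2)])
    return out
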