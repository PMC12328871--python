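"""Digital phantom generator for hyperpolarised [1-13C]pyruvate CSI.

Builds a 2-D brain-like phantom with regionally varying metabolite
amplitude maps and known ground-truth AUC ratios, synthesises the
voxel-wise FIDs as sums of decaying complex exponentials (Lorentzian
lines after Fourier transform), encodes them through the phase-encoded
CSI acquisition (box-average to the acquisition grid, orthonormal 2-D
DFT, centric shot ordering, optional per-shot polarisation consumption)
and adds circular complex Gaussian noise.  A matched T2-weighted
anatomical guide image is rendered from the same geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.ndimage import gaussian_filter

from .core import (
    DEFAULT_T1_S,
    METABOLITES,
    AcquisitionProtocol,
    CsiTensor,
    Dynamics,
    PeakModel,
    default_peaks,
)

__all__ = [
    "PhantomSpec",
    "GuideImage",
    "make_brain_phantom",
    "ground_truth_ratios",
    "synthesize_spectral_cube",
    "centric_order",
    "box_downsample",
    "acquire_csi",
    "add_complex_noise",
    "noise_sd_for_snr",
    "make_guide",
    "downsample_guide",
]

_ABBREV = {
    "pyr": "pyruvate",
    "lac": "lactate",
    "bic": "bicarbonate",
    "ala": "alanine",
    "hyd": "pyruvate_hydrate",
    "pyruvate_hydrate": "pyruvate_hydrate",
}

# Mask-mean amplitudes (pyruvate units) for metabolites not pinned by a
# requested ratio; small, as in vivo.
_DEFAULT_MEANS = {"alanine": 0.06, "pyruvate_hydrate": 0.08}


def _canon_metabolite(name: str) -> str:
    key = name.strip().lower()
    if key in METABOLITES:
        return key
    if key in _ABBREV:
        return _ABBREV[key]
    for m in METABOLITES:
        if m.startswith(key):
            return m
    raise ValueError(f"unknown metabolite name {name!r}")


def parse_ratio_key(key) -> tuple[str, str]:
    """``"Lac/Pyr"`` or ``("lactate", "pyruvate")`` -> canonical pair."""
    if isinstance(key, str):
        parts = key.split("/")
        if len(parts) != 2:
            raise ValueError(f"ratio key {key!r} must look like 'Lac/Pyr'")
    else:
        parts = tuple(key)
        if len(parts) != 2:
            raise ValueError(f"ratio key {key!r} must be a metabolite pair")
    return _canon_metabolite(parts[0]), _canon_metabolite(parts[1])


@dataclass(frozen=True)
class GuideImage:
    """2-D anatomical T2-weighted image with grid metadata."""

    pixels: np.ndarray
    grid: int
    fov_mm: tuple[float, float] = (32.0, 32.0)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2 or px.shape[0] != px.shape[1]:
            raise ValueError("guide must be a square 2-D image")
        if px.shape[0] != self.grid:
            raise ValueError("guide grid metadata does not match pixels")
        if not np.all(np.isfinite(px)) or px.min() < 0:
            raise ValueError("guide intensities must be finite and non-negative")
        object.__setattr__(self, "pixels", px)


@dataclass
class PhantomSpec:
    """Ground truth for one synthetic CSI experiment.

    ``geometry`` stores the analytic ellipse parameters (in unit
    coordinates) so the brain mask and the anatomical guide can be
    rendered consistently on any grid.
    """

    grid: int
    brain_mask: np.ndarray
    amplitude_maps: dict[str, np.ndarray]
    peaks: list[PeakModel]
    t1_s: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_T1_S))
    noise_sd: float = 0.0
    seed: int = 0
    geometry: dict = field(default_factory=dict)

    def mask_mean(self, metabolite: str) -> float:
        return float(self.amplitude_maps[metabolite][self.brain_mask].mean())


def _ellipse_mask(grid: int, cx: float, cy: float, ax: float, ay: float,
                  theta: float) -> np.ndarray:
    """Boolean ellipse on pixel centres of a unit square, (row, col)=(y, x)."""
    u = (np.arange(grid) + 0.5) / grid
    yy, xx = np.meshgrid(u, u, indexing="ij")
    c, s = np.cos(theta), np.sin(theta)
    xr = (xx - cx) * c + (yy - cy) * s
    yr = -(xx - cx) * s + (yy - cy) * c
    return (xr / ax) ** 2 + (yr / ay) ** 2 <= 1.0


def _smooth_field(rng: np.random.Generator, grid: int, sigma_frac: float = 0.12
                  ) -> np.ndarray:
    """Smooth zero-mean random field normalised to max |.| = 1."""
    f = gaussian_filter(rng.standard_normal((grid, grid)), sigma=sigma_frac * grid,
                        mode="nearest")
    f -= f.mean()
    peak = np.abs(f).max()
    return f / peak if peak > 0 else f


def _solve_amplitude_means(targets: Mapping[tuple[str, str], float]) -> dict[str, float]:
    """Propagate ratio constraints to per-metabolite mask means (pyruvate = 1)."""
    means: dict[str, float] = {"pyruvate": 1.0}
    pending = dict(targets)
    changed = True
    while pending and changed:
        changed = False
        for (num, den), val in list(pending.items()):
            if den in means and num not in means:
                means[num] = val * means[den]
            elif num in means and den not in means:
                means[den] = means[num] / val
            elif num in means and den in means:
                if abs(means[num] / means[den] - val) > 1e-9 * max(1.0, val):
                    raise ValueError(
                        f"conflicting ratio constraint {num}/{den}={val}")
            else:
                continue
            del pending[(num, den)]
            changed = True
    if pending:
        raise ValueError(f"unresolvable ratio constraints: {sorted(pending)}")
    for m, v in _DEFAULT_MEANS.items():
        means.setdefault(m, v)
    for m in METABOLITES:
        means.setdefault(m, 0.0)
    return means


def make_brain_phantom(seed: int, grid: int = 64,
                       target_ratios: Mapping | None = None,
                       heterogeneity: float = 0.2,
                       fwhm_hz: float = 8.0,
                       noise_sd: float = 0.0) -> PhantomSpec:
    """Build a brain phantom whose whole-mask AUC ratios equal ``target_ratios``.

    The mask is an ellipse occupying roughly a third of the grid; each
    amplitude map carries smooth +/- ``heterogeneity`` spatial variation
    with its mask mean pinned exactly to the requested target, so the
    ground-truth ratios are recoverable to machine precision.
    """
    if grid < 16:
        raise ValueError("grid must be >= 16")
    if target_ratios is None:
        target_ratios = {"lactate/pyruvate": 0.256, "bicarbonate/pyruvate": 0.138}
    targets = {}
    for key, val in dict(target_ratios).items():
        if val <= 0:
            raise ValueError(f"target ratio for {key!r} must be positive")
        targets[parse_ratio_key(key)] = float(val)
    means = _solve_amplitude_means(targets)

    rng = np.random.default_rng(seed)
    geometry = {
        "cx": 0.5 + rng.uniform(-0.02, 0.02),
        "cy": 0.48 + rng.uniform(-0.02, 0.02),
        "ax": 0.36,
        "ay": 0.29,
        "theta": rng.uniform(-0.15, 0.15),
        # interior darker structure of the T2w guide (ventricle-like)
        "vx_off": 0.04, "vy_off": -0.03, "vax": 0.10, "vay": 0.055,
    }
    mask = _ellipse_mask(grid, geometry["cx"], geometry["cy"],
                         geometry["ax"], geometry["ay"], geometry["theta"])
    frac = mask.mean()
    if not (0.30 <= frac <= 0.60):
        raise RuntimeError(f"brain mask occupies {frac:.0%} of grid")

    maps: dict[str, np.ndarray] = {}
    for m in METABOLITES:
        target = means[m]
        amp = np.zeros((grid, grid))
        if target > 0:
            f = _smooth_field(rng, grid)
            amp[mask] = 1.0 + heterogeneity * f[mask]
            amp[mask] *= target / amp[mask].mean()  # pin mask mean exactly
        maps[m] = amp
    return PhantomSpec(grid=grid, brain_mask=mask, amplitude_maps=maps,
                       peaks=default_peaks(fwhm_hz=fwhm_hz),
                       noise_sd=noise_sd, seed=seed, geometry=geometry)


def ground_truth_ratios(phantom: PhantomSpec) -> dict[str, float]:
    """Mask-mean amplitude ratios for the three reported pairs."""
    out = {}
    for num, den in (("lactate", "pyruvate"), ("bicarbonate", "pyruvate"),
                     ("lactate", "bicarbonate")):
        d = phantom.mask_mean(den)
        out[f"{num}/{den}"] = phantom.mask_mean(num) / d if d > 0 else np.nan
    return out


# ---------------------------------------------------------------------------
# Signal synthesis and acquisition


def synthesize_spectral_cube(phantom: PhantomSpec, protocol: AcquisitionProtocol,
                             split_metabolites: bool = False):
    """Voxel-wise FIDs: sum over peaks of A * e^{i phi} e^{(2 pi i f - pi G) t}.

    Each peak's Fourier transform is a complex Lorentzian of FWHM G whose
    integrated (absorption-mode) area is proportional to the amplitude map,
    which is the linearity contract the quantification stage relies on.
    With ``split_metabolites`` the per-metabolite sub-cubes are returned as
    a dict (needed for metabolite-specific T1 dynamics in the acquisition).
    """
    g = phantom.grid
    mx, my = protocol.matrix_size
    if g < mx or g % mx or g % my:
        raise ValueError("phantom grid must be an integer multiple of matrix size")
    t = protocol.time_axis_s()
    components: dict[str, np.ndarray] = {}
    for peak in phantom.peaks:
        peak.validate_in_window(protocol)
        amp = phantom.amplitude_maps.get(peak.metabolite)
        if amp is None:
            continue
        f0 = peak.offset_hz(protocol)
        fid = np.exp((2j * np.pi * f0 - np.pi * peak.fwhm_hz) * t)
        fid = peak.amplitude_scale * np.exp(1j * peak.relative_phase_rad) * fid
        contrib = amp[:, :, None] * fid[None, None, :]
        if peak.metabolite in components:
            components[peak.metabolite] = components[peak.metabolite] + contrib
        else:
            components[peak.metabolite] = contrib
    total = np.zeros((g, g, protocol.spectral_points), dtype=np.complex128)
    for c in components.values():
        total += c
    cube = CsiTensor(total, spatial_domain="spatial", spectral_domain="time",
                     protocol=protocol)
    if split_metabolites:
        return cube, {
            m: CsiTensor(c, spatial_domain="spatial", spectral_domain="time",
                         protocol=protocol)
            for m, c in components.items()
        }
    return cube


def centric_order(mx: int, my: int) -> np.ndarray:
    """Phase-encode visit order: ascending distance from the k-space origin.

    The origin sits at index floor(N/2) on each axis.  Equal-distance
    offsets are ordered by angle from the +kx axis, counter-clockwise.
    Returns an (mx*my, 2) array of (row, col) = (ky, kx) indices.
    """
    ky = np.arange(my) - my // 2
    kx = np.arange(mx) - mx // 2
    KY, KX = np.meshgrid(ky, kx, indexing="ij")
    d2 = KX.ravel() ** 2 + KY.ravel() ** 2
    ang = np.mod(np.arctan2(KY.ravel(), KX.ravel()), 2 * np.pi)
    order = np.lexsort((ang, d2))
    rows = KY.ravel()[order] + my // 2
    cols = KX.ravel()[order] + mx // 2
    return np.stack([rows, cols], axis=1)


def box_downsample(data: np.ndarray, factor_y: int, factor_x: int | None = None
                   ) -> np.ndarray:
    """Block-mean downsampling of the two leading (spatial) axes."""
    fx = factor_x if factor_x is not None else factor_y
    ny, nx = data.shape[:2]
    if ny % factor_y or nx % fx:
        raise ValueError("grid not divisible by downsampling factor")
    shape = (ny // factor_y, factor_y, nx // fx, fx) + data.shape[2:]
    return data.reshape(shape).mean(axis=(1, 3))


def _spatial_fft(img: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(np.fft.fft2(img, axes=(0, 1), norm="ortho"),
                           axes=(0, 1))


def _spatial_ifft(ksp: np.ndarray) -> np.ndarray:
    return np.fft.ifft2(np.fft.ifftshift(ksp, axes=(0, 1)), axes=(0, 1),
                        norm="ortho")


def acquire_csi(cube: CsiTensor, protocol: AcquisitionProtocol,
                dynamics: Dynamics | None = None,
                components: Mapping[str, CsiTensor] | None = None) -> CsiTensor:
    """Encode the high-resolution cube into 2-D phase-encoded k-space.

    Box-averages the cube down to the acquisition matrix, applies an
    orthonormal 2-D DFT over space, and (optionally) scales the FID of
    the n-th visited phase-encode line by the polarisation-consumption
    factor sin(FA) cos(FA)^(n-1) exp(-n TR/T1).  With per-metabolite T1
    values, pass the per-metabolite sub-cubes via ``components``.
    Without dynamics the encoding is unitary (Parseval).
    """
    mx, my = protocol.matrix_size
    g = cube.grid[0]
    if cube.grid[0] % my or cube.grid[1] % mx:
        raise ValueError("cube grid must be divisible by the acquisition matrix")
    if cube.spectral_domain != "time" or cube.spatial_domain != "spatial":
        raise ValueError("acquire_csi expects a spatial/time-domain cube")

    if dynamics is not None and dynamics.consume_rf and isinstance(
            dynamics.t1_s, Mapping):
        if components is None:
            raise ValueError(
                "per-metabolite t1_s requires the per-metabolite sub-cubes "
                "(synthesize_spectral_cube(..., split_metabolites=True))")
        total = None
        for name, sub in components.items():
            t1 = dynamics.t1_s.get(name)
            if t1 is None:
                raise ValueError(f"no T1 given for metabolite {name!r}")
            part = acquire_csi(sub, protocol,
                               Dynamics(consume_rf=True, t1_s=float(t1)))
            total = part.data if total is None else total + part.data
        return CsiTensor(total, spatial_domain="kspace", spectral_domain="time",
                         protocol=protocol)

    lowres = box_downsample(cube.data, cube.grid[0] // my, cube.grid[1] // mx)
    ksp = _spatial_fft(lowres)
    if dynamics is not None and dynamics.consume_rf:
        t1 = float(dynamics.t1_s)
        if protocol.encode_order == "centric":
            order = centric_order(mx, my)
        else:
            order = np.stack(np.meshgrid(np.arange(my), np.arange(mx),
                                         indexing="ij"), axis=-1).reshape(-1, 2)
        scales = dynamics.shot_scale(np.arange(1, len(order) + 1), protocol, t1)
        scale_map = np.empty((my, mx))
        scale_map[order[:, 0], order[:, 1]] = scales
        ksp = ksp * scale_map[:, :, None]
    return CsiTensor(ksp, spatial_domain="kspace", spectral_domain="time",
                     protocol=protocol)


def add_complex_noise(kspace: CsiTensor, sd: float, seed: int) -> CsiTensor:
    """Add i.i.d. circular complex Gaussian noise of total std ``sd``.

    ``sd`` is the standard deviation of the complex sample, i.e. the real
    and imaginary parts each have variance ``sd**2 / 2``.  ``sd = 0``
    returns the input unchanged; a fixed seed reproduces the noise
    bit-identically.
    """
    if sd < 0:
        raise ValueError("noise sd must be non-negative")
    if sd == 0:
        return kspace.with_data(kspace.data.copy())
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(kspace.data.shape) + 1j * rng.standard_normal(
        kspace.data.shape)
    return kspace.with_data(kspace.data + (sd / np.sqrt(2.0)) * noise)


def noise_sd_for_snr(kspace: CsiTensor, snr: float) -> float:
    """Noise std giving peak SNR ``snr`` in the reconstructed spectrum.

    SNR is defined as (max magnitude of the noiseless spatial-domain
    spectrum) / (total complex noise std).  Because every transform in
    the chain is an orthonormal FFT, the noise std is identical in
    k-space/time and image/frequency domains, so the returned value can
    be passed directly to :func:`add_complex_noise` on k-space data.
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    img = _spatial_ifft(kspace.data)
    spec = np.fft.fftshift(np.fft.fft(img, axis=2, norm="ortho"), axes=2)
    return float(np.abs(spec).max() / snr)


# ---------------------------------------------------------------------------
# Anatomical guide


def make_guide(phantom: PhantomSpec, native_grid: int = 128,
               texture: float = 0.08, blur_px: float = 1.0) -> GuideImage:
    """Render the T2-weighted anatomical guide from the phantom geometry.

    Brain parenchyma is bright on a dark background with a darker
    interior (ventricle-like) structure, mild smooth texture and a light
    blur, so guide edges co-localise with the brain-mask boundary.
    """
    if native_grid % 2:
        raise ValueError("native grid must be even")
    geo = phantom.geometry
    if not geo:
        raise ValueError("phantom carries no geometry; cannot render a guide")
    brain = _ellipse_mask(native_grid, geo["cx"], geo["cy"], geo["ax"],
                          geo["ay"], geo["theta"])
    vent = _ellipse_mask(native_grid, geo["cx"] + geo["vx_off"],
                         geo["cy"] + geo["vy_off"], geo["vax"], geo["vay"],
                         geo["theta"])
    img = np.full((native_grid, native_grid), 0.05)
    img[brain] = 1.0
    img[vent & brain] = 0.65
    if texture > 0:
        rng = np.random.default_rng(phantom.seed + 104729)
        img[brain] *= 1.0 + texture * _smooth_field(rng, native_grid)[brain]
    if blur_px > 0:
        img = gaussian_filter(img, sigma=blur_px, mode="nearest")
    img = np.clip(img, 0.0, None)
    return GuideImage(pixels=img, grid=native_grid)


def downsample_guide(guide: GuideImage, factor: int = 2) -> GuideImage:
    """Block-mean downsampling of the guide (128 -> 64 by default)."""
    if factor < 1 or guide.grid % factor:
        raise ValueError("guide grid must be divisible by the factor")
    px = box_downsample(guide.pixels, factor)
    return GuideImage(pixels=px, grid=guide.grid // factor, fov_mm=guide.fov_mm)
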