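"""Core containers for hyperpolarised 13C chemical-shift-imaging (CSI) data.

A CSI acquisition phase-encodes a 2-D grid and records a free-induction
decay (FID) per k-space point, yielding a complex 3-D tensor
(x, y, spectral-or-time).  Every reconstruction stage in this package
transforms a :class:`CsiTensor` and updates its domain flags.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "METABOLITES",
    "AcquisitionProtocol",
    "PeakModel",
    "Dynamics",
    "CsiTensor",
    "default_peaks",
]

#: Canonical metabolite names for the [1-13C]pyruvate experiment.
METABOLITES = ("pyruvate", "lactate", "bicarbonate", "alanine", "pyruvate_hydrate")

#: Literature 13C chemical shifts (ppm) for the resolved peaks.  The carrier
#: is centred on pyruvate; only relative positions matter downstream.
DEFAULT_SHIFTS_PPM: Mapping[str, float] = {
    "pyruvate": 171.0,
    "pyruvate_hydrate": 179.5,
    "alanine": 176.5,
    "lactate": 183.2,
    "bicarbonate": 161.0,
}

#: Spin-lattice relaxation defaults (s) used by the optional per-shot
#: polarisation-consumption model.
DEFAULT_T1_S: Mapping[str, float] = {
    "pyruvate": 30.0,
    "lactate": 30.0,
    "bicarbonate": 20.0,
    "alanine": 30.0,
    "pyruvate_hydrate": 30.0,
}


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Scan parameters of the 2-D phase-encoded CSI protocol.

    Defaults reproduce a single-slice mouse-brain protocol at 1.5 T:
    16x16 phase encodes over a 32x32 mm field of view, 12 mm slice,
    TE/TR = 10/75 ms, 10 deg flip angle, 2 kHz spectral bandwidth over
    128 points, centric encode order, acquisition starting 13 s after
    injection.
    """

    matrix_size: tuple[int, int] = (16, 16)
    fov_mm: tuple[float, float] = (32.0, 32.0)
    slice_thickness_mm: float = 12.0
    te_ms: float = 10.0
    tr_ms: float = 75.0
    flip_angle_deg: float = 10.0
    spectral_bandwidth_hz: float = 2000.0
    spectral_points: int = 128
    encode_order: str = "centric"
    post_injection_delay_s: float = 13.0
    carrier_ppm: float = 171.0
    ppm_window: float = 122.4  # printed spectral width of the 2 kHz window

    def __post_init__(self) -> None:
        mx, my = self.matrix_size
        if mx < 2 or my < 2 or mx % 2 or my % 2:
            raise ValueError("matrix sizes must be even integers >= 2")
        n = self.spectral_points
        if n < 2 or (n & (n - 1)):
            raise ValueError("spectral_points must be a power of two")
        if not (0.0 < self.flip_angle_deg < 90.0):
            raise ValueError("flip_angle_deg must lie in (0, 90)")
        if self.tr_ms <= 0:
            raise ValueError("tr_ms must be positive")
        if self.encode_order not in ("centric", "linear"):
            raise ValueError(f"unknown encode_order {self.encode_order!r}")

    @property
    def n_shots(self) -> int:
        return self.matrix_size[0] * self.matrix_size[1]

    @property
    def scan_duration_s(self) -> float:
        """Nominal scan duration: one TR per phase-encode shot."""
        return self.n_shots * self.tr_ms / 1000.0

    @property
    def dwell_s(self) -> float:
        return 1.0 / self.spectral_bandwidth_hz

    @property
    def hz_per_ppm(self) -> float:
        return self.spectral_bandwidth_hz / self.ppm_window

    def time_axis_s(self) -> np.ndarray:
        return np.arange(self.spectral_points) * self.dwell_s

    def freq_axis_hz(self, n_points: int | None = None) -> np.ndarray:
        """Frequency offsets (Hz from carrier) of the fftshifted spectrum."""
        n = n_points or self.spectral_points
        return (np.arange(n) - n // 2) * (self.spectral_bandwidth_hz / n)

    def ppm_axis(self, n_points: int | None = None) -> np.ndarray:
        return self.carrier_ppm + self.freq_axis_hz(n_points) / self.hz_per_ppm


@dataclass(frozen=True)
class PeakModel:
    """One Lorentzian resonance of the 13C spectrum."""

    metabolite: str
    chemical_shift_ppm: float
    fwhm_hz: float = 8.0
    relative_phase_rad: float = 0.0
    amplitude_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.metabolite not in METABOLITES:
            raise ValueError(f"unknown metabolite {self.metabolite!r}")
        if self.fwhm_hz <= 0:
            raise ValueError("fwhm_hz must be positive")

    def offset_hz(self, protocol: AcquisitionProtocol) -> float:
        return (self.chemical_shift_ppm - protocol.carrier_ppm) * protocol.hz_per_ppm

    def validate_in_window(self, protocol: AcquisitionProtocol) -> None:
        half = protocol.spectral_bandwidth_hz / 2.0
        off = self.offset_hz(protocol)
        if not (-half < off < half):
            raise ValueError(
                f"peak {self.metabolite} at {off:.1f} Hz lies outside the "
                f"+/-{half:.0f} Hz spectral window"
            )
        if self.fwhm_hz >= protocol.spectral_bandwidth_hz / 4:
            raise ValueError("fwhm_hz must be < spectral_bandwidth_hz / 4")


def default_peaks(fwhm_hz: float = 8.0) -> list[PeakModel]:
    """The five resolved peaks of the in-vivo [1-13C]pyruvate spectrum."""
    return [
        PeakModel(m, DEFAULT_SHIFTS_PPM[m], fwhm_hz=fwhm_hz) for m in METABOLITES
    ]


@dataclass(frozen=True)
class Dynamics:
    """Per-shot polarisation consumption model.

    Hyperpolarised magnetisation is non-renewable: each RF excitation
    consumes cos(FA) of the longitudinal store while T1 decays the rest.
    Shot n (1-based) therefore carries transverse signal
    ``sin(FA) * cos(FA)**(n-1) * exp(-n*TR/T1)``.
    """

    consume_rf: bool = True
    t1_s: float | Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_T1_S))

    def shot_scale(self, n: np.ndarray | int, protocol: AcquisitionProtocol,
                   t1_s: float) -> np.ndarray | float:
        if not self.consume_rf:
            return np.ones_like(np.asarray(n, dtype=float))
        fa = np.deg2rad(protocol.flip_angle_deg)
        n = np.asarray(n, dtype=float)
        tr = protocol.tr_ms / 1000.0
        return np.sin(fa) * np.cos(fa) ** (n - 1) * np.exp(-n * tr / t1_s)


@dataclass
class CsiTensor:
    """Complex 3-D CSI array (x, y, spectral) with domain bookkeeping.

    ``spatial_domain`` is ``"spatial"`` or ``"kspace"``; ``spectral_domain``
    is ``"time"`` or ``"frequency"``.  Every transform returns a new tensor
    with updated flags; the ppm axis exists only in the frequency domain.
    """

    data: np.ndarray
    spatial_domain: str = "spatial"
    spectral_domain: str = "time"
    protocol: AcquisitionProtocol | None = None
    ppm_axis: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("CsiTensor data must be 3-D (x, y, spectral)")
        if not np.iscomplexobj(self.data):
            self.data = self.data.astype(np.complex128)
        if self.spatial_domain not in ("spatial", "kspace"):
            raise ValueError(f"bad spatial_domain {self.spatial_domain!r}")
        if self.spectral_domain not in ("time", "frequency"):
            raise ValueError(f"bad spectral_domain {self.spectral_domain!r}")
        if self.ppm_axis is not None:
            self.ppm_axis = np.asarray(self.ppm_axis, dtype=float)
            if self.ppm_axis.size != self.data.shape[2]:
                raise ValueError("ppm_axis length must match spectral axis")
            d = np.diff(self.ppm_axis)
            if not (np.all(d > 0) or np.all(d < 0)):
                raise ValueError("ppm_axis must be strictly monotone")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def grid(self) -> tuple[int, int]:
        return self.data.shape[:2]

    def with_data(self, data: np.ndarray, **flag_updates) -> "CsiTensor":
        kwargs = dict(
            spatial_domain=self.spatial_domain,
            spectral_domain=self.spectral_domain,
            protocol=self.protocol,
            ppm_axis=self.ppm_axis,
        )
        kwargs.update(flag_updates)
        return CsiTensor(data, **kwargs)

    def energy(self) -> float:
        return float(np.sum(np.abs(self.data) ** 2))
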