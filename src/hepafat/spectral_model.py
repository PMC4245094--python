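"""Multipeak fat spectral model and forward signal equations.

Liver triglyceride protons resonate at several chemical shifts; water resonates
at 4.7 ppm. Both the gradient-echo imaging branch and the spectroscopy branch
of proton-density fat fraction (PDFF) estimation share one description of that
spectrum: a small set of peaks, each with a chemical shift (ppm) and a relative
amplitude (fraction of total fat proton density). Peaks between 0.5 and 3.0 ppm
are directly *measurable* in a non-water-suppressed spectrum; peaks close to
water (the 4.2 and 5.3 ppm resonances) are *hidden* underneath the water line
and must be restored from their published relative amplitudes.

This module holds the spectrum container, the acquisition protocol and tissue
descriptions, and the noise-free forward models used both to simulate data and
to fit it:

* ``fat_modulation`` -- the complex dephasing factor of the fat ensemble at a
  given echo time,
* ``gre_signal`` -- the magnitude spoiled gradient-echo signal
  ``|W + F c(TE)| exp(-TE/T2*)``,
* ``pdff_from_densities`` -- the defining ratio ``F / (F + W)``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "GYROMAGNETIC_RATIO_MHZ_PER_T",
    "WATER_PPM",
    "FatSpectrum",
    "AcquisitionProtocol",
    "TissueState",
    "default_fat_spectrum",
    "triple_echo_protocol",
    "multi_echo_protocol",
    "ppm_to_hz",
    "fat_modulation",
    "gre_signal",
    "pdff_from_densities",
]

#: Proton gyromagnetic ratio, MHz per tesla.
GYROMAGNETIC_RATIO_MHZ_PER_T = 42.576

#: Chemical shift of tissue water, ppm.
WATER_PPM = 4.7

# Measurable fat region and the half-width of the "hidden under water" band.
_MEASURABLE_PPM_LOW = 0.5
_MEASURABLE_PPM_HIGH = 3.0
_HIDDEN_PPM_HALFWIDTH = 0.8


@dataclass(frozen=True)
class FatSpectrum:
    """Multipeak fat resonance model.

    Parameters
    ----------
    peaks
        Sequence of ``(chemical_shift_ppm, relative_amplitude)`` pairs.
        Amplitudes must be positive and sum to 1 (within 1e-9).
    water_shift_ppm
        Chemical shift of water, default 4.7 ppm.

    Every peak must fall either in the measurable band (0.5--3.0 ppm) or in
    the hidden band (within 0.8 ppm of water); the two bands are disjoint,
    so the measurable/hidden partition is disjoint and exhaustive.
    """

    peaks: tuple[tuple[float, float], ...]
    water_shift_ppm: float = WATER_PPM

    def __post_init__(self) -> None:
        peaks = tuple((float(s), float(a)) for s, a in self.peaks)
        object.__setattr__(self, "peaks", peaks)
        if not peaks:
            raise ValueError("FatSpectrum requires at least one peak")
        total = 0.0
        for shift, amp in peaks:
            if amp <= 0:
                raise ValueError(f"relative amplitude must be positive, got {amp}")
            if not (0.0 <= shift <= 6.0):
                raise ValueError(f"chemical shift {shift} ppm outside [0, 6] ppm")
            if not (self._is_measurable(shift) or self._is_hidden(shift)):
                raise ValueError(
                    f"peak at {shift} ppm is neither measurable "
                    f"({_MEASURABLE_PPM_LOW}-{_MEASURABLE_PPM_HIGH} ppm) nor hidden "
                    f"(within {_HIDDEN_PPM_HALFWIDTH} ppm of water)"
                )
            total += amp
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"relative amplitudes must sum to 1, got {total!r}")

    def _is_measurable(self, shift: float) -> bool:
        return _MEASURABLE_PPM_LOW <= shift <= _MEASURABLE_PPM_HIGH

    def _is_hidden(self, shift: float) -> bool:
        return abs(shift - self.water_shift_ppm) <= _HIDDEN_PPM_HALFWIDTH

    @property
    def measurable_peaks(self) -> tuple[tuple[float, float], ...]:
        return tuple(p for p in self.peaks if self._is_measurable(p[0]))

    @property
    def hidden_peaks(self) -> tuple[tuple[float, float], ...]:
        return tuple(p for p in self.peaks if self._is_hidden(p[0]))

    @property
    def measurable_fraction(self) -> float:
        """Fraction of fat proton density in directly measurable peaks."""
        return sum(a for _, a in self.measurable_peaks)

    @property
    def hidden_fraction(self) -> float:
        """Fraction of fat proton density hidden under the water line."""
        return sum(a for _, a in self.hidden_peaks)

    # --- JSON interchange -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "water_shift_ppm": self.water_shift_ppm,
            "peaks": [{"shift_ppm": s, "amplitude": a} for s, a in self.peaks],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "FatSpectrum":
        peaks = tuple((p["shift_ppm"], p["amplitude"]) for p in d["peaks"])
        return cls(peaks=peaks, water_shift_ppm=d.get("water_shift_ppm", WATER_PPM))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "FatSpectrum":
        return cls.from_dict(json.loads(Path(path).read_text()))


def default_fat_spectrum() -> FatSpectrum:
    """Six-peak liver fat spectrum (Hamilton-type liver triglyceride model).

    Shifts 5.3, 4.2, 2.75, 2.1, 1.3, 0.9 ppm with relative amplitudes
    0.047, 0.039, 0.006, 0.120, 0.700, 0.088. The 5.3 and 4.2 ppm peaks sit
    under/near the water line and form the hidden subset (8.6% of fat
    protons); the remaining 91.4% are directly measurable.
    """
    return FatSpectrum(
        peaks=(
            (5.3, 0.047),
            (4.2, 0.039),
            (2.75, 0.006),
            (2.1, 0.120),
            (1.3, 0.700),
            (0.9, 0.088),
        )
    )


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Spoiled gradient-echo acquisition descriptor.

    ``label`` is ``"triple"`` (3 echoes) or ``"multi"`` (7 echoes).
    """

    echo_times_ms: tuple[float, ...]
    repetition_time_ms: float
    flip_angle_deg: float
    field_strength_T: float = 3.0
    label: str = "triple"

    def __post_init__(self) -> None:
        te = tuple(float(t) for t in self.echo_times_ms)
        object.__setattr__(self, "echo_times_ms", te)
        if any(t <= 0 for t in te):
            raise ValueError("echo times must be positive")
        if any(b <= a for a, b in zip(te, te[1:])):
            raise ValueError("echo times must be strictly increasing")
        if self.label not in ("triple", "multi"):
            raise ValueError(f"unknown protocol label {self.label!r}")
        expected = {"triple": 3, "multi": 7}[self.label]
        if len(te) != expected:
            raise ValueError(
                f"{self.label} protocol requires {expected} echoes, got {len(te)}"
            )
        if self.repetition_time_ms <= 0 or self.flip_angle_deg <= 0:
            raise ValueError("TR and flip angle must be positive")

    @property
    def n_echoes(self) -> int:
        return len(self.echo_times_ms)


def triple_echo_protocol(field_strength_T: float = 3.0) -> AcquisitionProtocol:
    """Breath-hold triple-echo protocol: TE 2.3/3.45/4.6 ms, TR 180 ms, flip 30 deg."""
    return AcquisitionProtocol(
        echo_times_ms=(2.3, 3.45, 4.6),
        repetition_time_ms=180.0,
        flip_angle_deg=30.0,
        field_strength_T=field_strength_T,
        label="triple",
    )


def multi_echo_protocol(field_strength_T: float = 3.0) -> AcquisitionProtocol:
    """Multi-echo protocol: TE 1.15--8.05 ms in 1.15 ms steps, TR 180 ms, flip 15 deg."""
    return AcquisitionProtocol(
        echo_times_ms=(1.15, 2.3, 3.45, 4.6, 5.75, 6.9, 8.05),
        repetition_time_ms=180.0,
        flip_angle_deg=15.0,
        field_strength_T=field_strength_T,
        label="multi",
    )


@dataclass
class TissueState:
    """Water/fat proton densities and relaxation parameters of one voxel/ROI.

    Densities are in arbitrary proton-density units; only their ratio (the
    PDFF) is meaningful. ``per_peak_t2_ms`` maps a fat peak's chemical shift
    (ppm) to its spin-echo T2; peaks absent from the map fall back to
    ``default_fat_t2_ms`` in the simulator.
    """

    water_density: float
    fat_density: float
    t2star_ms: float
    water_t2_ms: float = 25.0
    per_peak_t2_ms: dict[float, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.water_density < 0 or self.fat_density < 0:
            raise ValueError("proton densities must be nonnegative")
        if self.t2star_ms <= 0:
            raise ValueError("T2* must be positive")
        if self.water_t2_ms <= 0:
            raise ValueError("water T2 must be positive")
        for ppm, t2 in self.per_peak_t2_ms.items():
            if t2 <= 0:
                raise ValueError(f"T2 of peak at {ppm} ppm must be positive")

    @property
    def pdff(self) -> float:
        return pdff_from_densities(self.fat_density, self.water_density)


def ppm_to_hz(shift_ppm: float, field_T: float = 3.0,
              water_ppm: float = WATER_PPM) -> float:
    """Frequency offset (Hz) of a resonance relative to water.

    ``(shift - water) * 42.576 MHz/T * B0``; negative for upfield fat peaks.
    """
    return (shift_ppm - water_ppm) * GYROMAGNETIC_RATIO_MHZ_PER_T * field_T


def fat_modulation(te_ms: float, spectrum: FatSpectrum,
                   field_T: float = 3.0) -> complex:
    """Complex dephasing factor of the fat ensemble at echo time ``te_ms``.

    ``c(TE) = sum_p a_p exp(i 2 pi df_p TE)`` with ``df_p`` the peak's offset
    from water in Hz. ``|c| <= 1`` with equality at TE = 0.
    """
    if te_ms < 0:
        raise ValueError("echo time must be nonnegative")
    t_s = te_ms * 1e-3
    c = 0.0 + 0.0j
    for shift, amp in spectrum.peaks:
        df = ppm_to_hz(shift, field_T, spectrum.water_shift_ppm)
        c += amp * np.exp(2j * np.pi * df * t_s)
    return complex(c)


def _spoiled_gre_scale(flip_angle_deg: float, tr_ms: float, t1_ms: float) -> float:
    """Steady-state spoiled GRE scale factor sin(a)(1-E1)/(1-cos(a)E1)."""
    a = math.radians(flip_angle_deg)
    e1 = math.exp(-tr_ms / t1_ms)
    return math.sin(a) * (1.0 - e1) / (1.0 - math.cos(a) * e1)


def gre_signal(tissue: TissueState, protocol: AcquisitionProtocol,
               spectrum: FatSpectrum, t1_ms: float | None = None) -> np.ndarray:
    """Noise-free magnitude gradient-echo signal at each protocol echo.

    ``S(TE) = |W + F c(TE)| exp(-TE / T2*)``. T1 weighting is omitted by
    default (low flip angles at short TR make the signal approximately
    proton-density weighted); pass ``t1_ms`` to apply a global steady-state
    scale shared by water and fat (it cancels in the PDFF and exists only
    for sensitivity studies).
    """
    if tissue.water_density == 0 and tissue.fat_density == 0:
        raise ValueError("water and fat densities cannot both be zero")
    if tissue.t2star_ms <= 0:
        raise ValueError("T2* must be positive")
    te = np.asarray(protocol.echo_times_ms, dtype=float)
    c = np.array([fat_modulation(t, spectrum, protocol.field_strength_T) for t in te])
    s = np.abs(tissue.water_density + tissue.fat_density * c)
    s = s * np.exp(-te / tissue.t2star_ms)
    if t1_ms is not None:
        s = s * _spoiled_gre_scale(protocol.flip_angle_deg,
                                   protocol.repetition_time_ms, t1_ms)
    return s


def pdff_from_densities(fat_density: float, water_density: float) -> float:
    """Proton-density fat fraction ``F / (F + W)``, in [0, 1]."""
    if fat_density < 0 or water_density < 0:
        raise ValueError("proton densities must be nonnegative")
    total = fat_density + water_density
    if total == 0:
        raise ValueError("fat and water densities cannot both be zero")
    return fat_density / total
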