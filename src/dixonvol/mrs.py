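"""Single-voxel MRS fat quantification with T1/T2 relaxation correction.

A PRESS acquisition at long TR measures a water peak amplitude Sw and a
summed lipid amplitude Sf (peaks at 1.3, 0.9 and 1.6 ppm). Both amplitudes
are attenuated by transverse decay exp(-TE/T2) and longitudinal saturation
(1 - exp(-TR/T1)), with different constants for water and fat, so the raw
ratio is biased. Dividing each amplitude by its decay factor recovers
amplitudes proportional to proton densities, and

    PDFF (%) = 100 * Sf / (Sf + Sw)

on the corrected amplitudes is the proton-density fat fraction.

Default constants are for liver at 3 T: TE = 35 ms, TR = 3000 ms,
T2 water/fat = 30/52 ms, T1 water/fat = 990/402 ms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "AcquisitionConstants",
    "MRSMeasurement",
    "decay_factor",
    "relaxation_correct",
    "mrs_pdff",
    "integrate_toy_spectrum",
]

# Lipid resonances summed into Sf, and the water resonance, in ppm.
LIPID_PPM = (1.3, 0.9, 1.6)
WATER_PPM = 4.7

DEFAULT_LIPID_WINDOWS = ((1.15, 1.45), (0.75, 1.05), (1.45, 1.75))
DEFAULT_WATER_WINDOW = (4.2, 5.2)


@dataclass(frozen=True)
class AcquisitionConstants:
    """Echo/repetition times and relaxation constants, all in ms."""

    TE: float = 35.0
    TR: float = 3000.0
    T2w: float = 30.0
    T2f: float = 52.0
    T1w: float = 990.0
    T1f: float = 402.0

    def __post_init__(self) -> None:
        for name in ("TE", "TR", "T2w", "T2f", "T1w", "T1f"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.TE >= self.TR:
            raise ValueError(f"TE ({self.TE} ms) must be < TR ({self.TR} ms)")


@dataclass(frozen=True)
class MRSMeasurement:
    """Raw water/summed-lipid peak amplitudes plus acquisition constants."""

    sw_raw: float
    sf_raw: float
    acq: AcquisitionConstants = AcquisitionConstants()

    def __post_init__(self) -> None:
        if self.sw_raw < 0 or self.sf_raw < 0:
            raise ValueError("peak amplitudes must be non-negative")
        if self.sw_raw == 0 and self.sf_raw == 0:
            raise ValueError("water and lipid amplitudes are both zero")


def decay_factor(TE: float, TR: float, T1: float, T2: float) -> float:
    """Signal attenuation exp(-TE/T2) * (1 - exp(-TR/T1)) for one species."""
    if T1 <= 0 or T2 <= 0:
        raise ValueError("T1 and T2 must be strictly positive")
    return float(np.exp(-TE / T2) * (1.0 - np.exp(-TR / T1)))


def relaxation_correct(amplitude_raw: float, TE: float, TR: float, T1: float, T2: float) -> float:
    """Undo T2 decay and T1 saturation on a raw peak amplitude.

    Divides by exp(-TE/T2) * (1 - exp(-TR/T1)); linear in the amplitude and
    always >= the raw value (the decay factor is < 1).
    """
    if amplitude_raw < 0:
        raise ValueError("amplitude must be non-negative")
    return float(amplitude_raw) / decay_factor(TE, TR, T1, T2)


def mrs_pdff(m: MRSMeasurement) -> float:
    """Relaxation-corrected PDFF in percent, 100 * Sf / (Sf + Sw)."""
    a = m.acq
    sf = relaxation_correct(m.sf_raw, a.TE, a.TR, a.T1f, a.T2f)
    sw = relaxation_correct(m.sw_raw, a.TE, a.TR, a.T1w, a.T2w)
    total = sf + sw
    if total <= 0:
        raise ValueError("corrected water and fat amplitudes are both zero")
    return 100.0 * sf / total


def _window_area(ppm: np.ndarray, amp: np.ndarray, window: tuple[float, float]) -> float:
    """Trapezoidal area inside a ppm window above a linear local baseline."""
    lo, hi = sorted(window)
    if lo < ppm.min() - 1e-12 or hi > ppm.max() + 1e-12:
        raise ValueError(f"window {window} outside sampled ppm range")
    a_lo = float(np.interp(lo, ppm, amp))
    a_hi = float(np.interp(hi, ppm, amp))
    sel = (ppm > lo) & (ppm < hi)
    xs = np.concatenate(([lo], ppm[sel], [hi]))
    ys = np.concatenate(([a_lo], amp[sel], [a_hi]))
    baseline = a_lo + (a_hi - a_lo) * (xs - lo) / (hi - lo) if hi > lo else xs * 0
    area = float(np.trapezoid(ys - baseline, xs))
    return max(area, 0.0)


def integrate_toy_spectrum(
    ppm: np.ndarray,
    amplitude: np.ndarray,
    water_window: tuple[float, float] = DEFAULT_WATER_WINDOW,
    lipid_windows: tuple[tuple[float, float], ...] = DEFAULT_LIPID_WINDOWS,
    acq: AcquisitionConstants = AcquisitionConstants(),
) -> MRSMeasurement:
    """Integrate a sampled synthetic spectrum into an :class:`MRSMeasurement`.

    This is a deliberately simple stand-in for basis-set spectral fitting,
    intended only for spectra this package synthesises: each window's
    amplitude is the trapezoidal area above a straight baseline joining the
    window end-points, and the lipid windows (centred at 1.3, 0.9, 1.6 ppm)
    are summed into Sf.
    """
    ppm = np.asarray(ppm, dtype=float)
    amplitude = np.asarray(amplitude, dtype=float)
    if ppm.ndim != 1 or ppm.shape != amplitude.shape:
        raise ValueError("ppm and amplitude must be 1D arrays of equal length")
    if not np.all(np.diff(ppm) > 0):
        order = np.argsort(ppm)
        ppm, amplitude = ppm[order], amplitude[order]
    wlo, whi = sorted(water_window)
    for lw in lipid_windows:
        llo, lhi = sorted(lw)
        if llo < whi and wlo < lhi:
            raise ValueError(f"water window {water_window} overlaps lipid window {lw}")
    sw = _window_area(ppm, amplitude, water_window)
    sf = sum(_window_area(ppm, amplitude, lw) for lw in lipid_windows)
    return MRSMeasurement(sw_raw=sw, sf_raw=sf, acq=acq)
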