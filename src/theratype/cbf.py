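"""Ciliary beat frequency from time-lapse intensity stacks.

Beating cilia modulate pixel intensity periodically; the beat frequency of
a field of view is the dominant peak of its temporal power spectrum.  Each
pixel's series is mean-detrended, Hann-windowed and Fourier-transformed;
the field spectrum is the mean per-pixel power spectrum (averaging power
after the transform keeps cilia beating out of phase from cancelling), and
the dominant frequency is the argmax within a search band.  Field estimates
are averaged per culture, then mean ± SEM across cultures per participant,
with a physiological-range flag (default 3.0–11.1 Hz) as QC rather than a
hard filter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PixelStack",
    "SpectrumResult",
    "CBF_PHYSIOLOGICAL_RANGE",
    "DEFAULT_BAND",
    "field_spectrum",
    "aggregate_cbf",
    "read_tiff_stack",
]

#: Beat-frequency range (Hz) regarded as physiological for airway epithelia.
CBF_PHYSIOLOGICAL_RANGE = (3.0, 11.1)

#: Default spectral search band (Hz) — deliberately wider than the
#: physiological range so out-of-range beats are reported, then flagged.
DEFAULT_BAND = (0.5, 30.0)

# Pixels whose temporal variance falls below this fraction of the maximum
# pixel variance are treated as static background.
_VARIANCE_FLOOR = 1e-12


@dataclass
class PixelStack:
    """Time-lapse intensity stack (time × height × width) for one field."""

    frames: np.ndarray
    frame_rate: float
    field_id: str = ""
    culture_id: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a 3-D array (time, height, width)")
        if self.frames.shape[0] < 2:
            raise ValueError("stack needs at least two frames")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    @property
    def nyquist(self) -> float:
        return self.frame_rate / 2.0


@dataclass
class SpectrumResult:
    frequencies: np.ndarray
    power: np.ndarray
    dominant_frequency: float
    band: tuple[float, float]
    bin_width: float
    field_id: str = ""
    culture_id: str = ""

    @property
    def in_physiological_range(self) -> bool:
        lo, hi = CBF_PHYSIOLOGICAL_RANGE
        return lo <= self.dominant_frequency <= hi


def field_spectrum(
    stack: PixelStack, band: tuple[float, float] = DEFAULT_BAND
) -> SpectrumResult:
    """Mean per-pixel power spectrum and its dominant peak within ``band``."""
    lo, hi = band
    if not (0 < lo < hi):
        raise ValueError(f"band must satisfy 0 < low < high, got {band}")
    if hi >= stack.nyquist:
        raise ValueError(
            f"band upper edge {hi} Hz is not below the Nyquist frequency "
            f"{stack.nyquist} Hz"
        )
    n_t = stack.frames.shape[0]
    pixels = stack.frames.reshape(n_t, -1)
    variances = pixels.var(axis=0)
    vmax = variances.max()
    if vmax == 0.0:
        raise ValueError("no oscillation: all pixel series are constant")
    active = variances > _VARIANCE_FLOOR * vmax
    pixels = pixels[:, active]

    detrended = pixels - pixels.mean(axis=0)
    window = np.hanning(n_t)
    nfft = 1 << (n_t - 1).bit_length()  # next power of two
    spectra = np.fft.rfft(detrended * window[:, None], n=nfft, axis=0)
    power = np.mean(np.abs(spectra) ** 2, axis=1)
    freqs = np.fft.rfftfreq(nfft, d=1.0 / stack.frame_rate)

    in_band = (freqs >= lo) & (freqs <= hi)
    band_power = np.where(in_band, power, -np.inf)
    dominant = float(freqs[int(np.argmax(band_power))])
    return SpectrumResult(
        frequencies=freqs,
        power=power,
        dominant_frequency=dominant,
        band=(lo, hi),
        bin_width=float(stack.frame_rate / nfft),
        field_id=stack.field_id,
        culture_id=stack.culture_id,
    )


def aggregate_cbf(
    results: list[SpectrumResult],
    physiological_range: tuple[float, float] = CBF_PHYSIOLOGICAL_RANGE,
) -> pd.DataFrame:
    """Culture-level CBF summary: mean field frequency per culture plus flags.

    Returns one row per culture with columns ``culture_id``, ``n_fields``,
    ``mean_cbf_hz`` and ``in_physiological_range``.  Participant-level
    mean ± SEM across cultures is left to :func:`theratype.report.aggregate`.
    """
    if not results:
        raise ValueError("no spectrum results to aggregate")
    lo, hi = physiological_range
    rows = []
    df = pd.DataFrame(
        {
            "culture_id": [r.culture_id for r in results],
            "cbf": [r.dominant_frequency for r in results],
        }
    )
    for culture, grp in df.groupby("culture_id", sort=True):
        mean = float(grp["cbf"].mean())
        rows.append(
            {
                "culture_id": culture,
                "n_fields": int(len(grp)),
                "mean_cbf_hz": mean,
                "in_physiological_range": lo <= mean <= hi,
            }
        )
    return pd.DataFrame(rows)


def read_tiff_stack(path, frame_rate: float, **labels) -> PixelStack:
    """Read a multi-page TIFF into a :class:`PixelStack`."""
    import tifffile

    frames = tifffile.imread(str(path))
    if frames.ndim == 2:
        frames = frames[None, ...]
    return PixelStack(frames=frames, frame_rate=frame_rate, **labels)
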