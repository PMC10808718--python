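"""Canonical hemodynamic response function (double-gamma, SPM convention).

The kernel is the difference of two gamma densities: a positive response
peaking ~6 s after a neural event and a delayed undershoot peaking ~16 s,
with the undershoot scaled down by the peak:undershoot ratio. The kernel is
normalized to unit peak so that regressor amplitudes are in units of the
neural input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class CanonicalHrf:
    """Sampled canonical HRF kernel.

    Parameters follow the SPM convention: delays are the gamma *means*
    (shape = delay / dispersion, scale = dispersion).

    Attributes
    ----------
    peak_delay, undershoot_delay : float
        Response and undershoot delays in seconds (defaults 6 and 16).
    peak_disp, undershoot_disp : float
        Dispersions in seconds (defaults 1 and 1).
    ratio : float
        Peak-to-undershoot amplitude ratio (default 6).
    length : float
        Kernel support in seconds (default 32).
    dt : float
        Fine sampling step in seconds.
    tr : float
        Volume repetition time in seconds.
    """

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_disp: float = 1.0
    undershoot_disp: float = 1.0
    ratio: float = 6.0
    length: float = 32.0
    dt: float = 0.1
    tr: float = 1.0
    kernel_dt: np.ndarray = field(repr=False, default=None)
    kernel_tr: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if self.tr <= 0 or self.dt <= 0:
            raise ValueError("tr and dt must be positive")
        object.__setattr__(self, "kernel_dt", self._sample(self.dt))
        object.__setattr__(self, "kernel_tr", self._sample(self.tr))

    def _sample(self, step: float) -> np.ndarray:
        t = np.arange(0.0, self.length + step / 2, step)
        peak = stats.gamma.pdf(t, self.peak_delay / self.peak_disp, scale=self.peak_disp)
        under = stats.gamma.pdf(
            t, self.undershoot_delay / self.undershoot_disp, scale=self.undershoot_disp
        )
        h = peak - under / self.ratio
        return h / h.max()


def build_chrf(tr: float = 1.0, dt: float = 0.1) -> CanonicalHrf:
    """Build the canonical double-gamma kernel sampled at ``dt`` and ``tr``."""
    return CanonicalHrf(tr=tr, dt=dt)


def convolve_causal(signal: np.ndarray, kernel: np.ndarray, step: float = 1.0) -> np.ndarray:
    """Causally convolve ``signal`` with ``kernel``; output trimmed to input length.

    ``step`` scales the discrete sum so the convolution approximates the
    continuous integral when the inputs live on a fine time grid.
    """
    signal = np.asarray(signal, dtype=float)
    if kernel.size > signal.size:
        raise ValueError(
            f"kernel ({kernel.size} samples) longer than signal ({signal.size} samples)"
        )
    return np.convolve(signal, kernel)[: signal.size] * step
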