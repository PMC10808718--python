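"""Causal per-volume processing of the feedback ROI signal.

The chain mirrors what a real-time neurofeedback system applies to the raw
ROI average before it can be displayed: spike removal with a scalar Kalman
filter, drift removal by an expanding-window (cumulative) least-squares fit
of a constant plus linear trend, a running first-order autoregressive
estimate for serial-correlation accounting, and adaptive dynamic-range
scaling onto [0, 1] using the running average of the 5% highest and lowest
values observed so far.

Every step is strictly causal: the output at volume t depends only on
volumes 1..t. ``OnlineChain.process_volume`` composes the steps in order
(despike -> detrend -> AR(1) -> scale) and returns all intermediates.
By default the *displayed* (scaled) signal is the detrended level: a
prewhitened innovation tracks the change of the target signal rather than
its state, which would break the intended coupling between display and
region activity. Set ``apply_ar1`` to scale the whitened series instead;
the AR(1) estimate and whitened value are computed and reported either
way.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

AR1_BOUND = 0.95  # |rho| ceiling for the running AR(1) estimate


@dataclass
class ChainSettings:
    """Tunable constants of the online chain.

    kalman_process_var / kalman_obs_var are chosen so that a flat stream
    converges within ~10 samples; spike_threshold is in units of the
    innovation standard deviation. tail_frac is the fraction of the history
    used for each scaling extreme; warmup_n is the history size below which
    both tails pool all values seen so far.
    """

    kalman_process_var: float = 0.05
    kalman_obs_var: float = 1.0
    spike_threshold: float = 1.96
    spike_damping: float = 0.1
    tail_frac: float = 0.05
    warmup_n: int = 10
    apply_ar1: bool = False  # scale the whitened innovation, not the level


@dataclass
class ProcessedSample:
    raw: float
    despiked: float
    detrended: float
    whitened: float
    normalized: float
    was_spike: bool


@dataclass
class OnlineChain:
    """Streaming state for the online processing chain."""

    settings: ChainSettings = field(default_factory=ChainSettings)
    # Kalman scalar state
    kalman_x: float = 0.0
    kalman_p: float = 1e6
    # expanding-window regression sufficient statistics on (1, t)
    n_seen: int = 0
    sum_t: float = 0.0
    sum_tt: float = 0.0
    sum_y: float = 0.0
    sum_ty: float = 0.0
    # AR(1) running statistics over detrended residuals
    prev_resid: float = 0.0
    ar_sum_xy: float = 0.0
    ar_sum_xx: float = 0.0
    rho: float = 0.0
    # scaling buffer of whitened values (sorted on demand)
    buffer: list[float] = field(default_factory=list)

    # ------------------------------------------------------------------ kalman
    def kalman_despike_step(self, raw_value: float) -> tuple[float, bool]:
        """One predict/update cycle of the random-walk Kalman filter.

        An observation whose innovation exceeds ``spike_threshold`` times the
        innovation standard deviation is flagged as a spike: the output is
        the model prediction and the state update is damped so a single
        outlier cannot drag the filter.
        """
        if not math.isfinite(raw_value):
            raise ValueError(f"non-finite input {raw_value!r}")
        s = self.settings
        if self.n_seen == 0 and self.kalman_p >= 1e6:
            # initialize on the first observation
            self.kalman_x = raw_value
            self.kalman_p = s.kalman_obs_var if s.kalman_obs_var > 0 else 1.0
            return raw_value, False
        if s.kalman_obs_var == 0.0:
            # degenerate pass-through: observations are trusted exactly
            self.kalman_x = raw_value
            return raw_value, False
        p_pred = self.kalman_p + s.kalman_process_var
        innovation = raw_value - self.kalman_x
        innov_var = p_pred + s.kalman_obs_var
        was_spike = abs(innovation) > s.spike_threshold * math.sqrt(innov_var)
        gain = p_pred / innov_var
        if was_spike:
            out = self.kalman_x  # replace by the prediction
            self.kalman_x = self.kalman_x + s.spike_damping * gain * innovation
            self.kalman_p = (1.0 - s.spike_damping * gain) * p_pred
        else:
            self.kalman_x = self.kalman_x + gain * innovation
            self.kalman_p = (1.0 - gain) * p_pred
            out = self.kalman_x
        return out, was_spike

    # ----------------------------------------------------------------- detrend
    def cumulative_detrend_step(self, value: float, volume_index: int) -> float:
        """Residual of an expanding-window LS fit of [constant, linear trend].

        ``volume_index`` is 0-based and must increment by one per call. With
        fewer than 3 samples the residual is taken against the running mean.
        """
        if volume_index != self.n_seen:
            raise ValueError(
                f"out-of-order volume index {volume_index}, expected {self.n_seen}"
            )
        t = float(volume_index)
        self.n_seen += 1
        self.sum_t += t
        self.sum_tt += t * t
        self.sum_y += value
        self.sum_ty += t * value
        n = self.n_seen
        if n < 3:
            return value - self.sum_y / n
        # closed-form simple linear regression on all samples so far
        denom = n * self.sum_tt - self.sum_t**2
        slope = (n * self.sum_ty - self.sum_t * self.sum_y) / denom
        intercept = (self.sum_y - slope * self.sum_t) / n
        return value - (intercept + slope * t)

    # --------------------------------------------------------------------- ar1
    def ar1_step(self, residual: float) -> float:
        """Prewhiten with a running lag-1 autocorrelation estimate.

        rho is the ratio of running lag-1 cross-products to lagged squared
        sums, clipped to (-0.95, 0.95); the whitened value is
        residual - rho * previous residual.
        """
        if not math.isfinite(residual):
            raise ValueError(f"non-finite input {residual!r}")
        if self.ar_sum_xx > 0:
            self.rho = float(
                np.clip(self.ar_sum_xy / self.ar_sum_xx, -AR1_BOUND, AR1_BOUND)
            )
        whitened = residual - self.rho * self.prev_resid
        self.ar_sum_xy += residual * self.prev_resid
        self.ar_sum_xx += self.prev_resid**2
        self.prev_resid = residual
        return whitened

    # ----------------------------------------------------------------- scaling
    def dynamic_range_bounds(self) -> tuple[float, float]:
        """Running scaling extremes: mean of the bottom/top 5% of history.

        Each tail holds ceil(tail_frac * n) values, at least one; during
        warm-up (fewer than ``warmup_n`` samples) both tails pool the entire
        history, so the bounds start at the running min/max neighbourhood.
        """
        if not self.buffer:
            raise ValueError("dynamic range undefined before any sample")
        vals = np.sort(self.buffer)
        n = vals.size
        if n < self.settings.warmup_n:
            k = n
        else:
            k = max(1, math.ceil(self.settings.tail_frac * n))
        return float(vals[:k].mean()), float(vals[-k:].mean())

    @staticmethod
    def scale_to_unit(value: float, lo: float, hi: float) -> float:
        """Map ``value`` to [0, 1] given the running extremes (clipped).

        A degenerate range (hi == lo) maps to 0.5 so the display sits at the
        middle of the morph continuum rather than frozen at an extreme.
        """
        if lo > hi:
            raise ValueError(f"lo ({lo}) exceeds hi ({hi})")
        if hi == lo:
            return 0.5
        return float(np.clip((value - lo) / (hi - lo), 0.0, 1.0))

    # ------------------------------------------------------------- composition
    def process_volume(self, raw_value: float, volume_index: int) -> ProcessedSample:
        """Apply despike -> detrend -> AR(1) -> scale to one raw volume."""
        despiked, was_spike = self.kalman_despike_step(raw_value)
        detrended = self.cumulative_detrend_step(despiked, volume_index)
        whitened = self.ar1_step(detrended)
        display_value = whitened if self.settings.apply_ar1 else detrended
        self.buffer.append(display_value)
        lo, hi = self.dynamic_range_bounds()
        normalized = self.scale_to_unit(display_value, lo, hi)
        return ProcessedSample(
            raw=float(raw_value),
            despiked=float(despiked),
            detrended=float(detrended),
            whitened=float(whitened),
            normalized=normalized,
            was_spike=was_spike,
        )


def batch_detrend(values: np.ndarray) -> np.ndarray:
    """Batch reference for the cumulative detrend: for each prefix 1..t fit
    [constant, trend] by ordinary least squares and return the residual at t.

    Used as the independent oracle for the incremental implementation.
    """
    values = np.asarray(values, dtype=float)
    out = np.empty_like(values)
    for t in range(values.size):
        y = values[: t + 1]
        n = t + 1
        if n < 3:
            out[t] = values[t] - y.mean()
            continue
        X = np.column_stack([np.ones(n), np.arange(n)])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        out[t] = values[t] - (beta[0] + beta[1] * t)
    return out


def process_stream(
    values: np.ndarray, settings: ChainSettings | None = None
) -> list[ProcessedSample]:
    """Run a fresh chain over a whole stream (convenience for offline replay)."""
    chain = OnlineChain(settings=settings or ChainSettings())
    return [chain.process_volume(v, i) for i, v in enumerate(np.asarray(values, float))]
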