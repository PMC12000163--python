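"""Synthetic detector traces with known ground truth.

Emulates the particle-counter measurement: particles arrive at the
counter as an inhomogeneous Poisson process whose rate is
proportional to the decaying effective concentration, and each
arrival produces a pulse on top of baseline noise. Generating
traces from a known concentration curve gives the signal-analysis
chain an input whose true half-life is known exactly, enabling
end-to-end parameter-recovery tests.

Not modelled: optical scattering amplitude versus particle size,
pulse-shape variation, doublets — the traces exercise the counting
chain, not the optics.
"""

from __future__ import annotations

import math
from typing import Callable

import numpy as np

from .signal import CounterTrace
from .specs import ConcentrationCurve, InvalidParameterError

__all__ = ["model_rate", "sample_arrivals", "synthesize_trace"]


def model_rate(curve: ConcentrationCurve, rate0: float) -> Callable:
    """Event-rate function λ(t) = rate0·(C_E/C_0)(t), events/s.

    Piecewise-linear between curve samples; clamped to the edge
    values outside the sampled range and floored at zero.
    """
    if rate0 <= 0:
        raise InvalidParameterError("rate0 must be > 0")
    times = np.asarray(curve.times, dtype=float)
    ratio = np.asarray(curve.ratio, dtype=float)

    def lam(t):
        return rate0 * np.maximum(np.interp(t, times, ratio), 0.0)

    return lam


def sample_arrivals(
    rate: Callable, duration: float, seed: int, rate_max: float = None
) -> np.ndarray:
    """Inhomogeneous-Poisson event times on [0, duration) by thinning.

    Candidate events are drawn from a homogeneous process at
    ``rate_max`` (an upper bound on λ; by default the maximum of λ
    probed on a dense grid, exact for piecewise-linear rates built
    on grids coarser than the probe) and accepted with probability
    λ(t)/rate_max. Reproducible given seed.
    """
    if duration <= 0:
        raise InvalidParameterError("duration must be > 0")
    rng = np.random.default_rng(seed)
    if rate_max is None:
        probe = np.linspace(0.0, duration, 10001)
        rate_max = float(np.max(rate(probe)))
    if rate_max <= 0:
        return np.array([])
    n_cand = rng.poisson(rate_max * duration)
    cand = np.sort(rng.uniform(0.0, duration, n_cand))
    accept = rng.random(n_cand) < np.asarray(rate(cand)) / rate_max
    return cand[accept]


def synthesize_trace(
    events,
    sampling_rate: float = 1e4,
    peak_width: float = 2e-3,
    snr: float = 10.0,
    seed: int = 0,
    duration: float = None,
    margin: float = 1.0,
) -> CounterTrace:
    """Detector trace: Gaussian pulses at event times over noise.

    ``peak_width`` is the pulse FWHM in seconds. The default 2 ms is
    a typical transit pulse for a ~100 µm measurement region at
    cm/s channel velocities, and is consistent with the 100 Hz
    analysis bandwidth of the counting chain (much narrower pulses
    would be largely removed by the chain's own low-pass filter);
    ``snr`` is the pulse amplitude over the
    baseline noise standard deviation (σ = 1 in trace units). The
    trace spans ``duration`` seconds, defaulting to the last event
    plus ``margin``.
    """
    events = np.asarray(events, dtype=float)
    if peak_width < 2.0 / sampling_rate:
        raise InvalidParameterError(
            f"peak_width must be >= 2/sampling_rate = {2.0 / sampling_rate}"
        )
    if duration is None:
        duration = (float(events.max()) if events.size else 0.0) + margin
    n = int(round(duration * sampling_rate))
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)  # baseline noise, sigma = 1
    sigma_s = peak_width / (2.0 * math.sqrt(2.0 * math.log(2.0))) * sampling_rate
    half = int(math.ceil(5.0 * sigma_s))
    kernel_idx = np.arange(-half, half + 1)
    for te in events:
        ic = te * sampling_rate
        i0 = int(round(ic))
        idx = i0 + kernel_idx
        ok = (idx >= 0) & (idx < n)
        x[idx[ok]] += snr * np.exp(-0.5 * ((idx[ok] - ic) / sigma_s) ** 2)
    return CounterTrace(x, sampling_rate)
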