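"""Synthetic inputs for the mushroom-body pipeline.

Generates the three kinds of data the analysis consumes:

* odour-response panels (odours x olfactory receptor-neuron classes, firing
  rates in Hz) with Hallem-Carlson-like marginal statistics,
* paired KC/APL odour-response tables (per-sample 7-odour mean dF/F vectors,
  APL = KC + Gaussian noise whose per-sample SD is drawn log-normally),
* simple square-pulse fluorescence traces.

All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._rng import as_generator

__all__ = [
    "ORNPanel",
    "GroundTruthNoise",
    "Trace",
    "RateStats",
    "gen_orn_panel",
    "gen_kc_table",
    "gen_paired_responses",
    "gen_trace",
]

# Default mean dF/F of the 7-odour panel, emulating odours of differing
# intensities (strongest first, near-zero weakest).
DEFAULT_ODOUR_AMPLITUDES = np.array([1.5, 1.0, 0.8, 0.6, 0.4, 0.2, 0.05])


@dataclass
class RateStats:
    """Marginal statistics of synthetic ORN firing rates.

    Rates are gamma-distributed with a configurable fraction of
    zero/non-responses, mimicking the sparse, skewed odour-response
    distributions of the published 110x24 receptor panel.
    """

    mean_rate: float = 30.0  # Hz, mean of the gamma component
    shape: float = 0.7       # gamma shape; <1 gives the heavy right skew
    zero_fraction: float = 0.2

    def __post_init__(self):
        if self.mean_rate <= 0 or self.shape <= 0:
            raise ValueError("mean_rate and shape must be positive")
        if not 0 <= self.zero_fraction < 1:
            raise ValueError("zero_fraction must be in [0, 1)")


@dataclass
class ORNPanel:
    """Odour x ORN-class firing-rate matrix.

    One odour is flagged as the designated isoamyl-acetate analogue: the
    plasticity read-out odour.
    """

    rates: np.ndarray                      # (n_odours, n_orns), Hz, >= 0
    odour_labels: list[str]
    orn_labels: list[str]
    designated_odour: int = 0              # index of the IA analogue

    def __post_init__(self):
        self.rates = np.asarray(self.rates, dtype=float)
        if self.rates.ndim != 2:
            raise ValueError("rates must be 2-D (odours x ORNs)")
        if not np.all(np.isfinite(self.rates)):
            raise ValueError("rates must be finite")
        if np.any(self.rates < 0):
            raise ValueError("rates must be non-negative (clip before building)")
        n_od, n_orn = self.rates.shape
        if len(self.odour_labels) != n_od or len(self.orn_labels) != n_orn:
            raise ValueError("label lengths must match the rate matrix")
        if not 0 <= self.designated_odour < n_od:
            raise ValueError("designated_odour out of range")

    @property
    def n_odours(self) -> int:
        return self.rates.shape[0]

    @property
    def n_orns(self) -> int:
        return self.rates.shape[1]


@dataclass
class GroundTruthNoise:
    """Log-normal model of per-sample APL noise SDs (dF/F units).

    Each sample's noise SD is exp(N(mu_n, sigma_n)); sigma_n = 0 collapses all
    SDs to exp(mu_n).
    """

    mu_n: float = -2.0
    sigma_n: float = 0.0
    per_sample_sd: np.ndarray | None = None

    def __post_init__(self):
        if self.sigma_n < 0:
            raise ValueError("sigma_n must be >= 0")
        if self.per_sample_sd is not None:
            self.per_sample_sd = np.asarray(self.per_sample_sd, dtype=float)
            if np.any(self.per_sample_sd <= 0):
                raise ValueError("per_sample_sd must be positive")

    def draw_sds(self, n_samples: int, rng) -> np.ndarray:
        """Realise per-sample SDs (stored on the instance and returned)."""
        rng = as_generator(rng)
        self.per_sample_sd = np.exp(rng.normal(self.mu_n, self.sigma_n, n_samples))
        return self.per_sample_sd


@dataclass
class Trace:
    """Uniformly sampled fluorescence trace."""

    frame_time: float            # s
    values: np.ndarray           # raw F or dF/F

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.frame_time <= 0:
            raise ValueError("frame_time must be positive")

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.values.size) * self.frame_time


def gen_orn_panel(
    n_odours: int = 110,
    n_orns: int = 24,
    rate_stats: RateStats | None = None,
    seed: int | np.random.Generator = 0,
) -> ORNPanel:
    """Generate a synthetic odour x ORN firing-rate panel.

    Rates are gamma(shape, mean/shape) with a ``zero_fraction`` of entries set
    to 0 and the rest clipped at 0 (the published panel contains inhibitory
    responses; the downstream power transform requires non-negative input).
    The designated isoamyl-acetate analogue is the odour whose summed ORN
    drive sits at the 80th percentile — a strong but not extreme odour.
    """
    if n_odours < 1 or n_orns < 1:
        raise ValueError("n_odours and n_orns must be >= 1")
    stats = rate_stats if rate_stats is not None else RateStats()
    rng = as_generator(seed)
    scale = stats.mean_rate / stats.shape
    rates = rng.gamma(stats.shape, scale, size=(n_odours, n_orns))
    if stats.zero_fraction > 0:
        zero = rng.random((n_odours, n_orns)) < stats.zero_fraction
        rates[zero] = 0.0
    rates = np.clip(rates, 0.0, None)

    totals = rates.sum(axis=1)
    target = np.percentile(totals, 80)
    designated = int(np.argmin(np.abs(totals - target)))
    return ORNPanel(
        rates=rates,
        odour_labels=[f"odour_{i:03d}" for i in range(n_odours)],
        orn_labels=[f"orn_{i:02d}" for i in range(n_orns)],
        designated_odour=designated,
    )


def gen_kc_table(
    n_samples: int = 220,
    n_odours: int = 7,
    odour_amplitudes: np.ndarray | None = None,
    gain_sigma: float = 0.4,
    jitter_sd: float = 0.05,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Generate per-sample KC odour-response vectors (mean dF/F).

    Each sample (one mushroom-body region of one hemisphere) responds to the
    shared odour panel with a log-normal per-sample gain plus small additive
    jitter: ``kc[s, o] = gain_s * amp_o + N(0, jitter_sd)``.
    """
    if n_samples < 1 or n_odours < 1:
        raise ValueError("n_samples and n_odours must be >= 1")
    rng = as_generator(seed)
    if odour_amplitudes is None:
        amps = DEFAULT_ODOUR_AMPLITUDES
        if n_odours != amps.size:
            # Interpolate the default intensity profile to the requested size.
            amps = np.interp(
                np.linspace(0, 1, n_odours), np.linspace(0, 1, amps.size), amps
            )
    else:
        amps = np.asarray(odour_amplitudes, dtype=float)
        if amps.size != n_odours:
            raise ValueError("odour_amplitudes length must equal n_odours")
    gains = rng.lognormal(0.0, gain_sigma, n_samples)
    kc = gains[:, None] * amps[None, :] + rng.normal(0.0, jitter_sd, (n_samples, n_odours))
    return kc


def gen_paired_responses(
    kc_table: np.ndarray | None,
    noise: GroundTruthNoise,
    seed: int | np.random.Generator = 0,
    n_samples: int = 220,
    n_odours: int = 7,
) -> tuple[np.ndarray, np.ndarray]:
    """Return a paired (KC, APL) response table.

    APL responses are the KC responses plus Gaussian noise whose per-sample SD
    is drawn from the log-normal noise model: ``apl[s, o] = kc[s, o] +
    N(0, sd_s)`` with ``sd_s = exp(N(mu_n, sigma_n))``. The KC matrix is
    returned unchanged. If ``kc_table`` is None a synthetic KC table with the
    default generator parameters is created first.
    """
    rng = as_generator(seed)
    if kc_table is None:
        kc = gen_kc_table(n_samples=n_samples, n_odours=n_odours, seed=rng)
    else:
        kc = np.asarray(kc_table, dtype=float)
        if kc.ndim != 2:
            raise ValueError("kc_table must be 2-D (samples x odours)")
        if not np.all(np.isfinite(kc)):
            raise ValueError("kc_table must be finite")
    n_s = kc.shape[0]
    if noise.per_sample_sd is not None and noise.per_sample_sd.size != n_s:
        raise ValueError(
            f"per_sample_sd has {noise.per_sample_sd.size} entries "
            f"but the table has {n_s} samples"
        )
    if noise.per_sample_sd is not None:
        sds = noise.per_sample_sd
    else:
        sds = np.exp(rng.normal(noise.mu_n, noise.sigma_n, n_s))
    apl = kc + rng.standard_normal(kc.shape) * sds[:, None]
    return kc, apl


def gen_trace(
    frame_time: float,
    duration: float,
    baseline: float = 1.0,
    odour_window: tuple[float, float] = (5.0, 10.0),
    amplitude: float = 1.0,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> Trace:
    """Generate a square-pulse fluorescence trace.

    The trace is ``baseline`` outside the odour window and ``baseline +
    amplitude`` inside it, plus optional white noise; length is
    floor(duration / frame_time) frames.
    """
    if not 0 < frame_time < duration:
        raise ValueError("require 0 < frame_time < duration")
    start, end = odour_window
    if not (0 <= start < end <= duration):
        raise ValueError("odour_window must be within [0, duration] and ordered")
    rng = as_generator(seed)
    n = int(np.floor(duration / frame_time))
    t = np.arange(n) * frame_time
    values = np.full(n, baseline, dtype=float)
    inside = (t >= start) & (t < end)
    values[inside] += amplitude
    if noise_sd > 0:
        values += rng.normal(0.0, noise_sd, n)
    return Trace(frame_time=frame_time, values=values)
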