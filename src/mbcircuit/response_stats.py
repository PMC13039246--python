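"""Statistics for paired KC/APL odour responses and imaging traces.

Covers four analyses:

* per-sample Pearson correlations and origin-constrained regression slopes of
  APL vs KC odour responses (the APL-sensitivity read-out),
* a log-normal noise model of APL responses (APL = KC + Gaussian noise whose
  per-sample SD is exp(N(mu, sigma))), fitted by a sign-driven search on the
  mean and variance of the simulated correlation distribution,
* a Monte-Carlo two-sample Kolmogorov-Smirnov test comparing the observed
  correlation distribution against that noise model,
* the nuclear localisation index (NLI) and mean-dF/F quantification of odour
  pulse responses from fluorescence traces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d

from ._rng import as_generator
from .synthetic_data import Trace

__all__ = [
    "PairedResponseTable",
    "NoiseModelFit",
    "MCKSResult",
    "sample_correlation",
    "origin_slope",
    "simulate_apl",
    "fit_noise_model",
    "ks_statistic",
    "mc_ks_test",
    "nli",
    "nli_hemisphere",
    "dff_quantify",
]


@dataclass
class PairedResponseTable:
    """Per-sample KC and APL odour-response vectors (mean dF/F).

    A sample is one mushroom-body region of one hemisphere; the default
    panel has 7 odour responses per sample.
    """

    kc: np.ndarray                      # (n_samples, n_odours)
    apl: np.ndarray                     # same shape
    sample_ids: list[str] | None = None
    odour_ids: list[str] | None = None

    def __post_init__(self):
        self.kc = np.asarray(self.kc, dtype=float)
        self.apl = np.asarray(self.apl, dtype=float)
        if self.kc.shape != self.apl.shape or self.kc.ndim != 2:
            raise ValueError("kc and apl must be 2-D matrices of equal shape")
        if not (np.all(np.isfinite(self.kc)) and np.all(np.isfinite(self.apl))):
            raise ValueError("response values must be finite")
        if self.sample_ids is None:
            self.sample_ids = [f"s{i:03d}" for i in range(self.kc.shape[0])]
        if self.odour_ids is None:
            self.odour_ids = [f"od{i}" for i in range(self.kc.shape[1])]

    @property
    def n_samples(self) -> int:
        return self.kc.shape[0]

    @property
    def n_odours(self) -> int:
        return self.kc.shape[1]


@dataclass
class NoiseModelFit:
    """Log-normal hyperparameters of the per-sample noise SD."""

    mu_n: float
    sigma_n: float
    iterations: int = 0
    converged: bool = True
    degenerate: bool = False
    trace: np.ndarray | None = None     # (iterations, 2) parameter path

    def __post_init__(self):
        if self.sigma_n < 0:
            raise ValueError("sigma_n must be >= 0")

    @property
    def implied_sd(self) -> float:
        """Median per-sample noise SD, exp(mu_n)."""
        return float(np.exp(self.mu_n))


@dataclass
class MCKSResult:
    """Monte-Carlo two-sample K-S comparison of data vs fitted noise model."""

    dn_sim_sim: np.ndarray      # per-simulation mean D_n vs the other sims
    dn_sim_data: float          # mean D_n of simulations vs the data
    p_value: float
    n_sims: int
    n_excluded: int = 0         # undefined (zero-variance) correlations dropped


def _row_pearson(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise Pearson r; rows with zero variance give NaN."""
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)
    denom = np.sqrt((a * a).sum(axis=1) * (b * b).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, (a * b).sum(axis=1) / denom, np.nan)


def sample_correlation(table: PairedResponseTable) -> np.ndarray:
    """Per-sample Pearson correlation of APL vs KC odour responses.

    Samples with zero variance in either channel are flagged as NaN rather
    than silently dropped; downstream consumers exclude and count them.
    """
    if table.n_odours < 2:
        raise ValueError("need at least 2 odours per sample for a correlation")
    return _row_pearson(table.kc, table.apl)


def origin_slope(kc_row: np.ndarray, apl_row: np.ndarray) -> float:
    """Least-squares slope of APL = k * KC constrained through the origin.

    The constraint reflects that APL does not respond to odours when KCs are
    silenced. Closed form: k = sum(kc*apl) / sum(kc^2).
    """
    kc = np.asarray(kc_row, dtype=float)
    apl = np.asarray(apl_row, dtype=float)
    if kc.shape != apl.shape:
        raise ValueError("kc and apl vectors must have equal length")
    denom = float((kc * kc).sum())
    if denom == 0:
        raise ValueError("all KC values are zero; origin slope undefined")
    return float((kc * apl).sum() / denom)


def simulate_apl(
    kc: np.ndarray,
    fit: NoiseModelFit,
    seed: int | np.random.Generator = 0,
    n_reps: int = 1,
) -> np.ndarray:
    """Simulate APL responses as KC responses plus log-normal-SD noise.

    Per sample s, a noise SD ``sd_s = exp(N(mu_n, sigma_n))`` is drawn and
    ``apl_sim[s, o] = kc[s, o] + N(0, sd_s)``. With ``n_reps > 1`` the
    leading axis enumerates independent simulated datasets.
    """
    rng = as_generator(seed)
    kc = np.asarray(kc, dtype=float)
    if kc.ndim != 2:
        raise ValueError("kc must be (n_samples, n_odours)")
    n_s, n_o = kc.shape
    sds = np.exp(rng.normal(fit.mu_n, fit.sigma_n, (n_reps, n_s)))
    sims = kc[None] + rng.standard_normal((n_reps, n_s, n_o)) * sds[:, :, None]
    return sims[0] if n_reps == 1 else sims


def _sim_corr_stats(kc, mu, sigma, n_reps, rng):
    """Mean and variance of simulated per-sample correlations (pooled)."""
    fit = NoiseModelFit(mu_n=mu, sigma_n=max(sigma, 0.0))
    sims = simulate_apl(kc, fit, rng, n_reps=max(n_reps, 2))
    corrs = np.concatenate(
        [_row_pearson(kc, sims[r]) for r in range(sims.shape[0])]
    )
    corrs = corrs[np.isfinite(corrs)]
    return corrs.mean(), corrs.var(ddof=1)


MU_FLOOR = -10.0
MIN_STEP = 0.02     # keeps the sign-driven walk dithering around the root


def fit_noise_model(
    table: PairedResponseTable,
    init: tuple[float, float] = (-1.0, 0.25),
    steps: int = 150,
    n_sim_per_step: int = 10,
    seed: int | np.random.Generator = 0,
) -> NoiseModelFit:
    """Fit (mu_n, sigma_n) of the log-normal noise model by sign-driven search.

    On each iteration, ``n_sim_per_step`` APL datasets are simulated from the
    current hyperparameters and their per-sample correlations pooled. If the
    simulated correlations are higher (lower) than the real ones, mu is
    increased (decreased); if their variance is higher (lower) than the real
    variance, sigma is decreased (increased). Step sizes start at 0.1 and are
    halved at every sign flip; the search stops once both parameters have
    flipped sign on 5 consecutive iterations (dithering around the root) or
    after ``steps`` iterations (flagged non-converged). sigma is floored at 0
    and mu at -10; a fit driven to the mu floor (zero-noise data) is flagged
    degenerate.
    """
    if table.n_samples < 2:
        raise ValueError("need at least 2 samples to fit the noise model")
    rng = as_generator(seed)
    real = sample_correlation(table)
    real = real[np.isfinite(real)]
    if real.size < 2:
        raise ValueError("fewer than 2 samples with defined correlations")
    real_mean, real_var = real.mean(), real.var(ddof=1)

    mu, sigma = float(init[0]), float(init[1])
    step_mu, step_sigma = 0.1, 0.1
    prev_sign_mu = prev_sign_sigma = 0
    flips_mu = flips_sigma = 0
    path = []
    converged = False
    it = 0
    for it in range(1, steps + 1):
        sim_mean, sim_var = _sim_corr_stats(table.kc, mu, sigma,
                                            n_sim_per_step, rng)
        # Higher simulated correlation => too little noise => raise mu.
        sign_mu = 1 if sim_mean > real_mean else -1
        # Higher simulated variance => sigma too large => lower sigma.
        sign_sigma = -1 if sim_var > real_var else 1
        if prev_sign_mu and sign_mu != prev_sign_mu:
            step_mu = max(0.5 * step_mu, MIN_STEP)
            flips_mu += 1
        elif prev_sign_mu:
            flips_mu = 0
        if prev_sign_sigma and sign_sigma != prev_sign_sigma:
            step_sigma = max(0.5 * step_sigma, MIN_STEP)
            flips_sigma += 1
        elif prev_sign_sigma:
            flips_sigma = 0
        mu = min(max(mu + sign_mu * step_mu, MU_FLOOR), 5.0)
        # sigma's chain may wander (slightly) negative; simulation clips it at
        # 0, and the reported estimate is the clipped tail mean. Without this
        # mirroring, a zero-heterogeneity truth acquires a positive bias
        # because the chain can only dither upward from the boundary.
        sigma = max(sigma + sign_sigma * step_sigma, -1.0)
        prev_sign_mu, prev_sign_sigma = sign_mu, sign_sigma
        path.append((mu, sigma))
        if not converged and flips_mu >= 5 and flips_sigma >= 5:
            converged = True
            dither_until = it + 30
        if converged and it >= dither_until:
            break
    # Once both parameters dither around the root (steps at the floor), the
    # time-average of the chain is a lower-variance estimate than any single
    # iterate (stochastic-approximation averaging).
    path_arr = np.asarray(path)
    tail = path_arr[-min(len(path), 30):]
    mu_hat, sigma_hat = float(tail[:, 0].mean()), float(max(tail[:, 1].mean(), 0.0))
    degenerate = mu_hat <= MU_FLOOR + 0.5
    return NoiseModelFit(
        mu_n=mu_hat,
        sigma_n=sigma_hat,
        iterations=it,
        converged=converged,
        degenerate=degenerate,
        trace=np.asarray(path),
    )


def ks_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sample Kolmogorov-Smirnov statistic D_n.

    Supremum distance between the empirical CDFs, computed on raw (unbinned)
    values: the sup is attained at an observed value of either sample, so it
    suffices to evaluate both ECDFs at every pooled observation.
    """
    a = np.sort(np.asarray(a, dtype=float).ravel())
    b = np.sort(np.asarray(b, dtype=float).ravel())
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    z = np.concatenate([a, b])
    fa = np.searchsorted(a, z, side="right") / a.size
    fb = np.searchsorted(b, z, side="right") / b.size
    return float(np.abs(fa - fb).max())


def _pairwise_mean_ks(datasets: np.ndarray) -> np.ndarray:
    """All-pairs D_n matrix for equal-length datasets, vectorised.

    ``datasets`` is (m, n). Every dataset's ECDF is evaluated (as a rank
    count, which fits in uint16) at every pooled observation; the pairwise
    sup is then taken over each pair's own 2n observations.
    """
    m, n = datasets.shape
    S = np.sort(datasets, axis=1)
    V = S.ravel()                                   # all m*n observations
    dtype = np.uint8 if n < 256 else np.uint16
    counts = np.empty((m, m * n), dtype=dtype)
    for d in range(m):
        counts[d] = np.searchsorted(S[d], V, side="right")
    D = np.zeros((m, m))
    idx = np.arange(n)
    for a in range(m):
        cols = slice(a * n, (a + 1) * n)
        block = counts[:, cols].astype(np.int32)
        # max over a's observations of |F_x - F_a| for all x at once
        D_a = np.abs(block - block[a][None, :]).max(axis=1) / n
        D[a] = np.maximum(D[a], D_a)
        D[:, a] = np.maximum(D[:, a], D_a)
    return D


def mc_ks_test(
    real_corrs: np.ndarray,
    kc_table: np.ndarray,
    fit: NoiseModelFit,
    n_sims: int = 1000,
    seed: int | np.random.Generator = 0,
) -> MCKSResult:
    """Monte-Carlo two-sample K-S test of data vs the fitted noise model.

    The noise-model simulation is run ``n_sims`` times; D_n is computed for
    every simulation-vs-simulation and simulation-vs-data pair. Each
    simulation's mean D_n against the other simulations is compared with the
    mean simulation-vs-data D_n; the p-value is the fraction of
    simulation-vs-simulation means exceeding the data mean. Undefined
    (zero-variance) correlations are excluded, with the count reported.
    """
    if n_sims < 2:
        raise ValueError("n_sims must be >= 2")
    rng = as_generator(seed)
    real = np.asarray(real_corrs, dtype=float).ravel()
    defined = np.isfinite(real)
    n_excluded = int((~defined).sum())
    real = real[defined]
    kc = np.asarray(kc_table, dtype=float)

    sims = simulate_apl(kc, fit, rng, n_reps=n_sims)    # (n_sims, n_s, n_o)
    sim_corrs = np.stack([_row_pearson(kc, sims[r]) for r in range(n_sims)])
    # Samples whose correlation is undefined in any simulation are dropped
    # everywhere so all simulated distributions have equal length.
    keep = np.all(np.isfinite(sim_corrs), axis=0)
    sim_corrs = sim_corrs[:, keep]
    D = _pairwise_mean_ks(sim_corrs)
    sums = D.sum(axis=1)                             # includes self (0)
    dn_sim_sim = sums / (n_sims - 1)
    dn_vs_data = np.array(
        [ks_statistic(sim_corrs[r], real) for r in range(n_sims)]
    )
    dn_sim_data = float(dn_vs_data.mean())
    p = float((dn_sim_sim > dn_sim_data).mean())
    return MCKSResult(
        dn_sim_sim=dn_sim_sim,
        dn_sim_data=dn_sim_data,
        p_value=p,
        n_sims=n_sims,
        n_excluded=n_excluded,
    )


def nli(nuclear, cytoplasmic):
    """Nuclear localisation index: (nuclear - cytoplasmic)/(nuclear + cytoplasmic).

    Inputs are background-subtracted signals; the index lies in [-1, 1] for
    non-negative inputs and is antisymmetric under swapping the compartments.
    """
    nuc = np.asarray(nuclear, dtype=float)
    cyt = np.asarray(cytoplasmic, dtype=float)
    denom = nuc + cyt
    if np.any(denom == 0):
        raise ValueError("nuclear + cytoplasmic signal must be nonzero")
    out = (nuc - cyt) / denom
    return float(out) if out.ndim == 0 else out


def nli_hemisphere(nuclear, cytoplasmic):
    """Hemisphere-level KC NLI: mean of the per-cell index over the 20 cells."""
    values = nli(nuclear, cytoplasmic)
    return float(np.mean(values))


def dff_quantify(
    trace: Trace,
    baseline_window: tuple[float, float],
    odour_window: tuple[float, float],
    smooth_width: float = 0.2,
    target_frame_time: float = 0.018,
) -> float:
    """Mean dF/F over the odour pulse from a raw fluorescence trace.

    Processing order: dF/F = (F - F0)/F0 with F0 the mean over the baseline
    window; boxcar smoothing of width ``smooth_width`` seconds; linear
    interpolation onto a uniform grid with ``target_frame_time`` spacing
    (endpoints clamped); mean over the odour window (equivalent to the
    integral for a fixed-length pulse).
    """
    values = trace.values
    t = trace.time
    dur = values.size * trace.frame_time
    b0, b1 = baseline_window
    o0, o1 = odour_window
    if not (0 <= b0 < b1 <= dur):
        raise ValueError("baseline_window outside the trace")
    if not (0 <= o0 < o1 <= dur):
        raise ValueError("odour_window outside the trace")
    if smooth_width < trace.frame_time:
        raise ValueError("smooth_width must be at least one frame")
    base = (t >= b0) & (t < b1)
    f0 = values[base].mean()
    if f0 == 0:
        raise ValueError("baseline fluorescence is zero; dF/F undefined")
    dff = (values - f0) / f0
    width = max(int(round(smooth_width / trace.frame_time)), 1)
    smoothed = uniform_filter1d(dff, size=width, mode="nearest")
    if abs(target_frame_time - trace.frame_time) > 1e-12:
        new_t = np.arange(0.0, t[-1] + 1e-12, target_frame_time)
        smoothed = np.interp(new_t, t, smoothed)
        t = new_t
    window = (t >= o0) & (t < o1)
    if not np.any(window):
        raise ValueError("odour window contains no frames")
    return float(smoothed[window].mean())
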