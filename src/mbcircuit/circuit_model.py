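"""Firing-rate model of the mushroom-body KC/APL circuit.

The model comprises 2000 Kenyon cells (KCs) receiving excitation from 24
olfactory projection neurons (PNs) and feedback inhibition from the single
anterior paired lateral (APL) neuron. APL inhibition is driven by the combined
PN input to all KCs, independent of KC firing (mimicking dendro-dendritic
interactions), so the response of KC j to stimulus k is

    y_jk = Relu( sum_i w_ij x_ik  -  alpha * T_k  -  C_theta * theta_j )

with T_k = sum_j sum_i w_ij x_ik the total KC input (the APL drive), w_ij the
PN->KC synaptic weights, theta_j per-KC threshold factors and (alpha, C_theta)
the tunable inhibitory gain and global threshold scale.

PN activity x_ik derives from olfactory receptor-neuron (ORN) firing rates
through a saturating transfer function with antennal-lobe lateral
suppression:

    x_ik = R_max * ORN^1.5 / (ORN^1.5 + s_k^1.5 + sigma^1.5),
    s_k  = m * sum_i ORN_ik / 190.

Connectivity is sparse: each KC samples 2-11 distinct PNs ("claws"), with
log-normal synaptic weights and normally distributed thresholds. Weights are
equalised so all KCs have the same mean response across the odour panel, and
(alpha, C_theta) are tuned so that on average 10% of KCs respond per odour,
rising to 20% when inhibition is blocked.
"""

from __future__ import annotations

import copy as _copy
import warnings
from dataclasses import dataclass

import numpy as np

from ._rng import as_generator, stream
from .synthetic_data import ORNPanel

__all__ = [
    "TransferParams",
    "MBCircuit",
    "KCResponseSet",
    "PNInputs",
    "EqualisationError",
    "TuningError",
    "relu",
    "lateral_suppression",
    "pn_transfer",
    "default_cv",
    "add_pn_noise",
    "sample_connectivity",
    "sample_thresholds",
    "kc_responses",
    "coding_level",
    "equalise_weights",
    "tune_parameters",
    "make_pn_inputs",
    "build_tuned_circuit",
]


class EqualisationError(RuntimeError):
    """Weight equalisation failed to converge."""


class TuningError(RuntimeError):
    """(alpha, C_theta) tuning could not reach a target coding level."""


@dataclass
class TransferParams:
    """Parameters of the ORN->PN transfer function.

    r_max : maximal PN firing rate (Hz).
    m : gain of antennal-lobe lateral inhibition.
    sigma_t : half-saturation constant (Hz) setting the nonlinearity.
    exponent : power of the saturating nonlinearity.
    norm_const : divisor of the summed ORN input in the suppression term s_k.
    """

    r_max: float = 165.0
    m: float = 10.63
    sigma_t: float = 12.0
    exponent: float = 1.5
    norm_const: float = 190.0

    def __post_init__(self):
        for name in ("r_max", "m", "sigma_t", "exponent", "norm_const"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass
class MBCircuit:
    """Connectivity, weights, thresholds and gains of the KC/APL model.

    ``w`` is the (n_pn, M) PN->KC weight matrix, nonzero exactly where PN i is
    a claw of KC j. ``theta`` are dimensionless per-KC threshold factors with
    mean 1, so ``c_theta`` alone carries the threshold scale.
    """

    M: int = 2000
    n_pn: int = 24
    w: np.ndarray | None = None              # (n_pn, M)
    claws: list[np.ndarray] | None = None    # per-KC distinct PN indices
    theta: np.ndarray | None = None          # (M,), > 0
    alpha: float = 0.0
    c_theta: float = 0.0
    claw_mu: float = 6.0
    claw_sigma: float = 1.7
    claw_range: tuple[int, int] = (2, 11)
    weight_mu: float = -0.0507
    weight_sigma: float = 0.3527
    theta_cv: float = 0.26
    seed: int = 0

    def __post_init__(self):
        if self.alpha < 0 or self.c_theta < 0:
            raise ValueError("alpha and c_theta must be >= 0")
        if self.w is not None:
            self.w = np.asarray(self.w, dtype=float)
            if self.w.shape != (self.n_pn, self.M):
                raise ValueError(
                    f"w must have shape ({self.n_pn}, {self.M}), got {self.w.shape}"
                )
            if np.any(self.w < 0):
                raise ValueError("weights must be non-negative")
        if self.theta is not None:
            self.theta = np.asarray(self.theta, dtype=float)
            if self.theta.shape != (self.M,):
                raise ValueError("theta must have shape (M,)")
            if np.any(self.theta <= 0):
                raise ValueError("theta must be strictly positive")

    def copy(self) -> "MBCircuit":
        c = _copy.copy(self)
        if self.w is not None:
            c.w = self.w.copy()
        if self.theta is not None:
            c.theta = self.theta.copy()
        if self.claws is not None:
            c.claws = [a.copy() for a in self.claws]
        return c

    @property
    def is_sampled(self) -> bool:
        return self.w is not None and self.theta is not None


@dataclass
class KCResponseSet:
    """KC responses and APL drive for a set of trials."""

    y: np.ndarray            # (n_trials, M), >= 0
    apl: np.ndarray          # (n_trials,) total KC input T_k
    odour_ids: np.ndarray | None = None   # trial -> odour index


@dataclass
class PNInputs:
    """PN activity for an odour panel plus noisy trials of it."""

    x: np.ndarray            # (n_odours, n_pn) noiseless PN activity
    trials: np.ndarray       # (n_odours * n_trials, n_pn)
    odour_ids: np.ndarray    # (n_odours * n_trials,)
    designated_odour: int

    @property
    def designated_trials(self) -> np.ndarray:
        return self.trials[self.odour_ids == self.designated_odour]


def relu(x):
    """Rectified linear unit: 0 for x <= 0, x otherwise."""
    return np.maximum(x, 0)


def _panel_rates(orn) -> np.ndarray:
    rates = orn.rates if isinstance(orn, ORNPanel) else np.asarray(orn, dtype=float)
    if rates.ndim != 2 or rates.size == 0:
        raise ValueError("ORN panel must be a non-empty 2-D matrix")
    if np.any(rates < 0):
        raise ValueError("ORN rates must be non-negative (clip at 0 first)")
    return rates


def lateral_suppression(orn, params: TransferParams | None = None) -> np.ndarray:
    """Per-odour lateral-suppression term s_k = m * sum_i ORN_ik / norm_const."""
    params = params or TransferParams()
    rates = _panel_rates(orn)
    return params.m * rates.sum(axis=1) / params.norm_const


def pn_transfer(orn, params: TransferParams | None = None) -> np.ndarray:
    """PN activity x_ik from ORN rates via the saturating transfer function.

    Output is bounded in [0, r_max) and monotone in the ORN rate for fixed
    suppression s_k.
    """
    params = params or TransferParams()
    rates = _panel_rates(orn)
    s = lateral_suppression(rates, params)
    e = params.exponent
    num = rates**e
    den = num + (s[:, None] ** e) + params.sigma_t**e
    return params.r_max * num / den


def default_cv(x: np.ndarray) -> np.ndarray:
    """Default firing-rate-dependent coefficient of variation of PN noise.

    Monotone decreasing with rate: CV(x) = 0.1 + 0.9 * exp(-x / 30 Hz).
    The empirical curve this stands in for is not published; the shape
    (high relative variability at low rates, ~10% at saturation) follows the
    qualitative form reported for antennal-lobe PNs. Fully configurable.
    """
    x = np.asarray(x, dtype=float)
    return 0.1 + 0.9 * np.exp(-x / 30.0)


def add_pn_noise(
    x: np.ndarray,
    cv_fn=default_cv,
    n_trials: int = 30,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Generate noisy PN trials: x + N(0, cv(x)*x), clipped at 0.

    Returns ``(trials, odour_ids)`` with ``trials`` of shape
    (n_odours * n_trials, n_pn), grouped by odour.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    if np.any(x < 0):
        raise ValueError("PN activity must be non-negative")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = as_generator(seed)
    cv = np.asarray(cv_fn(x), dtype=float)
    if np.any(cv < 0):
        raise ValueError("cv_fn must return non-negative values")
    sd = cv * x
    n_od, n_pn = x.shape
    noise = rng.standard_normal((n_od, n_trials, n_pn)) * sd[:, None, :]
    trials = np.clip(x[:, None, :] + noise, 0.0, None)
    odour_ids = np.repeat(np.arange(n_od), n_trials)
    return trials.reshape(n_od * n_trials, n_pn), odour_ids


def sample_connectivity(
    M: int,
    n_pn: int,
    claw_mu: float = 6.0,
    claw_sigma: float = 1.7,
    claw_range: tuple[int, int] = (2, 11),
    weight_mu: float = -0.0507,
    weight_sigma: float = 0.3527,
    seed: int | np.random.Generator = 0,
) -> tuple[list[np.ndarray], np.ndarray]:
    """Sample per-KC claws and the PN->KC weight matrix.

    Claw counts are normal(claw_mu, claw_sigma), rounded and truncated to
    ``claw_range``; each KC's claws are distinct PNs drawn uniformly without
    replacement; nonzero weights are log-normal(weight_mu, weight_sigma).
    """
    lo, hi = claw_range
    if n_pn < hi:
        raise ValueError(f"n_pn={n_pn} cannot host {hi} distinct claws")
    rng = as_generator(seed)
    counts = np.clip(np.rint(rng.normal(claw_mu, claw_sigma, M)), lo, hi).astype(int)
    w = np.zeros((n_pn, M))
    claws = []
    for j in range(M):
        pns = rng.choice(n_pn, size=counts[j], replace=False)
        claws.append(np.sort(pns))
        w[pns, j] = rng.lognormal(weight_mu, weight_sigma, counts[j])
    return claws, w


def sample_thresholds(
    M: int,
    cv: float = 0.26,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Sample per-KC threshold factors theta_j ~ N(1, cv), redrawn to be > 0.

    The mean is 1 so that the global scale C_theta is the only threshold
    tunable.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    if not 0 <= cv < 1:
        raise ValueError("cv must be in [0, 1)")
    rng = as_generator(seed)
    theta = rng.normal(1.0, cv, M)
    bad = theta <= 0
    while np.any(bad):
        theta[bad] = rng.normal(1.0, cv, int(bad.sum()))
        bad = theta <= 0
    return theta


def kc_responses(x_trial: np.ndarray, circuit: MBCircuit) -> KCResponseSet:
    """Evaluate KC responses and APL drive for one or more PN activity vectors.

    The inhibition term alpha*T_k is identical for every KC (dendro-dendritic
    feedback from the summed input). The APL activity read-out is the total
    input T_k itself, not alpha*T_k: calcium responses reflect APL's inputs,
    whereas alpha conflates input and output strength.
    """
    if not circuit.is_sampled:
        raise ValueError("circuit has no sampled weights/thresholds")
    x = np.asarray(x_trial, dtype=float)
    squeeze = x.ndim == 1
    if squeeze:
        x = x[None, :]
    if x.shape[1] != circuit.n_pn:
        raise ValueError(
            f"PN vector length {x.shape[1]} does not match n_pn={circuit.n_pn}"
        )
    if np.any(x < 0):
        raise ValueError("PN activity must be non-negative")
    excitation = x @ circuit.w                    # (trials, M)
    T = excitation.sum(axis=1)                    # APL drive per trial
    y = relu(excitation - circuit.alpha * T[:, None]
             - circuit.c_theta * circuit.theta[None, :])
    return KCResponseSet(y=y, apl=T)


def coding_level(y: np.ndarray, activity_eps: float = 0.0) -> float:
    """Fraction of KCs active (response > activity_eps), averaged over trials."""
    y = np.asarray(y, dtype=float)
    if y.size == 0:
        raise ValueError("empty response matrix")
    if y.ndim == 1:
        y = y[None, :]
    if np.any(y < 0):
        raise ValueError("responses must be non-negative")
    return float((y > activity_eps).mean())


# ---------------------------------------------------------------------------
# Weight equalisation and (alpha, C_theta) tuning
# ---------------------------------------------------------------------------

def _mean_activity(E0, g, theta, alpha, c_theta):
    """Per-KC mean response across the panel for column scales g."""
    E = E0 * g[None, :]
    T = E.sum(axis=1)
    y = relu(E - alpha * T[:, None] - c_theta * theta[None, :])
    return y.mean(axis=0)


def _solve_equal_activity(E0, offsets, target):
    """Per-KC column scale g_j with mean_k Relu(g_j*E0_kj - offsets_kj) = target.

    The left side is piecewise linear and non-decreasing in g_j, with
    breakpoints at offsets/E0; solved exactly and vectorised across KCs.
    Columns with no positive drive yield NaN.
    """
    K, M = E0.shape
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(E0 > 0, offsets / np.where(E0 > 0, E0, 1.0), np.inf)
    order = np.argsort(r, axis=0)
    rs = np.take_along_axis(r, order, axis=0)
    Ecum = np.cumsum(np.take_along_axis(E0, order, axis=0), axis=0)
    Bcum = np.cumsum(np.take_along_axis(offsets, order, axis=0), axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        cand = (K * target + Bcum) / Ecum         # candidate g on each segment
    seg_hi = np.vstack([rs[1:], np.full((1, M), np.inf)])
    valid = (cand >= rs) & (cand <= seg_hi) & (Ecum > 0)
    g = np.full(M, np.nan)
    hit = valid.any(axis=0)
    first = np.argmax(valid, axis=0)
    cols = np.arange(M)[hit]
    g[hit] = cand[first[hit], cols]
    return g


def equalise_weights(
    circuit: MBCircuit,
    pn_panel: np.ndarray,
    tol: float = 0.02,
    max_iter: int = 200,
) -> MBCircuit:
    """Rescale each KC's input weights so mean panel responses are equal.

    At the circuit's current operating point (alpha, C_theta), each KC's
    weight column is rescaled multiplicatively towards the scale at which its
    mean response across the panel equals the population mean; steps are
    damped by half in log space because the population mean and the total
    APL drive shift as the weights move. KCs with zero excitatory drive to
    every panel odour cannot be rescued by scaling; they are excluded and
    reported via a warning. Raises :class:`EqualisationError` naming the
    worst deviation on non-convergence.
    """
    if not circuit.is_sampled:
        raise ValueError("circuit has no sampled weights/thresholds")
    x = np.asarray(pn_panel, dtype=float)
    if x.ndim != 2 or x.shape[1] != circuit.n_pn:
        raise ValueError("pn_panel must be (n_odours, n_pn)")
    E0 = x @ circuit.w                            # (n_odours, M)
    drive = E0.mean(axis=0)
    excluded = drive == 0
    if np.any(excluded):
        warnings.warn(
            f"{int(excluded.sum())} KC(s) receive zero panel drive and are "
            "excluded from weight equalisation",
            RuntimeWarning,
            stacklevel=2,
        )
    live = ~excluded
    g = np.ones(circuit.M)
    worst = np.inf
    for _ in range(max_iter):
        a = _mean_activity(E0, g, circuit.theta, circuit.alpha, circuit.c_theta)
        abar = a[live].mean()
        if abar == 0:
            raise EqualisationError(
                "population mean activity is zero; lower c_theta before equalising"
            )
        worst = float(np.abs(a[live] / abar - 1.0).max())
        if worst <= tol:
            break
        T = (E0 * g[None, :]).sum(axis=1)
        offsets = circuit.alpha * T[:, None] + circuit.c_theta * circuit.theta[None, :]
        g_star = _solve_equal_activity(E0 * g[None, :], offsets, abar)
        ok = live & np.isfinite(g_star) & (g_star > 0)
        g[ok] = g[ok] * np.exp(0.5 * np.log(g_star[ok]))
    else:
        a = _mean_activity(E0, g, circuit.theta, circuit.alpha, circuit.c_theta)
        abar = a[live].mean()
        j = int(np.argmax(np.abs(a / max(abar, 1e-300) - 1.0)))
        raise EqualisationError(
            f"not converged after {max_iter} iterations; worst deviation "
            f"{worst:.3g} at KC {j}"
        )
    out = circuit.copy()
    out.w = circuit.w * g[None, :]
    return out


def _bisect_coding_level(level_fn, lo, hi, target, tol, max_iter=200):
    """Bisection for a parameter at which the (decreasing) coding level hits target."""
    f_lo, f_hi = level_fn(lo), level_fn(hi)
    if f_lo < target - tol or f_hi > target + tol:
        raise TuningError(
            f"target coding level {target} unreachable in bracket "
            f"[{lo:.4g}, {hi:.4g}] (achieved {f_lo:.4f}..{f_hi:.4f})"
        )
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f_mid = level_fn(mid)
        if abs(f_mid - target) <= tol:
            return mid
        if f_mid > target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def tune_parameters(
    circuit: MBCircuit,
    pn_trials: np.ndarray,
    target_full: float = 0.10,
    target_blocked: float = 0.20,
    tol: float = 0.002,
) -> MBCircuit:
    """Tune (alpha, C_theta) to the sparse-coding constraints.

    Two-stage bisection exploiting the triangular structure of the
    constraints: the blocked (alpha = 0) coding level depends only on
    C_theta, so C_theta is bisected first until the blocked coding level
    equals ``target_blocked``; then, with C_theta fixed, alpha is bisected
    until the full coding level equals ``target_full``.
    """
    if not 0 < target_full < 1 or not 0 < target_blocked < 1:
        raise ValueError("targets must be in (0, 1)")
    if target_blocked <= target_full:
        raise ValueError(
            "target_blocked must exceed target_full: inhibition cannot raise activity"
        )
    if not circuit.is_sampled:
        raise ValueError("circuit has no sampled weights/thresholds")
    x = np.asarray(pn_trials, dtype=float)
    if x.ndim != 2 or x.shape[1] != circuit.n_pn:
        raise ValueError("pn_trials must be (n_trials, n_pn)")

    E = (x @ circuit.w).astype(np.float32)        # (trials, M)
    theta = circuit.theta.astype(np.float32)
    R = E / theta[None, :]                        # threshold-normalised drive

    # Stage 1: C_theta at alpha = 0 -> blocked target.
    hi = float(R.max())
    c_theta = _bisect_coding_level(
        lambda c: float((R > c).mean()), 0.0, hi, target_blocked, tol
    )

    # Stage 2: alpha at fixed C_theta -> full target.
    T = E.sum(axis=1)
    margin = E - c_theta * theta[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        A = margin / T[:, None]                   # alpha at which each KC shuts off
    pos = T > 0
    if not np.any(pos):
        raise TuningError("all trials have zero total drive")
    n_pairs = margin.size
    # Pairs in zero-drive trials feel no inhibition; they contribute a
    # constant count of active KCs at any alpha.
    const_active = int((margin[~pos] > 0).sum())
    A = A[pos]
    alpha_hi = float(np.nanmax(A))

    def full_level(alpha):
        return (float((A > alpha).sum()) + const_active) / n_pairs

    alpha = _bisect_coding_level(full_level, 0.0, max(alpha_hi, 1e-12),
                                 target_full, tol)
    out = circuit.copy()
    out.c_theta = float(c_theta)
    out.alpha = float(alpha)
    return out


def make_pn_inputs(
    panel: ORNPanel,
    transfer: TransferParams | None = None,
    cv_fn=default_cv,
    n_trials: int = 30,
    seed: int | np.random.Generator = 0,
) -> PNInputs:
    """Propagate an ORN panel to PN activity and generate noisy trials."""
    transfer = transfer or TransferParams()
    x = pn_transfer(panel, transfer)
    trials, odour_ids = add_pn_noise(x, cv_fn, n_trials, seed)
    return PNInputs(x=x, trials=trials, odour_ids=odour_ids,
                    designated_odour=panel.designated_odour)


def build_tuned_circuit(
    panel: ORNPanel,
    pn_inputs: PNInputs | None = None,
    M: int = 2000,
    seed: int = 0,
    transfer: TransferParams | None = None,
    cv_fn=default_cv,
    n_trials: int = 30,
    target_full: float = 0.10,
    target_blocked: float = 0.20,
    tune_tol: float = 0.002,
    eq_tol: float = 0.05,
    n_rounds: int = 6,
    **circuit_kwargs,
) -> tuple[MBCircuit, PNInputs]:
    """Sample, equalise and tune one model instance against an odour panel.

    Pipeline: sample connectivity/weights/thresholds from named sub-streams of
    ``seed``; tune (alpha, C_theta) on the noisy PN trials; then alternate
    weight equalisation (on the noiseless panel, at the current operating
    point) with retuning until both the coding levels and the equalisation
    objective hold simultaneously.
    """
    claws, w = sample_connectivity(
        M, panel.n_orns,
        circuit_kwargs.pop("claw_mu", 6.0), circuit_kwargs.pop("claw_sigma", 1.7),
        circuit_kwargs.pop("claw_range", (2, 11)),
        circuit_kwargs.pop("weight_mu", -0.0507),
        circuit_kwargs.pop("weight_sigma", 0.3527),
        seed=stream(seed, "connectivity"),
    )
    theta = sample_thresholds(M, circuit_kwargs.pop("theta_cv", 0.26),
                              seed=stream(seed, "thresholds"))
    circuit = MBCircuit(M=M, n_pn=panel.n_orns, w=w, claws=claws, theta=theta,
                        seed=seed, **circuit_kwargs)
    if pn_inputs is None:
        pn_inputs = make_pn_inputs(panel, transfer, cv_fn, n_trials,
                                   stream(seed, "pn_noise"))

    # Joint calibration: equalisation and the coding-level constraints are
    # coupled (rescaling weights shifts the coding level; retuning C_theta
    # re-spreads the activities), so single damped equalisation steps are
    # interleaved with exact empirical retuning of (alpha, C_theta) until the
    # combined fixed point is reached. The weight scale is gauge-fixed to
    # geometric mean 1 each step; C_theta carries the overall scale.
    E0 = pn_inputs.x @ circuit.w                  # (n_odours, M)
    theta = circuit.theta
    drive = E0.mean(axis=0)
    live = drive > 0
    if not np.all(live):
        warnings.warn(
            f"{int((~live).sum())} KC(s) receive zero panel drive and are "
            "excluded from weight equalisation",
            RuntimeWarning,
            stacklevel=2,
        )
    g = np.ones(circuit.M)
    for _ in range(max(1, n_rounds) * 10):
        E = E0 * g[None, :]
        R = E / theta[None, :]
        c_theta = float(np.quantile(R, 1.0 - target_blocked))
        T = E.sum(axis=1)
        margin = E - c_theta * theta[None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            alpha = float(max(np.quantile(margin / T[:, None], 1.0 - target_full), 0.0))
        offsets = alpha * T[:, None] + c_theta * theta[None, :]
        a = relu(E - offsets).mean(axis=0)
        abar = a[live].mean()
        if abar > 0 and np.abs(a[live] / abar - 1.0).max() <= eq_tol:
            break
        g_star = _solve_equal_activity(E, offsets, abar)
        ok = live & np.isfinite(g_star) & (g_star > 0)
        g[ok] = g[ok] * np.exp(0.5 * np.log(g_star[ok]))
        g[live] = g[live] / np.exp(np.log(g[live]).mean())
    circuit.w = circuit.w * g[None, :]
    # Final (alpha, C_theta) from the noisy trials, the tuning data proper.
    circuit = tune_parameters(circuit, pn_inputs.trials, target_full,
                              target_blocked, tune_tol)
    return circuit, pn_inputs
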