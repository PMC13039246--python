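"""State-space exploration of the tuned circuit by proportional scaling.

After tuning, KC properties are modified proportionally for the whole
population: excitatory weights w, inhibitory gain alpha and thresholds
C_theta are each multiplied by a scale factor (1.0 = the base model). The
main read-out is the mean total KC activity across noisy trials of the
designated isoamyl-acetate analogue odour, averaged over independently
sampled and tuned model instances. Grid searches over (g_w, g_alpha) and
(g_theta, g_alpha) reproduce the activity heat maps; "plasticity arrows"
(joint reduction of excitation and inhibition, with or without a complete
APL block) emulate the adapted-state experiments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._rng import stream
from .circuit_model import (
    MBCircuit,
    PNInputs,
    TransferParams,
    build_tuned_circuit,
    default_cv,
    kc_responses,
    make_pn_inputs,
    relu,
)
from .synthetic_data import ORNPanel

__all__ = [
    "ScalingPoint",
    "PlasticityGrid",
    "ModelInstance",
    "ArrowResult",
    "scale_circuit",
    "total_activity",
    "block_inhibition",
    "grid_search",
    "plasticity_arrow",
    "make_instances",
]

# Grid-search ranges used in the state-space exploration; single-point probes
# outside them are allowed with a warning.
W_ALPHA_RANGE = (0.0, 1.2)
THETA_RANGE = (0.8, 2.0)


@dataclass(frozen=True)
class ScalingPoint:
    """Proportional scales applied to the whole KC population."""

    g_w: float = 1.0
    g_alpha: float = 1.0
    g_theta: float = 1.0

    def __post_init__(self):
        if min(self.g_w, self.g_alpha, self.g_theta) < 0:
            raise ValueError("scale factors must be >= 0")


@dataclass
class ModelInstance:
    """One sampled and tuned circuit with its PN inputs."""

    circuit: MBCircuit
    pn_inputs: PNInputs

    # Cached per-trial excitation/APL drive for the designated odour, so grid
    # evaluation is pure elementwise work.
    _E: np.ndarray | None = None
    _T: np.ndarray | None = None

    def _cache(self):
        if self._E is None:
            trials = self.pn_inputs.designated_trials
            self._E = trials @ self.circuit.w
            self._T = self._E.sum(axis=1)
        return self._E, self._T

    def activity_at(self, point: ScalingPoint) -> float:
        """Mean total KC activity to the designated odour at a scaling point."""
        E, T = self._cache()
        c = self.circuit
        y = relu(point.g_w * E
                 - point.g_alpha * c.alpha * point.g_w * T[:, None]
                 - point.g_theta * c.c_theta * c.theta[None, :])
        return float(y.sum(axis=1).mean())


@dataclass
class PlasticityGrid:
    """Mean total KC activity over a grid of scaling points."""

    g_w_values: np.ndarray
    g_alpha_values: np.ndarray
    g_theta_values: np.ndarray
    mean_activity: np.ndarray   # (n_w, n_alpha, n_theta)
    sd_activity: np.ndarray     # across instances, same shape
    n_instances: int
    n_trials: int


@dataclass
class ArrowResult:
    """Read-outs of one plasticity-arrow experiment (means over instances)."""

    adapted: float
    adapted_blocked: float
    base: float
    base_blocked: float


def scale_circuit(circuit: MBCircuit, point: ScalingPoint) -> MBCircuit:
    """Return a copy with w, alpha and C_theta scaled; the base is unmodified."""
    out = circuit.copy()
    out.w = circuit.w * point.g_w
    out.alpha = circuit.alpha * point.g_alpha
    out.c_theta = circuit.c_theta * point.g_theta
    return out


def block_inhibition(circuit: MBCircuit) -> MBCircuit:
    """Copy of the circuit with inhibition set to zero (APL blocked)."""
    out = circuit.copy()
    out.alpha = 0.0
    return out


def total_activity(circuit: MBCircuit, pn_trials: np.ndarray) -> float:
    """Mean over trials of the summed KC activity."""
    pn_trials = np.asarray(pn_trials, dtype=float)
    if pn_trials.size == 0:
        raise ValueError("pn_trials must be non-empty")
    resp = kc_responses(pn_trials, circuit)
    return float(resp.y.sum(axis=1).mean())


def _check_axis(name, values):
    values = np.asarray(values, dtype=float)
    if np.any(values < 0):
        raise ValueError(f"{name} values must be >= 0")
    lo, hi = THETA_RANGE if name == "g_theta" else W_ALPHA_RANGE
    if values.min() < lo - 1e-12 or values.max() > hi + 1e-12:
        warnings.warn(
            f"{name} axis extends outside the grid-search range [{lo}, {hi}]",
            RuntimeWarning,
            stacklevel=3,
        )
    return values


def make_instances(
    n_instances: int = 20,
    panel: ORNPanel | None = None,
    seed: int = 0,
    M: int = 2000,
    n_trials: int = 30,
    transfer: TransferParams | None = None,
    cv_fn=default_cv,
    **tune_kwargs,
) -> list[ModelInstance]:
    """Sample and tune independent model instances against one odour panel.

    Each instance gets its own sub-seed (circuit sampling and PN noise), while
    the panel itself is shared, matching the averaged-over-20-instances
    read-out of the grid experiments.
    """
    if panel is None:
        from .synthetic_data import gen_orn_panel

        panel = gen_orn_panel(seed=stream(seed, "synthetic"))
    instances = []
    for i in range(n_instances):
        circuit, pn_inputs = build_tuned_circuit(
            panel, M=M, seed=seed * 1009 + i, transfer=transfer,
            cv_fn=cv_fn, n_trials=n_trials, **tune_kwargs,
        )
        instances.append(ModelInstance(circuit=circuit, pn_inputs=pn_inputs))
    return instances


def grid_search(
    instances: list[ModelInstance],
    g_w_values=(1.0,),
    g_alpha_values=(1.0,),
    g_theta_values=(1.0,),
) -> PlasticityGrid:
    """Mean total KC activity over a grid of scaling points.

    Activity at each grid cell is averaged over model instances (each already
    averaging over its noisy trials of the designated odour); the SD across
    instances is reported alongside.
    """
    if not instances:
        raise ValueError("need at least one model instance")
    g_w = _check_axis("g_w", g_w_values)
    g_a = _check_axis("g_alpha", g_alpha_values)
    g_t = _check_axis("g_theta", g_theta_values)
    acts = np.empty((len(instances), g_w.size, g_a.size, g_t.size))
    for n, inst in enumerate(instances):
        for i, gw in enumerate(g_w):
            for j, ga in enumerate(g_a):
                for k, gt in enumerate(g_t):
                    acts[n, i, j, k] = inst.activity_at(ScalingPoint(gw, ga, gt))
    n_trials = instances[0].pn_inputs.designated_trials.shape[0]
    return PlasticityGrid(
        g_w_values=g_w,
        g_alpha_values=g_a,
        g_theta_values=g_t,
        mean_activity=acts.mean(axis=0),
        sd_activity=acts.std(axis=0, ddof=1) if len(instances) > 1
        else np.zeros_like(acts[0]),
        n_instances=len(instances),
        n_trials=n_trials,
    )


def plot_heatmap(grid: PlasticityGrid, path, theta_axis: bool = False) -> None:
    """Render a 2-D activity heat map (w-alpha or theta-alpha) to a file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if theta_axis:
        act = grid.mean_activity[0, :, :].T
        x_vals, xlabel = grid.g_theta_values, "threshold scale"
    else:
        act = grid.mean_activity[:, :, 0].T
        x_vals, xlabel = grid.g_w_values, "excitatory scale"
    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.pcolormesh(x_vals, grid.g_alpha_values, act, shading="nearest",
                       cmap="magma")
    ax.set_xlabel(xlabel)
    ax.set_ylabel("inhibitory scale")
    fig.colorbar(im, ax=ax, label="total KC activity")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plasticity_arrow(
    instances: list[ModelInstance] | ModelInstance,
    endpoint: ScalingPoint,
    with_block: bool = True,
) -> ArrowResult:
    """Activity read-outs for an adapted state vs the base model, +/- APL block.

    ``endpoint`` is the adapted scaling (typically g_w < 1 and g_alpha < 1:
    "southwest" on the heat map). The blocked conditions re-evaluate the same
    circuits with inhibition set to zero, emulating the histamine-gated APL
    block.
    """
    if isinstance(instances, ModelInstance):
        instances = [instances]
    base = ScalingPoint(1.0, 1.0, 1.0)
    adapted_blocked = ScalingPoint(endpoint.g_w, 0.0, endpoint.g_theta)
    base_blocked = ScalingPoint(1.0, 0.0, 1.0)
    res = {"adapted": endpoint, "base": base}
    if with_block:
        res["adapted_blocked"] = adapted_blocked
        res["base_blocked"] = base_blocked
    means = {
        key: float(np.mean([inst.activity_at(pt) for inst in instances]))
        for key, pt in res.items()
    }
    return ArrowResult(
        adapted=means["adapted"],
        adapted_blocked=means.get("adapted_blocked", float("nan")),
        base=means["base"],
        base_blocked=means.get("base_blocked", float("nan")),
    )
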