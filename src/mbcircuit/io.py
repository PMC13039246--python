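"""CSV/JSON round-tripping of panels, tables, grids, traces and circuits.

All CSV artifacts carry a provenance header of ``#``-prefixed lines (package
version, seed, key parameters); readers skip them. Values round-trip at full
stored precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .circuit_model import MBCircuit
from .plasticity import PlasticityGrid
from .synthetic_data import ORNPanel, Trace

__all__ = [
    "write_orn_panel", "read_orn_panel",
    "write_paired_table", "read_paired_table",
    "write_grid", "read_grid",
    "write_trace", "read_trace",
    "write_circuit", "read_circuit",
]

_FLOAT_FMT = "%.17g"


def _provenance(kind: str, **meta) -> str:
    parts = [f"# mbcircuit v{__version__} {kind}"]
    parts += [f"# {k} = {v}" for k, v in meta.items()]
    return "\n".join(parts) + "\n"


def _write_csv(df: pd.DataFrame, path: Path, kind: str, index=False, **meta):
    with open(path, "w") as fh:
        fh.write(_provenance(kind, **meta))
        df.to_csv(fh, index=index, float_format=_FLOAT_FMT)


def _read_csv(path: Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", float_precision="round_trip", **kwargs)


def write_orn_panel(panel: ORNPanel, path: str | Path, **meta) -> None:
    """Odours as rows, ORN classes as columns, header row of labels."""
    df = pd.DataFrame(panel.rates, index=panel.odour_labels,
                      columns=panel.orn_labels)
    df.index.name = "odour"
    _write_csv(df, Path(path), "orn_panel", index=True,
               designated_odour=panel.odour_labels[panel.designated_odour],
               **meta)


def read_orn_panel(path: str | Path) -> ORNPanel:
    designated = 0
    for line in Path(path).read_text().splitlines():
        if line.startswith("# designated_odour ="):
            label = line.split("=", 1)[1].strip()
            break
    else:
        label = None
    df = _read_csv(Path(path), index_col=0)
    if df.empty or df.index.name != "odour":
        raise ValueError("expected an ORN panel CSV with an 'odour' index column")
    odours = [str(x) for x in df.index]
    if label is not None and label in odours:
        designated = odours.index(label)
    return ORNPanel(rates=df.to_numpy(dtype=float), odour_labels=odours,
                    orn_labels=[str(c) for c in df.columns],
                    designated_odour=designated)


def write_paired_table(kc: np.ndarray, apl: np.ndarray, path: str | Path,
                       sample_ids=None, odour_ids=None, **meta) -> None:
    """Long format: sample id, odour id, KC value, APL value."""
    kc = np.asarray(kc, dtype=float)
    apl = np.asarray(apl, dtype=float)
    n_s, n_o = kc.shape
    sample_ids = sample_ids or [f"s{i:03d}" for i in range(n_s)]
    odour_ids = odour_ids or [f"od{i}" for i in range(n_o)]
    df = pd.DataFrame({
        "sample_id": np.repeat(sample_ids, n_o),
        "odour_id": np.tile(odour_ids, n_s),
        "kc": kc.ravel(),
        "apl": apl.ravel(),
    })
    _write_csv(df, Path(path), "paired_table", **meta)


def read_paired_table(path: str | Path):
    df = _read_csv(Path(path))
    expected = {"sample_id", "odour_id", "kc", "apl"}
    if set(df.columns) != expected:
        raise ValueError(
            f"paired table must have columns {sorted(expected)}, "
            f"got {sorted(df.columns)}"
        )
    samples = df["sample_id"].unique().tolist()
    odours = df["odour_id"].unique().tolist()
    kc = df.pivot(index="sample_id", columns="odour_id", values="kc")
    apl = df.pivot(index="sample_id", columns="odour_id", values="apl")
    kc = kc.loc[samples, odours]
    apl = apl.loc[samples, odours]
    return (kc.to_numpy(dtype=float), apl.to_numpy(dtype=float),
            [str(s) for s in samples], [str(o) for o in odours])


def write_grid(grid: PlasticityGrid, path: str | Path, **meta) -> None:
    """Long-format grid CSV: scaling factors, mean and SD of total activity."""
    rows = []
    for i, gw in enumerate(grid.g_w_values):
        for j, ga in enumerate(grid.g_alpha_values):
            for k, gt in enumerate(grid.g_theta_values):
                rows.append((gw, ga, gt, grid.mean_activity[i, j, k],
                             grid.sd_activity[i, j, k]))
    df = pd.DataFrame(rows, columns=["g_w", "g_alpha", "g_theta",
                                     "mean_activity", "sd_activity"])
    _write_csv(df, Path(path), "plasticity_grid",
               n_instances=grid.n_instances, n_trials=grid.n_trials, **meta)


def read_grid(path: str | Path) -> PlasticityGrid:
    meta = {"n_instances": 0, "n_trials": 0}
    for line in Path(path).read_text().splitlines():
        for key in meta:
            if line.startswith(f"# {key} ="):
                meta[key] = int(line.split("=", 1)[1])
    df = _read_csv(Path(path))
    needed = {"g_w", "g_alpha", "g_theta", "mean_activity", "sd_activity"}
    if not needed <= set(df.columns):
        raise ValueError(f"grid CSV must have columns {sorted(needed)}")
    gw = np.unique(df["g_w"])
    ga = np.unique(df["g_alpha"])
    gt = np.unique(df["g_theta"])
    shape = (gw.size, ga.size, gt.size)
    mean = np.full(shape, np.nan)
    sd = np.full(shape, np.nan)
    iw = np.searchsorted(gw, df["g_w"])
    ia = np.searchsorted(ga, df["g_alpha"])
    it = np.searchsorted(gt, df["g_theta"])
    mean[iw, ia, it] = df["mean_activity"]
    sd[iw, ia, it] = df["sd_activity"]
    return PlasticityGrid(g_w_values=gw, g_alpha_values=ga, g_theta_values=gt,
                          mean_activity=mean, sd_activity=sd,
                          n_instances=meta["n_instances"],
                          n_trials=meta["n_trials"])


def write_trace(trace: Trace, path: str | Path, column: str = "dff",
                **meta) -> None:
    """Two-column CSV: time (s) and signal."""
    df = pd.DataFrame({"time_s": trace.time, column: trace.values})
    _write_csv(df, Path(path), "trace", frame_time=repr(trace.frame_time), **meta)


def read_trace(path: str | Path) -> Trace:
    df = _read_csv(Path(path))
    if df.shape[1] != 2 or df.columns[0] != "time_s":
        raise ValueError("trace CSV must have columns (time_s, <signal>)")
    t = df["time_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError("trace must have at least 2 frames")
    return Trace(frame_time=float(t[1] - t[0]),
                 values=df.iloc[:, 1].to_numpy(dtype=float))


def write_circuit(circuit: MBCircuit, prefix: str | Path) -> None:
    """Serialise a circuit: JSON header plus CSV weight and claw tables."""
    prefix = Path(prefix)
    header = {
        "version": __version__,
        "M": circuit.M,
        "n_pn": circuit.n_pn,
        "alpha": circuit.alpha,
        "c_theta": circuit.c_theta,
        "claw_mu": circuit.claw_mu,
        "claw_sigma": circuit.claw_sigma,
        "claw_range": list(circuit.claw_range),
        "weight_mu": circuit.weight_mu,
        "weight_sigma": circuit.weight_sigma,
        "theta_cv": circuit.theta_cv,
        "seed": circuit.seed,
    }
    prefix.with_suffix(".json").write_text(json.dumps(header, indent=2))
    w_df = pd.DataFrame(circuit.w)
    w_df.to_csv(prefix.with_suffix(".weights.csv"), index=False,
                float_format=_FLOAT_FMT)
    rows = [(j, " ".join(map(str, circuit.claws[j]))) for j in range(circuit.M)]
    claws_df = pd.DataFrame(rows, columns=["kc", "claw_pns"])
    theta_df = pd.DataFrame({"theta": circuit.theta})
    claws_df.to_csv(prefix.with_suffix(".claws.csv"), index=False)
    theta_df.to_csv(prefix.with_suffix(".theta.csv"), index=False,
                    float_format=_FLOAT_FMT)


def read_circuit(prefix: str | Path) -> MBCircuit:
    prefix = Path(prefix)
    header = json.loads(prefix.with_suffix(".json").read_text())
    w = pd.read_csv(prefix.with_suffix(".weights.csv"),
                    float_precision="round_trip").to_numpy(dtype=float)
    theta = pd.read_csv(prefix.with_suffix(".theta.csv"),
                        float_precision="round_trip")["theta"].to_numpy(dtype=float)
    claws_df = pd.read_csv(prefix.with_suffix(".claws.csv"))
    claws = [np.array([int(p) for p in str(s).split()])
             for s in claws_df["claw_pns"]]
    return MBCircuit(
        M=header["M"], n_pn=header["n_pn"], w=w, claws=claws, theta=theta,
        alpha=header["alpha"], c_theta=header["c_theta"],
        claw_mu=header["claw_mu"], claw_sigma=header["claw_sigma"],
        claw_range=tuple(header["claw_range"]), weight_mu=header["weight_mu"],
        weight_sigma=header["weight_sigma"], theta_cv=header["theta_cv"],
        seed=header["seed"],
    )
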