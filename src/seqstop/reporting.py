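"""I/O and figure helpers shared by the command-line entry points.

Covers reading user data (one-column streams, two-column group/value CSV),
writing run manifests, and rendering the two standard figures: p-value
trajectories with the 0.05 reference line, and the false-positive-rate
curve of sequential stopping against the independent-test FWER curve.
"""

from __future__ import annotations

import dataclasses
import json
import sys
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__

__all__ = [
    "RunManifest",
    "write_manifest",
    "read_single_column",
    "read_two_group_csv",
    "load_config_file",
    "log_phase",
    "plot_trajectories",
    "plot_fdr_curve",
]


@dataclass(frozen=True)
class RunManifest:
    """Everything needed to reproduce one CLI run exactly."""

    command: str
    config_snapshot: dict
    seed: int
    version: str = __version__
    timestamp: str = ""

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        if not d["timestamp"]:
            d["timestamp"] = datetime.now(timezone.utc).isoformat(timespec="seconds")
        return json.dumps(d, indent=2, sort_keys=True, default=str)


def write_manifest(out_dir: Path, command: str, config: dict, seed: int) -> Path:
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "manifest.json"
    path.write_text(RunManifest(command, config, seed).to_json() + "\n")
    return path


def log_phase(phase: str, **info) -> None:
    """One structured status line per phase, to stderr."""
    extra = " ".join(f"{k}={v}" for k, v in info.items())
    print(f"[seqstop] {phase}" + (f" {extra}" if extra else ""), file=sys.stderr)


def read_single_column(path) -> np.ndarray:
    """Read one numeric value per line; '#' lines are comments."""
    values = []
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        s = line.strip()
        if not s or s.startswith("#"):
            continue
        try:
            values.append(float(s))
        except ValueError:
            raise ValueError(f"{path}:{i}: not a number: {s!r}") from None
    return np.asarray(values)


def read_two_group_csv(path):
    """Read a two-column CSV (group,value); returns exactly two arrays.

    The two group labels are taken in order of first appearance.
    """
    df = pd.read_csv(path)
    cols = [c.lower() for c in df.columns]
    if "group" not in cols or "value" not in cols:
        raise ValueError(f"{path}: expected columns 'group' and 'value', got {list(df.columns)}")
    df.columns = cols
    labels = list(dict.fromkeys(df["group"]))
    if len(labels) != 2:
        raise ValueError(f"{path}: expected exactly 2 groups, found {len(labels)}")
    a = df.loc[df["group"] == labels[0], "value"].to_numpy(dtype=float)
    b = df.loc[df["group"] == labels[1], "value"].to_numpy(dtype=float)
    return labels, a, b


def load_config_file(path) -> dict:
    """Plain key-value YAML config; flags override these values."""
    import yaml

    data = yaml.safe_load(Path(path).read_text())
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config file must be a mapping of key: value")
    return {str(k).replace("-", "_"): v for k, v in data.items()}


def _agg():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def plot_trajectories(trajectories, alpha: float, path) -> None:
    """p-value vs per-group n for several runs, log-scaled p axis.

    The first crossing of each run is dotted; runs that never cross are
    drawn dashed so the 'never crossed' category is visually distinct.
    """
    plt = _agg()
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for k, traj in enumerate(trajectories):
        style = "-" if traj.first_crossing is not None else "--"
        (line,) = ax.plot(traj.n, traj.p_values, style, lw=1.2, alpha=0.8)
        if traj.first_crossing is not None:
            i = traj.first_crossing - traj.n[0]
            ax.plot(traj.first_crossing, traj.p_values[i], "ko", ms=5, zorder=5)
    ax.axhline(alpha, color="gray", ls=":", lw=1)
    ax.set_yscale("log")
    ax.set_xlabel("per-group sample size n")
    ax.set_ylabel("p-value")
    ax.set_title("Sequential p-values under H0 (dots: first crossing)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_fdr_curve(curve, independent_rates, path) -> None:
    """Sequential false-positive curve vs independent-test FWER curve."""
    plt = _agg()
    fig, ax = plt.subplots(figsize=(7, 4.5))
    ax.plot(curve.caps, curve.rates, color="tab:blue", label="sequential (unadjusted)")
    ax.plot(curve.caps, independent_rates, color="tab:red", label="independent tests")
    ax.set_xlabel("stopping cap (per-group n)")
    ax.set_ylabel("false discovery rate under H0")
    ax.set_ylim(0, 1)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
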