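"""Optional figure rendering (trajectory lines, sweep heatmaps).

Plots are a convenience for eyeballing runs; nothing downstream depends on
them.  matplotlib is imported lazily so the rest of the package works
without it.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np


def plot_trajectory(traj, path: str | Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.plot(traj.times, traj.e, "-", label="efficient e(t)")
    ax.plot(traj.times, traj.i, "--", label="inefficient i(t)")
    ax.plot(traj.times, traj.n, ":", label="naive n(t)")
    ax.set_xlabel("time")
    ax.set_ylabel("fraction")
    ax.set_ylim(-0.02, 1.02)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_sweep(grid, path: str | Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    masked = np.ma.masked_where(~grid.reachable, grid.values)
    fig, ax = plt.subplots(figsize=(4.6, 3.6))
    mesh = ax.pcolormesh(
        grid.axis2_values, grid.axis1_values, masked, shading="nearest"
    )
    fig.colorbar(mesh, ax=ax, label=grid.value_name)
    ax.set_xlabel(grid.axis2_name)
    ax.set_ylabel(grid.axis1_name)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
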