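"""Matplotlib views of actuator states and strain maps."""

from __future__ import annotations

import numpy as np

from .fem import ActuatorState
from .strainmap import LandmarkSet, TriangulationMap

#: Display magnification for principal-strain crosses.
STRAIN_CROSS_SCALE = 3.0


def plot_actuator_state(state: ActuatorState, ax=None, configuration="dry"):
    """Region-coloured triangle plot of the wet or dry configuration."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    nodes = state.dry_nodes if configuration == "dry" else state.mesh.nodes
    ax.tripcolor(nodes[:, 0], nodes[:, 1], state.mesh.triangles,
                 facecolors=state.mesh.region_id.astype(float), cmap="tab10",
                 vmin=0, vmax=9)
    ax.set_aspect(1.0)
    ax.set_xlabel("x (μm)")
    ax.set_ylabel("y (μm)")
    ax.set_title(f"{configuration} configuration, θ = {state.theta:.1f}°")
    return ax


def plot_displacement_quiver(state: ActuatorState, ax=None, step: int = 6):
    """Displacement field relative to the podium centre (wet frame)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    u = state.displacement_relative_to_podium()
    sel = np.arange(0, state.mesh.n_nodes, step)
    ax.quiver(state.mesh.nodes[sel, 0], state.mesh.nodes[sel, 1],
              u[sel, 0], u[sel, 1], angles="xy", scale_units="xy", scale=1.0,
              width=2e-3)
    ax.set_aspect(1.0)
    return ax


def plot_area_change_map(tmap: TriangulationMap, lm: LandmarkSet, ax=None,
                         crosses: bool = True):
    """Smoothed wet/dry area-ratio heat map with principal-strain crosses."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    vals = np.where(tmap.valid, tmap.smoothed, np.nan)
    ax.tripcolor(lm.dry[:, 0], lm.dry[:, 1], tmap.triangles,
                 facecolors=vals, cmap="viridis")
    if crosses and tmap.stretches is not None:
        cent = lm.dry[tmap.triangles].mean(axis=1)
        for i in np.flatnonzero(tmap.valid):
            for k in range(2):
                d = tmap.directions[i, k] * tmap.stretches[i, k] * STRAIN_CROSS_SCALE
                ax.plot([cent[i, 0] - d[0], cent[i, 0] + d[0]],
                        [cent[i, 1] - d[1], cent[i, 1] + d[1]],
                        color="r", lw=0.6)
    ax.set_aspect(1.0)
    return ax
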