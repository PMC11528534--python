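"""Matplotlib rendering of tissue snapshots (side-effect free)."""

from __future__ import annotations

import numpy as np

from ..tissue_mech import LINEAGE_CANCER, TissueState

__all__ = ["render_tissue", "render_snapshot_file"]


def render_tissue(tissue: TissueState, ax=None, cmap: str = "viridis", show_cancer: bool = True):
    """Draw cell polygons coloured by glucose; cancer cells outlined in red."""
    import matplotlib.pyplot as plt
    from matplotlib.collections import PolyCollection

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    tess = tissue.tessellation()
    colors = np.clip(tissue.glucose, 0.0, 1.0)
    pc = PolyCollection(tess.vertices, array=colors, cmap=cmap, edgecolor="k", linewidth=0.4)
    pc.set_clim(0.0, 1.0)
    ax.add_collection(pc)
    if show_cancer:
        for i in np.where(tissue.lineages == LINEAGE_CANCER)[0]:
            ax.plot(*np.vstack([tess.vertices[i], tess.vertices[i][:1]]).T, color="red", lw=1.5)
    minx, miny, maxx, maxy = tissue.domain.polygon.bounds
    ax.set_xlim(minx, maxx)
    ax.set_ylim(miny, maxy)
    ax.set_aspect("equal")
    ax.figure.colorbar(pc, ax=ax, label="glucose concentration")
    return ax


def render_snapshot_file(snapshot_path, out_path):
    """Render a JSON snapshot to PNG/SVG (format from the extension)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .snapshots import read_snapshot

    tissue, _, doc = read_snapshot(snapshot_path)
    ax = render_tissue(tissue)
    ax.set_title(f"t = {doc.get('time', 0):.2f}")
    ax.figure.savefig(out_path, dpi=150, bbox_inches="tight")
    plt.close(ax.figure)
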