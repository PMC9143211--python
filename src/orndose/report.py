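"""Per-case figure panels: mandible, Vm56, Vm-PTV, post-resection, residual.

Each case is rendered as a five-panel axial maximum-intensity-projection
figure mirroring the workflow stages: total mandible, mandible inside the
56 Gy isodose, mandible inside the PTV, residual mandible after resection,
and residual Vm56. An empty region renders as an empty panel, not an error.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .pipeline import CaseResult, iso56_and_mandible
from .volumetrics import intersect, volume_ml

__all__ = ["render_case"]

_PANELS = ["Vm", "Vm56", "Vm-PTV", "VmR (residual)", "Vm56R"]


def _panel_masks(result: CaseResult):
    mandible = result.mandible
    vm56 = iso56_and_mandible(result.iso56, mandible)
    vmptv = intersect(mandible, result.ptv)
    residual = result.residual if result.residual is not None else mandible
    vm56r = intersect(residual, result.iso56)
    return [mandible, vm56, vmptv, residual, vm56r]


def render_case(result: CaseResult, out_path: str | Path, case_id: str = "case") -> Path:
    """Write the five-panel figure for one case; returns the written path."""
    out_path = Path(out_path)
    masks = _panel_masks(result)
    colors = ["#c8c8c8", "#e6c300", "#cc2222", "#c8c8c8", "#e6c300"]

    fig, axes = plt.subplots(1, 5, figsize=(16, 3.6))
    outline = result.mandible.mask.any(axis=2).T
    for ax, mask, title, color in zip(axes, masks, _PANELS, colors):
        ax.imshow(outline, origin="lower", cmap="gray", alpha=0.25)
        mip = mask.mask.any(axis=2).T
        if mip.any():
            overlay = np.zeros((*mip.shape, 4))
            rgb = matplotlib.colors.to_rgb(color)
            overlay[mip] = (*rgb, 0.9)
            ax.imshow(overlay, origin="lower")
        ax.set_title(f"{title}\n{volume_ml(mask):.1f} mL", fontsize=10)
        ax.set_axis_off()
    fig.suptitle(case_id)
    fig.tight_layout()
    fig.savefig(out_path, dpi=110)
    plt.close(fig)
    return out_path
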