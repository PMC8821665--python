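"""Figure views: serial coronal overlays, whole-brain projections, the
rotated tangential barrel-field view, and per-region bar charts.

All views are orthographic drops of one anatomical axis of the resampled
point cloud.  Conventions (CCF-style): axis 0 = anterior-posterior (AP),
axis 1 = dorso-ventral (DV, depth), axis 2 = medio-lateral (ML).

* coronal: drop AP (plot ML vs DV).
* horizontal: drop DV (plot ML vs AP).
* tangential: rotate about the AP axis (30 degrees by default, bringing
  the barrel-field pial surface toward the view normal), then drop DV.

Serial overlays partition the cloud into half-open AP slabs of equal
thickness (span / section count) and project each slab; the figures use a
maximum projection of each 300-800 um slab.  Tests assert on the exported
coordinate/value arrays, never on encoded image bytes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
import numpy as np
import pandas as pd

from .quantify import CohortSummary, RegionLengthTable
from .resampling import ResampledCloud

__all__ = ["ViewSpec", "Projection", "project", "serial_sections",
           "region_bar_chart", "DEFAULT_COLORS"]

AP_AXIS, DV_AXIS, ML_AXIS = 0, 1, 2

DEFAULT_COLORS = {
    "gray_matter": "red",
    "fiber_tract": "blue",
    "striatum": "green",
    "dendrite": "black",
}


@dataclass
class ViewSpec:
    """Parameters of one rendered view."""

    view: str = "coronal"               # coronal | horizontal | tangential
    rotation_deg: float = 30.0          # used by the tangential view
    section_span_um: float | None = None
    section_count: int = 5
    rotation_axis: int = AP_AXIS        # configurable; see methods note
    colors: dict = field(default_factory=lambda: dict(DEFAULT_COLORS))

    def __post_init__(self) -> None:
        if self.view not in ("coronal", "horizontal", "tangential"):
            raise ValueError(f"unknown view {self.view!r}")
        if self.section_count < 1:
            raise ValueError("section_count must be >= 1")
        if self.section_span_um is not None and self.section_span_um <= 0:
            raise ValueError("section span must be positive")

    @property
    def section_thickness_um(self) -> float:
        """Slab thickness of the serial overlay: span / count."""
        if self.section_span_um is None:
            raise ValueError("no section span configured")
        return self.section_span_um / self.section_count


@dataclass
class Projection:
    """2D point set of one view plus enough provenance to re-plot it."""

    coords2d: np.ndarray          # (n, 2) um
    type_codes: np.ndarray
    axes: tuple[str, str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            self.axes[0]: self.coords2d[:, 0],
            self.axes[1]: self.coords2d[:, 1],
            "type": self.type_codes,
        })

    def figure(self, dpi: int = 100, point_size: float = 0.5):
        import matplotlib
        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(dpi=dpi)
        ax.scatter(self.coords2d[:, 0], self.coords2d[:, 1],
                   s=point_size, c="k", linewidths=0)
        ax.set_xlabel(f"{self.axes[0]} (um)")
        ax.set_ylabel(f"{self.axes[1]} (um)")
        ax.set_aspect("equal")
        ax.invert_yaxis()
        return fig


def _rotation_matrix(axis: int, angle_deg: float) -> np.ndarray:
    c, s = math.cos(math.radians(angle_deg)), math.sin(math.radians(angle_deg))
    other = [a for a in range(3) if a != axis]
    m = np.eye(3)
    m[other[0], other[0]] = c
    m[other[0], other[1]] = -s
    m[other[1], other[0]] = s
    m[other[1], other[1]] = c
    return m


def project(cloud: ResampledCloud, view: ViewSpec) -> Projection:
    """Orthographic projection of the cloud for one view."""
    pts = cloud.points
    if len(pts) == 0:
        warnings.warn("projecting an empty cloud")
    if view.view == "coronal":
        keep, axes = (ML_AXIS, DV_AXIS), ("ml", "dv")
    elif view.view == "horizontal":
        keep, axes = (ML_AXIS, AP_AXIS), ("ml", "ap")
    else:  # tangential: rotate about the AP axis, then view from above
        rot = _rotation_matrix(view.rotation_axis, view.rotation_deg)
        pts = pts @ rot.T
        keep, axes = (ML_AXIS, AP_AXIS), ("ml", "ap")
    coords2d = pts[:, list(keep)] if len(pts) else np.empty((0, 2))
    return Projection(coords2d, cloud.type_codes.copy(), axes)


def serial_sections(
    cloud: ResampledCloud,
    view: ViewSpec,
    ap_start: float | None = None,
) -> list[Projection]:
    """Partition the cloud into AP slabs and project each.

    Slabs are half-open ``[start + k*t, start + (k+1)*t)`` with thickness
    t = span / section_count; the last slab is closed at the top so the
    union covers the span and every point lands in exactly one slab.
    """
    if view.section_span_um is None or view.section_span_um <= 0:
        raise ValueError("serial sections need a positive section span")
    t = view.section_thickness_um
    ap = cloud.points[:, AP_AXIS] if len(cloud) else np.empty(0)
    start = float(ap.min()) if ap_start is None and len(ap) else (ap_start or 0.0)
    out = []
    for k in range(view.section_count):
        lo, hi = start + k * t, start + (k + 1) * t
        if k == view.section_count - 1:
            mask = (ap >= lo) & (ap <= hi)
        else:
            mask = (ap >= lo) & (ap < hi)
        slab = cloud.select(mask) if len(cloud) else cloud
        sub = ViewSpec(view="coronal", colors=view.colors)
        out.append(project(slab, sub))
    return out


def region_bar_chart(
    data: RegionLengthTable | CohortSummary,
    neurite_type: str = "axon",
    top: int | None = None,
):
    """Descending bar chart of per-region lengths (or cohort means).

    Returns ``(figure, ordered_values)`` where ``ordered_values`` is the
    DataFrame behind the bars (descending by length/mean, acronym
    tie-break) so tests can assert on values rather than pixels.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if isinstance(data, CohortSummary):
        df = data.df.copy()
        value_col, err_col = "mean_um", "sd_um"
    else:
        df = data.rows_for(neurite_type).copy()
        value_col, err_col = "length_um", None
        df = df.sort_values([value_col, "acronym"],
                            ascending=[False, True], ignore_index=True)
    if top is not None:
        df = df.head(top)
    fig, ax = plt.subplots(dpi=100, figsize=(max(4, 0.4 * len(df)), 3))
    ax.bar(df.acronym, df[value_col] / 1000.0,
           yerr=(df[err_col] / 1000.0) if err_col else None,
           color="0.4")
    ax.set_ylabel("length (mm)")
    ax.tick_params(axis="x", rotation=90)
    fig.tight_layout()
    return fig, df
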