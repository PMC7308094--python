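"""Isodensity maps and quadrant opsin-composition profiles.

Density maps bin cone positions on a square grid (83.3 μm bins by default)
and convert counts to cones/mm²; rendering uses a 10-step color scale whose
maximum depends on the population (17,300 cones/mm² for all/mixed/M-only in
the pigmented strain; 5,000 for true S-cones and albino M-only; 1,400 for
SCBCs).  Quadrant profiles split the retina into dorsotemporal, dorsonasal,
ventrotemporal and ventronasal sectors around the optic-nerve head and
report, per radial distance bin, the relative percentage of the three cone
classes (summing to 100 in each bin).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic_retina import CONE_TYPES, ConeMosaic

DEFAULT_BIN_UM = 83.3
SCALE_MAX = {
    "all": 17_300.0,
    "mixed": 17_300.0,
    "m_only": 17_300.0,
    "true_s": 5_000.0,
    "m_only_albino": 5_000.0,
    "scbc": 1_400.0,
}
N_COLOR_STEPS = 10

QUADRANTS = ("DT", "DN", "VT", "VN")


@dataclass
class DensityGrid:
    """Binned counts/densities with the color-scale specification."""

    counts: np.ndarray  # (ny, nx), row 0 at the ventral-most bin
    x_edges: np.ndarray
    y_edges: np.ndarray
    bin_size_um: float
    scale_max: float
    n_steps: int = N_COLOR_STEPS

    @property
    def density(self) -> np.ndarray:
        """Cones/mm² per bin."""
        bin_area_mm2 = (self.bin_size_um * 1e-3) ** 2
        return self.counts / bin_area_mm2

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def color_levels(self) -> np.ndarray:
        """Boundaries of the 10-step color scale over [0, scale_max]."""
        return np.linspace(0.0, self.scale_max, self.n_steps + 1)


def density_map(
    points: np.ndarray,
    bin_size_um: float = DEFAULT_BIN_UM,
    extent: tuple[float, float, float, float] | None = None,
    population: str = "all",
) -> DensityGrid:
    """Bin a point set into a density grid.

    Bin edges are aligned to integer multiples of ``bin_size_um`` so that
    translating all points by one full bin shifts the grid by exactly one
    index.  The sum of bin counts equals the number of points inside the
    grid (all of them when ``extent`` is None).
    """
    if bin_size_um <= 0:
        raise ValueError("bin_size_um must be positive")
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if extent is None:
        if len(pts) == 0:
            extent = (0.0, 0.0, bin_size_um, bin_size_um)
        else:
            extent = (
                pts[:, 0].min(),
                pts[:, 1].min(),
                pts[:, 0].max(),
                pts[:, 1].max(),
            )
    x0 = np.floor(extent[0] / bin_size_um) * bin_size_um
    y0 = np.floor(extent[1] / bin_size_um) * bin_size_um
    nx = max(1, int(np.ceil((extent[2] - x0) / bin_size_um + 1e-9)))
    ny = max(1, int(np.ceil((extent[3] - y0) / bin_size_um + 1e-9)))
    x_edges = x0 + bin_size_um * np.arange(nx + 1)
    y_edges = y0 + bin_size_um * np.arange(ny + 1)
    counts, _, _ = np.histogram2d(pts[:, 1], pts[:, 0], bins=(y_edges, x_edges))
    scale = SCALE_MAX.get(population, SCALE_MAX["all"])
    return DensityGrid(counts.astype(int), x_edges, y_edges, bin_size_um, scale)


def assign_quadrant(x, y) -> np.ndarray:
    """Quadrant labels with boundaries along the x/y axes through the
    optic-nerve head: DT (dorsal-temporal, x<0 y≥0), DN (x≥0, y≥0),
    VT (x<0, y<0), VN (x≥0, y<0).  The DT–VN diagonal is the axis used for
    the circular mosaic samples."""
    x = np.asarray(x)
    y = np.asarray(y)
    out = np.where(
        y >= 0,
        np.where(x < 0, "DT", "DN"),
        np.where(x < 0, "VT", "VN"),
    )
    return out


def quadrant_profiles(
    mosaic: ConeMosaic,
    bin_width_um: float = 2 * DEFAULT_BIN_UM,
    min_cones_per_bin: int = 20,
) -> pd.DataFrame:
    """Relative cone-class composition versus distance from the optic-nerve
    head, per retinal quadrant.

    Returns a tidy table: quadrant, bin_center_um, n, pct_MIXED, pct_TRUE_S,
    pct_M_ONLY (percentages sum to 100 per bin) and a low_n flag for bins
    with fewer than ``min_cones_per_bin`` cones.
    """
    df = mosaic.df
    x = df["x_um"].to_numpy()
    y = df["y_um"].to_numpy()
    r = np.hypot(x, y)
    quad = assign_quadrant(x, y)
    types = df["type"].to_numpy()
    r_max = r.max() if len(r) else bin_width_um
    edges = np.arange(0.0, r_max + bin_width_um, bin_width_um)
    which = np.clip(np.digitize(r, edges) - 1, 0, len(edges) - 2)

    records = []
    for q in QUADRANTS:
        in_q = quad == q
        for b in range(len(edges) - 1):
            sel = in_q & (which == b)
            n = int(sel.sum())
            if n == 0:
                continue
            rec = {
                "quadrant": q,
                "bin_center_um": (edges[b] + edges[b + 1]) / 2,
                "n": n,
                "low_n": n < min_cones_per_bin,
            }
            for t in CONE_TYPES:
                rec[f"pct_{t}"] = 100.0 * np.sum(types[sel] == t) / n
            records.append(rec)
    return pd.DataFrame(records)
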