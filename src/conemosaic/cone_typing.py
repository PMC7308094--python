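"""Cone-type classification from paired S- and M-channel detections.

A cone co-expressing both opsins appears in both channels at (nearly) the
same position, so mutual-nearest-neighbour pairs within a small matching
radius are classified MIXED; unmatched S detections are TRUE_S and
unmatched M detections are M_ONLY.  Mutual matching (rather than greedy)
makes the result deterministic and independent of input order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from ._geometry import Disk, Rect, square
from .synthetic_retina import MIXED, M_ONLY, TRUE_S, ConeMosaic

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TypingConfig:
    """match_radius_um: maximum S–M centroid separation for a MIXED call.

    Region sampling follows a three-regions scheme along the dorso-ventral
    axis (dorsal +1.5 mm, medial near the optic-nerve head but shifted off
    it, ventral −1.5 mm), each probed with three 135 × 135 μm squares.
    """

    match_radius_um: float = 3.0
    sample_side_um: float = 135.0
    region_centers: dict = field(
        default_factory=lambda: {
            "dorsal": (0.0, 1500.0),
            "medial": (300.0, 0.0),
            "ventral": (0.0, -1500.0),
        }
    )
    samples_per_region: int = 3
    sample_spacing_um: float = 150.0

    def region_squares(self, region: str) -> list[Rect]:
        cx, cy = self.region_centers[region]
        offs = (np.arange(self.samples_per_region) - (self.samples_per_region - 1) / 2)
        return [square(cx + o * self.sample_spacing_um, cy, self.sample_side_um) for o in offs]


def _dedupe(points: np.ndarray) -> np.ndarray:
    """Drop exact duplicate coordinates, keeping first occurrence."""
    _, idx = np.unique(points.round(6), axis=0, return_index=True)
    if len(idx) < len(points):
        logger.warning("deduplicated %d duplicate detections", len(points) - len(idx))
    return np.sort(idx)


def match_detections(
    s_points: np.ndarray, m_points: np.ndarray, match_radius_um: float
) -> list[tuple[int, int]]:
    """Mutual-nearest-neighbour pairs (s_index, m_index) within the radius.

    Each detection is used at most once; ties broken toward the smaller
    index by the stable nearest-neighbour query.
    """
    if len(s_points) == 0 or len(m_points) == 0:
        return []
    s_tree = cKDTree(s_points)
    m_tree = cKDTree(m_points)
    d_sm, nn_sm = m_tree.query(s_points, distance_upper_bound=match_radius_um)
    _, nn_ms = s_tree.query(m_points, distance_upper_bound=match_radius_um)
    pairs = []
    for i, (d, j) in enumerate(zip(d_sm, nn_sm)):
        if np.isfinite(d) and j < len(m_points) and nn_ms[j] == i:
            pairs.append((i, int(j)))
    return pairs


def classify_cones(
    s_dets: np.ndarray | pd.DataFrame,
    m_dets: np.ndarray | pd.DataFrame,
    cfg: TypingConfig | None = None,
    region: Disk | Rect | None = None,
) -> ConeMosaic:
    """Combine per-channel detections into a typed cone table.

    Accepts (n, 2) arrays or DataFrames with x_um/y_um columns, in the same
    coordinate frame.  The class counts partition the detections:
    |MIXED| + |TRUE_S| + |M_ONLY| = |S| + |M| − |matched pairs|.
    """
    cfg = cfg or TypingConfig()
    s_xy = np.asarray(s_dets[["x_um", "y_um"]] if isinstance(s_dets, pd.DataFrame) else s_dets, float)
    m_xy = np.asarray(m_dets[["x_um", "y_um"]] if isinstance(m_dets, pd.DataFrame) else m_dets, float)
    s_xy = s_xy.reshape(-1, 2)[_dedupe(s_xy.reshape(-1, 2))] if len(s_xy) else s_xy.reshape(-1, 2)
    m_xy = m_xy.reshape(-1, 2)[_dedupe(m_xy.reshape(-1, 2))] if len(m_xy) else m_xy.reshape(-1, 2)

    pairs = match_detections(s_xy, m_xy, cfg.match_radius_um)
    s_matched = {i for i, _ in pairs}
    m_matched = {j for _, j in pairs}

    rows = []
    for i, j in pairs:
        x = (s_xy[i, 0] + m_xy[j, 0]) / 2
        y = (s_xy[i, 1] + m_xy[j, 1]) / 2
        rows.append((x, y, 1.0, 1.0, MIXED))
    for i in range(len(s_xy)):
        if i not in s_matched:
            rows.append((s_xy[i, 0], s_xy[i, 1], 1.0, 0.0, TRUE_S))
    for j in range(len(m_xy)):
        if j not in m_matched:
            rows.append((m_xy[j, 0], m_xy[j, 1], 0.0, 1.0, M_ONLY))

    df = pd.DataFrame(rows, columns=["x_um", "y_um", "s_level", "m_level", "type"])
    df.insert(0, "id", np.arange(len(df)))
    df["pedicle_x_um"] = df["x_um"]
    df["pedicle_y_um"] = df["y_um"]
    if region is None:
        r = float(np.max(np.hypot(df["x_um"], df["y_um"]))) if len(df) else 1.0
        region = Disk(0.0, 0.0, max(r, 1.0))
    return ConeMosaic(df, region)


def regional_composition(mosaic: ConeMosaic, cfg: TypingConfig | None = None) -> pd.DataFrame:
    """Class counts and percentages per region over the pooled square samples.

    Returns a table indexed by region with columns n_<class>, pct_<class>
    and n_total.  Empty regions are flagged (n_total 0, NaN percentages)
    and should be excluded from downstream means.
    """
    cfg = cfg or TypingConfig()
    x = mosaic.df["x_um"].to_numpy()
    y = mosaic.df["y_um"].to_numpy()
    types = mosaic.df["type"].to_numpy()
    records = []
    for region in cfg.region_centers:
        inside = np.zeros(len(x), dtype=bool)
        for sq in cfg.region_squares(region):
            inside |= np.asarray(sq.contains(x, y))
        n = int(inside.sum())
        rec = {"region": region, "n_total": n}
        for t in (MIXED, TRUE_S, M_ONLY):
            cnt = int(np.sum(types[inside] == t))
            rec[f"n_{t}"] = cnt
            rec[f"pct_{t}"] = 100.0 * cnt / n if n else float("nan")
        if n == 0:
            logger.warning("region %s contains no cones; excluded from means", region)
        records.append(rec)
    return pd.DataFrame(records).set_index("region")
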