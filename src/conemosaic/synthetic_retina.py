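"""Synthetic retina generator: cone mosaics, SCBC mosaics, wiring, and images.

Generates flat-mount-like data with known ground truth, emulating the
statistical structure of the mouse cone mosaic:

* quasi-even ("hard-core") cone mosaics at mouse densities, by random
  sequential adsorption (RSA) with position-dependent thinning for density
  gradients;
* opposing dorso-ventral S/M opsin gradients per strain preset, giving each
  cone a class (mixed M+S+, true S, M-only) and relative expression levels;
* an optionally clustered true-S subpopulation (clonal/Neyman–Scott style
  relabelling around "mother" cones, conserving the total true-S count);
* a sparser S-cone bipolar cell (SCBC) mosaic with a shallower ventral
  gradient;
* distance-limited divergent (dorsal) or convergent (ventral) wiring
  between true-S pedicles and SCBCs;
* two-channel image rendering (Gaussian spots + background + noise) with a
  sub-pixel ground-truth table.

Coordinate frame: μm, origin at the optic-nerve head, +y dorsal, +x nasal.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Union

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from ._geometry import Disk, Rect
from .presets import Logistic, StrainPreset

logger = logging.getLogger(__name__)

MAX_DEFAULT_DENSITY = 17_300.0  # cones/mm², upper end of the mouse range
MAX_SCBC_DENSITY = 1_400.0  # SCBCs/mm²

TRUE_S = "TRUE_S"
M_ONLY = "M_ONLY"
MIXED = "MIXED"
CONE_TYPES = (MIXED, TRUE_S, M_ONLY)

MOSAIC_COLUMNS = [
    "id",
    "x_um",
    "y_um",
    "s_level",
    "m_level",
    "type",
    "pedicle_x_um",
    "pedicle_y_um",
]


class InfeasibleMosaicError(RuntimeError):
    """Requested density cannot be realized under the hard-core constraint."""


@dataclass(frozen=True)
class ClonalClustering:
    """Neyman–Scott-style relabelling of true-S cones around mother cones.

    ``mother_rate_per_mm2`` mothers are chosen among true-S cones; each
    converts its ``offspring_count`` nearest non-true-S cones within
    ``offspring_radius_um`` to TRUE_S, while an equal number of true-S
    cones far from any mother are converted away, conserving the total
    true-S count.  ``offspring_count`` is either a constant int or
    ("poisson", mean).
    """

    mother_rate_per_mm2: float = 3.0
    offspring_count: Union[int, tuple] = ("poisson", 5.0)
    offspring_radius_um: float = 18.0

    def draw_counts(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if isinstance(self.offspring_count, int):
            return np.full(n, self.offspring_count, dtype=int)
        kind, mean = self.offspring_count
        if kind != "poisson":
            raise ValueError(f"unknown offspring_count spec: {self.offspring_count!r}")
        return rng.poisson(mean, size=n)


@dataclass(frozen=True)
class MosaicSpec:
    """Specification of a hard-core cone mosaic.

    density_profile: cones/mm², either a constant or a callable d(x, y).
    """

    retina_radius_um: float = 2000.0
    density_profile: Union[float, Callable] = 12_000.0
    hard_core_um: float = 4.0
    clustering: ClonalClustering | None = None
    seed: int = 0

    def __post_init__(self):
        if self.hard_core_um <= 0:
            raise ValueError("hard_core_um must be positive")

    def density_at(self, x, y):
        if callable(self.density_profile):
            return np.asarray(self.density_profile(x, y), dtype=float)
        return np.full(np.broadcast(np.asarray(x), np.asarray(y)).shape, float(self.density_profile))


@dataclass
class ConeMosaic:
    """A labelled 2-D point set of cones with retinal-frame metadata.

    ``df`` columns: id, x_um, y_um, s_level, m_level, type, pedicle_x_um,
    pedicle_y_um.  Class/level invariants: TRUE_S has s_level > 0 and
    m_level = 0; M_ONLY the reverse; MIXED both positive.
    """

    df: pd.DataFrame
    region: Disk | Rect
    strain: str = "unknown"

    def __post_init__(self):
        missing = [c for c in MOSAIC_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"mosaic table missing columns: {missing}")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def positions(self) -> np.ndarray:
        return self.df[["x_um", "y_um"]].to_numpy()

    @property
    def types(self) -> np.ndarray:
        return self.df["type"].to_numpy()

    def of_type(self, cone_type: str) -> pd.DataFrame:
        return self.df[self.df["type"] == cone_type]

    def clip(self, region: Disk | Rect) -> "ConeMosaic":
        m = region.contains(self.df["x_um"].to_numpy(), self.df["y_um"].to_numpy())
        return ConeMosaic(self.df[m].reset_index(drop=True), region, self.strain)


def generate_positions(
    spec: MosaicSpec,
    region: Disk | Rect | None = None,
    rng: np.random.Generator | None = None,
    max_attempts_per_point: int = 400,
) -> np.ndarray:
    """Place points by random sequential adsorption with a hard core.

    Density gradients are realized by position-dependent thinning of
    uniform proposals.  Returns an (n, 2) array; no two points are closer
    than ``spec.hard_core_um``.  Raises InfeasibleMosaicError when the
    requested density cannot be reached within the attempt budget.
    """
    if region is None:
        region = Disk(0.0, 0.0, spec.retina_radius_um)
    if region.area <= 0:
        raise ValueError("region area must be positive")
    rng = np.random.default_rng(spec.seed) if rng is None else rng

    # deterministic estimate of mean/max density over the region
    gx = np.linspace(region.bounds[0], region.bounds[2], 101)
    gy = np.linspace(region.bounds[1], region.bounds[3], 101)
    GX, GY = np.meshgrid(gx, gy)
    inside = region.contains(GX, GY)
    dens = spec.density_at(GX, GY)
    if not np.any(inside):
        return np.empty((0, 2))
    d_max = float(np.max(dens[inside]))
    d_mean = float(np.mean(dens[inside]))
    if d_max <= 0:
        return np.empty((0, 2))

    area_mm2 = region.area * 1e-6
    n_target = int(round(d_mean * area_mm2))
    if n_target == 0:
        return np.empty((0, 2))

    h = spec.hard_core_um
    h2 = h * h
    cell: dict[tuple[int, int], list[int]] = {}
    xs: list[float] = []
    ys: list[float] = []

    def free(x: float, y: float) -> bool:
        ix, iy = int(x // h), int(y // h)
        for jx in (ix - 1, ix, ix + 1):
            for jy in (iy - 1, iy, iy + 1):
                for k in cell.get((jx, jy), ()):
                    dx = xs[k] - x
                    dy = ys[k] - y
                    if dx * dx + dy * dy < h2:
                        return False
        return True

    max_attempts = max_attempts_per_point * n_target + 1000
    # a long run with no acceptance means the pattern has jammed: the
    # density is infeasible for this hard core, so fail fast
    max_stall = 30_000
    attempts = 0
    stall = 0
    batch = 4096
    while len(xs) < n_target and attempts < max_attempts and stall < max_stall:
        m = min(batch, max_attempts - attempts)
        px, py = region.sample_uniform(m, rng)
        accept = rng.random(m) < spec.density_at(px, py) / d_max
        attempts += m
        for x, y, a in zip(px, py, accept):
            if not a:
                stall += 1
                continue
            x = float(x)
            y = float(y)
            if free(x, y):
                ix, iy = int(x // h), int(y // h)
                cell.setdefault((ix, iy), []).append(len(xs))
                xs.append(x)
                ys.append(y)
                stall = 0
                if len(xs) >= n_target:
                    break
            else:
                stall += 1

    if len(xs) < n_target:
        raise InfeasibleMosaicError(
            f"placed {len(xs)}/{n_target} points after {attempts} attempts; "
            f"density {d_mean:.0f}/mm² is infeasible with a {h} μm hard core"
        )
    return np.column_stack([xs, ys])


def _truncated_gaussian_offsets(
    n: int, sigma: float, max_norm: float, rng: np.random.Generator
) -> np.ndarray:
    """Isotropic Gaussian displacements rejected beyond max_norm."""
    out = np.zeros((n, 2))
    todo = np.arange(n)
    while todo.size:
        d = rng.normal(0.0, sigma, size=(todo.size, 2))
        ok = np.hypot(d[:, 0], d[:, 1]) <= max_norm
        out[todo[ok]] = d[ok]
        todo = todo[~ok]
    return out


def assign_types(
    points: np.ndarray,
    preset: StrainPreset,
    clustering: ClonalClustering | None = None,
    rng: np.random.Generator | None = None,
    seed: int = 0,
    region: Disk | Rect | None = None,
    pedicle_sigma_um: float = 3.0,
    pedicle_max_um: float = 10.0,
    level_noise_sd: float = 0.1,
    level_floor: float = 0.3,
) -> ConeMosaic:
    """Label cone positions with types, expression levels and pedicles.

    Type probabilities follow the preset's dorso-ventral gradients.  With
    clonal clustering, true-S labels are aggregated around mother cones
    while the total true-S count is conserved (labels converted toward
    mothers are balanced by conversions away elsewhere).
    """
    points = np.asarray(points, dtype=float)
    rng = np.random.default_rng(seed) if rng is None else rng
    n = len(points)
    if region is None:
        r = float(np.max(np.hypot(points[:, 0], points[:, 1]))) if n else 1.0
        region = Disk(0.0, 0.0, max(r, 1.0))

    y = points[:, 1] if n else np.empty(0)
    p_s, p_m, p_mix = preset.class_probabilities(y)
    u = rng.random(n)
    types = np.where(u < p_s, TRUE_S, np.where(u < p_s + p_m, M_ONLY, MIXED)).astype(object)

    mothers = np.empty(0, dtype=int)
    if clustering is not None and n:
        mothers = _apply_clonal_clustering(points, types, clustering, rng)

    s_expr = types != M_ONLY
    m_expr = types != TRUE_S
    s_level = np.zeros(n)
    m_level = np.zeros(n)
    if n:
        s_level[s_expr] = np.clip(
            preset.s_level(y[s_expr]) + rng.normal(0.0, level_noise_sd, s_expr.sum()),
            level_floor,
            1.0,
        )
        m_level[m_expr] = np.clip(
            preset.m_level(y[m_expr]) + rng.normal(0.0, level_noise_sd, m_expr.sum()),
            level_floor,
            1.0,
        )

    ped = points + _truncated_gaussian_offsets(n, pedicle_sigma_um, pedicle_max_um, rng)

    df = pd.DataFrame(
        {
            "id": np.arange(n),
            "x_um": points[:, 0] if n else np.empty(0),
            "y_um": points[:, 1] if n else np.empty(0),
            "s_level": s_level,
            "m_level": m_level,
            "type": types,
            "pedicle_x_um": ped[:, 0] if n else np.empty(0),
            "pedicle_y_um": ped[:, 1] if n else np.empty(0),
        }
    )
    mosaic = ConeMosaic(df, region, preset.name)
    mosaic.clonal_mothers = mothers
    return mosaic


def _apply_clonal_clustering(
    points: np.ndarray, types: np.ndarray, clustering: ClonalClustering, rng: np.random.Generator
) -> np.ndarray:
    """In-place relabelling: aggregate TRUE_S labels around mother cones.
    Returns the indices of the mother cones."""
    trues = np.flatnonzero(types == TRUE_S)
    if trues.size == 0:
        return np.empty(0, dtype=int)
    # Poisson number of mothers for the whole field, capped by availability
    area_mm2 = _convex_area_mm2(points)
    n_mothers = min(int(rng.poisson(clustering.mother_rate_per_mm2 * area_mm2)), trues.size)
    if n_mothers == 0:
        return np.empty(0, dtype=int)
    mothers = rng.choice(trues, size=n_mothers, replace=False)
    counts = clustering.draw_counts(n_mothers, rng)

    tree = cKDTree(points)
    converted: list[int] = []
    protected = set(mothers.tolist())
    for mother, k in zip(mothers, counts):
        if k <= 0:
            continue
        idx = tree.query_ball_point(points[mother], clustering.offspring_radius_um)
        idx = [i for i in idx if i != mother and types[i] != TRUE_S and i not in converted]
        idx.sort(key=lambda i: float(np.sum((points[i] - points[mother]) ** 2)))
        take = idx[:k]
        for i in take:
            types[i] = TRUE_S
            converted.append(i)
            protected.add(i)
    if not converted:
        return mothers
    # conserve total TRUE_S count: convert an equal number of true-S cones
    # away from clusters (not mothers, not converted, not near a mother)
    near_mother = set()
    for mother in mothers:
        near_mother.update(tree.query_ball_point(points[mother], clustering.offspring_radius_um))
    donors = [
        i
        for i in np.flatnonzero(types == TRUE_S)
        if i not in protected and i not in near_mother
    ]
    rng.shuffle(donors)
    for i in donors[: len(converted)]:
        types[i] = MIXED
    logger.info(
        "clonal clustering: %d mothers, %d conversions, %d donors relabelled",
        n_mothers,
        len(converted),
        min(len(donors), len(converted)),
    )
    return mothers


def _convex_area_mm2(points: np.ndarray) -> float:
    if len(points) < 3:
        return 0.0
    from scipy.spatial import ConvexHull

    return float(ConvexHull(points).volume) * 1e-6


# ---------------------------------------------------------------------------
# SCBC mosaic


@dataclass(frozen=True)
class ScbcSpec:
    """S-cone bipolar cell mosaic: sparse hard-core process with a shallow
    ventral density gradient.

    Default dorsal/ventral densities (430 vs 690 cells/mm²) sit well below
    the 1,400 cells/mm² scale ceiling and, combined with the default cone
    preset, give dorsal true-S:SCBC ratios near 1:3.6 and ventral near
    5.3:1.
    """

    density: Logistic = field(
        default_factory=lambda: Logistic(430.0, 690.0, midpoint_um=0.0, slope_um=500.0)
    )
    hard_core_um: float = 10.0
    dendritic_reach_um: float = 80.0
    seed: int = 0


def generate_scbc_mosaic(
    spec: ScbcSpec,
    region: Disk | Rect | None = None,
    retina_radius_um: float = 2000.0,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Generate the SCBC point set.  Columns: id, x_um, y_um, reach_um."""
    if region is None:
        region = Disk(0.0, 0.0, retina_radius_um)
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    mspec = MosaicSpec(
        retina_radius_um=retina_radius_um,
        density_profile=lambda x, y: spec.density(y),
        hard_core_um=spec.hard_core_um,
        seed=spec.seed,
    )
    pts = generate_positions(mspec, region, rng=rng)
    return pd.DataFrame(
        {
            "id": np.arange(len(pts)),
            "x_um": pts[:, 0] if len(pts) else np.empty(0),
            "y_um": pts[:, 1] if len(pts) else np.empty(0),
            "reach_um": np.full(len(pts), spec.dendritic_reach_um),
        }
    )


# ---------------------------------------------------------------------------
# Wiring

CONTACT_COLUMNS = ["scbc_id", "pedicle_id", "branch_id", "is_blind"]


def generate_wiring(
    mosaic: ConeMosaic,
    scbcs: pd.DataFrame,
    mode: str,
    degree_mean: float | None = None,
    reach_um: float | None = None,
    blind_rate: float = 0.0,
    rng: np.random.Generator | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate a contact table between true-S pedicles and SCBCs.

    mode "dorsal_divergent": each true-S pedicle contacts its k nearest
    SCBCs within reach, k ~ 1 + Poisson(degree_mean − 1) (mean 3.8 by
    default).  mode "ventral_convergent": each SCBC contacts its m nearest
    true-S pedicles, m with mean 4.6 by default.  Cells with no eligible
    partner within reach are dropped (count logged).  Optional blind
    endings (dendrites ending on no pedicle) are appended per SCBC at
    ``blind_rate`` and carry a null pedicle_id.
    """
    if mode not in ("dorsal_divergent", "ventral_convergent"):
        raise ValueError(f"unknown wiring mode {mode!r}")
    if degree_mean is None:
        degree_mean = 3.8 if mode == "dorsal_divergent" else 4.6
    if degree_mean < 1:
        raise ValueError("degree_mean must be ≥ 1")
    rng = np.random.default_rng(seed) if rng is None else rng

    true_s = mosaic.of_type(TRUE_S)
    pedicles = true_s[["pedicle_x_um", "pedicle_y_um"]].to_numpy()
    ped_ids = true_s["id"].to_numpy()
    scbc_xy = scbcs[["x_um", "y_um"]].to_numpy()
    scbc_ids = scbcs["id"].to_numpy()

    if reach_um is None:
        reach_um = float(scbcs["reach_um"].iloc[0]) if len(scbcs) else 0.0

    rows: list[tuple] = []
    if reach_um <= 0 or len(pedicles) == 0 or len(scbc_xy) == 0:
        warnings.warn("wiring: no eligible contacts (zero reach or empty mosaics)")
        return pd.DataFrame(columns=CONTACT_COLUMNS)

    if mode == "dorsal_divergent":
        sources, source_ids = pedicles, ped_ids
        targets, target_ids = scbc_xy, scbc_ids
    else:
        sources, source_ids = scbc_xy, scbc_ids
        targets, target_ids = pedicles, ped_ids

    tree = cKDTree(targets)
    ks = 1 + rng.poisson(degree_mean - 1.0, size=len(sources))
    dropped = 0
    for src, sid, k in zip(sources, source_ids, ks):
        idx = tree.query_ball_point(src, reach_um)
        if not idx:
            dropped += 1
            continue
        idx.sort(key=lambda i: float(np.sum((targets[i] - src) ** 2)))
        partners = idx[: int(k)]
        for j, t in enumerate(partners):
            if mode == "dorsal_divergent":
                rows.append((int(target_ids[t]), int(sid), f"s{target_ids[t]}_b{j}", False))
            else:
                rows.append((int(sid), int(target_ids[t]), f"s{sid}_b{j}", False))
    if dropped:
        logger.info("wiring: dropped %d source cells with no partner within reach", dropped)

    if blind_rate > 0:
        for sid in scbc_ids:
            for j in range(int(rng.poisson(blind_rate))):
                rows.append((int(sid), pd.NA, f"s{sid}_blind{j}", True))

    return pd.DataFrame(rows, columns=CONTACT_COLUMNS)


# ---------------------------------------------------------------------------
# Rendering


@dataclass(frozen=True)
class RenderSpec:
    """Two-channel raster rendering of a mosaic field.

    Each cone expressing the channel's opsin contributes a Gaussian spot
    (the point-spread surrogate) with amplitude proportional to its
    expression level, over a background with an optional linear gradient;
    Gaussian or Poisson noise is then applied and the image quantized to
    16-bit.
    """

    pixel_size_um: float = 0.5
    psf_sigma_um: float = 1.0
    amplitude: float = 4000.0
    background: float = 400.0
    background_gradient: float = 0.0  # counts per μm along +y (dorsal)
    noise: str = "gaussian"  # {"gaussian", "poisson", "none"}
    noise_sigma: float = 60.0

    def __post_init__(self):
        if self.pixel_size_um <= 0 or self.psf_sigma_um <= 0:
            raise ValueError("pixel_size_um and psf_sigma_um must be positive")


@dataclass(frozen=True)
class ImageFrame:
    """Mapping between image pixels (row, col) and retina coordinates (μm).

    Column 0 is at x0; row 0 is at y1 (top of field); y decreases with row.
    """

    x0: float
    y1: float
    pixel_size_um: float
    shape: tuple[int, int]

    def to_pixel(self, x, y):
        col = (np.asarray(x) - self.x0) / self.pixel_size_um - 0.5
        row = (self.y1 - np.asarray(y)) / self.pixel_size_um - 0.5
        return row, col

    def to_retina(self, row, col):
        x = self.x0 + (np.asarray(col) + 0.5) * self.pixel_size_um
        y = self.y1 - (np.asarray(row) + 0.5) * self.pixel_size_um
        return x, y


def render_image(
    mosaic: ConeMosaic,
    spec: RenderSpec,
    channel: str,
    region: Rect | None = None,
    rng: np.random.Generator | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, pd.DataFrame, ImageFrame]:
    """Render one opsin channel of a mosaic field to a 16-bit raster.

    Returns (image uint16, ground-truth table, frame).  The truth table
    lists, for every cone expressing the channel, the sub-pixel centroid in
    both retina μm and pixel coordinates together with its level.
    """
    if channel not in ("s", "m"):
        raise ValueError("channel must be 's' or 'm'")
    rng = np.random.default_rng(seed) if rng is None else rng
    if region is None:
        x0, y0, x1, y1 = mosaic.region.bounds
        region = Rect(x0, y0, x1, y1)

    px = spec.pixel_size_um
    nx = int(np.ceil((region.x1 - region.x0) / px))
    ny = int(np.ceil((region.y1 - region.y0) / px))
    frame = ImageFrame(region.x0, region.y1, px, (ny, nx))

    level_col = "s_level" if channel == "s" else "m_level"
    df = mosaic.df
    m = (df[level_col].to_numpy() > 0) & region.contains(
        df["x_um"].to_numpy(), df["y_um"].to_numpy()
    )
    truth = df.loc[m, ["id", "x_um", "y_um", level_col]].rename(columns={level_col: "level"})
    rows, cols = frame.to_pixel(truth["x_um"].to_numpy(), truth["y_um"].to_numpy())
    truth = truth.assign(row_px=rows, col_px=cols).reset_index(drop=True)

    img = np.zeros((ny, nx), dtype=float)
    sig = spec.psf_sigma_um / px
    w = int(np.ceil(4 * sig))
    for r0, c0, lev in zip(truth["row_px"], truth["col_px"], truth["level"]):
        ra, rb = max(0, int(r0) - w), min(ny, int(r0) + w + 1)
        ca, cb = max(0, int(c0) - w), min(nx, int(c0) + w + 1)
        if ra >= rb or ca >= cb:
            continue
        rr = np.arange(ra, rb)[:, None]
        cc = np.arange(ca, cb)[None, :]
        img[ra:rb, ca:cb] += (
            spec.amplitude * lev * np.exp(-((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * sig**2))
        )

    ygrid = frame.to_retina(np.arange(ny), np.zeros(ny))[1]
    img += spec.background + spec.background_gradient * (ygrid - region.y0)[:, None]

    if spec.noise == "gaussian":
        img += rng.normal(0.0, spec.noise_sigma, size=img.shape)
    elif spec.noise == "poisson":
        img = rng.poisson(np.clip(img, 0, None)).astype(float)
    elif spec.noise != "none":
        raise ValueError(f"unknown noise model {spec.noise!r}")

    return np.clip(img, 0, 65535).astype(np.uint16), truth, frame
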