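"""Spatial regularity and clustering statistics for cone mosaics.

Implements the clustering analysis for circular retinal samples (1 mm
diameter, centred on the DT–VN axis at 1 mm from the optic-nerve head):

* a density-scaled search radius r = 3·√(A / (√2·π·N)), the first-minimum
  estimate of the density recovery profile for a regular mosaic of N cells
  in area A;
* k-nearest-neighbour maps (counts of same-class neighbours within 18 μm);
* NNRI — nearest-neighbour regularity index, mean/SD of nearest-neighbour
  distances of the focal class;
* VDRI — Voronoi-domain regularity index, mean/SD of Voronoi cell areas;
* SCNR — S-cone neighbour ratio, the per-cone proportion of true S-cones
  among all cones within r;
* two null models over the fixed cone positions: "shuffled" (random
  permutation of cone identities, class proportions held constant) and
  "distributed" (mutual-repulsion spreading of the true-S labels snapped
  back onto real cone positions);
* Z-score normalization of real measurements against the shuffled
  ensemble and one-tailed t-tests across samples.

Edge policy: cones closer to the sample boundary than r are excluded as
focal points for all three metrics, but still serve as potential
neighbours and as Voronoi generators.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import Voronoi, cKDTree

from ._geometry import Disk
from .synthetic_retina import TRUE_S, ConeMosaic

logger = logging.getLogger(__name__)

DEFAULT_SAMPLE_DIAMETER_UM = 1000.0
DEFAULT_KNN_RADIUS_UM = 18.0
DEFAULT_N_SIMS = 200
METRICS = ("nnri", "vdri", "scnr_true_s", "scnr_all")

# NNRI of a large homogeneous Poisson pattern: mean/SD of Rayleigh-like
# nearest-neighbour distances, 0.5·√(4π/(4−π)) ≈ 1.913
CSR_NNRI = 0.5 * float(np.sqrt(4 * np.pi / (4 - np.pi)))


def compute_search_radius(area_um2: float, n: int) -> float:
    """First-minimum estimate of the density recovery profile:
    r = 3·√(A / (√2·π·N)) (μm).  The radius of a circle around a cone
    expected to contain its first tier of neighbours in an even mosaic."""
    if n < 1:
        raise ValueError("need at least one cone to compute the search radius")
    if area_um2 <= 0:
        raise ValueError("area must be positive")
    return 3.0 * float(np.sqrt(area_um2 / (np.sqrt(2.0) * np.pi * n)))


def knn_count_map(points: np.ndarray, radius_um: float = DEFAULT_KNN_RADIUS_UM) -> np.ndarray:
    """Number of other points of the same set within ``radius_um`` of each
    point (self excluded).  Symmetric by construction."""
    if radius_um <= 0:
        raise ValueError("radius must be positive")
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(pts) == 0:
        return np.zeros(0, dtype=int)
    tree = cKDTree(pts)
    counts = tree.query_ball_point(pts, radius_um, return_length=True)
    return np.asarray(counts, dtype=int) - 1


@dataclass
class MosaicSample:
    """A circular sub-region of a mosaic prepared for regularity analysis.

    Caches position-dependent structures (edge-exclusion focal mask and
    within-r neighbour lists) that are shared across label permutations, so
    null ensembles only recompute label-dependent quantities.
    """

    positions: np.ndarray  # (N, 2) μm
    is_true_s: np.ndarray  # (N,) bool
    disk: Disk
    name: str = "sample"

    search_radius_um: float = field(init=False)
    focal: np.ndarray = field(init=False)  # edge-exclusion mask
    _nb_flat: np.ndarray = field(init=False, repr=False)
    _nb_owner: np.ndarray = field(init=False, repr=False)
    _nb_counts: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 2)
        self.is_true_s = np.asarray(self.is_true_s, dtype=bool)
        if len(self.positions) != len(self.is_true_s):
            raise ValueError("positions and labels differ in length")
        self.search_radius_um = compute_search_radius(self.disk.area, max(len(self.positions), 1))
        self._build_neighbours(self.search_radius_um)

    def _build_neighbours(self, radius_um: float) -> None:
        self.search_radius_um = radius_um
        edge = self.disk.edge_distance(self.positions[:, 0], self.positions[:, 1])
        self.focal = np.asarray(edge >= radius_um)
        n = len(self.positions)
        if n == 0:
            self._nb_counts = np.zeros(0, dtype=np.intp)
            self._nb_flat = np.zeros(0, dtype=np.intp)
            self._nb_owner = np.zeros(0, dtype=np.intp)
            return
        tree = cKDTree(self.positions)
        lists = tree.query_ball_point(self.positions, radius_um)
        nb = [np.array([j for j in lst if j != i], dtype=np.intp) for i, lst in enumerate(lists)]
        self._nb_counts = np.array([len(v) for v in nb], dtype=np.intp)
        self._nb_flat = np.concatenate(nb) if nb else np.zeros(0, dtype=np.intp)
        self._nb_owner = np.repeat(np.arange(n, dtype=np.intp), self._nb_counts)

    def neighbour_label_sums(self, labels: np.ndarray) -> np.ndarray:
        """Per-cone sum of ``labels`` over its within-radius neighbours."""
        return np.bincount(
            self._nb_owner, weights=np.asarray(labels, float)[self._nb_flat], minlength=len(labels)
        )

    # -- basic facts -----------------------------------------------------
    @property
    def n_total(self) -> int:
        return len(self.positions)

    @property
    def n_true_s(self) -> int:
        return int(self.is_true_s.sum())

    @property
    def area_um2(self) -> float:
        return self.disk.area

    @property
    def n_excluded_edge(self) -> int:
        return int((~self.focal).sum())

    def with_labels(self, is_true_s: np.ndarray) -> "MosaicSample":
        """Cheap copy sharing the cached geometry, with new labels."""
        new = MosaicSample.__new__(MosaicSample)
        new.positions = self.positions
        new.is_true_s = np.asarray(is_true_s, dtype=bool)
        new.disk = self.disk
        new.name = self.name
        new.search_radius_um = self.search_radius_um
        new.focal = self.focal
        new._nb_flat = self._nb_flat
        new._nb_owner = self._nb_owner
        new._nb_counts = self._nb_counts
        return new


def extract_sample(
    mosaic: ConeMosaic,
    which: str = "VN",
    distance_um: float = 1000.0,
    diameter_um: float = DEFAULT_SAMPLE_DIAMETER_UM,
) -> MosaicSample:
    """Cut a circular sample centred on the DT–VN axis.

    "DT" places the centre 1 mm toward the dorsotemporal pole (direction
    (−1, +1)/√2); "VN" toward the ventronasal pole ((+1, −1)/√2).
    """
    u = {"DT": (-1.0, 1.0), "VN": (1.0, -1.0)}[which.upper()]
    cx = distance_um * u[0] / np.sqrt(2.0)
    cy = distance_um * u[1] / np.sqrt(2.0)
    disk = Disk(cx, cy, diameter_um / 2.0)
    sub = mosaic.clip(disk)
    return MosaicSample(
        sub.df[["x_um", "y_um"]].to_numpy(),
        sub.df["type"].to_numpy() == TRUE_S,
        disk,
        name=which.upper(),
    )


# ---------------------------------------------------------------------------
# Regularity indices


def _regularity_ratio(values: np.ndarray) -> float:
    """mean/SD with the sample SD (n−1); SD of 0 flags infinite regularity."""
    sd = float(np.std(values, ddof=1))
    if sd == 0.0:
        return float("inf")
    return float(np.mean(values)) / sd


def nn_distances(points: np.ndarray, focal_mask: np.ndarray | None = None) -> np.ndarray:
    """Nearest-neighbour distance of each focal point to any other point of
    the set (non-focal points still count as neighbours)."""
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if focal_mask is None:
        focal_mask = np.ones(len(pts), dtype=bool)
    if len(pts) < 2 or focal_mask.sum() == 0:
        return np.zeros(0)
    tree = cKDTree(pts)
    d, _ = tree.query(pts[focal_mask], k=2)
    return d[:, 1]


def nnri(points: np.ndarray, focal_mask: np.ndarray | None = None) -> float:
    """Nearest-neighbour regularity index: mean/SD of NN distances over the
    focal points.  NaN when fewer than 3 focal points; inf when SD = 0
    (e.g. a perfect lattice)."""
    d = nn_distances(points, focal_mask)
    if len(d) < 3:
        return float("nan")
    return _regularity_ratio(d)


def voronoi_cell_areas(points: np.ndarray, region=None) -> np.ndarray:
    """Area of each point's Voronoi cell.

    NaN marks unusable cells: unbounded ones and — when ``region`` is
    given — cells with a vertex outside the region.  Cells of points near
    the pattern boundary are otherwise bounded but arbitrarily large, which
    would swamp the area SD.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(pts) < 4:
        return np.full(len(pts), np.nan)
    vor = Voronoi(pts)
    areas = np.full(len(pts), np.nan)
    for i, reg_idx in enumerate(vor.point_region):
        reg = vor.regions[reg_idx]
        if not reg or -1 in reg:
            continue
        poly = vor.vertices[reg]
        if region is not None and not np.all(region.contains(poly[:, 0], poly[:, 1])):
            continue
        x, y = poly[:, 0], poly[:, 1]
        areas[i] = 0.5 * abs(np.dot(x, np.roll(y, 1)) - np.dot(y, np.roll(x, 1)))
    return areas


def vdri(points: np.ndarray, focal_mask: np.ndarray | None = None, region=None) -> float:
    """Voronoi-domain regularity index: mean/SD of the Voronoi cell areas of
    focal points; unbounded cells and cells crossing the region boundary
    are excluded.  NaN when fewer than 4 usable cells; inf when SD = 0
    (perfect lattice)."""
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if focal_mask is None:
        focal_mask = np.ones(len(pts), dtype=bool)
    areas = voronoi_cell_areas(pts, region=region)
    use = focal_mask & np.isfinite(areas)
    if use.sum() < 4:
        return float("nan")
    return _regularity_ratio(areas[use])


# ---------------------------------------------------------------------------
# SCNR


@dataclass
class ScnrResult:
    per_cone: pd.DataFrame  # index: cone index; columns ratio, is_true_s
    mean_true_s: float
    mean_all: float
    search_radius_um: float
    n_zero_neighbour: int


def scnr(sample: MosaicSample, radius_um: float | None = None) -> ScnrResult:
    """S-cone neighbour ratio: for each focal cone, the proportion of true
    S-cones among all other cones within the search radius.

    The focal set is edge-excluded; the focal cone itself is not counted in
    its own denominator.  Focal cones with no neighbour at all are dropped
    (their ratio is undefined) and counted in ``n_zero_neighbour``.
    Reported means are over true-S focal cones and over all focal cones.
    """
    if radius_um is not None and radius_um != sample.search_radius_um:
        tmp = MosaicSample(sample.positions, sample.is_true_s, sample.disk, sample.name)
        tmp._build_neighbours(radius_um)
        sample = tmp

    labels = sample.is_true_s.astype(float)
    if len(labels) == 0:
        return ScnrResult(pd.DataFrame(columns=["ratio", "is_true_s"]), np.nan, np.nan, sample.search_radius_um, 0)
    sums = sample.neighbour_label_sums(labels)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratios = np.where(sample._nb_counts > 0, sums / sample._nb_counts, np.nan)

    usable = sample.focal & (sample._nb_counts > 0)
    n_zero = int((sample.focal & (sample._nb_counts == 0)).sum())
    if n_zero:
        logger.info("SCNR: %d focal cones with no neighbour excluded", n_zero)
    per = pd.DataFrame(
        {"ratio": ratios[usable], "is_true_s": sample.is_true_s[usable]},
        index=np.flatnonzero(usable),
    )
    m_true = float(per.loc[per["is_true_s"], "ratio"].mean()) if per["is_true_s"].any() else float("nan")
    m_all = float(per["ratio"].mean()) if len(per) else float("nan")
    return ScnrResult(per, m_true, m_all, sample.search_radius_um, n_zero)


# ---------------------------------------------------------------------------
# Null models


def shuffle_identities(sample: MosaicSample, rng: np.random.Generator | int = 0) -> MosaicSample:
    """Permute cone identities uniformly over the fixed positions, holding
    the number of true S-cones constant."""
    if sample.n_true_s < 1:
        raise ValueError("sample contains no true S-cone to shuffle")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    return sample.with_labels(rng.permutation(sample.is_true_s))


def _reflect_into_disk(pts: np.ndarray, disk: Disk) -> np.ndarray:
    dx = pts[:, 0] - disk.cx
    dy = pts[:, 1] - disk.cy
    r = np.hypot(dx, dy)
    out = r > disk.radius
    if np.any(out):
        r_ref = 2 * disk.radius - r[out]
        r_ref = np.clip(r_ref, 0.0, disk.radius)
        scale = np.where(r[out] > 0, r_ref / r[out], 0.0)
        pts = pts.copy()
        pts[out, 0] = disk.cx + dx[out] * scale
        pts[out, 1] = disk.cy + dy[out] * scale
    return pts


def _greedy_snap(virtual: np.ndarray, positions: np.ndarray) -> np.ndarray:
    """Assign each virtual point to its nearest unclaimed cone position,
    greedily by snap distance; deterministic, ties by smaller index."""
    n_virtual = len(virtual)
    tree = cKDTree(positions)
    k = min(16, len(positions))
    d, idx = tree.query(virtual, k=k)
    d = np.atleast_2d(d)
    idx = np.atleast_2d(idx)
    order = sorted(
        ((float(d[i, j]), i, int(idx[i, j])) for i in range(n_virtual) for j in range(k)),
        key=lambda t: (t[0], t[1], t[2]),
    )
    assigned: dict[int, int] = {}
    claimed: set[int] = set()
    for dist, i, p in order:
        if i in assigned or p in claimed:
            continue
        assigned[i] = p
        claimed.add(p)
    for i in range(n_virtual):  # rare: all k candidates already claimed
        if i in assigned:
            continue
        free = np.setdiff1d(np.arange(len(positions)), np.fromiter(claimed, dtype=int))
        j = free[np.argmin(np.hypot(*(positions[free] - virtual[i]).T))]
        assigned[i] = int(j)
        claimed.add(int(j))
    return np.array([assigned[i] for i in range(n_virtual)], dtype=int)


def distribute_true_s(
    sample: MosaicSample,
    n_iter: int = 500,
    step_um: float = 2.0,
    rng: np.random.Generator | int = 0,
) -> MosaicSample:
    """Maximally spread relabelling: mutual-repulsion simulation of K
    virtual points (K = number of true S-cones) in the sample disk, then
    greedy snapping of each virtual point to the nearest unclaimed cone
    position.

    Virtual points repel with inverse-square pairwise forces and move a
    fixed step along the net force each iteration, reflecting off the disk
    boundary; the iterate with the largest minimum pairwise distance is
    kept.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    k = sample.n_true_s
    n = sample.n_total
    if k > n:
        raise ValueError("more true S labels than cone positions")
    if k == 0:
        return sample.with_labels(np.zeros(n, dtype=bool))
    if k == n:
        return sample.with_labels(np.ones(n, dtype=bool))

    start = rng.choice(n, size=k, replace=False)
    pts = sample.positions[start].astype(float).copy()
    if k == 1:
        labels = np.zeros(n, dtype=bool)
        labels[start] = True
        return sample.with_labels(labels)

    best = pts.copy()
    best_min = 0.0
    for it in range(n_iter):
        diff = pts[:, None, :] - pts[None, :, :]
        d2 = np.sum(diff**2, axis=-1)
        np.fill_diagonal(d2, np.inf)
        min_d = float(np.sqrt(d2.min()))
        if min_d > best_min:
            best_min = min_d
            best = pts.copy()
        force = np.sum(diff / (d2[..., None] ** 1.5 + 1e-12), axis=1)
        norm = np.hypot(force[:, 0], force[:, 1])
        norm[norm == 0] = 1.0
        pts = _reflect_into_disk(pts + step_um * force / norm[:, None], sample.disk)

    diff = pts[:, None, :] - pts[None, :, :]
    d2 = np.sum(diff**2, axis=-1)
    np.fill_diagonal(d2, np.inf)
    final_min = float(np.sqrt(d2.min()))
    if final_min < best_min:
        # fixed-step dynamics oscillate around the optimum; keep the best
        # iterate and only warn when the end state fell well away from it
        if final_min < 0.8 * best_min:
            warnings.warn("repulsion did not converge; returning best iterate")
        pts = best

    chosen = _greedy_snap(pts, sample.positions)
    labels = np.zeros(n, dtype=bool)
    labels[chosen] = True
    return sample.with_labels(labels)


# ---------------------------------------------------------------------------
# Ensembles and tests


def sample_metrics(sample: MosaicSample, metrics=METRICS) -> dict[str, float]:
    """Compute the requested regularity/clustering metrics for one sample.

    NNRI and VDRI take the true-S sub-mosaic as the focal class; edge
    exclusion uses the sample's search radius for all metrics.
    """
    out: dict[str, float] = {}
    ts = sample.is_true_s
    pts_ts = sample.positions[ts]
    focal_ts = sample.focal[ts]
    if "nnri" in metrics:
        out["nnri"] = nnri(pts_ts, focal_ts)
    if "vdri" in metrics:
        out["vdri"] = vdri(pts_ts, focal_ts, region=sample.disk)
    if "scnr_true_s" in metrics or "scnr_all" in metrics:
        res = scnr(sample)
        if "scnr_true_s" in metrics:
            out["scnr_true_s"] = res.mean_true_s
        if "scnr_all" in metrics:
            out["scnr_all"] = res.mean_all
    return out


@dataclass
class NullEnsemble:
    """Metric values over simulated relabellings of one sample, with the
    normalization statistics and Z-scores of the real sample."""

    kind: str  # {"shuffled", "distributed"}
    n_sims: int
    values: pd.DataFrame  # one row per simulation
    real: pd.Series
    n_regenerated: int = 0

    @property
    def mean(self) -> pd.Series:
        return self.values.mean()

    @property
    def sd(self) -> pd.Series:
        return self.values.std(ddof=1)

    @property
    def z_scores(self) -> pd.Series:
        return (self.real - self.mean) / self.sd

    def ks_normality(self) -> pd.Series:
        """Kolmogorov–Smirnov p-value of each metric's simulated values
        against a fitted normal; large p = consistent with normality."""
        out = {}
        for c in self.values.columns:
            v = self.values[c].to_numpy()
            out[c] = stats.kstest((v - v.mean()) / v.std(ddof=1), "norm").pvalue
        return pd.Series(out)


def null_ensemble(
    sample: MosaicSample,
    kind: str = "shuffled",
    n_sims: int = DEFAULT_N_SIMS,
    seed: int | np.random.Generator = 0,
    metrics=METRICS,
    distribute_kwargs: dict | None = None,
) -> NullEnsemble:
    """Build a null ensemble and normalize the real sample against it.

    Each simulated relabelling is measured identically to the real sample.
    A simulation with an undefined metric (SD of 0, or too few focal
    points) is regenerated and logged; if regenerations exceed 10% of
    n_sims the ensemble aborts with a diagnostic.
    """
    if n_sims < 2:
        raise ValueError("n_sims must be ≥ 2")
    if kind not in ("shuffled", "distributed"):
        raise ValueError(f"unknown null kind {kind!r}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    distribute_kwargs = distribute_kwargs or {}

    rows = []
    n_regen = 0
    max_regen = max(1, int(0.1 * n_sims))
    while len(rows) < n_sims:
        if kind == "shuffled":
            sim = shuffle_identities(sample, rng)
        else:
            sim = distribute_true_s(sample, rng=rng, **distribute_kwargs)
        vals = sample_metrics(sim, metrics)
        if any(not np.isfinite(v) for v in vals.values()):
            n_regen += 1
            logger.info("regenerating simulation with undefined metric (%d so far)", n_regen)
            if n_regen > max_regen:
                raise RuntimeError(
                    f"metric undefined in more than 10% of {kind} simulations "
                    f"({n_regen} regenerations); sample too sparse for this analysis"
                )
            continue
        rows.append(vals)

    values = pd.DataFrame(rows)
    real = pd.Series(sample_metrics(sample, metrics))
    return NullEnsemble(kind, n_sims, values, real, n_regen)


def significance_test(z_scores, direction: str = "greater"):
    """One-sample, one-tailed t-test of normalized measures against 0 (the
    shuffled-null mean after normalization).

    direction "greater" tests for values above the null (e.g. SCNR
    clustering); "less" for regularity deficits.  Returns (t, p,
    significant_at_05).
    """
    z = np.asarray(z_scores, dtype=float)
    if z.size < 2:
        raise ValueError("need at least two samples")
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    if np.std(z, ddof=1) == 0:
        p = 0.5 if np.mean(z) == 0 else (0.0 if (np.mean(z) > 0) == (direction == "greater") else 1.0)
        t = 0.0 if np.mean(z) == 0 else np.inf * np.sign(np.mean(z))
        return float(t), float(p), p < 0.05
    res = stats.ttest_1samp(z, 0.0, alternative=direction)
    return float(res.statistic), float(res.pvalue), bool(res.pvalue < 0.05)
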