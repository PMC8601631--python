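"""Synthetic wood-section scenes with exact ground truth.

Real evaluation data for this problem — stained transversal sections with
hand-drawn lumen annotations — cannot ship with a library, so this module
draws caricature sections for the four porosity types:

* ``conifer``      — a lattice of rectangular tracheids in rings whose lumens
                     shrink monotonically from earlywood to latewood;
* ``diffuse``      — uniformly sized vessels scattered over fibrous tissue;
* ``semidiffuse``  — vessels whose size decreases gradually within each ring;
* ``ringporous``   — a distinct band of very large earlywood vessels per ring
                     plus many small latewood vessels.

Non-target structures (rays, pits, resin canals, fibres, scalariform bars,
bark) are drawn in the image but never enter the label map, mirroring how a
human annotator marks only the true conduit lumens.  Artifact injection
(dust, overlapping tissue, stains, paraffin, broken walls, blur, uneven
illumination) corrupts the image only: the ground truth stays the true
lumens regardless of image quality.

:func:`perturb_labelmap` turns a ground truth into a *prediction with known
errors* — deletions, spurious blobs, splits, merges, boundary erosion and
dilation — engineered so that the instance matcher at τ = κ = 0.5 classifies
every planted error unambiguously.  The returned expected-count dictionary is
therefore an exact oracle for the evaluator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import cKDTree
from skimage.draw import disk as draw_disk
from skimage.draw import line as draw_line
from skimage.morphology import disk as disk_selem


def _dilate(mask, selem):
    return ndi.binary_dilation(mask, structure=selem)


def _erode(mask, selem):
    return ndi.binary_erosion(mask, structure=selem)

from .imaging_core import LabelMap, LabelsLike, as_labels, _frame_ids

__all__ = [
    "GenerationError",
    "PlanInfeasibleError",
    "WoodTypeConfig",
    "ArtifactConfig",
    "PerturbationPlan",
    "Scene",
    "generate_scene",
    "inject_artifacts",
    "perturb_labelmap",
]

POROSITIES = ("conifer", "diffuse", "semidiffuse", "ringporous")

# render tones (RGB)
_TISSUE = (178, 160, 138)
_WALL = (72, 52, 44)
_LUMEN = (242, 238, 230)
_RAY = (205, 190, 165)
_PIT = (150, 138, 122)
_RESIN = (200, 185, 160)
_FIBER = (96, 78, 62)
_BARK = (122, 92, 70)
_NOISE_SIGMA = 5.0


class GenerationError(ValueError):
    """The requested geometry cannot be drawn (cells do not fit)."""


class PlanInfeasibleError(ValueError):
    """The perturbation plan cannot be realised on this scene."""


@dataclass(frozen=True)
class WoodTypeConfig:
    """Geometry and density knobs of one synthetic section.

    The defaults per porosity (see the ``conifer()`` … constructors) emulate
    the qualitative structure of the four wood types: tracheid lattices with a
    0.45 earlywood→latewood linear shrink for conifers, ~60 uniformly sized
    vessels for diffuse-porous, a gradual within-ring size decline for
    semi-diffuse, and a large-vessel band plus small latewood vessels for
    ring-porous sections.
    """

    porosity: str = "conifer"
    height: int = 384
    width: int = 384
    seed: int = 0
    n_rings: int = 3
    # conifer lattice
    cells_per_ring: Tuple[int, int] = (7, 10)
    cell_height: Tuple[int, int] = (20, 27)
    earlywood_cell_width: int = 27
    shrink_factor: float = 0.45
    wall_thickness: Tuple[int, int] = (2, 4)
    # hardwood vessels
    n_vessels: int = 60
    vessel_radius: Tuple[int, int] = (8, 13)
    n_large_vessels: int = 9
    n_small_vessels: int = 45
    large_vessel_radius: Tuple[int, int] = (19, 26)
    small_vessel_radius: Tuple[int, int] = (4, 7)
    vessel_wall: int = 3
    # non-targets
    n_rays: int = 3
    ray_height: Tuple[int, int] = (4, 6)
    pit_probability: float = 0.15
    n_resin_canals: int = 1
    fiber_density: float = 0.0012
    scalariform_probability: float = 0.0
    bark_band: int = 0

    def __post_init__(self) -> None:
        if self.porosity not in POROSITIES:
            raise ValueError(f"porosity must be one of {POROSITIES}")
        if not 0.0 < self.shrink_factor <= 1.0:
            raise ValueError("shrink_factor must lie in (0, 1]")
        if self.height < 32 or self.width < 32:
            raise GenerationError("image too small for any cell layout")

    # convenience per-porosity constructors -------------------------------
    @staticmethod
    def conifer(seed: int = 0, **kw) -> "WoodTypeConfig":
        return WoodTypeConfig(porosity="conifer", seed=seed, **kw)

    @staticmethod
    def diffuse(seed: int = 0, **kw) -> "WoodTypeConfig":
        kw.setdefault("scalariform_probability", 0.15)
        return WoodTypeConfig(porosity="diffuse", seed=seed, n_resin_canals=0,
                              n_rays=2, **kw)

    @staticmethod
    def semidiffuse(seed: int = 0, **kw) -> "WoodTypeConfig":
        kw.setdefault("scalariform_probability", 0.05)
        return WoodTypeConfig(porosity="semidiffuse", seed=seed, n_resin_canals=0,
                              n_rays=2, **kw)

    @staticmethod
    def ringporous(seed: int = 0, **kw) -> "WoodTypeConfig":
        kw.setdefault("height", 448)
        kw.setdefault("width", 448)
        return WoodTypeConfig(porosity="ringporous", seed=seed, n_resin_canals=0,
                              n_rays=2, **kw)


@dataclass(frozen=True)
class ArtifactConfig:
    """Counts/intensities of sample-preparation and acquisition artifacts."""

    dust_particles: int = 0
    overlapping_tissue: int = 0
    stains: int = 0
    paraffin_drops: int = 0
    broken_walls: int = 0
    blur_regions: int = 0
    illumination_gradient: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("dust_particles", "overlapping_tissue", "stains",
                     "paraffin_drops", "broken_walls", "blur_regions"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class Scene:
    """A rendered section: image, exact ground truth, non-target annotations."""

    image: np.ndarray            # (H, W, 3) uint8
    labels: LabelMap             # target-cell lumens only
    non_targets: List[dict] = field(default_factory=list)


# ---------------------------------------------------------------------------
# scene generation
# ---------------------------------------------------------------------------

def generate_scene(cfg: WoodTypeConfig) -> Scene:
    """Render one synthetic section; deterministic for a fixed config."""
    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.height, cfg.width
    img = np.empty((h, w, 3), dtype=np.float64)
    img[:] = _TISSUE
    labels = np.zeros((h, w), dtype=np.int32)
    non_targets: List[dict] = []
    reserved = np.zeros((h, w), dtype=bool)

    # bark band at the right edge (non-target texture)
    if cfg.bark_band > 0:
        band = slice(w - cfg.bark_band, w)
        img[:, band] = _BARK
        stripe = (np.arange(h) // 6 % 2).astype(bool)
        img[stripe, band] = np.asarray(_BARK) * 0.8
        reserved[:, band] = True
        non_targets.append({"kind": "bark", "bbox": (0, w - cfg.bark_band, h - 1, w - 1)})

    # rays: thin horizontal bands of parenchyma (non-target)
    for _ in range(cfg.n_rays):
        rh = int(rng.integers(cfg.ray_height[0], cfg.ray_height[1] + 1))
        r0 = int(rng.integers(0, max(1, h - rh)))
        img[r0:r0 + rh, :] = _RAY
        reserved[r0:r0 + rh, :] = True
        non_targets.append({"kind": "ray", "bbox": (r0, 0, r0 + rh - 1, w - 1)})

    # resin canals (conifer): large round non-target openings
    if cfg.porosity == "conifer":
        for _ in range(cfg.n_resin_canals):
            r = int(rng.integers(11, 16))
            cy = int(rng.integers(r + 2, h - r - 2))
            cx = int(rng.integers(r + 2, w - r - 2))
            rr, cc = draw_disk((cy, cx), r, shape=(h, w))
            img[rr, cc] = _RESIN
            rr2, cc2 = draw_disk((cy, cx), r - 3, shape=(h, w))
            img[rr2, cc2] = np.asarray(_RESIN) * 1.05
            dil = np.zeros((h, w), dtype=bool)
            dil[rr, cc] = True
            reserved |= _dilate(dil, disk_selem(2))
            non_targets.append({"kind": "resin_canal", "center": (cy, cx), "radius": r})

    if cfg.porosity == "conifer":
        _draw_conifer(cfg, rng, img, labels, reserved, non_targets)
    else:
        _draw_vessels(cfg, rng, img, labels, reserved, non_targets)

    if int(labels.max()) == 0:
        raise GenerationError("no target cell fits the requested geometry")

    noise = rng.normal(0.0, _NOISE_SIGMA, size=img.shape)
    out = np.clip(img + noise, 0, 255).astype(np.uint8)
    return Scene(image=out, labels=LabelMap(labels), non_targets=non_targets)


def _draw_conifer(cfg: WoodTypeConfig, rng: np.random.Generator,
                  img: np.ndarray, labels: np.ndarray, reserved: np.ndarray,
                  non_targets: List[dict]) -> None:
    h, w = labels.shape
    t_early, t_late = cfg.wall_thickness
    # ring column layout: widths shrink earlywood -> latewood within each ring
    columns: List[Tuple[int, int, int]] = []  # (x0, width, wall)
    x = 0
    while x < w:
        k = int(rng.integers(cfg.cells_per_ring[0], cfg.cells_per_ring[1] + 1))
        non_targets.append({"kind": "ring_boundary", "x": x})
        for i in range(k):
            frac = i / max(k - 1, 1)
            cw = int(round(cfg.earlywood_cell_width *
                           (1.0 - (1.0 - cfg.shrink_factor) * frac)))
            t = int(round(t_early + (t_late - t_early) * frac))
            if cw - 2 * t < 2:
                raise GenerationError(
                    "latewood lumens vanish: shrink the walls or raise shrink_factor")
            columns.append((x, cw, t))
            x += cw
            if x >= w:
                break

    next_id = int(labels.max()) + 1
    y = 0
    wall_mask = np.zeros((h, w), dtype=bool)
    while y < h:
        rh = int(rng.integers(cfg.cell_height[0], cfg.cell_height[1] + 1))
        for (x0, cw, t) in columns:
            y1, x1 = min(y + rh, h), min(x0 + cw, w)
            if reserved[y:y1, x0:x1].any():
                continue
            img[y:y1, x0:x1] = _WALL
            wall_mask[y:y1, x0:x1] = True
            ly0, ly1 = y + t, min(y + rh - t, h)
            lx0, lx1 = x0 + t, min(x0 + cw - t, w)
            if ly1 - ly0 < 2 or lx1 - lx0 < 2:
                continue
            img[ly0:ly1, lx0:lx1] = _LUMEN
            wall_mask[ly0:ly1, lx0:lx1] = False
            labels[ly0:ly1, lx0:lx1] = next_id
            next_id += 1
        y += rh

    # pit chambers on shared walls (image-only)
    n_pits = 0
    for (x0, cw, t) in columns[1:]:
        col_centers = np.arange(10, h - 10, 24)
        for cy in col_centers:
            if rng.random() < cfg.pit_probability:
                rr, cc = draw_disk((int(cy), x0), 2, shape=(h, w))
                keep = wall_mask[rr, cc]
                img[rr[keep], cc[keep]] = _PIT
                if keep.any():
                    n_pits += 1
                    non_targets.append({"kind": "pit", "center": (int(cy), x0)})


def _draw_vessels(cfg: WoodTypeConfig, rng: np.random.Generator,
                  img: np.ndarray, labels: np.ndarray, reserved: np.ndarray,
                  non_targets: List[dict]) -> None:
    h, w = labels.shape
    # fibrous matrix: small dark non-target speckles
    n_fibers = rng.poisson(cfg.fiber_density * h * w)
    fy = rng.integers(0, h, size=n_fibers)
    fx = rng.integers(0, w, size=n_fibers)
    for y0, x0 in zip(fy, fx):
        if not reserved[y0, x0]:
            rr, cc = draw_disk((int(y0), int(x0)), 1, shape=(h, w))
            img[rr, cc] = _FIBER
    if n_fibers:
        non_targets.append({"kind": "fibers", "count": int(n_fibers)})

    occupied = reserved.copy()
    next_id = 1

    def place(radius: int, x_range: Tuple[int, int]) -> Optional[Tuple[int, int]]:
        pad = radius + cfg.vessel_wall + 2
        lo = max(pad, x_range[0])
        hi = min(w - pad, x_range[1])
        if hi <= lo:
            return None
        for _ in range(400):
            cy = int(rng.integers(pad, h - pad))
            cx = int(rng.integers(lo, hi))
            rr, cc = draw_disk((cy, cx), radius + cfg.vessel_wall + 2, shape=(h, w))
            if not occupied[rr, cc].any():
                return cy, cx
        return None

    def draw_vessel(cy: int, cx: int, radius: int) -> int:
        nonlocal next_id
        rr, cc = draw_disk((cy, cx), radius + cfg.vessel_wall, shape=(h, w))
        img[rr, cc] = _WALL
        rr2, cc2 = draw_disk((cy, cx), radius, shape=(h, w))
        img[rr2, cc2] = _LUMEN
        labels[rr2, cc2] = next_id
        rr3, cc3 = draw_disk((cy, cx), radius + cfg.vessel_wall + 2, shape=(h, w))
        occupied[rr3, cc3] = True
        vid = next_id
        next_id += 1
        return vid

    ring_w = w / cfg.n_rings
    if cfg.porosity == "ringporous":
        # earlywood band of large vessels, then scattered small latewood vessels
        for j in range(cfg.n_large_vessels):
            ring = j % cfg.n_rings
            band = (int(ring * ring_w), int(ring * ring_w + 0.38 * ring_w))
            r = int(rng.integers(cfg.large_vessel_radius[0],
                                 cfg.large_vessel_radius[1] + 1))
            pos = place(r, band)
            if pos is None:
                raise GenerationError("large earlywood vessels do not fit")
            draw_vessel(*pos, r)
        for j in range(cfg.n_small_vessels):
            ring = j % cfg.n_rings
            band = (int(ring * ring_w + 0.38 * ring_w), int((ring + 1) * ring_w))
            r = int(rng.integers(cfg.small_vessel_radius[0],
                                 cfg.small_vessel_radius[1] + 1))
            pos = place(r, band)
            if pos is None:
                raise GenerationError("small latewood vessels do not fit")
            draw_vessel(*pos, r)
    else:
        for j in range(cfg.n_vessels):
            r0, r1 = cfg.vessel_radius
            base = int(rng.integers(r0, r1 + 1))
            if cfg.porosity == "semidiffuse":
                # gradual within-ring size decline
                cx_try = int(rng.integers(0, w))
                frac = (cx_try % ring_w) / ring_w
                r = max(3, int(round(base * (1.0 - (1.0 - cfg.shrink_factor) * frac))))
                pos = place(r, (cx_try - 10, cx_try + 10))
                if pos is None:
                    pos = place(r, (0, w))
            else:
                r = base
                pos = place(r, (0, w))
            if pos is None:
                raise GenerationError("vessels do not fit; lower n_vessels")
            vid = draw_vessel(*pos, r)
            if rng.random() < cfg.scalariform_probability:
                _draw_scalariform(img, labels, vid, pos, r, rng)
                non_targets.append({"kind": "scalariform", "vessel_id": vid,
                                    "center": pos})


def _draw_scalariform(img: np.ndarray, labels: np.ndarray, vid: int,
                      center: Tuple[int, int], radius: int,
                      rng: np.random.Generator) -> None:
    """Thin ladder bars across a vessel lumen (image only; the vessel stays a
    single ground-truth instance)."""
    cy, cx = center
    h, w = labels.shape
    for off in range(-radius + 3, radius - 2, 4):
        rr = cy + off
        if 0 <= rr < h:
            cols = np.arange(max(0, cx - radius), min(w, cx + radius + 1))
            on_lumen = labels[rr, cols] == vid
            img[rr, cols[on_lumen]] = _WALL


# ---------------------------------------------------------------------------
# artifact injection
# ---------------------------------------------------------------------------

def inject_artifacts(scene: Scene, cfg: ArtifactConfig) -> Tuple[np.ndarray, List[dict]]:
    """Corrupt the image with sample-preparation artifacts.

    Returns a new image and a list of artifact records (kind, bounding box,
    overlapped ground-truth ids).  The scene's label map is never altered:
    artifacts degrade the picture, not the truth.
    """
    rng = np.random.default_rng(cfg.seed)
    img = scene.image.astype(np.float64).copy()
    labels = scene.labels.labels
    h, w = labels.shape
    records: List[dict] = []

    def record(kind: str, mask: np.ndarray) -> None:
        rs, cs = np.nonzero(mask)
        bbox = (int(rs.min()), int(cs.min()), int(rs.max()), int(cs.max()))
        ids = np.unique(labels[mask])
        records.append({"kind": kind, "bbox": bbox,
                        "gt_ids": [int(i) for i in ids if i > 0]})

    for _ in range(cfg.dust_particles):
        r = int(rng.integers(2, 6))
        cy, cx = int(rng.integers(r, h - r)), int(rng.integers(r, w - r))
        mask = np.zeros((h, w), dtype=bool)
        rr, cc = draw_disk((cy, cx), r, shape=(h, w))
        mask[rr, cc] = True
        img[mask] = (40, 35, 30)
        record("dust", mask)

    for _ in range(cfg.overlapping_tissue):
        # a translucent fold: a thick band at a random angle
        theta = rng.uniform(0, np.pi)
        d = rng.uniform(0.2, 0.8) * (h + w) / 2
        yy, xx = np.mgrid[0:h, 0:w]
        dist = np.abs(np.cos(theta) * xx + np.sin(theta) * yy - d)
        mask = dist < rng.uniform(10, 25)
        img[mask] = 0.55 * img[mask] + 0.45 * np.asarray(_TISSUE) * 0.8
        record("overlapping_tissue", mask)

    for _ in range(cfg.stains):
        r = int(rng.integers(15, 40))
        cy, cx = int(rng.integers(0, h)), int(rng.integers(0, w))
        mask = np.zeros((h, w), dtype=bool)
        rr, cc = draw_disk((cy, cx), r, shape=(h, w))
        mask[rr, cc] = True
        tint = np.array([150, 60, 80], dtype=np.float64)
        img[mask] = 0.6 * img[mask] + 0.4 * tint
        record("stain", mask)

    for _ in range(cfg.paraffin_drops):
        r = int(rng.integers(10, 25))
        cy, cx = int(rng.integers(0, h)), int(rng.integers(0, w))
        mask = np.zeros((h, w), dtype=bool)
        rr, cc = draw_disk((cy, cx), r, shape=(h, w))
        mask[rr, cc] = True
        img[mask] = 0.5 * img[mask] + 0.5 * np.array([250, 248, 240])
        record("paraffin", mask)

    for _ in range(cfg.broken_walls):
        # erase a wall chunk next to a random cell: lumen tone leaks out
        ids = np.unique(labels)
        ids = ids[ids > 0]
        if ids.size == 0:
            break
        vid = int(rng.choice(ids))
        rs, cs = np.nonzero(labels == vid)
        k = int(rng.integers(0, len(rs)))
        edge = np.argmax(np.abs(rs - rs.mean()) + np.abs(cs - cs.mean()))
        cy, cx = int(rs[edge]), int(cs[edge])
        mask = np.zeros((h, w), dtype=bool)
        rr, cc = draw_disk((cy, cx), int(rng.integers(2, 5)), shape=(h, w))
        mask[rr, cc] = True
        img[mask] = _LUMEN
        record("broken_wall", mask)

    for _ in range(cfg.blur_regions):
        bh, bw = int(rng.integers(50, 100)), int(rng.integers(50, 100))
        r0 = int(rng.integers(0, max(1, h - bh)))
        c0 = int(rng.integers(0, max(1, w - bw)))
        mask = np.zeros((h, w), dtype=bool)
        mask[r0:r0 + bh, c0:c0 + bw] = True
        region = img[r0:r0 + bh, c0:c0 + bw]
        img[r0:r0 + bh, c0:c0 + bw] = ndi.gaussian_filter(region, sigma=(2.5, 2.5, 0))
        record("blur", mask)

    if cfg.illumination_gradient > 0:
        g = cfg.illumination_gradient
        ramp = np.linspace(1.0 - g, 1.0 + g, w)[None, :, None]
        img = img * ramp
        records.append({"kind": "illumination_gradient", "bbox": (0, 0, h - 1, w - 1),
                        "gt_ids": []})

    return np.clip(img, 0, 255).astype(np.uint8), records


# ---------------------------------------------------------------------------
# perturbation oracle
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PerturbationPlan:
    """Planned error counts to inject into a ground truth.

    n_delete    whole cells removed            → missed FN
    n_spurious  background blobs added         → spurious FP
    n_split     cells cut into two fragments   → disconnected positive FP (×2)
                                                 + disconnected victim FN
    n_merge     adjacent cell pairs bridged    → merged negative FN (×2)
                                                 + merged prediction FP
    n_erode / erode_px, n_dilate / dilate_px
                matched cells whose boundary is shifted inward/outward by the
                given radius (they stay matched; only pixel metrics change)
    """

    n_delete: int = 0
    n_spurious: int = 0
    n_split: int = 0
    n_merge: int = 0
    n_erode: int = 0
    erode_px: int = 1
    n_dilate: int = 0
    dilate_px: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_delete", "n_spurious", "n_split", "n_merge",
                     "n_erode", "n_dilate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.erode_px < 0 or self.dilate_px < 0:
            raise ValueError("radii must be >= 0")


def perturb_labelmap(gt: LabelsLike, plan: PerturbationPlan
                     ) -> Tuple[LabelMap, Dict[str, int]]:
    """Build a prediction with exactly the planned errors.

    Every construction is verified against the matching rules (τ = κ = 0.5):
    split fragments stay ≤ 0.45 of the parent area; merge partners come from
    the same size class (area ratio ≤ 2) and the bridge is widened until each
    partner's IoU with the union is below 0.5 while the pair's joint IoU stays
    above it; spurious blobs keep ≥ 2 px clearance from every true cell; and
    eroded/dilated cells keep IoU ≥ 0.55 with their truth.  Raises
    :class:`PlanInfeasibleError` when the scene cannot host the plan.
    """
    labels = as_labels(gt)
    h, w = labels.shape
    rng = np.random.default_rng(plan.seed)
    areas = np.bincount(labels.ravel())
    border = set(int(i) for i in _frame_ids(labels))
    interior = [i for i in range(1, len(areas)) if areas[i] > 0 and i not in border]

    need = plan.n_delete + plan.n_split + 2 * plan.n_merge + plan.n_erode + plan.n_dilate
    if need > len(interior):
        raise PlanInfeasibleError(
            f"plan needs {need} interior cells, scene has {len(interior)}")

    pred = labels.copy()
    next_id = int(labels.max()) + 1
    pool = list(interior)
    rng.shuffle(pool)

    def pick(n: int, attempt, what: str) -> List[Tuple[int, object]]:
        """Draw n suitable cells from the pool, skipping unsuitable ones."""
        nonlocal pool
        chosen: List[Tuple[int, object]] = []
        rejected: List[int] = []
        while pool and len(chosen) < n:
            i = pool.pop(0)
            outcome = attempt(i)
            if outcome is None:
                rejected.append(i)
            else:
                chosen.append((i, outcome))
        pool.extend(rejected)
        if len(chosen) < n:
            raise PlanInfeasibleError(
                f"scene supports only {len(chosen)} of {n} requested {what}")
        return chosen

    expected = {"matched": 0, "fn_missed": 0, "fn_merged_negative": 0,
                "fn_disconnected_victim": 0, "fp_spurious": 0,
                "fp_disconnected_positive": 0, "fp_merged_prediction": 0}

    # --- merges first: they need adjacent same-size pairs ------------------
    merge_members: List[int] = []
    if plan.n_merge > 0:
        n_done = 0
        used: set = set()
        for a, b in _merge_candidates(labels, pool, areas):
            if n_done == plan.n_merge:
                break
            if a in used or b in used:
                continue
            union = _try_merge(labels, areas, a, b)
            if union is None:
                continue
            pred[union] = next_id
            next_id += 1
            used.update((a, b))
            merge_members.extend((a, b))
            n_done += 1
        if n_done < plan.n_merge:
            raise PlanInfeasibleError(
                f"only {n_done} mergeable adjacent pairs for {plan.n_merge} merges")
        pool = [i for i in pool if i not in used]
        expected["fn_merged_negative"] = 2 * n_done
        expected["fp_merged_prediction"] = n_done

    deleted = pick(plan.n_delete, lambda i: True, "deletions")
    for i, _ in deleted:
        pred[labels == i] = 0
    expected["fn_missed"] = len(deleted)

    def try_split(i: int):
        try:
            return _split_cell(labels, i)
        except PlanInfeasibleError:
            return None

    n_fragments = 0
    for i, frags in pick(plan.n_split, try_split, "splits"):
        pred[labels == i] = 0
        for fmask in frags:
            pred[fmask] = next_id
            next_id += 1
        n_fragments += len(frags)
    expected["fn_disconnected_victim"] = plan.n_split
    expected["fp_disconnected_positive"] = n_fragments

    def try_erode(i: int):
        small = _erode(labels == i, disk_selem(plan.erode_px))
        return small if small.sum() / areas[i] >= 0.55 else None

    for i, small in pick(plan.n_erode, try_erode, "erosions"):
        pred[labels == i] = 0
        pred[small] = i

    def try_dilate(i: int):
        mask = labels == i
        grown = _dilate(mask, disk_selem(plan.dilate_px))
        grown &= (labels == 0) | mask          # never eat another true cell
        grown &= (pred == 0) | mask            # never eat another prediction
        grown[0, :] = grown[-1, :] = False     # stay off the border
        grown[:, 0] = grown[:, -1] = False
        grown |= mask
        return grown if areas[i] / grown.sum() >= 0.55 else None

    for i, grown in pick(plan.n_dilate, try_dilate, "dilations"):
        pred[grown] = i

    if plan.n_spurious > 0:
        blobs = _spurious_blobs(labels, pred, plan.n_spurious, rng)
        for bmask in blobs:
            pred[bmask] = next_id
            next_id += 1
        expected["fp_spurious"] = len(blobs)

    expected["matched"] = (len(interior) - len(deleted) - plan.n_split
                           - len(merge_members))
    return LabelMap(pred), expected


def _split_cell(labels: np.ndarray, cell_id: int) -> List[np.ndarray]:
    """Cut one cell into two fragments, each ≤ 0.45 of the parent area, by
    removing a straight band through its interior."""
    mask = labels == cell_id
    area = int(mask.sum())
    rs, cs = np.nonzero(mask)
    # try the longer bbox axis first, then the other
    axes = [cs, rs] if (cs.max() - cs.min()) >= (rs.max() - rs.min()) else [rs, cs]
    for coords in axes:
        lo, hi = int(coords.min()), int(coords.max())
        if hi - lo < 6:
            continue
        order = np.sort(coords)
        mid = int(order[len(order) // 2])  # median position along the axis
        for thickness in range(2, max(3, (hi - lo) // 3)):
            c0 = mid - thickness // 2
            band = (coords >= c0) & (coords < c0 + thickness)
            removed = int(band.sum())
            cut = mask.copy()
            if coords is cs:
                cut[:, c0:c0 + thickness] = False
            else:
                cut[c0:c0 + thickness, :] = False
            lab, n = ndi.label(cut, structure=np.ones((3, 3), dtype=bool))
            if n < 2:
                break  # thicker bands will not reconnect it either; give up axis
            frag_areas = ndi.sum_labels(cut, lab, index=np.arange(1, n + 1))
            if removed > 0.35 * area:
                break
            if all(fa <= 0.45 * area for fa in frag_areas) and \
                    all(fa >= 4 for fa in frag_areas):
                return [lab == j for j in range(1, n + 1)]
    raise PlanInfeasibleError(f"cell {cell_id} cannot be split unambiguously")


def _merge_candidates(labels: np.ndarray, pool: List[int],
                      areas: np.ndarray) -> List[Tuple[int, int]]:
    """Adjacent pairs in the same size class (area ratio ≤ 2), most similar
    and closest first; whether a pair truly supports an unambiguous merge is
    decided by :func:`_try_merge`."""
    objs = ndi.find_objects(labels)
    boxes = {i: (objs[i - 1][0].start, objs[i - 1][1].start,
                 objs[i - 1][0].stop, objs[i - 1][1].stop) for i in pool}
    scored = []
    ids = sorted(pool)
    for ai in range(len(ids)):
        for bi in range(ai + 1, len(ids)):
            a, b = ids[ai], ids[bi]
            ra, rb = boxes[a], boxes[b]
            gap_r = max(ra[0], rb[0]) - min(ra[2], rb[2])
            gap_c = max(ra[1], rb[1]) - min(ra[3], rb[3])
            gap = max(gap_r, gap_c)
            ratio = max(areas[a], areas[b]) / min(areas[a], areas[b])
            # adjacency scales with cell size: big earlywood vessels sit
            # farther apart than latewood cells yet still count as neighbours
            gap_limit = max(20, int(0.9 * np.sqrt(min(areas[a], areas[b]))))
            if gap <= gap_limit and ratio <= 2.0:
                scored.append((ratio, gap, a, b))
    scored.sort()
    return [(a, b) for _, _, a, b in scored]


def _try_merge(labels: np.ndarray, areas: np.ndarray, a: int, b: int
               ) -> Optional[np.ndarray]:
    """Bridge cells a and b into one prediction mask, or None if impossible.

    The bridge widens until neither partner's IoU with the union reaches 0.5
    (so the matcher sees an unambiguous merged-negative case, never a greedy
    match) while the union still overlaps the pair at IoU ≥ 0.5.
    """
    pa = np.argwhere(labels == a)
    pb = np.argwhere(labels == b)
    tree = cKDTree(pb)
    dists, idx = tree.query(pa)
    k = int(np.argmin(dists))
    (r0, c0), (r1, c1) = pa[k], pb[idx[k]]
    rr, cc = draw_line(int(r0), int(c0), int(r1), int(c1))
    spine = np.zeros(labels.shape, dtype=bool)
    spine[rr, cc] = True
    others = (labels > 0) & (labels != a) & (labels != b)
    pair_mask = (labels == a) | (labels == b)
    pair_area = int(areas[a] + areas[b])
    for radius in range(1, 7):
        bridge = _dilate(spine, disk_selem(radius))
        if (bridge & others).any():
            return None  # a wider corridor would also hit a third cell
        bridge &= labels == 0
        bridge[0, :] = bridge[-1, :] = False
        bridge[:, 0] = bridge[:, -1] = False
        union = pair_mask | bridge
        ua = int(union.sum())
        if areas[a] / ua < 0.5 and areas[b] / ua < 0.5 and pair_area / ua >= 0.5:
            return union
    return None


def _spurious_blobs(labels: np.ndarray, pred: np.ndarray, n: int,
                    rng: np.random.Generator) -> List[np.ndarray]:
    """Round blobs in background, ≥ 2 px from every true cell and off the
    border, pairwise separated so each is its own prediction instance."""
    h, w = labels.shape
    clearance = ndi.distance_transform_edt(labels == 0)
    blobs: List[np.ndarray] = []
    occupied = pred > 0
    for _ in range(n):
        placed = False
        for _try in range(600):
            r = int(rng.integers(3, 6))
            cy = int(rng.integers(r + 2, h - r - 2))
            cx = int(rng.integers(r + 2, w - r - 2))
            if clearance[cy, cx] < r + 2.5:
                continue
            rr, cc = draw_disk((cy, cx), r, shape=(h, w))
            mask = np.zeros((h, w), dtype=bool)
            mask[rr, cc] = True
            if (_dilate(mask, disk_selem(2)) & occupied).any():
                continue
            blobs.append(mask)
            occupied |= _dilate(mask, disk_selem(2))
            placed = True
            break
        if not placed:
            raise PlanInfeasibleError("no room for the requested spurious blobs")
    return blobs
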