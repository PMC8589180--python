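"""Synthetic en-face OCT/OCTA scenes with ground truth.

The generator emulates the inputs of the quantification pipeline for one
eye of a MacTel (macular telangiectasia type 2) cohort:

* a DCP (deep capillary plexus) angiogram: a capillary mesh with a
  circumscribed zone of dilated, non-tapering telangiectatic vessels;
* an SCP (superficial capillary plexus) angiogram whose thick large
  vessels project into the DCP as artifacts;
* a photoreceptor-slab reflectance image with nested hypo-reflective
  regions — IZ attenuation ⊇ IZ loss ⊇ EZ loss — rendered as increasing
  intensity depressions;
* ground-truth masks for all of the above.

Region and telangiectasia areas are sampled per pooled disease group
(early / moderate / advanced) from truncated normals whose *truncated*
mean is moment-matched to the configured group target, so cohort-level
sample means converge to the targets.  Longitudinal pairs add a smooth
known deformation, new EZ-loss blobs placed predominantly inside the
baseline IZ-loss class, and an EZ recovery rim.

Everything is driven by a single integer seed per scene; identical seeds
give bit-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
from scipy import ndimage, optimize, stats
from skimage.draw import line
from skimage.morphology import disk

from .types import DEFAULT_FIELD_MM, DEFAULT_GRID, BinaryMask, EnFaceImage

log = logging.getLogger(__name__)

STAGE_GROUPS = ("early", "moderate", "advanced")

#: Cohort-level targets per pooled disease group: mean/SD of region areas
#: (mm², exclusive classes) and of the percent of telangiectasia area
#: overlapping each class.
GROUP_TARGETS: dict[str, dict] = {
    "early": {
        "tel": (0.160, 0.059),
        "attn": (0.745, 0.500),
        "izloss": (0.150, 0.149),
        "ezloss": (0.016, 0.031),
        "overlap_pct": {"attn": (48.55, 22.68), "izloss": (8.21, 11.64), "ezloss": (1.60, 3.73)},
    },
    "moderate": {
        "tel": (0.313, 0.123),
        "attn": (1.024, 0.856),
        "izloss": (0.401, 0.221),
        "ezloss": (0.247, 0.237),
        "overlap_pct": {"attn": (30.09, 16.61), "izloss": (25.49, 10.55), "ezloss": (17.94, 18.82)},
    },
    "advanced": {
        "tel": (0.561, 0.190),
        "attn": (1.095, 0.321),
        "izloss": (0.711, 0.464),
        "ezloss": (1.091, 0.560),
        "overlap_pct": {"attn": (10.06, 8.36), "izloss": (18.44, 8.06), "ezloss": (65.12, 17.79)},
    },
}

#: Stages pooled into each group (ordinal 0-6 severity grades).
GROUP_STAGES = {"early": (0, 1, 2), "moderate": (3, 4, 5), "advanced": (6,)}


# ---------------------------------------------------------------------------
# moment-matched truncated-normal sampling


@lru_cache(maxsize=256)
def _matched_truncnorm(mean: float, sd: float, lower: float, upper: float):
    """Frozen truncated normal on [lower, upper] whose *truncated* mean
    equals `mean`; the parent scale is `sd`.

    A plain normal truncated at the bounds has its mean pulled inward;
    solving for the parent location keeps cohort sample means on target.
    When the target mean is too close to a bound for any parent location
    to attain it exactly (heavily skewed cells), the closest attainable
    location is used.
    """
    if sd <= 0:
        return None  # degenerate: caller returns the constant

    def trunc_mean(mu: float) -> float:
        a, b = (lower - mu) / sd, (upper - mu) / sd
        return float(stats.truncnorm.mean(a, b, loc=mu, scale=sd))

    lo_mu, hi_mu = mean - 12 * sd, mean + 12 * sd
    f_lo, f_hi = trunc_mean(lo_mu) - mean, trunc_mean(hi_mu) - mean
    if f_lo > 0:  # even mu -> -inf cannot reach the target mean
        mu = lo_mu
    elif f_hi < 0:
        mu = hi_mu
    else:
        mu = optimize.brentq(lambda m: trunc_mean(m) - mean, lo_mu, hi_mu, xtol=1e-10)
    a, b = (lower - mu) / sd, (upper - mu) / sd
    return stats.truncnorm(a, b, loc=mu, scale=sd)


def sample_positive(rng: np.random.Generator, mean: float, sd: float, upper: float = np.inf) -> float:
    """Draw one value from the moment-matched truncated normal on [0, upper]."""
    if mean < 0:
        raise ValueError("target mean must be >= 0")
    dist = _matched_truncnorm(float(mean), float(sd), 0.0, float(upper))
    if dist is None:
        return float(mean)
    return float(dist.rvs(random_state=rng))


# ---------------------------------------------------------------------------
# parameters and truth containers


@dataclass(frozen=True)
class SceneParams:
    """Conditions for one synthetic eye.

    ``target_areas_mm2`` maps the exclusive disruption classes
    (``attn``, ``izloss``, ``ezloss``) to (mean, SD) areas in mm²;
    ``overlap_fractions`` maps them to (mean, SD) *fractions* in [0, 1] of
    the telangiectasia area falling inside each class.  Defaults come from
    the pooled-group cohort targets.
    """

    grid_size: int = DEFAULT_GRID
    field_mm: float = DEFAULT_FIELD_MM
    stage_group: str = "moderate"
    target_areas_mm2: dict | None = None
    telangiectasia_area_mm2: tuple[float, float] | None = None
    overlap_fractions: dict | None = None
    noise_level: float = 0.15
    seed: int = 0

    def resolved(self) -> "SceneParams":
        """Fill unset targets from the pooled-group defaults and validate."""
        if self.stage_group not in STAGE_GROUPS:
            raise ValueError(f"stage_group must be one of {STAGE_GROUPS}")
        g = GROUP_TARGETS[self.stage_group]
        areas = dict(self.target_areas_mm2 or {k: g[k] for k in ("attn", "izloss", "ezloss")})
        tel = self.telangiectasia_area_mm2 or g["tel"]
        if self.overlap_fractions is None:
            ov = {k: (m / 100.0, s / 100.0) for k, (m, s) in g["overlap_pct"].items()}
        else:
            ov = dict(self.overlap_fractions)
        p = replace(self, target_areas_mm2=areas, telangiectasia_area_mm2=tel, overlap_fractions=ov)
        field_area = p.field_mm**2
        if p.grid_size < 64:
            raise ValueError("grid_size must be >= 64")
        for name, (m, s) in {**areas, "tel": tel}.items():
            if m < 0 or s < 0:
                raise ValueError(f"negative area target for {name!r}")
            if m > field_area:
                raise ValueError(f"target area for {name!r} exceeds the {field_area} mm² field")
        if sum(m for m, _ in areas.values()) > field_area:
            raise ValueError("summed region targets exceed the field area")
        if not all(0 <= m <= 1 for m, _ in ov.values()) or sum(m for m, _ in ov.values()) > 1:
            raise ValueError("overlap fractions must lie in [0,1] and sum to <= 1")
        if not 0 <= p.noise_level < 1:
            raise ValueError("noise_level must be in [0, 1)")
        return p


@dataclass
class GroundTruth:
    """Ground-truth masks of one scene; C ⊆ B ⊆ A pixelwise."""

    telangiectasia: BinaryMask
    scp_large_vessels: BinaryMask
    region_combined_A: BinaryMask  # IZ attenuation + IZ loss + EZ loss
    region_combined_B: BinaryMask  # IZ loss + EZ loss
    region_ez_C: BinaryMask  # EZ loss

    @property
    def izloss_only(self) -> BinaryMask:
        return self.region_combined_B & ~self.region_ez_C

    @property
    def attn_only(self) -> BinaryMask:
        return self.region_combined_A & ~self.region_combined_B


@dataclass
class Scene:
    """One synthetic eye: the three en-face images and their ground truth."""

    scp: EnFaceImage
    dcp: EnFaceImage
    slab: EnFaceImage
    truth: GroundTruth
    params: SceneParams


# ---------------------------------------------------------------------------
# geometric helpers


def _smooth_field(rng: np.random.Generator, n: int, sigma: float) -> np.ndarray:
    f = ndimage.gaussian_filter(rng.standard_normal((n, n)), sigma, mode="reflect")
    s = f.std()
    return f / s if s > 0 else f


def _nested_regions(
    rng: np.random.Generator, n: int, n_attn: int, n_iz: int, n_ez: int
) -> tuple[BinaryMask, BinaryMask, BinaryMask]:
    """Nested combined regions A ⊇ B ⊇ C as sub-level... super-level sets of a
    smooth random potential biased toward a jittered field centre, so the
    classes form contiguous blobby annuli with exact pixel counts."""
    cy, cx = n / 2 + rng.uniform(-n / 12, n / 12, size=2)
    yy, xx = np.mgrid[0:n, 0:n]
    r = np.hypot(yy - cy, xx - cx) / (n / 2)
    pot = _smooth_field(rng, n, n / 10) * 0.55 - 1.8 * r
    order = np.argsort(pot.ravel())[::-1]  # most "diseased" pixels first
    C = np.zeros(n * n, dtype=bool)
    B = np.zeros(n * n, dtype=bool)
    A = np.zeros(n * n, dtype=bool)
    C[order[:n_ez]] = True
    B[order[: n_ez + n_iz]] = True
    A[order[: n_ez + n_iz + n_attn]] = True
    return A.reshape(n, n), B.reshape(n, n), C.reshape(n, n)


def _nearest_subset(candidates: BinaryMask, anchor: tuple[float, float], count: int) -> BinaryMask:
    """The `count` pixels of `candidates` nearest (Euclidean) to `anchor`."""
    out = np.zeros_like(candidates)
    if count <= 0:
        return out
    ys, xs = np.nonzero(candidates)
    if ys.size == 0:
        return out
    count = min(count, ys.size)
    d2 = (ys - anchor[0]) ** 2 + (xs - anchor[1]) ** 2
    keep = np.argpartition(d2, count - 1)[:count]
    out[ys[keep], xs[keep]] = True
    return out


def _random_paths(
    rng: np.random.Generator,
    n: int,
    n_paths: int,
    n_steps: int,
    step: float = 2.0,
    turn_sd: float = 0.35,
) -> BinaryMask:
    """Rasterized union of curvy random-walk polylines (persistent heading
    with a small random turn each step): a crude capillary mesh."""
    canvas = np.zeros((n, n), dtype=bool)
    for _ in range(n_paths):
        pos = rng.uniform(0, n, size=2)
        heading = rng.uniform(0, 2 * np.pi)
        pts = np.empty((n_steps, 2))
        for i in range(n_steps):
            heading += rng.normal(0, turn_sd)
            pos = pos + step * np.array([np.sin(heading), np.cos(heading)])
            pos = np.clip(pos, 0, n - 1)
            pts[i] = pos
        ipts = np.round(pts).astype(int)
        for (y0, x0), (y1, x1) in zip(ipts[:-1], ipts[1:]):
            rr, cc = line(y0, x0, y1, x1)
            canvas[rr, cc] = True
    return canvas


def _thick_path(rng: np.random.Generator, n: int, width: int) -> BinaryMask:
    """One thick curvilinear vessel crossing the field."""
    edge = rng.integers(0, 4)
    t0 = rng.uniform(0.15, 0.85) * n
    start = {0: (0.0, t0), 1: (n - 1.0, t0), 2: (t0, 0.0), 3: (t0, n - 1.0)}[int(edge)]
    # heading angle t gives step direction (dy, dx) = (cos t, sin t): point into the field
    heading = {0: 0.0, 1: np.pi, 2: np.pi / 2, 3: -np.pi / 2}[int(edge)]
    canvas = np.zeros((n, n), dtype=bool)
    pos = np.array(start)
    pts = [pos.copy()]
    for _ in range(int(n / 2)):
        heading += rng.normal(0, 0.12)
        pos = pos + 2.5 * np.array([np.cos(heading), np.sin(heading)])
        if not (0 <= pos[0] < n and 0 <= pos[1] < n):
            break
        pts.append(pos.copy())
    ipts = np.clip(np.round(np.array(pts)).astype(int), 0, n - 1)
    for (y0, x0), (y1, x1) in zip(ipts[:-1], ipts[1:]):
        rr, cc = line(y0, x0, y1, x1)
        canvas[rr, cc] = True
    return ndimage.binary_dilation(canvas, structure=disk(max(1, width // 2)))


def _telangiectasia_zone(
    rng: np.random.Generator,
    A: BinaryMask,
    B: BinaryMask,
    C: BinaryMask,
    n_tel: int,
    frac: dict[str, float],
) -> BinaryMask:
    """Circumscribed telangiectasia footprint with the requested share of
    its pixels in each exclusive disruption class (remainder outside A)."""
    n = A.shape[0]
    T = np.zeros_like(A)
    if n_tel <= 0:
        return T
    classes = {
        "attn": A & ~B,
        "izloss": B & ~C,
        "ezloss": C,
    }
    counts = {k: int(round(frac.get(k, 0.0) * n_tel)) for k in classes}
    # clip each demand to what the class can supply; spillover goes outside A
    for k, m in classes.items():
        avail = int(np.count_nonzero(m))
        if counts[k] > avail:
            log.debug("telangiectasia overlap demand for %s clipped: %d -> %d px", k, counts[k], avail)
            counts[k] = avail
    n_out = n_tel - sum(counts.values())
    all_classes = dict(classes)
    counts["outside"] = n_out

    if A.any():
        # Sector construction: the zone is a wedge about the centre of the
        # nested disruption regions.  Each class contributes the pixels of
        # its annulus angularly nearest a common random anchor angle, so
        # the per-class patches stack radially, stay contiguous and cannot
        # enclose unselected pixels of an inner class.
        ys_a, xs_a = np.nonzero(A)
        cy, cx = float(ys_a.mean()), float(xs_a.mean())
        theta0 = float(rng.uniform(-np.pi, np.pi))
        yy, xx = np.mgrid[0:n, 0:n]
        dtheta = np.abs(np.angle(np.exp(1j * (np.arctan2(yy - cy, xx - cx) - theta0))))
        # candidate band for the outside share: a ring hugging the lesion
        depth = 8
        ring = (~A) & ndimage.binary_dilation(A, structure=disk(depth))
        while np.count_nonzero(ring) < 2 * n_out and depth < n:
            depth *= 2
            ring = (~A) & ndimage.binary_dilation(A, structure=disk(depth))
        all_classes["outside"] = ring

        def sector_subset(mask: BinaryMask, count: int) -> BinaryMask:
            out = np.zeros_like(mask)
            if count <= 0:
                return out
            ys, xs = np.nonzero(mask)
            if ys.size == 0:
                return out
            if count < 300:
                # a small share arrives as a compact blob on the class
                # boundary at the wedge axis — a thin pie sliver would be
                # below the calibre the vessel delineation can carry
                bnd = mask & ~ndimage.binary_erosion(mask)
                bys, bxs = np.nonzero(bnd)
                if bys.size:
                    i = int(np.argmin(dtheta[bys, bxs]))
                    return _nearest_subset(mask, (float(bys[i]), float(bxs[i])), count)
            count = min(count, ys.size)
            keep = np.argpartition(dtheta[ys, xs], count - 1)[:count]
            out[ys[keep], xs[keep]] = True
            return out

        score = dtheta
        for k, m in all_classes.items():
            T |= sector_subset(m, counts[k])
    else:
        # no disruption at all: the zone is a blob near the field centre
        ay, ax = n / 2 + rng.uniform(-n / 8, n / 8), n / 2 + rng.uniform(-n / 8, n / 8)
        all_classes["outside"] = ~A
        for k, m in all_classes.items():
            T |= _nearest_subset(m, (ay, ax), counts[k])
        yy, xx = np.mgrid[0:n, 0:n]
        score = (yy - ay) ** 2.0 + (xx - ax) ** 2.0

    all_classes["outside"] = ~A  # full complement for the repair bookkeeping
    # Compact the zone while preserving per-class pixel counts.  A
    # circumscribed telangiectatic area has no enclosed holes or narrow
    # inlets (the downstream loop-and-fill delineation cannot represent
    # them), so annex such pixels and release the same number of
    # same-class pixels at the zone's selection fringe.
    for _ in range(6):
        compact = ndimage.binary_fill_holes(
            ndimage.binary_closing(T, structure=disk(3), border_value=0)
        )
        gained = compact & ~T
        if not gained.any():
            break
        for k, m in all_classes.items():
            gain_k = gained & m
            n_swap = int(np.count_nonzero(gain_k))
            if n_swap == 0:
                continue
            removable = T & m & ~gain_k
            ys, xs = np.nonzero(removable)
            if ys.size == 0:
                continue
            sc = score[ys, xs]
            n_swap = min(n_swap, ys.size)
            drop = np.argpartition(sc, ys.size - n_swap)[ys.size - n_swap :]
            T[ys[drop], xs[drop]] = False
            gys, gxs = np.nonzero(gain_k)
            T[gys[:n_swap], gxs[:n_swap]] = True
    return T


# ---------------------------------------------------------------------------
# rendering

_BACKGROUND = 0.10
_CAPILLARY = 0.50
_TEL_VESSEL = 0.90
_SCP_CAPILLARY = 0.42
_SCP_LARGE = 0.95
_SLAB_BASE = 0.70
_SLAB_DEPRESSION = {"attn": 0.15, "izloss": 0.35, "ezloss": 0.55}


def _speckle(rng: np.random.Generator, img: np.ndarray, contrast: float) -> np.ndarray:
    """Multiplicative gamma speckle with unit mean and SD = contrast."""
    if contrast <= 0:
        return np.clip(img, 0, 1)
    shape = 1.0 / contrast**2
    mult = rng.gamma(shape, 1.0 / shape, size=img.shape)
    return np.clip(img * mult, 0, 1)


def _render_telangiectasia(rng: np.random.Generator, T: BinaryMask) -> BinaryMask:
    """Dilated, non-tapering vessel loops whose filled footprint ~= T.

    The outermost loop follows the boundary of T (inset so that local
    thresholding, which spreads the bright band by about a pixel, recovers
    the zone without bias); chords through the interior mimic a tangle of
    dilated segments without changing the filled area.
    """
    if not T.any():
        return np.zeros_like(T)
    if np.count_nonzero(T) < 400:
        # a small zone is a single dilated vessel knot, not a loop; inset by
        # one pixel since thresholding spreads a solid bright blob outward
        return ndimage.binary_erosion(T, structure=disk(1))
    band = T & ~ndimage.binary_erosion(T, structure=disk(6))
    vessels = band.copy()
    ys, xs = np.nonzero(ndimage.binary_erosion(T, structure=disk(2)))
    if ys.size > 8:
        n_chords = 2 + int(ys.size // 400)
        for _ in range(n_chords):
            i, j = rng.integers(ys.size, size=2)
            rr, cc = line(ys[i], xs[i], ys[j], xs[j])
            chord = np.zeros_like(T)
            chord[rr, cc] = True
            vessels |= ndimage.binary_dilation(chord, structure=disk(2)) & T
    return vessels


def sample_truth(params: SceneParams) -> GroundTruth:
    """Sample the ground-truth masks of one scene (no image rendering)."""
    p = params.resolved()
    rng = np.random.default_rng(p.seed)
    n = p.grid_size
    px_per_mm2 = (n / p.field_mm) ** 2

    def npx(mean_sd: tuple[float, float]) -> int:
        return int(round(sample_positive(rng, *mean_sd, upper=p.field_mm**2) * px_per_mm2))

    n_attn = npx(p.target_areas_mm2["attn"])
    n_iz = npx(p.target_areas_mm2["izloss"])
    n_ez = npx(p.target_areas_mm2["ezloss"])
    total_cap = int(0.9 * n * n)
    if n_attn + n_iz + n_ez > total_cap:
        raise ValueError("sampled region areas exceed the usable field")
    A, B, C = _nested_regions(rng, n, n_attn, n_iz, n_ez)

    n_tel = int(round(sample_positive(rng, *p.telangiectasia_area_mm2, upper=p.field_mm**2) * px_per_mm2))
    # Overlap fractions are drawn by stick-breaking, innermost class first:
    # each class takes a random *relative* share of the telangiectasia area
    # still unallocated.  The relative shares are moment-matched so every
    # marginal mean equals its target exactly, the draw always lies on the
    # simplex, and nested classes compete for area (negatively correlated),
    # as they do in real eyes.  Each draw is additionally capped by the
    # class's own pixel supply, so a tiny lesion cannot be asked to host
    # more overlap than it has area (the cap is folded into the truncation,
    # keeping the attainable mean on target).
    supplies = {
        "ezloss": int(np.count_nonzero(C)),
        "izloss": int(np.count_nonzero(B & ~C)),
        "attn": int(np.count_nonzero(A & ~B)),
    }
    frac: dict[str, float] = {}
    rem = 1.0  # realized unallocated share
    rem_exp = 1.0  # its expectation under the targets
    for k in ("ezloss", "izloss", "attn"):
        m, s = p.overlap_fractions.get(k, (0.0, 0.0))
        if (m <= 0 and s <= 0) or rem_exp <= 1e-9 or rem <= 1e-9 or n_tel <= 0:
            frac[k] = 0.0
            continue
        supply_cap = supplies[k] / (rem * n_tel)
        upper = max(min(1.0, round(supply_cap, 3)), 1e-6)
        rel = sample_positive(rng, min(m / rem_exp, 1.0), s / rem_exp, upper=upper)
        frac[k] = rel * rem
        rem *= 1.0 - rel
        rem_exp = max(rem_exp - m, 0.0)
    T = _telangiectasia_zone(rng, A, B, C, n_tel, frac)

    n_large = int(rng.integers(1, 4))
    scp_large = np.zeros((n, n), dtype=bool)
    for _ in range(n_large):
        scp_large |= _thick_path(rng, n, width=int(rng.integers(8, 13)))

    return GroundTruth(
        telangiectasia=T,
        scp_large_vessels=scp_large,
        region_combined_A=A,
        region_combined_B=B,
        region_ez_C=C,
    )


def generate_scene(params: SceneParams) -> Scene:
    """Generate one synthetic eye: SCP/DCP angiograms, photoreceptor slab,
    and ground truth.  Same seed => bit-identical outputs."""
    p = params.resolved()
    truth = sample_truth(p)  # consumes the first part of the seed stream
    rng = np.random.default_rng((p.seed, 0x5CE7E))  # independent render stream
    n = p.grid_size

    # --- DCP: capillary mesh + dilated telangiectatic vessels
    mesh_fine = _random_paths(rng, n, n_paths=max(8, n // 8), n_steps=n // 2)
    mesh_coarse = ndimage.binary_dilation(
        _random_paths(rng, n, n_paths=max(4, n // 16), n_steps=n // 2),
        structure=np.ones((2, 2), dtype=bool),  # 2 px calibre, still capillary
    )
    tel_vessels = _render_telangiectasia(rng, truth.telangiectasia)
    dcp = np.full((n, n), _BACKGROUND)
    dcp[mesh_fine | mesh_coarse] = _CAPILLARY
    dcp[tel_vessels] = _TEL_VESSEL
    dcp = _speckle(rng, dcp, p.noise_level)

    # --- SCP: its own mesh + thick bright large vessels
    scp_mesh = _random_paths(rng, n, n_paths=max(8, n // 8), n_steps=n // 2)
    scp = np.full((n, n), _BACKGROUND)
    scp[scp_mesh] = _SCP_CAPILLARY
    scp[truth.scp_large_vessels] = _SCP_LARGE
    scp = _speckle(rng, scp, p.noise_level)

    # --- photoreceptor slab: nested hypo-reflective depressions
    slab = np.full((n, n), _SLAB_BASE)
    slab[truth.attn_only] -= _SLAB_DEPRESSION["attn"]
    slab[truth.izloss_only] -= _SLAB_DEPRESSION["izloss"]
    slab[truth.region_ez_C] -= _SLAB_DEPRESSION["ezloss"]
    slab = _speckle(rng, slab, p.noise_level)

    mk = lambda a: EnFaceImage(a, field_mm=p.field_mm)
    return Scene(scp=mk(scp), dcp=mk(dcp), slab=mk(slab), truth=truth, params=p)


# ---------------------------------------------------------------------------
# longitudinal pairs


@dataclass(frozen=True)
class LongitudinalParams:
    """Conditions for a 6-month follow-up of a baseline scene.

    ``new_ez_area_mm2`` / ``recovery_area_mm2`` give mean/SD of new EZ loss
    and EZ recovery; ``containment_range`` is the interval from which the
    per-eye fraction of new-loss pixels placed inside the baseline IZ-loss
    class is drawn.
    """

    deformation_amplitude_px: float = 3.0
    new_ez_area_mm2: tuple[float, float] = (0.052, 0.022)
    recovery_area_mm2: tuple[float, float] = (0.045, 0.023)
    containment_range: tuple[float, float] = (0.90, 0.95)
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.containment_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError("containment_range must satisfy 0 <= lo <= hi <= 1")
        for m, s in (self.new_ez_area_mm2, self.recovery_area_mm2):
            if m < 0 or s < 0:
                raise ValueError("areas must be >= 0")
        if self.deformation_amplitude_px < 0:
            raise ValueError("deformation amplitude must be >= 0")


@dataclass
class LongitudinalPair:
    """Baseline and follow-up of one eye, plus the generating deformation.

    ``sample_field`` (dy, dx on the follow-up grid) is the field used to
    resample the baseline; ``true_field`` is its numerical inverse on the
    baseline grid — the displacement an SCP registration should recover.
    Follow-up truth masks live in the *follow-up* frame.
    """

    baseline: Scene
    followup: Scene
    sample_field: np.ndarray  # (2, H, W): follow-up pixel -> baseline source offset
    true_field: np.ndarray  # (2, H, W): baseline pixel -> follow-up target offset
    new_ez_truth: BinaryMask  # follow-up frame
    recovery_truth: BinaryMask  # follow-up frame
    containment_fraction: float


def _smooth_displacement(rng: np.random.Generator, n: int, amplitude: float) -> np.ndarray:
    """(2, n, n) smooth displacement with maximum magnitude = amplitude."""
    if amplitude == 0:
        return np.zeros((2, n, n))
    f = np.stack([_smooth_field(rng, n, n / 6) for _ in range(2)])
    mag = np.hypot(f[0], f[1]).max()
    return f * (amplitude / mag) if mag > 0 else f


def _resample(arr: np.ndarray, field: np.ndarray, order: int, mode: str = "nearest") -> np.ndarray:
    """Sample `arr` at grid + field (field = (dy, dx) offsets)."""
    n0, n1 = arr.shape
    yy, xx = np.mgrid[0:n0, 0:n1].astype(np.float64)
    coords = np.stack([yy + field[0], xx + field[1]])
    return ndimage.map_coordinates(arr.astype(np.float64), coords, order=order, mode=mode)


def _warp_mask_by(mask: BinaryMask, field: np.ndarray) -> BinaryMask:
    return _resample(mask.astype(np.float64), field, order=0, mode="constant") > 0.5


def invert_field(field: np.ndarray, n_iter: int = 20) -> np.ndarray:
    """Numerical inverse of y -> y + field(y) by fixed-point iteration."""
    inv = -field.copy()
    for _ in range(n_iter):
        ey = _resample(field[0], inv, order=1)
        ex = _resample(field[1], inv, order=1)
        inv = -np.stack([ey, ex])
    return inv


def generate_longitudinal(baseline: Scene, params: LongitudinalParams) -> LongitudinalPair:
    """Generate the 6-month follow-up of a baseline scene.

    The follow-up images are the baseline resampled through a smooth random
    displacement; the follow-up EZ mask is the warped baseline EZ plus new
    loss blobs (predominantly inside the warped baseline IZ-loss class)
    minus a recovery rim along the warped EZ border.
    """
    params.validate()
    p = baseline.params
    n = p.grid_size
    rng = np.random.default_rng((params.seed, 0x10261))
    px_per_mm2 = (n / p.field_mm) ** 2

    e = _smooth_displacement(rng, n, params.deformation_amplitude_px)
    warp_img = lambda img: EnFaceImage(_resample(img.data, e, order=1, mode="nearest"), field_mm=p.field_mm)
    scp_f = warp_img(baseline.scp)
    dcp_f = warp_img(baseline.dcp)
    slab_f = EnFaceImage(_resample(baseline.slab.data, e, order=1, mode="nearest"), field_mm=p.field_mm)

    t = baseline.truth
    A_w = _warp_mask_by(t.region_combined_A, e)
    B_w = _warp_mask_by(t.region_combined_B, e)
    C_w = _warp_mask_by(t.region_ez_C, e)
    tel_w = _warp_mask_by(t.telangiectasia, e)
    scp_large_w = _warp_mask_by(t.scp_large_vessels, e)

    # --- new EZ loss
    n_new = int(round(sample_positive(rng, *params.new_ez_area_mm2, upper=p.field_mm**2) * px_per_mm2))
    lo, hi = params.containment_range
    contain = float(rng.uniform(lo, hi)) if hi > lo else float(lo)
    iz_only_w = B_w & ~C_w
    n_inside = int(round(contain * n_new))
    avail_inside = int(np.count_nonzero(iz_only_w))
    if n_inside > avail_inside:
        if contain >= 1.0:
            raise ValueError(
                f"new EZ loss ({n_inside} px) exceeds available IZ-loss area ({avail_inside} px) "
                "with full containment"
            )
        log.warning("contained new-loss demand clipped: %d -> %d px", n_inside, avail_inside)
        n_inside = avail_inside
    new_ez = np.zeros((n, n), dtype=bool)
    if n_new > 0:
        ys, xs = np.nonzero(iz_only_w)
        if ys.size:
            i = rng.integers(ys.size)
            anchor = (float(ys[i]), float(xs[i]))
        else:
            anchor = (n / 2.0, n / 2.0)
        new_ez |= _nearest_subset(iz_only_w, anchor, n_inside)
        new_ez |= _nearest_subset(~B_w, anchor, n_new - n_inside)

    # --- EZ recovery: a rim of the warped baseline EZ border
    n_rec = int(round(sample_positive(rng, *params.recovery_area_mm2, upper=p.field_mm**2) * px_per_mm2))
    recovery = np.zeros((n, n), dtype=bool)
    if n_rec > 0 and C_w.any():
        dt = ndimage.distance_transform_edt(C_w)
        ys, xs = np.nonzero(C_w)
        n_rec = min(n_rec, ys.size)
        order = np.argsort(dt[ys, xs] + rng.uniform(0, 1e-6, size=ys.size))
        keep = order[:n_rec]
        recovery[ys[keep], xs[keep]] = True

    C_f = (C_w | new_ez) & ~recovery
    B_f = B_w | C_f
    A_f = A_w | B_f

    # cosmetic: reflect EZ change in the follow-up slab
    slab_data = slab_f.data.copy()
    slab_data[new_ez] = np.clip(slab_data[new_ez] - 0.2, 0, 1)
    slab_data[recovery] = np.clip(slab_data[recovery] + 0.2, 0, 1)
    slab_f = EnFaceImage(slab_data, field_mm=p.field_mm)

    truth_f = GroundTruth(
        telangiectasia=tel_w,
        scp_large_vessels=scp_large_w,
        region_combined_A=A_f,
        region_combined_B=B_f,
        region_ez_C=C_f,
    )
    followup = Scene(scp=scp_f, dcp=dcp_f, slab=slab_f, truth=truth_f, params=p)
    true_field = invert_field(e) if params.deformation_amplitude_px > 0 else np.zeros_like(e)
    return LongitudinalPair(
        baseline=baseline,
        followup=followup,
        sample_field=e,
        true_field=true_field,
        new_ez_truth=new_ez,
        recovery_truth=recovery,
        containment_fraction=contain,
    )


#: Baseline conditions of the longitudinal study regime: an eye with a
#: well-formed IZ-loss annulus (~0.6 mm²) around established EZ loss
#: (~0.4 mm²), the setting in which new EZ loss emerges.
LONGITUDINAL_BASELINE_AREAS = {
    "attn": (1.00, 0.35),
    "izloss": (0.60, 0.15),
    "ezloss": (0.40, 0.20),
}


def longitudinal_scene_params(seed: int, grid_size: int = DEFAULT_GRID) -> SceneParams:
    """Baseline SceneParams for the longitudinal regime."""
    return SceneParams(
        grid_size=grid_size,
        stage_group="advanced",
        target_areas_mm2=dict(LONGITUDINAL_BASELINE_AREAS),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# cohort


@dataclass
class CohortEye:
    """Metadata and generator parameters for one cohort eye."""

    patient_id: str
    eye_id: str
    laterality: str
    stage: int
    pooled_group: str
    params: SceneParams


def generate_cohort(n_per_group: int, seed: int = 0) -> list[CohortEye]:
    """Plan a cohort of ``3 * n_per_group`` eyes grouped under patients.

    Patients contribute one or two eyes (both from the same pooled group);
    stages are drawn uniformly from the group's pool.  Scenes are realized
    lazily via :func:`generate_scene` on each eye's params.
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    rng = np.random.default_rng((seed, 0xC0407))
    eyes: list[CohortEye] = []
    patient_no = 0
    eye_no = 0
    for group in STAGE_GROUPS:
        remaining = n_per_group
        while remaining > 0:
            patient_no += 1
            pid = f"P{patient_no:03d}"
            n_eyes = 2 if (remaining >= 2 and rng.random() < 0.6) else 1
            lateralities = ["OD", "OS"]
            rng.shuffle(lateralities)
            for k in range(n_eyes):
                eye_no += 1
                stage = int(rng.choice(GROUP_STAGES[group]))
                eyes.append(
                    CohortEye(
                        patient_id=pid,
                        eye_id=f"E{eye_no:03d}",
                        laterality=lateralities[k],
                        stage=stage,
                        pooled_group=group,
                        params=SceneParams(stage_group=group, seed=int(rng.integers(2**31 - 1))),
                    )
                )
            remaining -= n_eyes
    return eyes
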