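"""Synthetic brain-like phantoms for PET/MR simulation studies.

Procedurally generated head phantoms stand in for segmented-MR subjects:
nested smooth-boundary compartments (scalp, skull, dura, a folded gray
ribbon and a white-matter core) built from a randomly deformed ellipsoid,
with

* an [18F]FDG-like activity map (gray:white 4:1, dura 0.5:1, spherical
  lesions of 5-15 mm diameter at 6:1-8:1 contrast with randomized
  position, size and edge sharpness),
* a T1-like guide volume with its own tissue contrast, and
* an attenuation map (0.13 /cm bone, 0.0975 /cm soft tissue).

Both the activity and the guide receive multiplicative random texture

    tau = phi o (1 + gamma * [2 G_sigma(rho) - 1]),   rho ~ U[0, 1)

(``o`` element-wise, ``G_sigma`` Gaussian smoothing) drawn from
*independent* random streams, so no trivial voxel-wise mapping exists
from the guide to the activity. Activity is clipped at zero: for
gamma = 1.5 the texture term can stray negative in distribution tails,
and activity is physically non-negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "BACKGROUND", "WHITE", "GRAY", "DURA", "BONE", "SOFT", "LESION_BASE",
    "LABEL_CODES", "PET_INTENSITY", "T1_INTENSITY",
    "SegmentationPhantom", "LesionSpec", "PhantomSet",
    "generate_segmentation", "assign_pet_intensities", "add_random_structure",
    "make_mu_map", "make_mr_guide", "random_lesions", "make_phantom",
]

# label codes
BACKGROUND, WHITE, GRAY, DURA, BONE, SOFT = 0, 1, 2, 3, 4, 5
LESION_BASE = 10  # lesion i carries code LESION_BASE + i
LABEL_CODES = (BACKGROUND, WHITE, GRAY, DURA, BONE, SOFT)

# piecewise activity relative to white matter = 1
PET_INTENSITY = {BACKGROUND: 0.0, WHITE: 1.0, GRAY: 4.0, DURA: 0.5, BONE: 0.0, SOFT: 0.25}
# T1-like contrast: white bright > gray > CSF/dura; deliberately not a
# monotone function of the PET contrast
T1_INTENSITY = {BACKGROUND: 0.0, WHITE: 1.0, GRAY: 0.6, DURA: 0.25, BONE: 0.15, SOFT: 0.8}
T1_LESION_INTENSITY = 0.9

MU_BONE = 0.13    # 1/cm
MU_TISSUE = 0.0975  # 1/cm


@dataclass(frozen=True)
class SegmentationPhantom:
    """Integer label volume plus voxel geometry."""

    labels: np.ndarray
    voxel_size: tuple[float, float, float]

    @property
    def shape(self) -> tuple[int, ...]:
        return self.labels.shape

    def tissue_mask(self) -> np.ndarray:
        """Brain tissue proper (white/gray, incl. lesion-coded voxels)."""
        lab = self.labels
        return (lab == WHITE) | (lab == GRAY) | (lab >= LESION_BASE)


@dataclass(frozen=True)
class LesionSpec:
    """A spherical lesion: center (voxel coords), diameter/contrast/edge blur."""

    center: tuple[int, int, int]
    diameter_mm: float
    contrast: float
    edge_sharpness_px: float = 0.7

    def __post_init__(self):
        if not (5.0 <= self.diameter_mm <= 15.0):
            raise ValueError(f"lesion diameter {self.diameter_mm} mm outside [5, 15]")
        if not (6.0 <= self.contrast <= 8.0):
            raise ValueError(f"lesion contrast {self.contrast} outside [6, 8]")
        if self.edge_sharpness_px < 0:
            raise ValueError("edge sharpness must be >= 0")


@dataclass
class PhantomSet:
    """Ground-truth activity, T1 guide, attenuation map and metadata."""

    tau: np.ndarray
    mr_t1: np.ndarray
    mu_map: np.ndarray
    seg: SegmentationPhantom
    lesions: list[LesionSpec] = field(default_factory=list)
    seed: int = 0

    @property
    def shape(self):
        return self.tau.shape

    @property
    def voxel_size(self):
        return self.seg.voxel_size


def _smooth_unit_field(shape, sigma_px, rng) -> np.ndarray:
    """Gaussian-smoothed U[0,1) noise, rescaled to zero mean / unit std."""
    f = ndimage.gaussian_filter(rng.random(shape), sigma_px, mode="reflect")
    f -= f.mean()
    s = f.std()
    return f / s if s > 0 else f


def generate_segmentation(shape, voxel_size, seed: int) -> SegmentationPhantom:
    """Nested-compartment head segmentation from a deformed ellipsoid.

    A radial level function of a centered ellipsoid is perturbed by a
    smooth random field, and thresholds carve scalp / skull / dura / a
    cortical gray ribbon / white core. A second smooth field folds extra
    gray-matter sheets into the interior so gray and white interdigitate.
    """
    shape = tuple(int(s) for s in shape)
    voxel_size = tuple(float(v) for v in np.broadcast_to(voxel_size, (3,)))
    if len(shape) != 3 or min(shape) < 16:
        raise ValueError(f"shape must be 3-D with every axis >= 16, got {shape}")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5E6]))

    grids = [
        (np.arange(n) - (n - 1) / 2.0) * v for n, v in zip(shape, voxel_size)
    ]
    z, y, x = np.meshgrid(*grids, indexing="ij")
    # semi-axes: slightly anisotropic, filling ~88% of the half-extent
    ext = [n * v / 2.0 for n, v in zip(shape, voxel_size)]
    semi = np.array([0.76 * ext[0], 0.82 * ext[1], 0.79 * ext[2]])
    f = np.sqrt((z / semi[0]) ** 2 + (y / semi[1]) ** 2 + (x / semi[2]) ** 2)

    # clamped so the deformed scalp surface can never reach the volume faces
    psi = np.clip(_smooth_unit_field(shape, sigma_px=max(2.0, min(shape) / 12.0), rng=rng),
                  -2.0, 2.0)
    t = f * (1.0 + 0.05 * psi)

    labels = np.full(shape, BACKGROUND, dtype=np.int32)
    labels[t <= 1.00] = SOFT
    labels[t <= 0.93] = BONE
    labels[t <= 0.86] = DURA
    labels[t <= 0.82] = GRAY          # cortical ribbon
    core = t <= 0.64
    labels[core] = WHITE
    # folded gray sheets inside the core
    xi = _smooth_unit_field(shape, sigma_px=max(1.5, min(shape) / 20.0), rng=rng)
    labels[core & (np.abs(xi) < 0.45)] = GRAY

    seg = SegmentationPhantom(labels=labels, voxel_size=voxel_size)
    _validate_segmentation(seg)
    return seg


def _validate_segmentation(seg: SegmentationPhantom) -> None:
    lab = seg.labels
    codes = set(np.unique(lab).tolist())
    allowed = set(LABEL_CODES) | {c for c in codes if c >= LESION_BASE}
    if not codes <= allowed:
        raise ValueError(f"unexpected label codes {sorted(codes - allowed)}")
    for ax in range(3):
        for face in (0, -1):
            sl = [slice(None)] * 3
            sl[ax] = face
            if not np.all(lab[tuple(sl)] == BACKGROUND):
                raise ValueError("background must touch every volume face")
    if not np.any(lab == GRAY) or not np.any(lab == WHITE):
        raise ValueError("both gray and white matter must be present")


def _lesion_weight(seg: SegmentationPhantom, les: LesionSpec) -> np.ndarray:
    """Soft (edge-blurred) indicator of a lesion sphere, in [0, 1]."""
    shape, vs = seg.shape, seg.voxel_size
    grids = [(np.arange(n) - c) * v for n, c, v in zip(shape, les.center, vs)]
    z, y, x = np.meshgrid(*grids, indexing="ij")
    r = np.sqrt(z**2 + y**2 + x**2)
    hard = (r <= les.diameter_mm / 2.0).astype(np.float64)
    if not np.any(hard):
        raise ValueError(f"lesion at {les.center} covers no voxel")
    if les.edge_sharpness_px > 0:
        w = ndimage.gaussian_filter(hard, les.edge_sharpness_px, mode="constant")
    else:
        w = hard
    return np.clip(w, 0.0, 1.0)


def assign_pet_intensities(seg: SegmentationPhantom, lesions=(), seed=None) -> np.ndarray:
    """Piecewise activity phi from labels, with lesions composited in.

    White matter is the reference (1.0), gray is 4.0, dura 0.5; each
    lesion is a sphere at ``contrast`` times white matter, alpha-blended
    with a per-lesion Gaussian edge blur. Deterministic; ``seed`` is
    accepted for signature uniformity and unused.
    """
    lab = seg.labels
    phi = np.zeros(lab.shape, dtype=np.float64)
    for code, val in PET_INTENSITY.items():
        phi[lab == code] = val
    for i, les in enumerate(lesions):
        hard = _lesion_weight(seg, LesionSpec(les.center, les.diameter_mm, les.contrast, 0.0)) > 0
        inside = seg.tissue_mask()
        if not np.all(inside[hard]):
            raise ValueError(f"lesion {i} at {les.center} extends outside brain tissue")
        w = _lesion_weight(seg, les)
        phi = phi * (1.0 - w) + les.contrast * PET_INTENSITY[WHITE] * w
    return phi


def add_random_structure(phi: np.ndarray, gamma: float, sigma_px: float, seed: int) -> np.ndarray:
    """Multiplicative smoothed-uniform texture; clipped at zero.

    tau = phi o (1 + gamma [2 G_sigma(rho) - 1]) with rho ~ U[0,1) per
    voxel. gamma = 0 returns phi unchanged (exact identity). The texture
    field has zero mean by construction (E[2 G(rho) - 1] = 0).
    """
    phi = np.asarray(phi, dtype=np.float64)
    if np.any(phi < 0):
        raise ValueError("phi must be non-negative")
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    if gamma == 0:
        return phi.copy()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x7A0]))
    rho = rng.random(phi.shape)
    g = ndimage.gaussian_filter(rho, float(sigma_px), mode="reflect")
    tau = phi * (1.0 + gamma * (2.0 * g - 1.0))
    return np.clip(tau, 0.0, None)


def make_mu_map(seg: SegmentationPhantom) -> np.ndarray:
    """Attenuation in 1/cm: bone 0.13, any other tissue 0.0975, vacuum 0."""
    lab = seg.labels
    mu = np.zeros(lab.shape, dtype=np.float64)
    mu[lab != BACKGROUND] = MU_TISSUE
    mu[lab == BONE] = MU_BONE
    return mu


def make_mr_guide(seg: SegmentationPhantom, gamma: float = 1.0, sigma_px: float = 1.0,
                  seed: int = 0) -> np.ndarray:
    """T1-like guide volume with its own randomized texture.

    The texture stream is derived from the seed but distinct from any PET
    stream, so the voxel-wise guide/activity ratio varies within tissue
    classes and no trivial guide-to-activity mapping exists.
    """
    lab = seg.labels
    t1 = np.zeros(lab.shape, dtype=np.float64)
    for code, val in T1_INTENSITY.items():
        t1[lab == code] = val
    t1[lab >= LESION_BASE] = T1_LESION_INTENSITY
    if gamma == 0:
        return t1
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x31]))
    rho = rng.random(t1.shape)
    g = ndimage.gaussian_filter(rho, float(sigma_px), mode="reflect")
    return np.clip(t1 * (1.0 + gamma * (2.0 * g - 1.0)), 0.0, None)


def random_lesions(seg: SegmentationPhantom, n: int, seed: int) -> list[LesionSpec]:
    """Randomized lesion specs fully inside brain tissue.

    Centers are drawn from voxels whose distance to the tissue boundary
    exceeds the lesion radius; diameter ~ U[5, 15] mm, contrast ~ U[6, 8],
    edge blur ~ U[0.4, 1.2] px ("varying sharpness").
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x1E5]))
    inside = seg.tissue_mask()
    vs = seg.voxel_size
    dist_mm = ndimage.distance_transform_edt(inside, sampling=vs)
    lesions: list[LesionSpec] = []
    for _ in range(int(n)):
        d = rng.uniform(5.0, 15.0)
        ok = dist_mm > (d / 2.0 + max(vs))
        cand = np.argwhere(ok)
        if len(cand) == 0:
            raise ValueError("phantom too small to host a lesion of diameter %.1f mm" % d)
        c = cand[rng.integers(len(cand))]
        lesions.append(LesionSpec(
            center=tuple(int(v) for v in c),
            diameter_mm=float(d),
            contrast=float(rng.uniform(6.0, 8.0)),
            edge_sharpness_px=float(rng.uniform(0.4, 1.2)),
        ))
    return lesions


def make_phantom(shape=(64, 64, 64), voxel_size=(2.0, 2.0, 2.0), n_lesions: int = 2,
                 gamma_pet: float = 1.5, gamma_mr: float = 1.0, sigma_px: float = 1.0,
                 seed: int = 0) -> PhantomSet:
    """Full phantom set: segmentation, activity tau, T1 guide, mu-map.

    All randomness is derived from ``seed`` through named substreams, so
    regeneration with the same seed is bit-identical.
    """
    seg = generate_segmentation(shape, voxel_size, seed=seed)
    lesions = random_lesions(seg, n_lesions, seed=seed) if n_lesions else []
    phi = assign_pet_intensities(seg, lesions)
    tau = add_random_structure(phi, gamma_pet, sigma_px, seed=seed)
    mu = make_mu_map(seg)
    t1 = make_mr_guide(seg, gamma=gamma_mr, sigma_px=sigma_px, seed=seed)
    # record lesion cores in the label volume for inspection
    lab = seg.labels.copy()
    for i, les in enumerate(lesions):
        hard = _lesion_weight(seg, LesionSpec(les.center, les.diameter_mm, les.contrast, 0.0)) > 0
        lab[hard] = LESION_BASE + i
    seg = SegmentationPhantom(labels=lab, voxel_size=seg.voxel_size)
    return PhantomSet(tau=tau, mr_t1=t1, mu_map=mu, seg=seg, lesions=lesions, seed=int(seed))
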