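"""Synthetic chest-CT phantoms with analytically known calcium burden.

Every downstream stage (segmentation, lesion scoring, vessel attribution,
bucket classification, agreement statistics) is testable against these
phantoms without any external data.  A phantom is a stack of axial slices:
soft-tissue background plus Gaussian noise, four disjoint coronary-vessel
territories (quadrant-offset tubes through the stack, one per artery:
LCA, LAD, LCX, RCA) holding hyperdense elliptical lesions, and non-coronary
distractor calcifications (aortic wall, aortic-root cusps, mitral annulus)
in a central region disjoint from every territory.

The generator records each lesion (slice, vessel, pixel set, peak HU, area)
in a manifest and computes per-vessel Agatston scores from the manifest with
its own copy of the score formula, written independently of the scoring
module — the generator is the oracle the pipeline is checked against.
Noise is added after lesion insertion and the manifest records clean-volume
HU, so the analytic reference is exact.

A degradation model turns a gated phantom into a non-gated look-alike
(in-plane motion blur, thicker effective slices via z-smoothing, extra
noise) while the ground truth stays that of the paired gated phantom,
mirroring the use of gated scores as the reference standard for non-gated
exams.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import json
from pathlib import Path

import numpy as np
from scipy import ndimage

from .ct_io import CTVolume, save_nifti, save_label_nifti
from .scoring import VESSELS, BUCKETS, VesselScores

__all__ = [
    "PhantomSpec",
    "DegradationParams",
    "LesionRecord",
    "PhantomGroundTruth",
    "PlacementError",
    "generate_volume",
    "degrade_to_nongated",
    "make_dataset",
    "bucket_spec",
    "ellipse_pixels",
    "analytic_vessel_scores",
    "write_phantom",
    "NON_CORONARY_LABEL",
]

NON_CORONARY_LABEL = 5


class PlacementError(RuntimeError):
    """A territory cannot host the requested lesion count/size."""


@dataclass(frozen=True)
class DegradationParams:
    """Gated -> non-gated degradation: in-plane motion blur along one axis,
    z-smoothing emulating thicker effective slices, and extra noise."""

    blur_sigma: float = 1.5       # pixels, along motion_axis
    slice_blur_sigma: float = 0.6  # slices
    extra_noise_sd: float = 15.0  # HU
    motion_axis: int = 1          # 1 = rows, 2 = cols (in-plane)
    seed: int = 0

    def __post_init__(self):
        if not np.isfinite([self.blur_sigma, self.slice_blur_sigma,
                            self.extra_noise_sd]).all():
            raise ValueError("degradation parameters must be finite")
        if min(self.blur_sigma, self.slice_blur_sigma,
               self.extra_noise_sd) < 0:
            raise ValueError("degradation parameters must be non-negative")
        if self.motion_axis not in (1, 2):
            raise ValueError("motion_axis must be 1 (rows) or 2 (cols)")


@dataclass(frozen=True)
class PhantomSpec:
    """Generator parameters; defaults emulate a gated calcium-scoring series
    (512x512 axial slices, 0.5 mm pixels, 5 mm slice spacing)."""

    n_slices: int = 8
    image_size: int = 512
    pixel_spacing: float = 0.5          # mm/pixel, isotropic in-plane
    slice_spacing: float = 5.0          # mm
    n_lesions_per_vessel: dict = field(
        default_factory=lambda: {v: 2 for v in VESSELS})
    lesion_hu_range: tuple[float, float] = (150.0, 800.0)
    lesion_radius_range: tuple[float, float] = (1.5, 3.0)   # pixels
    distractor_counts: dict = field(default_factory=lambda: {
        "aortic_wall": 2, "aortic_root": 2, "mitral_annulus": 1})
    distractor_hu_range: tuple[float, float] = (200.0, 900.0)
    background_hu: float = 40.0
    noise_sd: float = 10.0
    degradation: str = "none"           # "none" | "non_gated"
    degradation_params: DegradationParams = DegradationParams()
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.lesion_hu_range
        if not (130.0 < lo <= hi <= 4000.0):
            raise ValueError("lesion_hu_range must lie within (130, 4000]")
        if self.lesion_radius_range[0] < 0.8:
            raise ValueError("lesion radius below 0.8 px may rasterize empty")
        if self.image_size < 32:
            raise ValueError("image_size must be at least 32")
        if self.degradation not in ("none", "non_gated"):
            raise ValueError("degradation must be 'none' or 'non_gated'")
        if set(self.n_lesions_per_vessel) - set(VESSELS):
            raise ValueError(f"vessel keys must be among {VESSELS}")

    @property
    def pixel_area_mm2(self) -> float:
        return self.pixel_spacing ** 2


@dataclass
class LesionRecord:
    """Manifest entry: one coronary lesion with clean-volume statistics."""

    slice_index: int
    vessel: str
    pixels: np.ndarray      # (n, 2) (row, col)
    max_hu: float
    area_mm2: float


@dataclass
class PhantomGroundTruth:
    """Generator-side reference: label volume, manifest, analytic scores,
    and the noise-free HU volume."""

    label_volume: np.ndarray            # 0 bg, 1..4 vessels, 5 non-coronary
    vessel_scores: VesselScores
    lesion_manifest: list[LesionRecord]
    clean_volume: np.ndarray
    spec: PhantomSpec


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def _territory_centers(n: int) -> dict[str, tuple[float, float]]:
    c, d = n / 2.0, n / 4.0
    return {"LCA": (c - d, c - d), "LAD": (c - d, c + d),
            "LCX": (c + d, c - d), "RCA": (c + d, c + d)}


def _territory_radius(n: int) -> float:
    return n / 8.0


def _distractor_sites(n: int):
    """Non-coronary calcification sites (center, max radius).

    All three sit in the central column between the four territories and
    are mutually disjoint, so placing lesions at one site can never block
    another."""
    c = n / 2.0
    return {
        "aortic_wall": ((c, c), n / 12.0),      # wall calcification on aorta
        "aortic_root": ((c - n / 8.0, c), n / 24.0),    # cusp calcification
        "mitral_annulus": ((c + n / 8.0, c), n / 24.0),
    }


def ellipse_pixels(center: tuple[float, float], radii: tuple[float, float],
                   shape: tuple[int, int]) -> np.ndarray:
    """(row, col) pixel centers inside an axis-aligned filled ellipse."""
    cy, cx = center
    ry, rx = radii
    y0, y1 = int(np.floor(cy - ry)), int(np.ceil(cy + ry)) + 1
    x0, x1 = int(np.floor(cx - rx)), int(np.ceil(cx + rx)) + 1
    ys, xs = np.mgrid[max(0, y0):min(shape[0], y1),
                      max(0, x0):min(shape[1], x1)]
    inside = ((ys - cy) / ry) ** 2 + ((xs - cx) / rx) ** 2 <= 1.0
    return np.column_stack([ys[inside], xs[inside]])


# ---------------------------------------------------------------------------
# analytic (generator-side) Agatston oracle
# ---------------------------------------------------------------------------

def _analytic_weight(max_hu: float) -> int:
    # Independent re-statement of the density binning; deliberately not
    # imported from the scoring module so it can serve as its oracle.
    if max_hu >= 400.0:
        return 4
    if max_hu >= 300.0:
        return 3
    if max_hu >= 200.0:
        return 2
    if max_hu > 130.0:
        return 1
    return 0


def analytic_vessel_scores(manifest: list[LesionRecord]) -> VesselScores:
    """Per-vessel Agatston scores summed straight off the manifest."""
    per_vessel = {v: 0.0 for v in VESSELS}
    for rec in manifest:
        per_vessel[rec.vessel] += rec.area_mm2 * _analytic_weight(rec.max_hu)
    return VesselScores(per_vessel)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

_MAX_ATTEMPTS = 500


def _place(rng, clean, labels, occupied, site_center, site_radius,
           radius_range, hu_range, label, n_slices, shape):
    """Rejection-sample one non-overlapping ellipse; returns (slice, pixels,
    hu). Lesions keep a >=2 pixel 8-connectivity gap from everything placed
    before, so components never merge and ties never arise."""
    for _ in range(_MAX_ATTEMPTS):
        si = int(rng.integers(n_slices))
        a = float(rng.uniform(*radius_range))
        b = a * float(rng.uniform(0.7, 1.0))
        if rng.random() < 0.5:
            a, b = b, a
        r_eff = max(a, b)
        margin = site_radius - r_eff - 1.0
        if margin <= 0:
            continue
        rad = margin * np.sqrt(rng.random())
        ang = rng.uniform(0, 2 * np.pi)
        center = (site_center[0] + rad * np.sin(ang),
                  site_center[1] + rad * np.cos(ang))
        px = ellipse_pixels(center, (a, b), shape)
        if px.shape[0] == 0:
            continue
        # 1-pixel Chebyshev dilation of the candidate must miss everything
        # already placed -> minimum gap of 2 pixels.
        y0, x0 = px.min(axis=0) - 1
        y1, x1 = px.max(axis=0) + 2
        cand = np.zeros((y1 - y0 + 2, x1 - x0 + 2), dtype=bool)
        cand[px[:, 0] - y0 + 1, px[:, 1] - x0 + 1] = True
        cand = ndimage.binary_dilation(cand, structure=np.ones((3, 3)))
        yy0, xx0 = max(0, y0 - 1), max(0, x0 - 1)
        yy1 = min(shape[0], y1 + 1)
        xx1 = min(shape[1], x1 + 1)
        sub = cand[yy0 - (y0 - 1):yy1 - (y0 - 1),
                   xx0 - (x0 - 1):xx1 - (x0 - 1)]
        if (occupied[si][yy0:yy1, xx0:xx1] & sub).any():
            continue
        hu = float(rng.uniform(*hu_range))
        clean[si, px[:, 0], px[:, 1]] = hu
        labels[si, px[:, 0], px[:, 1]] = label
        occupied[si][yy0:yy1, xx0:xx1] |= sub
        return si, px, hu
    raise PlacementError(
        f"could not place a lesion of radius {radius_range} inside a site of "
        f"radius {site_radius:.1f} after {_MAX_ATTEMPTS} attempts")


def generate_volume(spec: PhantomSpec
                    ) -> tuple[CTVolume, PhantomGroundTruth]:
    """Generate one phantom exam and its exact ground truth.

    Deterministic for a fixed ``spec.seed``.  Raises
    :class:`PlacementError` when a territory cannot host the requested
    lesions (never silently truncates).
    """
    rng = np.random.default_rng(spec.seed)
    n, s = spec.image_size, spec.n_slices
    shape = (n, n)
    clean = np.full((s, n, n), spec.background_hu, dtype=np.float64)
    labels = np.zeros((s, n, n), dtype=np.uint8)
    occupied = [np.zeros(shape, dtype=bool) for _ in range(s)]

    centers = _territory_centers(n)
    t_radius = _territory_radius(n)
    manifest: list[LesionRecord] = []
    for vi, vessel in enumerate(VESSELS):
        for _ in range(int(spec.n_lesions_per_vessel.get(vessel, 0))):
            si, px, hu = _place(
                rng, clean, labels, occupied, centers[vessel], t_radius,
                spec.lesion_radius_range, spec.lesion_hu_range, vi + 1,
                s, shape)
            manifest.append(LesionRecord(
                slice_index=si, vessel=vessel, pixels=px, max_hu=hu,
                area_mm2=px.shape[0] * spec.pixel_area_mm2))

    sites = _distractor_sites(n)
    for kind, count in spec.distractor_counts.items():
        site_center, site_radius = sites[kind]
        for _ in range(int(count)):
            _place(rng, clean, labels, occupied, site_center, site_radius,
                   (0.9, max(0.9, site_radius / 2.5)),
                   spec.distractor_hu_range, NON_CORONARY_LABEL, s, shape)

    scores = analytic_vessel_scores(manifest)
    noisy = clean + rng.normal(0.0, spec.noise_sd, size=clean.shape) \
        if spec.noise_sd > 0 else clean.copy()
    volume = CTVolume(noisy, (spec.pixel_spacing, spec.pixel_spacing),
                      spec.slice_spacing, source_id=f"phantom-{spec.seed}")
    gt = PhantomGroundTruth(labels, scores, manifest, clean, spec)
    if spec.degradation == "non_gated":
        volume = degrade_to_nongated(volume, gt, spec.degradation_params)
    return volume, gt


def degrade_to_nongated(volume: CTVolume, ground_truth: PhantomGroundTruth,
                        params: DegradationParams = DegradationParams()
                        ) -> CTVolume:
    """Emulate a routine non-gated chest CT from a gated phantom.

    The ground truth (from the paired gated phantom) is deliberately left
    untouched: gated scores serve as the reference standard for the degraded
    exam.  With all parameters at zero the output equals the input.
    """
    data = volume.slices.copy()
    if params.blur_sigma > 0:
        data = ndimage.gaussian_filter1d(data, params.blur_sigma,
                                         axis=params.motion_axis)
    if params.slice_blur_sigma > 0 and data.shape[0] > 1:
        data = ndimage.gaussian_filter1d(data, params.slice_blur_sigma,
                                         axis=0)
    if params.extra_noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        data = data + rng.normal(0.0, params.extra_noise_sd, size=data.shape)
    return replace(volume, slices=data,
                   source_id=volume.source_id + "-nongated")


# ---------------------------------------------------------------------------
# bucket-stratified cohorts
# ---------------------------------------------------------------------------

def bucket_spec(target_bucket: str, *, image_size: int = 64,
                n_slices: int = 8, seed: int = 0, noise_sd: float = 10.0,
                degradation: str = "none",
                degradation_params: DegradationParams = DegradationParams()
                ) -> PhantomSpec:
    """A spec whose analytic total is guaranteed to land in ``target_bucket``.

    Lesion counts, radii and HU windows are chosen so that the minimum and
    maximum attainable totals both fall inside the bucket, whatever the
    random placements (rasterized ellipse areas are bounded by the radius
    window; the density weight is pinned by the HU window).
    """
    plans = {
        "I":   (dict.fromkeys(VESSELS, 0), (150, 190), (1.0, 1.2)),
        "II":  ({"LCA": 1, "LAD": 0, "LCX": 0, "RCA": 0},
                (150.0, 190.0), (1.0, 1.2)),
        "III": (dict.fromkeys(VESSELS, 1), (200.0, 290.0), (2.0, 2.2)),
        "IV":  ({"LCA": 3, "LAD": 3, "LCX": 2, "RCA": 2},
                (400.0, 900.0), (2.4, 2.5)),
        "V":   (dict.fromkeys(VESSELS, 6), (400.0, 900.0), (3.0, 3.2)),
    }
    if target_bucket not in plans:
        raise ValueError(f"bucket must be one of {BUCKETS}")
    lesions, hu_range, radius_range = plans[target_bucket]
    return PhantomSpec(
        n_slices=n_slices, image_size=image_size,
        n_lesions_per_vessel=dict(lesions), lesion_hu_range=hu_range,
        lesion_radius_range=radius_range, noise_sd=noise_sd,
        degradation=degradation, degradation_params=degradation_params,
        seed=seed)


def make_dataset(n_exams: int, spec_distribution=None, seed: int = 0,
                 **bucket_kwargs):
    """Reproducible bucket-stratified phantom cohort.

    Buckets are assigned by cycling I..V, so requested per-bucket counts are
    met exactly.  ``spec_distribution`` may override spec construction: a
    callable ``(bucket, seed) -> PhantomSpec``.  Returns
    ``(pairs, bucket_counts)`` where pairs are (CTVolume,
    PhantomGroundTruth) and counts tally the generated ground-truth buckets.
    """
    if n_exams < 1:
        raise ValueError("n_exams must be >= 1")
    builder = spec_distribution or (
        lambda b, sd: bucket_spec(b, seed=sd, **bucket_kwargs))
    rng = np.random.default_rng(seed)
    pairs, counts = [], {b: 0 for b in BUCKETS}
    for i in range(n_exams):
        b = BUCKETS[i % len(BUCKETS)]
        sub_seed = int(rng.integers(0, 2 ** 31 - 1))
        pair = generate_volume(builder(b, sub_seed))
        counts[pair[1].vessel_scores.bucket] += 1
        pairs.append(pair)
    return pairs, counts


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def write_phantom(volume: CTVolume, gt: PhantomGroundTruth, out_dir) -> None:
    """Write image + label NIfTI volumes and a JSON manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    save_nifti(volume, out_dir / "image.nii.gz")
    save_label_nifti(gt.label_volume, volume, out_dir / "labels.nii.gz")
    manifest = {
        "vessel_scores": gt.vessel_scores.to_dict(),
        "pixel_spacing": list(volume.pixel_spacing),
        "slice_spacing": volume.slice_spacing,
        "lesions": [
            {"slice": rec.slice_index, "vessel": rec.vessel,
             "max_hu": rec.max_hu, "area_mm2": rec.area_mm2,
             "pixels": rec.pixels.tolist()}
            for rec in gt.lesion_manifest
        ],
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
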