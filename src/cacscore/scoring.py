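"""Deterministic second stage: probability maps -> lesions -> Agatston scores.

The pipeline, run independently on every axial slice:

1. binarize: a pixel is calcium when ``p_calc > 0.5`` (strict);
2. 8-connected components within the slice form candidate lesions
   (no merging across slices);
3. each pixel gets the artery ``argmax(p_lca, p_lad, p_lcx, p_rca)`` and the
   lesion takes the plurality vote of its pixels;
4. the lesion area counts only pixels with attenuation > 130 HU (strict,
   measured on the original-resolution HU volume), and the lesion score is
   ``area_mm2 x weight(peak HU)`` with the standard density bins
   130<HU<200 -> 1, 200<=HU<300 -> 2, 300<=HU<400 -> 3, HU>=400 -> 4;
5. slice scores are summed per artery and in total, and the total maps to
   risk bucket I–V (0, 1–10, 11–100, 101–400, >400).

A config flag switches the density weight to literal multiplication by the
peak attenuation; the binned weight is the default since it is what puts
scores on the clinical 0–400 scale the buckets assume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

from .network import ProbabilityVolume, VESSELS

__all__ = [
    "VESSELS",
    "BUCKETS",
    "ScoringConfig",
    "Lesion",
    "VesselScores",
    "agatston_weight",
    "binarize_calcium",
    "extract_lesions",
    "assign_vessel",
    "score_volume",
    "score_masks",
    "bucket",
    "bucket_index",
    "binary_at_cutoff",
    "CUTOFFS",
]

BUCKETS = ("I", "II", "III", "IV", "V")
CUTOFFS = (1, 10, 100, 400)

_EIGHT = np.ones((3, 3), dtype=int)  # in-plane 8-connectivity structure


@dataclass(frozen=True)
class ScoringConfig:
    calc_prob_threshold: float = 0.5
    hu_threshold: float = 130.0
    connectivity: int = 8
    min_lesion_area_mm2: float = 0.0
    literal_hu_weight: bool = False

    def __post_init__(self):
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


@dataclass
class Lesion:
    """One in-slice 8-connected component of predicted calcium."""

    slice_index: int
    pixels: np.ndarray            # (n, 2) array of (row, col)
    area_mm2: float               # counting only pixels with HU > threshold
    max_hu: float                 # over all component pixels
    vessel: Optional[str] = None  # set by assign_vessel

    def agatston(self, cfg: ScoringConfig = ScoringConfig()) -> float:
        if self.area_mm2 <= 0:
            return 0.0
        if cfg.literal_hu_weight:
            return self.area_mm2 * self.max_hu
        return self.area_mm2 * agatston_weight(self.max_hu, cfg.hu_threshold)


@dataclass
class VesselScores:
    """Per-artery Agatston scores, their total, and the risk bucket."""

    per_vessel: dict[str, float]
    total: float = field(init=False)
    bucket: str = field(init=False)

    def __post_init__(self):
        self.per_vessel = {v: float(self.per_vessel.get(v, 0.0))
                           for v in VESSELS}
        self.total = float(sum(self.per_vessel.values()))
        self.bucket = bucket(self.total)

    def to_dict(self) -> dict:
        return {**self.per_vessel, "total": self.total, "bucket": self.bucket}


def agatston_weight(max_hu: float, hu_threshold: float = 130.0) -> int:
    """Density weight from a lesion's peak attenuation (standard bins)."""
    if max_hu <= hu_threshold:
        return 0
    if max_hu < 200.0:
        return 1
    if max_hu < 300.0:
        return 2
    if max_hu < 400.0:
        return 3
    return 4


def binarize_calcium(prob_volume: ProbabilityVolume,
                     cfg: ScoringConfig = ScoringConfig()) -> np.ndarray:
    """Boolean calcium mask; strictly greater than the 0.5 threshold."""
    return prob_volume.calc > cfg.calc_prob_threshold


def extract_lesions(mask_volume: np.ndarray, hu_volume: np.ndarray,
                    pixel_area_mm2: float,
                    cfg: ScoringConfig = ScoringConfig()) -> list[Lesion]:
    """Per-slice connected components of the mask, with HU statistics.

    Components live strictly within one slice; identical masks on adjacent
    slices yield distinct lesions.  Components whose HU-restricted area falls
    below ``min_lesion_area_mm2`` are dropped.
    """
    mask_volume = np.asarray(mask_volume, dtype=bool)
    hu_volume = np.asarray(hu_volume, dtype=np.float64)
    if mask_volume.shape != hu_volume.shape:
        raise ValueError("mask and HU volumes must have identical shapes")
    structure = _EIGHT if cfg.connectivity == 8 else ndimage.generate_binary_structure(2, 1)
    lesions: list[Lesion] = []
    for si in range(mask_volume.shape[0]):
        labeled, n = ndimage.label(mask_volume[si], structure=structure)
        for comp in range(1, n + 1):
            rows, cols = np.nonzero(labeled == comp)
            hu = hu_volume[si, rows, cols]
            area = float(np.count_nonzero(hu > cfg.hu_threshold)
                         * pixel_area_mm2)
            if area < cfg.min_lesion_area_mm2:
                continue
            lesions.append(Lesion(
                slice_index=si,
                pixels=np.column_stack([rows, cols]),
                area_mm2=area,
                max_hu=float(hu.max()),
            ))
    return lesions


def assign_vessel(lesion: Lesion, prob_volume: ProbabilityVolume,
                  cfg: ScoringConfig = ScoringConfig()) -> Lesion:
    """Label a lesion by per-pixel artery argmax followed by plurality vote.

    Ties are broken by the larger summed probability mass over the lesion,
    then by fixed vessel order LCA < LAD < LCX < RCA.
    """
    pv = prob_volume.vessel[lesion.slice_index][
        :, lesion.pixels[:, 0], lesion.pixels[:, 1]]    # (4, n_pixels)
    votes = np.bincount(np.argmax(pv, axis=0), minlength=4)
    mass = pv.sum(axis=1)
    best = max(range(4), key=lambda i: (votes[i], mass[i], -i))
    lesion.vessel = VESSELS[best]
    return lesion


def bucket(total_score: float) -> str:
    """Risk bucket I–V for a total Agatston score."""
    if total_score < 0:
        raise ValueError("Agatston scores are non-negative")
    if total_score == 0:
        return "I"
    if total_score <= 10:
        return "II"
    if total_score <= 100:
        return "III"
    if total_score <= 400:
        return "IV"
    return "V"


def bucket_index(b: str) -> int:
    """I..V -> 1..5."""
    return BUCKETS.index(b) + 1


def binary_at_cutoff(total_score: float, cutoff: int) -> bool:
    """Dichotomized call at a clinical cutoff: positive iff score >= cutoff."""
    if cutoff not in CUTOFFS:
        raise ValueError(f"cutoff must be one of {CUTOFFS}")
    return total_score >= cutoff


def score_volume(prob_volume: ProbabilityVolume, hu_volume: np.ndarray,
                 pixel_area_mm2: float,
                 cfg: ScoringConfig = ScoringConfig()
                 ) -> tuple[VesselScores, list[Lesion]]:
    """Full second stage on one exam; see module docstring.

    ``hu_volume`` must be the original-resolution HU stack (never the
    clipped/normalized model input).
    """
    mask = binarize_calcium(prob_volume, cfg)
    lesions = extract_lesions(mask, hu_volume, pixel_area_mm2, cfg)
    per_vessel = {v: 0.0 for v in VESSELS}
    for lesion in lesions:
        assign_vessel(lesion, prob_volume, cfg)
        per_vessel[lesion.vessel] += lesion.agatston(cfg)
    return VesselScores(per_vessel), lesions


def score_masks(calc_mask: np.ndarray, vessel_labels: np.ndarray,
                hu_volume: np.ndarray, pixel_area_mm2: float,
                cfg: ScoringConfig = ScoringConfig()
                ) -> tuple[VesselScores, list[Lesion]]:
    """Score hard masks (e.g., manual or ground-truth segmentations).

    ``vessel_labels`` holds 1..4 for (LCA, LAD, LCX, RCA) on calcium pixels;
    the masks are converted to a degenerate probability volume and routed
    through the standard pipeline, so hard and soft inputs share one code
    path.
    """
    calc_mask = np.asarray(calc_mask, dtype=bool)
    vessel_labels = np.asarray(vessel_labels)
    onehot = np.zeros((calc_mask.shape[0], 4) + calc_mask.shape[1:])
    for k in range(4):
        onehot[:, k] = np.where(vessel_labels == k + 1, 0.97, 0.01)
    onehot /= onehot.sum(axis=1, keepdims=True)
    prob = ProbabilityVolume(np.where(calc_mask, 0.99, 0.01), onehot)
    return score_volume(prob, hu_volume, pixel_area_mm2, cfg)
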