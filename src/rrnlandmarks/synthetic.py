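"""Synthetic craniomaxillofacial landmark cohorts and shape-space augmentation.

The real CBCT cohort the method was designed for is not publicly available,
so this module emulates its landmark geometry: a procedural 14-landmark
template on a nominal 256 x 256 x 512 voxel grid (x = left-right with the
midsagittal plane at x = 128, y = posterior-to-anterior, z =
inferior-to-superior), per-case shape variation from a random similarity
transform plus a low-rank statistical-shape deformation (a fixed set of
smooth population modes with per-case coefficients, scaled by deformity
severity), and per-landmark annotation jitter.  Variation is deliberately
low-dimensional and coherent across landmarks — that is how anatomy varies
and is the premise of shape-model interpolation augmentation.  Augmentation
follows the shape-interpolation recipe: convex combinations of 2-3 cases
plus uniform per-component noise bounded by +/-5 px.

Default conditions (fixed, documented in the methods note): spacing
0.754 x 0.754 x 0.377 mm, severity mix severe 3% / deformed 27% / normal
70% (normal cases carry no deformity beyond pose and jitter), deformation
coefficient scales 0 / 6 / 15 px RMS per landmark, annotation jitter
sigma = 1 px.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from .landmarks import (CohortTable, Landmark, LandmarkCase, ValidationError,
                        VOCABULARY)
from .model import substream

__all__ = [
    "TemplateShape",
    "AugmentationConfig",
    "make_cmf_template",
    "sample_case",
    "interpolate_cases",
    "generate_dataset",
    "DEFAULT_SPACING",
    "SEVERITY_LEVELS",
    "DEFAULT_SEVERITY_MIX",
]

DEFAULT_SPACING = np.array([0.754, 0.754, 0.377])
GRID = np.array([256.0, 256.0, 512.0])
MIDSAGITTAL_X = 128.0

SEVERITY_LEVELS = ("normal", "deformed", "severe")
DEFAULT_SEVERITY_MIX = {"normal": 0.70, "deformed": 0.27, "severe": 0.03}

#: RMS per-landmark deformity (px) per severity level, added on top of the
#: baseline healthy variation; 'normal' cases have no deformity
DEFORMATION_AMPLITUDE = {"normal": 0.0, "deformed": 6.0, "severe": 15.0}

#: RMS per-landmark healthy inter-subject shape variation (px), present in
#: every sampled case (~2-3 mm at the default spacing)
BASELINE_SHAPE_SCALE = 4.0

#: number of population shape modes in the template
N_SHAPE_MODES = 6

#: per-axis annotation jitter (px); single-observer repeatability scale
ANNOTATION_JITTER = 1.0

#: the five sparsely spaced mandibular landmarks (pairwise far apart)
_SPARSE = (Landmark.Me, Landmark.CorL, Landmark.CorR, Landmark.CdL, Landmark.CdR)
#: the closely spaced anterior mandibular chain (consecutive near neighbours)
_CHAIN = (Landmark.Me, Landmark.Gn, Landmark.Pg, Landmark.B, Landmark.Id)

SYMMETRY_PAIRS = ((Landmark.CorL, Landmark.CorR), (Landmark.CdL, Landmark.CdR))

# Template geometry (px): anterior mandibular chain tightly spaced around the
# chin, bilateral condylar/coronoid processes superior-posterior /
# superior-anterior, maxillary landmarks above the mandible, nasion on top.
_TEMPLATE_BASE: Dict[Landmark, Tuple[float, float, float]] = {
    Landmark.Me: (128.0, 150.0, 120.0),
    Landmark.Gn: (128.0, 155.0, 128.0),
    Landmark.Pg: (128.0, 158.0, 140.0),
    Landmark.B: (128.0, 156.0, 152.0),
    Landmark.Id: (128.0, 154.0, 164.0),
    Landmark.CorL: (170.0, 120.0, 250.0),
    Landmark.CorR: (86.0, 120.0, 250.0),
    Landmark.CdL: (180.0, 80.0, 260.0),
    Landmark.CdR: (76.0, 80.0, 260.0),
    Landmark.Pr: (128.0, 156.0, 196.0),
    Landmark.A: (128.0, 158.0, 210.0),
    Landmark.ANS: (128.0, 162.0, 224.0),
    Landmark.PNS: (128.0, 95.0, 228.0),
    Landmark.Na: (128.0, 150.0, 330.0),
}


@dataclass
class TemplateShape:
    """Mean landmark geometry, population shape modes and variability scales.

    `deformation_modes` is a (K, 14, 3) array of smooth, unit-RMS landmark
    displacement fields; a case's deformity is a random linear combination of
    these fixed modes, so deviations at different landmarks are coherent the
    way real anatomical variation is.
    """

    mean_positions: Dict[Landmark, np.ndarray]
    deformation_modes: np.ndarray = field(
        default_factory=lambda: np.zeros((0, len(VOCABULARY), 3)))
    symmetry_pairs: Tuple[Tuple[Landmark, Landmark], ...] = SYMMETRY_PAIRS
    deformation_scales: Dict[Landmark, float] = field(default_factory=dict)

    def matrix(self) -> np.ndarray:
        return np.stack([self.mean_positions[lm] for lm in VOCABULARY])


@dataclass(frozen=True)
class AugmentationConfig:
    """Shape-interpolation augmentation settings."""

    n_output: int
    k_interp: int = 2
    k_random: bool = True  # draw k uniformly from {2, 3} per augmented case
    noise_max: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if self.k_interp not in (2, 3):
            raise ValidationError("k_interp must be 2 or 3")
        if self.noise_max < 0:
            raise ValidationError("noise_max must be >= 0")


def make_cmf_template(seed: int) -> TemplateShape:
    """Build the procedural CMF template and its population shape modes."""
    rng = substream(seed, "template")
    mean = {lm: np.array(p, dtype=float) for lm, p in _TEMPLATE_BASE.items()}
    # enforce exact mirror symmetry about the midsagittal plane
    for left, right in SYMMETRY_PAIRS:
        l = mean[left]
        mean[right] = np.array([2 * MIDSAGITTAL_X - l[0], l[1], l[2]])
    pts = np.stack([mean[lm] for lm in VOCABULARY])
    modes = np.empty((N_SHAPE_MODES, len(VOCABULARY), 3))
    for k in range(N_SHAPE_MODES):
        field_k = _smooth_field(pts, 1.0, rng)
        # unit RMS per-landmark displacement so severity sets physical scale
        modes[k] = field_k / np.sqrt((field_k ** 2).sum(axis=1).mean())
    rms = np.sqrt((modes ** 2).sum(axis=2).mean(axis=0))
    scales = {lm: float(rms[i]) for i, lm in enumerate(VOCABULARY)}
    return TemplateShape(mean_positions=mean, deformation_modes=modes,
                         deformation_scales=scales)


def _rotation_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def _smooth_field(points: np.ndarray, amplitude: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Sum of 3 low-frequency sinusoidal displacement fields (px)."""
    disp = np.zeros_like(points)
    for _ in range(3):
        freq = rng.uniform(1.0 / 300.0, 1.0 / 100.0, size=3)
        phase = rng.uniform(0, 2 * np.pi, size=3)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        amp = amplitude * rng.uniform(0.5, 1.0)
        phase_arg = 2 * np.pi * (points * freq).sum(axis=1) + phase[0]
        disp += amp * np.sin(phase_arg)[:, None] * direction
    return disp


def sample_case(template: TemplateShape, severity: str, spacing: np.ndarray,
                seed: int, case_id: Optional[str] = None,
                jitter: float = ANNOTATION_JITTER,
                transform: bool = True) -> LandmarkCase:
    """Draw one synthetic subject from the template.

    Applies, in order: a random similarity transform (rotation <= 10 deg,
    scale 0.9-1.1, translation <= 20 px about the template centroid) together
    with a baseline healthy shape-mode draw, an additional shape-mode draw
    scaled by `severity` (zero for 'normal' cases), and Gaussian per-landmark
    annotation jitter.  `transform=False` (which also skips the baseline
    shape draw) with severity 'normal' and `jitter=0` reproduces the template
    exactly.
    """
    if severity not in SEVERITY_LEVELS:
        raise ValidationError(f"severity must be one of {SEVERITY_LEVELS}")
    rng = substream(seed, "sample_case")
    pts = template.matrix()
    centroid = pts.mean(axis=0)
    K = len(template.deformation_modes)
    if transform:
        axis = rng.normal(size=3)
        angle = np.deg2rad(rng.uniform(0.0, 10.0))
        R = _rotation_matrix(axis, angle)
        scale = rng.uniform(0.9, 1.1)
        translation = rng.uniform(-20.0, 20.0, size=3)
        pts = (pts - centroid) @ R.T * scale + centroid + translation
        if K:  # healthy inter-subject variation, present in every case
            coeffs = rng.standard_normal(K) * BASELINE_SHAPE_SCALE / np.sqrt(K)
            pts = pts + np.tensordot(coeffs, template.deformation_modes, axes=1)
    amp = DEFORMATION_AMPLITUDE[severity]
    if amp > 0 and K:
        coeffs = rng.standard_normal(K) * amp / np.sqrt(K)
        pts = pts + np.tensordot(coeffs, template.deformation_modes, axes=1)
    if jitter > 0:
        pts = pts + rng.normal(0.0, jitter, size=pts.shape)
    positions = {lm: pts[k] for k, lm in enumerate(VOCABULARY)}
    return LandmarkCase(
        case_id=case_id or f"synth-{seed}",
        spacing=np.asarray(spacing, dtype=float),
        positions=positions,
        annotation_source=f"synthetic:{severity}",
    )


def interpolate_cases(cases: Sequence[LandmarkCase], weights: Sequence[float],
                      noise_max: float, seed: int,
                      case_id: Optional[str] = None) -> LandmarkCase:
    """Convex combination of 2-3 complete cases plus bounded uniform noise."""
    if not (2 <= len(cases) <= 3):
        raise ValidationError("interpolation takes 2 or 3 source cases")
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (len(cases),) or np.any(weights < 0):
        raise ValidationError("weights must be nonnegative, one per case")
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValidationError(f"weights must sum to 1, got {weights.sum()!r}")
    spacings = np.stack([c.spacing for c in cases])
    if not np.allclose(spacings, spacings[0]):
        raise ValidationError("interpolated cases must share voxel spacing")
    for c in cases:
        if not c.is_complete:
            raise ValidationError(f"case {c.case_id} is incomplete; cannot interpolate")
    rng = substream(seed, "interpolate")
    stack = np.stack([c.position_matrix() for c in cases])       # (k, 14, 3)
    mixed = np.tensordot(weights, stack, axes=1)
    if noise_max > 0:
        mixed = mixed + rng.uniform(-noise_max, noise_max, size=mixed.shape)
    positions = {lm: mixed[k] for k, lm in enumerate(VOCABULARY)}
    # primary parent first (largest weight) — used for fold assignment
    order = np.argsort(-weights, kind="stable")
    return LandmarkCase(
        case_id=case_id or f"aug-{seed}",
        spacing=cases[0].spacing.copy(),
        positions=positions,
        annotation_source="augmented",
        derived_from=tuple(cases[int(i)].case_id for i in order),
    )


def generate_dataset(template: TemplateShape, n_base: int, aug: AugmentationConfig,
                     spacing: np.ndarray = DEFAULT_SPACING,
                     severity_mix: Optional[Dict[str, float]] = None,
                     jitter: float = ANNOTATION_JITTER) -> CohortTable:
    """Sample `n_base` synthetic subjects plus `aug.n_output` augmented cases.

    Severity labels are drawn from `severity_mix`; each augmented case
    interpolates k random distinct base cases (k uniform on {2, 3} when
    `aug.k_random`, else fixed at `aug.k_interp`) with Dirichlet(1) convex
    weights plus +/- `aug.noise_max` px uniform noise per component.
    """
    if n_base < 2:
        raise ValidationError("need at least two base cases")
    mix = severity_mix or DEFAULT_SEVERITY_MIX
    levels = list(mix)
    probs = np.array([mix[l] for l in levels], dtype=float)
    probs /= probs.sum()
    master = aug.seed
    rng = substream(master, "dataset")
    cases = []
    for b in range(n_base):
        severity = levels[rng.choice(len(levels), p=probs)]
        cases.append(sample_case(
            template, severity, spacing,
            seed=int(rng.integers(0, 2 ** 31 - 1)),
            case_id=f"base-{b:05d}", jitter=jitter))
    augmented = []
    for a in range(aug.n_output):
        k = int(rng.choice([2, 3])) if aug.k_random else aug.k_interp
        idx = rng.choice(n_base, size=k, replace=False)
        weights = rng.dirichlet(np.ones(k))
        augmented.append(interpolate_cases(
            [cases[int(i)] for i in idx], weights, aug.noise_max,
            seed=int(rng.integers(0, 2 ** 31 - 1)),
            case_id=f"aug-{a:05d}"))
    return CohortTable(cases=cases + augmented, provenance="synthetic")
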