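"""Pairwise geometric features for the relational units.

Each ordered pair (A, B) of input landmarks is described by a 19-component
vector built from pixel-space positions, spherical coordinates of the
difference vectors relative to the menton (Me) reference origin, and a single
mandible-size scalar d1:

    [Ax, Ay, Az,  r_MeA, th_MeA, ph_MeA,
     Bx, By, Bz,  r_MeB, th_MeB, ph_MeB,
     Mex, Mey, Mez,  r_AB, th_AB, ph_AB,  d1]

The spherical convention is the physics one: r = Euclidean length, theta =
polar angle from the +z axis in [0, pi], phi = atan2(y, x) in (-pi, pi].  A
zero-length vector maps to (0, 0, 0) so that degenerate pairs stay finite.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Sequence, Tuple

import numpy as np

from .landmarks import (ConfigurationSpec, ConfigurationError, DataError,
                        Landmark, LandmarkCase, ValidationError)

__all__ = [
    "SphericalVector",
    "FEATURE_NAMES",
    "FEATURE_DIM",
    "cartesian_to_spherical",
    "spherical_to_cartesian",
    "mandible_extent",
    "pairwise_features",
    "feature_batch",
    "feature_tensor",
    "ordered_pairs",
    "export_feature_matrix",
]

FEATURE_NAMES: Tuple[str, ...] = (
    "Ax", "Ay", "Az", "r_MeA", "theta_MeA", "phi_MeA",
    "Bx", "By", "Bz", "r_MeB", "theta_MeB", "phi_MeB",
    "Mex", "Mey", "Mez", "r_AB", "theta_AB", "phi_AB", "d1",
)
FEATURE_DIM = len(FEATURE_NAMES)  # 19


@dataclass(frozen=True)
class SphericalVector:
    r: float
    theta: float
    phi: float

    def to_cartesian(self) -> np.ndarray:
        return spherical_to_cartesian(self)


def cartesian_to_spherical(v: np.ndarray) -> SphericalVector:
    """Convert a 3-vector to (r, theta, phi); the zero vector maps to zeros."""
    v = np.asarray(v, dtype=float)
    if v.shape != (3,) or not np.all(np.isfinite(v)):
        raise ValidationError(f"expected a finite 3-vector, got {v!r}")
    r = float(np.linalg.norm(v))
    if r == 0.0:
        return SphericalVector(0.0, 0.0, 0.0)
    theta = float(np.arccos(np.clip(v[2] / r, -1.0, 1.0)))
    phi = float(np.arctan2(v[1], v[0]))
    return SphericalVector(r, theta, phi)


def spherical_to_cartesian(s: SphericalVector) -> np.ndarray:
    return np.array([
        s.r * np.sin(s.theta) * np.cos(s.phi),
        s.r * np.sin(s.theta) * np.sin(s.phi),
        s.r * np.cos(s.theta),
    ])


def _spherical_block(V: np.ndarray) -> np.ndarray:
    """Vectorized (..., 3) cartesian -> (..., 3) [r, theta, phi]."""
    r = np.linalg.norm(V, axis=-1)
    safe = np.where(r > 0, r, 1.0)
    theta = np.arccos(np.clip(V[..., 2] / safe, -1.0, 1.0))
    phi = np.arctan2(V[..., 1], V[..., 0])
    zero = r == 0
    theta = np.where(zero, 0.0, theta)
    phi = np.where(zero, 0.0, phi)
    return np.stack([r, theta, phi], axis=-1)


def mandible_extent(case: LandmarkCase, config: ConfigurationSpec) -> float:
    """Diagonal of the bounding box of the input-set mandibular landmarks (px)."""
    mand = [lm for lm in config.mandibular_inputs if lm in case.positions]
    if len(mand) < 2:
        raise ConfigurationError(
            f"case {case.case_id}: need >=2 mandibular input landmarks for d1")
    pts = np.stack([case.positions[lm] for lm in mand])
    return float(np.linalg.norm(pts.max(axis=0) - pts.min(axis=0)))


def pairwise_features(case: LandmarkCase, config: ConfigurationSpec,
                      a: Landmark, b: Landmark) -> np.ndarray:
    """The 19-component descriptor of the ordered pair (a, b)."""
    if a == b:
        raise ValidationError("pairwise features require two distinct landmarks")
    if a not in config.input_set or b not in config.input_set:
        raise ValidationError(f"{a.symbol}/{b.symbol} must both be input landmarks")
    for lm in (a, b, Landmark.Me):
        if lm not in case.positions:
            raise DataError(f"case {case.case_id} is missing landmark {lm.symbol}")
    pa, pb, me = case.positions[a], case.positions[b], case.positions[Landmark.Me]
    d1 = mandible_extent(case, config)
    sph = lambda v: np.array(tuple(cartesian_to_spherical(v).__dict__.values()))
    sa, sb, sab = sph(pa - me), sph(pb - me), sph(pb - pa)
    return np.concatenate([pa, sa, pb, sb, me, sab, [d1]])


def ordered_pairs(config: ConfigurationSpec) -> Tuple[Tuple[Landmark, Landmark], ...]:
    """All n(n-1) ordered pairs of distinct input landmarks, canonical order."""
    return tuple((a, b) for a in config.input_set for b in config.input_set if a != b)


def feature_batch(case: LandmarkCase, config: ConfigurationSpec
                  ) -> Dict[Tuple[Landmark, Landmark], np.ndarray]:
    """Feature vectors for every ordered pair of distinct input landmarks."""
    for lm in config.input_set:
        if lm not in case.positions:
            raise DataError(f"case {case.case_id} is missing input landmark {lm.symbol}")
    return {pair: pairwise_features(case, config, *pair) for pair in ordered_pairs(config)}


def feature_tensor(positions: np.ndarray, config: ConfigurationSpec,
                   vocab_index: Dict[Landmark, int]) -> np.ndarray:
    """Vectorized feature construction for many cases at once.

    positions: (C, 14, 3) array in vocabulary order.  Returns (C, P, 19) with
    P = n(n-1), pairs in `ordered_pairs` order.  Used by the training loop;
    agrees with `pairwise_features` elementwise (asserted in tests).
    """
    pairs = ordered_pairs(config)
    ia = [vocab_index[a] for a, _ in pairs]
    ib = [vocab_index[b] for _, b in pairs]
    me = positions[:, vocab_index[Landmark.Me], :]                    # (C,3)
    pa = positions[:, ia, :]                                          # (C,P,3)
    pb = positions[:, ib, :]
    me_b = np.broadcast_to(me[:, None, :], pa.shape)
    mand_idx = [vocab_index[lm] for lm in config.mandibular_inputs]
    mand = positions[:, mand_idx, :]
    d1 = np.linalg.norm(mand.max(axis=1) - mand.min(axis=1), axis=-1)  # (C,)
    d1_b = np.broadcast_to(d1[:, None, None], pa.shape[:2] + (1,))
    return np.concatenate([
        pa, _spherical_block(pa - me_b),
        pb, _spherical_block(pb - me_b),
        me_b, _spherical_block(pb - pa),
        d1_b,
    ], axis=-1)


def export_feature_matrix(case: LandmarkCase, config: ConfigurationSpec,
                          path, format: str = "csv") -> None:
    """Write the per-pair feature matrix with a named header (CSV or HDF5)."""
    feats = feature_batch(case, config)
    pair_labels = [f"{a.symbol}->{b.symbol}" for a, b in feats]
    matrix = np.stack(list(feats.values()))
    path = Path(path)
    if format == "csv":
        import pandas as pd
        pd.DataFrame(matrix, index=pair_labels, columns=FEATURE_NAMES) \
            .rename_axis("pair").to_csv(path)
    elif format == "hdf5":
        import h5py
        with h5py.File(path, "w") as fh:
            ds = fh.create_dataset("features", data=matrix)
            ds.attrs["columns"] = ",".join(FEATURE_NAMES)
            ds.attrs["pairs"] = ",".join(pair_labels)
    else:
        raise ValidationError(f"unknown export format {format!r}")
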