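"""21-feature vectors per candidate configuration and the 4x21 sample matrix.

Column order (fixed):
    x1 y1 z1 x2 y2 z2 x3 y3 z3 x4 y4 z4   positions, mm
    E1 E2 E3 E4                            deposits, keV
    theta1_pos theta2_pos                  position-derived polar angles, deg
    theta1_energy theta2_energy            energy-derived polar angles, deg
    delta_phi                              azimuthal difference, deg

Indices (1, 2) are the assumed Compton scatter / photoelectric absorption in
panel 0 (side A), (3, 4) the same in panel 1 (side B).  The LOR vector is
a = r3 - r1 (the two assumed scatter points define the LOR); photon A's
incoming direction is r1 - r3 and photon B's is r3 - r1.  Wherever an
angular feature is physically undefined — the energy-derived angle when the
assumed scatter deposit exceeds the Compton edge, or the azimuthal
projection when a scattering vector is parallel to the LOR — the
placeholder 9999 is stored so the network can recognise unphysical
configurations.
"""

from __future__ import annotations

import numpy as np

from entpet import kinematics

__all__ = [
    "FEATURE_NAMES",
    "FEATURE_GROUPS",
    "PLACEHOLDER",
    "POST_SCALE_SENTINEL",
    "extract_features",
    "assemble_matrix",
    "FeatureScaler",
    "fit_scaler",
    "apply_scaler",
    "select_columns",
    "feature_subsets",
]

FEATURE_NAMES = [
    "x1", "y1", "z1", "x2", "y2", "z2",
    "x3", "y3", "z3", "x4", "y4", "z4",
    "E1", "E2", "E3", "E4",
    "theta1_pos", "theta2_pos", "theta1_energy", "theta2_energy",
    "delta_phi",
]

#: named column-group masks; the four groups partition the 21 columns
FEATURE_GROUPS = {
    "xyz": list(range(0, 12)),
    "E": list(range(12, 16)),
    "theta": list(range(16, 20)),
    "dphi": [20],
}

PLACEHOLDER = 9999.0
POST_SCALE_SENTINEL = 10.0


def extract_features(configs: np.ndarray) -> np.ndarray:
    """Compute 21-feature vectors for candidate configurations.

    ``configs``: (..., 16) arrays [r1 r2 r3 r4 E1 E2 E3 E4] (positions as
    consecutive xyz triples).  Returns (..., 21).  Degenerate LORs
    (r1 == r3) get all five angular features set to the placeholder.
    """
    c = np.asarray(configs, dtype=float)
    r1, r2 = c[..., 0:3], c[..., 3:6]
    r3, r4 = c[..., 6:9], c[..., 9:12]
    E1, E3 = c[..., 12], c[..., 14]

    lor = r3 - r1                      # LOR vector a
    b_a = r2 - r1                      # scattering vector, side A
    b_b = r4 - r3                      # scattering vector, side B
    # degenerate geometry (possible after 1 mm binning): zero-length LOR or
    # scattering vector -> the affected angular features get the placeholder
    bad_lor = np.linalg.norm(lor, axis=-1) == 0.0
    bad_a = np.linalg.norm(b_a, axis=-1) == 0.0
    bad_b = np.linalg.norm(b_b, axis=-1) == 0.0

    unit_x = np.array([1.0, 0.0, 0.0])
    safe_lor = np.where(bad_lor[..., None], unit_x, lor)
    safe_ba = np.where(bad_a[..., None], unit_x, b_a)
    safe_bb = np.where(bad_b[..., None], unit_x, b_b)
    theta1_pos = kinematics.theta_from_positions(-safe_lor, safe_ba)  # incoming r1-r3
    theta2_pos = kinematics.theta_from_positions(safe_lor, safe_bb)   # incoming r3-r1
    dphi = kinematics.delta_phi(safe_lor, safe_ba, safe_bb)
    degenerate = bad_lor
    theta1_pos = np.where(bad_a, np.nan, theta1_pos)
    theta2_pos = np.where(bad_b, np.nan, theta2_pos)
    dphi = np.where(bad_a | bad_b, np.nan, dphi)

    with np.errstate(invalid="ignore", divide="ignore"):
        theta1_e = kinematics.theta_from_energies(
            np.maximum(kinematics.ANNIHILATION_ENERGY_KEV - E1, 1e-9),
            kinematics.ANNIHILATION_ENERGY_KEV)
        theta2_e = kinematics.theta_from_energies(
            np.maximum(kinematics.ANNIHILATION_ENERGY_KEV - E3, 1e-9),
            kinematics.ANNIHILATION_ENERGY_KEV)

    def ph(x, extra_bad=False):
        bad = ~np.isfinite(x) | degenerate | extra_bad
        return np.where(bad, PLACEHOLDER, x)

    ang = np.stack([
        ph(theta1_pos), ph(theta2_pos), ph(theta1_e), ph(theta2_e), ph(dphi),
    ], axis=-1)
    return np.concatenate([c[..., 0:12], c[..., 12:16], ang], axis=-1)


def assemble_matrix(samples) -> tuple[np.ndarray, np.ndarray]:
    """Feature matrices for a :class:`~entpet.pipeline.SampleSet`.

    Returns ``(X, y)`` with X of shape (n, 4, 21) in post-shuffle row order
    and y the 5-class labels.
    """
    X = extract_features(samples.configs)
    return X, samples.labels.copy()


class FeatureScaler:
    """Per-column standardisation that is placeholder-aware.

    Mean and std are computed over non-placeholder entries of the training
    rows only; placeholder cells map to the fixed post-scale sentinel
    ``+10.0``.  Zero-variance columns pass through unscaled.
    """

    def __init__(self, mean: np.ndarray, std: np.ndarray):
        self.mean = mean
        self.std = std

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        is_ph = X == PLACEHOLDER
        out = (X - self.mean) / self.std
        out[is_ph] = POST_SCALE_SENTINEL
        return out


def fit_scaler(X: np.ndarray) -> FeatureScaler:
    """Fit a scaler on training matrices of shape (n, 4, d) or (rows, d)."""
    X = np.asarray(X, dtype=float)
    if X.size == 0:
        raise ValueError("cannot fit scaler on an empty training set")
    rows = X.reshape(-1, X.shape[-1])
    masked = np.ma.masked_where(rows == PLACEHOLDER, rows)
    mean = np.asarray(masked.mean(axis=0).filled(0.0))
    std = np.asarray(masked.std(axis=0).filled(1.0))
    std = np.where(std == 0.0, 1.0, std)
    # columns that are entirely placeholder or constant: identity transform
    const = np.asarray(masked.std(axis=0).filled(0.0)) == 0.0
    mean[const] = 0.0
    std[const] = 1.0
    return FeatureScaler(mean=mean, std=std)


def apply_scaler(X: np.ndarray, scaler: FeatureScaler) -> np.ndarray:
    return scaler.transform(X)


def select_columns(X: np.ndarray, groups) -> np.ndarray:
    """Restrict feature matrices to the union of named column groups,
    preserving the fixed column order."""
    groups = set(groups)
    if not groups:
        raise ValueError("at least one feature group is required")
    unknown = groups - set(FEATURE_GROUPS)
    if unknown:
        raise ValueError(f"unknown feature groups: {sorted(unknown)}")
    cols = sorted(c for g in groups for c in FEATURE_GROUPS[g])
    return np.asarray(X)[..., cols]


def feature_subsets() -> list[tuple[str, ...]]:
    """The 15 non-empty subsets of {dphi, theta, xyz, E} of the ablation
    design, in a deterministic order (singletons first, then pairs, ...)."""
    from itertools import combinations

    names = ["dphi", "theta", "xyz", "E"]
    out: list[tuple[str, ...]] = []
    for k in range(1, 5):
        out.extend(combinations(names, k))
    return out
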