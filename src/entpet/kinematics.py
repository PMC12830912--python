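"""Compton and entangled double-Compton kinematics.

Closed-form energies, angles and probability densities for 511 keV
annihilation photons and the 1157 keV prompt gamma, shared by the detector
simulator and the feature extractor.

Conventions
-----------
* All angles cross the API boundary in **degrees**; radians are internal.
* Polar scattering angles ``theta`` live in [0, 180]; the azimuthal
  difference ``delta_phi`` is reported as the unsigned angle between the two
  scattering planes, in [0, 180].
* ``theta_from_energies`` returns :data:`UNDEFINED` (NaN) when the Compton
  formula has no solution — i.e. when the assumed scatter deposit exceeds
  the Compton edge.  Callers map this to the 9999 feature placeholder.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ELECTRON_REST_ENERGY_KEV",
    "ANNIHILATION_ENERGY_KEV",
    "PROMPT_ENERGY_KEV",
    "UNDEFINED",
    "ScatterAngles",
    "compton_scattered_energy",
    "compton_edge",
    "theta_from_energies",
    "theta_from_positions",
    "delta_phi",
    "klein_nishina_pdf",
    "sample_klein_nishina_theta",
    "entangled_pair_pdf",
    "sample_entangled_pair",
]

ELECTRON_REST_ENERGY_KEV = 511.0
ANNIHILATION_ENERGY_KEV = 511.0
PROMPT_ENERGY_KEV = 1157.0

#: Distinguished "no physical solution" value; NaN so that it propagates
#: through vectorised arithmetic and is easy to mask.
UNDEFINED = float("nan")

# cosine clamp: |cos| may exceed 1 by float noise up to this tolerance and
# still be treated as a valid angle; beyond it the angle is undefined.
_COS_TOL = 1e-12
# relative projection-norm threshold below which delta_phi is degenerate
_PROJ_EPS = 1e-9


@dataclass(frozen=True)
class ScatterAngles:
    """Polar and azimuthal scattering angles of an annihilation pair.

    ``theta1``/``theta2`` in [0, 180] degrees; ``phi1``/``phi2`` in
    (-180, 180] degrees, measured about the LOR axis in a common
    transverse basis.
    """

    theta1: float
    phi1: float
    theta2: float
    phi2: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.theta1 <= 180.0 and 0.0 <= self.theta2 <= 180.0):
            raise ValueError("polar angles must lie in [0, 180] degrees")
        for phi in (self.phi1, self.phi2):
            if not (-180.0 < phi <= 180.0):
                raise ValueError("azimuthal angles must lie in (-180, 180]")

    @property
    def delta_phi(self) -> float:
        """Unsigned plane-to-plane azimuthal difference, folded to [0, 180]."""
        d = abs(self.phi1 - self.phi2) % 360.0
        return 360.0 - d if d > 180.0 else d


def _as_array(x):
    return np.asarray(x, dtype=float)


def compton_scattered_energy(E_i, theta):
    """Scattered-photon energy after a Compton scatter.

    E_s = E_i / (1 + (E_i / m_e c^2)(1 - cos theta)), with ``E_i`` in keV and
    ``theta`` the polar scattering angle in degrees.
    """
    E_i = _as_array(E_i)
    theta = _as_array(theta)
    if np.any(E_i <= 0):
        raise ValueError("incident energy must be positive")
    if np.any((theta < 0) | (theta > 180)):
        raise ValueError("theta must lie in [0, 180] degrees")
    out = E_i / (1.0 + (E_i / ELECTRON_REST_ENERGY_KEV) * (1.0 - np.cos(np.radians(theta))))
    return float(out) if out.ndim == 0 else out


def compton_edge(E_i):
    """Maximum energy a single Compton scatter can deposit (backscatter)."""
    E_i = _as_array(E_i)
    out = E_i - compton_scattered_energy(E_i, 180.0)
    return float(out) if np.ndim(out) == 0 else out


def theta_from_energies(E_s, E_i):
    """Energy-derived polar scattering angle (degrees), or UNDEFINED.

    theta_E = arccos(1 - m_e c^2 (1/E_s - 1/E_i)).  Returns NaN where the
    arccos argument leaves [-1, 1] beyond float tolerance — physically, when
    the assumed scatter deposit exceeds the Compton edge.
    """
    E_s = _as_array(E_s)
    E_i = _as_array(E_i)
    if np.any(E_s <= 0) or np.any(E_i <= 0):
        raise ValueError("energies must be positive")
    arg = 1.0 - ELECTRON_REST_ENERGY_KEV * (1.0 / E_s - 1.0 / E_i)
    valid = np.abs(arg) <= 1.0 + _COS_TOL
    out = np.where(valid, np.degrees(np.arccos(np.clip(arg, -1.0, 1.0))), UNDEFINED)
    return float(out) if out.ndim == 0 else out


def _norm(v, axis=-1):
    return np.sqrt(np.sum(np.square(v), axis=axis))


def theta_from_positions(a, b):
    """Angle (degrees) between vectors ``a`` and ``b``; cosine clamped."""
    a = _as_array(a)
    b = _as_array(b)
    na = _norm(a)
    nb = _norm(b)
    if np.any(na == 0) or np.any(nb == 0):
        raise ValueError("zero-length vector")
    cos = np.sum(a * b, axis=-1) / (na * nb)
    out = np.degrees(np.arccos(np.clip(cos, -1.0, 1.0)))
    return float(out) if np.ndim(out) == 0 else out


def delta_phi(lor, b1, b2):
    """Azimuthal difference of two scattering vectors about the LOR.

    Both vectors are projected onto the plane orthogonal to ``lor``; the
    unsigned angle between the projections is returned in [0, 180] degrees.
    Returns UNDEFINED (NaN) where a projection is degenerate (scattering
    vector parallel to the LOR within relative tolerance).
    """
    lor = _as_array(lor)
    b1 = _as_array(b1)
    b2 = _as_array(b2)
    nl = _norm(lor)
    if np.any(nl == 0):
        raise ValueError("zero-length LOR vector")
    n = lor / nl[..., None] if lor.ndim > 1 else lor / nl
    p1 = b1 - np.sum(b1 * n, axis=-1)[..., None] * n
    p2 = b2 - np.sum(b2 * n, axis=-1)[..., None] * n
    n1, n2 = _norm(p1), _norm(p2)
    ok = (n1 > _PROJ_EPS * _norm(b1)) & (n2 > _PROJ_EPS * _norm(b2))
    with np.errstate(invalid="ignore", divide="ignore"):
        cos = np.sum(p1 * p2, axis=-1) / (n1 * n2)
        out = np.where(ok, np.degrees(np.arccos(np.clip(cos, -1.0, 1.0))), UNDEFINED)
    return float(out) if np.ndim(out) == 0 else out


# ---------------------------------------------------------------------------
# Klein–Nishina (unpolarized) polar-angle density
# ---------------------------------------------------------------------------

def _kn_unnormalized(theta_rad, E_i):
    """k^2 (k + 1/k - sin^2 theta) sin theta with k = E_s/E_i."""
    k = 1.0 / (1.0 + (E_i / ELECTRON_REST_ENERGY_KEV) * (1.0 - np.cos(theta_rad)))
    return k * k * (k + 1.0 / k - np.sin(theta_rad) ** 2) * np.sin(theta_rad)


def _kn_norm(E_i, n=4001):
    grid = np.linspace(0.0, math.pi, n)
    return np.trapezoid(_kn_unnormalized(grid, E_i), grid)


def klein_nishina_pdf(theta, E_i):
    """Normalized polar-angle pdf (per degree) of an unpolarized Compton
    scatter of a photon with energy ``E_i`` keV; integral over [0,180] is 1."""
    if np.any(_as_array(E_i) <= 0):
        raise ValueError("incident energy must be positive")
    theta = _as_array(theta)
    if np.any((theta < 0) | (theta > 180)):
        raise ValueError("theta must lie in [0, 180] degrees")
    val = _kn_unnormalized(np.radians(theta), E_i) / _kn_norm(E_i)
    out = val * (math.pi / 180.0)  # per-degree density
    return float(out) if np.ndim(out) == 0 else out


def sample_klein_nishina_theta(E_i, size, rng):
    """Draw polar scattering angles (degrees) from the Klein–Nishina pdf.

    Vectorised rejection sampling with a uniform-in-theta proposal.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    grid = np.radians(np.linspace(0.0, 180.0, 1801))
    fmax = float(np.max(_kn_unnormalized(grid, E_i))) * 1.0001
    out = np.empty(size)
    filled = 0
    while filled < size:
        m = max(int((size - filled) * 2.5), 1000)
        t = rng.uniform(0.0, math.pi, m)
        u = rng.uniform(0.0, fmax, m)
        acc = t[u < _kn_unnormalized(t, E_i)]
        take = min(acc.size, size - filled)
        out[filled:filled + take] = acc[:take]
        filled += take
    return np.degrees(out)


# ---------------------------------------------------------------------------
# Entangled double-Compton joint density (511/511 keV pair)
# ---------------------------------------------------------------------------

def _gamma_k(theta_rad):
    """k = 1/(2 - cos theta) (511 keV) and gamma = k + 1/k."""
    k = 1.0 / (2.0 - np.cos(theta_rad))
    return k, k + 1.0 / k


def _entangled_bracket(t1, t2, dphi):
    """Angular bracket of the entangled pair density (radians in)."""
    k1, g1 = _gamma_k(t1)
    k2, g2 = _gamma_k(t2)
    s1, s2 = np.sin(t1) ** 2, np.sin(t2) ** 2
    brk = g1 * g2 - g1 * s2 - g2 * s1 + 2.0 * s1 * s2 * np.sin(dphi) ** 2
    return k1 ** 2 * k2 ** 2 * brk


def entangled_pair_pdf(theta1, theta2, dphi):
    """Unnormalized joint density of (theta1, theta2, dphi) for an entangled
    annihilation pair in which both photons Compton-scatter.

    With k_i = 1/(2 - cos theta_i) and gamma_i = k_i + 1/k_i the density is
    proportional to::

        k1^2 k2^2 [g1 g2 - g1 sin^2 t2 - g2 sin^2 t1
                   + 2 sin^2 t1 sin^2 t2 sin^2 dphi] sin t1 sin t2

    For fixed polar angles the dphi dependence is c0 + c1 sin^2(dphi) with
    c1 >= 0, peaking at |dphi| = 90 degrees.  Angles in degrees.
    """
    t1 = np.radians(_as_array(theta1))
    t2 = np.radians(_as_array(theta2))
    dp = np.radians(_as_array(dphi))
    if np.any((t1 < 0) | (t1 > math.pi)) or np.any((t2 < 0) | (t2 > math.pi)):
        raise ValueError("theta must lie in [0, 180] degrees")
    out = _entangled_bracket(t1, t2, dp) * np.sin(t1) * np.sin(t2)
    return float(out) if np.ndim(out) == 0 else out


def entangled_modulation_ratio(theta):
    """density(dphi=90)/density(dphi=0) along the diagonal theta1=theta2."""
    t = np.radians(_as_array(theta))
    num = _entangled_bracket(t, t, np.full_like(t, math.pi / 2.0))
    den = _entangled_bracket(t, t, np.zeros_like(t))
    out = num / den
    return float(out) if np.ndim(out) == 0 else out


def peak_modulation_theta(resolution_deg=0.01):
    """Polar angle (deg) maximizing the dphi=90 vs dphi=0 modulation ratio."""
    grid = np.arange(resolution_deg, 180.0, resolution_deg)
    return float(grid[np.argmax(entangled_modulation_ratio(grid))])


def sample_entangled_pair(size, rng, mode="entangled"):
    """Sample scattering angles for ``size`` annihilation pairs.

    Returns arrays ``(theta1, phi1, theta2, phi2)`` in degrees.  The
    dphi-averaged theta-marginal of the entangled density factorizes exactly
    into two independent 511 keV Klein–Nishina marginals (algebraic identity
    ``(g1 - s1)(g2 - s2) = g1 g2 - g1 s2 - g2 s1 + s1 s2``), so theta1 and
    theta2 are drawn independently from Klein–Nishina and dphi from the exact
    conditional ``c0 + c1 sin^2`` by rejection.  ``mode="independent"`` keeps
    the same marginals but draws both azimuths independently and uniformly
    (non-entangled control).
    """
    if mode not in ("entangled", "independent"):
        raise ValueError("mode must be 'entangled' or 'independent'")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    theta1 = sample_klein_nishina_theta(ANNIHILATION_ENERGY_KEV, size, rng)
    theta2 = sample_klein_nishina_theta(ANNIHILATION_ENERGY_KEV, size, rng)
    phi1 = rng.uniform(-180.0, 180.0, size)
    if mode == "independent":
        phi2 = rng.uniform(-180.0, 180.0, size)
        return theta1, phi1, theta2, phi2

    dphi = sample_dphi_given_thetas(theta1, theta2, rng)
    phi2 = phi1 - dphi
    phi2 = (phi2 + 180.0) % 360.0 - 180.0
    # fold the half-open interval edge: exactly -180 maps to +180
    phi2 = np.where(phi2 == -180.0, 180.0, phi2)
    return theta1, phi1, theta2, phi2


def sample_dphi_given_thetas(theta1, theta2, rng):
    """Draw the azimuthal difference (degrees, in [0, 360)) from the exact
    entangled conditional density c0 + c1 sin^2(dphi) at the given polar
    angles, by rejection under the exact bound c0 + c1."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    t1 = np.radians(np.asarray(theta1, dtype=float))
    t2 = np.radians(np.asarray(theta2, dtype=float))
    _, g1 = _gamma_k(t1)
    _, g2 = _gamma_k(t2)
    s1, s2 = np.sin(t1) ** 2, np.sin(t2) ** 2
    c0 = g1 * g2 - g1 * s2 - g2 * s1
    c1 = 2.0 * s1 * s2
    if np.any(c0 < -1e-12):
        raise AssertionError("entangled conditional density went negative")
    size = t1.size
    dphi = np.empty(size)
    todo = np.arange(size)
    while todo.size:
        d = rng.uniform(0.0, 2.0 * math.pi, todo.size)
        u = rng.uniform(0.0, 1.0, todo.size) * (c0[todo] + c1[todo])
        acc = u < c0[todo] + c1[todo] * np.sin(d) ** 2
        dphi[todo[acc]] = d[acc]
        todo = todo[~acc]
    return np.degrees(dphi)
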