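"""Desk-scale Monte Carlo detector simulation.

Generates ground-truth hit records for a simplified Sc-44 point source
(every decay emits a back-to-back 511 keV annihilation pair plus an
isotropic 1157 keV prompt gamma) in the dual-panel CZT geometry.  Photon
transport is deliberately simple: an exponential first-interaction depth
with an energy-dependent attenuation length, a Compton-vs-photoelectric
branch with an energy-dependent Compton fraction, and at most two
interactions per photon (topologies P, C->P, C->C with escape, C->escape).
A second Compton deposit followed by escape is what lets a 1157 keV prompt
leave a *partial* two-site deposit summing into the 511 keV window — the
contamination mechanism the classifier must reject.

Annihilation pairs in ``entangled`` mode draw their scattering angles from
the entangled double-Compton joint density; ``independent`` mode is the
non-entangled control with identical marginals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from entpet import kinematics
from entpet.geometry import DetectorGeometry

__all__ = [
    "SourceConfig",
    "EnergyModel",
    "InteractionModel",
    "PhotonHistory",
    "generate_decays",
    "sample_photon_history",
    "blur_energy",
    "HIT_COLUMNS",
]

HIT_COLUMNS = [
    "event_id", "photon_id", "interaction_index",
    "x_mm", "y_mm", "z_mm", "deposit_keV", "process", "panel",
]

PHOTON_IDS = ("prompt", "annih_A", "annih_B")


@dataclass(frozen=True)
class SourceConfig:
    """Simplified Sc-44 point source at the FOV center."""

    position: tuple[float, float, float] = (0.0, 0.0, 0.0)
    radius_mm: float = 0.1
    activity_uci: float = 30.0
    half_life_s: float = 14290.0
    scan_duration_s: float = 60.0
    prompt_energy_kev: float = kinematics.PROMPT_ENERGY_KEV
    pair_energy_kev: float = kinematics.ANNIHILATION_ENERGY_KEV

    def __post_init__(self) -> None:
        for name in ("radius_mm", "activity_uci", "half_life_s",
                     "scan_duration_s", "prompt_energy_kev", "pair_energy_kev"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class EnergyModel:
    """Gaussian energy blurring.

    Default scaling: fractional FWHM ~ 1/sqrt(E), anchored at 5.85% FWHM at
    511 keV, i.e. FWHM(E) = 0.0585 * sqrt(511 * E) keV — the usual
    statistics-driven semiconductor behaviour.  ``mode="constant"`` keeps
    the fractional FWHM fixed instead.
    """

    reference_resolution: float = 0.0585  # fractional FWHM at reference
    reference_energy_kev: float = 511.0
    mode: str = "inverse_sqrt"

    def fwhm(self, energy_kev):
        e = np.asarray(energy_kev, dtype=float)
        if self.mode == "constant":
            return self.reference_resolution * e
        return self.reference_resolution * np.sqrt(self.reference_energy_kev * e)


_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


def blur_energy(E_true, model: EnergyModel, rng):
    """Gaussian-blur true deposits; mean-preserving; resolution 0 => identity."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    e = np.asarray(E_true, dtype=float)
    if np.any(e <= 0):
        raise ValueError("true energy must be positive")
    if model.reference_resolution == 0:
        return float(e) if e.ndim == 0 else e.copy()
    sigma = model.fwhm(e) * _FWHM_TO_SIGMA
    out = e + rng.standard_normal(e.shape if e.ndim else ()) * sigma
    return float(out) if np.ndim(out) == 0 else out


# CZT-like attenuation length (mm) and Compton branch fraction vs energy.
# Anchored at lambda(511) = 20 mm, f_C(511) = 0.80, with the
# photoelectric/Compton crossover near 260 keV as in real CdZnTe; only the
# *relative* topology frequencies matter downstream.
_TABLE_E = np.array([50.0, 100.0, 170.0, 250.0, 340.0, 511.0, 750.0, 1157.0])
_TABLE_LAMBDA = np.array([0.8, 2.2, 5.0, 9.0, 13.0, 20.0, 27.0, 36.0])
_TABLE_FC = np.array([0.02, 0.12, 0.30, 0.48, 0.62, 0.80, 0.88, 0.93])


@dataclass(frozen=True)
class InteractionModel:
    """Energy-interpolated attenuation length and Compton fraction.

    ``compton_prob_override`` pins the Compton branch probability to a fixed
    value (degenerate/testing modes); ``force_absorption`` guarantees that a
    scattered photon is photoelectrically absorbed inside its panel by
    sampling the second depth from the chord-truncated exponential.
    """

    energies_kev: np.ndarray = field(default_factory=lambda: _TABLE_E.copy())
    att_length_mm: np.ndarray = field(default_factory=lambda: _TABLE_LAMBDA.copy())
    compton_fraction: np.ndarray = field(default_factory=lambda: _TABLE_FC.copy())
    compton_prob_override: float | None = None
    force_absorption: bool = False
    att_scale: float = 1.0  # multiplies all attenuation lengths

    def att_length(self, energy_kev):
        e = np.asarray(energy_kev, dtype=float)
        out = np.exp(np.interp(np.log(e), np.log(self.energies_kev),
                               np.log(self.att_length_mm)))
        return self.att_scale * out

    def f_compton(self, energy_kev):
        if self.compton_prob_override is not None:
            return np.full(np.shape(energy_kev) or (), self.compton_prob_override)
        return np.interp(np.asarray(energy_kev, dtype=float),
                         self.energies_kev, self.compton_fraction)


@dataclass
class PhotonHistory:
    """Ground-truth interaction history of one photon (at most two hits)."""

    positions: np.ndarray      # (n_int, 3) mm
    deposits: np.ndarray       # (n_int,) keV, pre-blur
    processes: list[str]       # 'compton' / 'photoelectric'
    panel: int                 # -1 if never detected
    escape_kev: float          # energy leaving the detector


# ---------------------------------------------------------------------------
# direction helpers
# ---------------------------------------------------------------------------

def _isotropic_dirs(rng, n):
    """Uniform directions on the unit sphere."""
    z = rng.uniform(-1.0, 1.0, n)
    phi = rng.uniform(0.0, 2.0 * math.pi, n)
    s = np.sqrt(1.0 - z * z)
    out = np.empty((n, 3))
    out[:, 0] = s * np.cos(phi)
    out[:, 1] = s * np.sin(phi)
    out[:, 2] = z
    return out


def _cross(a, b):
    out = np.empty(np.broadcast_shapes(a.shape, b.shape))
    out[:, 0] = a[:, 1] * b[:, 2] - a[:, 2] * b[:, 1]
    out[:, 1] = a[:, 2] * b[:, 0] - a[:, 0] * b[:, 2]
    out[:, 2] = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
    return out


def _transverse_basis(d):
    """Deterministic orthonormal (e1, e2) perpendicular to unit rows of d."""
    d = np.atleast_2d(d)
    helper = np.where(np.abs(d[:, 2:3]) < 0.9,
                      np.array([[0.0, 0.0, 1.0]]),
                      np.array([[1.0, 0.0, 0.0]]))
    e1 = _cross(helper, d)
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = _cross(d, e1)
    return e1, e2


def _deflect(ref_dir, theta_deg, phi_deg, sign=1.0):
    """Direction at polar ``theta`` / azimuth ``phi`` about ``sign*ref_dir``,
    with azimuth measured in the transverse basis of ``ref_dir`` itself."""
    e1, e2 = _transverse_basis(ref_dir)
    t = np.radians(np.asarray(theta_deg, dtype=float))[:, None]
    p = np.radians(np.asarray(phi_deg, dtype=float))[:, None]
    return (np.sin(t) * (np.cos(p) * e1 + np.sin(p) * e2)
            + sign * np.cos(t) * np.atleast_2d(ref_dir))


# ---------------------------------------------------------------------------
# vectorised transport
# ---------------------------------------------------------------------------

def _transport(origins, dirs, E0, panels, geometry, model, rng,
               theta1=None, phi1=None, ref_dirs=None, ref_sign=1.0):
    """Transport photons through their panel; at most two interactions.

    Pre-drawn first-scatter angles (``theta1``/``phi1`` about ``ref_dirs``
    with ``ref_sign``) may be supplied for entangled pairs; otherwise the
    polar angle is drawn from Klein-Nishina at ``E0`` and the azimuth
    uniformly about the photon's own direction.  Returns a dict of arrays.
    """
    n = origins.shape[0]
    E0 = np.broadcast_to(np.asarray(E0, dtype=float), (n,))
    out = {
        "n_int": np.zeros(n, dtype=np.int8),
        "pos1": np.full((n, 3), np.nan),
        "pos2": np.full((n, 3), np.nan),
        "dep1": np.full(n, np.nan),
        "dep2": np.full(n, np.nan),
        "isC1": np.zeros(n, dtype=bool),
        "isC2": np.zeros(n, dtype=bool),
        "escape": E0.copy(),
        "panel": np.asarray(panels, dtype=np.int8).copy(),
    }

    t_entry = np.full(n, np.nan)
    chord = np.full(n, np.nan)
    for p in (0, 1):
        m = out["panel"] == p
        if np.any(m):
            te, ch, hit = geometry.ray_panel_intersection(origins[m], dirs[m], p)
            t_entry[m] = np.where(hit, te, np.nan)
            chord[m] = np.where(hit, ch, np.nan)

    lam0 = model.att_length(E0)
    t1 = rng.exponential(1.0, n) * lam0
    u_type1 = rng.random(n)
    det1 = np.isfinite(chord) & (t1 < chord)

    p1 = origins + (t_entry + t1)[:, None] * dirs
    isC1 = det1 & (u_type1 < model.f_compton(E0))
    out["pos1"][det1] = p1[det1]
    out["n_int"][det1] = 1
    out["isC1"] = isC1

    # photoelectric first interaction: full deposit
    pe1 = det1 & ~isC1
    out["dep1"][pe1] = E0[pe1]
    out["escape"][pe1] = 0.0

    # first-scatter angles (drawn for the full batch to keep the RNG stream
    # independent of which photons were detected)
    if theta1 is None:
        theta1 = kinematics.sample_klein_nishina_theta(float(E0[0]), n, rng) \
            if np.all(E0 == E0[0]) else _kn_per_energy(E0, rng)
        phi1 = rng.uniform(-180.0, 180.0, n)
        ref_dirs, ref_sign = dirs, 1.0
    E_s = kinematics.compton_scattered_energy(E0, theta1)
    d2 = _deflect(ref_dirs, theta1, phi1, sign=ref_sign)

    out["dep1"][isC1] = (E0 - E_s)[isC1]
    out["escape"][isC1] = E_s[isC1]

    # second leg
    chord2 = np.full(n, np.nan)
    for p in (0, 1):
        m = isC1 & (out["panel"] == p)
        if np.any(m):
            chord2[m] = geometry.chord_to_exit(p1[m], d2[m], p)
    lam2 = model.att_length(E_s)
    x2 = rng.exponential(1.0, n)
    if model.force_absorption:
        # chord-truncated exponential: interaction guaranteed inside
        with np.errstate(invalid="ignore", over="ignore"):
            cdf_max = -np.expm1(-np.where(np.isfinite(chord2), chord2, 0.0) / lam2)
            t2 = -lam2 * np.log1p(-np.clip(1.0 - np.exp(-x2), 0.0, 1.0 - 1e-12) * cdf_max)
        det2 = isC1 & np.isfinite(chord2)
    else:
        t2 = x2 * lam2
        det2 = isC1 & np.isfinite(chord2) & (t2 < chord2)
    u_type2 = rng.random(n)
    if model.force_absorption:
        isC2 = np.zeros(n, dtype=bool)
    else:
        isC2 = det2 & (u_type2 < model.f_compton(np.maximum(E_s, 1e-6)))
    p2 = p1 + t2[:, None] * d2
    out["pos2"][det2] = p2[det2]
    out["n_int"][det2] = 2
    out["isC2"] = isC2

    pe2 = det2 & ~isC2
    out["dep2"][pe2] = E_s[pe2]
    out["escape"][pe2] = 0.0

    if np.any(isC2):
        theta2p = _kn_per_energy(E_s[isC2], rng)
        E_s2 = kinematics.compton_scattered_energy(E_s[isC2], theta2p)
        out["dep2"][isC2] = E_s[isC2] - E_s2
        out["escape"][isC2] = E_s2

    return out


_KN_FMAX_E = np.geomspace(1.0, 2000.0, 256)
_KN_FMAX = None


def _kn_fmax(E):
    """Interpolated per-energy maximum of the unnormalized KN density."""
    global _KN_FMAX
    if _KN_FMAX is None:
        grid = np.radians(np.linspace(0.0, 180.0, 721))
        _KN_FMAX = np.max(
            kinematics._kn_unnormalized(grid[None, :], _KN_FMAX_E[:, None]), axis=1)
    # 2% headroom covers interpolation error on the log-spaced energy grid
    return 1.02 * np.interp(E, _KN_FMAX_E, _KN_FMAX)


def _kn_per_energy(E, rng):
    """Klein-Nishina polar angles (deg) for per-photon energies, by
    rejection with a uniform-in-theta proposal under a tabulated envelope."""
    E = np.asarray(E, dtype=float)
    n = E.size
    out = np.empty(n)
    todo = np.arange(n)
    fmax = _kn_fmax(E)
    while todo.size:
        t = rng.uniform(0.0, math.pi, todo.size)
        u = rng.uniform(0.0, 1.0, todo.size) * fmax[todo]
        acc = u < kinematics._kn_unnormalized(t, E[todo])
        out[todo[acc]] = t[acc]
        todo = todo[~acc]
    return np.degrees(out)


# ---------------------------------------------------------------------------
# decay generation
# ---------------------------------------------------------------------------

def _central_panel_hit(geometry, d):
    """Panel index hit by rays from the exact FOV center, else -1.

    From the origin, |x(t)| and |y(t)| grow monotonically along the ray, so
    a ray enters a panel box iff it is inside the x/y aperture when it
    crosses the panel's front face: |d_xy| * z_front <= half_extent * |d_z|.
    """
    z_front = geometry.panel_separation / 2.0
    adz = np.abs(d[:, 2])
    ok = ((np.abs(d[:, 0]) * z_front <= geometry.half_x * adz)
          & (np.abs(d[:, 1]) * z_front <= geometry.half_y * adz)
          & (adz > 0))
    return np.where(ok, (d[:, 2] > 0).astype(np.int8), np.int8(-1))


def _sample_accepted_lors(geometry, rng, n):
    """LOR directions (oriented toward panel 1) whose back-to-back rays hit
    both panels; returns (dirs, effective_isotropic_trials).

    Proposals are drawn uniformly in the spherical cap that bounds the
    panel's acceptance cone; the returned trial count is rescaled by the
    cap's solid-angle fraction so that n / trials estimates the acceptance
    of fully isotropic emission, exactly as with plain rejection.
    """
    z_front = geometry.panel_separation / 2.0
    z_min = z_front / math.sqrt(z_front ** 2 + geometry.half_x ** 2
                                + geometry.half_y ** 2)
    cap_frac = 1.0 - z_min  # cap area fraction of the oriented hemisphere
    dirs = np.empty((n, 3))
    filled, cap_trials = 0, 0
    while filled < n:
        m = max(int((n - filled) * 2), 4096)
        z = rng.uniform(z_min, 1.0, m)
        phi = rng.uniform(0.0, 2.0 * math.pi, m)
        s = np.sqrt(1.0 - z * z)
        d = np.empty((m, 3))
        d[:, 0] = s * np.cos(phi)
        d[:, 1] = s * np.sin(phi)
        d[:, 2] = z
        idx = np.flatnonzero(_central_panel_hit(geometry, d) == 1)
        take = min(idx.size, n - filled)
        dirs[filled:filled + take] = d[idx[:take]]
        # count only proposals consumed up to the last accepted one
        cap_trials += m if take == idx.size else int(idx[take - 1]) + 1
        filled += take
    return dirs, cap_trials / cap_frac


def _sample_prompt_dirs(geometry, rng, n, condition):
    """Prompt-gamma directions; optionally conditioned on hitting a panel."""
    if not condition:
        d = _isotropic_dirs(rng, n)
        return d, _central_panel_hit(geometry, d), n
    dirs = np.empty((n, 3))
    panel = np.empty(n, dtype=np.int8)
    filled, trials = 0, 0
    while filled < n:
        m = max(int((n - filled) * 5), 4096)
        d = _isotropic_dirs(rng, m)
        p = _central_panel_hit(geometry, d)
        idx = np.flatnonzero(p >= 0)
        take = min(idx.size, n - filled)
        dirs[filled:filled + take] = d[idx[:take]]
        panel[filled:filled + take] = p[idx[:take]]
        trials += m if take == idx.size else int(idx[take - 1]) + 1
        filled += take
    return dirs, panel, trials


def _complete_mask(res, sum_range):
    """Exactly-two-interaction photons, optionally with the true deposit sum
    inside a widened pre-blur window (a lossless prefilter: blurring cannot
    carry a sum from outside the widened range into the final window)."""
    m = res["n_int"] == 2
    if sum_range is not None:
        s = res["dep1"] + res["dep2"]
        with np.errstate(invalid="ignore"):
            m = m & (s >= sum_range[0]) & (s <= sum_range[1])
    return m


def generate_decays(geometry: DetectorGeometry, source: SourceConfig, n_decays: int,
                    mode: str = "entangled", rng_seed=0,
                    interaction_model: InteractionModel | None = None,
                    condition_prompt: bool = True,
                    only_complete_groups: bool = False,
                    true_sum_range: tuple[float, float] | None = None,
                    _return_truth: bool = False):
    """Generate ground-truth hits for ``n_decays`` decays.

    Each decay emits a back-to-back 511 keV pair along an isotropic LOR
    accepted when both rays intersect opposite panels (acceptance fraction
    logged) and a 1157 keV prompt gamma.  Returns ``(hits, info)`` where
    ``hits`` is a DataFrame with :data:`HIT_COLUMNS` and ``info`` records
    seeds, acceptance fractions and topology counts.

    ``only_complete_groups`` drops, at generation time, decays in which any
    of the three photons fails to leave exactly two interactions, and stages
    the transport (pair first, prompt only for surviving decays) — a pure
    performance device for large runs; the pipeline's stage-3 filter applies
    the same rule and is the normative implementation.  ``true_sum_range``
    additionally requires each photon's *true* deposit sum to fall in the
    given (widened) pre-blur window; used with a >=6-sigma margin this
    cannot change the post-blur windowed dataset.
    """
    if n_decays < 1:
        raise ValueError("n_decays must be >= 1")
    if mode not in ("entangled", "independent"):
        raise ValueError("mode must be 'entangled' or 'independent'")
    geometry.panel_bounds(0)  # raises on invalid configuration
    model = interaction_model or InteractionModel()
    rng = np.random.default_rng(rng_seed)
    n = int(n_decays)
    staged = only_complete_groups
    sum_range = true_sum_range if only_complete_groups else None

    lor_dirs, lor_trials = _sample_accepted_lors(geometry, rng, n)
    event_ids = np.arange(n, dtype=np.int64)
    if staged:
        # lazy staging: transport photon A for every decay, then draw the
        # partner's angles / the prompt direction only for survivors; the
        # joint entangled density factorizes as KN(t1) KN(t2) p(dphi|t1,t2),
        # so conditioning on photon A's fate never biases the angles
        r = source.radius_mm * rng.random(n) ** (1.0 / 3.0)
        origins = np.asarray(source.position) + r[:, None] * _isotropic_dirs(rng, n)
        th1 = kinematics.sample_klein_nishina_theta(source.pair_energy_kev, n, rng)
        ph1 = rng.uniform(-180.0, 180.0, n)
        res_A = _transport(origins, lor_dirs, source.pair_energy_kev,
                           np.ones(n, dtype=np.int8), geometry, model, rng,
                           theta1=th1, phi1=ph1, ref_dirs=lor_dirs, ref_sign=1.0)
        idx_a = np.flatnonzero(_complete_mask(res_A, sum_range))
        th2 = kinematics.sample_klein_nishina_theta(
            source.pair_energy_kev, idx_a.size, rng)
        if mode == "entangled":
            dph = kinematics.sample_dphi_given_thetas(th1[idx_a], th2, rng)
            ph2 = (ph1[idx_a] - dph + 180.0) % 360.0 - 180.0
        else:
            ph2 = rng.uniform(-180.0, 180.0, idx_a.size)
        res_B = _transport(origins[idx_a], -lor_dirs[idx_a], source.pair_energy_kev,
                           np.zeros(idx_a.size, dtype=np.int8), geometry, model, rng,
                           theta1=th2, phi1=ph2,
                           ref_dirs=lor_dirs[idx_a], ref_sign=-1.0)
        idx_ab = idx_a[_complete_mask(res_B, sum_range)]
        prompt_dirs, prompt_panel, prompt_trials = _sample_prompt_dirs(
            geometry, rng, idx_ab.size, condition_prompt)
        res_P = _transport(origins[idx_ab], prompt_dirs,
                           source.prompt_energy_kev, prompt_panel,
                           geometry, model, rng)
        res_P["n_int"][prompt_panel < 0] = 0
        idx_full = idx_ab[_complete_mask(res_P, sum_range)]
        photon_results = (
            ("prompt", res_P, idx_ab), ("annih_A", res_A, event_ids),
            ("annih_B", res_B, idx_a))
        keep_ids = set(idx_full.tolist())
        n_complete = idx_full.size
    else:
        prompt_dirs, prompt_panel, prompt_trials = _sample_prompt_dirs(
            geometry, rng, n, condition_prompt)

        # 0.1 mm source extent: jitter emission origins uniformly in the sphere
        r = source.radius_mm * rng.random(n) ** (1.0 / 3.0)
        origins = np.asarray(source.position) + r[:, None] * _isotropic_dirs(rng, n)

        th1, ph1, th2, ph2 = kinematics.sample_entangled_pair(n, rng, mode=mode)

        res_A = _transport(origins, lor_dirs, source.pair_energy_kev,
                           np.ones(n, dtype=np.int8), geometry, model, rng,
                           theta1=th1, phi1=ph1, ref_dirs=lor_dirs, ref_sign=1.0)
        res_B = _transport(origins, -lor_dirs, source.pair_energy_kev,
                           np.zeros(n, dtype=np.int8), geometry, model, rng,
                           theta1=th2, phi1=ph2, ref_dirs=lor_dirs, ref_sign=-1.0)
        res_P = _transport(origins, prompt_dirs, source.prompt_energy_kev,
                           prompt_panel, geometry, model, rng)
        res_P["n_int"][prompt_panel < 0] = 0
        photon_results = (("prompt", res_P, event_ids),
                          ("annih_A", res_A, event_ids),
                          ("annih_B", res_B, event_ids))
        keep_ids = None
        n_complete = int(np.count_nonzero(
            (res_A["n_int"] == 2) & (res_B["n_int"] == 2) & (res_P["n_int"] == 2)))

    frames = []
    for pid, res, ids in photon_results:
        if keep_ids is None:
            keep = np.ones(ids.size, dtype=bool)
        else:
            keep = np.isin(ids, np.fromiter(keep_ids, dtype=np.int64))
        for idx, (pos, dep, isc) in enumerate(
                (("pos1", "dep1", "isC1"), ("pos2", "dep2", "isC2"))):
            m = keep & (res["n_int"] > idx)
            if not np.any(m):
                continue
            frames.append(pd.DataFrame({
                "event_id": ids[m],
                "photon_id": pid,
                "interaction_index": np.int8(idx),
                "x_mm": res[pos][m, 0],
                "y_mm": res[pos][m, 1],
                "z_mm": res[pos][m, 2],
                "deposit_keV": res[dep][m],
                "process": np.where(res[isc][m], "compton", "photoelectric"),
                "panel": res["panel"][m],
            }))
    if frames:
        hits = pd.concat(frames, ignore_index=True)
        hits = hits.sort_values(
            ["event_id", "photon_id", "interaction_index"],
            kind="mergesort").reset_index(drop=True)
    else:
        hits = pd.DataFrame({c: pd.Series(dtype=t) for c, t in zip(
            HIT_COLUMNS, [np.int64, object, np.int8, float, float, float,
                          float, object, np.int8])})

    info = {
        "n_decays": n,
        "mode": mode,
        "rng_seed": rng_seed,
        "lor_trials": lor_trials,
        "lor_acceptance": n / lor_trials,
        "prompt_conditioned": condition_prompt,
        "prompt_trials": prompt_trials,
        "prompt_acceptance": (prompt_dirs.shape[0] / prompt_trials
                              if condition_prompt else None),
        "kept_decays": n_complete if staged else n,
        "complete_groups": n_complete,
        "topology_counts": {
            pid: {int(k): int(v) for k, v in
                  zip(*np.unique(res["n_int"], return_counts=True))}
            for pid, res, _ in photon_results
        },
    }
    if _return_truth:
        if staged:
            raise ValueError("_return_truth requires only_complete_groups=False")
        info["_truth"] = {"lor_dirs": lor_dirs, "theta": (th1, th2),
                          "phi": (ph1, ph2),
                          "results": {"annih_A": res_A, "annih_B": res_B,
                                      "prompt": res_P}}
    return hits, info


def sample_photon_history(entry_origin, entry_dir, E0, geometry,
                          interaction_model: InteractionModel | None = None,
                          rng_seed=0) -> PhotonHistory:
    """Transport a single photon along an explicit entry ray.

    The ray must intersect a panel; raises otherwise.  Returns the
    ground-truth (pre-blur) interaction history.
    """
    model = interaction_model or InteractionModel()
    rng = np.random.default_rng(rng_seed) if not isinstance(rng_seed, np.random.Generator) else rng_seed
    o = np.asarray(entry_origin, dtype=float)[None, :]
    d = np.asarray(entry_dir, dtype=float)
    d = (d / np.linalg.norm(d))[None, :]
    panel = None
    best_t = np.inf
    for p in (0, 1):
        te, _, hit = geometry.ray_panel_intersection(o, d, p)
        if hit[0] and te[0] < best_t:
            best_t, panel = te[0], p
    if panel is None:
        raise ValueError("entry ray does not intersect a panel")
    res = _transport(o, d, float(E0), np.array([panel], dtype=np.int8),
                     geometry, model, rng)
    n_int = int(res["n_int"][0])
    positions = np.vstack([res["pos1"][0], res["pos2"][0]])[:n_int]
    deposits = np.array([res["dep1"][0], res["dep2"][0]])[:n_int]
    procs = [("compton" if res["isC1"][0] else "photoelectric"),
             ("compton" if res["isC2"][0] else "photoelectric")][:n_int]
    return PhotonHistory(positions=positions, deposits=deposits,
                         processes=procs, panel=panel if n_int else -1,
                         escape_kev=float(res["escape"][0]))
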