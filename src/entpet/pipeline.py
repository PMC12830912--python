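"""Five-stage event processing: combine, group, filter, blur/bin + window,
and construction of labeled True/Random DCSc samples.

A *DCSc sample* pairs two multiple-interaction photon events (MIPEs) in
opposite panels and enumerates the four candidate interaction orderings
(which deposit was the Compton scatter, which the photoelectric absorption,
on each side).  True samples pair the two annihilation MIPEs (label = index
of the ground-truth ordering after row shuffling, 0-3); random samples pair
the prompt-gamma MIPE with the annihilation MIPE in the opposite panel
(label 4, false LOR).

Sample geometry convention: side A is the MIPE in panel 0, side B in panel
1.  Candidate rows are enumerated (A:12,B:12), (A:21,B:12), (A:12,B:21),
(A:21,B:21), where "12" keeps the recorded (ground-truth temporal) order
and "21" swaps it; the enumeration is fixed so that the unshuffled true row
is always row 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from entpet import simulator
from entpet.geometry import DetectorGeometry
from entpet.simulator import EnergyModel, blur_energy

__all__ = [
    "EnergyWindow",
    "SampleSet",
    "split_joint_stream",
    "combine_by_event_id",
    "filter_groups",
    "blur_and_bin",
    "mipe_table",
    "apply_window",
    "construct_samples",
    "enumerate_configurations",
    "shuffle_rows",
]

# MIPE-table wide columns: two interactions per photon
_MIPE_COLS = ["x0", "y0", "z0", "e0", "x1", "y1", "z1", "e1"]


@dataclass(frozen=True)
class EnergyWindow:
    """Closed symmetric acceptance window on a photon's summed energy."""

    center_kev: float = 511.0
    width_kev: float = 50.0

    def __post_init__(self) -> None:
        if self.width_kev <= 0:
            raise ValueError("window width must be positive")

    @property
    def lo(self) -> float:
        return self.center_kev - self.width_kev / 2.0

    @property
    def hi(self) -> float:
        return self.center_kev + self.width_kev / 2.0

    def contains(self, energy_kev):
        e = np.asarray(energy_kev, dtype=float)
        out = (e >= self.lo) & (e <= self.hi)
        return bool(out) if out.ndim == 0 else out


@dataclass
class SampleSet:
    """Labeled DCSc samples.

    ``configs`` has shape (n, 4, 16) — per sample, four candidate rows of
    [x1 y1 z1 x2 y2 z2 x3 y3 z3 x4 y4 z4 E1 E2 E3 E4] where (1, 2) are the
    assumed scatter/absorption in panel 0 and (3, 4) in panel 1.  ``labels``
    in {0..4}; ``event_id`` and ``is_random`` are provenance only and carry
    no feature information.
    """

    configs: np.ndarray
    labels: np.ndarray
    event_id: np.ndarray
    is_random: np.ndarray
    log: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return self.configs.shape[0]


def split_joint_stream(hits: pd.DataFrame):
    """Split a joint simulator hit table into (prompt, annihilation) parts."""
    is_prompt = hits["photon_id"] == "prompt"
    return hits[is_prompt].copy(), hits[~is_prompt].copy()


def _check_unique(hits: pd.DataFrame, name: str) -> None:
    key = hits[["event_id", "photon_id", "interaction_index"]]
    if key.duplicated().any():
        raise ValueError(f"corrupt input: duplicate hit keys in {name}")


def combine_by_event_id(prompt_hits: pd.DataFrame, annihilation_hits: pd.DataFrame):
    """Stage 1: pair the two streams on their shared decay index.

    Returns ``(combined, log)``; decays present in only one stream are
    dropped and counted.
    """
    _check_unique(prompt_hits, "prompt stream")
    _check_unique(annihilation_hits, "annihilation stream")
    prompt_ids = set(prompt_hits["event_id"].unique())
    annih_ids = set(annihilation_hits["event_id"].unique())
    shared = prompt_ids & annih_ids
    combined = pd.concat([prompt_hits, annihilation_hits], ignore_index=True)
    combined = combined[combined["event_id"].isin(shared)]
    combined = combined.sort_values(
        ["event_id", "photon_id", "interaction_index"],
        kind="mergesort").reset_index(drop=True)
    log = {
        "prompt_decays": len(prompt_ids),
        "annihilation_decays": len(annih_ids),
        "matched_decays": len(shared),
        "dropped_prompt_only": len(prompt_ids - annih_ids),
        "dropped_annihilation_only": len(annih_ids - prompt_ids),
    }
    return combined, log


def filter_groups(hits: pd.DataFrame):
    """Stage 3: keep decays where all three photons underwent a MIPE.

    Requires exactly three detected photons per decay, each with exactly two
    interactions, and the two annihilation MIPEs in opposite panels (a DCSc
    LOR must span the panel gap).  Returns ``(filtered_hits, log)``.
    """
    counts = hits.groupby(["event_id", "photon_id"], sort=True).size().unstack(fill_value=0)
    for col in ("prompt", "annih_A", "annih_B"):
        if col not in counts.columns:
            counts[col] = 0
    all_mipe = ((counts["prompt"] == 2) & (counts["annih_A"] == 2)
                & (counts["annih_B"] == 2)
                & (counts.sum(axis=1) == 6))
    panels = hits.groupby(["event_id", "photon_id"], sort=True)["panel"].first().unstack()
    opposite = pd.Series(False, index=counts.index)
    if "annih_A" in panels.columns and "annih_B" in panels.columns:
        opposite = panels["annih_A"].notna() & panels["annih_B"].notna() \
            & (panels["annih_A"] != panels["annih_B"])
    keep_ids = counts.index[all_mipe & opposite.reindex(counts.index, fill_value=False)]
    filtered = hits[hits["event_id"].isin(set(keep_ids))].reset_index(drop=True)
    log = {
        "decays_in": int(counts.shape[0]),
        "decays_all_mipe": int(all_mipe.sum()),
        "decays_kept": int(len(keep_ids)),
    }
    return filtered, log


def blur_and_bin(hits: pd.DataFrame, geometry: DetectorGeometry,
                 energy_model: EnergyModel | None = None, rng_seed=0):
    """Stage 4a: Gaussian energy blurring and 1 mm position discretisation."""
    model = energy_model or EnergyModel()
    rng = np.random.default_rng(rng_seed)
    out = hits.copy()
    if len(out):
        out["deposit_keV"] = blur_energy(out["deposit_keV"].to_numpy(), model, rng)
        pos = geometry.voxelize(out[["x_mm", "y_mm", "z_mm"]].to_numpy())
        out[["x_mm", "y_mm", "z_mm"]] = pos
    return out


def mipe_table(hits: pd.DataFrame) -> pd.DataFrame:
    """Wide table, one row per photon MIPE: positions/energies of both
    interactions (recorded order) plus the summed energy and panel."""
    h = hits.sort_values(["event_id", "photon_id", "interaction_index"],
                         kind="mergesort")
    first = h[h["interaction_index"] == 0].set_index(["event_id", "photon_id"])
    second = h[h["interaction_index"] == 1].set_index(["event_id", "photon_id"])
    idx = first.index.intersection(second.index)
    first, second = first.loc[idx], second.loc[idx]
    wide = pd.DataFrame(index=idx)
    for c, s in zip(("x0", "y0", "z0", "e0"), ("x_mm", "y_mm", "z_mm", "deposit_keV")):
        wide[c] = first[s]
    for c, s in zip(("x1", "y1", "z1", "e1"), ("x_mm", "y_mm", "z_mm", "deposit_keV")):
        wide[c] = second[s]
    wide["panel"] = first["panel"]
    wide["summed"] = wide["e0"] + wide["e1"]
    return wide.reset_index()


def apply_window(summed_energy, window: EnergyWindow | None = None):
    """Stage 4b: pass iff a MIPE's summed blurred energy is in-window."""
    return (window or EnergyWindow()).contains(summed_energy)


def enumerate_configurations(side_a: np.ndarray, side_b: np.ndarray) -> np.ndarray:
    """Enumerate the four candidate orderings of a sample.

    ``side_a``/``side_b``: (..., 8) arrays [x0 y0 z0 e0 x1 y1 z1 e1] for the
    panel-0 / panel-1 MIPE in recorded order.  Returns (..., 4, 16) rows in
    the fixed order (A:12,B:12), (A:21,B:12), (A:12,B:21), (A:21,B:21).
    """
    a = np.asarray(side_a, dtype=float)
    b = np.asarray(side_b, dtype=float)
    a12 = np.concatenate([a[..., 0:3], a[..., 4:7]], axis=-1)  # r1, r2
    a21 = np.concatenate([a[..., 4:7], a[..., 0:3]], axis=-1)
    ea12 = np.stack([a[..., 3], a[..., 7]], axis=-1)           # E1, E2
    ea21 = np.stack([a[..., 7], a[..., 3]], axis=-1)
    b12 = np.concatenate([b[..., 0:3], b[..., 4:7]], axis=-1)
    b21 = np.concatenate([b[..., 4:7], b[..., 0:3]], axis=-1)
    eb12 = np.stack([b[..., 3], b[..., 7]], axis=-1)
    eb21 = np.stack([b[..., 7], b[..., 3]], axis=-1)

    def row(ra, rb, ea, eb):
        return np.concatenate([ra, rb, ea, eb], axis=-1)

    rows = [row(a12, b12, ea12, eb12), row(a21, b12, ea21, eb12),
            row(a12, b21, ea12, eb21), row(a21, b21, ea21, eb21)]
    return np.stack(rows, axis=-2)


def construct_samples(mipes: pd.DataFrame, window: EnergyWindow | None = None,
                      fraction_random: float = 0.5, rng_seed=0) -> SampleSet:
    """Stage 5: build labeled samples from filtered, blurred MIPEs.

    All three MIPEs of a decay must pass the energy window (groups failing
    are dropped and counted).  Each surviving decay is assigned True or
    Random by a Bernoulli(``fraction_random``) draw: True pairs the two
    annihilation MIPEs (prompt discarded; unshuffled label 0), Random pairs
    the prompt MIPE with the annihilation MIPE in the opposite panel
    (label 4).  Rows are *not* yet shuffled; see :func:`shuffle_rows`.
    """
    if not 0.0 <= fraction_random <= 1.0:
        raise ValueError("fraction_random must be in [0, 1]")
    window = window or EnergyWindow()
    rng = np.random.default_rng(rng_seed)

    m = mipes.copy()
    m["in_window"] = apply_window(m["summed"].to_numpy(), window)
    per_event = m.pivot(index="event_id", columns="photon_id", values="in_window")
    complete = per_event.reindex(columns=["prompt", "annih_A", "annih_B"])
    ok = complete.notna().all(axis=1) & complete.fillna(False).astype(bool).all(axis=1)
    good_ids = complete.index[ok].to_numpy()
    n_window_dropped = int(len(complete) - len(good_ids))

    wide = m.set_index(["event_id", "photon_id"])
    cols = _MIPE_COLS + ["panel"]

    def grab(pid):
        sub = wide.xs(pid, level="photon_id").reindex(good_ids)
        return sub[cols].to_numpy()

    prm, ann_a, ann_b = grab("prompt"), grab("annih_A"), grab("annih_B")

    is_random = rng.random(good_ids.size) < fraction_random

    # side assignment: side A = MIPE in panel 0, side B = MIPE in panel 1
    n = good_ids.size
    side_a = np.empty((n, 8))
    side_b = np.empty((n, 8))
    skipped = 0
    keep = np.ones(n, dtype=bool)
    a_panel = ann_a[:, 8]
    for i in range(n):
        if is_random[i]:
            p_panel = prm[i, 8]
            partner = ann_b if (a_panel[i] == p_panel) else ann_a
            # annihilation MIPE in the prompt's own panel is discarded
            pair = (prm[i, :8], partner[i, :8])
            panels = (p_panel, partner[i, 8])
        else:
            pair = (ann_a[i, :8], ann_b[i, :8])
            panels = (a_panel[i], ann_b[i, 8])
        if panels[0] == panels[1]:   # cannot form a LOR across the gap
            keep[i] = False
            skipped += 1
            continue
        if panels[0] == 0:
            side_a[i], side_b[i] = pair
        else:
            side_a[i], side_b[i] = pair[1], pair[0]

    side_a, side_b = side_a[keep], side_b[keep]
    labels = np.where(is_random[keep], 4, 0).astype(np.int8)
    configs = enumerate_configurations(side_a, side_b)
    log = {
        "decays_in": int(len(complete)),
        "window_dropped": n_window_dropped,
        "pairing_skipped": skipped,
        "samples": int(keep.sum()),
        "random_samples": int(np.count_nonzero(is_random[keep])),
    }
    return SampleSet(configs=configs, labels=labels,
                     event_id=good_ids[keep],
                     is_random=is_random[keep], log=log)


def shuffle_rows(samples: SampleSet, rng_seed=0) -> SampleSet:
    """Permute each sample's four candidate rows uniformly at random,
    remapping labels 0-3 to follow the true row; label 4 is unchanged."""
    rng = np.random.default_rng(rng_seed)
    n = len(samples)
    perms = np.argsort(rng.random((n, 4)), axis=1)  # uniform permutations
    configs = np.take_along_axis(samples.configs, perms[:, :, None], axis=1)
    labels = samples.labels.copy()
    true_mask = labels < 4
    # new position of old row `label`: where perm equals the old label
    new_pos = np.argmax(perms == labels[:, None], axis=1)
    labels[true_mask] = new_pos[true_mask].astype(np.int8)
    return SampleSet(configs=configs, labels=labels,
                     event_id=samples.event_id.copy(),
                     is_random=samples.is_random.copy(),
                     log=dict(samples.log))
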