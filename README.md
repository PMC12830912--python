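# entpet

Entanglement-informed event classification for dual-panel CZT PET.

PET tracers that emit a high-energy prompt gamma alongside the positron
(Sc-44: 1157 keV) suffer from prompt photons Compton-down-scattering into
the 511 keV acceptance window, where they mimic annihilation photons and
corrupt the line of response (LOR).  At the same time, when both
annihilation photons Compton-scatter once and are then absorbed (a
double-Compton-scatter coincidence, DCSc), the order of the two
interactions on each side is ambiguous, giving four candidate interaction
sequences per coincidence.  Annihilation photons are emitted in an
entangled state whose polarization correlation imprints itself on Compton
kinematics: the azimuthal scattering-angle difference &Delta;&phi;
(measured about the LOR) prefers &plusmn;90&deg;, most strongly when both
polar angles are near 81.7&deg;.  `entpet` implements the full chain that
turns these facts into a classifier:

* **kinematics** — closed-form Compton energies/angles, the unpolarized
  Klein–Nishina density, the entangled double-Compton joint density, and
  exact samplers for both;
* **simulator** — a desk-scale Monte Carlo of a simplified Sc-44 point
  source between two 15&times;20 cm&sup2; CZT panels (5&times;30 crystals
  of 40&times;5&times;40 mm&sup3; each), with energy-dependent attenuation
  and Compton/photoelectric branching, 5.85%-at-511 keV Gaussian energy
  blurring, and 1 mm position binning;
* **pipeline** — the five-stage event processing: combine by decay index,
  group, keep decays whose three photons each leave exactly two
  interactions, blur/bin and apply the closed [486, 536] keV window, then
  construct labeled samples (true annihilation pairs vs. random
  prompt–annihilation pairings);
* **features** — the 21-feature vector per candidate ordering (positions,
  energies, position- and energy-derived polar angles, &Delta;&phi;, with
  the 9999 placeholder for physically undefined entries) assembled into a
  4&times;21 matrix per coincidence;
* **classifier** — a shared-encoder network (512/256 per row, 128 fusion,
  5-way softmax: true-row index 0–3 or false LOR 4) trained with Adam and
  class-weighted focal loss under stratified 5-fold cross-validation —
  implemented in deterministic NumPy;
* **evaluation** — per-class one-vs-rest ROC-AUC and F1, vertical ROC
  averaging across folds, the 15-subset feature-ablation harness with
  paired fold splits, and sampling-Shapley group importance.

The energy-derived polar angle uses the Compton relation
`theta_E = arccos(1 - m_e c^2 (1/E_s - 1/E_i))` with `E_i = 511 keV`; a
deposit above the 340.7 keV Compton edge has no solution and flags an
unphysical ordering — the mismatch between `theta_E` and the
position-derived `theta_p` is the core discriminative mechanism, with
&Delta;&phi; supplying the entanglement-sensitive signal.

## Worked example

```python
import numpy as np
from entpet import workflow, classifier as clf, evaluation

X, y, info = workflow.build_dataset(2000, seeds=workflow.DatasetSeeds(42),
                                    chunk_decays=3_000_000)
print("samples:", len(y), "random fraction: %.3f" % info["random_fraction"])
print("decays simulated:", info["decays"],
      "LOR acceptance: %.3f" % info["lor_acceptance"])

folds = clf.make_folds(y, k=5, rng_seed=1)
tspec = clf.TrainSpec(max_epochs=10, seed=2)
_, agg = evaluation.cross_validate_subset(
    X, y, ("dphi", "theta", "xyz", "E"), folds, train_spec=tspec)
print("per-class AUC (all features):", np.round(agg["auc_mean"], 3))
```

prints

```
samples: 2000 random fraction: 0.496
decays simulated: 6000000 LOR acceptance: 0.279
per-class AUC (all features): [0.849 0.853 0.843 0.842 0.959]
```

`X` holds one 4&times;21 matrix per coincidence (rows in shuffled order);
`y` is 0–3 for the position of the physical ordering and 4 for a random
prompt pairing — here ~50% of samples by construction.  The LOR acceptance
is the fraction of isotropic back-to-back pairs whose both photons
geometrically reach opposite panels.  The per-class AUCs are fold-mean
one-vs-rest values: classes 0–3 measure interaction-order recovery, class 4
random-coincidence rejection (strongest, 0.959, because the 1157 keV
prompt's deposits routinely exceed the Compton edge and its interactions
sit deeper in the crystals).

The same workflow is scriptable from the shell:

```bash
entpet simulate --config config.yaml   # ground-truth hits + JSON sidecar
entpet build    --config config.yaml   # labeled 4x21 dataset
entpet train    --config config.yaml --subset E,dphi
entpet ablate   --config config.yaml   # 15-subset paired ablation
entpet importance --config config.yaml --subset E,dphi
```

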