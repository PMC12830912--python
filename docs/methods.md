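# Methods

`entpet` models event classification for a dual-panel CZT PET system imaging
a dual-emission isotope (Sc-44-like: every decay produces a back-to-back pair
of 511 keV annihilation photons plus a 1157 keV prompt gamma).  The task is
to recover, for each double-Compton-scatter coincidence (DCSc), which of the
four possible interaction orderings is physical — or to recognise that the
coincidence is a random pairing of a down-scattered prompt with an
annihilation photon.  This note records the model, its assumptions, the
defaults, and the choices made where the design was genuinely open.

## Entangled double-Compton kinematics

For a coordinate frame with the line of response (LOR) as polar axis, the
joint distribution of the two photons' polar scattering angles
(&theta;<sub>1</sub>, &theta;<sub>2</sub>) and azimuthal difference
&Delta;&phi; is taken proportional to

    k1^2 k2^2 [ g1 g2 - g1 sin^2(t2) - g2 sin^2(t1)
                + 2 sin^2(t1) sin^2(t2) sin^2(dphi) ] sin(t1) sin(t2)

with k<sub>i</sub> = 1/(2 &minus; cos &theta;<sub>i</sub>) (the 511 keV
Compton energy ratio) and g<sub>i</sub> = k<sub>i</sub> + 1/k<sub>i</sub>.
This is the standard annihilation-photon angular-correlation form; it
reproduces the two anchors that matter here: the &Delta;&phi;-modulation
ratio P(90&deg;)/P(0&deg;) is maximal (&asymp;2.84) at
&theta;<sub>1</sub> = &theta;<sub>2</sub> &asymp; 81.7&deg;, and for fixed
polar angles the density peaks at |&Delta;&phi;| = 90&deg;.

Two useful algebraic facts drive the sampler:

* averaged over &Delta;&phi;, the bracket factorises exactly as
  (g1 &minus; sin&sup2;t1)(g2 &minus; sin&sup2;t2) — i.e. the polar marginals
  are the unpolarized Klein–Nishina marginals at 511 keV.  The sampler draws
  &theta;<sub>1</sub>, &theta;<sub>2</sub> independently from Klein–Nishina
  and then &Delta;&phi; from the conditional c0 + c1&middot;sin&sup2;,
  which is bounded by c0 + c1, so rejection under that envelope is exact.
* the conditional never goes negative (c0 &ge; 1 for all angle pairs), which
  is asserted at run time.

The "independent" control mode keeps the same marginals but draws both
azimuths uniformly — it removes the modulation without changing anything
else.

Angle conventions: degrees at every API boundary; &Delta;&phi; is the
unsigned angle between the two scattering vectors' projections onto the
plane orthogonal to the LOR, in [0, 180].  The &plusmn;90&deg; statement is
symmetric, so the unsigned form loses nothing and avoids an arbitrary
handedness choice.  Cosines are clamped to [&minus;1, 1] with tolerance
1e&minus;12 before arccos; a violation beyond that tolerance in the
energy-derived angle means physical undefinedness (deposit above the
Compton edge), not noise.  The projection-degeneracy threshold for
&Delta;&phi; is 1e&minus;9 relative to the scattering-vector norm.

## Detector simulation

Geometry: two opposing 15&times;20 cm&sup2; panels, each a 5&times;30 array
of edge-on 40&times;5&times;40 mm&sup3; CZT crystals tiling a solid
150&times;200&times;40 mm&sup3; box; the face-to-face gap is configurable
(default 200 mm — the physics downstream is separation-agnostic, the value
is merely plausible for a two-panel organ-scale scanner).  The source is a
0.1 mm-radius point at the FOV centre (30 &mu;Ci, half-life 14,290 s, 60 s
scan retained as metadata; decay timing and dead time are not modelled, and
events are paired by decay index).

Transport is deliberately minimal — a desk-scale stand-in for a full Monte
Carlo code:

* first-interaction depth ~ exponential with an energy-interpolated
  attenuation length (&lambda;(511 keV) = 20 mm);
* interaction type Compton with probability f_C(E) from a small CZT-like
  table anchored at f_C(511) = 0.80 with the photoelectric/Compton
  crossover near 260 keV;
* on Compton, the deposit is E &minus; E_s(&theta;) with &theta; from
  Klein–Nishina (or from the entangled joint density for annihilation
  pairs in which both photons scatter), azimuth measured about the LOR in
  a shared transverse basis so that ground-truth &Delta;&phi; follows the
  joint density by construction;
* a second interaction is sampled along the scattered ray and kept only if
  it falls inside the same panel; its type is again Compton-or-photoelectric.
  Histories are truncated at two interactions, giving the topologies P,
  C&rarr;P, C&rarr;C (remainder escapes) and C&rarr;escape.  The C&rarr;C
  channel is what lets a 1157 keV prompt leave a partial two-site deposit
  that sums into the 511 keV window — the contamination the classifier must
  reject.  The truncation means histories that would have a third
  interaction in a full transport code appear here as two-site events with
  an escaping remainder.

Energy blurring is Gaussian with FWHM(E) = 0.0585&middot;&radic;(511&middot;E)
keV, i.e. fractional FWHM 5.85% at 511 keV scaling as 1/&radic;E (the usual
statistics-driven semiconductor behaviour; a constant-fraction mode exists
behind a flag).  Positions are discretised to 1 mm voxel centres on each
crystal's local grid, centres at half-integer offsets from the crystal's
minimum corner, boundary ties rounding toward the lower voxel — fixed for
bit-reproducibility.

Performance devices (all exact, none change the distribution of surviving
events): LOR directions are proposed inside the bounding spherical cap of
the panel-acceptance cone, with trial counts rescaled by the cap fraction so
the logged acceptance still estimates isotropic acceptance; the prompt
direction is by default sampled conditionally on intersecting a panel
(`condition_prompt`), which is internal rejection of decays that the
stage-3 filter would drop anyway; large runs stage the transport (photon A
first, the partner's angles and the prompt drawn only for surviving decays
— valid because the joint density factorises), and can pre-filter on the
*true* deposit sum with a 6.5&sigma;-widened window, which blurring cannot
defeat.

## Event processing and dataset construction

Five stages: (1) combine prompt and annihilation hit streams on the shared
decay index; (2) group per decay; (3) keep decays in which all three photons
are detected with exactly two interactions each (a multiple-interaction
photon event, MIPE) and the two annihilation MIPEs lie in opposite panels;
(4) blur energies, bin positions, and require each photon's summed blurred
energy inside the closed window [486, 536] keV (the 50 keV window is read as
symmetric &plusmn;25 keV; "each photon" includes the prompt for both sample
types); (5) pair each surviving decay as True (the two annihilation MIPEs;
the prompt discarded) or Random (the prompt MIPE with the annihilation MIPE
in the opposite panel) by a Bernoulli(0.5) draw.

Each sample enumerates the four candidate interaction orderings — which
deposit was the Compton scatter and which the photoelectric absorption, per
side — in the fixed order (A:12,B:12), (A:21,B:12), (A:12,B:21),
(A:21,B:21), so that the unshuffled true row is row 0.  Rows are then
permuted uniformly per sample, the label following the true row (or class 4
for randoms).  Side A is always the panel-0 MIPE.  The dataset is globally
shuffled under its own named seed before fold partitioning.

Each candidate row becomes a 21-feature vector: 12 position coordinates,
4 energies, two position-derived polar angles (from the LOR defined by the
two *assumed* scatter points), two energy-derived polar angles (Compton
formula with the incident energy taken as 511 keV), and &Delta;&phi;.
Physically undefined entries — an energy-derived angle whose assumed
scatter deposit exceeds the 340.7 keV Compton edge, a degenerate LOR or
scattering vector after 1 mm binning — carry the placeholder 9999.
Standardisation is per column, fit on training-fold rows only, excluding
placeholders; placeholder cells map to the fixed post-scale sentinel +10.0
(far outside the standardised range without a four-decade dynamic range),
and zero-variance columns pass through.

A consistency note: with exact (un-binned) positions and no blur, the
position- and energy-derived polar angles of the true ordering agree to
numerical precision; 1 mm binning alone makes the median disagreement about
3&deg; (scatter-to-absorption distances are a few attenuation lengths), and
wrong orderings disagree far more — this gap, not the absolute agreement,
is the discriminative signal.

## Classifier

Each of the four rows passes through a shared fully connected ReLU encoder
(512 then 256 units); the four latent vectors are concatenated and fused by
one 128-unit hidden layer into a 5-way softmax (classes 0–3: position of
the true row; class 4: false LOR).  The layer widths follow the reference
protocol's 512/256/128; allocating 512/256 to the shared encoder and 128 to
the fusion stage preserves both the printed widths and the
encoder-plus-fusion structure.  Concatenation fusion is only *empirically*
equivariant after training on shuffled rows; nothing is asserted
architecturally.

Training: Adam at 1e&minus;3, batch 128, class-weighted focal loss
(&gamma; = 2, weights inverse to label frequency normalised to mean 1),
reduce-on-plateau schedule (factor 0.5, patience 3, floor 1e&minus;6),
early stopping after 10 epochs without validation improvement, best
checkpoint restored.  The implementation is plain float32 NumPy (forward,
focal-gradient backward, Adam), single-device and bit-deterministic under
its seeds; gradients are verified against finite differences in the tests.
Five-fold stratified cross-validation; the per-fold scaler is fit on the
training fold only.

## Evaluation

Per-class one-vs-rest ROC-AUC from class probabilities and F1 from argmax
decisions; fold curves vertically averaged on a fixed 101-point
false-positive-rate grid; fold statistics reported as mean &plusmn; sample
standard deviation.  The ablation harness trains one model per feature
subset (the 15 non-empty subsets of {&Delta;&phi;, &theta;, xyz, E}; the
&theta; group contains all four polar-angle columns) with identical fold
splits across subsets, so subset comparisons are paired.  Group importance
is a permutation-sampling Shapley approximation over the four column
groups: a group outside the coalition is replaced by the training-set
post-scale means, attribution is on the predicted-class probability, and
the efficiency axiom (attributions summing to prediction minus baseline
prediction) is tested.  Exact SHAP-library machinery is intentionally out
of scope.

## Problem sizes and what passing tests show

The bundled study runs 30,000 samples (about 7.8&times;10<sup>7</sup>
simulated decays at the default geometry's per-decay survival of roughly
4&times;10<sup>-4</sup>), stratified 5-fold CV, and reduced-epoch training
(max 15 epochs; the loss plateaus around epoch 8–12 on these subsets).
Statistical tests in the suite use 10<sup>5</sup>–1.5&times;10<sup>6</sup>
draws for distributional checks.

The synthetic generator emulates the *structure* of the problem — entangled
scattering kinematics, prompt down-scatter contamination, candidate-ordering
ambiguity, blurring and binning — but not a full transport code: no Doppler
broadening, no &ge;3-interaction histories, no inter-panel scatter, no
charge sharing or readout effects.  Feature *content* therefore differs
from a full Monte Carlo dataset in composition: here the dominant
discriminators are the &theta;-consistency pair and the spatial depth
distribution (the 1157 keV prompt interacts deeper), and the
energy-only and &Delta;&phi;-only signals are weaker than in the reference
study.  With all 21 features the classifier separates the five classes
almost perfectly (fold-mean AUC &asymp; 0.98–0.999); with the energy and
&Delta;&phi; groups alone it reaches fold-mean AUCs around 0.66–0.78.
Passing tests demonstrate the pipeline's correctness and the qualitative
physics (modulation present and 90&deg;-peaked for true pairs, absent for
randoms; placeholder rates higher for randoms; E+&Delta;&phi; dominating
&Delta;&phi; alone under paired folds) — not that a real scanner would see
these exact AUCs.

## Known limitations

* Two-interaction truncation reshapes the two-site event population (see
  above); a third-interaction veto would thin and slightly re-weight the
  prompt contamination channel.
* The attenuation/branching table is a coarse CZT-like stand-in; absolute
  rates (samples per decay) should not be compared to measured systems.
* Class labels 0–3 are exchangeable by construction (uniform row
  shuffling), so per-class differences among them in any report are pure
  fold noise.
* The entangled density ignores decoherence; detected modulation depth is
  an upper bound on what a partially decohered beam would show.
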