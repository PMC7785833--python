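# Methods

## Overview

`plvtree` implements an activity-based functional-network analysis for
event-related fNIRS recordings: multi-trial HbO2 epochs are turned into a
phase-locking-value (PLV) connectivity matrix per subject, the
maximum-connectivity spanning tree (MST) of that matrix is extracted, and
tree topology metrics are compared between groups and correlated with
clinical scores.  Because the kind of clinical recordings this analysis
targets are typically restricted, the package ships a synthetic cohort
generator with a *planted* coupling topology, so that the whole chain can be
validated against a known ground truth.

## Connectivity model

Each subject contributes `N = 28` stimulus-locked epochs of 14 channels
sampled at 7.81 Hz.  An epoch spans [-6, 14] s around the stimulus: 2 s
margin + 4 s pre-stimulus + 12 s post-stimulus + 2 s margin (20 s, 156
samples).  The margins exist only to keep Hilbert-transform edge effects
away from the analysis windows and are never averaged.

1. **Instantaneous phase.**  The analytic signal `x_a[n] = x[n] + j x_h[n]`
   is computed per trial and channel by the discrete Hilbert transform over
   the full 20-s epoch; the phase is `atan2(x_h, x)`, wrapped to (-pi, pi].
2. **PLV.**  For each unordered channel pair {k, l} and sample n,
   `PLV_kl[n] = |(1/N) sum_p exp(j(phi_k[p,n] - phi_l[p,n]))|`, in [0, 1].
3. **Baseline z-scoring (zPLV).**  Each pair's PLV time course is z-scored
   against its own baseline, the samples in [-4, -1) s: subtract the
   baseline mean, divide by the baseline population standard deviation
   (ddof = 0).  A constant baseline (sigma = 0) is guarded: that pair's
   zPLV is set to 0 with a warning.  z-scoring cancels stationary,
   task-unrelated synchrony; see "Known biases" below for its small-sample
   cost.
4. **tPLV.**  zPLV is averaged over the [0, 12) s post-stimulus window,
   `M = round(12 x fs)` samples (94 at 7.81 Hz), giving a symmetric 14 x 14
   adjacency matrix with zero diagonal.  The subject-level global PLV
   (gPLV) is the mean over the 91 channel pairs.

Window conventions: time-to-sample maps use `floor(t * fs)` with sample 0
at -6 s; windows are half-open `[start, stop)`.  These conventions
reproduce M = 94 at the reference sampling rate.

## Tree extraction

The complete weighted graph on the 14 channels (tPLV weights, no
thresholding) is reduced to its maximum-weight spanning tree by Kruskal's
algorithm: edges sorted by descending weight and greedily added unless the
addition closes a cycle, detected with a depth-first search.  Ties (measure
zero for continuous data) break lexicographically by (smaller index, larger
index), which makes the output deterministic and exactly invariant under
strictly increasing weight transforms.  Because only the weight *ordering*
matters, negative weights (routine after z-scoring) need no special
handling.  Group trees are built from the element-wise mean tPLV matrix of
a group; the reference tree for overlap analysis comes from the
control-group average.

## Topology metrics

For a tree on N nodes with leaf count L (degree-1 nodes):

| metric | definition | star (N=14) | line (N=14) |
|---|---|---|---|
| leaf fraction `L_f` | L / (N-1) | 1 | 2/13 |
| max degree `k_max` | max degree | 13 | 2 |
| betweenness `BC(r)` | fraction of other-node pairs whose unique path crosses r | hub 1, leaf 0 | - |
| eccentricity (global) | max - min of nodal eccentricities | 1 | 6 |
| degree divergence `kappa` | sum(k^2) / sum(k) | 7 | 50/26 |
| diameter `D` | longest shortest path / (N-1) | 2/13 | 1 |
| tree hierarchy `T_H` | L / (2 (N-1) BC_max) | 0.5 | -> 0 |

Betweenness is normalized over unordered pairs, i.e. by `(N-1)(N-2)/2`, so
that the hub of a star scores exactly 1 and every leaf exactly 0; in a tree
each pair has a unique shortest path, so no path-count ratios arise.  The
global eccentricity is reported as the max - min range by default; the
max variant (the unnormalized diameter) is available via `ecc_variant="max"`
since the two readings coexist in the literature this analysis follows.
`T_H = 0.5` characterizes the star but is *not* exclusive to it (e.g. a
9-node tree with L = 6 and BC_max = 0.75 also gives 0.5); only the D = 1
<=> line equivalence is an iff.  Metrics are kept at full precision;
rounding to two decimals happens only in reports.

Hub/edge occurrence across a group's individual trees counts, per node, the
share of subjects where the node has degree > 1, and per edge the share of
trees containing it; a display threshold (default 25%) tags the edges worth
reporting.  Overlap with the reference tree is shared-edge count / (N-1).

## Statistics

Between-group contrasts use the two-sided Mann-Whitney U test: the exact
null distribution when the combined sample is at most 25 without ties
(always the case for the 9 + 10 reference design on continuous metrics),
otherwise the normal approximation with tie correction and *no* continuity
correction — so two identical samples give p = 1 exactly.  Clinical
associations within the patient group use Spearman rank correlation with
average ranks.  No multiple-testing correction is applied by default,
matching per-metric reporting; Benjamini-Hochberg is available as an
opt-in (`group_stats.adjust_pvalues`).

## Synthetic cohort generator

The generator emulates the reference acquisition — 14 channels, 7.81 Hz,
28 trials, 2/4/12/2-s epochs — and plants a spanning-tree coupling topology
("star", "line", or any explicit tree).

**Signal model.**  Per trial and channel the signal is
`A cos(2 pi f_c t + theta(t)) + e(t)` with carrier `f_c = 0.05` Hz (inside
the 0.01-0.15 Hz hemodynamic band), unit amplitude, and white Gaussian
noise `e` (sd 0.3 by default).  The phase offset `theta(t)` is a
tree-coupled *anchor* plus a variance-modulated random walk:

* Anchors: the template root draws a uniform trial phase; each child's
  anchor is its parent's plus von Mises jitter with concentration
  `coupling_kappa` (kappa = 0 is uniform jitter, i.e. no coupling; phase
  locking decays with hop distance along the tree).
* Walk: per-channel Gaussian increments, anchored to zero at stimulus
  onset, with step sd tapering (smoothstep over [-1, 0) s) from
  `baseline_drift_sd = 0.9` rad/sample before the stimulus to
  `post_drift_sd = 0.02` after it.  Pre-stimulus the walk decoheres every
  channel from its anchor — baseline phases are effectively independent —
  while post-stimulus the planted coupling is expressed cleanly.

Two properties of this construction matter:

1. *Phase continuity.*  At a 0.05 Hz carrier a 20-s epoch holds a single
   cycle, so any step-like phase reorganization at onset is broadband and
   biases the discrete Hilbert phase deep into the post-stimulus window.
   Modulating the *variance* of a continuous walk avoids a deterministic
   onset step.
2. *A well-defined baseline sigma.*  The walk gives the baseline PLV
   genuine within-epoch variation, so the z-scoring denominator sigma_kl
   is a real population quantity rather than a numerical residue.

`baseline_drift_sd = 0.9` is fixed by the baseline-independence contract,
not by tuning: the closest baseline sample is only 1 s (~8 samples) before
the onset anchor, so the accumulated pairwise wander there,
`sqrt(2 x 8) x sd`, must exceed ~3 rad for residual coherence
`exp(-sigma^2/2)` below 1%.

**Cohort structure.**  Subject i uses seed `seed + i` (reproducible,
parallel-safe).  Each subject's realized kappa is drawn uniformly within
`+/- kappa_spread` (relative, default 50%) of the configured value;
deterministic monotone links map it to clinical scores (a decreasing
ALSFRS-R-like functional score, an increasing disease-duration-like
value).  Records keep both the integer 0-48 score and the raw continuous
link output, so exact monotone relationships survive rounding.

**What the generator does not emulate.**  Optode physics, motion artifacts,
systemic physiology (cardiac/respiratory rhythms beyond the white-noise
floor), hemodynamic-response amplitude envelopes, channel-quality
variation, and trial rejection (all 28 trials are retained).  A green
recovery test therefore establishes that the pipeline recovers planted
*phase-coupling topology* under realistic sampling constraints — not that
it would survive every artifact of real recordings.

## Identifiability: what recovery is and is not achievable

With 28 trials, a 24-sample baseline and a one-cycle carrier, planted-tree
recovery through the full zPLV pipeline is *statistical*, not exact:

* The z-scoring denominator is estimated from ~24 baseline samples, so
  each pair's weight carries irreducible multiplicative noise
  (CV >~ (2x24)^{-1/2} ~ 15%).
* Making the baseline independent within the 1 s before onset is
  necessarily broadband at a <= 0.15 Hz carrier, which perturbs the
  Hilbert phase post-stimulus by an amount comparable to the inter-hop
  jitter differences once `coupling_kappa` is large.

Consequently recovery of the planted tree peaks at moderate coupling
(kappa ~ 2-4, where per-hop PLV gaps are large) rather than increasing
without bound, and an exact 13/13 edge match is not attainable in this
stated world at any setting.  The validated claims are: recovered-edge
fraction far above chance (chance ~ 2 of 13 edges) and monotone in kappa
over [0, 2]; and cohorts with star vs line templates reproduce all five
directional group contrasts (higher k_max, L_f, kappa; lower D, Ecc in the
star group) with p < 0.05 at n = 10 per group in at least 8 of 10 seeds.

## Known biases and numerical choices

* **Null tPLV offset.**  z-scoring against a short, skewed
  (Rayleigh-like) baseline has a small positive small-sample bias
  (~ +0.03 in tPLV units): when the baseline sample happens to miss the
  right tail, the estimated mean is low and the estimated sigma small
  simultaneously.  Under a fully uncoupled generator the mean tPLV over
  100 subjects stays within |z| < 3 of zero, which is the tested bound.
* Degenerate inputs: all-zero trials (undefined phase) are dropped
  consistently across all pairs; a constant-baseline pair's zPLV is zeroed;
  fewer than 2 surviving trials or epochs outside the recording are errors.
* The band-pass is a 4th-order Butterworth applied forward-backward
  (zero phase, `sosfiltfilt`); band edges 0.01-0.15 Hz; the filter family
  and order are package choices, as is DPF = 6.0 with standard extinction
  coefficients in the Beer-Lambert step (all configurable).
* Tie-breaks, index conventions and the eccentricity variant are described
  above; all are deterministic, so a fixed seed and config reproduce every
  output byte-for-byte.
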