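# Methods

This note records the models implemented, the assumptions behind them, the
parameter choices made where the design was genuinely open, what the
synthetic generator does and does not emulate, and the numerical decisions a
maintainer would want to know. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Coordinates and conventions

All residue intervals are 1-based and inclusive. A `SequenceRecord` carries
a numbering offset so a construct fragment keeps its full-length numbering
(e.g. a 200-residue fragment numbered 414–613 has `offset=413`). All tabular
I/O is plain TSV/CSV with explicit headers; `# key: value` comment lines
carry table-level metadata.

**Exchangeable amides.** A peptide's observable amides are its non-proline
residues from position 2 onward: the N-terminal amide back-exchanges too
fast to measure and prolines carry no amide proton. This equals the common
`length − prolines − 1` bookkeeping except when the first residue is itself
a proline (which that formula would subtract twice). The plain non-proline
count is reported separately for NMR assignment bookkeeping.

**State order.** Differential uptake is `state B − state A`. With A = free
and B = bound, protection (reduced uptake) is a *negative* difference, so
the default `protected_sign = -1`; the CLI logs the convention and it is
configurable for exports that use the opposite subtraction order.

## HDX-MS arm

### Kinetic model

Per-amide deuteration follows the standard single-amide scheme
`D_i(t) = 1 − exp(−(k_int,i / P_i) t)`. Intrinsic rates use a simplified
base-catalysed model `k_int = k_ref · 10^(pD − pD_ref)` with a uniform
`k_ref = 1 s⁻¹` referenced to pD 7.4; the generator's default labelling pD
is 6.0, emulating the slowed-exchange strategy needed to open the HDX time
window for an IDP whose physiological-pD exchange saturates within seconds.
Only *relative* protection matters downstream, so a uniform reference rate
suffices; a `TabulatedRateModel` hook accepts per-residue-type factors for a
sequence-dependent (Bai/Englander-style) table supplied as data. Back
exchange is not modelled by default (uptake is treated as relative, not
absolute); a uniform back-exchange factor exists for robustness tests.

### Statistics

`fx = (m_t − m_0)/(m_max − m_0)` per replicate, with `m_max` either from a
24 h maximally-labelled control or theoretical (amide count × 1.00628 Da).
Charge states of one peptide are pooled after centroid conversion — vendor
exports list them separately but the analysis is peptide-level. Differences
carry `u_c = sqrt(sd_A²/n_A + sd_B²/n_B)`; confidence half-widths use
two-tailed t quantiles at 0.98 and 0.99 with Welch–Satterthwaite degrees of
freedom (the test is named in the source protocol, the df convention is
not — Welch is the defensible default for small, possibly unequal replicate
variances).

### Region calling and sub-localisation

The rule is implemented exactly as stated, with strict inequality: a
peptide with |Δfx| > 5% (same sign) at ≥ 2 *observed* time points flags its
footprint (branch 1); ≥ 3 mutually overlapping peptides above 5% at a
single time point flag their union (branch 2; in one dimension pairwise
overlap is equivalent to sharing a residue, so groups are found via
coverage counts). Whether the original rule also required CI significance
is not stated; the rule is applied on magnitude only and the CI envelopes
are reported alongside.

Raw peptide footprints necessarily overhang the true protected residues by
up to a peptide length. The default `trim="subtractive"` therefore removes
residues whose amide signal is covered by a *quiescent* peptide (one never
exceeding the threshold at any time point) — the standard way overlapping
peptic peptides are used to sub-localise HDX signals. `trim="none"` keeps
the raw union. Subtractive trimming assumes the contrast is strong enough
that any peptide containing even one truly protected amide exceeds the
threshold; in weak-contrast data it can erode true regions, which is why it
is a switch.

## NMR shifts arm

ΔSCS Cα = observed − random-coil Cα. The random-coil reference is a
replaceable packaged table (Wishart-style values; uniform −2.0 ppm
pre-proline correction available but off by default, matching
"corrections default to 0"). Stretches are maximal runs of consecutive
assigned residues beyond ±1 SD of the profile, minimum length 3 (the
shortest stretch the motivating analysis reports); gaps from unassigned
residues break runs. The SD is estimated robustly by default
(MAD × 1.4826) because the structured stretches themselves inflate a plain
SD; `estimator="sd"` is exposed. On noiseless synthetic data the MAD is
zero, the threshold degenerates to "strictly nonzero", and recovered
boundaries equal the implanted ones exactly — which is what the round-trip
tests assert.

## Relaxation arm

Decay rates come from mono-exponential least squares (`scipy.optimize.
curve_fit`, log-linear start, slope floored at 0 so constant series fit
cleanly); duplicated delays in the acquisition grids provide error
estimates. hetNOE = I_sat/I_ref with SD from the two repeats. η_xy inverts
`I_A/I_B = tanh(2Δ·η_xy)`; with both delays (60, 100 ms) present the
default is a joint least-squares fit, with per-delay inversions also
reported (the combination rule is not stated in the protocol; for
consistent data the joint fit equals either inversion). |ratio| ≥ 1 flags
the residue rather than aborting.

The decomposition uses the signed gyromagnetic ratio γN/γH = −0.10136, so
σ = (NOE − 1)·R1·γN/γH is positive whenever NOE < 1 and R2⁰ = κ·η_xy +
1.3·σ stays a positive rate; κ defaults to the empirical 1.45 and is
configurable (it is field-strength dependent). Errors propagate first-order
into σ, R2⁰ and Rex.

ΔR2 significance uses the SD of ΔR2 over all matched residues (a trimmed
option exists; whether the original analysis trimmed is not stated, default
is all residues). Contiguous flagged runs become perturbed intervals.

## Binding arm

Receptor at 10 nM (final) is comparable to a ~6 nM K_d, so the fit uses the
exact ligand-depletion quadratic, in the numerically stable form
`fb = 2·L_t/(s + sqrt(s² − 4·L_t·R_t))`, `s = K_d + L_t + R_t` — the naive
`(s − sqrt)/2R_t` form loses the mass-action identity to cancellation at
extreme ratios. All concentrations are final (post-mix): the 1:1 mixing
step halves nominal values (250 nM top / 20 nM receptor nominal → 125/10
final). Whether the original fit used nominal or post-mix scale is
ambiguous; the choice changes K_d by ~2×, so the titration reader requires
an explicit declared scale and logs the conversion. Fluorescence intensity
is assumed binding-independent (no enhancement weighting). Uncertainty is
reported both as the pooled fit's asymptotic SE and as the SEM of
per-replicate K_d estimates (the convention used when quoting K_d ± SEM of
technical triplicates).

## Consensus

Per-residue evidence classes: HDX protection, secondary-shift stretch,
ΔR2 perturbation. The score is the count of non-null classes (0–3);
maximal intervals with score ≥ 2 are consensus elements, with gaps ≤ 2
residues bridged (a disordered linker between two binding helices is
treated as contributory). Both the threshold and the bridge width are
explicit parameters because the underlying convergence argument is
qualitative. Evidence strength is deliberately not weighted.

## The synthetic world

The generator's defaults state one concrete world: a 200-residue
disordered construct numbered 414–613 with three protected intervals
(426–439 ×100, 471–495 ×100, 556–571 ×50), helical stretches (428–430
+2.0 ppm, 474–477 +1.8, 548–560 +1.5), one extended stretch (446–449
−1.2 ppm), exchange hotspots (421–431 +4 s⁻¹, 474–480 +3, 558–560 +2,
scaled by a 10% bound fraction), and K_d = 5.8 nM. The sequence is random
with a disorder-biased composition — a synthetic stand-in, not any real
protein — with prolines excluded from the structured elements (prolines
break helices and would fragment amide-detected stretches). HDX uses
triplicates at 3/30/60/300 s; titrations use 16 two-fold dilutions from
125 nM (final) with 0.002 anisotropy noise, three replicates.

Chosen where no value was stated, with rationale:

* **peptide pool**: mean peptic length 9, mean redundancy 8 — a
  well-sampled map of a small construct ("high coverage with redundancy");
  the subtractive sub-localisation needs fully-outside overlapping
  peptides, which geometric analysis shows requires redundancy ≳ 6;
* **centroid noise** 0.03–0.05 Da (≈ 0.4–0.6% fx on an 8-amide peptide),
  typical of manually verified centroids;
* **relaxation baseline**: disordered-chain rates (R1 1.3 s⁻¹, NOE 0.35,
  η_xy 1.5 s⁻¹) with rigid helical elements (NOE 0.65, η_xy 4.0); apo R2
  is *constructed* exchange-free (R2 = κη_xy + 1.3σ) so the apo
  decomposition recovers Rex ≡ 0 identically; R2 measurement noise
  0.05 s⁻¹ (~1–2%);
* **anisotropy window** r_free 0.10 → r_bound 0.25, a typical dynamic
  range for a labelled ~20 kDa probe binding a 125 kDa partner.

What the generator does **not** emulate — and therefore what a green test
does not establish: isotope envelopes, EX1 behaviour, back-exchange
gradients, chromatographic artefacts or peptide misassignment in HDX;
sequence-dependent intrinsic rates (uniform by default); peak overlap,
assignment errors or field-dependent κ in NMR; pipetting/serial-dilution
error correlation in titrations (noise is i.i.d. Gaussian). Recovery
statistics on this world validate the *statistical machinery*, not
instrument-level robustness.

## Numerical details

* Strict inequalities everywhere a threshold is stated ("greater than 5%"),
  asserted by a boundary-sweep test.
* η_xy forward/inverse round trip is exact to 1e−10 for |ratio| ≤ 0.99.
* Degenerate inputs are typed errors: empty sequences, missing controls,
  peptides with no exchangeable amides, flat anisotropy responses,
  titrations with < 4 points.
* Determinism: every stochastic generator takes a seed and spawns
  `numpy` Generators from structured seed sequences; identical seeds give
  bit-identical outputs (asserted).
* Non-convergent per-residue fits are flagged, never fatal.

## Known limitations

* The HDX caller reports maximal contiguous intervals; it does not model
  per-residue exchange explicitly (no EX1/EX2 classification, no
  isotope-envelope fitting).
* No multi-nucleus secondary-structure propensity (Cβ/C′/HN) — Cα only.
* No model-free relaxation analysis or CPMG dispersion; Rex here is a
  difference statistic, not a fitted exchange model.
* Single-site 1:1 binding only; no cooperativity, competition or global
  multi-experiment fits.
* One acceptance check (the canonical-construct non-proline count) needs an
  external sequence download and is left failing offline rather than
  satisfied with a fabricated stand-in.
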