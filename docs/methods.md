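# Methods

This note documents the models and numerical choices behind `gqfret`: what
the analysis computes, what the synthetic generator does and does not
emulate, and where the design was genuinely open.

## Spectroscopic state model

The assay observes a surface-tethered partial-duplex DNA whose
single-stranded portion carries an intramolecular G-quadruplex (GQ) and an
overhang that a RecQ-family helicase binds. Each conformational state
produces a Gaussian-distributed FRET efficiency (proximity ratio,
uncorrected for gamma or crosstalk). The canonical levels, taken from
two-Gaussian fits to folded-state histograms and from reference constructs
of matched single-strand length:

| state                 | E_FRET (mean ± σ) | meaning                               |
|-----------------------|-------------------|---------------------------------------|
| `folded_conf2`        | 0.78 ± 0.05       | folded GQ, conformer 2 (K⁺)           |
| `folded_conf1`        | 0.64 ± 0.07       | folded GQ, conformer 1 (K⁺)           |
| `blm_bound_folded`    | ≈0.55             | helicase on the overhang, GQ folded   |
| `unfolded`            | 0.40 ± 0.06       | unfolded (coiled) DNA, unbound        |
| `blm_bound_unfolded`  | 0.20 ± 0.08       | helicase-bound unfolded DNA           |
| `coiled` (non-GQ tail)| ≈0.85             | coiled polythymine construct          |

In Na⁺ the folded class is a single conformer (one Gaussian); in K⁺ the
relative abundance of the two conformers is not pinned down by the data and
defaults to 50/50 (a free generator parameter). The low-FRET class is an
equilibrium of `unfolded` and `blm_bound_unfolded`; its 50/50 default
reproduces the merged peak observed at E ≈ 0.30.

Samples drawn from state Gaussians are **not** clipped to [0, 1]:
proximity-ratio noise legitimately produces values slightly outside, and the
histograms span [−0.2, 1.2] instead.

## Occupancy law

Steady-state low-class occupancy follows a Langmuir binding isotherm in the
effector concentration x (protein, or nucleotide at fixed protein),

    y(x) = α·x / (x + K_eq)   [percent of molecules],

with α the saturating unfolded population and K_eq the half-saturation
concentration. `OccupancySpec` turns (α, K_eq) into a per-state probability
vector:

- low class: `(baseline_low_percent + y(x))/100`, split across the low
  states by weight. `baseline_low_percent` (default 0) models nucleotide
  titrations whose reference state already contains protein-driven
  unfolding; the subtraction against that reference cancels the baseline, so
  the fitted isotherm describes the *additional* unfolding.
- folded class: the remainder; a constant `bound_folded_fraction` (default
  0) of it can be shown at the `blm_bound_folded` level.

`bound_folded_fraction` defaults to zero because the bound-folded level
overlaps the folded conformers heavily: any steady-state bound-folded
population inflates the cumulative positive area with mass that is not
unfolding (≈½ of the reassigned mass at the default widths). Observed
histograms show this level as a minor shoulder, consistent with bound
molecules proceeding quickly to the unfolded state at steady state; users
can raise the fraction to study the resulting bias.

## Synthetic trace generator

Static mode (the default) draws one state per molecule and holds it —
appropriate for steady-state histograms, which is what the quantification
uses. Per frame, E ~ N(e_mean, e_sigma); intensities are

    I_A = B·E + bg_A + N(0, σ_noise),   I_D = B·(1−E) + bg_D + N(0, σ_noise),

with per-molecule brightness B lognormal around `total_intensity`
(CV = `intensity_cv`, default 0.2, chosen to exercise the intensity-band
filter). Defaults B = 500 counts/frame, σ_noise = 30 counts, backgrounds
(20, 15) counts are plausible EMCCD-scale values; no instrument values are
published, so they are config-exposed. Photobleaching is geometric per frame
(donor 7·10⁻⁴, acceptor 5·10⁻⁴ per frame), so 30-frame short movies rarely
bleach while most 1000–4000-frame long movies do. Acceptor bleaching sends
E to ≈0 (signal moves to the donor channel); donor bleaching sends both
channels to background, since FRET requires an excited donor. Contaminants
(fraction 0.05 by default) are aggregates (two independent molecules summed,
≈2× brightness) or donor-only molecules, flagged in ground truth.

Dynamic mode alternates folded/unfolded classes with exponential dwells
(default 20 s each, several transitions within a ~2 min trace) and exists
only for qualitative long-trace inspection; no dwell-time kinetics are
quantified.

Reproducibility: every molecule draws from an independent
`SeedSequence(seed, dataset_index, molecule_index, stream)` stream, so any
trace regenerates bit-identically in isolation and datasets are
independently reproducible.

Not emulated (hence not validated by passing tests): camera excess noise and
digitization, spectral crosstalk and gamma factors, blinking, spot overlap
in the image plane, drift, and real dwell-time kinetics. The generator
validates the *analysis*, not the instrument.

## Analysis pipeline

**Background and filtering.** Constant per-channel background subtraction by
default; a `post_bleach` mode estimates the background from frames after the
last detected intensity step and falls back to constant (with a warning)
when no step exists. The single-molecule screen accepts a trace iff its mean
total intensity lies within median ± 40 % of the dataset, it shows at most
one large downward step (single-frame drop > 50 % of the pre-drop mean), and
its mean apparent FRET exceeds 0.1. No published thresholds exist; these are
standard-practice defaults, config-exposed. With a lognormal brightness
spread (CV 0.2) the band necessarily clips ~9 % of true single molecules —
a state-independent loss that does not bias occupancies.

**Histograms.** E_FRET per usable frame (usable ends at the first frame
whose total falls below 25 % of the trace median — donor bleaching lands
there); the first 20 frames per molecule are pooled so bright long-lived
molecules do not dominate; bins of width 0.025 over [−0.2, 1.2] (56 bins),
normalized to Σ = 100 %. The bin width resolves the 0.20/0.30/0.40 peaks
given σ ≈ 0.05–0.08 and is config-exposed.

**Subtraction score.** One histogram per condition (all accepted molecules
of all replicate fields pooled) minus the pooled zero-effector reference;
the cumulative positive area over *all* positive bins is the unfolded (or
bound, or refolded) percent. Summing all positive bins rather than bins
below a FRET cutoff follows the definition of the score; an optional `e_cut`
restricts the sum for sensitivity analysis. Error bars are the standard
deviation of per-field scores (replicate movies), or a binomial standard
error √(p(1−p)/n)·100 when only one field exists. Two numerical properties
matter:

- *Overlap loss.* The score counts only the part of the low-class mixture
  that exceeds the folded reference density, a factor
  c = ∫(f_low − f_folded)⁺ ≈ 0.94 at the default widths. K_eq recovery is
  unaffected (the loss is multiplicative in x), while fitted α sits at c·α.
  This is intrinsic to the subtraction method itself, not to the simulation.
- *Rectification floor.* With finitely many molecules, bins where the true
  difference is ≈0 contribute |noise|/2 on average, a small positive offset
  that decays as 1/√n_molecules. Pooling fields before subtracting (rather
  than averaging per-field scores) suppresses it; at 10×250 molecules it is
  ≲0.3 %.

**Isotherm fit.** Weighted least squares via Levenberg–Marquardt (lmfit)
with α ∈ (0, 100], K_eq > 0; initial guesses α₀ = max(y), K₀ = x at the
first point above max(y)/2 (robust whether or not the series saturates).
The supplied σᵢ are absolute uncertainties, so the covariance is **not**
rescaled by the reduced χ² (`scale_covar=False`); reported errors are the
1-σ covariance errors. The zero-concentration point is y ≡ 0 by construction
(it is the subtraction reference, not an observation) and is excluded from
the residuals by default; `include_zero` adds it with a small σ. A warning
is raised when max(x) < 3·K_eq, where α is an extrapolation. Concentration
units (nM for protein, µM for nucleotide) are carried explicitly and never
converted. For titrations where the effector *suppresses* unfolding (e.g.
ADP), the positive lobe of the subtraction sits at high FRET and tracks the
refolded population; the fit is identical and the series carries a
`folding` mode label.

## Replicates and problem sizes

A single imaging field holds ~250 molecules. One field per concentration
gives σ(K_eq) ≈ 65 nM on a 305 nM titration — far coarser than the ±16 nM
scale of reported fits. Reported error bars come from the spread of multiple
data sets per condition, so the pipeline's default experiment design
simulates **10 fields of 250 molecules per concentration** (30-frame short
movies, 20 frames pooled); fitted-parameter uncertainties then sit at the
reported scale (σ_α ≈ 0.8 points, σ(K_eq) ≈ 5 nM on the ADP-state design).
The acceptance script and the end-to-end tests use these sizes; they run in
seconds per titration on one CPU.

## Degenerate inputs and tie-breaks

- Frames with non-positive total intensity yield E = 0, never NaN, and are
  past the usable range in practice.
- Histogram values outside [−0.2, 1.2] are clamped into the edge bins so
  normalization is exact to 1e-9.
- `threshold_population` handles the bin straddling the cutoff pro-rata,
  removing bin-edge aliasing.
- Gaussian level fits initialize from a weighted two-means split of the
  occupied bins, with σ bounded to [0.01, 0.3]; non-convergence raises an
  error carrying the last iterate and residual.
- `relative_change` rounds half-away-from-zero when formatting (40 → 47 is
  a +18 % change); `fold_change` formats to one decimal.

## Known limitations

- The proximity ratio is used as-is; absolute E levels would shift under
  gamma/crosstalk correction, but generator and analyzer share the
  convention, so recovered populations and K_eq are unaffected.
- The subtraction score's overlap loss means saturation amplitudes are
  lower bounds on the true occupancy change (see above); comparisons
  *between* conditions analyzed the same way remain valid.
- Dynamic-mode traces are qualitative; no hidden-Markov idealization or
  dwell-time analysis is provided.
- The generator's contaminant taxonomy (aggregates, donor-only) is a
  minimal model of what the filter must reject, not a complete photophysics
  of bad spots.
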