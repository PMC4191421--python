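# gqfret

Quantification pipeline for single-molecule FRET (smFRET) assays of
protein-mediated G-quadruplex (GQ) unfolding, with a seeded synthetic trace
generator for end-to-end validation.

## The problem

G-quadruplexes are four-stranded DNA structures that form in guanine-rich
regions (telomeres, promoters) and must be resolved by proteins for
replication and transcription to proceed. In a prism-TIRF smFRET assay, a
surface-tethered partial-duplex DNA carries an intramolecular GQ and a
single-stranded overhang; a donor/acceptor pair reports the conformation
through the FRET efficiency (proximity ratio)

    E_FRET = I_A / (I_A + I_D).

Folded GQ shows high E_FRET (two conformers in K⁺ at ≈0.64 and ≈0.78);
unfolded DNA sits at ≈0.40 and helicase-bound unfolded DNA at ≈0.20. Titrating
a RecQ-family helicase (or a nucleotide cofactor at fixed helicase) shifts
population from the folded to the low-FRET class. The pipeline quantifies
that shift the way such experiments are analyzed:

1. **Trace processing** — background subtraction, screening to single
   molecules (intensity band, single-step donor photobleaching, donor-only
   rejection), per-frame E_FRET.
2. **Histogram subtraction** — per-condition E_FRET histograms normalized to
   100 % of the molecule population; the zero-effector reference histogram is
   subtracted, leaving balanced positive (unfolded/bound) and negative
   (folded) lobes; the **cumulative positive area** is the unfolded
   population in percent. A thresholded integral (E_FRET ≤ 0.40) and Gaussian
   level fitting are provided as complementary scores.
3. **Weighted Langmuir fit** — the unfolded percent *y* versus effector
   concentration *x* is fitted with the binding isotherm

       y = α·x / (x + K_eq),

   minimizing Σ((yᵢ − y(xᵢ))/σᵢ)²; α is the saturating unfolded population
   (percent) and K_eq the half-saturation concentration. Parameter 1-σ errors
   come from the covariance at the optimum.

Because no raw instrument data are publicly deposited for this kind of assay,
the package ships a first-class synthetic generator (`gqfret.simulate`) that
emulates the assay's statistics — Gaussian spectroscopic states under a
Langmuir occupancy law, per-molecule brightness spread, channel noise,
single-step photobleaching, aggregate and donor-only contaminants — so every
stage is testable against known ground truth.

## Worked example

Simulate a helicase titration (nucleotide-free state: α = 49 %,
K_eq = 305 nM, ten 250-molecule imaging fields per concentration), run the
full analysis and fit the isotherm:

```python
import gqfret as g

params = g.IsothermParams(alpha=49.0, k_eq=305.0, units="nM")
occupancy = g.OccupancySpec(
    params, g.folded_states_potassium(), g.default_low_states()
)
config = g.SimulationConfig(
    condition=g.Condition(protein=g.Protein.BLM),
    occupancy=occupancy,
    seed=42,
)
datasets = g.simulate_titration(
    config, [0, 50, 100, 300, 500, 1000, 2000], n_fields=10
)
series, _ = g.titration_series_from_datasets(datasets)
fit = g.fit_langmuir(series)
print(g.format_report(fit, series))
```

prints

```
Langmuir isotherm fit: y = alpha*x/(x + K_eq)   [unfolding]
effector: protein_conc (nM)
reference: (zero-effector state)

alpha = 44.3 +/- 2.9 %
K_eq  = 305 +/- 49 nM
chi2  = 1.02 over 6 points

        x (nM)    y (%)    err      fit
             0     0.00   1.00     0.00
            50     6.34   1.59     6.23
           100    11.23   1.14    10.93
           300    22.35   1.47    21.96
           500    26.01   1.73    27.51
          1000    34.34   2.62    33.95
          2000    39.20   2.37    38.44
```

The half-saturation concentration is recovered essentially unbiased
(305 ± 49 nM here against the configured 305 nM). The saturation amplitude
comes back a few points below the configured occupancy (44.3 vs 49 %): the
positive-area score loses the part of the unfolded Gaussian that overlaps the
folded reference distribution (an intrinsic property of the subtraction
method, about 6 % with these state widths — see `docs/methods.md`).

The same run is available from the shell via a YAML config:

```bash
gqfret simulate --config run.yaml --seed 42
gqfret analyze  --config run.yaml
gqfret fit      --config run.yaml
gqfret report   --config run.yaml
```

which writes trace tables, histogram/difference CSVs, the unfolded-percent
table, the fit JSON and a text report under the configured run directory.

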