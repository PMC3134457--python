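# weevilwalk

Habitat-dependent dispersal-kernel analysis of walking-insect movement.

Banana weevils (*Cosmopolites sordidus*) are flightless, nocturnal insects
that walk between banana mats, crop-residue litter, bare soil and drainage
ditches.  Radio-tracking such a cohort yields daily relocations on a
lattice of 1-m² habitat cells, and the question this package addresses is
whether the insect's *dispersal kernel* — the decay of movement
probability with distance — depends on the habitat it is leaving, or only
on where it could go.

## Model

Daily movement is a first-order Markov chain on cell centres.  The
probability of moving from cell *i* (habitat *h_i*) to cell *j* in one day
is a discrete-choice kernel over all *n* cells of the plot:

```
p_ij = α_{h_j} · exp(−β_{h_i} · d_ij) / Σ_k α_{h_k} · exp(−β_{h_i} · d_ik)
```

* `α_h ≥ 0` — attractiveness of arrival habitat *h*, identifiable only up
  to scale and therefore fixed on the simplex `α_P + α_C + α_B + α_D = 1`;
* `β_h ≥ 0` (per metre) — kernel shape for departures *from* habitat *h*;
  large `β_h` concentrates the kernel, so `β` acts as a per-habitat
  sedentariness coefficient (sojourn time in a cell is geometric with mean
  `1/(1 − p_ii)`);
* `d_ij` — Euclidean distance between cell centres (`d_ii = 0`).

The habitat-independent null family (M0) constrains all `β_h` equal; the
habitat-dependent family (MG) lets `β` vary with departure habitat.
Habitat groupings of α and β define a nested model family (M04, MG4,
M03/MG3 with P+C or B+D pooled, M02/MG2, MG1) compared by likelihood-ratio
tests, and the winning model is validated by pattern-oriented modelling
(POM): simulate the released cohort forward and check that it reproduces
(a) the per-plot proportion of individuals staying in their release cell
and (b) the distribution of one-day dispersal distances.

## Layout

* `src/weevilwalk/` — the library: `lattice` (habitat rasters, geometry),
  `kernel` (transition model, model specs), `inference` (step extraction,
  likelihood, Nelder–Mead MLE, LRT), `simulate` (individual-based walks,
  detection thinning), `pom` (patterns, χ² and Kolmogorov–Smirnov tests,
  figures), `synthetic` (study-system generator), `cli`/`config`
  (command line, plain-text I/O).
* `analysis/` — numbered drivers that run the study end to end and write
  tables and figures under `results/`.
* `docs/methods.md` — model, assumptions, numerical choices, limitations.

## Worked example

```
python analysis/01_synthesize_study.py
python analysis/02_fit_model_family.py
python analysis/04_pom_validation.py
```

`01` generates the default synthetic study — five plots of 800–2400 cells
(two dominated by bare soil, three rich in host plant and residue), 1200
individuals released uniformly, 10 days of daily relocations thinned by a
50–80% per-plot recapture rate — from seed 0, and prints:

```
five plots, cohort 1200, horizon 10 d, recapture (0.5, 0.8)
  plot1: 30×34 cells, {'P': '5%', 'C': '4%', 'B': '85%', 'D': '6%'}
  ...
observed 8427/13200 relocation records (64% daily detection incl. releases)
```

`02` extracts the 3436 one-day steps from the first tracking week, fits
the nine canonical models and tests nested pairs:

```
  M04      df=4  -2logL=  10854.4  converged=True
  MG4      df=7  -2logL=  10437.2  converged=True
  ...
habitat dependence: chi2_3 = 417.21, p <0.001
```

so on data generated with a habitat-dependent kernel the habitat-
independent null is rejected overwhelmingly, as it should be.  `04`
re-simulates 100 runs of the cohort from each refit and compares the two
POM patterns per plot; the M04 refit misses the stay proportion on a
suitable-habitat plot (χ² p = 0.0054) and the distance distributions on
plots 3 and 5 (KS p < 0.001), while the MG4 refit reproduces every
pattern (all χ² p ≥ 0.02, all KS p ≥ 0.79).

The command-line interface exposes the same stages
(`weevilwalk synth | fit | simulate | validate`).

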