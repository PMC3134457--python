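# Methods

## Movement model

An individual's daily position is a first-order Markov chain on the
centres of 1-m² habitat cells.  Each cell carries one of four mutually
exclusive habitat types: host plant (P), crop residue (C), bare soil (B),
ditch (D).  The one-day transition probability from cell *i* to cell *j*
is

    p_ij = α_{h_j} exp(−β_{h_i} d_ij) / Σ_{k=1..n} α_{h_k} exp(−β_{h_i} d_ik)

with the normalization running over all *n* cells of the plot, including
*j = i* (where `d_ii = 0`, so the self-stay weight is `α_{h_i}`).

Assumptions: individuals move independently of each other (no social
structure); moves are memoryless (first-order Markov — defensible for an
animal that rests by day and moves by night); parameters are constant over
time and shared across plots; movement is isotropic (distance enters the
kernel, direction does not).

Parameters and units:

| parameter | meaning | constraint | default (generator truth) |
|---|---|---|---|
| `α_h` | attractiveness of arrival habitat *h* | `Σ α_h = 1`, `α_h ≥ 0` | 0.545 / 0.404 / 0.036 / 0.014 (P/C/B/D) |
| `β_h` | kernel shape for departures from *h*, per metre | `β_h ≥ 0` | 2.01 / 2.11 / 1.14 / 0.71 (P/C/B/D) |

The simplex constraint on α is an identifiability device, not a model
restriction: every `p_ij` is invariant to a common rescaling of all α
(tested).  Reported group-level α under a habitat grouping is the block
*sum* of the per-habitat base values (e.g. `α_{P+C} = α_P + α_C`), except
that the single-block model reports the per-habitat value (0.25); both
representations appear in the comparison table, labelled
`alpha_<block>` and `alpha_per_habitat_<block>`.

Sojourn time in a cell is geometric on {1, 2, …} with continuation
probability `p_ii`, hence mean `1/(1 − p_ii)` days (infinite sojourn in an
absorbing cell is returned as `inf`, flagged, not an error).

A continuum approximation isolates the role of β on a large
uniform-attractiveness lattice: replacing the normalizer `Σ_k exp(−β
d_ik)` by `1 + ∫ 2πr e^{−βr} dr` gives `p_ii ≈ 1/(1 + 2π/β²)`.  This is a
reconstruction used only as a numerical cross-check of the exact lattice
computation, never in inference.  Its discretization error grows with β
(the integrand concentrates within a few cell widths): against the exact
stay probability at the centre of a 101×101 uniform plot the relative
error is ≈3% at β = 0.5, ≈11% at β = 1, ≈22% at β = 2, vanishing as
β → 0; the tests assert exactly this measured envelope.

## Nested model family and inference

A model spec is a pair of partitions of {P, C, B, D}: habitats in one α
(resp. β) block share one value.  Free parameters = #β blocks + (#α
blocks − 1).  The canonical family mirrors the published comparison: M04
(4), MG4 (7), M03/MG3 with P+C pooled (3/5), M03/MG3 with B+D pooled
(3/5), M02/MG2 (2/3), MG1 (1).

Only relocation pairs separated by exactly one day, with the arrival day
at most 7 days after release, enter the likelihood; longer gaps contribute
nothing (whether unobserved non-moves across gaps should contribute is
undecidable from the extraction rule; they are excluded).  The
log-likelihood decomposes into sufficient statistics — arrival-habitat
counts, total step distance per departure habitat, and normalizers at the
distinct departure cells only — which is what makes full-scale fits cheap.

Maximisation is Nelder–Mead (the method the original analysis used) on
unconstrained coordinates: log β per block, and an additive log-ratio
transform for the α blocks (last block as reference), which enforces
positivity and the simplex exactly without penalty terms.  Defaults: 10
jittered restarts, objective tolerance 1e-8, β confined to
[1e-4, 50] m⁻¹.  Replicated experiments in the tests use 1–2 restarts at
tolerance 1e-6/1e-7; spot checks on the hardest replicates show the full
settings land on the identical optimum, so the cheaper settings change
nothing but runtime.  If the profile towards a β bound is flat (data with
no movement, or a habitat never departed from), the fit is reported at the
bound and flagged `at_beta_boundary`; non-convergence is flagged, never
raised.  A slightly negative LRT statistic (optimizer noise on the nested
pair) is clamped to zero with a warning.  p-values are exact in machine
output and printed as `<0.001` below that threshold.

## Synthetic study system

The generator emulates the study conditions: five plots of 800–2400 cells
— two dominated by bare soil (~85% B), three rich in suitable habitat,
with host plants in staggered or irregular double rows, litter grown
adjacent to plants, and full-length ditch lines — a cohort of 1200
individuals released uniformly at random (the original release design is
unstated), 10 days of daily positions, and per-plot daily recapture drawn
from 0.5–0.8.  Layouts are stylized: the fidelity target is composition
(achieved within ±3 percentage points, enforced exactly by flipping
random bare-soil cells after structural placement) and qualitative
geometry, not any particular field.  At these conditions a cohort of
1000–1200 yields ~3100–4000 usable one-day steps, the order of the
original data set.

The walker uses the same transition-row code as inference (one
implementation, no drift), with one RNG stream per (run, individual)
keyed by a stable hash of the individual id, so subsetting or reordering
individuals never perturbs anyone else's path; output is bit-identical
per seed.  What the generator does *not* emulate: tag failure, the 30-cm
pre-rounding position noise, sex or social structure, births/deaths, or
any real-data deviation from the Markov model itself.  Passing recovery
tests therefore demonstrate that the inference machinery is correct and
well calibrated at the study's scale — not that the model is true of real
weevils.

## Pattern-oriented validation

Two patterns per plot discriminate the families: the proportion of
individuals never observed off their release cell within the 10-day
horizon (one-sample χ² of stay/leave counts against the across-run mean
simulated proportion, df = 1, no continuity correction), and the one-day
step-length distribution (two-sample Kolmogorov–Smirnov of observed steps
against steps pooled across 100 simulation runs; the across-run summary
for plotting is the mean with the 2.5–97.5% quantile band).  Dispersal
distance defaults to per-day step lengths, zero-length steps included; a
config switch offers net displacement from release instead.
Direction-of-movement and mean-squared displacement are deliberately out
of scope.

Observed tracks are detection-thinned, and an individual that moved while
undetected is scored as a stayer, so comparing them against *full*
simulated trajectories inflates the observed stay proportion
systematically — enough to fail the χ² under the true generating model.
POM comparisons therefore thin the simulations with the per-plot daily
recapture probability estimated from the observed tracks (fraction of
post-release record-days observed) before computing patterns, so both
sides see the same observation process.  The CLI exposes this as
`--detection matched|none`.

## Problem sizes in replicated experiments

Parameter recovery: 20 replicates at the study scale (5 plots, 1000
individuals, 7-day window).  LRT type-I calibration: 200 replicates on a
reduced two-plot system (12×14 cells each, one bare-dominated and one
suitable-rich, cohort 80, recapture 0.65) — the null distribution of the
statistic does not depend on scale, so the small system is used for
replication throughput.  POM discrimination: the full five-plot study,
100 runs per family.

## Known limitations

* β for rare departure habitats is weakly identified: ditch cells are ~6%
  of the lattice and nearly unattractive (α_D ≈ 0.014), so a one-week
  study yields only ~30–45 detected ditch departures and `SE(β̂_D) ≈ 0.08`
  at truth 0.71.  Recovery experiments show all other parameters land
  well inside ±0.05 (α) / ±15% (β); β_D misses the ±15% band in roughly
  one replicate in five purely through sampling noise.
* The LRT relies on standard χ² asymptotics; the α simplex boundary is
  never active in practice here (all habitats are visited), but fits with
  `at_beta_boundary` set should not be fed into the test.
* Distances are lattice-discrete, which ties the KS statistic; ties make
  the test conservative (measured null rejection ≤5% at nominal 5%),
  never anti-conservative.
* Habitat mosaics are static over the 10-day study; crop practice changes
  or flooding of ditches would violate time-homogeneity.
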