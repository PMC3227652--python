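# Methods

## The model

`smadscreen` implements a deliberately minimal, two-compartment ODE model of
canonical TGF-β signaling centred on the I-Smad negative feedback. The
state comprises 17 species: the receptor in four states (free `R`,
ligand-bound `LR`, active `LRa`, I-Smad-sequestered `LRaI`), R-Smad,
phospho-R-Smad and Co-Smad monomers in cytoplasm and nucleus, phospho-R-Smad
homodimers and phospho-R-Smad/Co-Smad heterodimers in both compartments,
I-Smad mRNA in both compartments, and free I-Smad protein. All reactions are
mass action except I-Smad transcription, which is a Hill function of the
nuclear heterodimer:

    v_txn = k14 · H_n^h / (k15^h + H_n^h)

Receptor, R-Smad and Co-Smad enter through conserved totals (defaults
R_tot = 1 nM, S_tot = 60 nM, C_tot = 100 nM) instead of synthesis/turnover;
ligand is a boundary condition that is never depleted. Receptor trafficking,
ligand degradation and explicit cross-talk reactions are deliberately out of
scope — cross-talk is representable only as changes in effective rate
constants.

Model assumptions where the network diagram leaves freedom:

* monomeric Smads shuttle with import `k8` and export `k9`; dimers import
  with `k12` and do not export (complex formation retains Smads in the
  nucleus);
* one shared formation rate `k10` and dissociation rate `k11` for homo- and
  heterodimers;
* dephosphorylation (`k13`) acts only on monomeric nuclear phospho-R-Smad;
  dimers must dissociate first. This makes the composite
  D = k8·(k11·k13)/k10 a natural "deactivation speed";
* only the nuclear heterodimer drives transcription; homodimers are inert;
* `k19` degrades free I-Smad only; receptor sequestered in `LRaI` is
  released solely through `k6`;
* compartments have equal effective volumes (no volume ratio is modelled),
  so conservation sums are unweighted;
* the Hill coefficient defaults to h = 2 (moderate cooperativity of the
  Smad-complex-driven promoter) and is held fixed during screens.

Units are nM and seconds internally; ligand protocols are specified in pM
and the reported output (nuclear heterodimer) is in pM.

## Simulation protocol

Every simulation runs in two phases: (1) 1 h equilibration at 10⁻⁶ pM
ligand starting from all receptor free and all Smad/Co-Smad cytoplasmic
and unphosphorylated; (2) the stimulus protocol from the phase-1 endpoint
(constant 200 pM for 10 h by default; a 12-point dose series; or a
triangular 0 → 720 pM → 0 profile over 10 h). Integration uses a stiff
variable-step solver (LSODA). Defaults are rtol = 1e-8, atol = 1e-12 nM;
Monte-Carlo screens use an explicit `SolverOptions.screening()` preset
(rtol = 1e-6, atol = 1e-10) because every classification threshold lives at
the pM = 1e-3 nM scale, four decades above that atol, and labels are
insensitive to the difference while screens run several-fold faster.
Solver failures are flagged per record and never abort a screen. Output is
sampled every 60 s.

An independent fixed-step RK4 integrator serves as a cross-check oracle.
Being explicit, it is only valid where the fastest linearized rate is
moderate; a conservative stability bound raises an error (rather than
silently producing garbage) when the required step would fall below 2 ms,
and randomly drawn sets outside that domain are skipped in oracle
comparisons.

## Response classification

A trace is `unresponsive` when its peak stays below θ = 10 pM within the
10 h window. Responsive traces are:

* `sustained` — 90% of the peak `Opeak` reached within 2 h and retained
  through 10 h;
* `transient` — output falls below 10% of `Opeak` within 2 h of
  stimulation onset and ends below 0.1·θ;
* `dampened_oscillatory` / `sustained_oscillatory` — at least four
  post-initial-peak amplitudes (local max minus preceding local min)
  exceed 0.1·θ. Peaks are numbered from the initial peak; the sub-label
  compares the amplitude of peak 5 against half that of peak 2 (the
  initial peak is excluded from the comparison because it can be
  disproportionately high);
* `undefined` — responsive but none of the above. The criteria are strict
  by design, so this is the largest class in screens.

Checks run in the order unresponsive → sustained → oscillatory →
transient; a high trace with sub-10% ripples is sustained, and the
oscillation test precedes the transient test. Ties at the 90%/10% levels
resolve toward the stricter criterion with a 1e-9 relative comparison
tolerance. Local extrema are strict; exact-plateau runs are merged to
their midpoint. No smoothing is applied (solver output is smooth) and no
frequency-domain detection is attempted.

If oscillations are still above the amplitude floor at 10 h, the horizon
doubles (up to 100 h) until they vanish, so slow oscillations acquire
their five peaks and the period does not bias the sub-label. The period is
estimated as the median spacing of all post-initial peaks — the amplitude
floor gates counting, not timing — and the duration is the time of the
last above-floor peak. In this implementation a 10× dose change shifts the
period by a few percent while the amplitude envelope changes several-fold;
"period invariance" is therefore tested at 10% with an amplitude contrast
an order of magnitude larger.

For multi-condition scans (dose series, protein-concentration series) the
threshold convention switches to *series mode*: θ is the trace's own peak,
making all sub-criteria purely relative, and responsiveness instead
requires the peak to clear an absolute floor of 0.1 pM that rejects
numerically zero traces. Per-trace θ was chosen over an across-series
maximum so each condition is judged on its own shape; the alternative is a
one-line config change.

## Parameter screening

Each rate constant is drawn as 10^U, U uniform between the log bounds of
its range. The full draw matrix comes from one seeded generator before any
simulation, so parallel execution cannot change results. The shipped
default range table is a reconstruction: the published supplementary table
behind the original screen is not available, so midpoints were set once
from the modelling literature the model descends from (nucleocytoplasmic
shuttling ≈ 3×10⁻³ s⁻¹, dimer on/off ≈ 2×10⁻³ nM⁻¹s⁻¹ / 1.6×10⁻² s⁻¹,
nuclear phosphatase ≈ 5×10⁻³ s⁻¹, receptor–ligand Kd ≈ 100 pM, mRNA and
protein half-lives of order hours) and spans follow the stated design:
3–4 decades for most rates, 5 for the poorly constrained transcription
parameters k14/k15, and 2 for k7/k13 (wider spans make extreme
phosphorylation/dephosphorylation imbalances dominate solver failures).
Every analysis accepts a user-supplied range table, so published ranges
can be dropped in verbatim; provenance is tracked per entry.

Derived per-set features:

* feedback strength F = (k14·k18)/(k15·k17·k19) · (k5/k6)
* dephosphorylation speed D = k8·(k11·k13)/k10
* I-Smad turnover T = k16·k17·k19

Failed simulations keep their own label and stay in the denominator of all
fractions.

## Downstream analyses

**Concentration switching.** Conserved totals of one species are scaled
(100-fold down/up, or on the 3ⁿ grid, n = −4…4); phase-1 equilibration is
re-run at each scaled total (the alternative — rescaling the phase-1
endpoint — was rejected as physically inconsistent with conservation). A
switch is specifically transient at one concentration and sustained at
another; other label changes are recorded but not counted. The
"restricted ranges" that enrich switching are reconstructed at run time as
the per-parameter 10–90% log-quantile envelope of the transient cohort of
a pilot screen, on the rationale that switchable sets must sit near the
transient/sustained boundary; the published restricted table is not
available.

**Dose–response.** Peaks across the dose grid (default: the 12 printed
doses, 0.2–2000 pM) are fit by constrained least squares to
Opeak(x) = max(Opeak)·(1 − exp(−x/η)), initial guesses η = median dose and
max = largest observed peak, both parameters positive. An all-zero peak
series is refused, not fitted. Dose-induced label changes are counted
between *defined* responsive types (a set drifting into `undefined` or
`unresponsive` at extreme doses is not a type change). The bimodal
sub-structure of the sustained η distribution is emitted as data but not
tested — its modes depend on the unavailable published ranges.

**Faithfulness.** Sets that respond sustainedly to constant ligand are
re-simulated under the triangular input; input and output are linearly
interpolated onto a shared 60 s grid over 10 h, each normalised by its own
maximum (so any proportionality constant cancels), and
R = Σⱼ (inputⱼ − outputⱼ)². The lowest/highest residual deciles
(`floor(n/10)` each, stable ties) are labelled faithful/unfaithful; if all
residuals are equal the deciles are degenerate and nothing is labelled.

## Synthetic fixtures

Closed-form trace families (saturating exponential, biexponential pulse,
damped raised-cosine, triangular ramp, constant) make the classifier and
downstream analyses testable without the ODE model; each family's label is
implied analytically by its shape parameters. Fixture *parameter* sets —
one per simulated response family — were found once by rejection sampling
the default ranges (an oscillation-biased sub-range for the rare
oscillatory family), confirmed against the RK4 oracle, and frozen as
plain-text files; the search script ships in `scripts/find_fixtures.py`
but is not run at test time. The generators emulate noiseless solver
output only; nothing here models measurement noise, cell-to-cell
variability or receptor trafficking, so passing tests validate the
pipeline's logic and numerics, not biological realism of any single
parameter set.

## Problem sizes and what the test suite shows

The original full screen (10⁶ sets) is far beyond a desk run; this package
runs its analyses at reduced scale as its own design choice: 3000 sets for
the fraction/cohort screen, 20000 for the oscillation-rarity screen, 1000
sets × 12 doses for dose stability, 300–400 sets for the switch screens.
At these sizes the published percentages are checked as orderings and
orders of magnitude, and cohort segregations as one-sided rank tests at
α = 0.01 — under a reconstructed range table the exact fractions are not
reproducible, and they shift with any defensible re-derivation of the
ranges.

## Known limitations

* The default range table is a literature-scale reconstruction, not the
  published one; fractions match the published screen in ordering and
  order of magnitude, not digit-for-digit. Concretely, at desk scale the
  unresponsive and sustained fractions come out statistically tied
  (~12% each) rather than clearly ordered, and full-range
  concentration switching sits near 2% for the Smad species rather than
  below 1%.
* With the default ranges and h = 2, sustained oscillations (amplitude of
  peak 5 ≥ half that of peak 2) are at best extremely rare; only dampened
  oscillations are reliably observed at desk scale. The oscillatory
  cohort found here is dominated by large-output damped ringing, so while
  its fast-I-Smad-turnover signature is very strong, its low-k2 signature
  is weaker than a strict α = 0.01 rank test at ~30 oscillatory sets.
* The faithful decile of the triangular-input analysis is selected mainly
  by avoided saturation (low k2 and k7); its composite feedback strength
  F is not low — the realized feedback gain depends on the operating
  point H_n/k15, which the scalar F does not capture.
* SBML support is export plus read-back of the exported parameters;
  importing arbitrary third-party SBML models (and overriding the wiring
  from a file) is not implemented.
* The model omits receptor trafficking and ligand depletion by design;
  conclusions about transient signaling generated by those mechanisms are
  out of scope.
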