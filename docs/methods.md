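# Methods

## Scope and model structure

`sirnatraffic` models receptor-mediated delivery of siRNA by a
monovalent protein carrier, with silencing read out as normalized
expression of a destabilized reporter. The system is deterministic mass
action over a well-mixed medium shared by `N_cells` identical cells;
each cell has an endosomal and a cytoplasmic compartment. Free siRNA
(`S`), free carrier (`C`) and the 1:1 complex (`X`) are tracked
separately everywhere because their fates differ: only carrier-containing
species bind receptor (the carrier provides targeting; free siRNA enters
only by optional fluid-phase uptake `k_pino`, default 0), and only free
cytoplasmic siRNA loads RISC.

Reactions, by compartment:

- **Medium (molar):** `S + C <-> X` with `kon_s`, `koff_s`. Carrier and
  complex bind surface receptor with apparent monovalent rates `kon_r`,
  `koff_r`. Conversions between per-cell amounts and medium molarity use
  `N_cells / (N_A * V_media)`.
- **Surface (molecules/cell):** bound receptor internalizes at `k_int`
  and recycles — a net-internalization description in which
  `R + RC + RX (+ R_cmp) = R_tot` holds exactly. Internalized cargo
  lands in the endosome.
- **Endosome (molecules/cell):** binding re-equilibrates with the same
  `kon_s` scaled to amount space (`kon_s / (N_A * V_endo)`); all three
  species escape at the same first-order `k_esc` (the pore-based escape
  route is wide enough for intact complexes — this asymmetry, escape of
  complex but loading only of free siRNA, is what produces the
  sequestration penalty at extreme affinity) and degrade at
  `k_deg_endo`.
- **Cytoplasm (molecules/cell):** re-equilibration at
  `kon_s / (N_A * V_cyt)`; degradation per species (`k_deg_s_cyt`,
  `k_deg_x_cyt` — destroys both partners, `k_deg_c_cyt`); RISC loading
  `k_load * S_c * (RISC_tot - RISC_a)`; active RISC decays at
  `k_risc_decay` (guide lost). mRNA: synthesis `k_txn`, basal decay
  `k_deg_m`, catalytic cleavage `k_slice * RISC_a * M`. Protein:
  `k_tln * M - k_deg_p * P`.
- **Sinks:** every degradation flux that destroys an siRNA equivalent
  (endosomal `S_e`/`X_e`, cytoplasmic `S_c`/`X_c`, RISC decay)
  accumulates in `d_sink`; siRNA removed by the media swap accumulates
  in `w_sink`. `mass_balance_residual` checks
  `total(t) + d_sink + w_sink = total(0)` over the whole grid.

A soluble receptor competitor is modeled as a monovalent binder
(`kon_cmp`, `koff_cmp`) that occupies receptor, internalizes at `k_int`
and returns the receptor while carrying nothing measurable. An optional
growth-dilution rate `k_dil` (default 0) applies to all intracellular
species; the default 24 h horizon with a destabilized reporter does not
need it.

**Protocol events.** A run starts with the dose pre-equilibrated at the
stated carrier:siRNA mixing ratio via the exact quadratic equilibrium
(an all-complex start is available with `preequilibrate=False`), the
cell naive (`R = R_tot`, reporter at steady state `M = k_txn/k_deg_m`,
`P = k_tln*M/k_deg_p`). At `t_transfect` (default 6 h) the medium is
replaced: extracellular pools are zeroed, the removed siRNA is booked to
`w_sink`, and the integrator restarts from the post-event state.
Surface-bound material subsequently re-dissociates into the fresh
medium, which is physical and conserved.

**Numerics.** LSODA with relative tolerance 1e-8 and per-species
absolute floors (1e-15 M for molar entries, 1e-3 molecules otherwise);
hard restart at the media swap; values below zero are clipped to zero,
with a warning only beyond max(1e-12 of the species scale, 10x the
absolute tolerance) — tiny negative excursions below the solver's own
resolution are expected and harmless. The conservation and
equilibrium-relaxation checks bound the integration error empirically
(residuals ~1e-13 at defaults, versus acceptance gates of 1e-6/1e-5).

## Default parameters

Defaults describe an EGFR-rich epidermoid carcinoma line
(`R_tot = 2e6`, `k_int = 1e-3 s^-1`, receptor KD 1 nM), a standard
96-well format (`V_media = 100 uL`, 1.5e4 cells), and literature-scale
RNAi constants (`RISC_tot = 1e4`, `k_load = 1e-4 molecule^-1 s^-1`,
mRNA half-life 4 h with steady state 500 copies, reporter protein
half-life 2 h). They are configuration defaults, not measurements.

Values the design left open were fixed once, with these rationales:

- `k_esc = 5e-4 s^-1` (escape half-time ~23 min): a potent pore-forming
  disruptor acts fast relative to the 6 h exposure; this is also the
  parameter `fit_escape_rate` estimates from data, so the default only
  anchors forward simulations.
- `k_deg_x_cyt = 1e-6 s^-1` << `k_deg_s_cyt = 1e-4 s^-1`: the carrier
  end-caps the duplex and shields it from cytoplasmic nucleases, so
  sequestered siRNA persists — sequestration delays rather than destroys
  it, and the potency cost of extreme affinity comes from the release
  time (`1 - exp(-koff * t)`), not from accelerated loss.
- `k_slice = 1e-7 molecule^-1 s^-1`: half-maximal mRNA knockdown at
  ~500 active RISC, i.e. well below the RISC pool, so dose-response
  curves traverse their transition inside the simulated dose range.
- `k_tln = 0.05 s^-1`: sets the protein scale only; the normalized
  readout is exactly invariant to `k_txn`/`k_tln` rescaling (mRNA and
  protein are linear in both), which is property-tested.
- Competitor rates `1e5 / 1e-4` (KD 1 nM): an engineered receptor
  binder comparable to the carrier's targeting arm.

## Inference procedures

**Escape rate.** `fit_escape_rate` minimizes, over `log10 k_esc` by
bounded scalar search, a joint objective combining uptake residuals in
log-molecule space and silencing residuals in linear normalized space.
Each stream is divided by its point count and by its residual scale at
the best point of a coarse one-decade scan, so neither stream dominates
regardless of units. A scan objective flat over the bounds — e.g.
uptake-only data when all intracellular sinks are off, so the intact
total is fixed by influx alone — is flagged unidentifiable rather than
returning an arbitrary minimizer. The reported uncertainty is a
curvature-based standard error on `log10 k_esc`.

**Affinity sweep.** `affinity_sweep` fixes `kon_s` (default
1e5 M^-1 s^-1, a standard biomolecular on-rate) and varies `koff_s`
over a log grid (default 25 points across 1e-7..1 s^-1). Each point gets
a simulated dose-response (shared zero-dose control) and a 4PL-extracted
EC50, mirroring the plate-assay analysis; the optimum is the grid
minimizer refined by a log-parabola through its neighbors. Regime labels
per point: *sequestration-limited* when more than half of cytoplasmic
siRNA is carrier-bound at the EC50 dose at readout;
*uptake-saturated* when the local slope `d log(uptake) / d log(koff)`
of a companion 6 h uptake series exceeds -0.05; otherwise
*uptake-limited*. The uptake series is taken at the top of the dose
grid — a saturating dose — because uptake/potency decoupling is a
statement about saturated uptake; EC50, by contrast, probes doses far
below that, where complexation is still affinity-limited. That
separation of scales is exactly why an intermediate flank exists in
which uptake no longer responds to `koff` while EC50 still improves.

One idealized property does **not** hold in this model and its test is
expected to fail: making RISC loading effectively instantaneous does not
flatten the tight-binding flank of the EC50 curve. At the default
loading rate (`k_load * RISC_tot ~ 1 s^-1`) loading already outruns
cytoplasmic rebinding by orders of magnitude, so raising `k_load`
changes nothing measurable; the tight-binding penalty is the release
step itself (`koff * t_obs << 1` at the low end of the grid), which no
downstream rate can remove. The same release bottleneck is what creates
the interior optimum, so "interior optimum exists" and "fast loading
removes the tight-binding penalty" cannot both hold. The directional
claims that are true — faster loading never hurts potency, and the
optimum does not move toward weaker binding — are asserted instead in
the unit suite.

**Competition.** `competition_curve` simulates the blocking titration
(default 20 nM complex, competitor 0..4 uM), emitting paired
internalized-siRNA (end of exposure) and normalized-expression series;
`per_sirna_potency()` re-sorts them into expression versus delivered
count. At the default dose the silencing branch stays saturated until
uptake falls below the RISC-saturating level (~1e4/cell), which the
packaged example points out.

## Synthetic data

Generators are pure functions of (truth, design, seed); identical seeds
reproduce datasets bit for bit. Noise is unit-mean lognormal
(multiplicative, CV per assay: 2% biosensor, 3% titration, 5% cell
assays) with an optional additive floor — the error structure of plate
readers and cytometers. Cell-assay generation applies the measurement
chain in reverse: simulated molecule counts become fluorescence via the
inverse bead-calibration line, knockdown becomes target-gene Ct via the
inverse comparative-Ct transform, normalized expression becomes raw
plate fluorescence via background/control levels. Every dataset carries
a truth sidecar; tests read truth from sidecars only.

What the generators deliberately do not emulate: instrument artifacts
(sensor drift steps, plate-edge effects, cytometer gating), biological
cell-to-cell heterogeneity, and replicate-level batch structure beyond
i.i.d. noise. Passing recovery tests therefore demonstrates estimator
correctness and precision under the stated noise model, not robustness
to real-instrument systematics.

## Known limitations

- Single well-mixed endosomal compartment: no maturation cascade or
  endosome-population heterogeneity; `k_esc` is an effective rate.
- Monovalent receptor engagement with constant surface receptor; no
  receptor down-regulation over the 6 h exposure.
- The RNAi module is a deliberately small two-state (mRNA, protein)
  description with catalytic cleavage; no RISC turnover saturation
  beyond the finite pool, no transcriptional feedback.
- Parameter defaults are plausible magnitudes; absolute EC50 values
  (~10 pM at defaults) track those choices and should be read as
  model-relative, with the off-rate *dependence* — the package's
  subject — being the robust output.
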