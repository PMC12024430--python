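# Methods

## The model in one paragraph

`flashrod` treats a cell as a homogeneous, aerated aqueous medium and asks
how much dissolved oxygen a single instantaneous (Dirac) pulse of low-LET
protons consumes, and through which chemistry. A pulse of *N* parallel
300-MeV protons (LET 0.3 keV/μm) crosses a 0.1 μm × 1 μm water cylinder;
every track deposits LET·L of energy, giving 1.53 Gy per proton. The water
radiolysis products (e⁻aq, •OH, H•, H₂, H₂O₂, H₃O⁺, OH⁻) then react with the
cellular solutes — a lumped 1 M oxidizable substrate RH, 30 μM O₂, 6.5 mM
glutathione, 1 mM ascorbate, 1 μM nitric oxide, 0.2 mM α-tocopherol — plus a
2.5 μM (at N=20, dose-proportional) pool of carbon radicals R• from direct
ionization of RH. Oxygen is consumed chiefly by R• + O₂ → ROO• and by
GSSG•⁻ + O₂ → GSSG + O₂•⁻; peroxyl radicals are terminated by the
antioxidants. The model tracks all 42 species from 1 ns (or, in hybrid mode,
from the spur stage at 1 ps) to 1 s.

## Reaction scheme

The bundled scheme (`data/cell_scheme.tsv`) holds 48 cell-chemistry
reactions — substrate radical chemistry, the peroxidation chain and its
termination, the glutathione/ascorbate/nitric-oxide/tocopherol network, and
the O₂/O₂•⁻/H₂O₂ interconversions including enzymatic superoxide
dismutation (R5) and catalase turnover (R6) as elementary bimolecular steps
— plus a 15-reaction pure-water core (labels W1–W15) with standard
literature constants. Conventions:

* **pH and protons.** The medium is buffered at pH 7. HO₂• (pKa 4.8) is
  folded into O₂•⁻. Reactions written with H⁺ as co-substrate carry an
  `implicit_protons` count; the proton pool is not a dynamic species, and
  the implicit count enters only the per-reaction charge audit.
* **Conservation audits.** Five integer moiety maps (glutathione backbone,
  ascorbate skeleton, R carbon, NO nitrogen, tocopherol) must lie in the
  left null space of the stoichiometric matrix, and every reaction must
  balance charge after crediting implicit protons. `validate_scheme` reports
  violations as data; the bundled scheme passes all audits.
* **Terminal sinks.** Products with no further reactions in the scheme
  ((RH)•⁻, R–R, ROOR, the ROO• self-termination product, ROH, ROONO, RNO,
  ONOO⁻, HNO₂, GSOH, GSO•, G•, H₂S, GSSG²⁺, dehydroascorbate) are inert and
  carry an immobile marker instead of a diffusion coefficient.
* **Kinetic classes.** Bimolecular steps with k ≥ 10⁹ M⁻¹s⁻¹ are flagged
  diffusion-influenced (Collins–Kimball partition; the threshold is a
  convention, configurable by editing the scheme file), the rest
  activation-controlled. Only the diffusion-scaling machinery uses the flag.

## Units

Yields *G* are molecules per 100 eV; concentrations follow *C* = ρ·D·G with
1 molecule/100 eV = 0.103364 μmol/J, the value standard in the
radiation-chemistry literature this model builds on. The CODATA-derived
value, 10⁶/(100·e·N_A) = 0.103643 μmol/J, differs by 0.27 %; the package
keeps the literature constant so printed endpoints are directly comparable,
and the difference is far below every tolerance used here. The compact
relation [–O₂](mM) = 5.3×10⁻⁴·N·LET·G(–O₂) agrees with the exact cylinder
geometry to ≤ 1 % (the constant is the geometry factor rounded to two
figures).

## Hand-off yields and calibration

The chemistry before ~1 ns happens inside track structure that a
homogeneous model cannot represent. Homogeneous mode therefore starts at
t₀ = 1 ns from configurable primary yields, default G = {e⁻aq 4.0, •OH 4.8,
H• 0.62, H₂ 0.40, H₂O₂ 0.50, H₃O⁺ 4.5, OH⁻ 0.5} — early-time,
literature-informed values, electroneutral by construction (G(H₃O⁺) =
G(e⁻aq) + G(OH⁻)). Because the nonhomogeneous code behind the published
reference endpoints is not public, the two highest-leverage yields, G(•OH)
and G(e⁻aq), are calibrated by bounded least squares (±20 % of the defaults,
hydronium slaved to the electron) against the published N = 20, 1 s
endpoints (13.6 μM depleted, G(–O₂) ≈ 4). A weak prior (1 % weight) pins
directions the targets cannot determine — in practice the electron yield,
which has almost no leverage on oxygen because 1 M RH captures e⁻aq into an
inert adduct within a nanosecond. The fit lands on the upper hydroxyl bound
(G(•OH) = 5.76) and reproduces the targets to −9.5 % and −2.7 %; the result
ships as `data/calibrated_yields.json` with its objective and residuals, and
`scripts/acceptance.py` re-runs the calibration from scratch rather than
reading the fixture.

## Spur stage (synthetic nonhomogeneous initial condition)

`generate_tracks` emulates the ~1 ps outcome of the physical and
physicochemical stages: entry points uniform over the beam disc, spur
centres a Poisson process along each track axis with mean energy 47.5 eV
per spur, per-spur species counts Poisson around 1 ps yields (hydronium
paired to electron + hydroxide so every spur is electroneutral), positions
Gaussian with σ = 4 nm (8 nm for the thermalized electron). These spur
parameters are conventional low-LET choices, not fitted quantities, and the
figure-level results never depend on them alone (the calibration step
absorbs the hand-off uncertainty).

`irt_simulate` runs classic independent reaction times: every reactive pair
draws a first-passage time from W(t) = (R/r₀)·erfc[(r₀−R)/√(4Dt)] with the
encounter radius R inverted from the observed rate constant (Smoluchowski,
effective-radius form for partially controlled reactions); every
radical–solute channel draws an exponential time with rate k·[S]. Events
execute in global time order with deterministic tie-breaking; products
appear at the event position and sample fresh times (the standard IRT
approximation for secondaries). Solute pools are finite integer counts over
the cylinder volume — 30 μM O₂ is ~570 molecules — and an exhausted pool
switches its channels off. What the generator does *not* emulate: explicit
track-structure physics (cross sections, sub-spur energy-deposition
geometry), spur-overlap correlations in the initial positions beyond what
Poisson statistics give, and re-sampling of a particle's surviving channels
when one of its pools empties. Hybrid mode hands the ensemble state (plus
the direct R• pool) to the deterministic stage at 0.2 μs, the conventional
spur-to-bulk transition time; full-IRT-to-1-s runs work but converge slowly
in replicate count, so they are not the default.

## Homogeneous stage numerics

* Mass-action rates with the elementary-event convention for
  self-reactions: for 2A → P, rate = k[A]², d[A]/dt = −2k[A]². Conventions
  in the literature differ by this factor of two; the bundled constants are
  used as elementary-event constants.
* BDF integration (scipy) of the augmented system [c; ξ] with analytic
  Jacobian, rtol 10⁻⁸, atol 10⁻¹⁸ M, on a log grid of ~60 points/decade.
  Integrating the extents ξ_r jointly makes ledger closure an identity up to
  solver tolerance; the measured closure residual on O₂ is < 10⁻¹⁹ M.
* Negative excursions: concentrations are clipped at zero on output; the
  run aborts if any excursion exceeds 10⁻¹¹ M (undershoot is governed by
  rtol on μM-scale species, and the observed worst case is ~10⁻¹² M when
  oxygen is driven to zero at N ≥ 45).
* Linear invariants (the moiety totals) drift by linear-solve roundoff
  accumulated over the ~10³–10⁴ steps of a nine-decade integration:
  measured 2×10⁻¹⁴…6×10⁻¹³ relative. This is the double-precision floor
  for an unprojected stiff integration, not a modelling error; the
  stochastic stages conserve moieties exactly (integer bookkeeping).
* Diffusion scaling: a global factor s multiplies the diffusion-limited
  component of every diffusion-influenced rate constant through
  1/k = 1/k_act + 1/(s·k_diff). By default the printed constant is taken as
  fully diffusion-limited (k_act → ∞), so k → s·k; per-reaction activation
  components can be supplied to soften the scaling. Activation-controlled
  reactions are untouched. In the spur stage the same factor scales the
  diffusion coefficients (stretching pair-reaction times ×1/s at unchanged
  reaction probabilities) and the diffusion-influenced scavenging constants.

## Stochastic oracle

`oracle.ssa_simulate` is a direct-method Gillespie simulator over the same
scheme in a configurable virtual volume (default 10⁻¹⁸ L: ~18 O₂, ~6×10⁵
RH, ~3.9×10³ GSH molecules), with propensities matching the deterministic
convention (k·n(n−1)/(N_A V) for self-pairs). It shares no integration code
with the ODE stage. Agreement is checked two ways: the SSA mean approaches
the ODE as the volume grows, and at 10⁻¹⁸ L the mean trajectory matches the
ODE within 3 standard errors of 500 replicates for ROO• and GSH. For O₂
itself the comparison resolves a real finite-copy-number effect: each
consumption event removes one radical *and* one O₂, anticorrelating the
reactant counts, so the jump-process mean runs ~1 % (≈0.2 molecule) above
the mass-action transient before converging at late times. That deviation
exceeds 3 SE once enough replicates are averaged; it vanishes with volume.

## The depletion-vs-N analysis

Two constructions are reported side by side.

* `depleted_eq8_um`: one reference G(–O₂)(t) curve (the calibrated N = 20
  run) scaled linearly in N through [–O₂] = 5.3×10⁻⁴·N·LET·G. This is the
  construction behind the published depletion-vs-intensity figures — their
  N = 30 value is exactly 1.5× their N = 20 value — and it deliberately
  ignores pool saturation. The complete-depletion threshold (smallest grid
  N with ≥ 99 % of the 30 μM pool depleted at 1 s; the 99 % cut
  operationalizes "complete" against asymptotic numerics) is evaluated on
  this column and falls at N = 50 on the 10…60 grid.
* `depleted_direct_um`: each N resimulated with its own finite oxygen pool.
  These endpoints are sublinear — 17.1 μM at N = 30 against 18.6 μM from
  the linear construction — because the O₂ branch of R• shrinks as O₂
  transiently falls, the 1 μM •NO pool saturates, and superoxide
  disproportionation is second order. The direct column never reaches 99 %
  depletion on the grid: after the radical pools are spent, superoxide
  dismutation and catalase regenerate part of the consumed O₂.

## Known disagreements with the reference treatment

Matching the *net* 1 s endpoint while keeping the printed rate constants
forces gross fluxes larger than the reference decomposition shows. In this
network ~35 % of consumed O₂ is regenerated in situ (O₂•⁻ → R5 → ½O₂ plus
H₂O₂ → R6 → ½O₂), so the GSSG•⁻ channel's gross extent comes out at
2.9 G units where ~2 is expected (its ratio to the R•+O₂ channel, 0.92, is
in the expected band). Relatedly, •NO ranks below GSH among peroxyl
terminators here because the finite 1 μM pool is consumed by R• + •NO well
before ROO• peaks at ~30 μs. Both observations, and the exact N-linearity
discussed above, are consistent with the reference treatment bookkeeping
scavenger concentrations as non-depleting in its stochastic stage (a
standard IRT idealization) — under that bookkeeping gross equals net and
depletion is exactly dose-proportional. This package models the pools as
finite and depleting throughout, reports both constructions where they
differ, and documents the residual gaps rather than tuning constants to
close them.

## Tunable parameters that matter

| parameter | default | units | role |
|---|---|---|---|
| N | 20 | protons/pulse | dose (1.53 Gy per proton); 20 ↔ ~30.6 Gy |
| LET | 0.3 | keV/μm | per-track energy; low-LET regime |
| Rₒ, L | 0.1, 1 | μm | beam cylinder = dose mass and pool volume |
| [O₂] | 30 | μM | the pool whose depletion is the endpoint |
| [RH] | 1.0 (0.5) | M | oxidizable substrate; drives R• production |
| [GSH], [AH⁻], [•NO], [TOH] | 6.5 m, 1 m, 1 μ, 0.2 m | M | antioxidant network |
| R•(direct) | 2.5 at N=20 | μM | direct-ionization radicals, ∝ dose |
| G₀ set | see above | /100 eV | 1 ns hand-off; •OH and e⁻aq calibrated ±20 % |
| diffusion_scale | 1.0 (0.01) | — | cytoplasmic-mobility scenario |
| spur energy, σ | 47.5 eV, 4 nm | | spur-stage structure |
| rtol, atol | 10⁻⁸, 10⁻¹⁸ | —, M | stiff-solver tolerances |

## What passing tests do and do not show

The test suite validates the implementation against closed forms
(pseudo-first-order decay, Smoluchowski pair statistics, dose arithmetic),
against an independent exact-stochastic simulator, and against the published
endpoints at their stated tolerances. It does not validate the biology: the
medium is a single well-mixed compartment with one lumped substrate, no
membranes, no oxygen resupply, no enzyme kinetics beyond effective
bimolecular constants, no pulse trains, and antioxidant pools that neither
regenerate nor exchange with the environment. Conclusions about real tissue
require the compartmental extensions this model deliberately omits.
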