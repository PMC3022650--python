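# Methods

## Scope and model structure

`pelocore` implements flux balance analysis (FBA) over curated *core*
reconstructions of the central fermentative and respiratory metabolism of
*Pelobacter carbinolicus* and *P. propionicus* — two strictly anaerobic
members of the *Geobacteraceae* that ferment acetoin and 2,3-butanediol and
reduce Fe(III) only indirectly, through a sulfide/elemental-sulfur shuttle.
The published genome-scale models of these organisms (≈700 reactions each)
are not redistributable, so the package builds compact models (≈60–80
reactions) that preserve the carbon, electron and ATP accounting of every
growth condition used for validation: all fermentation routes (acetoin,
2,3-butanediol, ethylene glycol, ethanol, lactate, propanol, butanol),
substrate-level phosphorylation via phosphate acetyltransferase + acetate
kinase, the methylmalonyl-CoA propionate pathway, the NAD-linked hydrogenase
and formate branch for syntrophic H2/formate export, the two sulfur
reductases (SRE with H2, SRE2 with NADPH as donor), the extracellular
nonenzymatic reaction FE3Rs (2 Fe3+ + HS- → 2 Fe2+ + S0 + H+), a complete
TCA cycle, ATP synthase and the maintenance reaction.

The standard FBA problem is solved throughout: maximize or minimize c·v
subject to S·v = 0 and l ≤ v ≤ u, with fluxes in mmol/gdw/h (biomass in
1/h). Three objective modes mirror how the growth conditions were simulated:
maximize biomass at fixed substrate uptake; minimize substrate uptake at
fixed growth rate; and maximize the ATP-maintenance flux under fixed measured
fluxes (used only for calibration). Exchange fluxes are negative for uptake
and positive for secretion, everywhere. Linear programs are solved with the
HiGHS solver behind `scipy.optimize.linprog`; the formulation (stoichiometric
matrix assembly, medium policy, objective construction) is the package's own.

Two compartments are used, cytosol (`c`) and extracellular (`e`). The
organism's periplasmic proton chemistry is represented as c→e proton
movement. This is an assumption of the package, not something the source
physiology fixes; it is the minimal structure that still supports
chemiosmotic ATP accounting.

## Proton bookkeeping and effective energy coupling

Every reaction is written with explicit protons and is elementally balanced
(the validator checks C, H, O, N, S, P, Fe on every non-exchange,
non-biomass, non-maintenance reaction; all metabolites carry formulas in
charged-species form). The default medium allows H+ to enter and leave
freely, which is the standard convention in constraint-based models. A
consequence worth stating explicitly: with an unconstrained external proton
pool, the energy coupling of the respiratory chain is set by the *cytosolic*
proton counts. A sulfur reductase written as

    H2(c) + S0(e) + n H+(c) → HS-(e) + (n+1) H+(e)

removes n cytosolic protons per electron pair, and the ATP synthase
(m H+(e) + ADP + Pi → ATP + H2O + (m−1) H+(c), default m = 3) returns m−1,
so the effective yield is n/(m−1) ATP per electron pair. The 2×2 scan over
n ∈ {1,2} for SRE and SRE2 therefore discriminates exactly as intended:
raising the SRE ratio raises the hydrogen-scenario biomass yield and lowers
the ethanol:hydrogen yield ratio. The membrane fumarate reductase of
*P. propionicus* is written with one extra chemical proton consumed on the
cytosolic side (NADH + fumarate + (k+1) H+(c) → NAD + succinate + k H+(e),
k = 2 by default) so that it is elementally balanced while translocating k
charges.

## Energy parameters

`EnergyParams` carries the calibrated energy contract:

| parameter | default | units | origin |
|---|---|---|---|
| GAM | 97.5 | mmol ATP/gdw | chemostat maintenance regression |
| nGAM (*P. carbinolicus*) | 0.844 | mmol ATP/gdw/h | same regression (intercept) |
| nGAM (*P. propionicus*) | 2.80 | mmol ATP/gdw/h | mean max-ATP over yield records |
| SRE H+/2e- | 2 | — | 2×2 stoichiometry scan |
| SRE2 H+/2e- | 1 | — | same scan |
| ATP synthase H+/ATP | 3 | — | package default, configurable |

The synthase ratio is not fixed by any of the reproduced observations; it
interacts with the SRE stoichiometries only through the effective coupling
above, and 3 is a conventional round value. nGAM enters as the lower bound
of the ATP-maintenance reaction; GAM as the ATP term of the biomass demand.

## Lumped biomass and its one-shot calibration

The full biomass composition behind the published models (inherited from the
*G. sulfurreducens* reconstruction) is not available, so biomass is lumped
into the only channels the validation ratios test: acetyl-CoA (carbon
skeletons, default 21 mmol/gdw ≈ 42 mmol C/gdw), NADPH (anabolic reducing
power, 8 mmol/gdw), ammonium (10 mmol/gdw) and the GAM ATP term. The
defaults are order-of-magnitude standards for bacterial biomass.

`calibrate_biomass` tunes free coefficients (by default the acetyl-CoA
coefficient alone) by deterministic grid search within ±50% of the defaults,
minimizing squared relative error against observed scenario ratios. The
package's standard calibration target is the acetoin fermentation at
μ = 0.087 1/h with observed acetate:acetoin = 1.0 mol/mol — the classic
equimolar acetoin → acetate + ethanol fermentation balance reported in the
physiological literature on these organisms. With the default grid this
target is not exactly reachable inside the ±50% bound, so the calibration
clamps at 10.5 mmol acetyl-CoA/gdw (a warning reports the nonzero residual).
All downstream validation numbers are produced with this calibrated value;
nothing is re-tuned per scenario.

## Scenario conventions

Minimal anaerobic media: CO2, H+, H2O, K+, Mg2+, NH4+, phosphate and sulfate
exchange freely; tested electron donors/acceptors receive maximum uptake
rates; every other extracellular metabolite may only leave. Where a growth
rate is published it is fixed (0.087 1/h for *P. carbinolicus*, 0.144 1/h for
*P. propionicus*) and substrate uptake is minimized; conditions without a
published rate (ethanol/Fe(III), H2+acetate/Fe(III)) maximize biomass at
fixed uptake, where exchange-flux ratios are scale-free once the constant
maintenance offset is negligible or removed.

Two scenario-level closures encode physiology the bare network would bypass:

* **Hydrogenase closure.** The NAD-linked hydrogenase is reversible so that
  syntrophic scenarios can vent NADH as H2. In conditions where H2 is neither
  a substrate nor an allowed product, the same reversibility would let NADH
  cycle internally through H2 to the hydrogen-dependent sulfur reductase,
  collecting SRE-level proton translocation for electrons that
  physiologically pass through SRE2. The hydrogenase is therefore closed in
  those scenarios. This mirrors the experimental picture in which hydrogen
  metabolism is active only when H2 is kept low by a partner or supplied.
* **Sulfide closure under Fe(III).** With Fe(III) as acceptor the sulfide
  exchange is closed, making HS- a strictly catalytic shuttle between the
  sulfur reductases and FE3Rs: every electron pair leaving the cell ends on
  Fe(III), and Fe2+:H2 is well defined.

Lactate uptake in *P. propionicus* ships in three variants. With proton-only
periplasmic bookkeeping and a free external proton pool, the electroneutral
lactate-/H+ symport is written as plain transfer (no net proton term), the
antiport (lactate(e) + H+(c) ⇌ lactate(c) + H+(e)) gains one periplasmic
proton relative to it, and anion uniport ("diffusion") is charged one proton
for the membrane-potential work of importing a negative charge. This yields
the ordering antiport > symport > diffusion in biomass yield; the antiport
is the default.

Acetaldehyde, a volatile free intermediate of every fermentation route here,
has a diffusion/exchange channel (secretion-only by default). No optimal
solution uses it — venting acetaldehyde wastes carbon — but it matters for
calibration: see below.

## The maintenance regression and why its round trip is exact

`fit_maintenance` reproduces the chemostat construction: for each
steady-state observation, the measured substrate uptake and acetate secretion
and the dilution rate are fixed, the growth-associated ATP term is removed
from the biomass reaction, and the ATP-maintenance flux is maximized; qATP is
then regressed on μ by ordinary least squares (unweighted), giving
qATP = GAM·μ + nGAM. Removing the GAM term during the max-ATP solves is what
makes the slope capture *total* growth-associated ATP rather than
double-counting it. Ethanol is never fixed for acetoin chemostats: the
volatile products are treated as unmeasured, and the fit leaves their fluxes
free. On noiseless synthetic observations the recovered slope and intercept
equal the generating GAM and nGAM to solver precision with R² = 1; this is an
identity of the construction, not a statistical statement (the NADPH-linked
terms that appear in both the generated acetate flux and the maximum-ATP
value cancel exactly).

With independent multiplicative measurement noise the fixed fluxes no longer
lie on the network's exact flux manifold; feasibility then requires slack
channels, which the H2 vent (upward) and the acetaldehyde volatilization
channel (downward) provide. Noise is Gaussian, truncated at ±3σ so fluxes
never change sign.

`estimate_ngam_from_yields` fixes, per fermentative yield record, the growth
rate and the substrate flux implied by the molar yield (uptake = μ / yield,
with yields carried in gdw per mmol so no unit factor appears), maximizes the
maintenance flux with GAM kept in biomass, and returns the mean.

## Synthetic data: what it emulates and what it does not

The generators supply every input the analyses need: chemostat observations
with the linear maintenance structure, fermentative growth-yield records, and
random feasible toy networks (≤6 metabolites, ≤8 reactions, finite bounds)
whose LP optima are computed by exhaustive basic-feasible-solution
enumeration and stored with the network as an independent oracle. All
generators are pure functions of their inputs and a seed.

Because the chemostat and yield generators run the same model family that
the fitting procedures later constrain, their noiseless round trips test the
*procedures* (construction, bookkeeping, solver use), not the biology: a
passing round trip says the machinery would recover the true parameters from
ideal data of this structure. It does not show that real chemostat
measurements — with correlated errors, gas-phase losses and a genome-scale
flux background — would yield the same estimates. The toy-network oracle, by
contrast, is fully independent of the LP solver and does exercise the
engine's correctness.

## Numerical choices

* Solver: HiGHS (dual simplex) via `scipy.optimize.linprog`; statuses
  optimal/infeasible/unbounded are reported faithfully, never clipped.
* Tolerances: mass balance |S·v| ≤ 1e-6·max(1, |v|∞) asserted on every
  optimal solution; bounds respected to 1e-9; producibility threshold 1e-6.
* Degenerate optima: flux vectors are not unique, so every contract and test
  is stated on objective values and exchange-flux ratios, never on internal
  flux identity.
* Grid searches are deterministic; ties break toward smaller coefficient
  values (biomass calibration) or lexicographically smaller (SRE, SRE2)
  cells with an explicit tie flag (stoichiometry scan).
* Internal reaction bounds are ±1000 mmol/gdw/h; condition-controlled
  exchanges use true infinities so unbounded formulations surface as such.
* Biomass producibility probes currency precursors (ATP, NAD(P)H,
  acetyl-CoA) as conversions to their conjugate forms, since a core model
  without de-novo cofactor biosynthesis can never produce a free cofactor
  sink.

## Known limitations

* The core models reproduce ratio- and yield-structure, not absolute genome
  counts: reaction/metabolite/gene totals and per-category comparison counts
  are not comparable to the published genome-scale tables.
* At the fixed *P. propionicus* growth rate the simulated acetate:propionate
  ratios on ethanol and lactate fall below the catabolic 1:2 (0.44 and 0.39)
  because biomass diverts acetyl-CoA from the acetate branch; at zero growth
  the ratio is exactly 1:2. The published comparison reports "approximately
  1:2" for the growing culture; the deviation of the lumped-biomass core
  exceeds the suite's 10% tolerance and the two rows are reported as
  failures rather than hidden.
* The simulated ethanol:lactate yield gap (≈0.7) is smaller than the
  published experimental gap (under 0.5); the same direction but muted, as
  expected when lactate's advantage rests entirely on one antiport proton.
* Charge balance checking exists but is off by default; no charges are
  assigned to the shipped metabolites.
* GPR coverage is illustrative (the loci discussed in the source physiology:
  acetoin oxidoreductase subunits, acetate kinase, the alcohol dehydrogenase
  isozyme pair, the methylmalonyl-CoA mutase pair, sulfate symporter), not a
  genome annotation.
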