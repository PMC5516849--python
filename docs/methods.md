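# Methods

## Whole-body model and state layout

The dynamical model is a whole-body PBPK system with a spatially resolved
gastrointestinal tract, carried as exactly 42 named states (amounts in mg):

* 18 luminal states — stomach, duodenum, two jejunum and four ileum
  segments, and colon, each split into undissolved solid and dissolved
  drug;
* 7 enterocyte states — gut-wall drug per small-intestinal segment (the
  stomach and colon have none: no absorption is assumed there);
* 17 systemic states — venous, arterial and portal blood; lung in series
  between venous and arterial blood; heart, brain, muscle, adipose, skin,
  bone, kidney, liver, spleen, pancreas and a rest-of-body compartment,
  all perfusion-limited (dA/dt = Q·(C_art − A/(V·K_p))); and two cumulative
  sinks, urine (renal clearance) and an eliminated pool collecting luminal
  degradation, fecal (colonic) loss and hepatic metabolism.

The liver receives the hepatic artery plus the portal vein, which itself
collects the gut mucosal flow, spleen and pancreas outflows and the
enterocyte basolateral secretion.  Venous return equals cardiac output by
construction, so the organ flow balance is exact.  Because every process
either moves mass between states or into a cumulative sink, the analytical
derivative of the total-drug sum is zero between dose events; tests assert
this both symbolically (random states) and over full simulated regimens
(0.1% of the administered dose).

Dissolution follows a Noyes–Whitney law, `kd · m^(2/3) · (C_sat(pH) − C)`,
floored at zero (no re-precipitation); the 2/3 exponent is the surface-area
scaling of a shrinking particle mass.  Solubility is a piecewise-linear
lookup over pH with higher solubility at gastric pH 2 than pH 5, so the fed
stomach both empties and dissolves more slowly.  Doses are applied to the
stomach-solid state with stop-and-restart integration (LSODA, rtol 1e-8,
atol 1e-10; state clipping is never applied — nonnegativity is asserted,
not enforced).

Prandial physiology (fasted/fed) switches gastric emptying rate (3.96/0.33
per h), stomach volume (50/1000 ml), colon volume (1/7 l), per-segment
small-intestinal transit rate (2.1/0.57 per h) and gastric pH (2/5).  The
single published transit rate is interpreted as a per-segment rate,
identical across the seven segments — the standard compartmental-transit
cascade; this is flagged in the configuration documentation because a
whole-tract reading would divide it by seven.

In uncoupled runs, absorption is first order per segment (`ka_fallback`,
identical across segments — the drug is absorbed comparably along the small
intestine) into the enterocyte state, which empties into the portal vein at
`basolateral_rate`.

## Enterocyte network and the levodopa transport module

The reduced enterocyte network is a deterministic, synthetic desk-scale
stand-in for a genome-scale enterocyte reconstruction: for each of the 22
species (20 proteinogenic amino acids, cystine, ornithine) a luminal
exchange, an apical uptake, a reversible basolateral transport and a
basolateral exchange; three interconversions; and a lumped biomass /
maintenance demand.  The levodopa module adds exactly 36 reactions — 20
luminal antiport exchanges (levodopa in / amino acid out, one per dibasic or
neutral substrate, including cystine and ornithine; the acidic amino acids
are not substrates of this carrier), 13 basolateral antiport exchanges
(levodopa out / neutral amino acid in), the basolateral uniporter and the
two levodopa boundary exchanges.  The published reconstruction can be
supplied as SBML instead; the module attaches identically (its inventory is
config-visible so it can be corrected against an external source without
code change).

Affinity on the shared luminal carrier is rank-based: only the anchors
(cystine highest, ornithine lowest) are experimentally fixed, so the
interior order — dibasic and large neutral amino acids high, small polar
amino acids low — is a model choice.  Rank r maps to weight 2^(−r) and the
carrier capacity `V_T` (default 15 mmol/gDW/h) is allocated by
weight×amount shares; with no competitors the full capacity goes to
levodopa, and the share is monotone non-increasing in any competitor
amount.  Levodopa's own rank is 15: placing the drug's affinity below the
bulk of the amino-acid spectrum makes even low-affinity competitors
displace it at meal-scale loads, which is what the clinical observations
require (a ~0.4 mmol drug dose faces amino-acid loads three orders of
magnitude larger).

The four-fifths uniporter / one-fifth antiporter split of basolateral
secretion is enforced as a linear coupling constraint
(`(1−f)·v_uni = f·Σv_anti`, f = 0.8), so it holds in every flux solution
rather than being a post-hoc scaling.  The basolateral antiporter capacity
scales with the total plasma concentration of its neutral substrates,
`cap = k_ts · C_plasma`; the gain k_ts = 0.2 mmol/gDW/h per mM is
calibrated once so that fasting-state secretion is mildly rate-limiting at
absorption peaks — the regime in which trans-stimulation by post-prandial
plasma amino acids can act, and the mechanism the model exists to study.

`fba()` resolves alternate optima lexicographically (optimise the
objective, fix it, minimise total absolute flux) so flux vectors are
deterministic across solvers.  Inside the coupled loop the levodopa path
through the cell is a single chain, so uptake and secretion totals are
degeneracy-free and the per-step solves use the plain optimum.

## Coupling algorithm

The 18 h simulation is divided into 0.1 h steps (180 steps; 7 LPs per step,
1260 per scenario).  Per step and segment: read the luminal levodopa and
amino-acid amounts and plasma amino-acid concentrations; select the
exchange mode — competition while luminal amino acids exceed 1e-6 mmol,
trans-stimulation when the lumen is clear but plasma amino acids exceed the
fasting baseline, plain uptake otherwise (competition with an empty
competitor set); derive bounds; solve the LP with luminal uptake
(competition) or basolateral secretion (trans-stimulation) as objective;
convert fluxes to mg/h with the segment dry weight and the levodopa
molecular weight (197.19 mg/mmol).

The uptake bound is `min(carrier share, amount · min(1/step, K_FAST) /
gDW)`: never more than the segment contains over one step, and never
faster than the intrinsic extraction rate K_FAST = 10/h.  The second cap
matters numerically: without it the amount/step term makes the effective
absorption conductance scale like 1/step, and the standing luminal stock —
and hence the degradation loss — would depend on the coupling step size.
With it, halving the step to 0.05 h changes the reference AUC by well under
1% (asserted in tests).  Inside the integrator the externally imposed rates
additionally saturate as `min(rate, K_FAST·dissolved)`, with secretion
scaled by the same factor, so a constant per-step rate can never overdraw
an emptying segment and the wall throughput stays balanced; the enterocyte
states therefore carry no standing mass in coupled runs (the cytosolic pool
is at steady state within each step), while remaining genuine states in
uncoupled runs.

Dietary amino acids are auxiliary states outside the 42-state census: a
parallel luminal transit chain with the same gastric-emptying and segmental
rates, absorption restricted to the two proximal jejunum segments
(3/h), and a single well-mixed plasma pool (distribution volume 15 l,
fasting baseline 0.12 mM per species) with first-order disposal at 0.25/h —
slow enough that an evening protein load still elevates plasma amino acids
many hours later, which is the premise of the protein-redistribution diet.
Dietary protein is delivered as free amino acids at meal time (free
fraction 1.0 by default; the di/tri-peptide route can be represented by
lowering it).

## Estimation and sensitivity

Fitting minimises weighted squared concentration residuals (weights
1/max(obs, 0.05 mg/l)) with a seeded Latin-hypercube multistart (default
16 starts) and bounded trust-region local solves; results are deterministic
given the seed, per-start convergence is logged, and degenerate point
bounds short-circuit to the pinned value.  The sequential two-occasion
design pins the gastric-emptying rate at its literature fasting value while
fitting the kinetics on fasted data, then freezes the kinetics and fits the
gastric-emptying rate alone on fed data.  Goodness of fit reports the
two-sample Kolmogorov–Smirnov p-value between the paired series — an
unconventional use of the two-sample test, mirrored deliberately as the
field reports it — and the Pearson correlation (undefined for constant
series, reported as such).

Sensitivity is the non-normalised time-dependent derivative of plasma
concentration with respect to each parameter, by central finite differences
(relative step 1e-4), scored as the trapezoidal integral of its absolute
value; parameters with non-finite derivatives are flagged and excluded.
The finite-difference engine is generic and is verified against the closed
form for one-compartment decay.  Because the scores are non-normalised,
their ordering depends on parameter units and magnitudes; with this
package's synthetic defaults the gastrointestinal parameters dominate all
perfusion and clearance parameters, but tissue partition coefficients can
interleave among the top ranks.

Synthetic observations sample a forward simulation on a 0.25 h grid (6 h
default) with optional multiplicative lognormal noise (5% CV default),
fully seeded.  What passing the recovery tests shows is that the estimation
machinery is correct and the design identifiable under the model's own
error structure; real plasma data add model misspecification,
between-subject variability and non-lognormal error that synthetic data do
not emulate.

## Scenarios, thresholds and the amino-acid ranking

Scenario value is the trapezoidal area under the plasma curve above
stage-specific efficacy thresholds.  The threshold concentrations
themselves are not published values: the defaults (0.5/0.9/1.4/2.0 mg/l for
stages 1–4, strictly increasing with stage) are placeholders, all
threshold-relative results are reported per stage, and users supply their
own values in the configuration.

Scenario encodings: ante cibum — 100 mg every 6 h, fasted physiology, no
amino acids; fed (aproteic/proteic) — fed physiology without/with the
protein-derived amino-acid load at dose time; low-protein diet — 200 mg
t.i.d. with 0.8 g/kg amino acids per meal, dose taken before the meal so
fasted physiology applies at dosing (single-species cystine/ornithine
variants probe the affinity extremes; the default meal composition is
equimolar across the catalog); protein redistribution — same dosing, no
daytime luminal amino acids, plasma pool initialised at 3× the fasting
baseline (the previous evening's protein load) decaying first-order, with
fasted daytime physiology since no daytime meal is taken; serine-rich —
ante cibum dosing with 50 mmol serine added to the plasma pool 1 h after
each dose (a post-dose meal).  Relative changes are computed against a
dose-matched reference (the first scenario), since exposure comparisons
across different dose sizes would conflate dose with diet.

The sIEC* extension adds a systemic levodopa pool, an enterocyte
consumption route, renal elimination and blood–brain-barrier delivery
(shared with the large neutral amino acids), plus renal/brain amino-acid
reactions.  The fasting reference fixes the luminal influx (15 mmol/gDW/h,
an arbitrary scale — all capacities scale with it, making the ranking's
class partition influx-invariant) and imposes the fasting calibration as
flux-ratio equality constraints: systemic delivery = 66% of the influx,
renal elimination = 30% of the absorbed flux.  Maximising brain delivery
then gives 0.36 × influx = 5.4 mmol/gDW/h.  Co-administered amino acids
act through three share rules: the luminal carrier share (competition), an
equal-affinity renal-carrier share that displaces levodopa from renal
elimination, and a brain-carrier share for large neutral amino acids.
Amino acids partition into three classes — improving (serine, threonine,
asparagine: near-bottom luminal affinity, so negligible competition, but
renal-carrier substrates, so reduced renal loss), neutral (the acidic amino
acids, which share no carrier with the drug) and competing (everything
else, with cystine lowest).

## Numerical and design notes

* Units: mg internally; mmol at the network interface via MW 197.19
  mg/mmol; carrier fluxes in mmol/gDW/h on the segment "effective dry
  weight" (0.05 g per segment) — an effective carrier-capacity
  normalisation chosen so that the default carrier capacity is of the same
  order as peak dose delivery, not an anatomical mucosal mass.
* Benserazide co-administration in typical fitting data is absorbed into
  the fitted hepatic clearance rather than modelled as an explicit
  decarboxylase inhibition.
* Degenerate inputs: empty time courses, non-increasing observation times,
  collapsed fit bounds, zero dry weights, duplicate module application and
  infeasible LPs all raise typed errors; an infeasible segment LP aborts
  the coupled run with the step index and segment.
* Test problem sizes: unit tests run mostly 3–6 h horizons and the reduced
  (~90-reaction) network; the acceptance suite runs the full 18 h study
  conditions for the scenario orderings and the 8-start fits.
* Known limitations: no enterohepatic recirculation, particle-size
  distributions, time-varying gastric emptying, or microbiota mechanism
  (luminal loss is lumped into first-order degradation); the reduced
  network's metabolic interior is minimal, so gut-wall metabolism of
  levodopa appears only in the sIEC* extension where the fasting
  calibration requires it; exact reproduction of published percentage
  changes requires the original fitted kinetic parameter set, which is
  consumed as configuration when available rather than hard-coded.
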