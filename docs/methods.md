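# Methods

## Community model and units

A single-species GEM is a stoichiometric network with flux bounds
(default +/-1000 mmol/gDW/h; irreversible reactions have lower bound
0), Boolean gene rules and one biomass reaction. A community couples
member networks through a shared luminal compartment: the community
matrix is block-diagonal over the members' internal metabolites, the
extracellular versions of each shared metabolite are merged into one
lumen row, member-level exchange reactions for shared metabolites are
removed, and every lumen metabolite receives two community exchange
columns — a dietary inflow `u_m` (capped by the feed) and an outflow
`s_m >= 0` (the pre-absorption fecal stream).

Measurements are concentrations per gram of cecal content, with no
independent estimate of the cecal production rate `D`. All fluxes are
therefore divided by `D` (normalized to 1/h), and member columns are
interpreted as specific rates scaled by that member's biomass
concentration. The units compose exactly: mmol/gDW/h x mg DW/g cecal
/ (1/h) = umol/g cecal, so one flux vector lives entirely in
concentration units and a biomass-reaction flux of `x` *is* a biomass
concentration of `x` mg DW/g cecal. In the alpha-problem the member
flux bounds are scaled by the member's abundance (a member fixed at
zero biomass is thereby switched off entirely); in the beta-problem,
where abundances are unknowns, the +/-1000 box is kept as an absolute
cap (never active on the toy ecosystem).

## The two problems

Both are linear programs over the community matrix, solved with HiGHS
(feasibility tolerance 1e-9; steady state re-verified to 1e-6 after
solving).

**alpha** (diet + abundances -> secretion): biomass flux of every
member fixed to its abundance; `min sum_d u_d` over the feed
metabolites, equal umol weights. Lumen cross-feeding between members is
internal to the matrix and never penalized; only the dietary draw
counts. **beta** (diet -> abundances): dietary draw of the stated
substrate(s) fixed; `max sum_s x_s`. A substrate with fixed uptake has
its outflow column closed — "uptake = u" means u is consumed, not
drawn and passed through.

Degenerate alternative optima in the secretion vector are resolved by a
second lexicographic stage: at the optimal primary objective (pinned
with a one-sided slack of 1e-9 relative), total non-free lumen
secretion is minimized. Reported profiles are therefore reproducible;
individual internal fluxes may still be degenerate, and all published
quantities are objective values or secretion totals that are unique at
the optimum.

Water and CO2 are freely exchangeable with the host environment
(unbounded inflow and outflow, never counted as substrate): the gut is
aqueous and bicarbonate-buffered. Net CO2 cross-feeding between
members is still visible in the flux vector. Feed metabolites that no
member can access are ignored rather than rejected — the feed describes
the environment, not the model.

`split_substrate` caps each member's consumption of each feed substrate
at `share x availability` via added inequality rows, summing the
consuming member columns. This is exact when substrate consumers are
irreversible, as they are in the toy models.

Epithelial absorption is applied after optimization to the optimal
secretion vector: `absorbed = produced x f`, `fecal = produced x (1-f)`
with f = 0.60/0.70/0.90 for acetate/propionate/butyrate and 0
otherwise. Conservation `produced = absorbed + fecal` is exact by
construction and asserted on every profile.

## Robustness

The sensitivity coefficient for a constraint/output pair is the mean
over a perturbation grid (default +/-10% and +/-20%) of the relative
output change divided by the relative constraint change. Because both
problems are LPs whose only inhomogeneous data are the perturbed
constraints (when no feed cap binds), scaling the constraint scales the
whole solution: S = 1 to numerical precision, meaning a relative error
in measured biomass propagates one-to-one into predicted SCFA
concentrations. For the beta scan this argument requires glucan to be
the only inhomogeneity, so the robustness scan is defined on a
glucan-only feed; with acetate also in the feed the coefficient is
~0.985 on the toy ecosystem (the unscaled acetate contributes a fixed
biomass increment). Infeasible grid points are flagged and excluded; a
zero baseline output reports S = NaN.

## The toy ecosystem

The synthetic generator builds three elementally balanced species
models (C/H/O tracked; ATP/ADP carry no elements, NADH carries the 2H
it transfers). Glucan is a hexose polymer with degree of
polymerization 10 (one glucan + 9 H2O -> 10 hexose); biomass carbon
demand is ~0.5 mg C/mg DW (7 umol hexose or 21 umol acetate per mg)
and ATP demand 40 umol/mg DW, inside the range reported for anaerobic
growth. Every species carries a non-growth ATP maintenance sink so
energy balance is an inequality rather than a forced equality.

* **Bth** (saccharolytic): glycolysis (2 ATP, 2 NADH per hexose), a
  PFL branch (pyruvate -> acetate + formate, 1 ATP) and NADH-consuming
  propionate (acrylate-type, 1 ATP) and succinate (reductive, CO2-
  fixing) branches; no hydrogenase. The NADH balance forces a 1:1
  pyruvate split between the PFL and reductive branches, so the optimal
  product mix {acetate, formate, propionate} is a stoichiometric
  consequence, not a choice. Succinate is producible (task-checkable)
  but carries no flux at the optimum because its branch yields less
  ATP.
* **Ere** (butyrogenic): glycolysis, pyruvate oxidation to acetate
  (+CO2+H2, 1 ATP), an NADH hydrogenase, reversible acetate transport
  and acetate + NADH -> butyrate (1 ATP). Biomass carbon comes from the
  acetate pool, so lumen acetate directly spares glucan — the mechanism
  that makes acetate-to-butyrate cross-feeding optimal in co-culture
  and leaves a mono-culture butyrate-free.
* **Msi** (methanogen): hydrogenotrophic (4 H2 + CO2), formatotrophic
  (4 formate) and aceticlastic methanogenesis; biomass from acetate.
  The aceticlastic route is not physiological for the modeled archaeon
  but provides the acetate-only methane pathway the toy set exercises.

Study-condition fixtures: feed glucan 31 and acetate 6 umol/g cecal;
absorption 0.60/0.70/0.90; beta-problem glucan uptake 20 umol/g cecal;
abundance scenarios for mono-, two- and three-member communities (Bth
1.2, Ere 0.2, Msi 0.08 mg DW/g cecal; mono-Msi 0.05, within what the
feed's acetate can sustain). Colonization levels reported as genome
equivalents/g convert to biomass at 2.8e-13 g DW per cell.

What the toys do and do not emulate: they reproduce the fermentation
stoichiometry, redox coupling and cross-feeding topology of the real
community and are exactly element-balanced, but their yields are
round-number choices, their gene complements are a dozen synthetic ids
per species rather than hundreds, and no transport energetics, pH or
thermodynamic constraints are represented. Passing tests therefore
demonstrate the correctness of the *framework* (formulations, solvers,
scoring, sampling) on a faithfully structured miniature, not the
quantitative accuracy of any real-organism prediction; real SBML
models are loaded through the same `load_sbml` interface when
available.

## Reporter metabolites and subnetworks

Gene p-values (clamped to [1e-15, 1-1e-15]) map to normal scores
`z_g = Phi^-1(1-p_g)`. A metabolite touched by `k` scored genes —
through the gene rules of the reactions it participates in — scores
`Z_raw = sum z_g / sqrt(k)`, corrected by the mean and SD of
`n_background` random size-k sets drawn from the full score pool
(default 10,000 per distinct k; seeded), giving `Z_corrected` and
`reporter_p = 1 - Phi(Z_corrected)`. A degenerate background (all
p-values identical) yields Z_corrected = 0 rather than a division by
zero. Direction classes come from directional re-runs on one-sided
p-values (p/2 for the reported direction, 1-p/2 otherwise); a
metabolite significant in both runs is classed "both". Metabolites
with no scored genes are excluded.

Subnetworks: reactions score the mean z of their genes; the objective
is `sum(score)/sqrt(n)`. Search greedily expands each of the top-5
scoring seed reactions over the reaction-adjacency graph (reactions
adjacent when they share a metabolite) after removing explicit
cofactors plus any metabolite in more than 10% of reactions — with an
absolute floor of 6 participations so tiny models keep their
connectivity. Growth stops at `max_size` or when no neighbor improves
the objective (growth is never accepted at a loss, so a subnetwork
never scores below its best member); overlapping results merge; only
subnetworks with objective >= 2.0 are reported. Deterministic; ties
break lexicographically.

Benjamini-Hochberg correction is the standard step-up procedure
(statsmodels implementation behind a validated wrapper).

## Flux sampling and regulation calls

For sampling, internal bounds are relaxed to +/-inf (removing the
arbitrary box) and exchange fluxes from an alpha solution are pinned
within a +/-5% relative band — strict equality would collapse the
polytope's dimension. The feasible set is parametrized on an
orthonormal null-space basis of the stoichiometric matrix (fixed fluxes
folded into the affine offset); unbounded directions are detected by
per-coordinate LPs and reported with the reactions involved. Sampling
is artificial-centering hit-and-run started from the Chebyshev center:
directions are drawn toward stored previous samples relative to their
running center (isotropic directions during the first ~2 x dimension
steps), the step is uniform on the feasible chord, warm-up is 1,000
steps and the chain is thinned by 10. Every returned sample is verified
against `S v = 0` and the bounds at 1e-6. On the triangle test polytope
the sampler reproduces the analytic centroid to <0.3% and the analytic
marginal CDFs to Kolmogorov-Smirnov D < 0.006 at n = 50,000.

Between two conditions, a reaction's flux change is `P(v_b > v_a)` over
paired samples (ties count half), significant outside [0.05, 0.95].
Expression changes map through gene rules with OR = min p and
AND = max p (most/least significant branch), BH-corrected across
reactions, significant below 0.05. A reaction with concordant
significant flux and expression changes is transcriptionally up-/down-
regulated; significant flux change without expression support is
metabolically regulated; reactions without gene rules are flagged and
never classed transcriptional.

## Numerical choices and limitations

LP feasibility 1e-9, steady state 1e-6, objective comparisons 1e-8
relative; secondary-stage objective pinning 1e-9 relative; secretion
values clipped at -1e-9. Problem sizes used throughout (toy models of
12-15 reactions, communities of <= 40 columns, 50,000 hit-and-run
samples, 20 recovery replicates at background 2,000) were chosen as the
smallest sizes at which every property is measured far from its
tolerance. Known limitations: no dynamics (the dilution formulation is
a steady-state chemostat analogy), no thermodynamic or pH constraints,
no spatial structure or host epithelial metabolism, degenerate
alternative optima below the level of objective values and secretion
totals, and the hit-and-run sampler targets bounded polytopes only —
loop-carrying models must be constrained before sampling.
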