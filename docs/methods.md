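# Methods

This note documents the model, the numerical choices, what the synthetic
data generator does and does not emulate, and the design decisions taken
where the design was genuinely open.

## The economy

Each region is a single-household, single-government open economy calibrated
to one balanced social accounting matrix (SAM). One model money unit is one
billion PPP dollars per year; all base prices are normalised to one, so base
quantities equal SAM values. Functional forms were chosen as the smallest
set that delivers every mechanism the scenario machinery exercises:

- **Technology.** Leontief intermediate demand (coefficients from the SAM's
  tax-stripped purchaser values). Value added is a CES aggregate of skilled
  and unskilled labor (substitution elasticity `sigma_labor`, default 1.5).
  Capital services are used in fixed proportion to labor within the year —
  producers cannot change the capital–labor utilization ratio on this
  horizon — and earn a proportional quasi-rent calibrated from the SAM's
  capital/labor payment ratio. This keeps capital income moving with sector
  activity without introducing a capital-market complementarity problem
  (with a literal fixed economy-wide capital endowment, a 20%+ labor shock
  would drive the rental rate to its zero bound).
- **Trade.** Armington CES between the domestic variety and a pooled import
  (elasticity 3 by default), and one CES world pool per commodity across
  exporting regions (elasticity 5). The pool's dual price and source demands
  are explicit functions of regional prices, so world prices are not solver
  unknowns and the pool's budget balances identically.
- **Demand.** LES (Stone–Geary). Subsistence fractions of base consumption
  by sector tag (staples 0.70, fruits & vegetables 0.10, meat & dairy 0.00,
  energy 0.30, manufacturing −0.10) give food the low income elasticities
  that move diets toward staples in a downturn. Face-to-face services are a
  luxury whose (negative) subsistence fraction is solved so their own-price
  demand elasticity equals a target (default 1.8, the value at which a 25%
  wedge removes roughly one third of demand). The LES bounds how elastic a
  large budget item can be; if the target is unattainable the calibration
  uses the closest attainable value.
- **Wedges are iceberg losses.** The face-to-face "shadow tax" (a fear and
  lockdown wedge on final *and* intermediate use, not a fiscal instrument),
  the extra post-harvest losses on perishables, and the ad-valorem freight
  margin all destroy real resources: the destroyed share is demanded and
  paid for on the relevant market. This is behaviourally identical to a tax
  whose revenue vanishes, but it keeps every budget constraint exact, which
  is what makes Walras' law hold at machine precision (a revenue sink would
  break the accounting identity the solver is tested against).
- **Closures.** Government consumption is fixed in real terms. Regions
  flagged for stimulus (OECD-like) receive an exogenous transfer of 3.2% of
  base GDP, deficit-financed; all other regions hold the deficit/GDP ratio
  at its base value through an endogenous lump-sum transfer. Investment
  equals total savings (household + government + fixed foreign savings).
  The private savings rule is piecewise: consumption is protected down to a
  floor of base consumption minus 5% of initial income, the savings cut is
  capped at 6 points of initial income, and savings stay in `[0, income]`.
  Inside the solver the rule operates on CPI-deflated income and its output
  is re-inflated, which preserves homogeneity of degree zero in the nominal
  scale. The numeraire is the world consumer price index.

## The square system and solver

Unknowns: log producer prices and log activity levels per (region, sector),
log wages per (region, skill), and one transfer level per deficit-rule
region. Equations: zero profit, commodity clearing (domestic variety =
domestic Armington demand + world-pool demand), labor clearing per skill,
and the fiscal rule. All residuals are scale-free (relative to prices, base
volumes, or base GDP). One labor-clearing equation is redundant by Walras'
law; it is replaced by the numeraire condition and its residual at the
solution is reported as `walras_residual` (tested < 1e-7 of world income,
observed ~1e-14).

The solver is a damped Newton iteration with a forward-difference Jacobian,
started at the benchmark: full step first, step halved (up to 28 times) when
the max-norm does not fall, convergence at 1e-10. If the full shock fails, a
warm-started homotopy loads the shock in steps (0.25…1.0). The solve is
deterministic; the `seed` argument exists only for API symmetry. The default
three-region, seven-sector world solves in a few milliseconds per scenario;
the whole April pipeline including the oil-price bisection and both
decompositions runs in ~2 s on one CPU.

Degenerate inputs: all-zero accounts are treated as balanced (0/0); sectors
without trade are excluded from the world pool; regions without capital or
subsistence calibrate to the Cobb-Douglas limits; the LES supernumerary
budget is floored at a tiny positive value so off-equilibrium Newton trial
points cannot produce NaNs.

## Accounting conventions

Real GDP changes are Fisher quantity indices (geometric mean of Laspeyres
and Paasche) over double-deflated sectoral value added; welfare is the LES
equivalent variation at base prices, reported in money and as a share of
base disposable income; diet shifts are consumption-volume changes per food
group weighted by base consumption values; household cost-of-living changes
are Laspeyres indices with the household's own budget shares.

## Shock translation

The model runs on an annual step, so durations are annualized (days/365,
confinement weeks/52 — the weeks basis is what makes 12 weeks a 23% and 8
weeks a 15% labor-supply cut at full idleness). Skilled workers recover one
third of the distancing loss through telework. Essential agri-food
activities are exempt: the effective endowment cut weights the distancing
loss by each skill's base employment share in exposed sectors, while the
raw 23%/15% multipliers are what the shock set reports. The September
template replaces the uniform 25% face-to-face wedge with a country-specific
rate interpolated linearly between 13% and 45% in a distancing-intensity
scalar (the underlying multi-indicator mapping is reduced to that scalar).
The oil shock is a supply/productivity shifter on energy sectors found by
bisection so the solved scenario's world energy price falls to the target
within half a percentage point. Health-related labor losses are additive
with distancing losses and default to zero (they are small relative to
confinement effects and are a plain scenario input).

## The microsimulation

The link vector carries relative changes of wages per skill, capital income,
employment per (skill × {agri-food, face-to-face, transport, other}),
consumer prices per commodity, and transfers. A household's new income is
its base income times the share-weighted product `(1+Δwage)(1+Δemployment)`
per source (transfers and capital scale by their own changes). Two modes:

- `proportional` spreads employment declines over every worker; it is
  deterministic and is what the aggregation-consistency checks use.
- `stochastic` draws job loss as a Bernoulli event with probability equal to
  the employment decline, zeroing that source; it is reproducible by seed.

The scenario pipeline and the three-way poverty decomposition default to the
stochastic mode: unemployment is a discrete event, and spreading it thinly
would suppress precisely the concentration of income losses that the third
decomposition component measures. A household is poor when its income
deflated by its own cost-of-living change falls below the PPP$1.90/day line
(the line is fixed in real terms).

The three-way decomposition is sequential — (1) all incomes scaled by the
region-average income change and deflated by the region-average price
change, (2) household-specific deflators, (3) household-specific incomes —
and the components sum to the total exactly by construction. The averages
default to person weighting: the decomposed outcome is a person-weighted
headcount, and an income-weighted average would fold the top of the
distribution's larger capital losses into the "uniform" component.
Income weighting remains available (`weighting="income"`), and the order
dependence of the sequence is reported, not hidden
(`poverty_three_way_order_sensitivity`).

The deletion decomposition is "full minus one": a channel's contribution is
the full-scenario outcome minus the outcome with that channel removed. The
parts need not sum to the total; the interaction residual is always
reported and shrinks quadratically as the scenario is scaled down.

## What the synthetic data emulate — and what they do not

`synthetic.generate_sam` builds each region's SAM from a coherent flow story
(value-added shares, input coefficients, trade propensities, final-demand
splits drawn around tag- and development-status-dependent priors) and closes
every account algebraically, so the result balances to machine precision and
world exports equal world imports by construction; RAS rebalancing is kept
as a repair fallback. `generate_survey` draws right-skewed lognormal incomes
per region, assigns income-source shares with the gradients that matter for
the distributional results — the poorest supply mostly unskilled labor;
safety-net transfers are poor-targeted; rural households have higher
agri-food shares but still earn the majority of income off-farm; locked-down
sectors are unskilled-intensive — and then reconciles weighted source totals
to the SAM's factor payments by damped iterative proportional fitting
(within 2%, asserted). Food budget shares follow a cubic in log income
relative to the national poverty line, anchored at 0.70 for the poorest and
0.15 for the richest with zero slope at the anchors (hence monotone between
them), clipped to [0.05, 0.85].

The default world is three regions × seven sectors with ~10,000 surveyed
households per region: an OECD-like region (12 confinement weeks, stimulus),
an Africa-like developing region (8 weeks, median income 2.4 $/day, σ=1.05),
and a South-Asia-like developing region (12 weeks, median 3.2 $/day,
σ=0.95). These sizes keep a full scenario run around two seconds while
placing enough survey mass near the poverty line for stable headcounts.

What passing tests on this world show: the mechanisms — annualization,
exemption, wedges, closures, linkage, decompositions — are implemented
correctly and produce the right qualitative pattern (essential agri-food
spared, urban poverty rising faster than rural, diets tilting toward
staples, labor dominating the GDP decline, uniform income changes a
majority but not the entirety of the poverty increase). What they do not
show: empirical magnitudes. The synthetic world's labor shock assumes full
idleness of exposed workers, so its recession (about −16% world GDP under
the April template) is deeper than one calibrated to a real global database;
survey weights are synthetic persons counts, not any country's population;
and there is no informality margin, no intra-household allocation, and no
nutrient conversion of diet shifts.

## Known limitations

- The capital quasi-rent ties capital income one-for-one to sector labor
  cost; smoother capital income (contractual rents, interest) would mute the
  losses at the top of the distribution.
- Labor is mobile across sectors within a region, so sectoral employment
  changes come from equilibrium labor use, not from worker-level attachment.
- The deletion decomposition requires one solve per channel and is exact
  only to first order; the residual is reported rather than redistributed.
- Single representative household per region in the CGE; all within-region
  heterogeneity lives in the microsimulation, which feeds nothing back.
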