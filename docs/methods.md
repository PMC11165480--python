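# Methods

## Enzyme kinetics

Initial-velocity data are fit to the Michaelis–Menten equation
`v0 = vmax·s/(Km + s)` by nonlinear least squares
(`scipy.optimize.curve_fit`, trust-region reflective with positivity
bounds, tolerances 1e-14).  Initial guesses are `vmax0 = max(v)` and
`Km0 =` the grid concentration whose mean velocity is closest to
`vmax0/2`; on the standard 1–80 mM assay grid this is robust and the
noiseless generate→fit round trip closes to 1e-6 relative.  Residuals
are unweighted by default; `weighting="1/v2"` gives relative-error
weighting for data whose scatter grows with the velocity.  A fit needs
at least three distinct substrate concentrations; all-zero velocity
vectors are rejected as degenerate rather than "fit".

Turnover is `kcat = vmax/[E]` with `[E]` the enzyme subunit
concentration (µM), and catalytic efficiency `kcat/Km` is kept in
mM⁻¹ min⁻¹, the unit of the packaged BT4131 panel (a converter from
µM⁻¹ s⁻¹ is provided).

Fold changes are reported in three conventions at once — ratio `v/r`,
excess `v/r − 1`, and signed percent `100·(v/r − 1)` — because published
comparisons mix the first two ("9.5-fold increase" is the plain ratio
for M4, while "1.4-fold increase" is ratio − 1 for M1).  The claims
table in `phoskin.claims` pins the convention and printed precision of
each published comparison individually; display rounding is
half-away-from-zero.

Plate fluorescence is normalized as `(FP − FPbg)/(OD − ODbg)`; the
correction is undefined (and raises) when the sample OD does not exceed
the background OD.

## Pathway model

States x1..x8 are relative concentrations of glucose, Glc6P, Fru6P,
GlcN6P, fructose, glucosamine, GlcNAc6P and GlcNAc; rates v1..v12 are
relative fluxes.  v1 is glucose uptake; v2..v4 the
glucose→Glc6P→Fru6P→GlcN6P backbone; v5/v6/v7/v11 the phosphatase
reactions on Glc6P/Fru6P/GlcN6P/GlcNAc6P; v8 deacetylation of GlcNAc6P
back to GlcN6P; v9 deamination of GlcN6P to Fru6P; v10 the GNA1
acetylation GlcN6P→GlcNAc6P; v12 re-phosphorylation of fructose.  Mass
balances are linear in the rates (`STOICHIOMETRY`), and summing them
gives d(Σx)/dt = v1 exactly — total mass grows only through uptake,
which is the conservation check the tests enforce by quadrature
(Simpson's rule on the stored v1 series, tolerance 1e-4 relative).

One printed rate law is inconsistent with the mass balances: v10
transfers mass x4→x7 but its printed saturation argument is x8.  The
default mode saturates v10 on its actual substrate x4; the literal mode
(`v10_substrate="x8"`) keeps the printed form, in which — starting from
an empty pathway — the product branch can never turn on (x7 and x8 stay
identically zero), a structural consequence the tests document.

Regulation: the GlcNAc6P-responsive biosensor multiplies each
phosphatase's bare saturation term by `p_r + v_rmax·x7ⁿ/(Kaⁿ + x7ⁿ)`.
The basal (leaky) expression `p_r` is set to the variant-scaled
`v_rmax`, so each phosphatase starts at its nominal maximum and full
induction doubles the ceiling; a `p_multiplier` rescales this choice.
Phosphosugar pressure inhibits uptake,
`v1 = v1max·Kiⁿᵗ/(Kiⁿᵗ + (x2+x3+x4+x7)ⁿᵗ)`.  Hill edge cases: the
exponent n = 0 is defined by continuity as activation 1/2 everywhere
(so regulated rates reduce to constant-prefactor MM kinetics); sampled
exponents are floored at 1e-6 to keep 0⁰ out of the solver unless exact
zero is requested.

Integration uses `scipy.integrate.solve_ivp` with LSODA (stiff-capable;
Hill exponents up to 4 near small Ka can produce sharp fronts), rtol
1e-8, atol 1e-10, dense output on a 1000-point grid over a default
horizon T = 200.  Initial conditions default to the empty pathway
x(0) = 0, fed only by uptake.  States are clipped at zero inside the
right-hand side and in outputs; observed undershoot is at solver
round-off level.

## Variant parameterization

The only per-variant, per-substrate quantity measured for the BT4131
panel is kcat/Km.  The default ratio table therefore carries the whole
preference in vmax: `v_rmax = 0.5·(kcat/Km)_{variant,substrate} /
(kcat/Km)_{WT,Glc6P}` (the WT/Glc6P anchor is 0.5) with `Km_ratio = 1`,
i.e. every phosphatase Km equals the sampled WT-Glc6P Km.  This is an
explicit modeling choice isolated in one replaceable table; if separate
kcat and Km values become available, a user-supplied ratio CSV slots in
unchanged.  M4 lacks measurements on Fru6P and GlcN6P, so it is
excluded from default ensembles; simulating it requires an explicit
imputation (e.g. copying M3's rows into a custom table) rather than a
silent fill.

## Parameter sampling and ensembles

Unknown parameters are sampled uniformly per draw: non-phosphatase Km
in [0.5, 2.0], non-phosphatase vmax in [0.6, 1.0], the WT-Glc6P Km in
[0.5, 2.0], Hill coefficients (one shared n for the four regulated
reactions, an independent n for transport) in [0, 4], and Ka, Ki in
[0.01, 1] — the lower end lifted from 0 to 0.01 to keep the Hill
half-constants away from a singular limit.  v1max and the WT-Glc6P
vmax are fixed at 0.5.  Uniformity is the maximum-entropy reading of
"sampled between".

Each draw index owns an independent RNG stream
(`numpy.random.default_rng([seed, index])`), so draw i is reproducible
regardless of ensemble size or execution order, and all variants at one
index share the same base draw.  This paired design makes the variant
comparison a within-draw contrast: win fractions and paired differences
for final GlcNAc are free of between-draw parameter noise.  Ties (which
are exact when two variants carry identical ratios) count one half, so
the null comparison gives a win fraction of exactly 0.5.

Summaries per trajectory: final GlcNAc x8(T); the minimum of Glc6P over
the second half of the horizon (the all-time minimum is trivially the
initial zero under the empty-pathway start and carries no information);
final fructose and glucosamine; time-averaged and maximal GlcNAc6P.
Accumulation of a side product is flagged when its median final value
exceeds 5% of the variant's median final product.  Default ensemble
size is 200 draws; 800 trajectories integrate in well under a minute on
one CPU.

## Synthetic data

Velocity datasets are generated from the MM forward model on the
published assay design — grid {1, 2, 5, 10, 20, 40, 80} mM within the
1–80 mM range, three replicates, enzyme at 0.1–1 µM — with
multiplicative Gaussian noise (default CV 5%, comparable to the low end
of the replicate scatter in the measured panel; recovery tests use the
1% CV the assay claims support).  Negative noisy velocities are
truncated at zero and counted in the provenance record.  Plate data
follow FP = I·(OD − ODbg) + FPbg + noise, so the correction inverts the
generator exactly in the noiseless case.  Every generator records its
ground truth and seed; regeneration is bit-identical.

The generators emulate the statistical structure the fitters assume —
independent, homogeneous-CV replicates on a fixed grid.  They do not
model pipetting bias, substrate depletion during the 10-min incubation,
or plate-position effects, so passing recovery tests demonstrate
estimator correctness, not robustness to those real-world artifacts.

## Known limitations

The default parameterization does not reproduce every published
directional claim about the mutant simulations, and the package reports
this honestly rather than adjusting constants.  Specifically, with the
preference carried entirely by vmax: (i) M2's median final GlcNAc comes
out slightly above M1's, and (ii) M2's operating-window Glc6P minimum
is not below M1's.  The structural reason is visible in the mass
balances: the Glc6P phosphatase flux v5 returns mass to the glucose
pool (dx1 = v1 − v2 + v5), which is re-imported by v2, and lowering the
phosphosugar pool raises uptake through the pressure term — so at
quasi-steady state the glycolytic throughput equals uptake regardless
of v5, and strong Glc6P activity is never penalized in-model.  Whatever
disadvantage M2 has in the published simulations must enter through the
separate kcat and Km values, which are not published per pair.  For the
same reason M3's glucosamine sits near, not under, the 5% accumulation
bound (the M3 GlcN6P-phosphatase leak v7 competes with GNA1 for GlcN6P
at a ratio set by the efficiency quotient).  All ensemble medians and
win fractions behind these statements are recomputed by
`scripts/acceptance.py` on every run.

The model is dimensionless; no mapping from relative units to titers or
times is attempted, and fermentation-scale phenomena (fed-batch
feeding, growth, oxygen transfer) are out of scope.
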