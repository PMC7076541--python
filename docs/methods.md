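# Methods

## The design and its data model

A half diallel crosses `p` parents in all unordered pairs without
reciprocals: `p(p-1)/2` F1 entries (Griffing method 4), or `p(p+1)/2`
entries when the selfed parents are included (method 2).  Entries are
grown in a randomized complete block design with `r` blocks, replicated in
`E` environments.  Records are long-format plots
(`env, block, parent_a, parent_b, trait, value`); the unordered pair is
canonicalized on ingest, so `(b, a)` and `(a, b)` are one entry.

Analyses run on the `p x p` table of entry means.  Because the layout is a
balanced RCBD, the arithmetic entry mean equals the least-squares mean;
unbalanced data are rejected rather than approximated (every downstream
closed-form formula assumes balance, and imputation would silently break
the exactness of the Griffing partition).  Missing environment x trait
combinations are simply skipped per trait.

## Griffing estimation

Method 4, with cross-row totals `X_i. = sum_{j != i} x_ij` and grand cross
total `X..`:

    m    = 2 X.. / (p (p-1))
    g_i  = (p X_i. - 2 X..) / (p (p-2))
    s_ij = x_ij - (X_i. + X_j.)/(p-2) + 2 X.. / ((p-1)(p-2))

Method 2, with full row totals `R_i` (diagonal once) and half-table total
`T`:

    m    = 2 T / (p (p+1))
    g_i  = (R_i + x_ii - 2T/p) / (p+2)
    s_ij = x_ij - (R_i + x_ii + R_j + x_jj)/(p+2) + 2T/((p+1)(p+2))

Both decompositions are saturated (`m + g_i + g_j + s_ij` reproduces every
cell; selfs are `m + 2 g_i + s_ii`) and coincide with the constrained
least-squares fit of the additive model under `sum g = 0`; the test suite
keeps an independent normal-equations oracle for exactly this check.
Standard errors are the classical fixed-model ones, e.g. for method 4
`se(g) = sqrt((p-1) Me / (p (p-2) r))` and
`se(s) = sqrt((p-3) Me / ((p-1) r))`, with `Me` the ANOVA error mean
square.

The ANOVA follows "Model B": blocks are removed as a stratum and **every**
F ratio — entries, GCA, SCA and all Env x interactions — is tested against
the pooled plot error, which is how the combined tables of the source
trial are laid out; no approximate synthesized denominators are formed.
Entry sums of squares are computed from the `r`-scaled Griffing totals
(not by refitting a regression), which makes
`SS(GCA) + SS(SCA) = SS(Entries)` an algebraic identity; interaction SS
come from applying the same partition within each environment and
subtracting the pooled partition.

## Variance components and heritability

Under the fully random model the method-4 EMS chain (combined analysis)

    E[Me]       = s2e
    E[MS_ExSCA] = s2e + r s2sE
    E[MS_ExGCA] = s2e + r s2sE + r(p-2) s2gE
    E[MS_SCA]   = s2e + r s2sE + rE s2s
    E[MS_GCA]   = s2e + r s2sE + r(p-2) s2gE + rE s2s + rE(p-2) s2g

is back-solved in the order `s2sE, s2gE, s2s, s2g`, truncating each
component at zero.  Two conventions were fixed by reproducing the source
trial's printed arithmetic:

* when `s2s` truncates to zero the GCA difference still uses `MS_SCA`
  (not `Me`);
* the phenotypic variance is the plot-basis sum
  `s2P = s2A + s2D + s2e` with the error variance entering undivided by
  `r` (entry-mean-basis conventions exist in the literature; the plot
  basis is what the reference tables print).

`s2A = 2 s2g` and `s2D = s2s` are the standard half-diallel conversions
(inbred parents, no epistasis assumed in the conversion).  The GCA/SCA
ratio is reported from unrounded components and is undefined when `s2s`
truncates.  Component significance stars come from the F ratio of each
component's numerator mean square against the next mean square in the
back-solve order (e.g. `MS_GCA` vs `MS_SCA`).  Method-2 tables are
accepted but processed with the same EMS template, flagged
`ems_template_approximate`: the method-2 EMS coefficients differ and the
available reference arithmetic for them is internally inconsistent, so
they are deliberately not given their own chain.

Environments are treated as fixed offsets in the ANOVA F-tests but as a
random factor in the EMS chain — a deliberate mirror of common practice in
multi-environment diallel reports.

## Heterosis

`MPH = 100 (F1 - MP)/MP`, `BPH = 100 (F1 - Ph)/Ph`.  The better parent is
direction-aware: the larger mean for higher-better traits, the smaller for
lower-better ones (days to ripening), which makes `BPH >= MPH` possible
for earliness, exactly as printed reference tables show.  Standard errors
are `SE(MPH) = sqrt(3 Me / 2r)` and `SE(BPH) = sqrt(2 Me / r)` in trait
units; t statistics divide the unit-scale deviations `F1 - MP` and
`F1 - Ph` by these SEs (the percent-scale ratio is identical), on the
error degrees of freedom.  `r` is counted from the data as the number of
replicate observations behind each entry mean, because fruit-level traits
can carry many more records per entry than the nominal block count.  A
parent without selfed records flags (rather than drops) its crosses, and
the error mean square then falls back to the crosses-only ANOVA.

The per-environment least-squares-mean standard error is reported as
`sqrt(Me/r)` and labelled as such; published diallel tables sometimes
print LsM SEs from other software whose formula is not stated, and no
attempt is made to reverse-engineer them.

## GGE biplot

The method-2 table (each genotype both entry and tester) is
tester-centered — each column minus its tester mean, no standardization,
no double centering — and decomposed by SVD.  Entry scores are
`U_2 S_2^f`, tester scores `V_2 S_2^(1-f)`; `f = 0.5` by default, the
symmetric partition that treats entries and testers alike while leaving
entry-tester inner products invariant to `f` (any `f` in [0, 1] may be
passed).  The average-tester-coordinate (ATC) axis is the unit vector
toward the mean tester score; entry projections on it approximate GCA, the
orthogonal projections approximate SCA behavior.  The polygon view takes
the convex hull of entry scores, cuts the plane by rays perpendicular to
the hull edges, and assigns each tester to the hull vertex maximizing its
inner product — that vertex is the predicted best mate, and a tester
falling in its own entry's sector is the "selfing beats crossing"
diagnostic.  A zero centered matrix or zero mean tester score yields a
flagged degenerate model rather than a guess.  The module emits
coordinates; plotting is left to the caller.

## Distances and the Mantel test

Euclidean distances between parent trait profiles are computed after
z-scoring each trait (sample SD), so kilogram-scale traits cannot dominate
Brix-scale ones.  Mahalanobis `D2` between selfed parents uses the pooled
within-parent covariance `W` of replicate-level multivariate records
within one environment; `D2 = d' W^-1 d` equals the squared Euclidean
distance in canonical-variate (whitened) space, and the tests verify the
two routes against each other.  Per-cross statistics (LsM, SCA, MPH, BPH)
are arranged as symmetric parent x parent matrices with zero diagonal and
may be signed.

The Mantel statistic is the Pearson correlation of the `p(p-1)/2`
upper-triangle pairs; the null is built by jointly permuting rows and
columns of the second matrix, with `p = (#{r_perm >= r_obs} + 1)/(N + 1)`
(upper tail by default — the working hypothesis is positive matrix
correlation; a two-sided option exists, and small matrices can be
enumerated exhaustively).  The permutation RNG is explicitly seeded for
bit-reproducibility.

## Synthetic trials

The generator draws

    y = mu + e_l + b_lk + g_i + g_j + s_ij + gE_il + gE_jl + sE_ijl + eps

with selfs receiving `2 g_i + s_ii + 2 gE_il + delta`; `delta` is a self
penalty emulating inbreeding depression (negative `delta` on a
higher-better trait produces positive MPH).  GCA draws are centered to sum
to zero; the main-effect SCA matrix is projected onto the
row-sum-to-zero-over-mates space, so on noise-free data the Griffing
estimators return the stored truth exactly.  The SCA x Env draws are
deliberately **not** projected (only stratum-mean centered): the EMS chain
counts their GCA content in `E[MS_ExGCA]`, and projecting them would bias
the variance-component back-solve by about `s2sE/(p-2)`; the residual
shrinkage from projecting the main-effect SCA (about `s2s/(p-2)` on
`s2g`) is accepted as the price of exact effect recovery and stays well
inside the recovery tolerance.  Environment main effects are fixed offsets
by default, with a random-environment switch for heritability simulation
studies.

Defaults are the conditions of the motivating melon trial: `p = 8`,
`r = 3`, `E = 6`, grand mean 10 kg/plant, and variance components
`s2g = 1.888`, `s2s = 0.242`, `s2gE = 0.204`, `s2sE = 0.436`,
`s2e = 2.86` (kg^2); the block variance, not reported in such summary
tables, is set to a small 0.25.  What the generator does **not** emulate:
epistatic (additive x additive) terms, trait-trait correlation (traits are
drawn independently), spatial field trends, or unbalancedness — so passing
recovery tests demonstrate estimator correctness under the stated model,
not robustness to real-field messiness.

## Numerical and testing choices

* Truncation of variance components at zero happens after the full
  back-solve, preserving downstream differences (see TSS convention
  above).
* Ranks use "first-occurrence" tie-breaking in parent order with an
  explicit tie flag.
* Zero-variance QC samples return flagged NaN moments instead of raising.
* The test suite's simulation sizes (200 trials for component recovery,
  1000 replicates for test calibration, 30 diallels for GGE/Griffing
  agreement) were chosen to keep Monte-Carlo error comfortably below the
  asserted tolerances while the whole suite runs in about a minute.
* Skewness/kurtosis are the moment estimators `g1 = m3/m2^1.5`,
  `g2 = m4/m2^2 - 3` (biased form), matching common pre-ANOVA QC output.

## Known limitations

Reciprocal and maternal effects (Griffing methods 1 and 3) are out of
scope, as are REML/mixed-model estimation for unbalanced layouts,
imputation of missing plots, multi-environment (mega-environment) GGE
models, partial Mantel tests, and computing genetic distances from marker
data — the GD matrix is consumed as an input.
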