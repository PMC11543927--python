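# Methods

This note documents the models implemented in `boxbind`, the defaults and
their rationale, what the synthetic-data generators do and do not emulate,
and the numerical choices that affect results.

## Motif scanning (`sequence_motifs`)

A motif is an ordered list of allowed-residue classes; `x`/`X` positions
expand to the full 20-letter alphabet. Scanning reports **all** windows
whose residues fall in the corresponding classes, including overlapping
ones, with 1-based inclusive coordinates. Letters outside the standard
alphabet (X, B, Z, U) never satisfy a finite class but do satisfy
wildcards — a conservative treatment of ambiguity codes.

Two CBM variants ship in the built-in library: the initial
proteome-search form `[TSNV]L[IL]D[ILMFW]` and the refined
`[DSNTV]L[IL]D[ILMFW]`, which additionally admits the Asp-flanked motifs
of Ent5 and Apl2. The refined variant is the default (`CBM`); the
scanner does not automate the iterative literature/ELM refinement loop
that produced it.

Disorder filtering keeps a hit iff the **arithmetic mean** score over the
matched span is ≥ cutoff for disorder probabilities (default 0.5) or
**strictly below** the cutoff for pLDDT (default 50; low pLDDT marks
predicted disorder). Span-mean aggregation is the common SLiM-scanner
convention; per-residue unanimity would be stricter and is not used.

## Tm-shift K_D fitting (`thermal_shift`)

Two-state unfolding with van't Hoff enthalpy ΔH_u at the apo midpoint
T_m0 and optional ΔC_p:

    ΔG_u(T) = ΔH_u (1 − T/T_m0) + ΔC_p [(T − T_m0) − T ln(T/T_m0)]
    K_u(T) = exp(−ΔG_u/RT),  f_u = K_u/(1 + K_u)

A 1:1 ligand binding the folded state makes the apparent unfolding
constant K_u/(1 + L_free/K_D); at the observed midpoint the folded
species total P_t/2 (definitional for two-state), so

    K_u(T_m) = 1 + L_free/K_D,
    L_free = L_t − (P_t/2) L_free/(K_D + L_free)  (closed-form quadratic).

`detect_tm` smooths with Savitzky–Golay (window 9, order 3 — the
instrument software's smoothing is not published, so a mild generic
filter is used), differentiates on the temperature grid, takes the
largest-|·| extremum, and refines it with a three-point parabola. A
trace whose extremum is below 3× the median absolute derivative has no
detectable transition.

`fit_kd_tmshift` minimizes Σ(T_m,pred − T_m,obs)² over (log10 K_D, ΔH_u,
T_m0) with log10 K_D bounded in [−2, 5] (µM scale) and multistart from
{1, 10, 100, 1000} µM. ΔC_p defaults to 0 and is user-set, not fitted
(barely identifiable from T_m ladders alone). The binding enthalpy is
taken as 0, so the reported K_D is the apparent value in the
melting-temperature regime — the same convention as reporting "K_D^app"
without a reference temperature. CI95 comes from a profile scan over
log10 K_D with an F(1, n−3)-based threshold on the residual sum of
squares; this reproduces the asymmetric intervals typical of such data
without bootstrap cost. A profile that never recrosses the threshold
before the weak-binding bound is flagged as an open (unbounded) upper
interval — the correct answer for a flat T_m ladder.

Temperatures are Kelvin internally and Celsius at every I/O boundary.

## Native-MS occupancy and competition (`native_ms_occupancy`)

The input boundary is per-stoichiometry species intensities (the
deconvolution of raw spectra is instrument-specific and out of scope),
used as concentration proxies with equal response factors across
stoichiometries — the standard native-MS assumption. From the fractions
f_0..f_n: ν = Σ i f_i, L_free = L_t − ν P_t (floored at 0 with a
warning), Scatchard point (ν, ν/L_free).

The non-interacting identical-sites null gives binomial fractions in the
per-site occupancy p, with p the physical root of the depletion
quadratic n P_t p² − (K_D + L_t + n P_t) p + L_t = 0. Under this model
the Scatchard plot is exactly the line ν/L_free = (n − ν)/K_D; curvature
is evidence for site heterogeneity or cooperativity. The fit minimizes
the summed squared fraction residuals over log10 K_D; the **deviation
statistic** is that minimum per degree of freedom (n_points · n_sites − 1).
Its null distribution is calibrated by parametric multinomial simulation
at the fitted K_D rather than an asymptotic χ² — small counts make the
asymptotics unreliable. Distributions observed up to n_max = 4 (a
fourth, possibly unspecific, binding event) are renormalized over
0..n_sites (default 3, the three specific boxes) before fitting.

Competition (P + A ⇌ PA, P + B ⇌ PB at one shared site) is solved by a
damped fixed-point iteration on the free concentrations (damping 0.5,
relative tolerance 1e−12, cap 10 000 iterations), then projected onto
exact ligand mass balance; conservation holds to better than 1e−9.

A note on displacement asymmetry: with K_D,A < K_D,B, titrating A
against fixed B removes a larger **fraction of the competitor's starting
occupancy** at every titrant concentration than the mirror experiment
does. The *absolute* occupancy drops can cross at high titrant
concentration, because the tighter binder starts from a higher bound
fraction in the mirror; the relative form is therefore the quantity the
package tests and reports.

## FRET statistics (`fret_stats`)

Efficiency per ROI is donor dequenching, E = 100·(D_post − D_pre)/D_post
(%), assuming background subtraction upstream and frame-averaged pre/post
intensities. Negative efficiencies are retained — discarding them biases
group means upward. QC keeps an ROI iff the acceptor bleach fraction
1 − A_post/A_pre reaches the threshold (default 0.85, inclusive).

Group comparisons use Yuen's trimmed-means test with γ = 0.2 (the
default of the robust-statistics packages this analysis style relies
on): trim g = ⌊γn⌋ per tail, h = n − 2g, squared standard errors
d = SS_winsorized/(h(h−1)), Welch–Satterthwaite df. At γ = 0 the test is
exactly Welch's t. Pairwise tests against the reference group are
Holm–Bonferroni step-down adjusted; stars at adjusted p < 0.05 / 0.01 /
0.001 / 0.0001. The omnibus heteroscedastic trimmed-means ANOVA and its
explanatory-measure effect size are not computed (their exact estimator
is implementation-specific); only pairwise-vs-reference comparisons are.

## Structure comparison (`structure_compare`)

Cα atoms are read with gemmi from PDB or mmCIF (first protein chain when
unspecified; altloc blank or 'A'; missing residues omitted), and paired
by author residue number over the intersection of the selections —
sufficient because the compared models are the same protein. The Kabsch
rotation comes from the SVD of the coordinate covariance with the
reflection case corrected (det R = +1); degenerate (collinear or < 3
atom) pairings are rejected.

## Synthetic data (`synthetic_data`)

Generators share no fitting code with the analyzers: the melting
generator evaluates the full three-species equilibrium (U/F/FL with
mass-balance root finding) at every temperature, the species generator
solves free ligand by bracketing rather than the occupancy quadratic,
and the toy-proteome manifest is built by exhaustive window checking.

Defaults are the study designs: eleven 1:1 dilutions from 3.75 mM plus
an apo curve at P_t = 8 µM for melting titrations; P_t = 1.75 µM, counts
of 5000 per point, and ligand grids up to 100 µM for species titrations;
eight groups of ~100 ROIs at ~8 % efficiency, SD 3 %, bleach ~0.92 for
FRET. The melting model defaults to T_m0 = 318.15 K and ΔH_u = 260
kJ/mol, which reproduces the > 15 K stabilization that saturating CBM
peptides produce on the NTD under this design; ΔC_p defaults to 0.

What the generators do **not** emulate: baseline photophysics of the
330/350 ratio, temperature-dependent binding enthalpy, non-equal MS
response factors, correlated segmentation noise between donor and
acceptor channels, and real disorder-score autocorrelation along
sequences. Passing recovery tests therefore demonstrates correctness of
the inference chain under its own assumptions, not robustness to these
real-data effects.

## Validation studies (`studies`) and problem sizes

The bundled studies run at sizes chosen to give stable rates at
interactive runtimes on one CPU: K_D recovery at 3 truth values × 20
seeds (pooled median relative error reported, with the noiseless round
trip as an exactness check); identical-sites calibration with 200-draw
null simulations, 10 null datasets and 20 cooperative seeds (stepwise
K_Ds 200/50/12.5 µM — statistical factors make K_i = K·i/(n−i+1) exactly
identical-sites, so anything tighter is genuine positive cooperativity);
family-wise error over 1000 null replicates of the eight-group design.
All randomness derives from a single base seed via fixed sub-seed
arithmetic, so every reported number is reproducible.
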