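# boxbind

Quantitative analytics for clathrin heavy-chain N-terminal-domain (NTD)
adaptor binding in budding yeast — and, more generally, for any study that
combines short-linear-motif scanning, thermal-shift affinity estimation,
native-MS stoichiometry, FRET mutant comparisons, and crystal-structure
superposition.

Yeast endocytic and trafficking adaptors (epsins Ent1/Ent2/Ent5, the
AP180 homologues Yap1801/2, Apl2, Sla1, ...) carry clathrin-binding
motifs (CBMs) — short linear motifs such as `[DSNTV]L[IL]D[ILMFW]` — in
intrinsically disordered regions. These dock into up to four binding
boxes on the WD40 β-propeller of the clathrin heavy-chain NTD. `boxbind`
implements the analysis chain used to measure which adaptor wins that
competition:

* **`sequence_motifs`** — positional character-class motif scanning over
  FASTA proteomes, restricted to disordered regions via per-residue
  disorder-probability or pLDDT tracks (span mean ≥ 0.5, or pLDDT < 50).
* **`thermal_shift`** — nanoDSF melting-temperature detection (extremum
  of the smoothed first derivative of the 350 nm trace) and apparent-K_D
  fitting with the two-state, ligand-coupled Tm-shift model:
  ΔG_u(T) = ΔH_u(1 − T/T_m0) + ΔC_p[(T − T_m0) − T ln(T/T_m0)],
  K_u = e^(−ΔG_u/RT), and at the observed midpoint K_u(T_m) = 1 +
  L_free/K_D with ligand depletion by P_t/2 of folded protein.
* **`native_ms_occupancy`** — species-intensity tables → occupancy
  fractions, average occupancy ν, Scatchard coordinates (ν/L_free vs ν),
  a non-interacting identical-sites null fit (binomial occupancy with
  simulated deviation-statistic calibration), and a damped fixed-point
  solver for two-ligand one-site competition.
* **`fret_stats`** — acceptor-photobleaching FRET efficiencies
  E = 100·(D_post − D_pre)/D_post with ≥85 % bleach QC, Yuen's
  trimmed-means test (winsorized variances, Welch–Satterthwaite df) and
  Holm–Bonferroni step-down correction.
* **`structure_compare`** — Cα extraction from PDB/mmCIF (gemmi) and
  closed-form Kabsch superposition RMSD over a residue range.
* **`synthetic_data`** — seeded generators for every input stream, with
  truth manifests, so the whole chain is testable without downloads.

## Worked example

Simulate an eleven-point 1:1 dilution nanoDSF titration (truth
K_D = 34 µM, P_t = 8 µM) and refit it:

```sh
$ boxbind simulate melting --seed 11 --out sim
$ boxbind tmfit --curves sim/curves.csv --protein-uM 8 --out fit.json
Kd_app = 34.67 uM (CI95 19.4 - 60.36)
```

The fitted apparent K_D (34.7 µM) recovers the generating value within
the profile-likelihood CI95; `fit.json` holds the per-concentration
observed and predicted T_m ladder.

Solve the competition design — NTD at 1.75 µM, the weaker ligand fixed
at 20 µM (K_D 177 µM), the tighter one titrated (K_D 138 µM):

```sh
$ boxbind nms-compete --pt 1.75 --fixed Ent2:20:177 \
    --titrant Ent1:0,5,10,15,20,25,30,50:138 --out compete.csv
Ent1_uM,frac_bound_Ent1,frac_bound_Ent2,frac_free
0,0,0.100718,0.899282
...
50,0.244126,0.0762779,0.679596
```

At 50 µM, the titrant has displaced ~24 % of the competitor's starting
occupancy (0.101 → 0.076) while taking 24 % of the protein itself — the
tighter binder dominates the shared site.

Compare FRET efficiency groups (simulated WT at 8 %, mutant at 5 %,
n = 100 each):

```sh
$ boxbind simulate fret --seed 2 --out fsim
$ boxbind fret --rois fsim/rois.csv --reference WT --out fret.tsv
group  n_kept trimmed_mean_pct       p_raw p_adj_vs_reference stars
   WT     100          8.01943          NA                 NA
  Cla      98          4.53755 1.01381e-12        1.01381e-12  ****
```

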