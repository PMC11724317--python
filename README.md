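# duplexkit

Thermodynamic and conformational analysis of RNA duplexes whose central
adenosine is replaced by an N7-glycosylated regioisomer (7A), an
LNA-adenosine (A^L), or both (7A^L). These substitutions flip the adenine
base's hydrogen-bonding face, destabilizing the duplex opposite pyrimidines
and (mostly) stabilizing it opposite purines. `duplexkit` is for anyone who
needs to quantify that: it fits two-state UV-melting curves, runs the
1/T_M versus ln(C_T/4) concentration analysis, compares modified duplexes
to their A-X references, classifies glycosidic syn/anti states and
middle-pair hydrogen bonds in coordinate frames, clusters frames by RMSD,
and aggregates per-frame binding-energy components into per-state
predictions.

## The model

A non-self-complementary duplex melts as D ⇌ S1 + S2 with

    K(T) = exp(−ΔH°/RT + ΔS°/R)      (van't Hoff, ΔC_p = 0)
    T_M  = ΔH°·1000 / (ΔS° + R ln(C_T/4))
    ΔG°₃₇ = ΔH° − 310.15·ΔS°/1000

(R = 1.9872 cal mol⁻¹ K⁻¹; ΔH° in kcal/mol, ΔS° in eu, formation-signed).
ΔH°/ΔS° come both from per-curve six-parameter fits (two linear baselines)
and from the concentration dependence of T_M; agreement within 15% between
the routes is the expected two-state signature. Stability comparisons use
ΔΔG°₃₇ = ΔG°₃₇(Y-X) − ΔG°₃₇(A-X) with SDs added in quadrature. On the
computational side, frames are clustered with a single-pass leader
algorithm at 0.5 Å middle-pair RMSD and each state gets
ΔG_pred = ΔG_MM/3D-RISM − ΔG_NMODE from per-frame energy tables.

See `docs/methods.md` for the full model description, conventions and
limitations.

## Worked example

Simulate a nine-concentration (1–100 μM) melting dataset with the A-A
duplex's true parameters and 0.002 AU noise, then fit it:

```
$ duplexkit synth melt --seed 3 --out melt_demo
$ duplexkit melt-fit melt_demo/manifest.tsv
duplex_id     avg_dh  avg_dh_sd      avg_ds  ...     vh_dh       vh_ds   vh_dg37     vh_tm  two_state_pct  two_state_pass
synthetic -68.544421   0.556358 -195.855922  ... -68.56054 -195.901605 -7.801657 42.856549       0.023516            True
```

The truth was ΔH° = −68.4 kcal/mol, ΔS° = −195.4 eu: both routes recover it
to well under 1%, the derived ΔG°₃₇ is −7.80 kcal/mol and T_M at 10⁻⁴ M is
42.9 °C, and the two routes agree to 0.02% — a clean two-state transition.

Analyze a synthetic two-state trajectory (70% anti-anti, 30% syn-anti,
0.05 Å jitter):

```
$ duplexkit synth frames --seed 5 --n-frames 200 --out frames_demo
$ duplexkit traj-analyze frames_demo/frames.pdb
 cluster  leader_frame  population orientation  n_members
       0             0         0.7   anti-anti        140
       1           140         0.3    syn-anti         60
mean middle-pair H-bonds: 2.00
```

Leader clustering at 0.5 Å recovers the generated populations exactly and
the joint glycosidic labels of the middle mismatch, and both posed
hydrogen bonds are detected in every frame.

The packaged printed-table fixtures reproduce the study's comparison
statistics:

```
$ duplexkit report
duplex_id  ddg37  ddg37_sd   dtm  two_state_pct
     7A-U   4.15  0.180278 -17.6      13.642757
    7AL-A  -1.80  0.337343   9.0       7.650273
     7A-G   0.99  0.113137  -4.5       1.010101
...
predicted-vs-experimental Pearson r = 0.96
```

Replacing A with 7A opposite U costs 4.15 ± 0.18 kcal/mol and 17.6 °C of
T_M; replacing A^L with 7A^L opposite A gains 1.80 kcal/mol. The eight
non-reference (ΔΔG°₃₇, ΔΔG_pred) pairs correlate at r = 0.96.

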