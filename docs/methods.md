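# Methods

`duplexkit` reimplements, as a tested pipeline, the quantitative analysis
behind a thermodynamic and structural study of RNA duplexes in which the
central adenosine is replaced by its N7-glycosylated regioisomer (7A), by
LNA-adenosine (A^L), or by N7-LNA-adenosine (7A^L), opposite each of the
four natural bases. The raw instrument and trajectory data are not
deposited, so synthetic generators with known ground truth stand in for
them; the printed summary tables travel with the package as fixtures and
drive the comparison stages.

## Two-state melting model

A non-self-complementary duplex melts as D ⇌ S1 + S2 with the van't Hoff
association constant

    K(T) = exp(−ΔH°/(RT) + ΔS°/R),        ΔC_p = 0,

R = 1.9872 cal mol⁻¹ K⁻¹, 0 °C = 273.15 K. With total strand concentration
C_T, mass balance gives K = 2f/((1−f)² C_T) for the duplex fraction f, with
the closed form f = ((a+1) − √(2a+1))/a, a = K·C_T (series limit a/2 as
a → 0). The melting temperature satisfies K(T_M) = 4/C_T, i.e.

    T_M = ΔH°·1000 / (ΔS° + R ln(C_T/4)),

and ΔG°₃₇ = ΔH° − 310.15·ΔS°/1000. All quantities are stored
formation-signed (negative for duplex formation); report layers print
magnitudes the way the field's tables do. A self-complementary mode
(C_T instead of C_T/4) exists as a flag but is unused by the study systems.

The observed absorbance interpolates between two linear baselines,
A(T) = (1−f)(m_ss T + b_ss) + f(m_ds T + b_ds). Note that the steepest
point of f(T) does **not** sit at T_M for a bimolecular transition (it lies
above it); T_M is the half-dissociation point, and the tests anchor on
that.

Two estimation routes are provided, mirroring standard melting-curve
practice:

1. **Per-curve fits**: a six-parameter (ΔH°, ΔS°, two baselines)
   Levenberg–Marquardt least-squares fit per curve
   (`scipy.optimize.least_squares`, ftol 1e-10, xtol 1e-12, ≤3500
   evaluations). Initialization: baselines from linear fits to the
   first/last 15% of points, T_M from the maximum of the smoothed dA/dT
   (Savitzky–Golay), ΔH° = −70 kcal/mol, ΔS° consistent with the T_M guess.
   Per-duplex parameters are the per-curve means with sample SDs (n−1);
   ΔG°₃₇ is averaged over per-curve values, **not** recomputed from the
   mean ΔH°/ΔS° — the two differ and the printed "average of curve fits"
   column follows the former. A fit reports `converged=False` (never
   silent garbage) when the optimizer fails, when the fitted transition
   sweeps less than 20% of the duplex fraction inside the window, when the
   fitted transition amplitude is under 1% of the data range (featureless
   input), or when ΔH° and ΔS° disagree in sign. An optional temperature
   window reproduces the baseline-truncation freedom of interactive
   melting-analysis programs; on clean data it moves parameters by ≲1%.
2. **Concentration dependence**: ordinary least squares of 1/T_M on
   ln(C_T/4) over ≥3 distinct concentrations; ΔH° = R/slope,
   ΔS° = intercept·ΔH°·1000. Duplicate concentrations are collapsed by
   averaging 1/T_M, with a warning.

Agreement of the two routes' ΔH° within 15% is the expected signature of a
genuinely two-state transition; `two_state_check` reports the percentage
and the pass/fail call (inclusive threshold). All 16 fixture duplexes pass,
the worst at 14.4%.

Strand concentrations come from Beer–Lambert at the high-temperature
(single-stranded) absorbance with nearest-neighbour 260 nm extinction
coefficients, ε = Σ 2ε(pair) − Σ ε(internal monomer), using an embedded
standard monomer/dimer RNA table. No coefficients exist for 7A, A^L or
7A^L; they alias to A's values, logged as an approximation.

## Comparison statistics

ΔΔG°₃₇ = ΔG°₃₇(Y-X) − ΔG°₃₇(A-X) on formation-signed values (positive =
destabilization), with SDs propagated in quadrature because the two
measurements are independent; ΔT_M likewise at the common 10⁻⁴ M. Reference
pairing is explicit (a duplex → reference map), never inferred from
sequence strings. The predicted-vs-experimental Pearson correlation is
computed over the eight non-reference (ΔΔG°₃₇, ΔΔG_pred) pairs by default
— including the four identically-(0,0) reference rows is a flag, and
changes r; the 8-point default reproduces the printed 0.96.

### Internal consistency of the printed fixture

Recomputing ΔG°₃₇ and T_M from the printed one-decimal (ΔH°, ΔS°) pairs
cannot reproduce the printed cells exactly: the rounding alone propagates
to ±0.066 kcal/mol on ΔG°₃₇ and roughly ±0.31 °C on T_M. Within those
bounds, 14 of the 16 concentration-plot rows are consistent; the A-U row
(ΔG error 0.64 kcal/mol) and the 7A-A row (0.11 kcal/mol, 0.43 °C) are
inconsistent beyond rounding and are flagged in the fixture
(`internally_consistent = no`). The comparison columns (ΔΔG°₃₇, SD, ΔT_M,
ΔΔG_pred) are exact functions of printed cells and reproduce exactly.

## Conformational-state analysis

Frames are ordered duplex snapshots (concatenated in the order of their
source trajectories — the order matters to the leader algorithm and is
recorded as provenance).

* **χ torsion**: O4′–C1′–N9–C4 for N9 purines, O4′–C1′–N1–C2 for
  pyrimidines, and O4′–C1′–N7–C5 for the N7-glycosylated adenosines — the
  latter chosen by structural analogy (the base atom adjacent to the
  six-membered ring), since no convention exists for the N7 linkage.
  Dihedrals follow the right-handed IUPAC sign convention, validated
  against an independent implementation; χ is reported in [−90°, 270°) so
  that syn = [−90°, 90°) and anti = [90°, 270°), folding "high-anti" into
  anti.
* **Hydrogen bonds**: inter-strand base–base bonds of the middle pair
  only; donor–acceptor distance ≤ 3.5 Å and donor–H–acceptor angle ≥ 135°
  (common MD-analysis defaults; the study names its analysis tool but not
  its thresholds — both are configurable). A declared donor without
  hydrogens is an error. The per-set statistic is the arithmetic mean of
  per-frame counts.
* **RMSD**: optimal rigid-body superposition (Kabsch, via
  `scipy.spatial.transform.Rotation.align_vectors`) over the middle-pair
  heavy atoms (sugar + base, no hydrogens). Validated against both an
  established trajectory-analysis implementation and a brute-force
  rotation-search oracle; numerically zero for exact rigid copies means
  ≲1e-7 Å through this path.
* **Leader clustering**: single pass in frame order; the first frame seeds
  cluster 1; each frame joins the *first* existing cluster whose leader is
  within the threshold (0.5 Å, inclusive), else seeds a new cluster.
  Populations are fractions over all frames; by construction they sum
  to 1 and every member satisfies the leader criterion (asserted post
  hoc). The algorithm is order-dependent; that is a documented property of
  this clustering family, not an accident.
* **Cluster averages**: every member is superposed onto its leader (using
  the clustering atom subset) before per-atom averaging.
* **Loop orientation**: the joint syn/anti label of the middle pair,
  5′-strand residue first; for frame sets, the modal label with its
  fraction — exact ties are reported, never broken silently.
* **Trimming**: the terminal two base pairs of each duplex end are removed
  before energy-related analyses; original residue numbering is preserved.

## Binding-energy aggregation

Per frame, the single-trajectory decomposition (strand terms taken from
complex frames — standard for end-point binding-energy pipelines, and
assumed here since the study does not say) gives interaction energies
E_complex − E_strand1 − E_strand2 for the molecular-mechanics + solvation
totals and for the normal-mode terms. Per state,

    ΔG_pred = ⟨ΔG_MM/3D-RISM⟩ − ⟨ΔG_NMODE⟩,

exactly as the study's footnote defines it — the normal-mode term enters
with a minus sign as printed, with no hidden re-signing. States are ranked
by ΔG_pred; alternates within 2.5 kcal/mol of the minimum (the study's
own near-tie window) are listed as co-populated. Whether the study
averaged over all cluster frames or representatives is unstated; the
aggregation accepts any per-frame table, so both groupings are expressible.
The solvation and normal-mode solvers themselves are out of scope; their
outputs enter as delimited text.

## Synthetic generators

All generators are deterministic given a seed and emit their ground truth.

* **Melting curves**: nine concentrations geometrically spaced over
  1–100 μM (the study's design), 0–90 °C at 0.5 °C steps, i.i.d. Gaussian
  absorbance noise of 0.002 AU by default — a realistic photometric noise
  floor at which default recovery tolerances pass with large margin.
  Default truth is the A-A duplex's parameters (−68.4 kcal/mol,
  −195.4 eu). Baselines default to a mild hyperchromic pair
  (single-strand above double-strand).
* **Duplex frames**: a 9-bp duplex with the study's strand sequences and
  residue/atom naming, including the N7 conventions. Geometry is
  idealized — computed ring polygons, a fixed ribose template, stacked
  residues with no helical twist, and an 18 Å strand separation so that
  only explicitly posed donor/acceptor pairs can satisfy hydrogen-bond
  geometry. The middle pair is posed exactly: the base is rotated rigidly
  about the glycosidic bond until χ equals its target (for the N7
  linkage, the base is first rotated 110° in its own plane so the
  χ-reference atom keeps a long lever arm about the axis — this keeps
  coordinate jitter from amplifying into χ noise), and acceptor atoms are
  placed along donor–H directions (2.9 Å, 180°) for "on" bonds or far
  beyond the cutoff for "off" bonds. Default states are anti-anti
  (χ = 210°, 210°) and syn-anti (χ = 30°, 210°), 2.2 Å apart in
  middle-pair heavy-atom RMSD — comfortably above the 0.5 Å clustering
  threshold and the ≥ 4× jitter well-posedness bound (violations warn).
  Frame states follow a quota schedule (round(fraction·n)), so nominal
  populations are realized exactly; jitter is 0.05 Å by default, at which
  per-frame χ noise is ~5° mean — far from the 120° state separation.
  What the generator does *not* emulate: force-field energetics, base-pair
  propeller/buckle, backbone continuity between residues, correlated
  thermal motion. Passing recovery tests therefore demonstrates the
  correctness of the geometric analyses, not fidelity to real MD
  ensembles.
* **Energy tables**: per-frame components drawn Gaussian (0.5 kcal/mol
  noise by default) around constants chosen so per-state mean differences
  equal the prescribed ΔG_MM/3D-RISM and ΔG_NMODE truths.

## Problem sizes and numerical choices

Recovery tests use 20 replicates of the nine-curve design for melting
parameters and 200–300-frame fixtures for clustering — sizes at which
standard-error formulas put the default tolerances (5% on ΔH°, ±0.02 on
populations, ±0.05 on H-bond means) at ≥99% pass probability, and the
whole suite runs in well under a minute. Ties in orientation calls are
explicit; degenerate inputs (featureless curves, zero-variance
correlations, too-short duplexes, empty clusters/states) raise or flag
rather than return numbers.

## Known limitations

* The extinction-coefficient table is the standard unmodified-RNA set;
  modified residues are approximated by adenosine, as the study implies
  but does not quantify.
* The curve-fit SDs of synthetic datasets are purely noise-driven and
  hence much smaller than the printed experimental spreads, which include
  run-to-run and truncation variability the generator does not model.
* The leader clustering reproduces a *family* of algorithms; the study's
  in-house code (frame ordering, superposition convention) is not public,
  so cluster identities — though not the recovered populations on
  well-separated states — may differ from the original in edge cases.
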