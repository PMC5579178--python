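# Methods

This note documents the models implemented in `nodulerisk`, the
statistical pipeline, the synthetic-data generator, and the numerical
and design choices made where the published rules leave room.

## Scoring systems

### PanCan (Brock) model

The malignancy risk of a baseline screen-detected nodule is modelled as

    logit(p) = β₀ + β_age (age − 62) + β_sex·[female] + β_fh·[family history]
             + β_emph·[emphysema] + β_size·((d/10)^(−1/2) − 1.58113883)
             + β_type + β_ul·[upper lobe] + β_count (n_additional − 3)
             + β_spic·[spiculation]

with the full-model ("2b", including spiculation) coefficients bundled
in `src/nodulerisk/data/pancan_model2b.json` (provenance recorded in the
file).  Notes:

* The size term uses an inverse-square-root transform of the diameter
  in cm, centred so it vanishes at 4 mm.  The transform is configurable
  (`SizeTransform`): any `(d/scale)^power − center` or the identity.
* The published model centres the *total* nodule count per scan at 4;
  this package stores the count of *additional* nodules per scan, so
  the bundled config centres it at 3 — numerically identical.
* Benign-pattern (complete/central/popcorn/concentric-ring) calcified
  nodules and perifissural nodules (PFNs, fissure-attached
  intrapulmonary lymph nodes) were excluded from the model's derivation
  cohort; they are assigned a risk of exactly 0%, placing them at the
  bottom of every ranking.  Non-benign ("other") calcification does not
  trigger this shortcut.
* Risk percent maps onto four published bands, left-closed:
  <1.5% → 1, [1.5, 6) → 2, [6, 30) → 3, ≥30% → 4.
* Default size definition: longest axial diameter.

Because only baseline information is modelled, Lung-RADS and NCCN are
implemented without their growth/follow-up branches, and the subjective
Lung-RADS 4X upgrade and the NCCN multiple-GGN provisions are omitted.
This restricts the categorical systems to what is knowable at first
screen — the setting the PanCan model is designed for — and is the only
way the three systems are commensurable.

### Lung-RADS v1.0 (baseline branches)

Sizes are rounded to the nearest whole millimetre before threshold
tests.  Solid: <6 → 2, 6–<8 → 3, 8–<15 → 4A, ≥15 → 4B.  Part-solid:
total <6 → 2; total ≥6 with solid component <6 → 3; solid component
6–<8 → 4A; solid component ≥8 → 4B.  Pure ground-glass: <20 → 2,
≥20 → 3.  Benign-pattern calcification → 1.

* **Rounding tie-break**: half-up (8.5 → 9).  Every worked-example
  assignment is consistent with this choice; half-to-even would fit
  them equally, so the tie-break is an explicit, documented assumption.
* **PFNs** are scored as solid nodules of their size (the system
  defines no PFN rule).

### NCCN v1.2016

No rounding.  Solid and part-solid nodules are classified by the
*total* diameter: <6 → 1, 6–8 (closed interval) → 5, >8 → 6.  Pure
ground-glass: ≤5 → 2, (5, 10] → 3, >10 → 4.

* The closed upper bound of the 6–8 band follows the guideline's
  "6–8 mm" wording and is confirmed by a worked solid example at
  6.1 mm falling in category 5.
* The guideline states no calcification rule; benign-pattern
  calcification maps to category 1, paralleling Lung-RADS 1 and the
  PanCan 0% rule.  This is a package convention, flagged here.
* Category order 1 < 2 < … < 6 is used for risk-dominance, consistent
  with a worked example where a category-5 solid nodule dominates a
  large pure-ground-glass nodule (category ≤4).

### Size definitions

* `LONGEST_C` — longest axial diameter (semi-automated segmentation);
  `LONGEST_M` is the manually measured variant and dispatches to the
  same stored field (a provenance distinction, not a different number).
* `MEAN_3D` — volume-equivalent-sphere diameter d = (6V/π)^(1/3).  An
  alternative reading (mean of three axis lengths) exists; the sphere
  convention is implemented and documented.
* `MEAN_AXIAL` — arithmetic mean of longest and perpendicular axial
  diameters.

Diameters are carried at full precision; rounding is the property of a
scoring system (only Lung-RADS rounds), never of the data model.
Records with both a volume and a volumetric diameter must agree to 1%
relative, else they are rejected; a missing volumetric diameter is
derived from the volume.  Part-solid nodules missing solid-component
measurements are rejected rather than imputed.

## Statistical pipeline

1. **Risk-dominant selection.**  Per system and size definition, each
   participant's nodule with the maximal rank is selected (PanCan rank =
   continuous risk percent; Lung-RADS 1, 2, 3, 4A, 4B → 1..5; NCCN
   numeric category).  Exact ties are broken uniformly at random from a
   seeded `numpy` generator, making selections reproducible; the same
   participant may contribute different nodules to different systems.
2. **Labels.**  The participant-level label is cancer status, even when
   the dominant pick for some system is a benign nodule — matching a
   per-person clinical reading rather than a per-nodule evaluation and
   deliberately penalising a system that ranks the wrong nodule on a
   cancer participant's scan.
3. **ROC/AUC.**  Midrank (Mann–Whitney) AUC with ties counted ½; the
   reported curve runs over all distinct thresholds and its trapezoidal
   area equals the midrank AUC exactly.  Categorical systems are
   additionally summarised by their category operating points, the
   PanCan model by its published band cutpoints (1.5/6/30%).
4. **DeLong test.**  Paired comparison of correlated AUCs via
   structural components computed with midranks; z = Δ/√var(Δ),
   two-sided normal p.  Zero variance with equal AUCs yields p = 1 (the
   degenerate all-tied case); zero variance with unequal AUCs raises.
   The implementation is cross-validated in the test suite against R
   pROC's `roc.test(method="delong")` to 1e-8 and against a
   swap-permutation oracle at the accuracy of the normal approximation
   (see *Numerical notes*).
5. **Multiplicity.**  Three system pairs per table row; Bonferroni
   threshold 0.05/3 ≈ 0.0167 for the significance flags.  The
   between-definition comparisons within each system use the same
   threshold.
6. **Demographics table.**  Built on the union of the risk-dominant
   nodules over the three systems (so a participant contributes up to
   three rows' worth of nodules).  Categorical rows use Pearson
   chi-square *without* Yates continuity correction, continuous rows
   Welch's unequal-variance t-test; both choices are conventions (the
   pooled/corrected variants are equally defensible) and p-values from
   this table should be read accordingly.

## Synthetic cohort generator

`GeneratorConfig` defaults describe the study conditions: 613
participants, cancer prevalence 64/613.  Cancer status is drawn per
participant first; each cancer participant's primary nodule is
malignant, every other nodule benign — a case–control structure, not a
per-nodule risk model.  Additional benign nodules per participant are
Poisson (mean 0.3 for cancer, 0.5 for benign participants, capped at 5).

Per-group marginals (malignant / benign):

| quantity | malignant | benign |
|---|---|---|
| longest-diameter median (log-normal) | 13.9 mm, σ_log 0.586 | 6.1 mm, σ_log 0.663 |
| type solid / part-solid / ground-glass | 66 / 23 / 11 % | 87 / 3 / 10 % |
| spiculation (marginal) | 28 % | 1 % |
| benign-pattern calcification | 0 % | 14 % |
| perifissural | 0 % | 8 % |
| upper lobe | 58 % | 48 % |
| age (normal, clipped 45–80) | 61 ± 5.5 y | 58 ± 5.5 y |
| female | 45 % | 47 % |
| family history | 27 % | 16 % |
| emphysema | 73 % | 67 % |

The log-sigmas are chosen so the group means (≈16.5 / 7.6 mm) sit above
the medians with the heavy right tail characteristic of screening data.
Spiculation is realised only on non-ground-glass nodules, calcification
only on solid nodules, and PFN status only on uncalcified solid
nodules, with conditional probabilities scaled so the *marginal* rates
match the table.  Malignant nodules are never calcified or perifissural.

Geometry: the perpendicular axial diameter is `0.6 + 0.4·Beta(6, 2)`
times the longest; the volumetric mean diameter is a compactness factor
`0.70 + 0.35·Beta(2, 2)` times the mean axial diameter, capped at the
longest diameter.  This reproduces the typical ordering
D<sup>mean3D</sup> ≲ D<sup>meanAxial</sup> ≤ D<sup>longest</sup> and
guarantees every generated record passes validation.  Part-solid solid
components are a Uniform(0.3, 0.9) fraction of each whole-nodule
measure.  The stored volume is exactly π d³/6 of the volumetric
diameter.

**What the generator does not emulate**: covariate correlations
(emphysema × age, etc. are drawn independently), measurement noise and
inter-observer variability, growth, multifocal disease (at most one
malignant nodule per participant), and any spatial/scan-level
structure.  Passing tests on synthetic cohorts therefore demonstrate
the *machinery* (scoring, selection, ROC/DeLong) and qualitative
orderings, not clinical performance on real screening data; in
particular the absolute AUCs obtained on synthetic cohorts are not
estimates of any system's real-world discrimination.

## Reported reproduction properties

The test suite reproduces, on synthetic data, two qualitative findings
one expects from the systems' construction, using 100 seeded replicates
of the default 613-participant cohort:

* the continuous PanCan model's participant-level AUC exceeds both
  categorical systems' AUCs in ≥90% of replicates;
* the NCCN AUC under the volumetric mean diameter is at least its AUC
  under the longest diameter in a majority of replicates (fixed
  size thresholds calibrated for mean-type diameters degrade when fed
  the systematically larger longest diameter).

Replicate counts and cohort size are the package's test conditions;
they were chosen to match the study design the generator emulates.

## Numerical notes

* Lung-RADS rounding is `floor(d + 0.5)` (half-up), applied after size
  derivation, before threshold tests.
* PanCan band boundaries and NCCN/Lung-RADS thresholds are compared
  with plain floating-point comparisons; band membership is verified by
  exhaustive grid sweeps in the tests (no gaps, no overlaps).
* AUC and DeLong components use `scipy.stats.rankdata` midranks; the
  AUC equals brute-force pair counting to 1e-12 on random instances.
* The DeLong p-value is asymptotic (normal approximation).  At small
  paired samples (n ≈ 30) it deviates from an exact permutation p by up
  to a few hundredths in absolute probability — an intrinsic property
  of the approximation, not of the implementation, which matches pROC
  to 1e-8 on the same data.  For the cohort sizes this package targets
  (hundreds of participants) the approximation error is much smaller.
* Tie-broken selections, generated cohorts and full comparison reports
  are byte-reproducible given (input, config, seed); the CLI fans one
  seed out to named consumers via `numpy.random.SeedSequence`.

## Known limitations

* The NCCN calcification rule and the Lung-RADS rounding tie-break are
  package conventions (documented above), not guideline text.
* The demographics-table test statistics (Welch, uncorrected
  chi-square) are one of several defensible conventions.
* No growth modelling anywhere: systems whose strength lies in
  follow-up behaviour are evaluated only on their baseline branches.
* `LONGEST_M` is an input-provenance alias; the package does not store
  separate manual and computerized measurements for one nodule.
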