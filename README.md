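# nodulerisk

Risk stratification of screen-detected pulmonary nodules, and a tested
pipeline for comparing stratification systems head-to-head.

In low-dose CT lung-cancer screening, every detected nodule must be
triaged: dismiss, re-scan, or work up.  Three widely used systems answer
that question differently:

* **PanCan (Brock) model** — a logistic regression giving a continuous
  malignancy probability from nodule size, type, location, spiculation
  and subject covariates (age, sex, family history, emphysema, nodule
  count).  The full variant including spiculation ("model 2b") is used;
  benign-pattern calcified and perifissural nodules are assigned 0% risk.
* **Lung-RADS v1.0** — the ACR's categorical reporting system
  (categories 1, 2, 3, 4A, 4B) from nodule type and size, with sizes
  rounded to the nearest whole millimetre.
* **NCCN guidelines v1.2016** — six categories from nodule type and
  size, unrounded.

The three systems also *define nodule size differently*: the PanCan
model uses the longest axial diameter (D<sup>longest-C</sup>),
Lung-RADS the volumetric mean diameter (D<sup>mean3D</sup>, the
volume-equivalent-sphere diameter d = (6V/π)<sup>1/3</sup>), and NCCN
the mean of the longest and perpendicular axial diameters
(D<sup>meanAxial</sup>).  `nodulerisk` makes the size definition an
explicit parameter of every scorer so both questions can be studied:
*which system discriminates best*, and *how sensitive is each system to
the diameter definition*.

The comparison is participant-level: per system, each participant's
**risk-dominant nodule** (highest risk index or category, ties broken
by a seeded random draw) carries that participant's score; the
participant label is cancer status.  Discrimination is measured by the
area under the ROC curve (midrank/Mann–Whitney AUC, ties counted ½) and
systems are compared pairwise with the **DeLong test for correlated ROC
curves**, Bonferroni-corrected over the three system pairs
(significance at p < 0.05/3 ≈ 0.0167).

Because screening-trial data are not redistributable, the package ships
a synthetic cohort generator (`nodulerisk.simulate`) reproducing the
marginal structure of a baseline screening case–control cohort —
613 participants, ~10% cancer prevalence, log-normal sizes (benign
median 6.1 mm, malignant 13.9 mm), realistic type/spiculation/
calcification/perifissural mixes — so the full pipeline runs and is
tested end-to-end without any download.

## Worked example

Score a single nodule — an 11.0 × 9.0 mm spiculated solid nodule in the
upper lobe of a 63-year-old woman with emphysema:

```python
from nodulerisk import *

nodule = NoduleRecord(
    "n1", "p1", NoduleType.SOLID, is_pfn=False,
    calcification=Calcification.NONE, spiculated=True, upper_lobe=True,
    d_longest_axial=11.0, d_perp_axial=9.0, d_mean3d=9.6, malignant=False,
)
subject = ParticipantRecord(
    "p1", age=63.0, sex=Sex.FEMALE, family_history_lung_cancer=False,
    emphysema=True, nodule_count_additional=0, has_cancer=False,
)
risk = pancan_risk(nodule, subject)          # bundled published coefficients
print(round(risk, 2), pancan_category(risk)) # 30.88 4
print(lung_rads_category(nodule))            # 4A  (9.6 mm -> 10 mm)
print(nccn_category(nodule))                 # 6   (mean axial 10.0 mm > 8)
```

The PanCan risk of 30.9% falls in the highest published band
(category 4, direct referral); Lung-RADS places the nodule in 4A
(solid, 8–<15 mm) and NCCN in category 6 (solid > 8 mm).

Run the whole pipeline on a simulated cohort:

```bash
nodulerisk simulate --n 613 --seed 42 --out cohort.csv
nodulerisk report --input cohort.csv --seed 42 --out-dir report/
```

which on this seed generates 893 nodules in 613 participants
(68 cancers) and writes `report/auc_by_system.csv`:

```
size_definition  auc_pancan  auc_lung_rads  auc_nccn  p_pancan_vs_lung_rads  p_pancan_vs_nccn  p_lung_rads_vs_nccn
   as_published       0.872          0.744     0.739                  <0.001            <0.001                0.728
      longest_c       0.872          0.757     0.736                  <0.001            <0.001                0.162
        mean_3d       0.868          0.744     0.752                  <0.001            <0.001                0.596
     mean_axial       0.870          0.756     0.739                  <0.001            <0.001                0.267
```

The "as_published" row scores each system with its own diameter
definition; the other rows apply one definition uniformly.  On this
synthetic cohort the continuous PanCan model discriminates markedly
better than either categorical ladder (p far below the 0.0167
threshold), while the two categorical systems do not differ
significantly — the qualitative behaviour such a comparison is designed
to expose.  `report/` also contains the between-definition tests per
system (`auc_by_definition.csv`), a cancer-vs-benign characteristics
table with chi-square/Welch-t p-values (`demographics.csv`), a Markdown
summary and an ROC plot with the categorical operating points.

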