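# anocost

Health-economic cost model of squamous cell anal cancer treatment in
England, plus a hospital-episode costing pipeline for HES-style
(Hospital Episode Statistics) extracts.

Anal cancer is rare (~1,100 UK cases/year) and mostly squamous; primary
curative treatment is chemoradiotherapy (CRT) or radiotherapy alone
(RT), with salvage abdominoperineal resection on loco-regional relapse.
Reimbursement in the English NHS flows through Payment by Results:
spells of care are grouped to healthcare resource groups (HRGs) and
priced from the national tariff, with chemotherapy/radiotherapy
"unbundled" and priced from reference costs. This package estimates
what treating one case costs over ten years, and what a national
episode extract implies per patient per year — for analysts costing
treatment pathways or assessing the value of prevention (e.g. HPV
vaccination).

## The model

A monthly-cycle Markov cohort model with four states: disease free
(D), relapse (R — a tunnel state occupied for exactly one month, during
which salvage surgery occurs), post-relapse (P) and dead (X). Three
monthly probabilities drive it: relapse `p_r`, death from disease free
`p_d`, and death post relapse `p_p` (shared by salvage and palliative
patients):

```
          ⎡ 1−p_r−p_d   p_r     0       p_d ⎤   D
    T  =  ⎢    0         0    1−p_p     p_p ⎥   R
          ⎢    0         0    1−p_p     p_p ⎥   P
          ⎣    0         0      0        1  ⎦   X
```

The cohort starts all-disease-free (curative treatment is assumed to
achieve local control) and runs 120 cycles — the extent of high-risk
follow-up. The probabilities are estimated by calibration: triples are
drawn in batches of 1,000 from plausible ranges, scored by least
squares against cumulative all-cause mortality and cumulative relapse
curves, and the ranges contract around each round's best fit until the
objective stops improving at three significant figures.

Costs attach to the trace from decision trees over the pathway:
diagnosis and staging (EUA/biopsy, MRI, CT, fine-needle aspiration,
pre-treatment colostomy), primary treatment by arm and admission type
(RT planning and fractions; plus PICC line, mitomycin C and 5-FU cycles
for CRT), a follow-up appointment/scan programme (low-risk intensity
for CRT, high-risk for RT), an expected one-off salvage cost on relapse
entry, and a blended post-relapse monthly cost. Two pricing scenarios
are reported: constant prices, and constant annual inflation; no
discounting (the model estimates realised reimbursement, not an
investment decision). A one-way sensitivity analysis moves each
published bound block jointly and ranks variables by spread (tornado
diagram).

The HES pipeline filters episodes on anal cancer ICD-10 codes
(C210/C211/C212/C218 invasive, D013 in situ; primary–tertiary
diagnosis for inpatients, primary–secondary for outpatients), groups
finished consultant episodes into spells, prices spells by admission
type with excess-bed-day per diems and unbundled chemo/radiotherapy
components, and produces annual per-patient summaries with
partial-year scaling (×1.33 for a nine-month year). A synthetic record
generator with closed-form ground truth stands in for the non-public
national extract.

## Worked example

The packaged configuration uses the published sensitivity bounds with
illustrative base-case values (midpoints where bounds exist — replace
`src/anocost/data/base_config.yaml` with a transcribed base-case
parameter file for a production analysis):

```
$ anocost run-model --inflation on --out-dir out/
total per-case cost (on inflation): £18,439

$ anocost run-model --inflation off --out-dir out_off/
total per-case cost (off inflation): £17,287

$ anocost sensitivity --out-dir sens/ --plot
base £18,439; range £15,517–£23,892
```

The first number is the expected ten-year cost of one case from
referral (staging + primary treatment + follow-up + salvage +
palliative care), blended over treatment arms (85% CRT) and the 5%
presenting with advanced disease, with future inflation held at a
constant annual rate; the second holds prices constant. The sensitivity
range comes from moving each variable block (admission type, staging
and primary treatment costs, palliative care, follow-up intensity and
costs, salvage/advanced/CRT proportions) to its bounds one at a time;
the widest bar is the admission type for primary treatment.
`sens/tornado.csv` holds the ordered table and `sens/tornado.png` the
diagram.

To calibrate against a target-curve CSV (`month, cum_mortality,
cum_relapse`) and to cost an episode extract:

```
$ anocost calibrate --target target.csv --seed 1 --out-dir calib/
$ anocost hes --records records.csv --tariff tariff.csv \
      --partial-years 2010 --out-dir hes_out/
$ anocost simulate --seed 1 --n-patients 1000 --out-dir synth/
```

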