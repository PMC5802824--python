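# cpttrial

An in silico paired-arm clinical trial for impaired long-bone fracture
healing in virtual NF1 subjects.

Each virtual subject is an eight-parameter phenotype vector describing
aberrant cellular behaviour (fibrous-cell invasion, fibroblastic
proliferation and differentiation, osteogenic and endochondral capacity,
cartilage and fibrous matrix formation, angiogenic growth-factor
production). A cohort of subjects is drawn with a space-filling uniform
design over the pathological parameter ranges and every subject is
simulated twice — untreated, and with an exponentially decaying
osteochondrogenic growth-factor source (BMP sponge, time constant 10
days) — through a surrogate compartmental ODE model of the healing
callus over 49 days. Each subject-arm receives a complication index
(CI): the mean of a hamartoma score, a fibroblast-presence score and a
binary non-union indicator. Subjects are stratified into four response
classes by a CI cutoff of 0.5 (asymptomatic / responder / non-responder
/ adverse responder), independently clustered with Ward's method
(ward.D2 convention), and the eight parameters are screened as class
biomarkers with a 100-repeat random-forest protocol including a
scrambled-label null control.

The simulator is a *calibrated surrogate*: its rate constants are tuned
to a behavioural contract (the healthy reference heals, the severe
pathological corner fails, treatment shifts outcomes and the cohort
populates all four response classes), not fitted to experiments.

## Command line

```sh
cpttrial cohort --n 200 --seed 42 -o cohort.csv          # uniform design
cpttrial run --cohort cohort.csv --gstar 2.0 -o trial.csv # both arms
cpttrial stratify --trial trial.csv --cutoff 0.5 --k 3 -o stratified.csv
cpttrial biomarkers --trial trial.csv --repeats 100 --seed 7 -o report.json
cpttrial full --n 200 --seed 0 -o results/               # entire pipeline
```

`full` writes cohort.csv, trial.csv, stratified.csv, linkage.txt,
confusion.json, biomarkers.json, spearman.csv and a summary.json whose
stages are all reproducible from the single master seed.

External per-subject trial tables can be analysed through the
column-mapping loader (`cpttrial.cli.read_trial_table`); the Dataset-1
conditioned acceptance tests enable themselves when the environment
variable `CPTTRIAL_DATASET1` points to such a CSV (optional mapping JSON
via `CPTTRIAL_DATASET1_MAPPING`).

## Layout

- `src/cpttrial/model.py` — surrogate ODE healing model, subject
  parameters, treatment arms, release kinetics
- `src/cpttrial/severity.py` — complication-index components
- `src/cpttrial/cohort.py` — uniform / latin-hypercube / random designs
- `src/cpttrial/trial.py` — paired two-arm execution, paired t-test
- `src/cpttrial/stratify.py` — cutoff classes, Ward clustering, agreement
- `src/cpttrial/biomarkers.py` — Spearman screen, repeated random forest,
  scrambled null, ROC, class summaries
- `src/cpttrial/cli.py` — CLI, pipeline orchestration, external loaders
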