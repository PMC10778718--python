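# exohem

Integrative analysis of paired plasma-exosomal RNA fold changes and
complete-blood-count (CBC) dynamics for early-death biomarker discovery in
chemoradiotherapy cohorts.

## The problem

A subset of cancer patients treated with concurrent chemo-radiotherapy
(CCRT) progresses and dies far earlier than stage and histology predict
("early death", ED: progression within 12 months and disease-specific death
within 15). `exohem` implements a discovery pipeline that links two cheap,
serial blood readouts — per-patient pre- vs week-2 on-treatment changes in
plasma-exosomal RNA abundance, and CBC trajectories — to this endpoint, and
distills them into a small signed RNA signature that stratifies
disease-specific survival.

For each patient and cell type c ∈ {ANC, PLT, Hb, ALC, Mo} the CBC
trajectory is summarized as

* c0 (pre-treatment), min c (on-treatment nadir), c1 = √(c0·min c),
  c2 (week-2 value), c3 = log(c2/c0),

plus the ratios NLR = ANC/ALC, PLR = PLT/ALC, LMR = ALC/Mo at the 0- and
1-levels. RNA read counts (two samples per patient, eight biotypes) are
detection-filtered, TMM-normalized, and reduced to per-patient
log₂ fold changes (week-2 vs pre). The pipeline then:

1. correlates every RNA's log₂FC with every CBC feature and with binary
   early-death / early-progression indicators (Pearson, screening threshold
   p < 0.05, no multiplicity correction — documented as a screen, not
   inference);
2. admits RNAs linked to ≥3 of the 8 hematological groups *and* to both
   outcome indicators, or strongly correlated with ED (|R| > 0.5), and
   builds their log₂FC correlation networks at |R| > 0.5 and |R| > 0.6;
3. selects key RNAs by exhaustive all-subsets regression of the ED
   indicator on the network RNAs (best model per size by adjusted R²;
   ncRNAs kept at inclusion frequency > 50%, mRNAs > 60%), and separately
   the RNAs linked to all five cell types;
4. forms the composite score = +log₂FC(ED-positive ncRNA) −
   log₂FC(ED-negative ncRNA) − log₂FC(all-CBC mRNA) and compares
   disease-specific survival between score < 0 and score ≥ 0 by
   Kaplan–Meier / log-rank, reporting the 30-month rates.

A fully parameterized synthetic-cohort generator (negative-binomial paired
counts, latent-severity coupling between planted driver RNAs, CBC dynamics
and survival) makes every stage testable with known ground truth; a
homeostasis screen, propensity-score matching with matched group
comparisons, and a local Fisher over-representation test round out the
toolkit.

## Worked example

```python
from exohem import SimulationConfig, simulate_cohort, EDBiomarkerModel

recs, counts, truth = simulate_cohort(SimulationConfig(seed=7))
res = EDBiomarkerModel(recs, counts).fit()
print(res.summary())
```

```
Early-death biomarker pipeline
==============================================
patients: 40 (ED 8, EP 14)
RNAs after detection filter: 1997
admitted to network pool: 30
network |R| > 0.5: 10 nodes, 8 edges
network |R| > 0.6: 5 nodes, 4 edges
key ncRNAs: lncRNA_0000, lncRNA_0045, lncRNA_0221, miRNA_0000
key mRNAs: mRNA_0435
all-five-CBC RNAs: lncRNA_0000, lncRNA_0045, mRNA_0000, mRNA_0435, mRNA_0510, miRNA_0000
composite triple: +miRNA_0000, -lncRNA_0000, -mRNA_0000
  score high: 30-month DSS = 57.9%
  score low: 30-month DSS = 100.0%
  log-rank p = 0.0201
  score ED vs non-ED Wilcoxon p = 1.5e-05
  median follow-up (reverse KM) = 73.0 months
```

The planted drivers here are `miRNA_0000` (ED-positive), `lncRNA_0000` and
`mRNA_0000` (ED-negative); the fitted triple recovers all three with the
correct signs, and patients with composite score < 0 show 100% 30-month
disease-specific survival versus 57.9% for score ≥ 0 (log-rank p = 0.02).

The same analysis is available from the shell:

```bash
exohem simulate --seed 7 --out cohort/
exohem run --clinical cohort/clinical.csv --counts cohort/counts.tsv --out results/
exohem score-survival --log2fc results/log2fc.tsv --clinical cohort/clinical.csv \
    --triple triple.yaml --plot km.png
```

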