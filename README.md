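# hivcanlink

Record linkage of HIV laboratory records with cancer pathology records, and
analysis of cross-province cancer-diagnosis flows among people living with
HIV (PLHIV) in South Africa's nine provinces — built to run entirely on
synthetic data with known ground truth, because the real national
laboratory and cancer-registry extracts are restricted.

## The problem

HIV care in South Africa is decentralised: most patients are tested and
monitored close to home. Cancer diagnosis is not — pathology services
concentrate in a few provinces, so many PLHIV who develop cancer are
diagnosed outside the province where they receive HIV care. Quantifying
that flow requires linking two person-level record sets that share no
unique identifier:

* HIV-related laboratory records (CD4 counts and percentages, rapid tests,
  qualitative PCR, antibody/antigen tests), several per person, with noisy
  names, dates of birth or ages, episode and folder numbers;
* cancer pathology records with the same identifier fields plus diagnosis
  date, cancer type and province of diagnosis.

The pipeline (1) deduplicates the HIV records into persons, (2) links each
cancer record to a person, (3) applies eligibility filters (documented
positive HIV result, HIV care on or before the cancer diagnosis, known
diagnosis province), and (4) tabulates the origin–destination (OD) matrix
of home province (the province of most HIV records, a residence proxy)
against province of cancer diagnosis.

## The method

For records *a*, *b* sharing a blocking key (Soundex(surname)+birth year,
first-name prefix+birth year, or episode number), a comparison vector

γ(a,b) = (sim_JW(first), sim_JW(surname), 1 − min(|Δage|, 5)/5,
1[dob equal], 1[episode equal], 1[folder equal])

is built, with missing comparisons encoded at the uninformative midpoint
0.5. A linear support-vector machine trained on labelled pairs scores each
candidate pair; pairs with *w·γ + b ≥ 0* are matches, persons are the
connected components of the match graph (union–find transitive closure).
Because one false match fuses two whole persons under closure, the hinge
loss weights false matches 10:1 — see `docs/methods.md`.

Downstream, the OD matrix is reported with column percentages (where did
province X's HIV patients get their cancer diagnoses?), group differences
are tested with Pearson's χ², and the odds of out-of-province diagnosis
are modelled by logistic regression on age (per year), sex (ref. female),
Black vs non-Black (ref. non-Black) and cancer type.

## Worked example

```bash
python examples/04_printed_tables.py
```

```
study population (cell total): 65,143
diagnosed outside home province: 16,225 (24.9%)
Gauteng diagnosed the most cancers: 27,660
Western Cape keeps 94.9% of its patients in province;
KwaZulu-Natal keeps only 43.4%, sending 46.8% to Gauteng.
of all travellers, 61.5% were diagnosed in Gauteng
Black patients diagnosed outside their province: 26.2%
male patients diagnosed within their province: 77.6%
Black vs non-Black × location: chi² = 212.0, df = 1, p = 5.14e-48
```

These numbers are recomputed from the packaged OD and demographic cell
counts: Gauteng is the dominant destination for cross-province cancer
diagnosis, the Western Cape is nearly self-sufficient, and KwaZulu-Natal
sends almost half of its HIV cohort's cancer diagnoses to Gauteng.

`examples/01_simulate.py` … `03_cohort_and_tables.py` walk the synthetic
pipeline: generation with identifier corruption, supervised linkage
(deduplication precision/recall ≈ 0.98–0.99 against ground truth at the
default noise level), cohort filters and the same analytical outputs.

The same stages are scriptable from the shell:

```bash
hivcanlink run -o runs/demo --seed 7          # simulate → … → tables
hivcanlink tables -o runs/printed --fixtures  # reproduce the printed tables
```

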