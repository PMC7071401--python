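"""Spearman screening of DBM regions against a follow-up score.

Correlates each of the 78 baseline atrophy regions with the raw year-2
MoCA score over the patients and keeps regions with two-sided p < 0.05 —
the feature-selection step that feeds the classifier.  The planted effect
region should top the list by |rho|.
"""

import pdprognosis as pp

table, outcomes, truth = pp.generate_cohort(pp.CohortConfig(seed=42))

patients = pp.exclude_incomplete(table)
patients = patients.subset(patients.patient_ids)
patients = pp.impute_median(patients, patients.subject_ids)

target = outcomes.raw_scores["MoCA"].loc[patients.subject_ids, 2]
results = pp.select_features(patients, target, patients.dbm_columns, alpha=0.05)

print("screened DBM regions, year-2 MoCA (selected = p < 0.05):")
print(pp.screening_table(results, patients).head(10).to_string(index=False))

n_selected = sum(r.selected for r in results)
print(f"\n{n_selected} of {len(results)} regions pass the screen.")
print("planted year-2 region:", truth.planted_salient_names()["MoCA"][2])
print("top screened region:  ", results[0].feature)
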