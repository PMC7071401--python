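"""Generate a synthetic Parkinson cohort and inspect its structure.

Builds the default cohort — 116 patients and 42 healthy controls with 78
regional DBM atrophy values, striatal binding ratios, demographics,
biospecimen assays, baseline clinical scores, and MoCA / MDS-UPDRS-III
outcomes at years 1-4 — and prints what was planted.
"""

import pdprognosis as pp

config = pp.CohortConfig(seed=42)
table, outcomes, truth = pp.generate_cohort(config)

print(f"subjects: {len(table.subject_ids)} "
      f"({len(table.patient_ids)} patients, {len(table.control_ids)} controls)")
print(f"features: {table.values.shape[1]} "
      f"({len(table.dbm_columns)} DBM regions)")
print(f"missing cells: {int(table.values.isna().sum().sum())}")

print("\nfirst rows of the feature table:")
print(table.values.iloc[:3, [0, 1, 78, 82]].round(3))

print("\nyear-2 outcome categories (patients, 1 = impaired):")
for mod in pp.MODALITIES:
    frac = outcomes.categories[mod].loc[table.patient_ids, 2].mean()
    print(f"  {mod}: {frac:.2f} impaired")

print("\nplanted most-salient region per year (the ground truth the")
print("saliency analysis should recover):")
for mod, by_year in truth.planted_salient_names().items():
    print(f"  {mod}: {by_year}")

# write the cohort as CSV + ground-truth JSON
pp.write_cohort("scratch/example_cohort", table, outcomes, truth)
print("\nwrote scratch/example_cohort/{features,feature_meta,outcomes}.csv "
      "and ground_truth.json")
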