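"""Cohort statistics on a simulated four-group hypertension experiment.

Generates a cohort (PBS/Ang II infusion × control/telmisartan, calibrated
group means for CMH density, mean arterial pressure and Iba-1
immunoreactivity), then reports the statistics the study design calls for:
group means ± SEM, two-way ANOVA with Tukey comparisons, the CMH–MAP
Pearson correlation, and the hypertension fold-change in CMH burden.
"""

from cmhquant import CohortSpec, generate_cohort
from cmhquant.stats import anova_tukey, fold_change, pearson_correlation, summarize_groups

cohort = generate_cohort(CohortSpec(n_per_group=26, seed=12))

print(f"animals: {len(cohort)} in groups {sorted(cohort['group'].unique())}\n")

print("CMH density (per cm^2), mean +/- SEM:")
summaries = {s.group: s for s in summarize_groups(cohort, "cmh_density")}
for g in ("PBS-CTL", "AngII-CTL", "PBS-Tel", "AngII-Tel"):
    s = summaries[g]
    print(f"  {g:10s} {s.mean:5.2f} +/- {s.sem:.2f}  (n={s.n})")

fc = fold_change(summaries["AngII-CTL"].mean, summaries["PBS-CTL"].mean)
print(f"\nfold-change AngII-CTL / PBS-CTL: {fc:.1f}")

cohort["infusion"] = ["AngII" if g.startswith("AngII") else "PBS" for g in cohort["group"]]
cohort["drug"] = [g.split("-", 1)[1] for g in cohort["group"]]
res = anova_tukey(cohort, "cmh_density", ["infusion", "drug"])
print("\ntwo-way ANOVA (infusion x drug), p-values:")
for term in ("infusion", "drug"):
    print(f"  {term:9s} p = {res['anova'].loc[term, 'PR(>F)']:.2e}")
print("\nTukey pairwise comparisons (adjusted p, stars):")
for _, row in res["tukey"].iterrows():
    print(f"  {row['group1']:10s} vs {row['group2']:10s} p = {row['p-adj']:.4f} {row['stars']}")

two = cohort[cohort["group"].isin(["PBS-CTL", "AngII-CTL"])]
r, p = pearson_correlation(two["cmh_density"], two["map_final"])
print(f"\nCMH density vs final MAP (untreated groups): r = {r:.2f}, p = {p:.3g}")
print()
print("Ang II roughly doubles CMH density; telmisartan abolishes the rise,")
print("and CMH burden tracks blood pressure across untreated animals.")
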