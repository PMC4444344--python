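"""Context-variability statistics and library summaries.

One promoter measured in three contexts (low-copy RFP, medium-copy RFP,
medium-copy GFP): one-way ANOVA, Bonferroni-corrected pairwise t-tests to
form statistically indistinguishable sub-groups, and the small-sample
corrected CV over the sub-group means.  Then the whole-library summary:
fold activity range and mean spacing between strength-sorted members.
"""

import numpy as np

from luxrep import stats

rng = np.random.default_rng(2)
groups = [
    stats.MeasurementGroup("RFP-LC", rng.normal(1.00, 0.05, 4)),
    stats.MeasurementGroup("RFP-MC", rng.normal(0.96, 0.05, 4)),
    stats.MeasurementGroup("GFP-MC", rng.normal(0.55, 0.05, 4)),
]
out = stats.group_cv_procedure(groups, alpha=0.05)
print(f"ANOVA p = {out.anova_p:.4g}")
print(f"sub-groups: {out.subgroups}")
print(f"corrected CV = {out.cv_corrected:.3f} (N = {out.n_used}; {out.notes})")

# A 12-member graded-strength library (RPU values):
activities = [0.033, 0.047, 0.075, 0.12, 0.19, 0.30, 0.50, 0.78, 1.15, 1.7,
              2.3, 3.0]
summary = stats.library_summary(activities)
print(f"\nlibrary: {summary.n_members} members, "
      f"{summary.fold_range:.0f}-fold activity range, "
      f"mean spacing {summary.mean_spacing:.0%}")

# The two RFP contexts merge into one sub-group while GFP-MC separates, so
# the context CV is computed over the two sub-group means with the
# CV*(1+1/(4N)) small-sample correction.
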