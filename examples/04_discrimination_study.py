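"""Run the two-stage discrimination study on a phantom cohort.

Standardization, 5-fold-CV LASSO screening with prior sample weights,
then Wilcoxon + Holm ranking with group variances, ROC/AUC with
bootstrap CIs and Youden operating points.
"""

from locrad import PhantomConfig, run_discrimination
from locrad.studies import STUDY_CT_SPACING, phantom_cohort_table

config = PhantomConfig.ct(
    n_pos=30, n_neg=30, effect=2.0, seed=42, spacing=STUDY_CT_SPACING
)
table = phantom_cohort_table(config)
report = run_discrimination(table, seed=42, bootstrap_reps=500)

print(f"modality {report.modality}: {report.n_pos} LRRC vs {report.n_neg} NO LRRC")
print(f"LASSO selected {len(report.selected)} of 144 features\n")
cols = ["Rank", "RF", "AUC", "SN", "SP", "I", "p", "p (Holm)"]
print(report.to_table()[cols].round(3).to_string(index=False))
# Features are ranked by Holm-adjusted then raw Wilcoxon p.  I = SN+SP-1
# is the informedness of the Youden-optimal ROC operating point; the
# planted signal (S-MAD, dispersion of local skewness) should appear
# near the top with AUC around 0.9.
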