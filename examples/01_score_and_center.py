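"""Compute a multiplicative polygenic risk score and center it on controls.

The PRS is sum_i g_i * ln(OR_i): risk-allele dosage times the log of the
per-allele odds ratio, summed over the weight panel.  Interaction models use
the score centered at the control-sister mean, so main effects refer to a
woman of average genetic risk.
"""

from famgxe import DosageVector, SnpWeight, SnpWeightPanel, center_scores, compute_prs

panel = SnpWeightPanel((
    SnpWeight("rs2981582", "A", 1.27),   # FGFR2-like weight
    SnpWeight("rs3803662", "T", 1.20),
    SnpWeight("rs889312", "C", 1.13),
))

subjects = {
    "case_01": {"rs2981582": 2.0, "rs3803662": 1.0, "rs889312": 1.0},
    "ctrl_01": {"rs2981582": 1.0, "rs3803662": 0.37, "rs889312": 1.0},  # imputed
    "ctrl_02": {"rs2981582": 0.0, "rs3803662": 1.0, "rs889312": 2.0},
}

scores = [compute_prs(DosageVector(sid, d), panel) for sid, d in subjects.items()]
centered = center_scores(scores, centering_ids={"ctrl_01", "ctrl_02"})

print("subject    raw PRS   centered")
for s in centered:
    print(f"{s.subject_id}  {s.raw:8.4f}  {s.centered:+9.4f}")
print("\nCentered values are log odds relative to the control mean; a value of")
print("+0.10 multiplies the disease odds by exp(b_prs * 0.10) in a fitted model.")
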