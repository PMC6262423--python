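"""Score one infant's term-equivalent MRI findings.

Builds an injury profile for an infant with grade IV intraventricular
hemorrhage, a unilateral small cerebellar hemorrhage, and three punctate
white matter lesions, then applies the weighted scoring system and the
published decision threshold.
"""

from neoscore import InjuryProfile, classify_by_threshold, final_weights, score_injury

profile = InjuryProfile(
    ivh_grade="IV",            # high-grade IVH: 5 points
    ch_size="small",           # punctate/small cerebellar hemorrhage: 1 point
    ch_bilateral=False,
    wmi_lesion_count=3,        # >2 punctate lesions: multiple category, 5 points
    wmi_cystic=False,
)

weights = final_weights()
score = score_injury(profile, weights)
predicted_severe = classify_by_threshold(score, 8)

print(f"weighted MRI injury score : {score} / {weights.max_score}")
print(f"score > 8 decision rule   : {'severe impairment predicted' if predicted_severe else 'below threshold'}")
print()
print("The score adds one points value per injury domain (IVH, WMI, CH) plus")
print("a bonus point for bilateral cerebellar hemorrhage; higher is worse.")
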