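"""Data preparation: covariate adjustment, genotype recoding, marker screening.

Clinical scores are adjusted for nuisance covariates (sex, treatment dose) by
taking OLS residuals before clustering; genotypes arrive as {0,1,2} allele
counts and are recoded to the symmetric additive {-1,0,1} scale; markers are
screened by deleteriousness (scaled CADD > 25) and allele frequency (> 0.01),
with a known-association list that bypasses the thresholds.
"""

import numpy as np
import pandas as pd

import trajmoe as tm
from trajmoe.data_model import MarkerAnnotation

rng = np.random.default_rng(0)

# covariate adjustment: remove a sex effect and a dose trend from a score
n = 8
sex = np.repeat(["F", "M"], n // 2)
dose = rng.uniform(0, 300, n)
score = 20 + 3.0 * (sex == "M") + 0.01 * dose + rng.normal(0, 1, n)
resid = tm.adjust_clinical(score, pd.DataFrame({"sex": sex, "dose": dose}))
print("adjusted score residuals (mean ~ 0):", np.round(resid, 2))

# genotype recoding: {0,1,2} alternative-allele counts -> {-1,0,1}
calls = np.array([[0, 1, 2], [2, 1, 0]])
print("additive coding:\n", tm.encode_genotypes(calls))

# screening: keep known-association markers plus high-impact common ones
ann = [
    MarkerAnnotation("rs_a", scaled_cadd=30.0, allele_frequency=0.02),
    MarkerAnnotation("rs_b", scaled_cadd=20.0, allele_frequency=0.02),
    MarkerAnnotation("rs_c", scaled_cadd=26.0, allele_frequency=0.005),
    MarkerAnnotation("rs_d", scaled_cadd=10.0, allele_frequency=0.30),
]
kept = tm.screen_markers(ann, known_assoc={"rs_d"})
print("retained markers:", kept)  # rs_a passes both thresholds, rs_d is known
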