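"""Cohort statistics on a simulated population of 2000 subjects.

The simulator draws total abdominal muscle mass linear in age at sex-specific
slopes (-0.96 g/year female, -1.73 g/year male) around sex-specific means
(about 2041 g / 3086 g at age 60) and splits it across the 12 classes. The
analyses below recover those generating parameters.
"""

from muscleidp.cohort_stats import (
    correlate_with_age,
    decline_rate,
    density_error_analysis,
    descriptive_by_age_sex,
    fit_interaction_model,
)
from muscleidp.phantom import CohortSimSpec, generate_cohort

cohort = generate_cohort(CohortSimSpec(n_subjects=2000, seed=42))

desc = descriptive_by_age_sex(cohort)
overall = desc[desc.age_bin == "all"][["sex", "n", "total_mean", "total_sd"]]
print("total mass by sex (mean ± SD, g):")
for _, r in overall.iterrows():
    print(f"  {r.sex:6s} n={r.n:4d}  {r.total_mean:7.0f} ± {r.total_sd:.0f}")

for sex in ("female", "male"):
    out = decline_rate(cohort, sex)
    lo, hi = out["ci95"]
    r, p = correlate_with_age(cohort, "total_mass_g", sex)
    print(f"{sex}: decline {out['slope_g_per_year']:+.2f} g/year "
          f"(95% CI {lo:+.2f}..{hi:+.2f}), Pearson r with age {r:+.3f}")

fit = fit_interaction_model(cohort)
print("\nheight-adjusted SMM = b0 + b1*BMI + b2*sex + b3*sex*BMI (sex: 0=F, 1=M)")
for k, v in fit["params"].items():
    print(f"  {k:8s} {v:+9.3f}  (p = {fit['pvalues'][k]:.3g})")

excess, err = density_error_analysis(0.9, 1.06, 0.5)
print(f"\nmuscle is {excess:.1f}% denser than fat; assuming pure muscle under "
      f"50% fatty replacement overestimates mass by {err:.1f}%")
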