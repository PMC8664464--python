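"""Left-right head symmetry: wild types vs F2 hybrid males.

Builds the default synthetic symmetry cohorts (58 wild-type heads, 105 F2
hybrid heads), scores each head by folding it across its facial midline and
measuring the Procrustes distance between the sides, and compares the
cohorts. Appendage (leg/wing) asymmetry is tested the same way the study
did, by one-way ANOVA of |left - right| lengths.
"""

from scipy import stats as sps

from waspmorph import GeneratorConfig, generate_study
from waspmorph.symmetry import appendage_asymmetry, score_cohort

study = generate_study(GeneratorConfig(seed=42))

wt = score_cohort(study.wildtype_symmetry)
hyb = score_cohort(study.hybrid_symmetry)
print(f"wild-type heads (n={len(wt)}):  mean correlation "
      f"{wt['correlation_pct'].mean():.2f}%  (mean D_sym {wt['d_sym'].mean():.5f})")
print(f"hybrid heads   (n={len(hyb)}): mean correlation "
      f"{hyb['correlation_pct'].mean():.2f}%  (mean D_sym {hyb['d_sym'].mean():.5f})")

t, p = sps.ttest_ind(wt["d_sym"], hyb["d_sym"], equal_var=False)
print(f"Welch t-test on per-wasp Procrustes distances: t = {t:.1f}, p = {p:.2e}")

print("\nAppendage |left - right| ANOVA across Nv / Ng / hybrid groups:")
print(appendage_asymmetry(study.appendages).round(3).to_string(index=False))

print(
    "\nHybrid heads sit near 93% left-right correlation vs ~99.5% in wild"
    "\ntypes (p << 0.001), while legs and wings show no group effect"
    "\n(p > 0.05): developmental instability in hybrids is head-specific."
)
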