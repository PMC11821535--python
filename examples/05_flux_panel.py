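"""The 13C6-glucose isotopologue flux-ratio panel.

Control epidermis burns glucose for ~60% of its TCA-cycle entry
(V_PDH/V_CS ~ 0.6); the mutant epidermis pushes this toward 1.0 ("fuelled
almost entirely by glucose").  The example plants those truths with
realistic between-mouse noise (CV 0.1, n = 8 control vs 6 mutant mice),
recomputes the per-sample panel and runs the ANOVA comparison vs control.
"""

from epiredox.flux import compute_ratios, glutamine_dilution_check, group_summary
from epiredox.synthetic import generate_isotopologues

planted = {
    "CONTROL": {"v_pdh_vcs_acetylcoa": 0.6, "co2_per_glucose": 0.08},
    "BCAT_GOF": {"v_pdh_vcs_acetylcoa": 1.0, "co2_per_glucose": 0.16},
}
table, _ = generate_isotopologues(planted, n_per_group={"CONTROL": 8, "BCAT_GOF": 6},
                                  noise_cv=0.1, seed=5)
ratios = compute_ratios(table)
ratios = glutamine_dilution_check(ratios)

summary, comps = group_summary(
    ratios, ratio_names=["v_pdh_vcs_acetylcoa", "co2_per_glucose"]
)
print("per-group means (planted: control 0.6/0.08, mutant 1.0/0.16):")
for _, row in summary.iterrows():
    print(f"  {row.ratio:22s} {row.group:9s} {row['mean']:.3f} "
          f"+- {row.sd:.3f} (n={row.n})")
print("\ncomparisons vs control (Holm-adjusted):")
for _, row in comps.iterrows():
    print(f"  {row.ratio:22s} {row.comparison:22s} p = {row.p_holm:.2e}")
print(f"\nglutamine dilution (1 - glutamate/acetyl-CoA): "
      f"mean {ratios.glutamine_dilution.mean():+.3f} "
      "(near 0 -> negligible glutaminase carbon entry)")
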