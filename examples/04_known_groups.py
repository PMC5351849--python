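"""Known-group validity: can the composite separate groups expected to differ?

Fits random-intercept mixed models of the indexed composite on depression
status — unadjusted, then adjusted for age and gender — and applies the 15%
change-in-estimate rule to judge whether adjustment materially moved the
contrast.
"""

from topicscep import GeneratorConfig, generate_outcomes, group_mean, known_group_analysis

cfg = GeneratorConfig(n_projects=28, project_sizes=[400] * 28, total_n=11200)
df = generate_outcomes(cfg, seed=3)

unadj, adj, cmp = known_group_analysis(df, "depression", reference=0)
(eff,) = unadj.effects
(aeff,) = adj.effects
print(f"reference (no depression) mean: {unadj.reference_mean:.2f}")
print(f"unadjusted contrast: {eff.estimate:.2f} [{eff.ci_low:.2f}; {eff.ci_high:.2f}]")
print(f"depression group mean: {group_mean(unadj.reference_mean, eff):.2f}")
print(f"age/gender adjusted:  {aeff.estimate:.2f} [{aeff.ci_low:.2f}; {aeff.ci_high:.2f}]")
print(f"change in estimate: {cmp.pct_change['1']:.1f}% "
      f"({'exceeds' if cmp.exceeds_threshold['1'] else 'within'} the 15% rule)")
print()
print("The generating truth is a -1.16 point lower composite score with\n"
      "depression. Age and gender are independent of depression in this\n"
      "cohort, so adjustment should (and does) leave the contrast nearly\n"
      "unchanged — the change-in-estimate stays under 15%.")
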