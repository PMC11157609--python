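"""Clean and thin occurrences, then screen the climate variables.

Thinning keeps one record per grid cell and drops duplicates and sea
points; screening removes zero-contribution variables and, within every
highly correlated pair (|r| > 0.8), the lower-contribution member.
"""

import nichecast as nc

stack, niche, occurrences = nc.demo_world(seed=0)

thinned, report = nc.thin_to_grid(occurrences, stack)
print(f"thinning: {report.n_input} records -> {report.n_after_dedup} after "
      f"de-duplication -> {report.n_after_sea_filter} on land -> "
      f"{report.n_retained} (one per occupied cell)")

contrib = nc.pretrain_contributions(thinned, stack, seed=0, n_background=2000)
corr = nc.correlation_matrix(stack, seed=0)
selection = nc.select_variables(contrib, corr, r_threshold=0.8)

print("\npre-training contributions (%):")
print(contrib.to_frame().sort_values("contribution_pct", ascending=False)
      .to_string(index=False))
print(f"\nretained variables: {selection.retained}")
for var, reason in selection.exclusions:
    print(f"  dropped {var}: {reason}")
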