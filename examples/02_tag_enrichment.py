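"""Characterize a hit set by tag enrichment.

Variable names are fragmented into semantic tags (paw identity, measurement
category); each tag is tested for over-representation among the group-term
hits with an exact upper-tail hypergeometric test.  Here the injected group
effect sits entirely on left-forepaw stand variables, so that tag should
top the ranking.
"""

from gaitscreen import (EffectSpec, NormalizationPolicy, SimConfig,
                        case_one_spec, drop_unusable_variables, enrich_tags,
                        normalize_to_baseline, screen, simulate_study,
                        wordcloud_weights)

structure = [(("LF", "Stand"), 8), (("RF", "Swing"), 8),
             (("RH", "Stride"), 8), (("LH", "Cadence"), 8)]
cfg = SimConfig(n_variables=32, n_per_group=10, tag_structure=tuple(structure),
                effects={"group": EffectSpec(tuple(range(8)), 2.5)}, seed=11)
study = simulate_study(cfg)
ds = normalize_to_baseline(drop_unusable_variables(study.to_dataset()),
                           NormalizationPolicy("pre"))
result = screen(ds, case_one_spec())

enrichment = enrich_tags(result, "group")
print("tag enrichment for the group-term hit set")
print(enrichment.head(8).to_string(index=False))
# K = universe variables carrying the tag, k = of those, how many are hits;
# p_enrich = P(X >= k) drawing n hits from the N-variable universe.

weights = wordcloud_weights(enrichment)
print("\nword-cloud weights (size = hits carrying tag, color = -log10 p):")
print(weights.head(8).to_string(index=False))
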