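"""Figures from a screened study: heatmap, Venn, trajectories, UMAP.

Writes PNGs plus the delimited tables each figure is drawn from into
./example_output/, so every figure is re-derivable without matplotlib.
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from gaitscreen import (EffectSpec, NormalizationPolicy, SimConfig,
                        case_one_spec, drop_unusable_variables, embed_animals,
                        hit_matrix, normalize_to_baseline, screen,
                        simulate_study, trajectory_plot_data, venn_counts)
from gaitscreen.viz import (plot_embedding, plot_heatmap, plot_trajectory,
                            plot_venn)

out = Path("example_output")
out.mkdir(exist_ok=True)

cfg = SimConfig(n_variables=40, n_per_group=10,
                effects={"group": EffectSpec(tuple(range(10)), 2.5),
                         "timepoint": EffectSpec(tuple(range(5, 15)), 2.0)},
                seed=3)
study = simulate_study(cfg)
nds = normalize_to_baseline(drop_unusable_variables(study.to_dataset()),
                            NormalizationPolicy("pre"))
result = screen(nds, case_one_spec())

neglog, hits = hit_matrix(result)
neglog.to_csv(out / "heatmap.tsv", sep="\t")
plot_heatmap(neglog).figure.savefig(out / "heatmap.png", dpi=150,
                                    bbox_inches="tight")

counts = venn_counts(result.hit_sets())
print("venn regions:", {"+".join(sorted(k)): v for k, v in counts.items()})
plot_venn(counts).figure.savefig(out / "venn.png", dpi=150)

affected = sorted(study.truth["group"])[0]
traj = trajectory_plot_data(nds, affected)
print(f"\ntrajectory of {affected!r} (normalized, group mean +/- sem):")
print(traj.to_string(index=False))
traj.to_csv(out / "trajectory.tsv", sep="\t", index=False)
plot_trajectory(traj, affected).figure.savefig(out / "trajectory.png", dpi=150,
                                               bbox_inches="tight")

embedding = embed_animals(nds, seed=42, n_neighbors=8)
embedding.to_csv(out / "umap.tsv", sep="\t", index=False)
plot_embedding(embedding).figure.savefig(out / "umap.png", dpi=150,
                                         bbox_inches="tight")
plt.close("all")
print(f"\nfigures and tables written to {out}/")
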