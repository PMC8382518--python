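"""Select genes from a simulated expression matrix and inspect the result.

Generates a 200-gene x 60-sample matrix with 3 sample clusters, 10
informative genes, 20 redundant copies and 170 noise genes, fits the
selector, and prints the top-ranked genes with their planted roles.
"""

from g3cs import (
    RunConfig,
    SyntheticSpec,
    fit,
    gene_scores,
    generate_dataset,
    select_top_genes,
)

data, truth = generate_dataset(SyntheticSpec(seed=0))
print(f"data: {data.n_genes} genes x {data.n_samples} samples, "
      f"{len(set(data.labels))} clusters")

config = RunConfig(c=3, seed=0)  # alpha=10, beta=1e-3, gamma=1 defaults
state = fit(data, config)
print(f"solver: converged={state.converged} after {state.iterations} sweeps, "
      f"objective {state.objective_trace[0]:.3f} -> {state.objective_trace[-1]:.3f}")

ranking = select_top_genes(gene_scores(state.P), 10)
print("\nrank  gene_id   score     planted role")
for r, g in enumerate(ranking.selected, start=1):
    print(f"{r:>4}  {data.gene_ids[g]:<8}  {ranking.scores[g]:<8.4f} "
          f"{truth.gene_roles[g]}")

n_signal = sum(truth.gene_roles[g] != "noise" for g in ranking.selected)
print(f"\n{n_signal}/10 of the selected genes carry planted cluster signal; "
      "'informative' and 'redundant' genes are near-copies of each other, "
      "so either label indicates a correct pick.")
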