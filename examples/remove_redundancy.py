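"""Build a redundancy graph over a family of similar complexes and prune it.

Four copies of one complex diverge structurally by 0/2/4/6 A RMS while
keeping identical sequences: pairs within 5 A RMSD of each other are
redundant (sequence identity > 60% and E-value < 1e-30 already hold), so
the family forms a path graph which greedy max-degree deletion reduces to
an independent set.  An update step then folds in one genuinely new case.
"""

from dockbench.fixtures import FixtureSpec, generate_redundant_family
from dockbench.redundancy import build_graph, prune_max_degree, update_benchmark

fam = generate_redundant_family(
    FixtureSpec(n_copies=4, conformational_rms=[0.0, 2.0, 4.0, 6.0], seed=7)
)
for v in fam.verdicts:
    print(f"{v.pair[0]} vs {v.pair[1]}: seq_redundant={v.sequence_redundant}"
          f"  RMSD={v.rmsd:.1f} A  redundant={v.redundant}")

g = build_graph(fam.verdicts, [c.case_id for c in fam.cases])
retained, log = prune_max_degree(g)
print(f"\ngraph: {g.number_of_nodes()} nodes, {g.number_of_edges()} edges")
for entry in log:
    print(f"  step {entry['step']}: removed {entry['removed']} (degree {entry['degree']})")
print(f"retained (non-redundant): {sorted(retained)}")

result = update_benchmark(sorted(retained), ["new_case"], lambda a, b: False)
print(f"\nafter update with one distinct new case: {sorted(result.retained)}")
print("a new case similar to nothing starts its own non-redundant group")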