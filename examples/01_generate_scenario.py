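"""Generate a synthetic study scenario with planted ground truth.

Builds the default end-to-end scenario (86 genes x 47 time points, a mixed
PPI/PDI network with three planted regulatory modules, and a toy GO layer)
and prints what was planted.
"""

from trnmotif import synthetic

data = synthetic.generate(synthetic.small_scenario(seed=17))

print(f"expression: {data.expr.n_genes} genes x {data.expr.n_times} time points, "
      f"{data.expr.missing_mask.mean():.1%} missing cells")
print(f"network:    {len(data.net.nodes)} nodes, "
      f"{len(data.net.ppi_edges)} PPI edges, {len(data.net.pdi_edges)} PDI edges")
print(f"ontology:   {len(data.ontology.terms)} terms, "
      f"{len(data.annotations.genes)} annotated genes")
print("planted modules (motif class, regulators, true target clusters):")
for mod in data.truth["modules"]:
    print(f"  {mod['name']:<16s} {mod['signature']:<22s} "
          f"TFs={mod['tfs']} clusters={mod['clusters']} "
          f"({len(mod['instances'])} network instances)")
# Each planted module is what the full pipeline should rediscover: its motif
# class must test significant and the GA-PSO search must point the TF back
# at the planted target clusters.
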