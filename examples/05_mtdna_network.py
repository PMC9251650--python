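"""mtDNA haplotypes: collapse an alignment and build the median-joining
network (epsilon = 0)."""

import powan

template = powan.StudyTemplate()
records, info = powan.generate_study_mtdna(template, seed=5)
print(f"{len(records)} sequences of {len(records[0][1])} bp, "
      f"{info['n_mutations']} mutations on the genealogy")

pop_of = {name: name.split("_")[0] for name, _ in records}
haps = powan.collapse_haplotypes(records, pop_of=pop_of)
print(f"{haps.n_haplotypes} haplotypes; frequencies {haps.frequency.tolist()}")
for lab in haps.labels:
    print(f"  {lab}: {haps.pop_counts[lab]}")

net = powan.median_joining(haps, epsilon=0)
print(f"network: {net.graph.number_of_nodes()} nodes "
      f"({len(net.medians)} median vectors), "
      f"{net.graph.number_of_edges()} edges, "
      f"total weight {net.total_weight()} mutational steps")
for u, v, d in sorted(net.graph.edges(data=True)):
    print(f"  {u} -- {v}  ({d['weight']} step(s))")
# Hash-mark counts on a published network figure correspond to these edge
# weights; median vectors are inferred unsampled intermediates.
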