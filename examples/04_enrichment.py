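"""Term over-representation of a selected trend cluster.

The hypergeometric upper tail (one-sided Fisher exact) asks whether an
annotation term contributes more members to the selected set than a
random draw from the quantified universe would.  The simulator plants
one enriched term per trend template; they should top the ranking.
"""

import phostrend as pt
from phostrend.io import terms_to_termsets

ds = pt.simulate_dataset(pt.SimulationConfig(seed=1))
truth = ds.truth
cluster = set(truth.protein_template.index[truth.protein_template >= 0])
universe = set(truth.protein_template.index)

res = pt.enrich(cluster, terms_to_termsets(ds.terms), universe, alpha=0.05)
print("top 5 terms (k/K = overlap/term size; fold = (k/n)/(K/N)):")
print(res.table.head(5)[["term", "k", "K", "fold", "p", "p_adj", "significant"]]
      .to_string(index=False))
print(f"\nplanted enriched terms: {sorted(truth.enriched_terms.values())}")
print(f"significant at p<0.05: {res.significant['term'].tolist()}")
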