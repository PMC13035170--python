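"""Over-representation analysis of a gene set against term annotations.

A query of 30 genes is tested against three terms by the hypergeometric
upper tail, BH-adjusted, and binned at the <0.01 / <0.001 / <1e-4
reporting thresholds.  The first term is deliberately enriched.
"""

import numpy as np

from oglyco import TermAnnotation, enrich

rng = np.random.default_rng(0)
background = [f"gene{i}" for i in range(400)]
terms = [
    TermAnnotation("GO:0008380", "RNA splicing", frozenset(background[:40]), "BP"),
    TermAnnotation("GO:0003723", "RNA binding",
                   frozenset(rng.choice(background, 60, replace=False)), "MF"),
    TermAnnotation("GO:0005681", "spliceosomal complex",
                   frozenset(rng.choice(background, 30, replace=False)), "CC"),
]

# 20 genes from the first term plus 10 random ones
query = set(background[:20]) | set(rng.choice(background[40:], 10, replace=False))

for res in enrich(query, terms, background):
    t = res.term
    print(f"{t.term_id}  {t.term_name:22s} overlap {res.overlap:2d}  "
          f"p {res.p_value:10.3g}  FDR {res.fdr:10.3g}  bin {res.fdr_bin}")

print("\nThe FDR bin is the reporting category; 'ns' means the adjusted "
      "value clears none of the three thresholds.")
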