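"""Two-source ortholog agreement over a worm gene list.

Nine query genes are mapped to human orthologs through two databases: one
maps seven, the other five, and two genes are mapped by neither — so 7/9
(78%) of the genes have an ortholog in at least one source.
"""

from oglyco.annotation import OrthologRecord, ortholog_agreement

records = []
for i in range(9):
    gene = f"worm-gene-{i}"
    records.append(OrthologRecord(gene, "UniProt", f"HUMAN{i}" if i < 7 else None))
    records.append(OrthologRecord(gene, "OrthoList2", f"HUMAN{i}" if i < 5 else None))

summary = ortholog_agreement(records)
print(f"genes queried:        {summary.n_genes}")
for source, count in summary.per_source.items():
    print(f"mapped by {source:12s} {count}")
print(f"mapped by both:       {summary.both_sources}")
print(f"mapped by neither:    {summary.neither}")
print(f"any-source coverage:  {summary.percent_any_source:.0f}%")
print("\nThe headline number is the share of query genes with a human "
      "ortholog in at least one database; disagreement between sources "
      "reflects coverage and curation differences, not conflicting biology.")
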