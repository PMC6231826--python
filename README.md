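# variantcompare

Compare 2–4 personal gene-variant reports, headlessly.

Direct-to-consumer genotyping hands people a raw file of hundreds of
thousands of genotype calls and leaves interpretation to them — and genetic
findings are rarely about one person alone: a recessive pathogenic allele in
a parent matters to the children, and siblings want to know what they share
and what sets them apart. `variantcompare` is a library and command-line
pipeline for exactly that comparison task:

1. **Annotate.** Join one person's raw genotype file (the consumer
   tab-separated dialect: `rsid  chromosome  position  genotype`) against a
   variant-effect knowledge base (CSV, modeled on public variant-
   interpretation reports). Only variants with known, published effects are
   reported. Each match is classified by **zygosity** (heterozygous /
   homozygous / hemizygous), **display impact** (pathogenic / benign /
   protective / pharmacogenetic — or **carrier**, when a recessive
   pathogenic variant is heterozygous), and a **rarity size** in (0, 1]
   that grows as the population allele frequency falls.
2. **Compare.** Partition the union of N ∈ {2,3,4} reports by *membership
   signature*: each distinct variant key `(rsid, risk allele)` is assigned
   to the exact subset of persons carrying it. Per-person views are kept —
   the same variant can be carrier status in a parent and pathogenic in a
   homozygous child. Query operations answer things like *which child
   shares the most cancer-related variants with parent 1?*
3. **Filter.** Combinable facets (person, health category, impact,
   certainty of evidence) plus case-insensitive substring search: OR within
   a facet, AND across facets, with the partition recomputed over visible
   persons.
4. **Lay out.** Deterministic geometry for four comparison views — tabular
   report, aligned linear rows, concentric sunburst rings, and a two-set
   Venn of packed bubbles — with the shared visual encoding: color =
   impact (red / gray / blue / purple, polka-dot pattern = carrier), size =
   rarity, shared variants placed first and aligned across rows/rings.
   Rendered as standalone, byte-deterministic SVG or JSON.

A seeded synthetic-data module generates the knowledge base and a nuclear
family (Hardy–Weinberg parents, Mendelian children, no de novo mutations),
so the whole pipeline is testable without any real genomes.

## Core definitions

For genotype g at a variant with risk allele r:

- zygosity(g, r) = heterozygous if exactly 1 of 2 alleles equals r,
  homozygous if 2 of 2, hemizygous if a single-allele call equals r;
  no-calls (`--`) and non-carriers are absent from the report.
- display impact = **carrier** iff base impact is pathogenic AND
  inheritance is recessive AND zygosity is heterozygous; otherwise the base
  impact passes through.
- rarity size for allele frequency f, with floor f_min = 1e-4 and minimum
  size s_min = 0.05:

  `size(f) = s_min + (1 − s_min) · log10(1/f) / log10(1/f_min)`, f clamped
  to [f_min, 1] — strictly decreasing, so glyph-size order always equals
  rarity order.
- membership class of variant v = { p : person p carries v }; every variant
  lies in exactly one class, and classes are ordered all-persons first,
  then by descending signature size.

## Worked example

```bash
variantcompare simulate --seed 42 --variants 50 --children 2 --out-dir data
for p in parent1 parent2 child1 child2; do
  variantcompare annotate data/$p.txt data/kb.csv --person-id $p -o $p.report.csv
done
variantcompare compare parent{1,2}.report.csv child{1,2}.report.csv -o family.json
variantcompare render family.json --view sunburst -o sunburst.svg
```

The same pipeline from Python, with the numbers it prints:

```python
>>> import variantcompare as vc
>>> cfg = vc.SimulationConfig(seed=42)          # 50 variants, 2 children
>>> kb = vc.generate_kb(cfg)
>>> fam = vc.simulate_family(kb, cfg)
>>> reports = {p: vc.annotate(g, kb) for p, g in fam.items()}
>>> cmp = vc.compare(list(reports.values()))
>>> len(cmp.all_keys())
10
>>> vc.shared_count(cmp, ("parent1", "child1"))
5
>>> [(v.effect.variant_name, v.zygosity.value) for v in vc.carrier_outlook(reports["child1"])]
[('GENE20-X20Y', 'heterozygous')]
>>> vc.compare_counts(cmp, "parent1", "parent2")
'more'
```

Of the 50 variants with known effects, this family carries 10 distinct
risk alleles; parent 1 and child 1 share 5 of them; child 1 is a carrier
(heterozygous for a recessive pathogenic allele — unaffected themselves,
relevant to their future children) of one variant; and parent 1 carries
more known variants than parent 2. The sunburst SVG draws one ring per
family member (first person outermost), one arc per carried variant, with
shared variants radially aligned and arc length proportional to rarity.

Filtering works on every view, e.g.
`variantcompare render family.json --view table --filter-category Cancer
--filter-impact carrier --search alzheimer -o hits.svg`.

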