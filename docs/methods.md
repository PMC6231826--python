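# Methods

## The annotation model

A person's raw genotype file is a set of calls `(rsid, chromosome,
position, genotype)` in the consumer tab-separated dialect; the
knowledge base is a table of effect records keyed by `(rsid, risk_allele)`
with a base impact (pathogenic, benign, protective, pharmacogenetic), an
inheritance mode (dominant, recessive, unknown), a certainty level
(well-established, likely, uncertain), a population allele frequency in
(0, 1], and free-text category/importance/summary fields. Annotation is an
inner join on rsid, kept only where at least one genotype allele equals the
risk allele. Three classifications are derived per match.

**Zygosity.** Count of risk alleles in the call: 1 of 2 → heterozygous,
2 of 2 → homozygous, the single allele of a length-1 call → hemizygous.
Any call containing `-` is treated as a no-call and excluded entirely: a
half-called genotype cannot distinguish heterozygous from homozygous, so we
do not guess.

**Carrier derivation.** Display impact equals base impact except that
(pathogenic, recessive, heterozygous) → carrier. The rule is the genetic
definition of carrier status: one working copy masks a recessive allele, so
the person is unaffected but can transmit it. Homozygous and hemizygous
recessive genotypes remain pathogenic, dominant alleles are pathogenic at
any zygosity, and `unknown` inheritance is treated like dominant —
deliberately conservative: we never downgrade a pathogenic call to carrier
without positive evidence the allele is recessive. Non-pathogenic impacts
never become carrier. The full 4 × 3 × 3 truth table is frozen in the test
suite and checked exhaustively.

**Rarity size.** Views draw rarer variants larger. The score is affine in
log frequency,

    size(f) = s_min + (1 − s_min) · log10(1/f) / log10(1/f_min),

with f clamped to [f_min, 1], f_min = 1e-4, s_min = 0.05 (both are config
keys, `rarity.f_min` / `rarity.s_min`). Frequencies at or below the floor
get the full size 1; frequency 1 gets s_min so the commonest allele is
still visible. We use the affine rescale rather than a hard floor
`max(s_min, ·)` because a floor would flatten the top of the frequency
range and break the strict monotonicity that makes glyph-size order
trustworthy: with this form, size ordering equals rarity ordering
everywhere on [f_min, 1], which the tests check on a dense grid and in all
three geometric layouts.

Only one strand convention is supported: genotypes are assumed reported on
the same strand as the knowledge base's risk alleles, and no complement
matching is attempted — strand ambiguity is unresolvable without genome
build metadata, and silently flipping would manufacture false matches.

## Comparison semantics

Variant identity across persons is the key `(rsid, risk_allele)`, not the
person-specific zygosity: a variant that is carrier status in one sibling
and pathogenic in the other still counts as shared. The comparison report
is a partition of the union of the input reports by membership signature
(the exact carrying subset), with per-person annotated views retained
inside each entry. Classes are ordered: the all-persons signature first,
then descending signature size, ties by the order persons were given —
fixed so layouts get "shared first" without re-sorting. The partition code
is general in N; the public surface caps N at 4, the largest family the
views are designed for.

Query operations are thin, oracle-checkable reductions over the partition:
`shared_count` sums class sizes over signatures that contain the queried
subset, `compare_counts` relates two persons' (optionally filtered) counts,
and `carrier_outlook` selects the carrier-status variants of one report —
the variants relevant to offspring rather than to the person themselves.

## Filter algebra

Facets: persons, categories, impacts, certainties, plus a search term
(case-insensitive substring over name, category, clinical importance, and
summary). Within a facet any selected token suffices; across facets every
nonempty facet must hold; the empty spec is the identity. Search is just
another facet, not a separate mode.

Two design points needed care:

- **Impact is evaluated per (variant, person) cell.** Display impact is the
  one per-person attribute, so "variant matches if any person matches"
  would make filter results depend on the order person-hiding and impact
  facets are applied. Instead a person's copy of a variant survives iff
  that person's display impact is selected; the variant survives iff any
  visible copy survives, and the membership signature is recomputed from
  surviving copies. This makes facet application commutative and
  associative — applying facets one at a time equals applying them at once,
  which the suite checks on hundreds of random (view, spec) pairs.
- **Category tokens and search terms are not validated against the view's
  current inventory.** Persons are validated (an unknown person id is a
  hard error) and impact/certainty tokens are validated against their
  closed enumerations, but categories are open labels: validating them
  against the view would make composed filters error where the algebra
  says they should simply select nothing.

Hiding persons recomputes the partition over the visible subset and must
leave at least 2 visible (a comparison is 2–4 persons by construction).

## Layout geometry

Sunburst and linear views share a slot allocator: one global slot per
distinct variant, in class order (shared first, then category, then
variant name), slot width proportional to rarity size, and a uniform gap of
`layout.gap_fraction` (default 0.2) times the mean slot width between
slots. Widths and gaps are normalized so that slots + gaps total exactly
360° (sunburst) or the unit interval (linear); the suite checks angular
closure to 1e-9. A glyph is emitted at the variant's slot in every
ring/row whose person carries it, so shared variants are radially and
vertically aligned by construction, and within-ring overlap is impossible
(slots are disjoint by construction).

Ring order is an explicit parameter because both conventions are defensible
for concentric family views; the default puts the first person outermost.
Rows run top-down in the given order. Certainty has no positional encoding
in these comparison views — it is exposed through filtering and the table
fields only.

The two-set Venn assigns bubbles to left-only / shared / right-only
regions (vertical thirds of the unit square). Packing is deterministic:
within a region, bubbles sorted by descending radius (ties by key) are
placed row-major at the cell centers of a `ceil(sqrt(k))`-column grid
inscribed in the region box. A single radius scale is used across all
three regions — chosen as 0.45 × the tightest grid cell over the fullest
region — so that radius ordering equals rarity ordering globally and no
circle can leave its cell, which makes overlap geometrically impossible.
This trades packing density for determinism and provable non-overlap; a
force-directed packer would be denser but order-sensitive.

Carrier glyphs use the pathogenic red base color with a polka-dot pattern
overlay (an SVG `<pattern>` fill): carrier status is a zygosity-derived
state of a pathogenic allele, so it keeps the pathogenic hue. SVG output
is generated by a deterministic string templater — identical layouts
produce byte-identical files, with one `class="glyph"` element per layout
element so documents are machine-checkable.

## Synthetic data: what it emulates and what it does not

The generator produces the study conditions the pipeline is exercised
under: a knowledge base of 50 variants (names `GENE{i}-X{i}Y`, log-uniform
allele frequencies in (0.001, 0.5), impact mix 0.35 pathogenic / 0.40
benign / 0.10 protective / 0.15 pharmacogenetic, categories cycled through
an 8-label health-category pool, inheritance assigned to pathogenic
variants with at least one recessive guaranteed so carrier status is always
exercisable), and a nuclear family of 2 parents plus up to 2 children.
Parents are drawn per site under Hardy–Weinberg equilibrium at the
variant's frequency; each child allele is chosen uniformly from the
corresponding parent's two alleles, independently per site. The impact mix
and frequency range are one-time choices meant to resemble a consumer
variant-interpretation report: mostly benign/pathogenic associations, few
protective alleles, and frequencies spanning rare to common. Sites are
autosomal by default; an `include_x` flag puts ~10% of sites on X with a
hemizygous father and hemizygous sons (single maternal allele), for
exercising hemizygous calls.

Deliberate non-realism, chosen because the comparison tool needs
controllable sharing structure rather than population-genetic fidelity: no
de novo mutations (so child-only membership classes are provably empty —
a pipeline-closure invariant the tests use), no linkage disequilibrium
(sites independent, so the Mendelian oracle is exhaustive), no phasing, no
genotyping error or no-calls, and a single fixed non-risk allele per
variant. Consequently, passing tests demonstrate the correctness of the
annotation/comparison/layout machinery under Mendelian inheritance — they
say nothing about strand handling of real array data, genome-build
mismatches, or error-laden calls, which are documented non-goals.

All randomness flows from one integer seed through independent named
streams (KB generation vs genotype sampling), so a configuration
reproduces byte-identical datasets.

## Problem sizes in the test suite

The default suite verifies the partition against a powerset-membership
oracle on 200 seeded families at each of N = 2, 3, 4 (25 variants each);
filter algebra on 500 random (view, spec) pairs; layout geometry on 100
random comparisons; Mendelian consistency on 20 seeds × 10,000 sites × 2
children with a 3-standard-error Hardy–Weinberg check on parental allele
counts; and an end-to-end run (seed 42, 50 variants) whose four rendered
SVGs are parsed and glyph-counted against the conservation formula
Σ_variants |carrying persons|. The whole suite completes in well under a
minute on a single CPU.

## Known limitations

- Presence requires the knowledge base's risk allele verbatim; opposite-
  strand reports produce false negatives by design (see strand note).
- Compound heterozygosity across different rsids in one gene is not
  modeled; each variant is classified independently.
- The Venn view is two-set only; for 3–4 persons use the table, linear, or
  sunburst views.
- Report CSVs carry the full effect record per row (denormalized) so that
  a report round-trips without the knowledge base; the cost is file size,
  irrelevant at report scale.
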