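# Methods

This note documents the models and procedures implemented in `panelvar`, the
parameters that matter, the design choices made where the underlying
conventions were genuinely open, and what the synthetic panel does and does
not establish about real data.

## Variant filtering and classification

A per-genotype call is retained when its phred quality is **strictly greater
than 30** and its read depth is **at least 5** (quality strict, depth
non-strict — exactly as the thresholds are phrased in common pipeline
practice for this analysis). A second pass removes every variant whose
nearest same-chromosome neighbour is **closer than 5 bp**; both members of a
too-close pair are removed, which makes the rule symmetric and
order-independent. Flanking distance is measured between VCF POS anchors,
not allele end coordinates; the brute-force oracle in the tests uses the
same definition so the two can be compared meaningfully. The flank rule is
applied per genotype, after the quality/depth pass, so a low-quality
neighbour cannot evict a good call.

Retained records are classed SNP (both alleles one base), insertion or
deletion. Only length differences of **1–58 bp** count as Indels; longer
events and equal-length multi-base substitutions go to an `OTHER` audit
class that is excluded from all SNP/Indel statistics but never silently
dropped, so `|input| = |kept| + |removed|` holds at every stage.
Multi-allelic sites are processed on their first ALT allele and flagged.

## Panel matrix and line-specific variants

The panel is the union of sites across genotypes. A genotype without a
record at a union site is called homozygous-reference **only when its depth
profile covers the site at >= 5 reads**; otherwise the cell is `missing`.
Depth is the only confidence signal available for a non-call, and the
line-specific rule below presumes confident reference calls in the other
genotypes, so this policy is load-bearing.

A site is **line-specific** for genotype *s* when *s* carries the alternate
allele (het or hom-alt) and every other genotype is hom-ref; a `missing`
call anywhere disqualifies the site. The heterozygosity rate is
`n_het / (n_het + n_hom)` over a genotype's SNP calls (0 when it has none),
which reproduces the 0–1 scale such panels report. Pairwise SNP counts use
genotype disagreement at SNP sites (neither genotype missing) — a
definition chosen because it counts exactly the polymorphisms usable
between a pair of parents; union-of-alternate-alleles would also count
shared non-reference sites that cannot segregate in a cross.

## Distribution statistics

Windows are fixed 100-kb tiles anchored at coordinate 0 (the last tile of a
chromosome may be short); every union site belongs to exactly one window,
so window counts sum to chromosome totals by construction. Per-chromosome
SNP density is SNP union sites per kb; the polymorphism rate additionally
counts Indel sites. All distribution statistics are computed over union
sites, making them invariant to sample and site order.

## Effect annotation

Gene models are single-transcript (gene-level effect reporting needs no
isoforms). A variant anchor inside a CDS interval is exonic; inside a gene
span but no exon, intronic; otherwise intergenic. Exonic-but-untranslated
positions and variants whose allele span crosses an exon boundary are routed
to the `OTHER` audit stream rather than guessed at.

For a coding SNP the affected codon is rebuilt on the coding strand
(alleles reverse-complemented for minus-strand genes) and both codons are
translated with the standard genetic code: same amino acid →
`SYNONYMOUS_CODING` (`SYNONYMOUS_STOP` when a stop codon remains a stop);
different → `NON_SYNONYMOUS_CODING`; sense→stop → `STOP_GAINED`; stop→sense
→ `STOP_LOST`. At the initiator codon, a change to GTG or TTG — the common
alternative initiation codons — is `NON_SYNONYMOUS_START` (the gene remains
plausibly translatable from a near-cognate start), any other change is
`START_LOST`. This is the one place a protein-diff oracle cannot
discriminate, so the initiator rule is tested against explicit genetic-code
expectations while every other codon is verified against a whole-CDS
re-translation oracle. Coding Indels are `FRAME_SHIFT` unless their length
is a multiple of three (`CODON_INSERTION` / `CODON_DELETION`).

Summary tallies define mis-sense = non-synonymous coding + non-synonymous
start, non-sense = stop gained, silent = synonymous coding + synonymous
stop.

## CNV/PAV calling

Only genes **>= 1,000 bp** are considered. Per gene and genotype the caller
computes *breadth* (fraction of gene-span bases covered by >= 1 read) and
the *depth ratio* (mean gene depth / genome-wide median depth of the
genotype). Breadth **< 10 %** is absence, **> 50 %** presence; the 10–50 %
gap is deliberately `AMBIGUOUS` rather than forced into a binary call, so
borderline genes are auditable. The absence/presence percentages are
interpreted as breadth of coverage — the standard PAV statistic — because a
percentage of a per-gene mean depth has no natural scale; both statistics
are computed and reported should a depth-based operand be preferred.

Duplication is called at depth ratio **>= 1.75**, the midpoint-plus-margin
between one-copy (≈1.0) and two-copy (≈2.0) expectations; a full
segmentation-based CNV caller is intentionally out of scope, and the
threshold statistic is transparent and testable instead. Any (gene, event)
pair also called in the reference-vs-self control is excluded as a mapping
artefact; exclusion is idempotent. Panel-level reductions produce the
non-redundant duplicated/absent gene sets (union over genotypes),
line-specific events (exactly one carrier), and per-gene carrier counts.

## Structural-variant typing

Discordant pairs below mapping quality 30 are discarded. Pairs are
canonicalized (mates ordered by chromosome and start) and clustered by
single linkage: two pairs link when both corresponding mate spans lie
within `insert_mean + 3·insert_sd` of each other. Clusters of fewer than
two pairs are dropped.

Typing from cluster geometry: mates on different chromosomes → **CTX**;
same chromosome with same-orientation mates (+/+ or −/−) in the majority →
**INV**; same chromosome, opposite orientations, but median outer span
beyond `insert_mean + 3·insert_sd` or reversed mate order → **ITX**;
concordant-looking clusters are dropped with a reason. The ITX geometry is
the standard discordant-pair reading; the CTX/ITX naming itself carries no
geometry, so the convention is documented here.

Confidence is the capped-linear score `min(99, 20 · n_supporting)` — it
reaches the 0–99 scale's cap at five coherent pairs, and the downstream
filter keeps only saturated calls (`score >= 99`, implemented as `>=` so it
is robust to a different score formula). Filtering happens before control
exclusion; both operations commute because neither changes the other's
inputs. Calls whose breakpoints fall within 1 kb of any control-supported
cluster are removed.

Breakpoints are refined from the supporting mates' inner edges: a `+` mate
reads toward the breakpoint so its inner edge is its end; a `−` mate reads
away so its inner edge is its start; each side uses its majority strand and
the innermost such edge (converted to 1-based). Keying the rule on strand
rather than on a left/right label makes it invariant to the canonical mate
ordering of the pair table. When supporting reads cannot be resolved, the
call keeps its raw cluster coordinates and is flagged unrefined. Same-
chromosome sizes are `pos_b − pos_a`; CTX size is the extent of the
supporting mate spans on both chromosomes. In the type-by-chromosome
summary a CTX is tallied on its first (canonical) chromosome.

## The synthetic panel

The simulator emits post-alignment evidence directly — no reads, no
aligner — for a panel whose defaults are: 5 genotypes, 2 pseudomolecules ×
1 Mb, 20 genes of 1.2–2.4 kb on both strands, SNPs at 1e-3 and Indels at
1e-4 per base (≈2,000 SNPs + 200 Indels per genotype), 30 % heterozygous
calls, 25 line-specific variants, 3 gene deletions + 3 duplications and 3
structural variants per type per genotype, ~10× coverage with noise SD 1,
100-bp reads and a 400 ± 40 bp insert model. Coverage and insert values
mirror a typical short-read resequencing design for such panels; the rates
give a panel dense enough that every statistic is exercised yet small
enough to regenerate in seconds.

Modelling choices that matter when interpreting test results:

* **Background variants are shared by >= 2 genotypes.** A uniquely drawn
  background variant *is* line-specific under the analytical definition, so
  leaving uniqueness to chance would make the planted line-specific flag
  disagree with the definition it is meant to test. Sharing background
  sites (carrier count uniform on 2..n) makes flag and definition coincide
  exactly; the flag is nevertheless recomputed post-hoc from the final
  assignments rather than trusted from the planting stage.
* **Planted positions of one genotype keep >= 64 bp spacing** (longest REF
  span + flank + 1), so every truth variant survives the flank filter.
  Separate filter-failing noise is planted on purpose: low-quality/low-depth
  records and close pairs 3 bp apart, none of which appear in the truth set.
* **Forced effect categories** are planted by construction (e.g. a TGG→TGA
  change recorded as stop-gained), one dedicated gene per
  initiator/terminator-targeting category and codon-spaced sites for the
  rest; each construction is verified against the genetic code at
  generation time.
* **Depth noise is piecewise-constant over 100-bp tiles**, truncated normal
  at zero. Real coverage is locally autocorrelated, and run-length-encoded
  bedGraph output stays compact. Deleted genes keep a ~3 % residual covered
  stretch (a mapping-noise analog) so the <10 % absence rule is exercised
  away from the trivial zero; duplicated genes double their depth.
* **No variants are planted inside any genotype's deleted genes**: under
  the depth-based absence policy a site in another genotype's deleted gene
  is `missing` there, which would disqualify line-specificity for reasons
  the truth set cannot express. Real panels do have such sites; the
  pipeline handles them (they are simply not line-specific), the simulator
  just does not score them.
* **SV events live in disjoint territories** sized so that clusters of
  different events can never merge; supporting mates jitter within one
  insert SD of the true breakpoints, which bounds refined-breakpoint error
  by one SD *by construction*. Concordant and low-mapping-quality noise
  pairs are added; both are rejected by the mapq filter, the support
  minimum, or the concordant-geometry drop.
* **Indel lengths are uniform on 1..`indel_length_max`** (default 58) —
  chosen to exercise the full classification range, not to mimic the
  strongly 1-bp-skewed spectra of real panels.

Hence passing tests demonstrate the *correctness of the rules* under a
controlled evidence model — exact planted-truth recovery, calibration of
rates, oracle equivalence — not the sensitivity/specificity the same rules
would achieve on real alignments, where mapping artefacts, indel
realignment and copy-number mosaics violate the generator's assumptions.

## Numerical and degenerate-input conventions

Determinism: one integer seed drives four independent generator streams
(reference, variants, depth, pairs); identical seed and configuration give
byte-identical output files. Heterozygosity and Indel ratios with empty
denominators report 0 and absent (None) respectively. Zygosity boundary
cases: `missing` genotypes never count as carriers or as reference.
Chromosomes are tiled by windows even when shorter than one window. Gene
packing, variant spacing and SV territory allocation fail loudly
(`SimulationError`) when a configuration cannot be realized, rather than
degrading the guarantees silently.

## Problem sizes

The default test and acceptance configurations (2 Mb genome, 5 genotypes,
~11,000 planted calls; a 2.2 Mb single-genotype calibration panel with
~11,000 calls; 500 oracle-checked coding variants) were chosen so the whole
validation cycle regenerates from scratch in well under a minute while
keeping every binomial/Poisson calibration check adequately powered.
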