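# Methods

## The discovery model

The pipeline assumes a fully penetrant autosomal-recessive disease in a
small sequenced cohort drawn from a single breed, with a larger
multi-breed reference panel of presumed-healthy genomes available on an
older genome assembly. Under those assumptions a causal variant must be

* homozygous-alternate in every affected animal and absent in homozygous
  form from controls (segregation filter),
* protein-altering (impact filter, MODERATE or above),
* rare in the wider population and never homozygous in healthy animals
  of unrelated breeds (population filter).

The array-based analyses are independent corroboration: a recessive
locus inherited from a common ancestor produces both a case/control
association peak and a run of homozygosity (ROH) shared by the cases.

## Segregation filter

Zygosity at each biallelic site is one of hom_ref / het / hom_alt /
missing; multiallelic VCF records are split per ALT, with genotypes that
reference a different ALT treated as missing for the split record (the
decomposition used by common normalization tools; it keeps the zygosity
vocabulary closed). The default pattern requires hom_alt in all
affecteds and allows {hom_ref, het} in controls; uncertain-status
samples never constrain.

Missing genotypes: a missing call in an affected sample *fails* the
variant (the required hom-alt state cannot be confirmed), a missing call
in a control leaves the variant in play (a violation cannot be
demonstrated). This is conservative for cases and permissive for
controls; the alternative (permissive for cases) would admit variants
whose segregation is simply unobserved.

The filter is monotone: adding samples can only shrink the surviving
set, which the test suite checks directly against a per-variant loop
oracle.

## Consequence annotation

One transcript per gene; coordinates are mapped between genome and
spliced CDS through the exon structure (strand-aware). The impact table
is fixed and total: frameshift, stop gained/lost, splice site → HIGH;
missense, in-frame indel → MODERATE; synonymous → LOW; intronic, UTR,
intergenic → MODIFIER. The splice-site window is the first/last 2 bp of
each intron (the donor/acceptor dinucleotides).

HGVS conventions: deletions are shifted to their most-3′ position in the
coding sequence before rendering `c.` notation (VCF left-aligns, HGVS
right-aligns); ranges use underscores (`c.4138_4139del`), though
hyphenated input is accepted where strings are parsed. For a frameshift,
both the wildtype and mutant CDS are translated in full and compared
residue by residue; with the first differing residue at codon *d* and
the premature stop at new-frame position *N* (counting codon *d* as 1):

    hgvs_p               = p.(RefAA d AltAA fs*N)
    novel_aa_count       = N − 1
    replaced_cterm_count = wildtype_length − d + 1
    percent_shorter      = replaced_cterm_count / wildtype_length

When the first frameshifted codon happens to encode the wildtype
residue, the scan advances (the HGVS rule); when the first change is
itself a stop, nonsense notation `p.(Xaa d *)` is used; a mutant CDS
with no downstream stop is reported `fs*?`. For the default generator
transcript the planted deletion gives d = 1380, N = 17, 16 novel
residues and 287 replaced C-terminal residues of the 1666-residue
protein — a 17.2% truncation by the replaced-fraction definition.
(`percent_shorter` is defined as the replaced fraction, not the
mutant/wildtype length ratio, which would give 16.2%; the two differ by
the novel tail.)

## Population filter and liftover

The liftover map is a list of non-overlapping blockwise affine
transforms; a plus-strand block maps `pos → tgt_start + (pos −
src_start)`, a minus-strand block reflects, `pos → tgt_start + (src_end
− pos)`. Alleles are not re-complemented for minus-strand blocks — no
candidate in the synthetic study crosses one, and a production liftover
of indels across strand flips would need re-normalization (a known
limitation).

Panel allele frequency uses non-missing calls only: AF = (n_het +
2·n_hom_alt) / (2·n_called). Two separately toggleable exclusion rules:

* `af_above_threshold`: AF strictly greater than `max_af` (default 0.05);
* `healthy_homozygotes_in_diverse_breeds`: more than
  `max_healthy_hom_alt` (default 0) homozygous-alternate panel animals
  carried by at least `min_breeds_for_diversity_exclusion` (default 2)
  breeds.

Candidates that fall outside every liftover block are retained but
flagged rather than dropped: an unmappable candidate is unassessable,
not exonerated. Retained candidates are ranked deterministically —
impact descending, panel AF ascending, then chromosome and position.
In the reported cascade, `post_population` counts the candidates
surviving the frequency rule; the diversity rule then selects the final
list (so "2 survive population filtering, 1 remains" is visible in one
report).

## Association and ROH

The association test is the two-sided Fisher exact test on the 2×2
allele table (case alt/ref vs control alt/ref), computed from the exact
hypergeometric distribution with integer binomial coefficients. At ten
cases a logistic fit adds nothing to locus ranking, while the exact test
is deterministic and oracle-checkable; the suite verifies it against
exhaustive enumeration for **every** table with total ≤ 60 and against
an independent library implementation on random tables. Fixed
−log₁₀(p) flags at 5 (suggestive) and 8 (genome-wide); no further
multiple-testing correction. SNPs with call rate < 0.9 are dropped, not
imputed.

ROH detection is the consecutive-runs method: a segment is a maximal
window starting and ending on homozygous calls with at most `max_het`
heterozygotes (default 1), no gap between called SNPs above `max_gap_bp`
(default 1 Mb), at least `min_snps` called SNPs (default 30) and at
least `min_length_bp` (default 1 Mb). Missing calls are ignored — they
neither break nor extend a run and do not count toward `min_snps`;
breaking on missingness would shatter real autozygous segments at
realistic no-call rates. Overlapping maximal windows (distinct
heterozygote subsets) are all reported; downstream interval union makes
this harmless. The shared region is computed by sweep-line over per-case
merged segments, keeping intervals covered by at least
⌈fraction × n_cases⌉ cases (default fraction 0.9, i.e. 9 of 10).

## Reporting

Diagnostic genotype classes map one-to-one from zygosity (hom_alt →
affected_genotype, het → carrier, hom_ref → wildtype, missing →
no_call). Concordance against histology review counts a "likely" label
as concordant when the genotype class is affected_genotype and an
"unlikely" label when it is not; "equivocal" (insufficient tissue) and
unreviewed samples are excluded from the denominator.

Pooled allele frequency over carrier-screen groups is Σ(n_het +
2·n_hom_alt) / Σ(2·n), with a Wilson score interval on the pooled allele
counts (via statsmodels). The worked example 2/256 + 1/236 alleles gives
3/492 ≈ 0.61%, reported as 0.6%. Wilson was chosen over the exact
(Clopper–Pearson) inversion because it is non-degenerate at zero counts
and close to exact at the allele-count denominators used here (the suite
quantifies the agreement at 2n ≥ 100; at very small n the exact interval
is wider by construction).

The pipeline report records the stage counts (input → post_segregation →
post_impact → post_liftover → post_population), per-chromosome shares of
the segregating set, the ranked candidates with their annotations and
panel summaries, all thresholds, and a provenance hash over input file
contents plus configuration — the hash changes iff any input byte or
threshold changes.

## Synthetic study generator

The generator emulates the *structure* of the study, not its genome
scale. Defaults, chosen once:

| parameter | default | rationale |
|---|---|---|
| cohort | 5 affected / 2 control / 1 uncertain | study cohort shape |
| panel | 935 samples, 70 breeds, 128 Merino | reference-panel shape |
| array cohort | 10 cases / 98 controls, 5000 SNPs | array-study shape |
| genome | chr1 6 Mb, chr2 12 Mb, chr3 6 Mb | desk-scale; large enough for Mb-scale ROH |
| gene | 26 exons on chr2, 1666-residue protein, deletion in exon 26 | worked-example arithmetic |
| background variants | 2000 cohort / 200 panel, AF ~ U(0.05, 0.5) and U(0.005, 0.4), Hardy–Weinberg | neutral noise; a handful of chance segregants |
| autozygous block | 4.5 Mb at the distal end of chr2 | matches the mapped interval's physical scale |
| array missingness | 1% | typical array no-call rate |

The coding sequence is constructed backwards from the required protein:
codon 1380 is leucine CTG; the −2 frameshifted read-through from that
codon encodes glycine, then 15 further sense codons, then a stop. This
guarantees `p.(Leu1380Glyfs*17)` exactly, makes the first changed codon
1380 (Gly ≠ Leu), and keeps the VCF record left-aligned (the codon
before the deletion is constrained not to end in T). Two further
variants are planted in the same gene: a decoy missense with exactly 10
homozygous-alternate panel animals spread over 4 non-Merino breeds
(panel AF ≈ 1.1%, below the frequency threshold — only the diversity
rule removes it), and a common missense mirroring an Asn→Ser
polymorphism at CDS 215, at panel AF ≈ 30% (removed by the frequency
rule). Both segregate in the cohort, so the cascade's population stage
does real discriminating work. The panel carries exactly two
heterozygous Merino animals for the causal deletion and no homozygotes.

The panel VCF lives on a second coordinate system ("chrN_alt") reached
only through the generated liftover map (three blocks per chromosome
with gaps, one minus-strand block on a chromosome that carries no
candidates), so coordinate remapping is exercised genuinely.

Array genotypes are Hardy–Weinberg draws (per-SNP allele frequency
U(0.1, 0.45)); 9 of the 10 cases are set homozygous for one shared
haplotype across the block, the tenth is left random — reproducing the
"9 of 10 share one ROH" outcome and leaving the association peak inside
the block.

All randomness flows through one seed via spawned child generators;
regenerating with the same configuration is byte-identical, and every
truth constraint (carrier counts, decoy counts, block recovery) holds
for every seed, not just on average.

**What the generator does not model** — and hence what passing tests do
not show about real data: read-level error and coverage variation
(genotypes are planted, not called), linkage disequilibrium beyond the
single planted block, pedigree structure, breed-specific allele
frequencies (background panel AFs are breed-independent), allele
re-complementation across minus-strand liftover blocks, and carrier
haplotype phase around the causal variant.

## Numerical and degenerate-input choices

* Fisher p-values: exact integer binomial coefficients; ties in the
  two-sided sum use the conventional (1 + 1e−7) relative tolerance, so
  results agree with standard implementations to ≤ 1e−9 relative.
* Zero-count groups, all-zero tables, empty variant lists, cohorts with
  no affected samples, sheets with unknown roles, overlapping liftover
  blocks, CDS lengths not divisible by 3, and missing stop codons all
  raise immediately with a specific message rather than propagating NaN.
* Stage counts are monotone by construction; the liftover stage retains
  flagged unmapped candidates, so its count equals the impact stage
  (the number actually repositioned is reported separately).
* Problem sizes in the test suite (2000 background variants, 5000 array
  SNPs, 20 generator seeds, exhaustive Fisher enumeration to table total
  60, ROH oracle vectors to 200 SNPs) were chosen to exercise every code
  path at desk scale while keeping the full suite under a couple of
  minutes.

## Known limitations

* One transcript per gene; no canonical-transcript selection, no
  multi-transcript reporting.
* Insertions are classified (frameshift/in-frame) but truncation
  statistics are implemented for deletions only.
* The association test has no covariates or relatedness correction.
* ROH parameters are not self-calibrating; defaults target array
  densities of roughly one SNP per few kb.
* The liftover map format is a simplified block TSV, not a UCSC chain
  file.
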