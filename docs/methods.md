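# Methods

## Problem setting

Human mtDNA haplotypes are reported as differences from the revised
Cambridge Reference Sequence (rCRS; 16,569 bp, circular, 1-based
coordinates). When mitogenomes are extracted from whole-genome sequencing
data, reads originating from nuclear mtDNA segments (NUMTs) co-align to
the mitochondrial reference; because any single NUMT is present at two
copies per cell against hundreds to thousands of mtDNA copies, NUMT
alleles appear as low-frequency variants. The analysis strategy
implemented here treats a *variant frequency threshold* as the primary
NUMT defence: only alleles at ≥ 10% of reads are eligible for the
haplotype, and the depth requirement (100X, 20X fallback) bounds the
binomial noise on that frequency estimate.

## Calling model

Per position, allele frequencies are computed over read depth.

- Exactly one base ≥ `min_vf` (default 0.10): that base is called; it
  enters the haplotype as a substitution if it differs from the reference.
- Exactly two bases ≥ `min_vf`: a point heteroplasmy (PHP); the two-base
  IUPAC symbol is reported and the minor fraction recorded. Only
  two-state PHPs are representable; three or more bases above threshold
  are treated as mixture evidence and only the major base is called.
- Deletions and each distinct inserted sequence are called at the same
  threshold. If the deletion fraction exceeds the major base fraction the
  position is deletion-major and no base-level call applies.
- Zero depth marks a position uncovered.

Reporting rules layered on top:

- **Suppressed PHP positions** (302, 16,182, 16,183): post-homopolymer
  sequencing error makes apparent heteroplasmy at these positions nearly
  universal, so the major nucleotide is always reported.
- **Homopolymer regions** (HVS1/HVS2/HVS3 C-stretches, the AC repeat at
  513–524, and the smaller C-stretches preceding 356, 460, 498, 960,
  5,899, 7,471, 8,276): insertion/deletion evidence is tallied as *length
  molecules* (the no-insertion reads are the reference-length molecule).
  When two or more molecules each reach `min_vf`, the region is flagged
  as length-heteroplasmic (LHP) and only the major length molecule is
  reported — minor molecules never enter the haplotype.
- **NUMT hotspots** (nps 12,501–13,105 and np 16,496): a minor allele
  above `min_vf` at a hotspot position is recorded as a NUMT flag
  (position, allele, frequency) and, under the default policy, excluded
  from the haplotype (the major base is reported). This automatic
  default is deliberately conservative: resolving whether such a call is
  a genuine PHP or NUMT interference requires evidence the caller does
  not model (read phase, mtDNA copy number), and a flagged-and-excluded
  call is recoverable from the QC output. Sub-threshold NUMT signal —
  any hotspot minor allele between the noise floor (2%) and the
  threshold — is reported as a boolean per sample.

QC metrics per sample: number of positions below the active depth
threshold; coverage class (complete = 0, nearly complete = 1–4,
incomplete = ≥ 5 positions below threshold); average major-nucleotide
frequency across variant positions (average VF), both over all variant
positions and excluding PHP positions and homopolymer regions (single
-source, high-quality samples are expected to exceed 98% on the latter);
and a mixture flag (more than three PHP-like positions, or average VF
excluding heteroplasmy below 98%).

## Matching and statistics

Comparisons operate on range-restricted substitution profiles; indels are
ignored by default (the forensic convention), and `N` calls are missing
data — the position is skipped in both profiles. Literal matching
requires identical symbols; pattern matching requires intersecting IUPAC
expansions. Literal matching is an equivalence relation and clusters by
exact key (N calls dropped from the key, the one point where transitivity
would otherwise fail); pattern matching is not transitive, so clusters
are formed by a deterministic greedy pass in input order — each haplotype
joins the first cluster whose founding member it matches. This greedy
rule is a documented design choice, not a claim about how any particular
published pattern-mode count was produced.

From the frequency spectrum {n_i}: observed RMP = Σ(n_i/n)² (two draws
with replacement — includes the 1/n self-match floor); empirical RMP =
Σ n_i(n_i−1)/(n(n−1)) (matching fraction among distinct pairs); haplotype
diversity = (n/(n−1))(1 − Σ(n_i/n)²). These definitions are validated in
the tests by exact agreement with brute-force all-pairs enumeration.
Percentages are rounded half-even at reporting precision (two decimals
for RMP percentages, four for diversity).

Maternal-relative de-duplication groups samples that share a haplotype
ignoring indels *and* heteroplasmy (ambiguous IUPAC calls excluded), then
keeps the lexicographically lowest sample id per cluster of flagged
first/second-degree relatives.

Haplogroup distributions are compared with the chi-squared test of
homogeneity using Yates's continuity correction applied per cell,
Σ(max(|O−E|−0.5, 0))²/E, with (r−1)(c−1) degrees of freedom. The
clipping at zero makes identical distributions score exactly 0.

## Haplogroup assignment

A haplogroup tree is a rooted hierarchy whose nodes carry defining
substitutions; expected variant sets accumulate along the root-to-node
path, with back-mutation tokens (`263A!`) *removing* the position from
the expected set (reversion to the reference state). This convention
lets the reference-identical haplotype accumulate an empty expected set
at its own deep node (H2a2a1) and therefore be assigned correctly.
Score = matches − 0.5 × missing; private variants are unpenalized (a
deliberately simple rule — fluctuation-rate weighting and full
EMPOP-style scoring are out of scope). Ties break to the shallower node,
then lexicographically, and are reported. The packaged 25-node mini-tree
is a synthetic fixture: its topology follows standard human mtDNA
nomenclature and its defining variants are consistent with the example
haplotypes used in the tests, but it is not a published tree build.

## Synthetic data

The generator is a labelled-clade model: each clade gets a distinct
random substitution profile (Poisson number of variants, mean 25.5 per
lineage; transition:transversion odds 15:1; positions drawn outside
homopolymer windows and suppressed positions), and every member of a
clade carries the identical profile, so the realized frequency spectrum
equals the configured clade sizes exactly when heteroplasmy injection is
off. The packaged example spectrum (7/6/5/4×5/3×16/2×51/1×746, n = 934)
reproduces the sharing structure of a large published Swedish population
sample.

Pileups: per-sample mean depth log-uniform over 500–3000X; per-position
depth negative-binomial (size 100, ≈ 10% coefficient of variation);
homopolymer dropout windows at a 0.5 depth multiplier by default;
per-base miscall rate 0.005 (comfortably below the 2% background-noise
floor), errors spread evenly over the three non-template bases. PHPs are
two-allele mixtures at a uniform 10–50% minor fraction, carried by 21.9%
of samples (1, 2 or 3 PHPs with probabilities 0.863/0.122/0.015). LHP is
modelled as a three-molecule mixture at the region's reporting anchor
(major inserted molecule 55–70%, reference length 18–28%, a longer minor
molecule taking the remainder) with per-region prevalences patterned on
the HVS2 > HVS1 > HVS3 > AC-repeat ordering seen in real data. NUMT
contamination adds Poisson-distributed reads of block-specific alleles so
their expected frequency equals the contamination fraction f; blocks
default to the two hotspot intervals.

Because the real rCRS sequence is not shipped, the simulator runs on a
synthetic 16,569-bp reference with C-stretches placed at the canonical
homopolymer coordinates (`synthetic_reference()`, and the
`synthetic-mtref-adapted` fixture in the tests). Parsing and matching
never require reference bases, so published example haplotypes are
handled verbatim.

What the simulator does *not* model: read-level artefacts (mapping
quality, strand bias, post-homopolymer quality decay beyond the dropout
multiplier), in-phase NUMT variants on individual reads, genealogical
structure within clades, and position-specific mutation-rate
heterogeneity. Passing parameter-recovery tests therefore demonstrates
the correctness of the thresholding logic under the stated statistical
conditions, not robustness to every artefact of a particular sequencing
chemistry.

## Problem sizes and numerical choices

The parameter-recovery suite uses 200 simulated samples at depth
1000–3000X with 0.5% noise, PHP minor fractions ≥ 12% and 8% NUMT
contamination in every sample — conditions under which exact recovery of
every haplotype and PHP symbol is the designed behaviour. At 8%
contamination the binomial sampling tail occasionally pushes a NUMT
allele just over the 10% threshold in an individual sample; such calls
are flagged and excluded, so haplotypes stay clean, and the tests bound
the flag rate rather than asserting it is zero. The brute-force
cross-check of the spectrum statistics enumerates all pairs of a
934-sample population (~436k comparisons). Frequency comparisons use
exact rational arithmetic where possible and 1e-12 absolute tolerance
elsewhere; the chi-squared implementation is checked against an
independent statistics library at 1e-10 on 2×2 tables.

## Known limitations

- Insertion calls are anchored at single positions; multi-anchor
  interplay inside one homopolymer region (e.g. simultaneous `309.1C`
  and `315.1C` molecules) is reported one molecule per anchor, and the
  wildcard notation `309.xC` is accepted on input but never emitted.
- Pattern-mode cluster counts depend on input order (greedy merge); the
  order is deterministic and documented, but other merge rules give
  different totals on data with chained ambiguities.
- The mixture flag is a screening heuristic, not a deconvolution; mixed
  samples are flagged for exclusion, never resolved.
- Haplogroup assignment quality is bounded by the supplied tree; the
  packaged mini-tree exists for testing and demonstration, not for
  production lineage assignment.
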