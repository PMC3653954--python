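# Methods

## Model and statistic

The dTDT treats each parent–offspring trio as contributing expected
transmission pseudo-counts. Let *t* be the probability that a heterozygous
parent transmits allele 1 to its affected child. Given parental dosage
triples, the child's implied dosage under independent transmissions is

    p_c11 = (p_f11 + t·p_f12)(p_m11 + t·p_m12)
    p_c22 = (p_f22 + (1−t)·p_f12)(p_m22 + (1−t)·p_m12)
    p_c12 = 1 − p_c11 − p_c22.

Summing the eleven informative transmission configurations (those with at
least one heterozygous parent) gives per-trio totals b_i = (p_f12 + p_m12)·t
and c_i = (p_f12 + p_m12)·(1−t). Substituting the observed child dosage and
eliminating *t* yields the closed form actually computed,

    b_i = 2·p_c11 + p_c12 − p_f11 − p_m11,     c_i = (p_f12 + p_m12) − b_i,

which is algebraically identical to the t-substituted form (the denominator of
the *t* estimate cancels) and cheaper. The pooled chi-square
(Σb − Σc)²/(Σb + Σc) has one degree of freedom under the null; the per-marker
estimate t̂ = Σb/(Σb + Σc) is reported pooled, never per trio. No continuity
correction is applied anywhere; the asymptotic form is used as is.

Numerical policy:

- **Clamping.** A dosage set consistent with *some* t ∈ [0, 1] always yields
  b_i ∈ [0, s_i], s_i = p_f12 + p_m12. Inconsistent sets (possible when
  posteriors from different sources are mixed, or after row renormalization of
  noisy files) can push b_i outside that range; by default b_i is clamped back
  into [0, s_i] preserving b_i + c_i = s_i, the event is flagged on the
  increment and logged. Clamping can be disabled for diagnostics
  (`trio_increments(..., clamp=False)`). Negative pseudo-counts would break
  the chi-square contract, which is why clamping is the default.
- **Uninformative trios** (s_i = 0, both parents certainly homozygous)
  contribute nothing but are counted in `n_trios`, mirroring the classic
  TDT's treatment of doubly homozygous parents.
- **Degenerate pools.** Σb + Σc = 0 gives chi-square 0, p = 1, t̂ undefined.
- **Tiny p-values.** The survival function is floored at the smallest
  positive double so p stays in (0, 1]; −log10 p is computed on the log scale
  via the identity P(χ²₁ > x) = 2·Φ(−√x), which never underflows.

## Exact nuclear-family inference

Full multipoint pedigree inference (Lander–Green and relatives) is out of
scope; the package computes the exact *single-marker* posterior for a nuclear
family by enumerating the nine ordered parental genotype pairs with a
Hardy–Weinberg founder prior at allele frequency q1 and Mendelian transmission
to the children, conditioning on all observed members. Children are
conditionally independent given the parents, so evidence multiplies across
observed siblings; un-genotyped children receive the marginal over the joint
parental posterior. An observation set impossible under Mendelian inheritance
raises an error naming the family.

This is the appropriate desk-scale stand-in here because the simulation design
never introduces a recombination fraction between the microsatellite and the
SNP: at a fully informative microsatellite the linkage marker adds no
information about the SNP beyond the child's own genotype, and the posterior
factorizes into exactly the computation above. Externally produced dosage
files (e.g. from a multipoint inference program) are interchangeable with the
inferred ones through the same dosage-table format.

The founder prior's q1 defaults to the estimate from all observed genotypes
at the marker, clipped to [1e-6, 1 − 1e-6] to avoid zero-mass priors; a
user-supplied frequency overrides it. **The choice matters**: in an
affected-children-only design the children are enriched for the risk allele,
so estimating q1 from them absorbs the transmission distortion and destroys
power — the test inherits the known sensitivity of dosage-based TDTs to
external allele-frequency estimates (and hence to population stratification).
The per-individual confidence filter drops a dosage row when its largest
genotype probability falls below τ; τ = 0.8 by default, with 0.7–0.8 being a
sensible band — lower admits too much inference noise, higher sheds too much
sample.

## Trio simulator

The generator encodes the study conditions used throughout the tests:

- Disease locus D with low/high-risk alleles at frequencies p1, p2 under HWE;
  penetrances (f11, f12, f22) patterned as dominant (f, g, g), recessive
  (f, f, g) or codominant (f, g/2, g).
- p1 is the root in (0, 1) of the prevalence identity
  f11·p1² + 2·f12·p1·p2 + f22·p2² = K, i.e. of
  (f11 − 2f12 + f22)p1² + 2(f12 − f22)p1 + (f22 − K) = 0. Settings with no
  admissible root are marked invalid and excluded from grid runs. If two
  distinct roots ever lie in (0, 1) (never the case on the standard grid,
  verified by enumeration) the larger p1 is taken, making the
  higher-penetrance allele 2 the rarer risk allele, and the choice is logged.
  Flat penetrances equal to K are non-identifiable and rejected.
- SNP S is tied to D via haplotype frequencies
  h11 = p1q1 + R·√(p1p2q1q2) (etc., alternating signs) with q = p, which lets
  the LD correlation R span its full range; negative R is excluded by
  contract since with p = q it mirrors positive R.
- The affected child's SNP genotype distribution is computed by exact
  enumeration of the 16 ordered haplotype pairs, each weighted by its
  frequency product and the penetrance of the implied D genotype, accumulated
  by the implied S genotype. The unnormalized mass sums to K — an identity
  the tests check across the whole grid — and genotypes are drawn by roulette
  wheel (inverse CDF) sampling.
- Each trio carries a fully informative microsatellite: father 1/2,
  mother 3/4, the child receiving one allele from each parent uniformly,
  independent of the SNP (no recombination fraction is modeled; the
  microsatellite's role is to mark parents as linkage-genotyped for trio
  extraction). All children are affected; parental phenotypes are unknown.
- Default set size is 1,000 trios per setting. The evaluation grid is
  K ∈ {0.01, 0.1, 0.2} × R ∈ {0.5, 0.7, 0.9, 1.0} × f ∈ {0, 0.1K, …, 0.9K} ×
  g ∈ {1.1K, 0.5, 0.7, 0.9, 1.0} per model — 120 raw settings per
  (model, K) group, all of which happen to admit a valid p1 under the
  any-root policy.
- RNG: numpy PCG64 throughout, seed recorded in output metadata; stratified
  (two-population) simulations derive sub-streams by `SeedSequence.spawn`,
  labels retained per trio.

What the generator does *not* emulate: genotyping error, missing data
patterns, multipoint linkage information, ascertainment beyond one affected
child per trio, multi-generation pedigrees, and real LD structure beyond a
single D–S pair. Passing tests therefore demonstrate the statistic's
correctness and calibration under the stated model, not robustness to the
error sources of real combined linkage/GWAS data (whose dominant failure
modes — inference error and allele-frequency misspecification — are discussed
above).

## Case-control stratum and Mantel–Haenszel pooling

The case-control allele test uses the 2×2 allele-count table with O = allele-1
count in cases, E = row·column/N, and the exact hypergeometric variance
r1r2c1c2/(N²(N−1)) — the Mantel–Haenszel variance, equal to the Pearson
chi-square times (N−1)/N (an identity the tests exploit as an independent
cross-check). The dTDT stratum is the 1×2 table O = Σb, E = (Σb+Σc)/2,
Var = (Σb+Σc)/4, reproducing the dTDT chi-square exactly. Pooling sums O−E
and Var across strata. Markers with a zero margin are skipped with a logged
reason, never patched with pseudo-counts. QQ coordinates use the (i − ½)/n
plotting position (the convention is not standardized; this one is symmetric
and avoids infinities at both ends).

## Genetic map

SNPs between two microsatellite anchors are placed by linear interpolation of
the anchors' genetic interval in proportion to physical distance; beyond the
terminal anchors the 1 cM ≈ 1 Mb convention extrapolates. Anchors at equal
genetic positions define a zero-length genetic interval and all SNPs between
them map to the shared value. Cleaning applies, in fixed order for
reproducible reports: missing physical position → MAF ≤ 0.05 (boundary
inclusive) → within 1,000 bp (inclusive) of a *retained* microsatellite on
the same chromosome. Cleaning is idempotent.

## File formats and design choices that were genuinely open

- Ped dialect: whitespace-delimited, 5 or 6 leading columns (the count is
  inferred from row length against the companion dat/map marker count),
  allele code 0 = missing, LINKAGE affection coding (0/−9 unknown,
  1 unaffected, 2 affected; configurable).
- Dosage tables: long TSV (individual, marker, p11, p12, p22). A row is
  renormalized when its sum is within 0.01 of 1 (tolerant of 2-decimal
  rounding, e.g. 0.33/0.33/0.33) and rejected beyond that, with a report.
  A wide per-individual layout (`<marker>:p11` … columns) is accepted via an
  adapter.
- Trio extraction: one trio per affected child whose father and mother are
  both present in the family, requiring at least one parent genotyped on the
  linkage (microsatellite) panel; several affected siblings yield several
  trios sharing parents. Children whose parent records are absent
  (unrecorded marry-ins) are skipped, not imputed.
- CLI: subcommands simulate / infer / dtdt / cc / mh / map; exit 0 on
  success, 2 on usage errors, 3 on data errors; every output carries a
  `.meta.json` sidecar (config echo, seed, RNG algorithm). Bonferroni
  correction is opt-in (`mh --alpha`), never silent.

## Problem sizes used in the checks

The shipped verification suite uses: 200 random hard-genotype trio sets for
the classic-TDT reduction; 1,000 forward-construction draws for t-recovery;
1,000 replicates of 500 complete trios for null calibration (the exact
asymptotic rejection rate at this size is 0.0499); 100 random families of up
to four children against the brute-force 3^(2+k) enumeration oracle; and 200
replicates of 1,000 trios per setting for the power study (recessive K = 0.01,
f = 0, g = 0.5 across R, against dominant K = 0.2 at matched penetrances).

## Known limitations

- Single-marker inference only; no multipoint haplotyping, no recombination
  modeling, no imputation-quality scoring.
- The dTDT with population-prior-inferred parents is *not* robust to
  population stratification (unlike the hard-genotype TDT), and pooling it
  with a case-control stratum compounds that sensitivity; stratified
  simulation (`simulate_stratified_set`) exists precisely to study this.
- Biallelic SNPs only; multi-allelic tests, sib-TDT/PDT/FBAT-style
  generalizations, VCF/PLINK-binary formats and map-function conversions
  (Haldane/Kosambi) are out of scope.
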