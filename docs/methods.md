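# Methods

## Study design the package models

Several clonally related tumor subclones (default four: Pa, Pb from a
primary tumor, Ra, Rb from a recurrence) are each profiled as a pure clone —
no subclonal mixture within a sample — against one matched normal (TIL,
tumor-infiltrating lymphocytes) on three molecular layers: somatic SNVs,
allele-specific copy number, and CpG methylation, plus replicate expression
counts. The analysis asks three questions: what is the subclones' genetic
phylogeny; how divergent are their transcriptomes and methylomes (and does
that divergence follow the phylogeny); and which sample-specific expression
changes are explained by copy-number dosage versus gene-body methylation.

## Variant filtering and phylogeny

Presence of an SNV in a tumor sample requires VAF > `min_vaf` (0.10),
variant reads > `min_reads` (5), and at least one variant read on each strand
("double-strand support"; a `per_strand_min` switch raises the per-strand
requirement). A variant is somatic when the matched normal has zero variant
reads. VAF is variant reads divided by total depth at the site.

LOH masking removes variants lying in any sample's segment with zero
B-allele copies before tree building. The union-over-samples rule is a
deliberate choice: a character erased by allele loss in one taxon corrupts
the presence/absence coding for the whole matrix, not just that taxon
(`any_sample=False` gives per-sample masking instead).

Tree search is exact: all rooted binary topologies over the ingroup are
enumerated (the outgroup, an all-absent taxon, attaches at the root) and each
is scored by the Fitch pass, which on binary characters equals Wagner
parsimony. Identical character patterns are collapsed and weighted, so the
cost is (2n−3)!! topologies × unique patterns; the hard cap of 12 ingroup
taxa marks where exhaustive search stops being sensible (the intended scale
is ~4–6). Branch changes come from one most-parsimonious assignment with
ties resolved toward the ancestral absent state; among equally parsimonious
topologies all canonical Newick strings are reported and the
lexicographically smallest is primary — we do not reproduce the input-order
dependence of heuristic implementations.

## Expression

Upper-quartile normalization scales each library so that its 75th percentile
over genes with nonzero count equals the mean of the raw per-library upper
quartiles. Normalizing twice yields unit factors.

The differential-expression score is a deliberate stand-in for an
empirical-Bayes posterior, designed to preserve the published decision
surface (evidence gate at 0.99 plus fold-change gate at 1.5) with only two
replicates per sample: a single negative-binomial dispersion φ is estimated
by the method of moments, pooled across genes with mean > 5 (median of
(s² − m)/m², floored at 10⁻³); the variance of a log₂ sample mean is
(1/μ + φ)/(n·ln²2); the two-sided normal p on the difference of log₂ means
is BH-adjusted across genes, and the score is 1 − q. The score is *not* a
posterior probability; under a complete null the DEG fraction stays below 1%
(tested). Fold change is the ratio of normalized means with a +0.5 offset
guarding zero means; log₂(x+1) is used wherever counts are log-transformed.

Sample-specific DEGs are the intersection of the three pairwise DEG lists
against the focal sample, with direction required to agree (discordant genes
are flagged and dropped). Sample dendrograms use complete linkage on
Euclidean distance over log₂(normalized mean + 1) of expressed genes
(mean normalized count > 1 in ≥ 1 sample); Spearman correlation quantifies
pairwise transcriptome similarity.

## Methylation

Coverage files are position-level; opposite-strand cytosines of one CpG
(consecutive positions) are pooled before filtering (`merge_strands=False`
disables this; the greedy pairing does not chain through CGCG runs). Only
sites with total reads strictly > `min_depth` (10) in **every** sample are
retained; all counts are preserved exactly.

DMS: per-site two-sided Fisher exact test on [methylated, unmethylated] ×
[sample a, sample b], BH-adjusted across all retained sites of the
comparison (one global family, not per chromosome), called at adjusted
p < 0.05. The Fisher test is evaluated in a vectorized form (full
hypergeometric pmf per table, summing probabilities ≤ observed × (1+10⁻⁷));
tests verify agreement with scipy and with direct enumeration to 10⁻⁹.

Region (promoter/gene body/category) methylation is the unweighted mean of
site levels; regions with fewer than `min_sites` (3) retained sites are
reported missing — a mean over one or two sites at 10–30× coverage is noise.
DMF calls (DMP = promoter, DMGB = gene body) require |ΔML| > 0.20 **and**
two-sided Fisher p < 0.05 (unadjusted) on counts pooled over the region's
sites; pooling is the only construction that yields a 2×2 table from a
region. Genome-wide comparisons use the paired Wilcoxon signed-rank test on
per-site levels (zero differences dropped; all-zero case reported as p = 1
with a degenerate flag). Methylome dendrograms cluster samples on per-site
levels of all common retained sites by default; a DMS-subset mode exists and
gives the same sample topology on data of this structure.

## Annotation geometry

Coordinates are 1-based inclusive internally; BED input is converted at the
reader. Promoters span 1,500 bp upstream to 500 bp downstream of the TSS,
strand-aware, 2,001 bp including the TSS base before clipping. Gene bodies
run TSS–TES. CGI shores are the 2-kb island flanks minus islands; shelves the
2-kb shore flanks minus shores and islands; precedence island > shore >
shelf makes the per-base labelling a partition, preventing double counting in
category means (which weight CpG sites equally, not regions). One
representative record per gene is assumed; multi-transcript inputs should be
reduced to the longest span upstream.

## Integration

Gene copy number is the copy number of the segment containing the TSS; genes
straddling a breakpoint are flagged and excluded from dosage analyses. For
the dosage test between two samples, genes are classed by the focal sample's
copy number **relative to the compared sample** (gain ⟺ CN_focal >
CN_other): that relative dosage, not dosage versus baseline ploidy, is what
the focal-minus-other expression change responds to. Gain (loss) genes'
log₂-mean changes are tested against copy-neutral genes' with the one-sided
KS alternative that they are stochastically larger (smaller); genes with
mean count < 1 in either sample are excluded.

A sample-specific CNA gene has a focal copy number differing from every
other sample while the others agree (a relaxed modal-reference mode exists).
Driven-gene classification intersects sample-specific CNA genes and
sample-specific DMGB genes with sample-specific DEGs and requires directional
consistency — gain→up/loss→down for CNA, hyper→up/hypo→down for gene-body
methylation (the coupling is positive, unlike promoter methylation). The
summary reports overlap counts, consistent counts with percentages to two
decimals, and the union identity
`n_union = n_cna_consistent + n_dmgb_consistent − n_both`.

The mutated-gene/DEG overlap uses an exact binomial test with
p₀ = |DEGs|/|universe| and n = |mutated genes|; both depletion and
enrichment tails are reported because a "no overlap" claim is a depletion
claim. Gene-set enrichment is the one-sided hypergeometric over-representation
test with BH across sets.

## Synthetic-data generative model

The generator is the package's test bed; its defaults *are* the study
conditions.

**Genome.** 3 chromosomes × 20 Mb; 3,000 non-overlapping genes (3–10 kb
spans, 6–14 kb gaps, 2–5 exons, random strand); 600 CpG islands at gene
promoters; 300 repeat intervals. 60,000 CpG sites: 35% in gene bodies, 25%
in promoter flanks, 40% in intergenic gaps.

**Clonal tree and SNVs.** Perfect phylogeny ((Pa,Pb),(Ra,Rb)) rooted by TIL;
branch SNV counts 300 (trunk), 50 per internal clade, 25 per leaf. Carrier
VAF is 1/CN at the site (one mutant copy on a triploid baseline → 1/3 in
copy-neutral regions); depth is Poisson(60); strand split is Binomial(½);
non-carriers and the normal draw zero variant reads. At these settings a
carrier passes the read filter in ≫ 99% of draws, so presence/absence coding
is near-perfect and topology recovery is an exact acceptance surface.

**CNA/LOH.** Two events per tree branch plus three extra events private to
the divergent sample (Ra), each snapped to a run of 15–30 whole genes (no
gene straddles a boundary by construction); gains of +1/+2/+3 copies with
probability 0.5/0.3/0.2, losses of −1/−2 with 0.6/0.4; half of the
two-copy-state losses and all single-copy states have zero B-allele copies
(LOH). SEG files tile whole chromosomes with the triploid baseline between
events.

**Methylome.** Region units are gene bodies, promoter upstream flanks, and
10-kb intergenic tiles. Target level = global sample level (Pa 0.46,
Ra 0.41, Rb 0.41 — three samples, mirroring a design where one primary
culture lacks bisulfite data) + a region baseline shared across samples
(SD 0.12) + sample-specific regional drift (SD 0.02; 0.06 for Ra, giving the
divergent sample a genome-wide distinct methylome), clipped to [0.02, 0.98].
150 planted DMGB genes and 100 planted DMP genes (disjoint; drawn from genes
whose region carries ≥ 3 simulated CpGs, since a methylation state is
undefined without CpGs) receive an extra Ra-specific offset of ±U(0.245,
0.455). When a hypomethylation planting hits the floor, the *realized*
(post-clipping) difference is recorded as the truth and used for the
expression coupling, keeping the planted effect internally consistent.
Per-site, per-sample levels are Beta(target·κ, (1−target)·κ) with κ = 30;
coverage is Poisson(25); methylated counts are Binomial(coverage, level).
Region-level targets are unimodal by design — the generator does not emulate
the bimodal (CGI-low / body-high) landscape of real methylomes, nor
incomplete bisulfite conversion, so passing tests certify the statistics,
not the realism of the level distribution.

**Expression.** Per-gene baseline means are lognormal weights normalized to
a 10⁶-read library; sample mean = baseline × (CN/3)^1 (dosage exponent
`dosage_coupling`) × 2^(5·ΔML_body) for the planted gene-body offsets
(`methylation_expression_coupling` = 5, so a planted |ΔML| of 0.35 moves
expression ~1.75 log₂ units) — promoter methylation and the regional drift
are deliberately decoupled from expression. 150 additional Ra-specific DEGs
with log₂ effects ±U(1.2, 2.1) model expression divergence beyond the two
measured mechanisms. Replicates (2 per sample) draw
NB(mean × lognormal(0, 0.08) library factor, dispersion 0.02) via
gamma–Poisson.

**Determinism.** All draws flow from `numpy.random.default_rng` seeded by
(seed, stream-id); identical config + seed reproduces byte-identical files.

## Problem sizes used in the checks

Statistical recovery checks run at the default scale above (one seed for the
coupling/classifier checks; 100 seeds at a down-scaled genome — 2 × 8 Mb,
800 genes, 8,000–20,000 CpGs, default SNV and coupling parameters — for the
topology-recovery and clustering-discordance sweeps, where only the planted
effects, not genome size, carry the signal). The null FDR check uses 200
seeds × 10,000 sites; the parsimony oracle 500 random matrices of ≤ 5 taxa ×
≤ 8 characters against brute-force enumeration of topologies and internal
state assignments.

## Known limitations

- Pure clones only: no tumor purity/contamination model, no subclonal
  mixtures within a sample; the cultures are treated as single clones.
- The DEG score is a calibrated frequentist stand-in, not an empirical-Bayes
  posterior; with two replicates its dispersion estimate is pooled, so
  gene-specific variance inflation is not captured.
- Exhaustive tree search only; no heuristic search, bootstrap, multi-state
  characters, or back-mutation model.
- The mutated-gene/DEG binomial test treats genes as exchangeable; gene
  length is ignored in the mutation-to-gene mapping.
- Strand merging pairs adjacent coverage rows greedily and will not resolve
  pathological CGCG runs; real Bismark output per CpG strand satisfies it.
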