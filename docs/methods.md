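# Methods

## Study design and model

The analysis targets a three-line mouse design — an obese inbred line
(BFMI), a lean control (B6) and their lean F1 offspring — crossed with
two sexes and two diets (standard maintenance vs high fat), 4–5
animals per cell (default 5). Obesity in this model is recessive: the
F1 animals are lean, so the analysis pools B6 and F1 into one lean
class against BFMI, ignoring sex and diet once the factorial ANOVA has
shown them to be negligible for the metabolome.

Concentrations are treated as lognormal: the per-metabolite model is

    ln c_ij = mu_j + beta_j * 1[line_i = BFMI] + e_ij,   e_ij ~ N(0, sigma^2)

with beta_j = 0 for unaffected metabolites. All statistics run on the
log scale; raw-scale means and SDs are reported alongside for
interpretation.

## Stage-by-stage choices

**CV quality control.** CV = sample SD (n−1 denominator, small
reference sets) divided by the mean, computed on *untransformed*
concentrations — the coefficient of variation is defined pre-transform
and the log applies only to retained metabolites. Metabolites with
CV strictly above 0.2 are excluded; CV exactly 0.2 is retained.
Missing values are excluded pairwise.

**ANOVA.** Main effects only (line + sex + diet), no interactions,
sequential (type I) sums of squares in that order; with a balanced
design the order is immaterial. The per-factor F test uses the
full-model residual. A factor with zero between-level SS gets p = 1 by
convention. The implementation solves the nested least-squares
problems once for the shared design and applies them to all metabolite
columns simultaneously, which keeps thousand-metabolite calibration
runs below a second; tests verify equality with statsmodels
`anova_lm(typ=1)` and with an explicit normal-equations oracle to
1e-8.

**Two-group comparison.** Pooled-variance two-group ANOVA (equivalent
to the classical two-sided t) on log concentrations, not Welch —
matching the stated analysis. Significance is strict p < 0.05 with no
multiplicity correction across metabolites; Bonferroni
(p_adj = min(1, m·p)) applies only to pairwise phenotype contrasts.
Printed fold ratios are rounded half-away-from-zero to one decimal.

**Random-forest importance.** The ranking statistic is the mean
decrease in out-of-bag accuracy under per-tree feature permutation
(the quantity classic random-forest software reports as mean decrease
in accuracy). scikit-learn's forest does not expose per-tree OOB
permutation importance, so the bagging loop is explicit here: per
tree, a bootstrap sample, a `DecisionTreeClassifier` with sqrt-k
feature subsampling, OOB accuracy, and one permutation pass per
feature. Defaults: 500 trees, sqrt(k) features per split, seeded;
output truncated to the top 31 (the published candidate-set size),
ties broken by metabolite id.

**Stepwise AIC.** The logistic fit is a straight Newton/IRLS iteration
converged to gradient max-norm < 1e-8, with AIC = 2k − 2ℓ̂ counting
the intercept. Complete separation is detected when a coefficient
magnitude exceeds 30 on the standardized inputs; iteration stops and
the fit is flagged instead of diverging. The search is greedy
bidirectional: every single addition and single drop is scored, the
largest AIC decrease wins, equal decreases prefer the drop
(parsimony), and the search stops when no move decreases AIC. It
starts from the full candidate model by default — the analysis is
described as discarding correlated metabolites — with
forward-from-empty available (`start="empty"`). The trace records
every evaluated model.

**ROC.** AUC via the rank-sum (Mann–Whitney) formulation with ties
counted 1/2; tests check it against exhaustive pair counting and
scikit-learn.

**Network linking.** Nodes are typed (metabolite / protein / gene);
metabolite–enzyme annotation edges are unscored, protein–protein edges
carry confidence scores normalized to [0, 1] (inputs on a 0–1000 scale
are rescaled when the maximum exceeds 1, so a 0.7 threshold equals a
STRING 700). Duplicate PPI edges collapse to the maximum score. Edges
strictly below the threshold are removed; 0.7 exactly survives. A gene
is reached through its encoded protein (identity edge). Path search
admits only the metabolite→enzyme(→protein)→gene topologies; for each
pair, 3-edge paths are reported only when no 2-edge path exists, all
ties are returned, sorted by descending minimum edge score then node
ids. The published phrase about eliminating "undirected paths" is
contradictory for an undirected PPI graph; it is read here as
restricting traversal to that fixed metabolite→gene direction.

**qPCR.** Replicate wells are averaged arithmetically (scatter above
0.5 cycles is flagged); the two endogenous controls combine by the
arithmetic mean of their Cts, which equals geometric-mean
normalization on the linear scale. ΔΔCt is anchored at the
calibrator-group mean ΔCt, making the calibrator's geometric mean RQ
exactly 1. Group inference runs on ΔCt (approximately normal, log2
scale); RQ is reported for interpretation.

**Variant annotation.** Sequences are compared by global pairwise
alignment (match +1, mismatch −1, gap open −5, gap extend −1; a
length-L gap costs open + (L−1)·extend). Adjacent mismatch columns
become individual SNPs; gaps become InDels, left-normalized by
rotating through repeat context so calls are deterministic.
Coordinates are 1-based inclusive; minus-strand genes are handled in
transcript orientation with alleles reported on the minus strand. The
promoter is the 420-bp window upstream (strand-aware) of exon 1; its
first upstream base is promoter, the first exon base is exonic.
Coding SNPs are translated with the standard code; InDels in the CDS
raise (frameshift consequences are out of scope).

PWM scanning uses log2-odds matrices (JASPAR-style count files are
accepted, pseudocount 0.5, uniform background) and the relative score
(raw − min)/(max − min); a hit is relative score ≥ 0.8, scanned on
both strands over the variant ± (motif length − 1) window. Gain = hit
in the alternate only, loss = in the reference only, modification =
hit in both with |Δ| ≥ 0.05.

miRNA sites require a perfect Watson–Crick seed match (miRNA positions
2–8, G:U disallowed in the seed), extended to the maximal contiguous
duplex with G:U allowed outside the seed, scored by per-pair energies
(GC −3.0, AU −2.0, GU −1.0; pluggable) and reported iff the score is
≤ −10. This energy model is a deliberate simplification: the package
reproduces the threshold semantics and the gain/loss bookkeeping of
the published scan, not the published tool's numeric energies, which
is also why site gains/losses are counted from site multiplicity per
miRNA rather than by matching published per-site scores.

## Synthetic data: what it emulates and what it does not

The generators reproduce the statistical structure the analysis
assumes: lognormal within-cell noise around per-metabolite baselines
(drawn over ~0.1–200 µmol/L), a recessive mean shift confined to the
obese line, reference replicates with exact theoretical CVs
(sigma = sqrt(ln(1 + CV²))), interactome tables whose noise edges
cannot shortcut a planted path (they never touch a gene's protein),
variant backbones with indel flanks de-repeated so left-normalization
is the identity on the planted records, and Ct tables whose expected
RQ equals the planted fold change. All randomness flows from one
explicit seed; identical specs give byte-identical outputs.

Not emulated: instrument drift and batch effects, plate layouts,
censoring at the detection limit, metabolite–metabolite correlation
beyond what the planted effects induce, and real genomic repeat
structure. Passing tests therefore demonstrate correctness of the
statistical machinery under the stated model, not robustness to those
real-data artifacts.

Default study conditions in tests: 5 animals per design cell, 100
reference replicates for stable CV estimates (the replicate count is
not specified by the study and is user-settable), noise SD 0.2–0.3 on
the log scale, planted effect sizes of 0.5 natural-log units —
comparable to the published group differences.

The three-signal recovery experiment plants three metabolites that
each track an *independent* component of the group-defining liability
(group = sign of the summed components, measurement noise SD 0.3).
Three case–control mean shifts would be mutually redundant given the
label — any two of them nearly separate the groups and AIC rightly
refuses the third — so independence of the informative directions is
the construction under which "the selected model contains all three"
is the correct expectation.

## Gene-model fixture

The published variant table fixes the variant positions, the 420-bp
promoter window, the exon labels of each variant and the amino-acid
readout of the two coding SNPs, but not the transcript's exon
boundaries. `datasets.ccna2_gene_model()` therefore uses synthetic
exon/CDS intervals constructed once to satisfy every published
constraint (promoter 36471074–36471493; the exon-1 coding SNP on
position 1 of a Leu codon; the exon-4 SNP on position 3 of a Gln
codon; 3'UTR spanning all published UTR variants). The sequence
backbone is random (~40 % GC) with reference alleles and codon
contexts pinned; the builder regenerates the backbone (incrementing
the seed) until the alignment-based caller round-trips the planted
records exactly, so the fixture is valid by construction for any
starting seed.

## Numerical conventions

- CV threshold 0.2, significance threshold 0.05, PPI threshold 0.7,
  PWM relative-score threshold 0.8 (inclusive), miRNA energy threshold
  −10 (inclusive), top-k 31 — all configurable, defaults as published.
- Logistic convergence: gradient max-norm < 1e-8, ≤ 100 Newton steps,
  separation bound 30.
- Ties: stepwise prefers drops; importance ranking breaks ties by id;
  path output orders by descending min score then node ids.
- Degenerate inputs: constant responses give p = 1; empty candidate
  sets give an intercept-only model with a warning; one-class label
  vectors and empty groups raise.

## Problem sizes

Test and acceptance runs use the study-scale design (60 samples, 163
metabolites), 200 reference replicates for the CV checkpoint, 1000
null metabolites for calibration, 100 seeded replicates for the
recovery properties, random 50–80-node graphs against the brute-force
path oracle, and one ~7.6-kb sequence pair for variant calling.

## Known limitations

- The published real-data results that depend on the undeposited
  animal measurements (the exact AUCs 0.752/0.711/0.725, per-metabolite
  p-values, the 2.3-fold qPCR estimate) are not reproducible from
  scratch; they are covered by parameter-recovery and
  oracle-equivalence properties on synthetic data instead.
- CONSITE/PITA numeric scores are not reproduced (threshold semantics
  and gain/loss logic are; the scoring functions are pluggable).
- InDel coding consequences (frameshifts) and amplification-efficiency
  correction for qPCR are out of scope.
- The stepwise search is greedy; it matches the exhaustive best-subset
  optimum on the tested fixtures but carries no global guarantee.
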