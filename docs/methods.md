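# Methods

## Setting and model

The package analyses samples of non-recombining haploid sequences — the
motivating case is the male-specific region of the human Y chromosome
(MSY) — under the standard neutral mutation model: mutations arrive as a
Poisson process along the branches of the (unknown) genealogy at rate
µ·L per year, where µ is the per-nucleotide rate and L the number of
accessible nucleotides. Because the locus does not recombine, every
variant maps onto a single genealogy, and almost every variant onto a
single branch.

## Tree building

Input haplotypes are polarized first (1 = derived) using an outgroup
sample, an ancestral-allele table, or the reference-is-ancestral
assumption; sites whose ancestral state cannot be resolved are flagged
and excluded from tree building rather than guessed.

A rooted perfect phylogeny exists exactly when the derived-carrier sets
are pairwise nested or disjoint (a laminar family). The builder groups
sites by carrier set, orders the distinct sets by support (number of
sites sharing the set), then size, then lexicographic tip order, and
greedily accepts every set compatible with the sets already accepted.
Support-first ordering means a clade witnessed by many mutations always
defeats a conflicting one-off homoplasy pattern. Accepted sets become
internal nodes (nesting gives the topology); each site whose carrier set
was accepted maps to exactly one branch. Tips with identical haplotypes
hang from a shared node on zero-length terminal branches, and identity
classes are read off those. Polytomies are retained, never arbitrarily
resolved.

Rejected (recurrent) sites are placed on the now-fixed tree by two-state
minimum-change parsimony, implemented as the exact dynamic program
`cost(v, s) = Σ_children min(cost(c, s), cost(c, 1−s) + 1)` — equivalent
to Fitch/Hartigan counting and valid on multifurcating trees. During
tree building the root state is fixed to ancestral (the data are
polarized), so a recurrent site always needs ≥ 2 events; the standalone
placement routine can instead infer the root state freely, in which case
a clade-complement pattern resolves to a single back-mutation and is
flagged as such. Ties among optimal placements are broken
deterministically: the backtrack keeps the parent state whenever that is
cost-neutral, deferring changes toward terminal branches, and prefers
the ancestral state otherwise.

Parsimony event counts are a *lower bound* on the true number of
events: a back-mutation nested inside its own clade, or two events whose
combined pattern happens to be laminar with every surviving clade, are
invisible to any parsimony method. On simulations with rare recurrence
the report has no false positives and never overcounts (asserted in the
tests); it undercounts precisely these invisible configurations.

## SNP dating (rho)

For a clade with n tips, branches b inside it, l_b mutations and n_b
descendant tips per branch:

    ρ = (1/n) Σ_b l_b·n_b        (equals the mean tip-to-root path count)
    σ = sqrt(Σ_b l_b·(n_b/n)²)   (Saillard-style Poisson SD)

TMRCA = ρ/(µ·L) years. Defaults µ = 1.0×10⁻⁹ /bp/year and
L = 3,724,156 bp give one mutation per 268.5 years. Uncertainty in the
published rate (95% CI 3.0×10⁻¹⁰–2.5×10⁻⁹) is propagated by rescaling
the point estimate to each CI bound — the bounds are treated as exact,
not folded jointly with σ, which is reported separately. Point estimates
are printed in ka rounded to 0.1, half away from zero. Ranges are
computed from the unrounded ρ, so the last digit can differ by ±0.1 ka
from tables that rescaled already-rounded points. Generation time
(default 30 years) is carried in the rate model but only used for STR
dating, the SNP rate being per year.

## STR dating

With root haplotype r over m loci and members' alleles a_ij:

    ASD = (1/(n·m)) Σ_i Σ_j (a_ij − r_j)²
    ρ_STR = (1/(n·m)) Σ_i Σ_j |a_ij − r_j|

Under an unbounded symmetric single-step mutation model E[ASD] = rate ×
generations at any depth, while ρ_STR measures net displacement and
saturates once rate×time is of order one (|Σ±1| ≤ number of steps).
The rho-on-STRs method of network software reduces to this step distance
on a star genealogy; on non-star data it is an approximation, documented
as such. Roots are either the true ancestral haplotype (available in
simulations, otherwise user-supplied, never inferred heuristically) or
the per-locus modal haplotype with ties broken to the smallest allele.

Marker subsets: set21 (all single-copy panel loci; the bilocal DYS385
pair is excluded from all dating), set17 (additionally dropping the
rapidly mutating DYS570/DYS576 and complex-repeat DYS389II/DYS448) and
set13 (the Yfiler core minus bilocal/complex loci). Rate regimes: the
"evolutionary" rate 6.9×10⁻⁴ /locus/generation applied to every subset,
and a "pedigree" regime whose shipped per-locus values are placeholders
chosen so the subset means (set21 3.93×10⁻³, set17 3.04×10⁻³, set13
2.82×10⁻³) fall inside the published 2.797–4.238×10⁻³ bracket; users
with locus-specific estimates should supply their own table.

TMRCA_generations = statistic / mean subset rate; years = × generation
time. The comparison module tabulates, per (method, subset, root,
regime) cell, the Pearson correlation between STR and SNP point
estimates over shared clades (undefined and reported as such below 3
clades), the mean signed relative error and an over/under flag.

## Heterogeneity protocol

Mutations-to-root counts are compared pairwise between groups with a
two-sided Mann–Whitney U test (exact enumeration when both n ≤ 8 without
ties, tie-corrected normal approximation otherwise; a permutation-exact
mode exists for tied data). Groups larger than k = 10 are subsampled
without replacement to k in each of R = 100 replicates; smaller groups
enter whole. Each replicate's p-values are Bonferroni-corrected with
divisor equal to the number of pairs actually tested (overridable, since
a fixed divisor such as C(17,2) = 136 is equally defensible), and a pair
is "of interest" when more than half of its replicate p-values remain
below α = 0.05. Tissue-source comparisons use a classical one-way
ANOVA. A Monte-Carlo routine estimates the power of the Mann–Whitney
comparison for Poisson count models at stated group sizes.

## Selection and recurrence tests

Singleton enrichment among damaging nonsynonymous variants uses a 2×2
chi-square with Yates' continuity correction, floored so |O−E|−0.5
cannot go negative: rows are the damaging variants (singleton /
non-singleton) and the whole-data-set background. Using the full data
set as the comparison row (rather than the data set minus the damaging
variants) is the layout validated against the published p-values, which
it reproduces to their printed precision (0.0065 and 0.0527); Fisher's
exact test is available behind a flag. Cross-study recurrence-rate
comparisons use the same corrected chi-square by default; the
uncorrected statistic is exposed because one published bound (P<0.0002
for 123/13,261 vs 4/2,386) is met only without the correction
(corrected p = 0.00023).

A site is CpG when its reference trinucleotide context carries the CG
dinucleotide through the site on either strand (site C followed by G, or
site G preceded by C). Recurrence summaries report recurrent-site counts
and the CpG share of recurrent events from integer counts.

## Synthetic data

The generator is the minimal process consistent with the dating
assumptions: a constant-size Kingman coalescent (haploid effective size
in generations; waiting times Exp with rate C(k,2)/Ne), a fixed-depth
star option that isolates estimator properties from genealogy noise, or
a user Newick. SNP mutations are Poisson per branch at µ·L per year;
infinite-sites assigns each event a fresh position, finite-sites draws
positions from a fixed set in which a CpG class (default 2% of sites at
10× rate — an order-of-magnitude convention, synthetic only) allows
recurrence, with every event logged. STRs mutate by strict symmetric ±1
steps, Poisson per branch per locus. Tissue labels default to the
152:208:88 LCL:blood:saliva proportions of the motivating study; LCL
tips can receive Poisson-distributed private singletons appended on
terminal branches, mimicking cell-line somatic variants. Defaults
(µ = 1.0×10⁻⁹, L = 3,724,156, g = 30 y, STR rate 6.9×10⁻⁴, Ne = 2,100
generations so coalescent depths land near the ~126 ka of the real
tree) are the study conditions; every stochastic routine is a pure
function of (config, seed).

What the generator does *not* emulate: population structure and
demography, ascertainment or coverage artefacts, multi-step or
locus-length-dependent STR mutation, gene conversion, and sequencing
error. Passing tests therefore demonstrate correctness of the
estimators under their own model assumptions, not robustness to the
messiness of real data.

## Problem sizes and numerical conventions

The test suite and the acceptance script run simulations sized to make
Monte-Carlo bands tight relative to the effects checked (e.g. star
genealogies with n = 500 tips for single-run recoveries, 200 replicates
of n = 20 for mean-recovery properties, 300–500 protocol runs for
calibration rates); stochastic assertions use 3-standard-error bands
around closed-form expectations, with every seed fixed. Degenerate
inputs (empty matrices, all-missing sites, zero rates, empty carrier
sets, zero marginals) raise typed errors rather than propagating NaNs.

## Known limitations

* The greedy laminar-family choice is support-weighted parsimony, not a
  global optimum; with heavy recurrence (finite-sites saturation) the
  reconstructed topology degrades, as any parsimony method's would.
* Event *locations* for recurrent sites depend on the deterministic tie
  rule and may differ from other software even when counts agree.
* STR pedigree per-locus rates are placeholders (see above).
* Newick serialization carries integer mutation counts only; per-site
  event detail travels in the events sidecar table.
* The coalescent is single-population and constant-size by design.
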