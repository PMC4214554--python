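# Methods

## Model

We call genotypes at bi-allelic candidate sites for all members of one
family jointly. The genotype space is {RR, RA, AA}, indexed 0/1/2 in VCF
PL order (0/0, 0/1, 1/1); this ordering is fixed everywhere in the
package. Per site, the inputs are per-member linear-scale likelihoods
P(Dᵢ|Gᵢ), a founder genotype prior P(G), and a transmission model
P(G_child|G_father, G_mother). The joint factorises over the pedigree as
a Bayesian network (each genotype depends only on the parents'), and
every engine computes the same target: the per-member marginal
posterior.

Unsequenced pedigree members (sample name `NA`) and samples with a
missing PL at a site receive the uniform likelihood (1,1,1) — they are
marginalised, which is the unique non-informative choice. Sites whose
ALT is `.` are skipped (everyone is homozygous reference by
construction); multi-allelic sites are skipped with a warning by
default, or reduced to their first ALT with `first_alt` (using the
0/0, 0/1, 1/1 subset of the PL vector).

## Transmission and de novo mutation

Each meiosis picks one of the parent's two alleles uniformly; the picked
allele then mutates into the other allele with probability m. This gives
per-allele transmit probabilities RR → (1−m, m), RA → (½, ½),
AA → (m, 1−m), and the 3×3×3 child tensor by combining the two
transmitted alleles. Only the transmitted allele can mutate, once — no
back-mutation chains; whether mutation is applied before or after the
allele pick is unobservable at this order, and we fix the
pick-then-flip mechanism. m defaults to 1e-7 (slightly above the
commonly estimated 1e-8 per base per generation, which controls false
calls better in practice); it is capped at 0.5, beyond which the allele
labels would effectively invert.

Priors: (0.9985, 0.001, 0.0005) for novel sites, (0.45, 0.1, 0.45) for
dbSNP sites, or Hardy-Weinberg from a user-supplied alternative allele
frequency q: ((1−q)², 2q(1−q), q²).

## Pedigree validation and loops

Pedigrees must be *complete*: every non-founder lists both parents
(exactly one recorded parent is an error, since full vs half siblings
would be ambiguous), every referenced parent has its own row, referenced
fathers must be male and mothers female, and the ancestry relation must
be acyclic. The no-parent sentinel is `0` (PED convention) and gender
accepts 1/2 or M/F case-insensitively; the upstream text format leaves
both unstated, so byte-level compatibility with other tools is not
claimed.

A pedigree *loop* is a cycle in the bipartite graph of individuals and
nuclear families (one family node per distinct couple, linked to the two
parents and all common children). This covers consanguineous loops
(related mates) and marriage loops (sibships exchanging spouses); both
break the anterior/posterior decomposition, so both are routed away from
peeling.

## Engines

**Exact enumeration.** Sums the joint over all 3ⁿ configurations,
indexed base-3 little-endian in member order. Per-configuration weights
are accumulated in log space and exponentiated after subtracting the
per-site maximum log-weight, so zero-probability configurations (m = 0)
and large n cannot underflow; the underflow strategy is this package's
choice. The size cap of n = 14 (≈4.8M configurations) is a guardrail,
not a modelling constant, and is overridable. `partitioned_sum` splits
the index range into contiguous parts summed independently and combined
by addition — the testable contract of a parallel (many-worker)
execution of the same sum; each part is bitwise-deterministic and the
recombination agrees with the single pass to ≤1e-12.

**Elston-Stewart peeling.** Implemented as sum-product message passing
on the individual/family tree, which is mathematically the
anterior/posterior recursion: the anterior of a member is the message
from its parental family (founders: the prior), the posterior
contribution per mate is the message from that spousal family, and the
marginal is anterior × likelihood × product of per-mate posteriors.
Members with several mates get one posterior factor per spousal family.
Messages are renormalised as they are formed, which provides the same
numerical protection as the log-max shift. Exact on loop-free pedigrees
(validated against enumeration to ≤1e-10 over hundreds of randomized
pedigrees, n = 3..12); looped pedigrees are a hard error here — loop
cutting is deliberately not implemented, since enumeration answers loops
exactly.

**MCMC.** Systematic-scan Gibbs over members in pedigree order; the
full conditional of a member involves only its likelihood, its parental
(or prior) term and one transmission term per child. With heat T > 1
the proposal is drawn from the tempered conditional p^(1/T) and accepted
with min(1, (p(g′)/p(g))^(1−1/T)); this is the standard tempered-proposal
construction (the upstream description does not reproduce the formulas)
and its correctness is established by stationarity tests (T = 1 and
T = 2 long runs agree with exact marginals). Defaults: T = 2, burn-in
10% of sweeps, single chain, seeded generator (mandatory for
reproducibility), start at the individual-based MAP configuration. One
*iteration* is one single-member update; the default budget is 20,000·n
iterations = 20,000 sweeps, interpreted as total including burn-in. When
dispatched per site by the caller, each site derives its own seed from
the run seed and the candidate index, so outputs are reproducible and
sites are independent.

Degenerate inputs: with m = 0 and contradictory certain evidence the
total joint weight can be exactly zero — enumeration and peeling raise
`NormalizationError`, and a Gibbs conditional that vanishes for all
three genotypes raises `ZeroConditionalError`. With the default m > 0
these cannot occur.

## Caller policy

`auto` dispatch: peeling on loop-free pedigrees, enumeration on looped
ones; explicit method flags override (peeling on a loop raises, with the
site coordinate attached). The individual-based posterior
(likelihood × prior, renormalised) is always computed and reported
alongside the family-based one.

The over-correction guard interprets "likelihood ratio" as each
sequenced member's best-vs-second-best *likelihood* ratio (not
posterior; the interpretation is isolated in one function). It fires
only when every sequenced member exceeds the cutoff AND the
individual-based MAP genotypes are Mendelian-impossible at m = 0;
unsequenced members are excluded from the ratio test. Disabled by
default (no cutoff). Output fields GPI/PPI/GPF/PPF and the 4-decimal
posterior formatting are this package's conventions.

## Synthetic data

`simdata` generates the study conditions end to end: founder genotypes
from a prior, child genotypes through the transmission model (de novo
flags recorded when a transmitted allele flipped), and read evidence via
depth ~ Poisson(λ), alt-count ~ Binomial(depth, μ_G) with μ = (ε, ½,
1−ε), likelihood = binomial pmf, Phred-scaled to integer PL (depth 0 →
uninformative). Defaults: trio, 10,000 sites, λ = 4, ε = 0.01, founder
alternative-allele frequency 0.2 under Hardy-Weinberg (candidate sites
are variant-enriched relative to the genome-wide prior), m = 1e-7.
The accuracy experiment uses the generating prior for both calling modes
so that each is a proper Bayes rule under the simulation and the
comparison isolates the value of pedigree information; the family mode
then strictly reduces the genotype-error rate at low depth (the
acceptance script prints the measured rates).

What the generator does **not** emulate: read-level artefacts (mapping
error, strand bias, indel realignment), linkage between sites, allele
bias at heterozygous sites, and population structure among founders.
Passing tests therefore demonstrate correctness of the inference given
the likelihood model, not robustness to real sequencing artefacts.

## Problem sizes and tolerances

Default test and acceptance runs use: 200 random loop-free pedigrees
(n = 3..12) for cross-engine agreement at 1e-10; exhaustive nested-loop
comparison up to n = 4 at 1e-12; the partition contract at 1e-12; MCMC
vs exact at ≤0.02 on a trio and a 7-member looped pedigree at the
default iteration budget over a handful of simulated depth-10 sites; and
the 10,000-site depth-4 trio experiment for the accuracy direction.
These sizes keep a full run to a few minutes on one core while
exercising every engine across its intended regime.

## Known limitations

Single family per run; autosomal transmission only (no hemizygous X/Y
model); bi-allelic sites only; no loop cutting for peeling (loops cost
3ⁿ enumeration or MCMC); no annotation of de novo events in the output;
no multi-chain MCMC convergence diagnostics; no uncertainty model on the
allele frequency itself.
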