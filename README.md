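# pedcall — pedigree-aware genotype calling from genotype likelihoods

Single-sample variant callers decide each genotype from one individual's
reads and a population prior. When a whole family has been sequenced,
that throws away information: genotypes inside a pedigree are tied
together by Mendelian transmission, and at low coverage the reads of
relatives can rescue calls that are ambiguous on their own. `pedcall`
takes per-sample genotype likelihoods P(D|G) (VCF `FORMAT/PL`, or a
likelihood-only table) plus a pedigree structure file, and reports for
every member at every candidate site both the **individual-based**
posterior and the **family-based** posterior that marginalises the whole
pedigree.

## Model

Bi-allelic sites with genotypes G ∈ {RR, RA, AA}. For a pedigree of n
members with genotype configuration **G** = (G₁…G_n) and data **D**:

P(**G** | **D**) ∝ ∏ᵢ P(Dᵢ|Gᵢ) · ∏_{founders} P(Gᵢ) · ∏_{non-founders} P(Gᵢ | G_father(i), G_mother(i))

The transmission probability P(G_c|G_f, G_m) includes de novo mutation:
each transmitted allele flips with probability m (default 1e-7), so e.g.
P(RA | RR×RR) = 2m(1−m). Founder priors default to (0.9985, 0.001,
0.0005) for novel sites and (0.45, 0.1, 0.45) for dbSNP sites (sites
with an ID), or can be derived from an allele frequency via
Hardy-Weinberg.

Three interchangeable engines compute the per-member marginals
P(Gᵢ | **D**):

* **exact enumeration** (`--method bn`) — sums the joint over all 3ⁿ
  configurations; exact on any pedigree, including inbreeding and
  marriage loops; capped at n = 14 by default.
* **Elston-Stewart peeling** (`--method es`) — anterior/posterior
  recursion over nuclear families; exact and near-linear in n, but only
  on loop-free pedigrees.
* **Gibbs MCMC with heated-Metropolis** (`--method mcmc`) — samples each
  member's genotype from its full conditional (parents, mates,
  children), with a tempered proposal (T = 2 by default) to escape local
  modes; approximate, works on loops, default budget 20,000·n updates.

`--method auto` (the default) uses peeling on loop-free pedigrees and
exact enumeration on looped ones.

An optional over-correction guard (`--lr-cutoff`) protects true de novo
mutations: when every member's evidence is individually decisive yet the
individual calls violate Mendelian transmission, the family-based call
is replaced by the individual-based one.

## Worked example

Simulate a low-coverage trio (mean depth 4, 1% base error) and call it:

```sh
pedcall simulate --ped-template trio --sites 1000 --seed 7 --out-prefix demo
pedcall call --vcf demo.vcf --ped demo.ped --out demo.calls.vcf
# wrote demo.calls.vcf: 1000 records, 1000 called, 0 skipped (method=auto, loop=no)
```

The pedigree file has five columns — ID, mother ID, father ID, gender,
sample name (`NA` for unsequenced members, `0` for "no parent"):

```
F 0 0 1 F
M 0 0 2 M
C M F 1 C
```

The output VCF preserves every record and appends four FORMAT fields per
sample: `GPI`/`PPI` (individual-based call and its posterior) and
`GPF`/`PPF` (family-based). First data line of `demo.calls.vcf`:

```
1  1000  .  A  G  .  .  .  PL:GPI:PPI:GPF:PPF  0,12,80:0/0:0.9999:0/0:0.9999  31,0,11:0/1:0.5456:0/1:0.9253  31,0,11:0/1:0.5456:0/1:0.9981
```

Mother and child each have ambiguous reads (PL 31,0,11 — individually
only 0.5456 posterior for 0/1, barely better than a coin flip). Jointly,
each one's heterozygous reads support the other's, and the family-based
posteriors rise to 0.9253 (mother) and 0.9981 (child) while the
confidently homozygous-reference father stays at 0.9999.

The same calling pass works from the likelihood-only table format
(`--lik`), a tab-separated file with columns
`#chrom pos id ref alt <sample>_RR <sample>_RA <sample>_AA ...`.

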