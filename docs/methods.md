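# Methods

This note documents the models implemented in `steppekin`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical choices that matter.

## Community model

`simulate_community` grows a multi-site community generation by generation
under configurable kinship rules:

* **Patriliny.** Founding males (default 3 per site) head independent
  patrilines; Y-chromosome labels copy father→son and mtDNA labels
  mother→child, so uniparental diversity mirrors the descent system.
* **Marriage.** Every adult son takes a wife.  With probability
  `exogamy_rate` (default 1.0 — in the communities this models, essentially
  every mother lacks parents at the site) she is an unrelated immigrant; in
  multi-site runs a fraction `female_exchange_rate` of exogamous brides are
  instead unmarried adult daughters of another simulated site, relocated to
  the husband's site (patrilocality) while keeping their natal parent links —
  this is what creates between-site IBD through women.  In-community brides
  must stand at genealogical degree ≥ `consanguinity_min_degree` (default 6)
  from the groom; if `exogamy_rate` is 0 and no eligible bride exists the
  simulation raises rather than silently violating the rule.
* **Polygyny.** After each marriage another wife is added with probability
  `polygyny_prob` (default 0.15), capped at four partners — the observed
  maximum in the communities modelled.
* **Levirate.** With probability `levirate_prob` a married man dies and each
  widow is re-partnered to the first eligible agnate in the priority order
  full brother → paternal half-brother → paternal uncle/nephew line → son of
  the deceased by another partner (never the widow's own son), subject to the
  same consanguinity rule.  Every event is logged (deceased, successor,
  widow, agnatic relation) so detection can be checked exactly.
* **Demography.** Offspring counts per union are Poisson with configurable
  means (default 1.5 sons, 1.5 daughters; the simplest count model consistent
  with a mean parametrisation).  A child dies before adulthood with
  probability 0.2; adult ages at death are uniform on 18–70.  Birth years
  advance by N(29, 6²) years per generation, the standard generation gap.
* **Community replacement.** Optionally a new founder cohort with a distinct
  Y label enters at generation g\* and takes over reproduction, reproducing
  the observable pattern of one male lineage replacing another mid-sequence
  while mtDNA diversity continues unchanged.

**Burial sampling** turns the full pedigree into an observed cemetery:
unmarried adult daughters emigrate with probability 0.9 (they marry out);
immigrant mothers' parents are absent by construction; a configurable
fraction (default 0.5) of last-generation unmarried adult men get a childless
partner buried as an unrelated female — drawn from another site's emigrated
daughters at the female-exchange rate, otherwise a fresh immigrant.  The
childless exchanged brides are the women who appear "unrelated within site"
yet carry IBD links to another site.

### Degree convention

Genealogical degree counts meioses: parent–child 1, full siblings 1 (shared
ancestral *couple*: g_a + g_b − 1), half siblings / avuncular / grandparent
2, first cousins 3, second cousins 5.  Kinship expectation is (½)^(degree+1).

## Genome transmission and observation

Gene dropping uses a sex-averaged 22-autosome map totalling ≈3,546 cM
(overridable).  Crossovers are Poisson(L/100) per meiosis, positions uniform,
no interference: interference changes segment-length variance slightly but
none of the first-moment quantities this analysis targets, and the
no-interference model keeps the simulator transparent.  Founder haplotypes
are IBD-free by construction, so all sharing is pedigree sharing; no
background relatedness, mutation or genotype level is simulated.

The observation model degrades true segments the way ancient-DNA IBD
detection does: a hard detection floor (default 8 cM), optional
length-dependent dropout, optional boundary jitter, and SNP counts assigned
at a density default of 250/cM — deliberately above the 220 SNPs/cM quality
screen applied downstream, as imputed high-quality data are.

## Relatedness inference

Degree classification bins φ = ¼p₁ + ½p₂ at log2 midpoints (0.354, 0.177,
0.088, 0.044).  Within the first degree, parent–child requires p₂ < 0.02 and
p₁ > 0.9; siblings require p₂ ≥ 0.1; anything else is reported
first-degree-ambiguous rather than forced.

Second-degree subtypes are separated by a per-class 2-D Gaussian KDE over
(segment count, mean segment length) fitted on 60 simulated reference
pedigrees (an eight-member structure containing all three pair types run
through the same observation model as the data).  At the defaults the
reference clouds sit at roughly 42 segments × 40 cM (avuncular), 26 × 70
(grandparent–grandchild) and 39 × 46 (half siblings); half siblings overlap
both neighbours at range level on both axes, which is why their recall is
intrinsically lower and why calls with a best/second-best likelihood ratio
under 2 are returned as "ambiguous".

Consanguinity is flagged when the summed length of long (>4 cM) ROH exceeds
10 cM.  Offspring of second cousins (F = 1/64) carry ≈55 cM of long ROH in
expectation spread over ≈4–5 segments, so the miss probability is a few
percent at most, while outbred individuals in this label-based model carry no
ROH at all — the threshold therefore trades essentially no false positives
for >80% sensitivity at the second-cousin level and >95% at the first-cousin
level.

## Pedigree assembly

Assembly is constraint propagation over classified pairs: connected
components of first/second-degree calls are candidate pedigrees;
parent–child edges are oriented by explicit chronological anchors when
supplied (calibrated ¹⁴C point estimates or simulation truth), else by the
adult/subadult distinction (a person dead before 18 cannot be a parent),
else by chronological phase; same-phase adult pairs are left unresolved
rather than guessed, because the real analyses resolve such ties with
archaeological context that has no algorithmic counterpart.  Phase alone is
too coarse over nine generations, which is why the anchor hook exists.
Mothers/fathers are slotted by sex; mtDNA (mother–child) and Y (father–son)
labels veto inconsistent placements, which are emitted as per-component
conflict reports.  Sibling groups share parents; a single unobserved parent
connecting two or more observed siblings with second-degree support is
emitted as an explicitly flagged "ghost" individual.  Children of a levirate
union pair (two agnatically related fathers, one mother) are genuinely
intermediate between full and half siblings and surface as a sibling-group
conflict — by design, since only context can adjudicate them.

Social metrics: sons/daughters are observed individuals with an observed
parent; mothers split into exogamous (no parent present) and lineage;
patriline purity is the fraction of fathers whose father-chain ends at a true
founder (neither parent present) — a chain that dead-ends at a male whose
mother is present marks a break in the male line.  Because generation-0
founder wives are exogamous by necessity, the metrics also report the
exogamous fraction restricted to non-founding unions; that restricted
fraction is an unbiased estimator of the configured exogamy rate whenever
eligible in-community brides exist.

## Network analysis

Edges require ≥1 retained segment >12 cM (two when the longest is <16 cM)
after the 8 cM / 220 SNPs-per-cM screen; weight is the pair's maximum IBD
length — the published ">280 cM for first-degree relatives" scale is only
attainable by a single near-chromosome-length segment, not by totals.  The
graph is simple and undirected; modules are burial sites.  The KS permutation
test pools the two samples and re-splits at the original sizes (the standard
exchangeable null), with p = (1+#{D\*≥D})/(1+n_perm).  Welch's t-statistic
uses the Welch–Satterthwaite df and is cross-checked against SciPy in tests.

The female-vs-male k_B/k contrast is a property of the **adults-only**
network: subadult daughters buried beside their parents have k_B/k = 0 and
dilute the female mean if left in.  The published full-network link count and
adult mean degree are in tension in the source material (1,211 adult links
against ⟨k⟩ = 18.07 × 195/2 ≈ 1,762 implied); this package reports raw link
counts and means separately and takes no side.

## Chronology

Calibration uses calendar years AD on a 1-year grid (cal BP = 1950 − AD) and
a Gaussian measurement model with curve error added in quadrature.  The joint
model places latent generation reference years on a positive random walk with
N(29, 6²)-year steps (scaled by the number of generations a gap spans),
individuals scattering N(0, 10²) years around their generation; all three
blocks (anchor year, gaps, individual years) are updated by
Metropolis-within-Gibbs with fixed step sizes (8, 4 and 6 years), 20,000
iterations, 4,000 burn-in, thinning 5.  A split-chain mean comparison is
reported as a convergence diagnostic.  Marginal densities are KDE-smoothed
onto the calendar grid so HPD widths (smallest cell set holding 95% mass; the
set may be non-contiguous on a wiggly curve) are directly comparable with
single-date calibration.  Dated events are treated as birth-cohort years;
age-at-death offsets are absorbed by the within-generation spread.  On a
nine-generation synthetic chain with σ_meas = 25 y and a wiggly curve the
constrained widths shrink by ~50% at the median and >60% at the maximum,
and never exceed the unconstrained widths.

## Synthetic scenarios

`rk_like` (one site, nine generations, strict exogamy, levirate on, community
replacement at generation 4), `multi_site` (three sites,
`female_exchange_rate` 0.15, daughter emigration 0.9 — almost all adult
daughters marry out, between-site marriage uncommon) and `null` (shallow,
structureless).  Presets are structural, not calibrated to any real site's
counts.  Problem sizes in the test-suite and acceptance experiments (e.g.
six-generation assembly scenarios, 1,000-replicate Monte-Carlo moments,
20,000 MCMC iterations) were chosen as the smallest sizes at which the
Monte-Carlo standard errors are far below the effects being measured.

## What the generator does not emulate

No background relatedness or population structure (founders are unrelated by
fiat), no genotype-level noise, contamination or phasing error beyond
boundary jitter and dropout, no admixture/ancestry, no mortality structure
beyond a flat adult age distribution, and no archaeological context.  Tests
passing on these data therefore validate the pipeline's logic and its
statistical calibration, not the behaviour of genotype-level inference tools
on real ancient DNA.

## Known limitations

* Assembly resolves orientation only as far as chronology allows; densely
  intermarried levirate families are reported as conflicts, not solved.
* Ghost-parent inference is limited to a single missing parent over an
  observed sibling group; deeper missing-individual reconstruction is out of
  scope.
* The subtype classifier's half-sibling recall is bounded by genuine
  distributional overlap; no amount of reference simulation removes it.
* The MCMC uses fixed step sizes tuned for century-scale problems; very
  different measurement errors may need retuning.
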