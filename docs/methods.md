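# Methods

This note records the model as implemented, the conventions and
numerical choices behind it, and what the validation does and does not
establish.

## Life cycle and environment

The population is an infinite set of patches, each with n breeders
(n = 2 by default: one high-quality, one low-quality; roles are
reassigned among the winners every generation).  Events within a
generation, in order:

1. social interactions and reproduction (fecundities from the
   competitive-effort function);
2. offspring dispersal: a fraction d leave, survive with probability
   1 − c, and land uniformly over patches;
3. competition for the n vacancies **on the patch's current state**:
   each vacancy is an independent fecundity-weighted draw from the local
   stayer pool plus the immigrant pool (fecundity is effectively
   infinite, so draws do not deplete the pool);
4. winners are assigned quality roles (probability 1/2 each in the
   fixed-roles model; Bernoulli(Q) in the early-quality extension);
5. the patch may switch resource state.

Patch state follows the unique two-state Markov chain with stationary
distribution (p, 1 − p) and lag-1 autocorrelation τ:
p(R→R) = p + (1 − p)τ, p(P→P) = (1 − p) + pτ.  Feasibility bounds τ
below by −min(p, 1−p)/max(p, 1−p); τ = ±1 are allowed and all linear
systems are solved directly (no geometric-series shortcuts), so the
frozen and alternating limits are exact.  Backward (history)
probabilities come from Bayes at stationarity.

## Fecundity and its marginals

f = μ_σ (q_ρσ + Ψ·Θ) with personal share component Ψ = x and group
component Θ = (1 − x̄)/x̄.  Two algebraic facts worth recording because
they are easy to get wrong:

- patch total fecundity is μ_σ(Σ_ρ q_ρσ + n(1 − x̄)): the effort
  profile enters group output only through its mean;
- own fecundity is *not* globally increasing in own effort: the own
  derivative is μ(Θ − x/(n x̄²)) and changes sign inside the domain.
  What rises monotonically is the resource share x/x̄.  The behavioural
  interface therefore exposes both the channel marginals
  (C = −μΘ, share channel only; B = recipient-side pool derivative) and
  the exact total derivatives used by the selection analysis.

Trait domain is [1e−6, 1]; x = 1 by all members is the fully selfish
corner where f = μq, used for the inequality baselines.

## Demography and reproductive value

The 4×4 class fitness matrix w[parent, child] (class order HR, LR, HP,
LP) counts expected recruits per parent: offspring settle at home with
probability (1 − d)·n/(O_π + I) or abroad via the dispersal pool, the
quality coin is flipped, and the settlement patch's state transition is
applied.  For any monomorphic resident the leading eigenvalue is 1 and
the stationary class frequencies are u_ρσ = π_σ/2 (both verified to
1e−10 in the tests).  Eigen-quantities use a dense solve; if the matrix
decouples (d = 0 with τ = 1) each strongly connected block is solved
separately and blocks are weighted by the analytic stationary
frequencies.  Reproductive values are normalised by Σ u v = 1; any
fixed positive scaling would leave all selection conclusions unchanged.

Offspring value V_σ and the philopatric component v^φ_ασ = f_ασ w^φ_σ s_σ
(value flowing through offspring that stay and win at home) follow from
the eigenvectors; V is independent of the mother's quality because
offspring are identical at birth.

## Relatedness

Pair relatedness by current patch state solves a linear two-equation
recursion: condition on the previous state (backward chain), both
members are philopatric with probability h², philopatric winners share
a mother with probability Σ_ρ f_ρ²/((n/2)(f_H+f_L)²), siblings count 1,
non-siblings inherit the mothers' relatedness.  Inheritance is haploid,
asexual, mutation-free.  In the symmetric limit this collapses to
r = φ/(2 − φ) with φ = ((1 − d)/(1 − cd))², which the tests verify to
1e−10 over random (d, c).

## Selection and the Hamilton partition

Selection gradients are slopes of mean fitness on class breeding
values under weak selection: only the focal patch's phenotypes,
fecundities and local pool deviate; the global pools, u and v stay
resident.  Partials are central finite differences (step 1e−6); the
resulting gradient has a numerical noise floor around 3e−9, which is
why the solver's default tolerance is 1e−8.

The inclusive-fitness route evaluates, per actor class,

    a·V + B_tot·r·V − (a + B_tot)·(w^φ/n)·[v^φ_a (1 + (n/2 − 1) r) + (n/2) r v^φ_o]

where a is the actor's total own-fecundity derivative (share gain minus
her own exposure to pool depletion), B_tot sums the pool-depletion
effect over her n − 1 patch-mates, and the last term prices the
displacement of local offspring: each extra recruit evicts a uniformly
random winner of the n home vacancies, hence the explicit 1/n.  With
these conventions the partition equals the direct gradient divided by
the class frequency u — exactly, not approximately — which the tests
assert at 1e−6 relative over random parameter sets.  The decomposition
is therefore not an independent approximation but a change of
accounting; its value is interpretive (cost, kin benefit, kin
competition) and diagnostic.

The potential for helping A = (rV − w̃D)/(V − w̃D), with w̃ = w^φ/n and
D = v^φ_a + r v^φ_o, is the critical cost–benefit ratio of a generic
helping act; it depends only on demography and relatedness, not on the
effort function.

## Singular strategies and stability

z* solves S(z) = 0 by damped fixed-point iteration
z ← clip(z + η S, [1e−6, 1]) with η halved on overshoot (cap 0.5),
recomputing the full resident state each step; default start 0.5,
tolerance 1e−8, 10⁴ iterations.  Warm and cold starts agree to 1e−6 on
the reference sweep.  Near τ = 1 the map's contraction weakens and the
frozen-environment solve needs ~3× the default iteration budget; the
sweep grants its τ = 1 reference solve 30 000 iterations.  Traits
pinned at a domain edge with an outward gradient are reported as
boundary equilibria (this occurs for large patch sizes).  Convergence
stability is judged from the Jacobian of the gradient map with respect
to *resident* trait values (central differences, step 1e−5): all
eigenvalue real parts negative.  This is the standard multidimensional
criterion; every interior equilibrium on the reference sweep passes it.

## The interior helping peak near τ = 1

A robust feature of this life cycle deserves its own paragraph because
it shapes several downstream quantities.  At τ = 1 a rich patch is rich
forever: philopatric value v^φ is at its maximum, kin competition is
maximal, and restraint is *less* favoured than just inside τ < 1, where
the risk that the patch turns poor sharply devalues home-grown
offspring.  Helping potential and evolved restraint therefore peak at
an interior τ slightly below 1, in both the fixed-fecundity analysis
and the full feedback solution (the singular point at exactly τ = 1 is
unique — verified by multi-start root finding — and the individual-based
simulator confirms it).  Consequently relative productivity
F(τ)/F(τ = 1) in rich patches *exceeds* one for moderately positive τ:
productivity normalised to the frozen environment is non-monotone even
though F_R rises and F_P falls monotonically with τ across the interior
of the correlation axis.  The acceptance suite states the stronger
monotone-normalised expectation and records its failure rather than
adjusting the model.

## Extensions

**Early-life quality.**  Quality is drawn Bernoulli(Q) at settlement,
so compositions are binomial (pure HH/LL and mixed HL patches) and
efforts condition on own quality, partner quality and patch state
(eight classes/traits).  Stationary class frequencies factorise as
Bernoulli(Q)² × patch frequency (asserted to 1e−8).  Pair relatedness
remains composition-independent because quality is assigned
independently of parentage; this modelling proposition was checked
against the individual-based simulator in the extension configuration
(all eight evolved traits within ~2 replicate SE).  With equal baseline
qualities the model collapses onto the main pipeline (asserted to
1e−5).  One qualitative caveat: at stable τ in rich patches the evolved
effort of pure-LL breeders slightly exceeds that of the mixed-patch H
breeder (~0.03), so "mixed patches carry both extremes" holds on the
unstable side of the axis but not uniformly; the simulator agrees with
the analytics here, and the acceptance suite records this honestly.

**Patch size.**  The core pipeline is written for general even n (half
of each quality): pools scale with n/2, the lottery with n, the sibling
probability generalises, and the gradient gains (n/2 − 1) same-class
and n/2 cross-class patch-mate terms.  n = 2 reduces exactly to the
pair model (asserted to 1e−8).  Larger patches dilute relatedness,
raise effort (often to the z = 1 boundary) and raise inequality.

## Individual-based simulator

The simulator executes the life cycle literally on a finite set of
patches (defaults: 2000 patches, 20 000 generations, per-trait
mutation rate 0.01 with reflected-Gaussian kernel sd 0.02, eight
infinite-allele neutral markers at rate 1e−3, all driven by one seeded
generator; bit-identical given the seed).  The migrant pool is global
and fecundity-weighted, matching the infinite-island expectation at
large patch numbers.  Relatedness is estimated as
(Q_w − Q_b)/(1 − Q_b) from the markers with patch-bootstrap SEs.

Two properties of the dynamics dictate the validation design.  First,
trait means wander with an autocorrelation time of thousands of
generations (weak stabilising selection against drift), so a
within-run standard error — even one scaled by the estimated
integrated autocorrelation time, which the trajectory statistics use —
cannot be trusted when the averaging window is only a few
autocorrelation times long.  Second, relaxation from a distant start
takes ~15 000 generations at the default mutation regime.  The oracle
comparison therefore initialises replicate populations *at* the
analytical optimum and tests stationarity: selection visibly moves
trait means by ~0.1 per 10⁴ generations when the population is away
from the optimum, so a wrong prediction would be detected, while the
across-replicate SE of independent seeded runs gives an honest
Monte-Carlo error for the grand mean.  Five replicates of 1000 patches
× 10⁴ generations at three τ values leave all trait and relatedness
deltas within ~1.5 replicate SE.  Convergence from a distant start was
checked separately on a 40 000-generation run, which oscillates around
the predicted optimum.  What this validates: the analytical machinery
correctly describes the stated life cycle at these population sizes.
What it does not: anything about real populations (no demographic
stochasticity in patch number, no overlapping generations, no explicit
space, haploid one-locus-per-trait genetics).

## Problem sizes and tolerances

Reaction-norm sweeps use 13 τ points on [−0.9, 0.9]; the validation
suite uses 50 random parameter draws for the closed-form relatedness
check (1e−10), 20 for the Hamilton/gradient equality (1e−6 relative),
and the simulator sizes above — chosen to make every check
statistically meaningful while keeping a full run in the minutes
range.  Eigen-solves are dense (4×4 / 8×8); all linear systems are
direct solves.

## Known limitations

- The Hamilton partition's labelling of "cost" uses the actor's total
  own-fecundity derivative; decompositions that keep the share channel
  separate relabel the same sum.
- The helping-potential peak analysis and figure-style sweeps are
  specific to the additive-baseline, multiplicative Ψ·Θ effort
  function; alternative behavioural functions would need only a new
  Ψ/Θ pair but are not implemented.
- The early-quality extension enumerates compositions for pairs only
  (n = 2 with Q); general n with binomial composition is out of scope.
- τ exactly at the feasibility boundary with p ≠ 1/2 makes one patch
  state transient; the solvers handle it but relatedness conditioning
  on the transient state is then of limited meaning.
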