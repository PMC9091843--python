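# Methods

## Model and assumptions

The package implements the Moran birth–death process on street graphs: at
each time step a reproducing individual is selected with probability
proportional to fitness (`r` for mutants, 1 for residents) and its offspring
replaces a uniformly chosen individual in the partition at the end of the
parent's street.  Mutant and resident offspring travel in opposite
directions along every street; this opposition is what makes the martingale
construction work, because the probability that a mutant reproduces into a
partition shares its state dependence with the probability that a resident
reproduces out of it, edge by edge.

Two topologies are supported.  A **cycle** with class sizes
`[A, B, …, Ω]`; "forward" sends mutant offspring from partition i to
partition i+1 (mod k).  A **megastar**: a centre of size `A` joined to `m`
identical leaf chains; mutant offspring travel centre → leaf position 1 →
… → leaf tip → centre.  Directed-connection graphs, undirected graphs,
death–birth updating and non-identical leaves are out of scope.

### Normalisation of the reproduction lottery

On a megastar the centre partition lies on `m` streets in each species
role.  The package defines the per-step lottery over *(individual, outgoing
street)* slots: the normalising weight is `W = Σ_streets (r·S_u + size_v −
S_v)`, so a centre individual, which owns `m` slots, is `m`-fold weighted.
For cycles every individual owns exactly one slot per role and `W` equals
the total fitness `F = Σ_i (r·S_i + size_i − S_i)` identically, so the
familiar tripartite transition probabilities are unchanged.  Normalising
megastar transitions by the raw `F` instead would assign some reachable
configurations total transition probability above 1 (e.g. a nearly full
centre feeding three leaves), i.e. it does not define a Markov chain; the
slot normalisation is the closest well-posed process.  The choice is
immaterial for everything derived through the martingale: ratios of
transition probabilities at a state are normalisation-free, so the edge
equations, branch vectors, fixation probability, and all statistics of the
active-step count are identical under either convention.  Only the raw-time
clock `T` — and therefore κ and the second-moment comparisons below — is
defined relative to it.

## Martingale construction and branch solving

The martingale condition `E[g^{Y_t} ∏ f_i^{X_{i,t}} | S_{t−1}] = 1` splits
into one state-independent hyperbola per street class.  Each equation
expresses `f_target` as a Möbius transform of `f_source`; composing the k
transforms around the class cycle gives a single quadratic fixed-point
equation, hence exactly two branch vectors, recovered by back-substitution
and validated against every edge equation (default tolerance 1e−10).  This
gives exact degree control without a general polynomial-system solver and
makes the two-root structure explicit.

At `g = 1` the trivial root is the all-ones vector; the nontrivial root is
the product of the quadratic's roots, which for a tripartite cycle
reproduces the compact closed forms such as
`f_a(1) = (A + Br² + Cr)/(Ar³ + Br² + Cr)`.  Branch labels (`branch1`
continued from all-ones) are tracked by nearest-neighbour matching along a
phase grid of spacing 2π/512 from θ = 0; a collision of the two roots away
from neutrality raises a diagnostic.  All downstream quantities are
symmetric under swapping the branches, so statistics are computed from the
unordered pair and labelling only matters for inspecting the branch
functions themselves.  The phase convention is real θ with `g = e^{iθ}` and
`ψ(θ) = E[e^{iθ C_T}]`, making the k-th conditional moment literally
`i^{−k} ψ^{(k)}(0)`.  Partition sizes are capped at 200 because products
`∏ f^{size}` are formed directly.

### Neutral fitness

At `r = 1` the two branches coincide at θ = 0 and the fixation-probability
formula is 0/0.  A tripartite cycle uses the exact limit
`(A·S_a + B·S_b + C·S_c)/(A² + B² + C²)`; other shapes use a two-sided
numerical limit (the mean of the values at r = 1 ± 1e−6).  The general-k
analogue `Σ size_i S_{i,0} / Σ size_i²` is verified against the exact
neutral chain in the tests but is not assumed by the implementation.  CCFs
at `r = 1` are evaluated directly at θ ≠ 0 (the branches are distinct
there) with `ψ(0) = 1` by continuity.

## Statistics

* **Moments** use second-order central differences of ψ at θ = 0 with base
  step 1e−3, at steps h and h/2, combined by Richardson extrapolation;
  orders up to 4 are exposed and an imaginary residue above 1e−4 (relative)
  raises rather than silently discarding.  The independent first-step
  analysis provides the external check at orders 1–2.
* **Distributions** invert the CCF on a uniform phase grid of size the next
  power of two above 4·n_max.  ψ is 2π-periodic because `C_T` is integer,
  so the inversion is an exact quadrature up to the (exponentially small)
  mass beyond the grid; residual mass above 1e−6 past `n_max` raises, and
  negative entries below 1e−8 in magnitude are clipped to zero.  The
  conditional distributions are heavy-tailed — for the worked [5, 3, 2]
  example `E[C_T|fix] ≈ 37.5` with standard deviation ≈ 21 — so `n_max`
  of several times the population size is typically needed.
* **Megastar aggregation**: the martingale depends on states only through
  per-class totals (the branch values are shared across identical leaves),
  so `S_0` and the boundary are aggregated per class, with boundary
  `a = [A, mB, …, mΩ]`.  The per-leaf detail matters only to the simulator
  and the chain oracle — which confirm that absorption statistics indeed
  depend only on the aggregate.
* **κ scaling**: `ψ_{T|·}(θ) ≈ ψ_{C_T|·}(κθ)` with `κ = E[T|·]/E[C_T|·]`.
  Percent differences between `E[T²|·]` and `κ²E[C_T²|·]` are computed as
  `100·|x − y|/x` with x the T-based moment (a convention, recorded here
  because alternatives exist).

## Verification layers

1. **Oracle** — exact sparse linear algebra on the absorbing chain:
   absorption probabilities, phase-type CFs and step distributions on the
   embedded jump chain (self-loops eliminated analytically per state), and
   first/second conditional moments of `C_T` and `T` by first-step
   analysis.  Systems are assembled over the states reachable from `S_0`
   (breadth-first search), solved directly up to 2000 unknowns and by
   BiCGSTAB (rtol 1e−13, residual-checked with a direct fallback) above —
   the jump chains mix fast, so Krylov iterations converge in a handful of
   steps where LU factors fill in badly.  The state-space cap is 2·10⁵.
2. **Simulator** — per-trial RNG substreams spawned deterministically from
   the batch seed; default "jump" mode draws active transitions from the
   embedded jump chain and adds geometrically distributed null-step runs to
   `T` (distributionally identical to the raw process), with a "full"
   per-step mode retained for defence in depth.

The central correctness property — martingale-derived α and CCFs agreeing
with the chain oracle to 1e−10 / 1e−8 — is exercised over random cycles
(k = 2…5) and megastars (m = 1…3) with sizes up to 6 and r ∈ [0.5, 2], in
both street directions.  Test problem sizes (state spaces up to a few
thousand, simulation batches of 10⁴–2·10⁵ trials) were chosen so the full
suite exercises every family while remaining quick to run routinely.

## What the synthetic conditions do and do not show

All inputs are small parametric graphs, not data; the "study conditions"
are the worked parameter sets ([5, 3, 2] at r ∈ {0.9, 1.5}, [5, 3, 1],
asymmetric 12-individual cycles, the three-leaf megastar at r = 1.2) plus
random families around them.  Agreement of the three routes (martingale,
chain, simulation) to stated tolerances demonstrates internal exactness of
the implementation for these families; it says nothing about graphs outside
scope (undirected or directed connections, death–birth updating) or about
the quality of `C_T` as a proxy for `T` beyond what the κ-gap quantifies.

## Known limitations

* Exact CCFs of the raw time `T` are not provided (no product martingale of
  this form exists for `T`); the κ scaling is an approximation whose error
  is largest conditional on extinction and grows as `S_0` moves away from
  the extinction boundary.
* Closed-form symbolic branch expressions for general k are not generated;
  branches are solved numerically per `g`.
* Whether branch collisions can occur at θ ≠ 0 for some non-isothermal size
  vectors is unresolved; the solver raises a diagnostic if root tracking
  becomes ambiguous rather than guessing.
* Megastar raw-time statistics depend on the slot-normalisation convention
  described above; active-step statistics do not.
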