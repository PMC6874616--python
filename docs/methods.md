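# Methods

## Model

`interflux` studies deterministic linear spreading on a *network of two
networks*: states evolve as `n(t) = M n(t-1) = M^t n(0)`, where `M` is the
transition matrix of the coupled system.  For the knowledge-spreading
demonstration `M` is simply the joint adjacency matrix: a node's knowledge
at `t` is the sum of its neighbours' knowledge at `t-1`.  Two networks A
and B, with leading eigenvalues `lam_A1 > lam_B1` of their isolated
matrices (A is the *strong* network), are joined by a small set of
*connector links* of weight `eps`; these are the only links a steering
strategy may rewire.

All long-run behaviour funnels through the Perron eigendata: `n(t)` aligns
with the leading eigenvector of the coupled matrix, and the *eigenvector
centrality* `u1` of each isolated network ranks its nodes from central (C)
to peripheral (P).  The scalar observable is the population distribution

    x(t) = (n . u_B1) / (n . u_A1),

with the isolated eigenvectors embedded (zero-padded) in the joint space:
`x = 0` means the population sits on A's equilibrium profile, `x = 1`
means it is equally split, `x -> inf` means it sits on B.

## Closed-form theory

First-order perturbation theory in the connector weight collapses the
dynamics onto four scalars.  With the *connection strength*
`eps*F`, where `F = sum over connector links of (u_A1)_i (u_B1)_j`, and
`dlam = lam_A1 - lam_B1`:

    x(t) = (K^t L + a) / (1 - K^t L a),        a = eps*F / dlam,
    K    = (lam_B1 dlam - (eps F)^2) / (lam_A1 dlam + (eps F)^2),
    L    = (x0 dlam - eps F) / (dlam + x0 eps F),

so `x` relaxes monotonically from `x0` to the equilibrium `x_eq = a` with
per-step contraction `K`; the flux `dx/dt = K^t ln(K) L (1+a^2)/(1-K^t L a)^2`
keeps one sign for all `t`.  `a` is the *normalised connection strength*,
the horizontal axis of the population flux diagram.  The formulas require
the perturbative regime `(eps F)^2 < lam_B1 dlam` (`K > 0`); outside it the
library refuses rather than extrapolates, since the derivation is
first-order.  `K^t` is evaluated for real `t >= 0` on the principal branch
even though simulation time is discrete.

### Exact vs first-order equilibria

The first-order equilibrium is the diagonal `x_eq = a`.  The exact
equilibrium (from the Perron vector of the coupled matrix) bends below the
diagonal at strong coupling; restricting the spectrum to the two leading
modes gives the closed form

    x_eq(a) = (sqrt(1/4 + a^2) - 1/2) / a,

which matches the dense eigensolver to ~5 digits on the reference fixture
up to `a ~ 0.6`.  Consequences adopted throughout:

* `equilibrium_curve` pairs exact equilibria with the analytic diagonal,
  and the *quiet* (zero-flux) line of a simulated flux grid is the exact
  curve, not the diagonal; the diagonal is exactly quiet only for the
  closed-form grid.
* "Reach-and-hold" strategies solve for the connector strength whose
  *exact* equilibrium equals the target (secant iteration seeded with the
  two-mode inverse `a = x/(1-x^2)`); holding with the first-order value
  would park the system visibly below the target at strong coupling.

### Bipartite toys

The star pairs used as closed-form oracles are exactly bipartite, so the
coupled spectrum is symmetric (`lam_min = -lam_1`) and a period-2
component of relative amplitude `O(eps^2)` never decays: `x(t)` ends in a
persistent two-cycle straddling the equilibrium.  The two-step mean
converges cleanly (to ~1e-5 relative at `eps = 0.1`), which is what the
tests assert; generic (non-bipartite) networks such as the
preferential-attachment fixtures show no floor down to solver tolerance.

## Numerics

* **Eigensolver.**  Shifted power iteration (shift `0.2 * max row sum`,
  which keeps the Perron root strictly dominant even for bipartite or
  periodic structures and makes convergence scale-invariant), tolerance
  `1e-10` on the infinity-norm residual, cap `1e5` iterations, dense
  fallback below 500 nodes.  Left eigenvectors iterate the transpose.
  Degenerate all-zero networks return `lam1 = 0` with a flagged uniform
  vector.
* **Evolution.**  Dense matrix-vector products with per-step
  renormalisation by total population (the raw model grows like
  `lam1^t`); `x` and `P_A` are invariant to the rescaling, and the
  accumulated factor is tracked in log space.  Raw-growth mode is kept for
  short runs and the spectral-expansion oracle, guarded at 1e250.
* **Numeric flux.**  Forward difference `x(t+1) - x(t)`; the closed form
  is continuous-time, and comparisons between the two absorb the
  discretisation in their stated tolerances.
* **Lookahead search.**  A single candidate link `(i, j)` is a rank-2
  update of the block-diagonal matrix, so the state after `h` steps stays
  in the span of `{M0^k n}` plus the columns `{M_A^k e_i, M_B^k e_j}`.
  Tracking the update coefficients needs only `diag(M_A^k)`,
  `colsum(M_A^k)` (and likewise for B), which evaluates `P_A` at the
  horizon for all `N_A x N_B` candidates simultaneously in
  `O(h^2 N_A N_B)` arithmetic -- the same numbers literal per-candidate
  simulation produces (equivalence is tested against an independent
  brute-force enumeration), at a cost that permits re-optimising every
  step on the 250+250 fixture.  Ties break by ascending `(i, j)`.
* **Tie-breaks.**  Centrality ties in static CC/PP selection break by
  ascending node index (star leaves, regular graphs).

## Strategies

* `select_static` -- CC/PP/CP/PC by centrality rank, `k` links paired in
  rank order, `eps` per link (default 1.0: in the knowledge model a
  connector link is an ordinary link).
* `run_heuristic_swap` -- CC while the per-step `|dx|` exceeds a threshold
  (default `1e-4`), then PP: fast approach first, optimal asymptote for
  the strong network after.
* `run_exhaustive_strategy` -- at every step (configurable cadence), pick
  the single link maximising `P_A` after `h` steps (default objective;
  minimise-`P_A` and max-|flux| variants included).  Budgets beyond one
  link are supported only as documented greedy extensions.
* `alternating_equilibrium` -- strict alternation of two configs; the
  even-step limit coincides with the half-weight union config's exact
  equilibrium up to `O(eps^2)` plus a cross term of order
  `eps (F_1 - F_2) dlam / (lam_A+lam_B)`, negligible in the near-degenerate
  regime (`dlam << lam`) the theory targets and within the tested bound
  `10 eps^2` even on the star toys where `dlam/lam ~ 0.4`.
* Rewiring is free and instantaneous; a new config takes effect at the
  start of its step.

## Directed flows (Markov chains)

A square table of directed flows `L` (e.g. inter-sector monetary flows)
becomes a column-stochastic chain `M(i, j) = L(j, i) / outflow(j)`, so
`n(t) = M n(t-1)` conserves total population (the closed-model reading in
which demand consumes its own output).  A row-stochastic variant sits
behind a flag.  For a group-vs-rest split the within-group matrices are
the internal blocks with inter-group entries zeroed, matching the
isolated-network convention; the directed normalised connection strength
is

    strength = (w_B^L  V_{A->B}  u_A1) / (lam_A1 - lam_B1),

using only the links that flow from the strong into the weak side and the
*dual-normalised* left eigenvector `w^L = u^L / (u^L . u)`.  The dual
normalisation is what makes the first-order expansion coefficient of the
stationary state equal the strength itself, so `(strength, x)` points
collapse on the diagonal within `O(strength^2)`; it reduces to the
unit-norm vector in the symmetric case and hence to the undirected
formula.  The stationary `x` projects the full chain's Perron vector on
the embedded dual left eigenvectors.  Periodic chains return their Perron
vector with a periodicity flag; reducible chains raise with the
communicating classes listed.

For yearly series the lag-1 Pearson correlation of the strength series
measures the persistence of a group's external coupling.  Note the sample
lag-1 correlation of a short AR(1) series is biased low (by about
`(1+4r)/n`); where the tests compare a recovered correlation against a
generative truth at 50 periods they average several independent series
and apply that standard (Marriott-Pope) first-order correction.

## Synthetic fixtures

* **Scale-free pair** (default study condition): two preferential-
  attachment graphs, `N = 250`, `m = 3`, grown from an `m`-clique (744
  links).  Default seeds (5, 30) give `lam_A1 = 11.053`,
  `lam_B1 = 10.982`, `dlam ~ 0.071` -- the close-eigenvalue competition
  regime in which the out-of-equilibrium transient is long and strategy
  timing matters; with well-separated eigenvalues the relaxation is
  essentially instantaneous and every strategy looks alike.  Generated
  networks emulate the heterogeneous-degree topology of real R&D and
  social networks but none of their weights, assortativity or community
  structure; passing tests show the spectral theory tracks the exact
  dynamics on such topologies, not that any particular empirical system
  behaves this way.
* **Stars, cliques, chains**: exact closed-form spectra
  (`lam1 = sqrt(k)`, `n-1`, `2 cos(pi/(n+1))`) used as oracles.
* **Two-group flow tables**: fixed dense intra-group flows; asymmetric
  inter-group blocks in which the strong group's outward leak is scaled by
  `asymmetry` (default 0.1) times a stationary log-AR(1) process, while
  the return flow is steady.  The asymmetry keeps the strong block's
  eigenvalue above the weak one's and places the tables in the
  perturbative regime; the AR(1) scale gives the strength series a known
  generative truth.

## Problem sizes and defaults

Grid defaults are 25 x 25 cells over `a` in [0, 1] (acceptance runs use
[0, 0.6], inside the epsilon cap of 1.0) and `x0` in [0, 2.5]; grid cells
are simulated independently from the two-eigenvector initial state, with
all `x0` columns for one `a` batched through one matrix.  Strategy runs
use 3000 steps on the 250+250 fixture, enough for the slowest (PP)
strategy to pass 99% of its asymptote (~1900 steps).  The monotonicity
scan uses 100 random 25+25-node pairs with random single links,
`eps ~ U(0.01, 0.3)` and `x0 ~ U(0, 3)`.

## Known limitations

* First-order theory only; no explicit `O(eps^2)` correction terms are
  computed (their scaling, not their value, is tested).
* Two networks only; multi-network partitions are out of scope.
* Dense linear algebra throughout: comfortable to ~2000 nodes, not tuned
  for large sparse systems.
* The exhaustive strategy searches single links; multi-link budgets are
  greedy, not exhaustive.
* Strategy timing claims are fixture-dependent: the CC->PP speedup factor
  over pure PP depends on the peripheral centrality product of the
  particular graphs (see `heuristic_speedup_ratio` in the acceptance
  output).
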