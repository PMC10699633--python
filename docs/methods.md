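# Methods

`mammosim` simulates the growth and epigenetic evolution of an avascular
breast tumor as a multiscale hybrid model: a cellular automaton for the
cells, quasi-static reaction-diffusion fields for the microenvironment,
a stochastic birth process for mutations, and a ten-gene regulatory
network (GRN) whose attractors define cell phenotypes.  This note
records the model as implemented, the numerical choices, and the places
where the design was genuinely open.

## Tissue and transport

Cells occupy a 2D square or 3D cubic lattice of edge `L`.  Each site
carries a normal-cell indicator `sigma_n`, a necrotic indicator
`sigma_d`, and a piled cancer-cell count `sigma_c` (normal and cancer
occupancy are mutually exclusive).  Glucose (C1), oxygen (C2) and
estrogen (C3) are dimensionless fields normalized to the capillary
value 1 and obey

    dC_l/dt = lap(C_l) - alpha_l^2 [sigma_n + lambda_l sigma_c] C_l ,

with a Dirichlet capillary face (C_l = 1 on the maximal last-axis
index) and zero-flux mirror conditions on the other faces.  Because
nutrient diffusion is much faster than the cellular dynamics, only the
stationary solution is used: once per automaton cycle the fields are
relaxed — first locally on 20-site blocks that contain cancer cells
(visited in random order, block-boundary values frozen, damped Jacobi),
then globally by a direct sparse solve of the 5/7-point discretization
(unit spacing, max-residual tolerance 1e-5).  The local pass mirrors the
published homogenization procedure; the global steady state is unique,
so the local pass serves as a pre-smoother rather than changing the
converged field.

The capillary face itself is treated as vessel wall: daughter cells
cannot colonize the Dirichlet row.  Consumption rates default to the
phenotype-map conditions `alpha_l = 8e-3`, `lambda = (100, 50, 200)`
(glucose, oxygen, estrogen).  At the full scale `L = 500` these equal
the published `4/L` scaling; the desk-scale preset (`L = 100`) keeps
the literal rates so that the nutrient boundary layers retain their
physical widths (an estrogen e-folding depth of ~9 sites through
single-occupancy tumor tissue) and the simulated window behaves like a
crop of the full system.

## Cell cycle and division

Each cancer cell carries a cyclin-E/cyclin-B phase oscillator

    du/dt = u (1 - v),    dv/dt = eps v (u - 1),

whose local rate parameter couples the cycle pace to estrogen:
`eps = (alpha_3^2 [sigma_n + lambda_3 sigma_c] C3)^2`.  A completed
oscillation (phase return to the starting Poincare section) is one
biological cell cycle and triggers a division; the automaton clock then
resets to zero, so a cell divides at most once per sweep.  The
published period expression `2 pi / eps` is dimensionally inconsistent
with `eps` being a squared rate; linearization about the (1,1)
equilibrium gives `2 pi / sqrt(eps)`, and the implementation uses the
*measured* phase-return period of the actual orbit (initial phase
(1.2, 1.0), a modest-amplitude orbit; configurable), interpolated from
a log-log table accurate to <0.5%.

One automaton cycle is anchored to the seed cell: it lasts
1/2.8 of the seed's division period under its initial local estrogen
level, mirroring the ~35 h biological cancer-cell cycle against the
~12-15 h automaton cycle reported for the full-scale runs.  Daughters
are placed uniformly at random on the 4 (2D) / 6 (3D) nearest
neighbors: a normal occupant is replaced, cancer occupants pile up, and
a necrotic site blocks the division (necrotic debris is a permanent
obstacle by default; both behaviors are configurable).  Normal cells do
not divide (the model computes their cycle pace but never describes
normal proliferation; configurable).

Deaths follow the hypoxia law `P_d = exp[-(C2/(theta_d sigma_c))^2]`
with one uniform draw per cancer cell per cycle (binomial per pile,
most-recently-added cell dies first).  Per-cell draws are essential:
births scale with the pile size, so a per-site death draw cannot
balance the division flux and crowded near-capillary bands grow without
bound.  A death decrements the pile and marks the site necrotic.

## Mutations

Spontaneous mutations follow a Yule-Furry pure-birth process whose
count distribution from one founder is geometric with the
glucose-coupled parameter `p = exp[-(C1/theta_div)^2]`.  Combined with
estrogen-receptor failure (probability `P(B)`) mediated by the local
lineage segregation index, the per-cell acceptance probability is

    Prm = p + beta_hat (1 - p) P(B).

Once per cycle every cancer cell is visited in random order and a
uniform draw `r` is compared against Prm; by default a mutation event
fires when `r > Prm`, the inequality as published.  The alternative
`r < Prm` convention is available in the configuration, but it makes
mutations concentrate where glucose is depleted (the tumor interior,
where `p -> 1`), inverting the published spatial result that mutation
maxima sit on the tumor surface; the as-published inequality produces
rim-concentrated mutations self-consistently.  A fired event performs
one tau-leap: an exponential leap interval `tau = ln(1/r)/a0` (all ten
gene propensities equal 1, `a0 = 10`), a gene index drawn from a
negative-binomial stream (geometric failures modulo the gene count;
parameterization not published, uniform selection available), and an
increment `k * z` with `k ~ Poisson(poisson_mean * tau)` and
`z ~ Geometric(p)`, capped at one new mutation per gene per leap.  The
Poisson mean is not among the published values; the default is 1.

## Lineage segregation and plasticity

The segregation index of a tumor cell averages, over all living cells
within Euclidean distance `R_o = 20`, a genetic activity term (0 for an
identical genotype, 1 otherwise) weighted by Michaelis-Menten estrogen
saturation at the neighbor site, `C3/(C3 + kappa_eps)`.  Normal cells
participate as neighbors carrying the unmutated genotype; necrotic
cells are excluded; an isolated cell scores 0.  For map output the
index is aggregated on the same 20-site blocks used by homogenization,
averaging over the tumor cells in each block (blocks without tumor
cells carry no lineage signal and map to 0).

Plasticity erodes the per-gene activation-inhibition thresholds once
per cycle:

    eta_i <- max(0, eta_i - s (xi eta0_i + beta_hat chi)) ,

with intrinsic susceptibility `xi` and extrinsic (quorum-sensing)
susceptibility `chi`.  The published relation fixes the displacement,
not a schedule; the step scale defaults to
`s = eta0/(xi eta0 + chi) / max_cycles`, i.e. sustained maximal
pressure (`beta_hat = 1`) erodes a threshold from `eta0` to 0 over one
full cycle budget.  Thresholds are clamped at zero and daughters
inherit their parent's current thresholds.

## Gene regulatory network

Each gene's expression fraction obeys

    dx_i/dt = ag_i (y_i/eta_i - 1)(1 - x_i) + R(x_i) Ht(x_i)
              + sum_j s_ij x_i H(x_j) - mu_i x_i ,

with microenvironmental input `y_i` (normalized oxygen directly for
TP53, ATR, MDM2, CDK2; Michaelis-Menten estrogen saturation for the
others), saturating self-feedback `R` (positive branch
`lg x/(d + x)`, negative branch `lg d/(d + x)`; the published form is
typographically collapsed and this is the standard saturating pair
consistent with the listed parameters), and Hill interactions
`H = beta (nu x)^gamma / (1/2 + (nu x)^gamma)` with signs on the
regulatory edges.  The drive factor is capped at +-1e3 so the system
stays finite when plasticity has driven a threshold to its clamp at
zero.  Integration is clipped fixed-step RK4 (dt = 0.05-0.1, states
confined to [0,1]); a state is converged when the free-coordinate rate
falls below tolerance.

The topology and per-gene parameters are data
(`mammosim/data/grn_default.yaml`), a documented reconstruction: the
exact published wiring diagram and per-edge parameter assignments are
not machine-readable, so the default encodes the stated constraints (the
ATR/ATM/CHEK1/CDK2 kinase cluster acting on the cell cycle,
estrogen-responsive BRCA1/HER2, oxygen-associated TP53/AKT1/MDM2/P21,
the MDM2-TP53, ATR-TP53, TP53-P21 and HER2-TP53 couplings) plus
standard repressions (TP53 on HER2/CDK2, BRCA1 on HER2/AKT1, CHEK1 on
CDK2/P21, ATM on MDM2), with every kinetic value drawn from the
published value sets and Hill exponents tied to the number of
regulators.  The five proliferative genes (HER2, AKT1, MDM2, CDK2,
P21) behave as positive-feedback switches; the five suppressors are
expressed in a low-concentration window.  The reconstruction was
calibrated once against the published qualitative patterns: expression
onsets of the switch genes at 30% normalized concentration for initial
thresholds 0.25, full expression only beyond 0.5 for thresholds 0.5,
and a Boolean attractor landscape whose 2^10 states partition into
basins of exactly one cancer attractor (HER2, AKT1, MDM2, CDK2, P21
over-expressed), the two normal patterns (all-off, and
TP53/ATM/CHEK1), and precancer attractors.

Phenotype labels: at birth and at each completed cell cycle, a cell's
GRN is settled from the resting state under its local inputs and
thresholds, binarized at 0.5, and classified — cancer if HER2, AKT1,
P21 and CDK2 are all expressed; normal for the all-off or
TP53/ATM/CHEK1 patterns; precancer otherwise.  Settling from rest makes
the label a function of the current microenvironment and thresholds
(no expression hysteresis across generations); since thresholds erode
uniformly across genes, label inputs reduce to (C2, C3, eta) and the
settled states are memoized on a 0.02-quantized grid — fine-grained
relative to the 0.5 binarization.

Note one structural property of the kinetics: at zero input the
suppressor genes are *expressed* (their drive is positive below
threshold), so the resting attractor of an unstimulated cell is the
damage-surveillance pattern, not the all-off state; the all-off state
persists exactly at threshold input, where the drive vanishes.

## Observables

Per cycle the simulation records population counts by phenotype,
necrotic count, mean segregation index, mean threshold, mean per-cell
total mutation count, the Shannon index
`H = -sum_i P_i ln P_i` over the per-cell total-mutation-count
distribution, and a box-counting fractal dimension of the cancer
occupancy mask (dyadic boxes 2-32, least-squares slope).  Mutation maps
report the maximum count over a site's pile.  Realization averaging
aligns runs to the shortest trajectory and takes per-cycle means.

## Determinism and problem sizes

One master seed spawns independent named streams (initialization,
placement, death, mutation, tau-leaping, homogenization order), so a
seed reproduces a run bit-for-bit and subsystems are reproducible in
isolation; snapshots (HDF5) carry the stream states, and resuming a
snapshot reproduces the subsequent trajectory.

The shipped desk-scale scenario runs a 100x100 lattice to the border
(tumor bounding box spanning 0.9 L, reached after roughly 250-300
cycles, a few minutes on one core).  The full-scale scenario
(`segmap2d_full`, 500x500) reproduces the published geometry and stopping
behavior (~800 cycles to a 450-site span) and takes hours; it is
shipped as a preset rather than exercised by the test suite.  The
miniature plasticity scan uses 60-site lattices and 90-cycle budgets.

## Known limitations

- The GRN wiring is a reconstruction; quantitative attractor basin
  sizes and the identities of the intermediate (precancer) attractors
  beyond the published anchors depend on it.
- Desk-scale segregation maps are ceiling-limited: with `R_o = 20` the
  segregation neighborhood of a capillary-adjacent cell spans the entire
  estrogen boundary layer, so even complete lineage distinctness yields
  block values near 0.5 rather than the published >0.8 (see the
  acceptance notes).
- No vascularization, metastasis, cell migration beyond daughter
  placement, or DNA-sequence-level mutation model.
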