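# Methods

## Flux estimation

Fluxes are computed by lexicographic parsimonious FBA.  Stage 1 minimises the
substrate uptake magnitude subject to S·v = 0, reaction bounds, and demand
reactions pinned to their fluxes J_γ (irreversible sinks with lb = ub = J_γ ≥
0, in the BiGG sign convention: exchange flux negative = uptake).  Stage 2
pins the uptake at the stage-1 optimum and minimises Σᵢ vᵢ² over **all**
reactions, which makes the optimum unique — the precondition for the response
analysis, since derivatives of a non-unique optimum are undefined.

Stage 1 is an LP solved with HiGHS (scipy.optimize.linprog).  Stage 2 is a
strictly convex box-constrained QP solved by an in-house primal active-set
method (`fdm.qp`): every working-set subproblem is a minimum-norm linear
solve (`lstsq`), so solutions are accurate to machine precision and fully
deterministic (ties broken by lowest variable index).  A first-order QP
solver with ~1e-5 residuals would corrupt finite differences taken at a 1e-6
perturbation; exactness here is what makes the 1e-6 oracle-agreement
tolerance achievable.  Because the QP is solved directly, the stage-1 uptake
is pinned *exactly* at the LP vertex value rather than within a relative
band; a relaxation band (useful for barrier solvers) makes the active-set
subproblem inconsistent on degenerate networks.

## Demand-flux response and decomposition

For each demand γ the response ξ^(γ) = ∂v/∂J_γ is measured by central
differences with relative step δ = 1e-6 (absolute floor 1e-6 mmol/gDW/h for
zero demands), re-running both pFBA stages at J_γ ± δ — the substrate is a
dependent variable and must respond.  One-sided differences are used when the
backward point would be negative or infeasible.  Components v^(γ) = ξ^(γ)·J_γ
must reconstruct v to 1e-6·max(1, ‖v‖∞); a larger residual means the optimum
changed active set under the perturbation and is raised as an error, never
silently accepted.  Because all fixture networks carry no finite capacity
bounds other than the demands, v(J) is positively homogeneous and the
reconstruction identity is exact up to finite-difference noise (~1e-9
observed).

## Coupling

Coupling re-expresses the components through a linear recombination whose
weights, per original function, sum to exactly 1 across groups — the
conservation identity Σ_γ v^(γ) is then preserved arithmetically.  Weights
may be signed: transferring a biosynthesis component's ride on the
fermentation route *out* of its mode requires a negative energy weight
(equivalently the energy mode receives weight > 1), and this is exactly what
makes biosynthesis a net ATP consumer in anaerobic conditions while remaining
a net producer aerobically.

The canonical coupling of a partner function γ to the energy function E uses
the transfer weight

    α_γ = − min over r in support(v^(E)) of  v_r^(γ) / v_r^(E),

with demand sinks excluded from the support.  The coupled mode
m_γ = v^(γ) + α_γ v^(E) is sign-consistent with the energy component over its
support and has zero flux through the binding reaction.  On the packaged
overflow motif this reproduces the stoichiometric yield of the excretion
route exactly (α = 0.15 gives the fermentation mode 6 ATP per acetate — its
substrate-level plus respiratory NADH yield), so the weights are derived, not
fitted.

The automatic coupling search greedily merges the pair of candidate functions
that most reduces the flux-weighted mixed total Σᵢ |vᵢ|·Fᵢ^mix, with one
admissibility condition: a merge is accepted only if the merged component is
sign-consistent with the net flux on every reaction.  Without it the search
degenerates (any merge shrinks Σ|v^(γ)| by the triangle inequality, so
everything would collapse into one function); with it, genuinely irremovable
cofactor-balancing mismatches — the NADPH-supplying pathway of the
`cofactor_mix` motif — are left alone, which is the scientifically meaningful
outcome.  Ties break lexicographically; the search is randomless.

## Shares, modules, costs

The mixed fraction follows its defining formula; reactions with
Σ|v^(γ)| = 0 get F^mix = 0.  The remainder 1 − F^mix is distributed over
functions whose component sign matches sign(vᵢ), proportional to |vᵢ^(γ)|;
this reduces to F^(γ) = v^(γ)/v exactly when nothing cancels and is
continuous as mismatches vanish.  The activity threshold (1e-4 mmol/gDW/h)
applies to reporting, clustering and gene mapping, never to the decomposition
arithmetic.  Functional modules come from average-linkage agglomerative
clustering of share profiles under the cityblock metric (scipy), with the
dendrogram exportable as Newick.

A component's net ATP is its flux through the maintenance hydrolysis
reaction — components are mass-balanced, so all internally produced/consumed
ATP nets out there, and Σ_γ equals J_ATPM by construction.  GTP/CTP/UTP
turnover inside a component is not converted to ATP equivalents; the network
itself performs any conversion.  Carbon costs divide the component's
substrate uptake (× substrate carbon count) by the demand flux; pathway-only
costs recompute the ATP balance from the component restricted to non-central
reactions (the maintenance reaction always excluded, so an empty central set
reproduces the full-network cost).  Costs are per molecule and demand-scaling
invariant; per-gDW variants multiply by J_γ/μ.

## Proteome projection and sectors

A gene's share vector is the |flux|-weighted average of its active reactions'
share vectors (promiscuous enzymes weighted by how much flux each reaction
carries); protein *mass* comes solely from the abundance table, so no
flux-splitting rule among isozymes or complex subunits is needed.  Genes
absent from the model, or whose reactions all sit below the activity
threshold, are categorized by the iterative GO procedure: repeatedly assign
all unassigned genes of the GO term carrying the largest summed mass
fraction, until the best remaining term is below 0.1% of proteome; ties break
on the term id.

The five-sector allocation model closes growth through the proteome budget:
foraging = φ_fo,0 + μ/ν_C, translation = φ_tr,0 + μ/ν_R, biomass = φ_bm,0 +
b·μ, housekeeping constant, energy per the allocation law φ_E = φ_E,0 +
κ_C μ/ν_C + κ_R μ/ν_R, and the five sectors plus a constant unmodelled
remainder sum to one, which yields μ(ν_C, ν_R) in closed form.  The fit
minimises χ² = Σ(Δφ)² + c Σ(Δμ)² with c = 0.1 h² (so growth-rate residuals
weigh like a ~0.02/h measurement uncertainty) over the global parameters and
the limitation variables.  Per-condition (ν_C, ν_R) pairs left fully free
create a gauge freedom (a uniform shift of μ/ν_C trades exactly against the
foraging and energy offsets), so the fit ties them to the experimental
design: carbon-limited conditions share the reference ν_R and vary ν_C,
translation-limited conditions the converse, with the reference condition at
(ν_C,0, ν_R,0).  Optimisation is bounded least squares from 16 deterministic
starts scaled off the data; best χ² wins, ties by start index.  Standard
errors come from the Gauss–Newton covariance at the optimum.

The overflow prediction splits φ_E so that ε_res φ_r + ε_fer φ_f meets the
maintenance demand σ₀ + σμ with φ_r + φ_f = φ_E, clipped at φ_f = 0
(respiration covers the demand alone — the carbon-limited regime) and flagged
infeasible when even pure fermentation falls short.  Acetate flux converts
the fermentation ATP flux through the ATP-per-acetate yield of the
fermentation flux mode (6 on the packaged motif), not a hard-coded constant.
Efficiencies are expressed per *percent* of proteome.

## Synthetic data and toy networks

The six packaged motifs (`linear_chain`, `parallel_paths`, `branch`,
`overflow`, `cofactor_mix`, `anaerobic_mix`) are built so the parsimonious
optimum is unique and the response matrix has a closed form: outside the
parallel-paths motif the active reactions form a square linear system, so the
analytic ξ is a direct solve — an oracle independent of the LP/QP/finite
difference path it checks.  Stoichiometries use canonical lumped yields
(24 ATP per fully respired 6-carbon substrate with the proton-pumping NADH
dehydrogenase, 6 ATP per excreted acetate, mixed-acid fermentation with a
succinate branch anaerobically); currency metabolites carry no elemental
formula and are skipped by the element-balance checker.

Synthetic condition series use μ grids of 0.4–1.1/h with maintenance truth
(σ₀, σ) = (3 mmol/gDW/h, 5 mmol/gDW), 2% multiplicative Gaussian noise on
uptakes; efficiency series use the fitted-literature-scale truths ε_res =
5.33 and ε_fer = 9.62 mmol/gDW/h per % proteome with 3–5% noise; sector
series use ν grids of 1.5–6/h giving growth rates of roughly 0.1–0.7/h and
fraction noise of 0.005 with 0.02/h on μ.  All generators are seeded and
bit-reproducible.  These series emulate steady-state chemostat/batch
titration designs with independent Gaussian errors; they do not emulate
correlated measurement error, growth-rate-dependent biomass composition
drift, missing proteins, or model–organism mismatch — passing tests
demonstrate the estimators and identities, not the fidelity of any particular
genome-scale model to data.

## Numerical choices and limitations

Solver tolerances: LP/QP feasibility and stationarity 1e-10..1e-9;
reconstruction tolerance 1e-6 relative; share normalisation 1e-9.  The
maintenance fit seeds a bounded Gauss–Newton refinement from the best four
points of a deterministic coarse grid because the squared-residual surface of
an LP value function is piecewise quadratic and can hold boundary-local
minima.  Problem sizes throughout (≤ 13 reactions, ≤ 11 conditions, 16 fit
starts) keep the full test suite and the acceptance script in the
tens-of-seconds range on one CPU; the same code paths accept genome-scale
SBML/JSON models through `fdm.network_io`, where a full response matrix costs
two pFBA solves per demand.  Known limitations: no loopless/thermodynamic
FBA, no elementary-mode enumeration, finite-difference (not analytic) QP
sensitivities, and the sector closure is one standard allocation form —
exposed as the packaged default rather than a claim of uniqueness.
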