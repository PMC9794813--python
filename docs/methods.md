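# Methods

## Model formulation

An ME model here is a reaction network over species of several kinds —
metabolites, mRNAs, tRNAs (uncharged and charged), proteins (cytosolic,
membrane, extracellular), complexes, and biomass constraint
components — whose stoichiometric coefficients are affine functions of
the growth rate, `a + b·μ`. The constant, linear and ratio forms of the
usual coupling conventions all reduce to this representation
(`MuCoefficient`), so substituting a numeric μ turns the model into an
ordinary linear program `S(μ)·v = 0`, `lb(μ) ≤ v ≤ ub(μ)`.

Reactions and their coefficients:

- **Metabolic core.** Taken verbatim from the organism spec; reversible
  reactions are split into `_FWD`/`_REV` members with bounds `[0, ub]`,
  so all internal fluxes are non-negative. Each enzyme assignment
  installs consumption of the catalyzing complex at `μ/k_eff` per unit
  flux; when several isozymes are assigned, the reaction is replicated
  per isozyme so the LP chooses among them.
- **Transcription.** One reaction per transcription unit: NTPs in the
  exact counts of the unit sequence, RNA polymerase at `μ·L_nt/k_txn`,
  one transcript per member gene. Stable RNA (tRNA, rRNA) credits the
  RNA biomass component by its length.
- **mRNA degradation.** A demand reaction per mRNA returns its NMP
  monomers and consumes degradosome capacity at `μ·L_nt/k_deg_cap`.
  Translation consumes mRNA at `(μ + k_deg)/κ` per event, which is why
  transcription must keep running even at fixed protein levels.
- **Translation.** Charged tRNAs per codon (uncharged returned), ATP
  per residue, ribosome at `μ·L/k_ribo`, the mRNA coupling above; the
  product protein plus a protein-biomass credit proportional to its
  residue count. Start-methionine excision removes the Met from the
  product and returns it to the free pool.
- **tRNA charging.** Amino acid + uncharged tRNA + ATP → charged tRNA,
  with synthetase coupling `μ/k_eff` and a tRNA-dilution surcharge
  `μ/k_dil` that forces ongoing tRNA transcription.
- **Complex formation and translocation.** Complexes assemble from
  processed proteins (membrane/extracellular proteins must first pass a
  translocase-coupled, ATP-costing translocation step) plus
  modification cofactors. Complexes whose subunits are extracellular
  get a free accumulation demand: in batch culture, secreted enzyme
  washes out rather than being recycled, so secretion may run above the
  catalytic requirement — without this outlet, forcing secretion beyond
  `μ/k_eff·v_catalysis` would be structurally infeasible.
- **Biomass.** A dilution reaction with both bounds pinned to μ
  consumes the composition (protein and RNA constraint components plus
  a precursor term) and growth-associated ATP. Macromolecule credits
  must therefore be produced at rate μ; an unmodeled-protein "slack"
  gene provides the protein sink that absorbs the quota not filled by
  enzymes, and a surplus demand absorbs stable-RNA credits beyond the
  quota (forced tRNA turnover can overshoot it).

## Solving

At fixed μ the model is solved as an LP feasibility problem with HiGHS
(double precision, primal/dual feasibility 1e-9); reported solutions
additionally minimize total flux, which makes flux vectors
deterministic and loop-free, and their steady-state residual is checked
explicitly (‖S·v‖∞ ≤ 1e-7). Growth maximization bisects on μ over a
default bracket [0, 2] h⁻¹ to a tolerance of 1e-6 h⁻¹; feasibility is
empirically monotone in μ (asserted in the test suite), which justifies
the search. An independent oracle (`grid_search_growth`) scans
successively finer uniform grids — no bisection logic — and the two
agree within twice the tolerance on every fixture.

Knockouts close a gene's translation reaction. At double precision the
chained couplings that make a missing protein lethal (`μ/k_eff` terms
of order 1e-9) can fall below LP tolerance, which is why full-scale ME
solvers resort to quad precision. We instead propagate the exact
structural consequences: a species with no remaining producer closes
every direction that consumes it, iterated to a fixed point. This is
what exact arithmetic would enforce, costs nothing, and keeps
machinery-loss phenotypes visible; `propagate=False` restores the
literal translation-only convention. The essentiality screen calls a
gene essential when no growth at 10× the bisection tolerance is
feasible, which needs one LP per gene.

## The mini-cell organism

The synthetic-data generator emits a complete organism description —
34 genes (28 protein-coding, 1 rRNA, 5 tRNA), 40 core reactions, 5
explicitly modeled amino acids (M, A, G, W, C; the remainder of the
proteome is represented by those five) — wired so that every analysis
has known ground truth:

- **Single-path core.** Glucose enters through one transporter; a
  glycolysis analog makes precursor; respiration (one gene) makes ATP;
  one synthesis gene per amino acid; a chorismate branch feeds both
  tryptophan and a folate cofactor required by the glycolysis complex.
- **Expression machinery.** RNA polymerase (homodimer), ribosome (two
  protein subunits + rRNA cofactor), one shared tRNA synthetase, an RNA
  degradosome, and a translocase. The carbon transporter is
  co-transcribed with a never-translated regulatory gene, so its mRNA
  share must be degraded — making the degradosome constructively
  essential.
- **Stress motifs.** Ethanol diffuses in and is degraded to acetate,
  whose exporter is tryptophan-rich (planted 12 W), so detoxification
  demands tryptophan. Sodium is injected directly into the cytosol (the
  uncoupled-uptake convention) and must be pumped out at an ATP cost.
- **Secretion motif.** A reporter enzyme with a declared composition
  (M1 A8 G4 W2, zero cysteine) is secreted through the translocase and
  hydrolyzes extracellular starch back to glucose. The biomass slack
  protein is cysteine-rich, so forcing secretion at fixed μ displaces
  slack mass and *lowers* cysteine synthesis — the planted negative
  sensitivity. Expected sensitivities
  `c_reporter(aa) − (w_rep/w_slack)·c_slack(aa)` are recorded in the
  spec.
- **Diagnostics.** An ATP-fabricating futile cycle with deliberately
  sluggish enzymes (k_eff 50 h⁻¹): thermodynamically impossible, so in
  the expression-coupled model the enzyme cost exceeds the ATP gained
  and the loop is suppressed, while the decoupled (M-like) variant
  exploits it freely. A redundant isozyme pair on NTP synthesis is
  singly dispensable and jointly lethal.

The recorded essential set contains the single-path transport and
biosynthesis genes, the translocase, and all machinery subunits (15
genes). Two classes are deliberately excluded: ATP-only genes, because
the futile cycle can fabricate ATP at low growth and rescues them, and
the slack gene itself, because the protein quota can be filled by
overexpressing any enzyme with a flux outlet.

Default rates (all configurable): k_eff 234000 h⁻¹ primary / 3600 h⁻¹
secondary tier; transcription 198000 nt·h⁻¹, translation 43200
residues·h⁻¹ per machine; mRNA degradation 8 h⁻¹ (≈5 min half-life);
mRNA capacity κ = 1000 translations·h⁻¹; 4 ATP per translated residue,
2 per charging, 0.1 per translocated residue; growth-associated ATP 20
mmol·gDW⁻¹; biomass 5 mmol residues + 0.3 mmol stable-RNA nt + 2 mmol
precursor per gDW. Glucose uptake 5, starch 2 mmol·gDW⁻¹·h⁻¹. These
give a wild-type μ* ≈ 1.42 h⁻¹ and let every pipeline stage run in
seconds. The motif inventory needs 28 protein genes; a leaner organism
could not host all the analyses at once.

What the generator does **not** emulate: real genome structure or codon
bias (uniform codon usage by default), regulatory logic (all responses
are resource-allocation effects), thermodynamics, metal/vitamin
cofactor diversity, protein folding and degradation, and realistic
k_eff heterogeneity. Passing tests therefore demonstrate that the
*machinery* — coupling algebra, bisection, screens, conventions,
estimators — is correct on a network with the right mathematical shape,
not that any biological prediction is accurate.

## Analyses

- **Stress.** `simulate_uncoupled_uptake` pins a stressor exchange to
  its rate and re-maximizes growth; sweeps record per-gene transcription
  and translation fluxes, normalized per gene by the maximum across the
  sweep (all-zero series stay zero). Folate damage adds a fixed-rate
  folate drain. Amino-acid demand attribution divides each protein's
  `Δ(translation flux) × (net amino-acid count)` by the total synthesis
  change; because charging/translation are the only sinks, fractions
  sum to one exactly. Differential-expression calls use a relative
  change threshold of 5% (configurable; no principled value exists at
  desk scale) on translation fluxes, and accuracy is scored over
  reference-changed genes, overall, per direction, and per subsystem.
- **Kinetics.** Natural-log linearization of dX/dt = μX (μ in h⁻¹
  requires base e), trapezoid quadrature for ∫X dt on the reported
  grid, activity→concentration through a specific-activity interval
  evaluated at both endpoints, molar units via the molecular weight of
  the mature (post-excision) sequence.
- **Sampling.** Near-optimal sampling draws μ uniformly in
  `[frac, 1]·μ_opt` and uptake-exchange capacities uniformly within the
  hull spanned by the optimal and `frac`-growth solutions (export
  capacities stay free — capping a by-product outlet below its forced
  rate would only produce spurious infeasibility); infeasible draws are
  re-drawn within a retry budget. Overexpression sampling fixes μ and
  forces the secretion flux to uniform draws in a given range. All
  draws come from a seeded generator; identical seeds reproduce sample
  sets exactly.
- **PCA.** Constant-flux reactions dropped, z-scoring, then
  scikit-learn PCA; subsystem loadings are means of absolute loadings.
- **Sensitivity.** One pass of mean ± 1.96·SD trimming per condition
  (a concrete reading of "outliers removed with 95% confidence",
  applied per-reaction marginal), then Welch's two-sided t test and the
  mean-difference ratio. Composition-vs-sensitivity regression flags
  outliers by leave-one-out 95% prediction intervals — a plain
  single-fit interval almost never flags points at n ≤ 10 because the
  outlier inflates its own interval.

## Numerical choices and degenerate inputs

Bisection bracket [0, 2] h⁻¹ and tolerance 1e-6 h⁻¹ are package
defaults (no canonical values exist). The zero-growth threshold is 10×
the tolerance. HiGHS occasionally returns an undecided status on
near-degenerate problems when presolve meets 1e-9 tolerances; such LPs
are re-solved without presolve, and LPs with conflicting bounds (a
structurally closed but growth-forced reaction) are reported infeasible
without a solver call. Division-by-zero cases are surfaced, not hidden:
undefined scores are `None`, zero-change attribution is flagged
undefined, all-zero normalization series map to zero.

## Limitations

Sequence-level detail (initiation/termination subreactions, rRNA
modification, folding chaperones, rho-dependent termination) is out of
scope; post-translational modification is represented only as cofactor
consumption at complex formation. The LP at fixed μ is a feasibility
problem, so flux vectors are unique only up to the minimum-total-flux
tie-break. Secreted-protein mass is credited to the biomass protein
component at translation (the accounting that creates proteome
competition); a model that tracked secreted mass separately would need
an explicit proteome-capacity constraint instead. The structural
knockout propagation assumes each complex's formation reaction is its
only source, which holds for models built by this package.
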