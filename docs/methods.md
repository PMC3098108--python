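# Methods

## Scope and model

`thermoscore` predicts *relative* thermostability of homologous protein
sequences from sequence-derived features; it does not predict melting
temperatures or absolute stability. The underlying assumption is the one
that motivates comparative HP/MP studies: orthologs from hyperthermophilic
and mesophilic organisms are, in effect, mutants of one another with many
substitutions, and the compositional signature that separates them also
separates stabilized mutants from their wild types.

The score of an ordered pair is S(seq1, seq2) = Σ wᵢ·Δxᵢ with the
symmetric mean-normalized relative difference
Δx = (x₁ − x₂) / ((x₁ + x₂)/2) and the 0/0 → 0 convention. This form was
chosen over asymmetric alternatives (denominator x₂ or max(x₁, x₂))
because it is antisymmetric — S(a,b) = −S(b,a) holds exactly, which the
pairwise-ranking semantics require — and scale-free; the choice is
confined to `scoring.relative_delta`. Orientation convention: positive
score ⇒ first argument predicted more thermostable; training pairs are
stored (stable, other), so correctly oriented pairs score positive.

## Features

All 72 non-predicted features are computed by `features.extract_features`:
length; per-residue counts and compositions; positive/negative/total
charge counts, fractions, and net charge (per length); count/fraction of
the small {T,D}, tiny {G,A,S,P}, aromatic {F,H,Y,W}, aliphatic {A,V,I,L},
hydrophobic {A,C,F,I,L,M,V} and polar classes; side-chain hydrogen-bond
capacity; sulfur atoms (C + M); mean aqueous solubility; mean maximum ASA;
pI and mean free-residue pI; instability index and class; aliphatic index;
GRAVY. The small/tiny/aromatic sets follow the convention of the feature
table this model was built on (note that "small = {T,D}" is narrower than
most textbook definitions); all class sets and property tables are
overridable through `ResidueClassConfig`, including counting His as
positive (excluded by default at neutral pH).

Compositional denominators use L_std, the count of standard residues;
ambiguity codes (B,J,X,Z,U,O) are tolerated on input but excluded from
numerators and denominators, since they carry no class membership. The
`L` feature reports full chain length.

Property tables (in `tables.py`, with citations): Kyte–Doolittle
hydropathy and the Guruprasad dipeptide instability weights are taken from
Biopython's published data module; maximum ASA is the Tien et al. (2013)
theoretical Gly-X-Gly set; free amino-acid aqueous solubilities are
CRC-style handbook values at 25 °C (lysine, listed in compilations only as
freely soluble, is set to a nominal 100 g/100 g — it enters no shipped
model feature weight directly and only shifts the `avg_solubility`
feature's scale); pK values are the ProtParam-lineage (Bjellqvist) set
with generic termini; free-residue pI values are the standard Lehninger
compilation. Predicted features (secondary structure, exposure, disorder)
are out of scope: they need external predictors, and none enters the
shipped scoring model.

Numerical details: pI is solved by bisection of the Henderson–Hasselbalch
net charge on [0, 14] to a 1e-4 pH bracket (well under the 0.01-pH
contract, so the net charge at the returned pI is itself ≈ 0); the
instability class boundary is II = 40 with "stable" strictly below;
instability for sequences containing ambiguity codes skips affected
dipeptides but keeps the full-length divisor.

## Training pipeline

*Sign determination.* The cumulative distribution of Δx(stable, other)
over training pairs is sigmoid; its half-height (inflexion) point is the
empirical median. Median > 0 fixes sign +1, median < 0 fixes −1. An exact
zero median leaves no defensible sign; such a feature is excluded with a
warning rather than guessed.

*Hill climbing.* Magnitudes start uniform in [0,1]. Each iteration
redraws one uniformly chosen feature's magnitude uniformly in [0,1] and
accepts iff the count of pairs with strictly positive score strictly
increases. Strict improvement and the one-feature redraw kernel are the
simplest members of their families; both live behind the
`hill_climb_fit` interface. Exact-zero scores count as incorrect, which
makes the objective conservative. Library default is 1e5 iterations — on
the synthetic objective the accepted-step curve plateaus within a few
thousand steps, and the budget is a parameter for anyone wanting more.

*Cross-validation.* Seeded k-fold (default 5) partition; per fold, signs
and 5 hill-climb restarts on the training portion, restart weights
averaged per fold, held-out pairwise accuracy recorded; the final model is
the element-wise fold mean, with a hard error if folds disagree on any
sign. Restart averaging (rather than best-of) follows the original
procedure's observation that independent restarts land close together.

## Feature ranking

`importance.rank_features` encodes each pair as two instances — the delta
vector Δx(stable, other) labeled positive and its negation labeled
negative — so class priors are exactly 0.5 and the task is identical to
the orientation problem the linear score solves. The ensemble is
scikit-learn's `RandomForestClassifier` (Gini criterion, default 3000
trees, library defaults otherwise); its normalized mean-decrease-impurity
importances order features identically to raw summed Gini decreases.
`gini_impurity` (I = 1 − Σpₖ²) is exposed directly. A per-sequence
encoding (`encoding="per_sequence"`) exists for questions where
within-pair differencing hides the effect of interest — e.g. showing that
length-normalized features outrank raw counts under length heterogeneity,
which is invisible in equal-length pair deltas where the two are
algebraically identical.

## Substitution matrix

Counting is defined on pre-aligned pairs (top row MP, bottom row HP — a
documented file contract, since direction is the matrix's meaning): every
column with two distinct standard residues increments N(mp→hp); gap,
identity, and ambiguity columns are skipped (ambiguity columns are
tallied). Asymmetry of each unordered pair uses the exact two-sided
binomial test at p = 0.5 in the minlike convention (sum of outcome
probabilities ≤ that of the observed count); a Fisher variant tests the
2×2 table of the cell's forward/reverse counts against the direction
totals. Default significance threshold 1e-10, configurable. Alignment
computation is out of scope; BLAST or any aligner's gapped FASTA output is
the expected input.

## Synthetic data generator

`synthetic` generates the study conditions end-to-end: MP sequences are
i.i.d. draws from the published mean mesophilic composition (lengths
uniform in 50–600, matching the real dataset's length filter); the HP
ortholog substitutes a fraction f (default 0.5) of positions with residues
drawn from the replacement distribution that makes the *expected* HP
composition equal MP + the published HP−MP shift. The default f = 0.5 is
the smallest fraction that can realize the full published shift (the most
depleted residue, Gln, drops to ~51% of its MP level, and expected
composition after substitution is bounded below by (1−f)·base); it also
guarantees identity ≥ 0.5, above the 0.30 ortholog-screen floor. Pairs are
equal-length by default (the real screen allowed < 5% length difference;
indels add nothing to a composition-driven model and are left out), and
identity is computed ungapped position-wise.

`mutant_series` draws one full substitution set and reveals it
cumulatively, the way chimera/progressive-mutant panels are built, so the
true stability order is exact by construction and adjacent mutants differ
only by added substitutions.

What the generator does *not* emulate: positional conservation, domain
structure, secondary-structure context, phylogenetic correlation between
pairs, or indels. Passing tests on this generator therefore demonstrate
that the pipeline recovers compositional signal under realistic noise —
not that it reaches any particular accuracy on real proteomes, whose
signal is entangled with family composition and shared ancestry.

## Verification scales

The test suite and `scripts/acceptance.py` use desk-scale sizes chosen
where the measured quantities are stable across seeds: 100–540 generated
pairs, 2×10⁴ hill-climb iterations × 5 restarts per fold, 150–300 forest
trees, 10–20 seeded repetitions of the stochastic checks. On this
generator the cross-validated accuracies land in the high 90s — the same
regime as published ortholog-pair results, slightly higher because i.i.d.
synthetic pairs are cleaner than real orthologs. Exact statistics
(two-sided binomial p-values) are verified against exhaustive rational
enumeration for all n ≤ 20; GRAVY and the instability index are
cross-checked against Biopython's independent implementations; pI is
checked against a dense pH grid scan.

## Known limitations

* Relative ordering only; no ΔTm or ΔΔG magnitudes.
* Composition-driven: mutations that preserve composition-class features
  (e.g. L→I swaps, position-specific effects) are mostly invisible.
* The solubility table's historical source is ambiguous in the literature
  this model descends from; the shipped CRC-style table is documented and
  replaceable via config.
* Scores across non-homologous pairs are comparable only in sign, not in
  magnitude, because Δx depends on both sequences' feature levels.
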