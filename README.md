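# thermoscore

Sequence-based scoring of **relative protein thermostability**: given two
homologous protein sequences — a hyperthermophilic/mesophilic (HP/MP)
ortholog pair, or a wild type and an engineered mutant — predict which one
is more thermostable, and rank whole mutant series, from sequence alone.

It is aimed at protein engineers and comparative genomicists who need a
fast, structure-free estimate of whether a set of substitutions is likely
stabilizing.

## The model

For each sequence, 72 sequence-derived features are computed (amino-acid
compositions, charge statistics, residue-class fractions, mean maximum
solvent-accessible surface area, pI, instability index, aliphatic index,
GRAVY, ...). For an ordered pair (seq1, seq2) and a feature *xᵢ*, the
**relative feature difference** is the symmetric mean-normalized form

    Δxᵢ = (xᵢ(seq1) − xᵢ(seq2)) / ((xᵢ(seq1) + xᵢ(seq2)) / 2),   Δxᵢ = 0 if both are 0

which is antisymmetric, scale-free, and bounded in [−2, 2]. The **score**
is a signed linear combination over ten features:

    S(seq1, seq2) = Σᵢ wᵢ · Δxᵢ

A positive score predicts seq1 the more thermostable. The shipped default
weights are:

| feature | x_K | x_E | x_pos | x_charge | ASA | x_small | x_tiny | x_A | x_Q | x_T |
|---------|-----|-----|-------|----------|-----|---------|--------|-----|-----|-----|
| weight  | 0.75 | 0.20 | 0.80 | 0.20 | 0.90 | −0.20 | −0.20 | −0.30 | −0.10 | −0.20 |

Positive weights sit on features enriched in hyperthermophilic proteins
(Lys, Glu, positive and total charge fraction, mean max ASA), negative
weights on features depleted there (small {T,D}, tiny {G,A,S,P}, Ala, Gln,
Thr fractions). Only weight *signs* are interpretable; magnitudes are not
normalized to a common feature scale.

The package also ships the full training pipeline (median-delta sign
determination, stochastic hill climbing of weight magnitudes, five-fold
cross-validation with restart averaging), random-forest Gini feature
ranking, a directional MP→HP amino-acid substitution preference matrix
builder with exact binomial asymmetry tests, a paired/unpaired t-test
composition comparison, and a synthetic ortholog-pair generator whose
defaults reproduce published HP/MP mean compositions.

## Worked example

Rank a wild type against a cumulative series of seven increasingly
substituted mutants (`python examples/rank_mutants.py`):

```
28 pairwise comparisons among 8 sequences
rank  id        wins  total_score
   1  wt_mut7      7  +3.416
   2  wt_mut6      6  +3.218
   3  wt_mut5      5  +1.494
   4  wt_mut3      4  +0.840
   5  wt_mut4      3  +0.458
   6  wt_mut2      2  -0.977
   7  wt_mut1      1  -3.143
   8  wt           0  -5.306
```

All C(8,2) = 28 ordered pair scores are computed; each sequence's `wins`
is its number of positive pairwise scores (Copeland count) and the ranking
sorts by wins, then total score. The true order by construction is
mut7 > mut6 > ... > wt; here 27 of 28 pairwise comparisons are correct
(mut3 and mut4 — the closest neighbors — are swapped).

Score a single pair and see why (`python examples/score_pair.py`):

```
score S(hp, mp) = +1.2109  ->  prediction: seq1
  delta x_K       = +0.6977
  delta x_Q       = -0.2000
  ...
```

The positive score says the first sequence (the HP-like one) is predicted
more stable; the per-feature deltas show the drivers (Lys enrichment,
Gln depletion).

Other examples: `train_model.py` (fit weights from labeled pairs),
`feature_importance.py` (Gini ranking), `substitution_matrix.py`
(directional substitution bias), `composition_table.py` (t-test
composition comparison).

## Command line

A thin CLI wraps the library:

```sh
thermoscore simulate --n 100 --seed 1 --fasta-out s.fasta --pairs-out p.tsv --truth-out t.tsv
thermoscore features s.fasta -o features.tsv
thermoscore score s.fasta --pairs p.tsv
thermoscore rank mutants.fasta
thermoscore train s.fasta p.tsv -o model.json
thermoscore rankfeat s.fasta p.tsv --top 10
thermoscore submat alignment1.fasta alignment2.fasta
thermoscore compstats s.fasta p.tsv
```

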