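# crystprop

Sequence-based screening of protein **crystallization propensity** with
*dynamic* amino-acid characteristics.

Most sequence features used to predict whether a purified protein will
crystallize are *constant* per-residue indices (hydrophobicity, volume, ...):
every lysine contributes the same number regardless of which protein it sits
in. `crystprop` implements three characteristics that instead depend on the
whole protein — so the same residue type scores differently in different
sequences — and the full benchmarking pipeline needed to compare them against
the constant indices catalogued in AAIndex:

1. **Distribution probability.** The r residues of one type are modelled as
   distinguishable balls dropped uniformly into n = r equal contiguous
   partitions of the sequence. The characteristic is the probability of the
   observed occupancy pattern,

   ```
   P = r!/(q0! q1! ... qn!) * r!/(r1! r2! ... rn!) * n^(-r)
   ```

   where r_i is the number of residues in partition i and q_j the number of
   partitions holding exactly j residues.

2. **Future composition.** The residue composition expected after one round
   of single-nucleotide codon mutation: a 20x20 transition matrix P(a→b) is
   derived from the standard genetic code (each codon's 9 single-nucleotide
   mutants, uniformly weighted) and applied to the current composition,
   reported in percent.

3. **Pair predictability.** For each ordered residue pair (X, Y) the expected
   adjacent count from composition alone is r_X·r_Y/L (r_X·(r_X−1)/L for
   X = Y). A pair type is *predictable* when its observed count equals the
   rounded expectation; the per-protein summary is the percentage of the
   L−1 adjacent pairs that are predictable.

Proteins are encoded as 20-vectors (one coordinate per amino-acid type,
alphabetical one-letter order) with either a dynamic characteristic or a
count-weighted AAIndex entry, and classified with logistic regression

```
P(y=1 | x) = 1 / (1 + exp(-(b0 + b1 x1 + ... + b20 x20)))
```

or a 20→10→1 feed-forward neural network (tanh hidden layer, logistic
output). Evaluation follows the screening workflow: full-data fits for a
first-pass screen of every characteristic, delete-1 jackknife validation
(n held-out predictions for n proteins), accuracy/sensitivity/specificity,
ROC curves, and a Mann–Whitney comparison of pair-predictable portions
between well- and poorly-predicted proteins.

All estimators follow scikit-learn conventions (`fit`/`predict`/`transform`,
`get_params`, fitted attributes with trailing underscores) and compose with
sklearn pipelines.

## Worked example

```python
from crystprop import (ProteinRecord, distribution_vector, future_composition,
                       pair_predictability, expected_pair_count)
from crystprop.sequences import AMINO_ACIDS

rec = ProteinRecord("demo", "MKKLLAGSTKKWYDEKKNAC")
dv = distribution_vector(rec)
fc = future_composition(rec)
_, pred, unpred = pair_predictability(rec)

print("K count:", rec.counts["K"], "at positions", rec.positions("K"))
print("dp_K = %.4f" % dv[AMINO_ACIDS.index("K")])
print("fc_K = %.2f" % fc[AMINO_ACIDS.index("K")])
print("expected KK = %.2f" % expected_pair_count(rec.counts, rec.length, "K", "K"))
print("predictable = %.2f%%" % pred)
```

prints

```
K count: 6 at positions [2, 3, 10, 11, 16, 17]
dp_K = 0.0386
fc_K = 6.32
expected KK = 1.50
predictable = 5.26%
```

The six lysines fall pairwise into three of their six sequence partitions, a
clustered pattern with probability 0.0386 (an evenly spread pattern would
score higher); after one mutation round lysine is expected to make up 6.32 %
of the protein (down from 30 %, since many single-nucleotide changes leave
AAA/AAG codons); 1.50 adjacent KK pairs are expected from composition (predicted count 2
after rounding), so the 3 observed KK pairs are unpredictable under the
strict rule — as are
most pairs in this deliberately clustered toy sequence.

The same quantities are available from the shell: `crystprop featurize
--fasta proteins.fasta --out results/` writes a TSV with one row per protein
(20 distribution probabilities, 20 future compositions, predictable and
unpredictable portions). `crystprop synth | screen | fit | jackknife | roc |
group-test` cover the rest of the workflow; every subcommand is
deterministic given `--seed` and writes a `manifest.json` beside its
outputs.

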