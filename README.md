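# seqsplit

Analysis pipeline for **sequence-splitting neural signals** in paired
odor–outcome sequences: single-neuron splitting detection, population
decoding geometry (splitting vectors, coding similarity, MDS), and a
generative linear model of how task variables shape splitting-signal
generalization, with full parameter recovery.

The task: two association problems, each with four odor sequences
(types `1a+, 1a-, 1b+, 1b-, 2a+, 2a-, 2b+, 2b-`). Within a pair the
(+) and (−) sequences are externally identical during the *overlap epoch*
(shared second odor or delay, 4–7 s) and differ only in history and
expected outcome; the outcome arrives at 7 s. Neurons that respond
differently to the two members of a pair during the overlap epoch are
*splitting neurons*.

A synthetic-data module generates sessions whose pair-discriminating
component is a known mixture of four latent directions — past cue (α),
current cue (β), sequence structure (γ), expected outcome (δ) — so every
stage can be validated against ground truth without external data.

## Modules

| module | contents |
|---|---|
| `seqsplit.task` | task design, trial types, sequence pairs, epochs, binning, schedules |
| `seqsplit.synth` | latent basis, splitting-vector composition, session & lick simulation |
| `seqsplit.behavior` | anticipatory lick rates, lick latency, performance index |
| `seqsplit.splitting` | rank-sum splitting detection, ROC-AUC discrimination index, fraction time courses, overlap/conversion tracking, lick-correlation screen |
| `seqsplit.decoding` | pseudo-ensembles, linear SVM decoding with leave-one-per-type-out CV, label-shuffle nulls, split-half coding-similarity matrices, classical MDS |
| `seqsplit.model` | generative model: Monte-Carlo and closed-form similarity prediction, bias-pattern simulation, predicted overlaps, noise term, bounded-simplex weight fitting |
| `seqsplit.io` / `seqsplit.pipeline` / `seqsplit.cli` | HDF5/CSV session containers, run configs, seeded stage pipeline, CLI |

## CLI

```bash
seqsplit run --seed 1 --out results/            # full pipeline
seqsplit simulate --seed 1 --out sessions/      # synthetic sessions (HDF5)
seqsplit behavior sessions/session_0.h5
seqsplit splitting sessions/session_0.h5 --pair 1a --epoch overlap
seqsplit decode sessions/*.h5 --pair 1a --seed 1
seqsplit similarity sessions/*.h5 --seed 1 --out sim.tsv
seqsplit fit-model sim.tsv --n-restarts 100 --seed 1
seqsplit recover --weights 0.8,0.9,0.25,0.25 --seed 1
```

All stochastic stages derive per-stage seeds from the master `--seed`;
identical configs reproduce every output bit-for-bit.

## Model in brief

For pair *i*, the splitting signal is `s_i = α·a_i + β·b_i + γ·t_i + δ·o_i`
with the weight vector L2-normalized. Across the four pairs:
`a_1..a_4, b_1, b_2` uncorrelated; `b_3 = b_4 = 0` (pure delay);
`t_1 = t_2`, `t_3 = t_4` (shared structure within type); `o_1 = … = o_4`
(shared outcome). Under exact orthogonality the expected coding
similarity has the closed form

```
cos(s_i, s_j) = (δ² + γ²·[same type]) / √(N_i · N_j),
N_i = α² + γ² + δ² + β²·[type a]
```

which the Monte-Carlo predictor (random 100-d bases, as in the fitting
procedure) matches to < 0.02. Weights are recovered from an observed
4×4 split-half similarity matrix by bounded Nelder–Mead on the MSE
between noise-scaled predictions and the six between-pair entries, where
the noise term is the mean within-pair split-half similarity.
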