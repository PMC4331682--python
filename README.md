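# csrwalign

Global multiple alignment of protein–protein interaction networks via a
context-sensitive random walk (CSRW). For every pair of networks, a two-mode
random walker (simultaneous moves over similar node pairs, individual moves
on one network otherwise) is restricted to the positive-similarity support,
its stationary distribution is blended with the normalized similarity scores
through an automatically chosen restart probability, the per-pair scores are
refined by a selective probabilistic consistency transformation, and a
greedy maximum-expected-accuracy procedure assembles the final equivalence
classes. A synthetic benchmark generator (CG / DMC / DMR duplication growth
models with ground-truth orthology and noisy similarity tables) makes the
whole pipeline testable offline.

## Package layout

| module                   | contents                                                            |
|--------------------------|---------------------------------------------------------------------|
| `csrwalign.netio`        | edge-list / similarity / annotation / alignment file formats        |
| `csrwalign.csrw_core`    | reduced chain, restart probability, stationary distribution, scores |
| `csrwalign.consistency`  | selective probabilistic consistency transformation                  |
| `csrwalign.aligner`      | greedy equivalence-class construction                               |
| `csrwalign.metrics`      | accuracy, expected accuracy, CN / SPE / MNE / CI / COI, coverage    |
| `csrwalign.synthgen`     | benchmark-family generator and ground truth                         |
| `csrwalign.cli`          | `csrwalign` command-line entry point                                |

## CLI

Generate a synthetic family, align it, and evaluate:

```sh
csrwalign simulate --model dmc --networks 3 --sizes 200,200,200 \
    --seed 7 -o bench/

csrwalign align \
    --net G1=bench/network_G1.tsv --net G2=bench/network_G2.tsv \
    --net G3=bench/network_G3.tsv \
    --sim G1,G2=bench/sim_G1_G2.tsv --sim G1,G3=bench/sim_G1_G3.tsv \
    --sim G2,G3=bench/sim_G2_G3.tsv \
    --out bench/result.aln

csrwalign eval --alignment bench/result.aln \
    --annotations bench/annotations.tsv --truth bench/truth.aln \
    --net G1=bench/network_G1.tsv --net G2=bench/network_G2.tsv \
    --net G3=bench/network_G3.tsv
```

Key options on `align`: `--K` (restart-probability percentile, default 99),
`--alpha` / `--beta` (consistency mixing weights, 0.9 / 0.8), `--lambda-t`
(per-pair gate on applying the consistency transform, 0.7), `--n-max`
(class-size cap, 10), `--override-lambda` (fix the restart probability).
`csrwalign walk-debug` dumps each pair's reduced transition matrix, restart
probability, and stationary vector.

Input formats: networks are two-column whitespace-delimited edge lists
(`#` comments allowed); similarity tables are `nodeU nodeV score` rows with
strictly positive scores kept; annotations are `network node function` rows;
alignments are written one class per line as tab-separated `label|node`
tokens.

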