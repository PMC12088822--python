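# hdbncaen

Binary disease prediction from mixed-type clinical tables, built around two
ideas: hierarchical feature extraction with a stack of restricted Boltzmann
machines (a hybrid deep belief network, *HDBN*), and dynamic aggregation of
several base classifiers whose ensemble weights follow a softmax of their
negative validation losses (a custom adaptive ensemble network, *CAEN*).
The package is aimed at researchers who want a small, fully inspectable
implementation of this pipeline — every numerical component is written in
numpy and checked against exact enumeration, closed forms, or finite
differences — together with a seeded synthetic-data test bed so the whole
chain is verifiable without any external clinical dataset.

## The model

An RBM over binary visible units `v` and hidden units `h` has energy

    E(v, h; θ) = − Σ_ij v_i W_ij h_j − Σ_i b_i v_i − Σ_j c_j h_j,
    P(v, h) = exp(−E) / Z,      Z = Σ_{v,h} exp(−E),

with factorial logistic conditionals `p(h_j = 1 | v) = σ(c_j + Σ_i v_i W_ij)`.
Layers are pretrained greedily with contrastive divergence,

    ΔW_ij = η (⟨v_i h_j⟩_data − ⟨v_i h_j⟩_model),

the negative statistics coming from a k-step Gibbs chain started at the data.
The pretrained stack is unrolled into a logistic feed-forward network with a
2-class softmax head and fine-tuned by mini-batch gradient descent on
L2-regularized cross-entropy `L = CE + λ‖W‖²`.

The ensemble trains three base learners — the fine-tuned deep-belief
classifier, a dense rectifier network, and a single-head self-attention
classifier for sequential inputs — and combines their probability outputs as

    Ŷ = Σ_m w_m Ŷ_m,      w_m = exp(−L_m) / Σ_j exp(−L_j),

where `L_m` is learner m's validation cross-entropy. Lower-loss learners
therefore get strictly larger weights, and the combination is a convex
mixture, so the ensemble's cross-entropy never exceeds the weighted mean of
the learners' (Jensen). Evaluation covers the full confusion-matrix family
(accuracy, precision, recall, specificity, FPR, FNR, FDR, MCC) plus
mask-overlap metrics (Dice, SSIM, proportion of correct patches).

For tiny RBMs (≤ 20 units) the partition function, joint probabilities and
model moments are computed by exhaustive enumeration and serve as oracles for
the sampled training statistics; the synthetic generator's numeric-only
configurations have closed-form Bayes accuracy `Φ(√d·Δμ/2)`, the ceiling for
end-to-end recovery tests.

## Worked example

```
$ cat demo.yaml
seed: 7
n_samples: 1500
mean_separation: 2.0
missing_rate: 0.05
outlier_rate: 0.01
epochs: 15
optimizer: adam
learning_rate: 0.01

$ hdbncaen --quiet run --config demo.yaml
{
  "seed": 7,
  "n_rows": 1500,
  "split_sizes": {"train": 1008, "valid": 225, "test": 224},
  "learners": ["hdbn", "dense", "attention"],
  "validation_losses": [0.1827, 0.0568, 0.0856],
  "ensemble_weights": [0.3090, 0.3505, 0.3405],
  "confusion": {"tp": 108, "fp": 6, "fn": 6, "tn": 104},
  "metrics": {
    "accuracy": 0.9464, "precision": 0.9474, "recall": 0.9474,
    "specificity": 0.9455, "fpr": 0.0545, "fnr": 0.0526,
    "fdr": 0.0526, "mcc": 0.8928
  },
  ...
}
```

Reading the output: 1500 synthetic patients with class-separation Δμ = 2σ
were corrupted (5% missing cells, 1% far outliers), cleaned and split
70/15/15; the three learners reached validation cross-entropies of 0.18,
0.057 and 0.086, so the softmax rule weighted the dense learner highest
(0.3505) and the deep-belief learner lowest (0.3090); the weighted ensemble
then classified the 224 held-out rows with 94.6% accuracy and MCC 0.89.
Losses and weights are reported in full precision by the tool and shortened
here for readability.

Other subcommands (`simulate`, `preprocess`, `train-hdbn`, `train-learner`,
`train`, `predict`, `evaluate`) expose the individual stages on CSV files;
see `hdbncaen --help`.

## Layout

    src/hdbncaen/
      synthdata.py   seeded generators (tabular, AR(1) series, mask pairs)
      preprocess.py  impute / flag outliers / scale / encode / PCA / RFE / split
      hdbn.py        RBM energy model, enumeration oracles, CD, fine-tuning
      learners.py    dense and self-attention base classifiers
      ensemble.py    softmax loss-weighting, aggregation, optimization steps
      metrics.py     confusion-matrix family, Dice / SSIM / patch agreement
      config.py,     flat YAML run configuration and
      cli.py         the command-line pipeline
    docs/methods.md  modeling assumptions, parameter choices, limitations
    tests/           unit, property and acceptance suites
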