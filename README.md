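# litenet

A lightweight 1-D convolutional network for five-class ECG arrhythmia beat
classification, built on a small, fully from-scratch neural micro-framework
(numpy forward/backward passes, gradient-checked against finite differences)
together with the complete surrounding pipeline: synthetic ECG generation,
R-peak-centered beat segmentation, Z-score normalization, class balancing,
ten-fold cross-validated training with Adam or SGD, and a full evaluation
stack (confusion matrices, precision/recall/F1, multiclass AUC with a
qualitative rating, and a conv-only parameter-count model-size metric).

## Who this is for

Researchers and students who want a transparent, dependency-light reference
implementation of a compact ECG beat classifier — every layer's forward and
backward pass is plain numpy you can read — and a reproducible test bed that
needs no data download: a seeded generator synthesizes single-lead ECG
records with the five AAMI beat classes (N normal, S supraventricular
ectopic, V ventricular ectopic, F fusion, Q unknown).

## The model

Beats are cut as fixed windows around annotated R-peaks (half-window *h*
gives a segment of 2*h* samples covering `[r-h, r+h)`; at 360 Hz, *h* = 180
gives 1-s/360-sample inputs, *h* = 360 gives 2-s/720-sample inputs), then
Z-scored per segment: x ↦ (x − μ)/σ with the population σ.

The network is

```
standard conv 1×5 (5 filters) → max-pool 1×2/2
→ Lite module → max-pool 1×2/2
→ flatten → dense 30 → dropout 0.3 → dense 20 → dropout 0.3 → softmax (5)
```

with LeakyReLU (α = 0.01) after every convolution and dense layer.  The
**Lite module** is a 1×1 squeeze convolution down to 3 channels feeding three
parallel branches — a standard 1×1 convolution, and two depthwise-separable
chains (standard 1×k → depthwise 1×k → pointwise 1×1, for k = 2 and 3) — each
producing 6 channels, concatenated to 18.  On a 360-sample input the shape
trace is 360 → 180 → (18 ch, 180) → (18 ch, 90) → 1620 → 30 → 20 → 5.

Training minimizes the mean cross-entropy H(p, q) = −Σ p log q with Adam
(m ← β₁m + (1−β₁)g, v ← β₂v + (1−β₂)g², θ ← θ − lr·m̂/(√v̂ + ε); defaults
lr = 0.005, batch 50, β₁ = 0.9, β₂ = 0.999, ε = 1e-8) or plain SGD.
Model size is summarized by **PC**, the parameter count of convolutional
layers only (weights + biases; dense layers excluded): basic LiteNet has
PC = 300 versus 368 (SqueezeNet-1D), 415 (MobileNets-1D), 810 (AlexNet-1D)
and 1054 (GoogLeNet-1D) under the same ledger convention.

Evaluation is k-fold cross-validation on disjoint stratified folds
(train on k−1, test on 1, rotate; metrics averaged over folds), with
rank-based one-vs-rest AUC rated Excellent (≥0.9) / Good / Fair / Poor /
Failure.

## Worked example

`examples/` contains one narrative script per capability.  Running
`python examples/05_crossvalidate.py` generates a synthetic record
(40 beats/class), segments it into 1-s windows, balances to 60 beats/class,
Z-scores, and runs ten-fold cross-validation of the basic network (Adam,
8 epochs, pinned seeds).  It prints:

```
fold  accuracy  macro-F1  macro-AUC
   0    1.000    1.000     1.000
   ...
mean accuracy:  1.0000
mean macro F1:  1.0000
mean macro AUC: 1.0000 → rated Excellent
pooled confusion total: 300 (= every segment tested exactly once)
```

Mean accuracy is the arithmetic mean of per-fold accuracies; the AUC rating
maps the macro one-vs-rest AUC into its qualitative band.  The pooled
confusion total equals the dataset size because the folds partition it.
`examples/04_train_and_evaluate.py` shows a single train/test split with the
full report (its first-epoch loss sits near ln 5 ≈ 1.609, the uniform-
prediction value for five classes), and `examples/03_architecture_and_
parameter_count.py` prints the shape trace and the PC comparison table.

A thin CLI wraps the same functions:

```sh
litenet generate --beats-per-class 40 --seed 11 --out rec.txt --ann rec.ann
litenet segment --record rec.txt --ann rec.ann --half-window 180 --out data.h5
litenet crossval --arch litenet-basic --data data.h5 --epochs 8 --report report.json
litenet describe --arch litenet-basic --input-len 360
litenet compare-pc
```

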