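# seedstage

Per-seed kinetics of early seedling development from top-view tray
time-lapses.

Seedling establishment — when each seed emerges from the soil, opens its
cotyledons and initiates its first true leaf — is a key determinant of crop
vigor, and scoring it seed by seed across trays of hundreds of pots is
exactly the kind of task time-lapse imaging should automate.  `seedstage`
implements the full computational pipeline for this problem: geometric
normalisation of raw tray photographs, per-pot sequence extraction,
frame-level developmental-stage classification with temporal deep networks,
ontology-aware label smoothing, and per-pot event-time tables.  Because raw
phenotyping datasets of this kind are rarely public, the package ships a
synthetic tray-scene generator with exact per-pot ground truth, so every
stage of the pipeline is testable end to end.

## The problem and the model

Each pot's time-lapse is a sequence of RGB crops (89 × 89 × 3 by default,
one frame every 15 min during a 16-h photoperiod) to be labelled with one of
four *ordinal* stages,

```
Soil (0)  <  FA (1)  <  OC (2)  <  FL (3)
```

— bare soil, first appearance of the cotyledon (emergence), open cotyledons,
first leaf.  Development is irreversible, and the package exploits that
order everywhere:

* **Baseline CNN** — four 3×3 conv layers (64, 128, 256, 256 filters, each
  with ReLU + 2×2 max-pool), a 512-unit dense layer with dropout 0.5, and a
  softmax head; every frame scored independently.  Trained by minimising
  cross-entropy with Adam (learning rate 10⁻³).
* **Chained binary CNNs** — three 2-class models M₁(Soil, FA), M₂(FA, OC),
  M₃(OC, FL); M₁ scans the sequence and, at the first FA, hands over to M₂
  from that frame on, and so forth — the ontology is hard-wired into the
  decision chain.
* **CNN-LSTM** — the same conv features feed a 128-unit peephole LSTM
  between feature extraction and classification:

  ```
  i_t = σ(W_xi x_t + W_hi h_{t-1} + w_ci ∘ c_{t-1} + b_i)
  f_t = σ(W_xf x_t + W_hf h_{t-1} + w_cf ∘ c_{t-1} + b_f)
  c_t = f_t ∘ c_{t-1} + i_t ∘ tanh(W_xc x_t + W_hc h_{t-1} + b_c)
  o_t = σ(W_xo x_t + W_ho h_{t-1} + w_co ∘ c_{t-1} + b_o)
  h_t = o_t ∘ tanh(c_t)
  ```

* **ConvLSTM** — the same cell with every matrix product replaced by a
  same-padding 2-D convolution over spatial feature maps.

All networks are pure numpy with hand-written backpropagation (im2col
convolutions on BLAS), so the package has no deep-learning-framework
dependency.

Predicted label sequences are denoised by a sliding **ordinal median**: the
window's labels are sorted and the ⌊(n+1)/2⌋-th smallest replaces the
current one (n = 4 frames ≈ one hour by default), followed by a running
maximum that forbids developmental regressions — when a first leaf grows
out of the crop and only cotyledons remain visible, the pot stays FL.
Event times are the first frames of each smoothed stage period, reported
with wall-clock timestamps (overnight transitions are flagged, since no
frames exist during the dark period).

Evaluation is one-vs-rest from the 4×4 confusion matrix: sensitivity,
specificity, precision, false-positive rate, accuracy/error and
F1 = 2·TP / (2·TP + FP + FN) per class.

## Worked example

A two-tray synthetic experiment, training a CNN-LSTM on tray 0 and scoring
the held-out tray 1:

```yaml
# run.yaml
scene:
  n_trays: 2
  grid_rows: 2
  grid_cols: 2
  pot_size_px: 32
  frames_total: 32
  margin_px: 30
  seed: 5
arch: cnnlstm
preset: small
split: by_tray
germination_prob: 1.0
delay_params:
  t_fa_range: [0.15, 0.3]
  fa_dur_range: [0.2, 0.3]
  oc_dur_range: [0.25, 0.35]
training: {epochs: 10, batch_size: 4, sequence_chunk_len: 16, seed: 0}
out_dir: runout
seed: 0
```

```text
$ seedstage run --config run.yaml
{
  "dataset": {
    "n_trays": 2,
    "pots_per_tray": 4,
    "n_sequences": 8,
    "total_images": 256
  },
  "event_mae_frames": 1.0,
  "mean_accuracy_post": 0.875
}
```

`event_mae_frames` is the median absolute difference, in frames, between
the recovered and the true transition frames of the held-out pots — here
one frame, i.e. 15 minutes of wall-clock time.  `runout/timings.csv` holds
the per-pot event table (frame and timestamp of FA, OC and FL, with
night-gap flags), `runout/metrics.json` the per-class metrics, and
`runout/trace/` the per-frame class probabilities.  The same stages are
available as library calls (`seedstage.pipeline.run_pipeline`) and as
separate subcommands (`generate`, `preprocess`, `train`, `predict`,
`smooth`, `evaluate`) for real image directories.

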