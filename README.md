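# nervedecode

Pseudo-online decoding of finger motor intent from multi-channel,
nerve-like recordings. The toolkit implements the full workflow:

* **synthetic sessions** — 16-channel recordings (channels 1–8 "median",
  9–16 "ulnar") of band-limited 25–600 Hz activity whose per-channel
  amplitude follows the intent envelopes of the active fingers, time-locked
  to 10-DOF glove trajectories in [0, 1]; 9-gesture codebook (5 single-finger
  flexions, index pinch, tripod pinch, fist, rest), 4-s rest/flex cycles,
  configurable SNR, fully seeded;
* **preprocessing** — downsampling + zero-phase 25–600 Hz band-pass and
  cutting into causal 4-s trials stepped at 100 ms, with threshold-derived
  finger-state labels and bit-rate accounting;
* **features** — 14 temporal features (ZC, SSC, WL, WA, MAB, MSQ, RMS, V3,
  LD, DABS, MFL, MPR, MAVS, WMA) over 80 %-overlapped 100-ms windows: a
  4-s, 16-channel trial becomes a 224 × 200 matrix; per-feature fixed
  normalization constants are fitted on the training split only;
* **decoders** — shallow CNN / RNN models built on an in-package NumPy
  neural-net framework (conv1d, LSTM, dropout, Adam with β₁ = 0.99,
  β₂ = 0.999, L2 = 1e-5, mini-batch 38, plateau LR scheduler), plus SVM /
  random-forest / MLP baselines (scikit-learn) with their published
  hyperparameters;
* **strategies** — one-step (regress all 10 DOF always) and two-step
  (classify the 5-bit finger state, then regress only active fingers'
  DOF, zeroing the rest) decoding;
* **evaluation** — sensitivity/specificity/precision/balanced-accuracy/F1,
  MSE and VAF, leakage-free block splits for regression (zero shared raw
  samples between train and validation windows, audited), gesture-stratified
  k-fold CV, and paired t-tests with Bonferroni correction.

## CLI

```sh
nervedecode simulate --seed 1 --repetitions 4 --snr-db 20 --out sess --csv
nervedecode preprocess --session sess.npz --window 4.0 --step 0.1 --out pre.json
nervedecode extract    --session sess.npz --window-ms 100 --step-ms 20 --out grid.npz
nervedecode train      --session sess.npz --family rf --reg-family svm \
                       --strategy 2s --seed 1 --out models.pkl
nervedecode decode     --session sess.npz --models models.pkl --out results.csv
nervedecode evaluate   --pred results.csv --session sess.npz --out metrics.json
nervedecode pipeline   --config cfg.yaml --out run/     # end-to-end
```

`pipeline` runs simulate → preprocess → extract → train → decode → evaluate
from one YAML document (see `nervedecode.pipeline.RunConfig`); every output
is stamped with the config hash and seed, and identical configs reproduce
identical outputs.

## Notes

* Trajectories are in [0, 1] with 0 = resting; DOF rows are (thumb MCP,
  thumb PIP, index MCP, …, little PIP).
* Finger-state vectors are ordered thumb-first; printed bit strings are
  derived labels with configurable direction (`GestureCode.code`), since
  both conventions appear in the literature.
* The offline band-pass is zero-phase (forward–backward); a real-time port
  must substitute causal filters.
* PyTorch is deliberately not a dependency: the shallow networks are small
  enough that a NumPy implementation (gradient-checked in the tests) keeps
  the package self-contained.
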