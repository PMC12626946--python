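# paratopenet

Sequence-only, chain-aware prediction of antibody paratope residues — the
residues of an antibody variable domain that directly contact the antigen.
Intended for antibody engineers and computational immunologists who need
residue-level binding-site calls in structure-free settings (early
discovery, repertoire profiling) where homology modelling or docking is
too slow or impossible.

## The model

Each heavy (VH) or light (VL) chain of 110–130 residues is zero-padded to
L = 130 and processed independently:

    x_t  ──►  one-hot (d = 21)  or  learnable embedding (d = 21)
         ──►  BiLSTM, hidden 64/direction      h_t = h⃗_t ⊕ h⃖_t ∈ R^128
         ──►  1-D "same" convolution, ReLU     z_t ∈ R^64, kernel k ∈ {7, 15, 31, 71, 130}
         ──►  dense + sigmoid                  p_t = σ(W·z_t + b) ∈ (0, 1)

Training minimizes a masked, class-weighted binary cross-entropy

    L = −(1/N) Σ_t m_t [ w₊ y*_t log p_t + w₋ (1 − y*_t) log(1 − p_t) ],

where m_t masks padding, w₋ = 1 and w₊ = N_neg/N_pos is the
negative-to-positive residue ratio of the training split (~8.6 at a 10.4%
positive rate), countering the heavy class imbalance of paratope labels.
Optimization is Adam (lr 0.001) with early stopping on validation MCC
(patience 5).  Splits are made at the antibody-complex level — paired H and
L chains always stay on the same side — with five stratified grouped folds
and a 10% blind hold-out.  Evaluation reports ROC AUC, PR AUC, accuracy,
precision, recall, F1 and MCC over unpadded residues.

The network (BiLSTM, convolution, backpropagation through time, Adam,
dropout) is implemented in NumPy with hand-derived gradients, verified
against finite differences and brute-force oracles in the test suite.
A seedable synthetic generator produces paired-chain datasets with planted,
learnable binding motifs so the entire pipeline is testable offline; see
`docs/methods.md` for the model, the generator's scope, and design choices.

## Worked example

```bash
paratopenet simulate --n-complexes 120 --seed 7 --out data.tsv
paratopenet split --data data.tsv --folds 5 --seed 7 --out plan.txt
printf 'training:\n  patience: 10\n  max_epochs: 40\n' > config.yaml
paratopenet train --data data.tsv --split-plan plan.txt --config config.yaml \
    --encoding onehot --regime H --kernel 31 --seed 7 --out run/
paratopenet evaluate --checkpoint run/checkpoint.npz --data data.tsv \
    --split-plan plan.txt --regime H --out report.json
```

prints (numbers from this exact command sequence):

```
wrote 120 complexes (28823 residues, 10.42% binding) to data.tsv
split 120 complexes: 12 blind, 108 modeling in 5 folds -> plan.txt
trained 40 epochs (best 36: val MCC 0.799) -> run
H blind set (12 chains, 1439 residues): MCC 0.804, F1 0.817, AUC 0.992 -> report.json
```

The simulated data plants compositional binding motifs (Tyr/Trp/Arg-rich
loops with cysteine anchors) in ~10.4% of residues.  Training on the heavy
chains of the 86 training-fold complexes recovers those motifs; on the 12
withheld complexes the model finds binding residues with MCC 0.80 — far
above the ~0 an uninformative predictor would score at this imbalance —
confirming the pipeline learns genuine sequence signal rather than class
priors.  The same library API is available from Python
(`paratopenet.generate_dataset`, `train_model`, `evaluate_blind`, ...).

Chain identity matters: models trained on H chains and evaluated on H
chains outperform cross-regime combinations, and the full sweep
(`paratopenet sweep`) compares 30 configurations — 2 encodings × 3 chain
regimes × 5 kernel sizes — over all folds, ranked by mean MCC.

Real data in the native four-column TSV (complex id, chain type, sequence,
'0'/'1' label string) or FASTA-plus-label-TSV is read with
`paratopenet.read_chain_table`; structure-derived labels are consumed, not
computed.

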