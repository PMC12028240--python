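# Methods

## The model

`dtialign` aligns two independently produced embedding spaces — one for
protein targets, one for drug molecules — so that cosine similarity in a
shared space predicts drug–target interaction (DTI).  The inputs are
pre-computed embedding tables (from a network-representation model, a
protein language model, a molecular VAE, a text LLM — the package is
agnostic) and an observed DTI edge list.  Nothing upstream is trained or
re-run: only the two projection heads are learned.

Each head is either a single affine map ("linear", depth 0) or an n-layer
MLP (depth n ≥ 1: n affine layers with the activation after every layer but
the last, so "2-layer non-linear" means two affine maps with one activation
between them).  Given a batch of N observed pairs (pᵢ, mᵢ), the heads
produce projections which are L2-normalized and multiplied into an N×N
cosine matrix S.  Supervision is *weak*: only diagonal cells carry a label
(yᵢᵢ = 1); off-diagonal cells are unconstrained and act purely as in-batch
negatives.  The objective is the bidirectional cross-entropy

    L = ½ (L_PM + L_MP),
    L_PM = −(1/N) Σᵢ log softmax_row(S/τ)ᵢᵢ,
    L_MP = −(1/N) Σᵢ log softmax_col(S/τ)ᵢᵢ,

optimized with Adam on analytically derived gradients (no autodiff
framework is used; the backward pass through the heads, the row
normalization and the masked softmaxes is written out by hand and verified
against central finite differences in the test suite).

Because repeated proteins or drugs may appear in one batch, a known true
interaction can occupy an off-diagonal cell.  By default it simply stays in
the denominators (the weak-label reading); `mask_known_positives` removes
such cells from both softmaxes instead.

At inference, a query protein and any candidate drugs — including entities
absent from the training graph — are projected, ranked by cosine, and
reported with softmax likelihoods over the candidate set.  Softmax is
monotone, so likelihoods and cosines induce the same ranking; likelihoods
are for interpretability only.

## Tunable parameters

| Parameter | Default | Notes |
| --- | --- | --- |
| `n_components` (shared dim) | 256 | experiments here use 32; data-driven, never inferred from upstream models |
| `depth` per head | 2 | ablation grid spans {0, 2, 3, 5, 12} |
| `hidden_dim` | `n_components` | |
| `activation` | relu | {relu, tanh, gelu} |
| `temperature` τ | 1.0 | faithful to a plain softmax over cosines; the experiments below use τ = 0.1, which sharpens the in-batch contrast and converges much faster when cosines are confined to [−1, 1] |
| `learning_rate` | 1e-2 | Adam; chosen for desk-scale problems (10²–10³ pairs, heads with 10³–10⁴ parameters) where smaller rates converge needlessly slowly |
| `batch_size` | 64 | a size-1 batch has no contrastive signal and is skipped |
| `epochs` | 50 | |

Head parameters initialize from U(−1/√fan_in, 1/√fan_in) under
`numpy.random.default_rng(seed)`, so a config reproduces bit-identically
across platforms.  Checkpoints serialize floats via `repr` and round-trip
exactly.

Splits follow the data: validation is a uniform `floor(0.1 · |edges|)`
sample of DTI *edges* (the 9:1 convention), cold-start proteins are a
uniform 10% of proteins whose every edge moves to the test partition, and
novel drugs are drugs holding embeddings but no train/valid edge.

## The synthetic generator

The generator plants the structure the model assumes: a shared latent space
in which interacting pairs are close.

1. Each protein draws a unit latent zₚ (isotropic Gaussian, normalized,
   dimension `latent_dim`).
2. Each protein interacts with `max(1, Poisson(λ))` drugs recruited from a
   shared pool.  Recruitment is *assortative*: visiting proteins in seeded
   random order, a protein joins drugs whose current member proteins are
   similar to it (weights `exp(cos/κ)`, κ = 0.1; unoccupied drugs get a
   baseline affinity of 0.5).  This mirrors the fact that a real drug's
   targets form a related protein family.  Under uniform recruitment a drug
   serving k independent proteins has cosine ≈ 1/√k to each of them, and
   with `latent_dim` 8 the distractor-cosine spread (sd ≈ 0.35) makes even
   an oracle that ranks by true latents top-1-correct only ~60% of the
   time; assortative recruitment restores oracle top-1 ≈ 0.99 while keeping
   the many-to-many degree structure (mean ≈ 2.8, max ≈ 6 at the default
   density).
3. A drug's latent is the unit-normalized mean of its member proteins'
   latents plus Gaussian jitter of scale `noise_sd`; unrecruited drugs get
   random unit latents (pure distractors).
4. Observed embeddings are A·zₚ + ε and B·z_d + ε with fixed seeded
   standard-normal mixing maps and isotropic noise `noise_sd`.  With
   `nonlinear_drug_map`, B is instead drawn as a scaled (semi-)orthogonal
   matrix √latent_dim · Q — every channel then sees exactly unit
   pre-activation variance instead of variance set by the conditioning of
   an iid draw — and each drug channel passes through the fixed elementwise
   distortion g(u) = (exp(1.5u) − m)/s (m, s the lognormal standardizing
   constants), *before* noise.
5. Hold-outs (novel drugs, cold proteins, 9:1 train/valid) apply as above.

The min-1 truncation lifts the realized mean drugs-per-protein to
λ + e^(−λ); the bundled full-scale world (670 drugs, 1894 proteins) uses
λ = 2.4704 so the expected interaction count is ≈ 4839 and the label
density ≈ 0.004.

What the generator does *not* emulate: real embedding geometry (cluster
anisotropy, hubness), biased negative sampling, noisy or disputed
interaction labels, and any chemistry — drugs are latent points, not
molecules.  Passing tests therefore demonstrate that the machinery recovers
structure *when the modelling assumption holds*, not performance on any
real database.

### On the non-linear drug map

The `nonlinear_drug_map` distortion exists to create a world in which a
linear drug head is insufficient, for the projection-depth ablation.  The
design is more constrained than it looks:

- Any *odd, monotone* elementwise distortion of dense random projections
  keeps its first Hermite (Bussgang) component, and when the embedding has
  many more channels than the latent has dimensions, averaging across
  channels lets an affine head undo the distortion almost perfectly (ridge
  recovery of an 8-dim latent from 64 tanh-squashed channels: R² ≈ 0.98).
- Harsh non-monotone maps (random-Fourier sin/cos at high frequency) or
  hard saturation destroy the information for *every* learner, linear or
  not.

The scaled exponential threads the needle — monotone and smoothly
invertible (the latent stays recoverable at low noise) but asymmetric
enough that the correlation between u and exp(1.5u) is ≈ 0.76 per channel —
*provided* there is no channel redundancy.  The ablation experiment
therefore uses a square drug map (`drug_dim = latent_dim = 8`); with
`drug_dim` ≫ `latent_dim` the averaging rescue reappears and the depth
contrast washes out by construction, not by any fault of the heads.

## Reference experiments (`dtialign.experiments`)

All three derive every stream from one root seed.

**Planted-structure recovery.**  200 proteins × 200 drugs, latent 8, noise
0.05, 10% novel drugs; 2-layer heads (hidden 64, shared dim 32) trained 50
epochs (τ 0.1, lr 3e-3, batch 64); Top-1/Top-3 on held-out edges against 4
sampled non-interacting distractors, with a uniform-random scorer on the
identical cases as the 0.2 baseline.

**Cold-start generalization.**  Same family, but 10% of proteins withheld
from training entirely; Top-1 on their edges, plus pooled AUROC/AUPR over
all (cold protein, drug) pairs — the drug-repositioning readout.

**Projection-depth ablation.**  300×300 world with the square non-linear
drug map (λ = 4 interactions per protein, noise 0.02, no novel drugs).
Arms differ only in
drug-head depth (0 vs 2, hidden 128, tanh); the protein head is linear in
both, matching the linear protein map.  Both arms train 1000 epochs at
lr 1e-3, τ 0.1 and are scored by MAP (mean precision@1) on validation
edges, ranking all drugs with the protein's training drugs excluded.  Each
arm averages three training seeds: single contrastive runs of small MLP
heads land in noticeably different basins, and a single-run MAP over ~120
validation edges carries a binomial sd of ≈ 0.04, so averaging is
needed before a gap of ~0.1 is resolvable at all.  This is the package's
least stable headline number: the 2-layer drug head beat the linear one at
every world seed we inspected, but the *size* of the gap varies with the
world draw and on some seeds falls short of 0.1.  The instability is a
property of the small-world regime, and we report it rather than hide it.

## Numerical choices

- Cosines are computed on L2-normalized rows and clipped to [−1, 1] only
  against floating-point spill; zero rows raise immediately with the row
  index.
- Masked softmax uses the max-shift trick; excluded cells enter as −∞
  logits and receive exactly zero gradient.
- All candidate rankings break cosine ties by ascending drug id, making
  every reported metric deterministic.
- MAR normalizes the recall sum by k so it lies in [0, 1]
  (`normalized=False` reproduces the raw sum, which can exceed 1); proteins
  with an empty truth set are excluded from recall-based metrics and
  counted in a log message.
- AUROC/AUPR pool all pairs (micro) by default, matching a single-number
  readout per method; a per-protein macro variant is available.
- Degenerate cases raise rather than guess: empty candidate lists,
  single-class AUROC inputs, recall with an empty truth set, splits that
  leave no training data.

## Known limitations

- The optimizer set is minimal (Adam, SGD); no schedulers or weight decay.
- Training is single-threaded dense numpy; fine to a few 10⁴ pairs, not
  beyond.
- Likelihood scores are softmax-normalized within the presented candidate
  set only; they are comparable within one query, not across queries.
- The ablation gap's seed sensitivity, discussed above.
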