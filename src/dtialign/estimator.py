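"""Scikit-learn style estimator for contrastive protein-drug embedding alignment.

:class:`ContrastiveAligner` plays the role of a paired-matrix transformer
(compare ``sklearn.cross_decomposition.CCA``): ``fit(X, Y)`` consumes two
row-aligned matrices — row i of X is the native embedding of the protein in
the i-th observed interaction and row i of Y the embedding of its drug —
and learns two projection heads into a shared space where interacting pairs
have high cosine similarity.  Training minimizes the bidirectional
cross-entropy over in-batch negatives with Adam on hand-written gradients.
"""

from __future__ import annotations

import logging

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .embeddings import l2_normalize_rows
from .loss import WeakLabelMask, bidirectional_contrastive_loss_grad, weak_label_matrix
from .projection import ProjectionConfig, ProjectionHead, init_projection

logger = logging.getLogger(__name__)

__all__ = ["ContrastiveAligner", "sample_batches"]


def sample_batches(n: int, batch_size: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Shuffle ``range(n)`` and chunk into batches; the final short chunk is kept."""
    if batch_size < 1:
        raise ValueError(f"batch_size must be >= 1, got {batch_size}")
    order = rng.permutation(n)
    return [order[i : i + batch_size] for i in range(0, n, batch_size)]


class _Adam:
    """Minimal Adam on a flat parameter vector."""

    def __init__(self, size: int, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = np.zeros(size)
        self.v = np.zeros(size)
        self.t = 0

    def step(self, params: np.ndarray, grad: np.ndarray) -> np.ndarray:
        self.t += 1
        self.m = self.beta1 * self.m + (1 - self.beta1) * grad
        self.v = self.beta2 * self.v + (1 - self.beta2) * grad**2
        mhat = self.m / (1 - self.beta1**self.t)
        vhat = self.v / (1 - self.beta2**self.t)
        return params - self.lr * mhat / (np.sqrt(vhat) + self.eps)


class _SGD:
    def __init__(self, size: int, lr: float):
        self.lr = lr

    def step(self, params: np.ndarray, grad: np.ndarray) -> np.ndarray:
        return params - self.lr * grad


_OPTIMIZERS = {"adam": _Adam, "sgd": _SGD}


def _normalize_backward(X: np.ndarray, Xn: np.ndarray, grad_out: np.ndarray) -> np.ndarray:
    # y = x/||x|| row-wise; dL/dx = (g - (g.y) y)/||x||
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    inner = np.sum(grad_out * Xn, axis=1, keepdims=True)
    return (grad_out - inner * Xn) / norms


class ContrastiveAligner(TransformerMixin, BaseEstimator):
    """Align two embedding modalities with a CLIP-style contrastive objective.

    Parameters
    ----------
    n_components : dimension of the shared space both heads project into.
    protein_depth, drug_depth : affine layer count per head; 0 means a single
        linear (affine) projection, n >= 2 an MLP with n-1 activations.
    hidden_dim : width of hidden layers (default: ``n_components``).
    activation : 'relu', 'tanh' or 'gelu'.
    temperature : softmax temperature on cosine logits.  Cosines live in
        [-1, 1], so the default 1.0 keeps the objective faithful to a plain
        softmax over similarities.
    learnable_scale : treat the inverse temperature as a trainable scalar
        (initialized at 1/temperature and optimized jointly with the heads);
        the fitted value is exposed as ``temperature_``.
    learning_rate, batch_size, epochs, optimizer : optimization knobs.
    mask_known_positives : drop off-diagonal cells that are known true
        interactions from the softmax denominators (requires id lists and
        ``known_positives`` at fit time).  Default False: weak labels leave
        off-diagonal cells unconstrained.
    normalize_inputs : L2-normalize raw embeddings before projection.
    random_state : root seed; head initialization and batch shuffling derive
        independent streams from it.
    protein_config, drug_config : optional full :class:`ProjectionConfig`
        overrides; when given they take precedence over the scalar
        architecture parameters (their seeds included) and must agree on
        ``output_dim``.

    Attributes
    ----------
    protein_head_, drug_head_ : fitted :class:`ProjectionHead` pair.
    loss_history_ : mean training loss per epoch.
    valid_history_ : per-epoch value returned by the fit-time callback.
    n_iter_ : number of completed epochs.
    """

    def __init__(
        self,
        n_components: int = 256,
        protein_depth: int = 2,
        drug_depth: int = 2,
        hidden_dim: int | None = None,
        activation: str = "relu",
        temperature: float = 1.0,
        learnable_scale: bool = False,
        learning_rate: float = 1e-2,
        batch_size: int = 64,
        epochs: int = 50,
        optimizer: str = "adam",
        mask_known_positives: bool = False,
        normalize_inputs: bool = False,
        random_state: int = 0,
        protein_config: ProjectionConfig | None = None,
        drug_config: ProjectionConfig | None = None,
    ):
        self.n_components = n_components
        self.protein_depth = protein_depth
        self.drug_depth = drug_depth
        self.hidden_dim = hidden_dim
        self.activation = activation
        self.temperature = temperature
        self.learnable_scale = learnable_scale
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.optimizer = optimizer
        self.mask_known_positives = mask_known_positives
        self.normalize_inputs = normalize_inputs
        self.random_state = random_state
        self.protein_config = protein_config
        self.drug_config = drug_config

    # ------------------------------------------------------------------

    def _head_config(self, input_dim: int, depth: int, seed: int) -> ProjectionConfig:
        return ProjectionConfig(
            input_dim=input_dim,
            output_dim=self.n_components,
            depth=depth,
            hidden_dim=self.hidden_dim,
            activation=self.activation,
            seed=seed,
        )

    def fit(
        self,
        X: np.ndarray,
        Y: np.ndarray,
        protein_ids: list[str] | None = None,
        drug_ids: list[str] | None = None,
        known_positives: set[tuple[str, str]] | None = None,
        epoch_callback=None,
    ) -> "ContrastiveAligner":
        """Fit both heads on row-aligned positive pairs.

        X : (n_pairs, protein_dim) protein embeddings, one row per
        interaction (a protein recurring in several interactions recurs as a
        row).  Y : (n_pairs, drug_dim) drug embeddings aligned with X.
        ``epoch_callback(est, epoch)`` may return a scalar validation metric
        recorded in ``valid_history_``.
        """
        X = check_array(X, dtype=np.float64)
        Y = check_array(Y, dtype=np.float64)
        if X.shape[0] != Y.shape[0]:
            raise ValueError(
                f"X and Y must have equal row counts, got {X.shape[0]} and {Y.shape[0]}"
            )
        if X.shape[0] == 0:
            raise ValueError("cannot fit on an empty pair set")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.optimizer not in _OPTIMIZERS:
            raise ValueError(f"unknown optimizer {self.optimizer!r}")
        if self.mask_known_positives and (protein_ids is None or drug_ids is None):
            raise ValueError("mask_known_positives requires protein_ids and drug_ids")

        if self.normalize_inputs:
            X = l2_normalize_rows(X)
            Y = l2_normalize_rows(Y)

        seeds = np.random.SeedSequence(self.random_state).spawn(3)
        p_seed, m_seed = (int(s.generate_state(1)[0] % (2**31)) for s in seeds[:2])
        shuffle_rng = np.random.default_rng(seeds[2])

        p_config = self.protein_config or self._head_config(X.shape[1], self.protein_depth, p_seed)
        m_config = self.drug_config or self._head_config(Y.shape[1], self.drug_depth, m_seed)
        if p_config.input_dim != X.shape[1]:
            raise ValueError(
                f"protein head expects input_dim {p_config.input_dim}, data has {X.shape[1]}"
            )
        if m_config.input_dim != Y.shape[1]:
            raise ValueError(
                f"drug head expects input_dim {m_config.input_dim}, data has {Y.shape[1]}"
            )
        if p_config.output_dim != m_config.output_dim:
            raise ValueError(
                "protein and drug heads must share output_dim, got "
                f"{p_config.output_dim} and {m_config.output_dim}"
            )
        self.protein_head_ = init_projection(p_config)
        self.drug_head_ = init_projection(m_config)
        self.n_features_in_ = X.shape[1]

        opt_cls = _OPTIMIZERS[self.optimizer]
        p_opt = opt_cls(self.protein_head_.get_flat_params().size, self.learning_rate)
        m_opt = opt_cls(self.drug_head_.get_flat_params().size, self.learning_rate)
        self._log_scale = np.log(1.0 / self.temperature)
        s_opt = opt_cls(1, self.learning_rate) if self.learnable_scale else None

        self.loss_history_: list[float] = []
        self.valid_history_: list[float] = []
        n = X.shape[0]
        for epoch in range(self.epochs):
            batch_losses = []
            for idx in sample_batches(n, self.batch_size, shuffle_rng):
                if idx.size < 2:
                    logger.debug("skipping size-1 batch (zero contrastive signal)")
                    continue
                mask = None
                if self.mask_known_positives and known_positives:
                    mask = weak_label_matrix(
                        [protein_ids[i] for i in idx],
                        [drug_ids[i] for i in idx],
                        known_positives,
                    )
                batch_losses.append(self._step(X[idx], Y[idx], mask, p_opt, m_opt, s_opt))
            mean_loss = float(np.mean(batch_losses)) if batch_losses else 0.0
            if not np.isfinite(mean_loss):
                raise FloatingPointError(f"non-finite training loss at epoch {epoch}")
            self.loss_history_.append(mean_loss)
            if epoch_callback is not None:
                metric = epoch_callback(self, epoch)
                if metric is not None:
                    self.valid_history_.append(float(metric))
        self.n_iter_ = self.epochs
        self.temperature_ = float(np.exp(-self._log_scale))
        return self

    def _step(
        self,
        Xb: np.ndarray,
        Yb: np.ndarray,
        mask: WeakLabelMask | None,
        p_opt,
        m_opt,
        s_opt=None,
    ) -> float:
        p_cache: list = []
        m_cache: list = []
        P = self.protein_head_.forward(Xb, cache=p_cache)
        M = self.drug_head_.forward(Yb, cache=m_cache)
        Pn = l2_normalize_rows(P)
        Mn = l2_normalize_rows(M)
        sims = Pn @ Mn.T
        scale = np.exp(self._log_scale)
        # loss on scale*sims at unit temperature == loss on sims at 1/scale
        loss, g_scaled = bidirectional_contrastive_loss_grad(scale * sims, 1.0, mask)
        g_sims = g_scaled * scale
        if s_opt is not None:
            g_log_scale = float(np.sum(g_scaled * sims)) * scale
            self._log_scale = float(
                s_opt.step(np.array([self._log_scale]), np.array([g_log_scale]))[0]
            )
        g_P = _normalize_backward(P, Pn, g_sims @ Mn)
        g_M = _normalize_backward(M, Mn, g_sims.T @ Pn)
        _, p_grads = self.protein_head_.backward(g_P, p_cache)
        _, m_grads = self.drug_head_.backward(g_M, m_cache)
        self._apply(self.protein_head_, p_grads, p_opt)
        self._apply(self.drug_head_, m_grads, m_opt)
        return loss

    @staticmethod
    def _apply(head: ProjectionHead, grads, opt) -> None:
        flat_g = np.concatenate([np.concatenate([gW.ravel(), gb]) for gW, gb in grads])
        head.set_flat_params(opt.step(head.get_flat_params(), flat_g))

    # ------------------------------------------------------------------

    def transform_proteins(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "protein_head_")
        return self.protein_head_.forward(check_array(X, dtype=np.float64))

    def transform_drugs(self, Y: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "drug_head_")
        return self.drug_head_.forward(check_array(Y, dtype=np.float64))

    def transform(self, X: np.ndarray, Y: np.ndarray | None = None):
        """Project one or both modalities into the shared space.

        With only X given, returns the projected protein matrix; with both,
        returns the (protein, drug) pair of projected matrices.
        """
        if Y is None:
            return self.transform_proteins(X)
        return self.transform_proteins(X), self.transform_drugs(Y)

    def similarity(self, X: np.ndarray, Y: np.ndarray) -> np.ndarray:
        """Cosine-similarity matrix between projected proteins and drugs."""
        from .loss import cosine_similarity_matrix

        return cosine_similarity_matrix(self.transform_proteins(X), self.transform_drugs(Y))
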