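"""Adversarially trained residual-GCN link predictor.

The generator is a stack of graph-convolution layers over the symmetrically
normalised heterogeneous network ``Y_norm = D^{-1/2} (Y + I) D^{-1/2}``.
Each node's input feature is its own row of ``Y``; layer ``l`` computes
``F^l = ReLU(Y_norm F^{l-1} W^{l-1})`` and the final embedding aggregates
all layer outputs with fixed cross-level weights plus a learned linear
projection of the input (a residual-style skip), which keeps deep stacks
from over-smoothing:

    h = H0 P + sum_l w_l F^l,      w_l = 1/L by default.

Pair scores are the bilinear decoder ``S = h_d h_m^T`` over the disease and
microbe row blocks.  Training follows the weight-clipped Wasserstein-GAN
recipe: a critic with a single ReLU hidden layer and a *linear* output
scores rows of the real heterogeneous matrix against rows of the generator
reconstruction ``h h^T``; the generator minimises the negative critic value
of its reconstruction plus a binary-cross-entropy reconstruction term on
the training association block.  The reconstruction term is an addition
beyond the plain adversarial objective; it supplies direct supervision on
the (sparse) observed associations and its weight is configurable.

Everything runs in double-precision NumPy on one thread, so a fixed seed
gives bit-for-bit reproducible training.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .data import AssociationMatrix
from .similarity import (
    HeterogeneousNetwork,
    SimilarityMatrix,
    build_heterogeneous_network,
    integrated_similarities,
)


@dataclass
class NormalizedGraph:
    """Symmetrically normalised graph ``D^{-1/2} Y D^{-1/2}`` and its degrees."""

    Y_norm: np.ndarray
    degree: np.ndarray


@dataclass
class GeneratorState:
    """Learned generator parameters.

    ``P`` projects the raw input features (width n) to the embedding width;
    ``Ws[0]`` maps n -> embed_dim and ``Ws[1:]`` map embed_dim -> embed_dim.
    ``layer_weights`` are the fixed cross-level aggregation weights.
    """

    P: np.ndarray
    Ws: list[np.ndarray]
    layer_weights: np.ndarray


@dataclass
class DiscriminatorState:
    """Wasserstein critic: one ReLU hidden layer, affine (linear) output."""

    Wh: np.ndarray
    bh: np.ndarray
    Wo: np.ndarray
    bo: np.ndarray

    def params(self) -> dict[str, np.ndarray]:
        return {"Wh": self.Wh, "bh": self.bh, "Wo": self.Wo, "bo": self.bo}


@dataclass
class ScoreMatrix:
    """Predicted association scores (diseases x microbes) with provenance."""

    diseases: list[str]
    microbes: list[str]
    S: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        if self.S.shape != (len(self.diseases), len(self.microbes)):
            raise ValueError("score matrix shape does not match id registries")
        if not np.isfinite(self.S).all():
            raise ValueError("score matrix contains non-finite entries")


def normalize_graph(
    network: HeterogeneousNetwork | np.ndarray, self_loops: bool = True
) -> NormalizedGraph:
    """Symmetric degree normalisation ``D^{-1/2} (Y [+ I]) D^{-1/2}``.

    Degrees are row sums of the (optionally self-loop-augmented) matrix;
    a zero-degree node without self-loops is an error because its scaling
    is undefined.
    """
    Y = network.Y if isinstance(network, HeterogeneousNetwork) else np.asarray(network, float)
    if self_loops:
        Y = Y + np.eye(Y.shape[0])
    deg = Y.sum(axis=1)
    zero = np.nonzero(deg <= 0.0)[0]
    if zero.size:
        raise ValueError(f"zero-degree node(s) at index {zero.tolist()}; cannot normalise")
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    Y_norm = Y * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]
    return NormalizedGraph(Y_norm, deg)


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def gcn_layer(
    H_in: np.ndarray,
    W: np.ndarray,
    graph: NormalizedGraph,
    activation: str = "relu",
) -> np.ndarray:
    """One graph convolution: ``act(Y_norm @ H_in @ W)``."""
    if H_in.shape[1] != W.shape[0]:
        raise ValueError(f"shape mismatch: H_in {H_in.shape} vs W {W.shape}")
    Z = graph.Y_norm @ H_in @ W
    if activation == "relu":
        return _relu(Z)
    if activation == "identity":
        return Z
    raise ValueError(f"unknown activation {activation!r}")


def _generator_layers(
    state: GeneratorState, graph: NormalizedGraph, H0: np.ndarray
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Forward the GCN chain; returns pre-activations Z and activations F."""
    Zs, Fs = [], []
    H = H0
    for W in state.Ws:
        Z = graph.Y_norm @ H @ W
        F = _relu(Z)
        Zs.append(Z)
        Fs.append(F)
        H = F
    return Zs, Fs


def generator_embedding(
    state: GeneratorState, graph: NormalizedGraph, H0: np.ndarray
) -> np.ndarray:
    """Aggregated node embedding ``H0 P + sum_l w_l F^l``."""
    _, Fs = _generator_layers(state, graph, H0)
    h = H0 @ state.P
    for w, F in zip(state.layer_weights, Fs):
        h = h + w * F
    if not np.isfinite(h).all():
        raise FloatingPointError("non-finite generator embedding")
    return h


def generator_forward(
    state: GeneratorState,
    graph: NormalizedGraph,
    H0: np.ndarray,
    nd: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Embedding and reconstructed network; scores are ``recon[:nd, nd:]``."""
    h = generator_embedding(state, graph, H0)
    recon = h @ h.T
    return h, recon


def discriminator_forward(sample: np.ndarray, state: DiscriminatorState) -> np.ndarray:
    """Critic value(s) for flattened sample row(s): ReLU hidden, linear out."""
    X = np.atleast_2d(np.asarray(sample, float))
    if X.shape[1] != state.Wh.shape[0]:
        raise ValueError(f"sample width {X.shape[1]} != critic input {state.Wh.shape[0]}")
    u = _relu(X @ state.Wh + state.bh)
    out = u @ state.Wo + state.bo
    return out[:, 0]


class _RMSProp:
    """Minimal RMSProp with per-parameter cache (WGAN convention)."""

    def __init__(self, lr: float, rho: float = 0.9, eps: float = 1e-8) -> None:
        self.lr, self.rho, self.eps = lr, rho, eps
        self.cache: dict[str, np.ndarray] = {}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray], sign: float) -> None:
        for k, g in grads.items():
            c = self.cache.setdefault(k, np.zeros_like(g))
            c *= self.rho
            c += (1.0 - self.rho) * g * g
            params[k] += sign * self.lr * g / (np.sqrt(c) + self.eps)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class GANLinkPredictor(BaseEstimator):
    """Microbe-disease association scorer: residual GCN vs. Wasserstein critic.

    Parameters
    ----------
    n_layers : depth L of the GCN stack.
    embed_dim : embedding width (also the critic hidden width).
    epochs : adversarial training rounds N; each runs ``critic_steps``
        critic updates then one generator update.
    generator_lr, discriminator_lr : RMSProp learning rates.
    critic_steps : critic updates per generator update.
    clip_value : critic weights are clipped to ``[-clip_value, clip_value]``
        after every critic update (weight-clipped Wasserstein training).
    recon_weight : weight of the binary-cross-entropy reconstruction term on
        the training association block (0 disables it).
    adversarial_weight : weight of the critic term in the generator loss;
        the critic sees whole heterogeneous-matrix rows, so this term pushes
        the reconstruction toward the similarity structure of the network
        and acts as the main regulariser against memorising the sparse
        association block.
    weight_decay : L2 penalty on all generator weights; with the learned
        input skip each node otherwise has enough free capacity to memorise
        its training row.
    layer_weights : cross-level aggregation weights; default ``1/L`` each.
    batch_size : node rows per critic batch; default all rows.
    self_loops : add I before degree normalisation.
    noise_input : feed seeded Gaussian noise instead of the network rows as
        generator input (ablation switch).
    random_state : seed for initialisation and batch sampling.

    Attributes (after :meth:`fit`)
    ------------------------------
    generator_, discriminator_ : learned parameter states.
    scores_ : :class:`ScoreMatrix` for every disease x microbe pair.
    loss_history_ : per-epoch dict of critic and generator losses.
    network_, graph_ : heterogeneous network and its normalisation.
    """

    def __init__(
        self,
        n_layers: int = 4,
        embed_dim: int = 64,
        epochs: int = 200,
        generator_lr: float = 2e-3,
        discriminator_lr: float = 2e-3,
        critic_steps: int = 5,
        clip_value: float = 0.01,
        recon_weight: float = 1.0,
        adversarial_weight: float = 2.0,
        weight_decay: float = 0.02,
        layer_weights: Sequence[float] | None = None,
        batch_size: int | None = None,
        self_loops: bool = True,
        noise_input: bool = False,
        random_state: int = 0,
    ) -> None:
        self.n_layers = n_layers
        self.embed_dim = embed_dim
        self.epochs = epochs
        self.generator_lr = generator_lr
        self.discriminator_lr = discriminator_lr
        self.critic_steps = critic_steps
        self.clip_value = clip_value
        self.recon_weight = recon_weight
        self.adversarial_weight = adversarial_weight
        self.weight_decay = weight_decay
        self.layer_weights = layer_weights
        self.batch_size = batch_size
        self.self_loops = self_loops
        self.noise_input = noise_input
        self.random_state = random_state

    # ------------------------------------------------------------------

    def _resolved_layer_weights(self) -> np.ndarray:
        L = self.n_layers
        if L < 1:
            raise ValueError("n_layers must be >= 1")
        if self.layer_weights is None:
            w = np.full(L, 1.0 / L)
        else:
            w = np.asarray(self.layer_weights, float)
            if w.shape != (L,) or (w < 0).any():
                raise ValueError("layer_weights must have length n_layers with non-negative entries")
        return w

    def _init_states(
        self, n: int, rng: np.random.Generator
    ) -> tuple[GeneratorState, DiscriminatorState]:
        d = self.embed_dim

        def glorot(fan_in: int, fan_out: int) -> np.ndarray:
            s = np.sqrt(6.0 / (fan_in + fan_out))
            return rng.uniform(-s, s, size=(fan_in, fan_out))

        Ws = [glorot(n, d)] + [glorot(d, d) for _ in range(self.n_layers - 1)]
        gen = GeneratorState(P=glorot(n, d), Ws=Ws, layer_weights=self._resolved_layer_weights())
        disc = DiscriminatorState(
            Wh=glorot(n, d),
            bh=np.zeros(d),
            Wo=glorot(d, 1),
            bo=np.zeros(1),
        )
        return gen, disc

    # ------------------------------------------------------------------

    def fit(
        self,
        am: AssociationMatrix,
        DS: SimilarityMatrix | None = None,
        MS: SimilarityMatrix | None = None,
    ) -> "GANLinkPredictor":
        """Train on an association matrix and its fused similarity blocks.

        When ``DS``/``MS`` are omitted they are computed from ``am`` using
        the GIP and cosine views only.
        """
        if am.n_positives == 0:
            raise ValueError("association matrix has no positives; nothing to train on")
        if DS is None or MS is None:
            auto_DS, auto_MS = integrated_similarities(am)
            DS = DS or auto_DS
            MS = MS or auto_MS
        net = build_heterogeneous_network(DS, MS, am)
        graph = normalize_graph(net, self_loops=self.self_loops)
        n, nd, nm = net.Y.shape[0], am.nd, am.nm
        rng = np.random.default_rng(self.random_state)
        gen, disc = self._init_states(n, rng)

        H0 = rng.standard_normal((n, n)) if self.noise_input else net.Y.copy()
        A = am.A
        batch = min(self.batch_size or n, n)
        opt_g = _RMSProp(self.generator_lr)
        opt_d = _RMSProp(self.discriminator_lr)
        history: list[dict[str, float]] = []

        for epoch in range(self.epochs):
            h, recon = generator_forward(gen, graph, H0, nd)
            if not np.isfinite(recon).all():
                raise FloatingPointError(f"divergence (non-finite reconstruction) at epoch {epoch}")

            # -- critic updates: maximise mean c(real) - mean c(fake)
            w_dist = 0.0
            for _ in range(self.critic_steps):
                idx = rng.choice(n, size=batch, replace=False)
                real, fake = net.Y[idx], recon[idx]
                g_real, c_real = self._critic_grads(real, disc)
                g_fake, c_fake = self._critic_grads(fake, disc)
                grads = {k: g_real[k] - g_fake[k] for k in g_real}
                params = disc.params()
                opt_d.step(params, grads, sign=+1.0)
                for p in params.values():
                    np.clip(p, -self.clip_value, self.clip_value, out=p)
                w_dist = c_real - c_fake

            # -- generator update: minimise -mean c(fake) + recon_weight * BCE
            S = recon[:nd, nd:]
            P_sig = _sigmoid(S)
            eps = 1e-12
            bce = -float(np.mean(A * np.log(P_sig + eps) + (1 - A) * np.log(1 - P_sig + eps)))
            dYhat = np.zeros_like(recon)
            # adversarial part through the (frozen) critic, over all rows
            Act = recon @ disc.Wh + disc.bh
            mask = (Act > 0).astype(float)
            dYhat += -self.adversarial_weight * (mask * disc.Wo[:, 0]) @ disc.Wh.T / n
            # reconstruction part on the association block
            dYhat[:nd, nd:] += self.recon_weight * (P_sig - A) / (nd * nm)
            g_loss = (
                -self.adversarial_weight * float(np.mean(discriminator_forward(recon, disc)))
                + self.recon_weight * bce
            )
            if not np.isfinite(g_loss):
                raise FloatingPointError(f"divergence (non-finite generator loss) at epoch {epoch}")
            grads = self._generator_grads(gen, graph, H0, h, dYhat)
            if self.weight_decay:
                grads["P"] = grads["P"] + self.weight_decay * gen.P
                for i, W in enumerate(gen.Ws):
                    grads[f"W{i}"] = grads[f"W{i}"] + self.weight_decay * W
            gparams = {"P": gen.P, **{f"W{i}": W for i, W in enumerate(gen.Ws)}}
            opt_g.step(gparams, grads, sign=-1.0)

            history.append(
                {"epoch": epoch, "wasserstein": float(w_dist), "generator": g_loss, "bce": bce}
            )

        h, recon = generator_forward(gen, graph, H0, nd)
        self.generator_ = gen
        self.discriminator_ = disc
        self.network_ = net
        self.graph_ = graph
        self.input_features_ = H0
        self.embedding_ = h
        self.loss_history_ = history
        self.scores_ = ScoreMatrix(
            list(am.diseases),
            list(am.microbes),
            recon[:nd, nd:],
            provenance={"params": self.get_params(), "seed": self.random_state},
        )
        return self

    # ------------------------------------------------------------------

    @staticmethod
    def _critic_grads(
        X: np.ndarray, disc: DiscriminatorState
    ) -> tuple[dict[str, np.ndarray], float]:
        """Gradients of the mean critic value over rows of X w.r.t. params."""
        b = X.shape[0]
        a = X @ disc.Wh + disc.bh
        u = _relu(a)
        c = float(np.mean(u @ disc.Wo + disc.bo))
        du = np.broadcast_to(disc.Wo[:, 0] / b, u.shape)
        da = du * (a > 0)
        return (
            {
                "Wh": X.T @ da,
                "bh": da.sum(axis=0),
                "Wo": u.mean(axis=0)[:, None],
                "bo": np.ones(1),
            },
            c,
        )

    def _generator_grads(
        self,
        gen: GeneratorState,
        graph: NormalizedGraph,
        H0: np.ndarray,
        h: np.ndarray,
        dYhat: np.ndarray,
    ) -> dict[str, np.ndarray]:
        """Backprop d loss / d recon through ``recon = h h^T`` and the stack."""
        Zs, Fs = _generator_layers(gen, graph, H0)
        dh = (dYhat + dYhat.T) @ h
        grads: dict[str, np.ndarray] = {"P": H0.T @ dh}
        L = len(gen.Ws)
        # walk the chain backwards; D holds d loss / d F^l (total)
        D = gen.layer_weights[L - 1] * dh
        for l in range(L - 1, -1, -1):
            dZ = D * (Zs[l] > 0)
            H_prev = H0 if l == 0 else Fs[l - 1]
            grads[f"W{l}"] = (graph.Y_norm @ H_prev).T @ dZ
            if l > 0:
                D = gen.layer_weights[l - 1] * dh + graph.Y_norm.T @ (dZ @ gen.Ws[l].T)
        return grads

    # ------------------------------------------------------------------

    def predict(self, squash: bool = False) -> np.ndarray:
        """Score every pair; ``squash`` applies a sigmoid for reporting only."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "scores_")
        return _sigmoid(self.scores_.S) if squash else self.scores_.S.copy()

    def decision_function(self) -> np.ndarray:
        return self.predict(squash=False)


class DegreeProductBaseline(BaseEstimator):
    """Sanity baseline: score(d, m) = rowdeg(d) * coldeg(m) on training data."""

    def fit(self, am: AssociationMatrix, DS=None, MS=None) -> "DegreeProductBaseline":
        row = am.A.sum(axis=1)
        col = am.A.sum(axis=0)
        self.scores_ = ScoreMatrix(
            list(am.diseases), list(am.microbes), np.outer(row, col), {"model": "degree"}
        )
        return self

    def predict(self) -> np.ndarray:
        return self.scores_.S.copy()


def train(
    am: AssociationMatrix,
    DS: SimilarityMatrix | None = None,
    MS: SimilarityMatrix | None = None,
    **params,
) -> tuple[GeneratorState, ScoreMatrix, list[dict]]:
    """Functional wrapper over :class:`GANLinkPredictor`."""
    est = GANLinkPredictor(**params).fit(am, DS, MS)
    return est.generator_, est.scores_, est.loss_history_


def predict_scores(
    state: GeneratorState, graph: NormalizedGraph, H0: np.ndarray, nd: int
) -> np.ndarray:
    """Deterministic forward pass; returns the disease x microbe block."""
    _, recon = generator_forward(state, graph, H0, nd)
    return recon[:nd, nd:]
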