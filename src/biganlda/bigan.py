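"""Bidirectional adversarial network over pair-similarity feature vectors.

Three sub-networks are trained jointly on the feature vectors of *verified*
disease-lncRNA pairs (the "real" data distribution):

* an encoder ``E`` mapping a feature vector x (length nd+nl) to a latent
  code of dimension 100,
* a generator ``G`` mapping standard-normal latent noise z back to feature
  space, and
* a discriminator ``D`` that judges *joint* tuples: it should output 1 on
  encoder tuples (x, E(x)) and 0 on generator tuples (G(z), z).

The minimax value being fought over is

    V(D, E, G) = E_x[log D(x, E(x))] + E_z[log(1 - D(G(z), z))]

with D ascending and E, G descending (non-saturating cross-entropy form).
At the saddle point E and G invert each other (x = G(E(x)), z = E(G(z))),
making the encoder-generator loop an identity exactly on the manifold of
verified-association feature vectors.  At realistic problem sizes the bare
minimax never reaches that saddle point, so the bidirectional identity is
enforced directly with a cycle-consistency penalty on the E/G step, and the
association score of a candidate pair is read from how well the identity
holds for its feature vector: the root-mean-square residual
``r(x) = ||x - G(E(x))||_rms``, calibrated against the mean training
residual ``tau`` and squashed to (0, 1) as ``sigmoid(3 * (1 - r(x)/tau))``.
A pair whose vector lies on the verified-association manifold reconstructs
well (score above 0.5); an off-manifold pairing reconstructs poorly.  The
raw discriminator probability ``D(x, E(x))`` remains available via
:func:`discriminator_forward` but is not used for ranking: at desk scale
the discriminator separates real from generated tuples through channels
that are independent of where x lies relative to the data manifold, so its
probability is near-constant across candidate pairs.

``BiGANAssociationScorer`` wraps the whole procedure as a scikit-learn
style estimator (``fit`` on positive-pair vectors, ``decision_function``
for scores); the module-level ``train`` / ``score_pairs`` functions are
thin wrappers kept for pipeline scripting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .datatypes import PairFeature
from .nn import MLP, Adam, EPS, bce_loss_and_grad, sigmoid

__all__ = [
    "NetworkConfig",
    "TrainConfig",
    "BiGANModel",
    "BiGANAssociationScorer",
    "encoder_forward",
    "generator_forward",
    "discriminator_forward",
    "bigan_value",
    "train",
    "score_pairs",
    "association_scores",
    "rank_candidates",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class NetworkConfig:
    """Architecture of the three sub-networks.

    ``input_dim`` is nd + nl (6137 for the original full-scale data);
    ``latent_dim`` defaults to 100.  Each network has three fully connected
    layers with ReLU on the hidden ones; hidden widths taper geometrically
    and are freely configurable.
    """

    input_dim: int
    latent_dim: int = 100
    hidden_dims_encoder: tuple[int, ...] = (1024, 256)
    hidden_dims_generator: tuple[int, ...] = (256, 1024)
    hidden_dims_discriminator: tuple[int, ...] = (512, 128)

    def encoder_dims(self) -> list[int]:
        return [self.input_dim, *self.hidden_dims_encoder, self.latent_dim]

    def generator_dims(self) -> list[int]:
        return [self.latent_dim, *self.hidden_dims_generator, self.input_dim]

    def discriminator_dims(self) -> list[int]:
        return [self.input_dim + self.latent_dim,
                *self.hidden_dims_discriminator, 1]


@dataclass
class TrainConfig:
    """Optimisation settings; defaults are the model's reference settings
    (5 epochs, batch size 64, Adam).

    ``cycle_weight`` scales the bidirectional-consistency penalty
    ``||x - G(E(x))||^2`` added to the encoder/generator step.  The trained
    model satisfies x = G(E(x)) only at the adversarial saddle point; at
    small problem sizes the bare minimax never reaches it, so the identity
    is enforced explicitly.
    """

    epochs: int = 5
    batch_size: int = 64
    learning_rate: float = 1e-3
    seed: int = 0
    optimizer: str = "adam"
    cycle_weight: float = 10.0

    def __post_init__(self) -> None:
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")
        if self.epochs < 0 or self.batch_size < 1:
            raise ValueError("epochs must be >= 0 and batch_size >= 1")


class BiGANModel:
    """Container for the encoder, generator and discriminator networks.

    ``recon_scale_`` is set after training to the mean root-mean-square
    residual ``||x - G(E(x))||_rms`` over the training vectors; it calibrates
    association scores so that a pair reconstructing like a typical verified
    pair scores 0.5.
    """

    def __init__(self, config: NetworkConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        self.encoder = MLP(config.encoder_dims(), rng)
        self.generator = MLP(config.generator_dims(), rng)
        self.discriminator = MLP(config.discriminator_dims(), rng)
        self.seed = seed
        self.recon_scale_: float | None = None


def encoder_forward(model: BiGANModel, x: np.ndarray) -> np.ndarray:
    """Latent code E(x); accepts a single vector or a (batch, input_dim) array."""
    single = np.asarray(x).ndim == 1
    out = model.encoder.forward(x)
    return out[0] if single else out


def generator_forward(model: BiGANModel, z: np.ndarray) -> np.ndarray:
    """Generated feature vector G(z)."""
    single = np.asarray(z).ndim == 1
    out = model.generator.forward(z)
    return out[0] if single else out


def discriminator_forward(
    model: BiGANModel, x: np.ndarray, z: np.ndarray
) -> np.ndarray | float:
    """Probability that the joint tuple (x, z) comes from the data branch."""
    single = np.asarray(x).ndim == 1
    x = np.atleast_2d(np.asarray(x, dtype=float))
    z = np.atleast_2d(np.asarray(z, dtype=float))
    logits = model.discriminator.forward(np.hstack([x, z]))
    p = sigmoid(logits[:, 0])
    return float(p[0]) if single else p


def bigan_value(
    model: BiGANModel, real_batch: np.ndarray, noise_batch: np.ndarray
) -> float:
    """Empirical minimax value E_x[log D(x,E(x))] + E_z[log(1-D(G(z),z))].

    Discriminator outputs are clamped away from {0, 1} so the value stays
    finite for a saturated discriminator.
    """
    real_batch = np.atleast_2d(np.asarray(real_batch, dtype=float))
    noise_batch = np.atleast_2d(np.asarray(noise_batch, dtype=float))
    if real_batch.shape[0] == 0 or noise_batch.shape[0] == 0:
        raise ValueError("batches must be non-empty")
    e = model.encoder.forward(real_batch)
    g = model.generator.forward(noise_batch)
    p_real = np.clip(_disc_prob(model, real_batch, e), EPS, 1 - EPS)
    p_fake = np.clip(_disc_prob(model, g, noise_batch), EPS, 1 - EPS)
    return float(np.log(p_real).mean() + np.log1p(-p_fake).mean())


def _disc_prob(model: BiGANModel, x: np.ndarray, z: np.ndarray,
               cache: bool = False) -> np.ndarray:
    logits = model.discriminator.forward(np.hstack([x, z]), cache=cache)
    return sigmoid(logits[:, 0])


def bigan_value_disc_grads(
    model: BiGANModel, real_batch: np.ndarray, noise_batch: np.ndarray
) -> list[np.ndarray]:
    """Analytic gradient of the minimax value w.r.t. discriminator parameters.

    Used to cross-check backprop against finite differences; E and G are
    treated as fixed.
    """
    real_batch = np.atleast_2d(np.asarray(real_batch, dtype=float))
    noise_batch = np.atleast_2d(np.asarray(noise_batch, dtype=float))
    e = model.encoder.forward(real_batch)
    g = model.generator.forward(noise_batch)
    nr, nf = real_batch.shape[0], noise_batch.shape[0]
    tuples = np.vstack([np.hstack([real_batch, e]), np.hstack([g, noise_batch])])
    d_in = model.config.input_dim
    p = _disc_prob(model, tuples[:, :d_in], tuples[:, d_in:], cache=True)
    p = np.clip(p, EPS, 1 - EPS)
    # dV/dlogit: real term -> (1-p)/nr ; fake term -> -p/nf
    dlogit = np.empty((nr + nf, 1))
    dlogit[:nr, 0] = (1.0 - p[:nr]) / nr
    dlogit[nr:, 0] = -p[nr:] / nf
    model.discriminator.backward(dlogit)
    return [gr.copy() for gr in model.discriminator.grads()]


def train(
    features: Sequence[PairFeature] | np.ndarray,
    net_cfg: NetworkConfig,
    train_cfg: TrainConfig,
) -> BiGANModel:
    """Adversarial training on the feature vectors of verified pairs.

    Only label-1 pairs define the data distribution; generator fakes supply
    the contrast.  One discriminator ascent step then one encoder+generator
    descent step per mini-batch, for ``epochs x ceil(N / batch_size)`` steps.
    The encoder/generator step minimises the non-saturating adversarial loss
    plus ``cycle_weight`` times the bidirectional-consistency residual
    ``||x - G(E(x))||^2``.  Fully deterministic given ``train_cfg.seed``.
    """
    X = _as_matrix(features, positives_only=True)
    if X.shape[1] != net_cfg.input_dim:
        raise ValueError(
            f"feature length {X.shape[1]} != configured input_dim {net_cfg.input_dim}"
        )
    n = X.shape[0]
    if n < train_cfg.batch_size:
        raise ValueError(
            f"{n} positive pairs is fewer than batch_size={train_cfg.batch_size}; "
            "reduce batch_size"
        )
    model = BiGANModel(net_cfg, seed=train_cfg.seed)
    rng = np.random.default_rng(np.random.SeedSequence([train_cfg.seed, 1]))
    enc, gen, disc = model.encoder, model.generator, model.discriminator
    opt_d = Adam(disc.params(), lr=train_cfg.learning_rate)
    opt_eg = Adam(enc.params() + gen.params(), lr=train_cfg.learning_rate)
    d_in = net_cfg.input_dim
    for _ in range(train_cfg.epochs):
        order = rng.permutation(n)
        for start in range(0, n, train_cfg.batch_size):
            x = X[order[start:start + train_cfg.batch_size]]
            b = x.shape[0]
            z = rng.standard_normal((b, net_cfg.latent_dim))
            targets_d = np.concatenate([np.ones(b), np.zeros(b)])[:, None]

            # --- discriminator ascent on V ---
            e = enc.forward(x)
            g = gen.forward(z)
            tuples = np.vstack([np.hstack([x, e]), np.hstack([g, z])])
            p = sigmoid(disc.forward(tuples, cache=True))
            _, dp = bce_loss_and_grad(p, targets_d)
            disc.backward(dp * p * (1 - p))
            opt_d.step(disc.grads())

            # --- encoder + generator descent (non-saturating labels flipped) ---
            e = enc.forward(x, cache=True)
            g = gen.forward(z, cache=True)
            tuples = np.vstack([np.hstack([x, e]), np.hstack([g, z])])
            p = sigmoid(disc.forward(tuples, cache=True))
            _, dp = bce_loss_and_grad(p, 1.0 - targets_d)
            dtuple = disc.backward(dp * p * (1 - p))
            de_adv = dtuple[:b, d_in:]
            gen.backward(dtuple[b:, :d_in])
            gen_adv_grads = [gr.copy() for gr in gen.grads()]
            # cycle penalty: reuse the cached encoder pass; second generator pass
            recon = gen.forward(e, cache=True)
            # cycle residual summed over features, averaged over the batch
            de_cyc = gen.backward(
                train_cfg.cycle_weight * 2.0 * (recon - x) / b
            )
            gen_grads = [ga + gc for ga, gc in zip(gen_adv_grads, gen.grads())]
            enc.backward(de_adv + de_cyc)
            opt_eg.step(enc.grads() + gen_grads)
    e = enc.forward(X)
    residual = np.sqrt(((X - gen.forward(e)) ** 2).mean(axis=1))
    model.recon_scale_ = max(float(residual.mean()), 1e-12)
    return model


#: Steepness of the residual-to-probability calibration in association scores.
SCORE_GAIN = 3.0


def association_scores(model: BiGANModel, X: np.ndarray) -> np.ndarray:
    """Score feature vectors by bidirectional-consistency.

    ``sigmoid(SCORE_GAIN * (1 - r(x)/tau))`` where ``r(x)`` is the
    root-mean-square residual of the encoder-generator loop and ``tau`` the
    mean residual over the training vectors.  A vector reconstructing like a
    typical verified pair scores 0.5; better, up to ~0.95; an off-manifold
    vector decays towards 0.
    """
    if model.recon_scale_ is None:
        raise RuntimeError("model has no recon_scale_; train it first")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    recon = model.generator.forward(model.encoder.forward(X))
    residual = np.sqrt(((X - recon) ** 2).mean(axis=1))
    return sigmoid(SCORE_GAIN * (1.0 - residual / model.recon_scale_))


def score_pairs(
    model: BiGANModel, features: Sequence[PairFeature]
) -> pd.DataFrame:
    """Score (disease, lncRNA) pairs by encoder-generator consistency.

    Returns a score table with columns disease_id, lncrna_id, score,
    known_flag, one row per input pair in input order.
    """
    X = _as_matrix(features)
    if X.shape[1] != model.config.input_dim:
        raise ValueError(
            f"feature length {X.shape[1]} != model input_dim {model.config.input_dim}"
        )
    scores = association_scores(model, X)
    return pd.DataFrame({
        "disease_id": [f.disease_id for f in features],
        "lncrna_id": [f.lncrna_id for f in features],
        "score": scores,
        "known_flag": [int(f.label) for f in features],
    })


def rank_candidates(
    scores: pd.DataFrame, disease_id: str, k: int
) -> list[str]:
    """Top-k unverified lncRNAs for a disease by descending score.

    Ties are broken lexicographically by (disease_id, lncrna_id).  Returns at
    most k ids (no padding).
    """
    if k < 1:
        raise ValueError("k must be positive")
    if disease_id not in set(scores["disease_id"]):
        raise KeyError(f"disease {disease_id!r} not present in score table")
    sub = scores[(scores["disease_id"] == disease_id) &
                 (scores["known_flag"] == 0)]
    sub = sub.sort_values(["score", "disease_id", "lncrna_id"],
                          ascending=[False, True, True], kind="mergesort")
    return sub["lncrna_id"].head(k).tolist()


def _as_matrix(
    features: Sequence[PairFeature] | np.ndarray, positives_only: bool = False
) -> np.ndarray:
    if isinstance(features, np.ndarray):
        X = np.atleast_2d(np.asarray(features, dtype=float))
    else:
        feats = list(features)
        if positives_only:
            feats = [f for f in feats if f.label == 1]
        if not feats:
            raise ValueError("no feature vectors supplied")
        X = np.stack([f.vector for f in feats])
    return X


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(model: BiGANModel, path: str | Path) -> None:
    """Persist all weights plus architecture and seed to a single .npz archive."""
    arrays: dict[str, np.ndarray] = {}
    for prefix, net in (("enc", model.encoder), ("gen", model.generator),
                        ("disc", model.discriminator)):
        for key, arr in net.state_dict().items():
            arrays[f"{prefix}_{key}"] = arr
    meta = {"config": asdict(model.config), "seed": model.seed,
            "recon_scale": model.recon_scale_}
    arrays["meta_json"] = np.frombuffer(
        json.dumps(meta).encode("utf-8"), dtype=np.uint8
    )
    np.savez(path, **arrays)


def load_checkpoint(path: str | Path) -> BiGANModel:
    """Restore a model saved by :func:`save_checkpoint`; scores round-trip exactly."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta_json"]).decode("utf-8"))
        cfg_d = meta["config"]
        for key in ("hidden_dims_encoder", "hidden_dims_generator",
                    "hidden_dims_discriminator"):
            cfg_d[key] = tuple(cfg_d[key])
        model = BiGANModel(NetworkConfig(**cfg_d), seed=meta["seed"])
        model.recon_scale_ = meta.get("recon_scale")
        for prefix, net in (("enc", model.encoder), ("gen", model.generator),
                            ("disc", model.discriminator)):
            state = {
                key[len(prefix) + 1:]: data[key]
                for key in data.files if key.startswith(prefix + "_")
            }
            net.load_state_dict(state)
    return model


# ---------------------------------------------------------------------------
# scikit-learn estimator facade
# ---------------------------------------------------------------------------

class BiGANAssociationScorer(BaseEstimator):
    """Adversarially trained one-class scorer for association feature vectors.

    Fit on the feature vectors of verified pairs only (an unsupervised,
    one-class setting: y is ignored).  ``decision_function`` returns the
    bidirectional-consistency score in (0, 1); higher means the pair's
    feature vector sits closer to the verified-association manifold.

    Parameters mirror the network and optimisation settings; fitted networks
    live in ``model_``.
    """

    def __init__(
        self,
        latent_dim: int = 100,
        hidden_dims_encoder: tuple[int, ...] = (1024, 256),
        hidden_dims_generator: tuple[int, ...] = (256, 1024),
        hidden_dims_discriminator: tuple[int, ...] = (512, 128),
        epochs: int = 5,
        batch_size: int = 64,
        learning_rate: float = 1e-3,
        cycle_weight: float = 10.0,
        random_state: int = 0,
    ):
        self.latent_dim = latent_dim
        self.hidden_dims_encoder = hidden_dims_encoder
        self.hidden_dims_generator = hidden_dims_generator
        self.hidden_dims_discriminator = hidden_dims_discriminator
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.cycle_weight = cycle_weight
        self.random_state = random_state

    def fit(self, X: np.ndarray, y=None) -> "BiGANAssociationScorer":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (n_samples, nd + nl)")
        self.n_features_in_ = X.shape[1]
        net_cfg = NetworkConfig(
            input_dim=X.shape[1],
            latent_dim=self.latent_dim,
            hidden_dims_encoder=tuple(self.hidden_dims_encoder),
            hidden_dims_generator=tuple(self.hidden_dims_generator),
            hidden_dims_discriminator=tuple(self.hidden_dims_discriminator),
        )
        train_cfg = TrainConfig(
            epochs=self.epochs,
            batch_size=self.batch_size,
            learning_rate=self.learning_rate,
            cycle_weight=self.cycle_weight,
            seed=self.random_state,
        )
        self.model_ = train(X, net_cfg, train_cfg)
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "model_")
        return association_scores(self.model_, X)

    def score_samples(self, X: np.ndarray) -> np.ndarray:
        return self.decision_function(X)
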