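"""Sklearn-style estimator wrapping the mixture-of-experts aging clock.

``MoEAgeRegressor`` owns the full training procedure: Gaussian augmentation
of training samples, Adam with step-decayed learning rate, per-sample
status routing between the MAE and Hinge-MAE branches, and the per-epoch
resampled saliency-alignment (AHK) term.  All randomness flows from
``random_state`` through named substreams, so a fit is reproducible
bit-for-bit on the same build.
"""
from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from . import engine as E
from . import network as net
from .losses import LossConfig, total_loss_graph, sample_pool_subset, mae


def augment_gaussian(X: np.ndarray, copies: int, sd: float, seed: int):
    """Originals plus ``copies`` noisy replicas; returns (X_aug, source_index)."""
    if sd < 0:
        raise ValueError("augmentation sd must be non-negative")
    if copies < 0:
        raise ValueError("copies must be non-negative")
    X = np.asarray(X, dtype=np.float64)
    m = X.shape[0]
    idx = np.concatenate([np.arange(m)] * (1 + copies))
    if copies == 0:
        return X.copy(), idx
    rng = np.random.default_rng(seed)
    noisy = np.concatenate(
        [X + (rng.normal(0.0, sd, size=X.shape) if sd > 0 else 0.0) for _ in range(copies)],
        axis=0,
    )
    return np.concatenate([X, noisy], axis=0), idx


def lr_at(epoch: int, lr0: float, decay: float, decay_every: int) -> float:
    """Step schedule: lr0 × decay^⌊epoch / decay_every⌋."""
    return lr0 * decay ** (epoch // decay_every)


class _Adam:
    def __init__(self, params, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0

    def step(self, grads, lr):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data -= lr * mhat / (np.sqrt(vhat) + self.eps)


class MoEAgeRegressor(BaseEstimator, RegressorMixin):
    """Mixture-of-experts transcriptomic age regressor.

    Defaults follow the published training recipe: two experts with hidden
    widths 640/256/128/64, margin Δ=5 years, loss weights λ=30 and γ=100,
    10% of the aging-gene pool resampled per epoch, top-1000 ranked genes,
    Adam at 5e-3 with step decay 0.8, batch size 512, and 30 Gaussian-noise
    augmentation copies per training sample.

    Parameters are sklearn-conventional (``get_params``/``set_params``
    compatible); fitted state lives in trailing-underscore attributes.
    """

    def __init__(self, n_experts=2, hidden_widths=(640, 256, 128, 64), dropout_rate=0.3,
                 batch_norm=True, margin=5.0, lam=30.0, gamma=100.0, pool_fraction=0.10,
                 top_k=1000, lr=5e-3, lr_decay=0.8, decay_every=20, batch_size=512,
                 epochs=200, aug_copies=30, aug_sd=0.5, random_state=0):
        self.n_experts = n_experts
        self.hidden_widths = hidden_widths
        self.dropout_rate = dropout_rate
        self.batch_norm = batch_norm
        self.margin = margin
        self.lam = lam
        self.gamma = gamma
        self.pool_fraction = pool_fraction
        self.top_k = top_k
        self.lr = lr
        self.lr_decay = lr_decay
        self.decay_every = decay_every
        self.batch_size = batch_size
        self.epochs = epochs
        self.aug_copies = aug_copies
        self.aug_sd = aug_sd
        self.random_state = random_state

    # -- helpers -----------------------------------------------------------
    def _loss_config(self) -> LossConfig:
        return LossConfig(margin=self.margin, lam=self.lam, gamma=self.gamma,
                          pool_fraction=self.pool_fraction, top_k=self.top_k)

    @staticmethod
    def _seeds(root: int) -> dict:
        ss = np.random.SeedSequence(root)
        names = ("init", "augment", "shuffle", "pool", "dropout")
        children = ss.spawn(len(names))
        return {n: int(c.generate_state(1)[0] % (2 ** 31)) for n, c in zip(names, children)}

    # -- API ---------------------------------------------------------------
    def fit(self, X, y, status=None, pool_indices=None, validation_data=None):
        """Fit on normalized expression X (m × d) and ages y (years).

        ``status`` is an optional per-sample array of "healthy"/"unhealthy"
        (all healthy when omitted); ``pool_indices`` are column indices of
        aging-gene-pool members, required when gamma > 0 and the AHK term
        should be active; ``validation_data`` is an optional ``(X_val,
        y_val)`` pair whose healthy MAE is traced per epoch.
        """
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64).ravel()
        if X.ndim != 2 or X.shape[0] != y.size:
            raise ValueError("X must be 2-D with one row per element of y")
        if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
            raise ValueError("X and y must be finite")
        m, d = X.shape
        status = np.asarray(
            ["healthy"] * m if status is None else status, dtype=object
        ).ravel()
        if status.size != m:
            raise ValueError("status length must match the number of samples")

        seeds = self._seeds(int(self.random_state))
        cfg = self._loss_config()
        top_k = min(self.top_k, d)
        cfg = LossConfig(cfg.margin, cfg.lam, cfg.gamma, cfg.pool_fraction, top_k)
        config = net.MoEConfig(
            input_dim=d, n_experts=self.n_experts, hidden_widths=tuple(self.hidden_widths),
            dropout_rate=self.dropout_rate, batch_norm=self.batch_norm, seed=seeds["init"],
        )
        model = net.init_model(config)
        # start each expert at the mean training age so early epochs fit the
        # signal rather than the global offset
        for expert in model.experts:
            expert[-1]["b"].data[:] = float(y.mean())
        params = model.parameters()
        adam = _Adam(params)

        X_aug, src = augment_gaussian(X, int(self.aug_copies), float(self.aug_sd), seeds["augment"])
        y_aug, status_aug = y[src], status[src]

        pool_idx = None
        if pool_indices is not None:
            pool_idx = np.asarray(pool_indices, dtype=int)
        use_ahk = self.gamma > 0 and pool_idx is not None and pool_idx.size > 0

        shuffle_rng = np.random.default_rng(seeds["shuffle"])
        dropout_rng = np.random.default_rng(seeds["dropout"])
        pool_rng_root = seeds["pool"]
        n = X_aug.shape[0]
        batch = max(1, min(int(self.batch_size), n))
        history = {"epoch": [], "lr": [], "total": [], "prediction": [], "ahk": [], "val_mae": []}

        for epoch in range(int(self.epochs)):
            lr = lr_at(epoch, self.lr, self.lr_decay, int(self.decay_every))
            subset = None
            if use_ahk:
                subset = sample_pool_subset(pool_idx, self.pool_fraction,
                                            (pool_rng_root + epoch) % (2 ** 31))
            order = shuffle_rng.permutation(n)
            tot_sum = pred_sum = ahk_sum = 0.0
            n_batches = 0
            for start in range(0, n, batch):
                rows = order[start:start + batch]
                breakdown, node = total_loss_graph(
                    model, X_aug[rows], y_aug[rows], status_aug[rows], cfg,
                    pool_subset=subset if use_ahk else None,
                    mode="train", rng=dropout_rng, update_stats=True,
                )
                if not np.isfinite(breakdown.total):
                    raise RuntimeError(
                        f"non-finite loss at epoch {epoch}, batch {n_batches}; "
                        "lower the learning rate or check the inputs"
                    )
                grads = [g.data for g in E.grad(node, params)]
                adam.step(grads, lr)
                tot_sum += breakdown.total
                pred_sum += breakdown.prediction_term
                ahk_sum += breakdown.ahk_term
                n_batches += 1
            history["epoch"].append(epoch)
            history["lr"].append(lr)
            history["total"].append(tot_sum / n_batches)
            history["prediction"].append(pred_sum / n_batches)
            history["ahk"].append(ahk_sum / n_batches)
            if validation_data is not None:
                Xv, yv = validation_data
                history["val_mae"].append(mae(net.predict(model, np.asarray(Xv)), yv))
            else:
                history["val_mae"].append(np.nan)

        self.model_ = model
        self.history_ = history
        self.n_features_in_ = d
        self.pool_indices_ = pool_idx
        return self

    def predict(self, X):
        """Predicted biological age in years (eval mode, deterministic)."""
        check_is_fitted(self, "model_")
        return net.predict(self.model_, np.asarray(X, dtype=np.float64))
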