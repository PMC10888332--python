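"""Conditional encoder-decoder for multi-parameter QUS reconstruction.

One network reconstructs all four parameter maps (AC, SoS, ESD, ESC) from
plane-wave channel data.  A one-hot condition vector selects the
reconstruction objective; conditional instance normalization re-parametrizes
the encoder's feature statistics per condition, so the same convolutional
weights extract AC-relevant features under [1 0 0 0] and SoS-relevant
features under [0 1 0 0].  The encoder compresses the input to a 16 x 16
latent; a parallel multi-resolution decoder reconstructs the map at
16/32/64/128 pixels through residual convolution blocks, and the four
resolution outputs are up-sampled, concatenated and fused by bottleneck
convolutions into the final 128 x 128 image.

The learning objective is the squared error of the final output plus the
squared errors of every resolution branch against average-pooled targets
plus an L2 penalty on convolutional weights; optimization is Adam with the
standard momentum constants.  The desk-scale default (64 latent channels)
keeps the full architecture — conditioning, multi-resolution decoding,
residual blocks, the loss — at a size a CPU trains in minutes; widening
``stage_channels`` to (128, 256, 512) restores the full-capacity layout.

Implemented as a scikit-learn style estimator: ``fit(X, y, cond=...)``,
``predict(X, cond=...)``, ``get_params``/``set_params``, fitted attributes
with trailing underscores.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from . import nn
from .metrics import mnae, psnr, ssim

__all__ = [
    "PARAMETERS",
    "TARGET_RANGES",
    "condition_onehot",
    "condition_index",
    "split_dataset",
    "loss_qi",
    "ConditionalQUSNet",
]

#: condition order; index i sets bit i of the one-hot vector
PARAMETERS = ("AC", "SoS", "ESD", "ESC")

#: physical ranges used to scale each target map into [0, 1]
TARGET_RANGES = {
    "AC": (0.0, 1.5),  # dB/cm/MHz
    "SoS": (1400.0, 1700.0),  # m/s
    "ESD": (20.0, 150.0),  # um
    "ESC": (0.0, 6.0),  # /wavelength^2
}


def condition_index(cond) -> int:
    """Accepts a parameter name, an index, or a one-hot vector."""
    if isinstance(cond, str):
        return PARAMETERS.index(cond)
    arr = np.asarray(cond)
    if arr.ndim == 0:
        return int(arr)
    if arr.shape != (4,) or arr.sum() != 1 or not np.isin(arr, (0, 1)).all():
        raise ValueError("condition must be one-hot with exactly one bit set")
    return int(np.argmax(arr))


def condition_onehot(cond) -> np.ndarray:
    v = np.zeros(4, dtype=int)
    v[condition_index(cond)] = 1
    return v


def scale_target(values: np.ndarray, parameter: str) -> np.ndarray:
    lo, hi = TARGET_RANGES[parameter]
    return (np.asarray(values, dtype=np.float32) - lo) / (hi - lo)


def unscale_target(values: np.ndarray, parameter: str) -> np.ndarray:
    lo, hi = TARGET_RANGES[parameter]
    return np.asarray(values, dtype=float) * (hi - lo) + lo


def split_dataset(n: int, test_fraction: float = 1.0 / 16.5, seed: int = 0):
    """Random train/test split at the study's ratio (16.5k -> 15.5k/1k)."""
    if n < 2:
        raise ValueError("need at least 2 samples to split")
    n_test = max(1, int(round(n * test_fraction)))
    perm = np.random.default_rng(seed).permutation(n)
    return np.sort(perm[n_test:]), np.sort(perm[:n_test])


def loss_qi(final, aux, target, aux_targets, l2_lambda=0.0, weights=()):
    """Reconstruction objective: main + multi-resolution + L2 terms.

    Squared errors are summed over pixels and averaged over the batch; the
    L2 term is ``lambda * sum(w^2)`` over the given weight arrays.  Returns
    ``(total, parts)`` with the three components.
    """
    if final.shape != target.shape:
        raise ValueError("final prediction and target shapes differ")
    n = final.shape[0]
    main = float(((final - target) ** 2).sum() / n)
    l_r = 0.0
    for r in sorted(aux):
        if aux[r].shape != aux_targets[r].shape:
            raise ValueError(f"auxiliary shape mismatch at resolution {r}")
        l_r += float(((aux[r] - aux_targets[r]) ** 2).sum() / n)
    l2 = float(l2_lambda * sum((w**2).sum() for w in weights))
    return main + l_r + l2, {"main": main, "L_R": l_r, "L2": l2}


class ConditionalQUSNet(BaseEstimator):
    """Conditional encoder-decoder QUS reconstruction network.

    Parameters
    ----------
    stage_channels : tuple of int
        Encoder widths per stride-2 stage; the last entry is the latent
        channel count (desk default 64; full scale 512).
    branch_channels : tuple of int
        Decoder width per resolution branch (16, 32, 64, 128 pixels).
    lr, beta1, beta2 : float
        Adam hyperparameters.
    batch_size, max_epochs, patience : int
        Training loop controls; early stopping monitors validation loss.
    dropout_retention : float
        Keep probability of the latent dropout.
    l2 : float
        Weight of the L2 penalty on convolution weights.
    seed : int
        Controls initialization, the train/validation split, shuffling and
        dropout; a fixed seed reproduces the loss curve exactly.
    """

    RESOLUTIONS = (16, 32, 64, 128)

    def __init__(
        self,
        stage_channels=(16, 32, 64),
        branch_channels=(64, 32, 16, 8),
        input_channels=8,
        lr=1e-4,
        beta1=0.9,
        beta2=0.999,
        batch_size=8,
        max_epochs=120,
        patience=10,
        dropout_retention=0.5,
        l2=1e-4,
        norm_eps=1e-5,
        cin_init_spread=0.1,
        seed=0,
    ):
        self.stage_channels = stage_channels
        self.branch_channels = branch_channels
        self.input_channels = input_channels
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.dropout_retention = dropout_retention
        self.l2 = l2
        self.norm_eps = norm_eps
        self.cin_init_spread = cin_init_spread
        self.seed = seed

    # ---------------------------------------------------------------- build

    def _build(self):
        rng = np.random.default_rng(self.seed)
        self.encoder_ = []
        c_in = self.input_channels
        for c_out in self.stage_channels:
            self.encoder_.append(
                {
                    "conv": nn.Conv2d(c_in, c_out, k=3, stride=2, rng=rng),
                    "norm": nn.ConditionalInstanceNorm(
                        c_out,
                        eps=self.norm_eps,
                        init_spread=self.cin_init_spread,
                        rng=rng,
                    ),
                    "relu": nn.ReLU(),
                }
            )
            c_in = c_out
        self.latent_channels_ = c_in
        self.dropout_ = nn.Dropout(self.dropout_retention)
        self.branches_ = []
        for r, bc in zip(self.RESOLUTIONS, self.branch_channels):
            self.branches_.append(
                {
                    "res": r,
                    "factor": r // 16,
                    "proj": nn.Conv2d(c_in, bc, k=1, rng=rng),
                    "conv1": nn.Conv2d(bc, bc, k=3, rng=rng),
                    "relu1": nn.ReLU(),
                    "conv2": nn.Conv2d(bc, bc, k=3, rng=rng, zero_init=True),
                    "head": nn.Conv2d(bc, 1, k=1, rng=rng),
                }
            )
        self.fuse_conv_ = nn.Conv2d(len(self.RESOLUTIONS), 8, k=3, rng=rng)
        self.fuse_relu_ = nn.ReLU()
        self.out_conv_ = nn.Conv2d(8, 1, k=1, rng=rng)
        # mid-range output prior: predictions start at 0.5 on the [0, 1] scale
        self.out_conv_.b[:] = 0.5

    def _modules(self):
        mods = {}
        for i, st in enumerate(self.encoder_):
            mods[f"enc{i}_conv"] = st["conv"]
            mods[f"enc{i}_norm"] = st["norm"]
        for br in self.branches_:
            r = br["res"]
            for name in ("proj", "conv1", "conv2", "head"):
                mods[f"br{r}_{name}"] = br[name]
        mods["fuse"] = self.fuse_conv_
        mods["out"] = self.out_conv_
        return mods

    def _param_dict(self):
        params, grads = {}, {}
        for mname, mod in self._modules().items():
            for pname, arr in mod.params().items():
                params[f"{mname}.{pname}"] = arr
                grads[f"{mname}.{pname}"] = mod.grads[pname]
        return params, grads

    def _conv_weights(self):
        return [
            mod.w for mod in self._modules().values() if isinstance(mod, nn.Conv2d)
        ]

    def _zero_grads(self):
        for mod in self._modules().values():
            for g in mod.grads.values():
                g[...] = 0.0

    # -------------------------------------------------------------- forward

    def _forward(self, x, cond_idx, train=False, rng=None):
        h = x
        for st in self.encoder_:
            h = st["relu"].forward(st["norm"].forward(st["conv"].forward(h), cond_idx))
        if h.shape[2] != 16 or h.shape[3] != 16:
            raise ValueError(
                f"input spatial size {x.shape[2:]} does not reduce to the "
                f"16 x 16 latent (got {h.shape[2:]})"
            )
        q = self.dropout_.forward(h, rng or np.random.default_rng(0), train)
        aux = {}
        feats = []
        for br in self.branches_:
            p = br["proj"].forward(q)
            u = nn.upsample_nearest(p, br["factor"])
            res = u + br["conv2"].forward(br["relu1"].forward(br["conv1"].forward(u)))
            out = br["head"].forward(res)
            aux[br["res"]] = out[:, 0]
            feats.append(nn.upsample_nearest(out, 128 // br["res"]))
        cat = np.concatenate(feats, axis=1)
        self._cat_shape = cat.shape
        final = self.out_conv_.forward(
            self.fuse_relu_.forward(self.fuse_conv_.forward(cat))
        )[:, 0]
        return final, aux

    def _backward(self, dfinal, daux):
        g = self.out_conv_.backward(dfinal[:, None])
        g = self.fuse_conv_.backward(self.fuse_relu_.backward(g))
        dq = None
        for i, br in enumerate(self.branches_):
            gi = nn.downsample_sum(g[:, i : i + 1], 128 // br["res"])
            gi = gi + daux[br["res"]][:, None]
            gres = br["head"].backward(gi)
            gskip = br["conv1"].backward(
                br["relu1"].backward(br["conv2"].backward(gres))
            )
            gu = gres + gskip
            gp = nn.downsample_sum(gu, br["factor"])
            gq = br["proj"].backward(gp)
            dq = gq if dq is None else dq + gq
        h = self.dropout_.backward(dq)
        for st in reversed(self.encoder_):
            h = st["conv"].backward(st["norm"].backward(st["relu"].backward(h)))
        return h

    # ------------------------------------------------------------------ fit

    def fit(self, X, y, cond=None, validation=None):
        """Train on (channel-data stack, condition, target map) triples.

        ``X``: (n, channels, 128, 128); ``y``: (n, 128, 128) targets on the
        [0, 1] scale; ``cond``: per-sample condition (names, indices or
        one-hot rows).  ``validation`` optionally supplies an explicit
        ``(X_val, y_val, cond_val)``; otherwise a split at the study ratio
        is carved from the data.  Records per-epoch training loss and
        validation loss/MNAE/PSNR/SSIM in ``history_``.
        """
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y, dtype=np.float32)
        if X.ndim != 4 or y.ndim != 3 or len(X) != len(y):
            raise ValueError("X must be (n, c, h, w) and y (n, h, w)")
        if len(X) == 0:
            raise ValueError("empty dataset")
        cond_idx = np.array(
            [condition_index(c) for c in (cond if cond is not None else [0] * len(X))]
        )

        if validation is None:
            tr, va = split_dataset(len(X), seed=self.seed)
            X_val, y_val, cv = X[va], y[va], cond_idx[va]
            X, y, cond_idx = X[tr], y[tr], cond_idx[tr]
        else:
            X_val, y_val, cv = validation
            X_val = np.asarray(X_val, dtype=np.float32)
            y_val = np.asarray(y_val, dtype=np.float32)
            cv = np.array([condition_index(c) for c in cv])

        self._build()
        params, grads = self._param_dict()
        opt = nn.Adam(params, lr=self.lr, beta1=self.beta1, beta2=self.beta2)
        rng = np.random.default_rng(self.seed + 1)

        self.history_ = {
            "train_loss": [],
            "val_loss": [],
            "val_mnae": [],
            "val_psnr": [],
            "val_ssim": [],
        }
        best_val = np.inf
        best_state = None
        stall = 0
        n = len(X)
        for epoch in range(self.max_epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            n_batches = 0
            for lo in range(0, n, self.batch_size):
                idx = order[lo : lo + self.batch_size]
                xb, yb, cb = X[idx], y[idx], cond_idx[idx]
                self._zero_grads()
                final, aux = self._forward(xb, cb, train=True, rng=rng)
                aux_t = {
                    r: nn.avg_pool(yb[:, None], 128 // r)[:, 0] for r in self.RESOLUTIONS
                }
                total, _ = loss_qi(
                    final, aux, yb, aux_t, self.l2, self._conv_weights()
                )
                nb = len(idx)
                dfinal = 2.0 * (final - yb) / nb
                daux = {r: 2.0 * (aux[r] - aux_t[r]) / nb for r in self.RESOLUTIONS}
                self._backward(dfinal, daux)
                for key, p in params.items():
                    if key.endswith(".w"):
                        grads[key] += 2.0 * self.l2 * p
                opt.step(grads)
                epoch_loss += total
                n_batches += 1
            self.history_["train_loss"].append(epoch_loss / n_batches)

            vloss, vm, vp, vs = self._evaluate(X_val, y_val, cv)
            self.history_["val_loss"].append(vloss)
            self.history_["val_mnae"].append(vm)
            self.history_["val_psnr"].append(vp)
            self.history_["val_ssim"].append(vs)

            if vloss < best_val - 1e-9:
                best_val = vloss
                best_state = {k: v.copy() for k, v in params.items()}
                stall = 0
            else:
                stall += 1
                if stall >= self.patience:
                    break
        if best_state is not None:
            for k, v in params.items():
                v[...] = best_state[k]
        self.n_epochs_ = len(self.history_["train_loss"])
        self.is_fitted_ = True
        return self

    def _evaluate(self, X, y, cond_idx, batch=16):
        tot, n = 0.0, len(X)
        preds = []
        for lo in range(0, n, batch):
            f, aux = self._forward(X[lo : lo + batch], cond_idx[lo : lo + batch])
            aux_t = {
                r: nn.avg_pool(y[lo : lo + batch][:, None], 128 // r)[:, 0]
                for r in self.RESOLUTIONS
            }
            t, _ = loss_qi(f, aux, y[lo : lo + batch], aux_t, self.l2, self._conv_weights())
            tot += t * len(f)
            preds.append(f)
        pred = np.concatenate(preds)
        return (
            tot / n,
            mnae(pred, y, data_range=1.0),
            psnr(pred, y, data_range=1.0),
            float(np.mean([ssim(p, t, data_range=1.0) for p, t in zip(pred, y)])),
        )

    # -------------------------------------------------------------- predict

    def predict(self, X, cond=None):
        """Reconstruct the parameter map selected by the condition."""
        if not getattr(self, "is_fitted_", False):
            raise RuntimeError("network is not trained; call fit first")
        X = np.asarray(X, dtype=np.float32)
        cond_idx = np.array(
            [condition_index(c) for c in (cond if cond is not None else [0] * len(X))]
        )
        final, _ = self._forward(X, cond_idx)
        return final

    def forward_full(self, X, cond=None, train=False, rng=None):
        """Final output plus the per-resolution auxiliary outputs."""
        if not hasattr(self, "encoder_"):
            self._build()
        X = np.asarray(X, dtype=np.float32)
        cond_idx = np.array(
            [condition_index(c) for c in (cond if cond is not None else [0] * len(X))]
        )
        return self._forward(X, cond_idx, train=train, rng=rng)

    def encode(self, X, cond=None):
        """Latent features q (n, channels, 16, 16) for the given condition."""
        if not hasattr(self, "encoder_"):
            self._build()
        X = np.asarray(X, dtype=np.float32)
        cond_idx = np.array(
            [condition_index(c) for c in (cond if cond is not None else [0] * len(X))]
        )
        h = X
        for st in self.encoder_:
            h = st["relu"].forward(st["norm"].forward(st["conv"].forward(h), cond_idx))
        if h.shape[2] != 16 or h.shape[3] != 16:
            raise ValueError("input spatial size does not reduce to 16 x 16")
        return h
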