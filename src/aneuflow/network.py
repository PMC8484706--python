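"""Double-input, double-sampling-channel point-cloud regression network.

The network maps a pair of point clouds to per-point hemodynamic values:

* **global channel** — shared per-point layers lift each *model-cloud* point
  (boundary coordinates) to a 512-d feature; a symmetric max reduction over
  points yields one order-invariant 512-d geometry descriptor, tiled to
  every query point;
* **local channel** — the same shared primary stage (FC1/FC2 weight sharing)
  followed by a 128-d per-point head embeds each *query-cloud* point;
* the two are stitched into a 640-d (512+128) per-point feature and an
  output stack regresses velocity (3 components) or pressure (1 value)
  point by point.

Training minimizes the mean absolute error with Adam (lr 0.001, beta1 0.9,
beta2 0.999, eps 1e-8), one model per optimization step, holding out a
validation fraction and checkpointing the lowest-validation-loss weights.

The whole forward/backward pass is written in NumPy (float32) and wrapped in
a scikit-learn-style estimator: ``fit(X, y)`` with ``X`` a list of
``(model_points, query_points)`` pairs and ``y`` a list of per-query-point
target arrays; ``predict`` returns one array per pair.

Inputs are centered per pair on the model-cloud centroid (translation
invariance) and scaled by a single train-set-wide radius: per-pair scaling
would erase absolute vessel size, which — at fixed inlet mass flow — is what
sets the velocity magnitude.  Targets are standardized per data set.
"""

from __future__ import annotations

import json
from typing import List, Sequence, Tuple

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = ["DualPointNetRegressor", "forward", "train", "predict",
           "save_model", "load_model"]

DT = np.float32


def _relu(x):
    return np.maximum(x, DT(0.0))


def _init_stage(rng, widths: Sequence[int]) -> List[List[np.ndarray]]:
    """He-initialized dense layers [(W, b), ...] for consecutive widths."""
    layers = []
    for fan_in, fan_out in zip(widths[:-1], widths[1:]):
        W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out)).astype(DT)
        b = np.zeros(fan_out, dtype=DT)
        layers.append([W, b])
    return layers


def _stage_forward(x, layers, final_linear=False):
    cache = []
    for li, (W, b) in enumerate(layers):
        z = x @ W + b
        out = z if (final_linear and li == len(layers) - 1) else _relu(z)
        cache.append((x, out))
        x = out
    return x, cache


def _stage_backward(dout, layers, cache, final_linear=False):
    grads = []
    for li in range(len(layers) - 1, -1, -1):
        W, _ = layers[li]
        x_in, out = cache[li]
        if not (final_linear and li == len(layers) - 1):
            dout = dout * (out > 0)
        grads.append([x_in.T @ dout, dout.sum(axis=0)])
        dout = dout @ W.T
    grads.reverse()
    return dout, grads


class DualPointNetRegressor(BaseEstimator, RegressorMixin):
    """Per-point hemodynamics regressor on (model cloud, query cloud) pairs.

    Parameters
    ----------
    output_dim : 3 for velocity, 1 for pressure.
    shared_widths : hidden widths of the shared primary stage applied
        per-point in both channels (FC1/FC2 weight sharing).
    global_hidden, global_dim : widths of the global channel after the shared
        stage; a coordinate-wise max over model points reduces the final
        ``global_dim`` features to one geometry vector.
    local_dim : per-query-point feature width; the stitched feature has
        ``local_dim + global_dim`` dimensions (128 + 512 = 640).
    head_widths : hidden widths of the output stack (final layer linear).
    learning_rate, adam_* : Adam hyperparameters; one model per step
        (batch_models is fixed at 1 by construction).
    max_epochs, patience, min_epochs : training length and early stopping on
        the validation loss; the best-validation weights are kept.
    val_fraction : fraction of training pairs held out for validation
        (skipped for < 5 pairs, where the training loss is monitored).
    max_query_points, max_model_points : per-step subsample sizes keeping a
        step affordable on large clouds (prediction always uses all points).
    share_first_stage : disable to give each channel its own primary stage.
    random_state : seeds initialization, subsampling and the split.

    Attributes
    ----------
    weights_ : dict of layer lists per stage.
    scale_ : global input scale (median model-cloud bounding radius), m.
    y_mean_, y_std_ : per-component target standardization.
    history_ : per-epoch (train MAE, validation MAE) in standardized units.
    best_epoch_, n_iter_ : checkpointed epoch and epochs run.
    """

    def __init__(self, output_dim: int = 3,
                 shared_widths: Tuple[int, ...] = (64, 64, 128),
                 global_hidden: Tuple[int, ...] = (256,),
                 global_dim: int = 512,
                 local_dim: int = 128,
                 head_widths: Tuple[int, ...] = (256, 128),
                 learning_rate: float = 1e-3,
                 lr_schedule: str = "cosine",
                 adam_beta1: float = 0.9,
                 adam_beta2: float = 0.999,
                 adam_eps: float = 1e-8,
                 max_epochs: int = 30,
                 patience: int = 5,
                 min_epochs: int = 3,
                 val_fraction: float = 0.1,
                 target_scale_exponent: float = 0.0,
                 max_query_points: int = 800,
                 max_model_points: int = 400,
                 max_val_points: int = 1500,
                 share_first_stage: bool = True,
                 random_state: int = 0,
                 verbose: int = 0):
        self.output_dim = output_dim
        self.shared_widths = shared_widths
        self.global_hidden = global_hidden
        self.global_dim = global_dim
        self.local_dim = local_dim
        self.head_widths = head_widths
        self.learning_rate = learning_rate
        self.lr_schedule = lr_schedule
        self.adam_beta1 = adam_beta1
        self.adam_beta2 = adam_beta2
        self.adam_eps = adam_eps
        self.max_epochs = max_epochs
        self.patience = patience
        self.min_epochs = min_epochs
        self.val_fraction = val_fraction
        self.target_scale_exponent = target_scale_exponent
        self.max_query_points = max_query_points
        self.max_model_points = max_model_points
        self.max_val_points = max_val_points
        self.share_first_stage = share_first_stage
        self.random_state = random_state
        self.verbose = verbose

    # -- plumbing ---------------------------------------------------------
    @property
    def stitched_dim(self) -> int:
        return self.local_dim + self.global_dim

    def _init_weights(self, rng) -> dict:
        shared = _init_stage(rng, (3, *self.shared_widths))
        weights = {
            "shared": shared,
            "global": _init_stage(rng, (self.shared_widths[-1], *self.global_hidden,
                                        self.global_dim)),
            "local": _init_stage(rng, (self.shared_widths[-1], self.local_dim)),
            "head": _init_stage(rng, (self.stitched_dim, *self.head_widths,
                                      self.output_dim)),
        }
        if not self.share_first_stage:
            weights["shared_q"] = _init_stage(rng, (3, *self.shared_widths))
        return weights

    def _param_list(self, weights) -> List[np.ndarray]:
        order = ["shared"] + (["shared_q"] if "shared_q" in weights else []) \
            + ["global", "local", "head"]
        return [arr for stage in order for layer in weights[stage] for arr in layer]

    @staticmethod
    def _validate_pair(pair) -> Tuple[np.ndarray, np.ndarray]:
        model_pts, query_pts = pair
        model_pts = np.asarray(model_pts, dtype=float).reshape(-1, 3)
        query_pts = np.asarray(query_pts, dtype=float).reshape(-1, 3)
        if len(model_pts) == 0 or len(query_pts) == 0:
            raise ValueError("clouds must be non-empty")
        return model_pts, query_pts

    @staticmethod
    def _inlet_radius(model_pts):
        """Lumen radius read off the inlet-cap points (pose convention: inlet plane x = 0).

        Returns None when the cloud carries no resolvable inlet cap.
        """
        cap = model_pts[np.abs(model_pts[:, 0]) < 1e-9]
        if len(cap) < 3:
            return None
        return float(np.linalg.norm(cap[:, 1:], axis=1).max())

    def _target_factor(self, model_pts) -> float:
        """Per-pair target scale (R/R_ref)^p, computed from inputs only.

        With a fixed inlet mass flow the field magnitude scales as a power of
        the lumen radius (v_mean ~ R^-2, axial pressure drop ~ R^-3);
        dividing it out lets the network learn a dimensionless field shape.
        """
        if not self.target_scale_exponent or getattr(self, "inlet_ref_radius_", None) is None:
            return 1.0
        r = self._inlet_radius(model_pts)
        if r is None or r <= 0:
            return 1.0
        return float((r / self.inlet_ref_radius_) ** self.target_scale_exponent)

    def _normalize(self, model_pts, query_pts, scale):
        center = model_pts.mean(axis=0)
        return (((model_pts - center) / scale).astype(DT),
                ((query_pts - center) / scale).astype(DT))

    def _forward(self, weights, model_n, query_n, need_cache=False):
        shared_q = weights.get("shared_q", weights["shared"])
        am, cache_m = _stage_forward(model_n, weights["shared"])
        gm, cache_g = _stage_forward(am, weights["global"])
        g = gm.max(axis=0)
        argmax = gm.argmax(axis=0)
        bq, cache_q = _stage_forward(query_n, shared_q)
        lq, cache_l = _stage_forward(bq, weights["local"])
        h = np.concatenate([lq, np.broadcast_to(g, (len(lq), len(g)))], axis=1)
        out, cache_h = _stage_forward(h, weights["head"], final_linear=True)
        if not need_cache:
            return out
        return out, (cache_m, cache_g, argmax, cache_q, cache_l, cache_h, gm.shape)

    def _backward(self, weights, cache, dout):
        cache_m, cache_g, argmax, cache_q, cache_l, cache_h, gm_shape = cache
        dh, g_head = _stage_backward(dout, weights["head"], cache_h, final_linear=True)
        dlq = dh[:, :self.local_dim]
        dg = dh[:, self.local_dim:].sum(axis=0)
        dbq, g_local = _stage_backward(dlq, weights["local"], cache_l)
        shared_q = weights.get("shared_q", weights["shared"])
        _, g_shared_q = _stage_backward(dbq, shared_q, cache_q)
        dgm = np.zeros(gm_shape, dtype=DT)
        dgm[argmax, np.arange(gm_shape[1])] = dg
        dam, g_global = _stage_backward(dgm, weights["global"], cache_g)
        _, g_shared_m = _stage_backward(dam, weights["shared"], cache_m)
        if "shared_q" in weights:
            g_shared = g_shared_m
            grads = {"shared": g_shared, "shared_q": g_shared_q,
                     "global": g_global, "local": g_local, "head": g_head}
        else:
            g_shared = [[a + b for a, b in zip(la, lb)]
                        for la, lb in zip(g_shared_m, g_shared_q)]
            grads = {"shared": g_shared, "global": g_global,
                     "local": g_local, "head": g_head}
        return self._param_list(grads)

    # -- sklearn API ------------------------------------------------------
    def fit(self, X, y):
        """Train on pairs ``X`` with per-point targets ``y`` (MAE loss, Adam)."""
        if len(X) != len(y) or len(X) == 0:
            raise ValueError("X and y must be equally long and non-empty")
        pairs = []
        targets = []
        for pair, t in zip(X, y):
            m, q = self._validate_pair(pair)
            t = np.asarray(t, dtype=float)
            t = t.reshape(len(q), -1)
            if t.shape[1] != self.output_dim:
                raise ValueError(
                    f"target has {t.shape[1]} components, expected {self.output_dim}")
            if not np.all(np.isfinite(t)):
                raise ValueError("non-finite target values")
            pairs.append((m, q))
            targets.append(t)

        rng = np.random.default_rng(self.random_state)
        radii = [np.linalg.norm(m - m.mean(axis=0), axis=1).max() for m, _ in pairs]
        self.scale_ = float(np.median(radii))
        self.inlet_ref_radius_ = None
        if self.target_scale_exponent:
            inlet_radii = [self._inlet_radius(m) for m, _ in pairs]
            if all(r is not None for r in inlet_radii):
                self.inlet_ref_radius_ = float(np.median(inlet_radii))
        factors = [self._target_factor(m) for m, _ in pairs]
        targets = [t * f for t, f in zip(targets, factors)]
        allt = np.concatenate(targets, axis=0)
        self.y_mean_ = allt.mean(axis=0)
        # vector targets share one scale: per-component standardization would
        # inflate the small transverse components and unbalance the MAE loss
        if self.output_dim > 1:
            self.y_std_ = np.full(self.output_dim, max(float(allt.std()), 1e-12))
        else:
            self.y_std_ = np.maximum(allt.std(axis=0), 1e-12)
        targets_std = [((t - self.y_mean_) / self.y_std_).astype(DT) for t in targets]

        weights = self._init_weights(rng)
        params = self._param_list(weights)
        m_adam = [np.zeros_like(p) for p in params]
        v_adam = [np.zeros_like(p) for p in params]
        t_adam = 0

        n = len(pairs)
        n_val = int(round(self.val_fraction * n)) if n >= 5 else 0
        order = rng.permutation(n)
        val_idx = order[:n_val]
        train_idx = order[n_val:]
        norm_pairs = [self._normalize(m, q, self.scale_) for m, q in pairs]
        val_sub = {}
        for i in val_idx:
            nq = len(norm_pairs[i][1])
            val_sub[i] = (rng.choice(nq, size=min(self.max_val_points, nq), replace=False)
                          if nq > self.max_val_points else np.arange(nq))

        def monitor_loss(w):
            idx = val_idx if n_val else train_idx
            tot, cnt = 0.0, 0
            for i in idx:
                mn, qn = norm_pairs[i]
                sub = val_sub.get(i, slice(None))
                pred = self._forward(w, mn, qn[sub])
                err = np.abs(pred - targets_std[i][sub])
                tot += float(err.sum())
                cnt += err.size
            return tot / max(cnt, 1)

        b1, b2, eps = DT(self.adam_beta1), DT(self.adam_beta2), DT(self.adam_eps)
        if self.lr_schedule not in ("cosine", "constant"):
            raise ValueError("lr_schedule must be 'cosine' or 'constant'")
        best_loss = np.inf
        best_weights = None
        best_epoch = 0
        self.history_ = []
        since_best = 0
        for epoch in range(1, self.max_epochs + 1):
            if self.lr_schedule == "cosine":
                # MAE sign gradients keep a constant-magnitude noise floor under
                # Adam; annealing the step is what lets the loss keep falling
                lr = DT(self.learning_rate * 0.5
                        * (1.0 + np.cos(np.pi * (epoch - 1) / max(self.max_epochs - 1, 1))))
            else:
                lr = DT(self.learning_rate)
            epoch_mae, epoch_n = 0.0, 0
            for i in rng.permutation(train_idx):
                mn, qn = norm_pairs[i]
                if len(mn) > self.max_model_points:
                    mn = mn[rng.choice(len(mn), self.max_model_points, replace=False)]
                if len(qn) > self.max_query_points:
                    qsub = rng.choice(len(qn), self.max_query_points, replace=False)
                    qn_s, t_s = qn[qsub], targets_std[i][qsub]
                else:
                    qn_s, t_s = qn, targets_std[i]
                out, cache = self._forward(weights, mn, qn_s, need_cache=True)
                err = out - t_s
                epoch_mae += float(np.abs(err).sum())
                epoch_n += err.size
                dout = (np.sign(err) / DT(err.size)).astype(DT)
                grads = self._backward(weights, cache, dout)
                t_adam += 1
                corr = np.sqrt(1.0 - float(b2) ** t_adam) / (1.0 - float(b1) ** t_adam)
                for p, g, mm, vv in zip(params, grads, m_adam, v_adam):
                    mm *= b1
                    mm += (1 - b1) * g
                    vv *= b2
                    vv += (1 - b2) * g * g
                    p -= lr * DT(corr) * mm / (np.sqrt(vv) + eps)
            mon = monitor_loss(weights)
            self.history_.append((epoch_mae / max(epoch_n, 1), mon))
            if self.verbose:
                print(f"epoch {epoch:3d}  train MAE {self.history_[-1][0]:.5f}  "
                      f"monitor MAE {mon:.5f}")
            if mon < best_loss - 1e-7:
                best_loss = mon
                best_weights = {k: [[W.copy(), b.copy()] for W, b in v]
                                for k, v in weights.items()}
                best_epoch = epoch
                since_best = 0
            else:
                since_best += 1
                if epoch >= self.min_epochs and since_best >= self.patience:
                    break
        self.weights_ = best_weights if best_weights is not None else weights
        self.best_epoch_ = best_epoch
        self.best_val_mae_ = float(best_loss)
        self.n_iter_ = len(self.history_)
        return self

    def predict(self, X) -> List[np.ndarray]:
        """Predict per-point targets for each pair; never mutates inputs."""
        check_is_fitted(self, "weights_")
        out = []
        for pair in X:
            m, q = self._validate_pair(pair)
            mn, qn = self._normalize(m, q, self.scale_)
            pred = self._forward(self.weights_, mn, qn)
            f = self._target_factor(m)
            out.append((pred.astype(float) * self.y_std_ + self.y_mean_) / f)
        return out

    def forward_raw(self, model_pts, query_pts) -> np.ndarray:
        """Standardized-space forward pass; initializes weights if unfitted.

        Used for architecture-level property checks (permutation behaviour)
        that do not require training.
        """
        m, q = self._validate_pair((model_pts, query_pts))
        if not hasattr(self, "weights_") or self.weights_ is None:
            self.weights_ = self._init_weights(np.random.default_rng(self.random_state))
        scale = getattr(self, "scale_", None)
        if scale is None:
            scale = float(np.linalg.norm(m - m.mean(axis=0), axis=1).max()) or 1.0
        mn, qn = self._normalize(m, q, scale)
        return self._forward(self.weights_, mn, qn)


# -- functional wrappers ---------------------------------------

def forward(model_cloud, query_coords, model: DualPointNetRegressor) -> np.ndarray:
    """Per-query-point network output (standardized space if unfitted)."""
    if hasattr(model, "weights_") and hasattr(model, "y_mean_"):
        return model.predict([(model_cloud, query_coords)])[0]
    return model.forward_raw(model_cloud, query_coords)


def train(train_pairs, targets, output_dim: int = 3, seed: int = 0,
          **config) -> DualPointNetRegressor:
    """Fit a fresh estimator on ``(model, query)`` pairs and target arrays."""
    est = DualPointNetRegressor(output_dim=output_dim, random_state=seed, **config)
    return est.fit(train_pairs, targets)


def predict(model: DualPointNetRegressor, model_cloud, query_coords) -> np.ndarray:
    """Predictions for one pair (shape (N2, output_dim))."""
    return model.predict([(model_cloud, query_coords)])[0]


# -- checkpointing ---------------------------------------------------------

def save_model(model: DualPointNetRegressor, path) -> None:
    """Serialize a fitted estimator (config + weights) to one .npz checkpoint."""
    check_is_fitted(model, "weights_")
    arrays = {}
    layout = {}
    for stage, layers in model.weights_.items():
        layout[stage] = len(layers)
        for li, (W, b) in enumerate(layers):
            arrays[f"{stage}_{li}_W"] = W
            arrays[f"{stage}_{li}_b"] = b
    meta = {"params": model.get_params(), "layout": layout,
            "scale": model.scale_, "y_mean": model.y_mean_.tolist(),
            "y_std": model.y_std_.tolist(),
            "inlet_ref_radius": getattr(model, "inlet_ref_radius_", None),
            "best_epoch": getattr(model, "best_epoch_", 0),
            "history": getattr(model, "history_", [])}
    arrays["meta_json"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_model(path) -> DualPointNetRegressor:
    """Restore a checkpoint written by :func:`save_model`."""
    with np.load(path) as npz:
        meta = json.loads(bytes(npz["meta_json"]).decode())
        params = meta["params"]
        for key in ("shared_widths", "global_hidden", "head_widths"):
            params[key] = tuple(params[key])
        model = DualPointNetRegressor(**params)
        model.weights_ = {
            stage: [[npz[f"{stage}_{li}_W"], npz[f"{stage}_{li}_b"]]
                    for li in range(n_layers)]
            for stage, n_layers in meta["layout"].items()}
    model.scale_ = float(meta["scale"])
    model.y_mean_ = np.asarray(meta["y_mean"])
    model.y_std_ = np.asarray(meta["y_std"])
    model.inlet_ref_radius_ = meta.get("inlet_ref_radius")
    model.best_epoch_ = meta["best_epoch"]
    model.history_ = [tuple(h) for h in meta["history"]]
    return model
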