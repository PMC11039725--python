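"""Attention-based bidirectional LSTM forecasting of efficiency series.

The monthly DEA efficiency scores of one device form a short series in
(0, 1].  The forecaster slides a length-L window over the series and learns
to predict the next month's score:

1. a forward and a backward LSTM encode the window; their hidden states are
   concatenated per step, ``H_t = H_t^f (+) H_t^b``;
2. an attention layer scores every encoder state against the final state
   ``s = H_T`` (scaled dot product by default, additive scoring optional),
   softmax-normalizes the scores into weights ``alpha`` and forms the
   context ``c = sum_i alpha_i H_i``;
3. the attention-enhanced state ``H' = c + s`` feeds a linear head.

Training minimizes mean squared error with Adam.  The whole model — forward
pass, backpropagation through time and the attention path — is implemented
directly on numpy arrays; gradients are exact (the test-suite checks them
against finite differences).  Series are min-max normalized on the training
portion only; gaps are filled by linear interpolation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ForecastConfig",
    "WindowedDataset",
    "ForecastReport",
    "BiLSTMAttention",
    "fill_missing",
    "make_windows",
    "train_forecaster",
    "evaluate",
    "forecast_series",
]


@dataclass(frozen=True)
class ForecastConfig:
    window: int = 6
    hidden: int = 32            # units per direction
    epochs: int = 200
    learning_rate: float = 0.01
    optimizer: str = "adam"
    train_fraction: float = 0.8
    seed: int = 7
    attention: str = "dot"      # "dot" | "additive" | "none"

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.window < 2:
            raise ValueError("window length must be >= 2")
        if self.attention not in ("dot", "additive", "none"):
            raise ValueError(f"unknown attention kind {self.attention!r}")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")


@dataclass(frozen=True)
class WindowedDataset:
    """Normalized sliding windows with a chronological train/test split."""

    X_train: np.ndarray   # (n_train, L)
    y_train: np.ndarray   # (n_train,)
    X_test: np.ndarray
    y_test: np.ndarray
    norm_min: float       # min-max scaler fitted on the training portion
    norm_max: float

    def denormalize(self, z: np.ndarray) -> np.ndarray:
        return np.asarray(z) * (self.norm_max - self.norm_min) + self.norm_min


@dataclass(frozen=True)
class ForecastReport:
    predictions: np.ndarray
    actuals: np.ndarray
    mse: float
    rmse: float
    mae: float
    mape: float
    r2: float
    relative_errors: np.ndarray | None = None
    final_training_loss: float | None = None
    attention: np.ndarray | None = None   # (n_test, L), rows sum to 1


def fill_missing(series: pd.Series | np.ndarray) -> np.ndarray:
    """Linear interpolation of interior gaps (edge gaps held constant)."""
    s = pd.Series(np.asarray(series, dtype=float))
    return s.interpolate(method="linear", limit_direction="both").to_numpy()


def make_windows(series: pd.Series | np.ndarray, window: int,
                 train_fraction: float = 0.8) -> WindowedDataset:
    """Sliding (window, next-value) pairs with a chronological split.

    The min-max normalization is fitted on the raw values that appear in
    the training windows and targets only, then applied to both splits, so
    no test information leaks into preprocessing.
    """
    values = fill_missing(series)
    n = values.size
    if n <= window + 1:
        raise ValueError(
            f"series of length {n} is too short for window {window} "
            "(need length > window + 1)")
    n_pairs = n - window
    n_train = max(1, int(np.floor(train_fraction * n_pairs)))
    if n_train >= n_pairs:
        n_train = n_pairs - 1
    train_raw = values[: n_train + window]  # everything a training pair touches
    lo, hi = float(train_raw.min()), float(train_raw.max())
    if hi == lo:
        hi = lo + 1.0  # constant training series: map to 0
    z = (values - lo) / (hi - lo)
    X = np.stack([z[k: k + window] for k in range(n_pairs)])
    y = z[window:]
    return WindowedDataset(X_train=X[:n_train], y_train=y[:n_train],
                           X_test=X[n_train:], y_test=y[n_train:],
                           norm_min=lo, norm_max=hi)


# ----------------------------------------------------------------------
# model
# ----------------------------------------------------------------------

def _sigmoid(x: np.ndarray) -> np.ndarray:
    with np.errstate(over="ignore"):  # saturates cleanly to 0/1
        return 1.0 / (1.0 + np.exp(-x))


class BiLSTMAttention:
    """Bidirectional LSTM encoder with attention and a linear head.

    Scalar-input, scalar-output network for short windows; all parameters
    live in a flat dict of float64 arrays and are trained by Adam on MSE.
    """

    def __init__(self, hidden: int, window: int, attention: str = "dot",
                 seed: int = 7):
        self.h = hidden
        self.T = window
        self.attention = attention
        rng = np.random.default_rng(seed)
        h = hidden
        k = 1.0 / np.sqrt(h)
        def u(*shape):
            return rng.uniform(-k, k, size=shape)
        self.params: dict[str, np.ndarray] = {
            "Wf": u(4 * h, 1 + h), "bf": u(4 * h),
            "Wb": u(4 * h, 1 + h), "bb": u(4 * h),
            "wo": u(2 * h), "bo": np.zeros(()),
        }
        # a small positive forget-gate bias stabilizes early training
        self.params["bf"][h: 2 * h] += 1.0
        self.params["bb"][h: 2 * h] += 1.0
        if attention == "additive":
            d = 2 * h
            self.params.update({"Wq": u(h, d), "Wk": u(h, d),
                                "ba": np.zeros(h), "va": u(h)})

    # -- forward ---------------------------------------------------------

    def _lstm_pass(self, x: np.ndarray, order: range, W: np.ndarray,
                   b: np.ndarray) -> tuple[np.ndarray, list[dict]]:
        """Run one direction over time indices ``order``; returns states
        aligned to original positions and the per-step cache."""
        N, T = x.shape
        h = self.h
        H = np.zeros((N, T, h))
        hp = np.zeros((N, h))
        cp = np.zeros((N, h))
        caches = []
        for t in order:
            inp = np.concatenate([x[:, t: t + 1], hp], axis=1)  # (N, 1+h)
            z = inp @ W.T + b
            i = _sigmoid(z[:, :h])
            f = _sigmoid(z[:, h: 2 * h])
            g = np.tanh(z[:, 2 * h: 3 * h])
            o = _sigmoid(z[:, 3 * h:])
            c = f * cp + i * g
            hh = o * np.tanh(c)
            caches.append({"t": t, "inp": inp, "i": i, "f": f, "g": g,
                           "o": o, "c": c, "cp": cp})
            H[:, t, :] = hh
            hp, cp = hh, c
        return H, caches

    def forward(self, x: np.ndarray, cache: bool = False):
        """Predict next-step values for windows ``x`` of shape (N, T)."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        N, T = x.shape
        h, p = self.h, self.params
        Hf, cf = self._lstm_pass(x, range(T), p["Wf"], p["bf"])
        Hb, cb = self._lstm_pass(x, range(T - 1, -1, -1), p["Wb"], p["bb"])
        H = np.concatenate([Hf, Hb], axis=2)          # (N, T, 2h)
        s = H[:, T - 1, :]                            # query: final state
        ctx: dict = {"x": x, "H": H, "s": s, "cf": cf, "cb": cb}
        if self.attention == "none":
            Hp = s
            alpha = None
        else:
            if self.attention == "dot":
                e = np.einsum("nd,ntd->nt", s, H) / np.sqrt(2 * h)
            else:  # additive
                a_pre = (np.einsum("nd,ad->na", s, p["Wq"])[:, None, :]
                         + np.einsum("ntd,ad->nta", H, p["Wk"]) + p["ba"])
                u_act = np.tanh(a_pre)
                e = np.einsum("nta,a->nt", u_act, p["va"])
                ctx["u_act"] = u_act
            e = e - e.max(axis=1, keepdims=True)
            alpha = np.exp(e)
            alpha /= alpha.sum(axis=1, keepdims=True)
            c_vec = np.einsum("nt,ntd->nd", alpha, H)
            Hp = c_vec + s
            ctx.update({"alpha": alpha})
        yhat = Hp @ p["wo"] + p["bo"]
        ctx.update({"Hp": Hp})
        if cache:
            return yhat, alpha, ctx
        return yhat, alpha

    # -- backward --------------------------------------------------------

    def _lstm_backprop(self, dH_dir: np.ndarray, caches: list[dict],
                       W: np.ndarray, grads: dict, wkey: str, bkey: str) -> None:
        N = dH_dir.shape[0]
        h = self.h
        dW = np.zeros_like(W)
        db = np.zeros(4 * h)
        dh_next = np.zeros((N, h))
        dc_next = np.zeros((N, h))
        for cache in reversed(caches):
            t = cache["t"]
            i, f, g, o = cache["i"], cache["f"], cache["g"], cache["o"]
            c, cp, inp = cache["c"], cache["cp"], cache["inp"]
            tanh_c = np.tanh(c)
            dh = dH_dir[:, t, :] + dh_next
            do = dh * tanh_c
            dc = dh * o * (1 - tanh_c ** 2) + dc_next
            di, dg, df = dc * g, dc * i, dc * cp
            dc_next = dc * f
            dz = np.concatenate([di * i * (1 - i), df * f * (1 - f),
                                 dg * (1 - g ** 2), do * o * (1 - o)], axis=1)
            dW += dz.T @ inp
            db += dz.sum(axis=0)
            dh_next = (dz @ W)[:, 1:]
        grads[wkey] = grads.get(wkey, 0) + dW
        grads[bkey] = grads.get(bkey, 0) + db

    def loss_and_grads(self, x: np.ndarray, y: np.ndarray
                       ) -> tuple[float, dict[str, np.ndarray]]:
        """MSE loss and exact parameter gradients on a batch."""
        p = self.params
        h = self.h
        yhat, alpha, ctx = self.forward(x, cache=True)
        N, T = ctx["x"].shape
        resid = yhat - np.asarray(y, dtype=float)
        loss = float(np.mean(resid ** 2))
        grads: dict[str, np.ndarray] = {}
        dyhat = 2.0 * resid / N
        grads["wo"] = ctx["Hp"].T @ dyhat
        grads["bo"] = np.asarray(dyhat.sum())
        dHp = dyhat[:, None] * p["wo"][None, :]
        H, s = ctx["H"], ctx["s"]
        if self.attention == "none":
            dH = np.zeros_like(H)
            ds = dHp
        else:
            al = ctx["alpha"]
            dc_vec = dHp
            ds = dHp.copy()
            dal = np.einsum("nd,ntd->nt", dc_vec, H)
            dH = al[:, :, None] * dc_vec[:, None, :]
            de = al * (dal - np.sum(al * dal, axis=1, keepdims=True))
            if self.attention == "dot":
                scale = 1.0 / np.sqrt(2 * h)
                ds += np.einsum("nt,ntd->nd", de, H) * scale
                dH += de[:, :, None] * s[:, None, :] * scale
            else:
                u_act = ctx["u_act"]
                grads["va"] = np.einsum("nt,nta->a", de, u_act)
                da = de[:, :, None] * p["va"][None, None, :] * (1 - u_act ** 2)
                grads["Wq"] = np.einsum("nta,nd->ad", da, s)
                grads["Wk"] = np.einsum("nta,ntd->ad", da, H)
                grads["ba"] = da.sum(axis=(0, 1))
                ds += np.einsum("nta,ad->nd", da, p["Wq"])
                dH += np.einsum("nta,ad->ntd", da, p["Wk"])
        dH[:, T - 1, :] += ds
        self._lstm_backprop(dH[:, :, :h], ctx["cf"], p["Wf"], grads, "Wf", "bf")
        self._lstm_backprop(dH[:, :, h:], ctx["cb"], p["Wb"], grads, "Wb", "bb")
        return loss, grads


@dataclass
class TrainedForecaster:
    model: BiLSTMAttention
    data: WindowedDataset
    config: ForecastConfig
    loss_curve: np.ndarray = field(default_factory=lambda: np.array([]))

    def predict(self, X: np.ndarray | None = None,
                denormalize: bool = True) -> tuple[np.ndarray, np.ndarray | None]:
        """Predictions (and attention rows) for windows ``X``; defaults to
        the held-out test windows, mapped back to the original scale."""
        if X is None:
            X = self.data.X_test
        yhat, alpha = self.model.forward(X)
        if denormalize:
            yhat = self.data.denormalize(yhat)
        return yhat, alpha


def train_forecaster(data: WindowedDataset,
                     config: ForecastConfig) -> TrainedForecaster:
    """Full-batch Adam training on MSE for the configured epochs."""
    if data.X_train.size == 0:
        raise ValueError("empty training set")
    model = BiLSTMAttention(hidden=config.hidden, window=data.X_train.shape[1],
                            attention=config.attention, seed=config.seed)
    p = model.params
    m = {k: np.zeros_like(v) for k, v in p.items()}
    v = {k: np.zeros_like(val) for k, val in p.items()}
    b1, b2, eps = 0.9, 0.999, 1e-8
    lr = config.learning_rate
    losses = np.empty(config.epochs)
    for epoch in range(1, config.epochs + 1):
        loss, grads = model.loss_and_grads(data.X_train, data.y_train)
        if not np.isfinite(loss) or (epoch > 1 and loss > 1e6 * (losses[0] + 1e-12)):
            raise FloatingPointError(
                f"training diverged at epoch {epoch} (loss={loss}); "
                f"reduce the learning rate (currently {lr})")
        for key, g in grads.items():
            m[key] = b1 * m[key] + (1 - b1) * g
            v[key] = b2 * v[key] + (1 - b2) * g ** 2
            mhat = m[key] / (1 - b1 ** epoch)
            vhat = v[key] / (1 - b2 ** epoch)
            p[key] = p[key] - lr * mhat / (np.sqrt(vhat) + eps)
        losses[epoch - 1] = loss
    return TrainedForecaster(model=model, data=data, config=config,
                             loss_curve=losses)


def evaluate(predictions: np.ndarray, actuals: np.ndarray) -> ForecastReport:
    """Forecast-quality metrics: MSE, RMSE, MAE, MAPE and R-squared.

    MAPE excludes (with a warning) points where the actual value is zero;
    R-squared needs at least two distinct actual values.
    """
    pred = np.asarray(predictions, dtype=float)
    act = np.asarray(actuals, dtype=float)
    if pred.shape != act.shape or pred.size < 2:
        raise ValueError("predictions and actuals must share length >= 2")
    if np.ptp(act) == 0:
        raise ValueError("actuals are constant: R-squared is undefined")
    err = act - pred
    mse = float(np.mean(err ** 2))
    rmse = float(np.sqrt(mse))
    mae = float(np.mean(np.abs(err)))
    nz = act != 0
    if not nz.all():
        warnings.warn(f"{(~nz).sum()} zero actuals excluded from MAPE",
                      stacklevel=2)
    mape = float(np.mean(np.abs(err[nz]) / np.abs(act[nz])))
    r2 = float(1.0 - np.sum(err ** 2) / np.sum((act - act.mean()) ** 2))
    rel = np.full_like(act, np.nan)
    rel[nz] = (pred[nz] - act[nz]) / act[nz]
    return ForecastReport(predictions=pred, actuals=act, mse=mse, rmse=rmse,
                          mae=mae, mape=mape, r2=r2, relative_errors=rel)


def forecast_series(series: pd.Series | np.ndarray,
                    config: ForecastConfig = ForecastConfig()) -> ForecastReport:
    """Convenience wrapper: window, train and score one efficiency series."""
    data = make_windows(series, config.window, config.train_fraction)
    trained = train_forecaster(data, config)
    pred, alpha = trained.predict()
    report = evaluate(pred, data.denormalize(data.y_test))
    return ForecastReport(
        predictions=report.predictions, actuals=report.actuals,
        mse=report.mse, rmse=report.rmse, mae=report.mae, mape=report.mape,
        r2=report.r2, relative_errors=report.relative_errors,
        final_training_loss=float(trained.loss_curve[-1]),
        attention=alpha)
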