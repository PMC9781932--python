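"""Ensemble of single-hidden-layer networks with admission gates.

The regression target is log10 mole-fraction solubility, predicted from
the 8 molecular descriptors.  Many small networks are trained from a
hyperparameter grid × seeds pool; each candidate is admitted into the
ensemble only when, on the held-out validation subset, it satisfies all
three gates simultaneously:

* accuracy    — RMSD < 0.06 log10 units,
* precision   — outliers (|standardized residual| > 3) make up <= 2%,
* reliability — >= 99% of predictions are physically admissible mole
  fractions, i.e. log10 x <= 0.

Predictions of the admitted members are averaged without weights.  An
applicability-domain check (descriptor-range box plus leverage against
the Williams h* = 3(p+1)/n cutoff) marks queries the ensemble should
not be trusted on.

The base learner is a deliberately small numpy network (one hidden
layer, Adam, squared or absolute loss, early stopping monitored on the
test subset) so that every stochastic step is driven by an explicit
seed and two runs with the same seeds are bit-identical.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "NetworkConfig", "Network", "MemberReport", "EnsembleModel",
    "AdmissionThresholds", "split_dataset", "train_candidate",
    "evaluate_member", "build_ensemble", "applicability_domain",
    "default_pool", "save_model", "load_model",
]


class SplitError(ValueError):
    pass


class TrainingError(RuntimeError):
    pass


class EnsembleBuildError(RuntimeError):
    pass


ACTIVATIONS = {
    "tanh": (np.tanh, lambda a: 1.0 - a ** 2),
    "logistic": (lambda z: 1.0 / (1.0 + np.exp(-z)), lambda a: a * (1.0 - a)),
    "rectifier": (lambda z: np.maximum(z, 0.0),
                  lambda a: (a > 0.0).astype(float)),
}


@dataclass(frozen=True)
class NetworkConfig:
    """Hyperparameters of one candidate network (one hidden layer, fixed)."""

    hidden_units: int = 8
    activation: str = "tanh"
    loss: str = "squared"
    seed: int = 0
    max_epochs: int = 800
    patience: int = 60
    learning_rate: float = 0.02
    batch_size: int = 32

    def __post_init__(self) -> None:
        if self.hidden_units < 1:
            raise ValueError("hidden_units must be >= 1")
        if self.activation not in ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")
        if self.loss not in ("squared", "absolute"):
            raise ValueError(f"unknown loss {self.loss!r}")


@dataclass(frozen=True)
class AdmissionThresholds:
    """The three inclusion gates (defaults are the working criteria)."""

    rmsd_max: float = 0.06        # log10 units, strict <
    outlier_max: float = 2.0      # percent, <=
    reliability_min: float = 99.0  # percent, >=


@dataclass
class Network:
    """A trained single-hidden-layer regressor (numpy weights)."""

    config: NetworkConfig
    w1: np.ndarray
    b1: np.ndarray
    w2: np.ndarray
    b2: float
    train_curve: list[float] = field(default_factory=list)

    def predict(self, x: np.ndarray) -> np.ndarray:
        act = ACTIVATIONS[self.config.activation][0]
        h = act(np.asarray(x, float) @ self.w1 + self.b1)
        return h @ self.w2 + self.b2


@dataclass(frozen=True)
class MemberReport:
    config: NetworkConfig
    rmsd_val: float
    outlier_rate: float     # percent
    reliability_rate: float  # percent
    admitted: bool


def split_dataset(n: int, seed: int,
                  fractions: tuple[float, float] = (0.15, 0.15)
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Deterministic disjoint 70/15/15 index split (remainder to train).

    Returns (train_idx, test_idx, val_idx).  Test and validation sizes
    are floor(fraction·n); training receives the remainder, so n = 100
    splits 70/15/15 and n = 101 splits 71/15/15.
    """
    if n < 20:
        raise SplitError(f"n={n} too small to split (need >= 20)")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_test = int(np.floor(fractions[0] * n))
    n_val = int(np.floor(fractions[1] * n))
    test = perm[:n_test]
    val = perm[n_test:n_test + n_val]
    train = perm[n_test + n_val:]
    return np.sort(train), np.sort(test), np.sort(val)


def _loss_and_grad(loss: str, pred: np.ndarray, y: np.ndarray):
    r = pred - y
    if loss == "squared":
        return float(np.mean(r ** 2)), 2.0 * r / len(r)
    return float(np.mean(np.abs(r))), np.sign(r) / len(r)


def train_candidate(config: NetworkConfig, x_train: np.ndarray,
                    y_train: np.ndarray, x_test: np.ndarray,
                    y_test: np.ndarray) -> Network:
    """Fit one candidate by Adam with early stopping on the test subset.

    Inputs are expected min-max normalised.  The weights snapshot with
    the best test loss is returned; training stops after ``patience``
    epochs without improvement.  Fully deterministic for a fixed config
    (seed drives initialisation and minibatch shuffling).
    """
    x_train = np.asarray(x_train, float)
    y_train = np.asarray(y_train, float).ravel()
    rng = np.random.default_rng(config.seed)
    n, p = x_train.shape
    h = config.hidden_units
    act, dact = ACTIVATIONS[config.activation]

    w1 = rng.normal(0.0, np.sqrt(1.0 / p), size=(p, h))
    b1 = np.zeros(h)
    w2 = rng.normal(0.0, np.sqrt(1.0 / h), size=h)
    b2 = 0.0

    params = [w1, b1, w2, np.array([b2])]
    m = [np.zeros_like(q) for q in params]
    v = [np.zeros_like(q) for q in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0

    best = (np.inf, None)
    curve: list[float] = []
    stall = 0
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            xb, yb = x_train[idx], y_train[idx]
            z1 = xb @ params[0] + params[1]
            a1 = act(z1)
            pred = a1 @ params[2] + params[3][0]
            loss, dpred = _loss_and_grad(config.loss, pred, yb)
            if not np.isfinite(loss):
                raise TrainingError(f"non-finite loss at epoch {epoch}")
            gw2 = a1.T @ dpred
            gb2 = np.array([np.sum(dpred)])
            da1 = np.outer(dpred, params[2]) * dact(a1)
            gw1 = xb.T @ da1
            gb1 = da1.sum(axis=0)
            grads = [gw1, gb1, gw2, gb2]
            step += 1
            for q, g, mi, vi in zip(params, grads, m, v):
                mi *= beta1
                mi += (1 - beta1) * g
                vi *= beta2
                vi += (1 - beta2) * g * g
                mhat = mi / (1 - beta1 ** step)
                vhat = vi / (1 - beta2 ** step)
                q -= config.learning_rate * mhat / (np.sqrt(vhat) + eps)

        test_pred = act(x_test @ params[0] + params[1]) @ params[2] \
            + params[3][0]
        test_loss, _ = _loss_and_grad(config.loss, test_pred,
                                      np.asarray(y_test, float).ravel())
        curve.append(test_loss)
        if test_loss < best[0] - 1e-12:
            best = (test_loss, [q.copy() for q in params])
            stall = 0
        else:
            stall += 1
            if stall >= config.patience:
                break

    bw = best[1] if best[1] is not None else params
    return Network(config=config, w1=bw[0], b1=bw[1], w2=bw[2],
                   b2=float(bw[3][0]), train_curve=curve)


def evaluate_member(network: Network, x_val: np.ndarray, y_val: np.ndarray,
                    thresholds: AdmissionThresholds | None = None
                    ) -> MemberReport:
    """Score one candidate on the validation subset and apply the gates.

    RMSD is computed on log10 values; outliers are validation points with
    |residual| > 3 standard deviations of the residuals; reliability is
    the share of predictions that are admissible mole fractions
    (log10 x <= 0).  Admission is the strict three-way conjunction.
    """
    if len(x_val) == 0:
        raise ValueError("validation subset is empty")
    thr = thresholds or AdmissionThresholds()
    y_val = np.asarray(y_val, float).ravel()
    pred = network.predict(x_val)
    resid = pred - y_val
    rmsd_val = float(np.sqrt(np.mean(resid ** 2)))
    sd = float(np.std(resid))
    if sd == 0.0:
        outlier_rate = 0.0
    else:
        outlier_rate = float(np.mean(np.abs(resid) > 3.0 * sd) * 100.0)
    reliability = float(np.mean(pred <= 0.0) * 100.0)
    admitted = (rmsd_val < thr.rmsd_max
                and outlier_rate <= thr.outlier_max
                and reliability >= thr.reliability_min)
    return MemberReport(config=network.config, rmsd_val=rmsd_val,
                        outlier_rate=outlier_rate,
                        reliability_rate=reliability, admitted=admitted)


@dataclass
class EnsembleModel:
    """Admitted networks, frozen normalisation, and the AD model."""

    members: list[Network]
    reports: list[MemberReport]
    norm_lo: np.ndarray
    norm_hi: np.ndarray
    ad_xtx_inv: np.ndarray | None
    ad_leverage_cutoff: float
    ad_margin: float = 0.0
    thresholds: AdmissionThresholds = field(default_factory=AdmissionThresholds)

    def _normalize(self, x: np.ndarray) -> np.ndarray:
        span = np.where(self.norm_hi > self.norm_lo,
                        self.norm_hi - self.norm_lo, 1.0)
        return (np.asarray(x, float) - self.norm_lo) / span

    def member_predictions(self, x: np.ndarray) -> np.ndarray:
        xn = self._normalize(np.atleast_2d(x))
        return np.stack([mem.predict(xn) for mem in self.members])

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Unweighted mean of member predictions (log10 x)."""
        preds = self.member_predictions(x)
        out = preds.mean(axis=0)
        return out if np.ndim(x) > 1 else float(out[0])


def build_ensemble(pool: list[NetworkConfig], x: np.ndarray, y: np.ndarray,
                   split_seed: int = 0,
                   thresholds: AdmissionThresholds | None = None,
                   ad_margin: float = 0.0) -> EnsembleModel:
    """Train every pool candidate and keep the ones passing the gates.

    The dataset is split 70/15/15 (train/test/validation) once with
    ``split_seed``; descriptors are min-max normalised on the training
    subset only and that scaling is frozen into the model.  Raises with
    the near-miss reports when nothing is admitted.
    """
    if not pool:
        raise EnsembleBuildError("candidate pool is empty")
    thr = thresholds or AdmissionThresholds()
    x = np.asarray(x, float)
    y = np.asarray(y, float).ravel()
    tr, te, va = split_dataset(len(x), split_seed)
    lo, hi = x[tr].min(axis=0), x[tr].max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)

    def norm(a):
        return (a - lo) / span

    members: list[Network] = []
    reports: list[MemberReport] = []
    for cfg in pool:
        net = train_candidate(cfg, norm(x[tr]), y[tr], norm(x[te]), y[te])
        rep = evaluate_member(net, norm(x[va]), y[va], thr)
        reports.append(rep)
        if rep.admitted:
            members.append(net)
    if not members:
        near = sorted(reports, key=lambda r: r.rmsd_val)[:5]
        raise EnsembleBuildError(
            "no candidate passed the admission gates; closest members: "
            + "; ".join(f"rmsd={r.rmsd_val:.4f} outl={r.outlier_rate:.1f}% "
                        f"rel={r.reliability_rate:.1f}%" for r in near))

    xn_tr = norm(x[tr])
    design = np.column_stack([np.ones(len(xn_tr)), xn_tr])
    p = x.shape[1]
    cutoff = 3.0 * (p + 1) / len(tr)
    try:
        xtx_inv = np.linalg.inv(design.T @ design)
    except np.linalg.LinAlgError:
        xtx_inv = None
    return EnsembleModel(members=members, reports=reports,
                         norm_lo=lo, norm_hi=hi, ad_xtx_inv=xtx_inv,
                         ad_leverage_cutoff=cutoff, ad_margin=ad_margin,
                         thresholds=thr)


def applicability_domain(ensemble: EnsembleModel, query: np.ndarray
                         ) -> tuple[bool, dict]:
    """Range-box + leverage applicability-domain check for one query.

    In-domain requires every normalised descriptor inside
    [0 − margin, 1 + margin] of the training ranges *and* leverage
    h = x'(X'X)⁻¹x <= h* = 3(p+1)/n.  With a singular training matrix
    the check degrades to the range box alone (flagged in diagnostics).
    """
    q = np.asarray(query, float).ravel()
    qn = ensemble._normalize(q)
    lo_ok = qn >= -ensemble.ad_margin - 1e-12
    hi_ok = qn <= 1.0 + ensemble.ad_margin + 1e-12
    in_box = bool(np.all(lo_ok & hi_ok))
    diag = {"normalized": qn, "in_box": in_box}
    if ensemble.ad_xtx_inv is None:
        diag["leverage"] = None
        diag["degraded"] = True
        return in_box, diag
    xq = np.concatenate([[1.0], qn])
    leverage = float(xq @ ensemble.ad_xtx_inv @ xq)
    diag["leverage"] = leverage
    diag["leverage_cutoff"] = ensemble.ad_leverage_cutoff
    diag["degraded"] = False
    return in_box and leverage <= ensemble.ad_leverage_cutoff, diag


def save_model(model: EnsembleModel, path) -> None:
    """Serialize an ensemble to version-stamped JSON (weights inline)."""
    import json
    doc = {
        "format": "cosolv-ensemble", "version": 1,
        "norm_lo": model.norm_lo.tolist(), "norm_hi": model.norm_hi.tolist(),
        "ad_xtx_inv": (model.ad_xtx_inv.tolist()
                       if model.ad_xtx_inv is not None else None),
        "ad_leverage_cutoff": model.ad_leverage_cutoff,
        "ad_margin": model.ad_margin,
        "thresholds": vars(model.thresholds),
        "members": [{
            "config": vars(mem.config),
            "w1": mem.w1.tolist(), "b1": mem.b1.tolist(),
            "w2": mem.w2.tolist(), "b2": mem.b2,
        } for mem in model.members],
        "reports": [{**{k: v for k, v in vars(r).items() if k != "config"},
                     "config": vars(r.config)} for r in model.reports],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_model(path) -> EnsembleModel:
    import json
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format") != "cosolv-ensemble":
        raise ValueError(f"{path} is not a cosolv ensemble bundle")
    members = [Network(config=NetworkConfig(**m["config"]),
                       w1=np.array(m["w1"]), b1=np.array(m["b1"]),
                       w2=np.array(m["w2"]), b2=float(m["b2"]))
               for m in doc["members"]]
    reports = [MemberReport(config=NetworkConfig(**r.pop("config")), **r)
               for r in [dict(r) for r in doc["reports"]]]
    return EnsembleModel(
        members=members, reports=reports,
        norm_lo=np.array(doc["norm_lo"]), norm_hi=np.array(doc["norm_hi"]),
        ad_xtx_inv=(np.array(doc["ad_xtx_inv"])
                    if doc["ad_xtx_inv"] is not None else None),
        ad_leverage_cutoff=float(doc["ad_leverage_cutoff"]),
        ad_margin=float(doc["ad_margin"]),
        thresholds=AdmissionThresholds(**doc["thresholds"]))


def default_pool(n_seeds: int = 10, base_seed: int = 0,
                 hidden_grid=(4, 8, 12, 16, 24, 32),
                 activations=("tanh", "logistic", "rectifier"),
                 losses=("squared", "absolute")) -> list[NetworkConfig]:
    """The full hyperparameter grid × seeds candidate pool (default 360)."""
    pool = []
    for i, (h, a, l) in enumerate(itertools.product(hidden_grid, activations,
                                                    losses)):
        for s in range(n_seeds):
            pool.append(NetworkConfig(hidden_units=h, activation=a, loss=l,
                                      seed=base_seed + 1000 * i + s))
    return pool
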