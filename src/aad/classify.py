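"""Classifier bank and evaluation for two-speaker attention decoding.

Five classifiers operate on the per-window feature tables: k-nearest
neighbors (k=1, Euclidean), an RBF support-vector machine (box constraint
1), stacked LSTM and bidirectional LSTM sequence classifiers, and GCQL —
a Q-learning agent whose action-value function is a GRU + 1-D-convolution
network.  In GCQL each analysis window is a one-step episode: the state
is the (standardized) feature vector, the two actions are "predict
speaker 1" / "predict speaker 2", and the reward is +1 for a correct
call, -1 otherwise.  With the default discount of 0 the temporal-
difference target reduces to the immediate reward, which is the honest
reading of a single-step decision process; the exploration schedule and
experience replay still shape which states the network fits hardest.

Evaluation reports accuracy, sensitivity (TPR) and specificity (TNR)
with "attend speaker 1" as the positive class.  Splits are at *trial*
granularity so windows from one trial never straddle train and test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .features import FeatureMatrix
from . import nn

__all__ = ["ClassifierSpec", "GCQLConfig", "EvalReport", "split_trials",
           "train", "train_gcql", "evaluate", "cross_validate", "window_sweep",
           "save_model", "load_model", "CLASSIFIER_KINDS"]

CLASSIFIER_KINDS = ("KNN", "SVM", "LSTM", "BILSTM", "GCQL")

_SCHEMAS: dict[str, dict] = {
    "KNN": {"n_neighbors": 1, "metric": "euclidean", "standardize": True},
    "SVM": {"C": 1.0, "kernel": "rbf", "kernel_scale": 1.1, "standardize": True},
    "LSTM": {"n_layers": 5, "hidden": 32, "dropout": 0.2, "batch_size": 512,
             "epochs": 100, "lr": 1e-3, "seq_len": 1, "standardize": True},
    "BILSTM": {"n_layers": 3, "hidden": 32, "dropout": 0.2, "batch_size": 512,
               "epochs": 100, "lr": 1e-3, "seq_len": 1, "standardize": True},
}


@dataclass
class ClassifierSpec:
    kind: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        self.kind = self.kind.upper()
        if self.kind not in CLASSIFIER_KINDS:
            raise ValueError(f"kind must be one of {CLASSIFIER_KINDS}")
        if self.kind == "GCQL":
            return  # GCQL carries its own config object
        schema = _SCHEMAS[self.kind]
        unknown = set(self.hyperparameters) - set(schema)
        if unknown:
            raise ValueError(f"unknown hyperparameters for {self.kind}: {sorted(unknown)}")

    def resolved(self) -> dict:
        out = dict(_SCHEMAS[self.kind])
        out.update(self.hyperparameters)
        return out


@dataclass
class GCQLConfig:
    gru_units: int = 64
    conv_filters: int = 32
    kernel_size: int = 3
    dense_units: int = 32
    gamma: float = 0.0
    eps_start: float = 1.0
    eps_end: float = 0.05
    eps_decay: str = "linear"
    replay_size: int = 10_000
    batch_size: int = 512
    learning_rate: float = 1e-3
    epochs: int = 100
    reward_correct: float = 1.0
    reward_wrong: float = -1.0
    update_every: int = 4
    seq_len: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.gamma <= 1:
            raise ValueError("gamma must be in [0, 1]")
        if not self.eps_end <= self.eps_start <= 1:
            raise ValueError("need eps_end <= eps_start <= 1")


@dataclass
class EvalReport:
    tp: int
    tn: int
    fp: int
    fn: int
    window_length_s: float = float("nan")

    @property
    def acc(self) -> float:
        total = self.tp + self.tn + self.fp + self.fn
        return (self.tp + self.tn) / total if total else float("nan")

    @property
    def tpr(self) -> float:
        denom = self.tp + self.fn
        if denom == 0:
            warnings.warn("positive class absent: TPR undefined")
            return float("nan")
        return self.tp / denom

    @property
    def tnr(self) -> float:
        denom = self.tn + self.fp
        if denom == 0:
            warnings.warn("negative class absent: TNR undefined")
            return float("nan")
        return self.tn / denom

    def as_dict(self) -> dict:
        return {"tp": self.tp, "tn": self.tn, "fp": self.fp, "fn": self.fn,
                "acc": self.acc, "tpr": self.tpr, "tnr": self.tnr,
                "window_length_s": self.window_length_s}


# ---------------------------------------------------------------------------
# splitting

def split_trials(fm: FeatureMatrix, train_fraction: float = 0.7,
                 seed: int = 0) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Trial-level stratified split (e.g. 48 trials at 0.7 -> 34 train / 14 test)."""
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    labels = fm.labels.to_numpy()
    tids = fm.trial_ids.to_numpy()
    train_trials: list = []
    for cls in np.unique(labels):
        trials = np.unique(tids[labels == cls])
        if len(trials) < 2:
            raise ValueError(f"need >= 2 trials for class {cls}")
        n_train = int(round(train_fraction * len(trials)))
        n_train = min(max(n_train, 1), len(trials) - 1)
        perm = rng.permutation(trials)
        train_trials.extend(perm[:n_train])
    mask = np.isin(tids, train_trials)
    return fm.subset(mask), fm.subset(~mask)


# ---------------------------------------------------------------------------
# sequence plumbing shared by the recurrent models

def _standardizer(X: np.ndarray):
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return mu, sd


def _make_sequences(fm: FeatureMatrix, seq_len: int,
                    mu: np.ndarray, sd: np.ndarray):
    """Group consecutive windows within each trial into length-L sequences.

    Returns (X (n, L, D), y (n,)) where y is the last window's class.
    """
    Xs, ys = [], []
    X = (fm.X - mu) / sd
    y = fm.y
    tids = fm.trial_ids.to_numpy()
    for tid in np.unique(tids):
        idx = np.flatnonzero(tids == tid)
        for i in range(0, len(idx) - seq_len + 1, seq_len):
            sl = idx[i:i + seq_len]
            Xs.append(X[sl])
            ys.append(y[sl[-1]])
    return np.array(Xs), np.array(ys)


# ---------------------------------------------------------------------------
# models

class _SklearnModel:
    def __init__(self, clf, mu, sd):
        self.clf, self.mu, self.sd = clf, mu, sd

    def predict_with_truth(self, fm: FeatureMatrix):
        X = (fm.X - self.mu) / self.sd
        return fm.y, self.clf.predict(X)


class _RecurrentModel:
    def __init__(self, layers, head, mu, sd, seq_len, bidirectional):
        self.layers, self.head = layers, head
        self.mu, self.sd, self.seq_len = mu, sd, seq_len
        self.bidirectional = bidirectional

    def _forward(self, X: np.ndarray, dropout: float = 0.0,
                 rng: np.random.Generator | None = None) -> nn.Tensor:
        B, L, _ = X.shape
        steps = [nn.Tensor(X[:, t, :]) for t in range(L)]
        for cells in self.layers:
            if self.bidirectional:
                fwd_cell, bwd_cell = cells
                outs_f, outs_b = [], [None] * L
                h = nn.Tensor(np.zeros((B, fwd_cell.nh)))
                c = nn.Tensor(np.zeros((B, fwd_cell.nh)))
                for t in range(L):
                    h, c = fwd_cell(steps[t], h, c)
                    outs_f.append(h)
                h = nn.Tensor(np.zeros((B, bwd_cell.nh)))
                c = nn.Tensor(np.zeros((B, bwd_cell.nh)))
                for t in reversed(range(L)):
                    h, c = bwd_cell(steps[t], h, c)
                    outs_b[t] = h
                steps = [outs_f[t].concat(outs_b[t]) for t in range(L)]
            else:
                cell = cells
                h = nn.Tensor(np.zeros((B, cell.nh)))
                c = nn.Tensor(np.zeros((B, cell.nh)))
                outs = []
                for t in range(L):
                    h, c = cell(steps[t], h, c)
                    outs.append(h)
                steps = outs
        pooled = steps[0]
        for t in range(1, L):
            pooled = pooled.maximum(steps[t])  # max-pool over time
        if dropout > 0 and rng is not None:
            mask = (rng.random(pooled.shape) >= dropout) / (1 - dropout)
            pooled = pooled * nn.Tensor(mask)
        return self.head(pooled)

    def predict_with_truth(self, fm: FeatureMatrix):
        X, y = _make_sequences(fm, self.seq_len, self.mu, self.sd)
        logits = self._forward(X)
        return y, logits.data.argmax(axis=1)


class GCQLModel:
    """Greedy policy of the trained GRU-CNN Q-network."""

    def __init__(self, gru, conv, dense1, dense2, mu, sd, seq_len, history):
        self.gru, self.conv = gru, conv
        self.dense1, self.dense2 = dense1, dense2
        self.mu, self.sd, self.seq_len = mu, sd, seq_len
        self.history = history  # per-epoch mean TD loss

    @property
    def params(self):
        return (self.gru.params + self.conv.params
                + self.dense1.params + self.dense2.params)

    def q_values(self, X: np.ndarray) -> nn.Tensor:
        """X is (batch, seq_len, n_features); returns (batch, 2) action values."""
        B, L, _ = X.shape
        h = nn.Tensor(np.zeros((B, self.gru.nh)))
        for t in range(L):
            h = self.gru(nn.Tensor(X[:, t, :]), h)
        z = self.conv(h).relu().mean_last()  # conv along the hidden-state axis
        z = self.dense1(z).relu()
        return self.dense2(z)

    def predict_with_truth(self, fm: FeatureMatrix):
        X, y = _make_sequences(fm, self.seq_len, self.mu, self.sd)
        q = self.q_values(X)
        return y, q.data.argmax(axis=1)


# ---------------------------------------------------------------------------
# training

def train(spec: ClassifierSpec, fm: FeatureMatrix,
          gcql_config: GCQLConfig | None = None):
    """Fit the classifier named by ``spec`` on a feature table."""
    if len(fm) == 0 or len(np.unique(fm.y)) < 2:
        raise ValueError("training set must be non-empty with both classes")
    if spec.kind == "GCQL":
        cfg = gcql_config or GCQLConfig(seed=spec.seed)
        return train_gcql(cfg, fm)
    hp = spec.resolved()
    if hp.get("standardize", True):
        mu, sd = _standardizer(fm.X)
    else:
        mu = np.zeros(fm.X.shape[1])
        sd = np.ones(fm.X.shape[1])

    if spec.kind == "KNN":
        from sklearn.neighbors import KNeighborsClassifier

        clf = KNeighborsClassifier(n_neighbors=hp["n_neighbors"],
                                   metric=hp["metric"])
        clf.fit((fm.X - mu) / sd, fm.y)
        return _SklearnModel(clf, mu, sd)
    if spec.kind == "SVM":
        from sklearn.svm import SVC

        Xs = (fm.X - mu) / sd
        # RBF gamma = 'scale' divided by the squared kernel-scale factor
        gamma = 1.0 / (hp["kernel_scale"] ** 2 * Xs.shape[1] * max(Xs.var(), 1e-12))
        clf = SVC(C=hp["C"], kernel=hp["kernel"], gamma=gamma,
                  random_state=spec.seed)
        clf.fit(Xs, fm.y)
        return _SklearnModel(clf, mu, sd)

    # LSTM / BiLSTM
    rng = np.random.default_rng(spec.seed)
    bidir = spec.kind == "BILSTM"
    X, y = _make_sequences(fm, hp["seq_len"], mu, sd)
    dim = X.shape[2]
    layers = []
    in_dim = dim
    for _ in range(hp["n_layers"]):
        if bidir:
            layers.append((nn.LSTMCell(in_dim, hp["hidden"], rng),
                           nn.LSTMCell(in_dim, hp["hidden"], rng)))
            in_dim = 2 * hp["hidden"]
        else:
            layers.append(nn.LSTMCell(in_dim, hp["hidden"], rng))
            in_dim = hp["hidden"]
    head = nn.Linear(in_dim, 2, rng)
    model = _RecurrentModel(layers, head, mu, sd, hp["seq_len"], bidir)
    params = head.params
    for cells in layers:
        if bidir:
            params += cells[0].params + cells[1].params
        else:
            params += cells.params
    model._params = params
    opt = nn.Adam(params, lr=hp["lr"])
    n = len(X)
    for _ in range(hp["epochs"]):
        order = rng.permutation(n)
        for start in range(0, n, hp["batch_size"]):
            idx = order[start:start + hp["batch_size"]]
            opt.zero_grad()
            logits = model._forward(X[idx], dropout=hp["dropout"], rng=rng)
            loss = nn.softmax_cross_entropy(logits, y[idx])
            loss.backward()
            opt.step()
    return model


def train_gcql(cfg: GCQLConfig, fm: FeatureMatrix) -> GCQLModel:
    """Q-learning over one-step window episodes with experience replay.

    Behavior policy is epsilon-greedy with a linear decay over all episodes;
    the Q-network is refit on replayed minibatches by squared TD error.
    Training aborts if the loss turns non-finite.
    """
    if len(fm) == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(cfg.seed)
    mu, sd = _standardizer(fm.X)
    X, y = _make_sequences(fm, cfg.seq_len, mu, sd)
    n, _, dim = X.shape

    gru = nn.GRUCell(dim, cfg.gru_units, rng)
    conv = nn.Conv1dSingleChannel(cfg.conv_filters, cfg.kernel_size, rng)
    dense1 = nn.Linear(cfg.conv_filters, cfg.dense_units, rng)
    dense2 = nn.Linear(cfg.dense_units, 2, rng)
    model = GCQLModel(gru, conv, dense1, dense2, mu, sd, cfg.seq_len, [])
    opt = nn.Adam(model.params, lr=cfg.learning_rate)

    replay_s = np.empty((cfg.replay_size, X.shape[1], dim))
    replay_a = np.empty(cfg.replay_size, dtype=np.int64)
    replay_r = np.empty(cfg.replay_size)
    filled, cursor = 0, 0

    total_steps = max(cfg.epochs * n, 1)
    chunk = 64  # episodes per greedy-action batch; purely a vectorization size
    step = 0
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for lo in range(0, n, chunk):
            idx = order[lo:lo + chunk]
            eps = cfg.eps_start + (cfg.eps_end - cfg.eps_start) * (
                (step + np.arange(len(idx))) / total_steps)
            explore = rng.random(len(idx)) < eps
            actions = np.where(
                explore,
                rng.integers(2, size=len(idx)),
                model.q_values(X[idx]).data.argmax(axis=1),
            )
            rewards = np.where(actions == y[idx],
                               cfg.reward_correct, cfg.reward_wrong)
            # episodes are single-step: no next state, so the TD target is
            # the immediate reward for any gamma (terminal bootstrap is zero)
            for j, i in enumerate(idx):
                replay_s[cursor] = X[i]
                replay_a[cursor] = actions[j]
                replay_r[cursor] = rewards[j]
                cursor = (cursor + 1) % cfg.replay_size
            filled = min(filled + len(idx), cfg.replay_size)
            prev_step, step = step, step + len(idx)
            n_updates = step // cfg.update_every - prev_step // cfg.update_every
            if filled < min(cfg.batch_size, 32):
                continue
            for _ in range(n_updates):
                b = rng.integers(filled, size=min(cfg.batch_size, filled))
                opt.zero_grad()
                q = model.q_values(replay_s[b])
                q_sel = q.gather_cols(replay_a[b])
                td = q_sel - nn.Tensor(replay_r[b])
                loss = td.square().mean()
                if not np.isfinite(loss.data):
                    raise FloatingPointError(
                        f"GCQL loss diverged at epoch {epoch}, step {step}")
                loss.backward()
                opt.step()
                losses.append(float(loss.data))
        model.history.append(float(np.mean(losses)) if losses else float("nan"))
    return model


# ---------------------------------------------------------------------------
# serialization

def save_model(model, out_dir) -> None:
    """Persist a trained model (numpy weights + JSON meta, joblib for sklearn)."""
    import json
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if isinstance(model, _SklearnModel):
        import joblib

        joblib.dump({"clf": model.clf, "mu": model.mu, "sd": model.sd},
                    out / "model.joblib")
        meta = {"kind": "sklearn"}
    elif isinstance(model, GCQLModel):
        arrays = {f"p{i}": p.data for i, p in enumerate(model.params)}
        np.savez(out / "weights.npz", mu=model.mu, sd=model.sd, **arrays)
        meta = {"kind": "GCQL", "seq_len": model.seq_len,
                "dim": int(model.gru.Wz.data.shape[0]),
                "gru_units": model.gru.nh,
                "conv_filters": int(model.conv.W.data.shape[0]),
                "kernel_size": model.conv.kernel,
                "dense_units": int(model.dense1.W.data.shape[1])}
    elif isinstance(model, _RecurrentModel):
        arrays = {f"p{i}": p.data for i, p in enumerate(model._params)}
        np.savez(out / "weights.npz", mu=model.mu, sd=model.sd, **arrays)
        first = model.layers[0][0] if model.bidirectional else model.layers[0]
        meta = {"kind": "BILSTM" if model.bidirectional else "LSTM",
                "seq_len": model.seq_len, "n_layers": len(model.layers),
                "hidden": first.nh, "dim": int(first.W.data.shape[0])}
    else:
        raise TypeError(f"cannot serialize {type(model).__name__}")
    (out / "model.json").write_text(json.dumps(meta, indent=2))


def load_model(model_dir):
    """Inverse of :func:`save_model`."""
    import json
    from pathlib import Path

    out = Path(model_dir)
    meta = json.loads((out / "model.json").read_text())
    if meta["kind"] == "sklearn":
        import joblib

        blob = joblib.load(out / "model.joblib")
        return _SklearnModel(blob["clf"], blob["mu"], blob["sd"])
    with np.load(out / "weights.npz") as npz:
        mu, sd = npz["mu"], npz["sd"]
        arrays = [npz[f"p{i}"] for i in range(len(npz.files) - 2)]
    rng = np.random.default_rng(0)  # shapes only; weights overwritten below
    if meta["kind"] == "GCQL":
        gru = nn.GRUCell(meta["dim"], meta["gru_units"], rng)
        conv = nn.Conv1dSingleChannel(meta["conv_filters"], meta["kernel_size"], rng)
        d1 = nn.Linear(meta["conv_filters"], meta["dense_units"], rng)
        d2 = nn.Linear(meta["dense_units"], 2, rng)
        model = GCQLModel(gru, conv, d1, d2, mu, sd, meta["seq_len"], [])
        params = model.params
    else:
        bidir = meta["kind"] == "BILSTM"
        layers, in_dim = [], meta["dim"]
        for _ in range(meta["n_layers"]):
            if bidir:
                layers.append((nn.LSTMCell(in_dim, meta["hidden"], rng),
                               nn.LSTMCell(in_dim, meta["hidden"], rng)))
                in_dim = 2 * meta["hidden"]
            else:
                layers.append(nn.LSTMCell(in_dim, meta["hidden"], rng))
                in_dim = meta["hidden"]
        head = nn.Linear(in_dim, 2, rng)
        model = _RecurrentModel(layers, head, mu, sd, meta["seq_len"], bidir)
        params = head.params
        for cells in layers:
            params += (cells[0].params + cells[1].params) if bidir else cells.params
        model._params = params
    for p, arr in zip(params, arrays):
        p.data = arr
    return model


# ---------------------------------------------------------------------------
# evaluation

def evaluate(model, test: FeatureMatrix,
             window_length_s: float | None = None) -> EvalReport:
    """Confusion counts and ACC/TPR/TNR with attend-speaker-1 positive."""
    if len(test) == 0:
        raise ValueError("empty test set")
    y_true, y_pred = model.predict_with_truth(test)
    # class 0 == SPK1 == positive
    tp = int(np.sum((y_true == 0) & (y_pred == 0)))
    fn = int(np.sum((y_true == 0) & (y_pred != 0)))
    tn = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 1) & (y_pred != 1)))
    wlen = test.window_length_s if window_length_s is None else window_length_s
    return EvalReport(tp=tp, tn=tn, fp=fp, fn=fn, window_length_s=wlen)


def cross_validate(spec: ClassifierSpec, fm: FeatureMatrix,
                   n_folds: int = 10) -> dict:
    """Seeded stratified k-fold accuracy (mean and sd) for KNN/SVM."""
    from sklearn.model_selection import StratifiedKFold

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=spec.seed)
    accs = []
    idx = np.arange(len(fm))
    for tr, te in skf.split(idx, fm.y):
        m = train(spec, fm.subset(np.isin(idx, tr)))
        rep = evaluate(m, fm.subset(np.isin(idx, te)))
        accs.append(rep.acc)
    return {"acc_mean": float(np.mean(accs)), "acc_std": float(np.std(accs)),
            "n_folds": n_folds}


def window_sweep(rec, lengths_s, spec: ClassifierSpec, prototypes,
                 mode: str = "MULTIVARIATE", selection="ALL",
                 train_fraction: float = 0.7, seed: int = 0,
                 gcql_config: GCQLConfig | None = None,
                 subwindow_s: float = 0.25) -> list[EvalReport]:
    """Full pipeline (windows -> features -> split -> train -> evaluate) per
    window length; lengths that do not fit any trial are skipped with a warning.
    """
    from .features import build_features
    from .io_preprocess import segment_windows

    shortest = min(t.end - t.start for t in rec.trials) / rec.sfreq
    reports = []
    for length in lengths_s:
        if length * rec.sfreq < 2 or length > shortest:
            warnings.warn(f"window length {length}s does not fit the trials; skipped")
            continue
        windows = segment_windows(rec, length)
        win_samples = int(round(length * rec.sfreq))
        sub_samples = min(int(round(subwindow_s * rec.sfreq)), win_samples // 4)
        sub = sub_samples / rec.sfreq
        mode_eff = mode
        if mode.upper() == "MULTIVARIATE" and sub_samples < 2:
            # too short to resolve per-state dynamics: fall back to the
            # recurrence statistics of the GFP series alone
            mode_eff = "RQA_ONLY"
        fm = build_features(windows, prototypes, mode=mode_eff,
                            selection=selection, subwindow_s=sub)
        tr, te = split_trials(fm, train_fraction, seed=seed)
        model = train(spec, tr, gcql_config=gcql_config)
        reports.append(evaluate(model, te, window_length_s=length))
    return reports
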