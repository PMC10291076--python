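"""Evaluation protocols over synthetic datasets.

All train/test splits partition the data at repetition, trial or subject
granularity — never at window granularity — so windows cut from the same
gesture repetition can never leak across the split.

Protocols:
  * ratio            — first N of the 8 repetitions train, the rest test;
  * electrode_shift  — per subject, leave one trial (one wearing) out;
  * user_independent — leave one subject out;
  * theta_sweep      — encoder threshold parameter vs mean input SRR and
                       accuracy over the standard grid;
  * vthr2_sweep      — neuron release threshold vs mean hidden-layer SRR;
  * ablation         — {adaptive, fixed} encoding x {LIF-V-I, LIF-V} neuron.

Each run records accuracy, the mean SRR of the test spike samples (SRR1),
the mean hidden-layer SRR (SRR2) and the corresponding inference-power
estimate, one row per fold/grid point, in a tidy DataFrame.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as _stats

from . import encode as enc
from . import snn as _snn
from .power import snn_total_power

__all__ = [
    "ProtocolConfig",
    "THETA_GRID",
    "VTHR2_GRID",
    "split_by_ratio",
    "split_leave_one_trial",
    "split_leave_one_subject",
    "run_protocol",
    "one_way_anova",
]

THETA_GRID = (-0.4, -0.2, 0.0, 0.2, 0.4, 0.6, 0.8, 1.0, 1.5, 2.0)
VTHR2_GRID = (-5.0, -2.0, 0.0, 2.0, 5.0, 10.0, 15.0, 20.0)


@dataclass(frozen=True)
class ProtocolConfig:
    protocol: str = "ratio"
    n_train_repetitions: int = 1
    theta_grid: tuple = THETA_GRID
    vthr2_grid: tuple = VTHR2_GRID
    theta: float = 0.6
    fixed_threshold: float = 0.18
    hidden: int = 100
    v_thr2: float = 10.0
    v_thr2_lif_v: float = 0.5
    epochs: int = 50
    learning_rate: float = 0.1
    seed: int = 0

    def __post_init__(self):
        valid = ("ratio", "electrode_shift", "user_independent",
                 "theta_sweep", "vthr2_sweep", "ablation")
        if self.protocol not in valid:
            raise ValueError(f"protocol must be one of {valid}")


# --------------------------------------------------------------------------
# splits (masks over a labels DataFrame)
# --------------------------------------------------------------------------

def split_by_ratio(labels: pd.DataFrame, n_train: int) -> tuple:
    """First ``n_train`` repetitions (recording order) -> train, rest -> test.

    Returns boolean masks (train, test) over the rows of ``labels``.
    """
    reps = np.sort(labels["repetition"].unique())
    if not 1 <= n_train < len(reps):
        raise ValueError(f"need 1 <= N < {len(reps)} repetitions")
    train = labels["repetition"].isin(reps[:n_train]).to_numpy()
    return train, ~train


def split_leave_one_trial(labels: pd.DataFrame, subject: int) -> list:
    """Per-subject leave-one-trial-out folds: [(train_mask, test_mask), ...]."""
    sub = (labels["subject"] == subject).to_numpy()
    trials = np.sort(labels.loc[sub, "trial"].unique())
    if len(trials) < 2:
        raise ValueError("need at least 2 trials")
    folds = []
    for t in trials:
        test = sub & (labels["trial"] == t).to_numpy()
        folds.append((sub & ~test, test))
    return folds


def split_leave_one_subject(labels: pd.DataFrame) -> list:
    """Leave-one-subject-out folds over the whole dataset."""
    subjects = np.sort(labels["subject"].unique())
    if len(subjects) < 2:
        raise ValueError("need at least 2 subjects")
    folds = []
    for s in subjects:
        test = (labels["subject"] == s).to_numpy()
        folds.append((~test, test))
    return folds


# --------------------------------------------------------------------------
# protocol execution
# --------------------------------------------------------------------------

def _fit_eval_snn(spk_train, y_train, spk_test, y_test, cfg: ProtocolConfig,
                  params: _snn.LifParams | None = None) -> dict:
    n_classes = int(max(y_train.max(), y_test.max())) + 1
    params = params or _snn.LifParams(v_thr2=cfg.v_thr2)
    net = _snn.SnnNetwork.init(spk_train.shape[1], cfg.hidden, n_classes,
                               params=params, T=spk_train.shape[2],
                               seed=cfg.seed)
    net, _ = _snn.train(net, spk_train, y_train, _snn.TrainConfig(
        learning_rate=cfg.learning_rate, epochs=cfg.epochs, seed=cfg.seed))
    acc = _snn.evaluate(net, spk_test, y_test)
    srr1 = float(np.mean(spk_test))
    srr2 = _snn.hidden_layer_srr(net, spk_test)
    power = snn_total_power(net.T, net.input_count, net.input_count,
                            net.hidden_count, net.output_count,
                            srr1, srr2).total
    return {"accuracy": acc, "srr1": srr1, "srr2": srr2, "power": power}


def _encoder(cfg: ProtocolConfig, mode: str = "adaptive",
             theta: float | None = None) -> enc.EncoderConfig:
    return enc.EncoderConfig(mode=mode,
                             theta=cfg.theta if theta is None else theta,
                             fixed_threshold=cfg.fixed_threshold)


def run_protocol(config: ProtocolConfig, X: np.ndarray,
                 labels: pd.DataFrame) -> pd.DataFrame:
    """Execute encode -> train -> evaluate per fold / grid point.

    ``X``: (n, channels, T) preprocessed real-valued windows; ``labels``
    must carry subject / trial / gesture / repetition columns.  Deterministic
    under ``config.seed``.
    """
    y = labels["gesture"].to_numpy()
    rows = []
    if config.protocol == "ratio":
        spikes = enc.encode_batch(X, _encoder(config))
        tr, te = split_by_ratio(labels, config.n_train_repetitions)
        res = _fit_eval_snn(spikes[tr], y[tr], spikes[te], y[te], config)
        rows.append({"protocol": "ratio", "fold": 0, "classifier": "snn",
                     "scheme": f"N={config.n_train_repetitions}", **res})

    elif config.protocol == "electrode_shift":
        spikes = enc.encode_batch(X, _encoder(config))
        for s in np.sort(labels["subject"].unique()):
            for f, (tr, te) in enumerate(split_leave_one_trial(labels, s)):
                res = _fit_eval_snn(spikes[tr], y[tr], spikes[te], y[te], config)
                rows.append({"protocol": "electrode_shift", "fold": f,
                             "classifier": "snn", "scheme": f"subject={s}",
                             **res})

    elif config.protocol == "user_independent":
        spikes = enc.encode_batch(X, _encoder(config))
        for f, (tr, te) in enumerate(split_leave_one_subject(labels)):
            res = _fit_eval_snn(spikes[tr], y[tr], spikes[te], y[te], config)
            rows.append({"protocol": "user_independent", "fold": f,
                         "classifier": "snn", "scheme": "loso", **res})

    elif config.protocol == "theta_sweep":
        tr, te = split_by_ratio(labels, config.n_train_repetitions)
        for f, theta in enumerate(config.theta_grid):
            spikes = enc.encode_batch(X, _encoder(config, theta=theta))
            res = _fit_eval_snn(spikes[tr], y[tr], spikes[te], y[te], config)
            rows.append({"protocol": "theta_sweep", "fold": f,
                         "classifier": "snn", "scheme": f"theta={theta}",
                         "theta": theta, **res})

    elif config.protocol == "vthr2_sweep":
        # train once, then treat the release threshold as an inference
        # parameter: SRR2 monotonicity is a property of fixed weights
        spikes = enc.encode_batch(X, _encoder(config))
        tr, te = split_by_ratio(labels, config.n_train_repetitions)
        n_classes = int(y.max()) + 1
        net = _snn.SnnNetwork.init(spikes.shape[1], config.hidden, n_classes,
                                   params=_snn.LifParams(v_thr2=config.v_thr2),
                                   T=spikes.shape[2], seed=config.seed)
        net, _ = _snn.train(net, spikes[tr], y[tr], _snn.TrainConfig(
            learning_rate=config.learning_rate, epochs=config.epochs,
            seed=config.seed))
        srr1 = float(np.mean(spikes[te]))
        for f, vt in enumerate(config.vthr2_grid):
            p = _snn.LifParams(v_thr2=vt)
            net_vt = replace(net, params1=p, params2=p)
            acc = _snn.evaluate(net_vt, spikes[te], y[te])
            srr2 = _snn.hidden_layer_srr(net_vt, spikes[te])
            power = snn_total_power(net.T, net.input_count, net.input_count,
                                    net.hidden_count, net.output_count,
                                    srr1, srr2).total
            rows.append({"protocol": "vthr2_sweep", "fold": f,
                         "classifier": "snn", "scheme": f"vthr2={vt}",
                         "v_thr2": vt, "accuracy": acc, "srr1": srr1,
                         "srr2": srr2, "power": power})

    elif config.protocol == "ablation":
        schemes = [("adaptive", "lif-v-i"), ("fixed", "lif-v-i"),
                   ("adaptive", "lif-v"), ("fixed", "lif-v")]
        folds = []
        for s in np.sort(labels["subject"].unique()):
            folds.extend(split_leave_one_trial(labels, s))
        for f, (tr, te) in enumerate(folds):
            for mode, variant in schemes:
                spikes = enc.encode_batch(X, _encoder(config, mode=mode))
                vt = config.v_thr2 if variant == "lif-v-i" else config.v_thr2_lif_v
                params = _snn.LifParams(v_thr2=vt, variant=variant)
                res = _fit_eval_snn(spikes[tr], y[tr], spikes[te], y[te],
                                    config, params=params)
                rows.append({"protocol": "ablation", "fold": f,
                             "classifier": "snn",
                             "scheme": f"{mode}+{variant}", **res})
    return pd.DataFrame(rows)


def one_way_anova(*groups) -> tuple:
    """Standard one-way ANOVA (F, p) across accuracy groups.

    Identical groups give F = 0; a perfectly separated pair gives a p-value
    below any conventional significance level.
    """
    if len(groups) == 1 and isinstance(groups[0], (list, tuple)) \
            and hasattr(groups[0][0], "__len__"):
        groups = tuple(groups[0])
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if np.ptp(np.concatenate(arrs)) == 0:
        return 0.0, 1.0          # all values equal: no effect by definition
    res = _stats.f_oneway(*arrs)
    return float(res.statistic), float(res.pvalue)
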