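"""Joint training objective and optimisation loop.

Per optimisation step, one minibatch is drawn from every source domain
and one from the (unlabeled) target.  Each source batch is pushed
through the shared extractor and its own branch bank; the target batch
is pushed through the shared extractor once and through every domain's
branch bank.  The loss for domain i is

    L_i = CE(softmax head_i, source labels) + alpha * sum_j MMD^2_ij,

where MMD^2_ij compares source and target batches in branch j's
representation space, and the total loss is the sum over domains.  The
trade-off coefficient follows the saturating schedule

    alpha(i) = 2 / (1 + exp(-10 i / epochs)) - 1,

which starts at 0 (classification first) and approaches 1, switching
emphasis to distribution alignment as training proceeds.  All domains
are updated jointly in one adaptive-moment (Adam) step.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
import pandas as pd

from .domains import DomainPartition
from .exceptions import (
    DomainCountError,
    InvalidConfigError,
    MissingLabelsError,
    MsmraError,
    ShapeError,
)
from .mmd import KernelConfig, MMDEstimate, mmd2_with_grad
from .model import ModelConfig, MSMRANetwork, softmax
from .preprocess import FeatureTensor, normalize_features

logger = logging.getLogger(__name__)

_clamp_events = 0  # process-wide count of clamped cross-entropy terms

__all__ = [
    "TrainConfig",
    "TrainState",
    "alpha_schedule",
    "classification_loss",
    "total_loss",
    "train",
    "train_arrays",
    "evaluate",
    "run_scenario",
]


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of the optimisation loop.

    ``alpha=None`` selects the dynamic schedule; a float fixes the
    coefficient (0.0 disables adaptation).  ``compute_mmd=False``
    detaches the alignment term entirely (no kernel evaluations), which
    with ``alpha=0.0`` must reproduce the pure multi-head classifier
    trajectory.  Ablation switches: ``normalize`` (per-recording
    z-score before training) and ``mdsfe`` (multi-representation banks
    vs. a single branch of the same concatenated width).
    """

    lr: float = 0.01
    batch_size: int = 256
    epochs: int = 50
    beta1: float = 0.9
    beta2: float = 0.999
    adam_eps: float = 1e-8
    alpha: float | None = None
    schedule_per_step: bool = False
    kernel: KernelConfig = field(default_factory=KernelConfig)
    normalize: bool = True
    mdsfe: bool = True
    compute_mmd: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise InvalidConfigError("epochs must be >= 1")
        if self.batch_size < 4:
            raise InvalidConfigError("batch_size must be >= 4 (MMD needs 2 per side)")


@dataclass
class TrainState:
    """Per-epoch training history."""

    cls_loss: list[list[float]] = field(default_factory=list)
    mmd_total: list[float] = field(default_factory=list)
    alpha: list[float] = field(default_factory=list)
    total: list[float] = field(default_factory=list)
    target_accuracy: list[float] = field(default_factory=list)

    @property
    def epochs_completed(self) -> int:
        return len(self.total)


def alpha_schedule(i: float, epochs: int) -> float:
    """Dynamic trade-off coefficient at (0-based) epoch ``i``.

    ``2 / (1 + exp(-10 i / epochs)) - 1``: zero at the start, ~0.9999
    at the end, strictly increasing.
    """
    if epochs <= 0:
        raise InvalidConfigError("epochs must be positive")
    return 2.0 / (1.0 + math.exp(-10.0 * i / epochs)) - 1.0


def classification_loss(probabilities: np.ndarray, labels: np.ndarray, eps: float = 1e-12) -> float:
    """Mean cross-entropy of predicted distributions against integer labels."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    if p.ndim != 2 or p.shape[0] != y.shape[0]:
        raise ShapeError(f"{p.shape} probabilities vs {y.shape} labels")
    picked = p[np.arange(len(y)), y]
    if np.any(picked <= eps):
        global _clamp_events
        _clamp_events += 1
        # warn once, then keep counting quietly
        (logger.warning if _clamp_events == 1 else logger.debug)(
            "probability at true class clamped to %g (event %d)", eps, _clamp_events
        )
    return float(-np.log(np.maximum(picked, eps)).mean())


def total_loss(per_domain_cls: list[float], mmd_estimate: MMDEstimate, alpha: float) -> float:
    """Sum over domains of classification loss plus alpha times that
    domain's alignment loss; equals ``sum(cls) + alpha * total`` by
    distributivity."""
    if len(per_domain_cls) != len(mmd_estimate.per_domain):
        raise DomainCountError(
            f"{len(per_domain_cls)} classification losses vs "
            f"{len(mmd_estimate.per_domain)} MMD domains"
        )
    return float(
        sum(c + alpha * m for c, m in zip(per_domain_cls, mmd_estimate.per_domain))
    )


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float, b1: float, b2: float, eps: float):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def _draw(rng: np.random.Generator, n: int, size: int, what: str, warned: set) -> np.ndarray:
    if n >= size:
        return rng.choice(n, size=size, replace=False)
    if what not in warned:
        logger.info("%s has %d rows < batch %d; sampling with replacement", what, n, size)
        warned.add(what)
    return rng.choice(n, size=size, replace=True)


def train_arrays(
    sources: list[tuple[np.ndarray, np.ndarray]],
    target: np.ndarray | None,
    config: TrainConfig,
    model_config: ModelConfig | None = None,
    network: MSMRANetwork | None = None,
    target_labels: np.ndarray | None = None,
) -> tuple[MSMRANetwork, TrainState]:
    """Core optimisation loop on plain arrays.

    ``sources`` holds one ``(X, y)`` pair per source domain (pooled over
    its member recordings); ``target`` the unlabeled target windows
    (``None`` trains a pure multi-head classifier).  ``target_labels``
    are used only to record per-epoch target accuracy in the history.
    """
    if not sources:
        raise InvalidConfigError("need at least one source domain")
    for i, (_, ys) in enumerate(sources):
        if ys is None or np.any(np.asarray(ys) < 0):
            raise MissingLabelsError(f"source domain {i} has missing labels")

    n_classes = int(max(int(np.max(ys)) for _, ys in sources)) + 1
    in_dim = sources[0][0].shape[1]
    if model_config is None:
        model_config = ModelConfig(
            in_dim=in_dim,
            n_domains=len(sources),
            n_classes=n_classes,
            mdsfe=config.mdsfe,
        )
    if network is None:
        network = MSMRANetwork(model_config, seed=config.seed)
    cfg = network.config
    if cfg.n_domains != len(sources):
        raise DomainCountError(f"network has {cfg.n_domains} domains, data has {len(sources)}")

    # independent streams so that detaching the alignment term (which
    # skips target draws) leaves the source batch sequence untouched
    _src_seed, _tgt_seed = np.random.SeedSequence(config.seed).spawn(2)
    rng = np.random.default_rng(_src_seed)
    rng_tgt = np.random.default_rng(_tgt_seed)
    params = network.parameters()
    opt = _Adam(params, config.lr, config.beta1, config.beta2, config.adam_eps)
    slices = network.grad_slices()
    state = TrainState()
    warned: set = set()

    use_mmd = config.compute_mmd and target is not None and target.shape[0] >= 2
    # one epoch = one pass over the pooled source windows (each step
    # consumes one batch per domain plus one target batch)
    steps_per_epoch = max(
        1, math.ceil(sum(X.shape[0] for X, _ in sources) / config.batch_size)
    )
    n_steps_total = config.epochs * steps_per_epoch

    for epoch in range(config.epochs):
        ep_cls = np.zeros(cfg.n_domains)
        ep_mmd = 0.0
        ep_total = 0.0
        for step in range(steps_per_epoch):
            if config.alpha is not None:
                alpha = float(config.alpha)
            elif config.schedule_per_step:
                alpha = alpha_schedule(epoch * steps_per_epoch + step, n_steps_total)
            else:
                alpha = alpha_schedule(epoch, config.epochs)

            grads = network.zero_grads()
            per_domain_cls: list[float] = []
            per_domain_mmd: list[list[float]] = []

            Ft = cache_t = None
            if use_mmd:
                ti = _draw(rng_tgt, target.shape[0], config.batch_size, "target", warned)
                Xt = target[ti]
                cache_t = []
                Ft = network.common.forward(Xt, cache_t)
                gFt = np.zeros_like(Ft)

            for i, (Xs_all, ys_all) in enumerate(sources):
                si = _draw(rng, Xs_all.shape[0], config.batch_size, f"source {i}", warned)
                Xs, ys = Xs_all[si], ys_all[si]
                b = Xs.shape[0]

                cache_s = []
                Fs = network.common.forward(Xs, cache_s)
                bcaches_s: list = []
                reps_s = network.mdsfe_extract(Fs, i, bcaches_s)
                concat = np.hstack(reps_s)
                hcache: list = []
                logits = network.heads[i].forward(concat, hcache)
                probs = softmax(logits)
                per_domain_cls.append(classification_loss(probs, ys))

                onehot = np.zeros_like(probs)
                onehot[np.arange(b), ys] = 1.0
                g_logits = (probs - onehot) / b
                hs, he = slices[f"head_{i}"]
                g_concat = network.heads[i].backward(hcache, g_logits, grads[hs:he])
                widths = list(cfg.effective_branch_dims)
                g_reps_cls = np.split(g_concat, np.cumsum(widths)[:-1], axis=1)

                mmd_i: list[float] = []
                reps_t = None
                bcaches_t: list = []
                if use_mmd:
                    reps_t = network.mdsfe_extract(Ft, i, bcaches_t)

                gFs = np.zeros_like(Fs)
                for j in range(len(widths)):
                    g_rep_s = g_reps_cls[j]
                    bs, be = slices[f"branch_{i}_{j}"]
                    if use_mmd:
                        m_ij, gS, gT = mmd2_with_grad(reps_s[j], reps_t[j], config.kernel)
                        mmd_i.append(m_ij)
                        g_rep_s = g_rep_s + alpha * gS
                        gFt += network.branches[i][j].backward(
                            bcaches_t[j], alpha * gT, grads[bs:be]
                        )
                    gFs += network.branches[i][j].backward(bcaches_s[j], g_rep_s, grads[bs:be])
                cs, ce = slices["common"]
                network.common.backward(cache_s, gFs, grads[cs:ce])
                per_domain_mmd.append(mmd_i if mmd_i else [0.0])

            if use_mmd:
                cs, ce = slices["common"]
                network.common.backward(cache_t, gFt, grads[cs:ce])

            opt.step(grads)

            est = MMDEstimate(per_representation=per_domain_mmd)
            ep_cls += np.asarray(per_domain_cls)
            ep_mmd += est.total
            ep_total += total_loss(per_domain_cls, est, alpha)

        network.trained = True
        state.cls_loss.append(list(ep_cls / steps_per_epoch))
        state.mmd_total.append(ep_mmd / steps_per_epoch)
        state.alpha.append(alpha)
        state.total.append(ep_total / steps_per_epoch)
        if target is not None and target_labels is not None:
            pred, _ = network.predict_target(target)
            state.target_accuracy.append(float(np.mean(pred == target_labels)))

    return network, state


def _prepared(tensor: FeatureTensor, normalize: bool) -> FeatureTensor:
    if normalize:
        return normalize_features(tensor, on_normalized="noop")
    return tensor


def train(
    partition: DomainPartition,
    config: TrainConfig,
    network: MSMRANetwork | None = None,
) -> tuple[MSMRANetwork, TrainState]:
    """Train on one partition, honouring the normalization switch.

    Normalization statistics are computed per recording, so the target's
    statistics never touch the sources.  Target labels are withheld from
    the optimiser and used only for the per-epoch accuracy trace.
    """
    sources = []
    for dom in partition.sources:
        members = [_prepared(m, config.normalize) for m in dom.members]
        X = np.vstack([m.values for m in members])
        y = np.concatenate([m.labels for m in members])
        sources.append((X, y))
    tgt = _prepared(partition.target, config.normalize)
    return train_arrays(
        sources, tgt.values, config, network=network, target_labels=tgt.labels
    )


def evaluate(
    network: MSMRANetwork,
    target: FeatureTensor,
    normalize: bool = True,
    trial_vote: bool = False,
) -> tuple[float, np.ndarray]:
    """Accuracy and confusion matrix on a labelled target recording.

    Window-level by default; ``trial_vote`` aggregates windows by trial
    majority (ties toward the lower class index) before scoring.
    """
    from sklearn.metrics import confusion_matrix

    tgt = _prepared(target, normalize)
    pred, _ = network.predict_target(tgt.values)
    true = tgt.labels
    if trial_vote:
        m = network.config.n_classes
        trials = np.unique(tgt.trial_index)
        p_out, t_out = [], []
        for t in trials:
            mask = tgt.trial_index == t
            counts = np.bincount(pred[mask], minlength=m)
            p_out.append(int(np.argmax(counts)))
            t_out.append(int(np.bincount(true[mask]).argmax()))
        pred, true = np.asarray(p_out), np.asarray(t_out)
    acc = float(np.mean(pred == true))
    cm = confusion_matrix(true, pred, labels=np.arange(network.config.n_classes))
    return acc, cm


def run_scenario(
    splits: list[DomainPartition], config: TrainConfig
) -> tuple[pd.DataFrame, dict]:
    """Train one model per partition and aggregate target accuracies.

    Returns the per-split results table (columns: split_id, scenario,
    n_domains, accuracy, seed, status) and a summary with the mean and
    population standard deviation over successful splits.
    """
    if not splits:
        raise InvalidConfigError("need at least one partition")
    rows = []
    for part in splits:
        try:
            network, _ = train(part, config)
            acc, _ = evaluate(network, part.target, normalize=config.normalize)
            rows.append(
                dict(
                    split_id=part.split_id,
                    scenario=part.scenario,
                    n_domains=part.n_domains,
                    accuracy=acc,
                    seed=config.seed,
                    status="ok",
                )
            )
        except MsmraError as exc:  # pragma: no cover - defensive
            logger.warning("split %s failed: %s", part.split_id, exc)
            rows.append(
                dict(
                    split_id=part.split_id,
                    scenario=part.scenario,
                    n_domains=part.n_domains,
                    accuracy=float("nan"),
                    seed=config.seed,
                    status=f"failed: {exc}",
                )
            )
    table = pd.DataFrame(rows)
    ok = table[table.status == "ok"].accuracy
    summary = {
        "mean_accuracy": float(ok.mean()) if len(ok) else float("nan"),
        "sd_accuracy": float(ok.std(ddof=0)) if len(ok) else float("nan"),
        "n_splits": len(splits),
        "n_ok": int(len(ok)),
    }
    return table, summary


def ablation_variants(config: TrainConfig) -> dict[str, TrainConfig]:
    """The four-row ablation grid: full, -normalization, -MDSFE, -both."""
    return {
        "full": config,
        "w/o normalization": dc_replace(config, normalize=False),
        "w/o MDSFE": dc_replace(config, mdsfe=False),
        "w/o normalization + MDSFE": dc_replace(config, normalize=False, mdsfe=False),
    }
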