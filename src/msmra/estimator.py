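"""Scikit-learn estimator facade for the multi-source adaptation network.

``MSMRAClassifier`` wraps the whole method behind the familiar
``fit`` / ``predict`` / ``predict_proba`` surface so it composes with
pipelines and model selection.  Domain structure enters through the
semi-supervised convention: rows with label ``-1`` are the unlabeled
target, and an optional ``domain`` array assigns each labeled row to a
source domain.  Without either, it degenerates to an ordinary
multi-layer softmax classifier (one source domain, no alignment term).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .mmd import KernelConfig
from .model import ModelConfig
from .train import TrainConfig, train_arrays

__all__ = ["MSMRAClassifier"]


class MSMRAClassifier(ClassifierMixin, BaseEstimator):
    """Multi-source, multi-representation domain-adaptive classifier.

    Parameters
    ----------
    common_dims : tuple of int
        Layer widths of the shared feature extractor (input width is
        taken from the data; default reduces 310 to 64 in three layers).
    branch_dims : tuple of int
        Output widths of the r parallel per-domain branches; their sum
        is the classifier input width.
    mdsfe : bool
        If False, collapse each domain's bank to a single branch with
        the same concatenated width (the "w/o MDSFE" ablation).
    alpha : float or None
        Fixed trade-off between classification and alignment losses;
        ``None`` uses the saturating epoch schedule
        ``2 / (1 + exp(-10 i / epochs)) - 1``.  ``0.0`` disables
        adaptation.
    lr, batch_size, epochs : optimisation hyperparameters (Adam).
    num_kernels, kernel_spread, unbiased_mmd : Gaussian kernel family
        for the alignment loss (bandwidths geometrically spaced around
        the median heuristic).
    random_state : int
        Seed for weight initialisation and batch sampling.

    Attributes
    ----------
    classes_ : ndarray
        Sorted class labels seen in the labeled rows.
    network_ : MSMRANetwork
        The trained parameter container.
    history_ : TrainState
        Per-epoch losses, alpha values and (if a labeled target was
        supplied) target accuracy.
    """

    def __init__(
        self,
        common_dims: tuple[int, ...] = (256, 128, 64),
        branch_dims: tuple[int, ...] = (48, 32, 16),
        branch_depth: int = 3,
        leaky_slope: float = 0.01,
        mdsfe: bool = True,
        lr: float = 0.01,
        batch_size: int = 256,
        epochs: int = 50,
        alpha: float | None = None,
        schedule_per_step: bool = False,
        num_kernels: int = 5,
        kernel_spread: float = 2.0,
        unbiased_mmd: bool = False,
        compute_mmd: bool = True,
        random_state: int = 0,
    ):
        self.common_dims = common_dims
        self.branch_dims = branch_dims
        self.branch_depth = branch_depth
        self.leaky_slope = leaky_slope
        self.mdsfe = mdsfe
        self.lr = lr
        self.batch_size = batch_size
        self.epochs = epochs
        self.alpha = alpha
        self.schedule_per_step = schedule_per_step
        self.num_kernels = num_kernels
        self.kernel_spread = kernel_spread
        self.unbiased_mmd = unbiased_mmd
        self.compute_mmd = compute_mmd
        self.random_state = random_state

    def _train_config(self) -> TrainConfig:
        return TrainConfig(
            lr=self.lr,
            batch_size=self.batch_size,
            epochs=self.epochs,
            alpha=self.alpha,
            schedule_per_step=self.schedule_per_step,
            kernel=KernelConfig(
                num_kernels=self.num_kernels,
                spread_factor=self.kernel_spread,
                unbiased=self.unbiased_mmd,
            ),
            mdsfe=self.mdsfe,
            compute_mmd=self.compute_mmd,
            seed=self.random_state,
        )

    def fit(self, X, y, domain=None, target_labels=None):
        """Fit on labeled source rows and (optionally) unlabeled target rows.

        Rows with ``y == -1`` form the unlabeled target.  ``domain``
        assigns each source row to a source domain (consecutive
        integers from 0); target rows may carry ``-1`` there too.
        ``target_labels`` (evaluation only) enables the per-epoch
        target-accuracy trace.
        """
        X, y = check_X_y(X, y, dtype=float)
        y = y.astype(int)
        self.n_features_in_ = X.shape[1]
        labeled = y >= 0
        if not np.any(labeled):
            raise ValueError("no labeled source rows (all labels are -1)")
        self.classes_ = np.unique(y[labeled])
        code = np.searchsorted(self.classes_, y[labeled])

        if domain is None:
            dom = np.zeros(labeled.sum(), dtype=int)
        else:
            dom = np.asarray(domain, dtype=int)[labeled]
        dom_ids = np.unique(dom)
        sources = [(X[labeled][dom == d], code[dom == d]) for d in dom_ids]
        target = X[~labeled] if np.any(~labeled) else None

        cfg = self._train_config()
        model_cfg = ModelConfig(
            in_dim=self.n_features_in_,
            common_dims=tuple(self.common_dims),
            branch_dims=tuple(self.branch_dims),
            branch_depth=self.branch_depth,
            n_domains=len(sources),
            n_classes=len(self.classes_),
            leaky_slope=self.leaky_slope,
            mdsfe=self.mdsfe,
        )
        tl = None
        if target is not None and target_labels is not None:
            tl = np.searchsorted(self.classes_, np.asarray(target_labels))
        self.network_, self.history_ = train_arrays(
            sources, target, cfg, model_config=model_cfg, target_labels=tl
        )
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "network_")
        X = check_array(X, dtype=float)
        return self.network_.predict_proba(X)

    def predict(self, X):
        proba = self.predict_proba(X)
        return self.classes_[np.argmax(proba, axis=1)]
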