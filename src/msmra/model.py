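"""Network architecture: shared extractor, per-domain branches, classifiers.

The network maps a 310-dimensional DE feature vector through a common
(domain-shared) extractor to a 64-dimensional low-level feature, then
through each source domain's bank of r parallel branch extractors to
representations of widths 48, 32 and 16.  The concatenated 96-wide
vector feeds that domain's softmax classifier.  All affine layers are
followed by a leaky rectifier except the classifier, which is a single
affine layer followed by softmax.

Everything is plain numpy with hand-written backprop: forward methods
optionally record caches that the training loop replays in reverse.
Parameters of the N branch banks and N heads are independent, so the
gradient of one domain's classification loss is identically zero with
respect to every other domain's branch and head parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import InvalidConfigError, NotTrainedError, ShapeError

__all__ = ["ModelConfig", "MSMRANetwork"]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    ``common_dims`` are the widths of the shared extractor's layers
    (input width is ``in_dim``); ``branch_dims`` the output widths of
    the r parallel branches; ``branch_depth`` the number of affine
    layers per branch (intermediate layers keep the low-level width).
    ``mdsfe=False`` collapses each domain's bank to one branch of width
    ``sum(branch_dims)`` so the classifier input width is unchanged.
    """

    in_dim: int = 310
    common_dims: tuple[int, ...] = (256, 128, 64)
    branch_dims: tuple[int, ...] = (48, 32, 16)
    branch_depth: int = 3
    n_domains: int = 1
    n_classes: int = 3
    leaky_slope: float = 0.01
    mdsfe: bool = True

    def __post_init__(self) -> None:
        if self.n_domains < 1 or self.n_classes < 2:
            raise InvalidConfigError("need n_domains >= 1 and n_classes >= 2")
        if self.branch_depth < 1 or not self.branch_dims:
            raise InvalidConfigError("need branch_depth >= 1 and at least one branch")

    @property
    def low_dim(self) -> int:
        return self.common_dims[-1]

    @property
    def effective_branch_dims(self) -> tuple[int, ...]:
        return self.branch_dims if self.mdsfe else (sum(self.branch_dims),)

    @property
    def concat_dim(self) -> int:
        return sum(self.branch_dims)

    @property
    def n_branches(self) -> int:
        return len(self.effective_branch_dims)


class _MLP:
    """Affine stack with a leaky rectifier after every layer (optional on the last)."""

    def __init__(
        self,
        rng: np.random.Generator,
        dims: list[int],
        slope: float,
        final_activation: bool = True,
    ):
        self.slope = slope
        self.final_activation = final_activation
        self.W: list[np.ndarray] = []
        self.b: list[np.ndarray] = []
        for n_in, n_out in zip(dims[:-1], dims[1:]):
            bound = 1.0 / np.sqrt(n_in)
            self.W.append(rng.uniform(-bound, bound, size=(n_in, n_out)))
            self.b.append(rng.uniform(-bound, bound, size=n_out))

    def params(self) -> list[np.ndarray]:
        out = []
        for W, b in zip(self.W, self.b):
            out.extend([W, b])
        return out

    def forward(self, X: np.ndarray, cache: list | None = None) -> np.ndarray:
        h = X
        for li, (W, b) in enumerate(zip(self.W, self.b)):
            z = h @ W + b
            act = self.final_activation or li < len(self.W) - 1
            out = np.where(z >= 0, z, self.slope * z) if act else z
            if cache is not None:
                cache.append((h, z, act))
            h = out
        return h

    def backward(
        self, cache: list, g_out: np.ndarray, grads: list[np.ndarray]
    ) -> np.ndarray:
        """Backprop through the stack; accumulates parameter grads in-place.

        ``grads`` is parallel to :meth:`params`.  Returns the gradient
        with respect to the stack's input.
        """
        g = g_out
        for li in range(len(self.W) - 1, -1, -1):
            h, z, act = cache[li]
            if act:
                g = g * np.where(z >= 0, 1.0, self.slope)
            grads[2 * li] += h.T @ g
            grads[2 * li + 1] += g.sum(axis=0)
            g = g @ self.W[li].T
        return g


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class MSMRANetwork:
    """Parameter container and forward passes for the full architecture."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        c = config
        self.common = _MLP(rng, [c.in_dim, *c.common_dims], c.leaky_slope)
        self.branches: list[list[_MLP]] = []
        self.heads: list[_MLP] = []
        for _ in range(c.n_domains):
            bank = []
            for width in c.effective_branch_dims:
                dims = [c.low_dim] * c.branch_depth + [width]
                bank.append(_MLP(rng, dims, c.leaky_slope))
            self.branches.append(bank)
            self.heads.append(
                _MLP(rng, [c.concat_dim, c.n_classes], c.leaky_slope, final_activation=False)
            )
        self.trained = False

    # -- parameter bookkeeping -------------------------------------------------

    def parameters(self) -> list[np.ndarray]:
        out = self.common.params()
        for bank, head in zip(self.branches, self.heads):
            for br in bank:
                out.extend(br.params())
            out.extend(head.params())
        return out

    def zero_grads(self) -> list[np.ndarray]:
        return [np.zeros_like(p) for p in self.parameters()]

    def grad_slices(self) -> dict:
        """Offsets of each module's grads inside the flat parameter list."""
        idx = {"common": (0, len(self.common.params()))}
        pos = idx["common"][1]
        for i, (bank, head) in enumerate(zip(self.branches, self.heads)):
            for j, br in enumerate(bank):
                n = len(br.params())
                idx[f"branch_{i}_{j}"] = (pos, pos + n)
                pos += n
            n = len(head.params())
            idx[f"head_{i}"] = (pos, pos + n)
            pos += n
        return idx

    # -- forward contracts -----------------------------------------------------

    def _check_width(self, X: np.ndarray, width: int, what: str) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != width:
            raise ShapeError(f"{what}: expected width {width}, got {X.shape[1]}")
        return X

    def common_extract(self, X: np.ndarray, cache: list | None = None) -> np.ndarray:
        X = self._check_width(X, self.config.in_dim, "common_extract")
        return self.common.forward(X, cache)

    def mdsfe_extract(
        self, F: np.ndarray, domain_index: int, caches: list | None = None
    ) -> list[np.ndarray]:
        F = self._check_width(F, self.config.low_dim, "mdsfe_extract")
        if not 0 <= domain_index < self.config.n_domains:
            raise IndexError(f"domain index {domain_index} outside 0..{self.config.n_domains - 1}")
        reps = []
        for br in self.branches[domain_index]:
            cache: list | None = None
            if caches is not None:
                cache = []
                caches.append(cache)
            reps.append(br.forward(F, cache))
        return reps

    def classify(
        self, concat: np.ndarray, domain_index: int, cache: list | None = None
    ) -> np.ndarray:
        concat = self._check_width(concat, self.config.concat_dim, "classify")
        logits = self.heads[domain_index].forward(concat, cache)
        return softmax(logits)

    def domain_proba(self, X: np.ndarray, domain_index: int) -> np.ndarray:
        F = self.common_extract(X)
        reps = self.mdsfe_extract(F, domain_index)
        return self.classify(np.hstack(reps), domain_index)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Average of the N domain heads' softmax outputs."""
        if not self.trained:
            raise NotTrainedError("model has not been trained")
        F = self.common_extract(X)
        probs = np.zeros((F.shape[0], self.config.n_classes))
        for i in range(self.config.n_domains):
            reps = self.mdsfe_extract(F, i)
            probs += self.classify(np.hstack(reps), i)
        return probs / self.config.n_domains

    def predict_target(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Predicted labels plus the head-averaged class distribution.

        Ties break toward the lowest class index (argmax convention).
        """
        probs = self.predict_proba(X)
        return np.argmax(probs, axis=1), probs
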