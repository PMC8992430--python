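"""Greedy treed emulation: axis-aligned partitions with per-leaf models.

A deliberate greedy stand-in for fully Bayesian treed-GP posteriors: the
tree is grown by recursive binary splits chosen to maximize the reduction
in residual sum of squares (CART-style), and each leaf gets its own model —
linear, GP, or GPllm. Prediction routes each site to its leaf. With
``max_depth=0`` the emulator degenerates to the plain leaf model on all
data, which is how the TLM/TGP/TGPllm benchmark rows relate to LR/GP/GPllm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .base import Emulator, EmulatorResults, Prediction, TrainSet
from .gp import GaussianProcess
from .llm import LimitingLinearGP, LinearModel

__all__ = ["TreedEmulator", "TreedResults"]

_LEAF_MODELS = ("linear", "gp", "gpllm")


@dataclass
class _Node:
    idx: np.ndarray
    split_dim: int = -1
    split_val: float = 0.0
    left: "._Node" = None
    right: "._Node" = None
    leaf_results: EmulatorResults = field(default=None, repr=False)

    @property
    def is_leaf(self) -> bool:
        return self.left is None


def _best_split(U: np.ndarray, z: np.ndarray, idx: np.ndarray, min_leaf: int):
    """(dim, threshold, sse_reduction) of the best axis-aligned split."""
    zz = z[idx]
    n = idx.size
    total_sse = float(((zz - zz.mean()) ** 2).sum())
    best = (None, 0.0, 0.0)
    if n < 2 * min_leaf:
        return best
    for j in range(U.shape[1]):
        order = np.argsort(U[idx, j], kind="stable")
        u = U[idx[order], j]
        zs = zz[order]
        csum = np.cumsum(zs)
        csq = np.cumsum(zs**2)
        cuts = np.arange(min_leaf, n - min_leaf + 1)  # left sizes
        cuts = cuts[u[cuts - 1] < u[cuts]]  # need a distinct boundary value
        if cuts.size == 0:
            continue
        nl = cuts.astype(float)
        nr = n - nl
        sl = csq[cuts - 1] - csum[cuts - 1] ** 2 / nl
        sr = (csq[-1] - csq[cuts - 1]) - (csum[-1] - csum[cuts - 1]) ** 2 / nr
        red = total_sse - (sl + sr)
        k = int(np.argmax(red))
        if red[k] > best[2]:
            cut = int(cuts[k])
            thr = 0.5 * (u[cut - 1] + u[cut])
            best = (j, thr, float(red[k]))
    return best


class TreedEmulator(Emulator):
    def __init__(self, train: TrainSet, leaf: str = "linear",
                 max_depth: int = 2, min_leaf: int | None = None,
                 nugget="estimate"):
        super().__init__(train)
        if leaf not in _LEAF_MODELS:
            raise ValueError(f"leaf must be one of {_LEAF_MODELS}")
        self.leaf = leaf
        self.max_depth = int(max_depth)
        if min_leaf is None:
            min_leaf = train.d + 2 if leaf in ("gp", "gpllm") else max(10, train.d + 2)
        self.min_leaf = int(min_leaf)
        if self.min_leaf < train.d + 2 and leaf in ("gp", "gpllm"):
            raise ValueError("min_leaf must be >= d + 2 for GP leaves")
        if train.n < self.min_leaf:
            raise ValueError("fewer training rows than min_leaf")
        self.nugget = nugget

    def _fit_leaf(self, idx: np.ndarray, seed: int, gp_kwargs: dict):
        sub = self.train.subset(idx)
        if self.leaf == "linear" or sub.n < sub.d + 2:
            return LinearModel(sub).fit(seed=seed)
        if self.leaf == "gp":
            return GaussianProcess(sub, nugget=self.nugget).fit(seed=seed, **gp_kwargs)
        return LimitingLinearGP(sub, nugget=self.nugget).fit(seed=seed, **gp_kwargs)

    def fit(self, seed: int = 0, **gp_kwargs) -> "TreedResults":
        U, z = self.train.U, self.train.z
        root = _Node(idx=np.arange(self.train.n))

        def grow(node: _Node, depth: int):
            if depth >= self.max_depth or node.idx.size < 2 * self.min_leaf:
                node.leaf_results = self._fit_leaf(node.idx, seed, gp_kwargs)
                return
            j, thr, red = _best_split(U, z, node.idx, self.min_leaf)
            if j is None or red <= 1e-12:
                node.leaf_results = self._fit_leaf(node.idx, seed, gp_kwargs)
                return
            node.split_dim, node.split_val = j, thr
            mask = U[node.idx, j] <= thr
            node.left = _Node(idx=node.idx[mask])
            node.right = _Node(idx=node.idx[~mask])
            grow(node.left, depth + 1)
            grow(node.right, depth + 1)

        grow(root, 0)
        return TreedResults(model=self, root=root)


@dataclass
class TreedResults(EmulatorResults):
    root: _Node = field(default=None, repr=False)

    def _route(self, u: np.ndarray) -> _Node:
        node = self.root
        while not node.is_leaf:
            node = node.left if u[node.split_dim] <= node.split_val else node.right
        return node

    def predict(self, Xnew) -> Prediction:
        Xnew = np.atleast_2d(np.asarray(Xnew, dtype=float))
        Un = self.train.scale_X(Xnew)
        leaf_rows: dict[int, list[int]] = {}
        leaves: dict[int, _Node] = {}
        for i, u in enumerate(Un):
            node = self._route(u)
            leaf_rows.setdefault(id(node), []).append(i)
            leaves[id(node)] = node
        mean = np.empty(Un.shape[0])
        sd = np.empty(Un.shape[0])
        for key, rows in leaf_rows.items():
            p = leaves[key].leaf_results.predict(Xnew[rows])
            mean[rows], sd[rows] = p.mean, p.sd
        return Prediction.gaussian(mean, sd)

    @property
    def splits(self) -> list[tuple[str, float]]:
        out = []

        def walk(node: _Node):
            if node.is_leaf:
                return
            out.append((self.train.names[node.split_dim], node.split_val))
            walk(node.left)
            walk(node.right)

        walk(self.root)
        return out

    @property
    def n_leaves(self) -> int:
        count = 0
        stack = [self.root]
        while stack:
            node = stack.pop()
            if node.is_leaf:
                count += 1
            else:
                stack += [node.left, node.right]
        return count

    def _summary_rows(self):
        return super()._summary_rows() + [
            ("Leaf model", self.model.leaf),
            ("Leaves", str(self.n_leaves)),
            ("Splits", "; ".join(f"{n} <= {v:.3f}" for n, v in self.splits) or "(none)"),
        ]
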