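"""Gradient boosting over trees whose split features are learned kernels.

The pixel classifier is an ensemble of M decision trees combined by gradient
boosting with a quadratic (Newton) approximation of the exponential margin
loss L(y, phi) = exp(-y * phi). At every boosting round the per-sample Newton
weights are w_i = exp(-y_i * phi_i) and the pseudo-residuals are r_i = y_i.

Each tree node owns a small convolution kernel: a square window of side
4-19 px anchored at a fixed position inside the 41 x 41 patch. Candidate
kernels are fit on one half of the training data (T1) by regularized weighted
least squares,

    K = argmin_K  sum_i w_i (K * x_i - r_i)^2
               + lambda * sum_{m,n neighbours} (K(m) - K(n))^2,

where the second term is a 4-neighbour graph-Laplacian smoothness penalty
with lambda drawn from {100, 500, 1000}. The split threshold and leaf values
are chosen on the other half (T2) by exhaustive search over sorted response
midpoints; the candidate with the smallest weighted split cost wins.

Self-training: the first round learns from the morphological harvest; each
later round predicts on the sampled frames, adds confidently classified
pixels (>= 0.9 leg / <= 0.1 leg) to the pools, resamples patches, and
retrains, so the training set grows without any annotation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from functools import lru_cache
from pathlib import Path
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .imaging_io import FrameStack, SilhouetteMask
from .training_harvest import (
    LabeledPixelPool,
    TrainingPatchSet,
    extract_patches,
    harvest_confident_pixels,
    sample_training_frames,
)

__all__ = [
    "ConvKernel",
    "SplitDecision",
    "WeakLearner",
    "BoostedClassifier",
    "ConfidenceMap",
    "TrainingConfig",
    "learn_kernel",
    "find_best_split",
    "grow_tree",
    "fit_classifier",
    "predict_confidence",
    "self_train",
    "save_classifier",
    "load_classifier",
]

logger = logging.getLogger(__name__)

PATCH = 41
KERNEL_SIZES = (4, 19)
LAMBDAS = (100.0, 500.0, 1000.0)
SCORE_CLIP = 30.0


@dataclass
class TrainingConfig:
    """Hyperparameters of the learner (defaults are the full-scale settings)."""

    n_pos: int = 30_000
    n_neg: int = 30_000
    patch_size: int = PATCH
    t1_size: int = 10_000  # samples used to fit candidate kernels
    n_rounds: int = 100  # boosting rounds M
    gamma: float = 0.1  # shrinkage
    n_candidates: int = 100  # candidate kernels per split
    max_depth: int = 5
    min_node_size: int = 20
    frame_stride: int = 20
    self_train_rounds: int = 2
    conf_pos_gate: float = 0.9
    conf_neg_gate: float = 0.1
    max_fit_samples: int = 2000  # per-candidate cap on kernel-fit samples
    seed: int = 0


@dataclass
class ConvKernel:
    weights: np.ndarray  # (s, s)
    anchor: tuple[int, int]  # (row, col) of the window inside the patch
    lambda_used: float = 0.0

    @property
    def size(self) -> int:
        return self.weights.shape[0]


@dataclass
class SplitDecision:
    kernel: ConvKernel
    tau: float
    eta_left: float
    eta_right: float
    cost: float
    candidate_index: int = -1


@dataclass
class _Node:
    kernel: ConvKernel | None = None
    tau: float = 0.0
    left: "_Node | None" = None
    right: "_Node | None" = None
    value: float = 0.0  # leaf value eta

    @property
    def is_leaf(self) -> bool:
        return self.kernel is None


@dataclass
class WeakLearner:
    root: _Node

    def predict_patches(self, patches: np.ndarray) -> np.ndarray:
        out = np.empty(patches.shape[0])
        self._route_patches(self.root, patches, np.arange(patches.shape[0]), out)
        return out

    def _route_patches(self, node, patches, idx, out) -> None:
        if node.is_leaf:
            out[idx] = node.value
            return
        resp = _responses(patches, node.kernel, idx)
        left = resp < node.tau
        self._route_patches(node.left, patches, idx[left], out)
        self._route_patches(node.right, patches, idx[~left], out)

    def depth(self) -> int:
        def d(n):
            return 0 if n.is_leaf else 1 + max(d(n.left), d(n.right))

        return d(self.root)


@dataclass
class BoostedClassifier:
    learners: list[WeakLearner]
    gamma: float
    n_rounds: int
    training_log: list[float] = field(default_factory=list)
    config: dict = field(default_factory=dict)

    def decision_scores(self, patches: np.ndarray) -> np.ndarray:
        s = np.zeros(patches.shape[0])
        for h in self.learners:
            s += h.predict_patches(patches)
        return self.gamma * s


@dataclass
class ConfidenceMap:
    values: np.ndarray  # (H, W) in [0, 1], zero off the foreground
    frame_index: int = -1


# ---------------------------------------------------------------------------
# Kernel learning (T1)
# ---------------------------------------------------------------------------


@lru_cache(maxsize=32)
def _grid_laplacian(s: int) -> np.ndarray:
    """Dense graph Laplacian of the 4-neighbour grid on an s x s kernel."""
    n = s * s
    L = np.zeros((n, n))
    for i in range(s):
        for j in range(s):
            a = i * s + j
            for di, dj in ((0, 1), (1, 0)):
                ii, jj = i + di, j + dj
                if ii < s and jj < s:
                    b = ii * s + jj
                    L[a, a] += 1.0
                    L[b, b] += 1.0
                    L[a, b] -= 1.0
                    L[b, a] -= 1.0
    return L


def _windows(patches: np.ndarray, kernel_size: int, anchor: tuple[int, int],
             idx: np.ndarray | None = None) -> np.ndarray:
    """Flattened s*s windows of the given patches at a fixed anchor."""
    r, c = anchor
    s = kernel_size
    sel = patches if idx is None else patches[idx]
    return sel[:, r : r + s, c : c + s].reshape(sel.shape[0], s * s)


def _responses(patches: np.ndarray, kernel: ConvKernel,
               idx: np.ndarray | None = None) -> np.ndarray:
    w = _windows(patches, kernel.size, kernel.anchor, idx)
    return w @ kernel.weights.ravel().astype(w.dtype)


def learn_kernel(
    patches: np.ndarray,
    w: np.ndarray,
    r: np.ndarray,
    size: int,
    anchor: tuple[int, int],
    lam: float,
    max_fit_samples: int | None = None,
    rng: np.random.Generator | None = None,
) -> ConvKernel:
    """Fit one convolution kernel by regularized weighted least squares.

    Solves the normal equations (A' W A + lam * L) k = A' W r, where rows of
    A are the flattened patch windows at the anchor and L is the 4-neighbour
    grid Laplacian. A singular system gets a 1e-8 ridge jitter (logged).
    """
    n = patches.shape[0]
    idx = None
    if max_fit_samples is not None and n > max_fit_samples:
        rng = rng or np.random.default_rng(0)
        idx = rng.choice(n, size=max_fit_samples, replace=False)
    A = _windows(patches, size, anchor, idx).astype(np.float64)
    ww = np.asarray(w, dtype=np.float64) if idx is None else np.asarray(w)[idx]
    rr = np.asarray(r, dtype=np.float64) if idx is None else np.asarray(r)[idx]
    Aw = A * ww[:, None]
    G = Aw.T @ A
    if lam != 0.0:
        G = G + lam * _grid_laplacian(size)
    b = Aw.T @ rr
    try:
        k = np.linalg.solve(G, b)
        if not np.all(np.isfinite(k)):
            raise np.linalg.LinAlgError("non-finite solution")
    except np.linalg.LinAlgError:
        logger.debug("singular kernel system (s=%d, lam=%g); ridge jitter", size, lam)
        G = G + 1e-8 * np.eye(G.shape[0])
        k = np.linalg.solve(G, b)
    return ConvKernel(
        weights=k.reshape(size, size), anchor=tuple(anchor), lambda_used=lam
    )


# ---------------------------------------------------------------------------
# Split search (T2)
# ---------------------------------------------------------------------------


def find_best_split(
    patches: np.ndarray,
    w: np.ndarray,
    r: np.ndarray,
    candidates: Sequence[ConvKernel],
) -> SplitDecision | None:
    """Exhaustive threshold search over every candidate kernel.

    For each candidate the responses are sorted and every midpoint between
    distinct consecutive responses is scored by the weighted SSE of the two
    resulting leaves (leaf values are the weighted residual means). Returns
    the minimal-cost decision, ties broken by lowest candidate index and then
    lowest threshold; ``None`` when no candidate yields a valid split.
    """
    w = np.asarray(w, dtype=np.float64)
    r = np.asarray(r, dtype=np.float64)
    best: SplitDecision | None = None
    for ci, kern in enumerate(candidates):
        resp = _responses(patches, kern).astype(np.float64)
        order = np.argsort(resp, kind="stable")
        rs = resp[order]
        ws = w[order]
        rrs = r[order]
        valid = rs[1:] > rs[:-1]
        if not valid.any():
            continue
        cw = np.cumsum(ws)
        cwr = np.cumsum(ws * rrs)
        cwr2 = np.cumsum(ws * rrs * rrs)
        tot_w, tot_wr, tot_wr2 = cw[-1], cwr[-1], cwr2[-1]
        lw, lwr, lwr2 = cw[:-1], cwr[:-1], cwr2[:-1]
        rw = tot_w - lw
        rwr = tot_wr - lwr
        rwr2 = tot_wr2 - lwr2
        cost = (lwr2 - lwr * lwr / lw) + (rwr2 - rwr * rwr / rw)
        cost = np.where(valid, cost, np.inf)
        i = int(np.argmin(cost))
        c = float(cost[i])
        if best is None or c < best.cost - 1e-15:
            tau = 0.5 * (rs[i] + rs[i + 1])
            best = SplitDecision(
                kernel=kern,
                tau=float(tau),
                eta_left=float(lwr[i] / lw[i]),
                eta_right=float(rwr[i] / rw[i]),
                cost=max(c, 0.0),
                candidate_index=ci,
            )
    return best


# ---------------------------------------------------------------------------
# Tree growth
# ---------------------------------------------------------------------------


def _random_candidate_spec(rng: np.random.Generator, n_candidates: int,
                           patch_size: int):
    sizes = rng.integers(KERNEL_SIZES[0], KERNEL_SIZES[1] + 1, size=n_candidates)
    anchors = [
        (
            int(rng.integers(0, patch_size - s + 1)),
            int(rng.integers(0, patch_size - s + 1)),
        )
        for s in sizes
    ]
    lams = rng.choice(LAMBDAS, size=n_candidates)
    return sizes, anchors, lams


def grow_tree(
    patches: np.ndarray,
    w: np.ndarray,
    r: np.ndarray,
    t1_idx: np.ndarray,
    t2_idx: np.ndarray,
    rng: np.random.Generator,
    max_depth: int = 5,
    n_candidates: int = 100,
    min_node_size: int = 20,
    max_fit_samples: int | None = 2000,
) -> WeakLearner:
    """Grow one weak learner: kernels fit on T1, splits chosen on T2.

    Fresh candidate kernels (random size in [4, 19], random anchor, random
    smoothness lambda) are generated at every node. Recursion stops at
    ``max_depth``, at nodes with fewer than ``min_node_size`` T2 samples, or
    when no candidate separates the node's responses.
    """
    patch_size = patches.shape[1]

    def leaf(t2: np.ndarray) -> _Node:
        if t2.size:
            ww = w[t2]
            return _Node(value=float(np.sum(ww * r[t2]) / np.sum(ww)))
        return _Node(value=0.0)

    def build(t1: np.ndarray, t2: np.ndarray, depth: int) -> _Node:
        if depth >= max_depth or t2.size < min_node_size or t1.size == 0:
            return leaf(t2)
        sizes, anchors, lams = _random_candidate_spec(rng, n_candidates, patch_size)
        cands = [
            learn_kernel(
                patches[t1], w[t1], r[t1], int(s), a, float(l),
                max_fit_samples=max_fit_samples, rng=rng,
            )
            for s, a, l in zip(sizes, anchors, lams)
        ]
        dec = find_best_split(patches[t2], w[t2], r[t2], cands)
        if dec is None:
            return leaf(t2)
        node = _Node(kernel=dec.kernel, tau=dec.tau)
        l2 = _responses(patches, dec.kernel, t2) < dec.tau
        l1 = _responses(patches, dec.kernel, t1) < dec.tau
        t2l, t2r = t2[l2], t2[~l2]
        t1l, t1r = t1[l1], t1[~l1]
        if t2l.size == 0 or t2r.size == 0:
            return leaf(t2)
        node.left = build(t1l, t2l, depth + 1)
        node.right = build(t1r, t2r, depth + 1)
        return node

    return WeakLearner(root=build(np.asarray(t1_idx), np.asarray(t2_idx), 0))


# ---------------------------------------------------------------------------
# Boosting
# ---------------------------------------------------------------------------


def fit_classifier(
    train: TrainingPatchSet,
    n_rounds: int = 100,
    gamma: float = 0.1,
    t1_size: int = 10_000,
    n_candidates: int = 100,
    max_depth: int = 5,
    min_node_size: int = 20,
    max_fit_samples: int | None = 2000,
    rng: np.random.Generator | None = None,
) -> BoostedClassifier:
    """Boost weak learners with Newton weights for the exponential loss.

    Per round: w_i = exp(-y_i * phi_i), r_i = y_i; the training set is
    randomly resplit into T1 (kernel fitting) and T2 (split selection); the
    model is updated phi <- phi + gamma * h. The mean training loss after
    each round is recorded (it is non-increasing). Scores are clipped to
    +/- 30 to keep the exponential weights finite.
    """
    rng = rng or np.random.default_rng(0)
    patches = train.patches
    y = train.labels.astype(np.float64)
    n = len(train)
    phi = np.zeros(n)
    t1_n = min(t1_size, n // 2) if n > 1 else 1

    learners: list[WeakLearner] = []
    log: list[float] = []
    for j in range(n_rounds):
        w = np.exp(np.clip(-y * phi, -SCORE_CLIP, SCORE_CLIP))
        r = y
        perm = rng.permutation(n)
        t1_idx, t2_idx = perm[:t1_n], perm[t1_n:]
        if t2_idx.size == 0:
            t2_idx = t1_idx
        h = grow_tree(
            patches,
            w,
            r,
            t1_idx,
            t2_idx,
            rng,
            max_depth=max_depth,
            n_candidates=n_candidates,
            min_node_size=min_node_size,
            max_fit_samples=max_fit_samples,
        )
        phi = phi + gamma * h.predict_patches(patches)
        phi = np.clip(phi, -SCORE_CLIP, SCORE_CLIP)
        learners.append(h)
        log.append(float(np.mean(np.exp(np.clip(-y * phi, -SCORE_CLIP, SCORE_CLIP)))))

    return BoostedClassifier(
        learners=learners,
        gamma=gamma,
        n_rounds=n_rounds,
        training_log=log,
        config={
            "n_rounds": n_rounds,
            "gamma": gamma,
            "t1_size": t1_size,
            "n_candidates": n_candidates,
            "max_depth": max_depth,
            "min_node_size": min_node_size,
        },
    )


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------


def _scores_at_pixels(
    clf: BoostedClassifier,
    padded: np.ndarray,
    ys: np.ndarray,
    xs: np.ndarray,
) -> np.ndarray:
    """Raw ensemble scores for pixels (ys, xs) of a zero-padded frame.

    ``padded`` must be the frame scaled to [0, 1] and padded by patch//2 on
    each side, so the 41 x 41 patch of pixel (y, x) starts at padded[y, x].
    """
    n = ys.shape[0]
    total = np.zeros(n)
    scratch = np.empty(n)

    def route(node: _Node, idx: np.ndarray) -> None:
        if node.is_leaf:
            scratch[idx] = node.value
            return
        s = node.kernel.size
        ar, ac = node.kernel.anchor
        sw = sliding_window_view(padded, (s, s))
        win = sw[ys[idx] + ar, xs[idx] + ac].reshape(idx.size, s * s)
        resp = win @ node.kernel.weights.ravel().astype(win.dtype)
        left = resp < node.tau
        route(node.left, idx[left])
        route(node.right, idx[~left])

    all_idx = np.arange(n)
    for h in clf.learners:
        route(h.root, all_idx)
        total += scratch
    return clf.gamma * total


def predict_confidence(
    clf: BoostedClassifier,
    frame: np.ndarray,
    mask: SilhouetteMask,
) -> ConfidenceMap:
    """Leg-pixel confidence for every foreground pixel of one frame.

    Scores are mapped to [0, 1] by the logistic transform
    ``1 / (1 + exp(-2 * score))``; background pixels are 0.
    """
    values = np.zeros(mask.mask.shape)
    ys, xs = np.nonzero(mask.mask)
    if ys.size:
        scale = 1.0 / float(np.iinfo(frame.dtype).max) if np.issubdtype(
            np.asarray(frame).dtype, np.integer
        ) else 1.0
        padded = np.pad(
            np.asarray(frame, dtype=np.float32) * scale, PATCH // 2
        )
        scores = _scores_at_pixels(clf, padded, ys, xs)
        values[ys, xs] = 1.0 / (1.0 + np.exp(-2.0 * np.clip(scores, -SCORE_CLIP, SCORE_CLIP)))
    return ConfidenceMap(values=values, frame_index=mask.frame_index)


# ---------------------------------------------------------------------------
# Iterative self-training
# ---------------------------------------------------------------------------


def self_train(
    stack: FrameStack,
    masks: Sequence[SilhouetteMask],
    rounds: int = 2,
    config: TrainingConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[BoostedClassifier, list[tuple[int, int]]]:
    """Train the pixel classifier with iterative training-set augmentation.

    ``masks`` are the silhouettes of the sampled training frames, in the same
    order as :func:`~clawtrack.training_harvest.sample_training_frames`.
    Round 1 learns from the morphological harvest; each later round adds
    pixels classified with confidence >= ``conf_pos_gate`` (positives) or
    <= ``conf_neg_gate`` (foreground negatives) to the pools, resamples
    patches, and retrains. Stops early when the pools grow by less than 1%.

    Returns the final classifier and the per-round (positives, negatives)
    pool sizes.
    """
    cfg = config or TrainingConfig()
    rng = rng or np.random.default_rng(cfg.seed)
    frame_ids = sample_training_frames(stack, cfg.frame_stride)
    if len(masks) != len(frame_ids):
        raise ValueError("need one silhouette per sampled training frame")

    pool = LabeledPixelPool()
    for m in masks:
        if not m.mask.any():
            continue
        pool.extend(harvest_confident_pixels(m, stack.frames[m.frame_index], rng=rng))
    pool_sizes = [pool.sizes()]
    seen_pos = set(pool.positives)
    seen_neg = set(pool.negatives)

    clf: BoostedClassifier | None = None
    for rnd in range(rounds):
        if rnd > 0:
            before = sum(pool.sizes())
            for m in masks:
                if not m.mask.any():
                    continue
                conf = predict_confidence(clf, stack.frames[m.frame_index], m)
                ys, xs = np.nonzero(m.mask)
                c = conf.values[ys, xs]
                for y, x in zip(ys[c >= cfg.conf_pos_gate], xs[c >= cfg.conf_pos_gate]):
                    key = (m.frame_index, int(x), int(y))
                    if key not in seen_pos:
                        seen_pos.add(key)
                        pool.positives.append(key)
                for y, x in zip(ys[c <= cfg.conf_neg_gate], xs[c <= cfg.conf_neg_gate]):
                    key = (m.frame_index, int(x), int(y))
                    if key not in seen_neg:
                        seen_neg.add(key)
                        pool.negatives.append(key)
            pool_sizes.append(pool.sizes())
            grown = sum(pool.sizes()) - before
            if before > 0 and grown < 0.01 * before:
                logger.info("self-training pool growth < 1%%; stopping early")
                break
        train = extract_patches(
            pool,
            stack,
            n_pos=cfg.n_pos,
            n_neg=cfg.n_neg,
            patch_size=cfg.patch_size,
            rng=rng,
            round_index=rnd,
        )
        clf = fit_classifier(
            train,
            n_rounds=cfg.n_rounds,
            gamma=cfg.gamma,
            t1_size=cfg.t1_size,
            n_candidates=cfg.n_candidates,
            max_depth=cfg.max_depth,
            min_node_size=cfg.min_node_size,
            max_fit_samples=cfg.max_fit_samples,
            rng=rng,
        )
    clf.config["pool_sizes"] = pool_sizes
    return clf, pool_sizes


# ---------------------------------------------------------------------------
# Serialization: one portable .npz holding arrays + a JSON topology record
# ---------------------------------------------------------------------------


def save_classifier(clf: BoostedClassifier, path: str | Path) -> Path:
    arrays: dict[str, np.ndarray] = {}
    trees = []

    def encode(node: _Node, tree_i: int, counter: list[int]) -> dict:
        if node.is_leaf:
            return {"leaf": True, "value": node.value}
        nid = counter[0]
        counter[0] += 1
        arrays[f"k_{tree_i}_{nid}"] = node.kernel.weights
        return {
            "leaf": False,
            "id": nid,
            "anchor": list(node.kernel.anchor),
            "lambda": node.kernel.lambda_used,
            "tau": node.tau,
            "left": encode(node.left, tree_i, counter),
            "right": encode(node.right, tree_i, counter),
        }

    for i, h in enumerate(clf.learners):
        trees.append(encode(h.root, i, [0]))
    meta = {
        "gamma": clf.gamma,
        "n_rounds": clf.n_rounds,
        "training_log": clf.training_log,
        "config": {k: v for k, v in clf.config.items() if k != "pool_sizes"},
        "trees": trees,
    }
    path = Path(path)
    np.savez_compressed(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def load_classifier(path: str | Path) -> BoostedClassifier:
    data = np.load(path)
    meta = json.loads(bytes(data["meta"]).decode())

    def decode(rec: dict, tree_i: int) -> _Node:
        if rec["leaf"]:
            return _Node(value=rec["value"])
        kern = ConvKernel(
            weights=data[f"k_{tree_i}_{rec['id']}"],
            anchor=tuple(rec["anchor"]),
            lambda_used=rec["lambda"],
        )
        return _Node(
            kernel=kern,
            tau=rec["tau"],
            left=decode(rec["left"], tree_i),
            right=decode(rec["right"], tree_i),
        )

    learners = [WeakLearner(root=decode(t, i)) for i, t in enumerate(meta["trees"])]
    return BoostedClassifier(
        learners=learners,
        gamma=meta["gamma"],
        n_rounds=meta["n_rounds"],
        training_log=meta["training_log"],
        config=meta["config"],
    )
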