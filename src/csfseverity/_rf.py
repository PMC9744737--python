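"""Compact regression-forest engine for small-n, very-wide feature matrices.

The backward-elimination pipeline fits hundreds of forests over feature
matrices with ~100 samples and up to hundreds of thousands of ratio
features.  This engine is optimized for that regime: features are presorted
once per candidate set and shared across all forests of a step; in-bag
samples are partitioned in place so node statistics ride on the stack; the
split search scans the presorted order for large nodes and insertion-sorts
the members directly for small ones.  Whole forests are grown inside a
single compiled call, so the per-tree overhead is negligible.

It implements the standard CART regression forest: bootstrap resampling,
variance-reduction (node impurity) splits over ``mtry`` randomly drawn
candidate features, out-of-bag predictions, and
per-feature importance as the total impurity decrease per tree (divided by
the bootstrap weight total, averaged over trees) — the quantity other
forest implementations report as impurity importance.

Split thresholds are placed at the largest left-child value (rule
``x <= a`` for an observed value ``a``) rather than at midpoints, so tree
structure AND routing depend only on the order of feature values: applying
any strictly monotone transform to a feature (e.g. exponentiating a
log-ratio) leaves every prediction bit-identical under the same seed.

Determinism: every forest is grown from an explicit integer seed; split
ties resolve to the first candidate encountered in the (seeded) feature
draw, and the branch taken for the split search never consumes randomness.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["RegressionForest", "fit_forest", "presort"]

_LEAF = -1
_SMALL = 24  # node size below which members are insertion-sorted directly


@njit(cache=True)
def _grow_forest(Xt, order, xsorted, y, n_trees, mtry, min_leaf, seed,
                 feature, threshold, left, right, value,
                 oob_sum, oob_cnt, importance):
    p, n = Xt.shape
    max_nodes = feature.shape[1]
    np.random.seed(seed)
    perm = np.arange(p)
    w = np.empty(n, np.int64)
    wy = np.empty(n)
    wy2 = np.empty(n)
    in_node = np.zeros(n, np.bool_)
    samples = np.empty(n, np.int64)
    scratch = np.empty(n, np.int64)
    buf_x = np.empty(_SMALL, np.float64)
    buf_s = np.empty(_SMALL, np.int64)
    # stack entries: start, end, node_id (ints) + sw, swy, swy2 (floats)
    st_i = np.empty((max_nodes, 3), np.int64)
    st_f = np.empty((max_nodes, 3), np.float64)

    for t in range(n_trees):
        # bootstrap
        w[:] = 0
        for _ in range(n):
            w[np.random.randint(0, n)] += 1
        m_root = 0
        sw0 = 0.0
        swy0 = 0.0
        swy20 = 0.0
        for s in range(n):
            if w[s] > 0:
                samples[m_root] = s
                m_root += 1
                ws = w[s]
                wy[s] = ws * y[s]
                wy2[s] = wy[s] * y[s]
                sw0 += ws
                swy0 += wy[s]
                swy20 += wy2[s]

        n_nodes = 1
        st_i[0, 0] = 0
        st_i[0, 1] = m_root
        st_i[0, 2] = 0
        st_f[0, 0] = sw0
        st_f[0, 1] = swy0
        st_f[0, 2] = swy20
        top = 1
        while top > 0:
            top -= 1
            start = st_i[top, 0]
            end = st_i[top, 1]
            node = st_i[top, 2]
            sw = st_f[top, 0]
            swy = st_f[top, 1]
            swy2 = st_f[top, 2]
            m = end - start
            node_val = swy / sw
            sse_parent = swy2 - swy * swy / sw
            if sw < 2 * min_leaf or sse_parent <= 1e-12 or n_nodes + 2 > max_nodes:
                feature[t, node] = _LEAF
                value[t, node] = node_val
                continue

            best_gain = 0.0
            best_f = -1
            best_thr = 0.0
            small = m <= _SMALL
            if not small:
                for i in range(start, end):
                    in_node[samples[i]] = True
            for j in range(mtry):
                r = j + np.random.randint(0, p - j)
                tmp = perm[j]
                perm[j] = perm[r]
                perm[r] = tmp
                f = perm[j]
                csw = 0.0
                cswy = 0.0
                cswy2 = 0.0
                if small:
                    # insertion sort the members by feature value
                    row = Xt[f]
                    for i in range(m):
                        s = samples[start + i]
                        xv = row[s]
                        k = i - 1
                        while k >= 0 and buf_x[k] > xv:
                            buf_x[k + 1] = buf_x[k]
                            buf_s[k + 1] = buf_s[k]
                            k -= 1
                        buf_x[k + 1] = xv
                        buf_s[k + 1] = s
                    prev_x = buf_x[0]
                    for i in range(m):
                        xv = buf_x[i]
                        if xv > prev_x and csw >= min_leaf and sw - csw >= min_leaf:
                            lsse = cswy2 - cswy * cswy / csw
                            rsw = sw - csw
                            rswy = swy - cswy
                            rsse = (swy2 - cswy2) - rswy * rswy / rsw
                            gain = sse_parent - lsse - rsse
                            if gain > best_gain:
                                best_gain = gain
                                best_f = f
                                best_thr = prev_x
                        s = buf_s[i]
                        csw += w[s]
                        cswy += wy[s]
                        cswy2 += wy2[s]
                        prev_x = xv
                else:
                    ord_f = order[f]
                    xs_f = xsorted[f]
                    prev_x = 0.0
                    seen = 0
                    for k in range(n):
                        s = ord_f[k]
                        if not in_node[s]:
                            continue
                        xv = xs_f[k]
                        if seen > 0 and xv > prev_x and csw >= min_leaf and sw - csw >= min_leaf:
                            lsse = cswy2 - cswy * cswy / csw
                            rsw = sw - csw
                            rswy = swy - cswy
                            rsse = (swy2 - cswy2) - rswy * rswy / rsw
                            gain = sse_parent - lsse - rsse
                            if gain > best_gain:
                                best_gain = gain
                                best_f = f
                                best_thr = prev_x
                        csw += w[s]
                        cswy += wy[s]
                        cswy2 += wy2[s]
                        prev_x = xv
                        seen += 1
            if not small:
                for i in range(start, end):
                    in_node[samples[i]] = False

            if best_f < 0:
                feature[t, node] = _LEAF
                value[t, node] = node_val
                continue

            lid = n_nodes
            rid = n_nodes + 1
            n_nodes += 2
            feature[t, node] = best_f
            threshold[t, node] = best_thr
            left[t, node] = lid
            right[t, node] = rid
            importance[best_f] += best_gain / (n * n_trees)

            # stable in-place partition; accumulate left-child stats
            row = Xt[best_f]
            nl = 0
            nr = 0
            lsw = 0.0
            lswy = 0.0
            lswy2 = 0.0
            for i in range(start, end):
                s = samples[i]
                if row[s] <= best_thr:
                    samples[start + nl] = s
                    nl += 1
                    lsw += w[s]
                    lswy += wy[s]
                    lswy2 += wy2[s]
                else:
                    scratch[nr] = s
                    nr += 1
            for i in range(nr):
                samples[start + nl + i] = scratch[i]

            st_i[top, 0] = start
            st_i[top, 1] = start + nl
            st_i[top, 2] = lid
            st_f[top, 0] = lsw
            st_f[top, 1] = lswy
            st_f[top, 2] = lswy2
            st_i[top + 1, 0] = start + nl
            st_i[top + 1, 1] = end
            st_i[top + 1, 2] = rid
            st_f[top + 1, 0] = sw - lsw
            st_f[top + 1, 1] = swy - lswy
            st_f[top + 1, 2] = swy2 - lswy2
            top += 2

        # out-of-bag predictions
        for s in range(n):
            if w[s] == 0:
                node = 0
                while feature[t, node] != _LEAF:
                    if Xt[feature[t, node], s] <= threshold[t, node]:
                        node = left[t, node]
                    else:
                        node = right[t, node]
                oob_sum[s] += value[t, node]
                oob_cnt[s] += 1


@njit(cache=True)
def _predict(Xt, feature, threshold, left, right, value):
    n_trees = feature.shape[0]
    m = Xt.shape[1]
    out = np.zeros(m)
    for t in range(n_trees):
        for s in range(m):
            node = 0
            while feature[t, node] != _LEAF:
                if Xt[feature[t, node], s] <= threshold[t, node]:
                    node = left[t, node]
                else:
                    node = right[t, node]
            out[s] += value[t, node]
    return out / n_trees


def presort(X: np.ndarray):
    """Presorted order and sorted values for ``X`` (samples x features).

    Returns ``(Xt, order, xsorted)`` shared by every forest fitted on X.
    """
    Xt = np.ascontiguousarray(np.asarray(X, dtype=np.float64).T)
    order = np.ascontiguousarray(np.argsort(Xt, axis=1, kind="stable").astype(np.int64))
    xsorted = np.ascontiguousarray(np.take_along_axis(Xt, order, axis=1))
    return Xt, order, xsorted


class RegressionForest:
    """A fitted forest: frozen trees plus OOB and importance summaries."""

    def __init__(self, feature, threshold, left, right, value,
                 oob_sum, oob_cnt, importance, y, seed, mtry, min_leaf):
        self._arrays = (feature, threshold, left, right, value)
        self._oob_sum = oob_sum
        self._oob_cnt = oob_cnt
        self.importance = importance
        self._y = y
        self.seed = seed
        self.mtry = mtry
        self.min_leaf = min_leaf
        self.n_trees = feature.shape[0]

    @property
    def n_features(self) -> int:
        return self.importance.shape[0]

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Forest-mean prediction for rows of ``X`` (samples x features)."""
        Xt = np.ascontiguousarray(np.asarray(X, dtype=np.float64).T)
        if Xt.shape[0] != self.n_features:
            raise ValueError(f"expected {self.n_features} features, got {Xt.shape[0]}")
        return _predict(Xt, *self._arrays)

    def oob_prediction(self) -> np.ndarray:
        """Per-training-sample prediction from trees whose bootstrap excluded it."""
        with np.errstate(invalid="ignore"):
            return np.where(self._oob_cnt > 0, self._oob_sum / self._oob_cnt, np.nan)

    def oob_mse(self) -> float:
        pred = self.oob_prediction()
        ok = ~np.isnan(pred)
        return float(np.mean((pred[ok] - self._y[ok]) ** 2))


def fit_forest(X: np.ndarray, y: np.ndarray, n_trees: int, mtry: int,
               seed: int, min_leaf: int = 5,
               presorted=None) -> RegressionForest:
    """Fit a regression forest.

    ``presorted`` is the :func:`presort` output for ``X``; pass it when
    fitting several forests on the same matrix to avoid re-sorting.
    """
    y = np.ascontiguousarray(np.asarray(y, dtype=np.float64))
    if presorted is None:
        presorted = presort(X)
    Xt, order, xsorted = presorted
    p, n = Xt.shape
    if not 1 <= mtry <= p:
        raise ValueError(f"mtry must be in [1, {p}], got {mtry}")
    max_nodes = 2 * n + 1
    feature = np.full((n_trees, max_nodes), _LEAF, np.int64)
    threshold = np.zeros((n_trees, max_nodes))
    left = np.zeros((n_trees, max_nodes), np.int64)
    right = np.zeros((n_trees, max_nodes), np.int64)
    value = np.zeros((n_trees, max_nodes))
    oob_sum = np.zeros(n)
    oob_cnt = np.zeros(n, np.int64)
    importance = np.zeros(p)
    _grow_forest(Xt, order, xsorted, y, n_trees, mtry, min_leaf, seed,
                 feature, threshold, left, right, value,
                 oob_sum, oob_cnt, importance)
    return RegressionForest(feature, threshold, left, right, value,
                            oob_sum, oob_cnt, importance, y, seed, mtry, min_leaf)
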