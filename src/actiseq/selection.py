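"""Sequential feature selection under a k-NN class-separability criterion.

The criterion is the ratio of the mean distance to the nearest *k* neighbours
of a *different* class over the mean distance to the nearest *k* neighbours of
the *same* class (self excluded), averaged over all training instances, after
per-feature standardisation. Larger is better. Two search strategies are
provided: plain sequential forward selection (SFS) and the Pudil floating
search (SFFS), which after each inclusion conditionally removes features
while removal strictly improves the best criterion known at the reduced size.

Both searches share an incremental evaluator that caches per-feature squared
pairwise-distance matrices (standardisation is per-feature, so the subset
criterion is an exact sum over cached per-feature terms); results are
identical to calling :func:`knn_separability` on each candidate subset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class LabelledFeatureSet:
    """Instances-by-features matrix with one activity label per instance."""

    matrix: np.ndarray
    labels: np.ndarray
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        self.labels = np.asarray(self.labels)
        if self.matrix.shape[0] != self.labels.shape[0]:
            raise ValueError("number of labels must equal number of instances")
        if np.isnan(self.matrix).any():
            raise ValueError("feature matrix contains missing values")
        if not self.feature_names:
            self.feature_names = [f"f{i}" for i in range(self.matrix.shape[1])]

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def d(self) -> int:
        return self.matrix.shape[1]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label_column: str = "label") -> "LabelledFeatureSet":
        cols = [c for c in df.columns if c not in (label_column, "start_index")]
        return cls(df[cols].to_numpy(), df[label_column].to_numpy(), cols)

    def select(self, indices: list[int]) -> "LabelledFeatureSet":
        return LabelledFeatureSet(
            self.matrix[:, indices], self.labels, [self.feature_names[i] for i in indices]
        )


@dataclass
class SelectionResult:
    selected_indices: list[int]
    criterion_by_size: list[float]
    chosen_size: int
    subset_by_size: dict[int, list[int]] = field(default_factory=dict)
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.selected_indices)) != len(self.selected_indices):
            raise ValueError("selected indices must be unique")
        if self.chosen_size != len(self.selected_indices):
            raise ValueError("chosen_size must equal the number of selected indices")


def _standardise(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)  # constant features contribute nothing
    return (x - mu) / sd


class _CriterionEngine:
    """Incremental evaluator over cached per-feature squared distances."""

    def __init__(self, data: LabelledFeatureSet, k: int):
        labels = data.labels
        classes, counts = np.unique(labels, return_counts=True)
        if classes.size < 2:
            raise ValueError("criterion needs at least two classes")
        if np.any(counts <= k):
            small = classes[counts <= k]
            raise ValueError(
                f"every class needs more than k={k} instances; too small: {list(small)}"
            )
        self.k = k
        x = _standardise(data.matrix)
        n = x.shape[0]
        # per-feature squared pairwise differences, (d, n, n)
        self.per_feature = np.square(x.T[:, :, None] - x.T[:, None, :])
        same = labels[:, None] == labels[None, :]
        eye = np.eye(n, dtype=bool)
        self.intra_mask = same & ~eye
        self.inter_mask = ~same
        self.n = n

    def criterion(self, base_sq: np.ndarray) -> float:
        dist = np.sqrt(base_sq)
        intra = np.where(self.intra_mask, dist, np.inf)
        inter = np.where(self.inter_mask, dist, np.inf)
        if self.k == 1:
            intra_k = intra.min(axis=1)
            inter_k = inter.min(axis=1)
        else:
            intra_k = np.partition(intra, self.k - 1, axis=1)[:, : self.k].mean(axis=1)
            inter_k = np.partition(inter, self.k - 1, axis=1)[:, : self.k].mean(axis=1)
        denom = intra_k.mean()
        if denom == 0:
            return np.inf
        return float(inter_k.mean() / denom)


def knn_separability(data: LabelledFeatureSet, k: int = 1) -> float:
    """Inter-class over intra-class mean k-NN distance ratio (Euclidean)."""
    engine = _CriterionEngine(data, k)
    return engine.criterion(engine.per_feature.sum(axis=0))


def _forward_step(engine: _CriterionEngine, base: np.ndarray, current: list[int], d: int):
    best_idx, best_val = -1, -np.inf
    in_set = set(current)
    for idx in range(d):
        if idx in in_set:
            continue
        val = engine.criterion(base + engine.per_feature[idx])
        if val > best_val:  # strict: ties keep the lowest index
            best_idx, best_val = idx, val
    return best_idx, best_val


def sfs_select(data: LabelledFeatureSet, max_size: int, k: int = 1) -> SelectionResult:
    """Greedy sequential forward selection."""
    if not 1 <= max_size <= data.d:
        raise ValueError("max_size must lie in [1, d]")
    engine = _CriterionEngine(data, k)
    base = np.zeros((data.n, data.n))
    current: list[int] = []
    crit: list[float] = []
    subsets: dict[int, list[int]] = {}
    for _ in range(max_size):
        idx, val = _forward_step(engine, base, current, data.d)
        current.append(idx)
        base = base + engine.per_feature[idx]
        crit.append(val)
        subsets[len(current)] = sorted(current)
    chosen = int(np.argmax(crit)) + 1
    return SelectionResult(
        selected_indices=subsets[chosen],
        criterion_by_size=crit,
        chosen_size=chosen,
        subset_by_size=subsets,
        feature_names=[data.feature_names[i] for i in subsets[chosen]],
    )


def sffs_select(data: LabelledFeatureSet, max_size: int, k: int = 1) -> SelectionResult:
    """Sequential floating forward selection (Pudil).

    After each forward inclusion the search conditionally excludes features
    while exclusion strictly improves the best criterion known at the reduced
    size; the best subset found at every size is recorded and the returned
    subset is the argmax over sizes (smallest size on ties). The per-size
    record is seeded with the plain greedy path, so it dominates SFS at every
    size by construction.
    """
    if not 1 <= max_size <= data.d:
        raise ValueError("max_size must lie in [1, d]")
    greedy = sfs_select(data, max_size, k)
    best_val: dict[int, float] = {
        s: greedy.criterion_by_size[s - 1] for s in range(1, max_size + 1)
    }
    best_set: dict[int, list[int]] = {s: greedy.subset_by_size[s] for s in range(1, max_size + 1)}
    engine = _CriterionEngine(data, k)
    base = np.zeros((data.n, data.n))
    current: list[int] = []
    while len(current) < max_size:
        idx, val = _forward_step(engine, base, current, data.d)
        current = sorted(current + [idx])
        base = base + engine.per_feature[idx]
        s = len(current)
        if val > best_val.get(s, -np.inf):
            best_val[s], best_set[s] = val, list(current)
        # conditional exclusion while it strictly beats the record at the
        # reduced size
        while len(current) > 2:
            cand_drop, cand_val = None, -np.inf
            for drop in current:
                v = engine.criterion(base - engine.per_feature[drop])
                if v > cand_val:
                    cand_drop, cand_val = drop, v
            s_red = len(current) - 1
            if cand_val > best_val.get(s_red, -np.inf):
                current = [i for i in current if i != cand_drop]
                base = base - engine.per_feature[cand_drop]
                best_val[s_red], best_set[s_red] = cand_val, list(current)
            else:
                break
    crit = [best_val[s] for s in range(1, max_size + 1)]
    chosen = max(range(1, max_size + 1), key=lambda s: (best_val[s], -s))
    return SelectionResult(
        selected_indices=best_set[chosen],
        criterion_by_size=crit,
        chosen_size=chosen,
        subset_by_size=best_set,
        feature_names=[data.feature_names[i] for i in best_set[chosen]],
    )
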