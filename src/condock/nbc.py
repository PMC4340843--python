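"""Naive Bayes contact classifier with equal-width discretization.

The classifier scores each candidate residue pair x by

    S(x) = [log p(C1) + sum_i log p(x_i | C1)]
         - [log p(C0) + sum_i log p(x_i | C0)]

where C1 is the contact class and C0 the non-contact class, assuming
conditional independence of features given the class.  Class-conditional
densities are histograms over equal-width bins (EWD); the bin count per
class follows the Rice rule, twice the cube root of the number of training
values of that class, so the sparse contact class gets coarser bins than
the abundant non-contact class.  Laplace +1 smoothing keeps every log
probability finite; bin ranges are per class, with out-of-range values
clamped into the boundary bins.

Ranking quality is measured by a modified R-precision: the precision among
the top R ranked pairs (R = number of true contacts) when at least one true
contact ranks within R, and otherwise 1 - highestTrue/R, which goes
negative in proportion to how far down the first true contact sits.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .structure import ResidueId

PairId = tuple[ResidueId, ResidueId]


def rice_bin_count(n_values: int) -> int:
    """Rice rule: round(2 * n^(1/3)), half away from zero, at least 1."""
    if n_values < 1:
        raise ValueError("n_values must be >= 1")
    raw = 2.0 * n_values ** (1.0 / 3.0)
    return max(1, int(math.floor(raw + 0.5)))


def ewd_edges(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-width bin edges spanning [min, max] of ``values``.

    A degenerate range (min == max) is expanded by a small epsilon so a
    single bin still contains every value.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("values must be non-empty")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    lo, hi = float(values.min()), float(values.max())
    if lo == hi:
        eps = 1e-9 * max(1.0, abs(lo))
        lo, hi = lo - eps, hi + eps
    return np.linspace(lo, hi, n_bins + 1)


def _bin_index(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Bin of each value, clamping out-of-range values to boundary bins."""
    idx = np.searchsorted(edges, values, side="right") - 1
    return np.clip(idx, 0, len(edges) - 2)


@dataclass
class NBCModel:
    """Priors plus per-feature, per-class equal-width histogram tables."""

    feature_names: list[str]
    log_priors: np.ndarray            # (2,)
    edges: list[list[np.ndarray]]     # [class][feature] -> (n_bins+1,)
    log_probs: list[list[np.ndarray]] # [class][feature] -> (n_bins,)
    bin_counts: tuple[int, int]
    class_counts: tuple[int, int]
    config: dict = field(default_factory=dict)

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def to_json(self) -> str:
        payload = {
            "feature_names": self.feature_names,
            "log_priors": self.log_priors.tolist(),
            "edges": [[e.tolist() for e in cls] for cls in self.edges],
            "log_probs": [[p.tolist() for p in cls] for cls in self.log_probs],
            "bin_counts": list(self.bin_counts),
            "class_counts": list(self.class_counts),
            "config": self.config,
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "NBCModel":
        d = json.loads(text)
        return cls(
            feature_names=d["feature_names"],
            log_priors=np.array(d["log_priors"]),
            edges=[[np.array(e) for e in c] for c in d["edges"]],
            log_probs=[[np.array(p) for p in c] for c in d["log_probs"]],
            bin_counts=tuple(d["bin_counts"]),
            class_counts=tuple(d["class_counts"]),
            config=d.get("config", {}),
        )


def train(
    features: np.ndarray,
    labels: np.ndarray,
    feature_names: list[str] | None = None,
) -> NBCModel:
    """Fit the EWD Naive Bayes model.

    Per class k the bin count is ``rice_bin_count(N_k)``; each feature's
    histogram is taken over that class's values with Laplace smoothing
    ``(count + 1) / (N_k + n_k)``.  Priors are the pooled class frequencies.
    Both classes must be present.
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels).astype(int)
    if x.ndim != 2:
        raise ValueError("features must be a 2-D matrix")
    n0, n1 = int((y == 0).sum()), int((y == 1).sum())
    if n0 == 0 or n1 == 0:
        raise ValueError("training data must contain both classes")
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(x.shape[1])]
    bins = (rice_bin_count(n0), rice_bin_count(n1))
    log_priors = np.log(np.array([n0, n1]) / (n0 + n1))
    edges: list[list[np.ndarray]] = [[], []]
    log_probs: list[list[np.ndarray]] = [[], []]
    for k, n_k in ((0, n0), (1, n1)):
        xk = x[y == k]
        for i in range(x.shape[1]):
            e = ewd_edges(xk[:, i], bins[k])
            counts = np.bincount(_bin_index(xk[:, i], e), minlength=bins[k])
            probs = (counts + 1.0) / (n_k + bins[k])
            edges[k].append(e)
            log_probs[k].append(np.log(probs))
    return NBCModel(
        feature_names=list(feature_names),
        log_priors=log_priors,
        edges=edges,
        log_probs=log_probs,
        bin_counts=bins,
        class_counts=(n0, n1),
    )


def score(model: NBCModel, x: np.ndarray) -> float:
    """Log-posterior-ratio score S(x) of a single feature vector."""
    return float(score_matrix(model, np.asarray(x, dtype=float)[None, :])[0])


def score_matrix(model: NBCModel, x: np.ndarray) -> np.ndarray:
    """S(x) for every row of ``x`` (values clamped into boundary bins)."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[1] != model.n_features:
        raise ValueError(
            f"feature matrix has {x.shape[-1] if x.ndim else 0} columns, "
            f"model expects {model.n_features}"
        )
    total = np.zeros((2, x.shape[0]))
    for k in (0, 1):
        total[k] += model.log_priors[k]
        for i in range(model.n_features):
            idx = _bin_index(x[:, i], model.edges[k][i])
            total[k] += model.log_probs[k][i][idx]
    return total[1] - total[0]


@dataclass
class Ranking:
    """Scored candidate pairs in non-increasing score order.

    Ties are broken deterministically by the pair identifier
    (chain_a, resnum_a, icode_a, chain_b, resnum_b, icode_b).
    """

    entries: list[tuple[PairId, float, bool | None]]
    complex_id: str = ""

    @classmethod
    def from_scores(
        cls,
        pair_ids: list[PairId],
        scores: np.ndarray,
        labels: np.ndarray | None = None,
        complex_id: str = "",
    ) -> "Ranking":
        items = [
            (
                pid,
                float(s),
                bool(labels[i]) if labels is not None else None,
            )
            for i, (pid, s) in enumerate(zip(pair_ids, scores))
        ]
        items.sort(key=lambda t: (-t[1], t[0]))
        return cls(entries=items, complex_id=complex_id)

    @property
    def n_true(self) -> int:
        return sum(1 for _, _, t in self.entries if t)

    def top(self, k: int) -> list[PairId]:
        return [pid for pid, _, _ in self.entries[:k]]


def r_precision(ranking: Ranking) -> float:
    """Modified R-precision of a labeled ranking.

    With R true contacts in total: if the best-ranked true contact sits at
    position <= R (1-based), the value is the fraction of true contacts
    among the top R; otherwise it is 1 - highestTrue/R, which is negative
    and measures how far the classifier missed.
    """
    flags = [t for _, _, t in ranking.entries]
    if any(t is None for t in flags):
        raise ValueError("ranking has unlabeled entries")
    r = sum(flags)
    if r == 0:
        raise ValueError("r_precision undefined: ranking has no true contacts")
    highest_true = next(i + 1 for i, t in enumerate(flags) if t)
    if highest_true <= r:
        return sum(flags[:r]) / r
    return 1.0 - highest_true / r


ComplexTable = tuple[np.ndarray, np.ndarray, list]


def cross_validate(
    complex_tables: dict[str, ComplexTable],
    n_folds: int = 5,
    feature_subset: list[int] | tuple[int, ...] | None = None,
    seed: int = 75,
) -> float:
    """Complex-level k-fold cross-validation, macro-averaged R-precision.

    ``complex_tables`` maps complex ids to (features, labels, pair_ids).
    Complexes (never pairs) are partitioned into folds by a seeded shuffle;
    each complex is scored by a model trained on the remaining folds and
    contributes its modified R-precision to the mean.  Complexes without a
    single true contact are skipped (their R-precision is undefined).
    """
    ids = sorted(complex_tables)
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if len(ids) < n_folds:
        raise ValueError(
            f"{len(ids)} complexes cannot fill {n_folds} folds"
        )
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(len(ids)))
    folds: list[list[str]] = [[] for _ in range(n_folds)]
    for pos, idx in enumerate(order):
        folds[pos % n_folds].append(ids[idx])

    subset = list(feature_subset) if feature_subset is not None else None
    values = []
    for fold in folds:
        held_out = set(fold)
        train_x, train_y = [], []
        for cid in ids:
            if cid in held_out:
                continue
            x, y, _ = complex_tables[cid]
            train_x.append(x if subset is None else x[:, subset])
            train_y.append(y)
        model = train(np.vstack(train_x), np.concatenate(train_y))
        for cid in fold:
            x, y, pair_ids = complex_tables[cid]
            if int(np.sum(y)) == 0:
                continue
            s = score_matrix(model, x if subset is None else x[:, subset])
            ranking = Ranking.from_scores(pair_ids, s, y, complex_id=cid)
            values.append(r_precision(ranking))
    if not values:
        raise ValueError("no complex with true contacts to evaluate")
    return float(np.mean(values))
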