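"""Forward sequential feature search retaining the best N subsets per size.

Classic greedy forward selection keeps a single best subset per size; here a
beam of N subsets survives each round.  Every retained subset is extended by
every unused feature, duplicates are removed (subsets are order-insensitive),
all candidates are scored by cross-validated mean R-precision, and the top N
move on.  With beam width 1 this reduces exactly to greedy forward
selection; with beam width >= C(pool, size) it is exhaustive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .nbc import ComplexTable, cross_validate

Subset = tuple[int, ...]


@dataclass
class SearchTrajectory:
    """Retained subsets and scores per subset size, plus the overall best."""

    retained: dict[int, list[tuple[Subset, float]]] = field(default_factory=dict)

    @property
    def best(self) -> tuple[Subset, float]:
        """Highest-scoring subset over all sizes.

        Ties break toward the smaller size, then lexicographic subset order.
        """
        candidates = []
        for size in sorted(self.retained):
            for subset, score in self.retained[size]:
                candidates.append((-score, size, subset))
        if not candidates:
            raise ValueError("empty trajectory")
        neg_score, _, subset = min(candidates)
        return subset, -neg_score

    def best_at_size(self, size: int) -> tuple[Subset, float]:
        return self.retained[size][0]


def beam_forward_search(
    complex_tables: dict[str, ComplexTable],
    pool: list[int] | None = None,
    beam_width: int = 10,
    max_size: int = 45,
    n_folds: int = 5,
    seed: int = 75,
) -> SearchTrajectory:
    """Beam forward search over feature subsets.

    ``pool`` defaults to all feature columns of the tables.  Size-1
    candidates are all single features; each iteration extends every
    retained subset by every unused pool feature.  Subsets are canonical
    sorted index tuples; score ties are broken by lexicographic subset
    order so the search is fully reproducible.  The search stops at
    ``max_size`` features (or earlier if the pool is exhausted).
    """
    if beam_width < 1:
        raise ValueError("beam_width must be >= 1")
    if pool is None:
        first = next(iter(complex_tables.values()))
        pool = list(range(first[0].shape[1]))
    if not pool:
        raise ValueError("empty feature pool")
    max_size = min(max_size, len(pool))

    cache: dict[Subset, float] = {}

    def evaluate(subset: Subset) -> float:
        if subset not in cache:
            cache[subset] = cross_validate(
                complex_tables, n_folds=n_folds,
                feature_subset=list(subset), seed=seed,
            )
        return cache[subset]

    trajectory = SearchTrajectory()
    frontier: list[Subset] = [()]
    for size in range(1, max_size + 1):
        candidates: set[Subset] = set()
        for subset in frontier:
            used = set(subset)
            for f in pool:
                if f not in used:
                    candidates.add(tuple(sorted(subset + (f,))))
        if not candidates:
            break
        scored = sorted(
            ((evaluate(s), s) for s in candidates),
            key=lambda t: (-t[0], t[1]),
        )
        kept = [(s, sc) for sc, s in scored[:beam_width]]
        trajectory.retained[size] = kept
        frontier = [s for s, _ in kept]
    return trajectory
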