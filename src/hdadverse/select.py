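"""Greedy forward feature-combination search and key-feature ranking.

The search grows feature combinations level by level.  Level 1 scores every
single feature with a cross-validated RUSBoost classifier and keeps the top
feature.  At each later level every retained combination is extended by each
unused feature, and extensions are kept only when they score strictly higher
than the best retained score of the previous level; retained lists are
truncated to a beam cap so the keep-all-improving rule cannot explode
combinatorially.  The score of a combination is the sum of held-out
sensitivity and specificity (range 0-2, chance ~1); an alternative
convention (TP and TN as fractions of all examples, range 0-1) is available
behind a switch.  Key features are the features ranked by how often they
appear in the deepest level's retained combinations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .evaluate import confusion_metrics
from .models import RUSBoostClassifier, RUSBoostConfig

__all__ = [
    "ScorerConfig",
    "ComboScore",
    "SelectionTrace",
    "score_combo",
    "greedy_forward_search",
    "key_features",
]


@dataclass(frozen=True, slots=True)
class ScorerConfig:
    """Configuration of the RUSBoost combination scorer."""

    n_rounds: int = 20
    max_depth: int = 2
    k: int = 4
    convention: str = "rate"  # "rate": sens+spec in [0,2]; "count": (TP+TN)/n

    def __post_init__(self) -> None:
        if self.convention not in ("rate", "count"):
            raise ValueError("convention must be 'rate' or 'count'")


@dataclass(frozen=True, slots=True)
class ComboScore:
    combo: tuple[int, ...]  # sorted 0-based column indices
    score: float
    cv_detail: tuple[dict, ...]
    seed: int


@dataclass(slots=True)
class SelectionTrace:
    levels: list[list[ComboScore]] = field(default_factory=list)
    scorer_config: ScorerConfig | None = None
    seed: int = 0

    @property
    def final_size(self) -> int:
        return len(self.levels)

    @property
    def best(self) -> ComboScore:
        return max(self.levels[-1], key=lambda c: c.score)


def _stratified_folds(y: np.ndarray, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    folds: list[list[int]] = [[] for _ in range(k)]
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        idx = idx[rng.permutation(idx.size)]
        for j, i in enumerate(idx):
            folds[j % k].append(int(i))
    return [np.sort(np.array(f, dtype=int)) for f in folds]


def score_combo(
    X: np.ndarray,
    y: np.ndarray,
    combo: Sequence[int],
    scorer_config: ScorerConfig | None = None,
    seed: int = 0,
) -> ComboScore:
    """Cross-validated RUSBoost score of one feature combination.

    Confusion counts are pooled over held-out folds; the score is
    sensitivity + specificity (rate convention) or (TP+TN)/n.  Deterministic
    given (data, combo, config, seed).
    """
    cfg = scorer_config or ScorerConfig()
    combo = tuple(sorted(int(c) for c in combo))
    if not combo:
        raise ValueError("empty feature combination")
    X = np.asarray(X, dtype=float)[:, combo]
    y = np.asarray(y, dtype=int)

    folds = _stratified_folds(y, cfg.k, np.random.default_rng(seed))
    pooled = {"tp": 0, "tn": 0, "fp": 0, "fn": 0}
    detail = []
    for j, test_idx in enumerate(folds):
        train_mask = np.ones(y.size, dtype=bool)
        train_mask[test_idx] = False
        model = RUSBoostClassifier(
            RUSBoostConfig(n_rounds=cfg.n_rounds, max_depth=cfg.max_depth, seed=seed + j)
        )
        model.fit(X[train_mask], y[train_mask])
        cm = confusion_metrics(model.predict(X[test_idx]), y[test_idx])
        detail.append({"fold": j, **cm})
        for key in pooled:
            pooled[key] += cm[key]
    tp, tn, fp, fn = pooled["tp"], pooled["tn"], pooled["fp"], pooled["fn"]
    if cfg.convention == "rate":
        sens = tp / (tp + fn) if tp + fn else 0.0
        spec = tn / (tn + fp) if tn + fp else 0.0
        score = sens + spec
    else:
        score = (tp + tn) / max(tp + tn + fp + fn, 1)
    return ComboScore(combo=combo, score=float(score), cv_detail=tuple(detail), seed=seed)


def greedy_forward_search(
    X: np.ndarray,
    y: np.ndarray,
    max_size: int = 20,
    scorer_config: ScorerConfig | None = None,
    beam_cap: int | None = 50,
    seed: int = 0,
) -> SelectionTrace:
    """Level-wise greedy growth of improving feature combinations.

    Stops at ``max_size`` or when no extension beats the previous level's
    best retained score.  Within a level all combinations are scored with
    the same seed so comparisons are paired; ``beam_cap=None`` disables the
    cap (keep every improving combination).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n_features = X.shape[1]
    if max_size > n_features:
        raise ValueError("max_size exceeds the number of features")
    cfg = scorer_config or ScorerConfig()
    trace = SelectionTrace(scorer_config=cfg, seed=seed)

    def level_seed(level: int) -> int:
        return int(np.random.SeedSequence([seed, level]).generate_state(1)[0] % (2**31 - 1))

    # level 1: keep the single top feature
    s1 = level_seed(1)
    singles = [score_combo(X, y, (f,), cfg, s1) for f in range(n_features)]
    best1 = max(singles, key=lambda c: (c.score, tuple(-i for i in c.combo)))
    trace.levels.append([best1])

    while trace.final_size < max_size:
        level = trace.final_size + 1
        benchmark = max(c.score for c in trace.levels[-1])
        sl = level_seed(level)
        seen: set[tuple[int, ...]] = set()
        kept: list[ComboScore] = []
        for parent in trace.levels[-1]:
            for f in range(n_features):
                if f in parent.combo:
                    continue
                combo = tuple(sorted(parent.combo + (f,)))
                if combo in seen:
                    continue
                seen.add(combo)
                cs = score_combo(X, y, combo, cfg, sl)
                if cs.score > benchmark:
                    kept.append(cs)
        if not kept:
            break
        kept.sort(key=lambda c: (-c.score, c.combo))
        if beam_cap is not None:
            kept = kept[:beam_cap]
        trace.levels.append(kept)
    return trace


def key_features(trace: SelectionTrace, top_n: int = 21) -> list[int]:
    """Features ranked by frequency across the deepest retained combinations.

    Ties break by the best score of a retained combination containing the
    feature, then by lower feature index.  Returns 0-based column indices.
    """
    if not trace.levels:
        raise ValueError("empty selection trace")
    final = trace.levels[-1]
    counts: dict[int, int] = {}
    best_with: dict[int, float] = {}
    for cs in final:
        for f in cs.combo:
            counts[f] = counts.get(f, 0) + 1
            best_with[f] = max(best_with.get(f, -np.inf), cs.score)
    ranked = sorted(counts, key=lambda f: (-counts[f], -best_with[f], f))
    if len(ranked) < top_n:
        warnings.warn(
            f"only {len(ranked)} features appear in the final combinations "
            f"(requested {top_n})",
            stacklevel=2,
        )
    return ranked[:top_n]
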