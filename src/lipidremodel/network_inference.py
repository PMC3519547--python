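"""Remodeling correlation-network inference from pulse-chase time courses.

The reduced reaction network is inferred in a single pass over the data:

1. at each time point, species whose concentration significantly decreases
   toward the next time point are flagged as candidate remodeling *sources*
   (one-sided two-sample t-test on replicates);
2. for each source, candidate *targets* — observed species sharing exactly
   one acyl chain with the source — are scored by the negated Pearson
   correlation of the two mean concentration series over an evidence window,
   so that a source draining into a rising target scores close to +1;
3. if no target passes the correlation threshold over the full remaining
   window, the window end is pulled in one point at a time (later fluxes can
   mask earlier anticorrelation) until an edge is found or the window hits
   its minimum length.

A second-order rule rescues true targets that are themselves drained onward
(source -> v -> w): the edge source -> v is accepted when both the source and
v anticorrelate with some common neighbor w of v.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import stats

from .lipid_model import (
    Edge,
    Position,
    RemodelingNetwork,
    SpeciesId,
    TimeCourse,
    differs_at_one_position,
)

__all__ = [
    "InferenceConfig",
    "detect_sources",
    "neighborhood",
    "edge_score",
    "infer_network",
    "bidirectionalize",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class InferenceConfig:
    """Knobs of the correlation-network step.

    alpha may be a single significance level used at every time point or a
    per-time-point sequence of length H-1.  fallback_margin is the relative
    mean decrease required to call a source when a time point carries fewer
    than two replicates and no t-test is possible.
    """

    alpha: float | Sequence[float] = 0.3
    corr_threshold: float = 0.5
    min_window: int = 3
    second_order: bool = True
    fallback_margin: float = 0.05
    prune_multitarget: bool = False

    def __post_init__(self) -> None:
        alphas = [self.alpha] if np.isscalar(self.alpha) else list(self.alpha)
        if any(not (0.0 < a < 1.0) for a in alphas):
            raise ValueError("alpha must lie in (0, 1)")
        if self.min_window < 2:
            raise ValueError("min_window must be at least 2")

    def alpha_at(self, h: int) -> float:
        if np.isscalar(self.alpha):
            return float(self.alpha)  # type: ignore[arg-type]
        return float(self.alpha[h])  # type: ignore[index]


def _decreases(a: np.ndarray, b: np.ndarray, alpha: float, margin: float) -> bool:
    """True if replicate sample ``b`` is significantly below ``a``."""
    if a.size < 2 or b.size < 2:
        # too few replicates for a t-test: mean decrease by relative margin
        logger.debug("t-test fallback: <2 replicates, using mean-decrease margin")
        ma, mb = float(np.mean(a)), float(np.mean(b))
        return mb < ma * (1.0 - margin)
    if np.ptp(a) == 0.0 and np.ptp(b) == 0.0:
        # t statistic undefined; exact replicates decide by strict mean order
        return float(b[0]) < float(a[0])
    t = stats.ttest_ind(a, b, equal_var=False, alternative="greater")
    return bool(t.pvalue < alpha)


def detect_sources(tc: TimeCourse, h: int, alpha: float = 0.3,
                   fallback_margin: float = 0.05) -> set[SpeciesId]:
    """Species whose concentration decreases from time index ``h`` to ``h+1``.

    Decrease is judged by a one-sided Welch t-test on the replicates at the
    two time points at significance level ``alpha``.
    """
    if not 0 <= h < tc.n_times - 1:
        raise ValueError(f"time index {h} out of range for H={tc.n_times}")
    out = set()
    for s in tc.species:
        a = tc.replicate_values(s, h)
        b = tc.replicate_values(s, h + 1)
        if _decreases(a, b, alpha, fallback_margin):
            out.add(s)
    return out


def neighborhood(s: SpeciesId, observed: set[SpeciesId] | Sequence[SpeciesId]) -> set[SpeciesId]:
    """Observed species sharing exactly one acyl chain (one sn position) with ``s``."""
    return {
        v for v in observed if v != s and differs_at_one_position(s, v) is not None
    }


def edge_score(
    s: SpeciesId,
    v: SpeciesId,
    tc: TimeCourse,
    window: tuple[int, int],
) -> float:
    """Inverse-correlation score of a candidate conversion s -> v.

    The score is the negated Pearson correlation of the replicate-mean series
    of ``s`` and ``v`` over the (inclusive) index window, in [-1, 1]: +1 means
    perfectly anticorrelated (source drains as target fills).  A sign guard
    forces the score non-positive when ``v`` never increases inside the
    window — a target that never accumulates cannot be the product of ``s``.
    Zero-variance series score 0.
    """
    h0, h1 = window
    if not (0 <= h0 < h1 < tc.n_times):
        raise ValueError(f"bad window {window} for H={tc.n_times}")
    xs = tc.mean_series(s)[h0 : h1 + 1]
    xv = tc.mean_series(v)[h0 : h1 + 1]
    if np.std(xs) == 0.0 or np.std(xv) == 0.0:
        logger.debug("zero-variance series in edge score %s->%s; score 0", s, v)
        return 0.0
    score = -float(np.corrcoef(xs, xv)[0, 1])
    if not np.any(np.diff(xv) > 0):
        score = -abs(score)
    return float(np.clip(score, -1.0, 1.0))


def _passes(
    s: SpeciesId,
    v: SpeciesId,
    tc: TimeCourse,
    window: tuple[int, int],
    cfg: InferenceConfig,
    observed: set[SpeciesId],
) -> tuple[bool, float]:
    sc = edge_score(s, v, tc, window)
    if sc > cfg.corr_threshold:
        return True, sc
    # second-order rescue: v may be a transient intermediate drained onward
    # to some w, masking the s/v anticorrelation.  v must still accumulate
    # somewhere in the window — a species that only decreases is another
    # source draining into a shared sink, not a conversion product of s.
    h0, h1 = window
    v_means = tc.mean_series(v)[h0 : h1 + 1]
    if cfg.second_order and bool(np.any(np.diff(v_means) > 0)):
        for w in sorted(neighborhood(v, observed)):
            if w == s:
                continue
            if (
                edge_score(s, w, tc, window) > cfg.corr_threshold
                and edge_score(v, w, tc, window) > cfg.corr_threshold
            ):
                return True, sc
    return False, sc


def infer_network(tc: TimeCourse, cfg: InferenceConfig | None = None) -> RemodelingNetwork:
    """Infer the reduced remodeling correlation network from a time course.

    For every time index with detected sources, each source accepts every
    passing target at the widest evidence window that yields any; edges found
    at several time points are merged keeping the best score.  A source
    assigned several targets is then re-scored against their summed series
    and pruned to its single highest-scoring edge if the combined score fails
    the threshold.  Every observed species is a node, so isolated species
    stay in the system with zero derivative downstream.
    """
    cfg = cfg or InferenceConfig()
    observed = set(tc.species)
    H = tc.n_times
    best: dict[tuple[SpeciesId, SpeciesId], Edge] = {}

    any_source = False
    for h in range(H - 1):
        sources = detect_sources(tc, h, cfg.alpha_at(h), cfg.fallback_margin)
        any_source = any_source or bool(sources)
        for s in sorted(sources):
            # sources flagged near the series end still get a full-length
            # window by pulling the start back to min_window points
            start = min(h, H - cfg.min_window)
            end = H - 1
            while end - start + 1 >= cfg.min_window:
                window = (start, end)
                accepted: list[tuple[float, SpeciesId]] = []
                for v in sorted(neighborhood(s, observed)):
                    ok, sc = _passes(s, v, tc, window, cfg, observed)
                    if ok:
                        accepted.append((sc, v))
                if accepted:
                    for sc, v in accepted:
                        pos = differs_at_one_position(s, v)
                        assert pos is not None
                        e = Edge(source=s, target=v, position=pos, score=sc, window=window)
                        prev = best.get(e.key)
                        if prev is None or e.score > prev.score:
                            best[e.key] = e
                    break
                end -= 1

    edges = list(best.values())
    edges = _recheck_multitarget_sources(edges, tc, cfg)
    if not any_source:
        logger.warning("no species passed source detection at any time point; empty network")
    return RemodelingNetwork(nodes=frozenset(observed), edges=tuple(sorted(
        edges, key=lambda e: (e.source, e.target)
    )))


def _recheck_multitarget_sources(
    edges: list[Edge], tc: TimeCourse, cfg: InferenceConfig
) -> list[Edge]:
    """When one source feeds several targets, re-score it against their sum.

    A genuine multi-way source should anticorrelate with the *total*
    concentration flowing into its targets.  A failing combined score is
    logged as a diagnostic; with ``prune_multitarget`` set, the source is
    additionally pruned to its single highest-scoring edge (each edge already
    passed acceptance on its own window, so pruning is off by default).
    """
    by_source: dict[SpeciesId, list[Edge]] = {}
    for e in edges:
        by_source.setdefault(e.source, []).append(e)
    kept: list[Edge] = []
    for s, group in by_source.items():
        if len(group) == 1:
            kept.extend(group)
            continue
        h0 = min(e.window[0] for e in group)
        h1 = max(e.window[1] for e in group)
        xs = tc.mean_series(s)[h0 : h1 + 1]
        xsum = np.sum([tc.mean_series(e.target)[h0 : h1 + 1] for e in group], axis=0)
        if np.std(xs) == 0.0 or np.std(xsum) == 0.0:
            combined = 0.0
        else:
            combined = -float(np.corrcoef(xs, xsum)[0, 1])
            if not np.any(np.diff(xsum) > 0):
                combined = -abs(combined)
        if combined > cfg.corr_threshold:
            kept.extend(group)
        elif cfg.prune_multitarget:
            best = max(group, key=lambda e: (e.score, e.target))
            logger.info(
                "source %s: combined-target score %.3f below threshold; keeping only %s",
                s, combined, best.target,
            )
            kept.append(best)
        else:
            logger.info(
                "source %s: combined-target score %.3f below threshold (diagnostic)",
                s, combined,
            )
            kept.extend(group)
    return kept


def bidirectionalize(net: RemodelingNetwork) -> RemodelingNetwork:
    """Add the reverse of every edge (score 0, same window) where missing.

    Remodeling reactions are reversible; fitting one-way networks biases the
    kinetics, so the dynamic stage always works on the bidirectional closure.
    Idempotent.
    """
    keys = net.edge_keys()
    extra = [e.reversed(score=0.0) for e in net.edges if (e.target, e.source) not in keys]
    return RemodelingNetwork(nodes=net.nodes, edges=net.edges + tuple(extra))
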