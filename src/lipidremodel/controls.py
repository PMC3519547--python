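"""Negative controls for fit specificity.

Two nulls probe whether a close fit reflects real structure rather than
model flexibility:

- label permutation: species identities of the data are shuffled and the
  shuffled data are fit to the system inferred from the *original* data; a
  genuine network should fit the real data markedly better than the nulls.
- parameter perturbation: the edges carrying the major flux are deleted from
  the network and replaced by randomly drawn single-position edges before
  refitting; the perturbed systems should converge to worse error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .dynamic_fit import FitResult, build_ode, fit_dynamics
from .lipid_model import (
    Edge,
    RemodelingNetwork,
    SpeciesId,
    TimeCourse,
    differs_at_one_position,
)
from .network_inference import bidirectionalize

__all__ = [
    "ControlReport",
    "permute_labels",
    "permutation_test",
    "parameter_perturbation_test",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ControlReport:
    """Real-data fit error against a null distribution of control errors."""

    real_error: float
    null_errors: tuple[float, ...]
    n_failed: int = 0

    @property
    def mean(self) -> float:
        return float(np.mean(self.null_errors)) if self.null_errors else float("nan")

    @property
    def stddev(self) -> float:
        if len(self.null_errors) < 2:
            return float("nan")
        return float(np.std(self.null_errors, ddof=1))

    @property
    def empirical_p(self) -> float:
        """Fraction of null errors at or below the real error."""
        if not self.null_errors:
            return float("nan")
        return float(np.mean(np.asarray(self.null_errors) <= self.real_error))

    @property
    def z_score(self) -> float:
        """How many null standard deviations the real error sits below the null mean."""
        return (self.mean - self.real_error) / self.stddev


def permute_labels(tc: TimeCourse, seed: int | None = None) -> TimeCourse:
    """Uniformly permute the species identities of a time course.

    The time/replicate structure is untouched; only which measurement series
    belongs to which species changes.  The identity permutation may be drawn.
    """
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(tc.species))
    mapping = {tc.species[i]: tc.species[perm[i]] for i in range(len(tc.species))}
    return tc.relabel(mapping)


def _best_error(fit: FitResult) -> float:
    return fit.final_errors[2]


def permutation_test(
    tc: TimeCourse,
    net: RemodelingNetwork,
    fit_kwargs: dict | None = None,
    n: int = 100,
    seed: int | None = None,
) -> ControlReport:
    """Fit ``n`` label-permuted copies of the data to the real-data network.

    The network (and hence the ODE system) is held fixed at the one inferred
    from the unpermuted data; only the data labels move.  Fit failures are
    counted, not silently dropped.
    """
    if len(tc.species) < 2:
        raise ValueError("need at least 2 species to permute")
    fit_kwargs = dict(fit_kwargs or {})
    sys = build_ode(bidirectionalize(net))
    real = fit_dynamics(tc, sys, **fit_kwargs)
    rng = np.random.default_rng(seed)
    nulls: list[float] = []
    n_failed = 0
    for k in range(n):
        child = int(rng.integers(0, 2**31 - 1))
        permuted = permute_labels(tc, seed=child)
        try:
            fit = fit_dynamics(permuted, sys, **fit_kwargs)
        except Exception:  # noqa: BLE001 - failures are part of the report
            logger.exception("permutation %d: fit failed", k)
            n_failed += 1
            continue
        nulls.append(_best_error(fit))
    return ControlReport(
        real_error=_best_error(real), null_errors=tuple(nulls), n_failed=n_failed
    )


def _replacement_pool(
    net: RemodelingNetwork, observed: Sequence[SpeciesId]
) -> list[tuple[SpeciesId, SpeciesId]]:
    used = net.edge_keys()
    pool = []
    for s in observed:
        for t in observed:
            if s != t and (s, t) not in used and differs_at_one_position(s, t) is not None:
                pool.append((s, t))
    return pool


def parameter_perturbation_test(
    tc: TimeCourse,
    net: RemodelingNetwork,
    targeted_edges: Sequence[tuple[SpeciesId, SpeciesId]],
    fit_kwargs: dict | None = None,
    n: int = 20,
    seed: int | None = None,
) -> ControlReport:
    """Delete the targeted (major-flux) edges, insert random replacements, refit.

    Each of the ``n`` runs removes the targeted reactions (both directions)
    from the bidirectionalized network, draws an equal number of replacement
    reactions uniformly from the unused single-position conversions among
    observed species (inserted bidirectionally), and refits.  Converged
    errors form the null distribution compared against the unperturbed fit.
    """
    fit_kwargs = dict(fit_kwargs or {})
    bnet = bidirectionalize(net)
    keys = bnet.edge_keys()
    targeted = [tuple(t) for t in targeted_edges]
    unknown = [t for t in targeted if t not in keys]
    if unknown:
        raise ValueError(f"targeted edges not in network: {unknown}")
    sys = build_ode(bnet)
    real = fit_dynamics(tc, sys, **fit_kwargs)
    real_error = _best_error(real)

    if not targeted:
        return ControlReport(real_error=real_error, null_errors=(real_error,) * n)

    # a targeted reaction is removed in both directions; otherwise the
    # surviving reverse partner would reintroduce it on re-closure
    removed = set(targeted) | {(t, s) for (s, t) in targeted}
    kept = tuple(e for e in bnet.edges if e.key not in removed)
    kept_net = RemodelingNetwork(nodes=bnet.nodes, edges=kept)
    rng = np.random.default_rng(seed)
    nulls: list[float] = []
    n_failed = 0
    for k in range(n):
        pool = [
            (s, t) for (s, t) in _replacement_pool(kept_net, list(tc.species))
            if (t, s) not in removed and s < t  # one entry per reaction
        ]
        if not pool:
            raise ValueError("no valid replacement edges available")
        idx = rng.choice(len(pool), size=min(len(targeted), len(pool)), replace=False)
        extra = []
        for i in np.atleast_1d(idx):
            s, t = pool[int(i)]
            pos = differs_at_one_position(s, t)
            assert pos is not None
            e = Edge(source=s, target=t, position=pos)
            extra.extend([e, e.reversed()])
        perturbed = RemodelingNetwork(nodes=bnet.nodes, edges=kept + tuple(extra))
        try:
            fit = fit_dynamics(tc, build_ode(perturbed), **fit_kwargs)
        except Exception:  # noqa: BLE001
            logger.exception("perturbation %d: fit failed", k)
            n_failed += 1
            continue
        nulls.append(_best_error(fit))
    return ControlReport(real_error=real_error, null_errors=tuple(nulls), n_failed=n_failed)
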