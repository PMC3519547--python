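"""Domain types for diacyl phospholipid remodeling.

A diacyl glycerophospholipid species is identified by the acyl chain at the
sn1 position and the acyl chain at the sn2 position of the glycerol backbone.
Chains are written in the field's ``C:D`` shorthand (carbons:double bonds),
species as ``sn1-sn2``, e.g. ``18:0-22:6``.  The position assignment matters:
``18:0-22:6`` and ``22:6-18:0`` are different species.

Remodeling (the Lands cycle) swaps one chain at a time through a lyso
intermediate, so two species connected by a single remodeling reaction differ
at exactly one sn position — the combinatorial rule everything downstream
builds on.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Literal, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AcylChain",
    "SpeciesId",
    "TimeCourse",
    "Edge",
    "RemodelingNetwork",
    "Position",
    "SpeciesParseError",
    "parse_species",
    "differs_at_one_position",
]

Position = Literal["sn1", "sn2"]

_CHAIN_RE = re.compile(r"^(\d+):(\d+)$")


class SpeciesParseError(ValueError):
    """A species or chain label could not be parsed."""


@dataclass(frozen=True, order=True)
class AcylChain:
    """A fatty acyl residue with ``carbons`` carbons and ``double_bonds`` double bonds."""

    carbons: int
    double_bonds: int

    def __post_init__(self) -> None:
        if self.carbons < 2:
            raise ValueError(f"acyl chain needs at least 2 carbons, got {self.carbons}")
        if self.double_bonds < 0:
            raise ValueError(f"negative double bond count: {self.double_bonds}")
        if self.double_bonds > self.carbons:
            raise ValueError(
                f"double bonds ({self.double_bonds}) cannot exceed carbons ({self.carbons})"
            )

    @classmethod
    def parse(cls, token: str) -> "AcylChain":
        m = _CHAIN_RE.match(token.strip())
        if m is None:
            raise SpeciesParseError(f"malformed acyl chain token {token!r}; expected 'C:D'")
        return cls(carbons=int(m.group(1)), double_bonds=int(m.group(2)))

    def __str__(self) -> str:
        return f"{self.carbons}:{self.double_bonds}"


@dataclass(frozen=True, order=True)
class SpeciesId:
    """A diacyl species: ordered (sn1, sn2) acyl chain pair."""

    sn1: AcylChain
    sn2: AcylChain

    @classmethod
    def parse(cls, label: str, sep: str = "-") -> "SpeciesId":
        return parse_species(label, sep=sep)

    def chain_at(self, position: Position) -> AcylChain:
        return self.sn1 if position == "sn1" else self.sn2

    def render(self, sep: str = "-") -> str:
        return f"{self.sn1}{sep}{self.sn2}"

    def __str__(self) -> str:
        return self.render()


def parse_species(label: str, sep: str = "-") -> SpeciesId:
    """Parse a ``C:D<sep>C:D`` species label into a :class:`SpeciesId`.

    Round-trips with :meth:`SpeciesId.render` for every well-formed label.
    """
    parts = label.strip().split(sep)
    if len(parts) != 2:
        raise SpeciesParseError(
            f"malformed species label {label!r}: expected two 'C:D' tokens separated by {sep!r}"
        )
    try:
        sn1 = AcylChain.parse(parts[0])
    except SpeciesParseError as exc:
        raise SpeciesParseError(f"species {label!r}: bad sn1 token: {exc}") from None
    try:
        sn2 = AcylChain.parse(parts[1])
    except SpeciesParseError as exc:
        raise SpeciesParseError(f"species {label!r}: bad sn2 token: {exc}") from None
    return SpeciesId(sn1=sn1, sn2=sn2)


def differs_at_one_position(a: SpeciesId, b: SpeciesId) -> Optional[Position]:
    """Return the single sn position at which ``a`` and ``b`` differ, if any.

    Returns ``"sn1"`` when the sn2 chains agree and the sn1 chains differ,
    ``"sn2"`` in the mirror case, and ``None`` when the species are identical
    or differ at both positions.  Symmetric in its arguments.
    """
    sn1_differs = a.sn1 != b.sn1
    sn2_differs = a.sn2 != b.sn2
    if sn1_differs and not sn2_differs:
        return "sn1"
    if sn2_differs and not sn1_differs:
        return "sn2"
    return None


@dataclass(eq=False)
class TimeCourse:
    """Replicate concentration measurements of a species panel over time.

    ``values[s][h]`` is the 1-D array of replicate concentrations of species
    ``s`` at time index ``h``.  Replicate counts may differ across time points
    but every species must carry at least one replicate at every time.
    Concentrations are arbitrary (MS-intensity) units, non-negative.
    """

    species: tuple[SpeciesId, ...]
    times: tuple[float, ...]
    values: Mapping[SpeciesId, tuple[np.ndarray, ...]]

    def __post_init__(self) -> None:
        self.species = tuple(self.species)
        self.times = tuple(float(t) for t in self.times)
        if len(self.times) < 3:
            raise ValueError(f"need at least 3 time points, got {len(self.times)}")
        if any(t1 >= t2 for t1, t2 in zip(self.times, self.times[1:])):
            raise ValueError("time points must be strictly increasing")
        if len(set(self.species)) != len(self.species):
            raise ValueError("duplicate species in panel")
        vals = {}
        for s in self.species:
            if s not in self.values:
                raise ValueError(f"species {s} has no measurements")
            per_time = []
            for h, arr in enumerate(self.values[s]):
                arr = np.asarray(arr, dtype=float).ravel()
                if arr.size < 1:
                    raise ValueError(f"species {s} has no replicate at time index {h}")
                if not np.all(np.isfinite(arr)):
                    raise ValueError(f"non-finite concentration for {s} at time index {h}")
                if np.any(arr < 0):
                    raise ValueError(f"negative concentration for {s} at time index {h}")
                per_time.append(arr)
            if len(per_time) != len(self.times):
                raise ValueError(
                    f"species {s}: {len(per_time)} time points, expected {len(self.times)}"
                )
            vals[s] = tuple(per_time)
        self.values = vals

    @property
    def n_times(self) -> int:
        return len(self.times)

    @property
    def n_species(self) -> int:
        return len(self.species)

    def replicate_values(self, s: SpeciesId, h: int) -> np.ndarray:
        return self.values[s][h]

    @cached_property
    def _means(self) -> np.ndarray:
        out = np.empty((self.n_species, self.n_times))
        for i, s in enumerate(self.species):
            out[i] = [float(np.mean(v)) for v in self.values[s]]
        return out

    def mean_matrix(self, order: Sequence[SpeciesId] | None = None) -> np.ndarray:
        """(N, H) matrix of replicate means, rows in ``order`` (default panel order)."""
        if order is None:
            return self._means.copy()
        idx = {s: i for i, s in enumerate(self.species)}
        return self._means[[idx[s] for s in order]].copy()

    def mean_series(self, s: SpeciesId) -> np.ndarray:
        return self._means[self.species.index(s)].copy()

    def sem_matrix(self) -> np.ndarray:
        """(N, H) standard error of the mean; 0 where only one replicate exists."""
        out = np.zeros((self.n_species, self.n_times))
        for i, s in enumerate(self.species):
            for h, v in enumerate(self.values[s]):
                if v.size > 1:
                    out[i, h] = float(np.std(v, ddof=1) / math.sqrt(v.size))
        return out

    def relabel(self, mapping: Mapping[SpeciesId, SpeciesId]) -> "TimeCourse":
        """Reassign measurements to new species identities (label permutation)."""
        if set(mapping) != set(self.species) or set(mapping.values()) != set(self.species):
            raise ValueError("mapping must be a bijection on the species panel")
        new_values = {mapping[s]: self.values[s] for s in self.species}
        return TimeCourse(species=self.species, times=self.times, values=new_values)

    def to_frame(self, sep: str = "-") -> pd.DataFrame:
        rows = []
        for s in self.species:
            label = s.render(sep)
            for h, t in enumerate(self.times):
                for r, c in enumerate(self.values[s][h], start=1):
                    rows.append((label, t, r, float(c)))
        return pd.DataFrame(rows, columns=["species", "time_h", "replicate", "concentration"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame, sep: str = "-") -> "TimeCourse":
        required = {"species", "time_h", "replicate", "concentration"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        species = [parse_species(lbl, sep) for lbl in pd.unique(df["species"])]
        times = tuple(sorted(float(t) for t in pd.unique(df["time_h"])))
        values: dict[SpeciesId, tuple[np.ndarray, ...]] = {}
        grouped = df.groupby(["species", "time_h"])["concentration"]
        for s, lbl in zip(species, pd.unique(df["species"])):
            per_time = []
            for t in times:
                try:
                    g = grouped.get_group((lbl, t))
                except KeyError:
                    raise ValueError(f"species {lbl} has no measurement at t={t}") from None
                per_time.append(np.asarray(g, dtype=float))
            values[s] = tuple(per_time)
        return cls(species=tuple(species), times=times, values=values)


@dataclass(frozen=True)
class Edge:
    """A directed single-position conversion reaction between observed species."""

    source: SpeciesId
    target: SpeciesId
    position: Position
    score: float = 0.0
    window: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        pos = differs_at_one_position(self.source, self.target)
        if pos is None:
            raise ValueError(
                f"edge {self.source}->{self.target} must join species differing at exactly one position"
            )
        if pos != self.position:
            raise ValueError(
                f"edge {self.source}->{self.target} differs at {pos}, not {self.position}"
            )

    @property
    def key(self) -> tuple[SpeciesId, SpeciesId]:
        return (self.source, self.target)

    def reversed(self, score: float = 0.0) -> "Edge":
        return Edge(
            source=self.target,
            target=self.source,
            position=self.position,
            score=score,
            window=self.window,
        )


@dataclass(frozen=True)
class RemodelingNetwork:
    """Directed weighted graph of single-position remodeling reactions."""

    nodes: frozenset[SpeciesId]
    edges: tuple[Edge, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "nodes", frozenset(self.nodes))
        object.__setattr__(self, "edges", tuple(self.edges))
        keys = [e.key for e in self.edges]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate directed edges")
        for e in self.edges:
            if e.source not in self.nodes or e.target not in self.nodes:
                raise ValueError(f"edge endpoint not in node set: {e.source}->{e.target}")

    @classmethod
    def from_edges(
        cls, edges: Iterable[Edge], extra_nodes: Iterable[SpeciesId] = ()
    ) -> "RemodelingNetwork":
        edges = tuple(edges)
        nodes = set(extra_nodes)
        for e in edges:
            nodes.add(e.source)
            nodes.add(e.target)
        return cls(nodes=frozenset(nodes), edges=edges)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def has_edge(self, source: SpeciesId, target: SpeciesId) -> bool:
        return any(e.source == source and e.target == target for e in self.edges)

    def edge_keys(self) -> set[tuple[SpeciesId, SpeciesId]]:
        return {e.key for e in self.edges}

    def is_bidirectional(self) -> bool:
        keys = self.edge_keys()
        return all((t, s) in keys for (s, t) in keys)

    def sorted_species(self) -> tuple[SpeciesId, ...]:
        return tuple(sorted(self.nodes))
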