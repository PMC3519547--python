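"""Decomposition of conversion-rate tables into deacylation/reacylation rates.

A fitted conversion rate k_{i->j} (initial chain i replaced by new chain j at
one sn position) runs through a lyso intermediate: a phospholipase removes
chain i at rate d_i, an acyltransferase adds chain j at rate a_j.  With the
lyso pool at steady state — lyso species are far less abundant than diacyl
species — the effective first-order conversion rate takes the rank-1 form

    k_{i->j} = d_i * a_j / sum_l a_l .

Absolute d and a are unidentifiable from k alone, but ratios survive:
within a row (fixed i) the k ratios equal reacylation-rate ratios a_j/a_j',
and within a column (fixed j) they equal deacylation-rate ratios d_i/d_i'.
The operations here compute those relative rates from a rate table, averaging
pairwise ratios over all shared rows/columns.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Literal, Mapping, Optional

import numpy as np
import pandas as pd

from .lipid_model import AcylChain, Position

__all__ = [
    "RateRow",
    "RateTable",
    "RelativeRates",
    "steady_state_rate_table",
    "pairwise_rate_ratio",
    "relative_reacylation",
    "relative_deacylation",
    "reacylation_consistency",
    "load_reference_rate_tables",
]

logger = logging.getLogger(__name__)

Mean = Literal["arithmetic", "geometric"]


class MissingRateError(KeyError):
    """A requested rate-table entry is structurally missing."""


@dataclass(frozen=True)
class RateRow:
    """Rates out of one initial chain, from one experiment."""

    initial_chain: AcylChain
    rates: Mapping[AcylChain, float]
    experiment: Optional[str] = None

    def __post_init__(self) -> None:
        rates = dict(self.rates)
        for new, k in rates.items():
            if new == self.initial_chain:
                raise ValueError(f"self-conversion entry {self.initial_chain}->{new}")
            if k < 0:
                raise ValueError(f"negative rate {self.initial_chain}->{new}: {k}")
        object.__setattr__(self, "rates", rates)


@dataclass(frozen=True)
class RateTable:
    """(initial chain, new chain) -> conversion rate, at one sn position.

    Several rows may share an initial chain (independent experiments); entries
    absent from a row are structurally missing, never zero.
    """

    position: Position
    rows: tuple[RateRow, ...]

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("rate table needs at least one row")

    @classmethod
    def from_records(
        cls,
        position: Position,
        records: Iterable[tuple[Optional[str], AcylChain, AcylChain, float]],
    ) -> "RateTable":
        grouped: dict[tuple[Optional[str], AcylChain], dict[AcylChain, float]] = {}
        for exp, initial, new, rate in records:
            grouped.setdefault((exp, initial), {})[new] = float(rate)
        rows = tuple(
            RateRow(initial_chain=initial, rates=rates, experiment=exp)
            for (exp, initial), rates in grouped.items()
        )
        return cls(position=position, rows=rows)

    def scaled(self, c: float) -> "RateTable":
        if c <= 0:
            raise ValueError("scale factor must be positive")
        return RateTable(
            position=self.position,
            rows=tuple(
                RateRow(r.initial_chain, {j: c * k for j, k in r.rates.items()}, r.experiment)
                for r in self.rows
            ),
        )

    def rows_for(self, initial: AcylChain) -> tuple[RateRow, ...]:
        return tuple(r for r in self.rows if r.initial_chain == initial)

    def initial_chains(self) -> tuple[AcylChain, ...]:
        seen: dict[AcylChain, None] = {}
        for r in self.rows:
            seen.setdefault(r.initial_chain)
        return tuple(seen)

    def new_chains(self) -> tuple[AcylChain, ...]:
        seen: dict[AcylChain, None] = {}
        for r in self.rows:
            for j in r.rates:
                seen.setdefault(j)
        return tuple(seen)

    def to_frame(self) -> pd.DataFrame:
        recs = [
            (self.position, r.experiment, str(r.initial_chain), str(j), k)
            for r in self.rows
            for j, k in r.rates.items()
        ]
        return pd.DataFrame(
            recs, columns=["position", "experiment", "initial_chain", "new_chain", "rate"]
        )


@dataclass(frozen=True)
class RelativeRates:
    """Per-chain rates relative to a reference chain (reference maps to 1)."""

    kind: Literal["deacylation", "reacylation"]
    reference: AcylChain
    ratios: Mapping[AcylChain, float]
    position: Position

    def __post_init__(self) -> None:
        ratios = dict(self.ratios)
        if ratios.get(self.reference) != 1.0:
            raise ValueError("reference chain ratio must be 1")
        if any(v <= 0 for v in ratios.values()):
            raise ValueError("relative rates must be positive")
        object.__setattr__(self, "ratios", ratios)

    def ranking(self) -> tuple[AcylChain, ...]:
        return tuple(sorted(self.ratios, key=lambda c: -self.ratios[c]))


def steady_state_rate_table(
    d: Mapping[AcylChain, float],
    a: Mapping[AcylChain, float],
    position: Position = "sn1",
) -> RateTable:
    """Effective conversion rates implied by deacylation/reacylation rates.

    k_{i->j} = d_i * a_j / sum_l a_l for i != j (steady-state lyso pool,
    all deacylations feeding one intermediate).
    """
    if not d or not a:
        raise ValueError("empty chain set")
    if any(v <= 0 for v in d.values()) or any(v <= 0 for v in a.values()):
        raise ValueError("deacylation and reacylation rates must be positive")
    a_sum = float(sum(a.values()))
    rows = []
    for i, di in d.items():
        rates = {j: di * aj / a_sum for j, aj in a.items() if j != i}
        if rates:
            rows.append(RateRow(initial_chain=i, rates=rates, experiment=None))
    return RateTable(position=position, rows=rows)


def _mean(samples: list[float], mean: Mean) -> float:
    if mean == "geometric":
        return float(np.exp(np.mean(np.log(samples))))
    return float(np.mean(samples))


def pairwise_rate_ratio(
    table: RateTable,
    i: AcylChain,
    j1: AcylChain,
    j2: AcylChain,
    ndigits: int | None = None,
) -> float:
    """k_{i->j1} / k_{i->j2}; averaged over rows carrying both entries."""
    samples = [
        r.rates[j1] / r.rates[j2]
        for r in table.rows_for(i)
        if j1 in r.rates and j2 in r.rates
    ]
    if not samples:
        raise MissingRateError(
            f"no row of initial chain {i} carries both {j1} and {j2} at {table.position}"
        )
    out = float(np.mean(samples))
    return round(out, ndigits) if ndigits is not None else out


def relative_reacylation(
    table: RateTable,
    ref_new_chain: AcylChain,
    mean: Mean = "arithmetic",
) -> RelativeRates:
    """Reacylation rate of each new chain relative to ``ref_new_chain``.

    Within each row, k_{i->j} / k_{i->ref} = a_j / a_ref; the estimate is the
    mean of that ratio over all rows where both entries exist.  Chains never
    co-occurring with the reference are excluded with a warning.
    """
    if not any(ref_new_chain in r.rates for r in table.rows):
        raise MissingRateError(f"reference chain {ref_new_chain} absent from every row")
    ratios: dict[AcylChain, float] = {ref_new_chain: 1.0}
    for j in table.new_chains():
        if j == ref_new_chain:
            continue
        samples = [
            r.rates[j] / r.rates[ref_new_chain]
            for r in table.rows
            if j in r.rates and ref_new_chain in r.rates
        ]
        if not samples:
            warnings.warn(
                f"new chain {j} never co-occurs with reference {ref_new_chain}; excluded",
                stacklevel=2,
            )
            continue
        ratios[j] = _mean(samples, mean)
    return RelativeRates(
        kind="reacylation", reference=ref_new_chain, ratios=ratios, position=table.position
    )


def relative_deacylation(
    table: RateTable,
    ref_initial_chain: AcylChain,
    mean: Mean = "arithmetic",
) -> RelativeRates:
    """Deacylation rate of each initial chain relative to ``ref_initial_chain``.

    Within each shared column, k_{i->j} / k_{ref->j} = d_i / d_ref; the
    estimate averages that ratio over all (row of i, row of ref, shared
    column) combinations.
    """
    ref_rows = table.rows_for(ref_initial_chain)
    if not ref_rows:
        raise MissingRateError(f"reference chain {ref_initial_chain} has no row")
    ratios: dict[AcylChain, float] = {ref_initial_chain: 1.0}
    for i in table.initial_chains():
        if i == ref_initial_chain:
            continue
        samples = [
            ri.rates[j] / rr.rates[j]
            for ri in table.rows_for(i)
            for rr in ref_rows
            for j in ri.rates
            if j in rr.rates
        ]
        if not samples:
            warnings.warn(
                f"initial chain {i} shares no column with reference {ref_initial_chain}; excluded",
                stacklevel=2,
            )
            continue
        ratios[i] = _mean(samples, mean)
    return RelativeRates(
        kind="deacylation", reference=ref_initial_chain, ratios=ratios, position=table.position
    )


def reacylation_consistency(table: RateTable) -> list[dict]:
    """Flag row pairs whose reacylation preference orderings conflict.

    Under the rank-1 steady-state model every row must rank new chains
    identically (the ordering of a_j).  A conflict — e.g. one initial chain
    preferring 20:4 over 18:1 while another prefers the reverse — is a
    diagnostic of position cross-talk and is reported, not corrected.
    """
    conflicts = []
    rows = table.rows
    for idx1 in range(len(rows)):
        for idx2 in range(idx1 + 1, len(rows)):
            r1, r2 = rows[idx1], rows[idx2]
            shared = sorted(set(r1.rates) & set(r2.rates))
            for k1 in range(len(shared)):
                for k2 in range(k1 + 1, len(shared)):
                    j1, j2 = shared[k1], shared[k2]
                    s1 = np.sign(r1.rates[j1] - r1.rates[j2])
                    s2 = np.sign(r2.rates[j1] - r2.rates[j2])
                    if s1 * s2 < 0:
                        conflicts.append(
                            {
                                "position": table.position,
                                "row1": str(r1.initial_chain),
                                "row2": str(r2.initial_chain),
                                "new_chain_1": str(j1),
                                "new_chain_2": str(j2),
                            }
                        )
    return conflicts


def load_reference_rate_tables() -> dict[Position, RateTable]:
    """Load the packaged BHK21 remodeling rate tables (one per sn position)."""
    with resources.files("lipidremodel").joinpath(
        "data/remodeling_rates_bhk21.tsv"
    ).open() as fh:
        df = pd.read_csv(fh, sep="\t", comment="#")
    out: dict[Position, RateTable] = {}
    for pos, sub in df.groupby("position"):
        records = [
            (
                row.experiment,
                AcylChain.parse(row.initial_chain),
                AcylChain.parse(row.new_chain),
                float(row.rate),
            )
            for row in sub.itertuples()
        ]
        out[pos] = RateTable.from_records(pos, records)  # type: ignore[index]
    return out
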