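"""All-vs-all pairwise genotype comparison via bytewise Boolean operations.

For two equal-length genotype byte strings the engine runs exactly three
bytewise operations and counts zero (NUL) result bytes:

* **XOR** — a zero byte wherever the two genotypes are byte-identical
  (*position matches*, which still include both-missing positions);
* **OR** — a zero byte only where *both* genotypes are missing
  (*missing matches*);
* **AND** — a zero byte exactly where *at least one* genotype is missing
  (*positions missing*), because every called genotype is an uppercase ASCII
  letter and therefore has bit 6 set.

Four closed-form count identities then yield the discordance rate::

    queryable_positions = length - positions_missing
    genotype_matches    = position_matches - missing_matches
    discrepancy_count   = queryable_positions - genotype_matches
    discordance_rate    = discrepancy_count / queryable_positions

A naive per-offset loop (``naive_compare_pair``) implements the identical
contract and exists solely as the correctness oracle and performance
baseline.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from .encoding import NULL, GenotypePanel
from .errors import EmptyPanelError, InvariantError, TooFewSamplesError

logger = logging.getLogger(__name__)

#: Pairs with fewer queryable positions than this are flagged low-confidence.
DEFAULT_MIN_QUERYABLE = 50

PAIR_TABLE_COLUMNS = [
    "sample_a",
    "sample_b",
    "length",
    "position_matches",
    "missing_matches",
    "positions_missing",
    "queryable_positions",
    "genotype_matches",
    "discrepancy_count",
    "discordance_rate",
    "low_confidence_flag",
]


@dataclass(frozen=True)
class PairwiseCounts:
    """Full comparison record for one sample pair.

    The count algebra is enforced at construction; any violation raises
    :class:`InvariantError` (a bug, never bad input).  ``discordance_rate``
    is ``None`` — explicitly undefined, not 0 — when no position is queryable.
    """

    length: int
    position_matches: int
    missing_matches: int
    positions_missing: int
    queryable_positions: int
    genotype_matches: int
    discrepancy_count: int
    discordance_rate: float | None

    def __post_init__(self) -> None:
        c = self
        checks = [
            c.queryable_positions == c.length - c.positions_missing,
            c.genotype_matches == c.position_matches - c.missing_matches,
            c.discrepancy_count == c.queryable_positions - c.genotype_matches,
            c.missing_matches <= c.position_matches,
            c.missing_matches <= c.positions_missing,
            0 <= c.positions_missing <= c.length,
            0 <= c.position_matches <= c.length,
            c.queryable_positions >= 0,
            c.genotype_matches >= 0,
            c.discrepancy_count >= 0,
        ]
        if not all(checks):
            raise InvariantError(f"count algebra violated: {c}")
        if c.queryable_positions > 0:
            expected = c.discrepancy_count / c.queryable_positions
            if c.discordance_rate is None or not math.isclose(
                c.discordance_rate, expected, rel_tol=0, abs_tol=1e-12
            ):
                raise InvariantError(
                    f"discordance_rate {c.discordance_rate} != "
                    f"{c.discrepancy_count}/{c.queryable_positions}"
                )
        elif c.discordance_rate is not None:
            raise InvariantError("rate must be undefined when nothing is queryable")

    @classmethod
    def from_step_counts(
        cls,
        length: int,
        position_matches: int,
        missing_matches: int,
        positions_missing: int,
    ) -> "PairwiseCounts":
        """Derive the full record from the three bytewise step counts."""
        queryable = length - positions_missing
        genotype_matches = position_matches - missing_matches
        discrepancy = queryable - genotype_matches
        rate = discrepancy / queryable if queryable > 0 else None
        return cls(
            length=length,
            position_matches=position_matches,
            missing_matches=missing_matches,
            positions_missing=positions_missing,
            queryable_positions=queryable,
            genotype_matches=genotype_matches,
            discrepancy_count=discrepancy,
            discordance_rate=rate,
        )


def _as_u8(a: bytes | np.ndarray, b: bytes | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.frombuffer(a, dtype=np.uint8) if isinstance(a, (bytes, bytearray)) else np.asarray(a, dtype=np.uint8)
    y = np.frombuffer(b, dtype=np.uint8) if isinstance(b, (bytes, bytearray)) else np.asarray(b, dtype=np.uint8)
    if x.shape != y.shape:
        raise ValueError(
            f"genotype strings differ in length ({x.size} vs {y.size}); "
            "panels must be built from one region map"
        )
    return x, y


def count_equal_bytes(a: bytes | np.ndarray, b: bytes | np.ndarray) -> int:
    """Number of offsets where ``a`` and ``b`` hold identical bytes
    (both-missing included): bytewise XOR, count the zero bytes."""
    x, y = _as_u8(a, b)
    return int(np.count_nonzero((x ^ y) == 0))


def count_both_null(a: bytes | np.ndarray, b: bytes | np.ndarray) -> int:
    """Number of offsets where both bytes are NUL: bytewise OR is zero only
    there."""
    x, y = _as_u8(a, b)
    return int(np.count_nonzero((x | y) == 0))


def count_any_null(a: bytes | np.ndarray, b: bytes | np.ndarray) -> int:
    """Number of offsets where at least one byte is NUL: with bit 6 set on
    every called genotype, bytewise AND is zero exactly there."""
    x, y = _as_u8(a, b)
    return int(np.count_nonzero((x & y) == 0))


def compare_pair(a: bytes | np.ndarray, b: bytes | np.ndarray) -> PairwiseCounts:
    """Compare two genotype strings with the three bytewise operations and
    the four count identities."""
    x, y = _as_u8(a, b)
    if x.size == 0:
        raise EmptyPanelError("cannot compare zero-length genotype strings")
    return PairwiseCounts.from_step_counts(
        length=int(x.size),
        position_matches=int(np.count_nonzero((x ^ y) == 0)),
        missing_matches=int(np.count_nonzero((x | y) == 0)),
        positions_missing=int(np.count_nonzero((x & y) == 0)),
    )


def naive_compare_pair(a: bytes | np.ndarray, b: bytes | np.ndarray) -> PairwiseCounts:
    """Reference implementation: explicit per-offset Python loop.

    Same contract and output as :func:`compare_pair`; kept as the independent
    oracle and the performance baseline, never used by the pipeline.
    """
    x, y = _as_u8(a, b)
    if x.size == 0:
        raise EmptyPanelError("cannot compare zero-length genotype strings")
    xa, ya = bytes(x), bytes(y)
    position_matches = missing_matches = positions_missing = 0
    for ga, gb in zip(xa, ya):
        if ga == gb:
            position_matches += 1
        a_null = ga == NULL
        b_null = gb == NULL
        if a_null and b_null:
            missing_matches += 1
        if a_null or b_null:
            positions_missing += 1
    return PairwiseCounts.from_step_counts(
        length=len(xa),
        position_matches=position_matches,
        missing_matches=missing_matches,
        positions_missing=positions_missing,
    )


@dataclass(frozen=True)
class PairRecord:
    """One row of the long-format pair table."""

    sample_a: str
    sample_b: str
    counts: PairwiseCounts
    low_confidence: bool

    def as_row(self) -> dict:
        c = self.counts
        return {
            "sample_a": self.sample_a,
            "sample_b": self.sample_b,
            "length": c.length,
            "position_matches": c.position_matches,
            "missing_matches": c.missing_matches,
            "positions_missing": c.positions_missing,
            "queryable_positions": c.queryable_positions,
            "genotype_matches": c.genotype_matches,
            "discrepancy_count": c.discrepancy_count,
            "discordance_rate": c.discordance_rate,
            "low_confidence_flag": self.low_confidence,
        }


@dataclass
class DiscordanceMatrix:
    """Symmetric sample-by-sample matrix of discordance rates.

    ``rates[i, j]`` is NaN where the rate is undefined (no mutually queryable
    position).  The diagonal is 0 for samples with at least one called
    genotype, NaN otherwise.  ``pair_records`` holds one
    :class:`PairRecord` per unordered pair, sorted by ascending discordance
    with undefined-rate pairs last.
    """

    sample_names: list[str]
    rates: np.ndarray
    pair_records: list[PairRecord] = field(default_factory=list)
    min_queryable: int = DEFAULT_MIN_QUERYABLE

    def __post_init__(self) -> None:
        n = len(self.sample_names)
        if self.rates.shape != (n, n):
            raise ValueError("rates matrix shape does not match sample count")

    @property
    def n_samples(self) -> int:
        return len(self.sample_names)

    def pair_table(self) -> pd.DataFrame:
        """Long-format table, one row per unordered pair, ascending rate."""
        if not self.pair_records:
            return pd.DataFrame(columns=PAIR_TABLE_COLUMNS)
        return pd.DataFrame([r.as_row() for r in self.pair_records])[
            PAIR_TABLE_COLUMNS
        ]

    def defined_rates(self) -> np.ndarray:
        """All defined off-diagonal pair rates (one value per pair)."""
        return np.array(
            [
                r.counts.discordance_rate
                for r in self.pair_records
                if r.counts.discordance_rate is not None
            ]
        )

    # -- TSV round-trip ------------------------------------------------------
    def to_tsv(self, path: str | Path) -> Path:
        """Square matrix TSV: header row/column of sample names, 6-decimal
        rates, ``NA`` for undefined cells."""
        path = Path(path)
        with open(path, "w") as fh:
            fh.write("sample\t" + "\t".join(self.sample_names) + "\n")
            for name, row in zip(self.sample_names, self.rates):
                cells = ["NA" if np.isnan(v) else f"{v:.6f}" for v in row]
                fh.write(name + "\t" + "\t".join(cells) + "\n")
        return path

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DiscordanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
        names = [str(c) for c in df.columns]
        return cls(sample_names=names, rates=df.to_numpy(dtype=float))

    def pair_table_to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        table = self.pair_table().copy()
        table["discordance_rate"] = table["discordance_rate"].map(
            lambda v: "NA" if pd.isna(v) else f"{v:.6f}"
        )
        table.to_csv(path, sep="\t", index=False)
        return path


def _sort_key(record: PairRecord):
    rate = record.counts.discordance_rate
    return (rate is None, rate if rate is not None else 0.0, record.sample_a, record.sample_b)


def all_vs_all(
    panel: GenotypePanel,
    min_queryable: int = DEFAULT_MIN_QUERYABLE,
    pair_fn: Callable[[np.ndarray, np.ndarray], PairwiseCounts] = compare_pair,
) -> DiscordanceMatrix:
    """One-way all-vs-all comparison: each unordered pair computed once.

    Parameters
    ----------
    panel
        Genotype panel with >= 2 samples.
    min_queryable
        Pairs with fewer mutually queryable positions are flagged
        low-confidence in the pair table (reported, never dropped).
    pair_fn
        The pairwise engine; defaults to the bytewise :func:`compare_pair`,
        the naive oracle may be injected for testing/benchmarking.
    """
    n = panel.n_samples
    if n < 2:
        raise TooFewSamplesError(f"all-vs-all needs >= 2 samples, got {n}")
    rates = np.full((n, n), np.nan)
    records: list[PairRecord] = []
    data = panel.data
    n_undefined = 0
    for i in range(n):
        for j in range(i + 1, n):
            counts = pair_fn(data[i], data[j])
            rate = counts.discordance_rate
            if rate is None:
                n_undefined += 1
            else:
                rates[i, j] = rates[j, i] = rate
            records.append(
                PairRecord(
                    sample_a=panel.sample_names[i],
                    sample_b=panel.sample_names[j],
                    counts=counts,
                    low_confidence=counts.queryable_positions < min_queryable,
                )
            )
    # self-discordance is analytically 0 whenever the sample has any call
    has_call = (data != NULL).any(axis=1)
    rates[np.arange(n), np.arange(n)] = np.where(has_call, 0.0, np.nan)
    records.sort(key=_sort_key)
    if n_undefined:
        logger.warning(
            "%d of %d pairs have no mutually queryable position; their "
            "discordance is undefined (reported as NA)",
            n_undefined,
            len(records),
        )
    return DiscordanceMatrix(
        sample_names=list(panel.sample_names),
        rates=rates,
        pair_records=records,
        min_queryable=min_queryable,
    )


def best_matches(matrix: DiscordanceMatrix) -> pd.DataFrame:
    """For each sample, its minimum-discordance partner.

    This is the swap-resolution view: a mislabeled sample's best match points
    at the individual its data actually came from.
    """
    rows = []
    r = matrix.rates.copy()
    np.fill_diagonal(r, np.nan)
    for i, name in enumerate(matrix.sample_names):
        row = r[i]
        if np.isnan(row).all():
            rows.append({"sample": name, "best_match": None, "discordance": np.nan})
            continue
        j = int(np.nanargmin(row))
        rows.append(
            {
                "sample": name,
                "best_match": matrix.sample_names[j],
                "discordance": float(row[j]),
            }
        )
    return pd.DataFrame(rows)
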