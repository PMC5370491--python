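"""Read-count quartets and homo-quartet classification.

A *quartet* is the vector of A/C/G/T read counts observed for one diploid
individual at one position of a reference sequence.  A *homo-quartet* is a
quartet with exactly two observed states, a major state supported by more
than ``major_threshold`` reads (default 40) and a minor state supported by
exactly one read: the canonical signature of a homozygous genotype carrying
a single erroneous or leaked read.

Positions are classified from the read counts pooled across individuals:

* *monoallelic* — the major state exceeds ``major_frac`` (default 95%) of
  the pooled counts; homo-quartets at such positions estimate the
  contamination-free sequencing-error pattern;
* *biallelic* — the second-ranked state exceeds ``biallelic_factor × n``
  pooled reads (default 10 per genotyped individual), i.e. a second allele
  genuinely segregates there;
* anything else is disregarded downstream.

Coordinates are 0-based internally; TSV I/O (see :mod:`contamkit.io`) uses
1-based positions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

logger = logging.getLogger(__name__)

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: Classification labels for pooled site columns.
MONOALLELIC = "monoallelic"
BIALLELIC = "biallelic"
OTHER = "other"

PositionClass = Literal["monoallelic", "biallelic", "other"]


class EmptyColumnError(ValueError):
    """Raised when a site column has zero pooled coverage."""


@dataclass(frozen=True)
class Quartet:
    """Read counts (r_1..r_4 for A, C, G, T) of one individual at one site."""

    counts: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        if len(self.counts) != 4 or any(c < 0 for c in self.counts):
            raise ValueError(f"quartet needs four non-negative counts, got {self.counts}")

    @property
    def r(self) -> int:
        """Total read count."""
        return int(sum(self.counts))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=np.int64)


@dataclass
class SiteColumn:
    """All individuals' quartets at one reference position.

    ``counts`` is an (n, 4) integer array, one row per genotyped individual,
    columns in A, C, G, T order.  ``position`` is 0-based.
    """

    contig: str
    position: int
    individuals: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[1] != 4:
            raise ValueError("counts must be (n, 4)")
        if self.counts.shape[0] != len(self.individuals):
            raise ValueError("one row of counts per individual required")
        if (self.counts < 0).any():
            raise ValueError("negative read counts")
        if self.n < 1:
            raise ValueError("need at least one individual")

    @property
    def n(self) -> int:
        """Number of genotyped individuals."""
        return len(self.individuals)

    def totals(self) -> np.ndarray:
        """Pooled per-state read counts across individuals."""
        return self.counts.sum(axis=0)

    def quartet(self, i: int) -> Quartet:
        return Quartet(tuple(int(c) for c in self.counts[i]))


@dataclass(frozen=True)
class HomoQuartetRecord:
    """A homo-quartet annotated with its position class.

    ``z`` (the segregating allele different from the major state) and
    ``r_z`` (1 iff the minor state equals ``z``) are defined only for the
    biallelic class.
    """

    individual: str
    contig: str
    position: int
    major: str
    minor: str
    position_class: PositionClass
    z: str | None = None
    r_z: int | None = None

    def __post_init__(self) -> None:
        if self.major == self.minor:
            raise ValueError("major and minor states must differ")
        if self.position_class == BIALLELIC:
            if self.z is None or self.r_z not in (0, 1):
                raise ValueError("biallelic records need z and r_z in {0,1}")
        elif self.z is not None or self.r_z is not None:
            raise ValueError("z/r_z defined only for biallelic records")


@dataclass
class ExtractionStats:
    """Counters accumulated while scanning a dataset for homo-quartets."""

    n_quartets: int = 0
    n_homo_quartets: int = 0
    n_monoallelic: int = 0
    n_biallelic: int = 0
    n_other_class: int = 0
    n_major_not_segregating: int = 0
    n_second_rank_ties: int = 0
    by_class: dict = field(default_factory=dict)


def classify_quartet(
    q: Quartet | Sequence[int] | np.ndarray, major_threshold: int = 40
) -> tuple[bool, str | None, str | None]:
    """Decide whether ``q`` is a homo-quartet.

    Returns ``(is_homo, major, minor)``.  The test is literal: exactly two
    states observed, the larger count strictly greater than
    ``major_threshold`` and the smaller count exactly 1.  A tie is
    impossible for a passing quartet (1 < major_threshold).
    """
    counts = q.as_array() if isinstance(q, Quartet) else np.asarray(q, dtype=np.int64)
    nonzero = np.flatnonzero(counts)
    if len(nonzero) != 2:
        return False, None, None
    a, b = nonzero
    if counts[a] < counts[b]:
        a, b = b, a
    if counts[a] > major_threshold and counts[b] == 1:
        return True, BASES[a], BASES[b]
    return False, None, None


def rank_states(totals: np.ndarray) -> tuple[int, int, bool]:
    """Indices of the top-two states by pooled count.

    Ties are broken by fixed base order A < C < G < T (stable sort).  The
    returned flag reports whether the second rank was tied with the third.
    """
    totals = np.asarray(totals)
    order = np.argsort(-totals, kind="stable")  # stable => base-order ties
    tie = len(totals) > 2 and totals[order[1]] == totals[order[2]] and totals[order[1]] > 0
    return int(order[0]), int(order[1]), bool(tie)


def classify_position(
    col: SiteColumn | np.ndarray,
    n: int | None = None,
    major_frac: float = 0.95,
    biallelic_factor: int = 10,
) -> PositionClass:
    """Classify a site column as monoallelic, biallelic or other.

    ``col`` may be a :class:`SiteColumn` or a pooled length-4 totals vector
    (in which case ``n`` must be given).  Totals include the focal
    individual.  Monoallelic: major-state total strictly above
    ``major_frac`` of the grand total.  Biallelic: second-ranked state total
    strictly above ``biallelic_factor * n``.  Monoallelic wins when both
    rules fire (possible only for extreme coverage); positions meeting
    neither rule are "other".
    """
    if isinstance(col, SiteColumn):
        totals, n = col.totals(), col.n
    else:
        totals = np.asarray(col, dtype=np.int64)
        if n is None:
            raise ValueError("n required when passing raw totals")
    grand = int(totals.sum())
    if grand == 0:
        raise EmptyColumnError("zero-coverage column")
    first, second, _ = rank_states(totals)
    if totals[first] > major_frac * grand:
        return MONOALLELIC
    if totals[second] > biallelic_factor * n:
        return BIALLELIC
    return OTHER


def extract_homo_quartets(
    columns: Iterable[SiteColumn],
    major_threshold: int = 40,
    major_frac: float = 0.95,
    biallelic_factor: int = 10,
    stats: ExtractionStats | None = None,
) -> list[HomoQuartetRecord]:
    """Scan site columns and return annotated homo-quartet records.

    Records at "other" positions are dropped.  At biallelic positions the
    two segregating alleles are the top-two pooled states; a homo-quartet
    whose major state is neither of them has no well-defined ``z`` and is
    excluded (counted in ``stats.n_major_not_segregating``).  Output order
    is deterministic: sorted by (contig, position, individual).
    """
    if stats is None:
        stats = ExtractionStats()
    records: list[HomoQuartetRecord] = []
    for col in sorted(columns, key=lambda c: (c.contig, c.position)):
        totals = col.totals()
        if totals.sum() == 0:
            continue
        # homo-quartet scan first: skip cheap columns without candidates
        homo_rows = []
        for i in range(col.n):
            stats.n_quartets += 1
            is_homo, major, minor = classify_quartet(col.counts[i], major_threshold)
            if is_homo:
                stats.n_homo_quartets += 1
                homo_rows.append((i, major, minor))
        if not homo_rows:
            continue
        pos_class = classify_position(col, major_frac=major_frac, biallelic_factor=biallelic_factor)
        first, second, tie = rank_states(totals)
        if tie:
            stats.n_second_rank_ties += 1
        for i, major, minor in sorted(homo_rows, key=lambda t: col.individuals[t[0]]):
            if pos_class == OTHER:
                stats.n_other_class += 1
                continue
            if pos_class == MONOALLELIC:
                stats.n_monoallelic += 1
                records.append(
                    HomoQuartetRecord(
                        individual=col.individuals[i],
                        contig=col.contig,
                        position=col.position,
                        major=major,
                        minor=minor,
                        position_class=MONOALLELIC,
                    )
                )
                continue
            # biallelic: z is the segregating allele different from the major
            seg = {BASES[first], BASES[second]}
            if major not in seg:
                stats.n_major_not_segregating += 1
                continue
            z = BASES[second] if major == BASES[first] else BASES[first]
            stats.n_biallelic += 1
            records.append(
                HomoQuartetRecord(
                    individual=col.individuals[i],
                    contig=col.contig,
                    position=col.position,
                    major=major,
                    minor=minor,
                    position_class=BIALLELIC,
                    z=z,
                    r_z=int(minor == z),
                )
            )
    if stats.n_major_not_segregating:
        logger.info(
            "excluded %d homo-quartets whose major state was not a segregating allele",
            stats.n_major_not_segregating,
        )
    return records


def columns_from_array(
    counts: np.ndarray, individuals: Sequence[str] | None = None, contig: str = "contig1"
) -> list[SiteColumn]:
    """Wrap a (positions, individuals, 4) count array as SiteColumns."""
    counts = np.asarray(counts)
    if counts.ndim != 3 or counts.shape[2] != 4:
        raise ValueError("expected (P, N, 4) array")
    n = counts.shape[1]
    if individuals is None:
        individuals = [f"ind{i + 1}" for i in range(n)]
    individuals = list(individuals)
    return [
        SiteColumn(contig=contig, position=p, individuals=individuals, counts=counts[p])
        for p in range(counts.shape[0])
    ]
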