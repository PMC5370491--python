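"""Between-species contamination screen against a barcode reference panel.

Short reads are aligned ungapped (both strands, every offset, mismatch
counting, ambiguous bases = mismatches) to an aligned panel of equal-length
cox1-style barcode sequences.  Hits to each reference are tallied per
sample and normalized per million reads.  Because barcodes of closely
related species can be nearly identical, species pairs whose minimum
pairwise p-distance is below a divergence threshold (default 5%) are
*non-diagnostic*: cross-hits between them are never counted as
contamination.  A directed contamination matrix M records, for each
diagnostic (contaminant, contaminated) species pair, whether at least
``min_reads`` unexpected reads attest a contamination event.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

_ENC = np.full(256, 4, dtype=np.int8)  # 4 = ambiguous (always mismatches)
for _i, _b in enumerate("ACGT"):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i
_COMP = np.array([3, 2, 1, 0, 4], dtype=np.int8)  # A<->T, C<->G, N->N

MIN_READ_LENGTH = 30


def encode_sequence(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def reverse_complement_codes(codes: np.ndarray) -> np.ndarray:
    return _COMP[codes[::-1]]


@dataclass
class ReferencePanel:
    """Aligned, equal-length barcode references with species labels."""

    ids: list[str]
    species: list[str]
    components: list[str]
    sequences: list[str]

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError(f"unequal sequence lengths in panel: {sorted(lengths)}")
        if not self.sequences:
            raise ValueError("empty panel")
        if any(not s for s in self.species):
            raise ValueError("species labels must be non-empty")
        self._matrix = np.stack([encode_sequence(s) for s in self.sequences])

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    @property
    def n(self) -> int:
        return len(self.sequences)

    @property
    def matrix(self) -> np.ndarray:
        return self._matrix

    def species_list(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.species:
            seen.setdefault(s)
        return list(seen)

    def species_of(self, ref_index: int) -> str:
        return self.species[ref_index]


@dataclass
class DivergenceTable:
    """Minimum between-species p-distances and reliability flags."""

    species: list[str]
    min_divergence: np.ndarray  # (S, S), 0 on diagonal
    unreliable: np.ndarray  # (S, S) bool: best pair had <50% comparable sites

    def get(self, sp1: str, sp2: str) -> float:
        i, j = self.species.index(sp1), self.species.index(sp2)
        return float(self.min_divergence[i, j])


def pairwise_divergence(panel: ReferencePanel, min_comparable_frac: float = 0.5) -> DivergenceTable:
    """Species-pair minimum p-distance with pairwise deletion.

    The per-sequence-pair distance is computed over positions where both
    sequences carry unambiguous bases; the species-pair value is the
    minimum over all their sequence pairs.  Pairs whose comparable fraction
    falls below ``min_comparable_frac`` of the alignment are flagged
    unreliable.
    """
    mat = panel.matrix
    valid = mat < 4
    species = panel.species_list()
    sp_idx = {s: i for i, s in enumerate(species)}
    members: list[list[int]] = [[] for _ in species]
    for k, s in enumerate(panel.species):
        members[sp_idx[s]].append(k)
    S = len(species)
    div = np.zeros((S, S))
    unrel = np.zeros((S, S), dtype=bool)
    L = panel.length
    # sequence-level distances, blockwise
    n = panel.n
    diff = np.zeros((n, n))
    comp = np.zeros((n, n), dtype=np.int64)
    for a in range(n):
        both = valid[a][None, :] & valid  # (n, L)
        mism = both & (mat != mat[a][None, :])
        comp[a] = both.sum(axis=1)
        with np.errstate(invalid="ignore"):
            diff[a] = np.where(comp[a] > 0, mism.sum(axis=1) / np.maximum(comp[a], 1), np.nan)
    for i in range(S):
        for j in range(i + 1, S):
            pairs = [(a, b) for a in members[i] for b in members[j]]
            dists = np.array([diff[a, b] for a, b in pairs])
            comps = np.array([comp[a, b] for a, b in pairs])
            ok = ~np.isnan(dists)
            if not ok.any():
                div[i, j] = div[j, i] = np.nan
                unrel[i, j] = unrel[j, i] = True
                continue
            k = int(np.flatnonzero(ok)[np.argmin(dists[ok])])
            div[i, j] = div[j, i] = dists[k]
            if comps[k] < min_comparable_frac * L:
                unrel[i, j] = unrel[j, i] = True
    return DivergenceTable(species=species, min_divergence=div, unreliable=unrel)


def diagnostic_mask(table: DivergenceTable, threshold: float = 0.05) -> dict[tuple[str, str], bool]:
    """Per species pair: can cross-hits attest contamination?

    Non-diagnostic iff the minimum divergence is strictly below the
    threshold (a pair at exactly the threshold is diagnostic).  Self-pairs
    are non-diagnostic by construction.
    """
    mask: dict[tuple[str, str], bool] = {}
    S = len(table.species)
    for i in range(S):
        for j in range(S):
            sp = (table.species[i], table.species[j])
            if i == j:
                mask[sp] = False
            else:
                d = table.min_divergence[i, j]
                mask[sp] = bool(not np.isnan(d) and d >= threshold)
    return mask


@dataclass(frozen=True)
class ReadHit:
    ref_index: int
    species: str
    strand: str
    offset: int
    mismatches: int


def default_max_mismatch(read_length: int) -> int:
    """Mapper tolerance by read length: 1 for <= 50 bp, else 2."""
    return 1 if read_length <= 50 else 2


def map_read(
    read: str,
    panel: ReferencePanel,
    max_mismatch: int | None = None,
    rng: np.random.Generator | None = None,
) -> ReadHit | None:
    """Best ungapped placement of a read on any panel sequence.

    Scans every offset on both strands of every reference; the best hit has
    the fewest mismatches, and must have at most ``max_mismatch`` of them
    (default from read length).  Ties are broken uniformly with the
    supplied generator.  Reads shorter than 30 bases are skipped.
    """
    if len(read) < MIN_READ_LENGTH:
        return None
    if max_mismatch is None:
        max_mismatch = default_max_mismatch(len(read))
    if rng is None:
        rng = np.random.default_rng()
    hits = _candidate_hits(read, panel, max_mismatch)
    if not hits:
        return None
    best = min(h[3] for h in hits)
    tie_set = [h for h in hits if h[3] == best]
    ref, strand, offset, mm = tie_set[int(rng.integers(len(tie_set)))]
    return ReadHit(
        ref_index=ref,
        species=panel.species_of(ref),
        strand=strand,
        offset=offset,
        mismatches=mm,
    )


def _candidate_hits(
    read: str, panel: ReferencePanel, max_mismatch: int
) -> list[tuple[int, str, int, int]]:
    """All placements with mismatches <= tolerance, in deterministic order."""
    fwd = encode_sequence(read)
    rev = reverse_complement_codes(fwd)
    L = panel.length
    l = len(fwd)
    if l > L:
        return []
    mat = panel.matrix  # (n, L)
    windows = np.lib.stride_tricks.sliding_window_view(mat, l, axis=1)  # (n, W, l)
    out: list[tuple[int, str, int, int]] = []
    for strand, codes in (("+", fwd), ("-", rev)):
        ambig = codes == 4
        mism = (windows != codes[None, None, :]) | ambig[None, None, :]
        counts = mism.sum(axis=2)  # (n, W)
        ref_idx, offs = np.nonzero(counts <= max_mismatch)
        for r, o in zip(ref_idx.tolist(), offs.tolist()):
            out.append((int(r), strand, int(o), int(counts[r, o])))
    return out


@dataclass
class HitTableRow:
    """Barcode-screen accounting for one sample."""

    sample: str
    expected_species: str
    total_reads: int
    hits_per_reference: dict[int, int]
    hits_per_species: dict[str, int]
    expected_hits: int
    unexpected_hits: int
    nondiagnostic_hits: int
    expected_prevalence: float
    unexpected_prevalence: float
    unexpected_by_species: dict[str, int]
    dubious: bool
    expected_in_panel: bool

    def to_dict(self) -> dict:
        return {
            "sample": self.sample,
            "expected_species": self.expected_species,
            "total_reads": self.total_reads,
            "expected_hits": self.expected_hits,
            "unexpected_hits": self.unexpected_hits,
            "nondiagnostic_hits": self.nondiagnostic_hits,
            "expected_prevalence_per_million": self.expected_prevalence,
            "unexpected_prevalence_per_million": self.unexpected_prevalence,
            "hits_per_species": self.hits_per_species,
            "unexpected_by_species": self.unexpected_by_species,
            "dubious": self.dubious,
            "expected_in_panel": self.expected_in_panel,
        }


def screen_sample(
    reads: Sequence[str],
    panel: ReferencePanel,
    expected_species: str,
    mask: Mapping[tuple[str, str], bool],
    total_reads: int | None = None,
    sample: str = "sample",
    max_mismatch: int | None = None,
    rng: np.random.Generator | None = None,
) -> HitTableRow:
    """Screen one sample's reads and split hits into expected vs unexpected.

    ``total_reads`` is the sample's full read count used for per-million
    normalization (defaults to ``len(reads)``; pass the true library size
    when ``reads`` are pre-filtered barcode candidates).  Hits to species
    non-diagnostic with respect to the expected species are counted apart
    and never treated as contamination.  The sample is flagged dubious when
    the unexpected:expected prevalence ratio exceeds 1.
    """
    if total_reads is None:
        total_reads = len(reads)
    if total_reads == 0:
        raise ValueError("sample has zero reads")
    if rng is None:
        rng = np.random.default_rng()
    expected_in_panel = expected_species in panel.species
    if not expected_in_panel:
        logger.warning(
            "expected species %r absent from panel: all hits counted unexpected",
            expected_species,
        )
    per_ref: dict[int, int] = {}
    per_species: dict[str, int] = {}
    skipped_short = 0
    for read in reads:
        if len(read) < MIN_READ_LENGTH:
            skipped_short += 1
            continue
        hit = map_read(read, panel, max_mismatch=max_mismatch, rng=rng)
        if hit is None:
            continue
        per_ref[hit.ref_index] = per_ref.get(hit.ref_index, 0) + 1
        per_species[hit.species] = per_species.get(hit.species, 0) + 1
    if skipped_short:
        logger.info("%s: skipped %d reads shorter than %d bp", sample, skipped_short, MIN_READ_LENGTH)
    expected_hits = per_species.get(expected_species, 0)
    unexpected = 0
    nondiag = 0
    unexpected_by_species: dict[str, int] = {}
    for sp, nhits in per_species.items():
        if sp == expected_species:
            continue
        if expected_in_panel and not mask.get((expected_species, sp), False):
            nondiag += nhits
            continue
        unexpected += nhits
        unexpected_by_species[sp] = nhits
    exp_prev = expected_hits * 1e6 / total_reads
    unexp_prev = unexpected * 1e6 / total_reads
    dubious = unexpected > 0 and (expected_hits == 0 or unexp_prev / exp_prev > 1.0)
    return HitTableRow(
        sample=sample,
        expected_species=expected_species,
        total_reads=total_reads,
        hits_per_reference=per_ref,
        hits_per_species=per_species,
        expected_hits=expected_hits,
        unexpected_hits=unexpected,
        nondiagnostic_hits=nondiag,
        expected_prevalence=exp_prev,
        unexpected_prevalence=unexp_prev,
        unexpected_by_species=unexpected_by_species,
        dubious=dubious,
        expected_in_panel=expected_in_panel,
    )


@dataclass
class ContaminationMatrix:
    """Directed species x species contamination indicator.

    ``m[i, j]`` concerns contamination *of* species ``j`` (read origin,
    column) *by* species ``i`` (reference hit, row): 1 when at least
    ``min_reads`` unexpected reads from samples of j hit references of i,
    0 otherwise, and NaN (missing) for non-diagnostic pairs, self-pairs
    and columns without samples.  ``p`` is the share of ones among
    non-missing cells.
    """

    species: list[str]
    m: np.ndarray  # float with NaN for missing
    min_reads: int

    @property
    def p(self) -> float:
        defined = ~np.isnan(self.m)
        if defined.sum() == 0:
            raise ValueError("no defined cells")
        return float(np.nansum(self.m) / defined.sum())

    @property
    def n_ones(self) -> int:
        return int(np.nansum(self.m))

    @property
    def n_defined(self) -> int:
        return int((~np.isnan(self.m)).sum())

    def cell(self, contaminant: str, contaminated: str) -> float:
        i = self.species.index(contaminant)
        j = self.species.index(contaminated)
        return float(self.m[i, j])


def build_contamination_matrix(
    hit_tables: Iterable[HitTableRow],
    mask: Mapping[tuple[str, str], bool],
    min_reads: int = 1,
    species: Sequence[str] | None = None,
) -> ContaminationMatrix:
    """Aggregate unexpected hits into the directed contamination matrix.

    Rows index contaminant (reference) species, columns contaminated
    (sample) species.  Samples from species absent from the panel are
    excluded.  Species present in the panel but without samples keep their
    contaminant rows; their contaminated columns are missing.
    """
    rows = list(hit_tables)
    sampled = {r.expected_species for r in rows if r.expected_in_panel}
    if species is None:
        species_set = set(sampled)
        for key in mask:
            species_set.update(key)
        species = sorted(species_set)
    species = list(species)
    idx = {s: i for i, s in enumerate(species)}
    S = len(species)
    reads_matrix = np.zeros((S, S), dtype=np.int64)
    for r in rows:
        if not r.expected_in_panel:
            continue
        j = idx[r.expected_species]
        for contaminant, nreads in r.unexpected_by_species.items():
            if contaminant in idx:
                reads_matrix[idx[contaminant], j] += nreads
    m = np.full((S, S), np.nan)
    for i, sp_i in enumerate(species):
        for j, sp_j in enumerate(species):
            if i == j or sp_j not in sampled:
                continue
            if not mask.get((sp_i, sp_j), False):
                continue
            m[i, j] = 1.0 if reads_matrix[i, j] >= min_reads else 0.0
    return ContaminationMatrix(species=species, m=m, min_reads=min_reads)
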