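"""Seeded generators for every input the toolkit consumes.

Three generators with fully logged ground truth:

* :func:`simulate_quartet_dataset` — Hardy-Weinberg genotypes at sites with
  a neutral-like folded frequency spectrum, multinomial read counts with
  class-specific error rates, and read-level allele leakage: with
  probability gamma a read is replaced by a state drawn uniformly from the
  other individuals' realized (pre-leakage) reads, mirroring the
  read-frequency formulation of the contamination-aware genotype model.
* :func:`simulate_barcode_experiment` — a synthetic barcode panel with
  controlled pairwise divergences (including sub-threshold pairs to
  exercise the diagnostic mask), per-sample reads with sequencing errors,
  contaminant reads injected according to a metadata-linked scenario, and
  the matching metadata table.
* :func:`simulate_metadata` — laboratory covariates with lanes nested in
  flowcells nested in shipments.

All generators are deterministic given a seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .barcode import ReferencePanel
from .genotyping import error_rate_matrix
from .leakage import ErrorMatrix
from .quartets import BASES

logger = logging.getLogger(__name__)


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# quartet datasets


@dataclass
class SimulatedQuartets:
    """Quartet counts with generating truth."""

    counts: np.ndarray  # (P, N, 4)
    genotypes: np.ndarray  # (P, N, 2) allele indices, truth
    allele_freqs: np.ndarray  # (P, 4) generating population frequencies
    n_leaked: np.ndarray  # (P, N) leaked reads per quartet
    params: dict
    individuals: list[str] = field(default_factory=list)

    @property
    def n_positions(self) -> int:
        return self.counts.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.counts.shape[1]

    def true_heterozygosity(self) -> float:
        return float((self.genotypes[..., 0] != self.genotypes[..., 1]).mean())


def folded_spectrum_frequencies(
    n_positions: int,
    n_individuals: int,
    monomorphic_fraction: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Reference/alternative alleles and alt frequencies per position.

    Segregating sites draw an allele-count class i in 1..2N-1 with weight
    1/i (the standard neutral spectrum) and use p_alt = i / 2N; the rest
    are monomorphic (p_alt = 0).
    """
    two_n = 2 * n_individuals
    ref = rng.integers(0, 4, size=n_positions)
    shift = rng.integers(1, 4, size=n_positions)
    alt = (ref + shift) % 4
    i = np.arange(1, two_n)
    w = 1.0 / i
    w /= w.sum()
    counts = rng.choice(i, size=n_positions, p=w)
    p_alt = counts / two_n
    mono = rng.random(n_positions) < monomorphic_fraction
    p_alt[mono] = 0.0
    return ref, alt, p_alt


def simulate_quartet_dataset(
    n_individuals: int = 6,
    n_positions: int = 20_000,
    coverage: float = 60.0,
    eps_ts: float = 0.003,
    eps_tv: float = 0.001,
    gamma: float = 0.0,
    inbreeding_f: float = 0.0,
    monomorphic_fraction: float = 0.8,
    leak_groups: Sequence | None = None,
    seed: int | np.random.Generator = 0,
    contig: str = "contig1",
) -> SimulatedQuartets:
    """Simulate a per-individual, per-position read-count table.

    Genotypes follow Hardy-Weinberg with optional inbreeding coefficient F;
    per-quartet coverage is Poisson(``coverage``); each read either comes
    from the focal genotype with class-specific error rates (probability
    1 - gamma) or copies a uniformly chosen realized read-state of the
    other individuals (probability gamma).  ``leak_groups`` (one label per
    individual) confines leakage sources to the focal individual's group,
    emulating contamination that happens within shipment batches.
    """
    if not 0.0 <= gamma <= 1.0:
        raise ValueError("gamma must be in [0, 1]")
    if gamma > 0 and n_individuals < 2:
        raise ValueError("leakage needs at least two individuals")
    if leak_groups is not None:
        leak_groups = list(leak_groups)
        if len(leak_groups) != n_individuals:
            raise ValueError("one leak group label per individual required")
        if gamma > 0 and any(
            sum(1 for g in leak_groups if g == lab) < 2 for lab in set(leak_groups)
        ):
            raise ValueError("every leak group needs at least two members")
    rng = _rng(seed)
    P, N = n_positions, n_individuals
    ref, alt, p_alt = folded_spectrum_frequencies(P, N, monomorphic_fraction, rng)
    # genotypes under HW with inbreeding
    u = rng.random((P, N))
    p = p_alt[:, None]
    hom_alt = p * p + inbreeding_f * p * (1 - p)
    het = 2 * p * (1 - p) * (1 - inbreeding_f)
    g_alt_copies = np.select(
        [u < hom_alt, u < hom_alt + het], [2, 1], default=0
    )  # copies of alt allele
    first = np.where(g_alt_copies == 2, alt[:, None], ref[:, None])
    second = np.where(g_alt_copies >= 1, alt[:, None], ref[:, None])
    genotypes = np.stack([np.minimum(first, second), np.maximum(first, second)], axis=-1)
    E = error_rate_matrix(eps_ts, eps_tv)
    cov = rng.poisson(coverage, size=(P, N))

    def emit_from_genotype(n_reads: np.ndarray) -> np.ndarray:
        """Multinomial read counts from each quartet's own genotype."""
        y, z = genotypes[..., 0], genotypes[..., 1]
        from_first = np.where(y == z, n_reads, rng.binomial(n_reads, 0.5))
        from_second = n_reads - from_first
        reads = rng.multinomial(from_first, E[y]) + rng.multinomial(from_second, E[z])
        return reads

    base = emit_from_genotype(cov)  # realized reads without leakage
    if gamma == 0.0:
        counts = base
        n_leaked = np.zeros((P, N), dtype=np.int64)
    else:
        n_leaked = rng.binomial(cov, gamma)
        own = emit_from_genotype(cov - n_leaked)
        if leak_groups is None:
            pool = base.sum(axis=1, keepdims=True) - base  # others' realized reads
        else:
            labels = np.asarray(leak_groups)
            pool = np.empty_like(base)
            for lab in np.unique(labels):
                members = labels == lab
                group_sum = base[:, members].sum(axis=1, keepdims=True)
                pool[:, members] = group_sum - base[:, members]
        pool_tot = pool.sum(axis=2, keepdims=True)
        have_pool = pool_tot[..., 0] > 0
        pool_p = np.where(pool_tot > 0, pool / np.maximum(pool_tot, 1), 0.25)
        leaked = rng.multinomial(n_leaked, pool_p)
        # no leakage source (others fully uncovered): emit from own genotype
        if not have_pool.all():
            fallback = emit_from_genotype(np.where(have_pool, 0, n_leaked))
            leaked = np.where(have_pool[..., None], leaked, fallback)
            n_leaked = np.where(have_pool, n_leaked, 0)
        counts = own + leaked
    freqs = np.zeros((P, 4))
    freqs[np.arange(P), ref] = 1 - p_alt
    freqs[np.arange(P), alt] += p_alt
    return SimulatedQuartets(
        counts=counts.astype(np.int64),
        genotypes=genotypes,
        allele_freqs=freqs,
        n_leaked=n_leaked,
        params={
            "n_individuals": N,
            "n_positions": P,
            "coverage": coverage,
            "eps_ts": eps_ts,
            "eps_tv": eps_tv,
            "gamma": gamma,
            "inbreeding_f": inbreeding_f,
            "monomorphic_fraction": monomorphic_fraction,
            "contig": contig,
        },
        individuals=[f"ind{i + 1}" for i in range(N)],
    )


def simulate_uniform_error_homo_quartets(
    n: int = 100_000,
    base_weights: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    seed: int | np.random.Generator = 0,
) -> ErrorMatrix:
    """Homo-quartet error counts with uniform errors (calibration aid).

    Major states are drawn with ``base_weights`` and the single erroneous
    read uniformly among the three alternative bases — the random-error
    null for the error-class summary.
    """
    rng = _rng(seed)
    majors = rng.choice(4, size=n, p=np.asarray(base_weights) / np.sum(base_weights))
    h = np.zeros((4, 4), dtype=np.int64)
    for a in range(4):
        n_a = int((majors == a).sum())
        others = [b for b in range(4) if b != a]
        counts = rng.multinomial(n_a, [1 / 3] * 3)
        for b, c in zip(others, counts):
            h[a, b] = c
    totals = h.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        P = h / np.maximum(totals, 1)[:, None]
    P[totals == 0] = np.nan
    return ErrorMatrix(P=P.astype(float), h_mono=h)


# ---------------------------------------------------------------------------
# metadata


def simulate_metadata(
    n_species: int,
    n_technicians: int = 2,
    shipment_dates: Sequence[str] = ("2012-03-01", "2012-09-01"),
    flowcells_per_shipment: int = 2,
    lanes_per_flowcell: int = 2,
    samples_per_species: int = 2,
    center: str = "SC1",
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Laboratory metadata with lanes nested in flowcells nested in shipments.

    Species are assigned round-robin to shipments and, independently, to
    technicians (so the two factors are not confounded by construction);
    entry dates precede shipment dates by 10-300 days.
    """
    if min(n_species, n_technicians, flowcells_per_shipment, lanes_per_flowcell,
           samples_per_species) < 1:
        raise ValueError("all counts must be positive")
    rng = _rng(seed)
    dates = [pd.Timestamp(d) for d in shipment_dates]
    rows = []
    for s in range(n_species):
        sp = f"species{s + 1:03d}"
        ship = dates[s % len(dates)]
        tech = f"tech{(s % n_technicians) + 1}"
        for k in range(samples_per_species):
            fc_num = int(rng.integers(flowcells_per_shipment))
            flowcell = f"FC_{ship.date()}_{fc_num + 1}"
            lane = int(rng.integers(lanes_per_flowcell)) + 1
            entry = ship - pd.Timedelta(days=int(rng.integers(10, 300)))
            rows.append(
                {
                    "species": sp,
                    "individual": f"{sp}_ind{k + 1}",
                    "technician": tech,
                    "entry_date": entry,
                    "shipment_date": ship,
                    "center": center,
                    "flowcell": flowcell,
                    "lane": lane,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# barcode experiments


@dataclass
class ContaminationScenario:
    """Metadata-linked contaminant-injection rule.

    ``prevalence_by_relation`` maps a species-pair relation
    (same_shipment / same_flowcell / same_lane / same_technician) to a
    contaminant-read prevalence per million reads; a pair satisfying
    several relations uses the maximum.  ``expected_prevalence`` is the
    per-million rate of genuine barcode reads from the sample's own
    species.
    """

    expected_prevalence: float = 100.0
    prevalence_by_relation: Mapping[str, float] = field(default_factory=dict)

    def contaminant_prevalence(self, relations: Mapping[str, bool]) -> float:
        rates = [
            rate
            for rel, rate in self.prevalence_by_relation.items()
            if relations.get(rel, False)
        ]
        return max(rates) if rates else 0.0


@dataclass
class SimulatedBarcodeExperiment:
    panel: ReferencePanel
    reads: dict[str, list[str]]
    total_reads: dict[str, int]
    expected_species: dict[str, str]
    metadata: pd.DataFrame
    truth: dict


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    out = seq.copy()
    hit = rng.random(seq.size) < rate
    shift = rng.integers(1, 4, size=int(hit.sum()))
    out[hit] = (out[hit] + shift) % 4
    return out


def _codes_to_str(codes: np.ndarray) -> str:
    return "".join(BASES[int(c)] for c in codes)


def simulate_barcode_experiment(
    n_species: int = 12,
    samples_per_species: int = 2,
    total_reads_per_sample: int = 200_000,
    read_length: int = 100,
    sequencing_error: float = 0.001,
    scenario: ContaminationScenario | None = None,
    panel_length: int = 351,
    lineage_divergence: float = 0.12,
    n_close_pairs: int = 0,
    close_pair_divergence: float = 0.02,
    metadata_kwargs: Mapping | None = None,
    seed: int | np.random.Generator = 0,
) -> SimulatedBarcodeExperiment:
    """Barcode panel, per-sample reads, metadata and truth, all seeded.

    ``n_close_pairs`` species are generated as near duplicates (divergence
    ``close_pair_divergence``, below the 5% default mask threshold) of
    another species to exercise the non-diagnostic masking; the remaining
    lineages mutate independently from a common ancestor at rate
    ``lineage_divergence`` and end up well above the threshold.
    Contaminant reads are injected between species according to the
    scenario's metadata relations; every read (genuine or contaminant) is
    a uniformly placed substring of the source barcode, random strand,
    with per-base sequencing errors.
    """
    if n_close_pairs * 2 > n_species:
        raise ValueError("too many close pairs for n_species")
    if scenario is None:
        scenario = ContaminationScenario()
    rng = _rng(seed)
    ancestor = rng.integers(0, 4, size=panel_length)
    n_lineages = n_species - n_close_pairs
    lineages = [_mutate(ancestor, lineage_divergence, rng) for _ in range(n_lineages)]
    seqs = list(lineages)
    for k in range(n_close_pairs):
        seqs.append(_mutate(lineages[k], close_pair_divergence, rng))
    species = [f"species{s + 1:03d}" for s in range(n_species)]
    panel = ReferencePanel(
        ids=[f"ref_{sp}" for sp in species],
        species=species,
        components=["target"] * n_species,
        sequences=[_codes_to_str(s) for s in seqs],
    )
    meta = simulate_metadata(
        n_species,
        samples_per_species=samples_per_species,
        seed=rng,
        **(metadata_kwargs or {}),
    )
    # species-level relations from the metadata
    by_sp = {}
    for sp, grp in meta.groupby("species"):
        by_sp[sp] = {
            "shipments": set(zip(grp["shipment_date"], grp["center"])),
            "technicians": set(grp["technician"]),
            "flowcells": set(grp["flowcell"]),
            "lanes": set(zip(grp["flowcell"], grp["lane"])),
        }

    def relations(sp1: str, sp2: str) -> dict[str, bool]:
        a, b = by_sp[sp1], by_sp[sp2]
        return {
            "same_shipment": bool(a["shipments"] & b["shipments"]),
            "same_technician": bool(a["technicians"] & b["technicians"]),
            "same_flowcell": bool(a["flowcells"] & b["flowcells"]),
            "same_lane": bool(a["lanes"] & b["lanes"]),
        }

    seq_by_species = {sp: seqs[i] for i, sp in enumerate(species)}

    def draw_reads(source_sp: str, n: int) -> list[str]:
        src = seq_by_species[source_sp]
        out = []
        max_off = panel_length - read_length
        for _ in range(n):
            off = int(rng.integers(max_off + 1))
            codes = src[off : off + read_length].copy()
            err = rng.random(read_length) < sequencing_error
            shift = rng.integers(1, 4, size=int(err.sum()))
            codes[err] = (codes[err] + shift) % 4
            if rng.random() < 0.5:
                codes = (3 - codes)[::-1]  # reverse complement in code space
            out.append(_codes_to_str(codes))
        return out

    reads: dict[str, list[str]] = {}
    total_reads: dict[str, int] = {}
    expected: dict[str, str] = {}
    injected: dict[str, dict[str, int]] = {}
    for _, row in meta.iterrows():
        sample = row["individual"]
        sp = row["species"]
        expected[sample] = sp
        total_reads[sample] = total_reads_per_sample
        n_own = rng.poisson(scenario.expected_prevalence * total_reads_per_sample / 1e6)
        sample_reads = draw_reads(sp, n_own)
        injected[sample] = {}
        for other in species:
            if other == sp:
                continue
            prev = scenario.contaminant_prevalence(relations(sp, other))
            if prev <= 0:
                continue
            n_c = rng.poisson(prev * total_reads_per_sample / 1e6)
            if n_c:
                sample_reads.extend(draw_reads(other, n_c))
                injected[sample][other] = n_c
        perm = rng.permutation(len(sample_reads))
        reads[sample] = [sample_reads[i] for i in perm]
    truth = {
        "injected_reads": injected,
        "scenario": {
            "expected_prevalence": scenario.expected_prevalence,
            "prevalence_by_relation": dict(scenario.prevalence_by_relation),
        },
        "n_species": n_species,
    }
    return SimulatedBarcodeExperiment(
        panel=panel,
        reads=reads,
        total_reads=total_reads,
        expected_species=expected,
        metadata=meta,
        truth=truth,
    )
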