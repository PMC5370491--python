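"""Allele-leakage indices from homo-quartets.

The logic: in a contamination-free sample, the identity of the single
erroneous read in a homo-quartet is independent of what other individuals
carry.  The 4x4 error matrix **P** — minor-state prevalence given the major
state — is therefore estimated from homo-quartets at monoallelic positions,

    P(a, b) = h_mono(a, b) / sum_k h_mono(a, k),

and used to predict how often, at biallelic positions, the minor state
should coincide with the other segregating allele z:

    q_obs = sum_k r_z(k) / h_bi          (observed coincidence fraction)
    q_exp = sum_k P(a_k, z_k) / sum_k sum_i P(a_k, i)
          = mean_k P(a_k, z_k)           (rows of P sum to 1)

The allele-leakage index is the relative excess

    lambda = (q_obs - q_exp) / q_exp,

zero in expectation without contamination and positive when reads leak
between individuals.  ``lambda_between_groups`` computes the variant
lambda' restricted to leakage *between* groups of individuals (e.g.
shipment batches): only homo-quartets at positions biallelic in the whole
sample but monoallelic within the focal individual's group are counted, so
that the coinciding minor allele can only have come from outside the group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .quartets import (
    BASES,
    BASE_INDEX,
    BIALLELIC,
    MONOALLELIC,
    HomoQuartetRecord,
    SiteColumn,
    extract_homo_quartets,
    rank_states,
)

logger = logging.getLogger(__name__)

#: Strand-pooled error classes (read direction is unknown, so X->Y and its
#: reverse-complement X*->Y* are indistinguishable and pooled).
STRAND_CLASSES: dict[str, tuple[tuple[str, str], tuple[str, str]]] = {
    "A>G|T>C": (("A", "G"), ("T", "C")),  # transition
    "G>A|C>T": (("G", "A"), ("C", "T")),  # transition
    "A>C|T>G": (("A", "C"), ("T", "G")),  # transversion (Illumina-biased)
    "C>A|G>T": (("C", "A"), ("G", "T")),  # transversion
    "A>T|T>A": (("A", "T"), ("T", "A")),  # transversion
    "C>G|G>C": (("C", "G"), ("G", "C")),  # transversion
}
TRANSITION_CLASSES = ("A>G|T>C", "G>A|C>T")
TRANSVERSION_CLASSES = ("A>C|T>G", "C>A|G>T", "A>T|T>A", "C>G|G>C")

TRANSITION_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}


class UndefinedStatisticError(ValueError):
    """A leakage statistic has no defined value (e.g. no qualifying data)."""


@dataclass
class ErrorMatrix:
    """Row-normalized minor-state prevalence given the major state.

    ``P[a, b]`` is the probability that a homo-quartet with major state
    ``a`` carries minor state ``b``; rows with zero homo-quartets are NaN.
    ``h_mono`` holds the integer counts behind each cell.
    """

    P: np.ndarray
    h_mono: np.ndarray

    @property
    def row_totals(self) -> np.ndarray:
        return self.h_mono.sum(axis=1)

    def defined_rows(self) -> np.ndarray:
        return self.row_totals > 0

    def to_dict(self) -> dict:
        return {
            "bases": BASES,
            "P": [[None if np.isnan(v) else float(v) for v in row] for row in self.P],
            "h_mono": self.h_mono.astype(int).tolist(),
        }


@dataclass
class LeakageResult:
    """Per-species (or pooled) allele-leakage summary."""

    h_bi: int
    q_obs: float
    q_exp: float
    lam: float
    n_skipped_undefined_row: int = 0
    per_species: dict[str, dict] = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {
            "h_bi": self.h_bi,
            "q_obs": self.q_obs,
            "q_exp": self.q_exp,
            "lambda": self.lam,
        }
        if self.per_species:
            out["per_species"] = self.per_species
        return out


def error_matrix(records: Iterable[HomoQuartetRecord]) -> ErrorMatrix:
    """Estimate **P** from homo-quartets at monoallelic positions."""
    h = np.zeros((4, 4), dtype=np.int64)
    for rec in records:
        if rec.position_class != MONOALLELIC:
            continue
        h[BASE_INDEX[rec.major], BASE_INDEX[rec.minor]] += 1
    totals = h.sum(axis=1)
    if (totals == 0).all():
        raise UndefinedStatisticError("no monoallelic homo-quartets: error matrix undefined")
    with np.errstate(invalid="ignore", divide="ignore"):
        P = h / totals[:, None]
    P[totals == 0] = np.nan
    return ErrorMatrix(P=P, h_mono=h)


def q_observed(records: Iterable[HomoQuartetRecord]) -> float:
    """Fraction of biallelic-position homo-quartets whose minor state is z."""
    hits = h_bi = 0
    for rec in records:
        if rec.position_class != BIALLELIC:
            continue
        h_bi += 1
        hits += rec.r_z  # type: ignore[operator]
    if h_bi == 0:
        raise UndefinedStatisticError("no biallelic homo-quartets: q_obs undefined")
    return hits / h_bi


def q_expected(
    records: Iterable[HomoQuartetRecord], P: ErrorMatrix
) -> tuple[float, int]:
    """Expected coincidence fraction under the error matrix alone.

    Returns ``(q_exp, n_skipped)``; records whose major state has an
    undefined row in **P** are dropped from numerator and denominator.
    Because each defined row of **P** sums to 1, the double-sum denominator
    equals the number of retained records, so q_exp is the mean of
    ``P(a, z)`` over them.
    """
    num = 0.0
    denom = 0.0
    skipped = 0
    defined = P.defined_rows()
    for rec in records:
        if rec.position_class != BIALLELIC:
            continue
        a = BASE_INDEX[rec.major]
        if not defined[a]:
            skipped += 1
            continue
        z = BASE_INDEX[rec.z]  # type: ignore[arg-type]
        num += P.P[a, z]
        denom += np.nansum(P.P[a])
    if denom == 0:
        raise UndefinedStatisticError("no scorable biallelic homo-quartets: q_exp undefined")
    if skipped:
        logger.info("q_expected: skipped %d records with undefined P row", skipped)
    return num / denom, skipped


def lambda_index(q_obs: float, q_exp: float) -> float:
    """Relative excess of observed over expected allele coincidence."""
    if q_exp <= 0:
        raise UndefinedStatisticError("q_exp must be positive for lambda")
    return (q_obs - q_exp) / q_exp


def leakage_result(
    records: Sequence[HomoQuartetRecord], P: ErrorMatrix | None = None
) -> LeakageResult:
    """Convenience wrapper: **P**, q_obs, q_exp and lambda in one call."""
    if P is None:
        P = error_matrix(records)
    bi = [r for r in records if r.position_class == BIALLELIC]
    q_obs = q_observed(bi)
    q_exp, skipped = q_expected(bi, P)
    return LeakageResult(
        h_bi=len(bi),
        q_obs=q_obs,
        q_exp=q_exp,
        lam=lambda_index(q_obs, q_exp),
        n_skipped_undefined_row=skipped,
    )


def species_leakage(
    columns_by_species: Mapping[str, Sequence[SiteColumn]],
    min_h_bi: int = 50,
    **extract_kwargs,
) -> dict[str, LeakageResult]:
    """Per-species lambda, reported only where h_bi >= ``min_h_bi``."""
    out: dict[str, LeakageResult] = {}
    for species, cols in columns_by_species.items():
        records = extract_homo_quartets(cols, **extract_kwargs)
        try:
            res = leakage_result(records)
        except UndefinedStatisticError:
            continue
        if res.h_bi >= min_h_bi:
            out[species] = res
    return out


def lambda_between_groups(
    columns_by_species: Mapping[str, Sequence[SiteColumn]],
    groups: Mapping[str, str],
    error_matrices: Mapping[str, ErrorMatrix] | None = None,
    major_threshold: int = 40,
    major_frac: float = 0.95,
    biallelic_factor: int = 10,
) -> LeakageResult:
    """Allele leakage between groups (lambda').

    ``groups`` maps individual id to a group label (e.g. shipment date).
    Only homo-quartets at positions biallelic across the whole species
    sample but monoallelic (same ``major_frac`` rule, applied to the
    group-restricted totals) within the focal individual's group are
    retained.  Numerators and denominators of q_obs / q_exp are pooled
    across species, each record scored against its species' **P**.
    """
    if error_matrices is None:
        error_matrices = {}
        for species, cols in columns_by_species.items():
            recs = extract_homo_quartets(
                cols,
                major_threshold=major_threshold,
                major_frac=major_frac,
                biallelic_factor=biallelic_factor,
            )
            try:
                error_matrices[species] = error_matrix(recs)
            except UndefinedStatisticError:
                logger.warning("species %s has no defined error matrix; skipped", species)
    obs_num = 0
    exp_num = 0.0
    exp_denom = 0.0
    h = 0
    per_species: dict[str, dict] = {}
    for species, cols in columns_by_species.items():
        if species not in error_matrices:
            continue
        P = error_matrices[species]
        defined = P.defined_rows()
        sp_h = sp_obs = 0
        records = extract_homo_quartets(
            cols,
            major_threshold=major_threshold,
            major_frac=major_frac,
            biallelic_factor=biallelic_factor,
        )
        by_pos = {(c.contig, c.position): c for c in cols}
        for rec in records:
            if rec.position_class != BIALLELIC:
                continue
            col = by_pos[(rec.contig, rec.position)]
            focal_group = groups[rec.individual]
            member_idx = [
                i for i, ind in enumerate(col.individuals) if groups[ind] == focal_group
            ]
            sub = col.counts[member_idx].sum(axis=0)
            if sub.sum() == 0:
                continue
            first, _, _ = rank_states(sub)
            if not sub[first] > major_frac * sub.sum():
                continue  # group not monoallelic: within-group leakage possible
            a = BASE_INDEX[rec.major]
            if not defined[a]:
                continue
            z = BASE_INDEX[rec.z]  # type: ignore[arg-type]
            h += 1
            sp_h += 1
            obs_num += rec.r_z  # type: ignore[operator]
            sp_obs += rec.r_z  # type: ignore[operator]
            exp_num += P.P[a, z]
            exp_denom += np.nansum(P.P[a])
        if sp_h:
            per_species[species] = {"h": sp_h, "obs": sp_obs}
    if h == 0 or exp_denom == 0:
        raise UndefinedStatisticError("no qualifying homo-quartets for lambda'")
    q_obs = obs_num / h
    q_exp = exp_num / exp_denom
    return LeakageResult(
        h_bi=h,
        q_obs=q_obs,
        q_exp=q_exp,
        lam=lambda_index(q_obs, q_exp),
        per_species=per_species,
    )


@dataclass
class ErrorClassSummary:
    """Strand-pooled error-class counts and composition-corrected ratios.

    ``ts_tv_ratio`` is the observed transition:transversion error-count
    ratio divided by its expectation under the observed major-state base
    composition, rescaled so that random (uniform) errors give 0.5 — the
    classical "1 transition vs 2 transversions per state" baseline.  Since
    every base has exactly one transition and two transversion partners,
    the composition term cancels and the statistic equals the raw count
    ratio.  ``ac_tg_enrichment`` is the share of the A>C|T>G class among
    transversions divided by its composition expectation (random errors
    give 1.0); ``ac_tg_vs_other_tv`` is the corresponding corrected count
    ratio on a "random = 1/3" scale.
    """

    class_counts: dict[str, int]
    ts_count: int
    tv_count: int
    ts_tv_ratio: float
    ac_tg_enrichment: float
    ac_tg_vs_other_tv: float

    def to_dict(self) -> dict:
        return {
            "class_counts": self.class_counts,
            "ts_count": self.ts_count,
            "tv_count": self.tv_count,
            "ts_tv_ratio": self.ts_tv_ratio,
            "ac_tg_enrichment": self.ac_tg_enrichment,
            "ac_tg_vs_other_tv": self.ac_tg_vs_other_tv,
        }


def error_class_summary(em: ErrorMatrix) -> ErrorClassSummary:
    """Pool complementary error classes and correct ratios for composition.

    Expected class weights under random error are proportional to the
    major-state composition observed among monoallelic homo-quartets, with
    each of a state's three alternative bases equally likely.
    """
    h = em.h_mono
    class_counts = {
        name: int(h[BASE_INDEX[a1], BASE_INDEX[b1]] + h[BASE_INDEX[a2], BASE_INDEX[b2]])
        for name, ((a1, b1), (a2, b2)) in STRAND_CLASSES.items()
    }
    ts = sum(class_counts[c] for c in TRANSITION_CLASSES)
    tv = sum(class_counts[c] for c in TRANSVERSION_CLASSES)
    # composition of major states among homo-quartets
    comp = em.row_totals.astype(float)
    total = comp.sum()
    if total == 0:
        raise UndefinedStatisticError("empty error matrix")
    # expected counts under uniform error: 1 ts and 2 tv alternatives per state
    exp_ts = total / 3.0
    exp_tv = 2.0 * total / 3.0
    if tv == 0:
        ts_tv = np.inf
        logger.warning("zero transversion errors: ts/tv ratio infinite")
    else:
        # (obs_ts/exp_ts)/(obs_tv/exp_tv) * 0.5: random error -> 0.5
        ts_tv = (ts / exp_ts) / (tv / exp_tv) * 0.5
    # A>C|T>G vs other transversions, composition-corrected
    obs_class = class_counts["A>C|T>G"]
    obs_other = tv - obs_class
    exp_class = (comp[BASE_INDEX["A"]] + comp[BASE_INDEX["T"]]) / 3.0
    exp_other = exp_tv - exp_class
    if obs_other == 0 or exp_class == 0 or exp_other == 0:
        enrichment = np.inf if obs_class > 0 else np.nan
        corrected_ratio = np.inf if obs_class > 0 else np.nan
    else:
        enrichment = (obs_class / exp_class) / (obs_other / exp_other)
        corrected_ratio = enrichment / 3.0  # random = 1/3 scale
    return ErrorClassSummary(
        class_counts=class_counts,
        ts_count=ts,
        tv_count=tv,
        ts_tv_ratio=float(ts_tv),
        ac_tg_enrichment=float(enrichment),
        ac_tg_vs_other_tv=float(corrected_ratio),
    )
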