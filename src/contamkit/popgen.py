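"""Population-genomic summary statistics from called genotypes.

Implements the standard estimators used to gauge the impact of
contamination-aware calling: per-site nucleotide diversity (unbiased
heterozygosity), Nei-Gojobori fractional synonymous/non-synonymous site
counts under the standard genetic code, pi_S and pi_N as ratios of sums,
the inbreeding/total-fixation index F_IT, and Tajima's D.

Conventions: pi and F_IT pool sites as ratio-of-sums (stable with few
SNPs); sites use their own number of called allele copies m
(pairwise-complete treatment of missing genotypes); Tajima's D uses the
median per-site m for its constants.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

from .quartets import BASES

logger = logging.getLogger(__name__)

_CODON_TABLE = standard_dna_table.forward_table  # codon -> amino acid
_STOPS = set(standard_dna_table.stop_codons)


class UndefinedStatisticError(ValueError):
    """A summary statistic has no defined value on the given data."""


def translate_codon(codon: str) -> str:
    codon = codon.upper()
    if codon in _STOPS:
        return "*"
    return _CODON_TABLE[codon]


def site_pi(genotypes: Iterable[tuple[int, int] | None]) -> float:
    """Unbiased per-site nucleotide diversity from diploid genotypes.

    ``genotypes`` holds allele-index pairs, None/negative for missing.
    pi = m/(m-1) * (1 - sum p_i^2) with m the number of called allele
    copies; equals the mean pairwise difference between allele copies.
    """
    alleles: list[int] = []
    for g in genotypes:
        if g is None:
            continue
        a, b = g
        if a < 0 or b < 0:
            continue
        alleles.extend((int(a), int(b)))
    m = len(alleles)
    if m < 2:
        raise UndefinedStatisticError("need >= 2 called allele copies")
    counts = np.bincount(alleles, minlength=4)
    p = counts / m
    return float(m / (m - 1) * (1.0 - (p**2).sum()))


def count_syn_nonsyn_sites(sequence: str, on_stop: str = "raise") -> tuple[float, float]:
    """Nei-Gojobori fractional synonymous/non-synonymous site counts.

    The in-frame coding ``sequence`` must have length a multiple of 3 and,
    by default, carry no stop codons (``on_stop='skip'`` drops them
    instead, for synthetic references).  For each codon position the
    synonymous fraction is the share of the three possible single-base
    changes that preserve the amino acid; changes creating stops count as
    non-synonymous.  Codons containing ambiguous bases are skipped
    (logged).  S + N = 3 for every counted codon.
    """
    sequence = sequence.upper()
    if len(sequence) % 3:
        raise ValueError("sequence length must be a multiple of 3")
    L_S = L_N = 0.0
    skipped = 0
    for i in range(0, len(sequence), 3):
        codon = sequence[i : i + 3]
        if any(b not in BASES for b in codon):
            skipped += 1
            continue
        if codon in _STOPS:
            if on_stop == "skip":
                skipped += 1
                continue
            raise ValueError(f"stop codon {codon} at {i}: stops must be excluded")
        aa = translate_codon(codon)
        for pos in range(3):
            syn = 0
            for b in BASES:
                if b == codon[pos]:
                    continue
                mut = codon[:pos] + b + codon[pos + 1 :]
                if mut not in _STOPS and translate_codon(mut) == aa:
                    syn += 1
            L_S += syn / 3.0
            L_N += (3 - syn) / 3.0
    if skipped:
        logger.info("count_syn_nonsyn_sites: skipped %d ambiguous codons", skipped)
    return L_S, L_N


def classify_snp_effect(
    codon: str, position_in_codon: int, alleles: tuple[str, str]
) -> str:
    """'synonymous' or 'non-synonymous' for a biallelic change in a codon.

    ``codon`` is the reference codon; the two alleles replace the base at
    ``position_in_codon`` (0-based).  Changes involving a stop codon are
    non-synonymous (flagged via logging).
    """
    codon = codon.upper()
    variants = []
    for allele in alleles:
        mut = codon[:position_in_codon] + allele.upper() + codon[position_in_codon + 1 :]
        variants.append(mut)
    if any(v in _STOPS for v in variants):
        logger.info("SNP creates/destroys a stop codon (%s): non-synonymous", variants)
        return "non-synonymous"
    aa = {translate_codon(v) for v in variants}
    return "synonymous" if len(aa) == 1 else "non-synonymous"


def f_it(
    genotypes_per_site: Sequence[Sequence[tuple[int, int] | None]],
) -> float:
    """Excess of individual homozygosity over Hardy-Weinberg expectation.

    F_IT = 1 - sum(H_obs) / sum(H_exp) across SNPs (ratio of sums), with
    H_obs the fraction of heterozygous called individuals and H_exp the
    unbiased expected heterozygosity at each site.
    """
    sum_obs = sum_exp = 0.0
    used = 0
    for site in genotypes_per_site:
        called = [g for g in site if g is not None and g[0] >= 0 and g[1] >= 0]
        if len(called) < 2:
            continue
        m = 2 * len(called)
        alleles = np.bincount([a for g in called for a in g], minlength=4)
        p = alleles / m
        h_exp = m / (m - 1) * (1.0 - (p**2).sum())
        h_obs = sum(1 for a, b in called if a != b) / len(called)
        sum_obs += h_obs
        sum_exp += h_exp
        used += 1
    if used == 0 or sum_exp == 0:
        raise UndefinedStatisticError("F_IT undefined: no polymorphic sites with data")
    return float(1.0 - sum_obs / sum_exp)


def tajima_constants(m: int) -> dict[str, float]:
    """Canonical a1, a2, b1, b2, c1, c2, e1, e2 for m sequences."""
    if m < 2:
        raise ValueError("need m >= 2 sequences")
    a1 = sum(1.0 / i for i in range(1, m))
    a2 = sum(1.0 / i**2 for i in range(1, m))
    b1 = (m + 1) / (3.0 * (m - 1))
    b2 = 2.0 * (m**2 + m + 3) / (9.0 * m * (m - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (m + 2) / (a1 * m) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajimas_d(pi_total: float, n_segregating: int, m: int) -> float:
    """Tajima's D from total pairwise diversity, S and m allele copies.

    ``pi_total`` is the sum over segregating sites of mean pairwise
    differences (i.e. the sum of per-site unbiased heterozygosities).
    """
    if n_segregating < 1:
        raise UndefinedStatisticError("Tajima's D undefined with S = 0")
    if m < 4:
        raise UndefinedStatisticError("need >= 4 allele copies")
    k = tajima_constants(m)
    theta_w = n_segregating / k["a1"]
    var = k["e1"] * n_segregating + k["e2"] * n_segregating * (n_segregating - 1)
    if var <= 0:
        raise UndefinedStatisticError("zero variance in Tajima's D")
    return float((pi_total - theta_w) / np.sqrt(var))


def tajimas_d_from_genotypes(
    genotypes_per_site: Sequence[Sequence[tuple[int, int] | None]],
) -> float:
    """Tajima's D over segregating sites; m = median called copies."""
    pis = []
    ms = []
    for site in genotypes_per_site:
        called = [g for g in site if g is not None and g[0] >= 0 and g[1] >= 0]
        if len(called) < 2:
            continue
        alleles = [a for g in called for a in g]
        if len(set(alleles)) < 2:
            continue
        pis.append(site_pi(called))
        ms.append(2 * len(called))
    if not pis:
        raise UndefinedStatisticError("no segregating sites")
    m = int(np.median(ms))
    return tajimas_d(float(np.sum(pis)), len(pis), m)


@dataclass
class PopgenSummary:
    """One-species summary of diversity and frequency-spectrum statistics."""

    n_snps: int
    pi_S: float
    pi_N: float
    pi_N_over_pi_S: float
    F_IT: float
    tajimas_D_syn: float
    tajimas_D_nonsyn: float
    L_S: float
    L_N: float

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "n_snps", "pi_S", "pi_N", "pi_N_over_pi_S", "F_IT",
            "tajimas_D_syn", "tajimas_D_nonsyn", "L_S", "L_N",
        )}


def diversity_summary(
    calls: np.ndarray,
    coding_sequence: str,
    frame_offset: int = 0,
) -> PopgenSummary:
    """Full summary from a (P, N, 2) genotype-call array over a coding region.

    ``calls`` holds allele indices with -1 for no-call, one row per position
    of ``coding_sequence`` starting at ``frame_offset`` (position
    ``frame_offset`` is the first base of the first codon).  SNPs are
    classified synonymous/non-synonymous against the reference codon built
    from the coding sequence; tri-allelic sites are classified per allele
    pair against the major allele and flagged.
    """
    calls = np.asarray(calls)
    P = calls.shape[0]
    usable = coding_sequence[frame_offset : frame_offset + 3 * ((len(coding_sequence) - frame_offset) // 3)]
    L_S, L_N = count_syn_nonsyn_sites(usable, on_stop="skip")
    if L_S == 0:
        raise UndefinedStatisticError("no synonymous sites")
    stop_codon_starts = {
        frame_offset + i
        for i in range(0, len(usable), 3)
        if usable[i : i + 3].upper() in _STOPS
    }
    syn_sites: list[list[tuple[int, int]]] = []
    nonsyn_sites: list[list[tuple[int, int]]] = []
    all_snp_sites: list[list[tuple[int, int]]] = []
    n_snps = 0
    for p in range(P):
        site = [tuple(g) for g in calls[p] if g[0] >= 0 and g[1] >= 0]
        if len(site) < 2:
            continue
        alleles = sorted({a for g in site for a in g})
        if len(alleles) < 2:
            continue
        n_snps += 1
        all_snp_sites.append(site)
        # codon context
        rel = p - frame_offset
        if rel < 0 or rel >= len(usable):
            continue
        codon_start = frame_offset + 3 * (rel // 3)
        if codon_start in stop_codon_starts:
            continue  # codon excluded from L_S/L_N, so its SNPs are too
        codon = coding_sequence[codon_start : codon_start + 3]
        pos_in_codon = rel % 3
        counts = np.bincount([a for g in site for a in g], minlength=4)
        major = int(counts.argmax())
        if len(alleles) > 2:
            logger.info("tri-allelic site at %d: classifying against major allele", p)
        effects = set()
        for a in alleles:
            if a == major:
                continue
            effects.add(
                classify_snp_effect(codon, pos_in_codon, (BASES[major], BASES[a]))
            )
        effect = "non-synonymous" if "non-synonymous" in effects else "synonymous"
        (syn_sites if effect == "synonymous" else nonsyn_sites).append(site)
    pi_S = float(np.sum([site_pi(s) for s in syn_sites])) / L_S if L_S else np.nan
    pi_N = float(np.sum([site_pi(s) for s in nonsyn_sites])) / L_N if L_N else np.nan
    try:
        ratio = pi_N / pi_S if pi_S > 0 else np.nan
    except ZeroDivisionError:  # pragma: no cover
        ratio = np.nan
    try:
        fit = f_it(all_snp_sites)
    except UndefinedStatisticError:
        fit = np.nan
    def _d(sites):
        try:
            return tajimas_d_from_genotypes(sites)
        except UndefinedStatisticError:
            return np.nan
    return PopgenSummary(
        n_snps=n_snps,
        pi_S=pi_S,
        pi_N=pi_N,
        pi_N_over_pi_S=ratio,
        F_IT=fit,
        tajimas_D_syn=_d(syn_sites),
        tajimas_D_nonsyn=_d(nonsyn_sites),
        L_S=L_S,
        L_N=L_N,
    )
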