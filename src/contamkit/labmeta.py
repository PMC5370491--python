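"""Linking contamination to laboratory metadata.

From per-sample metadata (species, technician, entry/shipment dates,
sequencing center, flowcell, lane) five species-pair predictors are
derived: ``lab_overlap`` (days of intersection of the two species'
laboratory processing periods), ``same_technician``, ``same_shipment``
(same day to the same center), ``same_flowcell`` and ``same_lane``.
Nested by construction: same_lane => same_flowcell => same_shipment.

The observed statistic for a predictor is its mean over contaminated cells
of the contamination matrix M.  Null distributions come from cellwise
Bernoulli randomizations of M — unconditional (probability p, the overall
contamination proportion) or conditional on one or more predictors
(stratum-specific probabilities) — always leaving missing cells missing.
Two synthetic factors summarize the laboratory (LAB: same technician with
long overlap) and the sequencing center (CENTER tiers: same shipment /
flowcell / lane, reported cumulatively).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .barcode import ContaminationMatrix

logger = logging.getLogger(__name__)

METADATA_COLUMNS = [
    "species",
    "individual",
    "technician",
    "entry_date",
    "shipment_date",
    "center",
    "flowcell",
    "lane",
]

PREDICTORS = ["lab_overlap", "same_technician", "same_shipment", "same_flowcell", "same_lane"]

CENTER_TIERS = ["CENTER-", "CENTER+", "CENTER++", "CENTER+++"]


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    """Coerce dtypes and check invariants (entry <= shipment, lane => flowcell)."""
    meta = meta.copy()
    for col in ("entry_date", "shipment_date"):
        meta[col] = pd.to_datetime(meta[col])
    if (meta["entry_date"] > meta["shipment_date"]).any():
        raise ValueError("entry date after shipment date")
    has_lane = meta["lane"].notna()
    if (has_lane & meta["flowcell"].isna()).any():
        raise ValueError("lane given without flowcell")
    return meta


def _technicians(cell) -> set[str]:
    if pd.isna(cell):
        return set()
    return {t.strip() for t in str(cell).split(";") if t.strip()}


def pair_predictors(
    meta: pd.DataFrame,
    lab_overlap_days: int = 200,
    lab_overlap_greater: bool = True,
) -> pd.DataFrame:
    """Species-pair predictor table (unordered pairs, sp1 < sp2).

    The processing period of a species runs from its first entry date to
    its last shipment date.  LAB is positive when the pair shares a
    technician and lab_overlap exceeds ``lab_overlap_days``
    (``lab_overlap_greater=False`` flips the direction of the overlap
    condition).  same_flowcell/same_lane are NA when either species lacks
    flowcell/lane information for some sample; the CENTER tier is NA then
    too unless resolvable.
    """
    meta = validate_metadata(meta)
    by_sp = {}
    for sp, grp in meta.groupby("species"):
        techs = set()
        for cell in grp["technician"]:
            techs |= _technicians(cell)
        by_sp[sp] = {
            "start": grp["entry_date"].min(),
            "end": grp["shipment_date"].max(),
            "technicians": techs,
            "shipments": set(zip(grp["shipment_date"], grp["center"])),
            "flowcells": set(grp["flowcell"].dropna()),
            "lanes": set(
                zip(grp["flowcell"].dropna(), grp.loc[grp["flowcell"].notna(), "lane"])
            ),
            "flowcell_complete": bool(grp["flowcell"].notna().all()),
            "lane_complete": bool(grp["lane"].notna().all()),
        }
    rows = []
    species = sorted(by_sp)
    for i, sp1 in enumerate(species):
        for sp2 in species[i + 1 :]:
            a, b = by_sp[sp1], by_sp[sp2]
            overlap = (min(a["end"], b["end"]) - max(a["start"], b["start"])).days
            overlap = max(0, overlap)
            same_tech = bool(a["technicians"] & b["technicians"])
            same_ship = bool(a["shipments"] & b["shipments"])
            complete = (
                a["flowcell_complete"]
                and b["flowcell_complete"]
                and a["lane_complete"]
                and b["lane_complete"]
            )
            same_fc = bool(a["flowcells"] & b["flowcells"]) if complete else np.nan
            same_lane = bool(a["lanes"] & b["lanes"]) if complete else np.nan
            overlap_ok = (
                overlap > lab_overlap_days if lab_overlap_greater else overlap < lab_overlap_days
            )
            lab = same_tech and overlap_ok
            if not same_ship:
                center = "CENTER-"
            elif complete:
                if same_lane:
                    center = "CENTER+++"
                elif same_fc:
                    center = "CENTER++"
                else:
                    center = "CENTER+"
            else:
                center = np.nan
            rows.append(
                {
                    "sp1": sp1,
                    "sp2": sp2,
                    "lab_overlap": overlap,
                    "same_technician": same_tech,
                    "same_shipment": same_ship,
                    "same_flowcell": same_fc,
                    "same_lane": same_lane,
                    "LAB": lab,
                    "CENTER": center,
                    "info_complete": complete,
                }
            )
    return pd.DataFrame(rows).set_index(["sp1", "sp2"])


def _pair_value_matrix(M: ContaminationMatrix, preds: pd.DataFrame, predictor: str) -> np.ndarray:
    """Per-directed-cell predictor values (symmetric; NaN where undefined)."""
    S = len(M.species)
    vals = np.full((S, S), np.nan)
    idx = {s: i for i, s in enumerate(M.species)}
    for (sp1, sp2), row in preds.iterrows():
        if sp1 not in idx or sp2 not in idx:
            continue
        v = row[predictor]
        if isinstance(v, (bool, np.bool_)):
            v = float(v)
        i, j = idx[sp1], idx[sp2]
        vals[i, j] = vals[j, i] = v
    return vals


def observed_statistic(
    M: ContaminationMatrix, preds: pd.DataFrame, predictor: str
) -> float:
    """Mean predictor value over contaminated (== 1) non-missing cells."""
    vals = _pair_value_matrix(M, preds, predictor)
    ones = (M.m == 1.0) & ~np.isnan(vals)
    if ones.sum() == 0:
        raise ValueError("no contaminated pairs: statistic undefined")
    return float(vals[ones].mean())


def _statistic_on(matrix: np.ndarray, vals: np.ndarray) -> float:
    ones = (matrix == 1.0) & ~np.isnan(vals)
    if ones.sum() == 0:
        return np.nan
    return float(vals[ones].mean())


def randomize_unconditional(
    M: ContaminationMatrix,
    preds: pd.DataFrame,
    predictor: str,
    reps: int = 1000,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Null distribution of the statistic under cellwise Bernoulli(p).

    Every non-missing cell of a replicate matrix is independently one with
    probability p (the observed contamination proportion); missing cells
    stay missing.
    """
    if rng is None:
        rng = np.random.default_rng()
    p = M.p
    vals = _pair_value_matrix(M, preds, predictor)
    defined = ~np.isnan(M.m)
    out = np.empty(reps)
    for k in range(reps):
        repl = np.full(M.m.shape, np.nan)
        repl[defined] = (rng.random(int(defined.sum())) < p).astype(float)
        out[k] = _statistic_on(repl, vals)
    return out


def stratum_labels(
    M: ContaminationMatrix,
    preds: pd.DataFrame,
    conditioning: Sequence[str],
    lab_overlap_bins: int = 4,
) -> np.ndarray:
    """Integer stratum label per directed cell from conditioning predictors.

    Boolean predictors stratify by value; the continuous lab_overlap is cut
    at its quartiles (``lab_overlap_bins`` equal-probability bins over
    defined pairs).  Cells with any undefined conditioning value get -1.
    """
    S = len(M.species)
    labels = np.zeros((S, S), dtype=np.int64)
    ok = np.ones((S, S), dtype=bool)
    base = 1
    for predictor in conditioning:
        vals = _pair_value_matrix(M, preds, predictor)
        if predictor == "lab_overlap":
            finite = vals[~np.isnan(vals)]
            edges = np.quantile(finite, np.linspace(0, 1, lab_overlap_bins + 1)[1:-1])
            coded = np.full(vals.shape, -1, dtype=np.int64)
            good = ~np.isnan(vals)
            coded[good] = np.searchsorted(edges, vals[good], side="right")
            ncat = lab_overlap_bins
        else:
            coded = np.full(vals.shape, -1, dtype=np.int64)
            good = ~np.isnan(vals)
            coded[good] = vals[good].astype(np.int64)
            ncat = 2
        ok &= coded >= 0
        labels = labels * ncat + np.where(coded >= 0, coded, 0)
        base *= ncat
    labels[~ok] = -1
    return labels


def randomize_conditional(
    M: ContaminationMatrix,
    preds: pd.DataFrame,
    predictor: str,
    conditioning: Sequence[str],
    reps: int = 1000,
    rng: np.random.Generator | None = None,
    lab_overlap_bins: int = 4,
) -> np.ndarray:
    """Null distribution with stratum-specific contamination probabilities.

    Strata are defined by the conditioning predictors; each stratum's
    Bernoulli probability is its observed proportion of ones (0 for empty
    strata, logged).  Cells with undefined conditioning values are dropped
    from the randomization (left missing).
    """
    if rng is None:
        rng = np.random.default_rng()
    labels = stratum_labels(M, preds, conditioning, lab_overlap_bins)
    defined = ~np.isnan(M.m) & (labels >= 0)
    strata = np.unique(labels[defined])
    p_stratum: dict[int, float] = {}
    for s in strata:
        cells = defined & (labels == s)
        n = int(cells.sum())
        if n == 0:
            p_stratum[int(s)] = 0.0
            logger.info("empty stratum %d: probability 0", s)
        else:
            p_stratum[int(s)] = float(np.nansum(M.m[cells]) / n)
    vals = _pair_value_matrix(M, preds, predictor)
    pmat = np.zeros(M.m.shape)
    for s, p in p_stratum.items():
        pmat[labels == s] = p
    out = np.empty(reps)
    for k in range(reps):
        repl = np.full(M.m.shape, np.nan)
        draw = rng.random(M.m.shape)
        repl[defined] = (draw[defined] < pmat[defined]).astype(float)
        out[k] = _statistic_on(repl, vals)
    return out


def empirical_pvalue(observed: float, null: np.ndarray, tail: str = "upper") -> float:
    """Add-one empirical p-value against a randomization sample."""
    null = np.asarray(null)
    null = null[~np.isnan(null)]
    if null.size == 0:
        raise ValueError("empty null sample")
    if tail == "upper":
        extreme = int((null >= observed).sum())
    elif tail == "lower":
        extreme = int((null <= observed).sum())
    else:
        raise ValueError("tail must be 'upper' or 'lower'")
    return (extreme + 1) / (null.size + 1)


@dataclass
class PredictorTest:
    predictor: str
    observed: float
    null_mean: float
    null_sd: float
    p_value: float

    def to_dict(self) -> dict:
        return {
            "predictor": self.predictor,
            "observed": self.observed,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "p": self.p_value,
        }


def predictor_randomization_test(
    M: ContaminationMatrix,
    preds: pd.DataFrame,
    predictor: str,
    conditioning: Sequence[str] | None = None,
    reps: int = 1000,
    rng: np.random.Generator | None = None,
    tail: str = "upper",
) -> PredictorTest:
    """Observed statistic + randomization p-value for one predictor."""
    obs = observed_statistic(M, preds, predictor)
    if conditioning:
        null = randomize_conditional(M, preds, predictor, conditioning, reps=reps, rng=rng)
    else:
        null = randomize_unconditional(M, preds, predictor, reps=reps, rng=rng)
    clean = null[~np.isnan(null)]
    return PredictorTest(
        predictor=predictor,
        observed=obs,
        null_mean=float(clean.mean()),
        null_sd=float(clean.std(ddof=1)) if clean.size > 1 else 0.0,
        p_value=empirical_pvalue(obs, null, tail=tail),
    )


def stratified_probabilities(
    M: ContaminationMatrix,
    preds: pd.DataFrame,
    cumulative: bool = True,
) -> pd.DataFrame:
    """Contamination probability per (CENTER tier x LAB) cell.

    Unordered pairs count as connected when either directed cell is 1;
    pairs with missing M cells or incomplete flowcell/lane information are
    excluded.  CENTER rows are cumulative by default (same shipment ⊇ same
    flowcell ⊇ same lane); ``cumulative=False`` reports disjoint tiers.
    """
    idx = {s: i for i, s in enumerate(M.species)}
    rows = []
    for (sp1, sp2), row in preds.iterrows():
        if sp1 not in idx or sp2 not in idx:
            continue
        if not row["info_complete"]:
            continue
        i, j = idx[sp1], idx[sp2]
        cells = [M.m[i, j], M.m[j, i]]
        if all(np.isnan(c) for c in cells):
            continue
        connected = any(c == 1.0 for c in cells if not np.isnan(c))
        rows.append(
            {
                "LAB": bool(row["LAB"]),
                "CENTER": row["CENTER"],
                "connected": connected,
            }
        )
    pairs = pd.DataFrame(rows)
    out = []
    tier_order = {t: k for k, t in enumerate(CENTER_TIERS)}
    for tier in CENTER_TIERS:
        if cumulative and tier != "CENTER-":
            sel = pairs["CENTER"].map(lambda t: tier_order.get(t, -1) >= tier_order[tier])
        else:
            sel = pairs["CENTER"] == tier
        for lab in (False, True):
            sub = pairs[sel & (pairs["LAB"] == lab)]
            total = len(sub)
            ones = int(sub["connected"].sum())
            out.append(
                {
                    "CENTER": tier,
                    "LAB": "LAB+" if lab else "LAB-",
                    "contaminated_pairs": ones,
                    "total_pairs": total,
                    "probability": ones / total if total else np.nan,
                }
            )
    return pd.DataFrame(out)


def subsample_one_per_stratum(
    meta: pd.DataFrame,
    rng: np.random.Generator | None = None,
    mode: str = "earliest",
) -> list[str]:
    """One species per (technician, shipment) stratum, chosen at random.

    A species spanning several strata is assigned to its earliest stratum
    by shipment date (``mode='earliest'``); ``mode='all'`` lets a species
    compete in every stratum it touches (it is still kept at most once).
    """
    if rng is None:
        rng = np.random.default_rng()
    meta = validate_metadata(meta)
    strata: dict[tuple[str, pd.Timestamp], list[str]] = {}
    if mode == "earliest":
        assign: dict[str, tuple[str, pd.Timestamp]] = {}
        for sp, grp in meta.groupby("species"):
            first = grp.sort_values("shipment_date").iloc[0]
            techs = sorted(_technicians(first["technician"]))
            tech = techs[0] if techs else ""
            assign[sp] = (tech, first["shipment_date"])
        for sp, key in assign.items():
            strata.setdefault(key, []).append(sp)
    elif mode == "all":
        for _, row in meta.iterrows():
            for tech in sorted(_technicians(row["technician"])) or [""]:
                strata.setdefault((tech, row["shipment_date"]), []).append(row["species"])
        strata = {k: sorted(set(v)) for k, v in strata.items()}
    else:
        raise ValueError("mode must be 'earliest' or 'all'")
    kept: list[str] = []
    for key in sorted(strata):
        candidates = sorted(set(strata[key]) - set(kept))
        if not candidates:
            continue
        kept.append(candidates[int(rng.integers(len(candidates)))])
    return sorted(set(kept))
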