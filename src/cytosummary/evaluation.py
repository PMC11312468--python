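"""Retrieval evaluation: cosine-similarity rank orders, average precision,
and mAP for replicate retrieval and mechanism-of-action (sister-compound)
retrieval.

AP is the step sum over the precision-recall curve,
AP = sum_k (r(k) - r(k-1)) * p(k), which for binary relevance equals the mean
precision at the positive ranks. Queries are individual wells. A compound's
AP averages its wells' APs; an MoA's AP averages its member compounds' APs;
mAP averages the per-entity APs. MoAs represented by a single compound are
excluded from MoA retrieval, and the query's own-compound wells are removed
from the candidate list there (sister-compound protocol).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ProfileTable, WellKey

__all__ = [
    "RetrievalReport",
    "cosine_similarity_matrix",
    "average_precision",
    "replicate_retrieval_map",
    "moa_retrieval_map",
    "compare_methods",
    "random_ranking_null",
]

log = logging.getLogger(__name__)


@dataclass
class RetrievalReport:
    """Per-query APs with their aggregations and exclusions."""

    task: str
    per_query: pd.DataFrame          # well key columns + ap
    per_compound: pd.DataFrame       # compound_id, ap
    per_moa: pd.DataFrame            # moa, ap (MoA task only; may be empty)
    map: float
    excluded: list[tuple[str, str]] = field(default_factory=list)  # (entity, reason)


def cosine_similarity_matrix(profiles: ProfileTable) -> np.ndarray:
    """K x K cosine similarities between all well profiles."""
    V = profiles.values
    if V.shape[0] < 2:
        raise ValueError("need at least two profiles")
    norms = np.linalg.norm(V, axis=1)
    bad = np.flatnonzero(norms == 0)
    if bad.size:
        key = profiles.well_keys()[bad[0]]
        raise ValueError(f"zero-norm profile for well {key}")
    U = V / norms[:, None]
    S = U @ U.T
    np.fill_diagonal(S, 1.0)
    return np.clip(S, -1.0, 1.0)


def average_precision(relevance_ranked) -> float:
    """AP of an ordered binary relevance list (1 = relevant), by the step sum
    over the precision-recall curve."""
    rel = np.asarray(relevance_ranked, dtype=np.float64)
    n_pos = rel.sum()
    if n_pos == 0:
        raise ValueError("average precision undefined with zero positives")
    k = np.arange(1, rel.size + 1)
    precision = np.cumsum(rel) / k
    recall = np.cumsum(rel) / n_pos
    r_prev = np.concatenate([[0.0], recall[:-1]])
    return float(np.sum((recall - r_prev) * precision))


def _rank_relevance(
    sims: np.ndarray, order_keys: list[WellKey], candidates: np.ndarray, positives: np.ndarray
) -> np.ndarray:
    """Binary relevance of candidates ordered by descending similarity.

    Ties are broken by canonical well-key order (stable, deterministic).
    """
    cand = np.flatnonzero(candidates)
    keys = [order_keys[i] for i in cand]
    order = sorted(range(len(cand)), key=lambda j: (-sims[cand[j]], keys[j]))
    if len({round(float(sims[i]), 12) for i in cand}) < len(cand):
        log.debug("similarity ties present; broken by canonical well-key order")
    return positives[cand[order]].astype(np.int8)


def replicate_retrieval_map(profiles: ProfileTable) -> RetrievalReport:
    """mAP for retrieving other replicate wells of the same compound.

    Each well queries all other wells; positives are same-compound wells.
    Compounds with a single well cannot be queried and are excluded.
    """
    S = cosine_similarity_matrix(profiles)
    keys = profiles.well_keys()
    compounds = profiles.meta["compound_id"].to_numpy()
    excluded: list[tuple[str, str]] = []
    rows = []
    counts = pd.Series(compounds).value_counts()
    for c in counts.index[counts < 2]:
        excluded.append((str(c), "single replicate well"))
        log.info("replicate retrieval: compound %s excluded (single well)", c)
    for i, key in enumerate(keys):
        if counts[compounds[i]] < 2:
            continue
        candidates = np.ones(len(keys), dtype=bool)
        candidates[i] = False
        positives = compounds == compounds[i]
        positives[i] = False
        rel = _rank_relevance(S[i], keys, candidates, positives)
        rows.append(
            {
                "plate_id": key.plate_id,
                "well_id": key.well_id,
                "compound_id": key.compound_id,
                "ap": average_precision(rel),
            }
        )
    per_query = pd.DataFrame(rows)
    per_compound = (
        per_query.groupby("compound_id", sort=True)["ap"].mean().reset_index()
    )
    return RetrievalReport(
        task="replicate",
        per_query=per_query,
        per_compound=per_compound,
        per_moa=pd.DataFrame(columns=["moa", "ap"]),
        map=float(per_compound["ap"].mean()),
        excluded=excluded,
    )


def moa_retrieval_map(
    profiles: ProfileTable, include_own_compound_as_negatives: bool = False
) -> RetrievalReport:
    """mAP for retrieving wells of *different* compounds sharing the query's
    annotated mechanism of action (sister compounds).

    Single-compound MoAs are excluded along with their replicates. By default
    the query's own-compound wells are removed from the candidate list; set
    ``include_own_compound_as_negatives`` to score them as negatives instead.
    """
    moas = profiles.meta["moa"]
    if moas.isna().all():
        raise ValueError("MoA retrieval requested but no MoA labels present")
    S = cosine_similarity_matrix(profiles)
    keys = profiles.well_keys()
    compounds = profiles.meta["compound_id"].to_numpy()
    moa_arr = moas.to_numpy()

    moa_compounds = (
        pd.DataFrame({"moa": moa_arr, "compound_id": compounds})
        .dropna(subset=["moa"])
        .drop_duplicates()
        .groupby("moa")["compound_id"]
        .nunique()
    )
    eligible_moas = set(moa_compounds.index[moa_compounds >= 2])
    excluded: list[tuple[str, str]] = []
    for m in sorted(set(moa_compounds.index) - eligible_moas):
        excluded.append((str(m), "single-compound MoA"))
        log.info("MoA retrieval: %s excluded (single compound)", m)
    if not eligible_moas:
        raise ValueError("no MoA with at least two compounds")

    rows = []
    for i, key in enumerate(keys):
        m = moa_arr[i]
        if pd.isna(m) or m not in eligible_moas:
            continue
        candidates = compounds != compounds[i] if not include_own_compound_as_negatives \
            else np.arange(len(keys)) != i
        positives = (moa_arr == m) & (compounds != compounds[i])
        if not positives[candidates].any():
            continue
        rel = _rank_relevance(S[i], keys, candidates, positives)
        rows.append(
            {
                "plate_id": key.plate_id,
                "well_id": key.well_id,
                "compound_id": key.compound_id,
                "moa": m,
                "ap": average_precision(rel),
            }
        )
    per_query = pd.DataFrame(rows)
    per_compound = (
        per_query.groupby(["moa", "compound_id"], sort=True)["ap"].mean().reset_index()
    )
    per_moa = per_compound.groupby("moa", sort=True)["ap"].mean().reset_index()
    return RetrievalReport(
        task="moa",
        per_query=per_query,
        per_compound=per_compound[["compound_id", "ap"]],
        per_moa=per_moa,
        map=float(per_moa["ap"].mean()),
        excluded=excluded,
    )


def compare_methods(reports: dict[str, RetrievalReport]) -> pd.DataFrame:
    """Absolute and relative mAP differences of each report vs. the baseline.

    ``reports`` maps a label to a report; the entry labelled "average" is the
    baseline. All reports must cover identical query wells.
    """
    if "average" not in reports:
        raise ValueError("comparison requires an 'average' baseline report")
    base = reports["average"]
    base_wells = set(map(tuple, base.per_query[["plate_id", "well_id"]].to_numpy()))
    rows = []
    for label, rep in reports.items():
        wells = set(map(tuple, rep.per_query[["plate_id", "well_id"]].to_numpy()))
        if wells != base_wells:
            raise ValueError(f"report {label!r} covers different wells than the baseline")
        delta = rep.map - base.map
        rows.append(
            {
                "method": label,
                "map": rep.map,
                "delta_map": delta,
                "relative_change": delta / base.map if base.map > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def random_ranking_null(
    profiles: ProfileTable, n_perm: int = 200, seed: int = 0
) -> tuple[float, float]:
    """Replicate-retrieval mAP under the permutation null.

    Profiles are randomly reassigned to wells ``n_perm`` times; returns the
    empirical (mean, standard deviation) of the null mAP distribution. This is
    the chance level against which a learned or averaged profile is judged.
    """
    rng = np.random.default_rng(seed)
    K = profiles.n_wells
    maps = np.empty(n_perm)
    for t in range(n_perm):
        perm = rng.permutation(K)
        shuffled = ProfileTable(
            meta=profiles.meta.copy(),
            values=profiles.values[perm],
            method=profiles.method,
            features=list(profiles.features),
        )
        maps[t] = replicate_retrieval_map(shuffled).map
    return float(maps.mean()), float(maps.std())
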