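"""Geospatial deduplication of survey responses and cross-wave matching.

Participation in the survey was on an individual basis, so one health-care
facility may appear several times.  Duplicates are found by single-linkage
agglomeration *within country*: two responses link when their great-circle
distance is at most ``radius_km`` and their normalised facility-name
similarity is at least ``name_threshold``; clusters are the connected
components of that link graph.  One representative response per cluster is
kept, preferring more complete surveys, then more answered indicators, then
the latest submission, then the smallest response id.

The same distance + name constraints drive the one-to-one matching of
facilities between two survey waves (greedy by distance).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from difflib import SequenceMatcher

import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0

DEFAULT_RADIUS_KM = 0.5
DEFAULT_NAME_THRESHOLD = 0.6

__all__ = [
    "haversine_km",
    "normalise_name",
    "token_set_ratio",
    "cluster_responses",
    "select_representative",
    "match_waves",
    "ResponseCluster",
]


def haversine_km(lat1, lon1, lat2, lon2):
    """Great-circle distance in km (Earth radius 6371 km); vectorises."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


_PUNCT = re.compile(r"[^\w\s]", re.UNICODE)
_WS = re.compile(r"\s+")


def normalise_name(name: str) -> str:
    """Case-fold, strip punctuation, collapse whitespace."""
    if not isinstance(name, str):
        return ""
    return _WS.sub(" ", _PUNCT.sub(" ", name.casefold())).strip()


def token_set_ratio(a: str, b: str) -> float:
    """Token-set similarity in [0, 1] on normalised strings.

    Compares the sorted token intersection against each side's sorted
    intersection-plus-remainder, taking the best pairwise sequence ratio, so
    that a name which is a token subset of another scores 1.0.
    """
    ta, tb = set(normalise_name(a).split()), set(normalise_name(b).split())
    if not ta or not tb:
        return 0.0
    inter = " ".join(sorted(ta & tb))
    sa = (inter + " " + " ".join(sorted(ta - tb))).strip()
    sb = (inter + " " + " ".join(sorted(tb - ta))).strip()
    pairs = [(inter, sa), (inter, sb), (sa, sb)]
    return max(SequenceMatcher(None, x, y).ratio() for x, y in pairs if x or y)


@dataclass(frozen=True)
class ResponseCluster:
    cluster_id: str
    country_code: str
    member_ids: tuple[str, ...]
    representative_id: str


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def _completeness_rank(scores: pd.DataFrame) -> pd.DataFrame:
    complete_cols = [c for c in scores.columns if c.startswith("complete_")]
    return scores[complete_cols].sum(axis=1)


def _count_answered(responses: pd.DataFrame, indicator_ids) -> pd.Series:
    present = [c for c in indicator_ids if c in responses.columns]
    block = responses[present]
    return (block.notna() & (block.astype("string") != "")).sum(axis=1)


def select_representative(members: pd.DataFrame) -> str:
    """Pick the representative response of one cluster.

    ``members`` needs columns ``response_id``, ``n_complete_elements``,
    ``n_answered``, ``submitted_at``.  Ranking: most complete elements,
    most answered indicators, latest submission, smallest response_id.
    """
    ranked = members.sort_values(
        by=["n_complete_elements", "n_answered", "submitted_at", "response_id"],
        ascending=[False, False, False, True],
        kind="mergesort",
    )
    return str(ranked.iloc[0]["response_id"])


def cluster_responses(
    responses: pd.DataFrame,
    scores: pd.DataFrame,
    instrument,
    radius_km: float = DEFAULT_RADIUS_KM,
    name_threshold: float = DEFAULT_NAME_THRESHOLD,
) -> list[ResponseCluster]:
    """Partition responses into facility clusters within each country.

    Responses without coordinates become singleton clusters.  The result is
    independent of the input row order: members are sorted and the cluster id
    is derived from the smallest member response id.
    """
    if radius_km <= 0:
        raise ValueError("radius_km must be positive")
    work = responses.copy()
    work["n_complete_elements"] = _completeness_rank(scores).values
    work["n_answered"] = _count_answered(responses, instrument.indicator_ids).values
    work["_norm_name"] = work["facility_name"].map(normalise_name)

    clusters: list[ResponseCluster] = []
    no_coords = work["latitude"].isna() | work["longitude"].isna()
    for _, row in work[no_coords].iterrows():
        rid = str(row["response_id"])
        clusters.append(ResponseCluster(
            cluster_id=f"c_{rid}", country_code=str(row["country_code"]),
            member_ids=(rid,), representative_id=rid))

    located = work[~no_coords]
    for country, grp in located.groupby("country_code", sort=True):
        grp = grp.sort_values("response_id", kind="mergesort").reset_index(drop=True)
        n = len(grp)
        uf = _UnionFind(n)
        lat = grp["latitude"].to_numpy(float)
        lon = grp["longitude"].to_numpy(float)
        names = grp["_norm_name"].tolist()
        for i in range(n - 1):
            d = haversine_km(lat[i], lon[i], lat[i + 1:], lon[i + 1:])
            for off in np.nonzero(np.atleast_1d(d) <= radius_km)[0]:
                j = i + 1 + int(off)
                if token_set_ratio(names[i], names[j]) >= name_threshold:
                    uf.union(i, j)
        comp: dict[int, list[int]] = {}
        for i in range(n):
            comp.setdefault(uf.find(i), []).append(i)
        for members_idx in comp.values():
            members = grp.iloc[members_idx]
            rep = select_representative(members)
            member_ids = tuple(sorted(members["response_id"].astype(str)))
            clusters.append(ResponseCluster(
                cluster_id=f"c_{member_ids[0]}", country_code=str(country),
                member_ids=member_ids, representative_id=rep))
    clusters.sort(key=lambda c: c.cluster_id)
    return clusters


def clusters_to_frame(clusters: list[ResponseCluster]) -> pd.DataFrame:
    rows = []
    for c in clusters:
        for rid in c.member_ids:
            rows.append({
                "cluster_id": c.cluster_id,
                "country_code": c.country_code,
                "response_id": rid,
                "is_representative": rid == c.representative_id,
            })
    return pd.DataFrame(rows, columns=[
        "cluster_id", "country_code", "response_id", "is_representative"])


def match_waves(
    wave1: pd.DataFrame,
    wave2: pd.DataFrame,
    radius_km: float = DEFAULT_RADIUS_KM,
    name_threshold: float = DEFAULT_NAME_THRESHOLD,
) -> pd.DataFrame:
    """One-to-one matching of deduplicated facilities across two waves.

    Each input frame carries one row per facility (the wave's representative
    responses) with columns ``response_id``, ``facility_name``,
    ``country_code``, ``latitude``, ``longitude``.  Candidate pairs share a
    country and satisfy the distance and name constraints; they are assigned
    greedily by increasing distance, each facility used at most once.

    Returns a frame with columns ``response_id_1``, ``response_id_2``,
    ``distance_km``, ``name_similarity``, sorted by distance.
    """
    cand = []
    w1 = wave1.dropna(subset=["latitude", "longitude"])
    w2 = wave2.dropna(subset=["latitude", "longitude"])
    for country, g1 in w1.groupby("country_code"):
        g2 = w2[w2["country_code"] == country]
        if g2.empty:
            continue
        lat2 = g2["latitude"].to_numpy(float)
        lon2 = g2["longitude"].to_numpy(float)
        for _, r1 in g1.iterrows():
            d = np.atleast_1d(haversine_km(r1["latitude"], r1["longitude"], lat2, lon2))
            for off in np.nonzero(d <= radius_km)[0]:
                r2 = g2.iloc[int(off)]
                sim = token_set_ratio(str(r1["facility_name"]), str(r2["facility_name"]))
                if sim >= name_threshold:
                    cand.append((float(d[off]), sim,
                                 str(r1["response_id"]), str(r2["response_id"])))
    cand.sort(key=lambda t: (t[0], -t[1], t[2], t[3]))
    used1: set[str] = set()
    used2: set[str] = set()
    rows = []
    for dist, sim, id1, id2 in cand:
        if id1 in used1 or id2 in used2:
            continue
        used1.add(id1)
        used2.add(id2)
        rows.append({"response_id_1": id1, "response_id_2": id2,
                     "distance_km": dist, "name_similarity": sim})
    return pd.DataFrame(rows, columns=[
        "response_id_1", "response_id_2", "distance_km", "name_similarity"])
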