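"""Joins MD-derived depth maps with quenching tables and quantifies agreement.

The spin label of N-tempoyl-palmitamide sits in the phospholipid head-group
region, so its quenching is compared against Dist_P; the 5-doxyl-stearate
label sits near acyl-chain carbon 5, so it is compared against Dist_C5.
The numeric concordance statistics (rank correlation, bin agreement) are an
extension: the underlying comparison in the source experiments is qualitative.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .fluor import QuenchingResult, ShiftResult
from .membrane import DEFAULT_BIN_EDGES, DepthRecord, classify_distance_bin

#: quencher → the depth metric its spin-label depth matches
QUENCHER_DEPTH_METRIC = {"tempoyl": "dist_P", "doxyl": "dist_C5"}


@dataclass(frozen=True)
class SiteRecord:
    site: int
    dist_P: float
    dist_C5: float
    bin_P: str
    bin_C5: str
    q_tempoyl: float | None = None
    q_doxyl: float | None = None
    neg_tempoyl: bool = False
    neg_doxyl: bool = False
    shift_nm: float | None = None


@dataclass(frozen=True)
class RankConcordance:
    quencher: str
    correlation: float
    n: int
    degenerate: bool = False


@dataclass(frozen=True)
class BinAgreement:
    quencher: str
    agreement: float
    n_concordant: int
    n_discordant: int
    n_indeterminate: int


def join(
    depths: Sequence[DepthRecord],
    quench: Sequence[QuenchingResult],
    shifts: Sequence[ShiftResult] = (),
    state: str | None = None,
    bin_edges: tuple[float, ...] = DEFAULT_BIN_EDGES,
) -> tuple[list[SiteRecord], dict[str, list]]:
    """Inner join of depth and quenching data on site.

    Quenching/shift results may be filtered to one binding state. Sites
    present on only one side are returned in the unmatched report, never
    silently dropped. Duplicate sites on either side are an error.
    """
    if state is not None:
        quench = [q for q in quench if q.state == state]
        shifts = [s for s in shifts if s.state == state]

    depth_by_site: dict[int, DepthRecord] = {}
    for d in depths:
        if d.site in depth_by_site:
            raise ValueError(f"duplicate site {d.site} in depth records")
        depth_by_site[d.site] = d

    q_by_site: dict[int, dict[str, QuenchingResult]] = {}
    for q in quench:
        per = q_by_site.setdefault(int(q.site), {})
        if q.quencher in per:
            raise ValueError(f"duplicate site {q.site} for quencher {q.quencher}")
        per[q.quencher] = q
    shift_by_site = {}
    for s in shifts:
        if int(s.site) in shift_by_site:
            raise ValueError(f"duplicate site {s.site} in shift records")
        shift_by_site[int(s.site)] = s

    matched = sorted(set(depth_by_site) & set(q_by_site))
    records = []
    for site in matched:
        d = depth_by_site[site]
        per = q_by_site[site]
        qt, qd = per.get("tempoyl"), per.get("doxyl")
        sh = shift_by_site.get(site)
        records.append(
            SiteRecord(
                site=site,
                dist_P=d.dist_P,
                dist_C5=d.dist_C5,
                bin_P=classify_distance_bin(d.dist_P, bin_edges),
                bin_C5=classify_distance_bin(d.dist_C5, bin_edges),
                q_tempoyl=qt.efficiency if qt else None,
                q_doxyl=qd.efficiency if qd else None,
                neg_tempoyl=qt.negative_flag if qt else False,
                neg_doxyl=qd.negative_flag if qd else False,
                shift_nm=sh.delta_nm if sh else None,
            )
        )
    unmatched = {
        "depth_only": sorted(set(depth_by_site) - set(q_by_site)),
        "quench_only": sorted(set(q_by_site) - set(depth_by_site)),
    }
    return records, unmatched


def _pairs(records: Sequence[SiteRecord], quencher: str) -> tuple[np.ndarray, np.ndarray]:
    metric = QUENCHER_DEPTH_METRIC[quencher]
    eff, dist = [], []
    for r in records:
        q = r.q_tempoyl if quencher == "tempoyl" else r.q_doxyl
        if q is None:
            continue
        eff.append(q)
        dist.append(getattr(r, metric))
    return np.asarray(eff, float), np.asarray(dist, float)


def rank_concordance(records: Sequence[SiteRecord], quencher: str) -> RankConcordance:
    """Tie-corrected Spearman correlation of efficiency vs −distance.

    +1 means quenching falls off perfectly monotonically with distance. A
    constant column makes the correlation undefined; it is reported as 0
    with the degenerate flag set.
    """
    eff, dist = _pairs(records, quencher)
    if len(eff) < 3:
        raise ValueError("rank concordance needs at least 3 records with both fields")
    if np.allclose(eff, eff[0]) or np.allclose(dist, dist[0]):
        return RankConcordance(quencher, 0.0, len(eff), degenerate=True)
    rho = stats.spearmanr(eff, -dist).statistic
    return RankConcordance(quencher, float(rho), len(eff))


def bin_agreement(
    records: Sequence[SiteRecord],
    quencher: str = "doxyl",
    quench_threshold: float = 10.0,
    near_edge: float = 10.0,
    far_edge: float = 15.0,
) -> BinAgreement:
    """Categorical MD-vs-quenching agreement.

    A site is concordant when (dist ≤ near_edge and Q ≥ threshold) or
    (dist > far_edge and Q < threshold); sites in (near_edge, far_edge] are
    indeterminate and excluded from the denominator, as are negative-
    quenching sites (control-side artifact, not a distance readout).
    """
    if min(quench_threshold, near_edge, far_edge) <= 0:
        raise ValueError("thresholds must be positive")
    metric = QUENCHER_DEPTH_METRIC[quencher]
    n_con = n_dis = n_ind = 0
    for r in records:
        q = r.q_tempoyl if quencher == "tempoyl" else r.q_doxyl
        neg = r.neg_tempoyl if quencher == "tempoyl" else r.neg_doxyl
        if q is None:
            continue
        dist = getattr(r, metric)
        if neg or (near_edge < dist <= far_edge):
            n_ind += 1
        elif (dist <= near_edge and q >= quench_threshold) or (
            dist > far_edge and q < quench_threshold
        ):
            n_con += 1
        else:
            n_dis += 1
    denom = n_con + n_dis
    agreement = n_con / denom if denom else float("nan")
    return BinAgreement(quencher, agreement, n_con, n_dis, n_ind)


def records_to_frame(records: Sequence[SiteRecord]) -> pd.DataFrame:
    """Tidy per-site comparison table (the distance-and-fluorescence map)."""
    return pd.DataFrame([r.__dict__ for r in records])
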