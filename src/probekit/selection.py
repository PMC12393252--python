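"""Prioritization-rank greedy probe selection.

Candidates are totally ordered by (number of off-target sites ascending,
energy gap ascending, target start ascending), where the energy gap is the
on-target hybridization free energy minus the summed off-target, hairpin
and accrued cross-dimer free energies — more negative means a probe that
binds its target strongly and everything else weakly.

Selection runs in two phases: first only candidates with zero off-target
sites, then the rest.  Each pick permanently removes candidates that would
violate the minimum spacing against the growing set, and folds each
remaining candidate's cross-dimer affinity with the new pick into its
energy gap before re-ranking, so probes complementary to an already chosen
probe sink in the order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable

from .homology import BindingSiteMap
from .thermo import DissociationConstants
from .tiling import CandidateProbe

__all__ = ["ProbeRank", "SelectionResult", "rank_candidates", "select_probes"]


@dataclass(frozen=True)
class ProbeRank:
    probe_id: str
    start: int
    n_offtargets: float  # site count, or expression-weighted sum
    dg_on: float  # kcal/mol, most favorable on-target configuration
    dg_off_sum: float
    dg_self: float
    dg_cross_accrued: float = 0.0

    @property
    def energy_gap(self) -> float:
        return self.dg_on - (self.dg_off_sum + self.dg_self + self.dg_cross_accrued)

    @property
    def rank_key(self) -> tuple:
        return (self.n_offtargets, self.energy_gap, self.start)


def rank_candidates(
    candidates: list[CandidateProbe],
    site_map: BindingSiteMap,
    kds: DissociationConstants,
    on_target_ids: set[str],
    expression: dict[str, float] | None = None,
    weight_by_expression: bool = False,
) -> list[ProbeRank]:
    """Initial prioritization rank for every candidate.

    Off-target counting is site-resolved (a transcript with two sites counts
    twice) and optionally weighted by the site's transcript expression.
    """
    site_probes: dict[str, list[tuple[str, str]]] = {}
    for site in site_map.all_sites():
        for pid in site.probe_ids():
            site_probes.setdefault(pid, []).append((site.target_id, site.site_id))

    ranks = []
    for cand in candidates:
        n_off = 0.0
        dg_on = math.inf
        dg_off = 0.0
        for tid, sid in site_probes.get(cand.probe_id, []):
            dg = kds.dg_site.get((cand.probe_id, tid, sid))
            if dg is None:
                continue
            if tid in on_target_ids:
                dg_on = min(dg_on, dg)
            else:
                n_off += expression.get(tid, 0.0) if weight_by_expression else 1.0
                dg_off += dg
        if not math.isfinite(dg_on):
            dg_on = 0.0  # no stable on-target duplex; rank on penalties alone
        dg_self = kds.dg_self.get(cand.probe_id, 0.0)
        ranks.append(
            ProbeRank(
                probe_id=cand.probe_id,
                start=cand.start,
                n_offtargets=n_off,
                dg_on=dg_on,
                dg_off_sum=dg_off,
                dg_self=dg_self,
            )
        )
    return sorted(ranks, key=lambda r: r.rank_key)


@dataclass
class SelectionResult:
    selected: list[str]
    excluded: dict[str, str] = field(default_factory=dict)  # probe_id -> reason
    max_probes: int = 0
    min_spacing: int = 3
    phase_of: dict[str, int] = field(default_factory=dict)


def _conflicts(cand: CandidateProbe, chosen: CandidateProbe, min_spacing: int) -> bool:
    if cand.target_id != chosen.target_id:
        return False
    return not (cand.start >= chosen.end + min_spacing or cand.end + min_spacing <= chosen.start)


def select_probes(
    ranked: list[ProbeRank],
    candidates: list[CandidateProbe],
    max_probes: int,
    min_spacing: int = 3,
    rrna_flagged: set[str] | None = None,
    cross_dg: Callable[[str, str], float] | None = None,
) -> SelectionResult:
    """Two-phase greedy assembly of the final probe set.

    ``cross_dg(i, j)`` returns the most favorable cross-dimer free energy of
    a probe pair (0 when they do not dimerize); it is accrued into remaining
    candidates' energy gaps after every pick.
    """
    if max_probes < 1:
        raise ValueError("max_probes must be >= 1")
    by_id = {c.probe_id: c for c in candidates}
    result = SelectionResult(selected=[], max_probes=max_probes, min_spacing=min_spacing)

    pool: dict[str, ProbeRank] = {}
    for r in ranked:
        if rrna_flagged and r.probe_id in rrna_flagged:
            result.excluded[r.probe_id] = "rRNA"
        else:
            pool[r.probe_id] = r

    for phase, predicate in ((1, lambda r: r.n_offtargets == 0), (2, lambda r: True)):
        while len(result.selected) < max_probes:
            eligible = [r for r in pool.values() if predicate(r)]
            if not eligible:
                break
            best = min(eligible, key=lambda r: r.rank_key)
            result.selected.append(best.probe_id)
            result.phase_of[best.probe_id] = phase
            del pool[best.probe_id]
            chosen = by_id[best.probe_id]
            # (ii) permanently drop spacing violators
            for pid in [p for p in pool if _conflicts(by_id[p], chosen, min_spacing)]:
                result.excluded[pid] = "overlap"
                del pool[pid]
            # (iii) fold cross-dimer affinity with the new pick into the gaps
            if cross_dg is not None:
                for pid, r in list(pool.items()):
                    dg = cross_dg(pid, best.probe_id)
                    if dg:
                        pool[pid] = replace(r, dg_cross_accrued=r.dg_cross_accrued + dg)
        if len(result.selected) >= max_probes:
            break

    for pid in pool:
        result.excluded.setdefault(pid, "cap" if len(result.selected) >= max_probes else "unplaced")
    return result
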