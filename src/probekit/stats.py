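"""Bound-probe statistics: site probabilities, Poisson-Binomial counts,
on/off-target molecule counts, specificity load, accumulation curves, SNR.

Site occupancies at equilibrium are independent Bernoulli trials, so the
number of probes bound to one transcript follows a Poisson-Binomial
distribution, computed here by iterative convolution of the per-site
(1-p, p) kernels — numerically stable and exactly equivalent to expanding
the probability generating function product.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .equilibrium import CellModel, EquilibriumState
from .homology import BindingSiteMap
from .reference import ExpressionMode
from .thermo import DissociationConstants

__all__ = [
    "SiteBoundProbability",
    "BoundCountDistribution",
    "SpecificityReport",
    "SignalStats",
    "site_bound_probability",
    "bound_count_distribution",
    "target_pmfs",
    "on_off_counts",
    "specificity_load",
    "offtarget_accumulation",
    "identify_problem_probes",
    "snr",
]


@dataclass
class SiteBoundProbability:
    """P(site is bound by any probe) per (target_id, site_id)."""

    p: dict[tuple[str, str], float]
    # per-probe numerator terms C_i,free / Kd(i,j,s), for attribution
    terms: dict[tuple[str, str], dict[str, float]] = field(default_factory=dict)


def site_bound_probability(state: EquilibriumState, kds: DissociationConstants) -> SiteBoundProbability:
    """p(j,s) = S / (S + 1) with S = sum_i C_i,free / Kd(i,j,s)."""
    p: dict[tuple[str, str], float] = {}
    terms: dict[tuple[str, str], dict[str, float]] = {}
    per_site: dict[tuple[str, str], dict[str, float]] = {k: {} for k in state.site_keys}
    for (pid, tid, sid), kd in kds.kd_site.items():
        key = (tid, sid)
        if key in per_site and pid in state.probe_ids:
            per_site[key][pid] = state.free_probe(pid) / kd
    for key in state.site_keys:
        s = sum(per_site[key].values())
        p[key] = s / (s + 1.0)
        terms[key] = per_site[key]
    return SiteBoundProbability(p=p, terms=terms)


def bound_count_distribution(p_sites: list[float]) -> np.ndarray:
    """Poisson-Binomial pmf over 0..N bound probes, by convolution."""
    pmf = np.array([1.0])
    for p in p_sites:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"site probability {p} outside [0, 1]")
        pmf = np.convolve(pmf, [1.0 - p, p])
    return pmf


@dataclass
class BoundCountDistribution:
    pmf: dict[str, np.ndarray]  # target_id -> P(n), n = 0..Nsites(j)


def target_pmfs(site_probs: SiteBoundProbability, site_map: BindingSiteMap) -> BoundCountDistribution:
    out: dict[str, np.ndarray] = {}
    for tid, sites in site_map.sites.items():
        ps = [site_probs.p.get((tid, s.site_id), 0.0) for s in sites]
        out[tid] = bound_count_distribution(ps)
    return BoundCountDistribution(pmf=out)


@dataclass
class SignalStats:
    mu_signal: float
    mu_background: float
    sigma_background: float


def snr(stats: SignalStats) -> float:
    """Spot signal-to-noise: (mu_signal - mu_background) / sigma_background."""
    if stats.sigma_background <= 0:
        raise ValueError("sigma_background must be positive")
    return (stats.mu_signal - stats.mu_background) / stats.sigma_background


@dataclass
class SpecificityReport:
    n_on: np.ndarray  # Non(n): on-target molecules with n probes bound
    n_off: np.ndarray  # Noff(n): same over off-targets
    specificity_load: float
    expected_off_per_probe: dict[str, float]
    cumulative_off: list[float]
    off_per_on_ratio: float
    mode: ExpressionMode


def on_off_counts(
    dists: BoundCountDistribution,
    expression: dict[str, float],
    on_target_ids: set[str],
) -> tuple[np.ndarray, np.ndarray]:
    """Expression-weighted counts of molecules with n probes bound.

    Non(n) = sum_{j in on} Expression_j P(n | j), and likewise Noff over
    off-targets.  Expression is read as RNA copies per cell, so the counts
    are molecules per cell; under the equal-expression mode (all weights 1)
    they are per-copy rates.
    """
    unknown = on_target_ids - set(dists.pmf) - set(expression)
    if unknown:
        raise ValueError(f"unknown on-target id(s): {sorted(unknown)}")
    nmax = max((len(pmf) for pmf in dists.pmf.values()), default=1)
    n_on = np.zeros(nmax)
    n_off = np.zeros(nmax)
    for tid, pmf in dists.pmf.items():
        e = expression.get(tid, 0.0)
        acc = n_on if tid in on_target_ids else n_off
        acc[: len(pmf)] += e * pmf
    return n_on, n_off


def specificity_load(n_on: np.ndarray, n_off: np.ndarray) -> float:
    """Total off-target probe bindings per mean probes bound on-target.

    (sum_n n Noff(n)) / (sum_n n Non(n) / sum_{n>=1} Non(n)); undefined
    (error) when nothing binds on-target.
    """
    ns_on = np.arange(len(n_on))
    ns_off = np.arange(len(n_off))
    on_bindings = float(np.sum(ns_on * n_on))
    on_molecules = float(np.sum(n_on[1:]))
    if on_bindings <= 0 or on_molecules <= 0:
        raise ValueError("specificity load undefined: no on-target binding")
    mean_on = on_bindings / on_molecules
    return float(np.sum(ns_off * n_off)) / mean_on


def offtarget_accumulation(
    site_probs: SiteBoundProbability,
    site_map: BindingSiteMap,
    expression: dict[str, float],
    on_target_ids: set[str],
    probe_order: list[str],
) -> tuple[dict[str, float], list[float], float]:
    """Per-probe expected off-target bindings and the cumulative curve.

    A site's expected occupancy (expression-weighted bound probability) is
    attributed to probes in proportion to their C_free/Kd share of its
    binding.  Returns (per-probe, cumulative in ``probe_order``, total
    off-target bindings per total on-target bindings).
    """
    per_probe: dict[str, float] = {pid: 0.0 for pid in probe_order}
    on_total = 0.0
    off_total = 0.0
    for tid, sites in site_map.sites.items():
        e = expression.get(tid, 0.0)
        for site in sites:
            key = (tid, site.site_id)
            p_bound = site_probs.p.get(key, 0.0)
            occupancy = e * p_bound
            if tid in on_target_ids:
                on_total += occupancy
                continue
            off_total += occupancy
            terms = site_probs.terms.get(key, {})
            denom = sum(terms.values())
            if denom <= 0:
                continue
            for pid, term in terms.items():
                if pid in per_probe:
                    per_probe[pid] += occupancy * term / denom
    cumulative: list[float] = []
    acc = 0.0
    for pid in probe_order:
        acc += per_probe[pid]
        cumulative.append(acc)
    ratio = off_total / on_total if on_total > 0 else math.inf
    return per_probe, cumulative, ratio


def identify_problem_probes(
    site_probs: SiteBoundProbability,
    site_map: BindingSiteMap,
    expression: dict[str, float],
    on_target_ids: set[str],
    probe_ids: list[str],
) -> tuple[list[tuple[str, float]], list[tuple[str, float]]]:
    """Rank probes by their contribution to off-target signal.

    Two rankings (worst first): by per-probe expected off-target bindings,
    and by the leave-one-out reduction of sum_{n>=2} Noff(n) — sites are
    re-scored with the probe's binding term removed, holding free
    concentrations fixed.
    """
    per_probe, _, _ = offtarget_accumulation(
        site_probs, site_map, expression, on_target_ids, probe_ids
    )
    by_total = sorted(per_probe.items(), key=lambda kv: (-kv[1], kv[0]))

    def noff_multi(excluded: str | None) -> float:
        total = 0.0
        for tid, sites in site_map.sites.items():
            if tid in on_target_ids:
                continue
            ps = []
            for site in sites:
                terms = site_probs.terms.get((tid, site.site_id), {})
                s = sum(v for pid, v in terms.items() if pid != excluded)
                ps.append(s / (s + 1.0))
            pmf = bound_count_distribution(ps)
            total += expression.get(tid, 0.0) * float(np.sum(pmf[2:]))
        return total

    base = noff_multi(None)
    by_multi = sorted(
        ((pid, base - noff_multi(pid)) for pid in probe_ids),
        key=lambda kv: (-kv[1], kv[0]),
    )
    return by_total, by_multi
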