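"""Coupled mass-action equilibrium of probes, hairpins, dimers and sites.

All probes share one well-mixed volume with all target binding sites.  Each
probe partitions between free solution, a self-hairpin, cross-dimers with
every other probe (a homodimer consumes two copies: parity coefficient 2),
and duplexes at every site it can bind.  Free-site concentrations are
eliminated analytically, leaving one fixed-point equation per probe

    C_i,free = C_i,total / (1 + 1/Kd_self,i
               + sum_j parity(i,j) C_j,free / Kd_cross,ij
               + sum_s C_s,total / (Kd_site,is (1 + sum_k C_k,free / Kd_site,ks)))

solved by damped Picard iteration with a Newton-type fallback.  Target
site totals come from nTPM treated as RNA copies per cell inside a sphere
of the cell radius (10 um, a Jurkat-sized cell, by default).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .thermo import DissociationConstants

logger = logging.getLogger(__name__)

__all__ = [
    "AVOGADRO",
    "CellModel",
    "ConcentrationProfile",
    "EquilibriumState",
    "parity",
    "site_total_concentration",
    "solve_equilibrium",
]

AVOGADRO = 6.02214076e23  # 1/mol


def parity(i, j) -> int:
    """Stoichiometric coefficient of a cross-dimer: 2 for a homodimer."""
    return 2 if i == j else 1


@dataclass(frozen=True)
class CellModel:
    """Spherical cell approximation used to convert copies/cell to molar."""

    cell_radius_um: float = 10.0

    @property
    def volume_L(self) -> float:
        return (4.0 / 3.0) * math.pi * self.cell_radius_um**3 * 1e-15


def site_total_concentration(ntpm: float, cell: CellModel = CellModel()) -> float:
    """Molar concentration of a target site, reading nTPM as copies per cell."""
    if ntpm < 0:
        raise ValueError("nTPM must be non-negative")
    return ntpm / (cell.volume_L * AVOGADRO)


@dataclass
class ConcentrationProfile:
    """Total (conserved) concentrations of every probe and site, in molar."""

    probe_total_M: dict[str, float]
    site_total_M: dict[tuple[str, str], float]  # (target_id, site_id) -> M

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.probe_total_M.values()) or any(
            v < 0 for v in self.site_total_M.values()
        ):
            raise ValueError("concentrations must be non-negative")


@dataclass
class EquilibriumState:
    probe_ids: list[str]
    site_keys: list[tuple[str, str]]
    probe_free_M: np.ndarray
    site_free_M: np.ndarray
    probe_total_M: np.ndarray
    site_total_M: np.ndarray
    self_M: np.ndarray  # hairpin complex per probe
    cross_M: dict[tuple[str, str], float]  # dimer complex, keyed once (i<=j)
    bound_M: np.ndarray  # probe x site duplex concentrations
    residual: float
    iterations: int
    _probe_index: dict[str, int] = field(default_factory=dict)
    _site_index: dict[tuple[str, str], int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._probe_index = {p: k for k, p in enumerate(self.probe_ids)}
        self._site_index = {s: k for k, s in enumerate(self.site_keys)}

    def free_probe(self, probe_id: str) -> float:
        return float(self.probe_free_M[self._probe_index[probe_id]])

    def free_site(self, target_id: str, site_id: str) -> float:
        return float(self.site_free_M[self._site_index[(target_id, site_id)]])

    def bound(self, probe_id: str, target_id: str, site_id: str) -> float:
        return float(
            self.bound_M[self._probe_index[probe_id], self._site_index[(target_id, site_id)]]
        )


def _assemble(kds: DissociationConstants, conc: ConcentrationProfile):
    probe_ids = sorted(conc.probe_total_M)
    site_keys = sorted(conc.site_total_M)
    p_idx = {p: k for k, p in enumerate(probe_ids)}
    s_idx = {s: k for k, s in enumerate(site_keys)}
    n, m = len(probe_ids), len(site_keys)

    totals = np.array([conc.probe_total_M[p] for p in probe_ids])
    site_totals = np.array([conc.site_total_M[s] for s in site_keys])

    ka_site = np.zeros((n, m))  # 1/Kd per (probe, site)
    for (pid, tid, sid), kd in kds.kd_site.items():
        if pid in p_idx and (tid, sid) in s_idx:
            ka_site[p_idx[pid], s_idx[(tid, sid)]] = 1.0 / kd

    ka_self = np.zeros(n)
    for pid, kd in kds.kd_self.items():
        if pid in p_idx:
            ka_self[p_idx[pid]] = 1.0 / kd

    x_cross = np.zeros((n, n))  # parity / Kd_cross
    for (i, j), kd in kds.kd_cross.items():
        if i in p_idx and j in p_idx:
            x_cross[p_idx[i], p_idx[j]] = parity(i, j) / kd
    return probe_ids, site_keys, totals, site_totals, ka_site, ka_self, x_cross


def solve_equilibrium(
    kds: DissociationConstants,
    conc: ConcentrationProfile,
    tol: float = 1e-12,
    max_iter: int = 10_000,
    damping: float = 0.5,
    newton_after: int = 1_000,
) -> EquilibriumState:
    """Solve the steady state for all probes and sites simultaneously.

    Damped Picard iteration on the free-probe vector, starting from
    all-free; after ``newton_after`` non-converged iterations the remaining
    work is handed to a Newton-type root finder on the same residual.
    Raises on non-convergence, reporting the residual and iteration count.
    """
    (probe_ids, site_keys, totals, site_totals, ka_site, ka_self, x_cross) = _assemble(kds, conc)
    n = len(probe_ids)

    def g(p_free: np.ndarray) -> np.ndarray:
        """One Picard update: total / (1 + sequestration terms)."""
        occ = 1.0 + p_free @ ka_site  # per-site saturation factor
        denom = 1.0 + ka_self + x_cross @ p_free + ka_site @ (site_totals / occ)
        return totals / denom

    p = totals.astype(float).copy()
    if n == 0 or not np.any(totals > 0):
        p = totals.astype(float)
        iterations, residual = 0, 0.0
    else:
        scale = np.where(totals > 0, totals, 1.0)
        residual = math.inf
        iterations = 0
        for iterations in range(1, max_iter + 1):
            p_new = g(p)
            residual = float(np.max(np.abs(p_new - p) / scale))
            p = (1.0 - damping) * p + damping * p_new
            if residual <= tol:
                break
            if iterations == newton_after:
                from scipy.optimize import root

                active = totals > 0
                # solve in log space to preserve positivity
                def res_log(x):
                    full = np.zeros(n)
                    full[active] = np.exp(x)
                    return np.log(g(full)[active]) - x

                sol = root(res_log, np.log(np.maximum(p[active], 1e-300)), method="hybr")
                if sol.success:
                    p = np.zeros(n)
                    p[active] = np.exp(sol.x)
                    residual = float(np.max(np.abs(g(p) - p) / scale))
                    if residual <= tol:
                        break
        if residual > tol:
            raise RuntimeError(
                f"equilibrium did not converge: residual {residual:.3e} after {iterations} iterations"
            )

    occ = 1.0 + p @ ka_site
    site_free = site_totals / occ
    self_M = p * ka_self
    bound_M = np.outer(p, np.ones_like(site_free)) * ka_site * site_free

    cross_M: dict[tuple[str, str], float] = {}
    for (i, j), kd in kds.kd_cross.items():
        if i in probe_ids and j in probe_ids and (j, i) not in cross_M:
            ci = p[probe_ids.index(i)]
            cj = p[probe_ids.index(j)]
            cross_M[(i, j)] = ci * cj / kd

    return EquilibriumState(
        probe_ids=probe_ids,
        site_keys=site_keys,
        probe_free_M=p,
        site_free_M=site_free,
        probe_total_M=totals,
        site_total_M=site_totals,
        self_M=self_M,
        cross_M=cross_M,
        bound_M=bound_M,
        residual=residual,
        iterations=iterations,
    )
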