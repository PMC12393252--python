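"""Nearest-neighbor duplex thermodynamics and dissociation constants.

Duplex enthalpy/entropy are summed from the unified DNA/DNA nearest-neighbor
stack table (shipped as a CSV resource), with one duplex-initiation
contribution per terminal base pair and the standard entropic salt
correction dS' = dS + 0.368 * N_stacks * ln[Na+].  Mismatched and gapped
alignment columns break the duplex into independent perfectly matched
segments; only segments of >= 2 bp contribute stacks (no mismatch or loop
energies — mismatches are treated as non-contributing, which slightly
underestimates off-target affinity).

Each binding partner pair may have several alternative duplex
configurations.  Their Boltzmann factors are summed into a bound-state
partition function Ka = sum_l exp(-dG_l / RT), and the dissociation constant
is its reciprocal: molar for bimolecular reactions (1 M standard state),
dimensionless for unimolecular hairpins.  Stronger binding (more negative
dG) therefore always means smaller Kd and more complex at equilibrium.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from importlib import resources

from .homology import BindingSiteMap, DimerAlignment
from .tiling import CandidateProbe, revcomp

__all__ = [
    "ThermoConditions",
    "DuplexEnergy",
    "DissociationConstants",
    "nn_parameters",
    "nn_duplex_energy",
    "kd_from_configs",
    "build_dissociation_constants",
]

GAS_CONSTANT_KCAL = 0.0019872  # kcal / (mol K)
SALT_ENTROPY_COEFF = 0.368  # cal / (mol K) per stack per ln[Na+]


@dataclass(frozen=True)
class ThermoConditions:
    """Hybridization conditions: 37 C and 300 mM Na+ by default."""

    temperature_K: float = 310.15
    sodium_M: float = 0.3
    R: float = GAS_CONSTANT_KCAL

    def __post_init__(self) -> None:
        if self.temperature_K <= 0 or self.sodium_M <= 0:
            raise ValueError("temperature_K and sodium_M must be positive")

    @property
    def RT(self) -> float:
        return self.R * self.temperature_K


@dataclass(frozen=True)
class DuplexEnergy:
    """dH (kcal/mol), salt-corrected dS (cal/(mol K)) and dG at T (kcal/mol)."""

    dH: float
    dS: float
    dG: float


def _load_nn_table() -> dict[str, tuple[float, float]]:
    table: dict[str, tuple[float, float]] = {}
    path = resources.files("probekit.data") / "nn_dna_unified.csv"
    with path.open() as fh:
        for row in csv.DictReader(filter(lambda ln: not ln.startswith("#"), fh)):
            table[row["term"]] = (float(row["dH"]), float(row["dS"]))
    # expand the 10 canonical stacks to all 16 dinucleotides via
    # reverse-complement symmetry (a stack equals its complementary stack)
    for a in "ACGT":
        for b in "ACGT":
            key = a + b
            if key not in table:
                table[key] = table[revcomp(key)]
    return table


_NN: dict[str, tuple[float, float]] | None = None


def nn_parameters() -> dict[str, tuple[float, float]]:
    global _NN
    if _NN is None:
        _NN = _load_nn_table()
    return _NN


def _matched_segments(aligned_pair: tuple[str, str]) -> list[str]:
    """Split an alignment (match = identical letters) at mismatches/gaps."""
    a, b = aligned_pair
    if len(a) != len(b):
        raise ValueError("aligned strings must have equal length")
    segs: list[str] = []
    cur: list[str] = []
    for x, y in zip(a, b):
        if x == y and x in "ACGT":
            cur.append(x)
        else:
            if cur:
                segs.append("".join(cur))
            cur = []
    if cur:
        segs.append("".join(cur))
    return segs


def nn_duplex_energy(aligned_pair: tuple[str, str],
                     conditions: ThermoConditions = ThermoConditions()) -> DuplexEnergy | None:
    """Hybridization free energy of one duplex configuration.

    Returns ``None`` ("no stable duplex") when no matched segment of at
    least 2 bp exists.  Initiation is applied once per duplex: one terminal
    term (A.T or G.C flavor) for each outermost matched base of the
    outermost stack-bearing segments.
    """
    segs = [s for s in _matched_segments(aligned_pair) if len(s) >= 2]
    if not segs:
        return None
    nn = nn_parameters()
    dH = 0.0
    dS = 0.0
    n_stacks = 0
    for seg in segs:
        for k in range(len(seg) - 1):
            h, s = nn[seg[k : k + 2]]
            dH += h
            dS += s
            n_stacks += 1
    for terminal in (segs[0][0], segs[-1][-1]):
        h, s = nn["init_AT" if terminal in "AT" else "init_GC"]
        dH += h
        dS += s
    dS_corr = dS + SALT_ENTROPY_COEFF * n_stacks * math.log(conditions.sodium_M)
    dG = dH - conditions.temperature_K * dS_corr / 1000.0
    return DuplexEnergy(dH=dH, dS=dS_corr, dG=dG)


def kd_from_configs(configs: list[DuplexEnergy], molecularity: str = "bi",
                    conditions: ThermoConditions = ThermoConditions()) -> float:
    """Aggregate configuration energies into a dissociation constant.

    Ka = sum_l exp(-dG_l/RT) (bound-state partition function); Kd = 1/Ka.
    No configurations means no stable interaction: Kd = +inf.
    """
    if molecularity not in {"uni", "bi"}:
        raise ValueError("molecularity must be 'uni' or 'bi'")
    if not configs:
        return math.inf
    ka = 0.0
    for cfg in configs:
        if not math.isfinite(cfg.dG):
            raise ValueError("non-finite dG in configuration")
        ka += math.exp(-cfg.dG / conditions.RT)
    return 1.0 / ka


@dataclass
class DissociationConstants:
    """Kd values for every self-hairpin, cross-dimer and probe-site reaction.

    Absent keys mean no stable interaction (Kd = +inf).  ``kd_cross`` stores
    both key orders.  ``dg_site``/``dg_self``/``dg_cross`` keep the most
    favorable single-configuration dG (kcal/mol) for ranking.
    """

    kd_self: dict[str, float] = field(default_factory=dict)
    kd_cross: dict[tuple[str, str], float] = field(default_factory=dict)
    kd_site: dict[tuple[str, str, str], float] = field(default_factory=dict)
    dg_self: dict[str, float] = field(default_factory=dict)
    dg_cross: dict[tuple[str, str], float] = field(default_factory=dict)
    dg_site: dict[tuple[str, str, str], float] = field(default_factory=dict)
    conditions: ThermoConditions = field(default_factory=ThermoConditions)

    def get_kd_self(self, probe_id: str) -> float:
        return self.kd_self.get(probe_id, math.inf)

    def get_kd_cross(self, i: str, j: str) -> float:
        return self.kd_cross.get((i, j), math.inf)

    def get_kd_site(self, probe_id: str, target_id: str, site_id: str) -> float:
        return self.kd_site.get((probe_id, target_id, site_id), math.inf)


def build_dissociation_constants(
    probes: list[CandidateProbe],
    site_map: BindingSiteMap,
    self_dimers: dict[str, list[DimerAlignment]] | None = None,
    cross_dimers: list[DimerAlignment] | None = None,
    conditions: ThermoConditions = ThermoConditions(),
) -> DissociationConstants:
    """Evaluate every recorded interaction's energies and aggregate to Kds.

    Probe-site Kds sum over all of that probe's duplex configurations within
    the site; hairpins are unimolecular, cross-dimers bimolecular over both
    orientations.
    """
    kds = DissociationConstants(conditions=conditions)
    known = {p.probe_id for p in probes}

    for site in site_map.all_sites():
        per_probe: dict[str, list[DuplexEnergy]] = {}
        for hit in site.configurations:
            if hit.probe_id not in known:
                continue
            e = nn_duplex_energy(hit.aligned_pair, conditions)
            if e is not None:
                per_probe.setdefault(hit.probe_id, []).append(e)
        for pid, energies in per_probe.items():
            key = (pid, site.target_id, site.site_id)
            kds.kd_site[key] = kd_from_configs(energies, "bi", conditions)
            kds.dg_site[key] = min(e.dG for e in energies)

    for pid, dimers in (self_dimers or {}).items():
        energies = [
            e for d in dimers if (e := nn_duplex_energy(d.aligned_pair, conditions)) is not None
        ]
        if energies:
            kds.kd_self[pid] = kd_from_configs(energies, "uni", conditions)
            kds.dg_self[pid] = min(e.dG for e in energies)

    by_pair: dict[tuple[str, str], list[DuplexEnergy]] = {}
    for d in cross_dimers or []:
        e = nn_duplex_energy(d.aligned_pair, conditions)
        if e is not None:
            by_pair.setdefault(tuple(sorted(d.probe_ids)), []).append(e)
    for (i, j), energies in by_pair.items():
        kd = kd_from_configs(energies, "bi", conditions)
        dg = min(e.dG for e in energies)
        kds.kd_cross[(i, j)] = kds.kd_cross[(j, i)] = kd
        kds.dg_cross[(i, j)] = kds.dg_cross[(j, i)] = dg
    return kds
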