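"""End-to-end design and evaluation pipelines.

``design_probe_set`` runs tiling -> homology search -> thermodynamics ->
prioritization-rank selection, then evaluates the selected set with the
mass-action equilibrium model and bound-probe statistics.
``evaluate_probe_set`` runs the same evaluation for an externally supplied
set of probe sequences, so a design can be re-scored (or refined)
independently of how it was produced.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from . import homology, selection, stats, thermo
from .equilibrium import (
    CellModel,
    ConcentrationProfile,
    EquilibriumState,
    site_total_concentration,
    solve_equilibrium,
)
from .reference import ExpressionMode, ExpressionTable, Transcriptome, expression_vector
from .tiling import CandidateProbe, revcomp, tile_candidates

logger = logging.getLogger(__name__)

__all__ = ["DesignConfig", "Evaluation", "DesignResult", "design_probe_set",
           "evaluate_probe_set", "refine_probe_set"]


@dataclass(frozen=True)
class DesignConfig:
    """Run parameters; defaults are the standard 20-nt / 37 C / 300 mM Na+
    design conditions with 5 nM probe and a 10 um (Jurkat-sized) cell."""

    probe_length: int = 20
    min_spacing: int = 3
    max_probes: int = 48
    temperature_C: float = 37.0
    sodium_M: float = 0.3
    probe_conc_nM: float = 5.0
    cell_radius_um: float = 10.0
    min_match: int = 15
    word_size: int = 7
    weight_offtargets_by_expression: bool = False
    tol: float = 1e-12
    max_iter: int = 10_000
    damping: float = 0.5

    @property
    def conditions(self) -> thermo.ThermoConditions:
        return thermo.ThermoConditions(
            temperature_K=self.temperature_C + 273.15, sodium_M=self.sodium_M
        )

    @property
    def cell(self) -> CellModel:
        return CellModel(cell_radius_um=self.cell_radius_um)


@dataclass
class Evaluation:
    """Equilibrium + statistics for one probe set under one expression mode."""

    probes: list[CandidateProbe]
    site_map: homology.BindingSiteMap
    kds: thermo.DissociationConstants
    state: EquilibriumState
    site_probs: stats.SiteBoundProbability
    dists: stats.BoundCountDistribution
    report: stats.SpecificityReport
    problem_by_total: list[tuple[str, float]]
    problem_by_multi: list[tuple[str, float]]


@dataclass
class DesignResult:
    candidates: list[CandidateProbe]
    ranked: list[selection.ProbeRank]
    selection: selection.SelectionResult
    rrna_flagged: set[str]
    evaluation: Evaluation

    @property
    def selected_probes(self) -> list[CandidateProbe]:
        by_id = {c.probe_id: c for c in self.candidates}
        return [by_id[pid] for pid in self.selection.selected]


def _cross_dg_cache(candidates: list[CandidateProbe], conditions: thermo.ThermoConditions):
    by_id = {c.probe_id: c for c in candidates}
    aligner = homology.make_aligner()

    @lru_cache(maxsize=None)
    def cross_dg(i: str, j: str) -> float:
        a, b = sorted((i, j))
        dims = homology.cross_alignments(by_id[a], by_id[b], aligner=aligner)
        best = 0.0
        for d in dims:
            e = thermo.nn_duplex_energy(d.aligned_pair, conditions)
            if e is not None:
                best = min(best, e.dG)
        return best

    return cross_dg


def _probe_hits(candidates: list[CandidateProbe], transcriptome: Transcriptome,
                config: DesignConfig) -> list[homology.AlignmentHit]:
    index = homology.build_seed_index(transcriptome, config.word_size)
    aligner = homology.make_aligner()
    hits: list[homology.AlignmentHit] = []
    for cand in candidates:
        hits.extend(homology.find_hits(cand, index, config.min_match, aligner=aligner))
    return hits


def evaluate_probe_set(
    probes: list[CandidateProbe],
    transcriptome: Transcriptome,
    on_target_ids: set[str],
    mode: ExpressionMode = ExpressionMode(),
    expression_table: ExpressionTable | None = None,
    config: DesignConfig = DesignConfig(),
) -> Evaluation:
    """Equilibrium simulation and specificity statistics for a probe set."""
    if not probes:
        raise ValueError("empty probe set")
    conditions = config.conditions
    hits = _probe_hits(probes, transcriptome, config)
    site_map = homology.build_site_map(hits, transcriptome)
    self_dimers = {p.probe_id: homology.self_alignments(p) for p in probes}
    aligner = homology.make_aligner()
    cross_dimers: list[homology.DimerAlignment] = []
    for a in range(len(probes)):
        for b in range(a, len(probes)):
            cross_dimers.extend(
                homology.cross_alignments(probes[a], probes[b], aligner=aligner)
            )
    kds = thermo.build_dissociation_constants(
        probes, site_map, self_dimers, cross_dimers, conditions
    )

    expr = expression_vector(expression_table, mode, transcriptome)
    cell = config.cell
    conc = ConcentrationProfile(
        probe_total_M={p.probe_id: config.probe_conc_nM * 1e-9 for p in probes},
        site_total_M={
            (s.target_id, s.site_id): site_total_concentration(expr[s.target_id], cell)
            for s in site_map.all_sites()
        },
    )
    state = solve_equilibrium(kds, conc, tol=config.tol, max_iter=config.max_iter,
                              damping=config.damping)
    site_probs = stats.site_bound_probability(state, kds)
    dists = stats.target_pmfs(site_probs, site_map)
    n_on, n_off = stats.on_off_counts(dists, expr, on_target_ids)
    load = stats.specificity_load(n_on, n_off)
    probe_order = [p.probe_id for p in probes]
    per_probe, cumulative, ratio = stats.offtarget_accumulation(
        site_probs, site_map, expr, on_target_ids, probe_order
    )
    by_total, by_multi = stats.identify_problem_probes(
        site_probs, site_map, expr, on_target_ids, probe_order
    )
    report = stats.SpecificityReport(
        n_on=n_on,
        n_off=n_off,
        specificity_load=load,
        expected_off_per_probe=per_probe,
        cumulative_off=cumulative,
        off_per_on_ratio=ratio,
        mode=mode,
    )
    return Evaluation(
        probes=probes,
        site_map=site_map,
        kds=kds,
        state=state,
        site_probs=site_probs,
        dists=dists,
        report=report,
        problem_by_total=by_total,
        problem_by_multi=by_multi,
    )


def design_probe_set(
    transcriptome: Transcriptome,
    target_id: str,
    on_target_ids: set[str] | None = None,
    mode: ExpressionMode = ExpressionMode(),
    expression_table: ExpressionTable | None = None,
    config: DesignConfig = DesignConfig(),
) -> DesignResult:
    """Design a probe set against one target transcript.

    ``on_target_ids`` defaults to all isoforms of the target's gene; hits on
    any other transcript are off-targets.
    """
    target = transcriptome[target_id]
    if on_target_ids is None:
        on_target_ids = {r.transcript_id for r in transcriptome.isoforms_of(target.gene_id)}
    conditions = config.conditions

    candidates = tile_candidates(target, config.probe_length)
    logger.info("tiled %d candidates on %s", len(candidates), target_id)

    hits = _probe_hits(candidates, transcriptome, config)
    site_map = homology.build_site_map(hits, transcriptome)
    rrna_flagged = homology.flag_rrna_probes(site_map, transcriptome)
    logger.info("%d retained hits, %d rRNA-flagged probes", len(hits), len(rrna_flagged))

    self_dimers = {c.probe_id: homology.self_alignments(c) for c in candidates}
    kds = thermo.build_dissociation_constants(candidates, site_map, self_dimers, None, conditions)

    expr = (
        expression_vector(expression_table, mode, transcriptome)
        if config.weight_offtargets_by_expression
        else None
    )
    ranked = selection.rank_candidates(
        candidates, site_map, kds, on_target_ids,
        expression=expr, weight_by_expression=config.weight_offtargets_by_expression,
    )
    sel = selection.select_probes(
        ranked,
        candidates,
        max_probes=config.max_probes,
        min_spacing=config.min_spacing,
        rrna_flagged=rrna_flagged,
        cross_dg=_cross_dg_cache(candidates, conditions),
    )
    logger.info("selected %d probes", len(sel.selected))

    by_id = {c.probe_id: c for c in candidates}
    selected = [by_id[pid] for pid in sel.selected]
    evaluation = evaluate_probe_set(
        selected, transcriptome, on_target_ids, mode, expression_table, config
    )
    return DesignResult(
        candidates=candidates,
        ranked=ranked,
        selection=sel,
        rrna_flagged=rrna_flagged,
        evaluation=evaluation,
    )


def locate_probes(sequences: dict[str, str], transcriptome: Transcriptome,
                  target_id: str) -> tuple[list[CandidateProbe], list[str]]:
    """Map probe sequences onto the target transcript (exact antisense match).

    Returns the located probes (renamed canonically by position, input order
    preserved) and the names of sequences that could not be placed.
    """
    target = transcriptome[target_id]
    located, missing = [], []
    for name, seq in sequences.items():
        window = revcomp(seq.upper().replace("U", "T"))
        start = target.sequence.find(window)
        if start < 0:
            missing.append(name)
            continue
        located.append(
            CandidateProbe(
                probe_id=f"{target_id}_p{start}", target_id=target_id,
                start=start, sequence=seq.upper().replace("U", "T"),
            )
        )
    return located, missing


def refine_probe_set(
    sequences: dict[str, str],
    transcriptome: Transcriptome,
    target_id: str,
    on_target_ids: set[str] | None = None,
    mode: ExpressionMode = ExpressionMode(),
    expression_table: ExpressionTable | None = None,
    config: DesignConfig = DesignConfig(),
    remove_worst: int = 0,
) -> tuple[Evaluation, list[str], list[str]]:
    """Evaluate an existing probe set (no re-tiling) and propose removals.

    Returns (evaluation, kept probe ids after removing the ``remove_worst``
    highest off-target contributors with positive contribution, skipped
    sequence names).
    """
    if not sequences:
        raise ValueError("empty probe set")
    if on_target_ids is None:
        gene = transcriptome[target_id].gene_id
        on_target_ids = {r.transcript_id for r in transcriptome.isoforms_of(gene)}
    probes, missing = locate_probes(sequences, transcriptome, target_id)
    if missing:
        logger.warning("could not locate %d probe(s): %s", len(missing), missing)
    if not probes:
        raise ValueError("no probe sequence could be located on the target")
    evaluation = evaluate_probe_set(
        probes, transcriptome, on_target_ids, mode, expression_table, config
    )
    removals = [pid for pid, contrib in evaluation.problem_by_total[:remove_worst] if contrib > 0]
    kept = [p.probe_id for p in probes if p.probe_id not in removals]
    return evaluation, kept, missing
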