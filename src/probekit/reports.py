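"""Writers for probe-set artifacts: TSV, FASTA, BED and the JSON report.

Human-readable tables use 1-based closed coordinates; BED stays 0-based
half-open with the transcript id as the chromosome name.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .pipeline import DesignResult, Evaluation
from .tiling import CandidateProbe

__all__ = ["probe_table", "write_probe_tsv", "write_probe_fasta", "write_bed",
           "evaluation_report", "write_report_json"]


def probe_table(result: DesignResult) -> pd.DataFrame:
    ranks = {r.probe_id: r for r in result.ranked}
    rows = []
    for pid in result.selection.selected:
        cand = next(c for c in result.candidates if c.probe_id == pid)
        r = ranks[pid]
        rows.append(
            {
                "probe_id": pid,
                "target": cand.target_id,
                "start": cand.start + 1,  # 1-based closed for reports
                "end": cand.end,
                "sequence": cand.sequence,
                "phase": result.selection.phase_of.get(pid, 0),
                "n_offtargets": r.n_offtargets,
                "dG_on_kcal_mol": r.dg_on,
                "energy_gap_kcal_mol": r.energy_gap,
            }
        )
    return pd.DataFrame(rows)


def write_probe_tsv(result: DesignResult, path: str | Path) -> None:
    probe_table(result).to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_probe_fasta(probes: list[CandidateProbe], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in probes:
            fh.write(f">{p.probe_id}\n{p.sequence}\n")


def write_bed(probes: list[CandidateProbe], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in probes:
            fh.write(f"{p.target_id}\t{p.start}\t{p.end}\t{p.probe_id}\t0\t-\n")


def evaluation_report(ev: Evaluation) -> dict:
    """JSON-serializable summary of an evaluation (deterministic key order)."""
    return {
        "n_probes": len(ev.probes),
        "probe_ids": [p.probe_id for p in ev.probes],
        "expression_mode": ev.report.mode.mode.value,
        "cell_line": ev.report.mode.cell_line,
        "n_sites_per_target": dict(sorted(ev.site_map.n_sites.items())),
        "equilibrium": {
            "iterations": ev.state.iterations,
            "residual": ev.state.residual,
        },
        "site_bound_probability": {
            f"{tid}:{sid}": p for (tid, sid), p in sorted(ev.site_probs.p.items())
        },
        "Non": [float(x) for x in ev.report.n_on],
        "Noff": [float(x) for x in ev.report.n_off],
        "specificity_load": ev.report.specificity_load,
        "off_per_on_ratio": ev.report.off_per_on_ratio,
        "expected_off_per_probe": dict(sorted(ev.report.expected_off_per_probe.items())),
        "cumulative_off": ev.report.cumulative_off,
        "problem_probes_by_total": ev.problem_by_total,
        "problem_probes_by_multi_site": ev.problem_by_multi,
    }


def write_report_json(report: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
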