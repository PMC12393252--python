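"""Probe on/off-target site enumeration and probe-probe dimer alignments.

Hybridization hits are found with a BLAST-style seed-and-extend strategy:
exact word seeds (default word size 7) against the reverse complement of
each transcript — the hybridization-relevant orientation for an antisense
DNA probe binding an RNA — followed by affine-gap local alignment (reward
+1, mismatch -3, gap open 5, gap extend 2) restricted to a window around the
seeded diagonal.  Hits with fewer than 15 matched nucleotides are discarded:
shorter stretches of complementarity do not contribute meaningfully to
hybridization at FISH conditions.

Overlapping retained hits on a target are clustered (single linkage on
interval overlap) into non-overlapping binding sites; each hit becomes one
duplex configuration of its site.  The same aligner evaluates probe
self-hairpin stems (brute-force enumeration of complementary substring
pairs) and the two cross-dimer orientations between probe pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

from Bio import Align

from .reference import Biotype, Transcriptome
from .tiling import CandidateProbe, complement, revcomp

logger = logging.getLogger(__name__)

__all__ = [
    "AlignmentHit",
    "Site",
    "BindingSiteMap",
    "DimerAlignment",
    "SeedIndex",
    "build_seed_index",
    "find_hits",
    "brute_force_hits",
    "build_site_map",
    "flag_rrna_probes",
    "self_alignments",
    "cross_alignments",
    "make_aligner",
]

#: BLAST-equivalent scoring: reward 1, penalty -3, gap open 5, gap extend 2
#: (a gap of length k costs 5 + 2k, hence open_gap_score = -(5 + 2)).
MATCH_SCORE = 1
MISMATCH_SCORE = -3
GAP_OPEN = -7
GAP_EXTEND = -2

MIN_MATCH_DEFAULT = 15
WORD_SIZE_DEFAULT = 7


def make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = MATCH_SCORE
    aligner.mismatch_score = MISMATCH_SCORE
    aligner.open_gap_score = GAP_OPEN
    aligner.extend_gap_score = GAP_EXTEND
    return aligner


@dataclass(frozen=True)
class AlignmentHit:
    """A retained probe-target local alignment.

    ``target_span`` is 0-based half-open on the transcript in sense
    orientation.  ``aligned_pair`` holds the gapped probe string and the
    gapped *complement* of the target (so matched positions show identical
    letters) — exactly the duplex configuration handed to the thermodynamic
    model.
    """

    probe_id: str
    target_id: str
    probe_span: tuple[int, int]
    target_span: tuple[int, int]
    matched_nt: int
    score: int
    aligned_pair: tuple[str, str]


@dataclass
class Site:
    """One non-overlapping binding region on a target with its duplex configs."""

    site_id: str
    target_id: str
    target_span: tuple[int, int]
    configurations: list[AlignmentHit] = field(default_factory=list)

    def probe_ids(self) -> set[str]:
        return {h.probe_id for h in self.configurations}


@dataclass
class BindingSiteMap:
    sites: dict[str, list[Site]] = field(default_factory=dict)  # target_id -> ordered sites

    @property
    def n_sites(self) -> dict[str, int]:
        return {tid: len(ss) for tid, ss in self.sites.items()}

    def all_sites(self) -> list[Site]:
        return [s for ss in self.sites.values() for s in ss]


class Orientation(str, Enum):
    ANTIPARALLEL = "antiparallel"
    PARALLEL = "parallel"


@dataclass(frozen=True)
class DimerAlignment:
    """A probe self-hairpin stem or a probe-probe cross-dimer configuration."""

    kind: str  # "self" | "cross"
    probe_ids: tuple[str, ...]
    orientation: Orientation
    aligned_pair: tuple[str, str]
    matched_nt: int


class SeedIndex:
    """Exact k-mer index over the reverse complement of every transcript."""

    def __init__(self, transcriptome: Transcriptome, word_size: int = WORD_SIZE_DEFAULT):
        if word_size < 4:
            raise ValueError("word_size must be >= 4")
        self.word_size = word_size
        self.transcriptome = transcriptome
        self.rc_seqs: dict[str, str] = {
            rec.transcript_id: revcomp(rec.sequence) for rec in transcriptome
        }
        self.index: dict[str, list[tuple[str, int]]] = {}
        for tid, rc in self.rc_seqs.items():
            for pos in range(len(rc) - word_size + 1):
                word = rc[pos : pos + word_size]
                if "N" in word:
                    continue
                self.index.setdefault(word, []).append((tid, pos))


def build_seed_index(transcriptome: Transcriptome, word_size: int = WORD_SIZE_DEFAULT) -> SeedIndex:
    return SeedIndex(transcriptome, word_size)


def _matched_nt(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x == y and x != "-")


def _hit_from_alignment(aln, probe: CandidateProbe, target_id: str, rc_len: int,
                        window_offset: int) -> AlignmentHit:
    (p0, p1) = int(aln.coordinates[0][0]), int(aln.coordinates[0][-1])
    (t0, t1) = int(aln.coordinates[1][0]) + window_offset, int(aln.coordinates[1][-1]) + window_offset
    a, b = str(aln[0]), str(aln[1])
    return AlignmentHit(
        probe_id=probe.probe_id,
        target_id=target_id,
        probe_span=(p0, p1),
        # map coordinates on the reverse complement back to sense orientation
        target_span=(rc_len - t1, rc_len - t0),
        matched_nt=_matched_nt(a, b),
        score=int(aln.score),
        aligned_pair=(a, b),
    )


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for lo, hi in sorted(intervals):
        if merged and lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    return [(lo, hi) for lo, hi in merged]


def find_hits(probe: CandidateProbe, index: SeedIndex,
              min_match: int = MIN_MATCH_DEFAULT,
              aligner: Align.PairwiseAligner | None = None,
              pad: int = 10) -> list[AlignmentHit]:
    """Seed-and-extend search of one probe against the whole transcriptome.

    Every exact word match seeds a local alignment of the probe against a
    window around the seeded region; hits with ``matched_nt >= min_match``
    are retained, deduplicated by (target, span) keeping the best score.
    The probe's own source window is always recovered as the on-target hit.
    """
    if aligner is None:
        aligner = make_aligner()
    w = index.word_size
    pseq = probe.sequence
    # collect candidate windows on each rc transcript
    windows: dict[str, list[tuple[int, int]]] = {}
    for q in range(len(pseq) - w + 1):
        word = pseq[q : q + w]
        for tid, pos in index.index.get(word, ()):
            lo = max(0, pos - q - pad)
            hi = min(len(index.rc_seqs[tid]), pos - q + len(pseq) + pad)
            windows.setdefault(tid, []).append((lo, hi))

    best: dict[tuple[str, tuple[int, int]], AlignmentHit] = {}
    for tid, ivs in windows.items():
        rc = index.rc_seqs[tid]
        for lo, hi in _merge_intervals(ivs):
            alns = aligner.align(pseq, rc[lo:hi])
            if alns.score <= 0:
                continue
            hit = _hit_from_alignment(alns[0], probe, tid, len(rc), lo)
            if hit.matched_nt < min_match:
                continue
            key = (tid, hit.target_span)
            if key not in best or hit.score > best[key].score:
                best[key] = hit
    return sorted(best.values(), key=lambda h: (h.target_id, h.target_span))


def brute_force_hits(probe: CandidateProbe, transcriptome: Transcriptome,
                     min_match: int = MIN_MATCH_DEFAULT,
                     aligner: Align.PairwiseAligner | None = None) -> list[AlignmentHit]:
    """Full (unseeded) local alignment of the probe against every transcript.

    Independent slow path used to validate the seeded search: the single best
    local alignment per transcript, retained under the same threshold.
    """
    if aligner is None:
        aligner = make_aligner()
    out = []
    for rec in transcriptome:
        rc = revcomp(rec.sequence)
        alns = aligner.align(probe.sequence, rc)
        if alns.score <= 0:
            continue
        hit = _hit_from_alignment(alns[0], probe, rec.transcript_id, len(rc), 0)
        if hit.matched_nt >= min_match:
            out.append(hit)
    return sorted(out, key=lambda h: (h.target_id, h.target_span))


def build_site_map(hits: list[AlignmentHit], transcriptome: Transcriptome) -> BindingSiteMap:
    """Cluster overlapping hit spans per target into non-overlapping sites.

    Single-linkage on interval overlap: each cluster becomes one Site whose
    span is the union of its member spans; every retained hit lands in
    exactly one site.
    """
    by_target: dict[str, list[AlignmentHit]] = {}
    for h in hits:
        by_target.setdefault(h.target_id, []).append(h)

    site_map = BindingSiteMap()
    for tid in transcriptome.transcript_ids:
        if tid not in by_target:
            continue
        hs = sorted(by_target[tid], key=lambda h: h.target_span)
        sites: list[Site] = []
        cur: list[AlignmentHit] = []
        cur_span: list[int] | None = None
        for h in hs:
            lo, hi = h.target_span
            if cur_span is not None and lo < cur_span[1]:
                cur_span[1] = max(cur_span[1], hi)
                cur.append(h)
            else:
                if cur:
                    sites.append(Site(f"{tid}:s{len(sites)}", tid, tuple(cur_span), cur))
                cur, cur_span = [h], [lo, hi]
        if cur:
            sites.append(Site(f"{tid}:s{len(sites)}", tid, tuple(cur_span), cur))
        site_map.sites[tid] = sites
    return site_map


def flag_rrna_probes(site_map: BindingSiteMap, transcriptome: Transcriptome) -> set[str]:
    """Probes with any retained hit on an rRNA transcript (to be excluded)."""
    flagged: set[str] = set()
    for tid, sites in site_map.sites.items():
        if transcriptome[tid].biotype == Biotype.RRNA:
            for site in sites:
                flagged |= site.probe_ids()
    return flagged


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def self_alignments(probe: CandidateProbe, top_k: int = 5, min_stem: int = 3,
                    min_loop: int = 3) -> list[DimerAlignment]:
    """Enumerate hairpin stems: complementary antiparallel substring pairs.

    All maximal runs of base pairs (a, b) with a + b constant, ``probe[a]``
    complementary to ``probe[b]`` and a loop of at least ``min_loop`` nt are
    found by brute force; the ``top_k`` longest stems (>= ``min_stem`` bp)
    are returned as configurations.  A homopolymer has none.
    """
    seq = probe.sequence
    n = len(seq)
    stems: list[tuple[int, int, int]] = []  # (a0, a1 inclusive, s = a + b)
    for s in range(3, 2 * n - 3):
        # pairs (a, b=s-a) with 0 <= a < b <= n-1; innermost pair must leave
        # a loop of >= min_loop unpaired bases (b - a - 1 >= min_loop)
        a_lo = max(0, s - n + 1)
        a_hi = (s - 1) // 2
        a_max_loop = (s - min_loop - 1) // 2
        run_start: int | None = None
        for a in range(a_lo, a_hi + 2):  # one past the end to flush the last run
            paired = a <= a_hi and _COMP.get(seq[a]) == seq[s - a]
            if paired:
                if run_start is None:
                    run_start = a
                continue
            if run_start is not None:
                a_end = min(a - 1, a_max_loop)
                if a_end - run_start + 1 >= min_stem:
                    stems.append((run_start, a_end, s))
                run_start = None
    stems.sort(key=lambda t: (-(t[1] - t[0] + 1), t[0], t[2]))
    out = []
    for a0, a1, s in stems[:top_k]:
        top = seq[a0 : a1 + 1]
        # bottom strand pairs base-for-base; in match convention it equals top
        out.append(
            DimerAlignment(
                kind="self",
                probe_ids=(probe.probe_id,),
                orientation=Orientation.ANTIPARALLEL,
                aligned_pair=(top, top),
                matched_nt=len(top),
            )
        )
    return out


def cross_alignments(probe_i: CandidateProbe, probe_j: CandidateProbe,
                     aligner: Align.PairwiseAligner | None = None,
                     min_match: int = 2) -> list[DimerAlignment]:
    """Best local alignment of a probe pair in each duplex orientation.

    Antiparallel (5'->3' vs 3'->5') and parallel (5'->3' vs 5'->3')
    configurations.  The pair is canonically ordered by probe id before
    aligning so that cross(i, j) and cross(j, i) are identical.  Stems
    shorter than ``min_match`` (no stack) are dropped; two probes with no
    complementarity yield an empty list (no stable dimer).
    """
    if aligner is None:
        aligner = make_aligner()
    p, q = sorted([probe_i, probe_j], key=lambda c: c.probe_id)
    out: list[DimerAlignment] = []
    for orientation, other in (
        (Orientation.ANTIPARALLEL, revcomp(q.sequence)),
        (Orientation.PARALLEL, complement(q.sequence)),
    ):
        alns = aligner.align(p.sequence, other)
        if alns.score <= 0:
            continue
        aln = alns[0]
        a, b = str(aln[0]), str(aln[1])
        m = _matched_nt(a, b)
        if m < min_match:
            continue
        out.append(
            DimerAlignment(
                kind="cross",
                probe_ids=(p.probe_id, q.probe_id),
                orientation=orientation,
                aligned_pair=(a, b),
                matched_nt=m,
            )
        )
    return out
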