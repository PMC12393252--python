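"""Candidate probe enumeration by exhaustive tiling of the target transcript.

Every window of the target of the configured probe length becomes an
antisense DNA candidate (written 5'->3').  No GC/Tm pre-filters are applied:
ranking and selection happen downstream on thermodynamic and off-target
grounds, so every overlapping window must be retained here.
"""

from __future__ import annotations

from dataclasses import dataclass
import logging

from .reference import TranscriptRecord

logger = logging.getLogger(__name__)

__all__ = ["CandidateProbe", "tile_candidates", "revcomp", "complement"]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_IUPAC = set("ACGTN")


def complement(seq: str) -> str:
    """Base-wise complement (no reversal)."""
    if set(seq) - _IUPAC:
        raise ValueError(f"non-IUPAC characters in {seq!r}")
    return seq.translate(_COMPLEMENT)


def revcomp(seq: str) -> str:
    """Reverse complement over the DNA alphabet (+N)."""
    return complement(seq)[::-1]


@dataclass(frozen=True)
class CandidateProbe:
    """A tiled antisense DNA oligo with 0-based coordinates on its target."""

    probe_id: str
    target_id: str
    start: int
    sequence: str  # reverse complement of target[start:start+length], 5'->3'

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def end(self) -> int:
        return self.start + self.length


def tile_candidates(target: TranscriptRecord, probe_length: int = 20) -> list[CandidateProbe]:
    """Enumerate one candidate per start offset 0..L-k, in ascending order.

    Windows containing N are skipped (logged).  Probe ids are deterministic:
    ``{target_id}_p{start}``.
    """
    if probe_length < 10:
        raise ValueError(f"probe_length must be >= 10, got {probe_length}")
    if target.length < probe_length:
        raise ValueError(
            f"target {target.transcript_id} ({target.length} nt) shorter than probe length {probe_length}"
        )
    out: list[CandidateProbe] = []
    seq = target.sequence
    for start in range(target.length - probe_length + 1):
        window = seq[start : start + probe_length]
        if "N" in window:
            logger.debug("skipping window at %d (contains N)", start)
            continue
        out.append(
            CandidateProbe(
                probe_id=f"{target.transcript_id}_p{start}",
                target_id=target.transcript_id,
                start=start,
                sequence=revcomp(window),
            )
        )
    return out
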