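"""Deterministic synthetic transcriptomes with planted off-target homologies.

Generates random decoy transcripts around one or more target transcripts
and plants exact complementary copies of chosen target windows into decoys,
so the ground truth of every recoverable off-target site is known.  Random
sequences are screened against the target's 15-mer content and re-rolled on
collision, keeping the manifest exact: the homology search must find the
planted sites (length >= 15) plus the on-target windows and nothing else.

The canned ``arf4_like_scenario`` miniaturizes a hard design case: a
~1.5 kb mRNA with a second isoform, 30 decoys including one rRNA, eight
planted off-target homologies of 15-20 nt, and log-normal expression.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .reference import Biotype, Transcriptome, TranscriptRecord, ExpressionTable, ExpressionLevel

__all__ = ["PlantSpec", "FixtureSpec", "Fixture", "generate_fixture", "arf4_like_scenario"]

MIN_HIT_NT = 15  # screening length for accidental homologies


@dataclass(frozen=True)
class PlantSpec:
    """Plant ``identity_nt`` exactly matching bases of the target window
    starting at ``window_start`` into decoy ``decoy`` at ``decoy_start``."""

    window_start: int
    window_len: int
    decoy: int
    identity_nt: int
    decoy_start: int | None = None

    def __post_init__(self) -> None:
        if self.identity_nt > self.window_len:
            raise ValueError(
                f"identity_nt {self.identity_nt} exceeds window length {self.window_len}"
            )


@dataclass
class FixtureSpec:
    seed: int = 0
    n_targets: int = 1
    target_length_nt: tuple[int, int] = (1400, 1600)
    n_decoys: int = 10
    decoy_length_nt: tuple[int, int] = (400, 900)
    planted: list[PlantSpec] = field(default_factory=list)
    include_rrna_decoy: bool = False
    # optional homology planted into the rRNA decoy (its ``decoy`` is ignored)
    rrna_plant: PlantSpec | None = None
    gc_fraction: float = 0.5
    # log-normal nTPM parameters (natural-log mean and sigma); median ~e^mu
    expression_lognorm: tuple[float, float] = (3.0, 1.5)
    contexts: tuple[str, ...] = ("lineA", "lineB", "lineC")
    second_isoform: bool = False
    isoform_gap: tuple[int, int] = (500, 800)  # internal deletion of isoform 2


@dataclass
class Fixture:
    transcriptome: Transcriptome
    expression: ExpressionTable
    manifest: dict
    spec: FixtureSpec


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=probs))


def _kmers(seq: str, k: int = MIN_HIT_NT) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def _plant_block(rng: np.random.Generator, seq: str, block: str, pos: int,
                 target: str, t0: int) -> str:
    """Insert ``block`` (== target[t0:t0+len]) into ``seq`` at ``pos`` and
    force several flanking bases to differ from the target's flanks, so the
    identity of the planted homology is exactly len(block): a probe (<= 20
    nt) overhangs a >= 15 nt block by at most 5 nt, and five consecutive
    forced mismatches make any local-alignment extension strictly losing."""
    seq = seq[:pos] + block + seq[pos + len(block) :]
    for step in range(1, 6):
        for d_idx, t_idx in (
            (pos - step, t0 - step),
            (pos + len(block) + step - 1, t0 + len(block) + step - 1),
        ):
            if 0 <= d_idx < len(seq) and 0 <= t_idx < len(target):
                if seq[d_idx] == target[t_idx]:
                    alt = rng.choice([b for b in "ACGT" if b != target[t_idx]])
                    seq = seq[:d_idx] + alt + seq[d_idx + 1 :]
    return seq


def generate_fixture(spec: FixtureSpec) -> Fixture:
    """Build the transcriptome, expression table and ground-truth manifest."""
    rng = np.random.default_rng(spec.seed)

    # targets: re-roll until free of internal repeated 15-mers
    targets: list[str] = []
    for t in range(spec.n_targets):
        length = int(rng.integers(spec.target_length_nt[0], spec.target_length_nt[1] + 1))
        while True:
            seq = _random_seq(rng, length, spec.gc_fraction)
            if len(_kmers(seq)) == length - MIN_HIT_NT + 1:
                targets.append(seq)
                break
    target_kmers: set[str] = set()
    for seq in targets:
        target_kmers |= _kmers(seq)

    records: list[TranscriptRecord] = []
    iso_counts: dict[str, int] = {}
    for t, seq in enumerate(targets):
        gene = f"GENE{t}"
        records.append(TranscriptRecord(f"TARGET{t}", gene, seq, Biotype.MRNA))
        iso_counts[gene] = 1
        if spec.second_isoform:
            gap = int(rng.integers(spec.isoform_gap[0], spec.isoform_gap[1] + 1))
            lo = int(rng.integers(100, len(seq) - gap - 100))
            records.append(
                TranscriptRecord(f"TARGET{t}.iso2", gene, seq[:lo] + seq[lo + gap :], Biotype.MRNA)
            )
            iso_counts[gene] = 2

    plants_by_decoy: dict[int, list[PlantSpec]] = {}
    for plant in spec.planted:
        if plant.window_start + plant.window_len > len(targets[0]):
            raise ValueError(f"planted window out of bounds: {plant}")
        plants_by_decoy.setdefault(plant.decoy, []).append(plant)

    manifest_sites: list[dict] = []
    for d in range(spec.n_decoys):
        length = int(rng.integers(spec.decoy_length_nt[0], spec.decoy_length_nt[1] + 1))
        plants = plants_by_decoy.get(d, [])
        for _ in range(1000):
            seq = _random_seq(rng, length, spec.gc_fraction)
            if _kmers(seq) & target_kmers:
                continue  # accidental homology with a target: re-roll
            break
        else:
            raise RuntimeError(f"could not generate collision-free decoy {d}")
        placed: list[tuple[int, int]] = []
        for plant in plants:
            # center the exact-identity block inside the stated window
            off = (plant.window_len - plant.identity_nt) // 2
            block = targets[0][
                plant.window_start + off : plant.window_start + off + plant.identity_nt
            ]
            if plant.decoy_start is not None:
                pos = plant.decoy_start
            else:
                for _ in range(1000):
                    pos = int(rng.integers(0, length - plant.identity_nt + 1))
                    if all(
                        pos + plant.identity_nt <= lo or pos >= hi for lo, hi in placed
                    ):
                        break
                else:
                    raise RuntimeError(f"no room to plant {plant} in decoy {d}")
            seq = _plant_block(rng, seq, block, pos, targets[0], plant.window_start + off)
            placed.append((pos, pos + plant.identity_nt))
            if plant.identity_nt >= MIN_HIT_NT:
                manifest_sites.append(
                    {
                        "target_window_start": plant.window_start + off,
                        "identity_nt": plant.identity_nt,
                        "decoy_id": f"DECOY{d}",
                        "decoy_span": [pos, pos + plant.identity_nt],
                    }
                )
        records.append(TranscriptRecord(f"DECOY{d}", f"DGENE{d}", seq, Biotype.MRNA))
        iso_counts[f"DGENE{d}"] = 1

    if spec.include_rrna_decoy:
        length = int(rng.integers(spec.decoy_length_nt[0], spec.decoy_length_nt[1] + 1))
        for _ in range(1000):
            seq = _random_seq(rng, length, spec.gc_fraction)
            if not (_kmers(seq) & target_kmers):
                break
        if spec.rrna_plant is not None:
            plant = spec.rrna_plant
            off = (plant.window_len - plant.identity_nt) // 2
            block = targets[0][
                plant.window_start + off : plant.window_start + off + plant.identity_nt
            ]
            pos = plant.decoy_start if plant.decoy_start is not None else length // 2
            seq = _plant_block(rng, seq, block, pos, targets[0], plant.window_start + off)
            if plant.identity_nt >= MIN_HIT_NT:
                manifest_sites.append(
                    {
                        "target_window_start": plant.window_start + off,
                        "identity_nt": plant.identity_nt,
                        "decoy_id": "RRNA0",
                        "decoy_span": [pos, pos + plant.identity_nt],
                    }
                )
        records.append(TranscriptRecord("RRNA0", "RRNA_GENE0", seq, Biotype.RRNA))
        iso_counts["RRNA_GENE0"] = 1

    transcriptome = Transcriptome(records, iso_counts)

    mu, sigma = spec.expression_lognorm
    values = {
        ctx: rng.lognormal(mu, sigma, size=len(records)) for ctx in spec.contexts
    }
    df = pd.DataFrame(values, index=[r.transcript_id for r in records])
    if spec.include_rrna_decoy:
        df.loc["RRNA0"] *= 100.0  # rRNA dominates cellular RNA
    expression = ExpressionTable(df, ExpressionLevel.TRANSCRIPT)

    manifest = {
        "seed": spec.seed,
        "targets": [f"TARGET{t}" for t in range(spec.n_targets)],
        "on_target_ids": [r.transcript_id for r in records if r.transcript_id.startswith("TARGET")],
        "planted_sites": manifest_sites,
        "rrna_ids": [r.transcript_id for r in records if r.biotype == Biotype.RRNA],
    }
    return Fixture(transcriptome=transcriptome, expression=expression, manifest=manifest, spec=spec)


def write_fixture(fixture: Fixture, outdir: str | Path) -> dict[str, Path]:
    """Write FASTA + TSV annotation + TSV expression + JSON manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "transcriptome.fasta",
        "annotation": outdir / "annotation.tsv",
        "expression": outdir / "expression.tsv",
        "manifest": outdir / "manifest.json",
    }
    with open(paths["fasta"], "w") as fh:
        for rec in fixture.transcriptome:
            fh.write(f">{rec.transcript_id}\n")
            for i in range(0, rec.length, 70):
                fh.write(rec.sequence[i : i + 70] + "\n")
    rows = [
        {
            "transcript_id": rec.transcript_id,
            "gene_id": rec.gene_id,
            "biotype": rec.biotype.value,
            "isoform_count": fixture.transcriptome.gene_to_isoform_count[rec.gene_id],
        }
        for rec in fixture.transcriptome
    ]
    pd.DataFrame(rows).to_csv(paths["annotation"], sep="\t", index=False)
    fixture.expression.values.to_csv(paths["expression"], sep="\t", index_label="transcript_id")
    with open(paths["manifest"], "w") as fh:
        json.dump(fixture.manifest, fh, indent=2, sort_keys=True)
    return paths


def arf4_like_scenario(seed: int = 0) -> FixtureSpec:
    """A miniature hard-gene design case: one ~1.5 kb target with a second
    isoform, 30 mRNA decoys plus one rRNA decoy, and eight planted
    off-target homologies of 15-20 nt spread along the target."""
    rng = np.random.default_rng(seed ^ 0x5F3D)
    plants = []
    # spread planted windows along the target so several candidates see them
    starts = np.linspace(100, 1250, 8).astype(int)
    identities = rng.integers(15, 21, size=8)
    decoys = rng.permutation(30)[:8]
    for k in range(8):
        plants.append(
            PlantSpec(
                window_start=int(starts[k]),
                window_len=20,
                decoy=int(decoys[k]),
                identity_nt=int(identities[k]),
            )
        )
    return FixtureSpec(
        seed=seed,
        n_targets=1,
        target_length_nt=(1450, 1550),
        n_decoys=30,
        planted=plants,
        include_rrna_decoy=True,
        rrna_plant=PlantSpec(window_start=700, window_len=20, decoy=-1, identity_nt=16),
        second_isoform=True,
    )
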