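"""Transcriptome reference model: sequences, annotation, and expression.

Loads a transcript FASTA plus annotation (tabular TSV or GTF/GFF3) into a
:class:`Transcriptome`, and handles expression matrices: TMM normalization of
TPM values into nTPM, imputation of transcript-level expression from
gene-level tables, and resolution of the three expression modes used for
off-target weighting (equal, mean across cell lines, or a single cell line).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

__all__ = [
    "Biotype",
    "TranscriptRecord",
    "Transcriptome",
    "ExpressionTable",
    "ExpressionMode",
    "load_transcriptome",
    "tmm_normalize",
    "impute_isoform_expression",
    "expression_vector",
]


class Biotype(str, Enum):
    MRNA = "mRNA"
    LNCRNA = "lncRNA"
    RRNA = "rRNA"
    OTHER = "other"

    @classmethod
    def parse(cls, value: str) -> "Biotype":
        v = value.strip().lower()
        if v in {"mrna", "protein_coding", "messenger_rna"}:
            return cls.MRNA
        if v in {"lncrna", "lincrna", "lnc_rna"}:
            return cls.LNCRNA
        if v in {"rrna", "ribosomal_rna", "rrna_pseudogene"}:
            return cls.RRNA
        return cls.OTHER


_DNA_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class TranscriptRecord:
    """One RNA species, stored in the DNA alphabet (U converted to T)."""

    transcript_id: str
    gene_id: str
    sequence: str
    biotype: Biotype = Biotype.OTHER

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for transcript {self.transcript_id!r}")
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(
                f"transcript {self.transcript_id!r} contains non-DNA characters {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


class Transcriptome:
    """Ordered collection of transcripts plus per-gene isoform counts.

    ``gene_to_isoform_count`` may exceed the number of loaded records for a
    gene (the annotation can know about isoforms that were not loaded); it is
    used when imputing transcript expression from gene-level tables.
    """

    def __init__(
        self,
        records: Iterable[TranscriptRecord],
        gene_to_isoform_count: Mapping[str, int] | None = None,
    ):
        self.records: list[TranscriptRecord] = list(records)
        if not self.records:
            raise ValueError("transcriptome has no records")
        self._by_id: dict[str, TranscriptRecord] = {}
        for rec in self.records:
            if rec.transcript_id in self._by_id:
                raise ValueError(f"duplicate transcript id {rec.transcript_id!r}")
            self._by_id[rec.transcript_id] = rec

        loaded: dict[str, int] = {}
        for rec in self.records:
            loaded[rec.gene_id] = loaded.get(rec.gene_id, 0) + 1
        if gene_to_isoform_count is None:
            gene_to_isoform_count = loaded
        self.gene_to_isoform_count: dict[str, int] = dict(gene_to_isoform_count)
        for gene, n_loaded in loaded.items():
            declared = self.gene_to_isoform_count.get(gene)
            if declared is None:
                self.gene_to_isoform_count[gene] = n_loaded
            elif declared < n_loaded:
                raise ValueError(
                    f"gene {gene!r}: declared isoform count {declared} < {n_loaded} loaded records"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self._by_id

    def __getitem__(self, transcript_id: str) -> TranscriptRecord:
        return self._by_id[transcript_id]

    @property
    def transcript_ids(self) -> list[str]:
        return [r.transcript_id for r in self.records]

    def isoforms_of(self, gene_id: str) -> list[TranscriptRecord]:
        return [r for r in self.records if r.gene_id == gene_id]


class ExpressionLevel(str, Enum):
    TRANSCRIPT = "transcript"
    GENE = "gene"


@dataclass
class ExpressionTable:
    """nTPM values per (feature, context). Contexts are cell lines."""

    values: pd.DataFrame  # rows = feature ids, columns = contexts
    level: ExpressionLevel = ExpressionLevel.TRANSCRIPT

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")

    @property
    def contexts(self) -> list[str]:
        return list(self.values.columns)


class ExprMode(str, Enum):
    EQUAL = "equal"
    MEAN_AVERAGE = "mean_average"
    CELL_LINE = "cell_line"


@dataclass(frozen=True)
class ExpressionMode:
    """How transcript abundance enters off-target weighting.

    ``equal`` assigns every transcript one copy per cell (the conventional
    design assumption), ``mean_average`` averages nTPM across contexts, and
    ``cell_line`` uses a single context's column.
    """

    mode: ExprMode = ExprMode.EQUAL
    cell_line: str | None = None

    def __post_init__(self) -> None:
        if (self.mode == ExprMode.CELL_LINE) != (self.cell_line is not None):
            raise ValueError("cell_line must be set iff mode == 'cell_line'")


def _read_annotation_tsv(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = {"transcript_id", "gene_id", "biotype"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation {path} missing columns {sorted(missing)}")
    if "isoform_count" in df.columns:
        df["isoform_count"] = df["isoform_count"].astype(int)
    return df


def _read_annotation_gtf(path: Path) -> pd.DataFrame:
    """Minimal GTF/GFF3 attribute extraction for transcript features."""
    import re

    rows = []
    attr_re = re.compile(r'(\w+)[ =]+"?([^";]+)"?')
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] not in {"transcript", "mRNA", "lnc_RNA", "rRNA"}:
                continue
            attrs = dict(attr_re.findall(parts[8]))
            tid = attrs.get("transcript_id") or attrs.get("ID")
            if tid is None:
                continue
            gid = attrs.get("gene_id") or attrs.get("Parent") or tid
            biotype = (
                attrs.get("transcript_biotype")
                or attrs.get("gene_biotype")
                or ("rRNA" if parts[2] == "rRNA" else parts[2])
            )
            rows.append({"transcript_id": tid, "gene_id": gid, "biotype": biotype})
    return pd.DataFrame(rows, columns=["transcript_id", "gene_id", "biotype"])


def load_transcriptome(fasta_path: str | Path, annotation_path: str | Path | None = None) -> Transcriptome:
    """Load a transcript FASTA (+ optional annotation) into a Transcriptome.

    RNA alphabets are normalized (U -> T).  Transcripts missing from the
    annotation fall back to biotype ``other`` with ``gene_id ==
    transcript_id``.  Duplicated FASTA ids and empty FASTA files are errors.
    """
    fasta_path = Path(fasta_path)
    seqs = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not seqs:
        raise ValueError(f"no FASTA records in {fasta_path}")

    ann: pd.DataFrame | None = None
    iso_counts: dict[str, int] = {}
    if annotation_path is not None:
        annotation_path = Path(annotation_path)
        if annotation_path.suffix.lower() in {".gtf", ".gff", ".gff3"}:
            ann = _read_annotation_gtf(annotation_path)
        else:
            ann = _read_annotation_tsv(annotation_path)
        ann = ann.set_index("transcript_id")
        if "isoform_count" in ann.columns:
            for _, row in ann.iterrows():
                iso_counts[row["gene_id"]] = max(
                    iso_counts.get(row["gene_id"], 0), int(row["isoform_count"])
                )

    records = []
    for rec in seqs:
        seq = str(rec.seq).upper().replace("U", "T")
        tid = rec.id
        if ann is not None and tid in ann.index:
            gene_id = ann.loc[tid, "gene_id"]
            biotype = Biotype.parse(str(ann.loc[tid, "biotype"]))
        else:
            if ann is not None:
                logger.warning("transcript %s missing from annotation; biotype=other", tid)
            gene_id, biotype = tid, Biotype.OTHER
        records.append(TranscriptRecord(tid, gene_id, seq, biotype))

    return Transcriptome(records, iso_counts or None)


def _tmm_factor(obs: np.ndarray, ref: np.ndarray, logratio_trim: float = 0.3,
                abs_expr_trim: float = 0.05) -> float:
    """Scaling factor for one context against the reference (weighted trimmed
    mean of M-values, the standard double-trim formulation)."""
    n_obs, n_ref = obs.sum(), ref.sum()
    keep = (obs > 0) & (ref > 0)
    o, r = obs[keep], ref[keep]
    if o.size == 0:
        return 1.0
    m = np.log2((o / n_obs) / (r / n_ref))
    a = 0.5 * np.log2((o / n_obs) * (r / n_ref))
    # asymptotic (delta-method) binomial variance weights
    w = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)

    if np.max(np.abs(m)) < 1e-10:
        return 1.0

    n = m.size
    lo_m, hi_m = np.floor(n * logratio_trim) + 1, n + 1 - (np.floor(n * logratio_trim) + 1)
    lo_a, hi_a = np.floor(n * abs_expr_trim) + 1, n + 1 - (np.floor(n * abs_expr_trim) + 1)
    rank_m = pd.Series(m).rank().to_numpy()
    rank_a = pd.Series(a).rank().to_numpy()
    keep2 = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep2.any():
        return 1.0
    f = np.sum(w[keep2] * m[keep2]) / np.sum(w[keep2])
    return float(2.0 ** (-f))  # divide observed by 2^f: factor multiplies TPM


def tmm_normalize(tpm: pd.DataFrame | Mapping, level: ExpressionLevel | str = ExpressionLevel.TRANSCRIPT,
                  logratio_trim: float = 0.3, abs_expr_trim: float = 0.05) -> ExpressionTable:
    """TMM-normalize a TPM matrix (rows = features, columns = contexts) into nTPM.

    The reference context is the one whose upper quartile is closest to the
    mean upper quartile.  Per-context factors come from the doubly trimmed
    (30% M, 5% A) weighted mean of M-values against that reference; the scaled
    columns are then rescaled to sum to 1e6 so values stay on the TPM scale.
    """
    if not isinstance(tpm, pd.DataFrame):
        # map (id, context) -> TPM
        ser = pd.Series(dict(tpm))
        tpm = ser.unstack(fill_value=0.0)
    tpm = tpm.astype(float)
    if tpm.shape[1] < 1:
        raise ValueError("need at least one context")
    if (tpm.to_numpy() < 0).any():
        raise ValueError("TPM values must be non-negative")
    sums = tpm.sum(axis=0)
    zero = sums[sums == 0]
    if len(zero):
        raise ValueError(f"context(s) with all-zero expression: {list(zero.index)}")

    if tpm.shape[1] == 1:
        ntpm = tpm * (1e6 / sums.iloc[0])
        return ExpressionTable(ntpm, ExpressionLevel(level))

    uq = tpm.apply(lambda col: np.quantile(col[col > 0], 0.75), axis=0)
    ref_ctx = (uq - uq.mean()).abs().idxmin()
    ref = tpm[ref_ctx].to_numpy()

    factors = {
        ctx: _tmm_factor(tpm[ctx].to_numpy(), ref, logratio_trim, abs_expr_trim)
        for ctx in tpm.columns
    }
    scaled = tpm * pd.Series(factors)
    ntpm = scaled * (1e6 / scaled.sum(axis=0))
    return ExpressionTable(ntpm, ExpressionLevel(level))


def impute_isoform_expression(gene_table: ExpressionTable, transcriptome: Transcriptome) -> ExpressionTable:
    """Distribute gene-level nTPM evenly over a gene's isoforms.

    Each transcript of gene g receives nTPM(g) / isoform_count(g), using the
    annotation's (maximum) isoform count, so gene totals are conserved when
    all isoforms are loaded.
    """
    if gene_table.level != ExpressionLevel.GENE:
        raise ValueError("impute_isoform_expression requires a gene-level table")
    rows = {}
    for rec in transcriptome:
        if rec.gene_id not in transcriptome.gene_to_isoform_count:
            raise ValueError(f"gene {rec.gene_id!r} has no isoform count")
        n_iso = transcriptome.gene_to_isoform_count[rec.gene_id]
        if rec.gene_id in gene_table.values.index:
            rows[rec.transcript_id] = gene_table.values.loc[rec.gene_id] / n_iso
        else:
            raise ValueError(f"gene {rec.gene_id!r} absent from gene-level table")
    df = pd.DataFrame(rows).T
    df.columns = gene_table.values.columns
    return ExpressionTable(df, ExpressionLevel.TRANSCRIPT)


def expression_vector(table: ExpressionTable | None, mode: ExpressionMode,
                      transcriptome: Transcriptome) -> dict[str, float]:
    """Resolve one nTPM value per transcript under the requested mode.

    Transcripts absent from the table are treated as not expressed (0 nTPM,
    logged).  ``equal`` mode ignores the table entirely.
    """
    out: dict[str, float] = {}
    if mode.mode == ExprMode.EQUAL:
        return {tid: 1.0 for tid in transcriptome.transcript_ids}
    if table is None:
        raise ValueError(f"expression mode {mode.mode.value!r} requires an expression table")
    if table.level == ExpressionLevel.GENE:
        table = impute_isoform_expression(table, transcriptome)
    if mode.mode == ExprMode.CELL_LINE:
        if mode.cell_line not in table.contexts:
            raise ValueError(
                f"unknown cell line {mode.cell_line!r}; available: {table.contexts}"
            )
        col = table.values[mode.cell_line]
    else:  # mean across contexts
        col = table.values.mean(axis=1)
    for tid in transcriptome.transcript_ids:
        if tid in col.index:
            out[tid] = float(col.loc[tid])
        else:
            logger.warning("transcript %s missing from expression table; nTPM=0", tid)
            out[tid] = 0.0
    return out
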