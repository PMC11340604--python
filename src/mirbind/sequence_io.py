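"""Readers and writers for the plain-text formats the pipeline touches.

FASTA (miRNAs and 3'-UTRs), TSV pair lists, TSV SNP tables, and a
bedGraph-like TSV for conservation in transcript-local coordinates.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple, Union

import numpy as np
import pandas as pd
from Bio import SeqIO

from mirbind.types import (
    ConservationTrack,
    MiRNA,
    SNPAnnotation,
    TranscriptUTR,
)

PathLike = Union[str, Path]


def read_fasta(path: PathLike, role: str) -> list:
    """Read a FASTA file into MiRNA or TranscriptUTR records.

    ``role`` is ``"mirna"`` or ``"utr"``.  Headers carry the identifier as the
    first whitespace-separated token; for UTRs a second token of the form
    ``gene=<id>`` is honoured as the gene mapping.  Sequences are normalized
    (T->U, uppercased); duplicate identifiers are rejected.
    """
    if role not in ("mirna", "utr"):
        raise ValueError(f"role must be 'mirna' or 'utr', got {role!r}")
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: empty or non-FASTA file")
    out: list = []
    seen: Set[str] = set()
    for rec in records:
        rec_id = rec.id
        if rec_id in seen:
            raise ValueError(f"{path}: duplicate ID {rec_id!r}")
        seen.add(rec_id)
        seq = str(rec.seq)
        if role == "mirna":
            out.append(MiRNA(id=rec_id, sequence=seq))
        else:
            gene_id = None
            for token in rec.description.split()[1:]:
                if token.startswith("gene="):
                    gene_id = token[len("gene="):]
            out.append(TranscriptUTR(transcript_id=rec_id, sequence=seq, gene_id=gene_id))
    return out


def write_fasta(records: Iterable, path: PathLike) -> None:
    """Write MiRNA or TranscriptUTR records; inverse of :func:`read_fasta`."""
    with open(path, "w") as fh:
        for rec in records:
            if isinstance(rec, MiRNA):
                fh.write(f">{rec.id}\n{rec.sequence}\n")
            else:
                gene = f" gene={rec.gene_id}" if rec.gene_id else ""
                fh.write(f">{rec.transcript_id}{gene}\n{rec.sequence}\n")


def read_pair_list(path: PathLike) -> Set[Tuple[str, str]]:
    """Read a validated-interaction TSV into a set of (miRNA ID, gene ID)."""
    pairs: Set[Tuple[str, str]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected >=2 tab-separated columns")
            mirna_id, gene_id = fields[0].strip(), fields[1].strip()
            if not mirna_id or not gene_id:
                raise ValueError(f"{path}:{lineno}: empty identifier")
            pairs.add((mirna_id, gene_id))
    return pairs


def read_snp_table(path: PathLike) -> pd.DataFrame:
    """Read a SNP TSV (transcript_id, position, disease_flag) -> DataFrame."""
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        names=["transcript_id", "position", "disease_related"],
        dtype={"transcript_id": str},
    )
    df["position"] = df["position"].astype(int)
    df["disease_related"] = df["disease_related"].astype(int).astype(bool)
    return df


def write_snp_table(snps: Sequence[SNPAnnotation], path: PathLike) -> None:
    with open(path, "w") as fh:
        for snp in snps:
            fh.write(f"{snp.transcript_id}\t{snp.position}\t{int(snp.disease_related)}\n")


def read_conservation(
    path: PathLike, utr_lengths: Dict[str, int]
) -> Dict[str, ConservationTrack]:
    """Read bedGraph-like TSV (transcript_id, start, end, score) into tracks.

    Positions not covered by any interval are NaN (missing).
    """
    tracks: Dict[str, ConservationTrack] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns")
            tid, start, end, score = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            if tid not in utr_lengths:
                raise ValueError(f"{path}:{lineno}: unknown transcript {tid!r}")
            if tid not in tracks:
                tracks[tid] = ConservationTrack(
                    tid, np.full(utr_lengths[tid], np.nan)
                )
            if end > utr_lengths[tid]:
                raise ValueError(f"{path}:{lineno}: interval exceeds UTR length")
            tracks[tid].scores[start:end] = score
    return tracks


def write_conservation(tracks: Dict[str, ConservationTrack], path: PathLike) -> None:
    """Write tracks as runs of equal score, skipping missing positions."""
    with open(path, "w") as fh:
        for tid in sorted(tracks):
            scores = tracks[tid].scores
            i = 0
            n = len(scores)
            while i < n:
                if np.isnan(scores[i]):
                    i += 1
                    continue
                j = i + 1
                while j < n and scores[j] == scores[i]:
                    j += 1
                fh.write(f"{tid}\t{i}\t{j}\t{scores[i]:.6g}\n")
                i = j


def read_expression(path: PathLike) -> pd.DataFrame:
    """Read an expression TSV (mirna_id, gene_id, relative_expression)."""
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        names=["mirna_id", "gene_id", "relative_expression"],
        dtype={"mirna_id": str, "gene_id": str},
    )
    df["relative_expression"] = df["relative_expression"].astype(float)
    return df


def write_expression(df: pd.DataFrame, path: PathLike) -> None:
    df.to_csv(path, sep="\t", header=False, index=False)


def resolve_gene_to_longest_transcript(
    gene_id: str, utr_corpus: Sequence[TranscriptUTR]
) -> TranscriptUTR:
    """Pick the longest UTR among a gene's transcripts (ties: smallest ID)."""
    candidates = [u for u in utr_corpus if u.gene_id == gene_id]
    if not candidates:
        raise KeyError(f"unknown gene {gene_id!r}")
    return min(candidates, key=lambda u: (-len(u), u.transcript_id))


@dataclass
class ResourceBundle:
    """All inputs one run needs, keyed for lookup."""

    mirnas: List[MiRNA] = field(default_factory=list)
    utrs: List[TranscriptUTR] = field(default_factory=list)
    conservation: Dict[str, ConservationTrack] = field(default_factory=dict)
    snps: Optional[pd.DataFrame] = None
    validated_pairs: Set[Tuple[str, str]] = field(default_factory=set)
    expression: Optional[pd.DataFrame] = None

    def mirna_by_id(self, mirna_id: str) -> MiRNA:
        for m in self.mirnas:
            if m.id == mirna_id:
                return m
        raise KeyError(f"unknown miRNA {mirna_id!r}")

    def utr_by_transcript(self, transcript_id: str) -> TranscriptUTR:
        for u in self.utrs:
            if u.transcript_id == transcript_id:
                return u
        raise KeyError(f"unknown transcript {transcript_id!r}")

    def utr_for_gene(self, gene_id: str) -> TranscriptUTR:
        return resolve_gene_to_longest_transcript(gene_id, self.utrs)

    def snps_for_transcript(self, transcript_id: str) -> pd.DataFrame:
        if self.snps is None or self.snps.empty:
            return pd.DataFrame(columns=["transcript_id", "position", "disease_related"])
        return self.snps[self.snps["transcript_id"] == transcript_id]


def load_resources(
    mirna_fasta: PathLike,
    utr_fasta: PathLike,
    conservation: Optional[PathLike] = None,
    snps: Optional[PathLike] = None,
    pairs: Optional[PathLike] = None,
    expression: Optional[PathLike] = None,
) -> ResourceBundle:
    bundle = ResourceBundle(
        mirnas=read_fasta(mirna_fasta, "mirna"),
        utrs=read_fasta(utr_fasta, "utr"),
    )
    if conservation is not None:
        lengths = {u.transcript_id: len(u) for u in bundle.utrs}
        bundle.conservation = read_conservation(conservation, lengths)
    if snps is not None:
        bundle.snps = read_snp_table(snps)
    if pairs is not None:
        bundle.validated_pairs = read_pair_list(pairs)
    if expression is not None:
        bundle.expression = read_expression(expression)
    return bundle
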