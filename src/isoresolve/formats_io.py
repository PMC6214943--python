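"""Sequence and report I/O: FASTQ in, FASTA and TSV reports out.

The pipeline consumes full-length, non-chimeric CCS reads (one FASTQ per gene
family / primer pair, Phred+33 qualities) and emits the predicted transcripts
as FASTA plus two TSV reports (per-read assignments and per-transcript
statistics). All coordinates in reports are 0-based, half-open.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .config import logger

_VALID_BASES = frozenset("ACGT")

# quality assigned to masked N positions: 10**(-1/10) ~= 0.79 error probability,
# i.e. effectively a mismatch to everything
_N_MASK_QUALITY = 1


class FastqFormatError(ValueError):
    """Raised when a FASTQ record is malformed (e.g. seq/qual length mismatch)."""


@dataclass
class CcsRead:
    """One full-length CCS read with per-base Phred qualities."""

    read_id: str
    sequence: str
    qualities: list[int]
    num_passes: int | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"read {self.read_id}: empty sequence")
        if len(self.qualities) != len(self.sequence):
            raise ValueError(
                f"read {self.read_id}: {len(self.qualities)} quality values for "
                f"{len(self.sequence)} bases"
            )


def read_ccs_fastq(path: str | os.PathLike, n_policy: str = "drop") -> list[CcsRead]:
    """Load CCS reads from a Phred+33 FASTQ file.

    Reads containing bases outside {A,C,G,T} are handled according to
    ``n_policy``: ``"drop"`` discards them with a logged warning, ``"mask"``
    replaces the offending bases by 'A' with quality 1 (error probability
    ~0.75). Record order is preserved.
    """
    reads: list[CcsRead] = []
    n_dropped = 0
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            seq = str(rec.seq).upper()
            quals = list(rec.letter_annotations["phred_quality"])
            if not set(seq) <= _VALID_BASES:
                if n_policy == "drop":
                    n_dropped += 1
                    continue
                chars = list(seq)
                for i, ch in enumerate(chars):
                    if ch not in _VALID_BASES:
                        chars[i] = "A"
                        quals[i] = _N_MASK_QUALITY
                seq = "".join(chars)
            reads.append(CcsRead(rec.id, seq, quals))
    except ValueError as exc:  # Biopython names the offending record
        raise FastqFormatError(f"malformed FASTQ record in {path}: {exc}") from exc
    if n_dropped:
        logger.warning(
            "dropped %d reads with ambiguous bases from %s", n_dropped, path
        )
    return reads


def write_ccs_fastq(reads: Iterable[CcsRead], path: str | os.PathLike) -> None:
    """Write reads back out as Phred+33 FASTQ (round-trip safe)."""
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.sequence), id=r.read_id, description="")
        rec.letter_annotations["phred_quality"] = list(r.qualities)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def _format_pvalue(p: float | None) -> str:
    if p is None:
        return "NA"
    return repr(float(p))


def write_transcripts_fasta(transcripts: Sequence, path: str | os.PathLike) -> None:
    """Write candidate transcripts as FASTA.

    Headers carry the transcript id, the number of supporting reads and the
    significance value. Duplicate sequences are a contract violation (the
    candidate set must be deduplicated upstream).
    """
    seqs = [t.sequence for t in transcripts]
    if len(set(seqs)) != len(seqs):
        raise ValueError("duplicate transcript sequences passed to FASTA writer")
    with open(path, "w") as fh:
        for t in transcripts:
            support = len(t.assigned_reads) if t.assigned_reads is not None else 0
            fh.write(
                f">{t.transcript_id} support={support} "
                f"p_value={_format_pvalue(t.significance)}\n"
            )
            fh.write(t.sequence + "\n")


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Load a FASTA file as an ordered id -> sequence mapping."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n{seq}\n")


def write_run_report(
    assignments: Mapping[str, tuple[str, int]],
    transcript_stats: Mapping[str, tuple[int, float]],
    out_dir: str | os.PathLike,
) -> tuple[str, str]:
    """Write the two TSV reports.

    ``assignments`` maps read_id -> (transcript_id, edit_distance); every read
    id must appear exactly once.  ``transcript_stats`` maps
    transcript_id -> (support, p_value).  Returns the two file paths.
    """
    out_dir = str(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    assign_path = os.path.join(out_dir, "read_assignments.tsv")
    stats_path = os.path.join(out_dir, "transcript_stats.tsv")
    with open(assign_path, "w") as fh:
        fh.write("read_id\ttranscript_id\tedit_distance\n")
        for read_id, (tid, dist) in assignments.items():
            fh.write(f"{read_id}\t{tid}\t{dist}\n")
    with open(stats_path, "w") as fh:
        fh.write("transcript_id\tsupport\tp_value\n")
        for tid, (support, p) in transcript_stats.items():
            fh.write(f"{tid}\t{support}\t{_format_pvalue(p)}\n")
    return assign_path, stats_path
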