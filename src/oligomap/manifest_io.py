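"""Probe-manifest, annotation-table and probe-FASTA input/output.

A *manifest* is the array manufacturer's per-probe table (one row per SNP
assay: identifier, 50-mer probe sequence, strand flags, allele string),
typically shipped as a CSV with a block of metadata lines before the header
and a block of control definitions after the data. An *annotation table*
maps each SNP identifier to a chromosome and a 1-based position; in the
manufacturer's convention a ``0`` in either column means "not assigned",
which this module normalises to missing values on input and writes back as
the literal ``NA``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ConfigError, DuplicateIDError, ValidationError

_DNA_RE = re.compile(r"^[ACGTN]+$")

#: Separator joining the four manifest fields into one FASTA header token.
#: Only the token before the first separator is treated as the probe ID
#: downstream.
FASTA_HEADER_SEP = "|"

#: Canonical annotation-table column names.
ANNOTATION_COLUMNS = ("ID", "CHROM", "POS")

DEFAULT_SKIP_HEAD = 7
DEFAULT_SKIP_TAIL = 53


@dataclass(frozen=True)
class OligoRecord:
    """One probe: identifier, sequence and the manufacturer's strand flags.

    ``ilmn_strand`` is the design-strand flag (TOP/BOT), ``source_strand``
    the genome-strand flag, ``alleles`` the bracketed allele string such as
    ``[A/G]``. Sequences are upper-case DNA over ``ACGTN``.
    """

    oligo_id: str
    sequence: str
    ilmn_strand: str = ""
    source_strand: str = ""
    alleles: str = ""


def validate_records(records: Sequence[OligoRecord], probe_length: int | None = None) -> None:
    """Check sequence alphabet, uniform length and ID uniqueness.

    Raises :class:`ValidationError` or :class:`DuplicateIDError`.
    """
    seen: set[str] = set()
    expected = probe_length
    for i, rec in enumerate(records):
        if not rec.oligo_id:
            raise ValidationError(f"record {i + 1}: empty probe ID")
        if not _DNA_RE.match(rec.sequence):
            raise ValidationError(
                f"record {i + 1} ({rec.oligo_id}): sequence contains characters outside ACGTN"
            )
        if expected is None:
            expected = len(rec.sequence)
        elif len(rec.sequence) != expected:
            raise ValidationError(
                f"record {i + 1} ({rec.oligo_id}): sequence length {len(rec.sequence)}"
                f" != expected probe length {expected}"
            )
        if rec.oligo_id in seen:
            raise DuplicateIDError(f"duplicate probe ID {rec.oligo_id!r}")
        seen.add(rec.oligo_id)


def read_manifest(
    path,
    sequence_column: str = "AlleleA_ProbeSeq",
    *,
    id_column: str = "Name",
    ilmn_strand_column: str = "IlmnStrand",
    source_strand_column: str = "SourceStrand",
    alleles_column: str = "SNP",
    skip_head: int = DEFAULT_SKIP_HEAD,
    skip_tail: int = DEFAULT_SKIP_TAIL,
    probe_length: int | None = None,
) -> list[OligoRecord]:
    """Read a manufacturer-style CSV manifest into a list of probes.

    ``skip_head`` metadata lines before the header row and ``skip_tail``
    trailing lines (control definitions etc.) are ignored. Sequences are
    upper-cased and validated against ``ACGTN``; a bad row raises
    :class:`ValidationError` naming the data row and file line.
    """
    df = pd.read_csv(
        path,
        skiprows=skip_head,
        skipfooter=skip_tail,
        engine="python",
        dtype=str,
    )
    for required in (id_column, sequence_column):
        if required not in df.columns:
            raise ConfigError(
                f"column {required!r} not found in manifest; available columns:"
                f" {list(df.columns)}"
            )

    def _get(row, col) -> str:
        if col not in df.columns:
            return ""
        v = row[col]
        return "" if pd.isna(v) else str(v)

    records: list[OligoRecord] = []
    for i, (_, row) in enumerate(df.iterrows()):
        seq = row[sequence_column]
        oid = row[id_column]
        file_line = skip_head + 1 + (i + 1)  # header occupies one line
        if pd.isna(oid) or not str(oid):
            raise ValidationError(f"data row {i + 1} (file line {file_line}): empty probe ID")
        if pd.isna(seq) or not str(seq):
            raise ValidationError(
                f"data row {i + 1} (file line {file_line}): missing probe sequence"
            )
        seq = str(seq).upper()
        if not _DNA_RE.match(seq):
            raise ValidationError(
                f"data row {i + 1} (file line {file_line}): sequence contains"
                " characters outside ACGTN"
            )
        records.append(
            OligoRecord(
                oligo_id=str(oid),
                sequence=seq,
                ilmn_strand=_get(row, ilmn_strand_column),
                source_strand=_get(row, source_strand_column),
                alleles=_get(row, alleles_column),
            )
        )
    validate_records(records, probe_length)
    return records


def harmonize_ids(
    records: Sequence[OligoRecord], prefix_map: Mapping[str, str]
) -> list[OligoRecord]:
    """Rewrite probe-ID prefixes so two vendor files use the same naming.

    Every ID beginning with an old prefix gets it replaced by the mapped new
    prefix (longest old prefix wins); other IDs pass through unchanged and
    order is preserved. A rewrite that makes two IDs collide raises
    :class:`DuplicateIDError`.
    """
    for old in prefix_map:
        if not old:
            raise ConfigError("prefix_map keys must be non-empty strings")
    by_length = sorted(prefix_map.items(), key=lambda kv: -len(kv[0]))
    out: list[OligoRecord] = []
    for rec in records:
        new_id = rec.oligo_id
        for old, new in by_length:
            if rec.oligo_id.startswith(old):
                new_id = new + rec.oligo_id[len(old):]
                break
        if new_id == rec.oligo_id:
            out.append(rec)
        else:
            out.append(
                OligoRecord(
                    oligo_id=new_id,
                    sequence=rec.sequence,
                    ilmn_strand=rec.ilmn_strand,
                    source_strand=rec.source_strand,
                    alleles=rec.alleles,
                )
            )
    counts: dict[str, int] = {}
    for rec in out:
        counts[rec.oligo_id] = counts.get(rec.oligo_id, 0) + 1
    collisions = sorted(k for k, v in counts.items() if v > 1)
    if collisions:
        raise DuplicateIDError(
            f"prefix rewriting produced duplicate IDs: {collisions[:10]}"
        )
    return out


def write_probe_fasta(records: Sequence[OligoRecord], path) -> int:
    """Write probes as multi-FASTA; returns the number of entries written.

    The header of each entry is the four manifest fields (Name, IlmnStrand,
    SourceStrand, alleles) joined by :data:`FASTA_HEADER_SEP`.
    """
    seq_records = [
        SeqRecord(
            Seq(rec.sequence),
            id=FASTA_HEADER_SEP.join(
                (rec.oligo_id, rec.ilmn_strand, rec.source_strand, rec.alleles)
            ),
            description="",
        )
        for rec in records
    ]
    return SeqIO.write(seq_records, str(path), "fasta")


def read_probe_fasta(path) -> list[OligoRecord]:
    """Read a probe FASTA written by :func:`write_probe_fasta`.

    Headers are split on :data:`FASTA_HEADER_SEP`; missing trailing fields
    default to empty strings, so plain single-token headers also work.
    """
    records: list[OligoRecord] = []
    for sr in SeqIO.parse(str(path), "fasta"):
        parts = sr.id.split(FASTA_HEADER_SEP)
        parts += [""] * (4 - len(parts))
        records.append(
            OligoRecord(
                oligo_id=parts[0],
                sequence=str(sr.seq).upper(),
                ilmn_strand=parts[1],
                source_strand=parts[2],
                alleles=parts[3],
            )
        )
    return records


def annotation_table(rows: Iterable[tuple]) -> pd.DataFrame:
    """Build a typed annotation table from ``(id, chromosome, position)`` rows.

    ``None`` (or NaN) marks a missing chromosome or position; positions are
    stored as nullable integers.
    """
    df = pd.DataFrame(list(rows), columns=list(ANNOTATION_COLUMNS))
    df["ID"] = df["ID"].astype(str)
    df["CHROM"] = df["CHROM"].astype("string").astype(object)
    df.loc[df["CHROM"].isna(), "CHROM"] = pd.NA
    df["POS"] = pd.array(df["POS"], dtype="Int64")
    return df


def _validate_annotation(df: pd.DataFrame) -> pd.DataFrame:
    dup = df["ID"][df["ID"].duplicated()]
    if len(dup):
        raise DuplicateIDError(f"duplicate SNP IDs in annotation: {sorted(set(dup))[:10]}")
    bad = df["POS"].dropna()
    if (bad < 1).any():
        raise ValidationError("annotation positions must be positive 1-based integers")
    orphan = df["POS"].notna() & df["CHROM"].isna()
    if orphan.any():
        ids = df.loc[orphan, "ID"].tolist()[:10]
        raise ValidationError(f"rows with a position but no chromosome: {ids}")
    return df


def read_annotation(path) -> pd.DataFrame:
    """Read an annotation CSV with columns ID, CHROM, POS.

    ``0`` in the chromosome or position column and the literal ``NA`` both
    denote "not assigned" and become missing values. Duplicate IDs, negative
    positions, and positions without a chromosome are rejected.
    """
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigError(
            f"annotation file lacks required columns {missing}; found {list(df.columns)}"
        )
    df = df[list(ANNOTATION_COLUMNS)].copy()
    df["ID"] = df["ID"].astype(str)
    df.loc[df["CHROM"] == "0", "CHROM"] = pd.NA
    df.loc[df["CHROM"].isna(), "CHROM"] = pd.NA
    pos = df["POS"].copy()
    pos[pos == "0"] = pd.NA
    try:
        df["POS"] = pd.array(
            [pd.NA if pd.isna(v) else int(v) for v in pos], dtype="Int64"
        )
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"non-integer position in annotation: {exc}") from exc
    df["CHROM"] = df["CHROM"].astype(object)
    df.loc[df["CHROM"].isna(), "CHROM"] = pd.NA
    return _validate_annotation(df)


def write_annotation(table: pd.DataFrame, path) -> int:
    """Write an annotation table as CSV with missing values as ``NA``.

    Round-trips with :func:`read_annotation`. Returns the row count.
    """
    _validate_annotation(table)
    table.to_csv(path, index=False, na_rep="NA")
    return len(table)
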