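"""Genome and metadata I/O plus basic assembly statistics.

Assembled genomes are multi-FASTA files of contigs.  The metadata table
(``full_metadata.csv``) is indexed by the FASTA path and carries the
provenance columns needed downstream: ``Source`` and
``RegistrationCode`` jointly identify the individual a sample came
from, ``SampleName`` the sample, ``AssemblyName`` the assembly, and
``DoNotTake`` holds a free-text exclusion reason (empty means usable).
Per-assembly quality estimates (completeness, contamination,
heterogeneity) are produced upstream by marker-gene tools and consumed
here as plain columns.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

ALLOWED = set("ACGTN")

REQUIRED_COLUMNS = (
    "Source",
    "Method",
    "AssemblyName",
    "SampleName",
    "RegistrationCode",
    "DoNotTake",
)

#: metadata ``Method`` strings mapped onto the internal enumeration
METHOD_ALIASES = {
    "mag": "short_read_mag",
    "short_read_mag": "short_read_mag",
    "nanopore": "nanopore_mag",
    "nanopore_mag": "nanopore_mag",
    "isolate": "isolate",
}


@dataclass(frozen=True)
class Contig:
    """One contig: an id and an uppercase A/C/G/T/N sequence."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("contig id must be non-empty")
        if len(self.sequence) == 0:
            raise ValueError(f"contig {self.id!r} has zero length")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class AssemblyRecord:
    """One assembled genome: contigs plus provenance and quality metadata.

    ``individual_id`` is always ``source + registration_code`` — the pair
    is the unique identifier of the individual the sample came from, and
    the per-individual dereplication stage groups assemblies by it.
    Quality percentages are on a 0–100 scale.  ``do_not_take`` carries
    the upstream exclusion reason; any non-empty value excludes the
    assembly from the build.
    """

    assembly_id: str
    fasta_path: str = ""
    contigs: tuple[Contig, ...] = ()
    source: str = ""
    method: str = "short_read_mag"
    sample_id: str = ""
    registration_code: str = ""
    completeness: float = float("nan")
    contamination: float = float("nan")
    heterogeneity: float = float("nan")
    do_not_take: str = ""

    @property
    def individual_id(self) -> str:
        return f"{self.source}{self.registration_code}"

    @property
    def excluded(self) -> bool:
        return bool(self.do_not_take)

    @property
    def total_length(self) -> int:
        return sum(len(c) for c in self.contigs)

    @property
    def sequence(self) -> str:
        """All contigs concatenated (used only for whole-genome stats)."""
        return "".join(c.sequence for c in self.contigs)

    def with_contigs(self, contigs: Sequence[Contig]) -> "AssemblyRecord":
        return replace(self, contigs=tuple(contigs))


def _clean_sequence(seq: str) -> str:
    """Uppercase and coerce any non-ACGTN character to N."""
    seq = seq.upper()
    if set(seq) <= ALLOWED:
        return seq
    return "".join(c if c in ALLOWED else "N" for c in seq)


def read_fasta(path: str | os.PathLike) -> list[Contig]:
    """Read a (possibly wrapped) multi-FASTA file into contigs.

    Sequences are uppercased; characters outside A/C/G/T/N become N.
    Record order is preserved.  Raises ``ValueError`` on an empty file,
    a malformed header, a duplicate id, or a header with no sequence.
    """
    contigs: list[Contig] = []
    header: str | None = None
    chunks: list[str] = []
    seen: set[str] = set()

    def _flush(line_no: int) -> None:
        nonlocal header, chunks
        if header is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise ValueError(f"{path}: record {header!r} has no sequence (line {line_no})")
        if header in seen:
            raise ValueError(f"{path}: duplicate contig id {header!r}")
        seen.add(header)
        contigs.append(Contig(header, _clean_sequence(seq)))
        header, chunks = None, []

    with open(path) as fh:
        for i, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush(i)
                name = line[1:].split()[0] if len(line) > 1 else ""
                if not name:
                    raise ValueError(f"{path}: malformed header at line {i}")
                header = name
            else:
                if header is None:
                    raise ValueError(f"{path}: sequence before header at line {i}")
                chunks.append(line)
        _flush(-1)
    if not contigs:
        raise ValueError(f"{path}: no sequences")
    return contigs


def write_fasta(path: str | os.PathLike, contigs: Iterable[Contig], width: int = 80) -> None:
    with open(path, "w") as fh:
        for c in contigs:
            fh.write(f">{c.id}\n")
            for i in range(0, len(c.sequence), width):
                fh.write(c.sequence[i : i + width] + "\n")


def assembly_stats(contigs: Sequence[Contig]) -> dict:
    """Total length, contig count and N50 of a contig collection.

    N50 is the largest contig length L such that contigs of length >= L
    cover at least half of the total assembly length (the >= comparison
    means a cumulative sum landing exactly on half already qualifies).
    """
    if not contigs:
        raise ValueError("empty contig collection")
    lengths = sorted((len(c) for c in contigs), reverse=True)
    total = sum(lengths)
    half = total / 2
    acc = 0
    for length in lengths:
        acc += length
        if acc >= half:
            return {"length": total, "n_contigs": len(lengths), "n50": length}
    raise AssertionError("unreachable")  # pragma: no cover


class MetadataTable:
    """The ``full_metadata.csv`` contract: assembly provenance + quality.

    The underlying frame is indexed by FASTA path.  Rows become
    :class:`AssemblyRecord` stubs (no contigs loaded); records with a
    non-empty ``DoNotTake`` are flagged excluded but retained so the
    decision log can report them.
    """

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"metadata missing required column(s): {', '.join(missing)}")
        dup = frame["AssemblyName"][frame["AssemblyName"].duplicated()]
        if len(dup):
            raise ValueError(f"duplicate AssemblyName: {dup.iloc[0]!r}")
        self.frame = frame

    @property
    def records(self) -> list[AssemblyRecord]:
        out = []
        for fasta_path, row in self.frame.iterrows():
            out.append(
                AssemblyRecord(
                    assembly_id=str(row["AssemblyName"]),
                    fasta_path=str(fasta_path),
                    source=str(row["Source"]),
                    method=_normalize_method(str(row["Method"])),
                    sample_id=str(row["SampleName"]),
                    registration_code=str(row["RegistrationCode"]),
                    completeness=float(row.get("completeness", np.nan)),
                    contamination=float(row.get("contamination", np.nan)),
                    heterogeneity=float(row.get("heterogeneity", np.nan)),
                    do_not_take=_clean_reason(row["DoNotTake"]),
                )
            )
        return out

    def resolve_paths(self, root: str | os.PathLike | None = None) -> list[str]:
        """Return metadata rows whose FASTA file does not exist on disk."""
        missing = []
        for p in self.frame.index:
            full = os.path.join(root, p) if root is not None else p
            if not os.path.exists(full):
                missing.append(str(p))
        return missing

    def write(self, path: str | os.PathLike) -> None:
        self.frame.to_csv(path, index=True, index_label="")

    def __len__(self) -> int:
        return len(self.frame)


def _clean_reason(value) -> str:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return ""
    return str(value).strip()


def _normalize_method(method: str) -> str:
    return METHOD_ALIASES.get(method.strip().lower(), method.strip().lower())


def load_metadata(path: str | os.PathLike) -> MetadataTable:
    """Load ``full_metadata.csv`` (index column = FASTA path)."""
    frame = pd.read_csv(path, index_col=0, dtype=str, keep_default_na=False)
    frame.index = frame.index.astype(str)
    for col in ("completeness", "contamination", "heterogeneity"):
        if col in frame.columns:
            frame[col] = pd.to_numeric(frame[col].replace("", np.nan))
    return MetadataTable(frame)
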