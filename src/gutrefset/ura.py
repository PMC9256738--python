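"""Unique-read relative abundance (URA) estimation.

Only uniquely mapping reads are trusted for abundance: a read is
*unique* when its best alignment score is attained at exactly one
mapping position in the whole reference set.  Correspondingly a
reference *position* is unique when the read-length substring starting
there occurs exactly once across all forward and reverse-complement
strands of the reference set — a read drawn from a unique position
maps uniquely.

Each genome is divided into windows containing the same number W of
expected unique positions ("uniqueness-balanced" windows), so under a
uniform read layout every full window expects the same unique-read
count.  A species is called present in a sample when (a) enough reads
align uniquely to it and (b) the per-window unique-read counts are
uniform enough (chi-square goodness of fit); its relative abundance is
the unique-read count divided by the genome's unique-position count,
normalised over present species.

Uniqueness is computed exactly at substring resolution via 64-bit
rolling hashes — an approximation of aligner-scoring uniqueness that is
exact for the error-free, desk-scale references this package targets.
Coordinates are 0-based half-open; reverse-strand placements are keyed
by their leftmost reference position.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

DEFAULT_MIN_READS = 50
DEFAULT_ALPHA = 0.05
DEFAULT_WINDOW_UNIQUE = 100

_COMP = str.maketrans("ACGTN", "TGCAN")

_HASH_MULT = np.uint64(0x5851F42D4C957F2D)  # odd multiplier, 64-bit wraparound
_BASE_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _substring_hashes(seq: str, length: int) -> tuple[np.ndarray, np.ndarray]:
    """Rolling 64-bit hashes of every length-``length`` substring.

    Returns (hashes, valid) over start positions; a window overlapping
    an N (or other non-ACGT character) is invalid.
    """
    codes = _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    n = len(codes) - length + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    bad = (codes == 4).astype(np.int32)
    bad_cum = np.concatenate(([0], np.cumsum(bad)))
    valid = (bad_cum[length:] - bad_cum[:-length]) == 0
    h = np.zeros(n, dtype=np.uint64)
    c64 = codes.astype(np.uint64)
    with np.errstate(over="ignore"):
        for j in range(length):
            h = h * _HASH_MULT + c64[j : j + n] + np.uint64(1)
    return h, valid


def _hash_one(seq: str) -> int | None:
    h, valid = _substring_hashes(seq, len(seq))
    if len(h) == 0 or not valid[0]:
        return None
    return int(h[0])


@dataclass
class UniquenessIndex:
    """Per-genome boolean uniqueness over read-start positions.

    ``unique[g][p]`` is True iff the read-length substring of genome g
    starting at p occurs exactly once over both strands of the whole
    reference set.  ``reference_version`` names the genome set the
    index was built against.
    """

    read_length: int
    genome_lengths: dict[str, int]
    unique: dict[str, np.ndarray]
    reference_version: str = ""

    @property
    def unique_counts(self) -> dict[str, int]:
        return {g: int(u.sum()) for g, u in self.unique.items()}


def build_uniqueness_index(
    genomes: dict[str, str], read_length: int, reference_version: str = ""
) -> UniquenessIndex:
    """Exact substring-resolution uniqueness across a reference set.

    ``genomes`` maps genome_id to its full sequence (contigs
    concatenated).  Both strands of every genome contribute substring
    occurrences; a position whose substring (or whose reverse
    complement elsewhere) appears more than once is non-unique.
    """
    if read_length < 1:
        raise ValueError("read_length must be >= 1")
    if not genomes:
        raise ValueError("empty reference set")
    fwd: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    all_hashes = []
    for gid, seq in genomes.items():
        h, valid = _substring_hashes(seq, read_length)
        fwd[gid] = (h, valid)
        all_hashes.append(h[valid])
        h_rc, valid_rc = _substring_hashes(reverse_complement(seq), read_length)
        all_hashes.append(h_rc[valid_rc])
    pool = np.concatenate(all_hashes) if all_hashes else np.empty(0, dtype=np.uint64)
    values, counts = np.unique(pool, return_counts=True)
    unique_values = values[counts == 1]
    out: dict[str, np.ndarray] = {}
    for gid, (h, valid) in fwd.items():
        is_unique = np.isin(h, unique_values, assume_unique=False)
        out[gid] = is_unique & valid
    return UniquenessIndex(
        read_length=read_length,
        genome_lengths={g: len(s) for g, s in genomes.items()},
        unique=out,
        reference_version=reference_version,
    )


@dataclass
class WindowPartition:
    """Uniqueness-balanced windows per genome, 0-based half-open.

    Full windows contain exactly ``window_unique`` unique positions;
    the trailing remainder forms a final short window.  Genomes with no
    unique positions are excluded and listed in ``skipped``.
    """

    window_unique: int
    windows: dict[str, list[tuple[int, int]]]
    expected_unique: dict[str, list[int]]
    skipped: list[str] = field(default_factory=list)

    def n_full_windows(self, genome_id: str) -> int:
        return sum(
            1 for e in self.expected_unique[genome_id] if e == self.window_unique
        )


def partition_windows(index: UniquenessIndex, window_unique: int = DEFAULT_WINDOW_UNIQUE) -> WindowPartition:
    """Greedy left-to-right accumulation of unique positions into windows."""
    if window_unique < 1:
        raise ValueError("window_unique must be >= 1")
    windows: dict[str, list[tuple[int, int]]] = {}
    expected: dict[str, list[int]] = {}
    skipped: list[str] = []
    for gid, u in index.unique.items():
        total = int(u.sum())
        if total == 0:
            skipped.append(gid)
            continue
        length = index.genome_lengths[gid]
        cum = np.cumsum(u)
        # a window closes right before the first unique position that
        # would overfill it, so trailing non-unique positions belong to
        # the window whose unique positions precede them
        ui = np.flatnonzero(u)
        bounds = [0]
        for t in range(window_unique, total, window_unique):
            bounds.append(int(ui[t]))
        bounds.append(length)
        win = list(zip(bounds[:-1], bounds[1:]))
        windows[gid] = win
        starts = np.array(bounds[:-1])
        ends = np.minimum(np.array(bounds[1:]), len(u))
        expected[gid] = [
            int(cum[e - 1] - (cum[s - 1] if s > 0 else 0)) if e > s else 0
            for s, e in zip(starts, ends)
        ]
    return WindowPartition(window_unique, windows, expected, skipped)


@dataclass(frozen=True)
class AlignmentRecord:
    """One reported placement of one read (several per read allowed)."""

    read_id: str
    genome_id: str
    position: int  # 0-based leftmost reference position
    score: float
    strand: str = "+"
    flags: int = 0


@dataclass
class ReadCall:
    read_id: str
    mapped: bool
    unique: bool
    best: AlignmentRecord | None  # None when unmapped or best-score tie


def classify_reads(records: list[AlignmentRecord]) -> dict[str, ReadCall]:
    """Per-read mapped/unique status from all reported placements.

    mapped: at least one placement.  unique: the maximal alignment
    score is attained at exactly one placement; on a best-score tie the
    read is non-unique and carries no best placement.
    """
    by_read: dict[str, list[AlignmentRecord]] = {}
    for rec in records:
        by_read.setdefault(rec.read_id, []).append(rec)
    out: dict[str, ReadCall] = {}
    for rid, placements in by_read.items():
        best_score = max(p.score for p in placements)
        top = [p for p in placements if p.score == best_score]
        if len(top) == 1:
            out[rid] = ReadCall(rid, True, True, top[0])
        else:
            out[rid] = ReadCall(rid, True, False, None)
    return out


@dataclass
class UraProfile:
    genome_id: str
    unique_read_count: int
    window_counts: np.ndarray
    uniformity_stat: float
    uniformity_p: float
    present: bool
    relative_abundance: float
    unique_positions: int


def ura_profile(
    partition: WindowPartition,
    classified: dict[str, ReadCall],
    index: UniquenessIndex,
    min_reads: int = DEFAULT_MIN_READS,
    alpha: float = DEFAULT_ALPHA,
) -> dict[str, UraProfile]:
    """Presence calls and relative abundances for every indexed genome.

    Unique reads land in windows by best-placement start position.
    Uniformity is a chi-square goodness-of-fit of the counts over full
    windows against an equal expectation; genomes with fewer than two
    full windows or too few reads for the test default to p = 1.
    Presence requires >= min_reads unique reads AND p >= alpha.
    Abundance = unique reads / unique positions, normalised over
    present genomes (absent genomes report 0).
    """
    unique_counts = index.unique_counts
    per_genome_positions: dict[str, list[int]] = {g: [] for g in partition.windows}
    totals: dict[str, int] = {g: 0 for g in index.unique}
    for call in classified.values():
        if not call.unique or call.best is None:
            continue
        g = call.best.genome_id
        if g in totals:
            totals[g] += 1
        if g in per_genome_positions:
            per_genome_positions[g].append(call.best.position)
    profiles: dict[str, UraProfile] = {}
    for gid in index.unique:
        n_unique = totals.get(gid, 0)
        if gid in partition.windows:
            win = partition.windows[gid]
            starts = np.array([s for s, _ in win])
            counts = np.zeros(len(win), dtype=np.int64)
            pos = np.array(per_genome_positions[gid], dtype=np.int64)
            if len(pos):
                idx = np.searchsorted(starts, pos, side="right") - 1
                idx = np.clip(idx, 0, len(win) - 1)
                np.add.at(counts, idx, 1)
            full = np.array(
                [e == partition.window_unique for e in partition.expected_unique[gid]]
            )
            full_counts = counts[full]
            if full.sum() >= 2 and full_counts.sum() > 0:
                stat, pval = stats.chisquare(full_counts)
                stat, pval = float(stat), float(pval)
            else:
                stat, pval = 0.0, 1.0
        else:
            counts = np.zeros(0, dtype=np.int64)
            stat, pval = 0.0, 1.0
        present = n_unique >= min_reads and pval >= alpha
        profiles[gid] = UraProfile(
            genome_id=gid,
            unique_read_count=n_unique,
            window_counts=counts,
            uniformity_stat=stat,
            uniformity_p=pval,
            present=present,
            relative_abundance=0.0,
            unique_positions=unique_counts.get(gid, 0),
        )
    dens = {
        g: p.unique_read_count / p.unique_positions
        for g, p in profiles.items()
        if p.present and p.unique_positions > 0
    }
    total_density = sum(dens.values())
    if total_density == 0:
        if any(p.unique_read_count for p in profiles.values()):
            warnings.warn("no genome passed the presence criteria; all abundances 0")
    else:
        for g, d in dens.items():
            profiles[g].relative_abundance = d / total_density
    return profiles


def alignment_rates(
    classified: dict[str, ReadCall], total_reads: int | None = None
) -> dict[str, float]:
    """Mapped and unique fractions over all reads.

    ``total_reads`` supplies the denominator including unmapped reads
    that produced no alignment records; defaults to the classified
    count (all of which are mapped by construction).
    """
    n = total_reads if total_reads is not None else len(classified)
    if n == 0:
        raise ValueError("zero reads")
    mapped = sum(1 for c in classified.values() if c.mapped)
    unique = sum(1 for c in classified.values() if c.unique)
    return {"mapped_fraction": mapped / n, "unique_fraction": unique / n}


def exact_read_mapper(
    reads: list[tuple[str, str]], genomes: dict[str, str]
) -> list[AlignmentRecord]:
    """Toy mapper: every exact placement of each read over both strands.

    All placements of all reads share the same length and are exact
    matches, so every placement scores 0 (the scale an end-to-end
    aligner reports for a perfect alignment).  Reverse-strand hits are
    keyed by leftmost forward-reference position.
    """
    if not reads:
        return []
    read_len = len(reads[0][1])
    if any(len(seq) != read_len for _, seq in reads):
        raise ValueError("all reads must share one length")
    placements: dict[int, list[tuple[str, int]]] = {}
    for gid, seq in genomes.items():
        h, valid = _substring_hashes(seq, read_len)
        for p in np.flatnonzero(valid):
            placements.setdefault(int(h[p]), []).append((gid, int(p)))
    out: list[AlignmentRecord] = []
    for rid, seq in reads:
        for strand, probe in (("+", seq), ("-", reverse_complement(seq))):
            key = _hash_one(probe)
            if key is None:
                continue
            for gid, pos in placements.get(key, []):
                out.append(AlignmentRecord(rid, gid, pos, 0.0, strand))
    return out


def read_alignments_tsv(path) -> list[AlignmentRecord]:
    """5-column TSV dialect: read_id, genome_id, pos, strand, score."""
    out = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise ValueError(f"{path}:{i}: expected 5 columns, got {len(parts)}")
            rid, gid, pos, strand, score = parts
            out.append(AlignmentRecord(rid, gid, int(pos), float(score), strand))
    return out


def write_alignments_tsv(records: list[AlignmentRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("#read_id\tgenome_id\tpos\tstrand\tscore\n")
        for r in records:
            fh.write(f"{r.read_id}\t{r.genome_id}\t{r.position}\t{r.strand}\t{r.score:g}\n")


def read_alignments_sam(path) -> list[AlignmentRecord]:
    """Read a SAM file of multi-placement alignments (AS = score tag).

    Unmapped records are skipped; reverse-strand flag maps to '-'.
    Positions come out 0-based.
    """
    import pysam

    out = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam.fetch(until_eof=True):
            if rec.is_unmapped:
                continue
            score = float(rec.get_tag("AS")) if rec.has_tag("AS") else 0.0
            out.append(
                AlignmentRecord(
                    read_id=rec.query_name,
                    genome_id=rec.reference_name,
                    position=int(rec.reference_start),
                    score=score,
                    strand="-" if rec.is_reverse else "+",
                    flags=int(rec.flag),
                )
            )
    return out
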