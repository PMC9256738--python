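"""Bottom-s MinHash sketching and Mash-style genomic distance.

A genome's sketch is the s smallest 64-bit hash values of its distinct
canonical k-mers (each k-mer is taken as the lexicographic minimum of
itself and its reverse complement, so sketches are strand-independent).
The Jaccard index of two k-mer sets is estimated from the merged
bottom-s sketch and converted to a genomic distance with the Mash
formula

    d = -(1/k) * ln(2j / (1 + j)),

which approximates 1 - ANI (average nucleotide identity); the
species-level threshold d = 0.05 therefore corresponds to the
conventional 95% ANI species boundary.

Hashing is a splitmix64 finalizer applied to the 2-bit integer encoding
of the canonical k-mer XORed with a mixed seed.  The function is fixed
and platform-independent: sketches are reproducible bit-for-bit across
runs and machines for a given (k, s, seed).
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field

import numpy as np

from gutrefset.genome_io import AssemblyRecord, Contig

DEFAULT_K = 21
DEFAULT_SKETCH_SIZE = 10_000
DEFAULT_HASH_SEED = 42

_BASE_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i

_GAMMA = np.uint64(0x9E3779B97F4A7C15)
_MIX1 = np.uint64(0xBF58476D1CE4E5B9)
_MIX2 = np.uint64(0x94D049BB133111EB)


def _splitmix64(x: np.ndarray) -> np.ndarray:
    """Vectorised splitmix64 finalizer (uint64 wrap-around arithmetic)."""
    with np.errstate(over="ignore"):
        z = (x + _GAMMA).astype(np.uint64)
        z ^= z >> np.uint64(30)
        z *= _MIX1
        z ^= z >> np.uint64(27)
        z *= _MIX2
        z ^= z >> np.uint64(31)
    return z


def _seed_mix(seed: int) -> np.uint64:
    return _splitmix64(np.array([seed], dtype=np.uint64))[0]


def _canonical_kmer_codes(seq: str, k: int) -> np.ndarray:
    """2-bit integer codes of all canonical k-mers of one sequence.

    k-mers overlapping an N (or any non-ACGT character) are skipped.
    """
    codes = _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    is_bad = (codes == 4).astype(np.int32)
    bad_cum = np.concatenate(([0], np.cumsum(is_bad)))
    valid = (bad_cum[k:] - bad_cum[:-k]) == 0
    c64 = codes.astype(np.uint64)
    fwd = np.zeros(n, dtype=np.uint64)
    rc = np.zeros(n, dtype=np.uint64)
    four = np.uint64(4)
    three = np.uint64(3)
    with np.errstate(over="ignore"):
        for j in range(k):
            win = c64[j : j + n]
            fwd = fwd * four + win  # Horner: weight 4^(k-1-j)
            rc += (three - win) * np.uint64(4**j)  # reverse complement weight 4^j
    return np.minimum(fwd, rc)[valid]


@dataclass(frozen=True)
class Sketch:
    """Bottom-s MinHash signature of a genome's canonical k-mer set.

    ``hashes`` holds the min(s, #distinct canonical k-mers) smallest
    64-bit hash values, strictly increasing.
    """

    kmer_size: int
    sketch_size: int
    hashes: np.ndarray  # uint64, sorted ascending, distinct
    genome_id: str
    hash_seed: int = DEFAULT_HASH_SEED

    def __post_init__(self) -> None:
        h = np.asarray(self.hashes, dtype=np.uint64)
        if len(h) > 1 and not (h[1:] > h[:-1]).all():
            raise ValueError("sketch hashes must be strictly increasing")
        if len(h) > self.sketch_size:
            raise ValueError("more hashes than sketch size")
        object.__setattr__(self, "hashes", h)

    def __len__(self) -> int:
        return len(self.hashes)

    def to_dict(self) -> dict:
        return {
            "genome_id": self.genome_id,
            "kmer_size": self.kmer_size,
            "sketch_size": self.sketch_size,
            "hash_seed": self.hash_seed,
            "hashes": [int(x) for x in self.hashes],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Sketch":
        return cls(
            kmer_size=int(d["kmer_size"]),
            sketch_size=int(d["sketch_size"]),
            hashes=np.array(d["hashes"], dtype=np.uint64),
            genome_id=str(d["genome_id"]),
            hash_seed=int(d.get("hash_seed", DEFAULT_HASH_SEED)),
        )


def sketch_sequence(
    sequences,
    k: int = DEFAULT_K,
    s: int = DEFAULT_SKETCH_SIZE,
    genome_id: str = "",
    hash_seed: int = DEFAULT_HASH_SEED,
) -> Sketch:
    """Sketch one sequence or a collection of contig sequences."""
    if isinstance(sequences, str):
        sequences = [sequences]
    parts = [_canonical_kmer_codes(seq, k) for seq in sequences]
    kmers = np.concatenate(parts) if parts else np.empty(0, dtype=np.uint64)
    if len(kmers) == 0:
        raise ValueError(f"genome {genome_id!r} too short to sketch (k={k})")
    raw = _splitmix64(kmers ^ _seed_mix(hash_seed))
    # bottom-s of the *distinct* hashes: pre-select the smallest 4s values
    # (linear) before deduplicating; exact unless duplicates dominate.
    if len(raw) > 4 * s:
        candidate = np.partition(raw, 4 * s)[: 4 * s]
        hashes = np.unique(candidate)
        if len(hashes) < s:
            hashes = np.unique(raw)  # heavy k-mer duplication; exact fallback
    else:
        hashes = np.unique(raw)
    if len(hashes) > s:
        hashes = hashes[:s]
    return Sketch(kmer_size=k, sketch_size=s, hashes=hashes, genome_id=genome_id, hash_seed=hash_seed)


def sketch_genome(
    record: AssemblyRecord | list[Contig],
    k: int = DEFAULT_K,
    s: int = DEFAULT_SKETCH_SIZE,
    hash_seed: int = DEFAULT_HASH_SEED,
) -> Sketch:
    """Sketch an assembly record (or a bare contig list)."""
    if isinstance(record, AssemblyRecord):
        contigs, genome_id = record.contigs, record.assembly_id
    else:
        contigs, genome_id = record, ""
    return sketch_sequence(
        [c.sequence for c in contigs], k=k, s=s, genome_id=genome_id, hash_seed=hash_seed
    )


def _check_compatible(a: Sketch, b: Sketch) -> None:
    if a.kmer_size != b.kmer_size:
        raise ValueError(f"k-mer size mismatch: {a.kmer_size} vs {b.kmer_size}")
    if a.sketch_size != b.sketch_size:
        raise ValueError(f"sketch size mismatch: {a.sketch_size} vs {b.sketch_size}")
    if a.hash_seed != b.hash_seed:
        raise ValueError("hash seed mismatch")


def jaccard_estimate(a: Sketch, b: Sketch) -> float:
    """Jaccard index estimated from the merged bottom-s sketch.

    The s smallest values of the union of the two sketches form a
    bottom-s sketch of the union of the two k-mer sets; the fraction of
    them present in both sketches is an unbiased Jaccard estimate.
    """
    _check_compatible(a, b)
    union = np.union1d(a.hashes, b.hashes)
    s_eff = min(a.sketch_size, len(union))
    if s_eff == 0:
        raise ValueError("cannot estimate Jaccard from empty sketches")
    merged = union[:s_eff]
    shared = int(
        np.sum(
            np.isin(merged, a.hashes, assume_unique=True)
            & np.isin(merged, b.hashes, assume_unique=True)
        )
    )
    return shared / s_eff


def mash_distance(a: Sketch, b: Sketch) -> float:
    """Mash distance, capped to [0, 1]; 0 iff the sketches are identical."""
    j = jaccard_estimate(a, b)
    if j == 0.0:
        return 1.0
    if j == 1.0:
        return 0.0
    d = -math.log(2.0 * j / (1.0 + j)) / a.kmer_size
    return min(max(d, 0.0), 1.0)


class DistanceStore:
    """Symmetric all-vs-all distance matrix with on-disk persistence.

    Backed by a float64 memory map when given a path, so any entry is
    addressable by (row, column) without the full matrix resident in
    working memory; a sidecar ``<path>.ids.tsv`` keeps the genome id
    order.  In-memory (no path) stores are supported for small runs.
    """

    def __init__(self, ids: list[str], values: np.ndarray, path: str | None = None):
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate genome_id in distance store")
        n = len(ids)
        if values.shape != (n, n):
            raise ValueError("distance matrix shape does not match id count")
        self.ids = list(ids)
        self.values = values
        self.path = path
        self._index = {g: i for i, g in enumerate(self.ids)}

    def __len__(self) -> int:
        return len(self.ids)

    def __getitem__(self, key) -> float:
        i, j = key
        if isinstance(i, str):
            i = self._index[i]
        if isinstance(j, str):
            j = self._index[j]
        return float(self.values[i, j])

    def row(self, i: int | str) -> np.ndarray:
        if isinstance(i, str):
            i = self._index[i]
        return np.asarray(self.values[i], dtype=np.float64)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(np.asarray(self.values), index=self.ids, columns=self.ids)

    def flush(self) -> None:
        if isinstance(self.values, np.memmap):
            self.values.flush()

    @classmethod
    def create(cls, ids: list[str], path: str | None = None) -> "DistanceStore":
        n = len(ids)
        if path is None:
            values = np.zeros((n, n), dtype=np.float64)
        else:
            values = np.memmap(path, dtype=np.float64, mode="w+", shape=(n, n))
            with open(str(path) + ".ids.tsv", "w") as fh:
                fh.write("genome_id\n")
                for g in ids:
                    fh.write(f"{g}\n")
        return cls(ids, values, path=None if path is None else str(path))

    @classmethod
    def open(cls, path: str) -> "DistanceStore":
        with open(str(path) + ".ids.tsv") as fh:
            lines = [ln.strip() for ln in fh if ln.strip()]
        ids = lines[1:]  # header row
        n = len(ids)
        values = np.memmap(path, dtype=np.float64, mode="r", shape=(n, n))
        return cls(ids, values, path=str(path))


def pairwise_distances(sketches: list[Sketch], path: str | None = None) -> DistanceStore:
    """All-vs-all Mash distances; symmetric with a zero diagonal.

    Each unordered pair is computed once.  With ``path`` set the matrix
    is written to a memory-mapped file plus an id sidecar.
    """
    if len(sketches) < 2:
        raise ValueError("need at least 2 sketches")
    ids = [sk.genome_id for sk in sketches]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate genome_id among sketches")
    for sk in sketches[1:]:
        _check_compatible(sketches[0], sk)
    store = DistanceStore.create(ids, path=path)
    n = len(sketches)
    for i in range(n):
        for j in range(i + 1, n):
            d = mash_distance(sketches[i], sketches[j])
            store.values[i, j] = d
            store.values[j, i] = d
    store.flush()
    return store


def save_sketches(sketches: list[Sketch], path: str | os.PathLike) -> None:
    """Write a sketch collection as versioned JSON."""
    payload = {"format": "gutrefset-sketch", "version": 1, "sketches": [s.to_dict() for s in sketches]}
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_sketches(path: str | os.PathLike) -> list[Sketch]:
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format") != "gutrefset-sketch":
        raise ValueError(f"{path}: not a sketch file")
    return [Sketch.from_dict(d) for d in payload["sketches"]]
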