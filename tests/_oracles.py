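"""Independent brute-force oracles used by the tests.

Deliberately naive: every quantity is recomputed from first principles
(full recomputation per step, exhaustive scans) so the oracles share no
code path with the package.
"""

from itertools import combinations


def brute_average_linkage(dist, bound):
    """Naive agglomerative average linkage with a merge bound.

    ``dist`` is a symmetric matrix (indexable [i][j]).  At every step
    all cluster-pair averages are recomputed from scratch; the first
    strictly-smallest pair merges.  Returns a frozenset of frozensets
    of item indices.
    """
    n = len(dist)
    clusters = [[i] for i in range(n)]
    while len(clusters) > 1:
        best = None
        for a, b in combinations(range(len(clusters)), 2):
            pairs = [(i, j) for i in clusters[a] for j in clusters[b]]
            avg = sum(dist[i][j] for i, j in pairs) / len(pairs)
            if best is None or avg < best[0]:
                best = (avg, a, b)
        if best[0] > bound:
            break
        _, a, b = best
        clusters[a] = clusters[a] + clusters[b]
        clusters.pop(b)
    return frozenset(frozenset(c) for c in clusters)


def brute_canonical_kmers(seq, k):
    """All distinct canonical k-mers of a sequence, by direct string ops."""
    comp = str.maketrans("ACGT", "TGCA")
    out = set()
    for i in range(len(seq) - k + 1):
        km = seq[i : i + k]
        if set(km) <= set("ACGT"):
            out.add(min(km, km.translate(comp)[::-1]))
    return out


def brute_unique_positions(genomes, read_length):
    """Per-genome unique read-start positions by exhaustive substring scan."""
    comp = str.maketrans("ACGTN", "TGCAN")
    counts = {}
    for seq in genomes.values():
        for strand_seq in (seq, seq.translate(comp)[::-1]):
            for i in range(len(strand_seq) - read_length + 1):
                sub = strand_seq[i : i + read_length]
                if "N" not in sub:
                    counts[sub] = counts.get(sub, 0) + 1
    out = {}
    for gid, seq in genomes.items():
        flags = []
        for i in range(len(seq) - read_length + 1):
            sub = seq[i : i + read_length]
            flags.append("N" not in sub and counts.get(sub, 0) == 1)
        out[gid] = flags
    return out
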