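"""Per-individual greedy dereplication.

Average-linkage clustering over-weights near-duplicate points: two
copies of the same genome merge at distance ~0 and from then on count
twice in every average.  Multiple samples of one individual inevitably
produce such near-duplicates, so before clustering each individual
contributes at most one assembly per species: that individual's
assemblies are ranked by quality score, and walking from highest to
lowest an assembly is kept only if its Mash distance to every
previously kept assembly of the same individual exceeds the
species-level threshold (0.05).  Assemblies from different individuals
never block each other.
"""

from __future__ import annotations

from dataclasses import dataclass

from gutrefset.genome_io import AssemblyRecord
from gutrefset.minhash import Sketch, mash_distance
from gutrefset.quality import QualityMetrics, quality_score

SPECIES_THRESHOLD = 0.05


@dataclass(frozen=True)
class DedupDecision:
    """Keep/block decision for one assembly, in greedy processing order."""

    assembly_id: str
    kept: bool
    blocked_by: str | None = None
    distance_to_blocker: float | None = None
    score: float = float("nan")

    def __post_init__(self) -> None:
        if not self.kept and self.blocked_by is None:
            raise ValueError("blocked decision must name its blocker")


def _ranked(records: list[AssemblyRecord], metrics: dict[str, QualityMetrics]):
    """Descending quality score; ties broken by assembly name."""
    scored = []
    for rec in records:
        if rec.assembly_id not in metrics:
            raise ValueError(f"missing quality metrics for {rec.assembly_id!r}")
        scored.append((quality_score(metrics[rec.assembly_id]), rec))
    scored.sort(key=lambda t: (-t[0], t[1].assembly_id))
    return scored


def dedup_individual(
    records: list[AssemblyRecord],
    sketches: dict[str, Sketch],
    metrics: dict[str, QualityMetrics],
    threshold: float = SPECIES_THRESHOLD,
) -> list[DedupDecision]:
    """Greedy dereplication of one individual's assemblies.

    An assembly is kept iff its distance to every previously kept
    assembly is strictly greater than ``threshold``; a distance exactly
    at the threshold blocks.  Decisions are returned in processing
    order (descending score, name tie-break), so the output is
    independent of input row order.
    """
    individuals = {r.individual_id for r in records}
    if len(individuals) > 1:
        raise ValueError(f"records span multiple individuals: {sorted(individuals)}")
    for rec in records:
        if rec.assembly_id not in sketches:
            raise ValueError(f"missing sketch for {rec.assembly_id!r}")
    decisions: list[DedupDecision] = []
    kept: list[AssemblyRecord] = []
    for score, rec in _ranked(records, metrics):
        blocker, block_d = None, None
        for prev in kept:
            d = mash_distance(sketches[rec.assembly_id], sketches[prev.assembly_id])
            if d <= threshold:
                blocker, block_d = prev.assembly_id, d
                break
        if blocker is None:
            kept.append(rec)
            decisions.append(DedupDecision(rec.assembly_id, True, score=score))
        else:
            decisions.append(
                DedupDecision(rec.assembly_id, False, blocker, block_d, score=score)
            )
    return decisions


def dedup_pool(
    records: list[AssemblyRecord],
    sketches: dict[str, Sketch],
    metrics: dict[str, QualityMetrics],
    threshold: float = SPECIES_THRESHOLD,
) -> tuple[list[AssemblyRecord], list[DedupDecision]]:
    """Apply :func:`dedup_individual` independently per individual.

    Returns the retained assemblies (in input order) and the full
    decision log.  Input records are expected to have passed quality
    filtration already.
    """
    by_individual: dict[str, list[AssemblyRecord]] = {}
    for rec in records:
        by_individual.setdefault(rec.individual_id, []).append(rec)
    decisions: list[DedupDecision] = []
    kept_ids: set[str] = set()
    for ind in sorted(by_individual):
        for dec in dedup_individual(by_individual[ind], sketches, metrics, threshold):
            decisions.append(dec)
            if dec.kept:
                kept_ids.add(dec.assembly_id)
    retained = [r for r in records if r.assembly_id in kept_ids]
    return retained, decisions
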