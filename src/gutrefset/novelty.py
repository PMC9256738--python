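"""Novelty classification against an external reference set.

Each representative genome is compared against every genome of an
external reference pool; its novelty tier follows from the Mash
distance to the closest external genome:

    d <= t_species          below_species (a known species)
    t_species < d <= t_genus   new species within a known genus
    t_genus  < d <= t_family   new genus within a known family
    t_family < d               new family or beyond ("order" tier)

t_species defaults to 0.05 (95% ANI).  The genus (0.15) and family
(0.30) defaults follow the hierarchical-bin convention of the MAG
cataloguing work this pipeline builds on; they are extrapolated rather
than universal and are always explicit, overridable parameters.
A distance exactly on a threshold takes the lower (less novel) tier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from gutrefset.minhash import Sketch, mash_distance

T_SPECIES = 0.05
T_GENUS = 0.15
T_FAMILY = 0.30

TIERS = ("below_species", "species", "genus", "family", "order")


@dataclass(frozen=True)
class NoveltyCall:
    genome_id: str
    nearest_external_id: str
    nearest_distance: float
    tier: str


def classify_tier(
    distance: float,
    t_species: float = T_SPECIES,
    t_genus: float = T_GENUS,
    t_family: float = T_FAMILY,
) -> str:
    if not (t_species < t_genus < t_family):
        raise ValueError("thresholds must be strictly increasing")
    if distance <= t_species:
        return "below_species"
    if distance <= t_genus:
        return "species"
    if distance <= t_family:
        return "genus"
    return "family"


def nearest_external(
    rep_sketches: list[Sketch], external_sketches: list[Sketch]
) -> dict[str, tuple[str, float]]:
    """Exact minimum distance from each representative to the external pool."""
    if not rep_sketches:
        raise ValueError("empty representative set")
    if not external_sketches:
        raise ValueError("empty external reference set")
    out: dict[str, tuple[str, float]] = {}
    for rep in rep_sketches:
        best_id, best_d = "", np.inf
        for ext in external_sketches:
            d = mash_distance(rep, ext)
            if d < best_d:
                best_id, best_d = ext.genome_id, d
        out[rep.genome_id] = (best_id, float(best_d))
    return out


def classify_novelty(
    rep_sketches: list[Sketch],
    external_sketches: list[Sketch],
    t_species: float = T_SPECIES,
    t_genus: float = T_GENUS,
    t_family: float = T_FAMILY,
) -> list[NoveltyCall]:
    nearest = nearest_external(rep_sketches, external_sketches)
    return [
        NoveltyCall(gid, ext_id, d, classify_tier(d, t_species, t_genus, t_family))
        for gid, (ext_id, d) in nearest.items()
    ]
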