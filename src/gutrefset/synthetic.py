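"""Synthetic genomes, cohorts and reads with known ground truth.

Every pipeline stage is testable without downloads: this module
fabricates random genomes, evolves them by per-site substitution (so
1 - ANI between an ancestor and a descendant is exactly the applied
substitution rate in expectation), fragments them into partial
assemblies of a target completeness, assembles multi-individual
cohorts with the ``full_metadata.csv`` schema, and draws error-free or
error-bearing reads at known species proportions.

Evolution is substitution-only by default — no indels — so the ANI
ground truth is exact.  All outputs are reproducible bit-for-bit from
(config, seed).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from gutrefset.genome_io import AssemblyRecord, Contig, assembly_stats, write_fasta
from gutrefset.quality import QualityMetrics

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, 0, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


def _to_seq(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def _to_codes(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def simulate_genome(length: int, seed, contig_id: str = "c0") -> Contig:
    """I.i.d. uniform A/C/G/T sequence of the given length."""
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = _rng(seed)
    return Contig(contig_id, _to_seq(rng.integers(0, 4, size=length, dtype=np.uint8)))


def evolve_genome(sequence: str, substitution_rate: float, seed) -> str:
    """Substitute each site with probability p to a uniformly chosen
    *different* base; expected mismatch fraction equals p exactly."""
    if not 0.0 <= substitution_rate <= 1.0:
        raise ValueError("substitution rate must be in [0, 1]")
    rng = _rng(seed)
    codes = _to_codes(sequence).copy()
    hit = np.flatnonzero(rng.random(len(codes)) < substitution_rate)
    if len(hit):
        shift = rng.integers(1, 4, size=len(hit), dtype=np.uint8)
        codes[hit] = (codes[hit] + shift) % 4
    return _to_seq(codes)


def fragment_assembly(
    sequence: str,
    completeness: float,
    seed,
    n_contigs: int = 1,
    mode: str = "contiguous",
    assembly_id: str = "frag",
) -> AssemblyRecord:
    """Partial assembly retaining a fraction ``completeness`` of a genome.

    contiguous mode keeps one uniformly placed window of length
    completeness * |genome|; random mode keeps ``n_contigs`` disjoint
    windows (one per equal-width genome segment) of that total length.
    Fabricated quality metrics record the true completeness (percent)
    and zero contamination/heterogeneity.
    """
    if not 0.0 < completeness <= 1.0:
        raise ValueError("completeness must be in (0, 1]")
    rng = _rng(seed)
    L = len(sequence)
    keep = int(round(completeness * L))
    if keep < 1:
        raise ValueError("fragment too short")
    if mode == "contiguous":
        start = int(rng.integers(0, L - keep + 1))
        contigs = [Contig(f"{assembly_id}_c0", sequence[start : start + keep])]
    elif mode == "random":
        seg = L // n_contigs
        per = keep // n_contigs
        if per < 1 or per > seg:
            raise ValueError("cannot fit fragments in segments")
        contigs = []
        for i in range(n_contigs):
            lo = i * seg
            start = int(rng.integers(lo, lo + seg - per + 1))
            contigs.append(Contig(f"{assembly_id}_c{i}", sequence[start : start + per]))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    rec = AssemblyRecord(assembly_id=assembly_id, contigs=tuple(contigs))
    rec.completeness = 100.0 * completeness
    rec.contamination = 0.0
    rec.heterogeneity = 0.0
    return rec


@dataclass
class SimulationConfig:
    """Study conditions for a synthetic multi-individual cohort.

    Species genomes descend from one ancestor at the inter-species
    substitution rate; each individual carries its own strain of each
    species at the intra-species rate.  ``assemblies_per_species``
    assemblies of every (individual, species) strain are produced —
    values above 1 inject the per-individual near-duplicates the
    dereplication stage exists to remove.  Completeness of each partial
    assembly is drawn uniformly from ``completeness_range`` (fractions;
    defaults chosen above the 70% quality threshold so every assembly
    survives filtration and the clustering ground truth stays exact).
    """

    seed: int = 0
    n_species: int = 4
    genome_length: int = 100_000
    inter_species_substitution: float = 0.10
    intra_species_substitution: float = 0.005
    n_individuals: int = 3
    assemblies_per_species: int = 2
    completeness_range: tuple[float, float] = (0.8, 0.95)
    read_length: int = 100
    depth: float = 2.0
    species_proportions: tuple[float, ...] | None = None


@dataclass
class Cohort:
    """A simulated cohort on disk plus its ground truth."""

    fasta_dir: str
    metadata_path: str
    truth: pd.DataFrame  # one row per assembly
    species_genomes: dict[str, str]  # species_id -> full sequence
    config: SimulationConfig


def simulate_cohort(config: SimulationConfig, out_dir: str | os.PathLike) -> Cohort:
    """Write a cohort (FASTA dir + full_metadata.csv) and its truth table.

    Produces n_individuals x n_species x assemblies_per_species
    assemblies.  Assemblies of one (individual, species) strain are
    fragments of the same evolved genome, hence within the 0.05
    species distance of each other; distinct species sit far beyond it.
    """
    rng = np.random.default_rng(config.seed)
    os.makedirs(out_dir, exist_ok=True)
    fasta_dir = os.path.join(str(out_dir), "fasta")
    os.makedirs(fasta_dir, exist_ok=True)

    ancestor = simulate_genome(config.genome_length, rng).sequence
    species = {
        f"sp{s:02d}": evolve_genome(ancestor, config.inter_species_substitution, rng)
        for s in range(config.n_species)
    }

    meta_rows = []
    truth_rows = []
    lo, hi = config.completeness_range
    for ind in range(config.n_individuals):
        reg = f"R{ind:03d}"
        for s_idx, (sp, sp_seq) in enumerate(species.items()):
            strain = evolve_genome(sp_seq, config.intra_species_substitution, rng)
            for copy in range(config.assemblies_per_species):
                aid = f"I{ind:03d}_{sp}_a{copy}"
                c = float(rng.uniform(lo, hi))
                rec = fragment_assembly(strain, c, rng, assembly_id=aid)
                path = os.path.join(fasta_dir, f"{aid}.fa")
                write_fasta(path, rec.contigs)
                stats = assembly_stats(rec.contigs)
                meta_rows.append(
                    {
                        "": path,
                        "Source": "SIM",
                        "Method": "MAG",
                        "AssemblyName": aid,
                        "SampleName": f"S{ind:03d}_{copy}",
                        "RegistrationCode": reg,
                        "DoNotTake": "",
                        "completeness": rec.completeness,
                        "contamination": 0.0,
                        "heterogeneity": 0.0,
                    }
                )
                truth_rows.append(
                    {
                        "assembly_id": aid,
                        "species": sp,
                        "individual": f"SIM{reg}",
                        "sample": f"S{ind:03d}_{copy}",
                        "copy_index": copy,
                        "is_duplicate": copy > 0,
                        "true_completeness": c,
                        "length": stats["length"],
                        "n50": stats["n50"],
                    }
                )
    metadata_path = os.path.join(str(out_dir), "full_metadata.csv")
    pd.DataFrame(meta_rows).set_index("").to_csv(metadata_path, index=True, index_label="")
    truth = pd.DataFrame(truth_rows)
    truth.to_csv(os.path.join(str(out_dir), "truth_assemblies.tsv"), sep="\t", index=False)
    return Cohort(fasta_dir, metadata_path, truth, species, config)


def simulate_reads(
    genomes: dict[str, str],
    proportions: dict[str, float],
    read_length: int,
    depth: float,
    seed,
    error_rate: float = 0.0,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Uniform-start reads from both strands at known species proportions.

    Read counts per genome are proportional to proportion x genome
    length (cell-count proportions, longer genomes yield more reads);
    ``depth`` is the mean per-base coverage of the whole mixture.
    Returns (reads, truth) where truth records each read's source
    genome, 0-based leftmost position and strand.
    """
    from gutrefset.ura import reverse_complement

    if abs(sum(proportions.values()) - 1.0) > 1e-9:
        raise ValueError("proportions must sum to 1")
    rng = _rng(seed)
    weights = {g: proportions.get(g, 0.0) * len(seq) for g, seq in genomes.items()}
    total_w = sum(weights.values())
    n_total = int(round(depth * total_w / read_length))
    reads: list[tuple[str, str]] = []
    truth_rows = []
    k = 0
    for g, seq in genomes.items():
        if weights[g] == 0.0:
            continue
        n_g = int(round(n_total * weights[g] / total_w))
        starts = rng.integers(0, len(seq) - read_length + 1, size=n_g)
        strands = rng.integers(0, 2, size=n_g)
        for p, rev in zip(starts, strands):
            frag = seq[p : p + read_length]
            if rev:
                frag = reverse_complement(frag)
            if error_rate > 0.0:
                frag = evolve_genome(frag, error_rate, rng)
            rid = f"read{k:07d}"
            reads.append((rid, frag))
            truth_rows.append(
                {"read_id": rid, "genome_id": g, "position": int(p), "strand": "-" if rev else "+"}
            )
            k += 1
    return reads, pd.DataFrame(truth_rows)


def write_fastq(reads: list[tuple[str, str]], path: str | os.PathLike) -> None:
    """Error-free FASTQ (all qualities 'I')."""
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")
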