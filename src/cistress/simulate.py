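"""Synthetic promoters with planted cis-elements and synthetic Ct tables.

The promoter generator emulates the study material: ~1-kb windows upstream
of a TSS with heat-shock elements and ER-UPR elements planted at known
TSS-relative positions and strands over an i.i.d. nucleotide background of
configurable GC content.  The Ct generator emulates the qPCR design: one
reference gene, technical triplicates, three biological replicates, known
fold-changes relative to a calibrator group, and Gaussian cycle noise at
the biological and technical levels.  Both are fully reproducible from
their seed, and both emit a truth table so recovery can be asserted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .hse import classify_unit
from .motifs import IUPAC_BASES, MotifSpec, builtin_upr_catalog, reverse_complement
from .sequence_io import GeneModel, PromoterRegion, write_promoters_fasta

__all__ = [
    "Planting",
    "PromoterSimConfig",
    "CtSimConfig",
    "SimulatedPromoters",
    "simulate_promoters",
    "simulate_ct_table",
    "write_promoter_sim",
    "write_ct_sim",
]

_BODY_LEN = 60  # synthetic transcribed region downstream of each TSS


@dataclass(frozen=True)
class Planting:
    """One element to plant: a catalogue motif id, or "HSE" with a unit
    count.  ``tss_offset`` is the TSS-relative position of the element's
    5'-most base (negative); strand is relative to promoter orientation."""

    element: str
    tss_offset: int
    strand: str = "+"
    n_units: int | None = None          # HSE only
    mode: str = "paper"                 # HSE only

    def length(self, catalog: dict[str, MotifSpec]) -> int:
        if self.element == "HSE":
            if not self.n_units or self.n_units < 2:
                raise ValueError("HSE planting needs n_units >= 2")
            return 5 * self.n_units
        spec = catalog[self.element]
        if spec.kind == "gapped":
            return len(spec.parts[0]) + spec.spacer[0] + len(spec.parts[1])
        return len(spec.parts[0])


@dataclass(frozen=True)
class PromoterSimConfig:
    n_promoters: int
    window: int = 1000
    gc: float = 0.4
    plantings: tuple[Planting, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.gc < 1.0):
            raise ValueError("gc must be in (0, 1)")
        if self.n_promoters < 1 or self.window < 1:
            raise ValueError("n_promoters and window must be >= 1")


@dataclass(frozen=True)
class SimulatedPromoters:
    """In-memory result of a promoter simulation: the promoters themselves,
    the genome/gene-model embedding they were cut from, and the planted
    truth (columns gene_id, element, tss_offset, strand, length, aux,
    sequence; aux is the HSE unit count or gapped spacer length)."""

    config: PromoterSimConfig
    promoters: list[PromoterRegion]
    genome: dict[str, str]
    genes: list[GeneModel]
    truth: pd.DataFrame


def _draw_background(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=n, p=p)


def _instantiate_iupac(rng: np.random.Generator, part: str) -> str:
    return "".join(rng.choice(list(IUPAC_BASES[c])) for c in part)


def _instantiate_hse_unit(rng: np.random.Generator, orientation: str,
                          mode: str) -> str:
    bases = "ACGT"
    n1, n5 = rng.choice(list(bases)), rng.choice(list(bases))
    if mode == "perfect":
        core = "GAA"
    else:
        # relaxed module: invariable G, A at module position 3 or 4
        if rng.random() < 0.5:
            core = "GA" + rng.choice(list(bases))
        else:
            core = "G" + rng.choice(list(bases)) + "A"
    unit = n1 + core + n5
    if orientation == "reverse":
        unit = reverse_complement(unit)
    assert classify_unit(unit, mode).orientation == orientation
    return unit


def _instantiate_planting(rng: np.random.Generator, planting: Planting,
                          catalog: dict[str, MotifSpec]) -> tuple[str, int | None]:
    """Realize a planting as a concrete sequence; returns (seq, aux)."""
    if planting.element == "HSE":
        orients = ["forward" if i % 2 == 0 else "reverse"
                   for i in range(planting.n_units)]
        seq = "".join(_instantiate_hse_unit(rng, o, planting.mode)
                      for o in orients)
        aux = planting.n_units
    else:
        spec = catalog[planting.element]
        if spec.kind == "gapped":
            spacer = int(rng.integers(spec.spacer[0], spec.spacer[1] + 1))
            seq = (_instantiate_iupac(rng, spec.parts[0])
                   + "".join(rng.choice(list("ACGT")) for _ in range(spacer))
                   + _instantiate_iupac(rng, spec.parts[1]))
            aux = spacer
        else:
            seq = _instantiate_iupac(rng, spec.parts[0])
            aux = None
    if planting.strand == "-":
        seq = reverse_complement(seq)
    return seq, aux


def simulate_promoters(config: PromoterSimConfig) -> SimulatedPromoters:
    """Generate promoters with the configured plantings in every promoter.

    Plantings are validated (in-window, non-overlapping) before any
    generation.  Genes alternate between the + and - strand of their
    synthetic contig so strand-aware extraction is exercised; the promoter
    sequences returned are always in promoter (gene-strand) orientation.
    """
    catalog = {s.motif_id: s for s in builtin_upr_catalog()}
    intervals = []
    for pl in config.plantings:
        if pl.element != "HSE" and pl.element not in catalog:
            raise ValueError(f"unknown element {pl.element!r}")
        length = pl.length(catalog)
        lo = pl.tss_offset
        hi = pl.tss_offset + length
        if lo < -config.window or hi > 0:
            raise ValueError(
                f"planting {pl.element} at {pl.tss_offset} does not fit the "
                f"{config.window}-bp window")
        intervals.append((lo, hi, pl))
    intervals.sort()
    for (lo1, hi1, a), (lo2, hi2, b) in zip(intervals, intervals[1:]):
        if hi1 > lo2:
            raise ValueError(
                f"plantings {a.element}@{a.tss_offset} and "
                f"{b.element}@{b.tss_offset} overlap")

    rng = np.random.default_rng(config.seed)
    promoters, genes, truth_rows = [], [], []
    genome: dict[str, str] = {}
    for i in range(config.n_promoters):
        gene_id = f"syng{i:04d}"
        contig_id = f"chr_{gene_id}"
        bg = _draw_background(rng, config.window, config.gc)
        prom = bg.tobytes().decode()
        for lo, hi, pl in intervals:
            seq, aux = _instantiate_planting(rng, pl, catalog)
            start = config.window + lo
            prom = prom[:start] + seq + prom[start + len(seq):]
            truth_rows.append({
                "gene_id": gene_id, "element": pl.element,
                "tss_offset": lo, "strand": pl.strand,
                "length": hi - lo, "aux": aux, "sequence": seq,
            })
        body = _draw_background(rng, _BODY_LEN, config.gc).tobytes().decode()
        if i % 2 == 0:  # plus-strand gene: contig = promoter + body
            contig = prom + body
            tss = config.window
            span = (tss, tss + _BODY_LEN)
            strand = "+"
            interval = (0, config.window)
        else:           # minus-strand gene: contig = body + revcomp(promoter)
            contig = body + reverse_complement(prom)
            tss = _BODY_LEN - 1
            span = (0, _BODY_LEN)
            strand = "-"
            interval = (_BODY_LEN, _BODY_LEN + config.window)
        genome[contig_id] = contig
        genes.append(GeneModel(gene_id=gene_id, seq_id=contig_id,
                               strand=strand, tss=tss, span=span))
        promoters.append(PromoterRegion(
            gene_id=gene_id, seq_id=contig_id, strand=strand,
            genomic_interval=interval, sequence=prom, window=config.window))
    truth = pd.DataFrame(
        truth_rows, columns=["gene_id", "element", "tss_offset", "strand",
                             "length", "aux", "sequence"])
    return SimulatedPromoters(config=config, promoters=promoters,
                              genome=genome, genes=genes, truth=truth)


def write_promoter_sim(sim: SimulatedPromoters, outdir) -> dict[str, Path]:
    """Write promoter FASTA, genome FASTA, gene-model GFF3 and truth TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "promoters": outdir / "promoters.fasta",
        "genome": outdir / "genome.fasta",
        "genes": outdir / "genes.gff3",
        "truth": outdir / "truth.tsv",
    }
    write_promoters_fasta(sim.promoters, paths["promoters"])
    with open(paths["genome"], "w") as fh:
        for seq_id, seq in sim.genome.items():
            fh.write(f">{seq_id}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")
    with open(paths["genes"], "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sim.genes:
            lo, hi = g.span
            fh.write(f"{g.seq_id}\tcistress_sim\tgene\t{lo + 1}\t{hi}\t.\t"
                     f"{g.strand}\t.\tID={g.gene_id}\n")
    sim.truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths


@dataclass(frozen=True)
class CtSimConfig:
    """Design of a synthetic qPCR experiment.

    ``folds`` maps group -> {target gene -> true fold change relative to the
    calibrator group}; the calibrator's folds are implicitly 1.  The default
    replication (3 biological x 3 technical) mirrors the usual qRT-PCR
    triplicate design.  ``target_offset`` is the noise-free Ct gap between
    an unregulated target and the reference gene.
    """

    folds: dict[str, dict[str, float]]
    calibrator_group: str
    reference: str = "EF1a"
    n_biorep: int = 3
    n_techrep: int = 3
    base_ct: float = 20.0
    target_offset: float = 2.0
    noise_sd_bio: float = 0.2
    noise_sd_tech: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.calibrator_group not in self.folds:
            raise ValueError("calibrator_group must appear in folds")
        genes = None
        for group, gf in self.folds.items():
            if self.reference in gf:
                raise ValueError("reference gene cannot have a fold entry")
            if any(f <= 0 for f in gf.values()):
                raise ValueError(f"non-positive fold in group {group!r}")
            if genes is None:
                genes = set(gf)
            elif set(gf) != genes:
                raise ValueError("all groups must list the same target genes")
        if any(f != 1.0 for f in self.folds[self.calibrator_group].values()):
            raise ValueError("calibrator folds must all equal 1")
        if self.n_biorep < 1 or self.n_techrep < 1:
            raise ValueError("replicate counts must be >= 1")

    @property
    def targets(self) -> list[str]:
        return sorted(self.folds[self.calibrator_group])


def simulate_ct_table(config: CtSimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a replicated Ct table with known truth.

    Per (group, biorep): the reference Ct is ``base_ct`` plus biological
    noise; each target Ct is ``base_ct + target_offset - log2(fold)`` plus
    its own biological noise.  Each technical replicate adds independent
    technical noise.  Returns (ct_table, truth) where truth lists the
    planted fold per (group, gene).
    """
    rng = np.random.default_rng(config.seed)
    rows = []
    for group in sorted(config.folds):
        for biorep in range(1, config.n_biorep + 1):
            sample_id = f"{group}_b{biorep}"
            cell_cts = {config.reference:
                        config.base_ct
                        + rng.normal(0.0, config.noise_sd_bio)}
            for gene in config.targets:
                fold = config.folds[group][gene]
                cell_cts[gene] = (config.base_ct + config.target_offset
                                  - float(np.log2(fold))
                                  + rng.normal(0.0, config.noise_sd_bio))
            for gene in [config.reference] + config.targets:
                for techrep in range(1, config.n_techrep + 1):
                    ct = cell_cts[gene] + rng.normal(0.0, config.noise_sd_tech)
                    rows.append({"sample_id": sample_id, "group": group,
                                 "gene": gene, "biorep": biorep,
                                 "techrep": techrep, "ct": ct})
    table = pd.DataFrame(rows, columns=["sample_id", "group", "gene",
                                        "biorep", "techrep", "ct"])
    truth = pd.DataFrame(
        [{"group": g, "gene": gene, "fold": config.folds[g][gene]}
         for g in sorted(config.folds) for gene in config.targets],
        columns=["group", "gene", "fold"])
    return table, truth


def write_ct_sim(table: pd.DataFrame, truth: pd.DataFrame,
                 outdir) -> dict[str, Path]:
    """Write the Ct table (CSV, qpcr input schema) and the truth TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"ct": outdir / "ct_table.csv", "truth": outdir / "ct_truth.tsv"}
    table.to_csv(paths["ct"], index=False)
    truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths
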