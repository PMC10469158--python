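"""Per-promoter element maps, positional summaries, exports and a
permutation test for proximal enrichment.

An element map is the merged, position-sorted list of cis-element hits in
one promoter, each assigned the TSS-relative offset of its 5'-most base.
The positional summary partitions each motif class into proximal
(``tss_offset >= -proximal_bp``, boundary inclusive) and distal counts,
quantifying the observation that stress cis-elements concentrate in the
TSS-proximal part of the promoter.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

from .hse import HSEMatch
from .motifs import MotifMatch
from .sequence_io import PromoterRegion

__all__ = [
    "ElementEntry",
    "ElementMap",
    "PositionalSummary",
    "element_map",
    "positional_summary",
    "export_matches",
    "read_matches_tsv",
    "permutation_enrichment",
]

_TSV_HEADER = ["gene_id", "window", "element", "tss_offset", "strand",
               "length", "aux"]


@dataclass(frozen=True, order=True)
class ElementEntry:
    """One located element: motif id (or "HSE"), TSS offset of its 5'-most
    base, strand, length, and an auxiliary value (spacer length for gapped
    motifs, unit count for HSEs, None otherwise)."""

    tss_offset: int
    element: str
    strand: str
    length: int
    aux: int | None = None


@dataclass(frozen=True)
class ElementMap:
    """All elements of one promoter, sorted by ascending tss_offset."""

    gene_id: str
    window: int
    entries: tuple[ElementEntry, ...] = field(default_factory=tuple)


def _entry_from_match(m: MotifMatch | HSEMatch) -> ElementEntry:
    if isinstance(m, HSEMatch):
        return ElementEntry(tss_offset=m.tss_offset, element="HSE",
                            strand="+", length=m.end - m.start, aux=m.n_units)
    return ElementEntry(tss_offset=m.tss_offset, element=m.motif_id,
                        strand=m.strand, length=m.end - m.start,
                        aux=m.spacer_len)


def element_map(promoter: PromoterRegion,
                matches: Iterable[MotifMatch | HSEMatch]) -> ElementMap:
    """Merge motif and HSE hits of one promoter into a sorted element map.

    Every element is assigned the TSS offset of its 5'-most base in
    promoter orientation; a hit outside the promoter bounds is an error.
    """
    n = len(promoter)
    entries = []
    for m in matches:
        if not (0 <= m.start < m.end <= n):
            raise ValueError(
                f"match [{m.start}, {m.end}) outside promoter {promoter.gene_id} "
                f"of length {n}"
            )
        entries.append(_entry_from_match(m))
    entries.sort()
    return ElementMap(gene_id=promoter.gene_id, window=promoter.window,
                      entries=tuple(entries))


@dataclass(frozen=True)
class PositionalSummary:
    """Per-class counts of proximal vs distal elements.

    ``counts`` maps motif class -> (n_proximal, n_distal); an element is
    proximal iff its tss_offset >= -proximal_bp (boundary inclusive).
    """

    proximal_bp: int
    counts: dict[str, tuple[int, int]]

    def total(self, element: str) -> int:
        p, d = self.counts.get(element, (0, 0))
        return p + d


def positional_summary(maps: Sequence[ElementMap],
                       proximal_bp: int = 500) -> PositionalSummary:
    """Partition each element class into proximal/distal counts over all maps."""
    for em in maps:
        if proximal_bp > em.window:
            raise ValueError(
                f"proximal_bp {proximal_bp} exceeds window {em.window} of "
                f"{em.gene_id}"
            )
    counts: dict[str, list[int]] = {}
    for em in maps:
        for e in em.entries:
            c = counts.setdefault(e.element, [0, 0])
            if e.tss_offset >= -proximal_bp:
                c[0] += 1
            else:
                c[1] += 1
    return PositionalSummary(proximal_bp=proximal_bp,
                             counts={k: (v[0], v[1]) for k, v in counts.items()})


def export_matches(maps: Sequence[ElementMap], format: str, path) -> None:
    """Write element maps as BED6 (0-based half-open), GFF3 (1-based closed)
    or TSV.  Coordinates in BED/GFF are promoter-local; the TSV stores TSS
    offsets and round-trips exactly through :func:`read_matches_tsv`."""
    if format == "TSV":
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(_TSV_HEADER)
            for em in maps:
                for e in em.entries:
                    w.writerow([em.gene_id, em.window, e.element, e.tss_offset,
                                e.strand, e.length,
                                "" if e.aux is None else e.aux])
    elif format == "BED6":
        with open(path, "w") as fh:
            for em in maps:
                for e in em.entries:
                    start = em.window + e.tss_offset
                    fh.write(f"{em.gene_id}\t{start}\t{start + e.length}\t"
                             f"{e.element}\t{0 if e.aux is None else e.aux}\t"
                             f"{e.strand}\n")
    elif format == "GFF3":
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for em in maps:
                for i, e in enumerate(em.entries):
                    start = em.window + e.tss_offset
                    fh.write(f"{em.gene_id}\tcistress\tcis_element\t"
                             f"{start + 1}\t{start + e.length}\t.\t{e.strand}\t.\t"
                             f"ID={em.gene_id}.{i};Name={e.element}\n")
    else:
        raise ValueError(f"unknown export format {format!r}")


def read_matches_tsv(path) -> list[ElementMap]:
    """Re-read a TSV written by :func:`export_matches` (exact round-trip).

    Promoters with no elements are not representable in the TSV and are
    absent from the result.
    """
    rows: dict[tuple[str, int], list[ElementEntry]] = {}
    with open(path, newline="") as fh:
        r = csv.reader(fh, delimiter="\t")
        header = next(r)
        if header != _TSV_HEADER:
            raise ValueError(f"unexpected TSV header {header!r}")
        for rec in r:
            gene_id, window, element, tss_offset, strand, length, aux = rec
            rows.setdefault((gene_id, int(window)), []).append(ElementEntry(
                tss_offset=int(tss_offset), element=element, strand=strand,
                length=int(length), aux=None if aux == "" else int(aux)))
    return [ElementMap(gene_id=g, window=w, entries=tuple(sorted(es)))
            for (g, w), es in rows.items()]


def permutation_enrichment(scan: Callable[[PromoterRegion],
                                          Iterable[MotifMatch | HSEMatch]],
                           promoter: PromoterRegion,
                           n_shuffles: int = 1000,
                           seed: int | None = None,
                           proximal_bp: int = 500,
                           classes: Sequence[str] | None = None,
                           class_min_len: dict[str, int] | None = None,
                           ) -> dict[str, float]:
    """Empirical p-value for proximal enrichment of each motif class.

    The null is generated by mononucleotide (composition-preserving)
    shuffles of the promoter sequence; for each class the p-value is
    ``(1 + #{shuffles with proximal count >= observed}) / (n_shuffles + 1)``
    (so a class with zero observed hits gets p = 1).  ``classes`` fixes the
    classes to report (default: those observed at least once); a class whose
    minimal match length in ``class_min_len`` exceeds the promoter length
    has an undefined p, reported as NaN.
    """
    if n_shuffles < 100:
        raise ValueError("n_shuffles must be >= 100")
    rng = np.random.default_rng(seed)

    def proximal_counts(p: PromoterRegion) -> dict[str, int]:
        em = element_map(p, scan(p))
        out: dict[str, int] = {}
        for e in em.entries:
            if e.tss_offset >= -proximal_bp:
                out[e.element] = out.get(e.element, 0) + 1
        return out

    obs_counts = proximal_counts(promoter)
    names = list(classes) if classes is not None else sorted(obs_counts)
    undefined = {k for k in names
                 if class_min_len and class_min_len.get(k, 0) > len(promoter)}
    observed = {k: obs_counts.get(k, 0) for k in names if k not in undefined}
    if not names:
        return {}
    if all(v == 0 for v in observed.values()):
        # every shuffle trivially reaches a count of >= 0
        out = {k: 1.0 for k in observed}
        out.update({k: math.nan for k in undefined})
        return out
    exceed = {k: 0 for k in observed}
    letters = np.frombuffer(promoter.sequence.encode(), dtype="S1")
    for _ in range(n_shuffles):
        shuf = rng.permutation(letters).tobytes().decode()
        p = PromoterRegion(
            gene_id=promoter.gene_id, seq_id=promoter.seq_id,
            strand=promoter.strand, genomic_interval=promoter.genomic_interval,
            sequence=shuf, window=promoter.window, truncated=promoter.truncated)
        counts = proximal_counts(p)
        for k in exceed:
            if counts.get(k, 0) >= observed[k]:
                exceed[k] += 1
    out = {k: (1 + exceed[k]) / (n_shuffles + 1) for k in observed}
    out.update({k: math.nan for k in undefined})
    return out
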