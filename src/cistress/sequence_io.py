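"""Reading genomes and gene models, and extracting strand-aware promoter windows.

All internal coordinates are 0-based, half-open.  GFF3 input (1-based,
closed) is converted on read.  The transcription start site (TSS) of a gene
is the 5'-most base of its annotated feature on the gene's strand; a
promoter is the window of up to ``window`` bases immediately upstream of the
TSS, reported 5'->3' on the gene's strand so that TSS-relative position -1
is the base adjacent to the TSS.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from Bio.Seq import Seq
from Bio.SeqIO.FastaIO import SimpleFastaParser
import gffutils.iterators

__all__ = [
    "GeneModel",
    "PromoterRegion",
    "FastaParseError",
    "read_fasta",
    "read_gene_models",
    "extract_promoter",
    "write_promoters_fasta",
    "read_promoters_fasta",
    "sanitize_sequence",
]

_VALID_STRANDS = frozenset("+-")
_SCAN_ALPHABET = frozenset("ACGTN")


class FastaParseError(ValueError):
    """Raised for structurally malformed FASTA input."""


@dataclass(frozen=True)
class GeneModel:
    """A gene feature reduced to what promoter extraction needs.

    ``span`` is the 0-based half-open genomic interval of the feature;
    ``tss`` is the 0-based coordinate of the transcription start site
    (``span[0]`` on the plus strand, ``span[1] - 1`` on the minus strand).
    """

    gene_id: str
    seq_id: str
    strand: str
    tss: int
    span: tuple[int, int]

    def __post_init__(self) -> None:
        if self.strand not in _VALID_STRANDS:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        lo, hi = self.span
        if not (lo <= self.tss < hi):
            raise ValueError(
                f"tss {self.tss} outside feature span [{lo}, {hi}) for {self.gene_id}"
            )


@dataclass(frozen=True)
class PromoterRegion:
    """An upstream promoter window oriented 5'->3' on the gene's strand.

    ``genomic_interval`` is 0-based half-open on the reference.  The last
    base of ``sequence`` is the base at TSS-relative position -1, i.e. the
    base immediately upstream of the TSS on the gene's strand.
    ``truncated`` is True when the contig boundary clipped the window.
    """

    gene_id: str
    seq_id: str
    strand: str
    genomic_interval: tuple[int, int]
    sequence: str
    window: int
    truncated: bool = field(default=False)

    def __post_init__(self) -> None:
        lo, hi = self.genomic_interval
        if len(self.sequence) != hi - lo:
            raise ValueError("sequence length does not match genomic_interval")
        if len(self.sequence) > self.window:
            raise ValueError("sequence longer than requested window")

    def __len__(self) -> int:
        return len(self.sequence)

    @classmethod
    def from_sequence(cls, gene_id: str, sequence: str, *, seq_id: str | None = None,
                      strand: str = "+") -> "PromoterRegion":
        """Wrap a pre-extracted promoter sequence (e.g. from a promoter FASTA).

        The window is taken to be the sequence length and coordinates are
        promoter-local.
        """
        seq = sanitize_sequence(sequence, name=gene_id)
        return cls(
            gene_id=gene_id,
            seq_id=seq_id or gene_id,
            strand=strand,
            genomic_interval=(0, len(seq)),
            sequence=seq,
            window=len(seq),
            truncated=False,
        )


def sanitize_sequence(seq: str, *, name: str = "<sequence>") -> str:
    """Uppercase ``seq``, convert U to T and replace non-ACGTN bases by N.

    A replacement triggers a single warning naming the sequence; scanning
    downstream is then fully deterministic over the {A,C,G,T,N} alphabet.
    """
    seq = seq.upper().replace("U", "T")
    if not _SCAN_ALPHABET.issuperset(seq):
        bad = sorted(set(seq) - _SCAN_ALPHABET)
        warnings.warn(
            f"{name}: replacing non-ACGTN characters {bad} by N", stacklevel=2
        )
        seq = "".join(c if c in _SCAN_ALPHABET else "N" for c in seq)
    return seq


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an id -> sequence mapping.

    Ids are the first whitespace-delimited token of each header.  Sequences
    are uppercased with U converted to T.  Duplicate ids and sequence data
    before the first header are errors.
    """
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise FastaParseError(
                    f"{path}: line {lineno}: sequence data before first FASTA header"
                )
            break
        else:
            return {}

    records: dict[str, str] = {}
    with open(path) as handle:
        for title, seq in SimpleFastaParser(handle):
            tokens = title.split()
            if not tokens:
                raise FastaParseError(f"{path}: FASTA header with empty id")
            seq_id = tokens[0]
            if seq_id in records:
                raise FastaParseError(f"{path}: duplicate sequence id {seq_id!r}")
            records[seq_id] = seq.upper().replace("U", "T")
    return records


def read_gene_models(path, feature: str = "gene") -> list[GeneModel]:
    """Read gene models from GFF3, converting to 0-based half-open coordinates.

    Only records of ``feature`` type are used.  Records with an unknown
    strand, inverted coordinates or no ``ID`` attribute are skipped with a
    warning naming the record (record-level validation; the rest of the file
    is still read).
    """
    models: list[GeneModel] = []
    for feat in gffutils.iterators.DataIterator(str(path)):
        if feat.featuretype != feature:
            continue
        ident = (feat.attributes.get("ID") or [None])[0]
        label = ident or f"{feat.seqid}:{feat.start}-{feat.end}"
        if ident is None:
            warnings.warn(f"skipping {feature} record {label}: no ID attribute",
                          stacklevel=2)
            continue
        if feat.strand not in _VALID_STRANDS:
            warnings.warn(
                f"skipping {feature} record {label}: unknown strand {feat.strand!r}",
                stacklevel=2,
            )
            continue
        if feat.start > feat.end:
            warnings.warn(
                f"skipping {feature} record {label}: start > end "
                f"({feat.start} > {feat.end})",
                stacklevel=2,
            )
            continue
        start0 = feat.start - 1          # GFF3 is 1-based closed
        end0 = feat.end                  # half-open
        tss = start0 if feat.strand == "+" else end0 - 1
        models.append(
            GeneModel(gene_id=ident, seq_id=feat.seqid, strand=feat.strand,
                      tss=tss, span=(start0, end0))
        )
    return models


def extract_promoter(gene: GeneModel, genome: dict[str, str],
                     window: int = 1000) -> PromoterRegion:
    """Extract the up-to-``window``-bp region immediately upstream of the TSS.

    On the plus strand the window is ``[tss - window, tss)`` read as-is; on
    the minus strand it is ``[tss + 1, tss + 1 + window)`` reverse
    complemented, so that in both cases the returned sequence runs 5'->3'
    on the gene's strand and ends at TSS-relative position -1.  Windows are
    clipped at contig bounds and flagged ``truncated``.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if gene.seq_id not in genome:
        raise KeyError(f"sequence {gene.seq_id!r} not found in genome")
    contig = genome[gene.seq_id]
    n = len(contig)
    if gene.strand == "+":
        lo = max(0, min(n, gene.tss - window))
        hi = max(0, min(n, gene.tss))
        raw = contig[lo:hi]
    else:
        lo = max(0, min(n, gene.tss + 1))
        hi = max(0, min(n, gene.tss + 1 + window))
        raw = str(Seq(contig[lo:hi]).reverse_complement())
    truncated = (hi - lo) < window
    if hi == lo:
        warnings.warn(
            f"promoter window for {gene.gene_id} lies entirely off-contig; "
            "returning empty region",
            stacklevel=2,
        )
    seq = sanitize_sequence(raw, name=gene.gene_id)
    return PromoterRegion(
        gene_id=gene.gene_id,
        seq_id=gene.seq_id,
        strand=gene.strand,
        genomic_interval=(lo, hi),
        sequence=seq,
        window=window,
        truncated=truncated,
    )


def write_promoters_fasta(promoters, path) -> None:
    """Write promoters as FASTA with headers ``gene_id seq_id:start-end(strand)``."""
    with open(path, "w") as out:
        for p in promoters:
            lo, hi = p.genomic_interval
            out.write(f">{p.gene_id} {p.seq_id}:{lo}-{hi}({p.strand})\n")
            for i in range(0, len(p.sequence), 70):
                out.write(p.sequence[i:i + 70] + "\n")


def read_promoters_fasta(path) -> list[PromoterRegion]:
    """Read a promoter FASTA (pre-extracted windows) into PromoterRegions."""
    return [PromoterRegion.from_sequence(gene_id, seq)
            for gene_id, seq in read_fasta(path).items()]
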