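"""Declarative cis-element definitions and both-strand promoter scanning.

Three motif kinds are supported:

* ``exact`` — a literal nucleotide word (e.g. the plant UPRE,
  ATTGGTCCACGTCATC, bound by bZIP28/bZIP60);
* ``degenerate`` — a single IUPAC-ambiguity word (e.g. ERSE-II,
  ATTGGNCCACG);
* ``gapped`` — two IUPAC words separated by an unconstrained spacer whose
  length lies in a closed range (e.g. the plant ERSE, CCAAT-N10-CACG,
  where NF-Y binds the CCAAT box and the bZIP dimer the CACG core).

Matching semantics for the sequence alphabet {A,C,G,T,N}: an N in the
*motif* matches any of A/C/G/T, while an N in the *sequence* (an unknown or
masked base) satisfies no motif position.  Minus-strand hits are windows
whose reverse complement matches the motif; they are reported in promoter
coordinates.  Overlapping hits are all reported.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from typing import Iterable, Literal

from Bio.Seq import Seq

from .sequence_io import PromoterRegion

__all__ = [
    "MotifSpec",
    "MotifMatch",
    "IUPAC_BASES",
    "reverse_complement",
    "builtin_upr_catalog",
    "scan_motif",
    "scan_catalog",
    "load_motif_file",
]

#: expansion of each IUPAC nucleotide code over the concrete bases it allows
IUPAC_BASES: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

MotifKind = Literal["exact", "degenerate", "gapped"]


@dataclass(frozen=True)
class MotifSpec:
    """A declarative motif definition.

    ``parts`` holds one IUPAC word for exact/degenerate motifs and two for
    gapped motifs; ``spacer`` is the closed range of allowed spacer lengths
    (gapped only).  ``enabled`` lets a catalogue carry variants that are not
    scanned by default.
    """

    motif_id: str
    kind: MotifKind
    parts: tuple[str, ...]
    spacer: tuple[int, int] | None = None
    source_label: str = ""
    enabled: bool = True

    def __post_init__(self) -> None:
        if not self.parts:
            raise ValueError("parts must be non-empty")
        for part in self.parts:
            for off, ch in enumerate(part):
                if ch not in IUPAC_BASES:
                    raise ValueError(
                        f"{self.motif_id}: non-IUPAC character {ch!r} at offset {off}"
                    )
        if self.kind == "gapped":
            if len(self.parts) != 2:
                raise ValueError(f"{self.motif_id}: gapped motif needs 2 parts")
            if self.spacer is None:
                raise ValueError(f"{self.motif_id}: gapped motif needs a spacer range")
            lo, hi = self.spacer
            if not (0 <= lo <= hi):
                raise ValueError(f"{self.motif_id}: invalid spacer range {self.spacer}")
        else:
            if len(self.parts) != 1:
                raise ValueError(f"{self.motif_id}: {self.kind} motif needs 1 part")
            if self.spacer is not None:
                raise ValueError(f"{self.motif_id}: spacer only valid for gapped kind")

    @property
    def min_length(self) -> int:
        if self.kind == "gapped":
            return len(self.parts[0]) + self.spacer[0] + len(self.parts[1])
        return len(self.parts[0])


@dataclass(frozen=True, order=True)
class MotifMatch:
    """A located motif hit in promoter-local coordinates (0-based half-open).

    ``strand`` is the strand of the match relative to the promoter's 5'->3'
    orientation.  ``tss_offset`` is ``start - len(promoter)``, i.e. the
    TSS-relative position of the 5'-most base (always negative).
    ``spacer_len`` is present only for gapped motifs.
    """

    start: int
    end: int
    strand: str
    motif_id: str
    tss_offset: int
    spacer_len: int | None = None


def reverse_complement(seq: str) -> str:
    """Reverse complement of an IUPAC nucleotide string (ambiguity-aware)."""
    seq = seq.upper()
    for off, ch in enumerate(seq):
        if ch not in IUPAC_BASES:
            raise ValueError(f"non-IUPAC character {ch!r} at offset {off}")
    return str(Seq(seq).reverse_complement())


def builtin_upr_catalog() -> list[MotifSpec]:
    """The built-in catalogue of ER-UPR cis-elements.

    Consensus elements bound by the ER-stress bZIP factors (bZIP28/bZIP60
    and relatives): the plant ERSE (CCAAT-N10-CACG), ERSE-II, the plant
    UPRE, UPRE-I/II/III, and the bZIP core pentamer CACGT whose reverse
    complement ACGTG is picked up by minus-strand scanning.  The rice-type
    UPRE-II variant is shipped under its own id but disabled by default.
    """
    return [
        MotifSpec("pERSE", "gapped", ("CCAAT", "CACG"), spacer=(10, 10),
                  source_label="pERSE"),
        MotifSpec("ERSE-II", "degenerate", ("ATTGGNCCACG",), source_label="ERSE-II"),
        MotifSpec("pUPRE", "exact", ("ATTGGTCCACGTCATC",), source_label="pUPRE"),
        MotifSpec("UPRE-I", "exact", ("CAGCGTG",), source_label="UPRE-I"),
        MotifSpec("UPRE-II", "exact", ("TACGTG",), source_label="UPRE-II"),
        MotifSpec("UPRE-III", "exact", ("TCATCG",), source_label="UPRE-III"),
        MotifSpec("BZIP_CORE", "degenerate", ("CACGT",), source_label="bZIP core"),
        MotifSpec("UPRE-II-rice", "exact", ("GATGACGCGTAC",),
                  source_label="UPRE-II (rice)", enabled=False),
    ]


def _part_regex(part: str) -> re.Pattern:
    # sequence N must match nothing, so classes expand over concrete bases only
    return re.compile("".join(f"[{IUPAC_BASES[c]}]" for c in part))


def _find_overlapping(pattern: re.Pattern, seq: str) -> Iterable[int]:
    pos = 0
    while True:
        m = pattern.search(seq, pos)
        if m is None:
            return
        yield m.start()
        pos = m.start() + 1


def _scan_one_strand(seq: str, spec: MotifSpec) -> list[tuple[int, int, int | None]]:
    """All (start, end, spacer_len) hits of ``spec`` on ``seq`` as given."""
    hits: list[tuple[int, int, int | None]] = []
    if spec.kind in ("exact", "degenerate"):
        for start in _find_overlapping(_part_regex(spec.parts[0]), seq):
            hits.append((start, start + len(spec.parts[0]), None))
    else:
        left, right = spec.parts
        right_re = _part_regex(right)
        lo, hi = spec.spacer
        for start in _find_overlapping(_part_regex(left), seq):
            for spacer in range(lo, hi + 1):
                rstart = start + len(left) + spacer
                rend = rstart + len(right)
                if rend > len(seq):
                    break
                if right_re.fullmatch(seq, rstart, rend):
                    hits.append((start, rend, spacer))
    return hits


def scan_motif(promoter: PromoterRegion, spec: MotifSpec,
               strands: str = "both") -> list[MotifMatch]:
    """Scan one promoter for one motif on the requested strand(s).

    Minus-strand hits are windows whose reverse complement matches the
    motif; for gapped motifs one hit is reported per (left-part position,
    spacer length) pair.  A window matching identically on both strands of
    a palindromic motif is reported once with strand '+'.  Results are
    sorted by start, then strand.
    """
    if strands not in ("+", "-", "both"):
        raise ValueError(f"strands must be '+', '-' or 'both', got {strands!r}")
    seq = promoter.sequence
    n = len(seq)
    raw: list[tuple[int, int, str, int | None]] = []
    if strands in ("+", "both"):
        for s, e, sp in _scan_one_strand(seq, spec):
            raw.append((s, e, "+", sp))
    if strands in ("-", "both"):
        rc = str(Seq(seq).reverse_complement())
        for s, e, sp in _scan_one_strand(rc, spec):
            raw.append((n - e, n - s, "-", sp))
    # palindromic dedup: identical (start, end) on both strands -> '+' once
    best: dict[tuple[int, int, int | None], str] = {}
    for s, e, strand, sp in raw:
        key = (s, e, sp)
        if key not in best or strand == "+":
            best[key] = strand
    matches = [
        MotifMatch(start=s, end=e, strand=strand, motif_id=spec.motif_id,
                   tss_offset=s - n, spacer_len=sp)
        for (s, e, sp), strand in best.items()
    ]
    matches.sort(key=lambda m: (m.start, m.strand, m.end))
    return matches


def scan_catalog(promoter: PromoterRegion,
                 catalog: Iterable[MotifSpec] | None = None,
                 strands: str = "both",
                 include_disabled: bool = False) -> list[MotifMatch]:
    """Scan a promoter against a catalogue (the built-in one by default)."""
    if catalog is None:
        catalog = builtin_upr_catalog()
    out: list[MotifMatch] = []
    for spec in catalog:
        if spec.enabled or include_disabled:
            out.extend(scan_motif(promoter, spec, strands=strands))
    out.sort(key=lambda m: (m.start, m.motif_id, m.strand))
    return out


def load_motif_file(path) -> list[MotifSpec]:
    """Load a user catalogue from JSON: a list of records with keys
    ``id``, ``kind``, ``parts`` and optionally ``spacer`` ([lo, hi]),
    ``label`` and ``enabled``."""
    with open(path) as fh:
        records = json.load(fh)
    specs = []
    for rec in records:
        specs.append(MotifSpec(
            motif_id=rec["id"],
            kind=rec["kind"],
            parts=tuple(rec["parts"]),
            spacer=tuple(rec["spacer"]) if rec.get("spacer") else None,
            source_label=rec.get("label", rec["id"]),
            enabled=rec.get("enabled", True),
        ))
    return specs
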