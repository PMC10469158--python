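"""Heat-shock-element (HSE) grammar scanning.

Heat stress transcription factors bind arrays of the palindromic pentamer
module nGAAn alternating with its reverse complement nTTCn (consensus
5'-GAAnnTTC-3').  Functional elements tolerate degeneracy: the G (and, on
the reverse module, the C) is invariable while the A may sit at either of
two positions, giving the relaxed module patterns nGANn / nGNAn and their
reverse complements.  An HSE is a run of at least ``min_units`` adjacent
(stride-5, non-overlapping) modules whose orientations strictly alternate.

Two classification modes are provided:

* ``paper`` — the relaxed rule: forward iff position 2 is G and position 3
  or 4 is A (1-based within the pentamer); reverse iff the reverse
  complement is forward.
* ``perfect`` — the strict consensus: forward iff the pentamer matches
  nGAAn, reverse iff it matches nTTCn.

The grammar is self-reverse-complementary: the reverse complement of a
valid alternating run is itself a valid alternating run, so scanning the
given strand already finds every physical element exactly once.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

from .motifs import reverse_complement
from .sequence_io import PromoterRegion

__all__ = ["PentamerClass", "HSEMatch", "classify_unit", "scan_hse"]

Mode = Literal["paper", "perfect"]


@dataclass(frozen=True)
class PentamerClass:
    """Classification of one 5-bp module.

    ``orientation`` is 'forward', 'reverse', 'both' or 'none';
    ``matched_patterns`` names the module pattern(s) satisfied per
    orientation (for the relaxed mode: subsets of {nGANn, nGNAn}).
    """

    orientation: str
    matched_patterns: dict[str, frozenset[str]]


@dataclass(frozen=True)
class HSEMatch:
    """A maximal alternating run of HSE modules, promoter-local coordinates."""

    start: int
    end: int
    n_units: int
    unit_orientations: tuple[str, ...]
    mode: Mode
    tss_offset: int

    def __post_init__(self) -> None:
        if self.end - self.start != 5 * self.n_units:
            raise ValueError("HSE length must be 5 x n_units")
        for a, b in zip(self.unit_orientations, self.unit_orientations[1:]):
            if a == b:
                raise ValueError("unit orientations must strictly alternate")


def _forward_patterns(pentamer: str, mode: Mode) -> frozenset[str]:
    """Which forward module pattern(s) a pentamer satisfies.

    N in the sequence is unknown and fails every constrained position.
    """
    p = pentamer
    hits = set()
    if mode == "paper":
        if p[1] == "G" and p[2] == "A":
            hits.add("nGANn")
        if p[1] == "G" and p[3] == "A":
            hits.add("nGNAn")
    else:
        if p[1] == "G" and p[2] == "A" and p[3] == "A":
            hits.add("nGAAn")
    return frozenset(hits)


def classify_unit(pentamer: str, mode: Mode = "paper") -> PentamerClass:
    """Classify a 5-nt module as forward, reverse, both or none.

    A module is reverse iff its reverse complement is forward; for these
    module grammars the two cases are mutually exclusive, but 'both' is
    retained in the interface for completeness.
    """
    if len(pentamer) != 5:
        raise ValueError(f"pentamer must have length 5, got {len(pentamer)}")
    pentamer = pentamer.upper()
    for ch in pentamer:
        if ch not in "ACGTN":
            raise ValueError(f"invalid base {ch!r} in pentamer")
    if "N" in pentamer:
        # an unknown base invalidates the whole module (same policy as
        # sequence N in motif scanning: unknown matches nothing)
        return PentamerClass(orientation="none",
                             matched_patterns={"forward": frozenset(),
                                               "reverse": frozenset()})
    fwd = _forward_patterns(pentamer, mode)
    rev = _forward_patterns(reverse_complement(pentamer), mode)
    if fwd and rev:
        orientation = "both"
    elif fwd:
        orientation = "forward"
    elif rev:
        orientation = "reverse"
    else:
        orientation = "none"
    return PentamerClass(
        orientation=orientation,
        matched_patterns={"forward": fwd, "reverse": rev},
    )


def scan_hse(promoter: PromoterRegion, mode: Mode = "paper",
             min_units: int = 3) -> list[HSEMatch]:
    """Find all maximal alternating module runs of >= ``min_units`` units.

    Runs are enumerated at every phase offset 0..4 with stride-5 module
    framing; within a phase a run ends where the next module is invalid or
    repeats the previous orientation, so reported runs cannot be extended
    on either flank at the same phase.  Overlapping runs at different
    phases are reported independently.  Results are sorted by start.
    """
    if min_units < 2:
        raise ValueError("min_units must be >= 2")
    seq = promoter.sequence
    n = len(seq)
    matches: list[HSEMatch] = []
    for phase in range(5):
        run_start: int | None = None
        run_orients: list[str] = []

        def flush() -> None:
            nonlocal run_start, run_orients
            if run_start is not None and len(run_orients) >= min_units:
                end = run_start + 5 * len(run_orients)
                matches.append(HSEMatch(
                    start=run_start, end=end, n_units=len(run_orients),
                    unit_orientations=tuple(run_orients), mode=mode,
                    tss_offset=run_start - n,
                ))
            run_start, run_orients = None, []

        pos = phase
        while pos + 5 <= n:
            cls = classify_unit(seq[pos:pos + 5], mode)
            o = cls.orientation
            if o == "none":
                flush()
            else:
                # 'both' cannot occur for these grammars; prefer the
                # orientation that extends the current run, else forward
                if o == "both":
                    o = ("reverse" if run_orients and run_orients[-1] == "forward"
                         else "forward")
                if run_orients and run_orients[-1] == o:
                    flush()
                    run_start = pos
                    run_orients = [o]
                elif run_orients:
                    run_orients.append(o)
                else:
                    run_start = pos
                    run_orients = [o]
            pos += 5
        flush()
    matches.sort(key=lambda m: (m.start, m.end))
    return matches
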