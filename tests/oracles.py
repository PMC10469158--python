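"""Independent brute-force oracles used only by the tests.

These deliberately avoid the implementation's code paths: motif matching is
re-derived position by position from the IUPAC expansion table, HSE runs by
enumerate-and-extend over pentamer sets generated exhaustively from the
module patterns, and studentized-range quantiles by direct quadrature of
the classical CDF integral followed by root finding.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import integrate, optimize
from scipy.stats import chi2, norm

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMP = str.maketrans("ACGTN", "TGCAN")


def rc(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _match_at(seq: str, part: str, i: int) -> bool:
    if i < 0 or i + len(part) > len(seq):
        return False
    return all(seq[i + j] in IUPAC[c] for j, c in enumerate(part))


def _one_strand_hits(seq, spec):
    out = []
    if spec.kind in ("exact", "degenerate"):
        part = spec.parts[0]
        for i in range(len(seq) - len(part) + 1):
            if _match_at(seq, part, i):
                out.append((i, i + len(part), None))
    else:
        left, right = spec.parts
        lo, hi = spec.spacer
        for i in range(len(seq) - len(left) + 1):
            if not _match_at(seq, left, i):
                continue
            for sp in range(lo, hi + 1):
                r = i + len(left) + sp
                if r + len(right) <= len(seq) and _match_at(seq, right, r):
                    out.append((i, r + len(right), sp))
    return out


def naive_scan(seq: str, spec, strands: str = "both"):
    """All (start, end, strand, spacer) hits of ``spec``, with the
    palindromic-window dedup of identical intervals to strand '+'."""
    n = len(seq)
    raw = []
    if strands in ("+", "both"):
        raw += [(s, e, "+", sp) for s, e, sp in _one_strand_hits(seq, spec)]
    if strands in ("-", "both"):
        raw += [(n - e, n - s, "-", sp)
                for s, e, sp in _one_strand_hits(rc(seq), spec)]
    best = {}
    for s, e, strand, sp in raw:
        key = (s, e, sp)
        if key not in best or strand == "+":
            best[key] = strand
    return sorted((s, e, strand, sp) for (s, e, sp), strand in best.items())


def hse_unit_sets(mode: str) -> tuple[frozenset[str], frozenset[str]]:
    """(forward, reverse) pentamer sets generated exhaustively from the
    module pattern strings ('n' = any concrete base)."""
    patterns = ["nGANn", "nGNAn"] if mode == "paper" else ["nGAAn"]
    fwd = set()
    for p in itertools.product("ACGT", repeat=5):
        word = "".join(p)
        for pat in patterns:
            if all(pc in ("n", "N") or pc == wc for pc, wc in zip(pat, word)):
                fwd.add(word)
    rev = {rc(w) for w in fwd}
    return frozenset(fwd), frozenset(rev)


def naive_hse(seq: str, mode: str = "paper", min_units: int = 3):
    """Maximal alternating module runs by enumerate-and-extend.

    Returns sorted (start, end, n_units, orientations) tuples.
    """
    fwd, rev = hse_unit_sets(mode)

    def orient(i):
        w = seq[i:i + 5]
        if len(w) < 5:
            return None
        if w in fwd:
            return "forward"
        if w in rev:
            return "reverse"
        return None

    out = []
    for s in range(len(seq)):
        o = orient(s)
        if o is None:
            continue
        left = orient(s - 5) if s >= 5 else None
        if left is not None and left != o:
            continue  # extendable to the left -> not maximal
        orients = [o]
        while True:
            nxt = orient(s + 5 * len(orients))
            if nxt is None or nxt == orients[-1]:
                break
            orients.append(nxt)
        if len(orients) >= min_units:
            out.append((s, s + 5 * len(orients), len(orients), tuple(orients)))
    return sorted(out)


def prange_cdf(r: float, k: int) -> float:
    """P(range of k independent standard normals <= r) by quadrature."""
    if r <= 0:
        return 0.0
    f = lambda u: k * norm.pdf(u) * (norm.cdf(u) - norm.cdf(u - r)) ** (k - 1)
    val, _ = integrate.quad(f, -10, 10, limit=200)
    return val


_GL_INNER = np.polynomial.legendre.leggauss(240)
_GL_OUTER = np.polynomial.legendre.leggauss(160)


def _gl_nodes(a: float, b: float, rule):
    x, w = rule
    return 0.5 * (b - a) * x + 0.5 * (b + a), 0.5 * (b - a) * w


def studentized_range_cdf(q: float, k: int, df: float) -> float:
    """CDF of the studentized range by double Gauss-Legendre quadrature.

    Integrates P(range of k std normals <= q*s) against the density of the
    scale estimate s = sqrt(chi2_df / df); accurate to ~1e-8 for the df
    ranges used here.
    """
    if q <= 0:
        return 0.0
    u, wu = _gl_nodes(-9.0, 9.0, _GL_INNER)          # location of the max
    s_max = max(3.0, 1.0 + 12.0 / np.sqrt(2.0 * df))
    s, ws = _gl_nodes(1e-9, s_max, _GL_OUTER)
    phi_u = norm.pdf(u)
    cdf_u = norm.cdf(u)
    # inner integral for each s: P(range <= q*s)
    low = cdf_u[None, :] - norm.cdf(u[None, :] - q * s[:, None])
    inner = (k * phi_u[None, :] * np.clip(low, 0.0, None) ** (k - 1)) @ wu
    dens = 2.0 * df * s * chi2.pdf(df * s * s, df)
    return float(np.dot(ws, dens * inner))


def studentized_range_ppf(p: float, k: int, df: float) -> float:
    """Quantile by root finding on the quadrature CDF (accurate ~1e-6)."""
    return optimize.brentq(
        lambda q: studentized_range_cdf(q, k, df) - p, 1e-3, 100.0,
        xtol=1e-8)
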