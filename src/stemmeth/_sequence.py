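"""Sequence-level helpers: strand-aware trinucleotide extraction and
cytosine context classification (CG / CHG / CHH, H = A, C or T).

All positions here are 1-based reference coordinates, matching the
cytosine-report convention; conversion to 0-based half-open happens in
:mod:`stemmeth.io_formats`.
"""

from __future__ import annotations

import numpy as np

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_COMPLEMENT_BYTES = bytes.maketrans(b"ACGTN", b"TGCAN")

CONTEXTS = ("CG", "CHG", "CHH")
_H = frozenset("ACT")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def context_from_trinucleotide(tri: str) -> str | None:
    """Classify a 3-mer read 5'->3' on the cytosine's own strand.

    Returns ``None`` when the context is undefined (3-mer truncated at a
    chromosome end, non-ACGT base, or first base not a cytosine).
    """
    if len(tri) != 3 or tri[0] != "C":
        return None
    if tri[1] == "G":
        return "CG"
    if tri[1] in _H and tri[2] == "G":
        return "CHG"
    if tri[1] in _H and tri[2] in _H:
        return "CHH"
    return None


def trinucleotide_at(seq: str, pos: int, strand: str) -> str:
    """3-mer starting at the cytosine, read 5'->3' on `strand`.

    `pos` is 1-based on the plus-strand reference. May be shorter than 3
    characters at chromosome ends.
    """
    i = pos - 1
    if strand == "+":
        return seq[i : i + 3].upper()
    if strand == "-":
        return revcomp(seq[max(0, i - 2) : i + 1].upper())
    raise ValueError(f"invalid strand {strand!r}")


def classify_context(seq: str, pos: int, strand: str) -> str | None:
    """Context of the cytosine at 1-based `pos` on `strand`.

    Raises ``ValueError`` if the base at that position is not a cytosine on
    the given strand (a G on the plus strand, for minus-strand cytosines).
    Returns ``None`` for contexts undefined because the 3-mer runs off the
    chromosome or contains a non-ACGT base.
    """
    i = pos - 1
    if i < 0 or i >= len(seq):
        raise ValueError(f"position {pos} outside sequence of length {len(seq)}")
    base = seq[i].upper()
    expected = "C" if strand == "+" else "G"
    if base != expected:
        raise ValueError(
            f"base at position {pos} ({strand}) is {base!r}, not a cytosine on that strand"
        )
    return context_from_trinucleotide(trinucleotide_at(seq, pos, strand))


def find_cytosines(seq: str) -> "np.ndarray":
    """All cytosines of a chromosome on both strands, vectorized.

    Returns a structured array with fields ``pos`` (1-based), ``strand``,
    ``context`` and ``trinucleotide``, sorted by (pos, strand). Cytosines
    with undefined context (chromosome ends, Ns) are excluded.
    """
    s = np.frombuffer(seq.upper().encode("ascii"), dtype="S1")
    n = len(s)
    out = []
    for strand, base in (("+", b"C"), ("-", b"G")):
        idx = np.flatnonzero(s == base)
        if strand == "+":
            ok = idx <= n - 3
            idx = idx[ok]
            b1, b2 = s[idx + 1], s[idx + 2]
        else:
            idx = idx[idx >= 2]
            # read 5'->3' on the minus strand: complement of i-1, i-2
            b1 = np.frombuffer(s[idx - 1].tobytes().translate(_COMPLEMENT_BYTES), dtype="S1")
            b2 = np.frombuffer(s[idx - 2].tobytes().translate(_COMPLEMENT_BYTES), dtype="S1")
        is_h1 = (b1 == b"A") | (b1 == b"C") | (b1 == b"T")
        is_h2 = (b2 == b"A") | (b2 == b"C") | (b2 == b"T")
        ctx = np.full(len(idx), "", dtype="U3")
        ctx[b1 == b"G"] = "CG"
        ctx[is_h1 & (b2 == b"G")] = "CHG"
        ctx[is_h1 & is_h2] = "CHH"
        keep = ctx != ""
        idx, ctx, b1, b2 = idx[keep], ctx[keep], b1[keep], b2[keep]
        tri = np.char.add(
            np.char.add("C", b1.astype("U1")), b2.astype("U1")
        )
        rec = np.empty(
            len(idx),
            dtype=[("pos", "i8"), ("strand", "U1"), ("context", "U3"), ("trinucleotide", "U3")],
        )
        rec["pos"] = idx + 1
        rec["strand"] = strand
        rec["context"] = ctx
        rec["trinucleotide"] = tri
        out.append(rec)
    allrec = np.concatenate(out)
    order = np.lexsort((allrec["strand"], allrec["pos"]))
    return allrec[order]
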