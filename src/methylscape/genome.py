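"""Genome container and cytosine sequence-context classification.

Plant cytosine methylation occurs in three sequence contexts, CG, CHG and
CHH (H = A, C or T), each maintained by a distinct methyltransferase
pathway.  The CHH context is further split into the CWA sub-context
(trinucleotides CAA and CTA, the CMT2 substrate) and the non-CWA remainder
(the RdDM/DRM substrate).  All classification here is strand-aware: the
trinucleotide is read 5'->3' on the cytosine's own strand, so for a minus
strand site the forward-strand base is G and the trinucleotide is the
reverse complement of the forward window ending at that position.

Internal coordinates are 0-based half-open throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONTEXTS = ("CG", "CHG", "CHH")
CWA_TRINUCLEOTIDES = frozenset({"CAA", "CTA"})

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class InvalidSiteError(ValueError):
    """Raised when a position queried as a cytosine is not a C on that strand."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GenomeAssembly:
    """A set of named chromosome sequences, optionally with an unmethylated
    control chromosome (the chloroplast's role: used to estimate bisulfite
    conversion error)."""

    sequences: dict[str, str]
    control_chrom: str | None = None

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            if not seq:
                raise ValueError(f"chromosome {name!r} has empty sequence")
            if set(seq) - set("ACGTN"):
                bad = sorted(set(seq) - set("ACGTN"))
                raise ValueError(f"chromosome {name!r}: alphabet outside ACGTN: {bad}")
        if self.control_chrom is not None and self.control_chrom not in self.sequences:
            raise ValueError(f"control chromosome {self.control_chrom!r} not in assembly")

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    @property
    def analysis_chroms(self) -> list[str]:
        """Chromosome names excluding the conversion-error control."""
        return [c for c in self.sequences if c != self.control_chrom]


def classify_context_from_trinucleotide(tri: str) -> str | None:
    """Context of a trinucleotide read 5'->3' on the cytosine's strand.

    Returns None (unclassifiable) if the window contains N.
    Raises :class:`InvalidSiteError` if the first base is not C.
    """
    if len(tri) != 3:
        raise InvalidSiteError(f"trinucleotide must have length 3, got {tri!r}")
    if "N" in tri:
        return None
    if tri[0] != "C":
        raise InvalidSiteError(f"trinucleotide {tri!r} does not start with C")
    if tri[1] == "G":
        return "CG"
    if tri[2] == "G":
        return "CHG"
    return "CHH"


def classify_context(
    genome: GenomeAssembly, chrom: str, pos: int, strand: str
) -> tuple[str | None, str | None]:
    """Classify the cytosine at (chrom, pos, strand) into CG/CHG/CHH.

    ``pos`` is the 0-based forward-strand coordinate.  For '+' the base
    there must be C; for '-' it must be G (a C on the reverse strand).
    Returns ``(context, trinucleotide)`` with the trinucleotide read
    5'->3' on the cytosine's strand, or ``(None, None)`` when the 3-base
    window runs off the chromosome or contains N.
    """
    seq = genome.sequences[chrom]
    if strand == "+":
        if seq[pos] != "C":
            raise InvalidSiteError(f"{chrom}:{pos}(+) is {seq[pos]!r}, not C")
        if pos + 3 > len(seq):
            return None, None
        tri = seq[pos : pos + 3]
    elif strand == "-":
        if seq[pos] != "G":
            raise InvalidSiteError(f"{chrom}:{pos}(-) is {seq[pos]!r}, not G")
        if pos - 2 < 0:
            return None, None
        tri = reverse_complement(seq[pos - 2 : pos + 1])
    else:
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    if "N" in tri:
        return None, None
    return classify_context_from_trinucleotide(tri), tri


def classify_chh_subcontext(tri: str) -> str:
    """Split a CHH trinucleotide into CWA (CAA/CTA) vs non-CWA."""
    if classify_context_from_trinucleotide(tri) != "CHH":
        raise ValueError(f"{tri!r} is not a CHH trinucleotide")
    return "CWA" if tri in CWA_TRINUCLEOTIDES else "non-CWA"


def enumerate_cytosines(genome: GenomeAssembly, chroms: list[str] | None = None) -> pd.DataFrame:
    """All classifiable cytosine positions on both strands.

    Returns a frame sorted by (chrom, pos, strand) with columns
    ``chrom, pos, strand, context, trinucleotide``.  Sites within 2 bases
    of a chromosome end on the reading strand, or whose window contains N,
    are excluded (context undefined).
    """
    frames = []
    for chrom in chroms if chroms is not None else list(genome.sequences):
        b = np.frombuffer(genome.sequences[chrom].encode("ascii"), dtype=np.uint8)
        L = len(b)
        C, G, A, T, N = (ord(x) for x in "CGATN")
        # forward strand: C at p, window [p, p+2]
        p = np.flatnonzero(b[: L - 2] == C)
        n1, n2 = b[p + 1], b[p + 2]
        ok = (n1 != N) & (n2 != N)
        p, n1, n2 = p[ok], n1[ok], n2[ok]
        ctx_f = np.where(n1 == G, 0, np.where(n2 == G, 1, 2))
        tri_f = _pack_tri(b[p], n1, n2)
        # reverse strand: G at p (C on minus), window reads comp(p), comp(p-1), comp(p-2)
        q = np.flatnonzero(b[2:] == G) + 2
        m1, m2 = b[q - 1], b[q - 2]
        ok = (m1 != N) & (m2 != N)
        q, m1, m2 = q[ok], m1[ok], m2[ok]
        cm1, cm2 = _complement_codes(m1), _complement_codes(m2)
        ctx_r = np.where(m1 == C, 0, np.where(m2 == C, 1, 2))
        tri_r = _pack_tri(np.full(len(q), C, np.uint8), cm1, cm2)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": np.concatenate([p, q]),
                    "strand": np.repeat(["+", "-"], [len(p), len(q)]),
                    "context": pd.Categorical.from_codes(
                        np.concatenate([ctx_f, ctx_r]), categories=list(CONTEXTS)
                    ),
                    "trinucleotide": np.concatenate([tri_f, tri_r]),
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    out = out.sort_values(["chrom", "pos", "strand"], kind="stable", ignore_index=True)
    return out


def _pack_tri(b0: np.ndarray, b1: np.ndarray, b2: np.ndarray) -> np.ndarray:
    packed = np.column_stack([b0, b1, b2]).astype(np.uint8)
    return packed.view("S3").ravel().astype("U3")


def _complement_codes(codes: np.ndarray) -> np.ndarray:
    lut = np.zeros(256, np.uint8)
    for x, y in zip("ACGTN", "TGCAN"):
        lut[ord(x)] = ord(y)
    return lut[codes]
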