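"""Codon alignments and counting-based divergence estimates.

This module is the counting core of the package: Jukes–Cantor corrected
third-position distances between alleles, raw pairwise-difference matrices,
and Nei–Gojobori (1986) style Ka/Ks from codon-aware alignments. All
downstream calibration arithmetic (substitution rates per third-position
site per year) consumes the distances produced here.

Conventions
-----------
* Codon positions are 0-based; third positions are offsets 2, 5, 8, ...
  after ``frame_offset``.
* Missing data uses pairwise deletion: a site enters a comparison only when
  both taxa carry an unambiguous base (A/C/G/T).
* NG86 site counting assigns every codon exactly 3 sites (synonymous
  fraction + nonsynonymous fraction); mutations creating stop codons count
  as nonsynonymous. Multi-step codon differences are averaged over all
  minimal mutational pathways that avoid intermediate stop codons.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import permutations
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "CodonAlignment",
    "DivergenceEstimate",
    "KaKsEstimate",
    "AlignmentError",
    "SaturationError",
    "read_codon_fasta",
    "jukes_cantor",
    "jc_p_from_d",
    "third_position_p_distance",
    "pairwise_difference_matrix",
    "ng86_kaks",
    "GENETIC_CODE",
    "STOP_CODONS",
]

VALID_CHARS = frozenset("ACGTN-")
BASES = ("A", "C", "G", "T")

# Standard genetic code (bacterial coding sequences use the same table for
# the amino acids relevant here; stops are TAA/TAG/TGA).
GENETIC_CODE: dict[str, str] = {}
_CODON_TABLE = """
TTT F TTC F TTA L TTG L CTT L CTC L CTA L CTG L
ATT I ATC I ATA I ATG M GTT V GTC V GTA V GTG V
TCT S TCC S TCA S TCG S CCT P CCC P CCA P CCG P
ACT T ACC T ACA T ACG T GCT A GCC A GCA A GCG A
TAT Y TAC Y TAA * TAG * CAT H CAC H CAA Q CAG Q
AAT N AAC N AAA K AAG K GAT D GAC D GAA E GAG E
TGT C TGC C TGA * TGG W CGT R CGC R CGA R CGG R
AGT S AGC S AGA R AGG R GGT G GGC G GGA G GGG G
"""
_items = _CODON_TABLE.split()
for _i in range(0, len(_items), 2):
    GENETIC_CODE[_items[_i]] = _items[_i + 1]
STOP_CODONS = frozenset(c for c, aa in GENETIC_CODE.items() if aa == "*")


class AlignmentError(ValueError):
    """Raised for malformed alignments (length or alphabet violations)."""


class SaturationError(ValueError):
    """Raised when a proportion of differences is at or beyond 3/4."""


@dataclass(frozen=True)
class CodonAlignment:
    """Equal-length, in-frame nucleotide sequences keyed by taxon.

    Parameters
    ----------
    taxa : ordered taxon labels (order preserved from source file)
    sequences : mapping taxon -> upper-case sequence over {A,C,G,T,N,-}
    frame_offset : 0-based index of the first codon position
    """

    taxa: tuple[str, ...]
    sequences: dict[str, str] = field(hash=False)
    frame_offset: int = 0

    def __post_init__(self) -> None:
        if not self.taxa:
            raise AlignmentError("alignment has no records")
        if set(self.taxa) != set(self.sequences):
            raise AlignmentError("taxa and sequences disagree")
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) != 1:
            raise AlignmentError(
                f"sequences have unequal lengths: {sorted(lengths)}"
            )
        (length,) = lengths
        if self.frame_offset < 0 or self.frame_offset >= 3:
            raise AlignmentError("frame_offset must be 0, 1 or 2")
        if (length - self.frame_offset) % 3 != 0:
            raise AlignmentError(
                f"length {length} minus frame_offset {self.frame_offset} "
                "is not a multiple of 3"
            )
        for taxon in self.taxa:
            seq = self.sequences[taxon]
            bad = set(seq) - VALID_CHARS
            if bad:
                pos = next(i for i, ch in enumerate(seq) if ch in bad)
                raise AlignmentError(
                    f"illegal character {seq[pos]!r} in taxon {taxon!r} "
                    f"at position {pos}"
                )

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values())))

    @property
    def n_codons(self) -> int:
        return (self.length - self.frame_offset) // 3

    def sequence(self, taxon: str) -> str:
        try:
            return self.sequences[taxon]
        except KeyError:
            raise KeyError(f"taxon {taxon!r} not in alignment") from None

    def codons(self, taxon: str) -> list[str]:
        s = self.sequence(taxon)
        o = self.frame_offset
        return [s[o + 3 * i : o + 3 * i + 3] for i in range(self.n_codons)]

    def third_positions(self, taxon: str) -> str:
        s = self.sequence(taxon)
        return s[self.frame_offset + 2 :: 3]

    def subset(self, taxa: Sequence[str]) -> "CodonAlignment":
        keep = tuple(t for t in self.taxa if t in set(taxa))
        return CodonAlignment(
            taxa=keep,
            sequences={t: self.sequences[t] for t in keep},
            frame_offset=self.frame_offset,
        )


@dataclass(frozen=True)
class DivergenceEstimate:
    """Proportion of differing sites and its Jukes–Cantor correction."""

    p: float
    d: float
    n_sites: int
    site_class: str = "third_position"

    def __post_init__(self) -> None:
        if not 0.0 <= self.p < 0.75:
            raise SaturationError(f"p = {self.p} outside [0, 0.75)")
        if self.d < self.p - 1e-12:
            raise ValueError("corrected distance d cannot be below p")


@dataclass(frozen=True)
class KaKsEstimate:
    """Counting-based Ka/Ks with effective site counts.

    ``omega`` is None (undefined) when Ks = 0 — never 0 or infinity.
    """

    Ka: float
    Ks: float
    n_syn_sites: float
    n_nonsyn_sites: float
    n_codons: int

    @property
    def omega(self) -> float | None:
        if self.Ks == 0.0:
            return None
        return self.Ka / self.Ks


def read_codon_fasta(path: str | Path, frame_offset: int = 0) -> CodonAlignment:
    """Read an aligned FASTA file into a :class:`CodonAlignment`.

    Record order is preserved; sequences are upper-cased. Unequal record
    lengths or characters outside {A,C,G,T,N,-} raise :class:`AlignmentError`
    naming the offending taxon and position.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"no FASTA records in {path}")
    taxa = tuple(r.id for r in records)
    if len(set(taxa)) != len(taxa):
        raise AlignmentError(f"duplicate taxon labels in {path}")
    sequences = {r.id: str(r.seq).upper() for r in records}
    return CodonAlignment(taxa=taxa, sequences=sequences, frame_offset=frame_offset)


def jukes_cantor(p: float) -> float:
    """Jukes–Cantor correction d = −(3/4)·ln(1 − (4/3)·p).

    Monotone increasing on [0, 0.75); raises :class:`SaturationError` at or
    beyond the saturation boundary p = 0.75.
    """
    if p < 0.0:
        raise ValueError(f"p = {p} is negative")
    if p >= 0.75:
        raise SaturationError(f"p = {p} >= 0.75 (saturated)")
    return -0.75 * math.log1p(-(4.0 / 3.0) * p)


def jc_p_from_d(d: float) -> float:
    """Inverse of :func:`jukes_cantor`: p(d) = (3/4)(1 − e^(−4d/3))."""
    if d < 0.0:
        raise ValueError(f"d = {d} is negative")
    return 0.75 * (1.0 - math.exp(-4.0 * d / 3.0))


def _comparable(a: str, b: str) -> np.ndarray:
    arr_a = np.frombuffer(a.encode(), dtype="S1")
    arr_b = np.frombuffer(b.encode(), dtype="S1")
    good = np.isin(arr_a, [b"A", b"C", b"G", b"T"]) & np.isin(
        arr_b, [b"A", b"C", b"G", b"T"]
    )
    return good


def third_position_p_distance(
    aln: CodonAlignment, a: str, b: str
) -> DivergenceEstimate:
    """p-distance over third codon positions with pairwise deletion.

    Sites where either taxon carries N or a gap are excluded. ``d`` is the
    Jukes–Cantor corrected estimate.
    """
    sa = aln.third_positions(a)
    sb = aln.third_positions(b)
    good = _comparable(sa, sb)
    n = int(good.sum())
    if n == 0:
        raise AlignmentError(
            f"no comparable third positions between {a!r} and {b!r}"
        )
    arr_a = np.frombuffer(sa.encode(), dtype="S1")
    arr_b = np.frombuffer(sb.encode(), dtype="S1")
    diffs = int(((arr_a != arr_b) & good).sum())
    p = diffs / n
    return DivergenceEstimate(p=p, d=jukes_cantor(p), n_sites=n)


def pairwise_difference_matrix(
    aln: CodonAlignment, site_class: str = "all"
) -> pd.DataFrame:
    """Symmetric matrix of raw nucleotide differences per taxon pair.

    ``site_class`` is "all" (every alignment column) or "third_position".
    Pairwise deletion throughout; the diagonal is 0.
    """
    if len(aln.taxa) < 2:
        raise AlignmentError("need at least 2 taxa")
    if site_class == "all":
        strings = {t: aln.sequence(t) for t in aln.taxa}
    elif site_class == "third_position":
        strings = {t: aln.third_positions(t) for t in aln.taxa}
    else:
        raise ValueError(f"unknown site_class {site_class!r}")
    arrays = {
        t: np.frombuffer(s.encode(), dtype="S1") for t, s in strings.items()
    }
    valid = {
        t: np.isin(arr, [b"A", b"C", b"G", b"T"]) for t, arr in arrays.items()
    }
    n = len(aln.taxa)
    mat = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            ta, tb = aln.taxa[i], aln.taxa[j]
            good = valid[ta] & valid[tb]
            diff = int(((arrays[ta] != arrays[tb]) & good).sum())
            mat[i, j] = mat[j, i] = diff
    return pd.DataFrame(mat, index=list(aln.taxa), columns=list(aln.taxa))


# ---------------------------------------------------------------------------
# NG86 counting Ka/Ks
# ---------------------------------------------------------------------------

def _syn_fraction(codon: str) -> float:
    """Synonymous site count (0..3) for one codon, NG86 style.

    For each position, the fraction of the three single-nucleotide changes
    that are synonymous; changes producing stop codons count as
    nonsynonymous.
    """
    aa = GENETIC_CODE[codon]
    s = 0.0
    for pos in range(3):
        syn = 0
        for base in BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if mutant not in STOP_CODONS and GENETIC_CODE[mutant] == aa:
                syn += 1
        s += syn / 3.0
    return s


_SYN_SITES: dict[str, float] = {
    c: _syn_fraction(c) for c in GENETIC_CODE if c not in STOP_CODONS
}


def _pathway_counts(ca: str, cb: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two codons.

    Averaged over all minimal mutational pathways; pathways passing through
    an intermediate stop codon are excluded (all pathways are used when
    every pathway is blocked).
    """
    diff_pos = [i for i in range(3) if ca[i] != cb[i]]
    if not diff_pos:
        return 0.0, 0.0
    results: list[tuple[float, float]] = []
    clean: list[tuple[float, float]] = []
    for order in permutations(diff_pos):
        syn = nsyn = 0.0
        current = ca
        blocked = False
        for pos in order:
            nxt = current[:pos] + cb[pos] + current[pos + 1 :]
            if nxt in STOP_CODONS and nxt != cb:
                blocked = True
            if (
                nxt not in STOP_CODONS
                and current not in STOP_CODONS
                and GENETIC_CODE[current] == GENETIC_CODE[nxt]
            ):
                syn += 1
            else:
                nsyn += 1
            current = nxt
        results.append((syn, nsyn))
        if not blocked:
            clean.append((syn, nsyn))
    use = clean if clean else results
    s = sum(r[0] for r in use) / len(use)
    n = sum(r[1] for r in use) / len(use)
    return s, n


def ng86_kaks(aln: CodonAlignment, a: str, b: str) -> KaKsEstimate:
    """Nei–Gojobori counting Ka/Ks between two taxa.

    Codons containing N or gaps in either taxon are skipped; codons that are
    stops in either sequence are skipped with a warning (disrupted alleles
    occur in real data and should not be fatal). Jukes–Cantor correction is
    applied separately to the proportions pN and pS.
    """
    codons_a = aln.codons(a)
    codons_b = aln.codons(b)
    syn_sites = nonsyn_sites = 0.0
    syn_diffs = nonsyn_diffs = 0.0
    n_compared = 0
    for ca, cb in zip(codons_a, codons_b):
        if any(ch not in "ACGT" for ch in ca + cb):
            continue
        if ca in STOP_CODONS or cb in STOP_CODONS:
            warnings.warn(
                f"stop codon in compared pair ({ca}, {cb}); codon skipped",
                stacklevel=2,
            )
            continue
        n_compared += 1
        s_sites = 0.5 * (_SYN_SITES[ca] + _SYN_SITES[cb])
        syn_sites += s_sites
        nonsyn_sites += 3.0 - s_sites
        sd, nd = _pathway_counts(ca, cb)
        syn_diffs += sd
        nonsyn_diffs += nd
    if n_compared == 0:
        raise AlignmentError(f"no comparable codons between {a!r} and {b!r}")
    pS = syn_diffs / syn_sites if syn_sites > 0 else 0.0
    pN = nonsyn_diffs / nonsyn_sites if nonsyn_sites > 0 else 0.0
    if pS >= 0.75:
        raise SaturationError(f"pS = {pS:.4f} >= 0.75 (synonymous saturation)")
    if pN >= 0.75:
        raise SaturationError(f"pN = {pN:.4f} >= 0.75 (nonsynonymous saturation)")
    return KaKsEstimate(
        Ka=jukes_cantor(pN),
        Ks=jukes_cantor(pS),
        n_syn_sites=syn_sites,
        n_nonsyn_sites=nonsyn_sites,
        n_codons=n_compared,
    )


def divergence_table(
    aln: CodonAlignment, pairs: Iterable[tuple[str, str]] | None = None
) -> pd.DataFrame:
    """Tidy table of third-position divergences for the given taxon pairs."""
    if pairs is None:
        pairs = [
            (aln.taxa[i], aln.taxa[j])
            for i in range(len(aln.taxa))
            for j in range(i + 1, len(aln.taxa))
        ]
    rows = []
    for a, b in pairs:
        est = third_position_p_distance(aln, a, b)
        rows.append(
            {
                "taxon_a": a,
                "taxon_b": b,
                "site_class": est.site_class,
                "n_sites": est.n_sites,
                "p": est.p,
                "d": est.d,
            }
        )
    return pd.DataFrame(rows)
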