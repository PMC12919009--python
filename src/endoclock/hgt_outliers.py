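"""Single-copy locus filters and the two-fold-outlier scan for HGT alleles.

Horizontally acquired alleles at otherwise vertically inherited loci stand
out as divergence outliers: one allele differs from every other allele far
more than the remaining alleles differ among themselves. The heuristic
adopted here flags an allele as a "two-fold outlier" when its minimum
pairwise difference to all other alleles is at least twice the maximum
pairwise difference among the remaining alleles.

Differences are raw nucleotide counts over all sites (not only third
positions), with pairwise deletion of gapped/ambiguous columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .seqdiv import CodonAlignment, pairwise_difference_matrix, read_codon_fasta

__all__ = [
    "LocusSet",
    "OutlierReport",
    "filter_single_copy_loci",
    "variable_site_fraction",
    "twofold_outlier_scan",
    "rank_loci_by_polymorphism",
    "read_locus_directory",
]


@dataclass
class LocusSet:
    """Mapping locus id -> CodonAlignment over one shared taxon set."""

    loci: dict[str, CodonAlignment]
    notes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        taxon_sets = {frozenset(a.taxa) for a in self.loci.values()}
        if len(taxon_sets) > 1:
            raise ValueError("all loci must cover the same taxon set")

    def __len__(self) -> int:
        return len(self.loci)


@dataclass(frozen=True)
class OutlierReport:
    """Result of the two-fold-outlier scan at one locus.

    verdict is "outlier" iff min_candidate_diff >= 2 * max_background_diff
    and the background shows at least one difference; a zero-variation
    background yields "indeterminate" (the two-fold criterion divides by
    zero conceptually), with raw counts reported so callers can apply an
    absolute threshold instead.
    """

    locus: str
    candidate: str | None
    min_candidate_diff: int
    max_background_diff: int
    variable_fraction: float
    verdict: str

    def __post_init__(self) -> None:
        if self.verdict not in {"outlier", "clean", "indeterminate"}:
            raise ValueError(f"bad verdict {self.verdict!r}")
        if self.verdict == "outlier":
            assert (
                self.max_background_diff >= 1
                and self.min_candidate_diff >= 2 * self.max_background_diff
            )


def filter_single_copy_loci(
    loci: dict[str, CodonAlignment],
    copy_numbers: dict[str, dict[str, int]] | None = None,
    min_length: int = 0,
    max_gapped_genomes: int = 1,
) -> tuple[LocusSet, pd.DataFrame]:
    """Retain loci that look like clean single-copy orthologs.

    Rules, applied in order; the first failure is logged:

    * ``multi-copy``: any genome carries more than one copy (``copy_numbers``
      maps locus -> taxon -> copy count; loci absent from it are assumed
      single-copy);
    * ``too-short``: alignment shorter than ``min_length`` bp (use 300 for
      recombination-style screens, 0 otherwise);
    * ``gapped-genomes``: more than ``max_gapped_genomes`` sequences contain
      gaps;
    * ``frameshift gap``: any gap run whose length is not a multiple of 3.

    Returns the retained :class:`LocusSet` and a rejection log DataFrame
    with columns (locus, reason).
    """
    kept: dict[str, CodonAlignment] = {}
    rejections: list[dict[str, str]] = []
    for locus_id in sorted(loci):
        aln = loci[locus_id]
        reason = None
        if copy_numbers and locus_id in copy_numbers:
            if any(c > 1 for c in copy_numbers[locus_id].values()):
                reason = "multi-copy"
        if reason is None and aln.length < min_length:
            reason = "too-short"
        if reason is None:
            gapped = [t for t in aln.taxa if "-" in aln.sequence(t)]
            if len(gapped) > max_gapped_genomes:
                reason = "gapped-genomes"
            else:
                for taxon in gapped:
                    for run in _gap_runs(aln.sequence(taxon)):
                        if run % 3 != 0:
                            reason = "frameshift gap"
                            break
                    if reason:
                        break
        if reason is None:
            kept[locus_id] = aln
        else:
            rejections.append({"locus": locus_id, "reason": reason})
    log = pd.DataFrame(rejections, columns=["locus", "reason"])
    return LocusSet(loci=kept), log


def _gap_runs(seq: str) -> list[int]:
    runs, n = [], 0
    for ch in seq:
        if ch == "-":
            n += 1
        elif n:
            runs.append(n)
            n = 0
    if n:
        runs.append(n)
    return runs


def variable_site_fraction(aln: CodonAlignment) -> float:
    """Fraction of alignment columns with >= 2 distinct non-missing states."""
    if len(aln.taxa) < 2:
        raise ValueError("need at least 2 taxa")
    mat = np.array(
        [np.frombuffer(aln.sequence(t).encode(), dtype="S1") for t in aln.taxa]
    )
    valid = np.isin(mat, [b"A", b"C", b"G", b"T"])
    variable = 0
    for col in range(mat.shape[1]):
        states = set(mat[valid[:, col], col])
        if len(states) >= 2:
            variable += 1
    return variable / aln.length


def twofold_outlier_scan(aln: CodonAlignment, locus: str = "") -> OutlierReport:
    """Scan one locus for a two-fold-outlier allele.

    For each candidate taxon, the statistic is the minimum of its pairwise
    differences to every other allele (the weakest link must still satisfy
    the two-fold criterion) against the maximum pairwise difference among
    the remaining alleles. At most one outlier is reported — the strongest
    by min-candidate/background ratio; exact ties give "indeterminate".
    """
    if len(aln.taxa) < 3:
        raise ValueError("two-fold-outlier scan needs at least 3 taxa")
    mat = pairwise_difference_matrix(aln, site_class="all")
    vf = variable_site_fraction(aln)
    taxa = list(aln.taxa)
    best: list[tuple[float, str, int, int]] = []
    for cand in taxa:
        others = [t for t in taxa if t != cand]
        min_cand = int(mat.loc[cand, others].min())
        bg = mat.loc[others, others].to_numpy()
        max_bg = int(bg.max())
        if max_bg >= 1 and min_cand >= 2 * max_bg:
            ratio = min_cand / max_bg
            best.append((ratio, cand, min_cand, max_bg))
    if not best:
        # no candidate satisfies the criterion; report the globally most
        # divergent allele's counts for context
        stats = []
        for cand in taxa:
            others = [t for t in taxa if t != cand]
            min_cand = int(mat.loc[cand, others].min())
            max_bg = int(mat.loc[others, others].to_numpy().max())
            stats.append((min_cand, cand, max_bg))
        min_cand, cand, max_bg = max(stats)
        verdict = "indeterminate" if max_bg == 0 and min_cand > 0 else "clean"
        return OutlierReport(
            locus=locus,
            candidate=None,
            min_candidate_diff=min_cand,
            max_background_diff=max_bg,
            variable_fraction=vf,
            verdict=verdict,
        )
    best.sort(reverse=True)
    if len(best) > 1 and best[0][0] == best[1][0]:
        ratio, cand, min_cand, max_bg = best[0]
        return OutlierReport(
            locus=locus,
            candidate=None,
            min_candidate_diff=min_cand,
            max_background_diff=max_bg,
            variable_fraction=vf,
            verdict="indeterminate",
        )
    ratio, cand, min_cand, max_bg = best[0]
    return OutlierReport(
        locus=locus,
        candidate=cand,
        min_candidate_diff=min_cand,
        max_background_diff=max_bg,
        variable_fraction=vf,
        verdict="outlier",
    )


def rank_loci_by_polymorphism(
    locus_set: LocusSet, top_k: int | None = None
) -> list[OutlierReport]:
    """Rank loci by variable-site fraction (descending) and scan the top k.

    Ties are broken by locus id lexicographically. Every returned report
    carries the full :func:`twofold_outlier_scan` result.
    """
    if len(locus_set) == 0:
        raise ValueError("empty locus set")
    fractions = {
        locus: variable_site_fraction(aln) for locus, aln in locus_set.loci.items()
    }
    order = sorted(fractions, key=lambda k: (-fractions[k], k))
    if top_k is not None:
        order = order[:top_k]
    return [twofold_outlier_scan(locus_set.loci[lid], locus=lid) for lid in order]


def read_locus_directory(path: str | Path) -> dict[str, CodonAlignment]:
    """Read every ``*.fasta``/``*.fa`` file in a directory as one locus."""
    path = Path(path)
    loci = {}
    for fp in sorted(path.glob("*.fa")) + sorted(path.glob("*.fasta")):
        loci[fp.stem] = read_codon_fasta(fp)
    if not loci:
        raise FileNotFoundError(f"no FASTA loci found in {path}")
    return loci


def outlier_report_table(reports: list[OutlierReport]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "locus": r.locus,
                "verdict": r.verdict,
                "candidate": r.candidate or "",
                "min_candidate_diff": r.min_candidate_diff,
                "max_background_diff": r.max_background_diff,
                "variable_fraction": r.variable_fraction,
            }
            for r in reports
        ]
    )
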