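"""Synthetic inputs with known ground truth for every pipeline stage.

Real inputs to this package are genome-scale alignments of codiverging
endosymbiont/host-nuclear/mtDNA compartments, per-site ω tables from codon
model fits, and predicted protein structures. The generators here emulate
their statistical structure at desk scale with planted, recoverable truth:

* sequence triplets evolved site-independently under a Jukes–Cantor
  process along a shared ultrametric host tree, with compartment-specific
  rates (defaults emulate the observed relative-rate structure: symbiont
  and host-nuclear third-position rates nearly equal, mtDNA faster by
  roughly an order of magnitude);
* horizontally transferred alleles implanted at chosen loci by replacing
  one taxon's allele with an independently diverged one;
* AR(1)-autocorrelated log-ω window series with a planted median gap
  (analytic integrated autocorrelation time (1+φ)/(1−φ));
* helix-like residue clouds with a configurable low-confidence fraction.

Every generator is deterministic under its seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np

from .chronogram import RelativeChronogram, chronogram_from_string
from .hgt_outliers import LocusSet
from .seqdiv import BASES, CodonAlignment
from .structure_windows import ResidueCloud

__all__ = [
    "SimulationConfig",
    "HgtEvent",
    "evolve_jc",
    "simulate_codiverging_triplet",
    "implant_hgt_allele",
    "simulate_omega_series",
    "simulate_residue_cloud",
    "write_fixture_bundle",
]

# relative trio: congener pair at 3.1% of the crown age (outgroup at 1.0)
DEFAULT_TRIO_NEWICK = "((ingroup1:0.031,ingroup2:0.031):0.969,outgroup:1.0);"
DEFAULT_CROWN_AGE = 64.73e6  # years
DEFAULT_RATES = {
    # substitutions per third-position site per year; symbiont/nuclear
    # ratio ~1.04, mtDNA/symbiont ratio ~13.8
    "symbiont": 1.82e-9,
    "nuclear": 1.75e-9,
    "mtdna": 2.51e-8,
}

_BASE_IDX = {b: i for i, b in enumerate(BASES)}


@dataclass(frozen=True)
class HgtEvent:
    """A horizontal-transfer implant: replace one allele at one locus."""

    locus: str
    recipient: str
    donor_divergence: float  # substitutions/site between donor and background

    def __post_init__(self) -> None:
        if self.donor_divergence < 0:
            raise ValueError("donor_divergence must be non-negative")


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic generators."""

    seed: int = 0
    n_loci: int = 10
    locus_length_codons: int = 166
    tree_newick: str = DEFAULT_TRIO_NEWICK
    crown_age: float = DEFAULT_CROWN_AGE
    rates: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_RATES))
    hgt_events: tuple[HgtEvent, ...] = ()
    mode: str = "third_only"  # or "uniform": evolve all three codon positions
    # ω-series spec
    series_length: int = 2000
    ar_phi: float = 0.5
    log_median_gap: float = -0.23
    log_omega_location: float = -1.0  # log ω of the slower-evolving series
    log_omega_scale: float = 0.35
    # residue-cloud spec
    n_residues: int = 166
    low_plddt_fraction: float = 0.2

    def __post_init__(self) -> None:
        if not -1.0 < self.ar_phi < 1.0:
            raise ValueError("ar_phi must lie in (-1, 1)")
        if any(r < 0 for r in self.rates.values()):
            raise ValueError("rates must be non-negative")


def evolve_jc(seq: np.ndarray, d: float, rng: np.random.Generator) -> np.ndarray:
    """Evolve integer-coded bases by a Jukes–Cantor process of depth ``d``.

    Each site changes with probability p = (3/4)(1 − e^(−4d/3)), moving to
    one of the three other bases uniformly (the exact JC transition kernel,
    so repeated short branches compose correctly).
    """
    if d < 0:
        raise ValueError("d must be non-negative")
    p_change = 0.75 * (1.0 - np.exp(-4.0 * d / 3.0))
    out = seq.copy()
    hits = rng.random(len(seq)) < p_change
    if hits.any():
        shift = rng.integers(1, 4, size=int(hits.sum()))
        out[hits] = (out[hits] + shift) % 4
    return out


def _decode(codes: np.ndarray) -> str:
    return "".join(BASES[c] for c in codes)


def _simulate_locus(
    chron: RelativeChronogram,
    crown_age: float,
    rate: float,
    n_sites: int,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Evolve one compartment's variable sites down the tree."""
    tree: dendropy.Tree = chron.tree
    root_seq = rng.integers(0, 4, size=n_sites)
    seqs: dict[dendropy.Node, np.ndarray] = {tree.seed_node: root_seq}
    out: dict[str, np.ndarray] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            pass
        else:
            d = rate * node.edge.length * crown_age
            seqs[node] = evolve_jc(seqs[node.parent_node], d, rng)
        if node.is_leaf():
            out[node.taxon.label] = seqs[node]
    return out


def _assemble_codons(
    third: dict[str, np.ndarray],
    full_first_second: dict[str, np.ndarray] | None,
    n_codons: int,
    rng: np.random.Generator,
) -> dict[str, str]:
    """Interleave (constant or evolved) first/second positions with thirds."""
    taxa = list(third)
    if full_first_second is None:
        backbone = rng.integers(0, 4, size=2 * n_codons)
        fs = {t: backbone for t in taxa}
    else:
        fs = full_first_second
    sequences = {}
    for t in taxa:
        arr = np.empty(3 * n_codons, dtype=int)
        arr[0::3] = fs[t][0::2]
        arr[1::3] = fs[t][1::2]
        arr[2::3] = third[t]
        sequences[t] = _decode(arr)
    return sequences


def simulate_codiverging_triplet(
    config: SimulationConfig,
) -> tuple[dict[str, LocusSet], RelativeChronogram]:
    """Evolve all three compartments along one shared host tree.

    Returns ({compartment: LocusSet}, true chronogram). Under
    ``mode="third_only"`` the stated rates apply to third codon positions
    and first/second positions are held constant (fast and sufficient when
    only third-position divergence is consumed); ``mode="uniform"`` evolves
    every position at the stated rate.
    """
    chron = chronogram_from_string(config.tree_newick)
    rng = np.random.default_rng(config.seed)
    n_codons = config.locus_length_codons
    compartments: dict[str, LocusSet] = {}
    for comp, rate in config.rates.items():
        loci = {}
        for i in range(config.n_loci):
            if config.mode == "third_only":
                third = _simulate_locus(
                    chron, config.crown_age, rate, n_codons, rng
                )
                sequences = _assemble_codons(third, None, n_codons, rng)
            elif config.mode == "uniform":
                full = _simulate_locus(
                    chron, config.crown_age, rate, 3 * n_codons, rng
                )
                sequences = {t: _decode(a) for t, a in full.items()}
            else:
                raise ValueError(f"unknown mode {config.mode!r}")
            loci[f"{comp}_locus{i:04d}"] = CodonAlignment(
                taxa=tuple(sequences), sequences=sequences
            )
        compartments[comp] = LocusSet(loci=loci)
    return compartments, chron


def implant_hgt_allele(
    locus_set: LocusSet, event: HgtEvent, seed: int = 0
) -> tuple[LocusSet, dict[str, str | float]]:
    """Replace the recipient's allele by an independently diverged one.

    The implanted allele is the recipient's own allele evolved onward by
    ``donor_divergence`` substitutions/site (uniformly over all positions),
    emulating replacement by a distantly related donor. Returns the
    modified set and a truth record.
    """
    if event.locus not in locus_set.loci:
        raise KeyError(f"unknown locus {event.locus!r}")
    aln = locus_set.loci[event.locus]
    if event.recipient not in aln.taxa:
        raise KeyError(f"unknown taxon {event.recipient!r} at {event.locus!r}")
    rng = np.random.default_rng(seed)
    codes = np.array([_BASE_IDX[ch] for ch in aln.sequence(event.recipient)])
    donor = evolve_jc(codes, event.donor_divergence, rng)
    sequences = dict(aln.sequences)
    sequences[event.recipient] = _decode(donor)
    new_aln = CodonAlignment(
        taxa=aln.taxa, sequences=sequences, frame_offset=aln.frame_offset
    )
    loci = dict(locus_set.loci)
    loci[event.locus] = new_aln
    truth = {
        "locus": event.locus,
        "recipient": event.recipient,
        "donor_divergence": event.donor_divergence,
    }
    return LocusSet(loci=loci, notes=dict(locus_set.notes)), truth


def simulate_omega_series(
    config: SimulationConfig, seed: int | None = None
) -> tuple[np.ndarray, np.ndarray, dict[str, float]]:
    """Two AR(1)-autocorrelated ω series with a planted log-median gap.

    Series are generated on the log(ω) scale as stationary AR(1) Gaussians
    (marginal sd ``log_omega_scale``) and exponentiated. Series A's
    location is shifted by ``log_median_gap`` relative to series B, so the
    true Δ = median difference on the log scale equals the gap. Truth also
    records the analytic IAT (1+φ)/(1−φ).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    phi = config.ar_phi
    n = config.series_length
    sd = config.log_omega_scale

    def _ar1(loc: float) -> np.ndarray:
        innov_sd = sd * np.sqrt(1.0 - phi**2)
        z = np.empty(n)
        z[0] = rng.normal(0.0, sd)
        eps = rng.normal(0.0, innov_sd, size=n - 1)
        for t in range(1, n):
            z[t] = phi * z[t - 1] + eps[t - 1]
        return np.exp(loc + z)

    series_b = _ar1(config.log_omega_location)
    series_a = _ar1(config.log_omega_location + config.log_median_gap)
    truth = {
        "phi": phi,
        "log_median_gap": config.log_median_gap,
        "iat": (1.0 + phi) / (1.0 - phi),
    }
    return series_a, series_b, truth


def simulate_residue_cloud(
    config: SimulationConfig, seed: int | None = None
) -> tuple[ResidueCloud, np.ndarray]:
    """Helix-like residue coordinates with a planted low-confidence subset.

    An ideal alpha-helix (radius 2.3 Å, rise 1.5 Å, 100° twist per residue)
    gives ~3.8 Å consecutive CA spacing. A fraction ``low_plddt_fraction``
    of residues receives pLDDT below 70 (uniform 40–69.5); the rest are
    uniform 75–100. Returns the cloud and the boolean low-confidence mask.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_residues
    if n < 2:
        raise ValueError("need at least 2 residues")
    t = np.arange(n) * np.deg2rad(100.0)
    xyz = np.column_stack(
        [2.3 * np.cos(t), 2.3 * np.sin(t), 1.5 * np.arange(n)]
    )
    low = rng.random(n) < config.low_plddt_fraction
    plddt = rng.uniform(75.0, 100.0, size=n)
    plddt[low] = rng.uniform(40.0, 69.5, size=int(low.sum()))
    return ResidueCloud(index=np.arange(1, n + 1), xyz=xyz, plddt=plddt), low


def write_fixture_bundle(config: SimulationConfig, outdir: str | Path) -> Path:
    """Write a FASTA/newick/TSV fixture bundle plus a JSON truth manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    compartments, chron = simulate_codiverging_triplet(config)
    truth_records = []
    for k, event in enumerate(config.hgt_events):
        comp = next(
            (c for c, ls in compartments.items() if event.locus in ls.loci), None
        )
        if comp is None:
            raise KeyError(f"HGT event names unknown locus {event.locus!r}")
        compartments[comp], rec = implant_hgt_allele(
            compartments[comp], event, seed=config.seed + 1000 + k
        )
        truth_records.append(rec)
    for comp, locus_set in compartments.items():
        comp_dir = outdir / comp
        comp_dir.mkdir(exist_ok=True)
        for locus_id, aln in locus_set.loci.items():
            with open(comp_dir / f"{locus_id}.fasta", "w") as fh:
                for taxon in aln.taxa:
                    fh.write(f">{taxon}\n{aln.sequence(taxon)}\n")
    chron.tree.write(path=str(outdir / "host_tree.nwk"), schema="newick")
    series_a, series_b, series_truth = simulate_omega_series(config)
    np.savetxt(
        outdir / "omega_series.tsv",
        np.column_stack([series_a, series_b]),
        delimiter="\t",
        header="omega_a\tomega_b",
        comments="",
    )
    cloud, low = simulate_residue_cloud(config)
    with open(outdir / "residue_cloud.tsv", "w") as fh:
        fh.write("index\tx\ty\tz\tplddt\n")
        for i in range(len(cloud)):
            fh.write(
                f"{cloud.index[i]}\t{cloud.xyz[i, 0]:.4f}\t{cloud.xyz[i, 1]:.4f}"
                f"\t{cloud.xyz[i, 2]:.4f}\t{cloud.plddt[i]:.2f}\n"
            )
    manifest = {
        "seed": config.seed,
        "crown_age": config.crown_age,
        "rates": config.rates,
        "tree_newick": config.tree_newick,
        "n_loci": config.n_loci,
        "locus_length_codons": config.locus_length_codons,
        "hgt_events": truth_records,
        "omega_series": series_truth,
        "n_low_plddt": int(low.sum()),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return outdir
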