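"""Synthetic genotype panels with known ground truth.

The generator emulates the structure of a cereal genebank collection:

* diverged subpopulations of largely homozygous inbred lines (landraces,
  cultivars), modelled with a Balding–Nichols-style draw — subpopulation
  allele frequencies are Beta-distributed around an ancestral frequency with
  an Fst-like ``divergence`` knob;
* planted duplicates — exact genotype copies (before missingness), the
  redundant entries a genebank accumulates;
* pedigree groups — breeder-line families sharing a common parent genotype
  and differing only at a limited set of segregating markers;
* residual heterozygosity and missing calls at configurable rates;
* wild populations sampled as a founder plus progeny with tunable
  within-population segregation.

Each accession draws ONE allele per marker from its subpopulation frequency
and is homozygous for it (marginally equivalent to repeated selfing).  Every
draw flows from a single seed, so identical configs reproduce matrices
bit-for-bit.  TruthLabels record the planted structure for downstream tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .genotype import GenotypeCall, GenotypeMatrix

__all__ = ["SimConfig", "TruthLabels", "simulate_panel", "simulate_wild_populations"]


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters.

    ``pedigree_groups`` is a list of ``(n_lines, n_segregating_markers)``
    pairs; each group occupies that many accession slots.  Duplicate pairs
    copy independent lines.  The defaults emulate a post-QC training matrix
    (accessions above a 99.5% call rate, hence ~0.2% missing); set
    ``missing_rate`` to 0.028–0.051 to emulate raw KASP fingerprinting runs.
    Residual heterozygosity defaults to the 0.1% ceiling expected of highly
    homozygous inbred material.
    """

    n_markers: int = 1000
    n_accessions: int = 500
    n_subpops: int = 3
    divergence: float = 0.15
    ancestral_maf_range: tuple[float, float] = (0.05, 0.5)
    residual_het_rate: float = 0.001
    missing_rate: float = 0.002
    n_duplicate_pairs: int = 0
    pedigree_groups: tuple[tuple[int, int], ...] = ()
    marker_dropout_rate: float = 0.0  # whole-marker failure (KASP failures are marker-wise)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("divergence", "residual_het_rate", "missing_rate", "marker_dropout_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0) or (name == "divergence" and v >= 1.0):
                raise ConfigurationError(f"{name} must be in [0, 1), got {v}")
        lo, hi = self.ancestral_maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigurationError("ancestral_maf_range must satisfy 0 < lo <= hi <= 0.5")
        object.__setattr__(self, "pedigree_groups", tuple(tuple(g) for g in self.pedigree_groups))
        n_ped = sum(g[0] for g in self.pedigree_groups)
        if 2 * self.n_duplicate_pairs + n_ped > self.n_accessions:
            raise ConfigurationError(
                "duplicates and pedigree members exceed n_accessions "
                f"({2 * self.n_duplicate_pairs} + {n_ped} > {self.n_accessions})"
            )
        if self.n_subpops < 1 or self.n_markers < 1 or self.n_accessions < 1:
            raise ConfigurationError("counts must be positive")


@dataclass
class TruthLabels:
    """Planted ground truth accompanying a simulated matrix."""

    subpop: pd.Series                     # accession -> subpopulation label
    category: pd.Series                   # accession -> line | pedigree | duplicate
    duplicate_partner: dict[str, str]     # symmetric map of planted copies
    pedigree_group: pd.Series             # accession -> group id (NaN outside groups)
    ancestral_freq: np.ndarray            # (n_markers,) reference-allele frequency
    subpop_freq: np.ndarray               # (n_subpops, n_markers)

    def duplicate_pairs(self) -> set[frozenset]:
        return {frozenset((a, b)) for a, b in self.duplicate_partner.items()}


def _subpop_frequencies(rng, ancestral: np.ndarray, n_subpops: int, fst: float) -> np.ndarray:
    """Balding–Nichols draw: Beta(p(1−F)/F, (1−p)(1−F)/F) per subpopulation."""
    if fst == 0.0:
        return np.tile(ancestral, (n_subpops, 1))
    scale = (1.0 - fst) / fst
    a = ancestral * scale
    b = (1.0 - ancestral) * scale
    return rng.beta(a[None, :], b[None, :], size=(n_subpops, len(ancestral)))


def _inbred_genotypes(rng, freqs: np.ndarray) -> np.ndarray:
    """One homozygous genotype row per frequency row (draw one allele per marker)."""
    ref = rng.random(freqs.shape) < freqs
    return np.where(ref, GenotypeCall.HOM_REF, GenotypeCall.HOM_ALT).astype(np.int8)


def simulate_panel(config: SimConfig) -> tuple[GenotypeMatrix, TruthLabels]:
    """Generate an inbred genebank-style panel with planted structure."""
    rng = np.random.default_rng(config.seed)
    m = config.n_markers
    lo, hi = config.ancestral_maf_range
    ancestral = rng.uniform(lo, hi, size=m)
    subpop_freq = _subpop_frequencies(rng, ancestral, config.n_subpops, config.divergence)

    n_ped = sum(g[0] for g in config.pedigree_groups)
    n_dup = config.n_duplicate_pairs
    n_ind = config.n_accessions - n_ped - n_dup  # independent lines (dup copies reuse them)
    if n_ind < n_dup:
        raise ConfigurationError("not enough independent lines to source duplicate pairs")

    ids: list[str] = []
    rows: list[np.ndarray] = []
    subpop: list[int] = []
    category: list[str] = []
    ped_group: list[object] = []

    # independent inbred lines, subpopulations round-robin
    for i in range(n_ind):
        sp = i % config.n_subpops
        g = _inbred_genotypes(rng, subpop_freq[sp][None, :])[0]
        _flip_het(rng, g, config.residual_het_rate)
        ids.append(f"ACC{i:05d}")
        rows.append(g)
        subpop.append(sp)
        category.append("line")
        ped_group.append(None)

    # pedigree groups: common parent, members redrawn at segregating markers
    for gid, (n_lines, n_seg) in enumerate(config.pedigree_groups):
        sp = gid % config.n_subpops
        parent = _inbred_genotypes(rng, subpop_freq[sp][None, :])[0]
        seg = rng.choice(m, size=min(n_seg, m), replace=False)
        for k in range(n_lines):
            child = parent.copy()
            redraw = _inbred_genotypes(rng, subpop_freq[sp][None, seg])[0]
            child[seg] = redraw
            _flip_het(rng, child, config.residual_het_rate)
            ids.append(f"PED{gid:02d}_{k:02d}")
            rows.append(child)
            subpop.append(sp)
            category.append("pedigree")
            ped_group.append(gid)

    # planted duplicates: exact copies of the first n_dup independent lines
    dup_partner: dict[str, str] = {}
    for d in range(n_dup):
        src = ids[d]
        dup_id = f"DUP{d:03d}"
        ids.append(dup_id)
        rows.append(rows[d].copy())  # exact copy (before missingness)
        subpop.append(subpop[d])
        category.append("duplicate")
        ped_group.append(None)
        dup_partner[src] = dup_id
        dup_partner[dup_id] = src

    calls = np.vstack(rows)

    # missingness last: uniform no-calls plus optional whole-marker dropout
    if config.marker_dropout_rate > 0:
        dead = rng.random(m) < config.marker_dropout_rate
        calls[:, dead] = GenotypeCall.MISSING
    if config.missing_rate > 0:
        miss = rng.random(calls.shape) < config.missing_rate
        calls[miss] = GenotypeCall.MISSING

    index = pd.Index(ids, name="accession")
    subpop_labels = pd.Series([f"subpop{s}" for s in subpop], index=index, name="subpop")
    category_s = pd.Series(category, index=index, name="category")
    ped_s = pd.Series(ped_group, index=index, name="pedigree_group", dtype=object)
    meta = pd.DataFrame({"subpop": subpop_labels, "category": category_s, "group": subpop_labels})
    marker_ids = [f"M{j:05d}" for j in range(m)]
    gm = GenotypeMatrix(ids, marker_ids, calls, accession_meta=meta)
    truth = TruthLabels(
        subpop=subpop_labels,
        category=category_s,
        duplicate_partner=dup_partner,
        pedigree_group=ped_s,
        ancestral_freq=ancestral,
        subpop_freq=subpop_freq,
    )
    return gm, truth


def _flip_het(rng, genotype_row: np.ndarray, rate: float) -> None:
    if rate > 0:
        het = rng.random(genotype_row.shape) < rate
        genotype_row[het] = GenotypeCall.HET


def simulate_wild_populations(
    n_populations: int = 16,
    progeny_per_population: tuple[int, int] = (4, 10),
    within_pop_diversity: float = 0.2,
    divergence: float = 0.3,
    seed: int = 0,
    n_markers: int = 1000,
    ancestral_maf_range: tuple[float, float] = (0.05, 0.5),
    missing_rate: float = 0.0,
) -> tuple[GenotypeMatrix, TruthLabels]:
    """Wild-population sampling design: a founder per site plus progeny.

    Each population is a diverged subpopulation (higher ``divergence`` than
    the domesticated panel); progeny inherit the founder genotype but redraw
    each marker allele from the population frequency with probability
    ``within_pop_diversity``.  At 0 the progeny of a population are identical;
    at 1 they are independent draws.
    """
    if not (0.0 <= within_pop_diversity <= 1.0):
        raise ConfigurationError("within_pop_diversity must be in [0, 1]")
    lo_p, hi_p = progeny_per_population
    if not (1 <= lo_p <= hi_p):
        raise ConfigurationError("progeny_per_population must be a valid (lo, hi) range")
    rng = np.random.default_rng(seed)
    lo, hi = ancestral_maf_range
    ancestral = rng.uniform(lo, hi, size=n_markers)
    pop_freq = _subpop_frequencies(rng, ancestral, n_populations, divergence)

    ids: list[str] = []
    rows: list[np.ndarray] = []
    pop_labels: list[str] = []
    for p in range(n_populations):
        founder = _inbred_genotypes(rng, pop_freq[p][None, :])[0]
        n_prog = int(rng.integers(lo_p, hi_p + 1))
        for k in range(n_prog):
            child = founder.copy()
            if within_pop_diversity > 0:
                redraw = rng.random(n_markers) < within_pop_diversity
                if redraw.any():
                    child[redraw] = _inbred_genotypes(rng, pop_freq[p][None, redraw])[0]
            ids.append(f"WILD{p:02d}_{k:02d}")
            rows.append(child)
            pop_labels.append(f"pop{p}")

    calls = np.vstack(rows)
    if missing_rate > 0:
        miss = rng.random(calls.shape) < missing_rate
        calls[miss] = GenotypeCall.MISSING

    index = pd.Index(ids, name="accession")
    pop_s = pd.Series(pop_labels, index=index, name="subpop")
    meta = pd.DataFrame(
        {"subpop": pop_s, "category": "wild", "group": pop_s}
    )
    marker_ids = [f"M{j:05d}" for j in range(n_markers)]
    gm = GenotypeMatrix(ids, marker_ids, calls, accession_meta=meta)
    truth = TruthLabels(
        subpop=pop_s,
        category=pd.Series("wild", index=index, name="category"),
        duplicate_partner={},
        pedigree_group=pd.Series([None] * len(ids), index=index, dtype=object),
        ancestral_freq=ancestral,
        subpop_freq=pop_freq,
    )
    return gm, truth
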