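"""Synthetic multi-breed genotype simulator.

Population allele frequencies follow the Balding–Nichols model: each locus
draws an ancestral frequency p, and each population k draws

    p_k ~ Beta(p (1-F)/F, (1-p)(1-F)/F)

so that E[p_k] = p and Var[p_k] = F p (1-p), with F the target level of
between-population differentiation (F_ST).  Within a population, genotypes
follow inbreeding-adjusted proportions with coefficient F_IS:

    P(het)     = 2 p_k (1-p_k) (1 - F_IS)
    P(hom alt) = p_k^2 + p_k (1-p_k) F_IS      (and symmetrically hom ref)

Negative F_IS produces heterozygote excess (as observed in commercial pig
lines under outbreeding/selection); the model is valid only while all three
genotype probabilities stay in [0,1], which is checked per locus.

Defaults emulate a 3-breed x 100-animal x 300-SNP coding-SNP panel with
F_ST ~= 0.04 and a slight heterozygote excess (F_IS = -0.03).  The default
ancestral MAF range, Uniform(0.45, 0.5), mirrors a deliberately assembled
panel of highly polymorphic markers with near-balanced alleles (mean minor
frequency ~0.45-0.48, per-population Hill profile ~ (2, 1.95, 1.92)); pass
a wider range such as (0.05, 0.5) for a chip-like spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genotypes import MISSING, GenotypeTable, Locus, Sample

_NUCS = np.array(["A", "C", "G", "T"])


@dataclass
class SimulationConfig:
    n_pops: int = 3
    n_per_pop: int | list[int] = 100
    n_loci: int = 300
    fst_target: float = 0.04
    fis_target: float = -0.03
    anc_maf_range: tuple[float, float] = (0.45, 0.5)
    missing_rate: float = 0.0
    seed: int = 0
    clip_freqs: bool = True  # pull drifted frequencies into the F_IS-valid range

    def __post_init__(self) -> None:
        if self.n_pops < 1:
            raise ValueError("n_pops must be >= 1")
        if not 0.0 < self.fst_target < 1.0:
            raise ValueError("fst_target must be in (0,1)")
        if not -1.0 < self.fis_target < 1.0:
            raise ValueError("fis_target must be in (-1,1)")
        lo, hi = self.anc_maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("anc_maf_range must satisfy 0 < low <= high <= 0.5")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0,1)")

    @property
    def pop_sizes(self) -> list[int]:
        if isinstance(self.n_per_pop, int):
            return [self.n_per_pop] * self.n_pops
        if len(self.n_per_pop) != self.n_pops:
            raise ValueError("n_per_pop list length must equal n_pops")
        return list(self.n_per_pop)


@dataclass
class SimulationTruth:
    """Ground truth retained for parameter-recovery tests."""

    ancestral_freqs: np.ndarray  # (L,) alt-allele frequencies
    pop_freqs: np.ndarray  # (K, L)
    config: SimulationConfig = field(repr=False, default=None)  # type: ignore[assignment]


def _pop_names(k: int) -> list[str]:
    base = ["POP1", "POP2", "POP3"]
    if k <= 3:
        return base[:k]
    return base + [f"POP{i + 1}" for i in range(3, k)]


def simulate(config: SimulationConfig) -> tuple[GenotypeTable, SimulationTruth]:
    """Draw a synthetic multi-breed genotype table; reproducible from seed."""
    rng = np.random.default_rng(config.seed)
    K, L = config.n_pops, config.n_loci
    sizes = config.pop_sizes
    F, Fis = config.fst_target, config.fis_target

    lo, hi = config.anc_maf_range
    p_anc = rng.uniform(lo, hi, size=L)

    # Balding–Nichols per-population frequencies
    shape = (1.0 - F) / F
    pop_freqs = rng.beta(p_anc * shape, (1.0 - p_anc) * shape, size=(K, L))
    pop_freqs = np.clip(pop_freqs, 1e-9, 1.0 - 1e-9)
    if Fis < 0.0 and config.clip_freqs:
        # heterozygote excess requires p(p + (1-p)F_IS) >= 0, i.e.
        # p in [f/(1+f), 1 - f/(1+f)] with f = -F_IS; nudge drifted
        # frequencies just inside so hom probabilities stay non-negative
        f = -Fis
        lo_valid = f / (1.0 + f) + 1e-9
        pop_freqs = np.clip(pop_freqs, lo_valid, 1.0 - lo_valid)

    # genotype probabilities with inbreeding adjustment
    het = 2.0 * pop_freqs * (1.0 - pop_freqs) * (1.0 - Fis)
    hom_alt = pop_freqs**2 + pop_freqs * (1.0 - pop_freqs) * Fis
    hom_ref = (1.0 - pop_freqs) ** 2 + pop_freqs * (1.0 - pop_freqs) * Fis
    bad = (het > 1.0) | (hom_alt < 0.0) | (hom_ref < 0.0)
    if bad.any():
        k, j = np.argwhere(bad)[0]
        raise ValueError(
            f"invalid genotype probabilities at population {k}, locus {j} "
            f"(p={pop_freqs[k, j]:.4f}, F_IS={Fis}); reduce |F_IS| or narrow the MAF range"
        )

    blocks = []
    samples: list[Sample] = []
    names = _pop_names(K)
    for k, n_k in enumerate(sizes):
        u = rng.random((n_k, L))
        block = np.where(u < hom_ref[k], 0, np.where(u < hom_ref[k] + het[k], 1, 2))
        blocks.append(block.astype(np.int8))
        samples += [Sample(sample_id=f"{names[k]}_{i:04d}", population=names[k]) for i in range(n_k)]
    dosages = np.vstack(blocks)

    if config.missing_rate > 0:
        miss = rng.random(dosages.shape) < config.missing_rate
        dosages[miss] = MISSING

    loci = []
    for j in range(L):
        ref, alt = rng.choice(4, size=2, replace=False)
        loci.append(
            Locus(
                locus_id=f"snp{j + 1:05d}",
                chromosome=str(j % 18 + 1),
                position=(j // 18 + 1) * 1000,
                allele_ref=str(_NUCS[ref]),
                allele_alt=str(_NUCS[alt]),
            )
        )

    table = GenotypeTable(samples=samples, loci=loci, dosages=dosages)
    truth = SimulationTruth(ancestral_freqs=p_anc, pop_freqs=pop_freqs, config=config)
    return table, truth
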