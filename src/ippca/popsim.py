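"""Synthetic genotype panels for structure-detection experiments.

Subpopulation allele frequencies follow the Balding-Nichols model: per
marker an ancestral frequency p0 is drawn uniformly from a configurable
range, and each subpopulation's frequency is Beta(p0(1-F)/F, (1-p0)(1-F)/F)
with F the divergence parameter, so the expected fixation index between
subpopulations is approximately F (F = 0 means every subpopulation shares
p0 exactly -- a homogeneous panel).  Genotypes are Hardy-Weinberg binomial
draws within each subpopulation.  Markers are independent biallelic SNPs;
linkage disequilibrium, admixture and migration histories are deliberately
out of scope (see docs/methods.md for what this does and does not emulate).

Presets reproduce the study conditions: ``paper-null`` (one population of
10,000 individuals, 10,000 SNPs), ``paper-twopop`` (two subpopulations of
5,000, 10,000 SNPs), and 2,000-SNP desk-scale analogs used by the bundled
experiments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ippca.exceptions import UsageError
from ippca.genotype_io import MISSING, GenotypeTable

__all__ = ["SimulationConfig", "PRESETS", "simulate", "subsample", "subsample_balanced"]

#: between-subpopulation divergence of the two-population preset; chosen so
#: the size-100 ROC of the EigenDev statistic sits in its informative
#: operating region while larger samples approach perfect detection
ROC_PRESET_DIVERGENCE = 0.004


@dataclass
class SimulationConfig:
    subpop_sizes: tuple[int, ...] = (1000,)
    n_markers: int = 2000
    divergence: float = 0.0  # Balding-Nichols F in [0, 1)
    ancestral_maf_range: tuple[float, float] = (0.05, 0.5)
    missing_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if not self.subpop_sizes or any(s < 1 for s in self.subpop_sizes):
            raise UsageError("subpop_sizes must all be >= 1")
        if self.n_markers < 1:
            raise UsageError("n_markers must be >= 1")
        if not 0.0 <= self.divergence < 1.0:
            raise UsageError("divergence must be in [0, 1)")
        lo, hi = self.ancestral_maf_range
        if not 0.0 < lo <= hi < 1.0:
            raise UsageError("ancestral_maf_range must satisfy 0 < lo <= hi < 1")
        if not 0.0 <= self.missing_rate < 1.0:
            raise UsageError("missing_rate must be in [0, 1)")


PRESETS: dict[str, SimulationConfig] = {
    "paper-null": SimulationConfig(subpop_sizes=(10_000,), n_markers=10_000),
    "paper-twopop": SimulationConfig(
        subpop_sizes=(5_000, 5_000), n_markers=10_000, divergence=ROC_PRESET_DIVERGENCE
    ),
    "desk-null": SimulationConfig(subpop_sizes=(2_000,), n_markers=2_000),
    "desk-twopop": SimulationConfig(
        subpop_sizes=(1_000, 1_000), n_markers=2_000, divergence=ROC_PRESET_DIVERGENCE
    ),
}


def simulate(config: SimulationConfig) -> GenotypeTable:
    """Draw a genotype panel; truth labels record the generating subpopulation.

    Deterministic given ``config.seed``.  Allele symbols are "A" (reference)
    and "B" (alternate); genotype calls store the number of "B" copies as an
    unordered symbol pair.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    lo, hi = config.ancestral_maf_range
    p0 = rng.uniform(lo, hi, config.n_markers)
    F = config.divergence
    blocks = []
    labels: list[str] = []
    for k, size in enumerate(config.subpop_sizes, start=1):
        if F > 0.0:
            ps = rng.beta(p0 * (1.0 - F) / F, (1.0 - p0) * (1.0 - F) / F)
        else:
            ps = p0
        blocks.append(rng.binomial(2, ps, size=(size, config.n_markers)))
        labels += [f"pop{k}"] * size
    g = np.vstack(blocks).astype(np.int16)  # copies of allele "B"
    m = g.shape[0]
    # genotype -> unordered allele-code pair over alleles ["A", "B"]
    calls = np.empty((m, config.n_markers, 2), dtype=np.int16)
    calls[:, :, 0] = (g >= 1)  # one "B" whenever any copy present
    calls[:, :, 1] = (g == 2)  # second slot "B" only for homozygote B
    if config.missing_rate > 0.0:
        miss = rng.random((m, config.n_markers)) < config.missing_rate
        calls[miss] = MISSING
    return GenotypeTable(
        individual_ids=[f"ind{i + 1}" for i in range(m)],
        marker_ids=[f"snp{j + 1}" for j in range(config.n_markers)],
        calls=calls,
        marker_alleles=[["A", "B"] for _ in range(config.n_markers)],
        labels=labels,
    )


def subsample(table: GenotypeTable, n: int, seed: int) -> GenotypeTable:
    """Uniform subset of n individuals without replacement, original order kept."""
    m = table.n_individuals
    if n > m:
        raise UsageError(f"cannot subsample {n} from {m} individuals")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(m, size=n, replace=False))
    return table.subset(idx)


def subsample_balanced(table: GenotypeTable, n: int, seed: int) -> GenotypeTable:
    """Subset of n individuals split as evenly as possible across truth labels."""
    if table.labels is None:
        raise UsageError("balanced subsampling needs truth labels")
    groups: dict[str, list[int]] = {}
    for i, lab in enumerate(table.labels):
        groups.setdefault(lab, []).append(i)
    g = len(groups)
    base, extra = divmod(n, g)
    rng = np.random.default_rng(seed)
    picked: list[int] = []
    for k, (lab, idx) in enumerate(sorted(groups.items())):
        want = base + (1 if k < extra else 0)
        if want > len(idx):
            raise UsageError(f"group '{lab}' has only {len(idx)} individuals, need {want}")
        picked += list(rng.choice(idx, size=want, replace=False))
    return table.subset(np.sort(np.asarray(picked)))
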