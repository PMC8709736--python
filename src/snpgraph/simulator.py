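"""Synthetic references, SNP panels, diploid individuals and reads.

The simulator emulates the data layout of a human SNP-genotyping study at
desk scale: a reference genome, a population SNP catalog with allele
frequencies (the role a dbSNP subset plays), one diploid individual whose
non-reference genotypes form the truth set (the role of a gold-standard
callset), and whole-genome shotgun reads at a target coverage with optional
substitution errors.  It models none of the realism that the exact aligner
ignores anyway: no indel errors, no quality model, no paired ends, no
linkage disequilibrium.

All stages draw from independent streams derived from a single seed, so
changing the read simulation does not perturb the panel or the individual.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from snpgraph.aligner import Read
from snpgraph.graph_model import reverse_complement

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# fixed per-stage stream labels
_STAGE_REFERENCE = 1
_STAGE_PANEL = 2
_STAGE_INDIVIDUAL = 3
_STAGE_READS = 4


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic dataset.

    ``snp_rate`` is panel sites per reference base; ``maf_range`` is the
    support of the uniform population alternative-allele frequency sampler;
    ``coverage`` is mean read bases per genome position.
    """

    genome_length: int = 100_000
    n_chromosomes: int = 1
    snp_rate: float = 0.01
    maf_range: tuple[float, float] = (0.05, 0.5)
    read_length: int = 100
    coverage: float = 20.0
    substitution_error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_length < 1 or self.n_chromosomes < 1:
            raise ValueError("genome_length and n_chromosomes must be positive")
        if not 0.0 <= self.snp_rate <= 1.0:
            raise ValueError("snp_rate must be in [0, 1]")
        if not 0.0 <= self.substitution_error_rate <= 1.0:
            raise ValueError("substitution_error_rate must be in [0, 1]")
        lo, hi = self.maf_range
        if not 0.0 <= lo <= hi <= 1.0:
            raise ValueError("maf_range must satisfy 0 <= lo <= hi <= 1")

    def rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng([stage, self.seed])


@dataclass
class Individual:
    """One diploid individual: per-site genotypes and two haplotypes per chromosome."""

    genotypes: dict[tuple[str, int], str]  # (chrom, pos 1-based) -> 0/0, 0/1, 1/1
    haplotypes: dict[str, tuple[str, str]] = field(default_factory=dict)


PanelSite = tuple[str, int, str, str]  # chrom, 1-based pos, ref, alt


def _chrom_names(n: int) -> list[str]:
    return [f"chr{i + 1}" for i in range(n)]


def simulate_reference(config: SimConfig) -> dict[str, str]:
    """I.i.d. uniform ACGT chromosomes; the total length is split evenly."""
    rng = config.rng(_STAGE_REFERENCE)
    names = _chrom_names(config.n_chromosomes)
    per = config.genome_length // config.n_chromosomes
    lengths = [per] * config.n_chromosomes
    lengths[-1] += config.genome_length - per * config.n_chromosomes
    reference = {}
    for name, length in zip(names, lengths):
        idx = rng.integers(0, 4, size=length)
        reference[name] = _BASES[idx].tobytes().decode("ascii")
    return reference


def simulate_snp_panel(
    reference: dict[str, str], config: SimConfig
) -> tuple[list[PanelSite], dict[tuple[str, int], float]]:
    """Sample panel sites and their population alternative-allele frequencies.

    Sites are drawn without replacement at distinct positions per
    chromosome (count = round(snp_rate x chromosome length)), the REF
    allele is the reference base, the ALT allele is uniform over the other
    three bases, and each site's frequency is uniform over ``maf_range``.
    Returned sorted by (chrom, pos).
    """
    rng = config.rng(_STAGE_PANEL)
    panel: list[PanelSite] = []
    freqs: dict[tuple[str, int], float] = {}
    lo, hi = config.maf_range
    for chrom, seq in reference.items():
        n_sites = int(round(config.snp_rate * len(seq)))
        if n_sites == 0:
            continue
        usable = [i for i, b in enumerate(seq) if b != "N"]
        if n_sites > len(usable):
            raise ValueError(
                f"{chrom}: requested {n_sites} sites but only {len(usable)} "
                f"usable positions"
            )
        positions = rng.choice(len(usable), size=n_sites, replace=False)
        positions = np.sort(np.asarray(usable)[positions])
        for p in positions:
            ref_base = seq[p]
            others = [b for b in "ACGT" if b != ref_base]
            alt_base = others[rng.integers(0, 3)]
            pos1 = int(p) + 1
            panel.append((chrom, pos1, ref_base, alt_base))
            freqs[(chrom, pos1)] = float(rng.uniform(lo, hi))
    return panel, freqs


def simulate_individual(
    panel: list[PanelSite],
    config: SimConfig,
    reference: dict[str, str],
    freqs: dict[tuple[str, int], float] | None = None,
) -> tuple[Individual, list[tuple[str, int, str, str, str]]]:
    """Draw a diploid individual under Hardy-Weinberg equilibrium.

    Each haplotype independently carries the alternative allele with the
    site's population frequency; the genotype is the unordered pair.  The
    returned truth records are the individual's non-reference genotypes as
    (chrom, pos, ref, alt, genotype) tuples.
    """
    if not panel:
        raise ValueError("panel must be nonempty")
    rng = config.rng(_STAGE_INDIVIDUAL)
    genotypes: dict[tuple[str, int], str] = {}
    hap_alleles: dict[tuple[str, int], tuple[int, int]] = {}
    truth: list[tuple[str, int, str, str, str]] = []
    for chrom, pos, ref_base, alt_base in panel:
        q = freqs.get((chrom, pos), 0.0) if freqs is not None else 0.0
        a = int(rng.random() < q)
        b = int(rng.random() < q)
        hap_alleles[(chrom, pos)] = (a, b)
        gt = f"{min(a, b)}/{max(a, b)}"
        genotypes[(chrom, pos)] = gt
        if gt != "0/0":
            truth.append((chrom, pos, ref_base, alt_base, gt))

    individual = Individual(genotypes=genotypes)
    alt_by_chrom: dict[str, dict[int, str]] = {}
    for chrom, pos, _ref, alt_base in panel:
        alt_by_chrom.setdefault(chrom, {})[pos] = alt_base
    for chrom, seq in reference.items():
        haps = []
        for h in (0, 1):
            chars = list(seq)
            for pos, alt_base in alt_by_chrom.get(chrom, {}).items():
                if hap_alleles[(chrom, pos)][h]:
                    chars[pos - 1] = alt_base
            haps.append("".join(chars))
        individual.haplotypes[chrom] = (haps[0], haps[1])
    return individual, truth


def simulate_reads(individual: Individual, config: SimConfig) -> Iterator[Read]:
    """Shotgun reads from the two haplotypes at the target coverage.

    The read count is ``ceil(coverage x genome_length / read_length)``,
    split evenly across haplotypes.  Start positions are uniform per
    haplotype (chromosomes weighted by the number of valid starts), strand
    is uniform, and each base is substituted independently at
    ``substitution_error_rate``.  Read names encode the truth placement as
    ``read<i>:hap<h>:<chrom>:<start0>:<+|->`` for aligner tests.
    """
    rng = config.rng(_STAGE_READS)
    rl = config.read_length
    chroms = sorted(individual.haplotypes)
    genome_length = sum(len(individual.haplotypes[c][0]) for c in chroms)
    n_reads = math.ceil(config.coverage * genome_length / rl)
    starts_per_chrom = {}
    for chrom in chroms:
        n_starts = len(individual.haplotypes[chrom][0]) - rl + 1
        if n_starts < 1:
            raise ValueError(f"{chrom}: read_length {rl} exceeds chromosome length")
        starts_per_chrom[chrom] = n_starts
    weights = np.array([starts_per_chrom[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    quality = "I" * rl
    err = config.substitution_error_rate
    for i in range(n_reads):
        hap = i % 2
        ci = int(rng.choice(len(chroms), p=weights)) if len(chroms) > 1 else 0
        chrom = chroms[ci]
        start = int(rng.integers(0, starts_per_chrom[chrom]))
        fragment = individual.haplotypes[chrom][hap][start : start + rl]
        strand = "-" if rng.random() < 0.5 else "+"
        if strand == "-":
            fragment = reverse_complement(fragment)
        if err > 0.0:
            n_err = rng.binomial(rl, err)
            if n_err:
                sites = rng.choice(rl, size=n_err, replace=False)
                chars = list(fragment)
                for s in sites:
                    others = [b for b in "ACGT" if b != chars[s]]
                    chars[s] = others[rng.integers(0, 3)]
                fragment = "".join(chars)
        yield Read(
            name=f"read{i}:hap{hap}:{chrom}:{start}:{strand}",
            sequence=fragment,
            qualities=quality,
        )
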