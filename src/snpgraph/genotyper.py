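"""Allele support, threshold genotype calls, VCF output and evaluation.

An alignment that traverses a SNP's reference-allele node supports the
reference allele at that site; one that traverses the alternative-allele
node supports the alternative.  The two nodes are parallel, so a single
alignment can support at most one allele per site, and a read spanning
several sites contributes to each independently.

The genotype caller is deliberately simple plumbing: a site with total
allele depth below ``min_depth`` is no-called (``./.``); otherwise the
alternative-allele fraction is compared with ``hom_threshold`` to call
``1/1`` (fraction >= threshold), ``0/0`` (fraction <= 1 - threshold) or
``0/1`` (in between).  With exact, error-filtered alignments the allele
fractions at true sites concentrate near 0, 1/2 and 1, so a wide
homozygous threshold of 0.9 keeps the heterozygous miscall rate of a
binomial(n, 1/2) depth-n site below about 1e-3 at 20x coverage (at 0.8 the
two 20%-tails of the binomial would miscall ~1-2% of heterozygous sites).

Evaluation is genotype-aware: a non-reference call is a true positive only
when the truth set carries the identical genotype at the same
(chrom, pos, ref, alt) key.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from cyvcf2 import VCF

from snpgraph.aligner import GraphAlignment
from snpgraph.graph_model import SnpRecord

TruthRecord = tuple[str, int, str, str, str]  # chrom, pos, ref, alt, genotype


@dataclass
class SiteSupport:
    """Read support for the two alleles of one SNP site."""

    snp: SnpRecord
    ref_count: int = 0
    alt_count: int = 0


@dataclass(frozen=True)
class GenotypeCall:
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    genotype: str  # one of 0/0, 0/1, 1/1, ./.
    ref_depth: int
    alt_depth: int

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref_allele, self.alt_allele)

    @property
    def is_nonref(self) -> bool:
        return self.genotype in ("0/1", "1/1")


@dataclass(frozen=True)
class EvalReport:
    tp: int
    fp: int
    fn: int
    precision: float
    sensitivity: float
    f_measure: float


@dataclass(frozen=True)
class GenotyperParams:
    """Thresholds of the plumbing caller (see module docstring)."""

    min_depth: int = 2
    hom_threshold: float = 0.9

    def __post_init__(self) -> None:
        if self.min_depth < 1:
            raise ValueError("min_depth must be positive")
        if not 0.5 < self.hom_threshold <= 1.0:
            raise ValueError("hom_threshold must be in (0.5, 1]")


DEFAULT_PARAMS = GenotyperParams()


# ---------------------------------------------------------------------------
# support counting and calling
# ---------------------------------------------------------------------------

def snp_support(
    alignments: Iterable[GraphAlignment], snp_table: Sequence[SnpRecord]
) -> list[SiteSupport]:
    """Count, per SNP site, the alignments traversing each allele node.

    Alignments must have been produced against the graph that ``snp_table``
    describes; an alignment referencing a node id that is neither an allele
    node nor otherwise known to the table's graph cannot be detected here,
    but allele-node ids are checked to map to exactly one site.
    """
    support = [SiteSupport(snp) for snp in snp_table]
    by_node: dict[int, tuple[int, bool]] = {}
    for i, snp in enumerate(snp_table):
        by_node[snp.ref_node_id] = (i, False)
        by_node[snp.alt_node_id] = (i, True)
    for aln in alignments:
        for node_id, _, _, _ in aln.steps:
            entry = by_node.get(node_id)
            if entry is None:
                continue
            i, is_alt = entry
            if is_alt:
                support[i].alt_count += 1
            else:
                support[i].ref_count += 1
    return support


def call_genotypes(
    support: Iterable[SiteSupport], params: GenotyperParams = DEFAULT_PARAMS
) -> list[GenotypeCall]:
    """Threshold diploid calls from per-site allele depths (deterministic)."""
    calls = []
    for site in support:
        ref, alt = site.ref_count, site.alt_count
        total = ref + alt
        if total < params.min_depth:
            gt = "./."
        else:
            frac = alt / total
            if frac >= params.hom_threshold:
                gt = "1/1"
            elif frac <= 1.0 - params.hom_threshold:
                gt = "0/0"
            else:
                gt = "0/1"
        snp = site.snp
        calls.append(
            GenotypeCall(snp.chrom, snp.pos, snp.ref_allele, snp.alt_allele, gt, ref, alt)
        )
    return calls


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def evaluate_calls(
    calls: Iterable[GenotypeCall], truth: Iterable[TruthRecord]
) -> EvalReport:
    """Genotype-aware confusion counts and precision/sensitivity/F-measure.

    A non-reference call (0/1 or 1/1) is a true positive iff the truth set
    holds the identical genotype at the same (chrom, pos, ref, alt) key,
    otherwise a false positive.  Truth non-reference records without a
    matching true positive are false negatives.  Reference calls (0/0) and
    no-calls never enter the confusion counts.  Zero denominators yield
    zero metrics.
    """
    truth_map: dict[tuple[str, int, str, str], str] = {}
    for chrom, pos, ref, alt, gt in truth:
        key = (chrom, pos, ref, alt)
        if key in truth_map:
            raise ValueError(f"duplicate truth record for {key}")
        gt = gt.replace("|", "/")
        if gt == "1/0":
            gt = "0/1"
        truth_map[key] = gt

    tp = fp = 0
    matched: set[tuple[str, int, str, str]] = set()
    seen_calls: set[tuple[str, int, str, str]] = set()
    for call in calls:
        if call.key in seen_calls:
            raise ValueError(f"duplicate call for {call.key}")
        seen_calls.add(call.key)
        if not call.is_nonref:
            continue
        if truth_map.get(call.key) == call.genotype:
            tp += 1
            matched.add(call.key)
        else:
            fp += 1
    fn = sum(
        1
        for key, gt in truth_map.items()
        if gt in ("0/1", "1/1") and key not in matched
    )

    precision = tp / (tp + fp) if tp + fp else 0.0
    sensitivity = tp / (tp + fn) if tp + fn else 0.0
    f_measure = (
        2 * precision * sensitivity / (precision + sensitivity)
        if precision + sensitivity
        else 0.0
    )
    return EvalReport(tp, fp, fn, precision, sensitivity, f_measure)


# ---------------------------------------------------------------------------
# VCF output / truth input
# ---------------------------------------------------------------------------

def write_vcf(
    calls: Sequence[GenotypeCall],
    contigs: dict[str, int],
    sample_name: str = "SAMPLE",
    all_sites: bool = False,
) -> str:
    """Render calls as VCF 4.2 text with GT and AD FORMAT fields.

    Calls must be sorted by (chrom, pos); by default only non-reference
    calls are written.
    """
    keys = [(c.chrom, c.pos) for c in calls]
    if keys != sorted(keys):
        raise ValueError("calls must be sorted by (chrom, pos)")
    lines = [
        "##fileformat=VCFv4.2",
        "##source=snpgraph",
    ]
    for name, length in contigs.items():
        lines.append(f"##contig=<ID={name},length={length}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append(
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele read depths">'
    )
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample_name
    )
    for call in calls:
        if not all_sites and not call.is_nonref:
            continue
        lines.append(
            f"{call.chrom}\t{call.pos}\t.\t{call.ref_allele}\t{call.alt_allele}"
            f"\t.\t.\t.\tGT:AD\t{call.genotype}:{call.ref_depth},{call.alt_depth}"
        )
    return "\n".join(lines) + "\n"


def read_truth_vcf(path: str) -> list[TruthRecord]:
    """Read biallelic SNP genotypes from a (possibly gzipped) VCF file.

    Only biallelic single-nucleotide records are kept.  Phased genotypes
    are unphased; half-calls and missing genotypes become ``./.``.
    """
    records: list[TruthRecord] = []
    vcf = VCF(path)
    try:
        for variant in vcf:
            if len(variant.REF) != 1 or len(variant.ALT) != 1:
                continue
            if len(variant.ALT[0]) != 1:
                continue
            gts = variant.genotypes
            if not gts:
                continue
            a, b = gts[0][0], gts[0][1]
            if a < 0 or b < 0:
                gt = "./."
            else:
                a, b = sorted((a, b))
                gt = f"{a}/{b}"
            records.append(
                (variant.CHROM, variant.POS, variant.REF, variant.ALT[0], gt)
            )
    finally:
        vcf.close()
    return records


def read_calls_vcf(path: str) -> list[GenotypeCall]:
    """Read back calls written by :func:`write_vcf` (GT and AD fields)."""
    calls: list[GenotypeCall] = []
    vcf = VCF(path)
    try:
        for variant in vcf:
            gts = variant.genotypes
            a, b = gts[0][0], gts[0][1]
            if a < 0 or b < 0:
                gt = "./."
            else:
                a, b = sorted((a, b))
                gt = f"{a}/{b}"
            try:
                ad = variant.format("AD")[0]
                ref_depth, alt_depth = int(ad[0]), int(ad[1])
            except (TypeError, IndexError):
                ref_depth = alt_depth = 0
            calls.append(
                GenotypeCall(
                    variant.CHROM,
                    variant.POS,
                    variant.REF,
                    variant.ALT[0],
                    gt,
                    ref_depth,
                    alt_depth,
                )
            )
    finally:
        vcf.close()
    return calls
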