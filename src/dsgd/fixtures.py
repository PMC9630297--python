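"""Synthetic genomic fixtures and a deterministic toy variant caller.

Everything the secure pipeline consumes can be generated here at desk
scale with no downloads: a random reference (FASTA), error-free reads with
planted substitution variants (FASTQ.gz) tracked in a :class:`TruthSet`,
and standalone VCFs of any record count for disclosure-scenario tests.
Real whole-genome inputs are tens of GB; these generators emulate only the
formats and the ground-truth bookkeeping, not sequencing realism — no
indels, no quality-score calibration, uniform read tiling by default.

The toy caller is an exact-match/Hamming seed-and-extend pileup caller.
With the generator's error-free reads and coverage >= 10 it recovers the
planted truth set exactly, which is what makes end-to-end pipeline tests
crisp.  Its thresholds (allele fraction 0.25 het / 0.75 hom, depth >= 4)
are fixture constants, not claims about real variant calling.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Dict, IO, List, Sequence, Tuple

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import PlacementError
from .io_utils import deterministic_gzip_writer, open_maybe_gzip

__all__ = [
    "TruthSet",
    "ReadSimProfile",
    "gen_reference",
    "gen_truth_and_reads",
    "toy_call_variants",
    "gen_vcf",
    "evaluate_calls",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_SEED_KMER = 20  # anchor length for read placement
_MIN_DEPTH = 4
_MIN_ALT_FRACTION = 0.25
_HOM_FRACTION = 0.75


@dataclass(frozen=True)
class ReadSimProfile:
    """How reads are simulated: length, total fold coverage, error rate."""

    read_length: int = 100
    coverage: float = 30.0
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error rate must lie in [0, 1)")


@dataclass
class TruthSet:
    """Planted variants with their genotypes, the ground truth for calling."""

    reference_lengths: Dict[str, int]
    variants: List[Tuple[str, int, str, str, str]]  # chrom, pos (1-based), ref, alt, het|hom
    seed: int = 0

    def positions(self) -> set:
        return {(c, p) for c, p, *_ in self.variants}

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("chrom\tpos\tref\talt\tgenotype\n")
            for chrom, pos, ref, alt, gt in self.variants:
                fh.write(f"{chrom}\t{pos}\t{ref}\t{alt}\t{gt}\n")

    @classmethod
    def from_tsv(cls, path: str, reference_lengths: Dict[str, int] | None = None) -> "TruthSet":
        variants = []
        with open(path) as fh:
            next(fh)
            for line in fh:
                chrom, pos, ref, alt, gt = line.rstrip("\n").split("\t")
                variants.append((chrom, int(pos), ref, alt, gt))
        return cls(reference_lengths=reference_lengths or {}, variants=variants)


def gen_reference(
    n_chroms: int, length_per_chrom: int, seed: int, out_path: str | None = None
) -> Dict[str, str]:
    """Uniform-random A/C/G/T reference, one record per chromosome.

    Deterministic under ``seed``; returns ``{name: sequence}`` and writes a
    FASTA when ``out_path`` is given.
    """
    if length_per_chrom < 1000:
        raise ValueError("chromosomes shorter than 1 kb cannot support read simulation")
    rng = np.random.default_rng(seed)
    ref = {}
    for i in range(n_chroms):
        seq_codes = rng.integers(0, 4, size=length_per_chrom)
        ref[f"chr{i + 1}"] = _BASES[seq_codes].tobytes().decode("ascii")
    if out_path is not None:
        records = [
            SeqRecord(Seq(seq), id=name, description="") for name, seq in ref.items()
        ]
        with open(out_path, "w") as fh:
            SeqIO.write(records, fh, "fasta")
    return ref


def load_reference(path: str) -> Dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def _plant_variants(
    ref: Dict[str, str], n_variants: int, rng: np.random.Generator
) -> List[Tuple[str, int, str, str, str]]:
    total = sum(len(s) for s in ref.values())
    if n_variants * 20 > total:
        raise PlacementError(
            f"{n_variants} variants are too dense for a {total} bp reference"
        )
    # global positions sampled without replacement, then mapped per chromosome
    chosen = rng.choice(total, size=n_variants, replace=False)
    chosen.sort()
    bounds = []
    offset = 0
    for name, seq in ref.items():
        bounds.append((name, offset, offset + len(seq)))
        offset += len(seq)
    variants = []
    for gpos in chosen:
        for name, lo, hi in bounds:
            if lo <= gpos < hi:
                pos0 = int(gpos - lo)
                ref_base = ref[name][pos0]
                alts = [b for b in "ACGT" if b != ref_base]
                alt = alts[int(rng.integers(0, 3))]
                gt = "hom" if rng.random() < 0.5 else "het"
                variants.append((name, pos0 + 1, ref_base, alt, gt))
                break
    return variants


def _haplotypes(ref: Dict[str, str], truth: TruthSet) -> Tuple[Dict[str, str], Dict[str, str]]:
    """hom variants go on both haplotypes, het variants on haplotype 1 only."""
    hap0 = {name: bytearray(seq, "ascii") for name, seq in ref.items()}
    hap1 = {name: bytearray(seq, "ascii") for name, seq in ref.items()}
    for chrom, pos, _ref, alt, gt in truth.variants:
        hap1[chrom][pos - 1] = ord(alt)
        if gt == "hom":
            hap0[chrom][pos - 1] = ord(alt)
    return (
        {k: v.decode("ascii") for k, v in hap0.items()},
        {k: v.decode("ascii") for k, v in hap1.items()},
    )


def gen_truth_and_reads(
    reference: Dict[str, str] | str,
    n_variants: int,
    profile: ReadSimProfile,
    out_fastq_gz: str,
    truth_tsv: str | None = None,
) -> Tuple[TruthSet, str]:
    """Plant substitution variants and tile error-free reads over both haplotypes.

    Reads of fixed length tile each haplotype uniformly to half the target
    coverage each (total coverage = ``profile.coverage``), so the read count
    per chromosome is ``floor(L * coverage / (2 * read_length))`` per
    haplotype and coverage is essentially exact.  Read names encode
    ``chrom|haplotype|start`` for debugging.  Output is gzip-compressed
     4-line FASTQ, byte-identical across runs with the same seed.
    """
    ref = load_reference(reference) if isinstance(reference, str) else reference
    rng = np.random.default_rng(profile.seed)
    truth = TruthSet(
        reference_lengths={k: len(v) for k, v in ref.items()},
        variants=_plant_variants(ref, n_variants, rng),
        seed=profile.seed,
    )
    hap0, hap1 = _haplotypes(ref, truth)
    records = []
    rl = profile.read_length
    for chrom in ref:
        length = len(ref[chrom])
        if rl > length:
            raise ValueError("read length exceeds chromosome length")
        n_per_hap = int(length * profile.coverage // (2 * rl))
        for hap_idx, hap in ((0, hap0), (1, hap1)):
            seq = hap[chrom]
            for i in range(n_per_hap):
                if n_per_hap == 1:
                    start = 0
                else:
                    start = round(i * (length - rl) / (n_per_hap - 1))
                read = seq[start : start + rl]
                if profile.error_rate > 0:
                    read = _inject_errors(read, profile.error_rate, rng)
                rec = SeqRecord(
                    Seq(read),
                    id=f"{chrom}|hap{hap_idx}|{start}|r{i}",
                    description="",
                )
                rec.letter_annotations["phred_quality"] = [40] * rl
                records.append(rec)
    with deterministic_gzip_writer(out_fastq_gz, "wt") as fh:
        SeqIO.write(records, fh, "fastq")
    if truth_tsv is not None:
        truth.to_tsv(truth_tsv)
    return truth, out_fastq_gz


def _inject_errors(read: str, rate: float, rng: np.random.Generator) -> str:
    arr = bytearray(read, "ascii")
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        choices = [b for b in b"ACGT" if b != arr[i]]
        arr[i] = choices[int(rng.integers(0, 3))]
    return arr.decode("ascii")


# ---------------------------------------------------------------------------
# Toy variant caller
# ---------------------------------------------------------------------------


def _kmer_index(ref: Dict[str, str], k: int) -> Dict[str, List[Tuple[str, int]]]:
    index: Dict[str, List[Tuple[str, int]]] = {}
    for chrom, seq in ref.items():
        for i in range(len(seq) - k + 1):
            index.setdefault(seq[i : i + k], []).append((chrom, i))
    return index


def _place_read(
    read: str, ref: Dict[str, str], index: Dict[str, List[Tuple[str, int]]], k: int
) -> Tuple[str, int] | None:
    """Seed-and-extend placement: anchor a k-mer, pick the Hamming-nearest hit."""
    best = None
    best_mismatches = None
    seen = set()
    for offset in range(0, len(read) - k + 1, k):
        for chrom, hit in index.get(read[offset : offset + k], ()):
            start = hit - offset
            if start < 0 or start + len(read) > len(ref[chrom]) or (chrom, start) in seen:
                continue
            seen.add((chrom, start))
            window = ref[chrom][start : start + len(read)]
            mism = sum(a != b for a, b in zip(read, window))
            if best_mismatches is None or mism < best_mismatches:
                best, best_mismatches = (chrom, start), mism
        if best_mismatches == 0:
            break
    return best


def toy_call_variants(
    fastq_gz: str,
    reference_fasta: str | Dict[str, str],
    out_vcf: str | None = None,
    sample_name: str = "SAMPLE",
) -> str:
    """Pileup-based substitution caller over exact/Hamming-nearest placements.

    Emits a VCF 4.2 record wherever a non-reference allele reaches fraction
    >= 0.25 at depth >= 4; genotype is hom (1/1) at fraction >= 0.75, else
    het (0/1).  Output ordering is (chromosome, position).  Returns the VCF
    text; writes it (gzip if the path ends ``.gz``) when ``out_vcf`` given.
    """
    ref = (
        load_reference(reference_fasta)
        if isinstance(reference_fasta, str)
        else reference_fasta
    )
    index = _kmer_index(ref, _SEED_KMER)
    counts = {
        chrom: np.zeros((4, len(seq)), dtype=np.int32) for chrom, seq in ref.items()
    }
    base_code = {65: 0, 67: 1, 71: 2, 84: 3}  # A C G T
    skipped = 0
    with open_maybe_gzip(fastq_gz, "rt") as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            read = str(rec.seq)
            placed = _place_read(read, ref, index, _SEED_KMER)
            if placed is None:
                skipped += 1
                continue
            chrom, start = placed
            codes = np.frombuffer(read.encode("ascii"), dtype=np.uint8)
            rows = np.array([base_code.get(c, -1) for c in codes])
            cols = np.arange(start, start + len(read))
            ok = rows >= 0
            np.add.at(counts[chrom], (rows[ok], cols[ok]), 1)
    if skipped:
        import logging

        logging.getLogger(__name__).info("toy caller skipped %d unmappable reads", skipped)

    lines = [
        "##fileformat=VCFv4.2",
        "##source=dsgd-toy-caller",
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##INFO=<ID=AF,Number=1,Type=Float,Description="Alternate allele fraction">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    for chrom, seq in ref.items():
        lines.append(f"##contig=<ID={chrom},length={len(seq)}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample_name
    )
    for chrom in sorted(ref):
        seq = ref[chrom]
        mat = counts[chrom]
        depth = mat.sum(axis=0)
        candidates = np.nonzero(depth >= _MIN_DEPTH)[0]
        for pos0 in candidates:
            ref_base = seq[pos0]
            ref_row = base_code.get(ord(ref_base))
            col = mat[:, pos0]
            alt_row = None
            alt_count = 0
            for row in range(4):
                if row != ref_row and col[row] > alt_count:
                    alt_row, alt_count = row, int(col[row])
            if alt_row is None:
                continue
            frac = alt_count / int(depth[pos0])
            if frac < _MIN_ALT_FRACTION:
                continue
            gt = "1/1" if frac >= _HOM_FRACTION else "0/1"
            alt_base = "ACGT"[alt_row]
            lines.append(
                f"{chrom}\t{pos0 + 1}\t.\t{ref_base}\t{alt_base}\t.\tPASS\t"
                f"DP={int(depth[pos0])};AF={frac:.3f}\tGT\t{gt}"
            )
    text = "\n".join(lines) + "\n"
    if out_vcf is not None:
        with open_maybe_gzip(out_vcf, "wt") as fh:
            fh.write(text)
    return text


# ---------------------------------------------------------------------------
# Standalone VCF generator for disclosure scenarios
# ---------------------------------------------------------------------------


def gen_vcf(
    n_records: int,
    n_chroms: int = 1,
    seed: int = 0,
    out_path: str | None = None,
) -> str:
    """A syntactically valid sorted VCF with exactly ``n_records`` data lines.

    Records carry rs-style IDs, DP/AF INFO fields and a GT FORMAT column —
    enough surface for every disclosure mode to have something to select on.
    Deterministic under ``seed``; gzip applied when the path ends ``.gz``.
    """
    if n_records < 0:
        raise ValueError("n_records must be non-negative")
    rng = np.random.default_rng(seed)
    per_chrom = [n_records // n_chroms] * n_chroms
    for i in range(n_records % n_chroms):
        per_chrom[i] += 1
    spacing = 10
    lines = ["##fileformat=VCFv4.2", "##source=dsgd-fixtures"]
    lines += [
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##INFO=<ID=AF,Number=1,Type=Float,Description="Allele frequency">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    for c in range(n_chroms):
        contig_len = max(per_chrom[c] * spacing + 1000, 2000)
        lines.append(f"##contig=<ID=chr{c + 1},length={contig_len}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tSAMPLE")
    rs = 1
    for c in range(n_chroms):
        pos = 0
        for _ in range(per_chrom[c]):
            pos += int(rng.integers(1, spacing + 1))
            ref_b, alt_b = rng.choice(4, size=2, replace=False)
            dp = int(rng.integers(10, 100))
            af = float(rng.integers(1, 1000)) / 1000
            gt = "0/1" if rng.random() < 0.5 else "1/1"
            lines.append(
                f"chr{c + 1}\t{pos}\trs{rs}\t{'ACGT'[ref_b]}\t{'ACGT'[alt_b]}"
                f"\t.\tPASS\tDP={dp};AF={af:.3f}\tGT\t{gt}"
            )
            rs += 1
    text = "\n".join(lines) + "\n"
    if out_path is not None:
        with open_maybe_gzip(out_path, "wt") as fh:
            fh.write(text)
    return text


def evaluate_calls(truth: TruthSet, vcf_source: str) -> Dict[str, float]:
    """Recall/precision of called substitutions against a truth set.

    ``vcf_source`` is a path or raw VCF text.  Genotype concordance counts a
    truth variant as matched only when the zygosity agrees (het vs hom).
    """
    truth_map = {(c, p): (r, a, g) for c, p, r, a, g in truth.variants}
    called = {}
    if "\n" in vcf_source:
        lines = vcf_source.splitlines()
    else:
        with open_maybe_gzip(vcf_source, "rt") as fh:
            lines = [l.rstrip("\n") for l in fh]
    for line in lines:
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        gt = f[9] if len(f) > 9 else ""
        called[(f[0], int(f[1]))] = (f[3], f[4], "hom" if gt == "1/1" else "het")
    tp = sum(
        1
        for locus, (r, a, g) in truth_map.items()
        if locus in called and called[locus][:2] == (r, a)
    )
    gt_match = sum(
        1
        for locus, (r, a, g) in truth_map.items()
        if locus in called and called[locus] == (r, a, g)
    )
    recall = tp / len(truth_map) if truth_map else 1.0
    precision = tp / len(called) if called else 1.0
    return {
        "recall": recall,
        "precision": precision,
        "genotype_concordance": gt_match / len(truth_map) if truth_map else 1.0,
        "n_truth": len(truth_map),
        "n_called": len(called),
    }
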