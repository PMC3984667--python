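"""Sequence variant calling and regulatory annotation.

Compares a re-sequenced promoter + transcript region between an obese
line and the reference line: calls SNPs and InDels from a global pairwise
alignment, classifies each variant against a gene model (promoter /
5'UTR / coding / 3'UTR, minus-strand aware), determines coding effects
for CDS SNPs, and predicts regulatory consequences — transcription-
factor binding sites gained or lost (position-weight-matrix scan at a
relative-score threshold) and miRNA recognition sites gained or lost in
the 3'UTR (seed-complement scan with a duplex energy threshold).

Coordinate conventions
----------------------
Chromosome positions are 1-based inclusive.  For a minus-strand gene the
sequences handled here are stored in *transcript* orientation (the minus
strand read 5'->3'), and alleles are reported on that strand.  Local
position ``i`` (1-based from the 5' end of the sequenced region) maps to
chromosome position ``high - i + 1`` where ``high`` is the highest
genomic coordinate of the region; on the plus strand the map is
``offset + i - 1``.

The energy model for miRNA sites is a deliberate simplification of
published duplex/open-energy scores: per-pair energies (GC -3.0,
AU -2.0, GU -1.0 by default, pluggable) summed over the maximal
contiguous duplex.  The threshold semantics (a site is reported iff its
score is <= the energy threshold, default -10) and the gain/loss logic
follow the published analysis; the numeric scores do not.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import Align, motifs
from Bio.Seq import Seq

_DNA = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# gene model


@dataclass(frozen=True)
class GeneModel:
    """Exon/CDS structure of one transcript plus its promoter window.

    ``exons`` are genomic 1-based inclusive intervals in ascending
    order; ``cds`` is the genomic interval spanned by the coding
    sequence.  The promoter comprises ``promoter_length`` bases
    immediately upstream of the first exon on the strand-aware upstream
    side (higher coordinates for a minus-strand gene).
    """

    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds: tuple[int, int]
    promoter_length: int = 420

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        prev_end = 0
        for start, end in self.exons:
            if start > end:
                raise ValueError(f"malformed exon ({start}, {end})")
            if start <= prev_end:
                raise ValueError("exons must be non-overlapping and ascending")
            prev_end = end
        c0, c1 = self.cds
        if not (self.exons[0][0] <= c0 <= c1 <= self.exons[-1][1]):
            raise ValueError("CDS outside exon span")

    @property
    def promoter(self) -> tuple[int, int]:
        if self.strand == "-":
            top = self.exons[-1][1]
            return (top + 1, top + self.promoter_length)
        bottom = self.exons[0][0]
        return (bottom - self.promoter_length, bottom - 1)

    @property
    def span(self) -> tuple[int, int]:
        """Genomic interval covered by promoter + transcript."""
        lo = min(self.promoter[0], self.exons[0][0])
        hi = max(self.promoter[1], self.exons[-1][1])
        return (lo, hi)

    def cds_position(self, pos: int) -> int | None:
        """1-based position within the spliced CDS, or None if the
        genomic position is not coding."""
        c0, c1 = self.cds
        if not (c0 <= pos <= c1):
            return None
        coding_exons = []
        for start, end in self.exons:
            s, e = max(start, c0), min(end, c1)
            if s <= e:
                coding_exons.append((s, e))
        if not any(s <= pos <= e for s, e in coding_exons):
            return None
        if self.strand == "-":
            offset = 0
            for s, e in sorted(coding_exons, key=lambda x: -x[1]):
                if s <= pos <= e:
                    return offset + (e - pos) + 1
                offset += e - s + 1
        else:
            offset = 0
            for s, e in coding_exons:
                if s <= pos <= e:
                    return offset + (pos - s) + 1
                offset += e - s + 1
        return None


# ---------------------------------------------------------------------------
# variants


@dataclass(frozen=True)
class Variant:
    """One SNP/INS/DEL, alleles in transcript-strand orientation.

    ``pos`` is the 1-based chromosome position of the first reference
    base of the event in transcript orientation (for an insertion, the
    position the inserted bases precede).  ``ref``/``alt`` use ``-``
    for the empty allele.
    """

    pos: int
    ref: str
    alt: str
    known_id: str | None = None
    region: str | None = None
    effect: str | None = None
    function: str | None = None

    def __post_init__(self) -> None:
        ref, alt = self.ref, self.alt
        if ref == alt:
            raise ValueError("ref and alt alleles are identical")
        for allele in (ref, alt):
            if allele != "-" and not set(allele) <= _DNA:
                raise ValueError(f"bad allele {allele!r}")

    @property
    def type(self) -> str:
        if self.ref != "-" and self.alt != "-" and len(self.ref) == len(self.alt) == 1:
            return "SNP"
        if self.alt == "-" or len(self.alt) < len(self.ref):
            return "DEL"
        return "INS"

    @property
    def novel(self) -> bool:
        return not self.known_id


def genomic_to_local(pos: int, offset: int, strand: str) -> int:
    """Map a chromosome position to a 1-based local index.

    ``offset`` is the chromosome position of local base 1 (the region's
    lowest coordinate on '+', highest on '-')."""
    return (offset - pos + 1) if strand == "-" else (pos - offset + 1)


def local_to_genomic(i: int, offset: int, strand: str) -> int:
    return (offset - i + 1) if strand == "-" else (offset + i - 1)


def _left_normalize(seq: str, pos: int, allele: str) -> tuple[int, str]:
    """Shift an indel event left through repeat context.

    ``pos`` is the local position of the first affected base (for DEL)
    or the base the insertion precedes (for INS); ``allele`` is the
    deleted/inserted string.  Rotation: while the base left of the event
    equals the allele's last base, move one left."""
    allele = list(allele)
    while pos > 1 and seq[pos - 2] == allele[-1]:
        allele.insert(0, allele.pop())
        pos -= 1
    return pos, "".join(allele)


def apply_variants(
    ref_seq: str, variants: Sequence[Variant], offset: int, strand: str
) -> str:
    """Apply variants (chromosome coordinates) to a local-orientation
    reference sequence, validating ref alleles; returns the alternate
    sequence."""
    events = []
    for v in variants:
        i = genomic_to_local(v.pos, offset, strand)
        ref_len = 0 if v.ref == "-" else len(v.ref)
        if i < 1 or i + max(ref_len, 1) - 1 > len(ref_seq):
            raise ValueError(f"variant at {v.pos} outside the modeled span")
        if v.ref != "-" and ref_seq[i - 1 : i - 1 + ref_len] != v.ref:
            raise ValueError(
                f"allele mismatch at {v.pos}: reference has "
                f"{ref_seq[i - 1:i - 1 + ref_len]!r}, variant says {v.ref!r}"
            )
        events.append((i, ref_len, v))
    events.sort(key=lambda e: e[0])
    for k in range(1, len(events)):
        prev_i, prev_len, prev_v = events[k - 1]
        if events[k][0] < prev_i + max(prev_len, 1):
            raise ValueError(
                f"overlapping variants at {prev_v.pos} and {events[k][2].pos}"
            )
    out = []
    cursor = 0  # 0-based index into ref_seq
    for i, ref_len, v in events:
        out.append(ref_seq[cursor : i - 1])
        out.append("" if v.alt == "-" else v.alt)
        cursor = i - 1 + ref_len
    out.append(ref_seq[cursor:])
    return "".join(out)


def call_variants(
    ref_seq: str,
    alt_seq: str,
    offset: int,
    strand: str = "+",
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -5.0,
    gap_extend: float = -1.0,
) -> list[Variant]:
    """Call SNPs and InDels between two sequences by global alignment.

    Adjacent mismatch columns are split into individual SNPs; gaps are
    emitted as left-normalized InDels.  Positions are chromosome
    coordinates via ``offset``/``strand``.
    """
    for name, s in (("ref", ref_seq), ("alt", alt_seq)):
        if not s:
            raise ValueError(f"empty {name} sequence")
        if not set(s) <= _DNA:
            raise ValueError(f"{name} sequence has non-ACGTN characters")
    if ref_seq == alt_seq:
        return []
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    aln = aligner.align(ref_seq, alt_seq)[0]
    ref_aln, alt_aln = aln[0], aln[1]

    raw: list[tuple[int, str, str]] = []  # (local pos, ref allele, alt allele)
    ref_pos = 0  # count of ref bases consumed
    col = 0
    n = len(ref_aln)
    while col < n:
        r, a = ref_aln[col], alt_aln[col]
        if r != "-" and a != "-":
            if r != a:
                raw.append((ref_pos + 1, r, a))
            ref_pos += 1
            col += 1
        elif a == "-":  # deletion from reference
            start = ref_pos + 1
            deleted = []
            while col < n and alt_aln[col] == "-":
                deleted.append(ref_aln[col])
                ref_pos += 1
                col += 1
            pos, allele = _left_normalize(ref_seq, start, "".join(deleted))
            raw.append((pos, allele, "-"))
        else:  # insertion into alternate
            inserted = []
            while col < n and ref_aln[col] == "-":
                inserted.append(alt_aln[col])
                col += 1
            pos, allele = _left_normalize(ref_seq, ref_pos + 1, "".join(inserted))
            raw.append((pos, "-", allele))
    variants = [
        Variant(pos=local_to_genomic(i, offset, strand), ref=r, alt=a)
        for i, r, a in raw
    ]
    variants.sort(key=lambda v: genomic_to_local(v.pos, offset, strand))
    return variants


def normalize_variant(v: Variant, ref_seq: str, offset: int, strand: str) -> Variant:
    """Left-normalize an indel against the local reference sequence."""
    if v.type == "SNP":
        return v
    i = genomic_to_local(v.pos, offset, strand)
    allele = v.ref if v.type == "DEL" else v.alt
    pos, allele = _left_normalize(ref_seq, i, allele)
    g = local_to_genomic(pos, offset, strand)
    if v.type == "DEL":
        return Variant(g, allele, "-", v.known_id, v.region, v.effect, v.function)
    return Variant(g, "-", allele, v.known_id, v.region, v.effect, v.function)


def classify_region(variant: Variant, model: GeneModel) -> str:
    """Assign promoter / 5'UTR / coding / 3'UTR / other, strand-aware."""
    pos = variant.pos
    p0, p1 = model.promoter
    if p0 <= pos <= p1:
        return "promoter"
    c0, c1 = model.cds
    for start, end in model.exons:
        if start <= pos <= end:
            if c0 <= pos <= c1:
                return "coding"
            if (model.strand == "-" and pos > c1) or (
                model.strand == "+" and pos < c0
            ):
                return "5'UTR"
            return "3'UTR"
    return "other"


def coding_effect(
    variant: Variant, model: GeneModel, ref_seq: str, offset: int
) -> str:
    """``synonymous`` or ``missense`` for a coding SNP.

    ``ref_seq`` is the transcript-orientation sequence of the region
    starting at local position 1 = chromosome position ``offset``.
    """
    if variant.type != "SNP":
        raise ValueError("frameshift handling out of scope")
    cds_pos = model.cds_position(variant.pos)
    if cds_pos is None:
        raise ValueError(f"variant at {variant.pos} is not coding")
    cds_seq = extract_cds(model, ref_seq, offset)
    codon_idx = (cds_pos - 1) // 3
    in_codon = (cds_pos - 1) % 3
    codon = cds_seq[codon_idx * 3 : codon_idx * 3 + 3]
    if codon[in_codon] != variant.ref:
        raise ValueError(
            f"reference allele mismatch in CDS at {variant.pos}: "
            f"codon {codon}, expected {variant.ref}"
        )
    alt_codon = codon[:in_codon] + variant.alt + codon[in_codon + 1 :]
    aa_ref = str(Seq(codon).translate())
    aa_alt = str(Seq(alt_codon).translate())
    return "synonymous" if aa_ref == aa_alt else "missense"


def extract_cds(model: GeneModel, ref_seq: str, offset: int) -> str:
    """Spliced CDS in translation order from the transcript-orientation
    region sequence."""
    c0, c1 = model.cds
    pieces = []
    exons = model.exons if model.strand == "+" else tuple(reversed(model.exons))
    for start, end in exons:
        s, e = max(start, c0), min(end, c1)
        if s > e:
            continue
        if model.strand == "-":
            i0 = genomic_to_local(e, offset, "-")
            i1 = genomic_to_local(s, offset, "-")
        else:
            i0 = genomic_to_local(s, offset, "+")
            i1 = genomic_to_local(e, offset, "+")
        pieces.append(ref_seq[i0 - 1 : i1])
    return "".join(pieces)


# ---------------------------------------------------------------------------
# PWM / TFBS


@dataclass(frozen=True)
class PWM:
    """Log-odds position weight matrix over A, C, G, T."""

    motif_id: str
    weights: tuple[tuple[float, float, float, float], ...]  # L x 4

    def __post_init__(self) -> None:
        if len(self.weights) < 4:
            raise ValueError("motif length must be >= 4")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("non-finite PWM entries")

    def __len__(self) -> int:
        return len(self.weights)


_BASE_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}


def pwm_from_counts(
    motif_id: str,
    counts: Mapping[str, Sequence[float]],
    pseudocount: float = 0.5,
    background: float = 0.25,
) -> PWM:
    """Build a log2-odds PWM from a base -> per-position count mapping."""
    length = len(counts["A"])
    weights = []
    for j in range(length):
        col = np.array([counts[b][j] for b in "ACGT"], dtype=float) + pseudocount
        freqs = col / col.sum()
        weights.append(tuple(np.log2(freqs / background)))
    return PWM(motif_id, tuple(weights))


def load_jaspar_pwms(path: str, pseudocount: float = 0.5) -> list[PWM]:
    """Read JASPAR-format motif files into log-odds PWMs."""
    with open(path) as fh:
        parsed = motifs.parse(fh, "jaspar")
    out = []
    for m in parsed:
        counts = {b: list(m.counts[b]) for b in "ACGT"}
        out.append(pwm_from_counts(m.matrix_id or m.name, counts, pseudocount))
    return out


def pwm_relative_score(window: str, pwm: PWM) -> float:
    """Relative score in [0, 1]: (raw - min) / (max - min) where raw is
    the summed per-position weight of the window."""
    if len(window) != len(pwm):
        raise ValueError(
            f"window length {len(window)} != motif length {len(pwm)}"
        )
    w = np.asarray(pwm.weights)
    raw = 0.0
    for j, base in enumerate(window):
        if base not in _BASE_IDX:
            return 0.0
        raw += w[j, _BASE_IDX[base]]
    lo, hi = w.min(axis=1).sum(), w.max(axis=1).sum()
    if hi == lo:
        return 1.0
    return float((raw - lo) / (hi - lo))


def _best_hits(seq: str, pwm: PWM) -> float:
    """Best relative score of ``pwm`` over all windows of ``seq`` on
    both strands."""
    L = len(pwm)
    best = 0.0
    for strand_seq in (seq, reverse_complement(seq)):
        for i in range(len(strand_seq) - L + 1):
            best = max(best, pwm_relative_score(strand_seq[i : i + L], pwm))
    return best


def scan_tfbs_delta(
    ref_seq: str,
    alt_seq: str,
    variant: Variant,
    pwms: Iterable[PWM],
    offset: int,
    strand: str = "+",
    threshold: float = 0.8,
    score_delta: float = 0.05,
) -> dict[str, list[str]]:
    """Per-motif gain/loss/modification caused by one variant.

    The scan window is the variant position +/- (motif length - 1) in
    each allele's sequence, both strands.  gain: hit (relative score >=
    threshold) in alt only; loss: hit in ref only; modification: hit in
    both with |delta relative score| >= score_delta.
    """
    i = genomic_to_local(variant.pos, offset, strand)
    shift = (0 if variant.alt == "-" else len(variant.alt)) - (
        0 if variant.ref == "-" else len(variant.ref)
    )
    gains, losses, mods = [], [], []
    for pwm in pwms:
        L = len(pwm)
        r0 = max(0, i - L)
        ref_len_evt = 0 if variant.ref == "-" else len(variant.ref)
        ref_win = ref_seq[r0 : min(len(ref_seq), i - 1 + ref_len_evt + L)]
        alt_win = alt_seq[r0 : min(len(alt_seq), i - 1 + ref_len_evt + shift + L)]
        ref_best = _best_hits(ref_win, pwm)
        alt_best = _best_hits(alt_win, pwm)
        ref_hit, alt_hit = ref_best >= threshold, alt_best >= threshold
        if alt_hit and not ref_hit:
            gains.append(pwm.motif_id)
        elif ref_hit and not alt_hit:
            losses.append(pwm.motif_id)
        elif ref_hit and alt_hit and abs(alt_best - ref_best) >= score_delta:
            mods.append(pwm.motif_id)
    return {"gain": gains, "loss": losses, "modification": mods}


# ---------------------------------------------------------------------------
# miRNA sites

DEFAULT_PAIR_ENERGIES = {"GC": -3.0, "AT": -2.0, "GT": -1.0}


@dataclass(frozen=True)
class MiRnaSite:
    mirna_id: str
    position: int  # 1-based UTR position of the 5'-most paired base
    seed_length: int
    score: float


def _pair_energy(b1: str, b2: str, energies: Mapping[str, float]) -> float | None:
    """Energy of pairing UTR base b1 with miRNA base b2 (both DNA
    alphabet, miRNA given 5'->3' with T for U); None if unpaired."""
    key = "".join(sorted((b1, b2)))
    if key in ("CG", "GC"):
        return energies["GC"]
    if key in ("AT", "TA"):
        return energies["AT"]
    if key in ("GT", "TG"):
        return energies.get("GT")
    return None


def mirna_site_scan(
    utr_seq: str,
    mirnas: Mapping[str, str],
    energy_threshold: float = -10.0,
    pair_energies: Mapping[str, float] | None = None,
) -> list[MiRnaSite]:
    """Scan a 3'UTR (sense strand) for miRNA recognition sites.

    A candidate site requires perfect Watson-Crick complementarity of
    the miRNA seed (positions 2-8; G:U disallowed in the seed).  The
    duplex is extended to the maximal contiguous run of paired bases
    (G:U allowed outside the seed) and scored as the sum of per-pair
    energies; a site is reported iff score <= ``energy_threshold``.
    """
    energies = dict(pair_energies or DEFAULT_PAIR_ENERGIES)
    utr = utr_seq.upper().replace("U", "T")
    if not set(utr) <= _DNA:
        raise ValueError("non-nucleotide characters in UTR")
    sites = []
    for mid, mseq in mirnas.items():
        m = mseq.upper().replace("U", "T")
        if len(m) < 8:
            raise ValueError(f"miRNA {mid} shorter than 8 nt")
        if not set(m) <= _DNA:
            raise ValueError(f"non-nucleotide characters in miRNA {mid}")
        seed = m[1:8]  # positions 2-8, 5'->3'
        target = reverse_complement(seed)
        start = 0
        while True:
            hit = utr.find(target, start)
            if hit < 0:
                break
            start = hit + 1
            score, first = _score_site(utr, m, hit, energies)
            if score <= energy_threshold:
                sites.append(MiRnaSite(mid, first + 1, len(seed), score))
    return sites


def _score_site(
    utr: str, mirna: str, seed_hit: int, energies: Mapping[str, float]
) -> tuple[float, int]:
    """Score the maximal contiguous duplex anchored at a seed match.

    ``seed_hit`` is the 0-based UTR index where the reverse complement
    of the seed begins.  The miRNA pairs antiparallel: miRNA position k
    (1-based, 5'->3') pairs with UTR index seed_hit + 8 - 1 - k.
    Returns (score, 0-based UTR index of the 5'-most paired base).
    """

    def utr_index(k: int) -> int:
        return seed_hit + 8 - k  # k=2..8 span the seed match, k>8 extends 5'

    # seed pairs (k = 2..8) are guaranteed Watson-Crick by construction
    score = 0.0
    for k in range(2, 9):
        e = _pair_energy(utr[utr_index(k)], mirna[k - 1], energies)
        score += e if e is not None else 0.0
    first = utr_index(8)
    # extend toward the miRNA 3' end (k = 9, 10, ...): UTR 5' direction
    for k in range(9, len(mirna) + 1):
        j = utr_index(k)
        if j < 0:
            break
        e = _pair_energy(utr[j], mirna[k - 1], energies)
        if e is None:
            break
        score += e
        first = j
    # extend at miRNA position 1 (UTR 3' direction)
    j = utr_index(1)
    if 0 <= j < len(utr):
        e = _pair_energy(utr[j], mirna[0], energies)
        if e is not None:
            score += e
    return score, first


def scan_mirna_delta(
    ref_utr: str,
    alt_utr: str,
    mirnas: Mapping[str, str],
    energy_threshold: float = -10.0,
    pair_energies: Mapping[str, float] | None = None,
) -> dict[str, list[str]]:
    """miRNA ids whose reported site count increases (gain) or
    decreases (loss) between the reference and alternate UTR."""

    def counts(seq: str) -> dict[str, int]:
        out: dict[str, int] = {}
        for site in mirna_site_scan(seq, mirnas, energy_threshold, pair_energies):
            out[site.mirna_id] = out.get(site.mirna_id, 0) + 1
        return out

    ref_counts, alt_counts = counts(ref_utr), counts(alt_utr)
    ids = sorted(set(ref_counts) | set(alt_counts))
    gains = [m for m in ids if alt_counts.get(m, 0) > ref_counts.get(m, 0)]
    losses = [m for m in ids if alt_counts.get(m, 0) < ref_counts.get(m, 0)]
    return {"gain": gains, "loss": losses}


# ---------------------------------------------------------------------------
# summaries / IO


def summarize_variants(variants: Sequence[Variant]) -> dict:
    """Deterministic bookkeeping over annotated variant records."""
    by_type: dict[str, int] = {}
    by_region: dict[str, int] = {}
    by_function: dict[str, int] = {}
    novel = 0
    for v in variants:
        by_type[v.type] = by_type.get(v.type, 0) + 1
        if v.region:
            by_region[v.region] = by_region.get(v.region, 0) + 1
        if v.function:
            by_function[v.function] = by_function.get(v.function, 0) + 1
        if v.novel:
            novel += 1
    return {
        "total": len(variants),
        "by_type": by_type,
        "by_region": by_region,
        "by_function": by_function,
        "novel": novel,
    }


def write_vcf(
    variants: Sequence[Variant], chrom: str, path: str, ref_seq: str | None = None
) -> None:
    """Minimal VCF output (CHROM/POS/ID/REF/ALT/INFO).

    Empty alleles are written as ``-`` (Table-style) since no anchor
    base resolution is attempted without a reference.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(
            '##INFO=<ID=TYPE,Number=1,Type=String,Description="SNP/INS/DEL">\n'
        )
        fh.write(
            '##INFO=<ID=REGION,Number=1,Type=String,Description="gene region">\n'
        )
        fh.write(
            '##INFO=<ID=EFFECT,Number=1,Type=String,Description="coding effect">\n'
        )
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in sorted(variants, key=lambda x: x.pos):
            info = [f"TYPE={v.type}"]
            if v.region:
                info.append(f"REGION={v.region}")
            if v.effect:
                info.append(f"EFFECT={v.effect}")
            fh.write(
                f"{chrom}\t{v.pos}\t{v.known_id or '.'}\t{v.ref}\t{v.alt}"
                f"\t.\t.\t{';'.join(info)}\n"
            )
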