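"""Transcript models and variant consequence calling.

Maps genomic positions to coding-DNA (c.) coordinates, classifies variants
into the functional classes the cascade filters on (stopgain, missense,
synonymous, frameshift, inframe indel, splicing, intronic, UTR, intergenic),
and produces HGVS-lite c./p. strings: ``c.N``, ``c.N±offset``, ``c.NdelX``,
``p.X###*``, ``p.X###Yfs*N``.  One canonical transcript per gene.

Conventions: genomic coordinates 1-based inclusive on the forward strand;
cds_pos counts along the coding strand starting at the A of the start codon;
intronic offsets follow HGVS (positive after a donor, negative before an
acceptor, anchored at the nearest exonic coding base).
"""

from __future__ import annotations

import bisect
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.Seq import Seq

from .io_formats import VariantRecord

STOP_CODONS = {"TAA", "TAG", "TGA"}

#: Standard genetic code as a plain dict (stops map to "*").
GENETIC_CODE: dict[str, str] = dict(unambiguous_dna_by_id[1].forward_table)
GENETIC_CODE.update({codon: "*" for codon in STOP_CODONS})

NON_STOP_CODONS = tuple(sorted(c for c in GENETIC_CODE if GENETIC_CODE[c] != "*"))

EXONIC_CODING_CLASSES = {
    "stopgain", "missense", "synonymous",
    "frameshift_deletion", "frameshift_insertion", "inframe_indel",
}
ALL_CLASSES = EXONIC_CODING_CLASSES | {"splicing", "intronic", "UTR5", "UTR3", "intergenic"}


class CoordinateError(ValueError):
    """Position outside the transcript span (plus flank)."""


def translate_codon(codon: str) -> str:
    return GENETIC_CODE[codon.upper()]


def translate_cds(seq: str) -> str:
    """Translate a coding sequence (stops as ``*``); via Biopython."""
    return str(Seq(seq).translate())


@dataclass(frozen=True)
class CdnaCoordinate:
    """A coding-DNA coordinate: position within the CDS plus an intronic offset.

    ``c.21-94`` is ``CdnaCoordinate(21, -94)``; exonic coding positions have
    offset 0.  ``region`` distinguishes coding from UTR anchors.
    """

    cds_pos: int
    intron_offset: int = 0
    region: str = "coding"  # coding | utr5 | utr3

    def __str__(self) -> str:
        if self.region == "utr5":
            base = f"-{self.cds_pos}"
        elif self.region == "utr3":
            base = f"*{self.cds_pos}"
        else:
            base = str(self.cds_pos)
        if self.intron_offset == 0:
            return f"c.{base}"
        sign = "+" if self.intron_offset > 0 else "-"
        return f"c.{base}{sign}{abs(self.intron_offset)}"


@dataclass(frozen=True)
class ConsequenceCall:
    functional_class: str
    cdna: CdnaCoordinate | None = None
    codon: int | None = None
    protein_change: str | None = None
    cdna_change: str | None = None

    def __post_init__(self) -> None:
        if self.functional_class not in ALL_CLASSES:
            raise ValueError(f"unknown functional class {self.functional_class!r}")


@dataclass
class TranscriptModel:
    """One canonical transcript: exon structure, CDS bounds, CDS sequence.

    ``exons`` are 1-based inclusive genomic intervals sorted by genomic
    position regardless of strand; ``cds_sequence`` (optional) is the spliced
    coding sequence read along the coding strand.
    """

    transcript_id: str
    gene: str
    chrom: str
    strand: str  # "+" or "-"
    exons: list[tuple[int, int]]
    cds_start: int  # genomic lower bound of coding region
    cds_end: int    # genomic upper bound of coding region
    cds_sequence: str | None = None
    utr3_sequence: str = ""  # read-through sequence for frameshift resolution

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if not (s1 <= e1 < s2 <= e2):
                raise ValueError(f"{self.transcript_id}: exons unsorted or overlapping")
        if not any(s <= self.cds_start <= e for s, e in self.exons):
            raise ValueError(f"{self.transcript_id}: cds_start not inside an exon")
        if not any(s <= self.cds_end <= e for s, e in self.exons):
            raise ValueError(f"{self.transcript_id}: cds_end not inside an exon")
        if self.cds_sequence is not None:
            seq = self.cds_sequence.upper()
            if len(seq) != self.cds_length:
                raise ValueError(
                    f"{self.transcript_id}: CDS sequence length {len(seq)} != "
                    f"coding-exon overlap {self.cds_length}"
                )
            if len(seq) % 3 != 0:
                raise ValueError(f"{self.transcript_id}: CDS length not a multiple of 3")
            if not seq.startswith("ATG"):
                raise ValueError(f"{self.transcript_id}: CDS does not start with ATG")
            if seq[-3:] not in STOP_CODONS:
                raise ValueError(f"{self.transcript_id}: CDS does not end with a stop codon")
            self.cds_sequence = seq

    # -- derived structure -------------------------------------------------

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    def coding_intervals(self) -> list[tuple[int, int]]:
        """Genomic intervals of the coding parts of each exon, sorted."""
        out = []
        for s, e in self.exons:
            lo, hi = max(s, self.cds_start), min(e, self.cds_end)
            if lo <= hi:
                out.append((lo, hi))
        return out

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.coding_intervals())

    @property
    def protein_length(self) -> int:
        """Residues encoded, excluding the stop codon."""
        return self.cds_length // 3 - 1

    def contains(self, gpos: int) -> bool:
        lo, hi = self.span
        return lo <= gpos <= hi

    def exon_index_at(self, gpos: int) -> int | None:
        """0-based index of the exon containing gpos, or None (intronic/outside)."""
        starts = [s for s, _ in self.exons]
        i = bisect.bisect_right(starts, gpos) - 1
        if i >= 0 and self.exons[i][0] <= gpos <= self.exons[i][1]:
            return i
        return None

    # -- coordinate mapping ------------------------------------------------

    def _coding_offset(self, gpos: int) -> int | None:
        """1-based offset of gpos within the spliced coding region counted
        along the *forward* strand, or None if not exonic-coding."""
        total = 0
        for lo, hi in self.coding_intervals():
            if lo <= gpos <= hi:
                return total + (gpos - lo + 1)
            total += hi - lo + 1
        return None

    def _forward_to_cds(self, fwd_offset: int) -> int:
        return fwd_offset if self.strand == "+" else self.cds_length - fwd_offset + 1

    def genomic_to_cdna(self, gpos: int, flank: int = 5000) -> CdnaCoordinate:
        """Map a genomic position to a :class:`CdnaCoordinate`.

        Exonic coding positions map to (cds_pos, 0).  Intronic positions are
        anchored at the nearest exon edge, HGVS style: the first half of the
        intron takes a positive offset from the preceding (donor-side) exonic
        base, the second half a negative offset from the first base of the
        following exon.  Exonic non-coding positions map into the UTRs.
        """
        lo, hi = self.span
        if not (lo - flank <= gpos <= hi + flank):
            raise CoordinateError(
                f"{self.transcript_id}: position {gpos} outside transcript span "
                f"{lo}-{hi} (+/- {flank})"
            )
        exon_i = self.exon_index_at(gpos)
        if exon_i is not None:
            fwd = self._coding_offset(gpos)
            if fwd is not None:
                return CdnaCoordinate(self._forward_to_cds(fwd), 0, "coding")
            return self._utr_coordinate(gpos)
        # intronic (or flanking): nearest exon edges
        return self._intronic_coordinate(gpos)

    def _utr_coordinate(self, gpos: int) -> CdnaCoordinate:
        # exonic, outside CDS: count exonic bases to the nearest CDS end
        if gpos < self.cds_start:
            dist = self._exonic_distance(gpos, self.cds_start)
            region = "utr5" if self.strand == "+" else "utr3"
        else:
            dist = self._exonic_distance(self.cds_end, gpos)
            region = "utr3" if self.strand == "+" else "utr5"
        return CdnaCoordinate(dist, 0, region)

    def _exonic_distance(self, g1: int, g2: int) -> int:
        """Number of exonic bases strictly between g1 and g2 plus... counts
        exonic bases in (g1, g2] ∩ exons when walking from g1 to g2."""
        n = 0
        for s, e in self.exons:
            lo, hi = max(s, g1 + 1), min(e, g2)
            if lo <= hi:
                n += hi - lo + 1
        return n

    def _intronic_coordinate(self, gpos: int) -> CdnaCoordinate:
        prev_exon = next_exon = None
        for i, (s, e) in enumerate(self.exons):
            if e < gpos:
                prev_exon = (s, e)
            if s > gpos and next_exon is None:
                next_exon = (s, e)
        if prev_exon is None or next_exon is None:
            # flanking the transcript: anchor at the terminal exon edge
            if prev_exon is None:
                anchor_g, offset = self.exons[0][0], gpos - self.exons[0][0]
            else:
                anchor_g, offset = self.exons[-1][1], gpos - self.exons[-1][1]
        else:
            d_donor = gpos - prev_exon[1]       # distance past the upstream exon end
            d_acceptor = next_exon[0] - gpos    # distance before the downstream exon start
            if d_donor <= d_acceptor:
                anchor_g, offset = prev_exon[1], d_donor
            else:
                anchor_g, offset = next_exon[0], -d_acceptor
        anchor = self.genomic_to_cdna(anchor_g)
        if self.strand == "-":
            offset = -offset
        return CdnaCoordinate(anchor.cds_pos, offset, anchor.region)

    def cdna_to_genomic(self, coord: CdnaCoordinate) -> int:
        """Inverse of :meth:`genomic_to_cdna` for coding anchors."""
        if coord.region != "coding":
            raise CoordinateError("cdna_to_genomic supports coding-region anchors only")
        fwd = coord.cds_pos if self.strand == "+" else self.cds_length - coord.cds_pos + 1
        total = 0
        gpos = None
        for lo, hi in self.coding_intervals():
            n = hi - lo + 1
            if total < fwd <= total + n:
                gpos = lo + (fwd - total - 1)
                break
            total += n
        if gpos is None:
            raise CoordinateError(f"cds_pos {coord.cds_pos} beyond CDS length {self.cds_length}")
        offset = coord.intron_offset if self.strand == "+" else -coord.intron_offset
        return gpos + offset

    # -- sequence access ---------------------------------------------------

    def cds_base(self, cds_pos: int) -> str:
        if self.cds_sequence is None:
            raise ValueError(f"{self.transcript_id}: no CDS sequence attached")
        return self.cds_sequence[cds_pos - 1]

    def codon_at(self, codon_number: int) -> str:
        start = (codon_number - 1) * 3
        return self.cds_sequence[start:start + 3]


# ---------------------------------------------------------------------------
# Codon arithmetic
# ---------------------------------------------------------------------------

def codon_index(cds_pos: int) -> int:
    """Codon number containing a 1-based coding position: ceil(cds_pos / 3).

    c.853 falls in codon 285; c.541 in codon 181; c.518 in codon 173.
    """
    if cds_pos < 1:
        raise ValueError(f"cds_pos must be >= 1, got {cds_pos}")
    return (cds_pos + 2) // 3


def truncated_tail_length(protein_length: int, stop_codon: int) -> int:
    """Residues lost when a premature stop replaces residue ``stop_codon`` of
    a ``protein_length``-residue protein (the replaced residue counts as lost)."""
    if not 1 <= stop_codon <= protein_length:
        raise ValueError(
            f"stop codon {stop_codon} outside protein of length {protein_length}"
        )
    return protein_length - stop_codon + 1


# ---------------------------------------------------------------------------
# Frameshift resolution
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FrameshiftResult:
    """Outcome of translating the shifted reading frame.

    ``stop_offset`` is N in p.X###Yfs*N — the position of the new stop in the
    shifted frame, counting the first altered codon as 1; None when no stop is
    reachable in the provided sequence (named fs*?).  ``stop_at_first`` marks
    the degenerate case where the first altered codon is itself a stop, which
    HGVS names as plain nonsense p.X###*.
    """

    first_codon: int
    first_new_aa: str | None
    stop_offset: int | None
    stop_at_first: bool


def frameshift_new_stop_offset(
    model: TranscriptModel, cds_pos: int, ref: str, alt: str
) -> FrameshiftResult:
    """Translate the shifted frame of an indel at ``cds_pos`` until a stop.

    ``ref``/``alt`` are the normalized alleles in coding-strand orientation,
    VCF anchor-base style for indels (e.g. ref "AT" alt "A" deletes the base
    *after* cds_pos).  The search extends through the 3'UTR read-through
    sequence if the model provides one.
    """
    if model.cds_sequence is None:
        raise ValueError("frameshift resolution needs a CDS sequence")
    seq = model.cds_sequence + model.utr3_sequence.upper()
    mutated = apply_coding_edit(seq, cds_pos, ref, alt)
    # first codon whose bases change under the shift
    edit_at = cds_pos + 1 if _is_anchor_style(ref, alt) else cds_pos
    first_codon = codon_index(edit_at)
    start = (first_codon - 1) * 3
    offset = 0
    first_new_aa = None
    while start + 3 <= len(mutated):
        codon = mutated[start:start + 3]
        offset += 1
        if offset == 1:
            first_new_aa = "*" if codon in STOP_CODONS else translate_codon(codon)
        if codon in STOP_CODONS:
            return FrameshiftResult(first_codon, first_new_aa, offset, stop_at_first=offset == 1)
        start += 3
    return FrameshiftResult(first_codon, first_new_aa, None, stop_at_first=False)


def _is_anchor_style(ref: str, alt: str) -> bool:
    return len(ref) != len(alt) and ref[0] == alt[0]


def apply_coding_edit(seq: str, cds_pos: int, ref: str, alt: str) -> str:
    """Apply a ref->alt edit anchored at 1-based cds_pos to a coding-strand
    sequence and return the mutated sequence."""
    i = cds_pos - 1
    if seq[i:i + len(ref)] != ref.upper():
        raise ValueError(
            f"reference mismatch at cds_pos {cds_pos}: expected {ref}, "
            f"found {seq[i:i + len(ref)]}"
        )
    return seq[:i] + alt.upper() + seq[i + len(ref):]


# ---------------------------------------------------------------------------
# Consequence calling
# ---------------------------------------------------------------------------

def call_consequence(
    variant: VariantRecord, model: TranscriptModel, splice_window: int = 2
) -> ConsequenceCall:
    """Classify one normalized variant against one transcript model.

    Order of precedence: splice-window intronic positions are ``splicing``;
    exonic coding SNVs are translated (stopgain/missense/synonymous); coding
    indels are frameshift or inframe by length arithmetic; exonic non-coding
    is UTR5/UTR3; deeper intronic keeps its offset coordinate; everything
    outside the transcript span is ``intergenic``.
    """
    if variant.chrom != model.chrom:
        raise CoordinateError(
            f"variant on {variant.chrom} vs model on {model.chrom}"
        )
    # position actually affected (anchor-base convention for indels)
    affected_g = variant.pos + 1 if _is_anchor_style(variant.ref, variant.alt) else variant.pos
    if not model.contains(affected_g):
        return ConsequenceCall("intergenic")

    exon_i = model.exon_index_at(affected_g)
    if exon_i is None:
        coord = model.genomic_to_cdna(affected_g)
        if abs(coord.intron_offset) <= splice_window:
            return ConsequenceCall("splicing", cdna=coord, cdna_change=_cdna_change(coord, variant, model))
        return ConsequenceCall("intronic", cdna=coord, cdna_change=_cdna_change(coord, variant, model))

    coord = model.genomic_to_cdna(affected_g)
    if coord.region == "utr5":
        return ConsequenceCall("UTR5", cdna=coord)
    if coord.region == "utr3":
        return ConsequenceCall("UTR3", cdna=coord)

    if variant.is_snv:
        return _call_coding_snv(variant, model, coord)
    return _call_coding_indel(variant, model, coord)


def _strand_allele(model: TranscriptModel, allele: str) -> str:
    return allele if model.strand == "+" else str(Seq(allele).reverse_complement())


def _cdna_change(coord: CdnaCoordinate, variant: VariantRecord, model: TranscriptModel) -> str:
    ref = _strand_allele(model, variant.ref)
    alt = _strand_allele(model, variant.alt)
    if len(ref) == 1 == len(alt):
        return f"{coord}{ref}>{alt}"
    if len(ref) > len(alt) and variant.ref[0] == variant.alt[0]:
        deleted = _strand_allele(model, variant.ref[1:])
        return f"{coord}del{deleted}"
    return f"{coord}{ref}>{alt}"


def _call_coding_snv(
    variant: VariantRecord, model: TranscriptModel, coord: CdnaCoordinate
) -> ConsequenceCall:
    codon_n = codon_index(coord.cds_pos)
    cdna_change = _cdna_change(coord, variant, model)
    if model.cds_sequence is None:
        warnings.warn(
            f"{model.transcript_id}: no CDS sequence; coding SNV at {coord} "
            "classified as missense without protein naming"
        )
        return ConsequenceCall("missense", cdna=coord, codon=codon_n, cdna_change=cdna_change)
    alt_base = _strand_allele(model, variant.alt)
    ref_base = model.cds_base(coord.cds_pos)
    expected_ref = _strand_allele(model, variant.ref)
    if ref_base != expected_ref:
        raise ValueError(
            f"{model.transcript_id}: reference mismatch at {coord} "
            f"(model {ref_base}, variant {expected_ref})"
        )
    within = (coord.cds_pos - 1) % 3
    ref_codon = model.codon_at(codon_n)
    alt_codon = ref_codon[:within] + alt_base + ref_codon[within + 1:]
    ref_aa = translate_codon(ref_codon)
    alt_aa = translate_codon(alt_codon)
    if alt_aa == "*" and ref_aa != "*":
        cls, protein = "stopgain", f"p.{ref_aa}{codon_n}*"
    elif alt_aa == ref_aa:
        cls, protein = "synonymous", f"p.{ref_aa}{codon_n}="
    else:
        cls, protein = "missense", f"p.{ref_aa}{codon_n}{alt_aa}"
    return ConsequenceCall(cls, cdna=coord, codon=codon_n, protein_change=protein, cdna_change=cdna_change)


def _call_coding_indel(
    variant: VariantRecord, model: TranscriptModel, coord: CdnaCoordinate
) -> ConsequenceCall:
    delta = len(variant.alt) - len(variant.ref)
    cdna_change = _cdna_change(coord, variant, model)
    if delta % 3 == 0:
        codon_n = codon_index(coord.cds_pos + (1 if _is_anchor_style(variant.ref, variant.alt) else 0))
        return ConsequenceCall("inframe_indel", cdna=coord, codon=codon_n, cdna_change=cdna_change)
    cls = "frameshift_deletion" if delta < 0 else "frameshift_insertion"
    if model.cds_sequence is None:
        warnings.warn(
            f"{model.transcript_id}: no CDS sequence; frameshift at {coord} "
            "reported without protein naming"
        )
        return ConsequenceCall(cls, cdna=coord, codon=codon_index(coord.cds_pos), cdna_change=cdna_change)
    ref_cs = _strand_allele(model, variant.ref)
    alt_cs = _strand_allele(model, variant.alt)
    # cds position of the first base of the coding-strand ref allele: the VCF
    # anchor base on +, the genomically-last ref base on -
    anchor_g = variant.pos if model.strand == "+" else variant.pos + len(variant.ref) - 1
    anchor = model.genomic_to_cdna(anchor_g)
    if anchor.region != "coding" or anchor.intron_offset != 0:
        warnings.warn(
            f"{model.transcript_id}: indel at {variant.key_str} straddles a coding "
            "boundary; reported without protein naming"
        )
        return ConsequenceCall(cls, cdna=coord, codon=codon_index(coord.cds_pos), cdna_change=cdna_change)
    fs = frameshift_new_stop_offset(model, anchor.cds_pos, ref_cs, alt_cs)
    ref_aa = translate_codon(model.codon_at(fs.first_codon))
    if fs.stop_at_first:
        protein = f"p.{ref_aa}{fs.first_codon}*"
    elif fs.stop_offset is None:
        protein = f"p.{ref_aa}{fs.first_codon}{fs.first_new_aa}fs*?"
    else:
        protein = f"p.{ref_aa}{fs.first_codon}{fs.first_new_aa}fs*{fs.stop_offset}"
    return ConsequenceCall(cls, cdna=coord, codon=fs.first_codon, protein_change=protein, cdna_change=cdna_change)


# ---------------------------------------------------------------------------
# Gene-model I/O (simplified TSV + FASTA dialect)
# ---------------------------------------------------------------------------

def load_gene_models(tsv_path: str | Path, fasta_path: str | Path | None = None) -> list[TranscriptModel]:
    """Load transcript models from a 7-column TSV, optionally attaching CDS
    sequences from a FASTA keyed by transcript id.

    Columns: transcript_id, gene, chrom, strand, exons (``start-end`` joined
    by ``,``), cds_start, cds_end.  A FASTA record ``>id|utr3`` supplies the
    3'UTR read-through sequence for frameshift naming.
    """
    sequences: dict[str, str] = {}
    if fasta_path is not None:
        from Bio import SeqIO

        for rec in SeqIO.parse(str(fasta_path), "fasta"):
            sequences[rec.id] = str(rec.seq).upper()

    models = []
    for line in Path(tsv_path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("transcript_id\t"):
            continue
        tid, gene, chrom, strand, exon_s, cds_start, cds_end = line.split("\t")
        exons = []
        for span in exon_s.split(","):
            s, e = span.split("-")
            exons.append((int(s), int(e)))
        models.append(
            TranscriptModel(
                transcript_id=tid,
                gene=gene,
                chrom=chrom,
                strand=strand,
                exons=exons,
                cds_start=int(cds_start),
                cds_end=int(cds_end),
                cds_sequence=sequences.get(tid),
                utr3_sequence=sequences.get(f"{tid}|utr3", ""),
            )
        )
    return models


def write_gene_models(models: Sequence[TranscriptModel], tsv_path: str | Path, fasta_path: str | Path) -> None:
    lines = ["transcript_id\tgene\tchrom\tstrand\texons\tcds_start\tcds_end"]
    fasta: list[str] = []
    for m in models:
        exon_s = ",".join(f"{s}-{e}" for s, e in m.exons)
        lines.append(f"{m.transcript_id}\t{m.gene}\t{m.chrom}\t{m.strand}\t{exon_s}\t{m.cds_start}\t{m.cds_end}")
        if m.cds_sequence:
            fasta.append(f">{m.transcript_id}\n{m.cds_sequence}")
        if m.utr3_sequence:
            fasta.append(f">{m.transcript_id}|utr3\n{m.utr3_sequence}")
    Path(tsv_path).write_text("\n".join(lines) + "\n")
    Path(fasta_path).write_text("\n".join(fasta) + ("\n" if fasta else ""))


# ---------------------------------------------------------------------------
# MAD2L1BP fixture transcript (synthetic reconstruction)
# ---------------------------------------------------------------------------

def mad2l1bp_transcript() -> TranscriptModel:
    """A synthetic reconstruction of the MAD2L1BP canonical transcript
    (NM_001003690) used as a test fixture.

    The exon layout and CDS content are *constrained*, not copied: they are
    chosen so that every published anchor holds — the four (genomic, cDNA)
    coordinate pairs Chr6:43608202/c.853, 43607890/c.541, 43607867/c.518 and
    43600837/c.21-94; a 306-residue protein (921 bp CDS); all three coding
    variants inside exon 4; c.21 as the first base of exon 2 (implied by the
    c.21-94 acceptor offset); reference codons CGA (Arg) at codons 285 and
    181 so that C>T yields p.R285* / p.R181*; and TTC (Phe) at codon 173 with
    downstream context making a 1-bp deletion of c.518 read through S-L-G to
    a stop at the 4th shifted codon (p.F173Sfs*4).  Sequence between the
    constrained codons is synthetic filler (non-stop codons) and carries no
    biological meaning.
    """
    n_codons = 307  # 306 residues + stop
    codons = ["GCT"] * n_codons  # Ala filler, never a stop
    codons[0] = "ATG"
    codons[172] = "TTC"  # F173 — c.518 is the middle T
    codons[173] = "GCT"
    codons[174] = "AGG"
    codons[175] = "CTA"  # shifted frame reads TCG|CTA|GGC|TAA after delT
    codons[176] = "AAA"
    codons[180] = "CGA"  # R181 — c.541C>T -> TGA
    codons[284] = "CGA"  # R285 — c.853C>T -> TGA
    codons[306] = "TAA"
    cds = "".join(codons)
    assert len(cds) == 921

    # Exon layout anchored to the Table-3-style coordinates:
    #   c.1  = 43600701 (exon 1, after a 5'UTR), c.20 = exon 1 end
    #   c.21 = 43600931 (exon 2 first base; the deep-intronic variant sits
    #          94 bp upstream at 43600837)
    #   exon 4 coding spans c.341-c.921 so that c.518 -> 43607867,
    #          c.541 -> 43607890, c.853 -> 43608202
    return TranscriptModel(
        transcript_id="NM_001003690",
        gene="MAD2L1BP",
        chrom="chr6",
        strand="+",
        exons=[
            (43600500, 43600720),  # exon 1: 5'UTR + c.1-20
            (43600931, 43601070),  # exon 2: c.21-160
            (43603000, 43603179),  # exon 3: c.161-340
            (43607690, 43608470),  # exon 4: c.341-921 + 3'UTR
        ],
        cds_start=43600701,
        cds_end=43608270,
        cds_sequence=cds,
        utr3_sequence="GCTGCTGCTGCTTAA",
    )
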