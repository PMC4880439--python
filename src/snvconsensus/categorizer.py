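"""Five-way SNV categorization from gene models and reference sequence.

Every SNV is assigned exactly one of five categories:

* ``nonsense``   — coding substitution creating a premature stop codon
* ``missense``   — coding substitution changing the encoded amino acid
* ``splicing``   — intronic position within ``splice_window`` bp (default 2,
  the canonical splice dinucleotide) of an exon boundary
* ``synonymous`` — coding substitution leaving the amino acid unchanged
* ``regulatory`` — everything else: intergenic, deep intronic, UTR,
  up/downstream and non-coding-gene positions

When overlapping transcripts disagree, the most severe consequence wins:
nonsense > missense > splicing > synonymous > regulatory.  Start-loss and
stop-loss substitutions have no category of their own and fall out of the
codon comparison as missense.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

from Bio.Data import CodonTable
from Bio.Seq import Seq

from .core_io import CATEGORIES, DataIntegrityError, Variant, normalize_chrom

logger = logging.getLogger(__name__)

DEFAULT_SPLICE_WINDOW = 2

_SEVERITY = {"regulatory": 0, "synonymous": 1, "splicing": 2,
             "missense": 3, "nonsense": 4}


@dataclass
class TranscriptModel:
    """A transcript as sorted 1-based closed exon and CDS intervals."""

    id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]]
    codon_table: str = "Standard"
    _cds_seq_cache: Optional[str] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        self.exons = sorted((int(a), int(b)) for a, b in self.exons)
        self.cds = sorted((int(a), int(b)) for a, b in self.cds)
        for ivals in (self.exons, self.cds):
            for (a, b), (c, d) in zip(ivals, ivals[1:]):
                if c <= b:
                    raise ValueError(f"overlapping intervals in transcript {self.id}")
        if self.cds_length % 3 != 0:
            raise ValueError(
                f"CDS length {self.cds_length} of transcript {self.id} "
                f"not divisible by 3"
            )

    @property
    def cds_length(self) -> int:
        return sum(b - a + 1 for a, b in self.cds)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    def cds_offset(self, pos: int) -> Optional[int]:
        """0-based offset of *pos* in the forward-concatenated CDS, or None."""
        off = 0
        for a, b in self.cds:
            if a <= pos <= b:
                return off + (pos - a)
            off += b - a + 1
        return None

    def in_exon(self, pos: int) -> bool:
        return any(a <= pos <= b for a, b in self.exons)

    def intron_boundary_distance(self, pos: int) -> Optional[int]:
        """For an intronic *pos*, distance in bp to the nearest exon boundary;
        None if *pos* is not inside an intron of this transcript."""
        lo, hi = self.span
        if not (lo <= pos <= hi) or self.in_exon(pos):
            return None
        best = None
        for (a1, b1), (a2, b2) in zip(self.exons, self.exons[1:]):
            if b1 < pos < a2:
                best = min(pos - b1, a2 - pos)
        return best

    def cds_sequence(self, ref_seq) -> str:
        """Spliced CDS in coding (5'->3') orientation."""
        if self._cds_seq_cache is None:
            parts = [fetch_sequence(ref_seq, self.chrom, a, b) for a, b in self.cds]
            seq = "".join(parts)
            if self.strand == "-":
                seq = str(Seq(seq).reverse_complement())
            self._cds_seq_cache = seq
        return self._cds_seq_cache


@dataclass
class CategoryCall:
    """Category assignment with a human-readable rationale."""

    category: str
    detail: str = ""
    transcript_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


# ---------------------------------------------------------------------------
# Reference sequence access


def fetch_sequence(ref_seq, chrom: str, start: int, end: int) -> str:
    """Fetch [start, end] (1-based, closed) from a pyfaidx Fasta or a
    plain mapping of chromosome name -> sequence string."""
    want = normalize_chrom(chrom)
    if isinstance(ref_seq, Mapping):
        for name, seq in ref_seq.items():
            if normalize_chrom(name) == want:
                return str(seq[start - 1: end]).upper()
        raise KeyError(f"chromosome {chrom!r} not in reference")
    # pyfaidx.Fasta
    for name in ref_seq.keys():
        if normalize_chrom(name) == want:
            return str(ref_seq[name][start - 1: end]).upper()
    raise KeyError(f"chromosome {chrom!r} not in reference")


# ---------------------------------------------------------------------------
# Gene model input


def _detect_gtf(path: str) -> bool:
    if path.endswith((".gtf", ".gtf.gz")):
        return True
    if path.endswith((".gff", ".gff3", ".gff.gz", ".gff3.gz")):
        return False
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            attrs = line.rstrip("\n").split("\t")[-1]
            return "=" not in attrs.split(";")[0]
    return False


def read_gene_models(path: str, fasta=None) -> list[TranscriptModel]:
    """Read transcript models from GFF3 or GTF via :mod:`gffutils`.

    One :class:`TranscriptModel` per mRNA/transcript feature; transcripts
    whose total CDS length is not divisible by 3 are dropped with a
    warning.  If *fasta* is given, transcripts referencing chromosomes
    absent from it raise :class:`DataIntegrityError`.
    """
    import gffutils

    is_gtf = _detect_gtf(path)
    db = gffutils.create_db(
        path, ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=is_gtf, disable_infer_transcripts=is_gtf,
    )
    if fasta is not None:
        known = {normalize_chrom(k) for k in
                 (fasta.keys() if not isinstance(fasta, Mapping) else fasta)}
    models: list[TranscriptModel] = []
    for ftype in ("mRNA", "transcript"):
        for tx in db.features_of_type(ftype):
            exons = [(f.start, f.end) for f in db.children(tx, featuretype="exon")]
            cds = [(f.start, f.end) for f in db.children(tx, featuretype="CDS")]
            if not exons and not cds:
                continue
            if not exons:
                exons = list(cds)
            if fasta is not None and normalize_chrom(tx.seqid) not in known:
                raise DataIntegrityError(
                    f"transcript {tx.id} references chromosome {tx.seqid!r} "
                    f"absent from the reference FASTA"
                )
            cds_len = sum(b - a + 1 for a, b in cds)
            if cds and cds_len % 3 != 0:
                logger.warning(
                    "dropping transcript %s: CDS length %d not divisible by 3",
                    tx.id, cds_len,
                )
                continue
            models.append(TranscriptModel(
                id=tx.id, chrom=tx.seqid, strand=tx.strand,
                exons=exons, cds=cds,
            ))
    return models


# ---------------------------------------------------------------------------
# Classification

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _translate_codon(codon: str, table: str = "Standard") -> str:
    """One-letter amino acid, '*' for stop."""
    return str(Seq(codon).translate(table=table))


def _coding_call(tx: TranscriptModel, v: Variant, ref_seq) -> Optional[CategoryCall]:
    off = tx.cds_offset(v.pos)
    if off is None:
        return None
    cds_seq = tx.cds_sequence(ref_seq)
    if tx.strand == "-":
        idx = len(cds_seq) - 1 - off
        alt_base = v.alt.translate(_COMPLEMENT)
        ref_base = v.ref.translate(_COMPLEMENT)
    else:
        idx = off
        alt_base = v.alt
        ref_base = v.ref
    if cds_seq[idx] != ref_base:
        raise DataIntegrityError(
            f"CDS sequence of {tx.id} disagrees with reference at "
            f"{v.chrom}:{v.pos}"
        )
    codon_i, within = divmod(idx, 3)
    codon = cds_seq[codon_i * 3: codon_i * 3 + 3]
    alt_codon = codon[:within] + alt_base + codon[within + 1:]
    ref_aa = _translate_codon(codon, tx.codon_table)
    alt_aa = _translate_codon(alt_codon, tx.codon_table)
    detail = f"{ref_aa}{codon_i + 1}{alt_aa}"
    if alt_aa == ref_aa:
        return CategoryCall("synonymous", detail, tx.id)
    if alt_aa == "*":
        return CategoryCall("nonsense", detail, tx.id)
    return CategoryCall("missense", detail, tx.id)


def classify_variant(v: Variant, models: Sequence[TranscriptModel], ref_seq,
                     splice_window: int = DEFAULT_SPLICE_WINDOW) -> CategoryCall:
    """Assign one of the five categories to an SNV.

    The ref allele is checked against the reference sequence (mismatch
    raises :class:`DataIntegrityError`).  The most severe call across
    overlapping transcripts wins; positions outside every transcript, or
    exonic but non-coding, fall through to ``regulatory``.
    """
    genome_base = fetch_sequence(ref_seq, v.chrom, v.pos, v.pos)
    if genome_base != v.ref:
        raise DataIntegrityError(
            f"ref allele {v.ref} does not match reference base {genome_base} "
            f"at {v.chrom}:{v.pos}"
        )
    chrom = normalize_chrom(v.chrom)
    best = CategoryCall("regulatory", "intergenic", None)
    for tx in models:
        if normalize_chrom(tx.chrom) != chrom:
            continue
        call: Optional[CategoryCall] = None
        coding = _coding_call(tx, v, ref_seq)
        if coding is not None:
            call = coding
        else:
            dist = tx.intron_boundary_distance(v.pos)
            if dist is not None:
                if dist <= splice_window:
                    call = CategoryCall(
                        "splicing", f"intron, {dist} bp from exon boundary", tx.id)
                else:
                    call = CategoryCall("regulatory", "intronic", tx.id)
            elif tx.in_exon(v.pos):
                call = CategoryCall("regulatory", "non-coding exon/UTR", tx.id)
        if call is not None and _SEVERITY[call.category] > _SEVERITY[best.category]:
            best = call
    return best


def classify_all(variants: Sequence[Variant], models: Sequence[TranscriptModel],
                 ref_seq, splice_window: int = DEFAULT_SPLICE_WINDOW
                 ) -> list[CategoryCall]:
    """Vector version of :func:`classify_variant` (same precedence rules)."""
    return [classify_variant(v, models, ref_seq, splice_window) for v in variants]
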