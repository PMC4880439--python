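"""Synthetic inputs for every pipeline stage.

Two generators, both pure functions of their seed:

* :func:`simulate_scores` draws class-conditional Gaussian raw scores for a
  set of named tools with a one-knob equicorrelation structure, emulating
  the overlapping, category-specific score distributions real predictors
  show.  The default specification includes one label-independent noise
  tool, because real ensembles contain weak members that can drag a
  consensus down.
* :func:`simulate_genome` builds a miniature reference (FASTA + GFF3) of
  intron-containing protein-coding genes on both strands and plants
  variants of every category with truth guaranteed by whole-CDS
  retranslation, for end-to-end testing of the categorizer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from Bio.Seq import Seq

from .categorizer import TranscriptModel
from .core_io import (
    DELETERIOUS,
    HIGHER_IS_DELETERIOUS,
    LOWER_IS_DELETERIOUS,
    NEUTRAL,
    CATEGORIES,
    LabeledDataset,
    ScoreTable,
    ToolSpec,
    Variant,
)

# ---------------------------------------------------------------------------
# Score simulation


@dataclass(frozen=True)
class ClassParams:
    """Class-conditional score distribution for one (tool, category)."""

    d_mean: float
    d_sd: float
    n_mean: float
    n_sd: float

    def __post_init__(self) -> None:
        if self.d_sd <= 0 or self.n_sd <= 0:
            raise ValueError("standard deviations must be positive")


@dataclass
class ScoreSimSpec:
    """Specification of a synthetic score dataset.

    ``params`` maps (tool name, category) to :class:`ClassParams`;
    ``rho`` is the equicorrelation of the latent Gaussians across tools
    (one knob controlling inter-tool score correlation); ``n_per_class``
    variants are drawn per class per category and split into equal train
    and test halves.
    """

    tools: list[ToolSpec]
    categories: list[str]
    params: dict
    rho: float = 0.0
    n_per_class: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.rho < 1.0):
            raise ValueError("inter-tool correlation must lie in [0, 1)")
        for t in self.tools:
            for c in self.categories:
                if (t.name, c) not in self.params:
                    raise ValueError(f"missing class params for ({t.name}, {c})")


def default_spec(seed: int = 0, n_per_class: int = 500, rho: float = 0.3
                 ) -> ScoreSimSpec:
    """A realistic five-tool, five-category specification.

    Four informative tools of varying strength (one with inverted score
    orientation) and one label-independent noise tool.  Class means shift
    between categories so category-optimal thresholds genuinely beat a
    pooled threshold, mirroring how real predictors score regulatory and
    coding variants on different parts of their range.
    """
    tools = [
        ToolSpec("alpha", HIGHER_IS_DELETERIOUS),
        ToolSpec("beta", HIGHER_IS_DELETERIOUS),
        ToolSpec("gamma", LOWER_IS_DELETERIOUS),
        ToolSpec("delta", HIGHER_IS_DELETERIOUS),
        ToolSpec("noise", HIGHER_IS_DELETERIOUS),
    ]
    # per-category baseline shift of the score scale
    shift = {"regulatory": 0.30, "splicing": 0.10, "missense": 0.0,
             "synonymous": -0.10, "nonsense": 0.20}
    sep = {"alpha": 0.40, "beta": 0.30, "gamma": 0.25, "delta": 0.20,
           "noise": 0.0}
    params = {}
    for t in tools:
        for c in CATEGORIES:
            base = shift[c]
            d = sep[t.name]
            if t.polarity == LOWER_IS_DELETERIOUS:
                dm, nm = base - d / 2, base + d / 2
            else:
                dm, nm = base + d / 2, base - d / 2
            params[(t.name, c)] = ClassParams(dm, 0.15, nm, 0.15)
    return ScoreSimSpec(tools=tools, categories=list(CATEGORIES), params=params,
                        rho=rho, n_per_class=n_per_class, seed=seed)


def simulate_scores(spec: ScoreSimSpec
                    ) -> tuple[dict, ScoreTable]:
    """Draw the synthetic score dataset described by *spec*.

    Returns ``(datasets, table)`` where ``datasets[category]`` is a dict
    with ``"train"`` and ``"test"`` :class:`LabeledDataset` halves, and
    ``table`` is the combined :class:`ScoreTable` over all variants.
    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    n_tools = len(spec.tools)
    table = ScoreTable(spec.tools)
    datasets: dict[str, dict[str, LabeledDataset]] = {}
    pos_counter = 1000
    for ci, category in enumerate(spec.categories):
        variants: list[Variant] = []
        for label in (DELETERIOUS, NEUTRAL):
            n = spec.n_per_class
            g = rng.standard_normal((n, 1))
            e = rng.standard_normal((n, n_tools))
            z = math.sqrt(spec.rho) * g + math.sqrt(1.0 - spec.rho) * e
            cols = []
            for ti, tool in enumerate(spec.tools):
                p: ClassParams = spec.params[(tool.name, category)]
                mean, sd = (p.d_mean, p.d_sd) if label == DELETERIOUS \
                    else (p.n_mean, p.n_sd)
                cols.append(mean + sd * z[:, ti])
            mat = np.column_stack(cols)
            for row in mat:
                v = Variant(chrom="1", pos=pos_counter, ref="A", alt="G",
                            label=label, category=category)
                pos_counter += 10
                variants.append(v)
                table.add(v.key, row)
        # equal train/test halves per class, shuffled once
        n = spec.n_per_class
        halves = {"train": [], "test": []}
        for start in (0, n):  # deleterious block, then neutral block
            perm = rng.permutation(n) + start
            halves["train"].extend(perm[: n // 2])
            halves["test"].extend(perm[n // 2:])
        datasets[category] = {}
        for split, idx in halves.items():
            vs = [variants[i] for i in sorted(idx)]
            datasets[category][split] = LabeledDataset(
                category=category, split=split, variants=vs,
                scores=table.subset(vs),
            )
    return datasets, table


# ---------------------------------------------------------------------------
# Genome simulation

_STOPS = ("TAA", "TAG", "TGA")
_BASES = "ACGT"
_NONSTOP_CODONS = tuple(
    a + b + c
    for a in _BASES for b in _BASES for c in _BASES
    if a + b + c not in _STOPS
)
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass
class GenomeFixture:
    """Miniature reference genome with planted, truth-known variants."""

    reference: dict  # chrom -> sequence string
    transcripts: list
    truth: list  # (Variant, category) pairs
    fasta_text: str
    gff3_text: str

    def write(self, outdir: str) -> dict:
        """Write ref.fa, genes.gff3 and truth.tsv; returns their paths."""
        import os

        os.makedirs(outdir, exist_ok=True)
        paths = {
            "fasta": os.path.join(outdir, "ref.fa"),
            "gff3": os.path.join(outdir, "genes.gff3"),
            "truth": os.path.join(outdir, "truth.tsv"),
        }
        with open(paths["fasta"], "w") as fh:
            fh.write(self.fasta_text)
        with open(paths["gff3"], "w") as fh:
            fh.write(self.gff3_text)
        with open(paths["truth"], "w") as fh:
            fh.write("chrom\tpos\tref\talt\tcategory\n")
            for v, cat in self.truth:
                fh.write(f"{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\t{cat}\n")
        return paths


def _classify_by_retranslation(cds: str, idx: int, alt: str) -> str:
    """Category of a CDS substitution by whole-protein comparison.

    The oracle: translate the entire mutant CDS; identical protein means
    synonymous, a premature stop at the first differing residue means
    nonsense, anything else (including start/stop-loss) missense.
    """
    ref_prot = str(Seq(cds).translate())
    mutant = cds[:idx] + alt + cds[idx + 1:]
    alt_prot = str(Seq(mutant).translate())
    if alt_prot == ref_prot:
        return "synonymous"
    for a, b in zip(ref_prot, alt_prot):
        if a != b:
            return "nonsense" if b == "*" else "missense"
    return "missense"


def simulate_genome(seed: int = 0, n_genes: int = 6,
                    intergenic_length: int = 300) -> GenomeFixture:
    """Build a miniature genome with planted variants of all 5 categories.

    Each gene has two coding exons separated by an intron of >= 20 bp;
    strands alternate.  Per gene, one synonymous, one missense and one
    nonsense substitution are planted (verified by whole-CDS
    retranslation), plus splice-region and regulatory (intergenic and
    deep-intronic) positions.  Byte-identical output for a fixed seed.
    """
    if n_genes < 1:
        raise ValueError("need at least one gene")
    rng = np.random.default_rng(seed)
    chrom = "1"
    seq_parts: list[str] = []
    cursor = 0  # 0-based length so far
    transcripts: list[TranscriptModel] = []
    truth: list[tuple[Variant, str]] = []
    gff_lines = ["##gff-version 3"]

    def rand_seq(n: int) -> str:
        return "".join(_BASES[i] for i in rng.integers(0, 4, size=n))

    def plant(pos: int, ref: str, alt: str, category: str) -> None:
        truth.append((Variant(chrom=chrom, pos=pos, ref=ref, alt=alt), category))

    for gi in range(n_genes):
        spacer = rand_seq(intergenic_length)
        seq_parts.append(spacer)
        # regulatory plant: middle of the spacer
        reg_pos = cursor + intergenic_length // 2  # 0-based genomic
        reg_ref = spacer[intergenic_length // 2]
        reg_alt = _BASES[(_BASES.index(reg_ref) + 1) % 4]
        plant(reg_pos + 1, reg_ref, reg_alt, "regulatory")
        cursor += intergenic_length

        strand = "+" if gi % 2 == 0 else "-"
        n_codons = int(rng.integers(30, 61))
        cds = "ATG" + "".join(
            _NONSTOP_CODONS[i]
            for i in rng.integers(0, len(_NONSTOP_CODONS), size=n_codons)
        ) + _STOPS[int(rng.integers(0, 3))]
        intron_len = int(rng.integers(25, 61))
        intron = "GT" + rand_seq(intron_len - 4) + "AG"
        split_at = int(rng.integers(6, len(cds) - 6))  # sense bp in exon 1
        premrna = cds[:split_at] + intron + cds[split_at:]
        L = len(premrna)
        seg_start = cursor + 1  # 1-based genomic start of the gene segment
        if strand == "+":
            segment = premrna
            exon1 = (seg_start, seg_start + split_at - 1)
            exon2 = (seg_start + split_at + intron_len,
                     seg_start + L - 1)

            def cds_to_genomic(i: int) -> int:
                # 0-based CDS index -> 1-based genomic position
                return seg_start + i if i < split_at \
                    else seg_start + i + intron_len

            def sense_to_genomic_allele(b: str) -> str:
                return b
        else:
            segment = str(Seq(premrna).reverse_complement())
            # sense interval [a, b] (1-based in premrna) -> genomic
            def g(i: int) -> int:
                return seg_start + L - i
            exon1 = (g(split_at), g(1))          # sense exon 1, genomic right
            exon2 = (g(L), g(split_at + intron_len + 1))  # genomic left

            def cds_to_genomic(i: int) -> int:
                j = i + 1 if i < split_at else i + intron_len + 1
                return g(j)

            def sense_to_genomic_allele(b: str) -> str:
                return b.translate(_COMPLEMENT)
        seq_parts.append(segment)
        cursor += L
        exons = sorted([tuple(sorted(exon1)), tuple(sorted(exon2))])
        tx = TranscriptModel(id=f"tx{gi + 1}", chrom=chrom, strand=strand,
                             exons=[tuple(e) for e in exons],
                             cds=[tuple(e) for e in exons])
        transcripts.append(tx)
        gene_start, gene_end = exons[0][0], exons[1][1]
        gff_lines.append(f"{chrom}\tsim\tgene\t{gene_start}\t{gene_end}\t.\t"
                         f"{strand}\t.\tID=gene{gi + 1}")
        gff_lines.append(f"{chrom}\tsim\tmRNA\t{gene_start}\t{gene_end}\t.\t"
                         f"{strand}\t.\tID=tx{gi + 1};Parent=gene{gi + 1}")
        # phases in transcription order
        first_len = (exons[1][1] - exons[1][0] + 1) if strand == "-" \
            else (exons[0][1] - exons[0][0] + 1)
        phases = {0: 0, 1: (3 - first_len % 3) % 3}
        for k, (a, b) in enumerate(exons):
            gff_lines.append(f"{chrom}\tsim\texon\t{a}\t{b}\t.\t{strand}\t.\t"
                             f"ID=tx{gi + 1}.exon{k + 1};Parent=tx{gi + 1}")
            order = k if strand == "+" else 1 - k
            gff_lines.append(f"{chrom}\tsim\tCDS\t{a}\t{b}\t.\t{strand}\t"
                             f"{phases[order]}\tID=tx{gi + 1}.cds{k + 1};"
                             f"Parent=tx{gi + 1}")

        # coding plants, truth by retranslation
        wanted = {"synonymous": None, "missense": None, "nonsense": None}
        cds_indices = rng.permutation(len(cds))
        for i in cds_indices:
            i = int(i)
            for alt in _BASES:
                if alt == cds[i]:
                    continue
                cat = _classify_by_retranslation(cds, i, alt)
                if wanted.get(cat) is None:
                    gpos = cds_to_genomic(i)
                    plant(gpos, sense_to_genomic_allele(cds[i]),
                          sense_to_genomic_allele(alt), cat)
                    wanted[cat] = (i, alt)
            if all(v is not None for v in wanted.values()):
                break

        # splice plants: 1 bp into the intron at both genomic boundaries
        left_exon_end = exons[0][1]
        right_exon_start = exons[1][0]
        for gpos in (left_exon_end + 1, right_exon_start - 1):
            ref = segment[gpos - seg_start]
            alt = _BASES[(_BASES.index(ref) + 1) % 4]
            plant(gpos, ref, alt, "splicing")
        # deep-intron regulatory plant (intron midpoint, > 2 bp from edges)
        mid = (left_exon_end + 1 + right_exon_start - 1) // 2
        ref = segment[mid - seg_start]
        alt = _BASES[(_BASES.index(ref) + 1) % 4]
        plant(mid, ref, alt, "regulatory")

    seq_parts.append(rand_seq(intergenic_length))
    genome = "".join(seq_parts)
    fasta_lines = [f">{chrom}"]
    for i in range(0, len(genome), 60):
        fasta_lines.append(genome[i: i + 60])
    fixture = GenomeFixture(
        reference={chrom: genome},
        transcripts=transcripts,
        truth=truth,
        fasta_text="\n".join(fasta_lines) + "\n",
        gff3_text="\n".join(gff_lines) + "\n",
    )
    return fixture
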