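"""Domain types and readers/writers for the formats the pipeline touches.

The pipeline operates exclusively on biallelic single-nucleotide variants
(SNVs).  Variants arrive as VCF 4.x or a 4-column TSV; per-variant raw
scores from external predictors arrive as a TSV score table; trained models
persist as a single versioned JSON document.

Coordinates are 1-based throughout, as in VCF.  Chromosome names are
normalized by stripping a leading ``chr`` prefix so UCSC- and Ensembl-style
inputs can be mixed.
"""

from __future__ import annotations

import datetime as _dt
import json
import logging
import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

NUCLEOTIDES = frozenset("ACGT")

#: The five variant categories, ordered from least to most severe coding
#: consequence (the categorizer resolves multi-transcript disagreement by
#: this severity order).
CATEGORIES = ("regulatory", "splicing", "missense", "synonymous", "nonsense")

DELETERIOUS = "deleterious"
NEUTRAL = "neutral"

HIGHER_IS_DELETERIOUS = "higher_is_deleterious"
LOWER_IS_DELETERIOUS = "lower_is_deleterious"

MODEL_SCHEMA_VERSION = "1"


class FormatError(ValueError):
    """Input file could not be parsed in the declared format."""


class EmptyInputError(ValueError):
    """No usable records were retained from an input file."""


class ConfigurationError(ValueError):
    """Declared configuration (tool lists, categories) does not match data."""


class DataIntegrityError(ValueError):
    """Input data contradicts the reference (e.g. ref-allele mismatch)."""


class UnsupportedVersionError(ValueError):
    """Persisted model was written by an incompatible schema version."""


def normalize_chrom(chrom: str) -> str:
    """Strip a leading ``chr``/``Chr`` prefix from a chromosome name."""
    c = str(chrom)
    if c.lower().startswith("chr"):
        return c[3:]
    return c


@dataclass
class Variant:
    """A biallelic genomic SNV.

    Attributes
    ----------
    chrom : str
        Chromosome name (stored as given; compared after ``chr``-stripping).
    pos : int
        1-based genomic position.
    ref, alt : str
        Single nucleotides, ``ref != alt``.
    id : str, optional
        External identifier such as an rsID.
    label : str, optional
        ``"deleterious"`` or ``"neutral"``.
    date : datetime.date, optional
        Submission date, used for time-based train/test splits.
    category : str, optional
        One of the five genomic categories once assigned.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    id: Optional[str] = None
    label: Optional[str] = None
    date: Optional[_dt.date] = None
    category: Optional[str] = None

    def __post_init__(self) -> None:
        self.chrom = str(self.chrom)
        self.pos = int(self.pos)
        self.ref = str(self.ref).upper()
        self.alt = str(self.alt).upper()
        if self.pos < 1:
            raise ValueError(f"variant position must be >= 1, got {self.pos}")
        if self.ref not in NUCLEOTIDES or self.alt not in NUCLEOTIDES:
            raise ValueError(
                f"alleles must be single nucleotides A/C/G/T, got "
                f"{self.ref!r}>{self.alt!r}"
            )
        if self.ref == self.alt:
            raise ValueError(f"ref and alt must differ, got {self.ref}>{self.alt}")
        if self.label is not None and self.label not in (DELETERIOUS, NEUTRAL):
            raise ValueError(f"unknown label {self.label!r}")
        if self.category is not None and self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Allele-specific variant key with the chromosome normalized."""
        return (normalize_chrom(self.chrom), self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class ToolSpec:
    """Name and score orientation of an external prediction tool."""

    name: str
    polarity: str = HIGHER_IS_DELETERIOUS

    def __post_init__(self) -> None:
        if self.polarity not in (HIGHER_IS_DELETERIOUS, LOWER_IS_DELETERIOUS):
            raise ValueError(f"unknown polarity {self.polarity!r}")


class ScoreTable:
    """Per-variant raw scores for an ordered set of named tools.

    Entries are keyed by the allele-specific variant key; missing scores are
    stored as ``nan`` and propagate to the consensus, where a variant with
    no scores at all is flagged rather than dropped.
    """

    def __init__(self, tools: Sequence[ToolSpec]):
        names = [t.name for t in tools]
        if len(set(names)) != len(names):
            raise ConfigurationError("tool names must be unique in a ScoreTable")
        self.tools: list[ToolSpec] = list(tools)
        self._index = {t.name: i for i, t in enumerate(self.tools)}
        self.entries: dict[tuple[str, int, str, str], np.ndarray] = {}

    @property
    def tool_names(self) -> list[str]:
        return [t.name for t in self.tools]

    def polarity(self, tool: str) -> str:
        return self.tools[self._index[tool]].polarity

    def add(self, key: tuple[str, int, str, str], scores: Sequence[float]) -> None:
        vec = np.asarray(scores, dtype=float)
        if vec.shape != (len(self.tools),):
            raise ValueError(
                f"score vector length {vec.size} != number of tools {len(self.tools)}"
            )
        if key in self.entries:
            logger.warning("duplicate score-table key %s: keeping last", key)
        self.entries[key] = vec

    def get(self, variant: Variant, tool: str) -> float:
        """Raw score of *tool* for *variant*; ``nan`` if absent."""
        vec = self.entries.get(variant.key)
        if vec is None:
            return math.nan
        return float(vec[self._index[tool]])

    def subset(self, variants: Iterable[Variant]) -> "ScoreTable":
        sub = ScoreTable(self.tools)
        for v in variants:
            if v.key in self.entries:
                sub.entries[v.key] = self.entries[v.key]
        return sub

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class LabeledDataset:
    """Category-homogeneous labeled variants with their scores."""

    category: str
    split: str
    variants: list[Variant]
    scores: ScoreTable

    def __post_init__(self) -> None:
        if self.split not in ("train", "test"):
            raise ValueError(f"split must be train/test, got {self.split!r}")
        for v in self.variants:
            if v.label is None:
                raise ValueError(f"unlabeled variant {v.key} in LabeledDataset")


@dataclass
class ModelBundle:
    """A trained model: thresholds, calibration curves and consensus models.

    ``thresholds`` maps (tool, category) to a decision threshold on the
    tool's raw-score scale, ``curves`` holds one score->accuracy calibration
    curve per (tool, category), and ``consensus`` one consensus model per
    category.  ``metadata`` echoes the training configuration.
    """

    thresholds: "object"  # calibration.ThresholdModel
    curves: dict  # (tool, category) -> calibration.CalibrationCurve
    consensus: dict  # category -> consensus.ConsensusModel
    metadata: dict = field(default_factory=dict)

    def validate(self) -> None:
        for cat, cm in self.consensus.items():
            for tool in cm.tools:
                if (tool, cat) not in self.curves:
                    raise ConfigurationError(
                        f"consensus for {cat!r} uses {tool!r} but no curve is fitted"
                    )
                self.thresholds.get(tool, cat)  # raises KeyError if absent


# ---------------------------------------------------------------------------
# Variant input


def _variants_from_vcf(path: str) -> tuple[list[Variant], int]:
    from cyvcf2 import VCF

    variants: list[Variant] = []
    skipped = 0
    try:
        reader = VCF(path)
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception
        raise FormatError(f"cannot open {path} as VCF: {exc}") from exc
    try:
        for rec in reader:
            ref = rec.REF
            for alt in rec.ALT:
                if (
                    len(ref) == 1
                    and len(alt) == 1
                    and ref.upper() in NUCLEOTIDES
                    and alt.upper() in NUCLEOTIDES
                    and ref.upper() != alt.upper()
                ):
                    variants.append(
                        Variant(
                            chrom=rec.CHROM,
                            pos=rec.POS,
                            ref=ref,
                            alt=alt,
                            id=rec.ID,
                        )
                    )
                else:
                    skipped += 1
    except Exception as exc:
        raise FormatError(f"malformed VCF record in {path}: {exc}") from exc
    return variants, skipped


def _variants_from_tsv(path: str) -> tuple[list[Variant], int]:
    variants: list[Variant] = []
    skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0].lower() in ("chrom", "chr", "chromosome"):
                continue
            if len(fields) < 4:
                raise FormatError(
                    f"{path}:{lineno}: expected >= 4 columns "
                    f"(chrom, pos, ref, alt), got {len(fields)}"
                )
            chrom, pos_s, ref, alt = fields[:4]
            try:
                pos = int(pos_s)
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: position {pos_s!r} is not an integer"
                ) from exc
            if (
                len(ref) == 1
                and len(alt) == 1
                and ref.upper() in NUCLEOTIDES
                and alt.upper() in NUCLEOTIDES
                and ref.upper() != alt.upper()
            ):
                vid = fields[4] if len(fields) > 4 and fields[4] not in (".", "") else None
                variants.append(Variant(chrom=chrom, pos=pos, ref=ref, alt=alt, id=vid))
            else:
                skipped += 1
    return variants, skipped


def read_variants(path: str, format: str = "auto") -> list[Variant]:
    """Read biallelic SNVs from a VCF 4.x or 4-column TSV file.

    Multi-allelic VCF records are split into one :class:`Variant` per alt
    allele.  Non-SNV alleles (indels, MNVs, symbolic alleles) are skipped
    and counted in the log.  Raises :class:`EmptyInputError` if no SNV is
    retained and :class:`FormatError` on unparseable input.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if format == "auto":
        format = "vcf" if path.endswith((".vcf", ".vcf.gz")) else "tsv"
    if format == "vcf":
        variants, skipped = _variants_from_vcf(path)
    elif format == "tsv":
        variants, skipped = _variants_from_tsv(path)
    else:
        raise ValueError(f"unknown variant format {format!r}")
    if skipped:
        logger.info("skipped %d non-SNV alleles while reading %s", skipped, path)
    if not variants:
        raise EmptyInputError(f"no biallelic SNVs retained from {path}")
    return variants


# ---------------------------------------------------------------------------
# Score tables


def read_score_table(path: str, tool_specs: Sequence[ToolSpec]) -> ScoreTable:
    """Read a per-variant raw-score TSV into a :class:`ScoreTable`.

    The file must carry a header ``chrom pos ref alt`` followed by one
    column per declared tool; missing scores are encoded as ``.``.
    Duplicate variant keys keep the last row (with a warning).
    """
    table = ScoreTable(tool_specs)
    try:
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, na_values=["."])
    except Exception as exc:
        raise FormatError(f"cannot parse score table {path}: {exc}") from exc
    required = ["chrom", "pos", "ref", "alt"]
    for col in required:
        if col not in df.columns:
            raise ConfigurationError(f"score table {path} lacks column {col!r}")
    for spec in tool_specs:
        if spec.name not in df.columns:
            raise ConfigurationError(
                f"score table {path} lacks declared tool column {spec.name!r}"
            )
        if not pd.api.types.is_numeric_dtype(df[spec.name]):
            coerced = pd.to_numeric(df[spec.name], errors="coerce")
            bad = df[spec.name][coerced.isna() & df[spec.name].notna()]
            if len(bad):
                raise FormatError(
                    f"non-numeric score token {bad.iloc[0]!r} in column "
                    f"{spec.name!r} of {path}"
                )
            df[spec.name] = coerced
    for row in df.itertuples(index=False):
        key = (normalize_chrom(row.chrom), int(row.pos), str(row.ref).upper(),
               str(row.alt).upper())
        table.add(key, [getattr(row, s.name) for s in tool_specs])
    return table


def write_score_table(table: ScoreTable, path: str) -> None:
    """Write a :class:`ScoreTable` back to TSV (missing scores as ``.``)."""
    with open(path, "w") as fh:
        fh.write("\t".join(["chrom", "pos", "ref", "alt"] + table.tool_names) + "\n")
        for (chrom, pos, ref, alt), vec in table.entries.items():
            cells = [chrom, str(pos), ref, alt]
            cells += ["." if math.isnan(x) else repr(float(x)) for x in vec]
            fh.write("\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# Model persistence


def save_model(bundle: ModelBundle, path: str) -> None:
    """Persist a :class:`ModelBundle` as a single versioned JSON document."""
    bundle.validate()
    doc = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "thresholds": bundle.thresholds.to_dict(),
        "curves": [
            {"tool": tool, "category": cat, **curve.to_dict()}
            for (tool, cat), curve in sorted(bundle.curves.items())
        ],
        "consensus": {cat: cm.to_dict() for cat, cm in sorted(bundle.consensus.items())},
        "metadata": bundle.metadata,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def load_model(path: str) -> ModelBundle:
    """Load a :class:`ModelBundle` written by :func:`save_model`.

    Numeric fields round-trip bit-exactly (JSON ``repr`` of Python floats).
    A truncated or malformed file raises :class:`FormatError` without
    producing a partial model; a foreign schema version raises
    :class:`UnsupportedVersionError`.
    """
    from .calibration import CalibrationCurve, ThresholdModel
    from .consensus import ConsensusModel

    try:
        with open(path) as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise FormatError(f"model file {path} is not valid JSON: {exc}") from exc
    version = doc.get("schema_version")
    if version != MODEL_SCHEMA_VERSION:
        raise UnsupportedVersionError(
            f"model file {path} has schema version {version!r}; "
            f"this build supports {MODEL_SCHEMA_VERSION!r}"
        )
    thresholds = ThresholdModel.from_dict(doc["thresholds"])
    curves = {
        (c["tool"], c["category"]): CalibrationCurve.from_dict(c)
        for c in doc["curves"]
    }
    consensus = {cat: ConsensusModel.from_dict(d) for cat, d in doc["consensus"].items()}
    bundle = ModelBundle(
        thresholds=thresholds, curves=curves, consensus=consensus,
        metadata=doc.get("metadata", {}),
    )
    bundle.validate()
    return bundle


# ---------------------------------------------------------------------------
# Prediction output


def _prediction_cells(pred, tool_names: Sequence[str]) -> list[str]:
    cells = [
        pred.variant.chrom, str(pred.variant.pos), pred.variant.ref,
        pred.variant.alt, pred.category or ".",
    ]
    if pred.no_scores:
        cells += [".", ".", "NO_SCORES"]
    else:
        cells += [pred.consensus_prediction, str(pred.consensus_confidence), "."]
    for name in tool_names:
        vote = pred.tool_votes.get(name)
        if vote is None:
            cells += [".", "."]
        else:
            cells += [vote[0], str(vote[1])]
    return cells


def write_predictions(preds: Sequence, path: str, format: str = "tsv",
                      tool_names: Optional[Sequence[str]] = None) -> None:
    """Write consensus predictions as TSV or annotated VCF.

    VCF output carries INFO keys ``PS2_CAT``, ``PS2_PRED`` (D/N),
    ``PS2_CONF`` (0-99) and per-tool ``<TOOL>_PRED``/``<TOOL>_CONF``;
    variants without any tool score are flagged ``NO_SCORES``.  The TSV
    mirrors the same columns.  Input order is preserved.
    """
    if tool_names is None:
        seen: dict[str, None] = {}
        for p in preds:
            for name in p.tool_votes:
                seen.setdefault(name)
        tool_names = list(seen)
    if format == "tsv":
        header = ["chrom", "pos", "ref", "alt", "PS2_CAT", "PS2_PRED", "PS2_CONF",
                  "FLAG"]
        for name in tool_names:
            header += [f"{name}_PRED", f"{name}_CONF"]
        with open(path, "w") as fh:
            fh.write("\t".join(header) + "\n")
            for p in preds:
                fh.write("\t".join(_prediction_cells(p, tool_names)) + "\n")
    elif format == "vcf":
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##INFO=<ID=PS2_CAT,Number=1,Type=String,'
                     'Description="Variant category">\n')
            fh.write('##INFO=<ID=PS2_PRED,Number=1,Type=String,'
                     'Description="Consensus prediction (D/N)">\n')
            fh.write('##INFO=<ID=PS2_CONF,Number=1,Type=Integer,'
                     'Description="Consensus confidence 0-99">\n')
            fh.write('##INFO=<ID=NO_SCORES,Number=0,Type=Flag,'
                     'Description="No tool scores available">\n')
            for name in tool_names:
                fh.write(f'##INFO=<ID={name}_PRED,Number=1,Type=String,'
                         f'Description="{name} prediction (D/N)">\n')
                fh.write(f'##INFO=<ID={name}_CONF,Number=1,Type=Integer,'
                         f'Description="{name} confidence 0-99">\n')
            contigs: dict[str, None] = {}
            for p in preds:
                contigs.setdefault(p.variant.chrom)
            for c in contigs:
                fh.write(f"##contig=<ID={c}>\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
            for p in preds:
                info = [f"PS2_CAT={p.category or '.'}"]
                if p.no_scores:
                    info += ["PS2_PRED=.", "NO_SCORES"]
                else:
                    info += [f"PS2_PRED={p.consensus_prediction}",
                             f"PS2_CONF={p.consensus_confidence}"]
                for name in tool_names:
                    vote = p.tool_votes.get(name)
                    if vote is not None:
                        info += [f"{name}_PRED={vote[0]}", f"{name}_CONF={vote[1]}"]
                v = p.variant
                fh.write(f"{v.chrom}\t{v.pos}\t{v.id or '.'}\t{v.ref}\t{v.alt}"
                         f"\t.\t.\t{';'.join(info)}\n")
    else:
        raise ValueError(f"unknown prediction format {format!r}")


def read_predictions_tsv(path: str) -> pd.DataFrame:
    """Read back a prediction TSV written by :func:`write_predictions`."""
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})
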