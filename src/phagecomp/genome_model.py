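"""Data model and I/O for genomes, gene annotations, and ortholog assignments.

Internal coordinates are always 0-based half-open on the forward strand;
file readers convert from the 1-based inclusive conventions of GFF3 and
GenBank, and writers convert back. Sequences are stored uppercase in the
DNA alphabet (``U`` is normalized to ``T`` on input).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

_VALID_BASES = frozenset("ACGTN")

#: feature kinds retained with their own label; everything else becomes "other"
_KIND_MAP = {"CDS": "CDS", "tRNA": "tRNA"}

_ANTICODON_RE = re.compile(r"\(([ACGUTacgut]{3})\)")


@dataclass(frozen=True)
class GenomeRecord:
    """A single genome sequence.

    Parameters
    ----------
    genome_id : str
        Unique identifier within a collection.
    sequence : str
        Uppercase nucleotide string over ``{A, C, G, T, N}``.
    topology : str
        ``"linear"`` or ``"circular"``. Windows and regions never wrap
        regardless of topology.
    """

    genome_id: str
    sequence: str
    topology: str = "linear"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValidationError(f"genome {self.genome_id!r}: empty sequence")
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise FormatError(
                f"genome {self.genome_id!r}: invalid characters {sorted(bad)}"
            )
        if self.topology not in ("linear", "circular"):
            raise ValidationError(f"unknown topology {self.topology!r}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneFeature:
    """An annotated gene (CDS, tRNA, or other feature).

    Coordinates are 0-based half-open; ``strand`` is ``"+"`` or ``"-"``.
    ``attributes`` carries format-specific key/value pairs (e.g. the
    ``anticodon`` of a tRNA).
    """

    gene_id: str
    genome_id: str
    start: int
    end: int
    strand: str
    kind: str = "CDS"
    product: str = ""
    category: str | None = None
    attributes: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"gene {self.gene_id!r}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise FormatError(
                f"gene {self.gene_id!r}: unknown strand symbol {self.strand!r}"
            )
        if self.kind not in ("CDS", "tRNA", "other"):
            raise ValidationError(f"gene {self.gene_id!r}: unknown kind {self.kind!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def anticodon(self) -> str | None:
        """RNA anticodon of a tRNA feature, or None if undetermined.

        Resolution order: an explicit ``anticodon`` attribute, then a
        parenthesized triplet in the product text (e.g. ``tRNA-Leu(UAA)``).
        """
        if self.kind != "tRNA":
            return None
        raw = self.attributes.get("anticodon")
        if raw is None and self.product:
            m = _ANTICODON_RE.search(self.product)
            raw = m.group(1) if m else None
        if raw is None:
            return None
        triplet = raw.upper().replace("T", "U")
        if len(triplet) != 3 or set(triplet) - set("ACGU"):
            return None
        return triplet


class OrthologTable:
    """Gene -> ortholog-group assignments for a genome collection."""

    def __init__(self, rows: Iterable[tuple[str, str, str]] = ()) -> None:
        self._og_by_gene: dict[str, str] = {}
        self._genome_by_gene: dict[str, str] = {}
        for gene_id, genome_id, og_id in rows:
            self.add(gene_id, genome_id, og_id)

    def add(self, gene_id: str, genome_id: str, og_id: str) -> None:
        prior = self._og_by_gene.get(gene_id)
        if prior is not None and prior != og_id:
            raise FormatError(
                f"gene {gene_id!r} assigned to conflicting ortholog groups "
                f"{prior!r} and {og_id!r}"
            )
        self._og_by_gene[gene_id] = og_id
        self._genome_by_gene[gene_id] = genome_id

    def og_of(self, gene_id: str) -> str | None:
        """Ortholog group of *gene_id*, or None for unassigned genes."""
        return self._og_by_gene.get(gene_id)

    def __len__(self) -> int:
        return len(self._og_by_gene)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._og_by_gene

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": list(self._og_by_gene),
                "genome_id": [self._genome_by_gene[g] for g in self._og_by_gene],
                "og_id": [self._og_by_gene[g] for g in self._og_by_gene],
            }
        )


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[GenomeRecord]:
    """Read a (multi-)FASTA file into GenomeRecords, order preserved.

    Sequences are uppercased and ``U`` is mapped to ``T``. Any character
    outside ``{A, C, G, T, N}`` after normalization is a format error
    naming the offending record.
    """
    path = Path(path)
    records: list[GenomeRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace("U", "T")
        bad = set(seq) - _VALID_BASES
        if bad:
            raise FormatError(
                f"{path.name}: record {rec.id!r} contains invalid characters "
                f"{sorted(bad)}"
            )
        if rec.id in seen:
            raise FormatError(f"{path.name}: duplicate genome id {rec.id!r}")
        seen.add(rec.id)
        records.append(GenomeRecord(genome_id=rec.id, sequence=seq))
    if not records:
        raise FormatError(f"{path.name}: no FASTA records found")
    return records


def write_fasta(records: Sequence[GenomeRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.genome_id}\n")
            for i in range(0, rec.length, width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Annotations


def _classify(feature_type: str) -> str:
    return _KIND_MAP.get(feature_type, "other")


def read_annotations(
    path: str | Path,
    format: str = "gff3",
    genome_lengths: Mapping[str, int] | None = None,
) -> list[GeneFeature]:
    """Read gene annotations from GFF3 or GenBank into GeneFeatures.

    File coordinates (1-based inclusive) are converted to 0-based
    half-open. CDS and tRNA features keep their kind; everything else is
    ``kind="other"``. If *genome_lengths* is given, features extending
    beyond the sequence are an error.
    """
    path = Path(path)
    if format == "gff3":
        feats = _read_gff3(path)
    elif format == "genbank":
        feats = _read_genbank(path)
    else:
        raise ValidationError(f"unknown annotation format {format!r}")
    if genome_lengths is not None:
        for f in feats:
            limit = genome_lengths.get(f.genome_id)
            if limit is not None and f.end > limit:
                raise FormatError(
                    f"gene {f.gene_id!r} extends to {f.end} beyond genome "
                    f"{f.genome_id!r} length {limit}"
                )
    if not any(f.kind == "CDS" for f in feats):
        logger.warning("%s: no CDS features found", path.name)
    return feats


def _parse_gff3_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in text.strip().split(";"):
        chunk = chunk.strip()
        if not chunk or "=" not in chunk:
            continue
        key, _, value = chunk.partition("=")
        attrs[key.strip()] = value.strip()
    return attrs


def _read_gff3(path: Path) -> list[GeneFeature]:
    feats: list[GeneFeature] = []
    counter = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path.name}:{lineno}: expected 9 columns, got {len(cols)}")
            seqid, _source, ftype, start_s, end_s, _score, strand, _phase, attr_s = cols
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"{path.name}:{lineno}: non-integer coordinates") from exc
            if start1 < 1 or end1 < start1:
                raise FormatError(f"{path.name}:{lineno}: bad interval {start1}..{end1}")
            attrs = _parse_gff3_attributes(attr_s)
            counter += 1
            gene_id = attrs.get("ID") or attrs.get("locus_tag") or f"feature_{counter}"
            feats.append(
                GeneFeature(
                    gene_id=gene_id,
                    genome_id=seqid,
                    start=start1 - 1,
                    end=end1,
                    strand=strand,
                    kind=_classify(ftype),
                    product=attrs.get("product", attrs.get("Name", "")),
                    category=attrs.get("category"),
                    attributes=attrs,
                )
            )
    return feats


def _read_genbank(path: Path) -> list[GeneFeature]:
    feats: list[GeneFeature] = []
    for rec in SeqIO.parse(str(path), "genbank"):
        counter = 0
        for sf in rec.features:
            if sf.type in ("source", "gene"):
                continue
            counter += 1
            quals = {k: v[0] for k, v in sf.qualifiers.items() if v}
            gene_id = quals.get("locus_tag") or quals.get("gene") or f"{rec.id}_{counter}"
            strand = "-" if sf.location.strand == -1 else "+"
            if sf.location.strand not in (1, -1):
                raise FormatError(f"{rec.id}: feature {gene_id!r} has no strand")
            feats.append(
                GeneFeature(
                    gene_id=gene_id,
                    genome_id=rec.id,
                    start=int(sf.location.start),
                    end=int(sf.location.end),
                    strand=strand,
                    kind=_classify(sf.type),
                    product=quals.get("product", ""),
                    category=quals.get("function"),
                    attributes=quals,
                )
            )
    return feats


def write_gff3(features: Sequence[GeneFeature], path: str | Path) -> None:
    """Write features as GFF3 (converting back to 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = dict(f.attributes)
            attrs["ID"] = f.gene_id
            if f.product:
                attrs.setdefault("product", f.product)
            if f.category:
                attrs.setdefault("category", f.category)
            attr_s = ";".join(f"{k}={v}" for k, v in attrs.items())
            ftype = f.kind if f.kind in ("CDS", "tRNA") else "misc_feature"
            fh.write(
                "\t".join(
                    [
                        f.genome_id,
                        "phagecomp",
                        ftype,
                        str(f.start + 1),
                        str(f.end),
                        ".",
                        f.strand,
                        "0" if f.kind == "CDS" else ".",
                        attr_s,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# CDS extraction


def extract_cds(genome: GenomeRecord, feature: GeneFeature) -> str:
    """Nucleotide sequence of a CDS feature in reading orientation.

    Returns the forward-strand substring for ``+`` features and its
    reverse complement for ``-`` features.
    """
    if feature.kind != "CDS":
        raise ValidationError(f"gene {feature.gene_id!r} is not a CDS")
    if feature.end > genome.length:
        raise ValidationError(
            f"gene {feature.gene_id!r} [{feature.start},{feature.end}) out of "
            f"bounds for genome {genome.genome_id!r} (length {genome.length})"
        )
    sub = genome.sequence[feature.start : feature.end]
    if feature.strand == "-":
        sub = str(Seq(sub).reverse_complement())
    return sub


# ---------------------------------------------------------------------------
# Ortholog table I/O


def read_ortholog_table(path: str | Path) -> OrthologTable:
    """Read a gene->OG TSV with header columns gene_id, genome_id, og_id."""
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        logger.warning("%s: empty ortholog table", path.name)
        return OrthologTable()
    required = {"gene_id", "genome_id", "og_id"}
    missing = required - set(frame.columns)
    if missing:
        raise FormatError(f"{path.name}: missing columns {sorted(missing)}")
    if frame.empty:
        logger.warning("%s: ortholog table has no rows", path.name)
    table = OrthologTable()
    for row in frame.itertuples(index=False):
        table.add(row.gene_id, row.genome_id, row.og_id)
    return table


def write_ortholog_table(table: OrthologTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)
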