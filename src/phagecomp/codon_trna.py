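"""Synonymous codon-usage statistics and tRNA anticodon-complement analysis.

Codon usage is expressed per amino-acid family: usage(c) is the fraction a
codon contributes among all codons encoding the same amino acid in a CDS
set. The no-bias baseline is 1/k for a family of k synonymous codons.
Codons are handled in the RNA alphabet throughout this module; tabular
display truncates fractions to three decimals (1/6 -> 0.166).

tRNA anticodons decode exactly one codon, their strict Watson-Crick
reverse complement; wobble pairing is deliberately not modeled.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .errors import ValidationError
from .genome_model import GeneFeature, GenomeRecord, extract_cds

logger = logging.getLogger(__name__)


def _rna(codon: str) -> str:
    return codon.upper().replace("T", "U")


class GeneticCode:
    """Codon -> amino-acid map with synonymous family sizes (RNA alphabet)."""

    def __init__(self, table_id: int = 11) -> None:
        bio_table = CodonTable.unambiguous_dna_by_id[table_id]
        self.table_id = table_id
        self.codon_to_aa: dict[str, str] = {
            _rna(c): aa for c, aa in bio_table.forward_table.items()
        }
        self.stop_codons: frozenset[str] = frozenset(
            _rna(c) for c in bio_table.stop_codons
        )
        fam: dict[str, list[str]] = {}
        for codon, aa in self.codon_to_aa.items():
            fam.setdefault(aa, []).append(codon)
        self.family: dict[str, tuple[str, ...]] = {
            aa: tuple(sorted(cods)) for aa, cods in fam.items()
        }
        self.family_size: dict[str, int] = {aa: len(c) for aa, c in self.family.items()}

    @property
    def sense_codons(self) -> list[str]:
        return sorted(self.codon_to_aa)

    def synonyms(self, codon: str) -> tuple[str, ...]:
        return self.family[self.codon_to_aa[_rna(codon)]]


STANDARD_CODE = GeneticCode(11)


def truncate3(x: float) -> float:
    """Truncate (not round) to 3 decimals, the tabular display convention."""
    return math.floor(x * 1000) / 1000


@dataclass
class CodonUsageProfile:
    """Aggregate codon counts and per-family synonymous usage for a CDS set."""

    source_id: str
    counts: Counter[str] = field(default_factory=Counter)
    n_cds: int = 0
    n_skipped: int = 0
    n_internal_stops: int = 0

    def usage(self, code: GeneticCode = STANDARD_CODE) -> dict[str, float]:
        return synonymous_usage(self.counts, code)

    def total_codons(self) -> int:
        return sum(self.counts.values())


def codon_counts(
    cds_sequences: Iterable[str],
    source_id: str = "cds_set",
    code: GeneticCode = STANDARD_CODE,
) -> CodonUsageProfile:
    """Aggregate codon counts over a set of CDS nucleotide sequences.

    Sequences whose length is not a multiple of 3 are skipped with a
    warning. A single terminal stop codon is excluded from the counts;
    internal stop codons are counted and flagged (annotations may contain
    pseudogenes).
    """
    profile = CodonUsageProfile(source_id=source_id)
    any_seq = False
    for i, seq in enumerate(cds_sequences):
        any_seq = True
        seq = _rna(seq)
        if len(seq) % 3 != 0:
            logger.warning(
                "%s: CDS #%d length %d not divisible by 3; skipped", source_id, i, len(seq)
            )
            profile.n_skipped += 1
            continue
        codons = [seq[j : j + 3] for j in range(0, len(seq), 3)]
        if codons and codons[-1] in code.stop_codons:
            codons = codons[:-1]
        for codon in codons:
            if codon in code.stop_codons:
                profile.n_internal_stops += 1
            profile.counts[codon] += 1
        profile.n_cds += 1
    if not any_seq:
        raise ValidationError(f"{source_id}: empty CDS set")
    return profile


def profile_from_genome(
    genome: GenomeRecord,
    features: Iterable[GeneFeature],
    code: GeneticCode = STANDARD_CODE,
) -> CodonUsageProfile:
    """Codon-usage profile from a genome and its CDS annotations."""
    seqs = [extract_cds(genome, f) for f in features if f.kind == "CDS"]
    return codon_counts(seqs, source_id=genome.genome_id, code=code)


def synonymous_usage(
    counts: Mapping[str, int], code: GeneticCode = STANDARD_CODE
) -> dict[str, float]:
    """usage(c) = count(c) / sum of counts over codons of c's amino acid.

    Families with zero total count are omitted (usage undefined).
    """
    usage: dict[str, float] = {}
    for aa, codons in code.family.items():
        total = sum(counts.get(c, 0) for c in codons)
        if total == 0:
            continue
        for c in codons:
            usage[c] = counts.get(c, 0) / total
    return usage


def random_usage(code: GeneticCode = STANDARD_CODE) -> dict[str, float]:
    """The no-bias baseline: 1 / family size, per sense codon."""
    return {
        codon: 1.0 / code.family_size[aa]
        for codon, aa in code.codon_to_aa.items()
    }


@dataclass
class TRNAComplement:
    """tRNA anticodon inventory of a genome with decoded codons."""

    source_id: str
    anticodon_counts: Counter[str] = field(default_factory=Counter)
    n_undetermined: int = 0

    @staticmethod
    def decode(anticodon: str) -> str:
        """Strict Watson-Crick decoded codon: reverse complement (RNA)."""
        return str(Seq(_rna(anticodon)).reverse_complement_rna())

    @property
    def decoded_codons(self) -> Counter[str]:
        out: Counter[str] = Counter()
        for anti, n in self.anticodon_counts.items():
            out[self.decode(anti)] += n
        return out

    def amino_acids(self, code: GeneticCode = STANDARD_CODE) -> set[str]:
        return {
            code.codon_to_aa[c]
            for c in self.decoded_codons
            if c in code.codon_to_aa
        }

    @property
    def n_determined(self) -> int:
        return sum(self.anticodon_counts.values())


def trna_complement(
    features: Iterable[GeneFeature], source_id: str = "genome"
) -> TRNAComplement:
    """Anticodon complement from tRNA annotations.

    Features whose anticodon cannot be resolved (no attribute and no
    parsable product text) are counted as undetermined rather than
    dropped, mirroring unassignable pseudo-tRNA genes.
    """
    comp = TRNAComplement(source_id=source_id)
    for feat in features:
        if feat.kind != "tRNA":
            continue
        anti = feat.anticodon()
        if anti is None:
            comp.n_undetermined += 1
        else:
            comp.anticodon_counts[anti] += 1
    return comp


def rare_codon_report(
    phage_profile: CodonUsageProfile,
    host_profile: CodonUsageProfile,
    phage_trnas: TRNAComplement,
    host_trnas: TRNAComplement | None = None,
    code: GeneticCode = STANDARD_CODE,
) -> pd.DataFrame:
    """For each codon decoded by a phage tRNA, compare host usage to baseline.

    A codon is flagged ``rare_host`` when the host's synonymous usage is
    strictly below the 1/k random baseline. ``host_trna_absent`` marks
    codons with no decoding tRNA in the host complement (pandas NA when no
    host complement was supplied).
    """
    baseline = random_usage(code)
    phage_usage = phage_profile.usage(code)
    host_usage = host_profile.usage(code)
    host_decoded = host_trnas.decoded_codons if host_trnas is not None else None
    rows = []
    for codon, n_trna in sorted(phage_trnas.decoded_codons.items()):
        if codon not in code.codon_to_aa:
            logger.warning("decoded codon %s is a stop codon; skipped", codon)
            continue
        h = host_usage.get(codon)
        rows.append(
            {
                "codon": codon,
                "amino_acid": code.codon_to_aa[codon],
                "phage_trnas": n_trna,
                "host_trnas": host_decoded.get(codon, 0) if host_decoded is not None else pd.NA,
                "random_usage": baseline[codon],
                "phage_usage": phage_usage.get(codon),
                "host_usage": h,
                "rare_host": (h < baseline[codon]) if h is not None else pd.NA,
                "host_trna_absent": (host_decoded.get(codon, 0) == 0)
                if host_decoded is not None
                else pd.NA,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "codon",
            "amino_acid",
            "phage_trnas",
            "host_trnas",
            "random_usage",
            "phage_usage",
            "host_usage",
            "rare_host",
            "host_trna_absent",
        ],
    )


def usage_table(
    phage_profile: CodonUsageProfile,
    host_profile: CodonUsageProfile,
    phage_trnas: TRNAComplement | None = None,
    host_trnas: TRNAComplement | None = None,
    codons: Sequence[str] | None = None,
    code: GeneticCode = STANDARD_CODE,
) -> pd.DataFrame:
    """Codon-usage comparison table with truncated 3-decimal display values."""
    baseline = random_usage(code)
    pu = phage_profile.usage(code)
    hu = host_profile.usage(code)
    pt = phage_trnas.decoded_codons if phage_trnas else Counter()
    ht = host_trnas.decoded_codons if host_trnas else Counter()
    if codons is None:
        codons = sorted(pt) if pt else code.sense_codons
    rows = []
    for codon in codons:
        codon = _rna(codon)
        rows.append(
            {
                "codon": codon,
                "amino_acid": code.codon_to_aa.get(codon, "*"),
                "phage_trnas": pt.get(codon, 0),
                "host_trnas": ht.get(codon, 0),
                "random_usage": truncate3(baseline[codon]) if codon in baseline else None,
                "phage_usage": truncate3(pu[codon]) if codon in pu else None,
                "host_usage": truncate3(hu[codon]) if codon in hu else None,
            }
        )
    return pd.DataFrame(rows)


def per_gene_codon_counts(
    genome: GenomeRecord,
    features: Iterable[GeneFeature],
    code: GeneticCode = STANDARD_CODE,
) -> dict[str, Counter[str]]:
    """Codon counts per CDS gene (terminal stop excluded, frameshifts skipped)."""
    out: dict[str, Counter[str]] = {}
    for feat in features:
        if feat.kind != "CDS":
            continue
        seq = _rna(extract_cds(genome, feat))
        if len(seq) % 3 != 0:
            logger.warning("gene %s: length not divisible by 3; skipped", feat.gene_id)
            continue
        codons = [seq[j : j + 3] for j in range(0, len(seq), 3)]
        if codons and codons[-1] in code.stop_codons:
            codons = codons[:-1]
        out[feat.gene_id] = Counter(codons)
    return out


def rank_genes_by_target_codons(
    gene_counts: Mapping[str, Mapping[str, int]],
    target_codons: Iterable[str],
    min_codons: int = 30,
) -> pd.DataFrame:
    """Rank genes by the fraction of their codons drawn from a target set.

    score(gene) = (# codons in target set) / (total codons). Genes with
    fewer than *min_codons* codons are excluded. Sorted by score
    descending, ties by total codon count descending then gene_id.
    """
    targets = {_rna(c) for c in target_codons}
    if not targets:
        raise ValidationError("empty target codon set")
    rows = []
    for gene_id, counts in gene_counts.items():
        total = sum(counts.values())
        if total < min_codons:
            continue
        hit = sum(n for c, n in counts.items() if _rna(c) in targets)
        rows.append({"gene_id": gene_id, "n_codons": total, "n_target": hit, "score": hit / total})
    frame = pd.DataFrame(rows, columns=["gene_id", "n_codons", "n_target", "score"])
    return frame.sort_values(
        ["score", "n_codons", "gene_id"], ascending=[False, False, True]
    ).reset_index(drop=True)
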