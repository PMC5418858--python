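"""Seeded generators for synthetic inputs with known ("planted") structure.

Each generator is deterministic given its seed, emits the exact on-disk
formats the pipeline consumes (FASTA, GFF3, ortholog TSV, counts TSV),
and records the planted truth in a machine-readable dict/JSON so tests
can verify recovery.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .codon_trna import STANDARD_CODE, GeneticCode
from .errors import ValidationError
from .genome_model import (
    GeneFeature,
    GenomeRecord,
    OrthologTable,
    write_fasta,
    write_gff3,
    write_ortholog_table,
)

_BASES = "ACGT"


def _random_cds(rng: np.random.Generator, n_codons: int, code: GeneticCode) -> str:
    """Random CDS: ATG + non-stop codons + TAA (DNA alphabet)."""
    sense = [c.replace("U", "T") for c in code.sense_codons]
    body = rng.choice(sense, size=max(n_codons - 1, 1))
    return "ATG" + "".join(body) + "TAA"


def _spacer(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(_BASES), size=length))


# ---------------------------------------------------------------------------
# Genome sets with planted ortholog-sharing structure


@dataclass
class GenomeSetResult:
    genomes: list[GenomeRecord]
    features: list[GeneFeature]
    table: OrthologTable
    truth: dict
    paths: dict[str, Path] = field(default_factory=dict)


def gen_genome_set(
    n_clusters: int = 2,
    genomes_per_cluster: int = 5,
    core_ogs_per_cluster: int = 15,
    shared_fraction_within: float = 0.5,
    noise_singletons: int = 3,
    seed: int = 0,
    accessory_pool: int = 6,
    gene_len_codons: int = 30,
    within_j_min: float = 0.3,
    between_j_max: float = 0.05,
    out_dir: str | Path | None = None,
) -> GenomeSetResult:
    """Genomes with planted cluster structure in their OG sets.

    Each cluster has a private OG namespace: every member carries the
    cluster's core OGs, a random subset of a shared accessory pool, and
    *noise_singletons* genes with no OG assignment. One OG per cluster is
    planted in exactly its first two members (subset-exclusive truth).
    Pairwise Jaccard bounds are verified after construction and violating
    parameter choices raise an error.
    """
    if min(n_clusters, genomes_per_cluster, core_ogs_per_cluster, gene_len_codons) < 1:
        raise ValidationError("all structural parameters must be positive")
    if within_j_min <= between_j_max:
        raise ValidationError(
            f"infeasible bounds: within_j_min ({within_j_min}) must exceed "
            f"between_j_max ({between_j_max})"
        )
    rng = np.random.default_rng(seed)
    genomes: list[GenomeRecord] = []
    features: list[GeneFeature] = []
    table = OrthologTable()
    membership: dict[str, list[str]] = {}
    core_truth: dict[str, list[str]] = {}
    exclusive_truth: dict[str, dict] = {}

    for c in range(n_clusters):
        cname = f"cluster{c}"
        core = [f"{cname}:core{k:03d}" for k in range(core_ogs_per_cluster)]
        accessory = [f"{cname}:acc{k:03d}" for k in range(accessory_pool)]
        excl_og = f"{cname}:excl" if genomes_per_cluster >= 2 else None
        member_ids = [f"{cname}_g{g}" for g in range(genomes_per_cluster)]
        membership[cname] = member_ids
        core_truth[cname] = core
        if excl_og is not None:
            exclusive_truth[cname] = {"og_id": excl_og, "genomes": member_ids[:2]}

        for g, gid in enumerate(member_ids):
            ogs = list(core)
            ogs += [og for og in accessory if rng.random() < shared_fraction_within]
            if excl_og is not None and g < 2:
                ogs.append(excl_og)
            parts: list[str] = []
            feats: list[GeneFeature] = []
            pos = 0
            gene_no = 0

            def add_gene(og: str | None) -> None:
                nonlocal pos, gene_no
                gene_no += 1
                gene_id = f"{gid}_{gene_no:04d}"
                cds = _random_cds(rng, gene_len_codons, STANDARD_CODE)
                spacer = _spacer(rng, 20)
                feats.append(
                    GeneFeature(
                        gene_id=gene_id, genome_id=gid,
                        start=pos, end=pos + len(cds),
                        strand="+", kind="CDS",
                        product=og or "hypothetical protein",
                    )
                )
                if og is not None:
                    table.add(gene_id, gid, og)
                parts.append(cds + spacer)
                pos += len(cds) + len(spacer)

            for og in ogs:
                add_gene(og)
            for _ in range(noise_singletons):
                add_gene(None)
            genomes.append(GenomeRecord(genome_id=gid, sequence="".join(parts)))
            features.extend(feats)

    _check_planted_bounds(membership, table, features, within_j_min, between_j_max)

    truth = {
        "clusters": membership,
        "core_ogs": core_truth,
        "exclusive_ogs": exclusive_truth,
        "within_j_min": within_j_min,
        "between_j_max": between_j_max,
        "seed": seed,
    }
    result = GenomeSetResult(genomes=genomes, features=features, table=table, truth=truth)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        result.paths = {
            "fasta": out / "genomes.fasta",
            "gff3": out / "genomes.gff3",
            "orthologs": out / "orthologs.tsv",
            "truth": out / "truth.json",
        }
        write_fasta(genomes, result.paths["fasta"])
        write_gff3(features, result.paths["gff3"])
        write_ortholog_table(table, result.paths["orthologs"])
        result.paths["truth"].write_text(json.dumps(truth, indent=2, sort_keys=True))
    return result


def _check_planted_bounds(membership, table, features, within_j_min, between_j_max):
    from .ortho_cluster import jaccard, og_set

    by_genome: dict[str, list[GeneFeature]] = {}
    for f in features:
        by_genome.setdefault(f.genome_id, []).append(f)
    sets = {g: og_set(fs, table, genome_id=g) for g, fs in by_genome.items()}
    cluster_of = {g: c for c, ms in membership.items() for g in ms}
    ids = sorted(sets)
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            j = jaccard(sets[a], sets[b])
            if cluster_of[a] == cluster_of[b]:
                if j < within_j_min:
                    raise ValidationError(
                        f"planted within-cluster J({a},{b})={j:.3f} < {within_j_min}; "
                        "increase core_ogs_per_cluster or reduce noise_singletons"
                    )
            elif j > between_j_max:
                raise ValidationError(
                    f"planted between-cluster J({a},{b})={j:.3f} > {between_j_max}"
                )


# ---------------------------------------------------------------------------
# CDS sets with a specified synonymous codon-usage profile


@dataclass
class BiasedCDSResult:
    genome: GenomeRecord
    features: list[GeneFeature]
    gene_sequences: dict[str, str]
    truth: dict
    paths: dict[str, Path] = field(default_factory=dict)


def gen_cds_biased(
    target_usage: Mapping[str, float],
    n_genes: int = 50,
    mean_length_codons: int = 100,
    seed: int = 0,
    code: GeneticCode = STANDARD_CODE,
    genome_id: str = "biased_genome",
    out_dir: str | Path | None = None,
) -> BiasedCDSResult:
    """CDS set whose synonymous codon usage follows *target_usage*.

    Amino acids are drawn uniformly; within each family the codon is
    drawn from the target profile. An initiator AUG and one terminal stop
    (UAA) frame every gene. Families whose target fractions sum to zero
    are an error.
    """
    if n_genes < 1 or mean_length_codons < 2:
        raise ValidationError("need n_genes >= 1 and mean_length_codons >= 2")
    usage = {c.upper().replace("T", "U"): f for c, f in target_usage.items()}
    family_probs: dict[str, tuple[list[str], np.ndarray]] = {}
    for aa, codons in code.family.items():
        probs = np.array([usage.get(c, 0.0) for c in codons], dtype=float)
        if probs.sum() <= 0:
            raise ValidationError(f"target usage sums to zero for amino acid {aa!r}")
        family_probs[aa] = (list(codons), probs / probs.sum())

    rng = np.random.default_rng(seed)
    aas = sorted(code.family)
    gene_sequences: dict[str, str] = {}
    features: list[GeneFeature] = []
    parts: list[str] = []
    pos = 0
    for i in range(n_genes):
        length = max(2, int(rng.poisson(mean_length_codons)))
        aa_seq = rng.choice(aas, size=length - 1)
        body = np.empty(length - 1, dtype=object)
        for aa in aas:  # batch draw per family keeps this fast at 1e5+ codons
            idx = np.flatnonzero(aa_seq == aa)
            if idx.size:
                syn, probs = family_probs[aa]
                body[idx] = rng.choice(syn, size=idx.size, p=probs)
        codons = ["AUG", *body.tolist(), "UAA"]
        dna = "".join(codons).replace("U", "T")
        gene_id = f"{genome_id}_{i + 1:04d}"
        gene_sequences[gene_id] = dna
        spacer = _spacer(rng, 20)
        features.append(
            GeneFeature(
                gene_id=gene_id, genome_id=genome_id,
                start=pos, end=pos + len(dna), strand="+", kind="CDS",
                product="synthetic biased CDS",
            )
        )
        parts.append(dna + spacer)
        pos += len(dna) + len(spacer)
    genome = GenomeRecord(genome_id=genome_id, sequence="".join(parts))
    truth = {"target_usage": usage, "n_genes": n_genes, "seed": seed}
    result = BiasedCDSResult(
        genome=genome, features=features, gene_sequences=gene_sequences, truth=truth
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        result.paths = {
            "fasta": out / "biased.fasta",
            "gff3": out / "biased.gff3",
            "truth": out / "truth.json",
        }
        write_fasta([genome], result.paths["fasta"])
        write_gff3(features, result.paths["gff3"])
        result.paths["truth"].write_text(json.dumps(truth, indent=2, sort_keys=True))
    return result


# ---------------------------------------------------------------------------
# Lagged phage/host abundance time series


@dataclass
class TimeseriesResult:
    counts: pd.DataFrame
    genome_lengths: dict[str, int]
    host_series: np.ndarray
    phage_series: np.ndarray
    truth: dict
    paths: dict[str, Path] = field(default_factory=dict)


def gen_timeseries(
    n_points: int = 20,
    lag: int = 1,
    coupling: float = 0.9,
    noise_sd: float = 0.1,
    baseline: float = 0.001,
    seed: int = 0,
    total_reads: int = 1_000_000,
    host_length: int = 2_000_000,
    phage_length: int = 50_000,
    host_id: str = "host",
    phage_id: str = "phage",
    out_dir: str | Path | None = None,
) -> TimeseriesResult:
    """Host/phage abundance counts where the phage lags the host.

    The host series is a smooth positive random walk around *baseline*
    (in RA% units); the phage series is ``coupling * host`` shifted
    forward by *lag* time points plus Gaussian noise with standard
    deviation ``noise_sd * sd(host)``. Series are converted to integer
    mapped-read counts under the stated totals and genome lengths.
    """
    if lag < 0:
        raise ValidationError("lag must be non-negative")
    if lag >= n_points:
        raise ValidationError(f"lag ({lag}) must be smaller than n_points ({n_points})")
    if n_points < lag + 4:
        raise ValidationError("need n_points >= lag + 4")
    rng = np.random.default_rng(seed)
    # mean-reverting walk: a pure random walk is so autocorrelated that
    # neighboring delays become indistinguishable to LSA
    host = np.empty(n_points)
    host[0] = baseline
    for t in range(1, n_points):
        host[t] = baseline + 0.6 * (host[t - 1] - baseline) + rng.normal(0.0, 0.3 * baseline)
    host = np.clip(host, 0.05 * baseline, None)

    shifted = np.empty(n_points)
    shifted[lag:] = host[: n_points - lag]
    shifted[:lag] = host[0]
    scale = float(np.std(host)) or baseline
    phage = coupling * shifted + rng.normal(0.0, noise_sd * scale, size=n_points)
    phage = np.clip(phage, 0.01 * baseline, None)

    rows = []
    for t in range(n_points):
        for target, series, length in (
            (host_id, host, host_length),
            (phage_id, phage, phage_length),
        ):
            # invert RA% = 100 * (m/T) / (L/1000)
            mapped = int(round(series[t] / 100.0 * total_reads * length / 1000.0))
            mapped = min(max(mapped, 0), total_reads)
            rows.append(
                {
                    "sample_id": f"S{t:03d}",
                    "time_index": t,
                    "total_reads": total_reads,
                    "target_id": target,
                    "mapped_reads": mapped,
                }
            )
    counts = pd.DataFrame(rows)
    truth = {
        "lag": lag,
        "coupling": coupling,
        "noise_sd": noise_sd,
        "baseline": baseline,
        "seed": seed,
        "host_id": host_id,
        "phage_id": phage_id,
    }
    result = TimeseriesResult(
        counts=counts,
        genome_lengths={host_id: host_length, phage_id: phage_length},
        host_series=host,
        phage_series=phage,
        truth=truth,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        result.paths = {
            "counts": out / "counts.tsv",
            "lengths": out / "genome_lengths.tsv",
            "truth": out / "truth.json",
        }
        counts.to_csv(result.paths["counts"], sep="\t", index=False)
        pd.DataFrame(
            {"target_id": [host_id, phage_id], "length_bp": [host_length, phage_length]}
        ).to_csv(result.paths["lengths"], sep="\t", index=False)
        result.paths["truth"].write_text(json.dumps(truth, indent=2, sort_keys=True))
    return result
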