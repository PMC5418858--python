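"""Gene-sharing similarity and reference-anchored clustering of phage genomes.

Similarity between two genomes is the Jaccard index of their ortholog-group
(OG) identifier sets: J(A, B) = |A n B| / |A u B|. Paralogs within a genome
collapse to a single OG element. Genes without an OG assignment can be kept
as unique "singleton:<gene_id>" elements, which inflate the union and thus
reflect genuine dissimilarity.

Clustering is reference-anchored: a cluster is the set of genomes whose
Jaccard similarity to a chosen reference meets a cutoff (boundary included).
No transitive closure is applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ValidationError
from .genome_model import GeneFeature, OrthologTable

logger = logging.getLogger(__name__)

SINGLETON_PREFIX = "singleton:"


@dataclass(frozen=True)
class OGSet:
    """Per-genome set of ortholog-group identifiers."""

    genome_id: str
    ogs: frozenset[str]

    def __len__(self) -> int:
        return len(self.ogs)


@dataclass(frozen=True)
class ClusterResult:
    """Reference-anchored cluster: members with J(ref, X) >= cutoff."""

    reference_id: str
    members: tuple[tuple[str, float], ...]
    cutoff: float

    @property
    def member_ids(self) -> tuple[str, ...]:
        return tuple(g for g, _ in self.members)

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class OGConservationRow:
    og_id: str
    n_genes: int
    n_genomes: int


def gene_og_assignments(
    features: Iterable[GeneFeature],
    table: OrthologTable,
    include_singletons: bool = True,
) -> dict[str, str]:
    """Map each gene of one genome to its OG id.

    Unassigned genes become unique ``singleton:<gene_id>`` entries when
    *include_singletons* is true, and are dropped otherwise. Only CDS and
    tRNA features are considered genes.
    """
    assignments: dict[str, str] = {}
    for feat in features:
        if feat.kind == "other":
            continue
        og = table.og_of(feat.gene_id)
        if og is None:
            if include_singletons:
                assignments[feat.gene_id] = SINGLETON_PREFIX + feat.gene_id
        else:
            assignments[feat.gene_id] = og
    return assignments


def og_set(
    features: Iterable[GeneFeature],
    table: OrthologTable,
    include_singletons: bool = True,
    genome_id: str | None = None,
) -> OGSet:
    """Ortholog-group set of a genome's annotated genes."""
    features = list(features)
    if genome_id is None:
        genome_ids = {f.genome_id for f in features}
        if len(genome_ids) > 1:
            raise ValidationError(
                f"features span multiple genomes {sorted(genome_ids)}; pass genome_id"
            )
        genome_id = genome_ids.pop() if genome_ids else "<empty>"
    assignments = gene_og_assignments(features, table, include_singletons)
    if not assignments:
        logger.warning("genome %s: no OG-assignable genes", genome_id)
    return OGSet(genome_id=genome_id, ogs=frozenset(assignments.values()))


def jaccard(a: OGSet | frozenset[str] | set[str], b: OGSet | frozenset[str] | set[str]) -> float:
    """Jaccard index |A n B| / |A u B|; defined as 0 when both sets are empty."""
    sa = a.ogs if isinstance(a, OGSet) else frozenset(a)
    sb = b.ogs if isinstance(b, OGSet) else frozenset(b)
    union = len(sa | sb)
    if union == 0:
        return 0.0
    return len(sa & sb) / union


def build_cluster(
    reference_id: str,
    og_sets: Mapping[str, OGSet],
    cutoff: float = 0.1,
) -> ClusterResult:
    """Group genomes with J(reference, X) >= cutoff around a reference.

    Members are sorted by J descending, ties broken by genome_id. The
    boundary value J == cutoff is included.
    """
    if reference_id not in og_sets:
        raise ValidationError(f"reference genome {reference_id!r} not among candidates")
    ref = og_sets[reference_id]
    members = [
        (gid, jaccard(ref, s)) for gid, s in og_sets.items() if jaccard(ref, s) >= cutoff
    ]
    members.sort(key=lambda m: (-m[1], m[0]))
    return ClusterResult(reference_id=reference_id, members=tuple(members), cutoff=cutoff)


def conservation_table(
    cluster: ClusterResult,
    assignments: Mapping[str, Mapping[str, str]],
) -> list[OGConservationRow]:
    """Per-OG gene and genome counts over a cluster's members.

    *assignments* maps genome_id -> (gene_id -> og_id), as produced by
    :func:`gene_og_assignments`. Rows are sorted by n_genomes descending,
    then n_genes descending, then og_id.
    """
    genes_per_og: dict[str, int] = {}
    genomes_per_og: dict[str, set[str]] = {}
    for gid in cluster.member_ids:
        for og in assignments.get(gid, {}).values():
            genes_per_og[og] = genes_per_og.get(og, 0) + 1
            genomes_per_og.setdefault(og, set()).add(gid)
    rows = [
        OGConservationRow(og_id=og, n_genes=n, n_genomes=len(genomes_per_og[og]))
        for og, n in genes_per_og.items()
    ]
    rows.sort(key=lambda r: (-r.n_genomes, -r.n_genes, r.og_id))
    return rows


def core_ogs(cluster: ClusterResult, og_sets: Mapping[str, OGSet]) -> set[str]:
    """OGs present in every member genome of the cluster."""
    if len(cluster) == 0:
        raise ValidationError("cluster has no members")
    sets = [og_sets[gid].ogs for gid in cluster.member_ids]
    core = set(sets[0])
    for s in sets[1:]:
        core &= s
    return core


def exclusive_ogs(
    subset: Iterable[str],
    cluster: ClusterResult,
    og_sets: Mapping[str, OGSet],
) -> set[str]:
    """OGs carried by every genome of *subset* and by no other cluster member."""
    subset = set(subset)
    members = set(cluster.member_ids)
    if not subset <= members:
        raise ValidationError(
            f"subset {sorted(subset - members)} not within cluster members"
        )
    if not subset:
        raise ValidationError("subset is empty")
    shared: set[str] | None = None
    for gid in sorted(subset):
        shared = set(og_sets[gid].ogs) if shared is None else shared & og_sets[gid].ogs
    assert shared is not None
    for gid in members - subset:
        shared -= og_sets[gid].ogs
    return shared


def pairwise_jaccard(og_sets: Mapping[str, OGSet]) -> pd.DataFrame:
    """Full symmetric Jaccard matrix over a genome collection."""
    ids = sorted(og_sets)
    mat = [[jaccard(og_sets[a], og_sets[b]) for b in ids] for a in ids]
    return pd.DataFrame(mat, index=ids, columns=ids)


def cluster_frame(cluster: ClusterResult) -> pd.DataFrame:
    return pd.DataFrame(cluster.members, columns=["genome_id", "jaccard"])


def conservation_frame(rows: Sequence[OGConservationRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.og_id, r.n_genes, r.n_genomes) for r in rows],
        columns=["og_id", "n_genes", "n_genomes"],
    )
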