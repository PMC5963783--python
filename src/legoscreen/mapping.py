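"""Map transforming tags to transcripts and choose a minimal explaining set.

Tags are mapped to the reference the way the enzymatic model produces them:
a guide is the first ``stem_len`` nt read away from an AluI cut, on either
strand, so the default lookup is an exact match against the enumerated
per-site guides of every database transcript. Redundant transcripts
(>=95% identity, >=90% single-sided coverage) are merged into clusters;
the minimal set of clusters explaining all tags is found by breadth-first
enumeration over subset sizes (maximum parsimony); clusters then pass a
>15% AluI-site coverage filter and an ambiguity filter (clusters mixing
gene labels are omitted).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import edlib
import networkx as nx
import pandas as pd
from Bio import Align

from .config import Config
from .errors import ValidationError
from .io import Transcript, reverse_complement
from .library import alui_sites, enumerate_vectors

logger = logging.getLogger(__name__)

#: above this many candidate clusters the exact breadth-first cover search
#: falls back to greedy (2^24 subsets is the practical enumeration bound).
EXACT_COVER_LIMIT = 24


@dataclass(frozen=True)
class TagHit:
    transcript_id: str
    site_index: int
    side: str


class TargetDB:
    """Searchable transcript database for tag lookup.

    Transcripts with more than ``max_alui_sites_db`` AluI sites are excluded
    (repeat-dense entries would soak up tags). The index maps every
    realizable guide to its (transcript, site, side) origins.
    """

    def __init__(self, transcripts: Sequence[Transcript], config: Config | None = None):
        config = config or Config()
        self.config = config
        self.transcripts: dict[str, Transcript] = {}
        self.site_counts: dict[str, int] = {}
        self.guide_index: dict[str, list[TagHit]] = {}
        n_excluded = 0
        for t in transcripts:
            n_sites = len(alui_sites(t.seq))
            if n_sites > config.max_alui_sites_db:
                n_excluded += 1
                continue
            self.transcripts[t.id] = t
            self.site_counts[t.id] = n_sites
            for v in enumerate_vectors(t, config):
                if v.realizable:
                    self.guide_index.setdefault(v.guide, []).append(
                        TagHit(v.transcript_id, v.site_index, v.side)
                    )
        if not self.transcripts:
            raise ValidationError("empty database after AluI-site filtering")
        logger.info(
            "build_db: %d transcripts indexed, %d excluded (>%d AluI sites)",
            len(self.transcripts), n_excluded, config.max_alui_sites_db,
        )

    def max_possible_vectors(self, transcript_id: str) -> int:
        return 2 * self.site_counts[transcript_id]


def build_db(transcripts: Sequence[Transcript], config: Config | None = None) -> TargetDB:
    return TargetDB(transcripts, config)


def _substring_hits(tag: str, db: TargetDB, max_mismatches: int) -> list[TagHit]:
    """Mismatch-tolerant, cut-agnostic lookup (for reference-free inputs)."""
    hits = []
    for t in db.transcripts.values():
        for query in (tag, reverse_complement(tag)):
            res = edlib.align(query, t.seq, mode="HW", task="distance", k=max_mismatches)
            if res["editDistance"] != -1:
                hits.append(TagHit(t.id, -1, "substring"))
                break
    return hits


def map_tags(
    tags: Iterable[str],
    db: TargetDB,
    config: Config | None = None,
    require_cut: bool = True,
) -> dict[str, list[TagHit]]:
    """Tag → hit sets; multi-hit tags retain all hits, unmapped map to []."""
    config = config or db.config
    out: dict[str, list[TagHit]] = {}
    for tag in tags:
        if require_cut and config.max_map_mismatches == 0:
            out[tag] = list(db.guide_index.get(tag, []))
        else:
            hits = list(db.guide_index.get(tag, []))
            if not hits:
                hits = _substring_hits(tag, db, config.max_map_mismatches)
            out[tag] = hits
    n_unmapped = sum(1 for h in out.values() if not h)
    logger.info("map_tags: %d tags, %d unmapped", len(out), n_unmapped)
    return out


@dataclass
class TranscriptCluster:
    """A redundancy cluster of near-identical transcripts."""

    cluster_id: str
    members: tuple[str, ...]
    representative: str
    gene_labels: tuple[str, ...]
    alui_sites: int
    explained_tags: frozenset[str] = frozenset()

    @property
    def max_possible_vectors(self) -> int:
        return 2 * self.alui_sites

    @property
    def ambiguous(self) -> bool:
        return len(set(self.gene_labels)) >= 2


_aligner = Align.PairwiseAligner()
_aligner.mode = "local"
_aligner.match_score = 1.0
_aligner.mismatch_score = -2.0
_aligner.open_gap_score = -2.5
_aligner.extend_gap_score = -0.5


def pairwise_identity(seq_a: str, seq_b: str) -> tuple[float, float]:
    """(identity, single-sided coverage) of the best local alignment.

    Coverage is the aligned span of the *shorter* sequence over its length;
    identity is the fraction of matching columns within that span.
    """
    shorter, longer = (seq_a, seq_b) if len(seq_a) <= len(seq_b) else (seq_b, seq_a)
    try:
        aln = _aligner.align(shorter, longer)[0]
    except IndexError:
        return 0.0, 0.0
    q_blocks = aln.aligned[0]
    if len(q_blocks) == 0:
        return 0.0, 0.0
    matches = sum(
        1
        for qb, tb in zip(aln.aligned[0], aln.aligned[1])
        for qi, ti in zip(range(qb[0], qb[1]), range(tb[0], tb[1]))
        if shorter[qi] == longer[ti]
    )
    span = int(q_blocks[-1][1] - q_blocks[0][0])
    if span == 0:
        return 0.0, 0.0
    return matches / span, span / len(shorter)


def cluster_transcripts(
    transcripts: Sequence[Transcript],
    config: Config | None = None,
) -> list[TranscriptCluster]:
    """Connected-component clustering at >=95% identity, >=90% coverage.

    The representative is the longest member (ties broken by id); cluster
    membership is invariant to input order.
    """
    config = config or Config()
    ts = sorted(transcripts, key=lambda t: t.id)
    g = nx.Graph()
    g.add_nodes_from(t.id for t in ts)
    for a, b in itertools.combinations(ts, 2):
        identity, coverage = pairwise_identity(a.seq, b.seq)
        if identity >= config.identity_min and coverage >= config.coverage_min:
            g.add_edge(a.id, b.id)
    by_id = {t.id: t for t in ts}
    clusters = []
    components = sorted(nx.connected_components(g), key=lambda c: sorted(c)[0])
    for i, comp in enumerate(components):
        members = tuple(sorted(comp))
        rep = max(members, key=lambda tid: (by_id[tid].length, tid))
        clusters.append(
            TranscriptCluster(
                cluster_id=f"C{i:04d}",
                members=members,
                representative=rep,
                gene_labels=tuple(by_id[m].gene_label for m in members),
                alui_sites=len(alui_sites(by_id[rep].seq)),
            )
        )
    return clusters


def attach_tags(
    clusters: Sequence[TranscriptCluster],
    tag_hits: Mapping[str, Sequence[TagHit]],
) -> list[TranscriptCluster]:
    """Annotate each cluster with the tags any of its members explains."""
    out = []
    for c in clusters:
        member_set = set(c.members)
        explained = frozenset(
            tag for tag, hits in tag_hits.items() if any(h.transcript_id in member_set for h in hits)
        )
        out.append(
            TranscriptCluster(
                cluster_id=c.cluster_id,
                members=c.members,
                representative=c.representative,
                gene_labels=c.gene_labels,
                alui_sites=c.alui_sites,
                explained_tags=explained,
            )
        )
    return out


def _greedy_cover(universe: frozenset, clusters: Sequence[TranscriptCluster]) -> list[TranscriptCluster]:
    remaining = set(universe)
    chosen = []
    pool = list(clusters)
    while remaining:
        best = max(pool, key=lambda c: (len(c.explained_tags & remaining), -int(c.cluster_id[1:]) if c.cluster_id[1:].isdigit() else 0))
        gain = len(best.explained_tags & remaining)
        if gain == 0:
            break
        chosen.append(best)
        remaining -= best.explained_tags
        pool.remove(best)
    return chosen


def minimal_cluster_set(
    clusters: Sequence[TranscriptCluster],
    tags: Iterable[str],
) -> list[TranscriptCluster]:
    """Exact minimum-cardinality set cover by breadth-first enumeration.

    Subset sizes are tried in increasing order; among covers of the minimal
    size, ties are broken by (more total tags explained, then lexicographic
    cluster ids). Instances with more than 24 candidate clusters fall back
    to a greedy cover with a logged warning.
    """
    universe = frozenset(tags)
    if not universe:
        return []
    candidates = [c for c in clusters if c.explained_tags & universe]
    covered = frozenset().union(*(c.explained_tags for c in candidates)) if candidates else frozenset()
    orphans = universe - covered
    if orphans:
        raise ValidationError(f"tags not explained by any cluster: {sorted(orphans)}")
    if len(candidates) > EXACT_COVER_LIMIT:
        logger.warning(
            "minimal_cluster_set: %d candidate clusters > %d, falling back to greedy cover",
            len(candidates), EXACT_COVER_LIMIT,
        )
        return _greedy_cover(universe, candidates)
    masks = []
    tag_bit = {t: 1 << i for i, t in enumerate(sorted(universe))}
    full = (1 << len(universe)) - 1
    for c in candidates:
        m = 0
        for t in c.explained_tags & universe:
            m |= tag_bit[t]
        masks.append(m)
    order = range(len(candidates))
    for size in range(1, len(candidates) + 1):
        covers = []
        for combo in itertools.combinations(order, size):
            acc = 0
            for i in combo:
                acc |= masks[i]
            if acc == full:
                covers.append(combo)
        if covers:
            def tie_key(combo: tuple[int, ...]):
                total_tags = sum(len(candidates[i].explained_tags) for i in combo)
                ids = tuple(sorted(candidates[i].cluster_id for i in combo))
                return (-total_tags, ids)

            best = min(covers, key=tie_key)
            return [candidates[i] for i in best]
    raise ValidationError("no cover found")  # unreachable: orphans checked above


@dataclass
class FilterReport:
    surviving: list[TranscriptCluster]
    removed: list[tuple[TranscriptCluster, str]]


def filter_alui_coverage(
    clusters: Sequence[TranscriptCluster],
    config: Config | None = None,
) -> FilterReport:
    """Keep clusters whose distinct transforming tags exceed 15% of the
    representative's theoretical vector maximum; drop ambiguous clusters
    (members from multiple gene copies) and zero-site representatives."""
    config = config or Config()
    surviving, removed = [], []
    for c in clusters:
        if c.alui_sites == 0:
            logger.warning("cluster %s: representative has no AluI sites, removed", c.cluster_id)
            removed.append((c, "no AluI sites"))
            continue
        if c.ambiguous:
            removed.append((c, "ambiguous: multiple gene labels"))
            continue
        coverage = len(c.explained_tags) / c.max_possible_vectors
        if coverage > config.alui_coverage_min:
            surviving.append(c)
        else:
            removed.append((c, f"AluI-site coverage {coverage:.3f} <= {config.alui_coverage_min}"))
    logger.info("filter_alui_coverage: %d surviving, %d removed", len(surviving), len(removed))
    return FilterReport(surviving=surviving, removed=removed)


def clusters_to_tsv(
    report_rows: Iterable[tuple[TranscriptCluster, str]],
    path: str | Path,
) -> None:
    """Cluster report: (cluster, status) pairs → TSV."""
    rows = []
    for c, status in report_rows:
        rows.append(
            {
                "cluster_id": c.cluster_id,
                "representative": c.representative,
                "members": ",".join(c.members),
                "gene_labels": ",".join(sorted(set(c.gene_labels))),
                "n_tags": len(c.explained_tags),
                "alui_sites": c.alui_sites,
                "coverage_pct": (
                    100.0 * len(c.explained_tags) / c.max_possible_vectors
                    if c.alui_sites else float("nan")
                ),
                "status": status,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
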