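"""Dual-library suppressor criterion, ranking score, expression flags.

A transcript cluster becomes a suppressor candidate when at least three
distinct transforming vectors hit it in *each* of the two independently
screened libraries. Candidates are ranked by

    score = n_total × pct,   pct = round(100 · n_total / max_possible)

where ``max_possible`` is the theoretical vector maximum of the cluster
representative (2 per AluI site) and the percentage is rounded half-up to
an integer before the multiplication, so scores are exact integer products
of the two reported columns. Expression flags mark repression/induction
strictly greater than 1.66-fold.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .config import Config
from .errors import ValidationError
from .mapping import TagHit, TranscriptCluster

logger = logging.getLogger(__name__)


def round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass
class SuppressorRecord:
    """One row of the final ranked suppressor profile."""

    gene_label: str
    n_vectors_lib1: int
    n_vectors_lib2: int
    n_vectors_total: int
    max_possible_vectors: int | None = None
    n_realizable_vectors: int | None = None
    pct_transforming: int | None = None
    ranking_score: int | None = None
    repression_fold_genotype1: float | None = None
    repression_fold_genotype2: float | None = None
    induction_fold_anchor_loss: float | None = None
    repressed_g1: bool | None = None
    repressed_g2: bool | None = None
    induced: bool | None = None
    cluster_id: str = ""


def _distinct_vectors(
    cluster: TranscriptCluster,
    tag_hits: Mapping[str, Sequence[TagHit]],
    tags: Iterable[str],
) -> set:
    """Distinct (transcript, AluI site, side) identities among the given tags.

    Duplicate tags hitting the same site/side count once; reference-free
    substring hits fall back to tag identity.
    """
    members = set(cluster.members)
    out = set()
    for tag in tags:
        for h in tag_hits.get(tag, []):
            if h.transcript_id in members:
                key = (h.transcript_id, h.site_index, h.side) if h.side != "substring" else ("tag", tag)
                out.add(key)
    return out


def classify_suppressors(
    clusters: Sequence[TranscriptCluster],
    tag_hits: Mapping[str, Sequence[TagHit]],
    transforming_tags: Mapping[str, set],
    config: Config | None = None,
) -> list[SuppressorRecord]:
    """Keep clusters with >=3 distinct transforming vectors in both libraries.

    ``transforming_tags`` maps each of the two library names to its set of
    transforming tag sequences.
    """
    config = config or Config()
    libraries = sorted(transforming_tags)
    if len(libraries) != 2:
        raise ValidationError(f"dual-library criterion needs exactly 2 libraries, got {libraries}")
    lib1, lib2 = libraries
    records = []
    for c in clusters:
        v1 = _distinct_vectors(c, tag_hits, transforming_tags[lib1] & c.explained_tags)
        v2 = _distinct_vectors(c, tag_hits, transforming_tags[lib2] & c.explained_tags)
        if len(v1) >= config.min_vectors_per_library and len(v2) >= config.min_vectors_per_library:
            labels = set(c.gene_labels)
            if len(labels) != 1:
                raise ValidationError(f"cluster {c.cluster_id} is ambiguous; filter before classification")
            records.append(
                SuppressorRecord(
                    gene_label=labels.pop(),
                    n_vectors_lib1=len(v1),
                    n_vectors_lib2=len(v2),
                    n_vectors_total=len(v1 | v2),
                    max_possible_vectors=c.max_possible_vectors,
                    cluster_id=c.cluster_id,
                )
            )
    logger.info("classify_suppressors: %d/%d clusters pass the dual >=%d criterion",
                len(records), len(clusters), config.min_vectors_per_library)
    return records


def score_and_rank(records: Sequence[SuppressorRecord]) -> list[SuppressorRecord]:
    """Fill pct/score and sort descending by score.

    The percentage is computed (rounded half-up) from ``max_possible_vectors``
    unless the record already carries one. Ties are broken by percentage
    descending, then input order (stable); records with a zero vector
    maximum are excluded with a warning.
    """
    scored = []
    for r in records:
        if r.pct_transforming is None:
            if not r.max_possible_vectors:
                logger.warning("record %s: zero possible vectors, excluded from ranking", r.gene_label)
                continue
            r.pct_transforming = round_half_up(100.0 * r.n_vectors_total / r.max_possible_vectors)
        r.ranking_score = r.n_vectors_total * r.pct_transforming
        scored.append(r)
    return sorted(scored, key=lambda r: (-r.ranking_score, -r.pct_transforming))


def annotate_expression(
    records: Sequence[SuppressorRecord],
    expression: pd.DataFrame,
    config: Config | None = None,
) -> list[SuppressorRecord]:
    """Attach fold changes and strict >1.66 flags from an expression table.

    Expected columns: gene, repression_fold_genotype1, repression_fold_genotype2,
    induction_fold_anchor_loss. Genes missing from the table keep null
    flags; malformed fold values are reported and skipped row-wise.
    """
    config = config or Config()
    by_gene: dict[str, dict] = {}
    for _, row in expression.iterrows():
        gene = row["gene"]
        try:
            by_gene[gene] = {
                "g1": float(row["repression_fold_genotype1"]),
                "g2": float(row["repression_fold_genotype2"]),
                "ind": float(row["induction_fold_anchor_loss"]),
            }
        except (TypeError, ValueError) as exc:
            logger.error("expression row for %s malformed (%s); skipped", gene, exc)
    thr = config.expr_fold_threshold
    for r in records:
        info = by_gene.get(r.gene_label)
        if info is None:
            continue
        r.repression_fold_genotype1 = info["g1"]
        r.repression_fold_genotype2 = info["g2"]
        r.induction_fold_anchor_loss = info["ind"]
        r.repressed_g1 = info["g1"] > thr
        r.repressed_g2 = info["g2"] > thr
        r.induced = info["ind"] > thr
    return list(records)


def hits_to_frame(records: Sequence[SuppressorRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": r.gene_label,
                "ranking": r.ranking_score,
                "n_vectors": r.n_vectors_total,
                "n_vectors_lib1": r.n_vectors_lib1,
                "n_vectors_lib2": r.n_vectors_lib2,
                "max_possible_vectors": r.max_possible_vectors,
                "n_realizable_vectors": r.n_realizable_vectors,
                "pct_transforming": r.pct_transforming,
                "repression_fold_genotype1": r.repression_fold_genotype1,
                "repression_fold_genotype2": r.repression_fold_genotype2,
                "induction_fold_anchor_loss": r.induction_fold_anchor_loss,
                "repressed_g1": r.repressed_g1,
                "repressed_g2": r.repressed_g2,
                "induced": r.induced,
            }
            for r in records
        ]
    )


def hits_to_tsv(records: Sequence[SuppressorRecord], path: str | Path) -> None:
    hits_to_frame(records).to_csv(path, sep="\t", index=False)
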