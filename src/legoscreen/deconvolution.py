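"""Turn sequencing reads of shRNA inserts into per-vector counts and calls.

A valid read contains a stem-loop-stem insert: ``stem_len`` nt, the known
9-nt loop, then the reverse complement of the stem. A read is accepted when
the loop can be located (exactly or with one substitution) and the joint
mismatch count — loop match plus stem/revcomp-stem complementarity — stays
within the configured allowance (default 1, covering one PCR artifact or
sequencing error). The canonical tag is the upstream stem read 5'→3'.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from .config import Config
from .errors import ConfigurationError, ValidationError
from .io import FastqRead, reverse_complement

logger = logging.getLogger(__name__)

CPM_SCALE = 1e6


def _hamming_leq(a: str, b: str, budget: int) -> int:
    """Mismatch count, or budget+1 as soon as it is exceeded."""
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > budget:
                return mm
    return mm


def _loop_candidates(seq: str, loop: str, stem_len: int, budget: int) -> Iterator[tuple[int, int]]:
    """Yield (position, loop_mismatches) for plausible loop placements."""
    lo, hi = stem_len, len(seq) - len(loop) - stem_len
    pos = seq.find(loop)
    exact: set[int] = set()
    while pos != -1:
        if lo <= pos <= hi:
            exact.add(pos)
            yield pos, 0
        pos = seq.find(loop, pos + 1)
    if budget >= 1:
        for p in range(lo, hi + 1):
            if p in exact:
                continue
            mm = _hamming_leq(seq[p : p + len(loop)], loop, 1)
            if mm <= 1:
                yield p, mm


def _resolve_tag(upstream: str, downstream_rc: str) -> str:
    # two stems give one vote each; the upstream base wins the tie
    if upstream == downstream_rc:
        return upstream
    return "".join(u if u == d else u for u, d in zip(upstream, downstream_rc))


def extract_tag(seq: str, config: Config) -> str | None:
    """Canonical tag of one read, or None if no acceptable structure exists.

    Both read orientations are tried; among acceptable loop placements the
    one with fewest total mismatches (leftmost on ties) wins.
    """
    loop, stem_len, budget = config.loop_seq, config.stem_len, config.max_tag_mismatches
    best: tuple[int, int, str] | None = None
    for oriented in (seq, reverse_complement(seq)):
        for pos, loop_mm in _loop_candidates(oriented, loop, stem_len, budget):
            up = oriented[pos - stem_len : pos]
            down = oriented[pos + len(loop) : pos + len(loop) + stem_len]
            if "N" in up or "N" in down:
                continue
            down_rc = reverse_complement(down)
            stem_mm = _hamming_leq(up, down_rc, budget - loop_mm)
            total = loop_mm + stem_mm
            if total <= budget and (best is None or total < best[0]):
                best = (total, pos, _resolve_tag(up, down_rc))
                if total == 0:
                    return best[2]
        if best is not None:
            break  # an acceptable structure in the forward orientation wins
    return best[2] if best else None


@dataclass
class ExtractionResult:
    counts: Counter
    n_reads: int
    n_accepted: int

    @property
    def n_discarded(self) -> int:
        return self.n_reads - self.n_accepted


def extract_tags(reads: Iterable[FastqRead | str], config: Config | None = None) -> ExtractionResult:
    """Count canonical tags over a read stream; discarded reads are tallied."""
    config = config or Config()
    if len(config.loop_seq) != config.loop_len:
        raise ConfigurationError("loop sequence length disagrees with configured loop length")
    counts: Counter = Counter()
    n_reads = n_accepted = 0
    for read in reads:
        seq = read if isinstance(read, str) else read.seq
        n_reads += 1
        tag = extract_tag(seq, config)
        if tag is not None:
            counts[tag] += 1
            n_accepted += 1
    logger.info("extract_tags: %d reads, %d accepted, %d discarded", n_reads, n_accepted, n_reads - n_accepted)
    return ExtractionResult(counts=counts, n_reads=n_reads, n_accepted=n_accepted)


def merge_error_tags(counts: Counter, min_ratio: float = 10.0) -> Counter:
    """Absorb tags into a Hamming-distance-1 neighbor at least ``min_ratio``
    times more abundant (sequencing-error correction)."""
    merged = Counter(counts)
    for tag in sorted(counts, key=lambda t: (counts[t], t)):
        count = merged.get(tag, 0)
        if count == 0:
            continue
        best_parent, best_count = None, 0
        for i, base in enumerate(tag):
            for alt in "ACGT":
                if alt == base:
                    continue
                neighbor = tag[:i] + alt + tag[i + 1 :]
                c = merged.get(neighbor, 0)
                if c >= min_ratio * count and c > best_count:
                    best_parent, best_count = neighbor, c
        if best_parent is not None:
            merged[best_parent] += count
            del merged[tag]
    return merged


class TagCountTable:
    """Canonical-tag counts per (library, sample).

    Samples are conventionally ``pre``, ``post1`` and ``post2``. Raw counts
    are kept; normalized counts scale every sample to one million.
    """

    def __init__(self) -> None:
        self._counts: dict[tuple[str, str], Counter] = {}

    def add_sample(self, library: str, sample: str, counts: Counter) -> None:
        self._counts[(library, sample)] = Counter(counts)

    @property
    def samples(self) -> list[tuple[str, str]]:
        return list(self._counts)

    def raw(self) -> pd.DataFrame:
        """Tags × (library, sample) raw count matrix (missing tags = 0)."""
        if not self._counts:
            return pd.DataFrame()
        df = pd.DataFrame(self._counts).fillna(0).astype(int)
        df.columns = pd.MultiIndex.from_tuples(df.columns, names=["library", "sample"])
        return df.sort_index()

    def cpm(self) -> pd.DataFrame:
        """Counts-per-million per sample; raw counts are retained in raw()."""
        raw = self.raw()
        totals = raw.sum(axis=0)
        if (totals == 0).any():
            empty = [c for c in raw.columns[totals == 0]]
            raise ValidationError(f"cannot normalize empty sample(s): {empty}")
        return raw / totals * CPM_SCALE

    def to_tsv(self, path: str | Path) -> None:
        raw = self.raw()
        flat = raw.copy()
        flat.columns = [f"{lib}.{smp}" for lib, smp in raw.columns]
        flat.index.name = "tag"
        flat.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TagCountTable":
        df = pd.read_csv(path, sep="\t", index_col="tag")
        table = cls()
        for col in df.columns:
            lib, smp = col.rsplit(".", 1)
            counts = Counter({t: int(c) for t, c in df[col].items() if c > 0})
            table.add_sample(lib, smp, counts)
        return table


def normalize_counts(table: TagCountTable) -> pd.DataFrame:
    """Counts-per-million normalization (idempotent on cpm input scale)."""
    return table.cpm()


@dataclass(frozen=True)
class TransformingCall:
    tag: str
    library: str
    enrichment_ratio: float
    is_transforming: bool


def call_transforming(
    table: TagCountTable,
    config: Config | None = None,
    pre: str = "pre",
    post: str = "post2",
) -> pd.DataFrame:
    """Per-library enrichment ratios and transforming calls.

    ``ratio = (post_cpm + eps) / (pre_cpm + eps)`` with a 0.5-cpm
    pseudocount so tags appearing from zero remain callable; transforming
    iff strictly greater than the 3-fold threshold.
    """
    config = config or Config()
    cpm = table.cpm()
    libraries = sorted({lib for lib, _ in table.samples})
    eps = config.pseudocount_cpm
    rows = []
    for lib in libraries:
        for sample in (pre, post):
            if (lib, sample) not in table.samples:
                raise ValidationError(f"library {lib}: missing sample '{sample}'")
        pre_cpm = cpm[(lib, pre)]
        post_cpm = cpm[(lib, post)]
        ratio = (post_cpm + eps) / (pre_cpm + eps)
        for tag in cpm.index:
            rows.append(
                {
                    "tag": tag,
                    "library": lib,
                    "pre_cpm": pre_cpm[tag],
                    "post_cpm": post_cpm[tag],
                    "enrichment_ratio": ratio[tag],
                    "is_transforming": bool(ratio[tag] > config.fold_enrichment_min),
                }
            )
    df = pd.DataFrame(rows)
    logger.info(
        "call_transforming: %d tag×library pairs, %d transforming",
        len(df), int(df["is_transforming"].sum()),
    )
    return df
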