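"""Tag mapping, redundancy clustering, minimal set cover, coverage filter."""

import itertools

import numpy as np
import pytest

from legoscreen import (
    Config,
    Transcript,
    ValidationError,
    build_db,
    cluster_transcripts,
    filter_alui_coverage,
    map_tags,
    minimal_cluster_set,
    reverse_complement,
)
from legoscreen.library import enumerate_vectors
from legoscreen.mapping import TranscriptCluster, attach_tags, pairwise_identity
from tests.conftest import random_transcript


def many_sites(n: int, tid: str = "rep") -> Transcript:
    return Transcript(tid, tid, "AGCT" * n + "A" * 50)


class TestTargetDB:
    def test_501_sites_excluded_500_retained(self):
        keeper = many_sites(500, "keep")
        dropped = many_sites(501, "drop")
        db = build_db([keeper, dropped])
        assert "keep" in db.transcripts and "drop" not in db.transcripts

    def test_empty_db_after_filter_rejected(self):
        with pytest.raises(ValidationError, match="empty database"):
            build_db([many_sites(501, "drop")])

    def test_planted_guide_lookup_returns_source(self, rng):
        t = random_transcript(rng, 2000, tid="src")
        db = build_db([t])
        vectors = [v for v in enumerate_vectors(t) if v.realizable]
        v = vectors[0]
        hits = db.guide_index[v.guide]
        assert any(h.transcript_id == "src" and h.site_index == v.site_index for h in hits)


class TestMapTags:
    def test_guide_at_cut_maps_and_scrambled_does_not(self, rng):
        t = random_transcript(rng, 2000, tid="src")
        db = build_db([t])
        v = next(v for v in enumerate_vectors(t) if v.realizable)
        scrambled = "".join(sorted(v.guide, reverse=True))
        hits = map_tags([v.guide, scrambled], db)
        assert hits[v.guide] and all(h.transcript_id == "src" for h in hits[v.guide])
        assert hits.get(scrambled) == [] or not hits[scrambled]

    def test_duplicated_transcripts_give_two_hits(self, rng):
        t = random_transcript(rng, 1000, tid="a")
        twin = Transcript("b", "geneB", t.seq)
        db = build_db([Transcript("a", "geneA", t.seq), twin])
        v = next(v for v in enumerate_vectors(t) if v.realizable)
        hits = map_tags([v.guide], db)[v.guide]
        assert {h.transcript_id for h in hits} == {"a", "b"}

    def test_interior_match_requires_cut_abutment(self, rng):
        # a 20-mer drawn from the middle of a fragment does not map by default
        t = random_transcript(rng, 2000, tid="src")
        db = build_db([t])
        interior = t.seq[31:51]
        if interior in db.guide_index:  # drew a guide by chance
            pytest.skip("interior window happened to abut a cut")
        assert map_tags([interior], db)[interior] == []
        cfg = Config(max_map_mismatches=1)
        hits = map_tags([interior], db, cfg, require_cut=False)
        assert any(h.transcript_id == "src" for h in hits[interior])


def mutate(seq: str, n: int, rng: np.random.Generator) -> str:
    positions = rng.choice(len(seq), size=n, replace=False)
    chars = list(seq)
    for p in positions:
        chars[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[chars[p]]
    return "".join(chars)


class TestClustering:
    def test_exact_copy_clusters_together(self, rng):
        t = random_transcript(rng, 600, tid="a")
        clusters = cluster_transcripts([t, Transcript("b", "g", t.seq)])
        assert len(clusters) == 1 and set(clusters[0].members) == {"a", "b"}

    def test_unrelated_sequences_stay_apart(self, rng):
        a = random_transcript(rng, 1000, tid="a")
        b = random_transcript(rng, 1000, tid="b")
        clusters = cluster_transcripts([a, b])
        assert len(clusters) == 2

    @pytest.mark.parametrize("n_subs,expected_clusters", [(50, 1), (60, 2)])
    def test_identity_threshold_at_95_percent(self, rng, n_subs, expected_clusters):
        base = random_transcript(rng, 1000, tid="a")
        variant = Transcript("b", "g", mutate(base.seq, n_subs, rng))
        clusters = cluster_transcripts([base, variant])
        assert len(clusters) == expected_clusters

    def test_identity_agrees_with_edit_distance_oracle(self, rng):
        import edlib

        base = random_transcript(rng, 400, tid="a")
        variant = mutate(base.seq, 12, rng)
        identity, coverage = pairwise_identity(base.seq, variant)
        d = edlib.align(base.seq, variant, mode="NW")["editDistance"]
        assert coverage > 0.9
        # local alignment may trim mismatched termini, never score worse
        assert identity == pytest.approx(1 - d / len(base.seq), abs=0.01)

    def test_short_near_identical_subsequence_respects_single_sided_coverage(self, rng):
        long_t = random_transcript(rng, 2000, tid="long")
        short = Transcript("short", "g", long_t.seq[100:1100])  # contained, full coverage of shorter
        clusters = cluster_transcripts([long_t, short])
        assert len(clusters) == 1

    def test_membership_invariant_to_input_order(self, rng):
        base = random_transcript(rng, 800, tid="a")
        ts = [base, Transcript("b", "g", mutate(base.seq, 10, rng)), random_transcript(rng, 700, tid="c")]
        members1 = {c.members for c in cluster_transcripts(ts)}
        members2 = {c.members for c in cluster_transcripts(ts[::-1])}
        assert members1 == members2

    def test_representative_is_longest_member(self, rng):
        long_t = random_transcript(rng, 1500, tid="long")
        short = Transcript("short", "g", long_t.seq[:1200])
        (cluster,) = cluster_transcripts([short, long_t])
        assert cluster.representative == "long"


def make_cluster(cid: str, tags: set, sites: int = 9, genes: tuple = ("g",)) -> TranscriptCluster:
    return TranscriptCluster(
        cluster_id=cid,
        members=(cid,),
        representative=cid,
        gene_labels=genes,
        alui_sites=sites,
        explained_tags=frozenset(tags),
    )


class TestMinimalClusterSet:
    def test_size_one_cover_preferred(self):
        clusters = [make_cluster("A", {"a", "b"}), make_cluster("B", {"a"})]
        assert [c.cluster_id for c in minimal_cluster_set(clusters, {"a", "b"})] == ["A"]

    def test_size_two_cover_with_tie_break(self):
        clusters = [
            make_cluster("A", {"a", "b"}),
            make_cluster("B", {"b", "c"}),
            make_cluster("C", {"c"}),
        ]
        chosen = {c.cluster_id for c in minimal_cluster_set(clusters, {"a", "b", "c"})}
        # brute force over all 8 subsets: {A,B} is the unique minimum
        assert chosen == {"A", "B"}

    def test_orphan_tags_reported(self):
        with pytest.raises(ValidationError, match="orphan|not explained"):
            minimal_cluster_set([make_cluster("A", {"a"})], {"a", "zzz"})

    def test_random_instances_match_exhaustive_minimum(self):
        rng = np.random.default_rng(2024)
        for _ in range(300):
            n_tags = int(rng.integers(3, 9))
            n_clusters = int(rng.integers(2, 13))
            universe = [f"t{i}" for i in range(n_tags)]
            sets = []
            for i in range(n_clusters):
                size = int(rng.integers(1, n_tags + 1))
                sets.append(set(rng.choice(universe, size=size, replace=False)))
            missing = set(universe) - set().union(*sets)
            if missing:
                sets[0] |= missing
            clusters = [make_cluster(f"C{i:02d}", s) for i, s in enumerate(sets)]
            result = minimal_cluster_set(clusters, set(universe))
            # oracle: exhaustive enumeration of all subsets
            best = min(
                (
                    len(combo)
                    for r in range(1, n_clusters + 1)
                    for combo in itertools.combinations(range(n_clusters), r)
                    if set().union(*(sets[i] for i in combo)) >= set(universe)
                ),
            )
            assert len(result) == best
            assert set().union(*(c.explained_tags for c in result)) >= set(universe)

    def test_greedy_fallback_beyond_limit(self, caplog):
        clusters = [make_cluster(f"C{i:02d}", {f"t{i}"}) for i in range(30)]
        universe = {f"t{i}" for i in range(30)}
        with caplog.at_level("WARNING"):
            result = minimal_cluster_set(clusters, universe)
        assert len(result) == 30
        assert any("greedy" in r.message for r in caplog.records)


class TestAluICoverageFilter:
    def test_three_tags_nine_sites_survives(self):
        c = make_cluster("A", {"x", "y", "z"}, sites=9)
        report = filter_alui_coverage([c])
        assert report.surviving == [c]  # 3/18 = 16.7% > 15%

    def test_two_tags_nine_sites_removed(self):
        c = make_cluster("A", {"x", "y"}, sites=9)
        report = filter_alui_coverage([c])
        assert report.surviving == [] and "coverage" in report.removed[0][1]

    def test_ambiguous_cluster_removed(self):
        c = make_cluster("A", {"x", "y", "z", "w"}, sites=2, genes=("geneX", "geneY"))
        report = filter_alui_coverage([c])
        assert report.surviving == [] and "ambiguous" in report.removed[0][1]

    def test_zero_site_representative_removed_with_warning(self, caplog):
        c = make_cluster("A", {"x"}, sites=0)
        with caplog.at_level("WARNING"):
            report = filter_alui_coverage([c])
        assert report.surviving == []

    def test_partition_is_exhaustive(self, rng):
        # every transforming tag is explained by a surviving cluster,
        # explained by a removed cluster, or unmapped — nothing vanishes
        t1 = random_transcript(rng, 1500, tid="t1")
        t2 = random_transcript(rng, 1500, tid="t2")
        db = build_db([t1, t2])
        guides = [v.guide for t in (t1, t2) for v in enumerate_vectors(t) if v.realizable]
        tags = guides[:6] + ["A" * 20]  # one unmappable tag
        tag_hits = map_tags(tags, db)
        mapped = {t for t, h in tag_hits.items() if h}
        unmapped = set(tags) - mapped
        clusters = attach_tags(cluster_transcripts([t1, t2]), tag_hits)
        selected = minimal_cluster_set(clusters, mapped)
        report = filter_alui_coverage(selected)
        explained = set().union(frozenset(), *(c.explained_tags for c in report.surviving))
        removed_explained = set().union(frozenset(), *(c.explained_tags for c, _ in report.removed))
        assert set(tags) == (explained | removed_explained | unmapped)
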