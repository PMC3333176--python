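"""BLAST parsing, score filtering, LCA assignment, min-support push-up."""

import numpy as np
import pytest

from silvamap import (
    AssignmentParams,
    BlastHit,
    MappingFile,
    ParseError,
    TaxonomicProfile,
    apply_min_support,
    assign_read,
    collapse_at_rank,
    filter_hits,
    parse_blast_tabular,
    read_profile,
    run_assignment,
    write_profile,
)
from silvamap.assignment import (
    STATUS_ASSIGNED,
    STATUS_LOW_SCORE,
    STATUS_NO_HITS,
    STATUS_UNMAPPED,
)

from conftest import iterative_min_support, random_tree


def hit(acc="A1", score=200.0, query="r1"):
    return BlastHit(query, acc, 98.0, 250, 1e-50, score)


class TestParseBlastTabular:
    def test_single_line(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text("r1\tACC1\t98.5\t250\t4\t0\t1\t250\t1\t250\t1e-100\t200.0\n")
        hits = parse_blast_tabular(path)
        assert list(hits) == ["r1"]
        assert hits["r1"][0].subject_accession == "ACC1"
        assert hits["r1"][0].bit_score == 200.0

    def test_empty_file(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text("")
        assert parse_blast_tabular(path) == {}

    def test_wrong_column_count_reports_line(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text("r1\tACC1\t98.5\n")
        with pytest.raises(ParseError, match=":1:"):
            parse_blast_tabular(path)

    def test_groups_match_generator_manifest(self, bundle):
        paths, manifest = bundle
        hits = parse_blast_tabular(paths["blast"])
        assert set(hits) == {read_id for read_id, _, _ in manifest.reads}
        # top-scoring hit of every read is its true source accession
        for read_id, accession, _ in manifest.reads:
            best = max(hits[read_id], key=lambda h: h.bit_score)
            assert best.subject_accession == accession


class TestFilterHits:
    def test_top_percent_band(self):
        hits = [hit(f"A{i}", s) for i, s in enumerate([200.0, 185.0, 150.0])]
        kept = filter_hits(hits, AssignmentParams())
        assert [h.bit_score for h in kept] == [200.0, 185.0]  # threshold 180

    def test_all_below_min_score(self):
        hits = [hit("A1", 80.0), hit("A2", 119.9)]
        assert filter_hits(hits, AssignmentParams()) == []

    def test_single_survivor_is_kept(self):
        hits = [hit("A1", 120.0)]
        assert filter_hits(hits, AssignmentParams()) == hits

    def test_matches_direct_arithmetic_on_random_scores(self):
        rng = np.random.default_rng(99)
        params = AssignmentParams()
        for _ in range(300):
            scores = rng.uniform(50, 400, size=int(rng.integers(1, 12)))
            hits = [hit(f"A{i}", float(s)) for i, s in enumerate(scores)]
            kept = {h.subject_accession for h in filter_hits(hits, params)}
            surviving = scores[scores >= 120.0]
            if surviving.size == 0:
                assert kept == set()
            else:
                threshold = surviving.max() * 0.9
                expected = {
                    f"A{i}"
                    for i, s in enumerate(scores)
                    if s >= 120.0 and s >= threshold
                }
                assert kept == expected

    def test_raising_min_score_never_keeps_more(self):
        rng = np.random.default_rng(3)
        scores = rng.uniform(50, 400, size=8)
        hits = [hit(f"A{i}", float(s)) for i, s in enumerate(scores)]
        sizes = [
            len(filter_hits(hits, AssignmentParams(min_score=ms)))
            for ms in (80, 120, 200, 300)
        ]
        assert sizes == sorted(sizes, reverse=True)


class TestAssignRead:
    @pytest.fixture()
    def mapping(self):
        # accessions onto the small_tree fixture: species 6, 7, and 11
        return MappingFile(rows={"A6": 6, "A7": 7, "A11": 11})

    def test_single_hit_identity(self, small_tree, mapping):
        result = assign_read("r1", [hit("A6")], mapping, small_tree)
        assert result.status == STATUS_ASSIGNED and result.taxon_id == 6

    def test_sibling_hits_give_parent(self, small_tree, mapping):
        result = assign_read("r1", [hit("A6"), hit("A7", 195.0)], mapping, small_tree)
        assert result.taxon_id == 4

    def test_no_hits(self, small_tree, mapping):
        assert assign_read("r1", [], mapping, small_tree).status == STATUS_NO_HITS

    def test_low_score(self, small_tree, mapping):
        result = assign_read("r1", [hit("A6", 60.0)], mapping, small_tree)
        assert result.status == STATUS_LOW_SCORE

    def test_unmapped_accession(self, small_tree, mapping):
        result = assign_read("r1", [hit("ZZZ")], mapping, small_tree)
        assert result.status == STATUS_UNMAPPED

    def test_mapping_to_unknown_taxon_errors_naming_accession(self, small_tree):
        broken = MappingFile(rows={"AX": 12345})
        with pytest.raises(KeyError, match="AX"):
            assign_read("r1", [hit("AX")], broken, small_tree)

    def test_duplicate_hsp_deduplicated(self, small_tree, mapping):
        # two HSPs to the same accession must not deepen or alter the LCA
        result = assign_read(
            "r1", [hit("A6"), hit("A6", 150.0), hit("A7", 195.0)], mapping, small_tree
        )
        assert result.taxon_id == 4

    def test_widening_top_percent_never_deepens(self, small_tree, mapping):
        hits = [hit("A6", 200.0), hit("A7", 185.0), hit("A11", 183.0)]
        narrow = assign_read("r1", hits, mapping, small_tree, AssignmentParams(top_percent=5))
        wide = assign_read("r1", hits, mapping, small_tree, AssignmentParams(top_percent=15))
        assert wide.taxon_id in small_tree.ancestors(narrow.taxon_id)


class TestMinSupport:
    def test_push_up_to_parent(self, small_tree):
        profile = TaxonomicProfile(counts={6: 3, 4: 10})
        out = apply_min_support(profile, small_tree, AssignmentParams(min_support=5))
        assert out.counts == {4: 13}

    def test_min_support_one_is_identity(self, small_tree):
        profile = TaxonomicProfile(counts={6: 1, 7: 2, 3: 1})
        out = apply_min_support(profile, small_tree, AssignmentParams(min_support=1))
        assert out.counts == profile.counts

    def test_cascading_push_reaches_root(self, small_tree):
        profile = TaxonomicProfile(counts={6: 1})
        out = apply_min_support(profile, small_tree, AssignmentParams(min_support=5))
        assert out.counts == {1: 1}

    def test_matches_iterative_oracle_on_random_profiles(self):
        rng = np.random.default_rng(17)
        for _ in range(60):
            tree = random_tree(rng, 30)
            counts = {
                int(tid): int(rng.integers(1, 10))
                for tid in rng.choice(np.arange(1, 31), size=10, replace=False)
            }
            min_support = int(rng.integers(2, 8))
            params = AssignmentParams(min_support=min_support)
            ours = apply_min_support(
                TaxonomicProfile(counts=counts), tree, params
            ).counts
            assert ours == iterative_min_support(counts, tree, min_support)
            # no surviving non-root taxon below the threshold
            assert all(
                c >= min_support for t, c in ours.items() if t != tree.root_id
            )
            assert sum(ours.values()) == sum(counts.values())


class TestCollapseAtRank:
    def test_species_sum_onto_genus(self, small_tree):
        profile = TaxonomicProfile(counts={6: 4, 7: 6})
        out = collapse_at_rank(profile, small_tree, "genus")
        assert out.counts == {4: 10}

    def test_count_at_rank_unchanged(self, small_tree):
        profile = TaxonomicProfile(counts={4: 9})
        out = collapse_at_rank(profile, small_tree, "genus")
        assert out.counts == {4: 9}

    def test_taxon_without_rank_ancestor_keeps_own_bin(self, small_tree):
        profile = TaxonomicProfile(counts={2: 5})
        out = collapse_at_rank(profile, small_tree, "genus")
        assert out.counts == {2: 5}

    def test_unknown_rank_is_error(self, small_tree):
        with pytest.raises(ValueError, match="tribe"):
            collapse_at_rank(TaxonomicProfile(), small_tree, "tribe")

    def test_conservation_on_random_profile(self, small_tree):
        rng = np.random.default_rng(23)
        counts = {int(t): int(rng.integers(1, 20)) for t in small_tree}
        profile = TaxonomicProfile(counts=counts)
        out = collapse_at_rank(profile, small_tree, "genus")
        assert sum(out.counts.values()) == sum(counts.values())


class TestRunAssignment:
    def test_empty_blast_file_gives_zero_reads(self, tmp_path, clean_bundle):
        paths, _ = clean_bundle
        empty = tmp_path / "empty.tsv"
        empty.write_text("")
        mapping_path = tmp_path / "mapping.tsv"
        _build_mapping_file(paths, mapping_path)
        profile = run_assignment(
            empty, mapping_path, paths["names"], paths["nodes"], AssignmentParams()
        )
        assert profile.total == 0

    def test_clean_fixture_recovers_true_taxa(self, tmp_path, clean_bundle):
        paths, manifest = clean_bundle
        mapping_path = tmp_path / "mapping.tsv"
        _build_mapping_file(paths, mapping_path)
        profile = run_assignment(
            paths["blast"],
            mapping_path,
            paths["names"],
            paths["nodes"],
            AssignmentParams(min_support=1),
        )
        expected: dict[int, int] = {}
        for _, accession, _ in manifest.reads:
            taxon = manifest.accession_expected[accession]
            expected[taxon] = expected.get(taxon, 0) + 1
        assert profile.counts == expected
        assert profile.total == manifest.params.n_reads

    def test_min_support_empties_small_genus(self, small_tree, tmp_path):
        # 3 reads on species 6 (under genus 4), defaults: pushed above genus
        blast = tmp_path / "b.tsv"
        blast.write_text(
            "".join(
                f"r{i}\tA6\t99.0\t250\t2\t0\t1\t250\t1\t250\t1e-99\t200.0\n"
                for i in range(3)
            )
        )
        from silvamap import write_mapping_file

        mpath = tmp_path / "m.tsv"
        write_mapping_file(MappingFile(rows={"A6": 6}), mpath)
        names = tmp_path / "names.dmp"
        names.write_text(
            "".join(f"{t}\t|\tT{t}\t|\t\t|\tscientific name\t|\n" for t in small_tree)
        )
        nodes = tmp_path / "nodes.dmp"
        nodes.write_text(
            "".join(
                f"{t}\t|\t{small_tree.parent(t)}\t|\t{small_tree.rank(t)}\t|\n"
                for t in small_tree
            )
        )
        profile = run_assignment(blast, mpath, names, nodes, AssignmentParams())
        assert 6 not in profile.counts and 4 not in profile.counts
        assert profile.assigned_total == 3


def _build_mapping_file(paths, out_path):
    from silvamap import (
        build_mapping,
        build_name_index,
        parse_names_dump,
        parse_silva_export,
        write_mapping_file,
    )

    index = build_name_index(parse_names_dump(paths["names"]))
    mapping = build_mapping(parse_silva_export(paths["silva"]), index)
    write_mapping_file(mapping, out_path)
    return mapping


class TestProfileIO:
    def test_round_trip(self, tmp_path, small_tree):
        profile = TaxonomicProfile(
            sample_id="s1", counts={4: 10, 6: 2}, no_hits=3, unassigned=1, unmapped=2
        )
        path = tmp_path / "p.tsv"
        write_profile(profile, path, tree=small_tree)
        back = read_profile(path)
        assert back.counts == profile.counts
        assert (back.no_hits, back.unassigned, back.unmapped) == (3, 1, 2)
        assert back.sample_id == "s1"
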