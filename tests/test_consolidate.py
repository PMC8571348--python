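"""Residue-level consolidation and containment clustering."""

import numpy as np
import pytest

from secscreen.consolidate import (
    LABEL_AMBIGUOUS,
    LABEL_DEPLETED,
    LABEL_SECRETED,
    LABEL_UNCOVERED,
    FilteredFragment,
    build_consolidated,
    build_residue_track,
    cluster_representatives,
    filter_for_consolidation,
)

PROTEIN = "".join(
    "ACDEFGHIKLMNPQRSTVWY"[i % 20] for i in range(120)
)  # deterministic 120-aa protein


class TestFilter:
    def _frag(self, pep, key="f1", cls="enriched"):
        return [(key, "P1", pep, cls)]

    def test_length_boundary_strict(self):
        proteins = {"P1": PROTEIN}
        kept31 = filter_for_consolidation(self._frag(PROTEIN[:31]), proteins)
        kept30 = filter_for_consolidation(self._frag(PROTEIN[:30]), proteins)
        assert len(kept31) == 1 and kept31[0].offset == 0
        assert kept30 == []

    def test_mismatch_dropped(self):
        pep = PROTEIN[10:50]
        mutated = pep[:20] + ("A" if pep[20] != "A" else "C") + pep[21:]
        assert (
            filter_for_consolidation(self._frag(mutated), {"P1": PROTEIN}) == []
        )

    def test_offset_recorded_and_multiple_flagged(self):
        protein = "A" * 40 + "CDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQ"
        pep = "A" * 35
        kept = filter_for_consolidation(
            [("f", "P1", pep, "depleted")], {"P1": protein}
        )
        assert kept[0].offset == 0
        assert kept[0].multiple_matches  # shifted match also exists


def _ff(key, lo, pep_len, label, protein_id="P1"):
    return FilteredFragment(
        key=key,
        protein_id=protein_id,
        peptide="A" * pep_len,
        offset=lo,
        label=label,
    )


class TestResidueTrack:
    def test_single_fragment_all_secreted(self):
        track = build_residue_track([_ff("a", 10, 50, LABEL_SECRETED)], 100, "P1")
        assert (track.labels[10:60] == LABEL_SECRETED).all()
        assert (track.labels[:10] == LABEL_UNCOVERED).all()
        assert (track.labels[60:] == LABEL_UNCOVERED).all()

    def test_overlap_becomes_ambiguous(self):
        frags = [
            _ff("a", 10, 50, LABEL_SECRETED),
            _ff("b", 40, 50, LABEL_DEPLETED),
        ]
        track = build_residue_track(frags, 100, "P1")
        assert (track.labels[10:40] == LABEL_SECRETED).all()
        assert (track.labels[40:60] == LABEL_AMBIGUOUS).all()
        assert (track.labels[60:90] == LABEL_DEPLETED).all()

    def test_no_fragments_all_uncovered(self):
        track = build_residue_track([], 30, "P1")
        assert (track.labels == LABEL_UNCOVERED).all()

    def test_labels_depend_only_on_covering_class_multiset(self):
        frags = [
            _ff("a", 0, 30, LABEL_SECRETED),
            _ff("b", 15, 30, LABEL_DEPLETED),
            _ff("c", 20, 30, LABEL_SECRETED),
        ]
        fwd = build_residue_track(frags, 60, "P1")
        rev = build_residue_track(frags[::-1], 60, "P1")
        assert (fwd.labels == rev.labels).all()
        assert (fwd.support == rev.support).all()

    def test_interval_overlap_oracle(self):
        rng = np.random.default_rng(17)
        frags = []
        for i in range(40):
            lo = int(rng.integers(0, 150))
            ln = int(rng.integers(5, 60))
            label = LABEL_SECRETED if rng.random() < 0.5 else LABEL_DEPLETED
            frags.append(_ff(f"f{i}", lo, ln, label))
        track = build_residue_track(frags, 200, "P1")
        for pos in range(200):
            covering = {
                f.label
                for f in frags
                if f.offset <= pos < min(f.offset + len(f.peptide), 200)
            }
            if not covering:
                expect = LABEL_UNCOVERED
            elif len(covering) == 2:
                expect = LABEL_AMBIGUOUS
            else:
                expect = covering.pop()
            assert track.labels[pos] == expect


class TestConsolidated:
    def test_runs_from_mixed_track(self):
        frags = [
            _ff("a", 10, 50, LABEL_SECRETED),
            _ff("b", 40, 50, LABEL_DEPLETED),
        ]
        track = build_residue_track(frags, 100, "P1")
        runs = build_consolidated(track)
        assert [(r.start, r.end, r.label) for r in runs] == [
            (10, 40, LABEL_SECRETED),
            (60, 90, LABEL_DEPLETED),
        ]

    def test_never_overlap_nor_cross_ambiguous(self):
        rng = np.random.default_rng(23)
        frags = [
            _ff(
                f"f{i}",
                int(rng.integers(0, 150)),
                int(rng.integers(5, 60)),
                LABEL_SECRETED if rng.random() < 0.5 else LABEL_DEPLETED,
            )
            for i in range(30)
        ]
        track = build_residue_track(frags, 200, "P1")
        runs = build_consolidated(track)
        prev_end = -1
        for r in runs:
            assert r.start >= prev_end
            assert (track.labels[r.start : r.end] == r.label).all()
            prev_end = r.end

    def test_condensed_profile_is_mean_over_covering_fragments(self):
        frags = [
            _ff("a", 0, 20, LABEL_SECRETED),
            _ff("b", 10, 20, LABEL_SECRETED),
        ]
        profiles = {"a": np.full(20, 1.0), "b": np.full(20, 3.0)}
        track = build_residue_track(frags, 30, "P1")
        (run,) = build_consolidated(track, frags, profiles)
        assert run.start == 0 and run.end == 30
        assert np.allclose(run.profile[:10], 1.0)
        assert np.allclose(run.profile[10:20], 2.0)
        assert np.allclose(run.profile[20:30], 3.0)

    def test_uniform_profiles_pass_through(self):
        frags = [_ff("a", 5, 25, LABEL_DEPLETED)]
        profiles = {"a": np.full(25, 7.5)}
        track = build_residue_track(frags, 40, "P1")
        (run,) = build_consolidated(track, frags, profiles)
        assert np.allclose(run.profile, 7.5)


class TestClustering:
    def test_containment_merges(self):
        clusters = cluster_representatives({"x": "ABCDE", "y": "BCD"})
        assert len(clusters) == 1
        assert clusters[0].representative == "ABCDE"
        assert set(clusters[0].members) == {"x", "y"}

    def test_disjoint_sequences_stay_apart(self):
        clusters = cluster_representatives({"x": "AAA", "y": "DEF"})
        assert len(clusters) == 2

    def test_matches_all_pairs_containment_oracle(self):
        rng = np.random.default_rng(31)
        alphabet = list("AB")  # tiny alphabet makes containment common
        peptides = {
            f"s{i}": "".join(rng.choice(alphabet, size=int(rng.integers(3, 12))))
            for i in range(100)
        }
        clusters = cluster_representatives(peptides)
        # union of members = input; members contained in representative
        all_members = [m for c in clusters for m in c.members]
        assert sorted(all_members) == sorted(peptides)
        for c in clusters:
            for m in c.members:
                assert peptides[m] in c.representative
        # representatives mutually non-contained
        reps = [c.representative for c in clusters]
        for i, r in enumerate(reps):
            for j, s in enumerate(reps):
                if i != j:
                    assert r not in s
        # oracle: greedy longest-first replay with an O(n^2) scan
        order = sorted(peptides, key=lambda k: (-len(peptides[k]), k))
        oracle_clusters: list[tuple[str, list[str]]] = []
        for key in order:
            seq = peptides[key]
            for rep, members in oracle_clusters:
                if seq in rep:
                    members.append(key)
                    break
            else:
                oracle_clusters.append((seq, [key]))
        assert [(c.representative, c.members) for c in clusters] == oracle_clusters

    def test_idempotent_on_representatives(self):
        rng = np.random.default_rng(37)
        peptides = {
            f"s{i}": "".join(rng.choice(list("ABC"), size=int(rng.integers(3, 10))))
            for i in range(50)
        }
        clusters = cluster_representatives(peptides)
        reps = {f"r{i}": c.representative for i, c in enumerate(clusters)}
        again = cluster_representatives(reps)
        assert all(len(c.members) == 1 for c in again)
        assert len(again) == len(reps)
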