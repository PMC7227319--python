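import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pretimeth import (
    build_assignments,
    kmer_features,
    nearest_neighbour,
    partition_loci,
    pearson_methylation,
    pearson_sequence,
    select_comethylated,
    select_sequence_match,
)
from pretimeth.feature_selection import KMER_ORDER, N_KMER_FEATURES, _BLOCK_SLICES


def brute_force_kmer(seq, k):
    """Independent sliding-window counter dropping windows with non-ACGT bases."""
    counts = {}
    total = 0
    for i in range(len(seq) - k + 1):
        w = seq[i : i + k]
        if set(w) <= set("ACGT"):
            counts[w] = counts.get(w, 0) + 1
            total += 1
    return {w: c / total for w, c in counts.items()} if total else {}


def textbook_pearson(a, b):
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    am, bm = a - a.mean(), b - b.mean()
    return float((am * bm).sum() / np.sqrt((am**2).sum() * (bm**2).sum()))


class TestKmerFeatures:
    def test_feature_space_is_340(self):
        assert N_KMER_FEATURES == 340 == 4 + 16 + 64 + 256
        assert len(set(KMER_ORDER)) == 340

    def test_uniform_composition(self):
        v = kmer_features("ACGT")
        np.testing.assert_allclose(v[_BLOCK_SLICES[1]], 0.25)

    def test_homopolymer(self):
        v = kmer_features("AAAA")
        for k in (1, 2, 3, 4):
            block = v[_BLOCK_SLICES[k]]
            assert block[0] == 1.0 and block[1:].sum() == 0.0

    def test_interior_n_matches_brute_force(self):
        seq = "ACGTNACGGTA"
        v = kmer_features(seq)
        for k in (1, 2, 3, 4):
            expected = brute_force_kmer(seq, k)
            got = dict(zip(KMER_ORDER[_BLOCK_SLICES[k]], v[_BLOCK_SLICES[k]]))
            for kmer, freq in got.items():
                assert freq == pytest.approx(expected.get(kmer, 0.0), abs=1e-12)

    def test_empty_sequence_all_zero(self):
        assert kmer_features("").sum() == 0.0

    @settings(deadline=None, max_examples=30)
    @given(st.text(alphabet="ACGTN", min_size=0, max_size=60))
    def test_blocks_sum_to_one_or_zero(self, seq):
        v = kmer_features(seq)
        for k in (1, 2, 3, 4):
            s = v[_BLOCK_SLICES[k]].sum()
            assert s == pytest.approx(1.0, abs=1e-9) or s == 0.0


class TestPearson:
    def test_self_correlation(self):
        a = np.array([0.1, 0.5, 0.9])
        r, n = pearson_methylation(a, a)
        assert r == pytest.approx(1.0) and n == 3

    def test_perfect_anticorrelation(self):
        r, _ = pearson_methylation([0.1, 0.2, 0.3], [0.9, 0.8, 0.7])
        assert r == pytest.approx(-1.0)

    def test_pairwise_complete_matches_textbook(self):
        rng = np.random.default_rng(5)
        a = rng.random(10)
        b = rng.random(10)
        a[2] = np.nan
        b[7] = np.nan
        r, n = pearson_methylation(a, b)
        ok = ~np.isnan(a) & ~np.isnan(b)
        assert n == 8
        assert r == pytest.approx(textbook_pearson(a[ok], b[ok]), abs=1e-12)

    def test_too_few_pairs_or_zero_variance_flagged(self):
        r, _ = pearson_methylation([0.5, 0.5, 0.5], [0.1, 0.2, 0.3])
        assert np.isnan(r)
        r, n = pearson_methylation([0.1, np.nan, 0.3], [np.nan, 0.2, 0.4],
                                   min_samples=2)
        assert np.isnan(r) and n == 1

    def test_sequence_correlation_symmetric_and_matches_oracle(self):
        s1 = kmer_features("AAAA" * 101)
        s2 = kmer_features("ACGTACGT" * 51)
        assert pearson_sequence(s1, s2) == pytest.approx(pearson_sequence(s2, s1))
        assert pearson_sequence(s1, s2) == pytest.approx(textbook_pearson(s1, s2), abs=1e-12)
        assert pearson_sequence(s2, s2) == pytest.approx(1.0)

    @settings(deadline=None, max_examples=40)
    @given(st.integers(0, 2**31 - 1))
    def test_correlation_matches_two_pass_formula(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.random(25), rng.random(25)
        r, _ = pearson_methylation(a, b)
        assert r == pytest.approx(textbook_pearson(a, b), abs=1e-12)


class TestNearestNeighbour:
    @pytest.fixture()
    def manifest(self, planted_fixture):
        return planted_fixture[1]

    def test_minimum_distance_wins(self, planted_fixture):
        _, manifest, _, truth = planted_fixture
        model, feature = partition_loci(manifest)
        # model locus 0 is placed within 2 kb of its planted partner
        probe, dist = nearest_neighbour("cgM00000", manifest, feature)
        assert probe == truth.iloc[0]["partner_probe"] and dist < 2000

    def test_max_distance_excludes_all(self, planted_fixture):
        _, manifest, _, _ = planted_fixture
        _, feature = partition_loci(manifest)
        # model locus 2 lives on chr2 where no feature locus exists
        assert nearest_neighbour("cgM00002", manifest, feature) is None
        # locus 1 is distal on chr1: a 2 kb cap excludes every candidate
        assert nearest_neighbour("cgM00001", manifest, feature, max_distance=2000) is None
        assert nearest_neighbour("cgM00001", manifest, feature) is not None

    def test_matches_exhaustive_scan_and_tie_rule(self, planted_fixture):
        _, manifest, _, _ = planted_fixture
        model, feature = partition_loci(manifest)
        t = manifest.table
        for mp in sorted(model)[:9]:
            got = nearest_neighbour(mp, manifest, feature)
            chrom, pos = manifest.position(mp)
            cands = [
                (abs(int(t.loc[f, "pos"]) - pos), f)
                for f in feature
                if t.loc[f, "chr"] == chrom
            ]
            expected = min(cands)[::-1] if cands else None
            if expected is None:
                assert got is None
            else:
                assert got == (expected[0], expected[1])

    def test_equidistant_tie_breaks_by_probe_id(self):
        from pretimeth.arrays_io import ProbeManifest

        table = pd.DataFrame(
            {
                "chr": "chr1",
                "pos": [100, 200, 300],
                "on450k": [True, False, True],
                "onEPIC": [True, True, True],
                "gene_annotation": [[], [], []],
                "cgi_relation": "island",
            },
            index=pd.Index(["cgB", "cgM", "cgA"], name="probe_id"),
        )
        man = ProbeManifest(table)
        probe, dist = nearest_neighbour("cgM", man, {"cgA", "cgB"})
        assert (probe, dist) == ("cgA", 100)  # lexicographic tie-break

    def test_unknown_model_probe_errors(self, manifest):
        with pytest.raises(KeyError):
            nearest_neighbour("cgNOPE", manifest, {"cgF00000"})


class TestCoMethylatedSelection:
    def test_planted_exact_copy_selected_with_score_one(self, make_matrix):
        rng = np.random.default_rng(2)
        x = rng.random(40)
        vals = np.vstack([x, rng.random((5, 40)), x])
        m = make_matrix(vals, probes=["F0", "F1", "F2", "F3", "F4", "F5", "M"])
        got = select_comethylated("M", m, {f"F{i}" for i in range(6)}, min_samples=10)
        assert got[0] == "F0" and got[1] == pytest.approx(1.0)

    def test_matches_exhaustive_argmax_on_50_candidates(self, make_matrix):
        rng = np.random.default_rng(3)
        vals = rng.random((51, 60))
        probes = [f"F{i:02d}" for i in range(50)] + ["M"]
        m = make_matrix(vals, probes=probes)
        got = select_comethylated("M", m, set(probes[:-1]), min_samples=10)
        y = vals[-1]
        oracle = max(
            (textbook_pearson(y, vals[i]), probes[i]) for i in range(50)
        )
        assert got[0] == oracle[1]
        assert got[1] == pytest.approx(oracle[0], abs=1e-12)

    def test_distal_high_correlation_beats_adjacent_weak(self, planted_fixture):
        matrix, manifest, _, truth = planted_fixture
        _, feature = partition_loci(manifest)
        # model locus 1 is planted against cgF00001 but placed far from it
        got = select_comethylated("cgM00001", matrix, feature, manifest=manifest)
        assert got[0] == truth.iloc[1]["partner_probe"]

    def test_unmodelable_when_constant(self, make_matrix):
        vals = np.vstack([np.full(40, 0.5), np.linspace(0, 1, 40)])
        m = make_matrix(vals, probes=["M", "F0"])
        assert select_comethylated("M", m, {"F0"}, min_samples=10) is None


class TestSequenceMatchSelection:
    def test_identical_flank_selected(self):
        rng = np.random.default_rng(4)
        bases = np.array(list("ACGT"))
        target = "".join(rng.choice(bases, 402))
        rows = {"M": kmer_features(target), "F0": kmer_features(target)}
        for i in range(1, 20):
            rows[f"F{i}"] = kmer_features("".join(rng.choice(bases, 402)))
        table = pd.DataFrame(rows).T
        got = select_sequence_match("M", table, {f"F{i}" for i in range(20)})
        assert got[0] == "F0" and got[1] == pytest.approx(1.0)

    def test_matches_exhaustive_argmax(self):
        rng = np.random.default_rng(6)
        bases = np.array(list("ACGT"))
        table = pd.DataFrame(
            {f"F{i}": kmer_features("".join(rng.choice(bases, 300))) for i in range(20)}
        ).T
        table.loc["M"] = kmer_features("".join(rng.choice(bases, 300)))
        got = select_sequence_match("M", table, {f"F{i}" for i in range(20)})
        y = table.loc["M"].to_numpy()
        oracle = max(
            (textbook_pearson(y, table.loc[f"F{i}"].to_numpy()), f"F{i}")
            for i in range(20)
        )
        assert got[0] == oracle[1]
        assert got[1] == pytest.approx(oracle[0], abs=1e-12)

    def test_all_identical_candidates_pick_lowest_probe_id(self):
        v = kmer_features("ACGT" * 100)
        table = pd.DataFrame({p: v for p in ["F2", "F1", "F3", "M"]}).T
        got = select_sequence_match("M", table, {"F1", "F2", "F3"})
        assert got[0] == "F1"


class TestBuildAssignments:
    def test_complete_records_and_planted_partners(self, planted_fixture):
        matrix, manifest, seqs, truth = planted_fixture
        model, feature = partition_loci(manifest)
        assignments, excluded = build_assignments(
            manifest, matrix, model, feature, seqs=seqs
        )
        assert not excluded and len(assignments) == len(model)
        recovered = sum(
            assignments[row.model_probe].comethylated[0] == row.partner_probe
            for row in truth.itertuples()
        )
        assert recovered == len(truth)
        for fa in assignments.values():
            assert fa.comethylated[0] != fa.model_probe_id
            assert fa.sequence_match is not None

    def test_sequence_partner_recovered_from_planted_similarity(self, planted_fixture):
        matrix, manifest, seqs, truth = planted_fixture
        model, feature = partition_loci(manifest)
        assignments, _ = build_assignments(manifest, matrix, model, feature, seqs=seqs)
        hits = sum(
            assignments[row.model_probe].sequence_match[0] == row.partner_probe
            for row in truth.itertuples()
        )
        assert hits == len(truth)  # mutated-copy flanks dominate random ones

    def test_constant_model_locus_excluded(self, planted_fixture, make_matrix):
        matrix, manifest, _, _ = planted_fixture
        model, feature = partition_loci(manifest)
        data = matrix.data.copy()
        data.loc["cgM00003"] = 0.5
        from pretimeth import MethylationMatrix

        assignments, excluded = build_assignments(
            manifest, MethylationMatrix(data), model, feature
        )
        assert "cgM00003" in excluded and "cgM00003" not in assignments

    def test_determinism_and_training_only_dependence(self, planted_fixture):
        matrix, manifest, _, _ = planted_fixture
        model, feature = partition_loci(manifest)
        a1, _ = build_assignments(manifest, matrix, model, feature)
        a2, _ = build_assignments(manifest, matrix, model, feature)
        assert {k: vars(v) for k, v in a1.items()} == {k: vars(v) for k, v in a2.items()}
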