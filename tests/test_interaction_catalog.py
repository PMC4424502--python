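"""Pair-catalog merging and Match-style PWM scanning against enumeration oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from loopmotif import PWM, load_transfac_pwms, match_scan, merge_pairs, restrict_to_de
from loopmotif.interaction_catalog import load_pairs, scan_sequence


def write_pairs(path, rows):
    path.write_text(
        "source_id\ttarget_id\tcatalog\n"
        + "".join(f"{s}\t{t}\t{c}\n" for s, t, c in rows)
    )
    return path


class TestMerge:
    def test_identical_pair_from_two_files_collapses_with_provenance(self, tmp_path):
        a = load_pairs(write_pairs(tmp_path / "a.tsv", [("m1", "g1", "dbA")]))
        b = load_pairs(write_pairs(tmp_path / "b.tsv", [("m1", "g1", "dbB")]))
        merged = merge_pairs(a, b)
        assert len(merged) == 1
        assert merged.loc[0, "provenance"] == frozenset({"dbA", "dbB"})

    def test_disjoint_files_union(self, tmp_path):
        a = load_pairs(write_pairs(tmp_path / "a.tsv",
                                   [(f"m{i}", f"g{i}", "dbA") for i in range(3)]))
        b = load_pairs(write_pairs(tmp_path / "b.tsv",
                                   [(f"x{i}", f"y{i}", "dbB") for i in range(4)]))
        assert len(merge_pairs(a, b)) == 7

    def test_union_matches_set_oracle(self, tmp_path):
        rng = np.random.default_rng(5)
        cat_a = {(f"m{rng.integers(8)}", f"g{rng.integers(8)+10}") for _ in range(30)}
        cat_b = {(f"m{rng.integers(8)}", f"g{rng.integers(8)+10}") for _ in range(30)}
        a = load_pairs(write_pairs(tmp_path / "a.tsv", [(s, t, "A") for s, t in cat_a]))
        b = load_pairs(write_pairs(tmp_path / "b.tsv", [(s, t, "B") for s, t in cat_b]))
        merged = merge_pairs(a, b)
        assert set(zip(merged["source_id"], merged["target_id"])) == cat_a | cat_b

    def test_merge_is_idempotent(self, tmp_path):
        a = load_pairs(write_pairs(tmp_path / "a.tsv",
                                   [("m1", "g1", "dbA"), ("m2", "g2", "dbA")]))
        once = merge_pairs(a)
        twice = merge_pairs(once, once)
        pd.testing.assert_frame_equal(once, twice)

    def test_malformed_row_reports_line_number(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("m1\tg1\tdbA\nm2_missing_fields\n")
        with pytest.raises(ValueError, match="line 2"):
            load_pairs(p)


class TestRestrict:
    def _de(self, passing):
        # passing: dict id -> class
        return pd.DataFrame(
            {
                "entity_id": list(passing),
                "class": list(passing.values()),
                "time_h": 24.0,
                "log2fc": 2.0,
                "p_raw": 0.01,
                "p_adj": 0.01,
                "passes": True,
            }
        )

    def _pairs(self, rows):
        return pd.DataFrame(rows, columns=["source_id", "target_id"]).assign(
            provenance=lambda d: [frozenset(["x"])] * len(d)
        )

    def test_no_de_entities_empty_result(self):
        out = restrict_to_de(self._pairs([("m1", "g1")]), self._de({}), 24.0)
        assert out.empty

    def test_mir_to_de_tf_typed_mir_tf(self):
        out = restrict_to_de(
            self._pairs([("m1", "f1")]), self._de({"m1": "miR", "f1": "TF"}), 24.0
        )
        assert list(out["edge_class"]) == ["miR->TF"]

    def test_matches_nested_loop_filter_oracle(self):
        rng = np.random.default_rng(9)
        ids = [f"m{i}" for i in range(6)] + [f"f{i}" for i in range(3)] + [
            f"g{i}" for i in range(10)
        ]
        cls = {i: ("miR" if i[0] == "m" else "TF" if i[0] == "f" else "mRNA") for i in ids}
        de_ids = set(rng.choice(ids, size=10, replace=False))
        pairs = []
        for _ in range(60):
            s = ids[rng.integers(len(ids))]
            t = ids[rng.integers(len(ids))]
            if s != t and cls[s] != "mRNA":
                pairs.append((s, t))
        pairs = sorted(set(pairs))
        out = restrict_to_de(
            self._pairs(pairs), self._de({i: cls[i] for i in de_ids}), 24.0
        )
        oracle = {(s, t) for s, t in pairs if s in de_ids and t in de_ids}
        assert set(zip(out["source_id"], out["target_id"])) == oracle

    def test_unclassified_labels_rejected(self):
        de = self._de({"m1": "miR"})
        de.loc[0, "class"] = "mystery"
        with pytest.raises(ValueError, match="unclassified"):
            restrict_to_de(self._pairs([("m1", "g1")]), de, 24.0)


def simple_pwm():
    # 3 positions, strongly informative: consensus ACG
    freq = np.array(
        [
            [0.85, 0.05, 0.05, 0.05],
            [0.05, 0.85, 0.05, 0.05],
            [0.05, 0.05, 0.85, 0.05],
        ]
    )
    return PWM(id="TF-A", frequencies=freq)


def oracle_score(pwm, window):
    """Direct evaluation of the matrix similarity formula, scalar loops only."""
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    info = [
        sum(f * math.log(4 * max(f, 1e-4)) for f in row) for row in pwm.frequencies
    ]
    raw = sum(info[i] * pwm.frequencies[i][idx[b]] for i, b in enumerate(window))
    lo = sum(info[i] * min(pwm.frequencies[i]) for i in range(len(pwm)))
    hi = sum(info[i] * max(pwm.frequencies[i]) for i in range(len(pwm)))
    return (raw - lo) / (hi - lo)


class TestMatchScan:
    def test_consensus_scores_one_anticonsensus_zero(self):
        pwm = simple_pwm()
        best, strand, off = scan_sequence(pwm, "ACG")
        assert best == pytest.approx(1.0)
        # anti-consensus: per-position argmin; any non-ACG minimal base works,
        # but its reverse complement must not score higher
        worst = "TTT"
        f, _, _ = scan_sequence(pwm, worst)
        assert f == pytest.approx(
            max(oracle_score(pwm, "TTT"), oracle_score(pwm, "AAA"))
        )
        assert oracle_score(pwm, "TTT") == pytest.approx(0.0)

    def test_all_64_trinucleotides_match_direct_formula_oracle(self):
        pwm = simple_pwm()
        hits = match_scan(
            [ (f"g_{w}", w) for w in map("".join, itertools.product("ACGT", repeat=3)) ],
            [pwm],
            threshold=0.8,
        )
        got = dict(zip(hits["gene_id"], hits["best_score"]))
        comp = str.maketrans("ACGT", "TGCA")
        for w in map("".join, itertools.product("ACGT", repeat=3)):
            rc = w.translate(comp)[::-1]
            expected = max(oracle_score(pwm, w), oracle_score(pwm, rc))
            if expected >= 0.8:
                assert got[f"g_{w}"] == pytest.approx(expected, abs=1e-12)
            else:
                assert f"g_{w}" not in got

    def test_strand_symmetry(self):
        pwm = simple_pwm()
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ACGT"), size=50))
        comp = str.maketrans("ACGT", "TGCA")
        rc = seq.translate(comp)[::-1]
        s1, _, _ = scan_sequence(pwm, seq)
        s2, _, _ = scan_sequence(pwm, rc)
        assert s1 == pytest.approx(s2)

    def test_scores_lie_in_unit_interval(self):
        pwm = simple_pwm()
        rng = np.random.default_rng(4)
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGTN"), size=30))
            s, _, _ = scan_sequence(pwm, seq)
            assert 0.0 <= s <= 1.0

    def test_raising_threshold_never_adds_pairs(self):
        pwm = simple_pwm()
        rng = np.random.default_rng(6)
        seqs = [
            (f"g{i}", "".join(rng.choice(list("ACGT"), size=40))) for i in range(15)
        ]
        low = match_scan(seqs, [pwm], threshold=0.5)
        high = match_scan(seqs, [pwm], threshold=0.9)
        assert set(high["gene_id"]) <= set(low["gene_id"])

    def test_n_contributes_position_minimum(self):
        pwm = simple_pwm()
        s_n, _, _ = scan_sequence(pwm, "ACN")
        # N at position 3 behaves like the minimum-frequency base there
        assert s_n == pytest.approx(oracle_score(pwm, "ACT"))

    def test_pwm_longer_than_sequence_warns_and_yields_nothing(self):
        pwm = simple_pwm()
        with pytest.warns(UserWarning, match="longer"):
            hits = match_scan([("g1", "AC")], [pwm], threshold=0.0)
        assert hits.empty

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            match_scan([("g1", "ACG")], [simple_pwm()], threshold=1.5)


class TestTransfacParsing:
    def test_counts_block_round_trips_to_frequencies(self, tmp_path):
        block = (
            "VV  TRANSFAC-like test matrices\n"
            "//\n"
            "ID  TF-A\n"
            "P0      A      C      G      T\n"
            "01      8      1      1      0      A\n"
            "02      0      9      1      0      C\n"
            "03      1      0      9      0      G\n"
            "//\n"
        )
        p = tmp_path / "pwms.dat"
        p.write_text(block)
        (pwm,) = load_transfac_pwms(p)
        assert pwm.id == "TF-A"
        np.testing.assert_allclose(pwm.frequencies.sum(axis=1), 1.0)
        assert pwm.consensus() == "ACG"

    def test_unnormalized_frequencies_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            PWM(id="bad", frequencies=np.array([[0.5, 0.2, 0.1, 0.1]]))
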