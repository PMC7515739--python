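import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from spaceracq import (
    GeneFeature,
    ReferenceGenome,
    classify_targeting,
    double_spacer_analysis,
    flank_matrix,
    jaccard_overlap,
)
from spaceracq.stats import annotate_clusters, strand_bias_report


class TestClassifyTargeting:
    features = [GeneFeature("g1", 100, 200, "+"), GeneFeature("g2", 300, 400, "-")]

    @pytest.mark.parametrize(
        "start,strand,expected",
        [
            (120, "-", "targeting"),       # gene on +, hit on - => crRNA pairs mRNA
            (120, "+", "non_targeting"),
            (320, "+", "targeting"),       # gene on -, hit on +
            (320, "-", "non_targeting"),
            (220, "+", "intergenic"),
        ],
    )
    def test_convention(self, start, strand, expected):
        assert classify_targeting(start, 38, strand, self.features) == expected

    def test_majority_overlap_rule(self):
        feats = [GeneFeature("a", 0, 110, "+"), GeneFeature("b", 110, 300, "-")]
        # protospacer [100, 138): 10 bp in a, 28 bp in b -> b wins, gene '-'
        assert classify_targeting(100, 38, "+", feats) == "targeting"

    def test_exact_tie_smaller_start_wins(self):
        feats = [GeneFeature("a", 81, 100, "+"), GeneFeature("b", 100, 119, "-")]
        # [81,119) overlaps both by 19 -> 'a' (smaller start), gene '+'
        assert classify_targeting(81, 38, "-", feats) == "targeting"


class TestJaccard:
    def test_unit_identities(self):
        assert jaccard_overlap({"a", "b", "c"}, {"a", "b", "c"}) == 1.0
        assert jaccard_overlap({"a"}, {"b"}) == 0.0
        assert jaccard_overlap({"a", "b", "c"}, {"b", "c", "d"}) == 0.5
        assert math.isnan(jaccard_overlap(set(), set()))

    @given(st.sets(st.integers(0, 50)), st.sets(st.integers(0, 50)))
    @settings(deadline=None)
    def test_properties(self, a, b):
        if a or b:
            j = jaccard_overlap(a, b)
            assert 0 <= j <= 1
            assert j == jaccard_overlap(b, a)
        if a:
            assert jaccard_overlap(a, a) == 1.0


class TestDoubleSpacer:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["read_id", "ordinal", "region"])

    def test_textbook_chi_square(self):
        """Observed [hot=10, cold=90] against 50/50 gives chi2 = 64, df 1."""
        rows = [(f"s{i}", 1, "hot") for i in range(50)] + [
            (f"t{i}", 1, "cold") for i in range(50)
        ]
        for i in range(5):
            rows += [(f"d{i}", 1, "hot"), (f"d{i}", 2, "hot")]
        for i in range(45):
            rows += [(f"e{i}", 1, "cold"), (f"e{i}", 2, "cold")]
        res = double_spacer_analysis(
            self._table(rows), single_distribution={"hot": 0.5, "cold": 0.5}
        )
        assert res.observed == {"hot": 10, "cold": 90}
        assert res.chi_square == pytest.approx(64.0)
        assert res.df == 1
        assert res.n_reads_two_spacers == 50

    def test_null_identity(self):
        rows = [("s1", 1, "hot"), ("s2", 1, "cold"), ("d1", 1, "hot"), ("d1", 2, "cold")]
        res = double_spacer_analysis(
            self._table(rows), single_distribution={"hot": 0.5, "cold": 0.5}
        )
        assert res.chi_square == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_leader_proximal_fraction(self):
        rows = [("s1", 1, "hot")] + [
            (f"d{i}", 1, "cold") for i in range(4)
        ] + [(f"d{i}", 2, "hot") for i in range(4)]
        res = double_spacer_analysis(
            self._table(rows), single_distribution={"hot": 0.5, "cold": 0.5}
        )
        assert res.cold_fraction_leader_proximal == 1.0
        assert res.cold_fraction_leader_distal == 0.0

    def test_degenerate_expected_raises(self):
        rows = [("s1", 1, "hot"), ("d1", 1, "cold"), ("d1", 2, "cold")]
        with pytest.raises(ValueError, match="expected"):
            double_spacer_analysis(self._table(rows))

    def test_pvalue_calibration_under_null(self, rng):
        """Null multinomial double-spacer tables give ~uniform p-values."""
        probs = np.array([0.7, 0.3])
        rejections = 0
        n_sim = 400
        for _ in range(n_sim):
            obs = rng.multinomial(200, probs)
            chi2, p = sps.chisquare(obs, probs * 200)
            rejections += p < 0.05
        assert 0.02 <= rejections / n_sim <= 0.08


class TestStrandBias:
    def _annotated(self, rows):
        return pd.DataFrame(
            rows,
            columns=["reference_id", "start", "length", "strand", "read_count",
                     "unique_sequences", "targeting", "region", "replicon",
                     "temporal_class"],
        )

    def test_weighted_vs_unweighted(self):
        ann = self._annotated([
            ("p", 10, 38, "-", 90, 1, "targeting", "hot", "phage", "early"),
            ("p", 50, 38, "+", 10, 1, "non_targeting", "hot", "phage", "early"),
            ("c", 5, 38, "+", 1, 1, "non_targeting", "NA", "chromosome", "NA"),
        ])
        rep = strand_bias_report(ann)
        t = rep["table"]
        phage_w = t[(t.value == "phage") & (t.weighting == "all_spacers")].iloc[0]
        phage_u = t[(t.value == "phage") & (t.weighting == "unique_spacers")].iloc[0]
        assert phage_w.fraction_targeting == pytest.approx(0.9)
        assert phage_u.fraction_targeting == pytest.approx(0.5)
        assert rep["phage_fraction_weighted"] == pytest.approx(100 / 101)

    def test_all_intergenic_gives_nan(self):
        ann = self._annotated([
            ("p", 10, 38, "+", 5, 1, "intergenic", "cold", "phage", "NA"),
        ])
        t = strand_bias_report(ann)["table"]
        assert t["fraction_targeting"].isna().all()


class TestFlankMatrix:
    def _ref(self, seq):
        return ReferenceGenome(id="ref", sequence=seq)

    def _clusters(self, rows):
        return pd.DataFrame(
            rows, columns=["reference_id", "start", "length", "strand", "read_count"]
        )

    def test_uniform_flanks(self):
        ref = self._ref("A" * 20 + "CGCG" * 10 + "A" * 20)
        cl = self._clusters([("ref", 20, 40, "+", 3)])
        fm = flank_matrix(cl, {"ref": ref}, flank=10, window=10)
        assert (fm.frequencies.loc["A", [c for c in fm.frequencies if c.startswith("up")]] == 1.0).all()
        assert fm.n_used == 1

    def test_columns_sum_to_one(self, rng):
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 2000))
        ref = self._ref(seq)
        rows = [("ref", int(s), 38, "+", 1) for s in rng.integers(20, 1900, 50)]
        fm = flank_matrix(self._clusters(rows), {"ref": ref})
        assert np.allclose(fm.frequencies.sum(axis=0), 1.0, atol=1e-9)

    def test_random_reference_near_uniform(self, rng):
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 40_000))
        ref = self._ref(seq)
        rows = [("ref", int(s), 38, "+" if rng.random() < 0.5 else "-", 1)
                for s in rng.integers(20, 39_900, 1200)]
        fm = flank_matrix(self._clusters(rows), {"ref": ref})
        assert ((fm.frequencies - 0.25).abs() <= 0.05).all().all()

    def test_boundary_protospacer_skipped(self):
        ref = self._ref("ACGT" * 30)
        cl = self._clusters([("ref", 2, 38, "+", 1), ("ref", 40, 38, "+", 1)])
        fm = flank_matrix(cl, {"ref": ref}, flank=10, window=10)
        assert fm.n_skipped == 1 and fm.n_used == 1

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            flank_matrix(self._clusters([]), {})


class TestAnnotateClusters:
    def test_region_and_replicon_assignment(self):
        ref = ReferenceGenome(
            id="phage_x",
            sequence="ACGT" * 1000,
            features=[GeneFeature("g", 100, 400, "+")],
            regions={"hot": (0, 500), "cold": (500, 4000)},
        )
        cl = pd.DataFrame(
            [("phage_x", 150, 38, "-", 4, 1), ("phage_x", 800, 38, "+", 2, 1)],
            columns=["reference_id", "start", "length", "strand", "read_count", "unique_sequences"],
        )
        ann = annotate_clusters(cl, {"phage_x": ref})
        assert list(ann["targeting"]) == ["targeting", "intergenic"]
        assert list(ann["region"]) == ["hot", "cold"]
        assert list(ann["replicon"]) == ["phage", "phage"]
        assert list(ann["temporal_class"]) == ["unassigned", "NA"]
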