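import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from refstab import (
    CtTable,
    SampleAnnotation,
    collapse_technical_replicates,
    read_ct_table,
    read_primer_table,
    summarize_ct,
    write_ct_table,
)
from refstab.data_io import StudyDesign, SubsetDef
from refstab.exceptions import (
    AmpliconLengthWarning,
    CompletenessError,
    ReplicateDispersionWarning,
    TableFormatError,
)

from conftest import make_ct


class TestReadWriteRoundTrip:
    def test_wide_round_trip_preserves_order_and_values(self, tmp_path):
        table = make_ct(["g2", "g1"], [[20.0, 21.5, 19.25], [18.0, 18.5, 18.75]])
        path = tmp_path / "ct.csv"
        write_ct_table(table, path, layout="wide")
        back = read_ct_table(path, layout="wide")
        assert back.genes == ["g2", "g1"]
        assert back.sample_ids == ["s1", "s2", "s3"]
        np.testing.assert_array_equal(back.ct, table.ct)

    def test_long_round_trip_preserves_annotations(self, tmp_path, time_course_table):
        path = tmp_path / "ct_long.tsv"
        write_ct_table(time_course_table, path, layout="long")
        back = read_ct_table(path, layout="long")
        assert back.genes == time_course_table.genes
        np.testing.assert_array_equal(back.ct, time_course_table.ct)
        assert [s.time_point for s in back.samples] == [
            s.time_point for s in time_course_table.samples
        ]
        assert [s.bio_replicate for s in back.samples] == [
            s.bio_replicate for s in time_course_table.samples
        ]

    def test_missing_cell_is_completeness_error_naming_the_cell(self, tmp_path):
        path = tmp_path / "ct.csv"
        path.write_text("gene,s1,s2\ng1,20.0,NA\ng2,21.0,22.0\n")
        with pytest.raises(CompletenessError, match=r"\(g1, s2\)"):
            read_ct_table(path)

    def test_allow_missing_then_drop_incomplete_columns(self, tmp_path):
        path = tmp_path / "ct.csv"
        path.write_text("gene,s1,s2,s3\ng1,20.0,NA,20.5\ng2,21.0,22.0,21.5\n")
        table = read_ct_table(path, allow_missing=True)
        with pytest.warns(UserWarning, match="excluding"):
            complete = table.drop_incomplete_samples()
        assert complete.sample_ids == ["s1", "s3"]

    def test_duplicate_gene_symbol_rejected(self, tmp_path):
        path = tmp_path / "ct.csv"
        path.write_text("gene,s1\ng1,20.0\ng1,21.0\n")
        with pytest.raises(TableFormatError, match="duplicate"):
            read_ct_table(path)

    def test_non_numeric_ct_names_the_cell(self, tmp_path):
        path = tmp_path / "ct.csv"
        path.write_text("gene,s1,s2\ng1,20.0,oops\n")
        with pytest.raises(ValueError, match="'g1'.*'s2'"):
            read_ct_table(path)

    def test_out_of_range_ct_rejected(self):
        with pytest.raises(ValueError, match="out of range"):
            make_ct(["g1"], [[20.0, 46.0]])


class TestCollapseTechnicalReplicates:
    @staticmethod
    def tech_table(values, gene="g1"):
        samples = [
            SampleAnnotation(f"a_t{r}", subset="x", bio_replicate=1, tech_replicate=r)
            for r in range(1, len(values) + 1)
        ]
        return make_ct([gene], [values], samples=samples)

    def test_arithmetic_mean_of_triplicate(self):
        out = collapse_technical_replicates(self.tech_table([20.0, 20.2, 20.4]))
        assert out.n_samples == 1
        assert out.ct[0, 0] == pytest.approx(20.2)
        assert out.samples[0].tech_replicate == 1

    def test_single_replicate_unchanged(self):
        out = collapse_technical_replicates(self.tech_table([19.5]))
        assert out.ct[0, 0] == 19.5
        assert out.samples[0].sample_id == "a_t1"  # nothing to merge, id kept

    def test_dispersion_warning_above_half_cycle(self):
        with pytest.warns(ReplicateDispersionWarning, match="span 0.80"):
            out = collapse_technical_replicates(self.tech_table([19.0, 19.8]))
        assert out.ct[0, 0] == pytest.approx(19.4)

    def test_biological_replicates_stay_separate(self):
        samples = [
            SampleAnnotation(f"b{b}_t{r}", subset="x", bio_replicate=b, tech_replicate=r)
            for b in (1, 2)
            for r in (1, 2)
        ]
        table = make_ct(["g1"], [[20.0, 20.2, 22.0, 22.2]], samples=samples)
        out = collapse_technical_replicates(table)
        assert out.n_samples == 2
        np.testing.assert_allclose(out.ct[0], [20.1, 22.1])

    @pytest.mark.filterwarnings(
        "ignore::refstab.exceptions.ReplicateDispersionWarning"
    )
    def test_commutes_with_column_permutation(self):
        samples = [
            SampleAnnotation(f"b{b}_t{r}", subset="x", bio_replicate=b, tech_replicate=r)
            for b in (1, 2)
            for r in (1, 2, 3)
        ]
        rng = np.random.default_rng(7)
        ct = rng.uniform(18, 24, size=(3, 6))
        table = make_ct(["g1", "g2", "g3"], ct, samples=samples)
        perm = [3, 0, 5, 2, 4, 1]
        permuted = table.select_samples([samples[j].sample_id for j in perm])
        a = collapse_technical_replicates(table).to_frame()
        b = collapse_technical_replicates(permuted).to_frame()
        np.testing.assert_allclose(a.to_numpy(), b[a.columns].to_numpy())


class TestSummarizeCt:
    def test_constant_gene(self):
        out = summarize_ct(make_ct(["g1"], [[20.0, 20.0, 20.0]]))
        assert out.loc["g1", "mean"] == 20.0
        assert out.loc["g1", "sd"] == 0.0

    def test_hand_computed_mean_and_sd(self):
        out = summarize_ct(make_ct(["g1"], [[18.0, 19.0, 20.0, 21.0]]))
        assert out.loc["g1", "mean"] == pytest.approx(19.5)
        assert out.loc["g1", "sd"] == pytest.approx(math.sqrt(5.0 / 3.0), abs=1e-4)

    def test_invariant_under_column_permutation(self):
        rng = np.random.default_rng(3)
        ct = rng.uniform(15, 30, size=(4, 7))
        table = make_ct([f"g{i}" for i in range(4)], ct)
        shuffled = table.select_samples([f"s{j}" for j in (3, 1, 7, 5, 2, 6, 4)])
        a, b = summarize_ct(table), summarize_ct(shuffled)
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy())

    @given(
        arrays(
            np.float64,
            st.tuples(st.integers(2, 5), st.integers(2, 8)),
            elements=st.floats(10.0, 35.0),
        )
    )
    def test_matches_two_pass_computation(self, ct):
        table = make_ct([f"g{i}" for i in range(ct.shape[0])], ct)
        out = summarize_ct(table)
        for i, g in enumerate(table.genes):
            mean = sum(ct[i]) / ct.shape[1]
            var = sum((x - mean) ** 2 for x in ct[i]) / (ct.shape[1] - 1)
            assert out.loc[g, "mean"] == pytest.approx(mean, abs=1e-12)
            assert out.loc[g, "sd"] == pytest.approx(math.sqrt(var), abs=1e-12)


class TestPrimerTable:
    def test_read_with_target_inference(self, tmp_path):
        path = tmp_path / "primers.csv"
        path.write_text(
            "symbol,id,size,e,r2\nACT,u1,170,1.87,0.999\nTGT,u2,150,1.82,0.999\n"
        )
        records = read_primer_table(path, target_genes=["TGT"])
        assert [r.gene_symbol for r in records] == ["ACT", "TGT"]
        assert [r.is_candidate_reference for r in records] == [True, False]

    def test_short_amplicon_parsed_with_warning(self, tmp_path):
        path = tmp_path / "primers.csv"
        path.write_text("symbol,size,e,r2\nX,90,1.9,0.99\n")
        with pytest.warns(AmpliconLengthWarning):
            (rec,) = read_primer_table(path)
        assert rec.amplicon_length == 90

    def test_bad_efficiency_rejected(self, tmp_path):
        path = tmp_path / "primers.csv"
        path.write_text("symbol,size,e,r2\nX,150,2.3,0.99\n")
        with pytest.raises(ValueError, match="efficiency"):
            read_primer_table(path)

    def test_duplicate_symbol_rejected(self, tmp_path):
        path = tmp_path / "primers.csv"
        path.write_text("symbol,size,e,r2\nX,150,1.9,0.99\nX,160,1.8,0.99\n")
        with pytest.raises(TableFormatError, match="duplicate"):
            read_primer_table(path)


class TestStudyDesign:
    def test_subset_selection_and_union(self, time_course_table):
        design = StudyDesign(
            subsets=[
                SubsetDef(name="treat"),
                SubsetDef(name="all", union_of=["treat"]),
            ]
        )
        assert design.select(time_course_table, "treat") == time_course_table.sample_ids
        assert design.select(time_course_table, "all") == time_course_table.sample_ids
        design.validate_samples(time_course_table)

    def test_unknown_subset_rejected(self, time_course_table):
        design = StudyDesign(subsets=[SubsetDef(name="treat")])
        with pytest.raises(ValueError, match="unknown subset"):
            design.select(time_course_table, "nope")

    def test_orphan_samples_detected(self, time_course_table):
        design = StudyDesign(subsets=[SubsetDef(name="other")])
        with pytest.raises(ValueError, match="outside every subset"):
            design.validate_samples(time_course_table)

    def test_from_dict_parameters(self):
        design = StudyDesign.from_dict(
            {"subsets": ["a", {"name": "b", "group_by": "group"}], "v_cutoff": 0.2}
        )
        assert design.subset_names == ["a", "b"]
        assert design.v_cutoff == 0.2
        assert design.subsets[1].group_by == "group"
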