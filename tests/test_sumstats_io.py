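"""Summary-statistics I/O: parsing contracts, SE derivation from p-values,
the p=1/beta=0 filter, and allele harmonization."""

import gzip

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from duogwas.sumstats_io import (
    SumstatsTable,
    derive_se,
    filter_underivable,
    ensure_se,
    harmonize_pair,
    read_sumstats,
    write_pairs,
    write_sumstats,
)

ROW = ("rs1", "1", 1000, "A", "G", 0.3, 0.05, 0.01, 1e-6, 5000)


def rows(*overrides):
    """Clone the template row with per-row field overrides (dicts keyed by
    column index)."""
    out = []
    for i, ov in enumerate(overrides):
        r = list(ROW)
        r[0] = f"rs{i + 1}"
        r[2] = 1000 + i
        for idx, val in (ov or {}).items():
            r[idx] = val
        out.append(tuple(r))
    return out


class TestRead:
    def test_roundtrip_of_written_fixture(self, sumstats_file):
        path = sumstats_file(rows({}, {}, {}))
        t = read_sumstats(path, scan_role="fetal")
        assert len(t) == 3
        assert list(t.df["variant_id"]) == ["rs1", "rs2", "rs3"]

    def test_unparseable_beta_dropped(self, sumstats_file):
        path = sumstats_file(rows({}, {6: "NA"}, {}))
        t = read_sumstats(path, scan_role="fetal")
        assert len(t) == 2

    def test_duplicate_ids_error_by_default(self, sumstats_file):
        r = rows({}, {})
        r[1] = ("rs1",) + r[1][1:]
        path = sumstats_file(r)
        with pytest.raises(ValueError, match="duplicated"):
            read_sumstats(path, scan_role="fetal")
        t = read_sumstats(path, scan_role="fetal", duplicates="keep-first")
        assert len(t) == 1

    def test_missing_mandatory_column_fatal(self, tmp_path):
        path = tmp_path / "bad.txt"
        pd.DataFrame({"SNP": ["rs1"], "BETA": [0.1]}).to_csv(path, sep="\t", index=False)
        with pytest.raises(ValueError, match="missing mandatory"):
            read_sumstats(path, scan_role="fetal")

    def test_chrom_normalization_and_gzip(self, tmp_path):
        df = pd.DataFrame({
            "SNP": ["rs1", "rs2"], "CHR": ["chr7", "23"], "POS": [10, 20],
            "EA": ["a", "t"], "NEA": ["g", "c"], "BETA": [0.1, 0.2],
            "SE": [0.01, 0.02], "P": [1e-4, 1e-5],
        })
        path = tmp_path / "scan.txt.gz"
        with gzip.open(path, "wt") as fh:
            df.to_csv(fh, sep="\t", index=False)
        t = read_sumstats(path, scan_role="maternal")
        assert list(t.df["chrom"]) == ["7", "X"]
        assert list(t.df["effect_allele"]) == ["A", "T"]

    def test_write_read_roundtrip_preserves_numerics(self, tmp_path, sumstats_file):
        t = read_sumstats(sumstats_file(rows({}, {}, {})), scan_role="fetal")
        out = tmp_path / "rt.txt"
        write_sumstats(t, out)
        t2 = read_sumstats(out, scan_role="fetal")
        np.testing.assert_allclose(t.df["beta"], t2.df["beta"], rtol=1e-12)
        np.testing.assert_allclose(t.df["se"], t2.df["se"], rtol=1e-12)


class TestDeriveSE:
    def test_standard_quantile_arithmetic(self):
        # R: 0.1 / qnorm(0.025, lower.tail=FALSE)
        assert derive_se(0.1, 0.05) == pytest.approx(0.051021345692465407, rel=1e-9)

    def test_sign_invariance(self):
        assert derive_se(-0.1, 0.05) == derive_se(0.1, 0.05)

    def test_extreme_p_against_r_qnorm_oracle(self):
        # R: 0.2 / qnorm(5e-11, lower.tail=FALSE)
        assert derive_se(0.2, 1e-10) == pytest.approx(0.03092647482592004, rel=1e-9)

    def test_log_scale_path_below_double_underflow(self):
        # two-sided p = exp(-803.915...) corresponds to |z| = 40 exactly
        se = derive_se(0.1, None, log_p=-803.91529483319391)
        assert se == pytest.approx(0.1 / 40.0, rel=1e-9)

    def test_underivable_inputs_raise(self):
        with pytest.raises(ValueError):
            derive_se(0.1, 1.0)
        with pytest.raises(ValueError):
            derive_se(0.0, 0.05)

    @settings(derandomize=True, max_examples=300)
    @given(logp=st.floats(np.log(1e-300), np.log(0.999)),
           beta=st.floats(0.001, 10.0))
    def test_p_roundtrip(self, logp, beta):
        """derive_se then two-sided p recomputation recovers p to 1e-6
        relative over p in [1e-300, 0.999]."""
        p = float(np.exp(logp))
        se = derive_se(beta, p)
        z = beta / se
        p_back = 2.0 * float(stats.norm.sf(z))
        assert p_back == pytest.approx(p, rel=1e-6)


class TestFilter:
    def test_p_equal_one_dropped(self, sumstats_file):
        t = read_sumstats(sumstats_file(rows({}, {}, {8: 1.0}, {}, {})), scan_role="fetal")
        out, n = filter_underivable(t)
        assert len(out) == 4 and n == 1

    def test_beta_zero_dropped(self, sumstats_file):
        t = read_sumstats(sumstats_file(rows({}, {}, {6: 0.0}, {}, {})), scan_role="fetal")
        out, n = filter_underivable(t)
        assert len(out) == 4 and n == 1

    def test_clean_rows_untouched(self, sumstats_file):
        t = read_sumstats(sumstats_file(rows({}, {}, {}, {}, {})), scan_role="fetal")
        out, n = filter_underivable(t)
        assert len(out) == 5 and n == 0

    def test_ensure_se_fills_from_p(self, sumstats_file):
        path = sumstats_file(rows({7: ""}, {}))
        t = read_sumstats(path, scan_role="fetal")
        t = ensure_se(t)
        assert t.df["se"].notna().all()
        assert t.df.loc[0, "se"] == pytest.approx(derive_se(ROW[6], ROW[8]), rel=1e-12)


class TestHarmonize:
    def _tables(self, rows_f, rows_m):
        f = pd.DataFrame(rows_f, columns=["variant_id", "chrom", "pos", "effect_allele",
                                          "other_allele", "beta", "se", "p"])
        m = pd.DataFrame(rows_m, columns=f.columns)
        return (SumstatsTable(f, "fetal"), SumstatsTable(m, "maternal"))

    def test_same_alleles_pass_through(self):
        f, m = self._tables([("rs1", "1", 100, "A", "G", 0.05, 0.01, 1e-6)],
                            [("rs1", "1", 100, "A", "G", 0.03, 0.01, 1e-3)])
        pairs, report = harmonize_pair(f, m)
        assert pairs.loc[0, "b_f"] == 0.05
        assert pairs.loc[0, "b_m"] == 0.03
        assert report.n_flipped == 0

    def test_swapped_alleles_negate_second_scan(self):
        f, m = self._tables([("rs1", "1", 100, "A", "G", 0.05, 0.01, 1e-6)],
                            [("rs1", "1", 100, "G", "A", 0.03, 0.01, 1e-3)])
        pairs, report = harmonize_pair(f, m)
        assert pairs.loc[0, "b_m"] == -0.03
        assert report.n_flipped == 1

    def test_irreconcilable_alleles_dropped(self):
        f, m = self._tables([("rs1", "1", 100, "A", "C", 0.05, 0.01, 1e-6),
                             ("rs2", "1", 200, "A", "G", 0.05, 0.01, 1e-6)],
                            [("rs1", "1", 100, "A", "G", 0.03, 0.01, 1e-3),
                             ("rs2", "1", 200, "A", "G", 0.03, 0.01, 1e-3)])
        pairs, report = harmonize_pair(f, m)
        assert list(pairs["variant_id"]) == ["rs2"]
        assert report.n_allele_mismatch == 1

    def test_ambiguous_variants_counted_and_optionally_dropped(self):
        f, m = self._tables([("rs1", "1", 100, "A", "T", 0.05, 0.01, 1e-6)],
                            [("rs1", "1", 100, "A", "T", 0.03, 0.01, 1e-3)])
        pairs, report = harmonize_pair(f, m)
        assert len(pairs) == 1 and report.n_ambiguous == 1
        with pytest.raises(ValueError):
            harmonize_pair(f, m, ambiguous="drop")  # nothing left

    def test_empty_intersection_fatal(self):
        f, m = self._tables([("rs1", "1", 100, "A", "G", 0.05, 0.01, 1e-6)],
                            [("rs9", "1", 900, "A", "G", 0.03, 0.01, 1e-3)])
        with pytest.raises(ValueError, match="empty intersection"):
            harmonize_pair(f, m)

    def test_order_invariance_up_to_roles(self):
        f, m = self._tables([("rs1", "1", 100, "A", "G", 0.05, 0.011, 1e-6),
                             ("rs2", "2", 200, "C", "T", -0.02, 0.012, 1e-3)],
                            [("rs1", "1", 100, "A", "G", 0.03, 0.013, 1e-3),
                             ("rs2", "2", 200, "C", "T", 0.01, 0.014, 0.5)])
        p1, _ = harmonize_pair(f, m)
        p2, _ = harmonize_pair(m, f)
        np.testing.assert_allclose(p1["b_f"], p2["b_f"])
        np.testing.assert_allclose(p1["b_m"], p2["b_m"])
        np.testing.assert_allclose(p1["se_m"], p2["se_m"])

    def test_pairs_write_roundtrip(self, tmp_path):
        f, m = self._tables([("rs1", "1", 100, "A", "G", 0.05, 0.01, 1e-6)],
                            [("rs1", "1", 100, "A", "G", 0.03, 0.01, 1e-3)])
        pairs, _ = harmonize_pair(f, m)
        out = tmp_path / "pairs.tsv"
        write_pairs(pairs, out)
        back = pd.read_csv(out, sep="\t")
        np.testing.assert_allclose(back["b_f"], pairs["b_f"], rtol=1e-12)
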