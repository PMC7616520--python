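"""Summary-statistic parsing and allele harmonization."""

import numpy as np
import pytest

from proxymr.gwas_io import (
    ColumnMappingError,
    EmptySummaryError,
    HarmonizationError,
    VariantAssociation,
    harmonize,
    merge_second_exposure,
    read_harmonized_tsv,
    read_summary_stats,
)
from proxymr.mr_core import ivw

from conftest import make_assoc, make_harmonized, make_stats


TSV = """SNP\tEA\tOA\tEAF\tBETA\tSE\tP\tN
rs1\tA\tG\t0.3\t0.10\t0.02\t5.7e-7\t10000
rs2\ta\tg\t0.4\t-0.05\t0.01\t5.7e-7\t10000
rs3\tC\tT\t0.2\t0.08\t0.02\t6.3e-5\t10000
"""


class TestReadSummaryStats:
    def test_parses_all_rows_and_uppercases_alleles(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text(TSV)
        stats = read_summary_stats(p, trait_label="x")
        assert len(stats) == 3
        assert stats["rs2"].effect_allele == "A"
        assert stats["rs2"].other_allele == "G"

    def test_invalid_rows_skipped(self, tmp_path):
        bad = TSV + "rs4\tA\tG\t0.3\t0.1\t0\t0.5\t10000\nrs5\tAT\tG\t0.3\t0.1\t0.1\t0.5\t10000\n"
        p = tmp_path / "s.tsv"
        p.write_text(bad)
        stats = read_summary_stats(p)
        # se=0 row and the indel row are both dropped
        assert len(stats) == 3

    def test_missing_mandatory_column_is_configuration_error(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text("SNP\tEA\tOA\tBETA\tP\tN\nrs1\tA\tG\t0.1\t0.5\t100\n")
        with pytest.raises(ColumnMappingError):
            read_summary_stats(p)

    def test_zero_parseable_rows_is_input_error(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text("SNP\tEA\tOA\tEAF\tBETA\tSE\tP\tN\nrs1\tA\tG\t0.3\tx\t0.02\t0.5\t100\n")
        with pytest.raises(EmptySummaryError):
            read_summary_stats(p)

    def test_custom_column_map_and_gzip(self, tmp_path):
        import gzip

        body = TSV.replace("SNP", "variant").replace("BETA", "b")
        p = tmp_path / "s.tsv.gz"
        with gzip.open(p, "wt") as fh:
            fh.write(body)
        stats = read_summary_stats(p, column_map={"rsid": "variant", "beta": "b"})
        assert len(stats) == 3

    def test_pval_beta_se_mismatch_warns_not_errors(self):
        with pytest.warns(UserWarning, match="implies"):
            make_assoc(beta=0.5, se=0.1, pval=0.5)


class TestHarmonize:
    def test_allele_swap_flips_outcome_beta(self):
        exp = make_stats("x", [make_assoc(beta=0.10)])
        out = make_stats("y", [make_assoc(ea="G", oa="A", beta=-0.05, eaf=0.7)])
        h = harmonize(exp, out)
        assert h.beta_y[0] == pytest.approx(0.05)

    def test_strand_complement_same_orientation_unchanged(self):
        exp = make_stats("x", [make_assoc(ea="A", oa="G", beta=0.10)])
        out = make_stats("y", [make_assoc(ea="T", oa="C", beta=-0.05)])
        h = harmonize(exp, out)
        assert h.beta_y[0] == pytest.approx(-0.05)

    def test_strand_complement_swapped_flips(self):
        exp = make_stats("x", [make_assoc(ea="A", oa="G", beta=0.10)])
        out = make_stats("y", [make_assoc(ea="C", oa="T", beta=-0.05, eaf=0.7)])
        h = harmonize(exp, out)
        assert h.beta_y[0] == pytest.approx(0.05)

    def test_ambiguous_palindrome_dropped_under_infer(self):
        exp = make_stats("x", [make_assoc(ea="A", oa="T", eaf=0.50),
                               make_assoc(rsid="rs9", beta=0.2)])
        out = make_stats("y", [make_assoc(ea="A", oa="T", eaf=0.50),
                               make_assoc(rsid="rs9", beta=0.1)])
        h = harmonize(exp, out, palindrome_policy="infer", eaf_window=0.08)
        assert ("rs1", "ambiguous palindrome") in h.dropped
        assert h.rsids == ["rs9"]

    def test_unambiguous_palindrome_kept_when_concordant(self):
        exp = make_stats("x", [make_assoc(ea="A", oa="T", eaf=0.2, beta=0.1)])
        out = make_stats("y", [make_assoc(ea="T", oa="A", eaf=0.78, beta=0.3)])
        h = harmonize(exp, out)
        # swapped labels: aligned eaf 0.22, concordant with 0.2 -> beta negated
        assert h.beta_y[0] == pytest.approx(-0.3)

    def test_discordant_palindrome_dropped(self):
        exp = make_stats("x", [make_assoc(ea="A", oa="T", eaf=0.2),
                               make_assoc(rsid="rs9")])
        out = make_stats("y", [make_assoc(ea="A", oa="T", eaf=0.8),
                               make_assoc(rsid="rs9")])
        h = harmonize(exp, out)
        assert ("rs1", "palindrome eaf discordant") in h.dropped

    def test_palindrome_policy_drop(self):
        exp = make_stats("x", [make_assoc(ea="C", oa="G", eaf=0.2),
                               make_assoc(rsid="rs9")])
        out = make_stats("y", [make_assoc(ea="C", oa="G", eaf=0.2),
                               make_assoc(rsid="rs9")])
        h = harmonize(exp, out, palindrome_policy="drop")
        assert h.rsids == ["rs9"]

    def test_palindrome_missing_eaf_always_dropped(self):
        exp = make_stats("x", [make_assoc(ea="A", oa="T", eaf=None),
                               make_assoc(rsid="rs9")])
        out = make_stats("y", [make_assoc(ea="A", oa="T", eaf=0.2),
                               make_assoc(rsid="rs9")])
        assert ("rs1", "ambiguous palindrome") in harmonize(exp, out).dropped

    def test_allele_mismatch_dropped(self):
        exp = make_stats("x", [make_assoc(ea="A", oa="G"), make_assoc(rsid="rs9")])
        out = make_stats("y", [make_assoc(ea="A", oa="C"), make_assoc(rsid="rs9")])
        assert ("rs1", "allele mismatch") in harmonize(exp, out).dropped

    def test_no_shared_rsids_raises(self):
        exp = make_stats("x", [make_assoc(rsid="rs1")])
        out = make_stats("y", [make_assoc(rsid="rs2")])
        with pytest.raises(HarmonizationError):
            harmonize(exp, out)

    def test_dropped_and_retained_partition_shared_set(self, default_trio):
        h = harmonize(default_trio.consumption, default_trio.outcome)
        shared = set(default_trio.consumption.rsids) & set(default_trio.outcome.rsids)
        assert set(h.rsids) | {r for r, _ in h.dropped} == shared
        assert not set(h.rsids) & {r for r, _ in h.dropped}

    def test_involution_already_aligned_is_noop(self):
        recs = [make_assoc(rsid=f"rs{i}", beta=0.1 * i) for i in range(1, 4)]
        exp = make_stats("x", recs)
        out = make_stats("y", recs)
        h = harmonize(exp, out)
        np.testing.assert_allclose(h.beta_y, [r.beta for r in recs])
        assert h.dropped == []

    def test_sign_coherence_of_downstream_ivw(self, default_trio):
        """Negating every exposure beta and swapping its allele labels
        must leave the IVW estimate unchanged."""
        cons, out = default_trio.consumption, default_trio.outcome
        flipped = make_stats(
            "x_flipped",
            [
                VariantAssociation(
                    rsid=r.rsid, effect_allele=r.other_allele, other_allele=r.effect_allele,
                    beta=-r.beta, se=r.se, pval=r.pval, n=r.n,
                    eaf=None if r.eaf is None else 1 - r.eaf,
                )
                for r in cons.records.values()
            ],
        )
        est1 = ivw(harmonize(cons, out))
        est2 = ivw(harmonize(flipped, out))
        assert est1.beta == pytest.approx(est2.beta, rel=1e-12)
        assert est1.se == pytest.approx(est2.se, rel=1e-12)


class TestMergeSecondExposure:
    def _base(self):
        exp = make_stats("x", [make_assoc(rsid=f"rs{i}", beta=0.1) for i in (1, 2, 3)])
        out = make_stats("y", [make_assoc(rsid=f"rs{i}", beta=0.05) for i in (1, 2, 3)])
        return harmonize(exp, out)

    def test_aligned_snp_copied(self):
        h2 = merge_second_exposure(self._base(), make_stats(
            "x2", [make_assoc(rsid=f"rs{i}", beta=0.2) for i in (1, 2, 3)]
        ))
        np.testing.assert_allclose(h2.beta_x2, 0.2)

    def test_swapped_alleles_negated(self):
        x2 = make_stats("x2", [
            make_assoc(rsid="rs1", ea="G", oa="A", beta=0.2, eaf=0.7),
            make_assoc(rsid="rs2", beta=0.2),
            make_assoc(rsid="rs3", beta=0.2),
        ])
        h2 = merge_second_exposure(self._base(), x2)
        np.testing.assert_allclose(h2.beta_x2, [-0.2, 0.2, 0.2])

    def test_missing_policy_drop_removes_and_logs(self):
        x2 = make_stats("x2", [make_assoc(rsid="rs1", beta=0.2),
                               make_assoc(rsid="rs3", beta=0.2)])
        h2 = merge_second_exposure(self._base(), x2, missing_policy="drop")
        assert h2.rsids == ["rs1", "rs3"]
        assert any(r == "rs2" for r, _ in h2.dropped)

    def test_missing_policy_zero_uses_sentinel(self):
        x2 = make_stats("x2", [make_assoc(rsid="rs1", beta=0.2),
                               make_assoc(rsid="rs3", beta=0.2)])
        h2 = merge_second_exposure(self._base(), x2, missing_policy="zero")
        assert h2.rsids == ["rs1", "rs2", "rs3"]
        assert h2.beta_x2[1] == 0.0
        assert h2.se_x2[1] >= 1e5


def test_harmonized_tsv_round_trip(tmp_path, default_trio):
    h = harmonize(default_trio.consumption, default_trio.outcome)
    h2 = merge_second_exposure(h, default_trio.biomarker)
    p = tmp_path / "h.tsv"
    h2.write_tsv(p, drop_log=tmp_path / "drops.tsv")
    back = read_harmonized_tsv(p)
    np.testing.assert_allclose(back.beta_x, h2.beta_x)
    np.testing.assert_allclose(back.beta_x2, h2.beta_x2)
    np.testing.assert_allclose(back.se_y, h2.se_y)
    assert back.rsids == h2.rsids
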