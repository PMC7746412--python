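import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mrsoc import (
    GenotypeMatrix, read_weights, harmonize, compute_prs, prs_correlation,
    PRSVector, fit_tsls,
)

WEIGHTS_TSV = (
    "snp\teffect_allele\tother_allele\tbeta\tse\tpval\n"
    "rs1\tA\tG\t0.2\t0.01\t1e-9\n"
    "rs2\tC\tT\t-0.1\t0.02\t2e-8\n"
    "rs3\tG\tA\t0.3\t0.03\t4e-10\n"
)


def make_panel(dosages, snps=None, counted=None, other=None):
    dosages = np.asarray(dosages, dtype=float)
    m = dosages.shape[1]
    snps = snps or [f"rs{j + 1}" for j in range(m)]
    counted = counted or ["A", "C", "G"][:m]
    other = other or ["G", "T", "A"][:m]
    variants = pd.DataFrame(
        {"snp": snps, "counted_allele": counted, "other_allele": other}
    )
    iids = np.array([f"i{k}" for k in range(dosages.shape[0])])
    return GenotypeMatrix(iids=iids, variants=variants, dosages=dosages)


class TestReadWeights:
    def test_well_formed(self):
        w = read_weights(io.StringIO(WEIGHTS_TSV))
        assert len(w) == 3
        assert list(w["snp"]) == ["rs1", "rs2", "rs3"]

    def test_duplicate_id_error_names_the_id(self):
        bad = WEIGHTS_TSV + "rs1\tT\tC\t0.5\t0.1\t0.5\n"
        with pytest.raises(ValueError, match="rs1"):
            read_weights(io.StringIO(bad))

    def test_missing_beta_row_dropped_with_warning(self):
        txt = WEIGHTS_TSV + "rs4\tT\tC\tNA\t0.1\t0.5\n"
        with pytest.warns(UserWarning, match="missing beta"):
            w = read_weights(io.StringIO(txt))
        assert len(w) == 3 and "rs4" not in set(w["snp"])

    def test_missing_mandatory_column_rejected(self):
        txt = "snp\teffect_allele\tbeta\nrs1\tA\t0.2\n"
        with pytest.raises(ValueError, match="other_allele"):
            read_weights(io.StringIO(txt))

    def test_ambiguous_variants_warned(self):
        txt = "snp\teffect_allele\tother_allele\tbeta\nrs9\tA\tT\t0.1\n"
        with pytest.warns(UserWarning, match="ambiguous"):
            read_weights(io.StringIO(txt))


class TestHarmonize:
    def test_matched_and_flipped_betas(self):
        panel = make_panel(np.zeros((2, 3)))
        w = read_weights(io.StringIO(WEIGHTS_TSV))
        # rs3 weights list G/A but the panel counts G as well -> kept;
        # flip rs1 to other-allele orientation in the weights
        w.loc[w["snp"] == "rs1", ["effect_allele", "other_allele"]] = ["G", "A"]
        h = harmonize(w, panel)
        assert list(h["snp"]) == ["rs1", "rs2", "rs3"]
        assert h.loc[h["snp"] == "rs1", "beta"].item() == pytest.approx(-0.2)
        assert h.loc[h["snp"] == "rs2", "beta"].item() == pytest.approx(-0.1)
        assert (h["effect_allele"] == panel.variants["counted_allele"]).all()

    def test_mismatched_alleles_dropped(self):
        panel = make_panel(np.zeros((2, 3)), counted=["A", "C", "T"],
                           other=["G", "T", "C"])
        w = read_weights(io.StringIO(WEIGHTS_TSV))
        h = harmonize(w, panel)  # rs3 alleles G/A do not match T/C
        assert list(h["snp"]) == ["rs1", "rs2"]

    def test_zero_overlap_is_error(self):
        panel = make_panel(np.zeros((2, 1)), snps=["rsX"], counted=["A"],
                           other=["G"])
        w = read_weights(io.StringIO(WEIGHTS_TSV))
        with pytest.raises(ValueError, match="overlap"):
            harmonize(w, panel)


class TestComputePrs:
    def test_direct_weighted_sum(self):
        panel = make_panel([[2.0, 0.0, 1.0]])
        w = pd.DataFrame({
            "snp": ["rs1", "rs2", "rs3"],
            "effect_allele": ["A", "C", "G"], "other_allele": ["G", "T", "A"],
            "beta": [0.1, -0.2, 0.3],
        })
        prs = compute_prs(panel, w)
        assert prs.score[0] == pytest.approx(0.5)
        assert prs.n_variants_used == 3

    def test_zero_betas_give_zero_scores(self):
        panel = make_panel(np.random.default_rng(0).integers(0, 3, (5, 3)))
        w = pd.DataFrame({"snp": ["rs1", "rs2", "rs3"],
                          "effect_allele": ["A", "C", "G"],
                          "other_allele": ["G", "T", "A"], "beta": [0.0] * 3})
        assert np.all(compute_prs(panel, w).score == 0.0)

    def test_unit_betas_count_alleles(self):
        dos = np.array([[2, 1, 0], [1, 1, 1]], dtype=float)
        panel = make_panel(dos)
        w = pd.DataFrame({"snp": ["rs1", "rs2", "rs3"],
                          "effect_allele": ["A", "C", "G"],
                          "other_allele": ["G", "T", "A"], "beta": [1.0] * 3})
        np.testing.assert_allclose(compute_prs(panel, w).score, dos.sum(axis=1))

    def test_missing_dosage_contributes_zero_and_is_counted(self):
        dos = np.array([[2.0, np.nan, 1.0], [1.0, 1.0, 1.0]])
        panel = make_panel(dos)
        w = pd.DataFrame({"snp": ["rs1", "rs2", "rs3"],
                          "effect_allele": ["A", "C", "G"],
                          "other_allele": ["G", "T", "A"],
                          "beta": [0.1, -0.2, 0.3]})
        prs = compute_prs(panel, w)
        assert prs.score[0] == pytest.approx(0.5)
        np.testing.assert_array_equal(prs.n_missing, [1, 0])

    def test_unharmonized_weights_rejected(self):
        panel = make_panel([[1.0]], snps=["rs1"], counted=["A"], other=["G"])
        w = pd.DataFrame({"snp": ["rs1"], "effect_allele": ["G"],
                          "other_allele": ["A"], "beta": [0.2]})
        with pytest.raises(ValueError, match="harmonize"):
            compute_prs(panel, w)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.lists(st.floats(-1, 1), min_size=3, max_size=3),
           st.lists(st.floats(-1, 1), min_size=3, max_size=3))
    def test_linearity_in_weights(self, b1, b2):
        dos = np.array([[2, 1, 0], [0, 2, 1], [1, 1, 2]], dtype=float)
        panel = make_panel(dos)
        def w(betas):
            return pd.DataFrame({"snp": ["rs1", "rs2", "rs3"],
                                 "effect_allele": ["A", "C", "G"],
                                 "other_allele": ["G", "T", "A"],
                                 "beta": betas})
        s1 = compute_prs(panel, w(b1)).score
        s2 = compute_prs(panel, w(b2)).score
        s12 = compute_prs(panel, w(np.add(b1, b2))).score
        np.testing.assert_allclose(s12, s1 + s2, atol=1e-12)


class TestFlipInvariance:
    def test_scores_invariant_to_panel_allele_storage(self):
        rng = np.random.default_rng(4)
        dos = rng.integers(0, 3, (50, 3)).astype(float)
        panel = make_panel(dos)
        w = read_weights(io.StringIO(WEIGHTS_TSV))
        base = compute_prs(panel, harmonize(w, panel)).score
        flipped = panel.flip_variant("rs2")
        new = compute_prs(flipped, harmonize(w, flipped)).score
        # allele-count offset shifts all scores equally; center both
        np.testing.assert_allclose(new - new.mean(), base - base.mean(),
                                   atol=1e-12)

    def test_iv_estimate_invariant_to_variant_storage(self):
        rng = np.random.default_rng(8)
        n = 400
        dos = rng.binomial(2, 0.3, (n, 3)).astype(float)
        panel = make_panel(dos)
        w = read_weights(io.StringIO(WEIGHTS_TSV))
        x = dos @ [0.4, -0.3, 0.2] + rng.standard_normal(n)
        y = 0.7 * x + rng.standard_normal(n)
        e1 = fit_tsls(x, y, compute_prs(panel, harmonize(w, panel)))
        flipped = panel.flip_variant("rs1")
        e2 = fit_tsls(x, y, compute_prs(flipped, harmonize(w, flipped)))
        assert e1.beta == pytest.approx(e2.beta, abs=1e-10)


class TestCorrelation:
    def _vec(self, score, iids=None):
        iids = iids if iids is not None else [f"i{k}" for k in range(len(score))]
        return PRSVector(iids=np.array(iids), score=np.asarray(score, float),
                         n_variants_used=1, n_missing=np.zeros(len(score), int))

    def test_self_correlation_is_one(self):
        a = self._vec([1.0, 2.0, 3.0, 4.0])
        assert prs_correlation(a, a).r == pytest.approx(1.0)

    def test_negated_score_gives_minus_one(self):
        a = self._vec([1.0, 2.0, 3.0, 4.0])
        b = self._vec([-1.0, -2.0, -3.0, -4.0])
        res = prs_correlation(a, b)
        assert res.r == pytest.approx(-1.0)
        assert res.r2 == pytest.approx(1.0)

    def test_independent_scores_are_near_zero(self):
        rng = np.random.default_rng(12)
        a = self._vec(rng.standard_normal(10_000))
        b = self._vec(rng.standard_normal(10_000))
        assert abs(prs_correlation(a, b).r) < 0.05

    def test_errors(self):
        with pytest.raises(ValueError, match="3 complete"):
            prs_correlation(self._vec([1.0, 2.0]), self._vec([1.0, 2.0]))
        with pytest.raises(ValueError, match="variance"):
            prs_correlation(self._vec([1.0] * 5), self._vec([1, 2, 3, 4, 5]))
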