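import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from histoprog.errors import AlignmentError, GroupSizeError, IPLParseError, ParameterError
from histoprog.pathways import (
    bh_adjust,
    correlate,
    differential_ipl,
    fit_variance_prior,
    ipl_from_frame,
    moderated_t,
    parse_ipl,
    write_ipl,
)


def _bh_oracle(p):
    """Literal step-up definition of the BH adjustment."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * m / rank_from_top)
        adj[i] = running
    return adj


class TestParseIPL:
    def test_example_id_parses(self, tmp_path):
        df = pd.DataFrame([[0.1, 0.2]], index=["19_EPHB3"], columns=["s1", "s2"])
        ipl = ipl_from_frame(df)
        assert ipl.pathway_index["19_EPHB3"] == 19
        assert ipl.concept["19_EPHB3"] == "EPHB3"

    def test_write_parse_roundtrip(self, tmp_path):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            rng.standard_normal((10, 4)),
            index=[f"{i}_G{i}" for i in range(10)],
            columns=[f"s{i}" for i in range(4)],
        )
        ipl = ipl_from_frame(df)
        path = tmp_path / "ipl.tsv"
        write_ipl(ipl, path)
        back = parse_ipl(path)
        np.testing.assert_allclose(back.values.to_numpy(), df.to_numpy())
        assert back.entity_ids == list(df.index)

    def test_missing_prefix_rejected(self):
        df = pd.DataFrame([[0.0]], index=["EPHB3"], columns=["s1"])
        with pytest.raises(IPLParseError, match="EPHB3"):
            ipl_from_frame(df)

    def test_duplicate_ids_rejected(self):
        df = pd.DataFrame([[0.0], [1.0]], index=["1_A", "1_A"], columns=["s1"])
        with pytest.raises(IPLParseError):
            ipl_from_frame(df)


class TestBHAdjust:
    def test_hand_evaluated_step_up(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_out_of_range_rejected(self):
        with pytest.raises(ParameterError):
            bh_adjust([0.5, 1.5])

    @settings(deadline=None, max_examples=30)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_bounds_property(self, p):
        adj = bh_adjust(p)
        assert (adj >= np.asarray(p) - 1e-12).all()
        assert (adj <= 1.0 + 1e-12).all()

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(1)
        for _ in range(1000):
            p = rng.uniform(size=rng.integers(1, 30))
            np.testing.assert_allclose(bh_adjust(p), _bh_oracle(p), atol=1e-12)


class TestCorrelate:
    def _features(self, n=30, f=4, seed=2):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            rng.standard_normal((n, f)),
            index=[f"s{i}" for i in range(n)],
            columns=[f"x{i}" for i in range(f)],
        )

    def test_self_correlation_is_one(self):
        feats = self._features()
        df = pd.DataFrame([feats["x0"].to_numpy()], index=["0_SELF"], columns=feats.index)
        res = correlate(feats, ipl_from_frame(df))
        row = res[(res["feature"] == "x0") & (res["entity_id"] == "0_SELF")].iloc[0]
        assert row["r"] == pytest.approx(1.0)
        assert row["p_adjusted"] <= 0.05

    def test_hand_sized_pearson_oracle(self):
        feats = self._features(n=5, f=1, seed=3)
        rng = np.random.default_rng(4)
        ent = rng.standard_normal(5)
        df = pd.DataFrame([ent], index=["1_E"], columns=feats.index)
        res = correlate(feats, ipl_from_frame(df))
        r_ref, p_ref = stats.pearsonr(feats["x0"], ent)
        assert res["r"].iloc[0] == pytest.approx(r_ref)
        assert res["p"].iloc[0] == pytest.approx(p_ref)

    def test_symmetry_under_matrix_swap(self):
        feats = self._features(n=20, f=3, seed=5)
        rng = np.random.default_rng(6)
        ent = pd.DataFrame(
            rng.standard_normal((3, 20)), index=["0_A", "1_B", "2_C"], columns=feats.index
        )
        a = correlate(feats, ipl_from_frame(ent))
        swapped = correlate(
            ent.T.rename(columns=str),
            ipl_from_frame(
                pd.DataFrame(
                    feats.T.to_numpy(),
                    index=[f"{i}_{c}" for i, c in enumerate(feats.columns)],
                    columns=feats.index,
                )
            ),
        )
        assert sorted(np.round(a["r"], 12)) == sorted(np.round(swapped["r"], 12))

    def test_too_few_shared_samples_rejected(self):
        feats = self._features(n=2)
        df = pd.DataFrame([[0.0, 1.0]], index=["0_A"], columns=feats.index)
        with pytest.raises(AlignmentError):
            correlate(feats, ipl_from_frame(df))

    def test_null_fdr_controlled(self):
        """Empirical FDR of BH-selected pairs stays <= 0.05 on pure noise."""
        rng = np.random.default_rng(7)
        n, f, e, reps = 100, 50, 50, 200
        fdp = []
        for rep in range(reps):
            F = rng.standard_normal((n, f))
            E = rng.standard_normal((e, n))
            feats = pd.DataFrame(F, index=[f"s{i}" for i in range(n)])
            feats.columns = [str(c) for c in feats.columns]
            ipl = ipl_from_frame(
                pd.DataFrame(E, index=[f"{i}_G{i}" for i in range(e)], columns=feats.index)
            )
            res = correlate(feats, ipl)
            n_sig = int(res["significant"].sum())
            fdp.append(1.0 if n_sig > 0 else 0.0)  # all discoveries are false
        # E[V/max(R,1)] <= alpha under independence; allow Monte-Carlo slack.
        assert np.mean(fdp) <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / reps)


class TestModeratedT:
    def _matrix(self, seed=8, n_ent=200, n1=12, n2=12):
        rng = np.random.default_rng(seed)
        V = rng.standard_normal((n_ent, n1 + n2)) * rng.uniform(0.5, 2.0, size=(n_ent, 1))
        mask = np.zeros(n1 + n2, bool)
        mask[:n1] = True
        return V, mask

    def test_equal_groups_give_zero_t(self):
        V, mask = self._matrix()
        V[0] = np.tile([1.0, 2.0], 12)  # identical values in both groups
        res = moderated_t(V, mask)
        assert res["t"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_large_shift_detected_after_bh(self):
        rng = np.random.default_rng(9)
        V = rng.standard_normal((300, 40))
        mask = np.zeros(40, bool)
        mask[:20] = True
        V[0, mask] += 5.0  # five pooled sds at n=20 per group
        df = pd.DataFrame(V, index=[f"{i}_G{i}" for i in range(300)])
        df.columns = [f"s{i}" for i in range(40)]
        res = differential_ipl(ipl_from_frame(df), mask.astype(int), threshold=0.1)
        assert res["p_adjusted"].iloc[0] <= 0.1
        assert bool(res["significant"].iloc[0])

    def test_null_matrix_fdr(self):
        rng = np.random.default_rng(10)
        false_hits = []
        for _ in range(100):
            V = rng.standard_normal((2000, 40))
            mask = np.zeros(40, bool)
            mask[:20] = True
            res = moderated_t(V, mask)
            adj = bh_adjust(res["p"].to_numpy())
            false_hits.append(1.0 if (adj <= 0.1).any() else 0.0)
        assert np.mean(false_hits) <= 0.1 + 2 * np.sqrt(0.1 * 0.9 / 100)

    def test_zero_prior_df_reduces_to_pooled_t(self):
        V, mask = self._matrix(seed=11)
        res = moderated_t(V, mask, prior_df=0)
        t_ref, p_ref = stats.ttest_ind(V[:, mask], V[:, ~mask], axis=1, equal_var=True)
        np.testing.assert_allclose(res["t"], t_ref, atol=1e-10)
        np.testing.assert_allclose(res["p"], p_ref, atol=1e-10)

    def test_matches_limma_oracle(self, tmp_path):
        """The moderation formulas agree with the reference R implementation."""
        V, mask = self._matrix(seed=3)
        V[:10, mask] += 1.5
        ours = moderated_t(V, mask)
        mpath = tmp_path / "m.tsv"
        np.savetxt(mpath, V, delimiter="\t")
        opath = tmp_path / "out.csv"
        script = f"""
        m <- as.matrix(read.table("{mpath}", sep="\\t"))
        suppressMessages(library(limma))
        grp <- factor(c(rep("A",12), rep("B",12)), levels=c("B","A"))
        fit <- eBayes(lmFit(m, model.matrix(~grp)))
        write.csv(data.frame(t=fit$t[,2], p=fit$p.value[,2]), "{opath}", row.names=FALSE)
        """
        subprocess.run(["Rscript", "-e", script], check=True, capture_output=True)
        ref = pd.read_csv(opath)
        np.testing.assert_allclose(ours["t"], ref["t"], atol=1e-8)
        np.testing.assert_allclose(ours["p"], ref["p"], atol=1e-8)

    def test_group_size_validation(self):
        V, _ = self._matrix()
        mask = np.zeros(24, bool)
        mask[0] = True
        with pytest.raises(GroupSizeError):
            moderated_t(V, mask)

    def test_variance_prior_moment_recovery(self):
        # Variances drawn from the assumed scaled-inverse-chi-square prior
        # should be recovered approximately by the moment matcher.
        rng = np.random.default_rng(12)
        d, d0, s0_sq = 20, 8.0, 1.7
        sigma2 = s0_sq * d0 / rng.chisquare(d0, size=5000)
        s2 = sigma2 * rng.chisquare(d, size=5000) / d
        s0_hat, d0_hat = fit_variance_prior(s2, d)
        assert s0_hat == pytest.approx(s0_sq, rel=0.1)
        assert d0_hat == pytest.approx(d0, rel=0.25)
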