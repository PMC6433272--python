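"""Array workflow: filtering, transforms, QC, empirical-Bayes testing."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps
from scipy.special import polygamma

from pawmeth import dm, synthdata as sd


def _pipeline(exp):
    retained, _ = dm.filter_probes(exp)
    common = dm.subset_common(exp, retained)
    M = dm.beta_to_m(exp.beta.loc[common])
    fit = dm.fit_two_group(M, exp.groups())
    return common, fit, dm.ebayes_moderate(fit)


class TestFilterProbes:
    def test_planted_failures_removed_exactly(self, tiny_experiment):
        exp, bad = tiny_experiment
        retained, log = dm.filter_probes(exp)
        assert set(log["probe_id"]) == set(bad)
        assert set(retained) == set(exp.beta.index) - set(bad)
        assert (log["reason"] == "detection").all()

    def test_idempotent(self, tiny_experiment):
        exp, _ = tiny_experiment
        retained, _ = dm.filter_probes(exp)
        sub = dm.BetaExperiment(
            exp.beta.loc[retained],
            exp.detection_p.loc[retained],
            exp.bead_count.loc[retained],
            exp.samples,
        )
        retained2, log2 = dm.filter_probes(sub)
        assert list(retained2) == list(retained) and len(log2) == 0

    def test_all_failing_rejected(self, tiny_experiment):
        exp, _ = tiny_experiment
        detp = exp.detection_p.copy()
        detp.iloc[:, :] = 0.9
        broken = dm.BetaExperiment(exp.beta, detp, exp.bead_count, exp.samples)
        with pytest.raises(ValueError, match="every probe"):
            dm.filter_probes(broken)

    def test_low_bead_rule(self, tiny_experiment):
        exp, _ = tiny_experiment
        beads = exp.bead_count.copy()
        target = exp.beta.index[20]
        beads.loc[target] = 1
        modified = dm.BetaExperiment(exp.beta, exp.detection_p, beads, exp.samples)
        _, log = dm.filter_probes(modified)
        assert target in set(log["probe_id"])
        row = log.set_index("probe_id").loc[target]
        assert "beads" in row["reason"]


class TestSubsetCommon:
    def test_generator_detectable_fraction_recovered(self):
        spec = sd.ArraySimSpec(n_probes=4000, frac_detectable=0.6, seed=13)
        exp, truth, _ = sd.gen_array_experiment(spec)
        retained, _ = dm.filter_probes(exp)
        common = dm.subset_common(exp, retained)
        assert len(common) / spec.n_probes == pytest.approx(0.6, abs=0.02)
        assert set(common) == set(exp.beta.index[truth.detectable])

    def test_clean_experiment_is_identity(self, tiny_experiment):
        exp, bad = tiny_experiment
        retained, _ = dm.filter_probes(exp)
        assert list(dm.subset_common(exp, retained)) == list(retained)

    def test_one_deaf_sample_empties_subset(self, tiny_experiment):
        exp, _ = tiny_experiment
        detp = exp.detection_p.copy()
        detp.iloc[:, 0] = 0.9
        broken = dm.BetaExperiment(exp.beta, detp, exp.bead_count, exp.samples)
        assert len(dm.subset_common(broken, broken.beta.index)) == 0


class TestBetaM:
    @pytest.mark.parametrize("beta,m", [(0.5, 0.0), (0.8, 2.0), (0.2, -2.0)])
    def test_known_values(self, beta, m):
        assert dm.beta_to_m(np.array([beta]))[0] == pytest.approx(m, abs=1e-12)

    @given(st.floats(1e-5, 1 - 1e-5))
    @settings(max_examples=100, deadline=None)
    def test_round_trip(self, beta):
        m = dm.beta_to_m(np.array([beta]))
        assert dm.m_to_beta(m)[0] == pytest.approx(beta, abs=1e-9)

    @given(st.floats(0.01, 0.49))
    @settings(max_examples=50, deadline=None)
    def test_antisymmetry_about_half(self, x):
        up = dm.beta_to_m(np.array([0.5 + x]))[0]
        down = dm.beta_to_m(np.array([0.5 - x]))[0]
        assert up == pytest.approx(-down, rel=1e-9)

    def test_strictly_increasing(self):
        grid = np.linspace(0.001, 0.999, 500)
        assert np.all(np.diff(dm.beta_to_m(grid)) > 0)


class TestQC:
    def test_bimodal_output_not_flagged(self, planted_array):
        _, exp, truth, _ = planted_array
        common = exp.beta.index[truth.detectable]
        qc = dm.beta_density_qc(exp, common)
        assert qc["flagged"] == []
        modes = np.array(list(qc["mode"].values()))
        assert np.all((modes < 0.25) | (modes > 0.45))

    def test_intermediate_pileup_flagged(self, planted_array):
        _, exp, _, _ = planted_array
        rng = np.random.default_rng(0)
        beta = pd.DataFrame(
            rng.uniform(0.25, 0.35, size=exp.beta.shape),
            index=exp.beta.index, columns=exp.beta.columns,
        )
        fake = dm.BetaExperiment(beta, exp.detection_p, exp.bead_count, exp.samples)
        qc = dm.beta_density_qc(fake)
        assert sorted(qc["flagged"]) == sorted(exp.beta.columns)

    def test_density_normalized(self, planted_array):
        _, exp, truth, _ = planted_array
        grid = np.linspace(-0.5, 1.5, 1001)
        qc = dm.beta_density_qc(exp, exp.beta.index[truth.detectable], grid=grid)
        for dens in qc["density"].values():
            assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=1e-3)

    def test_mds_identical_samples_collapse(self):
        M = pd.DataFrame(np.ones((50, 4)), columns=list("abcd"))
        coords = dm.mds_qc(M, top_k=50)
        assert np.allclose(coords.to_numpy(), 0.0, atol=1e-9)

    def test_mds_recovers_rank2_distances(self):
        """Exact for an intrinsically 2-D configuration."""
        rng = np.random.default_rng(2)
        latent = rng.normal(size=(6, 2))
        basis = rng.normal(size=(2, 200))
        M = pd.DataFrame((latent @ basis).T, columns=[f"s{i}" for i in range(6)])
        coords = dm.mds_qc(M, top_k=200).to_numpy()
        emb = np.linalg.norm(coords[:, None] - coords[None, :], axis=2)
        X = M.to_numpy().T
        true_d = np.linalg.norm(X[:, None] - X[None, :], axis=2)
        assert np.allclose(emb, true_d, atol=1e-8)

    def test_mds_separates_planted_clusters(self, planted_array):
        _, exp, truth, _ = planted_array
        common = exp.beta.index[truth.detectable]
        M = dm.beta_to_m(exp.beta.loc[common])
        coords = dm.mds_qc(M, top_k=500)
        groups = exp.groups()
        from sklearn.metrics import silhouette_score

        score = silhouette_score(coords[["dim1"]], groups)
        assert score > 0.5


class TestFitAndEbayes:
    def test_exact_logfc_without_noise(self):
        M = pd.DataFrame(
            np.array([[2.0, 2.0, 0.0, 0.0], [1.0, 1.5, 1.0, 1.5]]),
            columns=["L-1", "L-2", "C-1", "C-2"],
        )
        groups = pd.Series(["lymphoma", "lymphoma", "control", "control"],
                           index=M.columns)
        fit = dm.fit_two_group(M, groups)
        assert fit.logfc[0] == pytest.approx(2.0)
        assert fit.logfc[1] == pytest.approx(0.0)

    def test_label_swap_negates_logfc(self, planted_array):
        _, exp, truth, _ = planted_array
        common = exp.beta.index[truth.detectable]
        M = dm.beta_to_m(exp.beta.loc[common])
        g = exp.groups()
        fwd = dm.fit_two_group(M, g)
        swapped = g.map({"lymphoma": "control", "control": "lymphoma"})
        rev = dm.fit_two_group(M, swapped)
        assert np.allclose(fwd.logfc, -rev.logfc)

    def test_pooled_variance_matches_manual_fixture(self):
        rng = np.random.default_rng(3)
        M = pd.DataFrame(rng.normal(size=(5, 6)),
                         columns=["L-1", "L-2", "L-3", "C-1", "C-2", "C-3"])
        groups = pd.Series(["lymphoma"] * 3 + ["control"] * 3, index=M.columns)
        fit = dm.fit_two_group(M, groups)
        for i in range(5):
            a, b = M.iloc[i, :3], M.iloc[i, 3:]
            manual = (a.var(ddof=1) * 2 + b.var(ddof=1) * 2) / 4
            assert fit.s2[i] == pytest.approx(manual, rel=1e-12)

    def test_trigamma_inverse_round_trip(self):
        for y in (0.1, 1.0, 5.0, 50.0, 500.0):
            x = float(polygamma(1, y))
            assert dm.trigamma_inverse(x) == pytest.approx(y, abs=1e-8)

    def test_shrinkage_bounds(self, planted_array):
        _, exp, truth, _ = planted_array
        _, fit, _ = _pipeline(exp)
        lo = np.minimum(fit.s2, fit.s02)
        hi = np.maximum(fit.s2, fit.s02)
        assert np.all(fit.s2_post >= lo - 1e-12)
        assert np.all(fit.s2_post <= hi + 1e-12)

    def test_infinite_prior_df_limit(self):
        """With d0 = inf the moderated t reduces to logFC / (s0 * sqrt(2/n))."""
        fit = dm.DMFit(
            probe_ids=pd.Index([f"p{i}" for i in range(20)]),
            logfc=np.linspace(-1, 1, 20),
            s2=np.full(20, 0.25),  # constant variances force evar <= 0
            df_resid=6.0, n_case=4, n_control=4,
        )
        res = dm.ebayes_moderate(fit)
        assert np.isinf(fit.d0)
        expected = fit.logfc / (np.sqrt(fit.s02) * np.sqrt(0.5))
        assert np.allclose(res["t"], expected)

    def test_null_type_i_calibration(self, null_array):
        _, exp, _, _ = null_array
        _, _, res = _pipeline(exp)
        rate = (res["p_value"] < 0.05).mean()
        assert rate == pytest.approx(0.05, abs=0.02)

    def test_null_p_values_uniform(self, null_array):
        _, exp, _, _ = null_array
        _, _, res = _pipeline(exp)
        assert sps.kstest(res["p_value"], "uniform").pvalue > 0.01

    def test_matches_limma_reference(self, tmp_path):
        """Independent oracle: limma's eBayes on the same M matrix."""
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript unavailable")
        spec = sd.ArraySimSpec(n_probes=500, frac_dm=0.1, effect_mean=2.0, seed=3)
        exp, _, _ = sd.gen_array_experiment(spec)
        common, fit, res = _pipeline(exp)
        M = dm.beta_to_m(exp.beta.loc[common])
        M.to_csv(tmp_path / "m.tsv", sep="\t")
        (tmp_path / "groups.txt").write_text("\n".join(exp.groups()))
        script = """
        suppressMessages(library(limma))
        M <- as.matrix(read.delim("m.tsv", row.names=1))
        g <- factor(readLines("groups.txt"), levels=c("control", "lymphoma"))
        fit <- eBayes(lmFit(M, model.matrix(~g)))
        out <- topTable(fit, coef=2, number=Inf, sort.by="none")
        write.csv(data.frame(probe=rownames(out), logFC=out$logFC,
                             t=out$t, p=out$P.Value), "limma.csv", row.names=FALSE)
        """
        proc = subprocess.run(["Rscript", "-e", script], cwd=tmp_path,
                              capture_output=True, text=True)
        assert proc.returncode == 0, proc.stderr
        ref = pd.read_csv(tmp_path / "limma.csv").set_index("probe")
        assert np.allclose(ref["logFC"], res["logFC"], atol=1e-8)
        assert np.allclose(ref["t"], res["t"], atol=1e-6)
        assert np.allclose(ref["p"], res["p_value"], atol=1e-8)


class TestMVP:
    def test_planted_recall_and_direction(self, planted_array):
        _, exp, truth, manifest = planted_array
        common, _, res = _pipeline(exp)
        mvps = dm.mvp_table(res, 0.05, manifest)
        truth_dm = pd.Series(truth.is_dm, index=exp.beta.index)
        truth_dir = pd.Series(truth.direction, index=exp.beta.index)
        recall = truth_dm.loc[mvps.index].sum() / truth_dm.loc[common].sum()
        assert recall >= 0.8
        tp = mvps.index[truth_dm.loc[mvps.index]]
        want = np.where(truth_dir.loc[tp] > 0, "hyper", "hypo")
        assert (mvps.loc[tp, "direction"] == want).all()

    def test_zero_threshold_empty(self, planted_array):
        _, exp, _, _ = planted_array
        _, _, res = _pipeline(exp)
        assert len(dm.mvp_table(res, 0.0)) == 0

    def test_null_pass_rate(self, null_array):
        _, exp, _, _ = null_array
        _, _, res = _pipeline(exp)
        assert len(dm.mvp_table(res, 0.05)) / len(res) == pytest.approx(0.05, abs=0.02)

    def test_hyper_in_case_convention_end_to_end(self):
        """A probe with higher beta in lymphoma must be called 'hyper'."""
        spec = sd.ArraySimSpec(n_probes=500, frac_detectable=1.0, frac_dm=0.1,
                               effect_mean=3.0, frac_hyper=1.0, seed=21)
        exp, truth, _ = sd.gen_array_experiment(spec)
        dm_probes = exp.beta.index[truth.is_dm]
        case_cols = exp.samples.loc[exp.samples.group == "lymphoma", "sample"]
        ctrl_cols = exp.samples.loc[exp.samples.group == "control", "sample"]
        # planted hyper: beta really is higher in lymphoma on average
        assert (
            exp.beta.loc[dm_probes, case_cols].mean(axis=1)
            > exp.beta.loc[dm_probes, ctrl_cols].mean(axis=1)
        ).mean() > 0.95
        _, _, res = _pipeline(exp)
        mvps = dm.mvp_table(res, 0.05)
        called = mvps.index.intersection(dm_probes)
        assert (mvps.loc[called, "direction"] == "hyper").all()


class TestBH:
    def test_single_and_equal_values_unchanged(self):
        assert dm.bh_adjust([0.02])[0] == pytest.approx(0.02)
        assert np.allclose(dm.bh_adjust([0.3] * 5), 0.3)

    def test_matches_brute_force_definition(self):
        """Direct step-up formula on a 6-value fixture."""
        p = np.array([0.01, 0.4, 0.03, 0.005, 0.8, 0.03])
        m = len(p)
        order = np.argsort(p)
        raw = p[order] * m / np.arange(1, m + 1)
        stepped = np.minimum.accumulate(raw[::-1])[::-1]
        expected = np.empty(m)
        expected[order] = np.minimum(stepped, 1.0)
        assert np.allclose(dm.bh_adjust(p), expected)
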