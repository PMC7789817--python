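"""QC and preprocessing: value transforms, probe/sample filters, sex
prediction, bimodality, PCA and matched-control selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from episig.datasets import MethylationDataset
from episig.qc import (
    beta_to_m,
    check_bimodality,
    compute_beta,
    filter_probes,
    m_to_beta,
    match_controls,
    pca_scores,
    predict_sex,
    sample_qc,
)
from episig.simulate import CohortDesign, make_probe_manifest, simulate_cohort


class TestBetaAndM:
    @pytest.mark.parametrize(
        "meth,unmeth,offset,expected",
        [(600, 400, 0, 0.6), (0, 0, 100, 0.0), (300, 100, 100, 0.6)],
    )
    def test_beta_examples(self, meth, unmeth, offset, expected):
        assert compute_beta(meth, unmeth, offset) == pytest.approx(expected)

    def test_zero_denominator_is_zero_with_warning(self):
        with pytest.warns(UserWarning):
            assert compute_beta(0.0, 0.0, 0.0) == 0.0

    @pytest.mark.parametrize("b,m", [(0.5, 0.0), (0.8, 2.0), (0.2, -2.0)])
    def test_m_examples(self, b, m):
        assert beta_to_m(b) == pytest.approx(m)

    @settings(max_examples=200, derandomize=True)
    @given(st.floats(min_value=1e-5, max_value=1 - 1e-5))
    def test_m_roundtrip_identity(self, b):
        assert m_to_beta(beta_to_m(b)) == pytest.approx(b, abs=1e-12)

    @settings(max_examples=100, derandomize=True)
    @given(st.floats(min_value=1e-5, max_value=1 - 1e-5))
    def test_m_antisymmetry(self, b):
        assert beta_to_m(1 - b) == pytest.approx(-beta_to_m(b), abs=1e-9)


def _toy_dataset(n_probes=10, n_samples=3, flags=None, detection_fail=None):
    manifest = pd.DataFrame(
        {
            "probe_id": [f"p{i}" for i in range(n_probes)],
            "chrom": ["chr1"] * n_probes,
            "pos": np.arange(1, n_probes + 1) * 100,
            "flag_snp": False,
            "flag_cross_reactive": False,
            "is_sex_chrom": False,
        }
    )
    if flags:
        for col, idx in flags.items():
            manifest.loc[idx, col] = True
            if col == "is_sex_chrom":
                manifest.loc[idx, "chrom"] = "chrX"
                # keep (chrom, pos) sorted order stable for the test
    samples = pd.DataFrame(
        {
            "sample_id": [f"s{j}" for j in range(n_samples)],
            "age": 10,
            "sex": "female",
            "batch": "B1",
            "cohort": "control",
        }
    )
    rng = np.random.default_rng(0)
    beta = pd.DataFrame(
        rng.uniform(0.05, 0.95, (n_probes, n_samples)),
        index=manifest["probe_id"],
        columns=samples["sample_id"],
    )
    det = pd.DataFrame(0.0, index=manifest["probe_id"], columns=samples["sample_id"])
    if detection_fail:
        for pid in detection_fail:
            det.loc[pid, samples["sample_id"][0]] = 0.5
    return MethylationDataset(manifest=manifest, beta=beta, samples=samples, detection_p=det)


class TestFilterProbes:
    def test_disjoint_flag_enumeration(self):
        ds = _toy_dataset(
            flags={"is_sex_chrom": [0, 1], "flag_snp": [2], "flag_cross_reactive": [3]},
            detection_fail=["p4"],
        )
        out, report = filter_probes(ds)
        assert out.n_probes == 5
        reasons = report.probes.set_index("probe_id")["reason"]
        assert reasons["p2"] == "snp" and reasons["p4"] == "detection"

    def test_identity_when_nothing_flagged(self):
        ds = _toy_dataset()
        out, _ = filter_probes(ds)
        assert out.n_probes == ds.n_probes
        pd.testing.assert_frame_equal(out.beta, ds.beta)

    def test_idempotent(self):
        ds = _toy_dataset(flags={"flag_snp": [2, 5]})
        once, _ = filter_probes(ds)
        twice, _ = filter_probes(once)
        pd.testing.assert_frame_equal(once.beta, twice.beta)

    def test_all_removed_raises(self):
        ds = _toy_dataset(flags={"flag_snp": list(range(10))})
        with pytest.raises(ValueError):
            filter_probes(ds)


class TestSampleQc:
    @pytest.mark.parametrize(
        "fail_fraction,excluded", [(0.0, False), (0.06, True), (0.05, False)]
    )
    def test_failed_probe_rate_threshold_is_strict(self, fail_fraction, excluded):
        n = 100
        ds = _toy_dataset(n_probes=n)
        k = int(round(fail_fraction * n))
        ds.detection_p.iloc[:k, 0] = 0.5
        report = sample_qc(ds, max_fail_rate=0.05)
        assert bool(report.samples.loc[0, "excluded"]) is excluded


class TestPredictSex:
    def test_generator_truth_recovered(self, sex_cohort):
        pred = predict_sex(sex_cohort)
        truth = sex_cohort.samples.set_index("sample_id")["sex"]
        assert (pred == truth).all()

    def test_discordant_sample_flagged(self, sex_cohort):
        ds = sex_cohort
        flipped = ds.samples.copy()
        flipped.loc[0, "sex"] = (
            "male" if flipped.loc[0, "sex"] == "female" else "female"
        )
        ds2 = MethylationDataset(
            manifest=ds.manifest, beta=ds.beta, samples=flipped,
            meth=ds.meth, unmeth=ds.unmeth, detection_p=ds.detection_p,
        )
        report = sample_qc(ds2)
        assert bool(report.samples.loc[0, "sex_discordant"])

    def test_no_sex_probes_raises(self, small_manifest):
        ds = simulate_cohort(
            small_manifest,
            CohortDesign(n_cases=2, n_controls=4, n_probes=2000, n_signal_probes=0,
                         delta_beta=0.0, seed=0),
        )
        with pytest.raises(ValueError):
            predict_sex(ds)


class TestBimodality:
    def test_bimodal_mixture_passes(self):
        rng = np.random.default_rng(1)
        b = np.concatenate([rng.beta(1, 20, 500), rng.beta(20, 1, 500)])
        assert check_bimodality(b)

    def test_uniform_fails(self):
        rng = np.random.default_rng(2)
        assert not check_bimodality(rng.uniform(0, 1, 2000))

    def test_degenerate_midpoint_fails(self):
        assert not check_bimodality(np.full(200, 0.5))


class TestPca:
    def test_identical_samples_identical_scores(self):
        rng = np.random.default_rng(3)
        col = rng.normal(size=50)
        M = np.column_stack([col, col, rng.normal(size=50)])
        scores, _ = pca_scores(M, k=2)
        assert np.allclose(scores[0], scores[1], atol=1e-10)

    def test_scores_covariance_is_diagonal(self):
        rng = np.random.default_rng(4)
        M = rng.normal(size=(100, 12))
        scores, explained = pca_scores(M, k=4)
        cov = np.cov(scores.T)
        off = cov - np.diag(np.diag(cov))
        assert np.abs(off).max() < 1e-10
        assert np.allclose(np.diag(cov), explained)

    def test_rank_truncation_warns(self):
        col = np.arange(30.0)
        M = np.column_stack([col, 2 * col, 3 * col])  # rank 1 after centering
        with pytest.warns(UserWarning, match="rank"):
            scores, _ = pca_scores(M, k=3)


class TestMatchControls:
    def _sheets(self, n_cases=5, clones=4, extra=30, seed=0):
        rng = np.random.default_rng(seed)
        cases = pd.DataFrame(
            {
                "sample_id": [f"case{i}" for i in range(n_cases)],
                "age": rng.integers(3, 18, n_cases),
                "sex": rng.choice(["male", "female"], n_cases),
                "batch": rng.choice(["B1", "B2"], n_cases),
                "cohort": "case",
            }
        )
        rows = []
        for _, c in cases.iterrows():
            for j in range(clones):
                rows.append((f"{c.sample_id}_clone{j}", c.age, c.sex, c.batch, "control"))
        for j in range(extra):
            rows.append(
                (f"extra{j}", rng.integers(3, 18), rng.choice(["male", "female"]),
                 rng.choice(["B1", "B2"]), "control")
            )
        pool = pd.DataFrame(rows, columns=["sample_id", "age", "sex", "batch", "cohort"])
        ids = list(cases["sample_id"]) + list(pool["sample_id"])
        M = pd.DataFrame(rng.normal(size=(40, len(ids))), columns=ids)
        return cases, pool, M

    def test_exact_clones_selected(self):
        cases, pool, M = self._sheets()
        chosen = match_controls(cases, pool, M, ratio=4)
        assert sorted(chosen) == sorted(
            pool[pool["sample_id"].str.contains("clone")]["sample_id"]
        )

    def test_eleven_cases_ratio_four_gives_44(self, sex_cohort):
        ds = sex_cohort
        cases = ds.samples[ds.samples["cohort"] == "case"]
        pool = ds.samples[ds.samples["cohort"] == "control"]
        chosen = match_controls(cases, pool, ds.beta, ratio=4)
        assert len(chosen) == 44
        assert len(set(chosen)) == 44
        assert set(chosen) <= set(pool["sample_id"])
        assert not set(chosen) & set(cases["sample_id"])

    def test_planted_outlier_removed_and_replaced(self):
        cases, pool, M = self._sheets(seed=5)
        victim = pool[pool["sample_id"].str.contains("clone")]["sample_id"].iloc[0]
        M = M.copy()
        M[victim] = M[victim] + 200.0  # gross PC1 outlier
        chosen = match_controls(cases, pool, M, ratio=4)
        assert victim not in chosen
        assert len(chosen) == 4 * len(cases)

    def test_exhausted_pool_raises(self):
        cases, pool, M = self._sheets(clones=1, extra=0)
        with pytest.raises(ValueError, match="exhausted|candidates"):
            match_controls(cases, pool, M, ratio=4)
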