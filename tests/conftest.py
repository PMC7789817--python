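"""Shared fixtures: synthetic cohorts generated once per session.

The heavier fixtures reproduce the study conditions (11 cases vs a
4x control panel, 20,000 probes, 1,000 planted signature probes at a
15% beta shift; disjoint-signature specificity cohorts; planted 22q13
deletions) and are shared between unit and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from episig.classifier import MvpModel, select_features
from episig.cnv import CopyNumberModel, GenomicInterval
from episig.simulate import (
    CohortDesign,
    PlateDesign,
    make_probe_manifest,
    plant_deletion,
    simulate_cohort,
    simulate_plate_run,
)
from episig.metabolomics import PlateComparison, PlateLayout


@pytest.fixture(scope="session")
def small_manifest():
    return make_probe_manifest(2000, seed=1)


@pytest.fixture(scope="session")
def sex_manifest():
    return make_probe_manifest(
        3000, chrom_plan={"chr1": 2500, "chrX": 300, "chrY": 200}, seed=2
    )


@pytest.fixture(scope="session")
def sex_cohort(sex_manifest):
    return simulate_cohort(
        sex_manifest,
        CohortDesign(
            n_cases=11, n_controls=80, n_probes=3000, n_signal_probes=100,
            delta_beta=0.15, seed=5,
        ),
    )


@pytest.fixture(scope="session")
def signature_cohort():
    """Study-scale cohort: 11 cases vs 44 controls, 20,000 probes, 1,000
    planted signature probes at delta beta 0.15 (80% hypermethylated)."""
    manifest = make_probe_manifest(20_000, seed=1)
    return simulate_cohort(manifest, CohortDesign(seed=5))


@pytest.fixture(scope="session")
def confounded_null_cohort():
    """No planted signal; case blood composition shifted (dominant type
    from ~0.55 to ~0.70 mean proportion)."""
    manifest = make_probe_manifest(20_000, seed=1)
    return simulate_cohort(
        manifest,
        CohortDesign(n_signal_probes=0, delta_beta=0.0, case_cell_shift=0.5, seed=7),
    )


@pytest.fixture(scope="session")
def mvp_harness():
    """Three disjoint-signature cohorts on one manifest plus a trained
    MVP model: cohort A is the target syndrome (11 cases, 80 controls),
    B and C are other syndromes whose 300-probe signatures share no
    probes with A's."""
    manifest = make_probe_manifest(5000, seed=11)
    rng = np.random.default_rng(99)
    autosomal = manifest.loc[~manifest["is_sex_chrom"], "probe_id"].to_numpy()
    picks = rng.choice(autosomal, size=900, replace=False)
    sets = [list(np.sort(picks[i * 300 : (i + 1) * 300])) for i in range(3)]

    def _cohort(sig, n_controls, seed):
        return simulate_cohort(
            manifest,
            CohortDesign(
                n_cases=11, n_controls=n_controls, n_probes=5000,
                n_signal_probes=300, delta_beta=0.2, signal_probe_ids=sig, seed=seed,
            ),
        )

    ds_a = _cohort(sets[0], 80, 21)
    ds_b = _cohort(sets[1], 5, 22)
    ds_c = _cohort(sets[2], 5, 23)

    case = ds_a.sample_ids("case")
    ctrl = ds_a.sample_ids("control")
    probes = select_features(ds_a.beta, case, ctrl[:44], min_diff=0.10)
    b_case, c_case = ds_b.sample_ids("case"), ds_c.sample_ids("case")
    # 75/25 train/test split of the other-syndrome cohorts
    b_train, b_test = b_case[:8], b_case[8:]
    c_train, c_test = c_case[:8], c_case[8:]
    X = pd.concat(
        [
            ds_a.beta.loc[probes, case + ctrl].T,
            ds_b.beta.loc[probes, b_train].T,
            ds_c.beta.loc[probes, c_train].T,
        ]
    )
    y = ["phmds"] * len(case) + ["control"] * (len(ctrl) + len(b_train) + len(c_train))
    model = MvpModel(X, y).fit(seed=0)
    return {
        "manifest": manifest,
        "ds_a": ds_a,
        "ds_b": ds_b,
        "ds_c": ds_c,
        "probes": probes,
        "model": model,
        "b_test": b_test,
        "c_test": c_test,
    }


CNV_SIZES_MB = [0.1, 0.25, 0.5, 0.75, 1.0, 1.5, 2.0, 3.0, 4.0, 5.0]


def build_cnv_fixture(seed: int, n_perm: int = 500):
    """Cohort with one planted heterozygous deletion per case sample
    (0.1-5 Mb on chr22) plus a 20%-mosaic case, and the fitted CNV model."""
    rng = np.random.default_rng(seed)
    manifest = make_probe_manifest(
        12_000,
        chrom_plan={"chr21": 6000, "chr22": 6000},
        seed=int(rng.integers(1 << 30)),
        min_spacing=1500,
        max_spacing=2500,
    )
    ds = simulate_cohort(
        manifest,
        CohortDesign(
            n_cases=11, n_controls=20, n_probes=12_000, n_signal_probes=0,
            delta_beta=0.0, seed=int(rng.integers(1 << 30)),
        ),
    )
    case = ds.sample_ids("case")
    ctrl = ds.sample_ids("control")
    chr22 = manifest[manifest["chrom"] == "chr22"]
    lo, hi = int(chr22["pos"].min()), int(chr22["pos"].max())
    truth = {}
    for sid, size in zip(case[:10], CNV_SIZES_MB):
        start = int(rng.integers(lo, hi - int(size * 1e6)))
        iv = GenomicInterval("chr22", start, start + int(size * 1e6))
        ds = plant_deletion(ds, [sid], iv, 0.5, noise_sd=0.05, seed=int(rng.integers(1 << 30)))
        truth[sid] = iv
    mosaic_id = case[10]
    # 20% mosaic heterozygous loss: mean copy number 1.8 -> factor 0.9
    ds = plant_deletion(
        ds,
        [mosaic_id],
        GenomicInterval("chr22", lo + 2_000_000, lo + 4_000_000),
        0.9,
        noise_sd=0.05,
        seed=int(rng.integers(1 << 30)),
    )
    results = CopyNumberModel(ds.meth, ds.unmeth, ds.manifest, ctrl, sample_ids=case).fit(
        n_perm=n_perm, seed=int(rng.integers(1 << 30))
    )
    return {"dataset": ds, "truth": truth, "mosaic_id": mosaic_id, "results": results}


@pytest.fixture(scope="session")
def cnv_fixture():
    return build_cnv_fixture(seed=51)


def build_plate_null(seed: int):
    """No planted effect: 11 case vs 50 control lines."""
    layout = PlateLayout()
    runs, blanks = simulate_plate_run(layout, PlateDesign(seed=seed))
    case = [r for r in runs if r.group == "case"]
    ctrl = [r for r in runs if r.group == "control"]
    return PlateComparison(case, ctrl, blanks, layout).fit()


@pytest.fixture(scope="session")
def plate_null_results():
    return build_plate_null(seed=13)

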