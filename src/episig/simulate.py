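"""Synthetic cohorts for the epi-signature pipeline.

Generates every input the analysis needs: a probe manifest, case/control
methylation cohorts with a planted (mainly hypermethylated)
epi-signature riding on blood-cell-composition mixtures, intensity
tracks with planted heterozygous deletions, and Biolog PM-M plate runs
with planted reduced-NADH wells. Every generator is a pure function of
its seed; planted ground truth travels with the outputs so recovery can
be scored exactly.

The cohort model: each sample's baseline beta profile is a Dirichlet-
weighted mixture of cell-type reference profiles; the case/control
contrast (``delta_beta``, applied at the signal probes in a fixed
hyper/hypo direction) is added to the group mean before noise; noise is
Gaussian on the M (logit) scale with a per-probe standard deviation
calibrated so the beta-scale spread is approximately ``noise_sd``.
Intensity pairs satisfy beta = meth / (meth + unmeth + offset) exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import MethylationDataset, validate_manifest
from .deconvolution import CellReference
from .metabolomics import PlateLayout, PlateRun

LN2 = np.log(2.0)

#: mean blood leukocyte composition used for the Dirichlet proportions
BLOOD_CELL_TYPES = ("neutrophil", "cd4t", "cd8t", "bcell", "monocyte", "nk")
BLOOD_CELL_MEANS = (0.55, 0.15, 0.10, 0.08, 0.08, 0.04)
DIRICHLET_CONCENTRATION = 60.0

DEFAULT_TOTAL_INTENSITY = 10_000.0


def make_probe_manifest(
    n_probes: int,
    chrom_plan: dict[str, int] | None = None,
    seed: int = 0,
    flagged_fraction: float = 0.01,
    min_spacing: int = 200,
    max_spacing: int = 2000,
) -> pd.DataFrame:
    """Deterministic synthetic probe manifest.

    ``chrom_plan`` maps chromosome name to probe count (must sum to
    ``n_probes``; default splits evenly over chr1..chr3). Positions are
    strictly increasing within each chromosome with uniform random
    spacing. A fraction of autosomal probes carries SNP and
    cross-reactive flags, assigned by count (deterministic), not by coin
    flips; chrX/chrY probes carry ``is_sex_chrom``.
    """
    if n_probes <= 0:
        raise ValueError("n_probes must be positive")
    if chrom_plan is None:
        base = n_probes // 3
        chrom_plan = {"chr1": base, "chr2": base, "chr3": n_probes - 2 * base}
    if sum(chrom_plan.values()) != n_probes:
        raise ValueError("chrom_plan counts must sum to n_probes")
    if any(v <= 0 for v in chrom_plan.values()):
        raise ValueError("chromosome probe counts must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for chrom, count in chrom_plan.items():
        gaps = rng.integers(min_spacing, max_spacing + 1, size=count)
        pos = 1_000_000 + np.cumsum(gaps)
        sex = chrom in ("chrX", "chrY", "X", "Y")
        for p in pos:
            rows.append((chrom, int(p), sex))
    manifest = pd.DataFrame(rows, columns=["chrom", "pos", "is_sex_chrom"])
    manifest["probe_id"] = [f"cg{i:08d}" for i in range(n_probes)]

    n_flag = int(round(flagged_fraction * n_probes))
    auto = np.where(~manifest["is_sex_chrom"].to_numpy())[0]
    snp_idx = rng.choice(auto, size=min(n_flag, auto.size), replace=False)
    remaining = np.setdiff1d(auto, snp_idx)
    cross_idx = rng.choice(remaining, size=min(n_flag, remaining.size), replace=False)
    manifest["flag_snp"] = False
    manifest["flag_cross_reactive"] = False
    manifest.loc[snp_idx, "flag_snp"] = True
    manifest.loc[cross_idx, "flag_cross_reactive"] = True
    return validate_manifest(manifest)


def make_cell_reference(
    manifest: pd.DataFrame,
    n_cell_types: int = 6,
    n_discriminating: int = 600,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[str]]:
    """Synthetic cell-type reference beta profiles over all manifest probes.

    Most probes share a common bimodal baseline across cell types; a
    deterministic subset of ``n_discriminating`` probes is split evenly
    among the cell types, each marker probe high (~0.9) in its own type
    and low (~0.1) elsewhere — the strong contrast a reference-based
    deconvolution needs. Returns (cell types x probes profile frame, list
    of discriminating probe ids).
    """
    rng = np.random.default_rng(seed)
    probes = manifest["probe_id"].to_numpy()
    n = probes.size
    types = list(BLOOD_CELL_TYPES[:n_cell_types])
    if n_cell_types > len(BLOOD_CELL_TYPES):
        types += [f"cell{i}" for i in range(len(BLOOD_CELL_TYPES), n_cell_types)]
    # shared bimodal baseline
    low = rng.beta(2, 18, size=n)
    high = rng.beta(18, 2, size=n)
    is_high = rng.random(n) < 0.5
    base = np.where(is_high, high, low)
    profile = np.tile(base, (n_cell_types, 1))

    disc_idx = rng.choice(n, size=min(n_discriminating, n), replace=False)
    per_type = np.array_split(disc_idx, n_cell_types)
    for k, idx in enumerate(per_type):
        profile[:, idx] = rng.uniform(0.05, 0.15, size=(n_cell_types, idx.size))
        profile[k, idx] = rng.uniform(0.85, 0.95, size=idx.size)
    frame = pd.DataFrame(profile, index=types, columns=probes)
    return frame, list(probes[np.sort(disc_idx)])


@dataclass
class CohortDesign:
    """Study conditions for a synthetic methylation cohort.

    Defaults mirror the published study design: 11 cases against a
    4x-matched control panel drawn from a larger pool, a planted
    signature of 1000 probes at a 15% beta shift, mostly hypermethylated.
    """

    n_cases: int = 11
    n_controls: int = 44
    n_probes: int = 20_000
    n_signal_probes: int = 1000
    delta_beta: float = 0.15
    hyper_fraction: float = 0.8
    cell_reference: pd.DataFrame | None = None
    n_discriminating: int = 600
    batch_labels: tuple = ("B1", "B2")
    age_range: tuple = (3, 19)
    sex_ratio: float = 0.5
    noise_sd: float = 0.05
    beta_offset: float = 100.0
    #: shift of case Dirichlet weight toward the first cell type (builds
    #: cell-composition-confounded cohorts; 0 = no confounding)
    case_cell_shift: float = 0.0
    #: explicit signal-probe ids (overrides the seeded random choice);
    #: lets harnesses plant provably disjoint signatures across cohorts
    signal_probe_ids: list | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.delta_beta < 1.0:
            raise ValueError("delta_beta must lie in [0, 1)")
        if self.n_signal_probes > self.n_probes:
            raise ValueError("more signal probes than probes")
        if not 0.0 <= self.hyper_fraction <= 1.0:
            raise ValueError("hyper_fraction must lie in [0, 1]")


def _sample_sheet(design: CohortDesign, rng: np.random.Generator) -> pd.DataFrame:
    n = design.n_cases + design.n_controls
    ids = [f"case_{i:03d}" for i in range(design.n_cases)] + [
        f"ctrl_{i:03d}" for i in range(design.n_controls)
    ]
    cohort = ["case"] * design.n_cases + ["control"] * design.n_controls
    ages = rng.integers(design.age_range[0], design.age_range[1] + 1, size=n)
    sex = np.where(rng.random(n) < design.sex_ratio, "male", "female")
    batches = [design.batch_labels[i % len(design.batch_labels)] for i in range(n)]
    return pd.DataFrame(
        {"sample_id": ids, "age": ages, "sex": sex, "batch": batches, "cohort": cohort}
    )


def simulate_cohort(manifest: pd.DataFrame, design: CohortDesign) -> MethylationDataset:
    """Simulate a case/control beta + intensity cohort with planted signal.

    Signal probes are chosen deterministically from the seed; their
    baselines are drawn mid-range and made cell-type-invariant so the
    planted contrast survives the (0, 1) bounds (an out-of-range
    ``delta_beta`` raises). Ground truth (signal probes and directions,
    cell proportions, reference profiles) is stored in ``dataset.truth``.
    """
    manifest = validate_manifest(manifest)
    rng = np.random.default_rng(design.seed)
    n_probes = len(manifest)
    if design.n_probes != n_probes:
        raise ValueError("design.n_probes must match the manifest")

    if design.cell_reference is None:
        reference, disc = make_cell_reference(
            manifest, n_discriminating=design.n_discriminating, seed=design.seed
        )
    else:
        reference = design.cell_reference
        disc = list(reference.columns)
    n_types = reference.shape[0]

    samples = _sample_sheet(design, rng)
    n_samples = len(samples)
    is_case = (samples["cohort"] == "case").to_numpy()

    # signal probes: autosomal, deterministic choice; fixed directions
    auto_idx = np.where(~manifest["is_sex_chrom"].to_numpy())[0]
    if design.signal_probe_ids is not None:
        lookup = pd.Index(manifest["probe_id"])
        sig_idx = np.sort(lookup.get_indexer(design.signal_probe_ids))
        if (sig_idx < 0).any():
            raise ValueError("signal_probe_ids not all present in the manifest")
        if len(sig_idx) != design.n_signal_probes:
            raise ValueError("signal_probe_ids length must equal n_signal_probes")
    else:
        sig_idx = np.sort(rng.choice(auto_idx, size=design.n_signal_probes, replace=False))
    n_hyper = int(round(design.hyper_fraction * design.n_signal_probes))
    direction = np.concatenate(
        [np.ones(n_hyper), -np.ones(design.n_signal_probes - n_hyper)]
    )

    profile = reference.to_numpy(dtype=float).copy()  # types x probes
    if design.n_signal_probes and design.delta_beta > 0:
        hyper_base = rng.uniform(0.25, 0.45, size=n_hyper)
        hypo_base = rng.uniform(0.55, 0.75, size=design.n_signal_probes - n_hyper)
        base = np.concatenate([hyper_base, hypo_base])
        if np.any(base + direction * design.delta_beta >= 1.0) or np.any(
            base + direction * design.delta_beta <= 0.0
        ):
            raise ValueError("delta_beta pushes signal-probe means outside (0, 1)")
        profile[:, sig_idx] = base  # cell-type invariant at signal probes

    # per-sample Dirichlet cell proportions (case shift optional)
    alpha = np.asarray(BLOOD_CELL_MEANS[:n_types], dtype=float)
    alpha = alpha / alpha.sum() * DIRICHLET_CONCENTRATION
    W = rng.dirichlet(alpha, size=n_samples)
    if design.case_cell_shift:
        shifted = alpha.copy()
        shifted[0] += design.case_cell_shift * DIRICHLET_CONCENTRATION
        W[is_case] = rng.dirichlet(shifted, size=int(is_case.sum()))

    mu = W @ profile  # samples x probes
    if design.n_signal_probes and design.delta_beta > 0:
        mu[np.ix_(is_case, sig_idx)] += direction * design.delta_beta

    # logit-normal noise: Gaussian on M scale, sd calibrated so the
    # beta-scale spread approximates noise_sd for mid-range probes; the
    # cap keeps extreme-methylation probes tight on the beta scale (as on
    # real arrays) instead of letting the logit blow the tails up
    mu = np.clip(mu, 1e-3, 1.0 - 1e-3)
    m = np.log2(mu / (1.0 - mu))
    sd_m = np.minimum(design.noise_sd / (LN2 * mu * (1.0 - mu)), 8.0 * design.noise_sd)
    m_noisy = m + rng.standard_normal(mu.shape) * sd_m
    beta = 1.0 / (1.0 + np.exp2(-m_noisy))
    beta = np.clip(beta, 1e-4, 1.0 - 1e-4)
    beta = beta.T  # probes x samples

    # intensities consistent with beta at the configured offset; the
    # per-probe factor reproduces the wide probe-to-probe brightness
    # spread of real arrays (quantile normalization relies on it)
    probe_factor = rng.lognormal(0.0, 0.5, size=n_probes)
    total = (
        DEFAULT_TOTAL_INTENSITY
        * probe_factor[:, None]
        * rng.lognormal(0.0, 0.1, size=beta.shape)
    )
    on_x = manifest["chrom"].isin(["chrX", "X"]).to_numpy()
    on_y = manifest["chrom"].isin(["chrY", "Y"]).to_numpy()
    male = (samples["sex"] == "male").to_numpy()
    total[np.ix_(on_x, male)] *= 0.5
    total[np.ix_(on_y, male)] *= 0.5
    total[np.ix_(on_y, ~male)] *= 0.05
    meth = beta * (total + design.beta_offset)
    unmeth = total - meth
    neg = unmeth < 0
    if neg.any():  # only possible for beta near 1 with tiny totals
        meth[neg] = total[neg]
        unmeth[neg] = 0.0
    # recompute beta from the stored intensities so the
    # beta = meth / (meth + unmeth + offset) identity is exact
    beta = meth / (total + design.beta_offset)

    detection_p = rng.uniform(0.0, 0.005, size=beta.shape)

    probe_ids = manifest["probe_id"].to_numpy()
    ids = samples["sample_id"].to_numpy()
    mk = lambda arr: pd.DataFrame(arr, index=probe_ids, columns=ids)
    truth = {
        "signal_probes": list(probe_ids[sig_idx]),
        "signal_direction": pd.Series(direction, index=probe_ids[sig_idx]),
        "cell_proportions": pd.DataFrame(W, index=ids, columns=reference.index),
        # the effective reference actually mixed into the samples (signal
        # probes are cell-invariant baselines, not the raw draw)
        "cell_reference": pd.DataFrame(profile, index=reference.index, columns=probe_ids),
        "discriminating_probes": disc,
        "deletions": {},
    }
    return MethylationDataset(
        manifest=manifest,
        beta=mk(beta),
        samples=samples,
        meth=mk(meth),
        unmeth=mk(unmeth),
        detection_p=mk(detection_p),
        beta_offset=design.beta_offset,
        truth=truth,
    )


def deconvolution_reference(ds: MethylationDataset) -> CellReference:
    """The generator's cell reference restricted to its discriminating
    probes, packaged for :mod:`episig.deconvolution`."""
    ref = ds.truth["cell_reference"]
    return CellReference(ref[ds.truth["discriminating_probes"]])


def plant_deletion(
    ds: MethylationDataset,
    sample_ids: list[str],
    interval,
    intensity_factor: float = 0.5,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> MethylationDataset:
    """Scale intensities of probes inside ``interval`` for the listed
    samples by ``intensity_factor`` (0.5 = heterozygous loss), optionally
    with multiplicative log-normal measurement noise. Betas are untouched
    (copy number changes total signal, not the methylated fraction).
    """
    if not 0.0 < intensity_factor <= 1.0:
        raise ValueError("intensity_factor must lie in (0, 1]")
    unknown = set(sample_ids) - set(ds.samples["sample_id"])
    if unknown:
        raise KeyError(f"unknown sample ids: {sorted(unknown)}")
    if interval.end < interval.start:
        raise ValueError("empty interval")
    man = ds.manifest
    mask = (
        (man["chrom"] == interval.chrom)
        & (man["pos"] >= interval.start)
        & (man["pos"] <= interval.end)
    ).to_numpy()
    if interval.chrom not in set(man["chrom"]):
        raise ValueError(f"interval chromosome {interval.chrom} not in manifest")
    if not mask.any():
        warnings.warn("planted interval overlaps no probes; dataset unchanged")
        return ds
    meth = ds.meth.copy()
    unmeth = ds.unmeth.copy()
    rng = np.random.default_rng(seed)
    for sid in sample_ids:
        factor = intensity_factor
        if noise_sd > 0:
            factor = factor * rng.lognormal(0.0, noise_sd, size=int(mask.sum()))
        meth.loc[mask, sid] *= factor
        unmeth.loc[mask, sid] *= factor
    truth = dict(ds.truth)
    deletions = {k: list(v) for k, v in truth.get("deletions", {}).items()}
    for sid in sample_ids:
        deletions.setdefault(sid, []).append(interval)
    truth["deletions"] = deletions
    return MethylationDataset(
        manifest=ds.manifest,
        beta=ds.beta,
        samples=ds.samples,
        meth=meth,
        unmeth=unmeth,
        detection_p=ds.detection_p,
        beta_offset=ds.beta_offset,
        truth=truth,
    )


@dataclass
class PlateDesign:
    """Study conditions for a synthetic Biolog PM-M experiment.

    Defaults mirror the published comparison: 11 case lines vs 50
    control lines, 96-point kinetic series at 15-minute intervals.
    ``affected_wells`` is a set of (plate, well) ids whose case-line NADH
    production is reduced by ``effect_size`` OD units.
    """

    n_case_lines: int = 11
    n_control_lines: int = 50
    affected_wells: frozenset = frozenset()
    effect_size: float = 0.4
    n_timepoints: int = 96
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_timepoints < 2:
            raise ValueError("need at least 2 kinetic timepoints")


BLANK_LEVEL = 0.15  # media+dye endpoint background (A590)
A750_LEVEL = 0.05  # turbidity background channel
BASELINE_OD = 0.05


def simulate_plate_run(
    layout: PlateLayout, design: PlateDesign
) -> tuple[list[PlateRun], dict[str, list[PlateRun]]]:
    """Simulate case/control plate runs plus triplicate blank plates.

    Per well the kinetic series is a scaled logistic in time with
    additive Gaussian noise; the endpoint A590 adds the blank background.
    Affected wells in case lines have their amplitude reduced by
    ``effect_size`` (floored just above zero). Returns (runs, blanks).
    """
    bad = set(design.affected_wells) - set(layout.analyzed_wells)
    if bad:
        raise ValueError(f"affected wells outside the layout: {sorted(bad)[:5]}")
    if design.n_timepoints != layout.n_timepoints:
        warnings.warn(
            f"design n_timepoints {design.n_timepoints} != layout {layout.n_timepoints}"
        )
    rng = np.random.default_rng(design.seed)
    t = np.arange(design.n_timepoints) * layout.dt_minutes / 60.0
    logistic = 1.0 / (1.0 + np.exp(-(t - 8.0) / 3.0))

    # well-specific amplitude, fixed across lines (compound identity)
    wells_by_plate = {p: layout.wells(p) for p in layout.plates}
    amp: dict[tuple[str, str], float] = {}
    for plate in layout.plates:
        for well in wells_by_plate[plate]:
            amp[(plate, well)] = rng.uniform(0.5, 1.0)

    def _run(line_id: str, group: str, plate: str) -> PlateRun:
        wells = wells_by_plate[plate]
        a = np.array([amp[(plate, w)] for w in wells])
        a = a * rng.lognormal(0.0, 0.08, size=a.size)
        if group == "case":
            hit = np.array([(plate, w) in design.affected_wells for w in wells])
            a = np.where(hit, np.maximum(a - design.effect_size, 0.02), a)
        series = (
            BASELINE_OD
            + a[:, None] * logistic[None, :]
            + rng.normal(0.0, 0.01, size=(a.size, design.n_timepoints))
        )
        a590 = BLANK_LEVEL + series[:, -1] + rng.normal(0.0, 0.01, size=a.size)
        a750 = A750_LEVEL + rng.normal(0.0, 0.005, size=a.size)
        endpoints = pd.DataFrame({"a590": a590, "a750": a750}, index=wells)
        kin = pd.DataFrame(series, index=wells, columns=[f"t{j}" for j in range(design.n_timepoints)])
        return PlateRun(line_id, plate, group, endpoints, kin)

    runs: list[PlateRun] = []
    for i in range(design.n_case_lines):
        for plate in layout.plates:
            runs.append(_run(f"case_line_{i:02d}", "case", plate))
    for i in range(design.n_control_lines):
        for plate in layout.plates:
            runs.append(_run(f"ctrl_line_{i:02d}", "control", plate))

    blanks: dict[str, list[PlateRun]] = {}
    for plate in layout.plates:
        wells = wells_by_plate[plate]
        blanks[plate] = []
        for j in range(3):
            a590 = BLANK_LEVEL + BASELINE_OD + rng.normal(0.0, 0.005, size=len(wells))
            a750 = A750_LEVEL + rng.normal(0.0, 0.003, size=len(wells))
            endpoints = pd.DataFrame({"a590": a590, "a750": a750}, index=wells)
            blanks[plate].append(PlateRun(f"blank_{j}", plate, "blank", endpoints))
    return runs, blanks


def plate_runs_to_csv(runs: list[PlateRun], path) -> None:
    """Long-form endpoint CSV: line_id, group, plate, well, a590, a750."""
    rows = []
    for run in runs:
        for well, rec in run.endpoints.iterrows():
            rows.append((run.line_id, run.group, run.plate, well, rec["a590"], rec["a750"]))
    pd.DataFrame(
        rows, columns=["line_id", "group", "plate", "well", "a590", "a750"]
    ).to_csv(path, index=False)
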