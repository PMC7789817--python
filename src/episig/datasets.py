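"""In-memory containers and plain-text IO for methylation-array data.

The package works on three aligned tables:

* a probe manifest (one row per array probe: id, chromosome, position and
  the quality flags used for probe filtering),
* probes x samples matrices (methylated / unmethylated intensities, beta
  values and optional detection p-values), and
* a sample sheet (one row per sample: age, sex, batch, cohort label).

Everything is held as pandas objects so downstream models can use label
alignment rather than positional bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

MANIFEST_COLUMNS = [
    "probe_id",
    "chrom",
    "pos",
    "flag_snp",
    "flag_cross_reactive",
    "is_sex_chrom",
]

SAMPLE_SHEET_COLUMNS = ["sample_id", "age", "sex", "batch", "cohort"]

#: offset added to the total intensity in the beta denominator
#: (Illumina convention; 0 gives the literal ratio of signals)
DEFAULT_BETA_OFFSET = 100.0


def validate_manifest(manifest: pd.DataFrame) -> pd.DataFrame:
    """Check manifest invariants and return it sorted by (chrom, pos).

    Raises ``ValueError`` on duplicate probe ids or non-positive positions.
    """
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise ValueError(f"manifest is missing columns: {missing}")
    if manifest["probe_id"].duplicated().any():
        dupes = manifest.loc[manifest["probe_id"].duplicated(), "probe_id"]
        raise ValueError(f"duplicate probe ids: {list(dupes[:5])}")
    if (manifest["pos"] < 1).any():
        raise ValueError("probe positions must be >= 1 (1-based coordinates)")
    out = manifest.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    return out


def validate_sample_sheet(samples: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in samples.columns]
    if missing:
        raise ValueError(f"sample sheet is missing columns: {missing}")
    if samples["sample_id"].duplicated().any():
        raise ValueError("sample ids must be unique")
    if (samples["age"] < 0).any():
        raise ValueError("ages must be non-negative")
    return samples.reset_index(drop=True)


@dataclass
class MethylationDataset:
    """A methylation cohort: manifest, matrices and sample sheet.

    Matrices are probes x samples DataFrames indexed by probe_id with
    sample ids as columns. ``meth``/``unmeth``/``detection_p`` are optional;
    ``beta`` is always present. ``truth`` carries generator ground truth
    (planted signal probes, cell proportions, deletions) when the dataset
    is synthetic.
    """

    manifest: pd.DataFrame
    beta: pd.DataFrame
    samples: pd.DataFrame
    meth: pd.DataFrame | None = None
    unmeth: pd.DataFrame | None = None
    detection_p: pd.DataFrame | None = None
    beta_offset: float = DEFAULT_BETA_OFFSET
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.manifest = validate_manifest(self.manifest)
        self.samples = validate_sample_sheet(self.samples)
        order = self.manifest["probe_id"].to_numpy()
        sample_ids = self.samples["sample_id"].to_numpy()
        for name in ("beta", "meth", "unmeth", "detection_p"):
            mat = getattr(self, name)
            if mat is None:
                continue
            if set(mat.index) != set(order) or set(mat.columns) != set(sample_ids):
                raise ValueError(f"{name} matrix is not aligned with manifest/sample sheet")
            setattr(self, name, mat.loc[order, sample_ids])

    @property
    def n_probes(self) -> int:
        return len(self.manifest)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_ids(self, cohort: str | None = None) -> list[str]:
        if cohort is None:
            return list(self.samples["sample_id"])
        sel = self.samples["cohort"] == cohort
        return list(self.samples.loc[sel, "sample_id"])

    def subset_probes(self, probe_ids: Iterable[str]) -> "MethylationDataset":
        keep = pd.Index(probe_ids)
        manifest = self.manifest[self.manifest["probe_id"].isin(keep)]
        return MethylationDataset(
            manifest=manifest,
            beta=self.beta.loc[manifest["probe_id"]],
            samples=self.samples,
            meth=None if self.meth is None else self.meth.loc[manifest["probe_id"]],
            unmeth=None if self.unmeth is None else self.unmeth.loc[manifest["probe_id"]],
            detection_p=None
            if self.detection_p is None
            else self.detection_p.loc[manifest["probe_id"]],
            beta_offset=self.beta_offset,
            truth=self.truth,
        )

    def subset_samples(self, sample_ids: Iterable[str]) -> "MethylationDataset":
        ids = list(sample_ids)
        samples = self.samples[self.samples["sample_id"].isin(ids)]
        if len(samples) != len(ids):
            unknown = set(ids) - set(samples["sample_id"])
            raise KeyError(f"unknown sample ids: {sorted(unknown)}")
        return MethylationDataset(
            manifest=self.manifest,
            beta=self.beta[ids],
            samples=samples,
            meth=None if self.meth is None else self.meth[ids],
            unmeth=None if self.unmeth is None else self.unmeth[ids],
            detection_p=None if self.detection_p is None else self.detection_p[ids],
            beta_offset=self.beta_offset,
            truth=self.truth,
        )

    def total_intensity(self) -> pd.DataFrame:
        if self.meth is None or self.unmeth is None:
            raise ValueError("dataset has no intensity matrices")
        return self.meth + self.unmeth

    # ----- plain-text IO -------------------------------------------------

    def to_dir(self, outdir: str | Path) -> None:
        """Write the dataset as TSV/CSV files under ``outdir``."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.manifest.to_csv(outdir / "manifest.tsv", sep="\t", index=False)
        self.samples.to_csv(outdir / "samples.csv", index=False)
        self.beta.to_csv(outdir / "beta.tsv", sep="\t")
        if self.meth is not None:
            self.meth.to_csv(outdir / "meth.tsv", sep="\t")
        if self.unmeth is not None:
            self.unmeth.to_csv(outdir / "unmeth.tsv", sep="\t")
        if self.detection_p is not None:
            self.detection_p.to_csv(outdir / "detection_p.tsv", sep="\t")

    @classmethod
    def from_dir(cls, indir: str | Path) -> "MethylationDataset":
        indir = Path(indir)
        read = lambda p: pd.read_csv(p, sep="\t", index_col=0) if p.exists() else None
        return cls(
            manifest=pd.read_csv(indir / "manifest.tsv", sep="\t"),
            beta=pd.read_csv(indir / "beta.tsv", sep="\t", index_col=0),
            samples=pd.read_csv(indir / "samples.csv"),
            meth=read(indir / "meth.tsv"),
            unmeth=read(indir / "unmeth.tsv"),
            detection_p=read(indir / "detection_p.tsv"),
        )


def intervals_to_bed(intervals: pd.DataFrame, path: str | Path) -> None:
    """Write 1-based inclusive intervals as a BED file (0-based half-open)."""
    bed = intervals.copy()
    bed["start"] = bed["start"].astype(int) - 1
    bed["end"] = bed["end"].astype(int)
    cols = ["chrom", "start", "end"] + [c for c in bed.columns if c not in ("chrom", "start", "end")]
    bed[cols].to_csv(path, sep="\t", header=False, index=False)


def bed_to_intervals(path: str | Path, names: list[str] | None = None) -> pd.DataFrame:
    """Read a BED file back into 1-based inclusive intervals."""
    df = pd.read_csv(path, sep="\t", header=None)
    base = ["chrom", "start", "end"]
    extra = names if names is not None else [f"col{i}" for i in range(3, df.shape[1])]
    df.columns = base + list(extra[: df.shape[1] - 3])
    df["start"] = df["start"].astype(int) + 1
    df["end"] = df["end"].astype(int)
    return df


def load_phmds_deletions() -> pd.DataFrame:
    """Published EPIC-derived 22q13 deletion coordinates (hg19) for the
    Phelan-McDermid cohort: 11 signature-positive large deletions and 5
    signature-negative small deletions, 1-based inclusive."""
    path = Path(__file__).parent / "data" / "phmds_22q13_deletions_epic.csv"
    df = pd.read_csv(path)
    df["signature"] = df["signature"].astype(bool)
    return df
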