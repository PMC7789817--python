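"""Differentially methylated region (DMR) calling.

Per-probe moderated t statistics are Gaussian-kernel smoothed along each
chromosome (bandwidth lambda, scaling C, sigma = lambda / C), giving a
smoothed z per probe and a two-sided normal p. Probes significant after
BH correction of the smoothed p-values are chained into candidate
regions when consecutive candidates lie at most ``max_gap`` bp apart;
regions are retained when they contain at least ``min_probes`` probes,
show an average regional beta difference above ``min_mean_delta``, and
pass a Stouffer-combined, BH-recorrected regional FDR threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import intervals_to_bed
from .differential import adjust_bh


@dataclass
class Dmr:
    chrom: str
    start: int  # 1-based position of the first member probe
    end: int  # 1-based position of the last member probe
    n_probes: int
    mean_delta_beta: float
    stouffer_fdr: float
    direction: str  # "hyper" | "hypo"
    probe_ids: tuple = ()

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("DMR end before start")
        if self.n_probes < 3:
            raise ValueError("a DMR has at least three member probes")
        want = "hyper" if self.mean_delta_beta > 0 else "hypo"
        if self.direction != want:
            raise ValueError("direction inconsistent with mean delta beta sign")


def smooth_stats(
    t, positions, lam: float = 1000.0, C: float = 2.0
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian-kernel smoothing of per-probe statistics along a chromosome.

    Weights w_ij = exp(-(pos_i - pos_j)^2 / (2 sigma^2)) with sigma = lam/C;
    the smoothed statistic z_i = sum_j w_ij t_j / sqrt(sum_j w_ij^2) is
    standard normal under the null, giving two-sided p-values. An isolated
    probe (all neighbours far beyond the kernel support) keeps z_i = t_i.
    """
    t = np.asarray(t, dtype=float)
    pos = np.asarray(positions, dtype=float)
    if np.any(np.diff(pos) < 0):
        raise ValueError("positions must be sorted within the chromosome")
    sigma = lam / C
    n = t.size
    z = np.empty(n)
    # exact dense computation, row-chunked to bound memory
    chunk = max(1, int(2_000_000 // max(n, 1)))
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        d = pos[lo:hi, None] - pos[None, :]
        w = np.exp(-(d**2) / (2.0 * sigma**2))
        z[lo:hi] = (w @ t) / np.sqrt((w**2).sum(axis=1))
    p = 2.0 * stats.norm.sf(np.abs(z))
    return z, p


def smooth_by_chromosome(
    t, chrom, positions, lam: float = 1000.0, C: float = 2.0
) -> tuple[np.ndarray, np.ndarray]:
    """Apply :func:`smooth_stats` independently per chromosome."""
    t = np.asarray(t, dtype=float)
    chrom = np.asarray(chrom)
    pos = np.asarray(positions, dtype=float)
    z = np.empty_like(t)
    p = np.empty_like(t)
    for c in pd.unique(chrom):
        sel = chrom == c
        z[sel], p[sel] = smooth_stats(t[sel], pos[sel], lam=lam, C=C)
    return z, p


def _stouffer_region_p(q_members: np.ndarray, t_sign: np.ndarray) -> float:
    """Signed Stouffer combination of member-probe BH q-values."""
    q = np.clip(q_members, 1e-15, 1.0)
    z = stats.norm.isf(q / 2.0) * np.sign(t_sign)
    z_region = z.sum() / np.sqrt(len(z))
    return float(2.0 * stats.norm.sf(abs(z_region)))


def call_dmrs(
    smoothed_p,
    t,
    delta_beta,
    chrom,
    positions,
    probe_ids=None,
    max_gap: float = 1000.0,
    min_probes: int = 3,
    min_mean_delta: float = 0.10,
    max_fdr: float = 0.01,
    candidate_alpha: float = 0.05,
) -> list[Dmr]:
    """Chain BH-significant smoothed probes into DMRs and score them.

    All inputs are aligned per probe and must be sorted by (chrom, pos).
    Regional FDR: per-region two-sided normal p of the signed Stouffer
    combination over member probes' BH q-values, BH-adjusted again across
    the candidate regions that pass the probe-count and effect filters.
    """
    smoothed_p = np.asarray(smoothed_p, dtype=float)
    t = np.asarray(t, dtype=float)
    delta_beta = np.asarray(delta_beta, dtype=float)
    chrom = np.asarray(chrom)
    pos = np.asarray(positions, dtype=float)
    if probe_ids is None:
        probe_ids = np.array([f"probe_{i}" for i in range(len(pos))])
    else:
        probe_ids = np.asarray(probe_ids)

    q_probe = adjust_bh(smoothed_p)
    cand = np.where(q_probe < candidate_alpha)[0]
    if cand.size == 0:
        return []

    # chain candidates: same chromosome, consecutive candidates <= max_gap apart
    chains: list[list[int]] = [[int(cand[0])]]
    for i in cand[1:]:
        prev = chains[-1][-1]
        if chrom[i] == chrom[prev] and pos[i] - pos[prev] <= max_gap:
            chains[-1].append(int(i))
        else:
            chains.append([int(i)])

    regions = []
    for members in chains:
        idx = np.array(members)
        if idx.size < min_probes:
            continue
        mean_delta = float(delta_beta[idx].mean())
        if abs(mean_delta) <= min_mean_delta:
            continue
        p_region = _stouffer_region_p(q_probe[idx], t[idx])
        regions.append((idx, mean_delta, p_region))
    if not regions:
        return []

    fdr = adjust_bh([r[2] for r in regions])
    out: list[Dmr] = []
    for (idx, mean_delta, _), q_region in zip(regions, fdr):
        if q_region >= max_fdr:
            continue
        out.append(
            Dmr(
                chrom=str(chrom[idx[0]]),
                start=int(pos[idx[0]]),
                end=int(pos[idx[-1]]),
                n_probes=int(idx.size),
                mean_delta_beta=mean_delta,
                stouffer_fdr=float(q_region),
                direction="hyper" if mean_delta > 0 else "hypo",
                probe_ids=tuple(probe_ids[idx]),
            )
        )
    return out


def dmrs_from_results(
    results_table: pd.DataFrame,
    lam: float = 1000.0,
    C: float = 2.0,
    **call_kwargs,
) -> list[Dmr]:
    """Run smoothing + region calling on a differential results table
    (requires chrom/pos annotation; rows re-sorted by genome order)."""
    tab = results_table.sort_values(["chrom", "pos"], kind="mergesort")
    z, p = smooth_by_chromosome(
        tab["t_mod"].to_numpy(), tab["chrom"].to_numpy(), tab["pos"].to_numpy(), lam=lam, C=C
    )
    return call_dmrs(
        p,
        tab["t_mod"].to_numpy(),
        tab["delta_beta"].to_numpy(),
        tab["chrom"].to_numpy(),
        tab["pos"].to_numpy(),
        probe_ids=tab["probe_id"].to_numpy(),
        **call_kwargs,
    )


def dmrs_to_bed(dmrs: list[Dmr], path) -> None:
    """BED6+ output: name, score = -log10 regional FDR, strand '.', then
    n_probes, mean_delta_beta, direction."""
    rows = pd.DataFrame(
        {
            "chrom": [d.chrom for d in dmrs],
            "start": [d.start for d in dmrs],
            "end": [d.end for d in dmrs],
            "name": [f"dmr_{i+1}" for i in range(len(dmrs))],
            "score": [-np.log10(max(d.stouffer_fdr, 1e-300)) for d in dmrs],
            "strand": ["." for _ in dmrs],
            "n_probes": [d.n_probes for d in dmrs],
            "mean_delta": [d.mean_delta_beta for d in dmrs],
            "direction": [d.direction for d in dmrs],
        }
    )
    intervals_to_bed(rows, path)
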