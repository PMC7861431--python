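"""Synthetic shallow-WGS bin counts for panels, trisomy controls and tumours.

The generator emulates the statistical structure the downstream callers
assume: a shared locus-specific capture bias (fixed across samples drawn from
the same panel, so within-sample normalization can absorb it), over-dispersed
count noise, and copy-number spikes mixed at a cell-free tumour (or foetal)
DNA fraction ``f``.

The copy-number mixture model: a genomic segment at integer copy number ``c``
present in a fraction ``f`` of the cell-free DNA scales the expected coverage
of fully contained bins by ``(2(1-f) + c*f)/2`` relative to neutral; bins
partially overlapped are scaled by the length-weighted mixture.  The relative
coverage deviation ("effect size") of such a segment is therefore
``f*(c-2)/2``: e.g. c=5 at f=3% gives 4.5%.

Counts are Gamma-Poisson (negative-binomial-like): a bin with expectation
``m`` has variance ``m*(1 + dispersion*m)``, Poisson in the dispersion->0
limit.  The study itself does not model counts; this is the standard
shallow-WGS assumption and the dispersion default is an assumption, not a
calibration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import BinCountMatrix, BinGrid

__all__ = [
    "BiasProfile", "SimTruth", "simulate_panel", "simulate_case",
    "simulate_trisomy", "write_truth_bed", "read_truth_bed",
]


@dataclass(frozen=True)
class BiasProfile:
    """Per-bin multiplicative capture efficiency shared by a panel.

    ``gc`` is a GC-like covariate in (0, 1) that shapes the smooth component
    of the bias; ``efficiency`` is strictly positive with mean 1; ``dispersion``
    is the Gamma-Poisson over-dispersion of the count noise.
    """

    gc: np.ndarray
    efficiency: np.ndarray
    dispersion: float = 1e-4

    def __post_init__(self) -> None:
        if np.any(self.efficiency <= 0):
            raise ValueError("bias efficiencies must be strictly positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")

    @classmethod
    def flat(cls, grid: BinGrid, dispersion: float = 0.0) -> "BiasProfile":
        n = grid.n_bins
        return cls(gc=np.full(n, 0.45), efficiency=np.ones(n),
                   dispersion=dispersion)

    @classmethod
    def random(cls, grid: BinGrid, seed: int, jitter_sd: float = 0.05,
               dispersion: float = 1e-4) -> "BiasProfile":
        """A smooth unimodal function of a GC-like covariate times lognormal
        per-bin jitter; creates the correlated-bin structure that
        reference-bin selection exploits."""
        rng = np.random.default_rng(seed)
        n = grid.n_bins
        raw = rng.normal(0.45, 0.06, size=n)
        # smooth along the genome so neighbouring bins share bias
        kernel = np.ones(9) / 9.0
        gc = np.convolve(raw, kernel, mode="same")
        gc = np.clip(gc, 0.30, 0.70)
        smooth = np.exp(-((gc - 0.45) ** 2) / (2 * 0.08**2))
        jitter = rng.lognormal(mean=0.0, sigma=jitter_sd, size=n)
        eff = smooth * jitter
        eff = eff / eff.mean()
        return cls(gc=gc, efficiency=eff, dispersion=dispersion)


@dataclass(frozen=True)
class SimTruth:
    """Ground truth for one simulated case sample.

    ``segments`` are non-overlapping (chromosome, start, end, copy_number)
    tuples; ``fraction`` is the tumour (or foetal) DNA fraction in [0, 1].
    """

    sample_id: str
    fraction: float
    segments: tuple[tuple[str, int, int, int], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError(f"fraction must be in [0, 1], got {self.fraction}")
        for (_, s, e, c) in self.segments:
            if e <= s:
                raise ValueError("segment end must exceed start")
            if c < 0:
                raise ValueError("copy number must be >= 0")
        segs = sorted(self.segments, key=lambda t: (t[0], t[1]))
        for a, b in zip(segs, segs[1:]):
            if a[0] == b[0] and b[1] < a[2]:
                raise ValueError("segments overlap")


def _bin_scaling(grid: BinGrid, truth: SimTruth) -> np.ndarray:
    """Per-bin expected-coverage scaling under the copy-number mixture.

    A bin fully inside a segment at copy number c scales by (2(1-f)+c*f)/2;
    partially overlapped bins take the length-weighted mixture of copy states.
    """
    f = truth.fraction
    scale = np.ones(grid.n_bins)
    for (chrom, start, end, c) in truth.segments:
        frac = grid.overlap_fraction(chrom, start, end)
        seg_scale = (2.0 * (1.0 - f) + c * f) / 2.0
        scale += frac * (seg_scale - 1.0)
    return scale


def _draw_counts(rng: np.random.Generator, mean: np.ndarray,
                 dispersion: float) -> np.ndarray:
    if dispersion > 0:
        lam = rng.gamma(shape=1.0 / dispersion, scale=dispersion * mean)
    else:
        lam = mean
    return rng.poisson(lam)


def simulate_panel(grid: BinGrid, n_samples: int, mean_reads: int,
                   bias: BiasProfile, seed: int,
                   depth_jitter_sd: float = 0.2) -> BinCountMatrix:
    """Simulate an unaffected reference panel as a BinCountMatrix.

    Per-sample total depth is lognormal around ``mean_reads``; the expected
    count of bin t is proportional to its bias efficiency.  Identical
    (grid, bias, seed) reproduce identical output.
    """
    if grid.n_bins == 0:
        raise ValueError("empty grid")
    if n_samples < 2:
        raise ValueError("panel needs at least 2 samples")
    if mean_reads <= 0:
        raise ValueError("mean_reads must be positive")
    rng = np.random.default_rng(seed)
    p = bias.efficiency / bias.efficiency.sum()
    cols = {}
    for s in range(n_samples):
        depth = mean_reads * rng.lognormal(
            -0.5 * depth_jitter_sd**2, depth_jitter_sd)
        cols[f"N{s+1:03d}"] = _draw_counts(rng, depth * p, bias.dispersion)
    return BinCountMatrix(grid=grid, counts=pd.DataFrame(cols))


def simulate_case(grid: BinGrid, bias: BiasProfile, truth: SimTruth,
                  mean_reads: int) -> tuple[np.ndarray, SimTruth]:
    """Simulate one case (tumour plasma or aneuploid NIPT) sample.

    Returns the bin-count vector and the truth record.  Randomness is driven
    entirely by ``truth.seed``.
    """
    if grid.n_bins == 0:
        raise ValueError("empty grid")
    if mean_reads <= 0:
        raise ValueError("mean_reads must be positive")
    for (chrom, start, end, _) in truth.segments:
        if chrom not in grid.chromosomes:
            raise ValueError(f"segment chromosome {chrom!r} not in grid")
    rng = np.random.default_rng(truth.seed)
    p = bias.efficiency / bias.efficiency.sum()
    mean = mean_reads * p * _bin_scaling(grid, truth)
    return _draw_counts(rng, mean, bias.dispersion), truth


def simulate_trisomy(grid: BinGrid, bias: BiasProfile, ff: float,
                     chromosome: str, mean_reads: int,
                     seed: int) -> tuple[np.ndarray, SimTruth]:
    """A foetal-trisomy positive control: one whole-chromosome segment at
    copy number 3 mixed at foetal fraction ``ff``."""
    if chromosome not in grid.chromosomes:
        raise ValueError(f"chromosome {chromosome!r} not in grid")
    idx = grid.chrom_indices(chromosome)
    segs = () if ff == 0 else (
        (chromosome, int(grid.start[idx[0]]), int(grid.end[idx[-1]]), 3),)
    truth = SimTruth(sample_id=f"T{chromosome}", fraction=ff,
                     segments=segs, seed=seed)
    return simulate_case(grid, bias, truth, mean_reads)


def write_truth_bed(truths: list[SimTruth], path) -> None:
    """Truth as BED6+1: chrom, start, end, name=sample, score=c, strand, f."""
    rows = []
    for t in truths:
        for (chrom, start, end, c) in t.segments:
            rows.append((chrom, start, end, t.sample_id, c, ".", t.fraction))
    pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score",
                                "strand", "fraction"]).to_csv(
        path, sep="\t", index=False, header=False)


def read_truth_bed(path) -> list[SimTruth]:
    df = pd.read_csv(path, sep="\t", header=None, dtype={0: str},
                     names=["chrom", "start", "end", "name", "score",
                            "strand", "fraction"])
    out = []
    for name, sub in df.groupby("name", sort=False):
        segs = tuple(
            (r.chrom, int(r.start), int(r.end), int(r.score))
            for r in sub.itertuples())
        out.append(SimTruth(sample_id=str(name),
                            fraction=float(sub["fraction"].iloc[0]),
                            segments=segs))
    return out
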