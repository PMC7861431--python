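"""Within-sample z-score CNA caller for shallow-WGS cfDNA profiles.

A test sample is normalized against the reference panel: each usable bin's
count is divided by the mean count of its (same-sample) reference bins,
giving v_t; the per-bin z-score is (v_t - mu_t) / sigma_t against the panel
distribution and the effect size is e_t = v_t / mu_t - 1 (the relative
coverage deviation).  Segmentation combines consecutive bins with Stouffer's
method, Z = sum(z_i) / sqrt(n), exhaustively over all contiguous windows of a
chromosome: the maximal-|Z| window passing both the z threshold (default
4.95) and the minimal effect size (default 1.5%) is extracted greedily and
the flanks are re-scanned.

The model-object surface (`WithinSampleModel(...).fit()`) wraps the
functional operations `normalize_sample` / `scan_windows` / `call_sample_wc`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .calls import GAIN, LOSS, CnaCall
from .grid import BinGrid
from .panel import ReferencePanel

DEFAULT_Z_MIN = 4.95
DEFAULT_ES_MIN = 0.015


@dataclass
class NormalizedProfile:
    """Per-bin normalized coverage, z-score and effect size for one sample.

    Arrays are full grid length; values are only defined where ``usable`` is
    True (unusable or blacklisted bins are masked out before segmentation).
    """

    sample_id: str
    grid: BinGrid
    usable: np.ndarray = field(repr=False)
    v: np.ndarray = field(repr=False)
    z: np.ndarray = field(repr=False)
    e: np.ndarray = field(repr=False)

    @property
    def n_usable(self) -> int:
        return int(self.usable.sum())


def normalize_sample(counts: np.ndarray, panel: ReferencePanel,
                     sample_id: str = "sample") -> NormalizedProfile:
    """Within-sample normalization of a test sample against the panel.

    Scale-invariant: multiplying all counts by a constant leaves v, z and e
    unchanged, because v divides the target count by same-sample reference
    counts.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.shape[0] != panel.grid.n_bins:
        raise ValueError(
            f"counts length {counts.shape[0]} does not match grid "
            f"({panel.grid.n_bins} bins)")
    refmean = panel.reference_means(counts)
    usable = panel.usable & np.isfinite(refmean) & (refmean > 0)
    v = np.full(panel.grid.n_bins, np.nan)
    v[usable] = counts[usable] / refmean[usable]
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (v - panel.mu) / panel.sigma
        e = v / panel.mu - 1.0
    usable &= np.isfinite(z)
    return NormalizedProfile(sample_id=sample_id, grid=panel.grid,
                             usable=usable, v=v, z=z, e=e)


def stouffer(z_values) -> float:
    """Stouffer's combined z of an ordered window: sum(z_i) / sqrt(n)."""
    z = np.asarray(list(z_values), dtype=float)
    if z.size == 0:
        raise ValueError("stouffer requires a non-empty list")
    return float(z.sum() / math.sqrt(z.size))


def _best_window(z: np.ndarray, e: np.ndarray, z_min: float, es_min: float,
                 require_sign_concordance: bool = True):
    """Maximal-|Stouffer| contiguous window meeting both thresholds.

    Ties in |Z| are broken toward the longer window, then the leftmost.
    Returns (i, j, Z, mean_e) half-open in array positions, or None.
    """
    n = len(z)
    cz = np.concatenate(([0.0], np.cumsum(z)))
    ce = np.concatenate(([0.0], np.cumsum(e)))
    best = None  # (absZ, length, start, Z, mean_e)
    for i in range(n):
        lens = np.arange(1, n - i + 1)
        Z = (cz[i + 1:] - cz[i]) / np.sqrt(lens)
        me = (ce[i + 1:] - ce[i]) / lens
        ok = (np.abs(Z) >= z_min) & (np.abs(me) >= es_min)
        if require_sign_concordance:
            ok &= np.sign(Z) == np.sign(me)
        if not ok.any():
            continue
        absZ = np.where(ok, np.abs(Z), -np.inf)
        k = int(np.argmax(absZ))
        # prefer longer among exact |Z| ties within this start
        ties = np.flatnonzero(absZ == absZ[k])
        k = int(ties[-1])
        cand = (absZ[k], k + 1, i)
        if best is None or (cand[0], cand[1]) > (best[0], best[1]):
            best = (cand[0], cand[1], cand[2], float(Z[k]), float(me[k]))
    if best is None:
        return None
    _, length, start, Zval, meval = best
    return start, start + length, Zval, meval


def _scan_segment(z, e, bin_idx, grid, z_min, es_min, sample_tag, out,
                  require_sign_concordance):
    if len(z) == 0:
        return
    hit = _best_window(z, e, z_min, es_min, require_sign_concordance)
    if hit is None:
        return
    i, j, Z, me = hit
    first, last = bin_idx[i], bin_idx[j - 1]
    out.append(CnaCall(
        chrom=str(grid.chrom[first]), start=int(grid.start[first]),
        end=int(grid.end[last]), direction=GAIN if Z > 0 else LOSS,
        score=Z, effect_size=me, n_bins=j - i, caller=sample_tag))
    _scan_segment(z[:i], e[:i], bin_idx[:i], grid, z_min, es_min,
                  sample_tag, out, require_sign_concordance)
    _scan_segment(z[j:], e[j:], bin_idx[j:], grid, z_min, es_min,
                  sample_tag, out, require_sign_concordance)


def scan_windows(profile: NormalizedProfile, z_min: float = DEFAULT_Z_MIN,
                 es_min: float = DEFAULT_ES_MIN,
                 require_sign_concordance: bool = True) -> list[CnaCall]:
    """Greedy exhaustive Stouffer sliding-window segmentation.

    Per chromosome all contiguous windows over usable bins are evaluated;
    the maximal-|Z| window with |Z| >= z_min and |mean e| >= es_min (both
    thresholds inclusive) is emitted and the flanks re-scanned.  Emitted
    calls are non-overlapping and sorted by position.
    """
    calls: list[CnaCall] = []
    for chromosome in profile.grid.chromosomes:
        idx = profile.grid.chrom_indices(chromosome)
        idx = idx[profile.usable[idx]]
        if len(idx) == 0:
            continue
        _scan_segment(profile.z[idx], profile.e[idx], idx, profile.grid,
                      z_min, es_min, "wc", calls, require_sign_concordance)
    order = {c: i for i, c in enumerate(profile.grid.chromosomes)}
    calls.sort(key=lambda c: (order[c.chrom], c.start))
    return calls


def call_sample_wc(counts: np.ndarray, panel: ReferencePanel,
                   sample_id: str = "sample", z_min: float = DEFAULT_Z_MIN,
                   es_min: float = DEFAULT_ES_MIN) -> list[CnaCall]:
    """Normalize and segment one sample; calls tagged ``wc``.

    Blacklist/chromosome filtering is applied downstream (interpret module).
    """
    profile = normalize_sample(counts, panel, sample_id)
    return scan_windows(profile, z_min=z_min, es_min=es_min)


class WithinSampleModel:
    """Within-sample z-score caller as a fit-able model.

    Parameters
    ----------
    counts : array of per-bin read counts aligned to the panel's grid
    panel : ReferencePanel
    sample_id : label carried through results
    """

    def __init__(self, counts, panel: ReferencePanel,
                 sample_id: str = "sample"):
        self.counts = np.asarray(counts, dtype=float)
        self.panel = panel
        self.sample_id = sample_id

    def fit(self, z_min: float = DEFAULT_Z_MIN,
            es_min: float = DEFAULT_ES_MIN) -> "WithinSampleResults":
        profile = normalize_sample(self.counts, self.panel, self.sample_id)
        calls = scan_windows(profile, z_min=z_min, es_min=es_min)
        return WithinSampleResults(model=self, profile=profile, calls=calls,
                                   z_min=z_min, es_min=es_min)


@dataclass
class WithinSampleResults:
    model: WithinSampleModel
    profile: NormalizedProfile
    calls: list[CnaCall]
    z_min: float
    es_min: float

    def summary(self) -> str:
        lines = [
            f"Within-sample z-score CNA calls: {self.profile.sample_id}",
            f"  usable bins: {self.profile.n_usable} / {self.profile.grid.n_bins}",
            f"  thresholds : |Z| >= {self.z_min}, |effect| >= {self.es_min:.1%}",
            f"  calls      : {len(self.calls)}",
            "  chrom      start        end         dir   Z        effect  bins",
        ]
        for c in self.calls:
            lines.append(
                f"  {c.chrom:<6} {c.start:<12} {c.end:<11} {c.direction:<5}"
                f" {c.score:<8.2f} {c.effect_size:+.3f}  {c.n_bins}")
        return "\n".join(lines)
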