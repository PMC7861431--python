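"""Reference-panel construction: per-bin reference-bin sets, panel statistics,
sample QC by mean absolute error, and the recurrent-call blacklist.

The normalization is *within-sample*: a target bin's value is its count
divided by the mean count of a set of reference bins in the same sample.
Reference bins are chosen, per target bin, from *other chromosomes* as the
candidates whose count ratio to the target is most stable across the panel
(smallest across-panel variance of the log ratio).  This cancels both
sample-wide depth and the shared locus bias, so the panel distribution of the
normalized value v_t is tight; its mean and SD give the per-bin z-score for
test samples.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .grid import BinCountMatrix, BinGrid
from .intervals import merge_intervals

DEFAULT_N_REF = 100
DEFAULT_MIN_REF = 25
DEFAULT_SIGMA_FLOOR = 1e-4    # sigma_t >= floor * mu_t, numerical safety only
DEFAULT_MAE_THRESHOLD = 0.025  # samples noisier than 2.5% MAE are excluded


class PanelBuildError(ValueError):
    """No usable bins could be constructed from the panel counts."""


@dataclass
class PanelQcRecord:
    sample_id: str
    mae: float
    excluded: bool


@dataclass
class ReferencePanel:
    """Per-bin reference sets and panel statistics for within-sample z-scores.

    ``ref_idx`` is an (n_bins, n_ref) int array, -1 padded; ``mu``/``sigma``
    are the panel mean/SD of the within-sample normalized value v_t; ``v`` is
    the (n_bins, n_samples) matrix of panel v values (kept for leave-one-out
    recurrence screening); ``usable`` masks bins with enough reference bins.
    """

    grid: BinGrid
    ref_idx: np.ndarray = field(repr=False)
    usable: np.ndarray = field(repr=False)
    mu: np.ndarray = field(repr=False)
    sigma: np.ndarray = field(repr=False)
    v: np.ndarray = field(repr=False)
    sample_ids: list[str]
    n_ref: int = DEFAULT_N_REF
    min_ref: int = DEFAULT_MIN_REF
    sigma_floor: float = DEFAULT_SIGMA_FLOOR
    qc_records: list[PanelQcRecord] = field(default_factory=list)
    blacklist: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["chrom", "start", "end"]))

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def reference_means(self, counts: np.ndarray) -> np.ndarray:
        """Within-sample mean count over each bin's reference set."""
        counts = np.asarray(counts, dtype=float)
        padded = np.where(self.ref_idx >= 0,
                          counts[np.clip(self.ref_idx, 0, None)], np.nan)
        with np.errstate(invalid="ignore"):
            return np.nanmean(padded, axis=1)

    # -- persistence (plain-text archive: TSV tables + JSON metadata) --------

    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        stats = self.grid.to_frame()
        stats["usable"] = self.usable.astype(int)
        stats["mu"] = self.mu
        stats["sigma"] = self.sigma
        stats.to_csv(d / "panel_stats.tsv", sep="\t", index=False)
        pd.DataFrame(self.ref_idx).to_csv(d / "ref_bins.tsv", sep="\t",
                                          index=False)
        pd.DataFrame(self.v, columns=self.sample_ids).to_csv(
            d / "panel_v.tsv", sep="\t", index=False)
        qc = pd.DataFrame([(q.sample_id, q.mae, int(q.excluded))
                           for q in self.qc_records],
                          columns=["sample_id", "mae", "excluded"])
        qc.to_csv(d / "panel_qc.tsv", sep="\t", index=False)
        self.blacklist.to_csv(d / "blacklist.bed", sep="\t", index=False,
                              header=False)
        meta = {"bin_width": self.grid.bin_width, "n_ref": self.n_ref,
                "min_ref": self.min_ref, "sigma_floor": self.sigma_floor,
                "sample_ids": self.sample_ids}
        (d / "panel_meta.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, directory) -> "ReferencePanel":
        d = Path(directory)
        meta = json.loads((d / "panel_meta.json").read_text())
        stats = pd.read_csv(d / "panel_stats.tsv", sep="\t", dtype={"chrom": str})
        grid = BinGrid(chrom=stats["chrom"].to_numpy(dtype=object),
                       start=stats["start"].to_numpy(np.int64),
                       end=stats["end"].to_numpy(np.int64),
                       bin_width=int(meta["bin_width"]))
        ref_idx = pd.read_csv(d / "ref_bins.tsv", sep="\t").to_numpy(np.int64)
        v = pd.read_csv(d / "panel_v.tsv", sep="\t").to_numpy(float)
        qc_df = pd.read_csv(d / "panel_qc.tsv", sep="\t")
        qc = [PanelQcRecord(str(r.sample_id), float(r.mae), bool(r.excluded))
              for r in qc_df.itertuples()]
        bl_path = d / "blacklist.bed"
        if bl_path.stat().st_size > 0:
            blacklist = pd.read_csv(bl_path, sep="\t", header=None,
                                    names=["chrom", "start", "end"],
                                    dtype={"chrom": str})
        else:
            blacklist = pd.DataFrame(columns=["chrom", "start", "end"])
        return cls(grid=grid, ref_idx=ref_idx,
                   usable=stats["usable"].to_numpy(bool),
                   mu=stats["mu"].to_numpy(float),
                   sigma=stats["sigma"].to_numpy(float), v=v,
                   sample_ids=list(meta["sample_ids"]),
                   n_ref=int(meta["n_ref"]), min_ref=int(meta["min_ref"]),
                   sigma_floor=float(meta["sigma_floor"]), qc_records=qc,
                   blacklist=blacklist)


def _similarity_scores(L: np.ndarray) -> np.ndarray:
    """Across-panel variance of the pairwise log-count difference.

    score[t, c] = Var_s( L[t, s] - L[c, s] ) = var_t + var_c - 2 cov_tc.
    Symmetric; zero iff candidate counts are exactly proportional to the
    target's across all panel samples.
    """
    S = L.shape[1]
    Lc = L - L.mean(axis=1, keepdims=True)
    var = (Lc**2).sum(axis=1) / (S - 1)
    cov = (Lc @ Lc.T) / (S - 1)
    M = var[:, None] + var[None, :] - 2.0 * cov
    np.clip(M, 0.0, None, out=M)
    return M


def select_reference_bins(panel_counts: BinCountMatrix, target_bin: int,
                          n_ref: int = DEFAULT_N_REF,
                          min_ref: int = DEFAULT_MIN_REF) -> np.ndarray:
    """Reference bins for one target: up to ``n_ref`` other-chromosome bins
    ranked by similarity (smallest across-panel variance of the per-sample
    target/candidate count ratio).  Returns an empty array when fewer than
    ``min_ref`` candidates exist (the bin is then unusable, not an error).
    """
    raw = panel_counts.values().astype(float)
    if np.median(raw[target_bin]) <= 0:
        return np.empty(0, dtype=np.int64)
    L = np.log(raw + 0.5)
    Lc = L - L.mean(axis=1, keepdims=True)
    S = L.shape[1]
    d = Lc[target_bin][None, :] - Lc
    scores = (d - d.mean(axis=1, keepdims=True)) ** 2
    scores = scores.sum(axis=1) / (S - 1)
    chrom = panel_counts.grid.chrom
    ok = (chrom != chrom[target_bin]) & (np.median(raw, axis=1) > 0)
    cand = np.flatnonzero(ok)
    if len(cand) < min_ref:
        return np.empty(0, dtype=np.int64)
    order = cand[np.argsort(scores[cand], kind="stable")]
    return order[:n_ref].astype(np.int64)


def build_panel(panel_counts: BinCountMatrix, n_ref: int = DEFAULT_N_REF,
                min_ref: int = DEFAULT_MIN_REF,
                sigma_floor: float = DEFAULT_SIGMA_FLOOR,
                mae_threshold: float = DEFAULT_MAE_THRESHOLD) -> ReferencePanel:
    """Build the reference panel from panel bin counts.

    For every usable bin t the panel mean mu_t and SD sigma_t of
    v_t = count_t / mean(count over R_t) are computed per sample; sigma is
    floored at ``sigma_floor * mu`` for numerical safety.  QC records
    (mean absolute error per sample) are populated.
    """
    if panel_counts.n_samples < 2:
        raise ValueError("panel needs at least 2 samples")
    grid = panel_counts.grid
    raw = panel_counts.values().astype(float)
    n_bins, S = raw.shape

    L = np.log(raw + 0.5)
    M = _similarity_scores(L)

    chrom_codes = pd.factorize(grid.chrom)[0]
    nonzero_med = np.median(raw, axis=1) > 0
    same_chrom = chrom_codes[:, None] == chrom_codes[None, :]
    M[same_chrom] = np.inf
    M[:, ~nonzero_med] = np.inf

    ref_idx = np.full((n_bins, n_ref), -1, dtype=np.int64)
    usable = np.zeros(n_bins, dtype=bool)
    for t in range(n_bins):
        if not nonzero_med[t]:
            continue
        row = M[t]
        cand = np.flatnonzero(np.isfinite(row))
        if len(cand) < min_ref:
            continue
        order = cand[np.argsort(row[cand], kind="stable")][:n_ref]
        ref_idx[t, : len(order)] = order
        usable[t] = True
    if not usable.any():
        raise PanelBuildError("all bins unusable")

    # within-sample normalized value v_t per panel sample
    v = np.full((n_bins, S), np.nan)
    rows = np.flatnonzero(usable)
    for s in range(S):
        col = raw[:, s]
        padded = np.where(ref_idx[rows] >= 0,
                          col[np.clip(ref_idx[rows], 0, None)], np.nan)
        refmean = np.nanmean(padded, axis=1)
        good = refmean > 0
        v[rows[good], s] = col[rows[good]] / refmean[good]
    usable &= ~np.isnan(v).any(axis=1)
    if not usable.any():
        raise PanelBuildError("all bins unusable after normalization")

    rows = np.flatnonzero(usable)
    mu = np.full(n_bins, np.nan)
    sigma = np.full(n_bins, np.nan)
    mu[rows] = v[rows].mean(axis=1)
    sigma[rows] = np.maximum(v[rows].std(axis=1, ddof=1),
                             sigma_floor * np.abs(mu[rows]))

    panel = ReferencePanel(grid=grid, ref_idx=ref_idx, usable=usable, mu=mu,
                           sigma=sigma, v=v,
                           sample_ids=panel_counts.sample_ids, n_ref=n_ref,
                           min_ref=min_ref, sigma_floor=sigma_floor)
    panel.qc_records = qc_panel_samples(panel, panel_counts, mae_threshold)
    return panel


def qc_panel_samples(panel: ReferencePanel, panel_counts: BinCountMatrix,
                     mae_threshold: float = DEFAULT_MAE_THRESHOLD
                     ) -> list[PanelQcRecord]:
    """Per-sample mean absolute error over usable bins.

    MAE_s = mean_t |v_ts / mu_t^(-s) - 1| where mu^(-s) is the leave-one-out
    panel mean (excluding sample s); on large panels this is indistinguishable
    from the full-panel mean, on small panels it removes the self-bias that
    would blur the strict exclusion boundary.  A sample is excluded iff
    MAE > mae_threshold (strictly above; exactly at threshold is retained).
    """
    S = panel.n_samples
    u = panel.usable
    records = []
    for s, sid in enumerate(panel.sample_ids):
        if S > 2:
            mu_loo = (S * panel.mu[u] - panel.v[u, s]) / (S - 1)
        else:
            mu_loo = panel.mu[u]
        mae = float(np.mean(np.abs(panel.v[u, s] / mu_loo - 1.0)))
        records.append(PanelQcRecord(sample_id=sid, mae=mae,
                                     excluded=mae > mae_threshold))
    return records


def _loo_profile(panel: ReferencePanel, s: int):
    """Leave-one-out z and effect size of panel sample s against the rest."""
    S = panel.n_samples
    u = panel.usable
    v_s = panel.v[:, s]
    mu_loo = np.where(u, (S * panel.mu - v_s) / (S - 1), np.nan)
    # LOO variance from sufficient statistics
    sumsq = np.nansum((panel.v - panel.mu[:, None]) ** 2, axis=1)
    with np.errstate(invalid="ignore"):
        var_loo = (sumsq - (v_s - panel.mu) ** 2 * S / (S - 1)) / (S - 2)
    var_loo = np.clip(var_loo, 0.0, None)
    sigma_loo = np.sqrt(var_loo)
    sigma_loo = np.maximum(sigma_loo, panel.sigma_floor * np.abs(mu_loo))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (v_s - mu_loo) / sigma_loo
        e = v_s / mu_loo - 1.0
    return z, e


def call_panel_sample_loo(panel: ReferencePanel, sample_index: int,
                          z_min: float = 4.95, es_min: float = 0.015):
    """Call one panel sample against the rest of its own panel.

    Leave-one-out panel statistics (mean/SD recomputed without the sample)
    feed the within-sample z-score caller; this is how reference samples are
    screened for recurrent artifacts and how specificity is audited.
    """
    from .wisecondor import NormalizedProfile, scan_windows  # local: avoid cycle

    z, e = _loo_profile(panel, sample_index)
    prof = NormalizedProfile(
        sample_id=panel.sample_ids[sample_index], grid=panel.grid,
        usable=panel.usable & np.isfinite(z),
        v=panel.v[:, sample_index], z=z, e=e)
    return scan_windows(prof, z_min=z_min, es_min=es_min)


def build_blacklist(panel: ReferencePanel, panel_counts: BinCountMatrix,
                    static_regions=None, recurrence_min: int = 2,
                    z_min: float = 4.95, es_min: float = 0.015) -> pd.DataFrame:
    """Union of user-supplied static regions and panel-recurrent calls.

    Each panel sample is called leave-one-out against the rest with the
    within-sample z-score caller; bins hit in >= ``recurrence_min`` samples
    enter the blacklist.  The screening z uses *robust* leave-one-out panel
    statistics (median and MAD-scaled spread): an artifact recurring in a
    minority of panel samples inflates the moment SD of its own bin and
    would mask itself from a plain z-score, but leaves the median spread
    untouched.  Output is a merged, sorted interval table (idempotent under
    re-merging).
    """
    from .wisecondor import NormalizedProfile, scan_windows  # local: avoid cycle

    grid = panel.grid
    hits = np.zeros(grid.n_bins, dtype=int)
    if panel.n_samples >= 3:
        for s in range(panel.n_samples):
            others = np.delete(panel.v, s, axis=1)
            med = np.median(others, axis=1)
            mad = 1.4826 * np.median(np.abs(others - med[:, None]), axis=1)
            scale = np.maximum(mad, panel.sigma_floor * np.abs(med))
            with np.errstate(invalid="ignore", divide="ignore"):
                z = (panel.v[:, s] - med) / scale
                e = panel.v[:, s] / med - 1.0
            prof = NormalizedProfile(
                sample_id=panel.sample_ids[s], grid=grid,
                usable=panel.usable & np.isfinite(z),
                v=panel.v[:, s], z=z, e=e)
            for call in scan_windows(prof, z_min=z_min, es_min=es_min):
                on = ((grid.chrom == call.chrom) & (grid.start < call.end)
                      & (grid.end > call.start))
                hits[on] += 1
    recurrent = np.flatnonzero(hits >= recurrence_min)
    intervals = [(grid.chrom[i], int(grid.start[i]), int(grid.end[i]))
                 for i in recurrent]
    if static_regions is not None:
        static = static_regions if isinstance(static_regions, pd.DataFrame) \
            else pd.DataFrame(static_regions, columns=["chrom", "start", "end"])
        intervals += [(str(r.chrom), int(r.start), int(r.end))
                      for r in static.itertuples()]
    if not intervals:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    return merge_intervals(intervals)
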