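"""Tumour-fraction HMM caller over per-bin log2 ratios (ichor-style).

A simplified copy-state hidden Markov model: per usable bin the observation
is x_t = log2(1 + e_t).  For a tumour fraction f, a segment at integer copy
number c has expected log2 ratio

    expected_log2(c, f) = log2( (2(1-f) + c f) / 2 ),

so the state means are a deterministic function of f.  The model is fitted
by profiling f over a grid (default 0 to 0.5 in steps of 0.005): for each f
the only free emission parameter, a shared Gaussian SD, is estimated by EM
with sticky transitions, and the f maximizing the data log-likelihood wins.
States are decoded by the most probable (Viterbi) path; non-neutral runs
become segments whose mean log2 ratio converts to an effect size
2**log2R - 1.

The fraction is reported as *defined* only when the best f beats the f = 0
likelihood by a margin and the decoded aberrant span is large; profiles with
only one or two short aberrant segments therefore yield defined = False even
when the z-score caller calls them, mirroring the behaviour of
tumour-fraction estimators on sparse CNA profiles.

This is a diploid-baseline re-implementation in the ichorCNA style, not a
replica (no ploidy search, no subclone states, no replication-timing
correction).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calls import GAIN, LOSS, CnaCall
from .grid import BinGrid
from .wisecondor import NormalizedProfile

NEUTRAL_COPY = 2


@dataclass(frozen=True)
class HmmConfig:
    copy_states: tuple[int, ...] = (1, 2, 3, 4, 5)
    self_transition: float = 0.9999
    # None: initialize the emission SD from a robust (MAD) spread of x
    init_sd: float | None = None
    f_grid: tuple[float, ...] = tuple(np.round(np.arange(0.0, 0.5001, 0.005), 4))
    max_iter: int = 10
    tol: float = 1e-3
    sd_floor: float = 1e-3
    # per-bin log-prior penalty kappa*|c-2| toward the neutral state; breaks
    # the exact c*f ridge degeneracy (a gain fits (c=3, f) and (c=5, f/3)
    # with identical means) in favour of the least extreme copy state
    state_prior_strength: float = 0.05
    # f is "defined" only if its log-likelihood beats f=0 by this margin ...
    defined_margin: float = 2.0
    # ... and the decoded path has at least this many aberrant bins
    min_aberrant_bins: int = 40
    min_bins: int = 50

    def __post_init__(self) -> None:
        if NEUTRAL_COPY not in self.copy_states:
            raise ValueError("copy states must include the neutral state 2")
        if not 0.0 < self.self_transition < 1.0:
            raise ValueError("self-transition must be in (0, 1)")

    @classmethod
    def desk(cls, **overrides) -> "HmmConfig":
        """Settings for the reduced desk-scale genome.

        Segment persistence must scale with chromosome length in bins: the
        full-genome default 0.9999 implies expected segments of ~10,000 bins,
        nonsensical on a ~1,000-bin genome whose whole-chromosome events span
        ~50 bins, so the desk default is 0.999.
        """
        overrides.setdefault("self_transition", 0.999)
        return cls(**overrides)


@dataclass(frozen=True)
class TumourFractionEstimate:
    """ctDNA (or foetal) fraction estimate; f is reported 0 when undefined."""

    f: float
    defined: bool

    def __post_init__(self) -> None:
        if not self.defined and self.f != 0.0:
            raise ValueError("undefined estimate must report f = 0")


@dataclass
class HmmSegment:
    chrom: str
    start: int
    end: int
    copy_number: int
    mean_log2: float
    n_bins: int

    @property
    def effect_size(self) -> float:
        return float(2.0 ** self.mean_log2 - 1.0)


def expected_log2(c: int, f: float) -> float:
    """Expected log2 coverage ratio of a segment at copy number c, fraction f.

    Returns -inf for the fully clonal homozygous deletion (c = 0, f = 1),
    the documented sentinel for zero expected coverage.
    """
    if c < 0:
        raise ValueError("copy number must be >= 0")
    if not 0.0 <= f <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    mix = (2.0 * (1.0 - f) + c * f) / 2.0
    if mix == 0.0:
        return float("-inf")
    return float(np.log2(mix))


def _log_transition(n_states: int, self_p: float) -> np.ndarray:
    A = np.full((n_states, n_states), (1.0 - self_p) / (n_states - 1))
    np.fill_diagonal(A, self_p)
    return np.log(A)


def _log_start(states: tuple[int, ...]) -> np.ndarray:
    pi = np.full(len(states), 0.01 / (len(states) - 1))
    pi[states.index(NEUTRAL_COPY)] = 0.99
    return np.log(pi)


def _log_emission(x: np.ndarray, means: np.ndarray, sd: np.ndarray,
                  state_penalty: np.ndarray | None = None) -> np.ndarray:
    """log N(x_t; mu_fc, sd_f) for all f at once -> (F, T, C).

    ``state_penalty`` (per-state, >= 0) is subtracted per bin: a weak prior
    toward the neutral state that resolves the c*f ridge degeneracy.
    """
    diff = x[None, :, None] - means[:, None, :]
    logB = (-0.5 * (diff / sd[:, None, None]) ** 2
            - np.log(sd)[:, None, None] - 0.5 * np.log(2 * np.pi))
    if state_penalty is not None:
        logB = logB - state_penalty[None, None, :]
    return logB


def _lse(arr: np.ndarray, axis: int) -> np.ndarray:
    m = arr.max(axis=axis)
    return m + np.log(np.exp(arr - np.expand_dims(m, axis)).sum(axis=axis))


def _forward_backward(logB: np.ndarray, logA: np.ndarray, logpi: np.ndarray):
    """Batched forward-backward over the leading (f) axis.

    logB : (F, T, C) emission log-probs.  Returns (loglik (F,), gamma (F,T,C)).
    """
    F, T, C = logB.shape
    alpha = np.empty((F, T, C))
    beta = np.empty((F, T, C))
    alpha[:, 0] = logpi[None, :] + logB[:, 0]
    for t in range(1, T):
        m = _lse(alpha[:, t - 1, :, None] + logA[None], axis=1)
        alpha[:, t] = m + logB[:, t]
    beta[:, -1] = 0.0
    for t in range(T - 2, -1, -1):
        beta[:, t] = _lse(
            logA[None] + (logB[:, t + 1] + beta[:, t + 1])[:, None, :], axis=2)
    loglik = _lse(alpha[:, -1], axis=1)
    gamma = alpha + beta - loglik[:, None, None]
    return loglik, np.exp(gamma)


def _viterbi(logB: np.ndarray, logA: np.ndarray, logpi: np.ndarray) -> np.ndarray:
    T, C = logB.shape
    delta = logpi + logB[0]
    back = np.zeros((T, C), dtype=np.int64)
    for t in range(1, T):
        scores = delta[:, None] + logA
        back[t] = np.argmax(scores, axis=0)
        delta = scores[back[t], np.arange(C)] + logB[t]
    path = np.empty(T, dtype=np.int64)
    path[-1] = int(np.argmax(delta))
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1, path[t + 1]]
    return path


class TumourFractionHMM:
    """Copy-state HMM with tumour-fraction-dependent emission means.

    Parameters
    ----------
    profile : NormalizedProfile from the panel normalization
    config : HmmConfig
    """

    def __init__(self, profile: NormalizedProfile,
                 config: HmmConfig | None = None):
        self.profile = profile
        self.config = config or HmmConfig()

    def fit(self) -> "TumourFractionResults":
        cfg = self.config
        prof = self.profile
        idx = np.flatnonzero(prof.usable)
        if len(idx) < cfg.min_bins:
            raise ValueError(
                f"too few usable bins ({len(idx)} < {cfg.min_bins}) for the HMM")
        e = np.clip(prof.e[idx], -0.99, None)
        x = np.log2(1.0 + e)

        states = cfg.copy_states
        fs = np.asarray(cfg.f_grid, dtype=float)
        means = np.array([[expected_log2(c, f) for c in states] for f in fs])
        logA = _log_transition(len(states), cfg.self_transition)
        logpi = _log_start(states)
        penalty = cfg.state_prior_strength * np.abs(
            np.asarray(states, dtype=float) - NEUTRAL_COPY)

        if cfg.init_sd is not None:
            sd0 = cfg.init_sd
        else:  # robust spread, insensitive to aberrant segments
            sd0 = max(1.4826 * float(np.median(np.abs(x - np.median(x)))),
                      cfg.sd_floor)
        sd = np.full(len(fs), sd0)
        loglik = np.full(len(fs), -np.inf)
        loglik_history: list[np.ndarray] = []
        for _ in range(cfg.max_iter):
            logB = _log_emission(x, means, sd, penalty)
            loglik_new, gamma = _forward_backward(logB, logA, logpi)
            loglik_history.append(loglik_new)
            # M-step: shared emission SD per f
            diff2 = (x[None, :, None] - means[:, None, :]) ** 2
            sd = np.sqrt(np.einsum("ftc,ftc->f", gamma, diff2) / len(x))
            sd = np.maximum(sd, cfg.sd_floor)
            if np.all(np.abs(loglik_new - loglik) < cfg.tol):
                loglik = loglik_new
                break
            loglik = loglik_new

        best = int(np.argmax(loglik))
        f0 = int(np.argmin(np.abs(fs)))
        logB_best = _log_emission(x, means[best:best + 1], sd[best:best + 1],
                                  penalty)[0]
        path = _viterbi(logB_best, logA, logpi)
        copies = np.asarray(states)[path]
        segments = _segments_from_path(prof.grid, idx, copies, x)

        n_aberrant = int((copies != NEUTRAL_COPY).sum())
        defined = (fs[best] > 0
                   and loglik[best] - loglik[f0] >= cfg.defined_margin
                   and n_aberrant >= cfg.min_aberrant_bins)
        estimate = TumourFractionEstimate(
            f=float(fs[best]) if defined else 0.0, defined=defined)
        return TumourFractionResults(
            model=self, estimate=estimate, segments=segments,
            f_grid=fs, loglik=loglik, best_index=best, sd=sd,
            n_aberrant_bins=n_aberrant,
            loglik_history=np.array(loglik_history))


def _segments_from_path(grid: BinGrid, idx: np.ndarray, copies: np.ndarray,
                        x: np.ndarray) -> list[HmmSegment]:
    segments: list[HmmSegment] = []
    chroms = grid.chrom[idx]
    start_k = 0
    for k in range(1, len(idx) + 1):
        if (k == len(idx) or chroms[k] != chroms[start_k]
                or copies[k] != copies[start_k]):
            first, last = idx[start_k], idx[k - 1]
            segments.append(HmmSegment(
                chrom=str(grid.chrom[first]), start=int(grid.start[first]),
                end=int(grid.end[last]), copy_number=int(copies[start_k]),
                mean_log2=float(np.mean(x[start_k:k])), n_bins=k - start_k))
            start_k = k
    return segments


@dataclass
class TumourFractionResults:
    model: TumourFractionHMM
    estimate: TumourFractionEstimate
    segments: list[HmmSegment]
    f_grid: np.ndarray = field(repr=False)
    loglik: np.ndarray = field(repr=False)
    best_index: int = 0
    sd: np.ndarray = field(repr=False, default=None)
    n_aberrant_bins: int = 0
    loglik_history: np.ndarray = field(repr=False, default=None)

    def calls(self, es_min: float = 0.015) -> list[CnaCall]:
        return segments_to_calls(self.segments, es_min=es_min)

    def summary(self) -> str:
        est = self.estimate
        lines = [
            f"Tumour-fraction HMM: {self.model.profile.sample_id}",
            f"  ctDNA fraction : "
            + (f"{est.f:.1%}" if est.defined else "undefined (reported 0)"),
            f"  log-likelihood : {self.loglik[self.best_index]:.2f} "
            f"(emission SD {self.sd[self.best_index]:.4f})",
            f"  aberrant bins  : {self.n_aberrant_bins}",
            "  chrom  start        end          c  log2R    effect  bins",
        ]
        for s in self.segments:
            if s.copy_number == NEUTRAL_COPY:
                continue
            lines.append(
                f"  {s.chrom:<6} {s.start:<12} {s.end:<12} {s.copy_number}"
                f"  {s.mean_log2:+.4f}  {s.effect_size:+.3f}  {s.n_bins}")
        return "\n".join(lines)


def fit_hmm(profile: NormalizedProfile, config: HmmConfig | None = None
            ) -> tuple[TumourFractionEstimate, list[HmmSegment]]:
    """Functional wrapper: joint tumour-fraction estimate and segmentation."""
    res = TumourFractionHMM(profile, config).fit()
    return res.estimate, res.segments


def segments_to_calls(segments: list[HmmSegment],
                      es_min: float = 0.015) -> list[CnaCall]:
    """Non-neutral segments with |2**log2R - 1| >= es_min become calls
    tagged ``hmm``; direction from the copy state."""
    calls = []
    for s in segments:
        if s.copy_number == NEUTRAL_COPY:
            continue
        if abs(s.effect_size) < es_min:
            continue
        if np.sign(s.effect_size) != np.sign(s.copy_number - NEUTRAL_COPY):
            continue  # decode/observation sign mismatch: not a credible call
        calls.append(CnaCall(
            chrom=s.chrom, start=s.start, end=s.end,
            direction=GAIN if s.copy_number > NEUTRAL_COPY else LOSS,
            score=s.mean_log2, effect_size=s.effect_size,
            n_bins=s.n_bins, caller="hmm"))
    return calls
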