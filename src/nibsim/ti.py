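"""Temporal-interference exposure metrics and multi-goal stimulation planning.

Two sinusoidal channels at nearby kHz frequencies produce a total field
``E(t, r) = sin(w1 t) E1(r) + sin(w2 t) E2(r)`` whose low-frequency beat
envelope, not the carriers, is the neurally effective quantity.  The
modulation envelope magnitude (MEM) is the largest envelope modulation over
all spatial directions; per direction n the two-tone amplitude swings
between ``||p1| - |p2||`` and ``|p1| + |p2|`` (p_i = E_i . n), so the
modulation is ``2 min(|p1|, |p2|)`` and MEM maximizes that over n.

Candidate electrode/current configurations are scored with three
objectives: M1 'strength' (p-th percentile of the quantity of interest in
the target, maximize), M2 'selectivity' (target mean over off-target mean,
maximize) and M3 'collateral stimulation' (fraction of non-target brain
above a threshold, minimize).  The planner enumerates configurations,
extracts the Pareto-optimal front, ranks by interactive weights with
Pareto members always first, and supports current steering (optimizing the
split of a fixed total current across the two channels).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.optimize import minimize

from .em import EFieldBasis

__all__ = [
    "StimConfig", "ExposureMetrics", "ParetoResult",
    "mem_closed_form", "mem_bruteforce", "exposure_map", "exposure_metrics",
    "enumerate_configs", "pareto_front", "weighted_rank", "steer_currents",
]


@dataclass(frozen=True)
class StimConfig:
    """A two-channel tTIS (or single-channel tACS) electrode/current assignment."""

    pair1: tuple[str, str]
    current1_mA: float
    freq1_Hz: float
    pair2: tuple[str, str] | None = None
    current2_mA: float = 0.0
    freq2_Hz: float = 0.0

    def __post_init__(self):
        if self.current1_mA <= 0:
            raise ValueError("channel currents must be positive")
        if self.pair1[0] == self.pair1[1]:
            raise ValueError("channel 1 electrodes must differ")
        if self.freq1_Hz <= 0:
            raise ValueError("frequencies must be positive")
        if self.pair2 is not None:
            if self.current2_mA <= 0 or self.freq2_Hz <= 0:
                raise ValueError("channel 2 needs positive current and frequency")
            if self.pair2[0] == self.pair2[1]:
                raise ValueError("channel 2 electrodes must differ")
            if set(self.pair1) & set(self.pair2):
                raise ValueError(
                    f"channels share electrodes: {set(self.pair1) & set(self.pair2)}")
            if self.freq1_Hz == self.freq2_Hz:
                raise ValueError("tTIS channels need distinct frequencies")

    @property
    def is_tacs(self) -> bool:
        return self.pair2 is None


@dataclass
class ExposureMetrics:
    """M1-M3 scores of one configuration (see module docstring)."""

    m1: float          # V/m, percentile of the QoI in the target
    m2: float          # dimensionless selectivity (may be +inf)
    m3: float          # fraction of off-target brain above threshold
    p: float = 50.0
    threshold: float = float("nan")
    qoi: str = "MEM"

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.m1, self.m2, self.m3)


@dataclass
class ParetoResult:
    """Configurations with metrics, Pareto flags, and a weighted ranking."""

    configs: list
    metrics: list
    pareto_flags: np.ndarray
    weights: tuple[float, float, float] | None = None
    ranking: np.ndarray | None = None   # indices, best first
    scores: np.ndarray | None = None
    meta: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Modulation envelope magnitude


def mem_closed_form(e1, e2) -> float:
    """Closed-form MEM of two interfering field vectors (V/m).

    Convention: the smaller field is relabeled to e2, and e2 is flipped
    when the angle between the vectors is obtuse (MEM is invariant to the
    sign of either field).  With an acute angle alpha between them:

    - if ``|e2| <= |e1| cos(alpha)``: the optimal direction is along e1 and
      MEM = 2|e2|;
    - otherwise the optimum lies between the vectors and
      MEM = 2 |e2 x (e1 - e2)| / |e1 - e2|.
    """
    a = np.asarray(e1, float)
    b = np.asarray(e2, float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if nb > na:
        a, b, na, nb = b, a, nb, na
    if nb == 0.0:
        return 0.0
    if np.dot(a, b) < 0:
        b = -b
    cos_alpha = np.dot(a, b) / (na * nb)
    if nb <= na * cos_alpha:
        return 2.0 * nb
    d = a - b
    nd = np.linalg.norm(d)
    if nd == 0.0:           # identical vectors
        return 2.0 * nb
    return 2.0 * np.linalg.norm(np.cross(b, d)) / nd


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n)
    ga = np.pi * (3.0 - np.sqrt(5.0))
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(1.0 - z**2)
    th = ga * i
    return np.stack([r * np.cos(th), r * np.sin(th), z], axis=1)


def _envelope_modulation(p1, p2, n_timesteps: int) -> np.ndarray:
    """Beat-phase-sampled envelope modulation of a two-tone signal.

    For projections p1, p2 the carrier amplitude at beat phase tau is
    ``sqrt(p1^2 + p2^2 + 2 |p1 p2| cos tau)``; the modulation is its swing
    (max - min) over a full beat.
    """
    tau = np.linspace(0.0, 2 * np.pi, n_timesteps)
    amp = np.sqrt(np.clip(p1[..., None] ** 2 + p2[..., None] ** 2
                          + 2 * np.abs(p1 * p2)[..., None] * np.cos(tau), 0.0, None))
    return amp.max(axis=-1) - amp.min(axis=-1)


def mem_bruteforce(e1, e2, n_directions: int = 10_000, n_timesteps: int = 65,
                   refine: bool = True) -> float:
    """Direction/time-sampling MEM oracle, independent of the closed form.

    Samples unit directions on a Fibonacci sphere, computes each direction's
    envelope modulation by sampling the two-tone amplitude over a beat
    period, and maximizes; local refinement then polishes the best few
    well-separated candidate directions (the objective has several ridges,
    so a single start can settle on a secondary maximum).
    """
    a = np.asarray(e1, float)
    b = np.asarray(e2, float)
    dirs = _fibonacci_sphere(n_directions)
    mod = _envelope_modulation(dirs @ a, dirs @ b, n_timesteps)
    order = np.argsort(mod)[::-1]
    val = float(mod[order[0]])
    if not refine:
        return val

    def neg(x):
        th, ph = x
        n = np.array([np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), np.cos(th)])
        return -float(_envelope_modulation(np.atleast_1d(n @ a), np.atleast_1d(n @ b),
                                           n_timesteps)[0])

    starts: list[np.ndarray] = []
    for i in order[:200]:
        d = dirs[i]
        if all(min(np.linalg.norm(d - s), np.linalg.norm(d + s)) > 0.3
               for s in starts):
            starts.append(d)
        if len(starts) == 3:
            break
    for d0 in starts:
        th0, ph0 = np.arccos(np.clip(d0[2], -1, 1)), np.arctan2(d0[1], d0[0])
        res = minimize(neg, [th0, ph0], method="Nelder-Mead",
                       options={"xatol": 1e-7, "fatol": 1e-11, "maxiter": 80})
        val = max(val, -float(res.fun))
    return val


# ---------------------------------------------------------------------------
# Exposure maps and metrics


def exposure_map(basis: EFieldBasis, config: StimConfig,
                 quantity: str = "MEM") -> np.ndarray:
    """Per-voxel exposure volume for one configuration.

    ``quantity`` is ``"MEM"`` (tTIS beat envelope; requires two channels)
    or ``"|E|"`` (high-frequency / tACS field magnitude; channel fields
    summed vectorially for single-channel use).
    """
    f1 = basis.pair_field(*config.pair1, current_mA=config.current1_mA)
    if quantity == "|E|":
        tot = f1
        if config.pair2 is not None:
            tot = tot + basis.pair_field(*config.pair2, current_mA=config.current2_mA)
        return np.linalg.norm(tot, axis=0)
    if quantity != "MEM":
        raise ValueError(f"unknown quantity {quantity!r}")
    if config.pair2 is None:
        raise ValueError("MEM needs two channels")
    f2 = basis.pair_field(*config.pair2, current_mA=config.current2_mA)
    return _mem_volume(f1, f2)


def _mem_volume(f1: np.ndarray, f2: np.ndarray) -> np.ndarray:
    """Vectorized closed-form MEM over (3, nx, ny, nz) channel fields."""
    a = np.moveaxis(f1, 0, -1)
    b = np.moveaxis(f2, 0, -1)
    na = np.linalg.norm(a, axis=-1)
    nb = np.linalg.norm(b, axis=-1)
    swap = nb > na
    big = np.where(swap[..., None], b, a)
    small = np.where(swap[..., None], a, b)
    nbig = np.where(swap, nb, na)
    nsmall = np.where(swap, na, nb)
    dot = np.einsum("...i,...i->...", big, small)
    small = np.where((dot < 0)[..., None], -small, small)
    dot = np.abs(dot)
    out = np.zeros_like(na)
    aligned = (nsmall**2 <= dot) | (nsmall == 0)
    out[aligned] = 2.0 * nsmall[aligned]
    rest = ~aligned
    d = big[rest] - small[rest]
    nd = np.linalg.norm(d, axis=-1)
    cr = np.linalg.norm(np.cross(small[rest], d), axis=-1)
    safe = nd > 0
    vals = 2.0 * nsmall[rest]
    vals[safe] = 2.0 * cr[safe] / nd[safe]
    out[rest] = vals
    return out


def exposure_metrics(qoi: np.ndarray, target_mask: np.ndarray, brain_mask: np.ndarray,
                     p: float = 50.0, threshold="auto") -> ExposureMetrics:
    """M1-M3 of one exposure volume.

    ``threshold="auto"`` uses the configuration's own M1 as the collateral
    threshold; a number fixes a global threshold instead.
    """
    if not target_mask.any() or not brain_mask.any():
        raise ValueError("target and brain masks must be non-empty")
    if np.any(target_mask & ~brain_mask):
        raise ValueError("target mask must be contained in the brain mask")
    tgt = qoi[target_mask]
    off = qoi[brain_mask & ~target_mask]
    if off.size == 0:
        raise ValueError("no off-target brain voxels")
    m1 = float(np.percentile(tgt, p))  # linear-interpolation percentile
    off_mean = float(off.mean())
    if off_mean == 0.0:
        import warnings
        warnings.warn("off-target mean is zero; selectivity reported as +inf")
        m2 = float("inf")
    else:
        m2 = float(tgt.mean()) / off_mean
    thr = m1 if threshold == "auto" else float(threshold)
    m3 = float(np.mean(off > thr))
    return ExposureMetrics(m1=m1, m2=m2, m3=m3, p=p, threshold=thr)


# ---------------------------------------------------------------------------
# Configuration search, Pareto front, ranking, steering


def enumerate_configs(montage_labels, total_current_mA: float = 2.0,
                      ratios=(0.5,), frequencies=(2000.0, 2010.0),
                      candidate_pairs=None) -> list[StimConfig]:
    """All disjoint pair-of-pairs configurations x current splits.

    ``ratios`` lists channel-1 shares r of the total current
    (I1 = r I, I2 = (1 - r) I).  ``candidate_pairs`` restricts the electrode
    pairs considered; by default all unordered pairs of montage electrodes.
    """
    pairs = (list(candidate_pairs) if candidate_pairs is not None
             else [tuple(p) for p in combinations(montage_labels, 2)])
    out = []
    for pa, pb in combinations(pairs, 2):
        if set(pa) & set(pb):
            continue
        for r in ratios:
            if not 0.0 < r < 1.0:
                raise ValueError("current ratios must lie strictly in (0, 1)")
            out.append(StimConfig(
                pair1=tuple(pa), current1_mA=r * total_current_mA,
                freq1_Hz=frequencies[0],
                pair2=tuple(pb), current2_mA=(1.0 - r) * total_current_mA,
                freq2_Hz=frequencies[1]))
    return out


def _dominates(x: tuple, y: tuple) -> bool:
    """x dominates y under (max m1, max m2, min m3)."""
    ge = x[0] >= y[0] and x[1] >= y[1] and x[2] <= y[2]
    gt = x[0] > y[0] or x[1] > y[1] or x[2] < y[2]
    return ge and gt


def pareto_front(metrics, configs=None) -> ParetoResult:
    """Non-dominated set under maximize-M1, maximize-M2, minimize-M3.

    Identical metric triples are all kept on the front (tie rule).
    """
    if len(metrics) == 0:
        raise ValueError("need at least one configuration")
    triples = [m.as_tuple() if isinstance(m, ExposureMetrics) else tuple(m)
               for m in metrics]
    n = len(triples)
    flags = np.ones(n, bool)
    for i in range(n):
        for j in range(n):
            if i != j and _dominates(triples[j], triples[i]):
                flags[i] = False
                break
    return ParetoResult(
        configs=list(configs) if configs is not None else [None] * n,
        metrics=list(metrics), pareto_flags=flags)


def weighted_rank(result: ParetoResult, weights=(1.0, 1.0, 1.0)) -> ParetoResult:
    """Rank configurations by weighted min-max-normalized score.

    ``score = w1 norm(m1) + w2 norm(m2) + w3 norm(-m3)``; the sort is
    stable (ties keep input order) and Pareto members always precede
    dominated ones regardless of score.
    """
    w = np.asarray(weights, float)
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    t = np.array([m.as_tuple() if isinstance(m, ExposureMetrics) else tuple(m)
                  for m in result.metrics], float)
    cols = np.column_stack([t[:, 0], t[:, 1], -t[:, 2]])
    cols[np.isinf(cols)] = np.nan
    lo = np.nanmin(cols, axis=0)
    hi = np.nanmax(cols, axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    norm = (cols - lo) / span
    norm = np.where(np.isnan(norm), 1.0, norm)   # +inf selectivity -> best
    scores = norm @ w
    # sort key: Pareto membership first, then score desc, stable in input order
    order = np.lexsort((np.arange(len(scores)),
                        -scores,
                        ~result.pareto_flags))
    return ParetoResult(configs=result.configs, metrics=result.metrics,
                        pareto_flags=result.pareto_flags, weights=tuple(w),
                        ranking=order, scores=scores)


def steer_currents(basis: EFieldBasis, pair1, pair2, target_mask, brain_mask,
                   total_current_mA: float = 2.0,
                   ratios=tuple(np.round(np.arange(0.1, 0.91, 0.1), 10)),
                   weights=(1.0, 1.0, 1.0), frequencies=(2000.0, 2010.0),
                   p: float = 50.0, threshold="auto"):
    """Optimize the current split across two fixed electrode pairs.

    Evaluates every ratio on the grid (the 50/50 split is always included),
    scores with :func:`weighted_rank`, and returns
    ``(best_config, best_metrics, result)``.  By construction the winner
    never scores below the even split.
    """
    rset = sorted(set(float(r) for r in ratios) | {0.5})
    configs, mets = [], []
    for r in rset:
        cfg = StimConfig(pair1=tuple(pair1), current1_mA=r * total_current_mA,
                         freq1_Hz=frequencies[0], pair2=tuple(pair2),
                         current2_mA=(1 - r) * total_current_mA,
                         freq2_Hz=frequencies[1])
        qoi = exposure_map(basis, cfg, "MEM")
        mets.append(exposure_metrics(qoi, target_mask, brain_mask, p=p,
                                     threshold=threshold))
        configs.append(cfg)
    res = weighted_rank(pareto_front(mets, configs), weights)
    res.meta["ratios"] = rset
    best = int(res.ranking[0])
    return configs[best], mets[best], res
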