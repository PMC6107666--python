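"""Causal decomposition: the remove-and-redecompose phase-coherence probe.

The causal relationship between two series follows the covariation
principle — cause is that which put, the effect follows; and removed, the
effect is removed.  Operationally: decompose both series into IMFs, measure
the instantaneous phase coherence of index-matched IMF pairs, then remove
one IMF from a series, redecompose the remainder, and measure how the
coherence profile redistributes.  If the removed scale in the target was
driven by the source, redecomposition fills that scale from the target's
own intrinsic dynamics and the coherence with the source collapses; removal
from the source itself leaves the shared phase dynamics intact.

The change is summarised by the variance-weighted Euclidean distance

    D(1→2) = sqrt( Σ_j W_j [Coh(S1j, S2j) − Coh(S1j, S2j′)]² ),
    W_j    = Var_1j · Var_2j / Σ_j Var_1j · Var_2j,

(the prime marks redecomposed components, the sum runs over all paired
indices) and by the relative causal strength

    C(1→2) = D(1→2) / [D(1→2) + D(2→1)],

so C = 0.5 means no differential causality and C near 1 means series 1
dominates.  When both distances are below 0.05 (no causal change beyond the
ensemble noise floor) each D is replaced by D + 1 before forming the ratio,
which pins C to ~0.5 instead of amplifying a 0/0 ratio.

Causal strengths are validated by leave-one-out resampling: delete a single
time point (the same index from both series), rerun the whole procedure,
and summarise the distribution of C by its median and central interval.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .coherence import CoherenceProfile, coherence_profile
from .emd import (
    DEFAULT_ENSEMBLE_SIZE,
    DEFAULT_SIFT_ITERATIONS,
    IMFSet,
    TimeSeries,
    eemd,
)

logger = logging.getLogger(__name__)

#: Absolute-strength floor below which the D + 1 substitution applies.
SINGULARITY_THRESHOLD = 0.05

#: Default flagging margin on |median C − 0.5|.
DEFAULT_FLAG_MARGIN = 0.1

#: Default cap on leave-one-out runs for records of 100 points or more.
DEFAULT_LOO_RUNS = 100

__all__ = [
    "EEMDParams",
    "CausalResult",
    "CausalProfile",
    "LeaveOneOut",
    "redecompose_without",
    "absolute_strengths",
    "relative_strengths",
    "weighted_coherence_distance",
    "relative_strength_pair",
    "causal_profile",
    "leave_one_out",
    "legacy_component_index",
    "SINGULARITY_THRESHOLD",
]


@dataclass(frozen=True)
class EEMDParams:
    """Ensemble-EMD settings shared by decomposition and redecomposition.

    ``noise_level`` is the added-noise amplitude r as a fraction of the
    signal standard deviation (the analysis' only tuned parameter);
    ``max_imfs`` of None means the dyadic default floor(log2 L) − 1.
    ``reuse_noise_stream`` makes every redecomposition reuse the seed of
    the original decomposition of that series instead of an independently
    seeded stream (strict-reproducibility / exact-symmetry mode).
    """

    noise_level: float = 0.15
    ensemble_size: int = DEFAULT_ENSEMBLE_SIZE
    max_imfs: int | None = None
    sift_iterations: int = DEFAULT_SIFT_ITERATIONS
    reuse_noise_stream: bool = False
    edge_fraction: float = 0.0


@dataclass(frozen=True)
class CausalResult:
    """Absolute (D) and relative (C) causal strengths for one removed IMF.

    Direction a→b is measured by removing IMF ``removed_index`` (1-based)
    from b and redecomposing; b→a analogously from a.
    """

    removed_index: int
    d_ab: float
    d_ba: float
    c_ab: float
    c_ba: float
    weights: np.ndarray
    baseline: CoherenceProfile
    profile_after_removal_from_b: CoherenceProfile
    profile_after_removal_from_a: CoherenceProfile


@dataclass(frozen=True)
class LeaveOneOut:
    """Leave-one-out distribution of c_ab for one removal index."""

    values: np.ndarray
    deletion_indices: np.ndarray

    @property
    def median(self) -> float:
        return float(np.median(self.values))

    @property
    def q025(self) -> float:
        return float(np.quantile(self.values, 0.025))

    @property
    def q975(self) -> float:
        return float(np.quantile(self.values, 0.975))


@dataclass(frozen=True)
class CausalProfile:
    """Per-IMF causal results, leave-one-out distributions, and flags."""

    per_imf: tuple[CausalResult, ...]
    flagged: frozenset[int]
    loo: dict[int, LeaveOneOut] = field(default_factory=dict)
    flag_margin: float = DEFAULT_FLAG_MARGIN

    @property
    def pair_count(self) -> int:
        return len(self.per_imf)

    def strengths_ab(self) -> np.ndarray:
        """c_ab per removable IMF index."""
        return np.array([r.c_ab for r in self.per_imf])

    @property
    def primary(self) -> int | None:
        """The flagged index with the strongest absolute interaction, or None.

        Several scales can pass the flag criterion (a broadband coupling
        touches neighbouring IMFs); the primary causal scale is the flagged
        index with the largest max(D_ab, D_ba).
        """
        if not self.flagged:
            return None
        return max(self.flagged,
                   key=lambda i: max(self.per_imf[i - 1].d_ab,
                                     self.per_imf[i - 1].d_ba))

    @property
    def dominant(self) -> int:
        """The profile's dominant causal scale: argmax over i of |c_ab − 0.5|.

        Unlike :attr:`primary` this is always defined; it is the scale a
        reader would pick from the causal-strength bar profile, whether or
        not it passes the leave-one-out significance criterion.
        """
        return int(np.argmax(np.abs(self.strengths_ab() - 0.5))) + 1

    def to_records(self) -> list[dict]:
        """Serialisable rows: one per removable IMF index."""
        rows = []
        for r in self.per_imf:
            i = r.removed_index
            loo = self.loo.get(i)
            rows.append({
                "imf_index": i,
                "d_ab": r.d_ab,
                "d_ba": r.d_ba,
                "c_ab": r.c_ab,
                "c_ba": r.c_ba,
                "loo_median": loo.median if loo else None,
                "loo_q025": loo.q025 if loo else None,
                "loo_q975": loo.q975 if loo else None,
                "flagged": i in self.flagged,
            })
        return rows


def legacy_component_index(imf_index: int) -> int:
    """Translate a 1-based IMF index to the legacy component numbering.

    The classic Matlab ensemble-EMD lineage returns its decomposition as a
    matrix whose first column is the input signal itself, with the IMFs
    stored from the second column onward; analyses built directly on that
    matrix therefore label the first extracted IMF as component 2.  This
    helper converts this package's standard numbering (first IMF = 1) to
    that published convention for comparison with results in that lineage.
    """
    if imf_index < 1:
        raise ValueError("IMF indices are 1-based")
    return imf_index + 1


def _spawn_seeds(seed: int, n: int) -> np.ndarray:
    """Derive n independent child seeds (< 2**31) from one master seed."""
    return np.random.default_rng(seed).integers(2**31, size=n)


def _decompose(x: TimeSeries, params: EEMDParams, seed: int) -> IMFSet:
    return eemd(
        x,
        noise_level=params.noise_level,
        ensemble_size=params.ensemble_size,
        max_imfs=params.max_imfs,
        seed=seed,
        sift_iterations=params.sift_iterations,
    )


def redecompose_without(
    x: TimeSeries,
    d: IMFSet,
    i: int,
    params: EEMDParams,
    seed: int = 0,
) -> IMFSet:
    """Remove IMF ``i`` (1-based) from ``x`` and redecompose the remainder.

    The remainder is decomposed with the same noise level, ensemble size
    and sifting depth, forcing the same component count as ``d`` so the
    redecomposed profile is index-comparable with the original.
    """
    if not 1 <= i <= d.n_imfs:
        raise ValueError(f"removal index {i} outside 1..{d.n_imfs}")
    remainder = TimeSeries(x.values - d.imfs[i - 1], label=f"{x.label}-imf{i}")
    forced = replace(params, max_imfs=d.n_imfs)
    return _decompose(remainder, forced, seed)


def weighted_coherence_distance(
    weights: np.ndarray, base: np.ndarray, after: np.ndarray
) -> float:
    """Variance-weighted Euclidean distance between two coherence profiles."""
    w = np.asarray(weights, dtype=float)
    diff = np.asarray(base, dtype=float) - np.asarray(after, dtype=float)
    return float(np.sqrt(np.sum(w * diff * diff)))


def relative_strength_pair(d_ab: float, d_ba: float) -> tuple[float, float]:
    """Relative causal strengths from the two absolute distances.

    Applies the singularity rule: when both distances are below 0.05 each
    D is replaced by D + 1 before forming the ratio.
    """
    if d_ab < SINGULARITY_THRESHOLD and d_ba < SINGULARITY_THRESHOLD:
        num_ab, num_ba = d_ab + 1.0, d_ba + 1.0
    else:
        num_ab, num_ba = d_ab, d_ba
    total = num_ab + num_ba
    return num_ab / total, num_ba / total


def _imf_weights(da: IMFSet, db: IMFSet, m: int) -> np.ndarray:
    prod = da.variances()[:m] * db.variances()[:m]
    total = prod.sum()
    if total <= 0.0:
        raise ValueError(
            "degenerate variance weights: every paired IMF has zero variance "
            "(constant or empty decomposition) — causal strengths are undefined"
        )
    return prod / total


def absolute_strengths(
    a: TimeSeries,
    b: TimeSeries,
    da: IMFSet,
    db: IMFSet,
    i: int,
    params: EEMDParams,
    seed_removal_from_b: int = 0,
    seed_removal_from_a: int = 1,
    distance_mode: str = "full_profile",
) -> CausalResult:
    """Absolute causal strengths for removal index ``i`` (c fields unset).

    ``distance_mode`` selects how the profile change is summarised:
    ``"full_profile"`` (default) takes the variance-weighted distance over
    all paired indices; ``"single_pair"`` takes only the coherence change
    at the removed index itself.
    """
    m = min(da.n_imfs, db.n_imfs)
    baseline = coherence_profile(da, db, params.edge_fraction)
    weights = _imf_weights(da, db, m)
    db_prime = redecompose_without(b, db, i, params, seed_removal_from_b)
    da_prime = redecompose_without(a, da, i, params, seed_removal_from_a)
    after_b = coherence_profile(da, db_prime, params.edge_fraction)
    after_a = coherence_profile(da_prime, db, params.edge_fraction)
    if distance_mode == "full_profile":
        d_ab = weighted_coherence_distance(weights, baseline.values, after_b.values)
        d_ba = weighted_coherence_distance(weights, baseline.values, after_a.values)
    elif distance_mode == "single_pair":
        d_ab = abs(baseline.values[i - 1] - after_b.values[i - 1])
        d_ba = abs(baseline.values[i - 1] - after_a.values[i - 1])
    else:
        raise ValueError(f"unknown distance_mode {distance_mode!r}")
    return CausalResult(
        removed_index=i,
        d_ab=d_ab,
        d_ba=d_ba,
        c_ab=float("nan"),
        c_ba=float("nan"),
        weights=weights,
        baseline=baseline,
        profile_after_removal_from_b=after_b,
        profile_after_removal_from_a=after_a,
    )


def relative_strengths(r: CausalResult) -> CausalResult:
    """Populate the relative-strength fields of an absolute-strength result."""
    c_ab, c_ba = relative_strength_pair(r.d_ab, r.d_ba)
    return replace(r, c_ab=c_ab, c_ba=c_ba)


def _profile_strengths(
    a: TimeSeries,
    b: TimeSeries,
    params: EEMDParams,
    seed_a: int,
    seed_b: int,
    removal_seeds: np.ndarray,
    distance_mode: str,
) -> list[CausalResult]:
    """Decompose once and compute causal strengths for every removal index."""
    da = _decompose(a, params, seed_a)
    db = _decompose(b, params, seed_b)
    m = min(da.n_imfs, db.n_imfs)
    results = []
    for i in range(1, m + 1):
        sb = seed_b if params.reuse_noise_stream else int(removal_seeds[2 * (i - 1)])
        sa = seed_a if params.reuse_noise_stream else int(removal_seeds[2 * (i - 1) + 1])
        res = absolute_strengths(a, b, da, db, i, params,
                                 seed_removal_from_b=sb,
                                 seed_removal_from_a=sa,
                                 distance_mode=distance_mode)
        results.append(relative_strengths(res))
    return results


def _delete_point(x: TimeSeries, t: int) -> TimeSeries:
    return TimeSeries(np.delete(x.values, t), label=x.label)


def _deletion_indices(length: int, max_runs: int, rng: np.random.Generator) -> np.ndarray:
    """All deletion points for short records, else a seeded subsample.

    Records shorter than 100 points use every deletion point; longer
    records use ``max_runs`` uniformly random points without replacement.
    A ``max_runs`` below the record length always caps the count.
    """
    if length < 100:
        idx = np.arange(length)
        if max_runs < length:
            idx = np.sort(rng.choice(length, size=max_runs, replace=False))
        return idx
    return np.sort(rng.choice(length, size=min(max_runs, length), replace=False))


def leave_one_out(
    a: TimeSeries,
    b: TimeSeries,
    i: int,
    params: EEMDParams,
    max_runs: int = DEFAULT_LOO_RUNS,
    seed: int = 0,
    distance_mode: str = "full_profile",
) -> LeaveOneOut:
    """Leave-one-out distribution of c_ab for removal index ``i``.

    Each run deletes one time point (the same index from both series,
    preserving alignment), redecomposes, and recomputes the relative
    strength for index ``i``.
    """
    if len(a) != len(b):
        raise ValueError("series must have equal length")
    if len(a) - 1 <= 17:
        raise ValueError("series too short for leave-one-out (≤ 17 points after deletion)")
    rng = np.random.default_rng(seed)
    points = _deletion_indices(len(a), max_runs, rng)
    # one fixed set of EEMD noise streams for every run, so the spread of
    # the distribution reflects deletion sensitivity only
    seeds = rng.integers(2**31, size=4)
    values = np.empty(points.size)
    for k, t in enumerate(points):
        a_t, b_t = _delete_point(a, int(t)), _delete_point(b, int(t))
        da = _decompose(a_t, params, int(seeds[0]))
        db = _decompose(b_t, params, int(seeds[1]))
        res = absolute_strengths(a_t, b_t, da, db, i, params,
                                 seed_removal_from_b=int(seeds[2]),
                                 seed_removal_from_a=int(seeds[3]),
                                 distance_mode=distance_mode)
        values[k] = relative_strengths(res).c_ab
    return LeaveOneOut(values=values, deletion_indices=points)


def causal_profile(
    a: TimeSeries,
    b: TimeSeries,
    params: EEMDParams | None = None,
    flag_margin: float = DEFAULT_FLAG_MARGIN,
    loo_runs: int = DEFAULT_LOO_RUNS,
    seed: int = 0,
    distance_mode: str = "full_profile",
) -> CausalProfile:
    """Causal decomposition of a pair of series over every removable IMF.

    Both series are decomposed once; for each removal index the absolute
    and relative strengths are computed, and (when ``loo_runs`` > 0) a
    leave-one-out distribution of c_ab is accumulated with the deletion
    points shared across removal indices.

    An index is flagged as a significant causal interaction when the
    central 95% of its leave-one-out distribution excludes 0.5 and the
    median departs from 0.5 by at least ``flag_margin``.  With
    ``loo_runs=0`` the flag falls back to the point estimate's margin
    alone.  Flagging is an interpretation of "significant" exposed as
    configuration, not a hypothesis test.
    """
    if params is None:
        params = EEMDParams()
    if len(a) != len(b):
        raise ValueError("series must have equal length")
    master = _spawn_seeds(seed, 3)
    seed_a, seed_b, seed_loo = (int(s) for s in master)
    n_slots = 2 * (params.max_imfs or 64)
    removal_seeds = _spawn_seeds(seed_a ^ seed_b, max(n_slots, 2 * 64))

    per_imf = _profile_strengths(a, b, params, seed_a, seed_b,
                                 removal_seeds, distance_mode)
    m = len(per_imf)

    loo: dict[int, LeaveOneOut] = {}
    if loo_runs > 0:
        rng = np.random.default_rng(seed_loo)
        points = _deletion_indices(len(a), loo_runs, rng)
        # fixed EEMD streams across deletion runs: spread = deletion sensitivity
        run_seeds = rng.integers(2**31, size=2 + 2 * m)
        values = np.empty((m, points.size))
        for k, t in enumerate(points):
            a_t, b_t = _delete_point(a, int(t)), _delete_point(b, int(t))
            run = _profile_strengths(
                a_t, b_t, params, int(run_seeds[0]), int(run_seeds[1]),
                run_seeds[2:], distance_mode,
            )
            for j in range(min(m, len(run))):
                values[j, k] = run[j].c_ab
        for j in range(m):
            loo[j + 1] = LeaveOneOut(values=values[j], deletion_indices=points)

    flagged = set()
    for r in per_imf:
        i = r.removed_index
        if loo:
            dist = loo[i]
            excludes = dist.q025 > 0.5 or dist.q975 < 0.5
            if excludes and abs(dist.median - 0.5) >= flag_margin:
                flagged.add(i)
        elif abs(r.c_ab - 0.5) >= flag_margin:
            flagged.add(i)
    return CausalProfile(
        per_imf=tuple(per_imf),
        flagged=frozenset(flagged),
        loo=loo,
        flag_margin=flag_margin,
    )
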