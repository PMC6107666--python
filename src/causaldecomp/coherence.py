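"""Instantaneous phase coherence between paired IMFs of two series.

The coherence of two narrow-band components is the modulus of the
time-averaged unit phasor of their instantaneous phase difference,

    Coh = | (1/T) Σ_t exp(i Δφ(t)) |,    Δφ(t) = φ_v(t) − φ_u(t),

which is 1 when the phase difference is constant (locked phases, any fixed
offset) and near 0 when it wanders uniformly.  The complex exponential
absorbs phase wrap-around, so no unwrapping is needed, and the measure
depends on phases only — amplitudes never enter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .emd import AnalyticIMF, IMFSet, analytic

__all__ = ["CoherenceProfile", "phase_coherence", "coherence_profile"]


@dataclass(frozen=True)
class CoherenceProfile:
    """Per-IMF-pair phase-coherence values, index-matched, residuals excluded."""

    values: np.ndarray
    pair_count: int

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.size != self.pair_count:
            raise ValueError("pair_count must match the number of values")


def phase_coherence(u: AnalyticIMF, v: AnalyticIMF,
                    edge_fraction: float = 0.0) -> float:
    """Phase coherence of two analytic IMFs of equal length, in [0, 1].

    ``edge_fraction`` optionally excludes that fraction of samples at each
    end of the record (default 0: integrate over the full record).
    """
    if len(u) != len(v):
        raise ValueError(f"length mismatch: {len(u)} vs {len(v)}")
    dphi = v.phase - u.phase
    if edge_fraction:
        if not 0.0 <= edge_fraction < 0.5:
            raise ValueError("edge_fraction must be in [0, 0.5)")
        k = int(round(edge_fraction * dphi.size))
        if k:
            dphi = dphi[k:-k]
    # rounding can push the modulus of a mean of unit vectors a ulp past 1
    return float(min(1.0, np.abs(np.exp(1j * dphi).mean())))


def coherence_profile(da: IMFSet, db: IMFSet,
                      edge_fraction: float = 0.0) -> CoherenceProfile:
    """Coherence between index-matched IMF pairs 1..m, m = min of the counts.

    The ensemble-EMD reference frame keeps comparable scales at equal
    indices, so pairing is by index; residual trends are excluded.
    """
    m = min(da.n_imfs, db.n_imfs)
    if m == 0:
        raise ValueError("both decompositions must contain at least one IMF")
    values = np.empty(m)
    for j in range(m):
        values[j] = phase_coherence(
            analytic(da.imfs[j]), analytic(db.imfs[j]), edge_fraction
        )
    return CoherenceProfile(values=values, pair_count=m)
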