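"""Instantaneous-phase analysis of regional BOLD time series.

The analysis chain implemented here is: (optional) zero-phase band-pass
filtering of each regional signal, extraction of the instantaneous phase
:math:`\\theta_j(t)` as the angle of the analytic (Hilbert) signal, the
Kuramoto order parameter

.. math:: r(t) = \\left| \\frac{1}{n} \\sum_{j=1}^n e^{i\\theta_j(t)} \\right|,

and the two summary statistics used throughout the package:
*synchronization*, the temporal mean of :math:`r(t)`, and *metastability*,
its temporal standard deviation.  Metrics can be computed globally (all
cortical parcels) or restricted to a resting-state network defined by a
parcellation lookup.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.signal import butter, filtfilt, hilbert

logger = logging.getLogger(__name__)

#: Canonical seven resting-state networks (Yeo-style cortical partition).
RSN_NAMES = (
    "visual",
    "somatomotor",
    "dorsal attention",
    "ventral attention",
    "limbic",
    "frontoparietal",
    "default",
)

MIN_TIMEPOINTS = 20


def _as_2d_float(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"{name} must be a 2-D region-by-time matrix, got shape {arr.shape}")
    return arr


@dataclass
class BoldTimeSeries:
    """Region-by-time BOLD matrix for one subject.

    Parameters
    ----------
    values : (n_regions, n_timepoints) array
        Regional signals in arbitrary BOLD units.
    tr : float
        Sampling interval (repetition time) in seconds.
    region_ids : sequence of str
        Unique parcel labels, one per row.
    """

    values: np.ndarray
    tr: float
    region_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.values = _as_2d_float(self.values, "values")
        if not np.isfinite(self.values).all():
            bad = np.argwhere(~np.isfinite(self.values))
            r, t = bad[0]
            raise ValueError(
                f"non-finite value at region index {r}, time index {t} "
                f"({len(bad)} non-finite entries in total)"
            )
        if self.tr <= 0 or not np.isfinite(self.tr):
            raise ValueError(f"tr must be a positive finite number, got {self.tr}")
        if self.values.shape[1] < MIN_TIMEPOINTS:
            raise ValueError(
                f"time series too short: {self.values.shape[1]} samples "
                f"(need at least {MIN_TIMEPOINTS})"
            )
        if not self.region_ids:
            self.region_ids = tuple(f"R{i:03d}" for i in range(self.values.shape[0]))
        else:
            self.region_ids = tuple(str(r) for r in self.region_ids)
        if len(self.region_ids) != self.values.shape[0]:
            raise ValueError(
                f"{len(self.region_ids)} region ids for {self.values.shape[0]} rows"
            )
        if len(set(self.region_ids)) != len(self.region_ids):
            raise ValueError("region_ids must be unique")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]


@dataclass
class PhaseMatrix:
    """Region-by-time instantaneous phases in radians, wrapped to (-pi, pi]."""

    phases: np.ndarray
    tr: float
    region_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.phases = _as_2d_float(self.phases, "phases")
        if not np.isfinite(self.phases).all():
            raise ValueError("phases contain non-finite values")
        if self.phases.shape[1] == 0:
            raise ValueError("phase matrix has zero time points")
        self.phases = wrap_phase(self.phases)
        if self.tr <= 0:
            raise ValueError(f"tr must be positive, got {self.tr}")
        if not self.region_ids:
            self.region_ids = tuple(f"R{i:03d}" for i in range(self.phases.shape[0]))
        else:
            self.region_ids = tuple(str(r) for r in self.region_ids)
        if len(self.region_ids) != self.phases.shape[0]:
            raise ValueError("region_ids length does not match phase rows")

    @property
    def n_regions(self) -> int:
        return self.phases.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.phases.shape[1]


@dataclass
class OrderTrace:
    """Kuramoto order parameter r(t), one value per time point, in [0, 1]."""

    r: np.ndarray
    tr: float

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float).ravel()
        if not np.isfinite(self.r).all():
            raise ValueError("order trace contains non-finite values")
        # tolerate tiny numerical overshoot of the [0, 1] bound
        if self.r.min() < -1e-12 or self.r.max() > 1 + 1e-12:
            raise ValueError("order parameter outside [0, 1]")
        self.r = np.clip(self.r, 0.0, 1.0)

    def __len__(self) -> int:
        return self.r.size


@dataclass(frozen=True)
class SyncMetrics:
    """Temporal mean (synchronization) and SD (metastability) of r(t)."""

    synchronization: float
    metastability: float
    scope_label: str
    n_regions: int = 0


class ParcellationMap:
    """Mapping from parcel id to resting-state-network label.

    The labelled parcels form a partition: each parcel belongs to exactly
    one network.  Unlabelled parcels simply do not appear in the mapping.
    """

    def __init__(self, mapping: Mapping[str, str]):
        self._map = {str(k): str(v) for k, v in mapping.items()}
        if not self._map:
            raise ValueError("parcellation map is empty")

    def network_of(self, parcel_id: str) -> str | None:
        return self._map.get(str(parcel_id))

    @property
    def networks(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for v in self._map.values():
            seen.setdefault(v, None)
        return tuple(seen)

    def parcels_in(self, network: str) -> tuple[str, ...]:
        return tuple(k for k, v in self._map.items() if v == network)

    def __len__(self) -> int:
        return len(self._map)

    def items(self):
        return self._map.items()


def wrap_phase(theta: np.ndarray) -> np.ndarray:
    """Wrap angles to the half-open interval (-pi, pi]."""
    wrapped = np.mod(-np.asarray(theta, dtype=float) + np.pi, 2 * np.pi)
    return -(wrapped - np.pi)


def bandpass(
    ts: BoldTimeSeries,
    low_hz: float = 0.01,
    high_hz: float = 0.1,
    order: int = 2,
) -> BoldTimeSeries:
    """Zero-phase Butterworth band-pass of every regional series.

    The filter is applied forward and backward (``filtfilt``) so it has
    exactly zero phase distortion — a hard requirement upstream of any
    instantaneous-phase estimate.  The default 0.01–0.1 Hz band is the
    conventional resting-state BOLD range.
    """
    nyquist = 1.0 / (2.0 * ts.tr)
    if not (0.0 < low_hz < high_hz < nyquist):
        raise ValueError(
            f"band ({low_hz}, {high_hz}) Hz invalid: must satisfy "
            f"0 < low < high < Nyquist = {nyquist:.4g} Hz for tr = {ts.tr} s"
        )
    b, a = butter(order, [low_hz, high_hz], btype="bandpass", fs=1.0 / ts.tr)
    filtered = filtfilt(b, a, ts.values, axis=1)
    return BoldTimeSeries(values=filtered, tr=ts.tr, region_ids=ts.region_ids)


def instantaneous_phase(ts: BoldTimeSeries) -> PhaseMatrix:
    """Instantaneous phase of each regional signal via the analytic signal.

    Each series is demeaned, extended to its analytic form ``s + i*H(s)``
    with the Hilbert transform, and the four-quadrant angle of that complex
    signal is returned.  The four-quadrant angle (rather than the arctangent
    of the imaginary/real ratio) is required to recover phases over the full
    (-pi, pi] circle.
    """
    variances = ts.values.var(axis=1)
    dead = np.flatnonzero(variances == 0)
    if dead.size:
        names = ", ".join(ts.region_ids[i] for i in dead[:10])
        raise ValueError(f"zero-variance series for region(s): {names}")
    demeaned = ts.values - ts.values.mean(axis=1, keepdims=True)
    analytic = hilbert(demeaned, axis=1)
    return PhaseMatrix(phases=np.angle(analytic), tr=ts.tr, region_ids=ts.region_ids)


def order_parameter(
    phases: PhaseMatrix, subset: Sequence[str] | None = None
) -> OrderTrace:
    """Kuramoto order parameter r(t) over a set of regions.

    r(t) is the modulus of the mean unit phasor across the selected regions
    at each time point: 1 means full phase locking, values near zero mean
    incoherence.
    """
    if subset is None:
        idx = np.arange(phases.n_regions)
    else:
        subset = list(subset)
        if not subset:
            raise ValueError("subset of regions is empty")
        lookup = {rid: i for i, rid in enumerate(phases.region_ids)}
        missing = [rid for rid in subset if rid not in lookup]
        if missing:
            raise KeyError(f"unknown region id(s): {', '.join(map(str, missing))}")
        idx = np.array([lookup[rid] for rid in subset])
    phasors = np.exp(1j * phases.phases[idx])
    r = np.abs(phasors.mean(axis=0))
    return OrderTrace(r=r, tr=phases.tr)


def sync_metrics(trace: OrderTrace, scope_label: str = "global", n_regions: int = 0) -> SyncMetrics:
    """Summarize an order trace as (synchronization, metastability).

    Synchronization is the arithmetic mean of r(t); metastability its
    sample standard deviation (denominator L-1).
    """
    if len(trace) < 2:
        raise ValueError(f"need at least 2 time points for metastability, got {len(trace)}")
    return SyncMetrics(
        synchronization=float(trace.r.mean()),
        metastability=float(trace.r.std(ddof=1)),
        scope_label=scope_label,
        n_regions=n_regions,
    )


def network_metrics(
    phases: PhaseMatrix,
    parcellation: ParcellationMap,
    trim: int = 0,
) -> list[SyncMetrics]:
    """Global and per-network synchronization/metastability.

    The global scope covers every parcel that carries a network label in the
    parcellation; parcels present in the data but absent from the lookup are
    excluded from the global scope with a logged warning.  Networks with
    fewer than two mapped parcels are skipped (an order parameter over one
    oscillator is identically 1).  ``trim`` drops that many samples from each
    end of the phase matrix before computing r(t), as a guard against
    analytic-signal edge effects; the default keeps every sample.
    """
    if trim < 0:
        raise ValueError("trim must be non-negative")
    if trim:
        if phases.n_timepoints <= 2 * trim + 1:
            raise ValueError("trim removes all time points")
        phases = PhaseMatrix(
            phases=phases.phases[:, trim:-trim],
            tr=phases.tr,
            region_ids=phases.region_ids,
        )

    mapped = [rid for rid in phases.region_ids if parcellation.network_of(rid) is not None]
    unmapped = [rid for rid in phases.region_ids if parcellation.network_of(rid) is None]
    if unmapped:
        logger.warning(
            "%d parcel(s) absent from parcellation, excluded from global scope: %s",
            len(unmapped),
            ", ".join(unmapped[:5]) + ("..." if len(unmapped) > 5 else ""),
        )
    if not mapped:
        raise ValueError("no overlap between phase regions and parcellation map")

    results = [
        sync_metrics(order_parameter(phases, mapped), "global", n_regions=len(mapped))
    ]
    present = set(phases.region_ids)
    for network in parcellation.networks:
        parcels = [p for p in parcellation.parcels_in(network) if p in present]
        if len(parcels) < 2:
            logger.warning(
                "network %r has %d mapped parcel(s) in the data; skipped",
                network,
                len(parcels),
            )
            continue
        results.append(
            sync_metrics(order_parameter(phases, parcels), network, n_regions=len(parcels))
        )
    return results
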