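"""Time-to-event sub-model: piecewise-exponential baseline hazard.

The baseline hazard is a step function with (by default) five internal
knots, giving six constant pieces, and is stratified by ATA status: the
two strata share the knot locations but have their own piece heights.
Knots are placed at empirical quantiles of the observed (uncensored)
event times pooled across strata.

With no covariates the stratified piecewise-exponential model has a
closed-form maximum-likelihood solution: the hazard in each
(stratum, interval) cell is events divided by exposure, exactly the
Poisson-likelihood formulation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .data import JointDataset, UnfittableEndpointError

STRATA = ("ata_negative", "ata_positive")


@dataclass
class PiecewiseHazard:
    """Step baseline hazard shared-knot, stratified by ATA status.

    ``knots`` are the internal piece boundaries in years (strictly
    increasing); ``log_h0`` has one row per stratum (ATA-negative first)
    and one column per piece (len(knots) + 1).  Intervals are half-open
    ``[t_j, t_{j+1})`` and the final piece extends beyond the last knot
    indefinitely.
    """

    knots: np.ndarray
    log_h0: np.ndarray
    zero_exposure_cells: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.knots = np.atleast_1d(np.asarray(self.knots, dtype=float))
        self.log_h0 = np.asarray(self.log_h0, dtype=float)
        if self.knots.size and not np.all(np.diff(self.knots) > 0):
            raise ValueError("knots must be strictly increasing")
        if np.any(self.knots <= 0):
            raise ValueError("knots must be positive")
        if self.log_h0.ndim != 2 or self.log_h0.shape[1] != self.knots.size + 1:
            raise ValueError("log_h0 must be (n_strata, n_knots + 1)")

    @property
    def n_pieces(self) -> int:
        return self.log_h0.shape[1]

    @property
    def n_strata(self) -> int:
        return self.log_h0.shape[0]

    def heights(self, stratum: int) -> np.ndarray:
        return np.exp(self.log_h0[stratum])

    def piece_index(self, t) -> np.ndarray:
        return np.searchsorted(self.knots, np.asarray(t, dtype=float), side="right")

    def hazard(self, stratum: int, t) -> np.ndarray:
        """Baseline hazard h0_s(t), a step function of time."""
        return self.heights(stratum)[self.piece_index(t)]


def piece_edges(knots: np.ndarray, t_max: float) -> np.ndarray:
    """Piece boundaries [0, knots..., t_max] used for exposure integrals."""
    return np.concatenate([[0.0], np.atleast_1d(knots), [max(t_max, float(np.max(knots, initial=0.0)) + 1.0)]])


def piece_overlaps(knots: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Exposure of each follow-up interval [0, t_i] to each hazard piece.

    Returns an (n, n_pieces) array of overlap lengths; rows sum to t_i.
    """
    t = np.asarray(t, dtype=float)
    edges = piece_edges(knots, float(t.max(initial=0.0)) + 1.0)
    lo = edges[:-1][None, :]
    hi = edges[1:][None, :]
    return np.clip(np.minimum(hi, t[:, None]) - lo, 0.0, None)


def cumulative_baseline_hazard(pw: PiecewiseHazard, stratum: int, t) -> np.ndarray:
    """Integrated baseline hazard Lambda0_s(t): piecewise linear, 0 at 0."""
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    lam = piece_overlaps(pw.knots, t_arr) @ pw.heights(stratum)
    return lam if np.ndim(t) else float(lam[0])


def choose_knots(event_times, n_internal: int = 5) -> np.ndarray:
    """Internal knots at the j/(n+1) quantiles of uncensored event times.

    Quantiles use the linear-interpolation convention.  Duplicate quantiles
    (possible with heavily tied event times) are collapsed with a warning,
    yielding fewer pieces.
    """
    times = np.asarray(list(event_times), dtype=float)
    if times.size == 0:
        raise UnfittableEndpointError("unfittable endpoint: no observed events")
    if n_internal == 0:
        return np.empty(0)
    probs = np.arange(1, n_internal + 1) / (n_internal + 1)
    knots = np.quantile(times, probs, method="linear")
    unique = np.unique(knots)
    if unique.size < knots.size:
        warnings.warn(
            f"collapsed {knots.size - unique.size} duplicate knot(s); "
            f"{unique.size + 1} hazard pieces remain",
            stacklevel=2,
        )
    return unique


def exposure_and_events(
    dataset: JointDataset, knots: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per (stratum, piece) exposure time and event counts."""
    n_pieces = np.atleast_1d(knots).size + 1
    exposure = np.zeros((2, n_pieces))
    events = np.zeros((2, n_pieces))
    t = np.array([s.event_time_years for s in dataset.subjects])
    strat = np.array([s.ata_positive for s in dataset.subjects], dtype=int)
    delta = np.array([s.event_indicator for s in dataset.subjects], dtype=int)
    overlaps = piece_overlaps(np.atleast_1d(knots), t)
    piece_of_t = np.searchsorted(np.atleast_1d(knots), t, side="right")
    for s in (0, 1):
        mask = strat == s
        exposure[s] = overlaps[mask].sum(axis=0)
        np.add.at(events[s], piece_of_t[mask & (delta == 1)], 1.0)
    return exposure, events


def fit_pe(dataset: JointDataset, knots) -> tuple[PiecewiseHazard, float]:
    """Closed-form ML fit of the stratified piecewise-exponential model.

    Piece heights are events/exposure per (stratum, interval) cell; cells
    with zero exposure get height 0 and are recorded in
    ``zero_exposure_cells``.  Returns the hazard and its log-likelihood
    ``sum(d*log h - h*E)`` over cells.
    """
    knots = np.atleast_1d(np.asarray(knots, dtype=float))
    exposure, events = exposure_and_events(dataset, knots)
    with np.errstate(divide="ignore", invalid="ignore"):
        h = np.where(exposure > 0, events / np.maximum(exposure, 1e-300), 0.0)
        log_h = np.where(h > 0, np.log(np.maximum(h, 1e-300)), -np.inf)
    zero_cells = [tuple(map(int, c)) for c in np.argwhere(exposure <= 0)]
    pw = PiecewiseHazard(knots=knots, log_h0=log_h, zero_exposure_cells=zero_cells)
    with np.errstate(invalid="ignore"):
        ll_terms = np.where(events > 0, events * log_h, 0.0) - h * exposure
    return pw, float(ll_terms.sum())


def survival_loglik(pw: PiecewiseHazard, dataset: JointDataset) -> float:
    """Per-subject log-likelihood sum log[h0(T)^delta * exp(-Lambda0(T))]."""
    total = 0.0
    for s in dataset.subjects:
        lam = cumulative_baseline_hazard(pw, s.ata_positive, s.event_time_years)
        total -= lam
        if s.event_indicator:
            total += float(np.log(pw.hazard(s.ata_positive, s.event_time_years)))
    return total


def serialize(pw: PiecewiseHazard, dataset: JointDataset | None = None) -> dict:
    """JSON-ready description: knots, per-stratum heights, optional cell counts."""
    out = {
        "knots_years": pw.knots.tolist(),
        "strata": list(STRATA),
        "log_h0": pw.log_h0.tolist(),
        "heights": np.exp(pw.log_h0).tolist(),
        "zero_exposure_cells": pw.zero_exposure_cells,
    }
    if dataset is not None:
        exposure, events = exposure_and_events(dataset, pw.knots)
        out["exposure_years"] = exposure.tolist()
        out["events"] = events.tolist()
    return out
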