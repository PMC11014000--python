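"""Energy-to-Shannon-entropy fitness statistics and mother-wavelet ranking.

For a packet decomposition at level *n* with pooled terminal coefficients
``C_1 .. C_m``:

* energy               ``E = sum_i C_i**2``
* energy probabilities ``P_i = C_i**2 / E``  (so ``sum_i P_i = 1``)
* Shannon entropy      ``S = -sum_i P_i log P_i``  with ``0 log 0 := 0``
* fitness ratio        ``xi = E / S``

A mother wavelet that concentrates the signal's energy in few coefficients
gets a high ratio (large E relative to a narrow, low-entropy coefficient
distribution); candidates are ranked by the ratio averaged over segments,
per activity and overall, and the overall winner is selected.

Note that E scales with the square of the signal amplitude while S is
scale-invariant, so ``xi`` carries units of signal-units²: recordings in
m/s² produce ratios (9.80665)² times larger than the same recordings in g,
without changing any ranking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .wavelets import PacketCoefficients, WaveletSpec, get_wavelet, wpt_decompose

__all__ = [
    "DegenerateSegmentError",
    "FitnessResult",
    "SelectionReport",
    "level_energy",
    "energy_probabilities",
    "shannon_entropy",
    "energy_entropy_ratio",
    "score_wavelet",
    "select_mother_wavelet",
]

logger = logging.getLogger(__name__)

Pooling = Literal["pooled", "per_node"]
AxisMode = Literal["mean", "magnitude"]


class DegenerateSegmentError(ValueError):
    """A segment whose fitness ratio is undefined (zero energy or entropy)."""


def level_energy(packet: PacketCoefficients) -> float:
    """Sum of squared coefficients pooled over all terminal nodes."""
    return float(sum(np.dot(node, node) for node in packet.nodes))


def energy_probabilities(packet: PacketCoefficients) -> np.ndarray:
    """Per-coefficient energy shares ``P_i = C_i**2 / E``; sums to 1."""
    pooled = packet.pooled()
    energy = float(np.dot(pooled, pooled))
    if energy <= 0.0:
        raise DegenerateSegmentError("degenerate segment: zero energy")
    return pooled ** 2 / energy


def shannon_entropy(packet: PacketCoefficients, *, log_base: float | None = None) -> float:
    """Shannon entropy of the energy distribution, in nats by default.

    Zero-probability coefficients contribute exactly zero (the 0 log 0
    convention); the result lies in [0, log m] for m pooled coefficients.
    ``log_base`` rescales to another base (e.g. 2 for bits) — a pure
    rescaling that provably never changes a ratio ranking.
    """
    p = energy_probabilities(packet)
    nz = p[p > 0.0]
    s = float(-np.sum(nz * np.log(nz)))
    if log_base is not None:
        s /= np.log(log_base)
    return s


def energy_entropy_ratio(packet: PacketCoefficients, *, pooling: Pooling = "pooled",
                         log_base: float | None = None) -> float:
    """Fitness ratio ``xi = E / S`` of one packet.

    ``pooling="pooled"`` (default) computes E and S once over all terminal
    coefficients of the level.  ``pooling="per_node"`` computes a ratio per
    sub-band and averages across the non-degenerate sub-bands.
    """
    if pooling == "per_node":
        ratios = []
        for node in packet.nodes:
            sub = _single_node(packet, node)
            try:
                ratios.append(energy_entropy_ratio(sub, log_base=log_base))
            except DegenerateSegmentError:
                continue
        if not ratios:
            raise DegenerateSegmentError("degenerate segment: no usable sub-band")
        return float(np.mean(ratios))
    energy = level_energy(packet)
    entropy = shannon_entropy(packet, log_base=log_base)
    if entropy <= 0.0:
        raise DegenerateSegmentError(
            "undefined ratio: entropy is zero (single nonzero coefficient)"
        )
    return energy / entropy


def _single_node(packet: PacketCoefficients, node: np.ndarray) -> PacketCoefficients:
    return PacketCoefficients(
        wavelet_name=packet.wavelet_name,
        level=0,
        nodes=(node,),
        original_length=node.size,
        padded_length=node.size,
    )


@dataclass(frozen=True)
class FitnessResult:
    """Aggregated fitness of one wavelet over a set of segments."""

    wavelet_name: str
    activity: str
    axis: str
    mean_energy: float
    mean_entropy: float
    mean_ratio: float
    n_segments: int
    n_degenerate: int = 0


@dataclass(frozen=True)
class SelectionReport:
    """Per-activity and overall wavelet rankings by mean fitness ratio.

    ``overall`` and each entry of ``per_activity`` are DataFrames with
    columns wavelet, mean_energy, mean_entropy, mean_ratio, rank; rank 1 is
    the highest ratio, ties broken lexicographically by wavelet name.
    """

    overall: pd.DataFrame
    per_activity: dict[str, pd.DataFrame]
    selected: str

    def to_csv(self, path) -> None:
        frames = [self.overall.assign(activity="all")]
        frames += [t.assign(activity=a) for a, t in sorted(self.per_activity.items())]
        table = pd.concat(frames, ignore_index=True)
        cols = ["activity", "wavelet", "mean_energy", "mean_entropy", "mean_ratio", "rank"]
        table[cols].to_csv(path, index=False)


def _segment_axis_stats(samples: np.ndarray, wavelet: WaveletSpec, level: int,
                        pooling: Pooling, log_base: float | None,
                        axis_mode: AxisMode) -> tuple[float, float, float] | None:
    """(energy, entropy, ratio) of one segment, averaged across axes.

    Returns None for a fully degenerate segment.
    """
    data = np.atleast_2d(np.asarray(samples, dtype=float))
    if data.shape[0] < data.shape[1] and data.shape[0] in (1, 2, 3):
        data = data.T  # accept (n, axes) or (axes, n)
    if axis_mode == "magnitude":
        data = np.linalg.norm(data, axis=1, keepdims=True)
    stats = []
    for axis in range(data.shape[1]):
        packet = wpt_decompose(data[:, axis], wavelet, level)
        try:
            energy = level_energy(packet)
            entropy = shannon_entropy(packet, log_base=log_base)
            ratio = energy_entropy_ratio(packet, pooling=pooling, log_base=log_base)
        except DegenerateSegmentError:
            continue
        stats.append((energy, entropy, ratio))
    if not stats:
        return None
    return tuple(np.mean(stats, axis=0))  # type: ignore[return-value]


def score_wavelet(segments: Sequence, wavelet: WaveletSpec | str, level: int = 3, *,
                  activity: str = "all", pooling: Pooling = "pooled",
                  log_base: float | None = None,
                  axis_mode: AxisMode = "mean") -> FitnessResult:
    """Mean fitness of one wavelet over segments (ratio per axis, averaged
    across axes, then averaged over segments).

    Segments may be :class:`~wavehar.preprocess.Segment` objects or plain
    arrays.  Segments with zero energy or zero entropy are excluded from
    the averages and counted in ``n_degenerate``.
    """
    if isinstance(wavelet, str):
        wavelet = get_wavelet(wavelet)
    if len(segments) == 0:
        raise ValueError("score_wavelet requires at least one segment")
    per_segment = []
    n_degenerate = 0
    for seg in segments:
        samples = getattr(seg, "samples", seg)
        stats = _segment_axis_stats(samples, wavelet, level, pooling, log_base, axis_mode)
        if stats is None:
            n_degenerate += 1
            continue
        per_segment.append(stats)
    if not per_segment:
        raise DegenerateSegmentError("all segments degenerate")
    if n_degenerate:
        logger.warning("excluded %d degenerate segment(s) for %s", n_degenerate, wavelet.name)
    mean_energy, mean_entropy, mean_ratio = np.mean(per_segment, axis=0)
    return FitnessResult(
        wavelet_name=wavelet.name,
        activity=activity,
        axis=axis_mode,
        mean_energy=float(mean_energy),
        mean_entropy=float(mean_entropy),
        mean_ratio=float(mean_ratio),
        n_segments=len(per_segment),
        n_degenerate=n_degenerate,
    )


def _rank_table(results: Iterable[FitnessResult]) -> pd.DataFrame:
    rows = [
        {
            "wavelet": r.wavelet_name,
            "mean_energy": r.mean_energy,
            "mean_entropy": r.mean_entropy,
            "mean_ratio": r.mean_ratio,
        }
        for r in results
    ]
    table = pd.DataFrame(rows).sort_values(
        ["mean_ratio", "wavelet"], ascending=[False, True], kind="mergesort"
    )
    table["rank"] = np.arange(1, len(table) + 1)
    return table.reset_index(drop=True)


def select_mother_wavelet(segments: Sequence, candidates: Sequence[str], level: int = 3, *,
                          pooling: Pooling = "pooled", log_base: float | None = None,
                          axis_mode: AxisMode = "mean") -> SelectionReport:
    """Rank candidate mother wavelets by mean energy-to-entropy ratio.

    Builds one ranking table per activity label found on the segments plus
    an overall table over all segments; the overall rank-1 wavelet is the
    report's selected wavelet.
    """
    if len(candidates) == 0:
        raise ValueError("candidate list is empty")
    if len(segments) == 0:
        raise ValueError("no segments supplied")
    specs = [get_wavelet(c) if isinstance(c, str) else c for c in candidates]
    by_activity: dict[str, list] = {}
    for seg in segments:
        by_activity.setdefault(getattr(seg, "label", "all"), []).append(seg)
    kwargs = dict(level=level, pooling=pooling, log_base=log_base, axis_mode=axis_mode)
    overall = _rank_table(
        score_wavelet(segments, spec, **kwargs) for spec in specs
    )
    per_activity = {
        activity: _rank_table(
            score_wavelet(segs, spec, activity=activity, **kwargs) for spec in specs
        )
        for activity, segs in sorted(by_activity.items())
    }
    return SelectionReport(
        overall=overall,
        per_activity=per_activity,
        selected=str(overall.loc[0, "wavelet"]),
    )
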