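"""Wavelet filter registry and the wavelet packet transform engine.

A mother wavelet is represented discretely by its two-channel filter bank:
the low-pass/high-pass analysis pair (``dec_lo``, ``dec_hi``) and the
synthesis pair (``rec_lo``, ``rec_hi``).  The packet transform recursively
splits *both* the approximation and the detail branch, so an ``n``-level
decomposition yields ``2**n`` equal-width sub-bands.

Boundary handling is periodization: the signal is zero-padded to the next
multiple of ``2**level`` and every filtering stage is a circular
convolution followed by dyadic downsampling.  For orthonormal filters this
makes the transform exactly energy-preserving (Parseval) and perfectly
invertible, which is what makes the energy/entropy fitness statistics
downstream sharply testable.

Filter coefficients come from the standard published constructions as
shipped by PyWavelets; the cascade itself is implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt

__all__ = [
    "CANDIDATE_WAVELETS",
    "WaveletSpec",
    "PacketCoefficients",
    "UnsupportedWaveletError",
    "get_wavelet",
    "wpt_decompose",
    "wpt_reconstruct",
    "padded_length_for",
    "natural_to_frequency_order",
    "write_packet",
]

#: The eleven candidate mother wavelets ranked by the selection procedure:
#: one Haar, plus low- and high-vanishing-moment members of the Daubechies,
#: Symlet, Coiflet, biorthogonal and reverse-biorthogonal families.
CANDIDATE_WAVELETS: tuple[str, ...] = (
    "haar",
    "db5",
    "db37",
    "sym5",
    "sym18",
    "coif5",
    "coif14",
    "bior1.3",
    "bior5.5",
    "rbio1.3",
    "rbio5.5",
)

_ORTHOGONAL_PREFIXES = ("haar", "db", "sym", "coif")


class UnsupportedWaveletError(ValueError):
    """Raised when a wavelet name cannot be resolved to a filter bank."""


@dataclass(frozen=True)
class WaveletSpec:
    """A named mother wavelet as its analysis/synthesis filter pairs.

    Attributes
    ----------
    name : str
        Conventional lowercase identifier, e.g. ``"coif14"``.
    family : str
        Family short name (``"db"``, ``"coif"``, ``"bior"``, ...).
    vanishing_moments : int
        Number of vanishing moments of the analysis wavelet.
    dec_lo, dec_hi : ndarray
        Low-pass and high-pass analysis filters.
    rec_lo, rec_hi : ndarray
        Low-pass and high-pass synthesis filters.
    is_orthogonal : bool
        True for the orthonormal families (haar/db/sym/coif); False for the
        biorthogonal pairs, whose analysis and synthesis filters differ.
    """

    name: str
    family: str
    vanishing_moments: int
    dec_lo: np.ndarray = field(repr=False)
    dec_hi: np.ndarray = field(repr=False)
    rec_lo: np.ndarray = field(repr=False)
    rec_hi: np.ndarray = field(repr=False)
    is_orthogonal: bool

    @property
    def filter_length(self) -> int:
        return self.dec_lo.size


@dataclass(frozen=True)
class PacketCoefficients:
    """Terminal-node coefficients of an ``n``-level packet decomposition.

    ``nodes`` holds the ``2**level`` sub-band coefficient arrays in natural
    (Paley) order — the order induced by the low/high filter choices along
    the tree, not by centre frequency.
    """

    wavelet_name: str
    level: int
    nodes: tuple[np.ndarray, ...]
    original_length: int
    padded_length: int

    def __post_init__(self) -> None:
        if len(self.nodes) != 2 ** self.level:
            raise ValueError(
                f"expected {2 ** self.level} nodes at level {self.level}, "
                f"got {len(self.nodes)}"
            )
        node_len = self.padded_length // (2 ** self.level)
        for node in self.nodes:
            if node.size != node_len:
                raise ValueError(
                    f"node length {node.size} inconsistent with padded "
                    f"length {self.padded_length} at level {self.level}"
                )

    @property
    def n_coefficients(self) -> int:
        """Total coefficient count pooled over all terminal nodes."""
        return self.padded_length

    def pooled(self) -> np.ndarray:
        """All terminal coefficients concatenated in natural node order."""
        return np.concatenate(self.nodes)


def get_wavelet(name: str) -> WaveletSpec:
    """Resolve a wavelet name to its filter bank.

    The eleven candidate names in :data:`CANDIDATE_WAVELETS` all resolve;
    any other standard discrete-wavelet name (e.g. ``"db9"``) is accepted
    too.  Unknown names raise :class:`UnsupportedWaveletError`.
    """
    try:
        w = pywt.Wavelet(name)
    except ValueError as exc:
        raise UnsupportedWaveletError(
            f"unsupported wavelet {name!r}; the canonical candidates are "
            f"{', '.join(CANDIDATE_WAVELETS)} (any standard discrete "
            "wavelet name is also accepted)"
        ) from exc
    return WaveletSpec(
        name=name,
        family=w.short_family_name,
        vanishing_moments=int(w.vanishing_moments_psi),
        dec_lo=np.asarray(w.dec_lo, dtype=float),
        dec_hi=np.asarray(w.dec_hi, dtype=float),
        rec_lo=np.asarray(w.rec_lo, dtype=float),
        rec_hi=np.asarray(w.rec_hi, dtype=float),
        is_orthogonal=name.startswith(_ORTHOGONAL_PREFIXES),
    )


def padded_length_for(n: int, level: int) -> int:
    """Smallest multiple of ``2**level`` that is >= ``n``."""
    block = 2 ** level
    return int(np.ceil(n / block)) * block


def _split(x: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # One periodized analysis stage: circular convolution + downsample by 2.
    # y[n] = sum_k f[k] * x[(2n + L/2 - k) mod N]; the L/2 phase matches the
    # standard periodization convention so the synthesis stage below inverts
    # it exactly.  Valid for any even N, including filters longer than x.
    n = x.size
    length = lo.size
    idx = (2 * np.arange(n // 2)[:, None] + length // 2 - np.arange(length)[None, :]) % n
    windows = x[idx]
    return windows @ lo, windows @ hi


def _merge(a: np.ndarray, d: np.ndarray, rlo: np.ndarray, rhi: np.ndarray) -> np.ndarray:
    # Inverse stage: upsample both children by 2, circular-convolve with the
    # synthesis pair and sum.  Phase offset L/2 - 1 pairs with _split.
    n = 2 * a.size
    length = rlo.size
    up_a = np.zeros(n)
    up_a[::2] = a
    up_d = np.zeros(n)
    up_d[::2] = d
    idx = (np.arange(n)[:, None] + (length // 2 - 1) - np.arange(length)[None, :]) % n
    return up_a[idx] @ rlo + up_d[idx] @ rhi


def wpt_decompose(signal: np.ndarray, wavelet: WaveletSpec, level: int) -> PacketCoefficients:
    """Full ``level``-stage wavelet packet decomposition of a 1-D signal.

    The signal is zero-padded to the next multiple of ``2**level`` (zero
    padding adds no energy), then both children of every node are split
    recursively.  Terminal nodes are returned in natural (Paley) order.
    """
    x = np.asarray(signal, dtype=float).ravel()
    if level < 1:
        raise ValueError("level must be >= 1")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite samples")
    if x.size < wavelet.filter_length:
        raise ValueError(
            f"signal length {x.size} is shorter than the {wavelet.name} "
            f"filter length {wavelet.filter_length}"
        )
    original_length = x.size
    padded = padded_length_for(original_length, level)
    if padded > original_length:
        x = np.concatenate([x, np.zeros(padded - original_length)])
    nodes = [x]
    for _ in range(level):
        nxt: list[np.ndarray] = []
        for node in nodes:
            a, d = _split(node, wavelet.dec_lo, wavelet.dec_hi)
            nxt.extend((a, d))
        nodes = nxt
    return PacketCoefficients(
        wavelet_name=wavelet.name,
        level=level,
        nodes=tuple(nodes),
        original_length=original_length,
        padded_length=padded,
    )


def wpt_reconstruct(packet: PacketCoefficients, wavelet: WaveletSpec) -> np.ndarray:
    """Invert :func:`wpt_decompose`, returning ``padded_length`` samples.

    Truncating back to ``original_length`` is left to the caller, since the
    padded tail carries the (zero) energy bookkeeping.
    """
    n_nodes = len(packet.nodes)
    if n_nodes & (n_nodes - 1):
        raise ValueError(f"node count {n_nodes} is not a power of two")
    nodes = [np.asarray(v, dtype=float) for v in packet.nodes]
    while len(nodes) > 1:
        nodes = [
            _merge(nodes[i], nodes[i + 1], wavelet.rec_lo, wavelet.rec_hi)
            for i in range(0, len(nodes), 2)
        ]
    return nodes[0]


def natural_to_frequency_order(level: int) -> np.ndarray:
    """Permutation mapping frequency-ordered position -> natural node index.

    Natural (Paley) order follows the low/high filter path; physical centre
    frequency instead increases along the Gray-code reordering of that path.
    ``nodes[perm[j]]`` is the j-th sub-band by increasing frequency.
    """
    idx = np.arange(2 ** level)
    # the node at frequency rank j sits at natural index gray(j)
    return idx ^ (idx >> 1)


def write_packet(packet: PacketCoefficients, path) -> None:
    """Dump a packet to delimited text, one row per terminal node."""
    with open(path, "w") as fh:
        fh.write(
            f"# wavelet={packet.wavelet_name} level={packet.level} "
            f"original_length={packet.original_length} "
            f"padded_length={packet.padded_length}\n"
        )
        for i, node in enumerate(packet.nodes):
            fh.write(f"{i}\t" + "\t".join(f"{c:.17g}" for c in node) + "\n")
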