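"""Wavelet-packet decomposition (WPD) preprocessing for EEG epochs.

A wavelet packet transform recursively splits *both* the low- and
high-pass branches of the filter bank, producing a full binary tree of
sub-bands.  EEG preprocessing here keeps the low-frequency packet nodes
that contain the sensorimotor mu (8-13 Hz) and beta (13-30 Hz) rhythms
and reconstructs the time-domain signal from those nodes only.

Conventions
-----------
* Analysis step: stride-2 *circular* correlation,
  ``low[i] = sum_j h[j] x[(j + 2i) mod N]`` and likewise with ``g``.
  Worked Haar example (h = [1/sqrt2, 1/sqrt2], x = [1, 2, 3, 4]):
  ``low = [(1+2)/sqrt2, (3+4)/sqrt2]``, ``high = [(1-2)/sqrt2, (3-4)/sqrt2]``.
* Periodic (circular) boundary handling, which keeps the transform
  exactly orthogonal: Parseval holds to machine precision and
  reconstruction from all nodes is exact.
* Node indexing ``(level l, index m)`` with children
  ``(l+1, 2m)`` = low-pass and ``(l+1, 2m+1)`` = high-pass ("natural"
  ordering).  Because down-sampling mirrors the spectrum of high-pass
  branches, natural order is not frequency order; the frequency-ordered
  index ``f`` maps to the natural index via the binary-reflected Gray
  code ``m = f ^ (f >> 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt

from .epochs import EEGEpoch

DEFAULT_WAVELET = "db4"
DEFAULT_LEVEL = 4
#: Frequency-ordered level-4 nodes covering 0 .. fs/8 Hz (0-31.25 Hz at
#: fs = 250 Hz), i.e. the band holding the mu and beta rhythms.
DEFAULT_NODES: tuple[tuple[int, int], ...] = ((4, 0), (4, 1), (4, 2), (4, 3))


class InvalidFilterError(ValueError):
    """Raised for empty or non-finite filter coefficient sequences."""


class DecompositionDepthError(ValueError):
    """Raised when a signal is too short for the requested level."""


class InvalidNodeError(KeyError):
    """Raised for node indices outside the packet tree."""


@dataclass(frozen=True)
class WaveletFilterPair:
    """Quadrature-mirror low/high-pass filter pair (h, g).

    ``g`` is derived from ``h`` by ``g(k) = (-1)^k h(1-k)`` with indices
    taken modulo the filter support.
    """

    h: np.ndarray
    g: np.ndarray
    name: str = "custom"

    def __post_init__(self) -> None:
        object.__setattr__(self, "h", np.asarray(self.h, dtype=float))
        object.__setattr__(self, "g", np.asarray(self.g, dtype=float))
        if self.h.size == 0 or self.h.size != self.g.size:
            raise InvalidFilterError("h and g must be equal-length, non-empty")


def qmf_pair(h, name: str = "custom") -> WaveletFilterPair:
    """Build the quadrature-mirror pair from a low-pass filter.

    The QMF relation ``g(k) = (-1)^k h(1-k)`` is applied with the index
    origin placed so both filters share the support ``[0, L)``, i.e.
    the sign-alternated reversal ``g(k) = (-1)^k h(L-1-k)``.  This is
    the placement that keeps the stride-2 analysis operator orthogonal
    for every even-length orthogonal ``h``.  For Haar it yields
    ``g = [1/sqrt2, -1/sqrt2]``.
    """
    h = np.asarray(h, dtype=float)
    if h.size == 0 or not np.all(np.isfinite(h)):
        raise InvalidFilterError("low-pass filter must be non-empty and finite")
    L = h.size
    k = np.arange(L)
    g = ((-1.0) ** k) * h[L - 1 - k]
    return WaveletFilterPair(h=h, g=g, name=name)


def wavelet_filters(name: str = DEFAULT_WAVELET) -> WaveletFilterPair:
    """QMF pair for a named orthogonal wavelet family (via PyWavelets).

    The scaling (low-pass) filter is taken with the convention
    ``sum(h) = sqrt(2)``; the high-pass partner is derived by
    :func:`qmf_pair`, not taken from the library, so the in-package
    index convention is used throughout.
    """
    w = pywt.Wavelet(name)
    if not w.orthogonal:
        raise InvalidFilterError(f"wavelet {name!r} is not orthogonal")
    return qmf_pair(np.asarray(w.rec_lo, dtype=float), name=name)


@dataclass
class WPDTree:
    """Full wavelet-packet coefficient tree of one 1-D signal.

    ``nodes[(l, m)]`` holds the coefficient sequence of node ``m`` at
    depth ``l`` (natural ordering); ``(0, 0)`` is the input signal.
    """

    level: int
    signal_length: int
    filter: WaveletFilterPair
    nodes: dict[tuple[int, int], np.ndarray] = field(default_factory=dict)

    def node(self, level: int, index: int) -> np.ndarray:
        try:
            return self.nodes[(level, index)]
        except KeyError:
            raise InvalidNodeError(f"no node ({level}, {index}) in tree") from None


def _analysis_step(x: np.ndarray, filt: WaveletFilterPair
                   ) -> tuple[np.ndarray, np.ndarray]:
    """One split: stride-2 circular correlation with h and g."""
    N = x.size
    L = filt.h.size
    i = np.arange(N // 2)
    j = np.arange(L)
    idx = (j[:, None] + 2 * i[None, :]) % N          # (L, N/2)
    windows = x[idx]
    return filt.h @ windows, filt.g @ windows


def _synthesis_step(low: np.ndarray, high: np.ndarray,
                    filt: WaveletFilterPair) -> np.ndarray:
    """Adjoint of :func:`_analysis_step`; exact inverse for orthogonal h."""
    N = 2 * low.size
    L = filt.h.size
    i = np.arange(low.size)
    j = np.arange(L)
    idx = ((j[:, None] + 2 * i[None, :]) % N).ravel()
    x = np.zeros(N)
    np.add.at(x, idx, (filt.h[:, None] * low[None, :]).ravel())
    np.add.at(x, idx, (filt.g[:, None] * high[None, :]).ravel())
    return x


def wpd_decompose(signal, level: int,
                  filt: WaveletFilterPair | None = None) -> WPDTree:
    """Decompose a 1-D signal into a full packet tree of depth ``level``.

    The signal length must be divisible by ``2**level`` (callers that
    need padding do it beforehand; see :func:`preprocess_epoch`).
    """
    x = np.asarray(signal, dtype=float)
    if filt is None:
        filt = wavelet_filters()
    if level < 1:
        raise ValueError("level must be >= 1")
    if x.ndim != 1:
        raise ValueError("signal must be 1-D")
    if x.size < 2 ** level or x.size % (2 ** level) != 0:
        raise DecompositionDepthError(
            f"signal length {x.size} not divisible by 2^{level}")
    tree = WPDTree(level=level, signal_length=x.size, filter=filt)
    tree.nodes[(0, 0)] = x
    for l in range(level):
        for m in range(2 ** l):
            low, high = _analysis_step(tree.nodes[(l, m)], filt)
            tree.nodes[(l + 1, 2 * m)] = low
            tree.nodes[(l + 1, 2 * m + 1)] = high
    return tree


def freq_to_natural(level: int, f: int) -> int:
    """Natural node index of the ``f``-th frequency-ordered band."""
    return f ^ (f >> 1)


def _check_node(tree: WPDTree, l: int, m: int) -> None:
    if not (1 <= l <= tree.level) or not (0 <= m < 2 ** l):
        raise InvalidNodeError(f"node ({l}, {m}) out of range for level "
                               f"{tree.level} tree")


def wpd_reconstruct(tree: WPDTree, selected_nodes,
                    ordering: str = "freq") -> np.ndarray:
    """Inverse transform keeping only ``selected_nodes``; others zeroed.

    ``selected_nodes`` is a list of ``(level, index)`` pairs with the
    index interpreted in ``ordering`` ("freq" or "natural").  Each
    selected node is propagated back to the root with its sibling
    branches zero, and contributions are summed (the transform is
    linear, so selecting all nodes of a level reproduces the signal
    exactly).
    """
    if ordering not in ("freq", "natural"):
        raise ValueError("ordering must be 'freq' or 'natural'")
    out = np.zeros(tree.signal_length)
    for (l, f) in selected_nodes:
        m = freq_to_natural(l, int(f)) if ordering == "freq" else int(f)
        _check_node(tree, l, m)
        coeffs = tree.node(l, m)
        cur_l, cur_m = l, m
        while cur_l > 0:
            zeros = np.zeros_like(coeffs)
            if cur_m % 2 == 0:
                coeffs = _synthesis_step(coeffs, zeros, tree.filter)
            else:
                coeffs = _synthesis_step(zeros, coeffs, tree.filter)
            cur_l, cur_m = cur_l - 1, cur_m // 2
        out += coeffs
    return out


def band_edges(level: int, f: int, fs: float) -> tuple[float, float]:
    """Frequency band (Hz) of frequency-ordered node ``f`` at ``level``."""
    width = fs / 2 / 2 ** level
    return f * width, (f + 1) * width


def _pad_symmetric(x: np.ndarray, block: int) -> np.ndarray:
    """Pad by symmetric reflection to the next multiple of ``block``."""
    rem = (-x.size) % block
    if rem == 0:
        return x
    return np.pad(x, (0, rem), mode="symmetric")


def preprocess_epoch(epoch: EEGEpoch, level: int = DEFAULT_LEVEL,
                     nodes=DEFAULT_NODES,
                     wavelet: str = DEFAULT_WAVELET,
                     ordering: str = "freq") -> EEGEpoch:
    """Band-limit an epoch by packet decomposition and node reselection.

    Each channel is padded (symmetric reflection) to a multiple of
    ``2**level``, decomposed, reconstructed from the selected nodes and
    cropped back.  Default keeps the four lowest frequency-ordered
    level-4 nodes: 0 to fs/8 Hz, which at fs = 250 Hz spans the mu and
    beta motor rhythms.  Output shape, label and sampling rate equal
    the input's.
    """
    filt = wavelet_filters(wavelet)
    out = np.empty_like(epoch.data)
    for c in range(epoch.n_channels):
        x = _pad_symmetric(epoch.data[c], 2 ** level)
        tree = wpd_decompose(x, level, filt)
        out[c] = wpd_reconstruct(tree, nodes, ordering=ordering)[:epoch.n_samples]
    return epoch.copy_with(out)
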