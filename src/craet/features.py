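"""Feature extraction for every perceptual channel.

Raw channel inputs are turned into the vectors and sequences the network
consumes:

* vision — normalized Fourier descriptors of the object boundary (shape)
  and per-channel color histograms over the object mask (color),
* audition — syllable endpoint detection via short-time energy and
  zero-crossing rate, then Mel-frequency cepstral coefficients (MFCC) per
  syllable, compared with dynamic time warping (DTW),
* gustation — small non-negative flavor vectors, passed through unchanged.

All extractors are pure: fixed inputs and parameters give bit-identical
outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.fft import dct
from scipy.io import wavfile
from scipy.spatial.distance import cdist
from skimage import measure


@dataclass
class ObjectImage:
    """Binary object mask plus named intensity planes in [0, 1]."""

    mask: np.ndarray
    planes: dict  # channel tag ("grey" | "G" | "B" | "R") -> 2-D array
    stage: int = 0

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        for tag, plane in self.planes.items():
            plane = np.asarray(plane, dtype=float)
            if plane.shape != self.mask.shape:
                raise ValueError(f"plane {tag!r} shape {plane.shape} != mask {self.mask.shape}")
            self.planes[tag] = plane


@dataclass
class Waveform:
    samples: np.ndarray
    rate: int

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.rate <= 0:
            raise ValueError("sample rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("waveform contains non-finite samples")


@dataclass
class SyllableSequence:
    """Ordered MFCC (or generic coefficient) matrices, one per syllable."""

    syllables: list = field(default_factory=list)  # list of (frames, n_coeff) arrays

    def __post_init__(self) -> None:
        self.syllables = [np.asarray(m, dtype=float) for m in self.syllables]
        widths = {m.shape[1] for m in self.syllables}
        if len(widths) > 1:
            raise ValueError(f"inconsistent coefficient counts {sorted(widths)}")

    def __len__(self) -> int:
        return len(self.syllables)

    def __iter__(self):
        return iter(self.syllables)


FLAVOR_NAMES = ("sweet", "sour", "bitter", "salty", "umami")


def flavor_features(x) -> np.ndarray:
    """Identity extractor for gustatory input (already a feature vector)."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("flavor vector entries must be non-negative")
    return x.copy()


# -- vision ----------------------------------------------------------------


def _boundary_points(mask: np.ndarray) -> np.ndarray:
    """Closed pixel-edge boundary of the single foreground component.

    The boundary polygon runs along pixel edges (the "crack" between
    foreground and background), oriented consistently with the foreground
    on the walker's right.  Unlike iso-level contouring this polygon is an
    exact similarity under integer upsampling of the mask, which is what
    makes the descriptor's scale invariance exact.  Returned as complex
    points (col + i row).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    n_comp = measure.label(mask, connectivity=2).max()
    if n_comp != 1:
        raise ValueError(f"mask has {n_comp} connected components, expected exactly 1")
    fg = np.pad(mask, 1)
    # directed edges between lattice corners, foreground kept on the right
    out: dict[tuple[int, int], list[tuple[int, int]]] = {}
    rows, cols = np.nonzero(fg)
    for i, j in zip(rows.tolist(), cols.tolist()):
        if not fg[i - 1, j]:  # bg above: walk east along the top edge
            out.setdefault((i, j), []).append((i, j + 1))
        if not fg[i + 1, j]:  # bg below: walk west along the bottom edge
            out.setdefault((i + 1, j + 1), []).append((i + 1, j))
        if not fg[i, j - 1]:  # bg left: walk north along the left edge
            out.setdefault((i + 1, j), []).append((i, j))
        if not fg[i, j + 1]:  # bg right: walk south along the right edge
            out.setdefault((i, j + 1), []).append((i + 1, j + 1))
    start = min(out)
    loop = [start]
    prev, cur = None, start
    while True:
        nxts = out[cur]
        if len(nxts) == 1:
            nxt = nxts[0]
        else:  # pinch corner: deterministic choice, avoid bouncing back
            nxt = min(n for n in nxts if n != prev) if any(n != prev for n in nxts) else nxts[0]
        nxts.remove(nxt)
        if nxt == start:
            break
        loop.append(nxt)
        prev, cur = cur, nxt
    if len(loop) < 8:
        raise ValueError("boundary has fewer than 8 points")
    pts = np.asarray(loop, dtype=float)
    return pts[:, 1] + 1j * pts[:, 0]


def _resample_closed(z: np.ndarray, n_points: int) -> np.ndarray:
    """Resample a closed curve to n_points equally spaced by arc length."""
    zc = np.concatenate([z, z[:1]])
    seg = np.abs(np.diff(zc))
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    t = np.arange(n_points) * (total / n_points)
    re = np.interp(t, s, zc.real)
    im = np.interp(t, s, zc.imag)
    return re + 1j * im


def shape_descriptor(img: ObjectImage, n_desc: int = 32, n_points: int = 256) -> np.ndarray:
    """Normalized Fourier descriptors of the object boundary.

    The boundary is resampled to ``n_points`` by arc length and Fourier
    transformed as a complex signal.  The DC term is dropped (translation
    invariance), magnitudes are taken (rotation and start-point invariance)
    and everything is scaled by the dominant first harmonic (scale
    invariance).  Harmonics are interleaved ``+1, -1, +2, -2, ...`` and the
    scale reference is the dominant of the two first harmonics, so a circle
    maps to ``(1, 0, 0, ...)``.
    """
    z = _boundary_points(img.mask)
    z = _resample_closed(z, n_points)
    F = np.fft.fft(z) / n_points
    order = []
    for k in range(1, n_desc // 2 + 2):
        order.extend([k, -k])
    mags = np.abs(F[np.array(order[:n_desc]) % n_points])
    first = max(np.abs(F[1]), np.abs(F[-1]))
    if first == 0:
        raise ValueError("degenerate boundary: vanishing first harmonic")
    return mags / first


def color_histogram(img: ObjectImage, channels, bins: int = 8) -> np.ndarray:
    """Concatenated per-channel histograms over the object's mask pixels.

    Each channel block is normalized to sum to 1 independently, so adding a
    new receptor's channel later appends a block without rescaling the old
    dimensions.
    """
    blocks = []
    for tag in channels:
        if tag not in img.planes:
            raise KeyError(f"channel {tag!r} not present in image (has {sorted(img.planes)})")
        values = img.planes[tag][img.mask]
        hist, _ = np.histogram(values, bins=bins, range=(0.0, 1.0))
        total = hist.sum()
        if total == 0:
            raise ValueError(f"channel {tag!r} has no mask pixels")
        blocks.append(hist / total)
    return np.concatenate(blocks)


# -- audition --------------------------------------------------------------


def _frame_signal(x: np.ndarray, frame_len: int, hop: int) -> np.ndarray:
    if len(x) < frame_len:
        return np.empty((0, frame_len))
    n_frames = 1 + (len(x) - frame_len) // hop
    idx = np.arange(frame_len)[None, :] + hop * np.arange(n_frames)[:, None]
    return x[idx]


def segment_syllables(
    wav: Waveform,
    energy_thresh: float = 1e-4,
    zcr_thresh: float = 0.35,
    min_len: int = 3,
    frame_ms: float = 25.0,
    hop_ms: float = 10.0,
) -> list[tuple[int, int]]:
    """Endpoint detection via short-time energy and zero-crossing rate.

    Frames whose mean-square energy exceeds ``energy_thresh`` seed syllable
    runs; run edges are then extended outward through tonal tails (frames
    with energy above a tenth of the threshold and ZCR below
    ``zcr_thresh``).  Runs shorter than ``min_len`` frames are discarded.
    Returns ordered, non-overlapping (start_frame, end_frame) pairs
    (end exclusive).  Silence yields an empty list.
    """
    if len(wav.samples) == 0:
        raise ValueError("empty waveform")
    frame_len = max(1, int(round(wav.rate * frame_ms / 1000.0)))
    hop = max(1, int(round(wav.rate * hop_ms / 1000.0)))
    frames = _frame_signal(wav.samples, frame_len, hop)
    if frames.shape[0] == 0:
        return []
    energy = np.mean(frames**2, axis=1)
    signs = np.sign(frames)
    signs[signs == 0] = 1
    zcr = np.mean(np.abs(np.diff(signs, axis=1)) > 0, axis=1)

    active = energy > energy_thresh
    runs: list[list[int]] = []
    i = 0
    n = len(active)
    while i < n:
        if active[i]:
            j = i
            while j + 1 < n and active[j + 1]:
                j += 1
            runs.append([i, j + 1])
            i = j + 1
        else:
            i += 1
    # refine boundaries: absorb low-energy tonal tails
    tail_ok = (energy > 0.1 * energy_thresh) & (zcr < zcr_thresh)
    for run in runs:
        while run[0] > 0 and tail_ok[run[0] - 1]:
            run[0] -= 1
        while run[1] < n and tail_ok[run[1]]:
            run[1] += 1
    # merge overlaps created by tail extension, then length-filter
    merged: list[list[int]] = []
    for run in runs:
        if merged and run[0] <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], run[1])
        else:
            merged.append(run)
    return [(a, b) for a, b in merged if b - a >= min_len]


def _mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=float) / 700.0)


def _mel_inv(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=float) / 2595.0) - 1.0)


def _mel_filterbank(n_filters: int, n_fft: int, rate: int) -> np.ndarray:
    low, high = _mel(0.0), _mel(rate / 2.0)
    pts = _mel_inv(np.linspace(low, high, n_filters + 2))
    bins = np.floor((n_fft + 1) * pts / rate).astype(int)
    fb = np.zeros((n_filters, n_fft // 2 + 1))
    for i in range(n_filters):
        l, c, r = bins[i], bins[i + 1], bins[i + 2]
        if c == l:
            c = l + 1
        if r == c:
            r = c + 1
        fb[i, l:c] = (np.arange(l, c) - l) / (c - l)
        fb[i, c:r] = (r - np.arange(c, r)) / (r - c)
    return fb


def mfcc_features(
    wav: Waveform,
    ranges,
    n_coeff: int = 12,
    n_filters: int = 26,
    frame_ms: float = 25.0,
    hop_ms: float = 10.0,
    preemphasis: float = 0.97,
) -> SyllableSequence:
    """MFCC matrix (frames x n_coeff) per syllable range.

    Standard chain: pre-emphasis, Hamming window, power spectrum, triangular
    mel filterbank, log, orthonormal DCT-II.  Coefficient 0 (log energy
    term) is kept as the first column.
    """
    frame_len = max(1, int(round(wav.rate * frame_ms / 1000.0)))
    hop = max(1, int(round(wav.rate * hop_ms / 1000.0)))
    x = np.append(wav.samples[0], wav.samples[1:] - preemphasis * wav.samples[:-1])
    frames = _frame_signal(x, frame_len, hop)
    n_total = frames.shape[0]
    matrices = []
    window = np.hamming(frame_len)
    n_fft = int(2 ** np.ceil(np.log2(frame_len)))
    fb = _mel_filterbank(n_filters, n_fft, wav.rate)
    for start, end in ranges:
        if not (0 <= start < end <= n_total):
            raise ValueError(f"frame range ({start}, {end}) outside waveform ({n_total} frames)")
        seg = frames[start:end] * window
        power = np.abs(np.fft.rfft(seg, n_fft, axis=1)) ** 2 / n_fft
        mel_energy = np.maximum(power @ fb.T, 1e-30)
        cepstra = dct(np.log(mel_energy), type=2, axis=1, norm="ortho")
        matrices.append(cepstra[:, :n_coeff])
    return SyllableSequence(matrices)


def dtw_distance(A, B) -> float:
    """Classic dynamic-time-warping distance between coefficient matrices.

    Per-frame cost is the Euclidean distance between rows; the alignment is
    monotone and boundary-matched with unit steps (diagonal, down, right);
    the returned value is the minimal summed cost.  Symmetric by
    construction.
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if A.size == 0 or B.size == 0:
        raise ValueError("dtw_distance requires non-empty sequences")
    if A.shape[1] != B.shape[1]:
        raise ValueError(f"coefficient counts differ: {A.shape[1]} vs {B.shape[1]}")
    cost = cdist(A, B)  # pairwise frame costs (Euclidean, exact differences)
    n, m = cost.shape
    D = np.full((n + 1, m + 1), np.inf)
    D[0, 0] = 0.0
    for i in range(1, n + 1):
        D[i, 1:] = cost[i - 1]
        acc = D[i - 1]
        row = D[i]
        prev = np.minimum(acc[:-1], acc[1:])  # diag / up, shifted
        for j in range(1, m + 1):
            row[j] += min(prev[j - 1], row[j - 1])
    return float(D[n, m])


# -- file I/O ----------------------------------------------------------------


def read_wav(path) -> Waveform:
    """Load a PCM WAV file into a float waveform in [-1, 1]."""
    rate, data = wavfile.read(path)
    data = np.asarray(data)
    if data.ndim > 1:
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data / float(np.iinfo(data.dtype).max)
    return Waveform(samples=data.astype(float), rate=int(rate))


def write_wav(path, wav: Waveform) -> None:
    data = np.clip(wav.samples, -1.0, 1.0)
    wavfile.write(path, wav.rate, (data * 32767).astype(np.int16))
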