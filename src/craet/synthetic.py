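"""Synthetic multimodal object world and the staged presentation schedule.

The generator emulates the study conditions of the staged experiment: a
set of objects with distinct shapes, colors that are confusable without
the red receptor, multi-syllable audible and ultrasonic names, and
low-variance flavor vectors.  The schedule grows the sensory apparatus
stage by stage:

1. grey image (brightness receptor only — shape learning),
2. grey + green + blue image (dichromat color learning),
3. grey + G + B + R image (trichromat; dimensionality increase),
4. image + audible name (auditory channel comes online),
5. image + ultrasonic name (ultrasonic receptor added),
6. image + taste (gustatory channel comes online).

Shapes are radial-cosine blobs ``r(phi) = R (1 + A cos(m phi))`` whose
harmonic order ``m`` differs per object, which keeps Fourier descriptors
well separated; the first two objects share a shape and the (grey, G, B)
color planes and differ only in the R channel — the confusable pair that
only a trichromat stage can tell apart.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.draw import polygon as draw_polygon

from .features import ObjectImage, SyllableSequence, Waveform

AUDIBLE_TOKENS = ("ba", "do", "gi", "ka", "lu", "mei", "na", "po", "ri", "su")
ULTRASONIC_TOKENS = tuple(f"u{i}" for i in range(10))

AUDIO_RATE = 8000
_ULTRA_FRAMES = 10
_ULTRA_COEFF = 12


@dataclass
class ObjectSpec:
    """Ground truth for one synthetic object presentation.

    ``name`` is the ground-truth label used for naming and for answering
    the network's questions; two specs may share a name, in which case they
    are different *views* (or taste variants) of the same object — the
    confusable-pair scenario.  ``view`` just disambiguates bookkeeping.
    """

    name: str
    shape_m: int  # radial-cosine harmonic order
    shape_amp: float  # radial-cosine amplitude
    color: tuple  # (R, G, B) in [0, 1]
    grey: float  # brightness plane level (defaults near luminance)
    audible: tuple  # ordered syllable tokens
    ultrasonic: tuple  # ordered ultrasonic tokens
    flavor: np.ndarray  # 5-dim non-negative (sweet, sour, bitter, salty, umami)
    view: str = ""
    pixel_noise: float = 0.02
    audio_noise: float = 0.003
    ultra_noise: float = 0.05
    flavor_noise: float = 0.002
    scale_jitter: float = 0.08

    def __post_init__(self) -> None:
        self.flavor = np.asarray(self.flavor, dtype=float)
        if np.any(self.flavor < 0):
            raise ValueError("flavor values must be non-negative")


@dataclass
class StageSpec:
    index: int
    image_channels: tuple  # subset of ("grey", "G", "B", "R"), in order
    audio: str | None = None  # None | "audible" | "ultrasonic"
    taste: bool = False
    passes: int = 2


@dataclass
class StagePlan:
    stages: list
    seed: int = 0

    def __post_init__(self) -> None:
        seen: set = set()
        for st in self.stages:
            chans = set(st.image_channels)
            if not seen <= chans and chans:
                raise ValueError("receptor sets must grow monotonically across stages")
            seen |= chans


def default_plan(passes: int = 2, seed: int = 0) -> StagePlan:
    return StagePlan(
        stages=[
            StageSpec(1, ("grey",), passes=passes),
            StageSpec(2, ("grey", "G", "B"), passes=passes),
            StageSpec(3, ("grey", "G", "B", "R"), passes=passes),
            StageSpec(4, ("grey", "G", "B", "R"), audio="audible", passes=passes),
            StageSpec(5, ("grey", "G", "B", "R"), audio="ultrasonic", passes=passes),
            StageSpec(6, ("grey", "G", "B", "R"), taste=True, passes=passes),
        ],
        seed=seed,
    )


def default_world() -> list[ObjectSpec]:
    """Ten presentations of nine objects.

    The first two entries are two views of the same object ("pear"): they
    share the shape, the grey/G/B planes, the audible and ultrasonic names,
    and differ only in the R channel and in their taste variant — only a
    trichromat stage can tell the views apart, while naming and taste bind
    both views to one association circuit.
    """
    mk = ObjectSpec
    return [
        mk("pear", 2, 0.35, (0.6875, 0.5625, 0.1875), 0.5625,
           ("ba", "lu"), ("u0", "u3"), (0.67, 0.22, 0.0, 0.0, 0.0), view="bright"),
        mk("pear", 2, 0.35, (0.3125, 0.5625, 0.1875), 0.5625,
           ("ba", "lu"), ("u0", "u3"), (0.63, 0.14, 0.0, 0.0, 0.0), view="dark"),
        mk("banana", 3, 0.45, (0.9375, 0.8125, 0.3125), 0.8125,
           ("do", "na"), ("u2", "u5"), (0.80, 0.05, 0.0, 0.0, 0.05)),
        mk("apple", 4, 0.45, (0.8125, 0.1875, 0.1875), 0.4375,
           ("gi", "ka"), ("u3", "u6"), (0.55, 0.30, 0.02, 0.0, 0.0)),
        mk("orange", 5, 0.45, (0.9375, 0.5625, 0.0625), 0.6875,
           ("ka", "gi"), ("u4", "u7"), (0.60, 0.45, 0.05, 0.0, 0.0)),
        mk("lemon", 6, 0.45, (0.9375, 0.9375, 0.3125), 0.9375,
           ("lu", "mei"), ("u5", "u8"), (0.20, 0.85, 0.05, 0.0, 0.0)),
        mk("tomato", 7, 0.45, (0.8125, 0.3125, 0.1875), 0.5625,
           ("na", "po"), ("u6", "u9"), (0.30, 0.25, 0.0, 0.05, 0.40)),
        mk("cucumber", 8, 0.45, (0.1875, 0.6875, 0.3125), 0.5625,
           ("po", "su"), ("u7", "u0"), (0.15, 0.05, 0.10, 0.0, 0.05)),
        mk("pepper", 9, 0.45, (0.1875, 0.4375, 0.1875), 0.3125,
           ("ri", "do"), ("u8", "u1"), (0.10, 0.15, 0.60, 0.0, 0.05)),
        mk("grape", 10, 0.45, (0.4375, 0.1875, 0.4375), 0.3125,
           ("su", "mei"), ("u9", "u2"), (0.72, 0.35, 0.02, 0.0, 0.0)),
    ]


# -- vision -----------------------------------------------------------------


def _shape_boundary(spec: ObjectSpec, rng, size: int, n_points: int = 256) -> np.ndarray:
    base_radius = size * 0.29
    angle = rng.uniform(0.0, 2.0 * np.pi)
    scale = 1.0 + rng.uniform(-spec.scale_jitter, spec.scale_jitter)
    phi = np.linspace(0.0, 2.0 * np.pi, n_points, endpoint=False)
    r = base_radius * scale * (1.0 + spec.shape_amp * np.cos(spec.shape_m * (phi - angle)))
    cx = cy = size / 2.0
    rows = cy + r * np.sin(phi)
    cols = cx + r * np.cos(phi)
    return np.column_stack([rows, cols])


def render_image(
    spec: ObjectSpec, channels, rng, size: int = 96
) -> ObjectImage:
    """Render the object as a mask plus per-channel constant-color planes.

    The mask is the jittered (rotated, scaled) shape prototype; each plane
    is the object's channel level plus Gaussian pixel noise, clipped to
    [0, 1]; background pixels are zero.
    """
    boundary = _shape_boundary(spec, rng, size)
    mask = np.zeros((size, size), dtype=bool)
    rr, cc = draw_polygon(boundary[:, 0], boundary[:, 1], shape=mask.shape)
    mask[rr, cc] = True
    levels = {"grey": spec.grey, "R": spec.color[0], "G": spec.color[1], "B": spec.color[2]}
    planes = {}
    for tag in channels:
        plane = np.zeros((size, size))
        noise = rng.normal(0.0, spec.pixel_noise, size=int(mask.sum()))
        plane[mask] = np.clip(levels[tag] + noise, 0.0, 1.0)
        planes[tag] = plane
    return ObjectImage(mask=mask, planes=planes)


# -- audition ---------------------------------------------------------------


def _token_f0(token: str) -> float:
    idx = AUDIBLE_TOKENS.index(token)
    return 300.0 * (1.28**idx)


def synth_audible_name(
    spec: ObjectSpec, rng, burst_s: float = 0.25, gap_s: float = 0.18, rate: int = AUDIO_RATE
) -> Waveform:
    """One harmonic burst per syllable token, separated by silence gaps.

    Each token has a distinct base frequency; bursts carry three harmonics
    (those below Nyquist) under a Hann envelope, with additive Gaussian
    noise at the spec's audio noise scale over the whole waveform.
    """
    n_burst = int(burst_s * rate)
    n_gap = int(gap_s * rate)
    t = np.arange(n_burst) / rate
    env = np.hanning(n_burst)
    pieces = [np.zeros(n_gap)]
    for token in spec.audible:
        f0 = _token_f0(token)
        burst = np.zeros(n_burst)
        for k, amp in ((1, 1.0), (2, 0.5), (3, 0.25)):
            if k * f0 < rate / 2.0:
                burst += amp * np.sin(2.0 * np.pi * k * f0 * t)
        burst = 0.5 * env * burst / (np.max(np.abs(burst)) + 1e-12)
        pieces.extend([burst, np.zeros(n_gap)])
    samples = np.concatenate(pieces)
    samples = samples + rng.normal(0.0, spec.audio_noise, size=samples.shape)
    return Waveform(samples=samples, rate=rate)


def ultrasonic_prototype(token: str) -> np.ndarray:
    """Deterministic per-token coefficient-sequence prototype."""
    idx = ULTRASONIC_TOKENS.index(token)
    proto_rng = np.random.default_rng(10_000 + idx)
    return proto_rng.normal(0.0, 2.0, size=(_ULTRA_FRAMES, _ULTRA_COEFF))


def synth_ultrasonic_name(spec: ObjectSpec, rng) -> SyllableSequence:
    """Token-keyed prototype sequences plus small Gaussian noise.

    Ultrasonic features are emitted directly in coefficient space (no
    waveform step); distinct tokens are separated far beyond the ultrasonic
    area threshold.
    """
    mats = []
    for token in spec.ultrasonic:
        proto = ultrasonic_prototype(token)
        mats.append(proto + rng.normal(0.0, spec.ultra_noise, size=proto.shape))
    return SyllableSequence(mats)


def synth_flavor(spec: ObjectSpec, rng) -> np.ndarray:
    """Flavor vector near the spec value, clipped non-negative."""
    return np.clip(spec.flavor + rng.normal(0.0, spec.flavor_noise, size=spec.flavor.shape), 0.0, None)


# -- stream -----------------------------------------------------------------


@dataclass
class Sample:
    stage: int
    object_index: int
    name: str
    image: ObjectImage | None = None
    audible: Waveform | None = None
    ultrasonic: SyllableSequence | None = None
    flavor: np.ndarray | None = None


def generate_stream(specs, plan: StagePlan, rng=None) -> list[Sample]:
    """Replay the staged schedule: per stage, per pass, all objects shuffled."""
    if rng is None:
        rng = np.random.default_rng(plan.seed)
    samples: list[Sample] = []
    for stage in plan.stages:
        for _ in range(stage.passes):
            order = rng.permutation(len(specs))
            for oi in order:
                spec = specs[oi]
                sample = Sample(stage=stage.index, object_index=int(oi), name=spec.name)
                if stage.image_channels:
                    sample.image = render_image(spec, stage.image_channels, rng)
                    sample.image.stage = stage.index
                if stage.audio == "audible":
                    sample.audible = synth_audible_name(spec, rng)
                elif stage.audio == "ultrasonic":
                    sample.ultrasonic = synth_ultrasonic_name(spec, rng)
                if stage.taste:
                    sample.flavor = synth_flavor(spec, rng)
                samples.append(sample)
    return samples
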