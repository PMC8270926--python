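"""Task generators: STORE-RECALL working memory and sequential-MNIST encoding.

Everything here is synthetic and reproducible from a seed; the sequential
pixel encoder also accepts real MNIST images read from IDX files, but no
external dataset is required (see :func:`make_synthetic_digits`).
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional

import numpy as np

__all__ = [
    "SequenceLayout",
    "StoreRecallSpec",
    "TaskBatch",
    "generate_store_recall",
    "store_recall_factory",
    "SMNISTSpec",
    "encode_smnist",
    "make_synthetic_digits",
    "read_idx",
]


@dataclass(frozen=True)
class SequenceLayout:
    """Timing of the STORE-RECALL trial segments (ms).

    A trial is: a ``value_ms`` character presentation with the STORE
    command active concurrently (for its first ``store_ms``; the
    instruction arrives while the character is on), a delay of
    ``working_memory`` ms, then the ``recall_ms`` RECALL command — the
    decision window.  Requires ``store_ms <= value_ms``; with the default
    equal durations the STORE offset precedes the RECALL onset by exactly
    the working memory.
    """

    value_ms: float = 200.0
    store_ms: float = 200.0
    recall_ms: float = 200.0

    def __post_init__(self) -> None:
        if self.store_ms > self.value_ms:
            raise ValueError("store_ms must be <= value_ms (concurrent command)")


@dataclass(frozen=True)
class StoreRecallSpec:
    """STORE-RECALL task parameters.

    ``working_memory`` is the delay between the onset of the STORE command
    and the onset of the RECALL command.  Active input channels fire as
    Bernoulli/Poisson processes at ``input_rate`` Hz; the input layer has
    four equal groups (value-0, value-1, STORE, RECALL) of
    ``n_channels_per_symbol`` channels each.

    With ``distractors`` (default), the character stream continues through
    the delay: random bits are presented in consecutive ``value_ms`` slots
    between STORE and RECALL, and the network must report the bit that was
    marked by the STORE command while ignoring the later ones.  Without
    distractor presentations the delay is silent, and networks can fall
    back on recurrent reverberation instead of threshold memory.
    """

    working_memory: float = 1200.0
    delta_t: float = 1.0
    input_rate: float = 50.0
    n_channels_per_symbol: int = 10
    sequence_layout: SequenceLayout = field(default_factory=SequenceLayout)
    distractors: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.working_memory > 0):
            raise ValueError("working_memory must be > 0")
        if not (self.delta_t > 0):
            raise ValueError("delta_t must be > 0")
        if self.input_rate < 0:
            raise ValueError("input_rate must be >= 0")
        if self.n_channels_per_symbol < 1:
            raise ValueError("n_channels_per_symbol must be >= 1")
        for name, ms in (
            ("working_memory", self.working_memory),
            ("value_ms", self.sequence_layout.value_ms),
            ("store_ms", self.sequence_layout.store_ms),
            ("recall_ms", self.sequence_layout.recall_ms),
        ):
            steps = ms / self.delta_t
            if abs(steps - round(steps)) > 1e-9:
                raise ValueError(
                    f"{name} = {ms} ms is not a multiple of delta_t = {self.delta_t} ms"
                )
        if self.working_memory < self.sequence_layout.value_ms:
            raise ValueError(
                "working_memory must be at least one value slot (the RECALL "
                "onset trails the STORE onset by the working memory)"
            )

    @property
    def n_input(self) -> int:
        return 4 * self.n_channels_per_symbol

    def segment_steps(self) -> tuple[int, int, int, int]:
        """Steps of (value slot, concurrent STORE pulse, post-slot gap,
        recall).

        The working memory is measured STORE onset to RECALL onset, so the
        gap after the stored slot is ``working_memory - value_ms`` and the
        trial length is ``working_memory + recall_ms``.
        """
        lay = self.sequence_layout
        nv = int(round(lay.value_ms / self.delta_t))
        return (
            nv,
            int(round(lay.store_ms / self.delta_t)),
            int(round(self.working_memory / self.delta_t)) - nv,
            int(round(lay.recall_ms / self.delta_t)),
        )

    @property
    def n_steps(self) -> int:
        nv, _, nd, nr = self.segment_steps()
        return nv + nd + nr


@dataclass
class TaskBatch:
    """A batch of spike-encoded trials.

    ``input_spikes`` is a binary (batch, T, n_input) raster, ``target`` the
    per-case stored bit (or class label), and ``decision_mask`` a boolean
    (batch, T) array with exactly one contiguous readout window per case.
    """

    input_spikes: np.ndarray
    target: np.ndarray
    decision_mask: np.ndarray

    @property
    def n_cases(self) -> int:
        return self.input_spikes.shape[0]

    def events_to_csv(self, path) -> None:
        """Write the input rasters as a (case, time_step, channel) event
        list."""
        cases, times, chans = np.nonzero(self.input_spikes)
        with open(path, "w") as f:
            f.write("case,time_step,channel\n")
            for c, t, k in zip(cases, times, chans):
                f.write(f"{c},{t},{k}\n")


def generate_store_recall(
    spec: StoreRecallSpec,
    batch_size: int,
    rng: Optional[np.random.Generator] = None,
    *,
    randomize_store: bool = False,
) -> TaskBatch:
    """Generate a STORE-RECALL batch.

    The trial is a stream of character slots (``value_ms`` each) followed
    by the RECALL command; channel groups fire at ``input_rate`` Hz while
    their symbol is active (the value group matching the presented bit
    during its slot, the STORE/RECALL groups during their commands) and
    are silent otherwise.  The STORE command is received concurrently with
    the character it marks; the target is that character's bit, and the
    decision window is the RECALL segment.

    By default STORE marks the first slot, so every STORE precedes its
    RECALL by exactly ``working_memory`` ms.  With ``randomize_store`` the
    STORE slot is drawn uniformly per case, giving delays from 0 up to the
    full working memory — the training curriculum under which the maximum
    delay (the working-memory requirement) becomes learnable.
    """
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    if rng is None:
        rng = np.random.default_rng(spec.seed)

    nv, ns, nd, nr = spec.segment_steps()
    T = nv + nd + nr
    g = spec.n_channels_per_symbol
    n_in = spec.n_input
    p = spec.input_rate * spec.delta_t / 1000.0  # per-step spike probability
    if p > 1.0:
        raise ValueError("input_rate * delta_t exceeds one spike per step")

    # character slots: slot k occupies [k*nv, (k+1)*nv); slot 0 plus the
    # full value_ms slots inside the delay (a trailing remainder of the
    # delay stays silent)
    n_slots = 1 + (nd // nv if nv > 0 else 0)
    if randomize_store:
        store_slot = rng.integers(0, n_slots, size=batch_size)
    else:
        store_slot = np.zeros(batch_size, dtype=np.int64)
    bits = rng.integers(0, 2, size=(batch_size, n_slots))
    target = bits[np.arange(batch_size), store_slot]

    active = np.zeros((batch_size, T, n_in), dtype=bool)
    rows_all = np.arange(batch_size)
    for k in range(n_slots):
        sl = slice(k * nv, (k + 1) * nv)
        if spec.distractors:
            presented = np.ones(batch_size, dtype=bool)
        else:
            presented = store_slot == k
        # value groups: channels [0:g] encode bit 0, [g:2g] encode bit 1
        for bit in (0, 1):
            rows = presented & (bits[:, k] == bit)
            active[rows, sl, bit * g:(bit + 1) * g] = True
        # STORE command, concurrent with the character it marks
        rows = store_slot == k
        for b_ in rows_all[rows]:
            active[b_, k * nv:k * nv + ns, 2 * g:3 * g] = True
    active[:, nv + nd:T, 3 * g:4 * g] = True     # RECALL command

    raster = (rng.random((batch_size, T, n_in)) < p) & active

    mask = np.zeros((batch_size, T), dtype=bool)
    mask[:, nv + nd:T] = True

    return TaskBatch(
        input_spikes=raster.astype(np.float64),
        target=target.astype(np.int64),
        decision_mask=mask,
    )


def store_recall_factory(
    spec: StoreRecallSpec,
    *,
    randomize_store: bool = False,
) -> Callable[[np.random.Generator, int], TaskBatch]:
    """Batch generator closure for the training loop."""

    def factory(rng: np.random.Generator, batch_size: int) -> TaskBatch:
        return generate_store_recall(
            spec, batch_size, rng=rng, randomize_store=randomize_store
        )

    return factory


# --- sequential MNIST -------------------------------------------------------


@dataclass(frozen=True)
class SMNISTSpec:
    """Threshold-crossing pixel encoder for sequential 28x28 images.

    Each pixel is presented for one time step in row-major order (784
    steps); input neuron k fires at step t when the grey level crosses its
    threshold between pixels t-1 and t (either direction by default).  An
    extra cue neuron fires for ``cue_steps`` steps after the image to mark
    the readout window.
    """

    n_threshold_neurons: int = 80
    thresholds: Optional[tuple] = None
    cue_neuron: bool = True
    cue_steps: int = 56
    delta_t: float = 1.0
    both_directions: bool = True

    def __post_init__(self) -> None:
        if self.n_threshold_neurons < 2:
            raise ValueError("need at least 2 threshold neurons")
        if self.thresholds is not None:
            th = np.asarray(self.thresholds, dtype=float)
            if th.size != self.n_threshold_neurons:
                raise ValueError("thresholds length must match n_threshold_neurons")
            if np.any(np.diff(th) <= 0):
                raise ValueError("thresholds must be strictly increasing")

    def threshold_levels(self) -> np.ndarray:
        if self.thresholds is not None:
            return np.asarray(self.thresholds, dtype=float)
        n = self.n_threshold_neurons
        return np.linspace(0.0, 1.0, n + 2)[1:-1]  # evenly spaced in (0,1)

    @property
    def n_input(self) -> int:
        return self.n_threshold_neurons + (1 if self.cue_neuron else 0)


def encode_smnist(image: np.ndarray, spec: SMNISTSpec) -> np.ndarray:
    """Encode one 28x28 grey-level image as a spike raster.

    Returns a binary (784 + cue_steps, n_input) array (cue window absent
    when ``spec.cue_neuron`` is False).  Deterministic given image and spec.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.shape != (28, 28):
        raise ValueError(f"image must be 28x28, got {image.shape}")
    if image.min() < 0.0 or image.max() > 1.0:
        raise ValueError("image values must lie in [0, 1] after scaling")

    stream = image.reshape(-1)  # row-major pixel sequence, 784 steps
    th = spec.threshold_levels()
    n_steps = stream.size
    T = n_steps + (spec.cue_steps if spec.cue_neuron else 0)
    raster = np.zeros((T, spec.n_input))

    prev = stream[:-1, None]
    cur = stream[1:, None]
    rising = (prev < th) & (cur >= th)
    if spec.both_directions:
        falling = (prev > th) & (cur <= th)
        crossings = rising | falling
    else:
        crossings = rising
    raster[1:n_steps, : spec.n_threshold_neurons] = crossings

    if spec.cue_neuron:
        raster[n_steps:, -1] = 1.0
    return raster


def make_synthetic_digits(
    n: int, seed: int = 0, n_classes: int = 10
) -> tuple[np.ndarray, np.ndarray]:
    """Reproducible labelled 28x28 images with distinguishable classes.

    Each class has a fixed smooth random-field prototype (class-keyed, so
    prototypes are stable across datasets); samples add a small spatial
    shift, per-pixel noise, and a contrast jitter.  Returns
    ``(images, labels)`` with images in [0, 1].  These are stand-ins that
    exercise the sequential-pixel pipeline, not handwriting.
    """
    from scipy.ndimage import gaussian_filter

    if n < 1:
        raise ValueError("n must be >= 1")
    protos = []
    for c in range(n_classes):
        rng_c = np.random.default_rng([977, c])
        field_ = gaussian_filter(rng_c.standard_normal((28, 28)), sigma=3.0)
        field_ -= field_.min()
        field_ /= field_.max()
        protos.append(field_)
    protos = np.stack(protos)

    rng = np.random.default_rng(seed)
    labels = rng.integers(0, n_classes, size=n)
    images = np.empty((n, 28, 28))
    for i, lab in enumerate(labels):
        img = protos[lab]
        shift = rng.integers(-2, 3, size=2)
        img = np.roll(img, tuple(shift), axis=(0, 1))
        contrast = 0.7 + 0.3 * rng.random()
        img = contrast * img + 0.08 * rng.standard_normal((28, 28))
        images[i] = np.clip(img, 0.0, 1.0)
    return images, labels.astype(np.int64)


def read_idx(path) -> np.ndarray:
    """Read an IDX-format array (the MNIST container format).

    Optional convenience for feeding real digits through
    :func:`encode_smnist`; grey images should be scaled to [0, 1] by the
    caller (divide by 255).
    """
    data = Path(path).read_bytes()
    zero, dtype_code, ndim = struct.unpack(">HBB", data[:4])
    if zero != 0:
        raise ValueError("not an IDX file (bad magic)")
    dtypes = {
        0x08: np.uint8, 0x09: np.int8, 0x0B: np.dtype(">i2"),
        0x0C: np.dtype(">i4"), 0x0D: np.dtype(">f4"), 0x0E: np.dtype(">f8"),
    }
    if dtype_code not in dtypes:
        raise ValueError(f"unsupported IDX dtype code 0x{dtype_code:02x}")
    shape = struct.unpack(f">{ndim}I", data[4:4 + 4 * ndim])
    arr = np.frombuffer(data, dtype=dtypes[dtype_code], offset=4 + 4 * ndim)
    return arr.reshape(shape)
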