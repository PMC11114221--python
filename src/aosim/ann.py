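"""Device-aware two-layer perceptron.

A fully connected 27 → 14 → 4 network (27 → 27 → 9 for the mixed-odorant
task) whose synaptic weights are realized as differential conductance pairs
of the organic synaptic device:

    w = (G+ − G−) / (G_max − G_min)  ∈  [−1, 1]

Weight updates are therefore *not* free: a desired weight change is
converted into an integer number of potentiation pulses applied to one
member of the pair, and the conductance steps along the device's nonlinear
LTP curve from its current position.  Bounded conductance, pulse
quantization and LTP curvature are exactly the non-idealities through which
device nonlinearity degrades recognition accuracy; a near-linear device
(|A| ≫ P_max) approaches ideal floating-point training.

Both layers use logistic sigmoid activations.  Training is error-driven
stochastic descent on the cross-entropy error of the sigmoid outputs
against one-hot targets, with per-layer learning rates (0.03 for the
input-side matrix, 0.0001 for the output-side matrix) and three
hardware-oriented modifications that are standard practice for pulse-
programmed synapse arrays:

* patterns already classified correctly with a margin are skipped
  (perceptron-style error-driven gating), so a converged network stops
  burning programming pulses and sits stably at its solution;
* output errors smaller than a dead zone trigger no programming — the
  minimum weight increment of a pulse-programmed pair is finite, so
  chasing sub-pulse residuals only dithers the array;
* the hidden-layer delta propagates the raw error through the output
  weights without sigmoid-derivative damping (sign-preserving, as in
  resilient/Manhattan-style backpropagation), which keeps the update
  magnitude commensurate with the pulse step.

Binary patterns are presented with bipolar (±1) pixel encoding, so every
input line participates in each update.  Sub-pulse update remainders are
resolved by seeded stochastic rounding so the expected applied update
equals the requested one; ``round`` and ``none`` (continuous) quantization
modes are available, the latter serving as the continuous-limit oracle.
An ``ideal`` mode with unconstrained floating-point weights provides the
device-free baseline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .device import DeviceParams, g_ltp, ltp_pulse_of, ltp_slope
from .refine import PatternDataset

__all__ = [
    "AnnConfig",
    "AnnState",
    "AccuracyTrajectory",
    "init_network",
    "weight_of",
    "forward",
    "backprop_deltas",
    "train_step",
    "train",
    "evaluate",
    "predict",
    "linearity_sweep",
    "synapse_count",
]

#: maximum potentiation pulses applied to one synapse in one training step
MAX_PULSES_PER_STEP = 10
#: pair members within this fraction of saturation trigger a weight refresh
REFRESH_FRACTION = 0.99


@dataclass(frozen=True)
class AnnConfig:
    """Architecture and training hyper-parameters.

    Defaults are the single-odorant task: 27 inputs (the flattened 9 × 3
    pattern), 14 hidden neurons, 4 output classes, learning rates 0.03 and
    0.0001 for the first and second weight matrices, accuracy evaluated
    every 100 training steps (one epoch).
    """

    n_input: int = 27
    n_hidden: int = 14
    n_output: int = 4
    lr_layer1: float = 0.03
    lr_layer2: float = 0.0001
    steps_per_epoch: int = 100
    total_steps: int = 1000
    seed: int = 0
    quantization: str = "stochastic"  # 'stochastic' | 'round' | 'none'
    ideal: bool = False
    input_encoding: str = "bipolar"  # 'bipolar' (0 -> -1) | 'binary'
    init_scale_input: float = 0.1
    init_scale_output: float = 1.0
    error_deadzone: float = 0.3
    update_margin: float = 0.1

    def __post_init__(self) -> None:
        if min(self.n_input, self.n_hidden, self.n_output) < 1:
            raise ValueError("all layer sizes must be >= 1")
        if self.lr_layer1 <= 0 or self.lr_layer2 <= 0:
            raise ValueError("learning rates must be positive")
        if self.steps_per_epoch < 1:
            raise ValueError("steps_per_epoch must be >= 1")
        if self.total_steps < 0:
            raise ValueError("total_steps must be >= 0")
        if self.quantization not in ("stochastic", "round", "none"):
            raise ValueError(f"unknown quantization mode {self.quantization!r}")
        if self.input_encoding not in ("bipolar", "binary"):
            raise ValueError(f"unknown input encoding {self.input_encoding!r}")
        for name in ("init_scale_input", "init_scale_output"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0.0 <= self.error_deadzone < 1.0:
            raise ValueError("error_deadzone must be in [0, 1)")
        if self.update_margin < 0.0:
            raise ValueError("update_margin must be >= 0")

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "AnnConfig":
        return cls(**json.loads(text))


def synapse_count(config: AnnConfig) -> int:
    """Synapse count in the product convention n_input × n_hidden × n_output."""
    return config.n_input * config.n_hidden * config.n_output


@dataclass
class AnnState:
    """Network state: pulse positions of every differential pair.

    ``p1_plus``/``p1_minus`` are (n_input, n_hidden) arrays of cumulative
    LTP pulse positions; conductances are ``g_ltp(device, p)``.  In ideal
    mode the float weight matrices ``w1``/``w2`` are authoritative instead.
    ``pulse_count`` accumulates the total number of programming pulses
    applied per layer.
    """

    config: AnnConfig
    device: DeviceParams
    p1_plus: np.ndarray = None
    p1_minus: np.ndarray = None
    p2_plus: np.ndarray = None
    p2_minus: np.ndarray = None
    w1: np.ndarray = None
    w2: np.ndarray = None
    pulse_count: np.ndarray = None

    def weights(self):
        """Current (W1, W2) weight matrices."""
        if self.config.ideal:
            return self.w1, self.w2
        span = self.device.span
        w1 = (g_ltp(self.device, self.p1_plus) - g_ltp(self.device, self.p1_minus)) / span
        w2 = (g_ltp(self.device, self.p2_plus) - g_ltp(self.device, self.p2_minus)) / span
        return w1, w2

    def conductances(self):
        """Conductance arrays ((g1+, g1−), (g2+, g2−)) in μS."""
        d = self.device
        return (
            (g_ltp(d, self.p1_plus), g_ltp(d, self.p1_minus)),
            (g_ltp(d, self.p2_plus), g_ltp(d, self.p2_minus)),
        )

    def copy(self) -> "AnnState":
        return AnnState(
            config=self.config,
            device=self.device,
            p1_plus=None if self.p1_plus is None else self.p1_plus.copy(),
            p1_minus=None if self.p1_minus is None else self.p1_minus.copy(),
            p2_plus=None if self.p2_plus is None else self.p2_plus.copy(),
            p2_minus=None if self.p2_minus is None else self.p2_minus.copy(),
            w1=None if self.w1 is None else self.w1.copy(),
            w2=None if self.w2 is None else self.w2.copy(),
            pulse_count=None if self.pulse_count is None else self.pulse_count.copy(),
        )

    def to_json(self) -> str:
        w1, w2 = self.weights()
        payload = {
            "config": self.config.__dict__,
            "device": json.loads(self.device.to_json()),
            "weights_layer1": np.round(w1, 9).tolist(),
            "weights_layer2": np.round(w2, 9).tolist(),
            "pulse_count": None if self.pulse_count is None else self.pulse_count.tolist(),
        }
        if not self.config.ideal:
            payload["g1_plus_uS"] = np.round(g_ltp(self.device, self.p1_plus), 6).tolist()
            payload["g1_minus_uS"] = np.round(g_ltp(self.device, self.p1_minus), 6).tolist()
            payload["g2_plus_uS"] = np.round(g_ltp(self.device, self.p2_plus), 6).tolist()
            payload["g2_minus_uS"] = np.round(g_ltp(self.device, self.p2_minus), 6).tolist()
        return json.dumps(payload, indent=2)


def state_from_json(text: str) -> AnnState:
    """Rebuild an :class:`AnnState` from its JSON serialization.

    Device-mode pulse positions are recovered by inverting the LTP curve at
    the stored conductances.
    """
    d = json.loads(text)
    config = AnnConfig(**d["config"])
    device = DeviceParams.from_json(json.dumps(d["device"]))
    state = AnnState(
        config=config,
        device=device,
        pulse_count=None if d.get("pulse_count") is None else np.asarray(d["pulse_count"]),
    )
    if config.ideal:
        state.w1 = np.asarray(d["weights_layer1"], dtype=float)
        state.w2 = np.asarray(d["weights_layer2"], dtype=float)
    else:
        state.p1_plus = ltp_pulse_of(device, np.asarray(d["g1_plus_uS"], dtype=float))
        state.p1_minus = ltp_pulse_of(device, np.asarray(d["g1_minus_uS"], dtype=float))
        state.p2_plus = ltp_pulse_of(device, np.asarray(d["g2_plus_uS"], dtype=float))
        state.p2_minus = ltp_pulse_of(device, np.asarray(d["g2_minus_uS"], dtype=float))
    return state


@dataclass(frozen=True)
class AccuracyTrajectory:
    """Inference accuracy (%) recorded at increasing training steps."""

    steps: np.ndarray
    accuracy: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "steps", np.asarray(self.steps, dtype=int))
        object.__setattr__(self, "accuracy", np.asarray(self.accuracy, dtype=float))
        if len(self.steps) != len(self.accuracy):
            raise ValueError("steps and accuracy must align")
        if np.any(np.diff(self.steps) <= 0):
            raise ValueError("steps must be strictly increasing")
        if np.any((self.accuracy < 0) | (self.accuracy > 100)):
            raise ValueError("accuracies must be in [0, 100]")

    @property
    def final(self) -> float:
        return float(self.accuracy[-1])

    @property
    def peak(self) -> float:
        return float(self.accuracy.max())

    def to_tsv(self, path) -> None:
        df = pd.DataFrame({"step": self.steps, "accuracy_pct": self.accuracy})
        df["accuracy_pct"] = df["accuracy_pct"].map(lambda v: f"{v:.6g}")
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "AccuracyTrajectory":
        df = pd.read_csv(path, sep="\t")
        return cls(steps=df["step"].to_numpy(), accuracy=df["accuracy_pct"].to_numpy())


# ---------------------------------------------------------------------------
# initialization and forward pass


def _pair_for_weight(device: DeviceParams, w: np.ndarray):
    """Minimal-pulse differential-pair positions realizing weights ``w``.

    The member carrying the magnitude sits at the LTP position whose
    conductance offset equals |w|·span (rounded to an integer pulse); the
    other member rests at G_min (position 0).
    """
    target_g = device.g_min + np.abs(w) * device.span
    pos = np.rint(ltp_pulse_of(device, target_g)).astype(float)
    plus = np.where(w >= 0, pos, 0.0)
    minus = np.where(w >= 0, 0.0, pos)
    return plus, minus


def init_network(config: AnnConfig, device: DeviceParams, seed: int | None = None) -> AnnState:
    """Seeded network initialization, symmetric about zero weight.

    The input-side matrix starts small (uniform in ±``init_scale_input``)
    so that learned receptor-code structure quickly dominates; the
    output-side matrix starts over its full range (±``init_scale_output``)
    and acts as a rich, nearly fixed readout for the slow second-layer
    rate.  In device mode each weight is realized by its minimal-pulse
    differential pair, so achievable initial values are quantized to the
    pulse grid.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    w1 = rng.uniform(-config.init_scale_input, config.init_scale_input,
                     size=(config.n_input, config.n_hidden))
    w2 = rng.uniform(-config.init_scale_output, config.init_scale_output,
                     size=(config.n_hidden, config.n_output))
    state = AnnState(config=config, device=device, pulse_count=np.zeros(2, dtype=np.int64))
    if config.ideal:
        state.w1, state.w2 = w1, w2
    else:
        state.p1_plus, state.p1_minus = _pair_for_weight(device, w1)
        state.p2_plus, state.p2_minus = _pair_for_weight(device, w2)
    return state


def weight_of(g_plus, g_minus, device: DeviceParams):
    """Differential-pair weight ``(g_plus − g_minus) / (g_max − g_min)``."""
    g_plus = np.asarray(g_plus, dtype=float)
    g_minus = np.asarray(g_minus, dtype=float)
    tol = 1e-9 * device.span
    for g in (g_plus, g_minus):
        if np.any(g < device.g_min - tol) or np.any(g > device.g_max + tol):
            raise ValueError("conductance outside [g_min, g_max]")
    out = (g_plus - g_minus) / device.span
    return float(out) if out.ndim == 0 else out


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


def _as_input(state: AnnState, pattern) -> np.ndarray:
    """Flatten a pattern and apply the configured pixel encoding."""
    if hasattr(pattern, "grid"):
        x = pattern.flatten().astype(float)
    else:
        x = np.asarray(pattern, dtype=float).reshape(-1)
    if x.shape != (state.config.n_input,):
        raise ValueError(f"pattern width {x.shape} does not match n_input={state.config.n_input}")
    if state.config.input_encoding == "bipolar":
        x = 2.0 * x - 1.0
    return x


def forward(state: AnnState, pattern):
    """Single-pattern forward pass.

    Returns ``(hidden, output)`` sigmoid activations; the prediction is the
    arg-max of the output with ties broken toward the lowest class index.
    Accepts an :class:`OdorPattern` or a flat 0/1 vector.
    """
    x = _as_input(state, pattern)
    w1, w2 = state.weights()
    h = _sigmoid(x @ w1)
    y = _sigmoid(h @ w2)
    return h, y


def predict(state: AnnState, pattern) -> int:
    """Arg-max class index (lowest index wins ties)."""
    _, y = forward(state, pattern)
    return int(np.argmax(y))


def backprop_deltas(state: AnnState, x: np.ndarray, target: np.ndarray):
    """Desired weight changes for one (encoded) pattern, before quantization.

    The error is the cross-entropy residual ``y − t`` of the sigmoid
    outputs.  A pattern whose target output already leads its runner-up by
    ``update_margin`` is skipped entirely; output residuals inside
    ``error_deadzone`` are zeroed; the hidden delta back-propagates the
    surviving residuals through the output weights without
    sigmoid-derivative damping, preserving the gradient's sign.  Returns
    ``(delta_w1, delta_w2)`` scaled by the per-layer learning rates.
    """
    cfg = state.config
    w1, w2 = state.weights()
    h = _sigmoid(x @ w1)
    y = _sigmoid(h @ w2)
    k = int(np.argmax(target))
    others = np.delete(y, k)
    if others.size and y[k] - others.max() > cfg.update_margin:
        return np.zeros_like(w1), np.zeros_like(w2)
    d2 = y - target
    d2 = np.where(np.abs(d2) > cfg.error_deadzone, d2, 0.0)
    d1 = w2 @ d2
    delta_w2 = -cfg.lr_layer2 * np.outer(h, d2)
    delta_w1 = -cfg.lr_layer1 * np.outer(x, d1)
    return delta_w1, delta_w2


# ---------------------------------------------------------------------------
# device-constrained updates


def _apply_device_update(state, p_plus, p_minus, delta_w, rng, layer_idx):
    """Program one layer's pairs toward the desired weight changes.

    Positive changes potentiate G+, negative ones potentiate G−, by an
    integer pulse count matching the desired conductance change against the
    local LTP slope (stochastic rounding by default, capped per step).
    Saturating pairs are refreshed to the minimal-pulse configuration of
    their current weight.
    """
    device = state.device
    cfg = state.config
    delta_g = np.abs(delta_w) * device.span
    pos = np.where(delta_w >= 0, p_plus, p_minus)
    slope = ltp_slope(device, pos)
    n_f = np.where(delta_g > 0, delta_g / np.maximum(slope, 1e-300), 0.0)
    if cfg.quantization == "none":
        pulses = n_f
    elif cfg.quantization == "round":
        pulses = np.rint(n_f)
    else:
        base = np.floor(n_f)
        pulses = base + (rng.random(n_f.shape) < (n_f - base))
    if cfg.quantization != "none":
        pulses = np.minimum(pulses, MAX_PULSES_PER_STEP)
    new_pos = np.minimum(pos + pulses, float(device.p_max))
    applied = new_pos - pos
    np.copyto(p_plus, new_pos, where=delta_w >= 0)
    np.copyto(p_minus, new_pos, where=delta_w < 0)
    state.pulse_count[layer_idx] += int(np.ceil(applied).sum())

    # refresh saturated pairs: same weight, minimal pulse positions
    sat = (p_plus >= REFRESH_FRACTION * device.p_max) | (
        p_minus >= REFRESH_FRACTION * device.p_max
    )
    if np.any(sat):
        w = (g_ltp(device, p_plus[sat]) - g_ltp(device, p_minus[sat])) / device.span
        plus, minus = _pair_for_weight(device, w)
        p_plus[sat] = plus
        p_minus[sat] = minus


def train_step(state: AnnState, pattern, target, rng=None) -> AnnState:
    """One in-place stochastic-gradient training step on one pattern.

    ``target`` is the one-hot target vector (or a class index).  With zero
    output error the state is unchanged.  ``rng`` supplies the stochastic
    rounding draws; pass the training loop's generator for reproducibility.
    """
    cfg = state.config
    x = _as_input(state, pattern)
    if np.isscalar(target) or np.ndim(target) == 0:
        t = np.zeros(cfg.n_output)
        t[int(target)] = 1.0
    else:
        t = np.asarray(target, dtype=float)
    dw1, dw2 = backprop_deltas(state, x, t)
    if cfg.ideal:
        state.w1 += dw1
        state.w2 += dw2
        return state
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    _apply_device_update(state, state.p1_plus, state.p1_minus, dw1, rng, 0)
    _apply_device_update(state, state.p2_plus, state.p2_minus, dw2, rng, 1)
    return state


def evaluate(state: AnnState, dataset: PatternDataset) -> float:
    """Inference accuracy (%) = 100 · correct arg-max predictions / size."""
    X = dataset.inputs() if hasattr(dataset, "inputs") else np.asarray(dataset, dtype=float)
    labels = dataset.targets()
    if state.config.input_encoding == "bipolar":
        X = 2.0 * X - 1.0
    w1, w2 = state.weights()
    y = _sigmoid(_sigmoid(X @ w1) @ w2)
    pred = np.argmax(y, axis=1)
    return float(100.0 * np.mean(pred == labels))


def train(
    state: AnnState,
    train_set: PatternDataset,
    inference_set: PatternDataset,
    config: AnnConfig | None = None,
    seed: int | None = None,
) -> AccuracyTrajectory:
    """Train in place, recording inference accuracy every epoch.

    Each step consumes one training pattern sampled uniformly with
    replacement; accuracy on the inference set is recorded at step 0 (the
    untrained baseline) and every ``steps_per_epoch`` steps thereafter.
    Bit-reproducible for a fixed seed.
    """
    cfg = state.config if config is None else config
    if seed is None:
        seed = cfg.seed
    if len(train_set) == 0 or len(inference_set) == 0:
        raise ValueError("datasets must be non-empty")
    X = train_set.inputs()
    labels = train_set.targets()
    if X.shape[1] != cfg.n_input:
        raise ValueError(f"pattern width {X.shape[1]} does not match n_input={cfg.n_input}")
    targets = np.zeros((len(labels), cfg.n_output))
    targets[np.arange(len(labels)), labels] = 1.0

    rng = np.random.default_rng(seed)
    steps = [0]
    acc = [evaluate(state, inference_set)]
    for step in range(1, cfg.total_steps + 1):
        i = int(rng.integers(len(labels)))
        train_step(state, X[i], targets[i], rng=rng)
        if step % cfg.steps_per_epoch == 0:
            steps.append(step)
            acc.append(evaluate(state, inference_set))
    if steps[-1] != cfg.total_steps and cfg.total_steps > 0:
        steps.append(cfg.total_steps)
        acc.append(evaluate(state, inference_set))
    return AccuracyTrajectory(steps=np.array(steps), accuracy=np.array(acc))


def linearity_sweep(
    devices,
    train_set: PatternDataset,
    inference_set: PatternDataset,
    config: AnnConfig,
    seeds=(0,),
) -> pd.DataFrame:
    """Train identical networks that differ only in their device parameters.

    Returns one row per device with the per-seed final accuracies and
    their mean — the linearity-vs-recognition-accuracy comparison (a
    near-linear device should strictly outperform a strongly nonlinear
    one).
    """
    devices = list(devices)
    if len(devices) < 2:
        raise ValueError("need at least two device parameter sets to sweep")
    rows = []
    for d_idx, dev in enumerate(devices):
        finals = []
        for s in seeds:
            st = init_network(config, dev, seed=s)
            traj = train(st, train_set, inference_set, config, seed=s)
            finals.append(traj.final)
        rows.append(
            {
                "device_index": d_idx,
                "a_p": dev.a_p,
                "a_d": dev.a_d,
                "mean_final_accuracy_pct": float(np.mean(finals)),
                **{f"seed{s}_final_pct": f for s, f in zip(seeds, finals)},
            }
        )
    return pd.DataFrame(rows)
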