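"""The 1-D residual network for binary Raman-spectrum classification.

Architecture: a stem convolution lifts the single input channel to
``stem_channels``; then ``n_stages`` stages each apply one normal residual
block (length- and channel-preserving, identity shortcut) followed by one
downsample block (stride-2 first convolution, 1x1 stride-2 projection
shortcut, channel count stepping up a configurable doubling schedule capped
at ``channel_cap``).  Blocks are pre-activation: two
[BN -> ReLU -> dropout -> conv(kernel 3)] sets whose sum with the shortcut
forms the block output H(X) = F(X) + X.  After the last stage a final
BN -> ReLU feeds a dense layer with a single logit; the sigmoid of that
logit is the tumor probability.  With the default configuration a
(N, 1, 1024) batch reaches the head as a (N, 1024, 1) feature map.
"""

from __future__ import annotations

import io as _io
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .nn.layers import BatchNorm1d, Conv1d, Dropout, Linear, Module, ReLU, sigmoid

__all__ = ["ModelConfig", "BlockSpec", "ResNet1D", "build_model", "load_model"]


@dataclass
class ModelConfig:
    """Topology of the network; fully determines the parameter count.

    ``channel_schedule`` (per-stage output channels) defaults to doubling
    from the stem width up to ``channel_cap``.  ``input_length`` must equal
    ``2**n_stages * final_length`` with ``final_length >= 1``.
    """

    input_length: int = 1024
    stem_channels: int = 32
    n_stages: int = 10
    channel_schedule: Optional[Sequence[int]] = None
    kernel_size: int = 3
    dropout_rate: float = 0.1
    channel_cap: int = 1024
    seed: int = 0
    dtype: str = "float32"

    def resolved_schedule(self) -> list[int]:
        if self.channel_schedule is not None:
            return list(self.channel_schedule)
        sched = []
        c = self.stem_channels
        for _ in range(self.n_stages):
            c = min(2 * c, self.channel_cap)
            sched.append(c)
        return sched

    @property
    def final_length(self) -> int:
        return self.input_length // (2**self.n_stages)

    def validate(self) -> None:
        if self.input_length != (2**self.n_stages) * self.final_length or self.final_length < 1:
            raise ValueError(
                f"input_length {self.input_length} must be 2^{self.n_stages} * final_length "
                "with final_length >= 1"
            )
        if not (0 <= self.dropout_rate < 1):
            raise ValueError("dropout_rate must lie in [0, 1)")
        sched = self.resolved_schedule()
        if len(sched) != self.n_stages:
            raise ValueError("channel_schedule length must equal n_stages")
        prev = self.stem_channels
        for c in sched:
            if c < prev:
                raise ValueError(f"channel schedule may not shrink ({prev} -> {c})")
            prev = c

    def scaled_to(self, input_length: int) -> "ModelConfig":
        """Config for a shorter input: drop trailing stages so the terminal
        feature length is preserved (1024 -> 512 drops one stage)."""
        n_stages = self.n_stages
        while input_length % (2**n_stages) or input_length // (2**n_stages) < max(1, self.final_length):
            n_stages -= 1
            if n_stages == 0:
                break
        sched = self.resolved_schedule()[: n_stages]
        return ModelConfig(
            input_length=input_length,
            stem_channels=self.stem_channels,
            n_stages=n_stages,
            channel_schedule=sched,
            kernel_size=self.kernel_size,
            dropout_rate=self.dropout_rate,
            channel_cap=self.channel_cap,
            seed=self.seed,
            dtype=self.dtype,
        )

    @staticmethod
    def compact(input_length: int = 1024, stem_channels: int = 8,
                n_stages: int = 6, channel_cap: int = 32, seed: int = 0) -> "ModelConfig":
        """A narrow schedule of the same architecture family, sized for
        CPU-scale training experiments."""
        return ModelConfig(
            input_length=input_length,
            stem_channels=stem_channels,
            n_stages=n_stages,
            channel_cap=channel_cap,
            seed=seed,
        )


@dataclass(frozen=True)
class BlockSpec:
    """Shape contract of one residual block."""

    kind: str  # "normal" | "downsample"
    in_channels: int
    out_channels: int
    in_length: int

    @property
    def stride(self) -> int:
        return 2 if self.kind == "downsample" else 1

    @property
    def out_length(self) -> int:
        return self.in_length // self.stride


class _ResidualBlock:
    """Pre-activation residual block with two BN->ReLU->dropout->conv sets."""

    def __init__(self, spec: BlockSpec, kernel_size: int, dropout_rate: float,
                 rng: np.random.Generator, dtype) -> None:
        self.spec = spec
        pad = (kernel_size - 1) // 2
        cin, cout = spec.in_channels, spec.out_channels
        self.bn1 = BatchNorm1d(cin, dtype=dtype)
        self.relu1 = ReLU()
        self.drop1 = Dropout(dropout_rate)
        self.conv1 = Conv1d(cin, cout, kernel_size, stride=spec.stride, padding=pad,
                            rng=rng, dtype=dtype)
        self.bn2 = BatchNorm1d(cout, dtype=dtype)
        self.relu2 = ReLU()
        self.drop2 = Dropout(dropout_rate)
        self.conv2 = Conv1d(cout, cout, kernel_size, stride=1, padding=pad,
                            rng=rng, dtype=dtype)
        # zero-init of the residual branch's last convolution: every block
        # starts as the identity (or pure projection), which keeps deep
        # stacks stable early in training
        self.conv2.params["w"][:] = 0.0
        if spec.kind == "downsample":
            self.proj: Optional[Conv1d] = Conv1d(cin, cout, 1, stride=2, padding=0,
                                                 rng=rng, dtype=dtype)
        else:
            self.proj = None

    def modules(self) -> list[Module]:
        mods: list[Module] = [self.bn1, self.relu1, self.drop1, self.conv1,
                              self.bn2, self.relu2, self.drop2, self.conv2]
        if self.proj is not None:
            mods.append(self.proj)
        return mods

    def forward(self, x, training=False, rng=None):
        f = self.bn1.forward(x, training)
        f = self.relu1.forward(f, training)
        f = self.drop1.forward(f, training, rng)
        f = self.conv1.forward(f, training)
        f = self.bn2.forward(f, training)
        f = self.relu2.forward(f, training)
        f = self.drop2.forward(f, training, rng)
        f = self.conv2.forward(f, training)
        shortcut = x if self.proj is None else self.proj.forward(x, training)
        return f + shortcut

    def backward(self, dout):
        d = self.conv2.backward(dout)
        d = self.drop2.backward(d)
        d = self.relu2.backward(d)
        d = self.bn2.backward(d)
        d = self.conv1.backward(d)
        d = self.drop1.backward(d)
        d = self.relu1.backward(d)
        d = self.bn1.backward(d)
        if self.proj is None:
            return d + dout
        return d + self.proj.backward(dout)


class ResNet1D:
    """The assembled network.  ``forward_logits``/``predict_proba`` run the
    model; ``backward`` propagates a logit gradient and fills parameter
    gradients (used both by the optimizer and by Grad-CAM, which reads the
    recorded per-block activations and their gradients)."""

    def __init__(self, config: ModelConfig) -> None:
        config.validate()
        self.config = config
        self.history: dict[str, list[float]] = {}
        dtype = np.dtype(config.dtype).type
        rng = np.random.default_rng(config.seed)
        pad = (config.kernel_size - 1) // 2
        self.stem = Conv1d(1, config.stem_channels, config.kernel_size, 1, pad,
                           rng=rng, dtype=dtype)
        self.block_specs: list[BlockSpec] = []
        self.blocks: list[_ResidualBlock] = []
        c, length = config.stem_channels, config.input_length
        for c_out in config.resolved_schedule():
            for spec in (
                BlockSpec("normal", c, c, length),
                BlockSpec("downsample", c, c_out, length),
            ):
                self.blocks.append(
                    _ResidualBlock(spec, config.kernel_size, config.dropout_rate, rng, dtype)
                )
                self.block_specs.append(spec)
                length = spec.out_length
                c = spec.out_channels
        self.head_bn = BatchNorm1d(c, dtype=dtype)
        self.head_relu = ReLU()
        self.head = Linear(c * length, 1, rng=rng, dtype=dtype)
        self._flat_shape: Optional[tuple] = None
        self.block_outputs: Optional[list[np.ndarray]] = None
        self.block_output_grads: Optional[list[np.ndarray]] = None

    # -- plumbing ---------------------------------------------------------

    def modules(self) -> list[Module]:
        mods: list[Module] = [self.stem]
        for b in self.blocks:
            mods.extend(b.modules())
        mods.extend([self.head_bn, self.head_relu, self.head])
        return mods

    @property
    def n_parameters(self) -> int:
        return sum(p.size for m in self.modules() for p in m.params.values())

    def state_arrays(self) -> dict[str, np.ndarray]:
        out = {}
        for i, m in enumerate(self.modules()):
            for name, p in m.params.items():
                out[f"m{i}.{name}"] = p
            if isinstance(m, BatchNorm1d):
                out[f"m{i}.running_mean"] = m.running_mean
                out[f"m{i}.running_var"] = m.running_var
        return out

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        for i, m in enumerate(self.modules()):
            for name in m.params:
                m.params[name][...] = arrays[f"m{i}.{name}"]
            if isinstance(m, BatchNorm1d):
                m.running_mean[...] = arrays[f"m{i}.running_mean"]
                m.running_var[...] = arrays[f"m{i}.running_var"]

    def copy_state(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.state_arrays().items()}

    # -- computation ------------------------------------------------------

    def _check_batch(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=self.config.dtype)
        if x.ndim == 2:
            x = x[:, None, :]
        if x.ndim != 3 or x.shape[1] != 1 or x.shape[2] != self.config.input_length:
            raise ValueError(
                f"expected batch of shape (N, 1, {self.config.input_length}), got {x.shape}"
            )
        return x

    def forward_logits(self, x, training: bool = False,
                       rng: Optional[np.random.Generator] = None,
                       capture: bool = False) -> np.ndarray:
        x = self._check_batch(x)
        h = self.stem.forward(x, training)
        outputs = [] if capture else None
        for b in self.blocks:
            h = b.forward(h, training, rng)
            if capture:
                outputs.append(h)
        self.block_outputs = outputs
        h = self.head_bn.forward(h, training)
        h = self.head_relu.forward(h, training)
        self._flat_shape = h.shape
        logits = self.head.forward(h.reshape(h.shape[0], -1), training)
        return logits[:, 0]

    def backward(self, dlogits: np.ndarray, capture: bool = False) -> np.ndarray:
        d = self.head.backward(np.asarray(dlogits, dtype=self.config.dtype)[:, None])
        d = d.reshape(self._flat_shape)
        d = self.head_relu.backward(d)
        d = self.head_bn.backward(d)
        grads = [None] * len(self.blocks) if capture else None
        for i in range(len(self.blocks) - 1, -1, -1):
            if capture:
                grads[i] = d
            d = self.blocks[i].backward(d)
        self.block_output_grads = grads
        return self.stem.backward(d)

    def recalibrate_batchnorm(self, x, batch_size: int = 256) -> None:
        """Re-estimate BN running statistics on clean (dropout-free)
        activations.

        Dropout inflates activation variance during training, so running
        statistics collected then misrepresent evaluation-mode activations;
        the mismatch compounds across the many BN layers.  This pass runs
        the data through the network with batch-statistics normalization
        but dropout disabled, and replaces the running estimates with the
        average batch statistics.
        """
        x = np.asarray(x)
        bns = [m for m in self.modules() if isinstance(m, BatchNorm1d)]
        for bn in bns:
            bn.begin_stat_collection()
        for i in range(0, x.shape[0], batch_size):
            xb = x[i : i + batch_size]
            if xb.shape[0] < 2:
                continue
            self.forward_logits(xb, training="calibrate")
        for bn in bns:
            bn.end_stat_collection()

    def predict_proba(self, x, batch_size: int = 256) -> np.ndarray:
        """Evaluation-mode tumor probabilities, strictly inside (0, 1)."""
        x = np.asarray(x)
        out = np.empty(x.shape[0])
        for i in range(0, x.shape[0], batch_size):
            out[i : i + batch_size] = sigmoid(
                self.forward_logits(x[i : i + batch_size]).astype(float)
            )
        return np.clip(out, 1e-12, 1.0 - 1e-12)

    # -- presentation / persistence --------------------------------------

    def pre_head_shape(self, batch_size: int) -> tuple[int, int, int]:
        """(N, channels, length) of the feature map entering the head."""
        sched = self.config.resolved_schedule()
        return (batch_size, sched[-1], self.config.final_length)

    def describe(self) -> str:
        lines = [
            f"ResNet1D  input (N, 1, {self.config.input_length})  "
            f"params {self.n_parameters:,}",
            f"  stem     conv k{self.config.kernel_size}  1 -> {self.config.stem_channels}"
            f"  length {self.config.input_length}",
        ]
        for spec in self.block_specs:
            lines.append(
                f"  {spec.kind:<10} {spec.in_channels:>5} -> {spec.out_channels:<5}"
                f" length {spec.in_length} -> {spec.out_length}"
            )
        sched = self.config.resolved_schedule()
        lines.append(
            f"  head     BN -> ReLU -> dense ({sched[-1] * self.config.final_length} -> 1) -> sigmoid"
        )
        return "\n".join(lines)

    def save(self, path: str | Path) -> None:
        """Single-archive serialization: parameter arrays plus the config and
        training history as YAML metadata."""
        import yaml

        path = Path(path)
        buf = _io.BytesIO()
        np.savez_compressed(buf, **self.state_arrays())
        meta = {
            "config": {**self.config.__dict__,
                       "channel_schedule": self.config.resolved_schedule()},
            "history": {k: [float(v) for v in vs] for k, vs in self.history.items()},
        }
        with zipfile.ZipFile(path, "w") as z:
            z.writestr("arrays.npz", buf.getvalue())
            z.writestr("meta.yaml", yaml.safe_dump(meta))


def build_model(cfg: ModelConfig | None = None) -> ResNet1D:
    """Construct an initialized (untrained) network from ``cfg``."""
    return ResNet1D(cfg or ModelConfig())


def load_model(path: str | Path) -> ResNet1D:
    import yaml

    with zipfile.ZipFile(Path(path)) as z:
        meta = yaml.safe_load(z.read("meta.yaml"))
        with z.open("arrays.npz") as f:
            arrays = dict(np.load(_io.BytesIO(f.read())))
    model = ResNet1D(ModelConfig(**meta["config"]))
    model.load_state_arrays(arrays)
    model.history = meta["history"]
    return model
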