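"""3D residual networks for dual-channel patch classification.

The depth family mirrors the classic residual-network layouts generalised to
3D: an initial strided 3D convolution plus pooling, four residual stages
(basic blocks at depths 18/34, bottleneck blocks at 50/101/152 with the
standard block counts), global average pooling, and a 2-way softmax head.

The input patch is anisotropic — (50, 50, 20) voxels — so the first two
spatial reductions (stem conv and pool) act on all three axes while the later
stage downsamples act in-plane only, keeping at least two axial positions
ahead of the global pool.
"""

from __future__ import annotations

import numpy as np

from somafind.nn.layers import (
    AvgPool2x2x2,
    BatchNorm,
    Conv3D,
    Dense,
    GlobalAvgPool,
    Param,
    ReLU,
    softmax,
)

__all__ = ["ResNet3D", "RESNET_DEPTHS"]

RESNET_DEPTHS = (18, 34, 50, 101, 152)

_CONFIG = {
    18: ("basic", (2, 2, 2, 2)),
    34: ("basic", (3, 4, 6, 3)),
    50: ("bottleneck", (3, 4, 6, 3)),
    101: ("bottleneck", (3, 4, 23, 3)),
    152: ("bottleneck", (3, 8, 36, 3)),
}

# stage 1 keeps resolution; stage 2 halves all axes; stages 3-4 halve in-plane only
_STAGE_STRIDES = ((1, 1, 1), (2, 2, 2), (2, 2, 1), (2, 2, 1))


class _BasicBlock:
    expansion = 1

    def __init__(self, cin: int, width: int, stride, rng) -> None:
        cout = width * self.expansion
        self.conv1 = Conv3D(cin, width, 3, stride, rng)
        self.bn1 = BatchNorm(width)
        self.relu1 = ReLU()
        self.conv2 = Conv3D(width, cout, 3, 1, rng)
        self.bn2 = BatchNorm(cout)
        self.relu_out = ReLU()
        self.shortcut = None
        if stride != (1, 1, 1) or cin != cout:
            self.shortcut = (Conv3D(cin, cout, 1, stride, rng), BatchNorm(cout))

    def params(self) -> list[Param]:
        out = self.conv1.params() + self.bn1.params() + self.conv2.params() + self.bn2.params()
        if self.shortcut:
            out += self.shortcut[0].params() + self.shortcut[1].params()
        return out

    def batchnorms(self) -> list[BatchNorm]:
        out = [self.bn1, self.bn2]
        if self.shortcut:
            out.append(self.shortcut[1])
        return out

    def forward(self, x, train):
        out = self.relu1.forward(self.bn1.forward(self.conv1.forward(x, train), train), train)
        out = self.bn2.forward(self.conv2.forward(out, train), train)
        identity = x if self.shortcut is None else self.shortcut[1].forward(
            self.shortcut[0].forward(x, train), train
        )
        return self.relu_out.forward(out + identity, train)

    def backward(self, grad):
        grad = self.relu_out.backward(grad)
        g_main = self.conv1.backward(
            self.bn1.backward(self.relu1.backward(self.conv2.backward(self.bn2.backward(grad))))
        )
        if self.shortcut is None:
            g_identity = grad
        else:
            g_identity = self.shortcut[0].backward(self.shortcut[1].backward(grad))
        return g_main + g_identity


class _BottleneckBlock:
    expansion = 4

    def __init__(self, cin: int, width: int, stride, rng) -> None:
        cout = width * self.expansion
        self.conv1 = Conv3D(cin, width, 1, 1, rng)
        self.bn1 = BatchNorm(width)
        self.relu1 = ReLU()
        self.conv2 = Conv3D(width, width, 3, stride, rng)
        self.bn2 = BatchNorm(width)
        self.relu2 = ReLU()
        self.conv3 = Conv3D(width, cout, 1, 1, rng)
        self.bn3 = BatchNorm(cout)
        self.relu_out = ReLU()
        self.shortcut = None
        if stride != (1, 1, 1) or cin != cout:
            self.shortcut = (Conv3D(cin, cout, 1, stride, rng), BatchNorm(cout))

    def params(self) -> list[Param]:
        out = (
            self.conv1.params() + self.bn1.params()
            + self.conv2.params() + self.bn2.params()
            + self.conv3.params() + self.bn3.params()
        )
        if self.shortcut:
            out += self.shortcut[0].params() + self.shortcut[1].params()
        return out

    def batchnorms(self) -> list[BatchNorm]:
        out = [self.bn1, self.bn2, self.bn3]
        if self.shortcut:
            out.append(self.shortcut[1])
        return out

    def forward(self, x, train):
        out = self.relu1.forward(self.bn1.forward(self.conv1.forward(x, train), train), train)
        out = self.relu2.forward(self.bn2.forward(self.conv2.forward(out, train), train), train)
        out = self.bn3.forward(self.conv3.forward(out, train), train)
        identity = x if self.shortcut is None else self.shortcut[1].forward(
            self.shortcut[0].forward(x, train), train
        )
        return self.relu_out.forward(out + identity, train)

    def backward(self, grad):
        grad = self.relu_out.backward(grad)
        g = self.conv3.backward(self.bn3.backward(grad))
        g = self.conv2.backward(self.bn2.backward(self.relu2.backward(g)))
        g_main = self.conv1.backward(self.bn1.backward(self.relu1.backward(g)))
        if self.shortcut is None:
            g_identity = grad
        else:
            g_identity = self.shortcut[0].backward(self.shortcut[1].backward(grad))
        return g_main + g_identity


class ResNet3D:
    """A 3D residual classifier over (N, C, 50, 50, 20) patches."""

    def __init__(
        self,
        depth: int = 50,
        in_channels: int = 2,
        n_classes: int = 2,
        base_width: int = 16,
        seed: int = 0,
    ) -> None:
        if depth not in _CONFIG:
            raise ValueError(f"unsupported depth {depth}; choose from {RESNET_DEPTHS}")
        self.depth = depth
        self.in_channels = in_channels
        self.n_classes = n_classes
        self.base_width = base_width
        rng = np.random.default_rng(seed)

        kind, counts = _CONFIG[depth]
        block_cls = _BasicBlock if kind == "basic" else _BottleneckBlock

        self.stem_conv = Conv3D(in_channels, base_width, 3, (2, 2, 2), rng)
        self.stem_bn = BatchNorm(base_width)
        self.stem_relu = ReLU()
        self.pool = AvgPool2x2x2()

        self.blocks: list = []
        cin = base_width
        for stage, (n_blocks, stride) in enumerate(zip(counts, _STAGE_STRIDES)):
            width = base_width * (2**stage)
            for b in range(n_blocks):
                block = block_cls(cin, width, stride if b == 0 else (1, 1, 1), rng)
                self.blocks.append(block)
                cin = width * block_cls.expansion

        self.gap = GlobalAvgPool()
        self.head = Dense(cin, n_classes, rng)
        self.feature_channels = cin

    # ------------------------------------------------------------------ api
    def params(self) -> list[Param]:
        out = self.stem_conv.params() + self.stem_bn.params()
        for block in self.blocks:
            out += block.params()
        out += self.head.params()
        return out

    def _batchnorms(self) -> list[BatchNorm]:
        out = [self.stem_bn]
        for block in self.blocks:
            out += block.batchnorms()
        return out

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Logits for a batch; ``train=True`` uses batch statistics."""
        x = np.asarray(x, dtype=np.float32)
        out = self.stem_relu.forward(
            self.stem_bn.forward(self.stem_conv.forward(x, train), train), train
        )
        out = self.pool.forward(out, train)
        for block in self.blocks:
            out = block.forward(out, train)
        return self.head.forward(self.gap.forward(out, train), train)

    def backward(self, grad_logits: np.ndarray) -> None:
        g = self.gap.backward(self.head.backward(grad_logits))
        for block in reversed(self.blocks):
            g = block.backward(g)
        g = self.pool.backward(g)
        self.stem_conv.backward(self.stem_bn.backward(self.stem_relu.backward(g)))

    def predict_proba(self, x: np.ndarray, batch_size: int = 32) -> np.ndarray:
        """Per-class probabilities in inference mode (running BN statistics)."""
        chunks = [
            softmax(self.forward(x[i : i + batch_size], train=False))
            for i in range(0, len(x), batch_size)
        ]
        return np.concatenate(chunks, axis=0) if chunks else np.empty((0, self.n_classes))

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    # -------------------------------------------------------- serialization
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {f"param_{i}": p.value.copy() for i, p in enumerate(self.params())}
        for i, bn in enumerate(self._batchnorms()):
            state[f"bn_{i}_mean"] = bn.running_mean.copy()
            state[f"bn_{i}_var"] = bn.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.params()
        for i, p in enumerate(params):
            value = np.asarray(state[f"param_{i}"], dtype=np.float32)
            if value.shape != p.value.shape:
                raise ValueError(
                    f"weight shape mismatch for param_{i}: {value.shape} vs {p.value.shape}"
                )
            p.value = value
            p.grad = np.zeros_like(value)
        for i, bn in enumerate(self._batchnorms()):
            bn.running_mean = np.asarray(state[f"bn_{i}_mean"], dtype=np.float32)
            bn.running_var = np.asarray(state[f"bn_{i}_var"], dtype=np.float32)
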