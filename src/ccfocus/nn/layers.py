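"""Layers and residual backbones built on the autodiff engine."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, conv2d, matmul, relu, DTYPE


class Module:
    """Base class: parameter collection plus a train/eval mode flag."""

    def __init__(self):
        self.training = True

    def named_parameters(self, prefix: str = ""):
        for name, val in vars(self).items():
            if isinstance(val, Tensor) and val.requires_grad:
                yield f"{prefix}{name}", val
            elif isinstance(val, Module):
                yield from val.named_parameters(f"{prefix}{name}.")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{prefix}{name}.{i}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def train(self):
        self._set_mode(True)
        return self

    def eval(self):
        self._set_mode(False)
        return self

    def _set_mode(self, flag: bool):
        self.training = flag
        for val in vars(self).items():
            pass
        for val in vars(self).values():
            if isinstance(val, Module):
                val._set_mode(flag)
            elif isinstance(val, (list, tuple)):
                for item in val:
                    if isinstance(item, Module):
                        item._set_mode(flag)

    def state_dict(self):
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict):
        mine = dict(self.named_parameters())
        missing = set(mine) - set(state)
        if missing:
            raise KeyError(f"missing parameters in checkpoint: {sorted(missing)}")
        for name, p in mine.items():
            arr = np.asarray(state[name], dtype=DTYPE)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: {arr.shape} vs {p.data.shape}")
            p.data = arr


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(DTYPE)


class Conv2d(Module):
    def __init__(self, rng, in_ch, out_ch, kernel=3, stride=1, pad=None, bias=True):
        super().__init__()
        if pad is None:
            pad = kernel // 2
        self.stride, self.pad = stride, pad
        fan_in = in_ch * kernel * kernel
        self.weight = Tensor(_he_init(rng, (out_ch, in_ch, kernel, kernel), fan_in),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch, dtype=DTYPE), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride, pad=self.pad)


class Linear(Module):
    def __init__(self, rng, in_features, out_features):
        super().__init__()
        self.weight = Tensor(_he_init(rng, (in_features, out_features), in_features),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_features, dtype=DTYPE), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return matmul(x, self.weight) + self.bias


class Dropout(Module):
    """Inverted dropout; a no-op in eval mode. Randomness comes from the rng
    handed in at call time so training is reproducible end to end."""

    def __init__(self, rate: float):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def __call__(self, x: Tensor, rng: np.random.Generator | None = None) -> Tensor:
        if not self.training or self.rate == 0.0:
            return x
        if rng is None:
            raise ValueError("Dropout in train mode needs an rng")
        mask = (rng.random(x.data.shape) >= self.rate) / (1.0 - self.rate)
        return x * mask.astype(DTYPE)


class BasicBlock(Module):
    """Two 3x3 convs with an identity (or 1x1 projected) skip connection."""

    def __init__(self, rng, in_ch, out_ch, stride=1):
        super().__init__()
        self.conv1 = Conv2d(rng, in_ch, out_ch, 3, stride=stride)
        self.conv2 = Conv2d(rng, out_ch, out_ch, 3, stride=1)
        self.proj = None
        if stride != 1 or in_ch != out_ch:
            self.proj = Conv2d(rng, in_ch, out_ch, 1, stride=stride, pad=0)

    def __call__(self, x: Tensor) -> Tensor:
        h = relu(self.conv1(x))
        h = self.conv2(h)
        skip = self.proj(x) if self.proj is not None else x
        return relu(h + skip)


class ResidualBackbone(Module):
    """A stack of residual stages whose per-stage outputs are exposed so a
    cross-view interaction module can be inserted mid-network.

    stage_widths/stage_blocks define the architecture; stage k downsamples
    by 2 at entry (except stage 1 when the stem already downsampled enough).
    """

    def __init__(self, rng, in_ch=1, stem_width=16, stem_stride=2,
                 stage_widths=(16, 32), stage_blocks=(1, 1)):
        super().__init__()
        self.stem = Conv2d(rng, in_ch, stem_width, 3, stride=stem_stride)
        self.stages = []
        ch = stem_width
        for si, (width, nblocks) in enumerate(zip(stage_widths, stage_blocks)):
            blocks = []
            for bi in range(nblocks):
                stride = 2 if (bi == 0 and si > 0) else 1
                blocks.append(BasicBlock(rng, ch, width, stride=stride))
                ch = width
            self.stages.append(blocks)
        self.out_channels = ch
        self.n_stages = len(self.stages)

    def forward_stem(self, x: Tensor) -> Tensor:
        return relu(self.stem(x))

    def forward_stage(self, h: Tensor, stage_index: int) -> Tensor:
        for block in self.stages[stage_index - 1]:  # stages are 1-based
            h = block(h)
        return h
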