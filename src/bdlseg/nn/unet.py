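"""A 3D U-Net in the encoder/decoder style used for brain-tumor segmentation.

The architecture follows the residual-free reading of the Isensee-lineage
network: a context (encoder) pathway whose filter count doubles at each of
``depth`` resolution levels, stride-2 convolutions for downsampling, and a
localization (decoder) pathway built from nearest-neighbor upsampling, a
channel-halving convolution, skip concatenation and a 3x3x3 + 1x1x1
localization module. Every convolution is followed by instance normalization
and a leaky ReLU; the single-channel output head is a 1x1x1 convolution with
a sigmoid, producing a per-voxel foreground probability.
"""

from __future__ import annotations

import numpy as np

from .layers import Conv3d, InstanceNorm3d, LeakyReLU, Sigmoid, Upsample2x


class _ConvBlock:
    """Conv -> InstanceNorm -> LeakyReLU."""

    def __init__(self, cin, cout, k, stride, rng, slope, dtype):
        self.conv = Conv3d(cin, cout, k=k, stride=stride, rng=rng,
                           leaky_slope=slope, dtype=dtype)
        self.norm = InstanceNorm3d(cout, dtype=dtype)
        self.act = LeakyReLU(slope)

    @property
    def n_params(self):
        return self.conv.n_params + self.norm.n_params

    def params(self):
        return self.conv.params() + self.norm.params()

    def forward(self, x):
        return self.act.forward(self.norm.forward(self.conv.forward(x)))

    def backward(self, dy):
        return self.conv.backward(self.norm.backward(self.act.backward(dy)))


class UNet3D:
    """Single-sample 3D U-Net mapping ``(in_channels, S, S, S)`` to ``(S, S, S)``.

    Parameters
    ----------
    in_channels : number of input modalities (4 for T1/T1CE/T2/FLAIR).
    base_filters : filters at the top resolution level; level ``l`` uses
        ``base_filters * 2**l``.
    depth : number of resolution levels; the input edge must be divisible by
        ``2**(depth - 1)``.
    leaky_slope : negative slope of every leaky ReLU.
    seed : initialization seed (weights are reproducible given the seed).
    """

    def __init__(
        self,
        in_channels: int = 4,
        base_filters: int = 8,
        depth: int = 3,
        leaky_slope: float = 0.01,
        seed: int = 0,
        dtype=np.float32,
    ) -> None:
        if depth < 2:
            raise ValueError("depth must be >= 2")
        self.in_channels = in_channels
        self.base_filters = base_filters
        self.depth = depth
        self.leaky_slope = leaky_slope
        self.seed = seed
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        f = [base_filters * 2**l for l in range(depth)]
        mk = lambda cin, cout, k=3, s=1: _ConvBlock(
            cin, cout, k, s, rng, leaky_slope, dtype
        )

        # encoder: level 0 has no downsampling block
        self.down = [None] + [mk(f[l - 1], f[l], s=2) for l in range(1, depth)]
        self.enc_a = [mk(in_channels if l == 0 else f[l], f[l]) for l in range(depth)]
        self.enc_b = [mk(f[l], f[l]) for l in range(depth)]

        # decoder: levels depth-2 .. 0
        self.ups = [Upsample2x() for _ in range(depth - 1)]
        self.up_conv = [mk(f[l + 1], f[l]) for l in range(depth - 1)]
        self.loc_a = [mk(2 * f[l], f[l]) for l in range(depth - 1)]
        self.loc_b = [mk(f[l], f[l], k=1) for l in range(depth - 1)]

        self.head = Conv3d(f[0], 1, k=1, rng=rng, leaky_slope=leaky_slope,
                           dtype=dtype)
        # background-prior initialization: start the sigmoid near 0 so the
        # net does not waste epochs suppressing the (dominant) background
        self.head.b[:] = -4.0
        self.out_act = Sigmoid()

    # -- parameter plumbing ------------------------------------------------
    def _blocks(self):
        for l in range(self.depth):
            if self.down[l] is not None:
                yield f"down{l}", self.down[l]
            yield f"enc{l}a", self.enc_a[l]
            yield f"enc{l}b", self.enc_b[l]
        for l in range(self.depth - 1):
            yield f"up{l}", self.up_conv[l]
            yield f"loc{l}a", self.loc_a[l]
            yield f"loc{l}b", self.loc_b[l]
        yield "head", self.head

    def parameters(self):
        """Flat list of (name, value, grad) triples over all learnable arrays."""
        out = []
        for bname, block in self._blocks():
            for pname, val, grad in block.params():
                out.append((f"{bname}.{pname}", val, grad))
        return out

    @property
    def n_params(self) -> int:
        return sum(v.size for _, v, _ in self.parameters())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: val.copy() for name, val, _ in self.parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = {name: val for name, val, _ in self.parameters()}
        if set(own) != set(state):
            raise ValueError("state dict keys do not match this architecture")
        for name, val in own.items():
            if val.shape != state[name].shape:
                raise ValueError(
                    f"shape mismatch for {name}: {val.shape} vs {state[name].shape}"
                )
            val[...] = state[name]

    # -- forward / backward ------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=self.dtype)
        if x.ndim != 4 or x.shape[0] != self.in_channels:
            raise ValueError(
                f"expected ({self.in_channels}, S, S, S) input, got {x.shape}"
            )
        s = x.shape[1]
        if s % 2 ** (self.depth - 1) != 0:
            raise ValueError(
                f"input edge {s} not divisible by 2^{self.depth - 1}"
            )
        skips = []
        h = x
        for l in range(self.depth):
            if self.down[l] is not None:
                h = self.down[l].forward(h)
            h = self.enc_b[l].forward(self.enc_a[l].forward(h))
            skips.append(h)
        for i, l in enumerate(range(self.depth - 2, -1, -1)):
            h = self.ups[i].forward(h)
            h = self.up_conv[l].forward(h)
            h = np.concatenate([skips[l], h], axis=0)
            h = self.loc_b[l].forward(self.loc_a[l].forward(h))
        logits = self.head.forward(h)
        return self.out_act.forward(logits)[0]

    def backward(self, dprob: np.ndarray) -> None:
        """Backpropagate d(loss)/d(probability map); fills every ``grad`` array."""
        f = [self.base_filters * 2**l for l in range(self.depth)]
        dy = self.out_act.backward(dprob[None])
        dy = self.head.backward(dy)
        dskips: dict[int, np.ndarray] = {}
        for i, l in enumerate(range(0, self.depth - 1)):
            # reverse of decoder iteration order (decoder went depth-2 .. 0)
            dy = self.loc_a[l].backward(self.loc_b[l].backward(dy))
            dskips[l] = dy[: f[l]]
            dy = self.up_conv[l].backward(dy[f[l] :])
            dy = self.ups[self.depth - 2 - l].backward(dy)
        for l in range(self.depth - 1, -1, -1):
            if l in dskips:
                dy = dy + dskips[l]
            dy = self.enc_a[l].backward(self.enc_b[l].backward(dy))
            if self.down[l] is not None:
                dy = self.down[l].backward(dy)


class Adam:
    """Adam optimizer over a model's ``parameters()`` triples."""

    def __init__(self, model: UNet3D, lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.model = model
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {n: np.zeros_like(v) for n, v, _ in model.parameters()}
        self.v = {n: np.zeros_like(v) for n, v, _ in model.parameters()}

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for name, val, grad in self.model.parameters():
            m = self.m[name]
            v = self.v[name]
            m *= self.b1
            m += (1.0 - self.b1) * grad
            v *= self.b2
            v += (1.0 - self.b2) * grad**2
            val -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self) -> None:
        for _, _, grad in self.model.parameters():
            grad[...] = 0.0
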