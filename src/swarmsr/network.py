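"""A small FSRCNN-style super-resolution CNN in pure NumPy.

The architecture follows the fast-SR lineage: feature extraction (5×5),
shrinking (1×1), ``m`` mapping layers (3×3), expanding (1×1), and a strided
transposed convolution (9×9) that maps LR input directly to HR output at
the configured integer scale.  Activations are parametric rectifiers
(PReLU) whose slopes are trained parameters.

Everything is float64 with analytic gradients (im2col convolution;
transposed convolution via zero-dilation reduced to a regular convolution),
so the network can be trained by plain SGD on the MSE cost and checked
against central finite differences.  A flat parameter vector with a fixed
layout bridges the network to particle-swarm search space: round-trips
through ``flatten``/``unflatten`` are exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NetworkSpec",
    "ParameterVector",
    "PAPER_PRESET",
    "DESK_PRESET",
    "SRNetwork",
    "parameter_count",
    "build_network",
    "mse_cost",
    "mse_cost_grad",
    "sgd_step",
    "flatten",
    "unflatten",
    "super_resolve",
]


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture hyperparameters; parameter count is a pure function of it."""

    scale_factor: int = 2
    d: int = 16   # feature-extraction filters
    s: int = 4    # shrink filters
    m: int = 1    # mapping layers
    k_feature: int = 5
    k_map: int = 3
    k_deconv: int = 9
    activation: str = "prelu"

    def __post_init__(self):
        if self.scale_factor not in (2, 3, 4):
            raise ValueError("scale_factor must be 2, 3, or 4")
        if min(self.d, self.s, self.m) < 1:
            raise ValueError("d, s, m must be positive")


#: hyperparameters of the full-size model from the fast-SR lineage
PAPER_PRESET = NetworkSpec(d=56, s=12, m=4)
#: small preset keeping the particle dimension tractable for swarm search
DESK_PRESET = NetworkSpec(d=16, s=4, m=1)

#: (pad, output_pad) of the 9×9 deconvolution so output = scale × input
_DECONV_GEOM = {2: (4, 1), 3: (3, 0), 4: (3, 1)}


@dataclass(frozen=True)
class ParameterVector:
    """Flat view of every weight/bias with its ordered layout manifest."""

    values: np.ndarray
    layout: tuple  # ((layer_idx, name, shape), ...)


# ---------------------------------------------------------------------------
# layer primitives
# ---------------------------------------------------------------------------

def _im2col(xp: np.ndarray, k: int):
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    b, c, ho, wo = win.shape[:4]
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(b, ho * wo, c * k * k)
    return np.ascontiguousarray(cols), ho, wo


def _col2im(gcols: np.ndarray, shape, k: int, ho: int, wo: int):
    b, c, hp, wp = shape
    gwin = gcols.reshape(b, ho, wo, c, k, k)
    gxp = np.zeros(shape)
    for i in range(k):
        for j in range(k):
            gxp[:, :, i:i + ho, j:j + wo] += \
                gwin[:, :, :, :, i, j].transpose(0, 3, 1, 2)
    return gxp


class _Conv:
    """Stride-1 2-D convolution (cross-correlation) with symmetric padding."""

    def __init__(self, in_c, out_c, k, pad, rng):
        fan_in = in_c * k * k
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (out_c, in_c, k, k))
        self.b = np.zeros(out_c)
        self.k, self.pad, self.fan_in = k, pad, fan_in
        self.params = {"w": self.w, "b": self.b}

    def _wmat(self):
        return self.w.reshape(self.w.shape[0], -1)

    def forward(self, x):
        p = self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        self._cols, ho, wo = _im2col(xp, self.k)
        self._xp_shape = xp.shape
        y = self._cols @ self._wmat().T + self.b
        return y.transpose(0, 2, 1).reshape(x.shape[0], -1, ho, wo)

    def backward(self, gy):
        b, o, ho, wo = gy.shape
        g = gy.reshape(b, o, ho * wo).transpose(0, 2, 1)
        self.grads = {
            "w": np.einsum("bno,bnc->oc", g, self._cols).reshape(self.w.shape),
            "b": gy.sum(axis=(0, 2, 3))}
        gxp = _col2im(g @ self._wmat(), self._xp_shape, self.k, ho, wo)
        p = self.pad
        return gxp[:, :, p:gxp.shape[2] - p, p:gxp.shape[3] - p] if p else gxp


class _PReLU:
    """Per-channel parametric rectifier, slope a trained (init 0.25)."""

    def __init__(self, channels):
        self.a = np.full(channels, 0.25)
        self.params = {"a": self.a}
        self.fan_in = channels

    def forward(self, x):
        self._x = x
        a = self.a[:, None, None]
        return np.where(x > 0, x, a * x)

    def backward(self, gy):
        x = self._x
        neg = np.minimum(x, 0.0)
        self.grads = {"a": (gy * neg).sum(axis=(0, 2, 3))}
        return gy * np.where(x > 0, 1.0, self.a[:, None, None])


class _ConvTranspose:
    """Strided transposed convolution via zero-dilation + regular convolution.

    Geometry is fixed so the output is exactly ``stride ×`` the input size.
    """

    def __init__(self, in_c, out_c, k, stride, pad, out_pad, rng):
        fan_in = in_c * k * k
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (in_c, out_c, k, k))
        self.b = np.zeros(out_c)
        self.k, self.stride, self.pad, self.out_pad = k, stride, pad, out_pad
        self.fan_in = fan_in
        self.params = {"w": self.w, "b": self.b}

    def forward(self, x):
        # scatter form: each input pixel deposits a stride-offset copy of the
        # kernel; equivalent to zero-dilation + convolution but without the
        # large column matrix
        s, k = self.stride, self.k
        b, c, h, w = x.shape
        o = self.w.shape[1]
        self._x = x
        core = np.einsum("bchw,coij->bohwij", x, self.w)
        full_h = s * (h - 1) + k
        full_w = s * (w - 1) + k
        yfull = np.zeros((b, o, full_h, full_w))
        for i in range(k):
            for j in range(k):
                yfull[:, :, i:i + s * (h - 1) + 1:s,
                      j:j + s * (w - 1) + 1:s] += core[..., i, j]
        p = self.pad
        out_h = s * (h - 1) + k - 2 * p + self.out_pad
        out_w = s * (w - 1) + k - 2 * p + self.out_pad
        y = yfull[:, :, p:p + out_h, p:p + out_w]
        return y + self.b[:, None, None]

    def backward(self, gy):
        s, k, p = self.stride, self.k, self.pad
        x = self._x
        b, c, h, w = x.shape
        full_h = s * (h - 1) + k
        full_w = s * (w - 1) + k
        gfull = np.zeros((b, gy.shape[1], full_h, full_w))
        gfull[:, :, p:p + gy.shape[2], p:p + gy.shape[3]] = gy
        # gather the stride-offset windows back per kernel tap
        gcore = np.empty((b, gy.shape[1], h, w, k, k))
        for i in range(k):
            for j in range(k):
                gcore[..., i, j] = gfull[:, :, i:i + s * (h - 1) + 1:s,
                                         j:j + s * (w - 1) + 1:s]
        self.grads = {
            "w": np.einsum("bchw,bohwij->coij", x, gcore),
            "b": gy.sum(axis=(0, 2, 3))}
        return np.einsum("bohwij,coij->bchw", gcore, self.w)


# ---------------------------------------------------------------------------
# network
# ---------------------------------------------------------------------------

class SRNetwork:
    """Layer stack with deterministic initialization and a flat-vector bridge."""

    def __init__(self, spec: NetworkSpec, init_seed: int = 0):
        rng = np.random.default_rng(init_seed)
        d, s = spec.d, spec.s
        pad, out_pad = _DECONV_GEOM[spec.scale_factor]
        layers = [_Conv(1, d, spec.k_feature, spec.k_feature // 2, rng),
                  _PReLU(d),
                  _Conv(d, s, 1, 0, rng), _PReLU(s)]
        for _ in range(spec.m):
            layers += [_Conv(s, s, spec.k_map, spec.k_map // 2, rng),
                       _PReLU(s)]
        layers += [_Conv(s, d, 1, 0, rng), _PReLU(d),
                   _ConvTranspose(d, 1, spec.k_deconv, spec.scale_factor,
                                  pad, out_pad, rng)]
        self.spec = spec
        self.layers = layers
        self.layout = tuple((i, name, layer.params[name].shape)
                            for i, layer in enumerate(layers)
                            for name in sorted(layer.params))

    @property
    def n_parameters(self) -> int:
        return sum(int(np.prod(shape)) for _, _, shape in self.layout)

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Map an LR stack (B, 1, h, w) to an HR stack (B, 1, s·h, s·w)."""
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, gy: np.ndarray) -> None:
        for layer in reversed(self.layers):
            gy = layer.backward(gy)

    def gradient_vector(self) -> np.ndarray:
        return np.concatenate([self.layers[i].grads[name].ravel()
                               for i, name, _ in self.layout])

    def search_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-parameter swarm-search interval, ±3·√(2/fan_in) per layer.

        Three standard deviations of the He-normal initialization, so the
        box contains essentially all the mass of the distribution the
        network is initialized (and trainable) in.  Rectifier slopes get
        [0, 0.5] — the meaningful leaky-slope range around their 0.25
        initialization.
        """
        lower, upper = [], []
        for i, name, shape in self.layout:
            n = int(np.prod(shape))
            if name == "a":
                lower.append(np.zeros(n))
                upper.append(np.full(n, 0.5))
            else:
                r = 3.0 * np.sqrt(2.0 / self.layers[i].fan_in)
                lower.append(np.full(n, -r))
                upper.append(np.full(n, r))
        return np.concatenate(lower), np.concatenate(upper)


def parameter_count(spec: NetworkSpec) -> int:
    return SRNetwork(spec, init_seed=0).n_parameters


def build_network(spec: NetworkSpec, init_seed: int = 0) -> SRNetwork:
    """Deterministically initialized network (He-normal weights, zero biases)."""
    return SRNetwork(spec, init_seed)


def flatten(net: SRNetwork) -> ParameterVector:
    values = np.concatenate([net.layers[i].params[name].ravel()
                             for i, name, _ in net.layout])
    return ParameterVector(values=values, layout=net.layout)


def unflatten(net: SRNetwork, vector) -> SRNetwork:
    """Write a flat vector back into the network parameters (exact inverse)."""
    values = vector.values if isinstance(vector, ParameterVector) \
        else np.asarray(vector, dtype=float)
    if values.size != net.n_parameters:
        raise ValueError(
            f"vector length {values.size} != {net.n_parameters} parameters")
    pos = 0
    for i, name, shape in net.layout:
        n = int(np.prod(shape))
        net.layers[i].params[name][...] = values[pos:pos + n].reshape(shape)
        pos += n
    return net


def mse_cost(net: SRNetwork, batch) -> float:
    """J(θ) = (1/n) Σᵢ ‖F(Yᵢ;θ) − Xᵢ‖² — per-sample summed squared error."""
    out = net.forward(batch.lr)
    if out.shape != batch.hr.shape:
        raise ValueError(f"output {out.shape} vs target {batch.hr.shape}")
    n = out.shape[0]
    return float(np.sum((out - batch.hr) ** 2) / n)


def mse_cost_grad(net: SRNetwork, batch) -> tuple[float, np.ndarray]:
    """Cost and its analytic gradient as a flat vector in layout order."""
    out = net.forward(batch.lr)
    if out.shape != batch.hr.shape:
        raise ValueError(f"output {out.shape} vs target {batch.hr.shape}")
    n = out.shape[0]
    diff = out - batch.hr
    net.backward(2.0 * diff / n)
    return float(np.sum(diff ** 2) / n), net.gradient_vector()


def sgd_step(net: SRNetwork, batch, alpha: float) -> float:
    """One gradient-descent update θ ← θ − α ∂J/∂θ; returns pre-step J."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    cost, grad = mse_cost_grad(net, batch)
    vec = flatten(net)
    unflatten(net, vec.values - alpha * grad)
    return cost


def super_resolve(net: SRNetwork, lr_image: np.ndarray) -> np.ndarray:
    """Run the fully-convolutional network on a whole 2-D LR image."""
    out = net.forward(np.asarray(lr_image, dtype=float)[None, None])
    return out[0, 0]
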