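"""Shifted/rotated multimodal benchmark functions in the CEC 2013 style.

Each instance is a classic multimodal base function (Rosenbrock, Ackley,
Griewank, Rastrigin, or the expanded Griewank-plus-Rosenbrock hybrid)
composed with a seeded shift of the optimum, an optional random rotation,
and an additive bias equal to the function value at the optimum.  Bounds
follow the suite convention of [-100, 100] per dimension, with the base
function's native domain reached through a fixed linear rescaling.

Instances are self-generated from a seed rather than loaded from the
official data files: shift vectors are drawn uniformly within 80% of the
bound range and rotations are random orthogonal matrices obtained by QR
decomposition of a Gaussian matrix.  Official instance data, when
available as whitespace-separated text matrices, can be supplied through
:func:`load_instance_data`.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ObjectiveInstance",
    "RunStatistics",
    "FUNCTION_BIASES",
    "make_instance",
    "evaluate",
    "summarize_runs",
    "load_instance_data",
]

# Optima of F6..F20: an arithmetic progression by 100 skipping zero.
FUNCTION_BIASES: dict[str, float] = {
    f"F{i + 6}": float(v)
    for i, v in enumerate(list(range(-900, 0, 100)) + list(range(100, 700, 100)))
}

#: function id -> (base callable name, rotated?, domain rescale, shift of +1 in z-space)
_REGISTRY: dict[str, dict] = {
    "F6": {"base": "rosenbrock", "rotated": True, "rescale": 2.048 / 100, "z_offset": 1.0},
    "F8": {"base": "ackley", "rotated": True, "rescale": 1.0, "z_offset": 0.0},
    "F10": {"base": "griewank", "rotated": True, "rescale": 600 / 100, "z_offset": 0.0,
            "conditioning": 100.0},
    "F11": {"base": "rastrigin", "rotated": False, "rescale": 5.12 / 100, "z_offset": 0.0},
    "F12": {"base": "rastrigin", "rotated": True, "rescale": 5.12 / 100, "z_offset": 0.0},
    "F19": {"base": "griewank_rosenbrock", "rotated": True, "rescale": 5 / 100,
            "z_offset": 1.0},
}


@dataclass(frozen=True)
class ObjectiveInstance:
    """A fully specified benchmark instance with a known optimum.

    ``evaluate(instance, shift_vector)`` equals ``bias`` for every
    registered function, since each base function attains its minimum at
    the point that the shift/rotation pipeline maps the shift vector to.
    """

    function_id: str
    dimension: int
    lower: np.ndarray
    upper: np.ndarray
    shift_vector: np.ndarray
    rotation: np.ndarray
    bias: float
    instance_seed: int
    conditioning: np.ndarray | None = field(default=None, repr=False)

    def __call__(self, x: np.ndarray) -> np.ndarray | float:
        return evaluate(self, x)


@dataclass(frozen=True)
class RunStatistics:
    """Summary of independent-run final objective values."""

    best: float
    worst: float
    mean: float
    std: float
    mae: float
    n_runs: int


# ---------------------------------------------------------------------------
# base functions (minimum 0 at z = 0, except Rosenbrock-style at z = 1)
# ---------------------------------------------------------------------------

def _rosenbrock(z: np.ndarray) -> np.ndarray:
    # minimum 0 at z = 1 (instances add +1 in z-space so the shift maps there)
    return np.sum(100.0 * (z[:, :-1] ** 2 - z[:, 1:]) ** 2
                  + (z[:, :-1] - 1.0) ** 2, axis=1)


def _ackley(z: np.ndarray) -> np.ndarray:
    d = z.shape[1]
    rms = np.sqrt(np.sum(z ** 2, axis=1) / d)
    return (-20.0 * np.exp(-0.2 * rms)
            - np.exp(np.sum(np.cos(2.0 * np.pi * z), axis=1) / d)
            + 20.0 + np.e)


def _griewank(z: np.ndarray) -> np.ndarray:
    d = z.shape[1]
    idx = np.sqrt(np.arange(1, d + 1))
    return (np.sum(z ** 2, axis=1) / 4000.0
            - np.prod(np.cos(z / idx), axis=1) + 1.0)


def _rastrigin(z: np.ndarray) -> np.ndarray:
    return np.sum(z ** 2 - 10.0 * np.cos(2.0 * np.pi * z) + 10.0, axis=1)


def _griewank_rosenbrock(z: np.ndarray) -> np.ndarray:
    # expanded hybrid: 1-D Griewank applied to consecutive Rosenbrock pairs,
    # wrapped cyclically; minimum 0 at z = 1
    z_next = np.roll(z, -1, axis=1)
    r = 100.0 * (z ** 2 - z_next) ** 2 + (z - 1.0) ** 2
    return np.sum(r ** 2 / 4000.0 - np.cos(r) + 1.0, axis=1)


_BASES = {
    "rosenbrock": _rosenbrock,
    "ackley": _ackley,
    "griewank": _griewank,
    "rastrigin": _rastrigin,
    "griewank_rosenbrock": _griewank_rosenbrock,
}


def base_function(name: str, z: np.ndarray) -> np.ndarray:
    """Evaluate a base function (bias-free, untransformed) on rows of ``z``."""
    z = np.atleast_2d(np.asarray(z, dtype=float))
    return _BASES[name](z)


# ---------------------------------------------------------------------------
# instance generation
# ---------------------------------------------------------------------------

def _random_rotation(dim: int, rng: np.random.Generator) -> np.ndarray:
    q, r = np.linalg.qr(rng.standard_normal((dim, dim)))
    # fix signs so the decomposition is unique and Q is uniformly distributed
    return q * np.sign(np.diag(r))


def make_instance(function_id: str, dimension: int,
                  instance_seed: int = 0) -> ObjectiveInstance:
    """Build a seeded benchmark instance.

    The same ``(function_id, dimension, instance_seed)`` triple always
    produces an identical instance.  Raises ``KeyError`` for ids outside
    the registry, listing the supported ones.
    """
    if function_id not in _REGISTRY:
        raise KeyError(
            f"unknown function id {function_id!r}; "
            f"supported: {sorted(_REGISTRY)}")
    if dimension < 2:
        raise ValueError("dimension must be >= 2")
    entry = _REGISTRY[function_id]
    rng = np.random.default_rng([zlib.crc32(function_id.encode()),
                                 dimension, instance_seed])
    lower = np.full(dimension, -100.0)
    upper = np.full(dimension, 100.0)
    shift = rng.uniform(0.8 * lower, 0.8 * upper)
    if entry["rotated"]:
        rotation = _random_rotation(dimension, rng)
    else:
        rotation = np.eye(dimension)
    cond = None
    if "conditioning" in entry:
        alpha = entry["conditioning"]
        cond = alpha ** (np.arange(dimension) / (2.0 * (dimension - 1)))
    return ObjectiveInstance(
        function_id=function_id, dimension=dimension,
        lower=lower, upper=upper, shift_vector=shift, rotation=rotation,
        bias=FUNCTION_BIASES[function_id], instance_seed=instance_seed,
        conditioning=cond)


def evaluate(instance: ObjectiveInstance, x: np.ndarray) -> np.ndarray | float:
    """Evaluate an instance at one point ``(D,)`` or a batch ``(n, D)``.

    The pipeline is ``z = Λ · R · (rescale · (x − o)) + z_offset`` followed
    by the base function and the additive bias.
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    x2 = np.atleast_2d(x)
    if x2.shape[1] != instance.dimension:
        raise ValueError(
            f"expected dimension {instance.dimension}, got {x2.shape[1]}")
    entry = _REGISTRY[instance.function_id]
    z = entry["rescale"] * (x2 - instance.shift_vector)
    if entry["rotated"]:
        z = z @ instance.rotation.T
    if instance.conditioning is not None:
        z = z * instance.conditioning
    z = z + entry["z_offset"]
    values = _BASES[entry["base"]](z) + instance.bias
    return float(values[0]) if single else values


def summarize_runs(final_values: np.ndarray, bias: float) -> RunStatistics:
    """Best/worst/mean/sample-std/MAE summary of independent-run finals."""
    v = np.asarray(final_values, dtype=float)
    if v.size == 0:
        raise ValueError("need at least one run value")
    return RunStatistics(
        best=float(v.min()), worst=float(v.max()), mean=float(v.mean()),
        std=float(v.std(ddof=1)) if v.size > 1 else 0.0,
        mae=float(np.abs(v - bias).mean()), n_runs=int(v.size))


def load_instance_data(path) -> np.ndarray:
    """Read official instance data stored as a whitespace-separated matrix."""
    return np.loadtxt(path)
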